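"""NMR processing and fraction clustering: interpolation, Lorentzian peak
fitting, integration, Canberra distances, ward.D2 agglomeration and session
planning."""

import numpy as np
import pytest

from sensomics.nmr import (
    ClusterAssignment,
    NmrSpectrum,
    PeakMatrix,
    canberra_distance,
    canberra_condensed,
    cluster_fractions,
    consensus_peaks,
    default_grid,
    detect_peaks,
    integrate_peaks,
    normalize_spectra,
    plan_sessions,
    resample_spectrum,
)


def _lorentz(x, c, g, h):
    return h * g**2 / ((x - c) ** 2 + g**2)


def _spec(y, grid=None, sid="S"):
    grid = np.linspace(0.0, 14.85, len(y)) if grid is None else grid
    return NmrSpectrum(sid, grid, np.asarray(y, float))


# --- resampling ------------------------------------------------------------


def test_resample_constant_stays_constant():
    s = _spec(np.full(100, 3.7))
    r = resample_spectrum(s, n_points=257)
    np.testing.assert_allclose(r.intensity, 3.7)


def test_resample_identity_on_own_grid():
    grid = np.linspace(0.0, 14.85, 300)
    y = np.sin(grid)
    r = resample_spectrum(_spec(y, grid), 0.0, 14.85, 300)
    np.testing.assert_allclose(r.intensity, y, atol=1e-12)


def test_resample_linear_ramp_exact_at_midpoints():
    grid = np.linspace(0.0, 10.0, 11)
    s = NmrSpectrum("S", grid, 2.0 * grid)
    r = resample_spectrum(s, 0.0, 10.0, 21)
    np.testing.assert_allclose(r.intensity, 2.0 * r.ppm, atol=1e-12)


def test_resample_outside_support_zeroed():
    grid = np.linspace(4.0, 6.0, 50)
    r = resample_spectrum(NmrSpectrum("S", grid, np.ones(50)), 0.0, 14.85, 100)
    assert r.intensity[r.ppm < 4.0].max(initial=0.0) == 0.0
    assert r.intensity[r.ppm > 6.0].max(initial=0.0) == 0.0


def test_resample_no_overlap_raises():
    grid = np.linspace(20.0, 25.0, 10)
    with pytest.raises(ValueError):
        resample_spectrum(NmrSpectrum("S", grid, np.ones(10)), 0.0, 14.85, 50)


def test_default_grid_median_spacing():
    grids = [np.arange(0, 14.85, 0.005), np.arange(0, 14.85, 0.005)]
    spectra = [NmrSpectrum(f"S{i}", g, np.zeros_like(g)) for i, g in enumerate(grids)]
    n = default_grid(spectra)
    assert n == pytest.approx(14.85 / 0.005 + 1, abs=1.5)


# --- peak detection --------------------------------------------------------


def test_single_lorentzian_recovered():
    grid = np.arange(0.0, 14.85, 0.001)
    y = _lorentz(grid, 5.0, 0.005, 100.0)
    peaks = detect_peaks(_spec(y, grid), min_height=1.0)
    assert len(peaks) == 1
    c, g, h = peaks[0]
    assert c == pytest.approx(5.0, abs=1e-3)
    assert h == pytest.approx(100.0, rel=0.01)
    assert g == pytest.approx(0.005, rel=0.05)


def test_two_lorentzians_one_ppm_apart():
    grid = np.arange(0.0, 14.85, 0.001)
    y = _lorentz(grid, 4.0, 0.006, 50.0) + _lorentz(grid, 5.0, 0.004, 80.0)
    peaks = sorted(detect_peaks(_spec(y, grid), min_height=1.0))
    assert len(peaks) == 2
    assert peaks[0][0] == pytest.approx(4.0, abs=2e-3)
    assert peaks[1][0] == pytest.approx(5.0, abs=2e-3)


def test_flat_spectrum_no_peaks():
    assert detect_peaks(_spec(np.zeros(500)), min_height=0.1) == []


# --- normalization ---------------------------------------------------------


def test_normalize_scale_invariance():
    y = np.abs(np.sin(np.linspace(0, 3, 200))) + 0.1
    a = normalize_spectra([_spec(y)])[0]
    b = normalize_spectra([_spec(10.0 * y)])[0]
    np.testing.assert_allclose(a.intensity, b.intensity, atol=1e-14)
    assert a.intensity.sum() == pytest.approx(1.0)


def test_normalize_all_zero_raises():
    with pytest.raises(ValueError):
        normalize_spectra([_spec(np.zeros(50))])


def test_normalize_pqn_handles_dilution():
    y = np.abs(np.sin(np.linspace(0, 3, 200))) + 0.1
    spectra = [_spec(y, sid="a"), _spec(2.0 * y, sid="b"), _spec(0.5 * y, sid="c")]
    out = normalize_spectra(spectra, method="pqn")
    for s in out[1:]:
        np.testing.assert_allclose(s.intensity, out[0].intensity, rtol=1e-9)


# --- consensus + integration ----------------------------------------------


def test_consensus_merges_nearby_centers():
    lists = [[(5.000, 0.01, 1.0)], [(5.004, 0.01, 1.0)], [(7.0, 0.01, 1.0)]]
    centers = consensus_peaks(lists, width=0.01)
    np.testing.assert_allclose(centers, [5.002, 7.0])


def test_integrate_rectangular_pulse_closed_form():
    grid = np.arange(0.0, 10.0, 0.001)
    h, width = 4.0, 0.01
    y = np.where(np.abs(grid - 5.0) <= width, h, 0.0)  # wider than the window
    pm = integrate_peaks([_spec(y, grid)], np.array([5.0]), width=width)
    assert pm.areas[0, 0] == pytest.approx(h * width, rel=1e-9)


def test_integrate_linearity_and_absence():
    grid = np.arange(0.0, 10.0, 0.001)
    y = _lorentz(grid, 5.0, 0.02, 10.0)
    pm1 = integrate_peaks([_spec(y, grid)], np.array([5.0, 8.0]))
    pm2 = integrate_peaks([_spec(2 * y, grid)], np.array([5.0, 8.0]))
    assert pm2.areas[0, 0] == pytest.approx(2 * pm1.areas[0, 0], rel=1e-12)
    assert pm1.areas[0, 1] == pytest.approx(0.0, abs=1e-5)  # far-tail leakage only


def test_peak_matrix_rejects_negative_areas():
    with pytest.raises(ValueError):
        PeakMatrix(["a"], np.array([1.0]), np.array([[-0.1]]))


# --- Canberra --------------------------------------------------------------


def test_canberra_closed_forms():
    assert canberra_distance([1, 0], [0, 1]) == pytest.approx(2.0)
    assert canberra_distance([3, 4, 5], [3, 4, 5]) == 0.0
    expect = 9 / 11 + 9.4 / 11.6
    assert canberra_distance([1, 1.1], [10, 10.5]) == pytest.approx(expect, abs=1e-12)


def test_canberra_zero_zero_terms_ignored():
    assert canberra_distance([0, 1, 0], [0, 1, 0]) == 0.0


def test_canberra_matches_scipy(rng):
    from scipy.spatial.distance import pdist

    x = rng.uniform(0, 5, size=(8, 6))
    np.testing.assert_allclose(canberra_condensed(x), pdist(x, "canberra"), atol=1e-12)


def test_canberra_length_mismatch():
    with pytest.raises(ValueError):
        canberra_distance([1, 2], [1, 2, 3])


# --- clustering ------------------------------------------------------------


def _two_group_matrix(rng, n_per=6):
    a = np.array([5.0, 1.0, 0.0, 0.0, 2.0])
    b = np.array([0.0, 0.0, 4.0, 3.0, 0.5])
    rows, truth = [], []
    for i in range(2 * n_per):
        base = a if i % 2 == 0 else b
        rows.append(base * rng.uniform(0.7, 1.3) + rng.uniform(0, 0.01, 5))
        truth.append(i % 2)
    return np.array(rows), truth


def test_cluster_two_planted_groups_ari_one(rng):
    from sklearn.metrics import adjusted_rand_score

    areas, truth = _two_group_matrix(rng)
    pm = PeakMatrix([f"F{i:02d}" for i in range(len(truth))], np.arange(5.0), areas)
    ca = cluster_fractions(pm, k=2)
    labels = [ca.labels[s] for s in pm.sample_ids]
    assert adjusted_rand_score(truth, labels) == 1.0


def test_cluster_permutation_invariance(rng):
    areas, _ = _two_group_matrix(rng)
    ids = [f"F{i:02d}" for i in range(areas.shape[0])]
    ca1 = cluster_fractions(PeakMatrix(ids, np.arange(5.0), areas), k=2)
    perm = rng.permutation(len(ids))
    ca2 = cluster_fractions(
        PeakMatrix([ids[i] for i in perm], np.arange(5.0), areas[perm]), k=2
    )
    part1 = {s: ca1.labels[s] for s in ids}
    part2 = {s: ca2.labels[s] for s in ids}
    # identical partition up to label renaming
    mapping = {}
    for s in ids:
        mapping.setdefault(part1[s], part2[s])
        assert mapping[part1[s]] == part2[s]


def test_cluster_k_equals_n_singletons(rng):
    areas = rng.uniform(0.1, 1.0, size=(5, 4))
    pm = PeakMatrix(list("abcde"), np.arange(4.0), areas)
    ca = cluster_fractions(pm, k=5)
    assert sorted(ca.labels.values()) == [1, 2, 3, 4, 5]


def test_cluster_k_out_of_range(rng):
    pm = PeakMatrix(["a", "b"], np.arange(3.0), rng.uniform(size=(2, 3)))
    with pytest.raises(ValueError):
        cluster_fractions(pm, k=3)


def ward_d2_replay(dm, stop_at=1):
    """Naive O(n^3) ward.D2 agglomeration on a full dissimilarity matrix.

    Replays the Lance-Williams recurrence from singletons, returning the
    merge heights and the remaining clusters when ``stop_at`` are left.
    """
    n = dm.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {frozenset((i, j)): dm[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    next_id = n
    while len(clusters) > stop_at:
        (i, j), dij = min(dist.items(), key=lambda kv: (kv[1], sorted(kv[0])))
        i, j = sorted((i, j))
        heights.append(dij)
        ni, nj = len(clusters[i]), len(clusters[j])
        merged = clusters[i] + clusters[j]
        new_dist = {}
        for k in clusters:
            if k in (i, j):
                continue
            nk = len(clusters[k])
            dik, djk = dist[frozenset((i, k))], dist[frozenset((j, k))]
            new_dist[frozenset((next_id, k))] = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
        clusters.pop(i)
        clusters.pop(j)
        dist = {key: v for key, v in dist.items() if i not in key and j not in key}
        dist.update(new_dist)
        clusters[next_id] = merged
        next_id += 1
    return heights, clusters


def test_cluster_matches_bruteforce_lance_williams(rng):
    """The implementation's tree equals a naive replay of the ward.D2
    Lance-Williams recurrence (heights and k-cut partition)."""
    from scipy.cluster.hierarchy import fcluster
    from sklearn.metrics import adjusted_rand_score

    for n in (6, 9, 10):
        areas = rng.uniform(0.0, 4.0, size=(n, 6))
        pm = PeakMatrix([f"s{i}" for i in range(n)], np.arange(6.0), areas)
        ca = cluster_fractions(pm, k=3)
        d = canberra_condensed(np.sqrt(areas))
        dm = np.zeros((n, n))
        dm[np.triu_indices(n, 1)] = d
        dm += dm.T
        heights, _ = ward_d2_replay(dm, stop_at=1)
        np.testing.assert_allclose(
            sorted(heights), sorted(ca.linkage_matrix[:, 2]), rtol=1e-9
        )
        _, clusters = ward_d2_replay(dm, stop_at=3)
        oracle_labels = np.empty(n, dtype=int)
        for lab, (_, members) in enumerate(sorted(clusters.items())):
            oracle_labels[members] = lab
        impl = fcluster(ca.linkage_matrix, t=3, criterion="maxclust")
        assert adjusted_rand_score(oracle_labels, impl) == 1.0


@pytest.fixture(scope="module")
def simulated_nmr_stage(default_world):
    import sensomics as sm
    from sensomics.pipeline import cluster_nmr_stage
    from sensomics.config import RunConfig

    gt, *_ = default_world
    spectra = sm.simulate_nmr_spectra(gt)
    return cluster_nmr_stage(spectra, RunConfig(), None)


def test_merge_heights_monotone(simulated_nmr_stage):
    _, ca, _ = simulated_nmr_stage
    assert np.all(np.diff(ca.linkage_matrix[:, 2]) >= -1e-9)


def test_sqrt_applied_exactly_once(rng):
    # feeding pre-square-rooted areas must give the same tree as letting the
    # implementation do the transform on the squared matrix
    from scipy.cluster.hierarchy import linkage

    areas = rng.uniform(0.0, 4.0, size=(7, 5))
    pm = PeakMatrix([f"s{i}" for i in range(7)], np.arange(5.0), areas)
    ca = cluster_fractions(pm, k=3)
    manual = linkage(canberra_condensed(np.sqrt(areas)), method="ward")
    np.testing.assert_allclose(ca.linkage_matrix[:, 2], manual[:, 2], rtol=1e-12)


# --- session planning ------------------------------------------------------


def _assignment(labels):
    return ClusterAssignment(labels=labels, linkage_matrix=np.empty((0, 4)), k=len(set(labels.values())))


def test_oversized_cluster_split_seven_two():
    labels = {f"F{i:02d}": 1 for i in range(9)}
    plan = plan_sessions(_assignment(labels), max_per_session=7)
    sizes = [len(s.fractions) for s in plan.sessions]
    assert sizes == [7, 2]


def test_small_clusters_one_session_each():
    labels = {f"F{i:02d}": 1 + i // 4 for i in range(12)}
    plan = plan_sessions(_assignment(labels), max_per_session=7)
    assert len(plan.sessions) == 3
    assert all(len(s.fractions) <= 7 for s in plan.sessions)


def test_sessions_conserve_fractions(simulated_nmr_stage):
    _, ca, plan = simulated_nmr_stage
    assert sorted(plan.all_fractions) == sorted(ca.labels)
    assert max(len(s.fractions) for s in plan.sessions) <= 7
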