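"""End-to-end driver: simulate (or load) -> cluster NMR -> process sensory
-> correlate -> report.

Each stage writes its artifacts under the run directory and contributes its
counts to the :class:`RunReport`; any stage error aborts with a
stage-labeled message. All randomness flows from the single config seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pathlib import Path

from . import __version__, io
from .config import RunConfig
from .correlate import run_correlation
from .nmr import (
    cluster_fractions,
    consensus_peaks,
    default_grid,
    detect_peaks,
    integrate_peaks,
    normalize_spectra,
    plan_sessions,
    resample_spectrum,
)
from .sensory import (
    aggregate_profile,
    build_descriptor_network,
    compute_working_concentrations,
    consensus_filter,
    map_descriptors,
    mass_normalize,
)
from .simulate import (
    generate_ground_truth,
    PanelModel,
    simulate_feature_table,
    simulate_fraction_masses,
    simulate_nmr_spectra,
    simulate_taste_records,
)

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run_all"]


@dataclass
class RunReport:
    version: str
    config_hash: str
    counts: dict = field(default_factory=dict)
    wall_clock_s: float = 0.0

    def result_hash(self) -> str:
        """Hash of the scientific outputs (excludes wall clock and paths)."""
        import hashlib
        import json

        canon = json.dumps(
            {"version": self.version, "counts": self.counts}, sort_keys=True
        )
        return hashlib.sha1(canon.encode()).hexdigest()[:12]


class StageError(RuntimeError):
    pass


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


@_stage("simulate")
def _inputs(cfg: RunConfig, out: Path):
    """Load user-supplied inputs or simulate the synthetic scenario."""
    if cfg.features_path:
        ft = io.read_feature_table(cfg.features_path)
        records = io.read_taste_records(cfg.records_path) if cfg.records_path else None
        cmap = (
            io.read_category_map(cfg.category_map_path)
            if cfg.category_map_path
            else None
        )
        masses = io.read_masses(cfg.masses_path) if cfg.masses_path else None
        spectra = io.read_spectra_dir(cfg.spectra_dir) if cfg.spectra_dir else None
        return ft, records, cmap, masses, spectra, None

    panel = PanelModel(n_panelists=cfg.n_panelists, noise_sd=cfg.noise_sd)
    gt = generate_ground_truth(
        cfg.n_compounds, cfg.n_fractions, cfg.n_active, cfg.seed, panel=panel
    )
    ft = simulate_feature_table(gt, cfg.noise_cv, cfg.detection_limit)
    records = simulate_taste_records(gt, ft)
    masses = simulate_fraction_masses(gt)
    spectra = simulate_nmr_spectra(gt)
    cmap = {
        syn: cat for cat, syns in panel.synonym_table.items() for syn in syns
    }
    h = None
    inputs = out / "inputs"
    io.write_feature_table(ft, inputs / "features.csv", h)
    io.write_taste_records(records, inputs / "taste_records.csv", h)
    io.write_category_map(cmap, inputs / "category_map.csv", h)
    io.write_masses(masses, inputs / "fraction_masses.csv", h)
    io.write_spectra_dir(spectra, inputs / "spectra", h)
    gt.to_json(inputs / "ground_truth.json")
    return ft, records, cmap, masses, spectra, gt


@_stage("cluster-nmr")
def cluster_nmr_stage(spectra, cfg: RunConfig, out: Path | None, config_hash=None):
    """Resample, normalize, peak-pick, integrate, cluster, plan sessions."""
    if cfg.ppm_offsets:
        from .nmr import NmrSpectrum

        spectra = [
            NmrSpectrum(
                s.sample_id,
                s.ppm + cfg.ppm_offsets.get(s.sample_id, 0.0),
                s.intensity,
            )
            for s in spectra
        ]
    n_points = default_grid(spectra)
    resampled = [resample_spectrum(s, n_points=n_points) for s in spectra]
    normed = normalize_spectra(resampled, cfg.normalization)
    if cfg.peak_min_height is not None:
        min_height = cfg.peak_min_height
    else:
        # adaptive: well above the flat baseline of a unit-sum spectrum
        min_height = 5.0 * float(np.mean([s.intensity.mean() for s in normed]))
    peak_lists = [detect_peaks(s, min_height) for s in normed]
    centers = consensus_peaks(peak_lists, cfg.integration_width)
    pm = integrate_peaks(normed, centers, cfg.integration_width)
    ca = cluster_fractions(pm, cfg.k_clusters)
    plan = plan_sessions(ca, cfg.max_per_session)
    if out is not None:
        io.write_peak_matrix(pm, out / "nmr_peak_matrix.tsv", config_hash)
        io.write_cluster_labels(ca, out / "nmr_clusters.tsv", config_hash)
        io.write_session_plan(plan, out / "session_plan.yaml", config_hash)
        io.write_dendrogram(ca, out / "nmr_dendrogram.nwk", config_hash)
    return pm, ca, plan


@_stage("process-sensory")
def sensory_stage(
    records, cmap, masses, fractions, cfg: RunConfig,
    cluster_of=None, out: Path | None = None, config_hash=None,
):
    """Map, consensus-filter, aggregate, mass-normalize, network, dosing."""
    mapped = map_descriptors(records, cmap)
    kept = consensus_filter(mapped, cfg.min_panelists)
    categories = sorted(set(cmap.values()) | set(kept.get("category", [])))
    tp = aggregate_profile(kept, fractions=fractions, categories=categories)
    dosing = None
    if masses is not None:
        tp = mass_normalize(tp, masses)
        shares = masses / masses.sum()
        dosing = compute_working_concentrations(
            shares, cfg.base_concentration, cfg.cluster_factors, cluster_of or {}
        )
    net = build_descriptor_network(mapped)
    if out is not None:
        io.write_taste_profile(tp, out / "taste_profile.tsv", config_hash)
        io.write_network(
            net, out / "descriptor_network.graphml", out / "descriptor_edges.tsv",
            config_hash,
        )
        if dosing is not None:
            io._write_df(
                dosing.reset_index(), out / "dosing_plan.csv", config_hash=config_hash
            )
    return tp, net, dosing, mapped, kept


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage in order; deterministic under the config seed."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    config.to_yaml(out / "config.yaml")
    counts: dict = {}

    ft, records, cmap, masses, spectra, gt = _inputs(config, out)
    counts["n_fractions"] = len(ft.fractions)
    counts["n_features"] = ft.n_features
    counts["n_taste_records"] = 0 if records is None else int(len(records))

    cluster_of = None
    if spectra is not None:
        if config.k_clusters > len(spectra):
            raise StageError(
                f"[cluster-nmr] k={config.k_clusters} exceeds "
                f"{len(spectra)} fractions"
            )
        pm, ca, plan = cluster_nmr_stage(spectra, config, out, h)
        cluster_of = ca.labels
        counts["n_nmr_peaks"] = int(pm.centers.size)
        counts["n_clusters"] = ca.k
        counts["n_sessions"] = len(plan.sessions)

    tp = None
    if records is not None and cmap is not None:
        tp, net, dosing, mapped, kept = sensory_stage(
            records, cmap, masses, ft.fractions, config, cluster_of, out, h
        )
        counts["n_consensus_records"] = int(len(kept))
        counts["n_descriptors"] = net.number_of_nodes()

    if tp is not None:
        report = run_correlation(ft, tp, config.correlation_config())
        io.write_correlation_records(
            report.records, out / "correlation_records.tsv", h
        )
        io.write_correlation_records(
            report.summary, out / "correlation_summary.tsv", h
        )
        counts.update(
            {k: v for k, v in report.meta.items() if isinstance(v, (int, float))}
        )

    rr = RunReport(
        version=__version__,
        config_hash=h,
        counts=counts,
        wall_clock_s=round(time.perf_counter() - t0, 3),
    )
    io.write_json(
        {
            "version": rr.version,
            "config_hash": rr.config_hash,
            "result_hash": rr.result_hash(),
            "counts": rr.counts,
            "wall_clock_s": rr.wall_clock_s,
        },
        out / "run_metadata.json",
    )
    return rr
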