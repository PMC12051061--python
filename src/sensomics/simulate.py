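"""Synthetic fractionation study generator with a planted ground truth.

Emulates the data layout of a taste-guided fractionation campaign on a
bitter botanical extract: ~50 ordered chromatographic fractions, a few
hundred LC-MS features with bell-shaped elution profiles and left-censored
detection, per-fraction 1H NMR spectra built from Lorentzian resonances
shared within compound families, per-fraction dry masses, and ordinal 0-10
sensory scores from a small panel driven by a saturating dose-response on
the planted taste-active compounds.

Every generator is a pure function of its arguments and the ground-truth
seed, so the same :class:`GroundTruth` always reproduces bit-identical
inputs for the downstream pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .correlate import FeatureTable
from .nmr import NmrSpectrum

__all__ = [
    "CompoundSpec",
    "PanelModel",
    "GroundTruth",
    "DEFAULT_CATEGORIES",
    "DEFAULT_SYNONYMS",
    "generate_ground_truth",
    "simulate_feature_table",
    "simulate_nmr_spectra",
    "simulate_taste_records",
    "simulate_fraction_masses",
    "fraction_ids",
]

#: Curated taste categories used by default (the real study curated >200 raw
#: descriptors into 14 groups; ten suffice for a synthetic panel).
DEFAULT_CATEGORIES = (
    "bitter",
    "sweet",
    "sour",
    "astringent",
    "pungent",
    "metallic",
    "fatty",
    "floral",
    "woody",
    "cooling",
)

#: Raw free-vocabulary descriptors a panelist may emit per category
#: (deliberately bilingual, as free profiling vocabularies tend to be).
DEFAULT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "bitter": ("bitter", "amer", "harsh bitter"),
    "sweet": ("sweet", "sucre", "honey"),
    "sour": ("sour", "acide", "tart"),
    "astringent": ("astringent", "drying", "tannic"),
    "pungent": ("pungent", "piquant", "spicy"),
    "metallic": ("metallic", "metallique", "iron"),
    "fatty": ("fatty", "gras", "oily"),
    "floral": ("floral", "fleuri", "rose"),
    "woody": ("woody", "boise", "oak"),
    "cooling": ("cooling", "frais", "menthol"),
}

#: Characteristic 1H shift motifs (ppm) per compound family; individual
#: compounds jitter around these and add private resonances.
_FAMILY_SHIFTS: dict[str, tuple[float, ...]] = {
    "iridoid": (1.1, 2.6, 4.6, 5.5, 7.4),
    "xanthone": (3.9, 6.3, 6.8, 7.8, 12.9),
    "flavonoid": (3.8, 5.0, 6.2, 6.9, 8.1),
    "triterpene": (0.9, 1.3, 1.6, 2.3, 5.3),
}
_FAMILIES = tuple(_FAMILY_SHIFTS)


def fraction_ids(n_fractions: int) -> list[str]:
    """Ordered, lexicographic-safe fraction identifiers F01..Fnn."""
    width = max(2, len(str(n_fractions)))
    return [f"F{j:0{width}d}" for j in range(1, n_fractions + 1)]


@dataclass(frozen=True)
class CompoundSpec:
    """One simulated constituent of the extract."""

    compound_id: str
    family: str
    elution_center: float  # fraction-index units, 1-based
    elution_width: float
    abundance: float  # peak LC-MS intensity, arbitrary units
    nmr_shifts: tuple[tuple[float, float], ...]  # (ppm center, rel. height)
    taste_potencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.elution_width <= 0:
            raise ValueError("elution_width must be > 0")
        if self.abundance <= 0:
            raise ValueError("abundance must be > 0")
        if any(p < 0 for p in self.taste_potencies.values()):
            raise ValueError("taste potencies must be >= 0")

    @property
    def is_active(self) -> bool:
        return any(p > 0 for p in self.taste_potencies.values())

    def elution_profile(self, n_fractions: int) -> np.ndarray:
        """Relative concentration per fraction (Gaussian in fraction index, peak 1)."""
        j = np.arange(1, n_fractions + 1, dtype=float)
        return np.exp(
            -((j - self.elution_center) ** 2) / (2.0 * self.elution_width**2)
        )


@dataclass(frozen=True)
class PanelModel:
    """Psychophysical model of the sensory panel.

    A panelist's expected intensity for stimulus ``S`` follows a saturating
    Hill-type dose-response ``scale * S / (S + dose_halfsat)``; Gaussian
    noise is added before rounding to the integer 0-10 scale. A zero score
    is never emitted (it means "not reported"). ``detection_prob`` rises
    with the stimulus from a small false-alarm floor at S = 0, so weak and
    null tastes are reported only sporadically.
    """

    n_panelists: int = 12
    score_scale_max: int = 10
    dose_halfsat: float = 0.4
    noise_sd: float = 1.0
    detection_floor: float = 0.05  # false-alarm report probability at S = 0
    detection_scale: float = 0.15  # stimulus scale of the detection rise
    synonym_table: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SYNONYMS)
    )

    def __post_init__(self):
        if self.n_panelists < 2:
            raise ValueError("need at least 2 panelists")
        if self.dose_halfsat <= 0:
            raise ValueError("dose_halfsat must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.detection_floor <= 1.0:
            raise ValueError("detection_floor must be a probability")

    def detection_prob(self, stimulus: np.ndarray) -> np.ndarray:
        """Probability that a panelist reports the taste at all."""
        s = np.asarray(stimulus, dtype=float)
        return 1.0 - (1.0 - self.detection_floor) * np.exp(-s / self.detection_scale)

    def expected_intensity(self, stimulus: np.ndarray) -> np.ndarray:
        s = np.asarray(stimulus, dtype=float)
        return self.score_scale_max * s / (s + self.dose_halfsat)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.synonym_table)


@dataclass(frozen=True)
class GroundTruth:
    """Planted compound inventory, panel model and study geometry."""

    compounds: tuple[CompoundSpec, ...]
    n_fractions: int
    seed: int
    panel: PanelModel

    def __post_init__(self):
        if self.n_fractions < 5:
            raise ValueError("need at least 5 fractions")
        for c in self.compounds:
            if not 1 <= c.elution_center <= self.n_fractions:
                raise ValueError(
                    f"{c.compound_id}: elution_center outside [1, n_fractions]"
                )

    @property
    def fraction_ids(self) -> list[str]:
        return fraction_ids(self.n_fractions)

    @property
    def active_compounds(self) -> tuple[CompoundSpec, ...]:
        return tuple(c for c in self.compounds if c.is_active)

    def planted_pairs(self) -> list[tuple[str, str]]:
        """(compound_id, category) pairs with positive planted potency."""
        return [
            (c.compound_id, cat)
            for c in self.compounds
            for cat, pot in sorted(c.taste_potencies.items())
            if pot > 0
        ]

    def stimulus_matrix(self) -> pd.DataFrame:
        """Noise-free taste stimulus per (fraction, category)."""
        cats = self.panel.categories
        s = np.zeros((self.n_fractions, len(cats)))
        for c in self.compounds:
            if not c.is_active:
                continue
            prof = c.elution_profile(self.n_fractions)
            for k, cat in enumerate(cats):
                pot = c.taste_potencies.get(cat, 0.0)
                if pot > 0:
                    s[:, k] += pot * prof
        return pd.DataFrame(s, index=self.fraction_ids, columns=list(cats))

    def to_json(self, path) -> None:
        obj = asdict(self)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        panel = obj["panel"]
        panel["synonym_table"] = {
            k: tuple(v) for k, v in panel["synonym_table"].items()
        }
        compounds = tuple(
            CompoundSpec(
                compound_id=c["compound_id"],
                family=c["family"],
                elution_center=c["elution_center"],
                elution_width=c["elution_width"],
                abundance=c["abundance"],
                nmr_shifts=tuple((p, h) for p, h in c["nmr_shifts"]),
                taste_potencies=c["taste_potencies"],
            )
            for c in obj["compounds"]
        )
        return cls(
            compounds=compounds,
            n_fractions=obj["n_fractions"],
            seed=obj["seed"],
            panel=PanelModel(**panel),
        )


def _rng(gt_seed: int, stream: int) -> np.random.Generator:
    # independent, reproducible substream per generator
    return np.random.default_rng([gt_seed & 0x7FFFFFFF, stream])


def generate_ground_truth(
    n_compounds: int,
    n_fractions: int,
    n_active: int,
    seed: int,
    panel: PanelModel | None = None,
) -> GroundTruth:
    """Draw a compound inventory with ``n_active`` planted taste-actives.

    Active compounds get one taste category each (distinct while categories
    last, starting with bitter), elution centers spread over the middle of
    the fraction range, and abundances in the upper intensity range (taste
    correlates in such campaigns are major constituents).
    """
    if n_active < 0 or n_compounds < 0 or n_active > n_compounds:
        raise ValueError("need 0 <= n_active <= n_compounds")
    if n_fractions < 10:
        raise ValueError("need n_fractions >= 10")
    panel = panel or PanelModel()
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    cats = list(panel.categories)
    width = len(str(n_compounds))

    # spread active elution centers evenly with jitter so their taste
    # signals occupy distinct stretches of the fraction order
    if n_active:
        base = np.linspace(0.2 * n_fractions, 0.8 * n_fractions, n_active)
        active_centers = base + rng.uniform(-1.5, 1.5, size=n_active)
        active_cats = [cats[i % len(cats)] for i in range(n_active)]

    compounds = []
    for i in range(n_compounds):
        active = i < n_active
        family = _FAMILIES[int(rng.integers(len(_FAMILIES)))]
        if active:
            center = float(np.clip(active_centers[i], 2.0, n_fractions - 1.0))
            abundance = float(np.exp(rng.normal(math.log(3e6), 0.25)))
        else:
            center = float(rng.uniform(3.0, n_fractions - 2.0))
            abundance = float(np.exp(rng.normal(math.log(1e6), 1.0)))
        width_frac = float(rng.uniform(1.5, 2.0))
        shifts = []
        for ppm in _FAMILY_SHIFTS[family]:
            shifts.append(
                (
                    float(np.clip(ppm + rng.normal(0.0, 0.05), 0.02, 14.8)),
                    float(np.exp(rng.normal(0.0, 0.4))),
                )
            )
        # one private resonance distinguishing the compound
        shifts.append(
            (float(rng.uniform(0.5, 9.0)), float(np.exp(rng.normal(-0.3, 0.4))))
        )
        potencies: dict[str, float] = {}
        if active:
            potencies[active_cats[i]] = float(rng.uniform(0.45, 0.65))
        compounds.append(
            CompoundSpec(
                compound_id=f"C{i + 1:0{width}d}",
                family=family,
                elution_center=center,
                elution_width=width_frac,
                abundance=abundance,
                nmr_shifts=tuple(shifts),
                taste_potencies=potencies,
            )
        )
    return GroundTruth(
        compounds=tuple(compounds), n_fractions=n_fractions, seed=seed, panel=panel
    )


def simulate_feature_table(
    gt: GroundTruth,
    noise_cv: float = 0.1,
    detection_limit: float = 5e4,
) -> FeatureTable:
    """LC-MS feature intensity table: one feature per compound.

    Intensity of feature *f* in fraction *j* is the Gaussian elution profile
    scaled by abundance, times multiplicative lognormal noise with
    coefficient of variation ``noise_cv``; values below ``detection_limit``
    are left-censored (recorded as missing).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if detection_limit < 0:
        raise ValueError("detection_limit must be >= 0")
    rng = _rng(gt.seed, 1)
    n = gt.n_fractions
    frac_ids = gt.fraction_ids
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0

    rows, meta = [], []
    mz_ranges = {
        "iridoid": (330.0, 600.0),
        "xanthone": (240.0, 700.0),
        "flavonoid": (270.0, 750.0),
        "triterpene": (400.0, 950.0),
    }
    for c in gt.compounds:
        profile = c.abundance * c.elution_profile(n)
        if sigma > 0:
            profile = profile * np.exp(rng.normal(0.0, sigma, size=n))
        else:
            rng.normal(0.0, 1.0, size=n)  # keep the stream aligned
        values = np.where(profile >= detection_limit, profile, np.nan)
        lo, hi = mz_ranges[c.family]
        mz = float(rng.uniform(lo, hi))
        # reverse-phase-like retention: later fractions elute more apolar
        rt = float(0.2 * c.elution_center + rng.normal(0.0, 0.3))
        rows.append(values)
        meta.append(
            {
                "feature_id": f"M_{c.compound_id}",
                "mz": round(mz, 4),
                "rt": round(max(rt, 0.1), 2),
                "annotation": "",
            }
        )
    features = pd.DataFrame(meta).set_index("feature_id")
    intensities = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n)),
        index=features.index,
        columns=frac_ids,
    )
    return FeatureTable(features=features, intensities=intensities)


def simulate_nmr_spectra(
    gt: GroundTruth,
    grid_step: float = 0.002,
    gamma: float = 0.008,
    baseline_sd: float = 1e-3,
    ppm_max: float = 14.85,
) -> list[NmrSpectrum]:
    """Per-fraction 1H spectra: sums of Lorentzian resonances + baseline noise.

    Each compound contributes its family's shift motif scaled by its
    concentration in the fraction (relative profile x abundance / 1e6).
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    rng = _rng(gt.seed, 2)
    ppm = np.arange(0.0, ppm_max + grid_step / 2, grid_step)
    n = gt.n_fractions
    signal = np.zeros((n, ppm.size))
    for c in gt.compounds:
        conc = (c.abundance / 1e6) * c.elution_profile(n)
        shape = np.zeros_like(ppm)
        for center, height in c.nmr_shifts:
            shape += height * gamma**2 / ((ppm - center) ** 2 + gamma**2)
        signal += conc[:, None] * shape[None, :]
    spectra = []
    for j, fid in enumerate(gt.fraction_ids):
        noise = rng.normal(0.0, baseline_sd, size=ppm.size) if baseline_sd > 0 else 0.0
        spectra.append(NmrSpectrum(sample_id=fid, ppm=ppm, intensity=signal[j] + noise))
    return spectra


def simulate_taste_records(
    gt: GroundTruth, ft: FeatureTable | None = None
) -> pd.DataFrame:
    """Long-format panelist records (panelist, fraction, descriptor_raw, score).

    Stimulus for (fraction, category) is the potency-weighted sum of the
    planted compounds' relative concentrations. Each panelist's score is the
    Hill-type expected intensity plus Gaussian noise, rounded and clipped to
    the 0-10 scale; zero scores and non-detections emit no record.
    """
    if ft is not None and list(ft.fractions) != gt.fraction_ids:
        raise ValueError("feature table fraction set differs from ground truth")
    panel = gt.panel
    rng = _rng(gt.seed, 3)
    cats = list(panel.categories)
    stim = gt.stimulus_matrix().to_numpy()  # (n_fractions, n_cats)
    n_p, n_f, n_c = panel.n_panelists, gt.n_fractions, len(cats)

    expected = panel.expected_intensity(stim)
    noise = rng.normal(0.0, panel.noise_sd, size=(n_p, n_f, n_c)) if panel.noise_sd else np.zeros((n_p, n_f, n_c))
    scores = np.clip(np.rint(expected[None, :, :] + noise), 0, panel.score_scale_max)
    detect = rng.random(size=(n_p, n_f, n_c)) < panel.detection_prob(stim)[None, :, :]
    syn_idx = rng.integers(0, 10**9, size=(n_p, n_f, n_c))

    frac_ids = gt.fraction_ids
    pw = len(str(n_p))
    recs = []
    for p in range(n_p):
        for j in range(n_f):
            for k in range(n_c):
                sc = int(scores[p, j, k])
                if sc < 1 or not detect[p, j, k]:
                    continue
                syns = panel.synonym_table[cats[k]]
                recs.append(
                    (
                        f"P{p + 1:0{pw}d}",
                        frac_ids[j],
                        syns[syn_idx[p, j, k] % len(syns)],
                        sc,
                    )
                )
    return pd.DataFrame(
        recs, columns=["panelist", "fraction", "descriptor_raw", "score"]
    )


def simulate_fraction_masses(
    gt: GroundTruth,
    floor_mg: float = 2.0,
    mg_per_unit: float = 5.0,
    noise_cv: float = 0.05,
) -> pd.Series:
    """Per-fraction dry masses (mg): compound content plus a small floor.

    An empty fraction still weighs a little (salts, residues); masses are
    strictly positive.
    """
    rng = _rng(gt.seed, 4)
    n = gt.n_fractions
    content = np.zeros(n)
    for c in gt.compounds:
        content += (c.abundance / 1e6) * c.elution_profile(n)
    mass = floor_mg + mg_per_unit * content
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        mass = mass * np.exp(rng.normal(0.0, sigma, size=n))
    return pd.Series(mass, index=gt.fraction_ids, name="mass_mg")
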