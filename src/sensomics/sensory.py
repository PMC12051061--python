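"""Sensory panel data processing.

Raw free-profiling records (panelist, fraction, raw descriptor, 0-10
score) are harmonized into curated categories, consensus-filtered (a taste
counts only when at least two panelists reported it for a fraction),
summed into a fraction x category taste profile, and normalized by
fraction dry mass. Also here: the descriptor co-occurrence network,
fractionation recovery bookkeeping, and working-concentration dosing
arithmetic (base concentration x mass share, with per-cluster adjustment
factors).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TasteProfile",
    "UNCATEGORIZED",
    "RECORD_COLUMNS",
    "validate_records",
    "map_descriptors",
    "consensus_filter",
    "aggregate_profile",
    "mass_normalize",
    "category_shares",
    "build_descriptor_network",
    "compute_working_concentrations",
    "compute_recovery",
]

UNCATEGORIZED = "uncategorized"
RECORD_COLUMNS = ["panelist", "fraction", "descriptor_raw", "score"]


@dataclass
class TasteProfile:
    """Consolidated fraction x category taste intensities.

    ``intensities`` holds summed scores (consensus-filtered cells only,
    zeros elsewhere); ``counts`` the number of distinct supporting
    panelists per cell; ``mass_normalized`` the per-mg copy when masses
    have been applied.
    """

    intensities: pd.DataFrame
    counts: pd.DataFrame
    mass_normalized: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.intensities.index.equals(self.counts.index) or not (
            self.intensities.columns.equals(self.counts.columns)
        ):
            raise ValueError("intensities and counts must be aligned")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def fractions(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def categories(self) -> list[str]:
        return list(self.intensities.columns)


def validate_records(records: pd.DataFrame, scale_max: int | None = None) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing column(s): {missing}")
    if len(records) and (records["descriptor_raw"].astype(str).str.len() == 0).any():
        raise ValueError("empty raw descriptor")
    if len(records) and (records["score"] < 0).any():
        raise ValueError("negative score")
    if scale_max is not None and len(records) and (records["score"] > scale_max).any():
        raise ValueError(f"score above scale maximum {scale_max}")


def map_descriptors(records: pd.DataFrame, cmap) -> pd.DataFrame:
    """Attach a curated ``category`` to every record (case-insensitive lookup).

    ``cmap`` maps raw descriptor -> category (dict, Series, or a DataFrame
    with columns descriptor_raw/category). Unmapped descriptors go to the
    explicit "uncategorized" bucket and are logged.
    """
    validate_records(records)
    if isinstance(cmap, pd.DataFrame):
        cmap = dict(zip(cmap["descriptor_raw"], cmap["category"]))
    elif isinstance(cmap, pd.Series):
        cmap = cmap.to_dict()
    folded = {str(k).casefold().strip(): v for k, v in cmap.items()}
    keys = records["descriptor_raw"].astype(str).str.casefold().str.strip()
    out = records.copy()
    out["category"] = keys.map(folded)
    unmapped = out["category"].isna()
    if unmapped.any():
        words = sorted(set(records.loc[unmapped, "descriptor_raw"]))
        logger.warning("unmapped descriptor(s) -> %s: %s", UNCATEGORIZED, words)
        out.loc[unmapped, "category"] = UNCATEGORIZED
    return out


def consensus_filter(records: pd.DataFrame, min_panelists: int = 2) -> pd.DataFrame:
    """Keep a (fraction, category) cell only when >= ``min_panelists``
    distinct panelists reported it with a positive score.

    A panelist scoring the same cell repeatedly counts once.
    """
    if "category" not in records.columns:
        raise ValueError("records must be categorized first (map_descriptors)")
    pos = records[records["score"] > 0]
    support = pos.groupby(["fraction", "category"])["panelist"].nunique()
    keep = support[support >= min_panelists].index
    mask = pos.set_index(["fraction", "category"]).index.isin(keep)
    return pos[mask].reset_index(drop=True)


def aggregate_profile(
    records: pd.DataFrame,
    fractions: list[str] | None = None,
    categories: list[str] | None = None,
) -> TasteProfile:
    """Sum consensus-filtered scores into a fraction x category profile.

    Repeated reports by one panelist for the same cell are collapsed to
    their maximum before summing across panelists, so no single panelist
    dominates the "sum over panelists". Cells without surviving records
    are exactly 0, with a supporting-panelist count of 0.
    """
    if "category" not in records.columns:
        raise ValueError("records must be categorized first (map_descriptors)")
    per_panelist = (
        records.groupby(["fraction", "category", "panelist"])["score"].max().reset_index()
    )
    sums = per_panelist.groupby(["fraction", "category"])["score"].sum().unstack(
        fill_value=0.0
    )
    counts = (
        per_panelist[per_panelist["score"] > 0]
        .groupby(["fraction", "category"])["panelist"]
        .nunique()
        .unstack(fill_value=0)
    )
    fr = fractions if fractions is not None else sorted(sums.index)
    cat = categories if categories is not None else sorted(sums.columns)
    sums = sums.reindex(index=fr, columns=cat, fill_value=0.0).astype(float)
    counts = counts.reindex(index=fr, columns=cat, fill_value=0).astype(int)
    return TasteProfile(intensities=sums, counts=counts)


def mass_normalize(tp: TasteProfile, masses) -> TasteProfile:
    """Divide each fraction's row by its dry mass (mg)."""
    m = pd.Series(masses, dtype=float)
    missing = [f for f in tp.fractions if f not in m.index]
    if missing:
        raise ValueError(f"missing mass for fraction(s): {missing}")
    m = m.reindex(tp.fractions)
    if (m <= 0).any():
        bad = list(m.index[m <= 0])
        raise ValueError(f"non-positive mass for fraction(s): {bad}")
    return TasteProfile(
        intensities=tp.intensities,
        counts=tp.counts,
        mass_normalized=tp.intensities.div(m, axis=0),
    )


def category_shares(
    tp: TasteProfile, fraction: str | None = None, normalized: bool = False
) -> pd.Series:
    """Each category's share of total taste intensity (sums to 1).

    ``fraction=None`` pools all fractions; ``normalized=True`` uses the
    mass-normalized matrix.
    """
    mat = tp.mass_normalized if normalized else tp.intensities
    if normalized and mat is None:
        raise ValueError("profile has no mass-normalized matrix")
    totals = mat.loc[fraction] if fraction is not None else mat.sum(axis=0)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("all-zero taste profile: shares undefined")
    return totals / grand


def build_descriptor_network(records: pd.DataFrame) -> nx.Graph:
    """Descriptor co-occurrence network.

    One node per distinct raw descriptor (attributes: category, frequency =
    number of distinct fractions where it was assigned); an undirected edge
    links two descriptors assigned to the same fraction, weighted by the
    number of such fractions. No self-loops.
    """
    if "category" not in records.columns:
        raise ValueError("records must be categorized first (map_descriptors)")
    g = nx.Graph()
    desc = records[["fraction", "descriptor_raw", "category"]].drop_duplicates()
    for word, sub in desc.groupby("descriptor_raw"):
        g.add_node(
            word,
            category=sub["category"].iloc[0],
            frequency=int(sub["fraction"].nunique()),
        )
    for _, sub in desc.groupby("fraction"):
        for a, b in itertools.combinations(sorted(set(sub["descriptor_raw"])), 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def compute_working_concentrations(
    mass_shares,
    base: float = 3.0,
    cluster_factors: dict[int, float] | None = None,
    cluster_of: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-fraction working concentration (mg/L).

    concentration = ``base`` x mass share of the parent fraction x the
    fraction's cluster adjustment factor (default 1). The study's base was
    3 mg/L, with cluster-level factors such as 1/50 for a hyper-bitter
    cluster and 2 for the most massive one.
    """
    shares = pd.Series(mass_shares, dtype=float)
    if ((shares <= 0) | (shares > 1)).any():
        bad = list(shares.index[(shares <= 0) | (shares > 1)])
        raise ValueError(f"mass share outside (0, 1] for: {bad}")
    cluster_factors = cluster_factors or {}
    cluster_of = cluster_of or {}
    rows = []
    for frac, share in shares.items():
        cl = cluster_of.get(frac)
        factor = cluster_factors.get(cl, 1.0) if cl is not None else 1.0
        rows.append(
            {
                "fraction": frac,
                "mass_share": share,
                "cluster": cl,
                "factor": factor,
                "concentration_mg_per_L": base * share * factor,
            }
        )
    out = pd.DataFrame(rows).set_index("fraction")
    if (out["concentration_mg_per_L"] <= 0).any():
        raise ValueError("non-positive working concentration")
    return out


def compute_recovery(recovered_mass: float, input_mass: float) -> float:
    """Mass recovery of a fractionation step, in percent."""
    if input_mass <= 0:
        raise ValueError("input mass must be > 0")
    if recovered_mass < 0:
        raise ValueError("recovered mass must be >= 0")
    return 100.0 * recovered_mass / input_mass
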