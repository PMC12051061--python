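"""Segment-wise feature-taste correlation.

The central statistic of chemically informed tasting: for every MS feature,
taste category and contiguous window of 5-9 ordered fractions, correlate
feature intensity with consolidated taste intensity. Each window's two
vectors are first screened with a Shapiro-Wilk normality test; if either
deviates from normality (p < 0.05) the rank-based Kendall tau-b is used,
otherwise Pearson's r. All raw p-values are Benjamini-Hochberg adjusted in
one batch, correlations are retained at (p < alpha, coefficient > r_min),
and retained records are refined by requiring that at least ``min_count``
fractions of the window rank among the feature's ``top_k`` highest
intensities over all fractions.

Features must be detected in at least ``min_fractions`` fractions; the
remaining missing cells are imputed with half of the feature's lowest
observed value (left-censoring imputation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .stats import (
    adjust_bh,
    kendall_tau_batch,
    pearson_r_batch,
    shapiro_wilk_batch,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "Segment",
    "CorrelationRecord",
    "CorrelationConfig",
    "CorrelationReport",
    "filter_features",
    "impute_half_min",
    "enumerate_segments",
    "correlate_segment",
    "retain",
    "refine_top_rank",
    "run_correlation",
]


@dataclass
class FeatureTable:
    """MS feature intensities over ordered fractions, with feature metadata.

    ``features`` is indexed by feature_id with columns ``mz``, ``rt`` and
    optional ``annotation``; ``intensities`` shares that index and has one
    column per fraction, in elution order, with NaN marking cells below the
    detection limit.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self):
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("features and intensities must share the same index")
        if self.features.index.has_duplicates:
            dupes = self.features.index[self.features.index.duplicated()].unique()
            raise ValueError(f"duplicate feature_id(s): {list(dupes)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative where present")

    @property
    def fractions(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def observed_counts(self) -> pd.Series:
        """Number of non-missing fractions per feature."""
        return self.intensities.notna().sum(axis=1)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.intensities.copy())


@dataclass(frozen=True, order=True)
class Segment:
    """A contiguous window of ordered fractions, inclusive 0-based indices."""

    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start or self.start < 0:
            raise ValueError("invalid segment bounds")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


@dataclass(frozen=True)
class CorrelationRecord:
    feature_id: str
    category: str
    segment: Segment
    method: str  # "kendall" | "pearson"
    coefficient: float
    p_raw: float
    p_adj: float = float("nan")
    retained: bool = False
    refined: bool = False
    n_observed: int = 0


@dataclass(frozen=True)
class CorrelationConfig:
    """All tunables of the correlation pipeline, at the study's defaults."""

    min_fractions: int = 5
    seg_min: int = 5
    seg_max: int = 9
    alpha_normality: float = 0.05
    alpha: float = 0.05
    r_min: float = 0.95
    use_adjusted: bool = True
    signed: bool = True
    top_k: int = 5
    min_count: int = 4
    gate_mode: str = "either"  # Kendall if "either" vector non-normal, or "both"
    imputation: str = "feature"  # half-min per feature, or "global"

    def __post_init__(self):
        if self.gate_mode not in ("either", "both"):
            raise ValueError("gate_mode must be 'either' or 'both'")
        if self.imputation not in ("feature", "global"):
            raise ValueError("imputation must be 'feature' or 'global'")
        if not 0 < self.seg_min <= self.seg_max:
            raise ValueError("need 0 < seg_min <= seg_max")


@dataclass
class CorrelationReport:
    """Full record set plus per-pair summary and run metadata."""

    records: pd.DataFrame
    summary: pd.DataFrame
    meta: dict = field(default_factory=dict)


RECORD_COLUMNS = [
    "feature_id",
    "category",
    "seg_start",
    "seg_end",
    "length",
    "method",
    "coefficient",
    "p_raw",
    "p_adj",
    "retained",
    "refined",
    "n_observed",
]


def filter_features(ft: FeatureTable, min_fractions: int = 5) -> FeatureTable:
    """Keep only features detected in at least ``min_fractions`` fractions."""
    keep = ft.observed_counts() >= min_fractions
    return FeatureTable(ft.features.loc[keep], ft.intensities.loc[keep])


def impute_half_min(ft: FeatureTable, mode: str = "feature") -> FeatureTable:
    """Replace missing cells with half of the lowest observed value.

    ``mode='feature'`` (default) uses each feature's own minimum, preserving
    per-ion dynamic range; ``mode='global'`` uses the table-wide minimum.
    """
    x = ft.intensities.to_numpy(dtype=float).copy()
    missing = np.isnan(x)
    if mode == "feature":
        if x.size and np.any(np.all(missing, axis=1)):
            bad = ft.features.index[np.all(missing, axis=1)]
            raise ValueError(f"all-missing feature(s): {list(bad)}")
        fill = np.nanmin(x, axis=1) / 2.0 if x.size else np.empty(0)
        x[missing] = np.broadcast_to(fill[:, None], x.shape)[missing]
    elif mode == "global":
        if x.size and np.all(missing):
            raise ValueError("cannot impute an all-missing table")
        x[missing] = np.nanmin(x) / 2.0
    else:
        raise ValueError("mode must be 'feature' or 'global'")
    return FeatureTable(
        ft.features.copy(),
        pd.DataFrame(x, index=ft.intensities.index, columns=ft.intensities.columns),
    )


def enumerate_segments(
    n_fractions: int, min_len: int = 5, max_len: int = 9
) -> list[Segment]:
    """All contiguous fraction windows of length min_len..max_len."""
    segs = []
    for length in range(min_len, max_len + 1):
        for start in range(0, n_fractions - length + 1):
            segs.append(Segment(start, start + length - 1))
    return segs


def _choose_method(p_feat, p_taste, deg_feat, deg_taste, alpha, gate_mode):
    feat_bad = deg_feat | (p_feat < alpha)
    taste_bad = deg_taste | (p_taste < alpha)
    if gate_mode == "either":
        return feat_bad | taste_bad
    return feat_bad & taste_bad


def correlate_segment(
    feature_row,
    taste_row,
    seg: Segment,
    alpha_normality: float = 0.05,
    gate_mode: str = "either",
    feature_id: str = "",
    category: str = "",
    n_observed: int | None = None,
) -> CorrelationRecord | None:
    """Correlate one feature/taste pair on one segment.

    Returns ``None`` (a skipped record) when either vector is constant on
    the segment; otherwise a :class:`CorrelationRecord` carrying the chosen
    method, coefficient and raw p-value.
    """
    x = np.asarray(feature_row, dtype=float)[seg.indices()]
    y = np.asarray(taste_row, dtype=float)[seg.indices()]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    _, pxs, degx = shapiro_wilk_batch(x[None, :])
    _, pys, degy = shapiro_wilk_batch(y[None, :])
    kendall = _choose_method(
        pxs[0], pys[0], bool(degx[0]), bool(degy[0]), alpha_normality, gate_mode
    )
    if kendall:
        tau, p, _ = kendall_tau_batch(x[None, :], y[None, :])
        method, coef, p_raw = "kendall", float(tau[0]), float(p[0])
    else:
        r, p, _ = pearson_r_batch(x[None, :], y[None, :])
        method, coef, p_raw = "pearson", float(r[0]), float(p[0])
    return CorrelationRecord(
        feature_id=feature_id,
        category=category,
        segment=seg,
        method=method,
        coefficient=coef,
        p_raw=p_raw,
        n_observed=seg.length if n_observed is None else n_observed,
    )


def retain(
    records: pd.DataFrame,
    alpha: float = 0.05,
    r_min: float = 0.95,
    use_adjusted: bool = True,
    signed: bool = True,
) -> pd.DataFrame:
    """Flag records meeting the significance and strength thresholds."""
    out = records.copy()
    p = out["p_adj"] if use_adjusted else out["p_raw"]
    coef = out["coefficient"] if signed else out["coefficient"].abs()
    out["retained"] = (p < alpha) & (coef > r_min)
    return out


def _top_fraction_mask(x: np.ndarray, top_k: int) -> np.ndarray:
    """Boolean (features x fractions) mask of each feature's top-k fractions.

    All fractions tying the k-th largest intensity are included.
    """
    if x.shape[1] <= top_k:
        return np.ones_like(x, dtype=bool)
    thresh = np.partition(x, -top_k, axis=1)[:, -top_k]
    return x >= thresh[:, None]


def refine_top_rank(
    records: pd.DataFrame,
    ft_imputed: FeatureTable,
    top_k: int = 5,
    min_count: int = 4,
) -> pd.DataFrame:
    """Refine retained records by the top-intensity-rank rule.

    A record survives only if at least ``min_count`` fractions of its
    segment belong to the feature's ``top_k`` highest intensities across
    all fractions.
    """
    out = records.copy()
    if not len(out):
        out["refined"] = pd.Series(dtype=bool)
        return out
    x = ft_imputed.intensities.to_numpy(dtype=float)
    top = _top_fraction_mask(x, top_k)
    cum = np.concatenate(
        [np.zeros((top.shape[0], 1), dtype=int), np.cumsum(top, axis=1)], axis=1
    )
    fidx = ft_imputed.intensities.index.get_indexer(out["feature_id"])
    start = out["seg_start"].to_numpy()
    end = out["seg_end"].to_numpy()
    in_top = cum[fidx, end + 1] - cum[fidx, start]
    out["refined"] = out["retained"].to_numpy() & (in_top >= min_count)
    return out


def _kendall_in_chunks(x, y, chunk=40000):
    taus, ps = [], []
    for i in range(0, x.shape[0], chunk):
        t, p, _ = kendall_tau_batch(x[i : i + chunk], y[i : i + chunk])
        taus.append(t)
        ps.append(p)
    return np.concatenate(taus), np.concatenate(ps)


def run_correlation(
    ft: FeatureTable,
    tp,
    config: CorrelationConfig | None = None,
) -> CorrelationReport:
    """Run the full correlation pipeline and return the record set.

    ``tp`` is a :class:`~sensomics.sensory.TasteProfile` (or any object with
    an ``intensities`` fraction x category DataFrame) whose fraction order
    must match the feature table's.
    """
    config = config or CorrelationConfig()
    taste = tp.intensities if hasattr(tp, "intensities") else tp
    if list(taste.index) != list(ft.fractions):
        raise ValueError("fraction order mismatch between feature table and tastes")

    kept = filter_features(ft, config.min_fractions)
    imputed = impute_half_min(kept, config.imputation)
    x = imputed.intensities.to_numpy(dtype=float)
    observed = kept.intensities.notna().to_numpy()
    t = taste.to_numpy(dtype=float).T  # (categories, fractions)
    cats = list(taste.columns)
    feat_ids = list(imputed.features.index)
    n_frac = x.shape[1]

    chunks = []
    n_skipped = 0
    for length in range(config.seg_min, min(config.seg_max, n_frac) + 1):
        xw = sliding_window_view(x, length, axis=1)  # (F, S, L)
        ow = sliding_window_view(observed, length, axis=1).sum(axis=2)  # (F, S)
        tw = sliding_window_view(t, length, axis=1)  # (C, S, L)
        n_feat, n_seg = xw.shape[0], xw.shape[1]
        if n_feat == 0 or n_seg == 0:
            continue

        _, pxs, degx = shapiro_wilk_batch(xw.reshape(-1, length))
        pxs, degx = pxs.reshape(n_feat, n_seg), degx.reshape(n_feat, n_seg)
        _, pts, degt = shapiro_wilk_batch(tw.reshape(-1, length))
        pts, degt = pts.reshape(len(cats), n_seg), degt.reshape(len(cats), n_seg)

        for ci, cat in enumerate(cats):
            t_const = degt[ci]  # taste constant on segment
            valid = ~degx & ~t_const[None, :]
            n_skipped += int(n_feat * n_seg - valid.sum())
            if not valid.any():
                continue
            kendall = _choose_method(
                pxs, pts[ci][None, :], degx, t_const[None, :],
                config.alpha_normality, config.gate_mode,
            )
            fi, si = np.nonzero(valid)
            xv = xw[fi, si]  # (M, L)
            yv = tw[ci, si]
            kmask = kendall[fi, si]
            coef = np.empty(len(fi))
            p_raw = np.empty(len(fi))
            if kmask.any():
                tau, p = _kendall_in_chunks(xv[kmask], yv[kmask])
                coef[kmask], p_raw[kmask] = tau, p
            if (~kmask).any():
                r, p, _ = pearson_r_batch(xv[~kmask], yv[~kmask])
                coef[~kmask], p_raw[~kmask] = r, p
            chunks.append(
                pd.DataFrame(
                    {
                        "feature_id": np.asarray(feat_ids, dtype=object)[fi],
                        "category": cat,
                        "seg_start": si,
                        "seg_end": si + length - 1,
                        "length": length,
                        "method": np.where(kmask, "kendall", "pearson"),
                        "coefficient": coef,
                        "p_raw": p_raw,
                        "n_observed": ow[fi, si],
                    }
                )
            )

    if chunks:
        records = pd.concat(chunks, ignore_index=True)
    else:
        records = pd.DataFrame(
            columns=[c for c in RECORD_COLUMNS if c not in ("p_adj", "retained", "refined")]
        )
    records = records.sort_values(
        ["feature_id", "category", "length", "seg_start"], kind="stable"
    ).reset_index(drop=True)
    records["p_adj"] = adjust_bh(records["p_raw"].to_numpy(dtype=float))
    records = retain(
        records,
        alpha=config.alpha,
        r_min=config.r_min,
        use_adjusted=config.use_adjusted,
        signed=config.signed,
    )
    records = refine_top_rank(records, imputed, config.top_k, config.min_count)
    records = records[RECORD_COLUMNS]

    refined = records[records["refined"]]
    if len(records):
        summary = (
            records[records["retained"]]
            .groupby(["feature_id", "category"])
            .agg(
                best_coefficient=("coefficient", "max"),
                min_p_adj=("p_adj", "min"),
                n_retained=("retained", "sum"),
                n_refined=("refined", "sum"),
            )
            .reset_index()
        )
    else:
        summary = pd.DataFrame(
            columns=[
                "feature_id",
                "category",
                "best_coefficient",
                "min_p_adj",
                "n_retained",
                "n_refined",
            ]
        )
    n_seg_total = len(enumerate_segments(n_frac, config.seg_min, config.seg_max))
    meta = {
        "config": asdict(config),
        "n_features_in": ft.n_features,
        "n_features_kept": kept.n_features,
        "n_categories": len(cats),
        "n_segments": n_seg_total,
        "n_triples": kept.n_features * len(cats) * n_seg_total,
        "n_tested": int(len(records)),
        "n_skipped": int(n_skipped),
        "n_retained": int(records["retained"].sum()) if len(records) else 0,
        "n_refined": int(len(refined)),
    }
    logger.info(
        "correlation: %(n_tested)d tested, %(n_skipped)d skipped, "
        "%(n_retained)d retained, %(n_refined)d refined",
        meta,
    )
    return CorrelationReport(records=records, summary=summary, meta=meta)
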