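"""Readers and writers for the pipeline's plain-text artifacts.

All tabular files are CSV/TSV with explicit empty cells for missing values
(missingness is meaningful: it drives the half-minimum imputation). Every
file written here starts with a ``#`` header comment carrying the package
version and, when available, the run's config hash; readers skip comment
lines.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlate import FeatureTable
from .nmr import ClusterAssignment, NmrSpectrum, PeakMatrix, SessionPlan
from .sensory import RECORD_COLUMNS, TasteProfile, validate_records

FEATURE_META_COLUMNS = ["feature_id", "mz", "rt", "annotation"]


def _header(config_hash: str | None = None) -> str:
    tag = f" config={config_hash}" if config_hash else ""
    return f"# sensomics v{__version__}{tag}\n"


def _write_df(df: pd.DataFrame, path, sep=",", config_hash=None, index=False):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        df.to_csv(fh, sep=sep, index=index)


# --- feature tables --------------------------------------------------------


def write_feature_table(ft: FeatureTable, path, config_hash=None) -> None:
    df = ft.features.reset_index()
    if "annotation" not in df.columns:
        df["annotation"] = ""
    df = df[FEATURE_META_COLUMNS]
    out = pd.concat([df, ft.intensities.reset_index(drop=True)], axis=1)
    _write_df(out, path, config_hash=config_hash)


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("feature_id", "mz", "rt") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df["feature_id"].duplicated().any():
        dupes = sorted(df.loc[df["feature_id"].duplicated(), "feature_id"].unique())
        raise ValueError(f"{path}: duplicate feature_id(s) {dupes}")
    meta_cols = [c for c in FEATURE_META_COLUMNS if c in df.columns]
    features = df[meta_cols].set_index("feature_id")
    if "annotation" in features.columns:
        features["annotation"] = features["annotation"].fillna("")
    frac_cols = [c for c in df.columns if c not in FEATURE_META_COLUMNS]
    if not frac_cols:
        raise ValueError(f"{path}: no fraction columns")
    intensities = df.set_index("feature_id")[frac_cols].astype(float)
    return FeatureTable(features=features, intensities=intensities)


# --- sensory records, category map, masses ---------------------------------


def write_taste_records(records: pd.DataFrame, path, config_hash=None) -> None:
    cols = RECORD_COLUMNS + [c for c in records.columns if c not in RECORD_COLUMNS]
    _write_df(records[cols], path, config_hash=config_hash)


def read_taste_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    validate_records(df)
    return df


def write_category_map(cmap: dict, path, config_hash=None) -> None:
    df = pd.DataFrame(
        sorted(cmap.items()), columns=["descriptor_raw", "category"]
    )
    _write_df(df, path, config_hash=config_hash)


def read_category_map(path) -> dict:
    df = pd.read_csv(path, comment="#")
    for c in ("descriptor_raw", "category"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    return dict(zip(df["descriptor_raw"], df["category"]))


def write_masses(masses: pd.Series, path, config_hash=None) -> None:
    df = masses.rename("mass_mg").rename_axis("fraction").reset_index()
    _write_df(df, path, config_hash=config_hash)


def read_masses(path) -> pd.Series:
    df = pd.read_csv(path, comment="#")
    for c in ("fraction", "mass_mg"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    return df.set_index("fraction")["mass_mg"].astype(float)


# --- taste profiles --------------------------------------------------------


def write_taste_profile(tp: TasteProfile, path, config_hash=None) -> None:
    _write_df(
        tp.intensities.rename_axis("fraction").reset_index(),
        path, sep="\t", config_hash=config_hash,
    )
    counts_path = Path(path).with_suffix(".counts.tsv")
    _write_df(
        tp.counts.rename_axis("fraction").reset_index(),
        counts_path, sep="\t", config_hash=config_hash,
    )


def read_taste_profile(path, counts_path=None) -> TasteProfile:
    inten = pd.read_csv(path, sep="\t", comment="#")
    if "fraction" not in inten.columns:
        raise ValueError(f"{path}: missing 'fraction' column")
    inten = inten.set_index("fraction").astype(float)
    if counts_path is None:
        cand = Path(path).with_suffix(".counts.tsv")
        counts_path = cand if cand.exists() else None
    if counts_path is not None:
        counts = pd.read_csv(counts_path, sep="\t", comment="#").set_index("fraction")
        counts = counts.reindex(index=inten.index, columns=inten.columns).fillna(0)
    else:
        counts = pd.DataFrame(0, index=inten.index, columns=inten.columns)
    return TasteProfile(intensities=inten, counts=counts.astype(int))


# --- NMR artifacts ---------------------------------------------------------


def write_spectra_dir(spectra: list[NmrSpectrum], outdir, config_hash=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in spectra:
        df = pd.DataFrame({"ppm": s.ppm, "intensity": s.intensity})
        _write_df(df, outdir / f"{s.sample_id}.csv", config_hash=config_hash)


def read_spectra_dir(indir) -> list[NmrSpectrum]:
    indir = Path(indir)
    spectra = []
    for path in sorted(indir.glob("*.csv")):
        df = pd.read_csv(path, comment="#")
        for c in ("ppm", "intensity"):
            if c not in df.columns:
                raise ValueError(f"{path}: missing column {c}")
        spectra.append(
            NmrSpectrum(
                sample_id=path.stem,
                ppm=df["ppm"].to_numpy(),
                intensity=df["intensity"].to_numpy(),
            )
        )
    if not spectra:
        raise ValueError(f"no spectra (*.csv) found in {indir}")
    return spectra


def write_peak_matrix(pm: PeakMatrix, path, config_hash=None) -> None:
    df = pd.DataFrame(
        pm.areas,
        index=pd.Index(pm.sample_ids, name="sample"),
        columns=[f"{c:.4f}" for c in pm.centers],
    )
    _write_df(df.reset_index(), path, sep="\t", config_hash=config_hash)


def write_cluster_labels(ca: ClusterAssignment, path, config_hash=None) -> None:
    df = pd.DataFrame(
        sorted(ca.labels.items()), columns=["sample", "cluster"]
    )
    _write_df(df, path, sep="\t", config_hash=config_hash)


def write_session_plan(plan: SessionPlan, path, config_hash=None) -> None:
    obj = {
        "sessions": [
            {"session": i + 1, "cluster": s.cluster, "fractions": list(s.fractions)}
            for i, s in enumerate(plan.sessions)
        ]
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        yaml.safe_dump(obj, fh, sort_keys=False)


def _tree_to_newick(node, leaf_names):
    if node.is_leaf():
        return leaf_names[node.id]
    left = _tree_to_newick(node.get_left(), leaf_names)
    right = _tree_to_newick(node.get_right(), leaf_names)
    bl_left = node.dist - node.get_left().dist
    bl_right = node.dist - node.get_right().dist
    return f"({left}:{bl_left:.6g},{right}:{bl_right:.6g})"


def write_dendrogram(ca: ClusterAssignment, path, config_hash=None) -> None:
    """Newick text of the merge tree plus a merge-height table alongside."""
    from scipy.cluster.hierarchy import to_tree

    leaf_names = list(ca.labels)
    tree = to_tree(ca.linkage_matrix)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_tree_to_newick(tree, leaf_names) + ";\n")
    z = ca.linkage_matrix
    df = pd.DataFrame(z, columns=["left", "right", "height", "size"])
    _write_df(df, path.with_suffix(".heights.tsv"), sep="\t", config_hash=config_hash)


# --- networks, correlation outputs, metadata -------------------------------


def write_network(g: nx.Graph, path_graphml, path_edges=None, config_hash=None) -> None:
    Path(path_graphml).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, path_graphml)
    if path_edges is not None:
        rows = [
            {"descriptor_a": a, "descriptor_b": b, "weight": d["weight"]}
            for a, b, d in sorted(g.edges(data=True))
        ]
        _write_df(pd.DataFrame(rows), path_edges, sep="\t", config_hash=config_hash)


def write_correlation_records(records: pd.DataFrame, path, config_hash=None) -> None:
    _write_df(records, path, sep="\t", config_hash=config_hash)


def read_correlation_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (Path, os.PathLike)):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
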