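"""Electrophysiological typing via joint feature clustering.

Electrical features (AP amplitude, ISI CV, adaptation index, ... measured
at rheobase-percentage stimulation protocols) from a reference dataset
with canonical Petilla e-type labels and from patch-seq cells with t-type
labels are pooled, cleaned, standardized, and clustered into a common set
of feature clusters (agglomerative, Ward linkage). The clusters mediate
the conditional probability

    P(e_i | t_j) = Σ_k P(e_i | C_k) · P(C_k | t_j)

with P(e|C_k) estimated over reference cells in cluster k and P(C_k|t)
over patch-seq cells of t-type t.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from .errors import MappingError

__all__ = [
    "CANONICAL_ETYPES",
    "META_COLS",
    "clean_standardize",
    "cluster_efeatures",
    "p_e_given_t",
    "constrain_classes",
]

# the 11 canonical Petilla-convention e-types of the reference dataset
CANONICAL_ETYPES = [
    "cADpyr", "bAC", "bIR", "bNAC", "bSTUT", "cAC",
    "cIR", "cNAC", "cSTUT", "dNAC", "dSTUT",
]

META_COLS = ("source", "e_type", "t_type", "cell_id")


def _feature_cols(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c not in META_COLS]


def clean_standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Clean a pooled e-feature table and z-score every feature.

    Rows with no feature values are dropped, then any feature column still
    containing missing values is dropped (features must be shared by every
    retained cell of both sources), then zero-variance features (warned).
    Standardization pools reference and patch-seq cells.
    """
    feats = _feature_cols(table)
    if len(feats) < 1 or len(table) < 2:
        raise MappingError("need >= 2 cells and >= 1 feature column")
    out = table[~table[feats].isna().all(axis=1)].copy()
    keep = [c for c in feats if not out[c].isna().any()]
    out = out[[c for c in table.columns if c in META_COLS or c in keep]]
    dead = [c for c in keep if out[c].std(ddof=0) == 0]
    if dead:
        warnings.warn(f"dropping zero-variance features: {dead}")
        out = out.drop(columns=dead)
        keep = [c for c in keep if c not in dead]
    if not keep:
        raise MappingError("no usable shared feature columns after cleaning")
    vals = out[keep].astype(float)
    out[keep] = (vals - vals.mean()) / vals.std(ddof=0)
    return out


def cluster_efeatures(table: pd.DataFrame, k: int = 20) -> pd.Series:
    """Assign every cell to one of ``k`` feature clusters.

    Agglomerative clustering with Ward linkage on Euclidean distances over
    the pooled standardized features; deterministic.
    """
    feats = _feature_cols(table)
    if len(table) < k:
        raise MappingError(f"{len(table)} cells < k={k}")
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    labels = model.fit_predict(table[feats].to_numpy(dtype=float))
    return pd.Series(labels, index=table.index, name="cluster")


def p_e_given_t(
    assignment: pd.Series,
    table: pd.DataFrame,
    e_types: list | None = None,
    fallback: str = "nearest",
) -> pd.DataFrame:
    """Cluster-mediated conditional probability matrix P(e-type | t-type).

    Clusters containing no reference cell cannot anchor P(e|C_k); by
    default such a cluster borrows the e-type distribution of the nearest
    reference-containing cluster (Euclidean distance between cluster
    feature centroids) — a uniform distribution over e-types never
    vanishes with sample size and would bias the estimate. Set
    ``fallback='uniform'`` for the flat alternative. T-types with no
    patch-seq cells get no row (they are later extrapolated). Rows sum
    to 1.
    """
    df = table.copy()
    df["cluster"] = assignment
    ref = df[df["source"] == "reference"]
    pat = df[df["source"] == "patchseq"]
    e_types = e_types or sorted(ref["e_type"].dropna().unique())
    clusters = sorted(df["cluster"].unique())

    p_e_c = pd.DataFrame(0.0, index=clusters, columns=e_types)
    for ck, grp in ref.groupby("cluster"):
        counts = grp["e_type"].value_counts().reindex(e_types, fill_value=0)
        p_e_c.loc[ck] = counts / counts.sum()
    anchored = sorted(set(ref["cluster"]))
    empty = [ck for ck in clusters if ck not in anchored]
    if empty:
        warnings.warn(
            f"{len(empty)} clusters contain no reference cell; {fallback} fallback"
        )
        if fallback == "uniform":
            p_e_c.loc[empty] = 1.0 / len(e_types)
        elif fallback == "nearest":
            feats = _feature_cols(table)
            centroids = df.groupby("cluster")[feats].mean()
            ref_centroids = centroids.loc[anchored]
            for ck in empty:
                d = np.linalg.norm(
                    ref_centroids.to_numpy() - centroids.loc[ck].to_numpy()[None, :],
                    axis=1,
                )
                p_e_c.loc[ck] = p_e_c.loc[anchored[int(np.argmin(d))]]
        else:
            raise MappingError(f"unknown fallback {fallback!r}")

    rows = {}
    for tt, grp in pat.groupby("t_type"):
        p_c_t = grp["cluster"].value_counts(normalize=True).reindex(clusters, fill_value=0.0)
        rows[tt] = p_c_t.to_numpy() @ p_e_c.to_numpy()
    pmap = pd.DataFrame.from_dict(rows, orient="index", columns=e_types)
    pmap.index.name = "t_type"
    return pmap.sort_index()


def constrain_classes(
    pmap: pd.DataFrame,
    t_class: pd.Series,
    excitatory_etype: str = "cADpyr",
) -> pd.DataFrame:
    """Force class consistency: excitatory (Glut) t-types map entirely to
    the pyramidal e-type; inhibitory (GABA) t-types get zero pyramidal
    mass, renormalized. Rows of other classes are untouched.
    """
    out = pmap.copy()
    for tt in out.index:
        cls = t_class.get(tt)
        if cls == "Glut":
            out.loc[tt] = 0.0
            out.loc[tt, excitatory_etype] = 1.0
        elif cls == "GABA":
            out.loc[tt, excitatory_etype] = 0.0
            s = out.loc[tt].sum()
            if s > 0:
                out.loc[tt] /= s
            else:
                inhib = [c for c in out.columns if c != excitatory_etype]
                warnings.warn(f"t-type {tt}: all mass was excitatory; uniform over inhibitory")
                out.loc[tt, inhib] = 1.0 / len(inhib)
    return out
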