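"""Probabilistic t-type → m/e/me-type mapping and extrapolation.

Patch-seq cells (single-cell expression + morphology + electrophysiology)
are aligned to reference transcriptomic types by nearest neighbor in a
PCA embedding of a shared gene space. Empirical conditionals P(m|t) and
cluster-mediated P(e|t) are combined, assuming conditional independence
given the t-type, into P(me|t) = P(m|t) ⊗ P(e|t). T-types never sampled
by patch-seq are extrapolated: genes predictive of me-labels but not of
region-of-origin define a subspace in which the k nearest covered t-types
donate their probability rows, averaged with inverse-distance weights.
Finally me-type densities follow by linearity,
Densities(me_i) = Σ_j P(me_i|t_j) · Densities(t_j), and the reduction is
validated by comparing regional mRNA densities computed from t-types
against those recomputed from me-types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

from .densities import DensityAtlas
from .errors import MappingError

__all__ = [
    "GeneSelectionParams",
    "select_genes_zero_inflation",
    "align_t_types",
    "p_m_given_t",
    "p_me_given_t",
    "select_me_predictive_genes",
    "extrapolate_knn",
    "cross_validate_extrapolation",
    "me_densities",
    "mrna_validate",
    "MrnaValidation",
]


@dataclass
class GeneSelectionParams:
    """Zero-inflation gene-selection curve and mapping hyperparameters."""

    yoffset: float = 0.04
    xoffset: float = 6.2
    decay: float = 1.2
    n_genes: int = 100
    n_region_low: int = 100
    k_neighbors: int = 10


def select_genes_zero_inflation(
    counts: pd.DataFrame, params: GeneSelectionParams | None = None
) -> list:
    """Select genes with both frequent dropout and high nonzero expression.

    A gene is kept iff its zero fraction exceeds the exponential-decay
    curve ``exp(-decay·(µ - xoffset)) + yoffset`` where µ is the mean
    log₂(count+1) over cells with nonzero counts. Genes never expressed
    are excluded with a warning.
    """
    params = params or GeneSelectionParams()
    mat = counts.to_numpy(dtype=float)
    nonzero = mat > 0
    n_nonzero = nonzero.sum(axis=0)
    silent = n_nonzero == 0
    if silent.any():
        warnings.warn(f"{int(silent.sum())} genes expressed in zero cells; excluded")
    zero_frac = 1.0 - n_nonzero / mat.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(
            n_nonzero > 0,
            np.sum(np.log2(mat + 1.0) * nonzero, axis=0) / np.maximum(n_nonzero, 1),
            np.nan,
        )
    curve = np.exp(-params.decay * (mu - params.xoffset)) + params.yoffset
    keep = (~silent) & (zero_frac > curve)
    return [g for g, k in zip(counts.columns, keep) if k]


def align_t_types(
    reference: pd.DataFrame,
    cells: pd.DataFrame,
    n_pcs: int = 50,
    min_support: int = 3,
    native_labels: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Nearest-reference-t-type label transfer in PCA space.

    ``reference`` holds trimmed-mean expression per t-type (rows) over
    genes (columns); ``cells`` raw per-cell counts. Both are restricted to
    the common gene set and log₂(x+1)-transformed; principal components
    are fit on the reference and query cells are projected into the same
    embedding; each cell takes the t-type of its nearest reference row by
    Euclidean distance. When native labels are supplied, a contingency map
    native × assigned is returned, restricted to native labels supported
    by at least ``min_support`` cells.
    """
    common = [g for g in reference.columns if g in set(cells.columns)]
    if not common:
        raise MappingError("empty gene intersection between reference and cells")
    ref = np.log2(reference[common].to_numpy(dtype=float) + 1.0)
    qry = np.log2(cells[common].to_numpy(dtype=float) + 1.0)
    n_comp = min(n_pcs, ref.shape[0] - 1, len(common))
    pca = PCA(n_components=n_comp, random_state=0)
    ref_emb = pca.fit_transform(ref)
    qry_emb = pca.transform(qry)
    d2 = ((qry_emb[:, None, :] - ref_emb[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    assigned = pd.Series(
        reference.index.to_numpy()[nearest], index=cells.index, name="t_type"
    )
    contingency = None
    if native_labels is not None:
        native = native_labels.reindex(cells.index)
        contingency = pd.crosstab(native, assigned)
        support = contingency.sum(axis=1)
        weak = support[support < min_support].index
        contingency = contingency.drop(index=weak)
    return assigned, contingency


def p_m_given_t(assignments: pd.DataFrame) -> pd.DataFrame:
    """Empirical P(m-type | t-type): row-normalized contingency counts.

    ``assignments`` needs ``t_type`` and ``m_type`` columns, one row per
    cell carrying both labels.
    """
    tab = pd.crosstab(assignments["t_type"], assignments["m_type"])
    return tab.div(tab.sum(axis=1), axis=0)


def p_me_given_t(pm: pd.DataFrame, pe: pd.DataFrame) -> pd.DataFrame:
    """Joint map under conditional independence: outer product per t-type.

    Columns are composite labels ``"mtype|etype"``. T-types present in
    only one factor map are excluded (listed in a warning).
    """
    shared = [t for t in pm.index if t in set(pe.index)]
    missing = sorted((set(pm.index) | set(pe.index)) - set(shared))
    if missing:
        warnings.warn(f"t-types present in only one map, excluded: {missing}")
    if not shared:
        raise MappingError("no shared t-types between P(m|t) and P(e|t)")
    cols = [f"{m}|{e}" for m in pm.columns for e in pe.columns]
    rows = {
        t: np.outer(pm.loc[t].to_numpy(), pe.loc[t].to_numpy()).ravel()
        for t in shared
    }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    out.index.name = "t_type"
    out.attrs["assumption"] = "m and e conditionally independent given t"
    return out


def select_me_predictive_genes(
    cells: pd.DataFrame,
    me_labels: pd.Series,
    region_labels: pd.Series,
    params: GeneSelectionParams | None = None,
    seed: int = 0,
) -> list:
    """Gene subspace predictive of me-types but not of region of origin.

    Genes are ranked by seeded random-forest impurity importance for the
    me-labels (top ``n_genes``) and for the region-of-origin (the
    ``n_region_low`` *least* important); the intersection is returned.
    An empty intersection falls back to the me-predictive set.
    """
    params = params or GeneSelectionParams()
    X = cells.to_numpy(dtype=float)
    genes = np.asarray(cells.columns)
    rf_me = RandomForestClassifier(n_estimators=200, random_state=seed)
    rf_me.fit(X, me_labels.reindex(cells.index).to_numpy())
    top_me = set(genes[np.argsort(rf_me.feature_importances_)[::-1][: params.n_genes]])
    rf_rg = RandomForestClassifier(n_estimators=200, random_state=seed + 1)
    rf_rg.fit(X, region_labels.reindex(cells.index).to_numpy())
    low_rg = set(genes[np.argsort(rf_rg.feature_importances_)[: params.n_region_low]])
    both = [g for g in cells.columns if g in top_me and g in low_rg]
    if not both:
        warnings.warn("empty gene intersection; falling back to me-predictive genes")
        return [g for g in cells.columns if g in top_me]
    return both


def extrapolate_knn(
    covered: pd.DataFrame,
    ref_expr: pd.DataFrame,
    k: int = 10,
    eps: float = 1e-9,
) -> tuple[pd.DataFrame, pd.Series]:
    """Extend a probability map to t-types without patch-seq coverage.

    ``ref_expr`` holds selected-gene expression for every t-type (covered
    and uncovered). Expression is z-scored per gene over t-types; each
    uncovered t-type averages the rows of its ``k`` nearest covered
    t-types (Euclidean), weighted by inverse distance ``1/(d+eps)``; an
    exact-zero distance copies that neighbor's row. Returns the full map
    and a coverage flag per row ('direct'/'extrapolated').
    """
    missing_expr = [t for t in covered.index if t not in ref_expr.index]
    if missing_expr:
        raise MappingError(f"covered t-types without expression: {missing_expr}")
    cov = [t for t in ref_expr.index if t in set(covered.index)]
    unc = [t for t in ref_expr.index if t not in set(covered.index)]
    if len(cov) < k:
        warnings.warn(f"only {len(cov)} covered t-types < k={k}; using all")
        k = len(cov)
    X = ref_expr.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = pd.DataFrame((X - mu) / sd, index=ref_expr.index, columns=ref_expr.columns)
    cov_mat = Z.loc[cov].to_numpy()
    rows = {t: covered.loc[t].to_numpy(dtype=float) for t in cov}
    flags = {t: "direct" for t in cov}
    for t in unc:
        d = np.linalg.norm(cov_mat - Z.loc[t].to_numpy()[None, :], axis=1)
        order = np.argsort(d)[:k]
        if d[order[0]] == 0.0:
            rows[t] = covered.loc[cov[order[0]]].to_numpy(dtype=float)
        else:
            w = 1.0 / (d[order] + eps)
            stacked = np.vstack([covered.loc[cov[i]].to_numpy(dtype=float) for i in order])
            rows[t] = (w[:, None] * stacked).sum(axis=0) / w.sum()
        flags[t] = "extrapolated"
    full = pd.DataFrame.from_dict(rows, orient="index", columns=covered.columns)
    full = full.loc[list(ref_expr.index)]
    return full, pd.Series(flags).loc[full.index].rename("coverage")


def cross_validate_extrapolation(
    covered: pd.DataFrame,
    ref_expr: pd.DataFrame,
    k_values: tuple = (5, 10),
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Tune the kNN extrapolator by 10-fold cross-validation.

    Covered t-types are split into folds; each fold's probability rows are
    hidden, re-predicted from the remaining covered types, and scored with
    mean squared and mean absolute error against the held-out rows.
    Returns one row per k with columns ``mse`` and ``mae``.
    """
    from sklearn.model_selection import KFold

    cov = [t for t in covered.index if t in set(ref_expr.index)]
    if len(cov) < n_folds:
        n_folds = max(2, len(cov))
        warnings.warn(f"fewer covered t-types than folds; using {n_folds} folds")
    rows = []
    for k in k_values:
        sq, ab = [], []
        for train, test in KFold(n_folds, shuffle=True, random_state=seed).split(cov):
            train_t = [cov[i] for i in train]
            test_t = [cov[i] for i in test]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full, _ = extrapolate_knn(
                    covered.loc[train_t],
                    ref_expr.loc[train_t + test_t],
                    k=min(k, len(train_t)),
                )
            err = full.loc[test_t].to_numpy() - covered.loc[test_t].to_numpy()
            sq.append(np.mean(err**2))
            ab.append(np.mean(np.abs(err)))
        rows.append({"k": k, "mse": float(np.mean(sq)), "mae": float(np.mean(ab))})
    return pd.DataFrame(rows).set_index("k")


def me_densities(pmap: pd.DataFrame, atlas_t: DensityAtlas) -> DensityAtlas:
    """Convert t-type densities to me-type densities by linearity.

    Per region, the me density vector is the t density vector times the
    row-stochastic probability matrix; per-region totals are conserved.
    N/A regions stay N/A. Every t-type column of the atlas must have a
    probability row.
    """
    missing = [t for t in atlas_t.densities.columns if t not in pmap.index]
    if missing:
        raise MappingError(f"t-types without probability rows: {missing}")
    P = pmap.loc[list(atlas_t.densities.columns)]
    dens = atlas_t.densities.fillna(0.0).to_numpy() @ P.to_numpy()
    dens = pd.DataFrame(dens, index=atlas_t.densities.index, columns=P.columns)
    na_rows = atlas_t.densities.isna().all(axis=1)
    dens.loc[na_rows] = np.nan
    counts = atlas_t.counts.fillna(0.0).to_numpy() @ P.to_numpy()
    counts = pd.DataFrame(counts, index=dens.index, columns=dens.columns)
    counts.loc[na_rows] = np.nan
    return DensityAtlas(
        densities=dens,
        counts=counts,
        region_volumes=None if atlas_t.region_volumes is None else atlas_t.region_volumes.copy(),
        provenance=atlas_t.provenance + "+me_map",
    )


@dataclass
class MrnaValidation:
    """Comparison of regional mRNA densities computed from t-types vs
    recomputed from me-types."""

    mrna_t: pd.DataFrame  # region × gene
    mrna_me: pd.DataFrame  # region × gene
    correction: float
    relative_error: pd.DataFrame  # region × gene, NaN where mrna_t == 0
    error_by_region: pd.Series
    error_by_gene: pd.Series


def mrna_validate(
    densities_t: pd.DataFrame,
    pmap: pd.DataFrame,
    expression_t: pd.DataFrame,
    n_me: int | None = None,
    n_t: int | None = None,
) -> MrnaValidation:
    """Validate the t→me reduction through regional mRNA densities.

    ``mRNA_t = D_t · E_t`` (regions × genes). The me route applies the
    probabilistic map twice — ``D_me = D_t·P`` and ``E_me = Pᵀ·E_t`` — so
    ``mRNA_me = D_t·P·Pᵀ·E_t × correction`` with
    ``correction = (N_me/N_t)²`` compensating the density inflation of
    collapsing N_t types onto N_me types. With P the identity the two
    routes agree exactly (error ≡ 0). Relative error is
    ``|mRNA_t − mRNA_me| / mRNA_t`` (N/A where mRNA_t = 0), also summed
    over regions and over genes.
    """
    t_order = [t for t in densities_t.columns]
    if list(expression_t.index) != t_order:
        expression_t = expression_t.loc[t_order]
    P = pmap.loc[t_order].to_numpy(dtype=float)
    D = densities_t.fillna(0.0).to_numpy(dtype=float)
    E = expression_t.to_numpy(dtype=float)
    n_t = n_t if n_t is not None else P.shape[0]
    n_me = n_me if n_me is not None else P.shape[1]
    correction = (n_me / n_t) ** 2
    mrna_t = D @ E
    mrna_me = (D @ P) @ (P.T @ E) * correction
    genes = expression_t.columns
    regions = densities_t.index
    mrna_t = pd.DataFrame(mrna_t, index=regions, columns=genes)
    mrna_me = pd.DataFrame(mrna_me, index=regions, columns=genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (mrna_t - mrna_me).abs() / mrna_t
    rel[mrna_t == 0] = np.nan
    sum_r_t = mrna_t.sum(axis=1)
    sum_r_me = mrna_me.sum(axis=1)
    sum_g_t = mrna_t.sum(axis=0)
    sum_g_me = mrna_me.sum(axis=0)
    err_r = ((sum_r_t - sum_r_me).abs() / sum_r_t.replace(0, np.nan)).rename("rel_error")
    err_g = ((sum_g_t - sum_g_me).abs() / sum_g_t.replace(0, np.nan)).rename("rel_error")
    return MrnaValidation(
        mrna_t=mrna_t,
        mrna_me=mrna_me,
        correction=float(correction),
        relative_error=rel,
        error_by_region=err_r,
        error_by_gene=err_g,
    )
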