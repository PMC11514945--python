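"""Fetal-adult co-clustering preprocessing and neighbor enrichment.

The preprocessing chain is the standard single-cell recipe: CP10K
library-size normalization, optional averaging within (cell type x
replicate) groups, log1p, dispersion-based highly-variable-gene
selection, regression of total count and mitochondrial fraction,
per-gene scaling with upper clipping, PCA, and a seeded 2-D UMAP.

The neighbor-enrichment analysis asks whether tumor samples sit closer
to the fetal centroid than normal samples do: using Euclidean distance
in a 10-PC space, the k nearest non-fetal samples of the fetal centroid
are collected for each k and, per class (tumor / NAT / normal), the
fraction of that class captured is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io_formats import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingConfig:
    """Knobs of the embedding chain; defaults follow common single-cell use.

    HVG thresholds are interpreted on the log1p scale (mean in
    (0.0125, 3), normalized dispersion > 0.5); scaling clips values
    above 10 standard deviations.
    """

    hvg_min_mean: float = 0.0125
    hvg_max_mean: float = 3.0
    hvg_min_dispersion: float = 0.5
    hvg_n_bins: int = 20
    scale_clip: float = 10.0
    n_pcs: int = 50
    n_pcs_distance: int = 10
    umap_seed: int = 0
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    mito_prefixes: tuple[str, ...] = ("MT-",)

    def __post_init__(self) -> None:
        if not self.hvg_min_mean < self.hvg_max_mean:
            raise ValueError("hvg_min_mean must be below hvg_max_mean")
        if self.n_pcs_distance > self.n_pcs:
            raise ValueError("n_pcs_distance cannot exceed n_pcs")


@dataclass
class EmbeddingResult:
    pc_scores: pd.DataFrame  # units x n_pcs, ordered by explained variance
    umap_coords: pd.DataFrame  # units x 2
    hvg_list: list[str]
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.array([]))


def preprocess_embedding(
    counts: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    config: EmbeddingConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CP10K-normalize, optionally group-average, and log1p a count matrix.

    *counts* is genes x units (cells or samples).  When *annotations*
    with ``cell_type`` and ``donor`` columns are given, CP10K profiles
    are averaged within each (cell_type, donor) group before log1p.
    Returns (units x genes log1p matrix, per-unit covariates with
    ``total_count`` and ``mito_fraction`` computed on the raw counts).
    """
    config = config or EmbeddingConfig()
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        zero = totals.index[totals == 0][0]
        raise ValidationError(f"unit {zero!r} has zero total count")
    is_mito = pd.Index(counts.index).str.startswith(tuple(config.mito_prefixes))
    mito_frac = counts.loc[is_mito].sum(axis=0) / totals if is_mito.any() \
        else pd.Series(0.0, index=counts.columns)
    cp10k = counts.div(totals, axis=1) * 1e4

    if annotations is not None:
        ann = annotations.loc[counts.columns]
        groups = ann["cell_type"].astype(str) + "::" + ann["donor"].astype(str)
        cp10k = cp10k.T.groupby(groups).mean().T
        covar = pd.DataFrame({
            "total_count": totals.groupby(groups).mean(),
            "mito_fraction": mito_frac.groupby(groups).mean(),
        })
    else:
        covar = pd.DataFrame({"total_count": totals.astype(float),
                              "mito_fraction": mito_frac})
    normalized = np.log1p(cp10k).T  # units x genes
    return normalized, covar.loc[normalized.index]


def select_hvg(normalized: pd.DataFrame, config: EmbeddingConfig | None = None) -> list[str]:
    """Dispersion-based highly-variable genes on a units x genes log1p matrix.

    Per gene, the mean and dispersion (variance/mean) are computed on the
    linear (expm1) scale; the dispersion is z-scored within 20
    equal-frequency bins of log1p(mean); genes pass when log1p(mean) lies
    in (hvg_min_mean, hvg_max_mean) and the normalized dispersion exceeds
    hvg_min_dispersion.
    """
    config = config or EmbeddingConfig()
    if normalized.shape[0] < 2:
        raise ValidationError("HVG selection needs at least 2 units")
    lin = np.expm1(normalized.to_numpy())
    mean = lin.mean(axis=0)
    var = lin.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    log_mean = np.log1p(mean)
    with np.errstate(divide="ignore"):
        log_disp = np.log(disp)

    df = pd.DataFrame({"mean": log_mean, "disp": log_disp},
                      index=normalized.columns)
    ok = np.isfinite(df["disp"])
    bins = pd.qcut(df.loc[ok, "mean"], q=config.hvg_n_bins, duplicates="drop")
    norm_disp = pd.Series(np.nan, index=df.index)
    for _, sub in df.loc[ok].groupby(bins, observed=True):
        sd = sub["disp"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            # single-gene or constant-dispersion bin: center only
            norm_disp.loc[sub.index] = 0.0
        else:
            norm_disp.loc[sub.index] = (sub["disp"] - sub["disp"].mean()) / sd

    passing = (
        (df["mean"] > config.hvg_min_mean)
        & (df["mean"] < config.hvg_max_mean)
        & (norm_disp > config.hvg_min_dispersion)
    )
    hvg = list(df.index[passing.fillna(False)])
    if not hvg:
        raise ValidationError("no gene passes the HVG thresholds")
    logger.info("select_hvg: %d / %d genes highly variable", len(hvg), df.shape[0])
    return hvg


def regress_and_scale(
    matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    config: EmbeddingConfig | None = None,
) -> pd.DataFrame:
    """Regress out total count and mito fraction, then scale each gene.

    Per gene: ordinary-least-squares residual against
    [1, total_count, mito_fraction]; residuals are standardized to mean 0
    and unit (population) variance; values above ``scale_clip`` are set
    to the clip value.  Genes constant after regression become all-zero.
    """
    config = config or EmbeddingConfig()
    cov = covariates.loc[matrix.index, ["total_count", "mito_fraction"]].to_numpy()
    if not np.isfinite(cov).all():
        raise ValidationError("covariates contain non-finite values")
    x = np.column_stack([np.ones(len(matrix)), cov])
    y = matrix.to_numpy()
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sd = resid.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.info("regress_and_scale: %d constant genes scaled to zero",
                    int(constant.sum()))
    sd_safe = np.where(constant, 1.0, sd)
    scaled = (resid - resid.mean(axis=0)) / sd_safe
    scaled[:, constant] = 0.0
    scaled = np.minimum(scaled, config.scale_clip)
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def pca_umap(scaled: pd.DataFrame, config: EmbeddingConfig | None = None) -> EmbeddingResult:
    """PCA (centering only) followed by a seeded 2-D UMAP of the PC scores."""
    import umap  # deferred: numba compilation makes this import slow

    config = config or EmbeddingConfig()
    n_units = scaled.shape[0]
    if n_units < 3:
        raise ValidationError("embedding needs at least 3 units")
    n_pcs = min(config.n_pcs, n_units - 1, scaled.shape[1])
    if n_pcs < config.n_pcs:
        logger.warning("pca_umap: reducing n_pcs from %d to %d (limited by data)",
                       config.n_pcs, n_pcs)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(scaled.to_numpy())
    pc_cols = [f"PC{i + 1}" for i in range(n_pcs)]
    pc_scores = pd.DataFrame(scores, index=scaled.index, columns=pc_cols)

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(config.umap_n_neighbors, n_units - 1),
        min_dist=config.umap_min_dist,
        metric="euclidean",
        random_state=config.umap_seed,
    )
    coords = reducer.fit_transform(scores)
    umap_coords = pd.DataFrame(coords, index=scaled.index,
                               columns=["UMAP1", "UMAP2"])
    return EmbeddingResult(pc_scores, umap_coords, list(scaled.columns),
                           explained_variance_ratio=pca.explained_variance_ratio_)


def fetal_neighbor_enrichment(
    pc_scores: pd.DataFrame,
    class_labels: pd.Series,
    ks: list[int],
    config: EmbeddingConfig | None = None,
) -> pd.DataFrame:
    """Per-class capture among the k nearest non-fetal neighbors of the
    fetal centroid.

    The centroid is the mean of the fetal samples' first
    ``n_pcs_distance`` PC coordinates; fetal samples are excluded from
    the neighbor pool.  For each requested k the k closest non-fetal
    samples (Euclidean distance, ties broken by sample id) are taken and
    each class's captured fraction |class in subset| / |class total| is
    reported.  Rows are indexed by k; columns are the non-fetal classes.
    """
    config = config or EmbeddingConfig()
    labels = class_labels.loc[pc_scores.index]
    fetal_mask = labels == "fetal"
    if not fetal_mask.any():
        raise ValidationError("no fetal samples to form a centroid")
    n_dims = min(config.n_pcs_distance, pc_scores.shape[1])
    coords = pc_scores.iloc[:, :n_dims].to_numpy()
    centroid = coords[fetal_mask.to_numpy()].mean(axis=0)

    pool_idx = pc_scores.index[~fetal_mask]
    n_pool = len(pool_idx)
    for k in ks:
        if k > n_pool:
            raise ValidationError(f"k={k} exceeds the {n_pool} non-fetal samples")
    dist = np.linalg.norm(coords[~fetal_mask.to_numpy()] - centroid, axis=1)
    # stable two-key ordering: by distance, ties broken by sample id
    order = (pd.Series(dist, index=pool_idx)
             .sort_index(kind="mergesort")
             .sort_values(kind="mergesort"))
    ranked = list(order.index)

    classes = sorted(labels[~fetal_mask].unique())
    totals = labels[~fetal_mask].value_counts()
    rows = {}
    for k in sorted(ks):
        subset = labels.loc[ranked[:k]]
        rows[k] = {c: float((subset == c).sum() / totals[c]) for c in classes}
    out = pd.DataFrame.from_dict(rows, orient="index")[classes]
    out.index.name = "k"
    return out
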