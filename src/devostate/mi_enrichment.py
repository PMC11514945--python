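"""Information-theoretic gene-set enrichment against the fetalness index.

Following the iPAGE framework: genes are ranked by their Spearman
correlation with the index, the ranking is cut into 15 equal bins, and
for each gene set the plug-in mutual information (in bits) between the
bin variable and set membership is computed.  Significance comes from a
permutation null (gene-to-bin assignment shuffled with membership
fixed); direction comes from the per-bin over/under-representation
profile: a set concentrated among positively correlated genes gets sign
+1, one concentrated among negatively correlated genes sign -1.

MI itself is non-negative; the signed quantity reported alongside it is
the sign of the Spearman correlation between bin index and the per-bin
log2(observed/expected) profile.  Because everything downstream of the
per-gene Spearman correlation uses ranks only, the whole analysis is
invariant to strictly monotone transforms of the index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_formats import BulkExpressionMatrix, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 15
DEFAULT_N_PERM = 10_000


@dataclass
class CorrelationRanking:
    """Genes ordered by Spearman rho vs the index, cut into equal bins."""

    genes: list[str]  # ascending rho; ties broken by gene id
    rho: pd.Series  # gene -> Spearman rho, in ranking order
    bins: np.ndarray  # per-gene bin index, 1..n_bins, monotone in rank
    n_bins: int

    @property
    def bin_sizes(self) -> np.ndarray:
        return np.bincount(self.bins, minlength=self.n_bins + 1)[1:]


def correlate_with_index(
    expr: BulkExpressionMatrix | pd.DataFrame, index: pd.Series
) -> pd.Series:
    """Per-gene Spearman correlation (average ranks for ties) with the index.

    Constant genes have no defined rank correlation; they are dropped and
    logged.
    """
    values = expr.values if isinstance(expr, BulkExpressionMatrix) else expr
    samples = [s for s in values.index if s in index.index]
    if len(samples) < 3:
        raise ValidationError("Spearman correlation needs at least 3 shared samples")
    x = values.loc[samples].to_numpy()
    y = index.loc[samples].to_numpy()

    constant = x.std(axis=0) == 0
    if constant.any():
        logger.info("correlate_with_index: dropping %d constant genes",
                    int(constant.sum()))
    x = x[:, ~constant]
    genes = values.columns[~constant]

    xr = scipy.stats.rankdata(x, axis=0)
    yr = scipy.stats.rankdata(y)
    xr = (xr - xr.mean(axis=0)) / xr.std(axis=0)
    yr = (yr - yr.mean()) / yr.std()
    rho = (xr * yr[:, None]).mean(axis=0)
    return pd.Series(rho, index=genes, name="rho")


def bin_gene_ranks(rho: pd.Series, n_bins: int = DEFAULT_N_BINS) -> CorrelationRanking:
    """Sort genes ascending by rho (ties by gene id) and cut into equal bins.

    Bin 1 holds the most negatively correlated genes, bin ``n_bins`` the
    most positive; when the gene count is not divisible by ``n_bins``
    the remainder goes to the last bins, so bin sizes differ by at most 1.
    """
    n = len(rho)
    if n < n_bins:
        raise ValidationError(f"{n} genes cannot fill {n_bins} bins")
    ordered = (pd.DataFrame({"rho": rho.to_numpy(), "gene": rho.index.astype(str)})
               .sort_values(["rho", "gene"]))
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    if rem:
        sizes[-rem:] += 1
    bins = np.repeat(np.arange(1, n_bins + 1), sizes)
    rho_sorted = pd.Series(ordered["rho"].to_numpy(), index=ordered["gene"],
                           name="rho")
    return CorrelationRanking(list(ordered["gene"]), rho_sorted, bins, n_bins)


def _member_counts(ranking: CorrelationRanking, geneset: frozenset[str] | set[str]
                   ) -> np.ndarray:
    member = np.fromiter((g in geneset for g in ranking.genes), dtype=bool,
                         count=len(ranking.genes))
    return np.bincount(ranking.bins[member], minlength=ranking.n_bins + 1)[1:]


def _mi_bits(member_counts: np.ndarray, bin_sizes: np.ndarray) -> np.ndarray:
    """Plug-in MI (bits) between bin and membership; vectorized over rows.

    ``member_counts`` may be (n_bins,) or (n_perm, n_bins).
    """
    counts = np.atleast_2d(member_counts).astype(float)
    sizes = bin_sizes.astype(float)
    n = sizes.sum()
    joint = np.stack([counts, sizes - counts], axis=-1) / n  # (rows, bins, 2)
    p_bin = sizes / n
    m = counts.sum(axis=1, keepdims=True) / n
    p_mem = np.stack([np.broadcast_to(m, counts.shape),
                      np.broadcast_to(1 - m, counts.shape)], axis=-1)
    expected = p_bin[None, :, None] * p_mem
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / expected)
    mi = np.nansum(term, axis=(1, 2))
    mi = np.maximum(mi, 0.0)  # guard tiny negative round-off
    return mi if member_counts.ndim > 1 else mi[0]


def geneset_mutual_information(
    ranking: CorrelationRanking, geneset: frozenset[str] | set[str]
) -> float:
    """Plug-in discrete MI (bits) between bin index and set membership."""
    counts = _member_counts(ranking, geneset)
    if counts.sum() == 0:
        raise ValidationError("gene set does not intersect the ranked genes")
    return float(_mi_bits(counts, ranking.bin_sizes))


def permutation_pvalue(
    ranking: CorrelationRanking,
    geneset: frozenset[str] | set[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for the observed MI.

    The null shuffles the gene-to-bin assignment with membership fixed,
    which is equivalent to drawing the per-bin member counts from a
    multivariate hypergeometric distribution.  The add-one estimator
    p = (1 + #{MI_null >= MI_obs}) / (1 + n_perm) avoids zero p-values.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    counts = _member_counts(ranking, geneset)
    n_members = int(counts.sum())
    if n_members == 0:
        raise ValidationError("gene set does not intersect the ranked genes")
    obs = _mi_bits(counts, ranking.bin_sizes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null_counts = rng.multivariate_hypergeometric(
        ranking.bin_sizes, n_members, size=n_perm
    )
    null = _mi_bits(null_counts, ranking.bin_sizes)
    return float((1 + np.sum(null >= obs)) / (1 + n_perm))


def enrichment_sign(
    ranking: CorrelationRanking, geneset: frozenset[str] | set[str]
) -> tuple[int, np.ndarray]:
    """Direction of enrichment plus the per-bin over/under profile.

    Profile: log2((observed + 0.5) / (expected + 0.5)) per bin.  The sign
    is the sign of the Spearman correlation between bin index and the
    per-bin membership *rate* (members / bin size); the rate rather than
    the smoothed profile is used so that bins differing only in size do
    not introduce spurious order among equally (un)represented bins.
    Flat membership yields sign 0.
    """
    counts = _member_counts(ranking, geneset)
    sizes = ranking.bin_sizes
    expected = sizes * counts.sum() / sizes.sum()
    profile = np.log2((counts + 0.5) / (expected + 0.5))
    rate = counts / sizes
    if np.allclose(rate, rate[0]):
        return 0, profile
    rho = scipy.stats.spearmanr(np.arange(1, ranking.n_bins + 1), rate).statistic
    if not np.isfinite(rho) or rho == 0:
        return 0, profile
    return (1 if rho > 0 else -1), profile


def enrich_collection(
    expr: BulkExpressionMatrix | pd.DataFrame,
    index: pd.Series,
    collection: GeneSetCollection,
    n_bins: int = DEFAULT_N_BINS,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """MI, permutation p, BH FDR, sign and profile for every gene set.

    Returns a DataFrame indexed by set name with columns ``mi_bits``,
    ``pvalue``, ``fdr``, ``significant``, ``sign`` and ``profile``
    (semicolon-joined per-bin values).  Deterministic given the seed:
    each set gets an independent stream spawned in sorted-name order.
    """
    rho = correlate_with_index(expr, index)
    ranking = bin_gene_ranks(rho, n_bins=n_bins)
    names = sorted(collection.sets)
    streams = np.random.SeedSequence(seed).spawn(len(names))
    rows = []
    for name, ss in zip(names, streams):
        genes = collection.sets[name] & set(ranking.genes)
        if not genes:
            logger.warning("enrich_collection: set %r has no ranked genes; skipped",
                           name)
            continue
        mi = geneset_mutual_information(ranking, genes)
        p = permutation_pvalue(ranking, genes, n_perm=n_perm,
                               seed=np.random.default_rng(ss))
        sign, profile = enrichment_sign(ranking, genes)
        rows.append({"set": name, "mi_bits": mi, "pvalue": p, "sign": sign,
                     "profile": ";".join(f"{v:.6g}" for v in profile)})
    if not rows:
        raise ValidationError("no gene set overlaps the ranked genes")
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_alpha
    return out[["mi_bits", "pvalue", "fdr", "significant", "sign", "profile"]]
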