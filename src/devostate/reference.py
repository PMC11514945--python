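"""Build a developmental-status-aware signature matrix from single cells.

The recipe mirrors the reference-profile construction used by
CIBERSORT-style deconvolution, with cell states kept separate by
developmental stage (fetal vs adult):

1. drop low-quality cells (total UMI < 500 by default);
2. normalize each cell to counts-per-million (CPM);
3. drop cell states supported by < 20 high-quality cells;
4. for each state, average the CPM profiles of a random half of its
   cells into a "mega cell"; repeat 10 times to obtain replicates;
5. one-vs-rest Mann-Whitney U test per gene on the replicates, BH
   adjustment, and the top 200 genes by log2 fold change among those
   with adjusted p < 0.01 become the state's signature genes;
6. optionally remove confounding genes (cell cycle, ribosome
   biogenesis, apoptosis, mitochondrial) *before* the top-N cut, so each
   state can still fill its quota from eligible genes;
7. pool the union of signature genes and record each state's mean CPM
   over all of its high-quality cells.

A cell state is a (tissue, cell_type, stage) triple; its identifier is
``tissue|cell_type|stage``.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    CountMatrix,
    GeneSetCollection,
    OrthologMap,
    SignatureMatrix,
    ValidationError,
    state_id,
    validate_annotations,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_UMI = 500
DEFAULT_MIN_CELLS = 20
DEFAULT_N_REPLICATES = 10
DEFAULT_FRACTION = 0.5
DEFAULT_TOP_N = 200
DEFAULT_ALPHA_ADJ = 0.01

#: both groups at or below this many replicates -> exact Mann-Whitney null
_EXACT_MW_LIMIT = 12


@dataclass
class CPMMatrix:
    """Genes x cells counts-per-million; every column sums to 1e6."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1e6, rtol=1e-9):
            raise ValidationError("CPM columns do not sum to 1e6")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MegaReplicateSet:
    """Averaged-CPM pseudo-replicates per cell state.

    ``profiles`` holds genes x (state, replicate) mean-CPM columns;
    ``members`` records which cells entered each replicate; ``stages``
    maps each state to fetal/adult.
    """

    profiles: pd.DataFrame  # genes x MultiIndex(state, replicate)
    members: dict[tuple[str, int], list[str]]
    stages: pd.Series  # state -> stage

    @property
    def states(self) -> list[str]:
        return list(self.profiles.columns.get_level_values(0).unique())

    def state_profiles(self, state: str) -> pd.DataFrame:
        return self.profiles[state]


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


def filter_cells(counts: CountMatrix, min_umi: int = DEFAULT_MIN_UMI) -> CountMatrix:
    """Drop cells whose total UMI count is below *min_umi*."""
    if min_umi < 1:
        raise ValueError("min_umi must be >= 1")
    totals = counts.counts.sum(axis=0)
    keep = totals >= min_umi
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValidationError(
            f"all {len(keep)} cells fall below min_umi={min_umi}; "
            "review the threshold or the input"
        )
    if n_removed:
        logger.info("filter_cells: removed %d / %d low-quality cells", n_removed, len(keep))
    return CountMatrix(counts.counts.loc[:, keep])


def normalize_cpm(counts: CountMatrix) -> CPMMatrix:
    """Scale every cell to counts-per-million."""
    totals = counts.counts.sum(axis=0).to_numpy().astype(float)
    if (totals == 0).any():
        zero = counts.counts.columns[totals == 0][0]
        raise ValidationError(f"cell {zero!r} has zero total count; filter cells first")
    values = counts.counts.to_numpy(dtype=float) / totals * 1e6
    return CPMMatrix(pd.DataFrame(values, index=counts.counts.index,
                                  columns=counts.counts.columns))


def cell_states(annotations: pd.DataFrame) -> pd.Series:
    """Map every annotated cell to its ``tissue|cell_type|stage`` state id."""
    return pd.Series(
        [state_id(t, c, s) for t, c, s in
         zip(annotations["tissue"], annotations["cell_type"], annotations["stage"])],
        index=annotations.index,
        name="cell_state",
    )


def filter_cell_types(
    counts: CountMatrix,
    annotations: pd.DataFrame,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> list[str]:
    """Return the cell states supported by at least *min_cells* cells in *counts*."""
    ann = validate_annotations(counts, annotations)
    states = cell_states(ann)
    tally = states.value_counts()
    retained = sorted(tally.index[tally >= min_cells])
    dropped = sorted(tally.index[tally < min_cells])
    if dropped:
        logger.info("filter_cell_types: dropped %d states with < %d cells: %s",
                    len(dropped), min_cells, dropped)
    if not retained:
        raise ValidationError(
            f"no cell state has >= {min_cells} high-quality cells"
        )
    return retained


# ---------------------------------------------------------------------------
# mega-cell replicates
# ---------------------------------------------------------------------------


def _replicate_rng(seed: int, state: str, replicate: int) -> np.random.Generator:
    # stable per (state, replicate): adding a state never perturbs other draws
    key = (zlib.crc32(state.encode("utf-8")), replicate)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def make_mega_replicates(
    cpm: CPMMatrix,
    annotations: pd.DataFrame,
    states: list[str] | None = None,
    n_replicates: int = DEFAULT_N_REPLICATES,
    fraction: float = DEFAULT_FRACTION,
    seed: int = 0,
) -> MegaReplicateSet:
    """Average a random half (without replacement) of each state's cells,
    *n_replicates* times, into mega-cell CPM profiles."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    ann = annotations.loc[cpm.cell_ids]
    all_states = cell_states(ann)
    if states is None:
        states = sorted(all_states.unique())
    stage_of = {s: s.rsplit("|", 1)[1] for s in states}

    columns: dict[tuple[str, int], np.ndarray] = {}
    members: dict[tuple[str, int], list[str]] = {}
    values = cpm.values
    for state in states:
        cells = sorted(all_states.index[all_states == state])
        n_take = int(np.floor(len(cells) * fraction))
        if n_take < 1:
            raise ValidationError(
                f"state {state!r}: fraction {fraction} of {len(cells)} cells is < 1"
            )
        block = values[cells].to_numpy()
        for rep in range(1, n_replicates + 1):
            rng = _replicate_rng(seed, state, rep)
            idx = rng.choice(len(cells), size=n_take, replace=False)
            columns[(state, rep)] = block[:, idx].mean(axis=1)
            members[(state, rep)] = [cells[i] for i in idx]

    profiles = pd.DataFrame(columns, index=values.index)
    profiles.columns = pd.MultiIndex.from_tuples(profiles.columns,
                                                 names=["cell_state", "replicate"])
    stages = pd.Series(stage_of, name="stage")
    return MegaReplicateSet(profiles, members, stages)


# ---------------------------------------------------------------------------
# signature gene selection
# ---------------------------------------------------------------------------


def _flag_selected(table: pd.DataFrame, top_n: int, alpha_adj: float) -> pd.DataFrame:
    """(Re)compute the selected flag and rank per state from p_adj and log2fc.

    Passing genes are ordered by descending log2fc, ties broken by
    ascending adjusted p then gene id; the first *top_n* are selected.
    """
    table = table.copy()
    table["selected"] = False
    table["rank"] = np.nan
    for state, sub in table.groupby("cell_state", sort=False):
        passing = sub[sub["p_adj"] < alpha_adj]
        order = passing.sort_values(
            ["log2fc", "p_adj", "gene"], ascending=[False, True, True]
        )
        chosen = order.index[:top_n]
        table.loc[chosen, "selected"] = True
        table.loc[chosen, "rank"] = np.arange(1, len(chosen) + 1)
    return table


def select_signature_genes(
    replicates: MegaReplicateSet,
    top_n: int = DEFAULT_TOP_N,
    alpha_adj: float = DEFAULT_ALPHA_ADJ,
) -> pd.DataFrame:
    """One-vs-rest differential expression on mega-cell replicates.

    For every state, each gene's replicate values are compared against the
    pooled replicates of all other states with a one-sided (greater)
    Mann-Whitney U test; p-values are Benjamini-Hochberg adjusted across
    genes within the state.  Returns a long table with one row per
    (cell_state, gene): ``u_stat, pvalue, p_adj, log2fc, selected, rank``.

    The exact U null distribution is used when both groups have at most
    12 replicates, the tie-corrected normal approximation with
    continuity correction otherwise.
    """
    states = replicates.states
    if len(states) < 2:
        raise ValidationError("signature selection needs at least 2 cell states")
    genes = replicates.profiles.index
    frames = []
    for state in states:
        focal = replicates.profiles[state].to_numpy()  # genes x R
        rest_cols = [s for s in states if s != state]
        rest = replicates.profiles[rest_cols].to_numpy()  # genes x R_rest
        if focal.shape[1] < 2 or rest.shape[1] < 2:
            raise ValidationError(
                f"state {state!r}: need >= 2 replicates per group for the U test"
            )
        method = (
            "exact"
            if focal.shape[1] <= _EXACT_MW_LIMIT and rest.shape[1] <= _EXACT_MW_LIMIT
            else "asymptotic"
        )
        res = mannwhitneyu(focal, rest, axis=1, alternative="greater", method=method)
        p_adj = multipletests(res.pvalue, method="fdr_bh")[1]
        log2fc = np.log2((focal.mean(axis=1) + 1.0) / (rest.mean(axis=1) + 1.0))
        frames.append(pd.DataFrame({
            "cell_state": state,
            "gene": genes,
            "u_stat": res.statistic,
            "pvalue": res.pvalue,
            "p_adj": p_adj,
            "log2fc": log2fc,
        }))
    table = pd.concat(frames, ignore_index=True)
    table.attrs["top_n"] = top_n
    table.attrs["alpha_adj"] = alpha_adj
    return _flag_selected(table, top_n, alpha_adj)


def apply_exclusions(
    table: pd.DataFrame, catalog: GeneSetCollection | None
) -> pd.DataFrame:
    """Remove catalogued genes from signature candidacy before the top-N cut.

    Because exclusion happens before truncation, each state refills its
    selection from the next-ranked eligible genes.  An empty catalog is
    the identity.
    """
    if catalog is None or len(catalog) == 0:
        return table
    excluded = catalog.union()
    for name, genes in catalog.sets.items():
        hit = table.loc[table["gene"].isin(genes), "gene"].nunique()
        logger.info("apply_exclusions: %s removes %d candidate genes", name, hit)
    out = table[~table["gene"].isin(excluded)].copy()
    if out.empty:
        raise ValidationError("exclusion catalog removed every candidate gene")
    return _flag_selected(out, table.attrs.get("top_n", DEFAULT_TOP_N),
                          table.attrs.get("alpha_adj", DEFAULT_ALPHA_ADJ))


def state_mean_profiles(
    cpm: CPMMatrix,
    annotations: pd.DataFrame,
    states: list[str] | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Mean CPM per gene over each state's cells (genes x states)."""
    ann = annotations.loc[cpm.cell_ids]
    all_states = cell_states(ann)
    if states is None:
        states = sorted(all_states.unique())
    values = cpm.values if genes is None else cpm.values.loc[genes]
    cols = {}
    for state in states:
        cells = all_states.index[all_states == state]
        if len(cells) == 0:
            raise ValidationError(f"state {state!r} has no cells in the CPM matrix")
        cols[state] = values[cells].mean(axis=1)
    return pd.DataFrame(cols)


def build_signature_matrix(
    cpm: CPMMatrix,
    annotations: pd.DataFrame,
    table: pd.DataFrame,
    provenance: dict | None = None,
) -> SignatureMatrix:
    """Pool selected genes and each state's mean CPM over all of its cells."""
    selected = table[table["selected"]]
    if selected.empty:
        raise ValidationError("no selected signature genes")
    genes = sorted(selected["gene"].unique())
    missing = [g for g in genes if g not in cpm.values.index]
    if missing:
        raise ValidationError(f"selected genes absent from CPM matrix: {missing[:5]}")
    states = sorted(selected["cell_state"].unique())
    values = state_mean_profiles(cpm, annotations, states=states, genes=genes)
    stages = pd.Series({s: s.rsplit("|", 1)[1] for s in states}, name="stage")
    return SignatureMatrix(values, stages, provenance or {})


def map_orthologs(obj, omap: OrthologMap):
    """Rename gene rows via a one-to-one ortholog map, dropping unmapped genes.

    Accepts a gene-indexed DataFrame or a :class:`SignatureMatrix`; output
    rows follow the map's order restricted to genes present in the input.
    """
    if isinstance(obj, SignatureMatrix):
        mapped = map_orthologs(obj.values, omap)
        return SignatureMatrix(mapped, obj.stages.copy(), dict(obj.provenance))
    df = obj
    src = [g for g in omap.pairs if g in df.index]
    dropped = len(df.index) - len(src)
    if dropped:
        logger.info("map_orthologs: dropped %d genes without a one-to-one ortholog",
                    dropped)
    out = df.loc[src].copy()
    out.index = [omap.pairs[g] for g in src]
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def build_signature(
    counts: CountMatrix,
    annotations: pd.DataFrame,
    exclusions: GeneSetCollection | None = None,
    min_umi: int = DEFAULT_MIN_UMI,
    min_cells: int = DEFAULT_MIN_CELLS,
    n_replicates: int = DEFAULT_N_REPLICATES,
    fraction: float = DEFAULT_FRACTION,
    top_n: int = DEFAULT_TOP_N,
    alpha_adj: float = DEFAULT_ALPHA_ADJ,
    seed: int = 0,
) -> SignatureMatrix:
    """Run the full QC -> CPM -> mega-replicates -> DGE -> pooling pipeline.

    Deterministic given (input, seed, parameters).
    """
    hq = filter_cells(counts, min_umi=min_umi)
    states = filter_cell_types(hq, annotations, min_cells=min_cells)
    keep = cell_states(annotations.loc[hq.cell_ids]).isin(states)
    hq = CountMatrix(hq.counts.loc[:, keep[keep].index])
    cpm = normalize_cpm(hq)
    reps = make_mega_replicates(cpm, annotations, states=states,
                                n_replicates=n_replicates, fraction=fraction,
                                seed=seed)
    table = select_signature_genes(reps, top_n=top_n, alpha_adj=alpha_adj)
    table = apply_exclusions(table, exclusions)
    provenance = {
        "min_umi": min_umi, "min_cells": min_cells,
        "n_replicates": n_replicates, "fraction": fraction,
        "top_n": top_n, "alpha_adj": alpha_adj, "seed": seed,
    }
    return build_signature_matrix(cpm, annotations, table, provenance)
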