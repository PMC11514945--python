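"""Readers and writers for the tabular formats the pipeline touches.

All tabular files are TSV (tab-separated, ``.`` decimal, UTF-8, lines
starting with ``#`` ignored).  Single-cell counts come either as a dense
TSV (first column gene ids, header cell ids) or as a MatrixMarket triplet
with ``features.tsv`` / ``barcodes.tsv`` sidecars.  Gene sets use the GMT
dialect.  Every reader validates its input and returns a typed object so
downstream modules never see malformed data.

Gene identifiers are treated as case-sensitive opaque strings; no
symbol/Ensembl translation is attempted (use an ortholog/alias map for
that).  Duplicate gene rows in *count* matrices are collapsed by
summation (and logged); duplicate genes in expression tables are an
error, because summing normalized values is not meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

VALID_STAGES = ("fetal", "adult")

#: separator used to build a cell-state identifier from (tissue, cell_type, stage)
STATE_SEP = "|"


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A well-formed file carries values that violate a contract."""


def state_id(tissue: str, cell_type: str, stage: str) -> str:
    """Build the canonical cell-state identifier ``tissue|cell_type|stage``."""
    return STATE_SEP.join((tissue, cell_type, stage))


def parse_state_id(state: str) -> tuple[str, str, str]:
    parts = state.split(STATE_SEP)
    if len(parts) != 3:
        raise ValidationError(f"malformed cell-state id {state!r}")
    return parts[0], parts[1], parts[2]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Genes x cells UMI counts with unique, ordered identifiers."""

    counts: pd.DataFrame  # genes x cells, non-negative integers

    def __post_init__(self) -> None:
        self.counts = _validate_counts(self.counts)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class BulkExpressionMatrix:
    """Samples x genes expression values tagged with their unit.

    FPKM-tagged matrices must be converted with
    :func:`devostate.deconvolution.fpkm_to_tpm` before deconvolution.
    """

    values: pd.DataFrame  # samples x genes, non-negative reals
    unit: str  # "FPKM" or "TPM"

    def __post_init__(self) -> None:
        if self.unit not in ("FPKM", "TPM"):
            raise ValidationError(f"unknown expression unit {self.unit!r}")
        v = self.values
        if v.index.duplicated().any():
            raise FormatError("duplicate sample ids in expression table")
        if v.columns.duplicated().any():
            raise FormatError("duplicate gene ids in expression table")
        arr = v.to_numpy()
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise FormatError(
                f"NaN expression value at sample {v.index[r]!r}, gene {v.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative expression value at sample {v.index[r]!r}, gene {v.columns[c]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. hallmark signatures or exclusion lists)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def union(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for genes in self.sets.values():
            out |= genes
        return out


@dataclass
class OrthologMap:
    """One-to-one gene id mapping between two namespaces (e.g. human-mouse)."""

    pairs: dict[str, str]  # source -> target, bijective

    def __post_init__(self) -> None:
        targets = list(self.pairs.values())
        if len(set(targets)) != len(targets):
            dup = pd.Series(targets).value_counts()
            bad = dup.index[dup > 1][0]
            raise ValidationError(
                f"ortholog map is not one-to-one: target {bad!r} appears more than once"
            )

    def inverse(self) -> "OrthologMap":
        return OrthologMap({t: s for s, t in self.pairs.items()})


@dataclass
class SignatureMatrix:
    """Genes x cell-states mean-CPM reference with a stage label per state."""

    values: pd.DataFrame  # genes x states
    stages: pd.Series  # state -> "fetal" | "adult"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("signature matrix contains negative values")
        missing = [s for s in self.values.columns if s not in self.stages.index]
        if missing:
            raise ValidationError(f"states without a stage label: {missing}")
        bad = [s for s in self.values.columns if self.stages[s] not in VALID_STAGES]
        if bad:
            raise ValidationError(f"states with invalid stage labels: {bad}")
        self.stages = self.stages.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_states(self) -> list[str]:
        return list(self.values.columns)

    @property
    def fetal_states(self) -> list[str]:
        return [s for s in self.values.columns if self.stages[s] == "fetal"]


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    arr = df.to_numpy()
    if np.isnan(arr.astype(float)).any():
        raise FormatError("count matrix contains NaN entries")
    if (arr < 0).any():
        raise FormatError("count matrix contains negative entries")
    if not np.allclose(arr, np.round(arr)):
        raise FormatError("count matrix contains non-integer entries")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate cell id {dup!r} in count matrix")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by summation", n_dup)
        df = df.groupby(level=0, sort=False).sum()
    df = df.astype(np.int64)
    df.index.name = None
    df.columns.name = None
    return df


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str}, **kw)


def read_count_matrix(
    path: str | Path,
    format: str = "dense_tsv",
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> CountMatrix:
    """Load a genes x cells UMI count matrix.

    ``mtx_triplet`` expects ``features.tsv`` and ``barcodes.tsv`` sidecars
    next to the ``.mtx`` file (first column of each holds the ids) unless
    explicit paths are given.  ``dense_tsv`` expects gene ids in the first
    column and cell ids in the header.
    """
    path = Path(path)
    if format == "dense_tsv":
        df = _read_tsv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return CountMatrix(df)
    if format == "mtx_triplet":
        feat = Path(features_path) if features_path else path.parent / "features.tsv"
        barc = Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        for p in (feat, barc):
            if not p.exists():
                raise FormatError(f"missing sidecar file {p}")
        mat = scipy.io.mmread(path)
        genes = pd.read_csv(feat, sep="\t", header=None, comment="#")[0].astype(str)
        cells = pd.read_csv(barc, sep="\t", header=None, comment="#")[0].astype(str)
        mat = scipy.sparse.coo_matrix(mat)
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(genes)} features, {len(cells)} barcodes)"
            )
        df = pd.DataFrame(mat.toarray(), index=genes, columns=cells)
        return CountMatrix(df)
    raise ValueError(f"unknown count-matrix format {format!r}")


def write_count_matrix(cm: CountMatrix, path: str | Path, format: str = "dense_tsv") -> None:
    path = Path(path)
    if format == "dense_tsv":
        out = cm.counts.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")
    elif format == "mtx_triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts.to_numpy()))
        pd.Series(cm.gene_ids).to_csv(path.parent / "features.tsv", sep="\t",
                                      header=False, index=False)
        pd.Series(cm.cell_ids).to_csv(path.parent / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")


REQUIRED_METADATA_COLUMNS = ("cell_id", "tissue", "cell_type", "stage")


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Load per-cell annotations (cell_id, tissue, cell_type, stage, donor).

    Stage strings are normalized to lowercase and must be ``fetal`` or
    ``adult``.  The returned frame is indexed by ``cell_id``.
    """
    df = _read_tsv(path)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cell metadata is missing required columns: {missing}")
    if "donor" not in df.columns:
        df["donor"] = "unknown"
    for col in ("cell_id", "tissue", "cell_type", "stage", "donor"):
        df[col] = df[col].astype(str).str.strip()
    df["stage"] = df["stage"].str.lower()
    bad = df.loc[~df["stage"].isin(VALID_STAGES)]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"unknown stage {row['stage']!r} for cell {row['cell_id']!r} "
            f"(allowed: {VALID_STAGES})"
        )
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValidationError(f"duplicate annotation for cell {dup!r}")
    return df.set_index("cell_id", drop=False)


def validate_annotations(cm: CountMatrix, annotations: pd.DataFrame) -> pd.DataFrame:
    """Check that every cell of *cm* has exactly one annotation row."""
    missing = [c for c in cm.cell_ids if c not in annotations.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} cells lack annotations (first: {missing[:3]})"
        )
    return annotations.loc[cm.cell_ids]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Load a GMT gene-set file (name, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT lines need >=3 tab-separated fields"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_expression_table(path: str | Path, unit: str) -> BulkExpressionMatrix:
    """Load a samples x genes expression table tagged with its unit."""
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BulkExpressionMatrix(df.astype(float), unit=unit)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Load a two-column TSV of one-to-one gene id pairs (source, target)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("ortholog map needs two tab-separated columns")
    pairs: dict[str, str] = {}
    for src, tgt in zip(df[0], df[1]):
        if src in pairs:
            raise ValidationError(
                f"ortholog map is not one-to-one: source {src!r} appears more than once"
            )
        pairs[src] = tgt
    return OrthologMap(pairs)


def read_signature(path: str | Path) -> SignatureMatrix:
    """Read a signature matrix written by :func:`write_signature`.

    Layout: a header row of cell-state ids, a second row labelled
    ``__stage__`` with the stage of each state, then one row per gene.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if "__stage__" not in df.index:
        raise FormatError("signature file lacks the __stage__ row")
    stages = df.loc["__stage__"].astype(str)
    stages.name = "stage"
    values = df.drop(index="__stage__").astype(float)
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns.name = None
    stages.index.name = None
    return SignatureMatrix(values, stages)


def write_signature(sig: SignatureMatrix, path: str | Path) -> None:
    stage_row = pd.DataFrame(
        [sig.stages.to_numpy()], index=["__stage__"], columns=sig.values.columns
    )
    out = pd.concat([stage_row, sig.values])
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.12g")


# ---------------------------------------------------------------------------
# generic tabular output
# ---------------------------------------------------------------------------


def write_table(obj, path: str | Path) -> None:
    """Write a package result object to TSV.

    Column/row order is taken from the object, so two writes of the same
    object are byte-identical; floats are rendered at 12 significant
    digits, which round-trips all quantities the pipeline produces.
    """
    from .deconvolution import DecompositionResult  # local import avoids a cycle

    if isinstance(obj, DecompositionResult):
        df = obj.as_table()
    elif isinstance(obj, pd.DataFrame):
        df = obj
    elif isinstance(obj, pd.Series):
        df = obj.to_frame()
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    if index_col is not None:
        df.index = df.index.astype(str)
    return df
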