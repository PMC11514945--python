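"""Reference-based mixture deconvolution and the fetalness index.

A bulk TPM profile is modelled as a non-negative combination of
cell-state signature columns.  Two solvers are provided:

``nu_svr``
    The published core of CIBERSORT: mixture and signature are z-scored,
    a linear nu-support-vector regression is fit for nu in
    {0.25, 0.5, 0.75}, the fit with the lowest root-mean-square
    reconstruction error is kept, negative coefficients are clipped to
    zero and the rest renormalized to sum to one ("relative fractions").

``nnls``
    Plain non-negative least squares on the raw values, renormalized the
    same way.  Exact and fast; serves as a transparent cross-check.

The fetalness index of a sample is the summed fraction assigned to
fetal-stage states — an aggregate of fetal cell programs that serves as
a quantitative stemness surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.svm import NuSVR

from .io_formats import BulkExpressionMatrix, SignatureMatrix, ValidationError

logger = logging.getLogger(__name__)

NU_GRID = (0.25, 0.5, 0.75)

#: fractions below this after renormalization are snapped to zero
_SNAP_TOL = 1e-8


@dataclass
class DecompositionResult:
    """Per-sample relative cell-state fractions plus solver diagnostics."""

    fractions: pd.DataFrame  # samples x states, rows sum to 1
    stages: pd.Series  # state -> fetal | adult
    diagnostics: pd.DataFrame  # samples x (rmse, r, nu)
    failures: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy()
        if (arr < 0).any():
            raise ValidationError("negative fraction in decomposition result")
        if len(arr) and not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("fractions do not sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def cell_states(self) -> list[str]:
        return list(self.fractions.columns)

    def as_table(self) -> pd.DataFrame:
        """Samples x (states..., fetalness, rmse, r, nu) for TSV output."""
        out = self.fractions.copy()
        out["fetalness"] = fetalness_index(self)
        out = out.join(self.diagnostics)
        out.index.name = "sample"
        return out


def fpkm_to_tpm(bulk: BulkExpressionMatrix) -> BulkExpressionMatrix:
    """Convert FPKM to TPM: each sample is rescaled by its FPKM total.

    TPM_gs = FPKM_gs / sum_j FPKM_js * 1e6, so every sample sums to 1e6
    and within-sample gene ratios are preserved.
    """
    if bulk.unit != "FPKM":
        raise ValidationError(f"fpkm_to_tpm expects FPKM input, got {bulk.unit}")
    totals = bulk.values.sum(axis=1)
    if (totals == 0).any():
        zero = totals.index[totals == 0][0]
        raise ValidationError(f"sample {zero!r} has all-zero FPKM")
    values = bulk.values.div(totals, axis=0) * 1e6
    return BulkExpressionMatrix(values, unit="TPM")


def align_genes(
    bulk: BulkExpressionMatrix, signature: SignatureMatrix
) -> tuple[BulkExpressionMatrix, SignatureMatrix]:
    """Restrict bulk and signature to their shared genes, in the same order."""
    shared = [g for g in signature.gene_ids if g in set(bulk.gene_ids)]
    if not shared:
        raise ValidationError("bulk and signature share no genes")
    frac = len(shared) / len(signature.gene_ids)
    logger.info("align_genes: %d / %d signature genes found in bulk (%.1f%%)",
                len(shared), len(signature.gene_ids), 100 * frac)
    if frac < 0.5:
        logger.warning("align_genes: fewer than half of the signature genes "
                       "are present in the bulk table")
    bulk_a = BulkExpressionMatrix(bulk.values[shared], unit=bulk.unit)
    sig_a = SignatureMatrix(signature.values.loc[shared], signature.stages.copy(),
                            dict(signature.provenance))
    return bulk_a, sig_a


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot z-score a constant vector/matrix")
    return (a - a.mean()) / sd


def deconvolve_sample(
    mixture: np.ndarray,
    signature: np.ndarray,
    solver: str = "nu_svr",
    nu_grid: tuple[float, ...] = NU_GRID,
) -> tuple[np.ndarray, dict]:
    """Solve one mixture against a genes x states signature.

    Returns (fractions summing to 1, diagnostics with keys rmse/r/nu).
    Diagnostics are computed in the space the solver worked in (z-scores
    for nu_svr, raw values for nnls).
    """
    mixture = np.asarray(mixture, dtype=float)
    signature = np.asarray(signature, dtype=float)
    if signature.ndim != 2 or signature.shape[0] != mixture.shape[0]:
        raise ValidationError("mixture and signature are not gene-aligned")
    if signature.shape[1] < 2:
        raise ValidationError("deconvolution needs at least 2 cell states")
    col_sd = signature.std(axis=0)
    if (col_sd == 0).any():
        raise ValidationError(
            f"degenerate signature: zero-variance column(s) {np.where(col_sd == 0)[0]}"
        )

    if solver == "nnls":
        coef, _ = scipy.optimize.nnls(signature, mixture)
        fitted = signature @ coef
        rmse = float(np.sqrt(np.mean((fitted - mixture) ** 2)))
        r = _pearson(fitted, mixture)
        nu = float("nan")
        w = coef
    elif solver == "nu_svr":
        x = _zscore(signature)
        y = _zscore(mixture)
        best = None
        for nu_val in nu_grid:
            model = NuSVR(kernel="linear", nu=nu_val, C=1.0)
            model.fit(x, y)
            pred = model.predict(x)
            rmse_nu = float(np.sqrt(np.mean((pred - y) ** 2)))
            if best is None or rmse_nu < best[0]:
                best = (rmse_nu, _pearson(pred, y), nu_val, model.coef_.ravel().copy())
        rmse, r, nu, w = best
    else:
        raise ValueError(f"unknown solver {solver!r}")

    w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        raise ValidationError("solver returned no positive coefficient")
    frac = w / w.sum()
    frac[frac < _SNAP_TOL] = 0.0
    frac = frac / frac.sum()
    return frac, {"rmse": rmse, "r": r, "nu": nu}


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def decompose_cohort(
    bulk: BulkExpressionMatrix,
    signature: SignatureMatrix,
    solver: str = "nu_svr",
    strict: bool = False,
) -> DecompositionResult:
    """Deconvolve every sample of a TPM cohort against the signature.

    Failing samples are recorded (and skipped) unless *strict*, in which
    case the first failure aborts the run.
    """
    if bulk.unit != "TPM":
        raise ValidationError(
            f"decompose_cohort requires TPM input, got {bulk.unit}; "
            "run fpkm_to_tpm first"
        )
    bulk_a, sig_a = align_genes(bulk, signature)
    sig_arr = sig_a.values.to_numpy()
    rows, diags, failures = {}, {}, {}
    for sample in bulk_a.sample_ids:
        mix = bulk_a.values.loc[sample].to_numpy()
        try:
            frac, diag = deconvolve_sample(mix, sig_arr, solver=solver)
        except (ValidationError, ValueError) as exc:
            if strict:
                raise
            failures[sample] = str(exc)
            logger.warning("decompose_cohort: sample %r failed: %s", sample, exc)
            continue
        rows[sample] = frac
        diags[sample] = diag
    if not rows:
        raise ValidationError("every sample failed to decompose")
    fractions = pd.DataFrame.from_dict(rows, orient="index",
                                       columns=sig_a.cell_states)
    fractions.index.name = "sample"
    diagnostics = pd.DataFrame.from_dict(diags, orient="index")[["rmse", "r", "nu"]]
    return DecompositionResult(fractions, sig_a.stages, diagnostics, failures)


def fetalness_index(result: DecompositionResult) -> pd.Series:
    """Per-sample sum of fractions over fetal-stage states, in [0, 1]."""
    missing = [s for s in result.cell_states if s not in result.stages.index]
    if missing:
        raise ValidationError(f"states without stage labels: {missing}")
    fetal = [s for s in result.cell_states if result.stages[s] == "fetal"]
    if not fetal:
        return pd.Series(0.0, index=result.fractions.index, name="fetalness")
    out = result.fractions[fetal].sum(axis=1)
    out.name = "fetalness"
    return out
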