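"""Synthetic data generators with known ground truth.

Every pipeline stage is testable without downloads: these generators
produce annotated single-cell references (negative-binomial UMI counts
with planted state-exclusive markers), pseudo-bulk Dirichlet mixtures
with known fractions, survival cohorts with a planted hazard effect of
the fetalness index, and expression/gene-set designs with one set
coupled to the index.

Each generator is a pure function of its parameters and seed; the
parameters are echoed back inside a :class:`SyntheticTruth` record so a
fixture can always be regenerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .io_formats import BulkExpressionMatrix, CountMatrix, GeneSetCollection, state_id


@dataclass
class SyntheticTruth:
    """Ground truth and parameters behind a generated fixture."""

    params: dict
    seed: int
    state_markers: dict[str, list[str]] = field(default_factory=dict)
    fractions: pd.DataFrame | None = None
    coupled_set: str | None = None


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float
               ) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_reference(
    n_fetal_states: int = 4,
    n_adult_states: int = 4,
    n_genes: int = 2000,
    n_cells_per_state: int = 200,
    n_markers_per_state: int = 25,
    marker_fc: float = 8.0,
    nb_mean: float = 2.0,
    nb_dispersion: float = 0.4,
    tissue: str = "synthtissue",
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Annotated single-cell UMI reference with disjoint marker blocks.

    Each state's markers have their negative-binomial mean multiplied by
    *marker_fc* inside that state only; baseline per-gene means are
    log-normal around *nb_mean*.  Returns (counts, annotations, truth);
    annotations carry tissue, cell_type, stage and donor columns.
    """
    n_states = n_fetal_states + n_adult_states
    if n_markers_per_state * n_states > n_genes:
        raise ValueError("marker blocks do not fit into n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    base_mean = nb_mean * rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)

    states, stages = [], []
    for i in range(n_states):
        stage = "fetal" if i < n_fetal_states else "adult"
        states.append(state_id(tissue, f"ct{i:02d}", stage))
        stages.append(stage)

    state_markers = {
        st: genes[i * n_markers_per_state:(i + 1) * n_markers_per_state]
        for i, st in enumerate(states)
    }

    blocks, cell_ids, ann_rows = [], [], []
    for i, st in enumerate(states):
        mean = base_mean.copy()
        midx = slice(i * n_markers_per_state, (i + 1) * n_markers_per_state)
        mean[midx] *= marker_fc
        counts = _nb_counts(
            rng, np.broadcast_to(mean[:, None], (n_genes, n_cells_per_state)),
            nb_dispersion)
        blocks.append(counts)
        _, cell_type, stage = st.split("|")
        for j in range(n_cells_per_state):
            cid = f"{cell_type}_c{j:04d}"
            cell_ids.append(cid)
            ann_rows.append({"cell_id": cid, "tissue": tissue,
                             "cell_type": cell_type, "stage": stage,
                             "donor": f"d{j % 2}"})

    counts = pd.DataFrame(np.concatenate(blocks, axis=1), index=genes,
                          columns=cell_ids)
    annotations = pd.DataFrame(ann_rows).set_index("cell_id", drop=False)
    truth = SyntheticTruth(
        params={"n_fetal_states": n_fetal_states, "n_adult_states": n_adult_states,
                "n_genes": n_genes, "n_cells_per_state": n_cells_per_state,
                "n_markers_per_state": n_markers_per_state, "marker_fc": marker_fc,
                "nb_mean": nb_mean, "nb_dispersion": nb_dispersion,
                "tissue": tissue},
        seed=seed,
        state_markers=state_markers,
    )
    return CountMatrix(counts), annotations, truth


def simulate_mixtures(
    profiles: pd.DataFrame,
    n_samples: int = 100,
    dirichlet_alpha: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[BulkExpressionMatrix, pd.DataFrame]:
    """Pseudo-bulk TPM mixtures of state profiles with known fractions.

    Sample s = sum_k f_sk * profile_k, optionally multiplied per gene by
    exp(N(0, noise_sigma^2)), then renormalized so each sample sums to
    1e6 (TPM).  Returns (bulk, true fractions); fraction rows sum to 1
    exactly.
    """
    if dirichlet_alpha <= 0:
        raise ValueError("dirichlet_alpha must be positive")
    rng = np.random.default_rng(seed)
    states = list(profiles.columns)
    p = profiles.to_numpy()  # genes x K
    f = rng.dirichlet([dirichlet_alpha] * len(states), size=n_samples)  # S x K
    mix = f @ p.T  # samples x genes
    if noise_sigma > 0:
        mix = mix * rng.lognormal(mean=0.0, sigma=noise_sigma, size=mix.shape)
    mix = mix / mix.sum(axis=1, keepdims=True) * 1e6
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    bulk = BulkExpressionMatrix(
        pd.DataFrame(mix, index=sample_ids, columns=profiles.index), unit="TPM")
    fractions = pd.DataFrame(f, index=sample_ids, columns=states)
    return bulk, fractions


def simulate_survival_cohort(
    fetalness: pd.Series,
    beta: float = 1.0,
    baseline_hazard: float = 0.01,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times with log-hazard linear in the index.

    Event rate per sample: baseline_hazard * exp(beta * fetalness).
    Censoring is an independent exponential whose rate is calibrated so
    the expected censored fraction equals *censor_rate*.  Returns a
    survival table (time, event, age, stage) indexed like *fetalness*;
    age and stage are independent fillers for multivariate fits.
    """
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rates = baseline_hazard * np.exp(beta * fetalness.to_numpy())
    t_event = rng.exponential(1.0 / rates)
    if censor_rate == 0:
        time, event = t_event, np.ones(len(t_event), dtype=int)
    else:
        # for independent exponentials, P(censored) = rc / (rc + rate_i)
        def expected_censoring(rc: float) -> float:
            return float(np.mean(rc / (rc + rates))) - censor_rate

        rc = scipy.optimize.brentq(expected_censoring, 1e-12 * rates.min(),
                                   1e12 * rates.max())
        t_cens = rng.exponential(1.0 / rc, size=len(t_event))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({
        "time": time,
        "event": event,
        "age": rng.normal(60, 10, size=len(time)),
        "stage": rng.integers(1, 5, size=len(time)),
    }, index=fetalness.index)


def simulate_enrichment_design(
    n_genes: int = 1500,
    n_samples: int = 100,
    coupled_set_size: int = 50,
    coupling: float = 2.0,
    noise_sigma: float = 1.0,
    n_decoy_sets: int = 19,
    decoy_set_size: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, GeneSetCollection, SyntheticTruth]:
    """Expression + index + gene sets with one set coupled to the index.

    The index is Uniform(0, 1); coupled genes follow coupling * index +
    N(0, noise_sigma^2), all others pure noise.  Decoy sets are drawn
    uniformly from the non-coupled genes.  Expression is exponentiated so
    values are positive; Spearman-based enrichment is unaffected.
    """
    if coupled_set_size >= n_genes:
        raise ValueError("coupled_set_size must be below n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    index = pd.Series(rng.uniform(size=n_samples), index=samples, name="fetalness")
    noise = rng.normal(scale=noise_sigma, size=(n_samples, n_genes))
    signal = np.zeros((n_samples, n_genes))
    signal[:, :coupled_set_size] = coupling * index.to_numpy()[:, None]
    expr = pd.DataFrame(np.exp(signal + noise), index=samples, columns=genes)

    sets = {"COUPLED": frozenset(genes[:coupled_set_size])}
    other = genes[coupled_set_size:]
    for i in range(n_decoy_sets):
        pick = rng.choice(len(other), size=decoy_set_size, replace=False)
        sets[f"DECOY{i:02d}"] = frozenset(other[j] for j in pick)
    collection = GeneSetCollection(dict(sets))
    truth = SyntheticTruth(
        params={"n_genes": n_genes, "n_samples": n_samples,
                "coupled_set_size": coupled_set_size, "coupling": coupling,
                "noise_sigma": noise_sigma, "n_decoy_sets": n_decoy_sets,
                "decoy_set_size": decoy_set_size},
        seed=seed,
        coupled_set="COUPLED",
    )
    return expr, index, collection, truth
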