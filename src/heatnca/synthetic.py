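"""Synthetic expression data with known ground truth.

Two generators stand in for the study's microarray data:

* :func:`simulate_nca_instance` builds a decomposition instance
  ``E = A_true @ P_true + noise`` on an identifiability-checked connectivity
  pattern — the ground truth for TFA-recovery tests.
* :func:`simulate_ecotype_experiment` emulates the array design: multiple
  ecotype groups, replicated control/heat arrays on the log2 scale, a minority
  of genes with planted, ecotype-specific heat responses.

Everything is driven by explicit integer seeds: the same call with the same
seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import AnnotationTable, ExpressionMatrix
from .nca import ConnectivityPattern, check_identifiability, pattern_from_mask

CONTROL = "control"
HEAT = "heat"

#: default probability that a planted responder also responds in each
#: additional ecotype; small so most responders are ecotype-specific,
#: mirroring the heavily ecotype-specific response structure of the study
DEFAULT_MULTI_RATE = 0.05


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one decomposition instance E = A P + noise."""

    seed: int
    pattern: ConnectivityPattern
    a_true: np.ndarray        # n_genes x n_tfs control strengths
    p_true: np.ndarray        # n_tfs x n_conditions true TFAs
    noise_sd: float
    expression: np.ndarray    # n_genes x n_conditions


@dataclass(frozen=True)
class EcotypeSimTruth:
    """Planted differential-expression structure of an ecotype experiment."""

    seed: int
    de_labels: np.ndarray      # n_genes x n_ecotypes bool
    effect_sizes: np.ndarray   # n_genes x n_ecotypes log2 fold changes
    replicate_sd: float


def generate_connectivity(n_genes: int, n_tfs: int, density: float,
                          seed: int, max_retries: int = 100) -> ConnectivityPattern:
    """Sample a random identifiable connectivity pattern.

    Each entry is included independently with probability ``density``; empty
    gene rows and TF columns are then topped up with one random entry each.
    Candidates are rejection-sampled until structural identifiability
    criteria 1 and 2 hold (criterion 3 concerns the condition count, not the
    pattern).  Raises ``RuntimeError`` if no identifiable pattern is found
    within ``max_retries`` draws — the density/dimension combination is then
    infeasible in practice.
    """
    if n_genes <= 0 or n_tfs <= 0:
        raise ValueError("dimensions must be positive")
    if n_tfs > n_genes:
        raise ValueError(f"n_tfs ({n_tfs}) must not exceed n_genes ({n_genes})")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if density * n_genes < 1:
        raise ValueError("density * n_genes must be >= 1 (every TF needs a target)")

    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        mask = rng.random((n_genes, n_tfs)) < density
        for t in np.nonzero(~mask.any(axis=0))[0]:
            mask[rng.integers(n_genes), t] = True
        for g in np.nonzero(~mask.any(axis=1))[0]:
            mask[g, rng.integers(n_tfs)] = True
        pattern = pattern_from_mask(mask)
        report = check_identifiability(pattern, n_conditions=n_tfs)
        if report.criterion1 and all(report.criterion2):
            return pattern
    raise RuntimeError(
        f"no identifiable pattern found in {max_retries} draws "
        f"(n_genes={n_genes}, n_tfs={n_tfs}, density={density})")


def simulate_nca_instance(pattern: ConnectivityPattern, n_conditions: int,
                          noise_sd: float, seed: int) -> SyntheticTruth:
    """Instantiate a pattern into a noisy decomposition instance.

    Nonzeros of A_true are uniform on +-[0.5, 1.5] — bounded away from zero
    so the support is unambiguous; P_true is i.i.d. standard normal; additive
    Gaussian noise with standard deviation ``noise_sd`` on the log2 scale.
    """
    if n_conditions <= 0:
        raise ValueError("n_conditions must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    mask = pattern.mask()
    k = int(mask.sum())
    a = np.zeros((pattern.n_genes, pattern.n_tfs))
    a[mask] = rng.uniform(0.5, 1.5, size=k) * rng.choice([-1.0, 1.0], size=k)
    p = rng.standard_normal((pattern.n_tfs, n_conditions))
    clean = a @ p
    if noise_sd > 0:
        expression = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    else:
        expression = clean.copy()
    return SyntheticTruth(seed=seed, pattern=pattern, a_true=a, p_true=p,
                          noise_sd=float(noise_sd), expression=expression)


def _gene_ids(n_genes: int) -> list[str]:
    # AT-style synthetic loci, cycling over the five nuclear chromosomes
    return [f"AT{g % 5 + 1}G{(g // 5 + 1) * 10:05d}" for g in range(n_genes)]


def simulate_ecotype_experiment(
    n_genes: int,
    ecotypes: list[str],
    n_reps: int,
    prevalence: float,
    effect_sd: float,
    replicate_sd: float,
    seed: int,
    multi_rate: float = DEFAULT_MULTI_RATE,
    baseline_mean: float = 7.0,
    baseline_sd: float = 2.0,
) -> tuple[ExpressionMatrix, EcotypeSimTruth]:
    """Simulate a replicated multi-ecotype control/heat array experiment.

    Per-gene baseline log2 means are shared across ecotypes; a
    ``prevalence`` fraction of genes is planted as heat-responsive, each in
    one ecotype plus a Binomial(n_ecotypes - 1, ``multi_rate``) number of
    further ecotypes, with ecotype-specific log2 shifts drawn
    Normal(0, ``effect_sd``).  Replicate noise is Normal(0, ``replicate_sd``)
    on every array.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if not ecotypes:
        raise ValueError("need at least one ecotype")
    if len(set(ecotypes)) != len(ecotypes):
        raise ValueError("ecotype labels must be unique")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (tests need within-group variance)")
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    if effect_sd <= 0 or replicate_sd <= 0:
        raise ValueError("effect_sd and replicate_sd must be positive")

    rng = np.random.default_rng(seed)
    n_eco = len(ecotypes)
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)

    n_resp = int(round(prevalence * n_genes))
    responders = rng.choice(n_genes, size=n_resp, replace=False)
    de_labels = np.zeros((n_genes, n_eco), dtype=bool)
    effect = np.zeros((n_genes, n_eco))
    for g in responders:
        n_active = 1 + (rng.binomial(n_eco - 1, multi_rate) if n_eco > 1 else 0)
        active = rng.choice(n_eco, size=n_active, replace=False)
        de_labels[g, active] = True
        effect[g, active] = rng.normal(0.0, effect_sd, size=n_active)

    sample_ids, design_rows = [], []
    columns = []
    for e_idx, eco in enumerate(ecotypes):
        for treatment in (CONTROL, HEAT):
            shift = effect[:, e_idx] if treatment == HEAT else 0.0
            for rep in range(1, n_reps + 1):
                sample_ids.append(f"{eco}_{treatment}_{rep}")
                design_rows.append((eco, treatment, rep))
                columns.append(
                    baseline + shift + rng.normal(0.0, replicate_sd, size=n_genes))
    values = np.column_stack(columns)
    design = pd.DataFrame(design_rows, index=sample_ids,
                          columns=["ecotype", "treatment", "replicate"])
    expr = ExpressionMatrix(gene_ids=_gene_ids(n_genes), sample_ids=sample_ids,
                            values=values, design=design)
    truth = EcotypeSimTruth(seed=seed, de_labels=de_labels, effect_sizes=effect,
                            replicate_sd=float(replicate_sd))
    return expr, truth


def simulate_regulated_experiment(
    pattern: ConnectivityPattern,
    ecotypes: list[str],
    n_reps: int,
    noise_sd: float,
    replicate_sd: float,
    seed: int,
    baseline_mean: float = 7.0,
    baseline_sd: float = 2.0,
) -> tuple[ExpressionMatrix, SyntheticTruth, AnnotationTable]:
    """Embed a planted TF -> target regulatory layer into a replicated
    control/heat ecotype experiment.

    The per-ecotype heat log2 fold changes of the target genes are generated
    by a hidden decomposition: targets get fc = A_true @ P_true (+ fc-level
    noise ``noise_sd``), where P_true rows are the per-ecotype activities of
    the planted TFs.  The TF genes themselves respond with fold change equal
    to their own activity row — transcript level as a proxy of activity — so
    correlation of fold-change profiles can rediscover the planted edges.
    Arrays then add a shared per-gene baseline and replicate noise.

    Returns the expression matrix (targets first, then TF genes), the
    decomposition ground truth over the target rows, and an annotation table
    tagging the TF genes.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if len(set(ecotypes)) != len(ecotypes) or not ecotypes:
        raise ValueError("ecotype labels must be unique and nonempty")
    truth = simulate_nca_instance(pattern, n_conditions=len(ecotypes),
                                  noise_sd=noise_sd, seed=seed)
    rng = np.random.default_rng(seed + 1)
    n_tg, n_tf = pattern.n_genes, pattern.n_tfs
    n_genes = n_tg + n_tf
    fc = np.vstack([truth.expression, truth.p_true])   # genes x ecotypes
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)

    ids = _gene_ids(n_genes)
    target_ids, tf_ids = ids[:n_tg], ids[n_tg:]
    sample_ids, design_rows, columns = [], [], []
    for e_idx, eco in enumerate(ecotypes):
        for treatment in (CONTROL, HEAT):
            shift = fc[:, e_idx] if treatment == HEAT else 0.0
            for rep in range(1, n_reps + 1):
                sample_ids.append(f"{eco}_{treatment}_{rep}")
                design_rows.append((eco, treatment, rep))
                columns.append(
                    baseline + shift + rng.normal(0.0, replicate_sd, n_genes))
    design = pd.DataFrame(design_rows, index=sample_ids,
                          columns=["ecotype", "treatment", "replicate"])
    expr = ExpressionMatrix(gene_ids=ids, sample_ids=sample_ids,
                            values=np.column_stack(columns), design=design)
    annot = AnnotationTable(tags={g: frozenset({"TF"}) for g in tf_ids})
    return expr, truth, annot
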