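"""Per-ecotype differential-expression calling on log2 expression data.

The statistical workflow mirrors a standard replicated two-condition array
analysis: per ecotype, a two-sided two-sample t-test (pooled-variance by
default, Welch optional) between heat and control replicates of each gene; across ecotypes, the
genotype x treatment interaction from a per-gene two-way fixed-effects
ANOVA; log2 fold changes as mean differences; and tabulation of unified and
ecotype-unique significant sets.  Raw p-values are thresholded at a
configured alpha (0.01 by default) with no multiple-testing correction;
a Benjamini-Hochberg option is available but off by default, matching the
raw-cutoff convention of classical ecotype-panel array studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONTROL = "control"
HEAT = "heat"
TREATMENTS = (CONTROL, HEAT)

RECORD_COLUMNS = ["gene_id", "ecotype", "log2fc", "t_pvalue", "direction",
                  "significant"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample design metadata.

    ``design`` is indexed by sample id with columns ``ecotype``,
    ``treatment`` (control/heat) and ``replicate``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if list(self.design.index) != list(self.sample_ids):
            raise ValueError("design index must equal sample_ids, in order")
        missing = {"ecotype", "treatment", "replicate"} - set(self.design.columns)
        if missing:
            raise ValueError(f"design lacks columns: {sorted(missing)}")
        bad = set(self.design["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValueError(f"unknown treatment labels: {sorted(bad)}")

    @property
    def ecotypes(self) -> list[str]:
        return list(dict.fromkeys(self.design["ecotype"]))

    def arm(self, ecotype: str, treatment: str) -> np.ndarray:
        """Genes x replicates sub-matrix of one (ecotype, treatment) cell."""
        sel = ((self.design["ecotype"] == ecotype)
               & (self.design["treatment"] == treatment)).to_numpy()
        return self.values[:, sel]

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids, name="gene_id")


@dataclass
class DESummary:
    """Table-1-style count summary of per-ecotype significant sets."""

    per_ecotype: pd.DataFrame       # index ecotype; total, total_up, total_down,
                                    # unique_total, unique_up, unique_down
    unified_count: int
    unique_overall_count: int


@dataclass
class AnnotationTable:
    """Gene id -> category tags (subset of {TF, TE, HSP}) and TF family."""

    tags: dict[str, frozenset[str]]
    family: dict[str, str] = field(default_factory=dict)

    def tags_for(self, gene_id: str) -> frozenset[str]:
        return self.tags.get(gene_id, frozenset())


# ---------------------------------------------------------------------------
# per-ecotype statistics
# ---------------------------------------------------------------------------

def _require_arms(expr: ExpressionMatrix, ecotype: str) -> tuple[np.ndarray, np.ndarray]:
    if ecotype not in set(expr.design["ecotype"]):
        raise ValueError(f"unknown ecotype {ecotype!r}")
    heat = expr.arm(ecotype, HEAT)
    control = expr.arm(ecotype, CONTROL)
    for name, arm in ((HEAT, heat), (CONTROL, control)):
        if arm.shape[1] == 0:
            raise ValueError(f"ecotype {ecotype!r} has no {name} samples")
    return control, heat


def log2_fold_change(expr: ExpressionMatrix, ecotype: str) -> pd.Series:
    """Per-gene mean(log2 heat) - mean(log2 control) for one ecotype."""
    control, heat = _require_arms(expr, ecotype)
    fc = heat.mean(axis=1) - control.mean(axis=1)
    return pd.Series(fc, index=expr.gene_index(), name=f"log2fc_{ecotype}")


def fold_change_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Genes x ecotypes log2 fold-change matrix (heat minus control)."""
    return pd.DataFrame(
        {eco: log2_fold_change(expr, eco) for eco in expr.ecotypes})


def per_ecotype_t_test(expr: ExpressionMatrix, ecotype: str,
                       alpha: float = 0.01, *, equal_var: bool = True,
                       bh_correct: bool = False) -> pd.DataFrame:
    """Two-sided two-sample t-test, heat vs control, per gene.

    Pooled-variance (Student) test by default — exactly calibrated under a
    Gaussian equal-variance null even at triplicate sample sizes, where the
    Welch test (``equal_var=False``) is noticeably conservative.  Genes
    where both arms are constant get p = 1 by
    convention so constant probes never surface as significant.  Returns one
    record per gene with columns ``gene_id, ecotype, log2fc, t_pvalue,
    direction, significant``; direction is ``up``/``down`` by the sign of the
    fold change and empty for an exact zero.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    control, heat = _require_arms(expr, ecotype)
    if control.shape[1] < 2 or heat.shape[1] < 2:
        raise ValueError(f"ecotype {ecotype!r} needs >= 2 replicates per arm")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(heat, control, axis=1, equal_var=equal_var)
    pvals = np.asarray(res.pvalue, dtype=float)
    # zero variance in both arms: undefined t; p = 1 by convention
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    if bh_correct:
        pvals = _benjamini_hochberg(pvals)
    fc = heat.mean(axis=1) - control.mean(axis=1)
    direction = np.where(fc > 0, "up", np.where(fc < 0, "down", ""))
    return pd.DataFrame({
        "gene_id": expr.gene_ids,
        "ecotype": ecotype,
        "log2fc": fc,
        "t_pvalue": pvals,
        "direction": direction,
        "significant": pvals <= alpha,
    })


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    n = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def interaction_anova(expr: ExpressionMatrix, alpha: float = 0.01) -> pd.Series:
    """Genotype x treatment interaction p-value per gene.

    Fits the two-factor fixed-effects model with interaction gene by gene and
    returns the interaction-term p-value.  The computation is the closed-form
    balanced two-way ANOVA (identical cell counts), vectorized over genes —
    on a balanced design the sums-of-squares type is immaterial.  Empty
    (ecotype, treatment) cells raise, naming the offending cell; so do
    unequal replicate counts, since the closed form requires balance.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ecotypes = expr.ecotypes
    if len(ecotypes) < 2:
        raise ValueError("interaction ANOVA needs >= 2 ecotypes")
    counts = {}
    for eco in ecotypes:
        for trt in TREATMENTS:
            n = expr.arm(eco, trt).shape[1]
            if n == 0:
                raise ValueError(f"empty design cell: ({eco!r}, {trt!r})")
            if n < 2:
                raise ValueError(
                    f"design cell ({eco!r}, {trt!r}) has < 2 replicates")
            counts[(eco, trt)] = n
    reps = set(counts.values())
    if len(reps) > 1:
        raise ValueError(
            f"unbalanced design (replicate counts {sorted(reps)}); "
            "the closed-form two-way ANOVA requires equal cell counts")
    r = reps.pop()
    n_eco, n_trt = len(ecotypes), len(TREATMENTS)

    # cells: genes x ecotypes x treatments x reps
    cells = np.stack(
        [np.stack([expr.arm(eco, trt) for trt in TREATMENTS], axis=1)
         for eco in ecotypes], axis=1)
    cell_mean = cells.mean(axis=3)                      # g x E x T
    eco_mean = cell_mean.mean(axis=2)                   # g x E
    trt_mean = cell_mean.mean(axis=1)                   # g x T
    grand = cell_mean.mean(axis=(1, 2))                 # g

    inter = (cell_mean - eco_mean[:, :, None] - trt_mean[:, None, :]
             + grand[:, None, None])
    ss_int = r * np.sum(inter ** 2, axis=(1, 2))
    ss_err = np.sum((cells - cell_mean[:, :, :, None]) ** 2, axis=(1, 2, 3))
    df_int = (n_eco - 1) * (n_trt - 1)
    df_err = n_eco * n_trt * (r - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_int / df_int) / (ss_err / df_err)
    pvals = stats.f.sf(f, df_int, df_err)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    return pd.Series(pvals, index=expr.gene_index(), name="interaction_pvalue")


def de_records_all_ecotypes(expr: ExpressionMatrix, alpha: float = 0.01,
                            *, equal_var: bool = True,
                            with_interaction: bool = False) -> pd.DataFrame:
    """Concatenated per-ecotype t-test records, optionally with the shared
    interaction p-value merged in."""
    frames = [per_ecotype_t_test(expr, eco, alpha, equal_var=equal_var)
              for eco in expr.ecotypes]
    records = pd.concat(frames, ignore_index=True)
    if with_interaction:
        inter = interaction_anova(expr, alpha)
        records = records.merge(inter.rename("interaction_pvalue"),
                                left_on="gene_id", right_index=True, how="left")
    return records


# ---------------------------------------------------------------------------
# list assembly and tabulation
# ---------------------------------------------------------------------------

def assemble_union(records: pd.DataFrame) -> tuple[DESummary, dict[str, set[str]]]:
    """Unified significant list across ecotypes plus per-gene membership.

    The unified list is the set union of per-ecotype significant genes; a
    gene is *unique* when it is significant in exactly one ecotype.  Returns
    the count summary and the gene -> {ecotypes significant in} map.
    """
    if records.empty or records["ecotype"].nunique() < 1:
        raise ValueError("records must cover at least one ecotype")
    sig = records[records["significant"]]
    membership: dict[str, set[str]] = {}
    for gene, eco in zip(sig["gene_id"], sig["ecotype"]):
        membership.setdefault(gene, set()).add(eco)
    return summarize_counts(records, membership), membership


def summarize_counts(records: pd.DataFrame,
                     membership: dict[str, set[str]]) -> DESummary:
    """Tabulate per-ecotype total/up/down and unique counts."""
    ecotypes = list(dict.fromkeys(records["ecotype"]))
    unique_genes = {g for g, ecos in membership.items() if len(ecos) == 1}
    rows = []
    sig = records[records["significant"]]
    for eco in ecotypes:
        sub = sig[sig["ecotype"] == eco]
        uniq = sub[sub["gene_id"].isin(unique_genes)]
        rows.append({
            "ecotype": eco,
            "total": len(sub),
            "total_up": int((sub["direction"] == "up").sum()),
            "total_down": int((sub["direction"] == "down").sum()),
            "unique_total": len(uniq),
            "unique_up": int((uniq["direction"] == "up").sum()),
            "unique_down": int((uniq["direction"] == "down").sum()),
        })
    per_eco = pd.DataFrame(rows).set_index("ecotype")
    return DESummary(per_ecotype=per_eco, unified_count=len(membership),
                     unique_overall_count=len(unique_genes))


def annotate_genes(gene_ids: list[str],
                   annot: AnnotationTable) -> tuple[pd.DataFrame, dict[str, int]]:
    """Tag a gene list with TF/TE/HSP categories and count per tag.

    Genes absent from the annotation get empty tags and are counted under
    ``unannotated``.
    """
    rows = []
    counts: dict[str, int] = {"TF": 0, "TE": 0, "HSP": 0, "unannotated": 0}
    for gid in gene_ids:
        tags = annot.tags_for(gid)
        rows.append({
            "gene_id": gid,
            "tags": ";".join(sorted(tags)),
            "family": annot.family.get(gid, ""),
        })
        if not tags:
            counts["unannotated"] += 1
        for tag in tags:
            counts[tag] = counts.get(tag, 0) + 1
    table = pd.DataFrame(rows, columns=["gene_id", "tags", "family"])
    return table, counts
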