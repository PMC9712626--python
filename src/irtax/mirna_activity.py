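"""miRNA-activity inference from predicted-target expression behaviour.

A miRNA's activity change is read off its predicted targets: a Welch t-test
compares target vs background log2 fold-changes within one contrast; a
one-sided Fisher's exact test asks whether targets are over-represented
among genes with a specified sign pattern across two contrasts
(concordance); a hypergeometric test scores the overlap of two affected
gene sets; and a linear mixed-effects model with a per-patient random
intercept tests whether a group of introns shifts its PIR between genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from scipy import stats

from .types import DETable, PIRMatrix, SampleSheet, TargetSet


class DataError(ValueError):
    pass


class DesignError(ValueError):
    pass


@dataclass
class ShiftResult:
    set_name: str
    t_statistic: float
    p_value: float  # two-sided Welch
    mean_target: float
    mean_background: float
    n_target: int
    n_background: int


def target_shift_test(de: DETable, targets: TargetSet, universe: set) -> ShiftResult:
    """Two-sided Welch t-test: target vs non-target log2FC within one contrast."""
    table = de.table[de.table["gene_id"].isin(universe)]
    is_target = table["gene_id"].isin(targets.gene_ids)
    x = table.loc[is_target, "log2fc"].to_numpy(dtype=float)
    y = table.loc[~is_target, "log2fc"].to_numpy(dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 5 or len(y) < 5:
        raise DataError(
            f"{targets.set_name}: need >= 5 targets and >= 5 background genes "
            f"with finite log2FC (got {len(x)}, {len(y)})"
        )
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x.mean() == y.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(x, y, equal_var=False)
        if not np.isfinite(p):
            t, p = 0.0, 1.0
    return ShiftResult(
        targets.set_name, float(t), float(p), float(x.mean()), float(y.mean()), len(x), len(y)
    )


@dataclass
class ConcordanceResult:
    set_name: str
    table: np.ndarray  # 2x2 [target conc, target not; bg conc, bg not]
    odds_ratio: float
    p_value: float  # one-sided Fisher (greater)
    contrast_pair: tuple
    direction_rule: str


def _sign_matches(values: np.ndarray, predicate: str) -> np.ndarray:
    # strict inequalities; zero never concordant
    if predicate == "positive":
        return values > 0
    if predicate == "negative":
        return values < 0
    raise DataError(f"unknown sign predicate {predicate!r}")


def target_concordance_test(
    de_a: DETable,
    de_b: DETable,
    targets: TargetSet,
    predicate_a: str,
    predicate_b: str,
    universe: set,
) -> ConcordanceResult:
    """Are targets over-represented among genes with the given sign pattern?

    A gene is concordant iff its log2FC in contrast a matches predicate_a
    AND in contrast b matches predicate_b ('positive'/'negative', strict).
    One-sided Fisher (greater) on {target, non-target} x {concordant, not}.
    """
    a = de_a.table.set_index("gene_id")["log2fc"]
    b = de_b.table.set_index("gene_id")["log2fc"]
    shared = [g for g in sorted(universe) if g in a.index and g in b.index]
    if not shared:
        raise DataError("no universe genes shared by both contrasts")
    av, bv = a.loc[shared].to_numpy(float), b.loc[shared].to_numpy(float)
    conc = _sign_matches(av, predicate_a) & _sign_matches(bv, predicate_b)
    is_t = np.array([g in targets.gene_ids for g in shared])
    tab = np.array(
        [
            [int((is_t & conc).sum()), int((is_t & ~conc).sum())],
            [int((~is_t & conc).sum()), int((~is_t & ~conc).sum())],
        ]
    )
    odds, p = stats.fisher_exact(tab, alternative="greater")
    return ConcordanceResult(
        targets.set_name,
        tab,
        float(odds),
        float(p),
        (de_a.contrast_label, de_b.contrast_label),
        f"log2FC_a {predicate_a} and log2FC_b {predicate_b}",
    )


def significant_overlap_test(set_a: set, set_b: set, universe: set):
    """One-sided hypergeometric p for the overlap of two gene sets.

    Returns (p_value, overlap_count).  Symmetric in its two sets.
    """
    if not set_a <= universe or not set_b <= universe:
        raise DataError("both sets must be contained in the universe")
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return p, k


@dataclass
class PIRShiftResult:
    effect: float  # genotype coefficient, PIR points
    p_value: float
    method: str  # "lme" or "welch_patient_means"
    n_patients: dict


def group_pir_shift_test(pir: PIRMatrix, group: set, samples: SampleSheet | None = None) -> PIRShiftResult:
    """Genotype effect on a group's PIR with a per-patient random intercept.

    Long-form observations (one per intron x sample) are modelled as
    PIR ~ genotype + (1 | patient), fitted by REML; the genotype Wald
    statistic is referred to a t distribution with n_patients - 2 degrees
    of freedom (the between-patient information).  Falls back to a Welch
    t-test on per-patient mean PIR when the mixed fit is degenerate.
    """
    samples = samples or pir.samples
    gts = samples.table.groupby("patient_id")["genotype"].first()
    n_pat = gts.value_counts().to_dict()
    if len(n_pat) < 2:
        raise DesignError("need both genotypes in the design")
    keep = [i for i in pir.intron_ids if i in group]
    if not keep:
        raise DataError("no group introns present in the PIR matrix")
    sub = pir.values.loc[keep, samples.sample_ids]
    long = sub.reset_index(names="intron").melt(
        id_vars="intron", var_name="sample_id", value_name="pir"
    )
    meta = samples.table.set_index("sample_id")[["genotype", "patient_id"]]
    long = long.join(meta, on="sample_id").dropna(subset=["pir"])
    long["is_mutant"] = (long["genotype"] == "mutant").astype(float)

    def _fallback() -> PIRShiftResult:
        pm = long.groupby("patient_id").agg(pir=("pir", "mean"), mut=("is_mutant", "first"))
        a = pm.loc[pm["mut"] == 0, "pir"].to_numpy()
        b = pm.loc[pm["mut"] == 1, "pir"].to_numpy()
        t, p = stats.ttest_ind(b, a, equal_var=False)
        return PIRShiftResult(float(b.mean() - a.mean()), float(p), "welch_patient_means", n_pat)

    try:
        import statsmodels.formula.api as smf

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("pir ~ is_mutant", long, groups=long["patient_id"])
            fit = model.fit(reml=True)
        coef = float(fit.params["is_mutant"])
        se = float(fit.bse["is_mutant"])
        if not np.isfinite(coef) or not np.isfinite(se) or se <= 0:
            return _fallback()
        df = max(len(gts) - 2, 1)
        p = float(2 * stats.t.sf(abs(coef / se), df))
        return PIRShiftResult(coef, p, "lme", n_pat)
    except Exception:
        return _fallback()
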