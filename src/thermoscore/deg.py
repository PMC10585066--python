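"""Heat-induction statistics and cultivar comparisons.

Induction of a gene is the mean log2 stress expression minus the mean log2
control expression, with a two-sided Welch t-test across replicates.  Genes
are called up/down at a fold-change + p-value cut (default |log2FC| >= 1,
p < 0.05, boundary inclusive on the fold change).  Cultivars are compared
by Venn overlap of regulated sets and by per-gene differential induction
(default twofold, i.e. 1 log2 unit, with a Welch test on per-replicate
induction contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionStudy, ValidationError

__all__ = [
    "InductionTable",
    "VennResult",
    "induction",
    "call_regulated",
    "venn_overlap",
    "differential_induction",
    "top_n_upregulated",
]


@dataclass
class InductionTable:
    """Per gene x cultivar induction statistics for one stress-vs-control contrast.

    ``table`` has columns gene, cultivar, log2_induction, p_value,
    stress_level (mean log2 expression under stress).  ``contrasts`` keeps
    replicate-level induction values (stress replicate minus the control
    group mean) per cultivar, used by :func:`differential_induction`.
    """

    table: pd.DataFrame
    contrasts: dict
    genes: list

    def for_cultivar(self, cultivar: str) -> pd.DataFrame:
        sub = self.table[self.table["cultivar"] == cultivar]
        if sub.empty:
            raise ValidationError(f"cultivar {cultivar!r} not present in induction table")
        return sub.set_index("gene")


def _check_complete(vals: np.ndarray, genes: list, where: str) -> None:
    n_ok = np.sum(~np.isnan(vals), axis=1)
    bad = np.nonzero(n_ok < 2)[0]
    if bad.size:
        raise ValidationError(
            f"gene {genes[bad[0]]!r}: fewer than 2 non-missing replicates in {where}"
        )


def induction(
    study: ExpressionStudy,
    stress: tuple,
    control: tuple,
    cultivars: list | None = None,
) -> InductionTable:
    """Compute log2 induction and Welch p per gene for each cultivar.

    ``stress`` and ``control`` are (treatment, time_h) selectors; each must
    resolve to >= 2 replicates per cultivar.
    """
    cultivars = cultivars or study.cultivars
    rows = []
    contrasts = {}
    for cultivar in cultivars:
        sv = study.replicate_values(cultivar, stress[0], stress[1])
        cv = study.replicate_values(cultivar, control[0], control[1])
        _check_complete(sv, study.genes, f"{cultivar}/{stress[0]}")
        _check_complete(cv, study.genes, f"{cultivar}/{control[0]}")
        s_mean = np.nanmean(sv, axis=1)
        c_mean = np.nanmean(cv, axis=1)
        res = stats.ttest_ind(sv, cv, axis=1, equal_var=False, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
        # identical groups give 0/0 in the Welch statistic; no evidence of change
        p = np.where(np.isnan(p), 1.0, p)
        contrasts[cultivar] = sv - c_mean[:, None]
        rows.append(
            pd.DataFrame(
                {
                    "gene": study.genes,
                    "cultivar": cultivar,
                    "log2_induction": s_mean - c_mean,
                    "p_value": p,
                    "stress_level": s_mean,
                }
            )
        )
    return InductionTable(
        table=pd.concat(rows, ignore_index=True),
        contrasts=contrasts,
        genes=list(study.genes),
    )


def call_regulated(
    tab: InductionTable,
    fc_call_log2: float = 1.0,
    call_alpha: float = 0.05,
    correct: str | None = None,
) -> pd.DataFrame:
    """Call each gene up/down/unchanged per cultivar.

    up iff log2_induction >= fc_call_log2 and p < call_alpha; down iff
    log2_induction <= -fc_call_log2 and p < call_alpha.  ``correct="fdr_bh"``
    switches the p-value to a Benjamini-Hochberg adjusted one (off by
    default).
    """
    df = tab.table.copy()
    p = df["p_value"].to_numpy()
    if correct is not None:
        p = np.concatenate(
            [
                multipletests(grp["p_value"].to_numpy(), method=correct)[1]
                for _, grp in df.groupby("cultivar", sort=False)
            ]
        )
    fc = df["log2_induction"].to_numpy()
    status = np.where(
        (fc >= fc_call_log2) & (p < call_alpha),
        "up",
        np.where((fc <= -fc_call_log2) & (p < call_alpha), "down", "unchanged"),
    )
    return pd.DataFrame({"gene": df["gene"], "cultivar": df["cultivar"], "status": status})


@dataclass(frozen=True)
class VennResult:
    n_a: int
    n_b: int
    n_shared: int
    pct_of_b_shared: int | None  # 100 * n_shared / n_b, nearest integer; None if n_b = 0


def venn_overlap(calls_a: pd.DataFrame, calls_b: pd.DataFrame, status: str) -> VennResult:
    """Overlap of the genes holding ``status`` in two call sets.

    Both calls must cover the same gene universe.  The headline percentage
    is the share of set B also found in set A (e.g. "90% of genes
    upregulated in the sensitive cultivar were also upregulated in the
    tolerant one").
    """
    ua, ub = set(calls_a["gene"]), set(calls_b["gene"])
    if ua != ub:
        raise ValidationError("call sets cover different gene universes")
    a = set(calls_a.loc[calls_a["status"] == status, "gene"])
    b = set(calls_b.loc[calls_b["status"] == status, "gene"])
    shared = len(a & b)
    pct = int(100.0 * shared / len(b) + 0.5) if b else None
    return VennResult(n_a=len(a), n_b=len(b), n_shared=shared, pct_of_b_shared=pct)


def differential_induction(
    tab: InductionTable,
    cultivar_a: str,
    cultivar_b: str,
    diff_induction_log2: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag genes with significantly higher induction in one cultivar.

    higher_in_a iff induction_a - induction_b >= diff_induction_log2 (default
    1.0 = twofold) and a Welch test on the per-replicate induction contrasts
    gives p < alpha; symmetric for b; otherwise ns.
    """
    for c in (cultivar_a, cultivar_b):
        if c not in tab.contrasts:
            raise ValidationError(f"cultivar {c!r} lacks replicate-level data")
    ia = tab.for_cultivar(cultivar_a)["log2_induction"].reindex(tab.genes).to_numpy()
    ib = tab.for_cultivar(cultivar_b)["log2_induction"].reindex(tab.genes).to_numpy()
    res = stats.ttest_ind(
        tab.contrasts[cultivar_a], tab.contrasts[cultivar_b],
        axis=1, equal_var=False, nan_policy="omit",
    )
    p = np.where(np.isnan(res.pvalue), 1.0, np.asarray(res.pvalue, dtype=float))
    d = ia - ib
    flag = np.where(
        (d >= diff_induction_log2) & (p < alpha),
        "higher_in_a",
        np.where((-d >= diff_induction_log2) & (p < alpha), "higher_in_b", "ns"),
    )
    return pd.DataFrame(
        {
            "gene": tab.genes,
            "induction_a": ia,
            "induction_b": ib,
            "difference": d,
            "p_value": p,
            "flag": flag,
        }
    )


def top_n_upregulated(tab: InductionTable, cultivar: str, n: int) -> list:
    """Top-n genes by log2 induction, descending, lexicographic tie-break."""
    sub = tab.for_cultivar(cultivar)
    if len(sub) < n:
        raise ValidationError(f"only {len(sub)} genes available, need {n}")
    order = sorted(sub.index, key=lambda g: (-sub.at[g, "log2_induction"], g))
    return order[:n]
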