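"""Relative expression quantification by the ddCt method, with group statistics.

Fold change of a target gene in a condition, relative to a reference gene
and a control condition, assuming 100% amplification efficiency (each cycle
doubles the product):

    dCt(c)  = mean Ct_target(c) - mean Ct_reference(c)
    ddCt(c) = dCt(c) - dCt(control)
    fold(c) = 2 ** (-ddCt(c))

Group comparisons operate on the Ct values themselves: one-way ANOVA with
Tukey-adjusted pairwise comparisons for more than two groups, and a paired
t-test (replicate-matched) for exactly two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

CT_COLUMNS = ("gene", "condition", "replicate", "ct")


class QpcrError(ValueError):
    pass


def _check_ct_table(ct: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise QpcrError(f"Ct table missing columns {missing}")
    if (ct["ct"] <= 0).any():
        raise QpcrError("Ct values must be > 0")


@dataclass
class DdctResult:
    target: str
    condition: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float
    fold_sd: float  # dispersion over replicate-wise fold estimates


def ddct_fold_change(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    control_condition: str,
    dispersion: str = "replicate",
) -> pd.DataFrame:
    """Per-condition ddCt fold change of ``target`` vs ``reference``.

    The point estimate uses replicate-mean Cts, so the control condition's
    own fold change is exactly 1. Dispersion is, by default, the standard
    deviation over replicate-matched fold estimates ("replicate" mode);
    "ct" mode instead propagates the Ct standard deviations.
    """
    _check_ct_table(ct)
    conditions = list(dict.fromkeys(ct["condition"]))
    if control_condition not in conditions:
        raise QpcrError(f"control condition {control_condition!r} not in table")

    def mean_ct(gene: str, cond: str) -> float:
        sel = ct[(ct["gene"] == gene) & (ct["condition"] == cond)]["ct"]
        if sel.empty:
            raise QpcrError(f"no Ct values for gene {gene!r} in condition {cond!r}")
        return float(sel.mean())

    d_control = mean_ct(target, control_condition) - mean_ct(reference, control_condition)
    rows = []
    for cond in conditions:
        d = mean_ct(target, cond) - mean_ct(reference, cond)
        dd = d - d_control
        fold = 2.0 ** (-dd)
        if dispersion == "replicate":
            t = ct[(ct["gene"] == target) & (ct["condition"] == cond)].sort_values("replicate")
            r = ct[(ct["gene"] == reference) & (ct["condition"] == cond)].sort_values("replicate")
            k = min(len(t), len(r))
            d_rep = t["ct"].to_numpy()[:k] - r["ct"].to_numpy()[:k]
            folds = 2.0 ** (-(d_rep - d_control))
            sd = float(np.std(folds, ddof=1)) if k > 1 else float("nan")
        elif dispersion == "ct":
            t_sd = float(ct[(ct["gene"] == target) & (ct["condition"] == cond)]["ct"].std(ddof=1))
            r_sd = float(ct[(ct["gene"] == reference) & (ct["condition"] == cond)]["ct"].std(ddof=1))
            dd_sd = float(np.hypot(t_sd, r_sd))
            sd = float(np.log(2) * fold * dd_sd)  # delta-method on 2**(-ddCt)
        else:
            raise QpcrError(f"unknown dispersion mode {dispersion!r}")
        rows.append(DdctResult(target, cond, d, dd, fold, sd))
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class GroupComparison:
    method: str  # "anova_tukey" | "paired_t"
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, statistic?, p_adjusted, significant


def oneway_anova(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Plain one-way ANOVA over labelled groups (F, p)."""
    f, p = stats.f_oneway(*groups.values())
    return float(f), float(p)


def group_compare(
    groups: dict[str, "np.ndarray | list[float]"],
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare Ct groups: >2 groups -> ANOVA + Tukey; 2 -> paired t-test.

    The paired test requires replicate-matched groups of equal size. Every
    group needs at least three replicates.
    """
    if len(groups) < 2:
        raise QpcrError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 3:
            raise QpcrError(f"group {k!r} has fewer than 3 replicates")
    if len(arrays) == 2:
        (l1, v1), (l2, v2) = arrays.items()
        if v1.size != v2.size:
            raise QpcrError("paired t-test requires equal replicate counts")
        t, p = stats.ttest_rel(v1, v2)
        pw = pd.DataFrame(
            [{"group1": l1, "group2": l2, "p_adjusted": float(p),
              "significant": bool(p < alpha)}]
        )
        return GroupComparison("paired_t", float(t), float(p), pw)
    f, p = oneway_anova(arrays)
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * v.size for k, v in arrays.items()])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pw = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    ).rename(columns={"p-adj": "p_adjusted", "reject": "significant"})
    pw["p_adjusted"] = pw["p_adjusted"].astype(float)
    pw["significant"] = pw["significant"].astype(bool)
    return GroupComparison("anova_tukey", f, p, pw)


def compare_conditions(ct: pd.DataFrame, gene: str, alpha: float = 0.05) -> GroupComparison:
    """Group-compare one gene's Cts across all conditions in a Ct table."""
    _check_ct_table(ct)
    sub = ct[ct["gene"] == gene]
    if sub.empty:
        raise QpcrError(f"gene {gene!r} not in Ct table")
    groups = {
        str(cond): grp.sort_values("replicate")["ct"].to_numpy()
        for cond, grp in sub.groupby("condition", sort=True)
    }
    return group_compare(groups, alpha)


def all_fold_changes(
    ct: pd.DataFrame, reference: str, control_condition: str,
    dispersion: str = "replicate",
) -> pd.DataFrame:
    """ddCt fold changes for every non-reference gene in a Ct table."""
    _check_ct_table(ct)
    targets = [g for g in dict.fromkeys(ct["gene"]) if g != reference]
    parts = [
        ddct_fold_change(ct, t, reference, control_condition, dispersion)
        for t in targets
    ]
    return pd.concat(parts, ignore_index=True)
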