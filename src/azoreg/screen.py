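"""Plate-based loss-of-function decolorization screen scoring and hit calling.

Each well pairs an absorbance reading of the azo-dye medium (450 nm) at 0 h
and at 16 h; the drop, as a fraction of the initial reading, is the strain's
decolorization percentage. Mutant percentages are normalized to the wild
type (per plate by default, which absorbs plate effects) and classified:
normalized <= 65 -> reduced, >= 110 -> increased, otherwise neutral; both
boundaries inclusive. Preliminary hits are confirmed by replicate retesting
with a two-tailed Welch t-test of mutant vs wild-type decolorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CUT_LOW = 65.0
CUT_HIGH = 110.0

PLATE_COLUMNS = ("plate", "well", "strain", "A450_0h", "A450_16h")


def decolorization_pct(a_initial: float, a_final: float) -> float:
    """(A_initial - A_final) / A_initial * 100.

    Negative values (the well got *darker*) are returned as-is; callers flag
    them rather than clamping, because they signal growth/turbidity artefacts
    worth inspecting.
    """
    if a_initial <= 0:
        raise ValueError(f"initial absorbance must be > 0, got {a_initial}")
    return (a_initial - a_final) / a_initial * 100.0


def normalize_to_wt(mutant_decol: float, wt_decol: float) -> float:
    """Mutant decolorization as a percentage of the wild type's."""
    if wt_decol <= 0:
        raise ValueError(f"WT decolorization must be > 0 (assay failure), got {wt_decol}")
    return mutant_decol / wt_decol * 100.0


def classify(normalized_pct: float, cut_low: float = CUT_LOW,
             cut_high: float = CUT_HIGH) -> str:
    """Three-way hit class with inclusive boundaries."""
    if cut_low >= cut_high:
        raise ValueError("cut_low must be < cut_high")
    if normalized_pct <= cut_low:
        return "reduced"
    if normalized_pct >= cut_high:
        return "increased"
    return "neutral"


def score_plates(
    plates: pd.DataFrame,
    wt_strain: str = "WT",
    per_plate_wt: bool = True,
) -> pd.DataFrame:
    """Score every well of a plate table and normalize to the wild type.

    ``plates`` needs columns plate, well, strain, A450_0h, A450_16h. With
    ``per_plate_wt`` (default) each plate's own WT wells provide the
    denominator; otherwise the global WT mean is used. Returns one row per
    non-WT well with decol_pct, normalized_pct and a negative-decolorization
    flag.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plates.columns]
    if missing:
        raise ValueError(f"plate table missing columns {missing}")
    df = plates.copy()
    df["decol_pct"] = [
        decolorization_pct(a0, a1) for a0, a1 in zip(df["A450_0h"], df["A450_16h"])
    ]
    wt = df[df["strain"] == wt_strain]
    if wt.empty:
        raise ValueError(f"no wells for WT strain {wt_strain!r}")
    global_wt = float(wt["decol_pct"].mean())
    wt_by_plate = wt.groupby("plate")["decol_pct"].mean()
    out = df[df["strain"] != wt_strain].copy()
    if per_plate_wt:
        denom = out["plate"].map(wt_by_plate)
        if denom.isna().any():
            bad = sorted(out.loc[denom.isna(), "plate"].unique())
            raise ValueError(f"plates without WT wells: {bad}")
    else:
        denom = pd.Series(global_wt, index=out.index)
    out["normalized_pct"] = [
        normalize_to_wt(m, w) for m, w in zip(out["decol_pct"], denom)
    ]
    out["negative_decol"] = out["decol_pct"] < 0
    return out.reset_index(drop=True)


def call_hits(
    scored: pd.DataFrame,
    cut_low: float = CUT_LOW,
    cut_high: float = CUT_HIGH,
    value_col: str = "normalized_pct",
) -> pd.DataFrame:
    """Attach a hit class to every scored strain (partitioning them)."""
    out = scored.copy()
    out["hit_class"] = [classify(v, cut_low, cut_high) for v in out[value_col]]
    return out


@dataclass
class ConfirmedHit:
    strain: str
    n: int
    mean_normalized: float
    sd_normalized: float
    p_value: float | None
    confirmed: bool
    status: str  # "tested" | "untestable"
    hit_class: str


def confirm_hits(
    candidate_reps: pd.DataFrame,
    wt_reps: np.ndarray | pd.Series,
    alpha: float = 0.05,
    cut_low: float = CUT_LOW,
    cut_high: float = CUT_HIGH,
) -> pd.DataFrame:
    """Replicate-based confirmation of preliminary hits.

    ``candidate_reps`` has columns strain, decol_pct (one row per replicate
    measurement); ``wt_reps`` are the wild type's replicate decolorization
    percentages. A strain is confirmed when the Welch two-tailed t-test
    against WT rejects at ``alpha`` AND its mean normalized decolorization is
    still at or beyond its cutoff. Strains (or a WT) with fewer than three
    replicates are reported untestable.
    """
    wt = np.asarray(wt_reps, dtype=float)
    wt_mean = float(wt.mean()) if wt.size else float("nan")
    rows = []
    for strain, grp in candidate_reps.groupby("strain", sort=True):
        vals = grp["decol_pct"].to_numpy(dtype=float)
        n = vals.size
        mean_norm = normalize_to_wt(float(vals.mean()), wt_mean)
        sd_norm = float(vals.std(ddof=1) / wt_mean * 100.0) if n > 1 else float("nan")
        if n < 3 or wt.size < 3:
            rows.append(ConfirmedHit(strain, n, mean_norm, sd_norm, None, False,
                                     "untestable", classify(mean_norm, cut_low, cut_high)))
            continue
        p = float(stats.ttest_ind(vals, wt, equal_var=False).pvalue)
        cls = classify(mean_norm, cut_low, cut_high)
        rows.append(ConfirmedHit(strain, n, mean_norm, sd_norm, p,
                                 bool(p < alpha and cls != "neutral"), "tested", cls))
    return pd.DataFrame([r.__dict__ for r in rows])
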