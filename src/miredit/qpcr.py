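"""qPCR relative quantification and group statistics.

Implements efficiency-parameterized relative quantification: per sample,
dCt = Ct_target - Ct_reference (18S rRNA as the housekeeping gene in the
study); ddCt = dCt - mean dCt of the control group (the 3-month animals
of the same sex); fold change = E_target^(-ddCt), which reduces to the
classic 2^-ddCt at perfect doubling efficiency E = 2. When both target
and reference efficiencies are given, the dual-efficiency ratio
E_t^(dCt_t,control - Ct_t,sample) / E_r^(...) is also reported.

Group comparisons run on the dCt scale (one-way ANOVA with Tukey HSD
post-hoc), avoiding the bias of averaging exponentially transformed
data. Array-style screens flag fold changes > 3.0 as increase and
< 0.3 as decrease (strict boundaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

FOLD_UP = 3.0
FOLD_DOWN = 0.3

CT_RANGE = (0.0, 45.0)
EFFICIENCY_RANGE = (1.6, 2.2)


def _validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "sex", "age_months", "target", "ct_target", "ct_reference"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    t = table.copy()
    if "efficiency_target" not in t.columns:
        t["efficiency_target"] = 2.0
    if "efficiency_reference" not in t.columns:
        t["efficiency_reference"] = 2.0
    for col in ("efficiency_target", "efficiency_reference"):
        e = t[col].astype(float)
        if ((e < EFFICIENCY_RANGE[0]) | (e > EFFICIENCY_RANGE[1])).any():
            raise ValueError(f"{col} outside {EFFICIENCY_RANGE}")
    # samples without a reference-gene Ct cannot be quantified
    no_ref = t["ct_reference"].isna()
    if no_ref.any():
        dropped = t.loc[no_ref, "sample_id"].tolist()
        warnings.warn(f"excluding samples without reference Ct: {dropped}")
        t = t.loc[~no_ref]
    for col in ("ct_target", "ct_reference"):
        v = t[col].astype(float)
        if ((v <= CT_RANGE[0]) | (v >= CT_RANGE[1])).any():
            raise ValueError(f"{col} outside (0, 45) cycles")
    return t


def pfaffl_fold(
    table: pd.DataFrame, control_age_months: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample and per-group fold changes vs the same-sex control group.

    Returns ``(per_sample, per_group)``. Per-sample rows carry dCt, ddCt
    and the fold ``E_target^(-ddCt)`` (plus the dual-efficiency Pfaffl
    ratio); the group table reports the mean ddCt per (target, sex, age)
    and its fold ``E^(-mean ddCt)``, so the control group's own fold is
    exactly 1.
    """
    t = _validate_ct_table(table)
    t["delta_ct"] = t["ct_target"].astype(float) - t["ct_reference"].astype(float)
    out = []
    for (target, sex), sub in t.groupby(["target", "sex"], sort=False):
        control = sub[sub["age_months"] == control_age_months]
        if control.empty:
            raise ValueError(
                f"control group (age {control_age_months}) empty for "
                f"target={target!r}, sex={sex!r}"
            )
        ctrl_dct = control["delta_ct"].mean()
        ctrl_ct_t = control["ct_target"].astype(float).mean()
        ctrl_ct_r = control["ct_reference"].astype(float).mean()
        sub = sub.copy()
        sub["delta_delta_ct"] = sub["delta_ct"] - ctrl_dct
        e_t = sub["efficiency_target"].astype(float)
        e_r = sub["efficiency_reference"].astype(float)
        sub["fold"] = e_t ** (-sub["delta_delta_ct"])
        # dual-efficiency Pfaffl ratio
        sub["fold_pfaffl"] = (
            e_t ** (ctrl_ct_t - sub["ct_target"].astype(float))
            / e_r ** (ctrl_ct_r - sub["ct_reference"].astype(float))
        )
        out.append(sub)
    per_sample = pd.concat(out, ignore_index=True)
    grp = (
        per_sample.groupby(["target", "sex", "age_months"], sort=False)
        .agg(
            n=("sample_id", "size"),
            mean_delta_ct=("delta_ct", "mean"),
            mean_delta_delta_ct=("delta_delta_ct", "mean"),
            efficiency_target=("efficiency_target", "mean"),
        )
        .reset_index()
    )
    grp["fold"] = grp["efficiency_target"] ** (-grp["mean_delta_delta_ct"])
    return per_sample, grp


@dataclass(frozen=True)
class AnovaTukeyResult:
    f: float
    p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject


def anova_tukey(values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA on dCt with Tukey HSD pairwise tests.

    Singleton groups are excluded (with a warning). If all retained
    observations are an identical constant, the F ratio is 0/0; the
    convention here is p = 1 with F reported as nan.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": np.asarray(groups)})
    sizes = df.groupby("group")["value"].size()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        warnings.warn(f"excluding singleton groups from tests: {singletons}")
        df = df[~df["group"].isin(singletons)]
    kept = df["group"].unique()
    if len(kept) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    arrays = [df.loc[df["group"] == g, "value"].to_numpy() for g in kept]
    if np.ptp(df["value"].to_numpy()) == 0.0:
        empty = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"]
        )
        return AnovaTukeyResult(f=float("nan"), p=1.0, tukey=empty)
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*arrays)
    hsd = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy())
    tukey = pd.DataFrame(
        hsd.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"],
    )
    # recompute p-values at full precision (the summary rounds them)
    tukey["p_adj"] = hsd.pvalues
    return AnovaTukeyResult(f=float(f), p=float(p), tukey=tukey)


def classify_array_folds(folds: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Array-screen flags: fold > 3.0 increase, < 0.3 decrease, else unchanged.

    Boundaries are strict: a fold of exactly 3.0 or 0.3 is unchanged.
    """
    f = np.asarray(folds, dtype=float)
    if (f <= 0).any():
        raise ValueError("fold changes must be positive")
    return np.where(f > FOLD_UP, "increase", np.where(f < FOLD_DOWN, "decrease", "unchanged"))


def array_qc(
    rtc: np.ndarray | pd.Series | list[float],
    gpc: np.ndarray | pd.Series | list[float],
    rtc_max: float = 5.0,
    gpc_min: float = 35.0,
) -> np.ndarray:
    """Array quality-control pass flags.

    An array passes when its reverse-transcription-control value is
    <= ``rtc_max`` and its genomic-DNA-contamination-control value is
    >= ``gpc_min``; both thresholds are configurable.
    """
    r = np.asarray(rtc, dtype=float)
    g = np.asarray(gpc, dtype=float)
    return (r <= rtc_max) & (g >= gpc_min)
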