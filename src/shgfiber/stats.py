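"""Recurrence statistics: t-test, random-intercept model, survival analysis.

Three analyses connect percent fiber volume to recurrence:

1. A one-tailed unpaired Student t-test on patient-level mean volumes
   (the working hypothesis is that recurrent tumours carry denser collagen,
   i.e. alternative ``recurrent > non_recurrent``).
2. A linear mixed model on natural-log-transformed per-FOV volumes — the log
   reduces the right skew of raw fractions — with recurrence status as the
   fixed effect and a per-patient (tissue-block) random intercept absorbing
   repeated measurements, fitted by REML.
3. A median split of patients on mean fiber volume followed by Kaplan-Meier
   curves, the log-rank test, and a hazard ratio.  The primary HR estimator
   is (O_high/E_high)/(O_low/E_low) from the log-rank observed/expected
   table; a Cox partial-likelihood HR is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUP_ORDER = ("non_recurrent", "recurrent")


# ---------------------------------------------------------------------------
# t-test

@dataclass
class TTestResult:
    t: float
    df: float
    p_one_sided: float
    p_two_sided: float
    alternative: str
    pooled: bool


def _as_summary(group) -> tuple[float, float, int]:
    """Coerce raw values or a (mean, sd, n) triple to summary statistics."""
    if isinstance(group, tuple) and len(group) == 3 and np.isscalar(group[0]):
        mean, sd, n = group
        return float(mean), float(sd), int(n)
    values = np.asarray(group, dtype=float)
    if values.size < 2:
        raise ValueError("need n >= 2 per group")
    return float(values.mean()), float(values.std(ddof=1)), int(values.size)


def ttest_one_tailed(
    group_a,
    group_b,
    alternative: str = "greater",
    pooled: bool = True,
) -> TTestResult:
    """Unpaired Student t-test with one- and two-sided p-values.

    ``group_a`` and ``group_b`` are either arrays of raw values or
    ``(mean, sd, n)`` summary triples, so comparisons can be reproduced from
    published summary statistics alone.  ``alternative="greater"`` tests
    mean_a > mean_b.  ``pooled=True`` gives the classical equal-variance
    Student test; ``pooled=False`` the Welch test.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    m1, s1, n1 = _as_summary(group_a)
    m2, s2, n2 = _as_summary(group_b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 == 0 and s2 == 0:
        raise ValueError("zero variance in both groups; t undefined")

    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=pooled)
    t = float(res.statistic)
    if pooled:
        df = float(n1 + n2 - 2)
    else:
        va, vb = s1**2 / n1, s2**2 / n2
        df = (va + vb) ** 2 / (va**2 / (n1 - 1) + vb**2 / (n2 - 1))
    p_two = float(res.pvalue)
    sign_ok = t > 0 if alternative == "greater" else t < 0
    p_one = p_two / 2 if sign_ok else 1 - p_two / 2
    return TTestResult(t, df, p_one, p_two, alternative, pooled)


# ---------------------------------------------------------------------------
# random-intercept mixed model

@dataclass
class MixedModelFit:
    """REML fit of log(volume) ~ recurrence with a per-patient intercept."""

    beta_group: float
    se_beta: float
    p_two_sided: float
    p_one_sided: float
    var_between: float
    var_within: float
    n_patients: int
    n_fovs: int
    df_method: str = "normal"  # Wald z on the fixed effect
    transform: str = "natural_log"


def fit_random_intercept(
    fovs: pd.DataFrame,
    zero_policy: str = "error",
) -> MixedModelFit:
    """Fit the log-scale random-intercept model to per-FOV volumes.

    Parameters
    ----------
    fovs
        Table with columns ``patient_id``, ``group`` (non_recurrent /
        recurrent), ``percent_fiber_volume``.
    zero_policy
        ``"error"`` rejects non-positive volumes (default); ``"offset"``
        applies log(x + delta) with delta = half the smallest positive
        observed volume.

    The fixed-effect p-value uses the Wald normal approximation (recorded in
    ``df_method``); the one-sided p tests recurrent > non_recurrent.
    """
    import statsmodels.api as sm

    required = {"patient_id", "group", "percent_fiber_volume"}
    if required - set(fovs.columns):
        raise ValueError(f"missing columns: {sorted(required - set(fovs.columns))}")
    groups = set(fovs["group"])
    if not groups <= set(GROUP_ORDER):
        raise ValueError(f"unknown group labels: {sorted(groups - set(GROUP_ORDER))}")
    for g in GROUP_ORDER:
        if fovs.loc[fovs["group"] == g, "patient_id"].nunique() < 2:
            raise ValueError(f"need >= 2 patients in group {g!r}")

    vol = fovs["percent_fiber_volume"].to_numpy(dtype=float)
    nonpos = vol <= 0
    if nonpos.any():
        if zero_policy == "error":
            bad = fovs.loc[nonpos, ["patient_id"]].assign(
                fov=fovs.loc[nonpos].get("fov_id", pd.Series(index=fovs.index[nonpos]))
            )
            raise ValueError(
                "non-positive percent volumes cannot be log-transformed: "
                f"{bad.to_dict(orient='records')}"
            )
        if zero_policy != "offset":
            raise ValueError("zero_policy must be 'error' or 'offset'")
        delta = 0.5 * vol[vol > 0].min()
        vol = vol + delta

    y = np.log(vol)
    x = sm.add_constant((fovs["group"] == "recurrent").astype(float).to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, x, groups=fovs["patient_id"].to_numpy())
        fit = model.fit(reml=True)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    z = beta / se
    p_two = 2 * sps.norm.sf(abs(z))
    p_one = sps.norm.sf(z)  # H1: recurrent > non_recurrent
    return MixedModelFit(
        beta_group=beta,
        se_beta=se,
        p_two_sided=float(p_two),
        p_one_sided=float(p_one),
        var_between=float(np.asarray(fit.cov_re)[0, 0]),
        var_within=float(fit.scale),
        n_patients=int(fovs["patient_id"].nunique()),
        n_fovs=int(len(fovs)),
    )


# ---------------------------------------------------------------------------
# survival

@dataclass
class SurvivalSplit:
    """Median dichotomy of patients on mean fiber volume."""

    threshold: float
    high: pd.DataFrame = field(repr=False)
    low: pd.DataFrame = field(repr=False)
    tie_policy: str = "ties_to_low"


def median_split(patients: pd.DataFrame) -> SurvivalSplit:
    """Split patients at the median of ``mean_volume``.

    Strictly greater than the median goes to the high group; less than or
    equal (ties) to the low group.  All-identical volumes leave the split
    undefined and raise.
    """
    if len(patients) < 4:
        raise ValueError("need >= 4 patients for a median split")
    vols = patients["mean_volume"].to_numpy(dtype=float)
    if np.all(vols == vols[0]):
        raise ValueError("all volumes identical; median split undefined")
    threshold = float(np.median(vols))
    high = patients[vols > threshold].reset_index(drop=True)
    low = patients[vols <= threshold].reset_index(drop=True)
    return SurvivalSplit(threshold=threshold, high=high, low=low)


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate evaluated after each event time."""

    times: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t): survival probability just after time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(times, events) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator.

    Censored subjects (event 0) leave the risk set after their time; the
    curve starts at 1 and is non-increasing.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("event flags must be 0 or 1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KaplanMeierCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
    )


@dataclass
class LogrankResult:
    chi2: float
    p: float
    hr: float  # (O_high/E_high) / (O_low/E_low)
    o_high: float
    e_high: float
    o_low: float
    e_low: float
    cox_hr: float | None = None  # partial-likelihood alternative, high vs low


def logrank_and_hr(
    high: pd.DataFrame,
    low: pd.DataFrame,
    cox: bool = True,
) -> LogrankResult:
    """Log-rank test and hazard ratio between two survival groups.

    Both inputs need ``time`` and ``event`` columns.  The log-rank statistic
    accumulates, over pooled event times, the observed minus
    hypergeometric-expected events in the high group; the primary hazard
    ratio is the ratio of observed/expected ratios.  ``cox=True`` also fits a
    univariate Cox model for the partial-likelihood HR.
    """
    t1 = high["time"].to_numpy(dtype=float)
    e1 = high["event"].to_numpy(dtype=int)
    t2 = low["time"].to_numpy(dtype=float)
    e2 = low["event"].to_numpy(dtype=int)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both groups must be non-empty")
    if e1.sum() + e2.sum() == 0:
        raise ValueError("no events in either group; log-rank undefined")

    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    o1 = float(e1.sum())
    o2 = float(e2.sum())
    e_high = 0.0
    var = 0.0
    for t in event_times:
        n1 = float((t1 >= t).sum())
        n2 = float((t2 >= t).sum())
        n = n1 + n2
        d = float((t1[e1 == 1] == t).sum() + (t2[e2 == 1] == t).sum())
        e_high += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    e_low = (o1 + o2) - e_high

    if var > 0:
        chi2 = (o1 - e_high) ** 2 / var
        p = float(sps.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    if o1 == 0 or o2 == 0 or e_high == 0 or e_low == 0:
        hr = np.inf if (o1 > 0 and o2 == 0) else (0.0 if o1 == 0 else np.nan)
    else:
        hr = (o1 / e_high) / (o2 / e_low)

    cox_hr = None
    if cox:
        cox_hr = _cox_hr(t1, e1, t2, e2)
    return LogrankResult(
        chi2=float(chi2), p=p, hr=float(hr),
        o_high=o1, e_high=e_high, o_low=o2, e_low=e_low, cox_hr=cox_hr,
    )


def _cox_hr(t1, e1, t2, e2) -> float | None:
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = pd.DataFrame(
        {
            "time": np.concatenate([t1, t2]),
            "event": np.concatenate([e1, e2]),
            "high": np.concatenate([np.ones_like(t1), np.zeros_like(t2)]),
        }
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        return float(np.exp(fit.params_["high"]))
    except (ConvergenceError, ValueError):
        return None


def survival_report(patients: pd.DataFrame) -> dict:
    """Median split + log-rank + HR in one JSON-ready dictionary."""
    split = median_split(patients)
    res = logrank_and_hr(split.high, split.low)
    return {
        "median": split.threshold,
        "tie_policy": split.tie_policy,
        "n_high": len(split.high),
        "n_low": len(split.low),
        "hr": res.hr,
        "cox_hr": res.cox_hr,
        "chi2": res.chi2,
        "p": res.p,
    }


def compare_groups_report(fovs: pd.DataFrame, patients: pd.DataFrame) -> dict:
    """Patient-level t-test plus FOV-level mixed model, JSON-ready."""
    a = patients.loc[patients["group"] == "recurrent", "mean_volume"].to_numpy()
    b = patients.loc[patients["group"] == "non_recurrent", "mean_volume"].to_numpy()
    tt = ttest_one_tailed(a, b, alternative="greater")
    mm = fit_random_intercept(fovs)
    return {
        "ttest": {"t": tt.t, "df": tt.df, "p_one": tt.p_one_sided, "p_two": tt.p_two_sided},
        "mixed": {
            "beta": mm.beta_group,
            "se": mm.se_beta,
            "p_one": mm.p_one_sided,
            "p_two": mm.p_two_sided,
            "var_between": mm.var_between,
            "var_within": mm.var_within,
            "df_method": mm.df_method,
        },
    }
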