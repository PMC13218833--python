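"""Band-averaged NVC trajectories and group-trajectory statistics.

Each subject's coherence map is reduced to a time-resolved curve — the mean
R2 over the identified period band at each time point.  Group trajectories
are compared with a linear mixed-effects model (fixed effects: group, time,
group x time; random intercept per subject; REML), hourly marginal-mean
contrasts over the 0–6 h window with Bonferroni correction across the seven
evaluation points, and a one-tailed two-sample t-test on each subject's
window-mean coherence.

Group coding: group A (non-cooled) is the reference; the TH indicator is 1
for group B, so a negative group estimate means lower coupling under
therapeutic hypothermia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .wtc import CoherenceMap


class SummaryError(ValueError):
    pass


@dataclass
class NVCTrajectory:
    subject_id: str
    group: str                  # "A" (reference) or "B" (TH)
    time_h: np.ndarray
    value: np.ndarray           # mean R2 in band, within [0, 1]

    def __post_init__(self) -> None:
        v = self.value[np.isfinite(self.value)]
        if v.size and (v.min() < -1e-9 or v.max() > 1.0 + 1e-9):
            raise SummaryError("trajectory values outside [0, 1]")
        if np.any(np.diff(self.time_h) <= 0):
            raise SummaryError("time axis must be strictly increasing")


@dataclass
class LMEFit:
    params: pd.DataFrame        # index: term; columns: estimate, se, ci_lo, ci_hi, p
    random_intercept_var: float
    residual_var: float
    n_subjects: int
    n_obs: int
    cov_params: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ContrastSet:
    table: pd.DataFrame         # columns: hour, estimate, se, p_raw, p_adj
    correction: str = "bonferroni x 7"


def band_mean_timecourse(cmap: CoherenceMap, band: tuple[float, float],
                         subject_id: str = "", group: str = "A") -> NVCTrajectory:
    """Unweighted mean of R2 over period rows inside [band] at each time.

    Rows that are missing (NaN, e.g. unresolved short periods) are excluded
    from the mean column-wise.
    """
    lo, hi = band
    rows = (cmap.periods_min >= lo) & (cmap.periods_min <= hi)
    if not rows.any():
        raise SummaryError(f"band ({lo}, {hi}) min outside map period coverage")
    sub = cmap.r2[rows]
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(sub, axis=0)
    return NVCTrajectory(subject_id=subject_id, group=group,
                         time_h=np.asarray(cmap.time_h), value=vals)


def trajectories_frame(trajs: list[NVCTrajectory]) -> pd.DataFrame:
    frames = [pd.DataFrame({"subject": t.subject_id, "group": t.group,
                            "time_h": t.time_h, "nvc": t.value}) for t in trajs]
    return pd.concat(frames, ignore_index=True).dropna(subset=["nvc"])


def thin_to_hourly(df: pd.DataFrame) -> pd.DataFrame:
    """One observation per subject per whole hour (nearest map column)."""
    out = []
    for (_, sub) in df.groupby("subject", sort=False):
        hours = np.arange(np.floor(sub["time_h"].min()),
                          np.floor(sub["time_h"].max()) + 1)
        idx = np.abs(sub["time_h"].to_numpy()[None, :] - hours[:, None]).argmin(axis=1)
        picked = sub.iloc[idx].copy()
        picked["time_h"] = hours
        out.append(picked)
    return pd.concat(out, ignore_index=True)


def fit_lme(df: pd.DataFrame) -> LMEFit:
    """value ~ group + time + group:time, random intercept per subject, REML."""
    import statsmodels.formula.api as smf

    df = df.copy()
    if df.groupby("group")["subject"].nunique().min() < 2:
        raise SummaryError("need at least 2 subjects per group")
    df["th"] = (df["group"] == "B").astype(float)
    model = smf.mixedlm("nvc ~ th + time_h + th:time_h", df, groups=df["subject"])
    # the random-intercept variance often sits near its boundary for
    # strongly separated groups; fall back across optimizers before failing
    fit, last = None, None
    for method in ("lbfgs", "powell", "cg"):
        try:
            cand = model.fit(reml=True, method=method)
        except Exception as exc:
            last = exc
            continue
        if cand.converged:
            fit = cand
            break
        last = SummaryError(f"optimizer {method} did not converge")
    if fit is None:
        raise SummaryError(f"mixed model failed to converge: {last}") from (
            last if isinstance(last, Exception) else None)
    terms = ["Intercept", "th", "time_h", "th:time_h"]
    ci = fit.conf_int().loc[terms]
    params = pd.DataFrame({
        "estimate": fit.params.loc[terms],
        "se": fit.bse.loc[terms],
        "ci_lo": ci[0],
        "ci_hi": ci[1],
        "p": fit.pvalues.loc[terms],
    })
    resid = np.asarray(fit.resid)
    diagnostics = {
        "resid_skew": float(stats.skew(resid)),
        "resid_kurtosis": float(stats.kurtosis(resid)),
        "shapiro_p_subsample": float(
            stats.shapiro(resid[:: max(1, len(resid) // 500)]).pvalue),
    }
    return LMEFit(params=params,
                  random_intercept_var=float(fit.cov_re.iloc[0, 0]),
                  residual_var=float(fit.scale),
                  n_subjects=df["subject"].nunique(),
                  n_obs=len(df),
                  cov_params=fit.cov_params().loc[terms, terms],
                  diagnostics=diagnostics)


def hourly_contrasts(fit: LMEFit, hours=tuple(range(7))) -> ContrastSet:
    """Model-implied group difference (B - A) at each hour, Bonferroni x len.

    The contrast at hour h is beta_group + h * beta_interaction; its variance
    comes from the coefficient covariance.  Wald z p-values (two-sided raw),
    adjusted p = min(1, 7 * raw).
    """
    est_g = fit.params.loc["th", "estimate"]
    est_i = fit.params.loc["th:time_h", "estimate"]
    V = fit.cov_params
    rows = []
    m = len(hours)
    for h in hours:
        est = est_g + h * est_i
        var = (V.loc["th", "th"] + h * h * V.loc["th:time_h", "th:time_h"]
               + 2 * h * V.loc["th", "th:time_h"])
        se = float(np.sqrt(var))
        z = est / se
        p_raw = float(2 * stats.norm.sf(abs(z)))
        rows.append({"hour": h, "estimate": float(est), "se": se,
                     "p_raw": p_raw, "p_adj": min(1.0, m * p_raw)})
    return ContrastSet(table=pd.DataFrame(rows), correction=f"bonferroni x {m}")


def window_mean_test(df: pd.DataFrame, window: tuple[float, float] = (0.0, 6.0),
                     tail: str = "a>b"):
    """One-tailed two-sample t on per-subject window-mean coherence.

    Returns (t statistic, one-tailed p, per-subject means frame).
    """
    lo, hi = window
    sub = df[(df["time_h"] >= lo) & (df["time_h"] <= hi)]
    if sub.empty:
        raise SummaryError("no observations inside the window")
    means = sub.groupby(["subject", "group"], sort=False)["nvc"].mean().reset_index()
    a = means.loc[means["group"] == "A", "nvc"].to_numpy()
    b = means.loc[means["group"] == "B", "nvc"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise SummaryError("need at least 2 subjects per group in the window")
    alternative = {"a>b": "greater", "b>a": "less"}.get(tail)
    if alternative is None:
        raise SummaryError(f"unknown tail {tail!r}")
    res = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    return float(res.statistic), float(res.pvalue), means


def period_to_mhz(period_min: float) -> float:
    """Oscillation frequency in mHz for a period in minutes, 2 decimals."""
    if period_min <= 0:
        raise SummaryError("period must be positive")
    return round(1000.0 / (period_min * 60.0), 2)


def effective_cycles(duration_h: float, period_min: float) -> float:
    """Number of oscillatory cycles of ``period_min`` fitting the record."""
    if duration_h <= 0 or period_min <= 0:
        raise SummaryError("inputs must be positive")
    return duration_h * 60.0 / period_min
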