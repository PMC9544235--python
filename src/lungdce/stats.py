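"""Repeated-measures statistical layer for the imaging endpoints.

The endpoint analysis mirrors a method-evaluation design: each endpoint and
region is fitted with a linear model with fixed effects for participant
group, session and their interaction, and a per-subject block realized as a
random intercept (mixed model). From the fit we report descriptive
group-difference contrasts at each session and session-difference contrasts
within each group, with t-based 95% intervals. Degrees of freedom follow the
between-within (containment) convention: between-subject contrasts use
``n_subjects - n_groups``; within-subject contrasts use the residual
within-subject df. P-values are descriptive only; no multiplicity adjustment
is applied.

Within-subject repeatability between two sessions is expressed as a
coefficient of variation derived from the same mixed model fitted on
log-transformed values:

    CV% = 100 * sqrt(exp(MSE) - 1),

where MSE is the residual (within-subject) variance on the log scale — the
back-transform is exact for log-normal within-subject error, which is why
the log transform is mandatory here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

log = logging.getLogger("lungdce")


@dataclass
class ContrastResult:
    """One estimated difference of least-squares means with its 95% CI."""

    comparison: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_subjects: int
    df: float

    def as_row(self) -> dict:
        return {
            "comparison": self.comparison, "estimate": self.estimate,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value, "n_subjects": self.n_subjects,
            "df": self.df,
        }


@dataclass
class RepeatabilityResult:
    """Within-subject repeatability of one endpoint between two sessions."""

    endpoint: str
    group: str
    mse: float
    cv_percent: float
    n_pairs: int


def cv_from_mse(mse: float) -> float:
    """Within-subject CV (%) implied by a log-scale residual variance."""
    if mse < 0:
        raise ValueError("MSE must be nonnegative")
    return 100.0 * np.sqrt(np.expm1(mse))


def _cell_row(groups: list, sessions: list, g, s) -> np.ndarray:
    """Fixed-effect design row for the (group, session) cell mean under
    treatment coding with full interaction."""
    ng, ns = len(groups), len(sessions)
    row = np.zeros(1 + (ng - 1) + (ns - 1) + (ng - 1) * (ns - 1))
    row[0] = 1.0
    gi = groups.index(g)
    si = sessions.index(s)
    if gi > 0:
        row[gi] = 1.0
    if si > 0:
        row[(ng - 1) + si] = 1.0
    if gi > 0 and si > 0:
        row[ng + ns - 1 + (gi - 1) * (ns - 1) + (si - 1)] = 1.0
    return row


def _build_design(df: pd.DataFrame, groups: list, sessions: list) -> np.ndarray:
    rows = np.stack([
        _cell_row(groups, sessions, g, s)
        for g, s in zip(df["group"], df["session"])
    ])
    return rows


def _fit_mixed(endog: np.ndarray, exog: np.ndarray,
               subjects: np.ndarray):
    """Random-intercept mixed model fit (REML); returns the results object."""
    model = sm.MixedLM(endog, exog, groups=subjects)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return model.fit(reml=True)
        except Exception:
            return model.fit(reml=True, method="powell")


def fit_rm_anova(table: pd.DataFrame, endpoint: str,
                 region: str = "total") -> tuple[object, list[ContrastResult]]:
    """Group x session analysis of one endpoint in one region.

    Returns the fitted mixed-model results object and the contrast list:
    pairwise group differences at each session (patient minus control, i.e.
    HF - HV for the standard labels, with "HV" treated as reference) and
    session differences within each group. Raises if the endpoint is absent
    or any group has fewer than two subjects.
    """
    df = table[(table["endpoint"] == endpoint) &
               (table["region"] == region)].copy()
    if df.empty:
        raise ValueError(f"endpoint {endpoint!r} (region {region!r}) absent "
                         "from table")
    # control ("HV") first so contrasts read patient-minus-control (HF - HV)
    groups = sorted(df["group"].unique(),
                    key=lambda g: (g != "HV", g))
    sessions = sorted(df["session"].unique())
    for g in groups:
        n_sub = df.loc[df["group"] == g, "subject_id"].nunique()
        if n_sub < 2:
            raise ValueError(f"group {g!r} has only {n_sub} subject(s); "
                             "need at least 2")
    n_subjects = df["subject_id"].nunique()
    n_obs = len(df)

    exog = _build_design(df, groups, sessions)
    endog = df["value"].to_numpy(float)
    subjects = df["subject_id"].to_numpy()

    degenerate = np.ptp(endog) == 0
    if degenerate:
        warnings.warn("degenerate variance: all endpoint values identical",
                      RuntimeWarning, stacklevel=2)
        log.warning("fit_rm_anova: degenerate variance for %s/%s",
                    endpoint, region)
        beta, *_ = np.linalg.lstsq(exog, endog, rcond=None)
        cov = np.zeros((beta.size, beta.size))
        result = None
    else:
        result = _fit_mixed(endog, exog, subjects)
        beta = np.asarray(result.fe_params)
        cov = np.asarray(result.cov_params())[: beta.size, : beta.size]

    df_between = max(n_subjects - len(groups), 1)
    df_within = max(n_obs - n_subjects - len(groups) * (len(sessions) - 1), 1)

    contrasts: list[ContrastResult] = []

    def add(label: str, L: np.ndarray, dof: float, n_sub: int) -> None:
        est = float(L @ beta)
        se = float(np.sqrt(max(L @ cov @ L, 0.0)))
        if se == 0.0:
            ci_lo = ci_hi = est
            p = float("nan") if not degenerate else float("nan")
        else:
            tcrit = sps.t.ppf(0.975, dof)
            ci_lo, ci_hi = est - tcrit * se, est + tcrit * se
            tstat = est / se
            p = float(2 * sps.t.sf(abs(tstat), dof))
        contrasts.append(ContrastResult(label, est, ci_lo, ci_hi,
                                        p if se > 0 else float("nan"),
                                        n_sub, dof))

    # group differences at each session
    for s in sessions:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                g1, g2 = groups[i], groups[j]
                L = _cell_row(groups, sessions, g2, s) - \
                    _cell_row(groups, sessions, g1, s)
                n_sub = df.loc[df["group"].isin([g1, g2]),
                               "subject_id"].nunique()
                add(f"{g2}-{g1} @ session {s}", L, df_between, n_sub)
    # session differences within each group
    for g in groups:
        for i in range(len(sessions)):
            for j in range(i + 1, len(sessions)):
                s1, s2 = sessions[i], sessions[j]
                L = _cell_row(groups, sessions, g, s2) - \
                    _cell_row(groups, sessions, g, s1)
                n_sub = df.loc[df["group"] == g, "subject_id"].nunique()
                add(f"{g}: session {s2}-{s1}", L, df_within, n_sub)
    return result, contrasts


def within_subject_cv(table: pd.DataFrame, endpoint: str, group: str,
                      region: str = "total",
                      sessions: tuple[int, int] = (1, 2)) -> RepeatabilityResult:
    """Within-subject CV between two sessions for one endpoint and group.

    Fits the random-intercept model on log-transformed values (session as
    fixed effect); the residual variance is the MSE entering the exact
    back-transform ``100 * sqrt(exp(MSE) - 1)``. Only subjects observed at
    both sessions contribute. Nonpositive values are incompatible with the
    log transform and raise, listing the offending rows.
    """
    df = table[(table["endpoint"] == endpoint) & (table["region"] == region) &
               (table["group"] == group) &
               (table["session"].isin(sessions))].copy()
    if df.empty:
        raise ValueError(f"no rows for endpoint {endpoint!r}, group {group!r}")
    counts = df.groupby("subject_id")["session"].nunique()
    complete = counts[counts == 2].index
    df = df[df["subject_id"].isin(complete)]
    if df["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects with both sessions")
    bad = df[df["value"] <= 0]
    if not bad.empty:
        raise ValueError(
            "log transform requires strictly positive values; offending rows: "
            + ", ".join(f"{r.subject_id}/s{r.session}={r.value}"
                        for r in bad.itertuples())
        )
    logv = np.log(df["value"].to_numpy(float))
    sess = sorted(df["session"].unique())
    exog = np.column_stack([
        np.ones(len(df)),
        (df["session"] == sess[1]).to_numpy(float),
    ])
    if np.ptp(logv) == 0:
        mse = 0.0
    else:
        result = _fit_mixed(logv, exog, df["subject_id"].to_numpy())
        mse = float(result.scale)
    return RepeatabilityResult(endpoint=endpoint, group=group, mse=mse,
                               cv_percent=cv_from_mse(mse),
                               n_pairs=int(df["subject_id"].nunique()))


def age_correlation(values: np.ndarray, ages: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between an endpoint and age, with two-sided p.

    Requires >= 3 pairs and nonzero variance in both variables.
    """
    values = np.asarray(values, float)
    ages = np.asarray(ages, float)
    if values.shape != ages.shape or values.ndim != 1:
        raise ValueError("values and ages must be matching 1D arrays")
    if values.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(values) == 0 or np.ptp(ages) == 0:
        raise ValueError("zero variance in values or ages")
    r, p = sps.pearsonr(values, ages)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Simulation helpers (used by tests and calibration runs)

def simulate_endpoint_table(
    n_per_group: dict[str, int], group_means: dict[str, float],
    sessions: int, sd_between: float, sd_within: float, seed: int,
    endpoint: str = "ve", region: str = "total",
    session_effects: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Simulate a tidy endpoint table from the additive mixed-model truth:
    value = group mean + session effect + subject effect + within noise."""
    rng = np.random.default_rng(seed)
    rows = []
    session_effects = session_effects or {}
    for group, n in n_per_group.items():
        for i in range(n):
            sid = f"{group}{i:03d}"
            b = rng.normal(0.0, sd_between)
            for s in range(1, sessions + 1):
                val = group_means[group] + session_effects.get(s, 0.0) + b + \
                    rng.normal(0.0, sd_within)
                rows.append((sid, group, s, region, endpoint, val, "median"))
    return pd.DataFrame(rows, columns=["subject_id", "group", "session",
                                       "region", "endpoint", "value",
                                       "summary"])


def simulate_log_repeatability_table(
    n_subjects: int, true_median: float, sd_between_log: float,
    sd_within_log: float, seed: int, endpoint: str = "ktrans",
    group: str = "HV", region: str = "total",
) -> pd.DataFrame:
    """Two-session table with log-normal within-subject error of known
    log-scale sd, for CV-recovery simulations."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        sid = f"{group}{i:03d}"
        b = rng.normal(0.0, sd_between_log)
        for s in (1, 2):
            logv = np.log(true_median) + b + rng.normal(0.0, sd_within_log)
            rows.append((sid, group, s, region, endpoint, float(np.exp(logv)),
                        "median"))
    return pd.DataFrame(rows, columns=["subject_id", "group", "session",
                                       "region", "endpoint", "value",
                                       "summary"])
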