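"""Kaplan-Meier estimation, log-rank testing and biomarker
dichotomisation, implemented from first principles.

The product-limit estimator is

    S(t) = prod_{t_i <= t} (1 - d_i / n_i)

over distinct event times t_i with d_i events among n_i at risk; ties are
resolved with events preceding censorings at the same time (the standard
convention).  The two-group log-rank statistic accumulates observed minus
hypergeometric-expected events for group A over the shared event times,

    Z = sum_i (d_Ai - e_Ai),   V = sum_i v_i,   X^2 = Z^2 / V  ~  chi2(1),

with v_i = n_Ai n_Bi d_i (n_i - d_i) / (n_i^2 (n_i - 1)).  A seeded
label-permutation p-value is available as a small-sample alternative.

Biomarker splits follow the two conventions of the survival web tools this
field uses: a mean split (threshold = arithmetic mean of the covariate)
and a best-cutoff scan minimising the unadjusted log-rank p over observed
covariate values inside a quantile band.  Best-cutoff p-values are
reported unadjusted, with the selection bias this implies flagged on the
result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ContractError, DegenerateSplitError, UndefinedValueError


@dataclass(frozen=True)
class SurvivalRecord:
    """One right-censored observation: follow-up time in months, event
    flag (1 = death observed, 0 = censored) and an optional covariate
    (methylation beta in [0,1] or an expression level)."""

    subject_id: str
    time: float
    event: int
    covariate: float | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ContractError(f"non-positive time for {self.subject_id!r}")
        if self.event not in (0, 1):
            raise ContractError(f"event flag must be 0/1 for {self.subject_id!r}")


def _arrays(records: Iterable[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    recs = list(records)
    if not recs:
        raise ContractError("empty record set")
    t = np.array([r.time for r in recs], dtype=float)
    e = np.array([r.event for r in recs], dtype=int)
    return t, e


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate with at-risk/event tallies.

    Arrays are parallel over distinct event times; ``greenwood_var`` holds
    the Greenwood variance of S at each event time and ``ci_lower``/
    ``ci_upper`` the corresponding 95% bands (reported for completeness;
    nothing downstream depends on them).
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    max_followup: float
    greenwood_var: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray


def km_estimate(records: Iterable[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    t, e = _arrays(records)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n = len(t)
    # events precede censorings at equal times: at risk counts everyone
    # with observed time >= t_i
    at_risk = np.array([(t >= ti).sum() for ti in event_times], dtype=int)
    d = np.array([((t == ti) & (e == 1)).sum() for ti in event_times], dtype=int)
    frac = 1.0 - d / at_risk if len(at_risk) else np.array([])
    survival = np.cumprod(frac) if len(frac) else np.array([])
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
        gw = survival**2 * np.cumsum(terms) if len(d) else np.array([])
        gw = np.where(survival > 0, gw, np.nan)  # undefined once S hits 0
    se = np.sqrt(gw, where=np.isfinite(gw), out=np.full_like(gw, np.nan))
    lo = np.clip(survival - 1.96 * se, 0.0, 1.0)
    hi = np.clip(survival + 1.96 * se, 0.0, 1.0)
    return KMCurve(event_times, at_risk, d, survival, float(t.max()), gw, lo, hi)


@dataclass(frozen=True)
class SurvivalPoint:
    probability: float
    extrapolated: bool


def survival_at(curve: KMCurve, horizon: float = 60.0) -> SurvivalPoint:
    """Step-function value S(horizon); flagged when the horizon exceeds
    the last follow-up time."""
    if horizon < 0:
        raise ContractError("horizon must be non-negative")
    idx = np.searchsorted(curve.event_times, horizon, side="right")
    prob = 1.0 if idx == 0 else float(curve.survival[idx - 1])
    return SurvivalPoint(prob, horizon > curve.max_followup)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    observed_a: float
    expected_a: float
    permutation_p: float | None = None


def _logrank_arrays(
    tA: np.ndarray, eA: np.ndarray, tB: np.ndarray, eB: np.ndarray
) -> tuple[float, float, float, float]:
    """(chi-square statistic, p, observed A events, expected A events)."""
    t = np.concatenate([tA, tB])
    e = np.concatenate([eA, eB])
    grp = np.concatenate([np.zeros(len(tA), bool), np.ones(len(tB), bool)])
    times = np.unique(t[e == 1])
    if len(times) == 0:
        raise UndefinedValueError("no events: log-rank test undefined")
    nA = (tA[:, None] >= times[None, :]).sum(axis=0).astype(float)
    nB = (tB[:, None] >= times[None, :]).sum(axis=0).astype(float)
    dA = ((tA[:, None] == times[None, :]) & (eA[:, None] == 1)).sum(axis=0).astype(float)
    dB = ((tB[:, None] == times[None, :]) & (eB[:, None] == 1)).sum(axis=0).astype(float)
    n = nA + nB
    d = dA + dB
    expA = d * nA / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(n > 1, nA * nB * d * (n - d) / (n**2 * (n - 1)), 0.0)
    z = float((dA - expA).sum())
    v = float(var.sum())
    if v == 0.0:
        return 0.0, 1.0, float(dA.sum()), float(expA.sum())
    chi2 = z * z / v
    return chi2, float(stats.chi2.sf(chi2, df=1)), float(dA.sum()), float(expA.sum())


def logrank_test(
    group_a: Iterable[SurvivalRecord],
    group_b: Iterable[SurvivalRecord],
    n_permutations: int = 0,
    seed: int | None = None,
) -> LogRankResult:
    """Two-group log-rank test (1 df) with optional seeded permutation p.

    The permutation p shuffles group labels ``n_permutations`` times and
    reports the fraction of statistics >= observed (with the +1
    small-sample correction)."""
    tA, eA = _arrays(group_a)
    tB, eB = _arrays(group_b)
    chi2, p, obs, exp = _logrank_arrays(tA, eA, tB, eB)
    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        t = np.concatenate([tA, tB])
        e = np.concatenate([eA, eB])
        nA = len(tA)
        hits = 0
        for _ in range(n_permutations):
            idx = rng.permutation(len(t))
            a = idx[:nA]
            b = idx[nA:]
            stat, _, _, _ = _logrank_arrays(t[a], e[a], t[b], e[b])
            if stat >= chi2 - 1e-12:
                hits += 1
        perm_p = (hits + 1) / (n_permutations + 1)
    return LogRankResult(chi2, p, obs, exp, perm_p)


@dataclass(frozen=True)
class CutoffResult:
    """A biomarker dichotomisation with its log-rank comparison.

    ``threshold_percent`` restates the threshold on the percent scale used
    for methylation values (0.175 -> 17.5).  ``p_value`` from a
    best-cutoff scan is unadjusted for the multiplicity of thresholds
    tested (``n_thresholds_tested``); ``p_unadjusted`` stays True to flag
    that selection bias."""

    threshold: float
    n_low: int
    n_high: int
    statistic: float
    p_value: float
    method: str  # mean_split | best_cutoff
    n_thresholds_tested: int = 1
    p_unadjusted: bool = True

    @property
    def threshold_percent(self) -> float:
        return 100.0 * self.threshold


def _covariates(records: Sequence[SurvivalRecord]) -> np.ndarray:
    if any(r.covariate is None for r in records):
        raise ContractError("all records need a covariate for splitting")
    return np.array([r.covariate for r in records], dtype=float)


def _split_test(
    records: Sequence[SurvivalRecord], threshold: float
) -> tuple[int, int, float, float]:
    low = [r for r in records if r.covariate < threshold]
    high = [r for r in records if r.covariate >= threshold]
    if not low or not high:
        raise DegenerateSplitError(f"threshold {threshold} leaves an empty group")
    res = logrank_test(low, high)
    return len(low), len(high), res.statistic, res.p_value


def split_by_mean(records: Sequence[SurvivalRecord]) -> CutoffResult:
    """Dichotomise at the arithmetic mean of the covariate
    (groups {< mean, >= mean}) and run the log-rank comparison."""
    cov = _covariates(records)
    if np.ptp(cov) == 0:
        raise DegenerateSplitError("all covariate values identical")
    threshold = float(cov.mean())
    n_low, n_high, stat, p = _split_test(records, threshold)
    return CutoffResult(threshold, n_low, n_high, stat, p, "mean_split")


def best_cutoff_scan(
    records: Sequence[SurvivalRecord],
    lower_q: float = 0.1,
    upper_q: float = 0.9,
) -> CutoffResult:
    """Scan observed covariate values in the [lower_q, upper_q] quantile
    band and return the threshold minimising the log-rank p.

    The returned p is the minimum over all thresholds tested and is NOT
    adjusted for that selection; treat it as descriptive.  Ties on p are
    broken toward the smaller threshold for determinism.
    """
    if len(records) < 20:
        warnings.warn(
            "best-cutoff scan on fewer than 20 records is unstable", stacklevel=2
        )
    cov = _covariates(records)
    if np.ptp(cov) == 0:
        raise DegenerateSplitError("all covariate values identical")
    lo, hi = np.quantile(cov, [lower_q, upper_q])
    candidates = [v for v in np.unique(cov) if lo <= v <= hi]
    best: CutoffResult | None = None
    tested = 0
    for thr in candidates:
        try:
            n_low, n_high, stat, p = _split_test(records, float(thr))
        except (DegenerateSplitError, UndefinedValueError):
            continue
        tested += 1
        if best is None or p < best.p_value:
            best = CutoffResult(float(thr), n_low, n_high, stat, p, "best_cutoff")
    if best is None:
        raise DegenerateSplitError("no valid threshold in the quantile band")
    return CutoffResult(
        best.threshold, best.n_low, best.n_high, best.statistic, best.p_value,
        "best_cutoff", n_thresholds_tested=tested,
    )


def records_from_frame(df, time_col="time", event_col="event", covariate_col=None,
                       id_col=None) -> list[SurvivalRecord]:
    """Build records from a cohort table (TSV read into a DataFrame)."""
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        out.append(
            SurvivalRecord(
                str(d[id_col]) if id_col else f"subject_{i + 1}",
                float(d[time_col]),
                int(d[event_col]),
                float(d[covariate_col]) if covariate_col else None,
            )
        )
    return out
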