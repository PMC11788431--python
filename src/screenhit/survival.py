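"""Expression-based survival stratification and the scan-method cutpoint.

Patient cohorts carry (time, event, expression) triples: right-censored
follow-up time, an event indicator (1 = death observed), and a continuous
expression value for the gene of interest. Samples are split into low/high
expression groups by one of five fixed rules — median, average (mean),
first quartile, last quartile, or first-vs-last quartile (middle half
excluded) — or by the *scan method*: every admissible cutoff along the
ordered expression values is tried and the one maximizing the log-rank
statistic is chosen ("maximally selected" cutpoint).

The log-rank test is the Mantel-Haenszel form: at each distinct event time
the observed minus expected events in group A are accumulated
(``U = sum d_Ai - E_i``) together with the hypergeometric variances
(``V``); the statistic ``U^2 / V`` is chi-square with 1 df under the null.
The scan method's nominal p-value ignores the multiplicity of cutoffs and
is therefore anti-conservative; ``n_scanned`` is reported alongside to
make that visible.

Group assignment at a threshold is deterministic: values equal to the
threshold go to the low group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import DegenerateSplitError, InputError

SPLIT_METHODS = (
    "median",
    "average",
    "first_quartile",
    "last_quartile",
    "first_vs_last_quartile",
    "scan",
)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit (Kaplan-Meier) estimate of the survival function."""

    event_times: np.ndarray  # distinct times with >=1 event, ascending
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); step function, right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p: float
    defined: bool = True


@dataclass(frozen=True)
class CutpointScan:
    """Result of the scan method: all candidate cutoffs and the best one."""

    cutoffs: np.ndarray
    statistics: np.ndarray
    p_values: np.ndarray
    best_cutoff: float
    best_statistic: float
    best_p: float
    n_scanned: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "statistic": self.statistics,
                "p": self.p_values,
            }
        )


def _check_times(times: np.ndarray) -> None:
    if (times < 0).any():
        raise InputError("survival times must be non-negative")
    if not np.isfinite(times).all():
        raise InputError("survival times must be finite")


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimator with right censoring.

    At a tied time, events are counted before censorings (the censored
    subjects remain in the risk set for that time's factor).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise InputError("need at least one record")
    if times.shape != events.shape:
        raise InputError("times and events must have equal length")
    _check_times(times)

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = times.size
    uniq, start = np.unique(times, return_index=True)
    event_times, surv, at_risk, n_ev = [], [], [], []
    s = 1.0
    for t, i0 in zip(uniq, start):
        mask = times == t
        d = int(events[mask].sum())
        if d == 0:
            continue
        r = n - i0  # everyone with time >= t is at risk
        s *= 1.0 - d / r
        event_times.append(t)
        surv.append(s)
        at_risk.append(r)
        n_ev.append(d)
    return KMCurve(
        event_times=np.array(event_times),
        survival=np.array(surv),
        n_at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(n_ev, dtype=int),
    )


def log_rank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group Mantel-Haenszel log-rank test (chi-square, 1 df).

    Tied event times use the grouped hypergeometric treatment; censored
    observations at an event time stay in the risk set for that time.
    Returns ``defined=False`` (statistic NaN, p NaN) when the variance is
    zero — no events, or degenerate risk sets.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise InputError("both groups must be non-empty")
    _check_times(ta)
    _check_times(tb)

    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    u = 0.0
    v = 0.0
    for t in event_times:
        na = int((ta >= t).sum())
        nb = int((tb >= t).sum())
        da = int((ea & (ta == t)).sum())
        db = int((eb & (tb == t)).sum())
        n = na + nb
        d = da + db
        if n < 2 or d == 0:
            continue
        u += da - d * na / n
        v += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if v <= 0.0:
        return LogRankResult(float("nan"), float("nan"), defined=False)
    stat = u * u / v
    return LogRankResult(stat, float(chi2.sf(stat, df=1)), defined=True)


def split_by_expression(expression, method: str) -> np.ndarray:
    """Label samples ``low``/``high`` (or ``excluded``) by one of the five
    fixed grouping rules. Values equal to the threshold go to ``low``."""
    expr = np.asarray(expression, dtype=float)
    if not np.isfinite(expr).all():
        raise InputError("expression values must be finite")
    if method not in SPLIT_METHODS or method == "scan":
        raise InputError(
            f"method must be one of {SPLIT_METHODS[:-1]} (scan has its own entry point)"
        )
    if np.ptp(expr) == 0:
        raise DegenerateSplitError("all expression values are identical")
    if method in ("first_quartile", "last_quartile", "first_vs_last_quartile"):
        if expr.size < 4:
            raise InputError("quartile methods need at least 4 samples")

    labels = np.full(expr.size, "high", dtype=object)
    if method == "median":
        thr = float(np.median(expr))
        labels[expr <= thr] = "low"
    elif method == "average":
        thr = float(np.mean(expr))
        labels[expr <= thr] = "low"
    elif method == "first_quartile":
        thr = float(np.quantile(expr, 0.25))
        labels[expr <= thr] = "low"
    elif method == "last_quartile":
        thr = float(np.quantile(expr, 0.75))
        labels[expr <= thr] = "low"
    else:  # first_vs_last_quartile
        q1 = float(np.quantile(expr, 0.25))
        q3 = float(np.quantile(expr, 0.75))
        labels[:] = "excluded"
        labels[expr <= q1] = "low"
        labels[expr > q3] = "high"
    kept = labels != "excluded"
    if len(set(labels[kept])) < 2:
        raise DegenerateSplitError(f"{method} split produced a single group")
    return labels


def _min_group_size(n: int, min_group_fraction: float) -> int:
    return max(3, math.ceil(min_group_fraction * n))


def scan_cutpoint(
    times,
    events,
    expression,
    min_group_fraction: float = 0.1,
) -> CutpointScan:
    """Maximally selected log-rank cutpoint over expression ("scan method").

    Candidate cutoffs are the midpoints between consecutive distinct sorted
    expression values whose induced low (<= cutoff) and high groups both
    contain at least ``max(3, ceil(min_group_fraction * n))`` samples. The
    returned cutoff maximizes the log-rank statistic; ties are broken
    toward the more balanced split, then toward the lower cutoff. The
    nominal p-value is uncorrected for the multiplicity of cutoffs.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    expr = np.asarray(expression, dtype=float)
    if not (times.size == events.size == expr.size):
        raise InputError("times, events, expression must have equal length")
    _check_times(times)
    if not np.isfinite(expr).all():
        raise InputError("expression values must be finite")

    n = expr.size
    min_size = _min_group_size(n, min_group_fraction)
    distinct = np.unique(expr)
    if distinct.size < 2:
        raise DegenerateSplitError("all expression values are identical")
    mids = (distinct[:-1] + distinct[1:]) / 2.0

    cutoffs, stats, pvals, balances = [], [], [], []
    for cut in mids:
        low = expr <= cut
        n_low = int(low.sum())
        if n_low < min_size or n - n_low < min_size:
            continue
        res = log_rank_test(times[low], events[low], times[~low], events[~low])
        if not res.defined:
            continue
        cutoffs.append(float(cut))
        stats.append(res.statistic)
        pvals.append(res.p)
        balances.append(abs(n - 2 * n_low))
    if not cutoffs:
        raise DegenerateSplitError("no admissible cutoff under the size constraint")

    best = 0
    for i in range(1, len(cutoffs)):
        if stats[i] > stats[best]:
            best = i
        elif stats[i] == stats[best] and balances[i] < balances[best]:
            best = i  # lower cutoff wins remaining ties by iteration order
    return CutpointScan(
        cutoffs=np.array(cutoffs),
        statistics=np.array(stats),
        p_values=np.array(pvals),
        best_cutoff=cutoffs[best],
        best_statistic=stats[best],
        best_p=pvals[best],
        n_scanned=len(cutoffs),
    )


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Load a delimited survival table (sample_id, time, event, expression).

    Fixture loader emulating the column structure of public expression/
    survival series; delimiter sniffed among comma/tab.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "time", "event", "expression"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"survival table missing columns: {sorted(missing)}")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int).astype(bool)
    df["expression"] = df["expression"].astype(float)
    return df


def simulate_survival_cohort(
    n: int,
    effect: float = 0.0,
    censor_rate: float = 0.3,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Synthetic cohort: exponential survival with a log-linear expression
    effect on the hazard and uniform administrative censoring.

    ``effect`` is the log hazard ratio per standard deviation of
    expression; 0 gives the null (expression independent of survival).
    """
    if n < 2:
        raise InputError("need at least two samples")
    rng = np.random.default_rng(seed)
    expr = rng.normal(0.0, 1.0, size=n)
    hazard = np.exp(effect * expr)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0, np.quantile(t_event, 1 - censor_rate) * 2, size=n)
    times = np.minimum(t_event, t_censor)
    events = t_event <= t_censor
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n)],
            "time": times,
            "event": events,
            "expression": expr,
        }
    )
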