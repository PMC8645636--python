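"""Survival analysis for expression-dichotomized cohorts.

Implements the product-limit (Kaplan-Meier) estimator, the Mantel-Haenszel
log-rank test, the Gehan-Breslow-Wilcoxon weighted variant, a univariate
proportional-hazards hazard-ratio estimate for the high- vs low-expression
indicator (Newton iteration on the partial likelihood, Breslow tie
handling), and the best-cutoff scan that dichotomizes a continuous marker
at every observed value between the lower and upper quartiles, picking the
cutoff minimizing the log-rank p-value.

Orientation convention throughout: the second group passed to a two-group
comparison (or the expression >= cutoff group) is the "high" group, and the
hazard ratio is high-vs-low, so HR < 1 means high expression is protective.

The scanned minimum p-value is anticonservative (a minimum over many
correlated tests); a permutation-corrected min-p is available via
``permutation_corrected_p``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

log = logging.getLogger(__name__)

Z975 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class SurvivalCohort:
    """Per-patient time (months), event indicator, expression, optional sex."""

    data: pd.DataFrame  # columns: patient, time, event, expression[, sex]

    def __post_init__(self) -> None:
        req = ["patient", "time", "event", "expression"]
        missing = [c for c in req if c not in self.data.columns]
        if missing:
            raise ValueError(f"survival table missing columns {missing}")
        if (self.data["time"] < 0).any():
            raise ValueError("negative survival times")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (event)")

    def __len__(self) -> int:
        return len(self.data)

    def split(self, cutoff: float) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(low, high) at expression < cutoff vs >= cutoff."""
        hi = self.data["expression"] >= cutoff
        return self.data[~hi], self.data[hi]


def read_survival_table(path: str | Path) -> SurvivalCohort:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    return SurvivalCohort(data=df)


@dataclass
class KMCurve:
    times: np.ndarray      # distinct event times, increasing
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray
    median: float          # smallest event time with S <= 0.5; nan if never

    def at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event) -> KMCurve:
    """Product-limit estimator; records censored at an event time stay at risk
    for that time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty group")
    if event.sum() == 0 and np.all(time == 0):
        raise ValueError("degenerate curve: all times zero with no events")
    ts = np.unique(time[event == 1])
    sorted_all = np.sort(time)
    n_at_risk = time.size - np.searchsorted(sorted_all, ts, side="left")
    sorted_ev = np.sort(time[event == 1])
    d = (np.searchsorted(sorted_ev, ts, side="right")
         - np.searchsorted(sorted_ev, ts, side="left"))
    surv = np.cumprod(1.0 - d / n_at_risk)
    below = np.nonzero(surv <= 0.5 + 1e-12)[0]
    median = float(ts[below[0]]) if below.size else float("nan")
    return KMCurve(times=ts, survival=surv, at_risk=n_at_risk, events=d,
                   median=median)


@dataclass
class GroupComparison:
    chi2: float
    p: float
    hr: float           # hazard of group b ("high") relative to group a ("low")
    ci_low: float
    ci_high: float
    method: str         # "logrank" or "gbw"
    n_a: int = 0
    n_b: int = 0
    degenerate: bool = False  # monotone likelihood (a group with no events)


def _risk_table(ta, ea, tb, eb):
    """Per pooled distinct event time: n1, n2 at risk and d1, d2 events."""
    ta = np.asarray(ta, float); ea = np.asarray(ea, int)
    tb = np.asarray(tb, float); eb = np.asarray(eb, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in pooled data")
    ts = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    sa, sb = np.sort(ta), np.sort(tb)
    n1 = ta.size - np.searchsorted(sa, ts, side="left")
    n2 = tb.size - np.searchsorted(sb, ts, side="left")
    eva, evb = np.sort(ta[ea == 1]), np.sort(tb[eb == 1])
    d1 = (np.searchsorted(eva, ts, "right") - np.searchsorted(eva, ts, "left"))
    d2 = (np.searchsorted(evb, ts, "right") - np.searchsorted(evb, ts, "left"))
    return ts, n1, n2, d1, d2


def _weighted_logrank_stat(ta, ea, tb, eb, gbw: bool) -> tuple[float, float]:
    ts, n1, n2, d1, d2 = _risk_table(ta, ea, tb, eb)
    n = n1 + n2
    d = d1 + d2
    w = n.astype(float) if gbw else np.ones_like(n, dtype=float)
    u = float(np.sum(w * (d1 - d * n1 / n)))
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = np.where(
            n > 1, d * (n1 / n) * (n2 / n) * (n - d) / (n - 1), 0.0
        )
    v = float(np.sum(w * w * v_terms))
    if v <= 0.0:
        return 0.0, 1.0
    chi2 = u * u / v
    return chi2, float(chi2_dist.sf(chi2, 1))


def _cox_binary(time, event, z, max_iter: int = 50, tol: float = 1e-12):
    """Univariate PH fit for a binary indicator via Newton on the Breslow
    partial likelihood. Returns (beta, se, degenerate)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    z = np.asarray(z, int)
    d1_tot = int(event[z == 1].sum())
    d0_tot = int(event[z == 0].sum())
    if d1_tot == 0 or d0_tot == 0:
        # monotone partial likelihood: HR estimate on the boundary
        beta = -math.inf if d1_tot == 0 else math.inf
        return beta, math.nan, True

    ts = np.unique(time[event == 1])
    s0, s1 = np.sort(time[z == 0]), np.sort(time[z == 1])
    n0 = s0.size - np.searchsorted(s0, ts, side="left")
    n1 = s1.size - np.searchsorted(s1, ts, side="left")
    ev1 = np.sort(time[(event == 1) & (z == 1)])
    s1j = (np.searchsorted(ev1, ts, "right") - np.searchsorted(ev1, ts, "left"))
    ev_all = np.sort(time[event == 1])
    dj = (np.searchsorted(ev_all, ts, "right") - np.searchsorted(ev_all, ts, "left"))

    beta = 0.0
    info = 0.0
    for _ in range(max_iter):
        eb = math.exp(min(max(beta, -30.0), 30.0))
        denom = n0 + n1 * eb
        frac = n1 * eb / denom
        score = float(np.sum(s1j - dj * frac))
        info = float(np.sum(dj * frac * (1.0 - frac)))
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(step) < tol:
            break
    if abs(beta) >= 30.0 or info <= 0:
        # perfect separation: partial likelihood is monotone in beta
        return (math.inf if beta > 0 else -math.inf), math.nan, True
    se = 1.0 / math.sqrt(info)
    return beta, se, False


def _compare(ta, ea, tb, eb, method: str) -> GroupComparison:
    chi2, p = _weighted_logrank_stat(ta, ea, tb, eb, gbw=(method == "gbw"))
    t = np.concatenate([np.asarray(ta, float), np.asarray(tb, float)])
    e = np.concatenate([np.asarray(ea, int), np.asarray(eb, int)])
    z = np.concatenate([np.zeros(len(ta), int), np.ones(len(tb), int)])
    beta, se, degen = _cox_binary(t, e, z)
    if degen:
        hr = 0.0 if beta < 0 else math.inf
        ci_low, ci_high = math.nan, math.nan
        log.warning("degenerate comparison: HR on boundary (%g), CI undefined", hr)
    else:
        hr = math.exp(beta)
        ci_low = math.exp(beta - Z975 * se)
        ci_high = math.exp(beta + Z975 * se)
    return GroupComparison(chi2=chi2, p=p, hr=hr, ci_low=ci_low, ci_high=ci_high,
                           method=method, n_a=len(ta), n_b=len(tb),
                           degenerate=degen)


def logrank(time_a, event_a, time_b, event_b) -> GroupComparison:
    """Mantel-Haenszel log-rank test; HR is for group b vs group a."""
    return _compare(time_a, event_a, time_b, event_b, "logrank")


def gbw_test(time_a, event_a, time_b, event_b) -> GroupComparison:
    """Gehan-Breslow-Wilcoxon test: log-rank weighted by the number at risk,
    emphasizing early differences."""
    return _compare(time_a, event_a, time_b, event_b, "gbw")


def hazard_ratio(time_a, event_a, time_b, event_b) -> GroupComparison:
    """Univariate PH hazard ratio (b vs a) with Wald 95% CI and log-rank p."""
    return _compare(time_a, event_a, time_b, event_b, "logrank")


@dataclass
class CutoffScanResult:
    candidate_cutoffs: np.ndarray
    p_by_cutoff: np.ndarray          # nan where a candidate was skipped
    best_cutoff: float
    best_p: float
    comparison: GroupComparison      # at the best cutoff, high vs low
    n_low: int
    n_high: int
    km_low: KMCurve = field(repr=False, default=None)
    km_high: KMCurve = field(repr=False, default=None)
    n_skipped: int = 0


def best_cutoff_scan(cohort: SurvivalCohort, test: str = "logrank") -> CutoffScanResult:
    """Scan every distinct observed expression value between the lower and
    upper quartile as a dichotomization cutoff; keep the one minimizing the
    two-group p-value (ties broken toward the smaller cutoff).

    Candidates leaving a group empty (or with no pooled events) are skipped
    and logged. The reported p is the raw minimum — anticonservative by
    construction.
    """
    df = cohort.data
    if len(df) < 8:
        raise ValueError("best-cutoff scan needs at least 8 patients")
    expr = df["expression"].to_numpy(dtype=float)
    if np.all(expr == expr[0]):
        raise ValueError("expression is constant; no cutoff exists")
    q1, q3 = np.quantile(expr, [0.25, 0.75])  # linear interpolation
    values = np.unique(expr)
    candidates = values[(values >= q1) & (values <= q3)]
    if candidates.size == 0:
        candidates = np.array([np.median(expr)])

    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    pvals = np.full(candidates.size, np.nan)
    n_skipped = 0
    for i, v in enumerate(candidates):
        hi = expr >= v
        if hi.sum() == 0 or hi.sum() == hi.size:
            n_skipped += 1
            continue
        try:
            chi2, p = _weighted_logrank_stat(
                time[~hi], event[~hi], time[hi], event[hi], gbw=(test == "gbw")
            )
        except ValueError:
            n_skipped += 1
            continue
        pvals[i] = p
    if n_skipped:
        log.info("cutoff scan: skipped %d degenerate candidates", n_skipped)
    if np.all(np.isnan(pvals)):
        raise ValueError("no valid cutoff candidate")

    best_idx = int(np.nanargmin(pvals))  # first minimum = smallest cutoff
    best = float(candidates[best_idx])
    assert q1 <= best <= q3 or candidates.size == 1
    low, high = cohort.split(best)
    comparison = _compare(
        low["time"], low["event"], high["time"], high["event"], test
    )
    return CutoffScanResult(
        candidate_cutoffs=candidates,
        p_by_cutoff=pvals,
        best_cutoff=best,
        best_p=float(pvals[best_idx]),
        comparison=comparison,
        n_low=len(low),
        n_high=len(high),
        km_low=km_estimate(low["time"], low["event"]),
        km_high=km_estimate(high["time"], high["event"]),
        n_skipped=n_skipped,
    )


def permutation_corrected_p(
    cohort: SurvivalCohort, n_perm: int = 200, seed: int = 0, test: str = "logrank"
) -> tuple[float, float]:
    """Min-p permutation correction for the cutoff scan.

    Expression values are permuted against (time, event); the corrected p is
    the fraction of permutations whose scanned minimum p is at most the
    observed one (add-one estimator). Returns (raw best_p, corrected p).
    """
    obs = best_cutoff_scan(cohort, test=test)
    rng = np.random.default_rng(seed)
    expr = cohort.data["expression"].to_numpy()
    hits = 0
    for _ in range(n_perm):
        perm = cohort.data.copy()
        perm["expression"] = rng.permutation(expr)
        try:
            res = best_cutoff_scan(SurvivalCohort(perm), test=test)
        except ValueError:
            continue
        if res.best_p <= obs.best_p:
            hits += 1
    return obs.best_p, (1 + hits) / (n_perm + 1)


def write_km_curve(curve: KMCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("time\tsurvival\tat_risk\tevents\n")
        for t, s, n, d in zip(curve.times, curve.survival, curve.at_risk, curve.events):
            fh.write(f"{t:.10g}\t{s:.10g}\t{int(n)}\t{int(d)}\n")


def plot_km(curves: dict[str, KMCurve], path: str | Path, title: str = "") -> None:
    """Basic step-function KM plot (matplotlib imported lazily)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        t = np.concatenate([[0.0], c.times])
        s = np.concatenate([[1.0], c.survival])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
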