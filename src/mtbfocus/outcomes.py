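"""Outcome evaluation: PFS ratio, benefit categories, survival statistics.

The central outcome statistic is the PFS ratio (PFSr): time to progression on
the therapy initiated after molecular tumor board (MTB) review (PFS2) divided
by time to progression on the last prior systemic therapy (PFS1). A patient
is their own control; PFSr > 1 indicates longer disease control on the new
therapy. Benefit is additionally classified against absolute
time-to-progression cutoffs: major benefit at >= 6 months, minor benefit at
3-6 months (or clinical response with < 3 months follow-up), and no benefit
for progression/death before 3 months or a permanent toxicity stop.

Group comparisons use the Kaplan-Meier product-limit estimator with the
two-group log-rank test for PFS, and the Mann-Whitney rank-sum test for PFS
ratios. The log-rank tabulation (observed vs expected events with
hypergeometric variance at each distinct event time) is computed in-package
so the per-time terms are inspectable; the Mann-Whitney implementation uses
exact permutation enumeration when both samples have n <= 8 and a
tie-corrected, continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

ARMS = ("matched", "other")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 at one decimal -> 0.1, never banker's)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(k: int, n: int, decimals: int = 1) -> float | None:
    """k/n as a half-up-rounded percentage; None (undefined) when n == 0."""
    if n == 0:
        return None
    return round_half_up(100.0 * k / n, decimals)


@dataclass
class PatientOutcome:
    """One patient's post-MTB outcome record.

    ``pfs2`` is the observed time on the post-MTB therapy (progression/death
    time when ``event`` is True, censoring time otherwise), in months.
    ``pfs1`` may be None when no prior-therapy progression interval exists
    (the Table-style "n/a" rows).
    """

    patient_id: str
    pfs1: float | None
    pfs2: float
    event: bool
    follow_up: float
    arm: str = "matched"
    label_status: str = "off"
    clinical_response: bool = False
    toxicity_stop: bool = False

    def __post_init__(self) -> None:
        if self.pfs2 < 0 or self.follow_up < 0:
            raise ValueError("times must be non-negative")
        if self.pfs1 is not None and self.pfs1 < 0:
            raise ValueError("PFS1 must be non-negative")
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")


@dataclass(frozen=True)
class PfsRatio:
    """Raw PFS2/PFS1 ratio and its one-decimal report value."""

    raw: float | None
    report: float | None

    @property
    def defined(self) -> bool:
        return self.raw is not None

    def __str__(self) -> str:
        return "n/a" if self.report is None else f"{self.report:.1f}"


def pfs_ratio(pfs2: float, pfs1: float | None) -> PfsRatio:
    """PFS2/PFS1 with half-up one-decimal reporting; undefined for PFS1 0/missing."""
    if pfs2 < 0 or (pfs1 is not None and pfs1 < 0):
        raise ValueError("PFS times must be non-negative")
    if pfs1 is None or pfs1 == 0 or (isinstance(pfs1, float) and math.isnan(pfs1)):
        return PfsRatio(None, None)
    raw = pfs2 / pfs1
    return PfsRatio(raw, round_half_up(raw, 1))


@dataclass(frozen=True)
class BenefitCategory:
    category: str  # none | minor | major
    rule: str


def classify_benefit(record: PatientOutcome, minor_cutoff: float = 3.0,
                     major_cutoff: float = 6.0) -> BenefitCategory:
    """Classify clinical benefit from time to progression on therapy.

    Progression/death before the 3-month cutoff or a permanent toxicity stop
    means no benefit; >= 6 months on therapy (progressed or not) is major
    benefit; 3-6 months is minor, as is clinical response with under 3 months
    of follow-up. Both cutoffs are inclusive. A censored record under 3
    months without clinical response is not evaluable and raises.
    """
    if record.toxicity_stop and record.clinical_response:
        raise ValueError(f"{record.patient_id}: toxicity stop and ongoing "
                         "clinical response are inconsistent flags")
    if record.toxicity_stop:
        return BenefitCategory("none", "permanent toxicity stop")
    if record.event and record.pfs2 < minor_cutoff:
        return BenefitCategory("none", f"progressed/died before {minor_cutoff:g} months")
    if record.pfs2 >= major_cutoff:
        return BenefitCategory("major", f">= {major_cutoff:g} months to progression")
    if record.pfs2 >= minor_cutoff:
        return BenefitCategory("minor", f"{minor_cutoff:g}-{major_cutoff:g} months to progression")
    if record.clinical_response:
        return BenefitCategory("minor", f"clinical response with < {minor_cutoff:g} months follow-up")
    raise ValueError(f"{record.patient_id}: censored before {minor_cutoff:g} months "
                     "without clinical response; not evaluable")


# ---------------------------------------------------------------------------
# survival statistics


@dataclass
class KmEstimate:
    """Product-limit estimate: step function and median survival."""

    times: np.ndarray       # distinct event times (step locations)
    survival: np.ndarray    # S(t) just after each step
    median: float | None    # earliest time with S(t) <= 0.5; None if never

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KmEstimate:
    """Kaplan-Meier product-limit estimator (via lifelines)."""
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter().fit(times, events)
    sf = kmf.survival_function_
    step_times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KmEstimate(times=step_times, survival=surv, median=median)


def logrank_table(a: tuple, b: tuple) -> pd.DataFrame:
    """Per-event-time log-rank tabulation for two groups.

    Columns per distinct event time: at-risk counts (n, n_a), event counts
    (d, d_a), expected events in group a (e_a = d * n_a / n) and the
    hypergeometric variance of d_a.
    """
    ta, ea = np.asarray(a[0], float), np.asarray(a[1], bool)
    tb, eb = np.asarray(b[0], float), np.asarray(b[1], bool)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    group_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    rows = []
    for t in np.unique(all_t[all_e]):
        at_risk = all_t >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & group_a).sum())
        dying = at_risk & all_e & (all_t == t)
        d = int(dying.sum())
        d_a = int((dying & group_a).sum())
        e_a = d * n_a / n
        var = (d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)) if n > 1 else 0.0
        rows.append({"time": t, "n": n, "n_a": n_a, "d": d, "d_a": d_a,
                     "e_a": e_a, "var": var})
    return pd.DataFrame(rows, columns=["time", "n", "n_a", "d", "d_a", "e_a", "var"])


@dataclass(frozen=True)
class LogrankResult:
    statistic: float | None  # chi-square, 1 df; None when undefined
    p_value: float | None
    o_minus_e: float | None
    variance: float | None

    @property
    def defined(self) -> bool:
        return self.statistic is not None


def logrank_test(a: tuple, b: tuple) -> LogrankResult:
    """Two-group log-rank test; each group is (times, event_flags).

    The statistic is (sum(O-E))^2 / sum(V) over distinct event times, with p
    from the chi-square distribution with 1 df. With no events in either
    group the statistic is undefined (NA result).
    """
    if len(a[0]) == 0 or len(b[0]) == 0:
        raise ValueError("both groups must be non-empty")
    table = logrank_table(a, b)
    if table.empty:
        return LogrankResult(None, None, None, None)
    o_minus_e = float((table["d_a"] - table["e_a"]).sum())
    variance = float(table["var"].sum())
    if variance == 0:
        return LogrankResult(None, None, o_minus_e, 0.0)
    chi2 = o_minus_e**2 / variance
    return LogrankResult(chi2, float(stats.chi2.sf(chi2, df=1)), o_minus_e, variance)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample a: #(a_i > b_j) + 0.5 per tied pair."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


@dataclass(frozen=True)
class RankSumResult:
    u: float
    p_value: float
    method: str  # exact | normal


def ranksum_test(a, b, exact_max_n: int = 8) -> RankSumResult:
    """Mann-Whitney rank-sum test on two samples of ratios.

    U counts pairs with a_i > b_j plus half-ties. With both n <= 8 the
    two-sided p-value is computed by exhaustive permutation enumeration
    (tie-safe); otherwise by the normal approximation with tie-corrected
    variance and a 0.5 continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    n1, n2 = a.size, b.size

    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = np.concatenate([a, b])
        idx = range(n1 + n2)
        us = []
        for combo in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            us.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        eps = 1e-9
        lo = np.mean(us <= u + eps)
        hi = np.mean(us >= u - eps)
        p = min(1.0, 2.0 * min(lo, hi))
        return RankSumResult(u, float(p), "exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return RankSumResult(u, 1.0, "normal")
    cc = 0.5 if u != mu else 0.0
    z = (abs(u - mu) - cc) / math.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(z)
    return RankSumResult(u, float(min(1.0, p)), "normal")


# ---------------------------------------------------------------------------
# cohort summaries


def cohort_summary(records: pd.DataFrame, categorical: list[str] | None = None,
                   numeric: list[str] | None = None,
                   denominator: int | None = None) -> dict:
    """Counts + half-up one-decimal percentages per category; median/range
    for numeric fields.

    ``denominator`` overrides the percentage denominator (e.g. a full-cohort
    size when summarizing a subgroup); default is the table length. An empty
    table yields zero counts and None percentages.
    """
    n = len(records)
    denom = n if denominator is None else denominator
    out: dict = {"n": n, "denominator": denom, "fields": {}}
    for col in categorical or []:
        counts = records[col].value_counts().to_dict() if n else {}
        out["fields"][col] = {
            str(cat): {"count": int(c), "pct": percentage(int(c), denom)}
            for cat, c in sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
        }
    for col in numeric or []:
        vals = records[col].dropna() if n else pd.Series(dtype=float)
        out["fields"][col] = {
            "median": float(vals.median()) if len(vals) else None,
            "min": float(vals.min()) if len(vals) else None,
            "max": float(vals.max()) if len(vals) else None,
        }
    return out


def benefit_table(records: list[PatientOutcome]) -> dict:
    """Benefit-category proportions over evaluable patients."""
    cats = [classify_benefit(r).category for r in records]
    n = len(cats)
    return {
        cat: {"count": cats.count(cat), "pct": percentage(cats.count(cat), n)}
        for cat in ("none", "minor", "major")
    }
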