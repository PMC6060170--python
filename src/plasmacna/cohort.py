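"""Cohort-level summaries: detection tables, rate tests, survival analysis.

Detection counts and rates are tabulated per cancer type and FIGO stage
group (I–II "early", III–IV "advanced"), rates compared with Fisher's exact
test (chi-square available as an option), continuous quantities with the
Mann–Whitney U test, and progression-free / overall survival compared
between CNA-positive and CNA-negative patients with Kaplan–Meier curves and
the log-rank test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortRecord",
    "SurvivalCurve",
    "stage_group",
    "detection_table",
    "pooled_stage_rates",
    "compare_rates",
    "mann_whitney_u",
    "km_curve",
    "logrank_test",
    "plot_km",
]

CANCER_TYPES = ("ovarian", "cervical", "endometrial")


def stage_group(figo_stage: str) -> str:
    """FIGO I–II -> 'early', III–IV -> 'advanced'."""
    if figo_stage in ("I", "II"):
        return "early"
    if figo_stage in ("III", "IV"):
        return "advanced"
    raise ValueError(f"unknown FIGO stage '{figo_stage}'")


@dataclass
class CohortRecord:
    """One patient's type, stage, CNA burden and follow-up."""

    sample_id: str
    cancer_type: str
    figo_stage: str
    pfs_months: float
    pfs_event: int
    os_months: float
    os_event: int
    cna_positive: bool = False
    total_cna_mb: float = 0.0

    def __post_init__(self) -> None:
        if self.cancer_type not in CANCER_TYPES:
            raise ValueError(f"unknown cancer_type '{self.cancer_type}'")
        if self.pfs_months < 0 or self.os_months < 0:
            raise ValueError("survival times must be >= 0")
        if self.pfs_event not in (0, 1) or self.os_event not in (0, 1):
            raise ValueError("event flags must be 0/1")
        stage_group(self.figo_stage)  # validates

    @property
    def stage_group(self) -> str:
        return stage_group(self.figo_stage)


def detection_table(records: list[CohortRecord]) -> pd.DataFrame:
    """Per (cancer_type, stage_group): n, detected, rate %, CNA-size summary.

    Rates are 100*detected/n rounded half-up to one decimal as in clinical
    tables; size medians/ranges are over detected patients only and NaN for
    groups with none.
    """
    if not records:
        raise ValueError("no cohort records")
    rows = []
    for ctype, grp in itertools.product(CANCER_TYPES, ("early", "advanced")):
        sub = [r for r in records if r.cancer_type == ctype and r.stage_group == grp]
        if not sub:
            continue
        det = [r for r in sub if r.cna_positive]
        sizes = [r.total_cna_mb for r in det]
        rate = _round_half_up(100.0 * len(det) / len(sub), 1)
        rows.append({
            "cancer_type": ctype,
            "stage_group": grp,
            "n_patients": len(sub),
            "n_detected": len(det),
            "rate_pct": rate,
            "median_cna_mb": float(np.median(sizes)) if sizes else float("nan"),
            "min_cna_mb": float(min(sizes)) if sizes else float("nan"),
            "max_cna_mb": float(max(sizes)) if sizes else float("nan"),
        })
    return pd.DataFrame(rows).set_index(["cancer_type", "stage_group"])


def pooled_stage_rates(records: list[CohortRecord]) -> pd.DataFrame:
    """Detection counts/rates pooled across cancer types, by stage group."""
    rows = []
    for grp in ("early", "advanced"):
        sub = [r for r in records if r.stage_group == grp]
        det = sum(r.cna_positive for r in sub)
        rows.append({
            "stage_group": grp,
            "n_patients": len(sub),
            "n_detected": det,
            "rate_pct": _round_half_up(100.0 * det / len(sub), 1) if sub else float("nan"),
        })
    return pd.DataFrame(rows).set_index("stage_group")


def _round_half_up(x: float, ndigits: int) -> float:
    factor = 10**ndigits
    return math.floor(x * factor + 0.5) / factor


def compare_rates(k1: int, n1: int, k2: int, n2: int, method: str = "fisher") -> float:
    """Two-sided p for a difference of two detection rates.

    Fisher's exact test by default (sum over tables with probability at most
    the observed one); ``method='chi2'`` gives the uncorrected chi-square.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n in both groups")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if method == "fisher":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "chi2":
        return float(stats.chi2_contingency(table, correction=False)[1])
    raise ValueError(f"unknown method '{method}'")


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann–Whitney U with midrank ties; exact p for n1+n2 <= 12.

    The exact two-sided p enumerates all group assignments of the pooled
    values (valid with ties); larger samples use the normal approximation
    with tie correction and continuity correction via scipy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)
    if n1 + n2 <= 12:
        pooled = np.concatenate([x, y])
        center = n1 * n2 / 2.0
        dev = abs(u_obs - center)
        hits = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(idx)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            total += 1
            if abs(u - center) >= dev - 1e-12:
                hits += 1
        return float(u_obs), hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u_obs), float(res.pvalue)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


@dataclass
class SurvivalCurve:
    """Product-limit estimate: survival after each distinct event time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan–Meier estimator (subjects censored at an event time stay at risk)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must align")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times])
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return SurvivalCurve(
        times=event_times,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(times[events == 0]),
    )


def logrank_test(group_a: tuple, group_b: tuple) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test; returns (chi-square, p)."""
    ta, ea = (np.asarray(v, dtype=float) for v in group_a)
    tb, eb = (np.asarray(v, dtype=float) for v in group_b)
    if int(ea.sum() + eb.sum()) == 0:
        raise ValueError("no events in either group")
    from lifelines.statistics import logrank_test as _ll_logrank

    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def plot_km(groups: dict[str, tuple], path: str, title: str = "") -> None:
    """Overlayed Kaplan–Meier curves for labelled (times, events) groups."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, (times, events) in groups.items():
        KaplanMeierFitter().fit(times, events, label=label).plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
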