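"""Survival and categorical-marker association of LGT groupings.

Overall and progression-free survival are compared between patient
groups with Kaplan-Meier curves and the two-group log-rank test. A
continuous burden covariate is dichotomized at the maximally selected
log-rank cutpoint (the survminer-style scan standing behind
"Cox-regression-derived" cutoffs), with a 10%/90% group-fraction guard
against degenerate splits. Binary markers (IGHV mutation status, FISH
aberrations, CD38) are tested against the grouping with the two-sided
Fisher exact test; the multi-level RAI stage with Pearson's chi-squared
test without continuity correction. Subjects with a missing value are
dropped per marker (pairwise deletion); raw p-values are reported, with
a Benjamini-Hochberg column alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "CutpointResult",
    "km_estimate",
    "logrank_test",
    "cox_cutpoint",
    "fisher_2x2",
    "chisq_contingency",
    "associate_groups",
    "BINARY_MARKERS",
]

BINARY_MARKERS = ("ighv_mutated", "del11q", "del17q", "tri12", "del13q", "cd38")
_NA_VALUES = {"", "NA", "nan", "None"}


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit survival curve at the distinct event times."""

    times: tuple[float, ...]
    at_risk: tuple[int, ...]
    survival: tuple[float, ...]


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    Censored subjects leave the risk set without a step. Returns the
    curve at the distinct times with at least one event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate needs at least one subject")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    mask = table["observed"] > 0
    ts = table.index[mask].to_numpy(float)
    at_risk = table.loc[mask, "at_risk"].to_numpy(int)
    surv = kmf.survival_function_at_times(ts).to_numpy(float)
    return SurvivalCurve(tuple(ts), tuple(int(r) for r in at_risk),
                         tuple(float(s) for s in surv))


def logrank_test(group_labels, times, events) -> tuple[float, float]:
    """Two-group log-rank test: (chi-squared statistic, two-sided p)."""
    group_labels = np.asarray(group_labels)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.unique(group_labels)
    if groups.size != 2:
        raise ValueError("logrank_test needs exactly two groups")
    if events.sum() == 0:
        raise ValueError("logrank_test needs at least one event")
    m = group_labels == groups[0]
    res = _lifelines_logrank(times[m], times[~m], events[m], events[~m])
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CutpointResult:
    """Maximally selected log-rank cutpoint on the burden scale."""

    cutoff: float
    n_low: int
    n_high: int
    statistic: float
    p: float


def cox_cutpoint(values, times, events,
                 min_group_frac: float = 0.1) -> CutpointResult:
    """Scan burden cutoffs and keep the one maximizing the log-rank
    statistic.

    Candidate cutoffs are midpoints between consecutive sorted unique
    burden values; a candidate is admissible only if both induced groups
    hold at least ``min_group_frac`` of the subjects. Ties prefer the
    smaller cutoff. The resulting split (low: value < cutoff) is
    invariant to monotone transforms of the burden.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = values.size
    if n < 10:
        raise ValueError("cox_cutpoint needs at least 10 subjects")
    uniq = np.unique(values)
    min_n = min_group_frac * n
    best: CutpointResult | None = None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cutoff = 0.5 * (lo + hi)
        low_mask = values < cutoff
        n_low = int(low_mask.sum())
        n_high = n - n_low
        if n_low < min_n or n_high < min_n:
            continue
        if events[low_mask].sum() + events[~low_mask].sum() == 0:
            continue
        stat, p = logrank_test(low_mask.astype(int), times, events)
        if best is None or stat > best.statistic:
            best = CutpointResult(float(cutoff), n_low, n_high, stat, p)
    if best is None:
        raise ValueError("no admissible burden split")
    return best


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Computed by exact hypergeometric enumeration with integer
    arithmetic: with margins fixed, sum the probabilities of all tables
    whose probability does not exceed the observed table's. Integer
    comparison makes tie handling exact, with no floating-point gate.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("negative cell count")
    if sum(cells) == 0:
        raise ValueError("all-zero table")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def numerator(k: int) -> int:
        return comb(r1, k) * comb(r2, c1 - k)

    observed = numerator(a)
    total = sum(
        numerator(k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if numerator(k) <= observed
    )
    return float(Fraction(total, comb(n, c1)))


def chisq_contingency(table) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction.

    All-zero rows and columns are dropped first; at least a 2x2 table
    must remain.
    """
    table = np.asarray(table, dtype=float)
    if table.sum() == 0:
        raise ValueError("all-zero table")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs at least 2 rows and columns")
    stat, p, _dof, _exp = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def _clean(series: pd.Series) -> pd.Series:
    s = series.astype(str)
    return s.mask(s.isin(_NA_VALUES))


def associate_groups(group_labels: pd.Series,
                     clinical: pd.DataFrame,
                     burdens: pd.DataFrame | None = None) -> dict:
    """Association report of a two-group patient stratification.

    ``group_labels`` is indexed by sample_id with values 1/2 (e.g. from
    the MDS grouping); ``clinical`` follows the clinical-table layout
    (os_time/os_event, pfs_time/pfs_event, binary markers, rai_stage).
    Optionally, with per-sample burdens, each survival endpoint is also
    dichotomized at its maximally selected burden cutpoint. NA subjects
    are dropped per marker and the dropped counts logged in the report.
    """
    clinical = clinical.set_index("sample_id") \
        if "sample_id" in clinical.columns else clinical
    shared = [s for s in group_labels.index if s in clinical.index]
    if not shared:
        raise ValueError("no overlapping samples between grouping and clinic")
    labels = group_labels.loc[shared]
    clin = clinical.loc[shared]

    report: dict = {"n_samples": len(shared), "markers": {}, "survival": {}}
    marker_ps = []
    for marker in BINARY_MARKERS:
        if marker not in clin.columns:
            continue
        vals = _clean(clin[marker])
        mask = vals.notna()
        n_dropped = int((~mask).sum())
        sub_vals, sub_grp = vals[mask], labels[mask]
        levels = sorted(sub_vals.unique())
        if len(levels) != 2:
            report["markers"][marker] = {
                "skipped": True, "reason": "fewer than two marker levels",
                "n_dropped_na": n_dropped,
            }
            continue
        a = int(((sub_grp == 1) & (sub_vals == levels[0])).sum())
        b = int(((sub_grp == 1) & (sub_vals == levels[1])).sum())
        c = int(((sub_grp == 2) & (sub_vals == levels[0])).sum())
        d = int(((sub_grp == 2) & (sub_vals == levels[1])).sum())
        p = fisher_2x2(a, b, c, d)
        report["markers"][marker] = {
            "levels": levels, "table": [[a, b], [c, d]],
            "fisher_p": p, "n_dropped_na": n_dropped,
        }
        marker_ps.append((marker, p))

    if "rai_stage" in clin.columns:
        vals = _clean(clin["rai_stage"])
        mask = vals.notna()
        stages = sorted(vals[mask].unique())
        table = [
            [int(((labels[mask] == g) & (vals[mask] == s)).sum())
             for s in stages]
            for g in (1, 2)
        ]
        try:
            stat, p = chisq_contingency(table)
            report["rai"] = {
                "stages": stages, "table": table, "chi2": stat,
                "chi2_p": p, "n_dropped_na": int((~mask).sum()),
            }
        except ValueError as exc:
            report["rai"] = {"skipped": True, "reason": str(exc),
                             "n_dropped_na": int((~mask).sum())}

    if marker_ps:
        adjusted = stats.false_discovery_control(
            [p for _, p in marker_ps], method="bh"
        )
        report["bh_adjusted"] = {
            name: float(adj) for (name, _), adj in zip(marker_ps, adjusted)
        }

    for endpoint in ("os", "pfs"):
        tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
        if tcol not in clin.columns:
            continue
        times = clin[tcol].to_numpy(float)
        events = clin[ecol].to_numpy(int)
        entry: dict = {}
        try:
            stat, p = logrank_test(labels.to_numpy(), times, events)
            entry["group_logrank"] = {"statistic": stat, "p": p}
        except ValueError as exc:
            entry["group_logrank"] = {"skipped": True, "reason": str(exc)}
        for g in (1, 2):
            curve = km_estimate(times[labels == g], events[labels == g])
            entry[f"km_group{g}"] = {
                "times": list(curve.times), "survival": list(curve.survival),
            }
        if burdens is not None:
            pct = burdens.set_index("sample_id")["pct_lgt"].loc[shared]
            try:
                cut = cox_cutpoint(pct.to_numpy(float), times, events)
                entry["cutpoint"] = {
                    "cutoff": cut.cutoff, "n_low": cut.n_low,
                    "n_high": cut.n_high, "statistic": cut.statistic,
                    "p": cut.p,
                }
            except ValueError as exc:
                entry["cutpoint"] = {"skipped": True, "reason": str(exc)}
        report["survival"][endpoint] = entry
    return report
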