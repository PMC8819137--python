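"""Survival and frequency statistics for subtype comparisons.

Kaplan–Meier curves and the log-rank test (via lifelines), a label-permutation
test for differences in binary-feature frequency between two groups, and
Benjamini–Hochberg multiple-testing adjustment (via statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KMCurve",
    "TestResult",
    "kaplan_meier",
    "log_rank_test",
    "permutation_test_frequency",
    "benjamini_hochberg",
]


@dataclass
class KMCurve:
    """Product-limit estimate: S(t_i) = prod_{j<=i} (1 - d_j / n_j)."""

    times: np.ndarray        # distinct event times
    n_risk: np.ndarray       # at-risk counts just before each event time
    n_events: np.ndarray     # events at each time
    survival: np.ndarray     # S(t_i)

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "n_risk": self.n_risk,
                             "n_events": self.n_events, "survival": self.survival})


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_permutations: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


def _validate_times(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one record")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event flags must be 0 (censored) or 1 (observed)")
    return times, events


def kaplan_meier(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Censored subjects at time t remain at risk for events at t (standard
    convention).  Returns the curve evaluated at the distinct event times.
    """
    times, events = _validate_times(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    ev_times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ev_times, "KM_estimate"].to_numpy()
    return KMCurve(times=ev_times, n_risk=ev["at_risk"].to_numpy(dtype=int),
                   n_events=ev["observed"].to_numpy(dtype=int), survival=surv)


def log_rank_test(times, events, groups) -> TestResult:
    """Two-group log-rank test; chi-square statistic on 1 df."""
    times, events = _validate_times(times, events)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {labels.size}")
    for lab in labels:
        if events[groups == lab].sum() == 0:
            raise ValueError(f"group {lab!r} has no observed events")
    m = groups == labels[0]
    res = _ll_logrank(times[m], times[~m], event_observed_A=events[m],
                      event_observed_B=events[~m])
    return TestResult(statistic=float(res.test_statistic),
                      p_value=float(res.p_value), method="log-rank")


def permutation_test_frequency(group_labels, binary_feature, n_perm: int = 10000,
                               seed: int = 0) -> TestResult:
    """Permutation test for a binary-feature frequency difference.

    Statistic is the absolute difference in feature frequency between the two
    groups; the null is built by shuffling group labels.  The p-value uses the
    add-one estimator (1 + #{perm >= observed}) / (1 + n_perm), so it is never
    below 1 / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    groups = np.asarray(group_labels)
    feature = np.asarray(binary_feature)
    if not np.isin(feature, [0, 1]).all():
        raise ValueError("feature must be binary (0/1)")
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {labels.size}")
    mask = groups == labels[0]

    def _stat(f):
        return np.abs(f[..., mask].mean(axis=-1) - f[..., ~mask].mean(axis=-1))

    observed = float(_stat(feature.astype(float)))
    rng = np.random.default_rng(seed)
    n = feature.size
    # permuting the feature against fixed group masks == shuffling labels
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    null = _stat(feature.astype(float)[perms])
    hits = int(np.sum(null >= observed - 1e-12))
    p = (1 + hits) / (1 + n_perm)
    return TestResult(statistic=observed, p_value=p,
                      method="permutation-frequency", n_permutations=n_perm)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
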