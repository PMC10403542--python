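"""Survival estimation and lesion co-segregation statistics.

Kaplan-Meier product-limit curves with Greenwood standard errors, the
k-group log-rank test with hypergeometric variance, p-value adjustment
(Benjamini-Hochberg / Bonferroni), and pairwise Fisher exact testing of
lesion co-occurrence versus mutual exclusivity.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "CosegDirection",
    "CosegResult",
    "km_estimate",
    "logrank_test",
    "adjust_pvalues",
    "fisher_cosegregation",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate over the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    greenwood_se: np.ndarray

    def surv_at(self, t: float) -> float:
        """Step-function value: the last estimate at or before ``t``."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def five_year_efs(self) -> float:
        """Survival read at 60 months (the 5-year EFS rate)."""
        return self.surv_at(60.0)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    At tied times, events are handled before censorings (a subject censored
    at an event time is still at risk for that event).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if (t < 0).any():
        raise ValueError("negative survival times")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")

    event_times = np.unique(t[e == 1])
    surv, se2, s = [], [], 1.0
    at_risk, d_out = [], []
    gw = 0.0
    for et in event_times:
        n = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n
        if n > d:
            gw += d / (n * (n - d))
        else:
            gw = np.inf  # curve reaches 0; SE undefined beyond
        surv.append(s)
        se2.append(0.0 if s == 0.0 else s * np.sqrt(gw))
        at_risk.append(n)
        d_out.append(d)
    return SurvivalCurve(
        event_times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk),
        events=np.asarray(d_out),
        greenwood_se=np.asarray(se2),
    )


def logrank_test(
    groups: Sequence, times: Sequence[float], events: Sequence[int]
) -> tuple[float, int, float]:
    """k-group log-rank test.

    Returns ``(chi2, df, p)`` with ``df = k - 1`` and the usual
    hypergeometric variance of the observed-minus-expected event counts.
    """
    g = np.asarray(groups)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    labels = np.unique(g)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")

    omE = np.zeros(k)
    V = np.zeros((k, k))
    for et in np.unique(t[e == 1]):
        risk = t >= et
        N = int(risk.sum())
        D = int(((t == et) & (e == 1)).sum())
        n_j = np.array([(risk & (g == lab)).sum() for lab in labels], dtype=float)
        d_j = np.array([((t == et) & (e == 1) & (g == lab)).sum() for lab in labels], dtype=float)
        omE += d_j - D * n_j / N
        if N > 1:
            frac = n_j / N
            V += D * (N - D) / (N - 1) * (np.diag(frac) - np.outer(frac, frac))
    z = omE[:-1]
    Vz = V[:-1, :-1]
    chi2 = float(z @ np.linalg.pinv(Vz) @ z) if z.size else 0.0
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, k - 1, p


def adjust_pvalues(
    pvalues: Sequence[float], method: str = "benjamini_hochberg", m: int | None = None
) -> np.ndarray:
    """Multiple-testing adjustment.

    ``method`` is ``"benjamini_hochberg"`` (step-up FDR, monotone) or
    ``"bonferroni"``. ``m`` overrides the number of comparisons when more
    tests were performed than p-values are being adjusted.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("benjamini_hochberg", "bonferroni"):
        raise ValueError(f"unknown adjustment method {method!r}")
    if p.size == 0:
        return p
    if m is None:
        key = "fdr_bh" if method == "benjamini_hochberg" else "bonferroni"
        return multipletests(p, method=key)[1]
    if m < p.size:
        raise ValueError("declared m smaller than the number of p-values")
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(1.0, adj)
    return out


class CosegDirection(str, enum.Enum):
    CO_OCCURRING = "co_occurring"
    MUTUALLY_EXCLUSIVE = "mutually_exclusive"
    NONE = "none"


@dataclass(frozen=True)
class CosegResult:
    """Pairwise Fisher test of two lesions' carrier patterns."""

    lesion_a: str
    lesion_b: str
    both: int
    only_a: int
    only_b: int
    neither: int
    odds_ratio: float
    p: float
    q: float
    direction: CosegDirection


def fisher_cosegregation(
    carriers: pd.DataFrame, alpha: float = 0.05
) -> list[CosegResult]:
    """Pairwise co-occurrence / mutual-exclusivity testing.

    ``carriers`` is a patients x lesions boolean matrix. Each pair gets a
    two-sided Fisher exact p (sum of hypergeometric probabilities not
    exceeding the observed table's), a BH-adjusted q, and a direction label
    assigned only when significant after BH: co-occurring for an odds ratio
    above 1, mutually exclusive below 1. The displayed odds ratio uses the
    Haldane-Anscombe 0.5 correction when a cell is empty (the p-value never
    does). Lesions carried by every patient or by none are skipped.
    """
    X = carriers.astype(bool)
    usable = []
    for l in X.columns:
        n_carr = int(X[l].sum())
        if 0 < n_carr < len(X):
            usable.append(l)
        else:
            logger.info("skipping degenerate lesion %s (carriers: %d/%d)", l, n_carr, len(X))
    results = []
    for la, lb in combinations(usable, 2):
        a = int((X[la] & X[lb]).sum())
        b = int((X[la] & ~X[lb]).sum())
        c = int((~X[la] & X[lb]).sum())
        d = int((~X[la] & ~X[lb]).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            raw_gt1 = a * d > b * c
        else:
            orat = (a * d) / (b * c)
            raw_gt1 = orat > 1.0
        results.append([la, lb, a, b, c, d, orat, p, raw_gt1])

    qs = adjust_pvalues([r[7] for r in results]) if results else np.array([])
    out = []
    for r, q in zip(results, qs):
        la, lb, a, b, c, d, orat, p, raw_gt1 = r
        if q < alpha:
            direction = (
                CosegDirection.CO_OCCURRING if raw_gt1 else CosegDirection.MUTUALLY_EXCLUSIVE
            )
        else:
            direction = CosegDirection.NONE
        out.append(
            CosegResult(
                lesion_a=la, lesion_b=lb, both=a, only_a=b, only_b=c, neither=d,
                odds_ratio=float(orat), p=float(p), q=float(q), direction=direction,
            )
        )
    return out
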