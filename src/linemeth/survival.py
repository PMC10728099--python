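"""Cohort survival evaluation: mean-split, log-rank, signed P, bootstrap.

Patients are stratified into methylation-high and -low groups at the
cohort mean of a methylation score.  The two groups are compared by the
log-rank test; the resulting P value carries a sign encoding direction:
positive when the methylation-high group survives better (the
hypomethylation-resistance hypothesis), negative otherwise.  Bootstrap
resampling of patients yields a signed-P distribution per predictor, and
paired distributions are compared with the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

HIGH = "high"
LOW = "low"


@dataclass(frozen=True)
class SignedP:
    """Log-rank P value with a survival-direction sign.

    sign = +1 when the methylation-high group's observed events fall at or
    below expectation (better survival), -1 otherwise.
    """

    p: float
    sign: int
    chi_square: float
    o_minus_e_high: float

    @property
    def signed_value(self) -> float:
        return self.sign * self.p


@dataclass
class BootstrapResult:
    """Signed-P distribution over patient resamples."""

    signed_p_values: np.ndarray
    resamples: int
    seed: int
    skipped: int  # degenerate resamples that were redrawn

    def __post_init__(self) -> None:
        assert len(self.signed_p_values) == self.resamples


def split_by_mean(scores: np.ndarray | pd.Series) -> np.ndarray:
    """Label samples 'high' (score > cohort mean) or 'low' (<= mean)."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least two samples to split")
    if np.ptp(s) == 0:
        raise ValueError("degenerate split: scores are constant")
    return np.where(s > s.mean(), HIGH, LOW)


def km_estimate(time, event) -> pd.Series:
    """Product-limit survival estimate S(t), right-censored.

    Returns a step function as a Series indexed by time (including t=0
    with S=1), non-increasing.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), np.asarray(event, int))
    sf = kmf.survival_function_.iloc[:, 0]
    sf.index.name = "time"
    sf.name = "S"
    return sf


def _logrank_internals(time, event, is_high):
    """O, E and variance for the high group over pooled event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    is_high = np.asarray(is_high, bool)
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], is_high[order]
    n = len(t)
    # distinct event times
    uniq = np.unique(t[e == 1])
    O = E = V = 0.0
    for tj in uniq:
        at_risk = t >= tj
        nj = int(at_risk.sum())
        n1j = int((at_risk & g).sum())
        dying = (t == tj) & (e == 1)
        dj = int(dying.sum())
        d1j = int((dying & g).sum())
        O += d1j
        E += dj * n1j / nj
        if nj > 1:
            V += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    return O, E, V


def logrank_test(time, event, groups) -> tuple[float, float, float]:
    """Two-group log-rank test.

    Returns (chi_square, p, O - E for the high group).  The 1-df
    chi-square approximation is used, as in standard survival packages.
    """
    groups = np.asarray(groups)
    is_high = groups == HIGH
    if is_high.all() or (~is_high).all():
        raise ValueError("log-rank test needs two non-empty groups")
    event = np.asarray(event, int)
    if event.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    O, E, V = _logrank_internals(time, event, is_high)
    if V == 0:
        return 0.0, 1.0, O - E
    chi2 = (O - E) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), max(p, np.finfo(float).tiny), O - E


def signed_p(time, event, groups) -> SignedP:
    """Log-rank P with direction sign from the high group's O - E.

    O - E < 0 means the high group saw fewer events than expected, i.e.
    better survival: sign +1.  Ties (O - E == 0) take +1 by convention.
    """
    chi2, p, ome = logrank_test(time, event, groups)
    sign = 1 if ome <= 0 else -1
    return SignedP(p=p, sign=sign, chi_square=chi2, o_minus_e_high=ome)


def signed_p_from_scores(scores, time, event) -> SignedP:
    """Mean-split the scores, then compute the signed log-rank P."""
    return signed_p(time, event, split_by_mean(scores))


def bootstrap_signed_p(
    scores,
    time,
    event,
    resamples: int = 1000,
    seed: int = 0,
    max_redraws: int = 1000,
) -> BootstrapResult:
    """Signed-P distribution over patient bootstrap resamples.

    Each resample draws n patients with replacement, keeping each
    patient's (score, time, event) triple intact, then recomputes the
    mean-split and the signed log-rank P.  Degenerate resamples (constant
    scores, an empty group, or no events) are redrawn and counted.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = len(scores)
    if not (len(time) == len(event) == n):
        raise ValueError("scores, time, event must have equal length")
    rng = np.random.default_rng(seed)
    values = np.empty(resamples)
    skipped = 0
    for r in range(resamples):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            try:
                sp = signed_p_from_scores(scores[idx], time[idx], event[idx])
            except ValueError:
                skipped += 1
                continue
            values[r] = sp.signed_value
            break
        else:
            raise ValueError(
                f"no valid resample after {max_redraws} redraws "
                "(cohort too small or degenerate)"
            )
    return BootstrapResult(
        signed_p_values=values, resamples=resamples, seed=seed, skipped=skipped
    )


def compare_predictors(
    result_a: BootstrapResult | np.ndarray, result_b: BootstrapResult | np.ndarray
) -> float:
    """Two-sided Wilcoxon signed-rank P on paired signed-P collections.

    Pairs share resample indices.  All-zero differences (identical
    distributions) give P = 1 under the zero-difference drop rule.
    """
    a = result_a.signed_p_values if isinstance(result_a, BootstrapResult) else np.asarray(result_a, float)
    b = result_b.signed_p_values if isinstance(result_b, BootstrapResult) else np.asarray(result_b, float)
    if len(a) != len(b):
        raise ValueError(f"paired collections differ in length: {len(a)} vs {len(b)}")
    diff = a - b
    if np.all(diff == 0):
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


def significance_stars(p: float) -> str:
    """Star bands: **** < 1e-4, *** < 1e-3, ** < 1e-2, * < 0.05."""
    for thresh, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < thresh:
            return stars
    return "ns"
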