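"""Response classification: SD-based probe selection, logistic GLM, ROC-AUC.

Probes with little between-sample variation carry no classification
signal, so the probe with the smallest standard deviation and any probe
with SD < 0.015 are excluded before fitting a binomial GLM of responder
status (durable clinical benefit vs none) on the remaining betas.
Accuracy is the ROC-AUC of the in-sample fitted probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

SD_THRESHOLD = 0.015


@dataclass
class ProbeSelection:
    """Partition of probes into kept and dropped by the SD rule."""

    kept: tuple[str, ...]
    dropped_smallest_sd: str
    dropped_below_threshold: tuple[str, ...]
    threshold: float
    sd: dict[str, float]


@dataclass
class GlmFit:
    """Fitted binomial GLM with in-sample scores."""

    scores: np.ndarray  # fitted probabilities per sample
    params: pd.Series
    probes: tuple[str, ...]
    separation_flagged: bool


def select_probes_by_sd(
    beta_matrix: pd.DataFrame, threshold: float = SD_THRESHOLD
) -> ProbeSelection:
    """Drop the smallest-SD probe and every probe with SD < threshold.

    The smallest-SD probe is dropped unconditionally (even when all SDs
    clear the threshold); ties at the minimum go to the first probe in
    column order.  Sample SD uses the n-1 denominator.
    """
    if len(beta_matrix) < 2:
        raise ValueError("need >= 2 samples to compute probe SDs")
    sd = beta_matrix.std(ddof=1)
    smallest = sd.index[int(np.argmin(sd.to_numpy()))]
    below = tuple(p for p in sd.index if sd[p] < threshold and p != smallest)
    kept = tuple(p for p in sd.index if p != smallest and p not in below)
    if len(kept) < 2:
        raise ValueError(
            f"SD filter would keep {len(kept)} probe(s); need at least 2"
        )
    return ProbeSelection(
        kept=kept,
        dropped_smallest_sd=smallest,
        dropped_below_threshold=below,
        threshold=threshold,
        sd=sd.to_dict(),
    )


def fit_response_glm(
    selected_betas: pd.DataFrame,
    responses,
    family: str = "binomial",
) -> GlmFit:
    """Fit response ~ selected probes and return in-sample fitted scores.

    ``responses`` is binary (1 = durable clinical benefit).  The binomial
    family with logit link is the default; an identity-link Gaussian
    alternative exists for sensitivity analysis.  Perfect separation is
    flagged but the (monotone) scores are still returned.
    """
    y = np.asarray(responses, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("responses must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes must be present")
    X = sm.add_constant(selected_betas.to_numpy(float))
    if len(y) <= X.shape[1]:
        raise ValueError(
            f"n={len(y)} samples cannot support {X.shape[1]} parameters"
        )
    fam = sm.families.Binomial() if family == "binomial" else sm.families.Gaussian()
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=fam)
        res = model.fit(maxiter=100)
        for w in caught:
            if "separat" in str(w.message).lower():
                separation = True
    scores = np.asarray(res.fittedvalues, float)
    if family == "binomial" and (np.min(scores) < 1e-8 or np.max(scores) > 1 - 1e-8):
        separation = True
    names = ["const"] + list(selected_betas.columns)
    return GlmFit(
        scores=scores,
        params=pd.Series(res.params, index=names),
        probes=tuple(selected_betas.columns),
        separation_flagged=separation,
    )


def roc_auc(scores, labels) -> float:
    """ROC-AUC as the Mann-Whitney rank statistic, ties credited 0.5.

    Equals the probability that a random positive outranks a random
    negative (ties count half).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC needs both classes present")
    ranks = rankdata(scores)  # average rank on ties -> 0.5 credit
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def prediction_auc(
    beta_matrix: pd.DataFrame,
    responses,
    sd_threshold: float = SD_THRESHOLD,
) -> tuple[float, ProbeSelection, GlmFit]:
    """Full accuracy evaluation: SD filter -> GLM -> in-sample ROC-AUC."""
    selection = select_probes_by_sd(beta_matrix, threshold=sd_threshold)
    fit = fit_response_glm(beta_matrix[list(selection.kept)], responses)
    return roc_auc(fit.scores, responses), selection, fit
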