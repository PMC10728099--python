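"""Longitudinal monitoring: paired timepoint deltas and subset summaries.

Patients sampled at two timepoints (baseline vs progression, or
pretreatment vs early-during-treatment) are compared probe-by-probe as
delta = beta(later) - beta(baseline), so progressive hypomethylation is
negative.  Per-probe one-sided t-tests ask whether deltas fall below
zero; direction counts summarize per-patient movement; and named probe
subsets give tumor-burden-sensitive averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: probe subsets repeatedly informative for progression monitoring
FIVE_PROBE = ("P2", "P3", "P5", "P8", "P9")
FOUR_PROBE = ("P2", "P3", "P8", "P9")
SUBSETS = {"five": FIVE_PROBE, "four": FOUR_PROBE}


@dataclass
class PairedDeltaResult:
    """Per-patient, per-probe deltas between two timepoints."""

    deltas: pd.DataFrame  # patients x probes, later - baseline
    timepoints: tuple[str, str]
    unmatched_t0: tuple[str, ...]
    unmatched_t1: tuple[str, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.deltas)


def paired_deltas(
    betas_t0: pd.DataFrame,
    betas_t1: pd.DataFrame,
    timepoints: tuple[str, str] = ("baseline", "later"),
) -> PairedDeltaResult:
    """Inner-join two beta matrices on patient index and subtract.

    delta = t1 - t0 for every shared probe column; unmatched patients on
    either side are reported, zero matches is an error.
    """
    common = betas_t0.index.intersection(betas_t1.index)
    if len(common) == 0:
        raise ValueError("no patients matched between timepoints")
    probes = [c for c in betas_t0.columns if c in betas_t1.columns]
    deltas = betas_t1.loc[common, probes] - betas_t0.loc[common, probes]
    return PairedDeltaResult(
        deltas=deltas,
        timepoints=timepoints,
        unmatched_t0=tuple(betas_t0.index.difference(common)),
        unmatched_t1=tuple(betas_t1.index.difference(common)),
    )


def test_hypomethylation(deltas: pd.DataFrame) -> pd.Series:
    """Per-probe one-sample t-test of mean(delta) < 0.

    Needs >= 3 paired observations per probe.  Zero-variance probes are a
    degenerate limit: P = 0.5 when the common delta is 0, else 0 or 1 by
    its sign.
    """
    out = {}
    for probe in deltas.columns:
        d = deltas[probe].dropna().to_numpy(float)
        if len(d) < 3:
            raise ValueError(f"{probe}: need >= 3 paired observations, got {len(d)}")
        if np.ptp(d) == 0:
            out[probe] = 0.5 if d[0] == 0 else (0.0 if d[0] < 0 else 1.0)
            continue
        res = stats.ttest_1samp(d, popmean=0.0, alternative="less")
        out[probe] = float(res.pvalue)
    return pd.Series(out, name="p_less_than_zero")


test_hypomethylation.__test__ = False  # not a pytest case despite the name


def direction_counts(deltas: pd.DataFrame) -> pd.DataFrame:
    """Per-probe counts of patients whose beta increased / decreased / held."""
    return pd.DataFrame(
        {
            "n_increase": (deltas > 0).sum(),
            "n_decrease": (deltas < 0).sum(),
            "n_zero": (deltas == 0).sum(),
        }
    )


def subset_average(beta: pd.Series, probes) -> float:
    """Unweighted mean beta over a probe subset (e.g. FIVE_PROBE)."""
    probes = list(probes)
    missing = [p for p in probes if p not in beta.index or pd.isna(beta[p])]
    if missing:
        raise ValueError(f"missing beta for subset probes {missing}")
    return float(beta[probes].mean())


def monitoring_report(
    betas_t0: pd.DataFrame, betas_t1: pd.DataFrame, subset: str = "five"
) -> pd.DataFrame:
    """Per-patient subset delta alongside the all-probe absolute averages.

    Both views are reported deliberately: subset deltas track tumor
    burden, while the all-probe average is the better survival predictor.
    """
    probes = SUBSETS.get(subset, tuple(betas_t0.columns))
    result = paired_deltas(betas_t0, betas_t1)
    common = result.deltas.index
    return pd.DataFrame(
        {
            f"{subset}_probe_delta": result.deltas[list(probes)].mean(axis=1),
            "all_probe_avg_t0": betas_t0.loc[common].mean(axis=1),
            "all_probe_avg_t1": betas_t1.loc[common].mean(axis=1),
        }
    )
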