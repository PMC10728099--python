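"""Imputation of missing P8-P10 betas by linear regression on P1-P7.

Samples occasionally lack beta values for the non-CpG probes; those are
filled in by ordinary least squares against the seven CpG probes, trained
on samples with complete 10-probe vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PREDICTOR_PROBES = tuple(f"P{i}" for i in range(1, 8))
IMPUTABLE_PROBES = ("P8", "P9", "P10")


@dataclass
class ImputationModel:
    """OLS model: response probe ~ intercept + P1..P7."""

    response_probe: str
    intercept: float
    slopes: dict[str, float]  # keyed by predictor probe
    n_train: int
    r_squared: float

    def predict(self, predictors: pd.Series) -> float:
        return float(
            self.intercept
            + sum(self.slopes[p] * predictors[p] for p in PREDICTOR_PROBES)
        )


def fit_imputation_models(
    beta_matrix: pd.DataFrame,
    response_probes: tuple[str, ...] = IMPUTABLE_PROBES,
) -> dict[str, ImputationModel]:
    """Fit one OLS model per response probe on complete-case samples.

    Requires more complete samples than parameters (>= 9 rows for the
    7-predictor design).  Raises on a rank-deficient design, naming the
    collinear probes.
    """
    cols = list(PREDICTOR_PROBES) + list(response_probes)
    complete = beta_matrix[cols].dropna()
    n = len(complete)
    if n < len(PREDICTOR_PROBES) + 2:
        raise ValueError(
            f"need >= {len(PREDICTOR_PROBES) + 2} complete samples to fit "
            f"imputation models, got {n}"
        )
    X = np.column_stack(
        [np.ones(n)] + [complete[p].to_numpy(float) for p in PREDICTOR_PROBES]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify probes whose removal restores full rank
        collinear = [
            p
            for i, p in enumerate(PREDICTOR_PROBES, start=1)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear probes: {collinear}")
    models: dict[str, ImputationModel] = {}
    for probe in response_probes:
        y = complete[probe].to_numpy(float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ coef
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        models[probe] = ImputationModel(
            response_probe=probe,
            intercept=float(coef[0]),
            slopes=dict(zip(PREDICTOR_PROBES, coef[1:].tolist())),
            n_train=n,
            r_squared=r2,
        )
    return models


def impute_missing(
    sample: pd.Series, models: dict[str, ImputationModel]
) -> tuple[pd.Series, list[str]]:
    """Fill missing modelled probes in one sample's beta vector.

    Returns (imputed vector, list of probes that were imputed).
    Predictions are clipped to [0, 1].  A sample with nothing missing is
    returned unchanged; missing predictors are an error.
    """
    missing_predictors = [p for p in PREDICTOR_PROBES if pd.isna(sample.get(p))]
    if missing_predictors:
        raise ValueError(
            f"cannot impute: predictor probes missing {missing_predictors}"
        )
    out = sample.copy()
    flagged: list[str] = []
    for probe, model in models.items():
        if pd.isna(out.get(probe)):
            pred = model.predict(out)
            out[probe] = min(1.0, max(0.0, pred))
            flagged.append(probe)
    return out, flagged


def impute_matrix(
    beta_matrix: pd.DataFrame, models: dict[str, ImputationModel] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute every incomplete row of a beta matrix.

    Models are fitted on the matrix's own complete cases when not given.
    Returns (imputed matrix, boolean mask of imputed cells).
    """
    if models is None:
        models = fit_imputation_models(beta_matrix)
    out = beta_matrix.copy()
    mask = pd.DataFrame(False, index=out.index, columns=out.columns)
    for idx, row in beta_matrix.iterrows():
        if row[list(models)].isna().any():
            filled, flagged = impute_missing(row, models)
            out.loc[idx] = filled
            mask.loc[idx, flagged] = True
    return out, mask
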