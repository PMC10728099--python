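"""Tabular I/O for beta matrices and clinical tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .quant import BetaVector


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples x probes beta matrix TSV (sample_id index)."""
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_beta_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def append_beta_vector(vec: BetaVector, path: str | Path) -> None:
    """Append one quantified sample as a beta-matrix row (creates the file)."""
    path = Path(path)
    row = {**vec.beta, "conversion_rate": vec.conversion_rate}
    row.update({f"depth_{k}": v for k, v in vec.per_probe_depth.items()})
    df = pd.DataFrame([row], index=pd.Index([vec.sample_id], name="sample_id"))
    header = not path.exists()
    df.to_csv(path, sep="\t", mode="a", header=header)


def read_clinical(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a clinical CSV, optionally renaming columns to the canonical
    names (sample_id, patient_id, time, event, response, timepoint)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "patient_id" in df.columns:
        df = df.set_index("patient_id")
    return df
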