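"""Shared fixtures: toy probes/panels and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from linemeth.panel import AmpliconPanel, ProbeTarget, default_panel


def make_probe(probe_id: str, seq: str, include_cpa: bool = False) -> ProbeTarget:
    """Build a probe by scanning a literal sequence for site contexts.

    Targets are CpG sites (plus CpA when ``include_cpa``); naive cytosines
    are Cs followed by C or T.
    """
    seq = seq.upper()
    cpg = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
    cpa = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CA"]
    naive = tuple(i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] in "CT")
    targets = sorted(cpg + cpa) if include_cpa else cpg
    contexts = tuple("CpG" if seq[i + 1] == "G" else "CpA" for i in targets)
    return ProbeTarget(
        probe_id=probe_id,
        reference_seq=seq,
        target_offsets=tuple(targets),
        site_context=contexts,
        primer_fwd=seq[:10],
        primer_rev=seq[-10:],
        naive_c_offsets=naive,
    )


# two dissimilar 60-nt amplicons with several CpGs and naive Cs each
TOY_SEQ_1 = "ATACGATTGGACGTTCTACCTGTTACGGTAGCTTAGGACGTATTCCATGGATTACGTGAA"
TOY_SEQ_2 = "GGTTCGAAATCCGTGGACTTGTACGTTTGACGATAGGGTCGTTAGGTTACGGATCTTTGA"


@pytest.fixture(scope="session")
def toy_probe() -> ProbeTarget:
    return make_probe("P1", TOY_SEQ_1)


@pytest.fixture(scope="session")
def toy_panel() -> AmpliconPanel:
    return AmpliconPanel(
        probes=(make_probe("P1", TOY_SEQ_1), make_probe("P2", TOY_SEQ_2))
    )


@pytest.fixture(scope="session")
def bundled_panel() -> AmpliconPanel:
    return default_panel()


@pytest.fixture(scope="session")
def linear_beta_matrix() -> pd.DataFrame:
    """Complete 10-probe matrix where P8-P10 are exact linear functions of P1-P7."""
    rng = np.random.default_rng(11)
    n = 40
    base = rng.uniform(0.3, 0.9, size=(n, 7))
    df = pd.DataFrame(base, columns=[f"P{i}" for i in range(1, 8)])
    df["P8"] = 0.1 + 0.5 * df["P1"]
    df["P9"] = 0.05 + 0.2 * df["P2"] + 0.3 * df["P4"]
    df["P10"] = 0.4 * df["P7"] + 0.2
    df.index = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    return df
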