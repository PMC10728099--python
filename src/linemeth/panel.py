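"""Amplicon panel: probe references, scored cytosine sites, primers.

The panel abstracts each LINE-1 probe as a single consensus amplicon on
which all downstream quantification operates.  Coordinates are 0-based and
intervals are half-open, following BED convention.

Scored ("target") cytosines are CpG sites, plus CpA sites on the non-CpG
probes (P8-P10).  "Naive" cytosines sit outside CpG/CpA context, are
assumed unmethylated, and serve to estimate the per-sample bisulfite
conversion rate; the bundled default panel annotates 92 of them across its
10 probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROBE_IDS = tuple(f"P{i}" for i in range(1, 11))
#: probes whose targets include CpA (non-CpG) methylation sites
NON_CPG_PROBES = frozenset({"P8", "P9", "P10"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PanelValidationError(ValueError):
    """Raised when a panel definition violates its structural invariants."""


@dataclass(frozen=True)
class ProbeTarget:
    """One amplicon probe with its scored and naive cytosine positions.

    ``target_offsets`` are 0-based offsets of the scored cytosines on the
    Watson (reference) strand; ``site_context[i]`` tags each as ``"CpG"``
    or ``"CpA"``.  ``naive_c_offsets`` are non-CpG/non-CpA cytosines used
    for conversion-rate estimation.
    """

    probe_id: str
    reference_seq: str
    target_offsets: tuple[int, ...]
    site_context: tuple[str, ...]
    primer_fwd: str
    primer_rev: str
    naive_c_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.reference_seq)
        if len(self.target_offsets) != len(self.site_context):
            raise PanelValidationError(
                f"{self.probe_id}: {len(self.target_offsets)} target offsets but "
                f"{len(self.site_context)} context tags"
            )
        for off in (*self.target_offsets, *self.naive_c_offsets):
            if not 0 <= off < n:
                raise PanelValidationError(
                    f"{self.probe_id}: offset {off} outside [0, {n})"
                )
            if self.reference_seq[off] != "C":
                raise PanelValidationError(
                    f"{self.probe_id}: base at offset {off} is "
                    f"{self.reference_seq[off]!r}, expected 'C'"
                )
        if set(self.target_offsets) & set(self.naive_c_offsets):
            overlap = sorted(set(self.target_offsets) & set(self.naive_c_offsets))
            raise PanelValidationError(
                f"{self.probe_id}: offsets {overlap} annotated both target and naive"
            )
        for off, ctx in zip(self.target_offsets, self.site_context):
            if ctx not in ("CpG", "CpA"):
                raise PanelValidationError(
                    f"{self.probe_id}: unknown site context {ctx!r} at offset {off}"
                )

    @property
    def region(self) -> tuple[int, int]:
        """Half-open interval [start, end) covering all target offsets."""
        if not self.target_offsets:
            return (0, 0)
        return (min(self.target_offsets), max(self.target_offsets) + 1)

    def cpg_offsets(self) -> tuple[int, ...]:
        return tuple(
            o for o, c in zip(self.target_offsets, self.site_context) if c == "CpG"
        )

    def scored_offsets(self, context_mode: str) -> tuple[int, ...]:
        """Target offsets under ``context_mode`` ('cpg_only' or 'cpg_and_cpa')."""
        if context_mode == "cpg_only":
            return self.cpg_offsets()
        if context_mode == "cpg_and_cpa":
            return self.target_offsets
        raise ValueError(f"unknown context_mode {context_mode!r}")

    def crick_naive_g_offsets(self) -> tuple[int, ...]:
        """Watson G positions whose Crick-strand cytosine is naive.

        A Crick-strand cytosine pairs with a Watson G at offset g; its
        Crick dinucleotide context is CpG when Watson[g-1] == 'C' and CpA
        when Watson[g-1] == 'T'.  The remaining Gs carry naive Crick
        cytosines whose G-to-A conversion is observable on Crick reads.
        """
        seq = self.reference_seq
        return tuple(
            g
            for g in range(1, len(seq))
            if seq[g] == "G" and seq[g - 1] in ("A", "G")
        )


@dataclass(frozen=True)
class AmpliconPanel:
    """Ordered collection of probes sharing one assay definition."""

    probes: tuple[ProbeTarget, ...]

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise PanelValidationError(f"duplicate probe ids in panel: {ids}")

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(p.probe_id for p in self.probes)

    @property
    def total_naive_c(self) -> int:
        return sum(len(p.naive_c_offsets) for p in self.probes)

    def __iter__(self) -> Iterator[ProbeTarget]:
        return iter(self.probes)

    def __len__(self) -> int:
        return len(self.probes)

    def __getitem__(self, probe_id: str) -> ProbeTarget:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)


def bisulfite_references(panel: AmpliconPanel) -> dict[str, tuple[str, str]]:
    """Fully converted template pair per probe.

    Watson template: every C -> T (the read sequence when nothing is
    methylated and conversion is complete).  Crick template: every G -> A
    (the reverse-complemented Crick read in Watson coordinates).
    """
    return {
        p.probe_id: (
            p.reference_seq.replace("C", "T"),
            p.reference_seq.replace("G", "A"),
        )
        for p in panel
    }


def load_panel(panel_fasta: str | Path, sites_table: str | Path) -> AmpliconPanel:
    """Load and validate a panel from FASTA + BED-like sites TSV.

    The sites table has columns ``probe_id, offset, context, role`` with
    role in {target, naive}; context is ignored for naive rows.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(panel_fasta), "fasta")}
    if not records:
        raise PanelValidationError(f"no FASTA records in {panel_fasta}")
    sites = pd.read_csv(sites_table, sep="\t", dtype={"probe_id": str})
    required = {"probe_id", "offset", "context", "role"}
    if not required.issubset(sites.columns):
        raise PanelValidationError(
            f"sites table missing columns {sorted(required - set(sites.columns))}"
        )
    unknown = set(sites["probe_id"]) - set(records)
    if unknown:
        raise PanelValidationError(
            f"sites table references unknown probes: {sorted(unknown)}"
        )
    probes = []
    for probe_id, seq in records.items():
        rows = sites[sites["probe_id"] == probe_id]
        targets = rows[rows["role"] == "target"].sort_values("offset")
        naive = rows[rows["role"] == "naive"].sort_values("offset")
        probes.append(
            ProbeTarget(
                probe_id=probe_id,
                reference_seq=seq,
                target_offsets=tuple(int(o) for o in targets["offset"]),
                site_context=tuple(targets["context"]),
                primer_fwd=seq[:20],
                primer_rev=reverse_complement(seq[-20:]),
                naive_c_offsets=tuple(int(o) for o in naive["offset"]),
            )
        )
    return AmpliconPanel(probes=tuple(probes))


def write_panel(
    panel: AmpliconPanel, panel_fasta: str | Path, sites_table: str | Path
) -> None:
    """Write a panel back to FASTA + sites TSV (inverse of :func:`load_panel`)."""
    SeqIO.write(
        [SeqRecord(Seq(p.reference_seq), id=p.probe_id, description="") for p in panel],
        str(panel_fasta),
        "fasta",
    )
    rows = []
    for p in panel:
        for off, ctx in zip(p.target_offsets, p.site_context):
            rows.append((p.probe_id, off, ctx, "target"))
        for off in p.naive_c_offsets:
            rows.append((p.probe_id, off, ".", "naive"))
    pd.DataFrame(rows, columns=["probe_id", "offset", "context", "role"]).to_csv(
        sites_table, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Bundled default panel
# ---------------------------------------------------------------------------

_DEFAULT_SEED = 4
_DEFAULT_LENGTHS = (172, 158, 181, 166, 150, 175, 190, 163, 169, 177)
# annotated-naive quota per probe; sums to 92
_NAIVE_QUOTA = (9, 9, 9, 9, 9, 9, 9, 10, 10, 9)


def default_panel() -> AmpliconPanel:
    """The bundled 10-probe synthetic LINE-1-like panel.

    Sequences are generated deterministically with CpG density typical of
    young LINE-1 consensus amplicons; they are synthetic stand-ins, not
    genomic primer products.  Probes P1-P7 score CpG sites only; P8-P10
    additionally score CpA sites.  Exactly 92 naive cytosines are
    annotated across the panel for conversion-rate estimation.
    """
    rng = np.random.default_rng(_DEFAULT_SEED)
    probes = []
    for k, length in enumerate(_DEFAULT_LENGTHS):
        probe_id = PROBE_IDS[k]
        seq = "".join(rng.choice(list("ACGT"), size=length, p=[0.34, 0.21, 0.19, 0.26]))
        if seq[-1] == "C":  # trailing C has no dinucleotide context
            seq = seq[:-1] + "A"
        cpg = [i for i in range(length - 1) if seq[i : i + 2] == "CG"]
        cpa = [i for i in range(length - 1) if seq[i : i + 2] == "CA"]
        if probe_id in NON_CPG_PROBES:
            targets = sorted(cpg + cpa)
            contexts = tuple("CpG" if seq[i + 1] == "G" else "CpA" for i in targets)
        else:
            targets = cpg
            contexts = tuple("CpG" for _ in targets)
        naive_candidates = [
            i for i in range(length - 1) if seq[i] == "C" and seq[i + 1] in "CT"
        ]
        naive = tuple(naive_candidates[: _NAIVE_QUOTA[k]])
        probes.append(
            ProbeTarget(
                probe_id=probe_id,
                reference_seq=seq,
                target_offsets=tuple(targets),
                site_context=contexts,
                primer_fwd=seq[:20],
                primer_rev=reverse_complement(seq[-20:]),
                naive_c_offsets=naive,
            )
        )
    panel = AmpliconPanel(probes=tuple(probes))
    assert panel.total_naive_c == 92
    return panel
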