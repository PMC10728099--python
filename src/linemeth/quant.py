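"""Bisulfite amplicon read quantification.

Turns raw amplicon reads into per-probe beta values:

1. assign each read to a (probe, strand) by bisulfite-tolerant gapped
   alignment against the panel references;
2. remove reads with indels near the target region (+/- 30 nt);
3. count methylated vs converted base observations, strand-separated and
   pooled per probe;
4. estimate the sample bisulfite conversion rate from naive cytosines;
5. beta = M / (U + M) * sample_conversion_rate.

Strand chemistry in Watson coordinates: a Watson read shows a scored
cytosine as C (methylated) or T (converted).  A Crick read, after reverse
complementing into Watson coordinates, shows methylation at the *paired
guanine* of a CpG (offset + 1) as G (methylated) or A (converted); CpA
sites are asymmetric (the Crick strand carries TpG, no cytosine) and are
therefore scored from Watson reads only.  The same logic gives Crick-read
conversion observations at Crick-strand naive cytosines, i.e. Watson G
positions outside Crick CpG/CpA context.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import edlib
import numpy as np
from Bio import SeqIO

from .panel import AmpliconPanel, ProbeTarget, reverse_complement

WATSON = "watson"
CRICK = "crick"

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AssignedRead:
    """A read assigned to one probe and strand, in Watson coordinates.

    ``bases`` maps reference offset -> observed read base (aligned
    positions only); ``indel_ref_positions`` holds reference offsets
    touched by insertions or deletions.
    """

    probe_id: str
    strand: str
    bases: dict[int, str]
    indel_ref_positions: tuple[int, ...]
    n_edits: int
    read_name: str = ""

    @property
    def has_indel(self) -> bool:
        return bool(self.indel_ref_positions)


@dataclass
class ProbeCounts:
    """Pooled methylated (M) / converted (U) tallies for one probe."""

    probe_id: str
    M: int
    U: int
    depth: int

    def __post_init__(self) -> None:
        if self.M < 0 or self.U < 0:
            raise ValueError("negative methylation counts")


@dataclass
class ConversionEstimate:
    """Sample bisulfite conversion rate from naive cytosines."""

    rate: float
    n_observations: int
    n_positions: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"conversion rate {self.rate} outside [0, 1]")


@dataclass
class BetaVector:
    """Per-sample, per-probe beta values with QC metadata."""

    sample_id: str
    beta: dict[str, float]  # NaN marks missing
    conversion_rate: float
    per_probe_depth: dict[str, int]
    n_assigned: int = 0
    n_unassigned: int = 0
    n_indel_removed: int = 0

    def is_missing(self, probe_id: str) -> bool:
        return math.isnan(self.beta.get(probe_id, float("nan")))


@dataclass
class QuantConfig:
    """Tunables for the read-to-beta pipeline."""

    indel_window: int = 30          # nt around the target region
    min_depth: int = 100            # reads/probe below which beta is missing
    min_read_length: int = 30       # shorter reads are dropped pre-alignment
    max_edit_fraction: float = 0.1  # unassigned above this edit/length ratio
    context: str = "auto"           # 'auto' | 'cpg_only' | 'cpg_and_cpa'


def required_reads(resolution: float = 0.005, n_loci: int = 2000) -> int:
    """Read budget for a given per-locus methylation resolution.

    Resolving methylation differences of ``resolution`` at a single locus
    needs 1/resolution observations; the LINE-1 probes collectively map to
    about 2000 genomic copies, so the per-sample target is
    (1/resolution) * n_loci reads (400,000 at the defaults).
    """
    if resolution <= 0 or n_loci <= 0:
        raise ValueError("resolution and n_loci must be positive")
    return round((1.0 / resolution) * n_loci)


# ---------------------------------------------------------------------------
# Read ingestion
# ---------------------------------------------------------------------------

def read_fastq(*paths: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from one or more FASTQ files (mates pooled)."""
    for path in paths:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield rec.id, str(rec.seq).upper()


def reads_from_sam(path: str | Path, panel: AmpliconPanel) -> list[AssignedRead]:
    """Ingest pre-aligned reads from SAM/BAM with panel probes as references.

    Strand is taken from the reverse flag (forward = Watson), aligned bases
    from the alignment pairs, indels from the CIGAR.
    """
    import pysam

    out: list[AssignedRead] = []
    ids = set(panel.probe_ids)
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name not in ids:
                continue
            seq = rec.query_sequence or ""
            bases: dict[int, str] = {}
            indels: list[int] = []
            last_ref = None
            for qpos, rpos in rec.get_aligned_pairs():
                if qpos is not None and rpos is not None:
                    bases[rpos] = seq[qpos]
                    last_ref = rpos
                elif rpos is not None:  # deletion in read
                    indels.append(rpos)
                elif last_ref is not None:  # insertion after last_ref
                    indels.append(last_ref + 1)
            out.append(
                AssignedRead(
                    probe_id=rec.reference_name,
                    strand=CRICK if rec.is_reverse else WATSON,
                    bases=bases,
                    indel_ref_positions=tuple(sorted(set(indels))),
                    n_edits=0,
                    read_name=rec.query_name or "",
                )
            )
    return out


# ---------------------------------------------------------------------------
# Alignment / assignment
# ---------------------------------------------------------------------------

def _align_events(cigar: str, ref_start: int, query: str):
    """Walk an edlib extended CIGAR into per-offset bases and indel positions."""
    bases: dict[int, str] = {}
    indels: list[int] = []
    rpos, qpos = ref_start, 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op in "=XM":
            for i in range(n):
                bases[rpos + i] = query[qpos + i]
            rpos += n
            qpos += n
        elif op == "I":
            indels.append(rpos)
            qpos += n
        elif op == "D":
            indels.extend(range(rpos, rpos + n))
            rpos += n
    return bases, indels


# bisulfite-consistent equalities per strand: on Watson, read T may stand
# for an unmethylated reference C; on Crick (revcomp view), read A for G.
_EQ = {WATSON: [("T", "C")], CRICK: [("A", "G")]}


def assign_reads(
    reads: Iterable[tuple[str, str] | str],
    panel: AmpliconPanel,
    config: QuantConfig | None = None,
) -> tuple[list[AssignedRead], int]:
    """Assign reads to (probe, strand) by best bisulfite-tolerant alignment.

    Returns (assigned reads, number unassigned).  A read is unassigned when
    its best edit distance exceeds ``max_edit_fraction`` of its length or
    when two probes tie for best.  Empty input yields empty output.
    """
    config = config or QuantConfig()
    assigned: list[AssignedRead] = []
    n_unassigned = 0
    for i, item in enumerate(reads):
        name, seq = item if isinstance(item, tuple) else (f"read{i}", item)
        if not seq or not re.fullmatch(r"[ACGTN]+", seq):
            raise ValueError(f"malformed read record at index {i}: {name!r}")
        if len(seq) < config.min_read_length:
            n_unassigned += 1
            continue
        rc = reverse_complement(seq)
        best_d = None
        best = None
        ambiguous = False
        for probe in panel:
            ref = probe.reference_seq
            for strand in (WATSON, CRICK):
                for oriented in (seq, rc):
                    res = edlib.align(
                        oriented, ref, mode="HW", task="distance",
                        additionalEqualities=_EQ[strand],
                    )
                    d = res["editDistance"]
                    if best_d is None or d < best_d:
                        best_d = d
                        best = (probe, strand, oriented)
                        ambiguous = False
                    elif d == best_d and best is not None and probe.probe_id != best[0].probe_id:
                        ambiguous = True
        assert best is not None and best_d is not None
        if ambiguous or best_d > config.max_edit_fraction * len(seq):
            n_unassigned += 1
            continue
        probe, strand, oriented = best
        path = edlib.align(
            oriented, probe.reference_seq, mode="HW", task="path",
            additionalEqualities=_EQ[strand],
        )
        start = path["locations"][0][0]
        bases, indels = _align_events(path["cigar"], start, oriented)
        assigned.append(
            AssignedRead(
                probe_id=probe.probe_id,
                strand=strand,
                bases=bases,
                indel_ref_positions=tuple(sorted(set(indels))),
                n_edits=best_d,
                read_name=name,
            )
        )
    return assigned, n_unassigned


def filter_indel_reads(
    reads: Sequence[AssignedRead],
    panel: AmpliconPanel,
    window: int = 30,
) -> tuple[list[AssignedRead], int]:
    """Drop reads with an indel inside [region.start - window, region.end + window).

    Returns (retained reads, number removed).  Output order follows input
    order, so the operation is order-independent as a set.
    """
    if window < 0:
        raise ValueError(f"indel window must be non-negative, got {window}")
    kept: list[AssignedRead] = []
    removed = 0
    regions = {p.probe_id: p.region for p in panel}
    for read in reads:
        start, end = regions[read.probe_id]
        lo, hi = start - window, end + window
        if any(lo <= pos < hi for pos in read.indel_ref_positions):
            removed += 1
        else:
            kept.append(read)
    return kept, removed


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_methylation(
    reads: Iterable[AssignedRead],
    probe: ProbeTarget,
    context_mode: str = "cpg_and_cpa",
) -> ProbeCounts:
    """Pool strand-separated methylated/converted tallies into one (M, U).

    Watson reads: C at a scored offset counts M, T counts U.  Crick reads:
    G at the CpG's paired guanine (offset + 1) counts M, A counts U; CpA
    sites contribute nothing on Crick.  Other bases are ignored.
    """
    if not probe.target_offsets:
        raise ValueError(f"{probe.probe_id}: no target offsets to count")
    offsets = probe.scored_offsets(context_mode)
    contexts = dict(zip(probe.target_offsets, probe.site_context))
    M = U = depth = 0
    for read in reads:
        if read.probe_id != probe.probe_id:
            raise ValueError(
                f"read {read.read_name!r} assigned to {read.probe_id}, "
                f"not {probe.probe_id}"
            )
        depth += 1
        if read.strand == WATSON:
            for off in offsets:
                base = read.bases.get(off)
                if base == "C":
                    M += 1
                elif base == "T":
                    U += 1
        else:
            for off in offsets:
                if contexts[off] != "CpG":
                    continue
                base = read.bases.get(off + 1)
                if base == "G":
                    M += 1
                elif base == "A":
                    U += 1
    return ProbeCounts(probe_id=probe.probe_id, M=M, U=U, depth=depth)


def estimate_conversion_rate(
    reads: Iterable[AssignedRead], panel: AmpliconPanel
) -> ConversionEstimate:
    """Mean per-position bisulfite conversion over the panel's naive cytosines.

    Watson reads are scored at the annotated naive C offsets (T converted,
    C unconverted); Crick reads at the derived Crick-strand naive
    positions (A converted, G unconverted).  The rate is the unweighted
    mean of per-position conversion fractions over positions with at least
    one observation.
    """
    conv: dict[tuple[str, str, int], int] = {}
    tot: dict[tuple[str, str, int], int] = {}
    naive_w = {p.probe_id: p.naive_c_offsets for p in panel}
    naive_c = {p.probe_id: p.crick_naive_g_offsets() for p in panel}
    for read in reads:
        if read.strand == WATSON:
            for off in naive_w[read.probe_id]:
                base = read.bases.get(off)
                if base in ("C", "T"):
                    key = (read.probe_id, WATSON, off)
                    tot[key] = tot.get(key, 0) + 1
                    if base == "T":
                        conv[key] = conv.get(key, 0) + 1
        else:
            for off in naive_c[read.probe_id]:
                base = read.bases.get(off)
                if base in ("G", "A"):
                    key = (read.probe_id, CRICK, off)
                    tot[key] = tot.get(key, 0) + 1
                    if base == "A":
                        conv[key] = conv.get(key, 0) + 1
    if not tot:
        raise ValueError("conversion rate unavailable: no naive-cytosine observations")
    fractions = [conv.get(k, 0) / n for k, n in tot.items()]
    return ConversionEstimate(
        rate=float(np.mean(fractions)),
        n_observations=int(sum(tot.values())),
        n_positions=len(tot),
    )


def compute_beta(
    counts: ProbeCounts,
    conversion: ConversionEstimate | float,
    min_depth: int = 0,
) -> float:
    """beta = M / (U + M) * sample_conversion_rate, clipped to [0, 1].

    Returns NaN when M + U == 0 or probe depth is below ``min_depth``.
    """
    rate = conversion.rate if isinstance(conversion, ConversionEstimate) else float(conversion)
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"conversion rate {rate} outside [0, 1]")
    if counts.M + counts.U == 0 or counts.depth < min_depth:
        return float("nan")
    beta = counts.M / (counts.U + counts.M) * rate
    return float(min(1.0, max(0.0, beta)))


def quantify_sample(
    reads: Iterable[tuple[str, str] | str],
    panel: AmpliconPanel,
    config: QuantConfig | None = None,
    sample_id: str = "sample",
) -> BetaVector:
    """Full pipeline: assign, indel-filter, count, correct, per-probe beta.

    ``config.context='auto'`` scores CpG+CpA on the non-CpG probes
    (those annotating CpA targets) and CpG only elsewhere; 'cpg_only'
    forces CpG everywhere (for methylation-array comparability).
    """
    config = config or QuantConfig()
    assigned, n_unassigned = assign_reads(reads, panel, config)
    kept, n_removed = filter_indel_reads(assigned, panel, window=config.indel_window)
    by_probe: dict[str, list[AssignedRead]] = {pid: [] for pid in panel.probe_ids}
    for read in kept:
        by_probe[read.probe_id].append(read)

    try:
        conversion = estimate_conversion_rate(kept, panel)
        rate = conversion.rate
    except ValueError:
        rate = float("nan")

    beta: dict[str, float] = {}
    depth: dict[str, int] = {}
    for probe in panel:
        probe_reads = by_probe[probe.probe_id]
        depth[probe.probe_id] = len(probe_reads)
        if not probe_reads or math.isnan(rate):
            beta[probe.probe_id] = float("nan")
            continue
        if config.context == "auto":
            mode = "cpg_and_cpa" if "CpA" in probe.site_context else "cpg_only"
        else:
            mode = config.context
        counts = count_methylation(probe_reads, probe, context_mode=mode)
        beta[probe.probe_id] = compute_beta(counts, rate, min_depth=config.min_depth)

    return BetaVector(
        sample_id=sample_id,
        beta=beta,
        conversion_rate=rate,
        per_probe_depth=depth,
        n_assigned=len(assigned),
        n_unassigned=n_unassigned,
        n_indel_removed=n_removed,
    )
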