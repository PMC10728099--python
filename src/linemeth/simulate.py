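"""Synthetic cohorts and bisulfite amplicon reads with known truth.

Two generators back the test suite and desk-scale experiments:

* :func:`simulate_cohort` builds whole cohorts (beta matrices + clinical
  tables) under a two-component mixture: each specimen's beta is a blend
  of the patient's true tumor methylation ``m`` and a near-constant
  normal (PBMC-like) level.  Tissue blends by tumor purity ``p``; cfDNA
  blends by ctDNA fraction ``f`` drawn independently of ``p`` — which is
  exactly the structure that makes tissue betas purity-confounded while
  cfDNA betas are not.  Survival follows an exponential model with a
  log-linear hazard in mean tumor methylation (hypomethylated tumors,
  being more ICB-resistant in this model, progress faster).

* :func:`simulate_reads` emits per-read bisulfite sequences from a panel
  at known per-probe methylation and conversion rate, for end-to-end
  validation of the quantification pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import AmpliconPanel, reverse_complement

#: probe-specific mean tumor methylation (LINE-1 betas cluster near 0.5-0.65
#: in hypomethylating tumors, against a high normal background)
_DEFAULT_PROBE_MEANS = (0.55, 0.60, 0.58, 0.62, 0.57, 0.65, 0.60, 0.52, 0.56, 0.63)
_DEFAULT_CONCENTRATION = 30.0


@dataclass
class CohortSpec:
    """Generative description of one synthetic ICB cohort.

    ``gamma`` is the log-hazard slope per unit of (mean-centred) mean
    tumor methylation: gamma = 0 removes the methylation-survival link.
    ``probe_correlation`` couples a patient's probes through a Gaussian
    copula, reflecting genome-wide hypomethylation acting on all LINE-1
    copies at once.
    """

    n_patients: int = 100
    probe_ids: tuple[str, ...] = tuple(f"P{i}" for i in range(1, 11))
    tumor_beta_params: tuple[tuple[float, float], ...] = tuple(
        (m * _DEFAULT_CONCENTRATION, (1 - m) * _DEFAULT_CONCENTRATION)
        for m in _DEFAULT_PROBE_MEANS
    )
    normal_level: float = 0.80          # PBMC-like background, invariably high
    purity_range: tuple[float, float] = (0.1, 0.9)
    ctdna_range: tuple[float, float] = (0.2, 0.5)
    probe_correlation: float = 0.8
    gamma: float = 8.0                  # log-hazard per unit mean methylation
    baseline_hazard: float = 1.0 / 500  # events/day at cohort-mean methylation
    censor_ratio: float = 0.4           # censoring hazard / baseline hazard
    response_noise: float = 0.04        # latent-score noise for DCB assignment
    measurement_depth: int = 5000       # binomial reads/probe for beta noise
    endpoint_kind: str = "overall"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not 0 <= self.normal_level <= 1:
            raise ValueError("normal_level must be in [0, 1]")
        for lo, hi in (self.purity_range, self.ctdna_range):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("fraction ranges must satisfy 0 <= lo <= hi <= 1")
        if len(self.tumor_beta_params) != len(self.probe_ids):
            raise ValueError("one (a, b) pair per probe required")
        for a, b in self.tumor_beta_params:
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be positive")


@dataclass
class SimulatedCohort:
    """Beta matrices per specimen source, clinical table, and full truth."""

    tissue: pd.DataFrame
    cfdna: pd.DataFrame
    pbmc: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec


def _tumor_methylation(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Patients x probes matrix of true tumor methylation via Gaussian copula."""
    n, k = spec.n_patients, len(spec.probe_ids)
    rho = spec.probe_correlation
    z_patient = rng.standard_normal((n, 1))
    z = rho * z_patient + np.sqrt(1 - rho**2) * rng.standard_normal((n, k))
    u = stats.norm.cdf(z)
    m = np.empty((n, k))
    for j, (a, b) in enumerate(spec.tumor_beta_params):
        m[:, j] = stats.beta.ppf(u[:, j], a, b)
    return m


def _measure(betas: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Binomial measurement noise at the configured read depth."""
    if depth <= 0:
        return betas
    return rng.binomial(depth, np.clip(betas, 0, 1)) / depth


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate one cohort; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    probes = list(spec.probe_ids)
    patient_ids = [f"PT{i + 1:04d}" for i in range(n)]

    m = _tumor_methylation(spec, rng)
    mbar = m.mean(axis=1)
    p = rng.uniform(*spec.purity_range, size=n)
    f = rng.uniform(*spec.ctdna_range, size=n)  # independent of p by construction

    tissue_true = p[:, None] * m + (1 - p[:, None]) * spec.normal_level
    cfdna_true = f[:, None] * m + (1 - f[:, None]) * spec.normal_level
    pbmc_true = np.full((n, len(probes)), spec.normal_level)

    depth = spec.measurement_depth
    tissue = _measure(tissue_true, depth, rng)
    cfdna = _measure(cfdna_true, depth, rng)
    pbmc = _measure(pbmc_true, depth, rng)

    # exponential survival, log-linear hazard in mean tumor methylation
    hazard = spec.baseline_hazard * np.exp(-spec.gamma * (mbar - mbar.mean()))
    t_event = rng.exponential(1.0 / hazard)
    censor_hazard = spec.baseline_hazard * spec.censor_ratio
    t_censor = rng.exponential(1.0 / censor_hazard, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    latent = mbar + rng.normal(0, spec.response_noise, size=n)
    response = np.where(latent > np.median(mbar), "DCB", "NDB")

    idx = pd.Index(patient_ids, name="patient_id")
    clinical = pd.DataFrame(
        {
            "sample_id": patient_ids,
            "time": time,
            "event": event,
            "response": response,
            "endpoint_kind": spec.endpoint_kind,
            "timepoint": "baseline",
        },
        index=idx,
    )
    truth = pd.DataFrame(
        {
            **{f"m_{pr}": m[:, j] for j, pr in enumerate(probes)},
            "m_mean": mbar,
            "purity": p,
            "ctdna_fraction": f,
            "hazard": hazard,
            "time": time,
            "event": event,
        },
        index=idx,
    )
    return SimulatedCohort(
        tissue=pd.DataFrame(tissue, index=idx, columns=probes),
        cfdna=pd.DataFrame(cfdna, index=idx, columns=probes),
        pbmc=pd.DataFrame(pbmc, index=idx, columns=probes),
        clinical=clinical,
        truth=truth,
        spec=spec,
    )


def simulate_progression_pair(
    spec: CohortSpec,
    methylation_drift: float = -0.05,
    ctdna_increase: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulatedCohort]:
    """Matched baseline / progression cfDNA matrices for one cohort.

    At progression the true tumor methylation drifts by
    ``methylation_drift`` (negative = progressive hypomethylation) and the
    ctDNA fraction rises by ``ctdna_increase``; both are clipped to [0, 1].
    A (0, 0) setting gives a stable cohort whose deltas are pure
    measurement noise.
    """
    cohort = simulate_cohort(spec)
    rng = np.random.default_rng(spec.seed + 1)
    probes = list(spec.probe_ids)
    m0 = cohort.truth[[f"m_{p}" for p in probes]].to_numpy()
    f0 = cohort.truth["ctdna_fraction"].to_numpy()
    m1 = np.clip(m0 + methylation_drift, 0, 1)
    f1 = np.clip(f0 + ctdna_increase, 0, 1)
    cfdna1_true = f1[:, None] * m1 + (1 - f1[:, None]) * spec.normal_level
    cfdna1 = _measure(cfdna1_true, spec.measurement_depth, rng)
    t1 = pd.DataFrame(cfdna1, index=cohort.cfdna.index, columns=probes)
    return cohort.cfdna, t1, cohort


# ---------------------------------------------------------------------------
# Read-level simulator
# ---------------------------------------------------------------------------

def simulate_reads(
    panel: AmpliconPanel,
    m: dict[str, float] | float,
    conversion_rate: float = 1.0,
    depth: int = 1000,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit ``depth`` bisulfite reads per probe at known methylation.

    Per read: strand uniform.  On Watson, each scored cytosine stays C
    with probability ``m`` (methylated) and otherwise converts to T with
    probability ``conversion_rate``; every other cytosine converts as
    unmethylated.  Crick reads apply the mirrored logic to guanines in
    Watson coordinates (CpG methylation protects the paired G) and are
    emitted reverse-complemented.  ``indel_rate`` is the per-read chance
    of one random 1-2 nt deletion.  Returns (reads, truth table with one
    row per read).  depth = 0 yields an empty read set.
    """
    if not 0 < conversion_rate <= 1:
        raise ValueError("conversion_rate must be in (0, 1]")
    m_by_probe = (
        {p.probe_id: float(m) for p in panel} if np.isscalar(m) else dict(m)
    )
    for pid, val in m_by_probe.items():
        if not 0 <= val <= 1:
            raise ValueError(f"methylation for {pid} outside [0, 1]")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth_rows = []
    for probe in panel:
        ref = probe.reference_seq
        m_p = m_by_probe[probe.probe_id]
        cpg = set(probe.cpg_offsets())
        targets = set(probe.target_offsets)
        paired_g = {i + 1 for i in cpg}
        for r in range(depth):
            watson = rng.random() < 0.5
            seq = list(ref)
            if watson:
                for i, base in enumerate(ref):
                    if base != "C":
                        continue
                    if i in targets:
                        if rng.random() < m_p:
                            continue  # methylated, protected
                    if rng.random() < conversion_rate:
                        seq[i] = "T"
            else:
                for i, base in enumerate(ref):
                    if base != "G":
                        continue
                    if i in paired_g:
                        if rng.random() < m_p:
                            continue
                    if rng.random() < conversion_rate:
                        seq[i] = "A"
            has_indel = indel_rate > 0 and rng.random() < indel_rate
            if has_indel:
                width = int(rng.integers(1, 3))
                pos = int(rng.integers(0, len(seq) - width))
                del seq[pos : pos + width]
            out = "".join(seq)
            if not watson:
                out = reverse_complement(out)
            name = f"{probe.probe_id}:{'W' if watson else 'C'}:{r}"
            reads.append((name, out))
            truth_rows.append(
                {
                    "read_name": name,
                    "probe_id": probe.probe_id,
                    "strand": "watson" if watson else "crick",
                    "has_indel": has_indel,
                }
            )
    return reads, pd.DataFrame(truth_rows)


def write_fastq(reads, path) -> None:
    """Write (name, seq) pairs as a plain FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
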