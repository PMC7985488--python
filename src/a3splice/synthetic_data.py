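"""Synthetic cohorts with the statistical structure the analysis assumes.

Generates, with known ground truth: per-sample isoform mixtures over the two
homologous paralogs (with NMD depletion of the frameshifted isoform and a
tumor/normal shift of exon-5 inclusion), error-bearing RNA-seq reads,
mutation catalogs whose tCw burden rises with canonical-isoform expression,
exponential progression-free survival scaled by expression group, qPCR Ct
tables, and densitometry band tables.

All randomness derives from ``SimulationConfig.seed`` through fixed
substreams: ``default_rng([seed, purpose, index])`` where purpose is 0 for
the cohort, 1 for reads, 2 for mutations, 3 for qPCR, 4 for densitometry,
and 5 for the mutation reference sequence, and index is the sample's ordinal.
Adding samples therefore never perturbs earlier ones.
"""

from __future__ import annotations

import functools
import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gene_models import GeneModel, IsoformModel, paralog_fixture

__all__ = [
    "SimulationConfig",
    "CohortSample",
    "SimulatedRead",
    "MutationRecord",
    "simulate_cohort",
    "simulate_reads",
    "simulate_mutations",
    "mutation_context_windows",
    "simulate_qpcr",
    "simulate_densitometry",
    "reads_to_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``depth`` is the expected read count for a fully expressed isoform;
    ``psi_tumor``/``psi_normal`` are the exon-5 inclusion fractions the two
    conditions draw from (Beta-distributed around these means);
    ``nmd_retention`` is the fraction of exon-5-skipped transcripts that
    survive nonsense-mediated decay; ``burden_slope`` links log10 canonical
    expression to the expected tCw mutation count; ``hazard_ratios`` scale
    the exponential progression hazard of the No/Low/High expression groups.
    """

    seed: int = 0
    n_pairs: int = 30
    read_len: int = 100
    error_rate: float = 0.005
    depth: float = 2000.0
    paralog_identity: float = 0.92
    nmd_retention: float = 0.15
    psi_tumor: float = 0.95
    psi_normal: float = 0.85
    psi_concentration: float = 60.0
    a3b2_fraction: float = 0.05
    a3a2_fraction: float = 0.03
    expr_sigma: float = 0.6
    zero_rate_a: float = 0.35
    zero_rate_b: float = 0.15
    burden_slope: float = 0.30
    burden_intercept: float = 0.3
    background_c_mean: float = 30.0
    background_t_mean: float = 10.0
    hazard_ratios: tuple[float, float, float] = (1.0, 2.0, 4.0)
    base_median_survival: float = 40.0
    followup_horizon: float = 60.0
    reference_length: int = 100_000

    def __post_init__(self):
        for name in (
            "error_rate", "paralog_identity", "nmd_retention", "psi_tumor",
            "psi_normal", "a3b2_fraction", "a3a2_fraction", "zero_rate_a",
            "zero_rate_b",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not np.isfinite(self.burden_slope):
            raise ValueError("burden_slope must be finite")
        object.__setattr__(self, "hazard_ratios", tuple(self.hazard_ratios))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hazard_ratios"] = list(self.hazard_ratios)
        return d


@dataclass
class CohortSample:
    sample_id: str
    condition: str  # "tumor" | "normal"
    pair_id: str
    sex: str
    age: float
    stage: int
    followup_time: float
    progression_event: bool
    true_isoform_abundances: dict[str, float]
    true_psi: float
    expression_group: str | None = None  # ground-truth No/Low/High (tests only)

    def __post_init__(self):
        if self.followup_time <= 0:
            raise ValueError("followup_time must be > 0")
        if self.condition not in ("tumor", "normal"):
            raise ValueError(f"bad condition {self.condition!r}")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str
    true_isoform: str
    true_offset: int

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError("quality length must equal sequence length")


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    position: int
    ref_base: str
    alt_base: str
    trinucleotide_context: str  # pyrimidine-centred, 5'->3'

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt must differ")


def _rng(config: SimulationConfig, purpose: int, index: int = 0):
    return np.random.default_rng([int(config.seed) % (2**31), purpose, index])


def _stable_id(sample_id: str) -> int:
    """Deterministic, collision-resistant integer tag for a sample id."""
    return int.from_bytes(hashlib.sha256(sample_id.encode()).digest()[:4], "big")


def default_models(config: SimulationConfig):
    """The fixture gene/isoform pair at this config's paralog identity."""
    return paralog_fixture(identity=config.paralog_identity, seed=0)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _beta_around(mean: float, conc: float, rng) -> float:
    if mean <= 0.0 or mean >= 1.0:
        return float(mean)
    return float(rng.beta(mean * conc, (1.0 - mean) * conc))


def simulate_cohort(config: SimulationConfig) -> list[CohortSample]:
    """2*n_pairs samples in tumor/normal pairs with ground-truth abundances.

    Expected isoform counts: the exon-5 inclusion fraction psi (drawn per
    sample from the condition's Beta) splits the non-cryptic share of gene-B
    transcription between the canonical isoform and the exon-5 skip; the
    skipped isoform's expected count is then multiplied by ``nmd_retention``.
    Survival times are exponential with hazard scaled by the sample's
    expression group (No/Low/High over ground-truth canonical counts).
    """
    samples: list[CohortSample] = []
    for i in range(config.n_pairs):
        rng = _rng(config, 0, i)
        pair_id = f"P{i:04d}"
        sex = "F" if rng.random() < 0.5 else "M"
        age = float(np.clip(rng.normal(65.0, 10.0), 30.0, 90.0))
        stage = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
        f_a = 0.0 if rng.random() < config.zero_rate_a else float(
            rng.lognormal(0.0, config.expr_sigma))
        f_b = 0.0 if rng.random() < config.zero_rate_b else float(
            rng.lognormal(0.0, config.expr_sigma))
        for condition in ("normal", "tumor"):
            psi_mean = config.psi_tumor if condition == "tumor" else config.psi_normal
            psi = _beta_around(psi_mean, config.psi_concentration, rng)
            # paired samples share the pair's expression scale up to noise
            fa = f_a * float(rng.lognormal(0.0, 0.2)) if f_a > 0 else 0.0
            fb = f_b * float(rng.lognormal(0.0, 0.2)) if f_b > 0 else 0.0
            w2 = config.a3b2_fraction
            abundances = {
                "A3A1": config.depth * fa * (1.0 - config.a3a2_fraction),
                "A3A2": config.depth * fa * config.a3a2_fraction,
                "A3B1": config.depth * fb * (1.0 - w2) * psi,
                "A3B2": config.depth * fb * w2,
                "A3B3": config.depth * fb * (1.0 - w2) * (1.0 - psi)
                        * config.nmd_retention,
            }
            samples.append(
                CohortSample(
                    sample_id=f"S{i:04d}{'T' if condition == 'tumor' else 'N'}",
                    condition=condition,
                    pair_id=pair_id,
                    sex=sex,
                    age=age,
                    stage=stage,
                    followup_time=1.0,  # placeholder, filled below
                    progression_event=False,
                    true_isoform_abundances=abundances,
                    true_psi=psi,
                )
            )

    # expression grouping over ground-truth canonical gene-B counts
    counts = np.array([s.true_isoform_abundances["A3B1"] for s in samples])
    nonzero = counts[counts > 0]
    median = float(np.median(nonzero)) if nonzero.size else 0.0
    hr = dict(zip(("No", "Low", "High"), config.hazard_ratios))
    base_rate = np.log(2.0) / config.base_median_survival
    for k, s in enumerate(samples):
        c = counts[k]
        group = "No" if c == 0 else ("High" if c > median else "Low")
        s.expression_group = group
        rng = _rng(config, 0, 10_000 + k)
        t = float(rng.exponential(1.0 / (base_rate * hr[group])))
        s.followup_time = max(min(t, config.followup_horizon), 1e-3)
        s.progression_event = t <= config.followup_horizon
    return samples


def cohort_table(samples: list[CohortSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id, "condition": s.condition,
            "pair_id": s.pair_id, "sex": s.sex, "age": s.age,
            "stage": s.stage, "followup_time": s.followup_time,
            "progression_event": int(s.progression_event),
        }
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(
    sample: CohortSample,
    isoforms: dict[str, IsoformModel],
    genes: dict[str, GeneModel],
    config: SimulationConfig,
) -> list[SimulatedRead]:
    """Poisson read counts per isoform, uniform starts, iid substitution errors.

    Read counts follow the standard RNA-seq sampling model: the expected
    count is the isoform's abundance scaled by its effective length
    (fragment start positions) relative to the parent gene's canonical
    isoform, so equal abundances of a long and a short isoform yield equal
    junction-read counts and junction PSI is an unbiased abundance ratio.
    """
    rng = _rng(config, 1, _stable_id(sample.sample_id))
    reads: list[SimulatedRead] = []
    qual = "I" * config.read_len
    for iso_id in sorted(sample.true_isoform_abundances):
        abundance = sample.true_isoform_abundances[iso_id]
        if abundance <= 0:
            continue
        iso = isoforms[iso_id]
        mrna = iso.mrna(genes[iso.parent_gene])
        if config.read_len > len(mrna):
            raise ValueError(
                f"read_len {config.read_len} exceeds mRNA of {iso_id} ({len(mrna)} nt)"
            )
        canonical_len = len(genes[iso.parent_gene].mrna)
        eff = (len(mrna) - config.read_len + 1) / (canonical_len - config.read_len + 1)
        n = int(rng.poisson(abundance * eff))
        if n == 0:
            continue
        starts = rng.integers(0, len(mrna) - config.read_len + 1, size=n)
        arr = np.frombuffer(mrna.encode(), dtype="S1")
        idx = starts[:, None] + np.arange(config.read_len)[None, :]
        mat = arr[idx]
        if config.error_rate > 0:
            mask = rng.random(mat.shape) < config.error_rate
            if mask.any():
                # substitute with one of the three other bases
                shift = rng.integers(1, 4, size=int(mask.sum()))
                base_idx = np.searchsorted(_BASES, mat[mask])
                mat[mask] = _BASES[(base_idx + shift) % 4]
        seqs = mat.view(f"S{config.read_len}").ravel()
        for k in range(n):
            reads.append(
                SimulatedRead(
                    read_id=f"{sample.sample_id}:{iso_id}:{k}",
                    sequence=seqs[k].decode(),
                    quality=qual,
                    true_isoform=iso_id,
                    true_offset=int(starts[k]),
                )
            )
    return reads


def reads_to_fastq(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=4)
def _reference_sequence(seed: int, length: int) -> str:
    rng = np.random.default_rng([seed % (2**31), 5])
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@functools.lru_cache(maxsize=4)
def _site_classes(seed: int, length: int):
    """Positions of tCw-context C/G sites, other C/G sites, and T/A sites."""
    ref = _reference_sequence(seed, length)
    arr = np.frombuffer(ref.encode(), dtype="S1")
    tcw, other_cg, ta = [], [], []
    for i in range(20, length - 20):
        b = arr[i]
        if b in (b"C", b"G"):
            tri = ref[i - 1 : i + 2]
            if b == b"G":
                tri = tri.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            (tcw if tri[0] == "T" and tri[2] in "AT" else other_cg).append(i)
        elif b in (b"T", b"A"):
            ta.append(i)
    return np.array(tcw), np.array(other_cg), np.array(ta)


_PYR_COMP = str.maketrans("ACGT", "TGCA")


def _pyrimidine_context(ref: str, pos: int) -> tuple[str, str]:
    """(normalised trinucleotide, normalised ref base) at pos."""
    tri = ref[pos - 1 : pos + 2]
    if ref[pos] in "GA":
        tri = tri.translate(_PYR_COMP)[::-1]
    return tri, tri[1]


def simulate_mutations(
    sample: CohortSample, config: SimulationConfig
) -> list[MutationRecord]:
    """Mutation catalog whose tCw count tracks canonical gene-B expression.

    tCw mutations: Poisson with mean exp(intercept + slope*log10(1 + x))
    where x is the sample's expected canonical-isoform count; background C
    and T mutations are expression-independent.
    """
    ref = _reference_sequence(config.seed, config.reference_length)
    tcw_sites, cg_sites, ta_sites = _site_classes(config.seed, config.reference_length)
    rng = _rng(config, 2, _stable_id(sample.sample_id))
    x = sample.true_isoform_abundances.get("A3B1", 0.0)
    lam = np.exp(config.burden_intercept + config.burden_slope * np.log10(1.0 + x))
    n_tcw = int(rng.poisson(lam))
    n_bg_c = int(rng.poisson(config.background_c_mean))
    n_bg_t = int(rng.poisson(config.background_t_mean))

    records: list[MutationRecord] = []

    def emit(pos: int, alt_pyr: str):
        tri, ref_pyr = _pyrimidine_context(ref, pos)
        ref_base = ref[pos]
        # alt is expressed on the strand of the actual ref base
        alt = alt_pyr if ref_base in "CT" else alt_pyr.translate(_PYR_COMP)
        records.append(
            MutationRecord(
                sample_id=sample.sample_id,
                position=pos,
                ref_base=ref_base,
                alt_base=alt,
                trinucleotide_context=tri,
            )
        )

    for pos in rng.choice(tcw_sites, size=n_tcw, replace=True):
        emit(int(pos), "T" if rng.random() < 0.7 else "G")  # tCw -> tTw / tGw
    for pos in rng.choice(cg_sites, size=n_bg_c, replace=True):
        emit(int(pos), rng.choice(["T", "G", "A"]))
    for pos in rng.choice(ta_sites, size=n_bg_t, replace=True):
        emit(int(pos), rng.choice(["C", "G", "A"]))
    return records


def mutation_context_windows(
    records: list[MutationRecord], config: SimulationConfig, radius: int = 20
) -> dict[int, str]:
    """Map position -> the +/-radius nt reference window around each mutation."""
    ref = _reference_sequence(config.seed, config.reference_length)
    return {
        r.position: ref[r.position - radius : r.position + radius + 1]
        for r in records
    }


def mutations_to_table(
    records: list[MutationRecord], windows: dict[int, str] | None = None
) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id, "position": r.position,
            "ref": r.ref_base, "alt": r.alt_base,
            "context": r.trinucleotide_context,
        }
        if windows is not None:
            row["window"] = windows[r.position]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR and densitometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrParams:
    """True Ct layout for a two-control TaqMan experiment."""

    target_assay: str = "A3B1"
    control_assays: tuple[str, str] = ("GAPDH", "PPIA")
    base_ct_target: float = 27.0
    base_ct_controls: tuple[float, float] = (19.0, 21.0)
    group_shifts: dict = field(default_factory=lambda: {"control": 0.0})
    n_replicates: int = 3
    noise_sd: float = 0.1


def simulate_qpcr(params: QpcrParams, config: SimulationConfig) -> pd.DataFrame:
    """Long-format Ct table: group, replicate, assay, ct.

    Each treated group's *target* Ct is shifted by its configured delta;
    endogenous-control Cts are group-independent.  Gaussian noise of
    ``noise_sd`` cycles is added to every well.
    """
    rng = _rng(config, 3)
    rows = []
    for group, shift in params.group_shifts.items():
        for rep in range(params.n_replicates):
            rows.append(
                {"group": group, "replicate": rep, "assay": params.target_assay,
                 "ct": params.base_ct_target + shift + rng.normal(0, params.noise_sd)}
            )
            for assay, base in zip(params.control_assays, params.base_ct_controls):
                rows.append(
                    {"group": group, "replicate": rep, "assay": assay,
                     "ct": base + rng.normal(0, params.noise_sd)}
                )
    return pd.DataFrame(rows)


def simulate_densitometry(
    true_percent_skip: dict[str, float],
    config: SimulationConfig,
    n_replicates: int = 3,
    total_intensity: float = 1000.0,
    noise_sd: float = 0.03,
) -> pd.DataFrame:
    """Band-intensity table (condition_id, replicate, band_id, intensity)."""
    rng = _rng(config, 4)
    rows = []
    for cond, pct in true_percent_skip.items():
        if not 0.0 <= pct <= 100.0:
            raise ValueError(f"percent skip {pct} outside [0, 100]")
        for rep in range(n_replicates):
            frac = np.clip(pct / 100.0 + rng.normal(0, noise_sd), 0.0, 1.0)
            rows.append({"condition_id": cond, "replicate": rep,
                         "band_id": "skip", "intensity": total_intensity * frac})
            rows.append({"condition_id": cond, "replicate": rep,
                         "band_id": "inclusion",
                         "intensity": total_intensity * (1.0 - frac)})
    return pd.DataFrame(rows)
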