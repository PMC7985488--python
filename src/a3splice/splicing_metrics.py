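"""Percent-spliced-in (PSI) computation and paired tumor/normal comparison.

PSI for an exon-inclusion event is inclusion/(inclusion+exclusion), where
the inclusion evidence is the *mean* of the two flanking-junction counts
(an included exon yields two junction reads per molecule end to end, so the
mean puts inclusion and exclusion on the same per-event scale) and the
exclusion evidence is the sum of the skip-junction counts.  Samples with
fewer than ``min_informative_reads`` total informative reads get an
undefined PSI and are excluded from tests.

Band-intensity (densitometry) readouts are handled by
``percent_exon_skipping`` and ``splicing_shift``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .junction_quant import JunctionCountMatrix

__all__ = [
    "SpliceEventDefinition",
    "PsiValue",
    "DensitometryRecord",
    "EXON5_SKIP_EVENT",
    "compute_psi",
    "paired_psi_test",
    "percent_exon_skipping",
    "splicing_shift",
]


@dataclass(frozen=True)
class SpliceEventDefinition:
    event_id: str
    inclusion_junctions: tuple[str, ...]
    exclusion_junctions: tuple[str, ...]

    def __post_init__(self):
        if not self.inclusion_junctions or not self.exclusion_junctions:
            raise ValueError(f"{self.event_id}: junction sets must be non-empty")


# gene-B exon-5 inclusion/skip in the fixture topology
EXON5_SKIP_EVENT = SpliceEventDefinition(
    event_id="A3B:exon5",
    inclusion_junctions=("A3B1:E4-E5", "A3B1:E5-E6"),
    exclusion_junctions=("A3B3:E4-E6",),
)


@dataclass(frozen=True)
class PsiValue:
    event_id: str
    sample_id: str
    inclusion_count: int  # mean of inclusion junctions, rounded half-up
    exclusion_count: int
    psi: float | None  # None when below the informative-read floor

    def __post_init__(self):
        if self.psi is not None and not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi outside [0, 1]")


@dataclass(frozen=True)
class DensitometryRecord:
    condition_id: str
    replicate: int
    band_id: str  # inclusion | skip | other
    intensity: float

    def __post_init__(self):
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


def compute_psi(
    matrix: JunctionCountMatrix,
    event: SpliceEventDefinition,
    min_informative_reads: int = 10,
) -> list[PsiValue]:
    """One PsiValue per sample for the given inclusion/exclusion event."""
    for jid in event.inclusion_junctions + event.exclusion_junctions:
        if jid not in matrix.counts.columns:
            raise KeyError(f"junction {jid} not in count matrix")
    out = []
    for sample_id, row in matrix.counts.iterrows():
        inc_mean = sum(row[j] for j in event.inclusion_junctions) / len(
            event.inclusion_junctions
        )
        exc = int(sum(row[j] for j in event.exclusion_junctions))
        denom = inc_mean + exc
        psi = inc_mean / denom if denom >= min_informative_reads else None
        out.append(
            PsiValue(
                event_id=event.event_id,
                sample_id=sample_id,
                inclusion_count=math.floor(inc_mean + 0.5),
                exclusion_count=exc,
                psi=psi,
            )
        )
    return out


def psi_table(values: list[PsiValue]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample_id": v.sample_id, "event_id": v.event_id,
             "inclusion": v.inclusion_count, "exclusion": v.exclusion_count,
             "psi": v.psi}
            for v in values
        ]
    )


@dataclass(frozen=True)
class PairedPsiResult:
    statistic: float
    pvalue: float
    n_pairs_used: int
    median_difference: float


def paired_psi_test(
    pairs: dict[str, tuple[float | None, float | None]],
    min_pairs: int = 5,
) -> PairedPsiResult:
    """Wilcoxon matched-pairs signed-rank test on per-pair PSI differences.

    ``pairs`` maps pair_id -> (tumor_psi, normal_psi); pairs with an
    undefined PSI on either side are dropped, zero differences are dropped
    (Wilcoxon convention), and fewer than ``min_pairs`` informative pairs is
    an error mirroring the cohort-inclusion rule of the analysis.
    """
    diffs = [
        t - n for t, n in pairs.values() if t is not None and n is not None
    ]
    if len(diffs) < min_pairs:
        raise ValueError(
            f"only {len(diffs)} informative pairs; need >= {min_pairs}"
        )
    nonzero = [d for d in diffs if d != 0.0]
    if not nonzero:
        raise ValueError("no nonzero pair differences; test undefined")
    method = "exact" if len(nonzero) <= 25 else "approx"
    res = stats.wilcoxon(nonzero, alternative="two-sided", method=method)
    med = float(pd.Series(diffs).median())
    return PairedPsiResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_pairs_used=len(nonzero),
        median_difference=med,
    )


def _records(bands) -> list[DensitometryRecord]:
    if isinstance(bands, pd.DataFrame):
        return [
            DensitometryRecord(r.condition_id, int(r.replicate), r.band_id,
                               float(r.intensity))
            for r in bands.itertuples()
        ]
    return list(bands)


def percent_exon_skipping(bands) -> tuple[dict[int, float | None], float]:
    """Per-replicate 100*skip/(skip+inclusion) and its median, for one condition.

    ``bands`` is a DensitometryRecord iterable (or equivalent DataFrame) for a
    single condition; replicates with zero total intensity are undefined.
    """
    recs = _records(bands)
    if len({r.condition_id for r in recs}) > 1:
        raise ValueError("bands from more than one condition")
    by_rep: dict[int, dict[str, float]] = {}
    for r in recs:
        by_rep.setdefault(r.replicate, {}).setdefault(r.band_id, 0.0)
        by_rep[r.replicate][r.band_id] += r.intensity
    per_rep: dict[int, float | None] = {}
    for rep, bands_d in sorted(by_rep.items()):
        if "skip" not in bands_d or "inclusion" not in bands_d:
            raise ValueError(f"replicate {rep} missing a skip or inclusion band")
        tot = bands_d["skip"] + bands_d["inclusion"]
        per_rep[rep] = 100.0 * bands_d["skip"] / tot if tot > 0 else None
    defined = [v for v in per_rep.values() if v is not None]
    if not defined:
        raise ValueError("no replicate with nonzero total intensity")
    return per_rep, float(pd.Series(defined).median())


def splicing_shift(
    condition: list[float], control: list[float]
) -> tuple[float, list[float]]:
    """Median(condition) - median(control), in percentage points.

    Returns the shift and the per-replicate deltas of the condition
    percentages against the control median.
    """
    if not control:
        raise ValueError("control percentages must be non-empty")
    ctrl_med = float(pd.Series(control).median())
    cond_med = float(pd.Series(condition).median())
    deltas = [c - ctrl_med for c in condition]
    return cond_med - ctrl_med, deltas
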