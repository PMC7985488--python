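"""Deterministic calculators for the bench-assay readouts.

Three quantitative readouts are modelled: (1) the fluorophore-labelled
fragment sizes produced when a deaminated cytosine in an ssDNA probe is
excised (uracil-DNA glycosylase) and the abasic site cleaved under alkali —
the labelled 5' product keeps every nucleotide 5' of the excised base;
(2) relative qPCR quantification by 2^-ddCt against the mean of two
endogenous controls; (3) per-position substitution profiling of amplicon
reads against a short custom oligo reference (ungapped, best-offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_models import reverse_complement

__all__ = [
    "CleavageResult",
    "FoldChange",
    "SubstitutionProfile",
    "predict_cleavage_products",
    "ddct_fold_change",
    "amplicon_substitution_profile",
    "DEAMINATION_PROBE",
]

# the published deamination probe: (ATA)x8 TCC (ATA)x7, 48 nt
DEAMINATION_PROBE = "ATA" * 8 + "TCC" + "ATA" * 7

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class CleavageResult:
    substrate_length: int
    target_position: int       # 1-based index of the deaminated C
    five_prime_fragment: int   # nt, carries the 5' label
    three_prime_fragment: int

    def __post_init__(self):
        if self.five_prime_fragment + self.three_prime_fragment + 1 != self.substrate_length:
            raise ValueError("fragments + excised base must equal substrate length")


@dataclass(frozen=True)
class FoldChange:
    group: str
    target_assay: str
    delta_ct: float
    delta_delta_ct: float
    fold: float

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("fold change must be positive")


@dataclass(frozen=True)
class SubstitutionProfile:
    reference: str
    counts: np.ndarray       # (len(reference), 4, 4): ref-base x read-base
    coverage: np.ndarray     # per-position aligned-read coverage
    tc_context_ct_rate: float
    n_reads_used: int
    n_reads_discarded: int

    def __post_init__(self):
        per_pos = self.counts.sum(axis=(1, 2))
        if not np.array_equal(per_pos, self.coverage):
            raise ValueError("per-position counts must sum to coverage")


def predict_cleavage_products(
    substrate: str, motif: str = "TC", target_index: int | None = None
) -> CleavageResult:
    """Fragment sizes after deamination at the motif C, UDG and alkaline cleavage.

    The deaminated C (the motif's C, e.g. the first C of the unique TCC in
    the published probe) becomes uracil, is excised, and the strand is cut at
    the abasic site: the labelled 5' product spans positions 1..target-1 plus
    nothing of the excised base — length target_position - 1 — and the 3'
    fragment the remainder.  If the motif is absent or ambiguous an explicit
    1-based ``target_index`` is required.
    """
    substrate = substrate.upper()
    if target_index is None:
        hits = []
        start = substrate.find(motif)
        while start != -1:
            hits.append(start + motif.index("C") + 1)  # 1-based C position
            start = substrate.find(motif, start + 1)
        if len(hits) != 1:
            raise ValueError(
                f"{len(hits)} candidate target Cs for motif {motif!r}; "
                "pass an explicit target_index"
            )
        target_index = hits[0]
    if not 1 <= target_index <= len(substrate) or substrate[target_index - 1] != "C":
        raise ValueError(f"position {target_index} is not a C in the substrate")
    return CleavageResult(
        substrate_length=len(substrate),
        target_position=target_index,
        five_prime_fragment=target_index - 1,
        three_prime_fragment=len(substrate) - target_index,
    )


def ddct_fold_change(
    ct: pd.DataFrame,
    target_assay: str,
    control_assays: tuple[str, ...] = ("GAPDH", "PPIA"),
    reference_group: str = "control",
) -> list[FoldChange]:
    """2^-ddCt relative quantification with dual endogenous controls.

    ``ct`` is long format (group, replicate, assay, ct).  Per replicate,
    dCt = Ct_target - mean(Ct_controls); ddCt = mean dCt(group) -
    mean dCt(reference); fold = 2^-ddCt.  Combining the controls by the
    arithmetic mean of their Cts equals the geometric mean of their
    expression levels.
    """
    wide = ct.pivot_table(index=["group", "replicate"], columns="assay",
                          values="ct")
    needed = (target_assay,) + tuple(control_assays)
    missing = [a for a in needed if a not in wide.columns or wide[a].isna().any()]
    if missing:
        raise ValueError(f"missing Ct values for assays: {missing}")
    dct = wide[target_assay] - wide[list(control_assays)].mean(axis=1)
    group_dct = dct.groupby(level="group").mean()
    if reference_group not in group_dct.index:
        raise ValueError(f"reference group {reference_group!r} not in table")
    ref = group_dct[reference_group]
    out = []
    for group, d in group_dct.items():
        ddct = float(d - ref)
        out.append(
            FoldChange(group=group, target_assay=target_assay,
                       delta_ct=float(d), delta_delta_ct=ddct,
                       fold=float(2.0 ** (-ddct)))
        )
    return out


def _best_offsets(read_arr: np.ndarray, ref_arr: np.ndarray) -> tuple[int, int]:
    """(leftmost minimal-mismatch offset, mismatch count) for an ungapped read."""
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, len(read_arr))
    mismatches = (windows != read_arr).sum(axis=1)
    off = int(mismatches.argmin())  # argmin is leftmost on ties
    return off, int(mismatches[off])


def amplicon_substitution_profile(
    reads: list[str],
    reference: str,
    max_mismatch_fraction: float = 0.2,
    try_reverse: bool = True,
) -> SubstitutionProfile:
    """Per-position substitution tally of reads on a short oligo reference.

    Each read is placed ungapped at its minimal-mismatch offset (leftmost on
    ties; the reverse complement is also tried); reads whose best placement
    exceeds ``max_mismatch_fraction`` mismatches are discarded and counted.
    The summary rate is C->T events at TC-context reference positions
    divided by the coverage there.
    """
    reference = reference.upper()
    ref_arr = np.frombuffer(reference.encode(), dtype="S1")
    L = len(reference)
    counts = np.zeros((L, 4, 4), dtype=np.int64)
    coverage = np.zeros(L, dtype=np.int64)
    used = discarded = 0
    for read in reads:
        read = read.upper()
        if len(read) > L:
            raise ValueError("read longer than the reference oligo")
        candidates = [read] + ([reverse_complement(read)] if try_reverse else [])
        placements = []
        for k, seq in enumerate(candidates):
            arr = np.frombuffer(seq.encode(), dtype="S1")
            off, mm = _best_offsets(arr, ref_arr)
            placements.append((mm, k, off, arr))
        mm, _, off, arr = min(placements)
        if mm > max_mismatch_fraction * len(read):
            discarded += 1
            continue
        used += 1
        pos = np.arange(off, off + len(arr))
        ref_idx = np.array([_BASE_INDEX.get(b.decode(), -1) for b in ref_arr[pos]])
        read_idx = np.array([_BASE_INDEX.get(b.decode(), -1) for b in arr])
        ok = (ref_idx >= 0) & (read_idx >= 0)
        np.add.at(counts, (pos[ok], ref_idx[ok], read_idx[ok]), 1)
        np.add.at(coverage, pos[ok], 1)

    tc_positions = [
        i for i in range(1, L) if reference[i] == "C" and reference[i - 1] == "T"
    ]
    ct = sum(counts[i, _BASE_INDEX["C"], _BASE_INDEX["T"]] for i in tc_positions)
    cov = sum(coverage[i] for i in tc_positions)
    rate = float(ct / cov) if cov > 0 else 0.0
    return SubstitutionProfile(
        reference=reference, counts=counts, coverage=coverage,
        tc_context_ct_rate=rate, n_reads_used=used, n_reads_discarded=discarded,
    )
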