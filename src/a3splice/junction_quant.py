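"""Strict junction-read counting for homologous paralogs.

A read supports a junction only if some ungapped placement on the probe's
spliced context has zero mismatches over the covered probe window and at
least ``min_overhang`` perfectly matching nucleotides on *each* side of the
junction point.  When ``require_discriminating`` is set, the covered window
must additionally include a discriminating position (a base at which the
probe differs from its cross-paralog homologue) — probes without any
homologue are exempt, since no read from the other gene can resemble them.

``naive_gene_counts`` implements the failure mode this rule avoids: total
gene counting with a mismatch budget, under which reads from one paralog
inflate the other's count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_models import GeneModel, JunctionProbe, reverse_complement

__all__ = [
    "QuantConfig",
    "JunctionCountMatrix",
    "match_read_to_junction",
    "count_junction_reads",
    "naive_gene_counts",
    "call_expression",
    "DEFAULT_DEFINING_JUNCTIONS",
]

# the defining junction for each isoform in the fixture topology
DEFAULT_DEFINING_JUNCTIONS = {
    "A3A1": "A3A1:E1-E2",
    "A3A2": "A3A2:E1-aE2",
    "A3B1": "A3B1:E5-E6",
    "A3B2": "A3B2:E5-aE6",
    "A3B3": "A3B3:E4-E6",
}


@dataclass(frozen=True)
class QuantConfig:
    min_overhang: int = 10
    require_discriminating: bool = True
    expression_threshold: int = 1
    naive_max_mismatch: int = 3

    def __post_init__(self):
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")
        if self.expression_threshold < 1:
            raise ValueError("expression_threshold must be >= 1")


@dataclass
class JunctionCountMatrix:
    """samples x junctions count table plus the config that produced it."""

    counts: pd.DataFrame  # index: sample_id, columns: junction_id, int
    config: QuantConfig
    cross_ambiguous: pd.Series | None = None  # per-sample multi-gene match tally

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")


def _match_oriented(read: str, probe: JunctionProbe, config: QuantConfig) -> bool:
    """Check one orientation of the read against the probe window."""
    f = probe.flank_len
    oh = config.min_overhang
    if oh > f:
        return False
    seq = probe.sequence
    core = seq[f - oh : f + oh]
    if "N" in core:
        return False
    start = read.find(core)
    while start != -1:
        # probe coordinate of read[0] under this placement
        d = (f - oh) - start
        ol_start = max(0, d)
        ol_end = min(2 * f, d + len(read))
        window = seq[ol_start:ol_end]
        covered = read[ol_start - d : ol_end - d]
        if "N" not in window and "N" not in covered and window == covered:
            if not config.require_discriminating or not probe.discriminating_offsets:
                return True
            for off in probe.discriminating_offsets:
                if ol_start <= probe.index_of_offset(off) < ol_end:
                    return True
        start = read.find(core, start + 1)
    return False


def match_read_to_junction(
    read_seq: str, probe: JunctionProbe, config: QuantConfig | None = None
) -> bool:
    """True iff the read supports the junction under the strict overhang rule.

    Tries both orientations (unstranded library).  A read with >= min_overhang
    nt of perfect match on each side of the junction point and no mismatch
    anywhere in the covered probe window qualifies; 'N' never matches.
    """
    if not read_seq:
        raise ValueError("empty read")
    config = config or QuantConfig()
    read_seq = read_seq.upper()
    return _match_oriented(read_seq, probe, config) or _match_oriented(
        reverse_complement(read_seq), probe, config
    )


def count_junction_reads(
    reads_by_sample: dict[str, list[str]],
    probes: list[JunctionProbe],
    config: QuantConfig | None = None,
    probe_gene: dict[str, str] | None = None,
) -> JunctionCountMatrix:
    """Count supporting reads per junction per sample.

    A read increments every junction it matches (a read spanning two junctions
    of one isoform increments both).  When ``probe_gene`` maps junction ids to
    gene ids, reads matching junctions of more than one gene are tallied in
    the cross-ambiguity report.
    """
    config = config or QuantConfig()
    ids = [p.junction_id for p in probes]
    if len(set(ids)) != len(ids):
        raise ValueError("probe junction ids must be distinct")
    counts = pd.DataFrame(
        0, index=sorted(reads_by_sample), columns=ids, dtype=int
    )
    ambiguous = pd.Series(0, index=sorted(reads_by_sample), dtype=int)
    for sample_id, reads in reads_by_sample.items():
        for read in reads:
            hits = [p.junction_id for p in probes
                    if match_read_to_junction(read, p, config)]
            for jid in hits:
                counts.at[sample_id, jid] += 1
            if probe_gene and len({probe_gene[j] for j in hits}) > 1:
                ambiguous[sample_id] += 1
    return JunctionCountMatrix(counts=counts, config=config,
                               cross_ambiguous=ambiguous if probe_gene else None)


def _min_hamming_by_offset(read_arr: np.ndarray, target: np.ndarray) -> int:
    """Minimum Hamming distance of the read over all in-bounds offsets."""
    L, n = len(target), len(read_arr)
    if n > L:
        return n
    windows = np.lib.stride_tricks.sliding_window_view(target, n)
    return int((windows != read_arr).sum(axis=1).min())


def naive_gene_counts(
    reads_by_sample: dict[str, list[str]],
    genes: dict[str, GeneModel],
    config: QuantConfig | None = None,
) -> pd.DataFrame:
    """Total-gene counting with a mismatch budget (the cross-alignment trap).

    A read counts for every gene whose mature mRNA admits an ungapped
    placement with <= ``naive_max_mismatch`` mismatches, in either
    orientation; reads hitting both paralogs are counted for both,
    deliberately reproducing the homology-driven inflation.
    """
    if not genes:
        raise ValueError("need at least one gene")
    config = config or QuantConfig()
    gene_arrays = {
        gid: np.frombuffer(g.mrna.encode(), dtype="S1") for gid, g in genes.items()
    }
    out = pd.DataFrame(0, index=sorted(reads_by_sample), columns=sorted(genes),
                       dtype=int)
    for sample_id, reads in reads_by_sample.items():
        for read in reads:
            fwd = np.frombuffer(read.upper().encode(), dtype="S1")
            rev = np.frombuffer(
                reverse_complement(read.upper()).encode(), dtype="S1"
            )
            for gid, target in gene_arrays.items():
                d = min(_min_hamming_by_offset(fwd, target),
                        _min_hamming_by_offset(rev, target))
                if d <= config.naive_max_mismatch:
                    out.at[sample_id, gid] += 1
    return out


def call_expression(
    matrix: JunctionCountMatrix,
    defining_junctions: dict[str, str] | None = None,
    config: QuantConfig | None = None,
) -> pd.DataFrame:
    """Per-sample expressed/not call with the defining junction's count.

    An isoform is called expressed when its defining junction has at least
    ``expression_threshold`` reads in that sample.
    """
    config = config or matrix.config
    defining = defining_junctions or DEFAULT_DEFINING_JUNCTIONS
    missing = [i for i, j in defining.items() if j not in matrix.counts.columns]
    if missing:
        raise KeyError(f"isoforms with unmapped defining junction: {missing}")
    rows = []
    for sample_id, row in matrix.counts.iterrows():
        for iso, jid in defining.items():
            c = int(row[jid])
            rows.append({
                "sample_id": sample_id, "isoform_id": iso, "junction_id": jid,
                "count": c, "expressed": c >= config.expression_threshold,
            })
    return pd.DataFrame(rows)


def positive_fraction(calls: pd.DataFrame, isoform_id: str) -> float:
    """Fraction of samples in which the isoform is called expressed."""
    sub = calls[calls["isoform_id"] == isoform_id]
    if sub.empty:
        raise ValueError(f"no calls for {isoform_id}")
    return float(sub["expressed"].mean())
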