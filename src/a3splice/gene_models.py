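"""Gene/isoform models for a pair of highly homologous paralogs.

The two APOBEC3 paralogs studied here are ~92% identical at the nucleotide
level, so reads can only be assigned to a gene (and to a splice isoform)
through exon-exon junction sequences that carry at least one discriminating
base — a position where the two paralogs' junction contexts differ.  This
module defines the gene/isoform containers, builds junction probes with
their discriminating offsets, and annotates the protein-level consequence
of each alternative splice event (frame, premature stop, NMD candidacy).

Coordinates are 0-based half-open *transcript* coordinates on the pre-mRNA
(transcript orientation); strand is abstracted away.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneModel",
    "IsoformModel",
    "JunctionProbe",
    "SpliceEventAnnotation",
    "build_junction_probes",
    "find_discriminating_offsets",
    "annotate_event",
    "translate_isoform",
    "paralog_fixture",
]

_CODON_TABLE = {
    "".join(c): aa
    for c, aa in zip(
        itertools.product("TCAG", repeat=3),
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    )
}
_STOPS = frozenset(k for k, v in _CODON_TABLE.items() if v == "*")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene: pre-mRNA sequence, exon intervals, and translation start.

    ``exons`` are [start, end) intervals on ``transcript_sequence``;
    ``cds_start`` is the transcript-coordinate offset of the first base of
    the start codon and must fall inside an exon.
    """

    gene_id: str
    transcript_sequence: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end <= len(self.transcript_sequence)):
                raise ValueError(
                    f"{self.gene_id}: exon [{start}, {end}) outside sequence bounds"
                )
            if start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unordered")
            prev_end = end
        if not any(s <= self.cds_start < e for s, e in self.exons):
            raise ValueError(f"{self.gene_id}: cds_start {self.cds_start} not exonic")

    @property
    def mrna(self) -> str:
        """Mature mRNA: concatenation of the exon sequences."""
        return "".join(self.transcript_sequence[s:e] for s, e in self.exons)

    def canonical_isoform(self, isoform_id: str | None = None) -> "IsoformModel":
        return IsoformModel(
            isoform_id=isoform_id or f"{self.gene_id}.1",
            parent_gene=self.gene_id,
            segments=self.exons,
            canonical=True,
        )


@dataclass(frozen=True)
class IsoformModel:
    """A splice isoform: ordered sub-intervals of the parent gene's exons."""

    isoform_id: str
    parent_gene: str
    segments: tuple[tuple[int, int], ...]
    canonical: bool = False

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(tuple(s) for s in self.segments))
        prev_end = -1
        for start, end in self.segments:
            if start >= end:
                raise ValueError(f"{self.isoform_id}: empty segment [{start}, {end})")
            if start < prev_end:
                raise ValueError(f"{self.isoform_id}: segments unordered")
            prev_end = end

    def validate_against(self, gene: GeneModel) -> None:
        if gene.gene_id != self.parent_gene:
            raise ValueError(f"{self.isoform_id}: wrong parent gene {gene.gene_id}")
        for start, end in self.segments:
            if not any(es <= start and end <= ee for es, ee in gene.exons):
                raise ValueError(
                    f"{self.isoform_id}: segment [{start}, {end}) not inside an exon"
                )
        if self.canonical and self.segments != gene.exons:
            raise ValueError(f"{self.isoform_id}: canonical isoform must use all exons")

    def mrna(self, gene: GeneModel) -> str:
        self.validate_against(gene)
        return "".join(gene.transcript_sequence[s:e] for s, e in self.segments)

    def junction_positions(self) -> list[int]:
        """mRNA offsets of each segment-segment junction point."""
        positions, acc = [], 0
        for start, end in self.segments[:-1]:
            acc += end - start
            positions.append(acc)
        return positions

    def segment_label(self, index: int, gene: GeneModel) -> str:
        """Exon-style label: E<k>, prefixed 'a' when 5'-truncated (cryptic acceptor)."""
        start, end = self.segments[index]
        for k, (es, ee) in enumerate(gene.exons, start=1):
            if es <= start and end <= ee:
                return f"aE{k}" if start > es else f"E{k}"
        raise ValueError(f"segment {index} of {self.isoform_id} has no parent exon")


@dataclass(frozen=True)
class JunctionProbe:
    """Junction context sequence with paralog-discriminating positions.

    Offsets are relative to the junction point: -1 is the last base of the
    upstream segment, +1 the first base of the downstream one (there is no
    offset 0).  ``discriminating_offsets`` holds the offsets at which this
    probe differs from the most similar junction probe of the other paralog;
    it is empty when the junction has no cross-paralog homologue.
    """

    junction_id: str
    isoform_id: str
    left_seq: str
    right_seq: str
    flank_len: int
    discriminating_offsets: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.left_seq) != self.flank_len or len(self.right_seq) != self.flank_len:
            raise ValueError(f"{self.junction_id}: flank sequences must be {self.flank_len} nt")
        for off in self.discriminating_offsets:
            if off == 0 or abs(off) > self.flank_len:
                raise ValueError(f"{self.junction_id}: offset {off} outside +/-{self.flank_len}")

    @property
    def sequence(self) -> str:
        return self.left_seq + self.right_seq

    def offset_of_index(self, i: int) -> int:
        return i - self.flank_len if i < self.flank_len else i - self.flank_len + 1

    def index_of_offset(self, off: int) -> int:
        return off + self.flank_len if off < 0 else off + self.flank_len - 1


@dataclass(frozen=True)
class SpliceEventAnnotation:
    """Protein-level consequence of one alternative splice event."""

    event_id: str
    event_type: str | None  # exon_skip | cryptic_acceptor | cryptic_donor | None
    removed_nt: int
    frameshift: bool
    ptc_segment_index: int | None
    nmd_candidate: bool
    predicted_protein_length: int


def find_discriminating_offsets(probe_a: JunctionProbe, probe_b: JunctionProbe) -> frozenset[int]:
    """Offsets where two equal-length junction probes differ (symmetric)."""
    if probe_a.flank_len != probe_b.flank_len:
        raise ValueError("probes have unequal flank lengths")
    return frozenset(
        probe_a.offset_of_index(i)
        for i, (x, y) in enumerate(zip(probe_a.sequence, probe_b.sequence))
        if x != y
    )


def build_junction_probes(
    isoforms,
    genes,
    flank_len: int = 39,
) -> list[JunctionProbe]:
    """One probe per adjacent segment pair per isoform, with discriminating offsets.

    ``isoforms`` is an iterable of :class:`IsoformModel`, ``genes`` a mapping
    gene_id -> :class:`GeneModel` (or an iterable of genes).  The probe
    sequence is the 2*flank_len window of the isoform's mature mRNA centred
    on the junction.  Discriminating offsets are assigned by comparing each
    probe against the closest probe (minimum Hamming distance, <= 30% of the
    window) from any *other* gene — the cross-paralog homologue.  Junctions
    whose topology is unique to one paralog (no homologue within that radius)
    keep an empty offset set: no read from the other paralog resembles them,
    so no discriminating base is required there.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    if not isinstance(genes, dict):
        genes = {g.gene_id: g for g in genes}

    probes: list[JunctionProbe] = []
    for iso in isoforms:
        gene = genes[iso.parent_gene]
        if len(iso.segments) < 2:
            raise ValueError(f"{iso.isoform_id}: needs >=2 segments to have junctions")
        for i, ((ls, le), (rs, re)) in enumerate(zip(iso.segments, iso.segments[1:])):
            for j, (s, e) in ((i, (ls, le)), (i + 1, (rs, re))):
                if e - s < flank_len:
                    raise ValueError(
                        f"{iso.isoform_id}: segment {j} ([{s}, {e})) shorter than "
                        f"flank_len={flank_len}"
                    )
            left = gene.transcript_sequence[le - flank_len : le]
            right = gene.transcript_sequence[rs : rs + flank_len]
            jid = (
                f"{iso.isoform_id}:"
                f"{iso.segment_label(i, gene)}-{iso.segment_label(i + 1, gene)}"
            )
            probes.append(
                JunctionProbe(
                    junction_id=jid,
                    isoform_id=iso.isoform_id,
                    left_seq=left,
                    right_seq=right,
                    flank_len=flank_len,
                )
            )

    # Cross-paralog homologue search: nearest probe of any other gene.
    iso_gene = {iso.isoform_id: iso.parent_gene for iso in isoforms}
    out: list[JunctionProbe] = []
    for p in probes:
        best: frozenset[int] | None = None
        best_d = 2 * flank_len + 1
        for q in probes:
            if iso_gene[q.isoform_id] == iso_gene[p.isoform_id]:
                continue
            offs = find_discriminating_offsets(p, q)
            if len(offs) < best_d:
                best_d, best = len(offs), offs
        if best is not None and best_d <= 0.30 * 2 * flank_len:
            out.append(
                JunctionProbe(
                    p.junction_id, p.isoform_id, p.left_seq, p.right_seq,
                    p.flank_len, best,
                )
            )
        else:
            out.append(p)
    return out


def _translate_from(mrna: str, cds_offset: int) -> tuple[int, int | None]:
    """Conceptual translation: (protein length aa, mRNA offset of stop or None)."""
    for pos in range(cds_offset, len(mrna) - 2, 3):
        if mrna[pos : pos + 3] in _STOPS:
            return (pos - cds_offset) // 3, pos
    return (len(mrna) - cds_offset) // 3, None


def _cds_offset_in_mrna(iso: IsoformModel, gene: GeneModel) -> int:
    acc = 0
    for s, e in iso.segments:
        if s <= gene.cds_start < e:
            return acc + gene.cds_start - s
        acc += e - s
    raise ValueError(f"{iso.isoform_id}: translation start not retained by isoform")


def translate_isoform(iso: IsoformModel, gene: GeneModel) -> tuple[int, int | None, int | None]:
    """(protein length aa, mRNA stop offset or None, stop segment index or None)."""
    mrna = iso.mrna(gene)
    aa_len, stop = _translate_from(mrna, _cds_offset_in_mrna(iso, gene))
    if stop is None:
        return aa_len, None, None
    acc = 0
    for k, (s, e) in enumerate(iso.segments):
        if stop < acc + (e - s):
            return aa_len, stop, k
        acc += e - s
    raise AssertionError("stop offset outside mRNA")


def _classify_event(iso: IsoformModel, canonical: IsoformModel) -> str | None:
    if iso.segments == canonical.segments:
        return None
    # classify by the first segment-level difference
    iso_by_exon = {}
    for s, e in iso.segments:
        for cs, ce in canonical.segments:
            if cs <= s and e <= ce:
                iso_by_exon[(cs, ce)] = (s, e)
                break
    for cs, ce in canonical.segments:
        if (cs, ce) not in iso_by_exon:
            return "exon_skip"
        s, e = iso_by_exon[(cs, ce)]
        if s > cs:
            return "cryptic_acceptor"
        if e < ce:
            return "cryptic_donor"
    return None


def annotate_event(
    iso: IsoformModel, canonical: IsoformModel, gene: GeneModel
) -> SpliceEventAnnotation:
    """Annotate the splice event turning ``canonical`` into ``iso``.

    removed_nt is the mature-mRNA length difference; a frameshift occurs when
    the removed length is not a multiple of 3 (for removals downstream of the
    translation start); the isoform is an NMD candidate when its first stop
    codon falls in any segment other than the last.
    """
    if iso.parent_gene != canonical.parent_gene:
        raise ValueError("isoforms do not share a parent gene")
    can_mrna = canonical.mrna(gene)
    iso_mrna = iso.mrna(gene)
    removed = len(can_mrna) - len(iso_mrna)
    if removed < 0:
        raise ValueError(
            f"{iso.isoform_id} is longer than the canonical isoform; "
            "inclusion events are not modelled"
        )

    # removal upstream of the CDS never shifts the reading frame
    removed_coding = 0
    for (cs, ce) in canonical.segments:
        iso_cov = [(s, e) for s, e in iso.segments if cs <= s and e <= ce]
        kept = sum(e - s for s, e in iso_cov)
        lost_here = (ce - cs) - kept
        if lost_here > 0 and ce > gene.cds_start:
            lo = max(cs, gene.cds_start)
            removed_coding += min(lost_here, ce - lo)
    frameshift = removed_coding % 3 != 0

    can_len, can_stop, _ = translate_isoform(canonical, gene)
    iso_len, iso_stop, stop_seg = translate_isoform(iso, gene)

    premature = iso_len < can_len - removed_coding // 3 or (
        frameshift and iso_stop is not None
    )
    ptc_index = stop_seg if (premature and stop_seg is not None) else None
    nmd = ptc_index is not None and ptc_index < len(iso.segments) - 1

    return SpliceEventAnnotation(
        event_id=f"{canonical.isoform_id}->{iso.isoform_id}",
        event_type=_classify_event(iso, canonical),
        removed_nt=removed,
        frameshift=frameshift,
        ptc_segment_index=ptc_index,
        nmd_candidate=nmd,
        predicted_protein_length=iso_len,
    )


# ---------------------------------------------------------------------------
# Deterministic paralog fixture
# ---------------------------------------------------------------------------

# Gene B: 8 exons; exon 5 is 154 nt (skipping it shifts the frame by one) and
# exon 6 carries a 75-nt in-frame cryptic-acceptor deletion.  Gene A: 5 exons
# copied from gene B exons 4-8 at the configured identity, with a 54-nt
# cryptic-acceptor deletion at the start of exon 2.
_B_EXON_SIZES = (180, 150, 180, 160, 154, 210, 140, 250)
_A_FROM_B_EXONS = slice(3, 8)  # gene A exons mirror gene B exons 4..8
_INTRON_LEN = 150
_B_CDS_UTR5 = 60
_A_CDS_UTR5 = 30
_B2_CRYPTIC_NT = 75
_A2_CRYPTIC_NT = 54
_SENSE_CODONS = [c for c in _CODON_TABLE if c not in _STOPS]


def _random_intron(rng) -> str:
    body = "".join(rng.choice(list("ACGT"), size=_INTRON_LEN - 4))
    return "GT" + body + "AG"


def _assemble(exon_seqs: list[str], rng) -> tuple[str, tuple[tuple[int, int], ...]]:
    parts, exons, pos = [], [], 0
    for i, seq in enumerate(exon_seqs):
        exons.append((pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
        if i < len(exon_seqs) - 1:
            intron = _random_intron(rng)
            parts.append(intron)
            pos += len(intron)
    return "".join(parts), tuple(exons)


_DIVERGENCE_BLOCK = 120  # nt; paralog divergence alternates hot/cold blocks


def _mutate_codon_aware(seq: str, rate: float, frame_start: int, protected: set[int], rng) -> str:
    """Substitute bases at ``rate`` on average, never creating an in-frame stop.

    Divergence is block-structured (alternating blocks at 2*rate and ~0),
    mimicking recently duplicated paralogs whose near-identical stretches are
    what makes total-gene read counting unreliable, while junction windows
    still carry discriminating bases.
    """
    bases = "ACGT"
    out = list(seq)
    pos_rate = np.where(
        (np.arange(len(seq)) // _DIVERGENCE_BLOCK) % 2 == 0,
        min(2.0 * rate, 1.0),
        0.0,
    )
    for i in np.flatnonzero(rng.random(len(seq)) < pos_rate):
        i = int(i)
        if i in protected:
            continue
        choices = [b for b in bases if b != out[i]]
        rng.shuffle(choices)
        for b in choices:
            old = out[i]
            out[i] = b
            if i >= frame_start:
                c0 = i - (i - frame_start) % 3
                if "".join(out[c0 : c0 + 3]) in _STOPS:
                    out[i] = old
                    continue
            break
    return "".join(out)


def _try_build_fixture(identity: float, rng):
    # --- gene B mature mRNA ---
    mrna_len = sum(_B_EXON_SIZES)
    n_aa = (mrna_len - _B_CDS_UTR5 - 30 - 3) // 3  # leave >=30 nt of 3' UTR
    cds = "ATG" + "".join(rng.choice(_SENSE_CODONS, size=n_aa - 1)) + "TAA"
    utr5 = "".join(rng.choice(list("ACGT"), size=_B_CDS_UTR5))
    utr3 = "".join(rng.choice(list("ACGT"), size=mrna_len - _B_CDS_UTR5 - len(cds)))
    mrna_b = utr5 + cds + utr3

    bounds = np.cumsum((0,) + _B_EXON_SIZES)
    b_exon_seqs = [mrna_b[bounds[i] : bounds[i + 1]] for i in range(8)]

    # --- gene A exons: mutated copies of B exons 4..8 ---
    a_sizes = _B_EXON_SIZES[_A_FROM_B_EXONS]
    b_slice_start = int(bounds[_A_FROM_B_EXONS.start])  # mRNA-B offset of exon 4
    # frame alignment: A cds offset 30 vs B cds offset 60 on the shared sequence
    assert (b_slice_start + _A_CDS_UTR5 - _B_CDS_UTR5) % 3 == 0
    a_concat = "".join(b_exon_seqs[_A_FROM_B_EXONS])
    stop_b = mrna_b.index(cds) + len(cds) - 3  # offset of TAA in mRNA-B
    protected = {stop_b - b_slice_start + k for k in range(3)}
    a_concat = _mutate_codon_aware(a_concat, 1.0 - identity, _A_CDS_UTR5, protected, rng)

    # guarantee a discriminating base 3 nt left of every gene-A junction
    a_concat = list(a_concat)
    acc = 0
    for size in a_sizes[:-1]:
        acc += size
        i = acc - 3
        if a_concat[i] == a_concat_b_base(b_exon_seqs, i):
            a_concat[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[a_concat[i]]
    a_concat = "".join(a_concat)
    a_bounds = np.cumsum((0,) + a_sizes)
    a_exon_seqs = [a_concat[a_bounds[i] : a_bounds[i + 1]] for i in range(5)]

    # --- assemble pre-mRNAs ---
    seq_b, exons_b = _assemble(b_exon_seqs, rng)
    seq_a, exons_a = _assemble(a_exon_seqs, rng)
    gene_b = GeneModel("A3B", seq_b, exons_b, exons_b[0][0] + _B_CDS_UTR5)
    gene_a = GeneModel("A3A", seq_a, exons_a, exons_a[0][0] + _A_CDS_UTR5)

    b1 = gene_b.canonical_isoform("A3B1")
    a1 = gene_a.canonical_isoform("A3A1")
    # A3B2: cryptic acceptor in exon 6 removes its first 75 nt
    e6 = exons_b[5]
    b2 = IsoformModel(
        "A3B2", "A3B",
        exons_b[:5] + ((e6[0] + _B2_CRYPTIC_NT, e6[1]),) + exons_b[6:],
    )
    # A3B3: exon-5 skip (154 nt, frameshift)
    b3 = IsoformModel("A3B3", "A3B", exons_b[:4] + exons_b[5:])
    # A3A2: cryptic acceptor in exon 2 removes its first 54 nt
    ae2 = exons_a[1]
    a2 = IsoformModel(
        "A3A2", "A3A",
        exons_a[:1] + ((ae2[0] + _A2_CRYPTIC_NT, ae2[1]),) + exons_a[2:],
    )

    # --- constraints mirroring the published consequences ---
    n_aa_b, stop_b_off, stop_seg_b = translate_isoform(b1, gene_b)
    if stop_seg_b != 7:
        return None
    ann_b2 = annotate_event(b2, b1, gene_b)
    if ann_b2.frameshift or ann_b2.nmd_candidate:
        return None
    if ann_b2.predicted_protein_length != n_aa_b - _B2_CRYPTIC_NT // 3:
        return None
    ann_b3 = annotate_event(b3, b1, gene_b)
    if not (ann_b3.frameshift and ann_b3.nmd_candidate and ann_b3.ptc_segment_index == 4):
        return None
    n_aa_a, _, stop_seg_a = translate_isoform(a1, gene_a)
    if stop_seg_a != 4:
        return None
    ann_a2 = annotate_event(a2, a1, gene_a)
    if ann_a2.frameshift or ann_a2.nmd_candidate:
        return None
    if ann_a2.predicted_protein_length != n_aa_a - _A2_CRYPTIC_NT // 3:
        return None

    genes = {"A3A": gene_a, "A3B": gene_b}
    isoforms = {iso.isoform_id: iso for iso in (a1, a2, b1, b2, b3)}
    return genes, isoforms


def a_concat_b_base(b_exon_seqs: list[str], i: int) -> str:
    return "".join(b_exon_seqs[_A_FROM_B_EXONS])[i]


def paralog_fixture(identity: float = 0.92, seed: int = 0):
    """Deterministic two-paralog fixture with the studied splice topology.

    Returns ``(genes, isoforms)``: gene "A3B" (8 exons, 154-nt exon 5,
    75-nt cryptic-acceptor deletion in exon 6) and gene "A3A" (5 exons
    homologous to A3B exons 4-8 at ``identity``, 54-nt cryptic acceptor in
    exon 2), with isoforms A3A1/A3A2/A3B1/A3B2/A3B3.  Retries internal
    subseeds until the fixture satisfies the published event consequences
    (in-frame -25 aa and -18 aa events; frameshifting exon-5 skip with its
    stop codon in exon 6).
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError("identity must be in [0, 1]")
    for attempt in range(500):
        rng = np.random.default_rng([int(seed) % (2**31), attempt])
        built = _try_build_fixture(identity, rng)
        if built is not None:
            return built
    raise RuntimeError("could not satisfy fixture constraints; try another seed")
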