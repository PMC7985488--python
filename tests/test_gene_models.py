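"""Gene/isoform structures, junction probes, and splice-event annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from a3splice.gene_models import (
    GeneModel,
    IsoformModel,
    JunctionProbe,
    annotate_event,
    build_junction_probes,
    find_discriminating_offsets,
    paralog_fixture,
    translate_isoform,
)

BASES = "ACGT"


def _random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def _toy_gene(exon_seqs, intron="GTAAGTTTTTTTTTAG", cds_start_in_exon1=0,
              gene_id="toy"):
    parts, exons, pos = [], [], 0
    for i, seq in enumerate(exon_seqs):
        exons.append((pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
        if i < len(exon_seqs) - 1:
            parts.append(intron)
            pos += len(intron)
    return GeneModel(gene_id, "".join(parts), tuple(exons), cds_start_in_exon1)


class TestGeneModel:
    def test_exon_bounds_validated(self):
        with pytest.raises(ValueError, match="outside sequence"):
            GeneModel("g", "ACGT", ((0, 10),), 0)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneModel("g", "ACGTACGTACGT", ((0, 6), (4, 10)), 0)

    def test_cds_start_must_be_exonic(self):
        with pytest.raises(ValueError, match="cds_start"):
            GeneModel("g", "ACGTACGTACGT", ((0, 4), (8, 12)), 5)

    def test_mrna_concatenates_exons(self):
        g = GeneModel("g", "AAACCCGGGTTT", ((0, 3), (6, 9)), 0)
        assert g.mrna == "AAAGGG"


class TestBuildJunctionProbes:
    def test_two_exon_probe_is_junction_window(self):
        rng = np.random.default_rng(0)
        e1, e2 = _random_seq(rng, 20), _random_seq(rng, 20)
        gene = _toy_gene([e1, e2])
        iso = gene.canonical_isoform("toy.1")
        (probe,) = build_junction_probes([iso], {"toy": gene}, flank_len=4)
        mrna = iso.mrna(gene)
        j = 20
        assert probe.sequence == mrna[j - 4 : j + 4]
        assert probe.left_seq == e1[-4:] and probe.right_seq == e2[:4]

    def test_eight_exon_canonical_yields_seven_probes(self, genes, isoforms):
        got = build_junction_probes([isoforms["A3B1"]], genes, flank_len=10)
        assert len(got) == 7

    def test_short_segment_raises_naming_it(self):
        rng = np.random.default_rng(1)
        gene = _toy_gene([_random_seq(rng, 5), _random_seq(rng, 30)])
        iso = gene.canonical_isoform("toy.1")
        with pytest.raises(ValueError, match="segment 0"):
            build_junction_probes([iso], {"toy": gene}, flank_len=10)

    def test_single_mismatch_paralogs_get_offset_minus_3(self):
        rng = np.random.default_rng(2)
        e1, e2 = _random_seq(rng, 30), _random_seq(rng, 30)
        gene_a = _toy_gene([e1, e2], gene_id="pA")
        # paralog differs at one base, 3 nt left of the junction
        e1b = e1[:-3] + {"A": "C", "C": "A", "G": "T", "T": "G"}[e1[-3]] + e1[-2:]
        gene_b = _toy_gene([e1b, e2], gene_id="pB")
        probes = build_junction_probes(
            [gene_a.canonical_isoform("pA.1"), gene_b.canonical_isoform("pB.1")],
            {"pA": gene_a, "pB": gene_b},
            flank_len=10,
        )
        assert all(p.discriminating_offsets == frozenset({-3}) for p in probes)

    def test_probe_rescan_finds_exactly_the_junctions(self, genes, isoforms, probes):
        # substring-search oracle: each probe window occurs in the isoform
        # mRNA exactly at its junction position
        for iso_id, iso in isoforms.items():
            mrna = iso.mrna(genes[iso.parent_gene])
            own = [p for p in probes if p.isoform_id == iso_id]
            for p, j in zip(own, iso.junction_positions()):
                assert mrna[j - p.flank_len : j + p.flank_len] == p.sequence


class TestFindDiscriminatingOffsets:
    def test_identical_probes_give_empty_set(self):
        p = JunctionProbe("j", "i", "ACGTA", "TTTTT", 5)
        assert find_discriminating_offsets(p, p) == frozenset()

    def test_constructed_differences_recovered(self):
        p = JunctionProbe("j1", "i", "ACGTAACGTA", "CCCCCCCCCC", 10)
        # differ at offsets -3 and +7
        left = list(p.left_seq)
        left[10 - 3] = "T"
        right = list(p.right_seq)
        right[7 - 1] = "G"
        q = JunctionProbe("j2", "i", "".join(left), "".join(right), 10)
        assert find_discriminating_offsets(p, q) == frozenset({-3, 7})

    def test_unequal_lengths_error(self):
        p = JunctionProbe("j1", "i", "ACGT", "ACGT", 4)
        q = JunctionProbe("j2", "i", "ACGTA", "ACGTA", 5)
        with pytest.raises(ValueError):
            find_discriminating_offsets(p, q)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_base_by_base_scan(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_seq(rng, 20)
        b = _random_seq(rng, 20)
        pa = JunctionProbe("a", "i", a[:10], a[10:], 10)
        pb = JunctionProbe("b", "i", b[:10], b[10:], 10)
        got = find_discriminating_offsets(pa, pb)
        expected = set()
        for i in range(20):
            if a[i] != b[i]:
                expected.add(i - 10 if i < 10 else i - 9)
        assert got == frozenset(expected)
        assert got == find_discriminating_offsets(pb, pa)  # symmetry


class TestAnnotateEvent:
    def test_inframe_cryptic_acceptor_shortens_by_25_aa(self, genes, isoforms):
        ann = annotate_event(isoforms["A3B2"], isoforms["A3B1"], genes["A3B"])
        full, *_ = translate_isoform(isoforms["A3B1"], genes["A3B"])
        assert ann.removed_nt == 75
        assert not ann.frameshift and not ann.nmd_candidate
        assert ann.predicted_protein_length == full - 25
        assert ann.event_type == "cryptic_acceptor"

    def test_154nt_exon_skip_frameshifts_into_nmd(self, genes, isoforms):
        ann = annotate_event(isoforms["A3B3"], isoforms["A3B1"], genes["A3B"])
        assert ann.removed_nt == 154
        assert ann.frameshift  # 154 mod 3 == 1
        assert ann.nmd_candidate
        assert ann.ptc_segment_index is not None
        assert ann.ptc_segment_index < len(isoforms["A3B3"].segments) - 1

    def test_short_paralog_cryptic_event_shortens_by_18_aa(self, genes, isoforms):
        ann = annotate_event(isoforms["A3A2"], isoforms["A3A1"], genes["A3A"])
        full, *_ = translate_isoform(isoforms["A3A1"], genes["A3A"])
        assert ann.removed_nt == 54
        assert not ann.frameshift and not ann.nmd_candidate
        assert ann.predicted_protein_length == full - 18

    def test_frameshift_iff_removed_mod3(self, genes, isoforms):
        for iso_id, can_id, gid in [("A3A2", "A3A1", "A3A"),
                                    ("A3B2", "A3B1", "A3B"),
                                    ("A3B3", "A3B1", "A3B")]:
            ann = annotate_event(isoforms[iso_id], isoforms[can_id], genes[gid])
            assert ann.frameshift == (ann.removed_nt % 3 != 0)

    def test_multiple_of_three_skip_keeps_frame(self):
        rng = np.random.default_rng(3)
        # CDS made of sense codons so the only stop is the final one
        codons = [c for c in
                  ("".join(t) for t in __import__("itertools").product(BASES, repeat=3))
                  if c not in ("TAA", "TAG", "TGA")]
        body = "".join(rng.choice(codons, size=100))
        e1, e2, e3 = "ATG" + body[:60], body[60:213], body[213:297] + "TAA"
        assert len(e2) == 153
        gene = _toy_gene([e1, e2, e3])
        can = gene.canonical_isoform("toy.1")
        skip = IsoformModel("toy.2", "toy", (can.segments[0], can.segments[2]))
        ann = annotate_event(skip, can, gene)
        assert ann.removed_nt == 153 and not ann.frameshift

    def test_canonical_vs_itself_is_null(self, genes, isoforms):
        ann = annotate_event(isoforms["A3B1"], isoforms["A3B1"], genes["A3B"])
        assert ann.removed_nt == 0
        assert not ann.frameshift and not ann.nmd_candidate
        assert ann.event_type is None

    def test_longer_isoform_rejected(self, genes, isoforms):
        with pytest.raises(ValueError, match="longer"):
            annotate_event(isoforms["A3B1"], isoforms["A3B3"], genes["A3B"])


class TestParalogFixture:
    def test_deterministic(self):
        g1, _ = paralog_fixture(seed=0)
        g2, _ = paralog_fixture(seed=0)
        assert g1["A3B"].transcript_sequence == g2["A3B"].transcript_sequence
        assert g1["A3A"].transcript_sequence == g2["A3A"].transcript_sequence

    def test_topology(self, genes, isoforms):
        assert len(genes["A3B"].exons) == 8
        assert len(genes["A3A"].exons) == 5
        e5 = genes["A3B"].exons[4]
        assert e5[1] - e5[0] == 154
        assert isoforms["A3B1"].canonical and isoforms["A3A1"].canonical

    def test_identical_paralogs_supported(self):
        genes, isoforms = paralog_fixture(identity=1.0, seed=0)
        a = isoforms["A3A1"].mrna(genes["A3A"])
        b = isoforms["A3B1"].mrna(genes["A3B"])
        # gene A mirrors gene B exons 4-8 up to the forced junction markers
        diffs = sum(x != y for x, y in zip(a, b[len(b) - len(a):]))
        assert diffs <= 4
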