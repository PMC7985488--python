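"""Strict junction matching, counting, expression calls, naive counter."""

import numpy as np
import pytest

from a3splice.gene_models import JunctionProbe, reverse_complement
from a3splice.junction_quant import (
    DEFAULT_DEFINING_JUNCTIONS,
    QuantConfig,
    call_expression,
    count_junction_reads,
    match_read_to_junction,
    naive_gene_counts,
    positive_fraction,
)

from _oracles import brute_force_match


def _probe(left, right, offs=()):
    assert len(left) == len(right)
    return JunctionProbe("j", "iso", left, right, len(left), frozenset(offs))


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def b1_probe(probes):
    return next(p for p in probes if p.junction_id == "A3B1:E5-E6")


class TestMatchRead:
    def test_exact_window_matches(self, b1_probe):
        assert match_read_to_junction(b1_probe.sequence, b1_probe)

    def test_reverse_complement_matches(self, b1_probe):
        assert match_read_to_junction(reverse_complement(b1_probe.sequence),
                                      b1_probe)

    def test_overhang_boundary(self):
        rng = np.random.default_rng(0)
        p = _probe(_rand(rng, 20), _rand(rng, 20))
        cfg = QuantConfig(min_overhang=10)
        # exactly 10 nt each side: matches; 9 on one side: does not
        assert match_read_to_junction(p.sequence[10:30], p, cfg)
        assert not match_read_to_junction(p.sequence[11:30], p, cfg)
        assert not match_read_to_junction(p.sequence[10:29], p, cfg)

    def test_single_mismatch_in_covered_window_rejected(self):
        rng = np.random.default_rng(1)
        p = _probe(_rand(rng, 15), _rand(rng, 15))
        read = list(p.sequence)
        read[2] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[2]]
        assert not match_read_to_junction("".join(read), p)

    def test_bases_outside_probe_window_ignored(self, b1_probe):
        read = "ACGT" * 5 + b1_probe.sequence + "TTTT" * 5
        assert match_read_to_junction(read, b1_probe)

    def test_n_never_matches(self):
        rng = np.random.default_rng(2)
        p = _probe(_rand(rng, 12), _rand(rng, 12))
        read = p.sequence[:11] + "N" + p.sequence[12:]
        assert not match_read_to_junction(read, p)

    def test_discriminating_coverage_required(self):
        rng = np.random.default_rng(3)
        p = _probe(_rand(rng, 30), _rand(rng, 30), offs=(-25,))
        cfg = QuantConfig(min_overhang=10)
        covering = p.sequence[2:45]       # includes index 5 (offset -25)
        not_covering = p.sequence[15:45]  # core only, misses offset -25
        assert match_read_to_junction(covering, p, cfg)
        assert not match_read_to_junction(not_covering, p, cfg)
        relaxed = QuantConfig(min_overhang=10, require_discriminating=False)
        assert match_read_to_junction(not_covering, p, relaxed)

    def test_empty_offset_set_is_vacuous(self):
        rng = np.random.default_rng(4)
        p = _probe(_rand(rng, 30), _rand(rng, 30))
        assert p.discriminating_offsets == frozenset()
        assert match_read_to_junction(p.sequence[15:45], p,
                                      QuantConfig(min_overhang=10))

    def test_empty_read_rejected(self, b1_probe):
        with pytest.raises(ValueError):
            match_read_to_junction("", b1_probe)

    def test_agrees_with_bruteforce_oracle_small(self, probes):
        rng = np.random.default_rng(5)
        subset = probes[:6]
        for cfg in (QuantConfig(min_overhang=8),
                    QuantConfig(min_overhang=8, require_discriminating=False)):
            for _ in range(60):
                p = subset[rng.integers(len(subset))]
                L = int(rng.integers(20, 60))
                start = int(rng.integers(0, len(p.sequence) - L + 1))
                read = list(p.sequence[start : start + L])
                if rng.random() < 0.3:
                    i = int(rng.integers(L))
                    read[i] = rng.choice([b for b in "ACGT" if b != read[i]])
                read = "".join(read)
                for q in subset:
                    assert match_read_to_junction(read, q, cfg) == \
                        brute_force_match(read, q, cfg.min_overhang,
                                          cfg.require_discriminating)


class TestCounting:
    def test_counts_and_ambiguity(self, probes):
        b1 = next(p for p in probes if p.junction_id == "A3B1:E5-E6")
        b3 = next(p for p in probes if p.junction_id == "A3B3:E4-E6")
        reads = {"s1": [b1.sequence, b1.sequence, b3.sequence, "ACGT" * 25],
                 "s2": []}
        matrix = count_junction_reads(reads, probes,
                                      probe_gene={p.junction_id: p.isoform_id[:3]
                                                  for p in probes})
        assert matrix.counts.at["s1", "A3B1:E5-E6"] == 2
        assert matrix.counts.at["s1", "A3B3:E4-E6"] == 1
        assert matrix.counts.loc["s2"].sum() == 0
        assert matrix.cross_ambiguous["s1"] == 0

    def test_duplicate_probe_ids_rejected(self, probes):
        with pytest.raises(ValueError, match="distinct"):
            count_junction_reads({"s": []}, [probes[0], probes[0]])

    def test_read_spanning_two_junctions_counts_both(self, genes, isoforms,
                                                     probes):
        # a read across a short middle segment can support both of its junctions
        mrna = isoforms["A3B1"].mrna(genes["A3B"])
        j = isoforms["A3B1"].junction_positions()[4]  # E5-E6 junction
        read = mrna[j - 170 : j + 30]  # spans E4-E5 and E5-E6 (E5 is 154 nt)
        cfg = QuantConfig(min_overhang=10)
        matrix = count_junction_reads({"s": [read]}, probes, cfg)
        assert matrix.counts.at["s", "A3B1:E4-E5"] == 1
        assert matrix.counts.at["s", "A3B1:E5-E6"] == 1


class TestExpressionCalls:
    def test_threshold_and_fraction(self, probes):
        b1 = next(p for p in probes if p.junction_id == "A3B1:E5-E6")
        reads = {"s1": [b1.sequence] * 3, "s2": [b1.sequence], "s3": []}
        matrix = count_junction_reads(reads, probes, QuantConfig())
        calls = call_expression(matrix, DEFAULT_DEFINING_JUNCTIONS,
                                QuantConfig(expression_threshold=2))
        b1_calls = calls[calls["isoform_id"] == "A3B1"].set_index("sample_id")
        assert bool(b1_calls.at["s1", "expressed"])
        assert not bool(b1_calls.at["s2", "expressed"])
        assert positive_fraction(calls, "A3B1") == pytest.approx(1 / 3)

    def test_missing_defining_junction_errors(self, probes):
        matrix = count_junction_reads({"s": []}, probes[:2])
        with pytest.raises(KeyError):
            call_expression(matrix, DEFAULT_DEFINING_JUNCTIONS)


class TestNaiveCounts:
    def test_own_gene_perfect_read_counts(self, genes, isoforms):
        mrna = isoforms["A3B1"].mrna(genes["A3B"])
        reads = {"s": [mrna[100:200], reverse_complement(mrna[500:600])]}
        out = naive_gene_counts(reads, genes)
        assert out.at["s", "A3B"] == 2

    def test_budget_controls_cross_counting(self, genes, isoforms):
        # a gene-A read from a low-divergence stretch cross-counts on gene B
        # under the mismatch budget but not at budget 0
        mrna_a = isoforms["A3A1"].mrna(genes["A3A"])
        mrna_b = genes["A3B"].mrna
        win_b = np.lib.stride_tricks.sliding_window_view(
            np.frombuffer(mrna_b.encode(), dtype="S1"), 100
        )
        read = None
        for start in range(0, len(mrna_a) - 100, 10):
            candidate = np.frombuffer(
                mrna_a[start : start + 100].encode(), dtype="S1"
            )
            best = int((win_b != candidate).sum(axis=1).min())
            if 1 <= best <= 3:
                read = mrna_a[start : start + 100]
                break
        assert read is not None, "fixture should contain a near-identical stretch"
        loose = naive_gene_counts({"s": [read]}, genes,
                                  QuantConfig(naive_max_mismatch=3))
        strict = naive_gene_counts({"s": [read]}, genes,
                                   QuantConfig(naive_max_mismatch=0))
        assert loose.at["s", "A3B"] == 1 and loose.at["s", "A3A"] == 1
        assert strict.at["s", "A3B"] == 0
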