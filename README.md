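# a3splice

Isoform-level analysis of two highly homologous APOBEC3 paralogs
(APOBEC3A-like and APOBEC3B-like genes) from RNA-seq junction reads, with a
fully synthetic, ground-truth-bearing cohort simulator for validating every
statistical step.

## The problem

APOBEC3A and APOBEC3B are cytidine deaminases whose preferred tCw mutation
context dominates the mutation spectra of many tumors. The two genes are
~92% identical at the nucleotide level, so conventional total-gene RNA-seq
counting cannot tell them apart: reads from one paralog align to the other
within any reasonable mismatch budget, inflating both counts. The genes can
only be distinguished — and their splice isoforms only quantified — through
exon–exon junction reads that (a) span the splice point with enough perfect
overhang on both sides and (b) cover at least one *discriminating position*,
a base at which the two paralogs' junction contexts differ.

This package implements that analysis end to end:

- **`gene_models`** — gene/isoform containers, junction probes with
  discriminating offsets, and protein-consequence annotation of splice
  events (frame, premature stop, NMD candidacy). A deterministic two-paralog
  fixture reproduces the studied topology: an 8-exon gene with a
  frameshifting 154-nt exon-5 skip and a 75-nt in-frame cryptic acceptor in
  exon 6, and a 5-exon paralog with a 54-nt cryptic acceptor in exon 2.
- **`junction_quant`** — strict junction-read counting (≥10 nt perfect
  overhang per side, zero mismatches in the covered probe window,
  discriminating-position coverage), expression calls, and the *naive*
  total-gene counter that deliberately reproduces the cross-alignment trap.
- **`splicing_metrics`** — junction PSI (percent spliced-in), the paired
  tumor/normal Wilcoxon comparison, and densitometry percent-skipping.
- **`mutagenesis_stats`** — per-sample APOBEC tCw enrichment E, the
  conservative minimum-estimate burden m_tCw·(E−1)/E, and the Spearman
  expression–burden correlation on log10(x+1) scales.
- **`survival_analysis`** — No/Low/High expression grouping, an in-repo
  Kaplan–Meier estimator, and a Cox model adjusted for sex, age and stage.
- **`assay_models`** — deterministic calculators for the bench readouts:
  deamination cleavage fragment sizes, 2^−ΔΔCt qPCR quantification with dual
  endogenous controls, and amplicon substitution profiling.
- **`synthetic_data`** — cohorts with known ground truth: isoform mixtures
  with NMD depletion and a tumor/normal PSI shift, error-bearing reads,
  mutation catalogs whose tCw burden tracks expression, survival times with
  group-dependent hazards, qPCR and densitometry tables.
- **`pipeline` / CLI** — `simulate → quant → psi → score → correlate →
  survival → report` as one command or per-stage subcommands, with a
  SHA-256 manifest guaranteeing byte-level reproducibility.

## Quick start (CLI)

```sh
cat > demo.yaml <<EOF
seed: 7
n_pairs: 30
EOF
a3splice run --config demo.yaml --outdir demo
```

Output (about 20 s on one CPU):

```
a3splice simulate: 60 samples, 215291 reads -> demo
a3splice quant: 60 samples x 28 junctions
a3splice psi: 60 samples, 27 informative pairs
a3splice score: 60 samples, 0 undefined
a3splice correlate: rho=0.196 over 30 tumors
a3splice survival: groups {'No': 3, 'Low': 14, 'High': 13}
config d1b2a84723e7 seed 7: 80 result files in demo
```

`demo/summary.txt` then reads:

```
a3splice run summary
====================

expression-positive fraction per isoform:
  A3A1: 53.33%
  A3A2: 40.00%
  A3B1: 90.00%
  A3B2: 83.33%
  A3B3: 60.00%
paired tumor-normal PSI: median diff +0.0205, Wilcoxon p=1.67e-06 over 23 pairs
expression vs APOBEC burden: Spearman rho=0.196 (p=0.299, n=30)
Cox (vs No expression): Low HR=0.57, High HR=1.09
```

The paired PSI shift is already unambiguous at 30 pairs; the correlation and
survival effects are real but need larger cohorts to surface cleanly — the
test suite recovers the calibrated Spearman rho = 0.30 ± 0.05 at n = 400 and
a true hazard ratio of 2.0 within [1.6, 2.5] at n = 600 (see
`tests/test_acceptance.py`). Every result file is listed with its SHA-256 in
`demo/manifest.json`; rerunning with the same config and seed reproduces all
of them byte for byte.

## Worked example (library)

```python
>>> from a3splice.gene_models import paralog_fixture, annotate_event
>>> genes, isoforms = paralog_fixture()
>>> annotate_event(isoforms["A3B2"], isoforms["A3B1"], genes["A3B"])
SpliceEventAnnotation(event_id='A3B1->A3B2', event_type='cryptic_acceptor',
    removed_nt=75, frameshift=False, ptc_segment_index=None,
    nmd_candidate=False, predicted_protein_length=418)
>>> annotate_event(isoforms["A3B3"], isoforms["A3B1"], genes["A3B"])
SpliceEventAnnotation(event_id='A3B1->A3B3', event_type='exon_skip',
    removed_nt=154, frameshift=True, ptc_segment_index=4,
    nmd_candidate=True, predicted_protein_length=206)
```

The full-length protein is 443 aa, so the in-frame cryptic-acceptor isoform
loses exactly 75/3 = 25 aa (418 aa), while the 154-nt exon skip shifts the
frame and truncates to 206 aa with a premature stop in a non-final segment —
an NMD candidate. The junction probes carry the discriminating positions the
counter requires:

```python
>>> from a3splice.gene_models import build_junction_probes
>>> probes = build_junction_probes(isoforms.values(), genes, flank_len=39)
>>> p = next(q for q in probes if q.junction_id == "A3B1:E5-E6")
>>> sorted(p.discriminating_offsets)[:6]
[-34, -26, -5, -3, 1, 7]
```

And the deamination-assay fragment calculator reproduces the canonical
48-nt probe arithmetic:

```python
>>> from a3splice.assay_models import DEAMINATION_PROBE, predict_cleavage_products
>>> predict_cleavage_products(DEAMINATION_PROBE)
CleavageResult(substrate_length=48, target_position=26,
    five_prime_fragment=25, three_prime_fragment=22)
```

## Tests and reproduction

```sh
python -m pytest -q tests/                       # full suite (~2 min)
python scripts/acceptance.py --seed 1 --out acceptance.json
```

`tests/test_acceptance.py` holds the binding checks: the worked-example
numbers above (t1–t6 in `scripts/acceptance.py`) plus the statistical
recovery suites — junction matcher ≡ brute-force placement oracle, zero
cross-paralog misassignments over >10,000 error-free reads alongside
strictly positive naive-count inflation, PSI recovery within 0.03 at depth
5,000, Wilcoxon exact-enumeration agreement and type-I error control,
Spearman and Cox effect recovery, the closed-form minimum-estimate identity,
and end-to-end byte determinism. All oracles are independent
re-derivations in `tests/_oracles.py`, never the package's own code paths.

`scripts/acceptance.py` recomputes the six worked-example targets at runtime
and writes `{"<id>": {"value": ..., "n": ...}}` JSON; its output is
independent of `--seed` by construction (the fixture generator enforces the
event consequences for any seed).

Model assumptions, parameter rationale (including the one-time calibration
of `burden_slope = 0.30`) and known limitations are documented in
[docs/methods.md](docs/methods.md).
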