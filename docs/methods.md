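# Methods

This note records the models the package implements, the defaults it ships,
and the numerical and scope decisions behind them. Everything here describes
what the code computes on its own synthetic cohorts; no claim is made about
any external dataset.

## 1. Gene/isoform model and the paralog fixture

Genes are pre-mRNA sequences with ordered, non-overlapping exon intervals in
0-based half-open transcript coordinates; strand is abstracted away (both
modelled paralogs are co-oriented, and every downstream computation is
strand-symmetric where it matters — read matching and context counting fold
both orientations explicitly). Isoforms are ordered sub-intervals of parent
exons; the canonical isoform uses all exons unmodified.

`paralog_fixture()` builds a deterministic two-gene system:

- **A3B** (8 exons of 180/150/180/160/154/210/140/250 nt, 150-nt introns
  with GT..AG ends, 60-nt 5' UTR): canonical isoform **A3B1**; **A3B2**
  removes the first 75 nt of exon 6 via a cryptic acceptor (in-frame, −25
  aa); **A3B3** skips the 154-nt exon 5 (154 mod 3 = 1, frameshift).
- **A3A** (5 exons copied from A3B exons 4–8 at a configurable identity,
  default 92%, 30-nt 5' UTR so the shared sequence stays frame-aligned):
  canonical **A3A1**; **A3A2** removes the first 54 nt of exon 2 (in-frame,
  −18 aa).

The generator retries internal subseeds until the published event
consequences hold exactly for the emitted sequences: clean ORFs, the −25 aa
and −18 aa in-frame events, and the frameshift stop of A3B3 landing in the
exon-6 segment (a non-final segment, hence an NMD candidate). Because the
constraints are enforced, these properties hold for *every* fixture seed;
the acceptance script exploits this to be seed-independent.

**Paralog divergence is block-structured**: substitutions are applied
codon-aware (never creating an in-frame stop) at twice the nominal rate in
alternating 120-nt blocks and at ~0 in between. Recently duplicated genes
are exactly like this — long near-identical stretches interrupted by
diverged patches — and the near-identical stretches are what makes
total-gene read counting unreliable, while junction windows still carry
discriminating bases. A uniform 8% divergence would leave no 100-nt window
within a 3-mismatch budget of the other gene and would make the
cross-alignment failure mode invisible. One discriminating base 3 nt left of
each homologous junction is forced so junction identity never depends on
luck of the mutation draw.

**NMD rule.** A transcript is an NMD candidate when its first stop codon
falls in any segment other than the last. The finer 50-nt-from-last-junction
refinement of the canonical NMD rule is deliberately not modelled; for the
exon sizes used here the two rules agree.

## 2. Junction probes and strict read counting

A probe is the 2·`flank_len` window of the isoform's mature mRNA centred on
a junction (default `flank_len` 39 nt = the 10-nt overhang requirement plus
generous margin). Discriminating offsets are found by comparing each probe
to the *closest* probe (minimum Hamming distance) of any other gene; the
homologue must lie within 30% mismatches of the window, otherwise the
junction's topology is unique to its gene, no cross-paralog read can
resemble it, and the probe keeps an **empty discriminating set, which the
matcher treats as vacuously satisfied**. This matters: forcing a
discriminating-coverage requirement onto topology-unique junctions (e.g. the
A3B3 skip junction) would reject legitimate reads with short overhangs on
one side and bias PSI.

A read supports a junction iff some ungapped placement (either orientation)
has zero mismatches over the covered probe window, ≥ `min_overhang` (10)
matching nt on each side of the junction point, and — when the probe has
discriminating offsets — covers at least one of them. `N` never matches.
Reads are allowed to extend past the probe window; bases outside it are not
examined (they belong to exons whose identity the junction itself already
implies).

`naive_gene_counts` is the intentionally wrong comparator: a read counts for
every gene admitting an ungapped placement within a mismatch budget
(default 3). On fixture reads it inflates the other paralog by hundreds of
reads per 1500 while the junction counter misassigns none; tests pin both
behaviours.

## 3. PSI and the paired comparison

For the exon-5 event, inclusion evidence is the **mean** of the two flanking
junction counts (one included exon contributes two junctions, so the mean
puts inclusion and exclusion on a per-molecule scale) and exclusion evidence
is the skip-junction count. PSI = inclusion/(inclusion+exclusion); samples
with fewer than 10 informative reads are undefined and excluded. Reported
integer inclusion counts round half-up; the PSI ratio itself uses the
unrounded mean.

The tumor/normal comparison is a two-sided Wilcoxon matched-pairs
signed-rank test on per-pair PSI differences (scipy; exact null for ≤25
informative pairs, zero differences dropped per the test's convention,
minimum 5 informative pairs).

Read counts per isoform are Poisson with mean = abundance × effective-length
ratio, where effective length is (mRNA length − read length + 1) relative to
the gene's canonical isoform. Without this factor, equal abundances of a
long and a short isoform would put more junction-spanning reads on the
longer one and junction PSI would be biased (~0.05 at PSI 0.5 in early
prototypes); with it, PSI is recovered within 0.03 at depth 5,000.

The PSI-recovery suites switch decay off (`nmd_retention = 1.0`): the
cohort simulator multiplies the skipped isoform's abundance by
`nmd_retention` *after* drawing the inclusion fraction, so observed junction
PSI is by construction above the drawn value — exactly the biology (decayed
transcripts are invisible), but the convergence property under test is a
statement about the estimator, so it is checked on mixtures where the
estimand equals the drawn value.

## 4. APOBEC enrichment and burden

Per sample, over C>T/G mutations folded to the pyrimidine strand:

    E = (m_tCw · n_C) / (m_C · n_tCw)

where m are mutation counts and n are context availabilities summed over the
±20-nt reference windows of the mutated cytosines, counted on both strands.
The conservative burden ("minimum estimate") is m_tCw·(E−1)/E for E > 1,
else 0 — the expected number of tCw mutations beyond what availability alone
produces. E is undefined (with an explicit reason) when a sample has no C
mutations or its windows contain no tCw context.

The expression–burden association is Spearman rank correlation of
log10(x+1)-transformed values (monotone, hence rank-identical to the raw
scale; the transform keeps reported axes comparable). Cancer-type
eligibility uses a ≥10% APOBEC-positive-sample threshold with an explicit
exclusion list for confounded types.

## 5. Survival

Tumors with zero canonical-isoform evidence form the "No" group; the rest
split at their nonzero median into "Low" (ties included) and "High". The
Kaplan–Meier product-limit estimator is implemented in-repo (and checked
against both a hand oracle and lifelines); the Cox partial likelihood (Efron
ties) is delegated to lifelines, with group indicators versus "No" adjusted
for sex (0/1), age, and ordered integer stage. Degenerate designs (no events
in a group level, non-convergence) raise with the offending term named.

## 6. Bench-assay calculators

- **Cleavage**: deamination at the unique TC-context C of a probe, uracil
  excision and alkaline cleavage leave a 5'-labelled fragment of
  `target_position − 1` nt — 25 nt for the 48-nt (ATA)₈TCC(ATA)₇ probe.
- **2^−ΔΔCt**: per replicate, ΔCt = target Ct − arithmetic mean of the two
  control Cts (equivalent to geometric-mean normalisation of expression);
  ΔΔCt against the reference group's mean ΔCt.
- **Amplicon profiling**: each read is placed ungapped at its leftmost
  minimal-mismatch offset (reverse complement also tried; forward preferred
  on ties); reads worse than 20% mismatches are discarded and counted. The
  summary statistic is the C→T rate at TC-context reference positions.

## 7. Simulation defaults (the study conditions)

| parameter | default | rationale |
|---|---|---|
| `n_pairs` | 30 | desk-scale demo cohort; statistical suites override per their stated n |
| `read_len` / `error_rate` | 100 nt / 0.005 | typical short-read RNA-seq |
| `depth` | 2000 | expected reads for a fully expressed isoform at demo scale |
| `paralog_identity` | 0.92 | the paralogs' nucleotide identity |
| `psi_tumor` / `psi_normal` | 0.95 / 0.85 | small but systematic tumor shift toward inclusion |
| `psi_concentration` | 60 | Beta concentration; per-sample PSI sd ≈ 0.03–0.05 |
| `nmd_retention` | 0.15 | strong but incomplete decay of the frameshifted isoform |
| `a3b2_fraction` / `a3a2_fraction` | 0.05 / 0.03 | minor constitutive cryptic-acceptor share |
| `expr_sigma` | 0.6 | log-normal between-pair expression spread; paired samples share the pair scale up to lognormal(0, 0.2) noise |
| `zero_rate_a` / `zero_rate_b` | 0.35 / 0.15 | genes are undetectable in a substantial sample fraction, A more often than B |
| `burden_intercept` / `burden_slope` | 0.3 / 0.30 | tCw burden mean exp(intercept + slope·log10(1+x)); **slope calibrated once** by Monte Carlo so the cohort-level Spearman rho ≈ 0.30 (sweep over 0.1–0.4 gave rho 0.09/0.20/0.32/0.43; 0.30 frozen before the recovery test was written and not revisited) |
| `background_c_mean` / `background_t_mean` | 30 / 10 | expression-independent mutation background |
| `hazard_ratios` | (1, 2, 4) | No/Low/High progression hazards; recovery suites use (1, 1.4, 2.0) to test a true HR of 2.0 |
| `base_median_survival` / `followup_horizon` | 40 / 60 months | exponential times with administrative censoring |
| `reference_length` | 100 kb | synthetic mutation reference; large enough that context availability is stable |

All randomness flows from `seed` through fixed substreams
(`default_rng([seed mod 2^31, purpose, index])`, with SHA-256-derived
per-sample indices), so adding samples never perturbs existing ones and
every output is reproducible byte for byte.

## 8. Limitations

- Splice events are deletions relative to the canonical isoform; inclusion
  (retention/insertion) events are rejected, not modelled.
- Reads are single-end, ungapped, substitution-error-only; no indels,
  quality-dependent errors, or fragment-size model.
- The NMD rule ignores the 50-nt boundary refinement; NMD efficiency is a
  single retention fraction, not transcript-specific.
- The mutation model places mutations independently per site class with a
  fixed 70/30 C>T/C>G split in tCw; no clustering (kataegis), copy number,
  or signature mixture beyond tCw-vs-background.
- The Cox model assumes proportional hazards by construction of the
  simulator; no diagnostics are provided.
- Densitometry and qPCR noise are Gaussian on the natural scales, with no
  saturation or efficiency modelling.
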