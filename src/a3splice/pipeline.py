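"""End-to-end workflow: simulate -> quantify -> analyze -> report.

Each stage reads only the files of earlier stages (never simulation ground
truth), so the pipeline exercises the same label-free path a real cohort
would.  A run manifest records the config hash, seed, package version and
the SHA-256 of every result file; identical config + seed reproduce every
result file byte for byte (the manifest's timestamp is informational).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gene_models import build_junction_probes
from .io import (read_fastq_sequences, read_probes, write_gene_models,
                 write_probes)
from .junction_quant import (DEFAULT_DEFINING_JUNCTIONS, JunctionCountMatrix,
                             QuantConfig, call_expression, count_junction_reads,
                             positive_fraction)
from .mutagenesis_stats import (ApobecScore, apobec_enrichment,
                                correlate_expression_burden)
from .splicing_metrics import (EXON5_SKIP_EVENT, compute_psi, paired_psi_test,
                               psi_table)
from .survival_analysis import (cox_adjusted, kaplan_meier_by_group,
                                stratify_expression_groups)
from .synthetic_data import (SimulationConfig, cohort_table, default_models,
                             mutation_context_windows, mutations_to_table,
                             reads_to_fastq, simulate_cohort, simulate_mutations,
                             simulate_reads, MutationRecord)

__all__ = ["RunManifest", "run_end_to_end", "write_report", "load_config"]

log = logging.getLogger("a3splice")


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: dict[str, str]  # relative path -> sha256
    timestamp: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig(**data)


def _config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def stage_simulate(config: SimulationConfig, outdir: Path) -> None:
    genes, isoforms = default_models(config)
    write_gene_models(genes, isoforms, outdir / "models.gtf", outdir / "models.fasta")
    probes = build_junction_probes(isoforms.values(), genes)
    write_probes(probes, outdir / "probes.fasta", outdir / "probes.tsv")

    samples = simulate_cohort(config)
    cohort_table(samples).to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    fastq_dir = outdir / "fastq"
    fastq_dir.mkdir(exist_ok=True)
    n_reads = 0
    mutation_rows = []
    for s in samples:
        reads = simulate_reads(s, isoforms, genes, config)
        n_reads += len(reads)
        reads_to_fastq(reads, fastq_dir / f"{s.sample_id}.fastq")
        muts = simulate_mutations(s, config)
        windows = mutation_context_windows(muts, config)
        mutation_rows.append(mutations_to_table(muts, windows))
    pd.concat(mutation_rows, ignore_index=True).to_csv(
        outdir / "mutations.tsv", sep="\t", index=False
    )
    log.info("simulate: %d samples, %d reads -> %s", len(samples), n_reads, outdir)


def stage_quant(config: SimulationConfig, outdir: Path,
                quant: QuantConfig | None = None) -> JunctionCountMatrix:
    quant = quant or QuantConfig()
    probes = read_probes(outdir / "probes.fasta", outdir / "probes.tsv")
    cohort = pd.read_csv(outdir / "cohort.tsv", sep="\t")
    reads_by_sample = {
        sid: read_fastq_sequences(outdir / "fastq" / f"{sid}.fastq")
        for sid in cohort["sample_id"]
    }
    probe_gene = {p.junction_id: p.isoform_id[:3] for p in probes}
    matrix = count_junction_reads(reads_by_sample, probes, quant, probe_gene)
    matrix.to_tsv(outdir / "junction_counts.tsv")
    matrix.cross_ambiguous.rename("cross_ambiguous_reads").to_csv(
        outdir / "ambiguity.tsv", sep="\t", index_label="sample_id"
    )
    calls = call_expression(matrix, DEFAULT_DEFINING_JUNCTIONS, quant)
    calls.to_csv(outdir / "expression_calls.tsv", sep="\t", index=False)
    log.info("quant: %d samples x %d junctions", *matrix.counts.shape)
    return matrix


def _load_matrix(outdir: Path) -> JunctionCountMatrix:
    counts = pd.read_csv(outdir / "junction_counts.tsv", sep="\t",
                         index_col="sample_id")
    return JunctionCountMatrix(counts=counts, config=QuantConfig())


def stage_psi(config: SimulationConfig, outdir: Path) -> dict:
    matrix = _load_matrix(outdir)
    values = compute_psi(matrix, EXON5_SKIP_EVENT)
    psi_table(values).to_csv(outdir / "psi.tsv", sep="\t", index=False,
                             float_format="%.6g")
    cohort = pd.read_csv(outdir / "cohort.tsv", sep="\t")
    by_sample = {v.sample_id: v.psi for v in values}
    pairs = {}
    for pid, grp in cohort.groupby("pair_id"):
        t = grp.loc[grp["condition"] == "tumor", "sample_id"]
        n = grp.loc[grp["condition"] == "normal", "sample_id"]
        if len(t) == 1 and len(n) == 1:
            pairs[pid] = (by_sample.get(t.iloc[0]), by_sample.get(n.iloc[0]))
    n_informative = sum(1 for t, n in pairs.values()
                        if t is not None and n is not None)
    try:
        res = paired_psi_test(pairs)
        report = {
            "event_id": EXON5_SKIP_EVENT.event_id,
            "statistic": res.statistic, "pvalue": res.pvalue,
            "n_pairs_used": res.n_pairs_used,
            "median_difference": res.median_difference,
            "n_informative_pairs": n_informative,
        }
    except ValueError as exc:
        report = {"event_id": EXON5_SKIP_EVENT.event_id, "error": str(exc),
                  "n_informative_pairs": n_informative}
    _dump_json(report, outdir / "psi_test.json")
    log.info("psi: %d samples, %d informative pairs", len(values), n_informative)
    return report


def _read_mutations(outdir: Path):
    table = pd.read_csv(outdir / "mutations.tsv", sep="\t")
    by_sample: dict[str, list[MutationRecord]] = {}
    windows: dict[int, str] = {}
    for row in table.itertuples():
        by_sample.setdefault(row.sample_id, []).append(
            MutationRecord(row.sample_id, int(row.position), row.ref, row.alt,
                           row.context)
        )
        windows[int(row.position)] = row.window
    return by_sample, windows


def stage_score(config: SimulationConfig, outdir: Path) -> list[ApobecScore]:
    by_sample, windows = _read_mutations(outdir)
    cohort = pd.read_csv(outdir / "cohort.tsv", sep="\t")
    scores = [
        apobec_enrichment(by_sample.get(sid, []), windows, sample_id=sid)
        for sid in cohort["sample_id"]
    ]
    pd.DataFrame(
        [{"sample_id": s.sample_id, "m_tcw": s.m_tcw, "m_c": s.m_c,
          "n_tcw": s.n_tcw, "n_c": s.n_c, "enrichment_e": s.enrichment_e,
          "minimum_estimate": s.minimum_estimate, "reason": s.reason or "."}
         for s in scores]
    ).to_csv(outdir / "apobec_scores.tsv", sep="\t", index=False,
             float_format="%.6g")
    log.info("score: %d samples, %d undefined", len(scores),
             sum(s.enrichment_e is None for s in scores))
    return scores


def _representative_counts(outdir: Path, isoform: str = "A3B1") -> dict[str, float]:
    calls = pd.read_csv(outdir / "expression_calls.tsv", sep="\t")
    sub = calls[calls["isoform_id"] == isoform]
    return dict(zip(sub["sample_id"], sub["count"].astype(float)))


def stage_correlate(config: SimulationConfig, outdir: Path) -> dict:
    scores_df = pd.read_csv(outdir / "apobec_scores.tsv", sep="\t")
    cohort = pd.read_csv(outdir / "cohort.tsv", sep="\t")
    tumors = set(cohort.loc[cohort["condition"] == "tumor", "sample_id"])
    expression = {
        s: c for s, c in _representative_counts(outdir).items() if s in tumors
    }
    scores = [
        ApobecScore(r.sample_id, int(r.m_tcw), int(r.m_c), int(r.n_tcw),
                    int(r.n_c),
                    None if pd.isna(r.enrichment_e) else float(r.enrichment_e),
                    float(r.minimum_estimate))
        for r in scores_df.itertuples() if r.sample_id in tumors
    ]
    res = correlate_expression_burden(expression, scores)
    report = {
        "variables": list(res.variable_pair), "n": res.n,
        "spearman_rho": res.spearman_rho, "pvalue": res.pvalue,
    }
    _dump_json(report, outdir / "correlation.json")
    log.info("correlate: rho=%.3f over %d tumors", res.spearman_rho, res.n)
    return report


def stage_survival(config: SimulationConfig, outdir: Path) -> dict:
    cohort = pd.read_csv(outdir / "cohort.tsv", sep="\t").set_index("sample_id")
    tumors = cohort[cohort["condition"] == "tumor"]
    counts = {s: c for s, c in _representative_counts(outdir).items()
              if s in tumors.index}
    grouping = stratify_expression_groups(counts)
    pd.DataFrame(
        [{"sample_id": s, "group": g} for s, g in sorted(grouping.assignments.items())]
    ).to_csv(outdir / "expression_groups.tsv", sep="\t", index=False)
    times = tumors["followup_time"].to_dict()
    events = tumors["progression_event"].astype(bool).to_dict()
    curves = kaplan_meier_by_group(grouping, times, events)
    for g, curve in curves.items():
        curve.table().to_csv(outdir / f"km_{g}.tsv", sep="\t", index=False,
                             float_format="%.6g")
    report: dict = {
        "groups": {"No": grouping.n_no, "Low": grouping.n_low,
                   "High": grouping.n_high},
        "median_used": grouping.median_used,
    }
    try:
        cox = cox_adjusted(grouping, tumors[["sex", "age", "stage"]],
                           times, events)
        report["cox"] = {
            "hazard_ratios": cox.hazard_ratios, "pvalues": cox.pvalues,
            "ci_lower": cox.ci_lower, "ci_upper": cox.ci_upper,
            "n": cox.n, "n_events": cox.n_events,
        }
    except (ValueError, RuntimeError) as exc:
        report["cox"] = {"error": str(exc)}
    _dump_json(report, outdir / "survival.json")
    log.info("survival: groups %s", report["groups"])
    return report


def write_report(outdir: Path) -> dict:
    """Collect stage outputs into summary.json + summary.txt.

    Missing stage outputs leave explicit gaps rather than failing.
    """
    summary: dict = {"stages": {}}

    calls_path = outdir / "expression_calls.tsv"
    if calls_path.exists():
        calls = pd.read_csv(calls_path, sep="\t")
        summary["stages"]["expression"] = {
            iso: round(positive_fraction(calls, iso), 4)
            for iso in sorted(calls["isoform_id"].unique())
        }
    else:
        summary["stages"]["expression"] = None

    for name, path in [("psi_test", "psi_test.json"),
                       ("correlation", "correlation.json"),
                       ("survival", "survival.json")]:
        p = outdir / path
        summary["stages"][name] = json.loads(p.read_text()) if p.exists() else None

    _dump_json(summary, outdir / "summary.json")
    lines = ["a3splice run summary", "====================", ""]
    expr = summary["stages"]["expression"]
    if expr:
        lines.append("expression-positive fraction per isoform:")
        lines += [f"  {iso}: {frac:.2%}" for iso, frac in expr.items()]
    psi = summary["stages"]["psi_test"]
    if psi and "pvalue" in psi:
        lines.append(
            f"paired tumor-normal PSI: median diff {psi['median_difference']:+.4f}, "
            f"Wilcoxon p={psi['pvalue']:.3g} over {psi['n_pairs_used']} pairs"
        )
    corr = summary["stages"]["correlation"]
    if corr:
        lines.append(
            f"expression vs APOBEC burden: Spearman rho={corr['spearman_rho']:.3f} "
            f"(p={corr['pvalue']:.3g}, n={corr['n']})"
        )
    surv = summary["stages"]["survival"]
    if surv and "cox" in surv and "hazard_ratios" in surv.get("cox", {}):
        hr = surv["cox"]["hazard_ratios"]
        lines.append(
            "Cox (vs No expression): "
            f"Low HR={hr.get('group_low', float('nan')):.2f}, "
            f"High HR={hr.get('group_high', float('nan')):.2f}"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary


_STAGES = ("simulate", "quant", "psi", "score", "correlate", "survival")


def run_end_to_end(config: SimulationConfig, outdir) -> RunManifest:
    """Run every stage in order and write the manifest; fails loudly per stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_fns = {
        "simulate": stage_simulate, "quant": stage_quant, "psi": stage_psi,
        "score": stage_score, "correlate": stage_correlate,
        "survival": stage_survival,
    }
    for name in _STAGES:
        try:
            stage_fns[name](config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    write_report(outdir)

    outputs = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=config.seed,
        version=__version__,
        outputs=outputs,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
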