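"""APOBEC tCw mutation-burden scoring and expression correlation.

The enrichment statistic compares the fraction of C>T/G mutations occurring
in the tCw context (t = 5' thymine, w = 3' A or T; both strands folded to
the pyrimidine representation) against the availability of tCw versus C
contexts in the +/-20-nt windows around the mutated cytosines:

    E = (m_tcw * n_c) / (m_c * n_tcw)

The conservative per-sample APOBEC burden ("minimum estimate") is
m_tcw * (E - 1) / E for E > 1 and 0 otherwise — the expected number of tCw
mutations above what context availability alone would produce.

Expression/burden association uses Spearman rank correlation on
log10(x + 1)-transformed values (the transform is monotone, so rho is
unchanged; it is applied to keep reported scales comparable).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic_data import MutationRecord

__all__ = [
    "ApobecScore",
    "CorrelationResult",
    "apobec_enrichment",
    "correlate_expression_burden",
    "eligible_cancer_types",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ApobecScore:
    sample_id: str
    m_tcw: int          # tCw -> tTw/tGw mutations
    m_c: int            # all C -> T/G mutations (pyrimidine-normalised)
    n_tcw: int          # tCw context occurrences in the mutation windows
    n_c: int            # C context occurrences in the mutation windows
    enrichment_e: float | None
    minimum_estimate: float
    reason: str | None = None  # set when the score is undefined

    def __post_init__(self):
        if self.m_tcw > self.m_c:
            raise ValueError("m_tcw cannot exceed m_c")
        if self.minimum_estimate < 0 or self.minimum_estimate > self.m_tcw + 1e-9:
            raise ValueError("minimum_estimate outside [0, m_tcw]")


@dataclass(frozen=True)
class CorrelationResult:
    variable_pair: tuple[str, str]
    n: int
    spearman_rho: float
    pvalue: float

    def __post_init__(self):
        if abs(self.spearman_rho) > 1.0 + 1e-12:
            raise ValueError("|rho| must be <= 1")
        if self.n < 3:
            raise ValueError("need n >= 3")


def _is_c_mutation(rec: MutationRecord) -> tuple[bool, bool]:
    """(is C->T/G after pyrimidine folding, is tCw context)."""
    ref, alt, ctx = rec.ref_base, rec.alt_base, rec.trinucleotide_context
    if ref in "GA":
        ref, alt = _revcomp(ref), _revcomp(alt)
    if ctx[1] != ref:
        raise ValueError(
            f"context {ctx} inconsistent with ref {rec.ref_base} at {rec.position}"
        )
    is_c = ref == "C" and alt in "TG"
    is_tcw = is_c and ctx[0] == "T" and ctx[2] in "AT"
    return is_c, is_tcw


@functools.lru_cache(maxsize=262_144)
def _count_contexts(window: str) -> tuple[int, int]:
    """(tCw occurrences, C occurrences) on both strands of a window."""
    n_c = window.count("C") + window.count("G")
    n_tcw = 0
    for i in range(1, len(window) - 1):
        tri = window[i - 1 : i + 2]
        if tri[1] == "C" and tri[0] == "T" and tri[2] in "AT":
            n_tcw += 1
        elif tri[1] == "G" and tri[2] == "A" and tri[0] in "AT":
            n_tcw += 1  # reverse-strand tCw
    return n_tcw, n_c


def apobec_enrichment(
    mutations: list[MutationRecord],
    windows: dict[int, str],
    sample_id: str | None = None,
) -> ApobecScore:
    """Per-sample enrichment E and minimum-estimate burden.

    ``windows`` maps mutation position -> its +/-20-nt reference window;
    context availability is tallied over the windows of the C>T/G mutations.
    """
    if sample_id is None:
        sample_id = mutations[0].sample_id if mutations else "NA"
    m_c = m_tcw = n_c = n_tcw = 0
    for rec in mutations:
        if rec.position not in windows:
            raise KeyError(f"no context window for position {rec.position}")
        is_c, is_tcw = _is_c_mutation(rec)
        if not is_c:
            continue
        m_c += 1
        m_tcw += int(is_tcw)
        w_tcw, w_c = _count_contexts(windows[rec.position])
        n_tcw += w_tcw
        n_c += w_c
    if m_c == 0 or n_tcw == 0:
        return ApobecScore(sample_id, m_tcw, m_c, n_tcw, n_c, None, 0.0,
                           reason="no C mutations" if m_c == 0 else "no tCw contexts")
    e = (m_tcw * n_c) / (m_c * n_tcw)
    minimum = m_tcw * (e - 1.0) / e if e > 1.0 else 0.0
    return ApobecScore(sample_id, m_tcw, m_c, n_tcw, n_c, float(e), float(minimum))


def correlate_expression_burden(
    expression: dict[str, float],
    scores: list[ApobecScore],
    burden_attr: str = "minimum_estimate",
) -> CorrelationResult:
    """Spearman correlation of log10(x+1) expression vs log10(burden+1)."""
    burden = {s.sample_id: getattr(s, burden_attr) for s in scores}
    common = sorted(set(expression) & set(burden))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} paired samples; need >= 3")
    x = np.log10(1.0 + np.array([expression[s] for s in common], dtype=float))
    y = np.log10(1.0 + np.array([burden[s] for s in common], dtype=float))
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant variable; Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(
        variable_pair=("expression", burden_attr),
        n=len(common),
        spearman_rho=float(rho),
        pvalue=float(p),
    )


def eligible_cancer_types(
    per_type_scores: dict[str, list[ApobecScore]],
    threshold: float = 0.10,
    exclude: tuple[str, ...] = (),
) -> list[str]:
    """Cancer types where >= threshold of samples are APOBEC-signature positive.

    A sample is positive when its minimum estimate is > 0.  ``exclude`` drops
    named types regardless of their fraction (e.g. a UV-confounded type).
    """
    kept = []
    for t, scores in sorted(per_type_scores.items()):
        if t in exclude or not scores:
            continue
        frac = np.mean([s.minimum_estimate > 0 for s in scores])
        if frac >= threshold:
            kept.append(t)
    return kept
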