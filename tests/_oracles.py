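"""Independent reference implementations used as test oracles.

Each function here is a deliberately naive re-derivation of a statistic or
matching rule implemented (more efficiently) in the package; tests assert
equality against these, never against the package's own output.
"""

import itertools

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _match_one_orientation(read, probe, min_overhang, require_discriminating):
    f = probe.flank_len
    if min_overhang > f:
        return False
    seq = probe.sequence
    n = len(read)
    for d in range(-(n - 1), 2 * f):  # probe index of read[0]
        ol_start = max(0, d)
        ol_end = min(2 * f, d + n)
        if ol_start >= ol_end:
            continue
        # overlap must fully contain the [f-oh, f+oh) core
        if ol_start > f - min_overhang or ol_end < f + min_overhang:
            continue
        window = seq[ol_start:ol_end]
        covered = read[ol_start - d : ol_end - d]
        if "N" in window or "N" in covered or window != covered:
            continue
        if require_discriminating and probe.discriminating_offsets:
            if not any(
                ol_start <= probe.index_of_offset(o) < ol_end
                for o in probe.discriminating_offsets
            ):
                continue
        return True
    return False


def brute_force_match(read, probe, min_overhang, require_discriminating):
    """All-placements junction-match oracle (both orientations)."""
    read = read.upper()
    return _match_one_orientation(
        read, probe, min_overhang, require_discriminating
    ) or _match_one_orientation(
        revcomp(read), probe, min_overhang, require_discriminating
    )


def wilcoxon_exact_two_sided(diffs) -> float:
    """Exact two-sided signed-rank p-value by full sign-assignment enumeration.

    Assumes no zero differences and no ties in |diffs|.
    """
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    n = len(d)
    total = n * (n + 1) // 2
    w_obs = int(ranks[d > 0].sum())
    m = min(w_obs, total - w_obs)
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = int(sum(r for r, s in zip(ranks, signs) if s))
        if min(w, total - w) <= m:
            hits += 1
    return hits / 2**n


def product_limit(times, events):
    """Hand Kaplan-Meier: (event_times, survival_after_each_time)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(times[events])):
        at_risk = np.sum(times >= t)
        deaths = np.sum((times == t) & events)
        s *= 1.0 - deaths / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def count_contexts_naive(window: str):
    """(tCw contexts, C sites) counted on both strands, character by character."""
    n_tcw = n_c = 0
    for strand in (window, revcomp(window)):
        for i, b in enumerate(strand):
            if b != "C":
                continue
            n_c += 1
            if 0 < i < len(strand) - 1 and strand[i - 1] == "T" and strand[i + 1] in "AT":
                n_tcw += 1
    return n_tcw, n_c


def spearman_rank_formula(x, y) -> float:
    """Spearman rho via Pearson correlation of midranks."""
    def midrank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    rx, ry = midrank(x), midrank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
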