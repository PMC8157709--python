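"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — plain dynamic programming without the
affine-gap optimization, quadratic substring scans, exhaustive window
enumeration — and shares no code path with the implementation it verifies.
"""

from __future__ import annotations

import math

import numpy as np

from suckerscreen.seqcore import (
    PairwiseAlignment,
    Scoring,
    global_align,
    reverse_complement,
)

NEG_INF = float("-inf")


def brute_force_global_score(a: str, b: str, scoring: Scoring) -> float:
    """Optimal global alignment score by whole-gap-jump DP (no affine states).

    A gap of length L costs ``gap_open + L * gap_extend``; every possible gap
    length is scanned explicitly at every cell, giving O(nm(n+m)) time.
    """
    n, m = len(a), len(b)

    def gap(length: int) -> float:
        return scoring.gap_open + length * scoring.gap_extend

    S = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    S[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best = NEG_INF
            if i > 0 and j > 0:
                sub = (
                    scoring.match
                    if (a[i - 1] == b[j - 1] and a[i - 1] != "N")
                    else scoring.mismatch
                )
                best = S[i - 1][j - 1] + sub
            for k in range(1, i + 1):
                cand = S[i - k][j] + gap(k)
                if cand > best:
                    best = cand
            for k in range(1, j + 1):
                cand = S[i][j - k] + gap(k)
                if cand > best:
                    best = cand
            S[i][j] = best
    return S[n][m]


def column_slice_identity(aln: PairwiseAlignment, c0: int, c1: int) -> float:
    """Identity of alignment columns [c0, c1) recomputed character by character."""
    matches = 0
    for x, y in zip(aln.aligned_a[c0:c1], aln.aligned_b[c0:c1]):
        if x == y and x != "-" and x != "N":
            matches += 1
    return 100.0 * matches / (c1 - c0)


def naive_window_identities(
    aln: PairwiseAlignment, window: int, step: int = 1
) -> list[tuple[int, float]]:
    """Sliding-window identity along sequence a, recomputed from scratch."""
    cols = [i for i, c in enumerate(aln.aligned_a) if c != "-"]
    out = []
    for s in range(0, len(cols) - window + 1, step):
        c0 = cols[s]
        c1 = cols[s + window - 1] + 1
        out.append((s, column_slice_identity(aln, c0, c1)))
    return out


def naive_slide_max_identity(window: str, paralog: str, both_strands: bool = True) -> float:
    """Best gapless identity of the window over every full-window offset/strand."""
    w = len(window)
    win = np.frombuffer(window.encode(), dtype=np.uint8)
    n_code = ord("N")
    best = 0
    variants = [paralog]
    if both_strands:
        variants.append(reverse_complement(paralog))
    for seq in variants:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(arr) >= w:
            for off in range(len(arr) - w + 1):
                seg = arr[off : off + w]
                best = max(best, int(((win == seg) & (win != n_code)).sum()))
        else:
            for d in range(-(w - 1), len(arr)):
                i0, i1 = max(0, -d), min(w, len(arr) - d)
                if i1 <= i0:
                    continue
                seg_w = win[i0:i1]
                seg_p = arr[i0 + d : i1 + d]
                best = max(best, int(((seg_w == seg_p) & (seg_w != n_code)).sum()))
    return 100.0 * best / w


def exhaustive_design(pair, paralogs, config) -> tuple[int, float, float]:
    """Exhaustive window search; returns (start, st_identity, max_paralog_identity).

    Enumerates every window start, recomputes the S/T identity by naive column
    slicing of the global alignment and the paralog identity by the naive
    slide, and keeps the best valid window (strict improvement only, so ties
    stay leftmost).  Raises LookupError when no window is valid.
    """
    source = pair.t_gene if config.source_subgenome.value == "T" else pair.s_gene
    other = pair.s_gene if source is pair.t_gene else pair.t_gene
    aln = global_align(source.sequence, other.sequence)
    cols = [i for i, c in enumerate(aln.aligned_a) if c != "-"]
    L = config.trigger_length_nt
    best = None
    for s in range(0, source.length_nt - L + 1, config.step_nt):
        c0 = cols[s]
        c1 = cols[s + L - 1] + 1
        st = column_slice_identity(aln, c0, c1)
        window = source.sequence[s : s + L]
        pmax = max(
            (
                naive_slide_max_identity(window, p.sequence, config.scan_both_strands)
                for p in paralogs
            ),
            default=0.0,
        )
        if st < config.min_st_identity_pct or (paralogs and pmax >= config.max_paralog_identity_pct):
            continue
        if best is None or st > best[1]:
            best = (s, st, pmax)
    if best is None:
        raise LookupError("no valid window")
    return best


def naive_offtarget_hits(trigger_seq: str, transcripts, k: int, exclude_ids=frozenset()):
    """All maximal shared runs >= k, by quadratic diagonal scanning on both strands.

    Returns a set of tuples
    ``(transcript_id, strand, trigger_start, trigger_end, transcript_start,
    transcript_end)`` with trigger coordinates on the sense orientation.
    """
    out = set()
    n = len(trigger_seq)
    for strand, query in (("sense", trigger_seq), ("antisense", reverse_complement(trigger_seq))):
        for t in transcripts:
            if t.id in exclude_ids:
                continue
            s = t.sequence
            m = len(s)
            for d in range(-(n - 1), m):
                i0 = max(0, -d)
                i1 = min(n, m - d)
                run = 0
                for i in range(i0, i1 + 1):
                    if i < i1 and query[i] == s[i + d] and query[i] != "N":
                        run += 1
                        continue
                    if run >= k:
                        qs, qe = i - run, i
                        ts, te = qs + d, qe + d
                        if strand == "sense":
                            trig = (qs, qe)
                        else:
                            trig = (n - qe, n - qs)
                        out.add((t.id, strand, trig[0], trig[1], ts, te))
                    run = 0
    return out


def textbook_two_sample_t(a, b, pooled: bool) -> tuple[float, float, float]:
    """Two-sample t statistic, df and two-sided p from the textbook formulas."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = (a.mean() - b.mean()) / se
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Exactly n substitutions at distinct positions, each to a different base."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)
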