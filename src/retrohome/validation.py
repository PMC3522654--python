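"""Brute-force reference implementations used to validate the fast paths.

Each function here recomputes, by plain exhaustive enumeration in pure
Python, a quantity that the package's production code computes with seeding
heuristics or jitted kernels.  They share the declared conventions (scoring,
tie-breaks, thresholds) but none of the code, so agreement on random
instances is evidence of correctness, not of shared bugs.  They are
quadratic or worse and meant for small instances only.
"""

from __future__ import annotations

from .align import LocalHit

_WOBBLE_OK_PAIRS = {
    ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"),
    ("G", "T"), ("T", "G"),  # G.U wobble on DNA
}


def smith_waterman_all(
    subject: str,
    query: str,
    *,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
    min_score: int = 20,
    min_identity: float = 0.60,
    min_length: int = 50,
) -> list[LocalHit]:
    """Iterated full-matrix Smith-Waterman with affine gaps.

    Same contract and tie-break convention as
    :func:`retrohome.align.local_alignments`: best score, ties to smallest
    subject end then query end; traceback prefers diagonal, then the
    subject-consuming gap, then the query-consuming gap; each reported
    alignment's subject footprint is masked before re-running.
    """
    sub = list(subject)
    hits = []
    while True:
        res = _sw_once(sub, query, match, mismatch, gap_open, gap_extend)
        if res is None or res[0] < min_score:
            break
        score, ss, se, qs, qe, ident, alen, gcols = res
        if (se - ss) >= min_length and ident / alen >= min_identity:
            hits.append(
                LocalHit(
                    subject_start=ss, subject_end=se,
                    query_start=qs, query_end=qe,
                    score=score, identical_sites=ident, aligned_length=alen,
                    gap_columns=gcols,
                )
            )
        for p in range(ss, se):
            sub[p] = "!"  # mask: matches nothing
    hits.sort(key=lambda h: (h.subject_start, h.subject_end))
    return hits


def _sw_once(sub, query, match, mismatch, gap_open, gap_extend):
    n, m = len(sub), len(query)
    NEG = -(10**9)

    def score(a: str, b: str) -> int:
        if a == "!" or b == "!":
            return -(10**6)
        if a == b and a in "ACGT":
            return match
        return mismatch

    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        Hi, Hi1 = H[i], H[i - 1]
        Ei = E[i]
        Fi, Fi1 = F[i], F[i - 1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] + gap_open, Ei[j - 1] + gap_extend)
            Ei[j] = e
            f = max(Hi1[j] + gap_open, Fi1[j] + gap_extend)
            Fi[j] = f
            h = max(0, Hi1[j - 1] + score(sub[i - 1], query[j - 1]), e, f)
            Hi[j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best == 0:
        return None
    i, j, ident, alen, gcols, state = bi, bj, 0, 0, 0, 0
    while True:
        if state == 0:
            if H[i][j] == 0:
                break
            if H[i][j] == H[i - 1][j - 1] + score(sub[i - 1], query[j - 1]):
                alen += 1
                if sub[i - 1] == query[j - 1] and sub[i - 1] in "ACGT":
                    ident += 1
                i -= 1
                j -= 1
            elif H[i][j] == F[i][j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            alen += 1
            gcols += 1
            if F[i][j] == H[i - 1][j] + gap_open:
                state = 0
            i -= 1
        else:
            alen += 1
            gcols += 1
            if E[i][j] == H[i][j - 1] + gap_open:
                state = 0
            j -= 1
    return best, i, bi, j, bj, ident, alen, gcols


def exhaustive_consensus_scan(sequence: str, consensus: str) -> list[int]:
    """Every forward-strand start where the consensus matches exactly.

    N in the consensus accepts any of ACGT but not a genomic N; fixed
    consensus positions require literal equality.
    """
    out = []
    L = len(consensus)
    for i in range(len(sequence) - L + 1):
        window = sequence[i : i + L]
        ok = True
        for c, g in zip(consensus, window):
            if c == "N":
                if g not in "ACGT":
                    ok = False
                    break
            elif c != g:
                ok = False
                break
        if ok:
            out.append(i)
    return out


def exhaustive_terminators(
    sequence: str,
    *,
    min_stem: int = 5,
    max_stem: int = 18,
    min_loop: int = 3,
    max_loop: int = 10,
    max_mismatch: int = 1,
    max_tail_gap: int = 3,
    tail_window: int = 8,
    min_tail_t: int = 5,
) -> list[tuple[int, int, int, int, int]]:
    """Every (start, stem, loop, mismatches, tail_t) forward-strand terminator.

    Tests every stem length, loop length and start position within bounds: a
    stem-loop whose arms pair by Watson-Crick or G.T wobble with at most
    ``max_mismatch`` unpaired rungs, followed within ``max_tail_gap`` nt by a
    ``tail_window``-base window containing >= ``min_tail_t`` T's.  Maximality
    (containment filtering) is NOT applied here; callers compare against the
    production detector's pre-filter hit set or apply the same filter.
    """
    out = []
    n = len(sequence)
    for start in range(n):
        for stem in range(min_stem, max_stem + 1):
            for loop in range(min_loop, max_loop + 1):
                end = start + 2 * stem + loop
                if end > n:
                    continue
                left = sequence[start : start + stem]
                right = sequence[start + stem + loop : end]
                mism = 0
                bad = False
                for i in range(stem):
                    a, b = left[i], right[stem - 1 - i]
                    if (a, b) not in _WOBBLE_OK_PAIRS:
                        mism += 1
                        if mism > max_mismatch:
                            bad = True
                            break
                if bad:
                    continue
                best_t = -1
                for gap in range(max_tail_gap + 1):
                    window = sequence[end + gap : end + gap + tail_window]
                    if len(window) < tail_window:
                        continue
                    t = window.count("T")
                    if t > best_t:
                        best_t = t
                if best_t >= min_tail_t:
                    out.append((start, stem, loop, mism, best_t))
    return out
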