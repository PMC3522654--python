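"""Seed-and-extend local alignment used by the detection and orthology stages.

The search contract is identity-over-length rather than e-value based: a hit
is any maximal local alignment with identity >= ``min_identity`` over at
least ``min_length`` aligned subject bases.  Candidate regions are located
with exact k-mer seeds, then resolved by an affine-gap Smith-Waterman
(Gotoh) pass restricted to the seeded window; non-overlapping secondary
hits are recovered by masking each reported alignment and re-running.

Tie-break convention (shared with the brute-force validator in
:mod:`retrohome.validation`): the reported alignment ends at the
highest-scoring DP cell, ties broken by the smallest subject end then the
smallest query end; traceback prefers diagonal over a subject-consuming gap
over a query-consuming gap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from numba import njit

from .genome_io import Interval, Replicon, Strand, Topology, revcomp

__all__ = [
    "SearchParams",
    "LocalHit",
    "encode_dna",
    "encode_protein",
    "nucleotide_score_matrix",
    "blosum62_matrix",
    "local_alignments",
    "search_replicon",
]

# DNA alphabet: A C G T N X(mask)
DNA_ALPHABET = "ACGTNX"
_DNA_INDEX = {c: i for i, c in enumerate(DNA_ALPHABET)}

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*?"  # trailing '?' is the mask
_PROT_INDEX = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}

MASK_DNA = _DNA_INDEX["X"]
MASK_PROT = _PROT_INDEX["?"]
_NEG = -(10**6)


@dataclass(frozen=True)
class SearchParams:
    """Tunables of the nucleotide seed-and-extend search."""

    k: int = 8
    min_identity: float = 0.60
    min_length: int = 50
    min_score: int = 20
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5      # cost of the first gap column
    gap_extend: int = -2
    window_margin: int = 100
    max_chunk: int = 8192   # DP window cap; bounds Smith-Waterman memory

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k-mer size must be >= 8")


@dataclass(frozen=True)
class LocalHit:
    """One local alignment of a query against a subject sequence."""

    subject_start: int
    subject_end: int
    query_start: int
    query_end: int
    score: int
    identical_sites: int
    aligned_length: int
    gap_columns: int = 0
    strand: Strand = Strand.FORWARD

    @property
    def similarity(self) -> float:
        """BLAST-style identity: identical columns / all aligned columns."""
        return self.identical_sites / self.aligned_length

    @property
    def gapless_identity(self) -> float:
        """Identity over substitution columns only (gap columns excluded)."""
        cols = self.aligned_length - self.gap_columns
        return self.identical_sites / cols if cols else 0.0


def encode_dna(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        out[i] = _DNA_INDEX.get(c, _DNA_INDEX["N"])
    return out


def encode_protein(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        out[i] = _PROT_INDEX.get(c, _PROT_INDEX["X"])
    return out


def nucleotide_score_matrix(match: int = 1, mismatch: int = -2) -> np.ndarray:
    m = np.full((6, 6), mismatch, dtype=np.int32)
    for i in range(4):
        m[i, i] = match
    m[4, :] = mismatch  # N matches nothing, including N
    m[:, 4] = mismatch
    m[5, :] = _NEG      # mask
    m[:, 5] = _NEG
    return m


def blosum62_matrix() -> np.ndarray:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n = len(PROTEIN_ALPHABET)
    m = np.full((n, n), -4, dtype=np.int32)
    for i, a in enumerate(PROTEIN_ALPHABET[:-1]):
        for j, b in enumerate(PROTEIN_ALPHABET[:-1]):
            try:
                m[i, j] = int(blosum[a, b])
            except (KeyError, IndexError):
                pass
    m[MASK_PROT, :] = _NEG
    m[:, MASK_PROT] = _NEG
    return m


@njit(cache=True)
def _sw_best(sub, qry, smat, gap_open, gap_extend):  # pragma: no cover - jitted
    """Score-only Smith-Waterman pass with rolling rows.

    Returns (best score, best subject end, best query end) under the same
    tie-break as the full pass: first maximum in (i, j) scan order.
    """
    n = len(sub)
    m = len(qry)
    NEG = np.int32(-(10**9) // 2)
    Hprev = np.zeros(m + 1, dtype=np.int32)
    Hcur = np.zeros(m + 1, dtype=np.int32)
    F = np.full(m + 1, NEG, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        e = NEG
        Hcur[0] = 0
        ci = sub[i - 1]
        for j in range(1, m + 1):
            eo = Hcur[j - 1] + gap_open
            if e + gap_extend > eo:
                e = e + gap_extend
            else:
                e = eo
            fo = Hprev[j] + gap_open
            if F[j] + gap_extend > fo:
                F[j] = F[j] + gap_extend
            else:
                F[j] = fo
            h = Hprev[j - 1] + smat[ci, qry[j - 1]]
            if e > h:
                h = e
            if F[j] > h:
                h = F[j]
            if h < 0:
                h = 0
            Hcur[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = Hprev
        Hprev = Hcur
        Hcur = tmp
    return best, bi, bj


@njit(cache=True)
def _sw_align(sub, qry, smat, gap_open, gap_extend, ident_limit):  # pragma: no cover - jitted
    """Optimal local alignment; returns (score, ss, se, qs, qe, ident, alen, gcols).

    Best cell = max score, ties to smallest subject end then query end.
    Traceback prefers diagonal, then subject-consuming gap, then
    query-consuming gap.  ``ident_limit`` is the largest alphabet code that
    counts as an identical site (letters above it, e.g. N or the mask, never
    do).
    """
    n = len(sub)
    m = len(qry)
    NEG = np.int32(-(10**9) // 2)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap consuming query
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap consuming subject
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open
            if E[i, j - 1] + gap_extend > e:
                e = E[i, j - 1] + gap_extend
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            if F[i - 1, j] + gap_extend > f:
                f = F[i - 1, j] + gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + smat[sub[i - 1], qry[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    j = bj
    ident = 0
    alen = 0
    gcols = 0
    state = 0  # 0=H, 1=F (subject gap col), 2=E (query gap col)
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            s = smat[sub[i - 1], qry[j - 1]]
            if H[i, j] == H[i - 1, j - 1] + s:
                alen += 1
                if sub[i - 1] == qry[j - 1] and sub[i - 1] <= ident_limit:
                    ident += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            alen += 1
            gcols += 1
            if F[i, j] == H[i - 1, j] + gap_open:
                state = 0
            i -= 1
        else:
            alen += 1
            gcols += 1
            if E[i, j] == H[i, j - 1] + gap_open:
                state = 0
            j -= 1
    return best, i, bi, j, bj, ident, alen, gcols


def local_alignments(
    subject: np.ndarray,
    query: np.ndarray,
    smat: np.ndarray,
    *,
    gap_open: int,
    gap_extend: int,
    min_score: int,
    min_identity: float,
    min_length: int,
    mask_code: int = MASK_DNA,
    ident_limit: int = 3,
) -> list[LocalHit]:
    """All maximal non-overlapping local alignments passing the contract.

    Iteratively takes the optimal alignment, masks its subject footprint and
    repeats until the best score drops below ``min_score``.  Only alignments
    with identity >= ``min_identity`` over >= ``min_length`` subject bases
    are reported (weaker alignments are still masked so they cannot shadow
    later ones).
    """
    sub = subject.copy()
    m = len(query)
    hits: list[LocalHit] = []
    while True:
        # cheap score-only pass; the full traceback matrix is only built on a
        # window guaranteed to contain the whole optimal alignment (positive-
        # scoring alignments span < 1.5 * query length of subject under these
        # penalties, and exact neighbourhood values need twice that).
        best, bi, bj = _sw_best(sub, query, smat, gap_open, gap_extend)
        if best < min_score:
            break
        lo = max(0, bi - 3 * m - 64)
        score, ss, se, qs, qe, ident, alen, gcols = _sw_align(
            sub[lo:bi], query, smat, gap_open, gap_extend, ident_limit
        )
        ss += lo
        se += lo
        if score < min_score or alen == 0:
            break
        if (se - ss) >= min_length and ident / alen >= min_identity:
            hits.append(
                LocalHit(
                    subject_start=ss,
                    subject_end=se,
                    query_start=qs,
                    query_end=qe,
                    score=score,
                    identical_sites=ident,
                    aligned_length=alen,
                    gap_columns=gcols,
                )
            )
        sub[ss:se] = mask_code
    hits.sort(key=lambda h: (h.subject_start, h.subject_end))
    return hits


@lru_cache(maxsize=16)
def _kmer_index(subject: str, k: int) -> dict[str, list[int]]:
    """Exact k-mer positions in a subject; cached so one replicon is indexed once."""
    index: dict[str, list[int]] = {}
    for i in range(len(subject) - k + 1):
        kmer = subject[i : i + k]
        if "N" not in kmer and "X" not in kmer:
            index.setdefault(kmer, []).append(i)
    return index


def _seed_windows(subject: str, query: str, k: int, margin: int) -> list[tuple[int, int]]:
    """Merged subject windows around exact k-mer matches with the query.

    Each seed at subject position ``p`` matching query position ``j``
    implies an alignment footprint of roughly ``[p - j, p + qlen - j)``;
    overlapping projections merge into one window.
    """
    if len(subject) < k or len(query) < k:
        return []
    index = _kmer_index(subject, k)
    qlen = len(query)
    n = len(subject)
    spans: list[tuple[int, int]] = []
    for j in range(qlen - k + 1):
        kmer = query[j : j + k]
        for pos in index.get(kmer, ()):
            spans.append(
                (max(0, pos - j - margin), min(n, pos + (qlen - j) + margin))
            )
    if not spans:
        return []
    spans.sort()
    merged: list[tuple[int, int]] = []
    for w in spans:
        if merged and w[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], w[1]))
        else:
            merged.append(w)
    return merged


def _chunk_windows(windows: list[tuple[int, int]], qlen: int, max_chunk: int) -> list[tuple[int, int]]:
    """Split oversized DP windows, overlapping chunks by 2*qlen."""
    overlap = 2 * qlen
    out: list[tuple[int, int]] = []
    for lo, hi in windows:
        if hi - lo <= max_chunk:
            out.append((lo, hi))
            continue
        pos = lo
        while pos < hi:
            out.append((pos, min(pos + max_chunk, hi)))
            if pos + max_chunk >= hi:
                break
            pos += max_chunk - overlap
    return out


def _dedupe_hits(hits: list[LocalHit]) -> list[LocalHit]:
    seen: set[tuple[int, int, int, int]] = set()
    out = []
    for h in sorted(hits, key=lambda h: (h.subject_start, h.subject_end, -h.score)):
        key = (h.subject_start, h.subject_end, h.query_start, h.query_end)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


def align_query(
    subject_seq: str,
    query_seq: str,
    params: SearchParams,
    *,
    seeded: bool = True,
) -> list[LocalHit]:
    """Forward-strand local hits of one nucleotide query in a subject string."""
    smat = nucleotide_score_matrix(params.match, params.mismatch)
    query = encode_dna(query_seq)
    if seeded:
        windows = _seed_windows(subject_seq, query_seq, params.k, params.window_margin)
    else:
        windows = [(0, len(subject_seq))] if subject_seq else []
    max_chunk = max(params.max_chunk, 4 * len(query_seq) + 2 * params.window_margin)
    windows = _chunk_windows(windows, len(query_seq), max_chunk)
    hits: list[LocalHit] = []
    for lo, hi in windows:
        sub = encode_dna(subject_seq[lo:hi])
        for h in local_alignments(
            sub,
            query,
            smat,
            gap_open=params.gap_open,
            gap_extend=params.gap_extend,
            min_score=params.min_score,
            min_identity=params.min_identity,
            min_length=params.min_length,
        ):
            hits.append(
                replace(h, subject_start=h.subject_start + lo, subject_end=h.subject_end + lo)
            )
    return _dedupe_hits(hits)


def align_protein_query(
    subject_aa: str,
    query_aa: str,
    *,
    min_identity: float = 0.60,
    min_length_aa: int = 17,
    min_score: int = 40,
    gap_open: int = -11,
    gap_extend: int = -1,
    seed_k: int = 4,
) -> list[LocalHit]:
    """Local hits of a reference IEP against one translated reading frame."""
    if len(subject_aa) < seed_k or len(query_aa) < seed_k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(subject_aa) - seed_k + 1):
        index.setdefault(subject_aa[i : i + seed_k], []).append(i)
    positions = sorted(
        pos
        for j in range(len(query_aa) - seed_k + 1)
        for pos in index.get(query_aa[j : j + seed_k], ())
    )
    if not positions:
        return []
    qlen = len(query_aa)
    windows: list[tuple[int, int]] = []
    lo = hi = positions[0]
    for pos in positions[1:]:
        if pos - hi <= qlen:
            hi = pos
        else:
            windows.append((max(0, lo - qlen - 30), min(len(subject_aa), hi + qlen + 30)))
            lo = hi = pos
    windows.append((max(0, lo - qlen - 30), min(len(subject_aa), hi + qlen + 30)))
    smat = blosum62_matrix()
    query = encode_protein(query_aa)
    hits: list[LocalHit] = []
    prev_end = -1
    for wlo, whi in windows:
        wlo = max(wlo, prev_end)
        prev_end = whi
        sub = encode_protein(subject_aa[wlo:whi])
        for h in local_alignments(
            sub,
            query,
            smat,
            gap_open=gap_open,
            gap_extend=gap_extend,
            min_score=min_score,
            min_identity=min_identity,
            min_length=min_length_aa,
            mask_code=MASK_PROT,
            ident_limit=_PROT_INDEX["V"],
        ):
            hits.append(
                replace(h, subject_start=h.subject_start + wlo, subject_end=h.subject_end + wlo)
            )
    return _dedupe_hits(hits)


def search_replicon(
    replicon: Replicon,
    query_seq: str,
    params: SearchParams,
    *,
    both_strands: bool = True,
) -> list[tuple[Interval, LocalHit]]:
    """Search one replicon on one or both strands; wraps circular origins.

    Returns (genomic interval, hit) pairs; hit coordinates on the reverse
    strand still refer to the forward subject sequence, with
    ``Interval.strand`` recording the orientation of the match.
    """
    seq = replicon.sequence
    n = len(seq)
    wrap = 0
    if replicon.topology is Topology.CIRCULAR and n > len(query_seq):
        wrap = len(query_seq) - 1
        seq = seq + seq[:wrap]
    out: list[tuple[Interval, LocalHit]] = []
    strands = [Strand.FORWARD, Strand.REVERSE] if both_strands else [Strand.FORWARD]
    for strand in strands:
        q = query_seq if strand is Strand.FORWARD else revcomp(query_seq)
        for h in align_query(seq, q, params):
            start, end = h.subject_start, h.subject_end
            if wrap and start >= n:
                continue  # duplicate of an unwrapped hit
            iv = Interval(replicon.id, start, end, strand)
            out.append((iv, replace(h, strand=strand)))
    # wrapped duplicates: drop hits whose normalized footprint equals another's
    seen: set[tuple[int, int, str]] = set()
    dedup: list[tuple[Interval, LocalHit]] = []
    for iv, h in out:
        key = (iv.start % n, iv.end - iv.start, iv.strand.value)
        if key not in seen:
            seen.add(key)
            dedup.append((iv, h))
    if wrap:
        # a fragment at the origin may re-surface inside a wrapped hit:
        # drop same-strand hits contained (mod n) in a longer hit
        def contained(a: Interval, b: Interval) -> bool:
            la, lb = a.end - a.start, b.end - b.start
            if la >= lb:
                return False
            for shift in (0, n):
                sa = a.start % n + shift
                if sa >= b.start and sa + la <= b.end:
                    return True
            return False

        dedup = [
            (iv, h)
            for iv, h in dedup
            if not any(
                o.strand == iv.strand and contained(iv, o)
                for o, _ in dedup
            )
        ]
    dedup.sort(key=lambda t: (t[0].start, t[0].end, t[0].strand.value))
    return dedup
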