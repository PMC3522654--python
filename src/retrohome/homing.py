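"""Homing-site inference: consensus building, terminator finding, scanning.

A group II intron recognises its integration target mostly through
base-pairing between its exon-binding sites (EBS1/2/3 on the intron RNA)
and the intron-binding sites (IBS) on the target, which span roughly
positions -12..+1 around the insertion point.  Four schemes reconstruct a
target model per intron:

* ``FLANK_SIMILARITY`` — for IS-targeting introns, the 90 bp around known
  insertion sites is itself the model and is re-found by local alignment.
* ``EBS_CONSENSUS`` — IBS positions are fixed from the EBS motifs under
  Watson-Crick pairing with G.U wobble; positions identical across every
  observed flank (and an optional reference flank) extend the consensus.
* ``CLASSC_TERMINATOR`` — class C introns pair only EBS1/EBS3 and insert
  immediately downstream of Rho-independent transcription terminators, so
  their IBS1/3 matches count only when gated by a terminator stem-loop.
* ``CONSERVATION_CONSENSUS`` — with unknown EBS motifs, columns conserved
  across the flanks of many full-length copies define the consensus.

Consensus models are scanned genome-wide (both strands, wrapping circular
origins) requiring a perfect match at every non-N position; ``N`` accepts
any real base but never a genomic ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .detection import IntronCopy
from .genome_io import Interval, Replicon, Strand, Topology, revcomp

__all__ = [
    "Scheme",
    "SiteState",
    "HomingSiteModel",
    "TerminatorHit",
    "TerminatorParams",
    "SiteOccurrence",
    "build_consensus_from_ebs",
    "build_consensus_from_conservation",
    "find_rho_independent_terminators",
    "scan_perfect_match",
    "scan_flank_similarity",
    "restrict_to_terminator_downstream",
    "mark_occupancy",
    "occupancy_counts",
]

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
# target bases an EBS base can pair with: Watson-Crick plus G.U wobble
_PAIRABLE = {
    "A": ("T",),
    "C": ("G",),
    "G": ("C", "T"),  # G.C canonical, G.U wobble (target T)
    "T": ("A", "G"),  # U.A canonical, U.G wobble (target G)
}


class Scheme(str, Enum):
    FLANK_SIMILARITY = "flank_similarity"
    EBS_CONSENSUS = "ebs_consensus"
    CLASSC_TERMINATOR = "classc_terminator"
    CONSERVATION_CONSENSUS = "conservation_consensus"


class SiteState(str, Enum):
    AVAILABLE = "available"
    OCCUPIED = "occupied"


@dataclass
class HomingSiteModel:
    intron_name: str
    scheme: Scheme
    consensus: str = ""
    insertion_offset: int = 24       # column immediately 5' of the insertion point
    window: tuple[int, int] = (-25, 10)
    requires_terminator: bool = False
    context_sequence: Optional[str] = None  # 90 bp, insertion after base 45

    def __post_init__(self) -> None:
        if self.scheme is Scheme.CLASSC_TERMINATOR:
            self.requires_terminator = True
        if self.consensus and not (0 <= self.insertion_offset < len(self.consensus)):
            raise ValueError("insertion_offset outside consensus")
        if self.context_sequence is not None and len(self.context_sequence) != 90:
            raise ValueError("context_sequence must be exactly 90 bp")

    @property
    def fixed_positions(self) -> int:
        return sum(1 for c in self.consensus if c != "N")


@dataclass(frozen=True)
class TerminatorHit:
    interval: Interval
    stem_length: int
    loop_length: int
    mismatches: int
    u_tail_score: float
    strand: Strand


@dataclass(frozen=True)
class TerminatorParams:
    """Stem-loop + U-tail definition of a Rho-independent terminator."""

    min_stem: int = 5
    max_stem: int = 18
    min_loop: int = 3
    max_loop: int = 10
    max_mismatch: int = 1   # non-WC, non-wobble rungs tolerated in the stem
    max_tail_gap: int = 3   # nt between stem 3' end and the U-rich window
    tail_window: int = 8
    min_tail_t: int = 5


@dataclass
class SiteOccurrence:
    model: HomingSiteModel
    interval: Interval
    strand: Strand
    state: SiteState = SiteState.AVAILABLE
    occupied_by: Optional[str] = None

    @property
    def insertion_point(self) -> int:
        """Forward-strand coordinate of the junction the intron inserts at."""
        if self.strand is Strand.FORWARD:
            return self.interval.start + self.model.insertion_offset + 1
        return self.interval.end - self.model.insertion_offset - 1


def _window_length(window: tuple[int, int]) -> int:
    left, right = window
    if left >= 0 or right <= 0:
        raise ValueError("window must straddle the insertion point, e.g. (-25, 10)")
    return right - left


def build_consensus_from_ebs(
    ebs_motifs: dict[str, str],
    flank_windows: Sequence[str],
    reference_flank: Optional[str] = None,
    window: tuple[int, int] = (-25, 10),
    scheme: Scheme = Scheme.EBS_CONSENSUS,
    intron_name: str = "",
) -> HomingSiteModel:
    """IBS consensus from EBS motifs plus observed insertion flanks.

    EBS-covered columns take the wobble-consistent majority base of the
    windows (falling back to the strict Watson-Crick complement when no
    window base can pair); with a ``reference_flank``, columns identical
    across all windows *and* the reference are fixed too; everything else
    is N.  IBS1 sits immediately 5' of the insertion point, IBS2 (absent in
    class C) immediately 5' of IBS1, and IBS3 is the first base 3' of the
    insertion point.
    """
    L = _window_length(window)
    if not flank_windows:
        raise ValueError("at least one flank window is required")
    for w in flank_windows:
        if len(w) != L:
            raise ValueError("windows of unequal length")
    if reference_flank is not None and len(reference_flank) != L:
        raise ValueError("windows of unequal length")
    pre = -window[0]  # columns 5' of the insertion point
    ebs_for_col: dict[int, str] = {}
    ebs1 = ebs_motifs.get("EBS1", "")
    for t in range(len(ebs1)):  # IBS1: last len(ebs1) columns before insertion
        col = pre - len(ebs1) + t
        if 0 <= col < pre:
            ebs_for_col[col] = ebs1[len(ebs1) - 1 - t]
    ebs2 = ebs_motifs.get("EBS2", "")
    for t in range(len(ebs2)):  # IBS2 immediately 5' of IBS1
        col = pre - len(ebs1) - len(ebs2) + t
        if 0 <= col < pre:
            ebs_for_col[col] = ebs2[len(ebs2) - 1 - t]
    ebs3 = ebs_motifs.get("EBS3", "")
    if ebs3:  # IBS3: first base 3' of the insertion point
        ebs_for_col[pre] = ebs3[-1]
    consensus = []
    for col in range(L):
        if col in ebs_for_col:
            allowed = _PAIRABLE.get(ebs_for_col[col], ())
            counts: dict[str, int] = {}
            for w in flank_windows:
                b = w[col]
                if b in allowed:
                    counts[b] = counts.get(b, 0) + 1
            if not counts:
                consensus.append(_WC.get(ebs_for_col[col], "N"))
            else:
                best = max(counts.values())
                winners = sorted(b for b, c in counts.items() if c == best)
                consensus.append(winners[0] if len(winners) == 1 else "N")
        else:
            bases = {w[col] for w in flank_windows}
            if (
                reference_flank is not None
                and len(bases) == 1
                and reference_flank[col] in bases
                and reference_flank[col] in "ACGT"
            ):
                consensus.append(reference_flank[col])
            else:
                consensus.append("N")
    return HomingSiteModel(
        intron_name=intron_name,
        scheme=scheme,
        consensus="".join(consensus),
        insertion_offset=pre - 1,
        window=window,
    )


def build_consensus_from_conservation(
    flank_windows: Sequence[str],
    window: tuple[int, int] = (-25, 10),
    threshold: float = 0.8,
    intron_name: str = "",
) -> HomingSiteModel:
    """Column-wise modal consensus over many observed flanks.

    A column is fixed to its modal base when that base's frequency reaches
    ``threshold`` (default 0.8); otherwise N.
    """
    if len(flank_windows) < 5:
        raise ValueError("conservation consensus needs at least 5 windows")
    L = _window_length(window)
    for w in flank_windows:
        if len(w) != L:
            raise ValueError("windows of unequal length")
    n = len(flank_windows)
    consensus = []
    for col in range(L):
        counts: dict[str, int] = {}
        for w in flank_windows:
            b = w[col]
            if b in "ACGT":
                counts[b] = counts.get(b, 0) + 1
        if counts:
            base, cnt = max(sorted(counts.items()), key=lambda kv: kv[1])
            consensus.append(base if cnt / n >= threshold else "N")
        else:
            consensus.append("N")
    return HomingSiteModel(
        intron_name=intron_name,
        scheme=Scheme.CONSERVATION_CONSENSUS,
        consensus="".join(consensus),
        insertion_offset=-window[0] - 1,
        window=window,
    )


def _pair_matrix() -> np.ndarray:
    ok = np.zeros((5, 5), dtype=bool)
    idx = {c: i for i, c in enumerate("ACGTN")}
    for a, partners in _PAIRABLE.items():
        for b in partners:
            ok[idx[a], idx[b]] = True
    return ok


_PAIR_OK = _pair_matrix()


def _encode5(seq: str) -> np.ndarray:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.fromiter((idx.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))


def _scan_terminators_forward(seq: str, p: TerminatorParams) -> list[tuple[int, int, int, int, int]]:
    """All (start, stem, loop, mismatches, best_tail_t) on the given strand."""
    n = len(seq)
    if n < 2 * p.min_stem + p.min_loop + p.tail_window:
        return []
    codes = _encode5(seq)
    is_t = codes == 3
    # rolling count of T in tail_window
    c = np.concatenate([[0], np.cumsum(is_t)])
    tcount = np.full(n, -1, dtype=np.int64)
    valid = n - p.tail_window + 1
    if valid > 0:
        tcount[:valid] = c[p.tail_window :] - c[:-p.tail_window]
    out: list[tuple[int, int, int, int, int]] = []
    for stem in range(p.min_stem, p.max_stem + 1):
        for loop in range(p.min_loop, p.max_loop + 1):
            span = 2 * stem + loop
            m = n - span - p.tail_window + 1  # need room for a tail window at gap 0
            if m <= 0:
                continue
            mism = np.zeros(m, dtype=np.int64)
            for t in range(stem):
                left = codes[t : t + m]
                right = codes[span - 1 - t : span - 1 - t + m]
                mism += ~_PAIR_OK[left, right]
            cand = np.nonzero(mism <= p.max_mismatch)[0]
            for start in cand:
                end = start + span
                best_t = -1
                for gap in range(p.max_tail_gap + 1):
                    if end + gap < valid and end + gap >= 0 and tcount[end + gap] >= 0:
                        if tcount[end + gap] > best_t:
                            best_t = int(tcount[end + gap])
                if best_t >= p.min_tail_t:
                    out.append((int(start), stem, loop, int(mism[start]), best_t))
    return out


def _maximal(hits: list[TerminatorHit]) -> list[TerminatorHit]:
    out = []
    for h in hits:
        contained = False
        for g in hits:
            if (
                g is not h
                and g.strand == h.strand
                and g.interval.start <= h.interval.start
                and h.interval.end <= g.interval.end
                and (g.interval.start < h.interval.start or h.interval.end < g.interval.end)
            ):
                contained = True
                break
        if not contained:
            out.append(h)
    return out


def find_rho_independent_terminators(
    replicon: Replicon,
    params: TerminatorParams | None = None,
    *,
    maximal: bool = True,
) -> list[TerminatorHit]:
    """Stem-loop + U-tail terminator detection on both strands.

    Reports every locus where an inverted repeat (stem within bounds, at
    most one non-paired rung, G.T wobble allowed) is followed within a few
    nt by a U-rich tract.  Circular replicons are scanned across the origin.
    With ``maximal`` (default) hits strictly contained in a same-strand hit
    are dropped.
    """
    params = params or TerminatorParams()
    seq = replicon.sequence
    n = len(seq)
    wrap = 0
    max_span = 2 * params.max_stem + params.max_loop + params.max_tail_gap + params.tail_window
    if replicon.topology is Topology.CIRCULAR and n > max_span:
        wrap = max_span - 1
        seq = seq + seq[:wrap]
    hits: list[TerminatorHit] = []
    for strand in (Strand.FORWARD, Strand.REVERSE):
        scan_seq = seq if strand is Strand.FORWARD else revcomp(seq)
        for start, stem, loop, mism, tail_t in _scan_terminators_forward(scan_seq, params):
            span = 2 * stem + loop
            if strand is Strand.FORWARD:
                lo, hi = start, start + span
            else:
                lo, hi = len(seq) - start - span, len(seq) - start
            if wrap and lo >= n:
                continue  # duplicate of an unwrapped position
            hits.append(
                TerminatorHit(
                    interval=Interval(replicon.id, lo, hi, strand),
                    stem_length=stem,
                    loop_length=loop,
                    mismatches=mism,
                    u_tail_score=tail_t / params.tail_window,
                    strand=strand,
                )
            )
    # drop duplicated wrapped hits (same locus found unwrapped and wrapped)
    seen: set[tuple] = set()
    dedup = []
    for h in sorted(
        hits,
        key=lambda h: (h.interval.start % n, h.stem_length, h.loop_length, h.strand.value),
    ):
        key = (h.interval.start % n, h.stem_length, h.loop_length, h.strand.value)
        if key not in seen:
            seen.add(key)
            dedup.append(h)
    if maximal:
        dedup = _maximal(dedup)
    dedup.sort(key=lambda h: (h.interval.start, h.interval.end, h.strand.value))
    return dedup


def scan_perfect_match(replicon: Replicon, model: HomingSiteModel) -> list[SiteOccurrence]:
    """Every perfect occurrence of the consensus, both strands, wrap-aware."""
    consensus = model.consensus
    if not consensus or all(c == "N" for c in consensus):
        raise ValueError("consensus must contain at least one fixed position")
    seq = replicon.sequence
    n = len(seq)
    L = len(consensus)
    wrap = L - 1 if (replicon.topology is Topology.CIRCULAR and n > L) else 0
    ext = seq + seq[:wrap]
    codes = _encode5(ext)
    out: list[SiteOccurrence] = []
    for strand in (Strand.FORWARD, Strand.REVERSE):
        pattern = consensus if strand is Strand.FORWARD else revcomp(consensus)
        m = len(ext) - L + 1
        if m <= 0:
            continue
        match = np.ones(m, dtype=bool)
        for j, c in enumerate(pattern):
            col = codes[j : j + m]
            if c == "N":
                match &= col != 4
            else:
                match &= col == "ACGT".index(c)
        for start in np.nonzero(match)[0]:
            start = int(start)
            if wrap and start >= n:
                continue
            out.append(
                SiteOccurrence(
                    model=model,
                    interval=Interval(replicon.id, start, start + L, strand),
                    strand=strand,
                )
            )
    out.sort(key=lambda s: (s.interval.start, s.strand.value))
    return out


def scan_flank_similarity(
    replicon: Replicon,
    model: HomingSiteModel,
    *,
    min_identity: float = 0.90,
    min_context_span: int = 72,
) -> list[SiteOccurrence]:
    """Find the 90 bp insertion context by local alignment.

    A hit counts as a putative homing site when it reaches ``min_identity``
    over at least ``min_context_span`` bases *and* covers the precise
    integration junction (after base 45 of the context).
    """
    from .align import SearchParams, search_replicon

    if model.context_sequence is None:
        raise ValueError("model has no context sequence")
    ctx = model.context_sequence
    params = SearchParams(
        min_identity=min_identity, min_length=min_context_span, min_score=30
    )
    out: list[SiteOccurrence] = []
    for iv, h in search_replicon(replicon, ctx, params):
        if h.strand is Strand.FORWARD:
            qs, qe = h.query_start, h.query_end
        else:
            qs, qe = len(ctx) - h.query_end, len(ctx) - h.query_start
        if not (qs < 45 < qe):  # must overlap the integration junction
            continue
        site_model = HomingSiteModel(
            intron_name=model.intron_name,
            scheme=model.scheme,
            consensus=model.consensus or ctx,
            insertion_offset=45 - qs - 1 if h.strand is Strand.FORWARD else 45 - qs - 1,
            window=model.window,
            context_sequence=ctx,
        )
        # interval covers the aligned footprint; junction derived from offset
        out.append(
            SiteOccurrence(
                model=site_model,
                interval=iv,
                strand=h.strand,
            )
        )
    out.sort(key=lambda s: (s.interval.start, s.strand.value))
    return out


def _ibs1_gap(site: SiteOccurrence, term: TerminatorHit) -> Optional[int]:
    """Strand-wise distance from the terminator stem 3' end to IBS1 start."""
    if site.strand != term.strand:
        return None
    fixed = [i for i, c in enumerate(site.model.consensus) if c != "N"]
    first_fixed = fixed[0] if fixed else 0
    if site.strand is Strand.FORWARD:
        return (site.interval.start + first_fixed) - term.interval.end
    return term.interval.start - (site.interval.end - first_fixed)


def restrict_to_terminator_downstream(
    sites: Sequence[SiteOccurrence],
    terminators: Sequence[TerminatorHit],
    max_gap: int = 20,
) -> list[SiteOccurrence]:
    """Keep class-C sites lying just 3' of a terminator stem-loop."""
    out = []
    for site in sites:
        for term in terminators:
            if site.interval.replicon_id != term.interval.replicon_id:
                continue
            gap = _ibs1_gap(site, term)
            if gap is not None and 0 <= gap <= max_gap:
                out.append(site)
                break
    return out


def mark_occupancy(
    sites: Sequence[SiteOccurrence],
    copies: Sequence[IntronCopy],
    *,
    model: HomingSiteModel | None = None,
    junction_tolerance: int = 3,
) -> list[SiteOccurrence]:
    """Resolve scanned candidate sites against detected intron copies.

    Each copy of the model's intron yields one OCCUPIED occurrence at its
    5' junction.  A scanned candidate whose insertion point abuts a copy
    junction merges into that occupied record; candidates falling strictly
    inside any intron copy are removed; the rest stay AVAILABLE.
    """
    out: list[SiteOccurrence] = []
    models = {s.model.intron_name: s.model for s in sites}
    if model is not None:
        models.setdefault(model.intron_name, model)
    for site in sites:
        model = site.model
        near_copy = None
        for copy in copies:
            if copy.interval.replicon_id != site.interval.replicon_id:
                continue
            if _is_model_intron(copy, model):
                junction = (
                    copy.interval.start
                    if copy.interval.strand is Strand.FORWARD
                    else copy.interval.end
                )
                if abs(site.insertion_point - junction) <= junction_tolerance:
                    near_copy = copy
                    break
        if near_copy is not None:
            continue  # superseded by the copy-derived occupied record below
        if any(
            c.interval.contains(site.interval)
            and not c.interval == site.interval
            for c in copies
        ):
            continue  # inside an intron copy: not an available site
        out.append(site)
    for copy in copies:
        model = next(
            (m for name, m in models.items() if _is_model_intron(copy, m)), None
        )
        if model is None:
            continue
        junction = (
            copy.interval.start
            if copy.interval.strand is Strand.FORWARD
            else copy.interval.end
        )
        lo = max(junction - 1, 0)
        out.append(
            SiteOccurrence(
                model=model,
                interval=Interval(copy.interval.replicon_id, lo, junction + 1),
                strand=copy.interval.strand,
                state=SiteState.OCCUPIED,
                occupied_by=copy.id,
            )
        )
    out.sort(key=lambda s: (s.interval.replicon_id, s.interval.start, s.state.value))
    return out


def _is_model_intron(copy: IntronCopy, model: HomingSiteModel) -> bool:
    return model.intron_name in (copy.reference_name, copy.assigned_name)


def occupancy_counts(occurrences: Sequence[SiteOccurrence]) -> tuple[int, int]:
    """(occupied, available) over a set of occurrences for one model/genome."""
    occupied = sum(1 for s in occurrences if s.state is SiteState.OCCUPIED)
    available = sum(1 for s in occurrences if s.state is SiteState.AVAILABLE)
    return occupied, available
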