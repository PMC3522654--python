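"""Insertion-pattern classification and collapsing of orthologous copies.

Intron copies in different strains that descend from one ancestral
insertion share the sequence flanking the insertion point.  For each
detected copy the 3 kbp of genomic sequence on each side is compared
against every other genome of the same genus/complex:

* both flanks aligning to *directly adjacent* positions in the subject
  (the site is empty there) means the copy arose by retrohoming in its own
  genome after the strains diverged;
* a flank aligning to the flank of a subject copy of the same intron, at
  the same insertion point, makes the two copies orthologous;
* copies carried by independently-integrated mobile elements can share
  flanks without sharing the ancestral insertion — an explicit override
  table reclassifies those pairs as distinct.

Orthology is closed transitively: connected components of the orthologous
relation become the "distinct" elements that abundance tables count once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .align import SearchParams, align_query
from .detection import IntronCopy
from .genome_io import Genome, Replicon, Strand, Topology

__all__ = [
    "FlankPair",
    "InsertionClass",
    "InsertionCall",
    "DistinctSet",
    "OrthologyParams",
    "extract_flanks",
    "classify_insertion",
    "apply_mge_overrides",
    "collapse_distinct",
    "orthology_calls",
]


@dataclass(frozen=True)
class OrthologyParams:
    flank_width: int = 3000
    min_flank_identity: float = 0.80
    min_flank_span: int = 500
    max_adjacency_gap: int = 20   # accommodates target-site duplications
    junction_slack: int = 20      # how far a flank hit may stop short of the junction
    seed_k: int = 16              # long seeds: flank matches are near-identical


class InsertionClass(str, Enum):
    RETROHOMED = "retrohomed"
    ORTHOLOGOUS = "orthologous"
    DISTINCT_MGE = "distinct_mge"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class FlankPair:
    copy_id: str
    upstream: str    # genomic forward strand, ends at copy start
    downstream: str  # genomic forward strand, begins at copy end


@dataclass
class InsertionCall:
    copy_id: str
    subject_genome: str
    classification: InsertionClass
    evidence: dict = field(default_factory=dict)


@dataclass
class DistinctSet:
    member_copy_ids: frozenset[str]
    representative: str
    genus_complex: str


def extract_flanks(copy: IntronCopy, replicon: Replicon, width: int = 3000) -> FlankPair:
    """The immediate flanking sequences of a copy, wrap-aware.

    Circular replicons wrap across the origin; linear replicons truncate at
    their ends, so flanks may be shorter than ``width``.
    """
    iv = copy.interval
    if replicon.topology is Topology.CIRCULAR:
        free = len(replicon.sequence) - len(iv)
        w = min(width, free // 2)
        upstream = replicon.fetch(iv.start - w, iv.start)
        downstream = replicon.fetch(iv.end, iv.end + w)
    else:
        upstream = replicon.fetch(max(0, iv.start - width), iv.start)
        downstream = replicon.fetch(iv.end, min(len(replicon.sequence), iv.end + width))
    return FlankPair(copy_id=copy.id, upstream=upstream, downstream=downstream)


def _flank_hits(flank: str, replicon: Replicon, params: OrthologyParams):
    """(interval, strand, query_start, query_end, identity) per flank hit.

    Query coordinates are in the flank's own forward orientation regardless
    of the matched strand.
    """
    if len(flank) < params.min_flank_span:
        return []
    search = SearchParams(
        k=params.seed_k,
        min_identity=params.min_flank_identity,
        min_length=params.min_flank_span,
        min_score=50,
    )
    from .align import search_replicon

    out = []
    qlen = len(flank)
    for iv, h in search_replicon(replicon, flank, search):
        if h.strand is Strand.REVERSE:
            qs, qe = qlen - h.query_end, qlen - h.query_start
        else:
            qs, qe = h.query_start, h.query_end
        out.append((iv, h.strand, qs, qe, h.similarity))
    return out


def classify_insertion(
    flanks: FlankPair,
    subject_genome: Genome,
    subject_copies: Sequence[IntronCopy],
    params: OrthologyParams | None = None,
    *,
    copy_intron: Optional[str] = None,
) -> InsertionCall:
    """Classify one (copy, subject genome) pair from its flank alignments.

    ORTHOLOGOUS when a flank aligns to a flank of a subject copy of the
    same intron at the same insertion point; RETROHOMED when both flanks
    align directly adjacent (the subject locus is intron-free); UNRESOLVED
    otherwise.
    """
    params = params or OrthologyParams()
    slack = params.junction_slack
    up_len = len(flanks.upstream)
    down_len = len(flanks.downstream)
    best_evidence: dict = {}
    for rep in subject_genome.replicons:
        up_hits = _flank_hits(flanks.upstream, rep, params)
        down_hits = _flank_hits(flanks.downstream, rep, params)
        same_intron = [
            c for c in subject_copies
            if c.interval.replicon_id == rep.id
            and copy_intron in (None, c.reference_name, c.assigned_name)
        ]
        gap_tol = params.max_adjacency_gap
        # orthologous: a flank abuts a subject copy's junction
        for sc in same_intron:
            for iv, strand, qs, qe, ident in up_hits:
                if qe < up_len - slack:  # must reach the flank's 3' end
                    continue
                junction = iv.end if strand is Strand.FORWARD else iv.start
                anchor = (
                    sc.interval.start if strand is Strand.FORWARD else sc.interval.end
                )
                if abs(junction - anchor) <= gap_tol:
                    return InsertionCall(
                        flanks.copy_id, subject_genome.strain, InsertionClass.ORTHOLOGOUS,
                        {"subject_copy_id": sc.id, "flank": "upstream",
                         "identity": round(ident, 4), "span": len(iv)},
                    )
            for iv, strand, qs, qe, ident in down_hits:
                if qs > slack:  # must reach the flank's 5' end
                    continue
                junction = iv.start if strand is Strand.FORWARD else iv.end
                anchor = (
                    sc.interval.end if strand is Strand.FORWARD else sc.interval.start
                )
                if abs(junction - anchor) <= gap_tol:
                    return InsertionCall(
                        flanks.copy_id, subject_genome.strain, InsertionClass.ORTHOLOGOUS,
                        {"subject_copy_id": sc.id, "flank": "downstream",
                         "identity": round(ident, 4), "span": len(iv)},
                    )
        # retrohomed: flanks directly adjacent in the subject, no copy between
        for uiv, ustrand, uqs, uqe, uident in up_hits:
            if uqe < up_len - slack:
                continue
            for div, dstrand, dqs, dqe, dident in down_hits:
                if dstrand != ustrand or dqs > slack:
                    continue
                if ustrand is Strand.FORWARD:
                    gap = div.start - uiv.end
                else:
                    gap = uiv.start - div.end
                if -gap_tol <= gap <= gap_tol:
                    if ustrand is Strand.FORWARD:
                        between_lo, between_hi = uiv.end, div.start
                    else:
                        between_lo, between_hi = div.end, uiv.start
                    if between_lo > between_hi:
                        between_lo, between_hi = between_hi, between_lo
                    blocked = any(
                        c.interval.replicon_id == rep.id
                        and c.interval.start < between_hi
                        and between_lo < c.interval.end
                        for c in subject_copies
                    )
                    if not blocked:
                        return InsertionCall(
                            flanks.copy_id, subject_genome.strain, InsertionClass.RETROHOMED,
                            {"adjacency_gap": gap,
                             "identity": round(min(uident, dident), 4)},
                        )
        if up_hits or down_hits:
            best_evidence = {"partial_hits": len(up_hits) + len(down_hits)}
    return InsertionCall(
        flanks.copy_id, subject_genome.strain, InsertionClass.UNRESOLVED, best_evidence
    )


def orthology_calls(
    copies: Sequence[IntronCopy],
    genomes: Sequence[Genome],
    params: OrthologyParams | None = None,
) -> list[InsertionCall]:
    """One call per (copy, other genome of the same genus/complex)."""
    params = params or OrthologyParams()
    by_strain = {g.strain: g for g in genomes}
    copies_by_genome: dict[str, list[IntronCopy]] = {}
    for c in copies:
        copies_by_genome.setdefault(c.genome, []).append(c)
    calls: list[InsertionCall] = []
    for copy in copies:
        genome = by_strain[copy.genome]
        rep = genome.replicon(copy.interval.replicon_id)
        flanks = extract_flanks(copy, rep, params.flank_width)
        for other in genomes:
            if other.strain == copy.genome:
                continue
            if other.genus_complex != genome.genus_complex:
                continue
            calls.append(
                classify_insertion(
                    flanks,
                    other,
                    copies_by_genome.get(other.strain, []),
                    params,
                    copy_intron=copy.reference_name,
                )
            )
    return calls


def apply_mge_overrides(
    calls: Sequence[InsertionCall],
    overrides: Sequence[tuple[str, str]],
) -> list[InsertionCall]:
    """Reclassify listed (copy_id, subject_genome) pairs as DISTINCT_MGE.

    Stands in for manual synteny inspection of large mobile elements: pairs
    whose shared flanks are internal to an independently-integrated island
    are declared distinct rather than orthologous.
    """
    index = {(c.copy_id, c.subject_genome): i for i, c in enumerate(calls)}
    out = [InsertionCall(c.copy_id, c.subject_genome, c.classification, dict(c.evidence)) for c in calls]
    for copy_id, subject in overrides:
        key = (copy_id, subject)
        if key not in index:
            raise KeyError(f"override references unknown call {key}")
        call = out[index[key]]
        call.evidence["override"] = call.classification.value
        call.classification = InsertionClass.DISTINCT_MGE
    return out


def collapse_distinct(
    copies: Sequence[IntronCopy],
    calls: Sequence[InsertionCall],
    genus_of: dict[str, str] | None = None,
) -> list[DistinctSet]:
    """Connected components of the orthologous relation.

    Copies never called orthologous form singleton sets; the per-genus
    number of distinct elements is the number of components.
    """
    genus_of = genus_of or {}
    parent: dict[str, str] = {c.id: c.id for c in copies}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra

    for call in calls:
        if call.classification is InsertionClass.ORTHOLOGOUS:
            other = call.evidence.get("subject_copy_id")
            if other and other in parent and call.copy_id in parent:
                union(call.copy_id, other)
    groups: dict[str, set[str]] = {}
    for c in copies:
        groups.setdefault(find(c.id), set()).add(c.id)
    genome_of = {c.id: c.genome for c in copies}
    sets = [
        DistinctSet(
            member_copy_ids=frozenset(members),
            representative=min(members),
            genus_complex=genus_of.get(genome_of[min(members)], genome_of[min(members)]),
        )
        for members in groups.values()
    ]
    sets.sort(key=lambda s: s.representative)
    return sets
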