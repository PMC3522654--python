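"""Group II intron detection against a reference intron library.

The search is a two-round procedure.  Round one screens every replicon with
the full nucleotide library and, through 6-frame translation, with the IEP
protein library.  Overlapping detections are resolved by keeping the hit
with the most identical sites (nucleotides or residues), then hits shorter
than 100 bp of genomic footprint, or below 75% similarity for nucleotide
hits, are discarded.  Round two re-screens the genomes using the round-one
copies themselves as queries, recovering more divergent relatives, and the
merged hit set passes through the same overlap and threshold filters.

Copies are called full-length when their alignments reach both reference
extremities (within a small slack) or when both boundaries are confirmed by
an intron-free homologous locus; divergent copies (>10% nucleotide
divergence from their reference) receive a new host-derived name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from .align import (
    LocalHit,
    SearchParams,
    align_protein_query,
    align_query,
    search_replicon,
)
from .genome_io import Genome, Interval, Replicon, RepliconKind, Strand, revcomp
from .library import ReferenceIntron

__all__ = [
    "Completeness",
    "Container",
    "RawHit",
    "IntronCopy",
    "DetectionParams",
    "seed_extend_search",
    "filter_overlapping_hits",
    "apply_detection_thresholds",
    "second_round_search",
    "classify_completeness",
    "assign_intron_name",
    "NameRegistry",
    "assess_orf",
    "detect_introns",
]

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


class Completeness(str, Enum):
    FULL_LENGTH = "full_length"
    FRAGMENT = "fragment"


class Container(str, Enum):
    CHROMOSOME = "chromosome"
    PLASMID = "plasmid"
    MGE_INTEGRATED = "mge_integrated"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class RawHit:
    """One local alignment of a library entry against a replicon.

    ``query_start``/``query_end`` are reference-intron nucleotide
    coordinates (protein hits are projected back through the reference ORF),
    used later for completeness calls.
    """

    reference_name: str
    interval: Interval
    identical_sites: int
    aligned_length: int
    score: int
    is_nucleotide: bool = True
    query_start: int = 0
    query_end: int = 0
    gap_columns: int = 0
    query_is_reference: bool = True  # False for round-2 hits (query = a copy)

    def __post_init__(self) -> None:
        if self.identical_sites > self.aligned_length:
            raise ValueError("identical_sites exceeds aligned_length")

    @property
    def similarity(self) -> float:
        return self.identical_sites / self.aligned_length

    @property
    def footprint(self) -> int:
        return len(self.interval)


@dataclass
class IntronCopy:
    id: str
    genome: str
    reference_name: str
    assigned_name: str
    interval: Interval
    completeness: Completeness
    percent_identity: float
    orf_intact: Optional[bool] = None
    container: Container = Container.UNKNOWN
    sequence: str = ""
    hits: list[RawHit] = field(default_factory=list, repr=False)

    @property
    def divergence(self) -> float:
        return 1.0 - self.percent_identity


@dataclass(frozen=True)
class DetectionParams:
    """Post-alignment filtering and classification thresholds."""

    min_footprint: int = 100          # discard detections shorter than this
    min_nt_similarity: float = 0.75   # nucleotide hits only
    locus_merge_gap: int = 200        # same-reference hits closer than this merge
    edge_slack: int = 15              # bp tolerance at reference extremities
    naming_divergence: float = 0.10   # above this, a new host-derived name
    orf_overlap_fraction: float = 0.90
    search: SearchParams = field(default_factory=SearchParams)


def _translate(seq: str) -> str:
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate()) if usable else ""


def seed_extend_search(
    replicon: Replicon,
    library: Sequence[ReferenceIntron],
    params: SearchParams | None = None,
    *,
    include_protein: bool = True,
) -> list[RawHit]:
    """Round-one search of one replicon against the whole library."""
    if not library:
        raise ValueError("reference library is empty")
    params = params or SearchParams()
    hits: list[RawHit] = []
    for ref in library:
        qlen = len(ref.sequence)
        for iv, h in search_replicon(replicon, ref.sequence, params):
            if h.strand is Strand.REVERSE:
                qs, qe = qlen - h.query_end, qlen - h.query_start
            else:
                qs, qe = h.query_start, h.query_end
            hits.append(
                RawHit(
                    reference_name=ref.name,
                    interval=iv,
                    identical_sites=h.identical_sites,
                    aligned_length=h.aligned_length,
                    score=h.score,
                    is_nucleotide=True,
                    query_start=qs,
                    query_end=qe,
                    gap_columns=h.gap_columns,
                )
            )
        if include_protein and ref.protein:
            hits.extend(_protein_search(replicon, ref, params))
    hits.sort(key=_hit_order)
    return hits


def _protein_search(replicon: Replicon, ref: ReferenceIntron, params: SearchParams) -> list[RawHit]:
    seq = replicon.sequence
    n = len(seq)
    query = ref.protein.rstrip("*")
    min_len_aa = max(17, params.min_length // 3)
    out: list[RawHit] = []
    for strand, template in ((Strand.FORWARD, seq), (Strand.REVERSE, revcomp(seq))):
        for frame in range(3):
            aa = _translate(template[frame:])
            for h in align_protein_query(
                aa, query, min_identity=params.min_identity, min_length_aa=min_len_aa
            ):
                lo = frame + 3 * h.subject_start
                hi = frame + 3 * h.subject_end
                if strand is Strand.REVERSE:
                    lo, hi = n - hi, n - lo
                orf0 = ref.orf_interval[0]
                out.append(
                    RawHit(
                        reference_name=ref.name,
                        interval=Interval(replicon.id, lo, hi, strand),
                        identical_sites=h.identical_sites,
                        aligned_length=h.aligned_length,
                        score=h.score,
                        is_nucleotide=False,
                        query_start=orf0 + 3 * h.query_start,
                        query_end=orf0 + 3 * h.query_end,
                        gap_columns=h.gap_columns,
                    )
                )
    return out


def _hit_order(h: RawHit):
    return (h.interval.replicon_id, h.interval.start, h.interval.end, h.reference_name)


def filter_overlapping_hits(hits: Sequence[RawHit]) -> list[RawHit]:
    """Resolve overlapping detections, keeping the most identical sites.

    Single-linkage clusters on >=1 bp genomic overlap (strand-agnostic);
    within each cluster the best hit (most identical sites, ties to higher
    similarity then leftmost start) is kept, hits overlapping it are
    removed, and the rule recurses on what remains.
    """
    by_replicon: dict[str, list[RawHit]] = {}
    for h in hits:
        by_replicon.setdefault(h.interval.replicon_id, []).append(h)
    kept: list[RawHit] = []
    for group in by_replicon.values():
        group = sorted(group, key=lambda h: (h.interval.start, h.interval.end))
        cluster: list[RawHit] = []
        hi = -1
        for h in group:
            if cluster and h.interval.start >= hi:
                kept.extend(_resolve_cluster(cluster))
                cluster = []
                hi = -1
            cluster.append(h)
            hi = max(hi, h.interval.end)
        if cluster:
            kept.extend(_resolve_cluster(cluster))
    kept.sort(key=_hit_order)
    return kept


def _resolve_cluster(cluster: list[RawHit]) -> list[RawHit]:
    if not cluster:
        return []
    best = min(
        cluster,
        key=lambda h: (-h.identical_sites, -h.similarity, h.interval.start, h.interval.end),
    )
    rest = [
        h for h in cluster
        if h is not best and not h.interval.overlaps(best.interval)
    ]
    return [best] + filter_overlapping_hits(rest)


def apply_detection_thresholds(
    hits: Sequence[RawHit],
    *,
    min_footprint: int = 100,
    min_nt_similarity: float = 0.75,
) -> list[RawHit]:
    """Drop short detections and dissimilar nucleotide detections.

    Both rules are strict ("shorter than" / "less than"): a 100 bp hit and
    a 75%-similar hit survive.  Protein hits are exempt from the similarity
    rule.
    """
    out = []
    for h in hits:
        if h.footprint < min_footprint:
            continue
        if h.is_nucleotide and h.similarity < min_nt_similarity:
            continue
        out.append(h)
    return out


def second_round_search(
    replicons: Sequence[Replicon],
    detected_copies: Sequence[IntronCopy],
    params: SearchParams | None = None,
    *,
    mask_known: bool = True,
) -> list[RawHit]:
    """Re-screen replicons using round-one copies as queries.

    Returned hits carry the *original* reference name of the source copy;
    their query coordinates are projected onto the reference through the
    copy's own alignment footprint.  Hits fully contained in an
    already-detected copy are dropped; with ``mask_known`` (default) the
    detected footprints are N-masked up front, which skips re-aligning
    every query to every known locus.
    """
    if not detected_copies:
        return []
    params = params or SearchParams()
    existing = [c.interval for c in detected_copies]
    targets = list(replicons)
    if mask_known:
        masked = []
        for rep in replicons:
            seq = rep.sequence
            for iv in existing:
                if iv.replicon_id == rep.id:
                    seq = seq[: iv.start] + "N" * len(iv) + seq[iv.end :]
            masked.append(
                Replicon(
                    id=rep.id, genome_id=rep.genome_id, kind=rep.kind,
                    topology=rep.topology, sequence=seq,
                )
            )
        targets = masked
    out: list[RawHit] = []
    seen_queries: set[tuple[str, str]] = set()
    for copy in detected_copies:
        if not copy.sequence:
            continue
        qkey = (copy.reference_name, copy.sequence)
        if qkey in seen_queries:  # identical copies query identically
            continue
        seen_queries.add(qkey)
        ref_offset = min((h.query_start for h in copy.hits), default=0)
        qlen = len(copy.sequence)
        for rep in targets:
            for iv, h in search_replicon(rep, copy.sequence, params):
                if any(e.contains(iv) for e in existing):
                    continue
                if h.strand is Strand.REVERSE:
                    qs, qe = qlen - h.query_end, qlen - h.query_start
                else:
                    qs, qe = h.query_start, h.query_end
                out.append(
                    RawHit(
                        reference_name=copy.reference_name,
                        interval=iv,
                        identical_sites=h.identical_sites,
                        aligned_length=h.aligned_length,
                        score=h.score,
                        is_nucleotide=True,
                        query_start=ref_offset + qs,
                        query_end=ref_offset + qe,
                        gap_columns=h.gap_columns,
                        query_is_reference=False,
                    )
                )
    out.sort(key=_hit_order)
    return out


def classify_completeness(
    hit_cluster: Sequence[RawHit],
    reference: ReferenceIntron,
    *,
    edge_slack: int = 15,
    flanks: tuple[str, str] | None = None,
    context_sequences: Sequence[str] | None = None,
    flank_probe: int = 40,
) -> Completeness:
    """FULL_LENGTH when both reference extremities are resolved.

    Primary evidence: the merged alignment footprint reaches within
    ``edge_slack`` bp of both reference ends.  Fallback evidence: the copy's
    immediate flanks align contiguously across the insertion point of an
    intron-free homologous locus (or of another copy of the same intron),
    which pins both boundaries even when the alignment itself is ragged.
    """
    if not hit_cluster:
        return Completeness.FRAGMENT
    names = {h.reference_name for h in hit_cluster}
    if len(names) != 1:
        raise ValueError("hit cluster spans multiple references")
    cov_lo = min(h.query_start for h in hit_cluster)
    cov_hi = max(h.query_end for h in hit_cluster)
    if cov_lo <= edge_slack and cov_hi >= len(reference.sequence) - edge_slack:
        return Completeness.FULL_LENGTH
    if flanks and context_sequences:
        up, down = flanks
        up_probe = up[-flank_probe:]
        down_probe = down[:flank_probe]
        if len(up_probe) >= 20 and len(down_probe) >= 20:
            probe_params = SearchParams(
                min_identity=0.85, min_length=min(len(up_probe), len(down_probe)) - 5,
                min_score=10,
            )
            for ctx in context_sequences:
                ups = align_query(ctx, up_probe, probe_params)
                downs = align_query(ctx, down_probe, probe_params)
                for u in ups:
                    for d in downs:
                        gap = d.subject_start - u.subject_end
                        if 0 <= gap <= edge_slack:
                            return Completeness.FULL_LENGTH
    return Completeness.FRAGMENT


class NameRegistry:
    """Deterministic, idempotent naming of divergent copies per genome."""

    def __init__(self) -> None:
        self._counters: dict[str, int] = {}
        self._assigned: dict[str, str] = {}

    def new_name(self, copy_id: str, genome: str) -> str:
        if copy_id in self._assigned:
            return self._assigned[copy_id]
        self._counters[genome] = self._counters.get(genome, 0) + 1
        name = f"{genome}.I{self._counters[genome]}"
        self._assigned[copy_id] = name
        return name


def assign_intron_name(
    copy: IntronCopy,
    reference: ReferenceIntron,
    registry: NameRegistry,
    *,
    naming_divergence: float = 0.10,
) -> str:
    """Reference name unless nucleotide divergence strictly exceeds 10%."""
    if copy.divergence > naming_divergence:
        return registry.new_name(copy.id, copy.genome)
    return reference.name


def _find_orfs(seq: str) -> list[tuple[int, int]]:
    """All maximal (start codon .. stop) ORFs in the three forward frames."""
    orfs = []
    n = len(seq)
    for frame in range(3):
        pos = frame
        open_start: int | None = None
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if open_start is None and codon in START_CODONS:
                open_start = pos
            elif open_start is not None and codon in STOP_CODONS:
                orfs.append((open_start, pos + 3))
                open_start = None
            pos += 3
        if open_start is not None:
            orfs.append((open_start, n - (n - frame) % 3))
    return orfs


def assess_orf(
    copy: IntronCopy,
    reference: ReferenceIntron,
    *,
    overlap_fraction: float = 0.90,
) -> bool:
    """True when the copy retains an uninterrupted IEP reading frame.

    The ORF must overlap at least 90% of the reference ORF's projection onto
    the copy and reach at least 90% of the reference ORF length; a
    frameshift or premature stop inside the ORF fails both conditions.
    """
    if copy.completeness is not Completeness.FULL_LENGTH:
        raise ValueError("ORF status is only assessed on full-length copies")
    seq = copy.sequence
    ref_orf_len = reference.orf_length
    cov_lo = min((h.query_start for h in copy.hits), default=0)
    proj_lo = max(0, reference.orf_interval[0] - cov_lo)
    proj_hi = min(len(seq), reference.orf_interval[1] - cov_lo)
    if proj_hi <= proj_lo:
        return False
    need = overlap_fraction * ref_orf_len
    for start, end in _find_orfs(seq):
        overlap = min(end, proj_hi) - max(start, proj_lo)
        if overlap >= need and (end - start) >= overlap_fraction * ref_orf_len:
            return True
    return False


def _container_for(rep: Replicon) -> Container:
    return (
        Container.CHROMOSOME
        if rep.kind is RepliconKind.CHROMOSOME
        else Container.PLASMID
    )


def _merge_loci(hits: list[RawHit], merge_gap: int) -> list[list[RawHit]]:
    """Group non-overlapping retained hits into per-copy clusters."""
    clusters: list[list[RawHit]] = []
    for h in sorted(hits, key=_hit_order):
        placed = False
        if clusters:
            last = clusters[-1]
            same = (
                last[0].reference_name == h.reference_name
                and last[0].interval.replicon_id == h.interval.replicon_id
                and last[0].interval.strand == h.interval.strand
            )
            if same and h.interval.start - max(x.interval.end for x in last) <= merge_gap:
                last.append(h)
                placed = True
        if not placed:
            clusters.append([h])
    return clusters


def _extract(rep: Replicon, lo: int, hi: int, strand: Strand) -> str:
    seq = rep.fetch(lo, hi)
    return seq if strand is Strand.FORWARD else revcomp(seq)


def _identity_to_reference(copy_seq: str, ref: ReferenceIntron, params: SearchParams) -> float:
    """Gap-excluded identity of a copy against its reference intron."""
    relaxed = replace(params, min_identity=0.5, min_length=30, min_score=15)
    hits = align_query(copy_seq, ref.sequence, relaxed)
    ident = sum(h.identical_sites for h in hits)
    cols = sum(h.aligned_length - h.gap_columns for h in hits)
    return ident / cols if cols else 0.0


def detect_introns(
    genomes: Sequence[Genome],
    library: Sequence[ReferenceIntron],
    params: DetectionParams | None = None,
) -> list[IntronCopy]:
    """Full two-round detection over a set of genomes."""
    params = params or DetectionParams()
    refs = {r.name: r for r in library}
    registry = NameRegistry()
    copies: list[IntronCopy] = []
    for genome in genomes:
        round1: list[RawHit] = []
        for rep in genome.replicons:
            round1.extend(seed_extend_search(rep, library, params.search))
        retained = apply_detection_thresholds(
            filter_overlapping_hits(round1),
            min_footprint=params.min_footprint,
            min_nt_similarity=params.min_nt_similarity,
        )
        genome_copies = _build_copies(genome, retained, refs, params, registry)
        round2 = second_round_search(genome.replicons, genome_copies, params.search)
        if round2:
            merged = apply_detection_thresholds(
                filter_overlapping_hits(list(retained) + round2),
                min_footprint=params.min_footprint,
                min_nt_similarity=params.min_nt_similarity,
            )
            covered = [c.interval for c in genome_copies]
            extra = [
                h for h in merged
                if not any(c.contains(h.interval) or c.overlaps(h.interval) for c in covered)
            ]
            genome_copies.extend(_build_copies(genome, extra, refs, params, registry))
        copies.extend(genome_copies)
    copies.sort(key=lambda c: (c.genome, c.interval.replicon_id, c.interval.start))
    return copies


def _build_copies(
    genome: Genome,
    retained: list[RawHit],
    refs: dict[str, ReferenceIntron],
    params: DetectionParams,
    registry: NameRegistry,
) -> list[IntronCopy]:
    out: list[IntronCopy] = []
    for cluster in _merge_loci(retained, params.locus_merge_gap):
        ref = refs[cluster[0].reference_name]
        rep = genome.replicon(cluster[0].interval.replicon_id)
        lo = min(h.interval.start for h in cluster)
        hi = max(h.interval.end for h in cluster)
        strand = cluster[0].interval.strand
        seq = _extract(rep, lo, hi, strand)
        nt_hits = [h for h in cluster if h.is_nucleotide and h.query_is_reference]
        if nt_hits:
            ident = sum(h.identical_sites for h in nt_hits)
            cols = sum(h.aligned_length - h.gap_columns for h in nt_hits)
            pid = ident / cols if cols else 0.0
        else:
            # round-2 or protein-only evidence: realign against the reference
            pid = _identity_to_reference(seq, ref, params.search)
        copy = IntronCopy(
            id=f"{genome.strain}:{rep.id}:{lo}-{hi}{strand.value}",
            genome=genome.strain,
            reference_name=ref.name,
            assigned_name="",
            interval=Interval(rep.id, lo, hi, strand),
            completeness=classify_completeness(
                cluster, ref, edge_slack=params.edge_slack
            ),
            percent_identity=pid,
            container=_container_for(rep),
            sequence=seq,
            hits=list(cluster),
        )
        copy.assigned_name = assign_intron_name(
            copy, ref, registry, naming_divergence=params.naming_divergence
        )
        if copy.completeness is Completeness.FULL_LENGTH:
            copy.orf_intact = assess_orf(
                copy, ref, overlap_fraction=params.orf_overlap_fraction
            )
        out.append(copy)
    return out
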