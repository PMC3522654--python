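"""Detection filters, thresholds, naming, completeness and ORF assessment."""

import numpy as np
import pytest

from retrohome.align import SearchParams
from retrohome.detection import (
    Completeness,
    Container,
    DetectionParams,
    IntronCopy,
    NameRegistry,
    RawHit,
    apply_detection_thresholds,
    assess_orf,
    assign_intron_name,
    classify_completeness,
    detect_introns,
    filter_overlapping_hits,
    second_round_search,
)
from retrohome.genome_io import Genome, Interval, Replicon, RepliconKind, Topology
from retrohome.library import OrfClass, ReferenceIntron, RibozymeGroup
from retrohome.simulate import SyntheticIntronSpec, generate_reference_intron, mutate_sequence

from conftest import random_dna


def hit(start, end, ident, alen=None, rid="chr", nucleotide=True, qs=0, qe=None):
    alen = alen if alen is not None else end - start
    return RawHit(
        reference_name="I1",
        interval=Interval(rid, start, end),
        identical_sites=ident,
        aligned_length=alen,
        score=ident,
        is_nucleotide=nucleotide,
        query_start=qs,
        query_end=qe if qe is not None else (end - start),
    )


def make_genome(seq, strain="s1", kind=RepliconKind.CHROMOSOME):
    rep = Replicon(
        id=f"{strain}_chr", genome_id=strain, kind=kind,
        topology=Topology.LINEAR, sequence=seq,
    )
    return Genome(strain=strain, genus_complex="GenusA", replicons=[rep])


def greedy_overlap_oracle(hits):
    """Independent restatement of the overlap rule: repeatedly keep the hit
    with most identical sites (ties: higher similarity, leftmost), drop
    everything overlapping it."""
    remaining = list(hits)
    kept = []
    while remaining:
        best = min(
            remaining,
            key=lambda h: (-h.identical_sites, -h.similarity, h.interval.start,
                           h.interval.end),
        )
        kept.append(best)
        remaining = [
            h for h in remaining
            if h is not best and not h.interval.overlaps(best.interval)
        ]
    return sorted(kept, key=lambda h: (h.interval.start, h.interval.end))


class TestOverlapFilter:
    def test_better_hit_wins_overlap(self):
        a = hit(100, 400, 250)
        b = hit(300, 600, 180)
        assert filter_overlapping_hits([a, b]) == [a]

    def test_disjoint_hits_both_kept(self):
        a, b = hit(0, 100, 90), hit(200, 300, 80)
        assert filter_overlapping_hits([a, b]) == [a, b]

    def test_tie_keeps_leftmost(self):
        a = hit(100, 200, 80, alen=100)
        b = hit(150, 250, 80, alen=100)
        assert filter_overlapping_hits([a, b]) == [a]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_greedy_oracle_on_random_clusters(self, seed):
        rng = np.random.default_rng(seed)
        hits = []
        for _ in range(6):
            start = int(rng.integers(0, 500))
            length = int(rng.integers(60, 300))
            ident = int(rng.integers(30, length))
            hits.append(hit(start, start + length, ident, alen=length))
        got = filter_overlapping_hits(hits)
        assert got == greedy_overlap_oracle(hits)
        # output is pairwise non-overlapping and a subset of the input
        for i, a in enumerate(got):
            assert a in hits
            for b in got[i + 1:]:
                assert not a.interval.overlaps(b.interval)


class TestThresholds:
    def test_short_hit_discarded_despite_high_identity(self):
        assert apply_detection_thresholds([hit(0, 99, 98)]) == []

    def test_dissimilar_nucleotide_discarded_but_protein_kept(self):
        nt = hit(0, 150, 111)       # similarity 0.74
        prot = hit(0, 150, 37, alen=50, nucleotide=False)
        assert apply_detection_thresholds([nt]) == []
        assert apply_detection_thresholds([prot]) == [prot]

    def test_exact_boundary_retained(self):
        h = hit(0, 100, 75, alen=100)  # 100 bp and 75% exactly
        assert apply_detection_thresholds([h]) == [h]


@pytest.fixture(scope="module")
def reference():
    return generate_reference_intron(SyntheticIntronSpec(name="I1"), seed=123)


class TestNaming:
    def _copy(self, identity):
        return IntronCopy(
            id="s1:chr:0-600+", genome="s1", reference_name="I1", assigned_name="",
            interval=Interval("chr", 0, 600),
            completeness=Completeness.FULL_LENGTH, percent_identity=identity,
        )

    @pytest.mark.parametrize(
        "identity,expect_reference",
        [(1.0, True), (0.90, True), (0.89, False)],
    )
    def test_ten_percent_divergence_rule_is_strict(self, reference, identity, expect_reference):
        registry = NameRegistry()
        name = assign_intron_name(self._copy(identity), reference, registry)
        if expect_reference:
            assert name == "I1"
        else:
            assert name != "I1" and name.startswith("s1.")

    def test_new_names_are_deterministic_and_idempotent(self, reference):
        registry = NameRegistry()
        copy = self._copy(0.80)
        first = assign_intron_name(copy, reference, registry)
        again = assign_intron_name(copy, reference, registry)
        assert first == again
        other = self._copy(0.70)
        other.id = "s1:chr:900-1500+"
        assert assign_intron_name(other, reference, registry) != first


class TestCompleteness:
    def test_near_complete_coverage_is_full_length(self, reference):
        n = len(reference.sequence)
        h = hit(1000, 1000 + n - 5, n - 5, qs=3, qe=n - 2)
        assert classify_completeness([h], reference) is Completeness.FULL_LENGTH

    def test_internal_fragment_without_evidence(self, reference):
        h = hit(1000, 1250, 250, qs=200, qe=450)
        assert classify_completeness([h], reference) is Completeness.FRAGMENT

    def test_flank_evidence_resolves_boundaries(self, reference):
        rng = np.random.default_rng(9)
        up = random_dna(rng, 200)
        down = random_dna(rng, 200)
        intron_free_locus = up + down  # insertion site with no intron
        h = hit(1000, 1250, 250, qs=200, qe=450)
        got = classify_completeness(
            [h], reference, flanks=(up, down), context_sequences=[intron_free_locus]
        )
        assert got is Completeness.FULL_LENGTH


class TestOrfAssessment:
    def _planted_copy(self, reference, seq):
        copy = IntronCopy(
            id="c", genome="s1", reference_name="I1", assigned_name="I1",
            interval=Interval("chr", 0, len(seq)),
            completeness=Completeness.FULL_LENGTH, percent_identity=1.0,
            sequence=seq,
            hits=[hit(0, len(seq), len(seq), qs=0, qe=len(reference.sequence))],
        )
        return copy

    def test_exact_copy_has_intact_orf(self, reference):
        assert assess_orf(self._planted_copy(reference, reference.sequence), reference)

    def test_single_base_deletion_breaks_frame(self, reference):
        lo, hi = reference.orf_interval
        mid = (lo + hi) // 2
        seq = reference.sequence[:mid] + reference.sequence[mid + 1:]
        assert not assess_orf(self._planted_copy(reference, seq), reference)

    def test_premature_stop_fails(self, reference):
        lo, hi = reference.orf_interval
        mid = lo + 3 * (((hi - lo) // 2) // 3)
        seq = reference.sequence[:mid] + "TAA" + reference.sequence[mid + 3:]
        assert not assess_orf(self._planted_copy(reference, seq), reference)

    def test_fragment_rejected(self, reference):
        copy = self._planted_copy(reference, reference.sequence)
        copy.completeness = Completeness.FRAGMENT
        with pytest.raises(ValueError):
            assess_orf(copy, reference)


class TestSecondRound:
    def test_no_copies_returns_empty(self, reference):
        assert second_round_search([], []) == []

    def test_divergent_relative_found_only_via_round_one_copy(self, reference):
        # near: 20% from the reference (round-1 detectable at >=75% similarity);
        # far: 8% further, ~27% from the reference, below the round-1 cut but
        # within easy reach of the round-1 copy used as the round-2 query.
        rng = np.random.default_rng(21)
        near = mutate_sequence(reference.sequence, 0.20, rng)
        far = mutate_sequence(near, 0.08, rng)
        bg = random_dna(rng, 30_000)
        seq = bg[:5000] + near + bg[5000:20000] + far + bg[20000:]
        genome = make_genome(seq)
        from retrohome.detection import seed_extend_search
        round1 = apply_detection_thresholds(
            filter_overlapping_hits(
                seed_extend_search(genome.replicons[0], [reference])
            )
        )
        copies = detect_introns([genome], [reference])
        # the far copy spans [20000+len(near), ...); round 1 alone misses it
        far_start = 5000 + len(near) + 15_000
        assert not any(abs(h.interval.start - far_start) < 1000 for h in round1)
        assert len(copies) == 2
        starts = sorted(c.interval.start for c in copies)
        assert abs(starts[0] - 5000) <= 50 and abs(starts[1] - far_start) <= 50
        # both are divergent from the reference, so both get new names
        for c in copies:
            assert c.percent_identity < 0.90
            assert c.assigned_name.startswith("s1.")


class TestEndToEndDetection:
    def test_recall_on_divergent_planted_copies(self, reference):
        rng = np.random.default_rng(33)
        bg = random_dna(rng, 60_000)
        planted = []
        pos = 5000
        for div in (0.0, 0.05, 0.10, 0.20):
            copy = mutate_sequence(reference.sequence, div, rng)
            bg = bg[:pos] + copy + bg[pos + len(copy):]
            planted.append((pos, div))
            pos += 12_000
        copies = detect_introns([make_genome(bg)], [reference])
        assert len(copies) == 4
        n = len(reference.sequence)
        for c in sorted(copies, key=lambda c: c.interval.start):
            pos, div = min(planted, key=lambda t: abs(t[0] - c.interval.start))
            # local alignment may trim a few mutated end bases
            assert c.interval.start >= pos and c.interval.end <= pos + n
            assert len(c.interval) >= 0.9 * n
            assert c.percent_identity >= (1 - div) - 0.01
            if div <= 0.10:
                assert c.completeness is Completeness.FULL_LENGTH

    def test_no_detections_in_intron_free_genome(self, reference):
        rng = np.random.default_rng(99)
        genome = make_genome(random_dna(rng, 1_000_000))
        assert detect_introns([genome], [reference]) == []

    def test_plasmid_container_recorded(self, reference):
        rng = np.random.default_rng(55)
        seq = random_dna(rng, 8000)
        seq = seq[:3000] + reference.sequence + seq[3000:]
        genome = make_genome(seq, kind=RepliconKind.PLASMID)
        (copy,) = detect_introns([genome], [reference])
        assert copy.container is Container.PLASMID
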