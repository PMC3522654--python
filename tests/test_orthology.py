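"""Flank extraction, insertion classification and distinct-copy collapsing."""

import numpy as np
import pytest

from retrohome.detection import Completeness, IntronCopy
from retrohome.genome_io import (
    Genome,
    Interval,
    Replicon,
    RepliconKind,
    Strand,
    Topology,
)
from retrohome.orthology import (
    DistinctSet,
    InsertionCall,
    InsertionClass,
    OrthologyParams,
    apply_mge_overrides,
    classify_insertion,
    collapse_distinct,
    extract_flanks,
)

from conftest import random_dna


def make_copy(cid, start, end, rid="s1_chr", genome="s1", strand=Strand.FORWARD):
    return IntronCopy(
        id=cid, genome=genome, reference_name="I1", assigned_name="I1",
        interval=Interval(rid, start, end, strand),
        completeness=Completeness.FULL_LENGTH, percent_identity=1.0,
    )


def make_replicon(seq, rid="s1_chr", topology=Topology.LINEAR):
    return Replicon(id=rid, genome_id=rid.split("_")[0], kind=RepliconKind.CHROMOSOME,
                    topology=topology, sequence=seq)


class TestExtractFlanks:
    def test_interior_copy(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 20_000)
        rep = make_replicon(seq)
        flanks = extract_flanks(make_copy("c", 5000, 6000), rep)
        assert flanks.upstream == seq[2000:5000]
        assert flanks.downstream == seq[6000:9000]

    def test_edge_truncation(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 10_000)
        rep = make_replicon(seq)
        flanks = extract_flanks(make_copy("c", 100, 800), rep)
        assert flanks.upstream == seq[:100]
        assert len(flanks.upstream) == 100

    def test_circular_wrap_gives_full_width(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 20_000)
        rep = make_replicon(seq, topology=Topology.CIRCULAR)
        flanks = extract_flanks(make_copy("c", 500, 1500), rep)
        assert len(flanks.upstream) == len(flanks.downstream) == 3000
        assert flanks.upstream == seq[-2500:] + seq[:500]
        assert flanks.downstream == seq[1500:4500]


@pytest.fixture(scope="module")
def shared_locus():
    """A 3 kb + 3 kb locus shared between a query copy and subject genomes."""
    rng = np.random.default_rng(7)
    up = random_dna(rng, 3000)
    down = random_dna(rng, 3000)
    intron = random_dna(rng, 600)
    return up, down, intron, rng


def subject_genome(seq, strain="s2"):
    return Genome(strain=strain, genus_complex="GenusA",
                  replicons=[make_replicon(seq, rid=f"{strain}_chr")])


class TestClassifyInsertion:
    def test_empty_locus_means_retrohomed(self, shared_locus):
        up, down, intron, rng = shared_locus
        bg = random_dna(np.random.default_rng(8), 20_000)
        subject = subject_genome(bg[:7000] + up + down + bg[7000:])
        from retrohome.orthology import FlankPair
        call = classify_insertion(FlankPair("c1", up, down), subject, [])
        assert call.classification is InsertionClass.RETROHOMED
        assert abs(call.evidence["adjacency_gap"]) <= 20

    def test_same_intron_at_same_locus_is_orthologous(self, shared_locus):
        up, down, intron, rng = shared_locus
        bg = random_dna(np.random.default_rng(9), 20_000)
        seq = bg[:7000] + up + intron + down + bg[7000:]
        start = 7000 + 3000
        subject = subject_genome(seq)
        sc = make_copy("sc", start, start + 600, rid="s2_chr", genome="s2")
        from retrohome.orthology import FlankPair
        call = classify_insertion(FlankPair("c1", up, down), subject, [sc])
        assert call.classification is InsertionClass.ORTHOLOGOUS
        assert call.evidence["subject_copy_id"] == "sc"

    def test_occupied_locus_is_not_retrohomed_without_copy_record(self, shared_locus):
        """An intron between the flanks breaks adjacency: not retrohomed."""
        up, down, intron, rng = shared_locus
        bg = random_dna(np.random.default_rng(10), 20_000)
        subject = subject_genome(bg[:7000] + up + intron + down + bg[7000:])
        from retrohome.orthology import FlankPair
        call = classify_insertion(FlankPair("c1", up, down), subject, [])
        assert call.classification is InsertionClass.UNRESOLVED

    def test_absent_flanks_unresolved(self, shared_locus):
        up, down, intron, rng = shared_locus
        subject = subject_genome(random_dna(np.random.default_rng(11), 20_000))
        from retrohome.orthology import FlankPair
        call = classify_insertion(FlankPair("c1", up, down), subject, [])
        assert call.classification is InsertionClass.UNRESOLVED


class TestOverrides:
    def _calls(self):
        return [
            InsertionCall("a", "s2", InsertionClass.ORTHOLOGOUS,
                          {"subject_copy_id": "b"}),
            InsertionCall("b", "s1", InsertionClass.ORTHOLOGOUS,
                          {"subject_copy_id": "a"}),
            InsertionCall("a", "s3", InsertionClass.UNRESOLVED, {}),
        ]

    def test_override_reclassifies_pair(self):
        calls = apply_mge_overrides(self._calls(), [("a", "s2"), ("b", "s1")])
        assert calls[0].classification is InsertionClass.DISTINCT_MGE
        assert calls[1].classification is InsertionClass.DISTINCT_MGE
        assert calls[2].classification is InsertionClass.UNRESOLVED

    def test_empty_override_is_identity(self):
        calls = self._calls()
        got = apply_mge_overrides(calls, [])
        assert [c.classification for c in got] == [c.classification for c in calls]

    def test_override_on_unresolved_pair_applies(self):
        got = apply_mge_overrides(self._calls(), [("a", "s3")])
        assert got[2].classification is InsertionClass.DISTINCT_MGE

    def test_unknown_pair_rejected(self):
        with pytest.raises(KeyError):
            apply_mge_overrides(self._calls(), [("zz", "s9")])


def ortho_call(a, b, genome_b):
    return InsertionCall(a, genome_b, InsertionClass.ORTHOLOGOUS,
                         {"subject_copy_id": b})


class TestCollapseDistinct:
    def test_transitive_chain_collapses(self):
        copies = [make_copy(c, 100 * i + 100, 100 * i + 180, genome=f"s{i}")
                  for i, c in enumerate("abcde")]
        calls = [ortho_call("a", "b", "s1"), ortho_call("b", "c", "s2"),
                 ortho_call("d", "e", "s4")]
        sets = collapse_distinct(copies, calls)
        sizes = sorted(len(s.member_copy_ids) for s in sets)
        assert sizes == [2, 3]
        assert len(sets) == 2

    def test_no_calls_gives_singletons(self):
        copies = [make_copy(f"c{i}", 100 * i + 1, 100 * i + 80) for i in range(7)]
        sets = collapse_distinct(copies, [])
        assert len(sets) == 7
        assert all(len(s.member_copy_ids) == 1 for s in sets)

    def test_partition_covers_every_copy_once(self):
        copies = [make_copy(c, 100 * i + 100, 100 * i + 180) for i, c in enumerate("abcdef")]
        calls = [ortho_call("a", "c", "s1"), ortho_call("e", "f", "s1")]
        sets = collapse_distinct(copies, calls)
        seen = [m for s in sets for m in s.member_copy_ids]
        assert sorted(seen) == sorted(c.id for c in copies)

    def test_order_invariance(self):
        copies = [make_copy(c, 100 * i + 100, 100 * i + 180) for i, c in enumerate("abcd")]
        calls = [ortho_call("a", "b", "sx"), ortho_call("c", "d", "sy")]
        fwd = collapse_distinct(copies, calls)
        rev = collapse_distinct(list(reversed(copies)), list(reversed(calls)))
        assert {s.member_copy_ids for s in fwd} == {s.member_copy_ids for s in rev}


class TestPublishedAbundanceShape:
    """Per-genus distinct counts follow from copies and orthology groupings.

    Mirrors the published survey's per-genus reduction (122 copies -> 67
    distinct in Escherichia/Shigella etc.) using synthetic groupings with
    the same arithmetic.
    """

    @pytest.mark.parametrize(
        "n_copies,n_groups,group_sizes,expected_distinct",
        [
            (122, 18, None, 67),   # 55 copies absorbed into orthologous groups
            (38, 0, None, 38),
            (10, 1, [2], 9),
            (8, 0, None, 8),
            (5, 0, None, 5),
            (4, 1, [2], 3),
            (3, 0, None, 3),
            (8, 2, [4, 4], 2),
        ],
    )
    def test_distinct_counts(self, n_copies, n_groups, group_sizes, expected_distinct):
        copies = [make_copy(f"c{i}", 200 * i + 1, 200 * i + 100, genome=f"s{i}")
                  for i in range(n_copies)]
        calls = []
        if group_sizes is None and n_groups:
            # absorb surplus copies into n_groups groups as evenly as possible
            surplus = n_copies - expected_distinct
            group_sizes = []
            base = surplus // n_groups
            for g in range(n_groups):
                size = 1 + base + (1 if g < surplus % n_groups else 0)
                group_sizes.append(size)
        idx = 0
        for size in group_sizes or []:
            members = [copies[idx + j].id for j in range(size)]
            idx += size
            for a, b in zip(members, members[1:]):
                calls.append(ortho_call(a, b, "sx"))
        sets = collapse_distinct(copies, calls)
        assert len(sets) == expected_distinct
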