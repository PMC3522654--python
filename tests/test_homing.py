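"""Consensus building, terminator detection, scanning and occupancy marking."""

import numpy as np
import pytest

from retrohome.detection import Completeness, IntronCopy
from retrohome.genome_io import (
    Interval,
    Replicon,
    RepliconKind,
    Strand,
    Topology,
    revcomp,
)
from retrohome.homing import (
    HomingSiteModel,
    Scheme,
    SiteOccurrence,
    SiteState,
    TerminatorHit,
    TerminatorParams,
    build_consensus_from_conservation,
    build_consensus_from_ebs,
    find_rho_independent_terminators,
    mark_occupancy,
    occupancy_counts,
    restrict_to_terminator_downstream,
    scan_perfect_match,
)
from retrohome.validation import exhaustive_consensus_scan, exhaustive_terminators

from conftest import random_dna


def make_replicon(seq, rid="chr", topology=Topology.LINEAR):
    return Replicon(id=rid, genome_id="g", kind=RepliconKind.CHROMOSOME,
                    topology=topology, sequence=seq)


class TestEbsConsensus:
    def test_perfect_watson_crick_pairing_fixes_ibs1(self):
        rng = np.random.default_rng(0)
        ebs1 = "GAAAGC"
        ibs1 = revcomp(ebs1)  # GCTTTC
        window = random_dna(rng, 35)
        window = window[:19] + ibs1 + window[25:]
        model = build_consensus_from_ebs({"EBS1": ebs1}, [window])
        assert model.consensus[19:25] == ibs1
        # no EBS3 and no reference flank: everything else is N
        assert set(model.consensus[:19]) == {"N"}
        assert set(model.consensus[25:]) == {"N"}
        assert model.insertion_offset == 24

    def test_wobble_pairing_accepted(self):
        # EBS base G pairs target T (G.U wobble) as well as C
        ebs1 = "G"
        window = "N" * 24 + "T" + "N" * 10
        window = window.replace("N", "A")
        model = build_consensus_from_ebs({"EBS1": ebs1}, [window])
        assert model.consensus[24] == "T"

    def test_reference_flank_extends_consensus_at_identical_positions(self):
        rng = np.random.default_rng(3)
        w1 = random_dna(rng, 35)
        w2 = list(random_dna(rng, 35))
        keep = [0, 3, 5, 9, 12, 20, 28, 30, 34]
        for i in range(35):
            if i not in keep:
                while w2[i] == w1[i]:
                    w2[i] = "ACGT"[rng.integers(0, 4)]
            else:
                w2[i] = w1[i]
        w2 = "".join(w2)
        model = build_consensus_from_ebs({}, [w1, w2], reference_flank=w1)
        fixed = [i for i, c in enumerate(model.consensus) if c != "N"]
        assert fixed == keep

    def test_unequal_windows_rejected(self):
        with pytest.raises(ValueError):
            build_consensus_from_ebs({"EBS1": "GAAAGC"}, ["ACGT" * 8, "ACGT" * 9])


class TestConservationConsensus:
    def test_unanimous_column_fixed(self):
        windows = ["A" * 35] * 26
        model = build_consensus_from_conservation(windows)
        assert model.consensus == "A" * 35
        assert model.scheme is Scheme.CONSERVATION_CONSENSUS

    def test_split_column_is_n(self):
        windows = ["A" + "C" * 34] * 5 + ["C" * 35] * 5
        model = build_consensus_from_conservation(windows)
        assert model.consensus[0] == "N"
        assert model.consensus[1] == "C"

    def test_noisy_windows_recover_generator_consensus(self):
        rng = np.random.default_rng(17)
        truth = random_dna(rng, 35)
        windows = []
        for _ in range(10):
            w = list(truth)
            for i in range(35):
                if rng.random() < 0.10:
                    w[i] = "ACGT"[rng.integers(0, 4)]
            windows.append("".join(w))
        model = build_consensus_from_conservation(windows)
        for i, c in enumerate(model.consensus):
            counts = {b: sum(w[i] == b for w in windows) for b in "ACGT"}
            modal = max(counts, key=counts.get)
            if counts[modal] / 10 >= 0.8:
                assert c == modal
            else:
                assert c == "N"

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            build_consensus_from_conservation(["A" * 35] * 4)


CANONICAL = "GGGCGC" + "AAAA" + "GCGCCC" + "TTTTTTTT"


class TestTerminators:
    def test_canonical_terminator_found(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 300) + CANONICAL + random_dna(rng, 300)
        # the perfect 6 bp stem is reported before containment filtering ...
        raw = find_rho_independent_terminators(make_replicon(seq), maximal=False)
        assert any(
            h.strand is Strand.FORWARD and h.interval.start == 300
            and h.stem_length == 6 and h.loop_length == 4 and h.mismatches == 0
            for h in raw
        )
        # ... and the locus survives as a maximal hit
        hits = find_rho_independent_terminators(make_replicon(seq))
        assert any(
            h.strand is Strand.FORWARD
            and h.interval.start <= 300 and h.interval.end >= 316
            for h in hits
        )

    def test_broken_tail_gives_no_hit(self):
        seq = "A" * 100 + "GGGCGC" + "AAAA" + "GCGCCC" + "ACACACAC" + "A" * 100
        hits = find_rho_independent_terminators(make_replicon(seq))
        # the forward-strand stem-loop has no U-tail: nothing reported there
        # (the reverse strand of the poly-A background is legitimately U-rich)
        assert not [
            h for h in hits
            if h.strand is Strand.FORWARD and 95 <= h.interval.start <= 115
        ]

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 3000)
        fwd = find_rho_independent_terminators(make_replicon(seq), maximal=False)
        rev = find_rho_independent_terminators(make_replicon(revcomp(seq)), maximal=False)
        n = len(seq)
        mirrored = sorted(
            (n - h.interval.end, n - h.interval.start,
             "-" if h.strand is Strand.FORWARD else "+")
            for h in fwd
        )
        got = sorted(
            (h.interval.start, h.interval.end, h.strand.value) for h in rev
        )
        assert mirrored == got

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumerator(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 4000)
        if seed % 2:
            seq = seq[:1000] + CANONICAL + seq[1000:]
        params = TerminatorParams()
        got = {
            (h.interval.start, h.stem_length, h.loop_length, h.mismatches)
            for h in find_rho_independent_terminators(
                make_replicon(seq), params, maximal=False
            )
            if h.strand is Strand.FORWARD
        }
        want = {
            (start, stem, loop, mism)
            for start, stem, loop, mism, _ in exhaustive_terminators(seq)
        }
        assert got == want

    def test_maximal_filter_removes_contained_hits(self):
        rng = np.random.default_rng(11)
        seq = random_dna(rng, 2000) + CANONICAL + random_dna(rng, 2000)
        hits = find_rho_independent_terminators(make_replicon(seq))
        for h in hits:
            for g in hits:
                if g is not h and g.strand == h.strand:
                    strictly_inside = (
                        g.interval.start <= h.interval.start
                        and h.interval.end <= g.interval.end
                        and len(h.interval) < len(g.interval)
                    )
                    assert not strictly_inside


class TestPerfectScan:
    def model(self, consensus, offset=None):
        return HomingSiteModel(
            intron_name="I1", scheme=Scheme.EBS_CONSENSUS, consensus=consensus,
            insertion_offset=offset if offset is not None else len(consensus) - 2,
        )

    def test_wildcard_consensus_matches(self):
        rep = make_replicon("AGGTCCAGCT")
        sites = scan_perfect_match(rep, self.model("ANNT", offset=2))
        fwd = [s.interval.start for s in sites if s.strand is Strand.FORWARD]
        assert fwd == [0, 6]

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            scan_perfect_match(make_replicon("ACGT" * 10), self.model("NNNN"))

    def test_reverse_strand_reported_once(self):
        rng = np.random.default_rng(3)
        motif = random_dna(rng, 20)
        seq = random_dna(rng, 500) + revcomp(motif) + random_dna(rng, 500)
        sites = scan_perfect_match(make_replicon(seq), self.model(motif, offset=10))
        assert len(sites) == 1
        assert sites[0].strand is Strand.REVERSE
        assert sites[0].interval.start == 500

    def test_genomic_n_never_matches(self):
        rep = make_replicon("ANGT")
        sites = scan_perfect_match(rep, self.model("ANGT", offset=2))
        assert sites == []

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_exhaustive_window_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 20_000)
        motif = random_dna(rng, 8)
        consensus = motif[:3] + "NN" + motif[5:]
        seq = seq[:777] + motif[:3] + "GT" + motif[5:] + seq[777 + 8:]
        got = [
            s.interval.start
            for s in scan_perfect_match(make_replicon(seq), self.model(consensus, 4))
            if s.strand is Strand.FORWARD
        ]
        assert got == exhaustive_consensus_scan(seq, consensus)

    def test_circular_wrap_found(self):
        rng = np.random.default_rng(9)
        motif = random_dna(rng, 16)
        bg = random_dna(rng, 3000)
        seq = motif[10:] + bg + motif[:10]
        sites = scan_perfect_match(
            make_replicon(seq, topology=Topology.CIRCULAR), self.model(motif, 8)
        )
        fwd = [s for s in sites if s.strand is Strand.FORWARD]
        assert any(s.interval.start == len(seq) - 10 for s in fwd)


class TestFlankSimilarityScan:
    def _model(self, ctx):
        from retrohome.homing import scan_flank_similarity  # noqa: F401

        return HomingSiteModel(
            intron_name="I1", scheme=Scheme.FLANK_SIMILARITY,
            context_sequence=ctx,
        )

    def test_exact_context_found_once(self):
        from retrohome.homing import scan_flank_similarity

        rng = np.random.default_rng(31)
        ctx = random_dna(rng, 90)
        seq = random_dna(rng, 5000) + ctx + random_dna(rng, 5000)
        sites = scan_flank_similarity(make_replicon(seq), self._model(ctx))
        assert len(sites) == 1
        assert sites[0].interval.start == 5000

    def test_twelve_mismatches_below_identity_rule(self):
        from retrohome.homing import scan_flank_similarity

        rng = np.random.default_rng(32)
        ctx = random_dna(rng, 90)
        degraded = list(ctx)
        for p in rng.choice(90, size=12, replace=False):
            degraded[p] = "ACGT".replace(degraded[p], "")[0]
        seq = random_dna(rng, 3000) + "".join(degraded) + random_dna(rng, 3000)
        assert scan_flank_similarity(make_replicon(seq), self._model(ctx)) == []

    def test_hit_missing_integration_point_rejected(self):
        from retrohome.homing import scan_flank_similarity

        rng = np.random.default_rng(33)
        ctx = random_dna(rng, 90)
        # only the first 40 bases present: junction (after base 45) absent
        seq = random_dna(rng, 3000) + ctx[:40] + random_dna(rng, 3000)
        assert scan_flank_similarity(
            make_replicon(seq), self._model(ctx), min_context_span=30
        ) == []

    def test_ninety_bp_requirement(self):
        with pytest.raises(ValueError):
            HomingSiteModel(
                intron_name="I1", scheme=Scheme.FLANK_SIMILARITY,
                context_sequence="ACGT" * 10,
            )


def term_hit(start, end, strand=Strand.FORWARD):
    return TerminatorHit(
        interval=Interval("chr", start, end, strand), stem_length=6,
        loop_length=4, mismatches=0, u_tail_score=1.0, strand=strand,
    )


def site_at(start, consensus="GCTTTCA", strand=Strand.FORWARD):
    model = HomingSiteModel(
        intron_name="I1", scheme=Scheme.CLASSC_TERMINATOR,
        consensus=consensus, insertion_offset=len(consensus) - 2,
    )
    return SiteOccurrence(
        model=model,
        interval=Interval("chr", start, start + len(consensus), strand),
        strand=strand,
    )


class TestTerminatorGating:
    def test_site_just_downstream_kept(self):
        sites = [site_at(104)]  # 4 nt after the stem end
        assert restrict_to_terminator_downstream(sites, [term_hit(80, 100)]) == sites

    def test_upstream_site_dropped(self):
        sites = [site_at(50)]
        assert restrict_to_terminator_downstream(sites, [term_hit(80, 100)]) == []

    def test_opposite_strand_dropped(self):
        sites = [site_at(104, strand=Strand.REVERSE)]
        assert restrict_to_terminator_downstream(sites, [term_hit(80, 100)]) == []

    def test_output_is_subset_of_input(self):
        sites = [site_at(104), site_at(500), site_at(90)]
        kept = restrict_to_terminator_downstream(sites, [term_hit(80, 100)])
        assert all(s in sites for s in kept)


def make_copy(cid, start, end, name="I1"):
    return IntronCopy(
        id=cid, genome="g", reference_name=name, assigned_name=name,
        interval=Interval("chr", start, end),
        completeness=Completeness.FULL_LENGTH, percent_identity=1.0,
    )


class TestOccupancy:
    def test_no_copies_all_available(self):
        sites = [site_at(100 * i) for i in range(1, 6)]
        occ = mark_occupancy(sites, [])
        assert occupancy_counts(occ) == (0, 5)

    def test_copies_yield_occupied_records(self):
        copies = [make_copy(f"c{i}", 1000 * i, 1000 * i + 600) for i in range(1, 4)]
        sites = [site_at(100)]
        occ = mark_occupancy(sites, copies)
        assert occupancy_counts(occ) == (3, 1)
        occupied = [s for s in occ if s.state is SiteState.OCCUPIED]
        assert {s.occupied_by for s in occupied} == {"c1", "c2", "c3"}

    def test_candidate_inside_copy_removed(self):
        copies = [make_copy("c1", 1000, 1600)]
        sites = [site_at(1200), site_at(5000)]
        occ = mark_occupancy(sites, copies)
        assert occupancy_counts(occ) == (1, 1)
        available = [s for s in occ if s.state is SiteState.AVAILABLE]
        assert available[0].interval.start == 5000

    def test_candidate_at_copy_junction_not_double_counted(self):
        copies = [make_copy("c1", 1000, 1600)]
        # insertion point of this site is its start + offset + 1 = copy start
        model_len = 7
        site = site_at(1000 - model_len + 1)
        occ = mark_occupancy([site], copies)
        assert occupancy_counts(occ) == (1, 0)
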