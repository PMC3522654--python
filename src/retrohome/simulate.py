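"""Synthetic bacterial populations with planted introns and full ground truth.

The generator emulates the genomic structures the survey pipeline must
recover, without any real data: i.i.d. background chromosomes at a chosen
GC content carrying

* reference group II introns (ribozyme + embedded IEP ORF, recorded EBS
  motifs), including class C introns with only EBS1/EBS3;
* full-length and truncated (fragment) intron copies planted exactly at
  homing-site insertion points, with controlled substitution divergence;
* free homing sites — the 35 bp target context whose IBS positions pair
  with the intron's EBS motifs — for class C introns placed a few nt
  downstream of planted Rho-independent terminators;
* IS elements carrying the 90 bp homing context of IS-targeting introns;
* orthologous copies sharing identical 3 kbp flanks across strains,
  intron-free counterpart loci in other strains (retrohoming-testable),
  and genomic-island transfers sharing island-internal flanks but not the
  chromosomal locus;
* decoy terminators with no site behind them.

Everything planted is recorded in a :class:`TruthManifest` keyed to final
genome coordinates, so each pipeline stage can be scored exactly.
Substitution-only mutation keeps identity arithmetic exact; an optional
indel mode exists for robustness checks but is excluded from
exact-recovery guarantees.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genome_io import Genome, Replicon, RepliconKind, Topology, revcomp, write_genomes
from .homing import Scheme
from .library import OrfClass, ReferenceIntron, RibozymeGroup, write_library

__all__ = [
    "ISFamilySpec",
    "SyntheticIntronSpec",
    "PlantingPlan",
    "SimConfig",
    "TruthManifest",
    "SimPopulation",
    "generate_reference_intron",
    "generate_population",
    "mutate_sequence",
    "write_population",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

TERMINATOR_STEM = 8
TERMINATOR_LOOP = 4
TERMINATOR_TAIL = 8
SITE_WINDOW = (-25, 10)  # homing-site context around the insertion point


@dataclass(frozen=True)
class ISFamilySpec:
    """An insertion-sequence family whose copies carry an intron homing site."""

    name: str
    length: int = 1000
    copies_per_strain: int = 3
    homing_offset: int = 500  # insertion point of the targeting intron


@dataclass(frozen=True)
class SyntheticIntronSpec:
    name: str
    length: int = 600
    orf_class: str = "ML"          # "C" selects a class C intron
    ribozyme_group: str = "IIB"
    ebs1_length: int = 6
    ebs2_length: int = 6           # ignored for class C
    scheme: Scheme = Scheme.EBS_CONSENSUS
    target_is: Optional[str] = None  # IS family name for FLANK_SIMILARITY

    def __post_init__(self) -> None:
        if self.orf_class == "C" and self.scheme is Scheme.EBS_CONSENSUS:
            object.__setattr__(self, "scheme", Scheme.CLASSC_TERMINATOR)
        if self.length < 400:
            raise ValueError("reference introns must be at least 400 bp")


@dataclass(frozen=True)
class PlantingPlan:
    """What to plant for one intron, and where."""

    intron: str
    strain: int = 0                       # primary host strain index
    n_full_length: int = 0
    full_length_divergence: float = 0.0
    n_disrupted_orf: int = 0              # of the full-length, premature-stop copies
    n_fragments: int = 0
    fragment_divergence: float = 0.0
    fragment_fraction: float = 0.4        # interior slice kept
    n_free_sites: int = 0
    orthology_groups: tuple[tuple[int, ...], ...] = ()
    n_retrohoming_loci: int = 0           # empty counterpart loci in the next strain
    n_mge_transfers: int = 0              # island shared by (strain, strain+1)
    on_plasmid: bool = False


@dataclass(frozen=True)
class SimConfig:
    n_strains: int = 1
    chromosome_length: int = 100_000
    n_plasmids: int = 0
    plasmid_length: int = 10_000
    gc_content: float = 0.5
    circular: bool = False
    intron_specs: tuple[SyntheticIntronSpec, ...] = ()
    is_specs: tuple[ISFamilySpec, ...] = ()
    n_decoy_terminators: int = 0
    plans: tuple[PlantingPlan, ...] = ()
    genus_of_strain: Optional[tuple[str, ...]] = None
    seed: int = 0

    def genus(self, strain_index: int) -> str:
        if self.genus_of_strain:
            return self.genus_of_strain[strain_index]
        return "GenusA"


@dataclass
class PlantedCopy:
    strain: str
    replicon_id: str
    start: int
    end: int
    strand: str
    intron: str
    completeness: str           # "full_length" | "fragment"
    divergence: float
    orf_intact: Optional[bool]
    orthology_group: Optional[str] = None


@dataclass
class FreeSite:
    strain: str
    replicon_id: str
    insertion_point: int
    intron: str
    scheme: str


@dataclass
class PlantedTerminator:
    strain: str
    replicon_id: str
    start: int
    end: int
    decoy: bool = False


@dataclass
class MgeTransfer:
    intron: str
    strains: tuple[str, str]
    positions: dict = field(default_factory=dict)  # strain -> copy (start, end)


@dataclass
class TruthManifest:
    planted_copies: list[PlantedCopy] = field(default_factory=list)
    free_sites: list[FreeSite] = field(default_factory=list)
    terminators: list[PlantedTerminator] = field(default_factory=list)
    mge_transfers: list[MgeTransfer] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_copies": [asdict(c) for c in self.planted_copies],
                "free_sites": [asdict(s) for s in self.free_sites],
                "terminators": [asdict(t) for t in self.terminators],
                "mge_transfers": [asdict(m) for m in self.mge_transfers],
            },
            indent=1,
            default=int,  # numpy integers from placement arithmetic
        )

    def copies_of(self, intron: str, strain: str | None = None) -> list[PlantedCopy]:
        return [
            c for c in self.planted_copies
            if c.intron == intron and (strain is None or c.strain == strain)
        ]

    def orthology_partition(self) -> list[set[str]]:
        """Expected distinct sets as {(strain, start)} key groups."""
        groups: dict[str, set[str]] = {}
        singles: list[set[str]] = []
        for c in self.planted_copies:
            key = f"{c.strain}:{c.replicon_id}:{c.start}"
            if c.orthology_group:
                groups.setdefault(c.orthology_group, set()).add(key)
            else:
                singles.append({key})
        return list(groups.values()) + singles


@dataclass
class SimPopulation:
    genomes: list[Genome]
    library: list[ReferenceIntron]
    manifest: TruthManifest
    model_specs: list[dict]
    overrides: list[dict]
    site_contexts: dict[str, str]


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def mutate_sequence(seq: str, divergence: float, seed) -> str:
    """Substitute ``round(divergence * len)`` distinct positions.

    ``seed`` may be an integer or a numpy Generator; substitutions always
    change the base, so the realised divergence is exact.
    """
    if not 0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_mut = round(divergence * len(seq))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons:
        c = "".join(_BASES[rng.integers(0, 4, size=3)])
        if c not in _STOPS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def generate_reference_intron(spec: SyntheticIntronSpec, seed: int) -> ReferenceIntron:
    """A random reference intron with an embedded, uninterrupted IEP ORF."""
    rng = np.random.default_rng(seed)
    orf_len = 3 * int(0.6 * spec.length / 3)
    n_codons = orf_len // 3 - 2  # minus start and stop
    orf = _random_orf(rng, n_codons)
    lead = max(60, (spec.length - len(orf)) // 2)
    head = _random_dna(rng, lead)
    tail = _random_dna(rng, spec.length - lead - len(orf))
    seq = head + orf + tail
    ebs = {"EBS1": _random_dna(rng, spec.ebs1_length), "EBS3": _random_dna(rng, 1)}
    if spec.orf_class != "C":
        ebs["EBS2"] = _random_dna(rng, spec.ebs2_length)
    return ReferenceIntron(
        name=spec.name,
        ribozyme_group=RibozymeGroup(spec.ribozyme_group),
        orf_class=OrfClass(spec.orf_class),
        sequence=seq,
        orf_interval=(lead, lead + len(orf)),
        ebs_motifs=ebs,
    )


def _site_context(rng: np.random.Generator, ref: ReferenceIntron) -> str:
    """A 35 bp homing-site context whose IBS positions pair with the EBS."""
    left, right = SITE_WINDOW
    pre = -left
    ctx = list(_random_dna(rng, right - left))
    ibs1 = revcomp(ref.ebs_motifs["EBS1"])
    ctx[pre - len(ibs1) : pre] = list(ibs1)
    if "EBS2" in ref.ebs_motifs:
        ibs2 = revcomp(ref.ebs_motifs["EBS2"])
        ctx[pre - len(ibs1) - len(ibs2) : pre - len(ibs1)] = list(ibs2)
    ctx[pre] = revcomp(ref.ebs_motifs["EBS3"])
    return "".join(ctx)


def _canonical_terminator(rng: np.random.Generator) -> str:
    stem = "".join(_BASES[rng.choice(4, size=TERMINATOR_STEM, p=[0.1, 0.4, 0.4, 0.1])])
    loop = _random_dna(rng, TERMINATOR_LOOP)
    return stem + loop + revcomp(stem) + "T" * TERMINATOR_TAIL


def _disrupt_orf(ref: ReferenceIntron, seq: str) -> str:
    """Place an in-frame premature stop at the middle of the IEP ORF."""
    lo, hi = ref.orf_interval
    mid = lo + 3 * (((hi - lo) // 2) // 3)
    return seq[:mid] + "TAA" + seq[mid + 3 :]


class _StrainBuilder:
    """Accumulates insertion elements for one replicon, then assembles."""

    def __init__(self, rng: np.random.Generator, background: str, replicon_id: str):
        self.rng = rng
        self.background = background
        self.replicon_id = replicon_id
        self.elements: list[tuple[str, object]] = []  # (sequence, annotation fn input)

    def add(self, seq: str, annotate) -> None:
        """``annotate(element_start)`` is called after placement."""
        self.elements.append((seq, annotate))

    def assemble(self) -> str:
        n_bg = len(self.background)
        total = sum(len(seq) for seq, _ in self.elements)
        if total > n_bg:
            raise ValueError(
                f"infeasible packing: {total} planted bp exceed the "
                f"{n_bg} bp background of {self.replicon_id}"
            )
        n = len(self.elements)
        if n == 0:
            return self.background
        usable = n_bg - 2000
        if usable < n * 300:
            raise ValueError(f"infeasible packing: too many elements for {self.replicon_id}")
        for _ in range(200):
            positions = np.sort(self.rng.choice(usable // 100, size=n, replace=False)) * 100 + 1000
            if n == 1 or np.min(np.diff(positions)) >= 300:
                break
        else:
            raise ValueError(f"infeasible packing on {self.replicon_id}")
        parts = []
        cursor = 0
        offset = 0
        order = self.rng.permutation(n)
        for idx, pos in zip(order, positions):
            seq, annotate = self.elements[idx]
            parts.append(self.background[cursor:pos])
            annotate(pos + offset)
            parts.append(seq)
            offset += len(seq)
            cursor = pos
        parts.append(self.background[cursor:])
        return "".join(parts)


def generate_population(config: SimConfig) -> SimPopulation:
    """Build the strain population described by ``config``; fully seeded."""
    rng = np.random.default_rng(config.seed)
    specs = {s.name: s for s in config.intron_specs}
    refs: dict[str, ReferenceIntron] = {}
    contexts: dict[str, str] = {}
    for i, spec in enumerate(config.intron_specs):
        ref = generate_reference_intron(spec, int(rng.integers(0, 2**31 - 1)))
        refs[spec.name] = ref
        contexts[spec.name] = _site_context(rng, ref)
    is_seqs: dict[str, str] = {}
    for fam in config.is_specs:
        is_seqs[fam.name] = _random_dna(rng, fam.length, config.gc_content)
    # an IS-targeting intron's context is the 90 bp of IS around its insertion point
    is_contexts: dict[str, str] = {}
    for spec in config.intron_specs:
        if spec.target_is:
            fam = next(f for f in config.is_specs if f.name == spec.target_is)
            seq = is_seqs[fam.name]
            ref = refs[spec.name]
            ibs1 = revcomp(ref.ebs_motifs["EBS1"])
            seq = (
                seq[: fam.homing_offset - len(ibs1)]
                + ibs1
                + revcomp(ref.ebs_motifs["EBS3"])
                + seq[fam.homing_offset + 1 :]
            )
            is_seqs[fam.name] = seq
            is_contexts[spec.name] = seq[fam.homing_offset - 45 : fam.homing_offset + 45]

    manifest = TruthManifest()
    overrides: list[dict] = []
    strain_names = [f"strain{idx:02d}" for idx in range(config.n_strains)]
    pre = -SITE_WINDOW[0]

    builders: dict[tuple[int, str], _StrainBuilder] = {}
    plasmid_bg: dict[tuple[int, int], str] = {}
    for s in range(config.n_strains):
        chrom_id = f"{strain_names[s]}_chr"
        builders[(s, "chr")] = _StrainBuilder(
            rng, _random_dna(rng, config.chromosome_length, config.gc_content), chrom_id
        )
        for p in range(config.n_plasmids):
            plas_id = f"{strain_names[s]}_p{p+1}"
            builders[(s, f"p{p+1}")] = _StrainBuilder(
                rng, _random_dna(rng, config.plasmid_length, config.gc_content), plas_id
            )

    def copy_element(intron: str, divergence: float, rng_local, *, disrupted=False,
                     fragment=False, fragment_fraction=0.4):
        ref = refs[intron]
        seq = ref.sequence
        if disrupted:
            seq = _disrupt_orf(ref, seq)
        if fragment:
            n = len(seq)
            keep = int(fragment_fraction * n)
            lo = (n - keep) // 2
            seq = seq[lo : lo + keep]
        if divergence == 0:
            return seq
        # keep the outer 3 bp unmutated so local alignment cannot trim the
        # planted boundaries; the substitution count is computed on the whole
        # length, preserving the realised divergence
        n_mut = round(divergence * len(seq))
        interior = mutate_sequence(seq[3:-3], n_mut / len(seq[3:-3]), rng_local)
        return seq[:3] + interior + seq[-3:]

    def plant_full_length(builder, intron, divergence, rng_local, *, disrupted=False,
                          group=None, with_terminator=False, record_site=True,
                          wrap=("", "")):
        ctx = contexts[intron]
        body = copy_element(intron, divergence, rng_local, disrupted=disrupted)
        prefix = wrap[0]
        if with_terminator:
            term = _canonical_terminator(rng_local)
            prefix = prefix + term
        element = prefix + ctx[:pre] + body + ctx[pre:] + wrap[1]
        strain = builder.replicon_id.split("_")[0]

        def annotate(start, *, _body=body, _prefix=prefix, _term=with_terminator,
                     _div=divergence, _dis=disrupted, _grp=group):
            copy_start = start + len(_prefix) + pre
            manifest.planted_copies.append(
                PlantedCopy(
                    strain=strain,
                    replicon_id=builder.replicon_id,
                    start=copy_start,
                    end=copy_start + len(_body),
                    strand="+",
                    intron=intron,
                    completeness="full_length",
                    divergence=_div,
                    orf_intact=not _dis,
                    orthology_group=_grp,
                )
            )
            if _term:
                t0 = start + len(_prefix) - TERMINATOR_TAIL - (2 * TERMINATOR_STEM + TERMINATOR_LOOP)
                manifest.terminators.append(
                    PlantedTerminator(strain, builder.replicon_id, t0,
                                      t0 + 2 * TERMINATOR_STEM + TERMINATOR_LOOP)
                )
            return copy_start

        builder.add(element, annotate)

    def plant_free_site(builder, intron, rng_local, *, with_terminator=False):
        ctx = contexts[intron]
        prefix = _canonical_terminator(rng_local) if with_terminator else ""
        element = prefix + ctx
        strain = builder.replicon_id.split("_")[0]

        def annotate(start, *, _prefix=prefix, _term=with_terminator):
            manifest.free_sites.append(
                FreeSite(
                    strain=strain,
                    replicon_id=builder.replicon_id,
                    insertion_point=start + len(_prefix) + pre,
                    intron=intron,
                    scheme=specs[intron].scheme.value,
                )
            )
            if _term:
                t0 = start + len(_prefix) - TERMINATOR_TAIL - (2 * TERMINATOR_STEM + TERMINATOR_LOOP)
                manifest.terminators.append(
                    PlantedTerminator(strain, builder.replicon_id, t0,
                                      t0 + 2 * TERMINATOR_STEM + TERMINATOR_LOOP)
                )

        builder.add(element, annotate)

    group_counter = 0
    for plan in config.plans:
        spec = specs[plan.intron]
        classc = spec.scheme is Scheme.CLASSC_TERMINATOR
        rep_key = "p1" if plan.on_plasmid else "chr"
        host = builders[(plan.strain, rep_key)]
        if not spec.target_is:  # IS-targeting introns are planted inside IS copies
            for i in range(plan.n_full_length):
                plant_full_length(
                    host, plan.intron, plan.full_length_divergence, rng,
                    disrupted=i < plan.n_disrupted_orf, with_terminator=classc,
                )
            for _ in range(plan.n_free_sites):
                plant_free_site(host, plan.intron, rng, with_terminator=classc)
        for _ in range(plan.n_fragments):
            ref = refs[plan.intron]
            n_ref = len(ref.sequence)
            keep = int(plan.fragment_fraction * n_ref)
            frag_lo = (n_ref - keep) // 2
            frag = copy_element(
                plan.intron, plan.fragment_divergence, rng,
                fragment=True, fragment_fraction=plan.fragment_fraction,
            )
            # guard bases that mismatch the adjacent reference positions, so
            # the aligner cannot extend past the planted boundary by chance
            guard5 = "ACGT".replace(ref.sequence[frag_lo - 1], "")[0]
            guard3 = "ACGT".replace(ref.sequence[frag_lo + keep], "")[0]
            element = guard5 + frag + guard3
            strain = host.replicon_id.split("_")[0]

            def annotate_frag(start, *, _frag=frag, _b=host, _s=strain, _i=plan.intron,
                              _d=plan.fragment_divergence):
                manifest.planted_copies.append(
                    PlantedCopy(_s, _b.replicon_id, start + 1, start + 1 + len(_frag),
                                "+", _i, "fragment", _d, None)
                )

            host.add(element, annotate_frag)
        # shared-flank structures across strains
        for members in plan.orthology_groups:
            group_counter += 1
            gid = f"og{group_counter}"
            flank5 = _random_dna(rng, 3000, config.gc_content)
            flank3 = _random_dna(rng, 3000, config.gc_content)
            body = copy_element(plan.intron, plan.full_length_divergence, rng)
            ctx = contexts[plan.intron]
            cassette = flank5 + ctx[:pre] + body + ctx[pre:] + flank3
            for m in members:
                b = builders[(m, "chr")]
                strain = b.replicon_id.split("_")[0]

                def annotate_ortho(start, *, _b=b, _s=strain, _body=body, _gid=gid,
                                   _i=plan.intron, _d=plan.full_length_divergence):
                    cs = start + 3000 + pre
                    manifest.planted_copies.append(
                        PlantedCopy(_s, _b.replicon_id, cs, cs + len(_body), "+",
                                    _i, "full_length", _d, True, _gid)
                    )

                b.add(cassette, annotate_ortho)
        for _ in range(plan.n_retrohoming_loci):
            flank5 = _random_dna(rng, 3000, config.gc_content)
            flank3 = _random_dna(rng, 3000, config.gc_content)
            ctx = contexts[plan.intron]
            plant_full_length(
                host, plan.intron, plan.full_length_divergence, rng,
                wrap=(flank5, flank3),
            )
            other = (plan.strain + 1) % config.n_strains
            b = builders[(other, "chr")]
            empty = flank5 + ctx + flank3
            strain = b.replicon_id.split("_")[0]

            def annotate_empty(start, *, _b=b, _s=strain, _i=plan.intron):
                manifest.free_sites.append(
                    FreeSite(_s, _b.replicon_id, start + 3000 + pre, _i,
                             specs[_i].scheme.value)
                )

            b.add(empty, annotate_empty)
        for _ in range(plan.n_mge_transfers):
            gi5 = _random_dna(rng, 3500, config.gc_content)
            gi3 = _random_dna(rng, 3500, config.gc_content)
            body = copy_element(plan.intron, plan.full_length_divergence, rng)
            ctx = contexts[plan.intron]
            island = gi5 + ctx[:pre] + body + ctx[pre:] + gi3
            a, bdx = plan.strain, (plan.strain + 1) % config.n_strains
            transfer = MgeTransfer(
                plan.intron, (strain_names[a], strain_names[bdx])
            )
            manifest.mge_transfers.append(transfer)
            for m in (a, bdx):
                b = builders[(m, "chr")]
                strain = b.replicon_id.split("_")[0]

                def annotate_mge(start, *, _b=b, _s=strain, _body=body,
                                 _i=plan.intron, _t=transfer,
                                 _d=plan.full_length_divergence):
                    cs = start + 3500 + pre
                    manifest.planted_copies.append(
                        PlantedCopy(_s, _b.replicon_id, cs, cs + len(_body), "+",
                                    _i, "full_length", _d, True)
                    )
                    _t.positions[_s] = (cs, cs + len(_body))

                b.add(island, annotate_mge)
        # IS family copies hosting flank-similarity targets
        if spec.target_is:
            fam = next(f for f in config.is_specs if f.name == spec.target_is)
            occupied = plan.n_full_length
            free = max(fam.copies_per_strain - occupied, 0)
            for i in range(occupied):
                body = copy_element(plan.intron, plan.full_length_divergence, rng)
                isq = is_seqs[fam.name]
                element = isq[: fam.homing_offset] + body + isq[fam.homing_offset :]
                strain = host.replicon_id.split("_")[0]

                def annotate_is(start, *, _b=host, _s=strain, _body=body,
                                _i=plan.intron, _off=fam.homing_offset,
                                _d=plan.full_length_divergence):
                    cs = start + _off
                    manifest.planted_copies.append(
                        PlantedCopy(_s, _b.replicon_id, cs, cs + len(_body), "+",
                                    _i, "full_length", _d, True)
                    )

                host.add(element, annotate_is)
            for _ in range(free):
                strain = host.replicon_id.split("_")[0]

                def annotate_is_free(start, *, _b=host, _s=strain, _i=plan.intron,
                                     _off=fam.homing_offset):
                    manifest.free_sites.append(
                        FreeSite(_s, _b.replicon_id, start + _off, _i,
                                 Scheme.FLANK_SIMILARITY.value)
                    )

                host.add(is_seqs[fam.name], annotate_is_free)

    for s in range(config.n_strains):
        b = builders[(s, "chr")]
        for _ in range(config.n_decoy_terminators):
            term = _canonical_terminator(rng)
            strain = b.replicon_id.split("_")[0]

            def annotate_decoy(start, *, _b=b, _s=strain, _n=len(term)):
                manifest.terminators.append(
                    PlantedTerminator(_s, _b.replicon_id, start,
                                      start + _n - TERMINATOR_TAIL, decoy=True)
                )

            b.add(term, annotate_decoy)

    genomes: list[Genome] = []
    topo = Topology.CIRCULAR if config.circular else Topology.LINEAR
    for s, name in enumerate(strain_names):
        reps = [
            Replicon(
                id=f"{name}_chr", genome_id=name, kind=RepliconKind.CHROMOSOME,
                topology=topo, sequence=builders[(s, "chr")].assemble(),
            )
        ]
        for p in range(config.n_plasmids):
            reps.append(
                Replicon(
                    id=f"{name}_p{p+1}", genome_id=name, kind=RepliconKind.PLASMID,
                    topology=topo, sequence=builders[(s, f"p{p+1}")].assemble(),
                )
            )
        genomes.append(Genome(strain=name, genus_complex=config.genus(s), replicons=reps))

    # override rows for island transfers: both directions of each pair
    for t in manifest.mge_transfers:
        a, b = t.strains
        if a in t.positions and b in t.positions:
            overrides.append(
                {"genome": a, "replicon": f"{a}_chr", "position": t.positions[a][0],
                 "subject_genome": b}
            )
            overrides.append(
                {"genome": b, "replicon": f"{b}_chr", "position": t.positions[b][0],
                 "subject_genome": a}
            )

    model_specs = []
    for spec in config.intron_specs:
        entry = {
            "intron": spec.name,
            "scheme": spec.scheme.value,
            "window": list(SITE_WINDOW),
        }
        if spec.scheme is Scheme.FLANK_SIMILARITY:
            entry["context_sequence"] = is_contexts[spec.name]
        else:
            entry["reference_flank"] = contexts[spec.name]
        model_specs.append(entry)

    manifest.planted_copies.sort(key=lambda c: (c.strain, c.replicon_id, c.start))
    manifest.free_sites.sort(key=lambda s: (s.strain, s.replicon_id, s.insertion_point))
    manifest.terminators.sort(key=lambda t: (t.strain, t.replicon_id, t.start))
    return SimPopulation(
        genomes=genomes,
        library=[refs[s.name] for s in config.intron_specs],
        manifest=manifest,
        model_specs=model_specs,
        overrides=overrides,
        site_contexts=contexts,
    )


def config_from_dict(data: dict) -> SimConfig:
    """Build a SimConfig from a plain (e.g. YAML-loaded) dictionary."""
    intron_specs = tuple(
        SyntheticIntronSpec(**{**d, "scheme": Scheme(d["scheme"])} if "scheme" in d else d)
        for d in data.get("intron_specs", [])
    )
    is_specs = tuple(ISFamilySpec(**d) for d in data.get("is_specs", []))
    plans = []
    for d in data.get("plans", []):
        d = dict(d)
        if "orthology_groups" in d:
            d["orthology_groups"] = tuple(tuple(g) for g in d["orthology_groups"])
        plans.append(PlantingPlan(**d))
    fields_ = {
        k: v
        for k, v in data.items()
        if k not in ("intron_specs", "is_specs", "plans", "genus_of_strain")
    }
    genus = data.get("genus_of_strain")
    return SimConfig(
        intron_specs=intron_specs,
        is_specs=is_specs,
        plans=tuple(plans),
        genus_of_strain=tuple(genus) if genus else None,
        **fields_,
    )


def write_population(pop: SimPopulation, outdir: str | Path) -> None:
    """Emit FASTA + manifest + library + models + overrides + truth JSON."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genomes(pop.genomes, outdir / "genomes.fasta", outdir / "genomes.tsv")
    write_library(pop.library, outdir / "library")
    with open(outdir / "models.yaml", "w") as fh:
        yaml.safe_dump(pop.model_specs, fh, sort_keys=False)
    with open(outdir / "overrides.tsv", "w") as fh:
        fh.write("genome\treplicon\tposition\tsubject_genome\n")
        for row in pop.overrides:
            fh.write(
                f"{row['genome']}\t{row['replicon']}\t{row['position']}\t{row['subject_genome']}\n"
            )
    (outdir / "truth.json").write_text(pop.manifest.to_json())
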