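"""Occupancy, abundance and divergence statistics.

Homing-site occupancy for one intron in one genome is
``occupied / (occupied + available)`` expressed as a whole percent with
half-up rounding.  Abundance tables count distinct elements (orthologous
copies collapsed) per genus/complex, with an element counted as
full-length when any member copy is full-length.  Intra-genus diversity is
summarised as the mean pairwise p-distance over third codon positions of
concatenated, aligned MLST housekeeping genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from scipy import stats as sps

from .detection import Completeness, IntronCopy
from .genome_io import Genome
from .orthology import DistinctSet

__all__ = [
    "UNDEFINED",
    "occupancy_proportion",
    "OccupancyRecord",
    "AbundanceRow",
    "genus_abundance_table",
    "abundance_vs_strains_test",
    "DivergenceResult",
    "mlst_third_position_divergence",
]

logger = logging.getLogger(__name__)

UNDEFINED = None  # sentinel for table cells where sites cannot be inferred


def occupancy_proportion(occupied: int, available: int) -> Optional[int]:
    """Integer percent of occupied homing sites, rounded half-up.

    Returns the UNDEFINED sentinel when no sites exist at all.
    """
    if occupied < 0 or available < 0:
        raise ValueError("counts must be non-negative")
    total = occupied + available
    if total == 0:
        return UNDEFINED
    return int((200 * occupied + total) // (2 * total))  # round-half-up


@dataclass(frozen=True)
class OccupancyRecord:
    intron_name: str
    genome: str
    occupied: int
    available: int

    @property
    def proportion_pct(self) -> Optional[int]:
        return occupancy_proportion(self.occupied, self.available)


@dataclass(frozen=True)
class AbundanceRow:
    genus_complex: str
    n_strains: int
    n_copies: int
    n_distinct: int
    n_distinct_full_length: int
    n_distinct_fragments: int

    def __post_init__(self) -> None:
        if self.n_distinct != self.n_distinct_full_length + self.n_distinct_fragments:
            raise ValueError("distinct counts do not sum")


def genus_abundance_table(
    copies: Sequence[IntronCopy],
    distinct_sets: Sequence[DistinctSet],
    genomes: Sequence[Genome],
) -> tuple[list[AbundanceRow], AbundanceRow]:
    """Per-genus abundance rows plus a totals row.

    A distinct element is counted as full-length when *any* member copy is
    full-length, even if it is fragmented in other strains.
    """
    genus_of = {g.strain: g.genus_complex for g in genomes}
    strains_per_genus: dict[str, set[str]] = {}
    for g in genomes:
        strains_per_genus.setdefault(g.genus_complex, set()).add(g.strain)
    completeness = {c.id: c.completeness for c in copies}
    copy_genus = {c.id: genus_of[c.genome] for c in copies}
    rows: dict[str, list[int]] = {
        genus: [len(strains), 0, 0, 0, 0]
        for genus, strains in strains_per_genus.items()
    }
    for c in copies:
        rows[copy_genus[c.id]][1] += 1
    for ds in distinct_sets:
        genus = copy_genus[ds.representative]
        rows[genus][2] += 1
        full = any(
            completeness[m] is Completeness.FULL_LENGTH for m in ds.member_copy_ids
        )
        rows[genus][3 if full else 4] += 1
    out = [
        AbundanceRow(genus, *vals)
        for genus, vals in sorted(rows.items(), key=lambda kv: (-kv[1][2], kv[0]))
    ]
    total = AbundanceRow(
        "TOTAL",
        sum(r.n_strains for r in out),
        sum(r.n_copies for r in out),
        sum(r.n_distinct for r in out),
        sum(r.n_distinct_full_length for r in out),
        sum(r.n_distinct_fragments for r in out),
    )
    return out, total


def abundance_vs_strains_test(
    rows: Sequence[AbundanceRow], use_distinct: bool = False
) -> tuple[float, float]:
    """Chi-square goodness-of-fit of copy counts against strain counts.

    Expected copy numbers are proportional to the number of sequenced
    strains per genus; genera with no strains are dropped with a warning.
    """
    kept = [r for r in rows if r.n_strains > 0 and r.genus_complex != "TOTAL"]
    dropped = [r.genus_complex for r in rows if r.n_strains == 0]
    if dropped:
        logger.warning("dropping genera with zero strains: %s", ", ".join(dropped))
    if len(kept) < 2:
        raise ValueError("need at least two genera with strains")
    observed = [r.n_distinct if use_distinct else r.n_copies for r in kept]
    total_obs = sum(observed)
    total_strains = sum(r.n_strains for r in kept)
    expected = [total_obs * r.n_strains / total_strains for r in kept]
    chi2, p = sps.chisquare(observed, f_exp=expected)
    return float(chi2), float(p)


def read_aligned_fasta(path) -> dict[str, str]:
    """Load an aligned multi-FASTA (e.g. concatenated MLST genes) as
    strain -> sequence, preserving gaps."""
    from Bio import SeqIO

    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


@dataclass(frozen=True)
class DivergenceResult:
    genus_complex: str
    mean_p_distance_pos3: float
    n_genomes_used: int
    excluded: tuple[str, ...] = ()


def mlst_third_position_divergence(
    aligned: Mapping[str, str],
    exclusions: Sequence[str] = (),
    genus_complex: str = "",
) -> DivergenceResult:
    """Mean pairwise p-distance over third codon positions.

    ``aligned`` maps strain name to its concatenated, in-frame aligned MLST
    gene sequence (all the same length, divisible by 3; gaps as ``-``).
    Columns with a gap or ambiguous base in either sequence of a pair are
    skipped (complete pairwise deletion); excluded strains (e.g. outgroups)
    never enter the mean.
    """
    kept = {s: seq.upper() for s, seq in aligned.items() if s not in exclusions}
    if len(kept) < 2:
        raise ValueError("need at least two strains after exclusions")
    lengths = {len(s) for s in kept.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences differ in length")
    (length,) = lengths
    if length % 3:
        raise ValueError("alignment length not divisible by 3")
    third = {s: seq[2::3] for s, seq in kept.items()}
    names = sorted(third)
    dists = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            mism = comp = 0
            for x, y in zip(third[a], third[b]):
                if x in "ACGT" and y in "ACGT":
                    comp += 1
                    if x != y:
                        mism += 1
            if comp:
                dists.append(mism / comp)
    if not dists:
        raise ValueError("no comparable third-position columns")
    return DivergenceResult(
        genus_complex=genus_complex,
        mean_p_distance_pos3=sum(dists) / len(dists),
        n_genomes_used=len(names),
        excluded=tuple(sorted(set(exclusions) & set(aligned))),
    )
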