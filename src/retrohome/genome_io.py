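"""Genome containers, the coordinate model, and FASTA/GFF3 plumbing.

Every interval in the package is 0-based half-open ``[start, end)`` on the
forward strand of its replicon; GFF3 output converts to the standard 1-based
inclusive convention.  Sequences are uppercase DNA over ``{A,C,G,T,N}``:
IUPAC ambiguity codes (and anything else non-ACGT) collapse to ``N`` on
input, and ``N`` never satisfies a consensus match downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "RepliconKind",
    "Topology",
    "Strand",
    "Replicon",
    "Genome",
    "Interval",
    "read_genomes",
    "write_genomes",
    "write_features",
    "read_features",
    "clean_sequence",
    "revcomp",
]

_NON_ACGT = re.compile(r"[^ACGT]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def clean_sequence(seq: str) -> str:
    """Uppercase and collapse every non-ACGT letter to N."""
    return _NON_ACGT.sub("N", seq.upper())


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RepliconKind(str, Enum):
    CHROMOSOME = "chromosome"
    PLASMID = "plasmid"


class Topology(str, Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


class Strand(str, Enum):
    FORWARD = "+"
    REVERSE = "-"


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval on a named replicon."""

    replicon_id: str
    start: int
    end: int
    strand: Strand = Strand.FORWARD

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.replicon_id}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.replicon_id == other.replicon_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.replicon_id == other.replicon_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Replicon:
    id: str
    genome_id: str
    kind: RepliconKind
    topology: Topology
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.id} has empty sequence")
        self.sequence = clean_sequence(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps across the origin when circular.

        ``start`` may be negative and ``end`` may exceed the length for
        circular replicons; linear replicons truncate at their ends.
        """
        n = len(self.sequence)
        if self.topology is Topology.CIRCULAR:
            if end - start > n:
                raise ValueError("window longer than circular replicon")
            return "".join(self.sequence[i % n] for i in range(start, end))
        return self.sequence[max(start, 0) : min(end, n)]


@dataclass
class Genome:
    strain: str
    genus_complex: str
    replicons: list[Replicon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genus_complex:
            raise ValueError("genus_complex must be non-empty")

    def replicon(self, replicon_id: str) -> Replicon:
        for rep in self.replicons:
            if rep.id == replicon_id:
                return rep
        raise KeyError(f"no replicon {replicon_id!r} in genome {self.strain}")

    @property
    def chromosome(self) -> Replicon:
        for rep in self.replicons:
            if rep.kind is RepliconKind.CHROMOSOME:
                return rep
        raise KeyError(f"genome {self.strain} has no chromosome")


def _read_manifest(path: Path) -> dict[str, tuple[str, str, str, str]]:
    rows: dict[str, tuple[str, str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "record_id":  # header
                continue
            if len(fields) != 5:
                raise ValueError(f"manifest row needs 5 columns: {line!r}")
            record_id, strain, genus, kind, topology = fields
            if record_id in rows:
                raise ValueError(f"duplicate manifest record id {record_id!r}")
            rows[record_id] = (strain, genus, kind, topology)
    return rows


def read_genomes(fasta_paths: str | Path | Sequence[str | Path], manifest_path: str | Path) -> list[Genome]:
    """Read multi-FASTA replicons plus a manifest table into Genome objects.

    The manifest is a 5-column TSV (record_id, strain, genus_complex, kind,
    topology).  Every FASTA record must appear in the manifest; duplicate
    record ids are a hard error.
    """
    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    manifest = _read_manifest(Path(manifest_path))
    genomes: dict[str, Genome] = {}
    seen: set[str] = set()
    for fasta in fasta_paths:
        for record in SeqIO.parse(str(fasta), "fasta"):
            if record.id in seen:
                raise ValueError(f"duplicate FASTA record id {record.id!r}")
            seen.add(record.id)
            if record.id not in manifest:
                raise ValueError(f"record {record.id!r} missing from manifest")
            strain, genus, kind, topology = manifest[record.id]
            if strain not in genomes:
                genomes[strain] = Genome(strain=strain, genus_complex=genus)
            genomes[strain].replicons.append(
                Replicon(
                    id=record.id,
                    genome_id=strain,
                    kind=RepliconKind(kind.lower()),
                    topology=Topology(topology.lower()),
                    sequence=str(record.seq),
                )
            )
    return list(genomes.values())


def write_genomes(genomes: Iterable[Genome], fasta_path: str | Path, manifest_path: str | Path) -> None:
    """Emit genomes as one multi-FASTA plus the matching manifest TSV."""
    with open(fasta_path, "w") as fa, open(manifest_path, "w") as mf:
        mf.write("record_id\tstrain\tgenus_complex\tkind\ttopology\n")
        for genome in genomes:
            for rep in genome.replicons:
                fa.write(f">{rep.id}\n")
                for i in range(0, len(rep.sequence), 70):
                    fa.write(rep.sequence[i : i + 70] + "\n")
                mf.write(
                    f"{rep.id}\t{genome.strain}\t{genome.genus_complex}"
                    f"\t{rep.kind.value}\t{rep.topology.value}\n"
                )


def _gff_escape(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_features(copies, sites, path: str | Path, replicon_lengths: dict[str, int] | None = None) -> None:
    """Write detected intron copies and homing-site occurrences as GFF3.

    Internal 0-based half-open intervals become 1-based inclusive rows
    (``start+1, end``).  Copies get type ``group_II_intron``; sites get type
    ``homing_site`` with their AVAILABLE/OCCUPIED state in the attributes.
    """
    rows = []
    for copy in copies:
        iv = copy.interval
        _check_bounds(iv, replicon_lengths)
        attrs = (
            f"ID={_gff_escape(copy.id)};Name={_gff_escape(copy.assigned_name)}"
            f";completeness={copy.completeness.value}"
        )
        rows.append(
            (iv.replicon_id, "retrohome", "group_II_intron", iv.start + 1, iv.end,
             f"{copy.percent_identity:.4f}", iv.strand.value, attrs)
        )
    for site in sites:
        iv = site.interval
        _check_bounds(iv, replicon_lengths)
        attrs = (
            f"Name={_gff_escape(site.model.intron_name)};state={site.state.value}"
            f";scheme={site.model.scheme.value}"
        )
        if site.occupied_by:
            attrs += f";occupied_by={_gff_escape(site.occupied_by)}"
        rows.append(
            (iv.replicon_id, "retrohome", "homing_site", iv.start + 1, iv.end,
             ".", iv.strand.value, attrs)
        )
    rows.sort(key=lambda r: (r[0], r[3], r[4], r[2]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, start, end, score, strand, attrs in rows:
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t{score}\t{strand}\t.\t{attrs}\n"
            )


def _check_bounds(iv: Interval, replicon_lengths: dict[str, int] | None) -> None:
    if replicon_lengths is not None:
        length = replicon_lengths.get(iv.replicon_id)
        if length is not None and iv.end > length:
            raise ValueError(
                f"interval [{iv.start},{iv.end}) exceeds replicon "
                f"{iv.replicon_id} length {length}"
            )


def read_features(path: str | Path) -> list[dict]:
    """Parse a GFF3 file back into plain dicts (0-based half-open coords)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, source, ftype, start, end, score, strand, phase, attrs = (
                line.rstrip("\n").split("\t")
            )
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            out.append(
                {
                    "replicon_id": seqid,
                    "type": ftype,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                    "attributes": attributes,
                }
            )
    return out
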