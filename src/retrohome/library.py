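"""Reference intron library: entries and their on-disk layout.

A library directory holds ``introns.fasta`` (full intron nucleotide
sequences), ``proteins.fasta`` (the encoded IEP of each intron) and
``metadata.tsv`` with one row per intron: name, ribozyme group (IIA/IIB/IIC),
ORF class (A-F, CL1, CL2, ML, C), ORF coordinates within the intron
(0-based half-open), the EBS motifs, and a functional flag.  Class C introns
carry only EBS1 and EBS3 — they recognise targets downstream of
Rho-independent terminators rather than through an EBS2/IBS2 pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .genome_io import clean_sequence

__all__ = ["RibozymeGroup", "OrfClass", "ReferenceIntron", "read_library", "write_library"]


class RibozymeGroup(str, Enum):
    IIA = "IIA"
    IIB = "IIB"
    IIC = "IIC"


class OrfClass(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"
    CL1 = "CL1"
    CL2 = "CL2"
    ML = "ML"


@dataclass
class ReferenceIntron:
    name: str
    ribozyme_group: RibozymeGroup
    orf_class: OrfClass
    sequence: str
    orf_interval: tuple[int, int]
    protein: str = ""
    ebs_motifs: dict[str, str] = field(default_factory=dict)
    functional: bool = True

    def __post_init__(self) -> None:
        self.sequence = clean_sequence(self.sequence)
        start, end = self.orf_interval
        if not (0 <= start < end <= len(self.sequence)):
            raise ValueError(f"ORF interval {self.orf_interval} outside {self.name}")
        if self.orf_class is OrfClass.C:
            extra = set(self.ebs_motifs) - {"EBS1", "EBS3"}
            if extra or set(self.ebs_motifs) != {"EBS1", "EBS3"}:
                raise ValueError(
                    f"class C intron {self.name} must have exactly EBS1 and EBS3"
                )
        if not self.protein:
            orf = self.sequence[start:end]
            self.protein = str(Seq(orf).translate()).rstrip("*")

    @property
    def orf_length(self) -> int:
        return self.orf_interval[1] - self.orf_interval[0]

    def __len__(self) -> int:
        return len(self.sequence)


def write_library(introns: list[ReferenceIntron], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "introns.fasta", "w") as fa:
        for it in introns:
            fa.write(f">{it.name}\n")
            for i in range(0, len(it.sequence), 70):
                fa.write(it.sequence[i : i + 70] + "\n")
    with open(directory / "proteins.fasta", "w") as fa:
        for it in introns:
            fa.write(f">{it.name}\n{it.protein}\n")
    with open(directory / "metadata.tsv", "w") as tsv:
        tsv.write(
            "name\tribozyme_group\torf_class\torf_start\torf_end\tebs1\tebs2\tebs3\tfunctional\n"
        )
        for it in introns:
            tsv.write(
                "\t".join(
                    [
                        it.name,
                        it.ribozyme_group.value,
                        it.orf_class.value,
                        str(it.orf_interval[0]),
                        str(it.orf_interval[1]),
                        it.ebs_motifs.get("EBS1", ""),
                        it.ebs_motifs.get("EBS2", ""),
                        it.ebs_motifs.get("EBS3", ""),
                        "1" if it.functional else "0",
                    ]
                )
                + "\n"
            )


def read_library(directory: str | Path) -> list[ReferenceIntron]:
    directory = Path(directory)
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(directory / "introns.fasta"), "fasta")}
    prot_path = directory / "proteins.fasta"
    prots = (
        {r.id: str(r.seq) for r in SeqIO.parse(str(prot_path), "fasta")}
        if prot_path.exists()
        else {}
    )
    introns: list[ReferenceIntron] = []
    with open(directory / "metadata.tsv") as tsv:
        header = tsv.readline().rstrip("\n").split("\t")
        for line in tsv:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            name = row["name"]
            if name not in seqs:
                raise ValueError(f"metadata row {name!r} has no FASTA sequence")
            ebs = {
                key: clean_sequence(row[col])
                for key, col in (("EBS1", "ebs1"), ("EBS2", "ebs2"), ("EBS3", "ebs3"))
                if row.get(col)
            }
            introns.append(
                ReferenceIntron(
                    name=name,
                    ribozyme_group=RibozymeGroup(row["ribozyme_group"]),
                    orf_class=OrfClass(row["orf_class"]),
                    sequence=seqs[name],
                    orf_interval=(int(row["orf_start"]), int(row["orf_end"])),
                    protein=prots.get(name, ""),
                    ebs_motifs=ebs,
                    functional=row.get("functional", "1") == "1",
                )
            )
    return introns
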