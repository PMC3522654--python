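"""End-to-end survey: detection → orthology → homing sites → report tables.

``survey`` is the in-memory driver used by tests and by the command line;
``run_survey`` wraps it with file input/output, producing the survey's
standard report bundle: a copy table, insertion calls, the per-genus
distinct-element table, occupancy tables for full-length copies and for
fragments, and a GFF3 of copies and sites.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .detection import (
    Completeness,
    DetectionParams,
    IntronCopy,
    detect_introns,
)
from .genome_io import Genome, Replicon, Strand, read_genomes, write_features
from .homing import (
    HomingSiteModel,
    Scheme,
    SiteOccurrence,
    SiteState,
    TerminatorParams,
    build_consensus_from_conservation,
    build_consensus_from_ebs,
    find_rho_independent_terminators,
    mark_occupancy,
    restrict_to_terminator_downstream,
    scan_flank_similarity,
    scan_perfect_match,
)
from .library import ReferenceIntron, read_library
from .orthology import (
    DistinctSet,
    InsertionCall,
    OrthologyParams,
    apply_mge_overrides,
    collapse_distinct,
    orthology_calls,
)
from .stats import (
    AbundanceRow,
    OccupancyRecord,
    genus_abundance_table,
)

logger = logging.getLogger(__name__)

__all__ = ["SurveyResult", "survey", "run_survey", "copy_flank_window"]


@dataclass
class SurveyResult:
    copies: list[IntronCopy]
    calls: list[InsertionCall]
    distinct_sets: list[DistinctSet]
    abundance: list[AbundanceRow]
    abundance_total: AbundanceRow
    occupancy_full_length: list[OccupancyRecord]
    occupancy_fragments: list[OccupancyRecord]
    sites: list[SiteOccurrence] = field(default_factory=list)
    models: dict[str, HomingSiteModel] = field(default_factory=dict)

    def occupancy_pct(self, intron: str, genome: str) -> Optional[int]:
        for rec in self.occupancy_full_length:
            if rec.intron_name == intron and rec.genome == genome:
                return rec.proportion_pct
        return None


def copy_flank_window(
    copy: IntronCopy, replicon: Replicon, window: tuple[int, int] = (-25, 10)
) -> Optional[str]:
    """The insertion-site context around a copy, in intron orientation."""
    from .genome_io import revcomp

    pre, post = -window[0], window[1]
    iv = copy.interval
    if iv.strand is Strand.FORWARD:
        up = replicon.fetch(iv.start - pre, iv.start)
        down = replicon.fetch(iv.end, iv.end + post)
    else:
        up = revcomp(replicon.fetch(iv.end, iv.end + pre))
        down = revcomp(replicon.fetch(iv.start - post, iv.start))
    if len(up) != pre or len(down) != post:
        return None  # replicon edge: no usable window
    return up + down


def _build_models(
    model_specs: Sequence[dict],
    copies: Sequence[IntronCopy],
    genomes: Sequence[Genome],
    library: Sequence[ReferenceIntron],
) -> dict[str, HomingSiteModel]:
    refs = {r.name: r for r in library}
    by_strain = {g.strain: g for g in genomes}
    models: dict[str, HomingSiteModel] = {}
    for spec in model_specs:
        intron = spec["intron"]
        scheme = Scheme(spec["scheme"])
        window = tuple(spec.get("window", (-25, 10)))
        if scheme is Scheme.FLANK_SIMILARITY:
            models[intron] = HomingSiteModel(
                intron_name=intron,
                scheme=scheme,
                context_sequence=spec["context_sequence"],
                window=window,
            )
            continue
        windows = []
        for c in copies:
            if c.reference_name != intron or c.completeness is not Completeness.FULL_LENGTH:
                continue
            rep = by_strain[c.genome].replicon(c.interval.replicon_id)
            w = copy_flank_window(c, rep, window)
            if w is not None:
                windows.append(w)
        if not windows:
            logger.warning("no flank windows for %s; sites cannot be inferred", intron)
            continue
        if scheme is Scheme.CONSERVATION_CONSENSUS:
            if len(windows) < 5:
                logger.warning(
                    "%s: %d windows < 5 needed for a conservation consensus",
                    intron, len(windows),
                )
                continue
            models[intron] = build_consensus_from_conservation(
                windows, window, threshold=spec.get("threshold", 0.8), intron_name=intron
            )
        else:
            ref = refs.get(intron)
            ebs = dict(ref.ebs_motifs) if ref else {}
            models[intron] = build_consensus_from_ebs(
                ebs,
                windows,
                reference_flank=spec.get("reference_flank"),
                window=window,
                scheme=scheme,
                intron_name=intron,
            )
    return models


def _resolve_overrides(
    overrides: Sequence[dict], copies: Sequence[IntronCopy]
) -> list[tuple[str, str]]:
    """Map (genome, replicon, position, subject_genome) rows to copy ids."""
    out = []
    for row in overrides:
        pos = int(row["position"])
        match = None
        for c in copies:
            if (
                c.genome == row["genome"]
                and c.interval.replicon_id == row["replicon"]
                and c.interval.start <= pos < c.interval.end
            ):
                match = c
                break
        if match is None:
            logger.warning("override row matches no detected copy: %s", row)
            continue
        out.append((match.id, row["subject_genome"]))
    return out


def survey(
    genomes: Sequence[Genome],
    library: Sequence[ReferenceIntron],
    model_specs: Sequence[dict] = (),
    overrides: Sequence[dict] = (),
    *,
    detection_params: DetectionParams | None = None,
    orthology_params: OrthologyParams | None = None,
    terminator_params: TerminatorParams | None = None,
    terminator_max_gap: int = 20,
    user_terminators: Sequence | None = None,
) -> SurveyResult:
    """Run the full survey over in-memory genomes."""
    t0 = time.time()
    detection_params = detection_params or DetectionParams()
    orthology_params = orthology_params or OrthologyParams()
    copies = detect_introns(genomes, library, detection_params)
    logger.info("detection: %d copies in %.1fs", len(copies), time.time() - t0)

    calls = orthology_calls(copies, genomes, orthology_params)
    resolved = _resolve_overrides(overrides, copies)
    if resolved:
        calls = apply_mge_overrides(calls, resolved)
    genus_of = {g.strain: g.genus_complex for g in genomes}
    distinct_sets = collapse_distinct(copies, calls, genus_of)
    abundance, total = genus_abundance_table(copies, distinct_sets, genomes)

    models = _build_models(model_specs, copies, genomes, library)
    occupancy_full: list[OccupancyRecord] = []
    occupancy_frag: list[OccupancyRecord] = []
    all_sites: list[SiteOccurrence] = []
    term_cache: dict[str, list] = {}
    for intron, model in sorted(models.items()):
        host_genomes = sorted({c.genome for c in copies if c.reference_name == intron})
        for strain in host_genomes:
            genome = next(g for g in genomes if g.strain == strain)
            genome_copies = [c for c in copies if c.genome == strain]
            intron_copies = [c for c in genome_copies if c.reference_name == intron]
            candidates: list[SiteOccurrence] = []
            for rep in genome.replicons:
                if model.scheme is Scheme.FLANK_SIMILARITY:
                    found = scan_flank_similarity(rep, model)
                else:
                    found = scan_perfect_match(rep, model)
                if model.requires_terminator:
                    if rep.id not in term_cache:
                        term_cache[rep.id] = list(user_terminators or []) + (
                            find_rho_independent_terminators(rep, terminator_params)
                        )
                    found = restrict_to_terminator_downstream(
                        found, term_cache[rep.id], terminator_max_gap
                    )
                candidates.extend(found)
            occurrences = mark_occupancy(candidates, genome_copies, model=model)
            all_sites.extend(occurrences)
            available = sum(1 for s in occurrences if s.state is SiteState.AVAILABLE)
            n_fl = sum(
                1 for c in intron_copies if c.completeness is Completeness.FULL_LENGTH
            )
            n_frag = len(intron_copies) - n_fl
            if n_fl or available:
                occupancy_full.append(
                    OccupancyRecord(intron, strain, occupied=n_fl, available=available)
                )
            if n_frag:
                # sites available at the time of fragment acquisition include
                # those now occupied by full-length copies
                occupancy_frag.append(
                    OccupancyRecord(
                        intron, strain, occupied=n_frag, available=available + n_fl
                    )
                )
    logger.info("survey complete in %.1fs", time.time() - t0)
    return SurveyResult(
        copies=copies,
        calls=calls,
        distinct_sets=distinct_sets,
        abundance=abundance,
        abundance_total=total,
        occupancy_full_length=occupancy_full,
        occupancy_fragments=occupancy_frag,
        sites=all_sites,
        models=models,
    )


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def write_reports(result: SurveyResult, genomes: Sequence[Genome], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(
        outdir / "copies.tsv",
        ["genome", "replicon", "start", "end", "strand", "reference", "name",
         "completeness", "identity", "orf_intact", "container"],
        [
            [c.genome, c.interval.replicon_id, c.interval.start, c.interval.end,
             c.interval.strand.value, c.reference_name, c.assigned_name,
             c.completeness.value, f"{c.percent_identity:.4f}",
             c.orf_intact, c.container.value]
            for c in result.copies
        ],
    )
    _write_tsv(
        outdir / "insertion_calls.tsv",
        ["copy_id", "subject_genome", "classification", "evidence"],
        [
            [c.copy_id, c.subject_genome, c.classification.value, str(c.evidence)]
            for c in result.calls
        ],
    )
    rows = [
        [r.genus_complex, r.n_strains, r.n_copies, r.n_distinct,
         r.n_distinct_full_length, r.n_distinct_fragments]
        for r in result.abundance
    ]
    t = result.abundance_total
    rows.append([t.genus_complex, t.n_strains, t.n_copies, t.n_distinct,
                 t.n_distinct_full_length, t.n_distinct_fragments])
    _write_tsv(
        outdir / "distinct_report.tsv",
        ["genus_complex", "strains", "copies", "distinct", "distinct_full_length",
         "distinct_fragments"],
        rows,
    )
    _write_tsv(
        outdir / "occupancy_full_length.tsv",
        ["intron", "genome", "copies", "available_sites", "proportion_pct"],
        [
            [r.intron_name, r.genome, r.occupied, r.available, r.proportion_pct]
            for r in result.occupancy_full_length
        ],
    )
    _write_tsv(
        outdir / "occupancy_fragments.tsv",
        ["intron", "genome", "fragments", "available_at_acquisition", "proportion_pct"],
        [
            [r.intron_name, r.genome, r.occupied, r.available, r.proportion_pct]
            for r in result.occupancy_fragments
        ],
    )
    # bounds are only checkable on linear replicons: features may legitimately
    # wrap past the origin of circular ones
    from .genome_io import Topology

    lengths = {
        rep.id: len(rep.sequence)
        for g in genomes for rep in g.replicons
        if rep.topology is Topology.LINEAR
    }
    write_features(result.copies, result.sites, outdir / "sites.gff3", lengths)
    import json

    from .homing import SiteState

    summary = {
        "genomes": len(list(genomes)),
        "copies": len(result.copies),
        "full_length_copies": sum(
            c.completeness is Completeness.FULL_LENGTH for c in result.copies
        ),
        "distinct_elements": len(result.distinct_sets),
        "available_sites": sum(
            s.state is SiteState.AVAILABLE for s in result.sites
        ),
        "occupancy_full_length": [
            {"intron": r.intron_name, "genome": r.genome, "occupied": r.occupied,
             "available": r.available, "proportion_pct": r.proportion_pct}
            for r in result.occupancy_full_length
        ],
        "occupancy_fragments": [
            {"intron": r.intron_name, "genome": r.genome, "fragments": r.occupied,
             "available_at_acquisition": r.available,
             "proportion_pct": r.proportion_pct}
            for r in result.occupancy_fragments
        ],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")


def run_survey(
    genomes_fasta: str | Path,
    genomes_manifest: str | Path,
    library_dir: str | Path,
    outdir: str | Path,
    *,
    models_yaml: str | Path | None = None,
    overrides_tsv: str | Path | None = None,
    detection_params: DetectionParams | None = None,
    orthology_params: OrthologyParams | None = None,
) -> SurveyResult:
    """File-based survey entry point; writes the report bundle to ``outdir``."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("retrohome")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        logger.info(
            "run_survey genomes=%s library=%s models=%s overrides=%s",
            genomes_fasta, library_dir, models_yaml, overrides_tsv,
        )
        # full parameter echo so a run can be replayed exactly
        logger.info("detection_params=%s", detection_params or DetectionParams())
        logger.info("orthology_params=%s", orthology_params or OrthologyParams())
        genomes = read_genomes(genomes_fasta, genomes_manifest)
        library = read_library(library_dir)
        model_specs: list[dict] = []
        if models_yaml:
            model_specs = yaml.safe_load(Path(models_yaml).read_text()) or []
        overrides: list[dict] = []
        if overrides_tsv:
            with open(overrides_tsv) as fh:
                header = fh.readline().rstrip("\n").split("\t")
                for line in fh:
                    if line.strip():
                        overrides.append(dict(zip(header, line.rstrip("\n").split("\t"))))
        result = survey(
            genomes, library, model_specs, overrides,
            detection_params=detection_params,
            orthology_params=orthology_params,
        )
        write_reports(result, genomes, outdir)
        return result
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
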