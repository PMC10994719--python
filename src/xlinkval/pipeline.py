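"""End-to-end orchestration: read inputs, analyze, write outputs.

The pipeline chains the stages: cross-link table and FASTA parsing, position
normalization, overlap (OPS) analysis for intra-links, template selection
from the local structure library, distance evaluation over chain
permutations, and final classification. Outputs are the extended results
CSV, a summary (JSON and text), one molecular-viewer script per structure
used, and a diagnostics TSV. Everything is deterministic given the inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .classify import (
    FinalClassification,
    LinkerSpec,
    StructureAnalyzer,
    VALIDATED_CATEGORIES,
    WITHIN_CATEGORIES,
)
from .io import (
    CrossLink,
    CrossLinkIOError,
    Diagnostic,
    RESULT_COLUMNS,
    RunConfig,
    StructureModel,
    format_number,
    read_crosslink_table,
    read_fasta,
    read_structure,
    write_result_table,
)
from .ops import OPSResult, classify_ops
from .seqmap import DEFAULT_SCHEME, normalize_links

STRUCTURE_SUFFIXES = (".pdb", ".ent", ".cif", ".mmcif")


@dataclass
class LinkOutcome:
    """Everything the pipeline decided about one cross-link."""

    link: CrossLink
    ops: Optional[OPSResult]
    classification: FinalClassification

    @property
    def link_type_final(self) -> str:
        if self.classification.category in (
            "ops_inter", "ops_inter_validated", "out_of_range_inter_validated"
        ):
            return "inter"
        return self.link.link_type


@dataclass
class SummaryStats:
    n_links_total: int = 0
    n_intra: int = 0
    n_inter: int = 0
    n_ops: int = 0
    n_self_links: int = 0
    n_mapped: int = 0
    n_within_range: int = 0
    fraction_within_range: Optional[float] = None
    n_reclassified_ops: int = 0
    n_reclassified_out_of_range: int = 0
    n_validated_homo_multimer: int = 0
    n_unmapped: int = 0
    n_proteins: int = 0
    n_proteins_with_ops: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def to_text(self) -> str:
        frac = ("n/a" if self.fraction_within_range is None
                else f"{100 * self.fraction_within_range:.1f}%")
        return "\n".join([
            f"cross-links            {self.n_links_total} "
            f"({self.n_intra} intra, {self.n_inter} inter)",
            f"proteins               {self.n_proteins} "
            f"({self.n_proteins_with_ops} with OPS evidence)",
            f"OPS links              {self.n_ops} "
            f"({self.n_self_links} self-links)",
            f"mapped onto structures {self.n_mapped}",
            f"within linker range    {self.n_within_range} ({frac} of mapped)",
            f"reclassified           {self.n_reclassified_ops} by OPS, "
            f"{self.n_reclassified_out_of_range} out-of-range intra",
            f"validated homo-multimeric inter-links {self.n_validated_homo_multimer}",
            f"unmapped               {self.n_unmapped}",
        ])


def summarize(outcomes: Sequence[LinkOutcome]) -> SummaryStats:
    """Aggregate counts over classified links.

    ``n_mapped`` counts links with at least one structure evaluation;
    ``fraction_within_range`` is over mapped links and ``None`` when nothing
    mapped.
    """
    stats = SummaryStats()
    proteins = set()
    proteins_with_ops = set()
    for out in outcomes:
        link, ops, cls = out.link, out.ops, out.classification
        stats.n_links_total += 1
        proteins.add(link.protein_a)
        proteins.add(link.protein_b)
        if link.link_type == "intra":
            stats.n_intra += 1
        else:
            stats.n_inter += 1
        if ops is not None and ops.is_ops:
            stats.n_ops += 1
            stats.n_reclassified_ops += 1
            proteins_with_ops.add(link.protein_a)
            if ops.self_link:
                stats.n_self_links += 1
        if cls.best_result is not None:
            stats.n_mapped += 1
        if cls.category in WITHIN_CATEGORIES:
            stats.n_within_range += 1
        if cls.category in ("out_of_range_inter_validated", "intra_out_of_range"):
            stats.n_reclassified_out_of_range += 1
        if cls.category in VALIDATED_CATEGORIES:
            stats.n_validated_homo_multimer += 1
        if cls.category == "unmapped":
            stats.n_unmapped += 1
    stats.n_proteins = len(proteins)
    stats.n_proteins_with_ops = len(proteins_with_ops)
    if stats.n_mapped > 0:
        stats.fraction_within_range = stats.n_within_range / stats.n_mapped
    return stats


def load_structure_library(structure_dir) -> List[StructureModel]:
    """Read every PDB/mmCIF file in a directory (sorted for determinism)."""
    if structure_dir is None:
        return []
    structure_dir = Path(structure_dir)
    if not structure_dir.is_dir():
        raise CrossLinkIOError(f"structure library {structure_dir} is not a directory")
    library = []
    for path in sorted(structure_dir.iterdir()):
        if path.suffix.lower() in STRUCTURE_SUFFIXES:
            library.append(read_structure(path))
    return library


def outcome_row(out: LinkOutcome) -> dict:
    """Flatten one outcome into the result-table row schema."""
    link, ops, cls = out.link, out.ops, out.classification
    best = cls.best_result
    row: dict = {"extra": dict(link.extra)}
    row["link_type_original"] = link.link_type
    row["link_type_final"] = out.link_type_final
    row["ops_flag"] = None if ops is None else ops.is_ops
    row["overlap_length"] = None if ops is None else ops.overlap_length
    row["self_link_flag"] = None if ops is None else ops.self_link
    row["structure_id"] = cls.structure_id
    row["chain_pair"] = None if best is None else "-".join(best.chain_pair)
    row["euclidean_distance"] = None if best is None else best.euclidean
    row["topological_distance"] = None if best is None else best.topological
    row["within_range"] = (None if best is None
                           else cls.category in WITHIN_CATEGORIES)
    row["evidence_class"] = cls.category
    return row


WITHIN_COLOR = "green"
OUT_COLOR = "red"


def write_viewer_script(
    structure: StructureModel,
    outcomes: Sequence[LinkOutcome],
    structure_path: str,
    linker: Optional[LinkerSpec] = None,
) -> str:
    """PyMOL script drawing every evaluated assignment on one structure.

    One ``distance`` object per assignment between the two anchor atoms,
    colored by range verdict; self-links are marked with a sphere on the
    residue (the loop of a residue linked to itself has no second endpoint to
    draw).
    """
    if linker is None:
        linker = LinkerSpec()
    name = structure.structure_id
    lines = [
        f"# cross-links mapped onto {name}",
        f"load {structure_path}, {name}",
        f"hide everything, {name}",
        f"show cartoon, {name}",
        f"color grey80, {name}",
    ]
    for out in outcomes:
        if out.classification.structure_id != name:
            continue
        for k, res in enumerate(out.classification.all_results):
            if res.residue_a is None or res.residue_b is None:
                continue
            (na, ica), (nb, icb) = res.residue_a, res.residue_b
            ca, cb = res.chain_pair
            topo = res.topological
            within = (topo is not None
                      and linker.min_distance <= topo <= linker.max_distance)
            color = WITHIN_COLOR if within else OUT_COLOR
            topo_tag = "unreachable" if topo is None else f"{topo:.1f}A"
            obj = f"xl{out.link.row_id}_{k}_{topo_tag.replace('.', 'p')}"
            sel_a = f"{name} and chain {ca} and resi {na}{ica} and name CB+CA"
            sel_b = f"{name} and chain {cb} and resi {nb}{icb} and name CB+CA"
            if (ca, na, ica) == (cb, nb, icb):
                lines.append(f"show spheres, {sel_a}")
                lines.append(f"color {color}, {sel_a}")
                lines.append(f"# link {out.link.row_id}: self-link at "
                             f"chain {ca} residue {na}")
                continue
            lines.append(f"distance {obj}, ({sel_a}), ({sel_b})")
            lines.append(f"color {color}, {obj}")
            lines.append(f"# link {out.link.row_id}: {ca}/{na} - {cb}/{nb}, "
                         f"topological {topo_tag}")
    lines.append("set dash_radius, 0.15")
    lines.append("set dash_gap, 0.3")
    return "\n".join(lines) + "\n"


@dataclass
class PipelineResult:
    outcomes: List[LinkOutcome]
    stats: SummaryStats
    rows: List[dict]
    diagnostics: List[Diagnostic]
    viewer_scripts: Dict[str, str] = field(default_factory=dict)


def run_pipeline(
    config: RunConfig,
    crosslink_csv,
    fasta,
    structure_dir=None,
    linker: Optional[LinkerSpec] = None,
) -> PipelineResult:
    """Execute the full analysis on local files.

    Raises :class:`CrossLinkIOError` on unreadable inputs; malformed rows and
    unmappable links are reported as diagnostics instead of failing the run.
    """
    if linker is None:
        linker = LinkerSpec(min_distance=config.linker_min,
                            max_distance=config.linker_max)
    raws, diagnostics = read_crosslink_table(
        crosslink_csv, config.csv_delimiter, config.column_map
    )
    proteins = read_fasta(fasta)
    links, norm_diags = normalize_links(raws, proteins, DEFAULT_SCHEME)
    diagnostics = list(diagnostics) + list(norm_diags)
    library = load_structure_library(structure_dir)
    analyzer = StructureAnalyzer(proteins, library, config)

    outcomes: List[LinkOutcome] = []
    used_structures: Dict[str, StructureModel] = {}
    for link in links:
        ops = None
        if link.link_type == "intra":
            ops, ops_diags = classify_ops(link, proteins[link.protein_a])
            diagnostics.extend(ops_diags)
        cls = analyzer.full_classify(link, ops, linker)
        outcomes.append(LinkOutcome(link, ops, cls))
        if cls.structure_id is not None:
            for model in library:
                if model.structure_id == cls.structure_id:
                    used_structures[cls.structure_id] = model

    rows = [outcome_row(out) for out in outcomes]
    stats = summarize(outcomes)
    scripts = {
        sid: write_viewer_script(model, outcomes, f"{sid}.pdb", linker)
        for sid, model in sorted(used_structures.items())
    }
    return PipelineResult(outcomes, stats, rows, diagnostics, scripts)


def write_outputs(result: PipelineResult, outdir, delimiter: str = ",") -> dict:
    """Write results CSV, summary JSON/text, viewer scripts, diagnostics TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    csv_path = outdir / "results.csv"
    write_result_table(result.rows, csv_path, delimiter=delimiter)
    paths["results"] = str(csv_path)

    (outdir / "summary.json").write_text(result.stats.to_json() + "\n")
    (outdir / "summary.txt").write_text(result.stats.to_text() + "\n")
    paths["summary"] = str(outdir / "summary.json")

    diag_path = outdir / "diagnostics.tsv"
    with diag_path.open("w") as fh:
        fh.write("row_id\tcode\tmessage\n")
        for d in result.diagnostics:
            fh.write(f"{d.row_id}\t{d.code}\t{d.message}\n")
    paths["diagnostics"] = str(diag_path)

    script_dir = outdir / "viewer"
    script_dir.mkdir(exist_ok=True)
    for sid, text in result.viewer_scripts.items():
        (script_dir / f"{sid}.pml").write_text(text)
    paths["viewer_dir"] = str(script_dir)
    return paths
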