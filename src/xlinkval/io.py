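"""Domain types and file I/O for cross-link tables, sequences, and structures.

Cross-link records enter as CSV rows (one identified peptide pair per row),
protein sequences as FASTA, and structures as PDB or mmCIF coordinate files.
All residue positions are 1-based and, after normalization, expressed in
full-protein (UniProt-style) coordinates.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import gemmi

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: three-letter -> one-letter code for the standard amino acids
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class CrossLinkIOError(Exception):
    """Fatal error while reading or writing cross-link data files."""


@dataclass(frozen=True)
class Diagnostic:
    """A per-row (or per-link) problem report that does not abort the run."""

    row_id: int
    code: str
    message: str


@dataclass(frozen=True)
class ProteinRecord:
    """A full-length protein sequence keyed by its accession."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession!r}")
        if not self.sequence.isupper():
            raise ValueError(f"sequence for {self.accession!r} must be uppercase")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RawCrossLink:
    """One cross-link row as read from the input table, prior to normalization.

    Each side carries the peptide sequence plus the link-site position given
    within the peptide and/or within the full protein; at least one of the two
    must be present per side.
    """

    row_id: int
    protein_a: str
    protein_b: str
    peptide_a: str
    peptide_b: str
    pos_in_peptide_a: Optional[int] = None
    pos_in_peptide_b: Optional[int] = None
    pos_in_protein_a: Optional[int] = None
    pos_in_protein_b: Optional[int] = None
    source_tag: str = ""
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for side, pep, ppep, pprot in (
            ("a", self.peptide_a, self.pos_in_peptide_a, self.pos_in_protein_a),
            ("b", self.peptide_b, self.pos_in_peptide_b, self.pos_in_protein_b),
        ):
            if not pep:
                raise ValueError(f"row {self.row_id}: empty peptide on side {side}")
            if ppep is None and pprot is None:
                raise ValueError(
                    f"row {self.row_id}: side {side} has neither a peptide "
                    f"nor a protein position"
                )
            if ppep is not None and not (1 <= ppep <= len(pep)):
                raise ValueError(
                    f"row {self.row_id}: position {ppep} outside peptide "
                    f"of length {len(pep)} on side {side}"
                )


@dataclass(frozen=True)
class CrossLink:
    """A normalized cross-link: both link sites resolved to protein positions."""

    row_id: int
    protein_a: str
    protein_b: str
    peptide_a: str
    peptide_b: str
    pos_in_protein_a: int
    pos_in_protein_b: int
    pos_in_peptide_a: Optional[int] = None
    pos_in_peptide_b: Optional[int] = None
    source_tag: str = ""
    multiplicity: int = 1
    extra: Mapping[str, str] = field(default_factory=dict)

    @property
    def link_type(self) -> str:
        """``intra`` when both peptides stem from the same protein, else ``inter``."""
        return "intra" if self.protein_a == self.protein_b else "inter"

    @property
    def unique_key(self) -> tuple:
        """Canonical unordered identity: invariant under swapping the two sides."""
        sides = sorted(
            [(self.protein_a, self.pos_in_protein_a),
             (self.protein_b, self.pos_in_protein_b)]
        )
        return (sides[0][0], sides[0][1], sides[1][0], sides[1][1])


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    bfactor: float = 0.0

    @property
    def pos(self) -> tuple:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class Residue:
    auth_number: int
    insertion_code: str
    name: str
    atoms: tuple = ()

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    """An ordered list of polymer residues under one author chain identifier."""

    chain_id: str
    residues: list

    def __post_init__(self) -> None:
        keys = [(r.auth_number, r.insertion_code) for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"chain {self.chain_id}: duplicate residue numbers")

    def residue(self, auth_number: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.auth_number == auth_number and r.insertion_code == insertion_code:
                return r
        return None


@dataclass
class StructureModel:
    """One coordinate model: polymer chains plus retained heteroatoms.

    ``source`` distinguishes experimental structures (resolution in Å when the
    header provides one) from predicted models, whose B-factor column carries
    per-residue pLDDT confidence values in [0, 100].
    """

    structure_id: str
    source: str  # "experimental" | "predicted"
    resolution: Optional[float]
    chains: list
    het_atoms: tuple = ()

    def __post_init__(self) -> None:
        if self.source not in ("experimental", "predicted"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "predicted":
            for ch in self.chains:
                for res in ch.residues:
                    for a in res.atoms:
                        if not (0.0 <= a.bfactor <= 100.0):
                            raise ValueError(
                                f"{self.structure_id}: pLDDT {a.bfactor} outside "
                                f"[0, 100] at {ch.chain_id}/{res.auth_number}"
                            )

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in {self.structure_id}")


@dataclass
class RunConfig:
    """Tunable thresholds of the whole pipeline.

    Defaults: 90% sequence identity and 50% alignment coverage for accepting a
    chain as a template, 4 Å resolution cutoff for experimental structures,
    pLDDT >= 70 for residues of predicted models, and an accepted linker span
    of 5-35 Å of topological distance.
    """

    identity_cutoff: float = 0.90
    coverage_cutoff: float = 0.50
    resolution_cutoff: float = 4.0
    plddt_cutoff: float = 70.0
    linker_min: float = 5.0
    linker_max: float = 35.0
    grid_spacing: float = 1.0
    probe_radius: float = 1.4
    clearance_radius: float = 4.0
    grid_padding: Optional[float] = None  # defaults to linker_max
    distance_cap: Optional[float] = None  # defaults to 2 * linker_max
    anchor_mode: str = "cb"  # "cb" (beta-carbon, alpha for glycine) or "ca"
    candidate_depth: int = 1
    mse_as_met: bool = True
    csv_delimiter: str = ","
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    offline_mode: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.identity_cutoff <= 1):
            raise ValueError("identity_cutoff must be in (0, 1]")
        if not (0 < self.coverage_cutoff <= 1):
            raise ValueError("coverage_cutoff must be in (0, 1]")
        if not (0 <= self.linker_min < self.linker_max):
            raise ValueError("need 0 <= linker_min < linker_max")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.anchor_mode not in ("cb", "ca"):
            raise ValueError("anchor_mode must be 'cb' or 'ca'")

    @property
    def effective_padding(self) -> float:
        return self.linker_max if self.grid_padding is None else self.grid_padding

    @property
    def effective_cap(self) -> float:
        return 2 * self.linker_max if self.distance_cap is None else self.distance_cap


#: default input-table schema; remap via RunConfig.column_map for other layouts
DEFAULT_COLUMN_MAP = {
    "protein_a": "protein1",
    "protein_b": "protein2",
    "peptide_a": "peptide1",
    "peptide_b": "peptide2",
    "pos_in_peptide_a": "pos_pep1",
    "pos_in_peptide_b": "pos_pep2",
    "pos_in_protein_a": "pos_prot1",
    "pos_in_protein_b": "pos_prot2",
}

_MOD_ANNOTATION = re.compile(r"\[[^\]]*\]|\([^)]*\)|\{[^}]*\}")

#: appended output columns, in order
RESULT_COLUMNS = (
    "link_type_original",
    "link_type_final",
    "ops_flag",
    "overlap_length",
    "self_link_flag",
    "structure_id",
    "chain_pair",
    "euclidean_distance",
    "topological_distance",
    "within_range",
    "evidence_class",
)


def clean_peptide(raw: str) -> str:
    """Strip modification annotations, keeping only upper-case residue letters.

    Bracketed mass/modification tags (``[...]``, ``(...)``, ``{...}``) and
    lowercase annotation characters are removed: ``"KM(ox)LR"`` -> ``"KMLR"``.
    """
    s = _MOD_ANNOTATION.sub("", raw)
    return "".join(c for c in s if c.isalpha() and c.isupper())


def _parse_pos(value: str) -> Optional[int]:
    value = (value or "").strip()
    if value in ("", "NA", "nan", "None", "-"):
        return None
    return int(float(value))


def read_crosslink_table(path, delimiter: str = ",", column_map: Optional[Mapping[str, str]] = None):
    """Read a cross-link CSV into :class:`RawCrossLink` records.

    Returns ``(records, diagnostics)``. Malformed rows (missing positions on a
    side, non-standard residue letters after annotation stripping, unparsable
    numbers) yield one diagnostic each instead of aborting; every data row is
    accounted for either as a record or as a diagnostic.

    Raises :class:`CrossLinkIOError` when the file is unreadable or a required
    column is missing (the message lists the columns that were found).
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    path = Path(path)
    try:
        handle = path.open(newline="")
    except OSError as exc:
        raise CrossLinkIOError(f"cannot read {path}: {exc}") from exc

    records: list = []
    diagnostics: list = []
    with handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        if reader.fieldnames is None:
            raise CrossLinkIOError(f"{path}: empty file, no header row")
        found = set(reader.fieldnames)
        required = [colmap["protein_a"], colmap["protein_b"],
                    colmap["peptide_a"], colmap["peptide_b"]]
        missing = [c for c in required if c not in found]
        if missing:
            raise CrossLinkIOError(
                f"{path}: missing required columns {missing}; "
                f"found columns {sorted(found)}"
            )

        for row_id, row in enumerate(reader, start=1):
            try:
                record = _row_to_raw(row_id, row, colmap)
            except (ValueError, KeyError) as exc:
                diagnostics.append(Diagnostic(row_id, "bad_row", str(exc)))
                continue
            records.append(record)
    return records, diagnostics


def _row_to_raw(row_id: int, row: Mapping[str, str], colmap: Mapping[str, str]) -> RawCrossLink:
    def get(key: str) -> str:
        col = colmap[key]
        return (row.get(col) or "").strip()

    peptides = {}
    for side in ("a", "b"):
        pep = clean_peptide(get(f"peptide_{side}"))
        bad = set(pep) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"row {row_id}: non-standard residue letters {sorted(bad)} "
                f"in peptide on side {side}"
            )
        peptides[side] = pep

    return RawCrossLink(
        row_id=row_id,
        protein_a=get("protein_a"),
        protein_b=get("protein_b"),
        peptide_a=peptides["a"],
        peptide_b=peptides["b"],
        pos_in_peptide_a=_parse_pos(get("pos_in_peptide_a")) if colmap["pos_in_peptide_a"] in row else None,
        pos_in_peptide_b=_parse_pos(get("pos_in_peptide_b")) if colmap["pos_in_peptide_b"] in row else None,
        pos_in_protein_a=_parse_pos(get("pos_in_protein_a")) if colmap["pos_in_protein_a"] in row else None,
        pos_in_protein_b=_parse_pos(get("pos_in_protein_b")) if colmap["pos_in_protein_b"] in row else None,
        extra={k: (v if v is not None else "") for k, v in row.items()},
    )


def parse_fasta_accession(header: str) -> str:
    """Accession from a FASTA header: UniProt pipe convention or bare first token."""
    token = header.split()[0]
    if "|" in token:
        parts = token.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return token


def read_fasta(path) -> dict:
    """Read a FASTA file into ``{accession: ProteinRecord}``.

    Duplicate headers with identical sequences collapse silently; a duplicate
    accession with a conflicting sequence is fatal.
    """
    from Bio import SeqIO

    path = Path(path)
    records: dict = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except OSError as exc:
        raise CrossLinkIOError(f"cannot read {path}: {exc}") from exc
    for rec in parsed:
        accession = parse_fasta_accession(rec.description or rec.id)
        seq = str(rec.seq).upper()
        if accession in records and records[accession].sequence != seq:
            raise CrossLinkIOError(
                f"{path}: accession {accession!r} appears twice with "
                f"conflicting sequences"
            )
        records[accession] = ProteinRecord(accession, seq)
    if not records:
        raise CrossLinkIOError(f"{path}: no FASTA records found")
    return records


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def _is_amino_acid(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def read_structure(path, source: Optional[str] = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of multi-model files is used. Waters are dropped;
    non-water heteroatoms are kept aside for volume occupancy. Alternate
    locations resolve to the highest-occupancy (then first-seen) conformer.

    When ``source`` is not given it is inferred: files carrying a resolution
    in their header are experimental, files without one are treated as
    predicted models with pLDDT in the B-factor column.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise CrossLinkIOError(f"cannot parse structure {path}: {exc}") from exc
    if len(st) == 0:
        raise CrossLinkIOError(f"{path}: no coordinate models")
    model = st[0]

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    if resolution is None and path.suffix.lower() in (".cif", ".mmcif"):
        resolution = _cif_resolution(path)
    if source is None:
        source = "experimental" if resolution is not None else "predicted"

    chains: list = []
    het_atoms: list = []
    for gchain in model:
        residues: list = []
        for gres in gchain:
            if gres.name in _WATER_NAMES or gres.is_water():
                continue
            atoms = _dedupe_altlocs(gres)
            if not atoms:
                continue
            if _is_amino_acid(gres.name):
                residues.append(
                    Residue(
                        auth_number=gres.seqid.num,
                        insertion_code=(gres.seqid.icode or "").strip(),
                        name=gres.name,
                        atoms=tuple(atoms),
                    )
                )
            else:
                het_atoms.extend(atoms)
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    if not chains:
        raise CrossLinkIOError(f"{path}: no protein chains found")
    for ch in chains:
        for res in ch.residues:
            for a in res.atoms:
                if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                    raise CrossLinkIOError(
                        f"{path}: non-finite coordinates at "
                        f"{ch.chain_id}/{res.auth_number}/{a.name}"
                    )
    return StructureModel(
        structure_id=path.stem,
        source=source,
        resolution=resolution,
        chains=chains,
        het_atoms=tuple(het_atoms),
    )


def _cif_resolution(path) -> Optional[float]:
    """Resolution from mmCIF refinement/reflection categories, if present."""
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except (RuntimeError, ValueError):
        return None
    for tag in ("_refine.ls_d_res_high", "_reflns.d_resolution_high"):
        value = block.find_value(tag)
        if value is None:
            for row in block.find([tag]):
                value = row[0]
                break
        if value and value not in (".", "?"):
            try:
                return float(value)
            except ValueError:
                continue
    return None


def _dedupe_altlocs(gres) -> list:
    by_name: dict = {}
    for atom in gres:
        prev = by_name.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            by_name[atom.name] = atom
    out = []
    for atom in gres:  # preserve file order
        chosen = by_name.get(atom.name)
        if chosen is atom:
            out.append(
                Atom(
                    name=atom.name,
                    element=atom.element.name.upper(),
                    x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                    bfactor=atom.b_iso,
                )
            )
    return out


def format_number(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        return f"{value:.2f}"
    return str(value)


def write_result_table(rows: Sequence[Mapping[str, object]], path, delimiter: str = ",") -> None:
    """Write the extended results CSV.

    Every original input column is preserved; the analysis columns in
    :data:`RESULT_COLUMNS` are appended. Missing values are written as
    ``"NA"``. The output is plain strings, so write -> read -> write is
    byte-identical.
    """
    input_cols: list = []
    for row in rows:
        for col in row.get("extra", {}):
            if col not in input_cols:
                input_cols.append(col)
    fieldnames = input_cols + list(RESULT_COLUMNS)
    path = Path(path)
    try:
        handle = path.open("w", newline="")
    except OSError as exc:
        raise CrossLinkIOError(f"cannot write {path}: {exc}") from exc
    with handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(fieldnames)
        for row in rows:
            extra = row.get("extra", {})
            values = [str(extra.get(c, "NA")) for c in input_cols]
            values += [format_number(row.get(c)) for c in RESULT_COLUMNS]
            writer.writerow(values)
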