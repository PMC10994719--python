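"""Synthetic structures and cross-link tables with known ground truth.

Every scenario builds idealized helical coordinates whose inter-residue
geometry is known in closed form, plus the FASTA and cross-link CSV that a
real run would consume, and records the expected analysis outcome per link.
This makes the entire pipeline testable offline: no downloaded structures or
sequences are involved, and regeneration from the same seed is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

from .io import (
    Atom,
    Chain,
    ProteinRecord,
    RawCrossLink,
    Residue,
    StructureModel,
    THREE_TO_ONE,
)

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# ideal alpha-helix parameters: 1.5 A rise and 100 degrees twist per residue
# on a 2.3 A C-alpha radius give the canonical ~3.8 A CA(i)-CA(i+1) spacing
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3


@dataclass
class FixtureScenario:
    """A self-contained test case: inputs plus expected outcomes.

    ``truth`` maps link row ids to the expected final category and, where
    applicable, the expected OPS call (``is_ops``, ``overlap_length``,
    ``self_link``) and range verdict.
    """

    name: str
    seed: int
    proteins: Dict[str, ProteinRecord]
    structures: List[StructureModel]
    links: List[RawCrossLink]
    truth: Dict[int, dict]
    notes: str = ""

    def write(self, outdir) -> dict:
        """Emit FASTA, cross-link CSV, PDB files, and a JSON manifest.

        Returns a manifest dict with the paths written.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "proteins.fasta"
        with fasta.open("w") as fh:
            for rec in self.proteins.values():
                fh.write(f">{rec.accession}\n{rec.sequence}\n")

        csv_path = outdir / "links.csv"
        with csv_path.open("w") as fh:
            fh.write("protein1,protein2,peptide1,peptide2,"
                     "pos_pep1,pos_pep2,pos_prot1,pos_prot2\n")
            for link in self.links:
                def fmt(v):
                    return "" if v is None else str(v)
                fh.write(
                    f"{link.protein_a},{link.protein_b},"
                    f"{link.peptide_a},{link.peptide_b},"
                    f"{fmt(link.pos_in_peptide_a)},{fmt(link.pos_in_peptide_b)},"
                    f"{fmt(link.pos_in_protein_a)},{fmt(link.pos_in_protein_b)}\n"
                )

        struct_dir = outdir / "structures"
        struct_dir.mkdir(exist_ok=True)
        struct_paths = []
        for model in self.structures:
            p = struct_dir / f"{model.structure_id}.pdb"
            write_structure_pdb(model, p)
            struct_paths.append(str(p))

        common = {
            "name": self.name,
            "seed": self.seed,
            "truth": {str(k): v for k, v in self.truth.items()},
            "notes": self.notes,
        }
        # the stored manifest uses paths relative to its own directory, so a
        # regenerated scenario is byte-identical regardless of where it lands
        stored = dict(common)
        stored.update({
            "fasta": fasta.name,
            "crosslinks": csv_path.name,
            "structure_dir": struct_dir.name,
            "structures": [str(Path(p).relative_to(outdir)) for p in struct_paths],
        })
        (outdir / "manifest.json").write_text(
            json.dumps(stored, indent=2, sort_keys=True) + "\n"
        )
        manifest = dict(common)
        manifest.update({
            "fasta": str(fasta),
            "crosslinks": str(csv_path),
            "structure_dir": str(struct_dir),
            "structures": struct_paths,
        })
        return manifest


def to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.structure_id
    if model.resolution is not None:
        st.resolution = model.resolution
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.auth_number, res.insertion_code or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(a.x, a.y, a.z)
                ga.b_iso = a.bfactor
                ga.occ = 1.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_structure_pdb(model: StructureModel, path) -> None:
    to_gemmi(model).write_pdb(str(path))


def write_structure_cif(model: StructureModel, path) -> None:
    st = to_gemmi(model)
    doc = st.make_mmcif_document()
    if model.resolution is not None:
        doc.sole_block().set_pair("_refine.ls_d_res_high", f"{model.resolution:.2f}")
    doc.write_file(str(path))


def random_sequence(rng: np.random.Generator, length: int, unique_window: int = 9) -> str:
    """Random protein sequence whose ``unique_window``-mers are all distinct.

    Distinct windows guarantee that every peptide cut from the sequence has a
    single optimal placement, so fixture link positions are unambiguous.
    """
    for _ in range(1000):
        seq = "".join(rng.choice(list(ALPHABET), size=length))
        windows = [seq[i:i + unique_window] for i in range(length - unique_window + 1)]
        if len(windows) == len(set(windows)):
            return seq
    raise RuntimeError("could not draw a sequence with unique windows")


def make_helix_chain(
    n_residues: int,
    sequence: str,
    chain_id: str = "A",
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    reverse: bool = False,
    rise: float = HELIX_RISE,
    twist_deg: float = HELIX_TWIST_DEG,
    radius: float = HELIX_RADIUS,
    bfactor: float = 20.0,
    bfactors: Optional[Sequence[float]] = None,
) -> Chain:
    """Ideal helix backbone (N, CA, C, O and CB except glycine).

    The helix axis runs along +z from ``origin`` (or -z when ``reverse``), so
    CA(i) sits at height ``rise * i`` with azimuth ``twist_deg * i``; the
    beta-carbon points radially outward. Consecutive CA atoms are
    ``sqrt((2 r sin(twist/2))^2 + rise^2)`` apart (~3.83 Å with defaults).
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if len(sequence) < n_residues:
        raise ValueError("sequence shorter than n_residues")
    origin = np.asarray(origin, dtype=float)
    axis = np.array([0.0, 0.0, -1.0 if reverse else 1.0])
    residues = []
    twist = math.radians(twist_deg)
    for i in range(n_residues):
        theta = twist * i
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        ca = origin + axis * rise * i + radius * radial
        tangent_theta = twist * (i + 0.5)
        tangent = (axis * rise + radius * twist *
                   np.array([-math.sin(tangent_theta), math.cos(tangent_theta), 0.0]))
        tangent = tangent / np.linalg.norm(tangent)
        n_pos = ca - 1.46 * tangent
        c_pos = ca + 1.52 * tangent
        o_pos = c_pos + 1.23 * radial
        one = sequence[i]
        resname = ONE_TO_THREE[one]
        b = float(bfactors[i]) if bfactors is not None else bfactor
        atoms = [
            Atom("N", "N", *n_pos, b),
            Atom("CA", "C", *ca, b),
            Atom("C", "C", *c_pos, b),
            Atom("O", "O", *o_pos, b),
        ]
        if one != "G":
            cb = ca + 1.53 * radial
            atoms.append(Atom("CB", "C", *cb, b))
        residues.append(
            Residue(auth_number=i + 1, insertion_code="", name=resname, atoms=tuple(atoms))
        )
    return Chain(chain_id=chain_id, residues=residues)


def _peptide_around(seq: str, pos: int, half: int = 4) -> Tuple[str, int]:
    """9-residue peptide window centered (as possible) on a 1-based position."""
    start = max(1, min(pos - half, len(seq) - 2 * half))
    end = start + 2 * half
    return seq[start - 1:end], pos - start + 1


def _raw_link(row_id: int, acc: str, seq: str, pos_a: int, pos_b: int,
              with_protein_pos: bool = False) -> RawCrossLink:
    pep_a, ppa = _peptide_around(seq, pos_a)
    pep_b, ppb = _peptide_around(seq, pos_b)
    return RawCrossLink(
        row_id=row_id,
        protein_a=acc, protein_b=acc,
        peptide_a=pep_a, peptide_b=pep_b,
        pos_in_peptide_a=ppa, pos_in_peptide_b=ppb,
        pos_in_protein_a=pos_a if with_protein_pos else None,
        pos_in_protein_b=pos_b if with_protein_pos else None,
    )


def make_homodimer_scenario(seed: int = 0, monomer_only: bool = False) -> FixtureScenario:
    """Antiparallel homodimer with one in-range and one remappable link.

    The two 60-residue helices run antiparallel 14 Å apart, so residue i of
    chain A sits next to residue 60-i of chain B. Link 1 (sites 10-20) spans
    ~15 Å within one chain and stays intra. Link 2 (sites 5-56) spans ~77 Å
    within one chain — beyond any linker — but only ~14 Å across the dimer
    interface, so it is validated as a homo-multimeric inter-link. With
    ``monomer_only`` the deposited structure contains chain A alone and link 2
    ends as an out-of-range intra-link.
    """
    rng = np.random.default_rng(seed)
    n = 60
    seq = random_sequence(rng, n)
    acc = "DIMER1"
    protein = ProteinRecord(acc, seq)

    chain_a = make_helix_chain(n, seq, "A")
    chains = [chain_a]
    if not monomer_only:
        chain_b = make_helix_chain(
            n, seq, "B",
            origin=(14.0, 0.0, (n - 1) * HELIX_RISE),
            reverse=True,
        )
        chains.append(chain_b)
    structure = StructureModel(
        structure_id="dimr1" if not monomer_only else "mono1",
        source="experimental",
        resolution=2.0,
        chains=chains,
    )

    link1 = _raw_link(1, acc, seq, 10, 20, with_protein_pos=True)
    link2 = _raw_link(2, acc, seq, 5, 56)
    truth = {
        1: {"category": "intra_within_range", "is_ops": False,
            "self_link": False, "within_range": True},
        2: {"category": ("intra_out_of_range" if monomer_only
                         else "out_of_range_inter_validated"),
            "is_ops": False, "self_link": False,
            "within_range": not monomer_only},
    }
    return FixtureScenario(
        name="homodimer" + ("_monomer_only" if monomer_only else ""),
        seed=seed,
        proteins={acc: protein},
        structures=[structure],
        links=[link1, link2],
        truth=truth,
        notes="antiparallel two-helix homodimer; link 2 only fits across the interface",
    )


def make_ops_scenario(seed: int = 0) -> FixtureScenario:
    """Intra-links whose peptides overlap by 0, 1, 5, or 10 residues, plus a
    self-link; no structures, so OPS calls are the whole story."""
    rng = np.random.default_rng(seed)
    acc = "OPSP1"
    seq = random_sequence(rng, 80, unique_window=10)
    protein = ProteinRecord(acc, seq)

    def link(row_id, start_a, start_b, site_a, site_b):
        pep_a = seq[start_a - 1:start_a + 9]
        pep_b = seq[start_b - 1:start_b + 9]
        return RawCrossLink(
            row_id=row_id,
            protein_a=acc, protein_b=acc,
            peptide_a=pep_a, peptide_b=pep_b,
            pos_in_peptide_a=site_a - start_a + 1,
            pos_in_peptide_b=site_b - start_b + 1,
        )

    links = [
        link(1, 1, 21, 5, 25),    # disjoint peptides: no overlap
        link(2, 11, 20, 15, 25),  # peptides [11,20] and [20,29]: 1 shared residue
        link(3, 31, 36, 35, 40),  # [31,40] and [36,45]: 5 shared residues
        link(4, 51, 51, 55, 58),  # identical peptides: full overlap
        link(5, 61, 65, 66, 66),  # same residue linked to itself
    ]
    truth = {
        1: {"category": "unmapped", "is_ops": False, "overlap_length": 0,
            "self_link": False},
        2: {"category": "ops_inter", "is_ops": True, "overlap_length": 1,
            "self_link": False},
        3: {"category": "ops_inter", "is_ops": True, "overlap_length": 5,
            "self_link": False},
        4: {"category": "ops_inter", "is_ops": True, "overlap_length": 10,
            "self_link": False},
        5: {"category": "ops_inter", "is_ops": True, "overlap_length": 6,
            "self_link": True},
    }
    return FixtureScenario(
        name="ops",
        seed=seed,
        proteins={acc: protein},
        structures=[],
        links=links,
        truth=truth,
        notes="overlap ladder 0/1/5/10 plus a self-link; no structure library",
    )


def make_predicted_model_scenario(seed: int = 0) -> FixtureScenario:
    """Single-chain predicted model with a low-confidence N-terminal segment.

    Residues 1-15 carry pLDDT 55 and are trimmed at the default cutoff of 70,
    so a link anchored there becomes unmappable, while a link in the
    confident region is evaluated normally.
    """
    rng = np.random.default_rng(seed)
    acc = "PRED1"
    n = 50
    seq = random_sequence(rng, n)
    protein = ProteinRecord(acc, seq)
    plddt = [55.0] * 15 + [90.0] * (n - 15)
    chain = make_helix_chain(n, seq, "A", bfactors=plddt)
    model = StructureModel(
        structure_id="model1",
        source="predicted",
        resolution=None,
        chains=[chain],
    )
    links = [
        _raw_link(1, acc, seq, 5, 25),   # first site in the trimmed segment
        _raw_link(2, acc, seq, 20, 30),  # both sites confident
    ]
    truth = {
        1: {"category": "unmapped", "is_ops": False, "self_link": False,
            "trimmed_residues": 15},
        2: {"category": "intra_within_range", "is_ops": False,
            "self_link": False, "within_range": True},
    }
    return FixtureScenario(
        name="predicted_model",
        seed=seed,
        proteins={acc: protein},
        structures=[model],
        links=links,
        truth=truth,
        notes="pLDDT 55 on residues 1-15, 90 elsewhere; default cutoff 70",
    )


SCENARIOS = {
    "homodimer": make_homodimer_scenario,
    "ops": make_ops_scenario,
    "predicted_model": make_predicted_model_scenario,
}
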