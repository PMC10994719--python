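"""Template selection: match proteins to chains of a local structure library.

Each protein sequence is locally aligned against every chain of every library
structure. Chains passing the identity / coverage / resolution cutoffs yield
a residue-level map from protein positions to author residue numbers, which
the distance engine later uses to place link sites on the structure.

Predicted models (pLDDT in the B-factor column) are a fallback used only when
no experimental structure passes, and are trimmed to confident residues
first; their missing resolution is exempt from the resolution cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .io import Chain, ProteinRecord, Residue, StructureModel, THREE_TO_ONE
from .seqmap import DEFAULT_SCHEME, ScoringScheme, smith_waterman

ResidueKey = Tuple[int, str]  # (auth_number, insertion_code)


@dataclass(frozen=True)
class ChainMap:
    """Alignment of one protein onto one structure chain.

    ``residue_map`` sends 1-based protein positions to author residue numbers
    for every aligned column; it is injective because alignment columns are
    strictly increasing in both sequences.
    """

    structure_id: str
    chain_id: str
    identity: float
    coverage: float
    residue_map: Dict[int, ResidueKey] = field(default_factory=dict, hash=False, compare=False)


@dataclass
class CandidateStructure:
    """A structure whose chains pass the cutoffs for the queried protein(s)."""

    structure: StructureModel
    chain_maps: Dict[str, List[ChainMap]]  # accession -> passing chain maps

    @property
    def rank_key(self) -> tuple:
        best_identity = max(cm.identity for maps in self.chain_maps.values() for cm in maps)
        best_coverage = max(cm.coverage for maps in self.chain_maps.values() for cm in maps)
        res = self.structure.resolution
        return (
            -best_identity,
            -best_coverage,
            res if res is not None else math.inf,
            self.structure.structure_id,
        )


def chain_sequence(structure: StructureModel, chain: Chain, mse_as_met: bool = True):
    """One-letter sequence over the observed residues of a chain.

    Returns ``(sequence, ordinal_to_residue)`` where ordinal ``k`` (1-based)
    indexes the k-th observed residue. Gaps in author numbering do not insert
    gap characters. Non-standard residues become ``X`` (selenomethionine
    becomes ``M`` by default).
    """
    if not chain.residues:
        raise ValueError(f"chain {chain.chain_id} has no residues")
    letters = []
    ordinal_map: Dict[int, ResidueKey] = {}
    for k, res in enumerate(chain.residues, start=1):
        one = THREE_TO_ONE.get(res.name)
        if one is None:
            one = "M" if (mse_as_met and res.name == "MSE") else "X"
        letters.append(one)
        ordinal_map[k] = (res.auth_number, res.insertion_code)
    return "".join(letters), ordinal_map


def score_chain(
    protein: ProteinRecord,
    structure: StructureModel,
    chain: Chain,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    mse_as_met: bool = True,
) -> ChainMap:
    """Align a protein sequence to a chain and build its residue map.

    Identity is measured over alignment columns; coverage is the fraction of
    the *full* protein length that is aligned.
    """
    seq, ordinal_map = chain_sequence(structure, chain, mse_as_met=mse_as_met)
    aln = smith_waterman(protein.sequence, seq, scheme)
    if aln.is_empty:
        return ChainMap(structure.structure_id, chain.chain_id, 0.0, 0.0, {})
    residue_map = {qp: ordinal_map[tp] for qp, tp in aln.aligned_pairs}
    coverage = len(aln.aligned_pairs) / len(protein)
    return ChainMap(
        structure_id=structure.structure_id,
        chain_id=chain.chain_id,
        identity=aln.identity,
        coverage=coverage,
        residue_map=residue_map,
    )


def _passing_chain_maps(protein, structure, config, scheme) -> List[ChainMap]:
    out = []
    for chain in structure.chains:
        cm = score_chain(protein, structure, chain, scheme, mse_as_met=config.mse_as_met)
        if cm.identity >= config.identity_cutoff and cm.coverage >= config.coverage_cutoff:
            out.append(cm)
    return out


def _passes_resolution(structure: StructureModel, config) -> bool:
    if structure.source == "predicted":
        return True  # pLDDT is the quality gate for models
    return structure.resolution is not None and structure.resolution <= config.resolution_cutoff


def select_structures(
    protein: ProteinRecord,
    library: Sequence[StructureModel],
    config,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> List[CandidateStructure]:
    """Rank library structures usable as templates for one protein.

    A structure qualifies when at least one chain passes identity and
    coverage cutoffs and, for experimental entries, the resolution cutoff.
    Predicted models are considered only if no experimental structure
    qualifies, after trimming low-pLDDT residues. Ranking: identity desc,
    coverage desc, resolution asc, structure id asc.
    """
    experimental: List[CandidateStructure] = []
    predicted: List[CandidateStructure] = []
    for structure in library:
        if not _passes_resolution(structure, config):
            continue
        model = structure
        if structure.source == "predicted":
            model = trim_by_plddt(structure, config.plddt_cutoff)
            if not model.chains:
                continue
        maps = _passing_chain_maps(protein, model, config, scheme)
        if not maps:
            continue
        cand = CandidateStructure(structure=model, chain_maps={protein.accession: maps})
        (predicted if structure.source == "predicted" else experimental).append(cand)
    chosen = experimental if experimental else predicted
    chosen.sort(key=lambda c: c.rank_key)
    return chosen


def find_complex_structures(
    protein_a: ProteinRecord,
    protein_b: ProteinRecord,
    library: Sequence[StructureModel],
    config,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> List[CandidateStructure]:
    """Structures that contain both query proteins (complex templates).

    For a homo-multimer query (same accession twice) at least two distinct
    passing chains are required, so a monomer deposition never masquerades as
    a homo-complex. Only experimental structures are searched: a single-chain
    predicted model carries no quaternary information.
    """
    out: List[CandidateStructure] = []
    homo = protein_a.accession == protein_b.accession
    for structure in library:
        if structure.source != "experimental":
            continue
        if not _passes_resolution(structure, config):
            continue
        maps_a = _passing_chain_maps(protein_a, structure, config, scheme)
        if not maps_a:
            continue
        if homo:
            if len(maps_a) < 2:
                continue
            out.append(CandidateStructure(structure, {protein_a.accession: maps_a}))
        else:
            maps_b = _passing_chain_maps(protein_b, structure, config, scheme)
            if not maps_b:
                continue
            out.append(
                CandidateStructure(
                    structure,
                    {protein_a.accession: maps_a, protein_b.accession: maps_b},
                )
            )
    out.sort(key=lambda c: c.rank_key)
    return out


def trim_by_plddt(model: StructureModel, cutoff: float) -> StructureModel:
    """Drop residues of a predicted model below the pLDDT cutoff.

    The per-residue confidence is read from the alpha-carbon B-factor (every
    atom of a residue carries the same value in standard model files).
    Residue numbering is preserved; empty chains are removed.
    """
    if model.source != "predicted":
        raise ValueError("pLDDT trimming applies to predicted models only")
    chains = []
    for chain in model.chains:
        kept = []
        for res in chain.residues:
            ca = res.atom("CA") or (res.atoms[0] if res.atoms else None)
            if ca is not None and ca.bfactor >= cutoff:
                kept.append(res)
        if kept:
            chains.append(Chain(chain_id=chain.chain_id, residues=kept))
    return StructureModel(
        structure_id=model.structure_id,
        source=model.source,
        resolution=model.resolution,
        chains=chains,
        het_atoms=model.het_atoms,
    )


def map_link_residue(pos_in_protein: int, chain_map: ChainMap, protein_length: Optional[int] = None):
    """Author residue key for a protein position, or None when unobserved.

    Positions beyond the protein length violate the caller's contract and
    raise instead of silently returning unmapped.
    """
    if pos_in_protein < 1 or (protein_length is not None and pos_in_protein > protein_length):
        raise ValueError(f"protein position {pos_in_protein} out of bounds")
    return chain_map.residue_map.get(pos_in_protein)
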