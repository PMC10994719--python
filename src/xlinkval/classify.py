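"""Chain-permutation enumeration, range classification, and remapping.

An intra-link can be explained within one chain (same-chain assignment) or,
on a homo-multimeric structure, across two copies of the protein (cross-chain
assignment). Links whose same-chain topological distance falls outside the
accepted linker span, and links flagged by the overlap analysis, are
re-evaluated cross-chain on homo-complex templates; a within-range cross-chain
distance structurally validates the link as a homo-multimeric inter-link.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .distances import (
    AnchorAtom,
    DistanceError,
    DistanceResult,
    anchor_atom,
    build_base_grid,
    euclidean_distance,
    topological_distance,
)
from .io import CrossLink, ProteinRecord, RunConfig, StructureModel
from .ops import OPSResult
from .seqmap import DEFAULT_SCHEME, ScoringScheme
from .structures import (
    CandidateStructure,
    find_complex_structures,
    map_link_residue,
    select_structures,
)

#: final categories, in the order they are decided
CATEGORIES = (
    "intra_within_range",
    "intra_out_of_range",
    "ops_inter",
    "ops_inter_validated",
    "out_of_range_inter_validated",
    "inter_within_range",
    "inter_out_of_range",
    "unmapped",
)

VALIDATED_CATEGORIES = frozenset(
    {"ops_inter_validated", "out_of_range_inter_validated"}
)
WITHIN_CATEGORIES = frozenset(
    {"intra_within_range", "inter_within_range"} | set(VALIDATED_CATEGORIES)
)


@dataclass(frozen=True)
class LinkerSpec:
    """Accepted topological-distance span of the cross-linking reagent."""

    name: str = "default"
    min_distance: float = 5.0
    max_distance: float = 35.0

    def __post_init__(self) -> None:
        if not (0 <= self.min_distance < self.max_distance):
            raise ValueError("need 0 <= min_distance < max_distance")


@dataclass(frozen=True)
class PermutationAssignment:
    """One placement of the two link sides onto specific chains."""

    link: CrossLink
    structure_id: str
    chain_a: str
    chain_b: str
    residue_a: Tuple[int, str]
    residue_b: Tuple[int, str]


@dataclass
class FinalClassification:
    category: str
    best_result: Optional[DistanceResult] = None
    structure_id: Optional[str] = None
    evidence: str = ""
    all_results: List[DistanceResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def classify_distance(result: DistanceResult, linker: LinkerSpec) -> str:
    """``within`` iff min <= topological <= max; unreachable is out of range."""
    if result.topological is None:
        return "out_of_range"
    if linker.min_distance <= result.topological <= linker.max_distance:
        return "within"
    return "out_of_range"


def enumerate_assignments(
    link: CrossLink,
    candidate: CandidateStructure,
    mode: str = "all",
    protein_lengths: Optional[Dict[str, int]] = None,
) -> List[PermutationAssignment]:
    """All chain placements of a link on a candidate structure.

    ``same_chain``: both residues on one chain (one assignment per chain that
    observes both). ``cross_chain``: all ordered pairs of distinct chains,
    deduplicated by the unordered (chain, residue) pair set so a symmetric
    homodimer placement is not counted twice. Assignments with an unobserved
    residue are silently dropped.
    """
    if mode not in ("same_chain", "cross_chain", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    maps_a = candidate.chain_maps.get(link.protein_a, [])
    maps_b = candidate.chain_maps.get(link.protein_b, [])
    len_a = (protein_lengths or {}).get(link.protein_a)
    len_b = (protein_lengths or {}).get(link.protein_b)
    out: List[PermutationAssignment] = []
    sid = candidate.structure.structure_id

    if mode in ("same_chain", "all") and link.protein_a == link.protein_b:
        for cm in maps_a:
            ra = map_link_residue(link.pos_in_protein_a, cm, len_a)
            rb = map_link_residue(link.pos_in_protein_b, cm, len_b)
            if ra is None or rb is None:
                continue
            out.append(PermutationAssignment(link, sid, cm.chain_id, cm.chain_id, ra, rb))

    if mode in ("cross_chain", "all"):
        seen = set()
        for cma in maps_a:
            ra = map_link_residue(link.pos_in_protein_a, cma, len_a)
            if ra is None:
                continue
            for cmb in maps_b:
                if cmb.chain_id == cma.chain_id:
                    continue
                rb = map_link_residue(link.pos_in_protein_b, cmb, len_b)
                if rb is None:
                    continue
                key = frozenset(((cma.chain_id, ra), (cmb.chain_id, rb)))
                if key in seen:
                    continue
                seen.add(key)
                out.append(PermutationAssignment(link, sid, cma.chain_id, cmb.chain_id, ra, rb))
    return out


def evaluate_link(
    link: CrossLink,
    assignments: Sequence[PermutationAssignment],
    structure: StructureModel,
    config: RunConfig,
    grid_cache: Optional[dict] = None,
) -> Tuple[DistanceResult, List[DistanceResult]]:
    """Distances for every assignment; the verdict uses the best one.

    Best = smallest finite topological distance, ties broken by smaller
    Euclidean distance, then lexicographic chain pair. When every assignment
    is unreachable the one with the smallest Euclidean distance is reported.
    Occupancy grids include only the chains of the assignment under test, so
    a monomer evaluation is not obstructed by the rest of the assembly.
    """
    if not assignments:
        raise ValueError("evaluate_link needs at least one assignment")
    if grid_cache is None:
        grid_cache = {}
    results: List[DistanceResult] = []
    for asg in assignments:
        a = anchor_atom(structure, asg.chain_a, asg.residue_a, config.anchor_mode)
        b = anchor_atom(structure, asg.chain_b, asg.residue_b, config.anchor_mode)
        chain_set = frozenset((asg.chain_a, asg.chain_b))
        key = (structure.structure_id, chain_set)
        base = grid_cache.get(key)
        if base is None:
            base = build_base_grid(structure, config, chain_ids=chain_set)
            grid_cache[key] = base
        grid = base.with_clearance([a.coords, b.coords], config.clearance_radius)
        topo, capped = topological_distance(grid, a, b, cap=config.effective_cap)
        results.append(
            DistanceResult(
                euclidean=euclidean_distance(a, b),
                topological=topo,
                chain_pair=(asg.chain_a, asg.chain_b),
                capped=capped,
                residue_a=asg.residue_a,
                residue_b=asg.residue_b,
            )
        )

    def sort_key(r: DistanceResult):
        return (
            0 if r.topological is not None else 1,
            r.topological if r.topological is not None else math.inf,
            r.euclidean,
            r.chain_pair,
        )

    best = min(results, key=sort_key)
    return best, results


class StructureAnalyzer:
    """Caches template selection and occupancy grids across links.

    The per-link decision cascade:

    1. OPS intra-links are reclassified as inter-links and evaluated
       cross-chain on homo-complex templates; a within-range distance makes
       them ``ops_inter_validated``.
    2. Other intra-links are evaluated same-chain on the best template
       (experimental, else pLDDT-trimmed predicted model). Within range keeps
       them intra; out of range triggers cross-chain evaluation on
       homo-complex templates (``out_of_range_inter_validated`` on success,
       ``intra_out_of_range`` otherwise).
    3. Inter-links are evaluated cross-chain on shared complex templates.
    4. Links with no usable structure anywhere are ``unmapped``.
    """

    def __init__(
        self,
        proteins: Dict[str, ProteinRecord],
        library: Sequence[StructureModel],
        config: RunConfig,
        scheme: ScoringScheme = DEFAULT_SCHEME,
    ) -> None:
        self.proteins = proteins
        self.library = list(library)
        self.config = config
        self.scheme = scheme
        self._mono_cache: Dict[str, List[CandidateStructure]] = {}
        self._complex_cache: Dict[tuple, List[CandidateStructure]] = {}
        self._grid_cache: dict = {}

    # -- template lookup -------------------------------------------------
    def candidates(self, accession: str) -> List[CandidateStructure]:
        if accession not in self._mono_cache:
            self._mono_cache[accession] = select_structures(
                self.proteins[accession], self.library, self.config, self.scheme
            )
        return self._mono_cache[accession]

    def complex_candidates(self, acc_a: str, acc_b: str) -> List[CandidateStructure]:
        key = tuple(sorted((acc_a, acc_b)))
        if key not in self._complex_cache:
            self._complex_cache[key] = find_complex_structures(
                self.proteins[key[0]], self.proteins[key[1]],
                self.library, self.config, self.scheme,
            )
        return self._complex_cache[key]

    # -- evaluation ------------------------------------------------------
    def _protein_lengths(self, link: CrossLink) -> Dict[str, int]:
        return {
            acc: len(self.proteins[acc])
            for acc in (link.protein_a, link.protein_b)
            if acc in self.proteins
        }

    def _evaluate_on(
        self, link: CrossLink, cands: Sequence[CandidateStructure], mode: str
    ) -> Optional[Tuple[DistanceResult, List[DistanceResult], str]]:
        """Evaluate on the first candidate (up to candidate_depth) that yields
        assignments; returns (best, all, structure_id) or None."""
        lengths = self._protein_lengths(link)
        for cand in cands[: max(1, self.config.candidate_depth)]:
            assignments = enumerate_assignments(link, cand, mode, lengths)
            if not assignments:
                continue
            best, results = evaluate_link(
                link, assignments, cand.structure, self.config, self._grid_cache
            )
            return best, results, cand.structure.structure_id
        return None

    def full_classify(self, link: CrossLink, ops: Optional[OPSResult], linker: Optional[LinkerSpec] = None) -> FinalClassification:
        if linker is None:
            linker = LinkerSpec(
                min_distance=self.config.linker_min,
                max_distance=self.config.linker_max,
            )

        if link.link_type == "inter":
            hit = self._evaluate_on(
                link, self.complex_candidates(link.protein_a, link.protein_b), "cross_chain"
            )
            if hit is None:
                return FinalClassification("unmapped")
            best, results, sid = hit
            cat = (
                "inter_within_range"
                if classify_distance(best, linker) == "within"
                else "inter_out_of_range"
            )
            return FinalClassification(cat, best, sid, all_results=results)

        # intra-link branches
        if ops is not None and ops.is_ops:
            hit = self._evaluate_on(
                link, self.complex_candidates(link.protein_a, link.protein_a), "cross_chain"
            )
            if hit is None:
                return FinalClassification("ops_inter", evidence="OPS")
            best, results, sid = hit
            if classify_distance(best, linker) == "within":
                return FinalClassification(
                    "ops_inter_validated", best, sid,
                    evidence="OPS", all_results=results,
                )
            return FinalClassification(
                "ops_inter", best, sid, evidence="OPS", all_results=results
            )

        hit = self._evaluate_on(link, self.candidates(link.protein_a), "same_chain")
        if hit is None:
            return FinalClassification("unmapped")
        best, results, sid = hit
        if classify_distance(best, linker) == "within":
            return FinalClassification("intra_within_range", best, sid, all_results=results)

        cross = self._evaluate_on(
            link, self.complex_candidates(link.protein_a, link.protein_a), "cross_chain"
        )
        if cross is not None:
            cbest, cresults, csid = cross
            if classify_distance(cbest, linker) == "within":
                return FinalClassification(
                    "out_of_range_inter_validated", cbest, csid,
                    evidence="out_of_range_remap",
                    all_results=results + cresults,
                )
            results = results + cresults
        return FinalClassification("intra_out_of_range", best, sid, all_results=results)


def full_classify(
    link: CrossLink,
    ops: Optional[OPSResult],
    library: Sequence[StructureModel],
    proteins: Dict[str, ProteinRecord],
    config: RunConfig,
) -> FinalClassification:
    """One-shot convenience wrapper around :class:`StructureAnalyzer`."""
    return StructureAnalyzer(proteins, library, config).full_classify(link, ops)
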