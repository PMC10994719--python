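"""Overlapping-peptide-sequence (OPS) analysis.

Two cross-linked peptides that overlap on the protein sequence cannot both
come from a single chain (barring internal sequence duplication), so an
intra-link between overlapping peptides is evidence of a homo-multimer. The
extreme case is a self-link: a residue cross-linked to itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .io import CrossLink, Diagnostic, ProteinRecord
from .seqmap import (
    DEFAULT_SCHEME,
    ScoringScheme,
    all_optimal_placements,
)

Interval = Tuple[int, int]


@dataclass(frozen=True)
class OPSResult:
    """Outcome of the overlap analysis for one intra-link."""

    is_ops: bool
    overlap_length: int
    self_link: bool
    interval_a: Optional[Interval]
    interval_b: Optional[Interval]

    def __post_init__(self) -> None:
        if self.is_ops != (self.overlap_length >= 1):
            raise ValueError("is_ops must hold exactly when overlap >= 1")
        if self.self_link and not self.is_ops:
            raise ValueError("a self-link is always an overlap")


def compute_overlap(interval_a: Interval, interval_b: Interval) -> int:
    """Number of residues shared by two 1-based inclusive intervals."""
    (a1, a2), (b1, b2) = interval_a, interval_b
    if a1 > a2 or b1 > b2:
        raise ValueError("intervals must satisfy start <= end")
    return max(0, min(a2, b2) - max(a1, b1) + 1)


def classify_ops(
    link: CrossLink,
    protein: ProteinRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
):
    """Overlap analysis for one intra-link.

    Both peptides are locally aligned to the protein; the overlap of the two
    aligned intervals decides the call. When a peptide has several optimal
    placements (duplicated within the sequence), the placement pair with the
    *smallest* overlap is used, so duplicated peptides that can be explained
    within one chain are not called OPS; a diagnostic notes the ambiguity.

    Returns ``(OPSResult, diagnostics)``.
    """
    if link.link_type != "intra":
        raise ValueError("OPS analysis is defined for intra-links only")
    diagnostics: List[Diagnostic] = []

    placements_a = all_optimal_placements(link.peptide_a, protein.sequence, scheme)
    placements_b = all_optimal_placements(link.peptide_b, protein.sequence, scheme)
    if not placements_a or not placements_b:
        diagnostics.append(
            Diagnostic(link.row_id, "ops_unalignable",
                       "peptide could not be aligned to its protein; no OPS call")
        )
        return (
            OPSResult(False, 0, False, None, None),
            diagnostics,
        )
    if len(placements_a) > 1 or len(placements_b) > 1:
        diagnostics.append(
            Diagnostic(link.row_id, "ops_ambiguous",
                       "peptide duplicated in protein sequence; "
                       "minimal-overlap placement pair used")
        )

    best: Optional[Tuple[int, Interval, Interval]] = None
    for pa in placements_a:
        for pb in placements_b:
            ov = compute_overlap(pa.target_interval, pb.target_interval)
            key = (ov, pa.target_interval, pb.target_interval)
            if best is None or key < best:
                best = key
    overlap, interval_a, interval_b = best
    self_link = link.pos_in_protein_a == link.pos_in_protein_b
    # a self-link overlaps by construction even if interval arithmetic says
    # otherwise on ambiguous placements
    if self_link and overlap < 1:
        overlap = 1
    return (
        OPSResult(
            is_ops=overlap >= 1,
            overlap_length=overlap,
            self_link=self_link,
            interval_a=interval_a,
            interval_b=interval_b,
        ),
        diagnostics,
    )


def ops_reclassify(link: CrossLink, ops: OPSResult) -> dict:
    """Reclassification verdict: OPS intra-links become candidate inter-links.

    Returns a small record with the original and final link types and the
    evidence tag; the link object itself is immutable and kept as-is.
    """
    if ops.is_ops and link.link_type == "intra":
        return {
            "link": link,
            "link_type_original": "intra",
            "link_type_final": "inter",
            "evidence": "OPS",
        }
    return {
        "link": link,
        "link_type_original": link.link_type,
        "link_type_final": link.link_type,
        "evidence": "",
    }
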