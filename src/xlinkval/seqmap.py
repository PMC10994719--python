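"""Local alignment and normalization of link positions to protein coordinates.

Peptides reported by the search engine are aligned against the full protein
sequence with the Smith-Waterman algorithm (affine gaps, Gotoh recurrences)
to recover the link site in full-protein coordinates. The same routine later
scores protein sequences against structure chains.

A gap of length ``k`` scores ``gap_open + (k - 1) * gap_extend``, i.e. the
opening penalty already pays for the first gapped residue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

from .io import CrossLink, Diagnostic, ProteinRecord, RawCrossLink

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringScheme:
    """Simple identity-dominant scoring; all penalties are <= 0."""

    match: int = 2
    mismatch: int = -1
    gap_open: int = -4
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap penalties must be <= 0")


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    """One local alignment; intervals are 1-based inclusive.

    ``aligned_pairs`` holds the (query_pos, target_pos) of every match or
    mismatch column, strictly increasing in both coordinates. ``identity``
    is the fraction of identical columns over all alignment columns (gap
    columns included). An empty alignment (no positive-scoring cell) has
    score 0 and ``None`` intervals.
    """

    score: int
    query_interval: Optional[Tuple[int, int]]
    target_interval: Optional[Tuple[int, int]]
    identity: float
    aligned_pairs: Tuple[Tuple[int, int], ...]

    @property
    def is_empty(self) -> bool:
        return self.query_interval is None


EMPTY_ALIGNMENT = AlignmentResult(0, None, None, 0.0, ())


def _dp(query: str, target: str, s: ScoringScheme):
    """Gotoh matrices. H[i][j] uses 1-based i over query, j over target."""
    n, m = len(query), len(target)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in query (left moves)
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in target (up moves)
    for i in range(1, n + 1):
        qi = query[i - 1]
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            sub = s.match if qi == target[j - 1] else s.mismatch
            e = max(Hi[j - 1] + s.gap_open, Ei[j - 1] + s.gap_extend)
            f = max(Hi1[j] + s.gap_open, Fi1[j] + s.gap_extend)
            Ei[j] = e
            Fi[j] = f
            Hi[j] = max(0, Hi1[j - 1] + sub, e, f)
    return H, E, F


def _traceback(query: str, target: str, s: ScoringScheme, H, E, F, i: int, j: int) -> AlignmentResult:
    """Trace one optimal alignment ending at H[i][j].

    Tie preference: diagonal over up (gap in target) over left (gap in query);
    within a gap state, closing the gap is preferred over extending it.
    """
    pairs: List[Tuple[int, int]] = []
    n_cols = 0
    n_ident = 0
    qe, te = i, j
    state = "H"
    while True:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            sub = s.match if query[i - 1] == target[j - 1] else s.mismatch
            if i > 0 and j > 0 and h == H[i - 1][j - 1] + sub:
                pairs.append((i, j))
                n_cols += 1
                if query[i - 1] == target[j - 1]:
                    n_ident += 1
                i -= 1
                j -= 1
            elif h == F[i][j]:
                state = "F"
            elif h == E[i][j]:
                state = "E"
            else:  # pragma: no cover - recurrence guarantees one branch
                raise AssertionError("inconsistent traceback")
        elif state == "F":  # gap in target: consume query residue
            n_cols += 1
            if F[i][j] == H[i - 1][j] + s.gap_open:
                i -= 1
                state = "H"
            else:
                F_val = F[i][j]
                assert F_val == F[i - 1][j] + s.gap_extend
                i -= 1
        else:  # state == "E": gap in query: consume target residue
            n_cols += 1
            if E[i][j] == H[i][j - 1] + s.gap_open:
                j -= 1
                state = "H"
            else:
                assert E[i][j] == E[i][j - 1] + s.gap_extend
                j -= 1
    pairs.reverse()
    qs, ts = i + 1, j + 1
    identity = n_ident / n_cols if n_cols else 0.0
    return AlignmentResult(
        score=H[qe][te],
        query_interval=(qs, qe),
        target_interval=(ts, te),
        identity=identity,
        aligned_pairs=tuple(pairs),
    )


def smith_waterman(query: str, target: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> AlignmentResult:
    """Optimal local alignment of ``query`` against ``target``.

    Among equal-scoring end cells the one with the smallest
    ``(target_end, query_end)`` is reported; traceback ties prefer the
    diagonal, then the vertical (query-consuming) move, then the horizontal.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    H, E, F = _dp(query, target, scheme)
    best = 0
    bi = bj = 0
    n, m = len(query), len(target)
    for j in range(1, m + 1):  # column-major: smallest target_end wins ties
        for i in range(1, n + 1):
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best == 0:
        return EMPTY_ALIGNMENT
    return _traceback(query, target, scheme, H, E, F, bi, bj)


def all_optimal_placements(query: str, target: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> List[AlignmentResult]:
    """All distinct optimal local alignments (one traceback per maximal cell).

    Placements are deduplicated by their interval pair and returned sorted by
    (target_start, query_start). Used to resolve peptides that occur at
    several equally good protein locations.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    H, E, F = _dp(query, target, scheme)
    n, m = len(query), len(target)
    best = max(H[i][j] for i in range(n + 1) for j in range(m + 1))
    if best == 0:
        return []
    out: List[AlignmentResult] = []
    seen = set()
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if H[i][j] != best:
                continue
            aln = _traceback(query, target, scheme, H, E, F, i, j)
            key = (aln.query_interval, aln.target_interval)
            if key not in seen:
                seen.add(key)
                out.append(aln)
    out.sort(key=lambda a: (a.target_interval[0], a.query_interval[0]))
    return out


def map_position_through(aln: AlignmentResult, pos_in_query: int) -> Optional[int]:
    """Target position aligned with ``pos_in_query``, or None if in a gap."""
    for qp, tp in aln.aligned_pairs:
        if qp == pos_in_query:
            return tp
    return None


def map_peptide_position(
    peptide: str,
    pos_in_peptide: int,
    protein: ProteinRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> Optional[int]:
    """Map a link site inside a peptide onto the full protein sequence.

    The peptide is locally aligned to the protein and the link column is read
    off the alignment. The mapping is rejected (``None``) when the alignment
    is partial or imperfect *and* the link residue itself does not align to an
    identical residue — the link site must be trustworthy even if peripheral
    residues mismatch.
    """
    if not (1 <= pos_in_peptide <= len(peptide)):
        raise ValueError(
            f"pos_in_peptide {pos_in_peptide} outside peptide of length {len(peptide)}"
        )
    placements = all_optimal_placements(peptide, protein.sequence, scheme)
    if not placements:
        return None
    aln = placements[0]
    target_pos = map_position_through(aln, pos_in_peptide)
    if target_pos is None:
        return None
    link_identical = protein.sequence[target_pos - 1] == peptide[pos_in_peptide - 1]
    covers_peptide = {qp for qp, _ in aln.aligned_pairs} == set(range(1, len(peptide) + 1))
    if not (link_identical or covers_peptide):
        return None
    return target_pos


def count_placements(peptide: str, protein: ProteinRecord, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    return len(all_optimal_placements(peptide, protein.sequence, scheme))


def normalize_links(
    raw_links: Sequence[RawCrossLink],
    proteins: dict,
    scheme: ScoringScheme = DEFAULT_SCHEME,
):
    """Resolve all link sites to protein coordinates and collapse duplicates.

    For each side the protein position is taken as given, or mapped from the
    peptide position via local alignment; when both are supplied and disagree,
    the mapped value wins and a diagnostic is recorded. Exact duplicates under
    the unordered (protein, position) pair key collapse to one record with a
    multiplicity count. Idempotent: normalizing the output again is a no-op.

    Returns ``(links, diagnostics)``.
    """
    links: List[CrossLink] = []
    diagnostics: List[Diagnostic] = []
    by_key: dict = {}

    for raw in raw_links:
        sides = {}
        failed = False
        for side in ("a", "b"):
            acc = getattr(raw, f"protein_{side}")
            pep = getattr(raw, f"peptide_{side}")
            pos_pep = getattr(raw, f"pos_in_peptide_{side}")
            pos_prot = getattr(raw, f"pos_in_protein_{side}")
            protein = proteins.get(acc)
            if protein is None:
                diagnostics.append(
                    Diagnostic(raw.row_id, "missing_protein",
                               f"side {side}: accession {acc!r} not in FASTA; link dropped")
                )
                failed = True
                break
            mapped = None
            if pos_pep is not None:
                mapped = map_peptide_position(pep, pos_pep, protein, scheme)
                if count_placements(pep, protein, scheme) > 1:
                    diagnostics.append(
                        Diagnostic(raw.row_id, "ambiguous_placement",
                                   f"side {side}: peptide maps to multiple protein "
                                   f"locations; smallest start used")
                    )
            if pos_prot is not None and mapped is not None and mapped != pos_prot:
                diagnostics.append(
                    Diagnostic(raw.row_id, "position_conflict",
                               f"side {side}: given protein position {pos_prot} "
                               f"disagrees with mapped {mapped}; mapped value used")
                )
                pos_prot = mapped
            if pos_prot is None:
                pos_prot = mapped
            if pos_prot is None:
                diagnostics.append(
                    Diagnostic(raw.row_id, "unmappable_peptide",
                               f"side {side}: peptide {pep!r} could not be placed "
                               f"on {acc}; link dropped")
                )
                failed = True
                break
            if not (1 <= pos_prot <= len(protein)):
                diagnostics.append(
                    Diagnostic(raw.row_id, "position_out_of_bounds",
                               f"side {side}: protein position {pos_prot} outside "
                               f"{acc} (length {len(protein)}); link dropped")
                )
                failed = True
                break
            sides[side] = pos_prot
        if failed:
            continue

        link = CrossLink(
            row_id=raw.row_id,
            protein_a=raw.protein_a,
            protein_b=raw.protein_b,
            peptide_a=raw.peptide_a,
            peptide_b=raw.peptide_b,
            pos_in_protein_a=sides["a"],
            pos_in_protein_b=sides["b"],
            pos_in_peptide_a=raw.pos_in_peptide_a,
            pos_in_peptide_b=raw.pos_in_peptide_b,
            source_tag=raw.source_tag,
            extra=raw.extra,
        )
        existing = by_key.get(link.unique_key)
        if existing is not None:
            idx = links.index(existing)
            links[idx] = replace(existing, multiplicity=existing.multiplicity + getattr(raw, "multiplicity", 1))
            by_key[link.unique_key] = links[idx]
        else:
            mult = getattr(raw, "multiplicity", 1)
            if mult != 1:
                link = replace(link, multiplicity=mult)
            by_key[link.unique_key] = link
            links.append(link)
    return links, diagnostics
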