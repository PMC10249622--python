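"""Diagnostic-site discovery in species-grouped alignments.

Species-specific priming needs alignment columns that are conserved within
the target species and carry a residue absent (or rare) in every other
species. This module turns that visual-inspection criterion into column
statistics: per-species residue tallies, a conservation fraction, and a
strict diagnostic-site caller, plus the coordinate bridge between alignment
columns and ungapped template positions and a mismatch profile of a primer
footprint against all non-target records.

Coordinate convention: user-facing positions and columns are 1-based
inclusive; internals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from ._iupac import GAP, matches, reverse_complement
from .primer_eval import Primer
from .seqio import SequenceRecord, SpeciesAlignment

__all__ = [
    "ColumnProfile",
    "DiagnosticSite",
    "FootprintMismatch",
    "CoordinateError",
    "FootprintError",
    "column_profile",
    "diagnostic_sites",
    "alignment_to_ungapped",
    "ungapped_to_alignment",
    "consensus",
    "primer_footprint_specificity",
]


class CoordinateError(ValueError):
    """Requested a gapped position where an ungapped coordinate is needed."""


class FootprintError(ValueError):
    """A primer footprint could not be located on the alignment."""


@dataclass(frozen=True)
class ColumnProfile:
    """Residue tallies for one alignment column, per species.

    ``modal_residue`` is the most frequent non-gap residue (alphabetical
    tie-break; ``None`` for gap-only groups) and ``conservation`` its share
    of the non-gap residues (``None`` when gap-only).
    """

    column: int  # 1-based
    counts: dict[str, dict[str, int]]
    gap_counts: dict[str, int]
    modal_residue: dict[str, str | None]
    conservation: dict[str, float | None]


@dataclass(frozen=True)
class DiagnosticSite:
    """A column whose target-species residue disqualifies every non-target.

    ``nontarget_residues`` holds the residues that occur in non-target
    species above the allowed share, so the defining invariant
    ``target_residue not in nontarget_residues`` holds for any threshold.
    """

    column: int  # 1-based
    target: str
    target_residue: str
    nontarget_residues: frozenset[str]
    conservation: float

    def __post_init__(self) -> None:
        if self.target_residue in self.nontarget_residues:
            raise ValueError("target residue present in non-target residue set")


@dataclass(frozen=True)
class FootprintMismatch:
    """Mismatch profile of one primer footprint against one non-target record."""

    species: str
    record_id: str
    primer_length: int
    mismatches: int
    fraction: float
    three_prime_mismatches: int  # mismatches within the 3'-terminal window
    three_prime_window: int


def column_profile(aln: SpeciesAlignment, column: int) -> ColumnProfile:
    """Exact per-species residue tallies for a 1-based alignment column."""
    if not 1 <= column <= aln.columns:
        raise IndexError(f"column {column} outside 1..{aln.columns}")
    idx = column - 1
    counts: dict[str, dict[str, int]] = {}
    gap_counts: dict[str, int] = {}
    modal: dict[str, str | None] = {}
    conservation: dict[str, float | None] = {}
    for label, records in aln.groups.items():
        tally: dict[str, int] = {}
        gaps = 0
        for rec in records:
            ch = rec.residues[idx]
            if ch == GAP:
                gaps += 1
            else:
                tally[ch] = tally.get(ch, 0) + 1
        counts[label] = tally
        gap_counts[label] = gaps
        if tally:
            best = max(sorted(tally), key=lambda r: tally[r])
            modal[label] = best
            conservation[label] = tally[best] / sum(tally.values())
        else:  # gap-only column for this species: conservation undefined
            modal[label] = None
            conservation[label] = None
    return ColumnProfile(column, counts, gap_counts, modal, conservation)


def diagnostic_sites(
    aln: SpeciesAlignment,
    target: str,
    min_conservation: float = 1.0,
    max_nontarget_share: float = 0.0,
) -> list[DiagnosticSite]:
    """Columns diagnostic for ``target``, sorted by column.

    A column qualifies when the target's modal residue reaches
    ``min_conservation`` of the target's non-gap residues and that residue's
    share in every non-target species is at most ``max_nontarget_share``
    (0 = strict absence). Gap-only target columns never qualify, and a gap
    is never a diagnostic residue. Ambiguity codes count toward the modal
    residue only on exact equality: diagnosis stays conservative while
    annealing prediction elsewhere stays permissive.
    """
    if target not in aln.groups:
        raise KeyError(f"unknown species {target!r}")
    for name, value in (
        ("min_conservation", min_conservation),
        ("max_nontarget_share", max_nontarget_share),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")

    sites: list[DiagnosticSite] = []
    for column in range(1, aln.columns + 1):
        prof = column_profile(aln, column)
        residue = prof.modal_residue[target]
        cons = prof.conservation[target]
        if residue is None or cons is None or cons < min_conservation:
            continue
        ok = True
        disqualifying: set[str] = set()
        for label in aln.groups:
            if label == target:
                continue
            tally = prof.counts[label]
            non_gap = sum(tally.values())
            share = tally.get(residue, 0) / non_gap if non_gap else 0.0
            if share > max_nontarget_share:
                ok = False
                break
            for other, cnt in tally.items():
                if non_gap and cnt / non_gap > max_nontarget_share and other != residue:
                    disqualifying.add(other)
        if ok:
            sites.append(
                DiagnosticSite(column, target, residue, frozenset(disqualifying), cons)
            )
    return sites


def alignment_to_ungapped(record: SequenceRecord, column: int) -> int:
    """1-based position of an alignment column's residue in the degapped sequence."""
    if not 1 <= column <= len(record):
        raise IndexError(f"column {column} outside 1..{len(record)}")
    if record.residues[column - 1] == GAP:
        raise CoordinateError(
            f"record {record.id!r}: column {column} is a gap, no ungapped coordinate"
        )
    return column - record.residues[: column - 1].count(GAP)


def ungapped_to_alignment(record: SequenceRecord, position: int) -> int:
    """Inverse of :func:`alignment_to_ungapped` (1-based both sides)."""
    if position < 1:
        raise IndexError(f"position {position} must be >= 1")
    seen = 0
    for idx, ch in enumerate(record.residues):
        if ch != GAP:
            seen += 1
            if seen == position:
                return idx + 1
    raise IndexError(
        f"record {record.id!r}: only {seen} residues, no position {position}"
    )


def consensus(aln: SpeciesAlignment, species: str) -> SequenceRecord:
    """Gapped majority consensus of one species group.

    A column is a gap in the consensus when the group has no non-gap residue
    there or gaps outnumber residues; ties between residues break
    alphabetically, ties between gap and residue favor the residue.
    """
    if species not in aln.groups:
        raise KeyError(f"unknown species {species!r}")
    records = aln.groups[species]
    chars: list[str] = []
    for idx in range(aln.columns):
        tally: dict[str, int] = {}
        gaps = 0
        for rec in records:
            ch = rec.residues[idx]
            if ch == GAP:
                gaps += 1
            else:
                tally[ch] = tally.get(ch, 0) + 1
        if not tally:
            chars.append(GAP)
            continue
        best = max(sorted(tally), key=lambda r: tally[r])
        chars.append(GAP if gaps > tally[best] else best)
    return SequenceRecord(id=f"consensus|{species}", residues="".join(chars))


def _locate_footprint(primer: Primer, cons_ungapped: str) -> tuple[int, bool]:
    """Best (start0, is_revcomp) placement of a primer on an ungapped consensus.

    Scans both orientations, preferring fewer mismatches, then forward
    orientation, then the leftmost start. Placements with more than 20%
    mismatching positions are not considered locatable.
    """
    n = len(cons_ungapped)
    plen = len(primer.sequence)
    best: tuple[int, int, int] | None = None  # (mismatches, orient, start)
    for orient, seq in ((0, primer.sequence), (1, reverse_complement(primer.sequence))):
        for start in range(0, n - plen + 1):
            mm = sum(
                0 if matches(seq[k], cons_ungapped[start + k]) else 1
                for k in range(plen)
            )
            cand = (mm, orient, start)
            if best is None or cand < best:
                best = cand
    if best is None or best[0] > 0.2 * plen:
        raise FootprintError(
            f"primer {primer.name!r} not locatable on the target consensus"
        )
    return best[2], bool(best[1])


def primer_footprint_specificity(
    primer: Primer,
    aln: SpeciesAlignment,
    target: str,
    *,
    three_prime_window: int = 5,
) -> list[FootprintMismatch]:
    """Mismatch profile of a primer's footprint against every non-target record.

    The footprint is anchored on the target-species consensus (best match,
    either orientation), mapped back to alignment columns, and compared
    position-by-position against each non-target record. IUPAC codes match
    on non-empty base-set intersection; an alignment gap under the footprint
    counts as a mismatch. Mismatch positions falling in the primer's
    3'-terminal window are tallied separately, since 3' mismatches are what
    actually block extension.
    """
    if target not in aln.groups:
        raise KeyError(f"unknown species {target!r}")
    cons = consensus(aln, target)
    cons_ungapped = cons.ungapped
    start0, is_rc = _locate_footprint(primer, cons_ungapped)
    plen = len(primer.sequence)
    footprint_cols = [
        ungapped_to_alignment(cons, start0 + k + 1) for k in range(plen)
    ]
    oriented = reverse_complement(primer.sequence) if is_rc else primer.sequence

    reports: list[FootprintMismatch] = []
    for label, records in aln.groups.items():
        if label == target:
            continue
        for rec in records:
            mm = 0
            mm3 = 0
            for k, col in enumerate(footprint_cols):
                ch = rec.residues[col - 1]
                if ch == GAP or not matches(oriented[k], ch):
                    mm += 1
                    # primer 3' end sits at the footprint's right edge when
                    # placed forward, at the left edge when reverse-complemented
                    offset_from_3prime = k if is_rc else plen - 1 - k
                    if offset_from_3prime < three_prime_window:
                        mm3 += 1
            reports.append(
                FootprintMismatch(
                    species=label,
                    record_id=rec.id,
                    primer_length=plen,
                    mismatches=mm,
                    fraction=mm / plen,
                    three_prime_mismatches=mm3,
                    three_prime_window=three_prime_window,
                )
            )
    return reports
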