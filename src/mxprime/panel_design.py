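"""Candidate primer enumeration and multiplex panel assembly.

A species-specific forward primer is a window of the target-species
consensus whose 3'-terminal base sits on a diagnostic column: extension then
requires a perfect 3' pairing that only target DNA provides. Candidates that
pass primer QC are combined — one forward per species, plus the shared
universal reverse and a control pair — into a panel whose predicted bands
are mutually resolvable on a gel. The assembly objective is to maximize the
minimum pairwise band separation (control band included), subject to dimer
and Tm compatibility; exhaustive search when the candidate product is small,
deterministic greedy-with-swaps otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._iupac import GAP
from .diagnostics import (
    DiagnosticSite,
    alignment_to_ungapped,
    consensus,
    diagnostic_sites,
    primer_footprint_specificity,
    ungapped_to_alignment,
)
from .insilico_pcr import MismatchPolicy, find_binding_sites
from .primer_eval import (
    DimerPolicy,
    DimerReport,
    Primer,
    PrimerQC,
    QCConstraints,
    cross_dimer,
    qc_primer,
    wallace_tm,
)
from .seqio import SpeciesAlignment

logger = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 10**6

__all__ = [
    "PrimerCandidate",
    "MultiplexPanel",
    "PanelReport",
    "AnchoringError",
    "InfeasiblePanelError",
    "enumerate_candidates",
    "assemble_panel",
    "panel_report",
]


class AnchoringError(ValueError):
    """The universal reverse primer could not be located on the alignment."""


class InfeasiblePanelError(ValueError):
    """No candidate combination satisfies the panel constraints."""


@dataclass(frozen=True)
class PrimerCandidate:
    """A candidate species-specific forward primer with its footprint."""

    primer: Primer
    footprint_columns: tuple[int, int]  # 1-based alignment columns, inclusive
    start_ungapped: int  # 1-based 5' start on the degapped target consensus
    diagnostic_count: int
    three_prime_on_diagnostic: bool
    amplicon_length: int  # predicted primer-inclusive product, bp

    def __post_init__(self) -> None:
        if self.diagnostic_count < 1:
            raise ValueError("candidate must cover at least one diagnostic column")
        if self.amplicon_length < len(self.primer.sequence):
            raise ValueError("predicted amplicon shorter than the primer itself")

    @classmethod
    def fixed(cls, primer: Primer, amplicon_length: int) -> "PrimerCandidate":
        """Wrap an already-designed primer with a known product length."""
        return cls(
            primer=primer,
            footprint_columns=(1, len(primer.sequence)),
            start_ungapped=1,
            diagnostic_count=1,
            three_prime_on_diagnostic=True,
            amplicon_length=amplicon_length,
        )


@dataclass
class MultiplexPanel:
    """One multiplex assay: species forwards, universal reverse, control pair."""

    name: str
    marker: str
    forwards: dict[str, Primer]
    universal_reverse: Primer
    control_pair: tuple[Primer, Primer]
    expected_bands: dict[str, int]
    control_band: int

    def __post_init__(self) -> None:
        if len(self.forwards) < 2:
            raise ValueError("panel needs species forwards for at least 2 species")
        if set(self.forwards) != set(self.expected_bands):
            raise ValueError("expected bands must cover exactly the forward species")
        bands = list(self.expected_bands.values()) + [self.control_band]
        if len(set(bands)) != len(bands):
            raise ValueError(f"expected bands are not pairwise distinct: {sorted(bands)}")
        for sp, primer in self.forwards.items():
            if primer.target_species and primer.target_species != sp:
                raise ValueError(
                    f"forward {primer.name!r} targets {primer.target_species!r}, keyed {sp!r}"
                )

    def primers(self) -> list[Primer]:
        return [
            *self.forwards.values(),
            self.universal_reverse,
            *self.control_pair,
        ]

    def all_bands(self) -> list[int]:
        return sorted([*self.expected_bands.values(), self.control_band])

    def min_band_gap(self) -> int:
        bands = self.all_bands()
        return min(b2 - b1 for b1, b2 in zip(bands, bands[1:]))


def _candidate_name(target: str, start_ungapped: int) -> str:
    words = [w for w in target.replace(".", " ").split() if w]
    if len(words) >= 2:  # "B. rousseauxii" -> Bro<pos>, matching field convention
        stem = (words[0][0] + words[-1][:2]).capitalize()
        return f"{stem}{start_ungapped}"
    return f"{target}_{start_ungapped}"


def enumerate_candidates(
    aln: SpeciesAlignment,
    target: str,
    reverse_primer: Primer,
    *,
    length_range: tuple[int, int] = (18, 22),
    qc_constraints: QCConstraints | None = None,
    min_conservation: float = 1.0,
    max_nontarget_share: float = 0.0,
    policy: MismatchPolicy | None = None,
) -> list[PrimerCandidate]:
    """All QC-passing consensus windows whose 3' base lies on a diagnostic column.

    The universal reverse primer is anchored on the target consensus (it must
    bind the - strand downstream); each candidate's product length runs from
    its 5' start through the reverse primer's 5'-complement position, primer
    inclusive. Sorted by (diagnostic coverage desc, product length desc,
    start asc). An empty diagnostic-site list yields an empty result, not an
    error; an unlocatable reverse primer is an anchoring error.
    """
    sites = diagnostic_sites(aln, target, min_conservation, max_nontarget_share)
    if not sites:
        logger.info("no diagnostic sites for %r; no candidates", target)
        return []
    cons = consensus(aln, target)
    template = cons.ungapped
    policy = policy or MismatchPolicy()
    rev_sites = [
        s
        for s in find_binding_sites(template, reverse_primer, policy)
        if s.strand == "-"
    ]
    if not rev_sites:
        raise AnchoringError(
            f"reverse primer {reverse_primer.name!r} has no - strand site on the "
            f"{target!r} consensus"
        )

    diag_positions: dict[int, int] = {}  # ungapped pos -> column
    for site in sites:
        if cons.residues[site.column - 1] == GAP:
            continue  # consensus gap: the target mostly lacks this column
        diag_positions[alignment_to_ungapped(cons, site.column)] = site.column

    qc_constraints = qc_constraints or QCConstraints()
    lo, hi = length_range
    candidates: list[PrimerCandidate] = []
    for pos3 in sorted(diag_positions):
        for plen in range(lo, hi + 1):
            start = pos3 - plen + 1
            if start < 1:
                logger.debug(
                    "diagnostic position %d too close to the 5' end for length %d",
                    pos3,
                    plen,
                )
                continue
            window = template[start - 1 : pos3]
            primer = Primer(
                name=_candidate_name(target, start),
                sequence=window,
                role="species_forward",
                target_species=target,
            )
            if qc_primer(primer, qc_constraints).failures:
                continue
            downstream = [s for s in rev_sites if s.start >= pos3 + 1]
            if not downstream:
                logger.debug("no reverse site downstream of position %d", pos3)
                continue
            rev = min(downstream, key=lambda s: s.start)
            amplicon = rev.end - start + 1
            if amplicon > policy.max_product:
                continue
            n_diag = sum(1 for p in diag_positions if start <= p <= pos3)
            candidates.append(
                PrimerCandidate(
                    primer=primer,
                    footprint_columns=(
                        ungapped_to_alignment(cons, start),
                        ungapped_to_alignment(cons, pos3),
                    ),
                    start_ungapped=start,
                    diagnostic_count=n_diag,
                    three_prime_on_diagnostic=True,
                    amplicon_length=amplicon,
                )
            )
    if not candidates:
        logger.info(
            "target %r: %d diagnostic site(s) but no geometrically feasible, "
            "QC-passing window",
            target,
            len(sites),
        )
    candidates.sort(
        key=lambda c: (-c.diagnostic_count, -c.amplicon_length, c.start_ungapped)
    )
    return candidates


def _combo_valid(
    primers: Sequence[Primer],
    dimer_policy: DimerPolicy,
    tm_window: tuple[float, float],
) -> bool:
    for p in primers:
        if not tm_window[0] <= wallace_tm(p.sequence) <= tm_window[1]:
            return False
    for a, b in itertools.combinations(primers, 2):
        if cross_dimer(a.sequence, b.sequence, dimer_policy).flagged:
            return False
    return True


def _min_gap(bands: Sequence[int]) -> int:
    ordered = sorted(bands)
    return min(b2 - b1 for b1, b2 in zip(ordered, ordered[1:]))


def assemble_panel(
    candidates_by_species: Mapping[str, Sequence[PrimerCandidate]],
    universal_reverse: Primer,
    control_pair: tuple[Primer, Primer],
    control_band: int,
    *,
    min_band_separation: int = 50,
    dimer_policy: DimerPolicy | None = None,
    tm_window: tuple[float, float] = (45.0, 80.0),
    name: str = "multiplex",
    marker: str = "",
) -> MultiplexPanel:
    """Pick one forward per species maximizing the minimum pairwise band gap.

    The control band participates in the separation objective. A combination
    is admissible only if every pairwise primer dimer (forwards, reverse and
    control pair all included) is unflagged and every Wallace Tm falls in
    ``tm_window``. Exhaustive over the Cartesian product up to 10^6
    combinations, else greedy per-species choice with local swap improvement;
    both deterministic, with ties broken by (larger min gap, more diagnostic
    columns covered, lexicographic primer names).
    """
    dimer_policy = dimer_policy or DimerPolicy()
    species = sorted(candidates_by_species)
    if len(species) < 2:
        raise InfeasiblePanelError("need candidates for at least 2 species")
    for sp in species:
        if not candidates_by_species[sp]:
            raise InfeasiblePanelError(f"no candidates for species {sp!r}")

    shared = [universal_reverse, *control_pair]
    if not _combo_valid(shared, dimer_policy, tm_window):
        raise InfeasiblePanelError(
            "universal reverse / control primers fail dimer or Tm constraints alone"
        )

    # deterministic candidate order regardless of input permutation
    pools = [
        sorted(
            candidates_by_species[sp],
            key=lambda c: (c.primer.name, c.amplicon_length),
        )
        for sp in species
    ]

    def score(combo: Sequence[PrimerCandidate]):
        bands = [c.amplicon_length for c in combo] + [control_band]
        if len(set(bands)) != len(bands):
            return None
        gap = _min_gap(bands)
        if gap < min_band_separation:
            return None
        if not _combo_valid(
            [c.primer for c in combo] + shared, dimer_policy, tm_window
        ):
            return None
        return (
            gap,
            sum(c.diagnostic_count for c in combo),
            tuple(sorted(c.primer.name for c in combo)),
        )

    def better(s: tuple, t: tuple | None) -> bool:
        """Larger min gap, then more diagnostic columns, then earlier names."""
        if t is None:
            return True
        return (s[0], s[1]) > (t[0], t[1]) or (
            (s[0], s[1]) == (t[0], t[1]) and s[2] < t[2]
        )

    n_combos = 1
    for pool in pools:
        n_combos *= len(pool)

    best: tuple | None = None
    best_combo: tuple[PrimerCandidate, ...] | None = None
    if n_combos <= EXHAUSTIVE_LIMIT:
        for combo in itertools.product(*pools):
            s = score(combo)
            if s is not None and better(s, best):
                best, best_combo = s, combo
    else:  # greedy: start from each pool head, improve by single swaps
        current = [pool[0] for pool in pools]
        improved = True
        while improved:
            improved = False
            for i, pool in enumerate(pools):
                for cand in pool:
                    trial = list(current)
                    trial[i] = cand
                    s_trial = score(tuple(trial))
                    s_cur = score(tuple(current))
                    if s_trial is not None and better(s_trial, s_cur):
                        current = trial
                        improved = True
        best = score(tuple(current))
        best_combo = tuple(current) if best is not None else None

    if best is None or best_combo is None:
        raise InfeasiblePanelError(
            f"no feasible combination: {n_combos} combination(s) searched, none "
            f"satisfies min separation {min_band_separation} bp with compatible "
            f"dimers and Tm in {tm_window}"
        )

    forwards = {sp: c.primer for sp, c in zip(species, best_combo)}
    bands = {sp: c.amplicon_length for sp, c in zip(species, best_combo)}
    return MultiplexPanel(
        name=name,
        marker=marker,
        forwards=forwards,
        universal_reverse=universal_reverse,
        control_pair=control_pair,
        expected_bands=bands,
        control_band=control_band,
    )


@dataclass(frozen=True)
class PanelReport:
    """QC, dimer and specificity summary for an assembled panel."""

    panel_name: str
    qc: dict[str, PrimerQC]
    dimers: dict[tuple[str, str], DimerReport]
    band_order: tuple[tuple[str, int], ...]  # (label, bp) ascending
    footprint_specificity: dict[str, list] = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "primer": list(self.qc),
                "length": [q.length for q in self.qc.values()],
                "gc": [round(q.gc_fraction, 3) for q in self.qc.values()],
                "tm_wallace": [q.tm_wallace for q in self.qc.values()],
                "self_duplex": [q.self_duplex for q in self.qc.values()],
                "pass": [q.passed for q in self.qc.values()],
            }
        )


def panel_report(
    panel: MultiplexPanel,
    aln: SpeciesAlignment | None = None,
    *,
    qc_constraints: QCConstraints | None = None,
    dimer_policy: DimerPolicy | None = None,
) -> PanelReport:
    """Per-primer QC, all pairwise dimers, band ladder and (with an alignment)
    footprint specificity of every species forward against non-targets."""
    qc = {p.name: qc_primer(p, qc_constraints) for p in panel.primers()}
    dimer_policy = dimer_policy or DimerPolicy()
    dimers = {
        (a.name, b.name): cross_dimer(a.sequence, b.sequence, dimer_policy)
        for a, b in itertools.combinations(panel.primers(), 2)
    }
    ladder = sorted(
        [(sp, bp) for sp, bp in panel.expected_bands.items()]
        + [("control", panel.control_band)],
        key=lambda t: t[1],
    )
    specificity: dict[str, list] = {}
    if aln is not None:
        for sp, primer in panel.forwards.items():
            if sp in aln.groups:
                specificity[primer.name] = primer_footprint_specificity(
                    primer, aln, sp
                )
    return PanelReport(
        panel_name=panel.name,
        qc=qc,
        dimers=dimers,
        band_order=tuple(ladder),
        footprint_specificity=specificity,
    )
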