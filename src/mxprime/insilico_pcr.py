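"""In-silico PCR: 3'-anchored primer binding, amplification and lane verdicts.

Primer annealing is modeled as approximate string matching with a protected
3' window: a primer binds wherever the template agrees with it at all but a
bounded number of positions, with zero tolerance inside the 3'-terminal
window (mismatches there block polymerase extension, which is exactly the
mechanism species-specific primers exploit). A band is binary
present/absent; amplification efficiency, primer concentration and template
quantity are out of scope.

Scanning is vectorized over template positions with numpy bitmask tables;
an independent position-by-position oracle lives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._iupac import GAP, MASK_TABLE, reverse_complement
from .primer_eval import Primer
from .seqio import SequenceRecord

__all__ = [
    "MismatchPolicy",
    "BindingSite",
    "Amplicon",
    "BandSet",
    "LaneResult",
    "SpecificityMatrix",
    "find_binding_sites",
    "amplify",
    "multiplex_amplify",
    "specificity_matrix",
    "classify_bands",
    "band_matches",
    "DEFAULT_BAND_TOLERANCE",
]

# observed vs expected band lengths agree within max(5 bp, 3%) — gel sizes
# against a 100-bp ladder are approximate
DEFAULT_BAND_TOLERANCE = (5, 0.03)

#: exact-match mask table used when IUPAC-intersection matching is off:
#: only unambiguous bases carry a bit, so R/Y/... never match anything
_STRICT_TABLE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _STRICT_TABLE[ord(_b)] = 1 << _i


@dataclass(frozen=True)
class MismatchPolicy:
    """How forgiving primer annealing is.

    ``max_mismatches`` caps total mismatches per binding site;
    ``protected_window`` is the 3'-terminal stretch in which no mismatch is
    tolerated; ``iupac`` enables base-set-intersection matching for
    ambiguity codes; ``max_product`` discards implausibly long amplicons.
    """

    max_mismatches: int = 2
    protected_window: int = 3
    iupac: bool = True
    max_product: int = 2000

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.protected_window < 0 or self.max_product < 0:
            raise ValueError("policy maxima must be >= 0")


@dataclass(frozen=True)
class BindingSite:
    """One primer annealing location, in 1-based + strand coordinates."""

    template_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    mismatches: int
    mismatch_offsets: tuple[int, ...]  # offsets from the primer's 3' end
    primer: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end < self.start:
            raise ValueError("binding site end precedes start")


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product (primer-inclusive length)."""

    template_id: str
    forward_site: BindingSite  # the + strand site
    reverse_site: BindingSite  # the - strand site
    forward_primer: str
    reverse_primer: str

    @property
    def length(self) -> int:
        return self.reverse_site.end - self.forward_site.start + 1

    def __post_init__(self) -> None:
        if self.forward_site.strand != "+" or self.reverse_site.strand != "-":
            raise ValueError("amplicon requires a + strand and a - strand site")
        if self.forward_site.start > self.reverse_site.start:
            raise ValueError("forward site must not start after the reverse site")


@dataclass(frozen=True)
class BandSet:
    """Deduplicated, sorted band lengths for one lane, with provenance."""

    lane: str
    bands: tuple[int, ...]
    provenance: dict[int, tuple[tuple[str, str], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(sorted(set(self.bands))) != self.bands:
            raise ValueError("bands must be sorted ascending and unique")


@dataclass(frozen=True)
class LaneResult:
    lane: str
    species: str  # the template's true label ('' for a no-template control)
    bands: tuple[int, ...]
    called: str  # species name, 'non-target', 'assay-failure' or 'ambiguous'
    verdict: str  # 'target-confirmed', 'non-target', 'assay-failure', 'ambiguous'


@dataclass(frozen=True)
class SpecificityMatrix:
    """Computational analogue of a specificity-test gel: one verdict per lane."""

    panel_name: str
    rows: tuple[LaneResult, ...]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lane": [r.lane for r in self.rows],
                "species": [r.species for r in self.rows],
                "bands": [",".join(map(str, r.bands)) for r in self.rows],
                "called": [r.called for r in self.rows],
                "verdict": [r.verdict for r in self.rows],
            }
        )


def _as_sequence(template: SequenceRecord | str) -> tuple[str, str]:
    if isinstance(template, SequenceRecord):
        tid, seq = template.id, template.residues
    else:
        tid, seq = "template", template.upper()
    if not seq:
        raise ValueError("empty template sequence")
    if GAP in seq:
        raise ValueError(f"template {tid!r} is gapped; in-silico PCR needs ungapped input")
    return tid, seq


def _scan_oriented(
    tmask: np.ndarray,
    oriented: str,
    offsets_from_3p: Sequence[int],
    table: np.ndarray,
    policy: MismatchPolicy,
) -> list[tuple[int, int, tuple[int, ...]]]:
    """All starts where ``oriented`` matches the + strand under the policy.

    ``oriented`` reads along the + strand; ``offsets_from_3p[k]`` gives the
    distance of its position *k* from the primer's chemical 3' end.
    """
    n = tmask.shape[0]
    plen = len(oriented)
    if plen > n:
        return []
    pmask = table[np.frombuffer(oriented.encode(), dtype=np.uint8)]
    ns = n - plen + 1
    mm = np.zeros(ns, dtype=np.int32)
    mm_protected = np.zeros(ns, dtype=np.int32)
    for k in range(plen):
        miss = (pmask[k] & tmask[k : k + ns]) == 0
        mm += miss
        if offsets_from_3p[k] < policy.protected_window:
            mm_protected += miss
    valid = np.flatnonzero((mm <= policy.max_mismatches) & (mm_protected == 0))
    out = []
    for s in valid.tolist():
        offsets = tuple(
            sorted(
                offsets_from_3p[k]
                for k in range(plen)
                if (pmask[k] & tmask[s + k]) == 0
            )
        )
        out.append((s, int(mm[s]), offsets))
    return out


def find_binding_sites(
    template: SequenceRecord | str,
    primer: Primer,
    policy: MismatchPolicy | None = None,
) -> list[BindingSite]:
    """Every position on both strands where the primer anneals under the policy.

    A + strand site means the primer sequence reads along the + strand (its
    3' end at ``end``); a - strand site means the primer anneals to the +
    strand, i.e. the + strand carries the primer's reverse complement (the
    primer's 3' end at ``start``). Sites are sorted by (strand, start), +
    strand first.
    """
    policy = policy or MismatchPolicy()
    tid, seq = _as_sequence(template)
    plen = len(primer.sequence)
    if policy.protected_window > plen:
        raise ValueError("protected window longer than the primer")
    table = MASK_TABLE if policy.iupac else _STRICT_TABLE
    tmask = table[np.frombuffer(seq.encode(), dtype=np.uint8)]

    sites: list[BindingSite] = []
    # + strand: primer as written; 3' end is the rightmost footprint base
    plus_offsets = [plen - 1 - k for k in range(plen)]
    for s, mm, offs in _scan_oriented(tmask, primer.sequence, plus_offsets, table, policy):
        sites.append(BindingSite(tid, "+", s + 1, s + plen, mm, offs, primer.name))
    # - strand: + strand carries revcomp(primer); 3' end at the left edge
    rc = reverse_complement(primer.sequence)
    minus_offsets = list(range(plen))
    for s, mm, offs in _scan_oriented(tmask, rc, minus_offsets, table, policy):
        sites.append(BindingSite(tid, "-", s + 1, s + plen, mm, offs, primer.name))
    return sites


def amplify(
    template: SequenceRecord | str,
    forward: Primer,
    reverse: Primer,
    policy: MismatchPolicy | None = None,
) -> list[Amplicon]:
    """All products a primer pair yields on a template.

    A product needs one primer on the + strand upstream of the other on the
    - strand (either primer may take either role, so the prediction is
    invariant under reverse-complementing the template). Pairs whose product
    would be shorter than the two primers combined are synthesis artifacts
    and are rejected; products longer than the policy maximum are dropped.
    """
    policy = policy or MismatchPolicy()
    tid, _ = _as_sequence(template)
    sites_f = find_binding_sites(template, forward, policy)
    sites_r = find_binding_sites(template, reverse, policy)
    min_len = len(forward.sequence) + len(reverse.sequence)

    products: list[Amplicon] = []
    for plus_primer, plus_sites, minus_primer, minus_sites in (
        (forward, sites_f, reverse, sites_r),
        (reverse, sites_r, forward, sites_f),
    ):
        for ps in plus_sites:
            if ps.strand != "+":
                continue
            for ms in minus_sites:
                if ms.strand != "-" or ms.start < ps.start:
                    continue
                length = ms.end - ps.start + 1
                if length < min_len or length > policy.max_product:
                    continue
                products.append(
                    Amplicon(tid, ps, ms, plus_primer.name, minus_primer.name)
                )
    products.sort(key=lambda a: (a.forward_site.start, a.length))
    return products


def multiplex_amplify(
    template: SequenceRecord | str,
    panel,
    policy: MismatchPolicy | None = None,
) -> BandSet:
    """Predicted band pattern of one template under a full multiplex panel.

    Union of products over every (species forward x universal reverse) pair
    plus the control pair; duplicate lengths collapse, with provenance
    recording every contributing primer pair per band.
    """
    policy = policy or MismatchPolicy()
    tid, _ = _as_sequence(template)
    pairs = [(fwd, panel.universal_reverse) for fwd in panel.forwards.values()]
    pairs.append(panel.control_pair)

    prov: dict[int, list[tuple[str, str]]] = {}
    for fwd, rev in pairs:
        for amp in amplify(template, fwd, rev, policy):
            prov.setdefault(amp.length, []).append((fwd.name, rev.name))
    bands = tuple(sorted(prov))
    return BandSet(
        lane=tid,
        bands=bands,
        provenance={b: tuple(dict.fromkeys(prov[b])) for b in bands},
    )


def band_matches(
    observed: int, expected: int, tolerance: tuple[int, float] = DEFAULT_BAND_TOLERANCE
) -> bool:
    """Observed band length consistent with an expected one (±5 bp or ±3%)."""
    abs_bp, rel = tolerance
    return abs(observed - expected) <= max(abs_bp, rel * expected)


def classify_bands(
    bands: Sequence[int],
    panel,
    tolerance: tuple[int, float] = DEFAULT_BAND_TOLERANCE,
) -> str:
    """Pure band-pattern call: species name, 'non-target', 'assay-failure' or
    'ambiguous'.

    Control band present plus exactly one species band (and nothing else) is
    a species call; control only is non-target DNA; no control at all means
    the reaction itself failed; any other pattern is ambiguous.
    """
    bands = sorted(set(int(b) for b in bands))
    control = any(band_matches(b, panel.control_band, tolerance) for b in bands)
    matched = [
        sp
        for sp, exp in panel.expected_bands.items()
        if any(band_matches(b, exp, tolerance) for b in bands)
    ]
    unexplained = [
        b
        for b in bands
        if not band_matches(b, panel.control_band, tolerance)
        and not any(band_matches(b, exp, tolerance) for exp in panel.expected_bands.values())
    ]
    if not control:
        return "assay-failure"
    if len(matched) == 1 and not unexplained:
        return matched[0]
    if not matched and not unexplained:
        return "non-target"
    return "ambiguous"


def specificity_matrix(
    panel,
    templates: Sequence[tuple[str, SequenceRecord | None]],
    policy: MismatchPolicy | None = None,
    tolerance: tuple[int, float] = DEFAULT_BAND_TOLERANCE,
) -> SpecificityMatrix:
    """Run the whole panel against labeled templates and judge every lane.

    ``templates`` is a sequence of (true species label, record) pairs; a
    ``None`` record is a no-template (water) control lane. The verdict
    compares the pure band-pattern call against the lane's label:
    a call equal to the label is target-confirmed; control-only is
    non-target; no control band is assay-failure; anything else (including
    a call of a *different* species, i.e. crossover) is ambiguous.
    """
    policy = policy or MismatchPolicy()
    rows: list[LaneResult] = []
    for idx, (label, record) in enumerate(templates, start=1):
        if label is None:
            raise ValueError(f"lane {idx}: unlabeled template")
        if record is None:
            bands: tuple[int, ...] = ()
            lane = f"lane{idx}|no-template"
        else:
            bandset = multiplex_amplify(record, panel, policy)
            bands = bandset.bands
            lane = f"lane{idx}|{record.id}"
        called = classify_bands(bands, panel, tolerance)
        if called == label:
            verdict = "target-confirmed"
        elif called in ("non-target", "assay-failure", "ambiguous"):
            verdict = called
        else:  # called some other species: crossover amplification
            verdict = "ambiguous"
        rows.append(LaneResult(lane, label, bands, called, verdict))
    return SpecificityMatrix(panel_name=getattr(panel, "name", ""), rows=tuple(rows))
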