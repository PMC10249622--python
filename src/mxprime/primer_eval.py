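"""Primer quality control: composition, melting temperature, self-structure
and cross-primer dimers.

The checks mirror what a bench scientist runs on a candidate panel before
synthesis: simple composition windows, a Wallace-rule Tm for quick screening,
a nearest-neighbor Tm (unified thermodynamic parameters, monovalent-salt
corrected) for users who want duplex thermodynamics, and a run-based dimer
detector over all ungapped antiparallel offsets of one primer against another.
Dimer screening is binary (a long complementary run, or any run touching a
3' terminus, is flagged); duplex free energies are deliberately out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from ._iupac import (
    GAP,
    IUPAC_SETS,
    UNAMBIGUOUS,
    AlphabetError,
    complements,
    normalize,
    validate,
)

logger = logging.getLogger(__name__)

ROLES = ("species_forward", "universal_reverse", "control_forward", "control_reverse")

__all__ = [
    "Primer",
    "PrimerQC",
    "QCConstraints",
    "DimerPolicy",
    "DimerReport",
    "SelfStructure",
    "composition_stats",
    "melting_temperature",
    "wallace_tm",
    "nearest_neighbor_tm",
    "self_structure",
    "cross_dimer",
    "qc_primer",
]


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide with its role in a multiplex assay.

    ``concentration_uM`` is carried as assay metadata only; nothing in the
    binding or amplification model consumes it.
    """

    name: str
    sequence: str
    role: str = "species_forward"
    target_species: str = ""
    concentration_uM: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize(self.sequence).replace(" ", ""))
        if not self.name:
            raise ValueError("primer name must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"invalid primer role {self.role!r}; expected one of {ROLES}")
        validate(self.sequence, allow_gaps=False, context=f"primer {self.name!r}")
        if len(self.sequence) < 10:
            raise ValueError(f"primer {self.name!r}: length {len(self.sequence)} < 10")
        if set(self.sequence) - UNAMBIGUOUS:
            logger.warning("primer %r contains IUPAC ambiguity codes", self.name)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QCConstraints:
    """Windows a primer must satisfy to pass :func:`qc_primer`."""

    length: tuple[int, int] = (15, 30)
    gc: tuple[float, float] = (0.30, 0.70)
    tm_wallace: tuple[float, float] = (45.0, 80.0)
    max_self_duplex: int = 6          # longest tolerated self-complementary run
    max_gc_3prime: int = 4            # G+C in the 3'-terminal window
    gc_3prime_window: int = 5


@dataclass(frozen=True)
class DimerPolicy:
    """When is a primer-primer complementary stretch worth rejecting.

    ``flag_run``: any run of Watson-Crick pairs at least this long is flagged.
    ``flag_3prime_run``: a run at least this long that includes either
    primer's 3'-terminal base is flagged (extension from an annealed 3' end
    is what actually produces dimer artifacts).

    The defaults are calibrated against working published multiplex panels:
    field-validated primer sets routinely contain pairwise complementary
    runs of 5-6 bp (and 3'-touching runs up to 5 bp) without producing
    dimer artifacts, so only longer stretches are flagged by default.
    Tighten both knobs for conservative de-novo design.
    """

    flag_run: int = 7
    flag_3prime_run: int = 6


@dataclass(frozen=True)
class DimerReport:
    run: int                    # longest complementary run over all offsets
    total_pairs: int            # pair count at the best (most-paired) offset
    three_prime_involved: bool  # longest-run-or-better touching a 3' terminus
    flagged: bool


@dataclass(frozen=True)
class SelfStructure:
    duplex_length: int
    three_prime_involved: bool
    hairpin: bool


@dataclass(frozen=True)
class PrimerQC:
    name: str
    length: int
    gc_fraction: float
    tm_wallace: float
    tm_nearest_neighbor: float | None
    gc_3prime: int
    gc_3prime_window: int
    self_duplex: int
    hairpin: bool
    failures: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.failures


def _gc_weight(code: str) -> float:
    """Fractional G+C contribution of one IUPAC code (|set ∩ {G,C}| / |set|)."""
    bases = IUPAC_SETS[code]
    return len(bases & {"G", "C"}) / len(bases)


def composition_stats(sequence: str, *, window: int = 5) -> tuple[int, float, int]:
    """Length, GC fraction and G+C count in the 3'-terminal ``window`` bases.

    On unambiguous sequences the counts are exact; ambiguity codes contribute
    fractionally to the GC fraction and are rounded down in the 3'-window
    count (a conservative clamp estimate).
    """
    seq = normalize(sequence)
    if not seq:
        raise ValueError("empty sequence")
    validate(seq, allow_gaps=False, context="primer sequence")
    gc = sum(_gc_weight(c) for c in seq) / len(seq)
    tail = seq[-window:]
    gc3 = int(sum(_gc_weight(c) for c in tail))
    return len(seq), gc, gc3


def wallace_tm(sequence: str) -> float:
    """Wallace rule: Tm = 2(A+T) + 4(G+C) in deg C (short-oligo screen)."""
    seq = normalize(sequence)
    if not seq:
        raise ValueError("empty sequence")
    validate(seq, allow_gaps=False, context="primer sequence")
    gc_eff = sum(_gc_weight(c) for c in seq)
    return 2.0 * len(seq) + 2.0 * gc_eff


# Unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K) for
# Watson-Crick DNA/DNA stacks in 1 M NaCl, plus duplex-initiation terms.
_NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_NN_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}
_R_GAS = 1.987  # cal / (mol K)


def _is_self_complementary(seq: str) -> bool:
    from ._iupac import reverse_complement

    return seq == reverse_complement(seq)


def nearest_neighbor_tm(
    sequence: str, *, salt_mM: float = 50.0, primer_uM: float = 0.25
) -> float:
    """Two-state nearest-neighbor Tm in deg C.

    Sums unified dH/dS over adjacent stacks with terminal initiation terms,
    applies the entropic monovalent-salt correction
    dS' = dS + 0.368 (N-1) ln[Na+], and evaluates
    Tm = 1000 dH / (dS' + R ln(CT/x)) - 273.15 with x = 4 for
    non-self-complementary oligos (x = 1, dS - 1.4 for palindromes).
    Requires an unambiguous sequence.
    """
    seq = normalize(sequence)
    if not seq:
        raise ValueError("empty sequence")
    validate(seq, allow_gaps=False, context="primer sequence")
    if set(seq) - UNAMBIGUOUS:
        raise ValueError("nearest-neighbor Tm requires an unambiguous sequence")
    if len(seq) < 2:
        raise ValueError("nearest-neighbor Tm needs at least 2 bases")

    dh = _NN_INIT[seq[0]][0] + _NN_INIT[seq[-1]][0]
    ds = _NN_INIT[seq[0]][1] + _NN_INIT[seq[-1]][1]
    for i in range(len(seq) - 1):
        h, s = _NN_PARAMS[seq[i : i + 2]]
        dh += h
        ds += s

    sym = _is_self_complementary(seq)
    if sym:
        ds -= 1.4
    ds += 0.368 * (len(seq) - 1) * math.log(salt_mM / 1000.0)
    ct = primer_uM * 1e-6
    x = 1.0 if sym else 4.0
    return 1000.0 * dh / (ds + _R_GAS * math.log(ct / x)) - 273.15


def melting_temperature(
    sequence: str,
    method: str = "wallace",
    *,
    salt_mM: float = 50.0,
    primer_uM: float = 0.25,
) -> float:
    """Dispatch between the Wallace rule and the nearest-neighbor model."""
    if method == "wallace":
        return wallace_tm(sequence)
    if method == "nearest_neighbor":
        return nearest_neighbor_tm(sequence, salt_mM=salt_mM, primer_uM=primer_uM)
    raise ValueError(f"unknown Tm method {method!r}")


def _pair_runs(a: str, c: str):
    """Yield (offset, matches, runs) for every ungapped offset of a vs c.

    ``c`` is the reverse complement of the partner, so equality of masks at
    aligned positions corresponds to an antiparallel Watson-Crick pair.
    Runs are reported as (start_in_a, start_in_c, length).
    """
    from ._iupac import IUPAC_MASK

    n, m = len(a), len(c)
    am = [IUPAC_MASK[ch] for ch in a]
    cm = [IUPAC_MASK[ch] for ch in c]
    for d in range(-(n - 1), m):
        i0 = max(0, -d)
        i1 = min(n, m - d)
        total = 0
        runs = []
        run_start = None
        for i in range(i0, i1):
            if am[i] & cm[i + d]:
                total += 1
                if run_start is None:
                    run_start = i
            elif run_start is not None:
                runs.append((run_start, run_start + d, i - run_start))
                run_start = None
        if run_start is not None:
            runs.append((run_start, run_start + d, i1 - run_start))
        yield d, total, runs


def cross_dimer(
    seq_a: str, seq_b: str, policy: DimerPolicy | None = None
) -> DimerReport:
    """Scan all antiparallel ungapped offsets of two primers for dimers.

    Symmetric in its arguments. A position pairs when the two codes can form
    a strict Watson-Crick pair (IUPAC sets intersect under complementation;
    G.T wobbles never count).
    """
    from ._iupac import reverse_complement

    policy = policy or DimerPolicy()
    a = normalize(seq_a)
    b = normalize(seq_b)
    for s, ctx in ((a, "first primer"), (b, "second primer")):
        validate(s, allow_gaps=False, context=ctx)
    c = reverse_complement(b)  # pair(a[i], b[j]) == match(a[i], c[m-1-j])
    m = len(c)

    best_run = 0
    best_total = 0
    three_prime = False
    for _d, total, runs in _pair_runs(a, c):
        best_total = max(best_total, total)
        for ra, rc, length in runs:
            best_run = max(best_run, length)
            # a's 3' base is its last index; b's 3' base maps to c index 0
            # (c = revcomp(b) reverses b, so b's 3' terminus leads c)
            touches = (ra + length - 1 == len(a) - 1) or rc == 0
            if touches and length >= policy.flag_3prime_run:
                three_prime = True
    flagged = best_run >= policy.flag_run or three_prime
    return DimerReport(best_run, best_total, three_prime, flagged)


def self_structure(
    sequence: str, *, min_stem: int = 4, min_loop: int = 3
) -> SelfStructure:
    """Longest antiparallel self-duplex run and intramolecular hairpin check.

    The self-duplex is the longest contiguous Watson-Crick run in the best
    ungapped antiparallel overlap of the primer against itself; the hairpin
    flag is true iff an intramolecular stem of at least ``min_stem`` pairs
    can close a loop of at least ``min_loop`` unpaired bases.
    """
    seq = normalize(sequence)
    validate(seq, allow_gaps=False, context="primer sequence")
    dimer = cross_dimer(seq, seq)
    n = len(seq)
    hairpin = False
    for i in range(n):
        for j in range(i + min_stem * 2 + min_loop - 1, n):
            r = 0
            while (
                i + r < j - r
                and complements(seq[i + r], seq[j - r])
            ):
                r += 1
                if r >= min_stem and (j - r + 1) - (i + r - 1) - 1 >= min_loop:
                    hairpin = True
                    break
            if hairpin:
                break
        if hairpin:
            break
    return SelfStructure(dimer.run, dimer.three_prime_involved, hairpin)


def qc_primer(
    primer: Primer | str,
    constraints: QCConstraints | None = None,
    *,
    include_nn_tm: bool = False,
) -> PrimerQC:
    """Aggregate composition, Tm and self-structure checks into a verdict.

    Violations are reported as data in ``failures`` (named by the violated
    constraint), never as exceptions. The hairpin flag is informational:
    short-stem hairpins at primer Tm rarely block extension, so they do not
    fail a primer by default.
    """
    constraints = constraints or QCConstraints()
    if isinstance(primer, str):
        # raw sequences bypass the Primer type so even out-of-spec oligos
        # (e.g. an 8-mer) get a QC verdict rather than a constructor error
        seq = normalize(primer).replace(" ", "")
        name = seq
        validate(seq, allow_gaps=False, context="primer sequence")
    else:
        seq = primer.sequence
        name = primer.name
    length, gc, gc3 = composition_stats(seq, window=constraints.gc_3prime_window)
    tm_w = wallace_tm(seq)
    tm_nn = None
    if include_nn_tm and not (set(seq) - UNAMBIGUOUS):
        tm_nn = nearest_neighbor_tm(seq)
    struct = self_structure(seq)

    failures: list[str] = []
    if not (constraints.length[0] <= length <= constraints.length[1]):
        failures.append("length")
    if not (constraints.gc[0] <= gc <= constraints.gc[1]):
        failures.append("gc")
    if not (constraints.tm_wallace[0] <= tm_w <= constraints.tm_wallace[1]):
        failures.append("tm")
    if struct.duplex_length > constraints.max_self_duplex:
        failures.append("self_duplex")
    if gc3 > constraints.max_gc_3prime:
        failures.append("gc_3prime")

    return PrimerQC(
        name=name,
        length=length,
        gc_fraction=gc,
        tm_wallace=tm_w,
        tm_nearest_neighbor=tm_nn,
        gc_3prime=gc3,
        gc_3prime_window=constraints.gc_3prime_window,
        self_duplex=struct.duplex_length,
        hairpin=struct.hairpin,
        failures=tuple(failures),
    )
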