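"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: the IUPAC tables are
restated from the standard code definitions and every scan is a plain
position-by-position loop, so agreement with the vectorized implementation
is a real two-route check.
"""

from __future__ import annotations

import itertools

_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    out = []
    for ch in reversed(seq):
        bases = _SETS[ch]
        comp = {_COMP[b] for b in bases}
        for code, s in _SETS.items():
            if set(s) == comp:
                out.append(code)
                break
    return "".join(out)


def _compat(p: str, t: str, iupac: bool) -> bool:
    if iupac:
        return bool(set(_SETS[p]) & set(_SETS[t]))
    return p == t and p in "ACGT"


def naive_binding_sites(template: str, primer: str, *, max_mismatches=2,
                        protected_window=3, iupac=True):
    """All 3'-anchored annealing sites as (strand, start, end, mismatches),
    1-based + strand coordinates, scanned one position at a time."""
    sites = []
    n, L = len(template), len(primer)
    for start in range(n - L + 1):
        mm = 0
        ok = True
        for k in range(L):
            if not _compat(primer[k], template[start + k], iupac):
                mm += 1
                if L - 1 - k < protected_window or mm > max_mismatches:
                    ok = False
                    break
        if ok:
            sites.append(("+", start + 1, start + L, mm))
    rc = _revcomp(primer)
    for start in range(n - L + 1):
        mm = 0
        ok = True
        for k in range(L):
            if not _compat(rc[k], template[start + k], iupac):
                mm += 1
                if k < protected_window or mm > max_mismatches:
                    ok = False
                    break
        if ok:
            sites.append(("-", start + 1, start + L, mm))
    return sites


def brute_force_panel_choice(bands_by_species: dict[str, list[int]],
                             control_band: int, min_separation: int):
    """Exhaustively pick one band per species maximizing the minimum pairwise
    gap (control included); ties broken toward the earlier index tuple.
    Returns the chosen {species: band} or None if infeasible."""
    species = sorted(bands_by_species)
    best = None
    best_choice = None
    for combo in itertools.product(*(range(len(bands_by_species[s])) for s in species)):
        bands = [bands_by_species[s][i] for s, i in zip(species, combo)] + [control_band]
        if len(set(bands)) != len(bands):
            continue
        ordered = sorted(bands)
        gap = min(b - a for a, b in zip(ordered, ordered[1:]))
        if gap < min_separation:
            continue
        key = (gap, tuple(-i for i in combo))
        if best is None or key > best:
            best = key
            best_choice = {s: bands_by_species[s][i] for s, i in zip(species, combo)}
    return best_choice
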