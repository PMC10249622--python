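"""Seeded synthetic fixtures with planted ground truth.

Two generators make every other module testable without any download:

* :func:`simulate_species_alignment` emulates the statistical structure a
  species-diagnostic marker needs — low intraspecific divergence, higher
  interspecific divergence, and a controlled number of planted
  species-private (diagnostic) columns per species.
* :func:`synthesize_templates` builds ungapped PCR templates that carry a
  panel's primer binding sites at exactly the spacings implied by the
  panel's expected band sizes (non-targets carry only the control sites),
  so the whole in-silico PCR + gel pipeline has known expected output.

Substitutions are uniform over the three alternative bases (Jukes-Cantor
flavored, no transition bias); random flanks and fillers are rejection
resampled until the panel produces exactly the planted band set, so planted
truth is exact. All output is a pure function of the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._iupac import reverse_complement
from .insilico_pcr import MismatchPolicy, multiplex_amplify
from .seqio import SequenceRecord, SpeciesAlignment

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

__all__ = ["SyntheticTruth", "simulate_species_alignment", "synthesize_templates"]


@dataclass(frozen=True)
class SyntheticTruth:
    """What a synthetic fixture planted, for exact-recovery assertions."""

    seed: int
    species: tuple[str, ...]
    planted_diagnostics: dict[str, tuple[tuple[int, str], ...]] = field(
        default_factory=dict
    )  # species -> ((1-based column, residue), ...)
    expected_bands: dict[str, tuple[int, ...]] = field(default_factory=dict)
    planted_sites: dict[str, tuple[tuple[str, int], ...]] = field(
        default_factory=dict
    )  # template id -> ((primer name, 1-based start), ...)
    intra_divergence: float = 0.0
    inter_divergence: float = 0.0


def _mutate(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def simulate_species_alignment(
    n_species: int = 3,
    n_per_species: int = 5,
    columns: int = 600,
    intra_div: float = 0.002,
    inter_div: float = 0.05,
    n_planted_diagnostics: int = 2,
    seed: int = 0,
) -> tuple[SpeciesAlignment, SyntheticTruth]:
    """Simulate K species groups around one random ancestor.

    Each species consensus differs from the ancestor at ``inter_div x
    columns`` random background sites plus exactly
    ``n_planted_diagnostics`` planted species-private sites; individuals
    then mutate from their consensus at ``intra_div`` per site. Planted
    columns are disjoint across species and untouched by any background or
    individual mutation, so with zero background divergence they are
    exactly the diagnostic columns of the alignment.
    """
    if not 0 <= intra_div <= 1 or not 0 <= inter_div <= 1:
        raise ValueError("divergences must be in [0, 1]")
    if n_species < 2 or n_per_species < 1 or columns < 1:
        raise ValueError("need >= 2 species, >= 1 record each, >= 1 column")
    n_planted_total = n_planted_diagnostics * n_species
    if n_planted_total > columns:
        raise ValueError(
            f"cannot plant {n_planted_total} diagnostic columns in {columns} columns"
        )

    rng = np.random.default_rng(seed)
    labels = tuple(f"sp{i + 1:02d}" for i in range(n_species))
    ancestor = rng.choice(_BASES, size=columns)

    planted_cols = rng.choice(columns, size=n_planted_total, replace=False)
    planted: dict[str, list[tuple[int, str]]] = {lab: [] for lab in labels}
    consensi = {lab: ancestor.copy() for lab in labels}
    for i, col0 in enumerate(sorted(planted_cols.tolist())):
        lab = labels[i % n_species]
        new = _mutate(str(ancestor[col0]), rng)
        consensi[lab][col0] = new
        planted[lab].append((col0 + 1, new))
    protected = set(int(c) for c in planted_cols)

    free_cols = np.array([c for c in range(columns) if c not in protected])
    n_bg = int(round(inter_div * columns))
    for lab in labels:
        if n_bg:
            bg = rng.choice(free_cols, size=min(n_bg, free_cols.size), replace=False)
            for col0 in bg.tolist():
                consensi[lab][col0] = _mutate(str(consensi[lab][col0]), rng)

    groups: dict[str, list[SequenceRecord]] = {}
    for lab in labels:
        records = []
        for j in range(n_per_species):
            seq = consensi[lab].copy()
            if intra_div > 0:
                hits = np.flatnonzero(rng.random(columns) < intra_div)
                for col0 in hits.tolist():
                    if col0 not in protected:
                        seq[col0] = _mutate(str(seq[col0]), rng)
            records.append(
                SequenceRecord(id=f"{lab}_r{j + 1}", residues="".join(seq.tolist()))
            )
        groups[lab] = records

    truth = SyntheticTruth(
        seed=seed,
        species=labels,
        planted_diagnostics={
            lab: tuple(sorted(planted[lab])) for lab in labels
        },
        intra_divergence=intra_div,
        inter_divergence=inter_div,
    )
    return SpeciesAlignment(columns=columns, groups=groups), truth


def _random_filler(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length).tolist()) if length > 0 else ""


def synthesize_templates(
    panel,
    species: Sequence[str],
    *,
    flank_length: int = 30,
    cassette_gap: int = 25,
    seed: int = 0,
    policy: MismatchPolicy | None = None,
    max_attempts: int = 50,
) -> tuple[list[tuple[str, SequenceRecord]], SyntheticTruth]:
    """Templates that reproduce a panel's expected band geometry exactly.

    For each requested label the template embeds the control-primer sites
    spaced to yield the panel's control band and, when the label is one of
    the panel's target species, that species' forward site and the
    universal-reverse complement spaced to yield its expected band. Random
    flanks and fillers are resampled until the panel's band set on the
    template equals the planted set (accidental primer matches in random
    sequence are thereby scrubbed).
    """
    policy = policy or MismatchPolicy()
    rng = np.random.default_rng(seed)
    cf, cr = panel.control_pair
    ctrl_fill = panel.control_band - len(cf.sequence) - len(cr.sequence)
    if ctrl_fill < 0:
        raise ValueError(
            f"control band {panel.control_band} bp shorter than the control primers"
        )

    templates: list[tuple[str, SequenceRecord]] = []
    expected: dict[str, tuple[int, ...]] = {}
    planted_sites: dict[str, tuple[tuple[str, int], ...]] = {}
    for label in species:
        is_target = label in panel.forwards
        want: list[int] = [panel.control_band]
        if is_target:
            fwd = panel.forwards[label]
            rev = panel.universal_reverse
            sp_fill = (
                panel.expected_bands[label] - len(fwd.sequence) - len(rev.sequence)
            )
            if sp_fill < 0:
                raise ValueError(
                    f"expected band {panel.expected_bands[label]} bp for {label!r} "
                    "shorter than its primers"
                )
            want.append(panel.expected_bands[label])

        tid = f"synthetic|{label.replace(' ', '_')}"
        for attempt in range(max_attempts):
            parts = [_random_filler(flank_length, rng)]
            sites: list[tuple[str, int]] = []
            pos = len(parts[0])
            parts.append(cf.sequence)
            sites.append((cf.name, pos + 1))
            parts.append(_random_filler(ctrl_fill, rng))
            parts.append(reverse_complement(cr.sequence))
            sites.append((cr.name, pos + len(cf.sequence) + ctrl_fill + 1))
            if is_target:
                parts.append(_random_filler(cassette_gap, rng))
                pos = sum(len(p) for p in parts)
                parts.append(fwd.sequence)
                sites.append((fwd.name, pos + 1))
                parts.append(_random_filler(sp_fill, rng))
                parts.append(reverse_complement(rev.sequence))
                sites.append((rev.name, pos + len(fwd.sequence) + sp_fill + 1))
            parts.append(_random_filler(flank_length, rng))
            record = SequenceRecord(id=tid, residues="".join(parts))
            bands = multiplex_amplify(record, panel, policy).bands
            if list(bands) == sorted(want):
                break
            logger.debug(
                "template %s attempt %d produced %s, want %s; resampling",
                tid,
                attempt + 1,
                bands,
                sorted(want),
            )
        else:
            raise RuntimeError(
                f"could not scrub accidental primer sites for {label!r} "
                f"after {max_attempts} attempts"
            )
        templates.append((label, record))
        expected[tid] = tuple(sorted(want))
        planted_sites[tid] = tuple(sites)

    truth = SyntheticTruth(
        seed=seed,
        species=tuple(dict.fromkeys(species)),
        expected_bands=expected,
        planted_sites=planted_sites,
    )
    return templates, truth
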