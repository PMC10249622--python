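"""Virtual agarose gel: ladder calibration, band placement and lane calls.

First-order agarose behavior: migration distance is linear in the log of
fragment length, d(L) = a + b log10(L) with b < 0. The model is calibrated
by least squares on ladder points; the default calibration is a synthetic
100-1000 bp ladder (clearly non-empirical, shipped for rendering and
resolvability checks only). Species calls are made on band *lengths* with
the shared +-5 bp / +-3% tolerance, never on millimetres, so calls do not
depend on the cosmetic migration model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .insilico_pcr import BandSet, DEFAULT_BAND_TOLERANCE, classify_bands

logger = logging.getLogger(__name__)

__all__ = [
    "GelModel",
    "GelLane",
    "calibrate_gel",
    "default_gel_model",
    "DEFAULT_LADDER",
    "migration_distance",
    "resolvable",
    "call_species",
    "render_gel",
]

#: synthetic 100-bp ladder: distances generated from d = 160 - 50 log10(L);
#: a rendering convention, not an empirical mobility curve
DEFAULT_LADDER: tuple[tuple[int, float], ...] = tuple(
    (L, 160.0 - 50.0 * float(np.log10(L))) for L in range(100, 1001, 100)
)


@dataclass(frozen=True)
class GelModel:
    """Ladder-calibrated log-linear migration model d(L) = a + b log10 L."""

    calibration: tuple[tuple[int, float], ...]
    a: float
    b: float
    residuals: tuple[float, ...]
    resolution_threshold_mm: float = 2.0
    gel_length_mm: float = 80.0
    agarose_pct: float = 2.0  # metadata only

    def __post_init__(self) -> None:
        if self.b >= 0:
            raise ValueError("fitted slope must be negative (longer runs shorter)")


@dataclass(frozen=True)
class GelLane:
    """One rendered lane: bands with their migration distances."""

    label: str
    bands: tuple[tuple[int, float], ...]  # (bp, mm), sorted by migration
    source: BandSet | None = None


def calibrate_gel(
    points: Sequence[tuple[int, float]],
    *,
    resolution_threshold_mm: float = 2.0,
    gel_length_mm: float = 80.0,
    agarose_pct: float = 2.0,
) -> GelModel:
    """Least-squares fit of migration distance against log10 fragment length.

    Requires at least two points with distinct lengths and positive
    distances; points whose distances do not decrease with length are
    accepted with a warning (the fit proceeds anyway).
    """
    if len(points) < 2:
        raise ValueError("gel calibration needs at least 2 points")
    lengths = [p[0] for p in points]
    dists = [p[1] for p in points]
    if len(set(lengths)) != len(lengths):
        raise ValueError("duplicate fragment length in calibration points")
    if any(l <= 0 for l in lengths) or any(d <= 0 for d in dists):
        raise ValueError("calibration lengths and distances must be positive")
    ordered = sorted(points)
    if any(d2 >= d1 for (_, d1), (_, d2) in zip(ordered, ordered[1:])):
        logger.warning("calibration points are not monotonically decreasing")
    x = np.log10(np.asarray(lengths, dtype=float))
    y = np.asarray(dists, dtype=float)
    b, a = np.polyfit(x, y, 1)
    resid = tuple((y - (a + b * x)).tolist())
    return GelModel(
        calibration=tuple((int(l), float(d)) for l, d in points),
        a=float(a),
        b=float(b),
        residuals=resid,
        resolution_threshold_mm=resolution_threshold_mm,
        gel_length_mm=gel_length_mm,
        agarose_pct=agarose_pct,
    )


def default_gel_model() -> GelModel:
    """The model fitted to the packaged synthetic 100-bp ladder."""
    return calibrate_gel(DEFAULT_LADDER)


def migration_distance(model: GelModel, length: float) -> float:
    """Unclamped migration distance in mm; rendering clamps separately."""
    if length <= 0:
        raise ValueError(f"fragment length must be positive, got {length}")
    return model.a + model.b * float(np.log10(length))


def resolvable(model: GelModel, len1: float, len2: float) -> bool:
    """Can two fragment lengths be told apart on this gel."""
    gap = abs(migration_distance(model, len1) - migration_distance(model, len2))
    return gap >= model.resolution_threshold_mm


def call_species(
    bandset: BandSet | Sequence[int],
    panel,
    tolerance: tuple[int, float] = DEFAULT_BAND_TOLERANCE,
) -> str:
    """Species call from a band pattern (pure function of band lengths).

    Control band plus exactly one species band within tolerance names the
    species; control only is 'non-target'; no control is 'assay-failure';
    anything else is 'ambiguous'. Invariant under band order and duplicates.
    """
    bands = bandset.bands if isinstance(bandset, BandSet) else tuple(bandset)
    return classify_bands(bands, panel, tolerance)


def _clamp(model: GelModel, d: float) -> float:
    return min(max(d, 0.0), model.gel_length_mm)


def render_gel(
    lanes: Sequence[BandSet],
    model: GelModel | None = None,
    ladder: Sequence[tuple[int, float]] | None = None,
    *,
    row_mm: float = 2.0,
) -> str:
    """Deterministic ASCII gel diagram: ladder lane first, then each lane.

    Rows are ``row_mm`` millimetre bins down the gel; bands render as
    ``===``. Ladder rungs are annotated with their fragment lengths.
    """
    model = model or default_gel_model()
    ladder = list(ladder) if ladder is not None else [(L, None) for L, _ in DEFAULT_LADDER]
    ladder_rows = {
        int(round(_clamp(model, migration_distance(model, L)) / row_mm)): L
        for L, _ in ladder
    }
    lane_rows: list[dict[int, int]] = []
    for bs in lanes:
        rows: dict[int, int] = {}
        for bp in bs.bands:
            rows[int(round(_clamp(model, migration_distance(model, bp)) / row_mm))] = bp
        lane_rows.append(rows)

    n_rows = int(model.gel_length_mm / row_mm) + 1
    width = 7
    header = "mm".rjust(6) + " | " + "L".center(width) + "".join(
        bs.lane[:width].center(width) for bs in lanes
    )
    lines = [header, "-" * len(header)]
    for r in range(n_rows):
        cells = []
        if r in ladder_rows:
            cells.append(f"={ladder_rows[r]}=".center(width))
        else:
            cells.append(" " * width)
        for rows in lane_rows:
            cells.append(("===" if r in rows else "").center(width))
        lines.append(f"{r * row_mm:6.0f} | " + "".join(cells))
    return "\n".join(lines)
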