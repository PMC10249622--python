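"""Packaged multiplex panels.

Two published assays for the three commercially exploited *Brachyplatystoma*
catfishes ship with the package: a COI panel (species bands 254 / 405 / 466
bp, 16S control 650 bp) and a mitochondrial control-region panel (580 / 451
/ 290 bp, 16S control 160 bp). Each combines three species-specific forward
primers with one universal reverse primer plus a 16S rDNA control pair;
primer concentrations are carried as metadata.
"""

from __future__ import annotations

from importlib import resources

from .panel_design import MultiplexPanel
from .seqio import read_panel

__all__ = ["builtin_panel", "BUILTIN_PANELS"]

BUILTIN_PANELS = ("coi", "cr")


def builtin_panel(marker: str) -> MultiplexPanel:
    """Load a packaged panel by marker name (``"coi"`` or ``"cr"``)."""
    key = marker.strip().lower()
    if key not in BUILTIN_PANELS:
        raise KeyError(f"unknown builtin panel {marker!r}; choose from {BUILTIN_PANELS}")
    with resources.as_file(
        resources.files("mxprime.data").joinpath(f"{key}_panel.json")
    ) as path:
        return read_panel(path)
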