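"""File-format boundary: FASTA, species manifests and panel definition files.

All sequence text entering the package passes through this module, which
normalizes case, converts legacy ``.`` gaps to ``-`` and rejects characters
outside the IUPAC DNA alphabet, so downstream modules can assume clean input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from ._iupac import GAP, AlphabetError, normalize, validate

logger = logging.getLogger(__name__)

PANEL_FORMAT = "mxprime-panel/1"
FASTA_WIDTH = 70  # cosmetic line wrap on write

__all__ = [
    "SequenceRecord",
    "SpeciesAlignment",
    "SpeciesManifest",
    "AlphabetError",
    "AlignmentError",
    "DuplicateIdError",
    "ManifestError",
    "PanelSchemaError",
    "read_fasta",
    "write_fasta",
    "read_manifest",
    "read_grouped_alignment",
    "read_panel",
    "write_panel",
]


class AlignmentError(ValueError):
    """Records violate an alignment invariant (e.g. unequal lengths)."""


class DuplicateIdError(ValueError):
    """Two records in one file share an identifier."""


class ManifestError(ValueError):
    """Species manifest does not cover the alignment, or is malformed."""


class PanelSchemaError(ValueError):
    """A panel definition file is missing a mandatory field or role."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single DNA sequence, possibly gapped, over the IUPAC alphabet."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        validate(self.residues, context=f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class SpeciesManifest:
    """Mapping of record ids to species labels (insertion-ordered rows)."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec_id, label in self.rows:
            if not rec_id or not label:
                raise ManifestError(f"manifest row ({rec_id!r}, {label!r}) is incomplete")
            if rec_id in seen:
                raise ManifestError(f"duplicate id {rec_id!r} in manifest")
            seen.add(rec_id)

    def label_of(self) -> dict[str, str]:
        return dict(self.rows)


@dataclass
class SpeciesAlignment:
    """A gapped multiple alignment partitioned into species groups."""

    columns: int
    groups: dict[str, list[SequenceRecord]]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise AlignmentError("at least 2 species required")
        for label, records in self.groups.items():
            if not label:
                raise AlignmentError("empty species label")
            if not records:
                raise AlignmentError(f"species {label!r} has no records")
            for rec in records:
                if len(rec) != self.columns:
                    raise AlignmentError(
                        f"record {rec.id!r} has {len(rec)} columns, expected {self.columns}"
                    )

    @property
    def species(self) -> list[str]:
        return list(self.groups)

    def records(self) -> Iterable[tuple[str, SequenceRecord]]:
        for label, recs in self.groups.items():
            for rec in recs:
                yield label, rec


def _clean_residues(rec_id: str, raw: str) -> str:
    seq = normalize(raw)
    if "." in raw:
        logger.warning("record %r: '.' gaps converted to '-'", rec_id)
    try:
        validate(seq, context=f"record {rec_id!r}")
    except AlphabetError:
        raise
    return seq


def read_fasta(path: str | Path, *, aligned: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into validated, upper-cased records.

    With ``aligned`` set, all records must have equal length (gaps included).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise DuplicateIdError(f"duplicate record id {bio.id!r} in {path}")
        seen.add(bio.id)
        desc = bio.description[len(bio.id):].strip() if bio.description else ""
        records.append(SequenceRecord(bio.id, _clean_residues(bio.id, str(bio.seq)), desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if aligned:
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            raise AlignmentError(
                f"{path}: unequal record lengths {sorted(lengths)} under aligned mode"
            )
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> Path:
    """Write records as FASTA, wrapped at 70 columns."""
    path = Path(path)
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WIDTH)
        writer.write_file(bio)
    return path


def read_manifest(path: str | Path) -> SpeciesManifest:
    """Read a 2-column TSV (record id, species label); '#' lines are comments."""
    rows: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ManifestError(f"{path}:{lineno}: expected 2 tab-separated columns")
        rows.append((parts[0].strip(), parts[1].strip()))
    return SpeciesManifest(tuple(rows))


def read_grouped_alignment(
    fasta_path: str | Path, manifest_path: str | Path
) -> SpeciesAlignment:
    """Read an aligned FASTA plus manifest into a species-grouped alignment.

    Every FASTA id must appear in the manifest; manifest rows whose id is
    absent from the FASTA are ignored with a logged warning.
    """
    records = read_fasta(fasta_path, aligned=True)
    manifest = read_manifest(manifest_path)
    label_of = manifest.label_of()
    fasta_ids = {r.id for r in records}
    for rec_id in label_of:
        if rec_id not in fasta_ids:
            logger.warning("manifest id %r not present in FASTA; row ignored", rec_id)
    groups: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        if rec.id not in label_of:
            raise ManifestError(f"FASTA record {rec.id!r} missing from manifest")
        groups.setdefault(label_of[rec.id], []).append(rec)
    return SpeciesAlignment(columns=len(records[0]), groups=groups)


# --- panel definition files -------------------------------------------------

def read_panel(path: str | Path):
    """Read a JSON panel definition (format ``mxprime-panel/1``)."""
    from .panel_design import MultiplexPanel  # deferred: seqio is panel_design's IO layer
    from .primer_eval import Primer

    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise PanelSchemaError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("format") != PANEL_FORMAT:
        raise PanelSchemaError(
            f"{path}: expected format {PANEL_FORMAT!r}, got {doc.get('format')!r}"
        )
    for key in ("assay", "marker", "primers", "expected_bands_bp", "control_band_bp"):
        if key not in doc:
            raise PanelSchemaError(f"{path}: missing mandatory field {key!r}")

    primers: list[Primer] = []
    for row in doc["primers"]:
        for key in ("name", "sequence", "role"):
            if key not in row:
                raise PanelSchemaError(f"{path}: primer row missing field {key!r}")
        primers.append(
            Primer(
                name=row["name"],
                sequence=row["sequence"],
                role=row["role"],
                target_species=row.get("target_species", ""),
                concentration_uM=row.get("concentration_uM"),
            )
        )

    by_role: dict[str, list[Primer]] = {}
    for p in primers:
        by_role.setdefault(p.role, []).append(p)
    if "universal_reverse" not in by_role:
        raise PanelSchemaError(f"{path}: panel lacks a universal_reverse primer")
    if "control_forward" not in by_role or "control_reverse" not in by_role:
        raise PanelSchemaError(f"{path}: panel lacks a control primer pair")

    forwards = {p.target_species: p for p in by_role.get("species_forward", [])}
    return MultiplexPanel(
        name=doc["assay"],
        marker=doc["marker"],
        forwards=forwards,
        universal_reverse=by_role["universal_reverse"][0],
        control_pair=(by_role["control_forward"][0], by_role["control_reverse"][0]),
        expected_bands=dict(doc["expected_bands_bp"]),
        control_band=int(doc["control_band_bp"]),
    )


def write_panel(panel, path: str | Path) -> Path:
    """Write a panel as ``mxprime-panel/1`` JSON; inverse of :func:`read_panel`."""
    path = Path(path)
    rows = []
    for p in panel.primers():
        row = {"name": p.name, "sequence": p.sequence, "role": p.role}
        if p.target_species:
            row["target_species"] = p.target_species
        if p.concentration_uM is not None:
            row["concentration_uM"] = p.concentration_uM
        rows.append(row)
    doc = {
        "format": PANEL_FORMAT,
        "assay": panel.name,
        "marker": panel.marker,
        "primers": rows,
        "expected_bands_bp": panel.expected_bands,
        "control_band_bp": panel.control_band,
    }
    path.write_text(json.dumps(doc, indent=2, ensure_ascii=False) + "\n")
    return path
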