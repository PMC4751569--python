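"""Plain-text selection format: which segments are standards and which are fibrils.

A selection file replaces interactive picking.  The native dialect is
tab-separated, one record per line::

    kind<TAB>label<TAB>x0<TAB>y0<TAB>x1<TAB>y1<TAB>width

``#`` begins a comment, blank lines are skipped, and an optional header line
is auto-detected by a non-numeric third field.  A JSON mirror with identical
fields exists for programmatic use (dispatched on the ``.json`` suffix).

Coordinates are 0-based pixel centers (see :mod:`fibrilmpl.image_io`);
out-of-bounds endpoints are legal here and handled at sampling time, because
users routinely click to the image edge.  ``width`` is the full band width.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List

from .errors import SelectionParseError, SelectionValidationError

KINDS = ("standard", "fibril")

_COLUMNS = ("kind", "label", "x0", "y0", "x1", "y1", "width")


@dataclass(frozen=True)
class SelectionLine:
    """One user-designated straight segment with a band width.

    ``kind`` is ``"standard"`` (known mass per unit length, used for
    calibration) or ``"fibril"`` (the assembly being measured).  Curved
    filaments are handled by chaining several short segments that share a
    label prefix.
    """

    kind: str
    label: str
    x0: float
    y0: float
    x1: float
    y1: float
    width: float

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SelectionValidationError(
                f"selection {self.label!r}: unknown kind {self.kind!r}"
            )
        if self.width < 1:
            raise SelectionValidationError(
                f"selection {self.label!r}: width must be >= 1 px, got {self.width}"
            )
        if self.length < 2:
            raise SelectionValidationError(
                f"selection {self.label!r}: axial length must be >= 2 px, got {self.length:g}"
            )

    @property
    def length(self) -> float:
        """Euclidean length of the axis segment in pixels."""
        return math.hypot(self.x1 - self.x0, self.y1 - self.y0)

    def with_width(self, width: float) -> "SelectionLine":
        return SelectionLine(self.kind, self.label, self.x0, self.y0, self.x1, self.y1, width)


@dataclass
class SelectionSet:
    """An ordered collection of selections applying to one image."""

    lines: List[SelectionLine] = field(default_factory=list)
    image_ref: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for line in self.lines:
            key = (line.kind, line.label)
            if key in seen:
                raise SelectionValidationError(
                    f"duplicate label {line.label!r} for kind {line.kind!r}"
                )
            seen.add(key)

    def by_kind(self, kind: str) -> List[SelectionLine]:
        return [s for s in self.lines if s.kind == kind]

    @property
    def standards(self) -> List[SelectionLine]:
        return self.by_kind("standard")

    @property
    def fibrils(self) -> List[SelectionLine]:
        return self.by_kind("fibril")


def _fmt(x: float) -> str:
    # repr() is the shortest string that round-trips the float exactly
    return repr(float(x))


def _parse_tsv(text: str, path: Path) -> SelectionSet:
    lines: List[SelectionLine] = []
    image_ref = ""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("image_ref:"):
                image_ref = body.split(":", 1)[1].strip()
            continue
        fields = [f.strip() for f in raw.rstrip("\r\n").split("\t")]
        if len(fields) != len(_COLUMNS):
            raise SelectionParseError(
                f"{path}:{lineno}: expected {len(_COLUMNS)} tab-separated fields, "
                f"got {len(fields)}"
            )
        # header detection: third column of a data row must be numeric
        try:
            float(fields[2])
        except ValueError:
            if lines:
                raise SelectionParseError(f"{path}:{lineno}: non-numeric x0 {fields[2]!r}")
            continue
        kind, label = fields[0], fields[1]
        if kind not in KINDS:
            raise SelectionParseError(
                f"{path}:{lineno}: unknown kind {kind!r} (expected one of {KINDS})"
            )
        try:
            x0, y0, x1, y1, width = (float(v) for v in fields[2:])
        except ValueError as exc:
            raise SelectionParseError(f"{path}:{lineno}: {exc}") from exc
        lines.append(SelectionLine(kind, label, x0, y0, x1, y1, width))
    return SelectionSet(lines=lines, image_ref=image_ref)


def _parse_json(text: str, path: Path) -> SelectionSet:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SelectionParseError(f"{path}: invalid JSON: {exc}") from exc
    records = doc.get("lines", []) if isinstance(doc, dict) else doc
    image_ref = doc.get("image_ref", "") if isinstance(doc, dict) else ""
    lines = []
    for i, rec in enumerate(records):
        missing = [c for c in _COLUMNS if c not in rec]
        if missing:
            raise SelectionParseError(f"{path}: record {i}: missing fields {missing}")
        lines.append(
            SelectionLine(
                str(rec["kind"]), str(rec["label"]),
                float(rec["x0"]), float(rec["y0"]),
                float(rec["x1"]), float(rec["y1"]),
                float(rec["width"]),
            )
        )
    return SelectionSet(lines=lines, image_ref=str(image_ref))


def parse_selections(path) -> SelectionSet:
    """Parse a selection file (TSV dialect, or JSON mirror for ``.json``).

    File order is preserved; comments and blank lines are skipped; CRLF and
    trailing whitespace are tolerated.

    Raises
    ------
    SelectionParseError
        Malformed rows, with the offending line number.
    SelectionValidationError
        Rows violating geometric invariants (width < 1, near-zero length,
        duplicate labels within a kind).
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise OSError(f"cannot read selection file: {path}: {exc}") from exc
    if path.suffix.lower() == ".json":
        return _parse_json(text, path)
    return _parse_tsv(text, path)


def write_selections(sel: SelectionSet, path) -> None:
    """Write ``sel`` so that :func:`parse_selections` reproduces it exactly.

    The output dialect follows the file suffix (``.json`` for the JSON
    mirror, TSV otherwise).  Floats are written in shortest round-trip form.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "image_ref": sel.image_ref,
            "lines": [
                {
                    "kind": s.kind, "label": s.label,
                    "x0": s.x0, "y0": s.y0, "x1": s.x1, "y1": s.y1,
                    "width": s.width,
                }
                for s in sel.lines
            ],
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
        return
    rows = ["\t".join(_COLUMNS)]
    if sel.image_ref:
        rows.insert(0, f"# image_ref: {sel.image_ref}")
    for s in sel.lines:
        rows.append(
            "\t".join(
                [s.kind, s.label, _fmt(s.x0), _fmt(s.y0), _fmt(s.x1), _fmt(s.y1), _fmt(s.width)]
            )
        )
    path.write_text("\n".join(rows) + "\n")
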