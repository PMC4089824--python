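"""Reading and writing discrete morphological character matrices.

Matrices are tables of taxa (rows) by characters (columns) whose cells are
single-digit state codes 0-9, ``?`` for unobserved data, or ``-`` for
logically inapplicable characters.  Three plain-text dialects are supported:

``tnt``
    Hennig86/TNT ``xread`` block: header line ``xread``, a dimensions line
    ``<n_chars> <n_taxa>``, one whitespace-separated row per taxon, and a
    terminating ``;``.  Optional character notes follow the terminator as
    lines ``' <index> <text>``.
``nexus``
    A minimal ``DATA`` block with ``FORMAT SYMBOLS="0123456789" MISSING=?
    GAP=-``.  Character notes are carried in bracketed comments so that
    other NEXUS readers skip them.
``table``
    One row per taxon: first token is the taxon label, the remaining tokens
    are cells (either one token per cell or a single contiguous string).
    Lines starting with ``#`` carry character notes.

Taxon labels keep internal spaces only in the ``table`` dialect; TNT and
NEXUS output replaces spaces with underscores.  Character indices are
1-based everywhere user-facing.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "INAPPLICABLE",
    "CellValue",
    "CharacterMatrix",
    "TaxonMetadata",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "load_helopini_fixture",
]

#: Internal cell code for '?' (state not observed).
MISSING: int = -1
#: Internal cell code for '-' (character logically inapplicable).
INAPPLICABLE: int = -2

_FORMATS = ("tnt", "nexus", "table")


class MatrixFormatError(ValueError):
    """Raised when a matrix document cannot be parsed."""


@dataclass(frozen=True)
class CellValue:
    """A single matrix cell: a coded state, or a missing/inapplicable mark."""

    kind: str  # "state" | "missing" | "inapplicable"
    state: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "state":
            if self.state is None or not 0 <= self.state <= 9:
                raise ValueError("state cells need an integer state 0-9")
        elif self.kind in ("missing", "inapplicable"):
            if self.state is not None:
                raise ValueError(f"{self.kind} cells carry no state")
        else:
            raise ValueError(f"unknown cell kind {self.kind!r}")

    @property
    def symbol(self) -> str:
        if self.kind == "state":
            return str(self.state)
        return "?" if self.kind == "missing" else "-"


def _code_of(symbol: str, taxon: str, column: int) -> int:
    if symbol == "?":
        return MISSING
    if symbol == "-":
        return INAPPLICABLE
    if len(symbol) == 1 and symbol.isdigit():
        return int(symbol)
    raise MatrixFormatError(
        f"illegal cell symbol {symbol!r} for taxon {taxon!r}, character {column}"
        " (only digits 0-9, '?' and '-' are accepted; polymorphic codings are not supported)"
    )


def _symbol_of(code: int) -> str:
    if code == MISSING:
        return "?"
    if code == INAPPLICABLE:
        return "-"
    return str(code)


@dataclass
class CharacterMatrix:
    """A taxa x characters grid of discrete state codes.

    ``codes`` holds one int8 per cell: 0-9 for states, :data:`MISSING` for
    '?', :data:`INAPPLICABLE` for '-'.
    """

    taxon_labels: list[str]
    codes: np.ndarray
    character_notes: list[str] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        if len(self.taxon_labels) != self.codes.shape[0]:
            raise ValueError("one row per taxon required")
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            raise ValueError("taxon labels must be unique")
        if any(not t for t in self.taxon_labels):
            raise ValueError("taxon labels must be non-empty")
        bad = (self.codes > 9) | (self.codes < INAPPLICABLE)
        if bad.any():
            raise ValueError("cells must be states 0-9, MISSING or INAPPLICABLE")
        if self.character_notes is not None and len(self.character_notes) != self.n_chars:
            raise ValueError("need one character note per character")

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_chars(self) -> int:
        return self.codes.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self.taxon_labels.index(taxon)]

    def column(self, char_id: int) -> np.ndarray:
        """Character column by 1-based character number."""
        if not 1 <= char_id <= self.n_chars:
            raise IndexError(f"character {char_id} out of range 1..{self.n_chars}")
        return self.codes[:, char_id - 1]

    def cell(self, taxon: str, char_id: int) -> CellValue:
        code = int(self.column(char_id)[self.taxon_labels.index(taxon)])
        if code == MISSING:
            return CellValue("missing")
        if code == INAPPLICABLE:
            return CellValue("inapplicable")
        return CellValue("state", code)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxon_labels == other.taxon_labels
            and self.codes.shape == other.codes.shape
            and bool((self.codes == other.codes).all())
            and (self.character_notes or None) == (other.character_notes or None)
        )


@dataclass(frozen=True)
class TaxonMetadata:
    """Classification and sampling metadata for one terminal."""

    taxon: str
    tribe: str = ""
    subtribe: str = ""
    region: str = ""
    is_outgroup: bool = False
    is_root: bool = False

    def __post_init__(self) -> None:
        if self.is_root and not self.is_outgroup:
            raise ValueError("the root taxon must be an outgroup")


# ---------------------------------------------------------------------------
# parsing


def _as_text(source: str | IO[str]) -> str:
    if hasattr(source, "read"):
        return source.read()  # type: ignore[union-attr]
    return source


def _cells_from_tokens(tokens: Sequence[str], taxon: str) -> list[int]:
    cells: list[int] = []
    for tok in tokens:
        for ch in tok:
            cells.append(_code_of(ch, taxon, len(cells) + 1))
    return cells


def _rows_to_matrix(
    rows: list[tuple[str, list[int]]],
    notes: list[str] | None,
    expect: tuple[int, int] | None = None,
) -> CharacterMatrix:
    if not rows:
        raise MatrixFormatError("no taxon rows found")
    labels = [r[0] for r in rows]
    dupes = {t for t in labels if labels.count(t) > 1}
    if dupes:
        raise MatrixFormatError(f"duplicate taxon label(s): {sorted(dupes)}")
    width = len(rows[0][1])
    for taxon, cells in rows:
        if len(cells) != width:
            raise MatrixFormatError(
                f"ragged row for taxon {taxon!r}: {len(cells)} cells, expected {width}"
            )
    if expect is not None:
        n_chars, n_taxa = expect
        if len(rows) != n_taxa or width != n_chars:
            raise MatrixFormatError(
                f"header declares {n_taxa} taxa x {n_chars} characters,"
                f" found {len(rows)} x {width}"
            )
    codes = np.array([cells for _, cells in rows], dtype=np.int8)
    return CharacterMatrix(labels, codes, notes)


def _parse_tnt(text: str) -> CharacterMatrix:
    lines = text.splitlines()
    it = iter(enumerate(lines, 1))
    header = None
    for _, line in it:
        if line.strip().lower().startswith("xread"):
            header = line
            break
    if header is None:
        raise MatrixFormatError("no 'xread' header found")
    dims = None
    for _, line in it:
        s = line.strip()
        if not s:
            continue
        parts = s.split()
        if len(parts) != 2 or not all(p.isdigit() for p in parts):
            raise MatrixFormatError(f"expected '<n_chars> <n_taxa>' dimensions line, got {s!r}")
        dims = (int(parts[0]), int(parts[1]))
        break
    if dims is None:
        raise MatrixFormatError("missing dimensions line after 'xread'")
    rows: list[tuple[str, list[int]]] = []
    notes: list[str] = []
    seen_end = False
    for _, line in it:
        s = line.strip()
        if not s:
            continue
        if s == ";":
            seen_end = True
            continue
        if seen_end:
            if s.startswith("'"):
                m = re.match(r"'\s*(\d+)\s+(.*)$", s)
                if m:
                    idx, note = int(m.group(1)), m.group(2)
                    while len(notes) < idx:
                        notes.append("")
                    notes[idx - 1] = note
            continue
        parts = s.split()
        if len(parts) < 2:
            raise MatrixFormatError(f"cannot parse taxon row {s!r}")
        taxon = parts[0]
        rows.append((taxon, _cells_from_tokens(parts[1:], taxon)))
    if not seen_end:
        raise MatrixFormatError("missing ';' terminator")
    note_list = notes if any(notes) else None
    if note_list is not None:
        while len(note_list) < dims[0]:
            note_list.append("")
    return _rows_to_matrix(rows, note_list, expect=dims)


def _parse_nexus(text: str) -> CharacterMatrix:
    notes: list[str] = []
    for m in re.finditer(r"\[character note (\d+): (.*?)\]", text):
        idx, note = int(m.group(1)), m.group(2)
        while len(notes) < idx:
            notes.append("")
        notes[idx - 1] = note
    body = re.sub(r"\[[^\]]*\]", " ", text)  # strip comments
    if not body.lstrip().upper().startswith("#NEXUS"):
        raise MatrixFormatError("not a NEXUS document (missing #NEXUS)")
    m = re.search(r"DIMENSIONS\s+NTAX\s*=\s*(\d+)\s+NCHAR\s*=\s*(\d+)\s*;", body, re.I)
    if not m:
        raise MatrixFormatError("missing DIMENSIONS statement")
    n_taxa, n_chars = int(m.group(1)), int(m.group(2))
    m = re.search(r"\bMATRIX\b(.*?);", body, re.S | re.I)
    if not m:
        raise MatrixFormatError("missing MATRIX block")
    rows: list[tuple[str, list[int]]] = []
    for line in m.group(1).splitlines():
        s = line.strip()
        if not s:
            continue
        parts = s.split()
        if len(parts) < 2:
            raise MatrixFormatError(f"cannot parse matrix row {s!r}")
        taxon = parts[0].strip("'")
        rows.append((taxon, _cells_from_tokens(parts[1:], taxon)))
    note_list = notes if any(notes) else None
    if note_list is not None:
        while len(note_list) < n_chars:
            note_list.append("")
    return _rows_to_matrix(rows, note_list, expect=(n_chars, n_taxa))


def _parse_table(text: str) -> CharacterMatrix:
    rows: list[tuple[str, list[int]]] = []
    notes: list[str] = []
    for line in text.splitlines():
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            m = re.match(r"#\s*character\s+(\d+):\s?(.*)$", s)
            if m:
                idx, note = int(m.group(1)), m.group(2)
                while len(notes) < idx:
                    notes.append("")
                notes[idx - 1] = note
            continue
        parts = s.split("\t") if "\t" in s else s.split()
        taxon = parts[0].strip()
        rows.append((taxon, _cells_from_tokens([p.strip() for p in parts[1:] if p.strip()], taxon)))
    note_list = notes if any(notes) else None
    mat = _rows_to_matrix(rows, None)
    if note_list is not None:
        while len(note_list) < mat.n_chars:
            note_list.append("")
        mat.character_notes = note_list
    return mat


def read_matrix(source: str | IO[str], format: str = "tnt") -> CharacterMatrix:
    """Parse a character matrix from text or a text stream.

    '?' maps to :data:`MISSING`, '-' to :data:`INAPPLICABLE`; taxon order is
    preserved as given.  Raises :class:`MatrixFormatError` on ragged rows,
    duplicate labels or illegal symbols.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    text = _as_text(source)
    if format == "tnt":
        return _parse_tnt(text)
    if format == "nexus":
        return _parse_nexus(text)
    return _parse_table(text)


# ---------------------------------------------------------------------------
# writing


def _safe_label(label: str) -> str:
    return label.replace(" ", "_")


def write_matrix(matrix: CharacterMatrix, format: str = "tnt") -> str:
    """Serialize a matrix; ``read_matrix(write_matrix(M)) == M`` in every dialect."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    rows = [
        (_safe_label(t) if format != "table" else t, "".join(_symbol_of(int(c)) for c in matrix.codes[i]))
        for i, t in enumerate(matrix.taxon_labels)
    ]
    width = max(len(t) for t, _ in rows) + 2
    notes = matrix.character_notes
    out = io.StringIO()
    if format == "tnt":
        out.write(f"xread\n{matrix.n_chars} {matrix.n_taxa}\n")
        for taxon, cells in rows:
            out.write(taxon.ljust(width) + cells + "\n")
        out.write(";\n")
        if notes:
            for i, note in enumerate(notes, 1):
                if note:
                    out.write(f"' {i} {note}\n")
    elif format == "nexus":
        out.write("#NEXUS\nBEGIN DATA;\n")
        out.write(f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};\n")
        out.write('FORMAT SYMBOLS="0123456789" MISSING=? GAP=-;\n')
        if notes:
            for i, note in enumerate(notes, 1):
                if note:
                    clean = note.replace("[", "(").replace("]", ")")
                    out.write(f"[character note {i}: {clean}]\n")
        out.write("MATRIX\n")
        for taxon, cells in rows:
            out.write(taxon.ljust(width) + cells + "\n")
        out.write(";\nEND;\n")
    else:
        if notes:
            for i, note in enumerate(notes, 1):
                if note:
                    out.write(f"# character {i}: {note}\n")
        for taxon, cells in rows:
            out.write(f"{taxon}\t{cells}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# packaged study data


def _data_text(name: str) -> str:
    return resources.files("morphoclad.data").joinpath(name).read_text(encoding="utf-8")


def load_helopini_fixture() -> tuple[CharacterMatrix, list[TaxonMetadata]]:
    """The packaged Helopini study data: 33 taxa x 67 morphological characters.

    Returns the transcribed matrix together with taxon metadata (tribe,
    subtribe, sampling region).  *Uloma mexicana* is flagged as the root
    taxon; it and the other two non-helopine terminals (*Hypogena
    biimpressa*, *Tenebrio molitor*) are flagged as outgroups.
    """
    matrix = read_matrix(_data_text("helopini.tnt"), format="tnt")
    notes: list[str] = [""] * matrix.n_chars
    for line in _data_text("helopini_characters.tsv").splitlines()[1:]:
        idx, desc = line.split("\t", 1)
        notes[int(idx) - 1] = desc
    matrix.character_notes = notes
    meta: list[TaxonMetadata] = []
    for line in _data_text("helopini_taxa.tsv").splitlines()[1:]:
        taxon, tribe, subtribe, region, outg, root = line.split("\t")
        meta.append(
            TaxonMetadata(
                taxon=taxon,
                tribe=tribe,
                subtribe=subtribe or "unassigned",
                region=region,
                is_outgroup=outg == "1",
                is_root=root == "1",
            )
        )
    assert [m.taxon for m in meta] == matrix.taxon_labels
    return matrix, meta
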