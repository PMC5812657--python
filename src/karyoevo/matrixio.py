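"""Character-matrix serialization: NEXUS, TNT xread, and plain CSV.

State labels here are not single characters (e.g. ``10`` or the private
``4a``), so the NEXUS and TNT writers remap each character's alphabet to
single symbols and embed a ``STATEKEY`` legend (a comment in NEXUS, the
quoted title in TNT) that the readers use to restore the original labels.
Missing cells are ``?``; polymorphic cells use ``{..}`` in NEXUS and
``[..]`` in TNT.  Every writer round-trips exactly through its reader.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path

from .characters import CharacterMatrix
from .errors import MatrixFormatError, MatrixParseError

__all__ = ["write_matrix", "read_matrix", "MATRIX_FORMATS"]

MATRIX_FORMATS = ("nexus", "tnt", "csv")

_SYMBOL_POOL = (
    "0123456789"
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    "abcdefghijklmnopqrstuvwxyz"
)


def _symbol_maps(matrix: CharacterMatrix) -> dict[str, dict[str, str]]:
    maps = {}
    for char in matrix.characters:
        alphabet = matrix.alphabets[char]
        if len(alphabet) > len(_SYMBOL_POOL):
            raise MatrixFormatError(
                f"character {char!r} has {len(alphabet)} states, more than the "
                f"{len(_SYMBOL_POOL)} available symbols"
            )
        maps[char] = {state: _SYMBOL_POOL[i] for i, state in enumerate(alphabet)}
    return maps


def _statekey(matrix: CharacterMatrix, maps) -> str:
    parts = []
    for char in matrix.characters:
        pairs = " ".join(f"{s}={maps[char][s]}" for s in matrix.alphabets[char])
        parts.append(f"{char}: {pairs}")
    return "STATEKEY " + "; ".join(parts)


def _parse_statekey(text: str):
    # the legend ends at the NEXUS comment bracket / TNT quote / line end
    m = re.search(r"STATEKEY\s+([^\]'\n]*)", text)
    if not m:
        raise MatrixParseError("no STATEKEY legend found")
    characters, alphabets, decode = [], {}, {}
    for chunk in m.group(1).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        char, _, pairs = chunk.partition(":")
        char = char.strip()
        characters.append(char)
        alphabet, back = [], {}
        for pair in pairs.split():
            state, _, symbol = pair.partition("=")
            alphabet.append(state)
            back[symbol] = state
        alphabets[char] = tuple(alphabet)
        decode[char] = back
    return tuple(characters), alphabets, decode


def _taxon_out(label: str) -> str:
    return label.replace(" ", "_")


def _taxon_in(label: str) -> str:
    return label.replace("_", " ")


def _cell_symbols(cell, char, matrix, maps, open_b, close_b):
    if cell is None:
        return "?"
    symbols = [maps[char][s] for s in matrix.alphabets[char] if s in cell]
    if len(symbols) == 1:
        return symbols[0]
    return open_b + "".join(symbols) + close_b


def _row_cells(line: str, decode, characters, lineno: int, open_b, close_b):
    cells = {}
    i, ci = 0, 0
    while i < len(line):
        if ci >= len(characters):
            raise MatrixParseError("more cells than characters", line=lineno)
        char = characters[ci]
        c = line[i]
        if c == "?":
            cells[char] = None
            i += 1
        elif c == open_b:
            j = line.find(close_b, i)
            if j < 0:
                raise MatrixParseError(f"unclosed {open_b!r}", line=lineno)
            states = set()
            for symbol in line[i + 1 : j]:
                if symbol not in decode[char]:
                    raise MatrixParseError(
                        f"unknown symbol {symbol!r} for character {char!r}",
                        line=lineno,
                    )
                states.add(decode[char][symbol])
            cells[char] = frozenset(states)
            i = j + 1
        else:
            if c not in decode[char]:
                raise MatrixParseError(
                    f"unknown symbol {c!r} for character {char!r}", line=lineno
                )
            cells[char] = frozenset({decode[char][c]})
            i += 1
        ci += 1
    if ci != len(characters):
        raise MatrixParseError(
            f"expected {len(characters)} cells, got {ci}", line=lineno
        )
    return cells


# --------------------------------------------------------------------- NEXUS

def _write_nexus(matrix: CharacterMatrix) -> str:
    maps = _symbol_maps(matrix)
    used = sorted({sym for m in maps.values() for sym in m.values()},
                  key=_SYMBOL_POOL.index)
    out = _io.StringIO()
    out.write("#NEXUS\n")
    out.write("BEGIN TAXA;\n")
    out.write(f"    DIMENSIONS NTAX={len(matrix.taxa)};\n")
    out.write("    TAXLABELS\n")
    for t in matrix.taxa:
        out.write(f"        {_taxon_out(t)}\n")
    out.write("    ;\nEND;\n")
    out.write("BEGIN CHARACTERS;\n")
    out.write(f"    DIMENSIONS NCHAR={len(matrix.characters)};\n")
    out.write(
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{"".join(used)}" MISSING=?;\n'
    )
    labels = ", ".join(
        f"{i + 1} {name}" for i, name in enumerate(matrix.characters)
    )
    out.write(f"    CHARSTATELABELS {labels};\n")
    out.write(f"    [{_statekey(matrix, maps)}]\n")
    out.write("    MATRIX\n")
    pad = max(len(_taxon_out(t)) for t in matrix.taxa) + 2
    for t in matrix.taxa:
        row = "".join(
            _cell_symbols(matrix.cells[c].get(t), c, matrix, maps, "{", "}")
            for c in matrix.characters
        )
        out.write(f"        {_taxon_out(t):<{pad}}{row}\n")
    out.write("    ;\nEND;\n")
    return out.getvalue()


def _read_nexus(text: str) -> CharacterMatrix:
    if not text.strip():
        raise MatrixParseError("empty matrix file", line=1)
    if not text.lstrip().startswith("#NEXUS"):
        raise MatrixParseError("not a NEXUS file (missing #NEXUS header)", line=1)
    characters, alphabets, decode = _parse_statekey(text)
    lines = text.splitlines()
    taxa, cells = [], {c: {} for c in characters}
    in_matrix = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line.upper() == "MATRIX":
            in_matrix = True
            continue
        if not in_matrix:
            continue
        if line == ";":
            break
        if not line or line.startswith("["):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise MatrixParseError(
                f"expected 'taxon row', got {line!r}", line=lineno
            )
        taxon = _taxon_in(parts[0])
        taxa.append(taxon)
        for char, cell in _row_cells(
            parts[1], decode, characters, lineno, "{", "}"
        ).items():
            cells[char][taxon] = cell
    else:
        if not in_matrix:
            raise MatrixParseError("no MATRIX block found")
    if not taxa:
        raise MatrixParseError("matrix block contains no rows")
    return CharacterMatrix(
        taxa=tuple(taxa), characters=characters, alphabets=alphabets, cells=cells
    )


# ----------------------------------------------------------------------- TNT

def _write_tnt(matrix: CharacterMatrix) -> str:
    maps = _symbol_maps(matrix)
    out = _io.StringIO()
    out.write("xread\n")
    out.write(f"'{_statekey(matrix, maps)}'\n")
    out.write(f"{len(matrix.characters)} {len(matrix.taxa)}\n")
    pad = max(len(_taxon_out(t)) for t in matrix.taxa) + 2
    for t in matrix.taxa:
        row = "".join(
            _cell_symbols(matrix.cells[c].get(t), c, matrix, maps, "[", "]")
            for c in matrix.characters
        )
        out.write(f"{_taxon_out(t):<{pad}}{row}\n")
    out.write(";\n")
    return out.getvalue()


def _read_tnt(text: str) -> CharacterMatrix:
    if not text.strip():
        raise MatrixParseError("empty matrix file", line=1)
    lines = text.splitlines()
    if not lines[0].strip().lower().startswith("xread"):
        raise MatrixParseError("not a TNT xread file", line=1)
    characters, alphabets, decode = _parse_statekey(text)
    # locate the dimensions line (first "nchar ntax" after the title)
    dims_idx = None
    for i, line in enumerate(lines[1:], start=1):
        if re.fullmatch(r"\s*\d+\s+\d+\s*", line):
            dims_idx = i
            break
    if dims_idx is None:
        raise MatrixParseError("no 'nchar ntax' dimensions line found")
    nchar, ntax = map(int, lines[dims_idx].split())
    if nchar != len(characters):
        raise MatrixParseError(
            f"dimensions say {nchar} characters but legend lists {len(characters)}",
            line=dims_idx + 1,
        )
    taxa, cells = [], {c: {} for c in characters}
    for lineno, raw in enumerate(lines[dims_idx + 1 :], start=dims_idx + 2):
        line = raw.strip()
        if line == ";":
            break
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise MatrixParseError(f"expected 'taxon row', got {line!r}", line=lineno)
        taxon = _taxon_in(parts[0])
        taxa.append(taxon)
        for char, cell in _row_cells(
            parts[1], decode, characters, lineno, "[", "]"
        ).items():
            cells[char][taxon] = cell
    if len(taxa) != ntax:
        raise MatrixParseError(f"dimensions say {ntax} taxa but matrix has {len(taxa)}")
    return CharacterMatrix(
        taxa=tuple(taxa), characters=characters, alphabets=alphabets, cells=cells
    )


# ----------------------------------------------------------------------- CSV

def _write_csv(matrix: CharacterMatrix) -> str:
    out = _io.StringIO()
    out.write("#KARYOEVO-MATRIX\n")
    for char in matrix.characters:
        out.write(f"#ALPHABET {char}:{'|'.join(matrix.alphabets[char])}\n")
    out.write("taxon," + ",".join(matrix.characters) + "\n")
    for t in matrix.taxa:
        row = []
        for char in matrix.characters:
            cell = matrix.cells[char].get(t)
            if cell is None:
                row.append("?")
            else:
                row.append("|".join(s for s in matrix.alphabets[char] if s in cell))
        out.write(t + "," + ",".join(row) + "\n")
    return out.getvalue()


def _read_csv(text: str) -> CharacterMatrix:
    if not text.strip():
        raise MatrixParseError("empty matrix file", line=1)
    lines = text.splitlines()
    if lines[0].strip() != "#KARYOEVO-MATRIX":
        raise MatrixParseError("missing #KARYOEVO-MATRIX header", line=1)
    alphabets = {}
    i = 1
    while i < len(lines) and lines[i].startswith("#ALPHABET"):
        body = lines[i][len("#ALPHABET") :].strip()
        char, _, states = body.partition(":")
        alphabets[char] = tuple(states.split("|"))
        i += 1
    if i >= len(lines):
        raise MatrixParseError("missing column header", line=i)
    header = lines[i].split(",")
    if header[0] != "taxon":
        raise MatrixParseError(f"first column must be 'taxon', got {header[0]!r}", line=i + 1)
    characters = tuple(header[1:])
    missing_alpha = [c for c in characters if c not in alphabets]
    if missing_alpha:
        raise MatrixParseError(f"no #ALPHABET line for {missing_alpha}")
    taxa, cells = [], {c: {} for c in characters}
    for lineno, raw in enumerate(lines[i + 1 :], start=i + 2):
        if not raw.strip():
            continue
        parts = raw.split(",")
        if len(parts) != len(characters) + 1:
            raise MatrixParseError(
                f"expected {len(characters) + 1} fields, got {len(parts)}", line=lineno
            )
        taxon = parts[0]
        taxa.append(taxon)
        for char, value in zip(characters, parts[1:]):
            if value == "?":
                cells[char][taxon] = None
            else:
                states = value.split("|")
                unknown = [s for s in states if s not in alphabets[char]]
                if unknown:
                    raise MatrixParseError(
                        f"unknown state {unknown[0]!r} for character {char!r}",
                        line=lineno,
                    )
                cells[char][taxon] = frozenset(states)
    if not taxa:
        raise MatrixParseError("matrix contains no rows")
    return CharacterMatrix(
        taxa=tuple(taxa), characters=characters, alphabets=alphabets, cells=cells
    )


_WRITERS = {"nexus": _write_nexus, "tnt": _write_tnt, "csv": _write_csv}
_READERS = {"nexus": _read_nexus, "tnt": _read_tnt, "csv": _read_csv}


def write_matrix(matrix: CharacterMatrix, format: str, path=None) -> str:
    """Serialize ``matrix``; write to ``path`` if given, return the text."""
    try:
        text = _WRITERS[format](matrix)
    except KeyError:
        raise MatrixFormatError(
            f"unknown format {format!r}; choose from {MATRIX_FORMATS}"
        ) from None
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_matrix(source, format: str) -> CharacterMatrix:
    """Parse a matrix from a path or literal text (inverse of write_matrix)."""
    try:
        reader = _READERS[format]
    except KeyError:
        raise MatrixFormatError(
            f"unknown format {format!r}; choose from {MATRIX_FORMATS}"
        ) from None
    if (
        isinstance(source, str)
        and source
        and "\n" not in source
        and Path(source).exists()
    ):
        text = Path(source).read_text(encoding="utf-8")
    elif isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    else:
        text = source
    return reader(text)
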