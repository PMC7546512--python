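"""Readers, writers and small sequence/biometry utilities.

Formats handled here are all plain text: TNT ``xread`` character matrices
(with ``ccode`` additivity lines and bracketed polymorphisms), TPS landmark
files as produced by digitizing software, tab-separated specimen tables
with DMS latitude strings, aligned FASTA, and Newick trees (delegated to
:mod:`morphocline.parsimony`).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from morphocline.parsimony import Character, CharacterMatrix

__all__ = [
    "parse_dms_latitude",
    "read_specimen_table",
    "read_s1_table",
    "read_tnt",
    "write_tnt",
    "read_tps",
    "write_tps",
    "read_fasta",
    "AlignedSequencePair",
    "pairwise_identity",
    "round_ratio",
]


class MalformedRecordError(ValueError):
    """A file record that cannot be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


# --------------------------------------------------------------------------
# latitude parsing

_DMS_RE = re.compile(
    r"""^\s*(\d+)\s*[°º]\s*(\d+)\s*['’]\s*([\d.]+)\s*[\"”]?\s*([NSns])\s*$""",
    re.VERBOSE,
)


def parse_dms_latitude(text: str, strict: bool = False) -> float:
    """Convert a DMS latitude string like ``20°17'02.6"S`` to decimal degrees.

    North is positive.  Seconds (or minutes) of 60 or more are invalid in
    strict DMS; field data occasionally contain them (GPS transcription
    slips).  By default the excess is carried over into the next unit with
    a warning; with ``strict=True`` such values raise ``ValueError``.
    """
    m = _DMS_RE.match(text)
    if m is None:
        raise ValueError(f"not a DMS latitude: {text!r}")
    deg, minute, sec = int(m.group(1)), int(m.group(2)), float(m.group(3))
    hemi = m.group(4).upper()
    if sec >= 60 or minute >= 60:
        if strict:
            raise ValueError(f"invalid DMS component in {text!r}")
        warnings.warn(
            f"DMS component >= 60 in {text!r}; carrying over", stacklevel=2
        )
        minute += int(sec // 60)
        sec = sec % 60
        deg += minute // 60
        minute = minute % 60
    value = deg + minute / 60.0 + sec / 3600.0
    if value > 90:
        raise ValueError(f"latitude out of range: {text!r}")
    return value if hemi == "N" else -value


# --------------------------------------------------------------------------
# specimen table (tab-separated; 24-digit state strings; DMS latitude)


def read_specimen_table(path: str | Path, strict_dms: bool = False) -> pd.DataFrame:
    """Read a specimen table: id, country, coden, altitude, DMS latitude, states.

    The state column is a string of single-digit character states, one
    column per character, split into ``char_00 .. char_NN`` integer
    columns.  A trailing ``*`` on the specimen id marks the outgroup and
    is preserved in the boolean ``outgroup`` column.  Adds a decimal
    ``latitude_deg`` column (north positive).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"database", "country", "coden", "altitude_m", "latitude", "states"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedRecordError(f"missing columns: {sorted(missing)}")
    widths = df["states"].str.len().unique()
    if len(widths) != 1:
        raise MalformedRecordError(
            f"state strings of unequal length: {sorted(widths)}"
        )
    nchar = int(widths[0])
    out = pd.DataFrame(
        {
            "specimen_id": df["database"].str.rstrip("*"),
            "outgroup": df["database"].str.endswith("*"),
            "country": df["country"],
            "coden": df["coden"],
            "altitude_m": df["altitude_m"].astype(float),
            "latitude_dms": df["latitude"],
            "latitude_deg": [
                parse_dms_latitude(s, strict=strict_dms) for s in df["latitude"]
            ],
        }
    )
    for j in range(nchar):
        out[f"char_{j:02d}"] = [
            int(s[j]) if s[j] not in "?-" else None for s in df["states"]
        ]
    return out


def read_s1_table(
    path: str | Path,
    id_column: str = "specimen_id",
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a per-specimen RGB sample spreadsheet (CSV).

    The canonical layout is one row per specimen and three columns
    ``pNN_R, pNN_G, pNN_B`` per sampled body point; empty cells are
    missing.  ``column_map`` renames nonstandard headers before
    validation, accommodating files whose column ordering or naming is
    undocumented.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if id_column not in df.columns:
        raise MalformedRecordError(f"missing id column {id_column!r}")
    df = df.set_index(id_column)
    bad = [c for c in df.columns if not re.fullmatch(r"p\d+_[RGB]", c)]
    if bad:
        raise MalformedRecordError(f"unrecognized value columns: {bad[:5]}")
    return df.astype(float)


# --------------------------------------------------------------------------
# TNT xread

_TNT_TOKEN = re.compile(r"\[([0-9\-?]+)\]|([0-9?\-])")


def _parse_tnt_cell(token: str) -> frozenset[int] | None:
    if token in ("?", "-"):
        return None
    return frozenset(int(c) for c in token)


def read_tnt(path: str | Path) -> CharacterMatrix:
    """Read a TNT ``xread`` file with optional ``ccode`` additivity settings.

    Supports single-digit states, ``[01]`` polymorphism sets, ``?`` and
    ``-`` (both treated as missing), ``&[cont]`` continuous blocks, and
    ``ccode`` lines using ``+`` (additive) / ``-`` (non-additive) prefixes.
    """
    text = Path(path).read_text()
    m = re.search(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)", text)
    if m is None:
        raise MalformedRecordError("no xread header found")
    nchar, ntax = int(m.group(1)), int(m.group(2))
    body = text[m.end():]
    stop = body.find(";")
    if stop == -1:
        raise MalformedRecordError("unterminated xread block")
    tail = body[stop + 1:]
    body = body[:stop]

    continuous = False
    rows: dict[str, list] = {}
    order: list[str] = []
    for lineno, raw in enumerate(body.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("&"):
            continuous = "cont" in line.lower()
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MalformedRecordError(f"bad taxon row: {raw!r}", lineno)
        name, states = parts
        if name not in rows:
            rows[name] = []
            order.append(name)
        if continuous:
            for tok in states.split():
                rows[name].append(None if tok in ("?", "-") else float(tok))
        else:
            pos = 0
            states = states.replace(" ", "")
            while pos < len(states):
                mm = _TNT_TOKEN.match(states, pos)
                if mm is None:
                    raise MalformedRecordError(f"bad state at col {pos}", lineno)
                tok = mm.group(1) or mm.group(2)
                rows[name].append(_parse_tnt_cell(tok.replace("-", "?")
                                                  if tok in ("-",) else tok))
                pos = mm.end()
    if len(order) != ntax:
        raise MalformedRecordError(
            f"expected {ntax} taxa, found {len(order)}"
        )
    for name in order:
        if len(rows[name]) != nchar:
            raise MalformedRecordError(
                f"taxon {name}: expected {nchar} characters, found {len(rows[name])}"
            )

    additive = [False] * nchar
    for cm in re.finditer(r"ccode\s+([^;]*);", tail):
        flag = None
        for tok in cm.group(1).split():
            if tok in ("+", "-"):
                flag = tok == "+"
            elif flag is not None:
                if "." in tok:
                    a, b = tok.split(".")
                    rng = range(int(a), int(b) + 1)
                else:
                    rng = range(int(tok), int(tok) + 1)
                for j in rng:
                    additive[j] = flag

    characters = []
    for j in range(nchar):
        col = [rows[name][j] for name in order]
        cont = any(isinstance(v, float) for v in col)
        characters.append(Character(states=col, additive=additive[j] or cont,
                                    continuous=cont))
    return CharacterMatrix(taxa=order, characters=characters)


def write_tnt(matrix: CharacterMatrix, path: str | Path, title: str = "") -> None:
    """Write a matrix in TNT ``xread`` dialect (lossless round-trip)."""
    lines = [f"xread '{title}' {matrix.nchar} {matrix.ntax}"]
    disc = [j for j, c in enumerate(matrix.characters) if not c.continuous]
    cont = [j for j, c in enumerate(matrix.characters) if c.continuous]
    if cont and disc and cont != list(range(len(cont))):
        raise ValueError("continuous characters must precede discrete ones in TNT")
    if cont:
        lines.append("&[cont]")
        for i, t in enumerate(matrix.taxa):
            vals = []
            for j in cont:
                v = matrix.characters[j].states[i]
                vals.append("?" if v is None else f"{v:g}")
            lines.append(f"{t} " + " ".join(vals))
        if disc:
            lines.append("&[num]")
    if disc:
        for i, t in enumerate(matrix.taxa):
            cells = []
            for j in disc:
                v = matrix.characters[j].states[i]
                if v is None:
                    cells.append("?")
                elif len(v) == 1:
                    cells.append(str(next(iter(v))))
                else:
                    cells.append("[" + "".join(str(s) for s in sorted(v)) + "]")
            lines.append(f"{t} " + "".join(cells))
    lines.append(";")
    add = [j for j, c in enumerate(matrix.characters) if c.additive]
    nonadd = [j for j, c in enumerate(matrix.characters) if not c.additive]
    parts = []
    if add:
        parts.append("+ " + " ".join(str(j) for j in add))
    if nonadd:
        parts.append("- " + " ".join(str(j) for j in nonadd))
    if parts:
        lines.append("ccode " + " ".join(parts) + ";")
    lines.append("proc /;")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# TPS landmark files


def read_tps(path: str | Path) -> list[dict]:
    """Read a TPS landmark file into a list of specimen records.

    Each record is ``{"landmarks": [(x, y), ...], "image": str | None,
    "id": str | None}``.  Landmarks flagged as absent (coordinates
    ``-1 -1`` by the common digitizing convention) are stored as ``None``.
    TPS coordinates have their origin at the bottom-left of the image;
    see :func:`morphocline.imagecolor.extract_specimen_colors` for the
    flip to raster row order.
    """
    records = []
    current: dict | None = None
    expected = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key_upper = key.strip().upper()
        if key_upper == "LM":
            current = {"landmarks": [], "image": None, "id": None}
            records.append(current)
            expected = int(value)
        elif key_upper == "IMAGE" and current is not None:
            current["image"] = value.strip()
        elif key_upper == "ID" and current is not None:
            current["id"] = value.strip()
        elif key_upper in ("SCALE",):
            continue
        else:
            if current is None:
                raise MalformedRecordError("coordinates before LM= header", lineno)
            parts = line.split()
            if len(parts) != 2:
                raise MalformedRecordError(f"bad coordinate line: {raw!r}", lineno)
            x, y = float(parts[0]), float(parts[1])
            current["landmarks"].append(None if (x, y) == (-1.0, -1.0) else (x, y))
    for rec in records:
        if len(rec["landmarks"]) != expected and len(records) == 1:
            raise MalformedRecordError(
                f"expected {expected} landmarks, found {len(rec['landmarks'])}"
            )
    return records


def write_tps(records: Sequence[dict], path: str | Path) -> None:
    """Write specimen landmark records in TPS dialect."""
    lines = []
    for i, rec in enumerate(records):
        lms = rec["landmarks"]
        lines.append(f"LM={len(lms)}")
        for lm in lms:
            if lm is None:
                lines.append("-1 -1")
            else:
                lines.append(f"{lm[0]:g} {lm[1]:g}")
        if rec.get("image"):
            lines.append(f"IMAGE={rec['image']}")
        lines.append(f"ID={rec.get('id') or i}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# sequences


@dataclass
class AlignedSequencePair:
    """Two aligned nucleotide sequences of equal length (gaps allowed)."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        alphabet = set("ACGTN-")
        for s in (self.seq_a, self.seq_b):
            bad = set(s.upper()) - alphabet
            if bad:
                raise ValueError(f"unexpected symbols in alignment: {sorted(bad)}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def pairwise_identity(pair: AlignedSequencePair) -> tuple[float, float]:
    """Percent identity and p-distance over comparable aligned sites.

    Sites with a gap or ``N`` in either sequence are excluded from the
    denominator.  Returns ``(identity_percent, p_distance_percent)``.
    """
    a, b = pair.seq_a.upper(), pair.seq_b.upper()
    compared = matches = 0
    for ca, cb in zip(a, b):
        if ca in "N-" or cb in "N-":
            continue
        compared += 1
        if ca == cb:
            matches += 1
    if compared == 0:
        raise ValueError("no comparable sites")
    identity = 100.0 * matches / compared
    return identity, 100.0 - identity


# --------------------------------------------------------------------------
# biometric ratios


def round_ratio(x: float) -> float:
    """Round a biometric ratio to the nearest 0.05; exact ties round up.

    Measurement ratios are reported at this granularity to reflect a
    realistic level of precision.
    """
    if not math.isfinite(x):
        raise ValueError("ratio must be finite")
    if x < 0:
        raise ValueError("ratio must be non-negative")
    return math.floor(x * 20 + 0.5) / 20.0
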