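"""Reading, writing and validating MAF (Multiple Alignment Format) files.

A MAF file stores a series of multiple sequence alignment blocks (MSABs)
between whole genomes.  Each block starts with an ``a`` line and contains
``s`` lines (the aligned sequences), optionally followed by ``q`` lines
(per-base qualities), ``i`` lines (context of the aligning source before and
after the block) and ``e`` lines (sources bridged over the block with no
aligning bases).

The in-memory representation is canonical: fields are single-space
separated, ``q``/``i`` lines follow their owning ``s`` line (``q`` before
``i``) and ``e`` lines follow all ``s`` lines.  Parsing a canonical file and
serializing it again is byte-identical; inputs that deviate (e.g. UCSC
column padding) are normalized and flagged via :attr:`MafFile.was_normalized`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, List, Optional, Union

__all__ = [
    "MafFormatError",
    "QLine",
    "ILine",
    "ELine",
    "SLine",
    "MSAB",
    "MafFile",
    "parse_maf",
    "serialize_maf",
    "validate_msab",
]

#: The 11 symbols allowed in ``s``-line alignment text.
S_ALPHABET = frozenset("AaCcGgTtNn-")
#: Quality characters allowed in ``q`` lines ('-' mirrors the s-line gaps).
Q_ALPHABET = frozenset("0123456789F-.")
#: Status characters of ``i`` lines.
I_STATUS_ALPHABET = frozenset("CINnMT")
#: Status characters of ``e`` lines.
E_STATUS_ALPHABET = frozenset("CINMT")


class MafFormatError(ValueError):
    """Raised when an input does not conform to the MAF grammar."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class QLine:
    """Per-base quality values mirroring the owning ``s`` line (gaps replicated)."""

    values: str


@dataclass
class ILine:
    """Relationship of the source sequence to the previous/next block."""

    left_status: str
    left_count: int
    right_status: str
    right_count: int


@dataclass
class ELine:
    """A source with no aligning bases in this block, bridged by a chain."""

    source: str
    start: int
    size: int
    strand: str
    src_size: int
    status: str


@dataclass
class SLine:
    """One aligned sequence row: header fields plus the alignment text."""

    source: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str
    q_line: Optional[QLine] = None
    i_line: Optional[ILine] = None


@dataclass
class MSAB:
    """A multiple sequence alignment block.

    ``a_line_text`` is the verbatim remainder of the ``a`` line after the
    leading ``a`` (typically ``" score=..."``); it is kept opaque so the
    round trip is exact whatever the score formatting.
    ``inter_block_blank_lines`` counts the blank lines *preceding* this
    block in the file.
    """

    a_line_text: str
    rows: List[SLine] = field(default_factory=list)
    e_lines: List[ELine] = field(default_factory=list)
    inter_block_blank_lines: int = 1

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].text) if self.rows else 0


@dataclass
class MafFile:
    """A parsed MAF file: verbatim header lines, blocks, trailing blanks."""

    header_lines: List[str] = field(default_factory=list)
    blocks: List[MSAB] = field(default_factory=list)
    trailing_blank_lines: int = 0
    was_normalized: bool = False


def _iter_lines(source: Union[str, bytes, IO, Iterable[str]]) -> Iterator[str]:
    if isinstance(source, bytes):
        source = source.decode("utf-8")
    if isinstance(source, str):
        text = source
        if text == "":
            return iter(())
        lines = text.split("\n")
        if lines and lines[-1] == "":
            lines.pop()
        return iter(lines)
    return (line.rstrip("\n") for line in source)


def parse_maf(source: Union[str, bytes, IO, Iterable[str]]) -> MafFile:
    """Parse a MAF file from a string, bytes or an iterable of lines.

    ``q`` and ``i`` lines are attached to the immediately preceding ``s``
    line.  Structural violations (unknown line letter, orphan ``q``/``i``,
    row-length mismatch within a block) raise :class:`MafFormatError` with
    the offending line number.
    """
    maf = MafFile()
    block: Optional[MSAB] = None
    pending_blanks = 0
    in_header = True
    normalized = False

    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw
        if line.strip() == "":
            if line != "":
                normalized = True  # whitespace-only line treated as blank
            pending_blanks += 1
            continue
        if line[0] == "#":
            if not in_header:
                raise MafFormatError(
                    "'#' lines are only allowed before the first block", lineno
                )
            if pending_blanks:
                raise MafFormatError("blank line inside the file header", lineno)
            maf.header_lines.append(line)
            continue

        kind = line[0]
        if kind not in "asqie" or (len(line) > 1 and not line[1].isspace() and kind != "a"):
            raise MafFormatError(f"unknown line type {line.split()[0]!r}", lineno)

        if kind == "a":
            in_header = False
            block = MSAB(
                a_line_text=line[1:],
                inter_block_blank_lines=pending_blanks,
            )
            pending_blanks = 0
            maf.blocks.append(block)
            continue

        if block is None or pending_blanks:
            raise MafFormatError(f"'{kind}' line outside of a block", lineno)

        tokens = line.split()
        if " ".join(tokens) != line:
            normalized = True

        if kind == "s":
            if len(tokens) != 7:
                raise MafFormatError("'s' line must have 7 fields", lineno)
            _, source_name, start, size, strand, src_size, text = tokens
            if strand not in ("+", "-"):
                raise MafFormatError(f"invalid strand {strand!r}", lineno)
            bad = set(text) - S_ALPHABET
            if bad:
                raise MafFormatError(
                    f"invalid alignment characters {sorted(bad)!r}", lineno
                )
            if block.rows and len(text) != len(block.rows[0].text):
                raise MafFormatError(
                    f"row length {len(text)} != block column count "
                    f"{len(block.rows[0].text)}",
                    lineno,
                )
            if block.e_lines:
                normalized = True  # canonical order puts 'e' lines last
            try:
                row = SLine(
                    source=source_name,
                    start=int(start),
                    size=int(size),
                    strand=strand,
                    src_size=int(src_size),
                    text=text,
                )
            except ValueError as exc:
                raise MafFormatError(str(exc), lineno) from exc
            block.rows.append(row)
        elif kind == "q":
            if len(tokens) != 3:
                raise MafFormatError("'q' line must have 3 fields", lineno)
            if not block.rows:
                raise MafFormatError("'q' line with no preceding 's' line", lineno)
            owner = block.rows[-1]
            if tokens[1] != owner.source:
                raise MafFormatError(
                    f"'q' source {tokens[1]!r} does not match the preceding "
                    f"'s' line {owner.source!r}",
                    lineno,
                )
            values = tokens[2]
            if len(values) != len(owner.text):
                raise MafFormatError(
                    "'q' values length does not match the alignment text", lineno
                )
            bad = set(values) - Q_ALPHABET
            if bad:
                raise MafFormatError(f"invalid quality characters {sorted(bad)!r}", lineno)
            if owner.q_line is not None:
                raise MafFormatError("duplicate 'q' line for the same 's' line", lineno)
            if owner.i_line is not None:
                normalized = True  # canonical order is q before i
            owner.q_line = QLine(values=values)
        elif kind == "i":
            if len(tokens) != 6:
                raise MafFormatError("'i' line must have 6 fields", lineno)
            if not block.rows:
                raise MafFormatError("'i' line with no preceding 's' line", lineno)
            owner = block.rows[-1]
            if tokens[1] != owner.source:
                raise MafFormatError(
                    f"'i' source {tokens[1]!r} does not match the preceding "
                    f"'s' line {owner.source!r}",
                    lineno,
                )
            if tokens[2] not in I_STATUS_ALPHABET or tokens[4] not in I_STATUS_ALPHABET:
                raise MafFormatError("invalid 'i' status character", lineno)
            if owner.i_line is not None:
                raise MafFormatError("duplicate 'i' line for the same 's' line", lineno)
            try:
                owner.i_line = ILine(
                    left_status=tokens[2],
                    left_count=int(tokens[3]),
                    right_status=tokens[4],
                    right_count=int(tokens[5]),
                )
            except ValueError as exc:
                raise MafFormatError(str(exc), lineno) from exc
        else:  # 'e'
            if len(tokens) != 7:
                raise MafFormatError("'e' line must have 7 fields", lineno)
            if tokens[4] not in ("+", "-"):
                raise MafFormatError(f"invalid strand {tokens[4]!r}", lineno)
            if tokens[6] not in E_STATUS_ALPHABET:
                raise MafFormatError(f"invalid 'e' status {tokens[6]!r}", lineno)
            try:
                block.e_lines.append(
                    ELine(
                        source=tokens[1],
                        start=int(tokens[2]),
                        size=int(tokens[3]),
                        strand=tokens[4],
                        src_size=int(tokens[5]),
                        status=tokens[6],
                    )
                )
            except ValueError as exc:
                raise MafFormatError(str(exc), lineno) from exc

    maf.trailing_blank_lines = pending_blanks
    maf.was_normalized = normalized
    return maf


def serialize_maf(maf: MafFile) -> str:
    """Serialize to the canonical single-space dialect.

    ``serialize_maf(parse_maf(text)) == text`` for every canonical file.
    """
    out: List[str] = []
    for line in maf.header_lines:
        out.append(line)
        out.append("\n")
    for block in maf.blocks:
        out.append("\n" * block.inter_block_blank_lines)
        out.append("a")
        out.append(block.a_line_text)
        out.append("\n")
        for row in block.rows:
            out.append(
                f"s {row.source} {row.start} {row.size} {row.strand} "
                f"{row.src_size} {row.text}\n"
            )
            if row.q_line is not None:
                out.append(f"q {row.source} {row.q_line.values}\n")
            if row.i_line is not None:
                i = row.i_line
                out.append(
                    f"i {row.source} {i.left_status} {i.left_count} "
                    f"{i.right_status} {i.right_count}\n"
                )
        for e in block.e_lines:
            out.append(
                f"e {e.source} {e.start} {e.size} {e.strand} {e.src_size} "
                f"{e.status}\n"
            )
    out.append("\n" * maf.trailing_blank_lines)
    return "".join(out)


def validate_msab(block: MSAB) -> List[str]:
    """Check structural invariants of a block; returns diagnostics (not errors).

    An empty list means the block is valid: equal row lengths, ``size`` equal
    to the non-gap count of each row, legal alphabets, quality gaps mirroring
    the alignment gaps, and no quality line on the reference (first) row.
    """
    diags: List[str] = []
    n_cols = block.n_columns
    for idx, row in enumerate(block.rows):
        where = f"row {idx} ({row.source})"
        if len(row.text) != n_cols:
            diags.append(f"{where}: text length {len(row.text)} != column count {n_cols}")
        bad = set(row.text) - S_ALPHABET
        if bad:
            diags.append(f"{where}: invalid alignment characters {sorted(bad)!r}")
        non_gaps = len(row.text) - row.text.count("-")
        if row.size != non_gaps:
            diags.append(
                f"{where}: size field {row.size} != non-gap count {non_gaps}"
            )
        if row.strand not in ("+", "-"):
            diags.append(f"{where}: invalid strand {row.strand!r}")
        if row.q_line is not None:
            if idx == 0:
                diags.append(f"{where}: reference row must not carry a 'q' line")
            q = row.q_line.values
            if len(q) != len(row.text):
                diags.append(f"{where}: 'q' length {len(q)} != text length")
            else:
                for j, (qc, sc) in enumerate(zip(q, row.text)):
                    if (qc == "-") != (sc == "-"):
                        diags.append(
                            f"{where}: 'q' gap mismatch at column {j}"
                        )
                        break
            bad_q = set(q) - Q_ALPHABET
            if bad_q:
                diags.append(f"{where}: invalid quality characters {sorted(bad_q)!r}")
        if row.i_line is not None:
            i = row.i_line
            if i.left_status not in I_STATUS_ALPHABET:
                diags.append(f"{where}: invalid left status {i.left_status!r}")
            if i.right_status not in I_STATUS_ALPHABET:
                diags.append(f"{where}: invalid right status {i.right_status!r}")
            if i.left_count < 0 or i.right_count < 0:
                diags.append(f"{where}: negative 'i' count")
    for idx, e in enumerate(block.e_lines):
        if e.status not in E_STATUS_ALPHABET:
            diags.append(f"e-line {idx} ({e.source}): invalid status {e.status!r}")
        if e.strand not in ("+", "-"):
            diags.append(f"e-line {idx} ({e.source}): invalid strand {e.strand!r}")
    return diags
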