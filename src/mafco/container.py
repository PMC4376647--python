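"""The compressed container: global header, GOB index, independent payloads.

A compressed file is laid out as (all integers little-endian, fixed width)::

    magic   4 bytes  b"MAFC"
    version u8       1
    config           template id (u8), depth (u8), alpha num/den (u16 each),
                     then the 14 model orders as u8 in a fixed sequence
    flags   u8       bit 0: input was whitespace-normalized on parse
    header  u32 n, then n x (u32 length + UTF-8 bytes), the verbatim '#' lines
    trailing_blank_lines u32
    gob_count u32
    index            per GOB: u64 byte offset into the payload area +
                     u32 MSAB count; then u64 total payload length
    payloads         concatenated per-GOB arithmetic-coded segments

Each GOB (Group Of Blocks) holds an integer number of MSABs and is encoded
with fresh model state, so any GOB can be decoded given only the global
header and its own payload -- this is what enables parallel coding and
partial decoding, at a small compression cost because statistics gathered
in one GOB are not available to the others.
"""

from __future__ import annotations

import struct
from concurrent.futures import ProcessPoolExecutor
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple

from .codecs import CodecConfig, GobDecoder, GobEncoder
from .coder import CoderIntegrityError
from .maf import MSAB, MafFile, validate_msab

__all__ = [
    "ContainerFormatError",
    "DEFAULT_N_GOBS",
    "split_into_gobs",
    "compress_file",
    "decompress_file",
    "read_gob_index",
]

MAGIC = b"MAFC"
VERSION = 1
#: Default number of file parts, matching the tool's default of four
#: threads/GOBs.
DEFAULT_N_GOBS = 4

_ORDER_FIELDS = (
    "order_extra",
    "order_case",
    "order_start_flag",
    "order_strand",
    "order_q_values",
    "order_q_presence",
    "order_q_per_line",
    "order_i_presence",
    "order_i_status",
    "order_i_irregular_count",
    "order_i_irregular_status",
    "order_e_irregular_status_vs_e",
    "order_e_irregular_status_vs_i",
)


class ContainerFormatError(ValueError):
    """Raised for bad magic, unsupported version or malformed layout."""


def split_into_gobs(n_blocks: int, n_gobs: int) -> List[Tuple[int, int]]:
    """Balanced contiguous block ranges ``[(start, end), ...)`` (end exclusive).

    Range sizes differ by at most one block; when there are fewer blocks
    than requested GOBs each block gets its own GOB and the empty remainder
    is dropped.
    """
    if n_gobs < 1:
        raise ValueError("n_gobs must be >= 1")
    if n_blocks == 0:
        return []
    n_gobs = min(n_gobs, n_blocks)
    q, r = divmod(n_blocks, n_gobs)
    ranges = []
    pos = 0
    for i in range(n_gobs):
        size = q + 1 if i < r else q
        ranges.append((pos, pos + size))
        pos += size
    return ranges


def _pack_config(config: CodecConfig) -> bytes:
    alpha = Fraction(config.alpha)
    if not (0 < alpha.numerator < 1 << 16 and 0 < alpha.denominator < 1 << 16):
        raise ValueError("alpha must fit in 16-bit numerator/denominator")
    parts = [
        struct.pack(
            "<BBHH",
            ord(config.template_id),
            config.template_depth,
            alpha.numerator,
            alpha.denominator,
        )
    ]
    parts.append(bytes(getattr(config, f) for f in _ORDER_FIELDS))
    return b"".join(parts)


def _unpack_config(data: bytes, pos: int) -> Tuple[CodecConfig, int]:
    tid, depth, anum, aden = struct.unpack_from("<BBHH", data, pos)
    pos += 6
    orders = data[pos:pos + len(_ORDER_FIELDS)]
    if len(orders) != len(_ORDER_FIELDS):
        raise ContainerFormatError("truncated config block")
    pos += len(_ORDER_FIELDS)
    kwargs = {f: orders[i] for i, f in enumerate(_ORDER_FIELDS)}
    config = CodecConfig(
        template_id=chr(tid),
        template_depth=depth,
        alpha=Fraction(anum, aden),
        **kwargs,
    )
    return config, pos


def _encode_gob(blocks: Sequence[MSAB], config: CodecConfig) -> bytes:
    encoder = GobEncoder(config)
    for block in blocks:
        encoder.encode_block(block)
    return encoder.finish()


def _decode_gob(payload: bytes, config: CodecConfig, n_blocks: int) -> List[MSAB]:
    decoder = GobDecoder(payload, config)
    return [decoder.decode_block() for _ in range(n_blocks)]


def compress_file(
    maf: MafFile,
    config: Optional[CodecConfig] = None,
    n_gobs: int = DEFAULT_N_GOBS,
    n_workers: int = 1,
    validate: bool = True,
) -> bytes:
    """Compress a parsed MAF file into container bytes.

    The output is byte-identical for any ``n_workers``: the worker count
    only distributes the independent per-GOB encodes over processes.
    """
    config = config or CodecConfig()
    if validate:
        for i, block in enumerate(maf.blocks):
            diags = validate_msab(block)
            if diags:
                raise ValueError(f"block {i} is invalid: {diags[0]}")
    ranges = split_into_gobs(len(maf.blocks), n_gobs)
    slices = [maf.blocks[s:e] for s, e in ranges]
    if n_workers > 1 and len(slices) > 1:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            payloads = list(pool.map(_encode_gob, slices, [config] * len(slices)))
    else:
        payloads = [_encode_gob(blocks, config) for blocks in slices]

    out = bytearray()
    out += MAGIC
    out += struct.pack("<B", VERSION)
    out += _pack_config(config)
    out += struct.pack("<B", 1 if maf.was_normalized else 0)
    out += struct.pack("<I", len(maf.header_lines))
    for line in maf.header_lines:
        raw = line.encode("utf-8")
        out += struct.pack("<I", len(raw))
        out += raw
    out += struct.pack("<I", maf.trailing_blank_lines)
    out += struct.pack("<I", len(payloads))
    offset = 0
    for payload, (s, e) in zip(payloads, ranges):
        out += struct.pack("<QI", offset, e - s)
        offset += len(payload)
    out += struct.pack("<Q", offset)
    for payload in payloads:
        out += payload
    return bytes(out)


class _Header:
    __slots__ = ("config", "was_normalized", "header_lines",
                 "trailing_blank_lines", "offsets", "counts",
                 "payload_start", "payload_len")


def _read_header(data: bytes) -> _Header:
    if data[:4] != MAGIC:
        raise ContainerFormatError("bad magic: not a MAFCO container")
    pos = 4
    (version,) = struct.unpack_from("<B", data, pos)
    pos += 1
    if version != VERSION:
        raise ContainerFormatError(f"unsupported container version {version}")
    h = _Header()
    try:
        h.config, pos = _unpack_config(data, pos)
        (flags,) = struct.unpack_from("<B", data, pos)
        pos += 1
        h.was_normalized = bool(flags & 1)
        (n_header,) = struct.unpack_from("<I", data, pos)
        pos += 4
        h.header_lines = []
        for _ in range(n_header):
            (length,) = struct.unpack_from("<I", data, pos)
            pos += 4
            h.header_lines.append(data[pos:pos + length].decode("utf-8"))
            pos += length
        (h.trailing_blank_lines,) = struct.unpack_from("<I", data, pos)
        pos += 4
        (gob_count,) = struct.unpack_from("<I", data, pos)
        pos += 4
        h.offsets = []
        h.counts = []
        for _ in range(gob_count):
            off, cnt = struct.unpack_from("<QI", data, pos)
            pos += 12
            h.offsets.append(off)
            h.counts.append(cnt)
        (h.payload_len,) = struct.unpack_from("<Q", data, pos)
        pos += 8
    except struct.error as exc:
        raise ContainerFormatError(f"truncated container header: {exc}") from exc
    h.payload_start = pos
    if len(data) - pos < h.payload_len:
        raise CoderIntegrityError(
            f"payload truncated: expected {h.payload_len} bytes, "
            f"found {len(data) - pos}"
        )
    return h


def read_gob_index(data: bytes) -> List[Tuple[int, int]]:
    """(byte offset, MSAB count) of every GOB in a container."""
    h = _read_header(data)
    return list(zip(h.offsets, h.counts))


def decompress_file(
    data: bytes,
    gob_range: Optional[Tuple[int, int]] = None,
    n_workers: int = 1,
) -> MafFile:
    """Decompress a container; optionally only GOBs ``first..last`` (inclusive,
    zero-based).

    A partial decode returns exactly the MSABs of the selected GOBs prefixed
    by the global MAF header.  The worker count is independent of the one
    used by the encoder.
    """
    h = _read_header(data)
    gob_count = len(h.offsets)
    if gob_range is None:
        first, last = 0, gob_count - 1
    else:
        first, last = gob_range
        if not (0 <= first <= last < gob_count):
            raise ValueError(
                f"GOB range ({first},{last}) out of bounds for {gob_count} GOBs"
            )
    bounds = h.offsets + [h.payload_len]
    payloads = []
    for g in range(first, last + 1):
        seg = data[
            h.payload_start + bounds[g]: h.payload_start + bounds[g + 1]
        ]
        if len(seg) != bounds[g + 1] - bounds[g]:
            raise CoderIntegrityError(f"payload of GOB {g} is truncated")
        payloads.append(seg)
    counts = h.counts[first:last + 1]
    configs = [h.config] * len(payloads)
    if n_workers > 1 and len(payloads) > 1:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            decoded = list(pool.map(_decode_gob, payloads, configs, counts))
    else:
        decoded = [
            _decode_gob(p, c, n) for p, c, n in zip(payloads, configs, counts)
        ]
    blocks: List[MSAB] = []
    for part in decoded:
        blocks.extend(part)
    trailing = h.trailing_blank_lines if last == gob_count - 1 and gob_count else 0
    if gob_count == 0:
        trailing = h.trailing_blank_lines
    return MafFile(
        header_lines=list(h.header_lines),
        blocks=blocks,
        trailing_blank_lines=trailing,
        was_normalized=h.was_normalized,
    )
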