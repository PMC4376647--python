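"""MAF-specific predictive codecs.

The alignment text of the ``s`` lines is treated as an image with five
intensities {A, C, G, T, -} and coded cell by cell in raster order under a
2D causal context template.  Each character is decomposed into up to three
streams:

=======  ===========  ============  ===========
symbol   main stream  extra stream  case stream
=======  ===========  ============  ===========
A / a        0            --          0 / 1
C / c        1            0           0 / 1
G / g        2            --          0 / 1
T / t        3            --          0 / 1
N / n        1            1           0 / 1
``-``        4            --          --
=======  ===========  ============  ===========

The extra stream disambiguates C/c from N/n (main symbol 1); the case
stream carries upper/lower case for every non-gap symbol.  Headers are
coded predictively: source names through a dictionary built on first
occurrence, start positions as the offset ``start_x - start_{x-1} -
size_{x-1}`` from the previous line of the same source (zero for contiguous
alignments; negative offsets fall back to absolute coding signalled by a
binary side stream), and the ``size`` field is never transmitted for ``s``
lines -- the decoder recounts the non-gaps of the decoded row.

``q`` values are coded over the 12-symbol alphabet {0..9, F, .} at non-gap
positions only; ``i`` lines exploit the left==previous-right correlation
with per-field irregularity side streams; ``e`` statuses are predicted from
the last ``e``/``i`` status of the same source.  All streams share one
arithmetic coder per GOB with a fixed deterministic interleaving, so the
decoder mirrors the encoder's model state bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

from .coder import ArithmeticDecoder, ArithmeticEncoder, CoderIntegrityError
from .fcm import FCModel, build_template
from .maf import ELine, ILine, MSAB, QLine, SLine

__all__ = [
    "StreamBundle",
    "split_row",
    "merge_row",
    "CodecConfig",
    "SourceState",
    "predict_start",
    "GobEncoder",
    "GobDecoder",
]

# -- three-stream decomposition -------------------------------------------

MAIN_INDEX = {
    "A": 0, "a": 0, "C": 1, "c": 1, "G": 2, "g": 2,
    "T": 3, "t": 3, "N": 1, "n": 1, "-": 4,
}
EXTRA_BIT = {"C": 0, "c": 0, "N": 1, "n": 1}
CASE_BIT = {c: (1 if c.islower() else 0) for c in "AaCcGgTtNn"}
_MERGE = {
    (0, None, 0): "A", (0, None, 1): "a",
    (1, 0, 0): "C", (1, 0, 1): "c",
    (1, 1, 0): "N", (1, 1, 1): "n",
    (2, None, 0): "G", (2, None, 1): "g",
    (3, None, 0): "T", (3, None, 1): "t",
}

GAP = 4  # main-stream index of '-'; also the template padding symbol

Q_SYMBOLS = "0123456789F."
Q_INDEX = {c: i for i, c in enumerate(Q_SYMBOLS)}
I_STATUS = "CINnMT"
I_STATUS_INDEX = {c: i for i, c in enumerate(I_STATUS)}
E_STATUS = "CINMT"
E_STATUS_INDEX = {c: i for i, c in enumerate(E_STATUS)}

_MAX_TOTAL = 1 << 16
_STR_TERM = 256  # end-of-string symbol of the uniform byte model
_INT_TERM = 10   # terminator of the uniform decimal-digit model


@dataclass
class StreamBundle:
    """The main/extra/case streams of one alignment row."""

    main: List[int]
    extra: List[int]
    case: List[int]


def split_row(text: str) -> StreamBundle:
    """Decompose an alignment row into its main/extra/case streams."""
    main: List[int] = []
    extra: List[int] = []
    case: List[int] = []
    for ch in text:
        try:
            m = MAIN_INDEX[ch]
        except KeyError:
            raise ValueError(f"character {ch!r} outside the alignment alphabet")
        main.append(m)
        if m == GAP:
            continue
        if m == 1:
            extra.append(EXTRA_BIT[ch])
        case.append(CASE_BIT[ch])
    return StreamBundle(main=main, extra=extra, case=case)


def merge_row(bundle: StreamBundle) -> str:
    """Exact inverse of :func:`split_row`."""
    out: List[str] = []
    ei = ci = 0
    extra, case = bundle.extra, bundle.case
    for m in bundle.main:
        if m == GAP:
            out.append("-")
            continue
        eb: Optional[int] = None
        if m == 1:
            if ei >= len(extra):
                raise CoderIntegrityError("extra stream exhausted")
            eb = extra[ei]
            ei += 1
        if ci >= len(case):
            raise CoderIntegrityError("case stream exhausted")
        cb = case[ci]
        ci += 1
        out.append(_MERGE[(m, eb, cb)])
    if ei != len(extra) or ci != len(case):
        raise CoderIntegrityError("stream lengths inconsistent with main stream")
    return "".join(out)


# -- configuration ---------------------------------------------------------

@dataclass(frozen=True)
class CodecConfig:
    """Model orders and smoothing; recorded in the container header so the
    decoder mirrors the encoder exactly."""

    template_id: str = "C"
    template_depth: int = 10
    order_extra: int = 5
    order_case: int = 5
    order_start_flag: int = 5
    order_strand: int = 3
    order_q_values: int = 5
    order_q_presence: int = 5
    order_q_per_line: int = 5
    order_i_presence: int = 5
    order_i_status: int = 4
    order_i_irregular_count: int = 5
    order_i_irregular_status: int = 5
    order_e_irregular_status_vs_e: int = 5
    order_e_irregular_status_vs_i: int = 5
    alpha: Fraction = Fraction(1)

    def __post_init__(self):
        object.__setattr__(self, "alpha", Fraction(self.alpha))
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for name in self.__dataclass_fields__:
            if name.startswith("order_") and getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# -- per-source predictive state -------------------------------------------

class SourceState:
    """Predictive state of one source sequence, mutated only by the codecs."""

    __slots__ = ("sid", "name", "src_size", "last_start", "last_size",
                 "i_status", "i_count", "e_status", "e_from")

    def __init__(self, sid: int, name: str, src_size: int):
        self.sid = sid
        self.name = name
        self.src_size = src_size
        self.last_start: Optional[int] = None
        self.last_size: Optional[int] = None
        self.i_status: Optional[str] = None
        self.i_count: Optional[int] = None
        self.e_status: Optional[str] = None
        self.e_from: Optional[str] = None


def predict_start(state: Optional[SourceState], start: int) -> Tuple[str, int]:
    """Offset-or-absolute start prediction.

    Returns ``("offset", start - last_start - last_size)`` when the source
    has prior state and the offset is non-negative (zero for contiguous
    alignments); otherwise ``("absolute", start)``.
    """
    if state is not None and state.last_start is not None:
        off = start - state.last_start - state.last_size
        if off >= 0:
            return ("offset", off)
    return ("absolute", start)


# -- small adaptive models --------------------------------------------------

class BitModel:
    """Adaptive order-``k`` binary model contexted on its own last k bits."""

    __slots__ = ("mask", "hist", "c", "anum", "aden")

    def __init__(self, k: int, anum: int = 1, aden: int = 1):
        self.mask = (1 << k) - 1
        self.hist = 0
        self.c = [0] * ((1 << k) * 2)
        self.anum = anum
        self.aden = aden

    def encode(self, enc: ArithmeticEncoder, bit: int) -> None:
        i = (self.hist & self.mask) << 1
        c = self.c
        f0 = c[i] * self.aden + self.anum
        f1 = c[i + 1] * self.aden + self.anum
        total = f0 + f1
        if total >= _MAX_TOTAL:
            shift = total.bit_length() - 15
            f0 = max(1, f0 >> shift)
            f1 = max(1, f1 >> shift)
            total = f0 + f1
        if bit:
            enc.encode(f0, total, total)
        else:
            enc.encode(0, f0, total)
        c[i + bit] += 1
        self.hist = ((self.hist << 1) | bit) & self.mask

    def decode(self, dec: ArithmeticDecoder) -> int:
        i = (self.hist & self.mask) << 1
        c = self.c
        f0 = c[i] * self.aden + self.anum
        f1 = c[i + 1] * self.aden + self.anum
        total = f0 + f1
        if total >= _MAX_TOTAL:
            shift = total.bit_length() - 15
            f0 = max(1, f0 >> shift)
            f1 = max(1, f1 >> shift)
            total = f0 + f1
        bit = 1 if dec.decode_target(total) >= f0 else 0
        if bit:
            dec.decode_update(f0, total, total)
        else:
            dec.decode_update(0, f0, total)
        c[i + bit] += 1
        self.hist = ((self.hist << 1) | bit) & self.mask
        return bit


class RollingFCM:
    """Adaptive order-``k`` model over an m-ary alphabet, contexted on its
    own previous symbols (rolling packed key)."""

    __slots__ = ("model", "key", "mod", "a")

    def __init__(self, k: int, alphabet_size: int, alpha=1):
        self.model = FCModel(k, alphabet_size, alpha)
        self.key = 0
        self.mod = alphabet_size ** k
        self.a = alphabet_size

    def encode(self, enc: ArithmeticEncoder, symbol: int) -> None:
        m = self.model
        f, total = m.freqs(self.key)
        enc.encode_freqs(f, total, symbol)
        row = m.counts.get(self.key)
        if row is None:
            m.counts[self.key] = row = [0] * self.a
        row[symbol] += 1
        self.key = (self.key * self.a + symbol) % self.mod

    def decode(self, dec: ArithmeticDecoder) -> int:
        m = self.model
        f, total = m.freqs(self.key)
        symbol = dec.decode_freqs(f, total)
        row = m.counts.get(self.key)
        if row is None:
            m.counts[self.key] = row = [0] * self.a
        row[symbol] += 1
        self.key = (self.key * self.a + symbol) % self.mod
        return symbol


class _ModelBank:
    """All adaptive models of one GOB, in one place so encoder and decoder
    construct identical state."""

    def __init__(self, config: CodecConfig):
        anum = config.alpha.numerator
        aden = config.alpha.denominator
        self.anum = anum
        self.aden = aden
        self.template = build_template(config.template_id, config.template_depth)
        self.main_counts: Dict[int, List[int]] = {}
        self.extra = BitModel(config.order_extra, anum, aden)
        self.case = BitModel(config.order_case, anum, aden)
        self.start_flag = BitModel(config.order_start_flag, anum, aden)
        self.strand = BitModel(config.order_strand, anum, aden)
        self.q_block = BitModel(config.order_q_presence, anum, aden)
        self.q_line = BitModel(config.order_q_per_line, anum, aden)
        self.q_vals = RollingFCM(config.order_q_values, len(Q_SYMBOLS), config.alpha)
        self.i_block = BitModel(config.order_i_presence, anum, aden)
        self.i_line = BitModel(config.order_i_presence, anum, aden)
        self.i_status = RollingFCM(config.order_i_status, len(I_STATUS), config.alpha)
        self.i_irr_status = BitModel(config.order_i_irregular_status, anum, aden)
        self.i_irr_count = BitModel(config.order_i_irregular_count, anum, aden)
        self.e_irr_e = BitModel(config.order_e_irregular_status_vs_e, anum, aden)
        self.e_irr_i = BitModel(config.order_e_irregular_status_vs_i, anum, aden)
        self.e_status = RollingFCM(0, len(E_STATUS), config.alpha)


class _SourceTable:
    """Dense source-name dictionary shared by encoder and decoder."""

    def __init__(self):
        self.by_name: Dict[str, SourceState] = {}
        self.by_id: List[SourceState] = []

    def add(self, name: str, src_size: int) -> SourceState:
        state = SourceState(len(self.by_id), name, src_size)
        self.by_name[name] = state
        self.by_id.append(state)
        return state


# -- GOB encoder ------------------------------------------------------------

class GobEncoder:
    """Encodes a run of MSABs into one self-contained arithmetic-coded
    segment with fresh model state."""

    def __init__(self, config: Optional[CodecConfig] = None):
        self.config = config or CodecConfig()
        self.m = _ModelBank(self.config)
        self.table = _SourceTable()
        self.enc = ArithmeticEncoder()
        self.n_blocks = 0

    # small static-model primitives
    def _encode_int(self, value: int) -> None:
        if value < 0:
            raise ValueError("only non-negative integers are coded")
        enc = self.enc
        for ch in str(value):
            d = ord(ch) - 48
            enc.encode(d, d + 1, 11)
        enc.encode(_INT_TERM, _INT_TERM + 1, 11)

    def _encode_str(self, text: str) -> None:
        enc = self.enc
        for b in text.encode("utf-8"):
            enc.encode(b, b + 1, 257)
        enc.encode(_STR_TERM, _STR_TERM + 1, 257)

    def _lookup_source(self, name: str, src_size: int) -> SourceState:
        state = self.table.by_name.get(name)
        if state is None:
            self._encode_int(len(self.table.by_id))
            state = self.table.add(name, src_size)
            self._encode_str(name)
            self._encode_int(src_size)
        else:
            if state.src_size != src_size:
                raise ValueError(
                    f"source {name!r} reappears with src_size {src_size} != "
                    f"{state.src_size}"
                )
            self._encode_int(state.sid)
        return state

    def _encode_start(self, state: SourceState, start: int) -> None:
        if state.last_start is None:
            self._encode_int(start)
            return
        mode, value = predict_start(state, start)
        if mode == "offset":
            self.m.start_flag.encode(self.enc, 0)
        else:
            self.m.start_flag.encode(self.enc, 1)
        self._encode_int(value)

    def encode_block(self, msab: MSAB) -> None:
        enc = self.enc
        m = self.m
        rows = msab.rows
        n_rows = len(rows)
        n_cols = msab.n_columns
        self._encode_int(n_rows)
        if n_rows:
            self._encode_int(n_cols)
        self._encode_int(len(msab.e_lines))
        self._encode_int(msab.inter_block_blank_lines)
        self._encode_str(msab.a_line_text)

        # --- s headers (size is never transmitted: recounted on decode) ---
        for row in rows:
            if len(row.text) != n_cols:
                raise ValueError("unequal row lengths within a block")
            if row.size != len(row.text) - row.text.count("-"):
                raise ValueError(
                    f"size field of {row.source!r} does not match its non-gap "
                    "count; refusing to encode an invalid block"
                )
            state = self._lookup_source(row.source, row.src_size)
            self._encode_start(state, row.start)
            m.strand.encode(enc, 0 if row.strand == "+" else 1)

        # --- alignment image ---
        if n_rows:
            self._encode_image([r.text for r in rows])

        # start-prediction state updates happen after the image, mirroring
        # the decoder (which needs the decoded text to recount sizes)
        for row in rows:
            state = self.table.by_name[row.source]
            state.last_start = row.start
            state.last_size = row.size

        # --- q lines ---
        if n_rows:
            if rows[0].q_line is not None:
                raise ValueError("reference row must not carry a 'q' line")
            has_q = any(r.q_line is not None for r in rows[1:])
            m.q_block.encode(enc, 1 if has_q else 0)
            if has_q:
                for row in rows[1:]:
                    m.q_line.encode(enc, 1 if row.q_line is not None else 0)
                qm = m.q_vals
                for row in rows[1:]:
                    if row.q_line is None:
                        continue
                    for qc, sc in zip(row.q_line.values, row.text):
                        if sc != "-":
                            qm.encode(enc, Q_INDEX[qc])

        # --- i lines ---
        if n_rows:
            has_i = any(r.i_line is not None for r in rows)
            m.i_block.encode(enc, 1 if has_i else 0)
            if has_i:
                for row in rows:
                    m.i_line.encode(enc, 1 if row.i_line is not None else 0)
                for row in rows:
                    il = row.i_line
                    if il is None:
                        continue
                    self._encode_i(self.table.by_name[row.source], il)

        # --- e lines ---
        for e in msab.e_lines:
            state = self._lookup_source(e.source, e.src_size)
            self._encode_start(state, e.start)
            self._encode_int(e.size)
            m.strand.encode(enc, 0 if e.strand == "+" else 1)
            if state.e_status is None:
                m.e_status.encode(enc, E_STATUS_INDEX[e.status])
            else:
                irr_model = m.e_irr_e if state.e_from == "e" else m.e_irr_i
                irregular = 1 if e.status != state.e_status else 0
                irr_model.encode(enc, irregular)
                if irregular:
                    m.e_status.encode(enc, E_STATUS_INDEX[e.status])
            state.e_status = e.status
            state.e_from = "e"
            state.last_start = e.start
            state.last_size = e.size

        self.n_blocks += 1

    def _encode_i(self, state: SourceState, il: ILine) -> None:
        enc = self.enc
        m = self.m
        if state.i_status is None:
            # first 'i' of this source: all four fields explicitly
            m.i_status.encode(enc, I_STATUS_INDEX[il.left_status])
            self._encode_int(il.left_count)
        else:
            irr_s = 1 if il.left_status != state.i_status else 0
            m.i_irr_status.encode(enc, irr_s)
            if irr_s:
                m.i_status.encode(enc, I_STATUS_INDEX[il.left_status])
            irr_c = 1 if il.left_count != state.i_count else 0
            m.i_irr_count.encode(enc, irr_c)
            if irr_c:
                self._encode_int(il.left_count)
        m.i_status.encode(enc, I_STATUS_INDEX[il.right_status])
        self._encode_int(il.right_count)
        state.i_status = il.right_status
        state.i_count = il.right_count
        # the 'e' status predictor follows the most recent 'e' or 'i' line
        state.e_status = il.right_status
        state.e_from = "i"

    def _encode_image(self, texts: Sequence[str]) -> None:
        offs = self.m.template.offsets
        n_rows = len(texts)
        n_cols = len(texts[0])
        mr = max(-dr for dr, _ in offs)
        mcl = max(max(-dc for _, dc in offs), 0)
        mcr = max(max(dc for _, dc in offs), 0)
        width = n_cols + mcl + mcr
        grid = [GAP] * ((n_rows + mr) * width)
        ow = tuple(
            (dr * width + dc, 5 ** i) for i, (dr, dc) in enumerate(offs)
        )
        enc = self.enc
        encode = enc.encode
        main_counts = self.m.main_counts
        case = self.m.case
        extra = self.m.extra
        anum, aden = self.m.anum, self.m.aden
        a5 = 5 * anum
        main_index = MAIN_INDEX
        case_bit = CASE_BIT
        extra_bit = EXTRA_BIT
        for r, text in enumerate(texts):
            base = (r + mr) * width + mcl
            for c, ch in enumerate(text):
                p = base + c
                s = main_index[ch]
                key = 0
                for o, w in ow:
                    key += grid[p + o] * w
                row_c = main_counts.get(key)
                if row_c is None:
                    main_counts[key] = row_c = [0, 0, 0, 0, 0]
                    encode(s * anum, s * anum + anum, a5)
                else:
                    f0 = row_c[0] * aden + anum
                    f1 = row_c[1] * aden + anum
                    f2 = row_c[2] * aden + anum
                    f3 = row_c[3] * aden + anum
                    f4 = row_c[4] * aden + anum
                    total = f0 + f1 + f2 + f3 + f4
                    if total >= _MAX_TOTAL:
                        shift = total.bit_length() - 15
                        f0 = max(1, f0 >> shift)
                        f1 = max(1, f1 >> shift)
                        f2 = max(1, f2 >> shift)
                        f3 = max(1, f3 >> shift)
                        f4 = max(1, f4 >> shift)
                        total = f0 + f1 + f2 + f3 + f4
                    if s == 0:
                        encode(0, f0, total)
                    elif s == 1:
                        encode(f0, f0 + f1, total)
                    elif s == 2:
                        encode(f0 + f1, f0 + f1 + f2, total)
                    elif s == 3:
                        encode(f0 + f1 + f2, total - f4, total)
                    else:
                        encode(total - f4, total, total)
                row_c[s] += 1
                grid[p] = s
                if s != GAP:
                    if s == 1:
                        extra.encode(enc, extra_bit[ch])
                    case.encode(enc, case_bit[ch])

    def finish(self) -> bytes:
        return self.enc.finish()


# -- GOB decoder ------------------------------------------------------------

class GobDecoder:
    """Mirror of :class:`GobEncoder` over one GOB payload."""

    def __init__(self, data: bytes, config: Optional[CodecConfig] = None):
        self.config = config or CodecConfig()
        self.m = _ModelBank(self.config)
        self.table = _SourceTable()
        self.dec = ArithmeticDecoder(data)

    def _decode_int(self) -> int:
        dec = self.dec
        digits: List[str] = []
        while True:
            sym = dec.decode_target(11)
            dec.decode_update(sym, sym + 1, 11)
            if sym == _INT_TERM:
                break
            digits.append(chr(48 + sym))
            if len(digits) > 20:
                raise CoderIntegrityError("unterminated integer")
        if not digits:
            raise CoderIntegrityError("integer with no digits")
        return int("".join(digits))

    def _decode_str(self) -> str:
        dec = self.dec
        out = bytearray()
        while True:
            sym = dec.decode_target(257)
            dec.decode_update(sym, sym + 1, 257)
            if sym == _STR_TERM:
                break
            out.append(sym)
            if len(out) > 1 << 16:
                raise CoderIntegrityError("unterminated string")
        return out.decode("utf-8")

    def _decode_source(self) -> SourceState:
        sid = self._decode_int()
        n = len(self.table.by_id)
        if sid > n:
            raise CoderIntegrityError(f"source id {sid} out of table range {n}")
        if sid == n:
            name = self._decode_str()
            src_size = self._decode_int()
            return self.table.add(name, src_size)
        return self.table.by_id[sid]

    def _decode_start(self, state: SourceState) -> int:
        if state.last_start is None:
            return self._decode_int()
        absolute = self.m.start_flag.decode(self.dec)
        value = self._decode_int()
        if absolute:
            return value
        return state.last_start + state.last_size + value

    def decode_block(self) -> MSAB:
        dec = self.dec
        m = self.m
        n_rows = self._decode_int()
        n_cols = self._decode_int() if n_rows else 0
        n_e = self._decode_int()
        blank = self._decode_int()
        a_text = self._decode_str()
        msab = MSAB(a_line_text=a_text, inter_block_blank_lines=blank)

        headers: List[Tuple[SourceState, int, str]] = []
        for _ in range(n_rows):
            state = self._decode_source()
            start = self._decode_start(state)
            strand = "-" if m.strand.decode(dec) else "+"
            headers.append((state, start, strand))

        texts = self._decode_image(n_rows, n_cols) if n_rows else []

        for (state, start, strand), text in zip(headers, texts):
            size = len(text) - text.count("-")
            msab.rows.append(
                SLine(
                    source=state.name,
                    start=start,
                    size=size,
                    strand=strand,
                    src_size=state.src_size,
                    text=text,
                )
            )
            state.last_start = start
            state.last_size = size

        if n_rows:
            if m.q_block.decode(dec):
                flags = [m.q_line.decode(dec) for _ in msab.rows[1:]]
                qm = m.q_vals
                for row, flag in zip(msab.rows[1:], flags):
                    if not flag:
                        continue
                    vals = []
                    for sc in row.text:
                        if sc == "-":
                            vals.append("-")
                        else:
                            vals.append(Q_SYMBOLS[qm.decode(dec)])
                    row.q_line = QLine(values="".join(vals))

            if m.i_block.decode(dec):
                flags = [m.i_line.decode(dec) for _ in msab.rows]
                for row, flag in zip(msab.rows, flags):
                    if flag:
                        row.i_line = self._decode_i(self.table.by_name[row.source])

        for _ in range(n_e):
            state = self._decode_source()
            start = self._decode_start(state)
            size = self._decode_int()
            strand = "-" if m.strand.decode(dec) else "+"
            if state.e_status is None:
                status = E_STATUS[m.e_status.decode(dec)]
            else:
                irr_model = m.e_irr_e if state.e_from == "e" else m.e_irr_i
                if irr_model.decode(dec):
                    status = E_STATUS[m.e_status.decode(dec)]
                else:
                    status = state.e_status
            msab.e_lines.append(
                ELine(
                    source=state.name,
                    start=start,
                    size=size,
                    strand=strand,
                    src_size=state.src_size,
                    status=status,
                )
            )
            state.e_status = status
            state.e_from = "e"
            state.last_start = start
            state.last_size = size

        return msab

    def _decode_i(self, state: SourceState) -> ILine:
        dec = self.dec
        m = self.m
        if state.i_status is None:
            left_status = I_STATUS[m.i_status.decode(dec)]
            left_count = self._decode_int()
        else:
            if m.i_irr_status.decode(dec):
                left_status = I_STATUS[m.i_status.decode(dec)]
            else:
                left_status = state.i_status
            if m.i_irr_count.decode(dec):
                left_count = self._decode_int()
            else:
                left_count = state.i_count
        right_status = I_STATUS[m.i_status.decode(dec)]
        right_count = self._decode_int()
        state.i_status = right_status
        state.i_count = right_count
        state.e_status = right_status
        state.e_from = "i"
        return ILine(
            left_status=left_status,
            left_count=left_count,
            right_status=right_status,
            right_count=right_count,
        )

    def _decode_image(self, n_rows: int, n_cols: int) -> List[str]:
        offs = self.m.template.offsets
        mr = max(-dr for dr, _ in offs)
        mcl = max(max(-dc for _, dc in offs), 0)
        mcr = max(max(dc for _, dc in offs), 0)
        width = n_cols + mcl + mcr
        grid = [GAP] * ((n_rows + mr) * width)
        ow = tuple(
            (dr * width + dc, 5 ** i) for i, (dr, dc) in enumerate(offs)
        )
        dec = self.dec
        decode_target = dec.decode_target
        decode_update = dec.decode_update
        main_counts = self.m.main_counts
        case = self.m.case
        extra = self.m.extra
        anum, aden = self.m.anum, self.m.aden
        a5 = 5 * anum
        texts: List[str] = []
        for r in range(n_rows):
            base = (r + mr) * width + mcl
            chars: List[str] = []
            for c in range(n_cols):
                p = base + c
                key = 0
                for o, w in ow:
                    key += grid[p + o] * w
                row_c = main_counts.get(key)
                if row_c is None:
                    main_counts[key] = row_c = [0, 0, 0, 0, 0]
                    s = decode_target(a5) // anum
                    decode_update(s * anum, s * anum + anum, a5)
                else:
                    f0 = row_c[0] * aden + anum
                    f1 = row_c[1] * aden + anum
                    f2 = row_c[2] * aden + anum
                    f3 = row_c[3] * aden + anum
                    f4 = row_c[4] * aden + anum
                    total = f0 + f1 + f2 + f3 + f4
                    if total >= _MAX_TOTAL:
                        shift = total.bit_length() - 15
                        f0 = max(1, f0 >> shift)
                        f1 = max(1, f1 >> shift)
                        f2 = max(1, f2 >> shift)
                        f3 = max(1, f3 >> shift)
                        f4 = max(1, f4 >> shift)
                        total = f0 + f1 + f2 + f3 + f4
                    target = decode_target(total)
                    cum = 0
                    if target < f0:
                        s = 0
                        hi = f0
                    elif target < f0 + f1:
                        s = 1
                        cum = f0
                        hi = f0 + f1
                    elif target < f0 + f1 + f2:
                        s = 2
                        cum = f0 + f1
                        hi = cum + f2
                    elif target < total - f4:
                        s = 3
                        cum = f0 + f1 + f2
                        hi = total - f4
                    else:
                        s = 4
                        cum = total - f4
                        hi = total
                    decode_update(cum, hi, total)
                row_c[s] += 1
                grid[p] = s
                if s == GAP:
                    chars.append("-")
                else:
                    eb = extra.decode(dec) if s == 1 else None
                    cb = case.decode(dec)
                    chars.append(_MERGE[(s, eb, cb)])
            texts.append("".join(chars))
        return texts
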