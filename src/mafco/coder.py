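"""Binary arithmetic coder with 32-bit range registers.

Classic low/high interval coder: the interval is narrowed by the cumulative
frequency span of each symbol, renormalized bit by bit, with carry
propagation handled by a pending-bit counter (the E3 condition).  The
decoder, presented with the same frequency tables in the same order,
reproduces the symbol stream exactly; code length approaches the Shannon
information of the stream under the presented distributions.

Frequency totals must stay below 2**16 so that ``span * total`` fits well
inside the 32-bit interval arithmetic.
"""

from __future__ import annotations

from typing import List, Sequence

__all__ = ["ArithmeticEncoder", "ArithmeticDecoder", "CoderIntegrityError"]

_BITS = 32
_TOP = 1 << _BITS
_HALF = _TOP >> 1
_Q1 = _TOP >> 2
_Q3 = _HALF + _Q1
_MASK = _TOP - 1


class CoderIntegrityError(ValueError):
    """Raised when a bitstream is corrupted, truncated or inconsistent."""


class ArithmeticEncoder:
    __slots__ = ("low", "high", "pending", "_buf", "_nbits", "_out", "_finished")

    def __init__(self):
        self.low = 0
        self.high = _TOP - 1
        self.pending = 0
        self._buf = 0
        self._nbits = 0
        self._out = bytearray()
        self._finished = False

    def encode(self, cum_lo: int, cum_hi: int, total: int) -> None:
        """Encode a symbol occupying [cum_lo, cum_hi) of a ``total`` span."""
        low = self.low
        span = self.high - low + 1
        self.high = high = low + (span * cum_hi) // total - 1
        self.low = low = low + (span * cum_lo) // total
        if cum_lo >= cum_hi:
            raise ValueError("symbol has empty frequency span")
        pending = self.pending
        buf = self._buf
        nbits = self._nbits
        while True:
            if high < _HALF:
                bit = 0
            elif low >= _HALF:
                bit = 1
                low -= _HALF
                high -= _HALF
            elif low >= _Q1 and high < _Q3:
                pending += 1
                low -= _Q1
                high -= _Q1
                low <<= 1
                high = (high << 1) | 1
                continue
            else:
                break
            buf = (buf << 1) | bit
            nbits += 1
            if pending:
                buf = (buf << pending) | ((1 - bit) * ((1 << pending) - 1))
                nbits += pending
                pending = 0
            low <<= 1
            high = (high << 1) | 1
        if nbits >= 8:
            out = self._out
            while nbits >= 8:
                nbits -= 8
                out.append((buf >> nbits) & 0xFF)
            buf &= (1 << nbits) - 1
        self.low = low
        self.high = high
        self.pending = pending
        self._buf = buf
        self._nbits = nbits

    def encode_freqs(self, freqs: Sequence[int], total: int, symbol: int) -> None:
        """Encode ``symbol`` under an explicit frequency table."""
        cum = 0
        for s in range(symbol):
            cum += freqs[s]
        self.encode(cum, cum + freqs[symbol], total)

    def finish(self) -> bytes:
        """Flush the interval state; returns the complete code bytes."""
        if self._finished:
            raise RuntimeError("encoder already finished")
        self._finished = True
        self.pending += 1
        bit = 0 if self.low < _Q1 else 1
        buf = (self._buf << 1) | bit
        nbits = self._nbits + 1
        buf = (buf << self.pending) | ((1 - bit) * ((1 << self.pending) - 1))
        nbits += self.pending
        out = self._out
        while nbits >= 8:
            nbits -= 8
            out.append((buf >> nbits) & 0xFF)
        if nbits:
            out.append((buf << (8 - nbits)) & 0xFF)
        return bytes(out)

    @property
    def bytes_so_far(self) -> int:
        """Bytes emitted so far (excluding the final flush)."""
        return len(self._out)


class ArithmeticDecoder:
    __slots__ = ("low", "high", "value", "_data", "_pos", "_bit")

    def __init__(self, data: bytes):
        self.low = 0
        self.high = _TOP - 1
        self._data = data
        self._pos = 0
        self._bit = 0
        value = 0
        for _ in range(_BITS):
            value = (value << 1) | self._next_bit()
        self.value = value

    def _next_bit(self) -> int:
        # Zero bits past the end of the payload: the encoder's final flush
        # guarantees the remaining symbols decode identically.
        pos = self._pos
        if pos >= len(self._data):
            return 0
        bit = (self._data[pos] >> (7 - self._bit)) & 1
        if self._bit == 7:
            self._bit = 0
            self._pos = pos + 1
        else:
            self._bit += 1
        return bit

    def decode_target(self, total: int) -> int:
        """Scaled position of the pending symbol inside a ``total`` span."""
        span = self.high - self.low + 1
        target = ((self.value - self.low + 1) * total - 1) // span
        if target >= total:
            raise CoderIntegrityError("corrupted bitstream: target out of range")
        return target

    def decode_update(self, cum_lo: int, cum_hi: int, total: int) -> None:
        """Consume the symbol spanning [cum_lo, cum_hi); mirrors ``encode``."""
        low = self.low
        span = self.high - low + 1
        self.high = high = low + (span * cum_hi) // total - 1
        low = low + (span * cum_lo) // total
        value = self.value
        next_bit = self._next_bit
        while True:
            if high < _HALF:
                pass
            elif low >= _HALF:
                low -= _HALF
                high -= _HALF
                value -= _HALF
            elif low >= _Q1 and high < _Q3:
                low -= _Q1
                high -= _Q1
                value -= _Q1
            else:
                break
            low <<= 1
            high = (high << 1) | 1
            value = (value << 1) | next_bit()
        self.low = low
        self.high = high
        self.value = value

    def decode_freqs(self, freqs: Sequence[int], total: int) -> int:
        """Decode one symbol under an explicit frequency table."""
        target = self.decode_target(total)
        cum = 0
        for symbol, f in enumerate(freqs):
            if cum + f > target:
                self.decode_update(cum, cum + f, total)
                return symbol
            cum += f
        raise CoderIntegrityError("corrupted bitstream: no symbol matches target")
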