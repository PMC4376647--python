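"""Adaptive finite-context models and 2D causal context templates.

An order-``k`` finite-context model (FCM) over a finite alphabet assigns

    P(s | ctx) = (c(s|ctx) + alpha) / (c(ctx) + |A| * alpha)

where ``c(s|ctx)`` is the number of times symbol ``s`` followed context
``ctx`` so far and ``c(ctx)`` is the total count of the context.  With
``alpha = 1`` this is the Laplace estimator.  Counts accumulate while the
source is processed and are never rescaled; only the frequency snapshot
handed to the arithmetic coder is quantized (16-bit totals, every symbol
floor-forced to frequency >= 1) so that rare symbols stay decodable.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Sequence, Tuple

__all__ = ["FCModel", "ContextTemplate", "build_template", "TEMPLATE_IDS"]

#: Largest frequency total accepted by the arithmetic coder.
MAX_TOTAL = 1 << 16


class FCModel:
    """Adaptive order-``k`` count model over an ``alphabet_size``-ary alphabet.

    ``alpha`` is the additive smoothing parameter and may be a rational
    (e.g. ``Fraction(1, 16)``); probabilities are exact fractions, coder
    frequencies are the equivalent integers ``c*den + num``.
    """

    __slots__ = ("k", "alphabet_size", "alpha", "anum", "aden", "counts")

    def __init__(self, k: int, alphabet_size: int, alpha=1):
        if k < 0:
            raise ValueError("context order k must be >= 0")
        if alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")
        alpha = Fraction(alpha)
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.k = k
        self.alphabet_size = alphabet_size
        self.alpha = alpha
        self.anum = alpha.numerator
        self.aden = alpha.denominator
        self.counts: Dict[int, List[int]] = {}

    # -- context packing ---------------------------------------------------
    def key(self, context: Sequence[int]) -> int:
        """Pack a length-``k`` symbol sequence into an integer table key."""
        if len(context) != self.k:
            raise ValueError(f"context must have length {self.k}")
        key = 0
        a = self.alphabet_size
        for s in context:
            if not 0 <= s < a:
                raise ValueError(f"context symbol {s} outside alphabet")
            key = key * a + s
        return key

    # -- estimation --------------------------------------------------------
    def probability(self, context: Sequence[int], symbol: int) -> Fraction:
        """Exact smoothed probability of ``symbol`` after ``context``."""
        if not 0 <= symbol < self.alphabet_size:
            raise ValueError(f"symbol {symbol} outside alphabet")
        row = self.counts.get(self.key(context))
        c_s = row[symbol] if row is not None else 0
        c_tot = sum(row) if row is not None else 0
        return Fraction(c_s * self.aden + self.anum,
                        c_tot * self.aden + self.alphabet_size * self.anum)

    def update(self, context: Sequence[int], symbol: int) -> None:
        """Record one occurrence of ``symbol`` after ``context``."""
        if not 0 <= symbol < self.alphabet_size:
            raise ValueError(f"symbol {symbol} outside alphabet")
        key = self.key(context)
        row = self.counts.get(key)
        if row is None:
            row = [0] * self.alphabet_size
            self.counts[key] = row
        row[symbol] += 1

    # -- coder interface ---------------------------------------------------
    def freqs(self, key: int) -> Tuple[List[int], int]:
        """Integer frequencies and total for a packed context key.

        Quantized so ``total < 2**16`` with every frequency >= 1 (decodable
        rare symbols); exact whenever the raw total already fits.
        """
        row = self.counts.get(key)
        anum, aden, a = self.anum, self.aden, self.alphabet_size
        if row is None:
            return [anum] * a, anum * a
        f = [c * aden + anum for c in row]
        total = sum(f)
        if total >= MAX_TOTAL:
            shift = total.bit_length() - 15
            f = [max(1, x >> shift) for x in f]
            total = sum(f)
        return f, total


TEMPLATE_IDS = "ABCDE"
#: Number of previous rows each template may draw context from.
_TEMPLATE_ROWS = {"A": 1, "B": 2, "C": 3, "D": 4, "E": 5}


@dataclass(frozen=True)
class ContextTemplate:
    """Ordered set of strictly causal (row_delta, col_delta) offsets.

    Every offset precedes the current cell in raster order: either in a
    previous row, or to the left in the current row.  Cells falling outside
    the block grid contribute the designated padding symbol.
    """

    offsets: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        for dr, dc in self.offsets:
            if dr > 0 or (dr == 0 and dc >= 0):
                raise ValueError(f"offset ({dr},{dc}) is not strictly causal")

    @property
    def depth(self) -> int:
        return len(self.offsets)

    def context(self, grid: Sequence[Sequence[int]], row: int, col: int,
                pad: int = 4) -> Tuple[int, ...]:
        """Read the template cells at (row, col); out-of-grid cells give ``pad``."""
        n_rows = len(grid)
        out = []
        for dr, dc in self.offsets:
            r, c = row + dr, col + dc
            if 0 <= r < n_rows and 0 <= c < len(grid[r]):
                out.append(grid[r][c])
            else:
                out.append(pad)
        return tuple(out)


def build_template(template_id: str = "C", depth: int = 10) -> ContextTemplate:
    """Construct one of the five templates 'A'..'E' at the requested depth.

    The template takes the ``depth`` nearest strictly-causal cells under a
    fixed priority: cells are ranked by Chebyshev distance from the current
    cell; within a distance the left neighbour in the current row comes
    first, then previous-row cells left to right (nearer rows first on a
    column tie).  Templates A-E may use 1-5 previous rows respectively.
    """
    if template_id not in _TEMPLATE_ROWS:
        raise ValueError(f"unknown template {template_id!r}; expected one of A-E")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n_prev = _TEMPLATE_ROWS[template_id]
    # All candidates within a safely large window, sorted by the priority rule.
    max_d = depth + n_prev + 2
    candidates = []
    for dr in range(-n_prev, 1):
        for dc in range(-max_d, max_d + 1):
            if dr == 0 and dc >= 0:
                continue
            cheb = max(abs(dr), abs(dc))
            same_row = 0 if dr == 0 else 1
            candidates.append(((cheb, same_row, dc, -dr), (dr, dc)))
    candidates.sort()
    offsets = tuple(off for _, off in candidates[:depth])
    if len(offsets) < depth:
        raise ValueError("depth too large for the available causal window")
    return ContextTemplate(offsets=offsets)
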