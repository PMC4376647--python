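"""Seeded generator of synthetic MAF files.

The generator emulates the statistical structure that the codec exploits in
real whole-genome alignments -- not the biology.  Blocks have a heavy
point mass at a single row and a short-column regime (where the 2D
alignment model is weakest); rows are derived from a reference row by
substitution, gap, N and soft-mask (lower-case run) processes; quality
values are heavily skewed towards '9'; 'i' statuses are modally 'C' and
chain left==previous-right up to a configurable irregularity rate; 'e'
statuses are modally 'I' and persist across consecutive blocks; start
fields are contiguous (offset zero) at a configurable rate.

All randomness flows from the single seed: block structure is drawn from a
``random.Random`` and symbol arrays from a ``numpy`` PCG64 generator, in a
fixed documented order (structure first, then per-row arrays), so the same
parameters always produce byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .maf import ELine, ILine, MSAB, MafFile, QLine, SLine

__all__ = ["GenParams", "profile_params", "generate_maf", "maf_quality_value",
           "PROFILES"]

_Q_CHARS = "0123456789F."
_I_STATUS = "CINnMT"
_E_STATUS = "CINMT"
_UPPER = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)
_GAP_CODE = ord("-")
_N_CODE = ord("N")


def maf_quality_value(aqv: int) -> str:
    """Map an actual quality value (0..98) to its MAF quality character.

    ``MAFQV = min(floor(AQV / 5), 9)``; raw scores range 0-97 plus the
    manually assigned 98.
    """
    if not 0 <= aqv <= 98:
        raise ValueError(f"actual quality value {aqv} outside 0..98")
    return str(min(aqv // 5, 9))


@dataclass(frozen=True)
class GenParams:
    """Parameters of the synthetic corpus; defaults emulate an annotated
    28-species alignment (quality, context and empty-region lines present)."""

    seed: int = 0
    n_blocks: int = 100
    n_species: int = 28
    #: probability of a single-row block (the dominant small-block mode)
    p_single_row: float = 0.25
    #: mean additional rows of multi-row blocks (geometric, capped at pool)
    mean_rows: float = 8.0
    #: probability of the short-column regime (1..short_block_max columns)
    p_short_block: float = 0.15
    short_block_max: int = 5
    mean_cols: float = 60.0
    substitution_rate: float = 0.30
    gap_rate: float = 0.15
    ref_gap_rate: float = 0.05
    lowercase_rate: float = 0.10
    #: mean length of a soft-masked (lower-case) run, in columns
    case_run_length: float = 25.0
    n_rate: float = 0.01
    include_q: bool = True
    include_i: bool = True
    include_e: bool = True
    q_presence_rate: float = 0.9
    i_presence_rate: float = 0.9
    e_line_rate: float = 0.3
    max_e_lines: int = 8
    #: probability of each quality character 0..9, F, '.' (modal '9')
    q_char_probs: Tuple[float, ...] = (
        0.004, 0.004, 0.004, 0.004, 0.004, 0.006, 0.01, 0.015, 0.024,
        0.92, 0.004, 0.001,
    )
    #: probability of each 'i' status C, I, N, n, M, T (modal 'C')
    i_status_probs: Tuple[float, ...] = (0.85, 0.08, 0.03, 0.005, 0.03, 0.005)
    #: probability of each 'e' status C, I, N, M, T (modal 'I')
    e_status_probs: Tuple[float, ...] = (0.10, 0.80, 0.04, 0.05, 0.01)
    #: rate at which i-left / e-status predictions are deliberately broken
    irregularity_rate: float = 0.05
    #: rate at which a source's next start is exactly contiguous (offset 0)
    contiguity_rate: float = 0.90
    strand_minus_rate: float = 0.05
    chromosomes_per_species: int = 3

    def __post_init__(self):
        for name, lo, hi in (
            ("p_single_row", 0, 1), ("p_short_block", 0, 1),
            ("substitution_rate", 0, 1), ("gap_rate", 0, 1),
            ("lowercase_rate", 0, 1), ("n_rate", 0, 1),
            ("q_presence_rate", 0, 1), ("i_presence_rate", 0, 1),
            ("e_line_rate", 0, 1), ("irregularity_rate", 0, 1),
            ("contiguity_rate", 0, 1), ("strand_minus_rate", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo},{hi}]")
        if self.n_species < 1 or self.n_blocks < 0:
            raise ValueError("n_species must be >= 1 and n_blocks >= 0")
        for name in ("q_char_probs", "i_status_probs", "e_status_probs"):
            p = getattr(self, name)
            if abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise ValueError(f"{name} must be a probability vector")


#: Line-type availability per dataset profile: (q, i, e, n_species).
PROFILES: Dict[str, Tuple[bool, bool, bool, int]] = {
    "28way": (False, False, False, 28),
    "28wayB": (True, True, True, 28),
    "46way": (True, True, True, 46),
    "100way": (False, True, True, 100),
}


def profile_params(profile: str, seed: int = 0, n_blocks: int = 100,
                   **overrides) -> GenParams:
    """GenParams preset for one of the dataset profiles.

    The 100-species profile additionally shifts the column distribution
    towards very short blocks (the regime where the alignment model is
    least effective).
    """
    try:
        include_q, include_i, include_e, n_species = PROFILES[profile]
    except KeyError:
        raise ValueError(
            f"unknown profile {profile!r}; expected one of {sorted(PROFILES)}"
        )
    params = GenParams(
        seed=seed,
        n_blocks=n_blocks,
        n_species=n_species,
        include_q=include_q,
        include_i=include_i,
        include_e=include_e,
    )
    if profile == "100way":
        params = replace(params, p_short_block=0.35, short_block_max=3,
                         mean_cols=30.0, p_single_row=0.35)
    if overrides:
        params = replace(params, **overrides)
    return params


class _SourceGen:
    """Per-source bookkeeping of the generator (cursor, i/e chains)."""

    __slots__ = ("src_size", "cursor", "i_status", "i_count",
                 "e_start", "e_size", "e_status", "e_remaining")

    def __init__(self, src_size: int, cursor: int):
        self.src_size = src_size
        self.cursor = cursor
        self.i_status: Optional[str] = None
        self.i_count: Optional[int] = None
        self.e_start: Optional[int] = None
        self.e_size: Optional[int] = None
        self.e_status: Optional[str] = None
        self.e_remaining = 0


def _case_mask(rng: random.Random, n: int, p_lower: float, run_len: float) -> np.ndarray:
    """Alternating upper/lower run mask with stationary lower-case rate."""
    if p_lower <= 0:
        return np.zeros(n, dtype=bool)
    if p_lower >= 1:
        return np.ones(n, dtype=bool)
    mean_lower = max(run_len, 1.0)
    mean_upper = mean_lower * (1 - p_lower) / p_lower
    state = rng.random() < p_lower
    states: List[bool] = []
    lengths: List[int] = []
    total = 0
    while total < n:
        mean = mean_lower if state else mean_upper
        length = 1 + int(rng.expovariate(1.0 / mean))
        states.append(state)
        lengths.append(length)
        total += length
        state = not state
    return np.repeat(np.array(states, dtype=bool), lengths)[:n]


def generate_maf(params: GenParams) -> MafFile:
    """Generate a structurally valid MAF file (deterministic in the seed)."""
    rng = random.Random(params.seed)
    nprng = np.random.Generator(np.random.PCG64(params.seed))
    q_codes = np.array([ord(c) for c in _Q_CHARS], dtype=np.uint8)
    q_probs = np.asarray(params.q_char_probs)

    species = ["hg18"] + [f"sp{i:03d}" for i in range(1, params.n_species)]
    active_chrom = {sp: 1 for sp in species}
    sources: Dict[str, _SourceGen] = {}

    def current_source(sp: str) -> str:
        # occasionally move a species to a new chromosome (new dictionary entry)
        if rng.random() < 0.002 and active_chrom[sp] < params.chromosomes_per_species:
            active_chrom[sp] += 1
        return f"{sp}.chr{active_chrom[sp]}"

    def get_state(name: str) -> _SourceGen:
        st = sources.get(name)
        if st is None:
            st = _SourceGen(
                src_size=rng.randrange(50_000_000, 250_000_000),
                cursor=rng.randrange(0, 10_000_000),
            )
            sources[name] = st
        return st

    def next_start(st: _SourceGen, size: int) -> int:
        if st.cursor is None or rng.random() >= params.contiguity_rate:
            if rng.random() < 0.7:
                start = st.cursor + 1 + int(rng.expovariate(1 / 500.0))
            else:
                start = rng.randrange(0, max(st.src_size - size, 1))
        else:
            start = st.cursor
        st.cursor = start + size
        return start

    maf = MafFile(header_lines=["##maf version=1 scoring=autoMZ.v1"])

    for _ in range(params.n_blocks):
        # ---- structure draws (python RNG, fixed order) ----
        if rng.random() < params.p_single_row or params.n_species == 1:
            n_rows = 1
        else:
            extra = 1 + int(rng.expovariate(1.0 / max(params.mean_rows - 2, 0.5)))
            n_rows = min(2 + extra - 1, params.n_species)
        if rng.random() < params.p_short_block:
            n_cols = rng.randint(1, params.short_block_max)
        else:
            n_cols = params.short_block_max + 1 + int(
                rng.expovariate(1.0 / params.mean_cols)
            )
        others = rng.sample(range(1, params.n_species), n_rows - 1) if n_rows > 1 else []
        block_species = [species[0]] + [species[i] for i in others]
        score = rng.uniform(-5000.0, 500000.0)
        block = MSAB(a_line_text=f" score={score:.6f}",
                     inter_block_blank_lines=1)

        # ---- rows ----
        ref_bases = nprng.integers(0, 4, n_cols, dtype=np.uint8)
        for ridx, sp in enumerate(block_species):
            name = current_source(sp)
            st = get_state(name)
            bases = ref_bases.copy()
            if ridx > 0:
                sub = nprng.random(n_cols) < params.substitution_rate
                n_sub = int(sub.sum())
                if n_sub:
                    bases[sub] = nprng.integers(0, 4, n_sub, dtype=np.uint8)
            codes = _UPPER[bases]
            n_mask = nprng.random(n_cols) < params.n_rate
            codes[n_mask] = _N_CODE
            lower = _case_mask(rng, n_cols, params.lowercase_rate,
                               params.case_run_length)
            codes = np.where(lower, codes + 32, codes)
            gap_rate = params.ref_gap_rate if ridx == 0 else params.gap_rate
            gaps = nprng.random(n_cols) < gap_rate
            codes[gaps] = _GAP_CODE
            text = codes.tobytes().decode("ascii")
            size = n_cols - int(gaps.sum())
            start = next_start(st, size)
            strand = "+" if ridx == 0 or rng.random() >= params.strand_minus_rate \
                else "-"
            row = SLine(source=name, start=start, size=size, strand=strand,
                        src_size=st.src_size, text=text)

            if params.include_q and ridx > 0 and rng.random() < params.q_presence_rate:
                draws = nprng.choice(len(_Q_CHARS), size=n_cols, p=q_probs)
                qvals = q_codes[draws]
                qvals[gaps] = _GAP_CODE
                row.q_line = QLine(values=qvals.tobytes().decode("ascii"))

            if params.include_i and ridx > 0 and rng.random() < params.i_presence_rate:
                row.i_line = _draw_i_line(rng, params, st)

            block.rows.append(row)

        # ---- e lines: bridged sources absent from this block ----
        if params.include_e:
            in_block = {r.source for r in block.rows}
            candidates = [n for n in sorted(sources) if n not in in_block]
            n_e = 0
            for name in candidates:
                if n_e >= params.max_e_lines:
                    break
                st = sources[name]
                if st.e_remaining <= 0 and rng.random() >= params.e_line_rate:
                    continue
                block.e_lines.append(_draw_e_line(rng, params, name, st))
                n_e += 1

        maf.blocks.append(block)

    maf.trailing_blank_lines = 1
    return maf


def _draw_status(rng: random.Random, alphabet: str, probs) -> str:
    return rng.choices(alphabet, weights=probs, k=1)[0]


def _draw_i_line(rng: random.Random, params: GenParams, st: _SourceGen) -> ILine:
    if st.i_status is None:
        left_status = "N" if rng.random() < 0.7 else _draw_status(
            rng, _I_STATUS, params.i_status_probs)
        left_count = 0
    else:
        left_status = st.i_status
        left_count = st.i_count
        if rng.random() < params.irregularity_rate:
            left_status = _draw_status(rng, _I_STATUS, params.i_status_probs)
        if rng.random() < params.irregularity_rate:
            left_count = rng.randrange(0, 5000)
    right_status = _draw_status(rng, _I_STATUS, params.i_status_probs)
    right_count = 0 if right_status == "C" else rng.randrange(0, 5000)
    st.i_status = right_status
    st.i_count = right_count
    return ILine(left_status=left_status, left_count=left_count,
                 right_status=right_status, right_count=right_count)


def _draw_e_line(rng: random.Random, params: GenParams, name: str,
                 st: _SourceGen) -> ELine:
    if st.e_remaining <= 0:
        st.e_start = st.cursor
        st.e_size = 1 + int(rng.expovariate(1 / 800.0))
        st.e_remaining = rng.randint(1, 6)
        if st.e_status is None or rng.random() < params.irregularity_rate:
            st.e_status = _draw_status(rng, _E_STATUS, params.e_status_probs)
    elif rng.random() < params.irregularity_rate:
        st.e_status = _draw_status(rng, _E_STATUS, params.e_status_probs)
    st.e_remaining -= 1
    if st.e_remaining == 0:
        st.cursor = st.e_start + st.e_size
    return ELine(source=name, start=st.e_start, size=st.e_size, strand="+",
                 src_size=st.src_size, status=st.e_status)
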