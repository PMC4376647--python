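"""Evaluation utilities: compression gain vs gzip, parallel speedup/efficiency.

Compression gain relative to gzip is

    G_M = 100 * (NBytes_gzip - NBytes_M) / NBytes_gzip   [percent]

(negative when the method is larger than gzip).  Speedup of ``p`` parallel
processes is ``S_p = T_1 / T_p`` and efficiency ``E_p = S_p / p``; linear
(ideal) speedup means ``S_p = p``.  Wall-clock numbers are reported for
information only -- the benchmark runner asserts on sizes, never on time.
"""

from __future__ import annotations

import gzip
import time
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .container import compress_file
from .maf import serialize_maf
from .synth import profile_params, generate_maf

__all__ = [
    "compression_gain",
    "speedup_efficiency",
    "GainReport",
    "ParallelReport",
    "gzip_size",
    "run_benchmark",
]


def compression_gain(nbytes_gzip: int, nbytes_method: int) -> float:
    """Percent size reduction of a method relative to gzip (may be negative)."""
    if nbytes_gzip <= 0:
        raise ValueError("gzip size must be positive")
    return 100.0 * (nbytes_gzip - nbytes_method) / nbytes_gzip


def speedup_efficiency(t1: float, tp: float, p: int) -> Tuple[float, float]:
    """Speedup S_p = t1/tp and efficiency E_p = S_p/p of p parallel processes."""
    if t1 <= 0 or tp <= 0:
        raise ValueError("times must be positive")
    if p < 1:
        raise ValueError("p must be >= 1")
    s = t1 / tp
    return s, s / p


@dataclass
class GainReport:
    """Sizes and gain of one input."""

    name: str
    nbytes_raw: int
    nbytes_gzip: int
    nbytes_method: int

    @property
    def gain(self) -> float:
        return compression_gain(self.nbytes_gzip, self.nbytes_method)


@dataclass
class ParallelReport:
    """Timing of a p-way parallel run against the sequential baseline."""

    t1: float
    tp: float
    p: int

    @property
    def speedup(self) -> float:
        return speedup_efficiency(self.t1, self.tp, self.p)[0]

    @property
    def efficiency(self) -> float:
        return speedup_efficiency(self.t1, self.tp, self.p)[1]


def gzip_size(data: bytes, level: int = 9) -> int:
    """Size of the gzip-compressed data at the given level."""
    return len(gzip.compress(data, compresslevel=level))


def run_benchmark(
    profiles: Optional[List[str]] = None,
    seed: int = 0,
    n_blocks: int = 200,
    n_gobs: int = 1,
) -> List[GainReport]:
    """Compress one generated corpus per profile; returns size reports."""
    reports = []
    for profile in profiles or ["28way", "28wayB", "46way", "100way"]:
        params = profile_params(profile, seed=seed, n_blocks=n_blocks)
        maf = generate_maf(params)
        raw = serialize_maf(maf).encode("utf-8")
        compressed = compress_file(maf, n_gobs=n_gobs)
        reports.append(
            GainReport(
                name=profile,
                nbytes_raw=len(raw),
                nbytes_gzip=gzip_size(raw),
                nbytes_method=len(compressed),
            )
        )
    return reports


def format_benchmark_tsv(reports: List[GainReport]) -> str:
    """Tab-separated benchmark table (profile, sizes, gain%)."""
    lines = ["profile\traw_bytes\tgzip_bytes\tmafco_bytes\tgain_vs_gzip_pct"]
    for r in reports:
        lines.append(
            f"{r.name}\t{r.nbytes_raw}\t{r.nbytes_gzip}\t{r.nbytes_method}\t"
            f"{r.gain:.2f}"
        )
    return "\n".join(lines) + "\n"
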