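# Methods

## Model

All symbol streams are coded by adaptive finite-context models (FCMs): an
order-*k* model over alphabet 𝓐 estimates

P(s | ctx) = (c(s|ctx) + α) / (c(ctx) + |𝓐|·α),

with counts accumulated as the stream is processed and never rescaled or
expired. α defaults to 1 (Laplace estimator) for every model; it is carried
in the container header as a 16-bit rational so encoder and decoder always
agree. Following the single-model design, no model mixing or context-order
fallback is used anywhere: an unseen context simply yields the uniform
distribution and starts counting.

The alignment text of a block is a five-intensity image {A, C, G, T, −}
coded in raster order. The conditioning context of a cell is read through a
2D causal template; the published template geometries are not recoverable
from text, so the five templates `A`–`E` are defined constructively: a
template of depth *d* takes the *d* nearest strictly-causal cells, ranked by
Chebyshev distance, with the current-row left neighbour first within a
distance, then previous-row cells left to right (nearer rows first on a
column tie); templates `A`–`E` may use 1–5 previous rows respectively. The
default is template `C` at depth 10, giving the offsets
(0,−1), (−1,−1), (−1,0), (−1,1), (0,−2), (−1,−2), (−2,−2), (−2,−1), (−2,0),
(−2,1). The geometry is isolated behind `ContextTemplate` so it can be
swapped without touching the codecs. Out-of-grid template cells contribute
the gap symbol — the most frequent symbol in practice, and the choice only
affects compression, never correctness.

Case and extra streams, the start-mode flag, strand, presence and
irregularity streams are order-5 (strand: order-3, `i` status: order-4)
models contexted on their own previous symbols (1D self-context), per the
stated model orders; the block-positional alternative was rejected as the
less minimal reading. A per-row `i`-presence stream (mirroring the per-line
`q` stream) was added beyond the block-level one: without it a block in
which only some rows carry `i` lines could not be reconstructed.

## Arithmetic coder

Classic 32-bit low/high interval coder with bitwise renormalisation and
carry handling via a pending-bit counter. Model counts are exact; only the
frequency snapshot handed to the coder is quantized so the total stays
below 2^16, with every symbol floor-forced to frequency ≥ 1 so rare symbols
remain decodable. Truncated payloads are detected at the container level
(per-GOB byte lengths are indexed); the coder itself zero-pads past the end
of a segment, which is exactly compensated by the encoder's final flush.

Integers (starts, sizes, counts, ids, row/column counts) are coded as
decimal digits plus a terminator under a static uniform 11-symbol
distribution; one-shot strings (source names, `a`-line payloads) as raw
UTF-8 bytes under a static uniform 257-symbol distribution whose extra
symbol terminates the string (equivalent to a newline sentinel but safe for
any byte value). Adaptivity would buy nothing for strings that occur once.

## Codec ordering and mirrored state

Within a block the deterministic interleaving is: row/column/`e`/blank
counts and the `a`-line payload; `s` headers (source id or literal
name+srcSize, start mode+value, strand); the alignment image cell by cell
(main symbol, then extra bit if needed, then case bit); then — after the
decoder can recount sizes — the per-source (last start, last size) updates;
`q` presence bits and values; `i` presence bits and fields; `e` lines.
Start prediction for a row uses the state as of the previous block, so rows
and the decoder see identical state even when a source appears twice in one
block. `e` lines share the per-source (start, size) chain with `s` lines,
since their headers are coded the same way; repeated identical `e` regions
therefore produce negative offsets and ride the absolute path — correct,
merely not optimal. The `e`-status predictor follows the most recent of the
last `e` or `i` status of the source, with one irregularity stream per
predictor provenance. When an `i` or `e` irregularity fires, the literal
field is transmitted (status via the shared adaptive status model, counts
via the uniform integer model).

The `size` field of `s` lines is never serialized — it must equal the row's
non-gap count, which the decoder recomputes; the encoder refuses blocks
where it does not (and `compress_file` validates blocks up front). `e`
lines carry no alignment text, so their size is transmitted explicitly.

## Container

`MAFC` magic, version byte, codec configuration, verbatim header lines,
blank-line bookkeeping, then a fixed-width little-endian index of per-GOB
byte offsets and MSAB counts followed by the concatenated payloads. Blocks
are split into balanced contiguous GOBs (sizes differ by ≤ 1); each GOB is
encoded with fresh models, which is what makes parallel coding and partial
decoding possible and is the sole source of the multi-GOB size overhead.
Parallelism is a contract, not a mechanism: output bytes are independent of
the worker count (workers are a process pool over whole GOBs), and the
decoder's worker count is independent of the encoder's.

Losslessness is defined as byte identity for the canonical dialect
(single-space fields, `q` before `i` after their `s` row, `e` lines last,
blank-line counts preserved). Padded or oddly-ordered inputs are normalized
on parse and flagged `was_normalized`; the flag travels in the container.

## Synthetic corpora

The generator emulates the statistics the codec exploits, not biology:
block row counts with a point mass at one row; column counts with a short-
block mode (heavier in the 100-species profile, which also reproduces the
single-column regime where the image model is weakest); rows derived from a
reference by substitution (rate 0.30), gaps (0.15; 0.05 on the reference),
N overlay (0.01) and soft-mask lower-case runs (stationary rate 0.10, mean
run 25 columns); quality values drawn with P('9') = 0.92; `i` statuses
modally 'C' and `e` statuses modally 'I'; left/right and status chains
broken at an irregularity rate of 0.05; per-source cursors contiguous at
rate 0.90. Profiles `28way`/`28wayB`/`46way`/`100way` set line-type
availability (s-only / full / full / no qualities) and species pool sizes
28/28/46/100. Structure is drawn from a seeded `random.Random` and symbol
arrays from a seeded numpy PCG64 generator in a fixed documented order, so
a given (parameters, seed) pair always yields byte-identical files.

What the generator does *not* reproduce: phylogenetic correlation structure
between species, indel placement coherence across rows (gaps are
independent per cell), long-range repeat structure, and real soft-mask
geometry. Passing tests therefore demonstrate correctness of the codec and
the qualitative compression behaviour (structured redundancy → large gain
over gzip), not the exact gain figures attainable on real archives.

## Problem sizes and numerical choices

Unit and property tests run on corpora of tens of blocks. The large-corpus
checks (gain over `gzip -9` ≥ 30%, 8-GOB inflation < 2%) share one 32 MB
annotated-profile corpus (25 000 blocks, fixed seed) — the package's
desk-scale stand-in for the multi-gigabyte archives the method targets.
The GOB overhead shrinks as GOB length grows (measured here: 2.3% at 10 MB,
2.0% at 16 MB, 1.7–1.9% at 32 MB), converging towards the sub-1% regime of
very large inputs.

The coder-redundancy check feeds the adaptive order-0 model
fixed-composition samples (symbol counts exactly matching the design
distribution, order shuffled) so that the measured quantity is coder + 
adaptation overhead at the nominal entropy, not binomial sampling noise in
the sample entropy.

Integer decoding caps values at 20 digits and strings at 64 KiB as
corruption guards. Degenerate inputs handled explicitly: empty files
(header-only containers), blocks with no `s` rows (pure-`e` blocks carry
their own row/column counts of zero), all-gap rows (size 0), single-row and
single-column blocks.

## Known limitations

- Compression of very short blocks is weak (little context to condition
  on); this mirrors the method's behaviour and dominates the 100-species
  profile.
- `e`-line starts use the shared offset predictor, which degrades to
  absolute coding for repeated identical regions.
- The container has no checksum; integrity detection relies on framing and
  decode-time consistency checks.
- Random access is GOB-granular only.
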