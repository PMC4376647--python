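# mafco

Lossless, special-purpose compression for **MAF (Multiple Alignment Format)**
files — the format used by UCSC multiz whole-genome alignments. These archives
store millions of multiple sequence alignment blocks (MSABs) between dozens of
vertebrate genomes and routinely occupy hundreds of gigabytes, so they are
usually shipped as gzip; a compressor that understands the format's structure
can do substantially better while remaining fully reversible.

## Method

Every stream is modelled by an adaptive **finite-context model (FCM)**: an
order-*k* Markov estimator over a finite alphabet 𝓐,

```
P(s | x_{n-k+1..n}) = ( c(s | x_{n-k+1..n}) + α ) / ( c(x_{n-k+1..n}) + |𝓐|·α )
```

where `c(s|·)` counts past occurrences of symbol *s* in that context and
α balances maximum likelihood against a uniform prior (α = 1 is the Laplace
estimator). The model probabilities drive a 32-bit binary arithmetic coder,
so code length approaches the adaptive entropy of each stream.

Per line type:

- **`s` lines** — the alignment block is treated as an image with five
  intensities {A, C, G, T, −} and coded in raster order under a 2D causal
  context template (template `C`, depth 10 by default; five templates `A`–`E`
  are available). Each character is decomposed into a 5-ary *main* stream, a
  binary *extra* stream that disambiguates C/c from N/n, and a binary *case*
  stream for upper/lower case. Header fields are coded predictively: source
  names through a dictionary built on first occurrence, start positions as
  the offset `start_x − start_{x−1} − size_{x−1}` (usually zero; negative
  offsets fall back to absolute values via a binary side stream), strand with
  an order-3 binary model — and the `size` field is never transmitted, since
  it equals the decoded row's non-gap count.
- **`q` lines** — per-base qualities over the 12-symbol alphabet
  {0…9, F, .} with a single order-5 FCM; gap positions replicate the `s` row
  and are not coded. Presence is signalled by block-level and per-line binary
  streams.
- **`i` lines** — the left status/count of a source almost always equals its
  previous right status/count, so only the right fields are coded after the
  first occurrence, plus two independent binary irregularity streams.
- **`e` lines** — full header coding as for `s` lines plus a status predicted
  from the last `e`/`i` status of the same source, again with irregularity
  side streams.

The container splits the file into **GOBs (groups of blocks)**, each encoded
with fresh model state, so GOBs compress and decompress independently — in
parallel, and partially (`-ng FIRST[:LAST]` decodes a block range without
touching the rest). Compression performance is summarised as the gain over
gzip, `G = 100·(N_gzip − N_mafco)/N_gzip` %, and parallel scaling as speedup
`S_p = T_1/T_p` and efficiency `E_p = S_p/p`.

## Worked example

The package ships a statistics-faithful synthetic MAF generator (profiles
mirror the line-type availability of the common multiz releases: `28way`
s-only, `28wayB`/`46way` fully annotated, `100way` without qualities):

```
$ mafco synth --seed 7 --blocks 500 --profile 28wayB -o demo.maf
$ head -4 demo.maf
##maf version=1 scoring=autoMZ.v1

a score=42535.671180
s hg18.chr1 3602037 10 + 186213743 gcttncaggc

$ mafco encode -i demo.maf -o demo.mafco -ng 4
demo.maf: 110416 bytes, 500 MSABs, 4 GOBs

$ gzip -9 -k demo.maf && ls -l demo.maf demo.maf.gz demo.mafco
-rw-r--r-- 634149 demo.maf
-rw-r--r-- 160285 demo.maf.gz
-rw-r--r-- 110416 demo.mafco

$ mafco decode -i demo.mafco -o demo.out.maf && cmp demo.maf demo.out.maf && echo IDENTICAL
IDENTICAL

$ mafco decode -i demo.mafco -o part.maf -ng 1:2   # only GOBs 1..2
part.maf: 250 MSABs
```

Here the container is 110 416 bytes against 160 285 for `gzip -9` — a 31%
gain on a 500-block corpus (the gain grows with corpus size as the models
adapt) — and decoding reproduces the input byte for byte. `mafco bench`
prints the same size comparison for all four profiles as TSV.

The same operations are available as a library:

```python
from mafco import parse_maf, compress_file, decompress_file, serialize_maf

maf = parse_maf(open("demo.maf"))
blob = compress_file(maf, n_gobs=4, n_workers=4)
assert serialize_maf(decompress_file(blob)) == open("demo.maf").read()
```

## Scope

The canonical dialect is single-space-separated fields with `q`/`i` lines
following their owning `s` line; UCSC column padding is normalized on parse
(and flagged). Losslessness means byte identity for canonical files. The
compressor does not interpret alignments (no liftover, no re-alignment) and
offers no random access finer than one GOB.
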