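# Methods

## Coordinates and fragment model

All coordinates are BED-style 0-based half-open. A paired-end MNase
fragment `[start, end)` represents one protected particle; its dyad is
`floor((start + end) / 2)`. For even-length fragments this picks the
left-of-centre base — a deterministic, translation-invariant convention
(the underlying data do not determine the rounding). Size classes gate on
fragment length with both bounds inclusive: mononucleosomes 120–180 bp,
dinucleosomes 250–350 bp. Inclusive gating matches conventional MNase-seq
size selection and makes the three-way partition unambiguous; the bounds
are configurable (`SizeClassConfig`).

Minus-strand genes store TSS > TTS (transcription order); when a BED6/GFF3
interval is read, the minus-strand TSS is the rightmost transcribed base
(`end − 1`). This is what makes strand-flipped metagene alignment exact.

## Metagene profiles

For each gene the anchor is its +1 nucleosome dyad (or TSS). Offsets run
in transcription direction: offset `o` maps to genomic position
`anchor + o` on plus-strand genes and `anchor − o` on minus-strand genes.
Two track kinds:

- *dyad density*: count of fragment midpoints per offset;
- *occupancy*: per-base coverage (each fragment increments every base it
  spans).

The per-offset mean over genes is divided by the genomic average rate
(fragments/bp for dyads, covered-bases/bp for occupancy, computed over the
full genome length, not just genic regions), so a uniform genome-wide
distribution gives a flat profile of exactly 1. Design choices that matter:

- The denominator `n_genes` includes genes with no local fragments:
  depressed peaks must register as depressed rather than being averaged
  away.
- A dyad inside two overlapping gene windows contributes to both; the
  operation stays linear in the fragment set.
- Fragments on chromosomes absent from the annotation still enter the
  normalisation constant but never a gene window.
- Default window: −200 to +1000 bp around the +1 anchor (covers
  nucleosomes −1 through +6).

When +1 positions are not supplied, `call_plus1_reference` smooths each
gene's dyad histogram over a 0–250 bp window downstream of the TSS
(Gaussian kernel, sd 10 bp) and takes the maximum, ties breaking toward
the TSS; genes with zero dyads in the window are excluded from +1-anchored
analyses. This calling procedure is this package's own assumption — the
figures it emulates take +1 positions as given — and any supplied
`plus1_dyad` column overrides it.

## Spacing, phasing and the ND rule

Peaks are called on the Gaussian-smoothed (sd 10 bp, configurable, 0
disables) dyad profile: peak 1 is the leftmost argmax within ±50 bp of the
anchor, each subsequent peak the leftmost argmax within +110 to +220 bp of
the previous — brackets chosen to cover the plausible 110–220 bp repeat
range. Spacing is the unweighted OLS slope of peak offset on index 1..5;
values are reported to the nearest bp for display while full precision is
retained. Phasing metrics: peak heights, trough depths (minima between
consecutive peaks), their ratio, and the +5/+1 height decay.

ND ("not determined") is declared when (i) fewer than five peaks can be
called, (ii) the mean peak-to-flanking-trough ratio over peaks +2..+5 is
below 1.10 (a zero trough makes the ratio +inf, i.e. maximally phased on
that flank), or (iii) the slope falls outside 100–250 bp. The published
analyses this mirrors declare ND qualitatively ("phasing too weak"), so
the 1.10 threshold is an explicit, configurable decision, not an inferred
constant.

The spacing-shift rule: holding +1 fixed, a spacing change ΔS displaces
nucleosome k by `(k − 1)·ΔS` bp — 5/10/15 bp at +2/+3/+4 for a
160 → 165 bp change.

## Dinucleosome readout

Dinucleosome fragments are analysed by occupancy only; `dinuc_enrichment`
rejects dyad-mode profiles for the di class because a dinucleosome
midpoint falls between its two nucleosomes. The di occupancy maximum is
searched within ±75 bp (half a repeat) of the expected +2 offset (one
repeat length downstream of +1); the mono readout is the smoothed mono
occupancy at that offset. With a baseline (wild-type) profile pair,
mutant/baseline ratios are reported. Per-fragment junction attribution
(nearest expected junction `(j − ½)·S` by fragment midpoint, ties toward
the lower junction) is a convenience layered on the average-profile
analysis, not a reproduction of any published statistic — the figures this
emulates quantify dinucleosome levels visually, so all scalars here are
this package's own definitions.

## Simulator: the stated world

`synthetic_chromatin` draws, per gene, one chromatin configuration:

- +1 anchor at TSS + 73 bp (half a nucleosome) in transcription
  direction; the realized +1 dyad jitters around it with sd
  `plus1_jitter` (default 10 bp). The annotation's `plus1_dyad` is the
  anchor, mirroring a reference +1 map.
- Downstream dyads follow a random walk: `dyad_k = dyad_{k−1} + S +
  N(0, σ_step)` (defaults S = 165, σ_step = 10 bp), continuing while the
  dyad stays at least half a nucleosome inside the gene body. Cumulative
  jitter reproduces downstream peak flattening without extra parameters.
- With probability `dinuc_prob` one junction (+1/+2 or +2/+3, weights
  0.5/0.5) loses its linker: the downstream partner packs against its
  neighbour at 147 bp and every further nucleosome shifts upstream with
  it. The two packed nucleosomes emit a single fragment of length
  N(300, 20) clipped to [250, 350]; all other nucleosomes emit
  Poisson(depth = 20) mono fragments of length N(147, 10) clipped to
  [120, 180], centred on their dyad. At most one dinucleosome per gene —
  the minimal structure producing a +2-centred di signature.
- The promoter NDR is nucleosome-free by construction (no nucleosomes
  upstream of +1); uniform background fragments (1 per kb, mono-sized)
  cover the genome. A synthetic activity track gives the top 300 genes
  8-fold the baseline gene-body density, emulating the skewed Pol II
  occupancy distribution of real data.

One configuration per gene is statistically equivalent, for metagene
shape, to averaging many cells per gene, and keeps runtime at desk scale;
`depth` then plays the role of per-nucleosome read depth. Sample sizes and
noise defaults (2,000 genes, depth 20, jitter 10/10) are the conditions
the validation criteria state. What the simulator does **not** emulate:
MNase sequence bias and digestion-degree effects, sub-nucleosomal
particles, −1 nucleosomes, gene-to-gene depth covariance with expression,
and real genome composition — so a green parameter-recovery test
establishes correctness of the measurement pipeline on idealized phased
arrays, not robustness to those real-data artefacts.

### Normalisation caveat for the di class

Per-class normalisation (the paper-faithful convention: di coverage over
its own genomic average) is scale-invariant in the dinucleosome
probability π when, as in this background-free simulator, *all* di
fragments originate at gene junctions: doubling π doubles the peak and the
genomic average alike. Directional comparisons of dinucleosome *levels*
across simulated strains therefore use the common coverage scale (the
normalisation constant computed from all fragments), which grows
proportionally with π and equals the per-class quantity up to a
π-independent factor. `build_occupancy_profile(..., norm_constant=...)`
exposes this; `DinucReport` keeps the per-class value as its default.

## Numerical choices and degenerate inputs

- Gaussian smoothing uses `scipy.ndimage.gaussian_filter1d` with nearest
  edge handling; all argmax/argmin tie-breaks are leftmost (toward the
  anchor/TSS).
- Flat profiles raise "no peaks"; peak-search windows that leave the
  profile range raise rather than clip.
- Empty fragment classes raise at profile construction; an all-zero di
  profile raises "no dinucleosome fragments".
- Subset thresholds are strict (> 2 kb, > 4×); boundary genes are
  excluded. Activity density is the mean per-base signal over the TSS–TTS
  interval (the averaging window is not pinned down by the analyses this
  mirrors; the gene body is the simplest defensible choice). When both a
  multiplier and top-N are given, top-N wins.
- No fragment deduplication is performed anywhere (whether the original
  analyses deduplicated is unstated; weighting every sequenced fragment
  once is the neutral default).
- All simulator randomness flows from a single seeded
  `numpy.random.Generator`; equal seeds give byte-identical outputs.

## Known limitations

- The ND threshold calibrates poorly to extreme step jitter: because the
  +1 anchor is exact in the simulator, the +1/+2 trough stays deep and
  the mean peak-to-trough ratio remains above 1.10 even at σ_step = 40 bp
  (where the +2 peak, sd 40 bp against a 165 bp repeat, is in fact still
  measurably phased). Severely disrupted chromatin in real data loses +1
  phasing too, which this single-knob disruption does not model.
- Spacing estimates assume the first five peaks exist within the profile
  window; very short genes contribute their early nucleosomes only.
- `read_fragments` accepts name-sorted paired alignments (SAM/BAM) but
  performs no duplicate marking or quality filtering.
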