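"""Strand-aware metagene profiles of dyad density and occupancy.

A profile is built by aligning every gene on an anchor (its +1 nucleosome
dyad or its TSS), counting either fragment dyads or per-base coverage at
each offset in a window around the anchor (transcription direction
positive; minus-strand genes are mirrored), averaging over genes, and
dividing by the genomic average so that a uniform genome-wide distribution
gives a flat profile of 1.

Counting is done on dense per-chromosome arrays, so a dyad that falls in
two gene windows contributes to both, and genes with no local fragments
still enter the per-gene denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from nucspacer.fragment_io import FragmentRecord, GeneRecord, fragment_dyad

logger = logging.getLogger(__name__)


@dataclass
class NormalizationConstant:
    """Expected raw count per base under a uniform genome-wide distribution.

    Dyad mode: fragments per bp. Occupancy mode: covered bases per bp.
    """

    value: float
    genome_length: int


@dataclass
class AlignedProfile:
    """Per-offset normalized metagene track.

    values[i] corresponds to offset window_lo + i, in transcription
    direction relative to the anchor; unitless, genomic average = 1.
    """

    window_lo: int
    window_hi: int
    values: np.ndarray
    n_genes: int
    track_kind: str  # {dyad, occupancy}
    size_class: str  # {mono, di, all}
    anchor_kind: str  # {plus1, tss}
    norm_constant: NormalizationConstant | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.window_hi - self.window_lo + 1:
            raise ValueError("profile length does not match window")
        if self.n_genes < 1:
            raise ValueError("profile requires n_genes >= 1")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("profile values must be finite and >= 0")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.window_lo, self.window_hi + 1)

    def value_at(self, offset: int) -> float:
        if not self.window_lo <= offset <= self.window_hi:
            raise ValueError(f"offset {offset} outside window")
        return float(self.values[offset - self.window_lo])


def gaussian_smooth(values: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian-kernel smoothing; bandwidth is the kernel sd in bp, 0 disables."""
    values = np.asarray(values, dtype=float)
    if bandwidth <= 0:
        return values.copy()
    return gaussian_filter1d(values, sigma=bandwidth, mode="nearest")


def infer_chrom_sizes(
    fragments: Sequence[FragmentRecord], genes: Sequence[GeneRecord] = ()
) -> dict[str, int]:
    """Smallest chromosome sizes consistent with the given records."""
    sizes: dict[str, int] = {}
    for f in fragments:
        sizes[f.chrom] = max(sizes.get(f.chrom, 0), f.end)
    for g in genes:
        hi = max(g.tss, g.tts) + 1
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), hi)
    return sizes


def compute_normalization(
    fragments: Sequence[FragmentRecord], track_kind: str, genome_length: int
) -> NormalizationConstant:
    """Genomic-average raw count per bp for the given track kind."""
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    if not fragments:
        raise ValueError("cannot normalize: zero fragments")
    if track_kind == "dyad":
        value = len(fragments) / genome_length
    elif track_kind == "occupancy":
        value = sum(f.length for f in fragments) / genome_length
    else:
        raise ValueError(f"unknown track_kind: {track_kind!r}")
    return NormalizationConstant(value=value, genome_length=genome_length)


def _raw_arrays(
    fragments: Sequence[FragmentRecord],
    chrom_sizes: Mapping[str, int],
    track_kind: str,
) -> dict[str, np.ndarray]:
    """Dense per-chromosome raw count arrays (dyad counts or coverage)."""
    arrays = {c: np.zeros(int(n), dtype=np.float64) for c, n in chrom_sizes.items()}
    if track_kind == "dyad":
        for f in fragments:
            arr = arrays.get(f.chrom)
            if arr is None:
                continue  # off-annotation chromosome: normalization only
            d = fragment_dyad(f)
            if 0 <= d < len(arr):
                arr[d] += 1.0
    else:
        # coverage via difference array + cumsum
        diffs = {c: np.zeros(int(n) + 1, dtype=np.float64) for c, n in chrom_sizes.items()}
        for f in fragments:
            dif = diffs.get(f.chrom)
            if dif is None:
                continue
            s = max(f.start, 0)
            e = min(f.end, len(dif) - 1)
            if e > s:
                dif[s] += 1.0
                dif[e] -= 1.0
        arrays = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return arrays


def _gene_anchor(g: GeneRecord, anchor_kind: str) -> int | None:
    if anchor_kind == "tss":
        return g.tss
    if anchor_kind == "plus1":
        return g.plus1_dyad
    raise ValueError(f"unknown anchor_kind: {anchor_kind!r}")


def _accumulate_window(
    arr: np.ndarray, anchor: int, direction: int, lo: int, hi: int
) -> np.ndarray:
    """Raw counts at offsets lo..hi for one gene, strand-flipped, zero-padded."""
    width = hi - lo + 1
    out = np.zeros(width, dtype=np.float64)
    if direction == 1:
        g_lo, g_hi = anchor + lo, anchor + hi + 1
        c_lo, c_hi = max(g_lo, 0), min(g_hi, len(arr))
        if c_hi > c_lo:
            out[c_lo - g_lo : c_hi - g_lo] = arr[c_lo:c_hi]
    else:
        # offset o maps to genomic position anchor - o
        g_lo, g_hi = anchor - hi, anchor - lo + 1
        c_lo, c_hi = max(g_lo, 0), min(g_hi, len(arr))
        if c_hi > c_lo:
            seg = arr[c_lo:c_hi][::-1]
            # reversed segment starts at offset anchor - (c_hi - 1)
            o_start = anchor - (c_hi - 1)
            out[o_start - lo : o_start - lo + len(seg)] = seg
    return out


def _build_profile(
    fragments: Sequence[FragmentRecord],
    genes: Sequence[GeneRecord],
    anchor_kind: str,
    window: tuple[int, int],
    track_kind: str,
    size_class: str,
    chrom_sizes: Mapping[str, int] | None,
    norm_constant: NormalizationConstant | None,
) -> AlignedProfile:
    lo, hi = int(window[0]), int(window[1])
    if not lo < 0 < hi:
        raise ValueError("window must straddle the anchor: window_lo < 0 < window_hi")
    if not fragments:
        label = "mononucleosome" if size_class == "mono" else size_class
        raise ValueError(f"no {label} fragments")
    anchored = [g for g in genes if _gene_anchor(g, anchor_kind) is not None]
    if not anchored:
        raise ValueError(f"no genes with anchor {anchor_kind!r}")
    if chrom_sizes is None:
        chrom_sizes = infer_chrom_sizes(fragments, genes)
    if norm_constant is None:
        genome_length = int(sum(chrom_sizes.values()))
        norm_constant = compute_normalization(fragments, track_kind, genome_length)
    arrays = _raw_arrays(fragments, chrom_sizes, track_kind)
    total = np.zeros(hi - lo + 1, dtype=np.float64)
    for g in anchored:
        arr = arrays.get(g.chrom)
        if arr is None:
            continue
        anchor = _gene_anchor(g, anchor_kind)
        total += _accumulate_window(arr, anchor, g.direction, lo, hi)
    values = total / len(anchored) / norm_constant.value
    logger.info(
        "%s profile (%s, anchor=%s): n_genes=%d norm=%.6g",
        track_kind,
        size_class,
        anchor_kind,
        len(anchored),
        norm_constant.value,
    )
    return AlignedProfile(
        window_lo=lo,
        window_hi=hi,
        values=values,
        n_genes=len(anchored),
        track_kind=track_kind,
        size_class=size_class,
        anchor_kind=anchor_kind,
        norm_constant=norm_constant,
    )


def build_dyad_profile(
    mono_fragments: Sequence[FragmentRecord],
    genes: Sequence[GeneRecord],
    anchor_kind: str = "plus1",
    window: tuple[int, int] = (-200, 1000),
    chrom_sizes: Mapping[str, int] | None = None,
    norm_constant: NormalizationConstant | None = None,
    size_class: str = "mono",
) -> AlignedProfile:
    """Average dyad-density profile, normalized to a genomic average of 1.

    values[o] = (sum over genes of dyad counts at strand-flipped offset o
    / n_genes) / (fragments per bp genome-wide). Genes lacking any local
    fragment still count in the denominator, so weak phasing shows up as
    depressed peaks rather than being averaged away.
    """
    return _build_profile(
        mono_fragments, genes, anchor_kind, window, "dyad", size_class,
        chrom_sizes, norm_constant,
    )


def build_occupancy_profile(
    fragments: Sequence[FragmentRecord],
    genes: Sequence[GeneRecord],
    anchor_kind: str = "plus1",
    window: tuple[int, int] = (-200, 1000),
    chrom_sizes: Mapping[str, int] | None = None,
    norm_constant: NormalizationConstant | None = None,
    size_class: str = "mono",
) -> AlignedProfile:
    """Average per-base coverage profile for one fragment size class.

    Each fragment increments every base of [start, end); the genomic
    average (covered bases per bp) is set to 1. Pass norm_constant to
    normalize on a different scale (e.g. all fragment classes combined).
    """
    return _build_profile(
        fragments, genes, anchor_kind, window, "occupancy", size_class,
        chrom_sizes, norm_constant,
    )


def call_plus1_reference(
    mono_fragments: Sequence[FragmentRecord],
    genes: Sequence[GeneRecord],
    search_window: tuple[int, int] = (0, 250),
    smooth_bw: float = 10.0,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Call a major +1 nucleosome dyad per gene from mono dyad counts.

    The per-gene dyad histogram over search_window downstream of the TSS
    (transcription direction) is Gaussian-smoothed and its maximum taken as
    the +1 dyad; ties break toward the TSS. Genes already carrying a
    plus1_dyad keep it. Returns (genes with plus1 set, excluded genes with
    zero dyads in the window).
    """
    lo, hi = int(search_window[0]), int(search_window[1])
    if chrom_sizes is None:
        chrom_sizes = infer_chrom_sizes(mono_fragments, genes)
    arrays = _raw_arrays(mono_fragments, chrom_sizes, "dyad")
    called: list[GeneRecord] = []
    excluded: list[GeneRecord] = []
    for g in genes:
        if g.plus1_dyad is not None:
            called.append(g)
            continue
        arr = arrays.get(g.chrom)
        counts = (
            _strand_window(arr, g.tss, g.direction, lo, hi)
            if arr is not None
            else np.zeros(hi - lo + 1)
        )
        if counts.sum() == 0:
            excluded.append(g)
            continue
        smoothed = gaussian_smooth(counts, smooth_bw)
        best = int(np.argmax(smoothed))  # leftmost max = closest to TSS
        plus1 = g.tss + g.direction * (lo + best)
        called.append(
            GeneRecord(g.gene_id, g.chrom, g.tss, g.tts, g.strand, plus1)
        )
    if excluded:
        logger.info("+1 calling: %d genes excluded (no dyads in window)", len(excluded))
    return called, excluded


def _strand_window(
    arr: np.ndarray, anchor: int, direction: int, lo: int, hi: int
) -> np.ndarray:
    return _accumulate_window(arr, anchor, direction, lo, hi)


def write_profile_tsv(profile: AlignedProfile, path: str | Path) -> None:
    """Two-column TSV (offset, value) with a '#'-prefixed metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# track_kind={profile.track_kind}\n")
        fh.write(f"# size_class={profile.size_class}\n")
        fh.write(f"# anchor_kind={profile.anchor_kind}\n")
        fh.write(f"# n_genes={profile.n_genes}\n")
        if profile.norm_constant is not None:
            fh.write(f"# norm_constant={float(profile.norm_constant.value)!r}\n")
            fh.write(f"# genome_length={profile.norm_constant.genome_length}\n")
        fh.write("offset\tvalue\n")
        for o, v in zip(profile.offsets, profile.values):
            fh.write(f"{o}\t{float(v)!r}\n")


def read_profile_tsv(path: str | Path) -> AlignedProfile:
    """Read a profile written by write_profile_tsv."""
    meta: dict[str, str] = {}
    offsets: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line and not line.startswith("offset"):
                o, v = line.split("\t")
                offsets.append(int(o))
                values.append(float(v))
    norm = None
    if "norm_constant" in meta:
        norm = NormalizationConstant(
            float(meta["norm_constant"]), int(meta.get("genome_length", 0))
        )
    return AlignedProfile(
        window_lo=offsets[0],
        window_hi=offsets[-1],
        values=np.array(values),
        n_genes=int(meta.get("n_genes", 1)),
        track_kind=meta.get("track_kind", "dyad"),
        size_class=meta.get("size_class", "mono"),
        anchor_kind=meta.get("anchor_kind", "plus1"),
        norm_constant=norm,
    )
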