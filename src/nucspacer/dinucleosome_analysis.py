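"""Dinucleosome enrichment and +2 mononucleosome depletion.

Close-packed dinucleosomes (two nucleosomes with little or no linker)
survive MNase as 250-350 bp fragments. Because a dinucleosome midpoint
falls between its two nucleosomes, dyad plots are meaningless for this
class; all dinucleosome readouts here use occupancy (coverage) profiles.
The characteristic signature is a dinucleosome occupancy peak around the
+2 position together with a depressed +2 mononucleosome peak.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from nucspacer.fragment_io import FragmentRecord, GeneRecord
from nucspacer.profile_builder import AlignedProfile, gaussian_smooth

logger = logging.getLogger(__name__)

JUNCTION_KEYS = ("+1/+2", "+2/+3", "downstream", "intergenic")


@dataclass
class DinucReport:
    """Scalar readout of dinucleosome enrichment around the +2 nucleosome.

    di_peak_value and mono_plus2_value are normalized occupancies; the
    ratios are mutant/baseline and are None when no baseline was supplied.
    """

    di_peak_offset: int
    di_peak_value: float
    mono_plus2_value: float
    mono_plus2_expected_offset: int
    di_window: tuple[int, int]
    di_peak_ratio: float | None = None
    mono_plus2_ratio: float | None = None


def dinuc_enrichment(
    di_profile: AlignedProfile,
    mono_profile: AlignedProfile,
    spacing_ref: float,
    baseline: tuple[AlignedProfile, AlignedProfile] | None = None,
    search_half: int = 75,
    smooth_bw: float = 10.0,
) -> DinucReport:
    """Quantify the +2 dinucleosome peak and +2 mononucleosome depletion.

    The expected +2 dyad sits one repeat length downstream of the +1
    anchor; the dinucleosome occupancy maximum is searched within
    +-search_half bp of it (half a repeat by default). baseline, when
    given, is a matched (di, mono) wild-type pair and mutant/baseline
    ratios are reported.
    """
    if di_profile.track_kind == "dyad":
        raise ValueError(
            "dyad-mode profile not allowed for dinucleosomes: a dinucleosome "
            "midpoint lies between its two nucleosomes; use occupancy"
        )
    if not 100 <= spacing_ref <= 250:
        raise ValueError("spacing_ref must be in [100, 250] bp")
    if (di_profile.window_lo, di_profile.window_hi) != (
        mono_profile.window_lo,
        mono_profile.window_hi,
    ):
        raise ValueError("di and mono profiles must share the same window")
    if not np.any(di_profile.values > 0):
        raise ValueError("no dinucleosome fragments")

    plus2 = int(round(spacing_ref))
    w_lo, w_hi = plus2 - search_half, plus2 + search_half
    if w_lo < di_profile.window_lo or w_hi > di_profile.window_hi:
        raise ValueError("dinucleosome search window exceeds profile range")

    di_sm = gaussian_smooth(di_profile.values, smooth_bw)
    lo = di_profile.window_lo
    seg = di_sm[w_lo - lo : w_hi - lo + 1]
    i = int(np.argmax(seg))
    di_peak_offset, di_peak_value = w_lo + i, float(seg[i])

    mono_sm = gaussian_smooth(mono_profile.values, smooth_bw)
    mono_plus2_value = float(mono_sm[plus2 - mono_profile.window_lo])

    di_ratio = mono_ratio = None
    if baseline is not None:
        base = dinuc_enrichment(
            baseline[0], baseline[1], spacing_ref, None, search_half, smooth_bw
        )
        di_ratio = di_peak_value / base.di_peak_value if base.di_peak_value else math.inf
        mono_ratio = (
            mono_plus2_value / base.mono_plus2_value if base.mono_plus2_value else math.inf
        )
    return DinucReport(
        di_peak_offset=di_peak_offset,
        di_peak_value=di_peak_value,
        mono_plus2_value=mono_plus2_value,
        mono_plus2_expected_offset=plus2,
        di_window=(w_lo, w_hi),
        di_peak_ratio=di_ratio,
        mono_plus2_ratio=mono_ratio,
    )


def upstream_background(di_profile: AlignedProfile, boundary: int = -100) -> float:
    """Median dinucleosome occupancy upstream of the promoter NDR.

    Serves as the no-enrichment reference level for the +2 dinucleosome
    peak (offsets < boundary, i.e. upstream of the NDR).
    """
    mask = di_profile.offsets < boundary
    if not mask.any():
        raise ValueError("profile window has no offsets upstream of the NDR")
    return float(np.median(di_profile.values[mask]))


def junction_attribution(
    di_fragments: Sequence[FragmentRecord],
    genes: Sequence[GeneRecord],
    spacing_ref: float,
) -> dict[str, int]:
    """Assign dinucleosome fragments to expected inter-nucleosome junctions.

    The junction between nucleosomes j and j+1 is expected at offset
    (j - 1/2) * spacing_ref downstream of the +1 dyad. Each fragment whose
    midpoint falls inside a gene body is attributed to the nearest
    junction (ties toward the lower junction); midpoints outside any gene
    count as intergenic. This per-fragment attribution is a convenience
    readout layered on the average-profile analysis.
    """
    missing = [g.gene_id for g in genes if g.plus1_dyad is None]
    if missing:
        raise ValueError(
            f"junction attribution requires plus1_dyad on all genes; missing for "
            f"{len(missing)} genes (e.g. {missing[0]})"
        )
    # per-chromosome sorted gene bodies for midpoint lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[GeneRecord]]] = {}
    for chrom in {g.chrom for g in genes}:
        sub = sorted(
            (g for g in genes if g.chrom == chrom), key=lambda g: min(g.tss, g.tts)
        )
        starts = np.array([min(g.tss, g.tts) for g in sub])
        ends = np.array([max(g.tss, g.tts) + 1 for g in sub])
        by_chrom[chrom] = (starts, ends, sub)

    counts = {k: 0 for k in JUNCTION_KEYS}
    for f in di_fragments:
        mid = (f.start + f.end) // 2
        entry = by_chrom.get(f.chrom)
        gene = None
        if entry is not None:
            starts, ends, sub = entry
            i = int(np.searchsorted(starts, mid, side="right")) - 1
            if i >= 0 and mid < ends[i]:
                gene = sub[i]
        if gene is None:
            counts["intergenic"] += 1
            continue
        offset = gene.direction * (mid - gene.plus1_dyad)
        # nearest junction j >= 1; ties toward the lower junction
        j = max(1, math.ceil(offset / spacing_ref))
        if j == 1:
            counts["+1/+2"] += 1
        elif j == 2:
            counts["+2/+3"] += 1
        else:
            counts["downstream"] += 1
    return counts
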