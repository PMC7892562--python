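"""Gene subsets (long, highly active, listed) and grouped comparisons.

Long genes are those with > 2 kb between TSS and TTS (strict). Highly
active genes have mean per-base signal over the gene body > 4x the
genomic average of the supplied activity track (strict), or are the top-N
by density when a top_n is requested. Grouped analysis runs the profile /
spacing / dinucleosome readouts per subset with deterministic ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from nucspacer.dinucleosome_analysis import dinuc_enrichment
from nucspacer.fragment_io import (
    FragmentRecord,
    GeneRecord,
    SignalTrack,
    SizeClassConfig,
    classify_by_size,
)
from nucspacer.profile_builder import (
    build_dyad_profile,
    build_occupancy_profile,
    compute_normalization,
    infer_chrom_sizes,
)
from nucspacer.spacing_phasing import (
    call_peaks,
    estimate_spacing,
    phasing_metrics,
    spacing_display,
)

logger = logging.getLogger(__name__)

LOW_N_WARNING = 50


@dataclass
class SubsetSpec:
    """Declarative description of one gene subset."""

    kind: str  # {all, long_genes, active_genes, gene_list, complement}
    name: str | None = None
    length_threshold: int = 2000
    activity_multiplier: float = 4.0
    top_n: int | None = None
    list_path: str | Path | None = None

    def __post_init__(self) -> None:
        valid = {"all", "long_genes", "active_genes", "gene_list", "complement"}
        if self.kind not in valid:
            raise ValueError(f"unknown subset kind: {self.kind!r}")
        if self.kind in ("gene_list", "complement") and self.list_path is None:
            raise ValueError(f"subset kind {self.kind!r} requires list_path")
        if self.name is None:
            self.name = self.kind


def select_long_genes(
    genes: Sequence[GeneRecord], threshold: int = 2000
) -> list[GeneRecord]:
    """Genes with strictly more than `threshold` bp between TSS and TTS."""
    return [g for g in genes if g.gene_length > threshold]


def select_active_genes(
    genes: Sequence[GeneRecord],
    track: SignalTrack,
    multiplier: float = 4.0,
    top_n: int | None = None,
) -> list[GeneRecord]:
    """Genes whose gene-body signal density exceeds the genomic average.

    Density is the mean per-base signal over the TSS-TTS interval. The
    default keeps genes with density strictly > multiplier x genomic mean;
    when top_n is given the top_n genes by density are taken instead.
    Genes with no covered bases are excluded with a warning.
    """
    densities: list[tuple[GeneRecord, float]] = []
    n_uncovered = 0
    for g in genes:
        lo, hi = min(g.tss, g.tts), max(g.tss, g.tts) + 1
        dens, covered = track.mean_over(g.chrom, lo, hi)
        if covered == 0:
            n_uncovered += 1
            continue
        densities.append((g, dens))
    if n_uncovered:
        logger.warning("%d genes with zero covered bases excluded", n_uncovered)
    if top_n is not None:
        ranked = sorted(densities, key=lambda t: (-t[1], t[0].gene_id))
        return [g for g, _ in ranked[:top_n]]
    cutoff = multiplier * track.genomic_mean
    return [g for g, dens in densities if dens > cutoff]


def select_from_list(
    genes: Sequence[GeneRecord], list_path: str | Path
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Partition genes into (listed, complement) by a one-id-per-line file."""
    path = Path(list_path)
    with open(path) as fh:
        raw = [line.strip() for line in fh if line.strip()]
    if not raw:
        raise ValueError(f"empty gene list: {path}")
    wanted = set(raw)
    if len(wanted) < len(raw):
        logger.info("gene list: %d duplicate ids collapsed", len(raw) - len(wanted))
    known = {g.gene_id for g in genes}
    unknown = sorted(wanted - known)
    if unknown:
        logger.warning("gene list: %d unknown ids (e.g. %s)", len(unknown), unknown[0])
    subset = [g for g in genes if g.gene_id in wanted]
    complement = [g for g in genes if g.gene_id not in wanted]
    if not complement:
        logger.warning("gene list covers every annotated gene; complement is empty")
    return subset, complement


def resolve_subset(
    spec: SubsetSpec,
    genes: Sequence[GeneRecord],
    track: SignalTrack | None = None,
) -> list[GeneRecord]:
    """Materialize a SubsetSpec against an annotation."""
    if spec.kind == "all":
        return list(genes)
    if spec.kind == "long_genes":
        return select_long_genes(genes, spec.length_threshold)
    if spec.kind == "active_genes":
        if track is None:
            raise ValueError("active_genes subset requires a signal track")
        return select_active_genes(genes, track, spec.activity_multiplier, spec.top_n)
    listed, complement = select_from_list(genes, spec.list_path)
    return listed if spec.kind == "gene_list" else complement


def grouped_analysis(
    fragments: Sequence[FragmentRecord],
    genes: Sequence[GeneRecord],
    subsets: Sequence[SubsetSpec],
    analyses: Sequence[str] = ("dyad", "occupancy", "spacing", "dinuc"),
    *,
    sample: str = "sample",
    track: SignalTrack | None = None,
    size_cfg: SizeClassConfig | None = None,
    anchor_kind: str = "plus1",
    window: tuple[int, int] = (-200, 1000),
    nd_ratio_threshold: float = 1.10,
    spacing_ref: float | None = None,
) -> dict:
    """Run the requested readouts on every gene subset of one sample.

    Returns {"summary": DataFrame (one row per subset, deterministic
    order), "profiles": {(subset, track_kind, size_class): AlignedProfile}}.
    Empty subsets are skipped with a warning; subsets under 50 genes are
    flagged low_n. The dinucleosome readout uses the subset's own spacing
    estimate as reference unless spacing_ref is given.
    """
    if not subsets:
        raise ValueError("at least one subset is required")
    size_cfg = size_cfg or SizeClassConfig()
    mono, di, _other = classify_by_size(fragments, size_cfg)
    chrom_sizes = infer_chrom_sizes(fragments, genes)
    genome_length = int(sum(chrom_sizes.values()))

    rows = []
    profiles: dict[tuple[str, str, str], object] = {}
    for spec in subsets:
        sub = resolve_subset(spec, genes, track)
        if not sub:
            logger.warning("subset %s is empty; skipped", spec.name)
            continue
        row: dict = {
            "sample": sample,
            "subset": spec.name,
            "n_genes": len(sub),
            "low_n": len(sub) < LOW_N_WARNING,
        }
        if row["low_n"]:
            logger.warning("subset %s has only %d genes", spec.name, len(sub))

        dyad_prof = None
        if "dyad" in analyses or "spacing" in analyses:
            dyad_prof = build_dyad_profile(
                mono, sub, anchor_kind, window, chrom_sizes=chrom_sizes
            )
            profiles[(spec.name, "dyad", "mono")] = dyad_prof
        if "spacing" in analyses:
            try:
                peaks = call_peaks(dyad_prof)
                est = estimate_spacing(
                    peaks, phasing_metrics(dyad_prof, peaks), nd_ratio_threshold
                )
            except ValueError as exc:
                logger.warning("subset %s: spacing not measurable (%s)", spec.name, exc)
                est = None
            row["spacing_bp"] = spacing_display(est) if est else "ND"
            row["r_squared"] = est.r_squared if est else None
            row["status"] = est.status if est else "ND"
        if "occupancy" in analyses or "dinuc" in analyses:
            mono_occ = build_occupancy_profile(
                mono, sub, anchor_kind, window, chrom_sizes=chrom_sizes,
                size_class="mono",
            )
            profiles[(spec.name, "occupancy", "mono")] = mono_occ
            if di:
                di_occ = build_occupancy_profile(
                    di, sub, anchor_kind, window, chrom_sizes=chrom_sizes,
                    size_class="di",
                )
                profiles[(spec.name, "occupancy", "di")] = di_occ
            if "dinuc" in analyses and di:
                ref = spacing_ref
                if ref is None:
                    est_ok = row.get("status") == "OK"
                    ref = float(row["spacing_bp"]) if est_ok else 165.0
                rep = dinuc_enrichment(di_occ, mono_occ, ref)
                row["di_peak_offset"] = rep.di_peak_offset
                row["di_peak_value"] = rep.di_peak_value
                row["mono_plus2_value"] = rep.mono_plus2_value
            elif "dinuc" in analyses:
                logger.warning("subset %s: no dinucleosome fragments", spec.name)
        rows.append(row)
    summary = pd.DataFrame(rows)
    return {"summary": summary, "profiles": profiles}
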