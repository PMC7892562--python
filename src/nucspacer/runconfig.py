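"""End-to-end pipeline runs from a single YAML configuration.

A run processes one or more samples, each with one or more replicate
fragment files, against a shared gene annotation: size classification,
metagene dyad/occupancy profiles per gene subset, spacing regression and
the dinucleosome report, all written under an output directory together
with a top-level spacing summary (one row per sample x replicate x
subset, like the per-panel spacing annotations on metagene figures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from nucspacer.fragment_io import (
    SizeClassConfig,
    read_fragments,
    read_genes,
    read_signal_track,
)
from nucspacer.profile_builder import AlignedProfile, write_profile_tsv
from nucspacer.subsets_reporting import SubsetSpec, grouped_analysis

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parsed pipeline configuration (see `RunConfig.from_yaml`)."""

    samples: dict[str, dict[str, str]]  # sample -> {replicate label -> fragments path}
    genes_path: str
    genes_format: str = "tsv"
    anchor_kind: str = "plus1"
    window: tuple[int, int] = (-200, 1000)
    size_class: SizeClassConfig = field(default_factory=SizeClassConfig)
    nd_ratio_threshold: float = 1.10
    subsets: list[SubsetSpec] = field(default_factory=lambda: [SubsetSpec("all")])
    activity_track: str | None = None
    outdir: str = "nucspacer_out"
    seed: int = 0

    def validate(self) -> None:
        for sample, reps in self.samples.items():
            if len(set(reps)) != len(reps):
                raise ValueError(f"duplicate replicate labels in sample {sample}")
            for label, path in reps.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"fragments not found: {path}")
        if not Path(self.genes_path).exists():
            raise FileNotFoundError(f"genes not found: {self.genes_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        subsets = [SubsetSpec(**s) for s in raw.get("subsets", [{"kind": "all"}])]
        size = SizeClassConfig(**raw.get("size_class", {}))
        return cls(
            samples=raw["samples"],
            genes_path=raw["genes"],
            genes_format=raw.get("genes_format", "tsv"),
            anchor_kind=raw.get("anchor_kind", "plus1"),
            window=tuple(raw.get("window", (-200, 1000))),
            size_class=size,
            nd_ratio_threshold=raw.get("nd_ratio_threshold", 1.10),
            subsets=subsets,
            activity_track=raw.get("activity_track"),
            outdir=raw.get("outdir", "nucspacer_out"),
            seed=raw.get("seed", 0),
        )


def run_pipeline(config: RunConfig) -> "pd.DataFrame":
    """Execute the full analysis for every sample/replicate in the config.

    Writes per-replicate profile TSVs (sample__replicate__subset__track
    naming) and a top-level spacing_summary.tsv; returns the summary
    DataFrame.
    """
    import pandas as pd

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = read_genes(config.genes_path, config.genes_format)
    track = (
        read_signal_track(config.activity_track) if config.activity_track else None
    )
    all_rows = []
    for sample, reps in config.samples.items():
        for label, frag_path in reps.items():
            fragments = read_fragments(frag_path, "bed")
            result = grouped_analysis(
                fragments,
                genes,
                config.subsets,
                sample=sample,
                track=track,
                size_cfg=config.size_class,
                anchor_kind=config.anchor_kind,
                window=config.window,
                nd_ratio_threshold=config.nd_ratio_threshold,
            )
            summary = result["summary"].copy()
            summary.insert(1, "replicate", label)
            all_rows.append(summary)
            for (subset, tkind, sclass), prof in result["profiles"].items():
                name = f"{sample}__{label}__{subset}__{tkind}_{sclass}.tsv"
                write_profile_tsv(prof, outdir / name)
    summary = pd.concat(all_rows, ignore_index=True)
    summary.to_csv(outdir / "spacing_summary.tsv", sep="\t", index=False)
    logger.info("pipeline complete: %d summary rows -> %s", len(summary), outdir)
    return summary


def render_profiles(
    profiles: Sequence[AlignedProfile],
    labels: Sequence[str],
    out_path: str | Path,
    style: str = "overlay-replicates",
    title: str | None = None,
) -> Path:
    """Plot profiles as one panel (SVG) with a TSV twin of the series.

    style 'overlay-replicates' draws all series as lines; 'mutant-vs-wt'
    draws the first series as a grey-filled reference and the rest as
    lines over it. The TSV twin carries exactly the plotted values.
    """
    if not profiles:
        raise ValueError("no profiles to render")
    windows = {(p.window_lo, p.window_hi) for p in profiles}
    if len(windows) != 1:
        raise ValueError("profiles must share the same window")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(8, 3.2))
    offsets = profiles[0].offsets
    start = 0
    if style == "mutant-vs-wt":
        ax.fill_between(offsets, profiles[0].values, color="0.8", label=labels[0])
        start = 1
    for p, lab in zip(profiles[start:], labels[start:]):
        ax.plot(offsets, p.values, label=lab, lw=1)
    ax.set_xlabel("position relative to anchor (bp)")
    ax.set_ylabel(f"normalized {profiles[0].track_kind}")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)

    twin = out_path.with_suffix(".tsv")
    with open(twin, "w") as fh:
        fh.write("offset\t" + "\t".join(labels) + "\n")
        for i, o in enumerate(offsets):
            vals = "\t".join(repr(float(p.values[i])) for p in profiles)
            fh.write(f"{o}\t{vals}\n")
    return out_path
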