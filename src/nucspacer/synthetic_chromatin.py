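"""Seeded simulator of phased nucleosomal arrays with dinucleosomes.

The generative model mirrors the dinucleosome-interference picture of
disrupted chromatin: each gene carries a phased array downstream of a +1
nucleosome (repeat length S, positional jitter sigma1 on +1, random-walk
step jitter sigma_step on every linker), an upstream nucleosome-depleted
region, mononucleosome fragments of ~147 bp centered on each dyad, and —
with per-gene probability pi — one close-packed dinucleosome at the +1/+2
or +2/+3 junction whose linker is deleted, shifting all downstream
nucleosomes upstream by (S - nucleosome_size) and replacing the two
nucleosomes' mono fragments with a single 250-350 bp fragment. Increasing
pi therefore flattens downstream mono peaks (arrays out of phase by one
linker), depresses the +2 mono peak, and shortens the apparent spacing.

All randomness flows from one numpy Generator seeded from SimConfig.seed,
so outputs are reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from nucspacer.fragment_io import FragmentRecord, GeneRecord, SignalTrack

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Generative parameters of the toy chromatin world.

    Defaults describe wild-type-like yeast chromatin: 165 bp repeat length,
    147 bp nucleosomes, 10 bp positional jitter, no dinucleosomes, 20 mono
    fragments per nucleosome, a 140 bp promoter NDR, and an activity track
    in which the top 300 genes are 8-fold above baseline.
    """

    n_genes: int = 2000
    n_chroms: int = 4
    gene_length_range: tuple[int, int] = (500, 4000)
    intergenic_bp: int = 500
    spacing: float = 165.0
    nucleosome_size: int = 147
    plus1_jitter: float = 10.0  # sd of +1 dyad around its expected position
    step_jitter: float = 10.0  # sd added per inter-nucleosome step (random walk)
    dinuc_prob: float = 0.0  # per-gene probability of one close-packed dinucleosome
    dinuc_junction_weights: tuple[float, float] = (0.5, 0.5)  # (+1/+2, +2/+3)
    mono_len_mean: float = 147.0
    mono_len_sd: float = 10.0
    mono_len_clip: tuple[int, int] = (120, 180)
    di_len_mean: float = 300.0
    di_len_sd: float = 20.0
    di_len_clip: tuple[int, int] = (250, 350)
    ndr_width: int = 140
    depth: float = 20.0  # mean mono fragments per nucleosome
    background_rate: float = 1.0  # fragments per kb, uniform
    activity_topn: int = 300
    activity_fold: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.spacing <= self.nucleosome_size:
            raise ValueError("spacing must exceed nucleosome_size")
        if not 0 <= self.dinuc_prob <= 1:
            raise ValueError("dinuc_prob must be in [0, 1]")
        w = self.dinuc_junction_weights
        if any(x < 0 for x in w) or sum(w) <= 0:
            raise ValueError("junction weights must be >= 0 with positive sum")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.intergenic_bp < self.ndr_width:
            raise ValueError("intergenic_bp must be >= ndr_width")
        if self.seed is None:
            raise ValueError("seed must be set")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated fragments.

    per_gene maps gene_id to {plus1_dyad, dyads, dinuc_junction}; counts
    are exact fragment tallies by origin (mono / di / background).
    """

    per_gene: dict[str, dict]
    config: SimConfig
    n_mono_fragments: int = 0
    n_di_fragments: int = 0
    n_background_fragments: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "per_gene": self.per_gene,
            "n_mono_fragments": self.n_mono_fragments,
            "n_di_fragments": self.n_di_fragments,
            "n_background_fragments": self.n_background_fragments,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def generate_genome(cfg: SimConfig) -> tuple[dict[str, int], list[GeneRecord]]:
    """Lay out non-overlapping genes with random strands over n_chroms.

    Genes are placed sequentially with intergenic_bp gaps, distributed
    round-robin over chromosomes; gene lengths are uniform over
    gene_length_range and strands are drawn at random (seeded).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lengths = rng.integers(
        cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=cfg.n_genes
    )
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    genes: list[GeneRecord] = []
    cursors = {f"chrS{i + 1}": 0 for i in range(cfg.n_chroms)}
    chrom_names = list(cursors)
    for i in range(cfg.n_genes):
        chrom = chrom_names[i % cfg.n_chroms]
        start = cursors[chrom] + cfg.intergenic_bp
        end = start + int(lengths[i])
        cursors[chrom] = end
        strand = str(strands[i])
        if strand == "+":
            tss, tts = start, end
        else:
            tss, tts = end - 1, start
        genes.append(GeneRecord(f"g{i + 1:05d}", chrom, tss, tts, strand))
    chrom_sizes = {c: cursors[c] + cfg.intergenic_bp for c in chrom_names}
    return chrom_sizes, genes


def _emit_fragment(chrom: str, center: float, length: int) -> FragmentRecord:
    start = int(round(center)) - length // 2
    return FragmentRecord(chrom, start, start + length)


def simulate_fragments(
    cfg: SimConfig,
    chrom_sizes: dict[str, int],
    genes: Sequence[GeneRecord],
) -> tuple[list[FragmentRecord], list[GeneRecord], SimTruth]:
    """Draw one chromatin configuration per gene and emit MNase fragments.

    Returns (fragments, genes with true plus1_dyad filled in, truth). Per
    gene: the +1 dyad is jittered around TSS + ndr-offset; downstream
    dyads follow a random walk with step S + N(0, sigma_step); with
    probability dinuc_prob one junction's linker is set to zero and the
    two nucleosomes emit a single dinucleosome-sized fragment; every other
    nucleosome emits Poisson(depth) mono fragments centered on its dyad.
    Uniform background fragments (mono-sized) cover the whole genome.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    half_nuc = cfg.nucleosome_size // 2
    fragments: list[FragmentRecord] = []
    genes_out: list[GeneRecord] = []
    per_gene: dict[str, dict] = {}
    n_mono = n_di = 0

    for g in genes:
        d = g.direction
        # gene's +1 anchor: half a nucleosome downstream of the TSS; the
        # realized +1 dyad of this configuration jitters around it
        anchor = g.tss + d * half_nuc
        plus1 = anchor + d * int(round(rng.normal(0.0, cfg.plus1_jitter)))
        # array extends while the dyad stays within the gene body
        dyads: list[int] = [plus1]
        while True:
            step = cfg.spacing + rng.normal(0.0, cfg.step_jitter)
            nxt = dyads[-1] + d * int(round(step))
            if d * (g.tts - nxt) < half_nuc:
                break
            dyads.append(nxt)

        junction = None
        if len(dyads) >= 2 and rng.random() < cfg.dinuc_prob:
            w = np.asarray(cfg.dinuc_junction_weights, dtype=float)
            j = int(rng.choice([1, 2], p=w / w.sum()))
            if j + 1 > len(dyads):
                j = 1
            if j + 1 <= len(dyads):
                # delete the linker at junction j: +{j+1} packs against +j,
                # dragging every downstream nucleosome upstream with it
                shift = dyads[j] - (dyads[j - 1] + d * cfg.nucleosome_size)
                for i in range(j, len(dyads)):
                    dyads[i] -= shift
                junction = j

        for i, dy in enumerate(dyads, start=1):
            if junction is not None and i in (junction, junction + 1):
                continue
            n = rng.poisson(cfg.depth)
            if n:
                lens = np.clip(
                    np.round(rng.normal(cfg.mono_len_mean, cfg.mono_len_sd, size=n)),
                    *cfg.mono_len_clip,
                ).astype(int)
                for L in lens:
                    fragments.append(_emit_fragment(g.chrom, dy, int(L)))
                n_mono += n
        if junction is not None:
            mid = (dyads[junction - 1] + dyads[junction]) / 2
            L = int(np.clip(round(rng.normal(cfg.di_len_mean, cfg.di_len_sd)),
                            *cfg.di_len_clip))
            fragments.append(_emit_fragment(g.chrom, mid, L))
            n_di += 1

        genes_out.append(
            GeneRecord(g.gene_id, g.chrom, g.tss, g.tts, g.strand, anchor)
        )
        per_gene[g.gene_id] = {
            "plus1_dyad": int(anchor),
            "dyads": [int(x) for x in dyads],
            "dinuc_junction": junction,
        }

    n_bg = 0
    for chrom, size in chrom_sizes.items():
        n = rng.poisson(cfg.background_rate * size / 1000.0)
        if n == 0:
            continue
        centers = rng.integers(0, size, size=n)
        lens = np.clip(
            np.round(rng.normal(cfg.mono_len_mean, cfg.mono_len_sd, size=n)),
            *cfg.mono_len_clip,
        ).astype(int)
        for c, L in zip(centers, lens):
            fragments.append(_emit_fragment(chrom, int(c), int(L)))
        n_bg += n

    truth = SimTruth(
        per_gene=per_gene,
        config=cfg,
        n_mono_fragments=n_mono,
        n_di_fragments=n_di,
        n_background_fragments=n_bg,
    )
    logger.info(
        "simulated %d fragments (mono=%d di=%d background=%d) over %d genes",
        len(fragments), n_mono, n_di, n_bg, len(genes),
    )
    return fragments, genes_out, truth


def simulate_activity_track(
    cfg: SimConfig, genes: Sequence[GeneRecord]
) -> tuple[SignalTrack, list[str]]:
    """Synthetic activity (Pol II-like) signal over gene bodies.

    The activity_topn genes (chosen at random, seeded) get activity_fold x
    the baseline density of 1; all other gene bodies get the baseline.
    Returns the track and the ranked list of active gene ids.
    """
    cfg.validate()
    if cfg.activity_topn > len(genes):
        raise ValueError("activity_topn exceeds number of genes")
    rng = np.random.default_rng(cfg.seed + 2)
    order = rng.permutation(len(genes))
    top = set(order[: cfg.activity_topn])
    rows = []
    ranked: list[str] = []
    for i, g in enumerate(genes):
        val = cfg.activity_fold if i in top else 1.0
        if i in top:
            ranked.append(g.gene_id)
        rows.append(
            {
                "chrom": g.chrom,
                "start": min(g.tss, g.tts),
                "end": max(g.tss, g.tts) + 1,
                "value": val,
            }
        )
    df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return SignalTrack(df), ranked
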