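"""Shared fixtures: toy genomes and a reusable wild-type-like simulation."""

from __future__ import annotations

import pytest

from nucspacer.fragment_io import FragmentRecord, GeneRecord, classify_by_size
from nucspacer.synthetic_chromatin import (
    SimConfig,
    generate_genome,
    simulate_fragments,
)

TOY_GENOME = {"chrI": 10_000}


@pytest.fixture
def toy_plus_gene() -> GeneRecord:
    return GeneRecord("gA", "chrI", 1000, 3500, "+", plus1_dyad=1000)


@pytest.fixture
def toy_minus_gene() -> GeneRecord:
    return GeneRecord("gB", "chrI", 5000, 2999, "-", plus1_dyad=5000)


@pytest.fixture(scope="session")
def wt_sim():
    """Wild-type-like simulation: S=165, jitter 10/10, no dinucleosomes.

    Session-scoped; returned objects must not be mutated by tests.
    """
    cfg = SimConfig(n_genes=2000, spacing=165.0, seed=42)
    chrom_sizes, genes = generate_genome(cfg)
    fragments, genes_out, truth = simulate_fragments(cfg, chrom_sizes, genes)
    mono, di, other = classify_by_size(fragments)
    return {
        "cfg": cfg,
        "chrom_sizes": chrom_sizes,
        "genes": genes_out,
        "fragments": fragments,
        "mono": mono,
        "di": di,
        "other": other,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def dinuc_sim():
    """Disrupted-chromatin simulation with dinucleosomes on half the genes."""
    cfg = SimConfig(n_genes=1000, spacing=165.0, dinuc_prob=0.5, seed=43)
    chrom_sizes, genes = generate_genome(cfg)
    fragments, genes_out, truth = simulate_fragments(cfg, chrom_sizes, genes)
    mono, di, other = classify_by_size(fragments)
    return {
        "cfg": cfg,
        "chrom_sizes": chrom_sizes,
        "genes": genes_out,
        "fragments": fragments,
        "mono": mono,
        "di": di,
        "other": other,
        "truth": truth,
    }


def brute_force_profile(
    fragments: list[FragmentRecord],
    genes: list[GeneRecord],
    anchor_kind: str,
    window: tuple[int, int],
    track_kind: str,
    genome_length: int,
) -> list[float]:
    """Independent per-base counting oracle for metagene profiles.

    Counts dyads (or covered bases) at every genomic position with plain
    dicts, then reads the strand-flipped window per gene and normalizes.
    """
    counts: dict[tuple[str, int], float] = {}
    total = 0.0
    for f in fragments:
        if track_kind == "dyad":
            pos = (f.start + f.end) // 2
            counts[(f.chrom, pos)] = counts.get((f.chrom, pos), 0.0) + 1.0
            total += 1.0
        else:
            for pos in range(f.start, f.end):
                counts[(f.chrom, pos)] = counts.get((f.chrom, pos), 0.0) + 1.0
                total += 1.0
    norm = total / genome_length
    lo, hi = window
    values = []
    for off in range(lo, hi + 1):
        acc = 0.0
        for g in genes:
            anchor = g.plus1_dyad if anchor_kind == "plus1" else g.tss
            direction = 1 if g.strand == "+" else -1
            pos = anchor + direction * off
            acc += counts.get((g.chrom, pos), 0.0)
        values.append(acc / len(genes) / norm)
    return values
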