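"""Metagene profile construction against a brute-force per-base oracle."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import brute_force_profile
from nucspacer.fragment_io import FragmentRecord, GeneRecord
from nucspacer.profile_builder import (
    build_dyad_profile,
    build_occupancy_profile,
    call_plus1_reference,
    compute_normalization,
    read_profile_tsv,
    write_profile_tsv,
)

G = 10_000
CHROMS = {"chrI": G}


def test_single_fragment_single_gene_dyad_value(toy_plus_gene):
    """One dyad at offset +160 on one gene gives value (1/1)/(1/G) = G there."""
    frag = FragmentRecord("chrI", 1085, 1235)  # dyad 1160 = anchor + 160
    prof = build_dyad_profile(
        [frag], [toy_plus_gene], "plus1", (-200, 1000), chrom_sizes=CHROMS
    )
    assert prof.value_at(160) == pytest.approx(G)
    assert np.count_nonzero(prof.values) == 1


def test_minus_strand_flip(toy_minus_gene):
    """A dyad 160 bp downstream of a minus-strand anchor lands at offset +160."""
    frag = FragmentRecord("chrI", 4765, 4915)  # dyad 4840 = 5000 - 160
    prof = build_dyad_profile(
        [frag], [toy_minus_gene], "plus1", (-200, 1000), chrom_sizes=CHROMS
    )
    assert prof.value_at(160) == pytest.approx(G)


def test_uniform_dyads_normalize_to_one(toy_plus_gene):
    """One dyad per base genome-wide gives a profile identically 1.0."""
    frags = [FragmentRecord("chrI", p, p + 1) for p in range(G)]
    prof = build_dyad_profile(
        [frags[i] for i in range(G)], [toy_plus_gene], "plus1", (-500, 500),
        chrom_sizes=CHROMS,
    )
    assert np.allclose(prof.values, 1.0, atol=1e-9)


@pytest.mark.parametrize("track_kind", ["dyad", "occupancy"])
def test_oracle_equivalence_mixed_strands(track_kind, toy_plus_gene, toy_minus_gene):
    """Random toy fragment sets match per-base counting at every offset."""
    rng = np.random.default_rng(3)
    frags = []
    for _ in range(50):
        start = int(rng.integers(0, G - 200))
        frags.append(FragmentRecord("chrI", start, start + int(rng.integers(120, 181))))
    genes = [toy_plus_gene, toy_minus_gene]
    build = build_dyad_profile if track_kind == "dyad" else build_occupancy_profile
    prof = build(frags, genes, "plus1", (-200, 400), chrom_sizes=CHROMS)
    oracle = brute_force_profile(frags, genes, "plus1", (-200, 400), track_kind, G)
    np.testing.assert_allclose(prof.values, oracle, rtol=0, atol=1e-12)


def test_occupancy_coverage_additivity(toy_plus_gene):
    f = FragmentRecord("chrI", 1100, 1250)
    prof1 = build_occupancy_profile(
        [f], [toy_plus_gene], "plus1", (-200, 400), chrom_sizes=CHROMS
    )
    prof2 = build_occupancy_profile(
        [f, f], [toy_plus_gene], "plus1", (-200, 400), chrom_sizes=CHROMS
    )
    # doubling fragments doubles the normalization constant too -> identical profile
    np.testing.assert_allclose(prof1.values, prof2.values)
    raw1 = prof1.values * prof1.norm_constant.value
    assert np.count_nonzero(raw1) == 150


def test_strand_mirror_symmetry():
    """Mirroring the toy genome (coords + strands) leaves profiles unchanged.

    Odd-length fragments are used so the floor-midpoint dyad maps exactly
    under mirroring.
    """
    rng = np.random.default_rng(9)
    frags, mirrored = [], []
    for _ in range(40):
        start = int(rng.integers(0, G - 200))
        L = int(rng.choice([121, 147, 175]))
        frags.append(FragmentRecord("chrI", start, start + L))
        mirrored.append(FragmentRecord("chrI", G - (start + L), G - start))
    genes = [GeneRecord("g1", "chrI", 1000, 3500, "+", 1100)]
    genes_m = [GeneRecord("g1", "chrI", G - 1 - 1000, G - 1 - 3500, "-", G - 1 - 1100)]
    for build in (build_dyad_profile, build_occupancy_profile):
        p = build(frags, genes, "plus1", (-200, 400), chrom_sizes=CHROMS)
        pm = build(mirrored, genes_m, "plus1", (-200, 400), chrom_sizes=CHROMS)
        np.testing.assert_allclose(p.values, pm.values, atol=1e-12)


def test_dyad_conservation(toy_plus_gene, toy_minus_gene):
    """Sum of unnormalized mean counts x n_genes equals in-window dyads,
    counted once per overlapping gene window."""
    rng = np.random.default_rng(5)
    frags = [
        FragmentRecord("chrI", s, s + 147)
        for s in rng.integers(0, G - 150, size=60)
    ]
    genes = [toy_plus_gene, toy_minus_gene]
    window = (-200, 400)
    prof = build_dyad_profile(frags, genes, "plus1", window, chrom_sizes=CHROMS)
    total = prof.values.sum() * prof.n_genes * prof.norm_constant.value
    expected = 0
    for g in genes:
        d = 1 if g.strand == "+" else -1
        for f in frags:
            off = d * ((f.start + f.end) // 2 - g.plus1_dyad)
            if window[0] <= off <= window[1]:
                expected += 1
    assert total == pytest.approx(expected)


def test_normalization_constants():
    frags = [FragmentRecord("c", 0, 150), FragmentRecord("c", 10, 60)]
    assert compute_normalization(frags, "dyad", 1000).value == pytest.approx(0.002)
    assert compute_normalization(frags, "occupancy", 1000).value == pytest.approx(0.2)
    frags100 = [FragmentRecord("c", i, i + 10) for i in range(100)]
    assert compute_normalization(frags100, "dyad", 10_000).value == pytest.approx(0.01)
    with pytest.raises(ValueError):
        compute_normalization([], "dyad", 1000)


def test_error_conditions(toy_plus_gene):
    with pytest.raises(ValueError, match="no mononucleosome fragments"):
        build_dyad_profile([], [toy_plus_gene], "plus1", (-200, 400))
    f = FragmentRecord("chrI", 100, 250)
    bare = GeneRecord("g", "chrI", 1000, 3500, "+")  # no plus1
    with pytest.raises(ValueError, match="no genes with anchor"):
        build_dyad_profile([f], [bare], "plus1", (-200, 400), chrom_sizes=CHROMS)
    with pytest.raises(ValueError, match="window"):
        build_dyad_profile([f], [toy_plus_gene], "plus1", (100, 400))


class TestPlus1Calling:
    def test_unimodal(self):
        g = GeneRecord("g", "chrI", 1000, 3500, "+")
        frags = [FragmentRecord("chrI", 1075 - 73, 1075 + 74)] * 10  # dyads at 1075
        called, excluded = call_plus1_reference(frags, [g], chrom_sizes=CHROMS)
        assert not excluded
        assert called[0].plus1_dyad == 1075

    def test_zero_fragment_gene_excluded(self):
        g1 = GeneRecord("g1", "chrI", 1000, 3500, "+")
        g2 = GeneRecord("g2", "chrI", 6000, 9000, "+")
        frags = [FragmentRecord("chrI", 1002, 1149)]
        called, excluded = call_plus1_reference(frags, [g1, g2], chrom_sizes=CHROMS)
        assert [g.gene_id for g in called] == ["g1"]
        assert [g.gene_id for g in excluded] == ["g2"]

    def test_tie_breaks_toward_tss(self):
        g = GeneRecord("g", "chrI", 1000, 3500, "+")
        frags = [
            FragmentRecord("chrI", 1060 - 73, 1060 + 74),
            FragmentRecord("chrI", 1200 - 73, 1200 + 74),
        ]
        called, _ = call_plus1_reference(frags, [g], smooth_bw=5, chrom_sizes=CHROMS)
        assert called[0].plus1_dyad == 1060

    def test_existing_plus1_kept(self, toy_plus_gene):
        frags = [FragmentRecord("chrI", 1100, 1247)]
        called, _ = call_plus1_reference(frags, [toy_plus_gene], chrom_sizes=CHROMS)
        assert called[0].plus1_dyad == 1000


def test_profile_tsv_roundtrip(tmp_path, toy_plus_gene):
    frag = FragmentRecord("chrI", 1085, 1235)
    prof = build_dyad_profile(
        [frag], [toy_plus_gene], "plus1", (-50, 50 + 300), chrom_sizes=CHROMS
    )
    path = tmp_path / "p.tsv"
    write_profile_tsv(prof, path)
    back = read_profile_tsv(path)
    np.testing.assert_array_equal(back.values, prof.values)
    assert back.track_kind == "dyad"
    assert back.n_genes == 1
    assert back.norm_constant.value == pytest.approx(prof.norm_constant.value)
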