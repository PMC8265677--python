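import numpy as np
import pandas as pd
import pytest

from sixma.classify import classify_sites
from sixma.genome_io import GeneModel, Genome, ParseError
from sixma.nucleosome import (
    DyadProfile,
    compare_positioning,
    composite_dyad_profile,
    dyad_relative_6ma,
    estimate_periodicity,
    fragments_to_dyads,
    positioning_degree,
    read_bed_fragments,
)
from sixma.synthetic import SimConfig, simulate_genome, simulate_mnase

from conftest import make_callset


def profile_from(density, lo=-500):
    d = np.asarray(density, dtype=float)
    return DyadProfile(np.arange(lo, lo + len(d)), d / d.sum(), smooth=1)


class TestFragments:
    def test_midpoint_dyad(self):
        frags = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [247]})
        d = fragments_to_dyads(frags)
        assert d["dyad"].tolist() == [173]

    def test_length_gate(self):
        frags = pd.DataFrame({"chrom": ["c"] * 3, "start": [0, 0, 0],
                              "end": [80, 147, 200]})
        d = fragments_to_dyads(frags, 120, 180)
        assert d["dyad"].tolist() == [73]

    def test_bed_reader_reports_line_numbers(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("c\t0\t147\nc\t10\n")
        with pytest.raises(ParseError, match="2"):
            read_bed_fragments(p)
        p.write_text("c\t5\t2\n")
        with pytest.raises(ParseError, match="bad interval"):
            read_bed_fragments(p)

    def test_simulated_fragments_recover_known_dyads(self):
        cfg = SimConfig(seed=4, chrom_lengths=(30_000,), dyad_jitter=10.0)
        genome, genes = simulate_genome(cfg)
        frags, dyad_truth = simulate_mnase(cfg, genome, genes)
        dyads = fragments_to_dyads(frags)
        # histogram peak within 10 bp of each true +1 dyad of the first genes
        arr = np.sort(dyads["dyad"].to_numpy())
        for row in dyad_truth[dyad_truth["k"] == 1].head(5).itertuples(index=False):
            near = arr[np.abs(arr - row.dyad) <= 50]
            assert len(near) > 0
            assert abs(np.median(near) - row.dyad) <= 10


class TestCompositeProfile:
    def test_single_dyad_at_tss_is_delta_before_smoothing(self):
        genes = [GeneModel("g", "c", 1000, 3000, "+")]
        dyads = pd.DataFrame({"chrom": ["c"], "dyad": [1000]})
        prof = composite_dyad_profile(dyads, genes, smooth=1)
        assert prof.density[np.searchsorted(prof.positions, 0)] == pytest.approx(1.0)
        assert prof.density.sum() == pytest.approx(1.0)

    def test_uniform_dyads_give_flat_profile(self):
        genes = [GeneModel("g", "c", 1000, 3000, "+")]
        dyads = pd.DataFrame({"chrom": "c", "dyad": np.arange(0, 4000)})
        prof = composite_dyad_profile(dyads, genes, smooth=31)
        assert np.allclose(prof.density, prof.density[0])

    def test_phased_simulation_peaks_near_expected(self):
        rng = np.random.default_rng(0)
        genes = [GeneModel("g", "c", 5000, 9000, "+")]
        centers = 5000 + 100 + 200 * np.arange(5)
        dyads = pd.DataFrame({
            "chrom": "c",
            "dyad": np.concatenate([rng.normal(c, 15, 400).astype(int) for c in centers]),
        })
        prof = composite_dyad_profile(dyads, genes)
        rep = positioning_degree(prof, k_max=3)
        for peak, expected in zip(rep.peaks, [100, 300, 500]):
            assert abs(peak - expected) <= 20

    def test_minus_strand_orientation(self):
        genes = [GeneModel("g", "c", 1000, 3001, "-")]  # tss = 3000
        dyads = pd.DataFrame({"chrom": ["c"], "dyad": [2900]})  # 100 bp downstream
        prof = composite_dyad_profile(dyads, genes, smooth=1)
        assert prof.positions[np.argmax(prof.density)] == 100

    def test_union_profile_is_weighted_mixture(self):
        rng = np.random.default_rng(1)
        g1 = [GeneModel("a", "c", 5000, 8000, "+")]
        g2 = [GeneModel("b", "c", 20_000, 23_000, "+")]
        dyads = pd.DataFrame({"chrom": "c", "dyad": np.concatenate([
            rng.normal(5100, 30, 300).astype(int), rng.normal(20_100, 30, 700).astype(int)])})
        p1 = composite_dyad_profile(dyads, g1, smooth=1)
        p2 = composite_dyad_profile(dyads, g2, smooth=1)
        pu = composite_dyad_profile(dyads, g1 + g2, smooth=1)
        mix = (p1.n_dyads * p1.density + p2.n_dyads * p2.density) / (p1.n_dyads + p2.n_dyads)
        np.testing.assert_allclose(pu.density, mix, atol=1e-12)

    def test_even_smoothing_rejected(self):
        genes = [GeneModel("g", "c", 1000, 3000, "+")]
        dyads = pd.DataFrame({"chrom": ["c"], "dyad": [1000]})
        with pytest.raises(ValueError, match="odd"):
            composite_dyad_profile(dyads, genes, smooth=30)


class TestPositioningDegree:
    def test_flat_profile_degree_zero(self):
        rep = positioning_degree(profile_from(np.ones(2000)))
        assert all(abs(d) < 1e-12 for d in rep.degrees)

    def test_zero_troughs_give_degree_one(self):
        d = np.zeros(2000)
        for k in range(5):
            d[500 + 100 + 200 * k] = 1.0  # delta peaks, zero elsewhere
        rep = positioning_degree(profile_from(d), avg_half=0)
        assert rep.degrees == pytest.approx([1.0] * 5)

    def test_cosine_profile_matches_closed_form(self):
        # density m + a*cos(2*pi*x/200) peaking at the +k positions;
        # +/-20 bp window averaging shrinks the contrast by the sinc factor
        # sin(2*pi*W/P)/(2*pi*W/P) with W = 20.5 half-width steps
        m, a = 2.0, 0.5
        x = np.arange(-500, 1500)
        d = m + a * np.cos(2 * np.pi * (x - 100) / 200.0)
        rep = positioning_degree(profile_from(d))
        w = 2 * np.pi * 20.5 / 200.0
        shrink = np.sin(w) / w
        expected = (a / m) * shrink
        for deg in rep.degrees:
            assert deg == pytest.approx(expected, rel=0.02)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        d = 1.0 + 0.3 * np.cos(2 * np.pi * np.arange(-500, 1500) / 200) + rng.normal(0, 0.01, 2000)
        r1 = positioning_degree(profile_from(d))
        r2 = positioning_degree(profile_from(7.0 * d))
        assert r1.degrees == pytest.approx(r2.degrees)

    def test_degree_decreases_with_dyad_jitter(self):
        degrees = []
        for jitter in (10.0, 30.0, 60.0):
            cfg = SimConfig(seed=6, chrom_lengths=(60_000,), dyad_jitter=jitter,
                            frags_per_dyad=60.0, bg_fragment_frac=0.0)
            genome, genes = simulate_genome(cfg)
            frags, _ = simulate_mnase(cfg, genome, genes)
            prof = composite_dyad_profile(fragments_to_dyads(frags), genes)
            degrees.append(positioning_degree(prof, k_max=3).degrees[0])
        assert degrees[0] > degrees[1] > degrees[2]


class TestPeriodicity:
    def test_pure_200bp_cosine(self):
        x = np.arange(-500, 1500)
        d = 2.0 + np.cos(2 * np.pi * x / 200.0)
        assert estimate_periodicity(profile_from(d)) == 200.0

    def test_white_noise_is_aperiodic(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.5, 1.5, 2000)
        with pytest.raises(ValueError, match="aperiodic"):
            estimate_periodicity(profile_from(d))

    def test_damped_noisy_oscillation(self):
        rng = np.random.default_rng(4)
        x = np.arange(-500, 1500)
        d = 2.0 + np.exp(-np.clip(x, 0, None) / 800.0) * np.cos(2 * np.pi * x / 200.0)
        d += rng.normal(0, 0.05, len(d))
        assert abs(estimate_periodicity(profile_from(d)) - 200) <= 10

    @pytest.mark.parametrize("spacing", [150, 200, 250])
    def test_simulated_spacing_recovered(self, spacing):
        cfg = SimConfig(seed=7, chrom_lengths=(60_000,), spacing=spacing,
                        frags_per_dyad=40.0, bg_fragment_frac=0.05)
        genome, genes = simulate_genome(cfg)
        frags, _ = simulate_mnase(cfg, genome, genes)
        prof = composite_dyad_profile(fragments_to_dyads(frags), genes)
        assert abs(estimate_periodicity(prof) - spacing) <= 0.05 * spacing


class TestDyadRelative6ma:
    def _dyads(self, positions):
        return pd.DataFrame({"chrom": "c", "dyad": positions})

    def test_midway_and_at_dyad(self):
        g = Genome({"c": "AT" * 500})
        cl = classify_sites(make_callset([("c", 300, "+", 0.9), ("c", 200, "+", 0.5)]), g)
        out = dyad_relative_6ma(cl, self._dyads([200, 400]))
        rel = dict(zip(out["pos"], out["relative"]))
        assert rel[300] == pytest.approx(0.5)
        assert rel[200] == pytest.approx(0.0)

    def test_large_gaps_and_single_dyad_chromosomes_excluded(self):
        g = Genome({"c": "AT" * 500, "d": "AT" * 500})
        cl = classify_sites(make_callset([("c", 300, "+", 0.9), ("d", 100, "+", 0.9)]), g)
        dyads = pd.DataFrame({"chrom": ["c", "c", "d"], "dyad": [0, 900, 50]})
        out = dyad_relative_6ma(cl, dyads)  # gap 900 > 400 and single dyad on d
        assert len(out) == 0

    def test_linker_enriched_sites_mode_at_half(self):
        rng = np.random.default_rng(5)
        g = Genome({"c": "AT" * 30_000})
        dyads = self._dyads(np.arange(100, 50_000, 200))
        # sites drawn near linker midpoints (dyad + 100)
        pos = (rng.choice(np.arange(100, 49_000, 200), 400)
               + rng.integers(80, 121, 400))
        pos = np.unique(pos // 2 * 2)  # even -> Watson A on the AT genome
        cl = classify_sites(make_callset([("c", int(p), "+", 0.9) for p in pos]), g)
        out = dyad_relative_6ma(cl, dyads)
        hist, edges = np.histogram(out["relative"], bins=5, range=(0, 1))
        assert edges[np.argmax(hist)] == pytest.approx(0.4)  # mode bin covers 0.4-0.6

    def test_level_bins_carried_through(self):
        g = Genome({"c": "AT" * 500})
        cl = classify_sites(make_callset([("c", 300, "+", 0.95)]), g)
        out = dyad_relative_6ma(cl, self._dyads([200, 400]))
        assert out["level"].tolist() == ["L5"]


class TestComparePositioning:
    def test_identical_sets_zero_difference(self):
        cfg = SimConfig(seed=8, chrom_lengths=(40_000,))
        genome, genes = simulate_genome(cfg)
        frags, _ = simulate_mnase(cfg, genome, genes)
        dyads = fragments_to_dyads(frags)
        ids = {g.gene_id for g in genes}
        out = compare_positioning({"gain": ids, "loss": set(ids)}, dyads, genes, min_genes=1)
        assert out["delta_plus1"] == pytest.approx(0.0)
        assert out["delta_plus1to3"] == pytest.approx(0.0)

    def test_sharper_phasing_in_gain_set_detected(self):
        cfg = SimConfig(seed=9, chrom_lengths=(60_000,), dyad_jitter=10.0,
                        frags_per_dyad=50.0, bg_fragment_frac=0.0)
        genome, genes = simulate_genome(cfg)
        sharp, _ = simulate_mnase(cfg, genome, genes)
        fuzzy, _ = simulate_mnase(cfg.with_(dyad_jitter=60.0, seed=10), genome, genes)
        half = len(genes) // 2
        gain, loss = genes[:half], genes[half:]
        frags = pd.concat([
            sharp[sharp["chrom"] == "chr1"], fuzzy[fuzzy["chrom"] == "chr1"]], ignore_index=True)
        # restrict each set's fragments by gene ownership via coordinates:
        # gain genes get the sharp fragments, loss genes the fuzzy ones
        gain_ids = {g.gene_id for g in gain}
        loss_ids = {g.gene_id for g in loss}
        d_sharp = fragments_to_dyads(sharp)
        d_fuzzy = fragments_to_dyads(fuzzy)
        rep_gain = compare_positioning({"gain": gain_ids}, d_sharp, genes, min_genes=1)
        rep_loss = compare_positioning({"loss": loss_ids}, d_fuzzy, genes, min_genes=1)
        g1 = rep_gain["reports"]["gain"].degrees[0]
        l1 = rep_loss["reports"]["loss"].degrees[0]
        assert g1 - l1 > 0

    def test_empty_loss_set_reports_gain_only(self, caplog):
        cfg = SimConfig(seed=8, chrom_lengths=(40_000,))
        genome, genes = simulate_genome(cfg)
        frags, _ = simulate_mnase(cfg, genome, genes)
        dyads = fragments_to_dyads(frags)
        out = compare_positioning({"gain": {genes[0].gene_id}, "loss": set()},
                                  dyads, genes, min_genes=1)
        assert "gain" in out["reports"] and "loss" not in out["reports"]
        assert "delta_plus1" not in out
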