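import numpy as np
import pandas as pd
import pytest

import enhscreen as es
from enhscreen import simulate
from enhscreen._util import revcomp
from enhscreen.pipeline import call_induced_elements


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            es.SimulationConfig(n_enhancers=5, n_induced=6)
        with pytest.raises(ValueError):
            es.SimulationConfig(designable_fraction=1.5)
        with pytest.raises(ValueError):
            es.SimulationConfig(induction_fold=0)

    def test_too_small_genome_names_constraint(self):
        with pytest.raises(ValueError, match="non-overlapping loci"):
            es.SimulationConfig(n_enhancers=100, genome_length=1000)


class TestGenerateGenome:
    def test_same_seed_is_byte_identical(self, small_config):
        g1, t1 = es.generate_genome(small_config)
        g2, t2 = es.generate_genome(small_config)
        assert g1 == g2
        pd.testing.assert_frame_equal(t1.loci, t2.loci)

    def test_no_enhancers_plants_no_motif(self):
        cfg = es.SimulationConfig(n_enhancers=0, n_induced=0,
                                  n_decoy_unidirectional=2,
                                  n_decoy_convergent=0, n_decoy_divergent_far=0, seed=1)
        genome, truth = es.generate_genome(cfg)
        assert truth.enhancer_loci.empty
        assert truth.loci["motif_start"].isna().all()

    def test_each_enhancer_locus_carries_planted_motif(self, small_world):
        cfg, genome, truth, *_ = small_world
        seq = genome["chr1"]
        for _, row in truth.enhancer_loci.iterrows():
            s, e = int(row["motif_start"]), int(row["motif_end"])
            planted = seq[s:e]
            expected = (cfg.motif_consensus if row["motif_strand"] == "+"
                        else revcomp(cfg.motif_consensus))
            assert planted == expected

    def test_designable_counts_match_fraction_exactly(self):
        cfg = es.SimulationConfig(n_enhancers=100, n_induced=10,
                                  designable_fraction=0.62,
                                  n_decoy_unidirectional=0,
                                  n_decoy_convergent=0, n_decoy_divergent_far=0, seed=3)
        _, truth = es.generate_genome(cfg)
        assert int(truth.enhancer_loci["designable"].sum()) == 62

    @pytest.mark.parametrize("seed", range(20))
    def test_truth_flags_agree_with_guide_design(self, seed):
        """Planted designable motifs are exactly the ones guide design recovers."""
        cfg = es.SimulationConfig(
            n_enhancers=10, n_induced=2, designable_fraction=0.5,
            n_decoy_unidirectional=0, n_decoy_convergent=0,
            n_decoy_divergent_far=0, seed=seed,
        )
        genome, truth = es.generate_genome(cfg)
        for _, row in truth.enhancer_loci.iterrows():
            occ = {"chrom": row["chrom"], "start": int(row["motif_start"]),
                   "end": int(row["motif_end"])}
            g = es.designable_guides(occ, genome)
            assert (len(g) > 0) is bool(row["designable"])

    def test_designable_fraction_one_all_targetable(self):
        cfg = es.SimulationConfig(n_enhancers=10, n_induced=2, designable_fraction=1.0,
                                  n_decoy_unidirectional=0, n_decoy_convergent=0,
                                  n_decoy_divergent_far=0, seed=5)
        genome, truth = es.generate_genome(cfg)
        assert truth.enhancer_loci["designable"].all()
        for _, row in truth.enhancer_loci.iterrows():
            g = es.designable_guides(
                {"chrom": "chr1", "start": int(row["motif_start"]),
                 "end": int(row["motif_end"])}, genome)
            assert len(g) >= 1


class TestGenerateTuCounts:
    def test_matrix_shape_two_conditions_times_replicates(self, small_world):
        cfg, _, truth, tus, counts, samples = small_world
        assert counts.shape[1] == 2 * cfg.n_replicates
        assert len(samples) == counts.shape[1]
        assert (counts.to_numpy() >= 0).all()

    def test_determinism(self, small_config):
        _, truth = es.generate_genome(small_config)
        a = es.generate_tu_counts(truth, small_config)
        b = es.generate_tu_counts(truth, small_config)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_enhancer_loci_yield_divergent_pairs_within_window(self, small_world):
        cfg, _, truth, tus, _, _ = small_world
        res = es.pair_bidirectional(tus)
        enh_pairs = {
            frozenset((r["plus_tu"], r["minus_tu"]))
            for _, r in truth.enhancer_loci.iterrows()
        }
        called = {frozenset((r["plus_tu"], r["minus_tu"])) for _, r in res.iterrows()}
        assert enh_pairs <= called

    def test_far_and_convergent_decoys_never_paired(self, small_world):
        cfg, _, truth, tus, _, _ = small_world
        res = es.pair_bidirectional(tus)
        called_tus = set(res["plus_tu"]) | set(res["minus_tu"])
        decoys = truth.loci[truth.loci["kind"].isin(["far", "convergent"])]
        for _, row in decoys.iterrows():
            assert row["plus_tu"] not in called_tus
            assert row["minus_tu"] not in called_tus

    def test_negative_binomial_moments(self):
        """Empirical mean/variance match var = mu + (cv*mu)^2 at n = 10,000."""
        rng = np.random.default_rng(0)
        mu, cv = 200.0, 0.1
        draws = simulate._draw_counts(rng, np.full(10_000, mu), cv)
        assert draws.mean() == pytest.approx(mu, rel=0.02)
        expected_var = mu + (cv * mu) ** 2
        assert draws.var() == pytest.approx(expected_var, rel=0.1)

    def test_null_fold_produces_no_induced_calls(self):
        """Monte-Carlo false-positive rate under induction_fold = 1."""
        fp = 0
        total = 0
        for seed in range(10):
            cfg = es.SimulationConfig(
                n_enhancers=50, n_induced=10, induction_fold=1.0,
                n_decoy_unidirectional=5, n_decoy_convergent=5,
                n_decoy_divergent_far=5, seed=seed,
            )
            _, truth = es.generate_genome(cfg)
            tus, counts, samples = es.generate_tu_counts(truth, cfg)
            res, _ = call_induced_elements(tus, counts, samples)
            fp += int(res["induced"].sum())
            total += len(res)
        assert fp / total <= 0.01


class TestGenerateScreenCounts:
    def _library(self, n=100, guides_per_re=2):
        return pd.DataFrame({
            "guide_id": [f"sg{i:04d}" for i in range(n)],
            "re_id": [f"RE{i // guides_per_re:04d}" for i in range(n)],
        })

    def test_empty_library_rejected(self):
        cfg = es.SimulationConfig(seed=0)
        with pytest.raises(ValueError, match="empty"):
            es.generate_screen_counts(self._library(0), es.TruthSet(pd.DataFrame()), cfg)

    def test_fixed_seed_identical_counts(self):
        cfg = es.SimulationConfig(seed=9)
        lib = self._library()
        truth = es.TruthSet(pd.DataFrame(), enriched_guides=pd.DataFrame(
            {"guide_id": ["sg0000"], "effect_fold": [4.0]}))
        a, _ = es.generate_screen_counts(lib, truth, cfg)
        b, _ = es.generate_screen_counts(lib, truth, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_null_screen_centers_fold_changes_at_zero(self):
        from enhscreen.pipeline import score_screen
        cfg = es.SimulationConfig(seed=2)
        lib = self._library(500)
        truth = es.TruthSet(pd.DataFrame())  # nothing enriched
        counts, samples = es.generate_screen_counts(lib, truth, cfg)
        enr, _ = score_screen(counts, samples, lib, threshold_units="log2")
        assert abs(enr["mean_fc"].mean()) < 0.02

    def test_single_strong_guide_attains_top_z(self):
        """A fold-8 guide among 1000 nulls ranks first in >= 95% of seeds."""
        from enhscreen.pipeline import score_screen
        lib = self._library(1000)
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = es.SimulationConfig(seed=seed)
            truth = es.TruthSet(pd.DataFrame(), enriched_guides=pd.DataFrame(
                {"guide_id": ["sg0500"], "effect_fold": [8.0]}))
            counts, samples = es.generate_screen_counts(lib, truth, cfg)
            enr, _ = score_screen(counts, samples, lib, threshold_units="log2")
            wins += enr["z"].idxmax() == "sg0500"
        assert wins >= 0.95 * n_seeds

    def test_plant_screen_truth_targets_requested_res(self):
        cfg = es.SimulationConfig(seed=4, n_hit_res=3, n_guides_per_hit=2)
        lib = self._library(100)
        enriched = es.plant_screen_truth(lib, cfg)
        assert len(enriched) == 6
        merged = enriched.merge(lib, on="guide_id")
        assert merged.groupby("re_id").size().eq(2).all()
        assert merged["re_id"].nunique() == 3
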