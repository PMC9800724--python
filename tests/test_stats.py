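"""Densities, spectra, heteroplasmy tests, HVS goodness-of-fit, DssH
regression, normalized complex densities and the tRNA stem/loop tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import mtselect as mt
from mtselect.simulate import SyntheticConfig, generate_cohort, replay_analysis
from mtselect.stats import (
    benjamini_hochberg,
    build_selection_report,
    compare_heteroplasmy,
    compare_spectra,
    complex_mean_dssh,
    dssh_density_regression,
    heteroplasmy_level_bins,
    hvs_nonhvs_analysis,
    mutation_density,
    normalized_complex_density,
    rrna_vs_ctr_heteroplasmy,
    split_by_mutation_load,
    spectrum_proportions,
    trna_stem_loop_analysis,
)
from mtselect.variants import MutationCatalog, calls_from_records

from conftest import make_catalog


def simulated_catalog(model, seed=0, n_samples=100, mean=20, multipliers=None, gradient=(0.1, 1.0)):
    cfg = SyntheticConfig(
        n_samples=n_samples,
        mean_mutations_per_sample=mean,
        seed=seed,
        selection_multipliers=multipliers or {},
        dssh_gradient=gradient,
    )
    calls, truth = generate_cohort(cfg, model)
    catalog, _ = mt.classify_somatic(calls, n_samples, model)
    return mt.annotate_catalog(catalog, model), cfg


class TestDensity:
    def test_cohort_scale_arithmetic(self, model, ctr_positions):
        # 600 mutations over 432 samples on the 16.569 kb genome
        rng = np.random.default_rng(0)
        catalog = make_catalog(model, rng.choice(np.arange(1, 16570), 600), n_samples=432)
        d = mutation_density(catalog, "genome", model)
        assert d.density == pytest.approx((600 / 432) / 16.569, rel=1e-12)
        assert d.density == pytest.approx(0.0838, abs=5e-4)

    def test_zero_mutations(self, model):
        catalog = MutationCatalog(calls_from_records([]), n_samples=10)
        assert mutation_density(catalog, "genome", model).density == 0.0

    def test_unit_case(self, model):
        # 1 mutation, 1 sample, ~1 kb region -> ~1 per sample per kb
        catalog = make_catalog(model, [16100], n_samples=1)
        d = mutation_density(catalog, "mtCTR", model)
        assert d.density == pytest.approx(1.0 / 1.122, rel=1e-12)

    def test_invariant_under_sample_split(self, model):
        rng = np.random.default_rng(1)
        pos = rng.choice(np.arange(1, 16570), 400)
        ids = rng.choice([f"S{i}" for i in range(40)], 400)
        catalog = make_catalog(model, pos, n_samples=40, sample_ids=ids)
        whole = mutation_density(catalog, "genome", model)
        half_ids = {f"S{i}" for i in range(20)}
        in_a = catalog.mutations["sample_id"].isin(half_ids).to_numpy()
        a = MutationCatalog(catalog.mutations.loc[in_a], n_samples=20)
        b = MutationCatalog(catalog.mutations.loc[~in_a], n_samples=20)
        da = mutation_density(a, "genome", model)
        db = mutation_density(b, "genome", model)
        recombined = (da.density * 20 + db.density * 20) / 40
        assert recombined == pytest.approx(whole.density, rel=1e-12)

    def test_requires_positive_samples(self, model):
        catalog = MutationCatalog(calls_from_records([]), n_samples=10)
        catalog.n_samples = 0
        with pytest.raises(ValueError):
            mutation_density(catalog, "genome", model)


class TestSpectrum:
    def test_proportions_sum_to_one(self, model):
        catalog, _ = simulated_catalog(model, seed=2)
        table = spectrum_proportions(catalog, "genome", model)
        assert table["proportion"].sum() == pytest.approx(1.0)
        assert table["count"].sum() == len(catalog)

    def test_empty_region_flagged(self, model):
        catalog = make_catalog(model, [16100], n_samples=1)  # control region only
        table = spectrum_proportions(catalog, "Com IV", model)
        assert table["count"].sum() == 0
        assert table["proportion"].isna().all()

    def test_chi_square_agrees_with_hand_computed_2x2(self):
        # Yates-corrected 2x2 oracle computed from the closed form
        obs = np.array([[30, 10], [12, 28]])
        n = obs.sum()
        a, b, c, d = obs.ravel()
        expected_chi2 = (
            n * (abs(a * d - b * c) - n / 2) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        chi2, _, _, _ = sps.chi2_contingency(obs)
        assert chi2 == pytest.approx(expected_chi2, rel=1e-12)

    def test_inverted_ctr_spectrum_detected(self, model):
        # control region enriched for L-strand C>T, coding region for
        # heavy-strand C>T: the regional spectra must differ significantly
        rng = np.random.default_rng(4)
        ctr_pos = np.where(model.mask("mtCTR"))[0]
        cdr_pos = np.where(model.mask("mtCDR"))[0]
        seq = np.array(list(model.sequence))
        ctr_c = ctr_pos[seq[ctr_pos - 1] == "C"]
        cdr_g = cdr_pos[seq[cdr_pos - 1] == "G"]
        positions = np.concatenate([rng.choice(ctr_c, 120), rng.choice(cdr_g, 300)])
        catalog = make_catalog(model, positions, n_samples=100)
        res = compare_spectra(catalog, "mtCTR", "mtCDR", model)
        assert res["p"] < 0.05


class TestHeteroplasmy:
    def test_identical_lists(self):
        vals = [0.1, 0.2, 0.3]
        stat, p = compare_heteroplasmy(vals, vals, test="ks")
        assert stat == 0.0 and p == 1.0

    def test_singleton_mannwhitney(self):
        _, p = compare_heteroplasmy([0.1], [0.1], test="mannwhitney")
        assert p == 1.0

    def test_distinct_betas_detected_and_match_permutation_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.beta(1, 50, 200)
        b = rng.beta(5, 5, 200)
        _, p = compare_heteroplasmy(a, b, test="mannwhitney")
        assert p < 0.001
        # permutation oracle on the rank-sum statistic
        pooled = np.concatenate([a, b])
        obs = sps.rankdata(pooled)[: len(a)].sum()
        perm = []
        for _ in range(500):
            rng.shuffle(pooled)
            perm.append(sps.rankdata(pooled)[: len(a)].sum())
        perm = np.array(perm)
        p_perm = (np.abs(perm - perm.mean()) >= abs(obs - perm.mean())).mean()
        assert p_perm < 0.01  # oracle agrees the difference is extreme

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_heteroplasmy([], [0.1])

    def test_bins_all_low(self, model):
        catalog = make_catalog(model, [100, 200, 300], vafs=0.02)
        props = heteroplasmy_level_bins(catalog)
        assert props.iloc[0] == 1.0 and props.iloc[1:].sum() == 0.0

    def test_bins_must_partition(self, model):
        catalog = make_catalog(model, [100])
        with pytest.raises(ValueError):
            heteroplasmy_level_bins(catalog, bin_edges=(0.01, 0.5, 0.4))

    def test_uniform_vafs_match_bin_widths(self, model):
        rng = np.random.default_rng(6)
        n = 4000
        vafs = rng.uniform(0.01, 1.0, n)
        catalog = make_catalog(model, rng.integers(1, 16570, n), vafs=vafs)
        props = heteroplasmy_level_bins(catalog, bin_edges=(0.01, 0.25, 0.5, 1.0))
        widths = np.array([0.24, 0.25, 0.5]) / 0.99
        assert np.allclose(props.to_numpy(), widths, atol=0.03)


class TestHvsNonHvs:
    def test_neutral_simulation_matches_length_expectation(self, model, ctr_positions):
        rng = np.random.default_rng(7)
        catalog = make_catalog(model, rng.choice(ctr_positions, 400), n_samples=100)
        out = hvs_nonhvs_analysis(catalog, model)
        assert out["expected_nonhvs_pct"] == pytest.approx(27.54, abs=0.005)
        assert abs(out["observed_nonhvs_pct"] - 27.54) < 6
        assert out["p"] > 0.05

    def test_strict_constraint_detected(self, model, ctr_positions):
        rng = np.random.default_rng(8)
        nonhvs = ctr_positions[model.mask("non-HVS")[ctr_positions]]
        hvs = ctr_positions[model.mask("HVS")[ctr_positions]]
        # non-HVS rate suppressed 5x relative to length expectation
        positions = np.concatenate([rng.choice(hvs, 300), rng.choice(nonhvs, 23)])
        catalog = make_catalog(model, positions, n_samples=100)
        out = hvs_nonhvs_analysis(catalog, model)
        assert out["observed_nonhvs_pct"] < out["expected_nonhvs_pct"] / 2
        assert out["p"] < 0.05

    def test_no_ctr_mutations_flagged(self, model):
        catalog = make_catalog(model, [6000, 7000], n_samples=10)
        out = hvs_nonhvs_analysis(catalog, model)
        assert "flag" in out and "p" not in out

    def test_type_i_error_near_nominal(self, model, ctr_positions):
        # under neutral (uniform) control-region mutation placement the
        # goodness-of-fit should reject at ~5%
        rng = np.random.default_rng(9)
        nonhvs_mask = model.mask("non-HVS")
        p_non = nonhvs_mask[ctr_positions].mean()
        rejections = 0
        R = 500
        for _ in range(R):
            n_non = rng.binomial(150, p_non)
            chi2, p = sps.chisquare(
                [n_non, 150 - n_non], f_exp=[150 * 0.2754, 150 * (1 - 0.2754)]
            )
            rejections += p < 0.05
        rate = rejections / R
        ci = 1.96 * np.sqrt(0.05 * 0.95 / R)
        assert abs(rate - 0.05) < ci + 0.015  # binomial CI plus discreteness slack


class TestDsshRegression:
    def test_rate_proportional_to_dss_recovered(self, model):
        catalog, _ = simulated_catalog(model, seed=10, n_samples=200, mean=25, gradient=(0.0, 1.0))
        reg = dssh_density_regression(catalog, model)
        assert reg["r"] > 0.7
        assert reg["slope"] > 0

    def test_constant_rate_gives_weak_correlation(self, model):
        catalog, _ = simulated_catalog(model, seed=11, n_samples=200, mean=25, gradient=(1.0, 0.0))
        reg = dssh_density_regression(catalog, model)
        assert abs(reg["r"]) < 0.55

    def test_slope_sign_invariant_to_unit_choice(self, model):
        catalog, _ = simulated_catalog(model, seed=12)
        reg = dssh_density_regression(catalog, model)
        genes = reg["per_gene"]
        fit_bp = sps.linregress(genes["mean_dss"], genes["density"] / 1000.0)
        assert np.sign(fit_bp.slope) == np.sign(reg["slope"])
        assert fit_bp.slope == pytest.approx(reg["slope"] / 1000.0, rel=1e-9)

    def test_too_few_genes_rejected(self, model):
        catalog = make_catalog(model, [6000, 6001], n_samples=5)
        with pytest.raises(ValueError, match="3 protein genes"):
            dssh_density_regression(catalog, model)

    def test_spearman_option(self, model):
        catalog, _ = simulated_catalog(model, seed=13)
        reg = dssh_density_regression(catalog, model, correlation="spearman")
        assert -1 <= reg["r"] <= 1


class TestNormalizedComplexDensity:
    def test_complex_iv_score_is_one(self, model):
        catalog, _ = simulated_catalog(model, seed=14)
        table = normalized_complex_density(catalog, model).set_index("complex")
        assert table.loc["Com IV", "standardization_score"] == pytest.approx(1.0)
        assert table.loc["Com IV", "normalized_density"] == pytest.approx(
            table.loc["Com IV", "observed_density"]
        )

    def test_complex_v_suppression_recovered(self, model):
        ests = []
        for seed in range(30):
            catalog, cfg = simulated_catalog(
                model, seed=100 + seed, multipliers={"Com V": 0.5}
            )
            rec = replay_analysis(cfg, build_selection_report(catalog, model), model)
            ests.append(rec["complex_v_multiplier"]["estimate"])
        assert np.median(ests) == pytest.approx(0.5, abs=0.12)

    @pytest.mark.parametrize("multiplier", [0.25, 0.5, 1.0])
    def test_multiplier_ci_coverage(self, model, multiplier):
        # replicate-level 95% CIs should cover the injected truth >= 90%
        covered = 0
        R = 100
        for seed in range(R):
            catalog, cfg = simulated_catalog(
                model, seed=3000 + seed, multipliers={"Com V": multiplier}
            )
            rec = replay_analysis(cfg, build_selection_report(catalog, model), model)
            lo, hi = rec["complex_v_multiplier"]["ci95"]
            covered += lo <= multiplier <= hi
        assert covered >= 90


class TestTrnaStemLoop:
    def test_loop_suppression_detected(self, model):
        catalog, _ = simulated_catalog(
            model, seed=15, n_samples=100, mean=60, multipliers={"tRNA-loop": 0.4}
        )
        out = trna_stem_loop_analysis(catalog, model)
        assert out["n_trna_mutations"] > 300
        assert out["nonstem_density"] < out["stem_density"]
        assert out["p"] < 0.05
        assert set(out["per_arm"]["arm"]) == {"D", "anticodon", "T"}

    def test_neutral_catalog_composition_corrected_ratio_near_one(self, model):
        ests = []
        for seed in range(20):
            catalog, cfg = simulated_catalog(model, seed=400 + seed, mean=40)
            rec = replay_analysis(cfg, build_selection_report(catalog, model), model)
            ests.append(rec["trna_loop_multiplier"]["estimate"])
        assert np.median(ests) == pytest.approx(1.0, abs=0.15)

    def test_no_trna_mutations_flagged(self, model):
        catalog = make_catalog(model, [6000, 16100], n_samples=10)
        out = trna_stem_loop_analysis(catalog, model)
        assert "flag" in out

    def test_deleterious_proportions_reported(self, model):
        catalog, _ = simulated_catalog(model, seed=16, mean=40)
        out = trna_stem_loop_analysis(catalog, model)
        props = out["deleterious_proportion"]
        assert 0 <= props["stem"] <= 1
        # loop/variable substitutions are benign under the default proxy
        assert props["nonstem"] == 0.0


class TestRrnaVsCtr:
    def test_identical_sets(self, model):
        rng = np.random.default_rng(17)
        rrna_pos = np.where(model.mask("rRNA"))[0]
        ctr_pos = np.where(model.mask("mtCTR"))[0]
        pos = np.concatenate([rng.choice(rrna_pos, 50), rng.choice(ctr_pos, 50)])
        catalog = make_catalog(model, pos, vafs=0.05)
        out = rrna_vs_ctr_heteroplasmy(catalog, model)
        assert out["p"] == pytest.approx(1.0)

    def test_lower_rrna_heteroplasmy_detected(self, model):
        rng = np.random.default_rng(18)
        rrna_pos = np.where(model.mask("rRNA"))[0]
        ctr_pos = np.where(model.mask("mtCTR"))[0]
        pos = np.concatenate([rng.choice(rrna_pos, 150), rng.choice(ctr_pos, 150)])
        vafs = np.concatenate([rng.beta(1, 99, 150), rng.beta(2, 8, 150)])
        catalog = make_catalog(model, pos, vafs=vafs)
        out = rrna_vs_ctr_heteroplasmy(catalog, model)
        assert out["p"] < 0.001
        assert out["mean_vaf_rrna"] < out["mean_vaf_ctr"]

    def test_empty_group_flagged(self, model):
        catalog = make_catalog(model, [16100], n_samples=1)
        out = rrna_vs_ctr_heteroplasmy(catalog, model)
        assert "flag" in out


class TestUtilities:
    def test_median_load_split(self, model):
        ids = [f"S{i}" for i in range(6)]
        pos = [100, 200, 900, 1000, 1100, 1200]
        catalog = make_catalog(
            model, pos, n_samples=6, sample_ids=["S0", "S0", "S0", "S1", "S1", "S2"]
        )
        out = split_by_mutation_load(catalog, ids)
        assert "S0" in out["high"]
        assert {"S3", "S4", "S5"} <= set(out["low"])

    def test_benjamini_hochberg_bounds(self):
        p = [0.001, 0.02, 0.04, 0.5, 0.9]
        adj = benjamini_hochberg(p)
        assert (adj >= np.array(p)).all() and (adj <= 1).all()
        assert list(adj) == sorted(adj)


class TestReport:
    def test_report_deterministic(self, model):
        a, _ = simulated_catalog(model, seed=19)
        b, _ = simulated_catalog(model, seed=19)
        ra = build_selection_report(a, model).to_json()
        rb = build_selection_report(b, model).to_json()
        assert ra == rb

    def test_empty_catalog_flagged(self, model):
        catalog = mt.annotate_catalog(
            MutationCatalog(calls_from_records([]), n_samples=3), model
        )
        report = build_selection_report(catalog, model)
        assert "flag" in report.sections
        assert report.sections["summary"]["n_mutations"] == 0

    def test_sections_cover_all_analyses(self, model, tmp_path):
        catalog, _ = simulated_catalog(model, seed=20, mean=30)
        report = build_selection_report(catalog, model)
        for key in (
            "region_proportions",      # functional-unit distribution
            "coding_effects",          # synonymous/nonsynonymous/stopgain
            "spectrum_genome",         # strand-resolved substitution classes
            "heteroplasmy_bins",       # heteroplasmy-level proportions
            "spectrum_mtCTR",          # control vs coding spectra
            "density_mtCTR",
            "heteroplasmy_ctr_vs_cdr_ks",
            "hvs_nonhvs",              # relaxed-selection test
            "dssh_regression",         # replication-gradient fit
            "normalized_complex_density",
            "trna_stem_loop",
            "rrna_vs_ctr_heteroplasmy",
        ):
            assert key in report.sections, key
        report.write(tmp_path)
        assert (tmp_path / "selection_report.json").exists()
        assert (tmp_path / "dssh_per_gene.tsv").exists()
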