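"""Generator contracts: panel LD structure, cohort architecture, GWAS."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pleioscan import (
    CohortData,
    PanelSpec,
    ScenarioSpec,
    compute_gwas,
    simulate_cohort,
    simulate_reference_panel,
    simulate_trait_gwas,
)


class TestReferencePanel:
    def test_same_seed_is_bit_identical(self):
        spec = PanelSpec(n_blocks=3, block_size=5, n_haplotypes=500, seed=42)
        a = simulate_reference_panel(spec)
        b = simulate_reference_panel(spec)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.variants.equals(b.variants)

    def test_zero_correlation_gives_independent_haplotypes(self):
        panel = simulate_reference_panel(
            PanelSpec(
                n_blocks=2,
                block_size=5,
                within_block_correlation=0.0,
                n_haplotypes=10_000,
                seed=1,
            )
        )
        r2 = panel.r2_matrix(list(panel.variants["snp"]))
        off = r2[np.triu_indices_from(r2, k=1)]
        assert off.mean() < 0.02

    def test_two_variant_block_hits_correlation_target(self):
        panel = simulate_reference_panel(
            PanelSpec(
                n_blocks=1,
                block_size=2,
                within_block_correlation=0.9,
                maf_range=(0.3, 0.3),
                n_haplotypes=50_000,
                seed=3,
            )
        )
        h = panel.haplotypes.astype(float)
        r = np.corrcoef(h[:, 0], h[:, 1])[0, 1]
        assert abs(r - 0.9) < 0.05

    def test_empirical_r2_monotone_in_target(self):
        r_values = []
        for target in (0.1, 0.5, 0.8):
            panel = simulate_reference_panel(
                PanelSpec(
                    n_blocks=1,
                    block_size=2,
                    within_block_correlation=target,
                    maf_range=(0.25, 0.25),
                    n_haplotypes=20_000,
                    seed=9,
                )
            )
            h = panel.haplotypes.astype(float)
            r_values.append(np.corrcoef(h[:, 0], h[:, 1])[0, 1])
        assert r_values[0] < r_values[1] < r_values[2]

    def test_cross_block_independence(self):
        panel = simulate_reference_panel(
            PanelSpec(
                n_blocks=2,
                block_size=3,
                within_block_correlation=0.8,
                n_haplotypes=20_000,
                seed=5,
            )
        )
        snps = list(panel.variants["snp"])
        cross = [panel.r2(a, b) for a in snps[:3] for b in snps[3:]]
        assert max(cross) < 0.01

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"block_size": 0},
            {"n_blocks": 0},
            {"n_haplotypes": 0},
            {"within_block_correlation": 1.0},
            {"within_block_correlation": -0.1},
            {"maf_range": (0.0, 0.3)},
            {"maf_range": (0.4, 0.2)},
            {"maf_range": (0.2, 0.6)},
        ],
    )
    def test_degenerate_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PanelSpec(**kwargs)

    def test_variant_annotation_is_valid(self, small_panel):
        v = small_panel.variants
        assert not v["snp"].duplicated().any()
        assert v["a1"].isin(list("ACGT")).all()
        assert v["a2"].isin(list("ACGT")).all()
        assert (v["a1"] != v["a2"]).all()


class TestScenarioSpec:
    def test_causal_model_forbids_direct_effects(self):
        with pytest.raises(ValueError, match="n_direct_lf_causal"):
            ScenarioSpec(model="causal", n_direct_lf_causal=5)

    def test_causal_model_defaults_direct_to_zero(self):
        sc = ScenarioSpec(model="causal")
        assert sc.n_direct_lf_causal == 0
        assert ScenarioSpec(model="independent").n_direct_lf_causal == sc.n_nd_causal

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.2, 1.5])
    def test_copd_threshold_must_be_interior(self, threshold):
        with pytest.raises(ValueError):
            ScenarioSpec(copd_liability_threshold=threshold)

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(n_subjects_per_cohort=0)


class TestSimulateCohort:
    def test_same_seed_is_bit_identical(self, small_panel):
        sc = ScenarioSpec(n_subjects_per_cohort=300, seed=8)
        a = simulate_cohort(small_panel, sc)
        b = simulate_cohort(small_panel, sc)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.phenotypes.equals(b.phenotypes)

    def test_architecture_shared_across_cohort_draws(self, small_panel):
        common = dict(n_subjects_per_cohort=300, architecture_seed=4)
        a = simulate_cohort(small_panel, ScenarioSpec(seed=1, **common))
        b = simulate_cohort(small_panel, ScenarioSpec(seed=2, **common))
        assert a.truth["nd_causal_ids"] == b.truth["nd_causal_ids"]
        assert np.array_equal(a.truth["nd_effects"], b.truth["nd_effects"])
        assert not np.array_equal(a.dosages, b.dosages)

    def test_phenotype_invariants(self, independent_cohort):
        ph = independent_cohort.phenotypes
        never = ph["ever_smoked"] == 0
        assert ph.loc[never, "former_smoker"].isna().all()
        assert (ph.loc[never, "cpd"] == 0).all()
        assert ph.loc[~never, "former_smoker"].isin([0.0, 1.0]).all()
        assert ((ph["ratio"] > 0) & (ph["ratio"] <= 1.5)).all()
        assert (ph["smoking_duration"] >= 0).all()
        assert independent_cohort.dosages.min() >= 0
        assert independent_cohort.dosages.max() <= 2

    def test_copd_prevalence_matches_liability_threshold(self, small_panel):
        sc = ScenarioSpec(
            n_subjects_per_cohort=4000, copd_liability_threshold=0.70, seed=13
        )
        cohort = simulate_cohort(small_panel, sc)
        prevalence = cohort.phenotypes["copd_status"].mean()
        assert abs(prevalence - 0.30) < 0.02

    def test_causal_model_with_zero_gamma_breaks_genotype_lf_path(self, small_panel):
        sc = ScenarioSpec(
            model="causal",
            smoking_effect_on_lf=0.0,
            n_nd_causal=8,
            n_subjects_per_cohort=20_000,
            seed=31,
        )
        cohort = simulate_cohort(small_panel, sc)
        fev1 = cohort.phenotypes["fev1"].to_numpy()
        bound = 3.0 / np.sqrt(cohort.n_subjects)
        for snp in cohort.truth["nd_causal_ids"]:
            r = np.corrcoef(cohort.dosage(snp), fev1)[0, 1]
            assert abs(r) < bound

    def test_independent_model_direct_path_survives_smoking_residualization(
        self, independent_cohort
    ):
        """Partial-correlation oracle: residualizing lung function on the
        smoking phenotypes must NOT remove the dosage association of
        direct-pleiotropy variants."""
        ph = independent_cohort.phenotypes
        X = sm.add_constant(
            ph[["cpd", "smoking_status", "smoking_duration"]].fillna(0.0)
        )
        resid = sm.OLS(ph["fev1"], X).fit().resid.to_numpy()
        bound = 3.0 / np.sqrt(independent_cohort.n_subjects)
        r_values = [
            abs(np.corrcoef(independent_cohort.dosage(snp), resid)[0, 1])
            for snp in independent_cohort.truth["direct_ids"]
        ]
        assert np.mean(r_values) > bound
        assert np.mean(np.asarray(r_values) > bound) >= 0.8

    def test_panel_smaller_than_causal_count_rejected(self, small_panel):
        with pytest.raises(ValueError, match="fewer variants"):
            simulate_cohort(
                small_panel,
                ScenarioSpec(n_nd_causal=small_panel.n_variants + 1),
            )


def _manual_cohort(n=200, seed=0):
    rng = np.random.default_rng(seed)
    dosages = np.column_stack(
        [
            rng.integers(0, 3, n).astype(float),
            np.full(n, 2.0),  # monomorphic
        ]
    )
    variants = pd.DataFrame(
        {
            "snp": ["rs1", "rs2"],
            "chr": "1",
            "bp": [100, 200],
            "a1": ["A", "C"],
            "a2": ["G", "T"],
        }
    )
    pheno = pd.DataFrame(
        {
            "y": rng.standard_normal(n),
            "constant_trait": np.ones(n),
            "age": rng.uniform(40, 80, n),
            "ever_smoked": np.ones(n),
        }
    )
    return CohortData(dosages, ["rs1", "rs2"], variants, pheno)


class TestComputeGwas:
    def test_monomorphic_variant_flagged_not_dropped(self):
        stats = compute_gwas(_manual_cohort(), "y")
        assert len(stats) == 2
        row = stats.df.set_index("snp").loc["rs2"]
        assert row["status"] == "monomorphic"
        assert np.isnan(row["beta"]) and np.isnan(row["p"])
        assert stats.df.set_index("snp").loc["rs1", "status"] == "ok"

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            compute_gwas(_manual_cohort(), "constant_trait")

    def test_unknown_trait_or_covariate(self):
        with pytest.raises(KeyError):
            compute_gwas(_manual_cohort(), "nope")
        with pytest.raises(KeyError):
            compute_gwas(_manual_cohort(), "y", ["nope"])

    def test_null_variants_give_uniform_p(self):
        """Type-I calibration: with no causal effects the p-value
        distribution across thousands of independent variants is uniform."""
        panel = simulate_reference_panel(
            PanelSpec(
                n_blocks=3000,
                block_size=1,
                within_block_correlation=0.0,
                n_haplotypes=600,
                seed=17,
            )
        )
        stats = simulate_trait_gwas(panel, {}, n_subjects=5000, seed=18)
        frac = (stats.df["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.01

    def test_beta_recovery_is_unbiased(self):
        """Parameter recovery: mean estimated slope over replicates matches
        the simulated per-allele effect of 0.3 on a unit-variance trait."""
        panel = simulate_reference_panel(
            PanelSpec(
                n_blocks=2,
                block_size=1,
                maf_range=(0.3, 0.3),
                n_haplotypes=2000,
                seed=19,
            )
        )
        betas = [
            simulate_trait_gwas(panel, {"rs1": 0.3}, 10_000, seed=100 + rep)
            .df.set_index("snp")
            .loc["rs1", "beta"]
            for rep in range(200)
        ]
        assert abs(np.mean(betas) - 0.3) < 0.02

    def test_binary_trait_matches_statsmodels_logit(self, independent_cohort):
        stats = compute_gwas(independent_cohort, "copd_status", ["age", "sex"])
        snp = stats.df.loc[stats.df["status"] == "ok", "snp"].iloc[0]
        ph = independent_cohort.phenotypes
        X = np.column_stack(
            [
                np.ones(len(ph)),
                ph["age"],
                ph["sex"],
                independent_cohort.dosage(snp),
            ]
        )
        fit = sm.Logit(ph["copd_status"].to_numpy(), X).fit(disp=0)
        row = stats.df.set_index("snp").loc[snp]
        assert row["beta"] == pytest.approx(fit.params[-1], abs=1e-5)
        assert row["se"] == pytest.approx(fit.bse[-1], rel=1e-4)

    def test_smoker_only_traits_restrict_sample(self, independent_cohort):
        stats = compute_gwas(independent_cohort, "cpd")
        n_smokers = int((independent_cohort.phenotypes["ever_smoked"] == 1).sum())
        assert (stats.df["n"] == n_smokers).all()

    def test_causal_variant_attenuates_under_smoking_adjustment(self, small_panel):
        """Causal-model single-variant check: adjusting for the smoking
        phenotypes shrinks the lung-function effect of an ND-causal
        variant."""
        cohort = simulate_cohort(
            small_panel,
            ScenarioSpec(model="causal", n_subjects_per_cohort=20_000, seed=33),
        )
        crude = compute_gwas(cohort, "fev1")
        adjusted = compute_gwas(
            cohort, "fev1", ["cpd", "smoking_status", "smoking_duration"]
        )
        snp = cohort.truth["nd_causal_ids"][0]
        b_crude = crude.df.set_index("snp").loc[snp, "beta"]
        b_adj = adjusted.df.set_index("snp").loc[snp, "beta"]
        assert abs(b_adj) < abs(b_crude)
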