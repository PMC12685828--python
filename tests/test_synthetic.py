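import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from micronet.diversity import alpha_diversity
from micronet.exceptions import DesignError, ValidationError
from micronet.synthetic import (
    CommunityDesign,
    DifferentialSpec,
    ModuleSpec,
    copula_spearman,
    null_design,
    paper_design,
    planted_diversity_offset,
    simulate_dataset,
    test_scale_design,
)


def bare_design(**overrides):
    """A small effect-free design that individual tests specialise."""
    base = dict(
        n_taxa={"bacterial": 60, "eukaryotic": 20},
        depth=2_000,
        n_blocks=3,
        theta=0.0,
        richness_multiplier={"bacterial": {}, "eukaryotic": {}},
        differential={
            "bacterial": DifferentialSpec(n=0),
            "eukaryotic": DifferentialSpec(n=0),
        },
        modules={"bacterial": [], "eukaryotic": []},
        env_links={},
    )
    base.update(overrides)
    return CommunityDesign(**base)


class TestDeterminismAndShape:
    def test_same_seed_identical_tables(self):
        a = simulate_dataset(paper_design(), seed=1)
        b = simulate_dataset(paper_design(), seed=1)
        for domain in ("bacterial", "eukaryotic"):
            np.testing.assert_array_equal(
                a.feature_tables[domain].counts,
                b.feature_tables[domain].counts,
            )
        assert a.soil.equals(b.soil)
        assert a.truth.differential.equals(b.truth.differential)

    def test_column_sums_equal_depth(self):
        sim = simulate_dataset(test_scale_design(), seed=2)
        for domain, table in sim.feature_tables.items():
            assert (table.counts.sum(axis=0) == sim.design.depth).all()

    def test_paper_design_shape(self):
        sim = simulate_dataset(paper_design(), seed=3)
        assert sim.feature_tables["bacterial"].shape == (600, 18)
        assert sim.feature_tables["eukaryotic"].shape == (150, 18)
        assert sim.metadata["group"].value_counts().eq(3).all()
        assert list(sim.soil.columns)[:3] == ["TP", "TN", "AP"]

    def test_truth_taxa_exist(self):
        sim = simulate_dataset(test_scale_design(), seed=4)
        for domain, table in sim.feature_tables.items():
            ids = set(table.taxon_ids)
            truth = sim.truth.differential.query("domain == @domain")
            assert set(truth["taxon_id"]) <= ids
            for module in sim.truth.modules:
                if module.domain == domain:
                    assert set(module.taxon_ids) <= ids


class TestDesignValidation:
    def test_oversized_modules_rejected(self):
        design = bare_design(
            modules={"bacterial": [ModuleSpec(100, 0.5)],
                     "eukaryotic": []},
        )
        with pytest.raises(DesignError):
            simulate_dataset(design, seed=0)

    def test_shallow_depth_rejected(self):
        with pytest.raises(DesignError):
            simulate_dataset(bare_design(depth=100), seed=0)

    def test_bad_rho_rejected(self):
        design = bare_design(
            modules={"bacterial": [ModuleSpec(5, 1.0)], "eukaryotic": []},
        )
        with pytest.raises(DesignError):
            simulate_dataset(design, seed=0)


class TestCopulaCorrelation:
    def test_module_latent_spearman_matches_implied(self):
        """(6/pi) arcsin(rho/2) for a Gaussian copula at rho = 0.9,
        measured over ~200 samples."""
        design = bare_design(
            n_blocks=34,  # 204 samples
            modules={"bacterial": [ModuleSpec(10, 0.9, None)],
                     "eukaryotic": []},
        )
        sim = simulate_dataset(design, seed=3)
        module = sim.truth.modules[0]
        table = sim.feature_tables["bacterial"]
        idx = [table.taxon_ids.index(t) for t in module.taxon_ids]
        rho, _ = spearmanr(sim.latents["bacterial"][idx], axis=1)
        iu = np.triu_indices(len(idx), k=1)
        mean_rho = rho[iu].mean()
        assert mean_rho == pytest.approx(copula_spearman(0.9), abs=0.05)

    def test_negative_sign_mix(self):
        design = bare_design(
            n_blocks=20,
            modules={
                "bacterial": [ModuleSpec(8, 0.8, None, frac_negative=0.5)],
                "eukaryotic": [],
            },
        )
        sim = simulate_dataset(design, seed=5)
        module = sim.truth.modules[0]
        assert (module.signs == -1).sum() == 4
        table = sim.feature_tables["bacterial"]
        idx = [table.taxon_ids.index(t) for t in module.taxon_ids]
        rho, _ = spearmanr(sim.latents["bacterial"][idx], axis=1)
        signs = np.outer(module.signs, module.signs)
        iu = np.triu_indices(len(idx), k=1)
        assert np.all(np.sign(rho[iu]) == signs[iu])


class TestOverdispersion:
    def test_theta_zero_matches_multinomial_variance(self):
        """With theta -> 0 and no modules, per-taxon count variance over
        replicate draws matches the multinomial law."""
        rng = np.random.default_rng(0)
        depth, p = 5000, np.array([0.5, 0.3, 0.15, 0.05])
        draws = np.array(
            [np.random.default_rng(s).multinomial(depth, p)
             for s in range(2000)]
        )
        expected_var = depth * p * (1 - p)
        np.testing.assert_allclose(
            draws.var(axis=0), expected_var, rtol=0.15
        )

    def test_theta_inflates_variance(self):
        """The Dirichlet stage adds variance beyond multinomial."""
        def replicate_variance(theta, seed):
            # keep the latent noise small so the count-level dispersion
            # channel dominates
            design = bare_design(
                n_taxa={"bacterial": 20, "eukaryotic": 20},
                n_blocks=30, theta=theta,
                sigma_log=0.5, noise_sigma=0.1,
            )
            sim = simulate_dataset(design, seed=seed)
            counts = sim.feature_tables["bacterial"].counts
            return counts.var(axis=1).mean()

        assert replicate_variance(0.02, 11) > 2 * replicate_variance(0.0, 11)


class TestDiversityOffset:
    def test_zero_effect(self):
        assert planted_diversity_offset(null_design(), "SW") == 0.0

    def test_doubling_gives_ln2(self):
        assert planted_diversity_offset(
            paper_design(), "SW", "bacterial"
        ) == pytest.approx(math.log(2))
        assert planted_diversity_offset(
            paper_design(), "RSW", "bacterial"
        ) == pytest.approx(math.log(2))
        assert planted_diversity_offset(
            paper_design(), "W", "bacterial"
        ) == 0.0

    def test_unknown_group(self):
        with pytest.raises(ValidationError):
            planted_diversity_offset(paper_design(), "X")

    def test_realized_shift_matches_analytic(self):
        """Finite-depth Shannon shift within 10% of ln(2) at depth
        30,000, averaged over 100 replicate datasets."""
        design = bare_design(
            n_taxa={"bacterial": 250, "eukaryotic": 20},
            depth=30_000,
            n_blocks=1,
            sigma_log=1.0,
            noise_sigma=0.5,
            active_fraction=0.4,
            richness_multiplier={"bacterial": {"SW": 2.0},
                                 "eukaryotic": {}},
        )
        target = planted_diversity_offset(design, "SW", "bacterial")
        shifts = []
        for seed in range(100):
            sim = simulate_dataset(design, seed=seed)
            alpha = alpha_diversity(sim.feature_tables["bacterial"])
            meta = sim.metadata
            boosted = alpha.loc[meta.index[meta["treatment"] == "SW"],
                                "shannon"].mean()
            baseline = alpha.loc[meta.index[meta["treatment"] != "SW"],
                                 "shannon"].mean()
            shifts.append(boosted - baseline)
        assert np.mean(shifts) == pytest.approx(target, rel=0.10)


class TestNullCalibration:
    def test_permanova_on_null_design_rejects_at_nominal_rate(self):
        """A design with zero effects and zero modules yields
        exchangeable samples: PERMANOVA rejects at ~5% over 200
        replicate datasets."""
        from micronet.diversity import bray_curtis, permanova

        rejections = 0
        n_rep = 200
        design = bare_design(
            n_taxa={"bacterial": 60, "eukaryotic": 20}, n_blocks=2
        )
        for seed in range(n_rep):
            sim = simulate_dataset(design, seed=seed)
            table = sim.feature_tables["bacterial"]
            dm = bray_curtis(table)
            labels = list(sim.metadata.loc[table.sample_ids, "treatment"])
            res = permanova(dm, labels, n_permutations=99,
                            seed=1_000_000 + seed)
            rejections += res.p_value <= 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 3.3 * se


class TestSoilLinks:
    def test_linked_variables_track_gradients(self):
        design = CommunityDesign(
            n_taxa={"bacterial": 200, "eukaryotic": 120},
            depth=5_000,
            n_blocks=10,
            theta=0.0,
        )
        sim = simulate_dataset(design, seed=13)
        latent = sim.latents["bacterial"]
        centered = (latent - latent.mean(axis=1, keepdims=True)).T
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        g1 = u[:, 0]
        r_tp = abs(np.corrcoef(sim.soil["TP"], g1)[0, 1])
        r_tn = abs(np.corrcoef(sim.soil["TN"], g1)[0, 1])
        assert r_tp > 0.6
        assert r_tp > r_tn  # TN is a pure-noise control
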