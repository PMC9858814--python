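"""Phantom geometry, kinetic curves, NB expression and cohort planting."""

import numpy as np
import pandas as pd
import pytest

from radigen.enrichment import size_factors
from radigen.features import extract_shape
from radigen.synthetic import (
    ExpressionConfig,
    KineticParams,
    PhantomConfig,
    SyntheticTruth,
    cohort_manifest,
    enhancement_curve,
    make_tumor_mask,
    plant_cohort,
    simulate_association_cohort,
    simulate_dce,
    simulate_expression,
)


class TestConfigValidation:
    def test_radius_too_large_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            PhantomConfig(grid_shape=(32, 32, 32), tumor_radius_range=(8, 16))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ExpressionConfig(n_genes=100, n_sets=10, set_size_range=(5, 20))

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError, match="min <= max"):
            PhantomConfig(washout_range=(0.5, 0.1))


class TestTumorMask:
    CFG = PhantomConfig(n_patients=3, grid_shape=(48, 48, 48), lobulation=0.0, seed=2)

    def test_sphere_volume_within_5pct(self):
        mask, desc = make_tumor_mask(self.CFG, 0, semi_axes_mm=(10, 10, 10))
        true_v = 4 / 3 * np.pi * 10**3
        assert abs(desc["voxel_count"] - true_v) / true_v < 0.05

    def test_deterministic(self):
        a, _ = make_tumor_mask(self.CFG, 1)
        b, _ = make_tumor_mask(self.CFG, 1)
        np.testing.assert_array_equal(a, b)

    def test_lobulation_increases_surface_to_volume(self):
        smooth_cfg = PhantomConfig(
            n_patients=1, grid_shape=(48, 48, 48), lobulation=0.0, seed=3
        )
        rough_cfg = PhantomConfig(
            n_patients=1, grid_shape=(48, 48, 48), lobulation=2.0, seed=3
        )
        axes = (11.0, 11.0, 11.0)
        m0, _ = make_tumor_mask(smooth_cfg, 0, semi_axes_mm=axes)
        m2, _ = make_tumor_mask(rough_cfg, 0, semi_axes_mm=axes)
        s0 = extract_shape(m0)
        s2 = extract_shape(m2)
        assert s2["SurfaceVolumeRatio"] > s0["SurfaceVolumeRatio"]

    def test_mask_single_component_with_margin(self):
        cfg = PhantomConfig(n_patients=5, grid_shape=(40, 40, 40),
                            tumor_radius_range=(6, 12), lobulation=1.5, seed=9)
        from scipy import ndimage

        for i in range(5):
            mask, _ = make_tumor_mask(cfg, i)
            _, n = ndimage.label(mask, ndimage.generate_binary_structure(3, 1))
            assert n == 1
            assert not mask[0].any() and not mask[-1].any()

    def test_grid_too_small_names_patient(self):
        cfg = PhantomConfig(n_patients=1, grid_shape=(26, 26, 26),
                            tumor_radius_range=(11.5, 12.4), lobulation=0.0, seed=1)
        with pytest.raises(ValueError, match="patient 0"):
            make_tumor_mask(cfg, 0, semi_axes_mm=(13.0, 13.0, 13.0))


class TestSimulateDce:
    CFG = PhantomConfig(n_patients=1, grid_shape=(32, 32, 32),
                        tumor_radius_range=(6, 8), noise_sd=0.0, seed=4)
    MASK, _ = make_tumor_mask(
        PhantomConfig(n_patients=1, grid_shape=(32, 32, 32),
                      tumor_radius_range=(6, 8), lobulation=0.0, seed=4),
        0, semi_axes_mm=(7, 7, 7),
    )

    def test_instant_washin_no_washout_plateau(self):
        kin = KineticParams(washin=1e9, washout=0.0, heterogeneity=0.0, amplitude=1.5)
        series = simulate_dce(self.MASK, kin, self.CFG)
        pre = series.volumes["pre"]
        for label in ("early", "middle", "late"):
            np.testing.assert_allclose(
                series.volumes[label][self.MASK], pre[self.MASK] * 2.5, rtol=1e-9
            )

    def test_curve_matches_closed_form_at_timepoints(self):
        kin = KineticParams(washin=2.0, washout=0.4, heterogeneity=0.0, amplitude=1.2)
        series = simulate_dce(self.MASK, kin, self.CFG)
        pre = series.volumes["pre"]
        for label, t in (("early", 1.0), ("middle", 3.0), ("late", 5.0)):
            expected = pre[self.MASK] * (1.0 + enhancement_curve(t, 1.2, 2.0, 0.4))
            np.testing.assert_allclose(series.volumes[label][self.MASK], expected, rtol=1e-9)
        # strong washout relative to washin: late mean below early mean
        assert (
            series.volumes["late"][self.MASK].mean()
            < series.volumes["early"][self.MASK].mean()
        )

    def test_zero_heterogeneity_constant_within_tumor(self):
        kin = KineticParams(washin=3.0, washout=0.1, heterogeneity=0.0)
        series = simulate_dce(self.MASK, kin, self.CFG)
        for label in ("early", "middle", "late"):
            assert series.volumes[label][self.MASK].var() == pytest.approx(0.0, abs=1e-18)

    def test_nonfinite_kinetics_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            simulate_dce(self.MASK, KineticParams(np.nan, 0.1, 0.1), self.CFG)


class TestSimulateExpression:
    @staticmethod
    def _truth(n=200, n_sets=5, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"P{i:03d}" for i in range(n)]
        activity = pd.DataFrame(
            rng.standard_normal((n, n_sets)),
            index=ids, columns=[f"SET{i:02d}" for i in range(n_sets)],
        )
        latents = pd.DataFrame(rng.standard_normal((n, 1)), index=ids, columns=["size"])
        return SyntheticTruth(latents, activity, [])

    def test_zero_effect_uncorrelated(self):
        truth = self._truth()
        cfg = ExpressionConfig(n_genes=500, n_sets=5, effect_size=0.0, seed=1)
        counts, sets = simulate_expression(truth, cfg)
        member = counts.loc[sets["SET00"]]
        mean_log = np.log1p(member).mean(axis=0)
        r = np.corrcoef(mean_log, truth.pathway_activity["SET00"])[0, 1]
        assert abs(r) < 0.1

    def test_unit_effect_strongly_correlated(self):
        truth = self._truth(seed=2)
        cfg = ExpressionConfig(n_genes=500, n_sets=5, effect_size=1.0, seed=2)
        counts, sets = simulate_expression(truth, cfg)
        member = counts.loc[sets["SET00"]]
        mean_log = np.log1p(member).mean(axis=0)
        r = np.corrcoef(mean_log, truth.pathway_activity["SET00"])[0, 1]
        assert r > 0.8

    def test_doubled_library_doubles_size_factors(self):
        truth = self._truth(n=30, seed=3)
        cfg = ExpressionConfig(n_genes=400, n_sets=5, seed=3,
                               library_size_range=(1.0, 1.0))
        counts, _ = simulate_expression(truth, cfg)
        cfg2 = ExpressionConfig(n_genes=400, n_sets=5, seed=3,
                                library_size_range=(2.0, 2.0))
        counts2, _ = simulate_expression(truth, cfg2)
        f1 = size_factors(pd.concat([counts, counts.iloc[:, :1]], axis=1).iloc[:, :-1])
        # factors are relative within a matrix; compare via a mixed matrix
        mixed = pd.concat(
            [counts.add_suffix("_a"), counts2.add_suffix("_b")], axis=1
        )
        f = size_factors(mixed)
        ratio = f[[c for c in f.index if c.endswith("_b")]].median() / f[
            [c for c in f.index if c.endswith("_a")]
        ].median()
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_counts_nonnegative_integers(self):
        truth = self._truth(n=20, seed=4)
        counts, _ = simulate_expression(
            truth, ExpressionConfig(n_genes=300, n_sets=5, seed=4)
        )
        X = counts.to_numpy()
        assert (X >= 0).all() and np.issubdtype(X.dtype, np.integer)

    def test_nb_dispersion_recovered(self):
        # method-of-moments on a null 10k-gene simulation
        truth = self._truth(n=100, seed=5)
        cfg = ExpressionConfig(n_genes=10000, n_sets=5, effect_size=0.0,
                               nb_dispersion=0.2, seed=5,
                               library_size_range=(1.0, 1.0))
        counts, _ = simulate_expression(truth, cfg)
        X = counts.to_numpy(dtype=float)
        mu = X.mean(axis=1)
        var = X.var(axis=1, ddof=1)
        ok = mu > 5
        alpha = np.median((var[ok] - mu[ok]) / mu[ok] ** 2)
        assert alpha == pytest.approx(0.2, rel=0.15)


class TestPlantCohort:
    def test_unknown_names_rejected(self):
        pcfg = PhantomConfig(n_patients=2, grid_shape=(32, 32, 32),
                             tumor_radius_range=(5, 8), seed=1)
        ecfg = ExpressionConfig(n_genes=200, n_sets=2, set_size_range=(5, 10), seed=1)
        with pytest.raises(ValueError, match="unknown latent"):
            plant_cohort(pcfg, ecfg, [("nope", "SET00", 0.5)])
        with pytest.raises(ValueError, match="unknown gene set"):
            plant_cohort(pcfg, ecfg, [("washout", "SET99", 0.5)])

    def test_planted_correlation_exact_in_latent_space(self):
        feats, counts, sets, truth = simulate_association_cohort(
            n_patients=400, n_features=4,
            expr_cfg=ExpressionConfig(n_genes=200, n_sets=3, set_size_range=(5, 10), seed=6),
            planted_pairs=[("feat01", "SET02", 0.5)], seed=6,
        )
        r = np.corrcoef(
            truth.latent_phenotypes["feat01"], truth.pathway_activity["SET02"]
        )[0, 1]
        assert r == pytest.approx(0.5, abs=0.1)
        # unplanted set independent of all latents
        for f in truth.latent_phenotypes:
            r0 = np.corrcoef(
                truth.latent_phenotypes[f], truth.pathway_activity["SET00"]
            )[0, 1]
            assert abs(r0) < 0.15

    def test_manifest_byte_identical_across_runs(self):
        pcfg = PhantomConfig(n_patients=2, grid_shape=(32, 32, 32),
                             tumor_radius_range=(5, 8), seed=7)
        ecfg = ExpressionConfig(n_genes=200, n_sets=2, set_size_range=(5, 10), seed=7)
        outs = []
        for _ in range(2):
            _, _, _, _, truth = plant_cohort(pcfg, ecfg, [("washout", "SET01", 0.4)])
            outs.append(cohort_manifest(pcfg, ecfg, truth, {"counts": "counts.tsv"}))
        assert outs[0] == outs[1]
        assert "washout" in outs[0]
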