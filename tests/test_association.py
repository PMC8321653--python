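import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import fragilexpress as fx
from fragilexpress.association import results_to_frame


def _panel_from(values, n_normals):
    """Wrap a genes x samples array; the last n_normals columns are the
    normal reference."""
    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    tumours = [f"T{i}" for i in range(n_samples - n_normals)]
    normals = [f"N{i}" for i in range(n_normals)]
    meta = pd.DataFrame(
        {
            "tumour_type": ["X"] * n_samples,
            "is_tumour": [True] * len(tumours) + [False] * n_normals,
            "purity": [0.8] * len(tumours) + [np.nan] * n_normals,
        },
        index=tumours + normals,
    )
    return fx.ExpressionPanel(
        values=pd.DataFrame(values, index=genes, columns=tumours + normals),
        metadata=meta,
        protein_coding=pd.Series(True, index=genes),
    )


class TestZScore:
    def test_hand_computed_example(self):
        # normals {1, 3}: mean 2, SD (ddof=1) sqrt(2); tumour 4 -> z = sqrt(2)
        panel = _panel_from(np.array([[4.0, 1.0, 3.0]]), n_normals=2)
        zp = fx.zscore_vs_normal(panel, "X", log_transform=False)
        assert zp.z.loc["g0", "T0"] == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_tumour_at_normal_mean_scores_zero(self):
        panel = _panel_from(np.array([[2.0, 1.0, 3.0]]), n_normals=2)
        zp = fx.zscore_vs_normal(panel, "X", log_transform=False)
        assert zp.z.loc["g0", "T0"] == pytest.approx(0.0, abs=1e-15)

    def test_normals_self_score_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        panel = _panel_from(rng.uniform(1, 100, size=(20, 40)), n_normals=15)
        zp = fx.zscore_vs_normal(panel, "X", include_normals=True)
        znorm = zp.z[panel.normal_samples("X")]
        assert np.all(np.abs(znorm.mean(axis=1)) < 1e-12)
        assert np.all(np.abs(znorm.std(axis=1, ddof=1) - 1) < 1e-12)

    def test_constant_gene_dropped_and_reported(self):
        values = np.array([[4.0, 1.0, 3.0], [9.0, 2.0, 2.0]])
        panel = _panel_from(values, n_normals=2)
        zp = fx.zscore_vs_normal(panel, "X", log_transform=False)
        assert zp.dropped_genes == ["g1"]
        assert "g1" not in zp.z.index

    def test_fewer_than_two_normals_rejected(self):
        panel = _panel_from(np.array([[4.0, 1.0]]), n_normals=1)
        with pytest.raises(ValueError, match="normal"):
            fx.zscore_vs_normal(panel, "X")


def _make_zpanel(z_values, samples):
    return fx.ZScorePanel(
        z=pd.DataFrame(z_values, index=[f"g{i}" for i in range(len(z_values))],
                       columns=samples),
        reference=pd.DataFrame(),
        tumour_type="X",
        log_transformed=True,
        dropped_genes=[],
    )


def _simulate_design(rng, n=200, beta_del=0.0, beta_pur=0.5, noise_sd=1.0):
    deleted = rng.random(n) < 0.4
    purity = rng.beta(6, 2, size=n)
    y = beta_del * deleted + beta_pur * purity + rng.normal(0, noise_sd, n)
    return deleted, purity, y


class TestRobustAssociation:
    def test_matches_ols_on_clean_gaussian_data(self):
        # biweight has 95% Gaussian efficiency, so on outlier-free data it
        # tracks OLS; absolute agreement scales with the residual noise
        rng = np.random.default_rng(1)
        deleted, purity, y = _simulate_design(rng, beta_del=0.7, noise_sd=0.05)
        samples = [f"s{i}" for i in range(len(y))]
        zp = _make_zpanel(y[None, :], samples)
        (res,) = fx.robust_association(
            zp, dict(zip(samples, deleted)), dict(zip(samples, purity)), "R"
        )
        X = sm.add_constant(np.column_stack([deleted.astype(float), purity]))
        ols = sm.OLS(y, X).fit()
        assert res.beta_deletion == pytest.approx(ols.params[1], abs=1e-3)

    def test_robust_resists_gross_outliers_better_than_ols(self):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            deleted, purity, y = _simulate_design(rng, beta_del=0.5)
            # 10% gross outliers in the wild-type group, z inflated x10
            wt = np.flatnonzero(~deleted)
            bad = rng.choice(wt, size=len(y) // 10, replace=False)
            y = y.copy()
            y[bad] *= 10
            samples = [f"s{i}" for i in range(len(y))]
            zp = _make_zpanel(y[None, :], samples)
            (res,) = fx.robust_association(
                zp, dict(zip(samples, deleted)), dict(zip(samples, purity)), "R"
            )
            X = sm.add_constant(np.column_stack([deleted.astype(float), purity]))
            ols = sm.OLS(y, X).fit()
            if abs(res.beta_deletion - 0.5) < abs(ols.params[1] - 0.5):
                wins += 1
        assert wins >= 0.75 * n_seeds

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        deleted, purity, y = _simulate_design(rng)
        samples = [f"s{i}" for i in range(len(y))]
        zp = _make_zpanel(y[None, :], samples)
        status = dict(zip(samples, deleted))
        pur = dict(zip(samples, purity))
        (a,) = fx.robust_association(zp, status, pur, "R")
        perm = rng.permutation(len(samples))
        zp2 = _make_zpanel(y[None, perm], [samples[i] for i in perm])
        (b,) = fx.robust_association(zp2, status, pur, "R")
        assert a.beta_deletion == pytest.approx(b.beta_deletion, rel=1e-9)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_indicator_relabelling_flips_beta_keeps_p(self):
        rng = np.random.default_rng(4)
        deleted, purity, y = _simulate_design(rng, beta_del=0.8)
        samples = [f"s{i}" for i in range(len(y))]
        zp = _make_zpanel(y[None, :], samples)
        pur = dict(zip(samples, purity))
        (a,) = fx.robust_association(zp, dict(zip(samples, deleted)), pur, "R")
        flipped = dict(zip(samples, ~deleted))
        (b,) = fx.robust_association(zp, flipped, pur, "R")
        assert a.beta_deletion == pytest.approx(-b.beta_deletion, rel=1e-6)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-6)

    def test_degenerate_design_flagged_untestable(self):
        samples = [f"s{i}" for i in range(10)]
        zp = _make_zpanel(np.random.default_rng(0).normal(size=(1, 10)), samples)
        status = {s: True for s in samples}  # every sample deleted
        purity = {s: 0.8 for s in samples}
        (res,) = fx.robust_association(zp, status, purity, "R")
        assert not res.testable and math.isnan(res.p_value)

    def test_missing_purity_samples_dropped(self):
        rng = np.random.default_rng(5)
        deleted, purity, y = _simulate_design(rng)
        samples = [f"s{i}" for i in range(len(y))]
        pur = dict(zip(samples, purity))
        for s in samples[:10]:
            pur[s] = float("nan")
        zp = _make_zpanel(y[None, :], samples)
        (res,) = fx.robust_association(zp, dict(zip(samples, deleted)), pur, "R")
        assert res.n_deleted + res.n_wild_type == len(samples) - 10


class TestCorrectAndFilter:
    def _result(self, gene, p, beta=1.0):
        return fx.AssociationResult(
            gene=gene, region_name="R", tumour_type="X",
            beta_deletion=beta, beta_purity=0.0, se=0.1,
            p_value=p, p_adjusted=float("nan"),
            n_deleted=10, n_wild_type=10, direction="none",
        )

    def test_bonferroni_arithmetic(self):
        results = [self._result(f"g{i}", 0.5) for i in range(9)]
        results.append(self._result("hit", 0.0005))
        adjusted, significant, m = fx.correct_and_filter(
            results, {r.gene: True for r in results}, alpha=0.01
        )
        assert m == 10
        by_gene = {r.gene: r for r in adjusted}
        assert by_gene["hit"].p_adjusted == pytest.approx(0.005)
        assert by_gene["hit"].direction == "up"
        assert [r.gene for r in significant] == ["hit"]

    def test_adjusted_p_capped_at_one_and_never_below_raw(self):
        results = [self._result(f"g{i}", 0.5) for i in range(10)]
        adjusted, _, _ = fx.correct_and_filter(results, {})
        assert all(r.p_adjusted == 1.0 for r in adjusted)
        assert all(r.p_adjusted >= r.p_value for r in adjusted)

    def test_non_protein_coding_gene_excluded_despite_tiny_p(self):
        results = [self._result("pseudo", 1e-9), self._result("coding", 1e-9)]
        _, significant, _ = fx.correct_and_filter(
            results, {"pseudo": False, "coding": True}
        )
        assert [r.gene for r in significant] == ["coding"]

    def test_significant_count_non_increasing_in_family_size(self):
        results = [self._result(f"g{i}", 0.002) for i in range(4)]
        flags = {r.gene: True for r in results}
        counts = [
            len(fx.correct_and_filter(results, flags, family_size=m)[1])
            for m in (1, 4, 10, 100)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_down_direction_from_negative_beta(self):
        results = [self._result("g", 1e-6, beta=-2.0)]
        _, significant, _ = fx.correct_and_filter(results, {"g": True})
        assert significant[0].direction == "down"


class TestExonContrast:
    def test_identical_groups_give_near_zero_differences(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 1))
        values = pd.DataFrame(
            np.repeat(base, 8, axis=1),
            index=[f"e{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(8)],
        )
        labels = {f"s{i}": "three_prime_deleted" if i < 4 else "wild_type"
                  for i in range(8)}
        contrast = fx.exon_contrast(values, labels, n_boot=50, seed=0)
        assert np.allclose(contrast.difference, 0.0)

    def test_recovers_planted_breakpoint_signs(self, annotation):
        matches = []
        for seed in range(10):
            values, labels, truth = fx.simulate_exon_profile(
                annotation["exons"], deleted_block=(5, 7), shift=1.0,
                seed=seed,
            )
            contrast = fx.exon_contrast(values, labels, n_boot=50, seed=seed)
            signs = {
                name: "up" if d > 0 else "down"
                for name, d in zip(contrast.exon_names, contrast.difference)
            }
            matches.append(
                sum(signs[n] == truth[n] for n in signs)
            )
        assert all(m >= 9 for m in matches)

    def test_single_sample_groups_flagged_degenerate(self):
        values = pd.DataFrame(
            [[1.0, 2.0]], index=["e0"], columns=["a", "b"]
        )
        labels = {"a": "three_prime_deleted", "b": "wild_type"}
        contrast = fx.exon_contrast(values, labels, n_boot=10, seed=0)
        assert contrast.degenerate_band
        assert contrast.difference[0] == pytest.approx(-1.0)

    def test_empty_group_rejected(self):
        values = pd.DataFrame([[1.0]], index=["e0"], columns=["a"])
        with pytest.raises(ValueError, match="non-empty"):
            fx.exon_contrast(values, {"a": "wild_type"})


def test_results_frame_has_association_fields():
    r = fx.AssociationResult(
        gene="g", region_name="R", tumour_type="X", beta_deletion=1.0,
        beta_purity=0.1, se=0.2, p_value=0.01, p_adjusted=0.1,
        n_deleted=5, n_wild_type=7, direction="none",
    )
    frame = results_to_frame([r])
    assert {"gene", "beta_deletion", "p_adjusted", "direction"} <= set(frame)
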