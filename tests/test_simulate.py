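import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fragilexpress as fx
from fragilexpress import io as fio


def _cohort(seed=0, **kwargs):
    ann = fx.default_annotation()
    cfg = fx.default_config(seed=seed)
    for k, v in kwargs.items():
        setattr(cfg, k, v)
    return ann, cfg, fx.simulate_cohort(cfg, ann["sites"], ann["genes"])


def test_identical_seed_gives_bit_identical_cohort():
    _, _, (seg_a, panel_a, truth_a) = _cohort(seed=5)
    _, _, (seg_b, panel_b, truth_b) = _cohort(seed=5)
    assert seg_a == seg_b
    pd.testing.assert_frame_equal(panel_a.values, panel_b.values)
    pd.testing.assert_frame_equal(truth_a.deleted, truth_b.deleted)


def test_deleted_count_binomially_plausible():
    _, _, (_, _, truth) = _cohort(
        seed=1, n_tumours=100, deletion_prevalence=0.5
    )
    n_deleted = int(truth.deleted["FRA4F"].sum())
    assert 30 <= n_deleted <= 70


def test_zero_effect_sizes_plant_no_direction():
    ann = fx.default_annotation()
    cfg = fx.CohortConfig(seed=0, effect_sizes={("CCSER1", "FRA4F"): 0.0})
    _, _, truth = fx.simulate_cohort(cfg, ann["sites"], ann["genes"])
    assert set(truth.direction.values()) == {"none"}


def test_deleted_samples_carry_qualifying_segment_over_site():
    ann, _, (segments, panel, truth) = _cohort(seed=2)
    site = ann["sites"]["FRA4F"]
    filtered = fx.filter_segments(segments)
    samples_with_loss = {
        s.sample_id for s in filtered if s.interval.overlaps(site)
    }
    deleted = set(truth.deleted.index[truth.deleted["FRA4F"]])
    assert deleted == samples_with_loss
    lo, hi = -1.0, -0.3
    for s in filtered:
        assert lo <= s.seg_mean <= hi


def test_planted_z_shift_recovered_at_full_purity():
    """With purity pinned at ~1, the mean z difference between deleted and
    wild-type tumours matches the planted shift of +1.5 within 3 SE."""
    diffs = []
    for seed in range(20):
        ann = fx.default_annotation()
        cfg = fx.default_config(seed=seed, z_shift=1.5)
        cfg.purity_alpha, cfg.purity_beta = 1e6, 1e-3  # purity ~ 1
        _, panel, truth = fx.simulate_cohort(cfg, ann["sites"], ann["genes"])
        zp = fx.zscore_vs_normal(panel, "COAD")
        deleted = truth.deleted["FRA4F"]
        z = zp.z.loc["CCSER1"]
        diffs.append(
            z[deleted[deleted].index].mean() - z[deleted[~deleted].index].mean()
        )
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean() - 1.5) <= 3 * se


def test_null_cohort_groups_exchangeable():
    """With no effect and full purity, deleted and wild-type expression are
    exchangeable: a rank test rejects at roughly its nominal size."""
    rejections = 0
    n_seeds = 40
    for seed in range(n_seeds):
        ann = fx.default_annotation()
        cfg = fx.CohortConfig(
            seed=seed, n_tumours=80, n_normals=20,
            purity_alpha=1e6, purity_beta=1e-3, effect_sizes={},
        )
        _, panel, truth = fx.simulate_cohort(cfg, ann["sites"], ann["genes"])
        deleted = truth.deleted["FRA4F"]
        x = np.log1p(panel.values.loc["CCSER1", deleted[deleted].index])
        y = np.log1p(panel.values.loc["CCSER1", deleted[~deleted].index])
        if stats.mannwhitneyu(x, y, alternative="two-sided").pvalue < 0.05:
            rejections += 1
    # Binomial(40, 0.05): mean 2, P(X > 7) < 1e-3
    assert rejections <= 7


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        fx.CohortConfig(n_normals=1).validate()
    with pytest.raises(ValueError):
        fx.CohortConfig(deletion_prevalence=1.5).validate()
    with pytest.raises(ValueError):
        fx.CohortConfig(deleted_seg_mean_range=(-0.5, -0.05)).validate()
    with pytest.raises(ValueError):
        fx.CohortConfig(expression_noise_sd=0.0).validate()


class TestExonProfileSimulation:
    def test_planted_truth_marks_exons_outside_block_up(self, annotation):
        _, _, truth = fx.simulate_exon_profile(
            annotation["exons"], deleted_block=(5, 7), shift=1.0, seed=0
        )
        up = {name for name, d in truth.items() if d == "up"}
        down = {name for name, d in truth.items() if d == "down"}
        assert down == {"exon_6", "exon_7", "exon_8"}
        assert len(up) == 8

    def test_zero_shift_is_statistically_flat(self, annotation):
        values, labels, truth = fx.simulate_exon_profile(
            annotation["exons"], deleted_block=(5, 7), shift=0.0,
            n_deleted=200, n_wild_type=200, seed=1,
        )
        assert set(truth.values()) == {"none"}
        deleted = [s for s, l in labels.items() if l == "three_prime_deleted"]
        wt = [s for s, l in labels.items() if l == "wild_type"]
        diff = values[deleted].mean(axis=1) - values[wt].mean(axis=1)
        assert np.all(np.abs(diff) < 0.5)

    def test_block_covering_all_exons_rejected(self, annotation):
        with pytest.raises(ValueError, match="every exon"):
            fx.simulate_exon_profile(annotation["exons"], deleted_block=(0, 10))


class TestCoverageSimulation:
    def test_drop_factor_zero_silences_downstream(self, annotation):
        element = annotation["element"]["TMSB4XP8"]
        tracks = fx.simulate_coverage(
            annotation["exons"], element, drop_factor=0.0, n_tracks=2, seed=0
        )
        exons = annotation["exons"].sorted_by_coordinate()
        last = exons[-1]
        assert all(t.values_over(last).sum() == 0 for t in tracks)

    def test_drop_factor_one_has_no_systematic_difference(self, annotation):
        element = annotation["element"]["TMSB4XP8"]
        tracks = fx.simulate_coverage(
            annotation["exons"], element, drop_factor=1.0, n_tracks=6,
            mean_coverage=50.0, seed=1,
        )
        exons = annotation["exons"].sorted_by_coordinate()
        up = np.mean([t.values_over(exons[0]).mean() for t in tracks])
        down = np.mean([t.values_over(exons[-1]).mean() for t in tracks])
        assert abs(up - down) < 3 * np.sqrt(50.0 / (200 * 6)) * 2

    def test_downstream_upstream_ratio_matches_drop_factor(self, annotation):
        """Poisson expectation: downstream/upstream mean coverage equals
        the drop factor, here 0.3, within 3 SE across 14 tracks."""
        element = annotation["element"]["TMSB4XP8"]
        exons = annotation["exons"].sorted_by_coordinate()
        ratios = []
        for seed in range(10):
            tracks = fx.simulate_coverage(
                annotation["exons"], element, drop_factor=0.3, n_tracks=14,
                mean_coverage=100.0, seed=seed,
            )
            up = np.mean([t.values_over(exons[0]).mean() for t in tracks])
            down = np.mean([t.values_over(exons[-1]).mean() for t in tracks])
            ratios.append(down / up)
        ratios = np.asarray(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.3) <= 3 * max(se, 1e-4)

    def test_drop_factor_out_of_range_rejected(self, annotation):
        with pytest.raises(ValueError):
            fx.simulate_coverage(
                annotation["exons"], annotation["element"]["TMSB4XP8"],
                drop_factor=1.5,
            )


def test_written_cohort_re_reads_identically(tmp_path):
    ann, _, (segments, panel, truth) = _cohort(seed=9, n_tumours=20,
                                               n_normals=5)
    fio.write_seg(segments, tmp_path / "c.seg")
    assert fio.read_seg(tmp_path / "c.seg") == segments
    fio.write_expression(panel, tmp_path / "m.tsv", tmp_path / "meta.tsv")
    back = fio.read_expression(tmp_path / "m.tsv", tmp_path / "meta.tsv")
    assert np.allclose(back.values.to_numpy(), panel.values.to_numpy())
    assert list(back.sample_ids) == list(panel.sample_ids)
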