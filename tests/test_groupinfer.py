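"""Tests of screening masks and conjunction inference on planted effects."""

import numpy as np
import pytest
from scipy import ndimage, stats

from strata_ifc.groupinfer import (
    ScreeningMask,
    medication_effect,
    screen_group_difference,
    summarize_effect,
)

SHAPE = (12, 12, 8)
Z_HC = np.arctanh(0.5)
Z_PAT = np.arctanh(0.1)
# Fisher-z sampling SD for 180-volume runs: 1/sqrt(T-3).
Z_SD = 1.0 / np.sqrt(177)


def effect_region(shape=SHAPE):
    m = np.zeros(shape, dtype=bool)
    m[4:9, 4:10, 3] = True  # 30 voxels
    return m


def group_maps(rng, n, mean_effect, shape=SHAPE, sd=Z_SD):
    """Simulated Fisher-z maps: background ~ N(0, sd), effect region elevated."""
    maps = rng.normal(0.0, sd, (n,) + shape)
    maps[:, effect_region(shape)] += mean_effect
    return list(maps)


def manual_mask(mask_grid, direction="hypo"):
    labels, _ = ndimage.label(mask_grid, structure=ndimage.generate_binary_structure(3, 2))
    return ScreeningMask(
        direction=direction, alpha=0.001, extent_k=5, mask=mask_grid,
        cluster_labels=labels, t_map=np.zeros(mask_grid.shape), df=101,
    )


class TestScreening:
    def test_identical_groups_give_empty_mask(self, rng):
        maps = group_maps(rng, 20, Z_HC)
        mask = screen_group_difference(maps[:10], maps[10:], "hypo")
        assert mask.n_voxels == 0

    def test_planted_hypoconnectivity_recovered(self, rng):
        """Controls at z=atanh(0.5), patients atanh(0.1), n=50/53: the hypo
        mask recovers >=80% of the 30 effect voxels and <=1% of the rest."""
        hc = group_maps(rng, 50, Z_HC)
        pat = group_maps(rng, 53, Z_PAT)
        mask = screen_group_difference(hc, pat, "hypo", alpha=0.001, extent_k=5)
        eff = effect_region()
        assert (mask.mask & eff).sum() >= 0.8 * eff.sum()
        assert (mask.mask & ~eff).sum() <= 0.01 * (~eff).sum()

    def test_hyper_and_hypo_masks_disjoint(self, rng):
        hc = group_maps(rng, 30, Z_HC)
        pat = group_maps(rng, 30, Z_PAT)
        hypo = screen_group_difference(hc, pat, "hypo", alpha=0.05, extent_k=1)
        hyper = screen_group_difference(hc, pat, "hyper", alpha=0.05, extent_k=1)
        assert not (hypo.mask & hyper.mask).any()

    def test_null_rejection_rate_matches_alpha(self, rng):
        """Type-I oracle: pure-null groups, 200 replicates; the per-voxel
        rejection rate before extent filtering sits at alpha within binomial CI."""
        alpha, shape = 0.05, (6, 6, 4)
        n_rej = n_tot = 0
        for _ in range(200):
            a = rng.normal(0, 1, (8,) + shape)
            b = rng.normal(0, 1, (8,) + shape)
            mask = screen_group_difference(list(a), list(b), "hypo", alpha=alpha, extent_k=1)
            n_rej += mask.mask.sum()
            n_tot += np.prod(shape)
        rate = n_rej / n_tot
        ci = 4 * np.sqrt(alpha * (1 - alpha) / n_tot)
        assert rate == pytest.approx(alpha, abs=ci)

    def test_extent_threshold_removes_small_clusters(self, rng):
        hc = group_maps(rng, 40, 0.0)
        pat = group_maps(rng, 40, 0.0)
        # Plant a strong single-voxel difference: survives alpha, not extent k=5.
        for m in hc:
            m[0, 0, 0] += 1.0
        mask = screen_group_difference(hc, pat, "hypo", alpha=0.001, extent_k=5)
        assert not mask.mask[0, 0, 0]
        mask1 = screen_group_difference(hc, pat, "hypo", alpha=0.001, extent_k=1)
        assert mask1.mask[0, 0, 0]

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="[Gg]rid"):
            screen_group_difference(
                [rng.normal(size=(4, 4, 2))] * 3, [rng.normal(size=(5, 4, 2))] * 3, "hypo"
            )


def planted_normalization(rng, n_r=36, n_nr=17):
    """Responders normalize fully at M2; Non-Responders do not change."""
    r_m1 = group_maps(rng, n_r, Z_PAT)
    r_m2 = group_maps(rng, n_r, Z_HC)
    nr_m1 = group_maps(rng, n_nr, Z_PAT)
    nr_m2 = group_maps(rng, n_nr, Z_PAT)
    return r_m1, r_m2, nr_m1, nr_m2


class TestConjunction:
    def test_planted_normalization_yields_significant_cluster(self, rng):
        r_m1, r_m2, nr_m1, nr_m2 = planted_normalization(rng)
        mask = manual_mask(effect_region())
        res = medication_effect(r_m1, r_m2, nr_m1, nr_m2, mask)
        assert len(res.clusters) >= 1
        assert res.significant[effect_region()].any()
        # Responder change positive, Non-Responder change near zero:
        eff = effect_region()
        d_r = (np.stack(r_m2) - np.stack(r_m1))[:, eff].mean()
        d_nr = (np.stack(nr_m2) - np.stack(nr_m1))[:, eff].mean()
        assert d_r > 0.3
        assert abs(d_nr) < 0.05

    def test_conjunction_t_is_elementwise_min(self, rng):
        r_m1, r_m2, nr_m1, nr_m2 = planted_normalization(rng)
        mask = manual_mask(effect_region())
        res = medication_effect(r_m1, r_m2, nr_m1, nr_m2, mask)
        vox = mask.mask
        np.testing.assert_allclose(
            res.t_conjunction[vox],
            np.minimum(res.t_interaction[vox], res.t_simple[vox]),
        )
        assert (res.p_fwe[vox] >= res.p_uncorrected[vox] - 1e-15).all()

    def test_null_changes_rarely_survive_fwe(self, rng):
        """R and NR change distributions identical: FWE-significant voxels in
        at most a handful of 100 replicates."""
        shape = (6, 6, 4)
        mask_grid = np.zeros(shape, dtype=bool)
        mask_grid[1:4, 1:4, 1:3] = True
        mask = manual_mask(mask_grid)
        hits = 0
        for _ in range(100):
            r_m1 = list(rng.normal(0, Z_SD, (36,) + shape))
            r_m2 = list(rng.normal(0, Z_SD, (36,) + shape))
            nr_m1 = list(rng.normal(0, Z_SD, (17,) + shape))
            nr_m2 = list(rng.normal(0, Z_SD, (17,) + shape))
            res = medication_effect(r_m1, r_m2, nr_m1, nr_m2, mask)
            hits += bool(res.significant.any())
        assert hits <= 5  # 5% of replicates, Bonferroni is conservative

    def test_bonferroni_monotone_in_mask_size(self, rng):
        r_m1, r_m2, nr_m1, nr_m2 = planted_normalization(rng)
        small_grid = np.zeros(SHAPE, dtype=bool)
        small_grid[4:7, 4:7, 3] = True
        big_grid = effect_region() | small_grid
        small = medication_effect(r_m1, r_m2, nr_m1, nr_m2, manual_mask(small_grid))
        big = medication_effect(r_m1, r_m2, nr_m1, nr_m2, manual_mask(big_grid))
        common = small_grid
        assert (big.p_fwe[common] >= small.p_fwe[common] - 1e-12).all()

    def test_single_voxel_mask_fwe_equals_uncorrected(self, rng):
        r_m1, r_m2, nr_m1, nr_m2 = planted_normalization(rng)
        grid = np.zeros(SHAPE, dtype=bool)
        grid[5, 5, 3] = True
        res = medication_effect(r_m1, r_m2, nr_m1, nr_m2, manual_mask(grid))
        assert res.p_fwe[5, 5, 3] == pytest.approx(res.p_uncorrected[5, 5, 3])

    def test_permutation_and_bonferroni_order_voxels_alike(self, rng):
        """A graded planted effect (per-voxel strength ramping 0 -> full
        normalization) spreads the conjunction p-values; the two FWE methods
        must rank voxels the same way (Spearman rho >= 0.95)."""
        eff = effect_region()
        # Change-score means spanning conjunction t of roughly 1..5, where the
        # 2000-sample max-T null still resolves distinct p-values.
        ramp = np.linspace(0.02, 0.12, eff.sum())
        r_m1 = [rng.normal(0, Z_SD, SHAPE) for _ in range(36)]
        r_m2 = []
        for m in r_m1:
            m2 = rng.normal(0, Z_SD, SHAPE)
            m2[eff] += ramp
            r_m2.append(m2)
        nr_m1 = [rng.normal(0, Z_SD, SHAPE) for _ in range(17)]
        nr_m2 = [rng.normal(0, Z_SD, SHAPE) for _ in range(17)]
        mask = manual_mask(eff)
        bonf = medication_effect(r_m1, r_m2, nr_m1, nr_m2, mask, fwe_method="bonferroni")
        perm = medication_effect(
            r_m1, r_m2, nr_m1, nr_m2, mask, fwe_method="permutation", n_perm=2000, rng_seed=3
        )
        vox = mask.mask
        rho = stats.spearmanr(bonf.p_fwe[vox], perm.p_fwe[vox]).statistic
        assert rho >= 0.95
        # The strongly normalizing end of the ramp is found by both methods.
        assert perm.significant.any() and bonf.significant.any()

    def test_hyper_direction_flips_normalization_sign(self, rng):
        """In a hyperconnectivity mask, normalization means *decreasing* z."""
        r_m1 = group_maps(rng, 36, Z_HC)
        r_m2 = group_maps(rng, 36, Z_PAT)  # decrease toward normal
        nr_m1 = group_maps(rng, 17, Z_HC)
        nr_m2 = group_maps(rng, 17, Z_HC)
        mask = manual_mask(effect_region(), direction="hyper")
        res = medication_effect(r_m1, r_m2, nr_m1, nr_m2, mask)
        assert res.significant.any()

    def test_empty_search_volume_structured_result(self):
        mask = manual_mask(np.zeros(SHAPE, dtype=bool))
        res = medication_effect([], [], [], [], mask)
        assert res.empty_search_volume
        assert not res.significant.any()
        assert res.clusters == []


class TestSummarizeEffect:
    def test_single_voxel_means_and_sem_definition(self, rng):
        r_m1, r_m2, nr_m1, nr_m2 = planted_normalization(rng)
        grid = np.zeros(SHAPE, dtype=bool)
        grid[5, 5, 3] = True
        res = medication_effect(r_m1, r_m2, nr_m1, nr_m2, manual_mask(grid))
        assert res.significant[5, 5, 3]
        cells = {("Responder", "M1"): r_m1, ("Responder", "M2"): r_m2}
        table = summarize_effect(res, cells)
        vals = np.stack(r_m1)[:, 5, 5, 3]
        row = table[(table.group == "Responder") & (table.timepoint == "M1")].iloc[0]
        assert row["mean_z"] == pytest.approx(vals.mean())
        assert row["sem_z"] == pytest.approx(vals.std(ddof=1) / np.sqrt(len(vals)))

    def test_recovery_means_track_planted_levels(self, rng):
        r_m1, r_m2, nr_m1, nr_m2 = planted_normalization(rng)
        hc = group_maps(rng, 50, Z_HC)
        res = medication_effect(r_m1, r_m2, nr_m1, nr_m2, manual_mask(effect_region()))
        cells = {
            ("HC", "M1"): hc,
            ("Responder", "M2"): r_m2,
            ("NonResponder", "M1"): nr_m1,
            ("NonResponder", "M2"): nr_m2,
        }
        table = summarize_effect(res, cells).set_index(["group", "timepoint"])
        assert abs(table.loc[("Responder", "M2"), "mean_z"] - table.loc[("HC", "M1"), "mean_z"]) < 0.1
        assert (
            abs(table.loc[("NonResponder", "M2"), "mean_z"] - table.loc[("NonResponder", "M1"), "mean_z"])
            < 0.1
        )

    def test_no_significant_voxels_rejected(self):
        res = medication_effect([], [], [], [], manual_mask(np.zeros(SHAPE, dtype=bool)))
        with pytest.raises(ValueError, match="significant"):
            summarize_effect(res, {})
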