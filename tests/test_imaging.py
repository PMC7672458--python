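"""Microscopy quantification: ratios, speckles, spots, time courses."""

import numpy as np
import pandas as pd
import pytest

from fracloc.imaging import (
    ImageError,
    brightest_speckle_pearson,
    classify_spots,
    cyto_total_ratio,
    decay_ratio_timecourse,
    detect_spots,
    nuclear_fraction_fold_change,
    segment_speckles,
    speckle_enrichment,
)
from fracloc.simdata import SpeckleImageParams, simulate_cell_image


@pytest.fixture()
def simple_masks():
    cell = np.zeros((100, 100), dtype=bool)
    cell[10:90, 10:90] = True
    nucleus = np.zeros_like(cell)
    nucleus[30:70, 30:70] = True
    return nucleus, cell


class TestCytoTotalRatio:
    def test_all_signal_cytoplasmic(self, simple_masks):
        nucleus, cell = simple_masks
        rna = np.zeros(cell.shape)
        rna[cell & ~nucleus] = 5.0
        assert cyto_total_ratio(rna, nucleus, cell, "none") == pytest.approx(1.0)

    def test_all_signal_nuclear(self, simple_masks):
        nucleus, cell = simple_masks
        rna = np.zeros(cell.shape)
        rna[nucleus] = 5.0
        assert cyto_total_ratio(rna, nucleus, cell, "none") == pytest.approx(0.0)

    def test_thirty_seventy_split(self, simple_masks):
        nucleus, cell = simple_masks
        rna = np.zeros(cell.shape)
        rna[nucleus] = 30.0 / nucleus.sum()
        rna[cell & ~nucleus] = 70.0 / (cell & ~nucleus).sum()
        assert cyto_total_ratio(rna, nucleus, cell, "none") == pytest.approx(0.7)

    def test_uniform_rescaling_invariance(self, simple_masks):
        nucleus, cell = simple_masks
        rng = np.random.default_rng(0)
        rna = rng.uniform(0, 10, size=cell.shape)
        r1 = cyto_total_ratio(rna, nucleus, cell, "none")
        r2 = cyto_total_ratio(7.3 * rna, nucleus, cell, "none")
        assert r1 == pytest.approx(r2)

    def test_zero_signal_rejected(self, simple_masks):
        nucleus, cell = simple_masks
        with pytest.raises(ImageError):
            cyto_total_ratio(np.zeros(cell.shape), nucleus, cell, "none")


class TestSegmentSpeckles:
    def test_default_synthetic_cell_hits_ten_percent(self):
        img = simulate_cell_image(seed=7)
        seg = segment_speckles(img.sc35, img.nucleus_mask)
        assert 0.095 <= seg.area_fraction <= 0.105
        assert not (seg.speckle_mask & ~img.nucleus_mask).any()

    def test_planted_foci_recovered(self):
        # bright foci on a dim baseline covering ~8% of the nucleus
        params = SpeckleImageParams(
            n_speckles=10, speckle_sigma=2.0, speckle_amp=2000.0,
            nucleoplasm_level=5.0, gain=10.0,
        )
        img = simulate_cell_image(params, seed=21)
        seg = segment_speckles(img.sc35, img.nucleus_mask)
        truth_mask = np.zeros_like(img.nucleus_mask)
        yy, xx = np.mgrid[: truth_mask.shape[0], : truth_mask.shape[1]]
        # truth disks area-matched to the 10% selection target
        r = np.sqrt(0.10 * img.nucleus_mask.sum() / (params.n_speckles * np.pi))
        for cy, cx in img.truth["speckle_centers"]:
            truth_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        truth_mask &= img.nucleus_mask
        inter = (seg.speckle_mask & truth_mask).sum()
        union = (seg.speckle_mask | truth_mask).sum()
        assert inter / union > 0.8

    def test_constant_image_tie_break_is_deterministic(self):
        nucleus = np.zeros((80, 80), dtype=bool)
        nucleus[10:70, 10:70] = True
        sc35 = np.ones((80, 80))
        with pytest.warns(UserWarning, match="tie"):
            s1 = segment_speckles(sc35, nucleus)
        with pytest.warns(UserWarning, match="tie"):
            s2 = segment_speckles(sc35, nucleus)
        np.testing.assert_array_equal(s1.speckle_mask, s2.speckle_mask)
        assert s1.area_fraction == pytest.approx(0.10, abs=0.005)

    def test_small_nucleus_rejected(self):
        nucleus = np.zeros((40, 40), dtype=bool)
        nucleus[:10, :10] = True
        with pytest.raises(ImageError):
            segment_speckles(np.ones((40, 40)), nucleus)


class TestSpeckleEnrichment:
    def test_uniform_nuclear_rna_gives_area_fraction(self, simple_masks):
        nucleus, cell = simple_masks
        speckle = np.zeros_like(nucleus)
        speckle[40:50, 40:50] = True
        rna = np.zeros(cell.shape)
        rna[nucleus] = 2.0
        s_nuc, s_tot = speckle_enrichment(rna, speckle, nucleus, cell, "none")
        assert s_nuc == pytest.approx(speckle.sum() / nucleus.sum())
        assert s_tot == pytest.approx(s_nuc)  # no cytoplasmic signal

    def test_all_rna_in_speckles(self, simple_masks):
        nucleus, cell = simple_masks
        speckle = np.zeros_like(nucleus)
        speckle[40:50, 40:50] = True
        rna = np.where(speckle, 3.0, 0.0)
        s_nuc, _ = speckle_enrichment(rna, speckle, nucleus, cell, "none")
        assert s_nuc == pytest.approx(1.0)

    def test_known_mixture_ratios(self):
        params = SpeckleImageParams(w_spec=1.0, w_nuc=1.0, w_cyt=1.0, gain=20.0)
        img = simulate_cell_image(params, seed=9)
        seg = segment_speckles(img.sc35, img.nucleus_mask)
        s_nuc, s_tot = speckle_enrichment(img.rna, seg.speckle_mask,
                                          img.nucleus_mask, img.cell_mask)
        # expected from the planted mixture: integrate the noiseless fields
        assert 0 < s_tot <= s_nuc <= 1


class TestBrightestSpecklePearson:
    def test_identity_channels_give_unit_correlation(self):
        img = simulate_cell_image(seed=7)
        seg = segment_speckles(img.sc35, img.nucleus_mask)
        q = brightest_speckle_pearson(img.sc35, img.sc35, seg.speckle_mask)
        assert q.mean_pearson == pytest.approx(1.0)
        assert all(r == pytest.approx(1.0) for r in q.pearson_per_speckle)

    def test_positive_affine_transform_gives_unit_correlation(self):
        img = simulate_cell_image(seed=8)
        seg = segment_speckles(img.sc35, img.nucleus_mask)
        q = brightest_speckle_pearson(3.0 * img.sc35 + 11.0, img.sc35, seg.speckle_mask)
        assert q.mean_pearson == pytest.approx(1.0)

    def test_independent_noise_has_near_zero_mean(self):
        rng = np.random.default_rng(10)
        means = []
        for i in range(20):
            img = simulate_cell_image(seed=300 + i)
            seg = segment_speckles(img.sc35, img.nucleus_mask)
            noise = rng.uniform(0, 100, size=img.sc35.shape)
            q = brightest_speckle_pearson(noise, img.sc35, seg.speckle_mask)
            means.append(q.mean_pearson)
        assert abs(np.mean(means)) < 0.1

    def test_k_larger_than_component_count_uses_all(self):
        img = simulate_cell_image(SpeckleImageParams(n_speckles=3), seed=11)
        seg = segment_speckles(img.sc35, img.nucleus_mask)
        q = brightest_speckle_pearson(img.rna, img.sc35, seg.speckle_mask, k=50)
        assert 1 <= len(q.pearson_per_speckle) <= 50


class TestSpotDetection:
    def test_blank_image_has_no_spots(self):
        assert len(detect_spots(np.zeros((128, 128)))) == 0

    def test_planted_spots_recovered_at_high_snr(self):
        recalls, precisions = [], []
        for i in range(5):
            params = SpeckleImageParams(
                n_speckles=0, n_nuclear_spots=20, n_cyto_spots=30,
                spot_amp=500.0, nucleoplasm_level=40.0, cyto_level=40.0, gain=1.0,
            )
            img = simulate_cell_image(params, seed=40 + i)
            truth = np.vstack([img.truth["nuclear_spots"], img.truth["cytoplasmic_spots"]])
            found = detect_spots(img.rna)
            d = np.sqrt(((truth[:, None, :] - found[None, :, :]) ** 2).sum(-1))
            matched_truth = (d.min(axis=1) <= 3).sum()
            matched_found = (d.min(axis=0) <= 3).sum()
            recalls.append(matched_truth / len(truth))
            precisions.append(matched_found / max(len(found), 1))
        assert np.mean(recalls) >= 0.95
        assert np.mean(precisions) >= 0.95

    def test_brightness_rescaling_leaves_detections_unchanged(self):
        params = SpeckleImageParams(n_speckles=0, n_nuclear_spots=10,
                                    n_cyto_spots=10, spot_amp=500.0)
        img = simulate_cell_image(params, seed=50)
        c1 = detect_spots(img.rna)
        c2 = detect_spots(2.0 * img.rna)
        np.testing.assert_array_equal(c1, c2)


class TestClassifySpots:
    def test_all_nuclear(self, simple_masks):
        nucleus, cell = simple_masks
        spots = np.array([[40, 40], [50, 50], [35, 60]])
        counts = classify_spots(spots, nucleus, cell)
        assert counts.nuclear_fraction == 1.0

    def test_bookkeeping_with_perfect_detection(self):
        params = SpeckleImageParams(n_nuclear_spots=20, n_cyto_spots=30)
        img = simulate_cell_image(params, seed=12)
        truth = np.vstack([img.truth["nuclear_spots"], img.truth["cytoplasmic_spots"]])
        counts = classify_spots(truth, img.nucleus_mask, img.cell_mask)
        assert (counts.n_nuclear, counts.n_cytoplasmic) == (20, 30)

    def test_outside_cell_discarded(self, simple_masks):
        nucleus, cell = simple_masks
        counts = classify_spots(np.array([[0, 0], [40, 40]]), nucleus, cell)
        assert counts.n_discarded == 1

    def test_knockdown_fold_change_recovered(self):
        """2.5x more nuclear spots in KD recovers a fold change in [2, 3]."""
        from fracloc.imaging import SpotCounts

        spot_counts = {"control": (10, 40), "KD": (25, 25)}
        totals = {}
        for cond, (n_nuc, n_cyt) in spot_counts.items():
            tot_n = tot_c = 0
            for i in range(6):
                params = SpeckleImageParams(
                    n_speckles=0, n_nuclear_spots=n_nuc, n_cyto_spots=n_cyt,
                    spot_amp=500.0, nucleoplasm_level=40.0, cyto_level=40.0,
                )
                img = simulate_cell_image(params, seed=60 + i)
                spots = detect_spots(img.rna)
                counts = classify_spots(spots, img.nucleus_mask, img.cell_mask)
                tot_n += counts.n_nuclear
                tot_c += counts.n_cytoplasmic
            totals[cond] = SpotCounts(tot_n, tot_c, 0)
        fold = nuclear_fraction_fold_change(totals["KD"], totals["control"])
        assert 2.0 <= fold <= 3.0


class TestDecayRatio:
    def _table(self, ctrl, kd):
        rows = []
        for tp, vals in ctrl.items():
            rows += [{"timepoint": tp, "condition": "control", "value": v} for v in vals]
        for tp, vals in kd.items():
            rows += [{"timepoint": tp, "condition": "KD", "value": v} for v in vals]
        return pd.DataFrame(rows)

    def test_identical_conditions_give_unit_ratio(self):
        tbl = self._table({0: [10, 12], 1: [8, 9]}, {0: [10, 12], 1: [8, 9]})
        out = decay_ratio_timecourse(tbl)
        np.testing.assert_allclose(out["ratio"], 1.0)

    def test_unstable_fraction_decays_then_plateaus(self):
        # KD loses 40% of signal within the first hour, then is stable
        rng = np.random.default_rng(13)
        times = [0.0, 0.5, 1.0, 2.0, 3.0]
        ctrl = {t: 100 + rng.normal(0, 1, size=12) for t in times}
        kd = {t: (100 * (0.6 + 0.4 * np.exp(-t / 0.3))) + rng.normal(0, 1, size=12)
              for t in times}
        out = decay_ratio_timecourse(self._table(ctrl, kd))
        ratios = out["ratio"].to_numpy()
        assert (np.diff(ratios) <= 0.02).all()  # non-increasing up to noise
        assert ratios[0] > 0.95
        assert ratios[-1] == pytest.approx(0.6, abs=0.05)

    def test_scale_invariance(self):
        tbl = self._table({0: [10, 12]}, {0: [6, 7]})
        r1 = decay_ratio_timecourse(tbl)["ratio"]
        tbl2 = tbl.assign(value=tbl["value"] * 100)
        r2 = decay_ratio_timecourse(tbl2)["ratio"]
        np.testing.assert_allclose(r1, r2)

    def test_single_cell_timepoint_has_undefined_se(self):
        tbl = self._table({0: [10.0]}, {0: [6.0, 7.0]})
        out = decay_ratio_timecourse(tbl)
        assert np.isnan(out.loc[0, "se"])
        assert out.loc[0, "ratio"] == pytest.approx(6.5 / 10.0)
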