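import dataclasses
import logging

import numpy as np
import pytest
import tifffile
import yaml
from scipy import ndimage

from uvrfret import fret_physics as fp
from uvrfret import image_synth as synth
from uvrfret import quantify as qf


@pytest.fixture
def acq(make_config):
    return synth.render_acquisition(make_config(seed=11))


class TestReadAcquisition:
    def test_round_trip_uint16_is_lossless(self, acq, tmp_path):
        prefix = tmp_path / "field"
        synth.write_images(acq, prefix, dtype="uint16")
        back = qf.read_acquisition(prefix)
        for name, arr in acq.channels.items():
            assert np.array_equal(getattr(back, name), synth.quantize_u16(arr))
        assert np.array_equal(back.ground_truth["cell_labels"],
                              acq.ground_truth["cell_labels"])

    def test_round_trip_float32(self, acq, tmp_path):
        prefix = tmp_path / "field"
        synth.write_images(acq, prefix, dtype="float32")
        back = qf.read_acquisition(prefix)
        assert np.array_equal(back.donor_488,
                              acq.donor_488.astype(np.float32))

    def test_channels_mapped_by_metadata_not_page_order(self, acq, tmp_path):
        prefix = tmp_path / "field"
        synth.write_images(acq, prefix, dtype="uint16")
        # shuffle TIFF pages and fix up the sidecar indices accordingly
        pages = tifffile.imread(prefix.with_suffix(".tif"))
        perm = [2, 0, 1]
        tifffile.imwrite(prefix.with_suffix(".tif"), pages[perm],
                         photometric="minisblack")
        meta = yaml.safe_load(prefix.with_suffix(".yaml").read_text())
        for page in meta["pages"]:
            page["index"] = perm.index(page["index"])
        prefix.with_suffix(".yaml").write_text(yaml.safe_dump(meta))
        back = qf.read_acquisition(prefix)
        assert np.array_equal(back.fret_488, synth.quantize_u16(acq.fret_488))

    def test_missing_channel_error_names_the_channel(self, acq, tmp_path):
        prefix = tmp_path / "field"
        synth.write_images(acq, prefix, dtype="uint16")
        meta = yaml.safe_load(prefix.with_suffix(".yaml").read_text())
        meta["pages"] = [p for p in meta["pages"]
                        if p["channel"] != "acceptor_552"]
        prefix.with_suffix(".yaml").write_text(yaml.safe_dump(meta))
        with pytest.raises(qf.MissingChannelError, match="acceptor_552"):
            qf.read_acquisition(prefix)

    def test_missing_sidecar_raises_load_error(self, tmp_path):
        with pytest.raises(qf.LoadError):
            qf.read_acquisition(tmp_path / "nothing")

    def test_metadata_records_excitation_lines(self, acq, tmp_path):
        prefix = tmp_path / "field"
        synth.write_images(acq, prefix, dtype="uint16")
        meta = yaml.safe_load(prefix.with_suffix(".yaml").read_text())
        exc = {p["channel"]: p["excitation_nm"] for p in meta["pages"]}
        assert exc["donor_488"] == 488
        assert exc["fret_488"] == 488
        assert exc["acceptor_552"] == 552


class TestReadBleachSeries:
    def test_round_trip_and_page_counts(self, make_config, tmp_path):
        series = synth.render_bleach_series(make_config(seed=21))
        prefix = tmp_path / "bleach"
        files = synth.write_images(series, prefix, dtype="uint16")
        pages = tifffile.imread(prefix.with_suffix(".tif"))
        assert pages.shape[0] == 10  # 5 pre + 5 post scans
        names = {f.name for f in files}
        assert "bleach_bleach_mask.tif" in names
        assert "bleach_control_mask.tif" in names
        back = qf.read_bleach_series(prefix)
        assert np.array_equal(back.pre_stack,
                              synth.quantize_u16(series.pre_stack))
        assert np.array_equal(back.bleach_mask, series.bleach_mask)
        assert np.array_equal(back.control_mask, series.control_mask)


class TestSelectRandomRegions:
    def test_deterministic_given_seed(self, acq):
        a = qf.select_random_regions(acq, seed=9)
        b = qf.select_random_regions(acq, seed=9)
        assert a == b

    def test_blank_image_with_zero_threshold_samples_anywhere(self):
        blank = synth.AcquisitionSet(
            donor_488=np.zeros((64, 64)), fret_488=np.zeros((64, 64)),
            acceptor_552=np.zeros((64, 64)), metadata={})
        regions = qf.select_random_regions(blank, n_regions=5, min_signal=0,
                                           seed=1)
        assert len(regions) == 5

    def test_overlap_capped_at_half_area(self, acq):
        regions = qf.select_random_regions(acq, n_regions=20, seed=3)
        s = regions[0].side
        for i, a in enumerate(regions):
            for b in regions[i + 1:]:
                dr = abs(a.center[0] - b.center[0])
                dc = abs(a.center[1] - b.center[1])
                inter = max(0, s - dr) * max(0, s - dc)
                assert inter <= 0.5 * s * s

    def test_too_few_admissible_positions_raises(self, acq):
        with pytest.raises(qf.SamplingError, match="admissible"):
            qf.select_random_regions(acq, n_regions=10,
                                     min_signal=1e9, seed=1)

    def test_selected_regions_hit_the_periphery(self, acq):
        # with a signal threshold, every region overlaps the ground-truth band
        regions = qf.select_random_regions(acq, n_regions=20, seed=5)
        band = acq.ground_truth["expression_map"] > 0
        for r in regions:
            r0 = r.center[0] - r.side // 2
            c0 = r.center[1] - r.side // 2
            assert band[r0:r0 + r.side, c0:c0 + r.side].sum() >= 1


class TestSensitizedEmissionRatio:
    def _region(self, donor, fret, image="img0", exp="exp0", rid=0):
        return qf.RegionSample(image_id=image, region_id=rid, center=(8, 8),
                               side=16, mean_donor_488=donor,
                               mean_fret_488=fret, mean_acceptor_552=1.0,
                               experiment_id=exp)

    def test_zero_fret_region_gives_zero_ratio(self):
        res = qf.sensitized_emission_ratio([self._region(10.0, 0.0)])
        assert res.mean == 0.0

    def test_zero_donor_regions_excluded_with_warning(self, caplog):
        regions = [self._region(10.0, 5.0), self._region(0.0, 5.0, rid=1)]
        with caplog.at_level(logging.WARNING, logger="uvrfret"):
            res = qf.sensitized_emission_ratio(regions)
        assert res.n_excluded == 1
        assert "zero donor" in caplog.text

    def test_all_regions_excluded_raises(self):
        with pytest.raises(qf.EmptyResultError):
            qf.sensitized_emission_ratio([self._region(0.0, 5.0)])

    def test_nested_aggregation_across_experiments(self):
        regions = [
            self._region(10.0, 2.0, image="img0", exp="exp0", rid=0),
            self._region(10.0, 4.0, image="img1", exp="exp0", rid=1),
            self._region(10.0, 8.0, image="img0", exp="exp1", rid=2),
        ]
        res = qf.sensitized_emission_ratio(regions)
        # exp0: mean(0.2, 0.4) = 0.3; exp1: 0.8 -> grand mean 0.55
        assert res.per_experiment["exp0"] == pytest.approx(0.3)
        assert res.mean == pytest.approx(0.55)
        assert res.se == pytest.approx(np.std([0.3, 0.8], ddof=1) / np.sqrt(2))

    def test_noiseless_estimate_matches_closed_form(self, noiseless_config):
        cfg = noiseless_config()
        acq = synth.render_acquisition(cfg)
        regions = qf.select_random_regions(acq, n_regions=20, seed=2)
        res = qf.sensitized_emission_ratio(regions)
        expected = fp.expected_sensitized_ratio(cfg.mixture(), cfg.params)
        assert res.mean == pytest.approx(expected, rel=1e-3)

    def test_pooled_alternative_close_to_per_region_default(self, acq):
        regions = qf.select_random_regions(acq, n_regions=20, seed=2)
        a = qf.sensitized_emission_ratio(regions)
        b = qf.sensitized_emission_ratio(regions, pooled=True)
        assert b.pooled and a.mean == pytest.approx(b.mean, rel=0.1)

    def test_higher_dimer_fraction_gives_higher_ratio(self, make_config):
        wins = 0
        for s in range(10):
            ratios = {}
            for df in (0.9, 0.2):
                state = fp.PopulationState("NcCg", "WT", False,
                                           dimer_fraction=df)
                cfg = make_config(state=state, seed=500 + s)
                acq = synth.render_acquisition(cfg)
                regions = qf.select_random_regions(acq, n_regions=10, seed=s)
                ratios[df] = qf.sensitized_emission_ratio(regions).mean
            wins += ratios[0.9] > ratios[0.2]
        assert wins == 10


class TestTracePeriphery:
    def test_points_lie_on_the_band(self, make_config):
        cfg = make_config(n_cells=1, image_size=(128, 128))
        acq = synth.render_acquisition(cfg)
        band = acq.ground_truth["expression_map"] > 0
        profile = qf.trace_periphery(acq.donor_488, n_points=100)
        dist = ndimage.distance_transform_edt(~band)
        d = dist[np.clip(np.rint(profile.points[:, 0]).astype(int), 0, 127),
                 np.clip(np.rint(profile.points[:, 1]).astype(int), 0, 127)]
        assert np.mean(d <= 2.0) >= 0.9

    def test_point_count_and_even_spacing(self, make_config):
        acq = synth.render_acquisition(make_config(n_cells=1,
                                                   image_size=(128, 128)))
        profile = qf.trace_periphery(acq.donor_488, n_points=100)
        assert profile.points.shape == (100, 2)
        steps = np.sqrt((np.diff(profile.points, axis=0) ** 2).sum(1))
        assert steps.std() / steps.mean() < 0.25

    def test_uniform_image_raises(self):
        with pytest.raises(qf.TracingError):
            qf.trace_periphery(np.full((64, 64), 7.0), n_points=50)

    def test_too_few_points_rejected(self, make_config):
        acq = synth.render_acquisition(make_config())
        with pytest.raises(ValueError):
            qf.trace_periphery(acq.donor_488, n_points=5)


class TestBleachPercentIncrease:
    def test_identical_stacks_give_zero_percent(self, make_config):
        series = synth.render_bleach_series(make_config(seed=31))
        flat = synth.BleachSeries(
            pre_stack=series.pre_stack, post_stack=series.pre_stack.copy(),
            bleach_mask=series.bleach_mask, control_mask=series.control_mask,
            metadata={})
        res = qf.bleach_percent_increase(flat)
        assert res.percent_increase == pytest.approx(0.0)
        assert res.control_percent_increase == pytest.approx(0.0)

    def test_noiseless_complete_bleach_gives_exact_identity(
            self, noiseless_config):
        p = fp.FretParams(E_intra=0.2, E_inter=0.0)
        state = fp.PopulationState("NcCg", "WT", False, dimer_fraction=0.0)
        cfg = noiseless_config(state=state, params=p, bleach_completeness=1.0)
        series = synth.render_bleach_series(cfg)
        rs, cs = np.nonzero(series.bleach_mask)
        profile = qf.trace_periphery(
            series.pre_stack.mean(0),
            roi=(rs.min(), cs.min(), rs.max() + 1, cs.max() + 1))
        res = qf.bleach_percent_increase(series, profile)
        assert res.percent_increase == pytest.approx(25.0, abs=0.5)
        assert res.control_percent_increase == pytest.approx(0.0, abs=1e-9)
        assert res.n_points == 100

    def test_mask_and_profile_sampling_agree(self, make_config):
        series = synth.render_bleach_series(make_config(seed=41))
        rs, cs = np.nonzero(series.bleach_mask)
        profile = qf.trace_periphery(
            series.pre_stack.mean(0),
            roi=(rs.min(), cs.min(), rs.max() + 1, cs.max() + 1))
        a = qf.bleach_percent_increase(series)
        b = qf.bleach_percent_increase(series, profile)
        assert a.percent_increase == pytest.approx(b.percent_increase, abs=5.0)

    def test_nonpositive_pre_intensity_raises(self, make_config):
        series = synth.render_bleach_series(make_config(seed=31))
        dark = synth.BleachSeries(
            pre_stack=np.zeros_like(series.pre_stack),
            post_stack=series.post_stack, bleach_mask=series.bleach_mask,
            control_mask=series.control_mask, metadata={})
        with pytest.raises(ZeroDivisionError):
            qf.bleach_percent_increase(dark)
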