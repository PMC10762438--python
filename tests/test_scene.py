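import numpy as np
import pandas as pd
import pytest

from pamscape.noise import CalibrationSpec, counts_to_pressure, pressure_to_counts, welch_psd
from pamscape.scene import (
    ClippingError,
    ConfigurationError,
    DEFAULT_SPECIES,
    ICE_AFFILIATED,
    ICE_AVOIDING,
    SceneConfig,
    SpeciesSpec,
    make_bathymetry,
    make_call_schedule,
    make_env_fields,
    schedule_to_annotations,
    synth_recording,
)


def _tiny_config(**kw):
    defaults = dict(
        seed=7,
        resolution_deg=0.5,
        start_date="2017-02-10",
        end_date="2017-08-31",
    )
    defaults.update(kw)
    return SceneConfig(**defaults)


class TestBathymetry:
    def test_same_seed_is_bit_identical(self):
        a = make_bathymetry(_tiny_config())
        b = make_bathymetry(_tiny_config())
        assert (a.values == b.values).all()

    def test_flat_depth_override(self):
        depth = make_bathymetry(_tiny_config(flat_depth=1000.0))
        assert (depth.values == 1000.0).all()

    def test_northern_basin_deeper_than_shelf(self):
        depth = make_bathymetry(_tiny_config())
        north_mean = depth.isel(lat=-1).mean()
        shelf_mean = depth.isel(lat=slice(0, 3)).mean()
        assert float(north_mean) > float(shelf_mean)

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ConfigurationError):
            SceneConfig(lat_min=-60.0, lat_max=-60.0)


class TestEnvFields:
    def test_winter_ice_exceeds_summer_at_recorder(self, scene_config, env_fields):
        sic = env_fields.sic.sel(
            lat=scene_config.recorder_lat, lon=scene_config.recorder_lon, method="nearest"
        )
        july = float(sic.sel(time="2017-07").mean())
        feb = float(sic.sel(time="2017-02").mean())
        assert july > feb

    def test_sic_bounded(self, env_fields):
        assert float(env_fields.sic.min()) >= 0.0
        assert float(env_fields.sic.max()) <= 100.0

    def test_anomaly_delays_ice_advance(self):
        normal = make_env_fields(_tiny_config(year_mode="normal"))
        anom = make_env_fields(_tiny_config(year_mode="anomaly"))

        def first_crossing(env):
            cfg = _tiny_config()
            sic = env.sic.sel(lat=cfg.recorder_lat, lon=cfg.recorder_lon, method="nearest")
            over = np.flatnonzero(sic.values > 30.0)
            return pd.Timestamp(sic.time.values[over[0]])

        delay = (first_crossing(anom) - first_crossing(normal)).days
        assert delay >= 20  # configured 30-day shift, allowing front jitter

    def test_anomaly_raises_summer_sst(self):
        normal = make_env_fields(_tiny_config(year_mode="normal"))
        anom = make_env_fields(_tiny_config(year_mode="anomaly", seed=7))
        cfg = _tiny_config()
        sel = dict(lat=cfg.recorder_lat, lon=cfg.recorder_lon, method="nearest")
        d_feb = float(
            anom.sst.sel(time="2017-02", **sel).mean()
            - normal.sst.sel(time="2017-02", **sel).mean()
        )
        assert d_feb == pytest.approx(0.7, abs=0.15)

    def test_determinism(self):
        a = make_env_fields(_tiny_config())
        b = make_env_fields(_tiny_config())
        assert (a.sst.values == b.sst.values).all()
        assert (a.sic.values == b.sic.values).all()


class TestCallSchedule:
    def test_zero_coefficients_give_half_rate(self, env_fields, scene_config):
        sp = SpeciesSpec("X", ICE_AVOIDING, 50.0, 170.0, (0.0, 0.0, 0.0, 0.0))
        cfg = SceneConfig(
            seed=scene_config.seed,
            resolution_deg=scene_config.resolution_deg,
            start_date=scene_config.start_date,
            end_date=scene_config.end_date,
            species=[sp],
        )
        sched = make_call_schedule(cfg, env_fields)
        n = len(sched)
        assert n > 5000
        se = np.sqrt(0.25 / n)
        assert abs(sched["X"].mean() - 0.5) < 3 * se

    def test_ice_affiliated_presence_tracks_sic(self, scene_config, env_fields, schedule):
        daily_pres = schedule["AMW"].groupby(schedule.index.normalize()).mean()
        sic = env_fields.at_recorder(scene_config.recorder_lat, scene_config.recorder_lon)[
            "sic_prop"
        ]
        assert np.corrcoef(daily_pres.values, sic.values)[0, 1] > 0.0

    def test_minus_inf_intercept_silences_species(self, env_fields, scene_config):
        sp = SpeciesSpec("MUTE", ICE_AFFILIATED, 50.0, 170.0, (-np.inf, 0.0, 0.0, 0.0))
        cfg = SceneConfig(
            seed=1,
            resolution_deg=scene_config.resolution_deg,
            start_date=scene_config.start_date,
            end_date=scene_config.end_date,
            species=[sp],
        )
        sched = make_call_schedule(cfg, env_fields)
        assert (sched["MUTE"] == 0).all()

    def test_guild_separability(self, scene_config, env_fields, schedule):
        """Mean SIC on presence-days: ice-affiliated > ice-avoiding preset."""
        sic = env_fields.at_recorder(scene_config.recorder_lat, scene_config.recorder_lon)[
            "sic_prop"
        ]
        daily = schedule.groupby(schedule.index.normalize()).max()

        def mean_sic_on_presence(guild):
            names = [s.name for s in DEFAULT_SPECIES if s.guild == guild]
            vals = []
            for n in names:
                present = daily[n] == 1
                if present.any():
                    vals.append(sic.values[present.values].mean())
            return np.mean(vals)

        assert mean_sic_on_presence(ICE_AFFILIATED) > mean_sic_on_presence(ICE_AVOIDING)

    def test_determinism(self, scene_config, env_fields):
        a = make_call_schedule(scene_config, env_fields)
        b = make_call_schedule(scene_config, env_fields)
        assert (a.values == b.values).all()


class TestSynthRecording:
    calib = CalibrationSpec()

    def test_pure_noise_is_flat_and_gaussian(self):
        counts = synth_recording([], DEFAULT_SPECIES, 60.0, self.calib,
                                 duration_min=1.0, fs=32768.0, seed=3)
        p = counts_to_pressure(counts, self.calib)
        from scipy import stats

        # normality: skew/kurtosis-based test on a subsample
        assert stats.normaltest(p[::37]).pvalue > 1e-4
        psd = welch_psd(p, 32768.0, segment_minutes=1.0, nfft=8192)
        band = (psd.frequencies_hz >= 10.0) & (psd.frequencies_hz <= 10_000.0)
        level = psd.psd_db[band]
        assert np.all(np.abs(level - 60.0) < 2.0)

    def test_injected_call_peaks_at_its_frequency(self):
        fin = [s for s in DEFAULT_SPECIES if s.name == "FW"]
        counts = synth_recording(["FW"], fin, 40.0, self.calib,
                                 duration_min=0.5, fs=4096.0,
                                 received_level_db=120.0, seed=5)
        p = counts_to_pressure(counts, self.calib)
        psd = welch_psd(p, 4096.0, segment_minutes=0.5, nfft=4096)
        peak = psd.frequencies_hz[np.argmax(psd.psd_db)]
        df = psd.frequencies_hz[1] - psd.frequencies_hz[0]
        assert abs(peak - 20.0) <= df

    def test_noise_level_shift_measured(self):
        def band_level(nl):
            counts = synth_recording([], DEFAULT_SPECIES, nl, self.calib,
                                     duration_min=0.5, fs=8192.0, seed=11)
            p = counts_to_pressure(counts, self.calib)
            psd = welch_psd(p, 8192.0, segment_minutes=0.5, nfft=4096)
            band = (psd.frequencies_hz > 50) & (psd.frequencies_hz < 3000)
            return 10 * np.log10(np.mean(10 ** (psd.psd_db[band] / 10)))

        assert band_level(66.0) - band_level(60.0) == pytest.approx(6.0, abs=0.5)

    def test_clipping_raises(self):
        with pytest.raises(ClippingError):
            synth_recording(["FW"], DEFAULT_SPECIES, 60.0, self.calib,
                            duration_min=0.1, fs=4096.0, received_level_db=170.0)

    def test_nyquist_guard(self):
        with pytest.raises(ConfigurationError):
            synth_recording(["O"], DEFAULT_SPECIES, 60.0, self.calib, fs=1000.0)

    def test_calibration_round_trip(self, rng):
        p = rng.normal(0, 1e4, 1000)
        back = counts_to_pressure(pressure_to_counts(p, self.calib), self.calib)
        assert np.allclose(back, p, rtol=1e-12)


class TestIO:
    def test_netcdf_round_trip(self, tmp_path, env_fields):
        import xarray as xr

        path = tmp_path / "env.nc"
        env_fields.to_netcdf(path)
        ds = xr.open_dataset(path)
        assert np.allclose(ds["sst"].values, env_fields.sst.values)
        ds.close()

    def test_yaml_round_trip(self, tmp_path):
        cfg = _tiny_config()
        path = tmp_path / "scene.yaml"
        cfg.to_yaml(path)
        back = SceneConfig.from_yaml(path)
        assert back == cfg

    def test_wav_round_trip(self, tmp_path):
        from pamscape.scene import read_wav, write_wav

        calib = CalibrationSpec()
        counts = synth_recording([], DEFAULT_SPECIES, 60.0, calib,
                                 duration_min=0.05, fs=4096.0, seed=1)
        path = tmp_path / "rec.wav"
        write_wav(path, counts, 4096.0)
        data, fs = read_wav(path)
        assert fs == 4096.0
        assert np.allclose(data, np.round(counts), atol=0.5)

    def test_annotation_export_shape(self, schedule, scene_config):
        ann = schedule_to_annotations(schedule.iloc[:48], registry=scene_config.species)
        assert set(ann.columns) >= {"file", "start_s", "species", "certainty", "chorus"}
        assert (ann["start_s"] < ann["end_s"]).all()
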