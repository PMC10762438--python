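"""End-to-end synthetic-scene pipeline.

Runs the full chain on a generated scene: environmental fields → call
schedules → synthetic recordings → calibrated noise levels → monthly
ray-traced TL grids → daily audible masks → ice-constrained covariates →
presence series → collinearity screening, ordination and presence models.

The default problem sizes (bearing step, slice length, mesh) are chosen so
a full season runs in a couple of minutes on one core while preserving the
qualitative structure: an anomaly-year ice cycle, an audible area that
breathes with noise and ice, and a guild-separable community.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import covariates as cov
from . import presence as pres
from .gam import PresenceGAM, PresenceGAMResults
from .noise import CalibrationSpec, counts_to_pressure, noise_at_frequency, welch_psd
from .ordination import CCA, CCAResults, vif
from .raytrace import BottomSpec, TracerConfig, extract_slice, grid_tl, trace_tl
from .scene import (
    ICE_AFFILIATED,
    ICE_AVOIDING,
    EnvFieldSet,
    SceneConfig,
    make_call_schedule,
    make_env_fields,
    schedule_to_annotations,
    synth_recording,
)


@dataclass
class PipelineConfig:
    """Problem sizes and acoustic settings of the end-to-end run."""

    shared_frequency_hz: float = 50.0  # shared audible-area frequency
    shared_source_level_db: float = 160.0  # nominal SL for the shared mask
    bearing_step_deg: float = 15.0
    slice_length_m: float = 120_000.0
    mesh_nlat: int = 80
    mesh_nlon: int = 160
    recording_fs_hz: float = 2048.0
    recording_minutes: float = 0.5
    open_water_noise_db: float = 82.0  # ambient density at 50 Hz, ice-free
    ice_quieting_db: float = 12.0  # NL reduction under full ice cover
    snr_threshold_db: float = cov.SNR_THRESHOLD_DB
    tracer: TracerConfig = field(
        default_factory=lambda: TracerConfig(
            step_m=200.0, range_cell_m=2000.0, depth_cell_m=50.0, n_rays=121
        )
    )


@dataclass
class PipelineResult:
    config: SceneConfig
    env: EnvFieldSet
    schedule: pd.DataFrame
    daily: pd.DataFrame
    community: pd.DataFrame
    covariates: pd.DataFrame
    vif: pd.Series
    cca: CCAResults
    noise_series: pd.Series
    area_series: pd.Series

    def guild_contrast(self) -> dict:
        """Axis-1 guild separation and SIC-arrow alignment.

        Returns the mean CCA axis-1 score of each guild, their separation,
        and whether the SIC biplot arrow points toward the ice-affiliated
        cluster (alignment +1) or away from it (−1).
        """
        guilds = {s.name: s.guild for s in self.config.species}
        sp = self.cca.species_scores["CCA1"]
        aff = sp[[n for n in sp.index if guilds.get(n) == ICE_AFFILIATED]].mean()
        avo = sp[[n for n in sp.index if guilds.get(n) == ICE_AVOIDING]].mean()
        arrow = float(self.cca.biplot_scores.loc["SIC_prop", "CCA1"])
        alignment = float(np.sign(arrow) * np.sign(aff - avo))
        return {
            "axis1_ice_affiliated_mean": float(aff),
            "axis1_ice_avoiding_mean": float(avo),
            "separation": float(abs(aff - avo)),
            "sic_arrow_axis1": arrow,
            "sic_arrow_alignment": alignment,
        }

    def fit_presence_gam(self, species: str, *, k: int = 10) -> PresenceGAMResults:
        """Quasi-binomial GAM of one species on the constrained covariates."""
        covs = self.covariates.set_index("date")[["SST_mean", "SSH_mean", "vBAT", "SIC_prop"]]
        covs = covs.rename(
            columns={"SST_mean": "SST", "SSH_mean": "SSH", "vBAT": "vBAT", "SIC_prop": "SIC"}
        )
        return PresenceGAM.from_daily(self.daily, species, covs, k=k).fit()


def run_scene_pipeline(
    seed: int = 0,
    scene: SceneConfig | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline on a synthetic anomaly-year scene."""
    pcfg = config or PipelineConfig()
    scfg = scene or SceneConfig(seed=seed, year_mode="anomaly")
    env = make_env_fields(scfg)
    schedule = make_call_schedule(scfg, env)

    # presence series from the schedule via a synthetic annotation log
    deployment = pres.DeploymentSpec(
        start=scfg.dates[0],
        end=scfg.dates[-1] + pd.Timedelta(hours=23, minutes=59),
        duty_on_min=8.0,
        lat=scfg.recorder_lat,
        lon=scfg.recorder_lon,
    )
    annotations = schedule_to_annotations(schedule, registry=scfg.species)
    hourly = pres.hourly_presence(annotations, deployment)
    daily = pres.daily_presence(hourly)
    community = pres.community_matrix(daily)

    # daily noise level at the shared frequency from one synthetic
    # recording per day (ambient quietens as ice cover grows)
    calib = CalibrationSpec()
    rec_cov = env.at_recorder(scfg.recorder_lat, scfg.recorder_lon)
    nl = {}
    rng_seeds = np.random.SeedSequence([scfg.seed, 0x17EC]).generate_state(len(rec_cov))
    noon = schedule[schedule.index.hour == 12]
    for i, (date, row) in enumerate(rec_cov.iterrows()):
        level = pcfg.open_water_noise_db - pcfg.ice_quieting_db * row["sic_prop"]
        present = [
            s
            for s in noon.columns
            if noon.loc[date + pd.Timedelta(hours=12), s] == 1
            and scfg.species_by_name(s).frequency_hz < pcfg.recording_fs_hz / 2
        ]
        counts = synth_recording(
            present,
            scfg.species,
            level,
            calib,
            duration_min=pcfg.recording_minutes,
            fs=pcfg.recording_fs_hz,
            received_level_db=100.0,
            seed=int(rng_seeds[i] % (2**31)),
        )
        psd = welch_psd(
            counts_to_pressure(counts, calib),
            pcfg.recording_fs_hz,
            segment_minutes=pcfg.recording_minutes,
            nfft=4096,
        )
        nl[date] = noise_at_frequency(psd, pcfg.shared_frequency_hz)
    noise_series = pd.Series(nl, name="NL_db").rename_axis("date")

    # monthly TL grids at the shared frequency
    bearings = np.arange(0.0, 360.0, pcfg.bearing_step_deg)
    months = sorted({d.to_period("M") for d in scfg.dates})
    tl_grids = {}
    for month in months:
        sst_month = env.sst.sel(time=str(month))
        slices = {}
        for b in bearings:
            s_env = extract_slice(
                env.bathymetry,
                scfg.recorder_lat,
                scfg.recorder_lon,
                b,
                length_m=pcfg.slice_length_m,
                range_step_m=5000.0,
                sst=sst_month,
                bottom=BottomSpec(),
            )
            slices[b] = trace_tl(
                s_env, pcfg.shared_frequency_hz, config=pcfg.tracer
            )
        tl_grids[month] = grid_tl(
            slices,
            scfg.recorder_lat,
            scfg.recorder_lon,
            nlat=pcfg.mesh_nlat,
            nlon=pcfg.mesh_nlon,
            frequency_hz=pcfg.shared_frequency_hz,
        )

    # daily audible masks and ice-constrained covariates
    rows = []
    areas = {}
    for date in rec_cov.index:
        tl = tl_grids[date.to_period("M")]
        snr = cov.snr_grid(tl, pcfg.shared_source_level_db, float(noise_series[date]))
        rec_mask = cov.audible_mask(
            snr, threshold_db=pcfg.snr_threshold_db, date=date, species="shared",
            frequency_hz=pcfg.shared_frequency_hz,
        )
        day_mask = cov.daily_mask([rec_mask])
        sic_d = env.sic.sel(time=date)
        stats = cov.constrained_stats(
            day_mask, sic_d, env.sst.sel(time=date), env.ssh.sel(time=date), env.bathymetry
        )
        stats.sic25_pct = cov.radius_sic(sic_d, scfg.recorder_lat, scfg.recorder_lon, 25.0)
        stats.sic100_pct = cov.radius_sic(sic_d, scfg.recorder_lat, scfg.recorder_lon, 100.0)
        rows.append(stats.to_dict())
        areas[date] = day_mask.area_km2
    covariate_df = pd.DataFrame(rows)
    area_series = pd.Series(areas, name="area_km2").rename_axis("date")

    # statistics: VIF screening then CCA on the shared covariate set
    pred = covariate_df.set_index("date")[["SST_mean", "SSH_mean", "vBAT", "SIC_prop"]]
    pred["month"] = pred.index.month
    pred = pred.dropna()
    common = community.index.intersection(pred.index)
    vifs = vif(pred.loc[common])
    cca_res = CCA(community.loc[common], pred.loc[common]).fit()

    return PipelineResult(
        config=scfg,
        env=env,
        schedule=schedule,
        daily=daily,
        community=community,
        covariates=covariate_df,
        vif=vifs,
        cca=cca_res,
        noise_series=noise_series,
        area_series=area_series,
    )
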