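"""Synthetic multi-sensor meat-spoilage datasets.

The raw study spectra are not publicly deposited, so this module generates
datasets with the statistical structure the downstream analysis assumes, at
the tabular level the pipeline consumes:

* a two-batch, two-packaging-condition, three-temperature storage design with
  sampling every 24-48 h and 2-10 replicates per sampling point;
* total viable counts (TVC, log CFU/g) following a three-phase logistic
  growth curve in log-count space (lag, temperature- and packaging-dependent
  exponential phase, plateau), starting around 4.5-6 log CFU/g and rising
  past the 7-8 log CFU/g spoilage range;
* an FTIR absorbance block on a uniform wavenumber grid whose TVC-linked
  signal is concentrated in the 1750-1400 cm^-1 region (amide bands), with
  per-row multiplicative gain and additive offset artifacts for SNV to
  remove;
* MSI (18 bands, 405-970 nm) and fluorescent MSIF (8 bands, 270-405 nm)
  blocks tabularised as per-band mean and sd of reflectance, with TVC-linked
  trend in the 450-700 nm MSI bands;
* per-modality *unique* latent factors, sampled independently of each other
  and of the target: each modality observes ``tvc + w_u * u_m`` along its
  TVC loading, so every single sensor has an irreducible error floor of about
  ``w_u`` while the floors are independent across sensors. This is the lever
  that gives multi-sensor fusion genuine headroom over the best single
  sensor, and :func:`oracle_signal_report` exports the generative weights so
  recovery tests can condition on it.

Everything is reproducible bit-for-bit from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .dataset_io import MultiModalDataset, SpectralBlock, save_dataset

__all__ = [
    "GrowthParams",
    "SimConfig",
    "simulate_growth",
    "simulate_dataset",
    "oracle_signal_report",
    "ftir_grid",
    "default_config",
    "small_config",
    "config_from_yaml",
    "config_to_yaml",
]

# Uniform FTIR step chosen so the closed interval [900, 2000] cm^-1 contains
# exactly 1141 grid points.
FTIR_STEP = 1100.0 / 1140.0

#: VideometerLab-style 18 monochromatic MSI bands (nm), 405-970 nm.
MSI_BANDS = (
    405.0, 435.0, 450.0, 470.0, 505.0, 525.0, 570.0, 590.0, 630.0,
    645.0, 660.0, 700.0, 780.0, 850.0, 870.0, 890.0, 940.0, 970.0,
)

#: 8 UV/blue fluorescence bands (nm), 270-405 nm.
MSIF_BANDS = (270.0, 290.0, 310.0, 330.0, 350.0, 370.0, 390.0, 405.0)

#: dimensionless shape constant: the logistic half-rise sits at
#: LOGISTIC_SHAPE / rate hours after the lag ends.
LOGISTIC_SHAPE = 4.0


def ftir_grid(lo: float = 400.0, hi: float = 4000.0) -> np.ndarray:
    """Uniform ascending wavenumber grid with exact endpoints at 900 and 2000.

    The fingerprint section is built with ``linspace(900, 2000, 1141)`` so the
    closed-interval restriction retains exactly 1141 features; the grid is
    extended on the same step to cover [lo, hi] within the 4000-400 cm^-1
    instrument range.
    """
    core = np.linspace(900.0, 2000.0, 1141)
    n_below = int(np.floor((900.0 - lo) / FTIR_STEP))
    n_above = int(np.floor((hi - 2000.0) / FTIR_STEP))
    below = 900.0 - FTIR_STEP * np.arange(n_below, 0, -1)
    above = 2000.0 + FTIR_STEP * np.arange(1, n_above + 1)
    return np.concatenate([below, core, above])


@dataclass(frozen=True)
class GrowthParams:
    """Three-phase logistic growth in log-count space.

    initial_load / max_load in log CFU/g; rate_at_ref is the logistic rate
    (1/h) at the 0 degC reference; temp_sensitivity is the multiplicative rate
    change per degC; lag in hours; condition_rate_factor in (0, 1] slows
    growth under protective packaging (1 = aerobic).
    """

    initial_load: float = 5.2
    max_load: float = 9.3
    rate_at_ref: float = 0.035
    temp_sensitivity: float = 1.12
    lag: float = 12.0
    condition_rate_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.initial_load >= self.max_load:
            raise ValueError("initial_load must be below max_load")
        if self.rate_at_ref <= 0:
            raise ValueError("rate_at_ref must be positive")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        if not (0 < self.condition_rate_factor <= 1):
            raise ValueError("condition_rate_factor must lie in (0, 1]")


def growth_curve(params: GrowthParams, temperature: float, times: np.ndarray) -> np.ndarray:
    """Noise-free expected TVC curve (log CFU/g) at the given temperature."""
    t = np.asarray(times, dtype=float)
    rate = (
        params.rate_at_ref
        * params.temp_sensitivity ** temperature
        * params.condition_rate_factor
    )
    t_half = LOGISTIC_SHAPE / rate
    tp = np.maximum(t - params.lag, 0.0)
    s = 1.0 / (1.0 + np.exp(-rate * (tp - t_half)))
    s0 = 1.0 / (1.0 + np.exp(rate * t_half))
    f = (s - s0) / (1.0 - s0)
    return params.initial_load + (params.max_load - params.initial_load) * f


def simulate_growth(
    params: GrowthParams,
    temperature: float,
    times: Sequence[float],
    seed: int,
    noise_sd: float = 0.25,
) -> np.ndarray:
    """TVC observations along a storage time course.

    Expected curve: flat during the lag, logistic rise (rate scaled by
    temperature and packaging), plateau at ``max_load``; seeded replicate
    noise is added and values are clipped to [0, max_load + 1].
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be nonempty")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    y = growth_curve(params, temperature, t)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return np.clip(y, 0.0, params.max_load + 1.0)


def _default_sampling_times() -> dict:
    # 24 h sampling out to temperature-dependent end-of-monitoring horizons.
    return {
        0.0: tuple(float(t) for t in range(0, 217, 24)),
        5.0: tuple(float(t) for t in range(0, 193, 24)),
        10.0: tuple(float(t) for t in range(0, 97, 24)),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full design + signal/noise specification of one synthetic study.

    The per-modality ``unique_signal_sd`` entries are the standard deviations
    (log CFU/g equivalent) of each sensor's unique latent distortion; set one
    to zero to make that sensor a perfect TVC channel. ``signal_amplitude``
    scales the TVC loading of each block; ``noise_sd`` is iid per-feature
    measurement noise; ``gain_sd`` / ``offset_sd`` are the per-row
    multiplicative/additive baseline artifacts SNV is supposed to remove.
    """

    meat_type: str = "chicken"
    conditions: tuple = ("aerobic", "vacuum")
    temperatures: tuple = (0.0, 5.0, 10.0)
    sampling_times: Mapping[float, tuple] = field(default_factory=_default_sampling_times)
    batches: int = 2
    replicates_per_point: tuple = (2, 4)
    batch_tvc_offset: float = -0.7
    batch_gain_shift: float = 0.02
    growth: GrowthParams = field(default_factory=GrowthParams)
    condition_rate_factors: Mapping[str, float] = field(
        default_factory=lambda: {"aerobic": 1.0, "vacuum": 0.6}
    )
    ftir_lo: float = 400.0
    ftir_hi: float = 4000.0
    msi_bands: tuple = MSI_BANDS
    msif_bands: tuple = MSIF_BANDS
    tvc_noise_sd: float = 0.25
    signal_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {"FTIR": 0.03, "MSI": 1.2, "MSIF": 0.5}
    )
    unique_signal_sd: Mapping[str, float] = field(
        default_factory=lambda: {"FTIR": 0.40, "MSI": 0.28, "MSIF": 0.55}
    )
    shared_nuisance_sd: float = 0.3
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"FTIR": 0.01, "MSI": 0.4, "MSIF": 0.4}
    )
    gain_sd: float = 0.08
    offset_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.msi_bands or not self.msif_bands:
            raise ValueError("modality band lists must be nonempty")
        if not (405.0 <= min(self.msi_bands) and max(self.msi_bands) <= 970.0):
            raise ValueError("MSI bands must lie within 405-970 nm")
        if not (270.0 <= min(self.msif_bands) and max(self.msif_bands) <= 405.0):
            raise ValueError("MSIF bands must lie within 270-405 nm")
        if not (400.0 <= self.ftir_lo < self.ftir_hi <= 4000.0):
            raise ValueError("FTIR grid must lie within 4000-400 cm^-1")
        for temp, times in self.sampling_times.items():
            t = np.asarray(times, dtype=float)
            if t.size == 0 or (t.size > 1 and not np.all(np.diff(t) > 0)):
                raise ValueError(
                    f"sampling_times[{temp}] must be nonempty, strictly increasing"
                )
        lo, hi = self.replicates_per_point
        if not (1 <= lo <= hi):
            raise ValueError("replicates_per_point must be (lo, hi) with 1 <= lo <= hi")


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The standard study-scale configuration (~290 samples)."""
    return replace(SimConfig(seed=seed), **overrides) if overrides else SimConfig(seed=seed)


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced design (~150 samples) for fast experiments and tests."""
    times = {
        0.0: tuple(float(t) for t in range(0, 217, 48)),
        5.0: tuple(float(t) for t in range(0, 193, 48)),
        10.0: tuple(float(t) for t in range(0, 97, 48)),
    }
    cfg = SimConfig(seed=seed, sampling_times=times, replicates_per_point=(2, 3))
    return replace(cfg, **overrides) if overrides else cfg


def _gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def _ftir_profiles(grid: np.ndarray, amplitude: float) -> dict:
    baseline = (
        0.5
        + 0.4 * _gauss(grid, 1650.0, 120.0)
        + 0.3 * _gauss(grid, 1080.0, 150.0)
        + 0.6 * _gauss(grid, 3300.0, 250.0)
        + 0.05 * np.sin(grid / 300.0)
    )
    # TVC loading concentrated in the 1750-1400 cm^-1 amide region.
    tvc = amplitude * (
        0.8 * _gauss(grid, 1545.0, 40.0)
        + 1.0 * _gauss(grid, 1640.0, 35.0)
        + 0.3 * _gauss(grid, 1450.0, 50.0)
    )
    nuisance = amplitude * (
        0.7 * _gauss(grid, 1080.0, 60.0) + 0.4 * _gauss(grid, 2930.0, 50.0)
    )
    return {"baseline": baseline, "tvc": tvc, "nuisance": nuisance}


def _band_profiles(bands: np.ndarray, amplitude: float, fluorescent: bool) -> dict:
    """Mean+sd feature profiles for an imaging block (features = 2 x bands)."""
    if fluorescent:
        base_mean = 10.0 + 5.0 * _gauss(bands, 300.0, 60.0)
        tvc_mean = amplitude * _gauss(bands, 330.0, 45.0)
        nuis_mean = 0.4 * amplitude * _gauss(bands, 380.0, 40.0)
    else:
        base_mean = 30.0 + 20.0 * _gauss(bands, 480.0, 80.0) + 5.0 * np.sin(bands / 90.0)
        # TVC-linked trend concentrated in the 450-700 nm pigment region.
        tvc_mean = amplitude * (
            1.0 * _gauss(bands, 590.0, 60.0) + 0.7 * _gauss(bands, 630.0, 40.0)
        )
        nuis_mean = 0.4 * amplitude * _gauss(bands, 850.0, 80.0)
    base_sd = 0.15 * base_mean
    tvc_sd = 0.25 * tvc_mean
    nuis_sd = 0.25 * nuis_mean
    return {
        "baseline": np.concatenate([base_mean, base_sd]),
        "tvc": np.concatenate([tvc_mean, tvc_sd]),
        "nuisance": np.concatenate([nuis_mean, nuis_sd]),
    }


def _modality_profiles(config: SimConfig) -> dict:
    grid = ftir_grid(config.ftir_lo, config.ftir_hi)
    profiles = {
        "FTIR": _ftir_profiles(grid, config.signal_amplitude["FTIR"]),
        "MSI": _band_profiles(
            np.asarray(config.msi_bands), config.signal_amplitude["MSI"], False
        ),
        "MSIF": _band_profiles(
            np.asarray(config.msif_bands), config.signal_amplitude["MSIF"], True
        ),
    }
    axes = {
        "FTIR": list(grid),
        "MSI": [f"msi_{int(b)}nm_mean" for b in config.msi_bands]
        + [f"msi_{int(b)}nm_sd" for b in config.msi_bands],
        "MSIF": [f"msif_{int(b)}nm_mean" for b in config.msif_bands]
        + [f"msif_{int(b)}nm_sd" for b in config.msif_bands],
    }
    return {"profiles": profiles, "axes": axes}


def _design_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Enumerate samples: one row per (condition, temperature, time, batch, rep)."""
    rows = []
    for cond in config.conditions:
        for temp in config.temperatures:
            for time in config.sampling_times[temp]:
                for batch in range(1, config.batches + 1):
                    lo, hi = config.replicates_per_point
                    n_rep = int(rng.integers(lo, hi + 1))
                    for rep in range(1, n_rep + 1):
                        rows.append(
                            {
                                "sample_id": f"{config.meat_type}_{cond}_"
                                f"{int(temp)}_{int(time)}_{batch}_{rep}",
                                "meat_type": config.meat_type,
                                "condition": cond,
                                "temperature": float(temp),
                                "time": float(time),
                                "batch": batch,
                                "replicate": rep,
                            }
                        )
    meta = pd.DataFrame(rows)
    if meta["sample_id"].duplicated().any():
        raise ValueError("generated duplicate sample IDs")
    return meta


def simulate_dataset(config: SimConfig) -> MultiModalDataset:
    """Generate an aligned multi-sensor dataset from the configured design."""
    rng = np.random.default_rng(config.seed)
    meta = _design_table(config, rng)
    n = len(meta)

    # -- targets ------------------------------------------------------------
    crf = meta["condition"].map(dict(config.condition_rate_factors)).to_numpy(float)
    tvc_mean = np.empty(n)
    for i, (temp, time, f) in enumerate(
        zip(meta["temperature"], meta["time"], crf)
    ):
        params = replace(config.growth, condition_rate_factor=float(f))
        tvc_mean[i] = growth_curve(params, float(temp), np.asarray([time]))[0]
    batch2 = (meta["batch"] == 2).to_numpy()
    tvc = tvc_mean + np.where(batch2, config.batch_tvc_offset, 0.0)
    tvc = tvc + rng.normal(0.0, config.tvc_noise_sd, size=n)
    tvc = np.clip(tvc, 0.0, config.growth.max_load + 1.0)
    meta["tvc"] = tvc

    # -- latent factors -----------------------------------------------------
    uniques = {m: rng.normal(0.0, 1.0, size=n) for m in ("MSI", "FTIR", "MSIF")}
    shared_nuisance = rng.normal(0.0, 1.0, size=n)

    prof = _modality_profiles(config)
    blocks = {}
    for m in ("FTIR", "MSI", "MSIF"):
        p = prof["profiles"][m]
        w_u = float(config.unique_signal_sd[m])
        signal_level = tvc + w_u * uniques[m]
        X = (
            p["baseline"][np.newaxis, :]
            + signal_level[:, np.newaxis] * p["tvc"][np.newaxis, :]
            + (config.shared_nuisance_sd * shared_nuisance)[:, np.newaxis]
            * p["nuisance"][np.newaxis, :]
        )
        if config.noise_sd[m] > 0:
            X = X + rng.normal(0.0, config.noise_sd[m], size=X.shape)
        # row-level multiplicative gain and additive offset artifacts
        gain = np.ones(n)
        offset = np.zeros(n)
        if config.gain_sd > 0:
            gain = np.abs(1.0 + rng.normal(0.0, config.gain_sd, size=n))
        if config.offset_sd > 0:
            offset = rng.normal(0.0, config.offset_sd, size=n)
        if config.batch_gain_shift != 0.0:
            gain = gain * np.where(batch2, 1.0 + config.batch_gain_shift, 1.0)
        X = gain[:, np.newaxis] * X + offset[:, np.newaxis]
        blocks[m] = SpectralBlock(
            modality=m,
            feature_axis=prof["axes"][m],
            matrix=X,
            sample_ids=list(meta["sample_id"]),
        )
    return MultiModalDataset(blocks=blocks, metadata=meta)


def oracle_signal_report(config: SimConfig) -> pd.DataFrame:
    """Export the exact generative weights, keyed by modality and feature.

    Columns: ``tvc_loading`` (the coefficient multiplying TVC in that
    feature), ``unique_loading`` (the coefficient multiplying the modality's
    unique latent factor = ``unique_signal_sd * tvc_loading``), and
    ``nuisance_loading``. Deterministic in the config; regenerating from the
    same seed yields an identical table.
    """
    prof = _modality_profiles(config)
    frames = []
    for m in ("MSI", "FTIR", "MSIF"):
        p = prof["profiles"][m]
        axis = prof["axes"][m]
        labels = [
            f"{v:.4f}" if isinstance(v, (int, float, np.floating)) else str(v)
            for v in axis
        ]
        w_u = float(config.unique_signal_sd[m])
        frames.append(
            pd.DataFrame(
                {
                    "modality": m,
                    "feature": labels,
                    "tvc_loading": p["tvc"],
                    "unique_loading": w_u * p["tvc"],
                    "nuisance_loading": config.shared_nuisance_sd * p["nuisance"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# -- YAML config ------------------------------------------------------------

def config_to_yaml(config: SimConfig, path) -> None:
    d = {
        "meat_type": config.meat_type,
        "conditions": list(config.conditions),
        "temperatures": list(config.temperatures),
        "sampling_times": {float(k): list(v) for k, v in config.sampling_times.items()},
        "batches": config.batches,
        "replicates_per_point": list(config.replicates_per_point),
        "batch_tvc_offset": config.batch_tvc_offset,
        "batch_gain_shift": config.batch_gain_shift,
        "growth": {
            "initial_load": config.growth.initial_load,
            "max_load": config.growth.max_load,
            "rate_at_ref": config.growth.rate_at_ref,
            "temp_sensitivity": config.growth.temp_sensitivity,
            "lag": config.growth.lag,
            "condition_rate_factor": config.growth.condition_rate_factor,
        },
        "condition_rate_factors": dict(config.condition_rate_factors),
        "ftir_lo": config.ftir_lo,
        "ftir_hi": config.ftir_hi,
        "msi_bands": list(config.msi_bands),
        "msif_bands": list(config.msif_bands),
        "tvc_noise_sd": config.tvc_noise_sd,
        "signal_amplitude": dict(config.signal_amplitude),
        "unique_signal_sd": dict(config.unique_signal_sd),
        "shared_nuisance_sd": config.shared_nuisance_sd,
        "noise_sd": dict(config.noise_sd),
        "gain_sd": config.gain_sd,
        "offset_sd": config.offset_sd,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    growth = GrowthParams(**d.pop("growth", {}))
    for key in ("conditions", "temperatures", "msi_bands", "msif_bands",
                "replicates_per_point"):
        if key in d:
            d[key] = tuple(d[key])
    if "sampling_times" in d:
        d["sampling_times"] = {
            float(k): tuple(float(t) for t in v) for k, v in d["sampling_times"].items()
        }
    return SimConfig(growth=growth, **d)


def write_dataset(config: SimConfig, directory) -> dict:
    """Simulate and write one CSV per modality plus metadata.csv."""
    return save_dataset(simulate_dataset(config), directory)
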