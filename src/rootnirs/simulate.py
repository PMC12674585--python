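"""Synthetic field-trial traits and pocket-NIRS-like spectra.

The generator emulates the data regime of a handheld 740-1070 nm
spectrometer used to phenotype cassava root quality across multi-environment
trials:

* Plot-level traits follow the standard multi-environment mixed-model
  decomposition: overall mean, fixed environment effect, random clone,
  replication-within-environment, block-within-replication,
  clone-by-environment and residual effects, each with its own variance.
  Clone effects are drawn once and reused across environments.
* DMCg (gravimetric dry matter) is generated as DMCo (oven dry matter) plus
  extra zero-mean noise: the gravimetric field method is the noisier proxy
  for the same underlying composition.
* Spectra are trait-weighted Gaussian absorption bands distorted by
  multiplicative scatter (per-reading slope), additive and linear baseline
  drift, and channel noise. "Fresh" root surfaces yield noisier, more
  scatter-contaminated readings than homogenised "mashed" pulp, and fresh
  readings additionally perturb the trait values per reading to mimic
  within-root heterogeneity. Defaults: 47 readings per plot for fresh
  samples, 4 for mashed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import SAMPLE_TYPES, SpectralDataset, validate_trait_table
from .exceptions import ConfigurationError

__all__ = [
    "AbsorptionBand",
    "ScatterSpec",
    "SimulationConfig",
    "simulate_traits",
    "simulate_spectra",
    "inject_spectral_outliers",
]


@dataclass(frozen=True)
class AbsorptionBand:
    """Gaussian absorption band linking trait values to absorbance.

    ``loading_per_trait`` maps a trait name to the absorbance contributed per
    trait percentage point at the band centre.
    """

    center: float  # nm
    width: float  # nm, Gaussian sd
    loading_per_trait: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError("band width must be > 0")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        z = (np.asarray(wavelengths, dtype=float) - self.center) / self.width
        return np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class ScatterSpec:
    """Per-reading scatter/baseline distortion magnitudes (absorbance units)."""

    slope_sd: float = 0.0  # multiplicative, around 1
    offset_sd: float = 0.0  # additive baseline
    tilt_sd: float = 0.0  # linear baseline across the grid


def _default_bands() -> list[AbsorptionBand]:
    # Domain-plausible stand-ins inside the 740-1070 nm window: the 970 nm
    # O-H (water) overtone falls as dry matter rises, a C-H/starch band near
    # 910 nm tracks starch, and a secondary combination band sits at 1020 nm.
    return [
        AbsorptionBand(970.0, 35.0, {"DMCo": -0.0040, "StC": -0.0010}),
        AbsorptionBand(910.0, 25.0, {"StC": 0.0040, "DMCo": 0.0018}),
        AbsorptionBand(1020.0, 30.0, {"DMCo": 0.0030}),
    ]


def default_baseline(wavelengths: np.ndarray) -> np.ndarray:
    """Common absorbance profile shared by every sample (arbitrary smooth
    shape inside the device window, ~0.5 AU): trait information must ride on
    top of it as band shape, as in real diffuse-reflectance spectra, so
    multiplicative scatter acts on a large common amplitude."""
    wl = np.asarray(wavelengths, dtype=float)
    rel = (wl - wl[0]) / (wl[-1] - wl[0])
    return 0.45 + 0.10 * rel + 0.15 * np.exp(-0.5 * ((wl - 965.0) / 70.0) ** 2)


def _default_variance_components() -> dict:
    # trait-percent^2 units; genetic signal dominant, moderate plot noise
    return {
        "StC": dict(sigma2_g=4.0, sigma2_r=0.5, sigma2_k=0.25, sigma2_ge=1.0, sigma2_e=2.0),
        "DMCo": dict(sigma2_g=4.0, sigma2_r=0.5, sigma2_k=0.25, sigma2_ge=1.0, sigma2_e=1.0),
    }


VARIANCE_KEYS = ("sigma2_g", "sigma2_r", "sigma2_k", "sigma2_ge", "sigma2_e")


@dataclass
class SimulationConfig:
    """Complete description of a simulated study.

    Defaults mirror the emulated study conditions: randomized complete block
    trials with 2 replications, a 740-1070 nm grid at 1 nm (331 channels),
    47 fresh / 4 mashed readings per plot, and a mashed regime that is less
    scatter-contaminated and less noisy than the fresh regime.
    """

    n_clones: int = 100
    n_envs: int = 2
    n_reps: int = 2
    n_blocks_per_rep: int = 2
    variance_components: dict = field(default_factory=_default_variance_components)
    trait_means: dict = field(default_factory=lambda: {"StC": 30.0, "DMCo": 35.0})
    env_effect_sd: float = 2.0  # fixed env effects drawn once from N(0, sd^2)
    dmcg_noise_sd: float = 1.5  # DMCg = DMCo + N(0, sd^2)
    wavelength_grid: np.ndarray = field(
        default_factory=lambda: np.arange(740.0, 1071.0, 1.0)
    )
    bands: list = field(default_factory=_default_bands)
    baseline_amplitude: float = 1.0  # scales the common absorbance profile
    scatter: dict = field(
        default_factory=lambda: {
            "fresh": ScatterSpec(slope_sd=0.08, offset_sd=0.040, tilt_sd=0.030),
            "mashed": ScatterSpec(slope_sd=0.02, offset_sd=0.010, tilt_sd=0.008),
        }
    )
    noise_sd: dict = field(default_factory=lambda: {"fresh": 0.008, "mashed": 0.002})
    readings_per_plot: dict = field(default_factory=lambda: {"fresh": 47, "mashed": 4})
    fresh_trait_jitter_sd: float = 1.5  # per-reading trait perturbation, percent
    # Systematic per-plot trait offset for fresh surfaces: the scanned root
    # section misrepresents whole-root composition, and replicate readings of
    # the same surface share the error, so it does not average out.
    fresh_plot_bias_sd: float = 2.5
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        for name in ("n_clones", "n_envs", "n_reps", "n_blocks_per_rep"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        wl = np.asarray(self.wavelength_grid, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ConfigurationError("wavelength_grid must be a strictly increasing vector")
        for trait, comps in self.variance_components.items():
            for key in VARIANCE_KEYS:
                if comps.get(key, 0.0) < 0:
                    raise ConfigurationError(f"{trait}.{key} must be >= 0")
        for st, n in self.readings_per_plot.items():
            if st not in SAMPLE_TYPES:
                raise ConfigurationError(f"unknown sample type {st!r}")
            if int(n) < 1:
                raise ConfigurationError("readings_per_plot must be >= 1")
        if self.dmcg_noise_sd < 0 or self.env_effect_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        return self

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def _rng(config: SimulationConfig, *stream) -> np.random.Generator:
    """Independent, reproducible stream derived from the config seed."""
    digest = [zlib.crc32(str(s).encode("utf-8")) for s in stream]
    return np.random.default_rng(np.random.SeedSequence([int(config.seed)] + digest))


def simulate_traits(config: SimulationConfig) -> pd.DataFrame:
    """Generate a plot-level trait table under the mixed-model decomposition.

    Each plot value is ``mean + env effect (fixed, drawn once per environment)
    + clone + rep-within-env + block-within-rep + clone-x-env + residual``
    with independent zero-mean Gaussian draws at the configured variances.
    The same clone effect is reused across environments. DMCg is DMCo plus
    its own zero-mean measurement noise.
    """
    config.validate()
    rng = _rng(config, "traits")
    n_c, n_e, n_r, n_b = (
        int(config.n_clones),
        int(config.n_envs),
        int(config.n_reps),
        int(config.n_blocks_per_rep),
    )

    # Fixed environment effects: drawn once, then held fixed for this config.
    env_effects = {
        trait: rng.normal(0.0, config.env_effect_sd, size=n_e)
        for trait in config.trait_means
    }

    effects = {}
    for trait, comps in config.variance_components.items():
        effects[trait] = dict(
            g=rng.normal(0.0, math.sqrt(comps.get("sigma2_g", 0.0)), size=n_c),
            r=rng.normal(0.0, math.sqrt(comps.get("sigma2_r", 0.0)), size=(n_e, n_r)),
            k=rng.normal(
                0.0, math.sqrt(comps.get("sigma2_k", 0.0)), size=(n_e, n_r, n_b)
            ),
            ge=rng.normal(0.0, math.sqrt(comps.get("sigma2_ge", 0.0)), size=(n_c, n_e)),
            e=rng.normal(
                0.0, math.sqrt(comps.get("sigma2_e", 0.0)), size=(n_c, n_e, n_r)
            ),
        )

    rows = []
    for j in range(n_e):
        for l in range(n_r):
            for i in range(n_c):
                k = i % n_b  # clones spread across blocks within each replication
                row = dict(
                    clone_id=f"C{i + 1:04d}",
                    env_id=f"E{j + 1}",
                    rep_id=f"R{l + 1}",
                    block_id=f"B{k + 1}",
                    plot_id=f"E{j + 1}_R{l + 1}_C{i + 1:04d}",
                )
                for trait, mean in config.trait_means.items():
                    eff = effects[trait]
                    row[trait] = (
                        mean
                        + env_effects[trait][j]
                        + eff["g"][i]
                        + eff["r"][j, l]
                        + eff["k"][j, l, k]
                        + eff["ge"][i, j]
                        + eff["e"][i, j, l]
                    )
                rows.append(row)
    traits = pd.DataFrame(rows)
    dmcg_rng = _rng(config, "dmcg")
    traits["DMCg"] = traits["DMCo"] + dmcg_rng.normal(
        0.0, config.dmcg_noise_sd, size=len(traits)
    )
    return validate_trait_table(traits)


def clean_spectrum(trait_values: dict, config: SimulationConfig) -> np.ndarray:
    """Noise-free absorbance for given trait values (sum of weighted bands)."""
    wl = np.asarray(config.wavelength_grid, dtype=float)
    out = np.zeros_like(wl)
    for band in config.bands:
        loading = sum(
            coef * float(trait_values.get(trait, 0.0))
            for trait, coef in band.loading_per_trait.items()
        )
        out += loading * band.profile(wl)
    return out


def simulate_spectra(
    traits: pd.DataFrame, sample_type: str, config: SimulationConfig
) -> SpectralDataset:
    """Generate per-reading spectra for every plot in ``traits``.

    Each reading r of plot p is
    ``a_r * (s0 + clean(traits_p)) + b_r + c_r * (wl - mid)/span + noise``
    where ``s0`` is the common baseline absorbance profile and
    ``a_r ~ 1 + N(0, slope_sd)``, ``b_r ~ N(0, offset_sd)``,
    ``c_r ~ N(0, tilt_sd)`` and iid channel noise. The fresh regime draws a
    per-reading perturbation of the trait values (within-root heterogeneity)
    on top of its larger scatter.
    """
    if sample_type not in SAMPLE_TYPES:
        raise ConfigurationError(f"unknown sample_type {sample_type!r}")
    config.validate()
    rng = _rng(config, "spectra", sample_type)
    wl = np.asarray(config.wavelength_grid, dtype=float)
    mid, span = wl[len(wl) // 2], wl[-1] - wl[0]
    ramp = (wl - mid) / span
    scatter = config.scatter[sample_type]
    noise_sd = float(config.noise_sd[sample_type])
    base_profile = config.baseline_amplitude * default_baseline(wl)
    n_read = int(config.readings_per_plot[sample_type])
    jitter_sd = config.fresh_trait_jitter_sd if sample_type == "fresh" else 0.0
    plot_bias_sd = config.fresh_plot_bias_sd if sample_type == "fresh" else 0.0

    spectral_traits = [t for t in ("StC", "DMCo") if t in traits.columns]
    records, spectra = [], []
    for _, plot in traits.iterrows():
        base = {t: float(plot[t]) for t in spectral_traits}
        if plot_bias_sd > 0:
            # shared by all readings of this plot; does not average out
            base = {t: v + rng.normal(0.0, plot_bias_sd) for t, v in base.items()}
        for r in range(n_read):
            if jitter_sd > 0:
                values = {
                    t: v + rng.normal(0.0, jitter_sd) for t, v in base.items()
                }
            else:
                values = base
            clean = base_profile + clean_spectrum(values, config)
            a = 1.0 + rng.normal(0.0, scatter.slope_sd)
            b = rng.normal(0.0, scatter.offset_sd)
            c = rng.normal(0.0, scatter.tilt_sd)
            noise = (
                rng.normal(0.0, noise_sd, size=wl.size) if noise_sd > 0 else 0.0
            )
            spectra.append(a * clean + b + c * ramp + noise)
            records.append(
                dict(
                    reading_id=f"{plot['plot_id']}_{sample_type}_{r + 1:03d}",
                    plot_id=plot["plot_id"],
                    sample_type=sample_type,
                )
            )
    return SpectralDataset(
        wavelengths=wl,
        absorbance=np.asarray(spectra),
        meta=pd.DataFrame(records),
    )


def inject_spectral_outliers(
    ds: SpectralDataset, fraction: float, magnitude: float, seed: int
) -> tuple[SpectralDataset, list[str]]:
    """Offset ``ceil(fraction * n)`` randomly chosen readings by ``magnitude``
    absorbance across all channels; returns the perturbed dataset and the
    flagged reading ids."""
    if not 0 <= fraction <= 1:
        raise ConfigurationError("fraction must be in [0, 1]")
    n_out = math.ceil(fraction * ds.n_readings)
    if n_out == 0:
        return ds, []
    rng = np.random.default_rng(seed)
    idx = rng.choice(ds.n_readings, size=n_out, replace=False)
    absorbance = ds.absorbance.copy()
    absorbance[idx] += magnitude
    flagged = ds.meta["reading_id"].iloc[np.sort(idx)].tolist()
    return ds.with_absorbance(absorbance), flagged
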