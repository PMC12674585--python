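"""In-memory containers and CSV I/O for spectra and trait tables.

Two tabular objects flow through the pipeline:

``SpectralDataset``
    An absorbance matrix (readings x wavelength channels) plus the wavelength
    grid in nm and per-reading metadata (reading id, plot id, sample type).
    Pre-treatments are recorded in ``provenance`` so a treated dataset can be
    reproduced from the raw one.

Trait tables
    Plain :class:`pandas.DataFrame` objects with one row per field plot and
    the design labels (clone, environment, replication, block) alongside the
    measured traits StC, DMCo and DMCg (all in percent).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

TRAIT_NAMES = ("StC", "DMCo", "DMCg")
DESIGN_COLUMNS = ("clone_id", "env_id", "rep_id", "block_id", "plot_id")
SAMPLE_TYPES = ("fresh", "mashed")
META_COLUMNS = ("reading_id", "plot_id", "sample_type")


@dataclass
class SpectralDataset:
    """Absorbance readings on a common wavelength grid.

    Parameters
    ----------
    wavelengths : ndarray, shape (n_channels,)
        Strictly increasing wavelength grid in nm.
    absorbance : ndarray, shape (n_readings, n_channels)
        Absorbance values; no missing entries.
    meta : DataFrame
        One row per reading with columns ``reading_id``, ``plot_id`` and
        ``sample_type``.
    provenance : tuple
        Sequence of treatment descriptors applied so far (oldest first).
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame
    provenance: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ConfigurationError("absorbance must be 2-D (readings x channels)")
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ConfigurationError(
                f"absorbance has {self.absorbance.shape[1]} columns but the grid "
                f"has {self.wavelengths.size} wavelengths"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ConfigurationError("wavelength grid must be strictly increasing")
        if len(self.meta) != self.absorbance.shape[0]:
            raise ConfigurationError("meta rows must match absorbance rows")
        missing = set(META_COLUMNS) - set(self.meta.columns)
        if missing:
            raise ConfigurationError(f"meta missing columns: {sorted(missing)}")
        if np.isnan(self.absorbance).any():
            raise ConfigurationError("absorbance contains missing values")
        types = set(self.meta["sample_type"].unique())
        if len(types) > 1:
            raise ConfigurationError(f"mixed sample types in one dataset: {types}")

    @property
    def n_readings(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    @property
    def sample_type(self) -> str:
        return str(self.meta["sample_type"].iloc[0]) if len(self.meta) else ""

    def with_absorbance(self, absorbance: np.ndarray, step=None) -> "SpectralDataset":
        """Return a copy with new absorbance values, optionally appending a
        provenance step."""
        prov = self.provenance + (step,) if step is not None else self.provenance
        return replace(
            self,
            absorbance=np.asarray(absorbance, dtype=float),
            meta=self.meta.reset_index(drop=True),
            provenance=prov,
        )

    def subset(self, row_mask: np.ndarray) -> "SpectralDataset":
        return replace(
            self,
            absorbance=self.absorbance[row_mask],
            meta=self.meta.loc[row_mask].reset_index(drop=True),
        )


def validate_trait_table(traits: pd.DataFrame) -> pd.DataFrame:
    """Check the plot-level trait table schema and invariants."""
    required = set(DESIGN_COLUMNS) | set(TRAIT_NAMES)
    missing = required - set(traits.columns)
    if missing:
        raise ConfigurationError(f"trait table missing columns: {sorted(missing)}")
    if traits["plot_id"].duplicated().any():
        raise ConfigurationError("plot_id values must be unique")
    cell = traits[["clone_id", "env_id", "rep_id"]]
    if cell.duplicated().any():
        raise ConfigurationError("each (clone, env, rep) may appear at most once")
    for trait in ("StC", "DMCo"):
        vals = traits[trait].to_numpy(dtype=float)
        if np.any((vals <= 0) | (vals >= 100)):
            raise ConfigurationError(f"{trait} values must lie strictly in (0, 100)")
    return traits


def wavelength_columns(wavelengths: np.ndarray) -> list[str]:
    return [f"wl_{wl:g}" for wl in np.asarray(wavelengths)]


def write_spectra_csv(ds: SpectralDataset, path) -> None:
    """Write a SpectralDataset as wide CSV (RFC-4180, '.' decimal, UTF-8)."""
    frame = pd.concat(
        [
            ds.meta[list(META_COLUMNS)].reset_index(drop=True),
            pd.DataFrame(ds.absorbance, columns=wavelength_columns(ds.wavelengths)),
        ],
        axis=1,
    )
    frame.to_csv(path, index=False)


def read_spectra_csv(path) -> SpectralDataset:
    frame = pd.read_csv(path)
    wl_cols = [c for c in frame.columns if c.startswith("wl_")]
    wavelengths = np.array([float(c[3:]) for c in wl_cols])
    return SpectralDataset(
        wavelengths=wavelengths,
        absorbance=frame[wl_cols].to_numpy(dtype=float),
        meta=frame[list(META_COLUMNS)].copy(),
    )


def write_traits_csv(traits: pd.DataFrame, path) -> None:
    cols = list(DESIGN_COLUMNS) + list(TRAIT_NAMES)
    traits[cols].to_csv(path, index=False)


def read_traits_csv(path) -> pd.DataFrame:
    return validate_trait_table(pd.read_csv(path))
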