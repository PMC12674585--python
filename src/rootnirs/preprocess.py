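"""Spectral pre-treatments and outlier screening.

Implements the treatment set compared in the calibration study:

====== =======================================================
name   composition (applied left to right)
====== =======================================================
raw    identity
d1     gap-segment first derivative (window 11, segment 7)
snv    standard normal variate, per spectrum
msc    multiplicative scatter correction against a reference
d1_dt  gap-segment derivative, then polynomial detrend
d1_msc gap-segment derivative, then MSC
sg_snv Savitzky-Golay smoothing (11-point, cubic), then
       gap-segment derivative, then SNV
====== =======================================================

The "first derivative" is the gap-segment derivative: the slope between the
means of two ``segment``-channel windows separated by a gap whose span is set
by ``window``, expressed per nm. A plain two-point finite difference is
available as :func:`finite_difference` for comparison but is not part of any
named treatment.

Outlier screening uses per-channel Tukey fences (k times the IQR beyond the
quartiles, type-7 quartile interpolation); a reading is flagged when more
than ``channel_fraction`` of its channels fall outside the fences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .datasets import SpectralDataset
from .exceptions import ConfigurationError, DegenerateInputError, SizingError

TREATMENT_NAMES = ("raw", "d1", "snv", "msc", "d1_dt", "d1_msc", "sg_snv")

DEFAULT_PARAMS = dict(
    sg_window=11,
    sg_polyorder=3,
    gap_window=11,
    gap_segment=7,
    detrend_degree=2,
)


@dataclass(frozen=True)
class TreatmentSpec:
    """A named pre-treatment configuration."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in TREATMENT_NAMES:
            raise ConfigurationError(
                f"unknown treatment {self.name!r}; choose from {TREATMENT_NAMES}"
            )
        p = self.resolved_params()
        if p["sg_window"] % 2 == 0 or p["sg_window"] <= p["sg_polyorder"]:
            raise ConfigurationError("sg_window must be odd and > sg_polyorder")
        if p["gap_window"] < 1 or p["gap_segment"] < 1:
            raise ConfigurationError("gap_window and gap_segment must be >= 1")

    def resolved_params(self) -> dict:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        return merged


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre to mean 0, scale to unit sample sd."""
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise SizingError("snv needs a 1-D spectrum with >= 2 channels")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant spectrum has no SNV transform")
    return (x - x.mean()) / sd


def _snv_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(snv, 1, np.asarray(X, dtype=float))


def msc_fit_reference(X: np.ndarray) -> np.ndarray:
    """Column-wise mean spectrum used as the MSC reference."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise SizingError("MSC needs >= 2 spectra to form a mean reference")
    return X.mean(axis=0)


def msc_transform(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Correct each spectrum x by the OLS fit x = b0 + b1*ref: (x - b0)/b1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise DegenerateInputError("constant MSC reference")
    out = np.empty_like(X)
    for i, x in enumerate(X):
        b1 = float(ref_c @ (x - x.mean())) / denom
        if b1 == 0:
            raise DegenerateInputError(
                f"spectrum {i} is uncorrelated with the MSC reference"
            )
        b0 = x.mean() - b1 * ref.mean()
        out[i] = (x - b0) / b1
    return out


def msc(ds: SpectralDataset, reference: np.ndarray | None = None) -> SpectralDataset:
    """Multiplicative scatter correction of a dataset.

    When ``reference`` is omitted it defaults to the dataset's mean spectrum.
    The reference actually used is stored in provenance so holdout spectra
    can be corrected against the calibration reference.
    """
    ref = msc_fit_reference(ds.absorbance) if reference is None else np.asarray(reference, float)
    corrected = msc_transform(ds.absorbance, ref)
    return ds.with_absorbance(corrected, step=("msc", {"reference": ref.tolist()}))


def savitzky_golay(
    spectrum: np.ndarray,
    window: int = 11,
    polyorder: int = 3,
    deriv_order: int = 0,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing / differentiation.

    Each point is replaced by the ``deriv_order``-th derivative of the local
    least-squares polynomial at the window centre; derivatives are scaled by
    the channel spacing ``delta`` (per-nm units). Edge points come from a
    polynomial fitted to the truncated (asymmetric) window, so the output has
    the input's length.
    """
    x = np.asarray(spectrum, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ConfigurationError("window must be odd and > polyorder")
    if x.size < window:
        raise SizingError(f"spectrum length {x.size} < window {window}")
    return savgol_filter(
        x, window_length=window, polyorder=polyorder, deriv=deriv_order,
        delta=delta, mode="interp",
    )


def gap_segment_derivative(
    spectrum: np.ndarray, window: int = 11, segment: int = 7, delta: float = 1.0
) -> np.ndarray:
    """Gap-segment first derivative.

    At channel i the derivative is the difference between the mean of the
    ``segment`` channels starting ``(window-1)/2`` channels to the right and
    the mean of the ``segment`` channels ending ``(window-1)/2`` channels to
    the left, divided by the distance between the two segment centres in nm.
    Edges are filled with the nearest valid value so the length is preserved.
    """
    x = np.asarray(spectrum, dtype=float)
    half_gap = (window - 1) // 2
    if x.size < 2 * (half_gap + segment - 1) + 1:
        raise SizingError("spectrum too short for the gap-segment derivative")
    # mean of `segment` consecutive channels via cumulative sums
    csum = np.concatenate([[0.0], np.cumsum(x)])
    seg_means = (csum[segment:] - csum[:-segment]) / segment  # mean over [j, j+segment)
    reach = half_gap + segment - 1  # channels needed on each side of i
    centre_dist = (2 * half_gap + segment - 1) * delta
    out = np.full_like(x, np.nan)
    idx = np.arange(reach, x.size - reach)
    left_start = idx - half_gap - segment + 1
    right_start = idx + half_gap
    out[idx] = (seg_means[right_start] - seg_means[left_start]) / centre_dist
    out[:reach] = out[reach]
    out[x.size - reach:] = out[x.size - reach - 1]
    return out


def finite_difference(spectrum: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """Plain two-point first derivative (non-default alternative to the
    gap-segment derivative); central differences, one-sided at the edges."""
    return np.gradient(np.asarray(spectrum, dtype=float), delta)


def detrend(
    spectrum: np.ndarray,
    wavelengths: np.ndarray | None = None,
    degree: int = 2,
) -> np.ndarray:
    """Subtract the OLS polynomial of ``degree`` in wavelength."""
    x = np.asarray(spectrum, dtype=float)
    if degree >= x.size:
        raise SizingError("detrend degree must be < channel count")
    wl = np.arange(x.size, dtype=float) if wavelengths is None else np.asarray(wavelengths, float)
    fit = np.polynomial.Polynomial.fit(wl, x, degree)
    return x - fit(wl)


class FittedTreatment:
    """A treatment whose data-dependent state (the MSC reference) is frozen.

    Fit on the calibration partition, then ``transform`` both partitions so
    no holdout information enters the correction.
    """

    def __init__(self, spec: TreatmentSpec, wavelengths: np.ndarray):
        self.spec = spec
        self.wavelengths = np.asarray(wavelengths, dtype=float)
        self.delta = float(np.mean(np.diff(self.wavelengths)))
        self.msc_reference: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FittedTreatment":
        if self.spec.name in ("msc", "d1_msc"):
            self.msc_reference = msc_fit_reference(self._pre_msc(X))
        return self

    def _pre_msc(self, X: np.ndarray) -> np.ndarray:
        """Stages that run before the MSC step (for msc-containing treatments)."""
        p = self.spec.resolved_params()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.spec.name == "d1_msc":
            X = np.apply_along_axis(
                gap_segment_derivative, 1, X, p["gap_window"], p["gap_segment"], self.delta
            )
        return X

    def transform(self, X: np.ndarray) -> np.ndarray:
        p = self.spec.resolved_params()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        name = self.spec.name
        if name == "raw":
            return X.copy()
        if name == "snv":
            return _snv_rows(X)
        if name == "d1":
            return np.apply_along_axis(
                gap_segment_derivative, 1, X, p["gap_window"], p["gap_segment"], self.delta
            )
        if name in ("msc", "d1_msc"):
            Xp = self._pre_msc(X)
            ref = self.msc_reference
            if ref is None:  # fit-on-the-fly when used without an explicit fit
                ref = msc_fit_reference(Xp)
            return msc_transform(Xp, ref)
        if name == "d1_dt":
            Xd = np.apply_along_axis(
                gap_segment_derivative, 1, X, p["gap_window"], p["gap_segment"], self.delta
            )
            return np.apply_along_axis(
                detrend, 1, Xd, self.wavelengths, p["detrend_degree"]
            )
        if name == "sg_snv":
            Xs = np.apply_along_axis(
                savitzky_golay, 1, X, p["sg_window"], p["sg_polyorder"], 0, self.delta
            )
            Xd = np.apply_along_axis(
                gap_segment_derivative, 1, Xs, p["gap_window"], p["gap_segment"], self.delta
            )
            return _snv_rows(Xd)
        raise ConfigurationError(f"unknown treatment {name!r}")


def fit_treatment(
    spec: TreatmentSpec, X: np.ndarray, wavelengths: np.ndarray
) -> FittedTreatment:
    return FittedTreatment(spec, wavelengths).fit(X)


def apply_treatment(ds: SpectralDataset, spec: TreatmentSpec) -> SpectralDataset:
    """Apply a treatment to a whole dataset (fit state on that dataset) and
    record the spec in provenance."""
    fitted = fit_treatment(spec, ds.absorbance, ds.wavelengths)
    step = ("treatment", {"name": spec.name, "params": spec.resolved_params()})
    out = ds.with_absorbance(fitted.transform(ds.absorbance), step=step)
    return out


def replay_provenance(raw: SpectralDataset, provenance: tuple) -> SpectralDataset:
    """Re-apply recorded treatment steps to a raw dataset."""
    out = raw
    for kind, payload in provenance:
        if kind == "treatment":
            out = apply_treatment(out, TreatmentSpec(payload["name"], payload["params"]))
        elif kind == "msc":
            out = msc(out, np.asarray(payload["reference"]))
    return out


def iqr_outlier_filter(
    ds: SpectralDataset, k: float = 1.5, channel_fraction: float = 0.10
) -> tuple[SpectralDataset, list[str]]:
    """Flag readings with many channels outside per-channel Tukey fences.

    Fences are ``[Q1 - k*IQR, Q3 + k*IQR]`` per wavelength channel over all
    readings (type-7 quartiles). A reading is flagged when the fraction of
    its channels outside the fences exceeds ``channel_fraction``. With fewer
    than 4 readings the quartiles are unstable and the filter is skipped with
    a warning.
    """
    X = ds.absorbance
    if X.shape[0] < 4:
        warnings.warn("iqr_outlier_filter skipped: fewer than 4 readings")
        return ds, []
    q1 = np.percentile(X, 25, axis=0)
    q3 = np.percentile(X, 75, axis=0)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    outside = (X < lo) | (X > hi)
    frac = outside.mean(axis=1)
    flagged_mask = frac > channel_fraction
    flagged = ds.meta["reading_id"][flagged_mask].tolist()
    return ds.subset(~flagged_mask), flagged
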