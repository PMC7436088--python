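"""Dual-band ESIPT ratiometry.

A 3-hydroxyflavone probe emits from two excited states: the normal form
N* (shorter wavelengths, polarity-sensitive) and the proton-transfer
tautomer T* (longer wavelengths, polarity-indifferent).  The intensity
ratio of the two emission maxima, I_N*/I_T*, reads out local polarity.
This module finds the two band maxima in an emission spectrum and forms
the ratio, and computes the same ratio per pixel from two-channel vesicle
images over a membrane mask.

Default spectral windows bracket the observed band positions (the N* peak
wanders 475-551 nm with solvent polarity; confocal channels are 477-527
and 550-600 nm): N* = 460-540 nm, T* = 545-650 nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import ConfigurationError, NoSignalError

DEFAULT_WINDOW_N = (460.0, 540.0)
DEFAULT_WINDOW_T = (545.0, 650.0)
SMOOTH_POINTS = 5
DEFAULT_MASK_FRACTION = 0.2


@dataclass
class Spectrum:
    """Emission spectrum: strictly increasing wavelengths (nm), intensities >= 0."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ConfigurationError("wavelength and intensity arrays must align")
        if self.wavelengths.size < 10:
            raise ConfigurationError("spectrum needs at least 10 points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ConfigurationError("intensities must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths,
                      "intensity": self.intensities}).to_csv(path, index=False)


@dataclass
class BandRatio:
    """Located band maxima and their intensity ratio I_N*/I_T*."""

    lambda_N: float | None
    I_N: float | None
    lambda_T: float | None
    I_T: float | None
    ratio: float | None
    single_band: bool

    def to_dict(self) -> dict:
        return {
            "lambda_N_nm": self.lambda_N, "I_N": self.I_N,
            "lambda_T_nm": self.lambda_T, "I_T": self.I_T,
            "ratio": self.ratio, "single_band": self.single_band,
        }


def _window_peak(wl: np.ndarray, smooth: np.ndarray, window: tuple[float, float]):
    """Highest interior local maximum of the smoothed curve inside the window.

    Returns (lambda, intensity) or None when the only maximum sits on the
    window edge (no distinct band inside).  Ties go to the shorter
    wavelength (first occurrence).
    """
    lo, hi = window
    idx = np.flatnonzero((wl >= lo) & (wl <= hi))
    if idx.size == 0:
        raise ConfigurationError(f"window {window} lies outside the wavelength grid")
    best = None
    for i in idx:
        if i == idx[0] or i == idx[-1]:
            continue  # edge of the window is not a band
        if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]:
            # float-tolerant tie rule: equal-height maxima keep the shorter wavelength
            if best is None or (
                smooth[i] > smooth[best]
                and not np.isclose(smooth[i], smooth[best], rtol=1e-9, atol=1e-12)
            ):
                best = i
    if best is None:
        return None
    return float(wl[best]), float(smooth[best])


def band_ratio(
    spectrum: Spectrum,
    window_N: tuple[float, float] = DEFAULT_WINDOW_N,
    window_T: tuple[float, float] = DEFAULT_WINDOW_T,
) -> BandRatio:
    """Locate the N* and T* maxima and form I_N*/I_T*.

    Intensities are lightly smoothed (5-point moving average) before peak
    picking.  If no local maximum distinct from the window edge exists in
    the T* window the spectrum is flagged single-band (the protic-solvent
    case with one merged peak) and no ratio is reported.
    """
    if window_N[0] <= window_T[1] and window_T[0] <= window_N[1]:
        raise ConfigurationError("N* and T* windows must be disjoint")
    wl, inten = spectrum.wavelengths, spectrum.intensities
    smooth = uniform_filter1d(inten, size=SMOOTH_POINTS, mode="nearest")
    peak_N = _window_peak(wl, smooth, window_N)
    peak_T = _window_peak(wl, smooth, window_T)
    if peak_T is None or peak_N is None:
        found = peak_N or peak_T
        return BandRatio(
            lambda_N=found[0] if peak_N else None,
            I_N=found[1] if peak_N else None,
            lambda_T=peak_T[0] if peak_T else None,
            I_T=peak_T[1] if peak_T else None,
            ratio=None, single_band=True,
        )
    return BandRatio(
        lambda_N=peak_N[0], I_N=peak_N[1],
        lambda_T=peak_T[0], I_T=peak_T[1],
        ratio=peak_N[1] / peak_T[1], single_band=False,
    )


@dataclass
class ImageRatioResult:
    """Per-pixel I_N/I_T over the membrane mask plus the mask-mean ratio."""

    ratio_map: np.ndarray  # NaN outside the mask
    mask: np.ndarray
    mean_ratio: float
    n_mask_pixels: int
    n_excluded_zero_T: int


def image_band_ratio(
    ch_N: np.ndarray,
    ch_T: np.ndarray,
    threshold_fraction: float = DEFAULT_MASK_FRACTION,
) -> ImageRatioResult:
    """Ratio of two emission-channel images over a summed-intensity mask.

    The membrane mask keeps pixels whose summed intensity exceeds
    ``threshold_fraction`` of the pair's maximum summed intensity; the
    mask is therefore invariant to a common rescaling of both channels.
    T-channel zeros inside the mask are excluded and counted.
    """
    ch_N = np.asarray(ch_N, dtype=float)
    ch_T = np.asarray(ch_T, dtype=float)
    if ch_N.shape != ch_T.shape:
        raise ConfigurationError("channel images must share a shape")
    if not 0.0 < threshold_fraction < 1.0:
        raise ConfigurationError("threshold fraction must lie in (0, 1)")
    total = ch_N + ch_T
    peak = total.max()
    if peak <= 0:
        raise NoSignalError("both channels are empty")
    mask = total > threshold_fraction * peak
    if not mask.any():
        raise NoSignalError("no pixels above the masking threshold")
    valid = mask & (ch_T > 0)
    n_excluded = int(mask.sum() - valid.sum())
    if not valid.any():
        raise NoSignalError("all masked pixels have zero T-channel signal")
    ratio_map = np.full(ch_N.shape, np.nan)
    ratio_map[valid] = ch_N[valid] / ch_T[valid]
    return ImageRatioResult(
        ratio_map=ratio_map,
        mask=mask,
        mean_ratio=float(np.nanmean(ratio_map[valid])),
        n_mask_pixels=int(mask.sum()),
        n_excluded_zero_T=n_excluded,
    )
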