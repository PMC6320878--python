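"""Densitogram processing: baseline, peak detection, integration, identity.

A densitogram is the absorbance-vs-position trace a TLC scanner records
along one chromatographic track at a fixed wavelength.  This module turns
such a trace into quantified peaks: a morphological baseline estimate,
local-maximum peak detection with an SNR gate, trapezoidal band areas,
retention factors (R_F), band-to-band resolution, and UV-spectral peak
identity/purity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal


@dataclass(frozen=True)
class Densitogram:
    """Sampled absorbance vs plate position for one track.

    Parameters
    ----------
    positions : array, mm from the application line, strictly increasing.
    absorbances : array, AU, same length.
    wavelength : scan wavelength, nm.
    front_distance : solvent-front migration distance, mm.
    """

    positions: np.ndarray
    absorbances: np.ndarray
    wavelength: float = 254.0
    front_distance: float = 75.0

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        absb = np.asarray(self.absorbances, dtype=float)
        if pos.ndim != 1 or absb.ndim != 1 or pos.size != absb.size:
            raise ValueError("positions and absorbances must be 1-D and equal length")
        if pos.size < 2:
            raise ValueError("a densitogram needs at least 2 samples")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.front_distance <= 0:
            raise ValueError("front_distance must be positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "absorbances", absb)

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.positions)))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"position_mm": self.positions, "absorbance_AU": self.absorbances}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, wavelength: float = 254.0, front_distance: float = 75.0
    ) -> "Densitogram":
        df = pd.read_csv(path)
        for col in ("position_mm", "absorbance_AU"):
            if col not in df.columns:
                raise ValueError(f"densitogram CSV is missing column {col!r}")
        return cls(
            df["position_mm"].to_numpy(float),
            df["absorbance_AU"].to_numpy(float),
            wavelength=wavelength,
            front_distance=front_distance,
        )


@dataclass
class Peak:
    """One analyte band on a densitogram."""

    start: float
    apex: float
    end: float
    rf: float
    height: float
    area: float = 0.0
    analyte: str | None = None
    purity_r_sm: float | None = None
    purity_r_me: float | None = None

    def __post_init__(self):
        if not self.start < self.apex < self.end:
            raise ValueError("peak requires start < apex < end")
        if not 0.0 <= self.rf <= 1.0:
            raise ValueError("R_F must lie in [0, 1]")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")

    @property
    def width(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Spectrum:
    """UV absorbance spectrum recorded at one plate position (200–400 nm)."""

    wavelengths: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        if wl.size != ab.size or wl.size < 2:
            raise ValueError("spectrum needs matching wavelength/absorbance grids")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)

    @property
    def lambda_max(self) -> float:
        """Wavelength attaining the maximum absorbance (on the grid)."""
        return float(self.wavelengths[int(np.argmax(self.absorbances))])


@dataclass(frozen=True)
class PeakPurity:
    lambda_max: float
    r_sm: float
    r_me: float
    #: True when a spectrum had zero variance and the correlation is undefined.
    undefined: bool = False


def estimate_baseline(d: Densitogram, window: float = 10.0) -> np.ndarray:
    """Morphological (grey-opening) baseline under the bands.

    An erosion followed by a dilation over ``window`` mm removes features
    narrower than the window while following constant or drifting
    backgrounds exactly, so subtracting it from a band-free signal yields
    (numerically) zeros.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    span = d.positions[-1] - d.positions[0]
    if window > span:
        raise ValueError(f"window {window} mm exceeds the scan range {span:.1f} mm")
    size = max(3, int(round(window / d.step)) | 1)  # odd sample count
    # Pad by linear extrapolation of the outer samples so a drifting
    # background is followed exactly at the scan edges too.
    k = size // 2
    y = d.absorbances
    x = d.positions
    lo_fit = np.polyfit(x[:size], y[:size], 1)
    hi_fit = np.polyfit(x[-size:], y[-size:], 1)
    step = d.step
    left = np.polyval(lo_fit, x[0] - step * np.arange(k, 0, -1))
    right = np.polyval(hi_fit, x[-1] + step * np.arange(1, k + 1))
    padded = np.concatenate([left, y, right])
    opened = ndimage.grey_opening(padded, size=size)
    return opened[k : k + y.size]


def _noise_sd(residual: np.ndarray) -> float:
    """Robust noise scale from the outer 10% of the scan (MAD-based)."""
    n = residual.size
    k = max(3, n // 10)
    tails = np.concatenate([residual[:k], residual[-k:]])
    return float(1.4826 * np.median(np.abs(tails - np.median(tails))))


def detect_peaks(
    d: Densitogram,
    min_snr: float = 10.0,
    baseline: np.ndarray | None = None,
    baseline_window: float = 10.0,
    boundary_frac: float = 0.01,
    min_separation: float = 2.0,
) -> list[Peak]:
    """Detect bands as local maxima exceeding ``min_snr`` times the noise.

    Apexes closer than ``min_separation`` mm are treated as one band (the
    higher sample wins), which keeps noise from splitting a band top.
    Boundaries are placed at the nearest flanking local minima, falling
    back to the point where the signal drops below ``boundary_frac`` of
    the peak height.  Peaks are returned sorted by position, with areas
    already integrated.
    """
    if min_snr <= 0:
        raise ValueError("min_snr must be positive")
    if d.positions.size < 3:
        raise ValueError("peak detection needs at least 3 samples")
    if baseline is None:
        baseline = estimate_baseline(d, window=baseline_window)
    y = d.absorbances - baseline
    noise = _noise_sd(y)
    # Height gate: SNR threshold, with a numerical floor for noiseless data.
    floor = 1e-9 * max(1.0, float(np.max(np.abs(y))) if y.size else 1.0)
    height = max(min_snr * noise, floor)
    idx, _ = signal.find_peaks(
        y, height=height, distance=max(1, int(round(min_separation / d.step)))
    )
    peaks: list[Peak] = []
    for i in idx:
        cut = boundary_frac * y[i]
        lo = _walk_boundary(y, i, -1, cut, noise)
        hi = _walk_boundary(y, i, +1, cut, noise)
        if lo == i or hi == i:
            continue
        p = Peak(
            start=float(d.positions[lo]),
            apex=float(d.positions[i]),
            end=float(d.positions[hi]),
            rf=retention_factor(float(d.positions[i]), d.front_distance),
            height=float(y[i]),
        )
        p.area = integrate_peak(d, p, baseline=baseline)
        peaks.append(p)
    peaks.sort(key=lambda p: p.apex)
    return peaks


def _walk_boundary(
    y: np.ndarray, apex: int, step: int, cut: float, tol: float
) -> int:
    """March from the apex to the flanking valley (or near-baseline sample).

    Walks outward tracking the running minimum; stops when the signal rises
    more than ``tol`` (one noise SD) above it — a valley between bands —
    or once the minimum falls below ``cut`` (the 1%-of-height fallback).
    """
    i = apex
    best = apex
    while True:
        j = i + step
        if j < 0 or j >= y.size:
            break
        if y[j] < y[best]:
            best = j
        elif y[j] > y[best] + tol:
            break
        i = j
        if y[best] <= cut:
            break
    return best


def integrate_peak(
    d: Densitogram, p: Peak, baseline: np.ndarray | None = None
) -> float:
    """Trapezoidal area (AU·mm scale collapsed to AU) of a band.

    Integrates the baseline-subtracted signal over [start, end] on the
    sampled grid; no peak-model fitting, matching densitometer practice.
    """
    if p.start >= p.end:
        raise ValueError("peak bounds are inverted")
    if p.start < d.positions[0] or p.end > d.positions[-1]:
        raise ValueError("peak bounds fall outside the scan range")
    y = d.absorbances if baseline is None else d.absorbances - baseline
    mask = (d.positions >= p.start) & (d.positions <= p.end)
    area = float(np.trapezoid(y[mask], d.positions[mask]))
    return max(area, 0.0)


def retention_factor(apex: float, front_distance: float) -> float:
    """R_F = migration distance / solvent-front distance."""
    if front_distance <= 0:
        raise ValueError("front_distance must be positive")
    if not 0 <= apex <= front_distance:
        raise ValueError("apex must lie between the origin and the solvent front")
    return apex / front_distance


def resolution(p1: Peak, p2: Peak) -> float:
    """Band resolution R_S = 2·Δapex / (width1 + width2)."""
    if p1.apex > p2.apex:
        raise ValueError("p1 must precede p2")
    total_width = p1.width + p2.width
    if total_width <= 0:
        raise ValueError("total band width is zero")
    return 2.0 * (p2.apex - p1.apex) / total_width


def spectral_scan(start: Spectrum, apex: Spectrum, end: Spectrum) -> PeakPurity:
    """Identity and purity from spectra at peak start (S), apex (M), end (E).

    λmax is read from the apex spectrum; purity is the Pearson correlation
    of the (S, M) and (M, E) spectra — values near 1 indicate a single
    migrating compound.
    """
    grids = {tuple(np.round(s.wavelengths, 9).tolist()) for s in (start, apex, end)}
    if len(grids) != 1:
        raise ValueError("spectra must share a common wavelength grid")
    undefined = any(np.std(s.absorbances) == 0 for s in (start, apex, end))
    if undefined:
        return PeakPurity(apex.lambda_max, float("nan"), float("nan"), undefined=True)
    r_sm = float(np.corrcoef(start.absorbances, apex.absorbances)[0, 1])
    r_me = float(np.corrcoef(apex.absorbances, end.absorbances)[0, 1])
    return PeakPurity(apex.lambda_max, r_sm, r_me)


def peak_table(peaks: Sequence[Peak]) -> pd.DataFrame:
    """Tabulate detected peaks (one row per band)."""
    return pd.DataFrame(
        [
            {
                "analyte": p.analyte,
                "rf": p.rf,
                "start_mm": p.start,
                "apex_mm": p.apex,
                "end_mm": p.end,
                "height_AU": p.height,
                "area_AU": p.area,
                "purity_r_sm": p.purity_r_sm,
                "purity_r_me": p.purity_r_me,
            }
            for p in peaks
        ]
    )
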