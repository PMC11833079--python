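"""Spatial-resolution estimation from line-grating IQI images.

Per grating, the modulation ``(Imax - Imin) / (Imax + Imin)`` of the
bar profile measures how much contrast survives the imaging chain; the
resolution estimate is the finest bar spacing whose modulation still
clears a threshold (the MTF-limit reading of a star-pattern phantom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import IQILayout

__all__ = ["MTFCurve", "modulation_curve", "mtf_limit", "UNRESOLVED"]

#: Sentinel returned when no grating clears the modulation threshold.
UNRESOLVED = float("inf")


@dataclass
class MTFCurve:
    """Modulation vs bar spacing, spacings strictly descending."""

    spacings_um: np.ndarray
    modulations: np.ndarray
    threshold: float = 0.10

    def __post_init__(self) -> None:
        self.spacings_um = np.asarray(self.spacings_um, dtype=float)
        self.modulations = np.asarray(self.modulations, dtype=float)
        if self.spacings_um.size == 0:
            raise ValueError("MTF curve is empty")
        if np.any(np.diff(self.spacings_um) >= 0):
            raise ValueError("spacings must be strictly descending")
        if np.any((self.modulations < -1e-9) | (self.modulations > 1 + 1e-9)):
            raise ValueError("modulations must lie in [0, 1]")


def _grating_modulation(
    image: np.ndarray, rows: tuple[int, int], cols: tuple[int, int], period_px: float
) -> float:
    """Bar modulation (Imax - Imin)/(Imax + Imin) of one grating region.

    The line profile is averaged along the bars for noise robustness and
    detrended with a one-period moving baseline so that blur bleeding in
    from the grating's outer edge reads as trend, not as bar contrast.
    """
    from scipy.ndimage import uniform_filter1d

    region = image[rows[0] : rows[1], cols[0] : cols[1]]
    profile = region.mean(axis=0)
    w = len(profile)
    # a boxcar of exactly one period nulls the bar signal and its harmonics,
    # leaving only the slow falloff that blur drags in from the grating edge
    baseline = uniform_filter1d(profile, max(int(round(period_px)), 1), mode="nearest")
    # keep the central pairs: the outermost period carries edge falloff
    trim = int(max(1, w // 12, round(period_px)))
    if w - 2 * trim < max(2, period_px):
        trim = max(1, (w - int(max(2, period_px))) // 2)
    resid = (profile - baseline)[trim : w - trim]
    level = float(baseline[trim : w - trim].mean())
    if level <= 0:
        return 0.0
    amplitude = 0.5 * (float(resid.max()) - float(resid.min()))
    return max(0.0, min(1.0, amplitude / level))


def modulation_curve(image: np.ndarray, layout: IQILayout, threshold: float = 0.10) -> MTFCurve:
    """Measure per-grating modulation from an IQI image and its layout."""
    image = np.asarray(image, dtype=float)
    mods, spacings = [], []
    for g in layout.gratings:
        if g.rows[1] > image.shape[0] or g.cols[1] > image.shape[1]:
            raise ValueError(
                f"grating at rows {g.rows}, cols {g.cols} lies outside the image {image.shape}"
            )
        m = _grating_modulation(image, g.rows, g.cols, 2.0 * g.spacing_um / layout.pixel_um)
        if not g.resolvable:
            m = 0.0  # under 2 pixels per bar the reading is aliasing, not signal
        mods.append(m)
        spacings.append(g.spacing_um)
    return MTFCurve(np.array(spacings), np.array(mods), threshold=threshold)


def mtf_limit(curve: MTFCurve) -> float:
    """Resolution in um: the finest spacing whose modulation clears the
    threshold, linearly interpolated between the adjacent gratings where
    the curve crosses it.  Returns ``UNRESOLVED`` (+inf) if nothing does.
    """
    s, m, thr = curve.spacings_um, curve.modulations, curve.threshold
    above = m >= thr
    if not above.any():
        return UNRESOLVED
    if above.all():
        return float(s[-1])
    # index of the finest grating still above threshold
    last = int(np.max(np.nonzero(above)))
    if last == len(s) - 1:
        return float(s[-1])
    s0, s1 = s[last], s[last + 1]
    m0, m1 = m[last], m[last + 1]
    if m0 == m1:
        return float(s0)
    t = (m0 - thr) / (m0 - m1)
    return float(s0 + t * (s1 - s0))
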