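"""Canal segmentation: denoise -> hysteresis threshold -> cleanup.

The recovery chain mirrors standard micro-CT post-processing of fossil
cortical bone: non-local-means noise filtering, automatic hysteresis
thresholding of the low-attenuation canal phase, removal of small
speckle components, and removal of components narrower than the
certified spatial resolution.  Canals are treated as *darker* than bone
(voids or low-density fill); the polarity is a flag for data where the
fill attenuates more than bone.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.restoration import denoise_nl_means, estimate_sigma

from .io import BONE, CANAL, GrayVolume, LabelVolume

__all__ = [
    "denoise",
    "auto_thresholds",
    "hysteresis_threshold",
    "despeckle",
    "remove_subresolution",
    "segment",
    "dice",
]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def denoise(
    gray: GrayVolume,
    strength: float = 0.8,
    patch_size: int = 3,
    patch_distance: int = 2,
) -> GrayVolume:
    """Non-local-means denoising (patch-similarity-weighted averaging).

    ``strength`` scales the filtering parameter ``h`` relative to the
    estimated noise sigma; flat regions are smoothed strongly while step
    edges survive to within a voxel.
    """
    if patch_size < 1 or patch_distance < 1:
        raise ValueError("patch radii must be >= 1")
    data = np.ascontiguousarray(gray.data, dtype=np.float32)
    sigma = float(estimate_sigma(data))
    out = denoise_nl_means(
        data,
        patch_size=patch_size,
        patch_distance=patch_distance,
        h=strength * sigma,
        sigma=sigma,
        fast_mode=True,
    )
    return GrayVolume(data=out.astype(np.float32), spacing=gray.spacing, origin=gray.origin)


def auto_thresholds(gray: GrayVolume, alpha: float = 0.5) -> tuple[float, float]:
    """Automatic hysteresis thresholds for the dark canal phase.

    ``high`` is the between-class-variance-optimal (Otsu) split between
    the canal and bone intensity modes; ``low`` sits ``alpha`` of the
    inter-mode gap below it.  A volume without two separated modes is an
    error advising manual thresholds.
    """
    data = np.asarray(gray.data)
    if np.ptp(data) == 0:
        raise ValueError("intensity histogram is unimodal (constant); supply manual thresholds")
    if _n_histogram_modes(data) < 2:
        raise ValueError(
            "intensity histogram looks unimodal; supply manual thresholds"
        )
    high = float(threshold_otsu(data.ravel()))
    lo_mode = float(data[data < high].mean()) if np.any(data < high) else high
    hi_mode = float(data[data >= high].mean())
    gap = hi_mode - lo_mode
    low = high - alpha * gap
    return low, high


def _n_histogram_modes(data: np.ndarray, bins: int = 256) -> int:
    """Count separated peaks in the smoothed intensity histogram."""
    from scipy.signal import find_peaks

    hist, _ = np.histogram(data.ravel(), bins=bins)
    smooth = ndimage.gaussian_filter1d(hist.astype(float), 4.0)
    padded = np.concatenate([[0.0], smooth, [0.0]])  # peaks at the range ends count
    peaks, _ = find_peaks(padded, prominence=0.05 * smooth.max(), distance=bins // 16)
    return len(peaks)


def hysteresis_threshold(
    gray: GrayVolume,
    low: float,
    high: float,
    connectivity: int = 26,
    dark_canals: bool = True,
) -> LabelVolume:
    """Hysteresis threshold of the canal phase.

    Canal voxels are those below ``low`` plus voxels below ``high`` that
    are connected (26-connectivity by default) to a seed below ``low``.
    With ``dark_canals=False`` the comparisons flip sign.
    """
    if low > high:
        raise ValueError(f"low threshold {low} exceeds high threshold {high}")
    data = np.asarray(gray.data)
    if not dark_canals:
        data = -data
        low, high = -high, -low
    strong = data < low
    weak = data < high
    lab, n = ndimage.label(weak, structure=_STRUCTS[connectivity])
    if n:
        keep = np.zeros(n + 1, dtype=bool)
        keep[np.unique(lab[strong])] = True
        keep[0] = False
        canal = keep[lab]
    else:
        canal = strong
    labels = np.where(canal, CANAL, BONE).astype(np.uint8)
    return LabelVolume(labels=labels, spacing=gray.spacing, origin=gray.origin)


def despeckle(label: LabelVolume, min_voxels: int = 27, connectivity: int = 26) -> LabelVolume:
    """Reassign canal components smaller than ``min_voxels`` to bone."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    canal = label.labels == CANAL
    lab, n = ndimage.label(canal, structure=_STRUCTS[connectivity])
    if n == 0:
        return LabelVolume(label.labels.copy(), label.spacing, label.origin)
    sizes = np.bincount(lab.ravel(), minlength=n + 1)
    small = sizes < min_voxels
    small[0] = False
    out = label.labels.copy()
    out[small[lab]] = BONE
    return LabelVolume(out, label.spacing, label.origin)


def remove_subresolution(
    label: LabelVolume, resolution: float, connectivity: int = 26
) -> LabelVolume:
    """Remove canal components narrower than the certified resolution.

    A component's width is twice the maximum of the Euclidean distance
    transform inside it (its largest inscribed-sphere diameter, in um);
    components below ``resolution`` go back to bone.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0 um")
    canal = label.labels == CANAL
    if not canal.any():
        return LabelVolume(label.labels.copy(), label.spacing, label.origin)
    edt = ndimage.distance_transform_edt(canal, sampling=label.spacing)
    lab, n = ndimage.label(canal, structure=_STRUCTS[connectivity])
    max_d = 2.0 * np.asarray(
        ndimage.maximum(edt, labels=lab, index=np.arange(1, n + 1))
    )
    drop = np.concatenate([[False], max_d < resolution])
    out = label.labels.copy()
    out[drop[lab]] = BONE
    return LabelVolume(out, label.spacing, label.origin)


def segment(
    gray: GrayVolume,
    low: float | None = None,
    high: float | None = None,
    alpha: float = 0.5,
    min_voxels: int = 27,
    resolution: float | None = None,
    connectivity: int = 26,
    dark_canals: bool = True,
    denoise_strength: float = 0.8,
) -> tuple[LabelVolume, dict]:
    """Full recovery chain; returns labels plus a provenance record."""
    d = denoise(gray, strength=denoise_strength) if denoise_strength > 0 else gray
    if low is None or high is None:
        low, high = auto_thresholds(d, alpha=alpha)
    label = hysteresis_threshold(d, low, high, connectivity=connectivity, dark_canals=dark_canals)
    label = despeckle(label, min_voxels=min_voxels, connectivity=connectivity)
    if resolution is not None:
        label = remove_subresolution(label, resolution, connectivity=connectivity)
    prov = {
        "low": float(low),
        "high": float(high),
        "alpha": alpha,
        "min_voxels": min_voxels,
        "resolution_um": resolution,
        "connectivity": connectivity,
        "dark_canals": dark_canals,
        "denoise_strength": denoise_strength,
    }
    return label, prov


def dice(a: LabelVolume | np.ndarray, b: LabelVolume | np.ndarray) -> float:
    """Dice overlap of the canal phase between two labelings."""
    ma = (a.labels if isinstance(a, LabelVolume) else np.asarray(a)) == CANAL
    mb = (b.labels if isinstance(b, LabelVolume) else np.asarray(b)) == CANAL
    denom = ma.sum() + mb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(ma, mb).sum() / denom)
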