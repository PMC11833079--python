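import numpy as np
import pytest
from scipy import ndimage

from paleocanal.resolution import UNRESOLVED, MTFCurve, modulation_curve, mtf_limit
from paleocanal.synthetic import generate_iqi_image


def test_square_wave_modulation_is_unity():
    img, layout = generate_iqi_image(psf_sigma=0.0, noise_sd=0.0)
    curve = modulation_curve(img, layout)
    assert curve.modulations[0] > 0.99


def test_blurred_out_grating_is_flat():
    img, layout = generate_iqi_image(spacings=(8.0, 4.0), psf_sigma=20.0, noise_sd=0.0)
    curve = modulation_curve(img, layout)
    assert curve.modulations[-1] <= 0.05


def test_modulation_matches_direct_convolution_oracle():
    """Package modulations agree with independently blurred single gratings."""
    sigma = 6.0
    pixel = 2.0
    img, layout = generate_iqi_image(psf_sigma=sigma, noise_sd=0.0, pixel_um=pixel)
    curve = modulation_curve(img, layout)
    for g, m in zip(layout.gratings, curve.modulations):
        if not g.resolvable:
            continue
        # oracle: 1D square wave sampled finely, Gaussian-convolved directly
        fine = 0.05  # um per sample
        n_pairs = 6
        x = np.arange(0, 2 * g.spacing_um * (n_pairs + 4), fine)
        wave = ((x // g.spacing_um).astype(int) % 2 == 0).astype(float)
        blurred = ndimage.gaussian_filter1d(wave, sigma / fine)
        mid = blurred[len(blurred) // 4 : -len(blurred) // 4]
        oracle = (mid.max() - mid.min()) / (mid.max() + mid.min())
        assert m == pytest.approx(oracle, abs=0.02)


def test_mtf_limit_trivial_cases():
    c = MTFCurve(np.array([32.0, 16.0, 8.0, 4.0]), np.array([1.0, 0.9, 0.5, 0.2]))
    assert mtf_limit(c) == 4.0  # everything resolved -> finest spacing
    c = MTFCurve(np.array([32.0, 16.0]), np.array([0.05, 0.01]))
    assert mtf_limit(c) == UNRESOLVED


def test_mtf_limit_interpolates_between_gratings():
    c = MTFCurve(np.array([16.0, 8.0]), np.array([0.30, 0.05]), threshold=0.10)
    # crossing at 0.10: t = (0.30-0.10)/(0.30-0.05) = 0.8 of the way down
    assert mtf_limit(c) == pytest.approx(16.0 + 0.8 * (8.0 - 16.0))


def test_resolution_monotone_in_blur_and_threshold():
    res = []
    for sigma in (2.0, 5.0, 9.0):
        img, layout = generate_iqi_image(psf_sigma=sigma, noise_sd=0.0)
        res.append(mtf_limit(modulation_curve(img, layout)))
    assert res[0] <= res[1] <= res[2]

    img, layout = generate_iqi_image(psf_sigma=6.0, noise_sd=0.0)
    r10 = mtf_limit(modulation_curve(img, layout, threshold=0.10))
    r20 = mtf_limit(modulation_curve(img, layout, threshold=0.20))
    assert r20 >= r10


def test_grating_outside_image_is_an_error():
    img, layout = generate_iqi_image(psf_sigma=0.0, noise_sd=0.0)
    with pytest.raises(ValueError, match="outside"):
        modulation_curve(img[:20], layout)
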