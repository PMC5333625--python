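"""Shared fixtures: virtual-microscope scenes reused across test modules."""

import numpy as np
import pytest

from clpointer import (PointerGridSpec, SimilarityTransform,
                       default_ground_truth, render_pointer_image,
                       localize_all, match_grid)


@pytest.fixture(scope="session")
def calibration_grid() -> PointerGridSpec:
    """The dense calibration array: 25 x 25 pointers, 4 um (800 EM px) pitch."""
    return PointerGridSpec(rows=25, cols=25, spacing_px=800.0)


@pytest.fixture(scope="session")
def rendered_scene(calibration_grid):
    """One rendered 625-pointer FM exposure (camera noise, no jitter)."""
    gt = default_ground_truth(seed=2, jitter_sigma_nm=0.0)
    image, truth = render_pointer_image(calibration_grid, gt)
    return gt, image, truth


@pytest.fixture(scope="session")
def localized_scene(rendered_scene, calibration_grid):
    """Localized centers and the matched pair set of the rendered scene."""
    gt, image, truth = rendered_scene
    centers, detections = localize_all(image, calibration_grid.n_pointers,
                                       fwhm_px=3.0)
    pairs = match_grid(centers, calibration_grid)
    return gt, truth, centers, pairs


def gaussian_patch(cx: float, cy: float, n: int = 21, fwhm: float = 3.0,
                   amplitude: float = 1000.0, background: float = 100.0,
                   rng: np.random.Generator | None = None,
                   read_noise: float = 2.0) -> np.ndarray:
    """Synthetic single-spot patch; Poisson + read noise when rng is given."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    yy, xx = np.mgrid[0:n, 0:n]
    signal = amplitude * np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)) + background
    if rng is None:
        return signal
    return rng.poisson(signal).astype(float) + rng.normal(0, read_noise, signal.shape)
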