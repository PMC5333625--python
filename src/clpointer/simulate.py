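"""Virtual integrated-microscope scenes with exact ground truth.

Emulates the data an integrated CLEM instrument produces during
cathodoluminescence (CL) pointer registration:

* FM camera images of CL pointer arrays — circularly symmetric spots of
  ~300 nm FWHM (the diffraction limit) on a noisy background;
* EM images of nanosphere fiducials (40 nm disks) with their fluorescent
  counterparts in the FM frame;
* the ground-truth EM->FM similarity transform and a smooth sub-pixel
  distortion field, so every downstream stage can be scored exactly.

The generative model for an observed pointer position is

    FM_observed = T(EM_commanded) + D(T(EM_commanded)) + noise

with the distortion field ``D`` defined in the FM frame (nm).  Besides full
image rendering, a fast *coordinate mode* skips the camera model and emits
localized coordinates with isotropic Gaussian jitter directly — this
decouples studies of registration statistics from image-rendering cost.

Camera noise model: Poisson shot noise on (signal + background) plus
additive Gaussian read noise, the standard sCMOS/CCD model.  Spot
amplitudes and backgrounds are free parameters of the simulation chosen to
give ~10 nm-scale single-pointer localization error at the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .register import DistortionField, SimilarityTransform, fit_similarity

__all__ = [
    "RasterImage",
    "PointerGridSpec",
    "NoiseParams",
    "SceneGroundTruth",
    "PointerPool",
    "default_ground_truth",
    "make_distortion_field",
    "render_pointer_image",
    "simulate_pointer_pool",
    "render_fiducial_scene",
    "simulate_fiducial_coordinates",
]

#: FWHM of a diffraction-limited CL pointer in nm (optical diffraction limit).
DEFAULT_POINTER_FWHM_NM = 300.0
#: Physical diameter of the fluorescent silica nanosphere fiducials in nm.
NANOSPHERE_DIAMETER_NM = 40.0
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class RasterImage:
    """A 2D intensity image with physical pixel size and frame label."""

    pixels: np.ndarray
    pixel_size_nm: float
    frame: str  # "FM" or "EM"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.isfinite(self.pixels).all() or (self.pixels < 0).any():
            raise ValueError("intensities must be finite and non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.frame not in ("FM", "EM"):
            raise ValueError("frame must be 'FM' or 'EM'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class PointerGridSpec:
    """Commanded CL pointer grid in the EM frame.

    ``spacing_px`` is the node spacing in EM pixels; ``origin_px`` the EM
    position of node (row 0, col 0).  Nodes are indexed row-major, so
    pointer ``i`` sits at ``(col, row) = (i % cols, i // cols)``.
    """

    rows: int
    cols: int
    spacing_px: float
    origin_px: tuple[float, float] = (0.0, 0.0)
    exposure_count: int = 1

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be positive")
        if self.spacing_px <= 0:
            raise ValueError("spacing must be > 0")
        if self.exposure_count < 1:
            raise ValueError("exposure_count must be >= 1")

    @property
    def n_pointers(self) -> int:
        return self.rows * self.cols

    def em_coords(self) -> np.ndarray:
        """``(rows*cols, 2)`` commanded EM positions, row-major order."""
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        x = self.origin_px[0] + cc.ravel() * self.spacing_px
        y = self.origin_px[1] + rr.ravel() * self.spacing_px
        return np.column_stack([x, y]).astype(float)

    def corner_coords(self) -> np.ndarray:
        """The 4 grid corners in cyclic order (EM px)."""
        x0, y0 = self.origin_px
        w = (self.cols - 1) * self.spacing_px
        h = (self.rows - 1) * self.spacing_px
        return np.array([[x0, y0], [x0 + w, y0], [x0 + w, y0 + h], [x0, y0 + h]])


@dataclass(frozen=True)
class NoiseParams:
    """Camera/localization noise settings of a simulated scene.

    ``amplitude`` and ``background`` are in camera counts; ``jitter_sigma_nm``
    is the isotropic per-pointer localization jitter used by coordinate mode.
    ``shot_noise=False`` disables the Poisson step for exact noiseless renders.
    """

    amplitude: float = 1000.0
    background: float = 100.0
    read_noise_sigma: float = 2.0
    jitter_sigma_nm: float = 12.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("spot amplitude must be >= 0")
        if self.background < 0 or self.read_noise_sigma < 0:
            raise ValueError("background and read noise must be >= 0")
        if self.jitter_sigma_nm < 0:
            raise ValueError("jitter sigma must be >= 0")


@dataclass
class SceneGroundTruth:
    """Everything the virtual microscope knows that an instrument hides."""

    true_transform: SimilarityTransform
    true_distortion: DistortionField | None = None
    fm_pixel_size_nm: float = 100.0
    em_pixel_size_nm: float = 5.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fm_pixel_size_nm <= 0 or self.em_pixel_size_nm <= 0:
            raise ValueError("pixel sizes must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def true_fm_positions(self, em_points: np.ndarray) -> np.ndarray:
        """Noise-free FM positions: ``T(em) + D(T(em))`` in FM px."""
        mapped = self.true_transform.apply(np.atleast_2d(em_points))
        if self.true_distortion is not None:
            mapped = mapped + (self.true_distortion.evaluate(mapped)
                               / self.fm_pixel_size_nm)
        return mapped

    def to_dict(self) -> dict:
        d = {
            "true_transform": self.true_transform.to_dict(),
            "fm_pixel_size_nm": self.fm_pixel_size_nm,
            "em_pixel_size_nm": self.em_pixel_size_nm,
            "noise": {
                "amplitude": self.noise.amplitude,
                "background": self.noise.background,
                "read_noise_sigma": self.noise.read_noise_sigma,
                "jitter_sigma_nm": self.noise.jitter_sigma_nm,
                "shot_noise": self.noise.shot_noise,
            },
            "seed": self.seed,
        }
        if self.true_distortion is not None:
            d["true_distortion"] = self.true_distortion.to_dict()
        return d


def default_ground_truth(seed: int = 0, *, rotation_deg: float = 2.0,
                         jitter_sigma_nm: float = 12.0,
                         distortion: DistortionField | None = None) -> SceneGroundTruth:
    """A realistic default geometry: 5 nm EM px, 100 nm FM px, small rotation.

    The EM->FM scale is the pixel-size ratio (0.05 by default) so commanded
    EM-pixel coordinates land on the FM camera at their physical positions.
    """
    scale = 5.0 / 100.0
    t = SimilarityTransform(scale=scale, rotation=np.deg2rad(rotation_deg),
                            tx=48.0, ty=28.0)
    return SceneGroundTruth(
        true_transform=t, true_distortion=distortion,
        fm_pixel_size_nm=100.0, em_pixel_size_nm=5.0,
        noise=NoiseParams(jitter_sigma_nm=jitter_sigma_nm), seed=seed,
    )


# ---------------------------------------------------------------------------
# Ground-truth distortion field
# ---------------------------------------------------------------------------

def _similarity_projection(nodes: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Remove the component of ``vectors`` lying in the similarity-fit span.

    The least-squares similarity fit can absorb exactly four displacement
    modes at the node positions: uniform translation in x and y, and the
    scale/rotation modes (x, y) and (-y, x).  Projecting the field onto the
    orthogonal complement guarantees that fitting a similarity on
    (node, node + vector) pairs returns the identity — the field then holds
    only what the linear registration cannot represent.
    """
    n = nodes.shape[0]
    basis = np.zeros((2 * n, 4))
    basis[0::2, 0] = nodes[:, 0]
    basis[1::2, 0] = nodes[:, 1]
    basis[0::2, 1] = -nodes[:, 1]
    basis[1::2, 1] = nodes[:, 0]
    basis[0::2, 2] = 1.0
    basis[1::2, 3] = 1.0
    flat = vectors.reshape(-1)
    coef, *_ = np.linalg.lstsq(basis, flat, rcond=None)
    return (flat - basis @ coef).reshape(vectors.shape)


def make_distortion_field(field_shape: tuple[int, int] = (25, 25),
                          max_magnitude_nm: float = 200.0,
                          anomaly_count: int = 3,
                          seed: int = 0,
                          *,
                          node_origin_px: tuple[float, float] = (0.0, 0.0),
                          node_spacing_px: float = 42.6,
                          grid_to_fm: SimilarityTransform | None = None,
                          fm_pixel_size_nm: float = 100.0,
                          poly_order: int = 3) -> DistortionField:
    """Generate a smooth ground-truth distortion field on an FM lattice.

    The smooth part is a random 2D polynomial vector field of order
    ``poly_order`` (cubic by default) over the lattice; ``anomaly_count``
    nodes additionally receive localized deviant vectors of ~2x the smooth
    peak magnitude with random orientation, mimicking isolated camera-array
    defects.  The whole field is projected orthogonal to the similarity-fit
    degrees of freedom and scaled so the smooth part peaks at
    ``max_magnitude_nm``; the field is exactly linear in that magnitude.

    The node lattice is axis-aligned at ``node_origin_px`` with
    ``node_spacing_px`` unless an explicit ``grid_to_fm`` transform is
    given, in which case nodes sit on that similarity-mapped lattice —
    use this to place the field nodes exactly on the FM positions of a
    calibration pointer grid, as in the physical calibration.
    """
    if max_magnitude_nm < 0:
        raise ValueError("max_magnitude_nm must be >= 0")
    rows, cols = field_shape
    if anomaly_count < 0 or anomaly_count > rows * cols:
        raise ValueError("anomaly_count out of range")
    rng = np.random.default_rng(seed)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if grid_to_fm is None:
        grid_to_fm = SimilarityTransform(
            scale=node_spacing_px, rotation=0.0,
            tx=node_origin_px[0], ty=node_origin_px[1])
    nodes = grid_to_fm.apply(
        np.column_stack([cc.ravel(), rr.ravel()]).astype(float))

    # normalized coords in [-1, 1] for a well-conditioned polynomial basis
    u = 2 * cc.ravel() / max(cols - 1, 1) - 1
    v = 2 * rr.ravel() / max(rows - 1, 1) - 1
    vec = np.zeros((rows * cols, 2))
    for k in range(2):
        for i in range(poly_order + 1):
            for j in range(poly_order + 1 - i):
                vec[:, k] += rng.normal() * (u**i) * (v**j)

    anomaly = np.zeros(rows * cols, dtype=bool)
    if anomaly_count > 0:
        anom_idx = rng.choice(rows * cols, size=anomaly_count, replace=False)
        anomaly[anom_idx] = True

    smooth_peak = np.linalg.norm(vec, axis=1).max()
    if smooth_peak > 0:
        vec /= smooth_peak
    if anomaly_count > 0:
        mag = rng.uniform(1.8, 2.5, size=anomaly_count)
        ang = rng.uniform(0, 2 * np.pi, size=anomaly_count)
        vec[anom_idx] += np.column_stack([mag * np.cos(ang), mag * np.sin(ang)])

    vec = _similarity_projection(nodes, vec)
    peak = np.linalg.norm(vec[~anomaly], axis=1).max() if (~anomaly).any() else \
        np.linalg.norm(vec, axis=1).max()
    if peak > 0:
        vec /= peak
    vec *= max_magnitude_nm

    return DistortionField(
        node_xy_px=nodes.reshape(rows, cols, 2),
        vectors_nm=vec.reshape(rows, cols, 2),
        counts=np.ones((rows, cols), dtype=int),
        sd_nm=np.zeros((rows, cols)),
        anomaly=anomaly.reshape(rows, cols),
        grid_to_fm=grid_to_fm,
        fm_pixel_size_nm=fm_pixel_size_nm,
    )


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

def _add_gaussian_spots(img: np.ndarray, centers: np.ndarray, amplitude: float,
                        sigma_px: float) -> None:
    """Accumulate isotropic 2D Gaussians (peak ``amplitude``) in place."""
    h, w = img.shape
    half = max(int(np.ceil(4 * sigma_px)), 2)
    for cx, cy in centers:
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        xs = np.arange(x0c, x1c) - cx
        ys = np.arange(y0c, y1c) - cy
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma_px**2))
        img[y0c:y1c, x0c:x1c] += amplitude * g


def _add_disks(img: np.ndarray, centers: np.ndarray, amplitude: float,
               radius_px: float) -> None:
    """Accumulate anti-aliased uniform disks (1-px soft edge) in place."""
    h, w = img.shape
    half = int(np.ceil(radius_px)) + 2
    for cx, cy in centers:
        x0c, x1c = max(int(cx) - half, 0), min(int(cx) + half + 1, w)
        y0c, y1c = max(int(cy) - half, 0), min(int(cy) + half + 1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        xs = np.arange(x0c, x1c) - cx
        ys = np.arange(y0c, y1c) - cy
        r = np.hypot(ys[:, None], xs[None, :])
        img[y0c:y1c, x0c:x1c] += amplitude * np.clip(radius_px + 0.5 - r, 0.0, 1.0)


def _apply_camera_noise(signal: np.ndarray, noise: NoiseParams,
                        rng: np.random.Generator) -> np.ndarray:
    out = signal + noise.background
    if noise.shot_noise:
        out = rng.poisson(out).astype(float)
    if noise.read_noise_sigma > 0:
        out = out + rng.normal(0.0, noise.read_noise_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


def render_pointer_image(grid: PointerGridSpec, gt: SceneGroundTruth,
                         image_shape: tuple[int, int] = (1024, 1024),
                         fwhm_nm: float = DEFAULT_POINTER_FWHM_NM,
                         rng: np.random.Generator | None = None
                         ) -> tuple[RasterImage, pd.DataFrame]:
    """Render one FM exposure of a CL pointer array.

    Each commanded pointer becomes an isotropic Gaussian of the given FWHM
    (default 300 nm) at its true FM position, atop the scene background,
    followed by the camera noise model.  Returns the image and a table of
    true FM-frame centers (``id, x_px, y_px, frame``).

    Raises
    ------
    ValueError
        If any true pointer position falls outside the image.
    """
    if rng is None:
        rng = gt.rng()
    h, w = image_shape
    em = grid.em_coords()
    fm_true = gt.true_fm_positions(em)
    inside = ((fm_true[:, 0] >= 0) & (fm_true[:, 0] <= w - 1)
              & (fm_true[:, 1] >= 0) & (fm_true[:, 1] <= h - 1))
    if not inside.all():
        raise ValueError(
            f"{int((~inside).sum())} of {len(em)} pointers map outside the "
            f"{h}x{w} FM image; shrink the grid or enlarge the image")
    sigma_px = fwhm_nm / gt.fm_pixel_size_nm * _FWHM_TO_SIGMA
    signal = np.zeros((h, w))
    if gt.noise.amplitude > 0:
        _add_gaussian_spots(signal, fm_true, gt.noise.amplitude, sigma_px)
    pixels = _apply_camera_noise(signal, gt.noise, rng)
    truth = pd.DataFrame({
        "id": np.arange(len(em)),
        "x_px": fm_true[:, 0], "y_px": fm_true[:, 1],
        "frame": "FM",
    })
    return RasterImage(pixels, gt.fm_pixel_size_nm, "FM"), truth


# ---------------------------------------------------------------------------
# Coordinate mode
# ---------------------------------------------------------------------------

@dataclass
class PointerPool:
    """Pointer pairs pooled over repeated array exposures (coordinate mode)."""

    em: np.ndarray             # (M, 2) EM px
    fm: np.ndarray             # (M, 2) FM px (noisy, distorted as configured)
    array_id: np.ndarray       # (M,) exposure index
    pointer_index: np.ndarray  # (M,) grid-node index within each exposure
    fm_pixel_size_nm: float

    def __len__(self) -> int:
        return self.em.shape[0]

    @property
    def n_arrays(self) -> int:
        return int(self.array_id.max()) + 1 if len(self) else 0

    def array(self, i: int):
        from .register import PointPairSet

        m = self.array_id == i
        return PointPairSet(self.em[m], self.fm[m], self.pointer_index[m])


def simulate_pointer_pool(grid: PointerGridSpec, gt: SceneGroundTruth,
                          n_arrays: int | None = None,
                          rng: np.random.Generator | None = None) -> PointerPool:
    """Emit noisy localized pointer coordinates for sequential exposures.

    Fast path that bypasses image rendering: the observed FM position of
    every pointer is its true position plus isotropic Gaussian jitter of
    ``noise.jitter_sigma_nm``, independently per exposure.  ``n_arrays``
    defaults to ``grid.exposure_count``.
    """
    if rng is None:
        rng = gt.rng()
    if n_arrays is None:
        n_arrays = grid.exposure_count
    if n_arrays < 1:
        raise ValueError("n_arrays must be >= 1")
    em = grid.em_coords()
    fm_true = gt.true_fm_positions(em)
    n = len(em)
    sig_px = gt.noise.jitter_sigma_nm / gt.fm_pixel_size_nm
    fm_all = np.tile(fm_true, (n_arrays, 1))
    if sig_px > 0:
        fm_all = fm_all + rng.normal(0.0, sig_px, size=fm_all.shape)
    return PointerPool(
        em=np.tile(em, (n_arrays, 1)),
        fm=fm_all,
        array_id=np.repeat(np.arange(n_arrays), n),
        pointer_index=np.tile(np.arange(n), n_arrays),
        fm_pixel_size_nm=gt.fm_pixel_size_nm,
    )


# ---------------------------------------------------------------------------
# Fiducial scenes (nanospheres)
# ---------------------------------------------------------------------------

def _place_non_overlapping(n: int, lo: np.ndarray, hi: np.ndarray,
                           min_sep: float, rng: np.random.Generator,
                           max_tries: int = 5000) -> np.ndarray:
    pts: list[np.ndarray] = []
    for _ in range(max_tries):
        cand = rng.uniform(lo, hi)
        if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
            pts.append(cand)
            if len(pts) == n:
                return np.array(pts)
    raise RuntimeError(
        f"could not place {n} non-overlapping fiducials (min separation "
        f"{min_sep:.1f} px) in {max_tries} tries; reduce n or min_sep")


def render_fiducial_scene(n_spheres: int, gt: SceneGroundTruth,
                          fm_shape: tuple[int, int] = (128, 128),
                          em_shape: tuple[int, int] = (1024, 1024),
                          *,
                          em_amplitude: float = 60.0,
                          em_background: float = 100.0,
                          em_noise_sigma: float = 8.0,
                          fwhm_nm: float = DEFAULT_POINTER_FWHM_NM,
                          min_sep_nm: float | None = None,
                          rng: np.random.Generator | None = None
                          ) -> tuple[RasterImage, RasterImage, pd.DataFrame]:
    """Render matching FM and EM images of dye-doped nanosphere fiducials.

    Spheres are placed at random non-overlapping EM positions; in the EM
    image they appear as 40 nm-diameter disks with deliberately low
    signal-to-background (as for silica spheres under SEM), in the FM image
    as diffraction-limited Gaussian spots at the transform-mapped (and
    distorted) positions.  Returns both images and the true centers in both
    frames (``id, em_x_px, em_y_px, fm_x_px, fm_y_px``).
    """
    if n_spheres < 1:
        raise ValueError("n_spheres must be >= 1")
    if rng is None:
        rng = gt.rng()
    if min_sep_nm is None:
        min_sep_nm = 2.5 * fwhm_nm  # resolvable in the FM frame
    eh, ew = em_shape
    radius_em = NANOSPHERE_DIAMETER_NM / 2 / gt.em_pixel_size_nm
    margin = radius_em + 4
    em_centers = _place_non_overlapping(
        n_spheres,
        lo=np.array([margin, margin]),
        hi=np.array([ew - 1 - margin, eh - 1 - margin]),
        min_sep=min_sep_nm / gt.em_pixel_size_nm, rng=rng)
    fm_centers = gt.true_fm_positions(em_centers)
    fh, fw = fm_shape
    if ((fm_centers[:, 0] < 0) | (fm_centers[:, 0] > fw - 1)
            | (fm_centers[:, 1] < 0) | (fm_centers[:, 1] > fh - 1)).any():
        raise ValueError("fiducials map outside the FM image; check transform")

    em_signal = np.zeros(em_shape)
    _add_disks(em_signal, em_centers, em_amplitude, radius_em)
    em_pixels = em_signal + em_background
    if em_noise_sigma > 0 and gt.noise.shot_noise:
        em_pixels = em_pixels + rng.normal(0.0, em_noise_sigma, size=em_shape)
    em_img = RasterImage(np.clip(em_pixels, 0, None), gt.em_pixel_size_nm, "EM")

    sigma_px = fwhm_nm / gt.fm_pixel_size_nm * _FWHM_TO_SIGMA
    fm_signal = np.zeros(fm_shape)
    _add_gaussian_spots(fm_signal, fm_centers, gt.noise.amplitude, sigma_px)
    fm_img = RasterImage(_apply_camera_noise(fm_signal, gt.noise, rng),
                         gt.fm_pixel_size_nm, "FM")

    truth = pd.DataFrame({
        "id": np.arange(n_spheres),
        "em_x_px": em_centers[:, 0], "em_y_px": em_centers[:, 1],
        "fm_x_px": fm_centers[:, 0], "fm_y_px": fm_centers[:, 1],
    })
    return fm_img, em_img, truth


def simulate_fiducial_coordinates(n_spheres: int, gt: SceneGroundTruth,
                                  em_extent_px: tuple[float, float] = (1024.0, 1024.0),
                                  *,
                                  loc_noise_fm_nm: float = 5.0,
                                  loc_noise_em_nm: float = 5.0,
                                  min_sep_nm: float = 200.0,
                                  rng: np.random.Generator | None = None
                                  ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Coordinate-mode fiducial scene: noisy localizations in both frames.

    Emulates fitting sphere centers in the two images: the returned EM and
    FM coordinates carry independent isotropic Gaussian localization noise
    of the stated sigmas (nm), converted to the respective pixel sizes.
    Returns ``(em_obs, fm_obs, truth_table)``.
    """
    if rng is None:
        rng = gt.rng()
    ex, ey = em_extent_px
    margin = 8.0
    em_true = _place_non_overlapping(
        n_spheres, lo=np.array([margin, margin]),
        hi=np.array([ex - 1 - margin, ey - 1 - margin]),
        min_sep=min_sep_nm / gt.em_pixel_size_nm, rng=rng)
    fm_true = gt.true_fm_positions(em_true)
    em_obs = em_true + rng.normal(0, loc_noise_em_nm / gt.em_pixel_size_nm,
                                  size=em_true.shape)
    fm_obs = fm_true + rng.normal(0, loc_noise_fm_nm / gt.fm_pixel_size_nm,
                                  size=fm_true.shape)
    truth = pd.DataFrame({
        "id": np.arange(n_spheres),
        "em_x_px": em_true[:, 0], "em_y_px": em_true[:, 1],
        "fm_x_px": fm_true[:, 0], "fm_y_px": fm_true[:, 1],
    })
    return em_obs, fm_obs, truth
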