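"""EM->FM similarity registration and residual-distortion calibration.

The linear part of the mapping between the electron-microscope (EM) and
fluorescence-microscope (FM) coordinate frames of an integrated CLEM
instrument is a similarity transform: isotropic scale ``s``, rotation
``theta`` and translation ``(t_x, t_y)``.  Writing ``a = s*cos(theta)`` and
``b = s*sin(theta)`` the mapping of an EM point ``(x, y)`` into FM pixels is

    x_F = a*x - b*y + t_x
    y_F = b*x + a*y + t_y

which is linear in ``(a, b, t_x, t_y)`` and therefore admits a closed-form
least-squares fit.  Reflections are unrepresentable by construction: a
mirrored point set simply fits poorly and shows up in the residuals.

What the similarity cannot absorb — the field-dependent optical/scan
distortions of the two microscopes — appears in the residual difference
vectors ``delta_i = fm_i - T(em_i)``.  Averaging those residuals over many
sequentially exposed pointer arrays yields the distortion field, which is
calibrated once per instrument alignment and then subtracted from every
subsequent registration.

Coordinate convention (everywhere in this package): 0-based pixel indices,
a coordinate is the centre of its pixel, x grows with column index and y
with row index; physical position is pixel coordinate times pixel size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimilarityTransform",
    "PointPairSet",
    "DifferenceVectorSet",
    "DistortionField",
    "fit_similarity",
    "difference_vectors",
    "estimate_distortion_field",
    "register_with_distortion",
]


# ---------------------------------------------------------------------------
# Similarity transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityTransform:
    """Scale + rotation + translation mapping EM coordinates to FM pixels.

    Parameters
    ----------
    scale:
        Dimensionless isotropic scale ``s > 0``; no reflection is possible.
    rotation:
        Rotation angle in radians, counter-clockwise in the pixel frame
        (x right, y down), reported in ``(-pi, pi]``.
    tx, ty:
        Translation in FM pixels.
    """

    scale: float
    rotation: float
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.scale, self.rotation, self.tx, self.ty]).all():
            raise ValueError("transform parameters must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0 (reflection excluded), got {self.scale}")

    # -- derived linear parameters ------------------------------------
    @property
    def a(self) -> float:
        return self.scale * np.cos(self.rotation)

    @property
    def b(self) -> float:
        return self.scale * np.sin(self.rotation)

    @classmethod
    def from_ab(cls, a: float, b: float, tx: float = 0.0, ty: float = 0.0) -> "SimilarityTransform":
        s = float(np.hypot(a, b))
        if s == 0:
            raise ValueError("degenerate transform: a = b = 0")
        return cls(scale=s, rotation=float(np.arctan2(b, a)), tx=float(tx), ty=float(ty))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(scale=1.0, rotation=0.0, tx=0.0, ty=0.0)

    # -- application ---------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(N, 2)`` or ``(2,)`` EM points into the FM frame."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        a, b = self.a, self.b
        out = np.empty_like(pts)
        out[:, 0] = a * pts[:, 0] - b * pts[:, 1] + self.tx
        out[:, 1] = b * pts[:, 0] + a * pts[:, 1] + self.ty
        return out[0] if single else out

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.apply(points)

    def inverse(self) -> "SimilarityTransform":
        """Exact inverse transform (scale 1/s, rotation -theta)."""
        a, b = self.a, self.b
        s2 = self.scale**2
        ai, bi = a / s2, -b / s2
        txi = -(ai * self.tx - bi * self.ty)
        tyi = -(bi * self.tx + ai * self.ty)
        return SimilarityTransform.from_ab(ai, bi, txi, tyi)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        a1, b1 = other.a, other.b
        a2, b2 = self.a, self.b
        a = a2 * a1 - b2 * b1
        b = b2 * a1 + a2 * b1
        t = self.apply(np.array([other.tx, other.ty]))
        return SimilarityTransform.from_ab(a, b, t[0], t[1])

    def to_dict(self, fm_pixel_size_nm: float | None = None,
                em_pixel_size_nm: float | None = None) -> dict:
        d = {
            "s": float(self.scale),
            "theta_rad": float(self.rotation),
            "t_x_px": float(self.tx),
            "t_y_px": float(self.ty),
        }
        if fm_pixel_size_nm is not None:
            d["fm_pixel_size_nm"] = float(fm_pixel_size_nm)
            d["t_x_nm"] = float(self.tx * fm_pixel_size_nm)
            d["t_y_nm"] = float(self.ty * fm_pixel_size_nm)
        if em_pixel_size_nm is not None:
            d["em_pixel_size_nm"] = float(em_pixel_size_nm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(scale=d["s"], rotation=d["theta_rad"], tx=d["t_x_px"], ty=d["t_y_px"])


# ---------------------------------------------------------------------------
# Matched point pairs
# ---------------------------------------------------------------------------

@dataclass
class PointPairSet:
    """One-to-one matched (EM, FM) coordinate pairs from a pointer exposure.

    ``em`` is ``(N, 2)`` in EM pixels, ``fm`` is ``(N, 2)`` in FM pixels and
    ``pointer_index`` identifies the commanded grid node of each pair.
    Detections and commanded nodes left unmatched by the pairing stage are
    kept for diagnostics.
    """

    em: np.ndarray
    fm: np.ndarray
    pointer_index: np.ndarray
    unmatched_fm: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    unmatched_em_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.em = np.atleast_2d(np.asarray(self.em, dtype=float))
        self.fm = np.atleast_2d(np.asarray(self.fm, dtype=float))
        self.pointer_index = np.asarray(self.pointer_index, dtype=int)
        if self.em.shape != self.fm.shape or self.em.shape[0] != self.pointer_index.size:
            raise ValueError("em, fm and pointer_index must have matching lengths")
        if np.unique(self.pointer_index).size != self.pointer_index.size:
            raise ValueError("pointer_index must be unique (one-to-one pairing)")

    def __len__(self) -> int:
        return self.em.shape[0]

    def subset(self, idx: np.ndarray) -> "PointPairSet":
        return PointPairSet(self.em[idx], self.fm[idx], self.pointer_index[idx])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "pointer_index": self.pointer_index,
            "em_x_px": self.em[:, 0], "em_y_px": self.em[:, 1],
            "fm_x_px": self.fm[:, 0], "fm_y_px": self.fm[:, 1],
        })


# ---------------------------------------------------------------------------
# Least-squares similarity fit
# ---------------------------------------------------------------------------

def fit_similarity(pairs: PointPairSet | tuple[np.ndarray, np.ndarray]) -> SimilarityTransform:
    """Closed-form least-squares fit of the EM->FM similarity transform.

    Minimises ``sum_i |fm_i - T(em_i)|^2`` over ``(a, b, t_x, t_y)``; the
    solution is obtained from centred coordinates:

        a = sum(x~*u~ + y~*v~) / sum(x~^2 + y~^2)
        b = sum(x~*v~ - y~*u~) / sum(x~^2 + y~^2)

    with the translation fixed by mapping the EM centroid onto the FM
    centroid.  At least 2 non-coincident pairs are required; exactly 2
    general-position pairs give the unique zero-residual solution.

    Raises
    ------
    ValueError
        With fewer than 2 pairs, or when all EM points coincide (singular
        system), or when the fit collapses to zero scale.
    """
    if isinstance(pairs, PointPairSet):
        em, fm = pairs.em, pairs.fm
    else:
        em = np.atleast_2d(np.asarray(pairs[0], dtype=float))
        fm = np.atleast_2d(np.asarray(pairs[1], dtype=float))
    n = em.shape[0]
    if n < 2:
        raise ValueError(
            f"at least 2 pointer pairs are needed to fit the transform (got {n})")
    em_c = em.mean(axis=0)
    fm_c = fm.mean(axis=0)
    x = em - em_c
    u = fm - fm_c
    denom = float(np.sum(x**2))
    if denom <= 0:
        raise ValueError("all EM points coincide: similarity fit is singular")
    a = float(np.sum(x[:, 0] * u[:, 0] + x[:, 1] * u[:, 1])) / denom
    b = float(np.sum(x[:, 0] * u[:, 1] - x[:, 1] * u[:, 0])) / denom
    if a == 0.0 and b == 0.0:
        raise ValueError("degenerate fit: all FM points coincide (zero scale)")
    tx = fm_c[0] - (a * em_c[0] - b * em_c[1])
    ty = fm_c[1] - (b * em_c[0] + a * em_c[1])
    return SimilarityTransform.from_ab(a, b, tx, ty)


# ---------------------------------------------------------------------------
# Difference vectors (registration residuals)
# ---------------------------------------------------------------------------

@dataclass
class DifferenceVectorSet:
    """Residuals ``delta_i = fm_i - T(em_i)`` of one registered array.

    ``delta_px`` is ``(N, 2)`` in FM pixels; ``fm_position_px`` is the mapped
    position ``T(em_i)`` at which each residual is anchored.  ``delta_nm``
    converts through the FM pixel size when one is known.
    """

    pointer_index: np.ndarray
    fm_position_px: np.ndarray
    delta_px: np.ndarray
    fm_pixel_size_nm: float | None = None

    @property
    def delta_nm(self) -> np.ndarray:
        if self.fm_pixel_size_nm is None:
            raise ValueError("fm_pixel_size_nm not set")
        return self.delta_px * self.fm_pixel_size_nm

    @property
    def rms_px(self) -> float:
        return float(np.sqrt(np.mean(np.sum(self.delta_px**2, axis=1))))

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({
            "pointer_index": self.pointer_index,
            "fm_x_px": self.fm_position_px[:, 0],
            "fm_y_px": self.fm_position_px[:, 1],
            "dx_px": self.delta_px[:, 0],
            "dy_px": self.delta_px[:, 1],
        })
        if self.fm_pixel_size_nm is not None:
            df["dx_nm"] = df["dx_px"] * self.fm_pixel_size_nm
            df["dy_nm"] = df["dy_px"] * self.fm_pixel_size_nm
        return df


def difference_vectors(pairs: PointPairSet,
                       transform: SimilarityTransform | None = None,
                       fm_pixel_size_nm: float | None = None) -> DifferenceVectorSet:
    """Residual difference vectors of ``pairs`` under ``transform``.

    When ``transform`` is omitted it is fitted on the pairs themselves, in
    which case the residuals satisfy the least-squares orthogonality
    identities (zero sum, zero projection on the scale and rotation
    degrees of freedom).
    """
    if transform is None:
        transform = fit_similarity(pairs)
    mapped = transform.apply(pairs.em)
    return DifferenceVectorSet(
        pointer_index=pairs.pointer_index.copy(),
        fm_position_px=mapped,
        delta_px=pairs.fm - mapped,
        fm_pixel_size_nm=fm_pixel_size_nm,
    )


# ---------------------------------------------------------------------------
# Distortion field
# ---------------------------------------------------------------------------

@dataclass
class DistortionField:
    """Mean residual vectors sampled on the calibration pointer lattice.

    The field lives in the FM frame: ``node_xy_px[r, c]`` is the FM-pixel
    position of lattice node ``(r, c)`` and ``vectors_nm[r, c]`` the mean
    difference vector there.  ``grid_to_fm`` maps fractional lattice indices
    ``(col, row)`` to FM pixels, so arbitrary FM positions can be evaluated
    by bilinear interpolation in lattice-index space even when the lattice
    is rotated in the FM frame.
    """

    node_xy_px: np.ndarray           # (R, C, 2)
    vectors_nm: np.ndarray           # (R, C, 2)
    counts: np.ndarray               # (R, C)
    sd_nm: np.ndarray                # (R, C) pooled per-axis sd
    anomaly: np.ndarray              # (R, C) bool
    grid_to_fm: SimilarityTransform
    fm_pixel_size_nm: float

    def __post_init__(self) -> None:
        r, c = self.counts.shape
        if self.node_xy_px.shape != (r, c, 2) or self.vectors_nm.shape != (r, c, 2):
            raise ValueError("inconsistent field array shapes")
        if (self.counts < 1).any():
            raise ValueError("every reported node needs at least one sample")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def evaluate(self, points_fm_px: np.ndarray, strict: bool = False) -> np.ndarray:
        """Bilinear interpolation of the field (nm) at FM-pixel positions.

        Outside the lattice's coverage the value of the nearest node is used
        and a warning emitted, unless ``strict`` raises instead — the field
        is never extrapolated beyond the calibrated field of view.
        """
        pts = np.atleast_2d(np.asarray(points_fm_px, dtype=float))
        uv = self.grid_to_fm.inverse().apply(pts)  # (col, row) fractional indices
        rows, cols = self.shape
        u, v = uv[:, 0], uv[:, 1]
        tol = 1e-9
        outside = (u < -tol) | (u > cols - 1 + tol) | (v < -tol) | (v > rows - 1 + tol)
        if outside.any():
            msg = (f"{int(outside.sum())} of {len(pts)} positions fall outside the "
                   "calibrated distortion field; using nearest-node values")
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        u = np.clip(u, 0, cols - 1)
        v = np.clip(v, 0, rows - 1)
        c0 = np.clip(np.floor(u).astype(int), 0, cols - 2) if cols > 1 else np.zeros_like(u, int)
        r0 = np.clip(np.floor(v).astype(int), 0, rows - 2) if rows > 1 else np.zeros_like(v, int)
        fu = (u - c0) if cols > 1 else np.zeros_like(u)
        fv = (v - r0) if rows > 1 else np.zeros_like(v)
        c1 = np.minimum(c0 + 1, cols - 1)
        r1 = np.minimum(r0 + 1, rows - 1)
        w00 = (1 - fu) * (1 - fv)
        w10 = fu * (1 - fv)
        w01 = (1 - fu) * fv
        w11 = fu * fv
        V = self.vectors_nm
        out = (w00[:, None] * V[r0, c0] + w10[:, None] * V[r0, c1]
               + w01[:, None] * V[r1, c0] + w11[:, None] * V[r1, c1])
        return out

    def to_dataframe(self):
        import pandas as pd

        r, c = self.shape
        rr, cc = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
        return pd.DataFrame({
            "row": rr.ravel(), "col": cc.ravel(),
            "x_px": self.node_xy_px[..., 0].ravel(),
            "y_px": self.node_xy_px[..., 1].ravel(),
            "dx_nm": self.vectors_nm[..., 0].ravel(),
            "dy_nm": self.vectors_nm[..., 1].ravel(),
            "n": self.counts.ravel(),
            "sd_nm": self.sd_nm.ravel(),
            "anomaly": self.anomaly.ravel(),
        })

    def to_dict(self) -> dict:
        return {
            "rows": int(self.shape[0]),
            "cols": int(self.shape[1]),
            "grid_to_fm": self.grid_to_fm.to_dict(),
            "fm_pixel_size_nm": float(self.fm_pixel_size_nm),
            "node_xy_px": self.node_xy_px.tolist(),
            "vectors_nm": self.vectors_nm.tolist(),
            "counts": self.counts.tolist(),
            "sd_nm": self.sd_nm.tolist(),
            "anomaly": self.anomaly.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistortionField":
        return cls(
            node_xy_px=np.asarray(d["node_xy_px"], dtype=float),
            vectors_nm=np.asarray(d["vectors_nm"], dtype=float),
            counts=np.asarray(d["counts"], dtype=int),
            sd_nm=np.asarray(d["sd_nm"], dtype=float),
            anomaly=np.asarray(d["anomaly"], dtype=bool),
            grid_to_fm=SimilarityTransform.from_dict(d["grid_to_fm"]),
            fm_pixel_size_nm=float(d["fm_pixel_size_nm"]),
        )


def _local_median_field(vectors: np.ndarray) -> np.ndarray:
    """Per-node median of the 8-neighbourhood (excluding the node itself)."""
    from scipy.ndimage import median_filter

    # median over 3x3 window including self is a fine robust smoother for
    # anomaly detection; a single deviant node barely moves it
    out = np.empty_like(vectors)
    for k in range(2):
        out[..., k] = median_filter(vectors[..., k], size=3, mode="nearest")
    return out


def estimate_distortion_field(array_stack: list[DifferenceVectorSet],
                              grid_shape: tuple[int, int],
                              fm_pixel_size_nm: float,
                              anomaly_k: float = 5.0) -> DistortionField:
    """Average residual stacks from repeated pointer arrays into a field.

    Every array in the stack must come from the same commanded grid (same
    pointer indexing, ``rows*cols`` nodes).  Per node the mean residual
    (converted to nm), sample count and per-axis pooled standard deviation
    are reported.  Nodes whose mean deviates from a 3x3 local-median
    smoothed field by more than ``anomaly_k`` standard errors are flagged
    anomalous but retained — such outliers are a property of the camera
    pixel array, not noise, and belong in the field.

    Raises
    ------
    ValueError
        On an empty stack or when an array does not cover the grid shape.
    """
    if len(array_stack) == 0:
        raise ValueError("need at least one difference-vector set")
    rows, cols = grid_shape
    n_nodes = rows * cols
    sum_v = np.zeros((n_nodes, 2))
    sum_v2 = np.zeros((n_nodes, 2))
    sum_p = np.zeros((n_nodes, 2))
    count = np.zeros(n_nodes, dtype=int)
    for dvs in array_stack:
        idx = dvs.pointer_index
        if idx.min() < 0 or idx.max() >= n_nodes:
            raise ValueError(
                f"pointer indices {idx.min()}..{idx.max()} do not fit a "
                f"{rows}x{cols} grid")
        d_nm = dvs.delta_px * fm_pixel_size_nm
        np.add.at(sum_v, idx, d_nm)
        np.add.at(sum_v2, idx, d_nm**2)
        np.add.at(sum_p, idx, dvs.fm_position_px)
        np.add.at(count, idx, 1)
    if (count == 0).any():
        raise ValueError("some grid nodes received no samples")
    mean_v = (sum_v / count[:, None]).reshape(rows, cols, 2)
    node_xy = (sum_p / count[:, None]).reshape(rows, cols, 2)
    cnt = count.reshape(rows, cols)
    with np.errstate(invalid="ignore"):
        var = (sum_v2 / count[:, None] - (sum_v / count[:, None]) ** 2)
    var = np.clip(var, 0, None)
    # unbiased per-axis variance, pooled over x and y
    nf = count[:, None].astype(float)
    var = np.where(nf > 1, var * nf / np.maximum(nf - 1, 1.0), 0.0)
    sd = np.sqrt(var.mean(axis=1)).reshape(rows, cols)

    smoothed = _local_median_field(mean_v)
    dev = np.linalg.norm(mean_v - smoothed, axis=-1)
    se = sd / np.sqrt(np.maximum(cnt, 1))
    se_floor = np.median(se[se > 0]) if (se > 0).any() else 0.0
    se_eff = np.where(se > 0, se, se_floor)
    # the smooth field's curvature leaves small deviations from the local
    # median everywhere; an anomaly must also stand far outside that
    # distribution, not just outside its own standard error
    dev_scale = 1.4826 * np.median(dev)
    with np.errstate(divide="ignore", invalid="ignore"):
        anomaly = (se_eff > 0) & (dev > anomaly_k * se_eff) \
            & (dev > 5.0 * max(dev_scale, 1e-12))

    # lattice-index -> FM mapping fitted on the node positions
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    idx_pts = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
    grid_to_fm = fit_similarity((idx_pts, node_xy.reshape(-1, 2)))

    return DistortionField(
        node_xy_px=node_xy, vectors_nm=mean_v, counts=cnt, sd_nm=sd,
        anomaly=anomaly, grid_to_fm=grid_to_fm,
        fm_pixel_size_nm=fm_pixel_size_nm,
    )


def register_with_distortion(pairs: PointPairSet, dist_field: DistortionField | None,
                             strict: bool = False
                             ) -> tuple[SimilarityTransform, DifferenceVectorSet]:
    """Distortion-corrected similarity registration.

    Two-pass scheme: fit the similarity on the raw pairs, evaluate the
    calibrated field at each mapped position ``T(em_i)``, subtract the
    interpolated vector from the observed FM position and refit.  A single
    correction pass suffices — with distortions of order 200 nm over a
    >=50 um field the second-order term is far below localization noise.

    With ``dist_field=None`` this reduces exactly to :func:`fit_similarity`.
    Returns the corrected transform and the corrected residuals.
    """
    t0 = fit_similarity(pairs)
    if dist_field is None:
        return t0, difference_vectors(pairs, t0)
    mapped = t0.apply(pairs.em)
    corr_px = dist_field.evaluate(mapped, strict=strict) / dist_field.fm_pixel_size_nm
    corrected = PointPairSet(pairs.em, pairs.fm - corr_px, pairs.pointer_index)
    t1 = fit_similarity(corrected)
    dvs = difference_vectors(corrected, t1, fm_pixel_size_nm=dist_field.fm_pixel_size_nm)
    return t1, dvs
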