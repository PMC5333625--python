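"""End-to-end overlay generation and pipeline orchestration.

Ties the stages together: localize CL pointers in the FM exposure, sort
them against the commanded grid, fit the (distortion-corrected) EM->FM
similarity, resample the EM image into the FM pixel frame and blend a
composite.  Also provides the fiducial cross-validation: registering the
same scene independently from nanosphere fiducial pairs and comparing
where the two registrations send each fiducial.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from . import io as clio
from .localize import localize_all
from .pairing import match_grid
from .register import (DifferenceVectorSet, DistortionField, PointPairSet,
                       SimilarityTransform, difference_vectors, fit_similarity,
                       register_with_distortion)
from .simulate import PointerGridSpec, RasterImage

__all__ = ["OverlayResult", "build_overlay", "run_pipeline",
           "compare_fiducial_registration", "PipelineError"]

log = logging.getLogger("clpointer")

#: additive blend colors: FM in orange, EM in gray (cosmetic, configurable)
FM_COLOR = (1.0, 0.55, 0.0)
EM_COLOR = (0.7, 0.7, 0.7)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class OverlayResult:
    """EM image registered into the FM pixel grid plus the blended composite."""

    registered_em: np.ndarray     # FM-shaped, EM intensities, 0 outside footprint
    footprint: np.ndarray         # FM-shaped bool, True where EM data exists
    composite: np.ndarray         # (H, W, 3) float RGB in [0, 1]
    transform: SimilarityTransform
    report: dict

    @property
    def shape(self) -> tuple[int, int]:
        return self.registered_em.shape


def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(img, [1.0, 99.8])
    if hi <= lo:
        return np.zeros_like(img, dtype=float)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def build_overlay(fm: RasterImage, em: RasterImage, t: SimilarityTransform,
                  dist_field: DistortionField | None = None,
                  fm_color=FM_COLOR, em_color=EM_COLOR) -> OverlayResult:
    """Resample the EM image into the FM frame and blend a composite.

    Every FM pixel center is pulled back through the registration (and the
    distortion correction, to first order in the small field) to an EM
    position, where the EM image is sampled with bilinear interpolation.
    FM pixels mapping outside the EM footprint are zero/transparent.

    Raises
    ------
    ValueError
        If the EM footprint lies entirely outside the FM frame.
    """
    h, w = fm.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts_fm = np.column_stack([xx.ravel(), yy.ravel()])
    if dist_field is not None:
        # forward model: fm = T(em) + D(T(em)); invert to first order
        pts_corr = pts_fm - dist_field.evaluate(pts_fm) / fm.pixel_size_nm
    else:
        pts_corr = pts_fm
    pts_em = t.inverse().apply(pts_corr)
    eh, ew = em.shape
    inside = ((pts_em[:, 0] >= 0) & (pts_em[:, 0] <= ew - 1)
              & (pts_em[:, 1] >= 0) & (pts_em[:, 1] <= eh - 1))
    if not inside.any():
        raise ValueError("transform places the EM footprint entirely outside "
                         "the FM frame")
    sampled = map_coordinates(em.pixels, [pts_em[:, 1], pts_em[:, 0]],
                              order=1, mode="constant", cval=0.0)
    sampled[~inside] = 0.0
    registered = sampled.reshape(h, w)
    footprint = inside.reshape(h, w)

    fm_n = _normalize(fm.pixels)
    em_n = np.where(footprint, _normalize(registered), 0.0)
    composite = np.clip(
        fm_n[..., None] * np.asarray(fm_color)
        + em_n[..., None] * np.asarray(em_color), 0.0, 1.0)

    report = {
        "transform": t.to_dict(fm.pixel_size_nm, em.pixel_size_nm),
        "em_footprint_fraction": float(footprint.mean()),
        "distortion_corrected": dist_field is not None,
    }
    return OverlayResult(registered_em=registered, footprint=footprint,
                         composite=composite, transform=t, report=report)


# ---------------------------------------------------------------------------
# Fiducial cross-validation
# ---------------------------------------------------------------------------

def compare_fiducial_registration(fid_em: np.ndarray, fid_fm: np.ndarray,
                                  cl_transform: SimilarityTransform,
                                  dist_field: DistortionField | None = None,
                                  fm_pixel_size_nm: float = 100.0
                                  ) -> pd.DataFrame:
    """Compare CL-pointer-based and fiducial-based registrations per fiducial.

    Fits an independent similarity on the fiducial (EM, FM) center pairs,
    then evaluates both registrations at every fiducial EM position.  The
    returned table holds, per fiducial, the residual difference vector
    under each registration and the difference between the two mappings
    (all in nm).  The fiducial-based residuals sum to zero by the
    least-squares identity; the mapping differences quantify how close the
    fiducial-free CL registration comes to the conventional one.
    """
    fid_em = np.atleast_2d(np.asarray(fid_em, float))
    fid_fm = np.atleast_2d(np.asarray(fid_fm, float))
    if fid_em.shape[0] < 2:
        raise ValueError("need at least 2 fiducials localizable in both frames")
    t_fid = fit_similarity((fid_em, fid_fm))
    mapped_fid = t_fid.apply(fid_em)
    mapped_cl = cl_transform.apply(fid_em)
    if dist_field is not None:
        mapped_cl = mapped_cl + dist_field.evaluate(mapped_cl) / fm_pixel_size_nm
    d_cl = (fid_fm - mapped_cl) * fm_pixel_size_nm
    d_fid = (fid_fm - mapped_fid) * fm_pixel_size_nm
    d_map = (mapped_cl - mapped_fid) * fm_pixel_size_nm
    return pd.DataFrame({
        "id": np.arange(fid_em.shape[0]),
        "delta_cl_x_nm": d_cl[:, 0], "delta_cl_y_nm": d_cl[:, 1],
        "delta_fid_x_nm": d_fid[:, 0], "delta_fid_y_nm": d_fid[:, 1],
        "mapping_diff_x_nm": d_map[:, 0], "mapping_diff_y_nm": d_map[:, 1],
        "mapping_diff_nm": np.linalg.norm(d_map, axis=1),
    })


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("fm_image", "em_image", "pointer_image", "grid")
_REQUIRED_GRID_KEYS = ("rows", "cols", "spacing_px")


def _validate_config(config: dict) -> None:
    missing = [k for k in _REQUIRED_KEYS if k not in config]
    if missing:
        raise PipelineError("config", f"missing required keys: {missing}")
    gmissing = [k for k in _REQUIRED_GRID_KEYS if k not in config["grid"]]
    if gmissing:
        raise PipelineError("config", f"grid spec missing keys: {gmissing}")


def run_pipeline(config: dict, out_dir: str | Path) -> OverlayResult:
    """Full registration pipeline from a validated config dictionary.

    Stages: localize the CL pointer exposure -> sort detections against the
    commanded grid -> fit the similarity (with distortion correction when a
    calibrated field is configured) -> resample the EM image into the FM
    frame.  Writes ``transform.json``, ``pairs.csv``, ``residuals.csv``,
    ``registered_em.tif``, ``composite.png`` and ``report.json`` under
    ``out_dir``.  Configuration is validated before any stage runs; stage
    failures raise :class:`PipelineError` naming the stage, with partial
    outputs left in place for debugging.
    """
    _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]

    fm = clio.read_image(config["fm_image"], config.get("fm_pixel_size_nm"), "FM")
    em = clio.read_image(config["em_image"], config.get("em_pixel_size_nm"), "EM")
    pointer_img = clio.read_image(config["pointer_image"],
                                  config.get("fm_pixel_size_nm"), "FM")
    g = config["grid"]
    grid = PointerGridSpec(rows=int(g["rows"]), cols=int(g["cols"]),
                           spacing_px=float(g["spacing_px"]),
                           origin_px=tuple(g.get("origin_px", (0.0, 0.0))))
    dist_field = (clio.read_field(config["distortion_field"])
                  if config.get("distortion_field") else None)
    fwhm_px = float(config.get("pointer_fwhm_nm", 300.0)) / pointer_img.pixel_size_nm

    try:
        centers, _ = localize_all(pointer_img, grid.n_pointers, fwhm_px=fwhm_px)
        log.info("localize: %d pointer centers found", len(centers))
    except Exception as e:
        raise PipelineError("localize", str(e)) from e
    try:
        pairs = match_grid(centers, grid)
        log.info("pair: %d/%d pairs kept, %d spurious detections",
                 len(pairs), grid.n_pointers, len(pairs.unmatched_fm))
    except Exception as e:
        raise PipelineError("pair", str(e)) from e
    try:
        t, dvs = register_with_distortion(pairs, dist_field)
        if dvs.fm_pixel_size_nm is None:
            dvs.fm_pixel_size_nm = fm.pixel_size_nm
        log.info("register: s=%.6f theta=%.4f deg, residual RMS %.4f px",
                 t.scale, np.rad2deg(t.rotation), dvs.rms_px)
    except Exception as e:
        raise PipelineError("register", str(e)) from e

    clio.write_transform(out / "transform.json", t, fm.pixel_size_nm,
                         em.pixel_size_nm,
                         extra={"config_hash": cfg_hash})
    pairs.to_dataframe().to_csv(out / "pairs.csv", index=False)
    dvs.to_dataframe().to_csv(out / "residuals.csv", index=False)

    try:
        result = build_overlay(fm, em, t, dist_field)
        log.info("overlay: EM footprint covers %.1f%% of the FM frame",
                 100 * result.report["em_footprint_fraction"])
    except Exception as e:
        raise PipelineError("overlay", str(e)) from e

    clio.write_image(out / "registered_em.tif",
                     RasterImage(result.registered_em, fm.pixel_size_nm, "EM"))
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(out / "composite.png", result.composite)
    result.report.update({
        "config_hash": cfg_hash,
        "n_pairs": len(pairs),
        "n_unmatched_fm": int(len(pairs.unmatched_fm)),
        "residual_rms_px": dvs.rms_px,
        "residual_rms_nm": dvs.rms_px * fm.pixel_size_nm,
    })
    (out / "report.json").write_text(
        json.dumps(result.report, indent=2, sort_keys=True) + "\n")
    return result
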