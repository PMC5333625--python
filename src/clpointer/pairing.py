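"""Correspondence between detected FM spots and the commanded EM grid.

One FM exposure captures a whole CL pointer array, so the localized spot
centers come back as an unordered point cloud that must be matched
one-to-one with the commanded beam-grid nodes before any transform can be
fitted.  The match must tolerate an unknown translation, rotation and
scale between the frames, missing spots (failed detections) and spurious
detections (noise peaks, debris).

Strategy: an initial similarity guess from the outer corners of the
detected cloud, then iterative mutual-nearest-neighbour pairing with
robust discarding and refitting until the pair set is stable.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .register import PointPairSet, SimilarityTransform, fit_similarity
from .simulate import PointerGridSpec

__all__ = ["initial_guess_from_edges", "pair_by_iterative_nn", "match_grid"]


def _extreme_corners(points: np.ndarray) -> np.ndarray:
    """Pick 4 extreme detections approximating the cloud's corners.

    Greedy farthest-point construction on the convex hull: works for any
    grid rotation, unlike axis-aligned extremes.  Returned in cyclic
    (counter-clockwise in y-down pixel coords) order around the centroid.
    """
    try:
        hull = ConvexHull(points)
    except QhullError as e:
        raise ValueError("degenerate detection cloud (collinear points?): "
                         f"{e}") from None
    hp = points[hull.vertices]
    centroid = points.mean(axis=0)
    i1 = int(np.argmax(np.linalg.norm(hp - centroid, axis=1)))
    i2 = int(np.argmax(np.linalg.norm(hp - hp[i1], axis=1)))
    # third: farthest from the line through p1, p2
    d12 = hp[i2] - hp[i1]
    d12 /= np.linalg.norm(d12)
    perp = np.abs((hp - hp[i1]) @ np.array([-d12[1], d12[0]]))
    i3 = int(np.argmax(perp))
    # fourth: maximize total quadrilateral area
    def tri_area(a, b, c):
        return 0.5 * np.abs((b[0] - a[0]) * (c[1] - a[1])
                            - (c[0] - a[0]) * (b[1] - a[1]))

    areas = [tri_area(hp[i1], hp[i2], q) + tri_area(hp[i1], hp[i3], q)
             + tri_area(hp[i2], hp[i3], q) for q in hp]
    for i in (i1, i2, i3):
        areas[i] = -1.0
    i4 = int(np.argmax(areas))
    corners = hp[[i1, i2, i3, i4]]
    ang = np.arctan2(corners[:, 1] - centroid[1], corners[:, 0] - centroid[0])
    return corners[np.argsort(ang)]


def initial_guess_from_edges(detections: np.ndarray, grid: PointerGridSpec,
                             expected_rotation: float = 0.0
                             ) -> SimilarityTransform:
    """Similarity guess from the outer edges of the detected cloud.

    Matches the 4 extreme detections against the grid's corner coordinates,
    trying the 4 cyclic corner assignments (reflections are impossible for
    a physical FM/EM geometry, so only cyclic shifts need testing) and
    keeping the assignment with the lowest least-squares corner misfit.
    For a square grid the 4 assignments are exact ties by symmetry, so
    near-tie assignments are broken toward the rotation closest to
    ``expected_rotation`` — the frames of an integrated microscope are
    nearly aligned by construction, so the default prior is zero rotation.

    Raises
    ------
    ValueError
        With fewer than 4 detections or a degenerate (collinear) cloud.
    """
    det = np.atleast_2d(np.asarray(detections, dtype=float))
    if det.shape[0] < 4:
        raise ValueError(f"need at least 4 detections for a corner guess, got {det.shape[0]}")
    corners_fm = _extreme_corners(det)
    corners_em = grid.corner_coords()
    cen = corners_em.mean(axis=0)
    ang = np.arctan2(corners_em[:, 1] - cen[1], corners_em[:, 0] - cen[0])
    corners_em = corners_em[np.argsort(ang)]

    cands: list[tuple[float, float, SimilarityTransform]] = []
    diag2 = float(np.sum((corners_fm.max(0) - corners_fm.min(0)) ** 2))
    for shift in range(4):
        em_try = np.roll(corners_em, shift, axis=0)
        t = fit_similarity((em_try, corners_fm))
        cost = float(np.sum((t.apply(em_try) - corners_fm) ** 2))
        rot_dist = abs(float(np.arctan2(
            np.sin(t.rotation - expected_rotation),
            np.cos(t.rotation - expected_rotation))))
        cands.append((cost, rot_dist, t))
    min_cost = min(c for c, _, _ in cands)
    # ties (square grids, noisy corners): anything within the noise floor of
    # the best misfit competes; pick the rotation nearest the prior
    tie_band = max(2.0 * min_cost, 1e-4 * diag2)
    viable = [c for c in cands if c[0] <= tie_band]
    viable.sort(key=lambda c: (c[1], c[0]))
    return viable[0][2]


def _nn_loop(det: np.ndarray, em: np.ndarray, init: SimilarityTransform,
             spacing_px: float, discard_factor: float, floor_px: float,
             max_iter: int) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Mutual-NN / discard / refit loop; returns (grid idx, det idx,
    median residual, converged)."""
    t = init
    prev_key: tuple | None = None
    pairs_g = pairs_d = None
    med = np.inf
    converged = False
    tree_d = cKDTree(det)
    for _ in range(max_iter):
        mapped = t.apply(em)
        tree_g = cKDTree(mapped)
        d_g2d, nn_g2d = tree_d.query(mapped)      # each grid node's detection
        _, nn_d2g = tree_g.query(det)             # each detection's grid node
        g_idx = np.arange(len(em))
        mutual = nn_d2g[nn_g2d] == g_idx
        resid = d_g2d[mutual]
        if resid.size < 2:
            raise ValueError(
                "fewer than 2 pointer pairs survive; at least 2 pointer pairs "
                "are needed to fit the transform")
        med = float(np.median(resid))
        spacing_fm = t.scale * spacing_px
        thresh = min(max(discard_factor * med, floor_px), 0.5 * spacing_fm)
        keep = mutual & (d_g2d <= max(thresh, np.min(d_g2d[mutual])))
        pairs_g = g_idx[keep]
        pairs_d = nn_g2d[keep]
        if pairs_g.size < 2:
            raise ValueError(
                "fewer than 2 pointer pairs survive; at least 2 pointer pairs "
                "are needed to fit the transform")
        key = (tuple(pairs_g), tuple(pairs_d))
        t = fit_similarity((em[pairs_g], det[pairs_d]))
        if key == prev_key:
            converged = True
            break
        prev_key = key
    return pairs_g, pairs_d, med, converged


def pair_by_iterative_nn(detections: np.ndarray, grid: PointerGridSpec,
                         init: SimilarityTransform,
                         discard_factor: float = 3.0,
                         floor_px: float = 0.5,
                         max_iter: int = 20) -> PointPairSet:
    """Iterative mutual-nearest-neighbour pairing of detections with the grid.

    Loop: map the commanded grid through the current transform; form
    mutual-nearest-neighbour pairs (each grid node and each detection must
    choose each other, so two nodes can never claim one spot); discard
    pairs whose residual exceeds ``min(max(discard_factor * median residual,
    floor_px), 0.5 * mapped grid spacing)`` — the floor keeps ordinary
    sub-pixel localization scatter from being discarded when the median
    residual is tiny; refit the similarity on the survivors.
    Convergence: the same pair index set on two successive iterations.

    Nearest-neighbour iterations on a lattice have a finite rotation/scale
    basin; when the loop stalls or converges to a visibly poor matching
    (few pairs kept, median residual a large fraction of the spacing), a
    fresh initial guess is re-derived from the outer edges of the detected
    cloud and the loop rerun — making the result insensitive to the
    translation, rotation and scale errors of the supplied ``init``.

    Raises
    ------
    ValueError
        When fewer than 2 pairs survive (at least 2 pointer pairs are
        needed to fit the transform).
    RuntimeError
        When the pair set has not stabilized even after re-initialization.
    """
    det = np.atleast_2d(np.asarray(detections, dtype=float))
    em = grid.em_coords()
    pairs_g, pairs_d, med, converged = _nn_loop(
        det, em, init, grid.spacing_px, discard_factor, floor_px, max_iter)
    spacing_fm = fit_similarity((em[pairs_g], det[pairs_d])).scale * grid.spacing_px
    n_expect = min(len(det), len(em))
    poor = (pairs_g.size < 0.8 * n_expect and med > 0.15 * spacing_fm)
    if (not converged or poor) and len(det) >= 4:
        init2 = initial_guess_from_edges(det, grid)
        pairs_g, pairs_d, med, converged = _nn_loop(
            det, em, init2, grid.spacing_px, discard_factor, floor_px, max_iter)
    if not converged:
        raise RuntimeError(
            f"pairing did not converge in {max_iter} iterations "
            f"({pairs_g.size} pairs at last iteration)")

    matched_d = np.zeros(len(det), dtype=bool)
    matched_d[pairs_d] = True
    matched_g = np.zeros(len(em), dtype=bool)
    matched_g[pairs_g] = True
    return PointPairSet(
        em=em[pairs_g], fm=det[pairs_d], pointer_index=pairs_g,
        unmatched_fm=det[~matched_d],
        unmatched_em_index=np.flatnonzero(~matched_g),
    )


def match_grid(detections: np.ndarray, grid: PointerGridSpec,
               **kwargs) -> PointPairSet:
    """Convenience: corner-based initial guess followed by iterative pairing."""
    init = initial_guess_from_edges(detections, grid)
    return pair_by_iterative_nn(detections, grid, init, **kwargs)
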