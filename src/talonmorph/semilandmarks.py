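"""Template-to-target semilandmark transfer.

A thin-plate-spline warp of 3D space is anchored on the correspondence of
the 8 fixed anatomical landmarks; the template's curve semilandmarks are
carried through the warp and projected to the nearest point of the target
surface. Optionally the curve points then slide along their local curve
tangents to minimize thin-plate bending energy relative to the template
configuration (and are re-projected), for up to a few slide/project cycles.
Sliding is off by default: the transfer protocol alone defines the
correspondence.
"""

from __future__ import annotations

import logging

import numpy as np

from .geometry import TriMesh, closest_point_on_mesh
from .landmarks import LandmarkSet

log = logging.getLogger(__name__)


class TPSWarp:
    """3D thin-plate (polyharmonic, U(r) = r) spline interpolating
    ``source`` control points onto ``targets``."""

    def __init__(self, source: np.ndarray, targets: np.ndarray):
        source = np.asarray(source, float)
        targets = np.asarray(targets, float)
        n = len(source)
        if n < 4:
            raise ValueError("need at least 4 control points")
        K = np.linalg.norm(source[:, None] - source[None], axis=2)
        P = np.hstack([np.ones((n, 1)), source])
        L = np.zeros((n + 4, n + 4))
        L[:n, :n] = K
        L[:n, n:] = P
        L[n:, :n] = P.T
        rhs = np.zeros((n + 4, 3))
        rhs[:n] = targets
        try:
            sol = np.linalg.solve(L, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "degenerate fixed-landmark configuration (coplanar or "
                "coincident control points): TPS system is singular") from exc
        cond = np.linalg.cond(L)
        if cond > 1e12:
            raise ValueError(
                f"near-degenerate fixed-landmark configuration (cond={cond:.2g})")
        self.source = source
        self.w = sol[:n]
        self.affine = sol[n:]

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        U = np.linalg.norm(pts[:, None] - self.source[None], axis=2)
        poly = np.hstack([np.ones((len(pts), 1)), pts])
        return U @ self.w + poly @ self.affine


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Thin-plate bending-energy matrix of a reference configuration
    (p x p); the bending energy of displacements d is sum_dims d^T E d."""
    ref = np.asarray(reference, float)
    n = len(ref)
    K = np.linalg.norm(ref[:, None] - ref[None], axis=2)
    P = np.hstack([np.ones((n, 1)), ref])
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    Linv = np.linalg.pinv(L)
    return Linv[:n, :n]


def _curve_tangents(points: np.ndarray, curve_id: list[str | None]) -> np.ndarray:
    """Unit tangent along each point's curve (zero for fixed landmarks)."""
    tang = np.zeros_like(points)
    curves: dict[str, list[int]] = {}
    for i, c in enumerate(curve_id):
        if c is not None:
            curves.setdefault(c, []).append(i)
    for idx in curves.values():
        p = points[idx]
        d = np.gradient(p, axis=0) if len(p) > 1 else np.zeros_like(p)
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        tang[idx] = np.where(norm > 0, d / np.maximum(norm, 1e-300), 0.0)
    return tang


def project_semilandmarks(template: LandmarkSet, template_mesh: TriMesh,
                          target_fixed: LandmarkSet, target_mesh: TriMesh,
                          slide: bool = False, n_cycles: int = 5) -> LandmarkSet:
    """Transfer the template's semilandmarks onto a target specimen.

    ``target_fixed`` supplies the target's 8 fixed landmarks (labels must
    match the template's fixed landmarks); the returned LandmarkSet has the
    template's full labeling with the target's own fixed landmarks and the
    projected (optionally slid) semilandmarks.
    """
    fixed_mask = template.fixed_mask()
    fixed_labels = [lb for lb, m in zip(template.labels, fixed_mask) if m]
    src = template.points[fixed_mask]
    dst = target_fixed.subset(fixed_labels).points

    warp = TPSWarp(src, dst)
    mapped = warp(template.points)
    length_scale = float(np.linalg.norm(np.ptp(target_mesh.vertices, axis=0)))

    semi = ~fixed_mask
    proj, dist = closest_point_on_mesh(target_mesh, mapped[semi])
    if (dist > 0.1 * length_scale).any():
        log.warning("projection moved %d semilandmarks more than 10%% of the "
                    "talon length scale", int((dist > 0.1 * length_scale).sum()))
    out = mapped.copy()
    out[fixed_mask] = dst
    out[semi] = proj

    if slide:
        E = bending_energy_matrix(template.points)
        for _ in range(n_cycles):
            tang = _curve_tangents(out, template.curve_id)
            # minimize (d + T t)^T E (d + T t) over per-point slips t,
            # where d is the deviation from the (warped) template
            d = out - warp(template.points)
            a = np.einsum("ij,id,jd->ij", E, tang, tang)   # T^T E T
            b = np.einsum("ij,id,jd->i", E, tang, d)
            free = np.linalg.norm(tang, axis=1) > 0
            t = np.zeros(len(out))
            if free.any():
                t[free] = np.linalg.solve(
                    a[np.ix_(free, free)] + 1e-12 * np.eye(free.sum()),
                    -b[free])
            out = out + t[:, None] * tang
            proj, _ = closest_point_on_mesh(target_mesh, out[semi])
            out[semi] = proj
            out[fixed_mask] = dst

    return LandmarkSet(target_fixed.specimen_id, out, list(template.labels),
                       list(template.kind), list(template.curve_id))
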