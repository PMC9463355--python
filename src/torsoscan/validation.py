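"""Validation of reconstructions: metric scaling, registration, distances.

Mirrors the manual validation workflow of the target protocol, but
programmatically: (1) recover metric scale from measured inter-electrode
distances; (2) coarse alignment from point pairs (closed-form similarity);
(3) fine registration by iterative closest point against the reference
mesh, with the scale frozen after the coarse stage; (4) distance statistics
(mean / standard deviation of signed distances, maximum absolute distance,
all in millimeters) for the surface and for the electrode centers.

Sign convention: a point on the side the surface normal points to (outside
an outward-oriented torso mesh) gets a positive distance.  The statistics
of negative means reported for some reconstructions are only explicable
with such a signed convention, which is why it is the default here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .electrodes import ElectrodeSet
from .errors import DegenerateGeometryError, EmptyResultError, InvalidParameterError
from .geometry import SimilarityTransform
from .scene import BeltSpec
from .surface import SurfaceMesh
from .triangles import mesh_closest_points

log = logging.getLogger(__name__)

__all__ = [
    "DistanceReport",
    "estimate_scale",
    "align_point_pairs",
    "icp_refine",
    "cloud_to_mesh_distance",
    "electrode_error",
    "clinical_threshold_check",
    "ClinicalCheck",
]


@dataclass
class DistanceReport:
    """Mean/std of signed distances and max |distance|, millimeters."""

    mean_signed: float
    std_signed: float
    max_abs: float
    n: int
    distances: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @classmethod
    def from_distances_mm(cls, d_mm: np.ndarray) -> "DistanceReport":
        d_mm = np.asarray(d_mm, dtype=float)
        if d_mm.size == 0:
            raise EmptyResultError("no distances to report")
        return cls(float(d_mm.mean()), float(d_mm.std()),
                   float(np.abs(d_mm).max()), int(d_mm.size), d_mm)

    def summary_dict(self) -> dict:
        return {"mean_mm": self.mean_signed, "std_mm": self.std_signed,
                "max_mm": self.max_abs, "n": self.n}


def estimate_scale(electrodes: ElectrodeSet,
                   reference_distances: list[tuple[int, int, float]]) -> float:
    """Least-squares metric scale from measured electrode-pair distances.

    ``reference_distances``: (index_i, index_j, measured distance in m)
    from tape measurements along the worn belt.  The scale minimizing
    sum (d_ref - s * d_rec)^2 is s = sum(d_ref*d_rec) / sum(d_rec^2),
    over the pairs whose two electrodes were both reconstructed.
    """
    centers = electrodes.centers()
    d_rec, d_ref = [], []
    for i, j, dm in reference_distances:
        if i in centers and j in centers:
            d_rec.append(np.linalg.norm(centers[i] - centers[j]))
            d_ref.append(dm)
    if not d_rec:
        raise InvalidParameterError("no usable reference distance pairs")
    d_rec = np.asarray(d_rec)
    d_ref = np.asarray(d_ref)
    denom = float(np.sum(d_rec ** 2))
    if denom < 1e-300:
        raise DegenerateGeometryError("reconstructed distances are all zero")
    return float(np.sum(d_ref * d_rec) / denom)


def align_point_pairs(source: np.ndarray, target: np.ndarray,
                      with_scale: bool = True) -> SimilarityTransform:
    """Closed-form least-squares similarity (Umeyama) mapping source onto
    target: centroid demeaning, cross-covariance SVD with reflection guard,
    scale from the variance ratio.  Requires >= 3 non-collinear pairs."""
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    dst = np.asarray(target, dtype=float).reshape(-1, 3)
    if len(src) < 3 or len(src) != len(dst):
        raise InvalidParameterError("need >= 3 matched point pairs")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    ss = src - mu_s
    dd = dst - mu_d
    sing = np.linalg.svd(ss, compute_uv=False)
    if sing[1] < 1e-12 * max(sing[0], 1e-300):
        raise DegenerateGeometryError("source points (nearly) collinear")
    cov = dd.T @ ss / len(src)
    U, S, Vt = np.linalg.svd(cov)
    D = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        D[2, 2] = -1.0
    R = U @ D @ Vt
    if with_scale:
        var_s = (ss ** 2).sum() / len(src)
        scale = float(np.trace(np.diag(S) @ D) / var_s)
    else:
        scale = 1.0
    t = mu_d - scale * R @ mu_s
    return SimilarityTransform(scale, R, t)


def icp_refine(source_points: np.ndarray, target_mesh: SurfaceMesh,
               init: SimilarityTransform | None = None,
               max_iter: int = 50, tol: float = 1e-10
               ) -> tuple[SimilarityTransform, list[float]]:
    """Iterative closest point against the mesh surface (rigid updates,
    scale frozen at the coarse-stage value).

    Correspondences are exact nearest points on the triangles.  RMS is
    non-increasing by construction: a step that would increase it is
    reverted and iteration stops with a warning.  Returns the refined
    transform and the RMS history (m).
    """
    if len(target_mesh.faces) == 0:
        raise InvalidParameterError("target mesh is empty")
    src = np.asarray(source_points, dtype=float).reshape(-1, 3)
    transform = init or SimilarityTransform()
    tri = target_mesh.triangles
    cur = transform.apply(src)
    d, closest, _ = mesh_closest_points(cur, tri)
    rms_hist = [float(np.sqrt(np.mean(d ** 2)))]
    for _ in range(max_iter):
        rigid = align_point_pairs(cur, closest, with_scale=False)
        cand = rigid.compose(transform)
        cand_pts = cand.apply(src)
        d, cl, _ = mesh_closest_points(cand_pts, tri)
        rms = float(np.sqrt(np.mean(d ** 2)))
        if rms > rms_hist[-1] + 1e-15:
            log.warning("ICP step increased RMS (%.3e -> %.3e); reverting",
                        rms_hist[-1], rms)
            break
        transform, cur, closest = cand, cand_pts, cl
        converged = abs(rms_hist[-1] - rms) <= tol * max(rms_hist[-1], 1e-300)
        rms_hist.append(rms)
        if converged:
            break
    return transform, rms_hist


def cloud_to_mesh_distance(points: np.ndarray, mesh: SurfaceMesh
                           ) -> DistanceReport:
    """Signed distance of each point to the nearest mesh triangle (mm).

    Sign: positive on the side of the nearest triangle's oriented normal.
    """
    if len(mesh.faces) == 0:
        raise InvalidParameterError("mesh has no faces")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    d, closest, tri_idx = mesh_closest_points(pts, mesh.triangles)
    normals = mesh.face_normals()[tri_idx]
    side = np.einsum("ni,ni->n", pts - closest, normals)
    signed = d * np.where(side >= 0, 1.0, -1.0)
    return DistanceReport.from_distances_mm(signed * 1e3)


def electrode_error(recon: ElectrodeSet | dict[int, np.ndarray],
                    truth_centers: dict[int, np.ndarray]) -> DistanceReport:
    """Euclidean center error per electrode present in both sets (mm)."""
    centers = recon.centers() if isinstance(recon, ElectrodeSet) else recon
    common = sorted(set(centers) & set(truth_centers))
    if not common:
        raise EmptyResultError("no common electrode indices")
    missing = sorted(set(truth_centers) - set(centers))
    if missing:
        log.info("electrode_error: indices missing from reconstruction: %s",
                 missing)
    d = np.array([np.linalg.norm(np.asarray(centers[i])
                                 - np.asarray(truth_centers[i]))
                  for i in common])
    return DistanceReport.from_distances_mm(d * 1e3)


@dataclass
class ClinicalCheck:
    """Outcome of the one-electrode-shift criterion."""

    passed: bool
    spacing_mm: float
    max_error_mm: float
    margin_mm: float
    mean_warning: bool


def clinical_threshold_check(report: DistanceReport, belt: BeltSpec,
                             circumference_m: float | None = None
                             ) -> ClinicalCheck:
    """Fail when the max electrode error reaches one inter-electrode
    spacing (a one-place shift corrupts EIT side information); warn when
    the mean reaches half a spacing.

    ``circumference_m`` is the worn belt circumference; defaults to the
    unstretched belt length.
    """
    circ = circumference_m if circumference_m is not None else belt.rest_length
    spacing_mm = circ * 1e3 / belt.n_electrodes
    max_err = report.max_abs
    passed = max_err < spacing_mm
    return ClinicalCheck(
        passed=passed,
        spacing_mm=spacing_mm,
        max_error_mm=max_err,
        margin_mm=spacing_mm - max_err,
        mean_warning=abs(report.mean_signed) >= spacing_mm / 2,
    )
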