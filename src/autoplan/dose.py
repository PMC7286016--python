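"""Beamlet dose-deposition matrix.

Dose is a linear map of nonnegative per-beamlet fluence weights,
``D(phi) = A @ phi``.  Each beamlet is a simple exponential-attenuation
pencil beam: along its ray the dose per unit weight decays as
``exp(-mu * depth)`` with depth measured geometrically inside the body mask
(water-equivalent), and laterally the beamlet's top-hat profile of width
``beamlet_width_mm`` is blurred by a Gaussian penumbra of width ``sigma_mm``.
Dose outside the body is zero.  The defaults (mu = 0.05 / cm, sigma = 3 mm)
give a qualitatively 6-MV-like depth curve; the outer planning loop is
agnostic to the dose model's realism.

Beamlet lateral offsets span the union-of-targets projection plus a margin,
mimicking fields conformed to the target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.special import erf

from .cases import Case
from .config import DEFAULT_CONFIG, AutoplanConfig

log = logging.getLogger("autoplan")


@dataclass(frozen=True)
class BeamletIndex:
    """Identity of one beamlet: its beam angle and lateral offset (mm,
    measured from the grid center along the beam's lateral axis)."""

    beam: int
    angle_deg: float
    offset_mm: float


@dataclass
class BeamletMatrix:
    """Sparse dose-deposition matrix for one case.

    ``matrix`` has shape (n_voxels, n_beamlets) over the C-order flattened
    grid; column j is the dose per unit weight of beamlet ``index[j]``.
    """

    matrix: sparse.csr_matrix
    index: list[BeamletIndex]
    grid_shape: tuple[int, int]
    case_hash: str
    mu_per_cm: float
    sigma_mm: float

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]


def build_beamlet_matrix(
    case: Case,
    mu_per_cm: float | None = None,
    sigma_mm: float | None = None,
    config: AutoplanConfig = DEFAULT_CONFIG,
) -> BeamletMatrix:
    """Ray-march every beam through the body mask and assemble A."""
    mu = config.mu_per_cm if mu_per_cm is None else mu_per_cm
    sigma = config.sigma_mm if sigma_mm is None else sigma_mm
    if mu <= 0:
        raise ValueError("mu must be positive")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")

    body = case.body.mask
    yy, xx = case.voxel_centers_mm()
    ny, nx = case.grid_shape
    vy, vx = case.voxel_size_mm
    cy, cx = ny * vy / 2.0, nx * vx / 2.0
    n_vox = ny * nx
    inside = body.ravel()

    tgt = case.target_union()
    columns: list[np.ndarray] = []
    rows: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    index: list[BeamletIndex] = []

    for b, beam in enumerate(case.beams):
        theta = math.radians(beam.angle_deg)
        # propagation direction and lateral axis (y, x components)
        u = np.array([math.cos(theta), math.sin(theta)])
        v = np.array([-math.sin(theta), math.cos(theta)])

        # depth inside the body along -u from each voxel
        depth_cm = _depth_map_cm(body, yy - cy, xx - cx, u, (vy, vx))

        # lateral coordinate of every voxel and of the target projection
        lat = (yy - cy) * v[0] + (xx - cx) * v[1]
        t_lat = lat[tgt]
        lo = t_lat.min() - config.beamlet_margin_mm
        hi = t_lat.max() + config.beamlet_margin_mm
        w = beam.beamlet_width_mm
        n_bl = max(1, int(math.ceil((hi - lo) / w)))
        offsets = lo + (np.arange(n_bl) + 0.5) * w

        atten = np.exp(-mu * depth_cm)
        atten[~body] = 0.0
        atten_flat = atten.ravel()
        lat_flat = lat.ravel()

        for off in offsets:
            profile = _lateral_profile(lat_flat - off, w, sigma)
            col = atten_flat * profile
            col[~inside] = 0.0
            nz = np.flatnonzero(col > 1e-8 * col.max()) if col.max() > 0 else np.array([], int)
            if nz.size == 0:
                log.warning(
                    "dropping beamlet (beam %d, offset %.1f mm): ray misses the body", b, off
                )
                continue
            rows.append(nz)
            vals.append(col[nz])
            columns.append(np.full(nz.size, len(index)))
            index.append(BeamletIndex(beam=b, angle_deg=beam.angle_deg, offset_mm=float(off)))

    if not index:
        raise ValueError("no beamlet deposits dose inside the body")
    mat = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(columns))),
        shape=(n_vox, len(index)),
    )
    return BeamletMatrix(
        matrix=mat,
        index=index,
        grid_shape=case.grid_shape,
        case_hash=case.case_hash(),
        mu_per_cm=mu,
        sigma_mm=sigma,
    )


def _depth_map_cm(
    body: np.ndarray,
    y_rel: np.ndarray,
    x_rel: np.ndarray,
    u: np.ndarray,
    voxel_size_mm: tuple[float, float],
) -> np.ndarray:
    """Geometric path length (cm) inside the body from the beam entry point to
    each voxel, marching backwards along -u with 1 mm steps."""
    vy, vx = voxel_size_mm
    ny, nx = body.shape
    diag_mm = math.hypot(ny * vy, nx * vx)
    ds = 1.0  # mm
    n_steps = int(diag_mm / ds) + 2
    s = (np.arange(n_steps) + 0.5) * ds
    # sample points: voxel position minus s * u
    py = y_rel[None, :, :] - s[:, None, None] * u[0]
    px = x_rel[None, :, :] - s[:, None, None] * u[1]
    fy = np.round(py / vy + ny / 2.0 - 0.5)
    fx = np.round(px / vx + nx / 2.0 - 0.5)
    valid = (fy >= 0) & (fy < ny) & (fx >= 0) & (fx < nx)
    iy = np.clip(fy.astype(np.int32), 0, ny - 1)
    ix = np.clip(fx.astype(np.int32), 0, nx - 1)
    hits = body[iy, ix] & valid
    depth_mm = hits.sum(axis=0) * ds + 0.5 * ds * body  # half-voxel self term
    return depth_mm / 10.0


def _lateral_profile(dist_mm: np.ndarray, width_mm: float, sigma_mm: float) -> np.ndarray:
    """Top-hat of width ``width_mm`` convolved with a Gaussian of ``sigma_mm``."""
    half = width_mm / 2.0
    if sigma_mm == 0.0:
        return (np.abs(dist_mm) <= half).astype(float)
    a = (dist_mm + half) / (sigma_mm * math.sqrt(2.0))
    b = (dist_mm - half) / (sigma_mm * math.sqrt(2.0))
    return 0.5 * (erf(a) - erf(b))


def compute_dose(matrix: BeamletMatrix, weights: np.ndarray) -> np.ndarray:
    """Dose grid (Gy) for a nonnegative fluence-weight vector."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (matrix.n_beamlets,):
        raise ValueError(
            f"expected {matrix.n_beamlets} weights, got shape {w.shape}"
        )
    if np.any(w < 0):
        raise ValueError("fluence weights must be nonnegative")
    return np.asarray(matrix.matrix @ w).reshape(matrix.grid_shape)
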