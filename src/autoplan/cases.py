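"""Synthetic voxel phantoms and beam geometries.

Two desk-scale test sites are emulated on a 2-D axial slice: a prostate-like
case (one PTV with two nearby organs at risk, one of which may overlap the
PTV by a controlled fraction) and a head-and-neck-like case planned with a
simultaneous-integrated boost (nested targets at strictly decreasing dose
levels, a small serial-OAR analogue posterior to the targets and two lateral
parallel-OAR analogues).  All shapes are analytic ellipses rasterized on the
voxel grid, so identical seeds reproduce identical cases bit for bit.

Case files are versioned JSON with run-length-encoded masks; DICOM-RT is
deliberately not supported.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CASE_SCHEMA_VERSION = "1"

TARGET = "target"
OAR = "oar"
BODY = "body"

_KINDS = {TARGET, OAR, BODY}


@dataclass
class Beam:
    """A static coplanar field: gantry-like angle and beamlet width."""

    angle_deg: float
    beamlet_width_mm: float = 4.0


@dataclass
class Structure:
    """A named contoured region on the case grid.

    Targets carry a strictly positive ``prescribed_dose`` in Gy; OARs and the
    body do not.
    """

    name: str
    mask: np.ndarray  # bool array, case grid shape
    kind: str
    prescribed_dose: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown structure kind {self.kind!r}")
        if self.kind == TARGET:
            if self.prescribed_dose is None or self.prescribed_dose <= 0:
                raise ValueError(f"target {self.name!r} needs a positive prescribed_dose")
        elif self.prescribed_dose is not None:
            raise ValueError(f"non-target {self.name!r} must not carry a prescribed_dose")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def volume_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Case:
    """A voxel phantom: grid, structures, and beam geometry."""

    grid_shape: tuple[int, int]
    voxel_size_mm: tuple[float, float]
    structures: list[Structure]
    beams: list[Beam]
    seed: int
    site: str = "custom"

    def __post_init__(self) -> None:
        names = [s.name for s in self.structures]
        if len(names) != len(set(names)):
            raise ValueError("structure names must be unique within a case")
        bodies = [s for s in self.structures if s.kind == BODY]
        if len(bodies) != 1:
            raise ValueError("a case needs exactly one body structure")
        if not any(s.kind == TARGET for s in self.structures):
            raise ValueError("a case needs at least one target")
        body = bodies[0].mask
        for s in self.structures:
            if s.mask.shape != tuple(self.grid_shape):
                raise ValueError(f"mask shape mismatch for {s.name!r}")
            if np.any(s.mask & ~body):
                raise ValueError(f"structure {s.name!r} leaves the body mask")

    # -- lookup helpers -------------------------------------------------

    def structure(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(f"no structure named {name!r} in case")

    def has_structure(self, name: str) -> bool:
        return any(s.name == name for s in self.structures)

    @property
    def body(self) -> Structure:
        return next(s for s in self.structures if s.kind == BODY)

    @property
    def targets(self) -> list[Structure]:
        """Targets sorted by prescribed dose, highest (primary) first."""
        ts = [s for s in self.structures if s.kind == TARGET]
        return sorted(ts, key=lambda s: (-s.prescribed_dose, s.name))

    @property
    def primary_target(self) -> Structure:
        return self.targets[0]

    @property
    def oars(self) -> list[Structure]:
        return [s for s in self.structures if s.kind == OAR]

    def target_union(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        for t in self.targets:
            m |= t.mask
        return m

    def unspecified_tissue(self) -> np.ndarray:
        """Body minus the union of all targets."""
        return self.body.mask & ~self.target_union()

    def voxel_volume_fraction(self) -> float:
        return 1.0 / max(int(self.body.mask.sum()), 1)

    # -- physical coordinates -------------------------------------------

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) physical coordinates of voxel centers, mm."""
        ny, nx = self.grid_shape
        vy, vx = self.voxel_size_mm
        y = (np.arange(ny) + 0.5) * vy
        x = (np.arange(nx) + 0.5) * vx
        yy, xx = np.meshgrid(y, x, indexing="ij")
        return yy, xx

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": CASE_SCHEMA_VERSION,
            "site": self.site,
            "seed": self.seed,
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": list(self.voxel_size_mm),
            "beams": [
                {"angle_deg": b.angle_deg, "beamlet_width_mm": b.beamlet_width_mm}
                for b in self.beams
            ],
            "structures": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "prescribed_dose_gy": s.prescribed_dose,
                    "mask_rle": _rle_encode(s.mask),
                }
                for s in self.structures
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Case":
        if str(d.get("schema_version")) != CASE_SCHEMA_VERSION:
            raise ValueError(f"unsupported case schema version {d.get('schema_version')!r}")
        shape = tuple(int(v) for v in d["grid_shape"])
        structures = [
            Structure(
                name=s["name"],
                mask=_rle_decode(s["mask_rle"], shape),
                kind=s["kind"],
                prescribed_dose=s["prescribed_dose_gy"],
            )
            for s in d["structures"]
        ]
        beams = [Beam(b["angle_deg"], b["beamlet_width_mm"]) for b in d["beams"]]
        return cls(
            grid_shape=shape,
            voxel_size_mm=tuple(float(v) for v in d["voxel_size_mm"]),
            structures=structures,
            beams=beams,
            seed=int(d["seed"]),
            site=d.get("site", "custom"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Case":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def case_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _rle_encode(mask: np.ndarray) -> list[int]:
    """Run lengths of the C-order flattened mask, starting with a run of False."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    bounds = np.concatenate(([0], changes, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: list[int], shape: tuple[int, ...]) -> np.ndarray:
    total = int(np.prod(shape))
    flat = np.zeros(total, dtype=bool)
    pos, value = 0, False
    for run in runs:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    if pos != total:
        raise ValueError("RLE length does not match grid size")
    return flat.reshape(shape)


# ---------------------------------------------------------------------------
# shape rasterization
# ---------------------------------------------------------------------------

def _ellipse_mask(
    grid_shape: tuple[int, int],
    voxel_size_mm: tuple[float, float],
    center_mm: tuple[float, float],
    semi_axes_mm: tuple[float, float],
) -> np.ndarray:
    ny, nx = grid_shape
    vy, vx = voxel_size_mm
    y = (np.arange(ny) + 0.5) * vy
    x = (np.arange(nx) + 0.5) * vx
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cy, cx = center_mm
    ay, ax = semi_axes_mm
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _check_grid(grid_shape: tuple[int, int]) -> None:
    if len(grid_shape) != 2 or any(n < 16 for n in grid_shape):
        raise ValueError(f"degenerate grid {grid_shape}: every axis must be >= 16")


def _default_beams(n: int = 7, beamlet_width_mm: float = 4.0) -> list[Beam]:
    return [Beam(angle_deg=k * 360.0 / n, beamlet_width_mm=beamlet_width_mm) for k in range(n)]


# ---------------------------------------------------------------------------
# prostate-like site
# ---------------------------------------------------------------------------

def make_prostate_case(
    seed: int,
    grid_shape: tuple[int, int] = (64, 64),
    overlap_fraction: float = 0.1,
    voxel_size_mm: float = 4.0,
) -> Case:
    """Prostate-like phantom: one PTV, a posterior OAR whose overlap with the
    PTV is controlled by ``overlap_fraction`` (fraction of the OAR volume), and
    a displaced anterior OAR.

    ``overlap_fraction`` is the knob for planning difficulty: the posterior
    OAR is slid along the posterior axis until the rasterized overlap fraction
    first reaches the requested value, so increasing the request never
    decreases the realized overlap.
    """
    _check_grid(grid_shape)
    if not 0.0 <= overlap_fraction < 0.5:
        raise ValueError("overlap_fraction must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    vs = (float(voxel_size_mm), float(voxel_size_mm))
    ny, nx = grid_shape
    cy, cx = ny * vs[0] / 2.0, nx * vs[1] / 2.0

    body_semi = (0.40 * ny * vs[0] + rng.uniform(-4, 4), 0.44 * nx * vs[1] + rng.uniform(-4, 4))
    body = _ellipse_mask(grid_shape, vs, (cy, cx), body_semi)

    ptv_r = 26.0 + rng.uniform(-2, 2)
    ptv_c = (cy - 8.0 + rng.uniform(-2, 2), cx + rng.uniform(-2, 2))
    ptv = _ellipse_mask(grid_shape, vs, ptv_c, (ptv_r, ptv_r)) & body

    oar_r = 22.0 + rng.uniform(-2, 2)
    # posterior OAR: slide along +y until the overlap fraction is reached
    d = _distance_for_overlap(
        grid_shape, vs, ptv, ptv_c, oar_r, overlap_fraction, direction=(1.0, 0.0)
    )
    rectum_c = (ptv_c[0] + d, ptv_c[1])
    rectum = _ellipse_mask(grid_shape, vs, rectum_c, (oar_r, oar_r)) & body

    bladder_r = 26.0 + rng.uniform(-2, 2)
    bladder_c = (ptv_c[0] - ptv_r - bladder_r - 10.0, ptv_c[1] + rng.uniform(-3, 3))
    bladder = _ellipse_mask(grid_shape, vs, bladder_c, (bladder_r, bladder_r)) & body

    return Case(
        grid_shape=tuple(grid_shape),
        voxel_size_mm=vs,
        structures=[
            Structure("body", body, BODY),
            Structure("ptv", ptv, TARGET, prescribed_dose=67.5),
            Structure("rectum", rectum, OAR),
            Structure("bladder", bladder, OAR),
        ],
        beams=_default_beams(7, vs[0]),
        seed=int(seed),
        site="prostate",
    )


def _distance_for_overlap(
    grid_shape: tuple[int, int],
    voxel_size_mm: tuple[float, float],
    ptv_mask: np.ndarray,
    ptv_center_mm: tuple[float, float],
    oar_radius_mm: float,
    fraction: float,
    direction: tuple[float, float],
) -> float:
    """Center distance at which the rasterized OAR∩PTV / OAR fraction first
    reaches ``fraction``, scanning from far (no overlap) to near."""
    d_far = 3.0 * (oar_radius_mm + 30.0)
    if fraction <= 0.0:
        # guaranteed-zero overlap: keep a one-voxel air gap
        step = 0.25
        d = d_far
        best = d_far
        while d > oar_radius_mm:
            c = (ptv_center_mm[0] + direction[0] * d, ptv_center_mm[1] + direction[1] * d)
            oar = _ellipse_mask(grid_shape, voxel_size_mm, c, (oar_radius_mm, oar_radius_mm))
            if (oar & ptv_mask).any():
                return best
            best = d
            d -= step
        return best
    step = 0.25
    for d in np.arange(d_far, 0.0, -step):
        c = (ptv_center_mm[0] + direction[0] * d, ptv_center_mm[1] + direction[1] * d)
        oar = _ellipse_mask(grid_shape, voxel_size_mm, c, (oar_radius_mm, oar_radius_mm))
        n_oar = int(oar.sum())
        if n_oar == 0:
            continue
        if (oar & ptv_mask).sum() / n_oar >= fraction:
            return float(d)
    raise RuntimeError("could not realize the requested overlap fraction")


# ---------------------------------------------------------------------------
# head-and-neck-like SIB site
# ---------------------------------------------------------------------------

_SIB_DOSES = {2: (66.0, 54.0), 3: (70.0, 60.0, 54.0)}


def make_hn_case(
    seed: int,
    n_dose_levels: int = 2,
    grid_shape: tuple[int, int] = (64, 64),
    voxel_size_mm: float = 4.0,
) -> Case:
    """Head-and-neck-like SIB phantom: nested targets at strictly decreasing
    prescribed doses, a small serial-OAR analogue (cord stand-in) posterior to
    the targets and two lateral parallel-OAR analogues (parotid stand-ins)."""
    _check_grid(grid_shape)
    if n_dose_levels not in _SIB_DOSES:
        raise ValueError("n_dose_levels must be 2 or 3")
    rng = np.random.default_rng(seed)
    vs = (float(voxel_size_mm), float(voxel_size_mm))
    ny, nx = grid_shape
    cy, cx = ny * vs[0] / 2.0, nx * vs[1] / 2.0

    body_semi = (0.40 * ny * vs[0] + rng.uniform(-4, 4), 0.42 * nx * vs[1] + rng.uniform(-4, 4))
    body = _ellipse_mask(grid_shape, vs, (cy, cx), body_semi)

    doses = _SIB_DOSES[n_dose_levels]
    elective_c = (cy - 12.0 + rng.uniform(-2, 2), cx + rng.uniform(-2, 2))
    elective_semi = (30.0 + rng.uniform(-2, 2), 38.0 + rng.uniform(-2, 2))
    elective = _ellipse_mask(grid_shape, vs, elective_c, elective_semi) & body

    boost_r = 16.0 + rng.uniform(-1.5, 1.5)
    boost_c = (elective_c[0] + rng.uniform(-2, 2), elective_c[1] + rng.uniform(-2, 2))
    boost = _ellipse_mask(grid_shape, vs, boost_c, (boost_r, boost_r)) & elective

    structures = [Structure("body", body, BODY)]
    if n_dose_levels == 2:
        structures += [
            Structure("ptv_boost", boost, TARGET, prescribed_dose=doses[0]),
            Structure("ptv_elective", elective, TARGET, prescribed_dose=doses[1]),
        ]
    else:
        mid_semi = (
            boost_r + 0.5 * (elective_semi[0] - boost_r),
            boost_r + 0.5 * (elective_semi[1] - boost_r),
        )
        mid = _ellipse_mask(grid_shape, vs, boost_c, mid_semi) & elective
        mid |= boost  # keep strict nesting even under jitter
        structures += [
            Structure("ptv_boost", boost, TARGET, prescribed_dose=doses[0]),
            Structure("ptv_mid", mid, TARGET, prescribed_dose=doses[1]),
            Structure("ptv_elective", elective, TARGET, prescribed_dose=doses[2]),
        ]

    # serial-OAR analogue, posterior, never touching the targets
    elective_ymax = elective_c[0] + elective_semi[0]
    cord_r = 7.0 + rng.uniform(-1, 1)
    cord_c = (elective_ymax + cord_r + 12.0, cx + rng.uniform(-2, 2))
    cord = _ellipse_mask(grid_shape, vs, cord_c, (cord_r, cord_r)) & body
    cord &= ~elective  # construction guarantee, belt and braces
    structures.append(Structure("cord", cord, OAR))

    # parallel-OAR analogues, lateral
    par_r = 12.0 + rng.uniform(-1, 1)
    for name, side in (("parotid_l", -1.0), ("parotid_r", 1.0)):
        pc = (elective_c[0] + rng.uniform(-3, 3), cx + side * (elective_semi[1] + par_r + 6.0))
        pm = _ellipse_mask(grid_shape, vs, pc, (par_r, par_r)) & body
        pm &= ~boost
        structures.append(Structure(name, pm, OAR))

    return Case(
        grid_shape=tuple(grid_shape),
        voxel_size_mm=vs,
        structures=structures,
        beams=_default_beams(7, vs[0]),
        seed=int(seed),
        site="hn_sib",
    )
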