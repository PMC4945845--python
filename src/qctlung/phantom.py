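"""Digital thorax phantom: ground-truthed synthetic CT volumes and cohorts.

The phantom emulates the measurement substrate of a quantitative chest-CT
study of pulmonary congestion in heart failure (HF): a soft-tissue body
ellipsoid containing two lung fields and a dichotomous airway tree rendered
as nested cylinders (dark lumen inside a soft-tissue wall).  Lung
parenchyma is a per-voxel air/tissue attenuation mixture with Gaussian
noise; extravascular lung water (EVLW) is a two-component mixture — each
parenchymal voxel is, with probability ``evlw_weight``, drawn from a
brighter "edema" component instead.  Raising ``evlw_weight`` shifts the
attenuation histogram rightward, raises the congestion index, widens the
FWHM and lowers skewness/kurtosis — the HF-versus-control pattern.

Default EVLW component: Normal(-700, 150) HU with parenchymal noise of
40 HU.  This calibration places the congestion index, skewness, kurtosis
and FWHM of a 5%-weight (control-like) and 25%-weight (HF-like) phantom in
the range reported for real cohorts; it also makes the EVLW tail overlap
the parenchymal peak, which is what lets fluid clearance visibly narrow
the histogram (a far-off narrow component would leave the FWHM unchanged).

A simulated bronchodilator resamples a fraction of EVLW voxels from the
clean parenchymal model and thins the airway walls without touching the
lumen.  Cohort sampling draws per-subject parameters from group
distributions and couples generation-level airway areas to spirometry
through a Gaussian copula with configurable target correlations.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .airways import AirwaySegment, AirwayTree
from .cohort import SPIRO_VARS, SubjectRecord
from .core import CTVolume, RegionMask
from .density import (
    DensityMetrics,
    build_histogram,
    congestion_index,
    distribution_moments,
    fwhm,
    voxel_air_fraction,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "GroupParams",
    "CohortSpec",
    "CohortSubject",
    "build_phantom",
    "apply_bronchodilator",
    "sample_parenchyma_hu",
    "sample_cohort",
    "simulate_cohort_records",
]

HU_AIR = -1000.0


# ---------------------------------------------------------------------------
# specs


@dataclass
class PhantomSpec:
    """Parameters of one synthetic thorax volume.

    Lengths in mm, attenuations in HU.  ``radius_ratio`` and ``wall_ratio``
    are the per-generation geometric decay factors of airway lumen radius
    and wall thickness (0.71 halves the luminal area per generation;
    0.9 thins the wall by ~10% per generation).
    """

    grid_shape: tuple[int, int, int] = (128, 120, 120)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body_hu: float = 30.0
    lung_air_fraction: float = 0.9
    noise_sd: float = 40.0
    evlw_weight: float = 0.05
    evlw_mean: float = -700.0
    evlw_sd: float = 150.0
    #: weight of an additional right-tail component (small vessels and
    #: interstitium) drawn from the same distribution as the EVLW component
    #: but NOT cleared by the bronchodilator; 0 gives the pure two-component
    #: air/tissue + EVLW mixture
    vascular_weight: float = 0.0
    airway_generations: int = 6
    root_radius: float = 8.0
    root_wall: float = 2.5
    radius_ratio: float = 0.71
    wall_ratio: float = 0.9
    branch_angle: float = 32.0  # degrees
    root_length: float = 28.0
    length_ratio: float = 0.78
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lung_air_fraction <= 1.0:
            raise ValueError("lung_air_fraction must lie in [0, 1]")
        if not 0.0 <= self.evlw_weight <= 1.0:
            raise ValueError("evlw_weight must lie in [0, 1]")
        if not 0.0 <= self.vascular_weight <= 1.0 - self.evlw_weight:
            raise ValueError("vascular_weight must lie in [0, 1 - evlw_weight]")
        for name in ("radius_ratio", "wall_ratio", "length_ratio"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("root_radius", "root_wall", "root_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.airway_generations < 1:
            raise ValueError("airway_generations must be >= 1")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if max(self.voxel_spacing) > self.root_radius:
            raise ValueError(
                f"voxel spacing {max(self.voxel_spacing)} mm exceeds root "
                f"radius {self.root_radius} mm: airway unresolvable"
            )

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_spacing)


@dataclass
class PhantomTruth:
    """Exact ground truth of a phantom volume.

    ``lung_mask`` is parenchyma only (airway lumen and wall excluded);
    ``lung_territory`` is the full lung-ellipsoid region including voxels
    later claimed by the rendered airway tree.
    """

    lung_mask: RegionMask
    airway_lumen_mask: RegionMask
    airway_wall_mask: RegionMask
    tree: AirwayTree
    true_air_fraction_map: np.ndarray
    evlw_voxel_mask: RegionMask
    body_mask: RegionMask
    lung_territory: RegionMask
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# tree geometry


def _rotate(d: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of unit vector d about unit axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return d * c + np.cross(axis, d) * s + axis * np.dot(axis, d) * (1 - c)


def _tree_geometry(spec: PhantomSpec, start_mm: np.ndarray) -> list[dict]:
    """Dichotomous tree of line segments: in-plane trachea along the slice
    axis, planar branching with the branching plane alternating per
    generation."""
    theta = np.deg2rad(spec.branch_angle)
    segs: list[dict] = []
    # axis order (z, y, x); trachea runs in +z
    d0 = np.array([1.0, 0.0, 0.0])
    stack = [(start_mm, d0, 1, None, 0)]  # (start, dir, generation, parent, plane_idx)
    next_id = 0
    while stack:
        p, d, gen, parent, plane = stack.pop()
        L = spec.root_length * spec.length_ratio ** (gen - 1)
        r = spec.root_radius * spec.radius_ratio ** (gen - 1)
        w = spec.root_wall * spec.wall_ratio ** (gen - 1)
        end = p + L * d
        sid = next_id
        next_id += 1
        segs.append({"id": sid, "parent": parent, "generation": gen,
                     "p0": p, "p1": end, "radius": r, "wall": w})
        if gen < spec.airway_generations:
            # branching plane alternates: rotate about the y then x axis
            axis_global = np.array([0.0, 1.0, 0.0]) if plane % 2 == 0 else np.array([0.0, 0.0, 1.0])
            # orthogonalise against d so the rotation stays planar
            axis = axis_global - np.dot(axis_global, d) * d
            nrm = np.linalg.norm(axis)
            if nrm < 1e-6:
                axis_global = np.array([0.0, 0.0, 1.0]) if plane % 2 == 0 else np.array([0.0, 1.0, 0.0])
                axis = axis_global - np.dot(axis_global, d) * d
                nrm = np.linalg.norm(axis)
            axis /= nrm
            for sign in (+1.0, -1.0):
                child_dir = _rotate(d, axis, sign * theta)
                child_dir /= np.linalg.norm(child_dir)
                stack.append((end, child_dir, gen + 1, sid, plane + 1))
    return segs


def _truth_tree(segs: list[dict]) -> AirwayTree:
    out = []
    for s in segs:
        p0, p1 = s["p0"], s["p1"]
        mid = 0.5 * (p0 + p1)
        out.append(AirwaySegment(
            id=s["id"], parent_id=s["parent"], generation=s["generation"],
            centerline=np.stack([p0, mid, p1]),
            mean_lumen_area=float(np.pi * s["radius"] ** 2),
            mean_wall_thickness=float(s["wall"]),
            quality_flag="ok",
            radius_mm=float(s["radius"]), wall_mm=float(s["wall"]),
        ))
    return AirwayTree(segments=out)


def _raster_tree(
    segs: list[dict],
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    wall_scale: float = 1.0,
    sheath_mm: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize lumen, wall and peribronchial-sheath masks by
    center-point membership."""
    lumen = np.zeros(shape, dtype=bool)
    outer = np.zeros(shape, dtype=bool)
    sheath = np.zeros(shape, dtype=bool)
    for s in segs:
        p0, p1 = s["p0"], s["p1"]
        r_out = s["radius"] + s["wall"] * wall_scale
        lo = np.minimum(p0, p1) - r_out - sheath_mm - spacing
        hi = np.maximum(p0, p1) + r_out + sheath_mm + spacing
        i0 = np.maximum(0, np.floor(lo / spacing).astype(int))
        i1 = np.minimum(np.asarray(shape), np.ceil(hi / spacing).astype(int) + 1)
        if np.any(i0 >= i1):
            continue
        zz, yy, xx = np.meshgrid(
            *[(np.arange(i0[k], i1[k]) + 0.5) * spacing[k] for k in range(3)],
            indexing="ij",
        )
        pts = np.stack([zz, yy, xx], axis=-1)
        ax = p1 - p0
        L2 = float(np.dot(ax, ax))
        rel = pts - p0
        t = np.clip(np.tensordot(rel, ax, axes=([-1], [0])) / L2, 0.0, 1.0)
        nearest = p0 + t[..., None] * ax
        dist = np.linalg.norm(pts - nearest, axis=-1)
        sl = tuple(slice(i0[k], i1[k]) for k in range(3))
        lumen[sl] |= dist < s["radius"]
        outer[sl] |= dist < r_out
        if sheath_mm > 0:
            sheath[sl] |= dist < r_out + sheath_mm
    wall = outer & ~lumen
    return lumen, wall, sheath


def _validate_tree_fits(segs: list[dict], extent: np.ndarray) -> None:
    for s in segs:
        # the wall capsule's end caps must fit; sheath clipping is harmless
        margin = s["radius"] + s["wall"]
        for p in (s["p0"], s["p1"]):
            if np.any(p - margin < 0) or np.any(p + margin > extent):
                raise ValueError(
                    f"airway tree generation {s['generation']} exceeds the "
                    f"grid (endpoint {np.round(p, 1).tolist()} mm, margin "
                    f"{margin:.1f} mm, extent {extent.tolist()} mm)"
                )


# ---------------------------------------------------------------------------
# volume synthesis


def _ellipsoid(shape, spacing, center, semi) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        *[(np.arange(shape[k]) + 0.5) * spacing[k] for k in range(3)], indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1)
    return ((pts - center) ** 2 / np.asarray(semi) ** 2).sum(axis=-1) <= 1.0


def sample_parenchyma_hu(
    spec: PhantomSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` parenchymal voxel attenuations from the mixture.

    Returns ``(hu, is_evlw, is_tail)``: EVLW voxels and (optional)
    vascular-tail voxels are drawn from the bright component
    Normal(evlw_mean, evlw_sd); the remainder follow the noisy linear
    air/tissue mixing model.
    """
    u = rng.random(n)
    is_evlw = u < spec.evlw_weight
    is_tail = u < spec.evlw_weight + spec.vascular_weight
    hu = np.empty(n, dtype=float)
    f = spec.lung_air_fraction
    base = HU_AIR * f + spec.body_hu * (1.0 - f)
    n_clean = int((~is_tail).sum())
    hu[~is_tail] = base + (rng.normal(0.0, spec.noise_sd, n_clean)
                           if spec.noise_sd > 0 else 0.0)
    n_tail = int(is_tail.sum())
    if n_tail:
        hu[is_tail] = rng.normal(spec.evlw_mean, spec.evlw_sd, n_tail)
    return hu, is_evlw, is_tail


def build_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Render a thorax phantom and its exact ground truth.

    Voxels are assigned by center-point membership (no antialiasing), so
    the truth masks are exact at the cost of a <= 1 voxel bias in rendered
    radii.  Bit-identical output for equal specs (seed included).
    """
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    extent = spec.extent_mm
    center = extent / 2.0

    body_semi = np.array([0.47, 0.40, 0.45]) * extent
    body = _ellipsoid(shape, spacing, center, body_semi)

    lung_semi = np.array([0.36, 0.30, 0.185]) * extent
    lung_dz = 0.065 * extent[0]
    offset_x = 0.225 * extent[2]
    lungs = (
        _ellipsoid(shape, spacing, center + [lung_dz, 0, -offset_x], lung_semi)
        | _ellipsoid(shape, spacing, center + [lung_dz, 0, offset_x], lung_semi)
    )
    # keep a >= 2 mm soft-tissue shell so lung air never reaches ambient air
    shell_vox = max(1, int(np.ceil(2.0 / spacing.min())))
    from scipy import ndimage as _ndi
    lungs &= _ndi.binary_erosion(body, structure=np.ones((3, 3, 3), bool),
                                 iterations=shell_vox)

    start_z = max(0.11 * extent[0],
                  spec.root_radius + spec.root_wall + spacing[0])
    start = np.array([start_z, center[1], center[2]])
    segs = _tree_geometry(spec, start)
    _validate_tree_fits(segs, extent)
    # a 2 mm peribronchial soft-tissue sheath keeps the lumen enclosed even
    # where distal branches leave the body/lung ellipsoids
    lumen, wall, sheath = _raster_tree(segs, shape, spacing, sheath_mm=2.0)
    body |= sheath

    parenchyma = lungs & ~lumen & ~wall

    rng = np.random.default_rng(spec.seed)
    values = np.full(shape, HU_AIR, dtype=float)
    values[body] = spec.body_hu
    par_idx = np.nonzero(parenchyma)
    hu, is_evlw, is_tail = sample_parenchyma_hu(spec, par_idx[0].size, rng)
    values[par_idx] = hu
    values[wall] = spec.body_hu
    values[lumen] = HU_AIR

    evlw_mask = np.zeros(shape, dtype=bool)
    evlw_mask[par_idx] = is_evlw
    tail_mask = np.zeros(shape, dtype=bool)
    tail_mask[par_idx] = is_tail

    air_map = np.zeros(shape, dtype=float)
    air_map[parenchyma] = spec.lung_air_fraction
    air_map[tail_mask] = voxel_air_fraction(values[tail_mask])

    volume = CTVolume(values=values, spacing=tuple(spacing))
    truth = PhantomTruth(
        lung_mask=RegionMask(parenchyma, label="lung"),
        airway_lumen_mask=RegionMask(lumen, label="airway_lumen"),
        airway_wall_mask=RegionMask(wall, label="airway_wall"),
        tree=_truth_tree(segs),
        true_air_fraction_map=air_map,
        evlw_voxel_mask=RegionMask(evlw_mask, label="other"),
        body_mask=RegionMask(body & ~lungs & ~lumen & ~wall, label="other"),
        lung_territory=RegionMask(lungs, label="other"),
        spec=spec,
    )
    return volume, truth


def apply_bronchodilator(
    volume: CTVolume,
    truth: PhantomTruth,
    clearance: float,
    wall_thinning: float,
    seed: int = 0,
) -> tuple[CTVolume, PhantomTruth]:
    """Simulate the post-bronchodilator state of a phantom.

    A fraction ``clearance`` of the EVLW voxels is resampled from the clean
    parenchymal model (fluid cleared); airway wall thickness is reduced by
    the fraction ``wall_thinning`` with the lumen untouched.  Returns a new
    paired volume and updated truth; the inputs are not modified.
    """
    if not 0.0 <= clearance <= 1.0:
        raise ValueError("clearance must lie in [0, 1]")
    if not 0.0 <= wall_thinning <= 1.0:
        raise ValueError("wall_thinning must lie in [0, 1]")
    spec = truth.spec
    rng = np.random.default_rng(seed)
    values = volume.values.copy()
    evlw = truth.evlw_voxel_mask.mask.copy()
    parenchyma = truth.lung_mask.mask.copy()
    air_map = truth.true_air_fraction_map.copy()

    # --- fluid clearance -------------------------------------------------
    idx = np.argwhere(evlw)
    n_clear = int(round(clearance * idx.shape[0]))
    if n_clear > 0:
        chosen = idx[rng.choice(idx.shape[0], size=n_clear, replace=False)]
        sel = tuple(chosen.T)
        f = spec.lung_air_fraction
        base = HU_AIR * f + spec.body_hu * (1.0 - f)
        values[sel] = base + (rng.normal(0.0, spec.noise_sd, n_clear)
                              if spec.noise_sd > 0 else 0.0)
        evlw[sel] = False
        air_map[sel] = f

    # --- wall thinning ---------------------------------------------------
    new_tree = truth.tree
    lumen_mask = truth.airway_lumen_mask
    wall_mask = truth.airway_wall_mask
    if wall_thinning > 0:
        spacing = np.asarray(spec.voxel_spacing, dtype=float)
        start = truth.tree.root.centerline[0]
        segs = _tree_geometry(spec, np.asarray(start, dtype=float))
        _, new_wall, _ = _raster_tree(segs, volume.shape, spacing,
                                      wall_scale=1.0 - wall_thinning)
        new_wall &= ~lumen_mask.mask
        freed = wall_mask.mask & ~new_wall
        inside = freed & truth.lung_territory.mask
        n_free = int(inside.sum())
        if n_free > 0:
            f = spec.lung_air_fraction
            base = HU_AIR * f + spec.body_hu * (1.0 - f)
            values[inside] = base + (rng.normal(0.0, spec.noise_sd, n_free)
                                     if spec.noise_sd > 0 else 0.0)
            parenchyma |= inside
            air_map[inside] = f
        # freed voxels outside the lungs revert to body soft tissue: HU unchanged
        wall_mask = RegionMask(new_wall, label="airway_wall")
        new_tree = copy.deepcopy(truth.tree)
        for s in new_tree.segments:
            if s.wall_mm is not None:
                s.wall_mm *= 1.0 - wall_thinning
                s.mean_wall_thickness = s.wall_mm

    post = CTVolume(values=values, spacing=volume.spacing, origin=volume.origin)
    new_truth = PhantomTruth(
        lung_mask=RegionMask(parenchyma, label="lung"),
        airway_lumen_mask=lumen_mask,
        airway_wall_mask=wall_mask,
        tree=new_tree,
        true_air_fraction_map=air_map,
        evlw_voxel_mask=RegionMask(evlw, label="other"),
        body_mask=truth.body_mask,
        lung_territory=truth.lung_territory,
        spec=spec,
    )
    return post, new_truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class GroupParams:
    """Per-group subject-parameter distributions (mean, SD pairs)."""

    n: int
    evlw_weight: tuple[float, float] = (0.05, 0.02)
    #: uncleared right-tail (small-vessel) weight per subject
    vascular_weight: tuple[float, float] = (0.04, 0.01)
    tlc: tuple[float, float] = (6.5, 1.0)  # L
    spirometry: dict[str, tuple[float, float]] = field(default_factory=dict)
    clearance: tuple[float, float] = (0.9, 0.05)
    #: correlation between a subject's baseline EVLW weight and the cleared
    #: fraction — subjects with more fluid clear proportionally more
    clearance_evlw_rho: float = 0.5
    wall_thinning: tuple[float, float] = (0.12, 0.04)
    #: mean luminal area per generation 1..6, mm^2
    gen_areas: tuple[float, ...] = (245.0, 141.0, 83.0, 39.0, 19.0, 9.5)
    area_cv: float = 0.20
    #: mean wall thickness per generation 1..6, mm
    gen_walls: tuple[float, ...] = (2.53, 2.16, 1.71, 1.42, 1.22, 1.1)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 per group")
        if not 0.0 <= self.clearance[0] <= 1.0:
            raise ValueError("clearance mean must lie in [0, 1]")
        if not self.spirometry:
            self.spirometry = {
                "fvc_pct": (101.0, 15.0),
                "fev1_pct": (103.0, 15.0),
                "fef2575_pct": (118.0, 36.0),
                "pef_pct": (105.0, 18.0),
            }


def default_cohort_groups() -> dict[str, GroupParams]:
    """Control / HF group distributions emulating a 29 + 31 cohort with
    mildly congested HF lungs, reduced HF spirometry, and near-complete
    bronchodilator fluid clearance in both groups."""
    return {
        "control": GroupParams(
            n=29,
            evlw_weight=(0.05, 0.02),
            tlc=(6.5, 1.0),
            spirometry={
                "fvc_pct": (101.0, 15.0), "fev1_pct": (103.0, 15.0),
                "fef2575_pct": (118.0, 36.0), "pef_pct": (105.0, 18.0),
            },
            gen_areas=(245.0, 141.0, 83.0, 39.0, 19.0, 9.5),
            gen_walls=(2.53, 2.16, 1.71, 1.42, 1.22, 1.1),
        ),
        "hf": GroupParams(
            n=31,
            evlw_weight=(0.25, 0.08),
            tlc=(5.6, 1.0),
            spirometry={
                "fvc_pct": (83.0, 18.0), "fev1_pct": (82.0, 19.0),
                "fef2575_pct": (86.0, 36.0), "pef_pct": (85.0, 20.0),
            },
            gen_areas=(267.0, 143.0, 83.0, 36.0, 19.0, 9.5),
            gen_walls=(2.62, 2.21, 2.03, 1.81, 1.48, 1.28),
        ),
    }


def default_target_correlations() -> list[tuple[int, str, float]]:
    """Airway-area-versus-spirometry correlation targets (generation,
    variable, rho) of the magnitude seen in real cohorts."""
    table = {
        "fev1_pct": (0.46, 0.56, 0.32, 0.31, 0.31, 0.29),
        "fvc_pct": (0.39, 0.53, 0.33, 0.31, 0.28, 0.31),
        "fef2575_pct": (0.53, 0.49, 0.24, 0.25, 0.40, 0.30),
        "pef_pct": (0.59, 0.63, 0.25, 0.40, 0.54, 0.47),
    }
    return [(g, v, table[v][g - 1]) for v in table for g in range(1, 7)]


@dataclass
class CohortSpec:
    """A two-group cohort with copula-coupled structure and function."""

    groups: dict[str, GroupParams] = field(default_factory=default_cohort_groups)
    target_correlations: list[tuple[int, str, float]] = field(
        default_factory=default_target_correlations
    )
    gen_gen_rho: float = 0.55  # latent correlation between generation areas
    spiro_spiro_rho: float = 0.65  # latent correlation between spirometry vars
    seed: int = 0

    def __post_init__(self) -> None:
        for g, v, rho in self.target_correlations:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"|rho| must be <= 1, got {rho} for gen {g}/{v}")
            if not 1 <= g <= 6:
                raise ValueError(f"generation must lie in 1..6, got {g}")
            if v not in SPIRO_VARS:
                raise ValueError(f"unknown spirometry variable {v!r}")


@dataclass
class CohortSubject:
    """One sampled subject: record stub plus phantom parameters."""

    record: SubjectRecord
    phantom_spec: PhantomSpec
    clearance: float
    wall_thinning: float
    evlw_weight: float
    true_gen_areas: np.ndarray  # mm^2, generations 1..6
    true_gen_walls: np.ndarray  # mm


def _copula_matrix(cspec: CohortSpec) -> np.ndarray:
    """10x10 latent correlation matrix: 6 generation areas then 4
    spirometry variables."""
    k = 6 + len(SPIRO_VARS)
    C = np.eye(k)
    C[:6, :6] = cspec.gen_gen_rho
    C[6:, 6:] = cspec.spiro_spiro_rho
    np.fill_diagonal(C, 1.0)
    for g, v, rho in cspec.target_correlations:
        j = 6 + SPIRO_VARS.index(v)
        C[g - 1, j] = C[j, g - 1] = rho
    eig = np.linalg.eigvalsh(C)
    if eig.min() < -1e-8:
        raise ValueError(
            f"infeasible correlation targets: matrix not positive "
            f"semi-definite (min eigenvalue {eig.min():.3g})"
        )
    return C


def _mvn_factor(C: np.ndarray) -> np.ndarray:
    """Square root of a PSD correlation matrix (handles singular cases,
    e.g. a target rho of exactly 1)."""
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def sample_cohort(cspec: CohortSpec) -> list[CohortSubject]:
    """Draw a cohort of subjects with copula-coupled airway areas and
    spirometry; deterministic given ``cspec.seed``."""
    C = _copula_matrix(cspec)
    A = _mvn_factor(C)
    rng = np.random.default_rng(cspec.seed)
    subjects: list[CohortSubject] = []
    for group, gp in cspec.groups.items():
        for i in range(gp.n):
            z = A @ rng.standard_normal(C.shape[0])
            areas = np.asarray(gp.gen_areas) * (1.0 + gp.area_cv * z[:6])
            areas = np.maximum(areas, 0.05 * np.asarray(gp.gen_areas))
            spiro = {
                v: gp.spirometry[v][0] + gp.spirometry[v][1] * z[6 + j]
                for j, v in enumerate(SPIRO_VARS)
            }
            z_w = rng.standard_normal()
            evlw_w = float(np.clip(gp.evlw_weight[0] + gp.evlw_weight[1] * z_w,
                                   0.001, 0.8))
            vasc_w = float(np.clip(rng.normal(*gp.vascular_weight), 0.0, 0.2))
            tlc = float(max(rng.normal(*gp.tlc), 2.0))
            rho_c = gp.clearance_evlw_rho
            z_c = rho_c * z_w + np.sqrt(1.0 - rho_c**2) * rng.standard_normal()
            clearance = float(np.clip(
                gp.clearance[0] + gp.clearance[1] * z_c, 0.0, 1.0))
            thinning = float(np.clip(rng.normal(*gp.wall_thinning), 0.0, 0.9))
            walls = np.asarray(gp.gen_walls, dtype=float)
            root_radius = float(np.sqrt(areas[0] / np.pi))
            pspec = PhantomSpec(
                evlw_weight=evlw_w,
                vascular_weight=vasc_w,
                root_radius=root_radius,
                root_wall=float(walls[0]),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec = SubjectRecord(
                subject_id=f"{group}-{i:03d}", group=group, tlc=tlc,
                spirometry=spiro,
            )
            subjects.append(CohortSubject(
                record=rec, phantom_spec=pspec, clearance=clearance,
                wall_thinning=thinning, evlw_weight=evlw_w,
                true_gen_areas=areas, true_gen_walls=walls,
            ))
    return subjects


def _metrics_from_hu(hu: np.ndarray, tlc: float) -> DensityMetrics:
    mean_hu, g1, g2 = distribution_moments(hu)
    f_air = float(np.mean(voxel_air_fraction(hu)))
    return DensityMetrics(
        mean_hu=mean_hu, skewness=g1, kurtosis=g2, kurtosis_raw=g2 + 3.0,
        fwhm=fwhm(build_histogram(hu, bin_width=1.0)),
        pct_gt_m500=congestion_index(hu),
        v_air=f_air * tlc, v_tis=(1.0 - f_air) * tlc,
        n_voxels=int(hu.size),
    )


def simulate_cohort_records(
    subjects: list[CohortSubject],
    n_voxels: int = 50_000,
    post_fraction: float = 1.0,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Fill subject records by sampling the parenchymal attenuation mixture
    directly (no volume rasterization) — the fast path for cohort-scale
    statistics.  Density metrics come from ``n_voxels`` mixture draws per
    scan; per-generation summaries come from the subjects' ground-truth
    areas and walls.  A trailing ``1 - post_fraction`` share of each group
    is left without a post scan.
    """
    from .airways import GenerationSummary, normalize_to_subject

    rng = np.random.default_rng(seed)
    records = []
    counters: dict[str, int] = {}
    totals: dict[str, int] = {}
    for s in subjects:
        totals[s.record.group] = totals.get(s.record.group, 0) + 1
    for s in subjects:
        rec = s.record
        hu_pre, _, _ = sample_parenchyma_hu(s.phantom_spec, n_voxels, rng)
        rec.pre_density = _metrics_from_hu(hu_pre, rec.tlc)
        rec.pre_generations = [
            normalize_to_subject(GenerationSummary(
                generation=g + 1, mean_area=float(s.true_gen_areas[g]),
                mean_wall=float(s.true_gen_walls[g]), n_segments=2**g,
            ), rec.tlc)
            for g in range(6)
        ]
        k = counters.get(rec.group, 0)
        counters[rec.group] = k + 1
        if k < int(np.ceil(post_fraction * totals[rec.group])):
            post_spec = replace(
                s.phantom_spec,
                evlw_weight=s.phantom_spec.evlw_weight * (1.0 - s.clearance),
            )
            hu_post, _, _ = sample_parenchyma_hu(post_spec, n_voxels, rng)
            rec.post_density = _metrics_from_hu(hu_post, rec.tlc)
            post_walls = s.true_gen_walls * (1.0 - s.wall_thinning)
            rec.post_generations = [
                normalize_to_subject(GenerationSummary(
                    generation=g + 1, mean_area=float(s.true_gen_areas[g]),
                    mean_wall=float(post_walls[g]), n_segments=2**g,
                ), rec.tlc)
                for g in range(6)
            ]
        records.append(rec)
    return records
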