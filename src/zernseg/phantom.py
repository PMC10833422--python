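"""Seeded synthetic Zernike-nanoCT-like bone volumes with paired labels.

The phantom emulates the contrast pathology of Zernike phase-contrast
reconstructions of a bone rod: an outer geometry with convex and concave
regions partially coated by mounting polymer, ellipsoidal osteocyte lacunae
connected by tubular canaliculi (the LCN), bright halo rims at material
interfaces, dark shade-off ramps extending into the bone from air
interfaces (stronger at concave surfaces, attenuated under polymer), and
additive Gaussian noise.  Per-class gray-value distributions deliberately
overlap so that no single threshold separates the classes.

Artifacts are written directly into the reconstructed-domain volume; no
wave-optics or sinogram simulation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .volumes import (
    BONE,
    CLASSES,
    LCN,
    SHADE_OFF,
    GrayVolume,
    LabelVolume,
    extract_slices,  # noqa: F401  (re-exported: slicing belongs to phantom's surface too)
)


def _default_class_means() -> dict[str, float]:
    return {"background": 0.12, "bone": 0.62, "shade_off": 0.48, "lcn": 0.28}


@dataclass
class PhantomSpec:
    """Full parameterization of a synthetic volume/label pair.

    All geometric lengths are in voxels; gray levels are on ``[0, 1]``.
    A single integer ``seed`` drives every stochastic draw.
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    voxel_size_nm: float = 94.0
    target_porosity_frac: float = 0.021
    n_lacunae: int = 8
    lacuna_radii_vox: tuple[float, float] = (3.0, 6.0)
    canaliculus_radius_vox: float = 1.2
    concavity_depth_vox: float = 6.0
    polymer_arc_frac: float = 0.25
    halo_amplitude: float = 0.22
    halo_width_vox: float = 1.8
    shade_amplitude: float = 0.22
    shade_width_vox: float = 7.0
    shade_polymer_attenuation: float = 0.25
    class_means: dict = field(default_factory=_default_class_means)
    noise_sd: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        z, y, x = self.shape
        if min(z, y, x) < 32:
            raise ConfigurationError(f"shape: each dimension must be >= 32, got {self.shape}")
        if not 0.0 < self.target_porosity_frac < 0.1:
            raise ConfigurationError(
                f"target_porosity_frac: must lie in (0, 0.1), got {self.target_porosity_frac}"
            )
        if self.n_lacunae < 1:
            raise ConfigurationError("n_lacunae: must be a positive integer")
        lo, hi = self.lacuna_radii_vox
        if not 0 < lo <= hi:
            raise ConfigurationError(f"lacuna_radii_vox: invalid range {self.lacuna_radii_vox}")
        if self.canaliculus_radius_vox <= 0:
            raise ConfigurationError("canaliculus_radius_vox: must be > 0")
        if self.concavity_depth_vox < 0:
            raise ConfigurationError("concavity_depth_vox: must be >= 0")
        if not 0.0 <= self.polymer_arc_frac <= 1.0:
            raise ConfigurationError("polymer_arc_frac: must lie in [0, 1]")
        if not 0.0 <= self.shade_polymer_attenuation <= 1.0:
            raise ConfigurationError("shade_polymer_attenuation: must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be >= 0")
        for name in ("background", "bone", "lcn"):
            if name not in self.class_means:
                raise ConfigurationError(f"class_means: missing entry for '{name}'")


@dataclass
class ContrastShift:
    """Contrast-statistics override emulating a different beamline setup.

    Fields left at ``None`` keep the source spec's value; the geometry
    (and its random draws) is unchanged, so a shift with all fields ``None``
    reproduces the unshifted phantom bit-for-bit.  A shift with
    ``shade_amplitude=0`` produces a 3-class phantom (background, bone,
    LCN) with no shade-off voxels.
    """

    class_means: dict | None = None
    shade_amplitude: float | None = None
    noise_sd: float | None = None
    halo_amplitude: float | None = None


@dataclass
class PhantomRealization:
    """A generated phantom together with its oracle geometry masks."""

    gray: GrayVolume
    labels: LabelVolume
    spec: PhantomSpec
    bone_mask: np.ndarray
    lcn_mask: np.ndarray
    polymer_mask: np.ndarray
    halo_band: np.ndarray  # solid-side bright rim (diagnostic band)
    shade_band: np.ndarray  # voxels labeled shade_off
    d_air: np.ndarray  # distance of solid voxels to nearest air voxel
    lacuna_centers: np.ndarray
    canaliculi_edges: list[tuple[int, int]]
    graph_components: int
    realized_porosity: float


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def _rod_masks(spec: PhantomSpec, rng: np.random.Generator):
    """Rasterize the outer bone rod, its polymer coat and concavity boost."""
    z, y, x = spec.shape
    cy, cx = (y - 1) / 2.0, (x - 1) / 2.0
    r0 = 0.33 * min(y, x)
    zz = np.arange(z)[:, None, None]
    yy = np.arange(y)[None, :, None] - cy
    xx = np.arange(x)[None, None, :] - cx
    theta = np.arctan2(yy, xx)  # (1, y, x) broadcastable
    r = np.sqrt(yy * yy + xx * xx)

    theta_concave = rng.uniform(-np.pi, np.pi)
    theta_polymer = rng.uniform(-np.pi, np.pi)
    phase = rng.uniform(0, 2 * np.pi)

    # sinusoidal convexity + one Gaussian concave groove running along z
    bump = np.exp(-_wrap_angle(theta - theta_concave) ** 2 / (2 * 0.55**2))
    radius = (
        r0 * (1.0 + 0.10 * np.sin(2 * theta + 2 * np.pi * zz / z + phase))
        - spec.concavity_depth_vox * bump
    )
    bone = r <= radius

    arc_half = np.pi * spec.polymer_arc_frac
    in_arc = np.abs(_wrap_angle(theta - theta_polymer)) <= arc_half
    polymer = (~bone) & (r <= radius + 4.0) & np.broadcast_to(in_arc, bone.shape)

    boost = 1.0 + np.broadcast_to(bump, bone.shape)  # concave surfaces shade ~2x
    atten = np.where(np.broadcast_to(in_arc, bone.shape), spec.shade_polymer_attenuation, 1.0)
    return bone, polymer, boost, atten, r0


def _sample_lacunae(spec: PhantomSpec, rng: np.random.Generator, r0: float):
    z = spec.shape[0]
    lo, hi = spec.lacuna_radii_vox
    margin = hi + 2
    cy, cx = (spec.shape[1] - 1) / 2.0, (spec.shape[2] - 1) / 2.0
    centers = np.empty((spec.n_lacunae, 3))
    for i in range(spec.n_lacunae):
        rho = 0.55 * r0 * np.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * np.pi)
        cz = rng.uniform(margin, z - margin)
        centers[i] = (cz, cy + rho * np.sin(ang), cx + rho * np.cos(ang))
    semi = rng.uniform(lo, hi, size=(spec.n_lacunae, 3))
    return centers, semi


def _nearest_neighbor_edges(centers: np.ndarray) -> list[tuple[int, int]]:
    n = len(centers)
    edges = set()
    for i in range(n):
        d = np.linalg.norm(centers - centers[i], axis=1)
        d[i] = np.inf
        j = int(np.argmin(d))
        edges.add((min(i, j), max(i, j)))
    return sorted(edges)


def _graph_components(n: int, edges: list[tuple[int, int]]) -> int:
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def _paint_ellipsoid(mask: np.ndarray, c: np.ndarray, semi: np.ndarray) -> None:
    zl = [max(0, int(np.floor(c[k] - semi[k] - 1))) for k in range(3)]
    zh = [min(mask.shape[k], int(np.ceil(c[k] + semi[k] + 2))) for k in range(3)]
    if any(zl[k] >= zh[k] for k in range(3)):
        return
    grids = np.meshgrid(*[np.arange(zl[k], zh[k]) - c[k] for k in range(3)], indexing="ij")
    q = sum((g / s) ** 2 for g, s in zip(grids, semi))
    mask[zl[0] : zh[0], zl[1] : zh[1], zl[2] : zh[2]] |= q <= 1.0


def _paint_tube(mask: np.ndarray, a: np.ndarray, b: np.ndarray, radius: float) -> None:
    lo = np.maximum(0, np.floor(np.minimum(a, b) - radius - 1).astype(int))
    hi = np.minimum(mask.shape, np.ceil(np.maximum(a, b) + radius + 2).astype(int))
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij")
    p = np.stack(grids, axis=-1).astype(float)
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else np.zeros(p.shape[:-1])
    closest = a + t[..., None] * ab
    d2 = ((p - closest) ** 2).sum(axis=-1)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= d2 <= radius**2


def _rasterize_lcn(spec, centers, semi, edges, scale, bone_interior):
    lcn = np.zeros(spec.shape, dtype=bool)
    for c, s in zip(centers, semi):
        _paint_ellipsoid(lcn, c, s * scale)
    for i, j in edges:
        _paint_tube(lcn, centers[i], centers[j], spec.canaliculus_radius_vox)
    return lcn & bone_interior


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_phantom_full(spec: PhantomSpec) -> PhantomRealization:
    """Generate a phantom and return it with all oracle geometry masks."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    bone, polymer, boost, atten, r0 = _rod_masks(spec, rng)
    v_bone = int(bone.sum())
    if v_bone == 0:
        raise ConfigurationError("shape: bone rod does not fit in the requested shape")

    centers, semi = _sample_lacunae(spec, rng, r0)
    edges = _nearest_neighbor_edges(centers) if spec.n_lacunae > 1 else []
    n_graph = _graph_components(spec.n_lacunae, edges)

    # porosity targeting: scale ellipsoid semi-axes so carved LCN volume hits
    # target_porosity_frac * V(rod); a couple of corrective re-rasterizations
    # absorb clipping and tube/ellipsoid overlap.
    v_target = spec.target_porosity_frac * v_bone
    tube_len = sum(np.linalg.norm(centers[i] - centers[j]) for i, j in edges)
    v_tubes = np.pi * spec.canaliculus_radius_vox**2 * tube_len
    v_ellipsoids = (4.0 / 3.0) * np.pi * np.prod(semi, axis=1).sum()
    if v_tubes >= v_target:
        raise ConfigurationError(
            "target_porosity_frac: unreachable — canaliculi alone exceed the porosity budget"
        )
    scale = ((v_target - v_tubes) / v_ellipsoids) ** (1.0 / 3.0)
    if scale * semi.max() > 0.45 * r0 or scale * semi.min() < 0.7:
        raise ConfigurationError(
            "target_porosity_frac: unreachable with n_lacunae="
            f"{spec.n_lacunae} and lacuna_radii_vox={spec.lacuna_radii_vox}"
        )

    bone_interior = ndimage.binary_erosion(bone, ndimage.generate_binary_structure(3, 1))
    lcn = _rasterize_lcn(spec, centers, semi, edges, scale, bone_interior)
    for _ in range(3):
        realized = lcn.sum() / v_bone
        if abs(realized - spec.target_porosity_frac) <= 0.10 * spec.target_porosity_frac:
            break
        scale *= (spec.target_porosity_frac / max(realized, 1e-9)) ** (1.0 / 3.0)
        lcn = _rasterize_lcn(spec, centers, semi, edges, scale, bone_interior)
    realized = float(lcn.sum() / v_bone)

    solid = bone & ~lcn

    # distance fields for artifact synthesis
    d_air = ndimage.distance_transform_edt(bone | polymer)  # to exterior air
    d_in = ndimage.distance_transform_edt(solid)  # to any non-solid (air or LCN)
    d_out = ndimage.distance_transform_edt(~solid)
    d_interface = np.where(solid, d_in, d_out) - 0.5

    # halo: Gaussian bright band centered on interfaces (both sides)
    halo = spec.halo_amplitude * np.exp(-np.maximum(d_interface, 0.0) ** 2 / (2 * spec.halo_width_vox**2))
    # shade-off: exponential dark ramp into the bone from air interfaces,
    # starting past the halo rim, boosted at concave surfaces, attenuated
    # under polymer arcs
    d0 = max(2.0 * spec.halo_width_vox, 1.0)
    shade_shape = np.exp(-np.maximum(d_air - d0, 0.0) / max(spec.shade_width_vox, 1e-6))
    shade_shape *= np.clip(d_air / d0, 0.0, 1.0)  # ramp up past the halo rim
    shade = spec.shade_amplitude * boost * atten * shade_shape * solid

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[solid] = BONE
    shade_band = solid & (d_air <= spec.shade_width_vox) & (shade >= 0.04)
    labels[shade_band] = SHADE_OFF
    labels[lcn] = LCN

    means = spec.class_means
    gray = np.full(spec.shape, means["background"], dtype=np.float64)
    gray[solid] = means["bone"]
    gray[lcn] = means["lcn"]
    gray += halo
    gray -= shade
    if spec.noise_sd > 0:
        rng_noise = np.random.default_rng([spec.seed, 0xA5])
        gray += spec.noise_sd * rng_noise.standard_normal(spec.shape)
    np.clip(gray, 0.0, 1.0, out=gray)

    halo_band = solid & (d_in - 0.5 <= spec.halo_width_vox)

    return PhantomRealization(
        gray=GrayVolume(gray.astype(np.float32), spec.voxel_size_nm, f"phantom(seed={spec.seed})"),
        labels=LabelVolume(labels, CLASSES, spec.voxel_size_nm),
        spec=spec,
        bone_mask=bone,
        lcn_mask=lcn,
        polymer_mask=polymer,
        halo_band=halo_band,
        shade_band=shade_band,
        d_air=d_air,
        lacuna_centers=centers,
        canaliculi_edges=edges,
        graph_components=n_graph,
        realized_porosity=realized,
    )


def generate_phantom(spec: PhantomSpec) -> tuple[GrayVolume, LabelVolume]:
    """Generate a seeded synthetic volume and its ground-truth labels."""
    real = generate_phantom_full(spec)
    return real.gray, real.labels


def generate_domain_shifted(
    spec: PhantomSpec, shift: ContrastShift
) -> tuple[GrayVolume, LabelVolume]:
    """Same geometry as :func:`generate_phantom`, different contrast statistics."""
    real = generate_domain_shifted_full(spec, shift)
    return real.gray, real.labels


def generate_domain_shifted_full(spec: PhantomSpec, shift: ContrastShift) -> PhantomRealization:
    overrides = {}
    if shift.class_means is not None:
        overrides["class_means"] = dict(shift.class_means)
    if shift.shade_amplitude is not None:
        overrides["shade_amplitude"] = shift.shade_amplitude
    if shift.noise_sd is not None:
        overrides["noise_sd"] = shift.noise_sd
    if shift.halo_amplitude is not None:
        overrides["halo_amplitude"] = shift.halo_amplitude
    return generate_phantom_full(replace(spec, **overrides))


def label_porosity(labels: LabelVolume) -> float:
    """LCN voxels / (LCN + bone-material voxels), as a fraction.

    Shade-off voxels count as bone material (they are bone under an
    artifact), matching the class merge applied before morphometry.
    """
    counts = labels.class_counts()
    lcn = counts.get("lcn", 0)
    bone = counts.get("bone", 0) + counts.get("shade_off", 0)
    if lcn + bone == 0:
        raise ConfigurationError("label volume contains no bone or LCN voxels")
    return lcn / (lcn + bone)
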