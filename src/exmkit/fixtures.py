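"""Synthetic ExM scenes with full ground truth.

Every downstream module (registration, distortion mapping, calibration,
surface tracing, puncta statistics) is exercised against scenes generated
here: endosome-sized ellipsoidal shells decorated with clustered membrane
puncta plus interior puncta, sparse cytoplasmic nanocage point sources of
known true diameter, anisotropic Gaussian PSF blur, Poisson + Gaussian
detector noise, and analytic distortion fields (global isotropic expansion
plus local radial under-expansion around compartments).

All coordinates are physical nm in ``(z, y, x)`` order; see
:mod:`exmkit.volume` for the shared grid convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume import ImageVolume, index_to_phys

__all__ = [
    "FWHM_PER_SIGMA",
    "PSFModel",
    "CompartmentSpec",
    "NanocageFieldSpec",
    "DistortionSpec",
    "SceneSpec",
    "GroundTruth",
    "build_scene",
    "apply_distortion",
    "render_volume",
    "render_tem_nanocages",
]

#: FWHM of a Gaussian of unit sigma: 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PSFModel:
    """Anisotropic Gaussian point-spread function.

    ``sigma_lateral`` applies to y and x, ``sigma_axial`` to z (nm).  With
    ``normalize=True`` a rendered unit-intensity point integrates to 1 (to
    within the truncation of the rendering patch); otherwise the peak voxel
    value equals the source intensity.
    """

    sigma_lateral: float
    sigma_axial: float
    normalize: bool = True

    def __post_init__(self):
        if self.sigma_lateral <= 0 or self.sigma_axial <= 0:
            raise ValueError("PSF sigmas must be positive")

    @property
    def fwhm_lateral(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_lateral

    @property
    def fwhm_axial(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_axial

    @property
    def sigmas_zyx(self) -> tuple[float, float, float]:
        return (self.sigma_axial, self.sigma_lateral, self.sigma_lateral)


@dataclass(frozen=True)
class CompartmentSpec:
    """One endosome-like compartment: an ellipsoidal shell of membrane puncta
    (optionally clustered into nanodomains) plus puncta in the lumen.

    ``channel_map`` assigns marker names to punctum subsets, e.g.
    ``{"endofin": "membrane", "EGF": "interior"}``; subsets are ``"membrane"``,
    ``"interior"`` or ``"all"``.
    """

    centroid: tuple[float, float, float]
    radii: tuple[float, float, float]
    n_membrane_puncta: int = 200
    n_clusters: int = 12
    cluster_concentration: float = 30.0
    n_interior_puncta: int = 0
    channel_map: dict = field(default_factory=lambda: {"membrane": "membrane"})

    def __post_init__(self):
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"radii must be positive, got {self.radii}")
        if self.n_membrane_puncta < 0:
            raise ValueError("n_membrane_puncta must be >= 0")
        if self.n_interior_puncta < 0:
            raise ValueError("n_interior_puncta must be >= 0")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.cluster_concentration < 0:
            raise ValueError("cluster_concentration must be >= 0")


@dataclass(frozen=True)
class NanocageFieldSpec:
    """Sparse field of cytoplasmic nanocage calibrants of known true diameter.

    Diameters are drawn from a normal distribution (resampled until positive);
    cages are generated as *points* carrying a true diameter — any blur or
    annulus rendering is the renderer's job, never done at generation time.
    """

    n_cages: int
    diameter_mean: float = 28.3
    diameter_sd: float = 1.6
    intensity: float = 1.0
    region_low: tuple[float, float, float] = (0.0, 0.0, 0.0)
    region_high: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.n_cages < 0:
            raise ValueError("n_cages must be >= 0")
        if self.diameter_mean <= 0:
            raise ValueError("diameter_mean must be positive")
        if self.diameter_sd < 0:
            raise ValueError("diameter_sd must be >= 0")


@dataclass(frozen=True)
class DistortionSpec:
    """Global isotropic expansion plus local radial Gaussian bumps.

    A point ``p`` maps to ``g*p + sum_i a_i * exp(-|g*p - c_i|^2 / (2 f^2)) *
    (g*p - c_i)`` where ``g`` is the global expansion factor, ``c_i`` the
    (post-scale) local centers, ``a_i = local_amplitude`` (negative =
    under-expansion toward the center) and ``f = local_falloff`` (nm).  The
    bump is applied after global scaling so its parameters live on the
    post-expansion physical scale, where distortion is measured.
    """

    global_factor: float = 1.0
    local_centers: tuple = ()
    local_amplitude: float = 0.0
    local_falloff: float = 300.0

    def __post_init__(self):
        if self.global_factor <= 0:
            raise ValueError("global_factor must be positive")
        if abs(self.local_amplitude) >= 1.0:
            raise ValueError(
                "abs(local_amplitude) must be < 1 (fold-over risk); "
                f"got {self.local_amplitude}"
            )
        if self.local_falloff <= 0:
            raise ValueError("local_falloff must be positive")

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Analytic displacement (nm) of each point: mapped - original."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        mapped = self.map_points(p)
        return mapped - p

    def map_points(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if not np.all(np.isfinite(p)):
            raise ValueError("points must be finite")
        out = self.global_factor * p
        for c in self.local_centers:
            d = out - np.asarray(c, dtype=float)
            r2 = np.sum(d * d, axis=1, keepdims=True)
            out = out + self.local_amplitude * np.exp(-r2 / (2.0 * self.local_falloff**2)) * d
        return out


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to build one synthetic scene."""

    compartments: tuple = ()
    nanocages: NanocageFieldSpec | None = None
    distortion: DistortionSpec | None = None
    n_background_puncta: int = 0
    background_low: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_high: tuple[float, float, float] = (2000.0, 2000.0, 2000.0)


@dataclass
class GroundTruth:
    """Complete record of a generated scene.

    ``points`` maps channel name -> (N,3) pre-distortion coordinates (nm,
    z,y,x order); ``post_points`` holds the distorted counterparts (equal to
    ``points`` when the scene has no distortion).  ``true_displacement``
    evaluates the analytic displacement at arbitrary points, and by
    construction ``post_points[ch] - points[ch] ==
    true_displacement(points[ch])`` exactly.
    """

    points: dict
    post_points: dict
    intensities: dict
    surfaces: list
    nanocage_diameters: np.ndarray
    distortion: DistortionSpec | None
    seed: int

    def all_points(self, which: str = "pre") -> np.ndarray:
        d = self.points if which == "pre" else self.post_points
        arrays = [v for v in d.values() if len(v)]
        return np.vstack(arrays) if arrays else np.empty((0, 3))

    def true_displacement(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.distortion is None:
            return np.zeros_like(pts)
        return self.distortion.displacement(pts)


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def _sample_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform unit vectors (z,y,x)."""
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _sample_vmf(rng: np.random.Generator, mu: np.ndarray, kappa: float, n: int) -> np.ndarray:
    """von Mises–Fisher draws on S^2 around mean direction mu (Wood 1994)."""
    if kappa <= 0:
        return _sample_sphere(rng, n)
    # sample the cosine of the colatitude by inversion
    u = rng.uniform(size=n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    # orthonormal frame around mu
    a = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    return (
        w[:, None] * mu[None, :]
        + (s * np.cos(phi))[:, None] * e1[None, :]
        + (s * np.sin(phi))[:, None] * e2[None, :]
    )


def _membrane_points(rng: np.random.Generator, comp: CompartmentSpec) -> np.ndarray:
    """Puncta on the ellipsoid surface, clustered into nanodomains."""
    n = comp.n_membrane_puncta
    if n == 0:
        return np.empty((0, 3))
    if comp.n_clusters > 0 and comp.cluster_concentration > 0:
        axes = _sample_sphere(rng, comp.n_clusters)
        assign = rng.integers(0, comp.n_clusters, size=n)
        dirs = np.empty((n, 3))
        for k in range(comp.n_clusters):
            idx = np.flatnonzero(assign == k)
            if len(idx):
                dirs[idx] = _sample_vmf(rng, axes[k], comp.cluster_concentration, len(idx))
    else:
        dirs = _sample_sphere(rng, n)
    radii = np.asarray(comp.radii, dtype=float)
    return np.asarray(comp.centroid, dtype=float) + dirs * radii[None, :]


def _interior_points(rng: np.random.Generator, comp: CompartmentSpec) -> np.ndarray:
    """Puncta strictly inside the ellipsoid (uniform in the enclosed volume)."""
    n = comp.n_interior_puncta
    if n == 0:
        return np.empty((0, 3))
    dirs = _sample_sphere(rng, n)
    # radius^3 uniform -> uniform density in the ball, scaled per-axis
    u = rng.uniform(size=(n, 1)) ** (1.0 / 3.0) * 0.97
    radii = np.asarray(comp.radii, dtype=float)
    return np.asarray(comp.centroid, dtype=float) + dirs * u * radii[None, :]


def _ellipsoid_mesh(comp: CompartmentSpec):
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    mesh.vertices = mesh.vertices * np.asarray(comp.radii, float)[None, ::-1]  # trimesh is xyz
    mesh.vertices = mesh.vertices + np.asarray(comp.centroid, float)[None, ::-1]
    return mesh


def build_scene(spec: SceneSpec, seed: int) -> GroundTruth:
    """Generate all point sets, true surfaces and nanocage truths of a scene.

    Deterministic given ``seed``.  Channel labels follow each compartment's
    ``channel_map``; nanocages land in channel ``"nanocage"`` and unstructured
    cytoplasmic texture in ``"background"``.
    """
    rng = np.random.default_rng(seed)
    points: dict[str, list] = {}
    intensities: dict[str, list] = {}
    surfaces = []

    def add(channel, pts, inten=None):
        if channel not in points:
            points[channel], intensities[channel] = [], []
        points[channel].append(np.atleast_2d(pts) if len(pts) else np.empty((0, 3)))
        if inten is None:
            inten = np.ones(len(pts))
        intensities[channel].append(np.atleast_1d(inten))

    for comp in spec.compartments:
        mem = _membrane_points(rng, comp)
        inter = _interior_points(rng, comp)
        surfaces.append(_ellipsoid_mesh(comp))
        for channel, subset in comp.channel_map.items():
            if subset == "membrane":
                add(channel, mem)
            elif subset == "interior":
                add(channel, inter)
            elif subset == "all":
                add(channel, np.vstack([mem, inter]) if len(mem) or len(inter) else np.empty((0, 3)))
            else:
                raise ValueError(f"unknown channel subset {subset!r}")

    diameters = np.empty(0)
    if spec.nanocages is not None and spec.nanocages.n_cages > 0:
        nc = spec.nanocages
        high = np.asarray(nc.region_high if nc.region_high is not None else spec.background_high, float)
        low = np.asarray(nc.region_low, float)
        pos = rng.uniform(low, high, size=(nc.n_cages, 3))
        diameters = nc.diameter_mean + nc.diameter_sd * rng.standard_normal(nc.n_cages)
        while np.any(diameters <= 0):  # resample the (vanishingly rare) non-physical draws
            bad = diameters <= 0
            diameters[bad] = nc.diameter_mean + nc.diameter_sd * rng.standard_normal(bad.sum())
        add("nanocage", pos, np.full(nc.n_cages, nc.intensity))

    if spec.n_background_puncta > 0:
        pos = rng.uniform(
            np.asarray(spec.background_low, float),
            np.asarray(spec.background_high, float),
            size=(spec.n_background_puncta, 3),
        )
        add("background", pos, rng.uniform(0.5, 1.5, size=spec.n_background_puncta))

    points = {k: np.vstack(v) for k, v in points.items()}
    intensities = {k: np.concatenate(v) for k, v in intensities.items()}
    if spec.distortion is not None:
        post = {k: spec.distortion.map_points(v) if len(v) else v.copy() for k, v in points.items()}
    else:
        post = {k: v.copy() for k, v in points.items()}
    return GroundTruth(points, post, intensities, surfaces, diameters, spec.distortion, seed)


# ---------------------------------------------------------------------------
# distortion
# ---------------------------------------------------------------------------

def apply_distortion(points: np.ndarray, d: DistortionSpec, grid_shape=None, voxel_size=None):
    """Displace a point set and (optionally) sample the analytic displacement
    field on a voxel grid.

    Returns ``(displaced_points, field)`` where ``field`` is a ``(3, z, y, x)``
    array of (dz, dy, dx) displacements in nm at the voxel centers of the
    stated grid, or ``None`` if no grid was given.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    displaced = d.map_points(pts) if len(pts) else pts.copy()

    field = None
    if grid_shape is not None:
        if voxel_size is None:
            raise ValueError("voxel_size required when sampling the field on a grid")
        zz, yy, xx = np.meshgrid(
            *[(np.arange(n) + 0.5) * v for n, v in zip(grid_shape, voxel_size)],
            indexing="ij",
        )
        grid_pts = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
        field = d.displacement(grid_pts).reshape(*grid_shape, 3)
        field = np.moveaxis(field, -1, 0)
    return displaced, field


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_volume(
    points: np.ndarray,
    intensities,
    psf: PSFModel,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    poisson_gain: float = 0.0,
    gaussian_sd: float = 0.0,
    seed: int = 0,
    allow_clipping: bool = False,
    point_sigmas=None,
) -> ImageVolume:
    """Render point sources through the Gaussian PSF onto a voxel grid.

    Each source adds a separable 3D Gaussian evaluated on a local patch of
    ±4 sigma.  With a normalizing PSF the integrated signal of an interior
    point equals its intensity to within the patch truncation (<1%).
    ``point_sigmas`` optionally overrides the PSF width per point (N,3 z,y,x
    sigmas in nm) — used to render supra-resolution objects whose apparent
    size combines structure and PSF.

    Noise model: Poisson on ``poisson_gain``-scaled intensities (skipped when
    the gain is 0) followed by additive Gaussian noise of ``gaussian_sd``.
    """
    if any(v <= 0 for v in voxel_size):
        raise ValueError(f"voxel sizes must be positive, got {voxel_size}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inten = np.broadcast_to(np.asarray(intensities, dtype=float), (len(pts),))
    vs = np.asarray(voxel_size, float)
    extent = np.asarray(shape) * vs
    if len(pts) and not allow_clipping:
        if np.any(pts < 0) or np.any(pts >= extent):
            raise ValueError(
                "points fall outside the grid; pass allow_clipping=True to permit"
            )

    vol = np.zeros(shape, dtype=np.float64)
    base_sigmas = np.asarray(psf.sigmas_zyx, float)
    for i, p in enumerate(pts):
        sig = base_sigmas if point_sigmas is None else np.asarray(point_sigmas[i], float)
        lo = np.maximum(np.floor((p - 4 * sig) / vs - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((p + 4 * sig) / vs - 0.5).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        kernels = []
        for ax in range(3):
            centers = (np.arange(lo[ax], hi[ax]) + 0.5) * vs[ax]
            g = np.exp(-0.5 * ((centers - p[ax]) / sig[ax]) ** 2)
            if psf.normalize:
                g = g * (vs[ax] / (np.sqrt(2.0 * np.pi) * sig[ax]))
            kernels.append(g)
        vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            inten[i]
            * kernels[0][:, None, None]
            * kernels[1][None, :, None]
            * kernels[2][None, None, :]
        )

    if poisson_gain > 0 or gaussian_sd > 0:
        rng = np.random.default_rng(seed)
        if poisson_gain > 0:
            vol = rng.poisson(np.clip(vol * poisson_gain, 0, None)).astype(float) / poisson_gain
        if gaussian_sd > 0:
            vol = vol + rng.normal(0.0, gaussian_sd, size=vol.shape)
    return ImageVolume(vol.astype(np.float32), tuple(voxel_size))


def _jittered_grid(rng: np.random.Generator, n: int, extent, margin: float) -> np.ndarray:
    """n 2D centers on a jittered grid, keeping cages separated and off the
    image border (manual TEM analysis traces isolated, fully visible cages)."""
    extent = np.asarray(extent, float)
    usable = extent - 2.0 * margin
    cells = int(np.ceil(np.sqrt(n)))
    cell = usable / cells
    if np.any(cell < margin):
        raise ValueError(
            f"cannot place {n} non-overlapping cages of size ~{margin:.0f} nm "
            f"in a {extent[0]:.0f}x{extent[1]:.0f} nm field"
        )
    ij = np.stack(np.meshgrid(np.arange(cells), np.arange(cells), indexing="ij"), -1).reshape(-1, 2)
    chosen = ij[rng.permutation(len(ij))[:n]]
    jitter = rng.uniform(0.25, 0.75, size=(n, 2))
    return margin + (chosen + jitter) * cell[None, :]


def render_tem_nanocages(
    spec: NanocageFieldSpec,
    shape: tuple[int, int],
    pixel_size: float,
    seed: int,
    ring_thickness: float = 6.0,
    ellipticity_jitter: float = 0.03,
    density_warn: float = 0.2,
):
    """Render a negative-stain-TEM-like 2D image of nanocage annuli.

    Each cage appears as a bright annulus whose *outer* diameter is the cage's
    true diameter (the stain outlines the particle boundary, which is what
    manual ellipse tracing measures); the ring extends ``ring_thickness`` nm
    inward and gets a mild area-preserving ellipticity jitter.  Edges are
    anti-aliased over one pixel; no PSF blur is applied (TEM at this
    magnification resolves the ring sharply).

    Returns ``(image, truth)`` where ``truth`` is a pandas DataFrame with one
    row per cage (center, true diameter, axis ratio).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=np.float64)
    rows = []
    if spec.n_cages > 0:
        extent = np.asarray(shape, float) * pixel_size
        margin = spec.diameter_mean + 4 * spec.diameter_sd
        centers = _jittered_grid(rng, spec.n_cages, extent, margin)
        diameters = spec.diameter_mean + spec.diameter_sd * rng.standard_normal(spec.n_cages)
        while np.any(diameters <= ring_thickness):
            bad = diameters <= ring_thickness
            diameters[bad] = spec.diameter_mean + spec.diameter_sd * rng.standard_normal(bad.sum())
        ratios = np.exp(rng.uniform(0.0, ellipticity_jitter, size=spec.n_cages))
        angles = rng.uniform(0.0, np.pi, size=spec.n_cages)

        occupied = spec.n_cages * np.pi * (spec.diameter_mean / 2) ** 2
        if occupied / float(np.prod(extent)) > density_warn:
            warnings.warn(
                "nanocage density high; overlapping cages likely", stacklevel=2
            )

        aa = pixel_size  # anti-aliasing width: one pixel
        for (cy, cx), dia, ratio, ang in zip(centers, diameters, ratios, angles):
            r_out = dia / 2.0
            a_out, b_out = r_out * np.sqrt(ratio), r_out / np.sqrt(ratio)
            pad = a_out + 2 * aa
            lo = np.maximum(((np.array([cy, cx]) - pad) / pixel_size).astype(int), 0)
            hi = np.minimum(((np.array([cy, cx]) + pad) / pixel_size).astype(int) + 2, shape)
            ys = (np.arange(lo[0], hi[0]) + 0.5) * pixel_size - cy
            xs = (np.arange(lo[1], hi[1]) + 0.5) * pixel_size - cx
            yy, xx = np.meshgrid(ys, xs, indexing="ij")
            c, s = np.cos(ang), np.sin(ang)
            u = c * xx + s * yy
            v = -s * xx + c * yy
            # elliptical radius: 1.0 on the outer boundary
            rho = np.sqrt((u / a_out) ** 2 + (v / b_out) ** 2)
            r_eff = rho * r_out  # approx metric distance along the ellipse normal
            outer = np.clip((r_out - r_eff) / aa + 0.5, 0.0, 1.0)
            inner = np.clip((r_eff - (r_out - ring_thickness)) / aa + 0.5, 0.0, 1.0)
            img[lo[0]:hi[0], lo[1]:hi[1]] += spec.intensity * outer * inner
            rows.append(
                {
                    "y_nm": cy,
                    "x_nm": cx,
                    "true_diameter_nm": dia,
                    "axis_ratio": ratio,
                    "angle_rad": ang,
                }
            )
    truth = pd.DataFrame(rows, columns=["y_nm", "x_nm", "true_diameter_nm", "axis_ratio", "angle_rad"])
    return img, truth
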