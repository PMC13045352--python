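"""Puncta segmentation and the descriptive statistics of endosomal sorting.

Operates on EF-calibrated volumes (voxel sizes in biological-scale nm) so
every size filter and distance is physical.  Provides: watershed-based
punctum segmentation, nearest-neighbor distances between channels,
volume/count ratios, moment-preserving (Tsai) auto-thresholding as used for
colocalization masks, Manders overlap percentages, chord-diagram tables, and
small arithmetic helpers (percent change, ellipse width).

Statistical hypothesis testing is deliberately out of scope: the functions
emit tidy per-observation tables for external tools and report descriptive
summaries only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .fixtures import FWHM_PER_SIGMA
from .volume import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "Punctum",
    "PunctaSet",
    "MandersResult",
    "ChordTable",
    "SegmentConfig",
    "segment_puncta",
    "nearest_neighbor_distances",
    "ratio_stats",
    "moments_threshold",
    "manders_percent",
    "chord_table",
    "percent_change",
    "ellipse_width",
]


@dataclass
class Punctum:
    """One segmented punctum: centroid (z,y,x nm), in-plane width, volume."""

    centroid_nm: tuple
    width_nm: float
    volume_nm3: float
    intensity: float
    channel: str = ""
    flags: str = ""

    def __post_init__(self):
        if self.width_nm <= 0:
            raise ValueError("punctum width must be positive")
        if self.volume_nm3 <= 0:
            raise ValueError("punctum volume must be at least one voxel")


@dataclass
class PunctaSet:
    puncta: list
    channel: str = ""

    def __len__(self):
        return len(self.puncta)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([p.centroid_nm for p in self.puncta]).reshape(-1, 3)

    @property
    def widths(self) -> np.ndarray:
        return np.array([p.width_nm for p in self.puncta])

    @property
    def volumes(self) -> np.ndarray:
        return np.array([p.volume_nm3 for p in self.puncta])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "channel": p.channel,
                    "z_nm": p.centroid_nm[0],
                    "y_nm": p.centroid_nm[1],
                    "x_nm": p.centroid_nm[2],
                    "width_nm": p.width_nm,
                    "volume_nm3": p.volume_nm3,
                    "intensity": p.intensity,
                    "flags": p.flags,
                }
                for p in self.puncta
            ]
        )


@dataclass
class MandersResult:
    """Directional overlap percentages between two thresholded channels.

    ``percent_a_in_b`` is 100 * |maskA & maskB| / |maskA| (None when maskA is
    empty: undefined, not zero).  Thresholds and mask pixel counts are stored
    so the percentages are exactly recomputable.
    """

    percent_a_in_b: float | None
    percent_b_in_a: float | None
    threshold_a: float
    threshold_b: float
    n_a: int
    n_b: int
    n_overlap: int

    def to_dict(self) -> dict:
        return {
            "percent_a_in_b": self.percent_a_in_b,
            "percent_b_in_a": self.percent_b_in_a,
            "threshold_a": self.threshold_a,
            "threshold_b": self.threshold_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_overlap": self.n_overlap,
        }


@dataclass
class ChordTable:
    """Arc fractions per marker plus all directed colocalization percentages."""

    arc_fractions: dict
    pair_percent: dict  # (source, target) -> percent of source overlapping target

    def __post_init__(self):
        total = sum(self.arc_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("arc fractions must sum to 1")

    def to_frame(self):
        import pandas as pd

        rows = [
            {"source": s, "target": t, "percent": p} for (s, t), p in self.pair_percent.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentConfig:
    """Watershed segmentation parameters (all sizes in physical nm)."""

    background_radius_nm: float = 200.0
    seed_fwhm_nm: float = 60.0
    min_separation_nm: float | None = None  # default: seed_fwhm_nm
    k_mad: float = 5.0
    min_volume_nm3: float = 1e3
    max_volume_nm3: float = 1e8
    min_solidity: float = 0.65


def segment_puncta(vol: ImageVolume, cfg: SegmentConfig = SegmentConfig(), channel=0) -> PunctaSet:
    """Segment puncta in a calibrated volume.

    Pipeline: rolling-ball-style background subtraction (grayscale opening
    with a ball of ``background_radius_nm``) -> smoothed local maxima above
    ``median + k_mad * MAD`` as seeds -> seeded watershed on the inverted
    intensity, masked to the above-threshold region -> physical size filter.
    Regions whose low solidity suggests merged puncta are flagged.
    """
    from skimage.morphology import ball
    from skimage.segmentation import watershed
    from skimage.feature import peak_local_max

    data = np.asarray(vol.channel(channel), float)
    voxel = vol.voxel_size
    ch_name = (
        vol.channel_names[channel]
        if vol.channel_names and isinstance(channel, int) and channel < len(vol.channel_names)
        else (channel if isinstance(channel, str) else "")
    )

    r_vox = max(int(round(cfg.background_radius_nm / min(voxel))), 1)
    if r_vox <= 12:
        selem = ball(r_vox)
        background = ndi.grey_opening(data, footprint=selem)
    else:  # large structuring elements: separable approximation
        background = ndi.minimum_filter(data, size=2 * r_vox + 1)
        background = ndi.maximum_filter(background, size=2 * r_vox + 1)
    img = data - background

    sig = [cfg.seed_fwhm_nm / FWHM_PER_SIGMA / v for v in voxel]
    smooth = ndi.gaussian_filter(img, sig)
    med = np.median(smooth)
    mad = np.median(np.abs(smooth - med))
    floor = med + cfg.k_mad * 1.4826 * mad
    if mad <= 1e-9 * max(float(smooth.max()), 1e-30) or (smooth > floor).mean() > 0.25:
        # MAD degenerates on near-empty or heavily smoothed backgrounds;
        # fall back to Otsu rather than flooding the mask
        from skimage.filters import threshold_otsu

        floor = threshold_otsu(smooth)
    sep_nm = cfg.min_separation_nm if cfg.min_separation_nm is not None else cfg.seed_fwhm_nm
    min_dist = max(int(round(sep_nm / max(voxel[1], voxel[2]))), 1)
    seeds = peak_local_max(smooth, min_distance=min_dist, threshold_abs=floor, exclude_border=False)
    if len(seeds) == 0:
        logger.info("segment_puncta: no seeds above threshold; returning empty set")
        return PunctaSet([], channel=ch_name)

    markers = np.zeros(data.shape, dtype=int)
    for i, s in enumerate(seeds, start=1):
        markers[tuple(s)] = i
    mask = smooth > floor
    labels = watershed(-smooth, markers=markers, mask=mask)

    voxel_vol = float(np.prod(voxel))
    puncta = []
    for sl, lab in zip(ndi.find_objects(labels), range(1, labels.max() + 1)):
        if sl is None:
            continue
        region = labels[sl] == lab
        vol_nm3 = region.sum() * voxel_vol
        if not (cfg.min_volume_nm3 <= vol_nm3 <= cfg.max_volume_nm3):
            continue
        w = np.where(region, img[sl], 0.0)
        tot = w.sum()
        if tot <= 0:
            continue
        zz, yy, xx = np.meshgrid(
            *[np.arange(s.start, s.stop) for s in sl], indexing="ij"
        )
        cz = float((w * zz).sum() / tot)
        cy = float((w * yy).sum() / tot)
        cx = float((w * xx).sum() / tot)
        centroid = ((cz + 0.5) * voxel[0], (cy + 0.5) * voxel[1], (cx + 0.5) * voxel[2])

        # in-plane width on the brightest z-plane: intensity-weighted second
        # moments -> FWHM-equivalent extent, averaged over major/minor
        zplane = int(np.clip(round(cz - sl[0].start), 0, region.shape[0] - 1))
        wp = w[zplane]
        if wp.sum() > 0:
            ys, xs = np.meshgrid(np.arange(wp.shape[0]), np.arange(wp.shape[1]), indexing="ij")
            tp = wp.sum()
            my = (wp * ys).sum() / tp
            mx = (wp * xs).sum() / tp
            cyy = (wp * (ys - my) ** 2).sum() / tp
            cxx = (wp * (xs - mx) ** 2).sum() / tp
            cyx = (wp * (ys - my) * (xs - mx)).sum() / tp
            lam = np.clip(np.linalg.eigvalsh(np.array([[cyy, cyx], [cyx, cxx]])), 1 / 12, None)
            extents = FWHM_PER_SIGMA * np.sqrt(lam) * np.array([voxel[1], voxel[2]])
            width = float(extents.mean())
        else:
            width = float(min(voxel[1], voxel[2]))

        flags = ""
        hull_vox = _region_solidity(region)
        if hull_vox < cfg.min_solidity:
            flags = "low_solidity"  # likely merged puncta
        puncta.append(
            Punctum(centroid, width, vol_nm3, float(tot), channel=str(ch_name), flags=flags)
        )
    return PunctaSet(puncta, channel=str(ch_name))


def _region_solidity(region: np.ndarray) -> float:
    """Voxel solidity of a 3D region via its convex hull (1.0 for compact blobs)."""
    from scipy.spatial import ConvexHull, Delaunay

    pts = np.argwhere(region)
    if len(pts) < 5:
        return 1.0
    try:
        hull = Delaunay(pts[ConvexHull(pts).vertices])
    except Exception:
        return 1.0
    bbox = [np.arange(region.shape[i]) for i in range(3)]
    zz, yy, xx = np.meshgrid(*bbox, indexing="ij")
    grid = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], 1)
    inside = hull.find_simplex(grid) >= 0
    n_hull = inside.sum()
    return float(region.sum()) / float(max(n_hull, 1))


# ---------------------------------------------------------------------------
# distances and ratios
# ---------------------------------------------------------------------------

def nearest_neighbor_distances(source, target) -> np.ndarray:
    """3D centroid-to-centroid distance (nm) from each source punctum to its
    nearest target punctum.  Asymmetric by design (source -> target)."""
    from scipy.spatial import cKDTree

    src = source.centroids if isinstance(source, PunctaSet) else np.atleast_2d(np.asarray(source, float))
    tgt = target.centroids if isinstance(target, PunctaSet) else np.atleast_2d(np.asarray(target, float))
    if len(tgt) == 0:
        raise ValueError("target set is empty; nearest-neighbor distance undefined")
    if len(src) == 0:
        return np.empty(0)
    d, _ = cKDTree(tgt).query(src, k=1)
    return np.asarray(d, float)


def ratio_stats(a, b) -> dict:
    """Total-volume and count ratios of channel a over channel b."""
    vol_a = a.volumes.sum() if len(a) else 0.0
    vol_b = b.volumes.sum() if len(b) else 0.0
    if len(b) == 0 or vol_b <= 0:
        raise ValueError("channel b has no puncta; ratios undefined")
    return {"volume_ratio": float(vol_a / vol_b), "count_ratio": len(a) / len(b)}


# ---------------------------------------------------------------------------
# thresholding and colocalization
# ---------------------------------------------------------------------------

def _quantize_8bit(image: np.ndarray):
    """Map an arbitrary-range image onto 0..255 integer levels (as histogram-
    based auto-thresholds conventionally operate on 8-bit data)."""
    img = np.asarray(image, float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise ValueError("constant image: threshold undefined")
    q = np.clip(np.round((img - lo) / (hi - lo) * 255.0), 0, 255).astype(int)
    return q, lo, hi


def moments_threshold(image: np.ndarray) -> float:
    """Moment-preserving (Tsai) threshold on the 8-bit-quantized histogram.

    The gray-level histogram's first three moments determine a two-level
    (binary) image with identical moments; its below-threshold fraction p0
    has a closed form, and the threshold is the 8-bit level whose cumulative
    histogram fraction best matches p0.  Returns the threshold on the
    original intensity scale; pixels strictly above it are foreground.
    """
    q, lo, hi = _quantize_8bit(image)
    hist = np.bincount(q.ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    levels = np.arange(256, dtype=float)
    m1 = (p * levels).sum()
    m2 = (p * levels**2).sum()
    m3 = (p * levels**3).sum()

    cd = m2 - m1 * m1
    if cd <= 0:
        raise ValueError("degenerate histogram: threshold undefined")
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise ValueError("degenerate histogram: threshold undefined")
    p0 = (z1 - m1) / (z1 - z0)  # target below-threshold fraction

    cum = np.cumsum(p)
    t8 = int(np.argmin(np.abs(cum - p0)))
    # represent the cut between quantized levels t8 and t8+1 on the original
    # scale, so the threshold separates the classes strictly
    return lo + (t8 + 0.5) / 255.0 * (hi - lo)


def manders_percent(vol_a, vol_b, threshold_fn=moments_threshold) -> MandersResult:
    """Manders overlap percentages with auto-thresholded masks.

    Masks are built per channel by ``threshold_fn`` (moment-preserving by
    default); ``percent_a_in_b = 100 |A & B| / |A|``.  An empty mask makes
    that direction undefined (None), never 0.
    """
    a = np.asarray(vol_a.data if isinstance(vol_a, ImageVolume) else vol_a, float)
    b = np.asarray(vol_b.data if isinstance(vol_b, ImageVolume) else vol_b, float)
    if a.shape != b.shape:
        raise ValueError("channels must share a grid")
    ta = threshold_fn(a)
    tb = threshold_fn(b)
    mask_a = a > ta
    mask_b = b > tb
    n_a = int(mask_a.sum())
    n_b = int(mask_b.sum())
    n_ab = int((mask_a & mask_b).sum())
    return MandersResult(
        percent_a_in_b=100.0 * n_ab / n_a if n_a else None,
        percent_b_in_a=100.0 * n_ab / n_b if n_b else None,
        threshold_a=float(ta),
        threshold_b=float(tb),
        n_a=n_a,
        n_b=n_b,
        n_overlap=n_ab,
    )


def chord_table(occupancy: dict, coloc: dict) -> ChordTable:
    """Build the chord-diagram table: arcs proportional to marker occupancy,
    chords carrying directed colocalization percentages.

    ``occupancy`` maps marker -> percent pixel occupancy (> 0); ``coloc``
    maps ordered (source, target) pairs -> percent of source overlapping
    target, and must contain every ordered pair of distinct markers.
    """
    markers = sorted(occupancy)
    for m, occ in occupancy.items():
        if occ <= 0:
            raise ValueError(f"marker {m!r} has non-positive occupancy")
    missing = [
        (s, t) for s in markers for t in markers if s != t and (s, t) not in coloc
    ]
    if missing:
        raise ValueError(f"missing colocalization pairs: {missing}")
    total = sum(occupancy.values())
    arcs = {m: occupancy[m] / total for m in markers}
    pairs = {(s, t): float(coloc[(s, t)]) for s in markers for t in markers if s != t}
    return ChordTable(arcs, pairs)


def percent_change(before: float, after: float) -> float:
    """100 * (after - before) / before."""
    if before == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return 100.0 * (after - before) / before


def ellipse_width(major: float, minor: float) -> float:
    """Width of a manually fitted ellipse: the mean of its two axes."""
    if minor > major:
        logger.warning("ellipse_width: axes given in (minor, major) order; swapping")
        major, minor = minor, major
    if minor <= 0:
        raise ValueError("axes must be positive")
    return 0.5 * (major + minor)
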