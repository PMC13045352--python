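"""Pre/post-expansion volume registration by iterative block matching.

The pre-ExM volume is first rescaled by the macroscopic expansion factor
(``init_scale``), globally shifted by phase correlation, then refined by
iterating: warp the pre volume with the current transform, match blocks of
the warped volume against the post volume by normalized cross-correlation,
and fit a similarity transform (isotropic scale + rotation + translation) to
the retained block correspondences by least squares with one round of
2.5 x MAD outlier rejection.  The similarity family is deliberate: removing
only global scale and pose leaves local distortion in the residual flow,
which is the downstream measurand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import match_template
from skimage.registration import phase_cross_correlation

from .volume import ImageVolume, index_to_phys

__all__ = [
    "AffineTransform3D",
    "BlockMatchConfig",
    "estimate_transform",
    "resample_to_reference",
    "fit_similarity",
]


@dataclass
class AffineTransform3D:
    """4x4 homogeneous transform acting on physical (z,y,x) nm coordinates."""

    matrix: np.ndarray
    provenance: str = "estimated"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1]):
            raise ValueError("last row must be (0,0,0,1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("transform is singular")

    @classmethod
    def identity(cls) -> "AffineTransform3D":
        return cls(np.eye(4), provenance="identity")

    @classmethod
    def similarity(cls, scale=1.0, rotation=None, translation=(0, 0, 0), provenance="composed"):
        m = np.eye(4)
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        m[:3, :3] = scale * R
        m[:3, 3] = translation
        return cls(m, provenance=provenance)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform3D":
        return AffineTransform3D(np.linalg.inv(self.matrix), provenance=f"inverse({self.provenance})")

    def compose(self, other: "AffineTransform3D") -> "AffineTransform3D":
        """self after other: (self @ other)(x) = self(other(x))."""
        return AffineTransform3D(self.matrix @ other.matrix, provenance="composed")

    @property
    def scale(self) -> float:
        """Isotropic scale for similarity transforms (cube root of |det|)."""
        return float(np.abs(np.linalg.det(self.matrix[:3, :3])) ** (1.0 / 3.0))

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3].copy()

    def to_json(self, path=None) -> str:
        payload = {
            "matrix_row_major": self.matrix.tolist(),
            "units": "nm (physical z,y,x coordinates, voxel centers at (i+0.5)*voxel_size)",
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "AffineTransform3D":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else source)
        return cls(np.asarray(payload["matrix_row_major"]), payload.get("provenance", "loaded"))


@dataclass(frozen=True)
class BlockMatchConfig:
    """Parameters of the iterative block matcher (voxel units on the post grid)."""

    block_size: int = 32
    stride: int = 16
    search_radius: int = 8
    min_correlation: float = 0.3
    max_iterations: int = 5
    tolerance_nm: float = 0.5
    min_block_std: float = 1e-3

    def __post_init__(self):
        if self.block_size < 8:
            raise ValueError("block_size must be >= 8 voxels per axis")
        if not 0.0 <= self.min_correlation <= 1.0:
            raise ValueError("min_correlation must be in [0, 1]")


def fit_similarity(src: np.ndarray, dst: np.ndarray, weights=None):
    """Least-squares similarity transform mapping src -> dst (Umeyama 1991).

    Returns ``(scale, R, t)`` with dst ~ scale * R @ src + t.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if len(src) < 4:
        raise ValueError("need at least 4 correspondences to fit a similarity transform")
    w = np.ones(len(src)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mu_s = (w[:, None] * src).sum(0)
    mu_d = (w[:, None] * dst).sum(0)
    sc = src - mu_s
    dc = dst - mu_d
    cov = (w[:, None, None] * dc[:, :, None] * sc[:, None, :]).sum(0)
    var_s = (w * (sc**2).sum(1)).sum()
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    scale = np.trace(np.diag(S) @ D) / var_s
    t = mu_d - scale * R @ mu_s
    return float(scale), R, t


def _subvoxel_peak(ncc: np.ndarray, peak: tuple) -> np.ndarray:
    """Parabolic refinement of an argmax, per axis, within +-0.5 voxel."""
    offset = np.zeros(3)
    for ax in range(3):
        i = peak[ax]
        if 0 < i < ncc.shape[ax] - 1:
            idx = list(peak)
            idx[ax] = slice(i - 1, i + 2)
            y0, y1, y2 = ncc[tuple(idx)]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                offset[ax] = np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)
    return offset


def estimate_transform(
    pre: ImageVolume,
    post: ImageVolume,
    init_scale: float,
    cfg: BlockMatchConfig = BlockMatchConfig(),
):
    """Estimate the similarity transform mapping pre physical coordinates onto
    post physical coordinates.

    Returns ``(transform, diagnostics)``; diagnostics record per-iteration
    residual RMS (nm), retained block counts and correlations.  Raises
    ``RuntimeError`` when fewer than 4 block correspondences survive the
    correlation cutoff.
    """
    if init_scale <= 0:
        raise ValueError("init_scale must be positive")
    post_img = np.asarray(post.channel(0), float)
    pre_img = np.asarray(pre.channel(0), float)

    T = AffineTransform3D.similarity(scale=init_scale, provenance="init_scale")
    warped = _warp(pre_img, pre.voxel_size, T, post.spatial_shape, post.voxel_size)
    shift_vox, _, _ = phase_cross_correlation(post_img, warped, upsample_factor=10, normalization=None)
    shift_nm = np.asarray(shift_vox) * np.asarray(post.voxel_size)
    T = AffineTransform3D.similarity(translation=shift_nm).compose(T)
    T.provenance = "phase_correlation_init"

    diagnostics = {
        "residual_rms_nm": [],
        "n_blocks_retained": [],
        "mean_correlation": [],
        "converged": False,
    }
    b, s, r = cfg.block_size, cfg.stride, cfg.search_radius
    shape = np.asarray(post.spatial_shape)
    post_vs = np.asarray(post.voxel_size)

    starts = [np.arange(r, shape[ax] - b - r + 1, s) for ax in range(3)]
    if any(len(a) == 0 for a in starts):
        raise RuntimeError(
            "volume too small for the configured block size / search radius"
        )

    prev_rms = np.inf
    best_T = T
    for _ in range(cfg.max_iterations):
        warped = _warp(pre_img, pre.voxel_size, T, post.spatial_shape, post.voxel_size)
        src_pts, dst_pts, corrs = [], [], []
        for z0 in starts[0]:
            for y0 in starts[1]:
                for x0 in starts[2]:
                    block = warped[z0:z0 + b, y0:y0 + b, x0:x0 + b]
                    if block.std() <= cfg.min_block_std:
                        continue  # flat block: no matchable structure
                    region = post_img[z0 - r:z0 + b + r, y0 - r:y0 + b + r, x0 - r:x0 + b + r]
                    if region.std() <= cfg.min_block_std:
                        continue
                    ncc = match_template(region, block)
                    peak = np.unravel_index(np.argmax(ncc), ncc.shape)
                    cmax = float(ncc[peak])
                    if cmax < cfg.min_correlation:
                        continue
                    delta_vox = np.asarray(peak, float) - r + _subvoxel_peak(ncc, peak)
                    center_idx = np.array([z0, y0, x0], float) + (b - 1) / 2.0
                    center_phys = index_to_phys(center_idx, post.voxel_size)
                    dst_pts.append(center_phys + delta_vox * post_vs)
                    src_pts.append(T.inverse().apply(center_phys)[0])
                    corrs.append(cmax)
        if len(src_pts) < 4:
            raise RuntimeError(
                f"only {len(src_pts)} block correspondences above the correlation "
                f"cutoff {cfg.min_correlation}; cannot fit a similarity transform"
            )
        src_pts = np.asarray(src_pts)
        dst_pts = np.asarray(dst_pts)
        corrs = np.asarray(corrs)

        resid = dst_pts - T.apply(src_pts)
        rms = float(np.sqrt((resid**2).sum(1).mean()))
        if rms > prev_rms:  # keep residual series monotone; revert and stop
            break
        diagnostics["residual_rms_nm"].append(rms)
        diagnostics["n_blocks_retained"].append(int(len(src_pts)))
        diagnostics["mean_correlation"].append(float(corrs.mean()))
        best_T = T
        prev_rms = rms

        scale, R, t = fit_similarity(src_pts, dst_pts, weights=corrs)
        err = np.linalg.norm(dst_pts - (scale * src_pts @ R.T + t), axis=1)
        mad = np.median(np.abs(err - np.median(err)))
        keep = err <= np.median(err) + 2.5 * max(mad, 1e-9)
        if keep.sum() >= 4:
            scale, R, t = fit_similarity(src_pts[keep], dst_pts[keep], weights=corrs[keep])
        T = AffineTransform3D.similarity(scale=scale, rotation=R, translation=t,
                                         provenance="block_match")
        best_T = T
        if rms < cfg.tolerance_nm:
            diagnostics["converged"] = True
            break

    diagnostics["final_residual_nm"] = diagnostics["residual_rms_nm"][-1] if diagnostics["residual_rms_nm"] else None
    return best_T, diagnostics


def _warp(img, src_voxel, T: AffineTransform3D, out_shape, out_voxel):
    """Sample img (on src grid) through T onto the output grid (trilinear)."""
    inv = T.inverse().matrix
    grids = np.meshgrid(*[(np.arange(n) + 0.5) * v for n, v in zip(out_shape, out_voxel)], indexing="ij")
    phys = np.stack([g.ravel() for g in grids], axis=1)
    src_phys = phys @ inv[:3, :3].T + inv[:3, 3]
    coords = (src_phys / np.asarray(src_voxel) - 0.5).T.reshape(3, *out_shape)
    return ndi.map_coordinates(img, coords, order=1, mode="constant", cval=0.0)


def resample_to_reference(vol: ImageVolume, t: AffineTransform3D, reference: ImageVolume):
    """Resample ``vol`` through ``t`` onto the reference grid.

    Trilinear interpolation; voxels mapping outside the source domain are set
    to 0 and marked invalid in the returned mask.

    Returns ``(resampled ImageVolume, validity mask)``.
    """
    inv = t.inverse().matrix
    out_shape = reference.spatial_shape
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * v for n, v in zip(out_shape, reference.voxel_size)],
        indexing="ij",
    )
    phys = np.stack([g.ravel() for g in grids], axis=1)
    src_phys = phys @ inv[:3, :3].T + inv[:3, 3]
    coords = (src_phys / np.asarray(vol.voxel_size) - 0.5).T.reshape(3, *out_shape)

    src_shape = np.asarray(vol.spatial_shape)
    valid = np.ones(out_shape, dtype=bool)
    for ax in range(3):
        valid &= (coords[ax] >= 0) & (coords[ax] <= src_shape[ax] - 1)

    channels = []
    data = vol.data if vol.data.ndim == 4 else vol.data[None]
    for ch in data:
        channels.append(ndi.map_coordinates(np.asarray(ch, float), coords, order=1,
                                            mode="constant", cval=0.0))
    out = np.stack(channels) if vol.data.ndim == 4 else channels[0]
    meta = dict(vol.metadata)
    meta["resampled_through"] = t.provenance
    return ImageVolume(out.astype(np.float32), reference.voxel_size, vol.channel_names, meta), valid
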