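"""Projective registration of visible and thermal images.

The two sensors of a dual thermal/visible camera do not share a pixel grid:
resolutions differ and the optical axes are offset. Given manually annotated
corresponding points, a 3x3 homography mapping visible-image coordinates to
thermal-image coordinates is estimated by normalized least squares (Hartley's
normalized direct linear transform). Binary canopy masks segmented in the
visible image are then carried into thermal coordinates by inverse-mapped
nearest-neighbour warping, so the mask stays strictly binary.

Coordinate convention (binding package-wide): 0-based (row, col) with the
origin at the top-left; homographies act on homogeneous (col, row, 1) triples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PointCorrespondences",
    "estimate_homography",
    "apply_homography",
    "warp_mask",
    "read_correspondences",
    "write_correspondences",
]

#: Relative threshold below which the homogeneous coordinate w is treated as 0.
_W_TOL = 1e-12


@dataclass(frozen=True)
class PointCorrespondences:
    """Annotated matching points between the visible and thermal image.

    Parameters
    ----------
    src : (N, 2) float array
        (col, row) positions in the visible image.
    dst : (N, 2) float array
        (col, row) positions in the thermal image.

    At least four pairs are required. With exactly four, no three source
    points may be collinear (within a tolerance scaled by the point spread)
    or the projective transform is not determined; with more points,
    collinear triples are harmless and only full collinearity of the set is
    rejected here — residual degeneracy is caught by the estimator's
    singular-value check.
    """

    src: np.ndarray
    dst: np.ndarray

    def __post_init__(self):
        src = np.asarray(self.src, dtype=float)
        dst = np.asarray(self.dst, dtype=float)
        if src.ndim != 2 or src.shape[1] != 2 or src.shape != dst.shape:
            raise ValueError("src and dst must both be (N, 2) arrays of equal shape")
        if len(src) < 4:
            raise ValueError(f"at least 4 point correspondences required, got {len(src)}")
        if not (np.isfinite(src).all() and np.isfinite(dst).all()):
            raise ValueError("correspondences must be finite")
        if len(src) == 4:
            _check_not_collinear(src, "src")
        else:
            _check_not_all_collinear(src, "src")
        object.__setattr__(self, "src", src)
        object.__setattr__(self, "dst", dst)

    def __len__(self) -> int:
        return len(self.src)


def _check_not_collinear(pts: np.ndarray, name: str) -> None:
    """Reject point sets in which any three points are (nearly) collinear."""
    n = len(pts)
    scale = max(np.ptp(pts, axis=0).max(), 1.0)
    tol = 1e-8 * scale * scale
    for i in range(n - 2):
        rest = pts[i + 1:] - pts[i]
        for j in range(len(rest) - 1):
            c = rest[j + 1:]
            # twice the triangle area spanned by (a, b, c); ~0 means collinear
            area = np.abs(rest[j, 0] * c[:, 1] - rest[j, 1] * c[:, 0])
            if (area < tol).any():
                raise ValueError(f"three {name} points are collinear within tolerance")


def _check_not_all_collinear(pts: np.ndarray, name: str) -> None:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError(f"{name} points are all collinear; homography undetermined")


def _normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity T centering pts and scaling mean distance to sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean()
    if d <= 0:
        raise ValueError("degenerate correspondences: coincident points")
    s = np.sqrt(2.0) / d
    return np.array(
        [[s, 0.0, -s * centroid[0]], [0.0, s, -s * centroid[1]], [0.0, 0.0, 1.0]]
    )


def estimate_homography(pts: PointCorrespondences) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares projective transform from annotated correspondences.

    Uses the normalized direct linear transform: both point sets are centred
    and isotropically scaled to mean distance sqrt(2); the 2N x 9 design
    matrix is assembled; the solution is the right singular vector belonging
    to the smallest singular value; the result is denormalized and scaled to
    H[2, 2] = 1.

    Returns
    -------
    H : (3, 3) ndarray
        Homography mapping src (visible) to dst (thermal) coordinates.
    residuals : (N,) ndarray
        Per-point Euclidean reprojection error in dst pixels.
    """
    if not isinstance(pts, PointCorrespondences):
        raise TypeError("pts must be a PointCorrespondences")
    Ts = _normalization(pts.src)
    Td = _normalization(pts.dst)
    src_n = _to_homogeneous(pts.src) @ Ts.T
    dst_n = _to_homogeneous(pts.dst) @ Td.T

    n = len(pts)
    A = np.zeros((2 * n, 9))
    u, v = src_n[:, 0], src_n[:, 1]
    up, vp = dst_n[:, 0], dst_n[:, 1]
    A[0::2, 3:6] = -np.column_stack([u, v, np.ones(n)])
    A[0::2, 6:9] = np.column_stack([vp * u, vp * v, vp])
    A[1::2, 0:3] = np.column_stack([u, v, np.ones(n)])
    A[1::2, 6:9] = np.column_stack([-up * u, -up * v, -up])

    _, s, Vt = np.linalg.svd(A)
    # A degenerate configuration leaves the nullspace >1-dimensional: the two
    # smallest singular values collapse together toward zero.
    if s[-2] <= max(1e-12, 1e-9 * s[0]):
        raise ValueError(
            "degenerate point configuration: homography not uniquely determined "
            "(two near-zero singular values in the DLT system)"
        )
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    if abs(H[2, 2]) < 1e-15:
        raise ValueError("estimated homography has H[2,2] ~ 0; cannot normalize")
    H = H / H[2, 2]
    residuals = np.sqrt(((apply_homography(H, pts.src) - pts.dst) ** 2).sum(axis=1))
    return H, residuals


def _to_homogeneous(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    return np.column_stack([points, np.ones(len(points))])


def apply_homography(H: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map (col, row) points through H with perspective division.

    Raises if any point maps to (or near) the plane at infinity.
    """
    H = np.asarray(H, dtype=float)
    if H.shape != (3, 3):
        raise ValueError("H must be 3x3")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(points).all():
        raise ValueError("points must be finite")
    ph = _to_homogeneous(points) @ H.T
    w = ph[:, 2]
    bad = np.abs(w) < _W_TOL * max(1.0, np.abs(ph).max())
    if bad.any():
        raise ValueError(
            f"points {np.nonzero(bad)[0].tolist()} map to the plane at infinity (w ~ 0)"
        )
    return ph[:, :2] / w[:, None]


def warp_mask(mask: np.ndarray, H: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Warp a binary mask into the thermal grid defined by ``out_shape``.

    Inverse mapping with nearest-neighbour sampling keeps the output strictly
    binary; output pixels whose pre-image falls outside the mask domain are
    False.
    """
    mask = np.asarray(mask, dtype=bool)
    H = np.asarray(H, dtype=float)
    if abs(np.linalg.det(H)) < 1e-12:
        raise ValueError("homography is not invertible")
    Hinv = np.linalg.inv(H)
    h_out, w_out = out_shape
    rr, cc = np.meshgrid(np.arange(h_out), np.arange(w_out), indexing="ij")
    pts = np.column_stack([cc.ravel(), rr.ravel()])  # (col, row)
    src = apply_homography(Hinv, pts)
    col = np.rint(src[:, 0]).astype(int)
    row = np.rint(src[:, 1]).astype(int)
    inside = (row >= 0) & (row < mask.shape[0]) & (col >= 0) & (col < mask.shape[1])
    out = np.zeros(h_out * w_out, dtype=bool)
    out[inside] = mask[row[inside], col[inside]]
    return out.reshape(h_out, w_out)


def read_correspondences(path) -> PointCorrespondences:
    """Load correspondences from CSV with header src_col,src_row,dst_col,dst_row."""
    df = pd.read_csv(path)
    required = ["src_col", "src_row", "dst_col", "dst_row"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"correspondence file {path} missing columns {missing}")
    return PointCorrespondences(
        src=df[["src_col", "src_row"]].to_numpy(float),
        dst=df[["dst_col", "dst_row"]].to_numpy(float),
    )


def write_correspondences(path, pts: PointCorrespondences) -> None:
    pd.DataFrame(
        {
            "src_col": pts.src[:, 0],
            "src_row": pts.src[:, 1],
            "dst_col": pts.dst[:, 0],
            "dst_row": pts.dst[:, 1],
        }
    ).to_csv(path, index=False)
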