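"""Arterial residual strain: longitudinal pre-stretch and ring opening angle.

Longitudinal residual strain is quantified by the axial pre-stretch map: the
artery is marked equidistantly in situ, excised, allowed to retract, and the
per-segment stretch λ = (in-situ distance)/(ex-vivo distance) is computed and
binned into proximal/middle/distal thirds.

Circumferential residual strain is quantified by the ring-opening test: a
radially cut ring springs open and the opening angle α is the interior angle
at the midpoint of the opened ring's perimeter between the rays to the two
cut ends.  Under this convention an unopened ring gives α → 0° and a ring
that opens into a flat strip gives α = 180°.

Measurement repeatability (three angle readings per ring image) is summarized
by per-sample standard deviations and Cronbach's alpha across the replicate
positions.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MarkerTrace",
    "PrestretchMap",
    "RingContour",
    "OpeningAngleResult",
    "ReliabilityReport",
    "compute_prestretch",
    "opening_angle",
    "opening_angle_from_image",
    "cronbach_alpha",
    "repeatability",
]

REGIONS = ("proximal", "middle", "distal")


def _points_array(points, name="points") -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"{name} must be an (n, 2) array")
    return pts


@dataclass
class MarkerTrace:
    """Ordered 2-D marker coordinates (µm, after scale calibration)."""

    points: np.ndarray
    scale: float = 1.0
    label: str = ""

    def __post_init__(self):
        self.points = _points_array(self.points)
        if len(self.points) < 2:
            raise ValueError("points must contain at least 2 markers")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("points must not contain consecutive duplicates")

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)


@dataclass
class PrestretchMap:
    segment_lambdas: np.ndarray
    region_bins: list
    region_means: dict


@dataclass
class RingContour:
    """Ordered midline points (µm) of a (cut) ring."""

    points: np.ndarray
    closed: bool = False

    def __post_init__(self):
        self.points = _points_array(self.points)
        if len(self.points) < 10:
            raise ValueError("contour must contain at least 10 points")
        if self.arc_lengths().sum() <= 0:
            raise ValueError("contour has zero arc length")

    def arc_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)


@dataclass
class OpeningAngleResult:
    alpha: float
    endpoint_1: np.ndarray
    endpoint_2: np.ndarray
    perimeter_midpoint: np.ndarray
    replicate_alphas: Optional[np.ndarray] = None


@dataclass
class ReliabilityReport:
    per_sample_sd: np.ndarray
    max_sd: float
    min_sd: float
    cronbach_alpha: Optional[float]
    n_samples: int
    n_items: int
    alpha_available: bool = True


def _region_of(position: float) -> str:
    """Bin a normalized position into thirds (0–33.3 / 33.6–66.6 / 66.6–100%).

    Positions falling in the 33.3–33.6% gap are assigned to the middle third.
    """
    if position <= 0.333:
        return "proximal"
    if position <= 0.666:
        return "middle"
    return "distal"


def compute_prestretch(in_situ: MarkerTrace, ex_vivo: MarkerTrace) -> PrestretchMap:
    """Per-segment axial pre-stretch λ = in-situ / ex-vivo marker distance.

    Both traces must carry the same markers in the same proximal→distal
    order.  Segments are binned into thirds by the normalized in-situ
    position of their midpoint.
    """
    if len(in_situ.points) != len(ex_vivo.points):
        raise ValueError("marker count mismatch between in-situ and ex-vivo traces")
    d_in = in_situ.segment_lengths()
    d_ex = ex_vivo.segment_lengths()
    if np.any(d_ex <= 0):
        raise ValueError("ex-vivo marker distances must be positive")
    lambdas = d_in / d_ex
    cum = np.concatenate([[0.0], np.cumsum(d_in)])
    total = cum[-1]
    mids = (cum[:-1] + cum[1:]) / 2.0 / total
    bins = [_region_of(p) for p in mids]
    means = {}
    for region in REGIONS:
        vals = lambdas[[b == region for b in bins]]
        means[region] = float(np.mean(vals)) if len(vals) else float("nan")
    return PrestretchMap(lambdas, bins, means)


def opening_angle(contour: RingContour) -> OpeningAngleResult:
    """Opening angle of a cut ring from its ordered midline contour.

    The two rays run from the point at half the cumulative arc length (the
    perimeter midpoint) to the first and last contour points; α is their
    interior angle in degrees.
    """
    pts = contour.points
    if contour.closed or np.allclose(pts[0], pts[-1]):
        raise ValueError("contour is closed: ring has no cut")
    seg = contour.arc_lengths()
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half, side="right")) - 1
    i = min(i, len(seg) - 1)
    t = (half - cum[i]) / seg[i]
    mid = pts[i] * (1 - t) + pts[i + 1] * t
    u = pts[0] - mid
    v = pts[-1] - mid
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("degenerate contour: perimeter midpoint coincides with an endpoint")
    cosang = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    alpha = float(np.degrees(np.arccos(cosang)))
    return OpeningAngleResult(alpha, pts[0].copy(), pts[-1].copy(), mid)


# ---------------------------------------------------------------------------
# image route: skeletonize the wall band, order it, delegate to opening_angle

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray):
    coords = [tuple(c) for c in np.argwhere(skel)]
    index = {c: i for i, c in enumerate(coords)}
    adj: list[list[int]] = [[] for _ in coords]
    for c, i in index.items():
        for dr, dc in _OFFSETS:
            j = index.get((c[0] + dr, c[1] + dc))
            if j is not None:
                adj[i].append(j)
    return coords, adj


def _bfs(adj, start):
    dist = {start: 0}
    parent = {start: None}
    q = deque([start])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                parent[v] = u
                q.append(v)
    return dist, parent


def _longest_endpoint_path(coords, adj):
    endpoints = [i for i, nb in enumerate(adj) if len(nb) == 1]
    if not endpoints:
        raise ValueError("no cut detected: skeleton has no free ends")
    best = None
    for s in endpoints:
        dist, parent = _bfs(adj, s)
        reach = [(d, n) for n, d in dist.items() if n in set(endpoints)]
        d, e = max(reach)
        if best is None or d > best[0]:
            best = (d, s, e, parent)
    _, s, e, parent = best
    path = []
    node = e
    while node is not None:
        path.append(node)
        node = parent[node]
    return [coords[i] for i in path]


def opening_angle_from_image(image: np.ndarray, pixel_size: float) -> OpeningAngleResult:
    """Opening angle from a binary raster of the opened ring's wall band.

    The band is skeletonized and the longest end-to-end skeleton path is used
    as the midline.  Skeletons fork slightly at the band's end caps, so half
    the estimated wall thickness is trimmed from each end of the path and the
    trimmed length is restored by extrapolating along the local tangent;
    the result is then delegated to :func:`opening_angle`.
    """
    from scipy import ndimage as ndi
    from skimage.morphology import skeletonize

    mask = np.asarray(image).astype(bool)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    labels, n_comp = ndi.label(mask)
    if n_comp == 0:
        raise ValueError("no wall band found in image")
    if n_comp > 1:
        sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        if np.sum(sizes > 0.05 * sizes.max()) > 1:
            raise ValueError("multiple connected components: expected a single wall band")
        mask = labels == (int(np.argmax(sizes)) + 1)
    skel = skeletonize(mask)
    coords, adj = _skeleton_graph(skel)
    path_px = np.asarray(_longest_endpoint_path(coords, adj), dtype=float)
    # (row, col) -> (x, y) in µm
    pts = np.column_stack([path_px[:, 1], path_px[:, 0]]) * pixel_size

    # trim skeleton end-cap artifacts and restore length along the tangent
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    thickness = mask.sum() * pixel_size**2 / max(cum[-1], pixel_size)
    trim = min(0.75 * thickness, 0.2 * cum[-1])

    def _trim_and_extend(p: np.ndarray) -> np.ndarray:
        s = np.linalg.norm(np.diff(p, axis=0), axis=1)
        c = np.concatenate([[0.0], np.cumsum(s)])
        keep = c >= trim
        if keep.sum() < 5:
            return p
        q = p[keep]
        cq = c[keep] - c[keep][0]
        # tangent from a PCA line fit over one wall thickness of path
        win = q[cq <= max(thickness, 5 * pixel_size)]
        if len(win) < 3:
            win = q[: min(5, len(q))]
        centered = win - win.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
        if np.dot(direction, q[0] - win.mean(axis=0)) < 0:
            direction = -direction
        # march along the tangent to the cut face of the band
        h, w = mask.shape
        step = pixel_size / 2.0
        t_max = 0.0
        t = step
        while t <= trim + 2.0 * thickness:
            probe = q[0] + direction * t
            col = int(round(probe[0] / pixel_size))
            row = int(round(probe[1] / pixel_size))
            if not (0 <= row < h and 0 <= col < w and mask[row, col]):
                break
            t_max = t
            t += step
        tip = q[0] + direction * t_max
        return np.vstack([tip, q])

    pts = _trim_and_extend(pts)
    pts = _trim_and_extend(pts[::-1])[::-1]
    return opening_angle(RingContour(pts))


# ---------------------------------------------------------------------------
# reliability


def cronbach_alpha(measurements) -> float:
    """Cronbach's alpha α_C = k/(k−1) · (1 − Σ var(item_i)/var(Σ items)).

    ``measurements`` is an (n_samples × k_items) matrix with no missing
    cells; sample variances (ddof=1) are used throughout.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be a 2-D matrix (samples x items)")
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if k < 2:
        raise ValueError("need at least 2 items")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not supported")
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total variance: Cronbach's alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def repeatability(replicate_alphas: Sequence[Sequence[float]]) -> ReliabilityReport:
    """Repeatability of replicated angle measurements.

    Each row holds the replicate angle readings of one ring sample.
    Cronbach's alpha is computed across replicate positions when at least
    two samples share the same replicate count; otherwise it is flagged
    unavailable.
    """
    rows = [np.asarray(r, dtype=float) for r in replicate_alphas]
    if len(rows) < 1:
        raise ValueError("need at least 1 sample")
    if any(len(r) < 2 for r in rows):
        raise ValueError("each sample needs at least 2 replicates")
    sds = np.array([r.std(ddof=1) for r in rows])
    k = len(rows[0])
    same_k = all(len(r) == k for r in rows)
    alpha: Optional[float] = None
    available = False
    if len(rows) >= 2 and same_k:
        try:
            alpha = cronbach_alpha(np.vstack(rows))
            available = True
        except ValueError:
            alpha = None
    return ReliabilityReport(
        per_sample_sd=sds,
        max_sd=float(sds.max()),
        min_sd=float(sds.min()),
        cronbach_alpha=alpha,
        n_samples=len(rows),
        n_items=k,
        alpha_available=available,
    )
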