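"""Ground-truth-labelled synthetic inputs for every analysis stage.

Each generator emulates one experimental record type — tensile
force/displacement series with the characteristic four-zone stress-stretch
shape, opened-ring midline contours and rasters with a prescribed opening
angle, in-situ/ex-vivo marker traces with prescribed per-segment
pre-stretch, sigmoid dose-response series, and stained-section phantoms with
prescribed nuclei and fiber content — and returns the exact ground truth
alongside, so every analysis operation is testable by parameter recovery.

All generators are deterministic for a fixed seed and exactly invertible by
their paired analysis operations when their noise parameter is zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon2mask

from .histology import HistologyImage, StainMatrix, default_evg_stains
from .residual import MarkerTrace, RingContour
from .tensile import MechanicalParameters, TensileRecord, four_zone_stress
from .vasoreactivity import DoseResponseData, hill_response

__all__ = [
    "TensileGroundTruth",
    "RingPhantom",
    "MarkerPhantom",
    "CCRCGroundTruth",
    "HistologyPhantom",
    "HistologyGroundTruth",
    "gen_tensile_record",
    "gen_tensile_cohort",
    "gen_ring_contour",
    "render_ring_image",
    "gen_marker_traces",
    "gen_ccrc",
    "gen_histology_image",
]


def _require(cond: bool, message: str):
    if not cond:
        raise ValueError(message)


# ---------------------------------------------------------------------------
# tensile curves


@dataclass
class TensileGroundTruth:
    """Generator parameters for one four-zone tensile curve.

    The noise model is additive Gaussian on stress by default
    (``noise_sd`` in kPa); with ``noise_mode="relative"`` the standard
    deviation is ``noise_sd × |σ|`` (a fractional noise level).
    """

    E1_true: float = 14.0
    E2_true: float = 3100.0
    lambda_a: float = 2.2
    lambda_b: float = 3.0
    lambda_r_true: float = 4.4
    l0: float = 20.0
    w0: float = 4.0
    e0: float = 0.4
    noise_sd: float = 0.0
    n_points: int = 500
    seed: int = 0
    noise_mode: str = "additive"

    def validate(self):
        _require(self.E1_true > 0, "E1_true must be positive")
        _require(self.E2_true > self.E1_true, "E2_true must exceed E1_true")
        _require(1.0 < self.lambda_a, "lambda_a must exceed 1")
        _require(self.lambda_a <= self.lambda_b, "lambda_b must be >= lambda_a")
        _require(self.lambda_b < self.lambda_r_true, "lambda_r_true must exceed lambda_b")
        for name in ("l0", "w0", "e0"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(self.noise_sd >= 0, "noise_sd must be non-negative")
        _require(self.n_points >= 20, "n_points must be at least 20")
        _require(self.noise_mode in ("additive", "relative"), "noise_mode must be 'additive' or 'relative'")


def _noise_free_stress(lam: np.ndarray, gt: TensileGroundTruth) -> np.ndarray:
    """Four-zone stress including the post-rupture drop."""
    sig = four_zone_stress(lam, gt.E1_true, gt.E2_true, gt.lambda_a, gt.lambda_b)
    lr = gt.lambda_r_true
    sigma_r = float(four_zone_stress(np.array([lr]), gt.E1_true, gt.E2_true, gt.lambda_a, gt.lambda_b)[0])
    # post-rupture: steep linear decay to 5% of sigma_r over 2% stretch
    width = 0.02 * lr
    post = lam > lr
    frac = np.clip((lam[post] - lr) / width, 0.0, 1.0)
    sig[post] = sigma_r * (1.0 - 0.95 * frac)
    return sig


def gen_tensile_record(gt: TensileGroundTruth) -> tuple[TensileRecord, MechanicalParameters]:
    """Generate a force/displacement record plus its exact parameter tuple.

    Ground-truth λt/σt use the midpoint transition definition; Et and Er are
    adaptive quadrature of the noise-free curve.  Forces are back-computed
    from stress through the incompressible Cauchy relation.
    """
    gt.validate()
    lam_end = gt.lambda_r_true * 1.04
    lam = np.linspace(1.0, lam_end, gt.n_points)
    sig = _noise_free_stress(lam, gt)
    rng = np.random.default_rng(gt.seed)
    if gt.noise_sd > 0:
        if gt.noise_mode == "additive":
            noisy = sig + rng.normal(0.0, gt.noise_sd, size=sig.shape)
        else:
            noisy = sig * (1.0 + rng.normal(0.0, gt.noise_sd, size=sig.shape))
    else:
        noisy = sig.copy()
    force = np.clip(noisy, 0.0, None) / 1000.0 * gt.w0 * gt.e0 / lam
    record = TensileRecord(
        l0=gt.l0,
        w0=gt.w0,
        e0=gt.e0,
        displacement=(lam - 1.0) * gt.l0,
        force=force,
        specimen_id=f"synthetic-seed{gt.seed}",
    )
    sigma_a = gt.E1_true * (gt.lambda_a - 1.0)
    if gt.lambda_b > gt.lambda_a:
        sigma_b = sigma_a + 0.5 * (gt.E1_true + gt.E2_true) * (gt.lambda_b - gt.lambda_a)
    else:
        sigma_b = sigma_a
    lam_t = 0.5 * (gt.lambda_a + gt.lambda_b)
    sig_t = 0.5 * (sigma_a + sigma_b)
    sigma_r = float(
        four_zone_stress(np.array([gt.lambda_r_true]), gt.E1_true, gt.E2_true, gt.lambda_a, gt.lambda_b)[0]
    )

    def f(x):
        return four_zone_stress(np.array([x]), gt.E1_true, gt.E2_true, gt.lambda_a, gt.lambda_b)[0]

    pts = sorted({p for p in (gt.lambda_a, gt.lambda_b) if 1.0 < p})
    Et = quad(f, 1.0, lam_t, points=[p for p in pts if p < lam_t], limit=200)[0]
    Er = quad(f, 1.0, gt.lambda_r_true, points=pts, limit=200)[0]
    truth = MechanicalParameters(
        E1=gt.E1_true,
        E2=gt.E2_true,
        lambda_t=lam_t,
        sigma_t=sig_t,
        lambda_r=gt.lambda_r_true,
        sigma_r=sigma_r,
        Et=float(Et),
        Er=float(Er),
        ruptured=True,
    )
    return record, truth


def gen_tensile_cohort(
    base: TensileGroundTruth,
    n_animals: int,
    biological_cv: float = 0.05,
    seed: int = 0,
) -> tuple[list[TensileRecord], list[MechanicalParameters]]:
    """A cohort of records with between-animal variation around group means.

    Each animal's moduli are multiplied by independent lognormal-like factors
    ``max(1 + cv·z, 0.2)``; curve-shape parameters are shared.  Per-animal
    seeds are spawned deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    records, truths = [], []
    for i in range(n_animals):
        f1 = max(1.0 + biological_cv * rng.standard_normal(), 0.2)
        f2 = max(1.0 + biological_cv * rng.standard_normal(), 0.2)
        gt = dataclasses.replace(
            base,
            E1_true=base.E1_true * f1,
            E2_true=max(base.E2_true * f2, base.E1_true * f1 * 1.5),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, truth = gen_tensile_record(gt)
        records.append(rec)
        truths.append(truth)
    return records, truths


# ---------------------------------------------------------------------------
# ring phantoms


@dataclass
class RingPhantom:
    """An opened aortic ring with prescribed opening angle.

    The midline arc length is preserved at the closed-ring circumference
    2π·mid_radius; the opened ring is a circular arc of central angle
    360° − 2·alpha_true (for alpha_true ≤ 180°; beyond that the arc formula
    switches sign and only the contour form is supported).  alpha_true = 180°
    is the flat-strip limit, alpha_true = 0° the unopened (closed) ring.
    """

    alpha_true: float = 90.0
    mid_radius: float = 800.0
    wall_thickness: float = 150.0
    points_per_contour: int = 400
    pixel_size: Optional[float] = 4.0
    jitter_sd: float = 0.0
    seed: int = 0

    def validate(self):
        _require(0.0 <= self.alpha_true < 360.0, "alpha_true must be in [0, 360)")
        _require(self.mid_radius > 0, "mid_radius must be positive")
        _require(self.wall_thickness > 0, "wall_thickness must be positive")
        _require(self.points_per_contour >= 10, "points_per_contour must be >= 10")
        _require(self.jitter_sd >= 0, "jitter_sd must be non-negative")


def _ring_midline(ph: RingPhantom, n: int) -> tuple[np.ndarray, bool]:
    length = 2.0 * np.pi * ph.mid_radius
    if ph.alpha_true <= 180.0:
        theta_c = 360.0 - 2.0 * ph.alpha_true
    else:
        theta_c = 2.0 * ph.alpha_true - 360.0
    closed = theta_c >= 360.0 - 1e-9
    if theta_c < 1e-9:
        x = np.linspace(-length / 2.0, length / 2.0, n)
        return np.column_stack([x, np.zeros(n)]), False
    theta_rad = np.radians(theta_c)
    radius = length / theta_rad
    ang = np.linspace(-theta_rad / 2.0, theta_rad / 2.0, n, endpoint=not closed)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)]), closed


def gen_ring_contour(ph: RingPhantom) -> tuple[RingContour, float]:
    """Ordered midline contour of the opened ring, with its true angle."""
    ph.validate()
    pts, closed = _ring_midline(ph, ph.points_per_contour)
    if ph.jitter_sd > 0:
        rng = np.random.default_rng(ph.seed)
        pts = pts + rng.normal(0.0, ph.jitter_sd, size=pts.shape)
    return RingContour(pts, closed=closed), ph.alpha_true


def render_ring_image(ph: RingPhantom) -> np.ndarray:
    """Binary raster of the wall band (True = tissue) at ph.pixel_size µm/px.

    Rendered analytically (radial distance from the midline arc, with flat
    end caps at the cut) so that a narrow cut is never bridged by cap
    rounding.
    """
    ph.validate()
    _require(ph.pixel_size is not None and ph.pixel_size > 0, "pixel_size must be set to render")
    ps = ph.pixel_size
    length = 2.0 * np.pi * ph.mid_radius
    half_w = ph.wall_thickness / 2.0
    if ph.alpha_true <= 180.0:
        theta_c = 360.0 - 2.0 * ph.alpha_true
    else:
        theta_c = 2.0 * ph.alpha_true - 360.0
    margin = half_w + 3 * ps

    if theta_c < 1e-9:
        # flat strip
        x0, x1 = -length / 2.0 - margin, length / 2.0 + margin
        y0, y1 = -margin, margin
        nx, ny = int(np.ceil((x1 - x0) / ps)), int(np.ceil((y1 - y0) / ps))
        xs = x0 + (np.arange(nx) + 0.5) * ps
        ys = y0 + (np.arange(ny) + 0.5) * ps
        gx, gy = np.meshgrid(xs, ys)
        return (np.abs(gy) <= half_w) & (np.abs(gx) <= length / 2.0)

    theta_rad = np.radians(theta_c)
    radius = length / theta_rad
    half_span = theta_rad / 2.0
    ang = np.linspace(-half_span, half_span, 256)
    bx = radius * np.cos(ang)
    by = radius * np.sin(ang)
    x0, x1 = bx.min() - margin, bx.max() + margin
    y0, y1 = by.min() - margin, by.max() + margin
    nx, ny = int(np.ceil((x1 - x0) / ps)), int(np.ceil((y1 - y0) / ps))
    xs = x0 + (np.arange(nx) + 0.5) * ps
    ys = y0 + (np.arange(ny) + 0.5) * ps
    gx, gy = np.meshgrid(xs, ys)
    rr = np.hypot(gx, gy)
    phi = np.arctan2(gy, gx)
    in_band = np.abs(rr - radius) <= half_w
    in_span = np.abs(phi) <= half_span if theta_rad < 2 * np.pi - 1e-12 else np.ones_like(phi, bool)
    return in_band & in_span


# ---------------------------------------------------------------------------
# marker traces


@dataclass
class MarkerPhantom:
    """Equidistant ex-vivo markers and their stretched in-situ counterparts."""

    n_segments: int = 3
    lambda_true: tuple = (1.3, 1.35, 1.4)
    exvivo_spacing: float = 10000.0
    coordinate_noise_sd: float = 0.0
    seed: int = 0

    def validate(self):
        _require(self.n_segments >= 1, "n_segments must be >= 1")
        _require(len(self.lambda_true) == self.n_segments, "lambda_true must have n_segments entries")
        _require(all(l >= 1.0 for l in self.lambda_true), "lambda_true entries must be >= 1")
        _require(self.exvivo_spacing > 0, "exvivo_spacing must be positive")
        _require(self.coordinate_noise_sd >= 0, "coordinate_noise_sd must be non-negative")


def gen_marker_traces(ph: MarkerPhantom) -> tuple[MarkerTrace, MarkerTrace]:
    """(in_situ, ex_vivo) marker traces along the x axis, optionally jittered."""
    ph.validate()
    ex_x = np.arange(ph.n_segments + 1, dtype=float) * ph.exvivo_spacing
    in_x = np.concatenate([[0.0], np.cumsum(np.asarray(ph.lambda_true) * ph.exvivo_spacing)])
    ex = np.column_stack([ex_x, np.zeros_like(ex_x)])
    ins = np.column_stack([in_x, np.zeros_like(in_x)])
    if ph.coordinate_noise_sd > 0:
        rng = np.random.default_rng(ph.seed)
        ins = ins + rng.normal(0.0, ph.coordinate_noise_sd, size=ins.shape)
        ex = ex + rng.normal(0.0, ph.coordinate_noise_sd, size=ex.shape)
    return (
        MarkerTrace(ins, label="in_situ"),
        MarkerTrace(ex, label="ex_vivo"),
    )


# ---------------------------------------------------------------------------
# dose-response


@dataclass
class CCRCGroundTruth:
    """Four-parameter logistic ground truth for a dose series."""

    bottom: float = 0.0
    top: float = 100.0
    log_ec50: float = -6.0
    hill: float = 1.0
    doses: tuple = tuple(np.logspace(-9, -3, 8))
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self):
        _require(self.top != self.bottom, "top must differ from bottom")
        d = np.asarray(self.doses, dtype=float)
        _require(np.all(d > 0) and np.all(np.diff(d) > 0), "doses must be positive and strictly increasing")
        _require(self.noise_sd >= 0, "noise_sd must be non-negative")


def gen_ccrc(gt: CCRCGroundTruth) -> DoseResponseData:
    """Responses on the 4PL curve with additive Gaussian noise."""
    gt.validate()
    d = np.asarray(gt.doses, dtype=float)
    resp = hill_response(np.log10(d), gt.bottom, gt.top, gt.log_ec50, gt.hill)
    if gt.noise_sd > 0:
        rng = np.random.default_rng(gt.seed)
        resp = resp + rng.normal(0.0, gt.noise_sd, size=resp.shape)
    return DoseResponseData(d, resp)


# ---------------------------------------------------------------------------
# histology phantoms


@dataclass
class HistologyPhantom:
    """Stained-section phantom: annular vessel with nuclei and painted fibers.

    Geometry is an annulus (lumen inside ``inner_diameter``, media band out
    to ``media_outer_diameter`` — default midway — and adventitia out to
    ``outer_diameter``).  Elliptical nuclei with prescribed count, mean area
    and aspect ratio are placed without overlap in the media ROI and painted
    with the residual stain vector; fiber fractions are painted pixel-exactly
    with the elastin/collagen stain vectors in optical-density space.
    """

    inner_diameter: float = 200.0
    outer_diameter: float = 320.0
    media_outer_diameter: Optional[float] = None
    pixel_size: float = 0.2
    n_nuclei: int = 50
    nucleus_mean_area: float = 22.0
    nucleus_aspect: float = 2.2
    elastin_fraction: float = 0.25
    collagen_fraction: float = 0.15
    stain_matrix: Optional[StainMatrix] = None
    seed: int = 0
    # painting strengths (stain concentration units)
    nucleus_strength: float = 1.8
    fiber_strength: float = 1.0
    media_tint: float = 0.12
    adventitia_tint: float = 0.06

    def validate(self):
        _require(self.outer_diameter > self.inner_diameter > 0, "outer_diameter must exceed inner_diameter")
        med = self.media_outer_diameter
        if med is not None:
            _require(self.inner_diameter < med < self.outer_diameter, "media_outer_diameter must lie between inner_diameter and outer_diameter")
        _require(self.pixel_size > 0, "pixel_size must be positive")
        _require(self.n_nuclei >= 0, "n_nuclei must be non-negative")
        _require(self.nucleus_mean_area > 0, "nucleus_mean_area must be positive")
        _require(self.nucleus_aspect >= 1.0, "nucleus_aspect must be >= 1")
        _require(0.0 <= self.elastin_fraction <= 1.0, "elastin_fraction must be in [0, 1]")
        _require(0.0 <= self.collagen_fraction <= 1.0, "collagen_fraction must be in [0, 1]")
        _require(self.elastin_fraction + self.collagen_fraction <= 1.0, "elastin_fraction + collagen_fraction must be <= 1")


@dataclass
class HistologyGroundTruth:
    """Sidecar truth accompanying a generated section phantom."""

    nuclei_centroids_px: np.ndarray
    nucleus_areas_um2: np.ndarray
    nuclei_mask: np.ndarray
    elastin_mask: np.ndarray
    collagen_mask: np.ndarray
    elastin_fraction: float
    collagen_fraction: float
    roi_area_um2: float
    luminal_perimeter_um: float
    medial_perimeter_um: float
    adventitial_perimeter_um: float
    nuclei_density_per_mm2: float


def gen_histology_image(ph: HistologyPhantom) -> tuple[HistologyImage, HistologyGroundTruth]:
    """Render the phantom and return it with exact ground truth.

    Raises if the requested nuclei cannot be placed without overlap within a
    bounded number of retries (the achievable count is reported).
    """
    ph.validate()
    rng = np.random.default_rng(ph.seed)
    ps = ph.pixel_size
    stains = ph.stain_matrix or default_evg_stains()
    med_d = ph.media_outer_diameter or 0.5 * (ph.inner_diameter + ph.outer_diameter)
    r_in = ph.inner_diameter / 2.0 / ps
    r_med = med_d / 2.0 / ps
    r_out = ph.outer_diameter / 2.0 / ps
    margin = 8
    size = int(np.ceil(2 * r_out)) + 2 * margin
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    rr = np.hypot(yy + 0.5 - c, xx + 0.5 - c)
    media_band = (rr >= r_in) & (rr < r_med)
    adventitia = (rr >= r_med) & (rr < r_out)

    # stain-concentration raster (H, W, 3): elastin, collagen, residual
    conc = np.zeros((size, size, 3))
    conc[media_band, 2] = ph.media_tint
    conc[adventitia, 1] = ph.adventitia_tint

    # ROI: annular sector polygon (2°..358°) inset from the media band edges
    inset = 3.0  # px
    roi_r_in, roi_r_out = r_in + inset, r_med - inset
    ang = np.radians(np.linspace(2.0, 358.0, 179))
    outer_arc = np.column_stack([c + roi_r_out * np.cos(ang), c + roi_r_out * np.sin(ang)])
    inner_arc = np.column_stack([c + roi_r_in * np.cos(ang[::-1]), c + roi_r_in * np.sin(ang[::-1])])
    roi_polygon = np.vstack([outer_arc, inner_arc])
    roi_mask = polygon2mask((size, size), np.column_stack([roi_polygon[:, 1], roi_polygon[:, 0]]))

    # nuclei: non-overlapping ellipses fully inside the ROI
    area_px = ph.nucleus_mean_area / ps**2
    a = float(np.sqrt(area_px * ph.nucleus_aspect / np.pi))
    b = a / ph.nucleus_aspect
    pad = a + 2.0
    nuclei_mask = np.zeros((size, size), dtype=bool)
    centers: list[tuple[float, float]] = []
    areas_px: list[int] = []
    max_tries = 200 * max(ph.n_nuclei, 1)
    tries = 0
    r_lo, r_hi = roi_r_in + pad, roi_r_out - pad
    _require(r_hi > r_lo, "media band too thin for the requested nucleus size")
    ang_pad = pad / r_lo
    while len(centers) < ph.n_nuclei and tries < max_tries:
        tries += 1
        theta = rng.uniform(np.radians(2.0) + ang_pad, np.radians(358.0) - ang_pad)
        rad = np.sqrt(rng.uniform(r_lo**2, r_hi**2))
        cx = c + rad * np.cos(theta)
        cy = c + rad * np.sin(theta)
        if any(np.hypot(cx - px, cy - py) < 2 * a + 2.0 for px, py in centers):
            continue
        phi = rng.uniform(0.0, np.pi)
        rr_e, cc_e = draw_ellipse(cy, cx, b, a, shape=(size, size), rotation=phi)
        centers.append((cx, cy))
        areas_px.append(len(rr_e))
        nuclei_mask[rr_e, cc_e] = True
        conc[rr_e, cc_e] = 0.0
        conc[rr_e, cc_e, 2] = ph.nucleus_strength
    if len(centers) < ph.n_nuclei:
        raise ValueError(
            f"could only place {len(centers)} of {ph.n_nuclei} nuclei without overlap"
        )

    # fibers: pixel-exact painted fractions of the ROI
    from scipy.ndimage import binary_dilation

    candidates = roi_mask & ~binary_dilation(nuclei_mask, np.ones((3, 3)))
    n_roi = int(roi_mask.sum())
    k_e = int(round(ph.elastin_fraction * n_roi))
    k_c = int(round(ph.collagen_fraction * n_roi))
    cand_idx = np.flatnonzero(candidates.ravel())
    if k_e + k_c > len(cand_idx):
        raise ValueError("requested fiber fractions exceed the paintable ROI area")
    perm = rng.permutation(cand_idx)
    elastin_mask = np.zeros(size * size, dtype=bool)
    collagen_mask = np.zeros(size * size, dtype=bool)
    elastin_mask[perm[:k_e]] = True
    collagen_mask[perm[k_e : k_e + k_c]] = True
    elastin_mask = elastin_mask.reshape(size, size)
    collagen_mask = collagen_mask.reshape(size, size)
    conc[elastin_mask] = 0.0
    conc[elastin_mask, 0] = ph.fiber_strength
    conc[collagen_mask] = 0.0
    conc[collagen_mask, 1] = ph.fiber_strength

    od = conc @ stains.matrix
    pixels = np.clip(np.rint(255.0 * 10.0 ** (-od)), 0, 255).astype(np.uint8)

    image = HistologyImage(pixels=pixels, pixel_size=ps, roi=roi_polygon)
    roi_area_um2 = n_roi * ps**2
    truth = HistologyGroundTruth(
        nuclei_centroids_px=np.asarray(centers, dtype=float),
        nucleus_areas_um2=np.asarray(areas_px, dtype=float) * ps**2,
        nuclei_mask=nuclei_mask,
        elastin_mask=elastin_mask,
        collagen_mask=collagen_mask,
        elastin_fraction=k_e / n_roi,
        collagen_fraction=k_c / n_roi,
        roi_area_um2=roi_area_um2,
        luminal_perimeter_um=np.pi * ph.inner_diameter,
        medial_perimeter_um=np.pi * med_d,
        adventitial_perimeter_um=np.pi * ph.outer_diameter,
        nuclei_density_per_mm2=ph.n_nuclei / (roi_area_um2 / 1e6),
    )
    return image, truth
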