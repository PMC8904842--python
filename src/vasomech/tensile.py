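"""Uniaxial tensile mechanics of arterial strips.

Converts force-displacement records from a uniaxial test into Cauchy
stress-stretch curves and extracts the standard parameter set used to
describe the hyperelastic response of arterial tissue:

* ``E1`` — tangent modulus of the initial (low-strain) linear zone [kPa],
* ``E2`` — tangent modulus of the final (high-strain) linear zone [kPa],
* ``(lambda_t, sigma_t)`` — the transition ("elbow") point, defined as the
  midpoint between the end of the low-stiffness zone and the start of the
  high-stiffness zone,
* ``(lambda_r, sigma_r)`` — the rupture point,
* ``Et``, ``Er`` — strain energy per unit volume up to the transition and
  rupture stretches [µJ/mm³], by composite Simpson integration.

Kinematics assume incompressibility: stretch ``λ = (l0 + Δ)/l0`` and Cauchy
stress ``σ = F/(w0·e0)·λ``, with forces in N, lengths in mm and stress
reported in kPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.integrate import simpson
from scipy.ndimage import uniform_filter1d

__all__ = [
    "TensileConfig",
    "TensileRecord",
    "StressStretchCurve",
    "ZoneBoundaries",
    "RupturePoint",
    "MechanicalParameters",
    "TensileTest",
    "TensileResults",
    "compute_stretch",
    "compute_cauchy_stress",
    "four_zone_stress",
    "segment_zones",
    "transition_point",
    "fit_slopes",
    "detect_rupture",
    "strain_energy",
    "analyze_tensile",
]

#: kPa per N/mm² (= MPa)
KPA_PER_MPA = 1000.0


@dataclass
class TensileConfig:
    """Tunable parameters of the tensile analysis.

    Attributes
    ----------
    r2_min : minimum R² for the expanding-window linear fits that locate the
        zone boundaries.
    smooth_window : moving-average window (samples) applied to stress before
        segmentation only; slopes are always fitted on the raw curve.
    min_zone_points : minimum number of samples required in each linear zone.
    refine : if True, the window-based boundaries seed a constrained
        least-squares fit of the piecewise linear/cubic-bridge curve family,
        which localizes the boundaries much more sharply on steep curves.
    drop_frac : fractional stress drop (relative to the candidate peak) that
        must occur within ``drop_lookahead`` samples to declare rupture.
    energy_grid_points : grid size for Simpson integration when the curve must
        be resampled to a uniform grid.
    test_speed_mm_per_min, load_cell_N : protocol provenance metadata
        (recorded in reports; not used in computation).
    """

    r2_min: float = 0.995
    smooth_window: int = 5
    min_zone_points: int = 5
    refine: bool = True
    drop_frac: float = 0.2
    drop_lookahead: int = 5
    energy_grid_points: int = 1001
    test_speed_mm_per_min: float = 1.5
    load_cell_N: float = 10.0


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-D series")
    return arr


@dataclass
class TensileRecord:
    """Raw specimen geometry and the recorded force/displacement series.

    Lengths in mm, force in N.  ``displacement`` must be non-decreasing and
    start at zero (jaw reversal is not supported).
    """

    l0: float
    w0: float
    e0: float
    displacement: np.ndarray
    force: np.ndarray
    specimen_id: str = ""

    def __post_init__(self):
        for name in ("l0", "w0", "e0"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.displacement = _as_float_array(self.displacement, "displacement")
        self.force = _as_float_array(self.force, "force")
        if len(self.displacement) != len(self.force):
            raise ValueError("displacement and force must have equal length")
        if len(self.displacement) < 10:
            raise ValueError("displacement series must contain at least 10 samples")
        if self.displacement[0] != 0:
            raise ValueError("displacement must start at 0")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError("displacement must be non-decreasing (jaw reversal not supported)")
        if np.any(self.force < 0):
            raise ValueError("force must be non-negative")


@dataclass
class StressStretchCurve:
    """Cauchy stress [kPa] versus stretch (dimensionless)."""

    stretch: np.ndarray
    stress: np.ndarray

    def __post_init__(self):
        self.stretch = _as_float_array(self.stretch, "stretch")
        self.stress = _as_float_array(self.stress, "stress")
        if len(self.stretch) != len(self.stress):
            raise ValueError("stretch and stress must have equal length")
        if len(self.stretch) == 0:
            raise ValueError("stretch series is empty")
        if not np.isclose(self.stretch[0], 1.0):
            raise ValueError("stretch must start at 1")
        if np.any(np.diff(self.stretch) <= 0):
            raise ValueError("stretch must be strictly increasing")

    @classmethod
    def from_record(cls, record: TensileRecord) -> "StressStretchCurve":
        lam = compute_stretch(record.l0, record.displacement)
        sig = compute_cauchy_stress(record.force, record.w0, record.e0, lam)
        return cls(lam, sig)

    def __len__(self):
        return len(self.stretch)

    def sliced(self, stop: int) -> "StressStretchCurve":
        return StressStretchCurve(self.stretch[:stop], self.stress[:stop])


@dataclass
class ZoneBoundaries:
    """End of the low-stiffness zone and start of the high-stiffness zone."""

    lambda_a: float
    lambda_b: float
    degenerate: bool = False
    fit_diagnostics: dict = field(default_factory=dict)


@dataclass
class RupturePoint:
    lambda_r: float
    sigma_r: float
    ruptured: bool


@dataclass
class MechanicalParameters:
    """The per-specimen mechanical parameter tuple.

    ``Er`` (and ``sigma_r``'s interpretation as a rupture stress) are only
    meaningful when ``ruptured`` is True; for a test stopped before failure
    ``Er`` is NaN and ``(lambda_r, sigma_r)`` is the last recorded sample.
    """

    E1: float
    E2: float
    lambda_t: float
    sigma_t: float
    lambda_r: float
    sigma_r: float
    Et: float
    Er: float
    ruptured: bool = True


# ---------------------------------------------------------------------------
# kinematics


def compute_stretch(l0: float, displacement) -> np.ndarray:
    """Stretch λ = (l0 + Δ)/l0 from jaw displacement Δ [mm]."""
    if l0 <= 0:
        raise ValueError("l0 must be positive")
    d = _as_float_array(displacement, "displacement")
    if np.any(d < 0):
        raise ValueError("negative displacement (jaw reversal not supported)")
    if np.any(np.diff(d) < 0):
        raise ValueError("displacement must be non-decreasing")
    return (l0 + d) / l0


def compute_cauchy_stress(force, w0: float, e0: float, stretch) -> np.ndarray:
    """Cauchy stress σ = F/(w0·e0)·λ in kPa (incompressible specimen)."""
    if w0 <= 0 or e0 <= 0:
        raise ValueError("cross-section dimensions w0, e0 must be positive")
    f = _as_float_array(force, "force")
    lam = _as_float_array(stretch, "stretch")
    if len(f) != len(lam):
        raise ValueError("force and stretch must be aligned")
    return f / (w0 * e0) * lam * KPA_PER_MPA


# ---------------------------------------------------------------------------
# the four-zone curve family (shared with the synthetic generator)


def four_zone_stress(
    lam,
    E1: float,
    E2: float,
    lambda_a: float,
    lambda_b: float,
    sigma_b: Optional[float] = None,
):
    """Noise-free pre-rupture stress of the piecewise curve family.

    Linear with slope ``E1`` on [1, lambda_a]; a C¹ monotone cubic Hermite
    bridge on [lambda_a, lambda_b] (end slopes E1 and E2); linear with slope
    ``E2`` beyond lambda_b.  ``sigma_b`` is the stress at lambda_b; if None it
    defaults to the average-slope secant value
    ``sigma_a + (E1+E2)/2 · (lambda_b - lambda_a)``, which satisfies the
    Fritsch–Carlson monotonicity condition for any E2 > E1 > 0.
    """
    lam = np.asarray(lam, dtype=float)
    sigma_a = E1 * (lambda_a - 1.0)
    h = lambda_b - lambda_a
    if h < 1e-12:
        # sharp elbow (bilinear limit)
        return np.where(
            lam <= lambda_a, E1 * (lam - 1.0), sigma_a + E2 * (lam - lambda_a)
        )
    if sigma_b is None:
        sigma_b = sigma_a + 0.5 * (E1 + E2) * h
    out = np.empty_like(lam)
    lo = lam <= lambda_a
    hi = lam >= lambda_b
    mid = ~lo & ~hi
    out[lo] = E1 * (lam[lo] - 1.0)
    out[hi] = sigma_b + E2 * (lam[hi] - lambda_b)
    t = (lam[mid] - lambda_a) / h
    h00 = (1 + 2 * t) * (1 - t) ** 2
    h10 = t * (1 - t) ** 2
    h01 = t * t * (3 - 2 * t)
    h11 = t * t * (t - 1)
    out[mid] = h00 * sigma_a + h10 * h * E1 + h01 * sigma_b + h11 * h * E2
    return out


# ---------------------------------------------------------------------------
# zone segmentation


def _window_r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """R² of an OLS line on every prefix window [0..j], vectorized."""
    n = np.arange(1.0, len(x) + 1.0)
    sx, sy = np.cumsum(x), np.cumsum(y)
    sxx, syy, sxy = np.cumsum(x * x), np.cumsum(y * y), np.cumsum(x * y)
    cov = n * sxy - sx * sy
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    r2 = np.ones_like(cov)
    ok = (vx > 1e-300) & (vy > 1e-300 * np.maximum(1.0, syy))
    # guard: a constant-y window is fitted exactly by a line -> R² := 1
    denom = vx[ok] * vy[ok]
    r2[ok] = np.clip(cov[ok] ** 2 / denom, 0.0, 1.0)
    r2[vy <= 0] = 1.0
    return r2


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _profile_rss(
    lam: np.ndarray, sig: np.ndarray, la: float, lb: float, sqrt_w: np.ndarray
) -> float:
    """Weighted RSS of the four-zone family with (E1, E2, sigma_b) profiled out.

    For fixed boundaries the family is linear in (E1, E2, sigma_b), so the
    inner fit is a weighted least-squares solve.
    """
    h = lb - la
    col_e1 = np.where(lam <= la, lam - 1.0, 0.0)
    col_e2 = np.where(lam >= lb, lam - lb, 0.0)
    col_sb = np.where(lam >= lb, 1.0, 0.0)
    if h > 1e-12:
        mid = (lam > la) & (lam < lb)
        t = (lam[mid] - la) / h
        h00 = (1 + 2 * t) * (1 - t) ** 2
        h10 = t * (1 - t) ** 2
        h01 = t * t * (3 - 2 * t)
        h11 = t * t * (t - 1)
        col_e1[mid] = h00 * (la - 1.0) + h10 * h
        col_e2[mid] = h11 * h
        col_sb[mid] = h01
    a_mat = np.column_stack([col_e1, col_e2, col_sb]) * sqrt_w[:, None]
    rhs = sig * sqrt_w
    coef, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    resid = a_mat @ coef - rhs
    return float(resid @ resid)


def _refine_boundaries(lam, sig, la_0, lb_0, sqrt_w, hi_b=None):
    """Sharpen the zone boundaries by fitting the four-zone curve family.

    Iterative grid-zoom over admissible (lambda_a, lambda_b), seeded with the
    window-search solution, followed by a short Nelder-Mead polish of the
    profiled weighted residual.  ``hi_b`` caps lambda_b so the high-strain
    zone keeps enough samples.  Returns (lambda_a, lambda_b, rss).
    """
    lo, hi = float(lam[2]), float(lam[-3])
    if hi_b is not None:
        hi = min(hi, float(hi_b))
    if hi <= lo:
        return None
    n_grid = 13
    la_0, lb_0 = min(max(la_0, lo), hi), min(max(lb_0, lo), hi)
    best = (_profile_rss(lam, sig, la_0, lb_0, sqrt_w), la_0, lb_0)
    span = hi - lo
    ca, cb = 0.5 * (lo + hi), 0.5 * (lo + hi)
    half = 0.5 * span
    for _ in range(5):
        ga_grid = np.linspace(max(lo, ca - half), min(hi, ca + half), n_grid)
        gb_grid = np.linspace(max(lo, cb - half), min(hi, cb + half), n_grid)
        for ga in ga_grid:
            for gb in gb_grid:
                if gb < ga:
                    continue
                rss = _profile_rss(lam, sig, ga, gb, sqrt_w)
                if rss < best[0]:
                    best = (rss, float(ga), float(gb))
        ca, cb = best[1], best[2]
        half *= 2.5 / (n_grid - 1)

    def objective(x):
        la, lb = x
        if not (lo <= la <= lb <= hi):
            return np.inf
        return _profile_rss(lam, sig, la, lb, sqrt_w)

    res = optimize.minimize(
        objective,
        np.array([best[1], best[2]]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 200},
    )
    if np.isfinite(res.fun) and res.fun < best[0]:
        return float(res.x[0]), float(res.x[1]), float(res.fun)
    return float(best[1]), float(best[2]), float(best[0])


def segment_zones(curve: StressStretchCurve, cfg: Optional[TensileConfig] = None) -> ZoneBoundaries:
    """Locate the low/high-stiffness zone boundaries on a pre-rupture curve.

    Expanding-window linear fits from each end keep growing while R² stays
    above ``cfg.r2_min`` (on the moving-average-smoothed stress); the largest
    passing prefix gives ``lambda_a`` and the largest passing suffix gives
    ``lambda_b``.  When ``cfg.refine`` is set, these seed a constrained
    least-squares fit of the piecewise curve family which localizes the
    boundaries to within the sampling grid on noise-free curves.
    """
    cfg = cfg or TensileConfig()
    lam = curve.stretch
    sig = curve.stress
    n = len(lam)
    m = cfg.min_zone_points
    if n < 2 * m:
        raise ValueError("curve too short to segment")
    smooth = uniform_filter1d(sig, size=max(1, cfg.smooth_window), mode="nearest")

    r2_prefix = _window_r2(lam, smooth)
    r2_suffix = _window_r2(lam[::-1], smooth[::-1])[::-1]  # r2_suffix[i] = window [i..n-1]

    pref_ok = np.flatnonzero(r2_prefix[m - 1 : n - 1] >= cfg.r2_min) + (m - 1)
    suf_ok = np.flatnonzero(r2_suffix[1 : n - m + 1] >= cfg.r2_min) + 1
    if len(pref_ok) == 0 or len(suf_ok) == 0:
        if not cfg.refine:
            raise ValueError(
                f"no linear window reaches R² >= {cfg.r2_min}; consider lowering r2_min"
            )
        # very noisy small windows can miss the threshold; the global curve
        # fit below does not depend on accurate seeds, so fall back to
        # quartile boundaries
        ia = int(pref_ok[-1]) if len(pref_ok) else n // 4
        ib = int(suf_ok[0]) if len(suf_ok) else 3 * n // 4
    else:
        ia = int(pref_ok[-1])
        ib = int(suf_ok[0])
    diagnostics = {
        "r2_zone1": float(r2_prefix[ia]),
        "r2_zone3": float(r2_suffix[ib]),
        "refined": False,
    }

    degenerate_seed = False
    if ia >= ib:
        # windows overlap: sharp elbow or a single straight line
        m1, c1 = _ols_line(lam[: ia + 1], sig[: ia + 1])
        m2, c2 = _ols_line(lam[ib:], sig[ib:])
        if abs(m1 - m2) > 1e-9 * max(abs(m1), abs(m2), 1.0):
            cross = (c1 - c2) / (m2 - m1)
            cross = float(np.clip(cross, lam[0], lam[-1]))
        else:
            cross = float(0.5 * (lam[0] + lam[-1]))
        la = lb = cross
        degenerate_seed = True
        if not cfg.refine:
            return ZoneBoundaries(la, lb, degenerate=True, fit_diagnostics=diagnostics)
    else:
        la, lb = float(lam[ia]), float(lam[ib])
    if cfg.refine:
        # heteroscedastic weights: stress spans orders of magnitude, and
        # load-cell error grows with load; relative weighting keeps the
        # low-stiffness zone and the elbow informative in the fit
        floor = 0.02 * float(np.max(np.abs(smooth))) + 1e-12
        sqrt_w = 1.0 / np.maximum(np.abs(smooth), floor)
        i_max = int(np.argmax(sig))
        hi_b = lam[max(i_max - m, 2)]
        refined = _refine_boundaries(lam, sig, la, lb, sqrt_w, hi_b=hi_b)
        if refined is not None:
            la_r, lb_r, rss = refined
            # a single straight line is fitted equally well at any boundary
            # pair: keep the degenerate flag unless the four-zone fit is
            # substantially better than one line
            line_resid = np.polyval(
                np.polyfit(lam, sig, 1, w=sqrt_w), lam
            ) - sig
            line_rss = float((line_resid * sqrt_w) @ (line_resid * sqrt_w))
            wsig = sig * sqrt_w
            line_is_exact = line_rss <= 1e-10 * float(wsig @ wsig)
            if degenerate_seed and (line_is_exact or rss > 0.5 * line_rss):
                diagnostics["refined"] = True
                return ZoneBoundaries(la, lb, degenerate=True, fit_diagnostics=diagnostics)
            la, lb = la_r, lb_r
            diagnostics["refined"] = True
            diagnostics["rss"] = rss
            grid_step = float(np.median(np.diff(lam)))
            if lb - la < 1.5 * grid_step:
                mid = 0.5 * (la + lb)
                return ZoneBoundaries(mid, mid, degenerate=True, fit_diagnostics=diagnostics)
            degenerate_seed = False
    return ZoneBoundaries(la, lb, degenerate=degenerate_seed, fit_diagnostics=diagnostics)


def transition_point(curve: StressStretchCurve, zones: ZoneBoundaries) -> tuple[float, float]:
    """Transition ("elbow") point: midpoint between the zone boundaries."""
    lam_t = 0.5 * (zones.lambda_a + zones.lambda_b)
    sig_a = float(np.interp(zones.lambda_a, curve.stretch, curve.stress))
    sig_b = float(np.interp(zones.lambda_b, curve.stretch, curve.stress))
    return lam_t, 0.5 * (sig_a + sig_b)


def fit_slopes(
    curve: StressStretchCurve,
    zones: ZoneBoundaries,
    lambda_max: Optional[float] = None,
    min_zone_points: int = 5,
) -> tuple[float, float]:
    """OLS tangent moduli E1 (on [1, lambda_a]) and E2 (on [lambda_b, λ@σmax])."""
    lam, sig = curve.stretch, curve.stress
    if lambda_max is None:
        lambda_max = float(lam[np.argmax(sig)])
    tol = 1e-12
    z1 = lam <= zones.lambda_a + tol
    z3 = (lam >= zones.lambda_b - tol) & (lam <= lambda_max + tol)
    if z1.sum() < min_zone_points:
        raise ValueError(f"fewer than {min_zone_points} points in the low-strain zone")
    if z3.sum() < min_zone_points:
        raise ValueError(f"fewer than {min_zone_points} points in the high-strain zone")
    E1, _ = _ols_line(lam[z1], sig[z1])
    E2, _ = _ols_line(lam[z3], sig[z3])
    if E2 < E1:
        warnings.warn(
            "E2 < E1: curve is concave, violating the expected stiffening shape",
            stacklevel=2,
        )
    return E1, E2


def detect_rupture(
    curve: StressStretchCurve, drop_frac: float = 0.2, lookahead: int = 5
) -> RupturePoint:
    """Rupture point: the highest-stress sample followed by a >drop_frac fall.

    A sample qualifies as a rupture candidate when the stress falls below
    ``(1 - drop_frac)`` of its value within the next ``lookahead`` samples;
    among candidates the one with maximal stress is returned.  Without any
    candidate (test stopped early) the last sample is returned with
    ``ruptured=False``.
    """
    sig = curve.stress
    n = len(sig)
    if n == 0:
        raise ValueError("empty curve")
    future_min = np.full(n, np.inf)
    for k in range(1, lookahead + 1):
        if k < n:
            future_min[: n - k] = np.minimum(future_min[: n - k], sig[k:])
    cand = np.flatnonzero((future_min < (1.0 - drop_frac) * sig) & (sig > 0))
    if len(cand) == 0:
        return RupturePoint(float(curve.stretch[-1]), float(sig[-1]), ruptured=False)
    i = int(cand[np.argmax(sig[cand])])
    return RupturePoint(float(curve.stretch[i]), float(sig[i]), ruptured=True)


def strain_energy(
    curve: StressStretchCurve, lambda_end: float, n_grid: int = 1001
) -> float:
    """Strain energy ∫σ dλ from λ=1 to lambda_end by composite Simpson's rule.

    The curve's own samples are used directly when they already form a uniform
    grid ending at ``lambda_end`` with an odd point count (Simpson is then
    exact for polynomial stress up to degree 3); otherwise the curve is
    resampled by linear interpolation onto a uniform ``n_grid``-point grid.
    Units: kPa × (dimensionless stretch) ≡ µJ/mm³.
    """
    if lambda_end < 1.0:
        raise ValueError("lambda_end must be >= 1")
    lam, sig = curve.stretch, curve.stress
    if lambda_end > lam[-1] + 1e-9:
        raise ValueError("lambda_end outside the curve domain")
    if np.isclose(lambda_end, 1.0):
        return 0.0
    sel = lam <= lambda_end + 1e-12
    lam_s, sig_s = lam[sel], sig[sel]
    if not np.isclose(lam_s[-1], lambda_end):
        lam_s = np.append(lam_s, lambda_end)
        sig_s = np.append(sig_s, np.interp(lambda_end, lam, sig))
    d = np.diff(lam_s)
    uniform = len(lam_s) >= 3 and len(lam_s) % 2 == 1 and np.allclose(d, d[0], rtol=1e-8)
    if uniform:
        return float(simpson(sig_s, x=lam_s))
    grid = np.linspace(1.0, lambda_end, n_grid if n_grid % 2 == 1 else n_grid + 1)
    return float(simpson(np.interp(grid, lam, sig), x=grid))


# ---------------------------------------------------------------------------
# model / results objects


class TensileTest:
    """Uniaxial tensile analysis model for one specimen.

    Parameters
    ----------
    record : TensileRecord
        Specimen geometry and the force/displacement series.
    config : TensileConfig, optional
        Analysis settings; defaults are suitable for arterial strips.

    ``fit()`` returns a :class:`TensileResults` carrying the eight mechanical
    parameters, the detected zone boundaries and diagnostics.
    """

    def __init__(self, record: TensileRecord, config: Optional[TensileConfig] = None):
        self.record = record
        self.config = config or TensileConfig()

    @classmethod
    def from_csv(cls, path, config: Optional[TensileConfig] = None) -> "TensileTest":
        from .io import read_tensile_csv

        return cls(read_tensile_csv(path), config)

    def fit(self) -> "TensileResults":
        cfg = self.config
        curve = StressStretchCurve.from_record(self.record)
        rupture = detect_rupture(curve, cfg.drop_frac, cfg.drop_lookahead)
        i_r = int(np.searchsorted(curve.stretch, rupture.lambda_r, side="right"))
        pre = curve.sliced(i_r)
        zones = segment_zones(pre, cfg)
        lam_t, sig_t = transition_point(pre, zones)
        notes: list[str] = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            E1, E2 = fit_slopes(pre, zones, min_zone_points=cfg.min_zone_points)
            notes.extend(str(w.message) for w in caught)
        Et = strain_energy(pre, lam_t, cfg.energy_grid_points)
        if rupture.ruptured:
            Er = strain_energy(pre, rupture.lambda_r, cfg.energy_grid_points)
        else:
            Er = float("nan")
            notes.append("no rupture detected; Er unavailable, (lambda_r, sigma_r) is the last sample")
        params = MechanicalParameters(
            E1=E1,
            E2=E2,
            lambda_t=lam_t,
            sigma_t=sig_t,
            lambda_r=rupture.lambda_r,
            sigma_r=rupture.sigma_r,
            Et=Et,
            Er=Er,
            ruptured=rupture.ruptured,
        )
        return TensileResults(self.record, cfg, curve, zones, rupture, params, notes)


class TensileResults:
    """Fitted mechanical parameters for one tensile specimen."""

    def __init__(self, record, config, curve, zones, rupture, params, notes):
        self.record = record
        self.config = config
        self.curve = curve
        self.zones = zones
        self.rupture = rupture
        self.params = params
        self.notes = notes

    def as_dict(self) -> dict:
        p = self.params
        return {
            "specimen_id": self.record.specimen_id,
            "E1_kPa": p.E1,
            "E2_kPa": p.E2,
            "lambda_t": p.lambda_t,
            "sigma_t_kPa": p.sigma_t,
            "lambda_r": p.lambda_r,
            "sigma_r_kPa": p.sigma_r,
            "Et_uJ_mm3": p.Et,
            "Er_uJ_mm3": p.Er,
            "ruptured": p.ruptured,
            "degenerate_zones": self.zones.degenerate,
            "diagnostics": self.zones.fit_diagnostics,
            "notes": list(self.notes),
        }

    def summary(self) -> str:
        p = self.params
        lines = [
            "Uniaxial tensile analysis",
            "=" * 44,
            f"specimen: {self.record.specimen_id or '(unnamed)'}",
            f"samples:  {len(self.curve)}   ruptured: {p.ruptured}",
            "-" * 44,
            f"E1        {p.E1:12.3f} kPa",
            f"E2        {p.E2:12.3f} kPa",
            f"lambda_t  {p.lambda_t:12.4f} -",
            f"sigma_t   {p.sigma_t:12.3f} kPa",
            f"lambda_r  {p.lambda_r:12.4f} -",
            f"sigma_r   {p.sigma_r:12.3f} kPa",
            f"Et        {p.Et:12.3f} uJ/mm^3",
            f"Er        {p.Er:12.3f} uJ/mm^3",
        ]
        for n in self.notes:
            lines.append(f"note: {n}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curve.stretch, self.curve.stress, lw=1, label="data")
        for x, ls in ((self.zones.lambda_a, ":"), (self.zones.lambda_b, ":")):
            ax.axvline(x, color="gray", ls=ls, lw=0.8)
        p = self.params
        ax.plot([p.lambda_t], [p.sigma_t], "o", label="transition")
        ax.plot([p.lambda_r], [p.sigma_r], "x", label="rupture")
        ax.set_xlabel("stretch λ (-)")
        ax.set_ylabel("Cauchy stress σ (kPa)")
        ax.legend()
        return ax


def analyze_tensile(
    record: TensileRecord, cfg: Optional[TensileConfig] = None
) -> MechanicalParameters:
    """One-call tensile analysis returning the mechanical parameter tuple."""
    return TensileTest(record, cfg).fit().params
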