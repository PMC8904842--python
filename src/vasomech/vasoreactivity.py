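"""Wire-myography cumulative concentration-response curve (CCRC) analysis.

Ring segments mounted on a wire myograph produce wall tension (mN/mm)
readings at cumulative agonist doses.  Contractions (K+, phenylephrine) are
normalized to the maximal potassium contraction (%Kmax); relaxations
(methacholine, sodium nitroprusside) to the phenylephrine preconstriction
(%Rmax).  Each dose series is fitted with the four-parameter logistic in
log10 dose,

    R(c) = bottom + (top - bottom) / (1 + 10^((logEC50 - log10 c) * hill)),

from which sensitivity (EC50, pD2 = -log10 EC50) and the maximal response
(Emax / Kmax / Rmax) are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "CCRCRecord",
    "CCRCFit",
    "CCRCConfig",
    "DoseResponseData",
    "DoseResponseCurve",
    "DoseResponseResults",
    "wall_tension",
    "laplace_basal_tension",
    "normalize_contraction",
    "normalize_relaxation",
    "hill_response",
    "fit_ccrc",
    "summarize_ccrc_group",
]

MMHG_TO_KPA = 0.133322

#: preconstriction dose for vasodilator curves (protocol metadata)
PRECONSTRICTION_PE_M = 1e-6

AGENTS = ("K+", "PE", "MetCh", "SNP")


@dataclass
class CCRCRecord:
    """One animal's dose series for one vasoactive agent.

    Tensions are wall tensions in mN/mm; doses molar, strictly increasing.
    ``kmax_tension`` enables the %Kmax transform; ``preconstriction_tension``
    the %Rmax transform (vasodilators).
    """

    agent: str
    doses: np.ndarray
    tensions: np.ndarray
    segment_length: float
    basal_tension: float
    kmax_tension: Optional[float] = None
    preconstriction_tension: Optional[float] = None

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.tensions = np.asarray(self.tensions, dtype=float)
        if self.agent not in AGENTS:
            raise ValueError(f"agent must be one of {AGENTS}")
        if np.any(self.doses <= 0) or np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be positive and strictly increasing")
        if len(self.doses) != len(self.tensions):
            raise ValueError("doses and tensions must be aligned")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")


@dataclass
class DoseResponseData:
    """A bare dose/response series (output of the synthetic generator)."""

    doses: np.ndarray
    response: np.ndarray

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.response = np.asarray(self.response, dtype=float)


@dataclass
class CCRCConfig:
    """Fitting options for the four-parameter logistic."""

    emax_mode: str = "fitted_top"  # or "observed_max"
    hill_bounds: tuple = (0.05, 10.0)
    n_starts: int = 5
    abolished_span_frac: float = 0.1
    reference_span: Optional[float] = None


@dataclass
class CCRCFit:
    ec50: float
    pd2: float
    emax: float
    hill: float
    bottom: float
    top: float
    rss: float
    converged: bool
    response_abolished: bool = False


def wall_tension(force: float, segment_length: float, wall_factor: float = 2.0):
    """Wall tension (mN/mm) from myograph force (mN).

    The default divisor ``wall_factor * segment_length`` follows the wire
    myograph convention that two wall segments span the wires.
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    return np.asarray(force, dtype=float) / (wall_factor * segment_length)


def laplace_basal_tension(pressure_mmhg: float, internal_diameter_mm: float) -> float:
    """Target basal wall tension T = P·r (mN/mm) for a transmural pressure.

    Pressure in mmHg is converted to kPa (1 mmHg = 0.133322 kPa); with the
    radius in mm, kPa·mm ≡ mN/mm.  Used to set the 80 mmHg-equivalent
    resting tension before a concentration-response protocol.
    """
    if pressure_mmhg < 0 or internal_diameter_mm < 0:
        raise ValueError("pressure and diameter must be non-negative")
    return pressure_mmhg * MMHG_TO_KPA * internal_diameter_mm / 2.0


def normalize_contraction(tensions, kmax_tension: float, basal_tension: float):
    """%Kmax_i = 100 · (T_i − basal) / (Kmax − basal)."""
    if kmax_tension <= basal_tension:
        raise ValueError("kmax_tension must exceed basal_tension")
    t = np.asarray(tensions, dtype=float)
    return 100.0 * (t - basal_tension) / (kmax_tension - basal_tension)


def normalize_relaxation(tensions, preconstriction_tension: float, basal_tension: float):
    """%Rmax_i = 100 · (T_pre − T_i) / (T_pre − basal)."""
    if preconstriction_tension <= basal_tension:
        raise ValueError("preconstriction_tension must exceed basal_tension")
    t = np.asarray(tensions, dtype=float)
    return 100.0 * (preconstriction_tension - t) / (preconstriction_tension - basal_tension)


def hill_response(log10_dose, bottom, top, log_ec50, hill):
    """Four-parameter logistic in log10 dose."""
    log10_dose = np.asarray(log10_dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - log10_dose) * hill))


def fit_ccrc(doses, responses, cfg: Optional[CCRCConfig] = None) -> CCRCFit:
    """Least-squares 4PL fit with multi-start initialization.

    Requires >= 4 dose points spanning >= 2 log units.  A constant response
    series raises "no dose effect".  The convergence flag is honest: if no
    start converges, the best attempt is returned with ``converged=False``.
    """
    cfg = cfg or CCRCConfig()
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(d) != len(r):
        raise ValueError("doses and responses must be aligned")
    if len(d) < 4:
        raise ValueError("need at least 4 dose points")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    ld = np.log10(d)
    if ld.max() - ld.min() < 2.0:
        raise ValueError("doses must span at least 2 log units")
    if np.ptp(r) == 0:
        raise ValueError("no dose effect: responses are constant")

    lo = np.array([-np.inf, -np.inf, ld.min() - 3.0, cfg.hill_bounds[0]])
    hi = np.array([np.inf, np.inf, ld.max() + 3.0, cfg.hill_bounds[1]])
    increasing = r[-1] >= r[0]
    b0, t0 = (r.min(), r.max()) if increasing else (r.max(), r.min())
    quantiles = np.linspace(0.15, 0.85, cfg.n_starts)
    starts = [
        (b0, t0, float(np.quantile(ld, q)), h0)
        for q in quantiles
        for h0 in (0.5, 1.0, 2.0)
    ]
    best = None
    converged = False
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                hill_response, ld, r, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((hill_response(ld, *popt) - r) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
            converged = True
    if best is None:
        popt = np.array(starts[len(starts) // 2])
        rss = float(np.sum((hill_response(ld, *popt) - r) ** 2))
        best = (popt, rss)
    popt, rss = best
    bottom, top, log_ec50, hill = (float(v) for v in popt)
    span = abs(top - bottom)
    abolished = (
        cfg.reference_span is not None
        and span < cfg.abolished_span_frac * abs(cfg.reference_span)
    )
    if abolished:
        ec50, pd2 = float("nan"), float("nan")
    else:
        ec50 = 10.0**log_ec50
        pd2 = -log_ec50
    emax = float(np.max(np.abs(r))) if cfg.emax_mode == "observed_max" else top
    return CCRCFit(
        ec50=ec50,
        pd2=pd2,
        emax=emax,
        hill=hill,
        bottom=bottom,
        top=top,
        rss=rss,
        converged=converged,
        response_abolished=bool(abolished),
    )


class DoseResponseCurve:
    """Dose-response model for one ring segment / agonist.

    Thin statsmodels-style wrapper around :func:`fit_ccrc`; ``fit()``
    returns a :class:`DoseResponseResults`.
    """

    def __init__(self, doses, response, agent: str = "", config: Optional[CCRCConfig] = None):
        self.doses = np.asarray(doses, dtype=float)
        self.response = np.asarray(response, dtype=float)
        self.agent = agent
        self.config = config or CCRCConfig()

    @classmethod
    def from_record(
        cls, record: CCRCRecord, normalize: str = "auto", config: Optional[CCRCConfig] = None
    ) -> "DoseResponseCurve":
        """Build from a tension record, applying the %Kmax/%Rmax transform.

        ``normalize``: "kmax", "rmax", "none" or "auto" (contractile agents
        use %Kmax when a Kmax tension is available; vasodilators %Rmax).
        """
        if normalize == "auto":
            if record.agent in ("MetCh", "SNP") and record.preconstriction_tension is not None:
                normalize = "rmax"
            elif record.kmax_tension is not None:
                normalize = "kmax"
            else:
                normalize = "none"
        if normalize == "kmax":
            resp = normalize_contraction(
                record.tensions, record.kmax_tension, record.basal_tension
            )
        elif normalize == "rmax":
            resp = normalize_relaxation(
                record.tensions, record.preconstriction_tension, record.basal_tension
            )
            if config is None:
                config = CCRCConfig(reference_span=100.0)
        elif normalize == "none":
            resp = record.tensions
        else:
            raise ValueError("normalize must be 'auto', 'kmax', 'rmax' or 'none'")
        return cls(record.doses, resp, agent=record.agent, config=config)

    def fit(self) -> "DoseResponseResults":
        return DoseResponseResults(self, fit_ccrc(self.doses, self.response, self.config))


class DoseResponseResults:
    def __init__(self, model: DoseResponseCurve, fit: CCRCFit):
        self.model = model
        self.fit_result = fit

    def __getattr__(self, name):
        try:
            return getattr(self.__dict__["fit_result"], name)
        except (KeyError, AttributeError):
            raise AttributeError(name)

    def as_dict(self) -> dict:
        f = self.fit_result
        return {
            "agent": self.model.agent,
            "ec50_M": f.ec50,
            "pd2": f.pd2,
            "emax": f.emax,
            "hill": f.hill,
            "bottom": f.bottom,
            "top": f.top,
            "rss": f.rss,
            "converged": f.converged,
            "response_abolished": f.response_abolished,
        }

    def summary(self) -> str:
        f = self.fit_result
        lines = [
            "Concentration-response fit (4PL)",
            "=" * 40,
            f"agent:     {self.model.agent or '(unspecified)'}",
            f"doses:     {len(self.model.doses)}",
            f"converged: {f.converged}",
        ]
        if f.response_abolished:
            lines.append("response abolished: pD2 not assessed")
        else:
            lines += [
                f"EC50     {f.ec50:12.4g} M",
                f"pD2      {f.pd2:12.4f}",
            ]
        lines += [
            f"Emax     {f.emax:12.4f}",
            f"hill     {f.hill:12.4f}",
            f"bottom   {f.bottom:12.4f}",
            f"top      {f.top:12.4f}",
            f"RSS      {f.rss:12.4g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ld = np.log10(self.model.doses)
        ax.plot(ld, self.model.response, "o", label="data")
        grid = np.linspace(ld.min() - 0.5, ld.max() + 0.5, 200)
        f = self.fit_result
        ax.plot(
            grid,
            hill_response(grid, f.bottom, f.top, -f.pd2 if np.isfinite(f.pd2) else ld.mean(), f.hill),
            "-",
            label="4PL fit",
        )
        ax.set_xlabel("log10 dose (M)")
        ax.set_ylabel("response")
        ax.legend()
        return ax


def summarize_ccrc_group(fits: Sequence[CCRCFit], parameters=("pd2", "emax")) -> dict:
    """Group mean ± SEM of fitted parameters across animals.

    Non-converged fits are excluded and counted; abolished responses are
    excluded from the pD2 summary and reported as not assessed.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least 2 animals")
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValueError("all fits failed to converge")
    out = {
        "n_total": len(fits),
        "n_excluded_nonconverged": len(fits) - len(usable),
    }
    for p in parameters:
        vals = np.array([getattr(f, p) for f in usable], dtype=float)
        if p == "pd2":
            n_abol = int(np.sum([f.response_abolished for f in usable]))
            vals = vals[np.isfinite(vals)]
            out["pd2_not_assessed"] = n_abol
            if len(vals) == 0:
                out[p] = {"mean": float("nan"), "sem": float("nan"), "n": 0}
                continue
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out[p] = {"mean": float(vals.mean()), "sem": sem, "n": n}
    return out
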