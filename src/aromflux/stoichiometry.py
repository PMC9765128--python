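"""Growth physiology: rates, yields, elemental and electron balances.

Covers the quantitative side of batch cultivations of a facultative
anaerobe: exponential growth-rate fitting from OD readings, oxygen content
of dried cells by difference (fixed ash constant of 12.03 wt%, S included),
degrees of reduction on the CO₂/H₂O/NH₃ reference, electron-acceptor demand
for denitrification (NO₃⁻ → ½N₂, 5 e⁻) versus O₂ respiration (4 e⁻), and
carbon (C/C) biomass yields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Ash content of dried cells, wt%, includes S.
ASH_WT_PCT = 12.03

#: Molar mass of carbon, g/mol.
CARBON_MASS = 12.011

#: Electrons per mole accepted on full reduction.
ACCEPTOR_ELECTRONS = {"nitrate": 5.0, "oxygen": 4.0, "nitrite": 3.0}

#: Degree-of-reduction coefficients, CO₂/H₂O/NH₃ reference states.
GAMMA_COEFF = {"C": 4.0, "H": 1.0, "O": -2.0, "N": -3.0, "S": 6.0}


class StoichiometryError(ValueError):
    pass


@dataclass
class GrowthCurve:
    time: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # optical density at 660 nm
    substrate_mM: np.ndarray | None = None
    nitrate_mM: np.ndarray | None = None
    nitrite_mM: np.ndarray | None = None
    od_to_cdw: float = 1.0  # g CDW per L per OD unit

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.od.shape:
            raise StoichiometryError("time and od must be 1-d arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise StoichiometryError("time must be strictly increasing")
        for name in ("substrate_mM", "nitrate_mM", "nitrite_mM"):
            series = getattr(self, name)
            if series is not None:
                series = np.asarray(series, dtype=float)
                if series.shape != self.time.shape:
                    raise StoichiometryError(f"{name} length mismatch")
                setattr(self, name, series)

    @property
    def cdw(self) -> np.ndarray:
        return self.od * self.od_to_cdw


@dataclass
class GrowthFit:
    mu: float  # h⁻¹
    t_d: float  # h; NaN when mu <= 0
    r_squared: float
    window: tuple[float, float]
    n_points: int

    @property
    def positive(self) -> bool:
        return self.mu > 0


def fit_growth_rate(
    curve: GrowthCurve,
    window: tuple[float, float] | None = None,
    *,
    min_r2: float = 0.98,
) -> GrowthFit:
    """μ as the least-squares slope of ln(OD) versus time.

    ``window`` restricts the fit to a time interval; without it the longest
    contiguous stretch (≥3 points) with ln-linear R² ≥ ``min_r2`` is chosen
    automatically.  t_D = ln2/μ.  Non-positive OD inside the window is an
    error; μ ≤ 0 is flagged by t_D = NaN.
    """
    t, od = curve.time, curve.od
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if mask.sum() < 3:
            raise StoichiometryError("need at least 3 points in the window")
        if np.any(od[mask] <= 0):
            raise StoichiometryError("non-positive OD inside the fit window")
        return _fit_segment(t[mask], od[mask])
    if np.any(od <= 0):
        raise StoichiometryError("non-positive OD in curve; supply an explicit window")
    n = len(t)
    if n < 3:
        raise StoichiometryError("need at least 3 points")
    best: GrowthFit | None = None
    for i in range(n - 2):
        for j in range(n, i + 2, -1):
            if best is not None and (j - i) < best.n_points:
                break
            fit = _fit_segment(t[i:j], od[i:j])
            # the window must describe growth, not a flat or declining stretch
            if fit.r_squared >= min_r2 and fit.mu > 1e-12:
                if best is None or fit.n_points > best.n_points:
                    best = fit
                break
    if best is None:
        # nothing ln-linear enough: report the full-curve fit, flagged by R²
        best = _fit_segment(t, od)
    return best


def _fit_segment(t: np.ndarray, od: np.ndarray) -> GrowthFit:
    y = np.log(od)
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    mu = float(slope)
    # below ~1e-12 h⁻¹ the slope is numerical noise on a flat curve
    t_d = math.log(2) / mu if mu > 1e-12 else float("nan")
    return GrowthFit(mu=mu, t_d=t_d, r_squared=r2,
                     window=(float(t[0]), float(t[-1])), n_points=len(t))


@dataclass
class ElementalComposition:
    """wt% of dried cells; O is derived by difference (ash constant included)."""

    C: float
    H: float
    N: float
    S: float = 0.0
    ash_wt_pct: float = ASH_WT_PCT
    O: float = field(init=False, default=float("nan"))

    def __post_init__(self) -> None:
        if min(self.C, self.H, self.N, self.S) < 0:
            raise StoichiometryError("weight percentages must be >= 0")
        self.O = oxygen_by_difference(self.C, self.H, self.N, self.ash_wt_pct)


def oxygen_by_difference(
    c_wt: float, h_wt: float, n_wt: float, ash_wt: float = ASH_WT_PCT
) -> float:
    """O wt% = 100 − C − H − N − ash (S is inside the ash constant)."""
    o = 100.0 - c_wt - h_wt - n_wt - ash_wt
    if o < 0:
        raise StoichiometryError(
            f"inconsistent elemental analysis: C+H+N+ash = {100 - o:.2f} wt% > 100"
        )
    return o


def degree_of_reduction(formula: dict[str, float], charge: float = 0.0) -> float:
    """Available electrons per mole: γ = 4C + H − 2O − 3N + 6S − charge."""
    gamma = 0.0
    for el, n in formula.items():
        if el not in GAMMA_COEFF:
            raise StoichiometryError(f"unsupported element {el!r} in formula")
        gamma += GAMMA_COEFF[el] * n
    return gamma - charge


def acceptor_demand(
    substrate_mmol: float,
    substrate_gamma: float,
    biomass_c_mmol: float,
    biomass_gamma_per_c: float,
    acceptor: str,
) -> float:
    """Predicted acceptor consumption (mmol) from the electron ledger.

    Dissimilated electrons = substrate electrons − electrons retained in
    assimilated biomass carbon; the acceptor takes 5 e⁻ per NO₃⁻ (full
    denitrification to N₂), 4 per O₂, or 3 per NO₂⁻ when accounting for the
    nitrite intermediate separately.
    """
    if acceptor not in ACCEPTOR_ELECTRONS:
        raise StoichiometryError(f"unknown acceptor {acceptor!r}")
    if min(substrate_mmol, biomass_c_mmol) < 0:
        raise StoichiometryError("electron ledger inputs must be >= 0")
    electrons = substrate_mmol * substrate_gamma - biomass_c_mmol * biomass_gamma_per_c
    if electrons < 0:
        raise StoichiometryError(
            "assimilated electrons exceed substrate supply; check the ledger inputs"
        )
    return electrons / ACCEPTOR_ELECTRONS[acceptor]


def carbon_yield(
    delta_cdw_g_per_l: float,
    biomass_c_wt_pct: float,
    delta_substrate_mM: float,
    substrate_c_atoms: float,
) -> float:
    """C/C yield in percent: biomass carbon formed over substrate carbon consumed."""
    if delta_substrate_mM <= 0:
        raise StoichiometryError("substrate consumption must be > 0")
    if delta_cdw_g_per_l < 0:
        raise StoichiometryError("CDW change must be >= 0")
    biomass_c_mmol = 1000.0 * delta_cdw_g_per_l * (biomass_c_wt_pct / 100.0) / CARBON_MASS
    substrate_c_mmol = delta_substrate_mM * substrate_c_atoms
    return 100.0 * biomass_c_mmol / substrate_c_mmol


def yield_from_curve(
    curve: GrowthCurve,
    biomass_c_wt_pct: float,
    substrate_c_atoms: float,
) -> float:
    """C/C yield (%) by linear regression over the whole curve.

    Regresses remaining substrate carbon on biomass carbon across all
    sampling points (slope = −1/yield); the intercept absorbs the noisy
    initial readings, so no single measurement anchors the estimate, and
    per-point noise averages down compared to endpoint deltas.
    """
    if curve.substrate_mM is None:
        raise StoichiometryError("curve has no substrate series")
    bio_c = 1000.0 * curve.cdw * (biomass_c_wt_pct / 100.0) / CARBON_MASS
    sub_c = curve.substrate_mM * substrate_c_atoms
    if float(np.ptp(bio_c)) == 0.0:
        raise StoichiometryError("no biomass formation in curve")
    slope, _ = np.polyfit(bio_c, sub_c, 1)
    if slope >= 0:
        raise StoichiometryError("substrate does not decrease with growth")
    return -100.0 / float(slope)


@dataclass
class StoichiometrySummary:
    """Headline physiological parameters of one growth experiment."""

    mu: float  # h⁻¹
    t_d: float  # h
    q_c_per_x: float  # mmol C·gCDW⁻¹·h⁻¹
    q_h_per_x: float  # mmol e⁻ ([H] equivalents)·gCDW⁻¹·h⁻¹
    yield_cc: float  # %
    dissimilated_fraction: float  # % of consumed carbon
    predicted_acceptor_mM: float


def summarize(
    curve: GrowthCurve,
    *,
    substrate_formula: dict[str, float],
    substrate_charge: float = 0.0,
    biomass_c_wt_pct: float,
    biomass_gamma_per_c: float,
    acceptor: str,
    window: tuple[float, float] | None = None,
) -> StoichiometrySummary:
    """End-to-end evaluation of one growth experiment.

    Fits μ, estimates the C/C yield by regression, then closes the electron
    ledger to predict acceptor consumption per litre of culture.
    """
    fit = fit_growth_rate(curve, window)
    n_c = substrate_formula.get("C", 0.0)
    if n_c <= 0:
        raise StoichiometryError("substrate formula must contain carbon")
    y = yield_from_curve(curve, biomass_c_wt_pct, n_c)
    if curve.substrate_mM is None:
        raise StoichiometryError("curve has no substrate series")
    delta_sub = float(curve.substrate_mM[0] - curve.substrate_mM[-1])
    delta_cdw = float(curve.cdw[-1] - curve.cdw[0])
    if delta_sub <= 0 or delta_cdw <= 0:
        raise StoichiometryError("no net growth/consumption in curve")
    # biomass-specific rates during exponential growth: q = μ × (consumed per
    # g CDW formed); ΔS in mM is mmol per litre, ΔCDW in g per litre.
    gamma_s = degree_of_reduction(substrate_formula, substrate_charge)
    q_c = fit.mu * delta_sub * n_c / delta_cdw  # mmol C·gCDW⁻¹·h⁻¹
    q_h = fit.mu * delta_sub * gamma_s / delta_cdw  # mmol e⁻·gCDW⁻¹·h⁻¹
    biomass_c_mmol = 1000.0 * delta_cdw * (biomass_c_wt_pct / 100.0) / CARBON_MASS
    acceptor_mmol = acceptor_demand(
        delta_sub, gamma_s, biomass_c_mmol, biomass_gamma_per_c, acceptor
    )
    return StoichiometrySummary(
        mu=fit.mu,
        t_d=fit.t_d,
        q_c_per_x=q_c,
        q_h_per_x=q_h,
        yield_cc=y,
        dissimilated_fraction=100.0 - y,
        predicted_acceptor_mM=acceptor_mmol,
    )
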