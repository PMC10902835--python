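"""Gaussian and augmented fluctuation theories for cavity occupancy statistics.

The interpolated Gaussian fluctuation theory (IGFT) models the probability
p_n of finding n solvent molecules in a spherical cavity of radius R as a
normalized Gaussian with mean ⟨n⟩ = ρ·4πR³/3 and variance σ² = χ(R)·⟨n⟩.
The normalized variance χ(R) interpolates between exact sub-diameter
statistics (a cavity smaller than the solvent diameter holds at most one
molecular center, so the occupancy is Bernoulli and χ = 1 − ρv) and the
macroscopic compressibility limit χ∞ = ρ k_B T κ_T. For 2R > d_ww the
deficit χ − χ∞ is expanded in surface powers of d_ww/2R with the two
coefficients fixed by value and slope continuity at 2R = d_ww:

    χ(R) = χ∞ + a·u + b·u²,  u = d_ww/(2R),
    a = 2(1 − η − χ∞) − 3η,  b = 3η − (1 − η − χ∞),

where η = πρd_ww³/6 is the solvent packing fraction.

The augmented fluctuation theory (AFT) joins the Gaussian branch, at the
nucleation occupancy n*, to a bubble branch in which emptying the cavity
costs pressure-volume work plus surface tension acting on an effective
(Tolman-shifted) bubble surface:

    βμ_n = Z(⟨n⟩ − n) + βγ·4π(R_b + ΔR)² + ε,   n < n*,

with Z = βP/ρ, R_b = (3(⟨n⟩−n)/4πρ)^{1/3}, ΔR = (3/4πρ)^{1/3}·δ, and ε
fixed by continuity at n*. n* itself is the occupancy at which the
per-molecule removal work is equal along the two paths; its defining
equation is a quintic in R_b, solved numerically or by a second-order
series in Z and δ.

All free energies here are in units of k_B T; n is treated as continuous.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from . import constants

__all__ = [
    "TheoryInputs",
    "GaussianModel",
    "BubbleState",
    "chi_igft",
    "mean_occupancy",
    "gaussian_model",
    "mu_n_gaussian",
    "mu0_igft",
    "bubble_geometry",
    "delta_r_increment",
    "mu_n_bubble",
    "removal_work_gaussian",
    "removal_work_bubble",
    "n_star_numeric",
    "n_star_series",
    "mu_n_aft",
    "mu0_aft",
    "fit_delta",
    "corrected_surface_tension",
]

#: experimental slope of water's vapor-liquid surface tension near 25 °C,
#: in dyn/cm per K; used to shift a reference tension between temperatures.
WATER_DGAMMA_DT = -0.1514


def corrected_surface_tension(
    gamma_ref: float = 66.0, t_ref: float = 300.0, temperature: float = 298.15
) -> float:
    """Shift a reference surface tension (dyn/cm) to ``temperature``.

    Uses the experimental temperature dependence of water's surface tension
    (slope −0.1514 dyn/cm/K near ambient). The default arguments move the
    mW model's 66.0 dyn/cm at 300 K to 25 °C.
    """
    return gamma_ref + WATER_DGAMMA_DT * (temperature - t_ref)


@dataclass(frozen=True)
class TheoryInputs:
    """Thermodynamic state and model parameters for the theory layer.

    temperature : K
    pressure    : atm
    rho         : bulk number density, Å⁻³
    kappa_T     : isothermal compressibility, atm⁻¹
    d_ww        : effective solvent diameter, Å
    gamma       : surface tension, dyn/cm
    delta       : dimensionless Tolman-like parameter
    """

    temperature: float = 298.15
    pressure: float = 1.0
    rho: float = 0.033326
    kappa_T: float = 4.58e-5
    d_ww: float = 2.65
    gamma: float = 66.3
    delta: float = 0.83

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.kappa_T <= 0:
            raise ValueError("kappa_T must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.eta >= 1:
            raise ValueError("packing fraction must be below 1")

    @property
    def beta(self) -> float:
        return constants.beta(self.temperature)

    @property
    def Z(self) -> float:
        """Compressibility factor βP/ρ (dimensionless)."""
        return self.beta * constants.pressure_to_internal(self.pressure) / self.rho

    @property
    def eta(self) -> float:
        """Solvent packing fraction πρd_ww³/6."""
        return math.pi * self.rho * self.d_ww**3 / 6.0

    @property
    def chi_inf(self) -> float:
        """Macroscopic normalized variance ρ k_B T κ_T."""
        return (
            self.rho
            * constants.kT(self.temperature)
            * constants.compressibility_to_internal(self.kappa_T)
        )

    @property
    def beta_gamma(self) -> float:
        """βγ in Å⁻²."""
        return self.beta * constants.surface_tension_to_internal(self.gamma)

    def with_delta(self, delta: float) -> "TheoryInputs":
        return TheoryInputs(
            self.temperature, self.pressure, self.rho, self.kappa_T,
            self.d_ww, self.gamma, delta,
        )


def mean_occupancy(R: float, inputs: TheoryInputs) -> float:
    """Mean cavity occupancy ⟨n⟩ = ρ·4πR³/3."""
    if R <= 0:
        raise ValueError("R must be positive")
    return inputs.rho * 4.0 * math.pi * R**3 / 3.0


def chi_igft(R: float, inputs: TheoryInputs) -> float:
    """Normalized occupancy variance χ(R) = σ²/⟨n⟩ of IGFT.

    Exact Bernoulli statistics χ = 1 − ρv for 2R ≤ d_ww, joined with
    continuous value and slope to a surface expansion in d_ww/2R that decays
    to the compressibility limit χ∞ as R → ∞.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    chi_inf = inputs.chi_inf
    eta = inputs.eta
    u = inputs.d_ww / (2.0 * R)
    if u >= 1.0:
        return 1.0 - eta / u**3  # = 1 − ρ·4πR³/3
    s = 1.0 - eta - chi_inf
    a = 2.0 * s - 3.0 * eta
    b = 3.0 * eta - s
    return chi_inf + a * u + b * u * u


@dataclass(frozen=True)
class GaussianModel:
    """Gaussian occupancy model: mean ⟨n⟩, normalized variance χ, σ² = χ⟨n⟩."""

    mean: float
    chi: float

    def __post_init__(self) -> None:
        if self.chi <= 0 or self.mean <= 0:
            raise ValueError("mean and chi must be positive")

    @property
    def sigma2(self) -> float:
        return self.chi * self.mean


def gaussian_model(R: float, inputs: TheoryInputs) -> GaussianModel:
    return GaussianModel(mean=mean_occupancy(R, inputs), chi=chi_igft(R, inputs))


def mu_n_gaussian(n, R: float, inputs: TheoryInputs):
    """Gaussian-branch free energy βμ_n = (n−⟨n⟩)²/2σ² + ½ln(2πσ²), in k_B T."""
    m = gaussian_model(R, inputs)
    n = np.asarray(n, dtype=np.float64)
    out = (n - m.mean) ** 2 / (2.0 * m.sigma2) + 0.5 * math.log(
        2.0 * math.pi * m.sigma2
    )
    return out if out.ndim else float(out)


def mu0_igft(R: float, inputs: TheoryInputs) -> float:
    """IGFT empty-cavity hydration free energy βμ0 = ⟨n⟩/2χ + ½ln(2πχ⟨n⟩)."""
    m = gaussian_model(R, inputs)
    return m.mean / (2.0 * m.chi) + 0.5 * math.log(2.0 * math.pi * m.sigma2)


# ---------------------------------------------------------------------------
# bubble branch
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BubbleState:
    """Geometry of the empty bubble carved out of a partially filled cavity."""

    V_bubble: float  # Å³
    R_bubble: float  # Å
    DeltaR: float  # Å

    @property
    def R_eff(self) -> float:
        return self.R_bubble + self.DeltaR

    @property
    def A_eff(self) -> float:
        return 4.0 * math.pi * self.R_eff**2


def delta_r_increment(inputs: TheoryInputs) -> float:
    """Tolman-like radial increment ΔR = (3/4πρ)^{1/3}·δ in Å."""
    return (3.0 / (4.0 * math.pi * inputs.rho)) ** (1.0 / 3.0) * inputs.delta


def bubble_geometry(n: float, R: float, inputs: TheoryInputs) -> BubbleState:
    """Bubble volume/radius for occupancy n: V = (⟨n⟩−n)/ρ, R_b = (3V/4π)^{1/3}."""
    mean = mean_occupancy(R, inputs)
    if n < 0 or n > mean:
        raise ValueError("occupancy must lie in [0, ⟨n⟩]; no bubble otherwise")
    v = (mean - n) / inputs.rho
    rb = (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
    return BubbleState(V_bubble=v, R_bubble=rb, DeltaR=delta_r_increment(inputs))


def mu_n_bubble(
    n: float, R: float, inputs: TheoryInputs, epsilon_continuity: float = 0.0
) -> float:
    """Bubble-branch free energy βμ_n = Z(⟨n⟩−n) + βγA_eff + ε, in k_B T."""
    st = bubble_geometry(n, R, inputs)
    mean = mean_occupancy(R, inputs)
    return inputs.Z * (mean - n) + inputs.beta_gamma * st.A_eff + epsilon_continuity


def removal_work_gaussian(n: float, R: float, inputs: TheoryInputs) -> float:
    """Gaussian path: work (k_B T) to remove one molecule, −dβμ_n/dn = (⟨n⟩−n)/σ²."""
    m = gaussian_model(R, inputs)
    return (m.mean - n) / m.sigma2


def removal_work_bubble(n: float, R: float, inputs: TheoryInputs) -> float:
    """Bubble path: −dβμ_n/dn = Z + 2βγ(R_b + ΔR)/(ρR_b²), in k_B T."""
    st = bubble_geometry(n, R, inputs)
    if st.R_bubble == 0.0:
        return math.inf
    return inputs.Z + 2.0 * inputs.beta_gamma * st.R_eff / (inputs.rho * st.R_bubble**2)


# ---------------------------------------------------------------------------
# nucleation occupancy n*
# ---------------------------------------------------------------------------


def n_star_numeric(R: float, inputs: TheoryInputs) -> float | None:
    """Nucleation occupancy: root of the Gaussian/bubble removal-work balance.

    The balance is a quintic in the bubble radius; it is bracketed by a sign
    scan over n in (0, ⟨n⟩) followed by bisection. Returns None when the
    formal root is negative (no bubble nucleates; fluctuations stay Gaussian).
    If several roots lie in the bracket the one closest to ⟨n⟩ — the first
    transition met on emptying — is returned with a warning.
    """
    mean = mean_occupancy(R, inputs)

    def f(n: float) -> float:
        return removal_work_gaussian(n, R, inputs) - removal_work_bubble(n, R, inputs)

    n_grid = np.linspace(0.0, mean, 257)[:-1]
    vals = np.array([f(x) for x in n_grid])
    sign_changes = [
        i for i in range(len(vals) - 1) if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0
    ]
    # For γ > 0 the bubble work diverges as n → ⟨n⟩, so f < 0 at the top of
    # the bracket; with γ = 0 the crossing may sit between the last grid
    # point and ⟨n⟩ itself (f(⟨n⟩⁻) → −Z).
    if vals[-1] > 0 and f(mean * (1.0 - 1e-12)) < 0:
        sign_changes.append(len(vals) - 1)
        n_grid = np.append(n_grid, mean * (1.0 - 1e-12))
        vals = np.append(vals, f(n_grid[-1]))
    if not sign_changes:
        return None  # f < 0 throughout: bubble path never cheaper above n = 0
    if len(sign_changes) > 1:
        warnings.warn(
            "multiple removal-work crossings; returning the one closest to ⟨n⟩",
            stacklevel=2,
        )
    i = sign_changes[-1]
    if vals[i] == 0.0:
        return float(n_grid[i])
    return float(brentq(f, n_grid[i], n_grid[i + 1], xtol=1e-12, rtol=1e-15))


def _series_terms(R: float, inputs: TheoryInputs):
    """Zeroth-order bubble radius and perturbation shifts for the n* series."""
    m = gaussian_model(R, inputs)
    c = 2.0 * inputs.beta_gamma / inputs.rho  # Å
    a_coef = 1.0 / m.sigma2
    b_coef = 4.0 * math.pi * inputs.rho / 3.0
    r0 = (c / (a_coef * b_coef)) ** 0.25
    dr = delta_r_increment(inputs)
    z = inputs.Z
    r1 = z * r0**2 / (4.0 * c) + dr / 4.0
    r2 = -(r1**2 + r1 * dr) / (2.0 * r0)
    return m, b_coef, r0, r1, r2


def n_star_series(R: float, inputs: TheoryInputs) -> float:
    """Second-order expansion of n* in the compressibility factor Z and δ.

    At Z = δ = 0 it reduces to the closed form
    n* = ⟨n⟩ − (4πρ/3)·[3βγσ²/(2πρ²)]^{3/4}.
    """
    m, b_coef, r0, r1, r2 = _series_terms(R, inputs)
    # (R0 + r1 + r2)³ expanded through second order in (Z, δ)
    rb3 = r0**3 * (1.0 + 3.0 * r1 / r0 + 3.0 * (r2 * r0 + r1**2) / r0**2)
    return m.mean - b_coef * rb3


# ---------------------------------------------------------------------------
# piecewise AFT free energy
# ---------------------------------------------------------------------------


def _epsilon_continuity(n_star: float, R: float, inputs: TheoryInputs) -> float:
    return float(mu_n_gaussian(n_star, R, inputs)) - mu_n_bubble(
        n_star, R, inputs, epsilon_continuity=0.0
    )


def mu_n_aft(n, R: float, inputs: TheoryInputs, *, series: bool = False):
    """AFT free energy βμ_n (k_B T): Gaussian for n ≥ n*, bubble for n < n*.

    The matching constant ε makes the two branches equal at n*; their first
    derivatives are equal there by the definition of n*. When no bubble is
    nucleated (n* is None) the Gaussian branch applies everywhere.
    """
    n_star = n_star_series(R, inputs) if series else n_star_numeric(R, inputs)
    n_arr = np.asarray(n, dtype=np.float64)
    scalar = n_arr.ndim == 0
    n_flat = np.atleast_1d(n_arr)
    out = np.asarray(mu_n_gaussian(n_flat, R, inputs), dtype=np.float64).copy()
    if n_star is not None and n_star > 0:
        eps = _epsilon_continuity(n_star, R, inputs)
        for i, x in enumerate(n_flat):
            if x < n_star:
                out[i] = mu_n_bubble(float(x), R, inputs, eps)
    return float(out[0]) if scalar else out


def mu0_aft(R: float, inputs: TheoryInputs, *, series: bool = False) -> float:
    """AFT empty-cavity free energy βμ0 = Z⟨n⟩ + βγ·4π(R_b(0)+ΔR)² + ε (k_B T)."""
    n_star = n_star_series(R, inputs) if series else n_star_numeric(R, inputs)
    if n_star is None or n_star <= 0:
        return mu0_igft(R, inputs)
    eps = _epsilon_continuity(n_star, R, inputs)
    return mu_n_bubble(0.0, R, inputs, eps)


def fit_delta(
    mu0_data, inputs: TheoryInputs, *, delta0: float = 0.5, series: bool = True
) -> tuple[float, np.ndarray]:
    """Fit the Tolman-like parameter δ to empty-cavity free-energy data.

    mu0_data : sequence of (R, βμ0ex) or (R, βμ0ex, err) tuples
    Returns (fitted δ, residual vector). Raises if fewer than 3 points are
    given or if the objective is flat in δ (no point ever nucleates a bubble,
    leaving δ unidentifiable).
    """
    rows = [tuple(row) for row in mu0_data]
    if len(rows) < 3:
        raise ValueError("need at least 3 (R, βμ0) points")
    radii = np.array([r[0] for r in rows])
    values = np.array([r[1] for r in rows])
    errs = np.array([r[2] if len(r) > 2 else 1.0 for r in rows])
    if np.any(errs <= 0):
        raise ValueError("errors must be positive")

    def predict(delta: float) -> np.ndarray:
        ti = inputs.with_delta(delta)
        return np.array([mu0_aft(R, ti, series=series) for R in radii])

    probe = np.linspace(0.0, 2.0, 9)
    preds = np.array([predict(d) for d in probe])
    if np.ptp(preds, axis=0).max() < 1e-12:
        raise ValueError("flat objective: δ is unidentifiable for these data")

    def resid(x: np.ndarray) -> np.ndarray:
        return (predict(float(x[0])) - values) / errs

    sol = least_squares(resid, x0=[delta0], method="lm", xtol=1e-14, ftol=1e-14)
    return float(sol.x[0]), sol.fun * errs
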