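"""Seeded synthetic-data generators used as exact oracles.

The ideal gas is the central reference: i.i.d. uniform particle placements
make the cavity occupancy exactly Poisson with mean ρ·4πR³/3, so every
stage of the pipeline (sampling, unbiasing, RDF accumulation, knitting) can
be checked against closed forms. Hard-sphere frames provide a cheap
*structured* solvent, and biased ideal-gas frames emulate umbrella windows
with a known unbiased answer.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import poisson

from . import constants, theory
from .forcefield import SolventFrame
from .mc import CavitySpec, MODEL_HS, _sweep
from .wham import PnDistribution

__all__ = [
    "generate_ideal_gas_fixture",
    "generate_hard_sphere_fixture",
    "generate_biased_ideal_gas",
    "synthetic_pn",
]


def generate_ideal_gas_fixture(
    rho: float, box: float, n_frames: int, seed: int, cavity_center=None
) -> list[SolventFrame]:
    """Ideal-gas frames: particle count Poisson(ρV), positions i.i.d. uniform."""
    if rho < 0 or box <= 0:
        raise ValueError("rho must be non-negative and box positive")
    rng = np.random.default_rng(seed)
    box_vec = np.full(3, float(box))
    center = np.full(3, box / 2.0) if cavity_center is None else np.asarray(cavity_center)
    volume = box**3
    frames = []
    for _ in range(n_frames):
        n = int(rng.poisson(rho * volume)) if rho > 0 else 0
        pos = rng.uniform(0.0, box, size=(n, 3))
        frames.append(SolventFrame(pos, box_vec.copy(), center.copy()))
    return frames


def generate_hard_sphere_fixture(
    rho: float,
    diameter: float,
    box: float,
    n_frames: int,
    seed: int,
    equilibration_sweeps: int = 200,
    thin: int = 5,
    cavity_center=None,
) -> list[SolventFrame]:
    """Metropolis-equilibrated non-overlapping hard-sphere configurations.

    Particles start on a cubic lattice (feasible only if the lattice spacing
    exceeds the diameter) and are evolved with single-particle displacement
    sweeps; every ``thin``-th post-equilibration sweep yields a frame.
    """
    if rho < 0 or box <= 0:
        raise ValueError("rho must be non-negative and box positive")
    rng = np.random.default_rng(seed)
    box_vec = np.full(3, float(box))
    center = np.full(3, box / 2.0) if cavity_center is None else np.asarray(cavity_center)
    n = int(round(rho * box**3))
    if n == 0:
        return [
            SolventFrame(np.zeros((0, 3)), box_vec.copy(), center.copy())
            for _ in range(n_frames)
        ]
    cells = math.ceil(n ** (1.0 / 3.0))
    spacing = box / cells
    if spacing <= diameter:
        raise ValueError(
            f"infeasible packing: lattice spacing {spacing:.3f} Å "
            f"does not exceed the diameter {diameter:.3f} Å"
        )
    grid = (np.indices((cells, cells, cells)).reshape(3, -1).T + 0.5) * spacing
    pos = np.ascontiguousarray(grid[:n], dtype=np.float64)
    jitter = min(0.3 * (spacing - diameter), 0.3 * spacing)
    pos = (pos + rng.uniform(-jitter, jitter, size=pos.shape)) % box

    params_dummy = np.zeros(10)
    step = 0.3 * diameter
    frames = []
    total_sweeps = equilibration_sweeps + n_frames * thin
    for sweep in range(total_sweeps):
        idx = rng.integers(n, size=n)
        disp = rng.uniform(-step, step, size=(n, 3))
        ur = rng.random(n)
        _sweep(
            MODEL_HS, pos, box_vec, center, 1.0, 0.0, 0.0, 1.0,
            params_dummy, diameter, idx, disp, ur, 0,
        )
        if sweep >= equilibration_sweeps and (sweep - equilibration_sweeps + 1) % thin == 0:
            frames.append(SolventFrame(pos.copy(), box_vec.copy(), center.copy()))
    return frames[:n_frames]


def generate_biased_ideal_gas(
    rho: float,
    box: float,
    cavity: CavitySpec,
    n_frames: int,
    seed: int,
    temperature: float = 298.15,
    n_cap: int | None = None,
):
    """Ideal-gas frames sampled under an occupancy umbrella — exactly.

    The occupancy is drawn from P(n) ∝ Poisson(ρv)·exp(−βW(n)); conditioned
    on n, the interior holds n i.i.d. uniform points in the sphere and the
    exterior a Poisson(ρ(V−v)) number of uniform points outside it, which is
    the exact biased ideal-gas ensemble. Returns (frames, occupancies).
    """
    rng = np.random.default_rng(seed)
    box_vec = np.full(3, float(box))
    center = np.full(3, box / 2.0)
    v_cav = 4.0 * math.pi * cavity.R**3 / 3.0
    if cavity.R >= box / 2.0:
        raise ValueError("cavity must fit inside half the box")
    mean_n = rho * v_cav
    beta = constants.beta(temperature)
    if n_cap is None:
        n_cap = int(mean_n + max(10.0, 8.0 * math.sqrt(max(mean_n, 1.0))))
    n_grid = np.arange(n_cap + 1)
    log_w = poisson.logpmf(n_grid, mean_n) - beta * 0.5 * cavity.k0 * (
        n_grid - cavity.n0
    ) ** 2
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    occupancies = rng.choice(n_grid, size=n_frames, p=w)

    frames = []
    for n in occupancies:
        inner = _uniform_in_sphere(rng, int(n), cavity.R) + center
        m = rng.poisson(rho * (box**3 - v_cav))
        outer = np.empty((m, 3))
        filled = 0
        while filled < m:
            cand = rng.uniform(0.0, box, size=(max(m - filled, 16), 3))
            d = cand - center
            d -= box_vec * np.round(d / box_vec)
            keep = cand[np.einsum("ij,ij->i", d, d) >= cavity.R**2]
            take = min(len(keep), m - filled)
            outer[filled : filled + take] = keep[:take]
            filled += take
        pos = np.vstack([inner, outer]) if (len(inner) or m) else np.zeros((0, 3))
        frames.append(SolventFrame(pos, box_vec.copy(), center.copy()))
    return frames, occupancies.astype(np.int64)


def _uniform_in_sphere(rng: np.random.Generator, n: int, R: float) -> np.ndarray:
    if n == 0:
        return np.zeros((0, 3))
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    radii = R * rng.random(n) ** (1.0 / 3.0)
    return pts * radii[:, None]


def synthetic_pn(kind: str, **params) -> PnDistribution:
    """Closed-form occupancy distributions for testing downstream estimators.

    kind='poisson' : mean
    kind='gaussian': mean, var (discretized and renormalized), optional n_max
    kind='aft'     : R plus a TheoryInputs via ``inputs`` (exp(−βμ_n^AFT))
    """
    if kind == "poisson":
        mean = params["mean"]
        n_max = params.get("n_max", int(mean + 10 * math.sqrt(mean) + 20))
        p = poisson.pmf(np.arange(n_max + 1), mean)
        return PnDistribution.from_unnormalized(p, provenance="theory")
    if kind == "gaussian":
        mean, var = params["mean"], params["var"]
        n_max = params.get("n_max", int(mean + 10 * math.sqrt(var) + 5))
        n = np.arange(n_max + 1)
        log_w = -((n - mean) ** 2) / (2.0 * var)
        return PnDistribution.from_log_weights(log_w, provenance="theory")
    if kind == "aft":
        R = params["R"]
        inputs = params.get("inputs") or theory.TheoryInputs()
        mean = theory.mean_occupancy(R, inputs)
        sig = math.sqrt(theory.gaussian_model(R, inputs).sigma2)
        n_max = params.get("n_max", int(mean + 8 * sig + 5))
        n = np.arange(n_max + 1, dtype=float)
        log_w = -np.asarray(theory.mu_n_aft(n, R, inputs))
        return PnDistribution.from_log_weights(log_w, provenance="theory")
    raise ValueError(f"unknown synthetic p_n kind {kind!r}")
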