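"""Metropolis Monte Carlo in the isothermal-isobaric (NPT) ensemble.

A single spherical cavity rides along with the solvent as a passive probe:
it exerts no forces on the particles, but a harmonic umbrella potential
W(n) = k0/2·(n − n0)² acting on its occupancy n biases sampling toward rare
(nearly empty or overfilled) states. Displacement, cavity-translation and
isotropic volume moves satisfy detailed balance with respect to
exp(−β(U + W + PV) + N ln V); move sizes are tuned toward a target
acceptance during equilibration only and frozen for production.

Solvent models: mW water (Stillinger-Weber), ideal gas (U ≡ 0, exact
Poisson occupancies) and hard spheres (U ∈ {0, +inf}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import constants
from .forcefield import (
    ForceFieldParams,
    SolventFrame,
    _local_energy_kernel,
    _insertion_energy_kernel,
    _total_energy_kernel,
    _min_image,
    hard_sphere_energy,
    insertion_energy,
    mw_params,
    total_energy,
)

__all__ = [
    "CavitySpec",
    "SimulationConfig",
    "OccupancyHistogram",
    "WindowResult",
    "MCState",
    "occupancy",
    "umbrella_energy",
    "displacement_move",
    "cavity_move",
    "volume_move",
    "widom_mu_ex",
    "run_window",
    "initial_state",
    "build_window_ladder",
]

MODEL_IDEAL, MODEL_HS, MODEL_MW = 0, 1, 2
_MODEL_CODES = {"ideal_gas": MODEL_IDEAL, "hard_sphere": MODEL_HS, "mW": MODEL_MW}


@dataclass(frozen=True)
class CavitySpec:
    """Spherical observation volume with optional occupancy umbrella.

    R  : cavity radius, Å
    k0 : umbrella spring constant, kJ/mol per occupancy²; 0 means unbiased
    n0 : umbrella center (occupancy at which the bias is minimal)
    """

    R: float
    k0: float = 0.0
    n0: float = 0.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("cavity radius must be positive")
        if self.k0 < 0:
            raise ValueError("k0 must be non-negative")


@dataclass
class SimulationConfig:
    temperature: float = 298.15  # K
    pressure: float = 1.0  # atm
    n_particles: int = 128
    solvent_model: str = "mW"
    seed: int = 0
    passes_equilibration: int = 500
    passes_production: int = 2000
    volume_move_interval: int = 5  # passes between volume moves
    target_acceptance: float = 0.3
    rho_init: float = 0.033326  # Å⁻³, initial number density
    hs_diameter: float = 2.65  # Å, hard-sphere model only
    cavity_moves_per_pass: int = 1
    frame_interval: int = 0  # passes between stored frames; 0 = none
    tune_interval: int = 50  # passes between step-size updates (equilibration)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.solvent_model not in _MODEL_CODES:
            raise ValueError(f"unknown solvent model {self.solvent_model!r}")
        if not 0 < self.target_acceptance < 1:
            raise ValueError("target_acceptance must lie in (0, 1)")
        if self.passes_equilibration < 0 or self.passes_production < 0:
            raise ValueError("pass counts must be non-negative")


@dataclass
class OccupancyHistogram:
    """Counts of sampled cavity occupancies for one umbrella window."""

    counts: np.ndarray  # index n -> count
    k0: float
    n0: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_samples(cls, samples, k0: float = 0.0, n0: float = 0.0):
        samples = np.asarray(samples, dtype=np.int64)
        counts = np.bincount(samples) if samples.size else np.zeros(1, dtype=np.int64)
        return cls(counts=counts, k0=k0, n0=n0)


def occupancy(frame: SolventFrame, cavity: CavitySpec) -> int:
    """Number of particle centers strictly inside the cavity (minimum image)."""
    if frame.n_particles == 0:
        return 0
    d = frame.positions - frame.cavity_center
    d -= frame.box_lengths * np.round(d / frame.box_lengths)
    return int(np.count_nonzero(np.einsum("ij,ij->i", d, d) < cavity.R**2))


def umbrella_energy(n: float, cavity: CavitySpec) -> float:
    """Harmonic bias W(n) = k0/2·(n − n0)², in kJ/mol."""
    return 0.5 * cavity.k0 * (n - cavity.n0) ** 2


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------


@dataclass
class MCState:
    frame: SolventFrame
    cavity: CavitySpec
    config: SimulationConfig
    params: ForceFieldParams | None = None
    energy: float = 0.0  # solvent-solvent potential energy, kJ/mol
    n_occ: int = 0
    step_disp: float = 0.3
    step_cavity: float = 0.3
    step_dv: float = 50.0  # Å³

    def __post_init__(self) -> None:
        self.n_occ = occupancy(self.frame, self.cavity)
        self.energy = self._total_energy()

    @property
    def beta(self) -> float:
        return constants.beta(self.config.temperature)

    @property
    def pressure_internal(self) -> float:
        return constants.pressure_to_internal(self.config.pressure)

    @property
    def model_code(self) -> int:
        return _MODEL_CODES[self.config.solvent_model]

    def _total_energy(self) -> float:
        if self.model_code == MODEL_IDEAL:
            return 0.0
        if self.model_code == MODEL_HS:
            return hard_sphere_energy(self.frame, self.config.hs_diameter)
        return total_energy(self.frame, self.params)

    def params_array(self) -> np.ndarray:
        if self.model_code == MODEL_MW:
            return self.params.as_array()
        return np.zeros(10)


def initial_state(
    config: SimulationConfig,
    cavity: CavitySpec,
    params: ForceFieldParams | None = None,
    rng: np.random.Generator | None = None,
) -> MCState:
    """Particles on a perturbed cubic lattice at rho_init, cavity at the center."""
    if config.solvent_model == "mW" and params is None:
        params = mw_params()
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_particles
    volume = n / config.rho_init if n else 1.0 / config.rho_init
    box = float(volume ** (1.0 / 3.0))
    cells = max(1, math.ceil(n ** (1.0 / 3.0)))
    spacing = box / cells
    coords = []
    for ix in range(cells):
        for iy in range(cells):
            for iz in range(cells):
                coords.append((ix + 0.5, iy + 0.5, iz + 0.5))
                if len(coords) == n:
                    break
            if len(coords) == n:
                break
        if len(coords) == n:
            break
    pos = np.asarray(coords, dtype=np.float64).reshape(n, 3) * spacing
    pos += rng.uniform(-0.05, 0.05, size=pos.shape) * spacing
    frame = SolventFrame(
        positions=pos,
        box_lengths=np.full(3, box),
        cavity_center=np.full(3, box / 2.0),
    )
    state = MCState(frame=frame, cavity=cavity, config=config, params=params)
    state.step_disp = min(0.3, box / 10.0)
    state.step_cavity = min(0.3, box / 10.0)
    state.step_dv = 0.02 * volume
    return state


# ---------------------------------------------------------------------------
# moves
# ---------------------------------------------------------------------------


@njit(cache=True)
def _inside(pos_x, pos_y, pos_z, cav, box, R2):
    dx, dy, dz = _min_image(pos_x - cav[0], pos_y - cav[1], pos_z - cav[2], box)
    return dx * dx + dy * dy + dz * dz < R2


@njit(cache=True)
def _hs_overlap_one(pos, box, i, xi, d2):
    n = pos.shape[0]
    for j in range(n):
        if j == i:
            continue
        dx, dy, dz = _min_image(
            pos[j, 0] - xi[0], pos[j, 1] - xi[1], pos[j, 2] - xi[2], box
        )
        if dx * dx + dy * dy + dz * dz < d2:
            return True
    return False


@njit(cache=True)
def _sweep(
    model, pos, box, cav, R, k0, n0, beta, p, hs_d, idx, disp, urand, n_occ
):
    """One pass of single-particle displacement moves. Returns (n, acc, dE)."""
    n_acc = 0
    de_total = 0.0
    r2 = R * R
    d2 = hs_d * hs_d
    new = np.empty(3, dtype=np.float64)
    for m in range(idx.shape[0]):
        i = idx[m]
        for c in range(3):
            new[c] = pos[i, c] + disp[m, c]
            new[c] -= box[c] * math.floor(new[c] / box[c])
        if model == 2:
            du = _local_energy_kernel(pos, box, i, new, p) - _local_energy_kernel(
                pos, box, i, pos[i], p
            )
        elif model == 1:
            if _hs_overlap_one(pos, box, i, new, d2):
                continue  # infinite energy: always rejected
            du = 0.0
        else:
            du = 0.0
        was_in = _inside(pos[i, 0], pos[i, 1], pos[i, 2], cav, box, r2)
        now_in = _inside(new[0], new[1], new[2], cav, box, r2)
        n_new = n_occ + (1 if now_in else 0) - (1 if was_in else 0)
        dw = 0.5 * k0 * ((n_new - n0) ** 2 - (n_occ - n0) ** 2)
        arg = -beta * (du + dw)
        if arg >= 0.0 or urand[m] < math.exp(arg):
            pos[i, 0] = new[0]
            pos[i, 1] = new[1]
            pos[i, 2] = new[2]
            n_occ = n_new
            n_acc += 1
            de_total += du
    return n_occ, n_acc, de_total


def displacement_move(state: MCState, rng: np.random.Generator) -> bool:
    """Single-particle Metropolis displacement; returns the accepted flag."""
    if state.frame.n_particles == 0:
        return False
    i = int(rng.integers(state.frame.n_particles))
    disp = rng.uniform(-state.step_disp, state.step_disp, size=3)
    n_occ, n_acc, de = _sweep(
        state.model_code,
        state.frame.positions,
        state.frame.box_lengths,
        state.frame.cavity_center,
        state.cavity.R,
        state.cavity.k0,
        state.cavity.n0,
        state.beta,
        state.params_array(),
        state.config.hs_diameter,
        np.array([i], dtype=np.int64),
        disp.reshape(1, 3),
        rng.random(1),
        state.n_occ,
    )
    state.n_occ = int(n_occ)
    state.energy += de
    return bool(n_acc)


def cavity_move(state: MCState, rng: np.random.Generator) -> bool:
    """Translate the cavity; only the umbrella energy enters the acceptance."""
    disp = rng.uniform(-state.step_cavity, state.step_cavity, size=3)
    new_center = (state.frame.cavity_center + disp) % state.frame.box_lengths
    trial = SolventFrame(
        state.frame.positions, state.frame.box_lengths, new_center
    )
    n_new = occupancy(trial, state.cavity)
    dw = umbrella_energy(n_new, state.cavity) - umbrella_energy(
        state.n_occ, state.cavity
    )
    if dw <= 0 or rng.random() < math.exp(-state.beta * dw):
        state.frame.cavity_center = new_center
        state.n_occ = n_new
        return True
    return False


def volume_move(state: MCState, rng: np.random.Generator) -> bool:
    """Isotropic box rescale with the standard NPT acceptance rule.

    acc = exp(−β(ΔU + ΔW + PΔV) + N ln(V'/V)); the umbrella term is
    re-evaluated because occupancy can change on rescale.
    """
    frame = state.frame
    n = frame.n_particles
    v_old = float(np.prod(frame.box_lengths))
    v_new = v_old + rng.uniform(-state.step_dv, state.step_dv)
    if v_new <= 0:
        return False
    scale = (v_new / v_old) ** (1.0 / 3.0)
    trial = SolventFrame(
        frame.positions * scale,
        frame.box_lengths * scale,
        frame.cavity_center * scale,
    )
    if state.model_code == MODEL_MW and np.min(trial.box_lengths) < 2 * state.params.r_cut:
        return False
    if state.model_code == MODEL_IDEAL:
        u_new = 0.0
    elif state.model_code == MODEL_HS:
        u_new = hard_sphere_energy(trial, state.config.hs_diameter)
        if math.isinf(u_new):
            return False
    else:
        u_new = total_energy(trial, state.params)
    n_new = occupancy(trial, state.cavity)
    dw = umbrella_energy(n_new, state.cavity) - umbrella_energy(
        state.n_occ, state.cavity
    )
    arg = (
        -state.beta * (u_new - state.energy + dw + state.pressure_internal * (v_new - v_old))
        + n * math.log(v_new / v_old)
    )
    if arg >= 0 or rng.random() < math.exp(arg):
        state.frame = trial
        state.energy = u_new
        state.n_occ = n_new
        return True
    return False


# ---------------------------------------------------------------------------
# Widom insertion
# ---------------------------------------------------------------------------


def widom_mu_ex(
    frames,
    trials_per_frame: int,
    rng: np.random.Generator,
    temperature: float,
    *,
    params: ForceFieldParams | None = None,
    hs_radius: float | None = None,
):
    """Excess chemical potential by Widom test-particle insertion.

    For an interacting test particle pass ``params``; for a hard-sphere probe
    of radius R pass ``hs_radius`` (the Boltzmann factor is then 1 when no
    solvent center lies within R, yielding the empty-cavity probability p0
    and hence the empty-cavity μ0ex of small cavities).

    Returns (mu_ex kJ/mol, standard error kJ/mol, all_zero flag); when every
    Boltzmann factor vanishes mu_ex is +inf and the flag is set.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    if (params is None) == (hs_radius is None):
        raise ValueError("pass exactly one of params or hs_radius")
    kbt = constants.kT(temperature)
    beta = 1.0 / kbt
    frame_means = np.empty(len(frames))
    for fi, frame in enumerate(frames):
        points = rng.uniform(0.0, 1.0, size=(trials_per_frame, 3)) * frame.box_lengths
        if hs_radius is not None:
            if hs_radius == 0.0 or frame.n_particles == 0:
                frame_means[fi] = 1.0
                continue
            d = frame.positions[None, :, :] - points[:, None, :]
            d -= frame.box_lengths * np.round(d / frame.box_lengths)
            vacant = np.all(
                np.einsum("mnc,mnc->mn", d, d) >= hs_radius**2, axis=1
            )
            frame_means[fi] = vacant.mean()
        else:
            vals = np.empty(trials_per_frame)
            for ti, pt in enumerate(points):
                du = insertion_energy(frame, pt, params)
                vals[ti] = math.exp(-beta * du) if du < math.inf else 0.0
            frame_means[fi] = vals.mean()
    mean = float(frame_means.mean())
    if mean <= 0.0:
        return math.inf, math.inf, True
    se_mean = (
        float(frame_means.std(ddof=1) / math.sqrt(len(frames)))
        if len(frames) > 1
        else 0.0
    )
    mu = -kbt * math.log(mean)
    return mu, kbt * se_mean / mean, False


# ---------------------------------------------------------------------------
# window driver
# ---------------------------------------------------------------------------


@dataclass
class WindowResult:
    histogram: OccupancyHistogram
    records: np.ndarray  # structured: pass, n, volume, energy
    frames: list = field(default_factory=list)
    acceptance: dict = field(default_factory=dict)


def run_window(
    config: SimulationConfig,
    cavity: CavitySpec,
    params: ForceFieldParams | None = None,
    state: MCState | None = None,
) -> WindowResult:
    """Equilibrate then sample one umbrella window.

    Move sizes are tuned toward the target acceptance during equilibration
    only and frozen for production (tuning during production would break
    detailed balance). Occupancy is recorded once per production pass;
    frames every ``frame_interval`` passes when that is nonzero.
    """
    rng = np.random.default_rng(config.seed)
    if state is None:
        state = initial_state(config, cavity, params=params, rng=rng)
    n = config.n_particles
    p_arr = state.params_array()

    acc_counts = {"disp": 0, "disp_try": 0, "cav": 0, "cav_try": 0, "vol": 0, "vol_try": 0}
    tune_acc = {"disp": 0, "disp_try": 0, "cav": 0, "cav_try": 0, "vol": 0, "vol_try": 0}

    samples = []
    records = []
    frames = []

    total_passes = config.passes_equilibration + config.passes_production
    for ip in range(total_passes):
        production = ip >= config.passes_equilibration
        if n:
            idx = rng.integers(n, size=n)
            disp = rng.uniform(-state.step_disp, state.step_disp, size=(n, 3))
            ur = rng.random(n)
            n_occ, n_acc, de = _sweep(
                state.model_code,
                state.frame.positions,
                state.frame.box_lengths,
                state.frame.cavity_center,
                cavity.R,
                cavity.k0,
                cavity.n0,
                state.beta,
                p_arr,
                config.hs_diameter,
                idx,
                disp,
                ur,
                state.n_occ,
            )
            state.n_occ = int(n_occ)
            state.energy += de
            tune_acc["disp"] += int(n_acc)
            tune_acc["disp_try"] += n
            if production:
                acc_counts["disp"] += int(n_acc)
                acc_counts["disp_try"] += n
        for _ in range(config.cavity_moves_per_pass):
            ok = cavity_move(state, rng)
            tune_acc["cav"] += ok
            tune_acc["cav_try"] += 1
            if production:
                acc_counts["cav"] += ok
                acc_counts["cav_try"] += 1
        if config.volume_move_interval and (ip + 1) % config.volume_move_interval == 0:
            ok = volume_move(state, rng)
            tune_acc["vol"] += ok
            tune_acc["vol_try"] += 1
            if production:
                acc_counts["vol"] += ok
                acc_counts["vol_try"] += 1
        if not production and (ip + 1) % config.tune_interval == 0:
            _tune_steps(state, tune_acc, config.target_acceptance)
            for key in tune_acc:
                tune_acc[key] = 0
        if production:
            samples.append(state.n_occ)
            records.append(
                (
                    ip - config.passes_equilibration,
                    state.n_occ,
                    float(np.prod(state.frame.box_lengths)),
                    state.energy,
                )
            )
            if config.frame_interval and (ip + 1) % config.frame_interval == 0:
                frames.append(state.frame.copy())

    hist = OccupancyHistogram.from_samples(samples, k0=cavity.k0, n0=cavity.n0)
    rec = np.array(
        records,
        dtype=[("pass", "i8"), ("n", "i8"), ("volume", "f8"), ("energy", "f8")],
    )
    rates = {
        key: (acc_counts[key] / acc_counts[key + "_try"] if acc_counts[key + "_try"] else 0.0)
        for key in ("disp", "cav", "vol")
    }
    return WindowResult(histogram=hist, records=rec, frames=frames, acceptance=rates)


def _tune_steps(state: MCState, acc: dict, target: float) -> None:
    box_cap = float(np.min(state.frame.box_lengths)) / 4.0
    for key, attr in (("disp", "step_disp"), ("cav", "step_cavity")):
        tries = acc[key + "_try"]
        if not tries:
            continue
        rate = acc[key] / tries
        factor = 1.1 if rate > target else 1.0 / 1.1
        setattr(state, attr, float(np.clip(getattr(state, attr) * factor, 1e-3, box_cap)))
    if acc["vol_try"]:
        rate = acc["vol"] / acc["vol_try"]
        factor = 1.1 if rate > target else 1.0 / 1.1
        v_now = float(np.prod(state.frame.box_lengths))
        state.step_dv = float(np.clip(state.step_dv * factor, 1e-3, v_now))


def build_window_ladder(
    n_max: float,
    *,
    delta_n0: float = 2.0,
    k0_min: float = 2.5,
    k0_max: float = 9.0,
    overrides: dict | None = None,
) -> list[tuple[float, float]]:
    """Umbrella window centers and spring constants: n0 from 0 up in steps of 2.

    k0 interpolates linearly from k0_max at n0 = 0 down to k0_min at the top
    of the ladder (stiffer springs are needed as the cavity is emptied).
    ``overrides`` maps n0 -> k0 for manual adjustment.
    """
    if n_max <= 0:
        raise ValueError("n_max must be positive")
    centers = np.arange(0.0, n_max + delta_n0, delta_n0)
    span = max(centers[-1], 1.0)
    ladder = []
    for n0 in centers:
        k0 = k0_max - (k0_max - k0_min) * (n0 / span)
        if overrides and n0 in overrides:
            k0 = overrides[n0]
        ladder.append((float(n0), float(k0)))
    return ladder
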