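"""Energy models for the solvent.

The production model is mW water: a Stillinger-Weber (SW) potential with a
two-body term and a three-body term that penalizes deviations from the
tetrahedral angle, mimicking directional hydrogen bonding without explicit
hydrogens. Both terms vanish smoothly (value and derivative) at the cutoff
``a_cut * sigma`` through the SW exponential switching factor.

Two reference solvents used as exact oracles are also provided: the ideal gas
(energy identically zero, cavity occupancies exactly Poisson) and hard spheres
(energy zero or +inf on overlap).

All energies are in kJ/mol and lengths in Å. Periodic boundary conditions use
the minimum-image convention in an orthorhombic box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "ForceFieldParams",
    "SolventFrame",
    "load_params",
    "mw_params",
    "pair_energy",
    "triplet_energy",
    "total_energy",
    "total_energy_bruteforce",
    "delta_energy",
    "insertion_energy",
    "hard_sphere_energy",
    "ideal_gas_energy",
]


@dataclass(frozen=True)
class ForceFieldParams:
    """Stillinger-Weber parameter set.

    epsilon : energy scale, kJ/mol
    sigma   : length scale, Å
    a_cut   : dimensionless cutoff multiplier; interactions vanish at a_cut*sigma
    A, B, p, q : two-body shape constants
    lambda3 : three-body strength
    gamma3  : three-body exponential decay
    cos_theta0 : cosine of the preferred bond angle
    """

    epsilon: float
    sigma: float
    a_cut: float
    A: float
    B: float
    p: float
    q: float
    lambda3: float
    gamma3: float
    cos_theta0: float

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.a_cut <= 1:
            raise ValueError("a_cut must exceed 1")

    @property
    def r_cut(self) -> float:
        """Interaction range a_cut * sigma in Å."""
        return self.a_cut * self.sigma

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.epsilon, self.sigma, self.a_cut, self.A, self.B, self.p,
             self.q, self.lambda3, self.gamma3, self.cos_theta0],
            dtype=np.float64,
        )


def load_params(path: str | Path) -> ForceFieldParams:
    """Read a flat ``key = value`` parameter file (# starts a comment)."""
    fields: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed parameter line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        fields[key] = float(value)
    return ForceFieldParams(**fields)


def mw_params() -> ForceFieldParams:
    """The versioned mW water parameter set shipped with the package."""
    with resources.as_file(
        resources.files("cavityfluc.data").joinpath("mw.params")
    ) as path:
        return load_params(path)


@dataclass
class SolventFrame:
    """One snapshot: particle positions, periodic box, and cavity center."""

    positions: np.ndarray  # (N, 3), Å
    box_lengths: np.ndarray  # (3,), Å
    cavity_center: np.ndarray  # (3,), Å

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        self.box_lengths = np.asarray(self.box_lengths, dtype=np.float64)
        self.cavity_center = np.asarray(self.cavity_center, dtype=np.float64)
        if np.any(self.box_lengths <= 0):
            raise ValueError("box lengths must be strictly positive")
        self.positions = self.positions % self.box_lengths
        self.cavity_center = self.cavity_center % self.box_lengths

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SolventFrame":
        return SolventFrame(
            self.positions.copy(), self.box_lengths.copy(), self.cavity_center.copy()
        )


# ---------------------------------------------------------------------------
# numba kernels (params packed as the array from ForceFieldParams.as_array)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _phi2(r, p):
    eps, sigma, a_cut = p[0], p[1], p[2]
    A, B, pexp, qexp = p[3], p[4], p[5], p[6]
    rc = a_cut * sigma
    if r >= rc:
        return 0.0
    sr = sigma / r
    return A * eps * (B * sr ** pexp - sr ** qexp) * math.exp(sigma / (r - rc))


@njit(cache=True)
def _h3(rij, rik, cos_theta, p):
    eps, sigma, a_cut = p[0], p[1], p[2]
    lam, gam, cos0 = p[7], p[8], p[9]
    rc = a_cut * sigma
    if rij >= rc or rik >= rc:
        return 0.0
    d = cos_theta - cos0
    return (
        lam * eps * d * d
        * math.exp(gam * sigma / (rij - rc))
        * math.exp(gam * sigma / (rik - rc))
    )


@njit(cache=True)
def _min_image(dx, dy, dz, box):
    dx -= box[0] * math.floor(dx / box[0] + 0.5)
    dy -= box[1] * math.floor(dy / box[1] + 0.5)
    dz -= box[2] * math.floor(dz / box[2] + 0.5)
    return dx, dy, dz


@njit(cache=True)
def _total_energy_kernel(pos, box, p):
    n = pos.shape[0]
    rc = p[2] * p[1]
    e2 = 0.0
    e3 = 0.0
    # neighbor displacement scratch per central particle
    ndx = np.empty(n, dtype=np.float64)
    ndy = np.empty(n, dtype=np.float64)
    ndz = np.empty(n, dtype=np.float64)
    nr = np.empty(n, dtype=np.float64)
    for i in range(n):
        cnt = 0
        for j in range(n):
            if j == i:
                continue
            dx, dy, dz = _min_image(
                pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1], pos[j, 2] - pos[i, 2], box
            )
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r < rc:
                if j > i:
                    e2 += _phi2(r, p)
                ndx[cnt] = dx
                ndy[cnt] = dy
                ndz[cnt] = dz
                nr[cnt] = r
                cnt += 1
        for a in range(cnt):
            for b in range(a + 1, cnt):
                cos_t = (
                    ndx[a] * ndx[b] + ndy[a] * ndy[b] + ndz[a] * ndz[b]
                ) / (nr[a] * nr[b])
                e3 += _h3(nr[a], nr[b], cos_t, p)
    return e2 + e3


@njit(cache=True)
def _local_energy_kernel(pos, box, i, xi, p):
    """Energy terms involving particle i placed at xi.

    Sum of pair terms (i,j), triplets centered on i, and triplets centered on
    any other particle j with i as one wing. The difference of this quantity
    for two positions of i equals the total-energy difference exactly.
    """
    n = pos.shape[0]
    rc = p[2] * p[1]
    e = 0.0
    ndx = np.empty(n, dtype=np.float64)
    ndy = np.empty(n, dtype=np.float64)
    ndz = np.empty(n, dtype=np.float64)
    nr = np.empty(n, dtype=np.float64)
    cnt = 0
    for j in range(n):
        if j == i:
            continue
        dx, dy, dz = _min_image(
            pos[j, 0] - xi[0], pos[j, 1] - xi[1], pos[j, 2] - xi[2], box
        )
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < rc:
            e += _phi2(r, p)
            ndx[cnt] = dx
            ndy[cnt] = dy
            ndz[cnt] = dz
            nr[cnt] = r
            cnt += 1
    for a in range(cnt):
        for b in range(a + 1, cnt):
            cos_t = (
                ndx[a] * ndx[b] + ndy[a] * ndy[b] + ndz[a] * ndz[b]
            ) / (nr[a] * nr[b])
            e += _h3(nr[a], nr[b], cos_t, p)
    # triplets centered on j with wings (i, k)
    for j in range(n):
        if j == i:
            continue
        dxi, dyi, dzi = _min_image(
            xi[0] - pos[j, 0], xi[1] - pos[j, 1], xi[2] - pos[j, 2], box
        )
        rji = math.sqrt(dxi * dxi + dyi * dyi + dzi * dzi)
        if rji >= rc:
            continue
        for k in range(n):
            if k == i or k == j:
                continue
            dxk, dyk, dzk = _min_image(
                pos[k, 0] - pos[j, 0], pos[k, 1] - pos[j, 1], pos[k, 2] - pos[j, 2], box
            )
            rjk = math.sqrt(dxk * dxk + dyk * dyk + dzk * dzk)
            if rjk >= rc:
                continue
            cos_t = (dxi * dxk + dyi * dyk + dzi * dzk) / (rji * rjk)
            e += _h3(rji, rjk, cos_t, p)
    return e


@njit(cache=True)
def _insertion_energy_kernel(pos, box, xi, p):
    """Energy of adding a test particle at xi to an existing configuration."""
    n = pos.shape[0]
    rc = p[2] * p[1]
    e = 0.0
    ndx = np.empty(n, dtype=np.float64)
    ndy = np.empty(n, dtype=np.float64)
    ndz = np.empty(n, dtype=np.float64)
    nr = np.empty(n, dtype=np.float64)
    cnt = 0
    for j in range(n):
        dx, dy, dz = _min_image(
            pos[j, 0] - xi[0], pos[j, 1] - xi[1], pos[j, 2] - xi[2], box
        )
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < rc:
            e += _phi2(r, p)
            ndx[cnt] = dx
            ndy[cnt] = dy
            ndz[cnt] = dz
            nr[cnt] = r
            cnt += 1
    for a in range(cnt):
        for b in range(a + 1, cnt):
            cos_t = (
                ndx[a] * ndx[b] + ndy[a] * ndy[b] + ndz[a] * ndz[b]
            ) / (nr[a] * nr[b])
            e += _h3(nr[a], nr[b], cos_t, p)
    for j in range(n):
        dxi, dyi, dzi = _min_image(
            xi[0] - pos[j, 0], xi[1] - pos[j, 1], xi[2] - pos[j, 2], box
        )
        rji = math.sqrt(dxi * dxi + dyi * dyi + dzi * dzi)
        if rji >= rc:
            continue
        for k in range(n):
            if k == j:
                continue
            dxk, dyk, dzk = _min_image(
                pos[k, 0] - pos[j, 0], pos[k, 1] - pos[j, 1], pos[k, 2] - pos[j, 2], box
            )
            rjk = math.sqrt(dxk * dxk + dyk * dyk + dzk * dzk)
            if rjk >= rc:
                continue
            cos_t = (dxi * dxk + dyi * dyk + dzi * dzk) / (rji * rjk)
            e += _h3(rji, rjk, cos_t, p)
    return e


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def pair_energy(r: float, params: ForceFieldParams) -> float:
    """SW two-body energy at separation r (Å), in kJ/mol.

    Vanishes (value and derivative) continuously at r = a_cut*sigma and is
    identically zero beyond.
    """
    if r <= 0:
        raise ValueError("separation must be positive")
    return float(_phi2(float(r), params.as_array()))


def triplet_energy(
    r_ij: np.ndarray, r_ik: np.ndarray, params: ForceFieldParams
) -> float:
    """SW three-body energy for wings j, k about a central particle (kJ/mol).

    Proportional to (cosθ_jik − cosθ0)²; zero if either wing lies at or
    beyond the cutoff.
    """
    r_ij = np.asarray(r_ij, dtype=np.float64)
    r_ik = np.asarray(r_ik, dtype=np.float64)
    rij = float(np.linalg.norm(r_ij))
    rik = float(np.linalg.norm(r_ik))
    if rij == 0.0 or rik == 0.0:
        raise ValueError("zero-length separation vector")
    cos_t = float(np.dot(r_ij, r_ik)) / (rij * rik)
    return float(_h3(rij, rik, cos_t, params.as_array()))


def _check_box(frame: SolventFrame, params: ForceFieldParams) -> None:
    if np.min(frame.box_lengths) < 2.0 * params.r_cut:
        raise ValueError(
            "box edge must be at least twice the interaction range "
            f"({2.0 * params.r_cut:.3f} Å) for minimum-image energies"
        )


def total_energy(frame: SolventFrame, params: ForceFieldParams) -> float:
    """Total SW energy: all pairs plus all distinct centered triplets (kJ/mol)."""
    _check_box(frame, params)
    if frame.n_particles < 2:
        return 0.0
    return float(
        _total_energy_kernel(frame.positions, frame.box_lengths, params.as_array())
    )


def total_energy_bruteforce(frame: SolventFrame, params: ForceFieldParams) -> float:
    """O(N³) pure-python reference sum; the oracle for total_energy."""
    _check_box(frame, params)
    pos = frame.positions
    box = frame.box_lengths
    n = pos.shape[0]

    def mi(v: np.ndarray) -> np.ndarray:
        return v - box * np.round(v / box)

    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(mi(pos[j] - pos[i])))
            if 0 < r < params.r_cut:
                e += pair_energy(r, params)
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            dij = mi(pos[j] - pos[i])
            if np.linalg.norm(dij) >= params.r_cut:
                continue
            for k in range(j + 1, n):
                if k == i:
                    continue
                dik = mi(pos[k] - pos[i])
                if np.linalg.norm(dik) >= params.r_cut:
                    continue
                e += triplet_energy(dij, dik, params)
    return e


def delta_energy(
    frame: SolventFrame,
    moved_index: int,
    new_position: np.ndarray,
    params: ForceFieldParams,
) -> float:
    """Energy change for moving one particle, via local sums (kJ/mol).

    Equals total_energy(after) − total_energy(before) up to floating
    accumulation.
    """
    if not 0 <= moved_index < frame.n_particles:
        raise IndexError("moved_index out of range")
    _check_box(frame, params)
    p = params.as_array()
    new_position = np.asarray(new_position, dtype=np.float64) % frame.box_lengths
    e_old = _local_energy_kernel(
        frame.positions, frame.box_lengths, moved_index, frame.positions[moved_index], p
    )
    e_new = _local_energy_kernel(
        frame.positions, frame.box_lengths, moved_index, new_position, p
    )
    return float(e_new - e_old)


def insertion_energy(
    frame: SolventFrame, position: np.ndarray, params: ForceFieldParams
) -> float:
    """Energy of inserting a test particle at ``position`` (kJ/mol)."""
    _check_box(frame, params)
    position = np.asarray(position, dtype=np.float64) % frame.box_lengths
    if frame.n_particles == 0:
        return 0.0
    return float(
        _insertion_energy_kernel(
            frame.positions, frame.box_lengths, position, params.as_array()
        )
    )


# --- reference solvents -----------------------------------------------------


def ideal_gas_energy(frame: SolventFrame) -> float:
    """Ideal-gas reference: no interactions, energy identically zero."""
    return 0.0


@njit(cache=True)
def _hs_overlap(pos, box, diameter):
    n = pos.shape[0]
    d2 = diameter * diameter
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy, dz = _min_image(
                pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1], pos[j, 2] - pos[i, 2], box
            )
            if dx * dx + dy * dy + dz * dz < d2:
                return True
    return False


def hard_sphere_energy(frame: SolventFrame, diameter: float) -> float:
    """Hard-sphere reference: 0 without overlaps, +inf with any overlap."""
    if frame.n_particles < 2:
        return 0.0
    if _hs_overlap(frame.positions, frame.box_lengths, diameter):
        return math.inf
    return 0.0
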