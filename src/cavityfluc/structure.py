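"""Structural diagnostics of cavity emptying.

The radius of gyration of the solvent density inside a cavity — the
density-weighted second moment of the interior g_n(r) profile about the
cavity center — tracks where the remaining waters sit. A uniform interior
gives R_g = sqrt(3/5)·R; as a bubble nucleates the waters first segregate
toward the center (R_g drops) and then adsorb onto the inner surface
(R_g rises back toward R), so the minimum of R_g(n) marks the nucleation
occupancy. A second estimator reads the same transition from the peak of
ln K_n (shifted up by 1/2 to compare with the continuous derivative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .knitting import OccupancyRDFSet

__all__ = [
    "RgProfile",
    "rg_from_gn",
    "rg_from_coordinates",
    "rg_profile",
    "n_star_from_rg",
    "n_star_from_lnK",
]


@dataclass
class RgProfile:
    """R_g(n) per occupancy with the uniform-sphere normalization."""

    n: np.ndarray  # occupancies with a defined R_g
    rg: np.ndarray  # Å
    R: float  # cavity radius, Å
    mean_occupancy: float

    @property
    def rg_uniform(self) -> float:
        """R_g of a uniform-density sphere, sqrt(3/5)·R."""
        return math.sqrt(3.0 / 5.0) * self.R

    @property
    def normalized(self) -> np.ndarray:
        return self.rg / self.rg_uniform

    @property
    def n_fraction(self) -> np.ndarray:
        return self.n / self.mean_occupancy


def rg_from_gn(gset: OccupancyRDFSet, n: int) -> float:
    """Interior radius of gyration from the g_n(r < R) profile, in Å.

    R_g² = ∫ g_n(r) r⁴ dr / ∫ g_n(r) r² dr over the cavity interior.
    Undefined (raises) for an empty interior.
    """
    if n == 0:
        raise ValueError("R_g undefined for the empty cavity (n = 0)")
    if n >= gset.g.shape[0] or np.all(np.isnan(gset.g[n])):
        raise ValueError(f"g_{n} not available")
    mask = gset.r < gset.R
    r = gset.r[mask]
    g = gset.g[n, mask]
    if not np.any(np.nan_to_num(g) > 0):
        raise ValueError(f"interior profile for n = {n} is empty")
    g = np.nan_to_num(g)
    num = np.sum(g * r**4)
    den = np.sum(g * r**2)
    return float(math.sqrt(num / den))


def rg_from_coordinates(frames, cavity_R: float) -> float:
    """Coordinate-space cross-check: RMS distance of interior particles from
    the cavity center, pooled over frames."""
    total = 0.0
    count = 0
    for frame in frames:
        d = frame.positions - frame.cavity_center
        d -= frame.box_lengths * np.round(d / frame.box_lengths)
        r2 = np.einsum("ij,ij->i", d, d)
        inside = r2 < cavity_R**2
        total += float(r2[inside].sum())
        count += int(inside.sum())
    if count == 0:
        raise ValueError("no interior particles in any frame")
    return math.sqrt(total / count)


def rg_profile(gset: OccupancyRDFSet, min_frames: int = 1) -> RgProfile:
    ns, rgs = [], []
    for n in range(1, gset.g.shape[0]):
        if gset.frame_counts[n] < min_frames:
            continue
        try:
            rgs.append(rg_from_gn(gset, n))
        except ValueError:
            continue
        ns.append(n)
    return RgProfile(
        n=np.asarray(ns),
        rg=np.asarray(rgs),
        R=gset.R,
        mean_occupancy=gset.mean_occupancy,
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    return np.convolve(padded, kernel, mode="valid")[: len(y)]


def n_star_from_rg(profile: RgProfile, smooth_window: int = 0) -> int | None:
    """Nucleation occupancy from the minimum of R_g(n).

    A 3-point discrete interior minimum is required; ties break toward
    larger n (closer to ⟨n⟩, where the transition is defined). Monotone
    profiles yield None.
    """
    order = np.argsort(profile.n)
    n_sorted = profile.n[order]
    rg = _smooth(profile.rg[order].astype(float), smooth_window)
    if len(rg) < 3:
        return None
    best = None
    for i in range(1, len(rg) - 1):
        if rg[i] <= rg[i - 1] and rg[i] <= rg[i + 1]:
            if best is None or rg[i] <= rg[best] + 1e-12:
                best = i
    if best is None:
        return None
    return int(n_sorted[best])


def n_star_from_lnK(ln_k, n_values=None, smooth_window: int = 0) -> float | None:
    """Nucleation occupancy from the peak of ln K_n, shifted up by 1/2.

    ln K_n approximates the (negative) derivative of βμ_n at n + 1/2, so the
    peak location plus 0.5 compares directly with the continuous-n theory.
    Strictly monotone (Gaussian, linear) sequences have no interior peak and
    yield None.
    """
    ln_k = np.asarray(ln_k, dtype=np.float64)
    if n_values is None:
        n_values = np.arange(len(ln_k))
    n_values = np.asarray(n_values)
    ok = np.isfinite(ln_k)
    ln_k, n_values = ln_k[ok], n_values[ok]
    if len(ln_k) < 3:
        return None
    y = _smooth(ln_k, smooth_window)
    best = None
    for i in range(1, len(y) - 1):
        if y[i] >= y[i - 1] and y[i] >= y[i + 1]:
            if y[i] == y[i - 1] and y[i] == y[i + 1]:
                continue  # flat plateau, not a peak
            if best is None or y[i] >= y[best] - 1e-12:
                best = i
    if best is None:
        return None
    return float(n_values[best]) + 0.5
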