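"""Occupancy-resolved RDFs and the knitting estimator of p_n.

The cavity-solvent radial distribution function conditioned on occupancy n,
g_n(r), jumps discontinuously across the cavity boundary: interior
normalization forces the average of g_{n+1}(r) over the cavity volume to be
(n+1)/(ρ·4πR³/3), while the exterior branch tends to 1. The cavity
correlation function y_n(r) — the Boltzmann factor of the potential of mean
force for bringing a solvent molecule to distance r from a cavity holding n
particles — is continuous, and relates the two branches through a constant:

    y_n(r ≤ R) = K_n · g_{n+1}(r),    y_n(r ≥ R) = g_n(r),

with K_n = p_{n+1}/p_n. Fitting a quadratic-plus-step model of −ln y_n over
a narrow band R ± 1 Å therefore measures ln K_n directly from structure,
and the chain p_n ∝ exp(Σ_{i<n} ln K_i) assembles the full occupancy
distribution. For the ideal gas this machinery closes exactly: y_n ≡ 1,
interior g_{n+1} = (n+1)/⟨n⟩, K_n = ⟨n⟩/(n+1) and p_n is Poisson(⟨n⟩).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .mc import CavitySpec
from .wham import PnDistribution

__all__ = [
    "OccupancyRDFSet",
    "KnitFit",
    "accumulate_gn",
    "knit_fit",
    "knit_all",
    "assemble_pn",
    "passivity_check",
    "ideal_gas_reference",
]


@dataclass
class OccupancyRDFSet:
    """Occupancy-resolved cavity-solvent RDFs on a uniform r-grid.

    g[n] holds g_n(r) at the bin centers ``r``; rows of all-NaN mark
    occupancy states with no frames (missing, never zero-filled).
    """

    r: np.ndarray  # bin centers, Å
    g: np.ndarray  # (n_max+1, n_bins)
    counts: np.ndarray  # raw pair counts per (n, bin)
    frame_counts: np.ndarray  # frames observed per n
    R: float  # cavity radius, Å
    rho: float  # bulk number density, Å⁻³
    meta: dict = field(default_factory=dict)

    @property
    def bin_width(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def mean_occupancy(self) -> float:
        return self.rho * 4.0 * math.pi * self.R**3 / 3.0

    def g_stderr(self, n: int) -> np.ndarray:
        """Poisson-counting standard error on g_n(r) per bin."""
        shell = _shell_volumes(self.r, self.bin_width)
        norm = self.frame_counts[n] * self.rho * shell
        return np.sqrt(np.maximum(self.counts[n], 1.0)) / norm

    def interior_mean(self, n: int) -> float:
        """Volume-weighted mean of g_n(r) over the cavity interior."""
        mask = self.r < self.R
        shell = _shell_volumes(self.r, self.bin_width)[mask]
        return float(np.sum(self.g[n, mask] * shell) / np.sum(shell))


def _shell_volumes(r_centers: np.ndarray, dr: float) -> np.ndarray:
    lo = r_centers - dr / 2.0
    hi = r_centers + dr / 2.0
    return 4.0 * math.pi / 3.0 * (hi**3 - np.maximum(lo, 0.0) ** 3)


def accumulate_gn(
    frames,
    occupancies,
    cavity: CavitySpec,
    rho: float,
    bin_width: float = 0.05,
    r_max: float | None = None,
    weights=None,
) -> OccupancyRDFSet:
    """Accumulate g_n(r) from occupancy-labelled frames.

    ``weights`` are per-frame unbias factors (exp(+β·umbrella)); because the
    umbrella depends only on n, they are constant within each occupancy state
    and pooling same-n frames from different windows is exact, but they are
    honored when supplied. Distance histograms are normalized by ideal shell
    volumes and the bulk density. Occupancy states with no frames are left
    as NaN rows.
    """
    frames = list(frames)
    occupancies = np.asarray(occupancies, dtype=np.int64)
    if len(frames) != len(occupancies):
        raise ValueError("frames and occupancy labels differ in length")
    if weights is None:
        weights = np.ones(len(frames))
    weights = np.asarray(weights, dtype=np.float64)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    if r_max is None:
        r_max = float(min(min(f.box_lengths) for f in frames)) / 2.0
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_max = int(occupancies.max()) if len(occupancies) else 0

    counts = np.zeros((n_max + 1, len(centers)))
    wframes = np.zeros(n_max + 1)
    raw_frames = np.zeros(n_max + 1, dtype=np.int64)
    for frame, n, w in zip(frames, occupancies, weights):
        d = frame.positions - frame.cavity_center
        d -= frame.box_lengths * np.round(d / frame.box_lengths)
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        hist, _ = np.histogram(r, bins=edges)
        counts[n] += w * hist
        wframes[n] += w
        raw_frames[n] += 1

    shell = _shell_volumes(centers, bin_width)
    g = np.full_like(counts, np.nan)
    seen = wframes > 0
    g[seen] = counts[seen] / (wframes[seen, None] * rho * shell[None, :])
    return OccupancyRDFSet(
        r=centers,
        g=g,
        counts=counts,
        frame_counts=raw_frames,
        R=cavity.R,
        rho=rho,
        meta={"bin_width": bin_width, "weighted": weights is not None},
    )


@dataclass(frozen=True)
class KnitFit:
    """Quadratic-plus-step fit of −ln y_n across the cavity boundary.

    −ln y_n(r) ≈ α2(r−R)² + α1(r−R) + α0 over R ± half_width, with the
    interior branch −ln g_{n+1} offset from it by +ln K_n; the fitted y_n is
    continuous at r = R by construction.
    """

    n: int
    alpha0: float
    alpha1: float
    alpha2: float
    ln_Kn: float
    half_width: float
    residual_norm: float
    n_bins: int

    def minus_ln_y(self, r: np.ndarray, R: float) -> np.ndarray:
        dr = np.asarray(r) - R
        return self.alpha2 * dr**2 + self.alpha1 * dr + self.alpha0


def knit_fit(
    gset: OccupancyRDFSet,
    n: int,
    half_width: float = 1.0,
    weighted: bool = True,
) -> KnitFit:
    """Fit ln K_n by knitting g_{n+1}(r < R) to g_n(r ≥ R).

    Simultaneous least squares of the quadratic-plus-step model to
    −ln g_{n+1} (interior) and −ln g_n (exterior) over R ± half_width.
    Bins with non-positive RDF values are excluded with a warning; fewer
    than 6 usable bins is an error. Per-bin weights default to the raw pair
    counts (inverse-variance weighting of −ln g); pass weighted=False for an
    unweighted fit.
    """
    if n + 1 >= gset.g.shape[0]:
        raise ValueError(f"g_{n+1} not available")
    if np.all(np.isnan(gset.g[n])) or np.all(np.isnan(gset.g[n + 1])):
        raise ValueError(f"missing RDF for occupancy state {n} or {n+1}")
    R = gset.R
    r = gset.r
    inside = (r < R) & (r >= R - half_width)
    outside = (r >= R) & (r <= R + half_width)

    rows, targets, wts, step = [], [], [], []
    dropped = 0
    for mask, gvals, cvals, is_interior in (
        (inside, gset.g[n + 1], gset.counts[n + 1], True),
        (outside, gset.g[n], gset.counts[n], False),
    ):
        for ri, gi, ci in zip(r[mask], gvals[mask], cvals[mask]):
            if not np.isfinite(gi) or gi <= 0:
                dropped += 1
                continue
            rows.append(ri - R)
            targets.append(-math.log(gi))
            wts.append(ci if weighted else 1.0)
            step.append(1.0 if is_interior else 0.0)
    if dropped:
        warnings.warn(
            f"knit_fit(n={n}): excluded {dropped} empty/non-positive bins",
            stacklevel=2,
        )
    if len(rows) < 6:
        raise ValueError(
            f"knit_fit(n={n}): only {len(rows)} usable bins in the fit range"
        )
    dr = np.asarray(rows)
    y = np.asarray(targets)
    w = np.sqrt(np.maximum(np.asarray(wts), 1e-12))
    # model: -ln g = alpha0 + alpha1*dr + alpha2*dr^2 + ln_Kn * step
    # (interior: -ln g_{n+1} = -ln y_n + ln K_n)
    design = np.column_stack([np.ones_like(dr), dr, dr**2, np.asarray(step)])
    coef, *_ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
    resid = design @ coef - y
    return KnitFit(
        n=n,
        alpha0=float(coef[0]),
        alpha1=float(coef[1]),
        alpha2=float(coef[2]),
        ln_Kn=float(coef[3]),
        half_width=half_width,
        residual_norm=float(np.linalg.norm(resid * w)),
        n_bins=len(rows),
    )


def knit_all(
    gset: OccupancyRDFSet,
    half_width: float = 1.0,
    min_frames: int = 100,
    weighted: bool = True,
) -> tuple[np.ndarray, list[KnitFit]]:
    """ln K_n for every adjacent pair of adequately sampled occupancy states.

    States with fewer than ``min_frames`` frames are excluded and reported as
    NaN; no interpolation is performed across missing states.
    """
    n_states = gset.g.shape[0]
    ln_k = np.full(n_states - 1, np.nan)
    fits: list[KnitFit] = []
    for n in range(n_states - 1):
        if gset.frame_counts[n] < min_frames or gset.frame_counts[n + 1] < min_frames:
            continue
        fit = knit_fit(gset, n, half_width=half_width, weighted=weighted)
        ln_k[n] = fit.ln_Kn
        fits.append(fit)
    return ln_k, fits


def assemble_pn(ln_k) -> PnDistribution:
    """Assemble p_n ∝ exp(Σ_{i<n} ln K_i) from a contiguous ln K sequence."""
    ln_k = np.asarray(ln_k, dtype=np.float64)
    bad = np.where(~np.isfinite(ln_k))[0]
    if bad.size:
        raise ValueError(f"missing interior state: ln K_{bad[0]} is not finite")
    log_w = np.concatenate([[0.0], np.cumsum(ln_k)])
    return PnDistribution.from_log_weights(log_w, provenance="knitting")


def passivity_check(
    gset: OccupancyRDFSet, p: PnDistribution, p_floor: float = 1e-6
):
    """Deviation of Σ_n p_n g_n(r) from 1 — the cavity is a passive probe.

    Only occupancy states with p_n above ``p_floor`` (renormalized) enter the
    sum. Returns (max |deviation|, deviation profile over r).
    """
    n_states = min(gset.g.shape[0], len(p.p))
    weightvec = p.p[:n_states].copy()
    keep = weightvec > p_floor
    for n in range(n_states):
        if keep[n] and np.all(np.isnan(gset.g[n])):
            raise ValueError(f"g_{n} missing but p_{n} above floor")
    weightvec[~keep] = 0.0
    weightvec /= weightvec.sum()
    avg = np.zeros_like(gset.r)
    for n in range(n_states):
        if weightvec[n] > 0:
            avg += weightvec[n] * gset.g[n]
    deviation = avg - 1.0
    return float(np.nanmax(np.abs(deviation))), deviation


def ideal_gas_reference(mean_n: float, n: int) -> dict:
    """Closed-form ideal-gas values: y_n ≡ 1, interior g_{n+1} = (n+1)/⟨n⟩,
    K_n = ⟨n⟩/(n+1), p_n = Poisson(⟨n⟩)."""
    if mean_n <= 0:
        raise ValueError("mean occupancy must be positive")
    if n < 0:
        raise ValueError("occupancy must be non-negative")
    return {
        "y_n": 1.0,
        "g_interior": (n + 1) / mean_n,
        "g_exterior": 1.0,
        "K_n": mean_n / (n + 1),
        "ln_K_n": math.log(mean_n / (n + 1)),
        "p_n": float(poisson.pmf(n, mean_n)),
    }
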