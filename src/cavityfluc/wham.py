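"""Weighted histogram analysis of occupancy-umbrella windows.

Each window w samples occupancies under a harmonic bias W_w(n); WHAM
reconstructs the unbiased distribution p_n by self-consistent iteration of

    p_n = Σ_w c_w(n) / Σ_w N_w exp(f_w − βW_w(n)),
    exp(−f_w) = Σ_n p_n exp(−βW_w(n)),

carried out in log space. From p_n follow the ln K_n = ln(p_{n+1}/p_n)
differentials and the empty-cavity hydration free energy −k_B T ln p_0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from . import constants
from .mc import OccupancyHistogram, umbrella_energy, CavitySpec

__all__ = [
    "PnDistribution",
    "WhamConvergenceError",
    "wham_combine",
    "mu_ex_from_p0",
    "ln_K_series",
    "bootstrap_pn_errors",
]


class WhamConvergenceError(RuntimeError):
    def __init__(self, iterations: int, residual: float):
        super().__init__(
            f"WHAM failed to converge after {iterations} iterations "
            f"(residual {residual:.3e})"
        )
        self.iterations = iterations
        self.residual = residual


@dataclass
class PnDistribution:
    """Normalized occupancy distribution over n = 0..n_max.

    ln K_n = ln p_{n+1} − ln p_n wherever both probabilities are finite;
    entries where either vanishes are NaN (flagged, never fabricated).
    """

    p: np.ndarray
    provenance: str = "wham"  # wham | knitting | theory
    stderr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if np.any(self.p < 0):
            raise ValueError("probabilities must be non-negative")
        total = self.p.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-10):
            raise ValueError("probabilities must sum to 1 within 1e-10")

    @property
    def n_max(self) -> int:
        return len(self.p) - 1

    @property
    def ln_K(self) -> np.ndarray:
        return ln_K_series(self.p)

    @classmethod
    def from_unnormalized(cls, weights, **kwargs) -> "PnDistribution":
        w = np.asarray(weights, dtype=np.float64)
        return cls(p=w / w.sum(), **kwargs)

    @classmethod
    def from_log_weights(cls, log_w, **kwargs) -> "PnDistribution":
        log_w = np.asarray(log_w, dtype=np.float64)
        return cls(p=np.exp(log_w - logsumexp(log_w)), **kwargs)


def mu_ex_from_p0(p0: float, temperature: float) -> float:
    """Empty-cavity hydration free energy −k_B T ln p0, in kJ/mol."""
    if not 0.0 < p0 <= 1.0:
        raise ValueError("p0 must lie in (0, 1]; an unsampled empty state "
                         "must be reported upstream")
    return -constants.kT(temperature) * math.log(p0)


def ln_K_series(p) -> np.ndarray:
    """Pairwise log-ratios ln(p_{n+1}/p_n); NaN where either entry is zero."""
    p = np.asarray(getattr(p, "p", p), dtype=np.float64)
    out = np.full(len(p) - 1, np.nan)
    with np.errstate(divide="ignore"):
        lo = np.log(p)
    ok = np.isfinite(lo[1:]) & np.isfinite(lo[:-1])
    out[ok] = lo[1:][ok] - lo[:-1][ok]
    return out


def _window_matrix(windows: list[OccupancyHistogram], temperature: float):
    n_max = max(len(w.counts) for w in windows) - 1
    counts = np.zeros((len(windows), n_max + 1))
    for i, w in enumerate(windows):
        counts[i, : len(w.counts)] = w.counts
    beta = constants.beta(temperature)
    n_grid = np.arange(n_max + 1, dtype=np.float64)
    bias = np.array(
        [
            beta * umbrella_energy(n_grid, CavitySpec(R=1.0, k0=w.k0, n0=w.n0))
            for w in windows
        ]
    )
    return counts, bias, n_grid


def wham_combine(
    windows,
    temperature: float,
    tolerance: float = 1e-8,
    max_iters: int = 100_000,
    f_init: np.ndarray | None = None,
) -> tuple[PnDistribution, np.ndarray]:
    """Self-consistent WHAM solution for a set of umbrella windows.

    Requires the union of sampled occupancies to be contiguous (a gap makes
    the relative window free energies on the two sides undetermined).
    Returns (PnDistribution, per-window dimensionless free-energy shifts f_w).
    Convergence: max |Δf_w| < tolerance; a warm start may be supplied via
    ``f_init`` when windows are added incrementally.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one window")
    counts, bias, n_grid = _window_matrix(windows, temperature)
    sampled = counts.sum(axis=0) > 0
    lo, hi = np.argmax(sampled), len(sampled) - 1 - np.argmax(sampled[::-1])
    gaps = np.where(~sampled[lo : hi + 1])[0]
    if gaps.size:
        raise ValueError(
            f"non-contiguous occupancy coverage: no samples at n = {lo + gaps[0]}"
        )
    counts = counts[:, lo : hi + 1]
    bias = bias[:, lo : hi + 1]

    n_w = counts.shape[0]
    n_tot = counts.sum(axis=1)  # samples per window
    c_n = counts.sum(axis=0)  # pooled counts per occupancy
    f = np.zeros(n_w) if f_init is None else np.asarray(f_init, dtype=float).copy()
    log_ntot = np.log(n_tot)

    log_p = None
    for iteration in range(max_iters):
        # log denominator per occupancy: logsumexp over windows
        log_den = logsumexp(log_ntot[:, None] + f[:, None] - bias, axis=0)
        with np.errstate(divide="ignore"):
            log_p = np.where(c_n > 0, np.log(np.maximum(c_n, 1e-300)), -np.inf) - log_den
        log_p -= logsumexp(log_p)
        f_new = -logsumexp(log_p[None, :] - bias, axis=1)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tolerance:
            break
    else:
        raise WhamConvergenceError(max_iters, resid)

    p_full = np.zeros(len(sampled))
    p_full[lo : hi + 1] = np.exp(log_p - logsumexp(log_p))
    dist = PnDistribution.from_unnormalized(
        p_full,
        provenance="wham",
        meta={
            "iterations": iteration + 1,
            "shifts": f.tolist(),
            "windows": [(w.k0, w.n0, w.total) for w in windows],
            "n_offset": int(lo),
        },
    )
    return dist, f


def bootstrap_pn_errors(
    series_per_window,
    window_specs,
    temperature: float,
    rng: np.random.Generator,
    n_boot: int = 50,
    n_blocks: int = 20,
    **wham_kwargs,
) -> np.ndarray:
    """Block-bootstrap standard errors on p_n.

    ``series_per_window`` holds each window's production occupancy time
    series; each is cut into ``n_blocks`` contiguous blocks which are
    resampled with replacement to respect temporal correlation.
    """
    series = [np.asarray(s, dtype=np.int64) for s in series_per_window]
    n_max = max(int(s.max()) for s in series)
    boots = np.zeros((n_boot, n_max + 1))
    for b in range(n_boot):
        windows = []
        for s, (k0, n0) in zip(series, window_specs):
            blocks = np.array_split(s, n_blocks)
            pick = rng.integers(len(blocks), size=len(blocks))
            resampled = np.concatenate([blocks[i] for i in pick])
            counts = np.bincount(resampled, minlength=n_max + 1)
            windows.append(OccupancyHistogram(counts=counts, k0=k0, n0=n0))
        dist, _ = wham_combine(windows, temperature, **wham_kwargs)
        boots[b, : len(dist.p)] = dist.p
    return boots.std(axis=0, ddof=1)
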