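"""Occupancy-resolved RDF accumulation and the knitting estimator of p_n."""

import math

import numpy as np
import pytest
from scipy import stats

from cavityfluc.fixtures import generate_biased_ideal_gas, generate_ideal_gas_fixture
from cavityfluc.knitting import (
    OccupancyRDFSet,
    accumulate_gn,
    assemble_pn,
    ideal_gas_reference,
    knit_all,
    knit_fit,
    passivity_check,
)
from cavityfluc.forcefield import SolventFrame
from cavityfluc.mc import CavitySpec, occupancy
from cavityfluc.wham import PnDistribution


def _synthetic_gset(r, g_rows, R, rho, counts=None):
    g = np.asarray(g_rows, dtype=float)
    counts = np.ones_like(g) * 1000.0 if counts is None else counts
    return OccupancyRDFSet(
        r=r, g=g, counts=counts,
        frame_counts=np.full(g.shape[0], 1000, dtype=np.int64), R=R, rho=rho,
    )


class TestAccumulate:
    rho, box, R = 0.02, 16.0, 3.3

    @pytest.fixture(scope="class")
    def labelled(self):
        cav = CavitySpec(R=self.R)
        frames = generate_ideal_gas_fixture(self.rho, self.box, 6000, seed=42)
        occ = np.array([occupancy(f, cav) for f in frames])
        return frames, occ, cav

    def test_ideal_gas_levels(self, labelled):
        """Exterior g_n = 1 and interior g_{n+1} = (n+1)/⟨n⟩, flat."""
        frames, occ, cav = labelled
        gset = accumulate_gn(frames, occ, cav, self.rho, bin_width=0.2)
        mean_n = self.rho * 4 * math.pi * self.R**3 / 3
        for n in (1, 2, 3, 4):
            ref = ideal_gas_reference(mean_n, n - 1)
            assert gset.interior_mean(n) == pytest.approx(
                ref["g_interior"], rel=0.12
            )
        ext = (gset.r >= self.R) & (gset.r < self.box / 2 - 0.5)
        pooled = np.nansum(gset.counts[:, ext], axis=0)
        frames_tot = gset.frame_counts.sum()
        shell = 4 * math.pi / 3 * (
            (gset.r[ext] + 0.1) ** 3 - (gset.r[ext] - 0.1) ** 3
        )
        g_ext = pooled / (frames_tot * self.rho * shell)
        assert np.all(np.abs(g_ext - 1.0) < 0.1)

    def test_interior_normalization_invariant(self, labelled):
        """Volume average of g_n over the cavity equals n/(ρv) per state."""
        frames, occ, cav = labelled
        gset = accumulate_gn(frames, occ, cav, self.rho, bin_width=0.15)
        v = 4 * math.pi * self.R**3 / 3
        for n in range(1, 5):
            assert gset.interior_mean(n) == pytest.approx(n / (self.rho * v), rel=0.12)

    def test_single_frame_single_particle_bin(self):
        box = np.full(3, 16.0)
        center = np.full(3, 8.0)
        r0 = 1.73
        pos = center + np.array([[r0, 0.0, 0.0]])
        frame = SolventFrame(pos, box, center)
        gset = accumulate_gn([frame], [1], CavitySpec(R=3.3), 0.02, bin_width=0.1)
        interior = gset.counts[1][gset.r < 3.3]
        nonzero = np.flatnonzero(interior)
        assert len(nonzero) == 1
        assert abs(gset.r[gset.r < 3.3][nonzero[0]] - r0) <= 0.05

    def test_unconditioned_uniform_frames_give_unit_rdf(self):
        frames = generate_ideal_gas_fixture(0.03, 14.0, 3000, seed=7)
        gset = accumulate_gn(
            frames, np.zeros(len(frames), dtype=int), CavitySpec(R=3.0), 0.03,
            bin_width=0.25,
        )
        usable = gset.r > 0.8  # innermost shells hold too few counts
        assert np.all(np.abs(gset.g[0, usable] - 1.0) < 0.15)

    def test_missing_state_is_nan_not_zero(self, labelled):
        frames, occ, cav = labelled
        gset = accumulate_gn(frames[:50], occ[:50], cav, self.rho)
        unseen = [n for n in range(gset.g.shape[0]) if gset.frame_counts[n] == 0]
        for n in unseen:
            assert np.all(np.isnan(gset.g[n]))

    def test_mismatched_labels_rejected(self, labelled):
        frames, occ, cav = labelled
        with pytest.raises(ValueError):
            accumulate_gn(frames[:10], occ[:9], cav, self.rho)


class TestKnitFit:
    def test_recovers_injected_step_exactly(self):
        """−ln y quadratic in (r−R) with an injected step s returns s."""
        R, s = 3.3, -1.37
        r = np.arange(0.05, 8.0, 0.1)
        q = 0.8 * (r - R) ** 2 - 0.3 * (r - R) + 0.25  # −ln y
        minus_ln_g_out = q
        minus_ln_g_in = q + s  # −ln g_{n+1} = −ln y + ln K
        g = np.vstack([np.exp(-minus_ln_g_out), np.exp(-minus_ln_g_in)])
        gset = _synthetic_gset(r, g, R, 0.02)
        fit = knit_fit(gset, 0)
        assert fit.ln_Kn == pytest.approx(s, abs=1e-10)
        assert fit.alpha0 == pytest.approx(0.25, abs=1e-10)
        assert fit.alpha2 == pytest.approx(0.8, abs=1e-10)

    def test_continuous_branches_give_zero_step(self):
        R = 3.3
        r = np.arange(0.05, 8.0, 0.1)
        g = np.exp(-(0.5 * (r - R) ** 2 + 0.1))
        gset = _synthetic_gset(r, np.vstack([g, g]), R, 0.02)
        assert knit_fit(gset, 0).ln_Kn == pytest.approx(0.0, abs=1e-10)

    def test_fitted_y_is_continuous_at_boundary(self):
        R = 3.3
        r = np.arange(0.05, 8.0, 0.1)
        q = 0.4 * (r - R) ** 2 + 0.2 * (r - R) + 0.1
        g = np.vstack([np.exp(-q), np.exp(-(q - 2.0))])
        fit = knit_fit(_synthetic_gset(r, g, R, 0.02), 0)
        # the reconstructed interior branch (−ln g_{n+1} − ln K_n) and the
        # exterior branch (−ln g_n) are the same fitted polynomial at r = R
        interior_at_R = (fit.minus_ln_y(np.array([R]), R) + fit.ln_Kn) - fit.ln_Kn
        exterior_at_R = fit.minus_ln_y(np.array([R]), R)
        assert interior_at_R[0] == pytest.approx(exterior_at_R[0], abs=1e-12)
        assert exterior_at_R[0] == pytest.approx(fit.alpha0, abs=1e-12)

    def test_ideal_gas_step_is_poisson_ratio(self):
        rho, box, R = 0.02, 16.0, 3.3
        cav = CavitySpec(R=R)
        frames = generate_ideal_gas_fixture(rho, box, 8000, seed=9)
        occ = np.array([occupancy(f, cav) for f in frames])
        gset = accumulate_gn(frames, occ, cav, rho, bin_width=0.1)
        mean_n = rho * 4 * math.pi * R**3 / 3
        for n in (1, 2, 3):
            fit = knit_fit(gset, n)
            assert fit.ln_Kn == pytest.approx(math.log(mean_n / (n + 1)), abs=0.12)

    def test_too_few_usable_bins_rejected(self):
        R = 3.3
        r = np.arange(2.5, 4.2, 0.5)
        g = np.ones((2, len(r)))
        gset = _synthetic_gset(r, g, R, 0.02)
        with pytest.raises(ValueError, match="usable bins"):
            knit_fit(gset, 0, half_width=0.4)

    def test_nonpositive_bins_excluded_with_warning(self):
        R = 3.3
        r = np.arange(0.05, 8.0, 0.1)
        g = np.ones((2, len(r)))
        g[1, np.argmin(np.abs(r - (R - 0.5)))] = 0.0  # inside the fit window
        gset = _synthetic_gset(r, g, R, 0.02)
        with pytest.warns(UserWarning, match="excluded"):
            knit_fit(gset, 0)


class TestAssemble:
    def test_poisson_closure(self):
        mean = 3.0
        lnk = np.log(mean / (np.arange(12) + 1.0))
        dist = assemble_pn(lnk)
        truth = stats.poisson.pmf(np.arange(13), mean)
        assert np.allclose(dist.p, truth / truth.sum(), atol=1e-12)

    def test_constant_ln_K_gives_geometric_weights(self):
        c = -0.7
        dist = assemble_pn(np.full(9, c))
        direct = np.exp(c * np.arange(10))
        assert np.allclose(dist.p, direct / direct.sum(), atol=1e-12)

    def test_missing_state_raises_with_index(self):
        lnk = np.array([0.5, np.nan, -0.5])
        with pytest.raises(ValueError, match="ln K_1"):
            assemble_pn(lnk)


class TestPassivity:
    def test_ideal_gas_closed_forms_deviation_zero(self):
        """Poisson-weighted closed-form g_n sum to exactly 1 everywhere."""
        mean, R, rho = 3.0, 3.3, 0.02
        r = np.arange(0.1, 8.0, 0.2)
        n_states = 30  # Poisson(3) tail mass beyond this is ~1e-20
        g = np.empty((n_states, len(r)))
        for n in range(n_states):
            g[n] = np.where(r < R, ideal_gas_reference(mean, n - 1)["g_interior"]
                            if n > 0 else 0.0, 1.0)
        p = stats.poisson.pmf(np.arange(n_states), mean)
        dist = PnDistribution.from_unnormalized(p)
        gset = _synthetic_gset(r, g, R, rho)
        dev, profile = passivity_check(gset, dist, p_floor=0.0)
        assert dev == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_single_state(self):
        r = np.arange(0.1, 6.0, 0.2)
        g = np.vstack([np.ones_like(r), 1.0 + 0.3 * np.sin(r)])
        gset = _synthetic_gset(r, g, 2.5, 0.02)
        dist = PnDistribution.from_unnormalized(np.array([0.0, 1.0]))
        dev, _ = passivity_check(gset, dist, p_floor=0.0)
        assert dev == pytest.approx(float(np.max(np.abs(0.3 * np.sin(r)))), abs=1e-12)

    def test_simulated_ideal_gas_self_consistency(self):
        """Pooled deviation stays within a Bonferroni-corrected z bound."""
        rho, box, R = 0.02, 16.0, 3.3
        cav = CavitySpec(R=R)
        frames = generate_ideal_gas_fixture(rho, box, 5000, seed=17)
        occ = np.array([occupancy(f, cav) for f in frames])
        gset = accumulate_gn(frames, occ, cav, rho, bin_width=0.2)
        counts = np.bincount(occ, minlength=gset.g.shape[0]).astype(float)
        dist = PnDistribution.from_unnormalized(counts)
        dev, profile = passivity_check(gset, dist, p_floor=1e-4)
        shell = 4 * math.pi / 3 * ((gset.r + 0.1) ** 3 - (gset.r - 0.1) ** 3)
        total_counts = np.nansum(
            [dist.p[n] ** 2 * gset.counts[n] / max(gset.frame_counts[n], 1) ** 2
             for n in range(gset.g.shape[0]) if dist.p[n] > 1e-4], axis=0,
        )
        sigma = np.sqrt(total_counts) / (rho * shell)
        usable = (gset.r > 0.8) & (gset.r < box / 2 - 0.3)
        z = np.abs(profile[usable]) / sigma[usable]
        z_crit = stats.norm.ppf(1.0 - 0.005 / usable.sum())
        assert np.max(z) < z_crit


def test_ideal_gas_reference_values():
    ref = ideal_gas_reference(2.0, 1)
    assert ref["g_interior"] == pytest.approx(1.0)
    assert ideal_gas_reference(2.0, 0)["K_n"] == pytest.approx(2.0)
    for mean in (0.5, 5.0, 50.0):
        p = [ideal_gas_reference(mean, n)["p_n"] for n in range(200)]
        assert sum(p) == pytest.approx(1.0, abs=1e-9)
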