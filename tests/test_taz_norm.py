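"""TAZ normalization: zone counting, factor fitting, and invariants."""

import numpy as np
import pytest

from qznorm.genome_io import Track, ValidationError
from qznorm.profiles import MetaProfile, window_signal
from qznorm.synthetic_data import SimulationConfig, make_genome, simulate_fractions
from qznorm.profiles import midpoint_track
from qznorm.taz_norm import (
    average_reactions,
    cpm_factor,
    count_in_zones,
    fit_m,
    fit_n,
    normalize_reaction,
)

from conftest import make_intervals, normalized_reaction, random_track


def meta(values, offsets=None):
    values = np.asarray(values, dtype=float)
    if offsets is None:
        flank = (len(values) - 1) // 2
        offsets = np.arange(-flank, flank + 1)
    return MetaProfile(offsets=np.asarray(offsets), values=values, n_dyads=1)


def grid_search_n(A, Z, T, m, step=1e-4):
    """Independent oracle: dense grid over n minimizing the OLS objective."""
    scale = max(abs(np.dot(Z, T - m * A) / np.dot(Z, Z)), 1e-3)
    grid = np.arange(0.0, 2.5 * scale, step * scale)
    resid = (m * A - T)[None, :] + grid[:, None] * Z[None, :]
    obj = np.einsum("ij,ij->i", resid, resid)
    return grid[int(np.argmin(obj))]


class TestCountInZones:
    def test_uniform_track_single_zone(self, toy_genome):
        track = Track({c: np.ones(n) for c, n in toy_genome.lengths.items()})
        assert count_in_zones(track, make_intervals([("chrI", 100, 200)])) == 100.0

    def test_overlapping_zones_counted_once(self, toy_genome):
        track = Track({c: np.ones(n) for c, n in toy_genome.lengths.items()})
        zones = make_intervals([("chrI", 0, 50), ("chrI", 25, 75)])
        assert count_in_zones(track, zones) == 75.0

    def test_matches_per_bp_loop_oracle(self, toy_genome, rng):
        track = random_track(toy_genome, rng)
        zones = make_intervals(
            [("chrI", 10, 200), ("chrI", 150, 400), ("chrII", 600, 900)]
        )
        covered = set()
        expected = 0.0
        for _, z in zones.frame.iterrows():
            for b in range(z["start"], z["end"]):
                if (z["chrom"], b) not in covered:
                    covered.add((z["chrom"], b))
                    expected += track.data[z["chrom"]][b]
        assert count_in_zones(track, zones) == pytest.approx(expected)

    def test_empty_zone_set_error(self, toy_genome):
        import pandas as pd
        from qznorm.genome_io import IntervalSet
        empty = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "label"]))
        with pytest.raises(ValidationError):
            count_in_zones(Track.zeros(toy_genome), empty)


class TestFitM:
    def test_ratio_definition(self, toy_genome):
        t = Track.zeros(toy_genome)
        a = Track.zeros(toy_genome)
        t.data["chrI"][0:100] = 10.0  # zone count 1000
        a.data["chrI"][0:100] = 5.0  # zone count 500
        m = fit_m(t, a, make_intervals([("chrI", 0, 100)]))
        assert m == pytest.approx(2.0)

    def test_identical_tracks_give_unity(self, toy_genome, rng):
        track = random_track(toy_genome, rng)
        zones = make_intervals([("chrI", 50, 500)])
        assert fit_m(track, track, zones) == pytest.approx(1.0)

    def test_zero_ft_signal_error(self, toy_genome):
        t = Track({c: np.ones(n) for c, n in toy_genome.lengths.items()})
        with pytest.raises(ValidationError):
            fit_m(t, Track.zeros(toy_genome), make_intervals([("chrI", 0, 100)]))


class TestFitN:
    def test_exact_decomposition(self):
        # T = m*A + 2*Z exactly -> n = 2, residual 0
        A = meta([2, 2, 2])
        Z = meta([1, 1, 1])
        T = meta([4, 4, 4])
        n, residual, clamped = fit_n(A, Z, T, m=1.0)
        assert n == pytest.approx(2.0) and residual == pytest.approx(0.0)
        assert not clamped

    def test_orthogonal_components(self):
        A = meta([1, 0, 0])
        Z = meta([0, 0, 1])
        T = meta([1, 0, 2])
        n, residual, _ = fit_n(A, Z, T, m=1.0)
        assert n == pytest.approx(2.0) and residual == pytest.approx(0.0)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(50):
            A = meta(rng.random(41) * 10)
            Z = meta(rng.random(41) * 5 + 0.1)
            T = meta(rng.random(41) * 12)
            m = float(rng.random() * 2 + 0.1)
            n, _, clamped = fit_n(A, Z, T, m)
            if clamped:
                continue
            n_grid = grid_search_n(A.values, Z.values, T.values, m)
            assert n == pytest.approx(n_grid, rel=2e-4, abs=1e-8)

    def test_negative_optimum_clamped_and_flagged(self):
        A = meta([5, 5, 5])
        Z = meta([1, 1, 1])
        T = meta([1, 1, 1])  # T < m*A everywhere -> unconstrained n < 0
        n, _, clamped = fit_n(A, Z, T, m=1.0)
        assert n == 0.0 and clamped

    def test_all_zero_z_error(self):
        with pytest.raises(ValidationError):
            fit_n(meta([1, 1, 1]), meta([0, 0, 0]), meta([1, 1, 1]), m=1.0)

    def test_mismatched_axes_error(self):
        A = meta([1, 1, 1])
        Z = MetaProfile(offsets=np.arange(-2, 3), values=np.ones(5), n_dyads=1)
        with pytest.raises(ValidationError):
            fit_n(A, Z, A, m=1.0)

    def test_perturbing_n_increases_residual(self, rng):
        """Convexity: the closed-form n is the strict minimum."""
        A = meta(rng.random(41))
        Z = meta(rng.random(41) + 0.1)
        T = meta(rng.random(41) * 2)
        m = 0.8
        n, residual, _ = fit_n(A, Z, T, m)

        def rms(nn):
            return np.sqrt(np.mean((m * A.values + nn * Z.values - T.values) ** 2))

        for delta in (0.01, 0.1, 1.0):
            assert rms(n + delta) > residual
            assert rms(max(n - delta, 0.0)) >= residual


class TestCpmFactor:
    def test_two_million_fragments(self, toy_genome):
        t = Track.zeros(toy_genome)
        t.data["chrI"][0] = 2_000_000
        assert cpm_factor(t) == pytest.approx(0.5)

    def test_scaling_makes_total_one_million(self, toy_genome, rng):
        t = Track({c: rng.integers(0, 50, n).astype(float) for c, n in toy_genome.lengths.items()})
        c = cpm_factor(t)
        assert c * t.total() == pytest.approx(1e6)

    def test_empty_input_error(self, toy_genome):
        with pytest.raises(ValidationError):
            cpm_factor(Track.zeros(toy_genome))


class TestNormalizeReaction:
    def test_zone_calibration_exact(self, default_sim):
        """After normalization the A and T tracks agree over the no-Z-zones."""
        rxn = normalized_reaction(default_sim, seed=3)
        a = count_in_zones(rxn.A, default_sim.nozzones)
        t = count_in_zones(rxn.T, default_sim.nozzones)
        assert abs(a - t) / t < 1e-6

    def test_depth_invariance(self, default_sim):
        """Doubling every fragment's multiplicity leaves normalized tracks unchanged."""
        frags = simulate_fractions(default_sim, seed=11)
        tracks = {k: midpoint_track(v, default_sim.genome) for k, v in frags.items()}
        doubled = {k: Track({c: 2 * arr for c, arr in tr.data.items()}) for k, tr in tracks.items()}
        rxn1 = normalize_reaction(
            tracks["T"], tracks["A"], tracks["Z"], default_sim.nozzones, default_sim.plus_one
        )
        rxn2 = normalize_reaction(
            doubled["T"], doubled["A"], doubled["Z"], default_sim.nozzones, default_sim.plus_one
        )
        for c in default_sim.genome.chroms:
            np.testing.assert_allclose(rxn1.Z.data[c], rxn2.Z.data[c], rtol=1e-12)
            np.testing.assert_allclose(rxn1.A.data[c], rxn2.A.data[c], rtol=1e-12)

    def test_factor_recovery_on_planted_truth(self, default_sim):
        """Fitted (m, n) track the sampling-implied truth at default depth."""
        merrs, nerrs = [], []
        for seed in range(5):
            rxn = normalized_reaction(default_sim, seed=seed)
            merrs.append(abs(rxn.factors.m / default_sim.truth.m_true - 1))
            nerrs.append(abs(rxn.factors.n / default_sim.truth.n_true - 1))
        assert np.mean(merrs) < 0.02
        assert np.mean(nerrs) < 0.08  # single reaction; tighter bound over 20 seeds elsewhere

    def test_relative_occupancy_tracks_planted_fraction(self, default_sim):
        """(Z/T)/e at +1 dyads estimates the planted H2A.Z dimer fraction,
        averaged over reactions (a single fit carries ~4% amplitude noise)."""
        cfg = default_sim.config
        ests = []
        for seed in range(6):
            rxn = normalized_reaction(default_sim, seed=seed)
            wz = window_signal(rxn.Z, default_sim.plus_one, 60)
            wt = window_signal(rxn.T, default_sim.plus_one, 60)
            ests.append(np.nanmedian(wz / wt) / cfg.ip_efficiency)
        assert np.mean(ests) == pytest.approx(cfg.z_plus_one, rel=0.05)

    def test_average_reactions_is_per_bp_mean(self, default_sim):
        rxns = [normalized_reaction(default_sim, seed=s) for s in (0, 1)]
        avg = average_reactions(rxns)
        for tag in ("T", "A", "Z"):
            for c in default_sim.genome.chroms:
                np.testing.assert_allclose(
                    avg[tag].data[c],
                    (getattr(rxns[0], tag).data[c] + getattr(rxns[1], tag).data[c]) / 2,
                )

    def test_average_reactions_empty_error(self):
        with pytest.raises(ValidationError):
            average_reactions([])

    def test_degenerate_zero_z_reaction_raises(self):
        sim = make_genome(SimulationConfig(seed=0, z_plus_one=0.0, z_minus_one=0.0, z_body=0.0))
        frags = simulate_fractions(sim, seed=0)
        assert frags["Z"].total_count == 0  # H2A.Z-free genome: empty IP fraction
        tracks = {k: midpoint_track(v, sim.genome) for k, v in frags.items()}
        with pytest.raises(ValidationError):
            normalize_reaction(
                tracks["T"], tracks["A"], tracks["Z"], sim.nozzones, sim.plus_one
            )
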