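"""Unit and property tests of the Ising/PEL core against enumeration oracles."""

import numpy as np
import pytest

from methpel import _dp
from methpel.ising import (
    IsingParameters,
    fit_parameters,
    level_distribution,
    log_partition_function,
    pack_fragments,
    partition_function,
    potential,
    read_log_likelihood,
)
from oracles import (
    enum_level_distribution,
    enum_partition,
    enum_read_marginal,
    grid_search_a,
)


def chain(n, gap=10.0, rho_val=0.0):
    return np.full(n, rho_val), np.full(max(n - 1, 0), gap)


class TestPotential:
    def test_null_landscape_is_flat(self):
        rho, d = chain(4)
        params = IsingParameters(0, 0, 0)
        for pattern in ([0, 0, 0, 0], [1, 0, 1, 0], [1, 1, 1, 1]):
            assert potential(params, np.array(pattern), rho, d) == 0.0

    def test_two_site_value(self):
        # alpha=(1,1), beta=0.5 via c=5, d=10; fully methylated pattern
        rho, d = chain(2)
        params = IsingParameters(1.0, 0.0, 5.0)
        assert potential(params, np.array([1, 1]), rho, d) == pytest.approx(-2.5, abs=1e-12)

    def test_field_sign_flip_maps_to_complement(self):
        rng = np.random.default_rng(0)
        rho = rng.uniform(0, 1, 6)
        d = rng.integers(2, 50, 5).astype(float)
        x = rng.integers(0, 2, 6)
        a, b, c = 1.3, -0.7, 2.1
        v = potential(IsingParameters(a, b, c), x, rho, d)
        v_flip = potential(IsingParameters(-a, -b, c), 1 - x, rho, d)
        assert v == pytest.approx(v_flip, abs=1e-12)

    def test_length_mismatch_rejected(self):
        rho, d = chain(3)
        with pytest.raises(ValueError):
            potential(IsingParameters(0, 0, 0), np.array([1, 0]), rho, d)


class TestPartitionFunction:
    def test_null_landscape_counts_patterns(self):
        for n in (1, 3, 7):
            rho, d = chain(n)
            assert partition_function(IsingParameters(0, 0, 0), rho, d) == pytest.approx(2.0**n)

    def test_single_site_closed_form(self):
        z = partition_function(IsingParameters(1.0, 0, 0), np.zeros(1), np.empty(0))
        assert z == pytest.approx(np.exp(1) + np.exp(-1), rel=1e-12)

    def test_matches_enumeration_n8(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a, b = rng.uniform(-3, 3, 2)
            c = rng.uniform(-6, 6)
            rho = rng.uniform(0, 1, 8)
            d = rng.integers(2, 200, 7).astype(float)
            z = partition_function(IsingParameters(a, b, c), rho, d)
            assert z == pytest.approx(enum_partition(a, b, c, rho, d), rel=1e-10)


class TestReadLikelihood:
    def test_null_landscape_complete_read(self):
        rho, d = chain(2)
        assert read_log_likelihood(IsingParameters(0, 0, 0), 0, "MU", rho, d) == pytest.approx(
            np.log(0.25)
        )

    def test_null_landscape_dot_marginalized(self):
        rho, d = chain(3)
        assert read_log_likelihood(IsingParameters(0, 0, 0), 0, "M.U", rho, d) == pytest.approx(
            np.log(0.25)
        )

    def test_matches_enumeration_with_missing_sites(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            n = int(rng.integers(3, 9))
            a, b = rng.uniform(-3, 3, 2)
            c = rng.uniform(-6, 6)
            rho = rng.uniform(0, 1, n)
            d = rng.integers(2, 200, n - 1).astype(float)
            start = int(rng.integers(0, n - 1))
            width = int(rng.integers(2, n - start + 1))
            calls = "M" + "".join(rng.choice(list("MU."), max(width - 2, 0))) + "U"
            calls = calls[:width]
            if calls.endswith("."):
                calls = calls[:-1] + "U"
            ll = read_log_likelihood(IsingParameters(a, b, c), start, calls, rho, d)
            expected = enum_read_marginal(a, b, c, rho, d, start, calls)
            assert np.exp(ll) == pytest.approx(expected, rel=1e-10)

    def test_fully_unobserved_read_rejected(self):
        rho, d = chain(3)
        with pytest.raises(ValueError):
            read_log_likelihood(IsingParameters(0, 0, 0), 0, "...", rho, d)


class TestLevelDistribution:
    def test_null_landscape_binomial(self):
        rho, d = chain(2)
        dist = level_distribution(IsingParameters(0, 0, 0), rho, d)
        assert dist.p == pytest.approx([0.25, 0.5, 0.25], abs=1e-12)

    def test_saturated_field(self):
        rho, d = chain(5)
        dist = level_distribution(IsingParameters(10.0, 0, 0), rho, d)
        assert dist.p[-1] > 0.999

    def test_random_subset_matches_enumeration(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            a, b = rng.uniform(-3, 3, 2)
            c = rng.uniform(-6, 6)
            rho = rng.uniform(0, 1, 10)
            d = rng.integers(2, 200, 9).astype(float)
            subset = np.sort(rng.choice(10, 5, replace=False))
            dist = level_distribution(IsingParameters(a, b, c), rho, d, subset)
            expected = enum_level_distribution(a, b, c, rho, d, list(subset))
            assert dist.p == pytest.approx(expected, abs=1e-10)

    def test_field_negation_reverses_levels(self):
        rng = np.random.default_rng(41)
        rho = rng.uniform(0, 1, 7)
        d = rng.integers(2, 100, 6).astype(float)
        p_fwd = level_distribution(IsingParameters(1.2, -0.8, 3.0), rho, d).p
        p_rev = level_distribution(IsingParameters(-1.2, 0.8, 3.0), rho, d).p
        assert p_fwd == pytest.approx(p_rev[::-1], abs=1e-12)

    def test_mml_monotone_in_field(self):
        rho, d = chain(6)
        grid = np.linspace(-3, 3, 13)
        mml_values = []
        for a in grid:
            dist = level_distribution(IsingParameters(a, 0, 0), rho, d)
            mml_values.append(float((dist.levels * dist.p).sum()))
        assert np.all(np.diff(mml_values) > 0)

    def test_normalization(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            rho = rng.uniform(0, 1, 12)
            d = rng.integers(2, 400, 11).astype(float)
            dist = level_distribution(IsingParameters(*rng.uniform(-4, 4, 3)), rho, d)
            assert dist.p.sum() == pytest.approx(1.0, abs=1e-9)


class TestFit:
    def test_symmetric_reads_give_zero_field(self):
        # equal counts of all-M and all-U reads; rho ~ 0 so b is inert
        n = 10
        rho, d = chain(n, gap=600.0, rho_val=1 / 500)
        frags = [(0, "M" * n)] * 1000 + [(0, "U" * n)] * 1000
        fit = fit_parameters(pack_fragments(frags, n), rho, d, fix_b=0.0)
        assert abs(fit.params.a) < 0.05
        # grid-search oracle over a alone (b=c=0 landscape likelihood)
        from methpel.ising import reads_log_likelihood

        rr = pack_fragments(frags, n)
        best_a = grid_search_a(
            lambda a: -reads_log_likelihood(IsingParameters(a, 0, 0), rr, rho, d),
            np.linspace(-2, 2, 81),
        )
        assert abs(best_a) < 0.05

    def test_all_methylated_hits_upper_bound(self):
        n = 6
        rho, d = chain(n)
        frags = [(0, "M" * n)] * 200
        fit = fit_parameters(pack_fragments(frags, n), rho, d, fix_b=0.0)
        assert fit.params.a == pytest.approx(10.0, abs=1e-3)

    def test_parameter_recovery_single_replicate(self, recovery_region):
        rho, d = recovery_region
        true = IsingParameters(1.0, 0.0, 2.0)
        alpha, beta = true.alpha(rho), true.beta(d)
        f = _dp.forward_messages(alpha, beta)
        b = _dp.backward_messages(alpha, beta)
        rng = np.random.default_rng(99)
        spins = _dp.sample_windows(
            alpha, beta, f, b, np.zeros(2000, dtype=np.int64), 20, rng.random((2000, 20))
        )
        frags = [(0, "".join("M" if s == 1 else "U" for s in row)) for row in spins]
        fit = fit_parameters(pack_fragments(frags, 20), rho, d)
        assert fit.params.a == pytest.approx(1.0, abs=0.3)
        assert fit.params.b == pytest.approx(0.0, abs=0.3)
        assert fit.params.c == pytest.approx(2.0, abs=0.3)

    def test_no_reads_rejected(self):
        rho, d = chain(4)
        with pytest.raises(ValueError):
            fit_parameters(pack_fragments([], 4), rho, d)


def test_log_partition_large_fields_no_overflow():
    # 200 sites at the field box bound would overflow a linear-space product
    rho = np.zeros(200)
    d = np.full(199, 2.0)
    log_z = log_partition_function(IsingParameters(10.0, 0.0, 20.0), rho, d)
    assert np.isfinite(log_z)
    assert log_z == pytest.approx(200 * 10.0 + 199 * 10.0, rel=1e-6)
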