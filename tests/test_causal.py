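"""Entropies, conditional transfer entropy, and the local permutation test."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import proxysdm as px
from proxysdm.causal import (
    JointDistribution,
    conditional_te,
    local_permutation_test,
    shannon_entropy,
    triad_analysis,
)


def te_brute_force(x, y, z, lag=0):
    """Independent oracle: enumerate the 16 joint states and sum the
    conditional mutual-information decomposition term by term."""
    L = len(x)
    t = np.arange(lag, L - 1)
    tuples = list(zip(x[t + 1], x[t], y[t - lag], z[t - lag]))
    N = len(tuples)
    joint = Counter(tuples)

    def prob(pred):
        return sum(v for k, v in joint.items() if pred(k)) / N

    te = 0.0
    for k, v in joint.items():
        p_full = v / N
        xn, xp, ys, zs = k
        p_hist = prob(lambda q: q[1:] == (xp, ys, zs))
        p_xz = prob(lambda q: (q[1], q[3]) == (xp, zs))
        p_next_xz = prob(lambda q: (q[0], q[1], q[3]) == (xn, xp, zs))
        te += p_full * math.log2((p_full / p_hist) / (p_next_xz / p_xz))
    return te


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [([0.5, 0.5], 1.0), ([1.0, 0.0], 0.0), ([0.25] * 4, 2.0)],
    )
    def test_known_values(self, p, expected):
        assert shannon_entropy(np.array(p)) == pytest.approx(expected, abs=1e-14)

    def test_joint_distribution_normalization_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            JointDistribution(np.array([0.6, 0.6]))

    def test_chain_identity_mutual_information(self):
        # I(X;Y) = H(X) - H(X|Y) computed two ways on a random joint
        rng = np.random.default_rng(2)
        p = rng.random((2, 2))
        p /= p.sum()
        d = JointDistribution(p)
        h_x = d.marginal((0,)).entropy()
        h_y = d.marginal((1,)).entropy()
        h_xy = d.entropy()
        mi_a = h_x - (h_xy - h_y)          # H(X) - H(X|Y)
        mi_b = h_x + h_y - h_xy            # symmetric expansion
        assert mi_a == pytest.approx(mi_b, abs=1e-12)


class TestConditionalTE:
    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(40, 200))
        lag = int(rng.integers(0, 4))
        x, y, z = (rng.integers(0, 2, L) for _ in range(3))
        assert conditional_te(x, y, z, lag=lag).te_bits == pytest.approx(
            te_brute_force(x, y, z, lag), abs=1e-12
        )

    def test_engineered_independence_exactly_zero(self):
        # every (x_next, x, y, z) joint state equally frequent -> TE = 0
        pattern = np.array(
            [[xn, xp, ys, zs] for xn in (0, 1) for xp in (0, 1)
             for ys in (0, 1) for zs in (0, 1)]
        )
        reps = np.tile(pattern, (4, 1))
        xn, xp, ys, zs = reps.T
        # build series realizing those transitions via direct counting is
        # equivalent to feeding the embedded columns to the estimator
        from proxysdm.causal import _te_from_counts

        counts = np.bincount(
            ((xn * 2 + xp) * 2 + ys) * 2 + zs, minlength=16
        ).astype(float)
        assert float(_te_from_counts(counts)) == pytest.approx(0.0, abs=1e-14)

    def test_copy_process_approaches_one_bit(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 1000)
        x = np.empty(1000, dtype=int)
        x[0] = 0
        x[1:] = y[:-1]
        z = np.zeros(1000, dtype=int)
        te = conditional_te(x, y, z).te_bits
        assert te > 0.9

    def test_nonnegative(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x, y, z = (rng.integers(0, 2, 80) for _ in range(3))
            assert conditional_te(x, y, z).te_bits >= -1e-12

    def test_constant_conditioner_equals_unconditional(self):
        # with Z constant, conditioning is vacuous: compare against the
        # two-variable transfer entropy computed from entropies directly
        rng = np.random.default_rng(13)
        x, y = rng.integers(0, 2, 300), rng.integers(0, 2, 300)
        z = np.zeros(300, dtype=int)
        te = conditional_te(x, y, z).te_bits
        xn, xp, ys = x[1:], x[:-1], y[:-1]
        d3 = JointDistribution.from_symbols(xn, xp, ys)
        h_xx = d3.marginal((0, 1)).entropy() - d3.marginal((1,)).entropy()
        h_xxy = d3.entropy() - d3.marginal((1, 2)).entropy()
        assert te == pytest.approx(h_xx - h_xxy, abs=1e-12)

    def test_length_and_symbol_validation(self):
        with pytest.raises(ValueError, match="share a length"):
            conditional_te(np.zeros(30, int), np.zeros(29, int), np.zeros(30, int))
        with pytest.raises(ValueError, match="binary"):
            conditional_te(np.full(30, 2), np.zeros(30, int), np.zeros(30, int))


class TestLocalPermutationTest:
    def test_stratum_multisets_preserved(self):
        # re-implement one shuffle round and verify the per-stratum source
        # multiset is untouched; then check the estimator's own surrogates
        # via determinism of the seeded p-value
        rng = np.random.default_rng(0)
        x, y, z = (rng.integers(0, 2, 216) for _ in range(3))
        xn, xp, ys, zs = px.causal._embed(x, y, z, 0)
        strata = xp * 2 + zs
        g = np.random.default_rng(1)
        y_surr = ys.copy()
        for s in range(4):
            idx = np.flatnonzero(strata == s)
            y_surr[idx] = g.permutation(ys[idx])
        for s in range(4):
            idx = np.flatnonzero(strata == s)
            assert sorted(y_surr[idx]) == sorted(ys[idx])

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        x, y, z = (rng.integers(0, 2, 216) for _ in range(3))
        a = local_permutation_test(x, y, z, n_permutations=500, seed=9)
        b = local_permutation_test(x, y, z, n_permutations=500, seed=9)
        assert a.p_value == b.p_value
        assert a.te_bits == b.te_bits

    def test_coupled_process_detected(self):
        tri = px.generate_coupled_triad("y_to_x", 216, strength=1.0, seed=3)
        res = local_permutation_test(
            tri["x"], tri["y"], tri["z"], n_permutations=1000, seed=0
        )
        assert res.p_value < 0.05
        assert res.significant

    def test_null_p_value_not_extreme(self):
        tri = px.generate_coupled_triad("none", 216, seed=8)
        res = local_permutation_test(
            tri["x"], tri["y"], tri["z"], n_permutations=1000, seed=1
        )
        assert res.p_value > 0.001
        assert res.n_permutations == 1000

    def test_p_value_convention_lower_bound(self):
        # the add-one rule keeps p strictly positive
        tri = px.generate_coupled_triad("y_to_x", 500, strength=1.0, seed=5)
        res = local_permutation_test(
            tri["x"], tri["y"], tri["z"], n_permutations=200, seed=2
        )
        assert res.p_value >= 1.0 / 201


class TestTriadAnalysis:
    def test_six_links_and_table_layout(self):
        rng = np.random.default_rng(0)
        series = {
            "ownership": rng.normal(size=216).cumsum() * 0.01 + 5,
            "shootings": rng.poisson(0.5, size=216).astype(float),
            "media": np.exp(rng.normal(size=216)),
        }
        plans = {
            "ownership": {"seasonal_adjust": True, "detrend": True},
            "shootings": {"rule": "event"},
            "media": {"seasonal_adjust": False, "detrend": False},
        }
        res = triad_analysis(series, plans, n_permutations=200, seed=0)
        assert len(res.links) == 6
        table = res.table()
        off_diag = [
            table.iloc[i, j] for i in range(3) for j in range(3) if i != j
        ]
        assert all(cell != "-" for cell in off_diag)
        assert all(table.iloc[i, i] == "-" for i in range(3))
        # every link conditioned on the remaining third variable
        for link in res.links:
            assert {link.source, link.target, link.conditioner} == set(series)

    def test_planted_link_found(self):
        tri = px.generate_coupled_triad("y_to_x", 240, strength=0.9, seed=1)
        series = {"x": tri["x"].astype(float), "y": tri["y"].astype(float),
                  "z": tri["z"].astype(float)}
        plans = {k: {"seasonal_adjust": False, "detrend": False, "rule": "event"}
                 for k in series}
        res = triad_analysis(series, plans, n_permutations=500, seed=4)
        found = {(l.source, l.target): l.p_value for l in res.links}
        assert found[("y", "x")] < 0.05

    def test_chain_confounding_removed_by_conditioning(self):
        # y drives x only through z: unconditional TE is positive, but
        # conditioning on z annihilates it
        tri = px.generate_coupled_triad("chain", 2000, strength=1.0, seed=6)
        const = np.zeros(2000, dtype=int)
        uncond = conditional_te(tri["x"], tri["y"], const).te_bits
        cond = conditional_te(tri["x"], tri["y"], tri["z"]).te_bits
        assert uncond > 0.05
        assert cond < 1e-9
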