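import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from logddg import (
    DDParams,
    SubmodelSpec,
    between_edge_weight,
    between_region_rate,
    cut_set,
    dispersal_rate,
    extinction_rate,
    lineage_event_rates,
    log_rate_factor,
    range_bipartitions,
    split_score,
    within_speciation_rate,
)

E = math.e


def P(**kw):
    defaults = dict(rho_w=0.05, rho_e=0.02, rho_d=0.05, rho_b=0.02, n_regions=3)
    defaults.update(kw)
    return DDParams(**defaults)


class TestLogRateFactor:
    @pytest.mark.parametrize(
        "x,p,expected",
        [
            (1, 2, 1.0),        # a lineage alone feels no diversity effect
            (5, 0, 1.0),        # zero exponent switches the effect off
            (E, 1, 2.0),        # ln e = 1 -> (1+1)^1
            (E**2, 2, 9.0),
        ],
    )
    def test_values(self, x, p, expected):
        assert log_rate_factor(x, p) == pytest.approx(expected)

    def test_rejects_counts_below_one(self):
        with pytest.raises(ValueError):
            log_rate_factor(0.5, 1.0)

    @given(
        x=st.floats(min_value=1.0, max_value=1e6),
        p=st.floats(min_value=-2.0, max_value=4.0),
    )
    def test_finite_and_positive(self, x, p):
        v = log_rate_factor(x, p)
        assert v > 0 and math.isfinite(v)


class TestPerRegionRates:
    @pytest.mark.parametrize(
        "fn,rho_name,exp_name",
        [
            (extinction_rate, "rho_e", "e_D"),
            (within_speciation_rate, "rho_w", "w_D"),
        ],
    )
    def test_neutrality(self, fn, rho_name, exp_name):
        """Alone in the region, or zero exponent, recovers the base rate."""
        params = P(**{rho_name: 0.02, exp_name: 2.0})
        assert fn(0, [1, 5, 5], params) == pytest.approx(0.02)
        params0 = P(**{rho_name: 0.02, exp_name: 0.0})
        assert fn(0, [7, 1, 1], params0) == pytest.approx(0.02)

    def test_extinction_derived_value(self):
        # 0.01 * (ln(e^2) + 1)^2 = 0.01 * 9
        params = P(rho_e=0.01, e_D=2.0)
        # continuous count e^2 makes the factor (2 + 1)^2 exactly
        assert extinction_rate(0, [E**2, 1, 1], params) == pytest.approx(0.09)

    def test_within_speciation_halves_at_n_e(self):
        params = P(rho_w=0.05, w_D=-1.0)
        # use a float count so ln n = 1 exactly
        assert within_speciation_rate(0, [E, 1, 1], params) == pytest.approx(0.025)

    def test_empty_region_is_domain_error(self):
        with pytest.raises(ValueError):
            extinction_rate(0, [0, 3, 3], P())
        with pytest.raises(ValueError):
            within_speciation_rate(1, [3, 0, 3], P())

    @pytest.mark.parametrize("exponent,direction", [(1.5, 1), (-1.5, -1), (0.0, 0)])
    def test_monotone_in_richness(self, exponent, direction):
        """Rate responds to richness with the sign of its exponent."""
        params = P(rho_e=0.02, e_D=exponent)
        rates = [extinction_rate(0, [n, 1, 1], params) for n in range(1, 51)]
        diffs = np.diff(rates)
        if direction > 0:
            assert (diffs > 0).all()
        elif direction < 0:
            assert (diffs < 0).all()
        else:
            assert np.allclose(diffs, 0.0)


class TestDispersal:
    def test_neutrality_empty_destination(self):
        params = P(rho_d=0.05, d_D_src=-1.0, d_D_dest=-2.0)
        assert dispersal_rate(0, 1, [1, 0, 4], params) == pytest.approx(0.05)

    def test_neutrality_zero_exponents(self):
        params = P(rho_d=0.05)
        assert dispersal_rate(0, 1, [4, 3, 0], params) == pytest.approx(0.05)

    def test_derived_value(self):
        # n_i = e, n_j = e - 1: both factors are 2 -> 0.05 * 2 * 2
        params = P(rho_d=0.05, d_D_src=1.0, d_D_dest=1.0)
        assert dispersal_rate(0, 1, [E, E - 1, 0], params) == pytest.approx(0.2)

    def test_self_dispersal_rejected(self):
        with pytest.raises(ValueError):
            dispersal_rate(1, 1, [1, 1, 1], P())

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError):
            dispersal_rate(0, 1, [0, 1, 1], P())


class TestRangeSplits:
    def test_cut_set_sizes(self):
        assert cut_set({0}, {1}) == {(0, 1)}
        assert cut_set({0}, {1, 2}) == {(0, 1), (0, 2)}
        assert len(cut_set({0, 1}, {2, 3})) == 4

    def test_cut_set_rejects_overlap(self):
        with pytest.raises(ValueError):
            cut_set({0, 1}, {1, 2})

    def test_edge_weight_neutrality_and_symmetry(self):
        params = P(b_D=-1.0)
        assert between_edge_weight(0, 1, [1, 1, 1], params) == pytest.approx(1.0)
        assert between_edge_weight(0, 1, [3, 5, 1], P(b_D=0.0)) == pytest.approx(1.0)
        # (ln(e * 1) + 1)^-1 = 0.5
        assert between_edge_weight(0, 1, [E, 1, 1], params) == pytest.approx(0.5)

    @given(
        ni=st.integers(min_value=1, max_value=50),
        nj=st.integers(min_value=1, max_value=50),
        b_D=st.floats(min_value=-2.0, max_value=4.0),
    )
    def test_edge_weight_symmetric(self, ni, nj, b_D):
        params = P(b_D=b_D)
        n = [ni, nj, 1]
        assert between_edge_weight(0, 1, n, params) == between_edge_weight(1, 0, n, params)

    def test_split_score_single_edge_unit_weight(self):
        params = P(rho_b=0.02, b_D=0.0)
        n = [1, 1, 1]
        assert split_score({0}, {1}, n, params) == pytest.approx(1.0)
        assert between_region_rate({0}, {1}, n, params) == pytest.approx(params.rho_b)

    def test_split_score_two_unit_edges(self):
        params = P(b_D=0.0)
        assert split_score({0}, {1, 2}, [1, 1, 1], params) == pytest.approx(0.5)

    def test_bipartition_count(self):
        for size in (2, 3, 4):
            rng = frozenset(range(size))
            parts = list(range_bipartitions(rng))
            assert len(parts) == 2 ** (size - 1) - 1
            for k, l in parts:
                assert k | l == rng and not (k & l)


class TestLineageRates:
    def test_single_region_has_no_splits(self):
        rates = lineage_event_rates({0}, [1, 0, 0], P())
        assert rates.between == []
        assert len(rates.within) == 1 and len(rates.extinction) == 1
        assert len(rates.dispersal) == 2  # two unoccupied destinations

    def test_geosse_reduction_constant_rates(self):
        """All exponents zero: every entry equals its base rate."""
        params = P()
        rates = lineage_event_rates({0, 1}, [4, 7, 2], params)
        assert all(r == pytest.approx(params.rho_w) for _, r in rates.within)
        assert all(r == pytest.approx(params.rho_e) for _, r in rates.extinction)
        assert all(r == pytest.approx(params.rho_d) for _, r in rates.dispersal)
        assert all(r == pytest.approx(params.rho_b) for _, r in rates.between)

    def test_two_region_lineage_on_three_regions(self):
        rates = lineage_event_rates({0, 2}, [2, 1, 3], P())
        assert len(rates.within) == 2
        assert len(rates.extinction) == 2
        assert len(rates.dispersal) == 2  # (0 -> 1) and (2 -> 1)
        assert len(rates.between) == 1  # 2^(2-1) - 1

    @given(
        counts=st.lists(st.integers(min_value=1, max_value=30), min_size=3, max_size=3),
        w_D=st.floats(min_value=-2.0, max_value=4.0),
        e_D=st.floats(min_value=-2.0, max_value=4.0),
    )
    def test_all_rates_nonnegative(self, counts, w_D, e_D):
        params = P(w_D=w_D, e_D=e_D, d_D_src=-1.0, d_D_dest=2.0, b_D=-2.0)
        rates = lineage_event_rates({0, 1, 2}, counts, params)
        for group in (rates.within, rates.extinction, rates.dispersal, rates.between):
            for _, r in group:
                assert r >= 0 and math.isfinite(r)


class TestSubmodels:
    def test_bijection(self):
        seen = set()
        for sid in range(8):
            spec = SubmodelSpec.from_id(sid)
            assert spec.submodel_id == sid
            seen.add((spec.dd_extinction, spec.dd_within_speciation, spec.dd_dispersal_dest))
        assert len(seen) == 8

    def test_params_submodel_id(self):
        assert P().submodel_id == 0
        assert P(e_D=1.0, w_D=-1.0, d_D_dest=-0.5).submodel_id == 7
        assert P(w_D=-1.0).submodel_id == 2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            DDParams(rho_w=-0.1, rho_e=0, rho_d=0, rho_b=0)
        with pytest.raises(ValueError):
            DDParams(rho_w=0.1, rho_e=0, rho_d=0, rho_b=0, n_regions=1)
        with pytest.raises(ValueError):
            SubmodelSpec.from_id(8)
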