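import numpy as np
import pytest

from optenvelope import (
    InfeasibleProblemError,
    classify_coupling,
    compute_envelope,
    fba,
    mp_point,
    to_yield_units,
)
from optenvelope.envelope import min_production_at_zero_growth
from optenvelope.toys import make_coupling_toy
from tests.conftest import BIOMASS, PRODUCT


def knocked(model, rids):
    out = model.copy()
    out.knock_out(rids)
    return out


class TestFBA:
    def test_max_biomass(self, toy):
        value, flux = fba(toy, BIOMASS)
        assert value == pytest.approx(4.5, abs=1e-9)
        assert flux[toy.index(BIOMASS)] == pytest.approx(4.5, abs=1e-9)

    def test_max_product_at_zero_growth(self, toy):
        value, _ = fba(toy, PRODUCT, "max", fixed=[(BIOMASS, 0.0)])
        assert value == pytest.approx(10.0, abs=1e-9)

    def test_no_substrate_no_growth(self):
        starved = make_coupling_toy(maintenance_lb=0.0, substrate_ub=0.0)
        assert fba(starved, BIOMASS)[0] == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_fixing_signalled(self, toy):
        with pytest.raises(InfeasibleProblemError):
            fba(toy, PRODUCT, "max", fixed=[(BIOMASS, 100.0)])

    def test_bad_sense_rejected(self, toy):
        with pytest.raises(ValueError):
            fba(toy, BIOMASS, "maximize")


class TestComputeEnvelope:
    def test_wild_type_shape(self, toy):
        env = compute_envelope(toy, BIOMASS, PRODUCT)
        assert len(env.growth_grid) == 100
        assert env.growth_grid[0] == pytest.approx(0.0, abs=1e-9)
        assert env.max_growth == pytest.approx(4.5, abs=1e-9)
        assert np.allclose(env.min_product, 0.0, atol=1e-8)
        assert np.allclose(env.max_product, 10.0 - env.growth_grid, atol=1e-8)

    def test_r5_knockout_shape(self, toy):
        env = compute_envelope(knocked(toy, ["R5"]), BIOMASS, PRODUCT)
        assert env.max_growth == pytest.approx(4.5, abs=1e-9)
        assert np.allclose(env.min_product, env.growth_grid + 1.0, atol=1e-8)
        assert np.allclose(env.max_product, 10.0 - env.growth_grid, atol=1e-8)
        assert env.mp_point == pytest.approx((4.5, 5.5, 5.5), abs=1e-8)

    def test_blocked_product_all_zero(self, toy):
        blocked = toy.copy()
        blocked.upper_bounds[blocked.index(PRODUCT)] = 0.0
        env = compute_envelope(blocked, BIOMASS, PRODUCT)
        assert np.allclose(env.min_product, 0.0, atol=1e-9)
        assert np.allclose(env.max_product, 0.0, atol=1e-9)

    def test_min_max_ordering(self, toy):
        env = compute_envelope(toy, BIOMASS, PRODUCT, n_points=17)
        assert np.all(env.min_product <= env.max_product + 1e-9)
        assert np.all(np.diff(env.growth_grid) > 0)

    def test_two_points_consistent_with_mp(self, toy):
        env = compute_envelope(toy, BIOMASS, PRODUCT, n_points=2)
        assert env.mp_point == pytest.approx(mp_point(toy, BIOMASS, PRODUCT), abs=1e-8)

    def test_npoints_validation(self, toy):
        with pytest.raises(ValueError):
            compute_envelope(toy, BIOMASS, PRODUCT, n_points=1)

    @pytest.mark.parametrize("ko", ["R1", "R2", "R5"])
    def test_knockout_only_shrinks_envelope(self, toy, ko):
        wild = compute_envelope(toy, BIOMASS, PRODUCT, n_points=20)
        sub = knocked(toy, [ko])
        env = compute_envelope(sub, BIOMASS, PRODUCT, n_points=20)
        # compare at shared growth values of the knockout grid
        for g, lo, hi in zip(env.growth_grid, env.min_product, env.max_product):
            w_lo, w_hi = (
                fba(toy, PRODUCT, "min", fixed=[(BIOMASS, g)])[0],
                fba(toy, PRODUCT, "max", fixed=[(BIOMASS, g)])[0],
            )
            assert lo >= w_lo - 1e-8
            assert hi <= w_hi + 1e-8


class TestCoupling:
    def test_strong(self, toy):
        env = compute_envelope(knocked(toy, ["R5"]), BIOMASS, PRODUCT)
        assert env.coupling == "strong"
        assert env.min_production_at_zero_growth == pytest.approx(1.0, abs=1e-8)

    def test_weak_without_maintenance(self, toy_no_maintenance):
        env = compute_envelope(knocked(toy_no_maintenance, ["R5"]), BIOMASS, PRODUCT)
        assert env.coupling == "weak"

    def test_none_for_wild_type(self, toy):
        env = compute_envelope(toy, BIOMASS, PRODUCT)
        assert env.coupling == "none"

    def test_classify_uses_tolerance(self, toy):
        env = compute_envelope(knocked(toy, ["R5"]), BIOMASS, PRODUCT)
        assert classify_coupling(env, tol=2.0) in ("weak", "none")


class TestMPPoint:
    def test_r5_knockout(self, toy):
        assert mp_point(knocked(toy, ["R5"]), BIOMASS, PRODUCT) == pytest.approx(
            (4.5, 5.5, 5.5), abs=1e-8
        )

    def test_wild_type(self, toy):
        assert mp_point(toy, BIOMASS, PRODUCT) == pytest.approx(
            (4.5, 0.0, 5.5), abs=1e-8
        )

    def test_starved(self):
        starved = make_coupling_toy(maintenance_lb=0.0, substrate_ub=0.0)
        assert mp_point(starved, BIOMASS, PRODUCT) == pytest.approx(
            (0.0, 0.0, 0.0), abs=1e-8
        )


class TestYieldUnits:
    def test_acetate_yield(self):
        assert to_yield_units(27.49, 0.06005, 10.0, 0.18016) == pytest.approx(
            0.916, abs=0.001
        )

    def test_biomass_yield(self):
        assert to_yield_units(0.91, 1.0, 10.0, 0.18016) == pytest.approx(0.505, abs=0.001)

    def test_zero_rate(self):
        assert to_yield_units(0.0, 0.06005, 10.0, 0.18016) == 0.0

    def test_zero_uptake_errors(self):
        with pytest.raises(ValueError):
            to_yield_units(1.0, 0.06005, 0.0, 0.18016)


class TestExports:
    def test_tsv_and_json(self, toy, tmp_path):
        env = compute_envelope(toy, BIOMASS, PRODUCT, n_points=5)
        env.to_tsv(tmp_path / "env.tsv")
        env.to_json(tmp_path / "env.json")
        lines = (tmp_path / "env.tsv").read_text().splitlines()
        assert lines[0] == "growth\tmin_product\tmax_product"
        assert len(lines) == 6
        import json

        doc = json.loads((tmp_path / "env.json").read_text())
        assert doc["coupling"] == "none"
        assert len(doc["growth_grid"]) == 5

    def test_zero_growth_min_matches_direct_lp(self, toy):
        env = compute_envelope(knocked(toy, ["R5"]), BIOMASS, PRODUCT, n_points=10)
        assert env.min_production_at_zero_growth == pytest.approx(
            min_production_at_zero_growth(knocked(toy, ["R5"]), BIOMASS, PRODUCT),
            abs=1e-9,
        )
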