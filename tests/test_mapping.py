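"""Admin aggregation, dropout rates, zero-dose counts and surface summaries."""

import numpy as np
import pytest
from shapely.geometry import box

from vaxmono import (
    AdminUnit,
    IntegrityError,
    PredictionGrid,
    SimConfig,
    aggregate_admin,
    compose_targets,
    dropout_rates,
    make_fixture_geography,
    summarize_surface,
    zero_dose,
)
from vaxmono.data_model import assign_cells_to_units
from vaxmono.mapping import admin_summary_table


def _grid(pop, coords=None):
    L = len(pop)
    return PredictionGrid(
        cell_id=np.array([f"g{i}" for i in range(L)], dtype=object),
        coords=np.column_stack([np.arange(L, dtype=float), np.zeros(L)]) if coords is None else coords,
        covariates=np.zeros((L, 0)),
        population=np.asarray(pop, float),
        covariate_names=[],
    )


def _unit(cells, unit_id="U", level="state"):
    u = AdminUnit(unit_id=unit_id, level=level, geometry=box(0, 0, 1, 1))
    u.member_cells = list(cells)
    return u


class TestAggregateAdmin:
    def test_weighted_mean(self):
        grid = _grid([25.0, 75.0])
        draws = {"p1": np.array([[0.4, 0.8]])}
        (summ,) = aggregate_admin(draws, grid, [_unit(["g0", "g1"])])
        assert np.isclose(summ.draws[0], 0.7)

    def test_uniform_surface_invariant_to_population(self, rng):
        grid = _grid(rng.uniform(1, 100, 6))
        draws = {"p1": np.full((8, 6), 0.37)}
        (summ,) = aggregate_admin(draws, grid, [_unit(grid.cell_id)])
        np.testing.assert_allclose(summ.draws, 0.37, atol=1e-12)

    def test_nested_aggregation_is_associative(self, rng):
        pop = rng.uniform(1, 50, 8)
        grid = _grid(pop)
        p = rng.uniform(0, 1, (5, 8))
        d1 = _unit(grid.cell_id[:4], "d1", "district")
        d2 = _unit(grid.cell_id[4:], "d2", "district")
        state = _unit(grid.cell_id, "s", "state")
        summs = aggregate_admin({"p1": p}, grid, [d1, d2, state])
        by_id = {s.unit_id: s for s in summs}
        combined = (by_id["d1"].draws * pop[:4].sum() + by_id["d2"].draws * pop[4:].sum()) / pop.sum()
        np.testing.assert_allclose(combined, by_id["s"].draws, atol=1e-12)

    def test_monotonicity_preserved_across_doses(self, rng):
        grid = _grid(rng.uniform(1, 10, 5))
        t = compose_targets(*rng.uniform(0, 1, (3, 20, 5)))
        summs = aggregate_admin({"p1": t.p1, "p2": t.p2, "p3": t.p3},
                                grid, [_unit(grid.cell_id)])
        by_dose = {s.dose: s.draws for s in summs}
        assert np.all(by_dose["p1"] >= by_dose["p2"] - 1e-12)
        assert np.all(by_dose["p2"] >= by_dose["p3"] - 1e-12)

    def test_zero_population_unit_falls_back_unweighted(self):
        grid = _grid([0.0, 0.0])
        with pytest.warns(UserWarning, match="zero population"):
            (summ,) = aggregate_admin({"p1": np.array([[0.2, 0.6]])}, grid,
                                      [_unit(["g0", "g1"])])
        assert np.isclose(summ.draws[0], 0.4)

    def test_empty_unit_skipped_with_warning(self):
        grid = _grid([1.0])
        with pytest.warns(UserWarning, match="no member cells"):
            out = aggregate_admin({"p1": np.ones((2, 1))}, grid, [_unit([])])
        assert out == []


class TestDropout:
    def test_national_proportions_give_printed_rate(self):
        # DTP1 65.4%, DTP3 49.9% -> relative dropout 23.70%
        t = compose_targets(np.array([[0.654]]), np.array([[0.579 / 0.654]]),
                            np.array([[0.499 / 0.579]]))
        d, _ = dropout_rates(t, (1, 3))
        assert round(float(d[0, 0]), 2) == 23.70

    def test_equal_doses_zero_dropout(self):
        t = compose_targets(np.array([[0.5]]), np.array([[1.0]]), np.array([[1.0]]))
        d, _ = dropout_rates(t, (1, 2))
        assert d[0, 0] == 0.0

    def test_total_dropout_when_later_dose_zero(self):
        t = compose_targets(np.array([[0.8]]), np.array([[0.0]]), np.array([[0.0]]))
        d, _ = dropout_rates(t, (1, 3))
        assert d[0, 0] == 100.0

    def test_zero_reference_is_missing(self):
        t = compose_targets(np.array([[0.0]]), np.array([[0.0]]), np.array([[0.0]]))
        d, _ = dropout_rates(t, (1, 2))
        assert np.isnan(d[0, 0])

    def test_bounds_under_monotonicity(self, rng):
        t = compose_targets(*rng.uniform(0, 1, (3, 50, 40)))
        for pair in ((1, 2), (2, 3), (1, 3)):
            d, _ = dropout_rates(t, pair)
            ok = d[~np.isnan(d)]
            assert np.all((ok >= 0) & (ok <= 100))

    def test_invalid_pair_rejected(self, rng):
        t = compose_targets(*rng.uniform(0, 1, (3, 2, 2)))
        with pytest.raises(ValueError):
            dropout_rates(t, (3, 1))


class TestZeroDose:
    def test_fixed_coverage(self):
        from vaxmono.mapping import AdminSummary
        summ = AdminSummary("U", "state", "p1", np.full(100, 0.6), 0.6, 0.0, 0.6, 0.6)
        (z,) = zero_dose([summ], {"U": 1000.0})
        assert np.isclose(z.mean, 400.0) and np.isclose(z.ci_width, 0.0)

    def test_full_coverage_no_zero_dose(self):
        from vaxmono.mapping import AdminSummary
        summ = AdminSummary("U", "state", "p1", np.ones(10), 1.0, 0.0, 1.0, 1.0)
        (z,) = zero_dose([summ], {"U": 500.0})
        assert z.mean == 0.0

    def test_grid_and_admin_variants_agree_for_flat_coverage(self, rng):
        pop = rng.uniform(10, 100, 4)
        grid = _grid(pop)
        unit = _unit(grid.cell_id)
        p1 = np.tile(rng.uniform(0.2, 0.8, (30, 1)), (1, 4))  # flat within unit
        (summ,) = aggregate_admin({"p1": p1}, grid, [unit])
        (za,) = zero_dose([summ], {"U": pop.sum()})
        (zg,) = zero_dose([summ], {"U": pop.sum()}, grid=grid,
                          p1_grid_draws=p1, units=[unit], grid_level=True)
        np.testing.assert_allclose(za.draws, zg.draws, rtol=1e-9)

    def test_national_total_identity(self, rng):
        # zero-dose means over a partition sum to the national value
        cfg = SimConfig(seed=7, grid_shape=(6, 6))
        grid, units = make_fixture_geography(cfg)
        assign_cells_to_units(grid, units)
        states = [u for u in units if u.level == "state"]
        p1 = rng.uniform(0, 1, (40, len(grid)))
        summs = aggregate_admin({"p1": p1}, grid, states)
        pops = {u.unit_id: grid.population[[list(grid.cell_id).index(c)
                                            for c in u.member_cells]].sum()
                for u in states}
        zs = zero_dose(summs, pops)
        national_w = (p1 @ grid.population).mean() / grid.population.sum()
        expected = grid.population.sum() * (1 - national_w)
        assert np.isclose(sum(z.mean for z in zs), expected, rtol=1e-6)


class TestSummaries:
    def test_constant_draws_sd_zero(self):
        s = summarize_surface(np.full((5, 3), 0.2))
        assert (s["sd"] == 0).all() and (s["mean"] == 0.2).all()

    def test_two_draw_mean(self):
        s = summarize_surface(np.array([[0.4], [0.6]]))
        assert np.isclose(s["mean"][0], 0.5)

    def test_sd_matches_two_pass_oracle(self, rng):
        draws = rng.uniform(0, 1, (64, 9))
        s = summarize_surface(draws)
        oracle = np.sqrt(np.mean((draws - draws.mean(axis=0)) ** 2, axis=0))
        np.testing.assert_allclose(s["sd"], oracle, atol=1e-12)

    def test_summary_table_shape(self, rng):
        grid = _grid(rng.uniform(1, 5, 3))
        summs = aggregate_admin({"p1": rng.uniform(0, 1, (7, 3))}, grid,
                                [_unit(grid.cell_id)])
        df = admin_summary_table(summs)
        assert set(df.columns) == {"unit_id", "level", "dose", "mean", "sd", "q025", "q975"}
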