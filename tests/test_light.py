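import numpy as np
import pytest

from phytomer3d.assembly import Population, Shoot, assemble_population, assemble_shoot
from phytomer3d.core import (
    Component,
    ComponentParams,
    Phytomer,
    PhytomerSlot,
    PlacementTransform,
    PopulationSpec,
    SemanticMesh,
    ShootSpec,
    Skeleton,
)
from phytomer3d.light import (
    LightConfig,
    simulate_light,
    solar_position,
    summarize_central,
    sun_vector,
)

from conftest import flat_leaf_phytomer

ZENITH = LightConfig(incident_model="constant", incident_par=1000.0, fixed_sun=(180.0, 90.0))


def _single_leaf_pop(z=0.0, size=100.0):
    return Population([Shoot([flat_leaf_phytomer(z, size)])], np.zeros((1, 2)), np.zeros(1), None)


class TestSolarGeometry:
    def test_equator_equinox_noon_is_zenith(self):
        _, el = solar_position(0.0, 0.0, 80, 12.0)
        assert el == pytest.approx(90.0, abs=1.0)

    def test_midlatitude_solstice_noon(self):
        _, el = solar_position(40.0, 0.0, 172, 12.0)
        delta = 23.45 * np.sin(2 * np.pi * (284 + 172) / 365.0)
        assert el == pytest.approx(90.0 - 40.0 + delta, abs=1.0)

    def test_sun_below_horizon_at_midnight(self):
        _, el = solar_position(40.0, 0.0, 172, 0.0)
        assert el < 0

    def test_morning_sun_in_the_east(self):
        az, el = solar_position(40.0, 0.0, 172, 8.0)
        assert el > 0
        assert 0 < az < 180  # east of the meridian
        assert sun_vector(az, el)[0] > 0


class TestInterception:
    def test_closed_form_flux_on_one_horizontal_leaf(self):
        """1 m^2 leaf, sun at zenith, constant incident I: accumulated PAR
        equals I x area x duration."""
        res = simulate_light(_single_leaf_pop(), ZENITH, seed=0)
        steps = int((ZENITH.end_hour - ZENITH.start_hour) / (ZENITH.step_minutes / 60.0)) + 1
        expected = 1000.0 * 1.0 * steps * ZENITH.step_minutes * 60.0 * 1e-6
        assert res.table["par_mol"].iloc[0] == pytest.approx(expected, rel=1e-3)
        assert res.table["leaf_area_cm2"].iloc[0] == pytest.approx(1e4)

    def test_fully_shaded_leaf_intercepts_nothing(self):
        lower = flat_leaf_phytomer(0.0, size=100.0, index=1)
        upper = flat_leaf_phytomer(10.0, size=200.0, index=2, offset=(-50.0, -50.0))
        pop = Population([Shoot([lower, upper])], np.zeros((1, 2)), np.zeros(1), None)
        res = simulate_light(pop, ZENITH, seed=0)
        assert res.table.set_index("phytomer")["par_mol"].loc[1] == 0.0
        assert res.table.set_index("phytomer")["par_mol"].loc[2] > 0.0

    def test_interception_bounded_by_footprint(self, small_db):
        """Total intercepted power never exceeds incident flux through the
        canopy footprint (no-scattering energy bound)."""
        spec = ShootSpec(
            [PhytomerSlot("below_ear", PlacementTransform(azimuth=120.0 * j, height=8.0 * j), {})
             for j in range(4)]
        )
        shoot = assemble_shoot(spec, small_db)
        pop = assemble_population(PopulationSpec(2, 2, 40.0, 30.0), shoot)
        cfg = LightConfig(incident_model="constant", incident_par=1000.0,
                          fixed_sun=(180.0, 90.0), start_hour=11.5, end_hour=12.5)
        res = simulate_light(pop, cfg, seed=0)
        verts = np.vstack([
            c.mesh.vertices for s in pop.shoots for p in s.phytomers
            for c in p.components.values()
        ])
        span = verts.max(0) - verts.min(0)
        footprint_m2 = span[0] * span[1] * 1e-4
        assert (res.table["par_mol"] >= 0).all()
        assert (res.steps["intercepted_umol_s"] <= 1000.0 * footprint_m2 * (1 + 1e-9)).all()

    def test_added_geometry_never_increases_interception(self, small_db):
        """Occlusion monotonicity on a 3x3 canopy: inserting an opaque
        plate cannot raise any phytomer's interception."""
        spec = ShootSpec(
            [PhytomerSlot("below_ear", PlacementTransform(azimuth=180.0 * j, height=10.0 * j), {})
             for j in range(3)]
        )
        shoot = assemble_shoot(spec, small_db)
        pspec = PopulationSpec(3, 3, 60.0, 27.8)
        cfg = LightConfig(start_hour=10.0, end_hour=14.0, step_minutes=60.0)
        base_pop = assemble_population(pspec, shoot)
        base = simulate_light(base_pop, cfg, seed=0)

        plate_v = np.array([[-40.0, -40, 60], [40, -40, 60], [40, 40, 60], [-40, 40, 60]])
        plate = Component(
            SemanticMesh(plate_v, np.array([[0, 1, 2], [0, 2, 3]])),
            Skeleton(plate_v[:2], "appendage"),
            ComponentParams("appendage"),
        )
        shaded_pop = assemble_population(pspec, shoot)
        centre = shaded_pop.shoots[4].phytomers[-1]
        centre.components["appendage"] = plate
        shaded = simulate_light(shaded_pop, cfg, seed=0)

        a = base.table.set_index(["shoot", "phytomer"])["par_mol"]
        b = shaded.table.set_index(["shoot", "phytomer"])["par_mol"]
        assert (b <= a * (1 + 1e-9)).all()
        assert b.sum() < a.sum()  # the plate does shade something

    def test_sample_doubling_changes_little(self, small_db):
        spec = ShootSpec(
            [PhytomerSlot("below_ear", PlacementTransform(azimuth=180.0 * j, height=10.0 * j), {})
             for j in range(3)]
        )
        shoot = assemble_shoot(spec, small_db)
        pop = assemble_population(PopulationSpec(2, 2, 40.0, 27.8), shoot)
        cfg4 = LightConfig(start_hour=11.0, end_hour=13.0, samples_per_triangle=4)
        cfg8 = LightConfig(start_hour=11.0, end_hour=13.0, samples_per_triangle=8)
        a = simulate_light(pop, cfg4, seed=0).table["par_mol"].sum()
        b = simulate_light(pop, cfg8, seed=0).table["par_mol"].sum()
        assert abs(a - b) / b < 0.02

    def test_invariant_under_scene_and_sun_rotation(self, small_db):
        from phytomer3d.core import rotation_about_z

        spec = ShootSpec(
            [PhytomerSlot("below_ear", PlacementTransform(azimuth=90.0 * j, height=9.0 * j), {})
             for j in range(3)]
        )
        shoot = assemble_shoot(spec, small_db)
        pop_a = Population([shoot], np.zeros((1, 2)), np.zeros(1), None)
        theta = 50.0
        pop_b = Population([shoot.transformed(rotation_about_z(theta), np.zeros(3))],
                           np.zeros((1, 2)), np.zeros(1), None)
        cfg_a = LightConfig(incident_model="constant", fixed_sun=(140.0, 40.0),
                            start_hour=11.5, end_hour=12.5)
        # compass azimuth is clockwise from north, scene rotation CCW from +X
        cfg_b = LightConfig(incident_model="constant", fixed_sun=(140.0 - theta, 40.0),
                            start_hour=11.5, end_hour=12.5)
        a = simulate_light(pop_a, cfg_a, seed=0).table["par_mol"]
        b = simulate_light(pop_b, cfg_b, seed=0).table["par_mol"]
        assert np.allclose(a, b, rtol=1e-5)

    def test_night_only_period_warns_and_zeroes(self):
        cfg = LightConfig(start_hour=0.5, end_hour=1.5)
        with pytest.warns(UserWarning):
            res = simulate_light(_single_leaf_pop(), cfg, seed=0)
        assert (res.table["par_mol"] == 0).all()


class TestCentralSummary:
    def test_central_block_selection_and_symmetry(self, small_db):
        spec = ShootSpec([PhytomerSlot("below_ear", PlacementTransform(), {})])
        shoot = assemble_shoot(spec, small_db)
        pop = assemble_population(PopulationSpec(3, 3, 60.0, 27.8), shoot)
        res = simulate_light(pop, LightConfig(start_hour=11.5, end_hour=12.5), seed=0)
        centre = summarize_central(res, PopulationSpec(3, 3, 60.0, 27.8), (1, 1))
        mid = res.table[res.table["shoot"] == 5]
        assert centre["par_mol"].iloc[0] == pytest.approx(mid["par_mol"].iloc[0])

    def test_block_must_fit(self):
        import pandas as pd

        from phytomer3d.errors import SpecificationError
        from phytomer3d.light import LightResult

        res = LightResult(pd.DataFrame(columns=["shoot", "phytomer", "leaf_area_cm2",
                                                "par_mol", "par_per_m2"]),
                          pd.DataFrame())
        with pytest.raises(SpecificationError):
            summarize_central(res, PopulationSpec(2, 2, 60.0, 27.8), (3, 3))

    def test_grid_block_counts(self):
        """A 3x3 block centred in a 9x9 grid selects 9 shoots."""
        import pandas as pd

        from phytomer3d.light import LightResult

        rows = [(s, 1, 100.0, float(s), 1.0) for s in range(1, 82)]
        res = LightResult(
            pd.DataFrame(rows, columns=["shoot", "phytomer", "leaf_area_cm2",
                                        "par_mol", "par_per_m2"]),
            pd.DataFrame(),
        )
        pspec = PopulationSpec(9, 9, 60.0, 27.8)
        out = summarize_central(res, pspec, (3, 3))
        selected = [r * 9 + c + 1 for r in (3, 4, 5) for c in (3, 4, 5)]
        assert out["par_mol"].iloc[0] == pytest.approx(np.mean(selected))
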