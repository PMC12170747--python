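"""Habitat-quality model: threat rasters, decay, degradation, and scoring."""

import numpy as np
import pytest
from shapely.geometry import box

from coalscape.habitat import (
    ConfigurationError,
    HQParams,
    SensitivityTable,
    ThreatSpec,
    build_threat_rasters,
    decay_distance,
    default_sensitivity,
    default_threats,
    degradation,
    habitat_quality,
    hq_transition,
    load_params_yaml,
)
from coalscape.raster import Raster
from conftest import make_lc

WOOD, IMP = 2, 5  # class codes


@pytest.fixture
def sens():
    return default_sensitivity()


@pytest.fixture
def threats():
    return default_threats()


class TestSpecs:
    def test_invalid_threat_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            ThreatSpec("bad", max_dist=-1, weight=0.5)
        with pytest.raises(ConfigurationError):
            ThreatSpec("bad", max_dist=1, weight=0.0)
        with pytest.raises(ConfigurationError):
            ThreatSpec("bad", max_dist=1, weight=0.5, decay="cubic")

    def test_non_habitat_classes_have_zero_suitability(self, sens):
        assert sens.suitability["impervious"] == 0.0
        assert all(v == 0 for v in sens.sensitivity["impervious"].values())
        assert not sens.is_habitat("impervious")

    def test_hq_params_positive(self):
        with pytest.raises(ConfigurationError):
            HQParams(z=0.0)

    def test_yaml_roundtrip(self, tmp_path):
        text = """
threats:
  - {name: impervious, max_dist: 4, weight: 1, decay: exponential, source: landcover}
  - {name: mine_squares, max_dist: 6, weight: 1, source: geometry,
     active_years: [2000, 2005]}
sensitivity:
  woodland: {habitat: 0.95, impervious: 0.6, mine_squares: 0.7}
  impervious: {habitat: 0.0, impervious: 0.0, mine_squares: 0.0}
params: {z: 2.5, k: 0.5}
"""
        path = tmp_path / "p.yaml"
        path.write_text(text)
        specs, table, params = load_params_yaml(path)
        assert {s.name for s in specs} == {"impervious", "mine_squares"}
        assert not specs[1].active_in(2020)
        assert table.suitability["woodland"] == 0.95
        assert params.k == 0.5


class TestThreatRasters:
    def test_mine_squares_deactivated_after_closure(self, threats, sens):
        lc = make_lc(np.full((20, 20), WOOD), year=2020)
        geoms = {"mine_squares": [box(100, 100, 300, 300)]}
        out = build_threat_rasters(lc, geoms, 2020, threats, sens)
        assert "mine_squares" not in out
        out_2015 = build_threat_rasters(lc, geoms, 2015, threats, sens)
        assert "mine_squares" in out_2015

    def test_threat_count_per_epoch(self, threats, sens):
        lc = make_lc(np.full((20, 20), WOOD))
        for year, expected in [(2000, 6), (2005, 6), (2010, 6), (2015, 6), (2020, 5)]:
            lc_y = make_lc(np.full((20, 20), WOOD), year=year)
            out = build_threat_rasters(lc_y, {}, year, threats, sens)
            assert len(out) == expected

    def test_zero_impervious_cells_give_zero_raster(self, threats, sens):
        lc = make_lc(np.full((10, 10), WOOD))
        out = build_threat_rasters(lc, {}, 2000, threats, sens)
        assert out["impervious"].values.sum() == 0

    def test_sensitivity_threat_missing_from_specs_raises(self, sens):
        lc = make_lc(np.full((10, 10), WOOD))
        only_two = default_threats()[:2]
        with pytest.raises(ConfigurationError, match="absent from specs"):
            build_threat_rasters(lc, {}, 2000, only_two, sens)


class TestDecay:
    def test_impact_is_one_on_source_cells(self):
        vals = np.zeros((9, 9), dtype=np.uint8)
        vals[4, 4] = 1
        threat = Raster(vals, 30.0, (0.0, 270.0))
        impact = decay_distance(threat, ThreatSpec("t", max_dist=4.0, weight=1.0))
        assert impact.values[4, 4] == pytest.approx(1.0)

    def test_exponential_value_at_max_distance(self):
        # one source cell; a cell exactly d_max away keeps exp(-2.99)
        vals = np.zeros((1, 101), dtype=np.uint8)
        vals[0, 0] = 1
        threat = Raster(vals, 30.0, (0.0, 30.0))
        d_max_m = 1.5 * 1000
        spec = ThreatSpec("t", max_dist=1.5, weight=1.0)
        impact = decay_distance(threat, spec)
        j = int(d_max_m / 30)  # cell 50 is exactly 1500 m from cell 0
        assert impact.values[0, j] == pytest.approx(np.exp(-2.99), rel=1e-9)
        assert impact.values[0, j + 1] == 0.0  # clamped beyond d_max

    def test_linear_decay_profile(self):
        vals = np.zeros((1, 40), dtype=np.uint8)
        vals[0, 0] = 1
        threat = Raster(vals, 30.0, (0.0, 30.0))
        spec = ThreatSpec("t", max_dist=0.6, weight=1.0, decay="linear")
        impact = decay_distance(threat, spec)
        assert impact.values[0, 10] == pytest.approx(1 - 300 / 600)
        assert impact.values[0, 21] == 0.0

    def test_no_source_gives_zero_everywhere(self):
        threat = Raster(np.zeros((5, 5), dtype=np.uint8), 30.0, (0.0, 150.0))
        impact = decay_distance(threat, ThreatSpec("t", max_dist=1.0, weight=0.5))
        assert (impact.values == 0).all()


class TestDegradation:
    def _one_threat_setup(self, s_value=0.3):
        lc = make_lc(np.array([[WOOD, IMP]]))
        spec = ThreatSpec("impervious", max_dist=4.0, weight=1.0)
        impact = Raster(np.array([[1.0, 1.0]]), 30.0, lc.origin)
        return lc, spec, impact

    def test_insensitive_habitat_has_zero_degradation(self, sens):
        lc = make_lc(np.full((4, 4), IMP))  # impervious: all sensitivities 0
        spec = ThreatSpec("impervious", max_dist=4.0, weight=1.0)
        impact = Raster(np.ones((4, 4)), 30.0, lc.origin)
        d = degradation({"impervious": impact}, [spec], sens, lc)
        assert np.allclose(d.values, 0.0)

    def test_single_threat_weight_rescaling_cancels(self, sens):
        lc, spec, impact = self._one_threat_setup()
        d1 = degradation({"impervious": impact}, [spec], sens, lc)
        half = ThreatSpec("impervious", max_dist=4.0, weight=0.5)
        d2 = degradation({"impervious": impact}, [half], sens, lc)
        np.testing.assert_allclose(d1.values, d2.values)

    def test_woodland_next_to_impervious_sole_threat(self, sens):
        # impact 1 at the woodland cell, sensitivity 0.6 (woodland x impervious)
        lc, spec, impact = self._one_threat_setup()
        d = degradation({"impervious": impact}, [spec], sens, lc)
        assert d.values[0, 0] == pytest.approx(sens.sensitivity["woodland"]["impervious"])

    def test_missing_sensitivity_entry_raises(self):
        lc = make_lc(np.array([[WOOD]]))
        spec = ThreatSpec("impervious", max_dist=4.0, weight=1.0)
        impact = Raster(np.ones((1, 1)), 30.0, lc.origin)
        partial = SensitivityTable({"woodland": 0.95}, {"woodland": {}})
        with pytest.raises(ConfigurationError, match="missing sensitivity"):
            degradation({"impervious": impact}, [spec], partial, lc)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_nearest_distance(self, seed, sens, threats):
        """Single-threat degradation equals an explicit per-cell computation."""
        rng = np.random.default_rng(seed)
        n = 30
        vals = np.full((n, n), WOOD)
        vals[rng.random((n, n)) < 0.07] = IMP
        lc = make_lc(vals, cell_size=30.0)
        spec = next(t for t in threats if t.name == "impervious")
        src = (vals == IMP).astype(np.uint8)
        impact = decay_distance(Raster(src, 30.0, lc.origin), spec)
        d = degradation({"impervious": impact}, [spec], sens, lc)

        srcs = np.argwhere(src == 1)
        expect = np.zeros((n, n))
        s_wood = sens.sensitivity["woodland"]["impervious"]
        s_imp = sens.sensitivity["impervious"]["impervious"]
        for r in range(n):
            for c in range(n):
                dd = np.sqrt(((srcs - [r, c]) ** 2).sum(axis=1)).min() * 30.0 if len(srcs) else np.inf
                i = np.exp(-2.99 / (spec.max_dist * 1000) * dd) if dd <= spec.max_dist * 1000 else 0.0
                s = s_imp if vals[r, c] == IMP else s_wood
                expect[r, c] = i * s
        np.testing.assert_allclose(d.values, expect, atol=1e-12)


class TestQuality:
    def test_zero_degradation_returns_suitability(self, sens):
        lc = make_lc(np.array([[WOOD]]))
        d = Raster(np.zeros((1, 1)), 30.0, lc.origin)
        q = habitat_quality(d, lc, sens)
        assert q.values[0, 0] == pytest.approx(0.95)

    def test_half_saturation_identity(self, sens):
        params = HQParams(z=2.5, k=0.5)
        lc = make_lc(np.array([[WOOD]]))
        d = Raster(np.full((1, 1), params.k), 30.0, lc.origin)
        q = habitat_quality(d, lc, sens, params)
        assert q.values[0, 0] == pytest.approx(0.95 / 2)

    def test_non_habitat_is_zero_regardless_of_degradation(self, sens):
        lc = make_lc(np.array([[IMP]]))
        for dval in (0.0, 0.3, 5.0):
            d = Raster(np.full((1, 1), dval), 30.0, lc.origin)
            q = habitat_quality(d, lc, sens)
            assert q.values[0, 0] == 0.0

    def test_quality_bounded_and_monotone_in_degradation(self, sens):
        rng = np.random.default_rng(5)
        lc = make_lc(rng.integers(1, 7, (12, 12)))
        d1 = Raster(rng.uniform(0, 1, (12, 12)), 30.0, lc.origin)
        d2 = Raster(d1.values + rng.uniform(0, 0.5, (12, 12)), 30.0, lc.origin)
        q1 = habitat_quality(d1, lc, sens)
        q2 = habitat_quality(d2, lc, sens)
        assert np.nanmin(q1.values) >= 0
        assert (q2.values <= q1.values + 1e-12).all()
        q0 = habitat_quality(Raster(np.zeros((12, 12)), 30.0, lc.origin), lc, sens)
        hmax = max(sens.suitability.values())
        assert np.nanmax(q0.values) <= hmax + 1e-12


class TestHQTransition:
    def test_identity_is_diagonal(self):
        rng = np.random.default_rng(9)
        q = Raster(rng.uniform(0, 1, (20, 20)), 30.0, (0.0, 600.0), nodata=np.nan)
        tm = hq_transition(q, q)
        off = tm.areas - np.diag(np.diag(tm.areas))
        assert off.sum() == 0

    def test_default_bins_conserve_valid_area(self):
        rng = np.random.default_rng(10)
        a = Raster(rng.uniform(0, 1, (20, 20)), 30.0, (0.0, 600.0), nodata=np.nan)
        b = Raster(rng.uniform(0, 1, (20, 20)), 30.0, (0.0, 600.0), nodata=np.nan)
        tm = hq_transition(a, b)
        assert tm.areas.shape == (5, 5)
        assert tm.total == pytest.approx(400 * 900 / 1e6)

    def test_constant_quality_lands_in_single_bin(self):
        q = Raster(np.full((10, 10), 0.3), 30.0, (0.0, 300.0), nodata=np.nan)
        tm = hq_transition(q, q)
        idx = tm.labels.index("0.2-0.4")
        assert tm.areas[idx, idx] == pytest.approx(tm.total)
        assert (tm.areas.sum() - tm.areas[idx, idx]) == 0

    def test_non_monotone_bins_rejected(self):
        q = Raster(np.full((2, 2), 0.3), 30.0, (0.0, 60.0), nodata=np.nan)
        with pytest.raises(ValueError):
            hq_transition(q, q, bins=[0.4, 0.2])


class TestMineClosureMonotonicity:
    def test_removing_a_threat_never_decreases_quality(self, sens):
        """Dropping the mine-square threat can only raise per-pixel quality."""
        rng = np.random.default_rng(2)
        vals = rng.integers(1, 7, (40, 40))
        lc = make_lc(vals, cell_size=30.0, year=2020)
        geoms = {"mine_squares": [box(300, 300, 700, 700)]}
        active = default_threats(mine_closure_year=None)
        closed = default_threats(mine_closure_year=2020)

        def quality(threats):
            sources = build_threat_rasters(lc, geoms, 2020, threats, sens)
            impacts = {
                n: decay_distance(src, next(t for t in threats if t.name == n))
                for n, src in sources.items()
            }
            d = degradation(impacts, threats, sens, lc)
            return habitat_quality(d, lc, sens)

        q_active = quality(active)
        q_closed = quality(closed)
        assert (q_closed.values >= q_active.values - 1e-12).all()
        assert (q_closed.values > q_active.values).any()
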