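"""Unit and property tests for the cell/patch update rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcsim import core


class TestSurface:
    @pytest.mark.parametrize("n_links, expected", [
        (0, 1.0),        # isolated cell exposes its whole surface
        (3, 0.25),
        (7, 0.125),
    ])
    def test_examples(self, n_links, expected):
        assert core.compute_surface(n_links) == expected

    def test_reciprocal_identity(self):
        # surface * (links + 1) == 1 to within one ulp, for all link counts
        for n in range(0, 200):
            assert core.compute_surface(n) * (n + 1) == pytest.approx(
                1.0, abs=1e-15)

    def test_strictly_decreasing(self):
        surf = core.compute_surface(np.arange(30))
        assert np.all(np.diff(surf) < 0)

    def test_negative_links_rejected(self):
        with pytest.raises(ValueError):
            core.compute_surface(-1)


class TestVulnerability:
    @pytest.mark.parametrize("surface, a, b, expected", [
        (0.5, 2.0, 10.0, 0.5),                       # sigmoid midpoint
        (1.0, 2.0, 10.0, 1.0 / (1.0 + math.exp(-10.0))),
        (0.25, 2.0, 10.0, 1.0 / (1.0 + math.exp(5.0))),
    ])
    def test_hand_evaluated(self, surface, a, b, expected):
        assert core.compute_vulnerability(surface, a, b) == pytest.approx(
            expected, rel=1e-12)

    def test_midpoint_exact_where_surface_a_is_one(self):
        for a in (0.5, 1.0, 2.0, 4.0):
            assert core.compute_vulnerability(1.0 / a, a, 7.3) == 0.5

    @given(st.floats(min_value=1e-6, max_value=1.0),
           st.floats(min_value=1e-6, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_surface_for_positive_b(self, s1, s2):
        lo, hi = sorted((s1, s2))
        v_lo = core.compute_vulnerability(lo, 2.5, 9.0)
        v_hi = core.compute_vulnerability(hi, 2.5, 9.0)
        assert v_lo <= v_hi

    def test_overflow_guarded(self):
        with np.errstate(over="raise"):
            assert core.compute_vulnerability(1.0, 1e6, 1e6) == 1.0
            assert core.compute_vulnerability(1e-9, 1e6, 1e6) >= 0.0


class TestEnergyTerms:
    @pytest.mark.parametrize("resource, metabolic, surface, expected", [
        (1.0, 0.5, 1.0, 0.5),
        (0.0, 3.7, 0.9, 0.0),   # no resource, no gain
        (0.8, 1.0, 0.25, 0.2),
    ])
    def test_gain(self, resource, metabolic, surface, expected):
        assert core.energy_gain(resource, metabolic, surface) == pytest.approx(
            expected)

    def test_cost(self):
        assert core.energy_cost(0.0, 0.9) == 0.0
        assert core.energy_cost(0.4, 0.5) == pytest.approx(0.2)
        # loss term with the vulnerability of a fully exposed cell
        v = core.compute_vulnerability(1.0, 2.0, 10.0)
        assert core.energy_cost(0.8, v) == pytest.approx(0.7999637, abs=1e-7)

    @given(st.floats(0, 5), st.floats(0, 2), st.floats(0.01, 1),
           st.floats(0, 1), st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_budget_update_composition(self, resource, threat, surface,
                                       vuln, energy):
        # one-line oracle for the full energy budget update
        metabolic = 0.7
        oracle = energy + resource * metabolic * surface - threat * vuln
        updated = (energy
                   + core.energy_gain(resource, metabolic, surface)
                   - core.energy_cost(threat, vuln))
        assert updated == pytest.approx(oracle, rel=1e-12, abs=1e-12)


class TestPatchResource:
    def test_uniform_field_is_diffusion_fixed_point(self):
        assert core.update_patch_resource(5.0, [5.0] * 8, d=0.0, k=0.1,
                                          diffusion_active=True) == pytest.approx(5.0)

    def test_pure_degradation(self):
        assert core.update_patch_resource(5.0, [1, 2, 3, 4, 5, 6, 7, 8],
                                          d=0.05, k=0.3,
                                          diffusion_active=False) == pytest.approx(4.75)

    def test_export_without_import(self):
        # a loaded patch among empty neighbours keeps (1 - k) of its stock
        out = core.update_patch_resource(8.0, [0.0] * 8, d=0.0, k=0.1,
                                         diffusion_active=True)
        assert out == pytest.approx(7.2)

    @pytest.mark.parametrize("bad", [{"d": -0.1}, {"d": 1.0}, {"k": -0.2},
                                     {"k": 1.0}])
    def test_fraction_bounds(self, bad):
        kwargs = {"d": 0.1, "k": 0.1, **bad}
        with pytest.raises(ValueError):
            core.update_patch_resource(1.0, [1.0] * 8,
                                       diffusion_active=True, **kwargs)

    def test_grid_conservation_without_degradation(self):
        rng = np.random.default_rng(0)
        field = rng.uniform(0, 10, size=(33, 33))
        total = field.sum()
        for _ in range(25):
            field = core.step_resource_grid(field, d=0.0, k=0.17,
                                            diffusion_active=True)
        assert field.sum() == pytest.approx(total, abs=1e-9)
        assert np.all(field >= 0)

    def test_uniform_grid_stays_uniform(self):
        field = np.full((12, 9), 3.3)
        out = core.step_resource_grid(field, d=0.02, k=0.1,
                                      diffusion_active=True)
        assert np.allclose(out, out[0, 0])

    def test_scalar_and_grid_rules_agree(self):
        rng = np.random.default_rng(3)
        field = rng.uniform(0, 4, size=(6, 6))
        stepped = core.step_resource_grid(field, d=0.04, k=0.12,
                                          diffusion_active=True)
        i, j = 2, 4
        nbrs = [field[(i + di) % 6, (j + dj) % 6]
                for di in (-1, 0, 1) for dj in (-1, 0, 1)
                if (di, dj) != (0, 0)]
        expected = core.update_patch_resource(field[i, j], nbrs, 0.04, 0.12,
                                              diffusion_active=True)
        assert stepped[i, j] == pytest.approx(expected, rel=1e-12)

    def test_literal_mode_injects_resource(self):
        out = core.update_patch_resource(1.0, [1.0] * 8, d=0.0, k=0.1,
                                         diffusion_active=True, mode="literal")
        assert out == pytest.approx(1.8)

    def test_balanced_k_makes_cycle_stationary(self):
        d, period = 0.05, 10
        k = core.balanced_diffusion_k(d, period)
        field = np.full((33, 33), 1.0)
        for t in range(period):
            field = core.step_resource_grid(field, d, k, t % period == 0,
                                            mode="literal")
        assert field.sum() == pytest.approx(33 * 33 * 1.0, rel=1e-12)
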