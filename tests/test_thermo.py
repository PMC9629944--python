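"""Isosteric heat, entropy, Gibbs energy and the compensation regression."""

import math

import numpy as np
import pytest

from sorptherm.fitting import IsothermFit
from sorptherm.models import ModelId, gab
from sorptherm.thermo import (
    GAS_CONSTANT,
    KELVIN_OFFSET,
    ThermoTable,
    compensation,
    gibbs_free_energy,
    harmonic_mean_temperature,
    isosteric_analysis,
    smooth_polynomial,
)


def _pseudo_fit(temp_c, params, key=("s", "desorption")):
    return IsothermFit(
        key[0], key[1], temp_c, ModelId.GAB, tuple(params), (), 1.0, 0.0, True, 1
    )


def _clausius_family(q_j_mol=20_000.0, t0_c=30.0, base=(15.0, 0.9, 8.0)):
    """GAB isotherms at 30/40/50 degC constructed so that ln a_w is exactly
    linear in 1/T at every constant moisture, with slope -q/R.

    Scaling a_w by a temperature factor k maps GAB(a; A, B, C) onto
    GAB(a; A, B/k, C), so setting B(T) = B0 / exp((q/R)(1/T0 - 1/T))
    imposes the relation exactly.
    """
    A, B0, C = base
    t0_k = t0_c + KELVIN_OFFSET
    fits = {}
    for t in (30.0, 40.0, 50.0):
        k = math.exp(q_j_mol / GAS_CONSTANT * (1 / t0_k - 1 / (t + KELVIN_OFFSET)))
        fits[t] = _pseudo_fit(t, (A, B0 / k, C))
    return fits, (A, B0, C), t0_k


class TestIsostericAnalysis:
    def test_recovers_constructed_heat_and_entropy(self):
        q = 20_000.0
        fits, (A, B0, C), t0_k = _clausius_family(q)
        table = isosteric_analysis(fits, xeq_grid=np.arange(5.0, 26.0, 1.0))
        assert len(table.xeq_grid) > 10
        for x, qst, ds in zip(table.xeq_grid, table.qst_kj_mol, table.ds_j_mol_k):
            assert qst * 1000 == pytest.approx(q, rel=1e-6)
            # entropy implied by the 30 degC isotherm: dS = R ln a_w(T0) + q/T0
            aw0 = None
            from sorptherm.models import invert_isotherm

            aw0 = invert_isotherm(ModelId.GAB, (A, B0, C), x)
            expected_ds = GAS_CONSTANT * math.log(aw0) + q / t0_k
            assert ds == pytest.approx(expected_ds, rel=1e-6)

    def test_temperature_independent_isotherm_gives_zero_heat(self):
        params = (15.0, 0.9, 8.0)
        fits = {t: _pseudo_fit(t, params) for t in (30.0, 40.0, 50.0)}
        table = isosteric_analysis(fits, xeq_grid=[10.0, 15.0, 20.0])
        assert np.allclose(table.qst_kj_mol, 0.0, atol=1e-9)

    def test_unattainable_grid_points_dropped(self):
        fits, *_ = _clausius_family()
        table = isosteric_analysis(fits, xeq_grid=[15.0, 1e5])
        assert table.xeq_grid == (15.0,)

    def test_mixed_samples_rejected(self):
        fits, *_ = _clausius_family()
        bad = dict(fits)
        bad[50.0] = _pseudo_fit(50.0, (15.0, 0.8, 8.0), key=("other", "desorption"))
        with pytest.raises(ValueError, match="mix"):
            isosteric_analysis(bad)

    def test_single_temperature_rejected(self):
        fits, *_ = _clausius_family()
        with pytest.raises(ValueError):
            isosteric_analysis({30.0: fits[30.0]})


class TestGibbs:
    def test_approaches_zero_at_saturation(self):
        assert gibbs_free_energy(1 - 1e-12, 303.15) == pytest.approx(0.0, abs=1e-6)

    def test_hand_value(self):
        assert gibbs_free_energy(0.5, 303.15) == pytest.approx(
            8.314 * 303.15 * math.log(0.5), rel=1e-12
        )

    def test_strictly_increasing_in_aw(self):
        vals = [gibbs_free_energy(a, 313.15) for a in np.linspace(0.05, 0.95, 50)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("aw", [0.0, 1.0, -0.2, 1.5])
    def test_domain(self, aw):
        with pytest.raises(ValueError):
            gibbs_free_energy(aw, 303.15)


class TestPolynomialSmooth:
    def test_exact_cubic_recovery(self):
        x = np.arange(10.0, 26.0)
        true = [0.5, -2.0, 3.0, 7.0]
        y = np.polyval(true, x)
        coeffs, r = smooth_polynomial(x, y, 3)
        assert np.allclose(coeffs, true, rtol=1e-8)
        assert r == pytest.approx(1.0)

    def test_degree_zero_is_mean(self):
        coeffs, _ = smooth_polynomial([1, 2, 3], [5.0, 7.0, 9.0], 0)
        assert coeffs[0] == pytest.approx(7.0)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            smooth_polynomial([1, 2], [1.0, 2.0], 3)


def _table(ds_vals, qst_kj):
    n = len(ds_vals)
    return ThermoTable(
        "s", "desorption", (30.0, 40.0, 50.0),
        tuple(float(10 + i) for i in range(n)),
        tuple((0.3, 0.35, 0.4) for _ in range(n)),
        tuple(qst_kj), tuple(ds_vals), tuple(1.0 for _ in range(n)),
    )


class TestCompensation:
    def test_exact_line_recovered(self):
        ds = [10.0, 20.0, 30.0, 40.0, 50.0]
        qst_kj = [(350.0 * s + 800.0) / 1000.0 for s in ds]
        res = compensation(_table(ds, qst_kj))
        assert res.t_beta_k == pytest.approx(350.0, rel=1e-9)
        assert res.dg_beta_j_mol == pytest.approx(800.0, rel=1e-9)
        assert not res.spontaneous
        assert res.compensation_valid

    def test_negative_intercept_is_spontaneous(self):
        ds = [10.0, 20.0, 30.0]
        qst_kj = [(300.0 * s - 500.0) / 1000.0 for s in ds]
        assert compensation(_table(ds, qst_kj)).spontaneous

    def test_harmonic_mean_temperature(self):
        assert harmonic_mean_temperature([30, 40, 50]) == pytest.approx(
            312.94, abs=0.01
        )

    def test_degenerate_entropy_spread_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compensation(_table([5.0, 5.0, 5.0], [1.0, 2.0, 3.0]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            compensation(_table([1.0, 2.0], [1.0, 2.0]))


class TestGridStability:
    def test_t_beta_stable_under_grid_refinement(self):
        """Halving the moisture grid spacing moves T_beta by < 2 %."""
        fits, *_ = _clausius_family()
        # perturb one temperature so q_st varies with moisture (non-trivial line)
        a, b, c = fits[50.0].params
        fits[50.0] = _pseudo_fit(50.0, (a, b * 0.97, c + 1.0))
        coarse = compensation(
            isosteric_analysis(fits, xeq_grid=np.arange(10.0, 26.0, 2.0))
        )
        fine = compensation(
            isosteric_analysis(fits, xeq_grid=np.arange(10.0, 26.0, 1.0))
        )
        assert fine.t_beta_k == pytest.approx(coarse.t_beta_k, rel=0.02)
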