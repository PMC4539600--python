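"""Reaction kinetics of the per-cell crosstalk network.

The random-state checks compare the implementation against independently
hand-expanded formulas (written out term by term here, not imported from
the package), and the cascade checks integrate the seven-species receptor
subsystem with scipy's ODE solver as an independent oracle.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from rootcrosstalk import KineticParameters, apply_genotype
from rootcrosstalk import network
from rootcrosstalk.network import (
    auxin_reaction_rate, cytokinin_reaction_rate, ethylene_reaction_rate,
    receptor_cascade_rates, pls_expression_rates, pin_expression_rates,
    aux1_expression_rates,
)

SPECIES = ("auxin", "et", "ck", "plsm", "plsp", "pinm", "pinp_cyt",
           "aux1m", "aux1p_cyt", "ra", "ras", "re", "res", "ctr", "ctrs", "x")


def random_state(rng, scale=1.0):
    return {k: float(rng.uniform(0, scale)) for k in SPECIES}


@pytest.fixture()
def p():
    return KineticParameters()


class TestAuxinRate:
    def test_zero_state_gives_basal_synthesis(self, p):
        s = {k: 0.0 for k in SPECIES}
        assert auxin_reaction_rate(s, p) == pytest.approx(p.k_a0)

    def test_ck_inhibition_saturates_at_residual(self, p):
        s = {k: 0.0 for k in SPECIES}
        s["ck"] = 1e12
        assert auxin_reaction_rate(s, p) == pytest.approx(
            p.k_a0 * p.rho_a, rel=1e-6)

    def test_monotone_in_x_and_ck(self, p, rng):
        s = random_state(rng)
        lo, hi = dict(s, x=0.1), dict(s, x=0.5)
        assert auxin_reaction_rate(hi, p) >= auxin_reaction_rate(lo, p)
        lo, hi = dict(s, ck=0.1), dict(s, ck=0.5)
        assert auxin_reaction_rate(hi, p) <= auxin_reaction_rate(lo, p)

    def test_jones_mode_activates_instead(self, p, rng):
        pj = p.copy(ck_auxin_mode="jones")
        s = random_state(rng)
        lo, hi = dict(s, ck=0.1), dict(s, ck=0.5)
        assert auxin_reaction_rate(hi, pj) >= auxin_reaction_rate(lo, pj)

    def test_negative_input_rejected(self, p):
        s = {k: 0.0 for k in SPECIES}
        s["auxin"] = -1.0
        with pytest.raises(ValueError):
            auxin_reaction_rate(s, p)

    def test_matches_hand_expanded_formula(self, p, rng):
        for _ in range(20):
            s = random_state(rng, scale=3.0)
            expected = (
                (p.k_a0 + p.k_ax * s["x"] / (p.K_xa + s["x"]))
                * (p.rho_a + (1 - p.rho_a) / (1 + s["ck"] / p.K_cka))
                - p.d_a * s["auxin"]
            )
            assert auxin_reaction_rate(s, p) == pytest.approx(expected, rel=1e-12)


class TestCytokininRate:
    def test_no_synthesis_outside_central_files(self, p, rng):
        s = random_state(rng)
        for ct in ("epidermis", "outer", "columella", "qc"):
            assert cytokinin_reaction_rate(s, p, ct) == pytest.approx(
                -p.d_ck * s["ck"])

    def test_vascular_basal_synthesis_at_zero_auxin(self, p):
        s = {k: 0.0 for k in SPECIES}
        assert cytokinin_reaction_rate(s, p, "vascular") == pytest.approx(p.s_ck)

    def test_synthesis_strictly_decreasing_in_auxin(self, p):
        s = {k: 0.0 for k in SPECIES}
        rates = []
        for a in np.linspace(0, 2, 9):
            rates.append(cytokinin_reaction_rate(dict(s, auxin=a), p, "vascular"))
        assert np.all(np.diff(rates) < 0)


class TestEthyleneRate:
    def test_basal_at_zero_hormones(self, p):
        s = {k: 0.0 for k in SPECIES}
        s["et"] = 0.7
        assert ethylene_reaction_rate(s, p) == pytest.approx(
            p.k_e0 - p.d_et * 0.7)

    def test_synergistic_in_auxin_and_ck(self, p, rng):
        s = random_state(rng)
        base = ethylene_reaction_rate(s, p)
        assert ethylene_reaction_rate(dict(s, auxin=2 * s["auxin"] + 1), p) >= base
        assert ethylene_reaction_rate(dict(s, ck=2 * s["ck"] + 1), p) >= base

    def test_independent_of_pls(self, p, rng):
        s = random_state(rng)
        assert ethylene_reaction_rate(dict(s, plsp=0.0), p) == \
            ethylene_reaction_rate(dict(s, plsp=9.0), p)

    def test_matches_hand_expanded_formula(self, p, rng):
        for _ in range(20):
            s = random_state(rng, scale=3.0)
            expected = (p.k_e0
                        + p.k_es * s["auxin"] / (p.K_ae + s["auxin"])
                        * s["ck"] / (p.K_cke + s["ck"])
                        - p.d_et * s["et"])
            assert ethylene_reaction_rate(s, p) == pytest.approx(expected, rel=1e-12)


def cascade_rhs(p, a, et):
    """Independent right-hand side of the 7-species cascade subsystem."""
    def f(_, y):
        ra, ras, re, res, ctr, ctrs, x = y
        d_ras = p.k_ra_on * a * ra - p.k_ra_off * ras
        d_res = (p.k_re_off + p.k_re_pls * 0.0) * re - p.k_re_et * et * res
        d_ctrs = p.k_ctr_on * res * ctr - p.k_ctr_off * ctrs
        d_x = p.k_x / (1 + ctrs / p.K_ctrx) - p.d_x * x
        return [-d_ras, d_ras, -d_res, d_res, -d_ctrs, d_ctrs, d_x]
    return f


class TestReceptorCascade:
    def test_pair_sums_conserved(self, p, rng):
        s = random_state(rng)
        r = receptor_cascade_rates(s, p)
        assert r["ra"] + r["ras"] == pytest.approx(0.0, abs=1e-15)
        assert r["re"] + r["res"] == pytest.approx(0.0, abs=1e-15)
        assert r["ctr"] + r["ctrs"] == pytest.approx(0.0, abs=1e-15)

    def test_pls_promotes_active_ethylene_receptor(self, p):
        s = {k: 0.0 for k in SPECIES}
        s.update(re=1.0, plsp=1.0)
        r = receptor_cascade_rates(s, p)
        assert r["res"] > 0

    def test_steady_x_increases_with_ethylene(self, p):
        """Integrating the subsystem at two ET levels: more ethylene
        deactivates the receptor, relieves CTR1 repression and raises X."""
        y0 = [1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0]
        xs = []
        for et in (0.2, 2.0):
            sol = solve_ivp(cascade_rhs(p, a=0.5, et=et), (0, 50000), y0,
                            method="LSODA", rtol=1e-10, atol=1e-12)
            xs.append(sol.y[6, -1])
        assert xs[1] > xs[0] * 1.05

    def test_rates_match_independent_rhs(self, p, rng):
        s = random_state(rng)
        s["plsp"] = 0.0
        r = receptor_cascade_rates(s, p)
        f = cascade_rhs(p, a=s["auxin"], et=s["et"])
        y = [s[k] for k in ("ra", "ras", "re", "res", "ctr", "ctrs", "x")]
        expected = f(0.0, y)
        got = [r[k] for k in ("ra", "ras", "re", "res", "ctr", "ctrs", "x")]
        assert got == pytest.approx(expected, rel=1e-12)


class TestExpressionModules:
    def test_pls_knockout_leaves_pure_decay(self, p, rng):
        pk = apply_genotype(p, "pls")
        s = random_state(rng)
        d_plsm, d_plsp = pls_expression_rates(s, pk)
        assert d_plsm == pytest.approx(-pk.d_plsm * s["plsm"])
        assert d_plsp == pytest.approx(-pk.d_plsp * s["plsp"])

    def test_pls_basal_floor_without_auxin_signal(self, p):
        s = {k: 0.0 for k in SPECIES}
        d_plsm, _ = pls_expression_rates(s, p)
        assert d_plsm == pytest.approx(p.k_plsm * p.f0_pls)

    def test_plsox_adds_constitutive_term(self, p):
        s = {k: 0.0 for k in SPECIES}
        pox = apply_genotype(p, "plsox")
        d_ref, _ = pls_expression_rates(s, p)
        d_ox, _ = pls_expression_rates(s, pox)
        assert d_ox == pytest.approx(d_ref + pox.k_plsm_ox)

    def test_ablation_removes_auxin_dependence(self, p):
        pab = apply_genotype(p, "pls_no_auxin_regulation")
        s = {k: 0.5 for k in SPECIES}
        lo = pls_expression_rates(dict(s, ras=0.0), pab)[0]
        hi = pls_expression_rates(dict(s, ras=5.0), pab)[0]
        assert lo == pytest.approx(hi)

    def test_pin_transcription_factors(self, p, rng):
        s = random_state(rng)
        # saturating CK repression: falls to a floor, never to zero
        hi_ck = pin_expression_rates(dict(s, ck=1e12, pinm=0.0), p)[0]
        assert hi_ck > 0
        assert hi_ck < pin_expression_rates(dict(s, ck=0.0, pinm=0.0), p)[0]
        # X elevation raises transcription at fixed auxin/CK
        lo = pin_expression_rates(dict(s, x=0.05, pinm=0.0), p)[0]
        hi = pin_expression_rates(dict(s, x=0.5, pinm=0.0), p)[0]
        assert hi > lo

    def test_pin_matches_hand_expanded_formula(self, p, rng):
        for _ in range(20):
            s = random_state(rng, scale=3.0)
            fa = p.f0a_pin + (1 - p.f0a_pin) * s["ras"] / (p.K_ras_pin + s["ras"])
            fx = p.f0x_pin + (1 - p.f0x_pin) * s["x"] / (p.K_x_pin + s["x"])
            fc = p.rho_pin + (1 - p.rho_pin) / (1 + s["ck"] / p.K_ck_pin)
            expected = p.k_pinm * fa * fx * fc - p.d_pinm * s["pinm"]
            assert pin_expression_rates(s, p)[0] == pytest.approx(expected, rel=1e-12)

    def test_aux1_transcription_follows_x(self, p):
        s = {k: 0.0 for k in SPECIES}
        assert aux1_expression_rates(s, p)[0] == pytest.approx(
            p.k_aux1m * p.f0_aux1)
        rates = [aux1_expression_rates(dict(s, x=x), p)[0]
                 for x in np.linspace(0, 2, 8)]
        assert np.all(np.diff(rates) > 0)
        assert rates[-1] < p.k_aux1m  # saturates below the full rate


def full_point_rhs(p, ck_synth=True):
    """Independent ODE right-hand side of one isolated cytosol point
    (no transport, no recycling), assembled from the module surface."""
    def f(_, y):
        s = dict(zip(SPECIES, y))
        r = {k: 0.0 for k in SPECIES}
        r["auxin"] = auxin_reaction_rate(s, p)
        r["ck"] = cytokinin_reaction_rate(s, p,
                                          "vascular" if ck_synth else "epidermis")
        r["et"] = ethylene_reaction_rate(s, p)
        r.update(receptor_cascade_rates(s, p))
        r["plsm"], r["plsp"] = pls_expression_rates(s, p)
        r["pinm"], r["pinp_cyt"] = pin_expression_rates(s, p)
        r["aux1m"], r["aux1p_cyt"] = aux1_expression_rates(s, p)
        return [r[k] for k in SPECIES]
    return f


def test_single_point_stays_nonnegative(p=None):
    """Integrating one point with no transport keeps all species >= 0 and
    the receptor totals conserved."""
    p = KineticParameters()
    y0 = [0.0] * len(SPECIES)
    y0[SPECIES.index("ra")] = p.ra_total
    y0[SPECIES.index("re")] = p.re_total
    y0[SPECIES.index("ctr")] = p.ctr_total
    sol = solve_ivp(full_point_rhs(p), (0, 20000), y0, method="LSODA",
                    rtol=1e-8, atol=1e-12)
    assert sol.y.min() > -1e-9
    ra = sol.y[SPECIES.index("ra")] + sol.y[SPECIES.index("ras")]
    assert np.allclose(ra, p.ra_total, rtol=1e-6)
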