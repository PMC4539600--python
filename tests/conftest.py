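import numpy as np
import pytest

from rootcrosstalk import (
    GridSpec, KineticParameters, Simulator, SolverSettings, build_root_map,
    default_parameters, minimal_spec,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def tiny_map():
    """Two tiers of one mirrored vascular file (4 cells)."""
    return build_root_map(minimal_spec(n_tiers=2, files=(("vascular", 8.0),)))


@pytest.fixture(scope="session")
def two_cell_map():
    """One tier, one mirrored vascular file: the 2-cell oracle fixture."""
    return build_root_map(
        minimal_spec(n_tiers=1, files=(("vascular", 8.0),), cell_length=8.0,
                     spacing=4.0))


@pytest.fixture(scope="session")
def small_root_spec():
    """A complete miniature root: cap + QC + MZ + EZ, four files per side."""
    return GridSpec(
        spacing=2.0,
        file_widths=(8.0, 8.0, 8.0, 12.0),
        file_types=("epidermis", "outer", "pericycle", "vascular"),
        columella_tier_lengths=(8.0, 8.0),
        qc_length=8.0,
        mz_cell_length=8.0,
        mz_length=32.0,
        ez_cell_lengths=(12.0, 16.0),
    )


@pytest.fixture(scope="session")
def small_root_map(small_root_spec):
    return build_root_map(small_root_spec)


def fast_fixture_params(**overrides):
    """Parameters rescaled for explicit-integration oracles on tiny maps:
    smaller diffusivities and faster decays so both the explicit and the
    implicit path reach steady state quickly.  Kinetic structure unchanged."""
    base = dict(
        D_auxin=5.0, D_auxin_wall=2.0, D_et=5.0, D_et_wall=5.0,
        D_ck=5.0, D_ck_wall=2.0, D_mrna=0.5, D_protein=0.5,
        D_receptor=0.5, D_x=1.0,
        P_et_mem=2.0, P_ck_mem=1.0, P_pin=1.0, P_aux1=1.0,
        d_a=0.05, d_ck=0.05, d_et=0.05, d_x=0.1,
        s_ck=0.02, k_e0=0.05, k_a0=0.01, k_ax=0.02,
        k_x=0.05,
        d_plsm=0.05, d_plsp=0.05, k_plsm=0.02, k_pls_transl=0.05,
        d_pinm=0.05, d_pinp=0.05, k_pinm=0.02, k_pin_transl=0.05,
        d_aux1m=0.05, d_aux1p=0.05, k_aux1m=0.02, k_aux1_transl=0.05,
        k_pin_exo=0.05, k_pin_endo=0.02, k_aux1_exo=0.05, k_aux1_endo=0.02,
        k_ra_on=0.5, k_ra_off=0.5, k_re_et=0.5, k_re_off=0.05,
        k_re_pls=0.5, k_ctr_on=0.5, k_ctr_off=0.2,
        k_influx_shoot=0.2, k_efflux_shoot=0.2,
        P_et_shoot=1.0, P_ck_shoot=0.5, et_shoot=1.0, ck_shoot=0.2,
    )
    base.update(overrides)
    return KineticParameters(**base)


def transport_only_params(**overrides):
    """All reactions, recycling and boundary exchange switched off: a closed
    diffusion(+carrier) system for conservation oracles."""
    zeroed = dict(
        k_a0=0.0, k_ax=0.0, d_a=0.0, s_ck=0.0, d_ck=0.0, k_e0=0.0,
        k_es=0.0, d_et=0.0, k_x=0.0, d_x=0.0, k_plsm=0.0, d_plsm=0.0,
        k_pls_transl=0.0, d_plsp=0.0, k_pinm=0.0, d_pinm=0.0,
        k_pin_transl=0.0, d_pinp=0.0, k_aux1m=0.0, d_aux1m=0.0,
        k_aux1_transl=0.0, d_aux1p=0.0,
        k_pin_exo=0.0, k_pin_endo=0.0, k_aux1_exo=0.0, k_aux1_endo=0.0,
        k_ra_on=0.0, k_ra_off=0.0, k_re_et=0.0, k_re_off=0.0, k_re_pls=0.0,
        k_ctr_on=0.0, k_ctr_off=0.0,
        k_influx_shoot=0.0, k_efflux_shoot=0.0,
        P_et_shoot=0.0, P_ck_shoot=0.0,
        D_auxin=5.0, D_auxin_wall=2.0, D_et=5.0, D_et_wall=5.0,
        D_ck=5.0, D_ck_wall=2.0,
        P_et_mem=2.0, P_ck_mem=1.0, P_pin=1.0, P_aux1=1.0,
    )
    zeroed.update(overrides)
    return KineticParameters(**zeroed)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
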