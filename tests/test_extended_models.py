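"""Structural checks of the KB and VKBL model engines.

The published rate values are config-supplied, so these tests use small
synthetic parameter sets chosen only to exercise the model structure:
multiplicities, mass balance, equilibria, and the reduced-PDMP semantics.
"""

import importlib.resources as resources
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from titrosc.extended_models import (
    KbParams,
    KbState,
    VkblParams,
    VkblState,
    kb_drift,
    kb_hazards,
    rescale_mrna,
    simulate_kb_pdmp,
    simulate_reduced_pdmp_kb,
    simulate_vkbl_pdmp,
    vkbl_drift,
    vkbl_hazards,
)
from titrosc.pdmp_engine import occupancy_stats


def synthetic_kb(**overrides) -> KbParams:
    """Small synthetic KB parameter set for structural tests only."""
    base = dict(V=100, G_max=3, tx_A=1.0, tx_I_free=0.2, tx_I_bound=4.0,
                tl_A=2.0, tl_I=2.0, delta_rA=1.0, delta_rI=1.0,
                delta_A=0.3, delta_A2=0.3, delta_I=0.3, delta_AI=0.3,
                k_dim_f=1.0, k_dim_r=1.0, k_het_f=5.0, k_het_r=0.1,
                kappa_b=0.5, theta_b=0.3)
    base.update(overrides)
    return KbParams(**base)


def synthetic_vkbl(**overrides) -> VkblParams:
    """Small synthetic VKBL parameter set for structural tests only."""
    base = dict(V=100, tx_A_free=5.0, tx_A_bound=50.0, tx_R_free=0.01,
                tx_R_bound=5.0, tl_A=5.0, tl_R=1.0, delta_mA=1.0,
                delta_mR=0.5, delta_A=1.0, delta_R=0.2, k_C=20.0,
                kappa_A=1.0, theta_A=5.0, kappa_R=1.0, theta_R=10.0)
    base.update(overrides)
    return VkblParams(**base)


class TestParamLoading:
    def test_templates_are_structurally_complete_but_unset(self):
        tpl = resources.files("titrosc") / "templates" / "kb_params.yaml"
        with pytest.raises(ValueError, match="missing"):
            KbParams.load(str(tpl))
        tpl = resources.files("titrosc") / "templates" / "vkbl_params.yaml"
        with pytest.raises(ValueError, match="missing"):
            VkblParams.load(str(tpl))

    def test_complete_dict_loads(self):
        p = KbParams.load({f.name: getattr(synthetic_kb(), f.name)
                           for f in synthetic_kb().__dataclass_fields__.values()})
        assert p == synthetic_kb()

    def test_unknown_key_rejected(self):
        d = {f: getattr(synthetic_vkbl(), f)
             for f in synthetic_vkbl().__dataclass_fields__}
        d["typo"] = 1.0
        with pytest.raises(ValueError, match="unknown"):
            VkblParams.load(d)


class TestKbStructure:
    def test_zero_rates_freeze_everything(self):
        p = synthetic_kb(tx_A=0, tx_I_free=0, tx_I_bound=0, tl_A=0, tl_I=0,
                         delta_rA=0, delta_rI=0, delta_A=0, delta_A2=0,
                         delta_I=0, delta_AI=0, k_dim_f=0, k_dim_r=0,
                         k_het_f=0, k_het_r=0, kappa_b=0, theta_b=0)
        st = KbState(1, 1, 1, 1, 1, 1, G=1)
        assert np.all(kb_drift(st, p) == 0)
        assert all(rate == 0 for _, rate in kb_hazards(st, p))

    def test_distributive_multiplicity_boundaries(self):
        p = synthetic_kb()
        hz = dict(kb_hazards(KbState(A2=2.0, G=p.G_max), p))
        assert "bind" not in hz and hz["unbind"] == pytest.approx(
            p.theta_b * p.G_max)
        hz = dict(kb_hazards(KbState(A2=2.0, G=0), p))
        assert "unbind" not in hz and hz["bind"] == pytest.approx(
            p.kappa_b * p.G_max * 2.0)

    def test_dimerization_relaxes_to_mass_action_equilibrium(self):
        p = synthetic_kb(tx_A=0, tl_A=0, delta_A=0, delta_A2=0, k_het_f=0,
                         k_het_r=0, k_dim_f=2.0, k_dim_r=1.0)
        z0 = KbState(A=3.0, A2=0.0)
        sol = solve_ivp(lambda t, z: kb_drift(KbState(*z), p), (0, 200),
                        z0.z(), rtol=1e-10, atol=1e-12)
        A, A2 = sol.y[2, -1], sol.y[3, -1]
        assert p.k_dim_f * A**2 == pytest.approx(p.k_dim_r * A2, rel=1e-6)
        assert A + 2 * A2 == pytest.approx(3.0, rel=1e-8)  # mass conserved

    def test_promoter_state_stays_in_bounds(self):
        p = synthetic_kb()
        traj = simulate_kb_pdmp(p, t_end=40.0, seed=3)
        G = traj.columns["G"]
        assert G.min() >= 0 and G.max() <= p.G_max


class TestMrnaRescaling:
    def test_identity_at_one(self):
        p = synthetic_kb()
        assert rescale_mrna(p, 1.0) == p

    @pytest.mark.parametrize("w", [1.0, 4.0, 16.0])
    def test_steady_state_protein_flux_invariant(self, w):
        """For an unregulated gene, mRNA_ss = tx/delta_m, so the protein
        synthesis flux tl * mRNA_ss must not move with the rescaling."""
        p0 = synthetic_kb()
        p = rescale_mrna(p0, w)
        flux0 = p0.tl_A * p0.tx_A / p0.delta_rA
        flux = p.tl_A * p.tx_A / p.delta_rA
        assert flux == pytest.approx(flux0, rel=1e-12)

    def test_relaxation_time_shrinks(self):
        p = rescale_mrna(synthetic_kb(), 4.0)
        assert 1.0 / p.delta_rA == pytest.approx(0.25 / synthetic_kb().delta_rA)


class TestReducedKb:
    def test_constant_dimer_pool_binding_time(self):
        """With a frozen flow the binding survival is exponential and the
        deterministic binding fires at 1/(kappa_b (G_max - G) [A2])."""
        p = synthetic_kb(tx_A=0, tx_I_free=0, tx_I_bound=0, tl_A=0, tl_I=0,
                         delta_rA=0, delta_rI=0, delta_A=0, delta_A2=0,
                         delta_I=0, delta_AI=0, k_dim_f=0, k_dim_r=0,
                         k_het_f=0, k_het_r=0, theta_b=0.0, kappa_b=0.5,
                         V=1e6)
        c = 2.0
        traj = simulate_reduced_pdmp_kb(
            p, init=KbState(A2=c), t_end=10.0, seed=0)
        jumps = np.flatnonzero(np.diff(traj.columns["G"]) > 0)
        t_first = traj.times[jumps[0] + 1]
        assert t_first == pytest.approx(1.0 / (p.kappa_b * p.G_max * c),
                                        rel=1e-3)

    def test_without_unbinding_promoter_saturates(self):
        # suppress the inhibitor branch so the dimer pool keeps growing
        p = synthetic_kb(theta_b=0.0, tx_I_free=0, tx_I_bound=0,
                         k_het_f=0, k_het_r=0)
        traj = simulate_reduced_pdmp_kb(p, t_end=60.0, seed=1)
        G = traj.columns["G"]
        assert np.all(np.diff(G) >= 0)
        assert G[-1] == p.G_max

    def test_reduced_and_full_period_statistics_comparable(self):
        """Structural sanity at synthetic parameters: both engines produce
        promoter cycling with overlapping G dynamics."""
        p = synthetic_kb()
        full = simulate_kb_pdmp(p, t_end=120.0, seed=5)
        red = simulate_reduced_pdmp_kb(p, t_end=120.0, seed=5)
        assert full.columns["G"].max() >= 1
        assert red.columns["G"].max() >= 1


class TestVkblStructure:
    def test_zero_rates_freeze_everything(self):
        p = synthetic_vkbl(tx_A_free=0, tx_A_bound=0, tx_R_free=0,
                           tx_R_bound=0, tl_A=0, tl_R=0, delta_mA=0,
                           delta_mR=0, delta_A=0, delta_R=0, k_C=0,
                           kappa_A=0, theta_A=0, kappa_R=0, theta_R=0)
        st = VkblState(1, 1, 1, 1, 1, 0, 0)
        assert np.all(vkbl_drift(st, p) == 0)
        assert all(rate == 0 for _, rate in vkbl_hazards(st, p))

    def test_bound_promoter_cannot_bind_again(self):
        hz = dict(vkbl_hazards(VkblState(A=3.0, G_A=1, G_R=0),
                               synthetic_vkbl()))
        assert "bind_A" not in hz and "unbind_A" in hz

    def test_inhibitor_recycled_on_complexed_degradation(self):
        p = synthetic_vkbl()
        st = VkblState(A=0.0, R=0.0, C=4.0)
        d = vkbl_drift(st, p)
        assert d[3] == pytest.approx(p.delta_A * 4.0)   # dR/dt
        assert d[4] == pytest.approx(-p.delta_A * 4.0)  # dC/dt

    def test_telegraph_occupancy_at_frozen_activator(self):
        p = synthetic_vkbl(tx_A_free=0, tx_A_bound=0, tx_R_free=0,
                           tx_R_bound=0, tl_A=0, tl_R=0, delta_mA=0,
                           delta_mR=0, delta_A=0, delta_R=0, k_C=0,
                           kappa_A=1.0, theta_A=2.0, kappa_R=0.0,
                           theta_R=1.0, V=1e9)
        a = 4.0
        traj = simulate_vkbl_pdmp(p, init=VkblState(A=a), t_end=600.0,
                                  seed=2, sample_dt=0.5)
        occ = occupancy_stats(traj, column="G_A")
        expected = p.kappa_A * a / (p.kappa_A * a + p.theta_A)
        assert occ.get(1, 0.0) == pytest.approx(expected, abs=0.05)

    def test_promoters_stay_binary(self):
        traj = simulate_vkbl_pdmp(synthetic_vkbl(), t_end=30.0, seed=4)
        assert set(np.unique(traj.columns["G_A"])) <= {0, 1}
        assert set(np.unique(traj.columns["G_R"])) <= {0, 1}
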