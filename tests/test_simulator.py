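"""Integration protocol, ATP readout, dose-response and apparent-Km checks."""

import numpy as np
import pytest

from pgktz import (
    SimulationConfig,
    build_canonical_network,
    conservation_drift,
    dose_response,
    predict_apparent_km,
    simulate,
)
from pgktz.reaction_network import ENZYME_FORMS, RateParameters
from pgktz.simulator import ATP_POOL_SPECIES, atp_production

from oracles import stationary_distribution

ADP_GRID = np.logspace(1, 4.7, 10)  # 10 uM .. 50 mM


def test_product_accumulates_without_tz(default_network, default_config):
    traj = simulate(default_network, default_config, tz=0.0)
    pool = traj.pool(ATP_POOL_SPECIES)
    post = pool[traj.times > 1.0]
    assert np.all(np.diff(post) > 0)
    assert atp_production(traj) > 0


def test_no_enzyme_no_catalysis(default_network, default_config):
    cfg = default_config.replace(
        initial_concentrations={"E": 0.0, "ADP": 1000.0, "BPG": 80.0}
    )
    traj = simulate(default_network, cfg)
    assert atp_production(traj) == 0.0
    assert np.all(traj.states[:, default_network.indices(ENZYME_FORMS)] == 0.0)


@pytest.mark.parametrize("tz", [0.0, 2.5e-3, 25.0])
def test_conservation_along_default_runs(default_network, default_config, tz):
    traj = simulate(default_network, default_config, tz=tz)
    drift = conservation_drift(traj)
    assert set(drift) == {"enzyme", "adenine", "tz"}
    for law, value in drift.items():
        assert value <= 1e-8, f"{law} drifted by {value}"


def test_tz_free_model_reduces_to_seven_forms(default_config):
    """With no terazosin the 10-form trajectory equals the TZ-free sub-network's."""
    t_eval = np.linspace(0.0, 60.0, 61)
    full = simulate(build_canonical_network(), default_config, tz=0.0, t_eval=t_eval)
    reduced_net = build_canonical_network(include_tz=False)
    cfg = default_config.replace(
        initial_concentrations={
            k: v
            for k, v in default_config.initial_concentrations.items()
            if k != "TZ"
        }
    )
    reduced = simulate(reduced_net, cfg, t_eval=t_eval)
    for name in reduced_net.species_names:
        np.testing.assert_allclose(
            full.species(name), reduced.species(name), rtol=1e-6, atol=1e-10,
            err_msg=name,
        )


def test_clamped_ligand_steady_state_matches_null_space(rng):
    """ODE long-time enzyme distribution vs. the linear-algebra oracle."""
    for _ in range(20):
        params = RateParameters(
            **{
                name: float(rng.uniform(0.5, 50) if name.endswith("_plus") else rng.uniform(5, 500))
                for name in (
                    "a_plus", "a_minus", "b_plus", "b_minus", "c_plus",
                    "c_minus", "d_plus", "d_minus", "k_plus", "k_minus",
                )
            },
            eta=float(rng.uniform(1, 50)),
        )
        ligands = {name: float(rng.uniform(0.05, 5)) for name in ("ADP", "BPG", "ATP", "PG", "TZ")}
        network = build_canonical_network(params, clamped=ligands.keys())
        cfg = SimulationConfig(
            t_end=400.0,
            rtol=1e-12,
            atol=1e-16,
            initial_concentrations={"E": 1.0, **ligands},
        )
        traj = simulate(network, cfg)
        ode = traj.final_state[network.indices(ENZYME_FORMS)]
        oracle = stationary_distribution(params.to_dict(), ligands, total_enzyme=1.0)
        np.testing.assert_allclose(ode, oracle, rtol=1e-6, atol=0)


def test_atp_pool_equals_integrated_phosphotransfer_flux(default_network, default_config):
    """The ATP pool is fed only by phosphotransfer: pool(t) = integral of R5's net flux."""
    t_eval = np.linspace(0.0, 60.0, 4001)
    traj = simulate(default_network, default_config, tz=0.05, t_eval=t_eval)
    r5 = np.array(
        [default_network.reaction_fluxes(s)[4] for s in traj.states]
    )
    integral = np.trapezoid(r5, traj.times)
    # tolerance reflects the trapezoid discretization error on 4001 points
    assert integral == pytest.approx(atp_production(traj), rel=1e-3)


def test_production_nearly_linear_in_time(default_network, default_config):
    """At quasi-equilibrium the pool grows at a steady maximal rate."""
    full = atp_production(simulate(default_network, default_config, tz=0.0))
    half = atp_production(
        simulate(default_network, default_config.replace(t_end=30.0), tz=0.0)
    )
    assert full == pytest.approx(2 * half, rel=0.05)


def test_dose_response_basics(default_network, default_config):
    dr = dose_response(default_network, default_config.replace(tz_grid=(0.0,)))
    np.testing.assert_array_equal(dr.percent_change, [0.0])
    with pytest.raises(ValueError, match="baseline"):
        dose_response(default_network, default_config.replace(tz_grid=(0.05,)))


def test_dose_response_deterministic(default_network, default_config):
    cfg = default_config.replace(tz_grid=(0.0, 0.05), t_end=10.0)
    a = dose_response(default_network, cfg)
    b = dose_response(default_network, cfg)
    np.testing.assert_array_equal(a.atp_production, b.atp_production)
    np.testing.assert_array_equal(a.percent_change, b.percent_change)


def test_tolerance_robustness(default_network, default_config):
    """Tightening both solver tolerances 100x moves the readout < 0.1%."""
    loose = atp_production(simulate(default_network, default_config, tz=0.05))
    tight_cfg = default_config.replace(rtol=1e-11, atol=1e-14)
    tight = atp_production(simulate(default_network, tight_cfg, tz=0.05))
    assert loose == pytest.approx(tight, rel=1e-3)


class TestApparentKm:
    def test_tz_raises_apparent_km(self, default_network):
        fit0 = predict_apparent_km(default_network, 0.0, ADP_GRID)
        fit_tz = predict_apparent_km(default_network, 0.5, ADP_GRID)
        assert fit_tz.km > fit0.km

    def test_vmax_matches_saturating_rate(self, default_network, default_config):
        fit0 = predict_apparent_km(default_network, 0.0, ADP_GRID)
        cfg = default_config.replace(
            initial_concentrations={
                **default_config.initial_concentrations, "ADP": 10 * ADP_GRID[-1],
            },
            t_end=2.0,
        )
        t_eval = np.linspace(0.5, 2.0, 16)
        traj = simulate(default_network, cfg, tz=0.0, t_eval=t_eval)
        sat_rate = np.polyfit(traj.times, traj.pool(ATP_POOL_SPECIES), 1)[0]
        assert fit0.vmax == pytest.approx(sat_rate, rel=0.05)

    def test_vmax_scales_with_enzyme_km_does_not(self, default_network, default_config):
        # mass-action rates are proportional to total enzyme when the
        # ligand pools are effectively fixed; probe the law in the dilute
        # regime where product re-binding over the rate window is negligible
        fits = []
        for e_total in (0.004, 0.008):
            cfg = default_config.replace(
                initial_concentrations={
                    **default_config.initial_concentrations, "E": e_total,
                }
            )
            fits.append(predict_apparent_km(default_network, 0.0, ADP_GRID, config=cfg))
        assert fits[1].vmax == pytest.approx(2 * fits[0].vmax, rel=0.01)
        assert fits[1].km == pytest.approx(fits[0].km, rel=0.01)

    def test_grid_validation(self, default_network):
        with pytest.raises(ValueError, match="decade"):
            predict_apparent_km(default_network, 0.0, [100, 200, 300, 400])
        with pytest.raises(ValueError, match="at least 4"):
            predict_apparent_km(default_network, 0.0, [10, 10000])
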