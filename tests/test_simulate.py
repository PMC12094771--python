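"""Integration-to-steady-state and scenario-preset tests."""

import numpy as np
import pytest

from warconj.core import ModelParams, ModelVariant, SystemState, default_initial_state
from warconj.simulate import (
    Scenario,
    apply_scenario,
    frequencies,
    run_scenario,
    simulate,
)

from conftest import random_params


# --- frequencies ------------------------------------------------------------


@pytest.mark.parametrize(
    "state, expected",
    [
        (SystemState(C1=0.01, C2=0.01, C3=0.0), (0.5, 0.5, 0.0)),
        (SystemState(C1=0.0, C2=0.0, C3=0.3), (0.0, 0.0, 1.0)),
        (SystemState(C1=1.0, C2=2.0, C3=1.0), (0.25, 0.5, 0.25)),
    ],
)
def test_frequencies(state, expected):
    assert frequencies(state) == pytest.approx(expected, abs=1e-15)


def test_frequencies_require_biomass():
    with pytest.raises(ValueError, match="biomass"):
        frequencies(SystemState(C1=0, C2=0, C3=0))


# --- scenario presets -------------------------------------------------------


def test_scenario_overrides(default_params):
    assert apply_scenario(Scenario.KILLING_ONLY, default_params).b == 0.0
    transfer = apply_scenario(Scenario.TRANSFER_ONLY, default_params)
    assert transfer.E == 0.0 and transfer.gamma == default_params.gamma
    silent = apply_scenario(Scenario.TRANSFER_ONLY, default_params, zero_gamma=True)
    assert silent.E == 0.0 and silent.gamma == 0.0
    assert apply_scenario(Scenario.KILLING_AND_TRANSFER, default_params) == default_params


# --- trajectory structure ---------------------------------------------------


def test_no_conjugation_means_no_transconjugants(default_params, standard_init):
    traj = simulate(
        ModelVariant.DEFAULT, default_params.replace(b=0.0), standard_init
    )
    assert np.all(traj.component("C3") == 0.0)


def test_trajectory_invariants_on_random_parameters(standard_init):
    rng = np.random.default_rng(3)
    for _ in range(10):
        params = random_params(rng)
        variant = (ModelVariant.DEFAULT, ModelVariant.METABOLIC_DIVERSITY)[
            int(rng.integers(2))
        ]
        init = default_initial_state(variant)
        traj = simulate(variant, params, init, t_max=300.0)
        assert traj.times[0] == 0.0
        assert np.all(np.diff(traj.times) > 0)
        assert np.all(traj.states >= 0.0)
        for pool in ("N1", "N2", "N3"):
            assert np.all(np.diff(traj.component(pool)) <= 1e-12)


def test_closed_system_conserves_mass_without_toxin(standard_init):
    """gamma=0, T(0)=0: toxin stays identically zero and C1+C2+C3+N1 is a
    conserved quantity along the whole trajectory."""
    params = ModelParams(gamma=0.0)
    traj = simulate(ModelVariant.DEFAULT, params, standard_init)
    assert np.all(traj.component("T") == 0.0)
    total = traj.states[:, :3].sum(axis=1) + traj.component("N1")
    expected = standard_init.total_biomass + standard_init.N1
    assert np.all(np.abs(total - expected) < 1e-8)


def test_target_lineage_is_invariant_to_conjugation_rate(standard_init):
    """With no toxin production and no killing, conjugation only relabels
    target-lineage biomass: C2+C3 follows the same curve for any b."""
    base = ModelParams(gamma=0.0, E=0.0)
    grid = np.linspace(0.0, 50.0, 501)
    slow = simulate(
        ModelVariant.DEFAULT, base.replace(b=0.0), standard_init, t_max=50.0, t_eval=grid
    )
    fast = simulate(
        ModelVariant.DEFAULT, base.replace(b=0.25), standard_init, t_max=50.0, t_eval=grid
    )
    n = min(slow.times.size, fast.times.size)
    lineage_slow = (slow.component("C2") + slow.component("C3"))[:n]
    lineage_fast = (fast.component("C2") + fast.component("C3"))[:n]
    rel = np.abs(lineage_slow - lineage_fast) / lineage_slow
    assert np.max(rel) < 1e-6


def test_simulation_is_deterministic(default_params, standard_init):
    a = simulate(ModelVariant.DEFAULT, default_params, standard_init)
    b = simulate(ModelVariant.DEFAULT, default_params, standard_init)
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.states, b.states)


def test_killing_is_structurally_absent_without_toxin(standard_init):
    """T(0)=0 and gamma=0 make the killing term identically zero, so the
    potency parameter cannot influence the arithmetic: runs at E=10 and
    E=0 are bit-for-bit identical."""
    potent = simulate(ModelVariant.DEFAULT, ModelParams(gamma=0.0), standard_init)
    disarmed = simulate(
        ModelVariant.DEFAULT, ModelParams(gamma=0.0, E=0.0), standard_init
    )
    assert np.array_equal(potent.times, disarmed.times)
    assert np.array_equal(potent.states, disarmed.states)


def test_already_steady_initial_state(default_params):
    dead = SystemState(C1=0, C2=0, C3=0, N1=0, N2=0, N3=0, T=0)
    traj = simulate(ModelVariant.DEFAULT, default_params, dead)
    assert traj.converged and traj.t_final == 0.0


# --- steady-state endpoints -------------------------------------------------


def test_all_default_scenarios_converge():
    for scenario in Scenario:
        for variant in (ModelVariant.DEFAULT, ModelVariant.METABOLIC_DIVERSITY):
            result = run_scenario(scenario, variant)
            assert result.converged, (scenario, variant)
            assert result.t_final < 5000.0
            assert sum(result.frequencies) == pytest.approx(1.0, abs=1e-9)


def test_killing_only_leaves_a_pure_attacker_population():
    result = run_scenario(Scenario.KILLING_ONLY, ModelVariant.DEFAULT)
    assert result.f_attacker >= 0.999
    assert result.f_transconjugant == 0.0
    assert result.extinct_flags == (False, True, True)


def test_transfer_only_keeps_all_three_genotypes():
    result = run_scenario(Scenario.TRANSFER_ONLY, ModelVariant.DEFAULT)
    assert all(f > 0.0 for f in result.frequencies)
    assert result.extinct_flags == (False, False, False)


def test_killing_suppresses_but_does_not_abolish_transfer():
    """Killing removes recipients before they can be converted, so the
    combined scenario yields transconjugants at a strictly lower frequency
    than transfer alone."""
    combined = run_scenario(Scenario.KILLING_AND_TRANSFER, ModelVariant.DEFAULT)
    transfer = run_scenario(Scenario.TRANSFER_ONLY, ModelVariant.DEFAULT)
    assert 0.0 < combined.f_transconjugant < transfer.f_transconjugant


def test_metabolic_diversity_boosts_transconjugants():
    default = run_scenario(Scenario.KILLING_AND_TRANSFER, ModelVariant.DEFAULT)
    diverse = run_scenario(Scenario.KILLING_AND_TRANSFER, ModelVariant.METABOLIC_DIVERSITY)
    assert diverse.f_transconjugant > default.f_transconjugant


def test_two_nutrient_variant_also_favors_transconjugants():
    """Giving only the target lineage a (small) private pool still raises
    the transconjugant endpoint above the shared-nutrient model."""
    default = run_scenario(Scenario.KILLING_AND_TRANSFER, ModelVariant.DEFAULT)
    two = run_scenario(Scenario.KILLING_AND_TRANSFER, ModelVariant.TWO_NUTRIENT)
    assert two.f_transconjugant > default.f_transconjugant


def test_simulate_rejects_bad_settings(default_params, standard_init):
    with pytest.raises(ValueError):
        simulate(ModelVariant.DEFAULT, default_params, standard_init, t_max=0.0)
    with pytest.raises(ValueError):
        simulate(
            ModelVariant.DEFAULT, default_params, standard_init, convergence_tol=0.0
        )
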