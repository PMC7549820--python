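import numpy as np
import pytest

from meascreen.cell import StepperConfig, simulate_ap
from meascreen.compounds import ConductanceSet
from meascreen.signals import TimeSignal
from meascreen.tissue import (KLSampler, StimulusSpec, grid_preset,
                              solve_tissue, uniform_field)


def make_fp_template(spike_t=100.0, wave_t=400.0, wave_amp=40.0,
                     wave_sigma=20.0, spike_pos=200.0, spike_neg=100.0,
                     duration=800.0, dt=1.0, offset=0.0):
    """Synthetic single-beat FP: biphasic spike + Gaussian repol wave."""
    t = np.arange(0.0, duration, dt)
    v = np.zeros_like(t) + offset
    v += spike_pos * np.exp(-0.5 * ((t - spike_t) / 1.5) ** 2)
    v -= spike_neg * np.exp(-0.5 * ((t - spike_t - 5.0) / 1.5) ** 2)
    v += wave_amp * np.exp(-0.5 * ((t - wave_t) / wave_sigma) ** 2)
    return TimeSignal(v, dt, 0.0, "uV")


@pytest.fixture(scope="session")
def fp_template():
    return make_fp_template


@pytest.fixture(scope="session")
def epi_limit_cycle():
    """End-diastolic epicardial state after pre-pacing (for fast AP runs)."""
    _, _, state = simulate_ap("epicardial", n_prebeats=15, n_beats=1,
                              stepper=StepperConfig(dt=0.01, dt_out=5.0),
                              return_state=True)
    return state


@pytest.fixture(scope="session")
def mid_limit_cycle():
    """End-diastolic mid-myocardial state (EAD-prone variant)."""
    _, _, state = simulate_ap("mid_myocardial", n_prebeats=20, n_beats=1,
                              stepper=StepperConfig(dt=0.01, dt_out=5.0),
                              return_state=True)
    return state


@pytest.fixture(scope="session")
def bidomain_runs():
    """One heterogeneous well simulated at control, 50% I_Kr and 50% I_Na.

    Shared across tissue and acceptance tests; the paired runs reuse a
    single field and stimulus so drug effects are directly comparable.
    """
    grid = grid_preset("96w8e", nx=21)
    het = KLSampler(grid, 0.25).draw(7)
    stim = StimulusSpec(x0=0.15, y0=0.15, t0=20.0)
    out = {"grid": grid, "het": het, "stim": stim}
    out["vm_ctrl"], out["phi_ctrl"], out["cai_ctrl"] = solve_tissue(
        grid, het, None, stim, duration=700.0)
    _, out["phi_kr"], out["cai_kr"] = solve_tissue(
        grid, het, ConductanceSet(1.0, 0.5, 1.0), stim, duration=700.0)
    _, out["phi_na"], _ = solve_tissue(
        grid, het, ConductanceSet(0.5, 1.0, 1.0), stim, duration=700.0)
    return out


@pytest.fixture(scope="session")
def activation_run():
    """Corner-stimulated homogeneous sheet for activation-ordering checks."""
    grid = grid_preset("96w8e", nx=21)
    field = uniform_field(grid)
    stim = StimulusSpec(x0=0.15, y0=0.15, t0=20.0)
    vm, phi, _ = solve_tissue(grid, field, None, stim, duration=200.0)
    return {"grid": grid, "stim": stim, "vm": vm, "phi": phi}
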