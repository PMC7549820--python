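"""Fast parametric surrogate of the monolayer well simulation.

Generates per-electrode field-potential templates and a well-averaged
calcium transient whose dose-response behaviour mirrors the
conductance-block model acting on the full bidomain/ORd backend:

* sodium-channel block slows conduction (later activation) and shrinks
  the depolarization spike;
* hERG (I_Kr) block prolongs the interval between the depolarization
  spike and the repolarization wave (FPD prolongation);
* calcium-channel block shortens repolarization and shrinks the
  calcium transient.

The waveform constants below were calibrated once against single-cell
ORd dose-response runs (APD90 269 -> 425 ms for g_Kr scaled 1 -> 0.4)
and are deliberately simple: the surrogate exists to exercise the
feature/classification pipeline at realistic throughput, not to model
tissue electrophysiology — that is the bidomain backend's job.
"""

from __future__ import annotations

import numpy as np

from .compounds import ConductanceSet
from .signals import TimeSignal

# baseline template constants
CV0 = 0.25          # conduction speed, mm/ms
DA0 = 600.0         # depolarization spike peak-to-peak, uV
RA0 = 60.0          # repolarization wave amplitude, uV
FPD0 = 320.0        # baseline field-potential duration, ms
SPIKE_SIGMA = 1.2   # ms
REPOL_SIGMA = 25.0  # ms
CA_BASE = 0.10      # diastolic calcium, uM
CA_AMP0 = 0.45      # calcium transient amplitude, uM


def _fpd(scales: ConductanceSet) -> float:
    """FPD response: I_Kr block prolongs, Ca block shortens."""
    prolong = 1.0 + 0.65 * (1.0 - scales.scale_kr) ** 1.3
    shorten = 1.0 - 0.25 * (1.0 - scales.scale_ca)
    return FPD0 * prolong * shorten


def _da(scales: ConductanceSet) -> float:
    """Depolarization amplitude response to sodium block."""
    return DA0 * (0.15 + 0.85 * scales.scale_na ** 0.7)


def _cv(scales: ConductanceSet) -> float:
    """Conduction velocity response to sodium block."""
    return CV0 * (0.25 + 0.75 * scales.scale_na ** 0.5)


def surrogate_well_traces(grid, het, scales: ConductanceSet, stim,
                          duration: float, electrode=None,
                          dt: float = 1.0):
    """Build per-electrode FP templates and the well calcium transient.

    Electrode-to-electrode variability is driven deterministically by
    the shared heterogeneity field, so paired control/drug calls with
    one field cancel it in ratio features exactly as in the full model.
    """
    gx, gy = grid.node_coords()
    g_field = het.gaussian
    t = np.arange(0.0, duration, dt)
    cv = _cv(scales)
    fpd = _fpd(scales)
    da = _da(scales)

    fp = []
    for (ex, ey, er) in grid.electrodes:
        d2 = (gx - ex) ** 2 + (gy - ey) ** 2
        near = np.argsort(d2)[:5]
        g_loc = float(np.mean(g_field[near]))
        # mild local modulation from the cell-type field
        da_k = da * np.exp(0.12 * g_loc)
        ra_k = RA0 * np.exp(0.18 * g_loc)
        fpd_k = fpd * np.exp(0.05 * g_loc)
        dist = float(np.hypot(ex - stim.x0, ey - stim.y0))
        t_act = stim.t0 + dist / cv

        u = (t - t_act) / SPIKE_SIGMA
        spike = -u * np.exp(-0.5 * u ** 2)        # biphasic, derivative shape
        spike *= da_k / (np.abs(spike).max() * 2.0 + 1e-30)
        notch = 0.08 * da_k * np.exp(-0.5 * ((t - t_act - 6.0) / 2.5) ** 2)
        repol = ra_k * np.exp(-0.5 * ((t - t_act - fpd_k) / REPOL_SIGMA) ** 2)
        fp.append(TimeSignal(spike + notch + repol, dt, 0.0, "uV"))

    ca_amp = CA_AMP0 * (0.2 + 0.8 * scales.scale_ca ** 0.8) \
        * np.exp(0.08 * float(np.mean(g_field)))
    t_ca = stim.t0 + 0.5 * (gx.max() - gx.min()) / cv
    rise = 1.0 / (1.0 + np.exp(-(t - t_ca) / 6.0))
    decay = np.exp(-np.clip(t - t_ca, 0.0, None) / (0.55 * fpd))
    cai = CA_BASE + ca_amp * rise * decay
    return fp, TimeSignal(cai, dt, 0.0, "uM")
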