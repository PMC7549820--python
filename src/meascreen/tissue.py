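"""Reduced-grid bidomain simulation of an MEA well.

A cardiomyocyte monolayer is modelled as a 2-D rectangular grid of ORd
cells coupled by the bidomain equations (finite differences, 5-point
Laplacian, no-flux edges, grounded node set for the extracellular
potential). Cell-type heterogeneity is drawn from a correlated Gaussian
random field (squared-exponential kernel, Karhunen-Loeve expansion);
activation starts from a randomly placed Gaussian stimulus disc.
Electrode discs average the extracellular potential, which is passed
through an imperfect-electrode RC circuit and Gaussian measurement
noise to produce the recorded field potentials, alongside the
well-averaged intracellular calcium transient.

Units: potentials mV internally (FP outputs in uV), time ms, space mm
in the public API (cm internally where conductivities demand it),
conductivities mS/cm, calcium uM in outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh
from scipy.sparse.linalg import splu

from . import ordmodel
from .cell import StepperConfig, simulate_ap
from .compounds import CompoundSpec, ConductanceSet, drug_conductances
from .signals import TimeSignal

MM_PER_CM = 10.0


# ----------------------------------------------------------------- types

def _electrode_grid_3x3(side: float, keep_center: bool = True):
    """3x3 electrode layout on a square well of the given side (mm)."""
    pos = []
    for iy in range(3):
        for ix in range(3):
            if not keep_center and (ix, iy) == (1, 1):
                continue
            pos.append(((ix + 1) * side / 4.0, (iy + 1) * side / 4.0, 0.05))
    return tuple(pos)


@dataclass(frozen=True)
class TissueGrid:
    """Structured-grid well geometry and passive tissue parameters.

    Electrode entries are (x_mm, y_mm, radius_mm) discs. The bidomain
    passive constants (a_m, c_m, sigma_i, sigma_e, z_thick) default to
    physiologically plausible monolayer values.
    """

    nx: int = 41
    ny: int = 41
    dx: float = 0.06            # node spacing, mm
    a_m: float = 1000.0         # surface-to-volume ratio, 1/cm
    c_m: float = 1.0            # membrane capacitance, uF/cm^2
    sigma_i: float = 0.5        # intracellular conductivity, mS/cm
    sigma_e: float = 2.0        # extracellular conductivity, mS/cm
    z_thick: float = 0.002      # monolayer thickness, cm
    electrodes: tuple = ()
    ground: str = "boundary"    # nodes clamped to phi_e = 0

    def __post_init__(self):
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid must be at least 3x3")
        for name in ("dx", "a_m", "c_m", "sigma_i", "sigma_e", "z_thick"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.electrodes:
            object.__setattr__(
                self, "electrodes",
                _electrode_grid_3x3(self.dx * (self.nx - 1), keep_center=True))

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def extent(self) -> tuple[float, float]:
        return (self.dx * (self.nx - 1), self.dx * (self.ny - 1))

    def node_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened node coordinates in mm (row-major, y outer)."""
        xs = self.dx * np.arange(self.nx)
        ys = self.dx * np.arange(self.ny)
        gx, gy = np.meshgrid(xs, ys)
        return gx.ravel(), gy.ravel()

    def electrode_nodes(self) -> list[np.ndarray]:
        """Node indices within each electrode disc (nearest node if empty)."""
        gx, gy = self.node_coords()
        out = []
        for (ex, ey, er) in self.electrodes:
            d2 = (gx - ex) ** 2 + (gy - ey) ** 2
            idx = np.where(d2 <= er ** 2)[0]
            if idx.size == 0:
                idx = np.array([int(np.argmin(d2))])
            out.append(idx)
        return out

    def ground_nodes(self) -> np.ndarray:
        if self.ground == "boundary":
            gx, gy = self.node_coords()
            lx, ly = self.extent
            eps = 1e-9
            mask = ((gx < eps) | (gy < eps) | (gx > lx - eps) | (gy > ly - eps))
            return np.where(mask)[0]
        raise ValueError(f"unknown ground spec {self.ground!r}")


def grid_preset(name: str, nx: int | None = None, ny: int | None = None) -> TissueGrid:
    """Named device-like layouts: '6w9e' (9 electrodes) or '96w8e' (8)."""
    nx = nx or 41
    ny = ny or nx
    side = 2.4
    dx = side / (nx - 1)
    if name == "6w9e":
        el = _electrode_grid_3x3(side, keep_center=True)
    elif name == "96w8e":
        el = _electrode_grid_3x3(side, keep_center=False)
    else:
        raise ValueError(f"unknown grid preset {name!r}")
    return TissueGrid(nx=nx, ny=ny, dx=dx, electrodes=el)


@dataclass(frozen=True)
class ElectrodeModel:
    """Imperfect-electrode RC circuit.

    The recorded field potential is phi_f = R_i * I_el where the
    electrode current obeys dI_el/dt + I_el/tau = (C_el/tau) dphi/dt,
    tau = C_el (R_i + R_el). Defaults are plausible stand-ins giving a
    ~0.14 Hz high-pass corner so the repolarization wave survives.
    """

    r_el: float = 1.0e5     # Ohm
    c_el: float = 1.0e-6    # F
    r_i: float = 1.0e6      # Ohm

    def __post_init__(self):
        if min(self.r_el, self.c_el, self.r_i) <= 0:
            raise ValueError("electrode parameters must be positive")

    @property
    def tau(self) -> float:
        """RC time constant in seconds."""
        return self.c_el * (self.r_i + self.r_el)


@dataclass(frozen=True)
class StimulusSpec:
    """Gaussian-in-time stimulus applied on a small disc.

    I(x, y, t) = i0 * exp(-(t-t0)^2 / (2 sigma_t^2)) inside the disc of
    radius r around (x0, y0), zero outside; sigma_t = delta_t / 6.
    """

    x0: float
    y0: float
    t0: float = 20.0
    r: float = 0.05         # mm
    i0: float = -130.0      # pA/pF
    delta_t: float = 4.0    # ms

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("stimulus radius must be positive")

    @property
    def sigma_t(self) -> float:
        return self.delta_t / 6.0


def stimulus_current(x, y, t, spec: StimulusSpec):
    """Applied current (pA/pF) at position (mm) and time (ms)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = (x - spec.x0) ** 2 + (y - spec.y0) ** 2 <= spec.r ** 2
    amp = spec.i0 * math.exp(-((t - spec.t0) ** 2) / (2.0 * spec.sigma_t ** 2))
    return np.where(inside, amp, 0.0) if inside.ndim else (amp if inside else 0.0)


# ------------------------------------------------- heterogeneity field

@dataclass
class HeterogeneityField:
    """Correlated cell-type field over the grid.

    ``c_values`` hold the [0, 1] marginally-uniform field; ``gaussian``
    the underlying standard-normal field (kept for diagnostics);
    ``cell_type_map`` the per-node ORd variant codes.
    """

    c_values: np.ndarray
    gaussian: np.ndarray
    cell_type_map: np.ndarray
    l_c: float
    seed: int


def squared_exponential_kernel(coords: np.ndarray, l_c: float) -> np.ndarray:
    """Correlation kernel exp(-|dx|^2 / (2 l_c^2)) between all node pairs."""
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * l_c ** 2))


class KLSampler:
    """Karhunen-Loeve sampler of the squared-exponential Gaussian field.

    Modes are truncated to cover at least ``trace_fraction`` of the
    kernel trace (unit marginal variance). Reusable across draws so the
    eigendecomposition is paid once per grid.
    """

    def __init__(self, grid: TissueGrid, l_c: float = 0.25,
                 trace_fraction: float = 0.99):
        if l_c <= 0:
            raise ValueError("correlation length must be positive")
        gx, gy = grid.node_coords()
        coords = np.column_stack([gx, gy])
        kern = squared_exponential_kernel(coords, l_c)
        evals, evecs = eigh(kern)
        evals = evals[::-1]
        evecs = evecs[:, ::-1]
        evals = np.clip(evals, 0.0, None)
        total = evals.sum()
        if total <= 0:
            raise FloatingPointError("kernel trace vanished after truncation")
        keep = int(np.searchsorted(np.cumsum(evals) / total, trace_fraction) + 1)
        self.grid = grid
        self.l_c = l_c
        self.n_modes = keep
        self._scaled_modes = evecs[:, :keep] * np.sqrt(evals[:keep])

    def draw(self, seed: int) -> HeterogeneityField:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(self.n_modes)
        g = self._scaled_modes @ z
        # map to uniform marginals on [0, 1] via the standard normal CDF
        from scipy.stats import norm
        c = norm.cdf(g)
        return HeterogeneityField(
            c_values=c, gaussian=g, cell_type_map=assign_cell_types(c),
            l_c=self.l_c, seed=seed)


def uniform_field(grid: TissueGrid, c: float = 0.5) -> HeterogeneityField:
    """Homogeneous field (single cell type); useful for controlled runs."""
    cv = np.full(grid.n_nodes, float(c))
    return HeterogeneityField(c_values=cv, gaussian=np.zeros(grid.n_nodes),
                              cell_type_map=assign_cell_types(cv),
                              l_c=np.inf, seed=-1)


def sample_heterogeneity(grid: TissueGrid, l_c: float = 0.25,
                         seed: int = 0,
                         trace_fraction: float = 0.99) -> HeterogeneityField:
    """Draw one correlated cell-type field (convenience over KLSampler)."""
    return KLSampler(grid, l_c, trace_fraction).draw(seed)


def assign_cell_types(c_values: np.ndarray) -> np.ndarray:
    """Threshold rule: c < 1/3 epicardial, c > 2/3 mid-myocardial,
    endocardial otherwise."""
    c = np.asarray(c_values, dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError("field values must lie in [0, 1]")
    out = np.full(c.shape, ordmodel.ENDO, dtype=np.int8)
    out[c < 1.0 / 3.0] = ordmodel.EPI
    out[c > 2.0 / 3.0] = ordmodel.MID
    return out


# ------------------------------------------------------------- solver

def _laplacian(nx: int, ny: int, dx_cm: float) -> sp.csr_matrix:
    """5-point Laplacian with no-flux (mirror) boundaries, 1/cm^2 units."""
    ex = np.ones(nx)
    ey = np.ones(ny)
    lx = sp.diags([ex[:-1], -2 * ex, ex[:-1]], [-1, 0, 1], format="lil")
    ly = sp.diags([ey[:-1], -2 * ey, ey[:-1]], [-1, 0, 1], format="lil")
    # Neumann: mirror ghost node doubles the inner neighbour
    lx[0, 1] = 2.0
    lx[-1, -2] = 2.0
    ly[0, 1] = 2.0
    ly[-1, -2] = 2.0
    lap = sp.kronsum(lx.tocsr(), ly.tocsr(), format="csr")
    return lap / dx_cm ** 2


_STATE_CACHE: dict = {}


def _prepaced_states(prebeats: int = 20, cycle_length: float = 1000.0,
                     dt: float = 0.01) -> np.ndarray:
    """End-diastolic limit-cycle states for the three cell types (3, 41)."""
    key = (prebeats, cycle_length, dt)
    if key not in _STATE_CACHE:
        states = np.empty((3, ordmodel.N_STATES))
        for code, name in enumerate(ordmodel.CELL_TYPES):
            _, _, st = simulate_ap(name, n_prebeats=prebeats - 1, n_beats=1,
                                   cycle_length=cycle_length,
                                   stepper=StepperConfig(dt=dt, dt_out=5.0),
                                   return_state=True)
            states[code] = st
        _STATE_CACHE[key] = states
    return _STATE_CACHE[key]


@dataclass(frozen=True)
class TissueSolverConfig:
    """Numerical settings of the bidomain step.

    dt_pde: semi-implicit PDE step (ms). n_substeps: ionic sub-steps per
    PDE step. output_dt: recording interval of FP/calcium outputs before
    resampling (ms). prepace_beats: single-cell pre-pacing used to build
    the initial tissue state.
    """

    dt_pde: float = 0.1
    n_substeps: int = 5
    output_dt: float = 1.0
    vm_output_dt: float = 1.0
    prepace_beats: int = 20
    prepace_cycle: float = 1000.0
    prepace_dt: float = 0.01


def solve_tissue(grid: TissueGrid, het: HeterogeneityField,
                 scales: ConductanceSet | None = None,
                 stim: StimulusSpec | None = None,
                 duration: float = 700.0,
                 config: TissueSolverConfig | None = None):
    """Run the bidomain monolayer simulation.

    Returns ``(vm, phi_e_mean, cai_avg)``: the node membrane potentials
    sampled at ``vm_output_dt`` (n_out x n_nodes, mV), the per-electrode
    disc-averaged extracellular potential TimeSignals (uV), and the
    well-averaged intracellular calcium TimeSignal (uM).
    """
    scales = scales or ConductanceSet()
    cfg = config or TissueSolverConfig()
    if stim is not None and duration <= stim.t0:
        raise ValueError("duration must exceed the stimulus peak time")
    if het.c_values.size != grid.n_nodes:
        raise ValueError("heterogeneity field does not match the grid")

    n = grid.n_nodes
    dx_cm = grid.dx / MM_PER_CM
    lap = _laplacian(grid.nx, grid.ny, dx_cm)
    diff = grid.sigma_i / (grid.a_m * grid.c_m)  # cm^2/ms
    dt = cfg.dt_pde
    ident = sp.identity(n, format="csr")
    vm_solver = splu((ident - dt * diff * lap).tocsc())

    a_phi = (-(grid.sigma_i + grid.sigma_e) * lap).tolil()
    gnd = grid.ground_nodes()
    if gnd.size == 0:
        raise ValueError("ground node set is empty")
    for g in gnd:
        a_phi.rows[g] = [g]
        a_phi.data[g] = [1.0]
    phi_solver = splu(a_phi.tocsr().tocsc())

    celltypes = het.cell_type_map.astype(np.int8)
    base = _prepaced_states(cfg.prepace_beats, cfg.prepace_cycle, cfg.prepace_dt)
    y = base[celltypes].copy()

    gx, gy = grid.node_coords()
    if stim is not None:
        # A source smaller than the node spacing cannot excite a coarse
        # grid (discrete source-sink mismatch); represent the disc by all
        # nodes within max(r, 1.5 dx) of the centre, mimicking the several
        # mesh elements a 50 um disc covers at FEM resolution.
        r_eff = max(stim.r, 1.5 * grid.dx)
        in_disc = ((gx - stim.x0) ** 2 + (gy - stim.y0) ** 2 <= r_eff ** 2)
    else:
        in_disc = np.zeros(n, dtype=bool)

    el_nodes = grid.electrode_nodes()
    n_steps = int(round(duration / dt))
    out_stride = max(1, int(round(cfg.output_dt / dt)))
    vm_stride = max(1, int(round(cfg.vm_output_dt / dt)))
    n_out = n_steps // out_stride
    n_vm_out = n_steps // vm_stride
    phi_out = np.zeros((n_out, len(el_nodes)))
    cai_out = np.zeros(n_out)
    vm_out = np.zeros((n_vm_out, n))

    dy = np.empty_like(y)
    gss = np.empty((n, ordmodel.N_GATES))
    gtau = np.empty((n, ordmodel.N_GATES))
    i_app = np.zeros(n)
    sna, skr, sca = scales.as_tuple()
    dt_sub = dt / cfg.n_substeps

    sigma_lap_phi = np.zeros(n)
    phi = np.zeros(n)
    i_out = 0
    i_vm = 0
    for step in range(n_steps):
        t = step * dt
        # ionic sub-steps (reaction part) including the applied stimulus
        for s in range(cfg.n_substeps):
            if stim is not None:
                amp = stim.i0 * math.exp(
                    -((t + s * dt_sub - stim.t0) ** 2)
                    / (2.0 * stim.sigma_t ** 2))
                i_app[:] = 0.0
                i_app[in_disc] = amp
            ordmodel.rush_larsen_step(y, celltypes, sna, skr, sca, i_app,
                                      dt_sub, dy, gss, gtau)
        # implicit diffusion with the previous-step extracellular coupling
        rhs = y[:, 0] + dt / (grid.a_m * grid.c_m) * sigma_lap_phi
        y[:, 0] = vm_solver.solve(rhs)
        # extracellular potential with grounded nodes
        b = grid.sigma_i * (lap @ y[:, 0])
        b[gnd] = 0.0
        phi = phi_solver.solve(b)
        sigma_lap_phi = grid.sigma_i * (lap @ phi)
        if not np.isfinite(y[:, 0]).all():
            raise FloatingPointError(f"tissue solver diverged at t={t:.2f} ms")
        if (step + 1) % out_stride == 0:
            phi_out[i_out] = [phi[idx].mean() for idx in el_nodes]
            cai_out[i_out] = y[:, 5].mean()
            i_out += 1
        if (step + 1) % vm_stride == 0:
            vm_out[i_vm] = y[:, 0]
            i_vm += 1

    phi_sigs = [TimeSignal(phi_out[:i_out, k] * 1000.0, cfg.output_dt,
                           cfg.output_dt, "uV")
                for k in range(len(el_nodes))]
    cai_sig = TimeSignal(cai_out[:i_out] * 1000.0, cfg.output_dt,
                         cfg.output_dt, "uM")
    return vm_out[:i_vm], phi_sigs, cai_sig


# ------------------------------------------------------ electrode + noise

def electrode_filter(phi_e_mean: TimeSignal, model: ElectrodeModel) -> TimeSignal:
    """Pass the averaged extracellular potential through the RC electrode.

    Exponential integrator of dI/dt + I/tau = (C_el/tau) dphi/dt with
    piecewise-linear input; returns phi_f = R_i I in the input units.
    """
    tau_ms = model.tau * 1000.0
    h = phi_e_mean.dt
    decay = math.exp(-h / tau_ms)
    gain = model.c_el / (h / 1000.0) * (1.0 - decay)  # per unit dphi
    phi = phi_e_mean.values
    out = np.empty_like(phi)
    x = 0.0
    prev = phi[0]
    out[0] = 0.0
    for k in range(1, phi.size):
        x = x * decay + gain * (phi[k] - prev)
        prev = phi[k]
        out[k] = model.r_i * x
    return TimeSignal(out, phi_e_mean.dt, phi_e_mean.t0, phi_e_mean.units)


def add_noise(trace: TimeSignal, sd: float, seed: int) -> TimeSignal:
    """Add i.i.d. zero-mean Gaussian noise (seeded, reproducible)."""
    if sd < 0:
        raise ValueError("noise standard deviation must be non-negative")
    if sd == 0:
        return TimeSignal(trace.values.copy(), trace.dt, trace.t0, trace.units)
    rng = np.random.default_rng(seed)
    return TimeSignal(trace.values + rng.normal(0.0, sd, trace.values.size),
                      trace.dt, trace.t0, trace.units)


# ------------------------------------------------------------- recording

@dataclass
class MEARecording:
    """Per-well bundle of electrode FP traces and optional calcium."""

    well_id: str
    phase: str                      # {control, drug}
    compound: str | None
    concentration: float
    fp_traces: list                 # list[TimeSignal], uV
    calcium: TimeSignal | None
    seed: int
    config_digest: str = ""

    def __post_init__(self):
        if self.phase not in ("control", "drug"):
            raise ValueError(f"bad phase {self.phase!r}")
        if self.phase == "drug" and not self.compound:
            raise ValueError("drug phase requires a compound name")
        dts = {s.dt for s in self.fp_traces}
        lens = {len(s) for s in self.fp_traces}
        if len(dts) > 1 or len(lens) > 1:
            raise ValueError("all FP traces must share one sampling grid")

    def save(self, path, layout: str = "text") -> None:
        from pathlib import Path
        path = Path(path)
        if layout == "text":
            path.mkdir(parents=True, exist_ok=True)
            meta = {
                "well_id": self.well_id, "phase": self.phase,
                "compound": self.compound,
                "concentration": self.concentration, "seed": self.seed,
                "config_digest": self.config_digest,
                "n_electrodes": len(self.fp_traces),
                "has_calcium": self.calcium is not None,
            }
            (path / "meta.json").write_text(json.dumps(meta, indent=1))
            for k, sig in enumerate(self.fp_traces):
                sig.to_text(path / f"electrode_{k:02d}.tsv")
            if self.calcium is not None:
                self.calcium.to_text(path / "calcium.tsv")
        elif layout == "hdf5":
            import h5py
            with h5py.File(path, "w") as f:
                f.attrs.update({
                    "well_id": self.well_id, "phase": self.phase,
                    "compound": self.compound or "",
                    "concentration": self.concentration, "seed": self.seed,
                    "config_digest": self.config_digest,
                })
                for k, sig in enumerate(self.fp_traces):
                    d = f.create_dataset(f"fp/{k:02d}", data=sig.values)
                    d.attrs["dt"] = sig.dt
                    d.attrs["t0"] = sig.t0
                if self.calcium is not None:
                    d = f.create_dataset("calcium", data=self.calcium.values)
                    d.attrs["dt"] = self.calcium.dt
                    d.attrs["t0"] = self.calcium.t0
        else:
            raise ValueError(f"unknown layout {layout!r}")

    @classmethod
    def load(cls, path, layout: str = "text") -> "MEARecording":
        from pathlib import Path
        path = Path(path)
        if layout == "text":
            meta = json.loads((path / "meta.json").read_text())
            fp = [TimeSignal.from_text(path / f"electrode_{k:02d}.tsv", "uV")
                  for k in range(meta["n_electrodes"])]
            ca = (TimeSignal.from_text(path / "calcium.tsv", "uM")
                  if meta["has_calcium"] else None)
            return cls(meta["well_id"], meta["phase"], meta["compound"],
                       meta["concentration"], fp, ca, meta["seed"],
                       meta["config_digest"])
        if layout == "hdf5":
            import h5py
            with h5py.File(path, "r") as f:
                fp = []
                for k in sorted(f["fp"]):
                    d = f["fp"][k]
                    fp.append(TimeSignal(d[...], float(d.attrs["dt"]),
                                         float(d.attrs["t0"]), "uV"))
                ca = None
                if "calcium" in f:
                    d = f["calcium"]
                    ca = TimeSignal(d[...], float(d.attrs["dt"]),
                                    float(d.attrs["t0"]), "uM")
                return cls(f.attrs["well_id"], f.attrs["phase"],
                           f.attrs["compound"] or None,
                           float(f.attrs["concentration"]), fp, ca,
                           int(f.attrs["seed"]), f.attrs["config_digest"])
        raise ValueError(f"unknown layout {layout!r}")


@dataclass(frozen=True)
class WellConfig:
    """End-to-end well-simulation settings shared by both backends."""

    backend: str = "bidomain"       # or "surrogate"
    duration: float = 700.0
    l_c: float = 0.25               # heterogeneity correlation length, mm
    fp_noise_sd: float = 10.0       # uV
    ca_noise_sd: float = 1e-3       # uM
    fp_rate_khz: float = 1.0        # output sampling rate
    with_calcium: bool = True
    stim_t0: float = 20.0
    solver: TissueSolverConfig = field(default_factory=TissueSolverConfig)


def _config_digest(grid, electrode, config) -> str:
    blob = repr((grid, electrode, config)).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def simulate_well(compound: CompoundSpec | None, concentration: float,
                  grid: TissueGrid | None = None,
                  electrode: ElectrodeModel | None = None,
                  seed: int = 0, config: WellConfig | None = None,
                  well_id: str | None = None,
                  scales_override: ConductanceSet | None = None,
                  virtual_name: str | None = None,
                  _sampler: "KLSampler | None" = None) -> MEARecording:
    """Simulate one well phase (control when ``compound`` is None).

    The heterogeneity field and stimulus position derive only from
    ``seed``, so a control and a drug call with the same seed form a
    paired recording sharing field and source — the pairing on which
    the ratio-to-control features rely. ``scales_override`` runs a
    virtual compound given directly as conductance scales (used by the
    random channel-block study).
    """
    grid = grid or grid_preset("96w8e")
    electrode = electrode or ElectrodeModel()
    cfg = config or WellConfig()

    rng = np.random.default_rng(seed)
    lx, ly = grid.extent
    # stimulus position drawn away from the very edge
    x0 = rng.uniform(0.1 * lx, 0.9 * lx)
    y0 = rng.uniform(0.1 * ly, 0.9 * ly)
    stim = StimulusSpec(x0=x0, y0=y0, t0=cfg.stim_t0)
    field_seed = int(rng.integers(0, 2 ** 31 - 1))
    noise_seed = int(rng.integers(0, 2 ** 31 - 1))

    if scales_override is not None:
        scales = scales_override
        phase = "drug"
        compound_name = virtual_name or "virtual"
    elif compound is None:
        scales = ConductanceSet()
        phase = "control"
        compound_name = None
    else:
        scales = drug_conductances(compound, concentration)
        phase = "drug"
        compound_name = compound.name

    if cfg.backend == "bidomain":
        sampler = _sampler or KLSampler(grid, cfg.l_c)
        het = sampler.draw(field_seed)
        _, phi_sigs, cai_sig = solve_tissue(grid, het, scales, stim,
                                            cfg.duration, cfg.solver)
        fp = [electrode_filter(s, electrode) for s in phi_sigs]
    elif cfg.backend == "surrogate":
        from .surrogate import surrogate_well_traces
        sampler = _sampler or KLSampler(grid, cfg.l_c)
        het = sampler.draw(field_seed)
        fp, cai_sig = surrogate_well_traces(grid, het, scales, stim,
                                            cfg.duration, electrode)
    else:
        raise ValueError(f"unknown backend {cfg.backend!r}")

    dt_out = 1.0 / cfg.fp_rate_khz
    fp = [s if abs(s.dt - dt_out) < 1e-12 else s.resample(dt_out) for s in fp]
    fp = [add_noise(s, cfg.fp_noise_sd, noise_seed + k)
          for k, s in enumerate(fp)]
    calcium = None
    if cfg.with_calcium:
        calcium = add_noise(cai_sig, cfg.ca_noise_sd, noise_seed + 10_000)

    return MEARecording(
        well_id=well_id or f"well-{seed}",
        phase=phase,
        compound=compound_name,
        concentration=float(concentration) if phase == "drug" else 0.0,
        fp_traces=fp, calcium=calcium, seed=seed,
        config_digest=_config_digest(grid, electrode, cfg))


def simulate_well_pair(compound: CompoundSpec, concentration: float,
                       grid: TissueGrid | None = None,
                       electrode: ElectrodeModel | None = None,
                       seed: int = 0, config: WellConfig | None = None,
                       well_id: str | None = None,
                       _sampler: "KLSampler | None" = None):
    """Paired (control, drug) recordings sharing heterogeneity and source."""
    ctrl = simulate_well(None, 0.0, grid, electrode, seed, config,
                         well_id=well_id, _sampler=_sampler)
    drug = simulate_well(compound, concentration, grid, electrode, seed,
                         config, well_id=well_id, _sampler=_sampler)
    return ctrl, drug
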