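"""Compound specifications and the conductance-block (pore-block) drug model.

A drug at concentration D scales a channel's maximal conductance as

    g = g_control / (1 + (D / IC50)^n)

so the current is blocked at 50% when D equals the IC50. hERG block maps
onto g_Kr, Cav1.2 onto the PCa permeability group (I_CaL, I_CaNa, I_CaK)
and Nav1.5 onto g_Na.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

CHANNELS = ("hERG", "Cav1.2", "Nav1.5")


@dataclass(frozen=True)
class ConductanceSet:
    """Multiplicative conductance scales; the identity is (1, 1, 1)."""

    scale_na: float = 1.0
    scale_kr: float = 1.0
    scale_ca: float = 1.0

    def __post_init__(self):
        for name in ("scale_na", "scale_kr", "scale_ca"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.scale_na, self.scale_kr, self.scale_ca)


@dataclass
class CompoundSpec:
    """Per-compound channel potencies, test concentrations and labels.

    ``ic50`` maps channel name -> IC50 in uM; ``ic50_flags`` records
    entries parsed from censored table values (">30" -> bound 30 with
    flag ">"; "NA" -> channel block disabled).
    """

    name: str
    ic50: dict
    hill: float = 1.0
    concentrations: tuple = ()
    cmax: float | None = None
    tdp_label: str = "unknown"  # {risk, no_risk, unknown}
    channel_labels: frozenset = frozenset()
    split: str = "training"  # {training, validation}
    ic50_flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.hill <= 0:
            raise ValueError("Hill coefficient must be positive")
        for ch, v in self.ic50.items():
            if v is not None and v <= 0:
                raise ValueError(f"IC50 for {ch} must be positive, got {v}")
        conc = tuple(float(c) for c in self.concentrations)
        if any(c < 0 for c in conc):
            raise ValueError("concentrations must be non-negative")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly increasing")
        self.concentrations = conc
        if self.tdp_label not in ("risk", "no_risk", "unknown"):
            raise ValueError(f"bad tdp_label {self.tdp_label!r}")
        self.channel_labels = frozenset(self.channel_labels)
        if not self.channel_labels <= {"Na", "Ca", "K"}:
            raise ValueError("channel labels must be a subset of {Na, Ca, K}")


def conductance_block(g_control: float, concentration: float, ic50: float,
                      hill: float = 1.0) -> float:
    """Blocked conductance g_control / (1 + (D/IC50)^n)."""
    if ic50 is None or ic50 <= 0:
        raise ValueError("IC50 must be positive")
    if hill <= 0:
        raise ValueError("Hill coefficient must be positive")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    return g_control / (1.0 + (concentration / ic50) ** hill)


def drug_conductances(compound: CompoundSpec, concentration: float) -> ConductanceSet:
    """Conductance scales induced by a compound at a given dose (uM).

    A channel with no IC50 (parsed "NA") is left unblocked (scale 1).
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")

    def scale(channel: str) -> float:
        ic50 = compound.ic50.get(channel)
        if ic50 is None:
            return 1.0
        return conductance_block(1.0, concentration, ic50, compound.hill)

    return ConductanceSet(
        scale_na=scale("Nav1.5"),
        scale_kr=scale("hERG"),
        scale_ca=scale("Cav1.2"),
    )


def hill_sensitivity(concentration_factor: float,
                     hill_range: tuple[float, float] = (0.6, 1.4),
                     n_grid: int = 81) -> tuple[float, float]:
    """Mean and SD of the channel activity 1/(1+f^n) over a Hill-coefficient grid.

    ``concentration_factor`` f is the dose expressed in IC50 multiples.
    Quantifies how little the activity depends on n near therapeutic
    doses, the rationale for fixing n = 1.
    """
    if concentration_factor <= 0:
        raise ValueError("concentration factor must be positive")
    lo, hi = hill_range
    if not (0 < lo <= hi):
        raise ValueError("hill range must lie in (0, inf)")
    if n_grid < 1:
        raise ValueError("empty Hill grid")
    ns = np.linspace(lo, hi, n_grid)
    activity = 1.0 / (1.0 + concentration_factor ** ns)
    return float(activity.mean()), float(activity.std())


# -- compound tables -----------------------------------------------------

_TABLE_COLUMNS = ("name", "ic50_herg", "ic50_cav12", "ic50_nav15", "hill",
                  "concentrations", "cmax", "tdp_label", "channel_labels",
                  "split")


def _parse_ic50(cell: str):
    """Parse an IC50 table cell; handles censored '>x'/'<x' and 'NA'.

    Returns (value-or-None, flag) where flag is '', '>', '<' or 'NA'.
    """
    cell = cell.strip()
    if cell.upper() in ("NA", ""):
        return None, "NA"
    if cell[0] in "<>":
        return float(cell[1:]), cell[0]
    return float(cell), ""


def load_compound_table(path) -> list[CompoundSpec]:
    """Read a delimited compound table into CompoundSpec records.

    Expected header: name, ic50_herg, ic50_cav12, ic50_nav15, hill,
    concentrations (semicolon-separated), cmax, tdp_label,
    channel_labels (semicolon-separated), split.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"empty compound table: {path}")
    header = [h.strip() for h in lines[0].split(",")]
    if header != list(_TABLE_COLUMNS):
        raise ValueError(
            f"bad compound-table header in {path}: expected {_TABLE_COLUMNS}")
    compounds = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) != len(_TABLE_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected "
                             f"{len(_TABLE_COLUMNS)} fields, got {len(parts)}")
        try:
            ic50 = {}
            flags = {}
            for ch, cell in zip(CHANNELS, parts[1:4]):
                val, flag = _parse_ic50(cell)
                ic50[ch] = val
                if flag:
                    flags[ch] = flag
            conc = tuple(float(c) for c in parts[5].split(";") if c)
            labels = frozenset(s for s in parts[8].split(";") if s)
            compounds.append(CompoundSpec(
                name=parts[0],
                ic50=ic50,
                hill=float(parts[4]) if parts[4] else 1.0,
                concentrations=conc,
                cmax=float(parts[6]) if parts[6] else None,
                tdp_label=parts[7] or "unknown",
                channel_labels=labels,
                split={"T": "training", "V": "validation"}.get(parts[9], parts[9]),
                ic50_flags=flags,
            ))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return compounds


def reference_compound_table() -> list[CompoundSpec]:
    """The packaged 12-compound CiPA reference table (channel-block study)."""
    with resources.as_file(
            resources.files("meascreen.data") / "cipa12_compounds.csv") as p:
        return load_compound_table(p)
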