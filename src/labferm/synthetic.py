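"""Synthetic observation sets with the study's sampling design.

The generator reproduces the fermentation experiment's structure: six
sampling times (0, 12, 24, 36, 48, 60 hr), triplicate assays per time
point, and homoscedastic per-state Gaussian measurement noise at the
scale of the reported replicate spreads.  It simulates the kinetic model
for a chosen truth, adds noise, and can round-trip the result through a
plain CSV schema so every downstream stage is testable without any
external data.

Noise is Gaussian and, by default, *not* clipped at zero: with the
published rate constants the glucose balance runs negative (it is a pure
sink), and clipping would make the observations impossible under the
generating model, biasing every fit.  Set ``clip_negative=True`` to
emulate a detector that cannot report negative concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ObservationParseError
from .estimation import OBSERVATION_COLUMNS, ObservationSet
from .model import (
    STATE_NAMES,
    InoculumSpec,
    ParameterSet,
    StoichiometryConstants,
    cfu_to_mass,
    control_parameters,
    mass_to_cfu,
    p_acidilactici_parameters,
)
from .solver import DEFAULT_TIMES, SolverConfig, StateTrajectory, simulate

__all__ = [
    "GeneratorConfig",
    "default_initial_conditions",
    "default_parameters",
    "default_noise_sd",
    "generate",
    "write_observations",
    "read_observations",
]

BATCHES = ("control", "p_acidilactici", "custom")

#: inoculation dose common to every starter batch, CFU/g sausage
INOCULUM_DOSE = 2e7

#: per-batch CFU -> dry mass conversion, g/CFU (doublets vs doublet/tetrad mix)
CFU_CONVERSION = {"control": 2e-12, "p_acidilactici": 3e-12}

#: initial glucose is unreported; 1.0 g/100 g is a plausible free-sugar
#: level for a rice-supplemented sausage mix and is a config knob.
DEFAULT_GLUCOSE0 = 1.0

# Homoscedastic per-state measurement SDs.  Protein and NPN use the
# reported replicate spreads of each batch's 0-hr assays; the remaining
# states use plausible assay repeatabilities (plate counts, HPLC organic
# acids, enzymatic glucose) on the same basis.
_TABLE_NOISE = {
    "control": {"y1": 0.005, "y2": 0.023, "y3": 0.006,
                "y4": 0.05, "y5": 0.01, "y6": 0.05},
    "p_acidilactici": {"y1": 0.005, "y2": 0.017, "y3": 0.004,
                       "y4": 0.05, "y5": 0.01, "y6": 0.05},
}


def default_parameters(batch: str) -> ParameterSet:
    """Published kinetic constants for a recognised batch."""
    if batch == "control":
        return control_parameters()
    if batch == "p_acidilactici":
        return p_acidilactici_parameters()
    raise ConfigurationError(
        f"unknown batch {batch!r}; valid labels: {', '.join(BATCHES[:-1])}"
    )


def default_initial_conditions(batch: str, glucose0: float = DEFAULT_GLUCOSE0) -> np.ndarray:
    """Initial state for a recognised batch.

    Biomass converts the common 2e7 CFU/g inoculation dose with the
    batch's morphology-specific factor; protein and NPN are the measured
    0-hr values; lactate and formate start at zero; glucose at the
    configurable default.
    """
    if batch == "control":
        y1 = cfu_to_mass(INOCULUM_DOSE, CFU_CONVERSION["control"])
        y2, y3 = 0.563, 0.109
    elif batch == "p_acidilactici":
        y1 = cfu_to_mass(INOCULUM_DOSE, CFU_CONVERSION["p_acidilactici"])
        y2, y3 = 0.513, 0.127
    else:
        raise ConfigurationError(
            f"unknown batch {batch!r}; valid labels: {', '.join(BATCHES[:-1])}"
        )
    return np.array([y1, y2, y3, 0.0, 0.0, glucose0])


def default_noise_sd(batch: str) -> np.ndarray:
    """Per-state measurement SDs (g/100 g basis) for a recognised batch."""
    if batch not in _TABLE_NOISE:
        raise ConfigurationError(
            f"unknown batch {batch!r}; valid labels: {', '.join(_TABLE_NOISE)}"
        )
    return np.array([_TABLE_NOISE[batch][s] for s in STATE_NAMES])


@dataclass
class GeneratorConfig:
    """Everything needed to generate one synthetic observation set.

    ``noise_sd`` may be a per-state array/dict of absolute SDs; if None
    and ``noise_frac_of_range`` is set, SDs are that fraction of each
    state's noiseless trajectory range; if both are None the batch's
    default assay-scale SDs apply.
    """

    batch: str = "control"
    truth: ParameterSet | None = None
    y0: np.ndarray | None = None
    times: tuple = tuple(DEFAULT_TIMES)
    n_replicates: int = 3
    noise_sd: object = None
    noise_frac_of_range: float | None = None
    seed: int = 0
    clip_negative: bool = False
    glucose0: float = DEFAULT_GLUCOSE0
    solver: SolverConfig | None = None
    stoichiometry: StoichiometryConstants | None = None

    def __post_init__(self) -> None:
        if self.batch not in BATCHES:
            raise ConfigurationError(
                f"unknown batch {self.batch!r}; valid labels: {', '.join(BATCHES)}"
            )
        if self.batch == "custom" and (self.truth is None or self.y0 is None):
            raise ConfigurationError("custom batch requires explicit truth and y0")
        times = np.asarray(self.times, float)
        if times[0] != 0.0:
            raise ConfigurationError("sampling times must include 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")

    def resolved_truth(self) -> ParameterSet:
        return self.truth if self.truth is not None else default_parameters(self.batch)

    def resolved_y0(self) -> np.ndarray:
        if self.y0 is not None:
            return np.asarray(self.y0, float)
        return default_initial_conditions(self.batch, self.glucose0)

    def resolved_noise_sd(self, clean_states: np.ndarray) -> np.ndarray:
        if self.noise_sd is not None:
            if isinstance(self.noise_sd, dict):
                sd = np.array([self.noise_sd[s] for s in STATE_NAMES], float)
            else:
                sd = np.broadcast_to(np.asarray(self.noise_sd, float), (6,)).copy()
        elif self.noise_frac_of_range is not None:
            rng_ = clean_states.max(axis=0) - clean_states.min(axis=0)
            sd = self.noise_frac_of_range * rng_
        else:
            sd = default_noise_sd(self.batch)
        if np.any(sd < 0):
            raise ConfigurationError("noise SDs must be >= 0")
        return sd


def generate(
    cfg: GeneratorConfig,
    trajectory: StateTrajectory | None = None,
    return_trajectory: bool = False,
):
    """Simulate the truth and add replicate measurement noise.

    A precomputed noiseless ``trajectory`` (on ``cfg.times``) may be
    supplied to amortise the ODE solve across many noise realisations.
    With ``noise_sd=0`` the replicate means equal the trajectory exactly.
    """
    truth = cfg.resolved_truth()
    y0 = cfg.resolved_y0()
    if trajectory is None:
        solver = cfg.solver or SolverConfig(
            t_grid=tuple(cfg.times), t_end=float(max(cfg.times))
        )
        trajectory = simulate(truth, cfg.stoichiometry, y0, solver)
    clean = trajectory.states                      # (n_times, 6)
    sd = cfg.resolved_noise_sd(clean)
    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal((6, len(cfg.times), cfg.n_replicates))
    values = clean.T[:, :, None] + sd[:, None, None] * noise
    if cfg.clip_negative:
        values = np.clip(values, 0.0, None)
    obs = ObservationSet(np.asarray(cfg.times, float), values,
                         np.broadcast_to(sd[:, None], (6, len(cfg.times))).copy(),
                         batch_label=cfg.batch)
    if return_trajectory:
        return obs, trajectory
    return obs


def cfu_observations(obs: ObservationSet, conversion: float | None = None,
                     seed: int = 0, log_sd: float = 0.1) -> pd.DataFrame:
    """Plate-count view of the biomass observations.

    Converts the y1 replicate means to log10 CFU/g and adds lognormal
    plate-count noise (default 0.1 log units), the error structure typical
    of decimal-dilution viable counts.
    """
    if conversion is None:
        conversion = CFU_CONVERSION.get(obs.batch_label, 2e-12)
    rng = np.random.default_rng(seed)
    rows = []
    y1 = obs.values[0]                              # (n_times, n_rep)
    for j, t in enumerate(obs.times):
        for r in range(obs.n_replicates):
            v = y1[j, r]
            if np.isnan(v) or v <= 0:
                continue
            log_cfu = np.log10(mass_to_cfu(v, conversion)) + log_sd * rng.standard_normal()
            rows.append((t, r + 1, log_cfu))
    return pd.DataFrame(rows, columns=["time_hr", "replicate", "log10_cfu_per_g"])


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_observations(obs: ObservationSet, path: str | Path) -> None:
    """Write the long-format observation CSV (12 significant digits)."""
    obs.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_observations(path: str | Path) -> ObservationSet:
    """Read an observation CSV, validating the schema row by row."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as err:
        raise ObservationParseError(f"cannot parse {path}: {err}") from err
    return ObservationSet.from_frame(df)
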