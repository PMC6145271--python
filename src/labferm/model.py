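"""Kinetic model of lactic-acid-bacteria (LAB) sausage fermentation.

The model tracks six state variables on a per-100-g-sausage basis:

====  =============================  =======================
y1    LAB biomass                    g dry cells / 100 g
y2    total protein (as nitrogen)    g N / 100 g
y3    nonprotein nitrogen (NPN)      g N / 100 g
y4    lactic acid                    g / 100 g
y5    formic acid                    g / 100 g
y6    glucose                        g / 100 g
====  =============================  =======================

Biomass follows Monod kinetics in the limiting substrate (total protein)
with a logistic self-inhibition bracket ``(1 - y1/y1_max)``, an exponential
lag factor ``1 - exp(-k3 t)`` and first-order cell lysis ``k12 y1``.  NPN,
lactic and formic acid follow Luedeking-Piret laws (a growth-associated
term proportional to ``dy1/dt`` plus a non-growth term), the acids with
saturation brackets in their own concentration.  Glucose is consumed for
growth and lactate synthesis.  Total protein is depleted by incorporation
into biomass and NPN (via fixed elemental nitrogen stoichiometry and two
dimensionless correction factors) plus an extra proteolytic loss
controlled by ``cor_x``; see :class:`ParameterSet` for the two supported
loss forms.

Time is measured in hours and all rate constants are per hour.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "STATE_NAMES",
    "StoichiometryConstants",
    "ParameterSet",
    "StateVector",
    "InoculumSpec",
    "lag_factor",
    "biomass_rate",
    "protein_npn_rates",
    "lactate_rate",
    "formate_rate",
    "glucose_rate",
    "rhs",
    "cfu_to_mass",
    "mass_to_cfu",
    "control_parameters",
    "p_acidilactici_parameters",
]

STATE_NAMES = ("y1", "y2", "y3", "y4", "y5", "y6")

#: names of the kinetic constants and correction factors that are treated
#: as free parameters by the estimation machinery (saturation maxima and
#: stoichiometry are held fixed by default).
RATE_PARAMETER_NAMES = (
    "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9", "k10", "k11", "k12",
    "cor_bio", "cor_npn", "cor_x",
)

# JSON documents use the conventional symbol spellings for the two
# correction factors whose canonical capitalisation differs from the
# python attribute names.
_JSON_KEYS = {"cor_npn": "cor_NPN", "cor_x": "cor_X"}
_JSON_KEYS_INV = {v: k for k, v in _JSON_KEYS.items()}


@dataclass(frozen=True)
class StoichiometryConstants:
    """Elemental-nitrogen bookkeeping between protein, biomass and NPN.

    Biomass is represented by the generic microbial formula unit
    CH1.8O0.5N0.2 and NPN by an average free amino acid of formula weight
    120 with one nitrogen.  The derived nitrogen mass fractions convert a
    biomass (or NPN) formation rate into the protein-nitrogen it consumes
    (or carries).
    """

    n_bio: float = 0.2          # N atoms per biomass formula unit
    mw_bio: float = 24.63       # g/mol of the biomass formula unit
    n_npn: float = 1.0          # N atoms per NPN unit
    mw_npn: float = 120.0       # g/mol of the NPN unit
    aw_n: float = 14.007        # atomic weight of nitrogen, g/mol

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise DomainError(f"StoichiometryConstants.{f.name} must be > 0, got {v!r}")
        for name, frac in (("biomass", self.nitrogen_fraction_biomass),
                           ("NPN", self.nitrogen_fraction_npn)):
            if not 0.0 < frac < 1.0:
                raise DomainError(
                    f"derived nitrogen mass fraction of {name} is {frac:.4g}, "
                    "expected to lie strictly in (0, 1)"
                )

    @property
    def nitrogen_fraction_biomass(self) -> float:
        """g N per g biomass."""
        return self.n_bio * self.aw_n / self.mw_bio

    @property
    def nitrogen_fraction_npn(self) -> float:
        """g N per g NPN unit."""
        return self.n_npn * self.aw_n / self.mw_npn


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic constants, correction factors and saturation maxima.

    ``protein_loss`` selects the form of the extra protein loss term in
    the total-protein balance:

    * ``"first_order"`` (default): rate ``cor_x * y2`` with ``cor_x`` in
      1/hr.  Keeps the protein balance integrable over the full 60-hr
      fermentation for the published parameter magnitudes.
    * ``"constant"``: rate ``cor_x`` in g N/100 g/hr.  With the published
      values this drives y2 through zero and into the Monod pole at
      ``y2 = -k2`` inside the 0-60 hr window; it is retained for
      sensitivity studies only.
    """

    k1: float       # maximum specific growth rate, 1/hr
    k2: float       # Monod half-saturation constant, g N/100 g
    k3: float       # lag decay rate, 1/hr
    k4: float       # growth-associated NPN yield (per unit protein degraded)
    k5: float       # non-growth NPN rate constant, 1/hr
    k6: float       # growth-associated lactic acid yield, g acid/g biomass
    k7: float       # non-growth lactic acid rate, g/100 g/hr
    k8: float       # growth-associated formic acid yield
    k9: float       # non-growth formic acid rate, g/100 g/hr
    k10: float      # glucose-to-biomass uptake yield
    k11: float      # glucose-to-lactate uptake rate, g/100 g/hr
    k12: float      # cell lysis rate, 1/hr
    cor_bio: float  # correction on protein-into-biomass stoichiometry
    cor_npn: float  # correction on protein-into-NPN stoichiometry
    cor_x: float    # extra protein loss (1/hr or g N/100 g/hr, see protein_loss)
    y1_max: float = 0.2   # maximum biomass, g/100 g
    y4_max: float = 1.5   # lactic acid saturation level, g/100 g
    y5_max: float = 0.2   # formic acid saturation level, g/100 g
    protein_loss: str = "first_order"

    def __post_init__(self) -> None:
        for name in RATE_PARAMETER_NAMES:
            v = getattr(self, name)
            if not v >= 0 or not math.isfinite(v):
                raise DomainError(f"ParameterSet.{name} must be finite and >= 0, got {v!r}")
        if not self.k2 > 0:
            raise DomainError("k2 must be > 0 (Monod denominator)")
        for name in ("y1_max", "y4_max", "y5_max"):
            v = getattr(self, name)
            if not v > 0 or not math.isfinite(v):
                raise DomainError(f"ParameterSet.{name} must be finite and > 0, got {v!r}")
        if self.protein_loss not in ("first_order", "constant"):
            raise ConfigurationError(
                f"protein_loss must be 'first_order' or 'constant', got {self.protein_loss!r}"
            )

    # -- conversions -------------------------------------------------------
    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            d[_JSON_KEYS.get(f.name, f.name)] = getattr(self, f.name)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        kwargs = {_JSON_KEYS_INV.get(k, k): v for k, v in d.items()}
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def values(self, names) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)


@dataclass
class StateVector:
    """One point of the state trajectory, with its time tag in hours."""

    y1: float
    y2: float
    y3: float
    y4: float
    y5: float
    y6: float
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.y1, self.y2, self.y3, self.y4, self.y5, self.y6], float)

    @classmethod
    def from_array(cls, y, t: float = 0.0) -> "StateVector":
        y = np.asarray(y, float)
        if y.shape != (6,):
            raise DomainError(f"state array must have shape (6,), got {y.shape}")
        return cls(*y, t=t)


@dataclass(frozen=True)
class InoculumSpec:
    """Starter-culture dose and the CFU-to-dry-mass conversion.

    The conversion factor depends on cell morphology: 2e-12 g/CFU for
    doublet-forming LAB, 3e-12 g/CFU for the doublet/tetrad mix typical of
    *P. acidilactici*.
    """

    dose: float = 2e7                 # CFU per g sausage
    conversion: float = 2e-12         # g dry cell mass per CFU
    morphology_label: str = "doublets"

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise DomainError(f"inoculum dose must be > 0, got {self.dose!r}")
        if not self.conversion > 0:
            raise DomainError(f"conversion factor must be > 0, got {self.conversion!r}")

    def initial_biomass(self) -> float:
        """Inoculum biomass in g/100 g sausage."""
        return cfu_to_mass(self.dose, self.conversion)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def lag_factor(t, k3):
    """Lag-phase attenuation ``1 - exp(-k3 t)``.

    Rises from 0 at inoculation towards 1, modelling the adjustment period
    before exponential growth; monotone nondecreasing in ``t``.
    """
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise DomainError("time must be >= 0")
    if not k3 > 0:
        raise DomainError(f"k3 must be > 0, got {k3!r}")
    out = -np.expm1(-k3 * t)
    return float(out) if out.ndim == 0 else out


def _as_state_array(state):
    if isinstance(state, StateVector):
        return state.as_array(), state.t
    return np.asarray(state, float), None


def biomass_rate(t, y, p: ParameterSet):
    """dy1/dt: lagged Monod-logistic growth minus first-order lysis.

    The logistic bracket is deliberately not clamped: if y1 exceeds
    ``y1_max`` (noise, solver overshoot) the bracket goes negative and
    pulls the solution back, preserving the smoothness that collocation
    requires.
    """
    y = np.asarray(y, float)
    y1, y2 = y[0], y[1]
    growth = lag_factor(t, p.k3) * p.k1 * y2 / (p.k2 + y2) * y1 * (1.0 - y1 / p.y1_max)
    return growth - p.k12 * y1


def protein_npn_rates(t, y, dy1, p: ParameterSet, s: StoichiometryConstants):
    """(dy2/dt, dy3/dt): the algebraically coupled protein/NPN balance.

    The two balances are mutually implicit: protein loss includes the
    nitrogen carried into NPN (``dy3``), while NPN formation is
    growth-associated in protein degradation (``-k4 dy2``) plus a
    non-growth term ``k5 y2``.  Substituting one into the other gives a
    closed form; no iteration is involved.

    With ``a = cor_bio * Nbio*AWn/MWbio`` and ``b = cor_npn * Nnpn*AWn/MWnpn``::

        dy2 = -(a*dy1 + b*dy3) - loss        loss = cor_x*y2 (or cor_x)
        dy3 = -k4*dy2 + k5*y2
        =>  dy2 = (-(a*dy1) - b*k5*y2 - loss) / (1 - b*k4)

    The sign convention makes protein decrease whenever biomass and NPN
    are being formed.
    """
    y = np.asarray(y, float)
    y2 = y[1]
    a = p.cor_bio * s.nitrogen_fraction_biomass
    b = p.cor_npn * s.nitrogen_fraction_npn
    denom = 1.0 - b * p.k4
    if abs(denom) < 1e-12:
        raise ConfigurationError(
            "singular protein/NPN coupling: cor_npn * (n_npn*aw_n/mw_npn) * k4 "
            f"= {b * p.k4!r} makes the substitution denominator vanish"
        )
    loss = p.cor_x * y2 if p.protein_loss == "first_order" else p.cor_x
    dy2 = (-(a * dy1) - b * p.k5 * y2 - loss) / denom
    dy3 = -p.k4 * dy2 + p.k5 * y2
    return dy2, dy3


def lactate_rate(t, y, dy1, p: ParameterSet):
    """dy4/dt: Luedeking-Piret with product saturation, ``k6*dy1 + k7*(1 - y4/y4_max)``."""
    y = np.asarray(y, float)
    return p.k6 * dy1 + p.k7 * (1.0 - y[3] / p.y4_max)


def formate_rate(t, y, dy1, p: ParameterSet):
    """dy5/dt: ``k8*dy1 + k9*(1 - y5/y5_max)`` (hetero-fermentative by-product)."""
    y = np.asarray(y, float)
    return p.k8 * dy1 + p.k9 * (1.0 - y[4] / p.y5_max)


def glucose_rate(t, y, dy1, p: ParameterSet):
    """dy6/dt: uptake for growth and for lactate synthesis.

    ``-k10*dy1 - k11*(1 - y4/y4_max)``; nonpositive whenever ``dy1 >= 0``
    and ``y4 <= y4_max``.  Glucose feeds back on nothing, so the state may
    run negative when the zero-order uptake outlasts the supply; this is a
    known artefact of the published rate constants.
    """
    y = np.asarray(y, float)
    return -p.k10 * dy1 - p.k11 * (1.0 - y[3] / p.y4_max)


def rhs(t, y, p: ParameterSet, s: StoichiometryConstants | None = None):
    """Full six-component derivative vector ``(dy1 .. dy6)``.

    Pure function of its arguments; ``y`` may be a single state ``(6,)``
    or a batch ``(6, m)`` (broadcasts elementwise).  ``biomass_rate`` is
    evaluated once and reused by every growth-associated term.
    """
    if s is None:
        s = StoichiometryConstants()
    y_arr, t_tag = _as_state_array(y)
    if t_tag is not None and t is None:
        t = t_tag
    dy1 = biomass_rate(t, y_arr, p)
    dy2, dy3 = protein_npn_rates(t, y_arr, dy1, p, s)
    dy4 = lactate_rate(t, y_arr, dy1, p)
    dy5 = formate_rate(t, y_arr, dy1, p)
    dy6 = glucose_rate(t, y_arr, dy1, p)
    return np.stack(np.broadcast_arrays(dy1, dy2, dy3, dy4, dy5, dy6))


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def cfu_to_mass(count, conversion=2e-12):
    """Convert a plate count (CFU/g) to biomass in g/100 g sausage.

    ``conversion`` is the per-cell dry mass in g/CFU; the factor 100 moves
    from per-gram to the per-100-g basis used throughout.
    """
    if isinstance(conversion, InoculumSpec):
        conversion = conversion.conversion
    count = np.asarray(count, float)
    if np.any(count < 0):
        raise DomainError("CFU count must be >= 0")
    out = count * conversion * 100.0
    return float(out) if out.ndim == 0 else out


def mass_to_cfu(mass, conversion=2e-12):
    """Inverse of :func:`cfu_to_mass` (g/100 g -> CFU/g)."""
    if isinstance(conversion, InoculumSpec):
        conversion = conversion.conversion
    mass = np.asarray(mass, float)
    if np.any(mass < 0):
        raise DomainError("biomass must be >= 0")
    out = mass / (conversion * 100.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# published parameter estimates for the two modelled batches
# ---------------------------------------------------------------------------

def control_parameters(**overrides) -> ParameterSet:
    """Fitted constants for the spontaneously fermented (control) batch.

    The saturation maxima were not reported; defaults are ``y1_max``
    equivalent to 1e9 CFU/g at 2e-12 g/CFU and lactate/formate ceilings of
    1.5 and 0.2 g/100 g.
    """
    base = dict(
        k1=0.330, k2=0.061, k3=0.142, k4=3.7e-5, k5=1.517e-5, k6=0.414,
        k7=0.064, k8=0.013, k9=1.458e-3, k10=9.855e-3, k11=0.101, k12=1.7e-3,
        cor_bio=1.118, cor_npn=0.832, cor_x=0.025,
        y1_max=cfu_to_mass(1e9, 2e-12), y4_max=1.5, y5_max=0.2,
    )
    base.update(overrides)
    return ParameterSet(**base)


def p_acidilactici_parameters(**overrides) -> ParameterSet:
    """Fitted constants for the *P. acidilactici*-inoculated batch.

    ``y1_max`` uses the 3e-12 g/CFU conversion appropriate for the
    doublet/tetrad morphology.
    """
    base = dict(
        k1=0.244, k2=0.088, k3=0.141, k4=4.64e-4, k5=1.275e-5, k6=1.112e-3,
        k7=0.095, k8=2.623e-4, k9=1.7498e-3, k10=6.674e-3, k11=1.280, k12=1.9e-3,
        cor_bio=1.094, cor_npn=0.723, cor_x=0.046,
        y1_max=cfu_to_mass(1e9, 3e-12), y4_max=1.5, y5_max=0.2,
    )
    base.update(overrides)
    return ParameterSet(**base)
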