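"""Core model definition: parameters, state, right-hand side, observables.

The network couples three interlocked switches controlling the G2/M
transition:

* Cdk1/CycB activation by Tyr15 dephosphorylation, with the classical
  double-negative (Wee1) and double-positive (Cdc25) feedback loops;
* the Greatwall (Gwl) - ENSA/ARPP19 axis: active Cdk1 phosphorylates Gwl,
  Gwl phosphorylates ENSA/ARPP19, and phospho-ENSA binds PP2A/B55 as a
  stoichiometric (unfair-competition) inhibitor;
* PP2A/B55 as the counteracting phosphatase of Wee1, Cdc25 and - in one
  model variant - Gwl itself, closing an extra double-negative loop.

All reactions are mass action.  Concentrations are dimensionless (totals
are 1 except PP2A/B55 at 0.5, kept substoichiometric to its inhibitor
ENSA); time is in dimensionless model units.  Chemical inhibition of Cdk1
(RO3306, dose ``RO``) and PP2A (okadaic acid, dose ``OA``) is modelled as
instantaneous reversible binding, so the *active* fractions entering the
kinetics are MPFa = MPF/(1+RO) and PP2a = PP2/(1+OA).

Because the identity of the Gwl-inactivating phosphatase is unknown, three
variants are provided (see :data:`SCENARIOS`): dephosphorylation by an
OA-insensitive phosphatase (rate ``kigwl_p``, the paper-notation kigwl');
by an OA-sensitive phosphatase that is not B55-dependent and hence not
subject to ENSA inhibition (``kigwl_pp`` = kigwl'', acting through
PP2T/(1+OA)); or by PP2A/B55 itself (``kigwl``, acting through PP2a).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParameters",
    "ModelState",
    "Observables",
    "STATE_VARS",
    "OBSERVABLE_VARS",
    "G2_INIT",
    "METAPHASE_INIT",
    "SCENARIOS",
    "make_scenario",
    "effective_rates",
    "rhs",
    "rhs_state",
    "observables",
    "state_bounds",
    "validate_state",
]

#: Order of the dynamic variables everywhere in the package.
STATE_VARS = ("MPF", "Cdc25", "Wee1", "Gwl", "ENSAPt", "PP2")

#: Derived (algebraic) observables.
OBSERVABLE_VARS = ("MPFa", "PP2a", "preMPF", "complex")


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, total concentrations and inhibitor doses.

    Defaults are the published parameter set of the PP2A/B55
    Gwl-phosphatase variant.  ``kigwl_p`` and ``kigwl_pp`` are the
    ASCII-safe names for kigwl' and kigwl''.
    """

    CycT: float = 1.0      # total Cyclin B (control parameter of the switch)
    Va25: float = 2.0      # Cdk1-dependent Cdc25 activation
    Vi25: float = 2.0      # PP2A/B55-dependent Cdc25 inactivation
    Vawee: float = 2.0     # PP2A/B55-dependent Wee1 activation
    Viwee: float = 2.0     # Cdk1-dependent Wee1 inactivation
    kagwl: float = 10.0    # Cdk1-dependent Gwl phosphorylation
    kigwl_p: float = 0.02  # Gwl dephosphorylation, OA-insensitive phosphatase
    kigwl_pp: float = 0.0  # Gwl dephosphorylation, OA-sensitive non-B55 phosphatase
    kigwl: float = 2.0     # Gwl dephosphorylation by PP2A/B55 (feedback)
    kaensa: float = 2.0    # Gwl-dependent ENSA/ARPP19 phosphorylation
    kiensa: float = 0.6    # phospho-ENSA dephosphorylation (OA-insensitive)
    kas: float = 100.0     # PP2A:ENSAP association
    kdis: float = 1.0      # PP2A:ENSAP dissociation
    Cdc25T: float = 1.0
    Wee1T: float = 1.0
    GwlT: float = 1.0
    ENSAT: float = 1.0
    PP2T: float = 0.5
    k25_p: float = 0.01    # basal Cdc25 activity (k25')
    k25_pp: float = 1.0    # phosphorylated-Cdc25 activity (k25'')
    kwee_p: float = 0.01   # phosphorylated-Wee1 activity (kwee')
    kwee_pp: float = 1.0   # active-Wee1 activity (kwee'')
    RO: float = 0.0        # Cdk1-inhibitor dose (RO3306)
    OA: float = 0.0        # PP2A-inhibitor dose (okadaic acid)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v}")
        if self.PP2T >= self.ENSAT:
            raise ValueError(
                "PP2T must stay below ENSAT: PP2A/B55 is kept substoichiometric "
                f"to its inhibitor (PP2T={self.PP2T}, ENSAT={self.ENSAT})"
            )

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **overrides)

    # -- flat key = value serialization ---------------------------------

    def to_config(self) -> str:
        """Serialize as flat ``key = value`` text (lossless round-trip)."""
        lines = [f"{f.name} = {getattr(self, f.name)!r}" for f in dataclasses.fields(self)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "ModelParameters":
        """Parse ``key = value`` text.  Accepts the paper's primed symbols
        (kigwl', kigwl'', k25', ... in ASCII or Unicode prime) as aliases."""
        aliases = {
            "kigwl'": "kigwl_p", "kigwl''": "kigwl_pp",
            "kigwl′": "kigwl_p", "kigwl″": "kigwl_pp",
            "k25'": "k25_p", "k25''": "k25_pp",
            "k25′": "k25_p", "k25″": "k25_pp",
            "kwee'": "kwee_p", "kwee''": "kwee_pp",
            "kwee′": "kwee_p", "kwee″": "kwee_pp",
        }
        known = {f.name for f in dataclasses.fields(cls)}
        values: dict[str, float] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key = aliases.get(key.strip(), key.strip())
            if key not in known:
                raise ValueError(f"line {lineno}: unknown parameter {key!r}")
            values[key] = float(val)
        return cls(**values)


@dataclass(frozen=True)
class ModelState:
    """The six dynamic variables.

    ``MPF`` is the active (Tyr15-dephosphorylated) Cdk1/CycB pool,
    ``Cdc25`` the phosphorylated/active Cdc25, ``Wee1`` the
    unphosphorylated/active Wee1, ``Gwl`` phosphorylated/active Greatwall,
    ``ENSAPt`` total phospho-ENSA/ARPP19 (free plus PP2A-bound) and
    ``PP2`` the free, active PP2A/B55.
    """

    MPF: float
    Cdc25: float
    Wee1: float
    Gwl: float
    ENSAPt: float
    PP2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.MPF, self.Cdc25, self.Wee1, self.Gwl, self.ENSAPt, self.PP2])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(*(float(v) for v in y))


@dataclass(frozen=True)
class Observables:
    """Derived quantities: inhibitor-corrected activities and pools."""

    MPFa: float     # active Cdk1 corrected for RO3306 binding, MPF/(1+RO)
    PP2a: float     # active PP2A/B55 corrected for OA binding, PP2/(1+OA)
    preMPF: float   # Tyr15-phosphorylated Cdk1/CycB, CycT - MPF
    complex: float  # PP2A:ENSAP inhibitory complex, PP2T - PP2


#: Published G2 initial condition.
G2_INIT = ModelState(MPF=0.0, Cdc25=0.0, Wee1=1.0, Gwl=0.0, ENSAPt=0.0, PP2=0.5)

#: Published metaphase initial condition (used for mitotic-exit runs).
METAPHASE_INIT = ModelState(MPF=0.96, Cdc25=0.97, Wee1=0.03, Gwl=0.9, ENSAPt=0.75, PP2=0.027)

#: Gwl-phosphatase scenario presets: overrides applied to the defaults.
SCENARIOS: dict[str, dict[str, float]] = {
    # default parameter set: Gwl dephosphorylated by PP2A/B55 itself
    "pp2a_b55": {},
    # Gwl dephosphorylated by an okadaic-acid-insensitive phosphatase
    "oa_insensitive": {"kigwl_p": 2.0, "kigwl": 0.0},
    # Gwl dephosphorylated by an OA-sensitive, non-B55 phosphatase
    "oa_sensitive": {"kigwl_pp": 2.0, "kigwl": 0.0},
}


def make_scenario(label: str, **extra: float) -> ModelParameters:
    """Build the parameter set for one of the three Gwl-phosphatase variants.

    Parameters
    ----------
    label
        One of ``pp2a_b55``, ``oa_insensitive``, ``oa_sensitive``.
        Dashes are accepted in place of underscores.
    **extra
        Further overrides (e.g. inhibitor doses) applied on top.
    """
    key = label.replace("-", "_")
    if key not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {label!r}; expected one of {sorted(SCENARIOS)}"
        )
    return ModelParameters(**{**SCENARIOS[key], **extra})


def state_bounds(params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Lower and upper box bounds of the state space under ``params``."""
    lo = np.zeros(6)
    hi = np.array([params.CycT, params.Cdc25T, params.Wee1T,
                   params.GwlT, params.ENSAT, params.PP2T])
    return lo, hi


def validate_state(y: np.ndarray, params: ModelParameters, *,
                   tol: float = 1e-9, clamp: bool = False) -> np.ndarray:
    """Check the box invariants 0 <= x_i <= total_i.

    By default a violation beyond ``tol`` raises (silent clamping would
    hide solver pathologies); with ``clamp=True`` the state is clipped to
    the box instead.
    """
    y = np.asarray(y, dtype=float)
    lo, hi = state_bounds(params)
    if clamp:
        return np.clip(y, lo, hi)
    if np.any(y < lo - tol) or np.any(y > hi + tol):
        bad = [
            f"{name}={val:.6g} outside [0, {h:.6g}]"
            for name, val, h in zip(STATE_VARS, y, hi)
            if val < -tol or val > h + tol
        ]
        raise ValueError("state outside admissible box: " + "; ".join(bad))
    return y


def effective_rates(y: np.ndarray | ModelState, params: ModelParameters) -> tuple[float, float]:
    """Effective Tyr15 modification rates.

    k25 = k25'*(Cdc25T - Cdc25) + k25''*Cdc25 (dephosphorylation, i.e.
    Cdk1 activation) and kwee = kwee'*(Wee1T - Wee1) + kwee''*Wee1
    (phosphorylation, Cdk1 inactivation); both linear in the respective
    regulator because active and phosphorylated enzyme forms each carry a
    constant specific activity.
    """
    if isinstance(y, ModelState):
        Cdc25, Wee1 = y.Cdc25, y.Wee1
    else:
        Cdc25, Wee1 = float(y[1]), float(y[2])
    k25 = params.k25_p * (params.Cdc25T - Cdc25) + params.k25_pp * Cdc25
    kwee = params.kwee_p * (params.Wee1T - Wee1) + params.kwee_pp * Wee1
    return k25, kwee


def rhs(t: float, y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Time derivative of the six state variables (mass-action kinetics).

    Signature matches ``scipy.integrate.solve_ivp``.  The Gwl inactivation
    term sums the three candidate phosphatase routes: kigwl' (constant,
    OA-insensitive), kigwl''*PP2T/(1+OA) (OA-sensitive but not subject to
    ENSA inhibition, hence the *total* PP2A pool corrected only for the
    drug) and kigwl*PP2a (PP2A/B55 feedback route).  MPFa enters wherever
    Cdk1 acts as a kinase; the Tyr15 interconversion itself uses the
    chemical pools MPF / CycT - MPF.
    """
    MPF, Cdc25, Wee1, Gwl, ENSAPt, PP2 = y
    p = params
    MPFa = MPF / (1.0 + p.RO)
    PP2a = PP2 / (1.0 + p.OA)
    k25 = p.k25_p * (p.Cdc25T - Cdc25) + p.k25_pp * Cdc25
    kwee = p.kwee_p * (p.Wee1T - Wee1) + p.kwee_pp * Wee1
    cplx = p.PP2T - PP2
    dMPF = k25 * (p.CycT - MPF) - kwee * MPF
    dCdc25 = p.Va25 * MPFa * (p.Cdc25T - Cdc25) - p.Vi25 * PP2a * Cdc25
    dWee1 = p.Vawee * PP2a * (p.Wee1T - Wee1) - p.Viwee * MPFa * Wee1
    dGwl = (p.kagwl * MPFa * (p.GwlT - Gwl)
            - (p.kigwl_p + p.kigwl_pp * p.PP2T / (1.0 + p.OA) + p.kigwl * PP2a) * Gwl)
    dENSAPt = p.kaensa * Gwl * (p.ENSAT - ENSAPt) - p.kiensa * ENSAPt
    dPP2 = -p.kas * (ENSAPt - cplx) * PP2 + (p.kdis + p.kiensa) * cplx
    out = np.array([dMPF, dCdc25, dWee1, dGwl, dENSAPt, dPP2])
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"non-finite derivative at t={t}: y={y!r}")
    return out


def rhs_state(state: ModelState, params: ModelParameters) -> np.ndarray:
    """Convenience wrapper of :func:`rhs` taking a :class:`ModelState`."""
    return rhs(0.0, state.as_array(), params)


def observables(y: np.ndarray | ModelState, params: ModelParameters) -> Observables:
    """Algebraic observables of a state (see :class:`Observables`)."""
    if isinstance(y, ModelState):
        y = y.as_array()
    MPF, PP2 = float(y[0]), float(y[5])
    return Observables(
        MPFa=MPF / (1.0 + params.RO),
        PP2a=PP2 / (1.0 + params.OA),
        preMPF=params.CycT - MPF,
        complex=params.PP2T - PP2,
    )
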