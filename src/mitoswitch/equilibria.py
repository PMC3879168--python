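"""Steady states, linear stability and saddle-node (fold) analysis.

The G2/M transition behaves as a bistable switch: over an intermediate
range of total Cyclin B the model has two stable steady states (a G2-like
low-Cdk1-activity state and an M-like high-activity state) separated by a
saddle.  "Balance curves" - equilibrium branches of a readout such as
preMPF or Gwl against total Cyclin B - expose this hysteresis and the two
saddle-node folds bounding the bistable window.

Continuation is implemented as parameter stepping with multi-start
Newton root-finding and neighbour seeding (the system is 6-dimensional
and well conditioned at this scale); folds are localized by bisection on
the change of equilibrium count, not by pseudo-arclength continuation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root

from .model import (
    ModelParameters,
    ModelState,
    STATE_VARS,
    rhs,
    state_bounds,
)

__all__ = [
    "Equilibrium",
    "EquilibriumBranch",
    "ConvergenceError",
    "jacobian_fd",
    "find_steady_state",
    "find_all_equilibria",
    "balance_curve",
    "is_bistable",
    "bistability_region",
]

RESIDUAL_TOL = 1e-10       # max-norm of rhs at an accepted equilibrium
STABILITY_EPS = 1e-9       # eigenvalue real-part threshold for stable/unstable
MERGE_TOL = 1e-6           # duplicate-equilibrium merging (state max-norm)
BOX_TOL = 1e-8             # tolerance for "inside the box"
FOLD_TOL = 1e-4            # parameter tolerance for fold bisection


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the best residual reached."""

    def __init__(self, message: str, best_residual: float):
        super().__init__(f"{message} (best residual {best_residual:.3g})")
        self.best_residual = best_residual


@dataclass(frozen=True)
class Equilibrium:
    """A steady state with its linear-stability classification.

    ``stability`` is "stable" (all eigenvalue real parts < -1e-9),
    "unstable" (some real part > 1e-9) or "marginal" (leading real part
    within the threshold; never silently classified).
    """

    state: np.ndarray
    residual: float
    stability: str
    leading_eigenvalue: float

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"

    def as_state(self) -> ModelState:
        return ModelState.from_array(self.state)


@dataclass
class EquilibriumBranch:
    """Equilibria of the model along a one-parameter grid.

    ``equilibria[i]`` lists all steady states found at ``grid[i]``;
    ``folds`` are the saddle-node parameter values (bisected to 1e-4)
    bracketing windows where the equilibrium count changes.
    """

    control: str
    grid: np.ndarray
    equilibria: list[list[Equilibrium]]
    folds: list[float]
    params: ModelParameters

    def counts(self) -> np.ndarray:
        return np.array([len(e) for e in self.equilibria])

    def stable_counts(self) -> np.ndarray:
        return np.array([sum(eq.is_stable for eq in e) for e in self.equilibria])

    @property
    def bistable(self) -> bool:
        return bool(np.any(self.stable_counts() >= 2))

    def bistable_window(self) -> Optional[tuple[float, float]]:
        """(min, max) control values of the bistable grid region, or None."""
        mask = self.stable_counts() >= 2
        if not mask.any():
            return None
        vals = self.grid[mask]
        return float(vals.min()), float(vals.max())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for value, eqs in zip(self.grid, self.equilibria):
            for j, eq in enumerate(eqs):
                row = {self.control: value, "index": j}
                row.update(dict(zip(STATE_VARS, eq.state)))
                row["preMPF"] = (value if self.control == "CycT"
                                 else self.params.CycT) - eq.state[0]
                row["stability"] = eq.stability
                row["leading_eigenvalue"] = eq.leading_eigenvalue
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path_or_buf) -> None:
        header = (f"# control = {self.control}\n"
                  f"# folds = {', '.join(f'{f:.6g}' for f in self.folds) or 'none'}\n")
        body = self.to_frame().to_csv(index=False, float_format="%.10g")
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header + body)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(header + body)


def jacobian_fd(y: np.ndarray, params: ModelParameters, h: float = 1e-7) -> np.ndarray:
    """Jacobian of the right-hand side by central finite differences."""
    y = np.asarray(y, float)
    J = np.empty((6, 6))
    for j in range(6):
        e = np.zeros(6)
        e[j] = h
        J[:, j] = (rhs(0.0, y + e, params) - rhs(0.0, y - e, params)) / (2 * h)
    return J


def _classify(y: np.ndarray, params: ModelParameters) -> tuple[str, float]:
    eigs = np.linalg.eigvals(jacobian_fd(y, params))
    lead = float(np.max(eigs.real))
    if lead < -STABILITY_EPS:
        return "stable", lead
    if lead > STABILITY_EPS:
        return "unstable", lead
    return "marginal", lead


def find_steady_state(params: ModelParameters, guess: ModelState | np.ndarray,
                      *, tol: float = RESIDUAL_TOL,
                      max_iter: int = 200) -> Equilibrium:
    """Newton-type root of the right-hand side from ``guess``.

    The converged point must lie inside the state box and have residual
    max-norm below ``tol``; stability is classified from the eigenvalues
    of the finite-difference Jacobian.
    """
    y0 = guess.as_array() if isinstance(guess, ModelState) else np.asarray(guess, float)
    sol = root(lambda y: rhs(0.0, y, params), y0,
               jac=lambda y: jacobian_fd(y, params),
               method="hybr", options={"xtol": 1e-13, "maxfev": max_iter * 7})
    res = float(np.max(np.abs(rhs(0.0, sol.x, params))))
    if not sol.success or res >= tol:
        raise ConvergenceError("steady-state iteration did not converge", res)
    lo, hi = state_bounds(params)
    if np.any(sol.x < lo - BOX_TOL) or np.any(sol.x > hi + BOX_TOL):
        raise ConvergenceError("converged point outside the state box", res)
    y = np.clip(sol.x, lo, hi)
    stability, lead = _classify(y, params)
    return Equilibrium(state=y, residual=res, stability=stability,
                       leading_eigenvalue=lead)


def _canonical_starts(params: ModelParameters) -> list[np.ndarray]:
    """Deterministic multi-start seeds: G2-like, M-like corners and a
    small fixed quasi-random interior set."""
    lo, hi = state_bounds(params)
    g2 = np.array([0.0, 0.0, hi[2], 0.0, 0.0, hi[5]])
    mitotic = np.array([0.99 * hi[0], 0.97 * hi[1], 0.03 * hi[2],
                        0.90 * hi[3], 0.75 * hi[4], 0.05 * hi[5]])
    mid = 0.5 * (lo + hi)
    rng = np.random.default_rng(20131004)  # fixed: starts are part of the algorithm
    interior = lo + (hi - lo) * rng.random((6, 6))
    return [g2, mitotic, mid, *interior]


def _reduction_seeds(params: ModelParameters, n_grid: int = 8001) -> list[np.ndarray]:
    """Near-exact equilibrium localization by the Gwl-balance reduction.

    At steady state every variable is an explicit function of active Gwl:
    the ENSA balance gives ENSAPt(Gwl), the complex association/release
    balance gives free PP2(ENSAPt) (positive root of a quadratic), the
    Cdc25/Wee1 balances give Cdc25 and Wee1 in terms of MPFa and PP2a,
    and the Gwl balance itself yields MPFa(Gwl).  Equilibria of the full
    6-D system are then exactly the roots of the remaining scalar Tyr15
    balance, scanned on a dense Gwl grid.  Bracket midpoints are returned
    as Newton seeds; a pure multi-start Newton can jump basins from a
    box-corner start and silently lose a coexisting state, which this
    localization prevents.
    """
    p = params
    if p.kagwl == 0.0:
        # Gwl never activates: Gwl = ENSAPt = 0, PP2 from the release
        # balance, and the Tyr15 balance is scanned over MPF directly.
        PP2 = _pp2_of_ensapt(np.array([0.0]), p)[0]
        M = np.linspace(0.0, p.CycT, n_grid)
        phi = _tyr15_balance(M / (1.0 + p.RO), PP2 / (1.0 + p.OA), M, p)
        seeds = []
        for i in np.where(np.diff(np.sign(phi)) != 0)[0]:
            m = 0.5 * (M[i] + M[i + 1])
            MPFa, PP2a = m / (1.0 + p.RO), PP2 / (1.0 + p.OA)
            C, W = _cdc25_wee1(MPFa, PP2a, p)
            seeds.append(np.array([m, C, W, 0.0, 0.0, PP2]))
        return seeds

    frac = np.concatenate([np.geomspace(1e-10, 1e-2, 400),
                           np.linspace(1e-2, 1.0 - 1e-9, n_grid)])
    G = p.GwlT * frac
    denom = p.kaensa * G + p.kiensa
    with np.errstate(invalid="ignore", divide="ignore"):
        E = np.where(denom > 0, p.kaensa * G * p.ENSAT / denom, 0.0)
    PP2 = _pp2_of_ensapt(E, p)
    PP2a = PP2 / (1.0 + p.OA)
    decay = p.kigwl_p + p.kigwl_pp * p.PP2T / (1.0 + p.OA) + p.kigwl * PP2a
    MPFa = decay * G / (p.kagwl * (p.GwlT - G))
    M = MPFa * (1.0 + p.RO)
    phi = _tyr15_balance(MPFa, PP2a, M, p)
    valid = M <= p.CycT + 1e-12
    seeds = []
    for i in np.where(valid[:-1] & valid[1:]
                      & (np.diff(np.sign(phi)) != 0))[0]:
        g = 0.5 * (G[i] + G[i + 1])
        e = 0.5 * (E[i] + E[i + 1])
        pp2 = 0.5 * (PP2[i] + PP2[i + 1])
        m = 0.5 * (M[i] + M[i + 1])
        C, W = _cdc25_wee1(m / (1.0 + p.RO), pp2 / (1.0 + p.OA), p)
        seeds.append(np.array([m, C, W, g, e, pp2]))
    return seeds


def _pp2_of_ensapt(E: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Free active PP2A/B55 at the complex association/release balance,
    given total phospho-ENSA: positive root of
    kas*(E - (PP2T - PP2))*PP2 = (kdis + kiensa)*(PP2T - PP2)."""
    release = p.kdis + p.kiensa
    if p.kas == 0.0:
        return np.full_like(E, p.PP2T)
    b = p.kas * (E - p.PP2T) + release
    return (-b + np.sqrt(b * b + 4.0 * p.kas * release * p.PP2T)) / (2.0 * p.kas)


def _cdc25_wee1(MPFa: float, PP2a: float, p: ModelParameters) -> tuple[float, float]:
    """Steady-state active Cdc25 and Wee1 at given kinase/phosphatase
    activities (each a simple activation/inactivation balance)."""
    dc = p.Va25 * MPFa + p.Vi25 * PP2a
    dw = p.Vawee * PP2a + p.Viwee * MPFa
    C = p.Va25 * MPFa * p.Cdc25T / dc if dc > 0 else 0.0
    W = p.Vawee * PP2a * p.Wee1T / dw if dw > 0 else p.Wee1T
    return C, W


def _tyr15_balance(MPFa, PP2a, M, p: ModelParameters):
    """Residual of the Tyr15 phosphorylation balance,
    k25*(CycT - MPF) - kwee*MPF, with Cdc25 and Wee1 at their own
    steady-state values (vectorized)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        dc = p.Va25 * MPFa + p.Vi25 * PP2a
        dw = p.Vawee * PP2a + p.Viwee * MPFa
        C = np.where(dc > 0, p.Va25 * MPFa * p.Cdc25T / np.where(dc > 0, dc, 1.0), 0.0)
        W = np.where(dw > 0, p.Vawee * PP2a * p.Wee1T / np.where(dw > 0, dw, 1.0),
                     p.Wee1T)
    k25 = p.k25_p * (p.Cdc25T - C) + p.k25_pp * C
    kwee = p.kwee_p * (p.Wee1T - W) + p.kwee_pp * W
    return k25 * (p.CycT - M) - kwee * M


def find_all_equilibria(params: ModelParameters,
                        starts: Optional[Iterable[np.ndarray]] = None,
                        *, merge_tol: float = MERGE_TOL,
                        localize: bool = True) -> list[Equilibrium]:
    """All distinct equilibria from localization plus multi-start Newton.

    Seeds combine the semi-analytic Gwl-balance localization (see
    :func:`_reduction_seeds`), supplied/neighbour states and the
    canonical box corners.  After two distinct stable states are found,
    extra starts on the segment between them are tried so the separating
    saddle is never silently dropped.  Results are deduplicated at
    ``merge_tol`` in state max-norm and sorted by MPF.
    """
    seeds = list(starts) if starts is not None else []
    if localize:
        seeds += _reduction_seeds(params)
    seeds += _canonical_starts(params)
    found: list[Equilibrium] = []

    def try_seed(seed: np.ndarray) -> None:
        try:
            eq = find_steady_state(params, seed)
        except ConvergenceError:
            return
        for other in found:
            if np.max(np.abs(eq.state - other.state)) < merge_tol:
                return
        found.append(eq)

    for seed in seeds:
        try_seed(seed)

    stable = [eq for eq in found if eq.is_stable]
    if len(stable) >= 2:
        a, b = stable[0].state, stable[1].state
        for frac in (0.5, 0.25, 0.75, 0.4, 0.6):
            try_seed(a + frac * (b - a))

    found.sort(key=lambda eq: eq.state[0])
    return found


def _count_at(params: ModelParameters, control: str, value: float,
              seeds: Sequence[np.ndarray]) -> list[Equilibrium]:
    return find_all_equilibria(params.replace(**{control: value}), starts=seeds)


def balance_curve(params: ModelParameters, control: str = "CycT",
                  grid: Optional[np.ndarray] = None,
                  *, fold_tol: float = FOLD_TOL) -> EquilibriumBranch:
    """One-parameter equilibrium branch with saddle-node fold detection.

    For each grid value all equilibria are collected by multi-start
    Newton seeded from the neighbouring grid point's equilibria
    (continuation); folds are then located by bisection on each interval
    where the equilibrium count changes, to ``fold_tol`` in the
    parameter.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array")

    equilibria: list[list[Equilibrium]] = []
    prev_seeds: list[np.ndarray] = []
    for value in grid:
        eqs = _count_at(params, control, value, prev_seeds)
        equilibria.append(eqs)
        prev_seeds = [eq.state for eq in eqs]

    folds: list[float] = []
    counts = [len(e) for e in equilibria]
    for i in range(len(grid) - 1):
        if counts[i] == counts[i + 1]:
            continue
        lo_v, hi_v = float(grid[i]), float(grid[i + 1])
        lo_n = counts[i]
        seeds = [eq.state for eq in equilibria[i] + equilibria[i + 1]]
        while hi_v - lo_v > fold_tol:
            mid = 0.5 * (lo_v + hi_v)
            n_mid = len(_count_at(params, control, mid, seeds))
            if n_mid == lo_n:
                lo_v = mid
            else:
                hi_v = mid
        folds.append(0.5 * (lo_v + hi_v))

    return EquilibriumBranch(control=control, grid=grid, equilibria=equilibria,
                             folds=folds, params=params)


# Order in which grid values are probed when only a bistable/monostable
# verdict is needed: a van der Corput (bit-reversal) ordering covers the
# whole range coarsely first, so a bistable window anywhere on the grid
# is hit within a few probes and the scan can exit early.
def _probe_order(grid: np.ndarray) -> np.ndarray:
    n = len(grid)
    def radical_inverse(i: int) -> float:
        inv, f = 0.0, 0.5
        while i:
            inv += f * (i & 1)
            i >>= 1
            f *= 0.5
        return inv
    ranks = sorted(range(n), key=radical_inverse)
    return grid[np.asarray(ranks)]


def is_bistable(params: ModelParameters, control: str = "CycT",
                grid: Optional[np.ndarray] = None) -> bool:
    """Whether the model is bistable at some value of ``control``.

    A grid value counts as bistable when two distinct stable equilibria
    coexist there.  Early-exits on the first bistable value found.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    for value in _probe_order(np.asarray(grid, float)):
        p = params.replace(**{control: float(value)})
        # the reduction localizes every equilibrium, so polishing its
        # seeds alone suffices for counting stable states
        stable: list[np.ndarray] = []
        for seed in _reduction_seeds(p):
            try:
                eq = find_steady_state(p, seed)
            except ConvergenceError:
                continue
            if eq.is_stable and all(
                    np.max(np.abs(eq.state - s)) >= MERGE_TOL for s in stable):
                stable.append(eq.state)
        if len(stable) >= 2:
            return True
    return False


def bistability_region(params: ModelParameters, param_x: str, x_grid: np.ndarray,
                       param_y: str, y_grid: np.ndarray,
                       *, cyct_grid: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Two-parameter bistability map.

    Each (x, y) cell is classified by scanning total Cyclin B for
    coexisting stable states; solver failures mark a cell "unknown",
    never silently monostable.  Returns a tidy frame with columns
    ``param_x``, ``param_y`` and ``bistable`` in {"yes", "no", "unknown"}.
    """
    rows = []
    for xv in np.asarray(x_grid, float):
        for yv in np.asarray(y_grid, float):
            if not (np.isfinite(xv) and np.isfinite(yv)) or xv < 0 or yv < 0:
                raise ValueError("grid values must be finite and >= 0")
            try:
                p = params.replace(**{param_x: float(xv), param_y: float(yv)})
                verdict = "yes" if is_bistable(p, grid=cyct_grid) else "no"
            except (ConvergenceError, FloatingPointError, ValueError) as exc:
                verdict = "unknown"
            rows.append({param_x: xv, param_y: yv, "bistable": verdict})
    return pd.DataFrame(rows)
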