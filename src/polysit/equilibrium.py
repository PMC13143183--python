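"""Equilibrium and bifurcation analysis of the reduced SIT model.

With sterilized males at their decoupled equilibrium S* = σ/μS, the
infestation equilibria of the reduced model are the roots of the
downward parabola

    ζ(L*) = γ μS (μF+τI) / (η (μF+τF)) · ( −(R0/K) L*² + (R0−1) L* ) = σ,

so the system undergoes a saddle-node bifurcation at the parabola's
summit. The eradication threshold

    σ̄ = K γ μS (R0−1)² (μF+τI) / (4 η R0 (μF+τF))

is the minimum constant release rate above which the pest-free
equilibrium is the only equilibrium (and the only stable state). For
0 < σ < σ̄ and R0 > 1 there are three equilibria: pest-free (stable),
a low infestation equilibrium E1* (unstable) and a high one E2*
(stable). Stability is classified numerically from the eigenvalues of
a finite-difference Jacobian of the reduced vector field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .ode import reduced_rhs, simulate
from .parameters import ModelParameters, ParameterError, basic_reproduction_number, gamma_factor

__all__ = [
    "Equilibrium",
    "BifurcationTable",
    "zeta",
    "eradication_threshold",
    "find_equilibria",
    "classify_stability",
    "jacobian",
    "bifurcation_diagram",
    "threshold_heatmap",
    "transient_comparison",
    "HIGH_INFESTATION_INIT",
]

Kind = Literal["pest-free", "infestation-low", "infestation-high", "infestation-marginal"]
Stability = Literal["stable", "unstable", "marginal"]

#: Fig-4A style high-infestation initial condition (L, M, F_I, F_F);
#: S is initialised at σ/μS by the helpers that use it.
HIGH_INFESTATION_INIT = (30_000.0, 100_000.0, 0.0, 100_000.0)

#: stability tolerance on max Re(λ), day⁻¹ (absolute)
STABILITY_TOL = 1e-9


@dataclass(frozen=True)
class Equilibrium:
    state: np.ndarray  # (L, M, F_I, F_F, S)
    kind: Kind
    stability: Stability | None = None

    @property
    def L_star(self) -> float:
        return float(self.state[0])


def _zeta_prefactor(params: ModelParameters) -> float:
    if params.eta == 0:
        raise ParameterError("eta", "zeta undefined for eta = 0 (sterile males never mate)")
    return (
        gamma_factor(params)
        * params.mu_S
        * (params.mu_F + params.tau_I)
        / (params.eta * (params.mu_F + params.tau_F))
    )


def zeta(L_star: float, params: ModelParameters) -> float:
    """Release rate σ for which ``L_star`` is an infestation equilibrium."""
    R0 = basic_reproduction_number(params)
    A = _zeta_prefactor(params)
    return A * (-(R0 / params.K) * L_star**2 + (R0 - 1) * L_star)


def eradication_threshold(params: ModelParameters) -> float:
    """Critical release rate σ̄ (summit of the ζ parabola).

    Returns 0 when R0 ≤ 1: the pest dies out on its own and any σ > 0
    suffices.
    """
    R0 = basic_reproduction_number(params)
    if R0 <= 1:
        return 0.0
    if params.eta == 0:
        raise ParameterError("eta", "eradication impossible with eta = 0 and R0 > 1")
    return (
        params.K
        * gamma_factor(params)
        * params.mu_S
        * (R0 - 1) ** 2
        * (params.mu_F + params.tau_I)
        / (4 * params.eta * R0 * (params.mu_F + params.tau_F))
    )


def _complete_state(L_star: float, params: ModelParameters, sigma: float) -> np.ndarray:
    """Back-substitute the remaining compartments for a given L*.

    M* = νpL*/μM and S* = σ/μS are immediate; F_F* follows from the
    stationary L-equation and F_I* from the stationary F_I-equation.
    """
    pr = params
    M = pr.nu * pr.p * L_star / pr.mu_M
    S = sigma / pr.mu_S
    F_F = (pr.mu_L + pr.nu) * L_star / (pr.omega * (1 - L_star / pr.K))
    tot = M + pr.eta * S
    m = M / tot if tot > 0 else 0.0
    s = pr.eta * S / tot if tot > 0 else 0.0
    F_I = (pr.nu * (1 - pr.p) * s * L_star + pr.tau_F * s * F_F) / (pr.mu_F + pr.tau_I * m)
    return np.array([L_star, M, F_I, F_F, S])


def find_equilibria(params: ModelParameters, sigma: float, classify: bool = True) -> list[Equilibrium]:
    """All equilibria of the reduced model at release rate σ.

    The pest-free equilibrium (0, 0, 0, 0, σ/μS) is always present;
    infestation equilibria are the roots in (0, K) of the closed-form
    quadratic ζ(L*) = σ, labelled by their position relative to the
    parabola vertex K/2·(1−1/R0). An exact double root is reported as a
    single "infestation-marginal" equilibrium.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = [
        Equilibrium(
            state=np.array([0.0, 0.0, 0.0, 0.0, sigma / params.mu_S]),
            kind="pest-free",
            stability=classify_stability_state(
                np.array([0.0, 0.0, 0.0, 0.0, sigma / params.mu_S]), params, sigma
            ) if classify else None,
        )
    ]
    R0 = basic_reproduction_number(params)
    if R0 <= 1:
        return out
    A = _zeta_prefactor(params)
    # A(-(R0/K)L² + (R0-1)L) = sigma  ->  (R0/K)L² - (R0-1)L + sigma/A = 0
    a, b, c = R0 / params.K, -(R0 - 1), sigma / A
    disc = b * b - 4 * a * c
    # float-tolerant double-root detection at sigma = sigma_bar
    double = abs(disc) <= 1e-12 * b * b
    if disc < 0 and not double:
        return out
    vertex = params.K / 2 * (1 - 1 / R0)
    if double:
        roots = [(vertex, "infestation-marginal")]
    else:
        sq = math.sqrt(disc)
        lo, hi = (-b - sq) / (2 * a), (-b + sq) / (2 * a)
        roots = [(lo, "infestation-low"), (hi, "infestation-high")]
    for L_star, kind in roots:
        if 0 < L_star < params.K:
            state = _complete_state(L_star, params, sigma)
            stab = classify_stability_state(state, params, sigma) if classify else None
            out.append(Equilibrium(state=state, kind=kind, stability=stab))
    return out


def jacobian(state: np.ndarray, params: ModelParameters, sigma: float) -> np.ndarray:
    """Central finite-difference Jacobian of the reduced vector field
    (relative step 1e-6 per component, absolute floor for zeros)."""
    state = np.asarray(state, dtype=float)
    n = state.size
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * max(abs(state[j]), 1.0)
        up, dn = state.copy(), state.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (reduced_rhs(up, params, sigma) - reduced_rhs(dn, params, sigma)) / (2 * h)
    return J


def classify_stability_state(state: np.ndarray, params: ModelParameters, sigma: float) -> Stability:
    eigs = np.linalg.eigvals(jacobian(state, params, sigma))
    max_re = float(np.max(eigs.real))
    if abs(max_re) <= STABILITY_TOL:
        return "marginal"
    return "stable" if max_re < 0 else "unstable"


def classify_stability(eq: Equilibrium, params: ModelParameters, sigma: float) -> Stability:
    """Stability label from the Jacobian eigenvalues at ``eq``."""
    return classify_stability_state(eq.state, params, sigma)


@dataclass
class BifurcationTable:
    sigma_grid: np.ndarray
    equilibria: list[list[Equilibrium]]  # one list per σ

    def branch_counts(self) -> np.ndarray:
        return np.array([len(eqs) for eqs in self.equilibria])

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for s, eqs in zip(self.sigma_grid, self.equilibria):
            for eq in eqs:
                rows.append({"sigma": s, "L_star": eq.L_star, "kind": eq.kind,
                             "stability": eq.stability})
        return pd.DataFrame(rows, columns=["sigma", "L_star", "kind", "stability"])


def bifurcation_diagram(params: ModelParameters, sigma_grid: Sequence[float]) -> BifurcationTable:
    """Equilibria and stability labels along a σ grid (Fig-2 style)."""
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if sigma_grid.size == 0 or np.any(sigma_grid < 0):
        raise ValueError("sigma_grid must be non-empty and non-negative")
    return BifurcationTable(
        sigma_grid=sigma_grid,
        equilibria=[find_equilibria(params, float(s)) for s in sigma_grid],
    )


_HEATMAP_AXES = {"tau_F", "tau_I", "eta"}


def threshold_heatmap(
    params: ModelParameters,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    cap: float = 1_000_000.0,
) -> np.ndarray:
    """σ̄ over a 2-D parameter grid, capped at ``cap`` (Fig-6 style).

    Returns a matrix with shape (len(grid2), len(grid1)): rows follow
    axis2, columns axis1. Raw (uncapped) values are recomputable by
    passing ``cap=np.inf``.
    """
    name1, grid1 = axis1
    name2, grid2 = axis2
    for name in (name1, name2):
        if name not in _HEATMAP_AXES:
            raise ValueError(f"unknown heatmap axis {name!r}; choose from {sorted(_HEATMAP_AXES)}")
    if name1 == name2:
        raise ValueError("heatmap axes must be distinct")
    out = np.empty((len(grid2), len(grid1)))
    for i, v2 in enumerate(grid2):
        for j, v1 in enumerate(grid1):
            p = params.replace(**{name1: float(v1), name2: float(v2)})
            out[i, j] = eradication_threshold(p)
    return np.minimum(out, cap)


def transient_comparison(
    params: ModelParameters,
    sigma_grid: Sequence[float],
    horizon: float = 3000.0,
    init: Sequence[float] = HIGH_INFESTATION_INIT,
    n_times: int = 301,
) -> tuple[np.ndarray, np.ndarray]:
    """(L_First − L_Last)/L_WR over time × σ (Fig-5 style heatmap data).

    For each σ the reduced model is run under the First setting
    (τF = τI = 0), the Last setting (the given refractory rates) and the
    no-release baseline WR (σ = 0). Positive entries mean the Last
    scenario has reduced larvae further at that time; cells where the
    baseline has itself collapsed (L_WR < 1) are returned as NaN.

    Returns ``(t, matrix)`` with matrix shape (len(sigma_grid), n_times).
    """
    L0, M0, FI0, FF0 = init
    t = np.linspace(0.0, horizon, n_times)
    first_params = params.replace(tau_F=0.0, tau_I=0.0)

    wr = simulate("reduced", [L0, M0, FI0, FF0, 0.0], params, 0.0, horizon, grid=t)
    L_wr = wr["L"]
    out = np.empty((len(sigma_grid), n_times))
    for i, sigma in enumerate(sigma_grid):
        s0 = sigma / params.mu_S
        init_s = [L0, M0, FI0, FF0, s0]
        L_first = simulate("reduced", init_s, first_params, sigma, horizon, grid=t)["L"]
        L_last = simulate("reduced", init_s, params, sigma, horizon, grid=t)["L"]
        with np.errstate(divide="ignore", invalid="ignore"):
            row = (L_first - L_last) / L_wr
        row[L_wr < 1.0] = np.nan
        out[i] = row
    return t, out
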