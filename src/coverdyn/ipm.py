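"""Discretised integral projection models and the coupled community run.

Each functional group k projects its density ``n_k(x, t)`` of species per
unit log-cover through the annual kernel

    K_k(x, y) = s_k(x) g_k(x, y) + f_k(y)

on the bounded log-cover axis ``[L, U] = [0, log 100]``, discretised by the
midpoint rule on m cells.  The three groups are coupled only through the
total percent covers (N_g, N_l, N_f), which enter every vital-rate model as
logged covariates; within a year the update is synchronous — each kernel is
rebuilt at the current totals, all three densities are advanced, then the
totals are recomputed.

Total cover is the cover-weighted integral ``N_k = \\int e^x n_k(x) dx``:
a species sitting at log cover x contributes e^x percent.

Two colonisation placements are supported.  The default adds
``col_rate * f_k(y)`` as a density-independent inflow vector each year
(colonisation treated as independent of resident abundance, with
``col_rate`` the expected colonising species per plot-year); the
alternative keeps ``f_k(y)`` inside the integral, making colonist inflow
proportional to current species density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .params import VitalRateParams, covariates, growth_design
from .survey import GROUPS, L, U

COL_MODES = ("density", "independent")


@dataclass
class Mesh:
    """Midpoint-rule mesh on the log-cover interval [0, log 100]."""

    m: int = 100
    L: float = L
    U: float = U

    def __post_init__(self):
        self.h = (self.U - self.L) / self.m
        self.x = self.L + (np.arange(self.m) + 0.5) * self.h
        #: cover weights: dN/dn_i = e^{x_i} h
        self.w = np.exp(self.x) * self.h


class KernelError(RuntimeError):
    pass


@dataclass
class KernelGrid:
    """One group's discretised kernel at fixed community totals."""

    mesh: Mesh
    N: np.ndarray                   # totals the kernel was built at
    K: np.ndarray                   # m x m, K[i, j]: from x_j to y_i
    P: np.ndarray                   # survival-growth part s(x_j) g(x_j, y_i)
    fvec: np.ndarray                # colonist size density on the mesh
    col_mode: str = "independent"
    eviction: np.ndarray | None = None


def build_kernel(params: VitalRateParams, N, mesh: Mesh,
                 col_mode: str = "independent",
                 eviction_tol: float = 0.01,
                 warn_eviction: bool = True) -> KernelGrid:
    """Midpoint-rule kernel at fixed totals N = (N_g, N_l, N_f).

    Columns index the source cover x_j, rows the destination y_i; the
    Gaussian growth and colonist terms are evaluated as densities in y.
    In the default ``independent`` mode the colonisation profile (scaled by
    ``col_rate``) is kept out of K and applied additively during a step;
    in ``density`` mode it is added to every column of K.
    """
    if col_mode not in COL_MODES:
        raise ValueError(f"col_mode must be one of {COL_MODES}")
    u = covariates(np.asarray(N, float))
    x = mesh.x
    s = params.survival(x, u)                       # (m,)
    mu = params.growth_mean(x, u)                   # (m,)
    raw_sd = growth_design(x, *u) @ params.expansion_sd
    sd = params.growth_sd(x, u)
    if np.any(~np.isfinite(sd)):
        raise KernelError("non-finite expansion SD on the mesh")
    G = norm.pdf(x[:, None], loc=mu[None, :], scale=sd[None, :])
    P = s[None, :] * G
    fvec = params.col_rate * norm.pdf(x, loc=params.colonist_mean(u),
                                      scale=params.colonist_sd(u))
    K = P + fvec[:, None] if col_mode == "density" else P.copy()
    evict = 1.0 - mesh.h * G.sum(axis=0)
    if warn_eviction and np.any(evict > eviction_tol):
        cols = np.nonzero(evict > eviction_tol)[0]
        warnings.warn(
            f"growth-kernel eviction mass exceeds {eviction_tol:.0%} in "
            f"{len(cols)} column(s) (first offenders {cols[:5].tolist()})",
            RuntimeWarning, stacklevel=2)
    if np.any(raw_sd <= 0):
        # flooring keeps the kernel finite, but a negative evaluated SD means
        # the SD model is extrapolating outside its plausible range
        warnings.warn("expansion SD model evaluated <= 0 on the mesh; "
                      "floored at sigma_floor", RuntimeWarning, stacklevel=2)
    return KernelGrid(mesh=mesh, N=np.asarray(N, float), K=K, P=P,
                      fvec=fvec, col_mode=col_mode, eviction=evict)


@dataclass
class CommunityState:
    """Mesh densities for the three groups plus derived totals."""

    densities: dict                  # group -> (m,) array
    mesh: Mesh
    t: int = 0

    @property
    def N(self) -> np.ndarray:
        """(N_g, N_l, N_f): cover-weighted totals from the densities."""
        return np.array([float(self.mesh.w @ self.densities[g])
                         for g in GROUPS])

    def copy(self) -> "CommunityState":
        return CommunityState({g: v.copy() for g, v in
                               self.densities.items()}, self.mesh, self.t)


def state_from_log_covers(log_covers_by_group: dict, mesh: Mesh,
                          n_plots: int = 1) -> CommunityState:
    """Bin observed species log covers into a per-plot mesh density.

    ``n_plots`` divides the histogram so the state is an average quadrat.
    """
    dens = {}
    edges = np.linspace(mesh.L, mesh.U, mesh.m + 1)
    for g in GROUPS:
        vals = np.asarray(log_covers_by_group.get(g, ()), float)
        counts, _ = np.histogram(np.clip(vals, mesh.L, mesh.U - 1e-12),
                                 bins=edges)
        dens[g] = counts / (mesh.h * n_plots)
    return CommunityState(dens, mesh)


class DivergenceError(RuntimeError):
    pass


def step(state: CommunityState, params_by_group: dict,
         col_mode: str = "independent",
         warn_eviction: bool = False) -> CommunityState:
    """One synchronous annual update of all three coupled groups."""
    N = state.N
    mesh = state.mesh
    new = {}
    for g in GROUPS:
        kg = build_kernel(params_by_group[g], N, mesh, col_mode=col_mode,
                          warn_eviction=warn_eviction)
        n_next = mesh.h * (kg.K @ state.densities[g])
        if col_mode == "independent":
            n_next = n_next + kg.fvec
        if not np.all(np.isfinite(n_next)):
            raise DivergenceError(
                f"non-finite density for group {g!r} at step {state.t + 1}")
        new[g] = n_next
    return CommunityState(new, mesh, state.t + 1)


#: Convergence criterion on log totals (per annual step, per group).
CONV_TOL = 1e-6
#: Number of trailing steps over which the criterion must hold.
CONV_WINDOW = 10


@dataclass
class Trajectory:
    """N_k time series of a coupled run plus the final mesh densities."""

    years: np.ndarray
    N: np.ndarray                    # (T+1, 3) in GROUPS order
    final: CommunityState
    converged: bool = False
    convergence_step: int | None = None

    def to_frame(self):
        import pandas as pd
        rows = []
        for i, t in enumerate(self.years):
            for j, g in enumerate(GROUPS):
                rows.append(dict(t=int(t), group=g, N=self.N[i, j]))
        return pd.DataFrame(rows)


def _log_changes(N: np.ndarray) -> np.ndarray:
    """|Delta log N_k| per step; zero-to-zero transitions count as 0."""
    safe = np.where(N > 0, N, np.nan)
    d = np.abs(np.diff(np.log(safe), axis=0))
    both_zero = (N[:-1] == 0) & (N[1:] == 0)
    d[both_zero] = 0.0
    return np.where(np.isnan(d), np.inf, d)


def simulate(initial: CommunityState, params_by_group: dict, T: int = 300,
             col_mode: str = "independent") -> Trajectory:
    """Run the coupled system T annual steps and detect equilibrium.

    Converged means every group's log total changes by < 1e-6 per step over
    the final 10 steps.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    Ns = np.empty((T + 1, 3))
    state = initial.copy()
    Ns[0] = state.N
    for t in range(T):
        state = step(state, params_by_group, col_mode=col_mode)
        Ns[t + 1] = state.N
    d = _log_changes(Ns)
    window = d[-CONV_WINDOW:] if T >= CONV_WINDOW else d
    converged = bool(np.all(window < CONV_TOL))
    conv_step = None
    if converged:
        below = np.all(d < CONV_TOL, axis=1)
        # first step index after which the criterion holds to the end
        idx = np.nonzero(~below)[0]
        conv_step = int(idx[-1] + 2) if len(idx) else 1
    return Trajectory(years=np.arange(T + 1), N=Ns, final=state,
                      converged=converged, convergence_step=conv_step)


def check_plausibility(params: VitalRateParams, group: str,
                       observed_N: np.ndarray,
                       mesh: Mesh | None = None, T: int = 300,
                       cap: float = 1e4, col_mode: str = "independent",
                       initial_log_covers=None) -> bool:
    """Biological-plausibility screen for one group's vital rates.

    Runs a single-group projection for T years from the observed abundance,
    holding the other groups' totals at their observed values, and returns
    True iff the trajectory stays finite, the total cover stays below
    ``cap`` percent, no more than half of the final density has piled up
    against the mesh boundaries, and the density-weighted eviction mass of
    the final kernel stays below 10 percent.  The last two conditions catch
    runaway growth that the bounded mesh would otherwise mask: a growth
    model pushing species past the upper cover bound shows up as density
    stacked at, or constantly leaking through, the boundary.
    """
    mesh = mesh or Mesh(m=50)
    gi = GROUPS.index(group)
    if initial_log_covers is None or len(initial_log_covers) == 0:
        initial_log_covers = [math.log(max(observed_N[gi], 1.0))
                              if observed_N[gi] < 100 else U * 0.9]
    n = state_from_log_covers({group: initial_log_covers}, mesh).densities[
        group].astype(float)
    if n.sum() == 0:
        n[mesh.m // 2] = 1.0 / mesh.h
    N = np.asarray(observed_N, float).copy()
    try:
        for _ in range(T):
            N[gi] = float(mesh.w @ n)
            if not np.isfinite(N[gi]) or N[gi] > cap:
                return False
            kg = build_kernel(params, N, mesh, col_mode=col_mode,
                              warn_eviction=False)
            n = mesh.h * (kg.K @ n)
            if col_mode == "independent":
                n = n + kg.fvec
            if not np.all(np.isfinite(n)):
                return False
    except (KernelError, FloatingPointError):
        return False
    N_final = float(mesh.w @ n)
    if not np.isfinite(N_final) or N_final > cap:
        return False
    tot = n.sum()
    if tot > 0:
        if (n[0] + n[-1]) / tot > 0.5:
            return False
        N[gi] = N_final
        kg = build_kernel(params, N, mesh, col_mode=col_mode,
                          warn_eviction=False)
        # density-weighted mass the growth kernel loses past the bounds
        evicted = float(np.clip(kg.eviction, 0.0, None) @ n) / tot
        if evicted > 0.10:
            return False
    return True
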