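"""Cover-class-structured community matrix for one treatment.

The coupled annual map advances the stacked mesh densities
``v = (n_g, n_l, n_f)`` of the three functional-group IPMs, which interact
only through the total covers ``N_j = w_j^T n_j`` (``w_j[i] = e^{x_i} h``).
The community matrix ``C`` is the Jacobian of that map at a converged
equilibrium: its eigenvalues govern asymptotic perturbation decay (unit
circle criterion) and its nonnormality governs transient amplification.

In group-major block layout, block (k, j) is

    C_kj = delta_kj * h K_k(N*)  +  h [dK_k/dN_j  n_k*] w_j^T

with the kernel sensitivity evaluated analytically through the persistence,
expansion and colonisation coefficients (each feedback correction is an
outer product, so off-diagonal blocks have rank <= 1 per coupling path).
A central finite-difference Jacobian of one simulation step is provided as
an independent oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .ipm import COL_MODES, CommunityState, Mesh, build_kernel, step
from .params import (COLONISATION_TERMS, GROWTH_TERMS, SIGMA_FLOOR,
                     colonisation_design, covariates, dcovariates_dN,
                     growth_design)
from .survey import GROUPS

#: positions of (u_g, u_l, u_f) in the two design-term orders
_U_IDX_GROWTH = [GROWTH_TERMS.index(t) for t in ("ug", "ul", "uf")]
_U_IDX_COL = [COLONISATION_TERMS.index(t) for t in ("ug", "ul", "uf")]


@dataclass
class StructuredCommunityMatrix:
    """3m x 3m community matrix with provenance."""

    C: np.ndarray
    mesh: Mesh
    equilibrium_N: np.ndarray
    col_mode: str
    groups: tuple = GROUPS

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.C))))

    def block(self, k: str, j: str) -> np.ndarray:
        m = self.mesh.m
        a, b = self.groups.index(k), self.groups.index(j)
        return self.C[a * m:(a + 1) * m, b * m:(b + 1) * m]

    def save(self, path_prefix: str) -> None:
        """Dense CSV + MatrixMarket + JSON sidecar with block metadata."""
        from scipy.io import mmwrite
        np.savetxt(f"{path_prefix}.csv", self.C, delimiter=",")
        mmwrite(f"{path_prefix}.mtx", np.asarray(self.C))
        meta = dict(groups=list(self.groups), m=self.mesh.m,
                    L=self.mesh.L, U=self.mesh.U,
                    equilibrium_N=self.equilibrium_N.tolist(),
                    col_mode=self.col_mode,
                    spectral_radius=self.spectral_radius)
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=2)


class NotConvergedError(RuntimeError):
    pass


def _kernel_sensitivity(params, N, n_k, mesh, col_mode):
    """h * (dK/dN_j n_k) for j = g, l, f, returned as an (m, 3) array."""
    u = covariates(N)
    du_dN = dcovariates_dN(N)
    x = mesh.x
    Xg = growth_design(x, *u)
    s = expit(Xg @ params.persistence)
    mu = Xg @ params.expansion_mean
    raw_sd = Xg @ params.expansion_sd
    sd = np.maximum(raw_sd, SIGMA_FLOOR)
    sd_active = (raw_sd > SIGMA_FLOOR).astype(float)
    G = norm.pdf(x[:, None], loc=mu[None, :], scale=sd[None, :])
    r = x[:, None] - mu[None, :]

    mu_f = float((colonisation_design(*u) @ params.colonisation_mean)[0])
    raw_sd_f = float((colonisation_design(*u) @ params.colonisation_sd)[0])
    sd_f = max(raw_sd_f, SIGMA_FLOOR)
    f_active = float(raw_sd_f > SIGMA_FLOOR)
    fvec = params.col_rate * norm.pdf(x, loc=mu_f, scale=sd_f)
    rf = x - mu_f

    total_nk = float(np.sum(n_k))
    out = np.empty((mesh.m, 3))
    for j in range(3):
        b_s = params.persistence[_U_IDX_GROWTH[j]]
        b_mu = params.expansion_mean[_U_IDX_GROWTH[j]]
        b_sd = params.expansion_sd[_U_IDX_GROWTH[j]]
        # dP/du_j = s'(x) G + s dG/du_j, columnwise in x
        ds = s * (1.0 - s) * b_s
        dG = G * (r / sd[None, :] ** 2 * b_mu
                  + (r**2 / sd[None, :] ** 3 - 1.0 / sd[None, :])
                  * (b_sd * sd_active)[None, :])
        dP_n = (ds[None, :] * G + s[None, :] * dG) @ n_k

        b_fmu = params.colonisation_mean[_U_IDX_COL[j]]
        b_fsd = params.colonisation_sd[_U_IDX_COL[j]]
        dfvec = fvec * (rf / sd_f**2 * b_fmu
                        + (rf**2 / sd_f**3 - 1.0 / sd_f) * b_fsd * f_active)
        if col_mode == "density":
            col_term = mesh.h * total_nk * dfvec
        else:
            col_term = dfvec
        out[:, j] = (mesh.h * dP_n + col_term) * du_dN[j]
    return out


def assemble_community_matrix(equilibrium: CommunityState, params_by_group,
                              mesh: Mesh | None = None,
                              col_mode: str = "independent",
                              require_converged: bool = True,
                              converged: bool = True
                              ) -> StructuredCommunityMatrix:
    """Jacobian of the coupled annual map at a converged equilibrium."""
    if col_mode not in COL_MODES:
        raise ValueError(f"col_mode must be one of {COL_MODES}")
    if require_converged and not converged:
        raise NotConvergedError(
            "community matrix requires a converged equilibrium state")
    mesh = mesh or equilibrium.mesh
    m = mesh.m
    N = equilibrium.N
    C = np.zeros((3 * m, 3 * m))
    for a, k in enumerate(GROUPS):
        n_k = equilibrium.densities[k]
        kg = build_kernel(params_by_group[k], N, mesh, col_mode=col_mode,
                          warn_eviction=False)
        sens = _kernel_sensitivity(params_by_group[k], N, n_k, mesh,
                                   col_mode)
        for b in range(3):
            blk = np.outer(sens[:, b], mesh.w)
            if b == a:
                blk = blk + mesh.h * kg.K
            C[a * m:(a + 1) * m, b * m:(b + 1) * m] = blk
    return StructuredCommunityMatrix(C=C, mesh=mesh, equilibrium_N=N,
                                     col_mode=col_mode)


def finite_difference_jacobian(equilibrium: CommunityState, params_by_group,
                               col_mode: str = "independent",
                               rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of one coupled step (the oracle).

    Each mesh coordinate of group j is perturbed by the density increment
    that shifts N_j by ``rel_step * N_j`` (absolute fallback when N_j ~ 0).
    """
    mesh = equilibrium.mesh
    m = mesh.m
    J = np.empty((3 * m, 3 * m))

    def flat(state):
        return np.concatenate([state.densities[g] for g in GROUPS])

    for b, j in enumerate(GROUPS):
        Nj = equilibrium.N[b]
        for i in range(m):
            delta = rel_step * max(Nj, 1.0) / mesh.w[i]
            up, dn = equilibrium.copy(), equilibrium.copy()
            up.densities[j][i] += delta
            dn.densities[j][i] -= delta
            Fp = flat(step(up, params_by_group, col_mode=col_mode))
            Fm = flat(step(dn, params_by_group, col_mode=col_mode))
            J[:, b * m + i] = (Fp - Fm) / (2.0 * delta)
    return J
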