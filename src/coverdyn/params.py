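"""Vital-rate parameter container and the community-analogue rate functions.

One :class:`VitalRateParams` holds every coefficient of the three community
vital-rate models for a single functional group under one treatment:

* persistence ``s(x)``: Bernoulli with logit link, linear predictor over
  ``{1, x, x^2, u_g, u_l, u_f}``;
* expansion ``g(x, y)``: Gaussian in next year's log cover ``y`` with mean
  and standard deviation each linear over the same terms;
* colonisation ``f(y)``: Gaussian in the colonist's log cover with mean and
  standard deviation linear over ``{1, u_g, u_l, u_f}`` (independent of x).

Here ``x`` is a species' log percent cover and ``(u_g, u_l, u_f)`` are the
logged functional-group totals ``log N_g``, ``log(N_l + e^-1)``, ``log N_f``.
Excluded model terms simply carry a zero coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .survey import NL_OFFSET

#: Canonical term order for persistence/expansion designs (intercept first).
GROWTH_TERMS = ("1", "x", "x2", "ug", "ul", "uf")
#: Canonical term order for colonisation designs.
COLONISATION_TERMS = ("1", "ug", "ul", "uf")

#: Selectable (non-intercept) terms per role.
SELECTABLE = {
    "persistence": ("x", "x2", "ug", "ul", "uf"),
    "expansion": ("x", "x2", "ug", "ul", "uf"),
    "colonisation": ("ug", "ul", "uf"),
}

#: Floor applied to every evaluated standard deviation (log-cover scale).
SIGMA_FLOOR = 1e-3

#: Numerical guard for grass/forb totals before logging (percent cover).
#: Set to e^-1 — the magnitude of the legume offset, below the 0.5 percent
#: recording resolution — so a collapsing group cannot drag covariates into
#: log(0)-like extrapolation far outside the fitted range.
N_FLOOR = np.exp(-1.0)


def growth_design(x, ug, ul, uf) -> np.ndarray:
    """Design matrix rows (1, x, x^2, u_g, u_l, u_f); x may be an array."""
    x = np.asarray(x, dtype=float)
    shape = np.broadcast_shapes(x.shape, np.shape(ug))
    one = np.ones(shape)
    return np.stack([one, x * one, x**2 * one, ug * one, ul * one, uf * one],
                    axis=-1)


def colonisation_design(ug, ul, uf, n: int = 1) -> np.ndarray:
    """Design matrix rows (1, u_g, u_l, u_f)."""
    one = np.ones(n)
    return np.stack([one, ug * one, ul * one, uf * one], axis=-1)


def covariates(N: np.ndarray) -> np.ndarray:
    """(u_g, u_l, u_f) from percent totals, with the legume e^-1 offset.

    Grass/forb totals are floored at a tiny positive value purely so the log
    is defined if a simulated group collapses to zero.
    """
    N = np.asarray(N, dtype=float)
    return np.array([
        np.log(max(N[0], N_FLOOR)),
        np.log(N[1] + NL_OFFSET),
        np.log(max(N[2], N_FLOOR)),
    ])


def dcovariates_dN(N: np.ndarray) -> np.ndarray:
    """d(u_g, u_l, u_f)/d(N_g, N_l, N_f) — diagonal, returned as a vector."""
    N = np.asarray(N, dtype=float)
    return np.array([1.0 / max(N[0], N_FLOOR),
                     1.0 / (N[1] + NL_OFFSET),
                     1.0 / max(N[2], N_FLOOR)])


@dataclass
class VitalRateParams:
    """All coefficients for one functional group x treatment.

    Arrays follow :data:`GROWTH_TERMS` / :data:`COLONISATION_TERMS` order.
    ``col_rate`` is the expected number of colonising species per plot-year
    (the count model closing the generative loop; the size distribution above
    is all the selection machinery ever fits).
    """

    persistence: np.ndarray = field(
        default_factory=lambda: np.zeros(len(GROWTH_TERMS)))
    expansion_mean: np.ndarray = field(
        default_factory=lambda: np.zeros(len(GROWTH_TERMS)))
    expansion_sd: np.ndarray = field(
        default_factory=lambda: np.zeros(len(GROWTH_TERMS)))
    colonisation_mean: np.ndarray = field(
        default_factory=lambda: np.zeros(len(COLONISATION_TERMS)))
    colonisation_sd: np.ndarray = field(
        default_factory=lambda: np.zeros(len(COLONISATION_TERMS)))
    col_rate: float = 1.0

    def __post_init__(self):
        self.persistence = np.asarray(self.persistence, dtype=float)
        self.expansion_mean = np.asarray(self.expansion_mean, dtype=float)
        self.expansion_sd = np.asarray(self.expansion_sd, dtype=float)
        self.colonisation_mean = np.asarray(self.colonisation_mean,
                                            dtype=float)
        self.colonisation_sd = np.asarray(self.colonisation_sd, dtype=float)

    # -- evaluated rate functions -------------------------------------------

    def survival(self, x, u):
        """Persistence probability s(x) at covariates u = (ug, ul, uf)."""
        X = growth_design(x, *u)
        return expit(X @ self.persistence)

    def growth_mean(self, x, u):
        return growth_design(x, *u) @ self.expansion_mean

    def growth_sd(self, x, u):
        return np.maximum(growth_design(x, *u) @ self.expansion_sd,
                          SIGMA_FLOOR)

    def colonist_mean(self, u):
        return float((colonisation_design(*u) @ self.colonisation_mean)[0])

    def colonist_sd(self, u):
        raw = (colonisation_design(*u) @ self.colonisation_sd)[0]
        return float(max(raw, SIGMA_FLOOR))

    def with_(self, **kw) -> "VitalRateParams":
        return replace(self, **kw)


def perturb(params: VitalRateParams, rng: np.random.Generator,
            scale: float = 0.05) -> VitalRateParams:
    """Small random perturbation of every coefficient (testing helper)."""
    def p(a):
        return a + scale * rng.standard_normal(a.shape) * (np.abs(a) + 0.1)
    return VitalRateParams(
        persistence=p(params.persistence),
        expansion_mean=p(params.expansion_mean),
        expansion_sd=params.expansion_sd.copy(),
        colonisation_mean=p(params.colonisation_mean),
        colonisation_sd=params.colonisation_sd.copy(),
        col_rate=params.col_rate)
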