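"""Synthetic percent-cover surveys generated from known vital rates.

The generator runs the persistence/expansion/colonisation models forward as a
simulator so that every downstream stage (transition assembly, model fitting,
selection, IPM construction, stability analysis) can be tested by parameter
and structure recovery, without any external data.

The default design mirrors a blocked precipitation experiment: 5 blocks, each
holding one irrigation plot, two control plots (a merged ambient/procedural
pair) and one drought plot — 20 plots — censused annually for 8 years, with
covers recorded to the nearest 0.5 percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import params as P
from .survey import GROUPS, L, TREATMENTS, U, validate_cover_table
from .params import VitalRateParams


@dataclass
class DesignSpec:
    """Survey design: what gets censused, how often, and how it is recorded."""

    n_blocks: int = 5
    treatments: tuple = TREATMENTS
    plots_per_block: dict = field(
        default_factory=lambda: {"irrigation": 1, "control": 2, "drought": 1})
    n_years: int = 8
    start_year: int = 2016
    rounding_step: float = 0.5
    initial_richness: dict = field(
        default_factory=lambda: {"grass": 6, "legume": 3, "forb": 6})
    initial_logcover_mean: dict = field(
        default_factory=lambda: {"grass": 1.6, "legume": 0.8, "forb": 0.9})
    initial_logcover_sd: dict = field(
        default_factory=lambda: {"grass": 0.8, "legume": 0.7, "forb": 0.8})
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if self.rounding_step <= 0:
            raise ValueError("rounding_step must be > 0")


class GenerationError(RuntimeError):
    """A vital-rate parameter became invalid at a realised covariate value."""


GeneratingParams = dict  # (group, treatment) -> VitalRateParams


def default_generating_params() -> GeneratingParams:
    """Self-limiting vital rates with treatment-dependent interactions.

    Each group's persistence and expansion depend on its own log cover x and
    on the logged group totals; self-limitation (the coefficient on the
    group's own total) dominates cross-group competition so the three groups
    coexist at an interior equilibrium of a few tens of percent cover per
    group.  Interactions are uniformly competitive (negative abundance
    coefficients) under irrigation, and under drought the two broad-leaved
    groups facilitate each other while grasses are suppressed — so grasses
    dominate when watered and legumes/forbs dominate when droughted.
    Expansion slopes on x are < 1, making individual covers mean-reverting.
    """
    # term order: (1, x, x^2, u_g, u_l, u_f); self-limitation sits on the
    # group's own u column
    spec = {
        # treatment: (persistence b0 per group, cross-competition,
        #             expansion-mean b0 per group, colonisation rate)
        "control": dict(b0=(4.2, 3.6, 3.9), cross=-0.15,
                        em0=(1.10, 0.80, 0.95), rate=(0.6, 0.4, 0.8)),
        "irrigation": dict(b0=(4.8, 3.5, 3.8), cross=-0.20,
                           em0=(1.35, 0.75, 0.90), rate=(0.7, 0.3, 0.6)),
        "drought": dict(b0=(3.2, 3.9, 4.2), cross=-0.15,
                        em0=(0.75, 1.10, 0.95), rate=(0.35, 0.7, 0.8)),
    }
    self_pers, self_em = -0.8, -0.12
    cross_em = {"control": -0.03, "irrigation": -0.04, "drought": -0.03}
    out: GeneratingParams = {}
    for treatment, cfg in spec.items():
        for gi, g in enumerate(GROUPS):
            pers = [cfg["b0"][gi], 0.3, 0.0,
                    cfg["cross"], cfg["cross"], cfg["cross"]]
            pers[3 + gi] = self_pers
            em = [cfg["em0"][gi], 0.67, 0.0,
                  cross_em[treatment], cross_em[treatment],
                  cross_em[treatment]]
            em[3 + gi] = self_em
            if treatment == "drought" and g != "grass":
                # facilitation between the broad-leaved groups under stress
                other = 5 if g == "legume" else 4      # uf helps legumes,
                pers[other] = 0.20                     # ul helps forbs
                em[other] = 0.05
            out[(g, treatment)] = VitalRateParams(
                persistence=pers,
                expansion_mean=em,
                expansion_sd=[0.50, 0.04, 0.0, 0.0, 0.0, 0.0],
                colonisation_mean=[0.60, 0.0, 0.0, 0.0],
                colonisation_sd=[0.60, 0.0, 0.0, 0.0],
                col_rate=cfg["rate"][gi])
    return out


def _plot_rng(seed: int, plot_index: int) -> np.random.Generator:
    # counter-based stream per plot: extending the design never disturbs
    # the realisation of existing plots
    key = np.array([seed & 0xFFFFFFFFFFFFFFFF, plot_index], dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


def _draw_truncnorm(rng, mu, sd, size=None):
    a, b = (L - mu) / sd, (U - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _round_cover(y_log: np.ndarray, step: float) -> np.ndarray:
    cover = np.round(np.exp(y_log) / step) * step
    return np.maximum(cover, step)


def generate_survey(design: DesignSpec,
                    params: GeneratingParams) -> pd.DataFrame:
    """Simulate a full survey table from known vital-rate parameters.

    Each plot runs an independent counter-based random stream.  Year to year,
    every species persists with probability s_k(x); survivors redraw log
    cover from the expansion Gaussian truncated to [0, log 100]; each group
    gains Poisson(col_rate) colonists whose log covers come from the
    colonisation Gaussian.  Covers are rounded to ``rounding_step`` and
    floored at one step (the recording resolution).
    """
    rows = []
    plot_index = 0
    blocks = [chr(ord("A") + i) for i in range(design.n_blocks)]
    for block in blocks:
        for treatment in design.treatments:
            for rep in range(design.plots_per_block.get(treatment, 1)):
                plot = f"{block}{treatment[:2].upper()}{rep + 1}"
                rng = _plot_rng(design.seed, plot_index)
                plot_index += 1
                rows.extend(_simulate_plot(design, params, block, treatment,
                                           plot, rng))
    df = pd.DataFrame(rows, columns=["year", "block", "plot", "treatment",
                                     "species", "functional_group",
                                     "percent_cover"])
    if df.empty:
        return df
    return validate_cover_table(df)


def _simulate_plot(design, params, block, treatment, plot, rng):
    step = design.rounding_step
    counters = {g: 0 for g in GROUPS}
    state = {}  # species -> (group, cover)

    def new_species(group):
        counters[group] += 1
        return f"{group[0]}{counters[group]:03d}"

    # initial community
    for group in GROUPS:
        r = design.initial_richness[group]
        mu0 = design.initial_logcover_mean[group]
        sd0 = design.initial_logcover_sd[group]
        y = np.atleast_1d(_draw_truncnorm(rng, mu0, sd0, size=r))
        for cov in _round_cover(y, step):
            state[new_species(group)] = (group, cov)

    rows = []
    for t in range(design.n_years):
        year = design.start_year + t
        for sp, (group, cov) in state.items():
            rows.append(dict(year=year, block=block, plot=plot,
                             treatment=treatment, species=sp,
                             functional_group=group, percent_cover=cov))
        if t == design.n_years - 1:
            break
        N = np.zeros(3)
        for sp, (group, cov) in state.items():
            N[GROUPS.index(group)] += cov
        u = P.covariates(N)
        nxt = {}
        for sp, (group, cov) in state.items():
            p = params[(group, treatment)]
            x = min(max(math.log(cov), L), U)
            if rng.random() < float(p.survival(x, u)):
                sd = float(p.growth_sd(x, u))
                raw_sd = float(P.growth_design(x, *u) @ p.expansion_sd)
                if raw_sd <= 0:
                    raise GenerationError(
                        f"expansion SD <= 0 for {group}/{treatment} at "
                        f"x={x:.3f}")
                y = float(_draw_truncnorm(rng, float(p.growth_mean(x, u)),
                                          sd))
                nxt[sp] = (group, float(_round_cover(np.array([y]), step)[0]))
        for group in GROUPS:
            p = params[(group, treatment)]
            n_col = rng.poisson(p.col_rate)
            if n_col == 0:
                continue
            mu_f, sd_f = p.colonist_mean(u), p.colonist_sd(u)
            raw_sd = float((P.colonisation_design(*u) @ p.colonisation_sd)[0])
            if raw_sd <= 0:
                raise GenerationError(
                    f"colonisation SD <= 0 for {group}/{treatment}")
            y = np.atleast_1d(_draw_truncnorm(rng, mu_f, sd_f, size=n_col))
            for cov in _round_cover(y, step):
                nxt[new_species(group)] = (group, float(cov))
        state = nxt
    return rows


# ---------------------------------------------------------------------------
# Worked fixture: two plots, four years, hand-checkable transitions.
# ---------------------------------------------------------------------------

_FIXTURE_ROWS = [
    # year, block, plot, treatment, species, group, cover
    # Plot P1 (control): persistence/expansion, one extinction with
    # recolonisation (g002), one extinction (l001), one colonisation (f002),
    # and a legume-free year (2018) exercising the e^-1 offset.
    (2016, "A", "P1", "control", "g001", "grass", 10.0),
    (2016, "A", "P1", "control", "g002", "grass", 5.0),
    (2016, "A", "P1", "control", "l001", "legume", 2.0),
    (2016, "A", "P1", "control", "f001", "forb", 4.0),
    (2017, "A", "P1", "control", "g001", "grass", 15.0),
    (2017, "A", "P1", "control", "l001", "legume", 1.5),
    (2017, "A", "P1", "control", "f001", "forb", 6.0),
    (2017, "A", "P1", "control", "f002", "forb", 1.0),
    (2018, "A", "P1", "control", "g001", "grass", 15.0),
    (2018, "A", "P1", "control", "g002", "grass", 2.0),
    (2018, "A", "P1", "control", "f001", "forb", 8.0),
    (2018, "A", "P1", "control", "f002", "forb", 1.5),
    (2019, "A", "P1", "control", "g001", "grass", 20.0),
    (2019, "A", "P1", "control", "g002", "grass", 2.5),
    (2019, "A", "P1", "control", "f001", "forb", 8.0),
    (2019, "A", "P1", "control", "f002", "forb", 2.0),
    # Plot P2 (drought): grass contraction, legume expansion, a sub-1%
    # colonist (f003, clamped to the mesh floor), a one-year legume (l003).
    (2016, "A", "P2", "drought", "g003", "grass", 20.0),
    (2016, "A", "P2", "drought", "l002", "legume", 1.0),
    (2016, "A", "P2", "drought", "f004", "forb", 2.0),
    (2017, "A", "P2", "drought", "g003", "grass", 10.0),
    (2017, "A", "P2", "drought", "l002", "legume", 2.0),
    (2017, "A", "P2", "drought", "l003", "legume", 0.5),
    (2017, "A", "P2", "drought", "f004", "forb", 2.0),
    (2018, "A", "P2", "drought", "g003", "grass", 5.0),
    (2018, "A", "P2", "drought", "l002", "legume", 4.0),
    (2018, "A", "P2", "drought", "f003", "forb", 0.5),
    (2018, "A", "P2", "drought", "f004", "forb", 2.5),
    (2019, "A", "P2", "drought", "g003", "grass", 2.5),
    (2019, "A", "P2", "drought", "l002", "legume", 8.0),
    (2019, "A", "P2", "drought", "f003", "forb", 1.0),
    (2019, "A", "P2", "drought", "f004", "forb", 3.0),
]

#: Hand-enumerated expectations for the worked fixture:
#: (group, treatment) -> dict(n_persistence, n_persisted, n_expansion,
#:                            n_colonisation)
WORKED_FIXTURE_EXPECTED = {
    ("grass", "control"): dict(n_persistence=5, n_persisted=4,
                               n_expansion=4, n_colonisation=1),
    ("legume", "control"): dict(n_persistence=2, n_persisted=1,
                                n_expansion=1, n_colonisation=0),
    ("forb", "control"): dict(n_persistence=5, n_persisted=5,
                              n_expansion=5, n_colonisation=1),
    ("grass", "drought"): dict(n_persistence=3, n_persisted=3,
                               n_expansion=3, n_colonisation=0),
    ("legume", "drought"): dict(n_persistence=4, n_persisted=3,
                                n_expansion=3, n_colonisation=1),
    ("forb", "drought"): dict(n_persistence=4, n_persisted=4,
                              n_expansion=4, n_colonisation=1),
}

#: Hand-summed year-2016 functional-group totals per plot.
WORKED_FIXTURE_TOTALS_2016 = {
    "P1": dict(N_g=15.0, N_l=2.0, N_f=4.0),
    "P2": dict(N_g=20.0, N_l=1.0, N_f=2.0),
}


def generate_worked_fixture():
    """A small deterministic survey with hand-enumerated transitions.

    Returns ``(records, params)`` where ``params`` are the default control /
    drought generating parameters (the fixture itself is hand-written, not
    simulated, so its transition counts can be checked by eye).
    """
    df = pd.DataFrame(_FIXTURE_ROWS, columns=["year", "block", "plot",
                                              "treatment", "species",
                                              "functional_group",
                                              "percent_cover"])
    return validate_cover_table(df), default_generating_params()
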