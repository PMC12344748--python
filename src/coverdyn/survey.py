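"""Percent-cover survey tables and the regression-ready transition dataset.

The raw survey atom is one species x plot x year percent-cover observation.
Absence is encoded by the *absence* of a row: a species that was not seen in a
quadrat simply has no record, so an explicit zero cover is a recording error
and is rejected.  Covers live on (0, 100] percent; all model work happens on
the natural-log scale, bounded by ``L = log 1 = 0`` and ``U = log 100``.

Because legume totals can be exactly zero in a plot-year, the legume covariate
is ``log(N_l + e^-1)`` (offset ~0.37 percent); grass and forb totals enter as
plain ``log N``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("grass", "legume", "forb")
TREATMENTS = ("irrigation", "control", "drought")

#: Lower and upper bounds of the log-cover axis: log 1 = 0 and log 100.
L = 0.0
U = math.log(100.0)

#: Offset added to legume totals before logging, in percent cover.
NL_OFFSET = math.exp(-1.0)

#: Canonical survey-table columns.
COLUMNS = ("year", "block", "plot", "treatment", "species",
           "functional_group", "percent_cover")

#: Header aliases accepted by :func:`read_cover_table` without a dialect.
_DEFAULT_ALIASES = {
    "year": "year", "block": "block", "plot": "plot",
    "treatment": "treatment", "species": "species",
    "functional_group": "functional_group", "group": "functional_group",
    "percent_cover": "percent_cover", "cover": "percent_cover",
}

#: Treatment labels collapsed onto "control" when merging controls.
_CONTROL_LABELS = {"control", "ambient_control", "procedural_control",
                   "ambient control", "procedural control"}


class SchemaError(ValueError):
    """A required survey column is missing."""


class ValidationError(ValueError):
    """A survey row violates the cover-record invariants."""


def read_cover_table(path, dialect: dict | None = None,
                     merge_controls: bool = True) -> pd.DataFrame:
    """Read a long-format cover table into a validated DataFrame.

    Parameters
    ----------
    path : str or file-like
        CSV with (aliases of) the canonical columns.
    dialect : dict, optional
        Extra ``{file_header: canonical_name}`` mappings.
    merge_controls : bool
        Collapse procedural/ambient control labels to ``"control"``
        (the default, matching the experimental design's pre-analysis merge).
    """
    raw = pd.read_csv(path)
    aliases = dict(_DEFAULT_ALIASES)
    if dialect:
        aliases.update(dialect)
    rename = {c: aliases[c.strip().lower()]
              for c in raw.columns if c.strip().lower() in aliases}
    df = raw.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(COLUMNS)].copy()
    if merge_controls:
        df["treatment"] = df["treatment"].map(
            lambda t: "control" if str(t).strip().lower() in _CONTROL_LABELS
            else t)
    return validate_cover_table(df)


def validate_cover_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate cover-record invariants; return a normalised copy."""
    df = df.copy()
    df["year"] = df["year"].astype(int)
    df["percent_cover"] = df["percent_cover"].astype(float)
    bad = df.index[~(df["percent_cover"] > 0)]
    if len(bad):
        raise ValidationError(
            f"cover must be > 0 (absence is encoded by omitting the row); "
            f"offending row index {bad[0]}")
    bad = df.index[df["percent_cover"] > 100]
    if len(bad):
        raise ValidationError(
            f"cover must be <= 100; offending row index {bad[0]}")
    bad = df.index[~df["functional_group"].isin(GROUPS)]
    if len(bad):
        raise ValidationError(
            f"unknown functional group {df.loc[bad[0], 'functional_group']!r} "
            f"at row index {bad[0]}; expected one of {GROUPS}")
    bad = df.index[~df["treatment"].isin(TREATMENTS)]
    if len(bad):
        raise ValidationError(
            f"unknown treatment {df.loc[bad[0], 'treatment']!r} at row index "
            f"{bad[0]}; expected one of {TREATMENTS}")
    dup = df.duplicated(subset=["year", "block", "plot", "species"])
    if dup.any():
        raise ValidationError(
            f"duplicate species record at row index {df.index[dup][0]}")
    return df.reset_index(drop=True)


def write_cover_table(df: pd.DataFrame, path) -> None:
    """Write a validated cover table back to CSV (canonical columns)."""
    df.loc[:, list(COLUMNS)].to_csv(path, index=False)


def aggregate_group_abundance(records: pd.DataFrame) -> pd.DataFrame:
    """Sum species covers into per-group totals N_g, N_l, N_f per plot-year.

    Groups with no species present get 0.  Totals may legitimately exceed
    100 percent because covers of overlapping canopies are summed.
    """
    keys = ["year", "block", "plot", "treatment"]
    pivot = (records.pivot_table(index=keys, columns="functional_group",
                                 values="percent_cover", aggfunc="sum",
                                 fill_value=0.0)
             .reindex(columns=list(GROUPS), fill_value=0.0)
             .reset_index())
    pivot.columns.name = None
    return pivot.rename(columns={"grass": "N_g", "legume": "N_l",
                                 "forb": "N_f"})


def covariates_from_totals(N_g: float, N_l: float, N_f: float):
    """Logged abundance covariates (u_g, u_l, u_f) from percent totals."""
    return (math.log(N_g), math.log(N_l + NL_OFFSET), math.log(N_f))


@dataclass
class TransitionDataset:
    """Regression-ready view of one functional group x treatment.

    ``persistence`` has columns (x, persisted, ug, ul, uf, ...);
    ``expansion``   has (x, y, ug, ul, uf, ...), only persisted species;
    ``colonisation`` has (y, ug, ul, uf, ...), species newly appearing at
    t+1 with covariates taken at t.  x, y are clamped to [0, log 100].
    """

    group: str
    treatment: str
    persistence: pd.DataFrame
    expansion: pd.DataFrame
    colonisation: pd.DataFrame
    n_clamped: int = 0
    n_dropped_zero_total: int = 0
    notes: list = field(default_factory=list)

    def to_csv(self, prefix) -> None:
        self.persistence.to_csv(f"{prefix}_persistence.csv", index=False)
        self.expansion.to_csv(f"{prefix}_expansion.csv", index=False)
        self.colonisation.to_csv(f"{prefix}_colonisation.csv", index=False)


def _clamp_log_cover(cover: float, counter: list) -> float:
    x = math.log(cover)
    if x < L:
        counter[0] += 1
        return L
    return min(x, U)


def build_transition_dataset(records: pd.DataFrame, group: str,
                             treatment: str) -> TransitionDataset:
    """Assemble persistence/expansion/colonisation rows for one group.

    Pairs are formed only for consecutive calendar years within a plot (the
    model time step is annual); covariates (u_g, u_l, u_f) are the logged
    group totals at time t of each pair.  A species present at t and absent
    at t+1 yields a persistence row with persisted=0 and no expansion row;
    a species absent at t and present at t+1 yields only a colonisation row
    (a reappearance after a gap counts as a fresh colonisation).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    totals = aggregate_group_abundance(records)
    sub = records[records["treatment"] == treatment]
    clamped = [0]
    dropped = 0
    pers_rows, exp_rows, col_rows = [], [], []
    for (block, plot), plot_df in sub.groupby(["block", "plot"], sort=True):
        years = sorted(plot_df["year"].unique())
        grp_of = dict(zip(plot_df["species"], plot_df["functional_group"]))
        by_year = {
            y: dict(zip(g["species"], g["percent_cover"]))
            for y, g in plot_df.groupby("year")
        }
        tot = totals[(totals["block"] == block) & (totals["plot"] == plot)]
        tot = tot.set_index("year")
        for t in years:
            if t + 1 not in by_year:
                continue  # gapped or final census: no annual pair
            N_g, N_l, N_f = (tot.loc[t, "N_g"], tot.loc[t, "N_l"],
                             tot.loc[t, "N_f"])
            if N_g <= 0 or N_f <= 0:
                dropped += 1
                continue
            ug, ul, uf = covariates_from_totals(N_g, N_l, N_f)
            grp_now = {s: c for s, c in by_year[t].items()
                       if grp_of[s] == group}
            grp_next = {s: c for s, c in by_year[t + 1].items()
                        if grp_of[s] == group}
            common = dict(year=t, block=block, plot=plot,
                          ug=ug, ul=ul, uf=uf)
            for s, c in grp_now.items():
                x = _clamp_log_cover(c, clamped)
                persisted = int(s in grp_next)
                pers_rows.append(dict(common, species=s, x=x,
                                      persisted=persisted))
                if persisted:
                    y = _clamp_log_cover(grp_next[s], clamped)
                    exp_rows.append(dict(common, species=s, x=x, y=y))
            for s, c in grp_next.items():
                if s not in grp_now:
                    y = _clamp_log_cover(c, clamped)
                    col_rows.append(dict(common, species=s, y=y))
    if not pers_rows and not col_rows:
        logger.warning("no adjacent-year pairs for %s/%s: empty dataset",
                       group, treatment)
    ds = TransitionDataset(
        group=group, treatment=treatment,
        persistence=pd.DataFrame(
            pers_rows, columns=["year", "block", "plot", "species", "x",
                                "persisted", "ug", "ul", "uf"]),
        expansion=pd.DataFrame(
            exp_rows, columns=["year", "block", "plot", "species", "x", "y",
                               "ug", "ul", "uf"]),
        colonisation=pd.DataFrame(
            col_rows, columns=["year", "block", "plot", "species", "y",
                               "ug", "ul", "uf"]),
        n_clamped=clamped[0], n_dropped_zero_total=dropped)
    if clamped[0]:
        ds.notes.append(f"{clamped[0]} log-cover value(s) below 0 clamped to "
                        f"the mesh floor L=0")
    if dropped:
        ds.notes.append(f"{dropped} plot-year pair(s) dropped because a "
                        f"grass/forb total was 0 (log undefined)")
    return ds


def initial_log_covers(records: pd.DataFrame, group: str, treatment: str,
                       year: int | None = None) -> np.ndarray:
    """Observed species log covers for one group x treatment in one year.

    Defaults to the first census year; used to build IPM initial densities.
    """
    sub = records[(records["treatment"] == treatment)
                  & (records["functional_group"] == group)]
    if sub.empty:
        return np.array([])
    if year is None:
        year = int(sub["year"].min())
    covers = sub.loc[sub["year"] == year, "percent_cover"].to_numpy(float)
    return np.clip(np.log(covers), L, U)
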