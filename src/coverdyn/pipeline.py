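"""End-to-end orchestration: survey -> vital rates -> IPMs -> stability.

Each stage is a plain function over in-memory objects so tests, the numbered
analysis drivers and the CLI all share one code path.  ``run_pipeline``
composes the stages and writes every artefact (selected-model tables, the
equilibrium trajectories, the community matrices and their pseudospectral
results, plus a manifest) to an output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community_matrix import assemble_community_matrix
from .ipm import Mesh, Trajectory, check_plausibility, simulate, \
    state_from_log_covers
from .pseudospectra import DEFAULT_EPS, analyze
from .survey import (GROUPS, TREATMENTS, aggregate_group_abundance,
                     build_transition_dataset, initial_log_covers,
                     read_cover_table)
from .synth import DesignSpec, default_generating_params, generate_survey
from .vitalrates import (CandidateModel, SelectionError,
                         colonisation_fallback, fit_all_candidates,
                         params_from_frame, params_from_models,
                         params_to_frame, select_model)

logger = logging.getLogger(__name__)

ROLES = ("persistence", "expansion", "colonisation")


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    input_csv: str | None = None          # survey table; None -> synthetic
    params_csv: str | None = None         # skip fitting, start at the IPMs
    treatments: tuple = TREATMENTS
    groups: tuple = GROUPS
    mesh_m: int = 100
    T: int = 300
    eps_grid: tuple = tuple(DEFAULT_EPS)
    n_angles: int = 180
    seed: int = 0
    col_mode: str = "independent"
    plausibility_cap: float = 1e4
    outdir: str = "results/run"
    design: dict = field(default_factory=dict)   # DesignSpec overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh)

    def hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def stage_synth(config: RunConfig) -> pd.DataFrame:
    """Generate (or load) the survey table."""
    if config.input_csv:
        return read_cover_table(config.input_csv)
    design = DesignSpec(seed=config.seed, **config.design)
    return generate_survey(design, default_generating_params())


def observed_initial_totals(records: pd.DataFrame,
                            treatment: str) -> np.ndarray:
    """Mean first-year (N_g, N_l, N_f) across the treatment's plots."""
    totals = aggregate_group_abundance(records)
    sub = totals[totals["treatment"] == treatment]
    y0 = int(sub["year"].min())
    sub = sub[sub["year"] == y0]
    return sub[["N_g", "N_l", "N_f"]].mean().to_numpy(float)


def _pair_counts(records: pd.DataFrame, treatment: str) -> int:
    """Number of consecutive-calendar-year plot pairs under a treatment."""
    sub = records[records["treatment"] == treatment]
    n = 0
    for _, g in sub.groupby(["block", "plot"]):
        years = sorted(g["year"].unique())
        n += sum(1 for t in years if t + 1 in years)
    return n


@dataclass
class FitResult:
    """Per group x treatment: every candidate fit plus the selection."""

    selected: dict                      # (group, treatment, role) -> model
    candidates: dict                    # (group, treatment, role) -> list
    params_by_gt: dict                  # (group, treatment) -> params
    warnings: list = field(default_factory=list)

    def selection_table(self) -> pd.DataFrame:
        rows = []
        for (g, tr, role), m in sorted(self.selected.items()):
            rows.append(dict(group=g, treatment=tr, role=role,
                             terms="+".join(m.terms) or "(intercept)",
                             k=m.k, n=m.n, loglik=m.loglik, aicc=m.aicc))
        return pd.DataFrame(rows)


def stage_fit(records: pd.DataFrame, config: RunConfig) -> FitResult:
    """Fit and select vital-rate models for every group x treatment.

    The plausibility oracle combines each candidate with the current best
    models of the other two roles and runs the single-group screen from the
    treatment's observed initial abundances.
    """
    mesh = Mesh(m=min(config.mesh_m, 50))
    selected, candidates = {}, {}
    params_by_gt = {}
    warns = []
    for tr in config.treatments:
        N0 = observed_initial_totals(records, tr)
        n_pairs = _pair_counts(records, tr)
        for g in config.groups:
            ds = build_transition_dataset(records, g, tr)
            warns.extend(f"{g}/{tr}: {n}" for n in ds.notes)
            cands = {role: fit_all_candidates(ds, role)
                     for role in ("persistence", "expansion")}
            if len(ds.colonisation):
                cands["colonisation"] = fit_all_candidates(ds,
                                                           "colonisation")
            else:
                cands["colonisation"] = []
            provisional, forced = {}, set()
            for role in ROLES:
                usable = [c for c in cands[role] if c.usable]
                if usable:
                    provisional[role] = min(usable, key=lambda c: c.aicc)
                elif role == "colonisation":
                    provisional[role] = colonisation_fallback(ds)
                    forced.add(role)
                    warns.append(f"{g}/{tr}: colonisation fallback "
                                 f"(n={len(ds.colonisation)})")
                else:
                    raise RuntimeError(
                        f"no usable {role} candidate for {g}/{tr}")
            # colonisation rate: events per plot-year pair (the inflow unit
            # of the independent placement); per resident species-year when
            # colonists are placed inside the integral
            if config.col_mode == "density":
                col_rate = len(ds.colonisation) / max(len(ds.persistence), 1)
            else:
                col_rate = len(ds.colonisation) / max(n_pairs, 1)
            init_lc = ds.persistence["x"].to_numpy(float) if len(
                ds.persistence) else None

            def oracle_for(role):
                def oracle(cand: CandidateModel) -> bool:
                    trio = dict(provisional)
                    trio[role] = cand
                    p = params_from_models(trio["persistence"],
                                           trio["expansion"],
                                           trio["colonisation"],
                                           col_rate=col_rate)
                    return check_plausibility(
                        p, g, N0, mesh=mesh, T=config.T,
                        cap=config.plausibility_cap,
                        col_mode=config.col_mode,
                        initial_log_covers=init_lc)
                return oracle

            # Greedy selection, expansion first: an implausible (runaway)
            # expansion or colonisation choice can poison the screen for
            # every candidate of another role, so roles whose selection
            # fails outright are retried once the rest are pinned down.
            pending = []
            for role in ("expansion", "colonisation", "persistence"):
                if role in forced:
                    continue
                try:
                    sel = select_model(cands[role], oracle_for(role))
                except SelectionError:
                    pending.append(role)
                    sel = provisional[role]
                provisional[role] = sel
            for role in pending:
                provisional[role] = select_model(cands[role],
                                                 oracle_for(role))
            for role in ROLES:
                selected[(g, tr, role)] = provisional[role]
                candidates[(g, tr, role)] = cands[role]
            params_by_gt[(g, tr)] = params_from_models(
                provisional["persistence"], provisional["expansion"],
                provisional["colonisation"], col_rate=col_rate)
            logger.info("fit %s/%s: %d/%d/%d rows, selected terms %s",
                        g, tr, len(ds.persistence), len(ds.expansion),
                        len(ds.colonisation),
                        {r: selected[(g, tr, r)].terms for r in ROLES})
    return FitResult(selected=selected, candidates=candidates,
                     params_by_gt=params_by_gt, warnings=warns)


def stage_simulate(records: pd.DataFrame | None, params_by_gt: dict,
                   config: RunConfig) -> dict:
    """Run the coupled three-group IPM per treatment from observed year-1."""
    mesh = Mesh(m=config.mesh_m)
    out = {}
    for tr in config.treatments:
        if records is not None:
            sub = records[records["treatment"] == tr]
            n_plots = sub.groupby(["block", "plot"]).ngroups or 1
            lc = {g: initial_log_covers(records, g, tr) for g in GROUPS}
        else:
            n_plots = 1
            lc = {g: [1.0, 1.5] for g in GROUPS}  # nominal starting covers
        init = state_from_log_covers(lc, mesh, n_plots=n_plots)
        params = {g: params_by_gt[(g, tr)] for g in GROUPS}
        traj = simulate(init, params, T=config.T, col_mode=config.col_mode)
        # a slow-converging realisation gets extra years rather than a
        # weakened equilibrium criterion (capped at 10x the nominal run);
        # short explicit runs (T below the convergence window) are left alone
        extensions = 0
        while (not traj.converged and config.T >= 50 and extensions < 9):
            more = simulate(traj.final, params, T=config.T,
                            col_mode=config.col_mode)
            traj = Trajectory(
                years=np.arange(len(traj.years) + len(more.years) - 1),
                N=np.vstack([traj.N, more.N[1:]]),
                final=more.final, converged=more.converged,
                convergence_step=more.convergence_step)
            extensions += 1
        if extensions:
            logger.info("simulate %s: extended %d x %d years to reach "
                        "equilibrium", tr, extensions, config.T)
        out[tr] = traj
        logger.info("simulate %s: converged=%s final N=%s", tr,
                    traj.converged, np.round(traj.N[-1], 3))
    return out


def stage_stability(trajectories: dict, params_by_gt: dict,
                    config: RunConfig) -> dict:
    """Community matrix + pseudospectral classification per treatment."""
    mesh = Mesh(m=config.mesh_m)
    out = {}
    for tr, traj in trajectories.items():
        params = {g: params_by_gt[(g, tr)] for g in GROUPS}
        scm = assemble_community_matrix(traj.final, params, mesh,
                                        col_mode=config.col_mode,
                                        converged=traj.converged)
        res = analyze(scm.C, eps_list=np.asarray(config.eps_grid),
                      n_angles=config.n_angles)
        out[tr] = (scm, res)
        logger.info("stability %s: rho=%.6f supT=%.3f %s", tr,
                    res.spectral_radius, res.sup_T, res.classification)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Compose all stages and write artefacts + manifest to ``outdir``."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = dict(config_hash=config.hash(), seed=config.seed,
                    version=__version__, stages={}, warnings=[])
    try:
        records = stage_synth(config)
        records.to_csv(outdir / "survey.csv", index=False)
        manifest["stages"]["synth"] = dict(rows=len(records))

        if config.params_csv:
            params_by_gt = params_from_frame(pd.read_csv(config.params_csv))
            manifest["stages"]["fit"] = dict(skipped=True,
                                             source=config.params_csv)
        else:
            fit = stage_fit(records, config)
            fit.selection_table().to_csv(outdir / "selected_models.csv",
                                         index=False)
            params_to_frame(fit.params_by_gt).to_csv(
                outdir / "vital_rate_params.csv", index=False)
            params_by_gt = fit.params_by_gt
            manifest["warnings"].extend(fit.warnings)
            manifest["stages"]["fit"] = dict(
                n_models={f"{g}/{t}/{r}": len(c) for (g, t, r), c in
                          fit.candidates.items()})

        trajectories = stage_simulate(records, params_by_gt, config)
        pd.concat([t.to_frame().assign(treatment=tr)
                   for tr, t in trajectories.items()]).to_csv(
            outdir / "trajectories.csv", index=False)
        manifest["stages"]["simulate"] = {
            tr: dict(converged=bool(t.converged),
                     final_N=t.N[-1].tolist())
            for tr, t in trajectories.items()}

        stability = stage_stability(trajectories, params_by_gt, config)
        for tr, (scm, res) in stability.items():
            scm.save(str(outdir / f"community_matrix_{tr}"))
            res.to_json(outdir / f"pseudospectrum_{tr}.json")
        manifest["stages"]["stability"] = {
            tr: dict(spectral_radius=res.spectral_radius, sup_T=res.sup_T,
                     classification=res.classification)
            for tr, (_, res) in stability.items()}
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["elapsed_s"] = round(time.time() - t0, 2)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=2)
        raise
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2)
    return dict(records=records, params_by_gt=params_by_gt,
                trajectories=trajectories, stability=stability,
                manifest=manifest)
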