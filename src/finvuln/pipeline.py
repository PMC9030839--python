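"""End-to-end orchestration: simulate/load -> margins -> copula -> score ->
summaries -> determinants -> decomposition, with a reproducibility manifest.

Strata are processed independently throughout; all randomness flows from a
single root seed expanded per stage, and every stage seed is recorded in the
manifest together with input hashes and stage order.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, DETERMINANTS
from .copula import fit_copula_mle, pseudo_observations, select_copula
from .decompose import contribution_table
from .marginals import fit_fgls
from .panel import chow_test, f_test_individual_effects, fit_panel, hausman_test
from .panel_io import clean_panel, read_panel, validate_panel
from .vulnerability import distress_probability, group_summary


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes()
    ).hexdigest()[:16]


def _stage_seeds(root_seed: int, stages) -> dict:
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(len(stages))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(stages, children)}


def run_pipeline(config: RunConfig, panel: pd.DataFrame | None = None,
                 specs: dict | None = None, outdir=None,
                 copula_family: str | None = None) -> dict:
    """Run every stage and return a dict of outputs plus the manifest.

    Either ``panel`` (a validated panel frame) or ``specs`` (a mapping
    stratum -> :class:`~finvuln.simulate.SyntheticSpec`) must be given.
    With ``copula_family`` set the family is fixed; otherwise it is selected
    by goodness of fit among ``config.copula_candidates``.
    """
    stages = ["simulate", "clean", "marginals", "copula", "score",
              "summaries", "determinants", "decomposition"]
    seeds = _stage_seeds(config.seed, stages)
    manifest = {"version": __version__, "config": config.to_dict(),
                "root_seed": config.seed, "stage_seeds": seeds, "stages": []}
    out: dict = {"manifest": manifest}

    def log(stage, **info):
        manifest["stages"].append({"stage": stage, **info})

    try:
        if panel is None:
            if not specs:
                raise ValueError("either a panel or synthetic specs required")
            from dataclasses import replace
            from .simulate import generate_panel

            frames, truths = [], {}
            for k, (stratum, spec) in enumerate(sorted(specs.items())):
                spec = replace(spec, seed=(seeds["simulate"] + k) % (2**31))
                frame, truth = generate_panel(spec)
                frames.append(frame)
                truth["delta_true"] = truth["delta_true"].tolist()
                truths[stratum] = truth
            panel = pd.concat(frames, ignore_index=True)
            out["truth"] = truths
            log("simulate", n_rows=len(panel))
        else:
            log("simulate", skipped=True)
        manifest["input_hash"] = _hash_frame(panel)
        strata = [s for s in config.strata
                  if (panel["stratum"] == s).any()]
        if not strata:
            raise ValueError("panel contains none of the configured strata")

        panel, clean_log = clean_panel(panel, config.clean_policy, config.me_offset)
        validate_panel(panel, strict=False)
        out["panel"] = panel
        log("clean", n_rows=len(panel), n_modified=clean_log.n_modified)

        # marginal models per (stratum, wave)
        margins: dict = {}
        for stratum in strata:
            for wave in config.waves:
                cell = panel[(panel["stratum"] == stratum) & (panel["wave"] == wave)]
                if len(cell) == 0:
                    continue
                margins[(stratum, wave)] = {
                    "income": fit_fgls(cell, "income", config.covariates_income,
                                       config.variance_floor),
                    "medical": fit_fgls(cell, "medical", config.covariates_medical,
                                        config.variance_floor),
                }
        out["margins"] = margins
        log("marginals", cells=[f"{s}:{w}" for s, w in margins])

        # copula per stratum (pooled across waves)
        copulas: dict = {}
        for stratum in strata:
            pieces = []
            for wave in config.waves:
                if (stratum, wave) not in margins:
                    continue
                cell = panel[(panel["stratum"] == stratum) & (panel["wave"] == wave)]
                m = margins[(stratum, wave)]
                pieces.append(pseudo_observations(m["income"], m["medical"], cell))
            pairs = np.vstack(pieces)
            if copula_family is not None:
                copulas[stratum] = fit_copula_mle(copula_family, pairs)
            else:
                copulas[stratum] = select_copula(
                    config.copula_candidates, pairs,
                    n_boot=config.gof_bootstrap_reps, seed=seeds["copula"])
        out["copulas"] = copulas
        log("copula", families={s: c.family for s, c in copulas.items()},
            gammas={s: c.gamma for s, c in copulas.items()})

        # score every household-wave cell with its own margins
        scored = []
        for (stratum, wave), m in margins.items():
            cell = panel[(panel["stratum"] == stratum) & (panel["wave"] == wave)]
            scored.append(distress_probability(
                m["income"], m["medical"], copulas[stratum], cell,
                config.blc_per_capita))
        delta = pd.concat(scored, ignore_index=True)
        out["delta"] = delta
        log("score", n_rows=len(delta), mean_delta=float(delta["delta"].mean()))

        out["summaries"] = {
            g: group_summary(delta, g, panel)
            for g in ("health_status", "labor_bins", "education_bins")}
        log("summaries")

        # determinants per stratum
        merged = delta.merge(panel, on=["household_id", "wave", "stratum"])
        out["determinants"] = {}
        for stratum in strata:
            sub = merged[merged["stratum"] == stratum]
            pooled = fit_panel(sub, DETERMINANTS, "pooled")
            fixed = fit_panel(sub, DETERMINANTS, "fixed")
            random = fit_panel(sub, DETERMINANTS, "random")
            tests = {
                "hausman": hausman_test(fixed, random),
                "f_individual": f_test_individual_effects(pooled, fixed),
            }
            if len(config.waves) >= 3:
                tests["chow"] = chow_test(
                    sub, DETERMINANTS,
                    (config.waves[:2], config.waves[1:3]))
            for est in (pooled, fixed, random):
                est.tests.update(tests)
            out["determinants"][stratum] = {
                "pooled": pooled, "fixed": fixed, "random": random,
                "tests": tests}
        log("determinants")

        # decomposition per stratum per adjacent wave pair
        out["decomposition"] = {}
        for stratum in strata:
            sub = merged[merged["stratum"] == stratum]
            fixed = out["determinants"][stratum]["fixed"]
            for t, t1 in zip(config.waves[:-1], config.waves[1:]):
                at, at1 = sub[sub["wave"] == t], sub[sub["wave"] == t1]
                dets = [c for c in DETERMINANTS if c in fixed.coefficients]
                table = contribution_table(
                    fixed,
                    {c: at[c].mean() for c in dets},
                    {c: at1[c].mean() for c in dets},
                    at["delta"].mean(), at1["delta"].mean(),
                    determinants=dets, window=(t, t1), stratum=stratum)
                out["decomposition"][(stratum, t, t1)] = table
        log("decomposition")
    except Exception as exc:
        log("ABORTED", error=f"{type(exc).__name__}: {exc}")
        out["manifest"] = manifest
        if outdir is not None:
            _write_outputs(out, outdir)
        raise

    if outdir is not None:
        _write_outputs(out, outdir)
    return out


def _write_outputs(out: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(out["manifest"], fh, indent=2, default=str)
    if "panel" in out:
        out["panel"].to_csv(outdir / "panel.csv", index=False)
    if "delta" in out:
        out["delta"].to_csv(outdir / "delta.csv", index=False)
    if "truth" in out:
        with open(outdir / "truth.json", "w") as fh:
            json.dump(out["truth"], fh, indent=2)
    for (stratum, wave), m in out.get("margins", {}).items():
        m["income"].to_json(outdir / f"income_{stratum}_{wave}.json")
        m["medical"].to_json(outdir / f"medical_{stratum}_{wave}.json")
    for stratum, c in out.get("copulas", {}).items():
        c.to_json(outdir / f"copula_{stratum}.json")
    for g, table in out.get("summaries", {}).items():
        table.to_csv(outdir / f"summary_{g}.csv")
    det = {}
    for stratum, fits in out.get("determinants", {}).items():
        det[stratum] = {
            est: {"coefficients": fits[est].coefficients,
                  "standard_errors": fits[est].standard_errors,
                  "r_squared": fits[est].r_squared,
                  "n_obs": fits[est].n_obs}
            for est in ("pooled", "fixed", "random")}
        det[stratum]["tests"] = {k: list(v) for k, v in fits["tests"].items()}
    if det:
        with open(outdir / "determinants.json", "w") as fh:
            json.dump(det, fh, indent=2, default=str)
    for (stratum, t, t1), table in out.get("decomposition", {}).items():
        table.to_frame().to_csv(outdir / f"decomposition_{stratum}_{t}_{t1}.csv")
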