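"""Cohort CSV schema and structured configuration files.

CSV schema (UTF-8, dot decimal), one row per individual:

    id,race_ethnicity,gender,entry_age,exit_age,is_case,smoking_status,
    age_started,cpd,age_quit,assessment_ages,episodes

``assessment_ages`` is semicolon-delimited; ``episodes`` is an optional
semicolon-delimited list of ``age:cpd`` pairs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd
import yaml

from .exposure import IncompleteRecordError, SmokingRecord, build_dose_history
from .inference import ModelSpec
from .likelihood import Cohort, Individual
from .synthetic import GeneratorConfig, GroupDemographics

COLUMNS = ["id", "race_ethnicity", "gender", "entry_age", "exit_age",
           "is_case", "smoking_status", "age_started", "cpd", "age_quit",
           "assessment_ages", "episodes"]


def _fmt(x) -> str:
    return "" if x is None else repr(float(x))


def write_cohort_csv(cohort: Cohort, path) -> None:
    rows = []
    for ind in cohort:
        rec = ind.record or SmokingRecord(
            status="never" if ind.dose_history.is_never else "current")
        rows.append({
            "id": ind.id,
            "race_ethnicity": ind.race,
            "gender": ind.gender,
            "entry_age": _fmt(ind.entry_age),
            "exit_age": _fmt(ind.exit_age),
            "is_case": int(ind.is_case),
            "smoking_status": rec.status,
            "age_started": _fmt(rec.age_started),
            "cpd": "" if rec.cpd is None else str(rec.cpd),
            "age_quit": _fmt(rec.age_quit),
            "assessment_ages": ";".join(_fmt(a) for a in rec.assessment_ages),
            "episodes": ";".join(f"{a}:{d}" for a, d in rec.episodes),
        })
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path, drop_incomplete: bool = True) -> Cohort:
    """Read the cohort schema; incomplete smoking records are dropped
    (mirroring study exclusions) unless ``drop_incomplete`` is False, in
    which case they raise."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    individuals: List[Individual] = []
    n_excluded = 0
    for _, r in df.iterrows():
        episodes = tuple(
            (float(a), float(d))
            for a, d in (p.split(":") for p in r["episodes"].split(";") if p))
        rec = SmokingRecord(
            status=r["smoking_status"] or "missing",
            age_started=float(r["age_started"]) if r["age_started"] else None,
            cpd=(float(r["cpd"]) if r["cpd"].replace(".", "", 1).isdigit()
                 else r["cpd"]) if r["cpd"] else None,
            age_quit=float(r["age_quit"]) if r["age_quit"] else None,
            assessment_ages=tuple(float(a) for a in
                                  r["assessment_ages"].split(";") if a),
            episodes=episodes,
        )
        try:
            dh = build_dose_history(rec)
        except IncompleteRecordError:
            if drop_incomplete:
                n_excluded += 1
                continue
            raise
        individuals.append(Individual(
            id=r["id"], race=r["race_ethnicity"], gender=r["gender"],
            entry_age=float(r["entry_age"]), exit_age=float(r["exit_age"]),
            is_case=bool(int(r["is_case"])), dose_history=dh, record=rec))
    return Cohort(individuals, {"source": str(path),
                                "n_excluded_incomplete": n_excluded})


@dataclasses.dataclass
class PipelineConfig:
    """Everything run_pipeline needs: generator + model + sampler settings."""

    generator: GeneratorConfig
    spec: ModelSpec
    candidates: Sequence[ModelSpec] = ()
    n_starts: int = 3
    mcmc_steps: int = 2000


def _spec_from_dict(d: dict) -> ModelSpec:
    kw = {}
    if "sharing" in d:
        kw["sharing"] = d["sharing"]
    else:
        kw["sharing"] = {p: d.get("default_sharing", "by_race_gender")
                         for p in ("mu0", "g", "g_c", "mu1_c")}
    for key in ("X", "alpha", "g_p", "mu1_p", "initiation_effect", "name"):
        if key in d:
            kw[key] = d[key]
    return ModelSpec(**kw)


def load_config(path, seed: Optional[int] = None,
                censor_window: Optional[float] = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (CLI flags override seed and
    censoring window)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    gen_kw = dict(raw.get("generator", {}))
    if "groups" in gen_kw:
        gen_kw["groups"] = tuple(GroupDemographics(**g) for g in gen_kw["groups"])
    if seed is not None:
        gen_kw["seed"] = seed
    if censor_window is not None:
        gen_kw["censor_window"] = censor_window
    if "params" in gen_kw:
        from .params import BiologicalParameters
        gen_kw["params"] = {
            (k.split(":")[0], k.split(":")[1]): BiologicalParameters(**v)
            for k, v in gen_kw["params"].items()}
    generator = GeneratorConfig(**gen_kw)
    spec = _spec_from_dict(raw.get("model", {}))
    candidates = tuple(_spec_from_dict(c) for c in raw.get("candidates", []))
    sampler = raw.get("sampler", {})
    return PipelineConfig(generator=generator, spec=spec,
                          candidates=candidates,
                          n_starts=int(sampler.get("n_starts", 3)),
                          mcmc_steps=int(sampler.get("mcmc_steps", 2000)))
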