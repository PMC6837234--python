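"""End-to-end orchestration: simulate -> cognates -> rates -> freq -> regress.

Each stage reads the standard-format files of the previous one from the
working directory, writes its outputs atomically (temp file + rename), and
appends a manifest entry recording the config hash, seeds and wall time, so
a completed run can be audited and reproduced. Stages are restartable:
``run_all`` skips stages whose outputs are already present unless forced.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import cognates as cg
from . import frequency as fq
from . import io as kio
from . import rates as rt
from . import regression as rg
from . import simulate as sim
from .types import ValidationError

log = logging.getLogger(__name__)

STAGES = ("simulate", "cognates", "rates", "freq", "regress")


@dataclasses.dataclass
class PipelineConfig:
    """Structured configuration for a pipeline run."""

    outdir: str = "kinrates_run"
    seed: int = 1
    # simulate
    simulation: sim.SimulationConfig = dataclasses.field(
        default_factory=sim.SimulationConfig
    )
    # cognates
    threshold: float = cg.DEFAULT_THRESHOLD
    linkage: str = "average"
    overrides_path: Optional[str] = None
    meanings: Optional[Sequence[str]] = None  # default: all in the word list
    # rates
    schedule: rt.ChainSchedule = dataclasses.field(default_factory=lambda: rt.TEST_SCHEDULE)
    n_chains: int = 3
    pi_mode: str = "empirical"
    tree_scheme: str = "random"
    prior_mean: float = 1.0
    compute_marginal: bool = False
    marginal_stones: int = 100
    marginal_iters: int = 1000
    # freq / regress
    laplace: bool = False
    outcome_transform: str = "log"
    # The outcome (mean rate) is constant within a meaning, so a free
    # meaning intercept would absorb the frequency effect wholesale;
    # the default candidate set therefore varies random effects by language.
    re_candidates: Sequence[str] = ("language_intercept", "language_intercept_slope")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        simc = sim.SimulationConfig(**raw.pop("simulation", {}))
        sched = raw.pop("schedule", None)
        kwargs = dict(raw)
        kwargs["simulation"] = simc
        if sched is not None:
            kwargs["schedule"] = rt.ChainSchedule(**sched)
        return cls(**kwargs)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _atomic_write_df(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)


def _append_manifest(outdir: Path, entry: dict) -> None:
    path = outdir / "pipeline_manifest.json"
    entries = json.loads(path.read_text()) if path.exists() else []
    entries.append(entry)
    tmp = path.with_suffix(".tmp")
    tmp.write_text(json.dumps(entries, indent=2, default=str))
    os.replace(tmp, path)


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    # derived deterministically per stage; kept below 2**31
    h = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_stage(name: str, config: PipelineConfig) -> dict:
    """Run one stage; returns its manifest entry.

    Stage inputs must already exist in ``config.outdir`` (error before any
    write); outputs land atomically in the same directory."""
    if name not in STAGES:
        raise ValidationError(f"unknown stage {name!r}; stages are {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    outputs = _STAGE_FNS[name](config, outdir)
    entry = {
        "stage": name,
        "config_hash": config.hash(),
        "seed": _stage_seed(config, name),
        "outputs": outputs,
        "wall_time_s": round(time.time() - t0, 3),
    }
    _append_manifest(outdir, entry)
    log.info("stage %s done in %.1fs (seed %d)", name, entry["wall_time_s"], entry["seed"])
    return entry


def _require(outdir: Path, *names: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise ValidationError(f"missing stage inputs: {missing}")


def _stage_simulate(config: PipelineConfig, outdir: Path) -> list[str]:
    cfg = dataclasses.replace(config.simulation, seed=_stage_seed(config, "simulate"))
    study = sim.make_study_fixture(cfg)
    sim.write_study(study, outdir)
    return ["wordlist.csv", "trees.nex", "frequencies.csv", "truth.csv", "manifest.json"]


def _stage_cognates(config: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, "wordlist.csv")
    wordlist = kio.read_wordlist(outdir / "wordlist.csv")
    overrides = (
        kio.read_overrides(config.overrides_path) if config.overrides_path else None
    )
    meanings = list(config.meanings) if config.meanings else wordlist.meanings
    taxa = wordlist.languages
    chars = []
    rows = []
    for m in meanings:
        part = cg.partition_meaning(
            wordlist, m, theta=config.threshold, linkage=config.linkage
        )
        if overrides is not None:
            part = cg.apply_overrides(part, overrides)
        chars.append(cg.build_character(part, taxa))
        for (lang, form), c in sorted(part.assignment.items()):
            rows.append(
                {
                    "meaning": m,
                    "language": lang,
                    "form": form,
                    "cognate_class": c,
                    "provenance": part.provenance[(lang, form)],
                }
            )
    kio.write_character_matrix(chars, outdir / "characters.nex")
    _atomic_write_df(pd.DataFrame(rows), outdir / "cognate_classes.csv")
    return ["characters.nex", "cognate_classes.csv"]


def _stage_rates(config: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, "characters.nex", "trees.nex")
    chars = kio.read_character_matrix(outdir / "characters.nex")
    trees = kio.read_tree_sample(outdir / "trees.nex", format="nexus")
    prior = rt.ExponentialPrior(mean=config.prior_mean)
    base_seed = _stage_seed(config, "rates")
    rows = []
    draws_dir = outdir / "draws"
    draws_dir.mkdir(exist_ok=True)
    for ci, char in enumerate(chars):
        posts = []
        for chain in range(config.n_chains):
            seed = (base_seed + 10_007 * ci + chain) % (2**31)
            posts.append(
                rt.mcmc_rate(
                    char,
                    trees,
                    prior=prior,
                    schedule=config.schedule,
                    seed=seed,
                    pi_mode=config.pi_mode,
                    tree_scheme=config.tree_scheme,
                )
            )
        summary = rt.summarize(posts)
        log_ml = float("nan")
        if config.compute_marginal:
            ss = rt.stepping_stone(
                char,
                trees,
                prior=prior,
                n_stones=config.marginal_stones,
                iters_per_stone=config.marginal_iters,
                seed=(base_seed + 10_007 * ci + 999) % (2**31),
                pi_mode=config.pi_mode,
            )
            log_ml = ss.log_ml
        rows.append(
            {
                "meaning": char.meaning,
                "mean_rate": summary.mean,
                "ci_low": summary.ci_low,
                "ci_high": summary.ci_high,
                "psrf": summary.psrf,
                "log_marginal_likelihood": log_ml,
                "n_chains": config.n_chains,
                "seed": base_seed,
                "schedule": f"{config.schedule.total}/{config.schedule.burn_in}/{config.schedule.thin}",
                "prior": f"exponential(mean={config.prior_mean})",
            }
        )
        np.savetxt(
            draws_dir / f"{char.meaning}.txt",
            np.column_stack([p.rates for p in posts]),
            header=" ".join(f"chain{j + 1}" for j in range(config.n_chains)),
        )
    _atomic_write_df(pd.DataFrame(rows), outdir / "rates.csv")
    return ["rates.csv", "draws/"]


def _stage_freq(config: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, "frequencies.csv", "wordlist.csv")
    counts = kio.read_frequency_table(outdir / "frequencies.csv")
    wordlist = kio.read_wordlist(outdir / "wordlist.csv")
    clfpm = fq.compute_clfpm(counts, wordlist, laplace=config.laplace)
    clfpm = fq.exclude_kin_swadesh(clfpm)
    _atomic_write_df(clfpm, outdir / "clfpm.csv")
    return ["clfpm.csv"]


def _stage_regress(config: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, "rates.csv", "clfpm.csv")
    rates_df = pd.read_csv(outdir / "rates.csv")
    clfpm = pd.read_csv(outdir / "clfpm.csv")
    flat = rates_df["mean_rate"] <= 0
    if flat.any():
        # constant characters carry no replacement signal; their rate is 0
        # and undefined on the log scale
        log.warning(
            "dropping %d meanings with zero estimated rate: %s",
            int(flat.sum()), list(rates_df.loc[flat, "meaning"]),
        )
        rates_df = rates_df[~flat]
    table = rg.build_regression_table(rates_df, clfpm)
    selection = rg.select_random_effects(
        table,
        candidates=tuple(config.re_candidates),
        outcome_transform=config.outcome_transform,
    )
    best = selection.best
    _atomic_write_df(
        best.fixed.reset_index(), outdir / "regression_fixed_effects.csv"
    )
    _atomic_write_df(selection.table, outdir / "regression_aic.csv")
    report = [
        f"mixed model: {config.outcome_transform}(mean_rate) ~ clfpm * lexical_class",
        f"random effects: {best.random_structure} (AIC-selected)",
        f"n = {best.n_obs} rows",
        "",
        best.fixed.to_string(),
        "",
        "AIC comparison:",
        selection.table.to_string(index=False),
    ]
    (outdir / "regression_report.txt").write_text("\n".join(report))
    return ["regression_fixed_effects.csv", "regression_aic.csv", "regression_report.txt"]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "cognates": _stage_cognates,
    "rates": _stage_rates,
    "freq": _stage_freq,
    "regress": _stage_regress,
}

_STAGE_DONE = {
    "simulate": "wordlist.csv",
    "cognates": "characters.nex",
    "rates": "rates.csv",
    "freq": "clfpm.csv",
    "regress": "regression_fixed_effects.csv",
}


def run_all(config: PipelineConfig, resume: bool = False) -> list[dict]:
    """Run all stages in dependency order.

    With ``resume=True`` stages whose outputs already exist are skipped, so a
    failed run can pick up where it stopped; prior outputs are never
    clobbered by a later failure."""
    if config.schedule.total >= 1_000_000:
        log.warning(
            "schedule has %d iterations per chain; expect a long runtime",
            config.schedule.total,
        )
    entries = []
    for stage in STAGES:
        if resume and (Path(config.outdir) / _STAGE_DONE[stage]).exists():
            log.info("stage %s: outputs present, skipped (resume)", stage)
            continue
        entries.append(run_stage(stage, config))
    return entries
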