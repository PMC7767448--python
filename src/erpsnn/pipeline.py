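"""End-to-end experiment orchestration: generate -> encode -> train ->
summarise -> test -> report.

``run_experiment`` reproduces the study workflow on a synthetic cohort: one
unsupervised reservoir is STDP-trained per participant x time x stimulus
condition (a 2-group x 2-time x 2-stimulus design yields 8 model cells of 10
participants each), region x hemisphere weight tables and feature
interaction networks are extracted, the mixed ANOVA and Kendall-tau reports
are computed, and target-stimulus samples are classified across time points
with leave-one-out deSNN plus conventional baselines.

Every stage derives its seed from the base seed and a stable stage/sample
identifier, so reruns with the same configuration are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity, desnn, stats
from .encoding import EncoderConfig, encode_sample
from .fixtures import load_montage
from .io import write_cohort
from .reservoir import (
    LIFConfig,
    NeuronGrid,
    STDPConfig,
    SWCConfig,
    build_reservoir,
    run_stdp,
)
from .simulate import CohortSpec, generate_cohort

__all__ = ["ExperimentConfig", "StageError", "run_experiment", "train_condition_models"]

STAGES = ("simulate", "train", "analyse", "classify", "report")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and sample id."""

    def __init__(self, stage: str, sample_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {sample_id!r}: {cause}")
        self.stage = stage
        self.sample_id = sample_id


@dataclass(frozen=True)
class ExperimentConfig:
    """One self-contained experiment definition.

    ``reservoir_neurons=None`` uses the full packaged 1471-site grid;
    a smaller integer subsamples the grid to scale runs down.
    """

    cohort: CohortSpec = field(default_factory=CohortSpec)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    swc: SWCConfig = field(default_factory=SWCConfig)
    lif: LIFConfig = field(default_factory=LIFConfig)
    stdp: STDPConfig = field(default_factory=STDPConfig)
    desnn: DeSNNConfig = None  # type: ignore[assignment]
    baselines: tuple = ("mlp", "svm", "mlr")
    reservoir_neurons: int | None = None
    stdp_passes: int = 1
    base_seed: int = 0

    def __post_init__(self):
        if self.desnn is None:
            object.__setattr__(self, "desnn", desnn.DeSNNConfig())

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kw = dict(d)
        for key, sub in [("cohort", CohortSpec), ("encoder", EncoderConfig),
                         ("swc", SWCConfig), ("lif", LIFConfig),
                         ("stdp", STDPConfig), ("desnn", desnn.DeSNNConfig)]:
            if key in kw and isinstance(kw[key], dict):
                kw[key] = sub(**kw[key])
        for key in ("baselines",):
            if key in kw and isinstance(kw[key], list):
                kw[key] = tuple(kw[key])
        for sub in ("cohort", "encoder", "swc", "lif", "stdp", "desnn"):
            if sub in kw and isinstance(kw[sub], dict):  # pragma: no cover
                raise ValueError(f"bad sub-config {sub}")
        return cls(**kw)


def _grid(config: ExperimentConfig) -> NeuronGrid:
    grid = NeuronGrid.from_fixture()
    if config.reservoir_neurons is not None and config.reservoir_neurons < len(grid):
        grid = grid.subsample(config.reservoir_neurons, seed=config.base_seed)
    return grid


def _stage_seed(base: int, stage: str, ident: str) -> int:
    return int((zlib.crc32(f"{stage}:{ident}".encode()) ^ (base * 0x9E3779B1)) % (2**31))


def train_condition_models(samples, config: ExperimentConfig, grid=None,
                           montage=None, record: bool = True):
    """STDP-train one reservoir per sample; returns (meta, reservoir, log) triples.

    Every condition model starts from the *same* initial network (wiring and
    weights are a deterministic function of the configuration, re-instantiated
    with reset weights per sample).  Differences between trained models then
    reflect only their input data, not wiring draws -- the prestructured-cube
    convention, which keeps between-model weight comparisons free of
    initialisation noise.
    """
    if montage is None:
        montage = load_montage()
    if grid is None:
        grid = _grid(config)
    swc = dataclasses.replace(
        config.swc, seed=_stage_seed(config.base_seed, "wiring", "shared")
    )
    initial = build_reservoir(grid, montage, swc)
    out = []
    for s in samples:
        sid = desnn.sample_key(s)
        try:
            spikes = encode_sample(s, config.encoder)
            res, log = run_stdp(initial, spikes, config.lif, config.stdp,
                                passes=config.stdp_passes, record=record)
        except Exception as e:  # noqa: BLE001 - stage context matters
            raise StageError("train", sid, e) from e
        meta = {
            "participant_id": s.participant_id,
            "group": s.group,
            "time_point": s.time_point,
            "stimulus": s.stimulus,
        }
        out.append((meta, res, log))
    return out


def _classification_reports(samples, config, grid, montage):
    """Per-group LOOCV over target samples with time point as the class."""
    reports = {}
    baselines = {}
    for group in sorted({s.group for s in samples}):
        sel = [s for s in samples
               if s.group == group and s.stimulus == "target"]
        labels = [s.time_point for s in sel]
        if len(set(labels)) < 2:
            continue
        settings = desnn.LoocvSettings(
            grid=grid, montage=montage, encoder=config.encoder,
            swc=config.swc, lif=config.lif, stdp=config.stdp,
            desnn=config.desnn, stdp_passes=config.stdp_passes,
            base_seed=config.base_seed,
        )
        try:
            reports[group] = desnn.run_loocv(sel, labels, settings)
        except Exception as e:  # noqa: BLE001
            raise StageError("classify", group, e) from e
        if config.baselines:
            baselines[group] = desnn.run_baselines(
                sel, labels, methods=config.baselines,
                seed=_stage_seed(config.base_seed, "baseline", group),
            )
    return reports, baselines


def _table1_layout(rwt: connectivity.RegionWeightTable) -> pd.DataFrame:
    """Region-by-cell table in the published layout: one row per group x site
    (plus a total row), columns time x stimulus."""
    cells = rwt.cells.copy()
    piv = cells.pivot_table(index=["group", "site"],
                           columns=["time_point", "stimulus"],
                           values="mean_w", aggfunc="mean")
    totals = rwt.totals.pivot_table(index="group", columns=["time_point", "stimulus"],
                                    values="total_w")
    totals.index = pd.MultiIndex.from_product([totals.index, ["total_weight"]],
                                              names=["group", "site"])
    return pd.concat([piv, totals]).sort_index()


def run_experiment(config: ExperimentConfig, out_dir, stages=STAGES) -> Path:
    """Run the configured experiment and write a run directory.

    Outputs: the written cohort, per-model activation/region tables, the
    aggregated region-weight table, ANOVA and Kendall-tau reports, per-group
    classification reports with baselines, per-cell FIN matrices, and a
    manifest carrying the config and its hash.  Reruns with an identical
    config produce identical report files.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = load_montage()
    grid = _grid(config)
    log_lines = []

    def log(stage, msg):
        line = f"[{stage}] {msg}"
        log_lines.append(line)

    samples, psych = generate_cohort(config.cohort, montage)
    log("simulate", f"cohort: {len(samples)} samples, seed={config.cohort.seed}")
    if "simulate" in stages:
        write_cohort(samples, psych, out / "cohort", seed=config.cohort.seed)

    results: dict = {}
    if "train" in stages or "analyse" in stages:
        models = train_condition_models(samples, config, grid, montage)
        log("train", f"trained {len(models)} condition models on "
                     f"{grid.coords.shape[0]} neurons")
        rwt = connectivity.region_weight_table(
            [(m, r) for m, r, _ in models], montage.regions
        )
        act = pd.DataFrame(
            [{**m, "activation_level": connectivity.activation_level(r)}
             for m, r, _ in models]
        )
        (out / "models").mkdir(exist_ok=True)
        act.to_csv(out / "models" / "activation_levels.csv", index=False)
        rwt.per_model.to_csv(out / "models" / "region_weights_per_model.csv", index=False)
        _table1_layout(rwt).to_csv(out / "models" / "region_weight_table.csv")
        # FIN per model cell, summed over participants
        fins: dict = {}
        for (meta, res, flog) in models:
            cell = (meta["group"], meta["time_point"], meta["stimulus"])
            fin = connectivity.build_fin(flog, res)
            fins[cell] = fin if cell not in fins else fins[cell] + fin
        from .io import fin_edge_list

        for cell, fin in fins.items():
            stem = "fin_" + "_".join(cell)
            fin.to_csv(out / "models" / f"{stem}.csv")
            fin_edge_list(fin).to_csv(out / "models" / f"{stem}_edges.csv",
                                      index=False)
        results["n_model_cells"] = len(fins)
        results["n_models"] = len(models)
        log("analyse", f"{len(fins)} model cells summarised")

        if "analyse" in stages:
            lateral = rwt.per_model[rwt.per_model["hemisphere"].isin(["left", "right"])]
            anova = stats.rm_anova_gg(
                lateral.rename(columns={"time_point": "Time", "site": "Site",
                                        "hemisphere": "Hemisphere",
                                        "stimulus": "Stimuli", "group": "Group"}),
                dv="mean_w", within=["Site", "Time", "Hemisphere", "Stimuli"],
                subject="participant_id", between="Group",
            )
            (out / "reports").mkdir(exist_ok=True)
            anova.table.to_csv(out / "reports" / "anova.csv")
            # right-frontal weights at baseline vs psychometrics
            rf = lateral[(lateral["site"] == "frontal")
                         & (lateral["hemisphere"] == "right")
                         & (lateral["time_point"] == "T1")]
            wdf = rf.pivot_table(index="participant_id", columns="stimulus",
                                 values="mean_w")
            wdf.columns = [f"right_frontal_{c}" for c in wdf.columns]
            tau = stats.kendall_tau_matrix(
                wdf, psych.drop(columns=["group", "latent_rf_gain"], errors="ignore")
            )
            tau.table.to_csv(out / "reports" / "kendall.csv", index=False)
            results["anova_effects"] = len(anova.table)
            log("analyse", "ANOVA and Kendall reports written")

    if "classify" in stages:
        reports, baselines = _classification_reports(samples, config, grid, montage)
        (out / "reports").mkdir(exist_ok=True)
        for group, rep in reports.items():
            payload = {
                "confusion": rep.confusion.to_dict(),
                "per_class_accuracy_pct": (rep.per_class_accuracy * 100).round(2).to_dict(),
                "total_accuracy_pct": round(rep.total_accuracy * 100, 2),
                "macro_f1_pct": round(rep.macro_f1 * 100, 2),
                "baselines_accuracy_pct": {
                    m: round(a * 100, 2) for m, a in baselines.get(group, {}).items()
                },
            }
            (out / "reports" / f"classification_{group}.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True) + "\n"
            )
            rep.confusion.to_csv(out / "reports" / f"confusion_{group}.csv")
            results[f"loocv_folds_{group}"] = len(rep.predictions)
        log("classify", f"classification reports for {sorted(reports)} written")

    if "report" in stages:
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "base_seed": config.base_seed,
            "stages": list(stages),
            "results": results,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )
    log("report", f"run complete ({time.time() - t0:.1f}s)")
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out
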