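"""Run configuration and the end-to-end synthetic demonstration pipeline.

``run_pipeline`` executes the full study on synthetic data: generate a
pretraining corpus and two clinical cohorts sharing a planted signature,
pretrain with the time-reversal pretext, optionally balance, fine-tune both a
pretrained (PTR) and a from-scratch (NPT) arm with cross-fitted probing,
validate latent features statistically, probe + attribute network importance,
and measure cross-cohort consistency.  All artifacts are CSV/NPZ/HDF5 files
under the configured output directory, plus a YAML run log recording every
derived seed.

One global seed fans out to stage-specific seeds through a fixed hash so that
stages are reproducible independently.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .balancing import balance_cohort
from .core_io import NetworkMap, default_network_map, load_network_map, save_cohort
from .finetune import ExperimentGrid, OOFResult, enumerate_grid, run_oof_cell
from .interpret import (
    NetworkImportance,
    aggregate_importance,
    cross_cohort_consistency,
    oof_network_importance,
)
from .latent_stats import latent_stat_report
from .model import HierarchicalAttentionNet, ModelConfig
from .pretrain import TrainSpec, run_pretraining
from .synthetic import EffectSpec, SynthConfig, gen_clinical_cohort, gen_pretrain_corpus

__all__ = ["RunConfig", "stage_seed", "run_pipeline", "enumerate_grid", "load_config"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed by a fixed hash."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Desk-scale demonstration settings.

    The model block is reduced relative to the reference architecture
    (encoder 32, latent 24 instead of 256/200) so the demonstration trains in
    minutes on one CPU while preserving every structural element of the
    pipeline; the training recipe (batch 32, Adam at 7e-4) is unchanged.
    """

    seed: int = 0
    out_dir: str = "runs/demo"
    synthetic: SynthConfig = field(default_factory=lambda: SynthConfig(
        n_subjects=100, T_total=140))
    effect: EffectSpec = field(default_factory=EffectSpec)
    n_hc: int = 80
    n_pat: int = 80
    model: ModelConfig = field(default_factory=lambda: ModelConfig(
        D_enc=32, D_main=24, D_attn=16))
    pretrain_spec: TrainSpec = field(default_factory=lambda: TrainSpec(
        max_epochs=25, patience=8))
    finetune_spec: TrainSpec = field(default_factory=lambda: TrainSpec(
        max_epochs=60, patience=15))
    pretrain_folds: int = 5
    probe_folds: int = 2          # cross-fitting folds for probing latents
    n_seeds: int = 2              # fine-tuning replicate seeds per arm/cohort
    balance_k: int | None = None  # Mahalanobis retention; None disables balancing
    network_map_path: str | None = None
    positive_class: str = "patient"
    mapping: str = "normalized"


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file of nested blocks."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    kwargs: dict = {}
    for key, cls in (("synthetic", SynthConfig), ("effect", EffectSpec),
                     ("model", ModelConfig)):
        if key in raw:
            kwargs[key] = cls(**raw.pop(key))
    for key in ("pretrain_spec", "finetune_spec"):
        if key in raw:
            kwargs[key] = TrainSpec(**raw.pop(key))
    kwargs.update(raw)
    return RunConfig(**kwargs)


def _log(lines: list[str], msg: str) -> None:
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    lines.append(f"{stamp} {msg}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict and writes artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    seeds = {s: stage_seed(cfg.seed, s) for s in
             ("simulate", "pretrain", "balance", "finetune", "probe")}
    _log(log, f"pipeline start seed={cfg.seed} derived={seeds}")

    stage = "setup"
    try:
        net_map = (load_network_map(cfg.network_map_path, cfg.model.C)
                   if cfg.network_map_path else default_network_map(cfg.model.C))

        # --- simulate -----------------------------------------------------
        stage = "simulate"
        syn = SynthConfig(**{**asdict(cfg.synthetic), "seed": seeds["simulate"]})
        corpus = gen_pretrain_corpus(syn)
        cohorts = {
            name: gen_clinical_cohort(
                SynthConfig(**{**asdict(syn), "seed": seeds["simulate"] + i + 1}),
                cfg.effect, net_map, cfg.n_hc, cfg.n_pat, cohort_id=name)
            for i, name in enumerate(("COHORT-A", "COHORT-B"))
        }
        save_cohort(corpus, out / "corpus.npz", out / "corpus_manifest.csv")
        _log(log, f"simulate: corpus {len(corpus)} subjects, "
                  f"cohorts {[len(c) for c in cohorts.values()]}")

        # --- balance (optional) ------------------------------------------
        stage = "balance"
        if cfg.balance_k is not None:
            for name in list(cohorts):
                res, cohorts[name] = balance_cohort(cohorts[name], cfg.balance_k,
                                                    seed=seeds["balance"])
                res.distances.to_csv(out / f"balance_{name}.csv", index=False)
                _log(log, f"balance {name}: kept {res.k} controls")

        # --- pretrain -----------------------------------------------------
        stage = "pretrain"
        pre_spec = TrainSpec(**{**cfg.pretrain_spec.__dict__, "seed": seeds["pretrain"]})
        folds = run_pretraining(corpus, cfg.model, pre_spec,
                                n_folds=cfg.pretrain_folds, out_dir=out)
        _log(log, "pretrain: fold TR-AUCs " +
             ", ".join(f"{r.val_auc:.3f}" for r in folds))

        # --- finetune + stats + probe, PTR and NPT arms -------------------
        stage = "finetune"
        ft_rows, stat_rows, cons_rows = [], [], []
        importances: dict[tuple[str, str], list[NetworkImportance]] = {}
        for arm, scratch in (("PTR", False), ("NPT", True)):
            for name, cohort in cohorts.items():
                for rep in range(cfg.n_seeds):
                    ckpt = folds[rep % len(folds)].model if not scratch else None
                    spec = TrainSpec(**{**cfg.finetune_spec.__dict__,
                                        "seed": seeds["finetune"] + rep})
                    oof = run_oof_cell(cohort, cfg.model, spec, ckpt,
                                       seed=seeds["finetune"] + rep,
                                       n_folds=cfg.probe_folds, scratch=scratch)
                    ft_rows.append({"arm": arm, "cohort": name, "rep": rep,
                                    "auc": oof.mean_auc})
                    report = latent_stat_report(oof.latents)
                    stat_rows.append({"arm": arm, "cohort": name, "rep": rep,
                                      **report.summary_row()})
                    imp = oof_network_importance(
                        oof, net_map, mapping=cfg.mapping,
                        positive_class=cfg.positive_class,
                        seed=seeds["probe"] + rep)
                    importances.setdefault((arm, name), []).append(imp)
                _log(log, f"finetune {arm} {name}: "
                          f"auc {np.mean([r['auc'] for r in ft_rows if r['arm']==arm and r['cohort']==name]):.3f}")

        pd.DataFrame(ft_rows).to_csv(out / "finetune_metrics.csv", index=False)
        pd.DataFrame(stat_rows).to_csv(out / "latent_stats.csv", index=False)

        # --- importance + consistency ------------------------------------
        stage = "report"
        for (arm, name), imps in importances.items():
            agg = aggregate_importance(imps)
            agg.to_csv(out / f"importance_{arm}_{name}.csv", index=False)
        for arm in ("PTR", "NPT"):
            reps = len(importances[(arm, "COHORT-A")])
            rs = [cross_cohort_consistency(importances[(arm, "COHORT-A")][r],
                                           importances[(arm, "COHORT-B")][r])
                  for r in range(reps)]
            cons_rows.append({"arm": arm, "cohort_a": "COHORT-A",
                              "cohort_b": "COHORT-B",
                              "pearson_r": float(np.median(rs)), "n_reps": reps})
        pd.DataFrame(cons_rows).to_csv(out / "consistency.csv", index=False)

        summary = {
            "seed": cfg.seed,
            "pretrain_tr_auc": [r.val_auc for r in folds],
            "finetune_auc": {
                arm: float(np.mean([r["auc"] for r in ft_rows if r["arm"] == arm]))
                for arm in ("PTR", "NPT")
            },
            "consistency": {row["arm"]: row["pearson_r"] for row in cons_rows},
            "n_sig_two": {
                arm: float(np.mean([r["two_sample_significant"] for r in stat_rows
                                    if r["arm"] == arm]))
                for arm in ("PTR", "NPT")
            },
        }
        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=2)
        _log(log, "pipeline complete")
        return summary
    except Exception as exc:
        _log(log, f"pipeline aborted in stage '{stage}': {exc}")
        raise RuntimeError(f"pipeline stage '{stage}' failed") from exc
    finally:
        with open(out / "run_log.txt", "w") as f:
            f.write("\n".join(log) + "\n")
        with open(out / "run_config.yaml", "w") as f:
            yaml.safe_dump(asdict(cfg), f, sort_keys=False)
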