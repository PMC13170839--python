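"""End-to-end experiment orchestration with stage caching.

Stage order: simulate -> split -> train-gan -> synthesize -> score-quality
-> extract-features -> select-features -> train-clf/predict -> evaluate.
Each stage writes its artifacts plus a ``<stage>.stage.json`` marker
holding a hash of the stage-relevant configuration; a rerun skips stages
whose marker matches and whose outputs exist, so changing e.g. the GAN
seed reruns the GAN and everything downstream but not the phantoms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evalstats, model, quality, radiomics, selection
from .data_io import Modality, normalize_0_255
from .gan import (DiscriminatorSpec, GeneratorSpec, TrainConfig,
                  TranslationModel, synthesize, train_on_cohort)
from .phantom import PhantomConfig, load_case, simulate_cohort, write_cohort

log = logging.getLogger("synthrad.pipeline")

STAGES = ["simulate", "split", "gan", "synthesize", "quality",
          "features", "select", "classify", "evaluate"]


@dataclass
class RunConfig:
    """Whole-experiment configuration (YAML-serializable)."""

    out_dir: str = "runs/desk"
    seed: int = 7
    profile: str = "desk"  # desk | full
    n_cases: int = 30
    fibrous_fraction: float = 64 / 152
    targets: tuple[str, ...] = ("DWI_b1000",)
    k_max: int = 15
    folds: int = 10
    epochs: int | None = None  # None -> profile default
    stages: tuple[str, ...] = tuple(STAGES)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)
        return path


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


def _profile(cfg: RunConfig):
    if cfg.profile == "desk":
        gen = GeneratorSpec(depth=2, base_channels=16, attention_residual_blocks=1)
        dis = DiscriminatorSpec(patch_depth=3, base_channels=16)
        epochs = cfg.epochs if cfg.epochs is not None else 5
        train = TrainConfig(epochs=epochs, batch_size=4, slice_size=64,
                            slices_per_case=3, seed=stage_seed(cfg.seed, "gan"))
    elif cfg.profile == "full":
        gen = GeneratorSpec(depth=3, base_channels=32, attention_residual_blocks=2)
        dis = DiscriminatorSpec(patch_depth=4, base_channels=32)
        epochs = cfg.epochs if cfg.epochs is not None else 100
        train = TrainConfig(epochs=epochs, batch_size=4, slice_size=64,
                            slices_per_case=8, seed=stage_seed(cfg.seed, "gan"))
    else:
        raise ValueError(f"unknown profile {cfg.profile!r}")
    return gen, dis, train


def _stage_hash(payload) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                          .encode()).hexdigest()


class _Cache:
    def __init__(self, out: Path):
        self.out = out

    def fresh(self, stage: str, payload) -> bool:
        marker = self.out / f"{stage}.stage.json"
        if not marker.exists():
            return False
        try:
            return json.loads(marker.read_text())["hash"] == _stage_hash(payload)
        except (json.JSONDecodeError, KeyError):
            return False

    def mark(self, stage: str, payload) -> None:
        marker = self.out / f"{stage}.stage.json"
        marker.write_text(json.dumps(
            {"hash": _stage_hash(payload), "time": time.time()}))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = _Cache(out)
    gen_spec, dis_spec, train_cfg = _profile(cfg)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": {}}
    t_start = time.time()

    def stage_enabled(name):
        return name in cfg.stages

    # ---- simulate -----------------------------------------------------
    sim_payload = {"n": cfg.n_cases, "frac": cfg.fibrous_fraction,
                   "seed": stage_seed(cfg.seed, "simulate")}
    phantom_cfg = PhantomConfig(n_cases=cfg.n_cases,
                                fibrous_fraction=cfg.fibrous_fraction,
                                seed=sim_payload["seed"])
    cohort_dir = out / "phantom"
    if stage_enabled("simulate"):
        if cache.fresh("simulate", sim_payload) and (cohort_dir / "manifest.csv").exists():
            log.info("simulate: cache hit")
            manifest["stages"]["simulate"] = "cached"
        else:
            t0 = time.time()
            write_cohort(simulate_cohort(phantom_cfg), cohort_dir)
            cache.mark("simulate", sim_payload)
            manifest["stages"]["simulate"] = f"{time.time() - t0:.1f}s"
    from .data_io import CohortManifest

    cohort_man = CohortManifest.load(cohort_dir / "manifest.csv")
    cases = [load_case(cohort_man, cid) for cid in cohort_man.case_ids]
    labels = pd.Series({c.case_id: c.label for c in cases})

    # ---- split --------------------------------------------------------
    split_payload = {"seed": stage_seed(cfg.seed, "split"), "labels": labels.to_dict()}
    plan = selection.make_split(labels, seed=split_payload["seed"])
    (out / "split.json").write_text(json.dumps(
        {"train_ids": plan.train_ids, "test_ids": plan.test_ids}, indent=2))
    cache.mark("split", split_payload)
    train_cases = [c for c in cases if c.case_id in set(plan.train_ids)]
    test_cases = [c for c in cases if c.case_id in set(plan.test_ids)]

    # ---- gan ----------------------------------------------------------
    targets = [Modality(t) for t in cfg.targets]
    models: dict[Modality, TranslationModel] = {}
    gan_payload = {"targets": [t.value for t in targets],
                   "gen": dataclasses.asdict(gen_spec),
                   "dis": dataclasses.asdict(dis_spec),
                   "train": dataclasses.asdict(train_cfg),
                   "upstream": sim_payload}
    if stage_enabled("gan"):
        hit = cache.fresh("gan", gan_payload) and all(
            (out / f"gan_{t.value}.npz").exists() for t in targets)
        for t in targets:
            ckpt = out / f"gan_{t.value}"
            if hit:
                models[t] = TranslationModel.load(ckpt)
                manifest["stages"].setdefault("gan", "cached")
            else:
                t0 = time.time()
                m = TranslationModel(Modality.T2WI, t, gen_spec, dis_spec, train_cfg)
                train_on_cohort(m, train_cases, train_cfg)
                m.save(ckpt)
                models[t] = m
                manifest["stages"][f"gan_{t.value}"] = f"{time.time() - t0:.1f}s"
        if not hit:
            cache.mark("gan", gan_payload)

    # ---- synthesize + quality ----------------------------------------
    syn: dict[tuple[str, Modality], np.ndarray] = {}
    if stage_enabled("synthesize") and models:
        for t, m in models.items():
            for case in cases:
                vol = synthesize(m, normalize_0_255(case.t2))
                syn[(case.case_id, t)] = vol
        manifest["stages"]["synthesize"] = f"{len(syn)} volumes"
    if stage_enabled("quality") and syn:
        reports = {}
        for t in targets:
            pairs = [(c.case_id, syn[(c.case_id, t)].voxels,
                      normalize_0_255(c.volumes[t]).voxels) for c in test_cases]
            rep = quality.similarity_report(pairs, t.value)
            rep.per_case.to_csv(out / f"quality_{t.value}.csv", index=False)
            reports[t.value] = {"summary": rep.summary(),
                                "flags": quality.quality_flags(rep)}
        (out / "quality.json").write_text(json.dumps(reports, indent=2))
        manifest["stages"]["quality"] = reports
    cache.mark("quality", gan_payload)

    # ---- features -----------------------------------------------------
    tables: dict[str, pd.DataFrame] = {}
    if stage_enabled("features"):
        t0 = time.time()
        tables["T2WI"] = radiomics.feature_table(cases, Modality.T2WI)
        for t in targets:
            if syn:
                tables[f"synthetic_{t.value}"] = radiomics.feature_table(
                    cases, t, volume_getter=lambda c, t=t: syn[(c.case_id, t)])
            tables[f"real_{t.value}"] = radiomics.feature_table(cases, t)
        for name, tab in tables.items():
            tab.to_csv(out / f"features_{name}.csv", index=False)
        manifest["stages"]["features"] = f"{time.time() - t0:.1f}s"

    # ---- select + classify + evaluate --------------------------------
    results = {}
    if stage_enabled("select") and tables:
        feature_sets = dict(tables)
        if len(targets) > 1 and syn:
            feature_sets["synthetic_combined"] = model.combine_modalities(
                {k: v for k, v in tables.items() if k.startswith("synthetic_")})
        sel_seed = stage_seed(cfg.seed, "select")
        clf_seed = stage_seed(cfg.seed, "classify")
        preds = {}
        for name, tab in feature_sets.items():
            tr = tab[tab["case_id"].isin(plan.train_ids)].reset_index(drop=True)
            te = tab[tab["case_id"].isin(plan.test_ids)].reset_index(drop=True)
            min_class = int(tr["label"].value_counts().min())
            sel = selection.select_features(
                tr, k_max=cfg.k_max, folds=min(cfg.folds, 10, min_class),
                seed=sel_seed)
            sel.to_json(out / f"selection_{name}.json")
            fitted = model.fit_mlp(tr, sel.chosen_subset,
                                   model.MLPConfig(seed=clf_seed))
            pred = model.predict(fitted, te, source_feature_set=name)
            pred.save(out / f"predictions_{name}.csv")
            preds[name] = pred
            y_true = te["label"].to_numpy()
            roc = evalstats.auc(pred.table["p_positive"], y_true,
                                seed=stage_seed(cfg.seed, "evaluate"))
            conf = evalstats.confusion_metrics(pred.table["pred_label"], y_true)
            results[name] = {
                "auc": roc.auc, "auc_ci": [roc.ci_low, roc.ci_high],
                "accuracy": conf["accuracy"]["value"],
                "sensitivity": conf["sensitivity"]["value"],
                "specificity": conf["specificity"]["value"],
                "chosen_subset": sel.chosen_subset,
            }
        # paired comparisons against conventional T2 features
        if "T2WI" in preds:
            ref = preds["T2WI"].table["p_positive"].to_numpy()
            te_labels = feature_sets["T2WI"][
                feature_sets["T2WI"]["case_id"].isin(plan.test_ids)
            ].sort_values("case_id")["label"].to_numpy()
            for name, pred in preds.items():
                if name == "T2WI":
                    continue
                pn = pred.table.sort_values("case_id")["p_positive"].to_numpy()
                z, p = evalstats.delong_test(pn, ref, te_labels)
                rec = evalstats.nri_idi(
                    _as_prob(ref), _as_prob(pn), te_labels)
                results[name]["vs_T2WI"] = {
                    "delong_z": z, "delong_p": p,
                    "nri": rec.nri, "idi": rec.idi,
                }
        (out / "eval_report.json").write_text(json.dumps(results, indent=2))
        manifest["stages"]["evaluate"] = results

    manifest["elapsed_s"] = time.time() - t_start
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _as_prob(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)


def load_case_from_dir(cohort_dir: Path, index: int):
    from .data_io import CohortManifest

    man = CohortManifest.load(Path(cohort_dir) / "manifest.csv")
    return load_case(man, man.case_ids[index])
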