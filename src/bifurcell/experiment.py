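"""Experiment orchestration: configuration, stage graph, manifest, report.

A run configuration is a key/value tree (YAML on disk) validated against
the default profile — unknown keys are rejected by name.  ``run_experiment``
executes the declared stage graph for an experiment preset and writes a
manifest recording the config snapshot, seeds, package version, and a
sha256 checksum of every output file; ``summarize`` tabulates the results
of a completed run.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import generate_dataset
from .grn import TwoGeneConfig, build_grn_pseudotime, transition_index
from .maps import CLASS_NAMES
from .nn import Ensemble, NetworkSpec, evaluate, train
from .pipeline import make_bundle, prediction_sweep

__all__ = ["RunConfig", "DEFAULT_CONFIG", "run_experiment", "summarize",
           "verify_manifest"]

logger = logging.getLogger("bifurcell")

#: Default profile.  "paper" scale is the full corpus / architecture;
#: the scaled profile reduces both for desk-scale runs.
DEFAULT_CONFIG: dict[str, Any] = {
    "experiment": "grn-demo",
    "seed": 0,
    "outdir": "runs/demo",
    "verbosity": "info",
    "profile": "scaled",  # "scaled" or "paper"
    "data": {
        "n_models_per_class": 1000,
        "sims_per_model": 20,
        "n_steps": 600,
        "series_length": 500,
    },
    "training": {
        "learning_rate": 0.0005,
        "batch_size": 1024,
        "epochs_max": 200,
        "patience": 20,
        "members_per_variant": 5,
    },
    "scaled_overrides": {
        "n_models_per_class": 50,
        "batch_size": 256,
        "epochs_max": 60,
        "patience": 10,
        "members_per_variant": 1,
    },
    "grn": {
        "n_sims": 20,
        "n_prediction_times": 10,
    },
}


class ConfigError(ValueError):
    pass


def _validate(cfg: dict, defaults: dict, prefix: str = "") -> None:
    for key, val in cfg.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key: {prefix}{key}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {prefix}{key} must be a mapping")
            _validate(val, defaults[key], prefix=f"{prefix}{key}.")


def _merge(defaults: dict, cfg: dict) -> dict:
    out = copy.deepcopy(defaults)
    for key, val in cfg.items():
        if isinstance(val, dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


@dataclass
class RunConfig:
    """Validated run configuration (defaults merged in)."""

    tree: dict[str, Any]

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        _validate(cfg, DEFAULT_CONFIG)
        return cls(tree=_merge(DEFAULT_CONFIG, cfg))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(cfg, dict):
            raise ConfigError("config file must hold a key/value mapping")
        return cls.from_dict(cfg)

    def __getitem__(self, key: str):
        return self.tree[key]

    def effective(self) -> dict[str, Any]:
        """Config tree with the scaled profile's overrides applied."""
        t = copy.deepcopy(self.tree)
        if t["profile"] == "scaled":
            ov = t["scaled_overrides"]
            t["data"]["n_models_per_class"] = ov["n_models_per_class"]
            for k in ("batch_size", "epochs_max", "patience", "members_per_variant"):
                t["training"][k] = ov[k]
        return t


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _train_ensemble(cfg: dict, dataset, seed: int) -> Ensemble:
    t = cfg["training"]
    members = []
    for variant in (1, 2):
        for j in range(t["members_per_variant"]):
            spec = (NetworkSpec.scaled(variant) if cfg["profile"] == "scaled"
                    else (NetworkSpec.variant1() if variant == 1
                          else NetworkSpec.variant2()))
            net, _ = train(dataset, spec, seed=seed + 13 * variant + j,
                           epochs_max=t["epochs_max"], lr=t["learning_rate"],
                           batch_size=t["batch_size"], patience=t["patience"])
            members.append(net)
    return Ensemble(members)


def run_experiment(config: RunConfig) -> Path:
    """Execute the experiment's stage graph; return the artifact directory."""
    cfg = config.effective()
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, cfg["verbosity"].upper(), logging.INFO))
    try:
        seed = int(cfg["seed"])
        logger.info("experiment %s (profile %s, seed %d)",
                    cfg["experiment"], cfg["profile"], seed)
        outputs: list[Path] = []
        d = cfg["data"]
        ds = generate_dataset(n_models_per_class=d["n_models_per_class"],
                              sims_per_model=d["sims_per_model"],
                              shuffle_seed=seed,
                              n_steps=d["n_steps"],
                              series_length=d["series_length"])
        ds.save(outdir / "dataset")
        outputs += sorted((outdir / "dataset").iterdir())
        logger.info("corpus: %d series", ds.n_series)

        ensemble = _train_ensemble(cfg, ds, seed)
        ensemble.save(outdir / "ensemble")
        outputs += sorted((outdir / "ensemble").iterdir())
        Xte, yte = ds.subset("test")
        res = evaluate(ensemble, Xte, yte, variant=2,
                       rng=np.random.default_rng(seed + 1))
        eval_df = pd.DataFrame([{"f1_multiclass": res.f1_multiclass,
                                 "f1_binary": res.f1_binary}])
        eval_path = outdir / "evaluation.csv"
        eval_df.to_csv(eval_path, index=False)
        outputs.append(eval_path)

        if cfg["experiment"] == "grn-demo":
            rng = np.random.default_rng(seed + 7)
            for name, gcfg in (("fold", TwoGeneConfig.fold()),
                               ("pitchfork", TwoGeneConfig.pitchfork()),
                               ("null", TwoGeneConfig.null())):
                series_set = build_grn_pseudotime(gcfg, n_sims=cfg["grn"]["n_sims"], rng=rng)
                series = series_set[0]
                t_idx = transition_index(gcfg)
                end = t_idx if t_idx is not None else len(series)
                bundle = make_bundle(series[:end], np.arange(end, dtype=float),
                                     transition_time=float(t_idx) if t_idx else None)
                times = np.linspace(0.5 * end, 0.95 * end,
                                    cfg["grn"]["n_prediction_times"])
                sweep = prediction_sweep(bundle, ensemble, times, baselines=False)
                path = outdir / f"sweep_{name}.csv"
                sweep.table.to_csv(path, index=False)
                outputs.append(path)
                logger.info("scenario %s: %d/%d predictions available", name,
                            sweep.n_available, len(times))

        manifest = {
            "version": __version__,
            "config": cfg,
            "seed": seed,
            "outputs": [{"file": str(p.relative_to(outdir)), "sha256": _sha256(p)}
                        for p in outputs],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return outdir
    finally:
        logger.removeHandler(handler)
        handler.close()


def verify_manifest(outdir: str | Path) -> list[str]:
    """Re-checksum all manifest outputs; return the names that mismatch."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    bad = []
    for entry in manifest["outputs"]:
        p = outdir / entry["file"]
        if not p.exists() or _sha256(p) != entry["sha256"]:
            bad.append(entry["file"])
    return bad


def summarize(outdir: str | Path) -> tuple[str, pd.DataFrame]:
    """Tabulate a completed run: F1, per-scenario favored class, gaps."""
    outdir = Path(outdir)
    rows = []
    eval_path = outdir / "evaluation.csv"
    if eval_path.exists():
        ev = pd.read_csv(eval_path).iloc[0]
        rows.append({"section": "classifier", "item": "f1_multiclass",
                     "value": ev["f1_multiclass"]})
        rows.append({"section": "classifier", "item": "f1_binary",
                     "value": ev["f1_binary"]})
    else:
        rows.append({"section": "classifier", "item": "f1", "value": "MISSING"})
    for path in sorted(outdir.glob("sweep_*.csv")):
        name = path.stem.replace("sweep_", "")
        tbl = pd.read_csv(path)
        avail = tbl[tbl["available"]]
        if len(avail) == 0:
            rows.append({"section": "sweep", "item": name, "value": "no predictions"})
            continue
        mean_p = avail[["p_null", "p_fold", "p_tc", "p_pf"]].mean()
        favored = CLASS_NAMES[int(np.argmax(mean_p.to_numpy()))]
        rows.append({"section": "sweep", "item": f"{name}_favored_class",
                     "value": favored})
        rows.append({"section": "sweep", "item": f"{name}_mean_p_null",
                     "value": float(mean_p["p_null"])})
    df = pd.DataFrame(rows)
    lines = [f"run summary: {outdir}"] + [
        f"  [{r.section}] {r.item} = {r.value}" for r in df.itertuples()]
    report = "\n".join(lines)
    df.to_csv(outdir / "summary.csv", index=False)
    return report, df
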