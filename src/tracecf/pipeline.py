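"""Configuration, seeding and the end-to-end pipeline runner.

``run_pipeline`` ties the stages together — synthetic cohort -> autoencoder
-> calibrated classifier -> counterfactuals for held-back normal queries ->
metrics report — with per-stage caching and a manifest recording the exact
configuration, derived sub-seeds and output checksums, so any stage can be
reproduced in isolation.

A single global seed is fanned out deterministically per stage via a named
stream splitter (SHA-256 of ``"<seed>:<stage>"``), so stages are
individually reproducible and never share a random stream.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .counterfactual import CFConfig, generate_trace
from .lbc import LbcConfig, class_probabilities, load_lbc, save_lbc, train_lbc
from .metrics import evaluate_batch
from .synthetic import generate_dataset, load_dataset, save_dataset
from .wae import WAEConfig, encode, load_wae, save_wae, train_wae

__all__ = ["RunConfig", "load_config", "save_config", "stage_seed", "run_pipeline"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataSection(_Section):
    n: int = 500
    class_balance: float = 0.5
    nuisance_policy: str = "none"
    image_size: int = 64
    age_severity_corr: float = 0.0


class WaeSection(_Section):
    latent_dim: int = 32
    epochs: int = 20
    warmup_epochs: int = 5
    batch_size: int = 32
    lr: float = 1e-3
    lr_schedule: dict[int, float] = Field(default_factory=lambda: {12: 2.0, 17: 5.0})


class LbcSection(_Section):
    alpha: float = 0.9
    tau: float = 0.05
    eps_negative: float = 0.01
    f_hidden: list[int] = Field(default_factory=lambda: [64, 64])
    g_hidden: list[int] = Field(default_factory=lambda: [64, 64])
    epochs: int = 80
    min_epochs: int = 40
    lr: float = 1e-3


class CfSection(_Section):
    eta1: float = 0.5
    eta2: float = 0.5
    eta3: float = 0.2
    tau: float = 0.05
    steps: int = 300
    lr: float = 0.05
    n_queries: int = 20
    target_class: int = 1


class MetricsSection(_Section):
    k_proximity: int = 5
    k_realism: int = 3
    change_epsilon: float = 1.0 / 255.0


class RunConfig(_Section):
    seed: int = 0
    out_dir: str = "runs/trace"
    verbosity: int = 1
    data: DataSection = Field(default_factory=DataSection)
    wae: WaeSection = Field(default_factory=WaeSection)
    lbc: LbcSection = Field(default_factory=LbcSection)
    counterfactual: CfSection = Field(default_factory=CfSection)
    metrics: MetricsSection = Field(default_factory=MetricsSection)


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(json.loads(config.model_dump_json()), f, sort_keys=False)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (named-stream splitter), < 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_key(section: BaseModel, upstream: list[str], seed: int) -> str:
    payload = json.dumps({"cfg": json.loads(section.model_dump_json()),
                          "upstream": upstream, "seed": seed}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in dependency order; return the run directory.

    Stage outputs already present with a matching manifest key are reused.
    On failure the manifest records the failed stage and partial outputs
    remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"stages": {}}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    old = manifest.get("stages", {})
    manifest["config"] = json.loads(config.model_dump_json())
    manifest["versions"] = {"tracecf": __version__, "numpy": np.__version__}
    manifest["seeds"] = {s: stage_seed(config.seed, s)
                        for s in ("data", "wae", "lbc", "counterfactual", "metrics")}
    stages = manifest["stages"] = {}
    log = print if config.verbosity else (lambda *a, **k: None)

    def cached(name: str, section: BaseModel, upstream: list[str],
               path: Path, build, load):
        key = _stage_key(section, upstream, manifest["seeds"][name])
        prev = old.get(name, {})
        if path.exists() and prev.get("key") == key \
                and prev.get("checksum") == _checksum(path):
            log(f"[{name}] cached -> {path.name}")
            result = load(path)
        else:
            log(f"[{name}] running")
            try:
                result = build(path)
            except Exception as exc:  # halt with the stage name, keep partials
                manifest["failed_stage"] = name
                manifest_path.write_text(json.dumps(manifest, indent=2))
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stages[name] = {"key": key, "path": str(path), "checksum": _checksum(path)}
        return result, key

    d = config.data
    ds, k_data = cached(
        "data", d, [], out / "data.h5",
        lambda p: (lambda ds: (save_dataset(ds, p), ds)[1])(
            generate_dataset(d.n, d.class_balance, d.nuisance_policy,
                             manifest["seeds"]["data"], d.image_size,
                             d.age_severity_corr)),
        load_dataset)

    w = config.wae
    wae_cfg = WAEConfig(latent_dim=w.latent_dim, image_size=d.image_size,
                        epochs=w.epochs, warmup_epochs=w.warmup_epochs,
                        batch_size=w.batch_size, lr=w.lr,
                        lr_schedule=dict(w.lr_schedule))
    wae, k_wae = cached(
        "wae", w, [k_data], out / "wae.h5",
        lambda p: (lambda m: (save_wae(m, p), m)[1])(
            train_wae(ds, wae_cfg, manifest["seeds"]["wae"])),
        load_wae)
    latents = encode(wae, ds.images)

    lb = config.lbc
    lbc_cfg = LbcConfig(alpha=lb.alpha, tau=lb.tau, eps_negative=lb.eps_negative,
                        f_hidden=tuple(lb.f_hidden), g_hidden=tuple(lb.g_hidden),
                        epochs=lb.epochs, min_epochs=lb.min_epochs, lr=lb.lr)
    model, k_lbc = cached(
        "lbc", lb, [k_data, k_wae], out / "lbc.h5",
        lambda p: (lambda m: (save_lbc(m, p), m)[1])(
            train_lbc(latents, ds.labels, "classification", lbc_cfg,
                      manifest["seeds"]["lbc"])),
        load_lbc)

    c = config.counterfactual
    cf_cfg = CFConfig(eta1=c.eta1, eta2=c.eta2, eta3=c.eta3, tau=c.tau,
                      steps=c.steps, lr=c.lr)
    source = 1 - c.target_class
    query_idx = np.flatnonzero(ds.labels == source)[:c.n_queries]

    def build_cfs(path):
        rows = []
        for i in query_idx:
            r = generate_trace(latents[i], c.target_class, model, wae, cf_cfg)
            rows.append(r)
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("query_idx", data=query_idx)
            f.create_dataset("z", data=np.stack([r.z for r in rows]))
            f.create_dataset("z_bar", data=np.stack([r.z_bar for r in rows]))
            f.create_dataset("x_bar", data=np.stack([r.x_bar for r in rows]))
        return rows

    def load_cfs(path):
        import h5py
        from .counterfactual import CounterfactualResult
        with h5py.File(path, "r") as f:
            return [CounterfactualResult(z=z, z_bar=zb, x_bar=xb, trajectory=[])
                    for z, zb, xb in zip(f["z"][...], f["z_bar"][...],
                                         f["x_bar"][...])]

    cfs, k_cf = cached("counterfactual", c, [k_data, k_wae, k_lbc],
                       out / "counterfactuals.h5", build_cfs, load_cfs)

    m = config.metrics
    report = evaluate_batch(cfs, ds.images[query_idx],
                            np.full(len(query_idx), c.target_class), model, wae,
                            ds.images, k_proximity=m.k_proximity,
                            k_realism=m.k_realism,
                            change_epsilon=m.change_epsilon)
    report.to_csv(out / "report.csv")
    (out / "summary.json").write_text(json.dumps(report.summary(), indent=2))
    stages["metrics"] = {"key": _stage_key(m, [k_cf], manifest["seeds"]["metrics"]),
                         "path": str(out / "report.csv"),
                         "checksum": _checksum(out / "report.csv")}
    p_abn = [float(class_probabilities(model, encode(wae, r.x_bar))[c.target_class])
             for r in cfs]
    manifest["counterfactual_p_target"] = p_abn
    manifest_path.write_text(json.dumps(manifest, indent=2))
    log(f"run complete -> {out}")
    return out
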