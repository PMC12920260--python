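"""End-to-end reproducible pipeline: generate -> prep -> train -> predict
-> Brain-PAD -> attribution -> trajectories.

Every stage derives its seed deterministically from the global seed, writes
its outputs under the working directory, and is skipped on rerun if its
output already exists (delete a stage file to recompute it). Healthy-
control-only training is enforced structurally: patient rows can never
reach the trainer.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import (activation_pad_correlation, gradcam,
                          phantom_region_set, regional_means)
from .io import read_table, read_volume
from .metrics import (group_comparisons, performance_metrics, prediction_table,
                      PREDICTIONS_COLUMNS)
from .model import BrainAgeRegressor, split_cohort
from .phantom import PhantomConfig, generate_cohort, load_manifest
from .preprocess import VolumePreprocessor
from . import trajectories as traj


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from the global seed."""
    h = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "little") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Everything one run needs; serializes losslessly to YAML."""

    workdir: str = "run"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    target_edge: int = 32
    estimator: dict = field(default_factory=dict)
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratify_split: bool = True
    train_ids: list | None = None  # optional explicit training list (HC only)
    target_block: int | None = None
    attribution_normalize: str = "max"
    bias_correction: str = "rescale"
    knot: float = 40.0
    run_quantile: bool = True
    run_attribution: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"] = self.phantom.to_dict()
        d["split_fractions"] = list(self.split_fractions)
        return json.loads(json.dumps(d))  # canonical JSON types (no tuples)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ph = d.pop("phantom", {})
        if isinstance(ph, dict):
            if ph.get("group_offsets"):
                ph["group_offsets"] = {g: tuple(v)
                                       for g, v in ph["group_offsets"].items()}
            ph = PhantomConfig(**{k: tuple(v) if k == "age_range" else v
                                  for k, v in ph.items()})
        d["split_fractions"] = tuple(d.get("split_fractions", (0.6, 0.2, 0.2)))
        return cls(phantom=ph, **d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def save_model(est: BrainAgeRegressor, path_npz, path_json) -> None:
    """Checkpoint: opaque parameter arrays plus a JSON sidecar."""
    state = est.model_.state_arrays()
    np.savez_compressed(path_npz, **state)
    sidecar = {
        "params": est.get_params(),
        "scaler": {"mean": est.scaler_.mean, "sd": est.scaler_.sd},
        "sex_levels": [str(v) for v in est._sex_enc_.levels],
        "scanner_levels": [str(v) for v in est._scanner_enc_.levels],
        "best_epoch": int(est.best_epoch_),
        "grid": int(round(est.n_features_in_ ** (1 / 3))),
        "version": __version__,
    }
    Path(path_json).write_text(json.dumps(sidecar, indent=2))


def load_model(path_npz, path_json) -> BrainAgeRegressor:
    from ._nn import BrainAgeCNN
    from .model import _CategoryEncoder
    from .preprocess import AgeScaler

    sidecar = json.loads(Path(path_json).read_text())
    est = BrainAgeRegressor(**sidecar["params"])
    grid = round(sidecar["grid"])
    est._sex_enc_ = _CategoryEncoder(sidecar["sex_levels"])
    est._scanner_enc_ = _CategoryEncoder(sidecar["scanner_levels"])
    est.scaler_ = AgeScaler(**sidecar["scaler"])
    est.best_epoch_ = sidecar["best_epoch"]
    est.n_features_in_ = grid ** 3
    net = BrainAgeCNN(
        grid=grid, channels=tuple(est.channels), head_units=est.head_units,
        head_dropout=est.head_dropout,
        n_sexes=len(sidecar["sex_levels"]),
        n_scanners=len(sidecar["scanner_levels"]),
        film=est.film, sex_batchnorm=est.sex_batchnorm,
        rng=np.random.default_rng(0))
    with np.load(path_npz) as data:
        net.load_state_arrays(dict(data))
    est.model_ = net
    est.history_ = pd.DataFrame()
    return est


def _load_preprocessed(manifest: pd.DataFrame, target_edge: int) -> np.ndarray:
    prep = VolumePreprocessor(target_edge=target_edge)
    out = np.empty((len(manifest),) + (target_edge,) * 3, dtype=np.float32)
    for i, path in enumerate(manifest["volume_path"]):
        vol, _ = read_volume(path)
        out[i] = prep.transform(vol[None])[0]
    return out


def run_pipeline(cfg: PipelineConfig, progress: bool = False,
                 until: str = "analyze") -> dict:
    """Execute the pipeline through stage ``until`` (generate, train,
    predict, attribute or analyze); returns the run report (written as
    ``report.json`` after the full run). Stage outputs are cached in the
    working directory and reused on rerun."""
    work = Path(cfg.workdir)
    work.mkdir(parents=True, exist_ok=True)
    log = (print if progress else (lambda *a, **k: None))
    files: dict[str, str] = {}

    # -- stage: generate -------------------------------------------------
    cohort_dir = work / "cohort"
    manifest_path = cohort_dir / "manifest.csv"
    phantom_cfg = replace(cfg.phantom, seed=stage_seed(cfg.seed, "generate"))
    if not manifest_path.exists():
        log("[generate] rendering phantom cohort ...")
        generate_cohort(phantom_cfg, out_dir=cohort_dir)
    manifest = load_manifest(manifest_path)
    files["manifest"] = str(manifest_path)
    if until == "generate":
        return {"files": files, "seed": cfg.seed}

    # -- stage: split + train (HC only, structurally) --------------------
    hc = manifest[manifest["group"] == "HC"]
    patients = manifest[manifest["group"] != "HC"]
    if cfg.train_ids is not None:
        bad = set(cfg.train_ids) - set(hc["id"])
        if bad:
            raise ValueError(
                f"training list contains non-HC subject(s): {sorted(bad)}; "
                "normative training uses healthy controls only")
    strata = None
    if cfg.stratify_split:
        decile = (hc["age"] // 10).astype(int).astype(str)
        strata = (hc["sex"].astype(str) + "|" + decile).to_numpy()
    part = split_cohort(hc["id"].tolist(), cfg.split_fractions,
                        seed=stage_seed(cfg.seed, "split"), strata=strata,
                        held_out={g: sub["id"].tolist()
                                  for g, sub in patients.groupby("group")})
    if cfg.train_ids is not None:
        part.train = list(cfg.train_ids)

    model_npz = work / "model.npz"
    model_json = work / "model.json"
    if model_npz.exists() and model_json.exists():
        log("[train] loading cached checkpoint")
        est = load_model(model_npz, model_json)
    else:
        log("[train] fitting the age regressor on HC training volumes ...")
        sub_tr = hc.set_index("id").loc[part.train].reset_index()
        sub_va = hc.set_index("id").loc[part.val].reset_index()
        X_tr = _load_preprocessed(sub_tr, cfg.target_edge)
        X_va = _load_preprocessed(sub_va, cfg.target_edge)
        est = BrainAgeRegressor(random_state=stage_seed(cfg.seed, "train"),
                                **cfg.estimator)
        est.fit(X_tr, sub_tr["age"].to_numpy(),
                sex=sub_tr["sex"], scanner=sub_tr["scanner"],
                X_val=X_va, y_val=sub_va["age"].to_numpy(),
                sex_val=sub_va["sex"], scanner_val=sub_va["scanner"])
        save_model(est, model_npz, model_json)
        est.history_.to_csv(work / "history.csv", index=False)
    files["model"] = str(model_npz)
    if until == "train":
        return {"files": files, "seed": cfg.seed,
                "partition_sizes": {"train": len(part.train),
                                    "val": len(part.val),
                                    "test": len(part.test)}}

    # -- stage: predict --------------------------------------------------
    pred_path = work / "predictions.csv"
    if pred_path.exists():
        preds = read_table(pred_path, PREDICTIONS_COLUMNS)
    else:
        log("[predict] predicting ages for all subjects ...")
        X_all = _load_preprocessed(manifest, cfg.target_edge)
        yhat = est.predict(X_all, sex=manifest["sex"], scanner=manifest["scanner"])
        preds = prediction_table(manifest["id"], manifest["group"],
                                 manifest["age"], yhat, manifest["sex"],
                                 manifest["scanner"])
        subset = np.where(preds["id"].isin(part.test), "test",
                          np.where(preds["id"].isin(part.val), "val",
                                   np.where(preds["id"].isin(part.train),
                                            "train", "held_out")))
        preds = preds.assign(subset=subset)
        preds.to_csv(pred_path, index=False)
    files["predictions"] = str(pred_path)
    if until == "predict":
        return {"files": files, "seed": cfg.seed}

    # -- stage: attribution ----------------------------------------------
    correlations = None
    act_path = work / "regional_activations.csv"
    corr_path = work / "activation_correlations.csv"
    regions = phantom_region_set(phantom_cfg, cfg.target_edge)
    if not cfg.run_attribution:
        regional = None
    elif act_path.exists():
        regional = pd.read_csv(act_path)
    else:
        log("[attribute] Grad-CAM maps and regional means ...")
        X_all = _load_preprocessed(manifest, cfg.target_edge)
        rows = []
        for i, rec in manifest.iterrows():
            attr = gradcam(est, X_all[i], sex=rec["sex"], scanner=rec["scanner"],
                           target_block=cfg.target_block,
                           normalize=cfg.attribution_normalize)
            rows.append({"id": rec["id"], **regional_means(attr, regions)})
        regional = pd.DataFrame(rows)
        regional.to_csv(act_path, index=False)
    if regional is not None:
      files["regional_activations"] = str(act_path)
      merged = regional.merge(preds, on="id")
      region_cols = [c for c in regional.columns if c != "id"]
      corr_frames = []
      for scope, sub in [("pooled", merged)] + list(merged.groupby("group")):
          if len(sub) < 8:
              continue
          plain = activation_pad_correlation(sub[region_cols], sub["brain_pad"])
          plain.insert(0, "scope", scope)
          cov = sub[["true_age", "sex", "scanner"]].rename(
              columns={"true_age": "age"})
          part_corr = activation_pad_correlation(sub[region_cols],
                                                 sub["brain_pad"], covariates=cov)
          part_corr.insert(0, "scope", scope)
          corr_frames.append(pd.concat([plain, part_corr], ignore_index=True))
      correlations = pd.concat(corr_frames, ignore_index=True)
      correlations.to_csv(corr_path, index=False)
      files["activation_correlations"] = str(corr_path)

    if until == "attribute":
        return {"files": files, "seed": cfg.seed}

    # -- stage: analyze ---------------------------------------------------
    log("[analyze] metrics and trajectory battery ...")
    metrics = {}
    hc_test = preds[(preds["group"] == "HC") & (preds["subset"] == "test")]
    metrics["HC_test"] = performance_metrics(
        hc_test["true_age"], hc_test["predicted_age"], group="HC_test").to_dict()
    for g, sub in preds.groupby("group"):
        metrics[g] = performance_metrics(
            sub["true_age"], sub["predicted_age"], group=g).to_dict()

    pad_table = preds.rename(columns={"true_age": "age"})[
        ["id", "group", "age", "brain_pad", "sex", "scanner"]]
    corrected, bias = traj.age_bias_correct(pad_table, method=cfg.bias_correction)
    inter = traj.fit_interaction(corrected)
    piece = traj.fit_piecewise(corrected, knot=cfg.knot)
    spline_df = 4
    spline = (traj.fit_spline(corrected, df=spline_df)
              if (corrected.groupby("group").size() > spline_df + 2).all()
              else None)
    bf = traj.brown_forsythe(*[sub["brain_pad"].to_numpy()
                               for _, sub in corrected.groupby("group")])
    disp = traj.dispersion_profile(corrected)
    ribbon = traj.ribbon_summary(corrected)
    tukey = group_comparisons({g: sub["brain_pad"].to_numpy()
                               for g, sub in corrected.groupby("group")})
    report = {
        "version": __version__,
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "files": files,
        "partition_sizes": {"train": len(part.train), "val": len(part.val),
                            "test": len(part.test),
                            **{g: len(v) for g, v in part.held_out.items()}},
        "metrics": metrics,
        "bias_correction": bias,
        "pad_means": {g: float(sub["brain_pad"].mean())
                      for g, sub in corrected.groupby("group")},
        "pad_means_raw": {g: float(sub["brain_pad"].mean())
                          for g, sub in pad_table.groupby("group")},
        "interaction": _fit_to_dict(inter),
        "piecewise": _fit_to_dict(piece),
        "spline_omnibus": (spline.contrasts["omnibus_group"]
                           if spline is not None else None),
        "brown_forsythe": {"W": bf[0], "p": bf[1]},
        "tukey": tukey.to_dict(orient="records"),
    }
    if cfg.run_quantile and (corrected.groupby("group").size() >= 20).all():
        quant = traj.quantile_fit(corrected, taus=(0.5,))
        report["quantile_tau50"] = {k: v for k, v in quant[0.5].contrasts.items()}
    disp.to_csv(work / "dispersion_profile.csv", index=False)
    ribbon.to_csv(work / "ribbon_summary.csv", index=False)
    files["dispersion_profile"] = str(work / "dispersion_profile.csv")
    files["ribbon_summary"] = str(work / "ribbon_summary.csv")

    for f in files.values():
        if not Path(f).exists():
            raise RuntimeError(f"report references missing file {f}")
    (work / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def _fit_to_dict(fit: traj.ModelFitResult) -> dict:
    return {"name": fit.name, "n": fit.n,
            "coef": fit.coef.round(6).to_dict(orient="index"),
            "contrasts": fit.contrasts}
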