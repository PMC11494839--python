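"""Dataset readers/writers, run configuration, and the end-to-end pipeline.

On-disk layout: ``<dir>/images/<id>.png`` (8-bit grayscale),
``<dir>/masks/<id>.png`` (0/255), and ``<dir>/manifest.csv`` with columns
id, label, split, synthetic.  Masks are binarized at 128 on load.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .balance import SmoteSpec, SplitSpec, smote_oversample, stratified_split
from .network import ModelConfig, build_model
from .objectives import LossConfig
from .phantom import PhantomParams, generate_dataset
from .preprocess import PreprocessConfig, preprocess_manifest
from .records import DatasetManifest, SampleRecord
from .train import TrainConfig, evaluate_model, save_checkpoint, train_model

MANIFEST_COLUMNS = ["id", "label", "split", "synthetic"]


def save_dataset(manifest: DatasetManifest, out_dir) -> Path:
    """Write images, masks and the manifest CSV; returns the directory."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(manifest):
        rid = rec.id or f"rec_{i:05d}"
        img8 = np.clip(np.asarray(rec.image, dtype=np.float64) * 255, 0, 255)
        Image.fromarray(np.round(img8).astype(np.uint8), mode="L").save(
            out / "images" / f"{rid}.png")
        if rec.mask is not None:
            Image.fromarray((rec.mask > 0).astype(np.uint8) * 255, mode="L").save(
                out / "masks" / f"{rid}.png")
        rows.append({"id": rid, "label": rec.label, "split": rec.split,
                     "synthetic": int(rec.synthetic)})
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(out / "manifest.csv",
                                                        index=False)
    return out


def load_dataset(in_dir) -> DatasetManifest:
    """Read a dataset directory back into a manifest.

    Images are normalized to [0,1] floats; masks binarized at 128.  A
    manifest row whose image file is missing raises a FileNotFoundError
    naming the record id; a missing mask leaves ``mask=None``.
    """
    root = Path(in_dir)
    mpath = root / "manifest.csv"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.csv under {root}")
    df = pd.read_csv(mpath, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        rid = str(row["id"])
        ipath = root / "images" / f"{rid}.png"
        if not ipath.exists():
            raise FileNotFoundError(f"record {rid}: missing image file {ipath}")
        img = np.asarray(Image.open(ipath).convert("L"), dtype=np.float32) / 255.0
        mask = None
        mpath_i = root / "masks" / f"{rid}.png"
        if mpath_i.exists():
            mask = (np.asarray(Image.open(mpath_i).convert("L")) >= 128
                    ).astype(np.uint8)
        records.append(SampleRecord(
            image=img, mask=mask, label=str(row["label"]), id=rid,
            synthetic=bool(int(row["synthetic"])) if "synthetic" in row else False,
            split=str(row.get("split", ""))))
    return DatasetManifest(records).validate()


@dataclass
class RunConfig:
    """Nested configuration for the full pipeline, loadable from YAML."""

    phantom: PhantomParams = field(default_factory=PhantomParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    smote: SmoteSpec = field(default_factory=SmoteSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_sdh: int = 56
    n_edh: int = 173
    seed: int = 0
    out_dir: str = "runs/run0"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {}
        blocks = {"phantom": PhantomParams, "preprocess": PreprocessConfig,
                  "split": SplitSpec, "smote": SmoteSpec, "model": ModelConfig,
                  "train": TrainConfig}
        for key, val in raw.items():
            if key in blocks:
                sub = dict(val or {})
                if key == "train" and "loss" in sub:
                    sub["loss"] = LossConfig(**sub["loss"])
                for tup in ("target_size", "clahe_tile_grid"):
                    if key == "preprocess" and tup in sub:
                        sub[tup] = tuple(sub[tup])
                kwargs[key] = blocks[key](**sub)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def with_derived_seeds(self) -> "RunConfig":
        """Derive per-stage seeds from the global one so each stage is
        independently reproducible."""
        import zlib

        def stage_seed(name):
            return (self.seed * 1000003 + zlib.crc32(name.encode())) % (2**31)

        cfg = RunConfig(**{**self.__dict__})
        cfg.phantom = PhantomParams(**{**asdict(self.phantom),
                                       "seed": stage_seed("phantom")})
        cfg.split = SplitSpec(test_fraction=self.split.test_fraction,
                              seed=stage_seed("split"))
        cfg.smote = SmoteSpec(per_class_target=dict(self.smote.per_class_target),
                              k_neighbors=self.smote.k_neighbors,
                              metric=self.smote.metric, seed=stage_seed("smote"))
        model_kw = {k: v for k, v in self.model.__dict__.items()}
        model_kw["seed"] = stage_seed("model")
        cfg.model = ModelConfig(**model_kw)
        train_kw = {k: v for k, v in self.train.__dict__.items()}
        train_kw["seed"] = stage_seed("train")
        cfg.train = TrainConfig(**train_kw)
        return cfg


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute dataset -> preprocess -> balance -> train -> evaluate.

    Writes stage artifacts under ``cfg.out_dir`` and returns the final
    metrics dict.  Configuration is validated up front (dataclass
    constructors), so invalid settings fail before any compute.
    """
    cfg = cfg.with_derived_seeds()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    data = generate_dataset(cfg.n_sdh, cfg.n_edh, cfg.phantom)
    train_raw, test_raw = stratified_split(data, cfg.split)

    train_pp = preprocess_manifest(train_raw, cfg.preprocess)
    test_cfg = PreprocessConfig(target_size=cfg.preprocess.target_size,
                                apply_enhancement=False)
    test_pp = preprocess_manifest(test_raw, test_cfg)

    smote = cfg.smote
    counts = train_pp.counts_by_class
    # clamp k for very small desk-scale classes; smote_oversample still validates
    k = min(smote.k_neighbors, max(1, min(counts.values()) - 1))
    target = smote.per_class_target or {c: max(counts.values()) for c in counts}
    smote = SmoteSpec(per_class_target=target, k_neighbors=k,
                      metric=smote.metric, seed=smote.seed)
    balanced = smote_oversample(train_pp, smote)

    model = build_model(cfg.model)
    best_state, history = train_model(model, balanced, val_set=None, cfg=cfg.train)
    model.load_state_dict(best_state)
    save_checkpoint(out / "model.ckpt", model, history)
    pd.DataFrame({k: v for k, v in history.__dict__.items()
                  if isinstance(v, list) and len(v)}).to_csv(
        out / "history.csv", index=False)

    report = evaluate_model(model, test_pp)
    result = report.to_dict()
    with open(out / "metrics.json", "w") as fh:
        json.dump(result, fh, indent=2, default=float)
    return result
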