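"""Orchestration: configuration, feature extraction, training, evaluation.

The heavy per-trial signal processing (denoise -> segment -> band powers
-> scalp images -> grid descriptors) is deterministic, so it is run once
up front (:func:`extract_features`) and the resulting arrays feed the
trainable network.  All randomness (initialisation, batch shuffling,
dropout) descends from ``RunConfig.seed``.
"""

from __future__ import annotations

import csv
import io
import json
import zipfile
from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path

import numpy as np

from . import preprocessing as pp
from .attention import export_attention_csv
from .bcn import DescriptorConfig, build_feature_matrix
from .metrics import macro_f1, micro_counts, f1_score, r_squared, recognition_accuracy
from .model import ModelConfig, MultimodalEmotionNet
from .nn import Adam
from .synthetic import Dataset


@dataclass
class RunConfig:
    """Schema-validated run settings; unknown keys are rejected on load."""

    seed: int = 0
    # preprocessing
    segment_duration: float = 0.2  # s
    topo_resolution: int = 32
    topo_method: str = "cubic"
    denoise: bool = True
    wavelet: str = "db4"
    wavelet_level: int = 4
    descriptor_grid: int = 5
    descriptor_support: int = 8
    descriptor_subcells: int = 2
    descriptor_orientations: int = 8
    max_segments: int = 25
    # model
    streams: tuple[str, ...] = ("expr", "eeg")
    heads: tuple[str, ...] = ("arousal", "valence")
    subspaces_k: int = 4
    dropout: float = 0.1
    am_scale: float = 12.0
    am_margin: float = 0.35
    # optimisation
    epochs: int = 25
    batch_size: int = 32
    learning_rate: float = 2e-3
    val_fraction: float = 0.2
    grad_clip: float = 5.0  # global gradient-norm ceiling (0 disables)

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.topo_method not in ("cubic", "linear"):
            raise ValueError("topo_method must be 'cubic' or 'linear'")
        self.streams = tuple(self.streams)
        self.heads = tuple(self.heads)

    @property
    def descriptor_config(self) -> DescriptorConfig:
        # unnormalised rows: the relative alpha/beta/theta descriptor
        # magnitudes within a trial carry the band-power contrast the
        # arousal label is linked to; a per-trial global scale is applied
        # in extract_features instead of per-row L2 normalisation
        return DescriptorConfig(
            grid=self.descriptor_grid,
            support=self.descriptor_support,
            subcells=self.descriptor_subcells,
            orientations=self.descriptor_orientations,
            normalize=False,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a plain-text key: value (YAML-subset) file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class FeatureSet:
    eeg: np.ndarray | None   # (n, S, 3, M, N) float32
    expr: np.ndarray | None  # (n, S, M, N) float32
    arousal: np.ndarray
    valence: np.ndarray

    def subset(self, idx: np.ndarray) -> "FeatureSet":
        return FeatureSet(
            None if self.eeg is None else self.eeg[idx],
            None if self.expr is None else self.expr[idx],
            self.arousal[idx],
            self.valence[idx],
        )

    def __len__(self) -> int:
        return len(self.arousal)


def extract_features(dataset: Dataset, cfg: RunConfig) -> FeatureSet:
    """Deterministic signal processing for every trial in the dataset."""
    mapper = pp.TopoMapper(resolution=cfg.topo_resolution, method=cfg.topo_method)
    dcfg = cfg.descriptor_config
    eeg_list = []
    expr_list = []
    for trial in dataset.trials:
        raw = trial.eeg
        if cfg.denoise:
            raw = pp.denoise_wavelet_soft(raw, cfg.wavelet, cfg.wavelet_level)
        bp = pp.trial_band_powers(raw, cfg.segment_duration)  # (S, 3, 32)
        images = mapper(bp)  # (S, 3, H, W)
        desc = build_feature_matrix(images, dcfg)  # (S, 3, M, N)
        # fixed elementwise compression (log energy is standard for EEG):
        # band-local and trial-independent, so normalisation cannot move
        # label information between bands; constants are a nominal
        # calibration for scalp maps of a few tens of uV^2
        desc = np.log1p(desc / 4.0) - 1.0
        S = min(desc.shape[0], cfg.max_segments, trial.face.shape[0])
        eeg_list.append(desc[:S].astype(np.float32))
        expr_list.append(trial.face[:S].astype(np.float32))
    S_min = min(x.shape[0] for x in eeg_list)
    eeg = np.stack([x[:S_min] for x in eeg_list])
    expr = np.stack([x[:S_min] for x in expr_list])
    return FeatureSet(eeg, expr, dataset.arousal, dataset.valence)


def build_model(cfg: RunConfig, features: FeatureSet,
                rng: np.random.Generator) -> MultimodalEmotionNet:
    dcfg = cfg.descriptor_config
    expr_shape = (
        tuple(features.expr.shape[-2:]) if features.expr is not None else (16, 32)
    )
    mcfg = ModelConfig(
        streams=cfg.streams,
        heads=cfg.heads,
        eeg_matrix_shape=(dcfg.n_keypoints, dcfg.n_dims),
        expr_matrix_shape=expr_shape,
        subspaces_k=cfg.subspaces_k,
        dropout=cfg.dropout,
        am_scale=cfg.am_scale,
        am_margin=cfg.am_margin,
    )
    return MultimodalEmotionNet(mcfg, rng)


def _batch_inputs(features: FeatureSet, idx: np.ndarray, streams) -> dict:
    return {
        "eeg_feats": features.eeg[idx].astype(np.float64) if "eeg" in streams else None,
        "expr_feats": features.expr[idx].astype(np.float64) if "expr" in streams else None,
    }


def _labels_for(features: FeatureSet, idx: np.ndarray, heads) -> dict[str, np.ndarray]:
    lab = {"arousal": features.arousal[idx], "valence": features.valence[idx]}
    return {h: lab[h] for h in heads}


def _walk_tensors(obj, prefix=""):
    if isinstance(obj, dict):
        for k, v in obj.items():
            yield from _walk_tensors(v, f"{prefix}{k}/")
    elif hasattr(obj, "data") or isinstance(obj, np.ndarray):
        yield prefix.rstrip("/"), getattr(obj, "data", obj)


def _check_finite(out: dict, loss_val: float, epoch: int) -> None:
    if np.isfinite(loss_val):
        return
    for stage in ("branch_features", "sf", "posteriors"):
        for name, data in _walk_tensors(out.get(stage), f"{stage}/"):
            if data is not None and not np.all(np.isfinite(np.asarray(data, float))):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: first non-finite stage '{name}'"
                )
    raise RuntimeError(f"non-finite loss at epoch {epoch} (loss={loss_val})")


@dataclass
class TrainResult:
    """One trained network per emotion dimension (head)."""

    models: dict[str, MultimodalEmotionNet]
    log: dict[str, list[dict]]
    run_config: RunConfig


def train(
    cfg: RunConfig,
    features: FeatureSet,
    log_path: str | Path | None = None,
) -> TrainResult:
    """Mini-batch Adam training on extracted features.

    Arousal and valence are separate dimensional experiments: one model
    is trained per requested head (they share nothing but the input
    features), which keeps each cosine-margin objective free of the
    other dimension's conflicting gradients.
    """
    n = len(features)
    if n == 0:
        raise ValueError("empty dataset")
    models: dict[str, MultimodalEmotionNet] = {}
    logs: dict[str, list[dict]] = {}
    for head in cfg.heads:
        rng = np.random.default_rng(cfg.seed)
        n_val = int(round(cfg.val_fraction * n))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        head_cfg = RunConfig(**{**asdict(cfg), "heads": (head,)})
        model = build_model(head_cfg, features, rng)
        opt = Adam(model.parameters(), lr=cfg.learning_rate)
        log: list[dict] = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(tr_idx)
            comps = np.zeros(4)
            n_batches = 0
            for start in range(0, len(order), cfg.batch_size):
                bidx = order[start : start + cfg.batch_size]
                out = model.forward(
                    train=True, rng=rng, **_batch_inputs(features, bidx, cfg.streams)
                )
                lb = model.loss(out, _labels_for(features, bidx, (head,)))
                _check_finite(out, lb.total.item(), epoch)
                opt.zero_grad()
                lb.total.backward()
                if cfg.grad_clip > 0:
                    opt.clip_global_norm(cfg.grad_clip)
                opt.step()
                comps += [lb.loss_F.item(), lb.loss_SF.item(), lb.loss_DF.item(),
                          lb.total.item()]
                n_batches += 1
            comps /= max(n_batches, 1)
            row = {
                "epoch": epoch,
                "head": head,
                "loss_F": comps[0],
                "loss_SF": comps[1],
                "loss_DF": comps[2],
                "total": comps[3],
            }
            if len(val_idx):
                val_rep = _evaluate_one(model, features.subset(val_idx), head)
                row["val_ra"] = val_rep["ra"]
            log.append(row)
        models[head] = model
        logs[head] = log
    if log_path is not None:
        rows = [r for head in cfg.heads for r in logs[head]]
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    return TrainResult(models, logs, cfg)


def _evaluate_one(model: MultimodalEmotionNet, features: FeatureSet, head: str) -> dict:
    out = model.forward(
        train=False,
        **_batch_inputs(features, np.arange(len(features)), model.cfg.streams),
    )
    pred = model.predict(out)[head]
    truth = {"arousal": features.arousal, "valence": features.valence}[head]
    counts = micro_counts(truth, pred)
    rep = {
        "ra": recognition_accuracy(counts),
        "f1_micro": f1_score(counts),
        "f1_macro": macro_f1(truth, pred, model.cfg.n_classes),
        "r2": r_squared(truth.astype(float), pred.astype(float)),
    }
    if out["attention"] is not None:
        rep["attention"] = out["attention"]
    return rep


def evaluate_features(
    result: TrainResult,
    features: FeatureSet,
    cfg: RunConfig | None = None,
    attention_dir: str | Path | None = None,
) -> dict:
    """Metrics report per head, plus optional attention-weight exports."""
    if len(features) == 0:
        raise ValueError("empty evaluation set")
    cfg = result.run_config if cfg is None else cfg
    report: dict = {}
    for head, model in result.models.items():
        rep = _evaluate_one(model, features, head)
        attention = rep.pop("attention", None)
        report[head] = rep
        if attention is not None and "attention_mean" not in report:
            report["attention_mean"] = attention.mean(axis=(0, 1)).tolist()
            if attention_dir is not None:
                attention_dir = Path(attention_dir)
                attention_dir.mkdir(parents=True, exist_ok=True)
                for i in range(attention.shape[0]):
                    export_attention_csv(
                        attention_dir / f"trial_{i:04d}_attention.csv", attention[i]
                    )
    return report


# ---------------------------------------------------------------------------
# checkpoints: a zip holding one .npy per parameter plus a JSON manifest
# ---------------------------------------------------------------------------

def _flatten_params(tree, prefix="") -> dict[str, np.ndarray]:
    from .autodiff import Tensor

    flat = {}
    if isinstance(tree, Tensor):
        flat[prefix.rstrip("/")] = tree.data
    elif isinstance(tree, dict):
        for k, v in tree.items():
            flat.update(_flatten_params(v, f"{prefix}{k}/"))
    return flat


def save_checkpoint(path: str | Path, result: TrainResult) -> None:
    flat = {}
    for head, model in result.models.items():
        flat.update(_flatten_params(model.modules, f"{head}/"))
    manifest = {
        "run_config": {
            **asdict(result.run_config),
            "streams": list(result.run_config.streams),
            "heads": list(result.run_config.heads),
        },
        "shapes": {k: list(v.shape) for k, v in flat.items()},
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))
        for k, v in flat.items():
            buf = io.BytesIO()
            np.save(buf, v)
            zf.writestr(k.replace("/", "__") + ".npy", buf.getvalue())


def load_checkpoint(path: str | Path, features: FeatureSet) -> TrainResult:
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        rc = manifest["run_config"]
        cfg = RunConfig(**{**rc, "streams": tuple(rc["streams"]),
                           "heads": tuple(rc["heads"])})
        models = {}
        flat = {}
        for head in cfg.heads:
            head_cfg = RunConfig(**{**asdict(cfg), "heads": (head,)})
            model = build_model(head_cfg, features, np.random.default_rng(cfg.seed))
            models[head] = model
            flat.update(_flatten_params(model.modules, f"{head}/"))
        for k, shape in manifest["shapes"].items():
            if k not in flat:
                raise ValueError(f"checkpoint parameter {k} unknown to this model")
            arr = np.load(io.BytesIO(zf.read(k.replace("/", "__") + ".npy")))
            if list(arr.shape) != shape or arr.shape != flat[k].shape:
                raise ValueError(f"shape-incompatible checkpoint entry {k}")
            flat[k][...] = arr
    return TrainResult(models, {h: [] for h in cfg.heads}, cfg)
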