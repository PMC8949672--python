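"""End-to-end orchestration of the four pipeline blocks.

segment -> scalogram -> network training / SFV extraction -> CoF reduction
-> classifier -> evaluation report, with stratified splitting, one root seed
fanned out into named substreams, and artifact persistence.

No information from the test split reaches any fitted component: beats are
z-scored per beat (no global statistics), the network trains on the training
split, and the CoF vocabulary is fitted on training descriptors only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import ClassifierSpec, fit as clf_fit, predict as clf_predict
from .cof import fit_transform_split
from .cwt import WaveletConfig, beat_to_scalogram
from .metrics import EvalReport, report as eval_report
from .net import NetConfig, Network, TrainConfig, extract_sfvs, train
from .preprocess import Beat, ECGRecord, segment_beats, zscore
from .synth import SynthDataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "split_data", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    test_fraction: float = 0.30
    cv_folds: int | None = None  # None -> holdout; 10 is the CV variant
    zscore_beats: bool = True
    window: float = 1.0
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    net: NetConfig = field(default_factory=NetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    cof_k: int | str = "auto"
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.cv_folds is not None and self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2 when enabled")
        if self.wavelet.output_side != self.net.input_side:
            raise ValueError(
                f"scalogram side {self.wavelet.output_side} must equal "
                f"network input side {self.net.input_side}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "wavelet" in d and isinstance(d["wavelet"], dict):
            d["wavelet"] = WaveletConfig(**d["wavelet"])
        if "net" in d and isinstance(d["net"], dict):
            nd = dict(d["net"])
            if "conv_channels" in nd:
                nd["conv_channels"] = tuple(nd["conv_channels"])
            d["net"] = NetConfig(**nd)
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        if "classifier" in d and isinstance(d["classifier"], dict):
            d["classifier"] = ClassifierSpec(**d["classifier"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _named_seed(seed: int, which: str) -> int:
    """Named child seed below 2**31, derived deterministically from the root."""
    offsets = {"split": 1, "init": 2, "shuffle": 3, "kmeans": 4, "clf": 5}
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(offsets[which],))
    return int(ss.generate_state(1)[0] % (2**31))


def split_data(labels, test_fraction: float = 0.30, cv_folds: int | None = None,
               seed: int = 0):
    """Stratified index split.

    Holdout: returns (train_idx, test_idx) with per-class test counts
    round(n_c * test_fraction), clamped so each class keeps >= 1 training
    member.  CV: returns a list of (train_idx, test_idx) pairs with disjoint
    test folds; classes with fewer than 2 members stay in training for every
    fold (with a warning).
    """
    labels = np.asarray(list(labels))
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to split")
    rng = np.random.default_rng(seed)
    if cv_folds is None:
        train_idx, test_idx = [], []
        for c in classes:
            idx = rng.permutation(np.flatnonzero(labels == c))
            n_test = int(round(test_fraction * idx.size))
            n_test = min(n_test, idx.size - 1)
            test_idx.append(idx[:n_test])
            train_idx.append(idx[n_test:])
        return (np.sort(np.concatenate(train_idx)),
                np.sort(np.concatenate(test_idx)))
    fold_members: list[list[int]] = [[] for _ in range(cv_folds)]
    always_train: list[int] = []
    for c in classes:
        idx = rng.permutation(np.flatnonzero(labels == c))
        if idx.size < 2:
            warnings.warn(
                f"class {c!r} has {idx.size} member(s); kept in training for "
                "all folds"
            )
            always_train.extend(idx.tolist())
            continue
        for j, i in enumerate(idx):
            fold_members[j % cv_folds].append(int(i))
    folds = []
    all_idx = np.arange(labels.size)
    for f in range(cv_folds):
        test = np.sort(np.array(fold_members[f], dtype=int))
        train = np.setdiff1d(all_idx, test)
        folds.append((train, test))
    return folds


@dataclass
class PipelineResult:
    report: EvalReport
    config: PipelineConfig
    loss_trace: list[float]
    network: Network | None
    vocabulary: object
    classifier: object
    labels_true: list[str]
    labels_pred: list[str]
    classes: list[str]
    manifest: dict


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _ctx()


class _StageError(RuntimeError):
    pass


def _to_beats(data, config: PipelineConfig) -> list[Beat]:
    if isinstance(data, SynthDataset):
        return [
            Beat(samples=s, source_record=f"synth{i}", index=0, label=lab,
                 fs=data.fs)
            for i, (s, lab) in enumerate(data.beats)
        ]
    beats: list[Beat] = []
    for rec in data:
        beats.extend(segment_beats(rec, window=config.window))
    return beats


def run_pipeline(data, config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute the full pipeline on a SynthDataset or a list of ECGRecords.

    With ``cv_folds`` unset, a stratified holdout split is used and the
    report evaluates the test split; with CV enabled every fold is evaluated
    and the pooled predictions are reported (the fitted artifacts are those
    of the last fold).
    """
    with _stage("segment"):
        beats = _to_beats(data, config)
        if config.zscore_beats:
            for b in beats:
                b.samples = zscore(b.samples)
        labels = [b.label for b in beats]
        if any(l is None for l in labels):
            raise ValueError("all beats must be labelled for supervised runs")
        classes = sorted(set(labels))

    with _stage("cwt"):
        images = np.stack(
            [beat_to_scalogram(b, config.wavelet).pixels for b in beats]
        )

    with _stage("split"):
        if config.cv_folds is None:
            splits = [split_data(labels, config.test_fraction,
                                 seed=_named_seed(config.seed, "split"))]
        else:
            splits = split_data(labels, cv_folds=config.cv_folds,
                                seed=_named_seed(config.seed, "split"))

    labels_arr = np.asarray(labels)
    all_true: list[str] = []
    all_pred: list[str] = []
    network = vocab = model = None
    loss_trace: list[float] = []
    for train_idx, test_idx in splits:
        with _stage("train-net"):
            network = Network(config.net, seed=_named_seed(config.seed, "init"))
            tc = dataclasses.replace(
                config.train,
                seed=_named_seed(config.seed, "shuffle"),
                batch_size=min(config.train.batch_size, len(train_idx)),
            )
            loss_trace = train(network, images[train_idx], labels_arr[train_idx],
                               tc)
        with _stage("extract-sfv"):
            sfv_train = extract_sfvs(network, images[train_idx])
            sfv_test = extract_sfvs(network, images[test_idx])
        with _stage("cof"):
            rfv_train, rfv_test, vocab = fit_transform_split(
                sfv_train, sfv_test, config.net, k=config.cof_k,
                seed=_named_seed(config.seed, "kmeans"),
                train_labels=labels_arr[train_idx],
                test_labels=labels_arr[test_idx],
            )
        with _stage("classify"):
            spec = dataclasses.replace(config.classifier,
                                       seed=_named_seed(config.seed, "clf"))
            model = clf_fit(spec, rfv_train, labels_arr[train_idx])
            pred = clf_predict(model, rfv_test)
        all_true.extend(labels_arr[test_idx].tolist())
        all_pred.extend(pred)

    with _stage("evaluate"):
        rep = eval_report(all_true, all_pred, classes)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "substreams": {k: _named_seed(config.seed, k)
                       for k in ("split", "init", "shuffle", "kmeans", "clf")},
        "n_beats": len(beats),
        "classes": classes,
        "attention_enabled": config.net.attention_enabled,
    }
    result = PipelineResult(
        report=rep, config=config, loss_trace=loss_trace, network=network,
        vocabulary=vocab, classifier=model, labels_true=all_true,
        labels_pred=all_pred, classes=classes, manifest=manifest,
    )
    if outdir is not None:
        _persist(result, Path(outdir))
    return result


def _persist(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.json", "w") as fh:
        json.dump(result.config.to_dict(), fh, indent=1, default=str)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1)
    with open(outdir / "loss_trace.json", "w") as fh:
        json.dump(result.loss_trace, fh)
    result.report.to_json(outdir / "report.json")
    result.report.confusion.to_frame().to_csv(outdir / "confusion.csv")
    if result.vocabulary is not None:
        np.savez(outdir / "vocabulary.npz",
                 centroids=result.vocabulary.centroids)
        with open(outdir / "vocabulary.json", "w") as fh:
            json.dump({"k": result.vocabulary.k,
                       "seed": result.vocabulary.fit_seed,
                       "sse": result.vocabulary.sse}, fh, indent=1)
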