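"""Metrics and the leave-one-domain-out (LODO) evaluation protocol.

Sensitivity Se = TP/(TP+FN) (abnormal recall), specificity Sp = TN/(TN+FP)
(normal recall) and their mean MAcc = (Se+Sp)/2 — the heart-sound challenge's
headline score.  The LODO protocol holds one acquisition-device domain out
per fold while the dominant domain (the "always-train" set) stays in every
training split; validation accuracies are summarised as mean +/- population
standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import (MelFilterbank, StftConfig, build_mel_filterbank,
                       extract_feature_map)
from .io_preprocess import (ABNORMAL, NORMAL, AudioRecording,
                            PreprocessConfig, preprocess)
from .model import (ArchitectureSpec, TrainConfig, VGGStyleCNN, predict,
                    train)

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "ProtocolSpec",
    "FoldResult",
    "EvalReport",
    "SegmentDataset",
    "confusion",
    "metrics_from_confusion",
    "mean_population_sd",
    "extract_segment_dataset",
    "run_lodo",
    "compare_flavors",
    "FlavorComparison",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with *abnormal* as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Metrics:
    se: float
    sp: float
    macc: float

    def __post_init__(self) -> None:
        if abs(self.macc - (self.se + self.sp) / 2.0) > 1e-12:
            raise ValueError("macc must equal (se + sp) / 2")


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FN/TN/FP over string labels (abnormal positive)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    valid = {NORMAL, ABNORMAL}
    bad = (set(np.unique(y_true)) | set(np.unique(y_pred))) - valid
    if bad:
        raise ValueError(f"labels outside {sorted(valid)}: {sorted(bad)}")
    pos_t, pos_p = y_true == ABNORMAL, y_pred == ABNORMAL
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)), fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)), fp=int(np.sum(~pos_t & pos_p)))


def metrics_from_confusion(c: ConfusionCounts) -> Metrics:
    if c.tp + c.fn == 0:
        raise ValueError("no abnormal records: sensitivity undefined")
    if c.tn + c.fp == 0:
        raise ValueError("no normal records: specificity undefined")
    se = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    return Metrics(se=se, sp=sp, macc=(se + sp) / 2.0)


def mean_population_sd(values) -> tuple[float, float]:
    """Mean and *population* standard deviation (divide by n)."""
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=0))


@dataclass(frozen=True)
class ProtocolSpec:
    """LODO folds: each fold trains on ``train_domains`` and tests on the
    held-out ``test_domain``; ``always_train_domains`` must appear in every
    training set and never as a test domain."""

    folds: tuple[tuple[tuple[str, ...], str], ...]
    always_train_domains: frozenset[str] = frozenset()
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        for train_doms, test_dom in self.folds:
            if test_dom in train_doms:
                raise ValueError(
                    f"test domain {test_dom!r} appears in its own train set")
            if test_dom in self.always_train_domains:
                raise ValueError(
                    f"domain {test_dom!r} is always-train and cannot be tested")
            missing = self.always_train_domains - set(train_doms)
            if missing:
                raise ValueError(
                    f"always-train domains {sorted(missing)} missing from a fold")

    @classmethod
    def leave_one_out(cls, domains, always_train=(), seeds=(0,)) -> "ProtocolSpec":
        domains = tuple(domains)
        always = frozenset(always_train)
        folds = tuple(
            (tuple(d for d in domains if d != dom), dom)
            for dom in domains if dom not in always)
        return cls(folds=folds, always_train_domains=always,
                   seeds=tuple(seeds))


@dataclass(frozen=True)
class SegmentDataset:
    """Model-ready feature maps for every segment of a dataset (one flavor)."""

    X: np.ndarray             # (n_segments, n_mels, n_frames) float32
    labels: np.ndarray        # str
    record_ids: np.ndarray    # parent recording id
    domain_ids: np.ndarray
    flavor: str

    def subset(self, mask: np.ndarray) -> "SegmentDataset":
        return SegmentDataset(self.X[mask], self.labels[mask],
                              self.record_ids[mask], self.domain_ids[mask],
                              self.flavor)

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.domain_ids)))


def extract_segment_dataset(records: list[AudioRecording], flavor: str,
                            pre_cfg: PreprocessConfig | None = None,
                            stft_cfg: StftConfig | None = None,
                            fb: MelFilterbank | None = None,
                            align: str = "none") -> SegmentDataset:
    """Preprocess + segment + featurize a list of recordings."""
    pre_cfg = pre_cfg or PreprocessConfig()
    stft_cfg = stft_cfg or StftConfig()
    if fb is None:
        fb = build_mel_filterbank(n_fft=stft_cfg.n_fft, fs=pre_cfg.target_fs)
    maps, labels, rec_ids, domains = [], [], [], []
    for rec in records:
        for seg in preprocess(rec, pre_cfg, align=align):
            fm = extract_feature_map(seg, flavor=flavor, stft_cfg=stft_cfg, fb=fb)
            maps.append(fm.values.astype(np.float32))
            labels.append(rec.label)
            rec_ids.append(rec.record_id)
            domains.append(rec.domain_id)
    if not maps:
        raise ValueError("no segments produced from the given recordings")
    return SegmentDataset(np.stack(maps), np.array(labels),
                          np.array(rec_ids, dtype=object),
                          np.array(domains), flavor)


@dataclass
class FoldResult:
    test_domain: str
    seed: int
    metrics: Metrics                  # segment level
    counts: ConfusionCounts
    metrics_record: Metrics | None    # majority vote per recording
    val_accuracy: float


@dataclass
class EvalReport:
    flavor: str
    folds: list[FoldResult]
    protocol: ProtocolSpec

    @property
    def val_mean_sd(self) -> tuple[float, float]:
        return mean_population_sd([f.val_accuracy for f in self.folds])

    @property
    def avg_metrics(self) -> Metrics:
        se = float(np.mean([f.metrics.se for f in self.folds]))
        sp = float(np.mean([f.metrics.sp for f in self.folds]))
        return Metrics(se=se, sp=sp, macc=(se + sp) / 2.0)

    def check_consistency(self) -> None:
        """Aggregates must be recomputable from the per-fold entries."""
        se = np.mean([f.metrics.se for f in self.folds])
        sp = np.mean([f.metrics.sp for f in self.folds])
        avg = self.avg_metrics
        assert abs(avg.se - se) < 1e-12 and abs(avg.sp - sp) < 1e-12
        assert abs(avg.macc - (se + sp) / 2) < 1e-12
        for f in self.folds:
            m = metrics_from_confusion(f.counts)
            assert abs(m.macc - f.metrics.macc) < 1e-12

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{
            "flavor": self.flavor, "test_domain": f.test_domain,
            "seed": f.seed, "se": f.metrics.se, "sp": f.metrics.sp,
            "macc": f.metrics.macc, "val_accuracy": f.val_accuracy,
        } for f in self.folds]
        return pd.DataFrame(rows)


def _record_vote(labels_pred: np.ndarray, rec_ids: np.ndarray,
                 labels_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    df = pd.DataFrame({"rec": rec_ids, "pred": labels_pred, "true": labels_true})
    # majority vote; ties go to abnormal (the safer clinical call)
    def vote(g):
        n_abn = (g == ABNORMAL).sum()
        return ABNORMAL if n_abn * 2 >= len(g) else NORMAL
    agg = df.groupby("rec").agg(pred=("pred", vote), true=("true", "first"))
    return agg["true"].to_numpy(), agg["pred"].to_numpy()


def run_lodo(dataset: SegmentDataset, protocol: ProtocolSpec,
             arch: ArchitectureSpec | None = None,
             train_cfg: TrainConfig | None = None) -> EvalReport:
    """Run the leave-one-domain-out protocol for one feature flavor.

    For each (seed, fold): train on the fold's train domains (stratified 20%
    validation split by record, oversampling on the training portion), then
    score Se/Sp/MAcc on the held-out domain at segment level and with
    majority vote per recording.  Folds whose test domain lacks one of the
    classes are skipped with a log entry.
    """
    arch = arch or ArchitectureSpec()
    train_cfg = train_cfg or TrainConfig()
    present = set(dataset.domains)
    for train_doms, test_dom in protocol.folds:
        needed = set(train_doms) | {test_dom}
        if not needed <= present:
            raise ValueError(f"domains {sorted(needed - present)} not in dataset")
    results: list[FoldResult] = []
    for seed in protocol.seeds:
        for train_doms, test_dom in protocol.folds:
            tr = dataset.subset(np.isin(dataset.domain_ids, list(train_doms)))
            te = dataset.subset(dataset.domain_ids == test_dom)
            if len(set(te.labels)) < 2:
                log.warning("fold %s (seed %d) skipped: test domain lacks a class",
                            test_dom, seed)
                continue
            cfg = TrainConfig(
                learning_rate=train_cfg.learning_rate,
                batch_size=train_cfg.batch_size, epochs=train_cfg.epochs,
                val_fraction=train_cfg.val_fraction,
                oversample=train_cfg.oversample,
                steps_per_epoch=train_cfg.steps_per_epoch, seed=seed)
            model = VGGStyleCNN(arch, seed=seed)
            result = train(model, tr.X, tr.labels, tr.record_ids, cfg)
            model.set_state(result.best_state)
            pred, _ = predict(model, te.X)
            counts = confusion(te.labels, pred)
            m_seg = metrics_from_confusion(counts)
            true_r, pred_r = _record_vote(pred, te.record_ids, te.labels)
            try:
                m_rec = metrics_from_confusion(confusion(true_r, pred_r))
            except ValueError:
                m_rec = None
            results.append(FoldResult(
                test_domain=test_dom, seed=seed, metrics=m_seg,
                counts=counts, metrics_record=m_rec,
                val_accuracy=result.best_val_acc))
    report = EvalReport(flavor=dataset.flavor, folds=results, protocol=protocol)
    report.check_consistency()
    return report


@dataclass
class FlavorComparison:
    per_fold: pd.DataFrame     # deltas log_mel - mel per (seed, test_domain)
    avg_delta: Metrics

    def to_markdown(self) -> str:
        lines = ["| test domain | seed | dSe | dSp | dMAcc |",
                 "|---|---|---|---|---|"]
        for _, r in self.per_fold.iterrows():
            lines.append(f"| {r.test_domain} | {r.seed} | {r.d_se:+.4f} "
                         f"| {r.d_sp:+.4f} | {r.d_macc:+.4f} |")
        lines.append(f"| **average** | | {self.avg_delta.se:+.4f} "
                     f"| {self.avg_delta.sp:+.4f} | {self.avg_delta.macc:+.4f} |")
        return "\n".join(lines)


def compare_flavors(report_mel: EvalReport,
                    report_logmel: EvalReport) -> FlavorComparison:
    """Per-fold and average (log_mel - mel) deltas for Se/Sp/MAcc."""
    if report_mel.protocol != report_logmel.protocol:
        raise ValueError("reports come from different protocols")
    if {report_mel.flavor, report_logmel.flavor} != {"mel", "log_mel"}:
        raise ValueError("expected one mel and one log_mel report")
    key = lambda f: (f.seed, f.test_domain)
    mel = {key(f): f for f in report_mel.folds}
    lm = {key(f): f for f in report_logmel.folds}
    if set(mel) != set(lm):
        raise ValueError("reports cover different folds")
    rows = []
    for k in sorted(mel):
        a, b = mel[k], lm[k]
        rows.append({"seed": k[0], "test_domain": k[1],
                     "d_se": b.metrics.se - a.metrics.se,
                     "d_sp": b.metrics.sp - a.metrics.sp,
                     "d_macc": b.metrics.macc - a.metrics.macc})
    df = pd.DataFrame(rows)
    d_se = float(df["d_se"].mean())
    d_sp = float(df["d_sp"].mean())
    return FlavorComparison(per_fold=df,
                            avg_delta=Metrics(se=d_se, sp=d_sp,
                                              macc=(d_se + d_sp) / 2.0))
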