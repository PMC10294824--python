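"""Run configuration: one YAML-serialisable object aggregating the
preprocessing, STFT, simulator, architecture, training and protocol
parameters, plus the global seed and output directory."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .acquisition_sim import DatasetSpec, NoiseParams, table2_spec
from .features import StftConfig
from .io_preprocess import PreprocessConfig
from .model import ArchitectureSpec, TrainConfig, small_architecture

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``dataset_scale`` scales the six-domain reference proportions;
    ``architecture`` is ``"paper"`` (widths 32/64/128) or ``"small"``
    (desk-scale widths, same 7-conv/3-pool/4-FC census).
    """

    seed: int = 0
    out_dir: str = "runs/default"
    log_level: str = "INFO"
    dataset_scale: float = 1.0 / 16.0
    record_seconds: float = 3.0
    snr_db: float = 15.0
    noise_kind: str = "pink"
    architecture: str = "small"
    flavors: tuple[str, ...] = ("mel", "log_mel")
    n_seeds: int = 3
    always_train_domains: tuple[str, ...] = ("e",)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    stft: StftConfig = field(default_factory=StftConfig)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=1e-3, batch_size=32, epochs=6))

    def dataset_spec(self) -> DatasetSpec:
        return table2_spec(
            scale=self.dataset_scale, seed=self.seed,
            record_seconds=self.record_seconds,
            noise=NoiseParams(snr_db=self.snr_db, noise_kind=self.noise_kind))

    def architecture_spec(self) -> ArchitectureSpec:
        if self.architecture == "paper":
            return ArchitectureSpec()
        if self.architecture == "small":
            return small_architecture()
        raise ValueError(f"unknown architecture {self.architecture!r}")

    def seeds(self) -> tuple[int, ...]:
        return tuple(self.seed + i for i in range(self.n_seeds))

    def configure_logging(self) -> None:
        logging.basicConfig(
            level=getattr(logging, self.log_level.upper(), logging.INFO),
            format="%(asctime)s %(levelname)s %(name)s: %(message)s")


def _to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["flavors"] = list(cfg.flavors)
    d["always_train_domains"] = list(cfg.always_train_domains)
    return d


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    for sub, cls in (("preprocess", PreprocessConfig), ("stft", StftConfig),
                     ("train", TrainConfig)):
        if sub in raw and isinstance(raw[sub], dict):
            raw[sub] = cls(**raw[sub])
    for tup in ("flavors", "always_train_domains"):
        if tup in raw:
            raw[tup] = tuple(raw[tup])
    return RunConfig(**raw)
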