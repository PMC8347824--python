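"""Run configuration: one serializable object covering paths, architecture,
training hyperparameters and phantom-generation settings, with a stable
content hash so identical configs are provably identical runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .phantom import PhantomParams, PREVALENCE_MIX


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    # architecture
    backbone: str = "resnet18"
    attention: str = "shuffle"
    num_classes: int = 4
    cbam_reduction: int = 16
    # preprocessing
    margin_threshold: float = 10.0
    resize_size: int = 270
    patch_size: int = 256
    normalization: str = "unit"
    # training
    optimizer: str = "adam"
    lr: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 0.0
    epochs: int = 8
    batch_size: int = 32
    class_weight: str | None = None
    # evaluation
    k_folds: int = 5
    # phantom generation
    n_phantoms: int = 1000
    class_mix: tuple = PREVALENCE_MIX
    noise_sd: float = 3.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_mix"] = list(self.class_mix)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "class_mix" in d:
            d = {**d, "class_mix": tuple(d["class_mix"])}
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text) or {}
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(text)
        elif path.suffix == ".json":
            data = json.loads(text)
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def phantom_params(self) -> PhantomParams:
        return PhantomParams(class_mix=tuple(self.class_mix), noise_sd=self.noise_sd, seed=self.seed)
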