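"""Flat run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Every tunable default in one flat key-value document.

    Unknown keys are rejected so a typo in a config file fails fast
    instead of silently falling back to a default.
    """

    # synthetic reference
    n_celltypes: int = 5
    n_peaks: int = 600
    cells_per_type: int = 100
    n_chroms: int = 3
    marker_fraction: float = 0.2
    marker_fold: float = 10.0
    base_rate: float = 0.1
    # pseudo-bulk simulation
    alpha: float = 1.0
    n_cells_per_sample: int = 500
    regimes: str = "random,rare,dominant,average"
    n_train_per_regime: int = 1000
    n_test: int = 50
    # model
    patch_size: int = 50
    d: int = 64
    L: int = 2
    h: int = 4
    decoder_dims: str = "64,128,256,512"
    # training: loss = w_P MSE(P) + w_M MSE(M) + w_R MSE(reconstruction)
    epochs: int = 12
    w_P: float = 1.0
    w_M: float = 5.0
    w_R: float = 1.0
    lr: float = 1e-3
    adapt_lr: float = 1e-4
    batch_size: int = 32
    patience: int = 5
    tol: float = 1e-6
    max_rounds: int = 2
    adaptive: bool = True
    # interpretability
    top_fraction: float = 0.05
    n_permutations: int = 50000
    # reproducibility: stage seeds are derived as seed + stage index
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def stage_seed(self, stage: int) -> int:
        return (self.seed + stage) % (2**31)

    def decoder_dims_list(self) -> list[int]:
        return [int(x) for x in str(self.decoder_dims).split(",")]

    def regimes_list(self) -> list[str]:
        return [r.strip().lower() for r in self.regimes.split(",") if r.strip()]
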