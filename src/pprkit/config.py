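"""Run configuration: YAML round-trip, validation, and content hashing."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All knobs of a reproducible run; YAML-serializable.

    CLI flags override config-file values. The hash covers the canonical
    sorted-key YAML dump, so semantically identical configs hash equal.
    """

    connectome_path: str | None = None
    labels_path: str | None = None
    atrophy_path: str | None = None
    csf_path: str | None = None
    csf_controls_path: str | None = None
    covariates_path: str | None = None
    volumes_path: str | None = None
    volumes_controls_path: str | None = None
    output_dir: str = "."
    laplacian_kind: str = "normalized"
    beta0: float = 0.05
    tbase_grid: tuple = (0.25, 50.0, 0.25)
    outlier_policy: str = "tukey-by-group"
    linkage_method: str = "ward"
    k_range: tuple = (2, 10)
    n_top_regions: int = 10
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.laplacian_kind not in {"normalized", "unnormalized"}:
            raise ValueError(f"unknown laplacian kind {self.laplacian_kind!r}")
        if self.beta0 <= 0:
            raise ValueError("beta0 must be > 0")
        start, stop, step = self.tbase_grid
        if start <= 0 or stop < start or step <= 0:
            raise ValueError(f"invalid tbase grid {self.tbase_grid}")
        kmin, kmax = self.k_range
        if kmin < 2 or kmax < kmin:
            raise ValueError(f"invalid k range {self.k_range}")
        if self.outlier_policy not in {"tukey-by-group", "none"}:
            raise ValueError(f"unknown outlier policy {self.outlier_policy!r}")
        self.tbase_grid = tuple(float(v) for v in self.tbase_grid)
        self.k_range = tuple(int(v) for v in self.k_range)

    def to_yaml(self, path=None) -> str:
        data = {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in asdict(self).items()
        }
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            data = yaml.safe_load(Path(source).read_text())
        else:
            data = yaml.safe_load(str(source))
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        for key in ("tbase_grid", "k_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific parameters only: file locations do not
        change what is computed, so they are excluded."""
        data = {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in asdict(self).items()
            if not k.endswith("_path") and k != "output_dir"
        }
        text = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]
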