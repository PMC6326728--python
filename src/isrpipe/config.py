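"""Pipeline configuration with YAML round-trip and range validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class PipelineConfig:
    """All tunable parameters of the single-cell pipeline stages.

    Defaults follow the published analysis where it states a value
    (K cap 750, Jaccard prune cutoff 1/15, resolution range 0.05-1.225,
    50 PCs, log10(UMI) floor 2.0, adjusted-p marker cutoff 0.05,
    assignment probability threshold 0.5) and era-standard practice
    elsewhere.
    """

    # qc
    bin_width: float = 0.05
    smooth_window: int = 7
    umi_floor: float = 2.0
    # normalization / variable genes / PCA
    scale_factor: float = 1e4
    n_bins: int = 20
    z_cutoff: float = 1.0
    mean_bounds: tuple[float, float] = (0.0125, 8.0)
    n_pcs: int = 50
    # SNN / clustering
    k_cap: int = 750
    prune_cutoff: float = 1.0 / 15.0
    res_min: float = 0.05
    res_max: float = 1.225
    res_step: float = 0.025
    min_cells: int = 10
    # markers / DE
    min_detect_frac: float = 0.1
    marker_alpha: float = 0.05
    adjust_method: str = "bonferroni"
    # celltype
    prob_threshold: float = 0.5
    # GSEA
    n_perm: int = 1000
    weight_exponent: float = 1.0
    # global
    seed: int = 0
    genotype_labels: tuple[str, str] = ("WT", "MUT")

    def validate(self) -> None:
        _require(self.bin_width > 0, "bin_width must be > 0")
        _require(self.smooth_window >= 1 and self.smooth_window % 2 == 1,
                 "smooth_window must be odd and >= 1")
        _require(self.scale_factor > 0, "scale_factor must be > 0")
        _require(self.n_bins >= 1, "n_bins must be >= 1")
        _require(self.mean_bounds[0] <= self.mean_bounds[1],
                 "mean_bounds must be ordered")
        _require(self.n_pcs >= 1, "n_pcs must be >= 1")
        _require(self.k_cap >= 1, "k_cap must be >= 1")
        _require(0 < self.prune_cutoff <= 1, "prune_cutoff must be in (0, 1]")
        _require(0 < self.res_min <= self.res_max,
                 "resolution range must be positive and ordered")
        _require(self.res_step > 0, "res_step must be > 0")
        _require(self.min_cells >= 1, "min_cells must be >= 1")
        _require(0 <= self.min_detect_frac <= 1,
                 "min_detect_frac must be in [0, 1]")
        _require(0 < self.marker_alpha < 1, "marker_alpha must be in (0, 1)")
        _require(self.adjust_method in ("bonferroni", "bh"),
                 "adjust_method must be 'bonferroni' or 'bh'")
        _require(0 < self.prob_threshold < 1,
                 "prob_threshold must be in (0, 1)")
        _require(self.n_perm >= 100, "n_perm must be >= 100")
        _require(self.weight_exponent >= 0, "weight_exponent must be >= 0")

    def resolution_grid(self):
        import numpy as np

        n = int(round((self.res_max - self.res_min) / self.res_step)) + 1
        return self.res_min + self.res_step * np.arange(n)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean_bounds"] = list(self.mean_bounds)
        d["genotype_labels"] = list(self.genotype_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "mean_bounds" in d:
            d["mean_bounds"] = tuple(d["mean_bounds"])
        if "genotype_labels" in d:
            d["genotype_labels"] = tuple(d["genotype_labels"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
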