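"""Pipeline configuration: one serializable object holding every tunable.

Defaults match the package's documented analysis choices (scar length rules,
purity/ploidy grid, signal noise model, score cutoffs 21 and 30), so an empty
config file reproduces the default pipeline.  YAML round-trips exactly:
``load_config(path)`` after ``save_config(cfg, path)`` compares equal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .genome import GenomeBuild, ScarParams, make_default_genome

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the scoring pipeline, serializable to/from YAML."""

    # genome: "default" for the built-in 22-autosome build, or a path to a
    # genome TSV (name/length/centromere_start/centromere_end)
    genome: str = "default"

    # scar length rules (bp) — see ScarParams
    loh_min_len: int = 15_000_000
    lst_min_seg: int = 10_000_000
    lst_smooth_len: int = 3_000_000
    tai_min_len: int = 11_000_000
    merge_max_gap: int = 3_000_000
    telomere_tolerance: int = 1_000_000

    # purity/ploidy search grid
    rho_min: float = 0.05
    rho_max: float = 1.0
    rho_step: float = 0.01
    psi_min: float = 1.0
    psi_max: float = 5.5
    psi_step: float = 0.05

    # signal model
    n_snps: int = 12_000
    noise_baf_sd: float = 0.03
    noise_logr_sd: float = 0.10
    gamma: float = 1.0

    # score dichotomization cutoffs
    cutoffs: tuple[int, ...] = (21, 30)

    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.rho_min < self.rho_max <= 1.0:
            raise ValueError("need 0 < rho_min < rho_max <= 1")
        if not 0.0 < self.psi_min < self.psi_max:
            raise ValueError("need 0 < psi_min < psi_max")
        if self.rho_step <= 0 or self.psi_step <= 0:
            raise ValueError("grid steps must be > 0")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be > 0")
        if min(self.noise_baf_sd, self.noise_logr_sd) < 0:
            raise ValueError("noise sds must be >= 0")
        if not self.cutoffs or any(c < 0 for c in self.cutoffs):
            raise ValueError("cutoffs must be nonnegative and nonempty")
        object.__setattr__(self, "cutoffs", tuple(int(c) for c in self.cutoffs))

    def scar_params(self) -> ScarParams:
        return ScarParams(
            loh_min_len=self.loh_min_len,
            lst_min_seg=self.lst_min_seg,
            lst_smooth_len=self.lst_smooth_len,
            tai_min_len=self.tai_min_len,
            merge_max_gap=self.merge_max_gap,
            telomere_tolerance=self.telomere_tolerance,
        )

    def rho_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.rho_min, self.rho_max + 1e-9, self.rho_step), 6
        )

    def psi_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.psi_min, self.psi_max + 1e-9, self.psi_step), 6
        )

    def load_genome(self) -> GenomeBuild:
        if self.genome == "default":
            return make_default_genome()
        from .io import read_genome

        return read_genome(self.genome)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cutoffs" in d:
            d = {**d, "cutoffs": tuple(int(c) for c in d["cutoffs"])}
        return cls(**d)

    def config_hash(self) -> str:
        """Stable hash of the canonical JSON form, for provenance records."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; ``None`` or an empty file yields the defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return PipelineConfig.from_dict(raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8"
    )
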