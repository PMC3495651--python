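"""Run configuration: one flat key=value file that fully reproduces a run."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields, replace
from pathlib import Path
from typing import Optional

from .gba import DEFAULT_ALPHA, bonferroni_coherent
from .preprocess import QcThresholds
from .votemap import RATIO_ORIENTATIONS

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    fold_threshold: float = 2.0
    friend_fraction: float = 0.05
    alpha: float = DEFAULT_ALPHA
    log_trigger: float = 25.0
    low_signal: float = 5_000.0
    out_of_range: float = 20_000_000.0
    min_coverage: float = 0.90
    ratio_cutoff: float = 0.8
    ratio_orientation: str = "self"
    universe_path: Optional[str] = None
    manifest_path: Optional[str] = None
    output_dir: str = "covote_out"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if not 0 < self.friend_fraction < 1:
            raise ValueError("friend_fraction must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.ratio_cutoff <= 1:
            raise ValueError("ratio_cutoff must be in (0, 1]")
        if self.ratio_orientation not in RATIO_ORIENTATIONS:
            raise ValueError(f"ratio_orientation must be one of {RATIO_ORIENTATIONS}")
        if not 0 <= self.min_coverage <= 1:
            raise ValueError("min_coverage must be in [0, 1]")

    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(
            log_trigger=self.log_trigger,
            low_signal=self.low_signal,
            out_of_range=self.out_of_range,
            min_coverage=self.min_coverage,
        )

    def check_alpha_coherence(self, n_genes: int) -> None:
        """Warn-level sanity check: alpha should not exceed 0.05/G."""
        if not bonferroni_coherent(self.alpha, n_genes):
            import logging
            logging.getLogger(__name__).warning(
                "alpha %g exceeds the Bonferroni level 0.05/%d = %g",
                self.alpha, n_genes, 0.05 / n_genes,
            )


_TYPES = {f.name: f.type for f in fields(RunConfig)}


def _coerce(name: str, raw: str):
    default = getattr(RunConfig(), name)
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(default, int) and not isinstance(default, bool):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw if raw != "" else None


def load_config(path, **overrides) -> RunConfig:
    """Read key=value lines; unknown keys are an error; overrides win."""
    values: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in _TYPES:
                raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
            values[key] = _coerce(key, raw.strip())
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in asdict(config).items():
            fh.write(f"{key}={'' if value is None else value}\n")
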