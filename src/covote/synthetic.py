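"""Synthetic multi-dataset expression corpora with planted ground truth.

Each dataset gets a per-gene baseline log2 level; per condition, every
planted module jointly jumps up or down (one coin and one shared sign per
module per condition) while background genes jump independently.  Replicates
add Gaussian noise, and cells are masked missing at a fixed rate.  The whole
corpus is a deterministic function of the rng seed, so tests and calibration
runs are exactly reproducible.

Values are generated directly on the log2 scale (well inside the QC window)
unless ``linear_scale`` is set, which emits 2**v to exercise the log
transform path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io import ExpressionDataset, GeneList

__all__ = [
    "CorpusParams",
    "PlantedTruth",
    "simulate_corpus",
    "null_corpus",
    "pick_tfs",
    "write_truth",
]

# Spread of per-(dataset, gene) baseline offsets; induces no co-expression
# because differential calls depend only on between-condition shifts.
_GENE_OFFSET_SD = 1.0


@dataclass(frozen=True)
class CorpusParams:
    """Parameters for :func:`simulate_corpus`."""

    G: int = 200
    D: int = 10
    conditions_per_dataset: int = 4
    replicates_per_condition: int = 2
    module_sizes: tuple[int, ...] = ()
    co_de_prob: float = 0.9
    background_de_rate: float = 0.1
    effect_size_log2: float = 2.0
    baseline_mean: float = 14.0
    noise_sd: float = 0.2
    missing_rate: float = 0.0
    rng_seed: int = 0
    linear_scale: bool = False

    def __post_init__(self) -> None:
        if self.G < 1 or self.D < 1:
            raise ValueError("G and D must be positive")
        if self.conditions_per_dataset < 2:
            raise ValueError("need at least 2 conditions per dataset")
        if self.replicates_per_condition < 1:
            raise ValueError("need at least 1 replicate per condition")
        if any(m < 2 for m in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if sum(self.module_sizes) > self.G:
            raise ValueError("modules do not fit into the gene universe")
        for name in ("co_de_prob", "background_de_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size_log2 < 1.0:
            raise ValueError(
                "effect_size_log2 must be >= 1 so planted jumps clear the 2-fold cutoff"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PlantedTruth:
    """Which genes belong to which planted module."""

    module_members: list[set[str]]
    background: set[str]

    @property
    def all_module_genes(self) -> set[str]:
        out: set[str] = set()
        for m in self.module_members:
            out |= m
        return out


def gene_symbols(G: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, G + 1)]


def simulate_corpus(params: CorpusParams):
    """Generate (datasets, truth); byte-identical for identical params.

    Returns a list of :class:`ExpressionDataset` with condition maps
    attached, plus the planted module membership.
    """
    rng = np.random.default_rng(params.rng_seed)
    genes = gene_symbols(params.G)

    module_slices: list[np.ndarray] = []
    start = 0
    for size in params.module_sizes:
        module_slices.append(np.arange(start, start + size))
        start += size
    module_genes = {i for sl in module_slices for i in sl}
    background_idx = np.array(
        [i for i in range(params.G) if i not in module_genes], dtype=np.int64
    )

    C = params.conditions_per_dataset
    R = params.replicates_per_condition
    datasets: list[ExpressionDataset] = []
    for d in range(params.D):
        base = params.baseline_mean + rng.normal(0.0, _GENE_OFFSET_SD, params.G)
        shifts = np.zeros((params.G, C))
        for sl in module_slices:
            fire = rng.random(C) < params.co_de_prob
            signs = rng.choice((-1.0, 1.0), size=C)
            shifts[np.ix_(sl, np.arange(C))] = (
                fire * signs * params.effect_size_log2
            )[np.newaxis, :]
        if background_idx.size:
            fire = rng.random((background_idx.size, C)) < params.background_de_rate
            signs = rng.choice((-1.0, 1.0), size=(background_idx.size, C))
            shifts[background_idx, :] = fire * signs * params.effect_size_log2

        samples: list[str] = []
        condition_of: dict[str, str] = {}
        cols: list[np.ndarray] = []
        for c in range(C):
            cond = f"cond{c + 1}"
            level = base + shifts[:, c]
            for r in range(R):
                sid = f"d{d + 1:03d}_{cond}_r{r + 1}"
                samples.append(sid)
                condition_of[sid] = cond
                col = level + (
                    rng.normal(0.0, params.noise_sd, params.G)
                    if params.noise_sd > 0 else 0.0
                )
                cols.append(col)
        values = np.column_stack(cols)
        if params.missing_rate > 0:
            mask = rng.random(values.shape) < params.missing_rate
            values = np.where(mask, np.nan, values)
        if params.linear_scale:
            values = 2.0 ** values
        datasets.append(
            ExpressionDataset(
                f"synth{d + 1:03d}", list(genes), samples, values, condition_of
            )
        )

    truth = PlantedTruth(
        module_members=[{genes[i] for i in sl} for sl in module_slices],
        background={genes[i] for i in background_idx},
    )
    return datasets, truth


def null_corpus(params: CorpusParams) -> list[ExpressionDataset]:
    """Corpus with independent background differential expression only."""
    datasets, _ = simulate_corpus(replace(params, module_sizes=()))
    return datasets


def pick_tfs(genes: list[str], count: int, rng_seed: int = 0) -> GeneList:
    """Designate a reproducible random subset of symbols as 'TFs'."""
    if count > len(genes):
        raise ValueError("cannot pick more TFs than genes")
    rng = np.random.default_rng(rng_seed)
    chosen = sorted(rng.choice(len(genes), size=count, replace=False))
    return GeneList("tfs", [genes[i] for i in chosen])


def write_truth(truth: PlantedTruth, path) -> None:
    """TSV of (gene, label) with label module<i> or background."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tlabel\n")
        for i, members in enumerate(truth.module_members, start=1):
            for g in sorted(members):
                fh.write(f"{g}\tmodule{i}\n")
        for g in sorted(truth.background):
            fh.write(f"{g}\tbackground\n")
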