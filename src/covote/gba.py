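"""Guilt-by-association ranking of candidate genes against a seed list.

For every gene g with at least one differential event, count k = number of
seed genes whose friend lists contain g, and score it with the right tail of
Binomial(n, p) where n is the effective seed size and p = occ(g)/G is the
background chance that g lands in a random gene's friend list.  Genes with
a p-value below alpha (default 1e-6) are flagged significant; a
randomization test over random seed lists calibrates that cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import GeneList
from .votemap import FriendTable

__all__ = [
    "GbaRecord",
    "GbaTable",
    "CalibrationReport",
    "binomial_tail",
    "count_seed_friends",
    "rank_candidates",
    "filter_tfs",
    "randomization_calibration",
    "bonferroni_coherent",
    "format_pvalue",
    "write_gba_table",
    "read_gba_table",
    "write_calibration_report",
]

log = logging.getLogger(__name__)

#: Smallest positive float; underflowed tails are clamped here, never to 0
#: (unless p == 0 forces an exact 0).
_TINY = math.ulp(0.0)

DEFAULT_ALPHA = 1e-6


def binomial_tail(k: int, n: int, p: float) -> float:
    """Right tail Pr(K >= k) for K ~ Binomial(n, p).

    Exact 1.0 at k=0 and p^n at k=n; evaluated with the regularized
    incomplete beta function in between, so values down to ~1e-300 are
    meaningful.  Underflow clamps to the smallest positive float.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability p must be in [0, 1], got {p}")
    if k == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    if k == n:
        v = p ** n
    else:
        v = float(stats.binom.sf(k - 1, n, p))
    if v <= 0.0:
        return _TINY
    return min(v, 1.0)


@dataclass
class GbaRecord:
    gene: str
    k: int
    n: int
    p: float
    pvalue: float
    significant: bool


@dataclass
class GbaTable:
    """Ranked guilt-by-association results for one seed list."""

    seed_name: str
    effective_seed: GeneList
    dropped_not_in_universe: list[str]
    dropped_no_friends: list[str]
    records: list[GbaRecord]
    alpha: float = DEFAULT_ALPHA
    excluded_no_friend_genes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def significant_genes(self) -> list[str]:
        return [r.gene for r in self.records if r.significant]


def _effective_seed(ft: FriendTable, seed: GeneList):
    """Restrict the seed to universe genes that have nonempty friend lists."""
    in_universe, dropped_universe = [], []
    for s in seed.symbols:
        (in_universe if s in ft._index else dropped_universe).append(s)
    kept, dropped_empty = [], []
    for s in in_universe:
        (kept if ft.has_friends(s) else dropped_empty).append(s)
    return kept, dropped_universe, dropped_empty


def count_seed_friends(ft: FriendTable, seed: GeneList, g: str) -> int:
    """Number of effective seed genes whose friend lists contain g."""
    kept, _, _ = _effective_seed(ft, seed)
    if not kept:
        raise ValueError(f"seed list {seed.name!r} is empty after universe restriction")
    return sum(ft.contains(s, g) for s in kept)


def rank_candidates(
    ft: FriendTable,
    seed: GeneList,
    alpha: float = DEFAULT_ALPHA,
) -> GbaTable:
    """Score every universe gene with friends against the seed list.

    Seed genes are scored like any candidate.  Genes whose own friend list
    is empty (no differential events) are excluded from the table and
    listed separately.
    """
    if not seed.symbols:
        raise ValueError("seed list is empty")
    kept, dropped_universe, dropped_empty = _effective_seed(ft, seed)
    if not kept:
        raise ValueError(
            f"seed list {seed.name!r} is empty after universe restriction"
        )
    if dropped_universe:
        log.info(
            "seed %s: %d symbols not in universe dropped", seed.name, len(dropped_universe)
        )
    if dropped_empty:
        log.info(
            "seed %s: %d symbols with empty friend lists dropped",
            seed.name, len(dropped_empty),
        )
    n = len(kept)
    G = ft.n_genes
    k = np.zeros(G, dtype=np.int64)
    for s in kept:
        idx = ft.friend_idx[ft.index_of(s)]
        k[idx[idx >= 0]] += 1

    eligible = (ft.friend_idx >= 0).any(axis=1)
    records = []
    for gi in np.nonzero(eligible)[0]:
        p = ft.occurrences[gi] / G
        pv = binomial_tail(int(k[gi]), n, float(p))
        records.append(
            GbaRecord(
                gene=ft.genes[gi],
                k=int(k[gi]),
                n=n,
                p=float(p),
                pvalue=pv,
                significant=pv < alpha,
            )
        )
    records.sort(key=lambda r: (r.pvalue, -r.k, r.gene))
    excluded = [g for g, e in zip(ft.genes, eligible) if not e]
    return GbaTable(
        seed_name=seed.name,
        effective_seed=GeneList(seed.name, kept),
        dropped_not_in_universe=dropped_universe,
        dropped_no_friends=dropped_empty,
        records=records,
        alpha=alpha,
        excluded_no_friend_genes=excluded,
    )


def filter_tfs(table: GbaTable, tfs: GeneList) -> GbaTable:
    """Restrict a ranked table to transcription factors, order preserved.

    P-values are *not* recomputed against the TF subset.
    """
    if not tfs.symbols:
        raise ValueError("transcription-factor list is empty")
    tf_set = set(tfs.symbols)
    records = [r for r in table.records if r.gene in tf_set]
    if not records:
        log.warning(
            "seed %s: no transcription factors among ranked genes", table.seed_name
        )
    return GbaTable(
        seed_name=f"{table.seed_name}|tfs",
        effective_seed=table.effective_seed,
        dropped_not_in_universe=list(table.dropped_not_in_universe),
        dropped_no_friends=list(table.dropped_no_friends),
        records=records,
        alpha=table.alpha,
        excluded_no_friend_genes=list(table.excluded_no_friend_genes),
    )


@dataclass
class CalibrationReport:
    seed_size: int
    replicates: int
    rng_seed: int
    min_pvalue: float
    pvalue_quantiles: dict[float, float]
    n_pvalues: int


def randomization_calibration(
    ft: FriendTable,
    seed_size: int,
    replicates: int,
    rng_seed: int,
    alpha: float = DEFAULT_ALPHA,
    quantiles: tuple[float, ...] = (0.001, 0.01, 0.05, 0.5),
) -> CalibrationReport:
    """Score random seed lists and aggregate the resulting p-values.

    Seeds are drawn uniformly without replacement from genes with nonempty
    friend lists; the rng_seed fully determines the output.
    """
    if seed_size < 2:
        raise ValueError("seed_size must be >= 2")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    eligible = [g for g in ft.genes if ft.has_friends(g)]
    if seed_size > len(eligible):
        raise ValueError(
            f"seed_size {seed_size} exceeds {len(eligible)} eligible genes"
        )
    rng = np.random.default_rng(rng_seed)
    pvals: list[float] = []
    for rep in range(replicates):
        chosen = rng.choice(len(eligible), size=seed_size, replace=False)
        seed = GeneList(f"random_{rep}", [eligible[i] for i in sorted(chosen)])
        table = rank_candidates(ft, seed, alpha=alpha)
        pvals.extend(r.pvalue for r in table.records)
    arr = np.asarray(pvals)
    qs = {float(q): float(np.quantile(arr, q)) for q in quantiles}
    return CalibrationReport(
        seed_size=seed_size,
        replicates=replicates,
        rng_seed=rng_seed,
        min_pvalue=float(arr.min()),
        pvalue_quantiles=qs,
        n_pvalues=len(pvals),
    )


def bonferroni_coherent(alpha: float, n_genes: int) -> bool:
    """True when alpha does not exceed the Bonferroni level 0.05/G."""
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    return alpha <= 0.05 / n_genes


def format_pvalue(p: float) -> str:
    """Scientific notation, >= 3 significant digits, float round-trip safe."""
    s = np.format_float_scientific(p, unique=True)
    mantissa, exp = s.split("e")
    if "." not in mantissa:
        mantissa += "."
    digits = sum(c.isdigit() for c in mantissa)
    if digits < 3:
        mantissa += "0" * (3 - digits)
    return mantissa + "e" + exp


def write_gba_table(table: GbaTable, path) -> None:
    """TSV: rank, gene, k, n, p_background, pvalue, significant."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rank\tgene\tk\tn\tp_background\tpvalue\tsignificant\n")
        for rank, r in enumerate(table.records, start=1):
            fh.write(
                f"{rank}\t{r.gene}\t{r.k}\t{r.n}\t{format_pvalue(r.p)}\t"
                f"{format_pvalue(r.pvalue)}\t{str(r.significant).lower()}\n"
            )


def read_gba_table(path, seed_name: str = "", alpha: float = DEFAULT_ALPHA) -> GbaTable:
    """Re-read a table written by :func:`write_gba_table`."""
    records: list[GbaRecord] = []
    n = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("rank\tgene"):
            raise ValueError(f"{path}: not a GBA table")
        for line in fh:
            _, gene, k, n_s, p, pv, sig = line.rstrip("\n").split("\t")
            n = int(n_s)
            records.append(
                GbaRecord(gene, int(k), n, float(p), float(pv), sig == "true")
            )
    seed = GeneList(seed_name or "unknown", [])
    return GbaTable(seed_name or "unknown", seed, [], [], records, alpha)


def write_calibration_report(report: CalibrationReport, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"seed_size\t{report.seed_size}\n")
        fh.write(f"replicates\t{report.replicates}\n")
        fh.write(f"rng_seed\t{report.rng_seed}\n")
        fh.write(f"n_pvalues\t{report.n_pvalues}\n")
        fh.write(f"min_pvalue\t{format_pvalue(report.min_pvalue)}\n")
        for q, v in sorted(report.pvalue_quantiles.items()):
            fh.write(f"q{q:g}\t{format_pvalue(v)}\n")
    log.info(
        "calibration: %d p-values over %d random seeds of size %d, min %.3g",
        report.n_pvalues, report.replicates, report.seed_size, report.min_pvalue,
    )
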