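"""Corpus-level vote-counting co-expression map.

Every unordered pair of distinct conditions inside a dataset is one
*comparison*.  A gene votes +1/-1 in a comparison when its log2 change is at
least log2(fold_threshold) (inclusive); a pair of genes co-votes when both
vote in the same direction.  Accumulated over the whole corpus this gives:

* ``Q[g]``   — number of comparisons where g was differentially expressed,
* ``N[a,b]`` — number of comparisons where a and b co-voted (symmetric,
  with the diagonal convention ``N[g,g] == Q[g]``),
* ``x``      — total number of comparisons.

The co-expression ratio ``r(g|s) = N[g,s] / Q[s]`` is the fraction of s's
differential events in which g co-moved; note it is not symmetric in its
arguments.  Per-gene "friend" lists are the top fraction (default 5%) of
other genes ranked by an N:Q ratio, with two orientations:

* ``"self"`` (default) — rank candidates g by ``N[g,s] / Q[g]``, each
  candidate's co-votes normalized by its *own* activity.  Globally busy
  genes must co-move specifically with s to rank highly, so planted
  co-regulated modules are recoverable downstream.
* ``"partner"`` — rank by ``N[g,s] / Q[s]``; since Q[s] is constant within
  one list this is rank-equivalent to raw N[g,s] and lets globally active
  genes crowd every list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import GeneList
from .preprocess import ConditionMatrix

__all__ = [
    "DifferentialCalls",
    "VoteMap",
    "FriendTable",
    "call_differential",
    "build_map",
    "coexpression_ratio",
    "friends_of",
    "build_friend_table",
    "global_friend_probability",
    "export_network",
    "write_edge_list",
    "write_votemap_dump",
    "all_vs_all_pair_count",
]

RATIO_ORIENTATIONS = ("self", "partner")
DEFAULT_ORIENTATION = "self"


@dataclass
class DifferentialCalls:
    """Per-gene +1/-1/0 direction calls for one condition comparison.

    Genes lacking a finite value in either condition are absent from
    ``calls``.
    """

    dataset_id: str
    comparison: tuple[str, str]
    calls: dict[str, int]


def _direction_vector(va: np.ndarray, vb: np.ndarray, log_cutoff: float):
    """Return (directions in {-1,0,+1}, observable mask) for vb vs va."""
    present = np.isfinite(va) & np.isfinite(vb)
    diff = np.where(present, vb - va, 0.0)
    d = np.zeros(va.shape, dtype=np.int8)
    d[present & (diff >= log_cutoff)] = 1
    d[present & (diff <= -log_cutoff)] = -1
    return d, present


def call_differential(
    cm: ConditionMatrix,
    cond_a: str,
    cond_b: str,
    fold_threshold: float = 2.0,
) -> DifferentialCalls:
    """Call per-gene differential direction for cond_b relative to cond_a.

    Direction is +1/-1 when |log2 change| >= log2(fold_threshold)
    (inclusive boundary), 0 otherwise; genes missing either value are
    absent.
    """
    if cond_a == cond_b:
        raise ValueError(f"cannot compare condition {cond_a!r} with itself")
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    try:
        ia = cm.conditions.index(cond_a)
        ib = cm.conditions.index(cond_b)
    except ValueError as exc:
        raise ValueError(f"unknown condition in dataset {cm.dataset_id!r}: {exc}") from None
    d, present = _direction_vector(
        cm.values[:, ia], cm.values[:, ib], math.log2(fold_threshold)
    )
    calls = {g: int(d[i]) for i, g in enumerate(cm.genes) if present[i]}
    return DifferentialCalls(cm.dataset_id, (cond_a, cond_b), calls)


@dataclass
class VoteMap:
    """Corpus-level co-vote counts over a fixed gene universe."""

    genes: list[str]
    N: np.ndarray           # (G, G) symmetric int64, diag == Q
    Q: np.ndarray           # (G,) int64
    x: int
    presence: np.ndarray    # (G,) comparisons in which the gene was observable
    _index: dict[str, int] = field(init=False, repr=False)
    _lexrank: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}
        order = np.argsort(np.asarray(self.genes, dtype=object))
        self._lexrank = np.empty(len(self.genes), dtype=np.int64)
        self._lexrank[order] = np.arange(len(self.genes))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def index_of(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"gene symbol {symbol!r} not in universe") from None

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            genes=np.asarray(self.genes, dtype=object),
            N=self.N, Q=self.Q, x=np.int64(self.x), presence=self.presence,
        )

    @classmethod
    def load(cls, path) -> "VoteMap":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                genes=[str(g) for g in z["genes"]],
                N=z["N"], Q=z["Q"], x=int(z["x"]), presence=z["presence"],
            )


def build_map(
    cms: Iterable[ConditionMatrix],
    universe: GeneList | Sequence[str],
    fold_threshold: float = 2.0,
) -> VoteMap:
    """Accumulate N, Q, x over all condition comparisons of all datasets.

    A dataset with c conditions contributes c*(c-1)/2 comparisons.  Genes
    outside the universe are ignored; the diagonal of N ends up equal to Q.
    """
    genes = list(universe.symbols if isinstance(universe, GeneList) else universe)
    if not genes:
        raise ValueError("gene universe is empty")
    index = {g: i for i, g in enumerate(genes)}
    G = len(genes)
    N = np.zeros((G, G), dtype=np.int64)
    Q = np.zeros(G, dtype=np.int64)
    presence = np.zeros(G, dtype=np.int64)
    x = 0
    log_cutoff = math.log2(fold_threshold)
    n_datasets = 0
    for cm in cms:
        n_datasets += 1
        rows = [(i, index[g]) for i, g in enumerate(cm.genes) if g in index]
        if not rows:
            continue
        local = np.fromiter((r for r, _ in rows), dtype=np.int64)
        uni = np.fromiter((u for _, u in rows), dtype=np.int64)
        V = cm.values[local, :]
        C = len(cm.conditions)
        for i in range(C):
            for j in range(i + 1, C):
                x += 1
                d, present = _direction_vector(V[:, i], V[:, j], log_cutoff)
                presence[uni[present]] += 1
                up = uni[d == 1]
                down = uni[d == -1]
                Q[up] += 1
                Q[down] += 1
                if up.size:
                    N[np.ix_(up, up)] += 1
                if down.size:
                    N[np.ix_(down, down)] += 1
    if n_datasets == 0:
        raise ValueError("empty corpus: no condition matrices supplied")
    return VoteMap(genes, N, Q, x, presence)


def _ratio_column(vm: VoteMap, s_idx: int, orientation: str) -> np.ndarray:
    """Co-expression ratio of every gene with s (NaN where undefined)."""
    if orientation not in RATIO_ORIENTATIONS:
        raise ValueError(f"unknown ratio orientation {orientation!r}")
    col = vm.N[:, s_idx].astype(float)
    if orientation == "partner":
        q = float(vm.Q[s_idx])
        if q == 0:
            return np.full(vm.n_genes, np.nan)
        return col / q
    denom = vm.Q.astype(float)
    out = np.full(vm.n_genes, np.nan)
    np.divide(col, denom, out=out, where=denom > 0)
    return out


def coexpression_ratio(
    vm: VoteMap, g: str, s: str, orientation: str = "partner"
) -> Optional[float]:
    """r(g|s) = N(g,s)/Q(s), or None when Q(s)=0 (undefined)."""
    gi = vm.index_of(g)
    si = vm.index_of(s)
    r = _ratio_column(vm, si, orientation)[gi]
    return None if np.isnan(r) else float(r)


def _friend_order(vm: VoteMap, s_idx: int, orientation: str) -> np.ndarray:
    """Candidate indices sorted by ratio desc, N desc, symbol asc; self last."""
    ratio = _ratio_column(vm, s_idx, orientation)
    ratio = np.where(np.isnan(ratio), -np.inf, ratio)
    ratio[s_idx] = -np.inf
    ncol = vm.N[:, s_idx].copy()
    ncol[s_idx] = -1
    return np.lexsort((vm._lexrank, -ncol, -ratio))


def friends_of(
    vm: VoteMap,
    s: str,
    fraction: float = 0.05,
    orientation: str = DEFAULT_ORIENTATION,
) -> list[tuple[str, float]]:
    """Top-fraction co-expressed genes of s as (symbol, ratio) pairs.

    List length is floor(fraction * (G-1)); a gene with Q=0 has an empty
    list.  Ties at the boundary break by higher N, then lexicographic
    symbol.
    """
    if not 0 < fraction < 1:
        raise ValueError("friend fraction must be in (0, 1)")
    si = vm.index_of(s)
    if vm.Q[si] == 0:
        return []
    L = int(math.floor(fraction * (vm.n_genes - 1)))
    order = _friend_order(vm, si, orientation)[:L]
    ratio = _ratio_column(vm, si, orientation)
    return [(vm.genes[i], float(ratio[i])) for i in order]


@dataclass
class FriendTable:
    """Per-gene friend lists plus global occurrence counts.

    ``friend_idx[s]`` holds the universe indices of s's friends in rank
    order (-1 padding for genes with Q=0, whose lists are empty);
    ``occurrences[g]`` counts how many lists contain g.
    """

    genes: list[str]
    fraction: float
    friend_idx: np.ndarray     # (G, L) int32, -1 = no entry
    friend_ratio: np.ndarray   # (G, L) float
    occurrences: np.ndarray    # (G,) int64
    orientation: str = "partner"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def list_length(self) -> int:
        return self.friend_idx.shape[1]

    def index_of(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"gene symbol {symbol!r} not in universe") from None

    def friends(self, s: str) -> list[tuple[str, float]]:
        row = self.index_of(s)
        idx = self.friend_idx[row]
        valid = idx >= 0
        return [
            (self.genes[i], float(r))
            for i, r in zip(idx[valid], self.friend_ratio[row][valid])
        ]

    def has_friends(self, s: str) -> bool:
        return bool((self.friend_idx[self.index_of(s)] >= 0).any())

    def contains(self, s: str, g: str) -> bool:
        """True iff g appears in s's friend list."""
        return self.index_of(g) in self.friend_idx[self.index_of(s)]

    def occurrence(self, g: str) -> int:
        return int(self.occurrences[self.index_of(g)])

    def as_dict(self) -> dict[str, list[tuple[str, float]]]:
        return {g: self.friends(g) for g in self.genes}


def build_friend_table(
    vm: VoteMap, fraction: float = 0.05, orientation: str = DEFAULT_ORIENTATION
) -> FriendTable:
    """Apply :func:`friends_of` to every gene and tally occurrences."""
    if not 0 < fraction < 1:
        raise ValueError("friend fraction must be in (0, 1)")
    G = vm.n_genes
    L = int(math.floor(fraction * (G - 1)))
    friend_idx = np.full((G, L), -1, dtype=np.int32)
    friend_ratio = np.full((G, L), np.nan)
    for si in range(G):
        if vm.Q[si] == 0 or L == 0:
            continue
        order = _friend_order(vm, si, orientation)[:L]
        friend_idx[si] = order
        friend_ratio[si] = _ratio_column(vm, si, orientation)[order]
    flat = friend_idx[friend_idx >= 0]
    occurrences = np.bincount(flat, minlength=G).astype(np.int64)
    return FriendTable(list(vm.genes), fraction, friend_idx, friend_ratio,
                       occurrences, orientation)


def global_friend_probability(ft: FriendTable, g: str) -> float:
    """Chance that g appears in the friend list of a random gene: occ(g)/G."""
    return ft.occurrence(g) / ft.n_genes


def export_network(vm: VoteMap, cutoff: float = 0.8) -> list[tuple[str, str, float]]:
    """Undirected edges (a, b, ratio) with max(r(a|b), r(b|a)) >= cutoff.

    Each unordered pair appears once, symbols in lexicographic order, edges
    sorted lexicographically.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("ratio cutoff must be in (0, 1]")
    q = vm.Q.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(q > 0, vm.N / q[np.newaxis, :], 0.0)
    Rmax = np.maximum(R, R.T)
    iu, ju = np.triu_indices(vm.n_genes, k=1)
    keep = Rmax[iu, ju] >= cutoff
    edges = []
    for i, j in zip(iu[keep], ju[keep]):
        a, b = vm.genes[i], vm.genes[j]
        if b < a:
            a, b = b, a
        edges.append((a, b, float(Rmax[i, j])))
    edges.sort(key=lambda e: (e[0], e[1]))
    return edges


def write_edge_list(edges: list[tuple[str, str, float]], path) -> None:
    """3-column TSV (gene_a, gene_b, ratio)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_a\tgene_b\tratio\n")
        for a, b, r in edges:
            fh.write(f"{a}\t{b}\t{r:.6g}\n")


def write_votemap_dump(vm: VoteMap, path) -> None:
    """TSV dump (gene_a, gene_b, N, r(a|b), r(b|a)) for pairs with N > 0."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_a\tgene_b\tN\tr_a_given_b\tr_b_given_a\n")
        iu, ju = np.triu_indices(vm.n_genes, k=1)
        nz = vm.N[iu, ju] > 0
        for i, j in zip(iu[nz], ju[nz]):
            n = vm.N[i, j]
            rab = n / vm.Q[j] if vm.Q[j] > 0 else float("nan")
            rba = n / vm.Q[i] if vm.Q[i] > 0 else float("nan")
            fh.write(f"{vm.genes[i]}\t{vm.genes[j]}\t{n}\t{rab:.6g}\t{rba:.6g}\n")


def all_vs_all_pair_count(universe: GeneList | Sequence[str]) -> int:
    """Number of cells in the square all-vs-all gene-pair matrix (G x G)."""
    genes = list(universe.symbols if isinstance(universe, GeneList) else universe)
    return len(genes) ** 2
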