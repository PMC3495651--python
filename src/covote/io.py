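"""Readers, writers and container types for the plain-text corpus dialect.

Expression matrices are tab-separated: first column holds row identifiers
(probe ids or gene symbols), the header row holds sample ids.  Empty cells,
``NA`` and ``NaN`` denote missing values; missing cells are written back as
empty.  Condition maps and probe maps are two-column TSV; gene lists are one
symbol per line with ``#`` comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

__all__ = [
    "ParseError",
    "ExpressionDataset",
    "ProbeMap",
    "GeneList",
    "read_expression_matrix",
    "write_expression_matrix",
    "collapse_probes",
    "read_condition_map",
    "read_probe_map",
    "read_gene_list",
    "write_gene_list",
]

log = logging.getLogger(__name__)

#: Tokens accepted as missing on read.  Written back as the empty string.
MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", "na", "N/A"})


class ParseError(ValueError):
    """Malformed input file; carries the path and 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass
class ExpressionDataset:
    """One genes x samples expression matrix with optional condition labels.

    ``values`` is a float array with ``NaN`` marking missing cells.  Row ids
    are gene symbols after probe collapsing, raw probe ids before.
    """

    dataset_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    condition_of: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"dataset {self.dataset_id!r}: value matrix shape "
                f"{self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"dataset {self.dataset_id!r}: duplicate row ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError(f"dataset {self.dataset_id!r}: duplicate sample ids")
        if self.condition_of is not None:
            self._check_conditions(self.condition_of)

    def _check_conditions(self, cmap: Mapping[str, str]) -> None:
        missing = [s for s in self.samples if s not in cmap]
        if missing:
            raise ValueError(
                f"dataset {self.dataset_id!r}: samples without a condition "
                f"label: {missing[:5]}"
            )

    def attach_conditions(self, cmap: Mapping[str, str]) -> "ExpressionDataset":
        """Return a copy with condition labels attached (extra entries ignored)."""
        self._check_conditions(cmap)
        sub = {s: cmap[s] for s in self.samples}
        return ExpressionDataset(
            self.dataset_id, list(self.genes), list(self.samples),
            self.values.copy(), sub,
        )

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in order of first appearance."""
        if self.condition_of is None:
            raise ValueError(f"dataset {self.dataset_id!r}: no condition map attached")
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.condition_of[s], None)
        return list(seen)


@dataclass
class ProbeMap:
    """Probe-id -> gene-symbol mapping (possibly many-to-one)."""

    entries: dict[str, str]

    def coverage(self, probe_ids: Iterable[str]) -> float:
        """Fraction of the given probes that carry a symbol annotation."""
        probes = list(probe_ids)
        if not probes:
            return 0.0
        return sum(p in self.entries for p in probes) / len(probes)


@dataclass
class GeneList:
    """Ordered, de-duplicated list of gene symbols."""

    name: str
    symbols: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for s in self.symbols:
            seen.setdefault(s, None)
        self.symbols = list(seen)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.symbols)


def _parse_cell(token: str, path, lineno: int) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(path, lineno, f"not a number: {token!r}") from None


def read_expression_matrix(path, dataset_id: Optional[str] = None) -> ExpressionDataset:
    """Read a raw expression matrix; no transformation, row ids verbatim.

    Raises :class:`ParseError` on a malformed header, non-rectangular rows,
    duplicate row/sample ids, or zero samples.
    """
    path = Path(path)
    dataset_id = dataset_id if dataset_id is not None else path.stem
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(path, 1, "empty file")
    header = lines[0].split("\t")
    samples = [s.strip() for s in header[1:]]
    if not samples:
        raise ParseError(path, 1, "header contains no sample ids")
    if any(not s for s in samples):
        raise ParseError(path, 1, "empty sample id in header")
    if len(set(samples)) != len(samples):
        raise ParseError(path, 1, "duplicate sample id in header")

    genes: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(samples) + 1:
            raise ParseError(
                path, lineno,
                f"expected {len(samples) + 1} columns, got {len(fields)}",
            )
        rid = fields[0].strip()
        if not rid:
            raise ParseError(path, lineno, "empty row id")
        if rid in seen:
            raise ParseError(path, lineno, f"duplicate row id {rid!r}")
        seen.add(rid)
        genes.append(rid)
        rows.append([_parse_cell(tok, path, lineno) for tok in fields[1:]])
    if not genes:
        raise ParseError(path, len(lines), "no data rows")
    values = np.array(rows, dtype=float)
    return ExpressionDataset(dataset_id, genes, samples, values)


def _format_cell(v: float) -> str:
    if np.isnan(v):
        return ""
    return repr(float(v))


def write_expression_matrix(ds: ExpressionDataset, path) -> None:
    """Write the TSV dialect; finite cells round-trip bit-exactly."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(ds.samples) + "\n")
        for g, row in zip(ds.genes, ds.values):
            fh.write(g + "\t" + "\t".join(_format_cell(v) for v in row) + "\n")


def collapse_probes(ds: ExpressionDataset, probe_map: ProbeMap) -> ExpressionDataset:
    """Collapse probe-level rows to gene symbols by averaging.

    Multiple probes mapping to one symbol are averaged per sample, ignoring
    missing probe values (all missing -> missing).  Unmapped probes are
    dropped (logged at debug level).
    """
    if not probe_map.entries:
        raise ValueError("probe map is empty")
    groups: dict[str, list[int]] = {}
    n_dropped = 0
    for i, probe in enumerate(ds.genes):
        symbol = probe_map.entries.get(probe)
        if symbol is None:
            n_dropped += 1
            log.debug("dataset %s: dropping unmapped probe %r", ds.dataset_id, probe)
            continue
        groups.setdefault(symbol.strip(), []).append(i)
    if n_dropped:
        log.debug(
            "dataset %s: dropped %d unmapped probes of %d",
            ds.dataset_id, n_dropped, len(ds.genes),
        )
    symbols = list(groups)
    out = np.full((len(symbols), len(ds.samples)), np.nan)
    for r, sym in enumerate(symbols):
        block = ds.values[groups[sym], :]
        finite = np.isfinite(block)
        counts = finite.sum(axis=0)
        sums = np.where(finite, block, 0.0).sum(axis=0)
        np.divide(sums, counts, out=out[r], where=counts > 0)
        out[r, counts == 0] = np.nan
    return ExpressionDataset(
        ds.dataset_id, symbols, list(ds.samples), out, ds.condition_of,
    )


def _read_two_column(path, what: str) -> list[tuple[str, str, int]]:
    path = Path(path)
    pairs: list[tuple[str, str, int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(path, lineno, f"{what}: expected 2 columns, got {len(fields)}")
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ParseError(path, lineno, f"{what}: empty field")
            pairs.append((a, b, lineno))
    return pairs


def read_condition_map(path) -> dict[str, str]:
    """Read a sample-id -> condition-label TSV.

    A sample listed twice with the same label is accepted once; conflicting
    labels raise :class:`ParseError`.
    """
    out: dict[str, str] = {}
    for sample, cond, lineno in _read_two_column(path, "condition map"):
        if sample in out and out[sample] != cond:
            raise ParseError(
                path, lineno,
                f"sample {sample!r} has conflicting labels "
                f"{out[sample]!r} and {cond!r}",
            )
        out[sample] = cond
    return out


def read_probe_map(path) -> ProbeMap:
    """Read a probe-id -> gene-symbol TSV (conflicts keep the first entry)."""
    entries: dict[str, str] = {}
    for probe, symbol, lineno in _read_two_column(path, "probe map"):
        if probe in entries and entries[probe] != symbol:
            raise ParseError(
                path, lineno,
                f"probe {probe!r} maps to both {entries[probe]!r} and {symbol!r}",
            )
        entries[probe] = symbol
    return ProbeMap(entries)


def read_gene_list(path, name: Optional[str] = None) -> GeneList:
    """Read a one-symbol-per-line gene list; blank lines and # comments skipped."""
    path = Path(path)
    symbols: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            symbols.append(s)
    if not symbols:
        raise ParseError(path, 1, "gene list is empty after filtering")
    return GeneList(name if name is not None else path.stem, symbols)


def write_gene_list(gl: GeneList, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in gl.symbols:
            fh.write(s + "\n")
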