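"""End-to-end orchestration: read -> preprocess -> map -> friends -> ranking.

A corpus is described by a manifest TSV of
(dataset_id, expression_path, condition_map_path[, probe_map_path]).
``run_pipeline`` executes all stages, writes every table plus a QC audit log
and a run-metadata file (effective config + SHA-256 digests of all inputs),
and returns the ranked tables.  Stage failures are re-raised with the stage
name and dataset id attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

from . import io as cio
from . import gba as cgba
from . import preprocess as cpre
from . import votemap as cvm
from .config import RunConfig, save_config

__all__ = [
    "ManifestEntry",
    "PipelineError",
    "read_manifest",
    "load_corpus",
    "preprocess_corpus",
    "run_pipeline",
    "write_results",
]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage and dataset id."""


@dataclass(frozen=True)
class ManifestEntry:
    dataset_id: str
    expression_path: str
    condition_map_path: str
    probe_map_path: Optional[str] = None


def read_manifest(path) -> list[ManifestEntry]:
    path = Path(path)
    entries: list[ManifestEntry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 4):
                raise cio.ParseError(
                    path, lineno, f"manifest: expected 3 or 4 columns, got {len(fields)}"
                )
            probe = fields[3].strip() if len(fields) == 4 and fields[3].strip() else None
            entries.append(
                ManifestEntry(fields[0].strip(), fields[1].strip(), fields[2].strip(), probe)
            )
    if not entries:
        raise cio.ParseError(path, 1, "manifest lists no datasets")
    return entries


def _stage(stage: str, dataset_id: str):
    """Context wrapper that annotates exceptions with stage + dataset."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(
                    f"stage {stage!r} failed for dataset {dataset_id!r}: {exc}"
                ) from exc
            return False
    return _Ctx()


def load_corpus(entries: list[ManifestEntry], base_dir=None):
    """Read every dataset, collapse probes when a probe map is given, and
    attach condition labels.  Returns (datasets, coverage-by-dataset)."""
    base = Path(base_dir) if base_dir is not None else None

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() or base is None else base / q

    datasets: list[cio.ExpressionDataset] = []
    coverage: dict[str, float] = {}
    for e in entries:
        with _stage("read", e.dataset_id):
            ds = cio.read_expression_matrix(_resolve(e.expression_path), e.dataset_id)
            cov = 1.0
            if e.probe_map_path:
                pm = cio.read_probe_map(_resolve(e.probe_map_path))
                cov = pm.coverage(ds.genes)
                ds = cio.collapse_probes(ds, pm)
            cmap = cio.read_condition_map(_resolve(e.condition_map_path))
            ds = ds.attach_conditions(cmap)
        coverage[e.dataset_id] = cov
        datasets.append(ds)
    return datasets, coverage


def preprocess_corpus(datasets, coverage, config: RunConfig):
    """QC + replicate averaging; returns (condition matrices, QC reports)."""
    thresholds = config.qc_thresholds()
    cms: list[cpre.ConditionMatrix] = []
    reports: list[cpre.QcReport] = []
    for ds in datasets:
        with _stage("preprocess", ds.dataset_id):
            ds = cpre.maybe_log_transform(ds, log_trigger=thresholds.log_trigger)
            report = cpre.qc_filter(
                ds, probe_coverage=coverage.get(ds.dataset_id, 1.0),
                thresholds=thresholds,
            )
            reports.append(report)
            if report.kept:
                cms.append(cpre.average_replicates(ds))
            else:
                log.info(
                    "dataset %s removed by QC: %s",
                    ds.dataset_id, ";".join(report.reasons),
                )
    return cms, reports


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    seed: cio.GeneList,
    tfs: Optional[cio.GeneList] = None,
):
    """Execute the full pipeline and write all artifacts to the output dir.

    Returns (GbaTable, TF GbaTable or None).  Outputs: qc_report.tsv,
    votemap.npz, gba.tsv, tf_gba.tsv (when tfs given), network_edges.tsv,
    run_metadata.json, effective config file.
    """
    if config.universe_path is None:
        raise PipelineError("configuration names no universe file")
    if config.manifest_path is None:
        raise PipelineError("configuration names no corpus manifest")
    universe_path = Path(config.universe_path)
    manifest_path = Path(config.manifest_path)
    for p, what in ((universe_path, "universe"), (manifest_path, "manifest")):
        if not p.exists():
            raise PipelineError(f"{what} file not found: {p}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    universe = cio.read_gene_list(universe_path, name="universe")
    entries = read_manifest(manifest_path)
    datasets, coverage = load_corpus(entries, base_dir=manifest_path.parent)
    cms, reports = preprocess_corpus(datasets, coverage, config)
    cpre.write_qc_log(reports, out / "qc_report.tsv")
    if not cms:
        raise PipelineError("stage 'build_map': every dataset was removed by QC")

    with _stage("build_map", "<corpus>"):
        vm = cvm.build_map(cms, universe, fold_threshold=config.fold_threshold)
    vm.save(out / "votemap.npz")
    config.check_alpha_coherence(vm.n_genes)

    with _stage("friend_table", "<corpus>"):
        ft = cvm.build_friend_table(
            vm, fraction=config.friend_fraction, orientation=config.ratio_orientation
        )

    with _stage("rank_candidates", seed.name):
        table = cgba.rank_candidates(ft, seed, alpha=config.alpha)
    write_results(table, out / "gba.tsv")

    tf_table = None
    if tfs is not None:
        with _stage("filter_tfs", seed.name):
            tf_table = cgba.filter_tfs(table, tfs)
        write_results(tf_table, out / "tf_gba.tsv")

    with _stage("export_network", "<corpus>"):
        edges = cvm.export_network(vm, cutoff=config.ratio_cutoff)
    cvm.write_edge_list(edges, out / "network_edges.tsv")

    save_config(config, out / "run_config.txt")
    digests = {
        "universe": _sha256(universe_path),
        "manifest": _sha256(manifest_path),
    }
    base = manifest_path.parent
    for e in entries:
        for key, p in (
            ("expression", e.expression_path),
            ("conditions", e.condition_map_path),
            ("probes", e.probe_map_path),
        ):
            if p:
                q = Path(p)
                digests[f"{e.dataset_id}:{key}"] = _sha256(
                    q if q.is_absolute() else base / q
                )
    metadata = {
        "config": asdict(config),
        "input_digests": digests,
        "n_datasets_read": len(datasets),
        "n_datasets_kept": len(cms),
        "n_comparisons": vm.x,
        "n_genes": vm.n_genes,
        "seed_name": seed.name,
        "effective_seed_size": len(table.effective_seed),
        "dropped_not_in_universe": table.dropped_not_in_universe,
        "dropped_no_friends": table.dropped_no_friends,
    }
    with open(out / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return table, tf_table


def write_results(table: cgba.GbaTable, path) -> None:
    """Write a ranked table (delegates to the TSV writer)."""
    cgba.write_gba_table(table, path)
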