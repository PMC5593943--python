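"""End-to-end pipeline: classify -> map -> count -> test, with report rendering.

A run either starts from read libraries plus a reference FASTA, or from a
pre-computed category count matrix (including the built-in published
fixture).  It writes three TSV reports mirroring the published result
tables — the test hierarchy summary, the per-category table with fold
changes and filters, and the pairwise matrix — plus a JSON bundle of every
result and a run log.  Outputs are byte-stable across re-runs of the same
configuration; timestamps are confined to the log.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .catalog import CATEGORY_ORDER, Catalog, load_catalog
from .counts import (
    ASSAYS,
    CONDITIONS,
    CategoryCountMatrix,
    CountTable,
    aggregate_by_category,
)
from .mapper import AlignmentParams, CleanRead, assign_all
from .simulate import table2_fixture
from . import stats as st


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the log."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    output_dir: Path
    catalog_fasta: Path | None = None
    annotation: Path | None = None
    #: (condition, assay, path) triples; FASTA or FASTQ decided by extension.
    read_libraries: tuple[tuple[str, str, Path], ...] = ()
    #: "table2" for the built-in fixture, or a path to a matrix TSV.
    count_matrix: str | Path | None = None
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    min_total_reads: float = 50.0
    grey_zone: tuple[float, float] = (0.5, 2.0)
    alpha: tuple[float, float] = (0.05, 0.01)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_total_reads <= 0:
            raise ValueError("min_total_reads must be positive")
        if not self.grey_zone[0] < self.grey_zone[1]:
            raise ValueError("grey zone lower bound must be below the upper bound")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        align = AlignmentParams(**raw.pop("alignment", {}))
        libs = tuple(
            (d["condition"], d["assay"], Path(d["path"]))
            for d in raw.pop("read_libraries", [])
        )
        if "grey_zone" in raw:
            raw["grey_zone"] = tuple(raw["grey_zone"])
        if "alpha" in raw:
            raw["alpha"] = tuple(raw["alpha"])
        return cls(alignment=align, read_libraries=libs, **raw)


def read_library_file(path: Path, condition: str, assay: str) -> list[CleanRead]:
    """Load one clean-read library (FASTA or FASTQ; qualities ignored)."""
    fmt = "fastq" if Path(path).suffix.lower() in (".fq", ".fastq") else "fasta"
    return [
        CleanRead(rec.id, str(rec.seq), condition, assay)
        for rec in SeqIO.parse(str(path), fmt)
    ]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _chi2_entry(result: st.ChiSquareResult) -> dict:
    return {
        "chi2": round(result.statistic, 6),
        "df": result.df,
        "p_value": float(f"{result.p_value:.6e}"),
        "flag": result.flag,
        "critical_05": round(result.critical_05, 2),
        "critical_01": round(result.critical_01, 2),
    }


def differential_report(
    matrix: CategoryCountMatrix,
    min_total: float = 50.0,
    grey_zone: tuple[float, float] = (0.5, 2.0),
) -> dict:
    """All tests the matrix supports, keyed by report table.

    Per-category and pairwise tables are produced for every assay with
    both conditions present; the hierarchy table adds the per-assay
    condition tests and, when the matrix carries the full 7x4 design,
    the modification and full-design tests.
    """
    results: dict = {"hierarchy": [], "per_category": {}, "pairwise": {}, "n_tests": 0}

    def add_hierarchy(name, fn, *args):
        try:
            res = fn(*args)
        except ValueError:
            return
        results["hierarchy"].append({"test": name, **_chi2_entry(res)})
        results["n_tests"] += 1

    add_hierarchy("full_design", st.full_design_test, matrix)
    add_hierarchy("modification", st.modification_test, matrix)
    for assay in ASSAYS:
        add_hierarchy(f"condition_{assay}", st.overall_condition_test, matrix, assay)

    for assay in ASSAYS:
        if not all(matrix.has_library(c, assay) for c in CONDITIONS):
            continue
        rows = []
        for cat in CATEGORY_ORDER:
            prec = matrix.get(cat, "precocious", assay)
            norm = matrix.get(cat, "normal", assay)
            decision = st.apply_filters(prec, norm, min_total, grey_zone)
            row = {
                "category": cat.value,
                "precocious": prec,
                "normal": norm,
                "fold_change": (
                    st.fold_change(norm, prec).rounded if prec > 0 else None
                ),
                "filter": decision.status,
            }
            try:
                res = st.category_vs_rest_test(matrix, cat, assay)
                row.update(_chi2_entry(res))
                results["n_tests"] += 1
            except st.DegenerateTableError as exc:
                row.update({"chi2": None, "flag": "untestable", "note": str(exc)})
            rows.append(row)
        results["per_category"][assay] = rows

        pair_rows = []
        for i, a in enumerate(CATEGORY_ORDER):
            for b in CATEGORY_ORDER[:i]:
                try:
                    res = st.pairwise_category_test(matrix, a, b, assay)
                    entry = _chi2_entry(res)
                    results["n_tests"] += 1
                except st.DegenerateTableError as exc:
                    entry = {"chi2": None, "flag": "untestable", "note": str(exc)}
                pair_rows.append({"category_a": a.value, "category_b": b.value, **entry})
        results["pairwise"][assay] = pair_rows
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline described by ``config`` and write the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"started {time.strftime('%Y-%m-%dT%H:%M:%S')}"]
    bundle: dict = {"config": _config_dict(config)}

    count_table: CountTable | None = None
    catalog: Catalog | None = None

    if config.count_matrix is not None:
        try:
            if str(config.count_matrix) == "table2":
                matrix = table2_fixture()
            else:
                matrix = CategoryCountMatrix.from_tsv(config.count_matrix)
        except Exception as exc:
            raise StageError("count_model", f"cannot load count matrix: {exc}")
        log_lines.append(f"count matrix loaded (provenance={matrix.provenance})")
    else:
        if config.catalog_fasta is None or not config.read_libraries:
            raise StageError(
                "config", "need either a count matrix or a catalog plus read libraries"
            )
        try:
            catalog = load_catalog(config.catalog_fasta, config.annotation)
        except Exception as exc:
            raise StageError("reference_catalog", str(exc))
        log_lines.append(f"catalog: {len(catalog)} records")

        reads: list[CleanRead] = []
        for condition, assay, path in config.read_libraries:
            lib = read_library_file(path, condition, assay)
            if not lib:
                raise StageError("read_mapper", f"empty read file: {path}")
            reads.extend(lib)
        try:
            count_table, map_report = assign_all(
                reads, catalog=catalog, params=config.alignment
            )
        except Exception as exc:
            raise StageError("read_mapper", str(exc))
        bundle["mapping"] = map_report
        log_lines.append(
            "mapped: total={total} assigned={assigned} unassigned={unassigned} "
            "ambiguous={ambiguous}".format(**map_report)
        )
        try:
            matrix = aggregate_by_category(count_table, catalog)
        except Exception as exc:
            raise StageError("count_model", str(exc))

    try:
        results = differential_report(
            matrix, config.min_total_reads, config.grey_zone
        )
    except Exception as exc:
        raise StageError("differential_stats", str(exc))
    bundle["matrix"] = {
        "provenance": matrix.provenance,
        "values": {
            f"{cond}:{assay}": matrix.column(cond, assay).round(6).to_dict()
            for cond, assay in matrix.libraries
        },
    }
    bundle["results"] = results

    _write_reports(out, matrix, results, count_table)
    with open(out / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    log_lines.append(f"finished {time.strftime('%Y-%m-%dT%H:%M:%S')}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return bundle


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["alignment"] = asdict(config.alignment)
    return d


def _write_reports(out, matrix, results, count_table) -> None:
    if results["hierarchy"]:
        pd.DataFrame(results["hierarchy"]).to_csv(
            out / "table1_hierarchy.tsv", sep="\t", index=False
        )
    for assay, rows in results["per_category"].items():
        pd.DataFrame(rows).to_csv(
            out / f"table2_per_category_{assay}.tsv", sep="\t", index=False
        )
    for assay, rows in results["pairwise"].items():
        pd.DataFrame(rows).to_csv(
            out / f"table3_pairwise_{assay}.tsv", sep="\t", index=False
        )
    if count_table is not None:
        count_table.to_tsv(out / "counts_per_accession.tsv")
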