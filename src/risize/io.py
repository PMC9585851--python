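"""File I/O: analyte tables (CSV/TSV), GCT expression matrices, run reports."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import AnalytePopulation
from .errors import InputError
from .search import EstimatorConfig, SearchResult, SizeGridPoint

logger = logging.getLogger("risize")

SCHEMA_VERSION = "1"

#: rendering of the not-converged sentinel in tabular output
NC = "NC"


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_analyte_table(path, column: str) -> AnalytePopulation:
    """Load one analyte column from a delimited text file with a header row.

    The delimiter follows the extension (``.tsv``/``.txt`` → tab, else
    comma). Non-numeric and missing cells are dropped with a logged count;
    values keep file order.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except FileNotFoundError:
        raise InputError(f"file not found: {path}", code="parse-error") from None
    except Exception as e:
        raise InputError(f"could not parse {path}: {e}", code="parse-error") from None
    if column not in df.columns:
        raise InputError(
            f"column {column!r} not found in {path.name}; available: "
            f"{', '.join(map(str, df.columns))}",
            code="missing-column",
        )
    raw = df[column]
    vals = pd.to_numeric(raw, errors="coerce").dropna()
    n_dropped = len(raw) - len(vals)
    if n_dropped:
        logger.warning("dropped %d non-numeric/missing cells from column %r",
                       n_dropped, column)
    if len(vals) == 0:
        raise InputError(
            f"column {column!r} contains no numeric values", code="empty-data"
        )
    return AnalytePopulation(values=vals.to_numpy(dtype=float), analyte_name=column)


def write_population_csv(pop: AnalytePopulation, path) -> None:
    """Write a population as a one-column CSV readable by read_analyte_table."""
    pd.DataFrame({pop.analyte_name: pop.values}).to_csv(path, index=False)


def read_gct(path, gene_id: str) -> AnalytePopulation:
    """Extract one gene's expression row from a GCT v1.2/v1.3 matrix.

    A GCT file has a version line (``#1.2``/``#1.3``), a dimension line
    (rows, columns, ...), then a tab-separated table whose first two columns
    are Name and Description and whose remaining columns are samples. The
    named gene's values across samples become the population. Matching is
    case-sensitive; a miss reports near matches.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            version = fh.readline().strip()
            dim_line = fh.readline().split()
            body = pd.read_csv(fh, sep="\t")
    except FileNotFoundError:
        raise InputError(f"file not found: {path}", code="parse-error") from None
    except Exception as e:
        raise InputError(f"could not parse GCT {path}: {e}", code="parse-error") from None
    if not version.startswith("#1."):
        raise InputError(
            f"{path.name}: missing GCT version line (got {version!r})",
            code="format-error",
        )
    try:
        n_rows, n_cols = int(dim_line[0]), int(dim_line[1])
    except (IndexError, ValueError):
        raise InputError(
            f"{path.name}: malformed GCT dimension line {dim_line!r}",
            code="format-error",
        ) from None
    if len(body) != n_rows or body.shape[1] != n_cols + 2:
        raise InputError(
            f"{path.name}: dimension line says {n_rows}×{n_cols} but body is "
            f"{len(body)}×{body.shape[1] - 2}",
            code="format-error",
        )
    names = body.iloc[:, 0].astype(str)
    hit = np.flatnonzero(names.to_numpy() == gene_id)
    if hit.size == 0:
        near = [n for n in names if n.lower() == gene_id.lower()
                or gene_id.lower() in n.lower()][:5]
        hint = f"; near matches: {', '.join(near)}" if near else ""
        raise InputError(
            f"gene {gene_id!r} not found in {path.name}{hint}", code="gene-not-found"
        )
    row = body.iloc[int(hit[0]), 2:]
    values = pd.to_numeric(row, errors="coerce").dropna().to_numpy(dtype=float)
    if values.size == 0:
        raise InputError(f"gene {gene_id!r} has no numeric values", code="empty-data")
    return AnalytePopulation(values=values, analyte_name=gene_id, unit="TPM")


# ---------------------------------------------------------------------------
# Run reports


@dataclass
class RunReport:
    """Serializable record of one estimation run (all methods)."""

    input: dict
    config: dict
    results: list = field(default_factory=list)
    schema_version: str = SCHEMA_VERSION
    package_version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )


def _point_to_dict(p: SizeGridPoint) -> dict:
    d = asdict(p)
    for k, v in d.items():
        if isinstance(v, float) and not np.isfinite(v):
            d[k] = None
    return d


def search_result_to_dict(res: SearchResult) -> dict:
    return {
        "method": res.method,
        "estimated_n": res.estimated_n,
        "validation": (
            None if res.validation is None else
            {"LLW_CI/W_RI": res.validation[0], "ULW_CI/W_RI": res.validation[1]}
        ),
        "trace": [_point_to_dict(p) for p in res.trace],
        "moving_sums": None if res.moving_sums is None else res.moving_sums.tolist(),
        "moving_medians": (
            None if res.moving_medians is None else res.moving_medians.tolist()
        ),
    }


def build_report(pop: AnalytePopulation, results: list[SearchResult],
                 config: EstimatorConfig, provenance: dict | None = None) -> RunReport:
    cfg = asdict(config)
    inp = {"analyte": pop.analyte_name, "unit": pop.unit, "n": pop.n}
    inp.update(provenance or {})
    return RunReport(
        input=inp, config=cfg,
        results=[search_result_to_dict(r) for r in results],
    )


def write_report(report: RunReport, path, format: str = "json") -> None:
    """Serialize a report: ``json`` (full nested document) or ``tsv`` (one
    row per method, the summary-table shape; non-convergence renders NC)."""
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(asdict(report), fh, indent=2)
            fh.write("\n")
    elif format == "tsv":
        cols = ["Analyte", "Method", "SampleSize", "LLW_CI/W_RI", "ULW_CI/W_RI"]
        rows = []
        for r in report.results:
            val = r["validation"] or {}
            fmt = lambda x: NC if x is None else f"{x:.3f}"
            rows.append({
                "Analyte": report.input.get("analyte", ""),
                "Method": r["method"],
                "SampleSize": NC if r["estimated_n"] is None else r["estimated_n"],
                "LLW_CI/W_RI": fmt(val.get("LLW_CI/W_RI")),
                "ULW_CI/W_RI": fmt(val.get("ULW_CI/W_RI")),
            })
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    else:
        raise InputError(f"unknown report format {format!r}", code="invalid-config")


def load_report(path) -> RunReport:
    """Reload a JSON report without loss of estimate, trace or validation."""
    with open(path) as fh:
        d = json.load(fh)
    return RunReport(
        input=d["input"], config=d["config"], results=d["results"],
        schema_version=d.get("schema_version", SCHEMA_VERSION),
        package_version=d.get("package_version", ""),
        created=d.get("created", ""),
    )


def input_provenance(path, extra: dict | None = None) -> dict:
    """File-level provenance (path + content hash) recorded in reports."""
    path = Path(path)
    d = {"file": str(path), "sha256": _file_sha256(path)}
    d.update(extra or {})
    return d
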