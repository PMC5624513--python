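"""Reading and writing expression matrices, edge lists and gold standards.

Expression matrices are delimited text with genes in rows: a header row of
cell identifiers and a first column of gene identifiers (``transpose``
accepts cells-in-rows files).  Gold standards use the three-column
regulator / target / flag edge-list dialect, where flag 1 marks an edge and
optional flag-0 rows are explicit negatives.  Ranked edge lists are written
as TSV with a provenance header echoing the run configuration, so a result
file records exactly how it was produced.

Also includes the qPCR preprocessing convention: expression = assumed
maximum cycle threshold minus Ct, optional per-cell normalisation by the
mean of housekeeping genes, and flooring of below-detection values.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import ALGORITHMS, Edge, RankedEdgeList
from .discretization import DISCRETIZERS
from .evaluation import GoldStandardNetwork
from .probability import ESTIMATORS

__all__ = [
    "RunConfig",
    "read_expression_matrix",
    "ct_to_expression",
    "write_expression_matrix",
    "write_ranked_edges",
    "read_ranked_edges",
    "read_gold_standard",
    "write_gold_standard",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings, echoed verbatim into output headers."""

    algorithm: str = "pidc"
    discretizer: str = "bayesian_blocks"
    estimator: str = "ml"
    edge_distribution: str = "gamma"
    tau: float = 0.1
    seed: int = 0
    top_percent: float = 100.0
    transpose: bool = False
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.discretizer not in DISCRETIZERS:
            raise ValueError(f"discretizer must be one of {DISCRETIZERS}")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")
        if self.edge_distribution not in ("gamma", "gaussian"):
            raise ValueError("edge_distribution must be gamma or gaussian")
        if not 0 <= self.tau < 1:
            raise ValueError("tau must be in [0, 1)")
        if not 0 < self.top_percent <= 100:
            raise ValueError("top_percent must be in (0, 100]")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError("invalid log level")

    def header_lines(self) -> list[str]:
        return [f"# {k}={v}" for k, v in sorted(vars(self).items())]


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    first = path.open().readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression_matrix(path, delimiter: str | None = None,
                           transpose: bool = False) -> pd.DataFrame:
    """Load a delimited genes x cells matrix with full validation.

    Rejects ragged rows, duplicate identifiers and non-numeric cells with
    1-based line numbers; warns about (but keeps) constant-valued genes.
    """
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    rows = [r for r in rows if r]
    if len(rows) < 2:
        raise ValueError(f"{path}: expected a header row and at least one data row")
    header = [c.strip() for c in rows[0][1:]]
    width = len(rows[0])
    ids, values = [], []
    for ln, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(f"{path}: line {ln}: expected {width} fields, got {len(row)}")
        ids.append(row[0].strip())
        try:
            values.append([float(v) for v in row[1:]])
        except ValueError:
            bad = next(v for v in row[1:] if not _is_float(v))
            raise ValueError(f"{path}: line {ln}: non-numeric value {bad!r}") from None
    df = _build_matrix(ids, header, np.asarray(values), path)
    if transpose:
        df = df.T
        _check_unique(df.index, "gene", path)
        _check_unique(df.columns, "cell", path)
    flat = df.index[df.nunique(axis=1) <= 1]
    if len(flat):
        logger.warning("%s: constant-valued genes (uninformative for inference): %s",
                       path, list(flat))
    return df


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def _check_unique(labels, what: str, path) -> None:
    dup = pd.Index(labels)[pd.Index(labels).duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate {what} id(s): {list(dup)}")


def _build_matrix(ids, header, values, path) -> pd.DataFrame:
    _check_unique(ids, "gene", path)
    _check_unique(header, "cell", path)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: matrix contains non-finite values")
    return pd.DataFrame(values, index=ids, columns=header)


def write_expression_matrix(data: pd.DataFrame, path, delimiter: str = "\t") -> None:
    data.to_csv(path, sep=delimiter)


def ct_to_expression(ct: pd.DataFrame, assumed_max: float = 40.0,
                     housekeeping=None, floor_value: float | None = None) -> pd.DataFrame:
    """qPCR cycle thresholds to expression: ``assumed_max - Ct``.

    If ``housekeeping`` genes are given, the per-cell mean of their
    expression is subtracted from every gene (cell-wise normalisation).
    Entries at or beyond the detection limit (Ct >= assumed_max) are set to
    ``floor_value`` when one is provided.
    """
    values = ct.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("Ct matrix contains non-finite values")
    expr = assumed_max - values
    below = values >= assumed_max
    if housekeeping is not None:
        housekeeping = [str(g) for g in housekeeping]
        missing = [g for g in housekeeping if g not in ct.index]
        if missing:
            raise ValueError(f"housekeeping gene(s) not in matrix: {missing}")
        hk_rows = [ct.index.get_loc(g) for g in housekeeping]
        expr = expr - expr[hk_rows].mean(axis=0, keepdims=True)
    if floor_value is not None:
        expr[below] = floor_value
    return pd.DataFrame(expr, index=ct.index, columns=ct.columns)


def write_ranked_edges(ranked: RankedEdgeList, path,
                       config: RunConfig | None = None) -> None:
    """TSV edge list: provenance header, then gene_a, gene_b, score, rank."""
    path = Path(path)
    with path.open("w") as fh:
        if config is not None:
            fh.write("\n".join(config.header_lines()) + "\n")
        fh.write("# genes=" + ",".join(ranked.genes) + "\n")
        fh.write("gene_a\tgene_b\tscore\trank\n")
        for rank, e in enumerate(ranked, start=1):
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.score:.17g}\t{rank}\n")


def read_ranked_edges(path) -> RankedEdgeList:
    """Read an edge list written by :func:`write_ranked_edges`."""
    path = Path(path)
    genes: tuple[str, ...] | None = None
    edges = []
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# genes="):
                    genes = tuple(line[len("# genes="):].split(","))
                continue
            parts = line.split("\t")
            if parts[0] == "gene_a":
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: expected >= 3 columns")
            try:
                score = float(parts[2])
            except ValueError:
                raise ValueError(f"{path}: line {ln}: bad score {parts[2]!r}") from None
            edges.append(Edge(parts[0], parts[1], score))
    if genes is None:
        genes = tuple(sorted({g for e in edges for g in (e.gene_a, e.gene_b)}))
    return RankedEdgeList(genes, tuple(edges))


def read_gold_standard(path, delimiter: str | None = None) -> GoldStandardNetwork:
    """Three-column edge list (regulator, target, flag): flag 1 is a
    directed edge, flag 0 an explicit known negative."""
    path = Path(path)
    positives, negatives, genes = [], [], []
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}: line {ln}: expected 3 columns, got {len(parts)}")
            src, dst, flag = parts
            if src == dst:
                raise ValueError(f"{path}: line {ln}: self-edge on {src!r}")
            if flag not in ("0", "1"):
                raise ValueError(f"{path}: line {ln}: flag must be 0 or 1, got {flag!r}")
            genes.extend((src, dst))
            (positives if flag == "1" else negatives).append((src, dst))
    if not genes:
        raise ValueError(f"{path}: no edges found")
    ordered = tuple(dict.fromkeys(genes))
    return GoldStandardNetwork(ordered, tuple(positives), tuple(negatives))


def write_gold_standard(gold: GoldStandardNetwork, path) -> None:
    with Path(path).open("w") as fh:
        for src, dst in gold.directed_edges:
            fh.write(f"{src}\t{dst}\t1\n")
        for src, dst in gold.known_negatives:
            fh.write(f"{src}\t{dst}\t0\n")
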