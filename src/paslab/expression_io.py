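"""Expression-matrix containers, file I/O and microarray-style preprocessing.

The two preprocessing steps mirror how custom-oligo microarray intensities are
prepared before pathway scoring: replicate probe signals are geometrically
averaged into one value per probe type, and samples are then quantile
normalized so every array shares one reference intensity distribution.

Intensities live on the linear (non-log) scale throughout this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .errors import ParseError

logger = logging.getLogger(__name__)

#: Default floor applied to zero intensities before taking logarithms/ratios.
DEFAULT_EPS = 1e-8

GROUP_VOCABULARY = ("case", "control", "none")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample table of nonnegative linear-scale expression values.

    Parameters
    ----------
    values
        DataFrame with unique gene identifiers as the index and unique sample
        identifiers as columns. All entries must be finite and >= 0.
    sample_annotations
        Optional DataFrame indexed by sample id with columns ``cohort`` and
        ``group`` (one of ``case``/``control``/``none``).
    """

    values: pd.DataFrame
    sample_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene rows: {dupes[:5]}")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(arr).any():
            raise ValueError("expression values contain missing entries")
        if (arr < 0).any():
            raise ValueError("negative expression values")
        if self.sample_annotations is not None:
            ann = self.sample_annotations
            if "group" in ann.columns:
                bad = set(ann["group"]) - set(GROUP_VOCABULARY)
                if bad:
                    raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cohorts(self) -> pd.Series:
        if self.sample_annotations is None or "cohort" not in self.sample_annotations:
            raise ValueError("no cohort annotations attached")
        return self.sample_annotations["cohort"].reindex(self.samples)


@dataclass
class ProbeMatrix:
    """Probe-level intensities with replicate-group and gene assignments.

    ``probe_info`` is indexed by probe id and carries ``replicate_group``
    (probes sharing an oligo sequence) and ``gene`` (empty string for probes
    with no gene assignment). ``values`` is probe-by-sample, intensities >= 0.
    """

    values: pd.DataFrame
    probe_info: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative probe intensities")
        missing = self.values.index.difference(self.probe_info.index)
        if len(missing):
            raise ValueError(f"probes without annotation: {missing[:5].tolist()}")
        for col in ("replicate_group", "gene"):
            if col not in self.probe_info.columns:
                raise ValueError(f"probe_info lacks required column {col!r}")


def _parse_numeric_block(lines, header, path, first_data_line):
    """Parse tab-separated gene rows, raising ParseError naming the bad line."""
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"duplicate sample id in header of {path}", line=first_data_line - 1)
    genes, rows = [], []
    for offset, line in enumerate(lines):
        lineno = first_data_line + offset
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, found {len(parts)}", line=lineno
            )
        genes.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"non-numeric cell: {exc}", line=lineno) from None
    return genes, sample_ids, rows


def read_expression(
    path,
    format: str = "tsv",
    annotations: str | None = None,
) -> ExpressionMatrix:
    """Read an expression table from TSV or GCT 1.2.

    Duplicate gene rows are collapsed by arithmetic mean (the number of
    collapsed groups is logged). ``annotations``, if given, is a 2- or
    3-column TSV ``sample<TAB>cohort[<TAB>group]``.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"empty file: {path}", line=1)

    if format == "tsv":
        header = lines[0].split("\t")
        genes, samples, rows = _parse_numeric_block(lines[1:], header, path, 2)
    elif format == "gct":
        if not lines[0].startswith("#1.2"):
            raise ParseError("GCT must begin with version line '#1.2'", line=1)
        try:
            n_rows, n_cols = (int(x) for x in lines[1].split("\t")[:2])
        except (ValueError, IndexError):
            raise ParseError("malformed GCT dimensions line", line=2) from None
        header = lines[2].split("\t")
        if header[:2] != ["Name", "Description"]:
            raise ParseError("GCT header must start with Name<TAB>Description", line=3)
        body = lines[3:]
        if len(body) != n_rows or len(header) - 2 != n_cols:
            raise ParseError(
                f"declared dims ({n_rows},{n_cols}) do not match body", line=2
            )
        # drop Description column, then parse as TSV
        stripped = ["\t".join([ln.split("\t", 2)[0]] + ln.split("\t")[2:]) for ln in body]
        genes, samples, rows = _parse_numeric_block(
            stripped, [header[0]] + header[2:], path, 4
        )
    else:
        raise ValueError(f"unknown format {format!r}")

    df = pd.DataFrame(rows, index=genes, columns=samples, dtype=float)
    if df.index.has_duplicates:
        n_dup_groups = int((df.index.value_counts() > 1).sum())
        logger.info("collapsing %d duplicate gene groups by arithmetic mean", n_dup_groups)
        df = df.groupby(level=0, sort=False).mean()

    ann = read_sample_annotations(annotations) if annotations else None
    return ExpressionMatrix(df, ann)


def read_sample_annotations(path) -> pd.DataFrame:
    """Read sample annotations: ``sample<TAB>cohort[<TAB>group]`` with header."""
    ann = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    ann.columns = [c.lower() for c in ann.columns]
    if "group" not in ann.columns:
        ann["group"] = "none"
    return ann


def write_expression(m: ExpressionMatrix, path, format: str = "tsv") -> None:
    """Write an expression matrix as TSV or GCT 1.2 (Description = gene id)."""
    if format == "tsv":
        m.values.to_csv(path, sep="\t", index_label="gene")
    elif format == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.shape[0]}\t{m.shape[1]}\n")
            fh.write("Name\tDescription\t" + "\t".join(map(str, m.samples)) + "\n")
            for gene, row in m.values.iterrows():
                vals = "\t".join(repr(float(x)) for x in row)
                fh.write(f"{gene}\t{gene}\t{vals}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def aggregate_probes(probes: ProbeMatrix, eps: float = DEFAULT_EPS) -> ExpressionMatrix:
    """Geometric-mean replicate probe signals into one value per probe type.

    Zero intensities are floored to ``eps`` before averaging (geometric means
    are undefined at zero); flooring events are counted and logged. Replicate
    groups whose gene assignment is empty are dropped and counted. Groups
    mapping to the same gene are then collapsed by arithmetic mean.
    """
    if probes.values.empty:
        raise ValueError("empty probe set")
    vals = probes.values.to_numpy(dtype=float)
    n_floored = int((vals < eps).sum())
    if n_floored:
        logger.info("floored %d probe intensities below eps=%g", n_floored, eps)
        vals = np.maximum(vals, eps)
    floored = pd.DataFrame(vals, index=probes.values.index, columns=probes.values.columns)

    info = probes.probe_info.reindex(floored.index)
    group_expr = floored.groupby(info["replicate_group"]).agg(gmean)
    group_gene = info.groupby("replicate_group")["gene"].first()

    gene_of = group_gene.reindex(group_expr.index).fillna("")
    unmapped = gene_of == ""
    if unmapped.any():
        logger.info("dropping %d replicate groups with no gene assignment", int(unmapped.sum()))
    mapped = group_expr.loc[~unmapped]
    out = mapped.groupby(gene_of[~unmapped].values).mean()
    out.index.name = "gene"
    return ExpressionMatrix(out)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common reference distribution.

    The reference is the vector of row-wise means of the column-sorted input.
    Within-column rank order is preserved; ties receive the arithmetic mean of
    the reference values at the tied positions. Idempotent.
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = m.values.to_numpy(dtype=float)
    reference = np.sort(X, axis=0).mean(axis=1)

    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # ties: average the reference values assigned within each tied run
        tied = pd.Series(assigned).groupby(col, sort=False).transform("mean")
        out[:, j] = tied.to_numpy()
    norm = pd.DataFrame(out, index=m.genes, columns=m.samples)
    return ExpressionMatrix(norm, m.sample_annotations)
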