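"""Expression-matrix and DEG-list I/O, kNN imputation, and a convenience DEG selector.

The two core containers are :class:`ExpressionMatrix` (genes x samples, missing
entries allowed) and :class:`DegList` (an ordered list of gene identifiers one
study declared differentially expressed).  Gene identifiers are treated as
opaque strings throughout: whether they are probe IDs or gene symbols is a
property of the upstream platform, not of this package.

``select_degs`` is a *labelled substitute* for SAM (significance analysis of
microarrays).  It ranks genes by a moderated difference statistic — a SAM-like
mean difference over a variance-stabilized standard deviation — and is provided
so that synthetic end-to-end experiments can run without external tooling.  It
does **not** reproduce SAM's permutation-based FDR machinery; analyses meant to
match published DEG lists should import externally produced lists instead,
which are first-class inputs everywhere in this package.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError, FormatError, ImputationError

MISSING_TOKENS = ["", "NA", "NaN", "nan", "null", "NULL"]


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued matrix; missing entries are NaN."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise FormatError(f"duplicate gene identifiers: {sorted(dup_g)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise FormatError(f"duplicate sample identifiers: {sorted(dup_s)}")
        if len(self.sample_ids) < 2:
            raise FormatError("an expression matrix needs at least 2 samples")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class DegList:
    """An ordered, duplicate-free list of differentially expressed gene IDs."""

    gene_ids: list[str]
    source_label: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        dup = _duplicates(self.gene_ids)
        if dup:
            raise FormatError(f"duplicate genes in DEG list: {sorted(dup)}")
        if not self.gene_ids:
            raise FormatError("a DEG list must contain at least one gene")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)

    def as_set(self) -> set[str]:
        return set(self.gene_ids)


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def read_expression(path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from tab-separated text.

    ``format="tsv"``: first column gene IDs, header row sample IDs.
    ``format="series_matrix"``: GEO series-matrix style — only lines between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` are parsed,
    every other (metadata) line is skipped.

    Missing-value tokens ("", "NA", "NaN", "null") map to NaN.  Duplicate gene
    IDs or non-numeric cells raise :class:`FormatError`.
    """
    if format == "tsv":
        with open(path, "rt", encoding="utf-8") as fh:
            text = fh.read()
    elif format == "series_matrix":
        text = _extract_series_matrix_table(path)
    else:
        raise ValueError(f"unknown expression format: {format!r}")

    df = pd.read_csv(
        io.StringIO(text), sep="\t", index_col=0, dtype=str,
        keep_default_na=False, quotechar='"',
    )
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    dup = _duplicates(list(df.index))
    if dup:
        raise FormatError(f"duplicate gene identifiers in {path}: {sorted(dup)}")

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].str.strip().str.strip('"')
        num = pd.to_numeric(raw.where(~raw.isin(MISSING_TOKENS)), errors="coerce")
        bad = num.isna() & ~raw.isin(MISSING_TOKENS)
        if bad.any():
            g = df.index[bad.to_numpy()][0]
            raise FormatError(
                f"non-numeric cell at gene {g!r}, sample {col!r}: {raw[bad].iloc[0]!r}"
            )
        values[:, j] = num.to_numpy(dtype=float)
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def _extract_series_matrix_table(path) -> str:
    lines: list[str] = []
    inside = False
    seen = False
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("!series_matrix_table_begin"):
                inside, seen = True, True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                inside = False
                continue
            if inside and stripped:
                lines.append(line)
    if not seen:
        raise FormatError(f"no series_matrix table delimiters found in {path}")
    return "".join(lines)


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write the TSV dialect read by :func:`read_expression` (NaN -> "NA")."""
    df = expr.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_deg_list(path, source_label: str | None = None) -> DegList:
    """Read a DEG list: one gene identifier per line, blanks ignored."""
    with open(path, "rt", encoding="utf-8") as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return DegList(genes, source_label=source_label or str(path))


def write_deg_list(degs: DegList, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for g in degs.gene_ids:
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# kNN imputation
# ---------------------------------------------------------------------------

def knn_impute(expr: ExpressionMatrix, k: int = 15) -> ExpressionMatrix:
    """Impute missing cells gene-wise by k nearest neighbours.

    A missing cell (g, s) is replaced by the unweighted mean, over the k genes
    nearest to g, of their values in sample s.  Distance between two genes is
    the Euclidean distance over the samples where *both* are observed; ties are
    broken by lexicographic gene-identifier order.  Only genes observed at
    sample s are eligible donors.  Observed cells pass through unchanged.

    Raises :class:`ImputationError` for a gene with no observed values.  If k
    is at least the number of other genes, all available donors are used with
    a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = expr.values.copy()
    obs = ~np.isnan(X)
    all_missing = np.where(~obs.any(axis=1))[0]
    if all_missing.size:
        raise ImputationError(
            f"gene(s) with all values missing: {[expr.gene_ids[i] for i in all_missing]}"
        )
    if not np.isnan(X).any():
        return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), X)
    if k >= expr.n_genes - 1:
        warnings.warn(
            f"k={k} >= number of other genes ({expr.n_genes - 1}); "
            "using all available genes as neighbours",
            stacklevel=2,
        )
        k = expr.n_genes - 1

    Xz = np.where(obs, X, 0.0)
    # rank of each row under lexicographic gene-ID order, for tie-breaking
    id_rank = np.empty(expr.n_genes)
    id_rank[np.argsort(np.asarray(expr.gene_ids, dtype=object))] = np.arange(expr.n_genes)

    out = X.copy()
    for g in np.where(np.isnan(X).any(axis=1))[0]:
        both = obs & obs[g]                      # (G, S) mutually observed mask
        d2 = (((Xz - Xz[g]) ** 2) * both).sum(axis=1)
        order = np.lexsort((id_rank, d2))
        order = order[order != g]
        for s in np.where(np.isnan(X[g]))[0]:
            donors = order[obs[order, s]][:k]
            if donors.size == 0:  # pragma: no cover - needs a fully missing column
                raise ImputationError(
                    f"no observed donor for gene {expr.gene_ids[g]!r} "
                    f"in sample {expr.sample_ids[s]!r}"
                )
            out[g, s] = X[donors, s].mean()
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), out)


# ---------------------------------------------------------------------------
# Convenience DEG selection (labelled SAM substitute)
# ---------------------------------------------------------------------------

def select_degs(
    expr: ExpressionMatrix,
    labels: Sequence[str],
    design: str = "unpaired",
    max_genes: int = 1000,
    pairs: Sequence[str] | None = None,
    source_label: str = "select_degs",
) -> DegList:
    """Rank genes by a moderated difference statistic and keep the top ones.

    Not SAM: a deliberately simple stand-in (see module docstring).  For the
    unpaired design the statistic is ``(mean_a - mean_b) / (pooled_sd + s0)``
    with s0 the median pooled SD across genes; for the paired design it is the
    mean paired difference over its stabilized SD.  The returned list holds the
    top ``min(max_genes - 1, n_genes)`` genes, so its length is strictly fewer
    than ``max_genes``.
    """
    if max_genes < 2:
        raise ValueError("max_genes must be >= 2")
    labels = [str(x) for x in labels]
    if len(labels) != expr.n_samples:
        raise DesignError(
            f"{len(labels)} labels for {expr.n_samples} samples"
        )
    X = expr.values
    if np.isnan(X).any():
        raise DesignError("select_degs requires a complete matrix; impute first")

    if design == "unpaired":
        stat = _unpaired_stat(X, labels)
    elif design == "paired":
        if pairs is None:
            raise DesignError("paired design requires per-sample pair identifiers")
        stat = _paired_stat(X, labels, [str(p) for p in pairs])
    else:
        raise ValueError(f"unknown design: {design!r}")

    n_keep = min(max_genes - 1, expr.n_genes)
    id_rank = np.argsort(np.argsort(np.asarray(expr.gene_ids, dtype=object)))
    order = np.lexsort((id_rank, -np.abs(stat)))
    genes = [expr.gene_ids[i] for i in order[:n_keep]]
    return DegList(genes, source_label=source_label)


def _unpaired_stat(X: np.ndarray, labels: list[str]) -> np.ndarray:
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise DesignError(f"unpaired design needs exactly 2 classes, got {classes}")
    a = np.array([l == classes[0] for l in labels])
    b = ~a
    if a.sum() < 2 or b.sum() < 2:
        raise DesignError("each class needs at least 2 samples")
    ma, mb = X[:, a].mean(axis=1), X[:, b].mean(axis=1)
    va = X[:, a].var(axis=1, ddof=1)
    vb = X[:, b].var(axis=1, ddof=1)
    na, nb = int(a.sum()), int(b.sum())
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    sp = sp * np.sqrt(1.0 / na + 1.0 / nb)
    s0 = float(np.median(sp))
    return (ma - mb) / (sp + s0)


def _paired_stat(X: np.ndarray, labels: list[str], pairs: list[str]) -> np.ndarray:
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise DesignError(f"paired design needs exactly 2 conditions, got {classes}")
    by_pair: dict[str, dict[str, int]] = {}
    for i, (lab, pid) in enumerate(zip(labels, pairs)):
        slot = by_pair.setdefault(pid, {})
        if lab in slot:
            raise DesignError(f"pair {pid!r} has two {lab!r} samples")
        slot[lab] = i
    incomplete = [p for p, slot in by_pair.items() if len(slot) != 2]
    if incomplete:
        raise DesignError(f"incomplete pairs: {sorted(incomplete)}")
    if len(by_pair) < 2:
        raise DesignError("paired design needs at least 2 complete pairs")
    pids = sorted(by_pair)
    diffs = np.stack(
        [X[:, by_pair[p][classes[0]]] - X[:, by_pair[p][classes[1]]] for p in pids],
        axis=1,
    )
    md = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1) / np.sqrt(diffs.shape[1])
    s0 = float(np.median(sd))
    return md / (sd + s0)
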