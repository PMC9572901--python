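"""Reading, validating and writing gene-expression datasets and result tables.

The internal layout is always samples x genes. Input files may be oriented
either way (``orientation`` flag); class labels come from a named column of
the matrix file or from a one-column sidecar file, both common conventions
for the classic microarray benchmarks this package targets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "write_expression",
    "write_summary",
    "read_summary",
]

SUMMARY_COLUMNS = [
    "classifier",
    "n_genes",
    "best_acc",
    "average_acc",
    "worst_acc",
    "n_runs",
    "seed",
]


@dataclass
class ExpressionDataset:
    """A labelled expression matrix: ``matrix[i, j]`` is gene ``j`` in sample ``i``.

    Parameters
    ----------
    matrix : ndarray of shape (n_samples, n_genes)
        Finite real expression levels.
    gene_ids : list of str
        Unique identifier per gene (column).
    labels : ndarray of str, shape (n_samples,)
        Class label per sample; at least two distinct classes.
    class_names : list of str
        Ordered distinct labels. Order is meaningful: classifier vote ties
        break toward the earlier class. Defaults to first-appearance order.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional (samples x genes)")
        self.labels = np.asarray(self.labels, dtype=object)
        self.gene_ids = [str(g) for g in self.gene_ids]
        n_samples, n_genes = self.matrix.shape
        if n_samples < 2:
            raise ValueError(f"need at least 2 samples, got {n_samples}")
        if n_genes < 1:
            raise ValueError("need at least 1 gene")
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.labels.shape != (n_samples,):
            raise ValueError(
                f"{self.labels.shape[0]} labels for {n_samples} samples"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains NaN or Inf")
        if not self.class_names:
            seen: dict[object, None] = {}
            for lab in self.labels:
                seen.setdefault(lab, None)
            self.class_names = [str(c) for c in seen]
        self.class_names = [str(c) for c in self.class_names]
        if len(self.class_names) < 2:
            raise ValueError("need at least 2 distinct classes")
        unknown = set(map(str, self.labels)) - set(self.class_names)
        if unknown:
            raise ValueError(f"labels not in class_names: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def label_codes(self) -> np.ndarray:
        """Integer class codes in ``class_names`` order."""
        index = {c: i for i, c in enumerate(self.class_names)}
        return np.array([index[str(lab)] for lab in self.labels], dtype=np.intp)

    def subset_genes(self, indices: np.ndarray) -> "ExpressionDataset":
        """Restrict to the given gene columns, keeping original gene ids."""
        indices = np.asarray(indices, dtype=np.intp)
        return ExpressionDataset(
            matrix=self.matrix[:, indices],
            gene_ids=[self.gene_ids[i] for i in indices],
            labels=self.labels.copy(),
            class_names=list(self.class_names),
        )


def _infer_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if os.path.splitext(path)[1].lower() in (".tsv", ".txt") else ","


def _read_sidecar_labels(path: str) -> np.ndarray:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    return np.array(lines, dtype=object)


def read_expression(
    path: str,
    orientation: str = "samples_rows",
    label_source: str = "label",
    delimiter: str | None = None,
    impute_mean: bool = False,
) -> ExpressionDataset:
    """Load a delimited expression matrix with class labels.

    Parameters
    ----------
    path : str
        CSV/TSV file. For ``samples_rows`` the header row holds gene ids
        (plus optionally the label column); for ``genes_rows`` the first
        column holds gene ids and the header holds sample names.
    orientation : {'samples_rows', 'genes_rows'}
        Whether file rows are samples or genes. Internally the matrix is
        always samples x genes.
    label_source : str
        Name of the label column (``samples_rows`` only) or path to a
        one-label-per-line sidecar file.
    delimiter : str, optional
        Defaults to tab for .tsv/.txt, comma otherwise.
    impute_mean : bool
        If True, missing cells are imputed with the per-gene mean;
        otherwise any missing value is an error.
    """
    if orientation not in ("samples_rows", "genes_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _infer_delimiter(path, delimiter)
    if orientation == "samples_rows":
        # pandas silently renames duplicate header names; check the raw header
        with open(path, encoding="utf-8") as fh:
            header = [tok.strip() for tok in fh.readline().rstrip("\n").split(sep)]
        dupes = sorted({h for h in header if header.count(h) > 1})
        if dupes:
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0 if orientation == "genes_rows" else None)

    labels: np.ndarray | None = None
    if os.path.exists(label_source) and label_source != path:
        labels = _read_sidecar_labels(label_source)

    if orientation == "genes_rows":
        if labels is None:
            raise ValueError(
                f"orientation='genes_rows' needs a sidecar label file; "
                f"{label_source!r} not found"
            )
        gene_ids = [str(g) for g in df.index]
        frame = df.T  # rows become samples
    else:
        if labels is None:
            if label_source not in df.columns:
                raise ValueError(
                    f"label column {label_source!r} not found in {path} "
                    f"(columns: {list(df.columns)[:5]}...)"
                )
            labels = df[label_source].astype(str).to_numpy(dtype=object)
            df = df.drop(columns=[label_source])
        gene_ids = [str(g) for g in df.columns]
        frame = df

    values = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw = frame.to_numpy()
    bad = np.isnan(values) & ~pd.isna(raw)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric cell at sample {frame.index[i]!r}, gene {gene_ids[j]!r}: "
            f"{raw[i, j]!r}"
        )
    missing = np.isnan(values)
    if missing.any():
        if not impute_mean:
            i, j = np.argwhere(missing)[0]
            raise ValueError(
                f"missing value at sample {frame.index[i]!r}, gene {gene_ids[j]!r}; "
                "pass impute_mean=True to impute per-gene means"
            )
        col_means = np.nanmean(values, axis=0)
        values = np.where(missing, col_means[np.newaxis, :], values)

    return ExpressionDataset(matrix=values, gene_ids=gene_ids, labels=labels)


def write_expression(
    dataset: ExpressionDataset,
    path: str,
    orientation: str = "samples_rows",
    label_column: str = "label",
    delimiter: str | None = None,
) -> None:
    """Write a dataset back to delimited text (inverse of :func:`read_expression`).

    With ``samples_rows`` the labels go into ``label_column``; with
    ``genes_rows`` they go into a ``<path>.labels`` sidecar file.
    """
    sep = _infer_delimiter(path, delimiter)
    if orientation == "samples_rows":
        df = pd.DataFrame(dataset.matrix, columns=dataset.gene_ids)
        df[label_column] = [str(lab) for lab in dataset.labels]
        df.to_csv(path, sep=sep, index=False)
    elif orientation == "genes_rows":
        df = pd.DataFrame(
            dataset.matrix.T,
            index=dataset.gene_ids,
            columns=[f"s{i}" for i in range(dataset.n_samples)],
        )
        df.to_csv(path, sep=sep, index_label="gene_id")
        with open(path + ".labels", "w", encoding="utf-8") as fh:
            fh.writelines(str(lab) + "\n" for lab in dataset.labels)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")


def write_summary(summaries, path: str) -> None:
    """Serialize run summaries as TSV.

    Columns ``best_acc``/``average_acc``/``worst_acc`` hold full-precision
    fractions (losslessly re-readable); ``best_pct``/``average_pct``/
    ``worst_pct`` repeat them as percentages rounded to 2 decimals for
    eyeballing against the usual best/average/worst reporting style.
    """
    rows = list(summaries)
    if not rows:
        raise ValueError("summary is empty")
    records = []
    for s in rows:
        rec = {
            "classifier": s.classifier,
            "n_genes": s.n_selected,
            "best_acc": repr(float(s.best_acc)),
            "average_acc": repr(float(s.average_acc)),
            "worst_acc": repr(float(s.worst_acc)),
            "n_runs": s.n_runs,
            "seed": s.seed,
            "best_pct": f"{100 * s.best_acc:.2f}",
            "average_pct": f"{100 * s.average_acc:.2f}",
            "worst_pct": f"{100 * s.worst_acc:.2f}",
            "best_genes": ",".join(s.best_gene_ids) if s.best_gene_ids else "",
        }
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)


def read_summary(path: str) -> pd.DataFrame:
    """Read a summary TSV back; accuracy columns parse to full precision."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary file {path} lacks columns {missing}")
    for col in ("best_acc", "average_acc", "worst_acc"):
        df[col] = df[col].astype(float)
    return df
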