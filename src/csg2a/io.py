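"""Expression-matrix, response-table and interaction-network I/O.

Expression matrices travel as TSV/CSV (header row = gene ids, first column =
sample ids) or GCT 1.2 text; in memory they are always samples × genes with a
fixed gene ordering.  The gene ordering of the pretraining matrix is canonical
for a model's lifetime: attention row/column *i* always refers to
``gene_ids[i]``, so later matrices are re-indexed to it.

Normalisation is the robust z-score used for L1000-style data,
``z = (x - median) / (1.4826 * MAD)`` per gene across samples, which is
resistant to the outliers common in expression panels.  The protein-interaction
prior is a binary adjacency over the gene universe keeping only high-confidence
edges (combined score strictly greater than 900 by default).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import ChemicalCondition

MAD_SCALE = 1.4826  # makes MAD a consistent sigma estimate under normality


@dataclass
class ExpressionMatrix:
    """A samples × genes real-valued matrix with identifier metadata."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples × genes)")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite expression value at sample "
                f"{self.sample_ids[bad[0]]!r}, gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def reindex_genes(
        self, gene_ids: Sequence[str], fill_value: float | None = None
    ) -> "ExpressionMatrix":
        """Re-order columns to a canonical gene ordering.

        Genes absent from this matrix raise unless ``fill_value`` is given
        (0 in robust-z units is the sensible imputation after normalisation).
        """
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing and fill_value is None:
            raise KeyError(f"genes missing from matrix: {missing[:5]}")
        out = np.full((self.n_samples, len(gene_ids)), fill_value or 0.0)
        for j, g in enumerate(gene_ids):
            if g in index:
                out[:, j] = self.values[:, index[g]]
        return ExpressionMatrix(list(self.sample_ids), list(gene_ids), out)


def _read_gct(path: Path) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1."):
            raise ValueError(f"{path}: not a GCT file (first line {version!r})")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t", index_col=0)
    data = body.drop(columns=[body.columns[0]])  # Description column
    if data.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: GCT header declares {n_rows}×{n_cols} "
            f"but body holds {data.shape[0]}×{data.shape[1]}"
        )
    # GCT stores genes in rows
    return ExpressionMatrix(
        sample_ids=[str(c) for c in data.columns],
        gene_ids=[str(i) for i in data.index],
        values=data.to_numpy(dtype=np.float64).T,
    )


def read_expression_matrix(
    path: str | Path, orientation: str = "samples"
) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV or GCT 1.2 text.

    Parameters
    ----------
    path:
        Input file.  GCT is auto-detected from the ``#1.x`` first line (GCT is
        always genes-in-rows, so ``orientation`` is ignored for it).
    orientation:
        ``"samples"`` if samples are in rows (default), ``"genes"`` if genes
        are in rows; the result is always samples × genes.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1."):
        return _read_gct(path)
    sep = "\t" if "\t" in first else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if frame.isna().any().any():
        r, c = np.argwhere(frame.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {frame.index[r]!r}, column {frame.columns[c]!r}"
        )
    if orientation not in ("samples", "genes"):
        raise ValueError("orientation must be 'samples' or 'genes'")
    if orientation == "genes":
        frame = frame.T
    return ExpressionMatrix(
        sample_ids=[str(i) for i in frame.index],
        gene_ids=[str(c) for c in frame.columns],
        values=frame.to_numpy(dtype=np.float64),
    )


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, orientation: str = "samples"
) -> None:
    """Write TSV/CSV (by extension) or GCT 1.2 (``.gct``)."""
    path = Path(path)
    if path.suffix == ".gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            fh.write("NAME\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
            for j, g in enumerate(matrix.gene_ids):
                vals = "\t".join(repr(float(v)) for v in matrix.values[:, j])
                fh.write(f"{g}\t{g}\t{vals}\n")
        return
    sep = "," if path.suffix == ".csv" else "\t"
    frame = matrix.to_frame()
    if orientation == "genes":
        frame = frame.T
    frame.to_csv(path, sep=sep, float_format=None)


def robust_zscore(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Robust z-score per gene across samples: (x − median) / (1.4826·MAD).

    MAD is the (unscaled) median absolute deviation from the per-gene median;
    the 1.4826 factor is applied exactly once.  Genes with MAD 0 cannot be
    scaled and map to all-zero columns; their ids are reported in a warning.
    """
    if matrix.n_samples < 2:
        raise ValueError("robust z-score needs at least 2 samples")
    x = matrix.values
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    scale = MAD_SCALE * mad
    constant = scale == 0
    safe = np.where(constant, 1.0, scale)
    z = (x - med) / safe
    z[:, constant] = 0.0
    if constant.any():
        bad = [g for g, c in zip(matrix.gene_ids, constant) if c]
        warnings.warn(
            f"{len(bad)} gene(s) with zero MAD set to 0: {bad[:10]}",
            RuntimeWarning,
            stacklevel=2,
        )
    return ExpressionMatrix(list(matrix.sample_ids), list(matrix.gene_ids), z)


@dataclass
class PPIAdjacency:
    """Binary symmetric protein-interaction prior aligned to a gene ordering."""

    matrix: np.ndarray
    gene_ids: list[str]
    threshold_used: int
    n_skipped_edges: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.gene_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("adjacency shape does not match gene_ids")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(self.matrix).any():
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(self.matrix, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum() // 2)


def load_ppi_adjacency(
    edge_list_path: str | Path,
    gene_ids: Sequence[str],
    score_threshold: int = 900,
    id_map: Mapping[str, str] | None = None,
) -> PPIAdjacency:
    """Build the binary interaction prior from a STRING-style edge list.

    The file holds whitespace- or tab-separated ``protein1 protein2
    combined_score`` rows, optionally with a header.  An edge is kept iff its
    score is strictly greater than ``score_threshold`` and both endpoints map
    into ``gene_ids``; self-edges are dropped and edges touching unmapped
    proteins are skipped (counted in ``n_skipped_edges``).
    """
    gene_ids = [str(g) for g in gene_ids]
    index = {g: i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    adj = np.zeros((n, n))
    skipped = 0
    with open(edge_list_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ValueError(f"{edge_list_path}:{lineno}: expected 3 columns")
            a, b, raw_score = parts[0], parts[1], parts[2]
            try:
                score = float(raw_score)
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ValueError(
                    f"{edge_list_path}:{lineno}: non-numeric score {raw_score!r}"
                ) from None
            if id_map is not None:
                a, b = id_map.get(a, a), id_map.get(b, b)
            if score <= score_threshold or a == b:
                continue
            if a not in index or b not in index:
                skipped += 1
                continue
            i, j = index[a], index[b]
            adj[i, j] = adj[j, i] = 1.0
    if adj.sum() == 0:
        warnings.warn(
            f"{edge_list_path}: no edges kept at score > {score_threshold}",
            RuntimeWarning,
            stacklevel=2,
        )
    return PPIAdjacency(adj, gene_ids, int(score_threshold), skipped)


@dataclass(frozen=True)
class DrugResponseRecord:
    """One cell-level response measurement: natural-log IC50."""

    cell_id: str
    compound_id: str
    smiles: str
    log_ic50: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_ic50):
            raise ValueError(f"non-finite log IC50 for {self.cell_id}/{self.compound_id}")


def read_response_table(path: str | Path) -> list[DrugResponseRecord]:
    """CSV with columns cell_id, compound_id, smiles, log_ic50."""
    frame = pd.read_csv(path)
    required = {"cell_id", "compound_id", "smiles", "log_ic50"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    return [
        DrugResponseRecord(str(r.cell_id), str(r.compound_id), str(r.smiles), float(r.log_ic50))
        for r in frame.itertuples()
    ]


def write_response_table(records: Iterable[DrugResponseRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "compound_id", "smiles", "log_ic50"])
        for r in records:
            w.writerow([r.cell_id, r.compound_id, r.smiles, repr(r.log_ic50)])


def read_compound_table(path: str | Path) -> list[ChemicalCondition]:
    """CSV with columns compound_id, smiles, dose_uM, time_h (one row/sample)."""
    frame = pd.read_csv(path)
    required = {"smiles", "dose_uM", "time_h"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    return [
        ChemicalCondition(str(r.smiles), float(r.dose_uM), float(r.time_h))
        for r in frame.itertuples()
    ]


def pair_with_controls(
    treated: ExpressionMatrix,
    controls: ExpressionMatrix,
    batch_of: Mapping[str, str],
    condition_of: Mapping[str, ChemicalCondition],
) -> list[tuple[np.ndarray, np.ndarray, ChemicalCondition]]:
    """Pair each treated profile with its batch's mean control profile.

    Vehicle-control (DMSO) samples from the same batch define the basal state
    g0 for every treated sample of that batch; with several controls the
    element-wise mean is used.  Returns one (g0, gc, condition) triple per
    treated sample, in treated order.
    """
    if treated.gene_ids != controls.gene_ids:
        raise ValueError("treated and control matrices must share gene ordering")
    control_mean: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for sid, row in zip(controls.sample_ids, controls.values):
        batch = batch_of[sid]
        control_mean[batch] = control_mean.get(batch, 0.0) + row
        counts[batch] = counts.get(batch, 0) + 1
    for batch in control_mean:
        control_mean[batch] = control_mean[batch] / counts[batch]

    missing = sorted(
        {batch_of[s] for s in treated.sample_ids} - set(control_mean)
    )
    if missing:
        raise ValueError(f"treated batches without any control sample: {missing}")

    return [
        (control_mean[batch_of[sid]], gc.copy(), condition_of[sid])
        for sid, gc in zip(treated.sample_ids, treated.values)
    ]
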