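"""TSV readers and writers for expression matrices, labels and run outputs.

File conventions
----------------
* expression matrix: TSV, first column sample identifiers, header row gene
  identifiers, real-valued cells, no missing values;
* labels: two-column TSV ``sample_id`` / ``label`` with label in {0, 1, NA};
  NA marks an unlabeled sample;
* truth (simulation only): ``sample_id`` / ``label`` plus a ``#support:``
  header comment listing the causal gene identifiers.

All files are UTF-8 with '.' as the decimal separator.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ModelState
from .trainer import LabeledPool, SampleStatus, TrainLog
from .simulate import SyntheticDataset

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "write_dataset",
    "read_pool",
    "write_model_json",
    "read_model_json",
    "write_trainlog_tsv",
    "write_predictions_tsv",
]


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    return ExpressionMatrix(
        df.to_numpy(dtype=float), tuple(map(str, df.index)), tuple(map(str, df.columns))
    )


def write_expression_tsv(X: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(X.values, index=list(X.sample_ids), columns=list(X.gene_ids)).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_labels_tsv(path: str | Path) -> pd.DataFrame:
    """Read a sample_id/label table; label NA means unlabeled."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "label"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns sample_id and label")
    bad = df["label"].dropna()
    if not bad.isin([0, 1]).all():
        raise ValueError(f"{path}: labels must be 0, 1 or NA")
    return df


def write_labels_tsv(sample_ids, labels, path: str | Path) -> None:
    """Write labels with NaN rendered as NA."""
    pd.DataFrame({"sample_id": list(sample_ids), "label": labels}).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.0f"
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write matrix.tsv, labels.tsv (NA-masked) and truth.tsv for a simulation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(dataset.X, out / "matrix.tsv")
    observed = np.where(dataset.observed_status, dataset.truth_labels.astype(float), np.nan)
    write_labels_tsv(dataset.X.sample_ids, observed, out / "labels.tsv")
    support_ids = [dataset.X.gene_ids[i] for i in dataset.true_support]
    with open(out / "truth.tsv", "w") as fh:
        fh.write("#support: " + ",".join(support_ids) + "\n")
        pd.DataFrame(
            {"sample_id": list(dataset.X.sample_ids), "label": dataset.truth_labels}
        ).to_csv(fh, sep="\t", index=False)


def read_pool(
    matrix_path: str | Path, labels_path: str | Path, truth_path: str | Path | None = None
) -> LabeledPool:
    """Assemble a training pool from matrix + labels (+ optional truth) files."""
    X = read_expression_tsv(matrix_path)
    lab = read_labels_tsv(labels_path).set_index("sample_id")["label"]
    try:
        labels = lab.loc[list(X.sample_ids)].to_numpy(dtype=float)
    except KeyError as e:
        raise ValueError(f"label file is missing samples present in the matrix: {e}") from None
    observed = ~np.isnan(labels)
    truth = None
    if truth_path is not None:
        tdf = pd.read_csv(truth_path, sep="\t", comment="#", dtype={"sample_id": str})
        truth = (
            tdf.set_index("sample_id")["label"].loc[list(X.sample_ids)].to_numpy(dtype=int)
        )
    filled = np.where(observed, labels, 0.0)
    return LabeledPool.from_labels(X, filled, observed, truth=truth)


def write_model_json(model: ModelState, path: str | Path) -> None:
    Path(path).write_text(model.to_json() + "\n")


def read_model_json(path: str | Path) -> ModelState:
    return ModelState.from_json(Path(path).read_text())


def write_trainlog_tsv(log: TrainLog, path: str | Path) -> None:
    log.to_dataframe().to_csv(path, sep="\t", index=False)


def write_predictions_tsv(
    pool: LabeledPool, probs: np.ndarray, path: str | Path
) -> None:
    """Per-sample probabilities, predicted labels and final statuses."""
    pd.DataFrame(
        {
            "sample_id": list(pool.X.sample_ids),
            "probability": probs,
            "predicted_label": (np.asarray(probs) > 0.5).astype(int),
            "status": [SampleStatus(s).name.lower() for s in pool.status],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
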