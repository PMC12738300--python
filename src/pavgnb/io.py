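"""CSV ingestion and model persistence.

Models are serialized as a structured JSON text document carrying the fit
configuration, the class vocabulary and every learner's (feature subset,
priors, means, variances).  Floats survive the text round trip exactly:
json emits the shortest decimal that reparses to the same double.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import BaseLearner, GaussianClassParams, PAVGaussianNB
from .dataset import LabeledDataset

MODEL_FORMAT = "pavgnb-model"
MODEL_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a model file has the wrong schema or version."""


def read_labeled_csv(path, response: str) -> LabeledDataset:
    """Read a header CSV into a LabeledDataset.

    The class vocabulary is the first-appearance order of the response
    column; all predictor columns must be numeric and complete.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: file contains no rows")
    if response not in frame.columns:
        raise ValueError(f"{path}: response column {response!r} not found "
                         f"(columns: {list(frame.columns)})")
    y = frame[response].to_numpy()
    predictors = frame.drop(columns=[response])
    bad = [c for c in predictors.columns
           if not np.issubdtype(predictors[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric predictor columns {bad}")
    if predictors.isna().any().any():
        cell = np.argwhere(predictors.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {cell[0]}, "
            f"column {predictors.columns[cell[1]]!r}")
    return LabeledDataset(X=predictors.to_numpy(dtype=float), y=y)


def write_dataset_csv(dataset: LabeledDataset, path, response: str = "class") -> None:
    dataset.to_frame(response).to_csv(path, index=False)


def save_model(model: PAVGaussianNB, path) -> None:
    """Serialize a fitted ensemble to JSON; round-trip exact for doubles."""
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        # n_jobs is an execution hint, not model state: leaving it out keeps
        # serialized models byte-identical across core counts.
        "params": {
            "n_iter": model.n_iter,
            "feature_fraction": model.feature_fraction,
            "var_smoothing": model.var_smoothing,
            "bootstrap": model.bootstrap,
        },
        "base_seed": model.base_seed_,
        "variance_floor": model.variance_floor_,
        "n_features": model.n_features_in_,
        "classes": np.asarray(model.classes_).tolist(),
        "learners": [
            {
                "iteration": lrn.iteration_index,
                "feature_subset": lrn.feature_subset.tolist(),
                "priors": lrn.params.priors.tolist(),
                "means": lrn.params.means.tolist(),
                "variances": lrn.params.variances.tolist(),
            }
            for lrn in model.learners_
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> PAVGaussianNB:
    """Reconstruct a fitted ensemble from :func:`save_model` output."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ModelFormatError(f"{path}: not a {MODEL_FORMAT} document")
    if doc.get("version") != MODEL_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model version {doc.get('version')!r}")
    model = PAVGaussianNB(random_state=doc["base_seed"], **doc["params"])
    model.classes_ = np.asarray(doc["classes"])
    model.n_features_in_ = int(doc["n_features"])
    model.variance_floor_ = float(doc["variance_floor"])
    model.base_seed_ = int(doc["base_seed"])
    model.learners_ = [
        BaseLearner(
            params=GaussianClassParams(
                priors=np.asarray(entry["priors"], dtype=float),
                means=np.asarray(entry["means"], dtype=float),
                variances=np.asarray(entry["variances"], dtype=float),
            ),
            feature_subset=np.asarray(entry["feature_subset"], dtype=np.intp),
            iteration_index=int(entry["iteration"]),
        )
        for entry in doc["learners"]
    ]
    if len(model.learners_) != model.n_iter:
        raise ModelFormatError(
            f"{path}: learner count {len(model.learners_)} does not match "
            f"n_iter={model.n_iter}")
    return model
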