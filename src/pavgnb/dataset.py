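"""Labeled tabular dataset container shared by the generator, IO and benchmarks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def class_vocabulary_of(labels: np.ndarray) -> np.ndarray:
    """Distinct labels in order of first appearance.

    The ensemble's class axis follows this order everywhere (posterior columns,
    argmax tie-breaking), so it is fixed once at construction time.
    """
    labels = np.asarray(labels)
    _, first = np.unique(labels, return_index=True)
    return labels[np.sort(first)]


@dataclass
class LabeledDataset:
    """A numeric feature matrix with a categorical response.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Continuous features; must be finite.
    y : ndarray of shape (n,)
        Class labels; every distinct value must appear in ``class_vocabulary``.
    class_vocabulary : ndarray of shape (K,), optional
        Ordered distinct labels. Defaults to first-appearance order in ``y``.
    """

    X: np.ndarray
    y: np.ndarray
    class_vocabulary: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must have one label per row of X")
        if not np.isfinite(self.X).all():
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(f"non-finite feature value at row {i}, column {j}")
        if self.class_vocabulary is None:
            self.class_vocabulary = class_vocabulary_of(self.y)
        else:
            self.class_vocabulary = np.asarray(self.class_vocabulary)
        vocab = set(self.class_vocabulary.tolist())
        if len(vocab) != len(self.class_vocabulary):
            raise ValueError("class_vocabulary contains duplicates")
        present = set(np.unique(self.y).tolist())
        if not present <= vocab:
            raise ValueError(f"labels {present - vocab} missing from class_vocabulary")
        if len(self.class_vocabulary) < 2:
            raise ValueError("need at least two classes")
        if self.n < self.n_classes:
            raise ValueError("need at least one observation per class")
        if self.p < 1:
            raise ValueError("need at least one feature")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_vocabulary)

    def class_counts(self) -> np.ndarray:
        """Per-class counts in vocabulary order."""
        return np.array([(self.y == c).sum() for c in self.class_vocabulary])

    def to_frame(self, response: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"x{j + 1}" for j in range(self.p)])
        df[response] = self.y
        return df
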