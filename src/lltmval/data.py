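"""Response and weight matrix containers with CSV I/O.

A :class:`ResponseMatrix` holds persons x items binary observations; a
:class:`WeightMatrix` holds the items x operations Q-matrix encoding which
cognitive operations each item requires.  Both read and write plain
comma-separated files, one row per person (respectively item), with an
optional header row that is auto-detected.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["ResponseMatrix", "WeightMatrix"]


def _read_csv_auto_header(path) -> pd.DataFrame:
    """Read a small numeric CSV, detecting whether a header row is present."""
    probe = pd.read_csv(path, header=None, nrows=1)
    has_header = not all(
        isinstance(v, (int, float, np.integer, np.floating)) for v in probe.iloc[0]
    )
    return pd.read_csv(path, header=0 if has_header else None)


@dataclass
class ResponseMatrix:
    """Persons x items binary response data.

    Parameters
    ----------
    data : ndarray of 0/1, shape (n_persons, k)
    person_ids, item_ids : optional labels; generated if omitted.
    """

    data: np.ndarray
    person_ids: list[str] = field(default_factory=list)
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        X = np.asarray(self.data)
        if X.ndim != 2:
            raise ValidationError("responses must be a persons x items matrix")
        n, k = X.shape
        if k < 2:
            raise ValidationError("at least two items are required (k >= 2)")
        if n < 1:
            raise ValidationError("at least one person is required")
        if not np.all(np.isin(np.unique(X), (0, 1))):
            raise ValidationError(
                "responses must contain only 0 and 1 (no missing values)"
            )
        self.data = X.astype(np.int8)
        if not self.person_ids:
            self.person_ids = [f"P{i + 1}" for i in range(n)]
        if not self.item_ids:
            self.item_ids = [f"I{j + 1}" for j in range(k)]
        if len(self.person_ids) != n or len(self.item_ids) != k:
            raise ValidationError("label lengths do not match the data shape")

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    @property
    def raw_scores(self) -> np.ndarray:
        return self.data.sum(axis=1)

    @property
    def checksum(self) -> str:
        """Fingerprint of the observations, used to pair fits for comparison."""
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.data).tobytes())
        h.update(str(self.data.shape).encode())
        return h.hexdigest()

    @classmethod
    def from_csv(cls, path) -> "ResponseMatrix":
        df = _read_csv_auto_header(path)
        item_ids = [str(c) for c in df.columns] if df.columns.dtype == object else []
        return cls(data=df.to_numpy(), item_ids=item_ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.data, columns=self.item_ids).to_csv(path, index=False)


@dataclass
class WeightMatrix:
    """Items x operations Q-matrix of non-negative integer weights.

    The LLTM restricts Rasch item difficulties to ``beta = Q eta + c``; for
    the basic parameters ``eta`` (and the implicit intercept ``c``) to be
    identified, ``[Q | 1]`` must have full column rank ``p + 1``.  Rank is
    reported through :attr:`is_identifiable` rather than raised here, so
    simulation loops can book rank-deficient draws as non-convergent.
    """

    weights: np.ndarray
    operation_ids: list[str] = field(default_factory=list)
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        Q = np.asarray(self.weights)
        if Q.ndim != 2:
            raise ValidationError("weight matrix must be items x operations")
        k, p = Q.shape
        if p < 1:
            raise ValidationError("at least one operation is required (p >= 1)")
        if p >= k:
            raise ValidationError(
                f"operations (p={p}) must be fewer than items (k={k}); "
                "the LLTM is a restriction of the Rasch model"
            )
        if not np.all(np.isfinite(Q)):
            raise ValidationError("weights must be finite")
        if np.any(Q < 0) or np.any(Q != np.round(Q)):
            raise ValidationError("weights must be non-negative integers")
        self.weights = Q.astype(np.int64)
        if not self.operation_ids:
            self.operation_ids = [f"O{j + 1}" for j in range(p)]
        if not self.item_ids:
            self.item_ids = [f"I{i + 1}" for i in range(k)]
        if len(self.operation_ids) != p or len(self.item_ids) != k:
            raise ValidationError("label lengths do not match the weight shape")

    @property
    def n_items(self) -> int:
        return self.weights.shape[0]

    @property
    def n_operations(self) -> int:
        return self.weights.shape[1]

    @property
    def is_identifiable(self) -> bool:
        """True when ``[Q | 1]`` has full column rank ``p + 1``."""
        k, p = self.weights.shape
        aug = np.column_stack([self.weights.astype(float), np.ones(k)])
        return int(np.linalg.matrix_rank(aug)) == p + 1

    @property
    def proportion_ones(self) -> float:
        """Fraction of non-zero entries (the 'proportion of ones' of a binary Q)."""
        return float(np.mean(self.weights != 0))

    def permuted_rows(self, permutation: np.ndarray) -> "WeightMatrix":
        perm = np.asarray(permutation)
        return WeightMatrix(
            weights=self.weights[perm],
            operation_ids=list(self.operation_ids),
            item_ids=[self.item_ids[i] for i in perm],
        )

    @classmethod
    def from_csv(cls, path) -> "WeightMatrix":
        df = _read_csv_auto_header(path)
        op_ids = [str(c) for c in df.columns] if df.columns.dtype == object else []
        return cls(weights=df.to_numpy(), operation_ids=op_ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.weights, columns=self.operation_ids).to_csv(path, index=False)
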