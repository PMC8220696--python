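"""Dipeptide composition encodings: DipC, GDipC(k) and the W-GDipC fusion.

For a sequence of length ``n`` over the 20 standard residues:

* DipC(i) = f(i) / (n - 1), the frequency of the i-th ordered adjacent
  residue pair among the n - 1 pairs (400 components).
* GDipC(k)(i) = f'(i) / (n - k - 1), the frequency of ordered pairs whose
  members are separated by k intervening residues (gap k); GDipC(0) is DipC.
* W-GDipC = sum_k alpha_k * GDipC(k) with convex, strictly decreasing
  weights; the two-term form alpha * DipC + (1 - alpha) * GDipC(1) is the
  default pipeline encoding with alpha = 0.8.

Every pure composition and every convex fusion sums to 1, so feature rows
are points on the 400-simplex. Sequences too short to form a pair at the
requested gap are hard errors rather than zero vectors, which would
silently break the sum-to-one invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import DIPEPTIDES, N_DIPEPTIDES, encode_residues
from .sequence_io import ProteinRecord, check_label_join

DEFAULT_ALPHA: float = 0.8


class SequenceLengthError(ValueError):
    """Sequence too short for the requested pair gap."""


@dataclass(frozen=True)
class DipeptideCounts:
    """Raw ordered-pair counts at a fixed gap.

    ``counts`` is indexed by ``20 * idx(first) + idx(second)`` and sums to
    ``n_pairs`` (= n - k - 1 for a length-n sequence at gap k).
    """

    counts: np.ndarray
    n_pairs: int


def count_pairs(rec: ProteinRecord, k: int = 0) -> DipeptideCounts:
    """Count ordered residue pairs (q_j, q_{j+1+k}) at gap ``k``."""
    if k < 0:
        raise ValueError(f"gap k must be >= 0, got {k}")
    n = len(rec.sequence)
    if n < k + 2:
        raise SequenceLengthError(
            f"record {rec.id!r}: length {n} < k + 2 = {k + 2}; no pair at gap {k}"
        )
    codes = encode_residues(rec.sequence)
    pair_idx = 20 * codes[: n - 1 - k] + codes[1 + k :]
    counts = np.bincount(pair_idx, minlength=N_DIPEPTIDES)
    return DipeptideCounts(counts=counts, n_pairs=n - k - 1)


def dipc(rec: ProteinRecord) -> np.ndarray:
    """Adjacent dipeptide composition f(i) / (n - 1)."""
    c = count_pairs(rec, k=0)
    return c.counts / c.n_pairs


def gdipc(rec: ProteinRecord, k: int) -> np.ndarray:
    """Generalized dipeptide composition at gap k: f'(i) / (n - k - 1)."""
    c = count_pairs(rec, k=k)
    return c.counts / c.n_pairs


def w_gdipc(rec: ProteinRecord, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Two-term weighted fusion ``alpha * DipC + (1 - alpha) * GDipC(1)``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"fusion coefficient alpha must lie in [0, 1], got {alpha}")
    if len(rec.sequence) < 3:
        raise SequenceLengthError(
            f"record {rec.id!r}: length {len(rec.sequence)} < 3; "
            "W-GDipC needs both DipC and GDipC(1)"
        )
    return alpha * dipc(rec) + (1.0 - alpha) * gdipc(rec, 1)


@dataclass(frozen=True)
class FusionConfig:
    """Convex fusion weights alpha_0..alpha_d over gaps 0..d.

    Weights must be nonnegative, sum to 1 (within 1e-12) and be strictly
    decreasing: the importance of a gapped pair decreases with gap length.
    """

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.weights)
        object.__setattr__(self, "weights", w)
        if len(w) == 0:
            raise ValueError("FusionConfig needs at least one weight")
        if any(x < 0 for x in w):
            raise ValueError("fusion weights must be nonnegative")
        if abs(sum(w) - 1.0) > 1e-12:
            raise ValueError(f"fusion weights must sum to 1, got {sum(w)!r}")
        if any(w[i] <= w[i + 1] for i in range(len(w) - 1)):
            raise ValueError("fusion weights must be strictly decreasing in the gap")

    @property
    def max_gap(self) -> int:
        return len(self.weights) - 1


def w_gdipc_general(rec: ProteinRecord, cfg: FusionConfig) -> np.ndarray:
    """General weighted fusion ``sum_k alpha_k * GDipC(k)``."""
    d = cfg.max_gap
    if len(rec.sequence) < d + 2:
        raise SequenceLengthError(
            f"record {rec.id!r}: length {len(rec.sequence)} < d + 2 = {d + 2}"
        )
    out = np.zeros(N_DIPEPTIDES)
    for k, alpha_k in enumerate(cfg.weights):
        out += alpha_k * gdipc(rec, k)
    return out


@dataclass
class FeatureMatrix:
    """A stacked dataset of 400-D composition vectors with labels.

    ``y`` holds integer class codes assigned in first-seen record order;
    ``classes`` maps code -> original label string.
    """

    X: np.ndarray
    ids: list[str]
    y: np.ndarray
    classes: list[str]
    columns: list[str] = field(default_factory=lambda: list(DIPEPTIDES))

    def __post_init__(self) -> None:
        if not (self.X.shape[0] == len(self.ids) == len(self.y)):
            raise ValueError("rows, ids and labels must have matching lengths")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column names must match the feature count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def label_names(self) -> list[str]:
        return [self.classes[c] for c in self.y]

    def subset_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        if len(idx) == 0:
            raise ValueError("cannot subset to an empty column list")
        for i in idx:
            if not 0 <= i < self.n_features:
                raise IndexError(f"feature index {i} out of range [0, {self.n_features})")
        return FeatureMatrix(
            X=self.X[:, idx].copy(),
            ids=list(self.ids),
            y=self.y.copy(),
            classes=list(self.classes),
            columns=[self.columns[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "label", self.label_names())
        df.insert(0, "id", self.ids)
        return df


def encode_dataset(
    records: Sequence[ProteinRecord],
    labels: Mapping[str, str],
    alpha: float = DEFAULT_ALPHA,
    *,
    fusion: FusionConfig | None = None,
    k: int | None = None,
) -> FeatureMatrix:
    """Encode a labeled sequence set into a FeatureMatrix, rows in input order.

    By default each row is the two-term W-GDipC at ``alpha``. Pass ``k`` for a
    raw GDipC(k) encoding or ``fusion`` for the general weighted form. Label
    strings are joined by id and mapped to integer codes in first-seen order.
    """
    if fusion is not None and k is not None:
        raise ValueError("pass at most one of fusion= and k=")
    check_label_join(records, labels)
    classes: list[str] = []
    code_of: dict[str, int] = {}
    y = np.empty(len(records), dtype=int)
    rows = np.empty((len(records), N_DIPEPTIDES))
    for i, rec in enumerate(records):
        label = labels[rec.id]
        if label not in code_of:
            code_of[label] = len(classes)
            classes.append(label)
        y[i] = code_of[label]
        try:
            if fusion is not None:
                rows[i] = w_gdipc_general(rec, fusion)
            elif k is not None:
                rows[i] = gdipc(rec, k)
            else:
                rows[i] = w_gdipc(rec, alpha)
        except SequenceLengthError:
            raise
    return FeatureMatrix(X=rows, ids=[r.id for r in records], y=y, classes=classes)


def write_feature_table(
    matrix: FeatureMatrix, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write a FeatureMatrix as TSV with optional '#' provenance comments."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        matrix.to_frame().to_csv(fh, sep="\t", index=False)


def read_feature_table(path: str | Path) -> FeatureMatrix:
    """Read a feature TSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path}: feature table must have 'id' and 'label' columns")
    feature_cols = [c for c in df.columns if c not in ("id", "label")]
    classes: list[str] = []
    code_of: dict[str, int] = {}
    y = np.empty(len(df), dtype=int)
    for i, label in enumerate(df["label"].astype(str)):
        if label not in code_of:
            code_of[label] = len(classes)
            classes.append(label)
        y[i] = code_of[label]
    return FeatureMatrix(
        X=df[feature_cols].to_numpy(dtype=float),
        ids=[str(x) for x in df["id"]],
        y=y,
        classes=classes,
        columns=feature_cols,
    )
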