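"""Labeled synthetic protein sequences with planted dipeptide signal.

Sequences are drawn residue by residue from a background distribution over
the 20 standard amino acids (uniform by default), then class-discriminative
signal is planted by inserting whole ordered pairs: for a planted
(dipeptide, gap k, enrichment rho) the number of insertions in a length-L
sequence is Binomial(L - k - 1, (rho - 1) / 400), which raises that pair's
expected composition from the background 1/400 to approximately rho/400.
Insertion (rather than Markov transition biasing) keeps the expected
enrichment analytically computable, which the recovery tests rely on.

The default configurations mirror the shapes of the benchmark data the
method was designed around: a binary set with 480/374 class imbalance and
sequence lengths 50-100, and an eight-class membrane-protein-like set whose
class sizes (1054, 390, 30, 56, 4581, 189, 228, 1054) include tiny classes
that reproduce the zero-metric phenomenon for rarely predicted categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, dipeptide_index
from .sequence_io import ProteinRecord

__all__ = [
    "SimConfig",
    "SimConfigError",
    "generate",
    "planted_truth",
    "binary_benchmark_config",
    "multiclass_benchmark_config",
]

PlantedPair = tuple[str, int, float]  # (dipeptide, gap k, enrichment rho >= 1)


class SimConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``planted_pairs`` holds one tuple of (dipeptide, gap, rho) plants per
    class; rho = 1 means no signal. ``background`` is a 20-vector of residue
    frequencies summing to 1 (uniform when omitted).
    """

    n_per_class: tuple[int, ...] = (480, 374)
    length_range: tuple[int, int] = (50, 100)
    planted_pairs: tuple[tuple[PlantedPair, ...], ...] = (
        (("AC", 0, 10.0), ("MK", 0, 10.0)),
        (("WY", 0, 10.0), ("TS", 0, 10.0)),
    )
    background: tuple[float, ...] | None = None
    class_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) < 1 or any(n < 1 for n in self.n_per_class):
            raise SimConfigError("n_per_class must hold positive counts")
        lo, hi = self.length_range
        if lo < 3 or hi < lo:
            raise SimConfigError("length range must satisfy 3 <= min <= max")
        if len(self.planted_pairs) != len(self.n_per_class):
            raise SimConfigError(
                "planted_pairs must list one (possibly empty) tuple per class"
            )
        for plants in self.planted_pairs:
            expected_insertions = 0.0
            for pair, k, rho in plants:
                dipeptide_index(pair)  # raises on a bad pair
                if k < 0:
                    raise SimConfigError(f"gap must be >= 0 in plant {pair!r}")
                if rho < 1.0:
                    raise SimConfigError(f"enrichment rho must be >= 1, got {rho}")
                if lo < k + 2:
                    raise SimConfigError(
                        f"plant {pair!r} at gap {k} needs length >= {k + 2}, "
                        f"but min length is {lo}"
                    )
                expected_insertions += (rho - 1.0) / 400.0 * (lo - k - 1)
            if expected_insertions > lo:
                raise SimConfigError(
                    "infeasible planting: expected planted residue pairs exceed "
                    f"the minimum sequence length {lo}"
                )
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or np.any(bg < 0) or abs(bg.sum() - 1.0) > 1e-9:
                raise SimConfigError(
                    "background must be 20 nonnegative frequencies summing to 1"
                )
        if self.class_names is not None and len(self.class_names) != len(
            self.n_per_class
        ):
            raise SimConfigError("class_names must match n_per_class in length")

    def names(self) -> tuple[str, ...]:
        if self.class_names is not None:
            return self.class_names
        return tuple(f"class{i}" for i in range(len(self.n_per_class)))


def generate(cfg: SimConfig) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Draw the configured dataset; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    bg = None if cfg.background is None else np.asarray(cfg.background, dtype=float)
    names = cfg.names()
    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    for ci, (n_class, plants) in enumerate(zip(cfg.n_per_class, cfg.planted_pairs)):
        for si in range(n_class):
            length = int(rng.integers(lo, hi + 1))
            if bg is None:
                codes = rng.integers(0, 20, size=length)
            else:
                codes = rng.choice(20, size=length, p=bg)
            for pair, k, rho in plants:
                if rho <= 1.0:
                    continue
                slots = length - k - 1
                n_insert = rng.binomial(slots, (rho - 1.0) / 400.0)
                if n_insert == 0:
                    continue
                positions = rng.choice(slots, size=min(n_insert, slots), replace=False)
                a, b = pair.upper()
                codes[positions] = AMINO_ACIDS.index(a)
                codes[positions + 1 + k] = AMINO_ACIDS.index(b)
            seq = "".join(AMINO_ACIDS[c] for c in codes)
            rec_id = f"{names[ci]}_seq{si:05d}"
            records.append(ProteinRecord(rec_id, seq))
            labels[rec_id] = names[ci]
    return records, labels


def planted_truth(cfg: SimConfig) -> list[list[int]]:
    """Canonical column indices of each class's planted pairs.

    Gapped pairs share the 400-name space with adjacent pairs, so a plant at
    any gap maps to the same column as its dipeptide string.
    """
    truth: list[list[int]] = []
    for plants in cfg.planted_pairs:
        truth.append(sorted({dipeptide_index(pair) for pair, _k, _rho in plants}))
    return truth


def binary_benchmark_config(
    scale: float = 1.0, rho: float = 10.0, seed: int = 0
) -> SimConfig:
    """Binary dataset mirroring the 480/374 positive/negative shape."""
    return SimConfig(
        n_per_class=(max(2, round(480 * scale)), max(2, round(374 * scale))),
        length_range=(50, 100),
        planted_pairs=(
            (("AC", 0, rho), ("MK", 0, rho)),
            (("WY", 0, rho), ("TS", 0, rho)),
        ),
        class_names=("AFP", "nonAFP"),
        seed=seed,
    )


_MEMBRANE_SIZES = (1054, 390, 30, 56, 4581, 189, 228, 1054)
_MEMBRANE_PLANTS = ("AC", "DE", "FG", "HI", "KL", "MN", "PQ", "ST")


def multiclass_benchmark_config(
    scale: float = 0.1, rho: float = 10.0, seed: int = 0
) -> SimConfig:
    """Eight-class dataset mirroring the membrane-protein class imbalance.

    The default scale keeps the tiny classes tiny (a few sequences) so that
    rarely predicted categories show the zero-metric behaviour.
    """
    sizes = tuple(max(6, round(s * scale)) for s in _MEMBRANE_SIZES)
    plants = tuple(((p, 0, rho),) for p in _MEMBRANE_PLANTS)
    return SimConfig(
        n_per_class=sizes,
        length_range=(50, 100),
        planted_pairs=plants,
        class_names=tuple(f"type{i + 1}" for i in range(8)),
        seed=seed,
    )
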