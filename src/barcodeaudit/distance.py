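"""Kimura 2-parameter distances with pairwise deletion.

Comparable sites for a pair are the positions where *both* sequences carry
an unambiguous base (A, C, G or T); everything else (N, gaps) is excluded
per pair rather than per column. Transitions are A<->G and C<->T, all other
mismatches are transversions, and

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the transition and transversion proportions over comparable
sites. Pairs where the logarithm's argument is non-positive are saturated:
their distance is *undefined*, never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Set

import numpy as np

from .errors import InsufficientOverlapError
from .library_io import ReferenceLibrary

DEFAULT_MIN_OVERLAP = 100

# A=0, C=1, G=2, T=3 so that a XOR b == 2 exactly for transitions.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode_sequence(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_library(lib: ReferenceLibrary) -> np.ndarray:
    return np.vstack([encode_sequence(r.sequence) for r in lib.records])


@dataclass(frozen=True)
class PairwiseComparison:
    """Site counts and the resulting K2P distance for one sequence pair."""

    comparable_sites: int
    transitions: int
    transversions: int
    P: float
    Q: float
    d: Optional[float]
    insufficient_overlap: bool = False
    saturated: bool = False

    @property
    def defined(self) -> bool:
        return self.d is not None


def k2p_from_counts(
    comparable_sites: int,
    transitions: int,
    transversions: int,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> PairwiseComparison:
    if transitions + transversions > comparable_sites:
        raise ValueError("more substitutions than comparable sites")
    if comparable_sites == 0:
        return PairwiseComparison(0, 0, 0, 0.0, 0.0, None, insufficient_overlap=True)
    P = transitions / comparable_sites
    Q = transversions / comparable_sites
    low = comparable_sites < min_overlap
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return PairwiseComparison(
            comparable_sites, transitions, transversions, P, Q, None,
            insufficient_overlap=low, saturated=True,
        )
    d = -0.5 * math.log(a) - 0.25 * math.log(b)
    # guard against -0.0 from rounding
    d = max(d, 0.0)
    return PairwiseComparison(
        comparable_sites, transitions, transversions, P, Q, d,
        insufficient_overlap=low,
    )


def k2p_distance(
    seq_a: str, seq_b: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> PairwiseComparison:
    """K2P comparison of two equal-length aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    a = encode_sequence(seq_a.upper())
    b = encode_sequence(seq_b.upper())
    valid = (a != 255) & (b != 255)
    diff = valid & (a != b)
    ts = int(np.count_nonzero(diff & ((a ^ b) == 2)))
    tv = int(np.count_nonzero(diff)) - ts
    return k2p_from_counts(int(np.count_nonzero(valid)), ts, tv, min_overlap)


@dataclass
class DistanceMatrix:
    """Symmetric labeled K2P matrix in substitutions/site.

    Undefined (saturated or zero-overlap) entries hold NaN and are listed in
    ``undefined_pairs``; pairs with fewer than ``min_overlap`` comparable
    sites are listed in ``low_overlap_pairs`` but keep their value.
    """

    labels: List[str]
    values: np.ndarray
    comparable_sites: np.ndarray
    undefined_pairs: Set[FrozenSet[str]] = field(default_factory=set)
    low_overlap_pairs: Set[FrozenSet[str]] = field(default_factory=set)
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def __post_init__(self):
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        self._index = {lbl: i for i, lbl in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def get(self, a: str, b: str) -> Optional[float]:
        v = self.values[self._index[a], self._index[b]]
        return None if np.isnan(v) else float(v)

    def is_complete(self) -> bool:
        return not self.undefined_pairs

    def submatrix(self, labels: List[str]) -> "DistanceMatrix":
        idx = [self._index[lbl] for lbl in labels]
        keep = set(labels)
        return DistanceMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)].copy(),
            comparable_sites=self.comparable_sites[np.ix_(idx, idx)].copy(),
            undefined_pairs={p for p in self.undefined_pairs if p <= keep},
            low_overlap_pairs={p for p in self.low_overlap_pairs if p <= keep},
            min_overlap=self.min_overlap,
        )

    def to_tsv(self, path) -> None:
        """Square TSV in percent units, 4 decimals, 'NA' for undefined."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("specimen_id\t" + "\t".join(self.labels) + "\n")
            for i, lbl in enumerate(self.labels):
                cells = [
                    "NA" if np.isnan(v) else f"{100.0 * v:.4f}"
                    for v in self.values[i]
                ]
                fh.write(lbl + "\t" + "\t".join(cells) + "\n")


def distance_matrix(
    lib: ReferenceLibrary,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    strict: bool = False,
) -> DistanceMatrix:
    """All-pairs K2P matrix for a library (>=2 records)."""
    if len(lib) < 2:
        raise ValueError("distance matrix requires at least 2 records")
    enc = encode_library(lib)
    labels = [r.specimen_id for r in lib.records]
    dm = _matrix_from_encoded(enc, labels, min_overlap)
    if strict and dm.low_overlap_pairs:
        raise InsufficientOverlapError(
            f"{len(dm.low_overlap_pairs)} pair(s) below minimum overlap "
            f"({min_overlap} sites)",
            pairs=sorted(tuple(sorted(p)) for p in dm.low_overlap_pairs),
        )
    return dm


def _matrix_from_encoded(
    enc: np.ndarray, labels: List[str], min_overlap: int
) -> DistanceMatrix:
    n = enc.shape[0]
    values = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=int)
    undefined: Set[FrozenSet[str]] = set()
    low: Set[FrozenSet[str]] = set()
    known = enc != 255
    np.fill_diagonal(sites, known.sum(axis=1))
    for i in range(n - 1):
        block = enc[i + 1 :]
        valid = known[i] & known[i + 1 :]
        diff = valid & (enc[i] != block)
        ts_mask = diff & ((enc[i] ^ block) == 2)
        comp = valid.sum(axis=1)
        ts = ts_mask.sum(axis=1)
        tv = diff.sum(axis=1) - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(comp > 0, ts / np.maximum(comp, 1), 0.0)
            Q = np.where(comp > 0, tv / np.maximum(comp, 1), 0.0)
            arg_a = 1.0 - 2.0 * P - Q
            arg_b = 1.0 - 2.0 * Q
            d = np.where(
                (arg_a > 0) & (arg_b > 0),
                -0.5 * np.log(np.maximum(arg_a, 1e-300))
                - 0.25 * np.log(np.maximum(arg_b, 1e-300)),
                np.nan,
            )
        d = np.where(comp == 0, np.nan, d)
        d = np.where(np.isnan(d), np.nan, np.maximum(d, 0.0))
        for k, j in enumerate(range(i + 1, n)):
            values[i, j] = values[j, i] = d[k]
            sites[i, j] = sites[j, i] = comp[k]
            pair = frozenset((labels[i], labels[j]))
            if np.isnan(d[k]):
                undefined.add(pair)
            if comp[k] < min_overlap:
                low.add(pair)
    return DistanceMatrix(
        labels=labels,
        values=values,
        comparable_sites=sites,
        undefined_pairs=undefined,
        low_overlap_pairs=low,
        min_overlap=min_overlap,
    )
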