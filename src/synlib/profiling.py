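"""Positional amino-acid composition and CDR-H3 length-distribution profiling.

A repertoire's CDR windows are tabulated position by position into residue
frequency matrices (one profile per CDR; CDR-H3 is stratified by length, with
no cross-length alignment). Length-range selection finds the shortest
contiguous window of CDR-H3 lengths reaching a target coverage of the natural
repertoire. Designed and observed profiles are compared by per-position total
variation distance (TVD), a bounded [0, 1] metric: TVD(p) = ½ Σ_r |d(p,r) − o(p,r)|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import AA_ALPHABET

_TOL = 1e-9


@dataclass
class CompositionProfile:
    """Position × residue frequency matrix for one CDR (one length stratum).

    ``matrix`` rows are positions, columns follow ``AA_ALPHABET`` order and
    sum to 1 except at positions with zero observations, which hold all-zero
    rows and are listed in ``unobserved_positions``.
    """

    cdr_id: str
    length: int
    matrix: np.ndarray
    counts: np.ndarray
    position_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.matrix.shape != (self.length, len(AA_ALPHABET)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"(length={self.length}, {len(AA_ALPHABET)})"
            )
        if self.counts.shape != self.matrix.shape:
            raise ValueError("counts shape must match matrix shape")
        if (self.matrix < 0).any():
            raise ValueError("frequencies must be nonnegative")
        if not self.position_labels:
            self.position_labels = [str(i + 1) for i in range(self.length)]
        row_sums = self.matrix.sum(axis=1)
        observed = ~self.unobserved_positions
        if not np.allclose(row_sums[observed], 1.0, atol=_TOL):
            raise ValueError("observed-position frequencies must sum to 1")
        if not np.allclose(row_sums[~observed], 0.0, atol=_TOL):
            raise ValueError("unobserved positions must carry zero frequency")

    @property
    def unobserved_positions(self) -> np.ndarray:
        return self.counts.sum(axis=1) == 0

    def frequency(self, position: int, residue: str) -> float:
        """Frequency of ``residue`` at 0-based ``position``."""
        return float(self.matrix[position, AA_ALPHABET.index(residue)])

    def to_table(self) -> pd.DataFrame:
        """Tidy long-format table: cdr, length, position_label, residue, frequency, count."""
        rows = []
        for p in range(self.length):
            for j, res in enumerate(AA_ALPHABET):
                rows.append(
                    {
                        "cdr": self.cdr_id,
                        "length": self.length,
                        "position_label": self.position_labels[p],
                        "residue": res,
                        "frequency": self.matrix[p, j],
                        "count": int(self.counts[p, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class LengthDistribution:
    """Probability distribution over CDR lengths (in amino acids)."""

    probabilities: dict[int, float]
    total_count: int = 0

    def __post_init__(self) -> None:
        if not self.probabilities:
            raise ValueError("length distribution must be nonempty")
        if any(length <= 0 for length in self.probabilities):
            raise ValueError("lengths must be positive")
        if any(p < 0 for p in self.probabilities.values()):
            raise ValueError("probabilities must be nonnegative")
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > _TOL:
            raise ValueError(f"probabilities must sum to 1 (got {total})")

    @property
    def support(self) -> list[int]:
        return sorted(length for length, p in self.probabilities.items() if p > 0)

    def probability(self, length: int) -> float:
        return self.probabilities.get(length, 0.0)


def profile_composition(cdr_seqs: list[str], cdr_id: str, position_labels=None) -> CompositionProfile:
    """Tabulate the percentage of each of the 20 amino acids at each CDR position.

    All sequences must share one length; stratify CDR-H3 by length first
    (see ``profile_h3_by_length``).
    """
    if not cdr_seqs:
        raise ValueError("empty input: no CDR sequences to profile")
    length = len(cdr_seqs[0])
    for i, seq in enumerate(cdr_seqs):
        if len(seq) != length:
            raise ValueError(
                f"mixed lengths: sequence {i} has length {len(seq)}, expected {length} "
                f"(stratify CDR-H3 by length before profiling)"
            )
    idx = {res: j for j, res in enumerate(AA_ALPHABET)}
    counts = np.zeros((length, len(AA_ALPHABET)), dtype=np.int64)
    for seq in cdr_seqs:
        for p, res in enumerate(seq.upper()):
            counts[p, idx[res]] += 1
    matrix = counts / counts.sum(axis=1, keepdims=True)
    return CompositionProfile(
        cdr_id=cdr_id,
        length=length,
        matrix=matrix,
        counts=counts,
        position_labels=list(position_labels) if position_labels else [],
    )


def h3_length_distribution(h3_seqs: list[str]) -> LengthDistribution:
    """Empirical CDR-H3 length distribution of a repertoire."""
    if not h3_seqs:
        raise ValueError("empty input: no CDR-H3 sequences")
    lengths = [len(s) for s in h3_seqs]
    n = len(lengths)
    counts: dict[int, int] = {}
    for length in lengths:
        counts[length] = counts.get(length, 0) + 1
    return LengthDistribution(
        probabilities={length: c / n for length, c in counts.items()}, total_count=n
    )


def profile_h3_by_length(h3_seqs: list[str]) -> dict[int, CompositionProfile]:
    """Stratify CDR-H3 sequences by length and profile each stratum."""
    by_len: dict[int, list[str]] = {}
    for seq in h3_seqs:
        by_len.setdefault(len(seq), []).append(seq)
    return {L: profile_composition(seqs, "H3") for L, seqs in sorted(by_len.items())}


def select_length_range(dist: LengthDistribution, coverage: float) -> tuple[int, int, float]:
    """Shortest contiguous length window with cumulative probability >= coverage.

    Ties are broken toward the smaller minimum length. Returns
    (min_len, max_len, achieved_coverage).
    """
    if not 0 < coverage <= 1 + _TOL:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    lo, hi = min(dist.support), max(dist.support)
    probs = np.array([dist.probability(L) for L in range(lo, hi + 1)])
    n = len(probs)
    for width in range(1, n + 1):
        for start in range(0, n - width + 1):
            mass = probs[start : start + width].sum()
            if mass >= coverage - _TOL:
                return lo + start, lo + start + width - 1, float(mass)
    return lo, hi, float(probs.sum())  # coverage == 1 within tolerance


@dataclass
class ProfileComparison:
    """Per-position total variation distances plus their mean."""

    table: pd.DataFrame
    mean_tvd: float


def compare_profiles(designed: CompositionProfile, observed: CompositionProfile) -> ProfileComparison:
    """Per-position TVD between a designed and an observed composition profile."""
    if designed.cdr_id != observed.cdr_id or designed.length != observed.length:
        raise ValueError(
            f"profile mismatch: {designed.cdr_id}/{designed.length} vs "
            f"{observed.cdr_id}/{observed.length}"
        )
    tvd = 0.5 * np.abs(designed.matrix - observed.matrix).sum(axis=1)
    table = pd.DataFrame(
        {
            "cdr": designed.cdr_id,
            "position_label": designed.position_labels,
            "tvd": tvd,
        }
    )
    return ProfileComparison(table=table, mean_tvd=float(tvd.mean()))


def profiles_to_table(profiles: list[CompositionProfile]) -> pd.DataFrame:
    return pd.concat([p.to_table() for p in profiles], ignore_index=True)
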