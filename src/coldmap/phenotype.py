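"""Seed survival rate (SR), severity of damage (SD), and extreme-bulk selection.

SR is the percentage of seeds per line surviving a cold treatment;
SD is the mean per-seed damage score on a 0-7 scale (0 = undamaged,
7 = dead). The two indices are near-duplicate measures of cold tolerance
and are expected to be strongly anticorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

#: seeds with a recovery damage score at or below this count as survivors
DEFAULT_SURVIVAL_SCORE_MAX = 5


@dataclass
class SeedScoreMatrix:
    """Per-seed damage scores and survival flags for each line.

    ``scores[line]`` is the list of 0-7 integer damage scores of the line's
    seeds; ``survived[line]`` the matching boolean survival flags. Survival is
    carried explicitly (not inferred from the score) so SR and SD remain
    formally independent inputs; :func:`flags_from_scores` provides the
    default score-threshold convention when only scores are available.
    """

    scores: Dict[str, np.ndarray]
    survived: Dict[str, np.ndarray]
    seeds_per_line: int = 50

    def __post_init__(self) -> None:
        if self.seeds_per_line <= 0:
            raise ValueError("seeds_per_line must be positive")
        for line, sc in self.scores.items():
            sc = np.asarray(sc)
            if sc.size != self.seeds_per_line:
                raise ValueError(f"line {line!r}: expected {self.seeds_per_line} scores")
            if sc.size and (sc.min() < 0 or sc.max() > 7):
                raise ValueError(f"line {line!r}: scores must lie in 0..7")
            self.scores[line] = sc
            fl = np.asarray(self.survived[line], dtype=bool)
            if fl.size != sc.size:
                raise ValueError(f"line {line!r}: flag/score length mismatch")
            self.survived[line] = fl


def flags_from_scores(
    scores: np.ndarray, survival_score_max: int = DEFAULT_SURVIVAL_SCORE_MAX
) -> np.ndarray:
    """Default convention: a seed survives if its score <= threshold."""
    return np.asarray(scores) <= survival_score_max


def compute_sr(matrix: SeedScoreMatrix, line: str) -> float:
    """Survival rate (%) = 100 * survivors / seeds-per-line."""
    if line not in matrix.survived:
        raise KeyError(f"unknown line {line!r}")
    return 100.0 * float(np.count_nonzero(matrix.survived[line])) / matrix.seeds_per_line


def compute_sd(matrix: SeedScoreMatrix, line: str) -> float:
    """Severity of damage: arithmetic mean of the per-seed 0-7 scores."""
    if line not in matrix.scores:
        raise KeyError(f"unknown line {line!r}")
    sc = matrix.scores[line]
    if sc.size == 0:
        raise ValueError(f"line {line!r} has no scores")
    return float(np.mean(sc))


def phenotype_table(matrix: SeedScoreMatrix) -> pd.DataFrame:
    """SR/SD per line as a tidy frame (line_id, SR, SD)."""
    rows = [
        (line, compute_sr(matrix, line), compute_sd(matrix, line))
        for line in matrix.scores
    ]
    return pd.DataFrame(rows, columns=["line_id", "SR", "SD"])


def pearson(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Sample Pearson r with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BulkAssignment:
    """The two disjoint, equal-size extreme bulks (sets of line ids)."""

    tolerant_ids: Set[str] = field(default_factory=set)
    sensitive_ids: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.tolerant_ids & self.sensitive_ids:
            raise ValueError("bulks must be disjoint")
        if len(self.tolerant_ids) != len(self.sensitive_ids):
            raise ValueError("bulks must have equal size")


def select_bulks(phenotypes: pd.DataFrame, n_per_bulk: int) -> BulkAssignment:
    """Pick the SR extremes: top n -> tolerant bulk, bottom n -> sensitive.

    Lines are ranked once, from most to least tolerant, by SR descending,
    then SD ascending (less damage = more tolerant), then line_id; the
    tolerant bulk is the first n of that ranking and the sensitive bulk the
    last n, which makes the selection deterministic and order-invariant.
    """
    if n_per_bulk < 1:
        raise ValueError("n_per_bulk must be >= 1")
    if 2 * n_per_bulk > len(phenotypes):
        raise ValueError("population too small for two disjoint bulks")
    ranked = phenotypes.sort_values(
        ["SR", "SD", "line_id"], ascending=[False, True, True], kind="mergesort"
    )["line_id"].tolist()
    return BulkAssignment(
        tolerant_ids=set(ranked[:n_per_bulk]),
        sensitive_ids=set(ranked[-n_per_bulk:]),
    )


def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"line_id", "SR"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    return df


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)
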