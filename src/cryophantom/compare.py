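"""Statistical harness for comparing alignment programs.

Per-micrograph metrics (resolution limit, CV, shift RMSE, ...) collected for
several programs over a common movie set are compared with a one-way ANOVA;
when the ANOVA is significant, a post-hoc analysis runs paired t-tests over
every program pair (paired by movie). Pixel-value distributions of
micrographs from different programs are compared with two-sample
Kolmogorov–Smirnov tests after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "MetricTable",
    "anova_across_programs",
    "posthoc_pairs",
    "ks_pixel_distributions",
]


@dataclass
class MetricTable:
    """Long-format per-(program, movie) metric table.

    Wraps a DataFrame with at least columns ``program`` and ``movie_id``
    plus one column per metric. Paired tests require a balanced design:
    every program scored on the same movie set.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"program", "movie_id"} - set(self.frame.columns)
        if missing:
            raise InvalidParameterError(f"metric table missing columns {missing}")

    @classmethod
    def from_csv(cls, path) -> "MetricTable":
        return cls(pd.read_csv(path))

    @property
    def programs(self) -> list[str]:
        return sorted(self.frame["program"].unique())

    def metric_by_program(self, metric: str) -> dict[str, np.ndarray]:
        if metric not in self.frame.columns:
            raise InvalidParameterError(f"unknown metric column {metric!r}")
        return {
            prog: grp.sort_values("movie_id")[metric].to_numpy(dtype=float)
            for prog, grp in self.frame.groupby("program")
        }

    def is_balanced(self) -> bool:
        sets = [
            frozenset(grp["movie_id"]) for _, grp in self.frame.groupby("program")
        ]
        return all(s == sets[0] for s in sets)


def anova_across_programs(
    table: MetricTable, metric: str, alpha: float = 0.05
) -> dict:
    """One-way ANOVA of ``metric`` grouped by program.

    Returns {"F", "p", "significant", "groups"}. Degenerate when every group
    has zero within-group variance (the F statistic is undefined).
    """
    groups = table.metric_by_program(metric)
    if len(groups) < 2:
        raise InvalidParameterError("need >= 2 programs")
    arrays = list(groups.values())
    if any(a.size < 2 for a in arrays):
        raise InvalidParameterError("need >= 2 movies per program")
    if all(np.ptp(a) == 0 for a in arrays):
        raise DegenerateInputError(
            "zero within-group variance in all groups; ANOVA undefined"
        )
    f_stat, p = stats.f_oneway(*arrays)
    return {
        "F": float(f_stat),
        "p": float(p),
        "significant": bool(p < alpha),
        "groups": list(groups),
    }


def posthoc_pairs(
    table: MetricTable, metric: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Paired t-tests for every program pair, run after a significant ANOVA.

    Pairing is by movie_id, so the design must be balanced. Each row reports
    the raw two-sided p-value plus both the uncorrected decision (the
    protocol's own) and a Bonferroni-adjusted one. Pairs whose differences
    have zero variance are degenerate: an exactly zero difference gives
    p = 1, a constant non-zero difference is flagged and treated as
    significant.
    """
    if not table.is_balanced():
        raise InvalidParameterError(
            "unbalanced pairing: every program must cover the same movie set"
        )
    groups = table.metric_by_program(metric)
    progs = sorted(groups)
    pairs = list(combinations(progs, 2))
    n_tests = max(len(pairs), 1)
    rows = []
    for a, b in pairs:
        diff = groups[a] - groups[b]
        degenerate = bool(np.ptp(diff) == 0)
        if degenerate:
            if np.allclose(diff, 0):
                t_stat, p = 0.0, 1.0
                sig = False
            else:  # constant non-zero difference: infinitely strong evidence
                t_stat, p = np.inf, 0.0
                sig = True
        else:
            t_stat, p = stats.ttest_rel(groups[a], groups[b])
            sig = bool(p < alpha)
        rows.append(
            {
                "program_a": a,
                "program_b": b,
                "t": float(t_stat),
                "p": float(p),
                "significant": sig,
                "significant_bonferroni": bool(p < alpha / n_tests),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def compare_programs(
    table: MetricTable, metric: str, alpha: float = 0.05
) -> dict:
    """Full protocol: ANOVA, then post-hoc paired t-tests only if significant."""
    anova = anova_across_programs(table, metric, alpha)
    result = {"anova": anova, "posthoc": None}
    if anova["significant"]:
        result["posthoc"] = posthoc_pairs(table, metric, alpha)
    return result


def ks_pixel_distributions(
    micrograph_a: np.ndarray,
    micrograph_b: np.ndarray,
    subsample: int | None = 100_000,
    seed: int = 0,
    normalize: bool = True,
) -> tuple[float, float]:
    """Two-sample KS test on pixel values of two micrographs.

    By default each image is normalized to mean 0 / sd 1 (so differing
    output conventions — average vs sum — cannot drive the test); pass
    ``normalize=False`` to compare raw values. On megapixel
    images the full-sample test is statistically over-powered, so pixels are
    subsampled (seeded) to ``subsample`` values by default; pass None to use
    every pixel. Returns (KS statistic, p-value).
    """
    a = np.asarray(micrograph_a, dtype=np.float64).ravel()
    b = np.asarray(micrograph_b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("empty input image")
    if normalize:
        if a.std() == 0 or b.std() == 0:
            raise DegenerateInputError("constant image: cannot normalize")
        # quantize at 1e-6 sd after standardising: micrographs of discrete
        # count data carry heavy ties, and float rounding would otherwise
        # split those atoms between scale-equivalent inputs, inflating the
        # statistic by the atom mass; 1e-6 sd is far below any physical
        # pixel-value difference
        a = np.round((a - a.mean()) / a.std(), 6)
        b = np.round((b - b.mean()) / b.std(), 6)
    if subsample is not None:
        # independent generators with the same seed: images of equal size are
        # subsampled at the same pixel positions, so scale-equivalent inputs
        # (e.g. average- vs sum-convention micrographs) stay identical
        if a.size > subsample:
            a = np.random.default_rng(seed).choice(a, size=subsample, replace=False)
        if b.size > subsample:
            b = np.random.default_rng(seed).choice(b, size=subsample, replace=False)
    stat, p = stats.ks_2samp(a, b)
    return float(stat), float(p)
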