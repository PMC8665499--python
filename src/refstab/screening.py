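"""Candidate reference-gene screening from a bulk expression matrix.

A good internal-control (reference) gene is abundant and, above all,
*uniformly* expressed across samples.  Screening a transcriptome cohort
therefore combines four per-gene statistics:

* ``mean_fpkm`` — arithmetic mean expression; candidates should be easy to
  amplify, so a floor (default FPKM ≥ 10) is applied.
* ``cv`` — coefficient of variation, sample SD / mean (default ≤ 0.40).
* ``fc5`` — fold change between the mean of a gene's top 5% of sample
  values and the mean of its bottom 5% (default ≤ 5); a robust range
  statistic insensitive to the middle of the distribution.
* ``dpm`` — dispersion measure, ``cv / sqrt(1 + cv²)`` (default ≤ 0.3), a
  bounded [0, 1) monotone transform of the CV that compresses extreme
  dispersion; equivalently SD / sqrt(mean² + SD²).

Genes with too many exact zeros (dropouts) are removed before any
statistic is computed.  Candidates are the four-way intersection of the
pass sets, ordered by CV rank (1 = most uniform).

The model-style entry point is :class:`ReferenceGeneScreen`; the
individual operations (:func:`filter_low_expression`,
:func:`gene_screen_stats`, :func:`apply_screen`) are plain functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, NoGenesSurviveError

__all__ = [
    "ScreenCriteria",
    "ReferenceGeneScreen",
    "ScreenResults",
    "dispersion_measure",
    "filter_low_expression",
    "gene_screen_stats",
    "apply_screen",
]

FILTERS = ("fpkm", "cv", "fc5", "dpm")


def dispersion_measure(cv):
    """Bounded dispersion statistic ``cv / sqrt(1 + cv**2)``.

    Maps CV in [0, ∞) strictly monotonically into [0, 1); equals
    SD / sqrt(mean² + SD²).  Used as the DPM screening filter.
    """
    cv = np.asarray(cv, dtype=float)
    out = cv / np.sqrt(1.0 + cv**2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds for the four screening filters plus the dropout prefilter.

    Defaults are the conventional cut-offs for a large bulk cohort:
    FPKM ≥ 10, CV ≤ 40%, FC-5% ≤ 5, DPM ≤ 0.3, and removal of genes with
    exact zeros in more than 5% of samples.
    """

    fpkm_min: float = 10.0
    cv_max: float = 0.40
    fc5_max: float = 5.0
    dpm_max: float = 0.3
    max_zero_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("fpkm_min", "cv_max", "fc5_max", "dpm_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.max_zero_fraction <= 1:
            raise ValueError("max_zero_fraction must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenCriteria":
        known = {k: float(v) for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown screening criteria: {sorted(unknown)}")
        return cls(**known)


def filter_low_expression(
    expr: ExpressionMatrix, max_zero_fraction: float = 0.05
) -> ExpressionMatrix:
    """Drop genes whose exact-zero count strictly exceeds ``n·fraction``.

    With 1217 samples and a 5% fraction the cut falls at 60.85, so genes
    with ≥ 61 zeros are removed.  Raises :class:`NoGenesSurviveError` when
    nothing is left.
    """
    if not 0 < max_zero_fraction <= 1:
        raise ValueError("max_zero_fraction must be in (0, 1]")
    vf = expr.values_frame
    zero_counts = (vf.to_numpy() == 0.0).sum(axis=1)
    keep = zero_counts <= vf.shape[1] * max_zero_fraction
    if not keep.any():
        raise NoGenesSurviveError(
            "no genes survive the low-expression prefilter "
            f"(zero-fraction threshold {max_zero_fraction})"
        )
    return ExpressionMatrix(vf.loc[keep])


def _tail_k(n_samples: int, tail: float) -> int:
    # round-half-away-from-zero to mirror spreadsheet ROUND, floor at 1
    return max(1, int(math.floor(tail * n_samples + 0.5)))


def gene_screen_stats(
    expr: ExpressionMatrix,
    *,
    tail: float = 0.05,
    fc_mode: str = "tail_mean",
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-gene screening statistics: mean FPKM, CV, FC-5%, DPM, CV rank.

    Parameters
    ----------
    expr : ExpressionMatrix
    tail : float
        Tail fraction for the fold-change statistic (default 0.05).
    fc_mode : {"tail_mean", "quantile"}
        ``tail_mean`` (default): ratio of the mean of the top ``k`` values
        to the mean of the bottom ``k``, ``k = round(tail·n)`` with a floor
        of one value per tail.  ``quantile``: ratio of the (1−tail) to the
        tail quantile.
    ddof : int
        Degrees-of-freedom for the SD behind the CV (1 = sample SD).

    Returns
    -------
    pandas.DataFrame indexed by gene with columns
    ``mean_fpkm, cv, fc5, dpm, degenerate, cv_rank``.  Genes with zero
    mean get ``cv = fc5 = inf`` and ``degenerate = True``; constant
    positive genes get ``cv = 0, fc5 = 1``.  ``cv_rank`` is 1 for the
    lowest CV; ties are broken by input gene order.
    """
    vf = expr.values_frame
    n = vf.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    arr = vf.to_numpy(dtype=float)

    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)

    k = _tail_k(n, tail)
    srt = np.sort(arr, axis=1)
    bottom = srt[:, :k].mean(axis=1)
    top = srt[:, -k:].mean(axis=1)
    if fc_mode == "quantile":
        bottom = np.quantile(arr, tail, axis=1)
        top = np.quantile(arr, 1 - tail, axis=1)
    elif fc_mode != "tail_mean":
        raise ValueError(f"unknown fc_mode {fc_mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        fc5 = np.where(bottom > 0, top / bottom, np.where(top > 0, np.inf, 1.0))

    degenerate = ~np.isfinite(cv)
    dpm = np.where(np.isfinite(cv), dispersion_measure(np.where(degenerate, 0, cv)), 1.0)

    stats = pd.DataFrame(
        {
            "mean_fpkm": mean,
            "cv": cv,
            "fc5": fc5,
            "dpm": dpm,
            "degenerate": degenerate,
        },
        index=vf.index,
    )
    # stable mergesort keeps input gene order on ties
    order = stats["cv"].to_numpy().argsort(kind="stable")
    rank = np.empty(len(stats), dtype=int)
    rank[order] = np.arange(1, len(stats) + 1)
    stats["cv_rank"] = rank
    return stats


def _venn_region_counts(pass_sets: dict[str, set]) -> dict[str, int]:
    """Counts of the 15 non-empty regions of the 4-set Venn diagram.

    Keys are '+'-joined sorted filter names; a gene is counted in the
    region of exactly the filters it passes (genes passing none are not
    in any region).
    """
    counts: dict[str, int] = {}
    names = list(pass_sets)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(pass_sets[c] for c in combo))
            outside = set.union(
                set(), *(pass_sets[c] for c in names if c not in combo)
            )
            counts["+".join(combo)] = len(inside - outside)
    return counts


def apply_screen(stats: pd.DataFrame, criteria: ScreenCriteria) -> "ScreenResults":
    """Apply thresholds to screening statistics and intersect the pass sets.

    Returns a :class:`ScreenResults` carrying the per-filter pass sets,
    the 15-region Venn partition counts, and the candidate list (4-way
    intersection ordered by CV rank).
    """
    if stats.empty:
        raise ValueError("empty screening statistics")
    flags = pd.DataFrame(
        {
            "pass_fpkm": stats["mean_fpkm"] >= criteria.fpkm_min,
            "pass_cv": stats["cv"] <= criteria.cv_max,
            "pass_fc5": stats["fc5"] <= criteria.fc5_max,
            "pass_dpm": stats["dpm"] <= criteria.dpm_max,
        },
        index=stats.index,
    )
    pass_sets = {f: set(stats.index[flags[f"pass_{f}"]]) for f in FILTERS}
    candidates = set.intersection(*pass_sets.values())
    ordered = stats.loc[sorted(candidates, key=lambda g: stats.at[g, "cv_rank"])]
    return ScreenResults(
        stats=pd.concat([stats, flags], axis=1),
        criteria=criteria,
        pass_sets=pass_sets,
        venn_counts=_venn_region_counts(pass_sets),
        candidates=list(ordered.index),
    )


@dataclass
class ReferenceGeneScreen:
    """Screening model over an expression matrix.

    Examples
    --------
    >>> screen = ReferenceGeneScreen(expr)          # doctest: +SKIP
    >>> res = screen.fit()                          # doctest: +SKIP
    >>> res.candidates                              # doctest: +SKIP
    """

    expr: ExpressionMatrix
    tail: float = 0.05
    fc_mode: str = "tail_mean"
    ddof: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.expr, pd.DataFrame):
            self.expr = ExpressionMatrix(self.expr)

    def fit(self, criteria: ScreenCriteria | None = None) -> "ScreenResults":
        criteria = criteria or ScreenCriteria()
        kept = filter_low_expression(self.expr, criteria.max_zero_fraction)
        stats = gene_screen_stats(
            kept, tail=self.tail, fc_mode=self.fc_mode, ddof=self.ddof
        )
        res = apply_screen(stats, criteria)
        res.n_prefiltered = self.expr.n_genes - kept.n_genes
        return res


@dataclass
class ScreenResults:
    """Fitted screening results: statistics, pass flags, Venn partition."""

    stats: pd.DataFrame
    criteria: ScreenCriteria
    pass_sets: dict
    venn_counts: dict
    candidates: list
    n_prefiltered: int = 0

    @property
    def candidate_stats(self) -> pd.DataFrame:
        return self.stats.loc[self.candidates]

    def stats_table(self) -> pd.DataFrame:
        """The exportable per-gene table (columns in the documented order)."""
        cols = [
            "mean_fpkm", "cv", "fc5", "dpm",
            "pass_fpkm", "pass_cv", "pass_fc5", "pass_dpm", "cv_rank",
        ]
        out = self.stats[cols].copy()
        out.index.name = "gene"
        return out

    def to_tsv(self, path) -> None:
        self.stats_table().to_csv(path, sep="\t")

    def report(self) -> dict:
        """JSON-ready screen report: Venn region counts + ordered candidates."""
        return {
            "criteria": vars(self.criteria) | {},
            "n_genes_evaluated": int(len(self.stats)),
            "n_prefiltered_low_expression": int(self.n_prefiltered),
            "venn_region_counts": {k: int(v) for k, v in self.venn_counts.items()},
            "pass_counts": {f: len(s) for f, s in self.pass_sets.items()},
            "candidates": list(self.candidates),
        }

    def summary(self) -> str:
        lines = [
            "Reference-gene screen",
            "=====================",
            f"genes evaluated:        {len(self.stats)}",
            f"dropout-prefiltered:    {self.n_prefiltered}",
        ]
        for f in FILTERS:
            lines.append(f"pass {f:<5}              {len(self.pass_sets[f])}")
        lines.append(f"candidates (4-way):     {len(self.candidates)}")
        if self.candidates:
            lines.append("top candidates by CV rank: " + ", ".join(
                map(str, self.candidates[:10])))
        return "\n".join(lines)
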