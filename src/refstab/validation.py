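"""Validation of chosen normalizers by relative-expression concordance.

Once candidate reference genes are ranked, the practical question is
whether a chosen single- or multi-gene normalizer actually changes the
biological read-out.  For a normalizer set the per-sample normalization
factor (NF) is the geometric mean of the member genes' Ct values; a
target gene's relative expression in sample *s* is

    2 ** -(Ct_target,s - NF_s)

Two normalizers are then compared by (i) the Pearson correlation of the
relative-expression profiles they produce (log2 scale by default) and
(ii) the correlation of the vectors of between-group t-test p-values —
the "detection efficiency" view: do the two normalizers lead to the same
statistical calls?
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data import CtMatrix
from .stability import _as_frame

__all__ = [
    "NormalizerSet",
    "normalization_factor",
    "relative_expression",
    "group_pairwise_ttests",
    "normalizer_concordance",
    "NormalizerValidation",
    "ValidationResults",
]


@dataclass(frozen=True)
class NormalizerSet:
    """A named combination of 1–5 reference genes."""

    name: str
    genes: tuple

    def __init__(self, genes, name: str | None = None):
        genes = tuple(genes)
        if not 1 <= len(genes) <= 5:
            raise ValueError("a normalizer set holds 1 to 5 reference genes")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in normalizer set")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "name", name or "+".join(map(str, genes)))


def normalization_factor(ct, rgs) -> pd.Series:
    """Per-sample NF: geometric mean of the reference genes' Ct values."""
    vf = _as_frame(ct)
    genes = list(rgs.genes) if isinstance(rgs, NormalizerSet) else list(rgs)
    missing = [g for g in genes if g not in vf.index]
    if missing:
        raise KeyError(f"reference genes absent from Ct matrix: {missing}")
    sub = vf.loc[genes].to_numpy(dtype=float)
    if (sub <= 0).any():
        raise ValueError("geometric mean undefined for non-positive Ct")
    return pd.Series(sps.gmean(sub, axis=0), index=vf.columns, name="nf")


def relative_expression(ct, target, rgs) -> pd.Series:
    """Relative expression ``2**-(Ct_target - NF)`` per sample."""
    vf = _as_frame(ct)
    if target not in vf.index:
        raise KeyError(f"target gene {target!r} absent from Ct matrix")
    genes = tuple(rgs.genes) if isinstance(rgs, NormalizerSet) else tuple(rgs)
    if target in genes:
        raise ValueError(f"target {target!r} cannot be part of its own normalizer")
    nf = normalization_factor(vf, genes)
    return pd.Series(
        np.power(2.0, -(vf.loc[target] - nf)), index=vf.columns, name=str(target)
    )


def group_pairwise_ttests(
    values: pd.Series,
    groups,
    *,
    equal_var: bool = True,
    adjust: str | None = None,
) -> dict:
    """Two-sided independent t-tests between every pair of group levels.

    Parameters
    ----------
    values : pandas.Series
        Per-sample relative expression.
    groups : sequence
        Per-sample group labels aligned with ``values``.
    equal_var : bool
        Student's pooled-variance test by default (spreadsheet
        convention); ``False`` switches to Welch.
    adjust : {"bh", None}
        Optionally add Benjamini–Hochberg adjusted p-values.

    Returns
    -------
    dict with ``p_matrix`` (symmetric DataFrame of raw p-values, unit-free
    diagonal of 1), ``group_stats`` (mean, SEM, n per level) and, when
    requested, ``p_matrix_adjusted``.  Pairs where both groups have zero
    variance and equal means are degenerate: p = 1 and the pair is listed
    under ``degenerate_pairs``.
    """
    values = pd.Series(values)
    groups = pd.Series(np.asarray(groups), index=values.index)
    levels = list(pd.unique(groups))
    by = {lev: values[groups == lev].to_numpy(dtype=float) for lev in levels}
    for lev, arr in by.items():
        if arr.size < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 samples")

    p = pd.DataFrame(np.ones((len(levels), len(levels))), index=levels, columns=levels)
    degenerate = []
    for a, b in itertools.combinations(levels, 2):
        xa, xb = by[a], by[b]
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            if xa.mean() == xb.mean():
                degenerate.append((a, b))
                pv = 1.0
            else:
                pv = 0.0
        else:
            pv = float(sps.ttest_ind(xa, xb, equal_var=equal_var).pvalue)
        p.loc[a, b] = p.loc[b, a] = pv

    stats = pd.DataFrame(
        {
            "n": [by[lev].size for lev in levels],
            "mean": [by[lev].mean() for lev in levels],
            "sem": [sps.sem(by[lev]) for lev in levels],
        },
        index=levels,
    )
    out = {"p_matrix": p, "group_stats": stats, "degenerate_pairs": degenerate}
    if adjust == "bh":
        iu = np.triu_indices(len(levels), k=1)
        flat = p.to_numpy()[iu]
        adj = multipletests(flat, method="fdr_bh")[1]
        pa = p.copy()
        pa.values[iu] = adj
        pa.values[(iu[1], iu[0])] = adj
        out["p_matrix_adjusted"] = pa
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def normalizer_concordance(a, b, *, log_scale: bool = False) -> tuple:
    """Pearson concordance (r, r², p) between two flattened result sets.

    ``a`` and ``b`` must share shape and ordering (relative-expression
    vectors/matrices, or p-value vectors).  ``log_scale=True`` correlates
    log2 values — the sensible default for exponential quantities like
    2^−ΔCt, selectable by the caller.
    """
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("concordance inputs must share shape and ordering")
    if log_scale:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log-scale concordance requires positive values")
        x, y = np.log2(x), np.log2(y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(r) ** 2, float(p)


def _concordance_matrix(vectors: dict, *, log_scale: bool) -> pd.DataFrame:
    names = list(vectors)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        r, _, _ = normalizer_concordance(vectors[a], vectors[b], log_scale=log_scale)
        mat.loc[a, b] = mat.loc[b, a] = r
    return mat


@dataclass
class NormalizerValidation:
    """Validation model: targets × normalizer sets on one Ct matrix.

    Parameters
    ----------
    ct : CtMatrix or DataFrame
    targets : sequence
        Target genes to quantify (must not appear in any normalizer).
    normalizers : sequence of NormalizerSet or gene tuples
    groups : sequence, optional
        Per-sample group labels; default from CtMatrix metadata.
    """

    ct: CtMatrix | pd.DataFrame
    targets: tuple
    normalizers: tuple
    groups: object = None

    def __post_init__(self):
        self.targets = tuple(self.targets)
        self.normalizers = tuple(
            ns if isinstance(ns, NormalizerSet) else NormalizerSet(ns)
            for ns in self.normalizers
        )
        if self.groups is None and isinstance(self.ct, CtMatrix):
            g = self.ct.groups()
            self.groups = None if g is None else g.to_numpy()

    def fit(self, *, equal_var: bool = True, log_concordance: bool = True,
            adjust: str | None = None) -> "ValidationResults":
        vf = _as_frame(self.ct)
        rel = {}
        tests = {}
        for t in self.targets:
            for ns in self.normalizers:
                rel[(t, ns.name)] = relative_expression(vf, t, ns)
                if self.groups is not None:
                    tests[(t, ns.name)] = group_pairwise_ttests(
                        rel[(t, ns.name)], self.groups,
                        equal_var=equal_var, adjust=adjust,
                    )

        expr_conc, pval_conc = {}, {}
        for t in self.targets:
            expr_conc[t] = _concordance_matrix(
                {ns.name: rel[(t, ns.name)] for ns in self.normalizers},
                log_scale=log_concordance,
            )
            if tests:
                iu = None
                vecs = {}
                for ns in self.normalizers:
                    pm = tests[(t, ns.name)]["p_matrix"].to_numpy()
                    if iu is None:
                        iu = np.triu_indices(pm.shape[0], k=1)
                    vecs[ns.name] = pm[iu]
                pval_conc[t] = _concordance_matrix(vecs, log_scale=False)

        return ValidationResults(
            relative=rel, tests=tests,
            expression_concordance=expr_conc,
            pvalue_concordance=pval_conc,
            targets=self.targets,
            normalizers=self.normalizers,
            groups=self.groups,
        )


@dataclass
class ValidationResults:
    """Fitted validation results (tidy tables + concordance matrices)."""

    relative: dict
    tests: dict
    expression_concordance: dict
    pvalue_concordance: dict
    targets: tuple
    normalizers: tuple
    groups: object = None

    def relative_table(self) -> pd.DataFrame:
        """Tidy table: target, normalizer, sample, (group), value."""
        rows = []
        for (t, name), series in self.relative.items():
            df = series.rename("value").rename_axis("sample").reset_index()
            df.insert(0, "normalizer", name)
            df.insert(0, "target", t)
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        if self.groups is not None:
            gmap = pd.Series(
                np.asarray(self.groups),
                index=self.relative[next(iter(self.relative))].index,
            )
            out["group"] = out["sample"].map(gmap)
        return out

    def report(self) -> dict:
        rep = {
            "targets": list(self.targets),
            "normalizers": {ns.name: list(ns.genes) for ns in self.normalizers},
            "expression_concordance_r": {
                t: self.expression_concordance[t].round(6).to_dict()
                for t in self.targets
            },
        }
        if self.pvalue_concordance:
            rep["pvalue_concordance_r"] = {
                t: self.pvalue_concordance[t].round(6).to_dict()
                for t in self.targets
            }
        return rep

    def summary(self) -> str:
        lines = [
            "Normalizer validation",
            "=====================",
            f"targets: {', '.join(map(str, self.targets))}",
            f"normalizers: {', '.join(ns.name for ns in self.normalizers)}",
        ]
        for t in self.targets:
            m = self.expression_concordance[t]
            ref = m.columns[0]
            lines.append(
                f"{t}: expression concordance r vs {ref}: "
                + ", ".join(
                    f"{c}={m.loc[ref, c]:.3f}" for c in m.columns[1:]
                )
            )
        return "\n".join(lines)
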