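"""Expression-stability estimators for candidate reference genes.

Five complementary views of "stable" Ct behaviour over a panel of
candidate genes measured across samples:

* **geNorm** (:func:`genorm`) — a gene's stability ``M`` is the mean,
  over all partner genes, of the sample SD of the pairwise log-ratio of
  relative quantities.  Genes are then excluded one at a time (highest
  ``M`` first), and the pairwise variation ``V_k`` between normalization
  factors built from the ``k`` and ``k+1`` most stable genes indicates
  how many reference genes suffice.
* **ΔCt method** (:func:`delta_ct_stability`) — the mean, over partner
  genes, of the sample SD of the raw Ct difference.  With a 100%
  (efficiency-2) quantity transform this is *identical* to geNorm's
  initial ``M``: log2 of a ratio of 2^(−Ct) quantities is an affine
  function of the Ct difference, and SDs ignore the constant.
* **NormFinder** (:func:`normfinder`) — a model-based decomposition of
  sample-centred Ct into intragroup variance and intergroup bias,
  combined into one stability value (see the function docstring).
* **BestKeeper** (:func:`bestkeeper`) — descriptive: a gene's "SD" is
  the mean absolute deviation of its Ct from the gene mean, plus the
  correlation of each gene with the BestKeeper index (per-sample
  geometric mean Ct across genes).
* **Comprehensive score** (:func:`comprfinder`) — rank aggregation of
  the above into a single final score.

For every method a *lower* value means a *more stable* gene.  The
model-style wrapper is :class:`StabilityAnalysis` /
:class:`StabilityResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import CtMatrix

__all__ = [
    "GenormResult",
    "genorm",
    "delta_ct_stability",
    "normfinder",
    "bestkeeper",
    "comprfinder",
    "StabilityAnalysis",
    "StabilityResults",
]

METHOD_COLUMNS = {
    "genorm": "genorm_m",
    "normfinder": "normfinder",
    "bestkeeper": "bestkeeper_sd",
    "delta_ct": "delta_ct_sd",
}


def _as_frame(ct) -> pd.DataFrame:
    if isinstance(ct, CtMatrix):
        return ct.values_frame
    return pd.DataFrame(ct).astype(float)


def _strict_ranks(values: pd.Series) -> pd.Series:
    """Ascending ranks 1..n, ties broken by input order (a permutation)."""
    order = values.to_numpy().argsort(kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return pd.Series(ranks, index=values.index)


# ---------------------------------------------------------------------------
# geNorm / ΔCt
# ---------------------------------------------------------------------------

def _pairwise_sd_matrix(log_q: np.ndarray) -> np.ndarray:
    """V[j, k] = sample SD over samples of (log_q[j] - log_q[k])."""
    n = log_q.shape[0]
    V = np.zeros((n, n))
    for j in range(n):
        diff = log_q[j] - log_q  # (n_genes, n_samples)
        V[j] = diff.std(axis=1, ddof=1)
    return V


@dataclass
class GenormResult:
    """Full geNorm output.

    Attributes
    ----------
    initial_m : pandas.Series
        M value of every gene computed on the full panel (identical to
        the ΔCt-method statistic under the efficiency-2 transform).
    stepwise_m : pandas.Series
        M value each gene had at the moment it was excluded; the final
        two genes share the same value.
    exclusion_order : list
        Genes in exclusion order, least stable first.
    stability_order : list
        Genes from most to least stable (reverse exclusion order with
        the final pair first, kept in input order).
    pairwise_variation : pandas.Series
        ``V_k`` for k = 2..n−1, indexed ``"V2/3"`` etc.: the SD of the
        log2 ratio of normalization factors built from the k and k+1
        most stable genes.
    ranks : pandas.Series
        1..n ranks by stepwise M (final pair tie broken by input order).
    """

    initial_m: pd.Series
    stepwise_m: pd.Series
    exclusion_order: list
    stability_order: list
    pairwise_variation: pd.Series
    ranks: pd.Series
    degenerate: bool = False


def genorm(ct, efficiency: float = 2.0) -> GenormResult:
    """geNorm stability analysis of a collapsed Ct matrix.

    Each gene is first transformed to a relative quantity
    ``Q = E**(min_ct − ct)`` (E = 2 assumes 100% amplification
    efficiency, i.e. the best sample of a gene has quantity 1).  The
    per-sample additive part of Ct cancels in every pairwise ratio, so
    all geNorm quantities are invariant to sample-loading offsets.
    """
    vf = _as_frame(ct)
    genes = list(vf.index)
    n_genes, n_samples = vf.shape
    if n_genes < 3:
        raise ValueError("geNorm needs at least 3 genes")
    if n_samples < 2:
        raise ValueError("geNorm needs at least 2 samples")

    arr = vf.to_numpy(dtype=float)
    log_e = np.log2(float(efficiency))
    # log2 Q = log2(E) * (min_ct - ct); the per-gene min is a constant and
    # cancels in every SD, but keeping it matches the classical transform.
    log_q = log_e * (arr.min(axis=1, keepdims=True) - arr)

    V = _pairwise_sd_matrix(log_q)
    with np.errstate(invalid="ignore"):
        initial_m = pd.Series(
            (V.sum(axis=1)) / (n_genes - 1), index=genes, name="genorm_m"
        )

    degenerate = bool(np.allclose(V, 0.0))
    if degenerate:
        warnings.warn("all pairwise variations are zero; geNorm M degenerate at 0",
                      stacklevel=2)

    # stepwise exclusion of the least stable gene
    active = list(range(n_genes))
    stepwise = {}
    exclusion: list = []
    while len(active) > 2:
        sub = V[np.ix_(active, active)]
        m = sub.sum(axis=1) / (len(active) - 1)
        # ties: exclude the later gene in input order (stable argmax on reversed)
        worst_pos = int(np.argmax(m[::-1]))
        worst_pos = len(active) - 1 - worst_pos
        gene = genes[active[worst_pos]]
        stepwise[gene] = float(m[worst_pos])
        exclusion.append(gene)
        active.pop(worst_pos)
    # final two genes: their mutual pairwise SD, shared
    j, k = active
    final_m = float(V[j, k])
    for idx in active:
        stepwise[genes[idx]] = final_m
    stability_order = [genes[j], genes[k]] + exclusion[::-1]

    stepwise_m = pd.Series({g: stepwise[g] for g in genes}, name="genorm_stepwise_m")

    # V_k series over successive normalization factors (geometric means of
    # the k most stable genes' quantities == arithmetic means of log2 Q)
    order_idx = [genes.index(g) for g in stability_order]
    v_k = {}
    for kk in range(2, n_genes):
        nf_k = log_q[order_idx[:kk]].mean(axis=0)
        nf_k1 = log_q[order_idx[: kk + 1]].mean(axis=0)
        v_k[f"V{kk}/{kk + 1}"] = float(np.std(nf_k - nf_k1, ddof=1))
    pairwise_variation = pd.Series(v_k, name="pairwise_variation")

    ranks = _strict_ranks(stepwise_m)
    return GenormResult(
        initial_m=initial_m,
        stepwise_m=stepwise_m,
        exclusion_order=exclusion,
        stability_order=stability_order,
        pairwise_variation=pairwise_variation,
        ranks=ranks,
        degenerate=degenerate,
    )


def delta_ct_stability(ct) -> pd.Series:
    """ΔCt-method stability: mean pairwise-ΔCt SD per gene.

    For each gene pair (j, k) the per-sample difference
    ``ΔCt = ct_j − ct_k`` has a sample SD; gene j's statistic is the
    mean of those SDs over all partners k ≠ j.  Per-sample additive
    shifts (loading differences) cancel in the differences.
    """
    vf = _as_frame(ct)
    if vf.shape[0] < 2:
        raise ValueError("the ΔCt method needs at least 2 genes")
    if vf.shape[1] < 2:
        raise ValueError("the ΔCt method needs at least 2 samples")
    V = _pairwise_sd_matrix(vf.to_numpy(dtype=float))
    return pd.Series(V.sum(axis=1) / (vf.shape[0] - 1), index=vf.index,
                     name="delta_ct_sd")


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def normfinder(ct, groups=None) -> pd.Series:
    """Model-based stability value per gene (variance decomposition).

    Ct values are first centred per sample (the column mean over genes is
    subtracted), removing the shared loading/abundance component; call the
    result ``z``.  For each gene *i* and sample group *g*:

    * the intragroup variance ``σ²_ig`` is estimated from the within-group
      sample variance ``u_ig`` of ``z``, corrected for the bias the
      gene-centring introduces: with *l* genes,
      ``E[u_ig] = σ²_ig (1 − 2/l) + S_g/l²`` where ``S_g = Σ_k σ²_kg``, and
      ``S_g`` itself is recovered from ``Σ_k u_kg = S_g (l − 1)/l``;
      estimates are floored at zero;
    * the intergroup difference ``d_ig`` is the group mean of ``z`` minus
      the gene's weighted overall mean, shrunk towards zero by the
      empirical-Bayes factor ``τ²_i / (τ²_i + σ²_ig/n_g)`` with
      ``τ²_i = max(Σ_g d²_ig/(G−1) − mean_g(σ²_ig/n_g), 0)``.

    The stability value combines bias and variance,

        ρ_i = mean over groups of ( |d̃_ig| + sqrt(σ̂²_ig / n_g) ),

    so both condition-dependence and noise penalise a gene; lower is more
    stable.  With a single group (or no grouping) the statistic reduces
    to ``sqrt(σ̂²_i)``, whose ranking equals ranking by the variance of
    sample-centred Ct.

    Parameters
    ----------
    ct : CtMatrix or DataFrame
    groups : sequence or pandas.Series, optional
        Per-sample group labels aligned with the matrix columns.  When
        ``ct`` is a :class:`CtMatrix` with metadata, its ``class_label``
        column is used by default.  Groups with fewer than 2 samples are
        excluded with a warning.
    """
    vf = _as_frame(ct)
    l = vf.shape[0]
    if l < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    if groups is None and isinstance(ct, CtMatrix):
        g = ct.groups()
        groups = None if g is None else g.to_numpy()
    if groups is not None:
        groups = np.asarray(pd.Series(groups, index=vf.columns))
        if len(groups) != vf.shape[1]:
            raise ValueError("groups must align with samples")

    z = vf.to_numpy(dtype=float)
    z = z - z.mean(axis=0, keepdims=True)  # centre each sample across genes

    def sigma2_hat(zg: np.ndarray) -> np.ndarray:
        """Bias-corrected intragroup variances for one group (genes,)."""
        u = zg.var(axis=1, ddof=1)
        S = u.sum() * l / (l - 1)
        return np.clip((u - S / l**2) * l / (l - 2), 0.0, None)

    if groups is None or len(pd.unique(groups)) < 2:
        return pd.Series(np.sqrt(sigma2_hat(z)), index=vf.index, name="normfinder")

    levels = list(pd.unique(groups))
    usable, sizes = [], []
    for lev in levels:
        n_g = int((groups == lev).sum())
        if n_g < 2:
            warnings.warn(
                f"group {lev!r} has a single sample; excluded from the "
                "intragroup variance", stacklevel=2)
        else:
            usable.append(lev)
            sizes.append(n_g)
    if len(usable) < 2:
        keep = np.isin(groups, usable)
        return pd.Series(np.sqrt(sigma2_hat(z[:, keep])), index=vf.index,
                         name="normfinder")

    G = len(usable)
    sizes = np.array(sizes, dtype=float)
    zbar = np.empty((l, G))
    sig2 = np.empty((l, G))
    for gi, lev in enumerate(usable):
        zg = z[:, groups == lev]
        zbar[:, gi] = zg.mean(axis=1)
        sig2[:, gi] = sigma2_hat(zg)

    overall = (zbar * sizes).sum(axis=1) / sizes.sum()
    d = zbar - overall[:, None]
    samp_var = sig2 / sizes  # variance of each group mean
    tau2 = np.clip((d**2).sum(axis=1) / (G - 1) - samp_var.mean(axis=1), 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(tau2[:, None] + samp_var > 0,
                          tau2[:, None] / (tau2[:, None] + samp_var), 0.0)
    d_shrunk = d * shrink
    rho = (np.abs(d_shrunk) + np.sqrt(samp_var)).mean(axis=1)
    return pd.Series(rho, index=vf.index, name="normfinder")


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper(ct) -> pd.DataFrame:
    """BestKeeper descriptive stability table plus index correlations.

    Per gene: arithmetic and geometric mean Ct, min, max, the BestKeeper
    "SD" (mean absolute deviation from the arithmetic mean — not the
    sample SD), CV% = SD/mean·100, and the Pearson correlation (r, r²,
    p) of the gene's Ct with the BestKeeper index, the per-sample
    geometric mean of Ct across genes.
    """
    vf = _as_frame(ct)
    if vf.shape[0] < 2:
        raise ValueError("BestKeeper needs at least 2 genes")
    arr = vf.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError("BestKeeper requires strictly positive Ct values")

    amean = arr.mean(axis=1)
    mad = np.abs(arr - amean[:, None]).mean(axis=1)
    index = sps.gmean(arr, axis=0)

    r = np.empty(arr.shape[0])
    p = np.empty(arr.shape[0])
    for i in range(arr.shape[0]):
        if arr[i].std() == 0 or index.std() == 0:
            r[i], p[i] = np.nan, np.nan
        else:
            r[i], p[i] = sps.pearsonr(arr[i], index)

    out = pd.DataFrame(
        {
            "mean_ct": amean,
            "geo_mean_ct": sps.gmean(arr, axis=1),
            "min_ct": arr.min(axis=1),
            "max_ct": arr.max(axis=1),
            "bestkeeper_sd": mad,
            "cv_pct": 100.0 * mad / amean,
            "r_vs_index": r,
            "r2_vs_index": r**2,
            "p_vs_index": p,
        },
        index=vf.index,
    )
    out.attrs["index"] = pd.Series(index, index=vf.columns, name="bestkeeper_index")
    return out


# ---------------------------------------------------------------------------
# Comprehensive aggregation
# ---------------------------------------------------------------------------

def comprfinder(values: pd.DataFrame, scheme: str = "minmax_mean") -> pd.DataFrame:
    """Aggregate per-method stability values into one final score.

    ``values`` has one row per gene and one column per method (lower =
    more stable everywhere).  The default scheme min–max scales each
    column onto [0, 1] (0 = most stable within that method) and averages
    the scaled values; it is invariant to any per-method affine
    rescaling.  ``scheme="rank_geomean"`` instead takes the geometric
    mean of the per-method ranks (the RefFinder-style alternative).  The
    default aggregation is a documented stand-in for the original
    comprehensive-score tool, whose exact formula is not public.

    Returns a DataFrame with columns ``score`` and ``rank``; ranks are
    ascending by score with ties broken by mean per-method rank, then by
    gene input order.
    """
    if values.isna().any().any():
        raise ValueError("stability values contain NaN")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 methods to aggregate")
    ranks = values.rank(axis=0, method="average")
    if scheme == "minmax_mean":
        rng = values.max() - values.min()
        scaled = (values - values.min()).div(rng.replace(0, np.inf))
        score = scaled.mean(axis=1)
    elif scheme == "rank_geomean":
        score = pd.Series(sps.gmean(ranks, axis=1), index=values.index)
    else:
        raise ValueError(f"unknown aggregation scheme {scheme!r}")

    mean_rank = ranks.mean(axis=1)
    order = sorted(
        range(len(score)),
        key=lambda i: (score.iloc[i], mean_rank.iloc[i], i),
    )
    final_rank = np.empty(len(score), dtype=int)
    final_rank[order] = np.arange(1, len(score) + 1)
    return pd.DataFrame(
        {"score": score, "rank": final_rank}, index=values.index
    )


# ---------------------------------------------------------------------------
# Model / Results wrapper
# ---------------------------------------------------------------------------

@dataclass
class StabilityAnalysis:
    """Reference-gene stability model over a collapsed Ct matrix.

    Parameters
    ----------
    ct : CtMatrix or DataFrame
        Genes × samples mean Ct.
    groups : sequence, optional
        Per-sample group labels for NormFinder; defaults to the
        metadata ``class_label`` when ``ct`` is a :class:`CtMatrix`.
    efficiency : float
        Amplification base for the geNorm quantity transform (2 = 100%).

    Examples
    --------
    >>> res = StabilityAnalysis(ct).fit()     # doctest: +SKIP
    >>> print(res.summary())                  # doctest: +SKIP
    """

    ct: CtMatrix | pd.DataFrame
    groups: object = None
    efficiency: float = 2.0

    def fit(
        self,
        methods: tuple = ("genorm", "normfinder", "bestkeeper", "delta_ct"),
        *,
        genorm_value: str = "stepwise",
        aggregation: str = "minmax_mean",
    ) -> "StabilityResults":
        """Run the selected estimators and aggregate their rankings.

        ``genorm_value`` selects which M enters the combined table:
        ``"stepwise"`` (M at exclusion, the default) or ``"initial"``.
        """
        vf = _as_frame(self.ct)
        values = {}
        genorm_res = None
        bestkeeper_table = None
        for m in methods:
            if m == "genorm":
                genorm_res = genorm(self.ct, efficiency=self.efficiency)
                values["genorm_m"] = (
                    genorm_res.stepwise_m if genorm_value == "stepwise"
                    else genorm_res.initial_m
                )
            elif m == "delta_ct":
                values["delta_ct_sd"] = delta_ct_stability(self.ct)
            elif m == "normfinder":
                values["normfinder"] = normfinder(self.ct, self.groups)
            elif m == "bestkeeper":
                bestkeeper_table = bestkeeper(self.ct)
                values["bestkeeper_sd"] = bestkeeper_table["bestkeeper_sd"]
            else:
                raise ValueError(f"unknown stability method {m!r}")

        table = pd.DataFrame(values, index=vf.index)
        agg = comprfinder(table, scheme=aggregation)
        return StabilityResults(
            values=table,
            ranks=table.apply(_strict_ranks),
            comprehensive=agg,
            genorm=genorm_res,
            bestkeeper_table=bestkeeper_table,
            settings={
                "methods": tuple(methods),
                "genorm_value": genorm_value,
                "aggregation": aggregation,
                "efficiency": self.efficiency,
                "grouped": self.groups is not None
                or (isinstance(self.ct, CtMatrix) and self.ct.groups() is not None),
            },
        )


@dataclass
class StabilityResults:
    """Fitted stability results: per-method values, ranks, final score."""

    values: pd.DataFrame
    ranks: pd.DataFrame
    comprehensive: pd.DataFrame
    genorm: GenormResult | None
    bestkeeper_table: pd.DataFrame | None
    settings: dict = field(default_factory=dict)

    @property
    def ranking(self) -> list:
        """Genes from most to least stable by the comprehensive score."""
        return list(self.comprehensive.sort_values("rank").index)

    def table(self) -> pd.DataFrame:
        """Combined per-gene table: value and rank per method + final score."""
        out = {}
        for col in self.values.columns:
            out[col] = self.values[col]
            out[f"{col}_rank"] = self.ranks[col]
        out["score"] = self.comprehensive["score"]
        out["final_rank"] = self.comprehensive["rank"]
        df = pd.DataFrame(out, index=self.values.index)
        df.index.name = "gene"
        return df

    def to_tsv(self, path) -> None:
        self.table().to_csv(path, sep="\t")

    def report(self) -> dict:
        """JSON-ready report including the full geNorm output."""
        rep = {
            "settings": dict(self.settings),
            "values": {c: self.values[c].round(6).to_dict() for c in self.values},
            "comprehensive_score": self.comprehensive["score"].round(6).to_dict(),
            "final_ranking": self.ranking,
            "aggregation_note": (
                "comprehensive score is a min-max/mean rank aggregation, a "
                "documented stand-in for the original comprehensive-score tool"
            ),
        }
        if self.genorm is not None:
            g = self.genorm
            rep["genorm"] = {
                "initial_m": g.initial_m.round(6).to_dict(),
                "stepwise_m": g.stepwise_m.round(6).to_dict(),
                "exclusion_order": list(g.exclusion_order),
                "stability_order": list(g.stability_order),
                "pairwise_variation": g.pairwise_variation.round(6).to_dict(),
            }
        return rep

    def summary(self) -> str:
        df = self.table()
        lines = [
            "Reference-gene stability analysis",
            "=================================",
            f"genes: {df.shape[0]}   methods: {', '.join(self.values.columns)}",
            "",
            df.round(4).to_string(),
            "",
            "most stable:  " + ", ".join(map(str, self.ranking[:3])),
            "least stable: " + ", ".join(map(str, self.ranking[-3:])),
        ]
        if self.genorm is not None and len(self.genorm.pairwise_variation):
            v = self.genorm.pairwise_variation
            lines.append("geNorm pairwise variation: "
                         + ", ".join(f"{k}={x:.4f}" for k, x in v.items()))
        return "\n".join(lines)
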