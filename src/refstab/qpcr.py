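"""qRT-PCR data handling: replicate collapsing, standard curves, Ct summaries.

Ct (cycle threshold) is the PCR cycle at which a well's fluorescence
crosses the detection threshold; it is approximately log2-inverse in
template abundance, so one cycle ≈ one two-fold dilution.  Technical
replicates of the same (gene, sample) reaction are averaged; the spread
of a replicate group is a quality flag, not an exclusion rule.

Amplification efficiency is estimated from a ten-fold dilution series:
an OLS fit of Ct on log10(template amount) has slope ``S`` (conventionally
negative, ≈ −3.32 for perfect doubling), and efficiency

    E = 10**(-1/S) - 1

so E = 1.0 means 100% (template doubles each cycle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import CtMatrix

__all__ = [
    "StandardCurve",
    "collapse_technical_replicates",
    "standard_curve_fit",
    "descriptive_ct_stats",
]


def collapse_technical_replicates(
    raw: pd.DataFrame,
    max_range: float = 0.5,
    meta: pd.DataFrame | None = None,
) -> tuple[CtMatrix, pd.DataFrame]:
    """Average technical replicates into a per-(gene, sample) Ct matrix.

    Parameters
    ----------
    raw : pandas.DataFrame
        Replicate-level long table with columns ``sample, gene, replicate,
        ct`` (as returned by :func:`refstab.data.read_ct_table`).
    max_range : float
        Replicate groups whose max − min exceeds this many cycles are
        recorded in the QC report (default 0.5 cycles) but still averaged.
    meta : pandas.DataFrame, optional
        Sample metadata to attach; defaults to ``raw.attrs['meta']`` when
        present.

    Returns
    -------
    (CtMatrix, qc_report) where ``qc_report`` lists every flagged
    (gene, sample) with its replicate count, range and mean.
    """
    required = {"sample", "gene", "replicate", "ct"}
    if not required.issubset(raw.columns):
        raise ValueError(f"replicate table needs columns {sorted(required)}")
    if raw.empty:
        raise ValueError("empty replicate table")

    grouped = raw.groupby(["gene", "sample"], sort=False)["ct"]
    agg = grouped.agg(mean="mean", n="count", rng=lambda x: x.max() - x.min())

    wide = agg["mean"].unstack("sample")
    # preserve first-appearance order of genes and samples
    gene_order = list(dict.fromkeys(raw["gene"]))
    sample_order = list(dict.fromkeys(raw["sample"]))
    wide = wide.loc[gene_order, sample_order]
    if wide.isna().any().any():
        g, s = np.argwhere(wide.isna().to_numpy())[0]
        raise ValueError(
            f"no replicates for gene {wide.index[g]!r}, sample {wide.columns[s]!r}"
        )

    flagged = agg[agg["rng"] > max_range].reset_index()
    qc = flagged.rename(columns={"rng": "ct_range", "n": "n_replicates", "mean": "mean_ct"})
    if meta is None:
        meta = raw.attrs.get("meta")
    return CtMatrix(wide, meta=meta), qc[["gene", "sample", "n_replicates", "ct_range", "mean_ct"]]


@dataclass
class StandardCurve:
    """OLS standard-curve fit of Ct against log10 template amount."""

    points: list  # (log10_amount, ct) pairs
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    positive_slope: bool = False

    def summary(self) -> str:
        return (
            f"standard curve: slope {self.slope:.4f} cycles/log10, "
            f"R^2 {self.r_squared:.4f}, efficiency {self.efficiency * 100:.1f}%"
            + (" [WARNING: positive slope]" if self.positive_slope else "")
        )


def standard_curve_fit(points) -> StandardCurve:
    """Fit a dilution series and derive primer amplification efficiency.

    ``points`` is an iterable of (log10_template_amount, ct) pairs; at
    least 3 points spanning at least 2 log10 units are required.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise ValueError("a standard curve needs at least 3 dilution points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10 template amounts")
    if np.ptp(x) < 2:
        warnings.warn("dilution series spans < 2 log10 units", stacklevel=2)

    fit = sps.linregress(x, y)
    slope = float(fit.slope)
    positive = slope > 0
    if positive:
        warnings.warn("positive standard-curve slope; check dilution labels", stacklevel=2)
    efficiency = float(10.0 ** (-1.0 / slope) - 1.0)
    return StandardCurve(
        points=pts,
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=efficiency,
        positive_slope=positive,
    )


def descriptive_ct_stats(ct: CtMatrix, by: str | None = None) -> pd.DataFrame:
    """Per-gene Ct summaries (mean, sample SD, min, max, quartiles).

    Parameters
    ----------
    ct : CtMatrix
        Collapsed (one value per gene and sample) matrix.
    by : str, optional
        Metadata column to stratify by (e.g. ``"material"`` or
        ``"class_label"``); without it one stratum covering all samples
        is summarised.

    Returns
    -------
    DataFrame with one row per (stratum, gene), columns
    ``n, mean, sd, min, q1, median, q3, max, sd_undefined``.
    """
    vf = ct.values_frame
    if by is None:
        strata = {"all": list(vf.columns)}
    else:
        if ct.meta is None or by not in ct.meta.columns:
            raise ValueError(f"no metadata column {by!r} to stratify by")
        labels = ct.meta.loc[vf.columns, by]
        strata = {
            lev: [s for s in vf.columns if labels[s] == lev]
            for lev in pd.unique(labels)
        }

    rows = []
    for level, samples in strata.items():
        sub = vf[samples]
        arr = sub.to_numpy()
        n = arr.shape[1]
        undef = n < 2
        if undef:
            warnings.warn(f"stratum {level!r} has < 2 samples; SD undefined", stacklevel=2)
        q1, med, q3 = np.percentile(arr, [25, 50, 75], axis=1)
        rows.append(pd.DataFrame({
            "stratum": level,
            "gene": sub.index,
            "n": n,
            "mean": arr.mean(axis=1),
            "sd": arr.std(axis=1, ddof=1) if not undef else np.nan,
            "min": arr.min(axis=1),
            "q1": q1,
            "median": med,
            "q3": q3,
            "max": arr.max(axis=1),
            "sd_undefined": undef,
        }))
    return pd.concat(rows, ignore_index=True).set_index(["stratum", "gene"])
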