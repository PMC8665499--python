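"""Published summary tables bundled as frozen inputs.

These are the printed per-gene summary statistics from a breast-cancer
reference-gene study (16 candidate genes screened from 1217 bulk
transcriptomes and profiled by qRT-PCR over 66 tissue samples in 11
groups and 7 cell lines).  They serve as fixed inputs for consistency
checks — e.g. verifying that the dispersion-measure transform reproduces
the printed (CV, DPM) pairs — and as reference orderings.

The per-sample measured Ct table itself was distributed only as online
supplementary material and is not redistributable here;
:func:`load_measured_tissue_ct` documents where to place it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "screening_table",
    "tissue_stability_table",
    "cell_line_stability_table",
    "standard_normalizer_sets",
    "load_measured_tissue_ct",
]

# gene: (mean FPKM, CV as fraction, FC-5%, DPM, CV order among all genes)
_SCREENING = {
    "SF1":    (38.65,  0.2170,  2.52, 0.21, 5),
    "TARDBP": (20.30,  0.1851,  2.32, 0.18, 1),
    "THRAP3": (41.96,  0.2444,  3.10, 0.24, 16),
    "QRICH1": (14.67,  0.2576,  3.11, 0.25, 45),
    "TRA2B":  (11.66,  0.2414,  2.78, 0.23, 12),
    "SRSF3":  (39.09,  0.2408,  2.76, 0.23, 11),
    "YY1":    (15.20,  0.2475,  2.83, 0.24, 23),
    "DNAJC8": (30.96,  0.2459,  2.92, 0.24, 19),
    "RNF10":  (32.58,  0.2462,  2.78, 0.24, 21),
    "RHOA":   (223.73, 0.2560,  3.05, 0.25, 40),
    "ACTB":   (1490.51, 0.3806, 5.02, 0.36, 1834),
    "TUBA1A": (72.98,  0.5942, 12.88, 0.51, 6728),
    "RPL13A": (716.37, 0.5646,  8.78, 0.49, 6189),
    "B2M":    (625.30, 0.6466, 12.56, 0.54, 7483),
    "GAPDH":  (739.50, 0.7226, 11.79, 0.59, 8454),
    "GUSB":   (31.47,  1.4243, 11.33, 0.82, 12695),
}

# gene: (value, rank) per method, tissue panel (66 samples)
_TISSUE_STABILITY = {
    "SF1":    {"genorm": (0.369, 1),  "normfinder": (0.018, 5),
               "bestkeeper": (1.233, 4),  "delta_ct": (0.626, 4),
               "comprehensive": (0.146, 1)},
    "TRA2B":  {"genorm": (0.455, 6),  "normfinder": (0.011, 1),
               "bestkeeper": (1.334, 10), "delta_ct": (0.602, 1),
               "comprehensive": (0.152, 2)},
    "THRAP3": {"genorm": (0.386, 2),  "normfinder": (0.016, 3),
               "bestkeeper": (1.245, 5),  "delta_ct": (0.624, 3),
               "comprehensive": (0.170, 3)},
    "YY1":    {"genorm": (0.465, 7),  "normfinder": (0.019, 6),
               "bestkeeper": (1.283, 7),  "delta_ct": (0.654, 6),
               "comprehensive": (0.193, 4)},
    "RHOA":   {"genorm": (0.475, 8),  "normfinder": (0.013, 2),
               "bestkeeper": (1.314, 8),  "delta_ct": (0.611, 2),
               "comprehensive": (0.200, 5)},
    "RNF10":  {"genorm": (0.441, 5),  "normfinder": (0.017, 4),
               "bestkeeper": (1.334, 11), "delta_ct": (0.637, 5),
               "comprehensive": (0.236, 6)},
    "QRICH1": {"genorm": (0.429, 4),  "normfinder": (0.020, 7),
               "bestkeeper": (1.281, 6),  "delta_ct": (0.659, 7),
               "comprehensive": (0.241, 7)},
    "TARDBP": {"genorm": (0.394, 3),  "normfinder": (0.024, 9),
               "bestkeeper": (1.183, 3),  "delta_ct": (0.693, 8),
               "comprehensive": (0.269, 8)},
    "SRSF3":  {"genorm": (0.514, 9),  "normfinder": (0.022, 8),
               "bestkeeper": (1.331, 9),  "delta_ct": (0.727, 9),
               "comprehensive": (0.359, 9)},
    "RPL13A": {"genorm": (0.615, 12), "normfinder": (0.037, 13),
               "bestkeeper": (1.087, 2),  "delta_ct": (0.839, 12),
               "comprehensive": (0.445, 10)},
    "TUBA1A": {"genorm": (0.552, 10), "normfinder": (0.027, 10),
               "bestkeeper": (1.424, 13), "delta_ct": (0.785, 10),
               "comprehensive": (0.513, 11)},
    "DNAJC8": {"genorm": (0.711, 15), "normfinder": (0.039, 14),
               "bestkeeper": (0.992, 1),  "delta_ct": (0.965, 15),
               "comprehensive": (0.583, 12)},
    "GUSB":   {"genorm": (0.646, 13), "normfinder": (0.032, 11),
               "bestkeeper": (1.344, 12), "delta_ct": (0.863, 13),
               "comprehensive": (0.593, 13)},
    "ACTB":   {"genorm": (0.583, 11), "normfinder": (0.032, 12),
               "bestkeeper": (1.529, 14), "delta_ct": (0.796, 11),
               "comprehensive": (0.608, 14)},
    "GAPDH":  {"genorm": (0.675, 14), "normfinder": (0.046, 15),
               "bestkeeper": (1.635, 16), "delta_ct": (0.882, 14),
               "comprehensive": (0.848, 15)},
    "B2M":    {"genorm": (0.748, 16), "normfinder": (0.055, 16),
               "bestkeeper": (1.576, 15), "delta_ct": (1.001, 16),
               "comprehensive": (0.977, 16)},
}

_CELL_STABILITY = {
    "THRAP3": {"genorm": (0.008, 1),  "normfinder": (0.354, 1),
               "bestkeeper": (0.616, 1),  "delta_ct": (0.300, 1),
               "comprehensive": (0.010, 1)},
    "RHOA":   {"genorm": (0.009, 2),  "normfinder": (0.447, 5),
               "bestkeeper": (0.622, 2),  "delta_ct": (0.426, 7),
               "comprehensive": (0.042, 2)},
    "QRICH1": {"genorm": (0.013, 3),  "normfinder": (0.544, 12),
               "bestkeeper": (0.664, 3),  "delta_ct": (0.507, 9),
               "comprehensive": (0.111, 3)},
    "SF1":    {"genorm": (0.018, 4),  "normfinder": (0.509, 8),
               "bestkeeper": (0.674, 4),  "delta_ct": (0.777, 13),
               "comprehensive": (0.136, 4)},
    "RNF10":  {"genorm": (0.026, 8),  "normfinder": (0.507, 7),
               "bestkeeper": (0.740, 5),  "delta_ct": (0.501, 8),
               "comprehensive": (0.209, 5)},
    "DNAJC8": {"genorm": (0.026, 7),  "normfinder": (0.377, 2),
               "bestkeeper": (0.762, 8),  "delta_ct": (0.419, 6),
               "comprehensive": (0.217, 6)},
    "GUSB":   {"genorm": (0.025, 6),  "normfinder": (0.523, 10),
               "bestkeeper": (0.757, 7),  "delta_ct": (0.402, 5),
               "comprehensive": (0.232, 7)},
    "YY1":    {"genorm": (0.027, 9),  "normfinder": (0.495, 6),
               "bestkeeper": (0.773, 9),  "delta_ct": (0.353, 3),
               "comprehensive": (0.254, 8)},
    "RPL13A": {"genorm": (0.038, 11), "normfinder": (0.393, 3),
               "bestkeeper": (0.784, 11), "delta_ct": (0.639, 11),
               "comprehensive": (0.267, 9)},
    "TARDBP": {"genorm": (0.019, 5),  "normfinder": (0.539, 11),
               "bestkeeper": (0.744, 6),  "delta_ct": (0.318, 2),
               "comprehensive": (0.268, 10)},
    "GAPDH":  {"genorm": (0.035, 10), "normfinder": (0.573, 13),
               "bestkeeper": (0.774, 10), "delta_ct": (0.606, 10),
               "comprehensive": (0.363, 11)},
    "TRA2B":  {"genorm": (0.039, 12), "normfinder": (0.421, 4),
               "bestkeeper": (0.918, 12), "delta_ct": (0.390, 4),
               "comprehensive": (0.386, 12)},
    "SRSF3":  {"genorm": (0.048, 13), "normfinder": (0.510, 9),
               "bestkeeper": (1.025, 13), "delta_ct": (0.716, 12),
               "comprehensive": (0.511, 13)},
    "B2M":    {"genorm": (0.058, 14), "normfinder": (0.946, 15),
               "bestkeeper": (1.084, 14), "delta_ct": (0.821, 14),
               "comprehensive": (0.767, 14)},
    "TUBA1A": {"genorm": (0.067, 15), "normfinder": (0.772, 14),
               "bestkeeper": (1.374, 16), "delta_ct": (0.932, 15),
               "comprehensive": (0.879, 15)},
    "ACTB":   {"genorm": (0.077, 16), "normfinder": (0.977, 16),
               "bestkeeper": (1.175, 15), "delta_ct": (1.475, 16),
               "comprehensive": (0.901, 16)},
}


def screening_table() -> pd.DataFrame:
    """Published screening statistics for the 16 candidate genes.

    Columns: ``mean_fpkm, cv, fc5, dpm, cv_order`` (CV as a fraction,
    e.g. 0.2170 for a printed 21.70%; ``cv_order`` is the gene's CV rank
    among all genes that survived screening in the source cohort).
    """
    df = pd.DataFrame.from_dict(
        _SCREENING, orient="index",
        columns=["mean_fpkm", "cv", "fc5", "dpm", "cv_order"],
    )
    df.index.name = "gene"
    return df


def _stability_frame(raw: dict) -> pd.DataFrame:
    rows = {}
    for gene, methods in raw.items():
        row = {}
        for m, (v, r) in methods.items():
            row[m] = v
            row[f"{m}_rank"] = r
        rows[gene] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene"
    return df


def tissue_stability_table() -> pd.DataFrame:
    """Published per-method stability values/ranks, tissue panel (n = 66)."""
    return _stability_frame(_TISSUE_STABILITY)


def cell_line_stability_table() -> pd.DataFrame:
    """Published per-method stability values/ranks, cell-line panel (n = 21)."""
    return _stability_frame(_CELL_STABILITY)


def standard_normalizer_sets() -> list:
    """The 13 validated single/multi reference-gene combinations."""
    from .validation import NormalizerSet

    combos = [
        ("SF1", "TRA2B", "THRAP3", "RHOA", "QRICH1"),
        ("SF1", "THRAP3", "TRA2B"),
        ("THRAP3", "RHOA", "QRICH1"),
        ("SF1", "THRAP3"),
        ("TRA2B", "RHOA"),
        ("SF1",), ("THRAP3",), ("TRA2B",), ("RHOA",), ("QRICH1",),
        ("ACTB",), ("GAPDH",), ("ACTB", "GAPDH"),
    ]
    return [NormalizerSet(c) for c in combos]


def load_measured_tissue_ct(path=None) -> pd.DataFrame:
    """Load the measured per-sample Ct table (not distributed here).

    The original study released the per-sample mean Ct values of the 16
    candidate genes only as online supplementary material, which this
    package cannot redistribute.  To run the checks that depend on the
    measured data, download that supplementary Ct table, save it as a
    wide CSV (gene rows, sample columns) and either pass its path here
    or place it at ``src/refstab/measured/tissue_ct.csv``.
    """
    if path is None:
        path = Path(__file__).parent / "measured" / "tissue_ct.csv"
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"measured Ct table not found at {path}; the per-sample Ct values "
            "are supplementary material of the source study and are not "
            "distributed with this package — see load_measured_tissue_ct.__doc__"
        )
    return pd.read_csv(path, index_col=0)
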