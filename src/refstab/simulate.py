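"""Synthetic data generators with known ground truth.

Two generators make the whole pipeline testable without any download:

* :func:`simulate_ct` builds a Ct matrix from an additive model on the
  cycle (log-abundance) scale,

      ct[g, s] = mu_g + phi_s + gamma[g, c(s)] + eps[g, s]

  with a per-sample loading offset ``phi_s ~ N(0, sigma_phi)`` shared by
  all genes, a frozen per-(gene, group) condition effect
  ``gamma[g, c] ~ N(0, group_effect_scale_g)``, and gene-specific noise
  ``eps ~ N(0, sigma_g)``.  The ground-truth stability ordering is the
  ascending realised per-gene variance excluding the shared sample
  offset (group-effect contribution + sigma_g²) — condition dependence
  counts as instability, which is exactly why classical housekeeping
  genes fail in practice.

* :func:`simulate_fpkm` builds an expression matrix containing a planted
  set of reference-like genes (abundant, low dispersion, so they pass
  every screening filter by construction) among decoy classes that each
  violate screening criteria (low expression; high dispersion; a low-end
  dropout tail that inflates FC-5% while leaving the CV moderate; a
  moderate-dispersion class that exceeds only the DPM cut; zero-inflated
  genes caught by the prefilter).

Both are deterministic under their spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CtMatrix, ExpressionMatrix

__all__ = ["CtSimSpec", "FpkmSimSpec", "simulate_ct", "simulate_fpkm"]


def _default_group_sizes() -> dict:
    # 11 tissue groups × 6 biological replicates
    return {f"G{i + 1:02d}": 6 for i in range(11)}


@dataclass
class CtSimSpec:
    """Design of a synthetic Ct experiment.

    Defaults emulate a tissue panel: 16 candidate genes over 11 sample
    groups of 6, with gene 0 planted as the most stable candidate
    (noise SD 0.1 cycles, no condition effect) and the rest spanning
    noise SDs up to 1.0 and condition-effect scales up to 1.5 cycles.
    The shared per-sample offset SD is 1 cycle.
    """

    n_genes: int = 16
    group_sizes: dict = field(default_factory=_default_group_sizes)
    baseline_mu: np.ndarray | None = None          # cycles; default spread 16..26
    sample_offset_sd: float = 1.0                  # sigma_phi, cycles
    gene_noise_sd: np.ndarray | None = None        # sigma_g, cycles
    group_effect_scale: np.ndarray | None = None   # gamma_g magnitude, cycles
    seed: int = 0

    def resolved(self) -> tuple:
        n = self.n_genes
        if n < 2:
            raise ValueError("need at least 2 genes")
        sizes = dict(self.group_sizes)
        if any(sz < 2 for sz in sizes.values()):
            raise ValueError("each group needs at least 2 samples")
        mu = (np.linspace(16.0, 26.0, n) if self.baseline_mu is None
              else np.asarray(self.baseline_mu, dtype=float))
        if self.gene_noise_sd is None:
            sd = np.concatenate([[0.1], np.linspace(0.2, 1.0, n - 1)])
        else:
            sd = np.asarray(self.gene_noise_sd, dtype=float)
        if self.group_effect_scale is None:
            gam = np.concatenate([[0.0], np.linspace(0.1, 1.5, n - 1)])
        else:
            gam = np.asarray(self.group_effect_scale, dtype=float)
        for name, arr in (("baseline_mu", mu), ("gene_noise_sd", sd),
                          ("group_effect_scale", gam)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length n_genes={n}")
        if (sd < 0).any() or (gam < 0).any() or self.sample_offset_sd < 0:
            raise ValueError("all SDs must be >= 0")
        return mu, sizes, sd, gam


def simulate_ct(spec: CtSimSpec) -> tuple[CtMatrix, pd.DataFrame]:
    """Draw a Ct matrix and return it with its ground-truth stability table.

    Returns
    -------
    (CtMatrix, truth) — ``truth`` is indexed by gene with columns
    ``noise_sd, group_effect_scale, group_effect_var, true_variance,
    true_rank`` (rank 1 = most stable).  ``group_effect_var`` is the
    realised population variance over samples of the frozen per-group
    effects, so the ordering reflects the data actually drawn.
    """
    mu, sizes, sd, gam = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes

    labels = [g for g, sz in sizes.items() for _ in range(sz)]
    n_samples = len(labels)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    group_levels = list(sizes)
    group_idx = np.array([group_levels.index(g) for g in labels])

    phi = rng.normal(0.0, spec.sample_offset_sd, size=n_samples)
    gamma = rng.normal(0.0, 1.0, size=(n, len(group_levels))) * gam[:, None]
    eps = rng.normal(0.0, 1.0, size=(n, n_samples)) * sd[:, None]

    ct = mu[:, None] + phi[None, :] + gamma[:, group_idx] + eps

    genes = [f"gene{i + 1:02d}" for i in range(n)]
    meta = pd.DataFrame(
        {"class_label": labels, "material": "tissue"}, index=pd.Index(sample_ids, name="sample")
    )
    ctm = CtMatrix(
        pd.DataFrame(ct, index=genes, columns=sample_ids),
        meta=meta,
        provenance="simulated",
    )

    per_sample_gamma = gamma[:, group_idx]
    gamma_var = per_sample_gamma.var(axis=1)  # realised, population
    total = gamma_var + sd**2
    order = total.argsort(kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    truth = pd.DataFrame(
        {
            "noise_sd": sd,
            "group_effect_scale": gam,
            "group_effect_var": gamma_var,
            "true_variance": total,
            "true_rank": rank,
        },
        index=pd.Index(genes, name="gene"),
    )
    return ctm, truth


@dataclass
class FpkmSimSpec:
    """Design of a synthetic FPKM screening matrix.

    ``n_genes`` are split into a planted reference-like class plus decoy
    classes; remaining counts are filled with low-expression genes.
    Class sizes beyond ``planted_reference_count`` can be overridden via
    ``class_counts`` (keys: ``dispersed, dropout_tail,
    moderate_dispersion, zero_inflated, low_expression``).
    """

    n_genes: int = 60
    n_samples: int = 300
    planted_reference_count: int = 5
    reference_median: float = 50.0   # FPKM location of planted genes
    reference_log_sd: float = 0.2    # log-normal scale; CV ~ 0.20
    zero_inflation: float = 0.15     # zero fraction of the zero-inflated class
    class_counts: dict | None = None
    seed: int = 0

    def resolved_counts(self) -> dict:
        if self.planted_reference_count > self.n_genes:
            raise ValueError("planted_reference_count exceeds n_genes")
        rest = self.n_genes - self.planted_reference_count
        counts = {
            "dispersed": rest // 4,
            "dropout_tail": rest // 4,
            "moderate_dispersion": rest // 6,
            "zero_inflated": rest // 4,
        }
        if self.class_counts:
            counts.update(self.class_counts)
        used = sum(counts.values())
        if used > rest:
            raise ValueError("class counts exceed available genes")
        counts["low_expression"] = rest - used
        return counts


def simulate_fpkm(spec: FpkmSimSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw an FPKM matrix with a planted reference-gene set.

    Returns
    -------
    (ExpressionMatrix, membership) — ``membership`` is indexed by gene
    with columns ``gene_class`` and ``planted`` (bool).  Genes are
    shuffled so class does not correlate with position.
    """
    if spec.n_samples < 40:
        raise ValueError("need at least 40 samples for stable tail statistics")
    counts = spec.resolved_counts()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_genes, spec.n_samples

    blocks: list[tuple[str, np.ndarray]] = []

    def lognormal(median, log_sd, size):
        return np.exp(rng.normal(np.log(median), log_sd, size=size))

    for _ in range(spec.planted_reference_count):
        blocks.append(("planted_reference",
                       lognormal(spec.reference_median, spec.reference_log_sd, m)))
    for _ in range(counts["dispersed"]):
        # CV ~ 1.3: fails CV, DPM and usually FC-5%
        blocks.append(("dispersed", lognormal(spec.reference_median, 1.0, m)))
    for _ in range(counts["dropout_tail"]):
        # tight around the median but ~5% of samples drop to a tenth:
        # FC-5% ~ 10 while CV stays ~ 0.2 — violates FC-5% only
        x = lognormal(spec.reference_median, 0.05, m)
        k = max(1, int(round(0.05 * m)))
        low = rng.choice(m, size=k, replace=False)
        x[low] *= 0.1
        blocks.append(("dropout_tail", x))
    for _ in range(counts["moderate_dispersion"]):
        # empirical CV pinned at 0.37, between the DPM cut (DPM 0.3 ==
        # CV 0.3145) and the CV cut (0.40): violates DPM only.  The draw
        # is rescaled to the target mean/CV so the class sits in that
        # window by construction, not just in expectation.
        z = lognormal(1.0, 0.36, m)
        u = (z - z.mean()) / z.std(ddof=1)
        blocks.append(("moderate_dispersion",
                       spec.reference_median * (1.0 + 0.37 * u)))
    for _ in range(counts["zero_inflated"]):
        x = lognormal(spec.reference_median, spec.reference_log_sd, m)
        nz = rng.binomial(m, spec.zero_inflation)
        nz = max(nz, int(np.floor(0.05 * m)) + 1)  # guarantee prefilter hit
        x[rng.choice(m, size=nz, replace=False)] = 0.0
        blocks.append(("zero_inflated", x))
    for _ in range(counts["low_expression"]):
        blocks.append(("low_expression", lognormal(2.0, 0.2, m)))

    perm = rng.permutation(len(blocks))
    genes = [f"g{i + 1:03d}" for i in range(n)]
    samples = [f"P{j + 1:04d}" for j in range(m)]
    values = np.vstack([blocks[i][1] for i in perm])
    classes = [blocks[i][0] for i in perm]

    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    membership = pd.DataFrame(
        {"gene_class": classes,
         "planted": [c == "planted_reference" for c in classes]},
        index=pd.Index(genes, name="gene"),
    )
    return expr, membership
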