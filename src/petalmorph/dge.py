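"""Negative-binomial Wald tests for two-group expression contrasts.

Counts for gene g in sample s are modelled as NB(mu_gs, alpha_g) with

    log mu_gs = log(effective library size_s) + b0_g + b1_g * x_s,

x_s = 1 for samples in the contrast's numerator group and 0 for the
denominator.  b1 is the natural-log fold-change; the Wald statistic
b1 / SE(b1) is referred to the standard normal and log2FC = b1 / ln 2.
Per-gene dispersions come from a method-of-moments estimate pooled within
groups on size-normalized counts, averaged 50/50 with a mean-dispersion
trend fitted log-linearly in the log mean.  Benjamini-Hochberg controls
the FDR across genes.

This is the same model family as the established NB differential-
expression tools but deliberately simpler: no Cox-Reid adjusted dispersion
likelihood, no fold-change shrinkage, no independent filtering and no
outlier handling.  Every result table records this in ``meta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastSpec",
    "standard_contrasts",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "NBWaldModel",
    "DGEResult",
]

_MODEL_NOTE = (
    "simplified NB Wald fit (method-of-moments dispersion with trend "
    "averaging, TMM-effective library offsets); not a DESeq2 re-implementation"
)


@dataclass
class ContrastSpec:
    """A named two-group comparison over (species, stage) cells."""

    name: str
    numerator: tuple[str, str]  # (species, stage) whose expression is "up" when log2FC > 0
    denominator: tuple[str, str]

    def groups(self, sample_info: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        num = ((sample_info["species"] == self.numerator[0])
               & (sample_info["stage"] == self.numerator[1])).to_numpy()
        den = ((sample_info["species"] == self.denominator[0])
               & (sample_info["stage"] == self.denominator[1])).to_numpy()
        if not num.any() or not den.any():
            raise ValueError(f"contrast {self.name}: empty group")
        if (num & den).any():
            raise ValueError(f"contrast {self.name}: overlapping groups")
        return num, den


def standard_contrasts(species_basal: str = "A", species_derived: str = "B"
                       ) -> list[ContrastSpec]:
    """The four study contrasts: bud vs mature within each species, and the
    two cross-species comparisons at matched stage."""
    a, b = species_basal, species_derived
    return [
        ContrastSpec(f"{a}_bud_vs_{a}_mature", (a, "bud"), (a, "mature")),
        ContrastSpec(f"{b}_bud_vs_{b}_mature", (b, "bud"), (b, "mature")),
        ContrastSpec(f"{a}_bud_vs_{b}_bud", (a, "bud"), (b, "bud")),
        ContrastSpec(f"{a}_mature_vs_{b}_mature", (a, "mature"), (b, "mature")),
    ]


def estimate_dispersion(counts: pd.DataFrame, groups: np.ndarray,
                        lib_sizes: pd.Series | None = None) -> pd.Series:
    """Per-gene NB dispersion alpha >= 0 for the samples in ``groups``.

    ``groups`` labels each selected sample; the moment estimator
    max(0, (s^2 - mean) / mean^2) is computed per group on size-normalized
    counts and pooled with (n_g - 1) weights, then averaged 50/50 with a
    log-linear mean-dispersion trend.  Genes with all-zero counts get NaN
    (untestable).  Floor 1e-8.
    """
    mat = counts.to_numpy(dtype=float)
    groups = np.asarray(groups)
    if lib_sizes is None:
        lib = mat.sum(axis=0)
    else:
        lib = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    sf = lib / lib.mean()
    q = mat / sf  # size-normalized counts on a common scale

    raw = np.zeros(mat.shape[0])
    wsum = 0.0
    any_group_ok = False
    for g in np.unique(groups):
        cols = groups == g
        n = int(cols.sum())
        if n < 2:
            continue
        any_group_ok = True
        m = q[:, cols].mean(axis=1)
        v = q[:, cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m**2
        a = np.where(m > 0, np.maximum(a, 0.0), np.nan)
        raw = raw + np.nan_to_num(a) * (n - 1)
        wsum += n - 1
    if not any_group_ok:
        raise ValueError("need >= 2 samples in at least one group")
    raw = raw / wsum

    mean_all = q.mean(axis=1)
    testable = mean_all > 0
    # Log-linear trend of dispersion on the mean.  The per-gene moment
    # estimates are extremely noisy at small n, so the trend is fitted to
    # arithmetic bin means (unbiased for the dispersion) rather than to
    # per-gene log estimates, which would be badly Jensen-biased downward.
    trend = None
    if testable.sum() >= 50:
        logm = np.log(mean_all[testable])
        bins = np.quantile(logm, np.linspace(0, 1, 13))
        bins[-1] += 1e-9
        which = np.digitize(logm, bins) - 1
        centers, means, weights = [], [], []
        for b in range(12):
            sel = which == b
            if sel.sum() >= 5:
                centers.append(logm[sel].mean())
                means.append(raw[testable][sel].mean())
                weights.append(sel.sum())
        centers, means, weights = map(np.asarray, (centers, means, weights))
        pos = means > 1e-8
        if pos.sum() >= 3:
            slope, intercept = np.polyfit(centers[pos], np.log(means[pos]), 1,
                                          w=np.sqrt(weights[pos]))
            with np.errstate(over="ignore"):
                trend = np.exp(intercept + slope * np.log(np.where(testable, mean_all, 1.0)))
            trend = np.clip(trend, 1e-8, 10.0)
    if trend is None:
        fallback = float(raw[testable].mean()) if testable.any() else 0.0
        trend = np.full(mat.shape[0], max(fallback, 1e-8))
    alpha = 0.5 * raw + 0.5 * trend
    alpha = np.maximum(alpha, 1e-8)
    alpha[~testable] = np.nan
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _irls_nb(y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
             max_iter: int = 50, tol: float = 1e-8):
    """Vectorized per-gene IRLS for the 2-parameter NB log-linear model.

    y: genes x samples; x: sample indicator; alpha: per-gene dispersion.
    Returns (b0, b1, se1, converged).
    """
    n_genes = y.shape[0]
    eps = 0.1
    mean1 = ((y + eps) / np.exp(offset))[:, x == 1].mean(axis=1)
    mean0 = ((y + eps) / np.exp(offset))[:, x == 0].mean(axis=1)
    b0 = np.log(mean0)
    b1 = np.log(mean1) - np.log(mean0)
    alpha = np.nan_to_num(alpha, nan=0.0)

    converged = np.zeros(n_genes, dtype=bool)
    for _ in range(max_iter):
        eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta, -50, 50))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        s00 = w.sum(axis=1)
        s01 = (w * x).sum(axis=1)
        s11 = (w * x * x).sum(axis=1)
        t0 = (w * z).sum(axis=1)
        t1 = (w * x * z).sum(axis=1)
        det = s00 * s11 - s01**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        new_b0 = (s11 * t0 - s01 * t1) / det
        new_b1 = (s00 * t1 - s01 * t0) / det
        step0 = np.clip(new_b0 - b0, -5, 5)
        step1 = np.clip(new_b1 - b1, -5, 5)
        delta = np.maximum(np.abs(step0), np.abs(step1))
        b0 = b0 + step0
        b1 = b1 + step1
        converged |= delta < tol
        if converged.all():
            break

    eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
    mu = np.exp(np.clip(eta, -50, 50))
    w = mu / (1.0 + alpha[:, None] * mu)
    s00 = w.sum(axis=1)
    s01 = (w * x).sum(axis=1)
    s11 = (w * x * x).sum(axis=1)
    det = s00 * s11 - s01**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var1 = s00 / det
    se1 = np.sqrt(np.where(var1 > 0, var1, np.nan))
    return b0, b1, se1, converged


def nb_wald_test(counts: pd.DataFrame, sample_info: pd.DataFrame,
                 contrast: ContrastSpec, dispersions: pd.Series | None = None,
                 effective_lib_sizes: pd.Series | None = None) -> "DGEResult":
    """Wald test of one contrast on a gene x sample count matrix.

    ``effective_lib_sizes`` should be the TMM-effective library sizes from
    the merge stage; plain column sums are used when absent.  Genes with an
    all-zero group are flagged ``zero_group``: their fold-change is
    reported through a 0.5 pseudo-fraction on the group means but they
    carry no Wald statistic.
    """
    num, den = contrast.groups(sample_info.loc[counts.columns])
    use = num | den
    sub = counts.loc[:, use]
    x = num[use].astype(float)

    if effective_lib_sizes is None:
        lib = sub.sum(axis=0).to_numpy(dtype=float)
    else:
        lib = effective_lib_sizes.reindex(sub.columns).to_numpy(dtype=float)
    offset = np.log(lib)

    if dispersions is None:
        dispersions = estimate_dispersion(
            sub, x, pd.Series(lib, index=sub.columns))
    alpha = dispersions.reindex(sub.index).to_numpy(dtype=float)

    y = sub.to_numpy(dtype=float)
    all_zero = y.sum(axis=1) == 0
    zero_num = y[:, x == 1].sum(axis=1) == 0
    zero_den = y[:, x == 0].sum(axis=1) == 0
    zero_group = (zero_num | zero_den) & ~all_zero

    b0, b1, se1, converged = _irls_nb(y, x, offset, alpha)

    base_mean = (y / (lib / lib.mean())).mean(axis=1)
    log2fc = b1 / np.log(2.0)
    # pseudo-fraction fold-change for zero-group genes (reporting only)
    frac = y / lib
    pseudo = 0.5 / lib.mean()
    fc_num = frac[:, x == 1].mean(axis=1) + pseudo
    fc_den = frac[:, x == 0].mean(axis=1) + pseudo
    log2fc = np.where(zero_group, np.log2(fc_num / fc_den), log2fc)

    stat = b1 / se1
    with np.errstate(invalid="ignore"):
        pval = 2.0 * stats.norm.sf(np.abs(stat))
    bad = all_zero | zero_group | ~converged | ~np.isfinite(stat) | np.isnan(alpha)
    stat = np.where(bad, np.nan, stat)
    pval = np.where(bad, np.nan, pval)
    se_out = np.where(bad, np.nan, se1 / np.log(2.0))
    log2fc = np.where(all_zero, np.nan, log2fc)

    flag = np.full(len(sub), "ok", dtype=object)
    flag[~converged] = "not_converged"
    flag[zero_group] = "zero_group"
    flag[all_zero] = "all_zero"

    padj = bh_adjust(pval)
    table = pd.DataFrame({
        "baseMean": base_mean,
        "log2FoldChange": log2fc,
        "lfcSE": se_out,
        "stat": stat,
        "pvalue": pval,
        "padj": padj,
        "flag": flag,
    }, index=sub.index)
    return DGEResult(contrast=contrast, table=table,
                     meta={"model": _MODEL_NOTE, "n_num": int(num.sum()),
                           "n_den": int(den.sum())})


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through and do not
    count toward the number of tests."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


@dataclass
class DGEResult:
    """Per-gene results of one contrast with its provenance."""

    contrast: ContrastSpec
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["padj"] <= fdr]

    def summary(self) -> str:
        n_sig = int((self.table["padj"] <= 0.05).sum())
        return (
            f"Contrast {self.contrast.name}: {len(self.table)} genes tested, "
            f"{n_sig} significant at FDR 0.05 [{self.meta.get('model', '')}]"
        )


class NBWaldModel:
    """Model facade: bind a merged count matrix + sample sheet once, then
    fit any number of contrasts."""

    def __init__(self, counts: pd.DataFrame, sample_info: pd.DataFrame,
                 effective_lib_sizes: pd.Series | None = None):
        missing = [s for s in counts.columns if s not in sample_info.index]
        if missing:
            raise ValueError(f"samples missing from the sample sheet: {missing}")
        self.counts = counts
        self.sample_info = sample_info
        self.effective_lib_sizes = effective_lib_sizes

    def fit(self, contrast: ContrastSpec, dispersions: pd.Series | None = None
            ) -> DGEResult:
        return nb_wald_test(self.counts, self.sample_info, contrast,
                            dispersions=dispersions,
                            effective_lib_sizes=self.effective_lib_sizes)

    def fit_all(self, contrasts: list[ContrastSpec] | None = None
                ) -> dict[str, DGEResult]:
        if contrasts is None:
            species = sorted(self.sample_info["species"].unique())
            contrasts = standard_contrasts(*species)
        return {c.name: self.fit(c) for c in contrasts}
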