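"""Cross-species count-table merging, TMM normalization and cpm filtering.

The two species were assembled and quantified against their own de novo
transcriptomes, so their isoform ids are incomparable.  A common reference
is established by mapping every isoform to the gene models of an annotated
outgroup genome via BLASTx: hits above the e-value threshold are dropped,
each surviving isoform keeps its single best hit (highest bitscore, ties by
smaller e-value then lexicographic gene id), per-gene counts are the sums
over mapped isoforms, and the two species' gene tables are inner-joined so
only gene models detected in both species remain.

Between-sample scaling uses the weighted trimmed mean of M-values (TMM):
library sizes are corrected by a factor derived from trimmed, precision-
weighted log-ratios against a reference sample, and expression is reported
as counts per million of the effective (factor-adjusted) library size.
Feature length is deliberately not corrected for.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "filter_hits",
    "collapse_isoforms",
    "inner_join_species",
    "tmm_factors",
    "tmm_normalize",
    "cpm",
    "cpm_and_filter",
    "qc_sample_similarity",
    "NormalizedMatrix",
]


def filter_hits(hits: pd.DataFrame, e_threshold: float = 1e-3,
                best_hit_only: bool = True) -> dict[str, str]:
    """Isoform -> reference-gene mapping from a BLAST tabular hit frame.

    Hits with e-value above the threshold are discarded.  With
    ``best_hit_only`` (default) each isoform keeps its highest-bitscore
    surviving hit, ties broken by smaller e-value and then lexicographic
    gene id; otherwise the best hit per (isoform, gene) pair is kept for
    every gene (an isoform may then map to several genes, and is counted
    toward each).
    """
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    required = {"qseqid", "sseqid", "evalue", "bitscore"}
    if not required.issubset(hits.columns):
        raise ValueError(f"hit table needs columns {sorted(required)}")
    bad = hits.index[~np.isfinite(hits["evalue"]) | (hits["evalue"] < 0)]
    if len(bad):
        raise ValueError(f"invalid e-value at row {bad[0]}")
    kept = hits[hits["evalue"] <= e_threshold]
    if kept.empty:
        return {}
    ranked = kept.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
    )
    if best_hit_only:
        best = ranked.drop_duplicates("qseqid", keep="first")
        return dict(zip(best["qseqid"].astype(str), best["sseqid"].astype(str)))
    pairs = ranked.drop_duplicates(["qseqid", "sseqid"], keep="first")
    mapping: dict[str, list[str]] = {}
    for q, s in zip(pairs["qseqid"].astype(str), pairs["sseqid"].astype(str)):
        mapping.setdefault(q, []).append(s)
    return mapping


def collapse_isoforms(counts: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Sum isoform counts into reference-gene rows; unmapped isoforms drop.

    ``mapping`` values may be a single gene id (best-hit mode) or a list of
    gene ids (all-hits mode, where an isoform counts toward each gene).
    """
    norm = {str(k): (v if isinstance(v, list) else [v]) for k, v in mapping.items()}
    iso = pd.Series(norm, dtype=object)
    present = counts.index.intersection(iso.index)
    if len(present) == 0:
        out = counts.iloc[:0].copy()
        out.index.name = "gene_id"
        return out.astype(int)
    expanded = iso.loc[present].explode()
    out = counts.loc[expanded.index].groupby(expanded.to_numpy()).sum()
    out.index.name = "gene_id"
    return out.astype(int).sort_index()


def inner_join_species(table_a: pd.DataFrame, table_b: pd.DataFrame
                       ) -> tuple[pd.DataFrame, dict]:
    """Merge two per-species gene tables on their shared gene-model keys.

    Returns the joined matrix (rows = intersection of gene ids, columns =
    union of samples) and a report listing the genes dropped from each side.
    """
    for name, tbl in (("A", table_a), ("B", table_b)):
        if tbl.index.has_duplicates:
            dup = tbl.index[tbl.index.duplicated()][0]
            raise ValueError(f"duplicate gene key {dup!r} in table {name}")
    shared = table_a.index.intersection(table_b.index)
    report = {
        "n_shared": int(len(shared)),
        "dropped_from_a": sorted(table_a.index.difference(table_b.index)),
        "dropped_from_b": sorted(table_b.index.difference(table_a.index)),
    }
    if len(shared) == 0:
        warnings.warn("inner join produced an empty gene set", stacklevel=2)
    merged = table_a.loc[shared].join(table_b.loc[shared], how="inner")
    merged = merged.sort_index()
    merged.index.name = "gene_id"
    return merged, report


@dataclass
class NormalizedMatrix:
    """TMM factors, effective library sizes and the cpm view of a matrix."""

    counts: pd.DataFrame
    factors: pd.Series
    cpm: pd.DataFrame
    filter_mask: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0) * self.factors

    def filtered_cpm(self) -> pd.DataFrame:
        if self.filter_mask is None:
            return self.cpm
        return self.cpm.loc[self.filter_mask[self.filter_mask].index]


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              trim_m: float, trim_a: float) -> float:
    """log2 TMM factor of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no positively expressed gene with the reference")
    o, r = obs[pos], ref[pos]
    m = np.log2(o / lib_obs) - np.log2(r / lib_ref)
    a = 0.5 * (np.log2(o / lib_obs) + np.log2(r / lib_ref))
    # inverse asymptotic variance of M (delta method, binomial sampling)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    finite = np.isfinite(m) & np.isfinite(a) & (w > 0)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        return 0.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank(method="average").to_numpy()
    rank_a = pd.Series(a).rank(method="average").to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
                ) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile/library-size ratio
    is closest to the mean of those ratios.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    uq = np.array([np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0
                   for col in mat.T]) / lib
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    log_f = np.array([
        0.0 if j == ref_idx else _tmm_pair(mat[:, j], mat[:, ref_idx],
                                           lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(mat.shape[1])
    ])
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million of the effective (TMM-adjusted) library size."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    return counts / lib * 1e6


def tmm_normalize(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
                  ) -> NormalizedMatrix:
    factors = tmm_factors(counts, trim_m=trim_m, trim_a=trim_a)
    return NormalizedMatrix(
        counts=counts, factors=factors, cpm=cpm(counts, factors),
        meta={"trim_m": trim_m, "trim_a": trim_a},
    )


def cpm_and_filter(norm: NormalizedMatrix, min_cpm: float = 1.0,
                   min_samples: int = 3) -> tuple[pd.DataFrame, list[str]]:
    """Keep genes with at least ``min_cpm`` in at least ``min_samples``
    samples (boundary inclusive); returns the filtered cpm and kept ids."""
    mask = (norm.cpm >= min_cpm).sum(axis=1) >= min_samples
    norm.filter_mask = mask
    kept = norm.cpm.loc[mask[mask].index]
    return kept, list(kept.index)


def qc_sample_similarity(filtered_cpm: pd.DataFrame, n_components: int = 5) -> dict:
    """Sample-level QC: PCA of centered log2(cpm + 1) and average-linkage
    clustering on 1 - Pearson correlation.  Deterministic."""
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    if filtered_cpm.shape[1] < 3:
        raise ValueError("QC needs >= 3 samples")
    x = np.log2(filtered_cpm.to_numpy(dtype=float).T + 1.0)  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    if not x.any():
        raise ValueError("constant matrix: no variation to analyse")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    # deterministic sign: largest-|loading| coordinate positive
    for j in range(k):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    var_explained = (s**2 / np.sum(s**2))[:k]

    corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = average(squareform(dist, checks=False))
    return {
        "samples": list(filtered_cpm.columns),
        "pca_coordinates": coords,
        "variance_explained": var_explained,
        "linkage": linkage,
        "distance": dist,
    }
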