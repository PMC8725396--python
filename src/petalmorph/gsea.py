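"""Keyword-built gene signatures and permutation-based set enrichment.

Four signatures describe the molecular machinery of pavement-cell lobe
formation and flower maturation: TCWI (turgor pressure-cell wall
interaction: kinesins, actin-related proteins, ROP/Rac GTPases, CRIB
proteins, cellulose synthase, CLIP-associated proteins, ABP1/PIN auxin
proteins), ICWP (intrinsic cell wall properties: pectin methylesterases,
pectinesterase inhibitors, galacturonosyltransferases), FDM (flower
differentiation-maturation: MADS-box, BEL1-like, JAGGED, ETTIN, DELLA RGA,
SPOROCYTELESS, TCP) and CE (cell elongation: DELLA proteins, aquaporins).
Membership is decided by case-insensitive substring match of the keywords
against annotation descriptions.

Enrichment follows the weighted running-sum statistic: walking down the
list of genes ranked by log2 fold-change, the sum rises by
|metric|^w / sum_hits |metric|^w at signature genes and falls by
1/(N - n_hits) elsewhere; the enrichment score ES is the extreme deviation.
The null redraws the signature's positions uniformly without replacement
(row permutation); the p-value compares |ES| among same-signed null scores.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from petalmorph.dge import bh_adjust

__all__ = [
    "DEFAULT_KEYWORDS",
    "Signature",
    "build_signature",
    "rank_genes",
    "enrichment_score",
    "permutation_pvalue",
    "gsea_report",
]

DEFAULT_KEYWORDS: dict[str, list[str]] = {
    "TCWI": [
        "kinesin-like", "actin-related", "Rac-like GTP-binding",
        "Rho of plants", "ROP", "CRIB domain-containing",
        "cellulose synthase", "CLIP-associated",
        "auxin-binding protein ABP1", "PIN",
    ],
    "ICWP": [
        "pectin methylesterase", "pectinesterase inhibitor",
        "galacturonosyltransferase",
    ],
    "FDM": [
        "MADS-box", "BEL1-like homeodomain", "JAGGED", "ETTIN",
        "DELLA protein RGA", "SPOROCYTELESS", "TCP",
    ],
    "CE": ["DELLA", "aquaporin"],
}


class DegenerateSignature(ValueError):
    """Signature covers the whole ranked list or none of it."""


@dataclass
class Signature:
    """A named gene set with the keywords that resolved it."""

    name: str
    keywords: list[str]
    genes: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.genes)


def build_signature(annotation: pd.DataFrame, name: str,
                    keywords: list[str] | None = None) -> Signature:
    """Resolve a signature by case-insensitive substring matching of its
    keywords against the annotation's description fields.

    ``annotation`` needs a ``gene_id`` column; every other column is
    searched as descriptive text.
    """
    if keywords is None:
        if name not in DEFAULT_KEYWORDS:
            raise ValueError(f"no default keyword set for {name!r}; pass keywords")
        keywords = DEFAULT_KEYWORDS[name]
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    if annotation.empty:
        raise ValueError("annotation table is empty")
    text_cols = [c for c in annotation.columns if c != "gene_id"]
    blob = annotation[text_cols].astype(str).agg(" ".join, axis=1)
    blob_lower = blob.str.lower()
    mask = np.zeros(len(annotation), dtype=bool)
    for kw in keywords:
        if len(kw) <= 4 and kw.isupper():
            # short gene-family symbols (ROP, PIN, TCP): case-sensitive with a
            # word-start boundary, tolerating trailing digits/capitals
            # (PIN3, TCP4) but not embedded lowercase matches (chloroplast)
            pat = re.compile(rf"\b{re.escape(kw)}(?![a-z])")
            mask |= blob.str.contains(pat, regex=True).to_numpy()
        else:
            mask |= blob_lower.str.contains(kw.lower(), regex=False).to_numpy()
    genes = sorted(annotation.loc[mask, "gene_id"].astype(str).unique())
    if not genes:
        warnings.warn(f"signature {name!r}: no annotation matched its keywords",
                      stacklevel=2)
    return Signature(name=name, keywords=list(keywords), genes=genes)


def rank_genes(dge_table: pd.DataFrame) -> pd.Series:
    """Genes ordered by descending log2 fold-change (ties broken by gene
    id), as a metric Series.  Genes without a statistic are excluded."""
    if dge_table.empty:
        raise ValueError("empty differential-expression table")
    tbl = dge_table
    if "stat" in tbl.columns:
        tbl = tbl[tbl["stat"].notna()]
    tbl = tbl[tbl["log2FoldChange"].notna()]
    if tbl.empty:
        raise ValueError("no genes with a finite ranking metric")
    s = pd.Series(tbl["log2FoldChange"].to_numpy(dtype=float),
                  index=tbl.index.astype(str))
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def _hit_mask(ranked: pd.Series, sig: Signature) -> np.ndarray:
    in_sig = np.isin(ranked.index.to_numpy(), np.asarray(sig.genes, dtype=object))
    n_hit = int(in_sig.sum())
    if n_hit == 0:
        raise DegenerateSignature(f"signature {sig.name!r} shares no gene with the list")
    if n_hit == len(ranked):
        raise DegenerateSignature(f"signature {sig.name!r} covers the whole list")
    return in_sig


def _es_from_positions(metric_abs_w: np.ndarray, positions: np.ndarray, n: int) -> float:
    """ES from the sorted 0-based hit positions.

    The running sum is piecewise linear between hits, so its extremes occur
    at hit steps: the maximum just after a hit, the minimum just before
    one.  ``metric_abs_w`` holds |metric|^w for the whole ranked list.
    """
    pos = np.sort(positions)
    n_hit = pos.size
    wsum = metric_abs_w[pos].sum()
    if wsum <= 0:
        # all-zero hit metrics: equal hit increments
        cum_hit = np.arange(1, n_hit + 1) / n_hit
    else:
        cum_hit = np.cumsum(metric_abs_w[pos]) / wsum
    miss_step = 1.0 / (n - n_hit)
    j = np.arange(n_hit)
    dev_top = cum_hit - (pos - j) * miss_step  # just after each hit
    dev_bot = np.concatenate(([0.0], cum_hit[:-1])) - (pos - j) * miss_step  # just before
    hi, lo = dev_top.max(), min(dev_bot.min(), 0.0)
    # tie on |deviation| resolves to the negative extreme
    return float(hi if hi > -lo else lo)


def enrichment_score(ranked: pd.Series, sig: Signature, weight_exponent: float = 1.0
                     ) -> float:
    """Signed extreme deviation of the weighted hit/miss running sum."""
    in_sig = _hit_mask(ranked, sig)
    metric = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    return _es_from_positions(metric, np.flatnonzero(in_sig), len(ranked))


def permutation_pvalue(ranked: pd.Series, sig: Signature, n_perm: int = 1000,
                       seed=None, weight_exponent: float = 1.0
                       ) -> tuple[float, np.ndarray]:
    """Row-permutation null: redraw the signature's positions uniformly
    without replacement.  p compares |ES| among null scores of the observed
    sign: p = (1 + #{|ES_perm| >= |ES_obs|, same sign}) / (1 + #{same sign}).
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    in_sig = _hit_mask(ranked, sig)
    n = len(ranked)
    n_hit = int(in_sig.sum())
    metric = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    es_obs = _es_from_positions(metric, np.flatnonzero(in_sig), n)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pos = rng.choice(n, size=n_hit, replace=False)
        null[i] = _es_from_positions(metric, pos, n)
    same_sign = null * np.sign(es_obs) >= 0 if es_obs != 0 else np.ones(n_perm, bool)
    extreme = same_sign & (np.abs(null) >= abs(es_obs))
    p = (1.0 + extreme.sum()) / (1.0 + same_sign.sum())
    return float(p), null


def gsea_report(ranked_lists: dict[str, pd.Series], signatures: list[Signature],
                n_perm: int = 1000, seed=None, weight_exponent: float = 1.0
                ) -> pd.DataFrame:
    """ES + permutation p per (contrast, signature), with BH adjustment
    across the signatures tested within each contrast.  Untestable
    signatures (no overlap / full overlap / empty) appear with NA scores
    and the reason in ``note``."""
    rows = []
    seed_seq = np.random.SeedSequence(seed)
    for ci, (contrast, ranked) in enumerate(ranked_lists.items()):
        child_seeds = seed_seq.spawn(len(signatures))
        pvals = []
        for sig, child in zip(signatures, child_seeds):
            row = {"contrast": contrast, "signature": sig.name,
                   "size": sig.size, "n_perm": n_perm}
            try:
                n_in_list = int(np.isin(ranked.index.to_numpy(),
                                        np.asarray(sig.genes, dtype=object)).sum())
                es = enrichment_score(ranked, sig, weight_exponent)
                p, _ = permutation_pvalue(ranked, sig, n_perm=n_perm,
                                          seed=child, weight_exponent=weight_exponent)
                row.update({"matched": n_in_list, "es": es, "pval": p, "note": ""})
            except DegenerateSignature as exc:
                row.update({"matched": 0, "es": np.nan, "pval": np.nan,
                            "note": str(exc)})
            pvals.append(row["pval"])
            rows.append(row)
        adj = bh_adjust(np.array(pvals, dtype=float))
        for j, a in enumerate(adj):
            rows[ci * len(signatures) + j]["padj"] = a
    if not rows:
        warnings.warn("no testable signatures", stacklevel=2)
    df = pd.DataFrame(rows, columns=["contrast", "signature", "size", "matched",
                                     "es", "pval", "padj", "n_perm", "note"])
    return df
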