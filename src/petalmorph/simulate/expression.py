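"""Two-species RNA-seq count simulator with planted signature shifts.

Emulates the structure the cross-species merge expects: each species has an
isoform-level count table (several isoforms per gene, Dirichlet-split
means), a BLAST-like hit table mapping isoforms to shared reference gene
models with e-values spanning the filtering threshold, and an annotation
table whose descriptions carry the keyword vocabulary the signature builder
matches against.  Counts are negative binomial via the gamma-Poisson
mixture; a Poisson limit is used when the dispersion is effectively zero.

Planted effects multiply the mean of selected genes by 2^delta in a chosen
(species, stage) group; every planted shift is recorded in the returned
truth object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlantedSignature",
    "ExpressionSimSpec",
    "CountSimData",
    "default_design",
    "gen_counts",
]

# Description templates: first four groups carry the signature keyword
# vocabulary, the rest are neutral background annotations.
_TCWI_TEMPLATES = [
    "Kinesin-like protein KIN-{i}",
    "Actin-related protein {i}",
    "Rac-like GTP-binding protein ARAC{i}",
    "Rho of plants guanine nucleotide exchange factor {i}",
    "CRIB domain-containing protein RIC{i}",
    "Cellulose synthase A catalytic subunit {i}",
    "CLIP-associated protein {i}",
    "Auxin-binding protein ABP1",
    "Auxin efflux carrier component PIN{i}",
]
_ICWP_TEMPLATES = [
    "Pectin methylesterase {i}",
    "Pectinesterase inhibitor {i}",
    "Probable galacturonosyltransferase {i}",
]
_FDM_TEMPLATES = [
    "MADS-box transcription factor {i}",
    "BEL1-like homeodomain protein {i}",
    "Zinc finger protein JAGGED",
    "Auxin response factor ETTIN",
    "DELLA protein RGA",
    "Protein SPOROCYTELESS",
    "TCP transcription factor TCP{i}",
]
_CE_TEMPLATES = [
    "DELLA protein GAI",
    "Aquaporin PIP2-{i}",
    "Aquaporin TIP1-{i}",
]
_NEUTRAL_TEMPLATES = [
    "Cytochrome P450 71A{i}",
    "Heat shock protein {i}",
    "Ribosomal protein L{i}",
    "Serine/threonine-protein kinase {i}",
    "Glutathione S-transferase U{i}",
    "Hypothetical protein",
    "Chlorophyll a-b binding protein {i}",
    "Ubiquitin-conjugating enzyme E2 {i}",
]

SIGNATURE_TEMPLATES = {
    "TCWI": _TCWI_TEMPLATES,
    "ICWP": _ICWP_TEMPLATES,
    "FDM": _FDM_TEMPLATES,
    "CE": _CE_TEMPLATES,
}


@dataclass
class PlantedSignature:
    """A named gene set shifted by ``log2fc`` in one (species, stage) group.

    ``opposite_fraction`` of the genes are shifted by ``-log2fc`` instead:
    functional modules observed in real petal data contain members highly
    expressed at either stage, so a signature is a mixed-direction set with
    a dominant sign, not a uniform block shift.
    """

    name: str
    n_genes: int
    log2fc: float
    species: str
    stage: str
    opposite_fraction: float = 0.0
    gene_ids: list[str] = field(default_factory=list)  # filled by the generator
    gene_log2fc: dict = field(default_factory=dict)  # filled by the generator

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc):
            raise ValueError("planted log2 fold-change must be finite")
        if self.n_genes < 1:
            raise ValueError("planted signature needs >= 1 gene")
        if not (0.0 <= self.opposite_fraction < 0.5):
            raise ValueError("opposite_fraction must lie in [0, 0.5)")


@dataclass
class ExpressionSimSpec:
    """Design of one simulated two-species expression experiment."""

    n_genes: int = 2000
    design: pd.DataFrame | None = None  # columns: sample, species, stage, replicate
    baseline_meanlog: float = np.log(200.0)
    baseline_sdlog: float = 1.2
    dispersion: float = 0.05
    planted: list[PlantedSignature] = field(default_factory=list)
    mean_extra_isoforms: float = 1.5  # isoforms per gene ~ 1 + Poisson(this)
    fraction_private: float = 0.2  # per species: genes absent from the other species
    depth_sdlog: float = 0.25  # library-size variation across samples
    species_effect_sd: float = 2.0  # per-gene log2 divergence between the species
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.design is None:
            self.design = default_design()
        if len(self.design) == 0:
            raise ValueError("empty sample design")
        required = {"sample", "species", "stage"}
        if not required.issubset(self.design.columns):
            raise ValueError(f"design needs columns {sorted(required)}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0 <= self.fraction_private < 0.5):
            raise ValueError("fraction_private must lie in [0, 0.5)")
        n_planted = sum(p.n_genes for p in self.planted)
        if n_planted > self.n_genes:
            raise ValueError("more planted genes than simulated genes")


def default_design() -> pd.DataFrame:
    """The study's sampling design: 3 bud + 4 mature petals for the basal
    species A and 3 + 3 for the derived species B (13 libraries)."""
    rows = []
    for sp, stage, n in [("A", "bud", 3), ("A", "mature", 4), ("B", "bud", 3), ("B", "mature", 3)]:
        for r in range(1, n + 1):
            rows.append({"sample": f"{sp}_{stage}_{r}", "species": sp, "stage": stage, "replicate": r})
    return pd.DataFrame(rows)


def demo_expression_spec(seed: int | None = 0, n_genes: int = 2000) -> ExpressionSimSpec:
    """The bundled demo scenario: deep cross-species divergence plus
    mixed-direction lobeyness-module shifts between the derived species'
    bud and mature stages (TCWI predominantly mature-high, ICWP
    predominantly bud-high; FDM and CE present but unshifted)."""
    return ExpressionSimSpec(
        n_genes=n_genes, seed=seed, species_effect_sd=2.0,
        planted=[
            PlantedSignature("TCWI", 40, -0.75, "B", "bud", opposite_fraction=0.35),
            PlantedSignature("ICWP", 30, 0.75, "B", "bud", opposite_fraction=0.35),
            PlantedSignature("FDM", 25, 0.0, "B", "bud"),
            PlantedSignature("CE", 15, 0.0, "B", "bud"),
        ],
    )


@dataclass
class CountSimData:
    """Everything the merge stage consumes, plus the planted truth."""

    isoform_counts: dict[str, pd.DataFrame]  # species -> isoform x sample table
    hits: pd.DataFrame  # qseqid, sseqid, evalue, bitscore
    annotation: pd.DataFrame  # gene_id, description
    sample_sheet: pd.DataFrame
    truth: dict


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson negative binomial; Poisson in the alpha -> 0 limit."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-8:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def _gene_ids(n: int) -> list[str]:
    return [f"REF_g{i:05d}" for i in range(1, n + 1)]


def gen_counts(spec: ExpressionSimSpec) -> CountSimData:
    """Simulate the full two-species dataset. Deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    design = spec.design.reset_index(drop=True)
    species_list = sorted(design["species"].unique())
    if len(species_list) != 2:
        raise ValueError("design must contain exactly two species")

    genes = _gene_ids(spec.n_genes)

    # Private/shared membership: each gene is private to one species with
    # probability fraction_private per species, otherwise shared.
    u = rng.random(spec.n_genes)
    private_to = np.full(spec.n_genes, "", dtype=object)
    private_to[u < spec.fraction_private] = species_list[0]
    private_to[(u >= spec.fraction_private) & (u < 2 * spec.fraction_private)] = species_list[1]

    baseline = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, spec.n_genes)

    # Assign planted signature genes among shared genes (so every planted
    # effect survives the inner join), disjointly across signatures.
    shared_idx = np.flatnonzero(private_to == "")
    perm = rng.permutation(shared_idx)
    cursor = 0
    shift = np.zeros((spec.n_genes, len(design)))  # additive log2 shifts per sample
    planted_truth = {}
    for sig in spec.planted:
        take = perm[cursor:cursor + sig.n_genes]
        if len(take) < sig.n_genes:
            raise ValueError(f"not enough shared genes to plant signature {sig.name}")
        cursor += sig.n_genes
        sig.gene_ids = [genes[i] for i in take]
        n_opp = int(np.floor(sig.opposite_fraction * sig.n_genes))
        signs = np.ones(sig.n_genes)
        signs[:n_opp] = -1.0
        rng.shuffle(signs)
        mask = ((design["species"] == sig.species) & (design["stage"] == sig.stage)).to_numpy()
        shift[np.ix_(take, np.flatnonzero(mask))] += sig.log2fc * signs[:, None]
        sig.gene_log2fc = {genes[i]: float(sig.log2fc * s) for i, s in zip(take, signs)}
        planted_truth[sig.name] = {
            "genes": sig.gene_ids,
            "log2fc": sig.log2fc,
            "species": sig.species,
            "stage": sig.stage,
            "gene_log2fc": sig.gene_log2fc,
        }

    # Species divergence: stage-independent per-gene expression differences
    # between the two lineages.  They cancel in within-species contrasts but
    # dominate the cross-species ones, as deep divergence does in real data.
    if spec.species_effect_sd > 0:
        div = rng.normal(0.0, spec.species_effect_sd, spec.n_genes)
        b_cols = np.flatnonzero((design["species"] == species_list[1]).to_numpy())
        shift[np.ix_(np.arange(spec.n_genes), b_cols)] += div[:, None]
    else:
        div = np.zeros(spec.n_genes)

    depth = np.exp(np.clip(rng.normal(0.0, spec.depth_sdlog, len(design)),
                           -3 * spec.depth_sdlog, 3 * spec.depth_sdlog))

    # Per-species isoform structure and counts.
    isoform_counts: dict[str, pd.DataFrame] = {}
    hit_rows = []
    for sp in species_list:
        sp_samples = design.index[design["species"] == sp].to_numpy()
        present = private_to != species_list[1 - species_list.index(sp)]
        iso_ids, iso_gene_idx, iso_prop = [], [], []
        n_iso = 1 + rng.poisson(spec.mean_extra_isoforms, spec.n_genes)
        for gi in np.flatnonzero(present):
            props = rng.dirichlet(np.ones(n_iso[gi]))
            for j, pr in enumerate(props):
                iso_ids.append(f"{sp}_TR{gi + 1:05d}_i{j + 1}")
                iso_gene_idx.append(gi)
                iso_prop.append(pr)
        iso_gene_idx = np.asarray(iso_gene_idx)
        iso_prop = np.asarray(iso_prop)

        mat = np.zeros((len(iso_ids), len(sp_samples)), dtype=int)
        for cj, di in enumerate(sp_samples):
            mu = baseline[iso_gene_idx] * (2.0 ** shift[iso_gene_idx, di]) * iso_prop * depth[di]
            mat[:, cj] = _nb_draw(rng, mu, spec.dispersion)
        isoform_counts[sp] = pd.DataFrame(
            mat, index=pd.Index(iso_ids, name="isoform_id"),
            columns=design.loc[sp_samples, "sample"].to_list(),
        )

        # Hit table: real hits well below threshold, decoy secondary hits,
        # and ~2% of isoforms whose only hit sits above the threshold.
        for ii, iso in enumerate(iso_ids):
            gi = iso_gene_idx[ii]
            r = rng.random()
            if r < 0.02:
                ev = 10.0 ** (-rng.uniform(0.0, 2.5))  # above 1e-3: discarded
                hit_rows.append((iso, genes[gi], ev, 40 + rng.normal(0, 3)))
                continue
            ev = 10.0 ** (-rng.uniform(4.0, 60.0))
            bs = 60.0 - 1.5 * np.log10(ev) + rng.normal(0, 2)
            hit_rows.append((iso, genes[gi], ev, bs))
            if rng.random() < 0.15:  # weaker secondary hit to another gene
                other = genes[int(rng.integers(spec.n_genes))]
                ev2 = min(ev * 10 ** rng.uniform(2, 8), 0.5)
                hit_rows.append((iso, other, ev2, bs - rng.uniform(5, 30)))

    hits = pd.DataFrame(hit_rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])

    # Annotation: planted signature genes receive keyword-bearing
    # descriptions; the rest are neutral.
    desc = np.empty(spec.n_genes, dtype=object)
    neutral = rng.integers(0, len(_NEUTRAL_TEMPLATES), spec.n_genes)
    for gi in range(spec.n_genes):
        desc[gi] = _NEUTRAL_TEMPLATES[neutral[gi]].format(i=gi % 90 + 1)
    for sig in spec.planted:
        templates = SIGNATURE_TEMPLATES.get(sig.name.split("_")[0])
        if templates is None:
            continue
        for j, gid in enumerate(sig.gene_ids):
            gi = genes.index(gid)
            desc[gi] = templates[j % len(templates)].format(i=j + 1)
    annotation = pd.DataFrame({"gene_id": genes, "description": desc})

    # True log2 fold-changes for the four standard contrasts (numerator
    # group mean shift minus denominator group mean shift).
    sp_a, sp_b = species_list
    group_cols = {
        (sp, st): np.flatnonzero(((design["species"] == sp) & (design["stage"] == st)).to_numpy())
        for sp in species_list for st in design["stage"].unique()
    }
    def _contrast_lfc(num, den):
        return (shift[:, group_cols[num]].mean(axis=1)
                - shift[:, group_cols[den]].mean(axis=1))
    true_lfc = {
        f"{sp_a}_bud_vs_{sp_a}_mature": _contrast_lfc((sp_a, "bud"), (sp_a, "mature")),
        f"{sp_b}_bud_vs_{sp_b}_mature": _contrast_lfc((sp_b, "bud"), (sp_b, "mature")),
        f"{sp_a}_bud_vs_{sp_b}_bud": _contrast_lfc((sp_a, "bud"), (sp_b, "bud")),
        f"{sp_a}_mature_vs_{sp_b}_mature": _contrast_lfc((sp_a, "mature"), (sp_b, "mature")),
    }
    truth = {
        "seed": spec.seed,
        "dispersion": spec.dispersion,
        "baseline_mean": dict(zip(genes, baseline.tolist())),
        "private_to": {g: p for g, p in zip(genes, private_to) if p},
        "planted": planted_truth,
        "species_divergence_log2": dict(zip(genes, div.tolist())),
        "true_log2fc": {c: dict(zip(genes, v.tolist())) for c, v in true_lfc.items()},
    }
    sample_sheet = design.set_index("sample", drop=False)
    return CountSimData(
        isoform_counts=isoform_counts, hits=hits, annotation=annotation,
        sample_sheet=sample_sheet, truth=truth,
    )
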