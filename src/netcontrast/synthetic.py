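"""Synthetic benchmark generator with planted ground truth.

Emulates the statistical structure of a paired NDD / cancer study so
the whole pipeline can be exercised with known answers:

* a scale-free weighted interactome (preferential attachment) with a
  densely wired *planted module* attached to the backbone;
* two mutation cohorts over the shared gene universe — cancer-like
  "driver" mutations concentrated in the module with high per-mutation
  carrier counts, NDD-like mutations spread more thinly with low carrier
  counts, and a small planted set of shared mutations copied into the
  cancer catalog at NDD-like (low) recurrence;
* a TF->target regulatory map in which one planted TF draws most of its
  regulon from one planted pathway, against random background TFs;
* pathway gene sets (GMT) over the universe; and
* per-disease expression z-scores with the planted pathway shifted by a
  strong (cancer-like, Δ=2.0) or weak (NDD-like, Δ=0.5) amount, signs
  random per gene so only the magnitude separates the diseases.

Per-mutation carrier counts follow a zero-truncated negative binomial
(over-dispersed, as in real recurrence data).  Every output is a pure
function of (parameters, rng_seed); stage-specific child seeds make the
individual generators independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .mutations import MutationCatalog, MutationRecord
from .regulation import GeneSetCollection, RegulatoryMap

__all__ = [
    "GeneratorParams",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_interactome",
    "generate_cohorts",
    "generate_regulation_and_pathways",
    "generate_expression",
    "generate_all",
    "write_dataset",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions of the synthetic benchmark.

    Carrier-count means (driver 20 vs NDD 2 patients per mutation) set
    the planted recurrence asymmetry; ``shared_fraction`` of the NDD
    mutations is copied into the cancer catalog at NDD-like recurrence;
    ``strong_shift`` / ``weak_shift`` are the |z| displacements of the
    planted pathway in the cancer-like and NDD-like disease.
    """

    n_genes: int = 2000
    attachment_m: int = 3
    module_size: int = 40
    module_density: float = 0.3
    n_samples_a: int = 500  # NDD-like cohort
    n_samples_b: int = 500  # cancer-like cohort
    n_ndd_genes: int = 250
    n_ndd_mutations: int = 600
    module_overlap_frac: float = 0.5  # module genes also mutated in NDD
    n_driver_genes: int = 30
    driver_module_frac: float = 0.8
    driver_muts_per_gene: tuple[int, int] = (2, 5)
    driver_mean_carriers: float = 20.0
    ndd_mean_carriers: float = 2.0
    nb_dispersion: float = 2.0
    shared_fraction: float = 0.02
    strong_shift: float = 2.0
    weak_shift: float = 0.5
    noise_sd: float = 1.0
    missing_rate: float = 0.1
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (20, 80)
    n_background_tfs: int = 80
    tf_module_frac: float = 0.15  # TFs drawn from the planted module
    tf_regulon_range: tuple[int, int] = (10, 40)
    planted_tf_targets: int = 40
    planted_target_frac: float = 0.7
    ndd_disease: str = "NDD"
    cancer_disease: str = "CANCER"
    rng_seed: int = 0

    def genes(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class SyntheticTruth:
    """Ground-truth manifest: everything needed to score recovery."""

    rng_seed: int
    planted_module: list[str] = field(default_factory=list)
    driver_genes: list[str] = field(default_factory=list)
    ndd_genes: list[str] = field(default_factory=list)
    shared_mutations: list[list[str]] = field(default_factory=list)
    planted_pathway: dict[str, dict] = field(default_factory=dict)
    planted_pathway_genes: list[str] = field(default_factory=list)
    planted_tf: Optional[str] = None
    planted_tf_targets: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage_rng(params: GeneratorParams, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.rng_seed, stage]))


def generate_interactome(
    params: GeneratorParams,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Scale-free weighted interactome with a planted dense module."""
    if params.n_genes < params.module_size:
        raise ValueError("n_genes must be >= module_size")
    rng = _stage_rng(params, 0)
    genes = params.genes()
    backbone = nx.barabasi_albert_graph(
        params.n_genes, params.attachment_m, seed=int(rng.integers(2**31))
    )
    g = nx.relabel_nodes(backbone, dict(enumerate(genes)))
    module = sorted(rng.choice(genes, size=params.module_size, replace=False))
    for i, u in enumerate(module):
        for v in module[i + 1:]:
            if not g.has_edge(u, v) and rng.random() < params.module_density:
                g.add_edge(u, v)
    weights = rng.beta(5, 2, size=g.number_of_edges())
    for (u, v), w in zip(sorted(map(tuple, map(sorted, g.edges()))), weights):
        g[u][v]["weight"] = float(max(w, 1e-6))
    truth = SyntheticTruth(rng_seed=params.rng_seed, planted_module=list(module))
    return g, truth


def _ztnb(rng: np.random.Generator, mean: float, r: float, size: int) -> np.ndarray:
    """Zero-truncated negative binomial by rejection (underlying mean given)."""
    p = r / (r + mean)
    out = rng.negative_binomial(r, p, size=size)
    while (out == 0).any():
        zero = out == 0
        out[zero] = rng.negative_binomial(r, p, size=int(zero.sum()))
    return out


def _new_change(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        ref = _AA[rng.integers(len(_AA))]
        pos = int(rng.integers(1, 1001))
        alt = "*" if rng.random() < 0.05 else _AA[rng.integers(len(_AA))]
        if alt == ref:
            continue
        change = f"{ref}{pos}{alt}"
        if change not in used:
            used.add(change)
            return change


def generate_cohorts(
    params: GeneratorParams, truth: SyntheticTruth
) -> tuple[MutationCatalog, MutationCatalog, pd.DataFrame]:
    """NDD-like and cancer-like catalogs plus the driver-mutation list.

    Driver mutations sit mostly in planted-module genes with high
    carrier counts; NDD mutations partially overlap the module with low
    counts; an exact ``round(shared_fraction * n_NDD_unique)`` subset of
    NDD mutations is copied into the cancer catalog.
    """
    rng = _stage_rng(params, 1)
    genes = params.genes()
    module = list(truth.planted_module)
    samples_a = [f"A{i:04d}" for i in range(params.n_samples_a)]
    samples_b = [f"B{i:04d}" for i in range(params.n_samples_b)]
    phenos_a = rng.choice(["ASD", "DD", "ID", "SCZ"], size=params.n_samples_a)
    pheno_of = dict(zip(samples_a, phenos_a))
    cancer_type = dict(
        zip(samples_b, rng.choice(["BRCA", "KIRC", "GBM"], size=params.n_samples_b))
    )

    # NDD gene panel: part of the module plus random background genes
    n_mod = int(round(params.module_overlap_frac * len(module)))
    mod_part = list(rng.choice(module, size=min(n_mod, len(module)), replace=False))
    background = [g for g in genes if g not in module]
    n_bg = max(params.n_ndd_genes - len(mod_part), 0)
    bg_part = list(rng.choice(background, size=n_bg, replace=False))
    ndd_genes = sorted(mod_part + bg_part)

    used_per_gene: dict[str, set[str]] = {}
    ndd_mutations: list[tuple[str, str]] = []
    gene_draw = rng.choice(ndd_genes, size=params.n_ndd_mutations)
    for gene in gene_draw:
        change = _new_change(rng, used_per_gene.setdefault(gene, set()))
        ndd_mutations.append((gene, change))

    # driver genes: mostly from the module
    n_from_mod = int(round(params.driver_module_frac * params.n_driver_genes))
    drv_mod = list(rng.choice(module, size=min(n_from_mod, len(module)), replace=False))
    drv_bg = list(
        rng.choice(background, size=params.n_driver_genes - len(drv_mod), replace=False)
    )
    driver_genes = sorted(drv_mod + drv_bg)
    driver_mutations: list[tuple[str, str]] = []
    lo, hi = params.driver_muts_per_gene
    for gene in driver_genes:
        for _ in range(int(rng.integers(lo, hi + 1))):
            change = _new_change(rng, used_per_gene.setdefault(gene, set()))
            driver_mutations.append((gene, change))

    n_shared = int(round(params.shared_fraction * len(ndd_mutations)))
    shared_idx = rng.choice(len(ndd_mutations), size=n_shared, replace=False)
    shared = [ndd_mutations[i] for i in sorted(shared_idx)]

    def carriers(samples: list[str], count: int) -> list[str]:
        count = min(count, len(samples))
        return list(rng.choice(samples, size=count, replace=False))

    records_a: list[MutationRecord] = []
    patho_a = {}
    counts_a = _ztnb(
        rng, params.ndd_mean_carriers, params.nb_dispersion, len(ndd_mutations)
    )
    for (gene, change), n in zip(ndd_mutations, counts_a):
        patho = float(np.clip(rng.beta(2, 3), 0, 1))
        patho_a[(gene, change)] = patho
        for s in carriers(samples_a, int(n)):
            records_a.append(
                MutationRecord(s, gene, change, pheno_of[s], patho)
            )

    records_b: list[MutationRecord] = []
    counts_drv = _ztnb(
        rng, params.driver_mean_carriers, params.nb_dispersion, len(driver_mutations)
    )
    for (gene, change), n in zip(driver_mutations, counts_drv):
        patho = float(np.clip(rng.beta(8, 2), 0, 1))
        for s in carriers(samples_b, int(n)):
            records_b.append(
                MutationRecord(s, gene, change, cancer_type[s], patho)
            )
    counts_shared = _ztnb(
        rng, params.ndd_mean_carriers, params.nb_dispersion, max(len(shared), 1)
    )
    for (gene, change), n in zip(shared, counts_shared):
        for s in carriers(samples_b, int(n)):
            records_b.append(
                MutationRecord(s, gene, change, cancer_type[s], patho_a[(gene, change)])
            )

    key = lambda r: (r.gene, r.protein_change, r.sample_id)
    catalog_a = MutationCatalog("ndd", sorted(records_a, key=key))
    catalog_b = MutationCatalog("cancer", sorted(records_b, key=key))
    driver_list = pd.DataFrame(
        sorted(driver_mutations), columns=["gene", "protein_change"]
    )
    truth.driver_genes = driver_genes
    truth.ndd_genes = ndd_genes
    truth.shared_mutations = [list(m) for m in shared]
    return catalog_a, catalog_b, driver_list


def generate_regulation_and_pathways(
    params: GeneratorParams, truth: SyntheticTruth
) -> tuple[RegulatoryMap, GeneSetCollection]:
    """Pathway sets plus a regulatory map with one planted TF.

    The planted TF is a planted-module gene (so it reliably appears in
    seed-anchored disease networks, as curated TFs do in real disease
    modules) and draws at least ``planted_target_frac`` of its regulon
    from the planted pathway (the first pathway, sized to fit).
    ``tf_module_frac`` of the background TFs are module genes too; the
    rest are uniform, all targeting uniform random genes.
    """
    rng = _stage_rng(params, 2)
    genes = params.genes()
    lo, hi = params.pathway_size_range
    sets: dict[str, frozenset[str]] = {}
    n_planted = int(np.ceil(params.planted_target_frac * params.planted_tf_targets))
    for i in range(params.n_pathways):
        pid = f"PW{i + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        if i == 0:
            size = max(size, n_planted + 10)
        members = rng.choice(genes, size=size, replace=False)
        sets[pid] = frozenset(members)
    planted_pid = "PW001"
    planted_genes = sorted(sets[planted_pid])

    pairs: set[tuple[str, str]] = set()
    module = list(truth.planted_module) or genes
    tf = str(rng.choice(module))
    in_path = rng.choice(planted_genes, size=n_planted, replace=False)
    outside_pool = [g for g in genes if g not in sets[planted_pid] and g != tf]
    n_out = params.planted_tf_targets - n_planted
    out_path = rng.choice(outside_pool, size=n_out, replace=False)
    planted_targets = sorted(set(map(str, in_path)) | set(map(str, out_path)))
    pairs.update((tf, t) for t in planted_targets)

    n_mod_tfs = int(round(params.tf_module_frac * params.n_background_tfs))
    mod_pool = [g for g in module if g != tf]
    n_mod_tfs = min(n_mod_tfs, len(mod_pool))
    mod_tfs = list(rng.choice(mod_pool, size=n_mod_tfs, replace=False))
    uni_pool = [g for g in genes if g != tf and g not in set(mod_tfs)]
    uni_tfs = list(
        rng.choice(uni_pool, size=params.n_background_tfs - n_mod_tfs, replace=False)
    )
    background_tfs = mod_tfs + uni_tfs
    rlo, rhi = params.tf_regulon_range
    for btf in background_tfs:
        n_t = int(rng.integers(rlo, rhi + 1))
        targets = rng.choice(genes, size=n_t, replace=False)
        pairs.update((str(btf), str(t)) for t in targets if str(t) != str(btf))

    truth.planted_tf = tf
    truth.planted_tf_targets = planted_targets
    truth.planted_pathway_genes = planted_genes
    truth.planted_pathway = {
        params.cancer_disease: {"pathway_id": planted_pid, "shift": params.strong_shift},
        params.ndd_disease: {"pathway_id": planted_pid, "shift": params.weak_shift},
    }
    return RegulatoryMap.from_pairs(pairs), GeneSetCollection(sets=dict(sets))


def generate_expression(
    params: GeneratorParams, truth: SyntheticTruth
) -> pd.DataFrame:
    """Gene x disease z-scores with the planted pathway shifted.

    Baseline z ~ N(0, noise_sd); planted-pathway genes get an extra
    ±shift with random sign per gene, so only |z| carries the planted
    signal; ``missing_rate`` of genes per disease are NaN.
    """
    rng = _stage_rng(params, 3)
    genes = params.genes()
    diseases = [params.ndd_disease, params.cancer_disease]
    members = [g for g in truth.planted_pathway_genes if g in set(genes)]
    table = pd.DataFrame(index=genes, columns=diseases, dtype=float)
    for disease in diseases:
        table[disease] = rng.normal(0.0, params.noise_sd, size=len(genes))
        planted = truth.planted_pathway.get(disease)
        if planted is not None and members:
            shift = float(planted["shift"])
            signs = rng.choice([-1.0, 1.0], size=len(members))
            table.loc[members, disease] = (
                table.loc[members, disease].to_numpy() + signs * shift
            )
        miss = rng.random(len(genes)) < params.missing_rate
        table.loc[miss, disease] = np.nan
    return table


@dataclass
class SyntheticDataset:
    interactome: nx.Graph
    catalog_a: MutationCatalog
    catalog_b: MutationCatalog
    driver_list: pd.DataFrame
    regulatory_map: RegulatoryMap
    pathways: GeneSetCollection
    expression: pd.DataFrame
    truth: SyntheticTruth


def generate_all(params: GeneratorParams) -> SyntheticDataset:
    """Run every generator stage with consistent ground truth."""
    g, truth = generate_interactome(params)
    catalog_a, catalog_b, drivers = generate_cohorts(params, truth)
    reg, pathways = generate_regulation_and_pathways(params, truth)
    expr = generate_expression(params, truth)
    return SyntheticDataset(g, catalog_a, catalog_b, drivers, reg, pathways, expr, truth)


def _catalog_frame(catalog: MutationCatalog) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": r.sample_id,
                "gene": r.gene,
                "protein_change": r.protein_change,
                "phenotype": r.phenotype if r.phenotype is not None else "",
                "pathogenicity": r.pathogenicity,
            }
            for r in catalog.records
        ]
    )


def write_dataset(outdir, params: GeneratorParams) -> SyntheticTruth:
    """Generate and write every pipeline input file plus the manifest.

    Emits catalog_a.tsv, catalog_b.tsv, drivers.tsv, interactome.tsv,
    regulation.tsv, pathways.gmt, expression.tsv and truth.json in the
    dialects the corresponding parsers consume.
    """
    from pathlib import Path

    from .scoring import write_expression_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_all(params)
    _catalog_frame(data.catalog_a).to_csv(
        outdir / "catalog_a.tsv", sep="\t", index=False
    )
    _catalog_frame(data.catalog_b).to_csv(
        outdir / "catalog_b.tsv", sep="\t", index=False
    )
    data.driver_list.to_csv(outdir / "drivers.tsv", sep="\t", index=False)
    edges = sorted(
        (min(u, v), max(u, v), d["weight"])
        for u, v, d in data.interactome.edges(data=True)
    )
    pd.DataFrame(edges, columns=["a", "b", "weight"]).to_csv(
        outdir / "interactome.tsv", sep="\t", index=False
    )
    data.regulatory_map.to_tsv(outdir / "regulation.tsv")
    data.pathways.to_gmt(outdir / "pathways.gmt")
    write_expression_table(data.expression, outdir / "expression.tsv")
    data.truth.to_json(outdir / "truth.json")
    return data.truth
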