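"""Config-driven orchestration of the full comparative workflow.

Stage order: mutation comparison -> seed selection (both cohorts) ->
disease-network inference (both cohorts) -> common TFs / common targets
-> overrepresentation of the common targets -> pathway ES/PS panel ->
TF-profile clustering and differential-TF selection.  Every stage
writes its output under the run directory with a fixed name, and a
manifest records input hashes, parameters and the rng seed so a run can
be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError
from .inference import InferenceParams, infer_network, read_interactome
from .mutations import compare_catalogs, parse_catalog, select_seed_genes
from .regulation import GeneSetCollection, RegulatoryMap, common_regulation, ora_enrich
from .scoring import (
    cluster_tf_profiles,
    read_expression_table,
    score_pathway_panel,
    select_differential_tfs,
)

logger = logging.getLogger("netcontrast")

__all__ = ["RunConfig", "run_pipeline"]

_THRESHOLD_DEFAULTS = {
    "min_patients": 3,
    "p_cut": 0.05,
    "fdr_cut": 0.05,
    "delta": 1.0,
    "k_clusters": 3,
}


@dataclass
class RunConfig:
    """Validated inputs, parameters and thresholds of one run."""

    catalog_a: str
    catalog_b: str
    interactome: str
    regulation: str
    pathways: str
    expression: str
    outdir: str
    drivers: Optional[str] = None  # seed list for cohort B (driver genes)
    disease_a: str = "NDD"
    disease_b: str = "CANCER"
    reference_disease: Optional[str] = None
    inference: InferenceParams = field(default_factory=InferenceParams)
    thresholds: dict = field(default_factory=lambda: dict(_THRESHOLD_DEFAULTS))
    rng_seed: int = 0

    def __post_init__(self):
        unknown = set(self.thresholds) - set(_THRESHOLD_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        merged = dict(_THRESHOLD_DEFAULTS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "inference" in raw and isinstance(raw["inference"], dict):
            raw["inference"] = InferenceParams(**raw["inference"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _child_seed(base: int, index: int) -> int:
    # counter-based fan-out so each stage is individually reproducible
    return (base * 1009 + index) % (2**31)


def _write_genes(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write artifacts, and return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    manifest: dict = {
        "version": __version__,
        "rng_seed": config.rng_seed,
        "config": config.to_dict(),
        "inputs": {},
        "stages": {},
    }
    t = config.thresholds

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - stage boundary
                failed_marker.write_text(f"{name}: {exc}\n")
                raise PipelineError(name, str(exc)) from exc
            dt = time.perf_counter() - t0
            manifest["stages"][name] = {
                "outputs": out,
                "seconds": round(dt, 3),
            }
            logger.info("stage %-18s done in %6.2fs -> %s", name, dt, out)
            return out

        return deco

    inputs = {
        "catalog_a": config.catalog_a,
        "catalog_b": config.catalog_b,
        "interactome": config.interactome,
        "regulation": config.regulation,
        "pathways": config.pathways,
        "expression": config.expression,
    }
    if config.drivers:
        inputs["drivers"] = config.drivers
    for name, path in inputs.items():
        if not Path(path).exists():
            raise PipelineError("load", f"input '{name}' not found: {path}")
        manifest["inputs"][name] = _sha256(path)

    state: dict = {}

    @stage("compare_mutations")
    def _compare():
        state["catalog_a"] = parse_catalog(config.catalog_a, config.disease_a)
        state["catalog_b"] = parse_catalog(config.catalog_b, config.disease_b)
        cmp_ = compare_catalogs(
            state["catalog_a"], state["catalog_b"],
            frequency_source=state["catalog_b"],
        )
        state["comparison"] = cmp_
        rows = [
            {
                "quantity": "shared_mutations", "value": len(cmp_.shared_mutations)
            },
            {"quantity": "a_specific_mutations", "value": len(cmp_.a_specific_mutations)},
            {"quantity": "b_specific_mutations", "value": len(cmp_.b_specific_mutations)},
            {"quantity": "shared_genes", "value": len(cmp_.shared_genes)},
            {"quantity": "frequency_t", "value": cmp_.frequency_test.statistic},
            {"quantity": "frequency_p", "value": cmp_.frequency_test.p_value},
        ]
        if cmp_.pathogenicity_test is not None:
            rows += [
                {"quantity": "pathogenicity_t", "value": cmp_.pathogenicity_test.statistic},
                {"quantity": "pathogenicity_p", "value": cmp_.pathogenicity_test.p_value},
            ]
        pd.DataFrame(rows).to_csv(outdir / "comparison.tsv", sep="\t", index=False)
        return ["comparison.tsv"]

    @stage("seeds")
    def _seeds():
        seeds_a = select_seed_genes(state["catalog_a"], t["min_patients"])
        if config.drivers:
            drv = pd.read_csv(config.drivers, sep="\t")
            seeds_b = sorted({str(g).upper() for g in drv["gene"]})
        else:
            seeds_b = select_seed_genes(state["catalog_b"], t["min_patients"])
        state["seeds_a"], state["seeds_b"] = seeds_a, seeds_b
        _write_genes(seeds_a, outdir / "seeds_a.txt")
        _write_genes(seeds_b, outdir / "seeds_b.txt")
        return ["seeds_a.txt", "seeds_b.txt"]

    @stage("networks")
    def _networks():
        state["interactome"] = read_interactome(config.interactome)
        outs = []
        for label, seeds, idx in (
            ("a", state["seeds_a"], 0), ("b", state["seeds_b"], 1)
        ):
            params = dataclasses.replace(
                config.inference, rng_seed=_child_seed(config.rng_seed, idx)
            )
            net = infer_network(state["interactome"], seeds, params)
            state[f"network_{label}"] = net
            if net.missing_seeds:
                warnings.warn(
                    f"network {label}: {len(net.missing_seeds)} seeds absent "
                    "from the selected edges", stacklevel=2,
                )
            nodes_f = f"network_{label}_nodes.tsv"
            edges_f = f"network_{label}_edges.tsv"
            net.node_table().to_csv(outdir / nodes_f, sep="\t", index=False)
            net.edge_table().to_csv(outdir / edges_f, sep="\t", index=False)
            nx.write_graphml(net.graph, outdir / f"network_{label}.graphml")
            outs += [nodes_f, edges_f, f"network_{label}.graphml"]
        return outs

    @stage("common_regulation")
    def _common():
        state["regulation"] = RegulatoryMap.from_tsv(config.regulation)
        common = common_regulation(
            state["network_a"], state["network_b"], state["regulation"]
        )
        state["common"] = common
        _write_genes(sorted(common.common_tfs), outdir / "common_tfs.txt")
        _write_genes(sorted(common.common_targets), outdir / "common_targets.txt")
        # re-write node tables now that roles are annotated
        state["network_a"].node_table().to_csv(
            outdir / "network_a_nodes.tsv", sep="\t", index=False
        )
        state["network_b"].node_table().to_csv(
            outdir / "network_b_nodes.tsv", sep="\t", index=False
        )
        return ["common_tfs.txt", "common_targets.txt"]

    @stage("enrichment")
    def _enrich():
        state["pathways"] = GeneSetCollection.from_gmt(config.pathways)
        common = state["common"]
        universe = set(state["regulation"].target_set) | set(state["pathways"].genes)
        if not common.common_targets:
            raise ValueError("no common targets to enrich")
        table = ora_enrich(
            common.common_targets, state["pathways"], universe=universe,
            p_cut=t["p_cut"], fdr_cut=t["fdr_cut"],
        )
        state["enrichment"] = table
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        return ["enrichment.tsv"]

    @stage("pathway_scores")
    def _scores():
        state["expression"] = read_expression_table(config.expression)
        enr = state["enrichment"]
        sig = list(enr.loc[enr["significant"], "pathway_id"])
        if not sig:
            warnings.warn(
                "no significantly enriched pathway; scoring all pathways",
                stacklevel=2,
            )
            sig = sorted(state["pathways"].sets)
        subset = {pid: state["pathways"].sets[pid] for pid in sig}
        catalogs = {
            config.disease_a: state["catalog_a"],
            config.disease_b: state["catalog_b"],
        }
        panel = score_pathway_panel(subset, state["expression"], catalogs)
        state["panel"] = panel
        panel.to_csv(outdir / "pathway_scores.tsv", sep="\t", index=False)
        return ["pathway_scores.tsv"]

    @stage("tf_profiles")
    def _tf():
        tfs = sorted(
            set(state["regulation"].tf_set) & set(state["expression"].index)
        )
        profiles = state["expression"].loc[tfs]
        outs = []
        k = t["k_clusters"]
        complete = profiles.dropna(axis=0)
        if len(complete) >= k and k >= 1:
            clusters = cluster_tf_profiles(profiles, k=k)
            clusters.labels.rename_axis("tf").reset_index().to_csv(
                outdir / "tf_clusters.tsv", sep="\t", index=False
            )
            outs.append("tf_clusters.tsv")
        else:
            warnings.warn(
                f"only {len(complete)} complete TF profiles; skipping "
                f"clustering (k={k})", stacklevel=2,
            )
        ref = config.reference_disease or config.disease_a
        diff = select_differential_tfs(profiles, ref, delta=t["delta"])
        _write_genes(diff, outdir / "differential_tfs.txt")
        outs.append("differential_tfs.txt")
        return outs

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
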