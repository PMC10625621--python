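"""TF->target regulation, shared regulators, and overrepresentation.

Transcription factors appearing as nodes of an inferred disease network
are its *specific transcription factors* (STFs); the union of their
regulon targets is the gene set the network regulates.  Comparing two
disease networks yields common TFs (STF intersection) and common
targets (intersection of the two regulated-target unions), which are
then tested against pathway gene sets with a hypergeometric
overrepresentation analysis under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .inference import DiseaseNetwork

__all__ = [
    "RegulatoryMap",
    "GeneSetCollection",
    "identify_stfs",
    "common_regulation",
    "CommonRegulation",
    "ora_enrich",
]


@dataclass
class RegulatoryMap:
    """Directed TF -> target pairs (duplicates collapsed)."""

    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "RegulatoryMap":
        return cls(frozenset((str(t).upper(), str(g).upper()) for t, g in pairs))

    @classmethod
    def from_tsv(
        cls, path, tf_col: str = "tf", target_col: str = "target",
        preset: str = "default",
    ) -> "RegulatoryMap":
        """Read a 2+-column TSV.  The ``trrust`` preset is headerless
        (TF, target, mode, PMID) and ignores the trailing columns."""
        if preset == "trrust":
            df = pd.read_csv(path, sep="\t", header=None, dtype=str)
            return cls.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_pairs(zip(df[tf_col], df[target_col]))

    @cached_property
    def tf_set(self) -> frozenset[str]:
        return frozenset(t for t, _ in self.pairs)

    @cached_property
    def target_set(self) -> frozenset[str]:
        return frozenset(g for _, g in self.pairs)

    @cached_property
    def _regulons(self) -> dict[str, frozenset[str]]:
        reg: dict[str, set[str]] = {}
        for t, g in self.pairs:
            reg.setdefault(t, set()).add(g)
        return {t: frozenset(g) for t, g in reg.items()}

    def targets_of(self, tf: str) -> frozenset[str]:
        return self._regulons.get(tf, frozenset())

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(sorted(self.pairs), columns=["tf", "target"])
        df.to_csv(path, sep="\t", index=False)


@dataclass
class GeneSetCollection:
    """Named pathway -> gene-set map, GMT-backed."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set '{name}' is empty")

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets: dict[str, frozenset[str]] = {}
        desc: dict[str, str] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{ln}: GMT line needs name, description and "
                        f">=1 gene"
                    )
                name = parts[0].strip()
                if name in sets:
                    raise ValueError(f"{path}:{ln}: duplicate pathway id '{name}'")
                genes = frozenset(
                    g.strip().upper() for g in parts[2:] if g.strip()
                )
                if not genes:
                    raise ValueError(f"{path}:{ln}: pathway '{name}' has no genes")
                sets[name] = genes
                desc[name] = parts[1]
        return cls(sets=sets, descriptions=desc)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                genes = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\t{self.descriptions.get(name, '')}\t{genes}\n")

    @cached_property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


def identify_stfs(
    network: DiseaseNetwork, reg: RegulatoryMap
) -> tuple[frozenset[str], frozenset[str]]:
    """Specific TFs of a network and the union of their regulons.

    STFs are the network nodes known as TFs in the regulatory map; the
    regulated-target union may extend beyond the network.  Node roles
    are updated in place: STFs become ``tf``, in-network regulated
    targets become ``target`` (seed role is preserved).
    """
    stf = frozenset(network.nodes & reg.tf_set)
    targets: set[str] = set()
    for t in stf:
        targets |= reg.targets_of(t)
    if not stf:
        warnings.warn(
            "no TF of the regulatory map occurs in the network", stacklevel=2
        )
    for u in network.graph.nodes:
        if network.graph.nodes[u].get("role") == "seed":
            continue
        if u in stf:
            network.graph.nodes[u]["role"] = "tf"
        elif u in targets:
            network.graph.nodes[u]["role"] = "target"
    return stf, frozenset(targets)


@dataclass(frozen=True)
class CommonRegulation:
    common_tfs: frozenset[str]
    common_targets: frozenset[str]


def common_regulation(
    net_a: DiseaseNetwork,
    net_b: DiseaseNetwork,
    reg: RegulatoryMap,
    targets_of_common_tfs_only: bool = False,
) -> CommonRegulation:
    """Shared TFs and shared regulated targets of two disease networks.

    Common targets default to the intersection of the two networks' full
    STF-regulon unions; the narrower alternative (regulons of the common
    TFs only) is available behind the flag.
    """
    stf_a, targets_a = identify_stfs(net_a, reg)
    stf_b, targets_b = identify_stfs(net_b, reg)
    common_tfs = stf_a & stf_b
    if targets_of_common_tfs_only:
        common_targets: set[str] = set()
        for t in common_tfs:
            common_targets |= reg.targets_of(t)
        common_targets = frozenset(common_targets)
    else:
        common_targets = targets_a & targets_b
    return CommonRegulation(frozenset(common_tfs), frozenset(common_targets))


def ora_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Optional[Iterable[str]] = None,
    p_cut: float = 0.05,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of a gene list in pathway sets.

    For each pathway: p = P(X >= k) with k = |query ∩ set|, drawing
    n = |query| genes from a universe of N containing K = |set ∩
    universe| pathway genes; BH-FDR across all pathways.  Query genes
    outside the universe are dropped (reported via warning).  Returns
    the full table sorted by p then pathway id, with a ``significant``
    column applying both cuts.
    """
    query = {str(g) for g in query}
    if not query:
        raise ValueError("empty query gene set")
    if universe is None:
        universe = set(collection.genes) | query
    else:
        universe = {str(g) for g in universe}
    if not universe:
        raise ValueError("empty universe")
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped",
            stacklevel=2,
        )
        query = query & universe
        if not query:
            raise ValueError("no query gene inside the universe")
    N, n = len(universe), len(query)
    rows = []
    for pid in sorted(collection.sets):
        pset = collection.sets[pid] & universe
        K = len(pset)
        k = len(query & pset)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "pathway_id": pid,
                "overlap_count": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = (df["p_value"] < p_cut) & (df["fdr"] < fdr_cut)
    df = df.sort_values(
        ["p_value", "pathway_id"], kind="mergesort"
    ).reset_index(drop=True)
    return df
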