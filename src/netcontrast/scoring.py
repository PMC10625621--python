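"""Pathway-level expression and mutation-propensity scoring.

Two per-pathway summary statistics contrast how strongly a disease
perturbs a pathway:

* expression score ``ES = mean over pathway genes of |z|`` — the mean
  absolute differential-expression z-score, a direction-agnostic proxy
  for the magnitude of signalling change; and
* propensity score ``PS = (sum of unique-mutation counts of pathway
  genes) / pathway size`` — the average number of distinct mutations per
  gene, a proxy for the pathway's mutation vulnerability.

TF expression profiles across diseases can additionally be clustered
(hierarchical, average linkage) and screened for TFs whose z-score in a
reference disease diverges from the other diseases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .mutations import MutationCatalog

__all__ = [
    "read_expression_table",
    "expression_score",
    "propensity_score",
    "score_pathway_panel",
    "TFProfileClusters",
    "cluster_tf_profiles",
    "select_differential_tfs",
]


def read_expression_table(path, layout: str = "long") -> pd.DataFrame:
    """Read z-scores into a gene x disease frame (NaN = unmeasured).

    ``long`` expects (disease, gene, z) columns; ``wide`` expects genes
    in the first column and one column per disease.
    """
    if layout == "long":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        df["gene"] = df["gene"].str.upper()
        return df.pivot_table(index="gene", columns="disease", values="z")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.str.upper()
    return df


def write_expression_table(table: pd.DataFrame, path) -> None:
    long = (
        table.rename_axis("gene")
        .reset_index()
        .melt(id_vars="gene", var_name="disease", value_name="z")
        .dropna(subset=["z"])
        .sort_values(["disease", "gene"])
    )
    long[["disease", "gene", "z"]].to_csv(path, sep="\t", index=False)


def expression_score(
    pathway_genes: Iterable[str],
    z: pd.Series,
    denominator: str = "scored",
) -> tuple[float, int]:
    """Mean absolute z over a pathway's measured genes.

    Genes without a z-score are excluded from numerator and denominator
    (``denominator="scored"``); with ``denominator="full"`` the sum is
    divided by the total pathway size instead.  Returns (ES, n_scored);
    ES is NaN when no pathway gene is measured.
    """
    genes = sorted({str(g) for g in pathway_genes})
    if not genes:
        raise ValueError("empty pathway")
    vals = z.reindex(genes).dropna()
    n_scored = int(len(vals))
    if n_scored == 0:
        return float("nan"), 0
    total = float(np.abs(vals.to_numpy()).sum())
    denom = n_scored if denominator == "scored" else len(genes)
    return total / denom, n_scored


def propensity_score(
    pathway_genes: Iterable[str], catalog: MutationCatalog
) -> float:
    """Average number of distinct mutations per pathway gene.

    The numerator counts unique (gene, protein_change) pairs of the
    catalog falling in the pathway; the denominator is the full pathway
    size, so unmutated members dilute the score.
    """
    genes = {str(g) for g in pathway_genes}
    if not genes:
        raise ValueError("empty pathway")
    n_unique = sum(1 for g, _ in catalog.unique_mutations if g in genes)
    return n_unique / len(genes)


def score_pathway_panel(
    pathways: Mapping[str, Iterable[str]],
    z_table: pd.DataFrame,
    catalogs: Optional[Mapping[str, MutationCatalog]] = None,
    denominator: str = "scored",
) -> pd.DataFrame:
    """Full pathway x disease panel of ES / PS rows.

    Every disease column of ``z_table`` is crossed with every pathway;
    PS is NaN for diseases without a mutation catalog.  Rows are ordered
    by (pathway_id, disease).
    """
    catalogs = catalogs or {}
    rows = []
    for pid in sorted(pathways):
        genes = sorted({str(g) for g in pathways[pid]})
        for disease in sorted(z_table.columns):
            es, n_scored = expression_score(
                genes, z_table[disease], denominator=denominator
            )
            cat = catalogs.get(disease)
            ps = propensity_score(genes, cat) if cat is not None else float("nan")
            rows.append(
                {
                    "pathway_id": pid,
                    "disease": disease,
                    "expression_score": es,
                    "propensity_score": ps,
                    "n_genes_scored": n_scored,
                    "n_genes_total": len(genes),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TFProfileClusters:
    profiles: pd.DataFrame  # complete rows only (tf x disease)
    labels: pd.Series  # tf -> cluster id in 1..k
    linkage_matrix: np.ndarray
    k: int


def cluster_tf_profiles(profiles: pd.DataFrame, k: int = 3) -> TFProfileClusters:
    """Hierarchically cluster TF expression profiles into k groups.

    Euclidean distance, average linkage, tree cut at k clusters; only
    TFs with a complete profile row participate.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    complete = profiles.dropna(axis=0)
    complete = complete.sort_index()
    if len(complete) < k:
        raise ValueError(
            f"need at least k={k} TFs with complete profiles, got {len(complete)}"
        )
    Z = linkage(complete.to_numpy(), method="average", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return TFProfileClusters(
        profiles=complete,
        labels=pd.Series(labels, index=complete.index, name="cluster"),
        linkage_matrix=Z,
        k=k,
    )


def select_differential_tfs(
    profiles: pd.DataFrame, reference_disease: str, delta: float = 1.0
) -> list[str]:
    """TFs whose reference-disease z diverges from some other disease.

    A TF is selected iff |z(reference) - z(c)| >= delta for at least one
    non-reference disease c with both values measured.
    """
    if reference_disease not in profiles.columns:
        raise ValueError(f"reference disease '{reference_disease}' not in profiles")
    ref = profiles[reference_disease]
    others = [c for c in profiles.columns if c != reference_disease]
    out = []
    for tf in profiles.index:
        r = ref.loc[tf]
        if pd.isna(r):
            continue
        for c in others:
            v = profiles.loc[tf, c]
            if not pd.isna(v) and abs(r - v) >= delta:
                out.append(tf)
                break
    return sorted(out)
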