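"""Mutation catalogs and cohort-level comparison statistics.

A *mutation catalog* holds per-sample point mutations for one cohort
(e.g. de novo variants in a neurodevelopmental cohort, or somatic
variants in a tumour cohort), each described at the protein level by a
short substitution string such as ``R130Q`` or ``R130*``.  The module
parses and harmonizes such catalogs, computes per-mutation recurrence
frequencies ``log10(N + 1)`` (N = number of distinct patients carrying
the mutation), partitions two catalogs into shared / cohort-specific
mutation and gene sets, compares frequency and pathogenicity
distributions with Welch's t-test, builds phenotype-overlap graphs and
per-residue mutation profiles, and selects recurrently mutated seed
genes for network inference.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import CatalogFormatError, EmptyCatalogError, InsufficientDataError

__all__ = [
    "MutationRecord",
    "MutationCatalog",
    "ParseReport",
    "TestResult",
    "CohortComparison",
    "parse_protein_change",
    "parse_catalog",
    "mutation_frequency",
    "welch_t_test",
    "compare_catalogs",
    "annotate_gene_classes",
    "phenotype_overlap_network",
    "residue_profile",
    "select_seed_genes",
]

# Short-HGVS point substitution: ref residue, 1-based position, alt
# residue or "*" (nonsense).  An optional "p." prefix is stripped first.
_PROTEIN_CHANGE_RE = re.compile(r"^([A-Z])(\d+)([A-Z]|\*)$")


def parse_protein_change(change: str) -> Optional[tuple[str, int, str]]:
    """Parse ``[p.]R130Q``-style strings into (ref, position, alt).

    Returns None for anything that is not a simple point substitution
    (frameshifts, "p.?", indels, splice notation, ...).
    """
    if not isinstance(change, str):
        return None
    s = change.strip()
    if s.startswith("p."):
        s = s[2:]
    m = _PROTEIN_CHANGE_RE.match(s)
    if m is None:
        return None
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if pos < 1:
        return None
    return ref, pos, alt


@dataclass(frozen=True)
class MutationRecord:
    """One observed point mutation in one sample."""

    sample_id: str
    gene: str
    protein_change: str
    phenotype: Optional[str] = None
    pathogenicity: Optional[float] = None

    @property
    def mutation(self) -> tuple[str, str]:
        return (self.gene, self.protein_change)


@dataclass
class ParseReport:
    n_rows: int = 0
    n_dropped_nonpoint: int = 0
    n_duplicates: int = 0
    n_records: int = 0


@dataclass
class MutationCatalog:
    """All point-mutation records of one cohort."""

    cohort_name: str
    records: list[MutationRecord]
    parse_report: Optional[ParseReport] = None

    @cached_property
    def unique_mutations(self) -> frozenset[tuple[str, str]]:
        return frozenset(r.mutation for r in self.records)

    @cached_property
    def mutated_genes(self) -> frozenset[str]:
        return frozenset(r.gene for r in self.records)

    @cached_property
    def _carriers(self) -> dict[tuple[str, str], frozenset[str]]:
        out: dict[tuple[str, str], set[str]] = {}
        for r in self.records:
            out.setdefault(r.mutation, set()).add(r.sample_id)
        return {k: frozenset(v) for k, v in out.items()}

    @cached_property
    def _gene_carriers(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for r in self.records:
            out.setdefault(r.gene, set()).add(r.sample_id)
        return {k: frozenset(v) for k, v in out.items()}

    def carriers(self, mutation: tuple[str, str]) -> frozenset[str]:
        """Distinct samples carrying an exact (gene, protein_change)."""
        return self._carriers.get(tuple(mutation), frozenset())

    def gene_carriers(self, gene: str) -> frozenset[str]:
        return self._gene_carriers.get(gene, frozenset())

    @cached_property
    def samples(self) -> frozenset[str]:
        return frozenset(r.sample_id for r in self.records)

    def pathogenicity_of(self, mutation: tuple[str, str]) -> Optional[float]:
        vals = [
            r.pathogenicity
            for r in self.records
            if r.mutation == tuple(mutation) and r.pathogenicity is not None
        ]
        return float(np.mean(vals)) if vals else None

    def __len__(self) -> int:
        return len(self.records)


#: Column-name presets for common input dialects.  A MAF-like export
#: uses the TCGA annotation-file headers; the driver-catalog preset fits
#: two-column (gene, protein_change) tables with an implicit sample.
COLUMN_PRESETS: dict[str, dict[str, str]] = {
    "default": {
        "sample": "sample",
        "gene": "gene",
        "protein_change": "protein_change",
        "phenotype": "phenotype",
        "pathogenicity": "pathogenicity",
    },
    "maf": {
        "sample": "Tumor_Sample_Barcode",
        "gene": "Hugo_Symbol",
        "protein_change": "HGVSp_Short",
        "phenotype": "Cancer_Type",
        "pathogenicity": "pathogenicity",
    },
}


def _norm_gene(g: str) -> str:
    return str(g).strip().upper()


def parse_catalog(
    path,
    cohort_name: str,
    point_only: bool = True,
    columns: Optional[Mapping[str, str]] = None,
    preset: str = "default",
    sep: str = "\t",
) -> MutationCatalog:
    """Read a tabular mutation catalog into a :class:`MutationCatalog`.

    Rows whose protein change is not a simple point substitution are
    dropped when ``point_only`` is set (counted in the parse report);
    duplicate (sample, gene, protein_change) rows collapse to one
    record.  Gene symbols are upper-cased and stripped.
    """
    cols = dict(COLUMN_PRESETS[preset])
    if columns:
        cols.update(columns)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyCatalogError(f"{path}: no data")
    if df.empty:
        raise EmptyCatalogError(f"{path}: no data rows")
    for key in ("sample", "gene", "protein_change"):
        if cols[key] not in df.columns:
            raise CatalogFormatError(
                f"{path}: required column '{cols[key]}' (for {key}) not found; "
                f"available: {list(df.columns)}"
            )
    has_pheno = cols.get("phenotype") in df.columns
    has_patho = cols.get("pathogenicity") in df.columns

    report = ParseReport(n_rows=len(df))
    records: list[MutationRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        sample = str(row[cols["sample"]]).strip()
        gene = _norm_gene(row[cols["gene"]])
        change = str(row[cols["protein_change"]]).strip()
        if change.startswith("p."):
            change = change[2:]
        if point_only and parse_protein_change(change) is None:
            report.n_dropped_nonpoint += 1
            continue
        key = (sample, gene, change)
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
        pheno = None
        if has_pheno:
            v = row[cols["phenotype"]]
            pheno = None if pd.isna(v) else str(v).strip()
        patho = None
        if has_patho:
            v = row[cols["pathogenicity"]]
            if not pd.isna(v):
                patho = float(v)
                if not 0.0 <= patho <= 1.0:
                    raise CatalogFormatError(
                        f"{path}: pathogenicity {patho} outside [0, 1] "
                        f"for {gene} {change}"
                    )
        records.append(MutationRecord(sample, gene, change, pheno, patho))
    report.n_records = len(records)
    return MutationCatalog(cohort_name=cohort_name, records=records, parse_report=report)


def mutation_frequency(catalog: MutationCatalog, mutation: tuple[str, str]) -> float:
    """Recurrence frequency ``log10(N + 1)``, N = distinct carriers."""
    return math.log10(len(catalog.carriers(mutation)) + 1)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def welch_t_test(
    x: Sequence[float],
    y: Sequence[float],
    pooled: bool = False,
    alternative: str = "two-sided",
) -> TestResult:
    """Two-sample t-test, Welch (unequal variance) by default.

    The degenerate both-variances-zero case is resolved by convention:
    equal means give p = 1, unequal means give p = 0 with an infinite
    statistic, so constant groups never raise a division error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx_, ny_ = len(x), len(y)
    if nx_ < 2 or ny_ < 2:
        raise InsufficientDataError(
            f"t-test needs >= 2 observations per group (got {nx_}, {ny_})"
        )
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, nx_, ny_)
        stat = math.inf if x.mean() > y.mean() else -math.inf
        p = 0.0 if alternative == "two-sided" else (
            0.0 if (alternative == "greater") == (stat > 0) else 1.0
        )
        return TestResult(stat, p, nx_, ny_)
    if pooled:
        sp2 = ((nx_ - 1) * vx + (ny_ - 1) * vy) / (nx_ + ny_ - 2)
        se = math.sqrt(sp2 * (1 / nx_ + 1 / ny_))
        df = nx_ + ny_ - 2
    else:
        se = math.sqrt(vx / nx_ + vy / ny_)
        df = (vx / nx_ + vy / ny_) ** 2 / (
            (vx / nx_) ** 2 / (nx_ - 1) + (vy / ny_) ** 2 / (ny_ - 1)
        )
    stat = (x.mean() - y.mean()) / se
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(abs(stat), df)
    elif alternative == "greater":
        p = stats.t.sf(stat, df)
    elif alternative == "less":
        p = stats.t.cdf(stat, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(float(stat), float(min(p, 1.0)), nx_, ny_)


@dataclass
class CohortComparison:
    shared_mutations: frozenset[tuple[str, str]]
    a_specific_mutations: frozenset[tuple[str, str]]
    b_specific_mutations: frozenset[tuple[str, str]]
    shared_genes: frozenset[str]
    a_specific_genes: frozenset[str]
    b_specific_genes: frozenset[str]
    frequency_test: TestResult
    pathogenicity_test: Optional[TestResult] = None


def compare_catalogs(
    a: MutationCatalog,
    b: MutationCatalog,
    frequency_source: Optional[MutationCatalog] = None,
    include_absent: bool = False,
    alternative: str = "two-sided",
    pooled: bool = False,
) -> CohortComparison:
    """Partition two catalogs and test their frequency distributions.

    ``frequency_source`` is the catalog in which recurrence of both
    mutation groups is counted (defaults to ``b``, i.e. both groups'
    frequencies among the second cohort's samples).  By default each
    group is restricted to mutations actually observed in the frequency
    source; ``include_absent`` instead scores absentees as 0.
    """
    if frequency_source is None:
        frequency_source = b
    mut_a, mut_b = a.unique_mutations, b.unique_mutations
    shared = mut_a & mut_b
    genes_a, genes_b = a.mutated_genes, b.mutated_genes

    def group_freqs(muts: Iterable[tuple[str, str]]) -> list[float]:
        # sorted so float accumulation does not depend on set order
        out = []
        for m in sorted(muts):
            n = len(frequency_source.carriers(m))
            if n == 0 and not include_absent:
                continue
            out.append(math.log10(n + 1))
        return out

    fx, fy = group_freqs(mut_a), group_freqs(mut_b)
    if len(fx) < 2 or len(fy) < 2:
        raise InsufficientDataError(
            "fewer than 2 mutations with nonzero frequency-source counts "
            f"in a group ({len(fx)}, {len(fy)})"
        )
    freq_test = welch_t_test(fx, fy, pooled=pooled, alternative=alternative)

    def group_patho(cat: MutationCatalog) -> list[float]:
        vals = []
        for m in sorted(cat.unique_mutations):
            p = cat.pathogenicity_of(m)
            if p is not None:
                vals.append(p)
        return vals

    px, py = group_patho(a), group_patho(b)
    patho_test = (
        welch_t_test(px, py, pooled=pooled, alternative=alternative)
        if len(px) >= 2 and len(py) >= 2
        else None
    )
    return CohortComparison(
        shared_mutations=frozenset(shared),
        a_specific_mutations=frozenset(mut_a - mut_b),
        b_specific_mutations=frozenset(mut_b - mut_a),
        shared_genes=frozenset(genes_a & genes_b),
        a_specific_genes=frozenset(genes_a - genes_b),
        b_specific_genes=frozenset(genes_b - genes_a),
        frequency_test=freq_test,
        pathogenicity_test=patho_test,
    )


@dataclass
class GeneClassCounts:
    """Per-class counts of mutated genes plus an upset-style breakdown.

    ``marginal`` counts each class over all mutated genes (a gene in two
    classes contributes to both); ``combinations`` maps a sorted tuple
    of class names — ``()`` for unannotated genes — to the number of
    mutated genes with exactly that membership.
    """

    marginal: dict[str, int]
    combinations: dict[tuple[str, ...], int]
    n_genes: int


_CLASS_FLAGS = {"tf": "is_tf", "tsg": "is_tsg", "oncogene": "is_oncogene"}


def annotate_gene_classes(
    catalog: MutationCatalog, annotations: pd.DataFrame
) -> GeneClassCounts:
    """Count mutated genes per functional class (TF / TSG / oncogene).

    ``annotations`` needs a ``gene`` column plus boolean ``is_tf``,
    ``is_tsg``, ``is_oncogene`` columns (missing flag columns are
    treated as all-False); genes absent from the table count as
    unannotated.
    """
    ann = annotations.copy()
    ann["gene"] = ann["gene"].map(_norm_gene)
    lookup: dict[str, frozenset[str]] = {}
    for row in ann.itertuples(index=False):
        classes = frozenset(
            name for name, col in _CLASS_FLAGS.items()
            if bool(getattr(row, col, False))
        )
        lookup[row.gene] = classes
    marginal = {name: 0 for name in _CLASS_FLAGS}
    marginal["none"] = 0
    combos: dict[tuple[str, ...], int] = {}
    for gene in catalog.mutated_genes:
        classes = lookup.get(gene, frozenset())
        if not classes:
            marginal["none"] += 1
        for c in classes:
            marginal[c] += 1
        key = tuple(sorted(classes))
        combos[key] = combos.get(key, 0) + 1
    return GeneClassCounts(marginal, combos, len(catalog.mutated_genes))


def phenotype_overlap_network(catalog: MutationCatalog) -> nx.Graph:
    """Graph of phenotypes linked when they share a mutated gene.

    Nodes carry ``n_samples``, ``n_mutated_genes`` and ``n_mutations``;
    edge weight is the number of commonly mutated genes.  Records
    without a phenotype are ignored.
    """
    per_pheno_genes: dict[str, set[str]] = {}
    per_pheno_samples: dict[str, set[str]] = {}
    per_pheno_muts: dict[str, set[tuple[str, str]]] = {}
    for r in catalog.records:
        if r.phenotype is None:
            continue
        per_pheno_genes.setdefault(r.phenotype, set()).add(r.gene)
        per_pheno_samples.setdefault(r.phenotype, set()).add(r.sample_id)
        per_pheno_muts.setdefault(r.phenotype, set()).add(r.mutation)
    g = nx.Graph()
    for p in per_pheno_genes:
        g.add_node(
            p,
            n_samples=len(per_pheno_samples[p]),
            n_mutated_genes=len(per_pheno_genes[p]),
            n_mutations=len(per_pheno_muts[p]),
        )
    phenos = sorted(per_pheno_genes)
    for i, p in enumerate(phenos):
        for q in phenos[i + 1:]:
            w = len(per_pheno_genes[p] & per_pheno_genes[q])
            if w > 0:
                g.add_edge(p, q, weight=w)
    return g


def residue_profile(
    a: MutationCatalog, b: MutationCatalog, gene: str
) -> pd.DataFrame:
    """Per-residue mutation profile of one gene across two cohorts.

    One row per (position, alt residue) with distinct-patient counts in
    each cohort and a flag marking exact protein changes present in
    both catalogs.  Nonsense changes keep ``*`` as the alt residue.
    """
    gene = _norm_gene(gene)
    rows: dict[tuple[int, str], dict] = {}

    def scan(cat: MutationCatalog, col: str) -> None:
        per_key: dict[tuple[int, str], set[str]] = {}
        refs: dict[tuple[int, str], str] = {}
        for r in cat.records:
            if r.gene != gene:
                continue
            parsed = parse_protein_change(r.protein_change)
            if parsed is None:
                continue
            ref, pos, alt = parsed
            per_key.setdefault((pos, alt), set()).add(r.sample_id)
            refs[(pos, alt)] = ref
        for key, samples in per_key.items():
            row = rows.setdefault(
                key, {"ref": refs[key], "count_a": 0, "count_b": 0}
            )
            row[col] = len(samples)

    scan(a, "count_a")
    scan(b, "count_b")
    if not rows:
        warnings.warn(f"gene {gene} absent from both catalogs", stacklevel=2)
        return pd.DataFrame(
            columns=["position", "alt", "ref", "count_a", "count_b", "shared"]
        )
    shared_changes = {
        m[1] for m in a.unique_mutations & b.unique_mutations if m[0] == gene
    }
    out = []
    for (pos, alt), row in sorted(rows.items()):
        change = f"{row['ref']}{pos}{alt}"
        out.append(
            {
                "position": pos,
                "alt": alt,
                "ref": row["ref"],
                "count_a": row["count_a"],
                "count_b": row["count_b"],
                "shared": change in shared_changes,
            }
        )
    return pd.DataFrame(out)


def select_seed_genes(
    catalog: MutationCatalog, min_patients: int = 3
) -> list[str]:
    """Genes mutated in at least ``min_patients`` distinct samples.

    Sorted by descending carrier count, ties broken lexicographically,
    so the list is invariant to record order.
    """
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    counts = {g: len(s) for g, s in catalog._gene_carriers.items()}
    hits = [g for g, n in counts.items() if n >= min_patients]
    return sorted(hits, key=lambda g: (-counts[g], g))
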