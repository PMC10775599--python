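"""DEG-table post-processing: filtering, Venn partitioning, concordance, enrichment.

The module consumes per-contrast differential-expression tables (gene id,
log2 fold change, FDR, per-group mean FPM) as produced upstream by an
edgeR/DESeq2-style fit — refitting those models is out of scope here.

A gene is a DEG when |log2FC| ≥ 0.59 (≈1.5-fold), FDR ≤ 0.05 and its
mean abundance exceeds 5 FPM in at least one group.  Set relations
between contrasts are summarized as a three-set Venn partition; effect
agreement between two contrasts as the fraction of shared DEGs regulated
in the same sense plus the slope of the regression of one contrast's
log2FC on the other's (deviation from the bisector = systematically
different effect size).  Gene-set enrichment uses the hypergeometric
upper tail with Benjamini–Hochberg adjustment and the fold-enrichment
statistic E = (intersection/query) / (term/domain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VennPartition",
    "ConcordanceResult",
    "EnrichmentTerm",
    "compute_fpm",
    "filter_degs",
    "deg_set",
    "venn_partition",
    "concordance",
    "enrich",
    "read_gmt",
    "write_gmt",
]

FC_THRESHOLD = 0.59
FDR_THRESHOLD = 0.05
FPM_THRESHOLD = 5.0


def compute_fpm(
    counts: pd.DataFrame,
    library_sizes: Mapping[str, float] | pd.Series | None = None,
    groups: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Fragments-per-million normalization of a genes x samples count table.

    ``FPM = count / library_size * 1e6``.  When ``library_sizes`` is
    omitted the per-sample column totals are used, making each FPM
    column sum to exactly 1e6.  ``groups`` (sample -> group label) adds
    per-group mean FPM columns; returns ``(fpm, group_means)``.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    sizes = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if sizes.isna().any():
        missing = list(sizes.index[sizes.isna()])
        raise ValueError(f"no library size for sample(s) {missing}")
    if (sizes <= 0).any():
        bad = list(sizes.index[sizes <= 0])
        raise ValueError(f"non-positive library size for sample(s) {bad}")
    fpm = counts.div(sizes, axis=1) * 1.0e6
    group_means = None
    if groups is not None:
        by_group: dict[str, pd.Series] = {}
        for sample, group in groups.items():
            by_group.setdefault(group, []).append(sample)
        group_means = pd.DataFrame(
            {g: fpm[samples].mean(axis=1) for g, samples in by_group.items()}
        )
    return fpm, group_means


def _check_deg_columns(table: pd.DataFrame) -> list[str]:
    for col in ("gene_id", "log2fc", "fdr"):
        if col not in table.columns:
            raise KeyError(f"DEG table missing column {col!r}")
    fpm_cols = [c for c in table.columns if c.startswith("fpm_")]
    if not fpm_cols:
        raise KeyError("DEG table missing per-group FPM columns (fpm_*)")
    return fpm_cols


def filter_degs(
    table: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    fpm_threshold: float = FPM_THRESHOLD,
) -> pd.DataFrame:
    """Rows passing all three DEG gates.

    Fold-change and FDR bounds are inclusive (≥, ≤); the abundance gate
    is strict: the gene's mean FPM must exceed ``fpm_threshold`` in at
    least one group.
    """
    fpm_cols = _check_deg_columns(table)
    keep = (
        (table["log2fc"].abs() >= fc_threshold)
        & (table["fdr"] <= fdr_threshold)
        & (table[fpm_cols].max(axis=1) > fpm_threshold)
    )
    return table.loc[keep].copy()


def deg_set(table: pd.DataFrame, **thresholds) -> set[str]:
    """Gene-id set version of :func:`filter_degs`."""
    return set(filter_degs(table, **thresholds)["gene_id"])


@dataclass(frozen=True)
class VennPartition:
    """Disjoint three-set partition: 7 regions keyed by label frozensets."""

    labels: tuple[str, str, str]
    regions: dict[frozenset[str], frozenset[str]]

    def counts(self) -> dict[frozenset[str], int]:
        return {key: len(genes) for key, genes in self.regions.items()}

    def specific(self, label: str) -> frozenset[str]:
        """Genes in exactly this contrast."""
        return self.regions[frozenset({label})]

    def total(self, label: str) -> int:
        """Total genes of one contrast = sum of its four regions."""
        return sum(len(g) for key, g in self.regions.items() if label in key)


def venn_partition(
    set_a: Iterable[str],
    set_b: Iterable[str],
    set_c: Iterable[str],
    labels: tuple[str, str, str] = ("HCl", "LA", "Na_lactate"),
) -> VennPartition:
    """Partition three gene sets into the seven disjoint Venn regions."""
    sets = {labels[0]: frozenset(set_a), labels[1]: frozenset(set_b), labels[2]: frozenset(set_c)}
    regions: dict[frozenset[str], frozenset[str]] = {}
    all_labels = set(labels)
    for r in (1, 2, 3):
        for inside in combinations(labels, r):
            genes = frozenset.intersection(*(sets[l] for l in inside))
            for outside in all_labels - set(inside):
                genes -= sets[outside]
            regions[frozenset(inside)] = genes
    return VennPartition(labels=labels, regions=regions)


@dataclass(frozen=True)
class ConcordanceResult:
    """Sign agreement and effect-size scaling between two DEG tables."""

    n_union: int
    n_common: int
    fraction_same_sign: float
    slope: float
    intercept: float
    slope_method: str

    @property
    def bisector_deviation(self) -> float:
        return self.slope - 1.0


def _tls_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Total-least-squares (first principal axis) slope and intercept."""
    xc, yc = x - x.mean(), y - y.mean()
    cov = np.cov(np.vstack([xc, yc]))
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, np.argmax(eigvals)]
    if v[0] == 0:
        raise ValueError("TLS slope undefined: vertical principal axis")
    slope = v[1] / v[0]
    return slope, y.mean() - slope * x.mean()


def concordance(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    universe: str = "union",
    slope_method: str = "ols",
    **thresholds,
) -> ConcordanceResult:
    """Sign concordance and regression slope of table B's log2FC on table A's.

    The gene universe is the ``union`` (default) or ``intersection`` of
    the two tables' DEG sets, restricted to genes present in both
    tables.  A log2FC of exactly zero counts as discordant with any
    nonzero partner.  The slope is ordinary least squares with intercept
    by default; ``slope_method='tls'`` uses the first principal axis
    (symmetric in A and B).
    """
    if universe not in ("union", "intersection"):
        raise ValueError("universe must be 'union' or 'intersection'")
    degs_a = deg_set(table_a, **thresholds)
    degs_b = deg_set(table_b, **thresholds)
    genes = degs_a | degs_b if universe == "union" else degs_a & degs_b
    merged = pd.merge(
        table_a[["gene_id", "log2fc"]],
        table_b[["gene_id", "log2fc"]],
        on="gene_id",
        suffixes=("_a", "_b"),
    )
    merged = merged[merged["gene_id"].isin(genes)]
    if len(merged) < 2:
        raise ValueError("fewer than 2 shared genes in the chosen universe")
    a = merged["log2fc_a"].to_numpy(float)
    b = merged["log2fc_b"].to_numpy(float)
    # sign(0) != sign(x != 0), so an exact zero is discordant with any
    # nonzero partner; two zeros agree trivially
    same = np.sign(a) == np.sign(b)
    if np.ptp(a) == 0:
        slope, intercept = math.nan, math.nan  # regression on A undefined
    elif slope_method == "ols":
        fit = _st.linregress(a, b)
        slope, intercept = float(fit.slope), float(fit.intercept)
    elif slope_method == "tls":
        slope, intercept = _tls_slope(a, b)
    else:
        raise ValueError("slope_method must be 'ols' or 'tls'")
    return ConcordanceResult(
        n_union=len(degs_a | degs_b),
        n_common=len(merged),
        fraction_same_sign=float(same.mean()),
        slope=float(slope),
        intercept=float(intercept),
        slope_method=slope_method,
    )


@dataclass(frozen=True)
class EnrichmentTerm:
    """One tested gene-set term with its enrichment statistics."""

    term_id: str
    term_size: int
    intersection_size: int
    query_size: int
    effective_domain_size: int
    E: float
    p_hyper: float
    p_adjusted: float


def enrich(
    query_set: Iterable[str],
    term_collection: Mapping[str, Iterable[str]],
    domain_size: int,
    min_term: int = 5,
    max_term: int = 3000,
    p_thresh: float = 0.001,
    e_thresh: float = 2.5,
    return_all: bool = False,
) -> list[EnrichmentTerm]:
    """Hypergeometric gene-set enrichment with a fold-enrichment gate.

    For each term of admissible size (``min_term`` ≤ size ≤ ``max_term``)
    the upper-tail hypergeometric p-value (probability of the observed
    intersection or larger) is computed and Benjamini–Hochberg adjusted
    across all tested terms.  Fold enrichment
    ``E = (intersection/query) / (term/domain)``.  Returned terms satisfy
    ``p_adjusted ≤ p_thresh`` and ``E ≥ e_thresh`` unless ``return_all``.
    """
    query = set(query_set)
    if not query:
        raise ValueError("empty query set")
    if domain_size < len(query):
        raise ValueError("effective domain smaller than the query set")
    terms = {tid: set(genes) for tid, genes in term_collection.items()}
    for tid, genes in terms.items():
        if domain_size < len(genes):
            raise ValueError(f"effective domain smaller than term {tid!r}")

    tested = [
        (tid, genes) for tid, genes in terms.items() if min_term <= len(genes) <= max_term
    ]
    if not tested:
        return []
    results = []
    p_values = []
    for tid, genes in tested:
        k = len(query & genes)
        t, q = len(genes), len(query)
        p = float(_st.hypergeom.sf(k - 1, domain_size, t, q))
        e = (k / q) / (t / domain_size)
        results.append((tid, t, k, q, e))
        p_values.append(p)
    p_adj = multipletests(p_values, method="fdr_bh")[1]
    out = [
        EnrichmentTerm(
            term_id=tid, term_size=t, intersection_size=k, query_size=q,
            effective_domain_size=domain_size, E=e, p_hyper=p, p_adjusted=float(pa),
        )
        for (tid, t, k, q, e), p, pa in zip(results, p_values, p_adj)
    ]
    if not return_all:
        out = [r for r in out if r.p_adjusted <= p_thresh and r.E >= e_thresh]
    return sorted(out, key=lambda r: (r.p_adjusted, r.term_id))


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (term, description, genes... per line)."""
    collection: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            collection[parts[0]] = [g for g in parts[2:] if g]
    return collection


def write_gmt(collection: Mapping[str, Iterable[str]], path) -> None:
    """Write a term -> gene-list mapping as a GMT file."""
    with open(path, "w") as fh:
        for term, genes in collection.items():
            fh.write("\t".join([term, "na", *genes]) + "\n")
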