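"""Downstream annotation statistics: term overrepresentation, gene-body
methylation fractions, and efficiency-corrected qPCR quantification."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import hypergeom

from .diffexpr import benjamini_hochberg

logger = logging.getLogger(__name__)


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) -> gene_id -> set of term ids."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise ValueError(f"{path}: need columns gene_id, term_id")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        out.setdefault(gene, set()).add(term)
    return out


def enrichment_test(
    gene_set: set[str],
    term_map: dict[str, set[str]],
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of every term in `gene_set`.

    For a term annotating K of N universe genes, and a set of n genes with
    overlap k, p = P[X >= k] with X ~ Hypergeometric(N, K, n), summed from
    the pmf; q is the Benjamini-Hochberg adjustment across tested terms.
    The universe defaults to all mapped genes.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    if universe is None:
        universe = set(term_map)
    outside = gene_set - universe
    if outside:
        raise ValueError(
            f"gene_set is not a subset of the universe (e.g. {sorted(outside)[:3]})"
        )
    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in term_map.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    # terms whose annotated genes fall partly outside the universe were
    # already restricted by construction above
    N, n = len(universe), len(gene_set)
    rows = []
    for term, genes in sorted(term_genes.items()):
        K = len(genes)
        k = len(gene_set & genes)
        support = np.arange(k, min(K, n) + 1)
        p = float(hypergeom.pmf(support, N, K, n).sum())
        rows.append(
            {
                "term_id": term,
                "overlap": k,
                "term_size": K,
                "expected": n * K / N,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("term_id")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out.sort_values("p")


@dataclass(frozen=True)
class MethylationSummary:
    set_pct: float
    genome_pct: float
    p: float
    direction: str  # depleted | enriched | equal


def methylation_fraction(
    gene_set: set[str], calls: dict[str, bool] | pd.Series
) -> MethylationSummary:
    """Gene-body methylation percentage of a set vs. the whole genome.

    calls: per-gene boolean methylation status for the whole genome.  The
    hypergeometric p is the lower tail when the set fraction falls below
    the genome fraction (depletion), the upper tail otherwise.
    """
    if isinstance(calls, pd.Series):
        calls = calls.astype(bool).to_dict()
    missing = sorted(g for g in gene_set if g not in calls)
    if missing:
        raise KeyError(f"genes missing from methylation calls: {missing[:5]}")
    N = len(calls)
    K = sum(bool(v) for v in calls.values())
    n = len(gene_set)
    if n == 0:
        raise ValueError("empty gene set")
    k = sum(bool(calls[g]) for g in gene_set)
    set_pct = 100.0 * k / n
    genome_pct = 100.0 * K / N
    if set_pct < genome_pct:
        p = float(hypergeom.cdf(k, N, K, n))
        direction = "depleted"
    elif set_pct > genome_pct:
        p = float(hypergeom.sf(k - 1, N, K, n))
        direction = "enriched"
    else:
        p, direction = 1.0, "equal"
    return MethylationSummary(set_pct=set_pct, genome_pct=genome_pct, p=min(p, 1.0), direction=direction)


def qgene_normalized_expression(
    ct_target: float | np.ndarray,
    ct_ref: float | np.ndarray,
    e_target: float = 2.0,
    e_ref: float = 2.0,
):
    """qGene normalized expression NE = E_ref^CT_ref / E_target^CT_target.

    E is the per-cycle amplification factor in (1, 2] (2 = perfect
    doubling); CT the threshold cycle.  NE is dimensionless: the target
    template amount relative to the reference gene.
    """
    for name, e in (("e_target", e_target), ("e_ref", e_ref)):
        if not 1.0 < e <= 2.0:
            raise ValueError(f"{name} must lie in (1, 2], got {e}")
    ct_target = np.asarray(ct_target, dtype=float)
    ct_ref = np.asarray(ct_ref, dtype=float)
    if (ct_target <= 0).any() or (ct_ref <= 0).any():
        raise ValueError("CT values must be positive")
    ne = np.power(e_ref, ct_ref) / np.power(e_target, ct_target)
    return ne if ne.ndim else float(ne)


def qgene_summary(
    measurements: pd.DataFrame,
    e_target: float = 2.0,
    e_ref: float = 2.0,
) -> pd.DataFrame:
    """Per-sample mean NE and standard error across replicate wells.

    measurements: columns sample, target_ct, ref_ct and optionally
    e_target/e_ref per row.  Requires >= 3 replicates per sample for a
    standard error.
    """
    df = measurements.copy()
    et = df["e_target"].astype(float) if "e_target" in df else np.full(len(df), e_target)
    er = df["e_ref"].astype(float) if "e_ref" in df else np.full(len(df), e_ref)
    df["ne"] = [
        qgene_normalized_expression(t, r, e_target=e1, e_ref=e2)
        for t, r, e1, e2 in zip(
            df["target_ct"].astype(float), df["ref_ct"].astype(float), et, er
        )
    ]
    grouped = df.groupby("sample")["ne"]
    sizes = grouped.size()
    small = sizes[sizes < 3]
    if len(small):
        logger.warning(
            "sample(s) with < 3 replicate measurements: %s", list(small.index)
        )
    out = pd.DataFrame(
        {"n": sizes.astype(int), "mean_ne": grouped.mean(), "se_ne": grouped.sem(ddof=1)}
    )
    out.index.name = "sample"
    return out


def qgene_compare(
    measurements: pd.DataFrame, sample_a: str, sample_b: str, **kwargs
) -> tuple[float, float]:
    """Two-sample Student's t-test on replicate NE values of two samples."""
    df = measurements.copy()
    df["ne"] = [
        qgene_normalized_expression(t, r, **kwargs)
        for t, r in zip(df["target_ct"].astype(float), df["ref_ct"].astype(float))
    ]
    a = df.loc[df["sample"] == sample_a, "ne"]
    b = df.loc[df["sample"] == sample_b, "ne"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per sample for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
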