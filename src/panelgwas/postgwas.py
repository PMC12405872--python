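"""Post-scan interpretation: LD locus grouping, gene assignment, threshold
reports and pathway fold-enrichment.

Top variants are grouped into LD-independent loci as connected components of
the graph with an edge wherever pairwise r-squared (squared Pearson
correlation of call vectors over pairwise-complete lines) reaches the
threshold (0.5 by default). A variant belongs to a gene when its position
falls within the gene's transcription boundaries extended by a flank
(1 kb by default) on the same chromosome; strand is ignored. Pathway
enrichment is the one-sided Fisher / hypergeometric upper tail with
fold = observed / (n * K / N) and Benjamini-Hochberg FDR across pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeMatrix
from .errors import ValidationError

logger = logging.getLogger("panelgwas")


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def pairwise_r2(geno: GenotypeMatrix, snp_ids: list[str]) -> pd.DataFrame:
    """Squared Pearson correlation between call vectors, pairwise-complete.

    Pairs sharing fewer than 3 lines with calls in both variants get ``nan``
    (treated as below any grouping threshold). Diagonal is 1.
    """
    sub = geno.select_variants(snp_ids)
    x = sub.dosage()
    m = len(snp_ids)
    r2 = np.full((m, m), np.nan)
    np.fill_diagonal(r2, 1.0)
    for i in range(m):
        for j in range(i + 1, m):
            mask = ~np.isnan(x[i]) & ~np.isnan(x[j])
            if mask.sum() < 3:
                logger.warning(
                    "pair (%s, %s): <3 pairwise-complete lines; r2 undefined",
                    snp_ids[i], snp_ids[j],
                )
                continue
            a, b = x[i, mask], x[j, mask]
            if a.std() == 0.0 or b.std() == 0.0:
                r2[i, j] = r2[j, i] = 0.0
                continue
            r = np.corrcoef(a, b)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    return pd.DataFrame(r2, index=snp_ids, columns=snp_ids)


@dataclass
class LocusGroups:
    """Partition of top variants into LD-independent loci."""

    snp_ids: list[str]
    r2: pd.DataFrame
    threshold: float
    groups: list[list[str]]

    @property
    def n_loci(self) -> int:
        return len(self.groups)


def group_loci(r2: pd.DataFrame, threshold: float = 0.5) -> LocusGroups:
    """Connected components of the graph with edges where r2 >= threshold.

    Missing r2 entries count as below threshold; singletons form their own
    locus. Groups are ordered by first member appearance, members keep input
    order, so the partition is independent of any internal ordering.
    """
    ids = list(r2.index)
    mat = r2.to_numpy(copy=True)
    adj = np.nan_to_num(mat, nan=0.0) >= threshold
    np.fill_diagonal(adj, True)
    n_comp, labels = sparse.csgraph.connected_components(
        sparse.csr_matrix(adj), directed=False
    )
    groups: dict[int, list[str]] = {}
    for snp, lab in zip(ids, labels):
        groups.setdefault(lab, []).append(snp)
    ordered = sorted(groups.values(), key=lambda g: ids.index(g[0]))
    return LocusGroups(snp_ids=ids, r2=r2, threshold=threshold, groups=ordered)


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------

def assign_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 1000,
) -> pd.DataFrame:
    """Map variants to genes whose (tx_start - flank, tx_end + flank) interval
    contains the variant position; one output row per (variant, gene) pair.

    ``snps`` needs columns ``variant_id, chrom, pos``. Variants hitting no
    gene appear once with ``gene_id = NaN`` (intergenic). A chromosome name
    present in ``snps`` but absent from a non-empty annotation is reported,
    not silently unmatched.
    """
    for col in ("variant_id", "chrom", "pos"):
        if col not in snps.columns:
            raise ValidationError(f"snps table lacks column {col!r}")
    if len(genes):
        unmatched = sorted(set(snps["chrom"]) - set(genes["chrom"]))
        if unmatched:
            raise ValidationError(
                f"chromosomes absent from annotation: {unmatched}"
            )
    rows = []
    by_chrom = dict(tuple(genes.groupby("chrom"))) if len(genes) else {}
    for snp in snps.itertuples(index=False):
        sub = by_chrom.get(snp.chrom)
        hit = False
        if sub is not None:
            within = (
                (sub["tx_start"] - flank <= snp.pos)
                & (snp.pos <= sub["tx_end"] + flank)
            )
            for gid in sub.loc[within, "gene_id"]:
                rows.append((snp.variant_id, snp.chrom, snp.pos, gid))
                hit = True
        if not hit:
            rows.append((snp.variant_id, snp.chrom, snp.pos, np.nan))
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "gene_id"])


# ---------------------------------------------------------------------------
# threshold report
# ---------------------------------------------------------------------------

def threshold_report(
    results: pd.DataFrame,
    mapping: pd.DataFrame,
    thresholds: list[float],
) -> pd.DataFrame:
    """Counts of associated variants/genes below each p cutoff (strict <).

    Returns one row per threshold: n_snps, n_genes, n_intergenic_snps and the
    sorted distinct gene list. Thresholds are nested by construction.
    """
    if not thresholds:
        raise ValidationError("no thresholds given")
    gene_of = mapping.groupby("variant_id")["gene_id"].apply(
        lambda s: sorted(set(s.dropna()))
    )
    rows = []
    for cutoff in sorted(thresholds, reverse=True):
        hits = results.loc[results["p_value"] < cutoff, "variant_id"]
        genes: set[str] = set()
        intergenic = 0
        for vid in hits:
            assigned = gene_of.get(vid, [])
            if assigned:
                genes.update(assigned)
            else:
                intergenic += 1
        rows.append(
            (cutoff, len(hits), len(genes), intergenic, ",".join(sorted(genes)))
        )
    return pd.DataFrame(
        rows,
        columns=["p_threshold", "n_snps", "n_genes", "n_intergenic_snps", "genes"],
    )


# ---------------------------------------------------------------------------
# pathway enrichment
# ---------------------------------------------------------------------------

def pathway_enrichment(
    input_genes: list[str],
    pathways: dict[str, set[str]],
    reference_size: int,
    reference_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric (one-sided Fisher) pathway enrichment.

    For each pathway with K genes in a reference of N genes, observing
    ``observed`` of the n mapped input genes gives the upper-tail p-value
    ``P(X >= observed)`` for X ~ Hypergeom(N, K, n); expected = n*K/N,
    fold = observed/expected. When ``reference_genes`` is supplied, n and K
    count only genes present in it; otherwise every input gene is assumed
    mapped. FDR is Benjamini-Hochberg across the tested pathways.
    """
    if not pathways:
        raise ValidationError("no pathways supplied")
    genes = set(input_genes)
    if reference_genes is not None:
        genes &= reference_genes
    n = len(genes)
    N = int(reference_size)
    rows = []
    for name, members in pathways.items():
        mem = set(members)
        if reference_genes is not None:
            mem &= reference_genes
        K = len(mem)
        if K > N:
            raise ValidationError(f"pathway {name!r}: K={K} exceeds N={N}")
        observed = len(genes & mem)
        if observed > min(n, K):
            raise ValidationError(f"pathway {name!r}: impossible observed count")
        expected = n * K / N
        fold = observed / expected if expected > 0 else np.nan
        pval = float(stats.hypergeom.sf(observed - 1, N, K, n)) if K else 1.0
        rows.append((name, K, n, observed, expected, fold, min(pval, 1.0)))
    out = pd.DataFrame(
        rows,
        columns=["pathway_id", "K", "n", "observed", "expected", "fold", "p_value"],
    )
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
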