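"""In-memory containers shared across the pipeline.

The two central objects are :class:`GenotypeMatrix` (variants x lines table of
homozygous calls, as produced by inbred panels such as the DGRP) and
:class:`PhenotypePanel` (replicated per-individual counts per line with batch
structure and line-level covariates). Gene annotations travel as a plain
validated :class:`pandas.DataFrame` with columns
``gene_id, chrom, tx_start, tx_end, strand`` (1-based inclusive coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: canonical per-line covariate columns: Wolbachia infection plus the five
#: major cosmopolitan inversions segregating in the DGRP
WOLBACHIA_COL = "wolbachia"
INVERSION_COLS = ["In_2L_t", "In_2R_NS", "In_3L_P", "In_3R_P", "In_3R_Mo"]
COVARIATE_COLS = [WOLBACHIA_COL] + INVERSION_COLS

VARIANT_COLUMNS = ["chrom", "pos", "variant_id", "ref", "alt", "variant_class"]
GENE_COLUMNS = ["gene_id", "chrom", "tx_start", "tx_end", "strand"]


@dataclass
class GenotypeMatrix:
    """Homozygous calls for a panel of inbred lines.

    Parameters
    ----------
    line_ids
        Ordered, unique line identifiers (one call column each).
    variants
        One row per variant with columns ``chrom, pos, variant_id, ref, alt,
        variant_class`` (class one of SNP/DEL/INS/MNP).
    calls
        ``(n_variants, n_lines)`` float array with values ``0.0``
        (reference homozygote), ``2.0`` (alternate homozygote) or ``nan``
        (missing call). Heterozygotes do not occur in fully inbred panels.
    """

    line_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.variants), len(self.line_ids)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.line_ids)} lines"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValidationError("line_ids are not unique")
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate variant_id {dup!r}")
        ok = np.isnan(self.calls) | (self.calls == 0.0) | (self.calls == 2.0)
        if not ok.all():
            bad = self.calls[~ok].flat[0]
            raise ValidationError(f"call value {bad!r} not in {{0, 2, missing}}")

    # ---- basic shape ----
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    # ---- derived per-variant statistics (always recomputed from calls) ----
    def dosage(self) -> np.ndarray:
        """Calls coded 0/1 (ref/alt homozygote) with nan for missing."""
        return self.calls / 2.0

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency among non-missing calls per variant."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage(), axis=1)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency among non-missing calls per variant."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missingness(self) -> np.ndarray:
        """Fraction of missing calls per variant."""
        return np.isnan(self.calls).mean(axis=1)

    def is_biallelic(self) -> np.ndarray:
        """True where ref and alt each encode a single allele."""
        ref = self.variants["ref"].astype(str)
        alt = self.variants["alt"].astype(str)
        return (~ref.str.contains(",") & ~alt.str.contains(",")).to_numpy()

    # ---- subsetting ----
    def take_variants(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given variant positions (row index)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            variants=self.variants.iloc[index].reset_index(drop=True),
            calls=self.calls[index],
        )

    def select_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        lookup = pd.Index(self.variants["variant_id"])
        idx = lookup.get_indexer(variant_ids)
        if (idx < 0).any():
            missing = [v for v, i in zip(variant_ids, idx) if i < 0]
            raise ValidationError(f"unknown variant ids: {missing[:5]}")
        return self.take_variants(idx)

    def select_lines(self, line_ids: list[str]) -> "GenotypeMatrix":
        lookup = pd.Index(self.line_ids)
        idx = lookup.get_indexer(line_ids)
        if (idx < 0).any():
            missing = [l for l, i in zip(line_ids, idx) if i < 0]
            raise ValidationError(f"lines absent from genotype matrix: {missing[:5]}")
        return GenotypeMatrix(
            line_ids=list(line_ids),
            variants=self.variants.copy(),
            calls=self.calls[:, idx],
        )

    def __eq__(self, other) -> bool:  # used by round-trip tests
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.line_ids == other.line_ids
            and self.variants.equals(other.variants)
            and np.array_equal(self.calls, other.calls, equal_nan=True)
        )


@dataclass
class PhenotypePanel:
    """Replicated counts per line with batch assignments and covariates.

    ``counts`` holds one row per individual (columns ``line_id, batch_id,
    count``); ``lines`` is indexed by line id and carries ``is_control``,
    ``survival`` and the Wolbachia/inversion covariates (nan = unknown).
    A panel may instead be constructed from pre-computed line means
    (``counts=None``), in which case operations that need replicates
    (ANOVA heritability) are unavailable.
    """

    lines: pd.DataFrame
    counts: pd.DataFrame | None = None
    means: pd.DataFrame = field(default=None)  # line_id, batch_id, mean, n
    corrected_means: pd.DataFrame | None = None  # same shape as means

    def __post_init__(self) -> None:
        if self.counts is not None:
            self.counts = self.counts.reset_index(drop=True)
            if self.means is None:
                g = self.counts.groupby(["line_id", "batch_id"], sort=True)["count"]
                self.means = (
                    g.agg(mean="mean", n="size").reset_index()
                )
        if self.means is None:
            raise ValidationError("panel needs either counts or line means")
        self.means = self.means.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        lines = self.lines
        if lines.index.duplicated().any():
            raise ValidationError("duplicate line ids in line table")
        if self.counts is not None:
            if (self.counts["count"] < 0).any():
                raise ValidationError("negative brain count")
            unknown = set(self.counts["line_id"]) - set(lines.index)
            if unknown:
                raise ValidationError(f"counts for unknown lines: {sorted(unknown)[:5]}")
        per_line_batches = self.means.groupby("line_id")["batch_id"].nunique()
        controls = set(lines.index[lines["is_control"].astype(bool)])
        multi = per_line_batches[per_line_batches > 1]
        bad = set(multi.index) - controls
        if bad:
            raise ValidationError(
                f"non-control lines measured in multiple batches: {sorted(bad)[:5]}"
            )
        if "survival" in lines:
            s = lines["survival"].dropna()
            if ((s < 0) | (s > 1)).any():
                raise ValidationError("survival outside [0, 1]")

    # ---- accessors ----
    @property
    def line_ids(self) -> list[str]:
        return list(self.lines.index)

    @property
    def batch_ids(self) -> list:
        return sorted(self.means["batch_id"].unique())

    @property
    def control_ids(self) -> list[str]:
        return list(self.lines.index[self.lines["is_control"].astype(bool)])

    def line_batch_means(self, corrected: bool = False) -> pd.DataFrame:
        if corrected:
            if self.corrected_means is None:
                raise ValidationError("panel has no batch-corrected means")
            return self.corrected_means
        return self.means

    def line_means(self, corrected: bool = False) -> pd.Series:
        """Per-line mean; multi-batch (control) lines average their
        per-batch means with equal batch weight."""
        df = self.line_batch_means(corrected)
        return df.groupby("line_id")["mean"].mean().rename("mean")

    def covariates_known(self) -> bool:
        cols = [c for c in COVARIATE_COLS if c in self.lines]
        if len(cols) != len(COVARIATE_COLS):
            return False
        return not self.lines[cols].isna().any().any()

    def covariate_matrix(self) -> pd.DataFrame:
        """Wolbachia + inversion design columns; raises if any are unknown."""
        if not self.covariates_known():
            raise ValidationError(
                "covariates unknown for some lines; cannot adjust "
                "(load a phenotype table with wolbachia/inversion columns)"
            )
        return self.lines[COVARIATE_COLS].astype(float)


def validate_gene_set(genes: pd.DataFrame) -> pd.DataFrame:
    """Check a gene-annotation frame (1-based inclusive tx bounds)."""
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValidationError(f"gene table lacks columns {missing}")
    if genes["gene_id"].duplicated().any():
        dup = genes["gene_id"][genes["gene_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate gene_id {dup!r}")
    if (genes["tx_start"] > genes["tx_end"]).any():
        bad = genes.loc[genes["tx_start"] > genes["tx_end"], "gene_id"].iloc[0]
        raise ValidationError(f"gene {bad!r} has tx_start > tx_end")
    if (genes["tx_start"] < 1).any():
        raise ValidationError("tx_start below 1 (coordinates are 1-based)")
    return genes.reset_index(drop=True)
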