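"""Readers and writers for every external format the pipeline touches.

Formats
-------
* genotype tables in the DGRP portal ("tgeno") dialect: whitespace-separated,
  header row ``chr pos id ref alt <line ...>``, calls coded ``0``
  (reference homozygote), ``2`` (alternate homozygote) and ``-`` (missing);
* phenotype tables as TSV with one row per measured brain (or one row per
  line mean), plus line-level covariates;
* gene annotations as BED (0-based half-open, converted on read) or GFF3
  (1-based inclusive, taken as is);
* association / enrichment result tables as TSV with p-values printed in
  scientific notation;
* pathway gene sets in GMT.

All coordinates are 1-based inclusive in memory.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    COVARIATE_COLS,
    GENE_COLUMNS,
    GenotypeMatrix,
    PhenotypePanel,
    validate_gene_set,
)
from .errors import FormatError, ValidationError

logger = logging.getLogger("panelgwas")

_TGENO_FIXED = ["chr", "pos", "id", "ref", "alt"]
_CALL_MAP = {"0": 0.0, "2": 2.0, "-": np.nan}
_CLASSES = {"SNP", "DEL", "INS", "MNP"}


# ---------------------------------------------------------------------------
# genotypes (tgeno dialect)
# ---------------------------------------------------------------------------

def read_tgeno(path: str | Path) -> GenotypeMatrix:
    """Parse a DGRP-dialect genotype table into a :class:`GenotypeMatrix`.

    Raises :class:`FormatError` on ragged rows (with the offending line
    number), unknown call symbols, duplicate variant ids, or ids inconsistent
    with their chrom/pos columns.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if header[: len(_TGENO_FIXED)] != _TGENO_FIXED:
            raise FormatError(
                f"{path}: header must start with {' '.join(_TGENO_FIXED)}"
            )
        line_ids = header[len(_TGENO_FIXED):]
        ncol = len(header)
        rows, calls = [], []
        for lineno, raw in enumerate(fh, start=2):
            fields = raw.split()
            if not fields:
                continue
            if len(fields) != ncol:
                raise FormatError(
                    f"{path}:{lineno}: expected {ncol} fields, got {len(fields)}"
                )
            chrom, pos, vid, ref, alt = fields[:5]
            vclass = vid.rsplit("_", 1)[-1]
            if vclass not in _CLASSES:
                raise FormatError(
                    f"{path}:{lineno}: cannot parse variant class from id {vid!r}"
                )
            if not vid.startswith(f"{chrom}_{pos}_"):
                raise FormatError(
                    f"{path}:{lineno}: id {vid!r} inconsistent with "
                    f"chrom/pos {chrom}:{pos}"
                )
            try:
                row_calls = [_CALL_MAP[c] for c in fields[5:]]
            except KeyError as exc:
                raise FormatError(
                    f"{path}:{lineno}: unknown call symbol {exc.args[0]!r}"
                ) from None
            rows.append((chrom, int(pos), vid, ref, alt, vclass))
            calls.append(row_calls)
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "variant_id", "ref", "alt", "variant_class"]
    )
    if variants["variant_id"].duplicated().any():
        dup = variants.loc[variants["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise FormatError(f"{path}: duplicate variant id {dup!r}")
    call_arr = (
        np.array(calls, dtype=float)
        if calls
        else np.empty((0, len(line_ids)))
    )
    return GenotypeMatrix(line_ids=line_ids, variants=variants, calls=call_arr)


def write_tgeno(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix in the tgeno dialect (round-trips exactly)."""
    inv = {0.0: "0", 2.0: "2"}
    with open(path, "w") as fh:
        fh.write(" ".join(_TGENO_FIXED + list(geno.line_ids)) + "\n")
        for i, v in geno.variants.iterrows():
            row = geno.calls[i]
            symbols = ["-" if np.isnan(c) else inv[c] for c in row]
            fh.write(
                f"{v.chrom} {v.pos} {v.variant_id} {v.ref} {v.alt} "
                + " ".join(symbols)
                + "\n"
            )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

_LINE_ALIASES = {"line": "line_id", "batch": "batch_id"}


def read_phenotypes(path: str | Path) -> PhenotypePanel:
    """Read a phenotype TSV into a :class:`PhenotypePanel`.

    Accepts per-brain replicate rows (``count`` column) or per-line summary
    rows (``mean`` column, optional ``n``). Covariate columns
    (``wolbachia`` + the five inversion karyotypes) are optional; when absent
    every line is marked covariate-unknown (nan) and downstream covariate
    adjustment refuses to run rather than imputing.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    df = df.rename(columns=_LINE_ALIASES)
    for col in ("line_id", "batch_id"):
        if col not in df:
            raise FormatError(f"{path}: required column {col!r} missing")
    if "is_control" not in df:
        df["is_control"] = False
    agg = {"is_control": "first", "survival": "first"}
    if "survival" not in df:
        df["survival"] = np.nan
    for col in COVARIATE_COLS:
        if col not in df:
            df[col] = np.nan
        agg[col] = "first"
    lines = df.groupby("line_id").agg(agg)
    lines["is_control"] = lines["is_control"].astype(bool)
    if "count" in df:
        if (df["count"] < 0).any():
            raise ValidationError(f"{path}: negative brain count")
        counts = df[["line_id", "batch_id", "count"]].copy()
        counts["count"] = counts["count"].astype(int)
        return PhenotypePanel(lines=lines, counts=counts)
    if "mean" in df:
        means = df[["line_id", "batch_id", "mean"]].copy()
        means["n"] = df["n"].astype(int) if "n" in df else 1
        return PhenotypePanel(lines=lines, counts=None, means=means)
    raise FormatError(f"{path}: need a 'count' or 'mean' column")


def write_phenotypes(panel: PhenotypePanel, path: str | Path) -> None:
    """Write a panel as TSV (replicate rows when available, else means)."""
    line_cols = ["is_control", "survival"] + COVARIATE_COLS
    meta = panel.lines.reindex(columns=line_cols)
    if panel.counts is not None:
        out = panel.counts.join(meta, on="line_id")
    else:
        out = panel.means.join(meta, on="line_id")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

_GFF_ATTR_ID = re.compile(r"(?:^|;)\s*(?:ID|Name|gene_id)=([^;]+)")


def read_gene_annotation(path: str | Path, format: str = "BED") -> pd.DataFrame:
    """Read gene models from BED or GFF3 into a 1-based inclusive gene table.

    BED intervals (0-based half-open) become ``(start+1, end)``; GFF3 rows of
    type ``gene`` are taken as is. Returns a frame with columns
    ``gene_id, chrom, tx_start, tx_end, strand``.
    """
    path = Path(path)
    fmt = format.upper()
    if fmt == "BED":
        names = ["chrom", "start", "end", "gene_id", "score", "strand"]
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#")
        except pd.errors.EmptyDataError:
            logger.warning("%s: empty annotation file", path)
            return pd.DataFrame(columns=GENE_COLUMNS)
        df.columns = names[: df.shape[1]]
        if "gene_id" not in df:
            df["gene_id"] = [f"interval_{i}" for i in range(len(df))]
        if "strand" not in df:
            df["strand"] = "."
        genes = pd.DataFrame(
            {
                "gene_id": df["gene_id"].astype(str),
                "chrom": df["chrom"].astype(str),
                "tx_start": df["start"].astype(int) + 1,
                "tx_end": df["end"].astype(int),
                "strand": df["strand"].astype(str),
            }
        )
    elif fmt == "GFF3":
        rows = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                if not raw.strip() or raw.startswith("#"):
                    continue
                fields = raw.rstrip("\n").split("\t")
                if len(fields) != 9:
                    raise FormatError(
                        f"{path}:{lineno}: GFF3 rows need 9 columns"
                    )
                chrom, _, ftype, start, end, _, strand, _, attrs = fields
                if ftype != "gene":
                    continue
                m = _GFF_ATTR_ID.search(attrs)
                gid = m.group(1) if m else f"gene_{lineno}"
                rows.append((gid, chrom, int(start), int(end), strand))
        if not rows:
            logger.warning("%s: no gene features found", path)
        genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    else:
        raise FormatError(f"unknown annotation format {format!r}")
    if len(genes) and (genes["tx_start"] > genes["tx_end"]).any():
        bad = genes.loc[genes["tx_start"] > genes["tx_end"]].iloc[0]
        raise FormatError(
            f"{path}: gene {bad.gene_id!r} has start > end after conversion"
        )
    return validate_gene_set(genes) if len(genes) else genes


def write_gene_annotation_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a gene table as 6-column BED (converting back to 0-based)."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["tx_start"] - 1,
            "end": genes["tx_end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_SCI_COLS = ("p_value", "fdr")


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write an association/enrichment table as TSV with a header.

    P-value-like columns are printed in scientific notation with three
    significant digits (``4.85E-07``); re-reading reproduces all values to
    printed precision. An empty table yields a header-only file.
    """
    if results is None:
        raise ValidationError("results table is None")
    out = results.copy()
    for col in _SCI_COLS:
        if col in out:
            out[col] = [
                "" if pd.isna(p) else f"{p:.2E}" for p in out[col]
            ]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# pathway gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT: one pathway per line, ``name<TAB>description<TAB>genes...``."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT rows need >= 3 fields")
            name = fields[0]
            if name in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway {name!r}")
            pathways[name] = set(g for g in fields[2:] if g)
    return pathways


def write_gmt(pathways: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in pathways:
            genes = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\tna\t{genes}\n")
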