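"""One-command orchestration of the full analysis.

Stage order mirrors the analysis narrative: correct -> h2 -> filter -> grm
-> nullfit/scan -> diagnostics -> ld -> annotate -> enrich. Stages exchange
data through files in the run directory, so any stage can be re-run from
cached upstream outputs and reproduce the full run's outputs for that stage.
All randomness is routed through the single configured seed and the run log
records versions, seed and a config hash (but no wall-clock state), so a
rerun with identical config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, association, io, normalize, postgwas
from .errors import ConfigError, PanelGwasError

logger = logging.getLogger("panelgwas")

STAGES = ["correct", "h2", "filter", "grm", "scan", "diagnostics",
          "ld", "annotate", "enrich"]


@dataclass
class PipelineConfig:
    geno: str
    pheno: str
    outdir: str
    annotation: str | None = None
    annotation_format: str | None = None  # inferred from suffix when None
    pathways: str | None = None
    control_ids: tuple[str, ...] = ()
    maf_min: float = 0.05
    miss_max: float = 0.30
    include_classes: tuple[str, ...] | None = None
    use_covariates: bool = True
    thresholds: tuple[float, ...] = (1e-4, 1e-5)
    ld_threshold: float = 0.5
    flank: int = 1000
    reference_size: int = 13767
    seed: int = 0
    stages: tuple[str, ...] = tuple(STAGES)

    def __post_init__(self) -> None:
        self.thresholds = tuple(sorted(self.thresholds, reverse=True))
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("control_ids", "include_classes", "thresholds", "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("geno", "pheno", "annotation", "pathways"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")

    def hash(self) -> str:
        # analytic configuration only: where outputs land is not part of it
        payload = {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)
                   if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _annotation_format(config: PipelineConfig) -> str:
    if config.annotation_format:
        return config.annotation_format
    suffix = Path(config.annotation).suffix.lower()
    return "GFF3" if suffix in (".gff", ".gff3") else "BED"


# ---------------------------------------------------------------------------
# stages (each reads its inputs from config paths / run dir, writes outputs)
# ---------------------------------------------------------------------------

def _stage_correct(config: PipelineConfig, out: Path) -> None:
    panel = io.read_phenotypes(config.pheno)
    controls = list(config.control_ids) or panel.control_ids
    if controls:
        res = normalize.compute_batch_residuals(panel, controls)
        panel = normalize.apply_batch_correction(panel, res)
        res_df = pd.DataFrame(
            {
                "batch_id": res.residuals.index,
                "residual": res.residuals.to_numpy(),
                "has_controls": res.has_controls.to_numpy(),
            }
        )
    else:
        logger.warning("no control lines; phenotypes used uncorrected")
        panel.corrected_means = panel.means.copy()
        res_df = pd.DataFrame(columns=["batch_id", "residual", "has_controls"])
    res_df.to_csv(out / "batch_residuals.tsv", sep="\t", index=False)
    raw = panel.line_means(corrected=False)
    corrected = panel.line_means(corrected=True)
    pd.DataFrame(
        {"line_id": raw.index, "raw_mean": raw.to_numpy(),
         "corrected_mean": corrected.reindex(raw.index).to_numpy()}
    ).to_csv(out / "corrected_phenotypes.tsv", sep="\t", index=False)


def _stage_h2(config: PipelineConfig, out: Path) -> None:
    panel = io.read_phenotypes(config.pheno)
    per_batch = normalize.heritability_by_batch(panel)
    overall = normalize.overall_heritability(per_batch)
    per_batch.to_csv(out / "heritability.tsv", sep="\t", index=False)
    (out / "heritability_overall.txt").write_text(f"{overall:.6f}\n")


def _stage_filter(config: PipelineConfig, out: Path) -> None:
    geno = io.read_tgeno(config.geno)
    spec = association.FilterSpec(
        maf_min=config.maf_min,
        miss_max=config.miss_max,
        include_classes=config.include_classes,
    )
    kept = association.filter_variants(geno, spec)
    io.write_tgeno(kept, out / "filtered.tgeno")
    (out / "filter_counts.txt").write_text(
        f"input\t{geno.n_variants}\nretained\t{kept.n_variants}\n"
    )


def _stage_grm(config: PipelineConfig, out: Path) -> None:
    geno = io.read_tgeno(out / "filtered.tgeno")
    a = association.compute_grm(geno)
    a.to_csv(out / "grm.tsv", sep="\t", float_format="%.10g")


def _null_fit(config: PipelineConfig, out: Path):
    geno = io.read_tgeno(out / "filtered.tgeno")
    panel = io.read_phenotypes(config.pheno)
    pheno = pd.read_csv(out / "corrected_phenotypes.tsv", sep="\t")
    y = pheno.set_index("line_id")["corrected_mean"]
    a = pd.read_csv(out / "grm.tsv", sep="\t", index_col=0)
    common = [l for l in geno.line_ids if l in set(y.index)]
    if not common:
        raise ConfigError("no overlap between genotyped and phenotyped lines")
    X0 = None
    if config.use_covariates and panel.covariates_known():
        X0 = panel.covariate_matrix()
    elif config.use_covariates:
        logger.warning("covariates unknown for some lines; fitting without")
    fit = association.fit_null_mixed_model(y.loc[common], X0, a)
    return fit, geno


def _stage_scan(config: PipelineConfig, out: Path) -> None:
    fit, geno = _null_fit(config, out)
    results = association.scan_snps(fit, geno)
    io.write_results(results, out / "association.tsv")
    with open(out / "null_model.json", "w") as fh:
        json.dump(
            {
                "sigma_g2": fit.sigma_g2,
                "sigma_e2": fit.sigma_e2,
                "delta": None if not np.isfinite(fit.delta) else fit.delta,
                "loglik": fit.loglik,
                "n_lines": len(fit.line_ids),
                "covariates": fit.covariate_names,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def _stage_diagnostics(config: PipelineConfig, out: Path) -> None:
    results = io.read_results(out / "association.tsv")
    lam, qq = association.genomic_inflation(results)
    (out / "diagnostics.tsv").write_text(f"lambda_gc\t{lam:.6f}\n")
    qq.to_csv(out / "qq.tsv", sep="\t", index=False, float_format="%.6g")
    manhattan = results[["chrom", "pos", "p_value"]].copy()
    manhattan["minus_log10_p"] = -np.log10(manhattan.pop("p_value"))
    manhattan.to_csv(out / "manhattan.tsv", sep="\t", index=False,
                     float_format="%.6g")


def _top_snps(config: PipelineConfig, out: Path) -> pd.DataFrame:
    results = io.read_results(out / "association.tsv")
    cutoff = min(config.thresholds)
    return results[results["p_value"] < cutoff]


def _stage_ld(config: PipelineConfig, out: Path) -> None:
    top = _top_snps(config, out)
    ids = list(top["variant_id"])
    if len(ids) < 2:
        (out / "loci.tsv").write_text("locus\tvariant_id\n" + "".join(
            f"1\t{v}\n" for v in ids))
        return
    geno = io.read_tgeno(out / "filtered.tgeno")
    r2 = postgwas.pairwise_r2(geno, ids)
    r2.to_csv(out / "ld_r2.tsv", sep="\t", float_format="%.6g")
    groups = postgwas.group_loci(r2, config.ld_threshold)
    with open(out / "loci.tsv", "w") as fh:
        fh.write("locus\tvariant_id\n")
        for k, members in enumerate(groups.groups, start=1):
            for v in members:
                fh.write(f"{k}\t{v}\n")


def _stage_annotate(config: PipelineConfig, out: Path) -> None:
    if config.annotation is None:
        logger.warning("no annotation; skipping gene assignment")
        return
    results = io.read_results(out / "association.tsv")
    genes = io.read_gene_annotation(config.annotation, _annotation_format(config))
    hits = results[results["p_value"] < max(config.thresholds)]
    mapping = postgwas.assign_snps_to_genes(
        hits[["variant_id", "chrom", "pos"]], genes, config.flank
    )
    mapping.to_csv(out / "snp_gene_map.tsv", sep="\t", index=False)
    report = postgwas.threshold_report(hits, mapping, list(config.thresholds))
    report.to_csv(out / "threshold_report.tsv", sep="\t", index=False)


def _stage_enrich(config: PipelineConfig, out: Path) -> None:
    if config.pathways is None or config.annotation is None:
        logger.warning("no pathway/annotation input; skipping enrichment")
        return
    report = pd.read_csv(out / "threshold_report.tsv", sep="\t")
    row = report.iloc[0]  # most permissive threshold nominates the gene list
    genes = [] if pd.isna(row["genes"]) or not row["genes"] else row["genes"].split(",")
    pathways = io.read_gmt(config.pathways)
    enr = postgwas.pathway_enrichment(genes, pathways, config.reference_size)
    io.write_results(enr, out / "enrichment.tsv")


_STAGE_FUNCS = {
    "correct": _stage_correct,
    "h2": _stage_h2,
    "filter": _stage_filter,
    "grm": _stage_grm,
    "scan": _stage_scan,
    "diagnostics": _stage_diagnostics,
    "ld": _stage_ld,
    "annotate": _stage_annotate,
    "enrich": _stage_enrich,
}


def run_full_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages in order; returns the run directory.

    A stage failure aborts the run, leaves earlier outputs in place and
    writes a ``FAILED`` marker naming the stage and the error.
    """
    config.validate_paths()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, out)
        except Exception as exc:
            failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
            raise PanelGwasError(f"stage {stage!r} failed: {exc}") from exc
    _write_log(config, out)
    return out


def _write_log(config: PipelineConfig, out: Path) -> None:
    import scipy

    lines = [
        f"panelgwas\t{__version__}",
        f"numpy\t{np.__version__}",
        f"scipy\t{scipy.__version__}",
        f"pandas\t{pd.__version__}",
        f"seed\t{config.seed}",
        f"config_hash\t{config.hash()}",
        f"stages\t{','.join(s for s in STAGES if s in config.stages)}",
    ]
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
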