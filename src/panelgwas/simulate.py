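"""Synthetic inbred-line panels with the statistical structure the analysis
assumes.

The generator emulates a DGRP-style study: ~186 fully homozygous lines typed
at biallelic markers with block LD and sporadic missing calls, phenotyped as
integer neuron counts (sum of three dopaminergic clusters) replicated over
7-36 brains per line, measured in 15 experimental batches of 8-14 lines with
two internal control lines repeated in 11 of the batches. Genetic and
residual variances are chosen so that between-line / total variance hits a
configurable broad-sense heritability target (0.85 by default).

Counts are produced as rounded, zero-truncated Gaussians
``round(mean + genetic + batch + residual)`` rather than per-neuron survival
draws: the downstream estimators treat the total count as an additive
quantitative trait, and this keeps the variance components exact by
construction. LD is produced by block-seed copying: each variant in a block
copies the block's seed variant with probability ``ld_copy_prob`` per line
and otherwise draws an independent Bernoulli call, which gives tunable
within-block r-squared without coalescent machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import COVARIATE_COLS, GENE_COLUMNS, GenotypeMatrix, PhenotypePanel
from .errors import ConfigError

CHROMS = ["2L", "2R", "3L", "3R", "X"]

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_annotation",
    "simulate_pathways",
]


@dataclass
class SimConfig:
    """All knobs of the synthetic panel.

    ``maf_law`` is ``("uniform", lo, hi)`` or ``("point", value)`` over
    (0, 0.5]. ``target_H2`` is the between-line fraction of per-brain
    phenotypic variance; ``residual_sd`` (neurons) sets the within-line
    spread and, together with ``target_H2``, the genetic variance.
    Explicit ``causal_variant_ids``/``causal_effects`` plant deterministic
    causal variants (effects in neurons per alternate allele); otherwise
    ``n_causal`` variants get Normal(0, ``causal_effect_sd``) effects and a
    polygenic term tops genetic variance up to the target.
    """

    n_lines: int = 186
    n_variants: int = 5000
    maf_law: tuple = ("uniform", 0.05, 0.5)
    ld_block_len: int = 10
    ld_copy_prob: float = 0.7
    missing_prob: float = 0.02
    n_batches: int = 15
    lines_per_batch: tuple[int, int] = (8, 14)
    control_line_ids: tuple[str, ...] | None = None
    control_batch_coverage: int = 11
    brains_per_line: tuple[int, int] = (7, 36)
    mean_count: float = 26.0
    target_H2: float = 0.85
    n_causal: int = 10
    causal_effect_sd: float = 1.0
    causal_variant_ids: tuple[str, ...] | None = None
    causal_effects: tuple[float, ...] | None = None
    residual_sd: float = 2.0
    batch_effect_sd: float = 1.5
    wolbachia_prob: float = 0.53
    inversion_probs: tuple[float, ...] = (0.15, 0.10, 0.10, 0.10, 0.05)
    survival_beta: tuple[float, float] = (4.5, 0.1875)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ld_copy_prob", "missing_prob", "wolbachia_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.inversion_probs):
            raise ConfigError("inversion_probs must lie in [0, 1]")
        if len(self.inversion_probs) != len(COVARIATE_COLS) - 1:
            raise ConfigError(
                f"need {len(COVARIATE_COLS) - 1} inversion probabilities"
            )
        if not 0.0 <= self.target_H2 < 1.0:
            raise ConfigError(f"target_H2={self.target_H2} outside [0, 1)")
        for name in ("lines_per_batch", "brains_per_line"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigError(f"{name}=({lo}, {hi}) is not a valid range")
        if self.maf_law[0] == "uniform":
            _, lo, hi = self.maf_law
            if not 0.0 < lo <= hi <= 0.5:
                raise ConfigError(f"maf_law bounds ({lo}, {hi}) outside (0, 0.5]")
        elif self.maf_law[0] == "point":
            if not 0.0 < self.maf_law[1] <= 0.5:
                raise ConfigError("point MAF outside (0, 0.5]")
        else:
            raise ConfigError(f"unknown maf_law {self.maf_law[0]!r}")
        if self.control_line_ids is not None:
            ids = list(self.control_line_ids)
            if len(set(ids)) != len(ids):
                raise ConfigError("control_line_ids are not distinct")
        if self.residual_sd < 0 or self.batch_effect_sd < 0:
            raise ConfigError("standard deviations must be non-negative")


@dataclass
class SimTruth:
    """Latent ground truth recorded for parameter-recovery tests."""

    causal_variant_ids: list[str]
    causal_effects: np.ndarray
    line_genetic_values: pd.Series
    batch_offsets: pd.Series
    realized_H2: float


def _draw_maf(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    if law[0] == "uniform":
        return rng.uniform(law[1], law[2], size)
    return np.full(size, float(law[1]))


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Generate homozygous biallelic calls with block LD and missingness.

    Variants are laid out in blocks of ``ld_block_len`` consecutive markers;
    the first variant of a block is the seed, and every other member copies
    the seed call per line with probability ``ld_copy_prob`` (independent
    Bernoulli(maf) otherwise). Deterministic for a fixed config/seed.
    """
    if config.n_lines < 2:
        raise ConfigError("need at least 2 lines")
    if config.n_variants < 1:
        raise ConfigError("need at least 1 variant")
    rng = np.random.default_rng(config.seed)
    n, m = config.n_lines, config.n_variants
    mafs = _draw_maf(rng, config.maf_law, m)
    dosage = np.empty((m, n), dtype=float)
    block_len = max(1, config.ld_block_len)
    for start in range(0, m, block_len):
        stop = min(start + block_len, m)
        seed_calls = (rng.random(n) < mafs[start]).astype(float)
        dosage[start] = seed_calls
        for j in range(start + 1, stop):
            own = (rng.random(n) < mafs[j]).astype(float)
            copy = rng.random(n) < config.ld_copy_prob
            dosage[j] = np.where(copy, seed_calls, own)
    calls = dosage * 2.0
    if config.missing_prob > 0:
        calls[rng.random((m, n)) < config.missing_prob] = np.nan

    # variant metadata: blocks assigned round-robin to chromosome arms,
    # positions strictly increasing within each arm
    alleles = np.array(list("ACGT"))
    chrom_of_block = [
        CHROMS[b % len(CHROMS)] for b in range((m + block_len - 1) // block_len)
    ]
    pos_state = {c: 0 for c in CHROMS}
    chroms, positions = [], []
    for j in range(m):
        c = chrom_of_block[j // block_len]
        pos_state[c] += int(rng.integers(100, 1000))
        chroms.append(c)
        positions.append(pos_state[c])
    ref_idx = rng.integers(0, 4, m)
    alt_idx = (ref_idx + rng.integers(1, 4, m)) % 4
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "variant_id": [f"{c}_{p}_SNP" for c, p in zip(chroms, positions)],
            "ref": alleles[ref_idx],
            "alt": alleles[alt_idx],
            "variant_class": "SNP",
        }
    )
    line_ids = [f"RAL-{100 + i}" for i in range(n)]
    return GenotypeMatrix(line_ids=line_ids, variants=variants, calls=calls)


def _batch_design(
    line_ids: list[str],
    controls: list[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Assign test lines to one batch each; controls to the configured
    number of batches (skipping a contiguous run, like batches 2-5 of the
    emulated design)."""
    test_lines = [l for l in line_ids if l not in controls]
    order = list(rng.permutation(test_lines))
    b = config.n_batches
    sizes = [len(order) // b + (1 if i < len(order) % b else 0) for i in range(b)]
    lo, hi = config.lines_per_batch
    if any(s < lo or s > hi for s in sizes):
        raise ConfigError(
            f"{len(order)} test lines cannot be split into {b} batches of "
            f"{lo}-{hi} lines"
        )
    if config.control_batch_coverage > b:
        raise ConfigError("control_batch_coverage exceeds n_batches")
    batches: dict[str, list[str]] = {}
    without_controls = set(range(1, 1 + b - config.control_batch_coverage))
    start = 0
    for i, size in enumerate(sizes):
        name = f"batch{i + 1:02d}"
        members = order[start : start + size]
        start += size
        if controls and i not in without_controls:
            members = list(controls) + members
        batches[name] = members
    return batches


def simulate_phenotypes(
    geno: GenotypeMatrix,
    config: SimConfig,
    phenotype_seed: int | None = None,
) -> tuple[PhenotypePanel, SimTruth]:
    """Draw replicated per-brain counts for every line of ``geno``.

    Genetic line values are the causal-variant contribution plus an
    independent polygenic top-up scaled so the between-line variance equals
    ``target_H2 / (1 - target_H2) * residual_sd**2``; if the causal variance
    alone exceeds that target it is left untouched (so planted large effects
    keep their stated size) and the realized heritability is recorded in the
    returned :class:`SimTruth`.
    """
    seed = config.seed + 1 if phenotype_seed is None else phenotype_seed
    rng = np.random.default_rng(seed)
    line_ids = list(geno.line_ids)
    if config.control_line_ids is not None:
        controls = list(config.control_line_ids)
        absent = set(controls) - set(line_ids)
        if absent:
            raise ConfigError(f"control lines not in panel: {sorted(absent)}")
    else:
        controls = line_ids[:2]
    if config.target_H2 >= 1.0:
        raise ConfigError("target_H2 = 1 requires the explicit zero-noise case")

    # causal architecture
    dosage = geno.dosage()
    p = np.nan_to_num(geno.alt_freq(), nan=0.0)
    dosage = np.where(np.isnan(dosage), p[:, None], dosage)  # latent truth
    if config.causal_variant_ids is not None:
        causal_ids = list(config.causal_variant_ids)
        idx = pd.Index(geno.variants["variant_id"]).get_indexer(causal_ids)
        if (idx < 0).any():
            raise ConfigError("causal_variant_ids not present in genotypes")
        if config.causal_effects is None:
            effects = rng.normal(0.0, config.causal_effect_sd, len(idx))
        else:
            effects = np.asarray(config.causal_effects, dtype=float)
            if len(effects) != len(idx):
                raise ConfigError("causal_effects length mismatch")
    else:
        common = np.flatnonzero(geno.maf() >= 0.1)
        k = min(config.n_causal, len(common))
        idx = rng.choice(common, size=k, replace=False) if k else np.array([], int)
        causal_ids = list(geno.variants["variant_id"].iloc[idx])
        effects = rng.normal(0.0, config.causal_effect_sd, len(idx))

    g_causal = effects @ dosage[idx] if len(idx) else np.zeros(len(line_ids))
    sigma_e = config.residual_sd
    if sigma_e > 0:
        var_target = config.target_H2 / (1.0 - config.target_H2) * sigma_e**2
    else:
        var_target = float(np.var(g_causal))
    var_causal = float(np.var(g_causal))
    if (
        config.causal_effects is None
        and var_causal > var_target > 0
    ):
        # drawn (non-planted) effects are rescaled so the causal variance
        # never exceeds the target genetic share
        shrink = np.sqrt(var_target / var_causal)
        effects = effects * shrink
        g_causal = g_causal * shrink
        var_causal = float(np.var(g_causal))
    topup_var = max(0.0, var_target - var_causal)
    g = g_causal + rng.normal(0.0, np.sqrt(topup_var), len(line_ids))
    g = g - g.mean()
    var_g = float(np.var(g))
    realized = var_g / (var_g + sigma_e**2) if (var_g + sigma_e**2) > 0 else 0.0

    batches = _batch_design(line_ids, controls, config, rng)
    offsets = {b: rng.normal(0.0, config.batch_effect_sd) for b in batches}
    g_of = dict(zip(line_ids, g))

    lo, hi = config.brains_per_line
    rows = []
    for batch, members in batches.items():
        for line in members:
            n_brains = int(rng.integers(lo, hi + 1))
            raw = (
                config.mean_count
                + g_of[line]
                + offsets[batch]
                + rng.normal(0.0, sigma_e, n_brains)
            )
            counts = np.maximum(0, np.round(raw)).astype(int)
            rows.extend((line, batch, c) for c in counts)
    counts_df = pd.DataFrame(rows, columns=["line_id", "batch_id", "count"])

    a, b_ = config.survival_beta
    lines = pd.DataFrame(index=pd.Index(line_ids, name="line_id"))
    lines["is_control"] = [l in controls for l in line_ids]
    lines["survival"] = rng.beta(a, b_, len(line_ids))
    lines["wolbachia"] = (rng.random(len(line_ids)) < config.wolbachia_prob).astype(float)
    for col, prob in zip(COVARIATE_COLS[1:], config.inversion_probs):
        lines[col] = (rng.random(len(line_ids)) < prob).astype(float)

    panel = PhenotypePanel(lines=lines, counts=counts_df)
    truth = SimTruth(
        causal_variant_ids=causal_ids,
        causal_effects=np.asarray(effects, dtype=float),
        line_genetic_values=pd.Series(g, index=line_ids, name="genetic_value"),
        batch_offsets=pd.Series(offsets, name="batch_offset"),
        realized_H2=realized,
    )
    return panel, truth


def simulate_annotation(
    n_genes: int,
    chrom_lengths: dict[str, int],
    seed: int,
    n_overlapping_pairs: int = 0,
) -> pd.DataFrame:
    """Toy gene models: non-degenerate 1-based inclusive intervals.

    ``n_overlapping_pairs`` of the genes are deliberately placed so each pair
    overlaps (for testing multi-gene SNP assignment).
    """
    if n_genes < 0:
        raise ConfigError("n_genes must be >= 0")
    if n_genes == 0:
        return pd.DataFrame(columns=GENE_COLUMNS)
    min_len, max_len = 500, 5000
    usable = {c: L for c, L in chrom_lengths.items() if L >= min_len + 1}
    if not usable:
        raise ConfigError("all chromosomes too short for requested genes")
    rng = np.random.default_rng(seed)
    chrom_names = sorted(usable)
    weights = np.array([usable[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    rows = []
    gid = 0
    while gid < n_genes:
        c = rng.choice(chrom_names, p=weights)
        length = int(rng.integers(min_len, min(max_len, usable[c] - 1) + 1))
        start = int(rng.integers(1, usable[c] - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"CG{9000 + gid}", c, start, start + length - 1, strand))
        gid += 1
        if n_overlapping_pairs > 0 and gid < n_genes:
            # partner overlapping the second half of the previous gene
            o_start = start + length // 2
            o_len = int(rng.integers(min_len, max_len + 1))
            o_end = min(o_start + o_len - 1, usable[c])
            rows.append((f"CG{9000 + gid}", c, o_start, o_end, strand))
            gid += 1
            n_overlapping_pairs -= 1
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def simulate_pathways(
    genes: pd.DataFrame,
    n_pathways: int,
    size_range: tuple[int, int],
    seed: int,
) -> dict[str, set[str]]:
    """Random flat pathway gene sets drawn from an annotation (plumbing for
    end-to-end demos; real analyses supply curated GMT files)."""
    rng = np.random.default_rng(seed)
    ids = list(genes["gene_id"])
    lo, hi = size_range
    if not ids or lo < 1 or hi < lo:
        raise ConfigError("invalid pathway size range or empty gene set")
    out = {}
    for i in range(n_pathways):
        k = int(rng.integers(lo, min(hi, len(ids)) + 1))
        members = rng.choice(ids, size=k, replace=False)
        out[f"PW{i:04d}"] = set(members)
    return out


def with_planted_causal(
    config: SimConfig, variant_id: str, effect_sd_units: float = 2.0
) -> SimConfig:
    """Config variant planting one causal SNP with an effect expressed in
    per-brain phenotype SD units (SD = residual_sd / sqrt(1 - target_H2))."""
    sd_pheno = config.residual_sd / np.sqrt(1.0 - config.target_H2)
    return replace(
        config,
        causal_variant_ids=(variant_id,),
        causal_effects=(effect_sd_units * sd_pheno,),
    )
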