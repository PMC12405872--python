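"""Control-line batch correction and ANOVA broad-sense heritability.

Batch effects are removed with internal control strains measured in most
batches: the residual of a batch is the combined control mean in that batch
minus the combined control mean over all control-bearing batches, and every
count in the batch is mean-centered by that residual. Batches without
controls are left uncorrected (residual 0).

Broad-sense heritability is estimated from replicated per-individual counts
by one-way random-effects ANOVA moments: H2 = sigma_L2 / (sigma_L2 +
sigma_E2) with the between-line component from the unbalanced-design
coefficient n0 = (N - sum n_i^2 / N) / (k - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .containers import PhenotypePanel
from .errors import ConfigError, EstimationError
from dataclasses import field

logger = logging.getLogger("panelgwas")


@dataclass
class BatchResiduals:
    """Per-batch control-line residuals (neurons); 0 for control-free batches."""

    residuals: pd.Series  # indexed by batch_id
    has_controls: pd.Series  # bool, same index
    control_ids: list[str] = field(default_factory=list)


@dataclass
class VarianceComponents:
    """One-way random-effects variance components for replicated counts."""

    sigma_L2: float
    sigma_E2: float
    H2: float
    n_lines: int
    n0: float


def compute_batch_residuals(
    panel: PhenotypePanel,
    control_ids: list[str],
    pooled: bool = False,
) -> BatchResiduals:
    """Control-line batch residuals.

    The combined control mean of a batch is, by default, the unweighted mean
    of the per-control-line batch means (robust to unequal brain numbers);
    with ``pooled=True`` all control brains in the batch are pooled instead.
    The overall reference is the unweighted mean of the per-batch combined
    means over control-bearing batches, so those residuals sum to zero.
    """
    present = set(panel.means["line_id"])
    absent = [c for c in control_ids if c not in present]
    if absent:
        raise ConfigError(f"control lines absent from panel: {absent}")
    per_batch_n = panel.means.set_index("line_id").loc[list(control_ids)]
    counts_by_ctrl = per_batch_n.groupby(level=0)["batch_id"].nunique()
    thin = counts_by_ctrl[counts_by_ctrl < 2]
    if len(thin):
        raise ConfigError(
            f"control lines measured in fewer than 2 batches: {list(thin.index)}"
        )

    ctrl = panel.means[panel.means["line_id"].isin(control_ids)]
    if pooled:
        if panel.counts is None:
            raise ConfigError("pooled combined means need replicate counts")
        craw = panel.counts[panel.counts["line_id"].isin(control_ids)]
        combined = craw.groupby("batch_id")["count"].mean()
    else:
        combined = ctrl.groupby("batch_id")["mean"].mean()
    overall = combined.mean()

    batch_ids = panel.batch_ids
    residuals = pd.Series(0.0, index=pd.Index(batch_ids, name="batch_id"))
    has = pd.Series(False, index=residuals.index)
    residuals.loc[combined.index] = combined - overall
    has.loc[combined.index] = True
    missing = [b for b in batch_ids if b not in combined.index]
    if missing:
        logger.warning(
            "batches without control lines left uncorrected: %s", missing
        )
    return BatchResiduals(residuals=residuals, has_controls=has,
                          control_ids=list(control_ids))


def apply_batch_correction(
    panel: PhenotypePanel, residuals: BatchResiduals
) -> PhenotypePanel:
    """Mean-center each batch by its control residual.

    Returns a new panel whose ``corrected_means`` hold
    ``per-batch line mean - r_b``; raw means are preserved. Within-batch
    line contrasts are untouched (a per-batch constant shift).
    """
    missing = set(panel.batch_ids) - set(residuals.residuals.index)
    if missing:
        raise ConfigError(f"no residual for batches: {sorted(missing)}")
    corrected = panel.means.copy()
    corrected["mean"] = corrected["mean"] - residuals.residuals.loc[
        corrected["batch_id"]
    ].to_numpy()
    out = PhenotypePanel(
        lines=panel.lines.copy(),
        counts=None if panel.counts is None else panel.counts.copy(),
        means=panel.means.copy(),
    )
    out.corrected_means = corrected
    return out


def anova_variance_components(counts_by_line: dict[str, np.ndarray]) -> VarianceComponents:
    """Method-of-moments one-way random-effects components.

    ``counts_by_line`` maps line id -> replicate counts. Negative
    between-line estimates are truncated at 0; H2 is reported as 0 when both
    components vanish.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in counts_by_line.items()}
    groups = {k: v for k, v in groups.items() if v.size > 0}
    k = len(groups)
    if k < 2:
        raise EstimationError("need at least 2 lines with counts")
    sizes = np.array([v.size for v in groups.values()], dtype=float)
    N = sizes.sum()
    if N - k < 1:
        raise EstimationError(
            "all lines have a single count; within-line variance undefined"
        )
    grand = np.concatenate(list(groups.values())).mean()
    means = np.array([v.mean() for v in groups.values()])
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(np.sum((v - v.mean()) ** 2) for v in groups.values()))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - np.sum(sizes**2) / N) / (k - 1)
    sigma_L2 = max(0.0, (ms_between - ms_within) / n0)
    sigma_E2 = ms_within
    total = sigma_L2 + sigma_E2
    H2 = sigma_L2 / total if total > 0 else 0.0
    return VarianceComponents(
        sigma_L2=sigma_L2, sigma_E2=sigma_E2, H2=H2, n_lines=k, n0=float(n0)
    )


def heritability_by_batch(
    panel: PhenotypePanel, include_controls: bool = True
) -> pd.DataFrame:
    """Per-batch variance components from raw (uncorrected) counts.

    Returns one row per batch with sigma_L2, sigma_E2, H2, n_lines, n0.
    Control lines measured in a batch are part of that batch's ANOVA unless
    ``include_controls`` is False.
    """
    if panel.counts is None:
        raise EstimationError("heritability needs replicate counts")
    counts = panel.counts
    if not include_controls:
        counts = counts[~counts["line_id"].isin(panel.control_ids)]
    rows = []
    for batch, sub in counts.groupby("batch_id"):
        by_line = {l: g["count"].to_numpy() for l, g in sub.groupby("line_id")}
        vc = anova_variance_components(by_line)
        rows.append((batch, vc.sigma_L2, vc.sigma_E2, vc.H2, vc.n_lines, vc.n0))
    return pd.DataFrame(
        rows, columns=["batch_id", "sigma_L2", "sigma_E2", "H2", "n_lines", "n0"]
    )


def overall_heritability(per_batch: list[VarianceComponents] | pd.DataFrame) -> float:
    """Unweighted mean of per-batch H2 estimates."""
    if isinstance(per_batch, pd.DataFrame):
        values = per_batch["H2"].to_numpy(dtype=float)
    else:
        values = np.array([vc.H2 for vc in per_batch], dtype=float)
    if values.size == 0:
        raise EstimationError("no batch estimates")
    return float(values.mean())
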