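"""Organelle gene-set expression scoring.

The score of an organelle list in a sample is the mean, over the list's
genes, of that gene's expression normalized to the average of the control
samples (control mean = 1 by construction).  Group comparison uses the
Welch (unequal-variance) t-test on the per-sample set scores, followed by a
Bonferroni correction whose default multiplier is the number of genes in the
list.  Changes are reported as signed percent deviation from control: a
set whose condition scores are uniformly 0.75x control reads as -25%.

Arithmetic is performed on intensity (linear) scale; log2 input is unlogged
first so "average expression" means average intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genelists import GeneList
from .stats import bonferroni, welch_t_test

__all__ = [
    "ExpressionMatrix",
    "OrganelleScoreResult",
    "control_normalize",
    "organelle_score",
    "per_gene_significant_fraction",
    "adjust_scores",
    "percent_change",
]

_SCALES = ("linear", "log2", "ratio")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized intensities with group labels.

    `scale` is one of 'linear' (intensities), 'log2' (log2 intensities, the
    usual RMA output) or 'ratio' (control-normalized, produced by
    :func:`control_normalize`).
    """

    values: pd.DataFrame
    sample_groups: Mapping[str, str]
    scale: str = "log2"

    def __post_init__(self):
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        self.sample_groups = dict(self.sample_groups)
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if self.values.index.has_duplicates:
            raise ValueError("gene IDs are not unique")
        self.values.index = self.values.index.astype(str).str.upper()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_groups[s], None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        out = [s for s in self.values.columns if self.sample_groups[s] == group]
        if not out:
            raise ValueError(f"no samples in group {group!r}")
        return out

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        if self.scale == "log2":
            return ExpressionMatrix(
                values=np.exp2(self.values), sample_groups=self.sample_groups, scale="linear"
            )
        raise ValueError("ratio-scale matrix cannot be converted back to intensities")


@dataclass
class OrganelleScoreResult:
    organelle: str
    per_sample_score: Mapping[str, float]
    group_mean_change: float
    p_raw: float
    n_genes: int
    control_group: str
    condition_group: str
    p_adjusted: float | None = None


def control_normalize(matrix: ExpressionMatrix, control_group: str) -> ExpressionMatrix:
    """Divide every gene by the mean of its control-sample intensities.

    Requires >= 2 control samples.  After normalization the mean of each
    gene over the control samples is exactly 1.
    """
    controls = matrix.samples_in_group(control_group)
    if len(controls) < 2:
        raise ValueError(f"control group {control_group!r} has fewer than 2 samples")
    linear = matrix.to_linear()
    ctrl_mean = linear.values[controls].mean(axis=1)
    zero = ctrl_mean[ctrl_mean == 0]
    if len(zero):
        raise ValueError(f"control mean is zero for gene(s): {list(zero.index[:5])}")
    ratios = linear.values.div(ctrl_mean, axis=0)
    return ExpressionMatrix(values=ratios, sample_groups=matrix.sample_groups, scale="ratio")


def organelle_score(
    matrix: ExpressionMatrix,
    gene_list: GeneList,
    control_group: str,
    condition_group: str,
) -> OrganelleScoreResult:
    """Score one organelle list on a control-normalized (ratio) matrix.

    per-sample score = mean ratio over the list's genes; the group change is
    mean(condition scores)/mean(control scores) - 1, and p_raw is the Welch
    t-test comparing the per-sample scores between the two groups.
    """
    if matrix.scale != "ratio":
        raise ValueError("organelle_score expects a control-normalized (ratio) matrix")
    genes = [g for g in matrix.gene_ids if g in gene_list.members]
    if len(genes) < 2:
        raise ValueError(
            f"gene list {gene_list.name!r} has {len(genes)} measured genes; need >= 2"
        )
    ctrl = matrix.samples_in_group(control_group)
    cond = matrix.samples_in_group(condition_group)
    if len(ctrl) < 2 or len(cond) < 2:
        raise ValueError("each compared group needs >= 2 samples")
    scores = matrix.values.loc[genes].mean(axis=0)
    ctrl_scores = scores[ctrl].to_numpy()
    cond_scores = scores[cond].to_numpy()
    change = float(cond_scores.mean() / ctrl_scores.mean() - 1.0)
    _, _, p = welch_t_test(cond_scores, ctrl_scores)
    p = 1.0 if np.isnan(p) else float(p)
    return OrganelleScoreResult(
        organelle=gene_list.name,
        per_sample_score=dict(zip(scores.index, scores.to_numpy(dtype=float))),
        group_mean_change=change,
        p_raw=p,
        n_genes=len(genes),
        control_group=control_group,
        condition_group=condition_group,
    )


def per_gene_significant_fraction(
    matrix: ExpressionMatrix,
    gene_list: GeneList,
    control_group: str,
    condition_group: str,
    alpha: float = 0.05,
) -> float:
    """Alternate set statistic: fraction of list genes individually
    significant by Welch test after Bonferroni over the list's genes.

    Exposed because the set-level protocol admits two readings (test on the
    per-sample set averages, or per-gene tests corrected over the hundreds
    of genes in the list); the per-sample mode is the primary one.
    """
    if matrix.scale != "ratio":
        raise ValueError("expects a control-normalized (ratio) matrix")
    genes = [g for g in matrix.gene_ids if g in gene_list.members]
    if not genes:
        raise ValueError("no list genes measured")
    ctrl = matrix.samples_in_group(control_group)
    cond = matrix.samples_in_group(condition_group)
    sub = matrix.values.loc[genes]
    _, _, p = welch_t_test(sub[cond].to_numpy(), sub[ctrl].to_numpy(), axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    p_adj = np.minimum(1.0, p * len(genes))
    return float(np.mean(p_adj < alpha))


def adjust_scores(
    results: Sequence[OrganelleScoreResult],
    mode: str = "per_gene_bonferroni",
) -> list[OrganelleScoreResult]:
    """Attach Bonferroni-adjusted p-values.

    'per_gene_bonferroni' (default): multiplier is the list's own gene count
    — the correction the set statistic motivates by the lists having
    hundreds of genes.  'per_list_bonferroni': multiplier is the number of
    lists tested together.
    """
    if mode == "per_gene_bonferroni":
        return [replace(r, p_adjusted=bonferroni(r.p_raw, r.n_genes)) for r in results]
    if mode == "per_list_bonferroni":
        m = len(results)
        return [replace(r, p_adjusted=bonferroni(r.p_raw, m)) for r in results]
    raise ValueError(f"unknown adjustment mode {mode!r}")


def percent_change(result: OrganelleScoreResult) -> float:
    """Signed percent change from control (+20% increase -> 20.0)."""
    return result.group_mean_change * 100.0
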