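"""Per-gene differential expression and the transcriptional signature.

The signature is the set of transcripts passing a per-gene test at raw
p < 0.05 (no multiple-testing correction — that is the protocol being
reproduced, deliberately not "fixed" here).  Two groups are compared with
the Welch t-test; three or more with one-way ANOVA.  Fold changes are
computed on intensity scale as condition mean over control mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .expression import ExpressionMatrix
from .genelists import GeneList
from .stats import welch_t_test

__all__ = ["SignatureTable", "per_gene_tests", "organelle_fraction", "fraction_ratio"]


@dataclass
class SignatureTable:
    """Per-gene table: fold_change (condition/control ratio), p_value,
    in_signature flag, zero_variance flag."""

    table: pd.DataFrame
    alpha: float
    control_group: str
    condition_groups: tuple[str, ...]

    def __post_init__(self):
        required = {"fold_change", "p_value", "in_signature", "zero_variance"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"signature table missing columns: {sorted(missing)}")

    @property
    def genes(self) -> set[str]:
        """Genes in the signature (passing the filter)."""
        return set(self.table.index[self.table["in_signature"]])

    def fold_changes(self) -> dict[str, float]:
        sig = self.table[self.table["in_signature"]]
        return dict(zip(sig.index, sig["fold_change"].to_numpy(dtype=float)))

    def __len__(self) -> int:
        return len(self.genes)


def per_gene_tests(
    matrix: ExpressionMatrix,
    control_group: str,
    condition_groups: str | list[str],
    alpha: float = 0.05,
) -> SignatureTable:
    """Test every gene for differential expression versus the control group.

    One condition group -> Welch t-test; several -> one-way ANOVA across all
    groups (control included).  Genes with zero variance in every group get
    p = 1 and a zero_variance flag rather than an exception.
    """
    if isinstance(condition_groups, str):
        condition_groups = [condition_groups]
    if not condition_groups:
        raise ValueError("need at least one condition group")
    linear = matrix.to_linear() if matrix.scale != "ratio" else matrix
    groups = [control_group, *condition_groups]
    cols = {g: linear.samples_in_group(g) for g in groups}
    for g, samples in cols.items():
        if len(samples) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    arrays = {g: linear.values[s].to_numpy(dtype=float) for g, s in cols.items()}
    ctrl = arrays[control_group]
    cond_all = np.hstack([arrays[g] for g in condition_groups])

    zero_var = np.all(
        [a.var(axis=1, ddof=1) == 0 for a in arrays.values()], axis=0
    )
    if len(condition_groups) == 1:
        _, _, p = welch_t_test(arrays[condition_groups[0]], ctrl, axis=1)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = sps.f_oneway(*arrays.values(), axis=1)
    p = np.asarray(p, dtype=float)
    p = np.where(np.isnan(p) | zero_var, 1.0, p)

    ctrl_mean = ctrl.mean(axis=1)
    if np.any(ctrl_mean == 0):
        raise ValueError("control mean is zero for at least one gene")
    fold = cond_all.mean(axis=1) / ctrl_mean

    table = pd.DataFrame(
        {
            "fold_change": fold,
            "p_value": p,
            "in_signature": p < alpha,
            "zero_variance": zero_var,
        },
        index=linear.values.index,
    )
    return SignatureTable(
        table=table,
        alpha=alpha,
        control_group=control_group,
        condition_groups=tuple(condition_groups),
    )


def organelle_fraction(signature: SignatureTable, gene_list: GeneList) -> float:
    """Proportion of the signature's genes belonging to the organelle list."""
    sig = signature.genes
    if not sig:
        raise ValueError("signature is empty")
    return len(sig & gene_list.members) / len(sig)


def fraction_ratio(
    later: SignatureTable, earlier: SignatureTable, gene_list: GeneList
) -> float:
    """Fold change of the organelle fraction between two signatures
    (e.g. symptomatic over pre-symptomatic)."""
    f_early = organelle_fraction(earlier, gene_list)
    if f_early == 0:
        raise ValueError("organelle fraction of the earlier signature is zero")
    return organelle_fraction(later, gene_list) / f_early
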