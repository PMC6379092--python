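"""Upstream-regulator over-representation on a differential signature.

For each TF in a signed TF -> target network, a one-sided Fisher exact test
asks whether the TF's known targets are over-represented among the
signature genes, with the universe restricted to the genes measured on the
platform (the signature's own sampling frame).  TFs pass at p < 0.01.

An optional activation z-score summarises directional consistency between
edge signs and observed target fold changes:

    z = sum_i sign(edge_i) * sign(log FC_i) / sqrt(N)

over the N signed edges whose targets are in the signature.  Sign
convention: an engaged repressor (negative edges, targets down) scores
positive z — its regulatory program agrees with the data.  z is undefined
(None) below 3 usable edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .signature import SignatureTable
from .stats import fisher_exact_greater

__all__ = [
    "RegulatorNetwork",
    "RegulatorActivityResult",
    "regulator_overlap",
    "activation_score",
]

MIN_SIGNED_EDGES = 3


@dataclass(frozen=True)
class RegulatorEdge:
    tf: str
    target: str
    sign: int  # +1 activating, -1 repressing, 0 unknown

    def __post_init__(self):
        if self.sign not in (-1, 0, 1):
            raise ValueError(f"edge sign must be -1, 0 or +1, got {self.sign}")


class RegulatorNetwork:
    """Signed TF -> target edges with no duplicate (TF, target) pairs."""

    def __init__(self, edges: Iterable[tuple[str, str, int] | RegulatorEdge]):
        self._by_tf: dict[str, dict[str, int]] = {}
        n = 0
        for e in edges:
            if not isinstance(e, RegulatorEdge):
                e = RegulatorEdge(*e)
            tf = e.tf.strip().upper()
            target = e.target.strip().upper()
            targets = self._by_tf.setdefault(tf, {})
            if target in targets:
                raise ValueError(f"duplicate edge ({tf}, {target})")
            targets[target] = e.sign
            n += 1
        if n == 0:
            raise ValueError("regulator network has no edges")

    @property
    def tfs(self) -> list[str]:
        return sorted(self._by_tf)

    def targets_of(self, tf: str) -> dict[str, int]:
        return dict(self._by_tf[tf.strip().upper()])

    def edges(self) -> list[RegulatorEdge]:
        return [
            RegulatorEdge(tf, target, sign)
            for tf in sorted(self._by_tf)
            for target, sign in sorted(self._by_tf[tf].items())
        ]

    def __len__(self) -> int:
        return sum(len(t) for t in self._by_tf.values())


@dataclass
class RegulatorActivityResult:
    tf: str
    a: int  # targets in signature
    b: int  # targets outside signature (within universe)
    c: int  # signature genes that are not targets
    d: int  # remaining universe
    fisher_p: float
    significant: bool
    activation_z: float | None = None


def activation_score(
    edges: Mapping[str, int], fold_changes: Mapping[str, float]
) -> float | None:
    """Directional consistency z for one TF.

    `edges`: target -> sign; `fold_changes`: signature gene -> linear fold
    change (condition/control).  Only signed edges whose target carries a
    fold change contribute; fewer than 3 such edges -> None.
    """
    terms = []
    for target, sign in edges.items():
        if sign == 0:
            continue
        fc = fold_changes.get(target.strip().upper())
        if fc is None:
            continue
        if fc <= 0:
            raise ValueError(f"fold change for {target} must be positive, got {fc}")
        log_fc = math.log(fc)
        fc_sign = (log_fc > 0) - (log_fc < 0)
        terms.append(sign * fc_sign)
    if len(terms) < MIN_SIGNED_EDGES:
        return None
    return sum(terms) / math.sqrt(len(terms))


def regulator_overlap(
    network: RegulatorNetwork,
    signature: SignatureTable,
    universe: set[str],
    alpha: float = 0.01,
) -> list[RegulatorActivityResult]:
    """Fisher over-representation of each TF's targets in the signature.

    Universe = measured genes; signature must be contained in it.
    """
    if not universe:
        raise ValueError("universe is empty")
    universe = {g.strip().upper() for g in universe}
    sig = {g.strip().upper() for g in signature.genes}
    if not sig <= universe:
        raise ValueError("signature contains genes outside the universe")
    fold_changes = {g.strip().upper(): fc for g, fc in signature.fold_changes().items()}
    results = []
    for tf in network.tfs:
        edges = network.targets_of(tf)
        targets = {t for t in edges} & universe
        a = len(targets & sig)
        b = len(targets - sig)
        c = len(sig - targets)
        d = len(universe) - a - b - c
        p = fisher_exact_greater(a, b, c, d)
        z = activation_score(edges, fold_changes)
        results.append(
            RegulatorActivityResult(
                tf=tf,
                a=a,
                b=b,
                c=c,
                d=d,
                fisher_p=p,
                significant=p < alpha,
                activation_z=z,
            )
        )
    return results
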