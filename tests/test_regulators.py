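import math

import numpy as np
import pandas as pd
import pytest

from mitoscreen import RegulatorNetwork, activation_score, regulator_overlap
from mitoscreen.signature import SignatureTable


def _signature(genes_fc: dict[str, float], universe_extra=()):
    all_genes = list(genes_fc) + list(universe_extra)
    table = pd.DataFrame(
        {
            "fold_change": [genes_fc.get(g, 1.0) for g in all_genes],
            "p_value": [0.01 if g in genes_fc else 0.9 for g in all_genes],
            "in_signature": [g in genes_fc for g in all_genes],
            "zero_variance": [False] * len(all_genes),
        },
        index=all_genes,
    )
    return SignatureTable(table=table, alpha=0.05, control_group="WT", condition_groups=("KO",))


class TestOverlap:
    def test_perfect_overlap_hypergeometric_value(self):
        """10 targets all inside a 10-gene signature, universe 100:
        p = 1 / C(100, 10)."""
        sig_genes = {f"S{i}": 0.5 for i in range(10)}
        extra = [f"U{i}" for i in range(90)]
        net = RegulatorNetwork([("TF1", g, -1) for g in sig_genes])
        (r,) = regulator_overlap(net, _signature(sig_genes, extra), set(sig_genes) | set(extra))
        assert r.fisher_p == pytest.approx(1 / math.comb(100, 10), rel=1e-9)
        assert r.significant

    def test_disjoint_targets_not_significant(self):
        sig_genes = {f"S{i}": 0.5 for i in range(5)}
        extra = [f"U{i}" for i in range(20)]
        net = RegulatorNetwork([("TF1", f"U{i}", 1) for i in range(5)])
        (r,) = regulator_overlap(net, _signature(sig_genes, extra), set(sig_genes) | set(extra))
        assert r.fisher_p == 1.0
        assert not r.significant

    def test_proportional_targets_not_significant(self):
        """Targets spread proportionally to the signature fraction give an
        unremarkable p."""
        sig_genes = {f"S{i}": 0.5 for i in range(20)}
        extra = [f"U{i}" for i in range(80)]
        universe = set(sig_genes) | set(extra)
        # 10 targets, 2 in the 20% signature = exactly proportional
        net = RegulatorNetwork(
            [("TF1", f"S{i}", -1) for i in range(2)] + [("TF1", f"U{i}", -1) for i in range(8)]
        )
        (r,) = regulator_overlap(net, _signature(sig_genes, extra), universe)
        assert r.fisher_p > 0.01

    def test_empty_universe_rejected(self):
        net = RegulatorNetwork([("TF1", "A", 1)])
        with pytest.raises(ValueError, match="universe"):
            regulator_overlap(net, _signature({"A": 2.0}), set())

    def test_overlap_matches_hypergeometric_enumeration(self):
        """Fisher p equals the exact hypergeometric tail for small universes."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_univ = int(rng.integers(10, 60))
            genes = [f"G{i}" for i in range(n_univ)]
            n_sig = int(rng.integers(1, n_univ))
            sig = {g: 2.0 for g in genes[:n_sig]}
            n_targets = int(rng.integers(1, n_univ))
            targets = rng.choice(genes, size=n_targets, replace=False)
            net = RegulatorNetwork([("TF", str(t), 1) for t in targets])
            (r,) = regulator_overlap(net, _signature(sig, genes[n_sig:]), set(genes))
            K, n, N = n_targets, n_sig, n_univ
            tail = sum(
                math.comb(K, k) * math.comb(N - K, n - k)
                for k in range(r.a, min(K, n) + 1)
            ) / math.comb(N, n)
            assert r.fisher_p == pytest.approx(tail, abs=1e-12)


class TestActivationScore:
    def test_consistent_activating_edges(self):
        edges = {f"G{i}": +1 for i in range(4)}
        fc = {f"G{i}": 2.0 for i in range(4)}  # all up
        assert activation_score(edges, fc) == pytest.approx(2.0)

    def test_one_inconsistent_edge(self):
        edges = {f"G{i}": +1 for i in range(4)}
        fc = {"G0": 2.0, "G1": 2.0, "G2": 2.0, "G3": 0.5}
        assert activation_score(edges, fc) == pytest.approx(1.0)

    def test_engaged_repressor_scores_positive(self):
        """Repressive edges with uniformly down targets: the regulatory
        program agrees with the data, z = +sqrt(N)."""
        edges = {f"G{i}": -1 for i in range(20)}
        fc = {f"G{i}": 0.5 for i in range(20)}
        assert activation_score(edges, fc) == pytest.approx(math.sqrt(20))

    def test_undefined_below_three_usable_edges(self):
        edges = {"G0": 1, "G1": 1, "G2": 0, "G3": 1}
        fc = {"G0": 2.0, "G1": 2.0}  # only 2 signed edges overlap
        assert activation_score(edges, fc) is None

    def test_antisymmetric_under_fold_change_flip(self):
        rng = np.random.default_rng(4)
        edges = {f"G{i}": int(s) for i, s in enumerate(rng.choice([-1, 1], size=10))}
        fc = {f"G{i}": float(v) for i, v in enumerate(rng.lognormal(0, 0.5, size=10))}
        flipped = {g: 1.0 / v for g, v in fc.items()}
        assert activation_score(edges, fc) == pytest.approx(-activation_score(edges, flipped))

    def test_permutation_null_mean_zero_sd_one(self):
        """Random sign permutations of a 50-edge TF give empirical z with
        mean ~0 and sd ~1."""
        rng = np.random.default_rng(10)
        targets = [f"G{i}" for i in range(50)]
        edges = {g: -1 for g in targets}
        zs = []
        for _ in range(500):
            fc = {g: (2.0 if rng.random() < 0.5 else 0.5) for g in targets}
            zs.append(activation_score(edges, fc))
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.15
        assert 0.85 < zs.std(ddof=1) < 1.15


class TestNetwork:
    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicate edge"):
            RegulatorNetwork([("TF", "G1", 1), ("tf", "g1", -1)])

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            RegulatorNetwork([])

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            RegulatorNetwork([("TF", "G1", 2)])
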