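import itertools

import numpy as np
import pytest

from mitoscreen import (
    PositionFrequencyMatrix,
    RunConfig,
    compute_ci,
    family_enrichment,
    matrix_similarity,
    scan_promoters,
    select_family_members,
)
from mitoscreen.motifs import MotifHit
from mitoscreen.promoters import PromoterRecord, PromoterSet, reverse_complement


def _promoter_set(seqs):
    return PromoterSet(
        PromoterRecord(gene_id=g, sequence=s, chrom=".", start=0, end=len(s), strand="+")
        for g, s in seqs.items()
    )


class TestConservation:
    def test_uniform_column_is_zero(self):
        freqs = np.full((4, 4), 0.25)
        np.testing.assert_allclose(compute_ci(freqs), 0.0, atol=1e-12)

    def test_conserved_column_is_100(self):
        freqs = np.zeros((4, 4))
        freqs[0] = 1.0
        np.testing.assert_allclose(compute_ci(freqs), 100.0)

    def test_two_base_column_is_50(self):
        # (0.5, 0.5, 0, 0): (100/ln4)(ln4 - ln2) = 50
        freqs = np.tile([[0.5], [0.5], [0.0], [0.0]], (1, 4))
        np.testing.assert_allclose(compute_ci(freqs), 50.0)

    def test_unnormalized_column_rejected(self):
        freqs = np.full((4, 4), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            compute_ci(freqs)


class TestMatrixSimilarity:
    def test_consensus_scores_exactly_one(self, sharp_pwm):
        m, c = matrix_similarity(sharp_pwm.consensus, sharp_pwm)
        assert m == pytest.approx(1.0, abs=1e-12)
        assert c == pytest.approx(1.0, abs=1e-12)

    def test_window_with_n_scores_zero(self, sharp_pwm):
        assert matrix_similarity("ACGNAC", sharp_pwm) == (0.0, 0.0)

    def test_length_mismatch_rejected(self, sharp_pwm):
        with pytest.raises(ValueError, match="length"):
            matrix_similarity("ACGT", sharp_pwm)

    def test_exhaustive_maximum_at_unique_consensus(self):
        """Brute-force all 4^3... (L=4 minimum) windows: the maximum score is
        1.0 and attained only by the consensus when column maxima are unique."""
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 50, size=(4, 4)).astype(float)
        # make maxima unique
        counts[rng.integers(0, 4, size=4), np.arange(4)] += 100
        pwm = PositionFrequencyMatrix(name="T", counts=counts)
        scores = {
            "".join(w): matrix_similarity("".join(w), pwm)[0]
            for w in itertools.product("ACGT", repeat=4)
        }
        best = max(scores, key=scores.get)
        assert best == pwm.consensus
        assert scores[best] == pytest.approx(1.0, abs=1e-12)
        assert sum(1 for s in scores.values() if s > 1 - 1e-12) == 1

    def test_high_ci_position_matters_more(self):
        """A mismatch at the most conserved position costs more score than a
        mismatch at the least conserved position."""
        counts = np.array(
            [
                [97.0, 40.0, 97.0, 97.0],
                [1.0, 30.0, 1.0, 1.0],
                [1.0, 20.0, 1.0, 1.0],
                [1.0, 10.0, 1.0, 1.0],
            ]
        )
        pwm = PositionFrequencyMatrix(name="T", counts=counts)
        lo_ci = int(np.argmin(pwm.ci))
        hi_ci = int(np.argmax(pwm.ci))
        consensus = pwm.consensus

        def mutate(pos):
            worst = "ACGT"[int(np.argmin(pwm.frequencies[:, pos]))]
            w = list(consensus)
            w[pos] = worst
            return matrix_similarity("".join(w), pwm)[0]

        assert mutate(hi_ci) < mutate(lo_ci)


class TestScan:
    def test_planted_consensus_found_at_offset(self, sharp_pwm, config):
        seq = "T" * 100 + sharp_pwm.consensus + "T" * 100
        hits = scan_promoters(_promoter_set({"P1": seq}), [sharp_pwm], config)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert plus[0].offset == 100
        assert plus[0].matrix_similarity == pytest.approx(1.0)

    def test_minus_strand_hit_offset_in_promoter_coordinates(self, sharp_pwm, config):
        site = reverse_complement(sharp_pwm.consensus)
        seq = "T" * 50 + site + "T" * 30
        hits = scan_promoters(_promoter_set({"P1": seq}), [sharp_pwm], config)
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        assert minus[0].offset == 50

    def test_all_n_promoter_yields_no_hits(self, sharp_pwm, config):
        hits = scan_promoters(_promoter_set({"P1": "N" * 50}), [sharp_pwm], config)
        assert hits == []

    def test_scan_matches_brute_force(self, config):
        """Scan of random promoters against a random PFM equals scoring every
        window on both strands with the scalar scorer."""
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 80, size=(4, 5)).astype(float)
        pwm = PositionFrequencyMatrix(name="F/T.01", family="F", counts=counts)
        seqs = {
            f"P{i}": "".join(rng.choice(list("ACGT"), size=80)) for i in range(10)
        }
        hits = scan_promoters(_promoter_set(seqs), [pwm], config)
        expected = set()
        L = pwm.length
        for pid, seq in seqs.items():
            for strand, s in (("+", seq), ("-", reverse_complement(seq))):
                for off in range(len(s) - L + 1):
                    m, c = matrix_similarity(s[off : off + L], pwm)
                    if m >= config.matrix_sim_threshold and c >= config.core_sim_threshold:
                        promoter_off = off if strand == "+" else len(seq) - L - off
                        expected.add((pid, promoter_off, strand))
        assert {(h.promoter_id, h.offset, h.strand) for h in hits} == expected

    def test_hit_ordering_deterministic(self, sharp_pwm, config):
        seq = sharp_pwm.consensus * 3
        ps = _promoter_set({"B": seq, "A": seq})
        hits = scan_promoters(ps, [sharp_pwm], config)
        keys = [(h.promoter_id, h.offset, h.strand, h.matrix) for h in hits]
        assert keys == sorted(keys)


def _hit(pid, family="FAM", matrix="FAM/TF.01"):
    return MotifHit(
        promoter_id=pid, matrix=matrix, family=family, offset=0, strand="+",
        matrix_similarity=0.9, core_similarity=0.9,
    )


class TestEnrichment:
    def _sets(self, n_target, n_bg):
        target = _promoter_set({f"T{i}": "ACGT" * 10 for i in range(n_target)})
        bg = _promoter_set({f"B{i}": "ACGT" * 10 for i in range(n_bg)})
        return target, bg

    def test_fully_separating_table(self, config):
        target, bg = self._sets(5, 5)
        hits = [_hit(f"T{i}") for i in range(5)]
        (r,) = family_enrichment(hits, target, bg, config)
        assert (r.a, r.b, r.c, r.d) == (5, 0, 0, 5)
        assert r.fisher_p == pytest.approx(1 / 252, rel=1e-9)
        assert r.coverage == 1.0
        assert r.enriched

    def test_zero_hits_in_target(self, config):
        target, bg = self._sets(5, 5)
        hits = [_hit("B0")]
        (r,) = family_enrichment(hits, target, bg, config)
        assert r.a == 0
        assert r.fisher_p == 1.0
        assert not r.enriched

    def test_coverage_threshold_blocks_enrichment(self, config):
        # 16/20 covered (0.80) with an extreme p still fails the 85% rule
        target, bg = self._sets(20, 300)
        hits = [_hit(f"T{i}") for i in range(16)]
        (r,) = family_enrichment(hits, target, bg, config)
        assert r.coverage == pytest.approx(0.80)
        assert r.fisher_p < 1e-6
        assert not r.enriched

    def test_promoter_counted_once_despite_multiple_hits(self, config):
        target, bg = self._sets(4, 4)
        hits = [_hit("T0"), _hit("T0"), _hit("T1")]
        (r,) = family_enrichment(hits, target, bg, config)
        assert r.a == 2

    def test_empty_background_rejected(self, config):
        target, _ = self._sets(3, 3)
        with pytest.raises(ValueError, match="background"):
            family_enrichment([], target, _promoter_set({}), config)

    def test_reverse_complement_symmetry(self, sharp_pwm, config):
        rng = np.random.default_rng(12)
        seqs_t = {f"T{i}": "".join(rng.choice(list("ACGT"), 60)) + sharp_pwm.consensus
                  for i in range(10)}
        seqs_b = {f"B{i}": "".join(rng.choice(list("ACGT"), 66)) for i in range(20)}
        target, bg = _promoter_set(seqs_t), _promoter_set(seqs_b)
        hits = scan_promoters(target, [sharp_pwm], config) + scan_promoters(bg, [sharp_pwm], config)
        res = family_enrichment(hits, target, bg, config)
        target_rc = target.reverse_complemented()
        bg_rc = bg.reverse_complemented()
        hits_rc = scan_promoters(target_rc, [sharp_pwm], config) + scan_promoters(
            bg_rc, [sharp_pwm], config
        )
        res_rc = family_enrichment(hits_rc, target_rc, bg_rc, config)
        assert [(r.family, r.a, r.b, r.c, r.d, r.fisher_p, r.enriched) for r in res] == [
            (r.family, r.a, r.b, r.c, r.d, r.fisher_p, r.enriched) for r in res_rc
        ]


class TestMemberSelection:
    def test_member_coverage_rule(self, config):
        from mitoscreen.motifs import EnrichmentResult

        target = _promoter_set({f"T{i}": "ACGT" * 5 for i in range(20)})
        enr = [EnrichmentResult(family="FAM", a=18, b=2, c=1, d=99,
                                fisher_p=1e-9, coverage=0.9, enriched=True)]
        hits = [_hit(f"T{i}", matrix="FAM/GOOD.01") for i in range(12)]
        hits += [_hit(f"T{i}", matrix="FAM/WEAK.01") for i in range(9)]
        selected = select_family_members(hits, enr, target, config)
        names = [t.name for t in selected]
        assert "FAM/GOOD.01" in names  # 12/20 = 0.60 >= 0.50
        assert "FAM/WEAK.01" not in names  # 9/20 = 0.45 < 0.50

    def test_non_enriched_family_members_excluded(self, config):
        from mitoscreen.motifs import EnrichmentResult

        target = _promoter_set({f"T{i}": "ACGT" * 5 for i in range(4)})
        enr = [EnrichmentResult(family="FAM", a=4, b=0, c=4, d=0,
                                fisher_p=1.0, coverage=1.0, enriched=False)]
        hits = [_hit(f"T{i}") for i in range(4)]
        assert select_family_members(hits, enr, target, config) == []
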