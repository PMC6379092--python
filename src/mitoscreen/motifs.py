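"""PWM scanning and TF-family cis-element enrichment.

The scorer is a conservation-weighted matrix similarity in the MatInspector
tradition: each matrix position i carries a conservation value

    ci(i) = (100 / ln 4) * ( sum_b f(i,b) ln f(i,b) + ln 4 )

(0 for a uniform column, 100 for a fully conserved one), and a window w
scores

    sim(w) = sum_i ci(i) f(i, w_i) / sum_i ci(i) max_b f(i,b)

so the consensus window scores exactly 1.  The core similarity is the same
ratio restricted to the 4 consecutive positions with the largest total
conservation (leftmost on ties).  A hit requires matrix similarity >= 0.85
and core similarity >= 0.75 (configurable).

Family enrichment counts promoters, not hits: a TF family is enriched in a
target promoter set when members hit at least 85% of the target promoters
and the one-sided Fisher exact test against a background promoter set gives
p < 0.05.  Within enriched families, individual matrices (TFs) are retained
when they alone cover at least 50% of the target promoters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import RunConfig
from .promoters import PromoterSet, reverse_complement
from .stats import fisher_exact_greater

logger = logging.getLogger(__name__)

__all__ = [
    "PositionFrequencyMatrix",
    "MotifHit",
    "EnrichmentResult",
    "SelectedTF",
    "compute_ci",
    "matrix_similarity",
    "scan_promoters",
    "family_enrichment",
    "select_family_members",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_LN4 = np.log(4.0)
CORE_WIDTH = 4


def compute_ci(frequencies: np.ndarray) -> np.ndarray:
    """Per-position conservation in [0, 100] from a column-normalized 4xL
    frequency matrix; 0*ln(0) is taken as 0."""
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.shape[0] != 4:
        raise ValueError("frequency matrix must be 4 x L")
    sums = freqs.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("frequency columns must each sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log(freqs), 0.0)
    ci = (100.0 / _LN4) * (plogp.sum(axis=0) + _LN4)
    return np.clip(ci, 0.0, 100.0)


@dataclass
class PositionFrequencyMatrix:
    """TF binding-site model: 4xL base counts (rows A, C, G, T), smoothed
    frequencies, conservation vector and the derived core window."""

    name: str
    counts: np.ndarray
    family: str = ""
    pseudocount: float = 0.01
    frequencies: np.ndarray = field(init=False, repr=False)
    ci: np.ndarray = field(init=False, repr=False)
    core_start: int = field(init=False)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError(f"PFM {self.name}: counts must be a 4 x L array")
        if counts.shape[1] < 4:
            raise ValueError(f"PFM {self.name}: length must be >= 4")
        if np.any(counts < 0):
            raise ValueError(f"PFM {self.name}: counts must be non-negative")
        col_sums = counts.sum(axis=0)
        if np.any(col_sums == 0):
            raise ValueError(f"PFM {self.name}: all-zero column")
        if not self.family:
            self.family = self.name
        self.counts = counts
        smoothed = counts + self.pseudocount
        self.frequencies = smoothed / smoothed.sum(axis=0, keepdims=True)
        self.ci = compute_ci(self.frequencies)
        # core = best CORE_WIDTH consecutive positions by total ci, leftmost tie
        window_sums = sliding_window_view(self.ci, CORE_WIDTH).sum(axis=1)
        self.core_start = int(np.argmax(window_sums))

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        """Per-position max-frequency base (lowest-index base on ties)."""
        return "".join(BASES[i] for i in np.argmax(self.frequencies, axis=0))

    def _weights(self) -> tuple[np.ndarray, float, float]:
        w = self.ci[None, :] * self.frequencies  # 4 x L
        denom = float((self.ci * self.frequencies.max(axis=0)).sum())
        core = slice(self.core_start, self.core_start + CORE_WIDTH)
        core_denom = float((self.ci[core] * self.frequencies[:, core].max(axis=0)).sum())
        return w, denom, core_denom


@dataclass(frozen=True)
class MotifHit:
    promoter_id: str
    matrix: str
    family: str
    offset: int  # 0-based window start within the promoter-sense sequence
    strand: str  # strand within the promoter: '+' as given, '-' = revcomp match
    matrix_similarity: float
    core_similarity: float


@dataclass
class EnrichmentResult:
    family: str
    a: int  # target promoters with >= 1 hit
    b: int  # target promoters without
    c: int  # background promoters with >= 1 hit
    d: int  # background promoters without
    fisher_p: float
    coverage: float
    enriched: bool


@dataclass(frozen=True)
class SelectedTF:
    name: str
    family: str
    coverage: float


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def matrix_similarity(window: str, pwm: PositionFrequencyMatrix) -> tuple[float, float]:
    """(matrix_similarity, core_similarity) of one window; scalar reference
    implementation of the scorer used by :func:`scan_promoters`.  Windows
    containing N score 0."""
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != matrix length {pwm.length} ({pwm.name})"
        )
    idx = _encode(window)
    if np.any(idx == 4):
        return 0.0, 0.0
    _, denom, core_denom = pwm._weights()
    pos = np.arange(pwm.length)
    num = float((pwm.ci * pwm.frequencies[idx, pos]).sum())
    core = slice(pwm.core_start, pwm.core_start + CORE_WIDTH)
    core_num = float((pwm.ci[core] * pwm.frequencies[idx[core], pos[core]]).sum())
    return num / denom, core_num / core_denom


def _score_all_offsets(encoded: np.ndarray, pwm: PositionFrequencyMatrix):
    """Matrix and core similarity at every offset of one encoded sequence.
    Offsets whose window contains N get -1 (never a hit)."""
    L = pwm.length
    if encoded.size < L:
        return np.empty(0), np.empty(0)
    w, denom, core_denom = pwm._weights()
    w5 = np.vstack([w, np.full((1, L), -1e9)])  # row 4 vetoes N
    windows = sliding_window_view(encoded, L)  # (n_offsets, L)
    pos = np.arange(L)
    sims = w5[windows, pos].sum(axis=1) / denom
    core = slice(pwm.core_start, pwm.core_start + CORE_WIDTH)
    w5_core = w5[:, core]
    core_sims = w5_core[windows[:, core], np.arange(CORE_WIDTH)].sum(axis=1) / core_denom
    sims = np.where(sims < 0, -1.0, sims)
    core_sims = np.where(core_sims < 0, -1.0, core_sims)
    return sims, core_sims


def scan_promoters(
    promoters: PromoterSet,
    pwms: Sequence[PositionFrequencyMatrix],
    config: RunConfig | None = None,
) -> list[MotifHit]:
    """Scan both strands of every promoter at every offset; return all hits
    passing the matrix- and core-similarity thresholds, ordered by
    (promoter, offset, strand, matrix)."""
    config = config or RunConfig()
    mthr = config.matrix_sim_threshold
    cthr = config.core_sim_threshold
    hits: list[MotifHit] = []
    for rec in promoters:
        fwd = _encode(rec.sequence)
        rev = _encode(reverse_complement(rec.sequence))
        n = len(rec.sequence)
        for pwm in pwms:
            L = pwm.length
            for strand, enc in (("+", fwd), ("-", rev)):
                sims, core_sims = _score_all_offsets(enc, pwm)
                keep = np.flatnonzero((sims >= mthr) & (core_sims >= cthr))
                for off in keep:
                    # map a reverse-strand offset back to promoter coordinates
                    offset = int(off) if strand == "+" else n - L - int(off)
                    hits.append(
                        MotifHit(
                            promoter_id=rec.gene_id,
                            matrix=pwm.name,
                            family=pwm.family,
                            offset=offset,
                            strand=strand,
                            matrix_similarity=float(sims[off]),
                            core_similarity=float(core_sims[off]),
                        )
                    )
    hits.sort(key=lambda h: (h.promoter_id, h.offset, h.strand, h.matrix))
    return hits


def _promoters_hit(hits: Iterable[MotifHit], ids: set[str], key) -> dict[str, set[str]]:
    """key(hit) -> set of promoter ids (from `ids`) with >= 1 hit."""
    out: dict[str, set[str]] = {}
    for h in hits:
        if h.promoter_id in ids:
            out.setdefault(key(h), set()).add(h.promoter_id)
    return out


def family_enrichment(
    hits: Sequence[MotifHit],
    target: PromoterSet,
    background: PromoterSet,
    config: RunConfig | None = None,
) -> list[EnrichmentResult]:
    """Per-family 2x2 promoter counts, one-sided Fisher p and the enriched
    call (p < 0.05 AND target coverage >= family_coverage_min).

    `hits` must have been computed on both promoter sets with identical
    thresholds.  Promoters are counted once per family regardless of hit
    multiplicity.
    """
    config = config or RunConfig()
    if len(background) == 0:
        raise ValueError("background promoter set is empty")
    target_ids = set(target.gene_ids)
    bg_ids = set(background.gene_ids)
    overlap = target_ids & bg_ids
    if overlap:
        logger.warning(
            "target and background promoter sets share %d promoters", len(overlap)
        )
    families = sorted({h.family for h in hits})
    t_hit = _promoters_hit(hits, target_ids, key=lambda h: h.family)
    b_hit = _promoters_hit(hits, bg_ids, key=lambda h: h.family)
    results = []
    for fam in families:
        a = len(t_hit.get(fam, ()))
        b = len(target_ids) - a
        c = len(b_hit.get(fam, ()))
        d = len(bg_ids) - c
        p = fisher_exact_greater(a, b, c, d)
        coverage = a / len(target_ids) if target_ids else 0.0
        results.append(
            EnrichmentResult(
                family=fam,
                a=a,
                b=b,
                c=c,
                d=d,
                fisher_p=p,
                coverage=coverage,
                enriched=(p < 0.05) and (coverage >= config.family_coverage_min),
            )
        )
    return results


def select_family_members(
    hits: Sequence[MotifHit],
    enrichment: Sequence[EnrichmentResult],
    target: PromoterSet,
    config: RunConfig | None = None,
) -> list[SelectedTF]:
    """Within each enriched family, keep the individual matrices (TFs) whose
    own hits cover at least member_coverage_min of the target promoters."""
    config = config or RunConfig()
    enriched_families = {r.family for r in enrichment if r.enriched}
    target_ids = set(target.gene_ids)
    if not target_ids:
        return []
    per_matrix = _promoters_hit(
        (h for h in hits if h.family in enriched_families),
        target_ids,
        key=lambda h: (h.family, h.matrix),
    )
    selected = []
    for (family, matrix), covered in sorted(per_matrix.items()):
        coverage = len(covered) / len(target_ids)
        if coverage >= config.member_coverage_min:
            selected.append(SelectedTF(name=matrix, family=family, coverage=coverage))
    return selected
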