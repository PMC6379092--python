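"""Synthetic inputs with the statistical structure the screen assumes.

The generator emulates a case/control microarray study of organelle
biogenesis: log-normal baseline intensities with multiplicative group
effects planted on organelle gene lists, promoter sets with a binding-site
consensus embedded at controlled coverage, and a signed regulator network
whose planted repressor points at the down-regulated genes.  Every
generator is a pure function of (spec, seed), and each returns the ground
truth needed to score the corresponding pipeline stage.

Defaults mirror the study design the pipeline targets: six case and six
control samples, a ~200-gene organelle list repressed to 0.75x control,
log-normal noise with sigma = 0.1, 100 target and 300 background promoters
of 600 bp, planted motif coverage 0.9 (targets) vs 0.1 (background), and a
planted repressor with 30 signed targets at 0.9 sign consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as msio
from .config import RunConfig
from .expression import ExpressionMatrix
from .genelists import GeneList
from .motifs import PositionFrequencyMatrix
from .promoters import PromoterRecord, PromoterSet, reverse_complement
from .regulators import RegulatorNetwork

__all__ = [
    "ScenarioSpec",
    "ExpressionTruth",
    "EmbeddingRecord",
    "Scenario",
    "make_planted_pfm",
    "gen_expression",
    "gen_promoters",
    "gen_network",
    "generate_scenario",
    "write_scenario",
]

BASES = "ACGT"


@dataclass
class ScenarioSpec:
    n_genes: int = 1000
    n_per_group: int = 6
    organelle_lists: Mapping[str, int] = field(
        default_factory=lambda: {
            "mitochondria": 200,
            "endoplasmic_reticulum": 120,
            "golgi": 80,
        }
    )
    planted_effects: Mapping[str, float] = field(
        default_factory=lambda: {"mitochondria": 0.75}
    )
    noise_sigma: float = 0.1
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    n_target_promoters: int = 100
    n_background_promoters: int = 300
    promoter_length: int = 600
    motif_target_coverage: float = 0.9
    motif_background_coverage: float = 0.1
    motif_length: int = 10
    gc_content: float = 0.5
    planted_tf: str = "KLF2"
    planted_family: str = "KLF"
    n_network_targets: int = 30
    sign_consistency: float = 0.9
    n_decoy_tfs: int = 5
    n_decoy_targets: int = 30
    seed: int = 0

    def __post_init__(self):
        for name in ("motif_target_coverage", "motif_background_coverage", "sign_consistency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(e <= 0 for e in self.planted_effects.values()):
            raise ValueError("planted effects must be positive multipliers")
        if self.n_genes < 2 or self.n_per_group < 2:
            raise ValueError("need at least 2 genes and 2 samples per group")
        if sum(self.organelle_lists.values()) > self.n_genes:
            raise ValueError("organelle lists exceed the number of genes")
        if self.motif_length >= self.promoter_length:
            raise ValueError("planted motif must be shorter than the promoter")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]


@dataclass
class ExpressionTruth:
    """Which genes carry which planted multiplicative effect."""

    list_effects: dict[str, float]
    affected_genes: dict[str, set[str]]

    def effect_of(self, gene: str) -> float:
        for lst, genes in self.affected_genes.items():
            if gene in genes:
                return self.list_effects.get(lst, 1.0)
        return 1.0


@dataclass(frozen=True)
class EmbeddingRecord:
    which_set: str  # 'target' or 'background'
    promoter_id: str
    offset: int
    strand: str


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _organelle_blocks(spec: ScenarioSpec) -> dict[str, list[str]]:
    """Deterministic disjoint gene blocks for the organelle lists."""
    genes = spec.gene_ids()
    blocks: dict[str, list[str]] = {}
    cursor = 0
    for name, size in spec.organelle_lists.items():
        blocks[name] = genes[cursor : cursor + size]
        cursor += size
    return blocks


def gen_expression(
    spec: ScenarioSpec, seed: int | None = None
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Simulate a log2 expression matrix (control 'WT' vs condition 'KO').

    Baseline intensities are log-normal; member genes of each planted list
    are multiplied by the list's effect in the condition samples; i.i.d.
    multiplicative noise exp(N(0, sigma^2)) is applied everywhere.
    """
    rng = _child_rng(spec.seed if seed is None else seed, 0)
    genes = spec.gene_ids()
    n = spec.n_per_group
    samples = [f"WT_{i+1}" for i in range(n)] + [f"KO_{i+1}" for i in range(n)]
    groups = {s: ("WT" if s.startswith("WT") else "KO") for s in samples}

    baseline = np.exp2(
        rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, size=spec.n_genes)
    )
    effect = np.ones(spec.n_genes)
    blocks = _organelle_blocks(spec)
    affected: dict[str, set[str]] = {}
    index = {g: i for i, g in enumerate(genes)}
    for lst, eff in spec.planted_effects.items():
        if lst not in blocks:
            raise ValueError(f"planted effect on unknown list {lst!r}")
        members = blocks[lst]
        affected[lst] = set(members)
        for g in members:
            effect[index[g]] = eff

    noise = np.exp(rng.normal(0.0, spec.noise_sigma, size=(spec.n_genes, 2 * n)))
    values = baseline[:, None] * noise
    values[:, n:] *= effect[:, None]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(np.log2(values), index=genes, columns=samples),
        sample_groups=groups,
        scale="log2",
    )
    truth = ExpressionTruth(list_effects=dict(spec.planted_effects), affected_genes=affected)
    return matrix, truth


def make_planted_pfm(
    name: str,
    family: str,
    length: int = 10,
    seed: int = 0,
    sharpness: int = 97,
) -> PositionFrequencyMatrix:
    """A sharp random-consensus matrix: `sharpness` counts on the consensus
    base per column, one count on each other base."""
    rng = _child_rng(seed, 7)
    consensus = rng.integers(0, 4, size=length)
    counts = np.ones((4, length))
    counts[consensus, np.arange(length)] = sharpness
    if not name.startswith(family + "/"):
        name = f"{family}/{name}"  # FAMILY/NAME convention survives file round trips
    return PositionFrequencyMatrix(name=name, family=family, counts=counts)


def _random_sequences(rng, n: int, length: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=(n, length), p=p)
    return [bytes(row).decode() for row in arr]


def gen_promoters(
    spec: ScenarioSpec,
    pfm: PositionFrequencyMatrix | None = None,
    seed: int | None = None,
) -> tuple[PromoterSet, PromoterSet, list[EmbeddingRecord], PositionFrequencyMatrix]:
    """Target and background promoter sets with the planted motif's
    consensus embedded at the specified coverages.

    Coverage is exact by construction: round(coverage * n) promoters of each
    set carry exactly one embedding at a random offset and strand.  The
    registry lists every embedding.
    """
    base_seed = spec.seed if seed is None else seed
    rng = _child_rng(base_seed, 1)
    if pfm is None:
        pfm = make_planted_pfm(
            f"{spec.planted_tf}.01", spec.planted_family, spec.motif_length, seed=base_seed
        )
    site = pfm.consensus
    registry: list[EmbeddingRecord] = []

    def build(which: str, ids: list[str], coverage: float) -> PromoterSet:
        seqs = _random_sequences(rng, len(ids), spec.promoter_length, spec.gc_content)
        n_embed = round(coverage * len(ids))
        chosen = rng.permutation(len(ids))[:n_embed]
        records = []
        for i, (gene, seq) in enumerate(zip(ids, seqs)):
            if i in chosen:
                offset = int(rng.integers(0, spec.promoter_length - len(site) + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                insert = site if strand == "+" else reverse_complement(site)
                seq = seq[:offset] + insert + seq[offset + len(site):]
                registry.append(EmbeddingRecord(which, gene, offset, strand))
            records.append(
                PromoterRecord(
                    gene_id=gene, sequence=seq, chrom=".", start=0,
                    end=spec.promoter_length, strand="+",
                )
            )
        return PromoterSet(records)

    width = len(str(spec.n_genes))
    target_ids = [f"RC_G{i:0{width}d}" for i in range(spec.n_target_promoters)]
    bg_ids = [f"BG_G{i:0{width}d}" for i in range(spec.n_background_promoters)]
    target = build("target", target_ids, spec.motif_target_coverage)
    background = build("background", bg_ids, spec.motif_background_coverage)
    return target, background, registry, pfm


def gen_network(
    spec: ScenarioSpec,
    truth: ExpressionTruth,
    seed: int | None = None,
) -> RegulatorNetwork:
    """Signed TF -> target network consistent with the planted effects.

    The planted repressor receives edges to genes carrying a down-regulating
    effect; a `sign_consistency` fraction of them are repressive (-1), the
    rest activating (+1).  Decoy TFs receive random targets and signs.
    """
    rng = _child_rng(spec.seed if seed is None else seed, 2)
    down_genes = sorted(
        g
        for lst, genes in truth.affected_genes.items()
        if truth.list_effects.get(lst, 1.0) < 1.0
        for g in genes
    )
    if len(down_genes) < spec.n_network_targets:
        raise ValueError("not enough down-regulated genes for the planted network")
    targets = rng.choice(down_genes, size=spec.n_network_targets, replace=False)
    n_consistent = round(spec.sign_consistency * spec.n_network_targets)
    edges = [
        (spec.planted_tf, str(t), -1 if i < n_consistent else +1)
        for i, t in enumerate(targets)
    ]
    all_genes = spec.gene_ids()
    for d in range(spec.n_decoy_tfs):
        decoy_targets = rng.choice(all_genes, size=spec.n_decoy_targets, replace=False)
        for t in decoy_targets:
            edges.append((f"DECOY{d+1}", str(t), int(rng.choice([-1, 0, 1]))))
    return RegulatorNetwork(edges)


@dataclass
class Scenario:
    """Everything one end-to-end run of the screen needs, plus ground truth."""

    spec: ScenarioSpec
    matrix: ExpressionMatrix
    truth: ExpressionTruth
    organelle_lists: list[GeneList]
    target_promoters: PromoterSet
    background_promoters: PromoterSet
    embeddings: list[EmbeddingRecord]
    pfms: list[PositionFrequencyMatrix]
    network: RegulatorNetwork
    name_map: dict[str, str]
    control_group: str = "WT"
    condition_group: str = "KO"


def generate_scenario(spec: ScenarioSpec, seed: int | None = None) -> Scenario:
    """A full planted-repressor study: repressed organelle list, target
    promoters enriched for the repressor's binding site, and a network in
    which the repressor points at the down-regulated genes.  A decoy motif
    family and decoy TFs are included so the screen has something to reject.
    """
    base_seed = spec.seed if seed is None else seed
    matrix, truth = gen_expression(spec, seed=base_seed)
    blocks = _organelle_blocks(spec)
    lists = [
        GeneList(name=name, members=frozenset(genes), provenance="synthetic")
        for name, genes in blocks.items()
    ]
    target, background, embeddings, planted_pfm = gen_promoters(spec, seed=base_seed)
    decoy_pfm = make_planted_pfm(
        "DECOYM.01", "DECOYFAM", spec.motif_length, seed=base_seed + 1_000_003
    )
    network = gen_network(spec, truth, seed=base_seed)
    name_map = {planted_pfm.name: spec.planted_tf, decoy_pfm.name: "DECOYM_GENE"}
    return Scenario(
        spec=spec,
        matrix=matrix,
        truth=truth,
        organelle_lists=lists,
        target_promoters=target,
        background_promoters=background,
        embeddings=embeddings,
        pfms=[planted_pfm, decoy_pfm],
        network=network,
        name_map=name_map,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Emit the scenario in the exact file formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "lists": outdir / "organelle_lists.gmt",
        "target_promoters": outdir / "target_promoters.fasta",
        "background_promoters": outdir / "background_promoters.fasta",
        "pfms": outdir / "matrices.jaspar.txt",
        "network": outdir / "network.tsv",
        "name_map": outdir / "name_map.tsv",
    }
    msio.write_expression_matrix(scenario.matrix, paths["expression"])
    msio.write_group_map(scenario.matrix.sample_groups, paths["groups"])
    msio.write_gmt(scenario.organelle_lists, paths["lists"])
    msio.write_promoters_fasta(scenario.target_promoters, paths["target_promoters"])
    msio.write_promoters_fasta(scenario.background_promoters, paths["background_promoters"])
    msio.write_pfms(scenario.pfms, paths["pfms"])
    msio.write_network(scenario.network, paths["network"])
    msio.write_name_map(scenario.name_map, paths["name_map"])
    return paths
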