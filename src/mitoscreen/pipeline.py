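"""End of the screen: intersect the promoter-predicted TFs with the
activity-significant TFs, and orchestrate the full run.

A candidate transcription factor must survive both arms: its binding-site
matrix belongs to a family enriched in the target promoters and itself
covers at least half of them, and its curated target set is
over-represented in the differential signature at p < 0.01.  Motif matrix
names are translated to gene symbols through an explicit two-column map —
no fuzzy matching; unmatched names are reported, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .config import RunConfig
from .expression import (
    ExpressionMatrix,
    adjust_scores,
    control_normalize,
    organelle_score,
    percent_change,
)
from .genelists import GeneList, restrict_to_measured
from .motifs import (
    EnrichmentResult,
    PositionFrequencyMatrix,
    SelectedTF,
    family_enrichment,
    scan_promoters,
    select_family_members,
)
from .promoters import PromoterSet
from .regulators import RegulatorActivityResult, RegulatorNetwork, regulator_overlap
from .signature import SignatureTable, organelle_fraction, per_gene_tests

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateTF",
    "PipelineInputs",
    "PipelineResult",
    "PipelineStageError",
    "intersect_candidates",
    "run_pipeline",
]


@dataclass(frozen=True)
class CandidateTF:
    name: str
    family: str
    promoter_coverage: float
    family_fisher_p: float
    regulator_fisher_p: float
    activation_z: float | None
    evidence_flags: tuple[str, ...]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def intersect_candidates(
    promoter_tfs: Sequence[SelectedTF],
    activity: Sequence[RegulatorActivityResult],
    name_map: Mapping[str, str],
    enrichment: Sequence[EnrichmentResult] = (),
    regulator_alpha: float = 0.01,
    direction_filter: bool = False,
) -> tuple[list[CandidateTF], list[str]]:
    """Intersect promoter-predicted TFs with activity-significant TFs.

    Matrix names are mapped to gene symbols via `name_map` (case-insensitive
    keys); promoter TFs without a map entry are returned in the unmatched
    list.  With `direction_filter`, candidates must additionally have a
    defined, positive activation z (regulatory program consistent with the
    observed fold changes).  Candidates are ordered by family then name.
    """
    if promoter_tfs and not name_map:
        raise ValueError("name map is empty but promoter TFs were supplied")
    norm_map = {k.strip().upper(): v.strip().upper() for k, v in name_map.items()}
    family_p = {r.family: r.fisher_p for r in enrichment}
    significant = {
        r.tf.strip().upper(): r for r in activity if r.fisher_p < regulator_alpha
    }
    candidates: list[CandidateTF] = []
    unmatched: list[str] = []
    for tf in promoter_tfs:
        symbol = norm_map.get(tf.name.strip().upper())
        if symbol is None:
            unmatched.append(tf.name)
            continue
        hit = significant.get(symbol)
        if hit is None:
            continue
        flags = ["family_enriched", "member_coverage", "regulator_significant"]
        if direction_filter:
            if hit.activation_z is None or hit.activation_z <= 0:
                continue
            flags.append("direction_consistent")
        candidates.append(
            CandidateTF(
                name=symbol,
                family=tf.family,
                promoter_coverage=tf.coverage,
                family_fisher_p=family_p.get(tf.family, float("nan")),
                regulator_fisher_p=hit.fisher_p,
                activation_z=hit.activation_z,
                evidence_flags=tuple(flags),
            )
        )
    if unmatched:
        logger.warning("promoter TFs without a name-map entry: %s", unmatched)
    candidates.sort(key=lambda c: (c.family, c.name))
    return candidates, unmatched


@dataclass
class PipelineInputs:
    matrix: ExpressionMatrix
    control_group: str
    condition_group: str
    organelle_lists: Sequence[GeneList]
    target_promoters: PromoterSet
    background_promoters: PromoterSet
    pfms: Sequence[PositionFrequencyMatrix]
    network: RegulatorNetwork
    name_map: Mapping[str, str]


@dataclass
class PipelineResult:
    scores: list
    signature: SignatureTable
    enrichment: list[EnrichmentResult]
    selected_tfs: list[SelectedTF]
    activity: list[RegulatorActivityResult]
    candidates: list[CandidateTF]
    unmatched: list[str]
    tables: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def candidate_names(self) -> list[str]:
        return [c.name for c in self.candidates]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", **kwargs)


def run_pipeline(
    config: RunConfig,
    inputs: PipelineInputs,
    outdir: str | Path,
    direction_filter: bool = False,
) -> PipelineResult:
    """Run the whole screen and write every intermediate table plus a JSON
    manifest (config, seed, output digests).  A stage failure raises
    :class:`PipelineStageError` naming the stage; tables written before the
    failure are retained."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, Path] = {}

    def stage(name, fn):
        try:
            return fn()
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    def measured_lists():
        return [restrict_to_measured(gl, inputs.matrix) for gl in inputs.organelle_lists]

    lists = stage("genelists", measured_lists)

    def score_lists():
        ratios = control_normalize(inputs.matrix, inputs.control_group)
        results = [
            organelle_score(ratios, gl, inputs.control_group, inputs.condition_group)
            for gl in lists
        ]
        return adjust_scores(results)

    scores = stage("organelle_expression", score_lists)
    _write(
        pd.DataFrame(
            {
                "organelle": [r.organelle for r in scores],
                "n_genes": [r.n_genes for r in scores],
                "percent_change": [percent_change(r) for r in scores],
                "p_raw": [r.p_raw for r in scores],
                "p_adjusted": [r.p_adjusted for r in scores],
            }
        ),
        tables.setdefault("organelle_scores", outdir / "organelle_scores.tsv"),
        index=False,
    )

    signature = stage(
        "differential_signature",
        lambda: per_gene_tests(
            inputs.matrix, inputs.control_group, inputs.condition_group, alpha=config.deg_alpha
        ),
    )
    _write(signature.table, tables.setdefault("signature", outdir / "signature.tsv"),
           index_label="gene")
    fractions = pd.DataFrame(
        {
            "organelle": [gl.name for gl in lists],
            "signature_fraction": [organelle_fraction(signature, gl) for gl in lists],
        }
    )
    _write(fractions, tables.setdefault("signature_fractions", outdir / "signature_fractions.tsv"),
           index=False)

    def scan():
        hits_t = scan_promoters(inputs.target_promoters, inputs.pfms, config)
        hits_b = scan_promoters(inputs.background_promoters, inputs.pfms, config)
        return hits_t + hits_b

    hits = stage("motif_scan", scan)
    _write(
        pd.DataFrame(
            {
                "promoter_id": [h.promoter_id for h in hits],
                "offset": [h.offset for h in hits],
                "strand": [h.strand for h in hits],
                "matrix": [h.matrix for h in hits],
                "family": [h.family for h in hits],
                "matrix_similarity": [round(h.matrix_similarity, 6) for h in hits],
                "core_similarity": [round(h.core_similarity, 6) for h in hits],
            }
        ),
        tables.setdefault("motif_hits", outdir / "motif_hits.tsv"),
        index=False,
    )

    enrichment = stage(
        "motif_enrichment",
        lambda: family_enrichment(
            hits, inputs.target_promoters, inputs.background_promoters, config
        ),
    )
    _write(
        pd.DataFrame(
            {
                "family": [r.family for r in enrichment],
                "target_with_site": [r.a for r in enrichment],
                "target_without_site": [r.b for r in enrichment],
                "background_with_site": [r.c for r in enrichment],
                "background_without_site": [r.d for r in enrichment],
                "coverage": [r.coverage for r in enrichment],
                "fisher_p": [r.fisher_p for r in enrichment],
                "enriched": [r.enriched for r in enrichment],
            }
        ),
        tables.setdefault("family_enrichment", outdir / "family_enrichment.tsv"),
        index=False,
    )

    selected = stage(
        "member_selection",
        lambda: select_family_members(hits, enrichment, inputs.target_promoters, config),
    )
    _write(
        pd.DataFrame(
            {
                "tf": [t.name for t in selected],
                "family": [t.family for t in selected],
                "coverage": [t.coverage for t in selected],
            }
        ),
        tables.setdefault("selected_tfs", outdir / "selected_tfs.tsv"),
        index=False,
    )

    activity = stage(
        "regulator_activity",
        lambda: regulator_overlap(
            inputs.network,
            signature,
            universe=set(inputs.matrix.gene_ids),
            alpha=config.regulator_alpha,
        ),
    )
    _write(
        pd.DataFrame(
            {
                "tf": [r.tf for r in activity],
                "targets_in_signature": [r.a for r in activity],
                "targets_outside": [r.b for r in activity],
                "fisher_p": [r.fisher_p for r in activity],
                "significant": [r.significant for r in activity],
                "activation_z": [r.activation_z for r in activity],
            }
        ),
        tables.setdefault("regulator_activity", outdir / "regulator_activity.tsv"),
        index=False,
    )

    def intersect():
        return intersect_candidates(
            selected,
            activity,
            inputs.name_map,
            enrichment=enrichment,
            regulator_alpha=config.regulator_alpha,
            direction_filter=direction_filter,
        )

    candidates, unmatched = stage("candidate_intersection", intersect)
    _write(
        pd.DataFrame(
            {
                "tf": [c.name for c in candidates],
                "family": [c.family for c in candidates],
                "promoter_coverage": [c.promoter_coverage for c in candidates],
                "family_fisher_p": [c.family_fisher_p for c in candidates],
                "regulator_fisher_p": [c.regulator_fisher_p for c in candidates],
                "activation_z": [c.activation_z for c in candidates],
            }
        ),
        tables.setdefault("candidates", outdir / "candidates.tsv"),
        index=False,
    )

    manifest = {
        "package": "mitoscreen",
        "version": __version__,
        "config": config.to_dict(),
        "control_group": inputs.control_group,
        "condition_group": inputs.condition_group,
        "n_genes": len(inputs.matrix.gene_ids),
        "n_target_promoters": len(inputs.target_promoters),
        "n_background_promoters": len(inputs.background_promoters),
        "unmatched_promoter_tfs": unmatched,
        "tables": {name: _digest(path) for name, path in sorted(tables.items())},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    tables["manifest"] = manifest_path

    return PipelineResult(
        scores=scores,
        signature=signature,
        enrichment=enrichment,
        selected_tfs=selected,
        activity=activity,
        candidates=candidates,
        unmatched=unmatched,
        tables=tables,
        manifest=manifest,
    )
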