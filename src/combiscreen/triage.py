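"""Two-stage screen orchestration: score every block, gate hits, group by MoA.

The primary screen scores every compound against the shared anchor drug on
6x6 blocks and advances pairs with combination index < 0.5 and beta < 1
(strict, matching the published thresholds) to a 10x10 confirmation stage.
Pairs whose CI or beta cannot be computed are reported with flags and listed
separately — they are never silently dropped, and the triage denominator
counts only scoreable pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DOSE_CEILING, FitError, fit_median_effect
from .screen_io import ScreenDataset, normalize_block
from .synergy import CI_FA_BAND, SynergyReport, summarize_pair

__all__ = [
    "StageConfig",
    "ScreenResult",
    "select_hits",
    "run_stage",
    "aggregate_by_class",
]

logger = logging.getLogger("combiscreen")


@dataclass(frozen=True)
class StageConfig:
    """Knobs of one triage stage (thresholds, CI policy, readout, ceiling)."""

    stage: str = "primary"
    readout: str = "viability"
    ci_max: float = 0.5
    beta_max: float = 1.0
    ci_policy: str = "median_in_band"
    fa_band: tuple[float, float] = CI_FA_BAND
    dose_ceiling: float | None = DOSE_CEILING

    def __post_init__(self) -> None:
        if self.ci_max <= 0 or self.beta_max <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ScreenResult:
    """Outcome of one stage: all per-pair reports, the ranked hit list, and
    the pairs excluded from gating for QC reasons."""

    stage: str
    reports: list[SynergyReport]
    hits: list[SynergyReport]
    excluded: list[SynergyReport]
    class_summary: pd.DataFrame | None = None
    config: StageConfig = field(default_factory=StageConfig)

    @property
    def hit_ids(self) -> list[str]:
        return [r.pair_id for r in self.hits]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                r.pair_id,
                r.drugA_id,
                r.drugB_id,
                r.sum_neg_hsa,
                r.sum_neg_bliss,
                r.ci,
                r.ci_fa_at,
                r.ci_policy,
                r.beta,
                r.hit,
                ";".join(r.flags),
            )
            for r in self.reports
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "pair_id", "drugA_id", "drugB_id", "sum_neg_hsa", "sum_neg_bliss",
                "ci", "ci_fa_at", "ci_policy", "beta", "hit", "flags",
            ],
        )


def select_hits(
    reports: list[SynergyReport],
    ci_max: float = 0.5,
    beta_max: float = 1.0,
) -> tuple[list[SynergyReport], list[SynergyReport]]:
    """Gate pairs on CI < ci_max AND beta < beta_max (strict inequalities).

    Returns ``(hits, excluded)``: hits ranked by CI ascending with ties broken
    by sum_neg_bliss ascending then pair id; ``excluded`` lists pairs whose CI
    or beta is undefined (they cannot be gated either way).
    """
    excluded = [r for r in reports if not (r.ci_defined and r.beta_defined)]
    scoreable = [r for r in reports if r.ci_defined and r.beta_defined]
    hits = [r for r in scoreable if r.ci < ci_max and r.beta < beta_max]
    hits.sort(key=lambda r: (r.ci, r.sum_neg_bliss, r.pair_id))
    return hits, excluded


def _fit_singles(nm, config: StageConfig):
    """Median-effect fits of both matrix edges; None where unfittable."""
    fa_A = np.clip(1.0 - nm.v[:, 0], 0.0, 1.0)
    fa_B = np.clip(1.0 - nm.v[0, :], 0.0, 1.0)
    fits = []
    for doses, fa in ((nm.dosesA, fa_A), (nm.dosesB, fa_B)):
        try:
            fits.append(fit_median_effect(doses, fa, dose_ceiling=config.dose_ceiling))
        except FitError:
            fits.append(None)
    return fits


def run_stage(dataset: ScreenDataset, config: StageConfig = StageConfig()) -> ScreenResult:
    """Run one full stage: normalize, fit singles, score, gate.

    All blocks must share the anchor drug on the B axis and the configured
    readout assay; blocks of other assays are ignored so that a combined
    viability/caspase dataset can be triaged on either readout.
    """
    blocks = [b for b in dataset.blocks if b.assay == config.readout]
    if not blocks:
        raise ValueError(f"no blocks with readout {config.readout!r} in dataset")
    anchor_ids = {b.drugB.compound_id for b in blocks}
    if len(anchor_ids) != 1:
        raise ValueError(
            f"blocks mix anchor drugs on the B axis: {sorted(anchor_ids)}"
        )
    reports: list[SynergyReport] = []
    for block in blocks:
        nm = normalize_block(block)
        fitA, fitB = _fit_singles(nm, config)
        report = summarize_pair(
            nm,
            fitA,
            fitB,
            ci_max=config.ci_max,
            beta_max=config.beta_max,
            ci_policy=config.ci_policy,
            fa_band=config.fa_band,
        )
        if report.flags:
            logger.info("pair %s flagged: %s", report.pair_id, ", ".join(report.flags))
        reports.append(report)
    hits, excluded = select_hits(reports, config.ci_max, config.beta_max)
    logger.info(
        "%s stage: %d pairs scored, %d hits, %d excluded from gating",
        config.stage, len(reports), len(hits), len(excluded),
    )
    return ScreenResult(
        stage=config.stage,
        reports=reports,
        hits=hits,
        excluded=excluded,
        config=config,
    )


def aggregate_by_class(result: ScreenResult, dataset: ScreenDataset) -> pd.DataFrame:
    """Tally tested and hit counts per mechanism-of-action class.

    Classes come from the dataset's annotation table (missing compounds count
    as "unannotated"); rows are sorted by hit fraction descending, ties by
    class name. Only the non-anchor drug of each pair is classified.
    """
    hit_ids = set(result.hit_ids)
    tested: dict[str, int] = {}
    hit_counts: dict[str, int] = {}
    for r in result.reports:
        moa = dataset.annotation_for(r.drugA_id).moa_class
        tested[moa] = tested.get(moa, 0) + 1
        if r.pair_id in hit_ids:
            hit_counts[moa] = hit_counts.get(moa, 0) + 1
    rows = [
        (moa, n, hit_counts.get(moa, 0), hit_counts.get(moa, 0) / n)
        for moa, n in tested.items()
    ]
    frame = pd.DataFrame(rows, columns=["moa_class", "n_tested", "n_hits", "hit_fraction"])
    frame = frame.sort_values(
        ["hit_fraction", "moa_class"], ascending=[False, True]
    ).reset_index(drop=True)
    result.class_summary = frame
    return frame
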