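"""End-to-end orchestration: counts + distances -> indices -> models -> thresholds.

Given a cross-count table and exactly one distance source (an aligned
FASTA, a square distance CSV, or the packaged study matrix), the pipeline
writes the distance matrix, the tidy index table, per-barrier model
reports following the interaction-driven simplification rule, and the
threshold table for the configured completeness levels.  Every model
decision (interaction kept or dropped, excluded observations, skipped
subsets) is logged.  The analysis stage is deterministic: identical
inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import cross_data, indices, k2p, qglm, thresholds

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs and settings for one pipeline run.

    Exactly one of ``fasta``, ``distance_csv`` or ``use_fixture`` must
    provide the distance source.
    """

    cross_csv: Path
    out_dir: Path
    fasta: Optional[Path] = None
    distance_csv: Optional[Path] = None
    use_fixture: bool = False
    barriers: Sequence[str] = field(default_factory=lambda: list(indices.BARRIERS))
    levels: Sequence[float] = thresholds.DEFAULT_LEVELS
    alpha: float = 0.05

    def __post_init__(self) -> None:
        sources = sum([self.fasta is not None, self.distance_csv is not None,
                       bool(self.use_fixture)])
        if sources != 1:
            raise ValueError("exactly one distance source is required "
                             "(FASTA, distance CSV, or the packaged fixture)")
        for lv in self.levels:
            if not 0.0 < lv < 1.0:
                raise ValueError(f"completeness level {lv} outside (0, 1)")


def _load_distances(cfg: RunConfig) -> cross_data.DistanceMatrix:
    if cfg.use_fixture:
        return cross_data.table2_fixture()
    if cfg.distance_csv is not None:
        return cross_data.DistanceMatrix.from_csv(cfg.distance_csv)
    aln = k2p.AlignedSequences.from_fasta(cfg.fasta)
    return k2p.distance_matrix(aln)


def _check_labels(records, dist: cross_data.DistanceMatrix) -> None:
    known = set(dist.labels)
    for rec in records:
        if rec.cross_class == "backcross":
            cross_data.split_dam_code(rec.dam_code, dist.labels)  # raises if unknown
            continue
        for lab in (rec.female_pop, rec.male_pop):
            if lab not in known:
                raise PipelineError(
                    f"validation: population {lab!r} present in the count table "
                    f"but absent from the distance source {dist.labels}"
                )


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a summary dict of artifact paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        records = cross_data.read_cross_table(cfg.cross_csv)
    except Exception as exc:
        raise PipelineError(f"read_counts: {exc}") from exc
    logger.info("read %d aggregated cross records", len(records))

    try:
        dist = _load_distances(cfg)
    except Exception as exc:
        raise PipelineError(f"distances: {exc}") from exc
    _check_labels(records, dist)
    dist.to_csv(out / "distances.csv")
    dist.to_phylip(out / "distances.phy")

    try:
        idx = indices.indices_table(records, dist)
    except Exception as exc:
        raise PipelineError(f"indices: {exc}") from exc
    idx.to_csv(out / "indices.csv", index=False)

    reports: dict[str, dict] = {}
    gd_fits: dict[str, qglm.GlmFit] = {}
    text_blocks: list[str] = []
    for barrier in cfg.barriers:
        try:
            obs = indices.observations(records, dist, barrier)
            if len(obs) < 3:
                logger.warning("%s: only %d observations; skipped", barrier, len(obs))
                continue
            if barrier == "sterility":
                # one observation per hybrid-dam type: a single gd curve,
                # no female-population structure to simplify over
                seq = tuple(qglm.sequential_f_tests(
                    qglm.DesignSpec(barrier, ("intercept", "gd"), tuple(obs))))
                report = qglm.AnalysisReport(
                    response=barrier, route="gd_only", full_tests=seq,
                    interaction_test=None,
                    main_fit=qglm.gd_only_fit(obs, barrier), main_tests=seq,
                    per_population={}, per_population_tests={},
                    skipped_populations=(), alpha=cfg.alpha,
                )
            else:
                report = qglm.simplify_and_refit(
                    qglm.DesignSpec(barrier, qglm.TERMS, tuple(obs)), alpha=cfg.alpha
                )
            reports[barrier] = report.to_dict()
            text_blocks.append(qglm.report_text(report))
            gd_fits[barrier] = qglm.gd_only_fit(obs, barrier)
        except Exception as exc:
            raise PipelineError(f"fit[{barrier}]: {exc}") from exc

    with open(out / "models.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    (out / "models.txt").write_text("\n\n".join(text_blocks) + "\n")

    try:
        table = thresholds.table3_report(gd_fits, cfg.levels)
        thresholds.write_report(table, out / "thresholds.tsv", out / "thresholds.json")
    except Exception as exc:
        raise PipelineError(f"thresholds: {exc}") from exc

    logger.info("pipeline complete: %s", out)
    return {
        "out_dir": str(out),
        "n_records": len(records),
        "barriers": list(gd_fits),
        "artifacts": [
            "distances.csv", "distances.phy", "indices.csv",
            "models.json", "models.txt", "thresholds.tsv", "thresholds.json",
        ],
    }
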