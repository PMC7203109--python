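"""End-to-end RBR-ID pipeline: read -> filter -> normalize -> stats -> project -> smooth -> call.

Orchestrates the library modules over files on disk, writes per-peptide
statistics, the residue-level score track, called segments, a track plot and
a JSON run report with stage-by-stage counts, so a tally like "N
significantly depleted peptides" is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import projection, simulate, stats, table_io
from .smoothing import SmootherConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs, outputs and every analysis parameter of one run.

    Defaults match the library modules' own defaults; each one is surfaced
    here (and on the CLI) because the underlying method leaves them open.
    """

    table_path: str | Path = ""
    design_path: str | Path = ""
    fasta_path: str | Path = ""
    out_dir: str | Path = "rbrid_out"
    dialect: str = "generic-tsv"
    protein_accession: str = ""
    contaminant_patterns: tuple[str, ...] = table_io.DEFAULT_CONTAMINANT_PATTERNS
    alpha: float = 0.1
    imputation_floor_factor: float = 0.5
    test_scale: str = "linear"
    multimap_policy: str = "all"
    smoother: SmootherConfig = field(default_factory=SmootherConfig)
    threshold_quantile: float = 0.85
    min_segment_length: int = 10
    merge_gap: int = 5
    make_plot: bool = True


@dataclass
class RunReport:
    """Stage counts and parameters of a completed run."""

    peptides_read: int = 0
    contaminants_removed: int = 0
    peptides_tested: int = 0
    peptides_dropped_undetected: int = 0
    significant_peptides: int = 0
    peptides_located: int = 0
    peptides_unlocated: int = 0
    segments_called: int = 0
    parameters: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _plot_profile(profile, segments, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(10, 3.2))
    positions = range(1, len(profile) + 1)
    ax.plot(positions, profile.raw_score, lw=0.5, color="0.6", label="per-residue score")
    ax.plot(positions, profile.smoothed_score, lw=1.5, color="C0", label="smoothed")
    for seg in segments:
        ax.axvspan(seg.start, seg.end, color="C2", alpha=0.25)
    ax.set_xlabel("residue")
    ax.set_ylabel("RBR-ID score")
    ax.set_title(profile.accession)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_rbrid(config: PipelineConfig) -> RunReport:
    """Run the full analysis; writes outputs under ``config.out_dir``.

    Outputs: ``peptide_stats.tsv``, ``residue_profile.tsv``,
    ``segments.tsv``, ``profile.png`` and ``report.json``. On failure all
    partial outputs are removed and :class:`PipelineError` names the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report = RunReport(
        parameters={
            "alpha": config.alpha,
            "imputation_floor_factor": config.imputation_floor_factor,
            "test_scale": config.test_scale,
            "multimap_policy": config.multimap_policy,
            "threshold_quantile": config.threshold_quantile,
            "min_segment_length": config.min_segment_length,
            "merge_gap": config.merge_gap,
            "dialect": config.dialect,
            "smoother_spans": list(config.smoother.primary_spans),
            "smoother_bass": config.smoother.bass,
        }
    )

    stage = "read"
    try:
        records = table_io.read_peptide_table(config.table_path, config.dialect)
        design = table_io.read_design(config.design_path)
        proteins = table_io.read_protein_fasta(config.fasta_path)
        table_io.validate_against_design(records, design)
        report.peptides_read = len(records)
        accession = config.protein_accession or proteins[0].accession
        try:
            protein = next(p for p in proteins if p.accession == accession)
        except StopIteration:
            raise table_io.ValidationError(
                f"protein {accession!r} not found in {config.fasta_path}"
            ) from None

        stage = "filter"
        records = table_io.filter_contaminants(records, config.contaminant_patterns)
        report.contaminants_removed = report.peptides_read - len(records)
        if not records:
            raise table_io.ValidationError("no peptides left after contaminant filter")

        stage = "normalize"
        records = stats.normalize_run_intensities(records, design)

        stage = "statistics"
        pep_stats = stats.compute_peptide_stats(
            records,
            design,
            alpha=config.alpha,
            imputation_floor_factor=config.imputation_floor_factor,
            test_scale=config.test_scale,
        )
        report.peptides_tested = len(pep_stats)
        report.peptides_dropped_undetected = len(records) - len(pep_stats)
        report.significant_peptides = len(
            stats.significant_peptides(pep_stats, config.alpha)
        )

        stage = "projection"
        located = [
            (projection.locate_peptide(s.peptide_seq, protein), s.score)
            for s in pep_stats
        ]
        report.peptides_located = sum(1 for lp, _ in located if lp.intervals)
        report.peptides_unlocated = len(located) - report.peptides_located
        profile = projection.residue_score_profile(
            located,
            len(protein),
            multimap_policy=config.multimap_policy,
            accession=protein.accession,
            smoother=config.smoother,
        )

        stage = "segment-calling"
        segments = projection.call_rbr_segments(
            profile,
            threshold_quantile=config.threshold_quantile,
            min_length=config.min_segment_length,
            merge_gap=config.merge_gap,
        )
        report.segments_called = len(segments)

        stage = "write"
        paths = {
            "peptide_stats": out_dir / "peptide_stats.tsv",
            "residue_profile": out_dir / "residue_profile.tsv",
            "segments": out_dir / "segments.tsv",
            "report": out_dir / "report.json",
        }
        stats.stats_to_frame(pep_stats).to_csv(paths["peptide_stats"], sep="\t", index=False)
        written.append(paths["peptide_stats"])
        profile.to_frame().to_csv(paths["residue_profile"], sep="\t", index=False)
        written.append(paths["residue_profile"])
        projection.segments_to_frame(segments, protein.accession).to_csv(
            paths["segments"], sep="\t", index=False
        )
        written.append(paths["segments"])
        if config.make_plot:
            paths["plot"] = out_dir / "profile.png"
            _plot_profile(profile, segments, paths["plot"])
            written.append(paths["plot"])
        report.outputs = {k: str(v) for k, v in paths.items()}
        paths["report"].write_text(report.to_json())
        written.append(paths["report"])
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    logger.info(
        "run complete: %d read, %d contaminants removed, %d tested, "
        "%d significant, %d segment(s)",
        report.peptides_read,
        report.contaminants_removed,
        report.peptides_tested,
        report.significant_peptides,
        report.segments_called,
    )
    return report


def run_simulate(
    sim_config: simulate.SimulationConfig,
    truth: simulate.PlantedRBR,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Generate a synthetic experiment and write it as pipeline-ready files.

    Writes ``peptides.tsv`` (generic dialect), ``design.tsv``,
    ``protein.fasta`` and ``truth.tsv``; returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    protein = simulate.generate_protein_sequence(
        sim_config.protein_length, sim_config.seed
    )
    records, design, truth = simulate.simulate_experiment(protein, truth, sim_config)
    paths = {
        "table": out_dir / "peptides.tsv",
        "design": out_dir / "design.tsv",
        "fasta": out_dir / "protein.fasta",
        "truth": out_dir / "truth.tsv",
    }
    table_io.write_peptide_table(records, paths["table"])
    table_io.write_design(design, paths["design"])
    paths["fasta"].write_text(f">{protein.accession}\n{protein.residues}\n")
    simulate.write_truth(truth, sim_config.seed, paths["truth"])
    return paths
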