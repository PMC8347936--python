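"""End-to-end orchestration: simulate -> expression -> peaks -> integrate -> motifs.

Every stage reads and writes plain TSV/FASTA files under a single output
directory, so any stage can be re-run or inspected in isolation, and a
``RunReport`` records the record count after each processing step together
with the configuration echo.  All thresholds live in :class:`RunConfig`
defaults -- none are hard-coded in stage logic.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expression import DE_ALPHA, profile_expression
from .integrate import (
    CHIP_EFFECT_THRESHOLD,
    EXPR_EFFECT_THRESHOLD,
    filter_targets,
    match_platforms,
)
from .motifs import (
    DEFAULT_MOTIFS,
    cooccurrence_distance,
    distance_histogram,
    motif_frequency,
    scan_promoters,
)
from .peaks import (
    GENE_FLANK,
    WINDOW_ALPHA,
    WINDOW_SIZE,
    assign_genes_all,
    call_bound_all,
)
from .simulate import (
    SimulationConfig,
    generate_array_design,
    generate_chip_signal,
    generate_expression,
    generate_promoters,
    sample_truth,
)
from . import io

logger = logging.getLogger("promtarget.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, thresholds and stage toggles for one pipeline run."""

    outdir: str = "promtarget_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    run_de: bool = True
    run_peaks: bool = True
    run_integrate: bool = True
    run_motifs: bool = True
    # thresholds (the analysis constants)
    de_alpha: float = DE_ALPHA
    window_size: int = WINDOW_SIZE
    window_alpha: float = WINDOW_ALPHA
    chip_effect_threshold: float = CHIP_EFFECT_THRESHOLD
    expr_effect_threshold: float = EXPR_EFFECT_THRESHOLD
    gene_flank: int = GENE_FLANK
    # simulation parameters (forwarded to SimulationConfig; seed is shared)
    simulation: dict = field(default_factory=dict)
    # input paths, used when simulate is false
    design: str | None = None
    signal: str | None = None
    expression: str | None = None
    groups: str | None = None
    probe_map: str | None = None
    annotation: str | None = None
    promoters: str | None = None
    motif_table: str | None = None
    reference_motif: str = "EKLF"

    def __post_init__(self) -> None:
        for name in (
            "de_alpha",
            "window_alpha",
            "chip_effect_threshold",
            "expr_effect_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_size < 2 or self.gene_flank < 0:
            raise ValueError("invalid window size or gene flank")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


@dataclass
class RunReport:
    """Per-stage record counts plus provenance (config echo, version, seed)."""

    counts: dict[str, int]
    config: dict
    version: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["count", "value"]
        )

    def write(self, directory) -> None:
        directory = Path(directory)
        self.to_frame().to_csv(directory / "report.tsv", sep="\t", index=False)
        lines = [f"promtarget {self.version}, seed {self.seed}", ""]
        lines += [f"{k:>32} = {v}" for k, v in sorted(self.counts.items())]
        (directory / "report.txt").write_text("\n".join(lines) + "\n")
        (directory / "config_echo.yaml").write_text(yaml.safe_dump(self.config))


def _require(config: RunConfig, stage: str, **paths) -> None:
    for name, p in paths.items():
        if p is None:
            raise PipelineError(stage, f"no {name} path configured")
        if not Path(p).exists():
            raise PipelineError(stage, f"{name} file {p} does not exist")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in order and write all outputs.

    Identical config + seed reproduces byte-identical outputs.  Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    paths = {k: getattr(config, k) for k in (
        "design", "signal", "expression", "groups", "probe_map",
        "annotation", "promoters", "motif_table",
    )}

    if config.simulate:
        logger.info("[simulate] generating synthetic inputs")
        try:
            sim = config.simulation_config()
            design, annotation = generate_array_design(sim)
            truth = sample_truth(design, annotation, sim)
            signal = generate_chip_signal(design, truth, sim)
            matrix = generate_expression(annotation, truth, sim)
            promoters = generate_promoters(design, truth, sim)
        except (ValueError, KeyError) as exc:
            raise PipelineError("simulate", str(exc)) from exc
        inputs = outdir / "inputs"
        inputs.mkdir(exist_ok=True)
        io.write_design(design, inputs / "design.tsv")
        io.write_signal(signal, inputs / "chip_signal.tsv")
        io.write_expression(
            matrix,
            inputs / "expression.tsv",
            inputs / "groups.tsv",
            inputs / "probe_map.tsv",
        )
        io.write_annotation(annotation, inputs / "annotation.tsv")
        io.write_promoters(promoters, inputs / "promoters.fasta")
        io.write_motif_table(DEFAULT_MOTIFS, inputs / "motifs.tsv")
        io.write_truth(truth, inputs)
        paths = {
            "design": inputs / "design.tsv",
            "signal": inputs / "chip_signal.tsv",
            "expression": inputs / "expression.tsv",
            "groups": inputs / "groups.tsv",
            "probe_map": inputs / "probe_map.tsv",
            "annotation": inputs / "annotation.tsv",
            "promoters": inputs / "promoters.fasta",
            "motif_table": inputs / "motifs.tsv",
        }
        counts["sim_seq_ids"] = design.probes["seq_id"].nunique()
        counts["sim_spiked_seq_ids"] = len(truth.bound)
        counts["sim_spiked_genes"] = len(truth.de)

    gene_table = None
    if config.run_de:
        logger.info("[de] probe-set t-tests and gene calls")
        _require(
            config, "de",
            expression=paths["expression"], groups=paths["groups"],
            probe_map=paths["probe_map"],
        )
        try:
            matrix = io.read_expression(
                paths["expression"], paths["groups"], paths["probe_map"]
            )
            de = profile_expression(matrix, alpha=config.de_alpha)
        except ValueError as exc:
            raise PipelineError("de", str(exc)) from exc
        de.probe_table.to_csv(outdir / "probe_results.tsv", sep="\t")
        de.gene_table.to_csv(outdir / "gene_results.tsv", sep="\t")
        gene_table = de.gene_table
        counts["de_probe_sets"] = len(de.probe_table)
        counts["de_significant_probe_sets"] = de.n_significant_probe_sets
        counts["de_genes_tested"] = len(de.gene_table)
        counts["de_genes_removed"] = len(de.removed_genes)
        counts["de_genes"] = int(de.gene_table["de"].sum())

    calls = assignment = None
    if config.run_peaks:
        logger.info("[peaks] moving-window binding calls")
        _require(
            config, "peaks",
            design=paths["design"], signal=paths["signal"],
            annotation=paths["annotation"],
        )
        try:
            design = io.read_design(paths["design"])
            signal = io.read_signal(paths["signal"])
            annotation = io.read_annotation(paths["annotation"])
            windows, calls = call_bound_all(
                design, signal, w=config.window_size, alpha=config.window_alpha
            )
            assignment = assign_genes_all(design, annotation, flank=config.gene_flank)
        except ValueError as exc:
            raise PipelineError("peaks", str(exc)) from exc
        windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)
        calls.merge(assignment, on="seq_id").to_csv(
            outdir / "bound_calls.tsv", sep="\t", index=False
        )
        counts["peaks_seq_ids"] = len(calls)
        counts["peaks_windows"] = len(windows)
        counts["peaks_bound_seq_ids"] = int(calls["bound"].sum())
        counts["peaks_untestable_seq_ids"] = int((calls["status"] == "untestable").sum())
        counts["peaks_intergenic_seq_ids"] = int(assignment["intergenic"].sum())

    if config.run_integrate:
        logger.info("[integrate] matching platforms and filtering targets")
        if gene_table is None or calls is None:
            raise PipelineError(
                "integrate", "integration requires the de and peaks stages"
            )
        matched, n_pairs = match_platforms(gene_table, calls, assignment)
        targets = filter_targets(
            matched,
            chip_threshold=config.chip_effect_threshold,
            expr_threshold=config.expr_effect_threshold,
        )
        matched.to_csv(outdir / "matched_genes.tsv", sep="\t", index=False)
        targets.to_csv(outdir / "targets.tsv", sep="\t", index=False)
        counts["int_matched_genes"] = len(matched)
        counts["int_matched_pairs"] = n_pairs
        counts["int_targets"] = len(targets)
        counts["int_activated"] = int((targets["regulation"] == "activated").sum())
        counts["int_repressed"] = int((targets["regulation"] == "repressed").sum())

    if config.run_motifs:
        logger.info("[motifs] scanning promoters and ranking motifs")
        _require(config, "motifs", promoters=paths["promoters"])
        try:
            promoters = io.read_promoters(paths["promoters"])
            motifs = (
                io.read_motif_table(paths["motif_table"])
                if paths["motif_table"]
                else list(DEFAULT_MOTIFS)
            )
            if calls is not None:  # restrict to bound promoters when available
                bound_ids = set(calls.loc[calls["bound"], "seq_id"])
                promoters = {
                    k: v for k, v in promoters.items() if k in bound_ids
                } or promoters
            occurrences = scan_promoters(promoters, motifs)
        except ValueError as exc:
            raise PipelineError("motifs", str(exc)) from exc
        ranking = motif_frequency(occurrences)
        occurrences.to_csv(outdir / "motif_occurrences.tsv", sep="\t", index=False)
        ranking.to_csv(outdir / "motif_rank.tsv", sep="\t", index=False)
        ref = config.reference_motif
        ref_occ = occurrences[occurrences["motif"] == ref]
        dist_frames = []
        hist_frames = []
        for partner in sorted(set(occurrences["motif"]) - {ref}):
            rec = cooccurrence_distance(
                ref_occ, occurrences[occurrences["motif"] == partner]
            )
            rec.insert(0, "partner", partner)
            dist_frames.append(rec)
            hist = distance_histogram(rec)
            hist_bins = hist.bins.copy()
            hist_bins.insert(0, "partner", partner)
            hist_frames.append(hist_bins)
        distances = (
            pd.concat(dist_frames, ignore_index=True)
            if dist_frames
            else pd.DataFrame(columns=["partner", "seq_id", "distance"])
        )
        histograms = (
            pd.concat(hist_frames, ignore_index=True)
            if hist_frames
            else pd.DataFrame(columns=["partner", "bin_start", "bin_end", "count"])
        )
        distances.to_csv(outdir / "motif_distances.tsv", sep="\t", index=False)
        histograms.to_csv(outdir / "motif_histograms.tsv", sep="\t", index=False)
        counts["motif_occurrences"] = len(occurrences)
        counts["motif_promoters_scanned"] = len(promoters)
        counts["motif_distance_records"] = len(distances)

    report = RunReport(
        counts=counts, config=config.to_dict(), version=__version__, seed=config.seed
    )
    report.write(outdir)
    logger.info("pipeline complete: %s", outdir)
    return report


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("promtarget")
    root.handlers[:] = [handler]
    root.setLevel(logging.INFO if verbose else logging.WARNING)
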