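"""End-to-end orchestration: dedup -> trim -> profile -> QC -> peaks.

Mirrors the pipeline overview: aligned BAMs per sample are
quality-filtered and deduplicated, read_1 is trimmed to the footprint
length, strand coverages are combined under the both-strand-overlap
rule, replicates are normalized and averaged into one wiggle track per
condition, QC figures/tables are emitted, and — when GEM event files are
supplied — peaks are SNR-filtered, assigned to genes, and written out as
the gene-target table, the analysis file, BED and peak-sequence FASTA.
A provenance JSON captures parameters, seeds and per-stage read counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignments import (
    GenomeLayout,
    deduplicate,
    extract_read1,
    filter_quality,
    read_alignments,
    trim_reads,
)
from .footprint import compute_footprint, compute_footprint_aa
from .peaks import (
    assign_peaks_to_genes,
    build_gene_target_table,
    extract_peak_sequences,
    parse_gem_events,
    read_tss_table,
    snr_filter,
    write_gem_analysis_file,
    write_peaks_bed,
)
from .profiles import (
    background_normalize,
    combine_strands,
    coverage_by_strand,
    merge_replicates,
    write_wig,
)
from .qc import bin_reads, correlate_samples, peak_shape_profiles, tss_metaprofile

logger = logging.getLogger("exofold")

__all__ = ["SampleEntry", "PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending file."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[{stage}] {detail}")


@dataclass
class SampleEntry:
    sample_id: str
    condition: str
    replicate: int
    bam: str


@dataclass
class PipelineConfig:
    """Validated run description (loadable from YAML)."""

    samples: list[SampleEntry]
    chrom_sizes: str
    tss: str
    out_dir: str
    fasta: str | None = None
    gem_events: dict[str, str] = field(default_factory=dict)
    trim_length: int | None = None
    tf_length_nt: int | None = None
    tf_length_aa: int | None = None
    min_mapq: int = 20
    min_snr: float = 2.0
    tss_distance: int = 1000
    bin_size: int = 1000
    tss_flank: int = 1000
    peak_flank: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleEntry(**s) for s in raw.pop("samples")]
        return cls(samples=samples, **raw)

    def validate(self) -> None:
        """Fail before any compute if inputs are missing or inconsistent."""
        if not self.samples:
            raise ValueError("no samples in config")
        for path in [self.chrom_sizes, self.tss, self.fasta, *[
            s.bam for s in self.samples
        ], *self.gem_events.values()]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured path does not exist: {path}")
        if (
            self.trim_length is None
            and self.tf_length_nt is None
            and self.tf_length_aa is None
        ):
            raise ValueError(
                "provide trim_length, tf_length_nt or tf_length_aa"
            )
        by_condition: dict[str, int] = {}
        for s in self.samples:
            by_condition[s.condition] = by_condition.get(s.condition, 0) + 1
        for condition, n in by_condition.items():
            if n == 1:
                logger.warning(
                    "condition %s has a single replicate; correlation QC "
                    "needs at least two",
                    condition,
                )

    def resolve_trim_length(self) -> int:
        if self.trim_length is not None:
            return self.trim_length
        if self.tf_length_nt is not None:
            return compute_footprint(self.tf_length_nt).tf_footprint_bp
        return compute_footprint_aa(self.tf_length_aa).tf_footprint_bp


def _finalize(path: Path) -> Path:
    """Incomplete-marker helper: returns the temp path to write to."""
    return path.with_suffix(path.suffix + ".incomplete")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the provenance record.

    Any stage failure raises :class:`PipelineError` naming the stage;
    files are written to ``*.incomplete`` names and renamed only once
    complete, so an aborted run leaves no ambiguous outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "exofold_version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_mapq": config.min_mapq,
            "min_snr": config.min_snr,
            "tss_distance": config.tss_distance,
            "bin_size": config.bin_size,
            "tss_flank": config.tss_flank,
            "peak_flank": config.peak_flank,
        },
        "samples": {},
        "outputs": [],
    }

    def emit(relpath: str, writer) -> Path:
        """Write through a .incomplete temp name, rename when done."""
        final = out / relpath
        tmp = _finalize(final)
        writer(tmp)
        tmp.rename(final)
        provenance["outputs"].append(str(final))
        return final

    try:
        layout = GenomeLayout.from_chrom_sizes(config.chrom_sizes)
        tss = read_tss_table(config.tss)
    except Exception as exc:
        raise PipelineError("load-annotation", str(exc)) from exc

    trim_length = config.resolve_trim_length()
    provenance["parameters"]["trim_length"] = trim_length
    logger.info("trim length: %d bp", trim_length)

    per_sample_read1 = {}
    binned = []
    for sample in config.samples:
        try:
            pairs, tally = read_alignments(sample.bam, layout)
            kept = filter_quality(pairs, config.min_mapq)
            deduped, n_dup = deduplicate(kept)
            read1s = extract_read1(deduped)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("dedup", f"{sample.bam}: {exc}") from exc
        per_sample_read1[sample.sample_id] = read1s
        provenance["samples"][sample.sample_id] = {
            "condition": sample.condition,
            "replicate": sample.replicate,
            "pairs_mapped": tally.get("pairs", 0),
            "pairs_after_quality": len(kept),
            "pairs_after_dedup": len(deduped),
            "duplicates_removed": n_dup,
            "dropped": {
                k: v for k, v in tally.items() if k.startswith("dropped")
            },
        }
        logger.info(
            "%s: %d pairs, %d after mapq>=%d, %d after dedup",
            sample.sample_id, tally.get("pairs", 0), len(kept),
            config.min_mapq, len(deduped),
        )
        binned.append(
            bin_reads(read1s, layout, config.bin_size, sample.sample_id)
        )

    # replicate-correlation QC across all samples
    if len(binned) >= 2:
        try:
            corr = correlate_samples(
                binned, fig_path=out / "sample_correlation.png"
            )
            emit("sample_correlation.tsv", lambda p: corr.to_csv(p, sep="\t"))
        except Exception as exc:
            raise PipelineError("qc-correlation", str(exc)) from exc

    conditions: dict[str, list] = {}
    for sample in config.samples:
        conditions.setdefault(sample.condition, []).append(sample)

    merged_profiles = {}
    for condition, members in conditions.items():
        try:
            replicate_profiles = []
            for sample in members:
                trimmed = trim_reads(
                    per_sample_read1[sample.sample_id], trim_length, layout
                )
                fwd, rev = coverage_by_strand(trimmed, layout)
                replicate_profiles.append(
                    background_normalize(combine_strands(fwd, rev))
                )
            merged = merge_replicates(replicate_profiles)
            merged_profiles[condition] = merged
            emit(
                f"{condition}.wig",
                lambda p, prof=merged, cond=condition: write_wig(prof, p, cond),
            )
            emit(
                f"{condition}_tss_profile.tsv",
                lambda p, prof=merged: tss_metaprofile(
                    prof, tss, config.tss_flank,
                    fig_path=out / f"{condition}_tss_profile.png",
                    tsv_path=p,
                ),
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("profile", f"condition {condition}: {exc}") from exc

    if config.gem_events:
        try:
            assignments = {}
            for condition, events_path in config.gem_events.items():
                called = parse_gem_events(events_path, condition)
                kept_peaks = snr_filter(called, config.min_snr)
                assignments[condition] = assign_peaks_to_genes(
                    kept_peaks, tss, config.tss_distance
                )
                emit(
                    f"{condition}_peaks.bed",
                    lambda p, pk=kept_peaks: write_peaks_bed(pk, p),
                )
                if config.fasta is not None:
                    emit(
                        f"{condition}_peak_seqs.fasta",
                        lambda p, pk=kept_peaks: extract_peak_sequences(
                            pk, config.fasta, p
                        ),
                    )
                cond_read1 = [
                    r
                    for s in conditions.get(condition, [])
                    for r in per_sample_read1[s.sample_id]
                ]
                if cond_read1 and kept_peaks:
                    peak_shape_profiles(
                        cond_read1, kept_peaks, layout, config.peak_flank,
                        fig_prefix=str(out / f"{condition}_peak_shape"),
                        tsv_path=out / f"{condition}_peak_shape.tsv",
                    )
                provenance["samples"].setdefault("peaks", {})[condition] = {
                    "called": len(called),
                    "after_snr": len(kept_peaks),
                    "assignments": len(assignments[condition]),
                }
            emit(
                "geneTargets.csv",
                lambda p: build_gene_target_table(assignments, tss, p),
            )
            emit(
                "gemAnalysis.csv",
                lambda p: write_gem_analysis_file(assignments, p),
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("peaks", str(exc)) from exc

    emit(
        "provenance.json",
        lambda p: Path(p).write_text(json.dumps(provenance, indent=2, sort_keys=True)),
    )
    return provenance
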