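"""Peak post-processing: SNR filtering, gene assignment, and text outputs.

Peak discovery itself is delegated to GEM (an external event finder);
this module consumes its tab-delimited events file.  Each peak's IP
strength is divided by the expected (control) strength at that position
to give an SNR, peaks with SNR <= 2 are discarded, and survivors are
assigned to every gene whose TSS lies strictly within 1000 bp of the
peak center — upstream or downstream, and to both genes when two
qualify.  The two main text outputs are the gene-target table (peaks per
gene per condition) and the per-assignment analysis file.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "Peak",
    "TssAnnotation",
    "PeakAssignment",
    "parse_gem_events",
    "read_tss_table",
    "snr_filter",
    "assign_peaks_to_genes",
    "build_gene_target_table",
    "write_gem_analysis_file",
    "write_peaks_bed",
    "extract_peak_sequences",
]

SNR_PSEUDOCOUNT = 1.0


@dataclass(frozen=True, slots=True)
class Peak:
    """A called binding event; ``position`` is the 0-based center."""

    chrom: str
    position: int
    ip_strength: float
    expected_strength: float
    snr: float
    qvalue_neglog: float = 0.0
    condition: str = ""


@dataclass(frozen=True, slots=True)
class TssAnnotation:
    """A gene's transcription start site (0-based) and orientation."""

    gene_id: str
    chrom: str
    position: int
    strand: str


@dataclass(frozen=True, slots=True)
class PeakAssignment:
    """A peak-gene link; ``distance`` is signed, negative = upstream of
    the TSS in the gene's orientation."""

    peak: Peak
    gene_id: str
    distance: int


def _compute_snr(ip: float, expected: float) -> float:
    return ip / (expected if expected > 0 else SNR_PSEUDOCOUNT)


def parse_gem_events(path: str | Path, condition: str = "") -> list[Peak]:
    """Parse a GEM "GEM events" file into peaks.

    The file is tab-delimited with a header; the ``Position`` column is
    ``chrom:coordinate`` (1-based, converted to 0-based here).  The
    expected strength is taken from GEM's ``Expectd`` column (its header
    spelling), falling back to ``Expected`` or ``Control``; if none is
    present the expected strength is recorded as 0 (so the SNR falls back
    to the pseudocount) and a warning is emitted.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            return []
        header = [h.strip() for h in header_line.rstrip("\n").split("\t")]
        lower = [h.lower() for h in header]

        def find(*names: str) -> int | None:
            for name in names:
                if name in lower:
                    return lower.index(name)
            return None

        pos_col = find("position")
        ip_col = find("ip")
        exp_col = find("expectd", "expected", "control")
        q_col = next(
            (i for i, h in enumerate(lower) if h.startswith("q_")), None
        )
        if pos_col is None or ip_col is None:
            raise ValueError(f"{path}: header lacks Position/IP columns")
        if exp_col is None:
            warnings.warn(
                f"{path}: no expected/control column; expected strength set "
                "to 0 and SNR computed against the pseudocount"
            )
        peaks: list[Peak] = []
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            loc = fields[pos_col].strip()
            if ":" not in loc:
                raise ValueError(
                    f"{path}:{lineno}: malformed Position field {loc!r}"
                )
            chrom, _, coord = loc.rpartition(":")
            try:
                position = int(coord) - 1
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed Position field {loc!r}"
                ) from exc
            ip = float(fields[ip_col])
            expected = float(fields[exp_col]) if exp_col is not None else 0.0
            qval = float(fields[q_col]) if q_col is not None else 0.0
            peaks.append(
                Peak(
                    chrom=chrom,
                    position=position,
                    ip_strength=ip,
                    expected_strength=expected,
                    snr=_compute_snr(ip, expected),
                    qvalue_neglog=qval,
                    condition=condition,
                )
            )
    return peaks


def read_tss_table(path: str | Path) -> list[TssAnnotation]:
    """Read a TSS annotation (TSV/CSV: gene_id, chrom, tss_position, strand).

    Positions in the file are 1-based and converted to 0-based here.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"gene_id", "chrom", "tss_position", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    return [
        TssAnnotation(r.gene_id, r.chrom, int(r.tss_position) - 1, r.strand)
        for r in df.itertuples()
    ]


def write_tss_table(tss: Sequence[TssAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss_position\tstrand\n")
        for t in tss:
            fh.write(f"{t.gene_id}\t{t.chrom}\t{t.position + 1}\t{t.strand}\n")


def snr_filter(peaks: Iterable[Peak], min_snr: float = 2.0) -> list[Peak]:
    """Keep peaks with SNR strictly greater than ``min_snr``.

    The boundary is removed: a peak at exactly SNR 2 is filtered out.
    """
    return [p for p in peaks if p.snr > min_snr]


def assign_peaks_to_genes(
    peaks: Iterable[Peak],
    tss: Sequence[TssAnnotation],
    max_distance: int = 1000,
) -> list[PeakAssignment]:
    """Link each peak to every gene with a TSS strictly closer than
    ``max_distance`` bp on the same chromosome.

    The distance is signed by gene orientation: negative means the peak
    lies upstream (promoter side) of the TSS.  A peak can yield zero, one
    or several assignments.
    """
    by_chrom: dict[str, list[TssAnnotation]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    assignments: list[PeakAssignment] = []
    for peak in peaks:
        for t in by_chrom.get(peak.chrom, ()):
            offset = peak.position - t.position
            if abs(offset) >= max_distance:
                continue
            distance = offset if t.strand == "+" else -offset
            assignments.append(PeakAssignment(peak, t.gene_id, distance))
    return assignments


def build_gene_target_table(
    assignments_by_condition: dict[str, Sequence[PeakAssignment]],
    tss: Sequence[TssAnnotation],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Count assigned peaks per gene per condition.

    Rows cover *every* gene in the TSS annotation so that absence of
    binding is explicit (count 0); a gene is a target in a condition iff
    its count is >= 1.  Written as CSV when ``path`` is given.
    """
    genes = [t.gene_id for t in tss]
    table = pd.DataFrame(
        0, index=pd.Index(genes, name="gene_id"),
        columns=list(assignments_by_condition),
        dtype=int,
    )
    for condition, assignments in assignments_by_condition.items():
        for a in assignments:
            table.loc[a.gene_id, condition] += 1
    if path is not None:
        table.to_csv(path)
    return table


def write_gem_analysis_file(
    assignments_by_condition: dict[str, Sequence[PeakAssignment]],
    path: str | Path,
) -> None:
    """Write one row per peak-gene assignment (positions 1-based in file)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["condition", "chrom", "position", "ip_strength", "snr",
             "gene_id", "distance"]
        )
        for condition, assignments in assignments_by_condition.items():
            for a in assignments:
                writer.writerow(
                    [condition, a.peak.chrom, a.peak.position + 1,
                     f"{a.peak.ip_strength:g}", f"{a.peak.snr:g}",
                     a.gene_id, a.distance]
                )


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """BED6 of peak centers (single-base intervals, score = SNR)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.position}\t{p.position + 1}\tpeak_{i}\t"
                f"{p.snr:g}\t.\n"
            )


def extract_peak_sequences(
    peaks: Sequence[Peak],
    genome_fasta: str | Path,
    path: str | Path,
    width: int = 60,
) -> None:
    """Write the ``width``-bp sequence centered on each peak as FASTA.

    The window ``[position - width//2, position + width - width//2)`` is
    clipped at chromosome ends (with a warning); headers name the
    extracted region as ``chrom:start-end`` (1-based, inclusive), ready
    for MEME.
    """
    genome = Fasta(str(genome_fasta))
    with open(path, "w") as fh:
        for p in peaks:
            if p.chrom not in genome:
                raise ValueError(
                    f"chromosome {p.chrom!r} missing from {genome_fasta}"
                )
            chrom_len = len(genome[p.chrom])
            start = p.position - width // 2
            end = start + width
            if start < 0 or end > chrom_len:
                warnings.warn(
                    f"peak window at {p.chrom}:{p.position} clipped to "
                    "chromosome bounds"
                )
                start, end = max(0, start), min(chrom_len, end)
            seq = genome[p.chrom][start:end].seq
            fh.write(f">{p.chrom}:{start + 1}-{end}\n{seq}\n")
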