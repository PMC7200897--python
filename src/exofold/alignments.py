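"""Aligned paired-end read model and the read-level filtering stages.

ChIP-exo libraries are paired-end: the 5' end of read_1 is placed by the
lambda-exonuclease stop at the protein-DNA crosslink, while read_2's
position comes from random sonication.  PCR duplicates are therefore
defined as read pairs sharing *both* the read_1 and the read_2 position
(identical sonication breakpoints are vanishingly unlikely), and the
informative coordinate downstream is read_1's 5' end.

Coordinates are 0-based, half-open everywhere in this package; the 5'
position of a minus-strand read is its rightmost aligned base.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

__all__ = [
    "GenomeLayout",
    "AlignedReadPair",
    "Read1",
    "TrimmedRead",
    "read_alignments",
    "write_alignments",
    "filter_quality",
    "deduplicate",
    "extract_read1",
    "trim_reads",
]


class GenomeLayout:
    """Ordered mapping of chromosome name to length in bp.

    Chromosome order is stable and propagates to every output (BAM
    headers, wiggle tracks, genome-wide bin vectors).
    """

    def __init__(self, sizes: dict[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, dict) else list(sizes)
        if not items:
            raise ValueError("genome layout needs at least one chromosome")
        for name, length in items:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._sizes: dict[str, int] = dict(items)

    @property
    def chroms(self) -> list[str]:
        return list(self._sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self._sizes == other._sizes

    def items(self):
        return self._sizes.items()

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column ``chrom<TAB>length`` table (UCSC chrom.sizes)."""
        items = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'chrom length'")
                items.append((fields[0], int(fields[1])))
        return cls(items)

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")

    def __repr__(self) -> str:
        return f"GenomeLayout({len(self)} chroms, {self.total_length} bp)"


@dataclass(frozen=True, slots=True)
class AlignedReadPair:
    """One properly mapped paired-end fragment (both mates on one chromosome)."""

    name: str
    chrom: str
    r1_strand: str  # '+' or '-'
    r1_five_prime: int
    r2_five_prime: int
    mapq: int
    r1_length: int = 75

    @property
    def dedup_key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.r1_strand, self.r1_five_prime, self.r2_five_prime)


@dataclass(frozen=True, slots=True)
class Read1:
    """The exonuclease-defined mate of a deduplicated pair."""

    chrom: str
    strand: str
    five_prime: int
    length: int = 75


@dataclass(frozen=True, slots=True)
class TrimmedRead:
    """A read_1 extended from its 5' end to a fixed trim length.

    ``[start, end)`` half-open; for '+' reads ``start`` is the 5' end,
    for '-' reads ``end - 1`` is.
    """

    chrom: str
    strand: str
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start


def _five_prime(rec: pysam.AlignedSegment) -> int:
    if rec.is_reverse:
        return rec.reference_end - 1
    return rec.reference_start


def read_alignments(
    path: str | Path, layout: GenomeLayout
) -> tuple[list[AlignedReadPair], Counter]:
    """Load properly paired primary alignments from a SAM/BAM file.

    Secondary, supplementary, unpaired and discordant records are dropped
    and counted in the returned tally (keys ``dropped_secondary``,
    ``dropped_unpaired``, ``dropped_improper``).  The pair mapq is the
    minimum of the two mates' mapping qualities.

    Returns ``(pairs, tally)``; ``tally['pairs']`` counts the pairs kept.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"alignment file not found: {path}")
    mode = "rb" if path.suffix == ".bam" else "r"
    tally: Counter = Counter()
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[AlignedReadPair] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                tally["dropped_secondary"] += 1
                continue
            if not rec.is_paired or rec.is_unmapped or rec.mate_is_unmapped:
                tally["dropped_unpaired"] += 1
                continue
            if not rec.is_proper_pair or rec.reference_id != rec.next_reference_id:
                tally["dropped_improper"] += 1
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            r1, r2 = (rec, mate) if rec.is_read1 else (mate, rec)
            chrom = r1.reference_name
            if chrom not in layout:
                raise ValueError(f"chromosome {chrom!r} not in genome layout")
            pairs.append(
                AlignedReadPair(
                    name=r1.query_name,
                    chrom=chrom,
                    r1_strand="-" if r1.is_reverse else "+",
                    r1_five_prime=_five_prime(r1),
                    r2_five_prime=_five_prime(r2),
                    mapq=min(r1.mapping_quality, r2.mapping_quality),
                    r1_length=r1.query_length or r1.infer_query_length() or 75,
                )
            )
            tally["pairs"] += 1
    if pending:
        tally["dropped_unpaired"] += len(pending)
    return pairs, tally


def write_alignments(
    pairs: Sequence[AlignedReadPair], layout: GenomeLayout, path: str | Path
) -> None:
    """Write pairs as a SAM/BAM file (extension decides the format).

    Records carry proper-pair flags and a full-length match CIGAR so that
    strand-aware 5' positions round-trip exactly.
    """
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in layout.items()],
    }
    tid = {name: i for i, name in enumerate(layout.chroms)}
    mode = "wb" if path.suffix == ".bam" else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for pair in pairs:
            chrom_len = layout[pair.chrom]

            def span(strand: str, five: int) -> tuple[int, int]:
                # clamp on-reference while keeping the 5' coordinate
                if strand == "+":
                    start = max(0, min(five, chrom_len - 1))
                    return start, min(pair.r1_length, chrom_len - start)
                start = max(0, five - pair.r1_length + 1)
                return start, five + 1 - start

            r2_strand = "-" if pair.r1_strand == "+" else "+"
            starts = {
                True: span(pair.r1_strand, pair.r1_five_prime),
                False: span(r2_strand, pair.r2_five_prime),
            }
            for is_r1 in (True, False):
                strand = pair.r1_strand if is_r1 else r2_strand
                start, length = starts[is_r1]
                mate_start, _ = starts[not is_r1]
                seg = pysam.AlignedSegment()
                seg.query_name = pair.name
                seg.reference_id = tid[pair.chrom]
                seg.reference_start = start
                seg.mapping_quality = pair.mapq
                seg.cigartuples = [(0, length)]
                seg.query_sequence = "N" * length
                seg.query_qualities = pysam.qualitystring_to_array("I" * length)
                flag = 0x1 | 0x2  # paired, proper
                flag |= 0x40 if is_r1 else 0x80
                if strand == "-":
                    flag |= 0x10
                else:
                    flag |= 0x20  # mate reverse (pairs are FR)
                seg.flag = flag
                seg.next_reference_id = tid[pair.chrom]
                seg.next_reference_start = mate_start
                out.write(seg)


def filter_quality(
    pairs: Iterable[AlignedReadPair], min_mapq: int = 20
) -> list[AlignedReadPair]:
    """Drop pairs with mapping quality below ``min_mapq`` (default 20)."""
    return [p for p in pairs if p.mapq >= min_mapq]


def deduplicate(
    pairs: Iterable[AlignedReadPair],
) -> tuple[list[AlignedReadPair], int]:
    """Remove PCR duplicates.

    Pairs are duplicates when they share chromosome, read_1 strand and the
    5' positions of both mates; the first pair seen in input order
    represents its group.  Returns ``(unique_pairs, n_removed)``.
    """
    seen: set[tuple[str, str, int, int]] = set()
    kept: list[AlignedReadPair] = []
    removed = 0
    for pair in pairs:
        key = pair.dedup_key
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(pair)
    return kept, removed


def extract_read1(pairs: Iterable[AlignedReadPair]) -> list[Read1]:
    """Keep only read_1 of each pair (the exonuclease-positioned mate)."""
    return [
        Read1(p.chrom, p.r1_strand, p.r1_five_prime, p.r1_length) for p in pairs
    ]


def trim_reads(
    read1s: Iterable[Read1], trim_length: int, layout: GenomeLayout
) -> list[TrimmedRead]:
    """Extend each read_1 from its 5' end to ``trim_length`` bases.

    '+' reads span ``[five_prime, five_prime + L)``; '-' reads span
    ``[five_prime - L + 1, five_prime + 1)``.  Spans are clipped to the
    chromosome (clipped reads keep their remaining width), so signal next
    to chromosome ends is preserved rather than discarded.
    """
    if trim_length < 1:
        raise ValueError(f"trim_length must be >= 1, got {trim_length}")
    trimmed: list[TrimmedRead] = []
    for read in read1s:
        chrom_len = layout[read.chrom]
        if read.strand == "+":
            start, end = read.five_prime, read.five_prime + trim_length
        else:
            start, end = read.five_prime - trim_length + 1, read.five_prime + 1
        start = max(0, start)
        end = min(chrom_len, end)
        if end <= start:
            warnings.warn(
                f"read at {read.chrom}:{read.five_prime} lies outside the "
                "chromosome after trimming; dropped"
            )
            continue
        trimmed.append(TrimmedRead(read.chrom, read.strand, start, end))
    return trimmed
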