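"""Synthetic ChIP-exo data and the graded-noise validation design.

The generator emulates what lambda-exonuclease digestion does to a bound
factor's neighbourhood: read_1 5' ends pile up at the two borders of
each planted site (center +/- footprint/2, plus-strand reads on the left
border, minus-strand on the right, with a small Gaussian jitter), while
read_2 is placed at a sonication-like insert distance (Normal(225, 75),
75 bp reads) outward from read_1.  Background reads and PCR duplicates
are injected on top, and every dataset is a pure function of its seed.

The validation design mirrors a graded-noise experiment: a pooled signal
dataset and a pooled uniform-noise dataset are subsampled without
replacement into 100,000-read mixtures at 0/25/50/75/100% noise, two
independently seeded pseudo-replicates per grade, and each mixture is
pushed through the full pipeline to watch replicate correlation and
promoter enrichment degrade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignments import (
    AlignedReadPair,
    GenomeLayout,
    deduplicate,
    extract_read1,
    filter_quality,
    trim_reads,
)
from .peaks import TssAnnotation
from .profiles import (
    background_normalize,
    combine_strands,
    coverage_by_strand,
    merge_replicates,
)
from .qc import bin_reads, correlate_samples, promoter_enrichment, tss_metaprofile

__all__ = [
    "SimConfig",
    "MixSpec",
    "SignalSim",
    "toy_layout",
    "write_toy_fasta",
    "promoter_annotation",
    "simulate_signal",
    "simulate_noise",
    "mix_datasets",
    "run_noise_validation",
]

SIM_MAPQ = 42  # bowtie2's maximum; simulated alignments are unambiguous


@dataclass
class SimConfig:
    """Parameters of the planted-site signal generator."""

    layout: GenomeLayout
    n_sites: int = 20
    site_positions: Sequence[tuple[str, int]] | None = None
    footprint_bp: int = 19
    reads_per_site: int = 100
    border_jitter_sd: float = 1.5
    # exonuclease digestion leaves little unprotected DNA: a high-quality
    # library is dominated by border reads, so background defaults low
    background_fraction: float = 0.05
    read_length: int = 75
    insert_mean: float = 225.0
    insert_sd: float = 75.0
    pcr_duplicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 0 or self.reads_per_site < 0:
            raise ValueError("counts must be non-negative")
        for frac in (self.background_fraction, self.pcr_duplicate_rate):
            if not 0 <= frac < 1:
                raise ValueError(f"fraction {frac} outside [0, 1)")
        if min(length for _, length in self.layout.items()) < self.footprint_bp:
            raise ValueError("footprint exceeds the shortest chromosome")


@dataclass(frozen=True)
class MixSpec:
    """One mixed pseudo-replicate: how many signal and noise reads."""

    noise_fraction: float
    total_reads: int = 100_000
    seed: int = 0

    @property
    def n_signal(self) -> int:
        return round(self.total_reads * (1.0 - self.noise_fraction))

    @property
    def n_noise(self) -> int:
        return self.total_reads - self.n_signal


@dataclass
class SignalSim:
    """Simulated signal dataset plus its ground truth.

    ``sites`` has one row per planted site (site_id, chrom, center,
    n_plus, n_minus); ``reads`` one row per pair in output order
    (name, site_id with -1 for background, strand, r1_five_prime,
    is_duplicate).  PCR-duplicate copies are appended after all base
    pairs, so :func:`exofold.alignments.deduplicate` drops exactly the
    flagged rows.
    """

    pairs: list[AlignedReadPair]
    sites: pd.DataFrame
    reads: pd.DataFrame


def toy_layout(
    n_chroms: int = 2, chrom_length: int = 200_000, prefix: str = "chr"
) -> GenomeLayout:
    """A small uniform genome for simulations (default 2 x 200 kb)."""
    return GenomeLayout(
        {f"{prefix}{i + 1}": chrom_length for i in range(n_chroms)}
    )


def write_toy_fasta(layout: GenomeLayout, path, seed: int = 0) -> None:
    """Random A/C/G/T sequence for each chromosome (60-column FASTA)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for name, length in layout.items():
            fh.write(f">{name}\n")
            seq = "".join(rng.choice(bases, size=length))
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60] + "\n")


def promoter_annotation(
    layout: GenomeLayout,
    n_genes: int,
    n_bound: int,
    seed: int = 0,
    site_offset: int = 200,
    margin: int = 2000,
) -> tuple[list[TssAnnotation], list[tuple[str, int]]]:
    """Evenly spaced genes with binding sites upstream of a bound subset.

    Genes are laid out on alternating strands at regular intervals
    (at least ``margin`` from chromosome ends); the first ``n_bound``
    genes (chosen at random) get a planted site ``site_offset`` bp
    upstream of their TSS in gene orientation.  Returns the TSS list and
    the site positions to hand to :class:`SimConfig`.
    """
    rng = np.random.default_rng(seed)
    chroms = layout.chroms
    lengths = np.array([layout[c] for c in chroms], dtype=float)
    per_chrom = np.maximum(1, np.round(n_genes * lengths / lengths.sum()).astype(int))
    while per_chrom.sum() > n_genes:
        per_chrom[np.argmax(per_chrom)] -= 1
    while per_chrom.sum() < n_genes:
        per_chrom[np.argmin(per_chrom)] += 1
    tss: list[TssAnnotation] = []
    gene_no = 0
    for chrom, k in zip(chroms, per_chrom):
        usable = layout[chrom] - 2 * margin
        if usable <= 0:
            raise ValueError(f"chromosome {chrom} shorter than 2x margin")
        positions = margin + (np.arange(k) + 0.5) / k * usable
        for pos in positions.astype(int):
            strand = "+" if gene_no % 2 == 0 else "-"
            tss.append(TssAnnotation(f"gene{gene_no:04d}", chrom, int(pos), strand))
            gene_no += 1
    bound_idx = rng.choice(len(tss), size=min(n_bound, len(tss)), replace=False)
    sites = []
    for i in sorted(bound_idx):
        t = tss[i]
        center = t.position - site_offset if t.strand == "+" else t.position + site_offset
        sites.append((t.chrom, int(center)))
    return tss, sites


def _place_read2(
    rng: np.random.Generator,
    r1_strand: np.ndarray,
    r1_pos: np.ndarray,
    chrom_lens: np.ndarray,
    read_length: int,
    insert_mean: float,
    insert_sd: float,
) -> np.ndarray:
    insert = np.maximum(
        read_length,
        np.round(rng.normal(insert_mean, insert_sd, size=len(r1_pos))),
    ).astype(np.int64)
    r2 = np.where(r1_strand == 1, r1_pos + insert - 1, r1_pos - insert + 1)
    return np.clip(r2, 0, chrom_lens - 1)


def simulate_signal(config: SimConfig) -> SignalSim:
    """Generate border reads around planted sites, plus background and
    PCR duplicates, with a full truth table.

    Half the reads of each site come from the left border on the plus
    strand (read_1 5' at center - footprint//2 + jitter), half from the
    right border on the minus strand (center + footprint//2 + jitter).
    Base pairs are guaranteed distinct under the PCR-duplicate key (the
    sonication-random read_2 makes collisions implausible), so the
    injected duplicate copies are exactly what deduplication removes.
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    chroms = layout.chroms
    chrom_len = {c: layout[c] for c in chroms}

    if config.site_positions is not None:
        sites = [(c, int(p)) for c, p in config.site_positions]
    else:
        lengths = np.array([chrom_len[c] for c in chroms], dtype=float)
        margin = int(config.footprint_bp + config.insert_mean + 3 * config.insert_sd)
        sites = []
        for _ in range(config.n_sites):
            ci = rng.choice(len(chroms), p=lengths / lengths.sum())
            c = chroms[ci]
            if chrom_len[c] <= 2 * margin:
                raise ValueError(
                    f"chromosome {c} too short for site geometry (margin {margin})"
                )
            sites.append((c, int(rng.integers(margin, chrom_len[c] - margin))))
    for c, p in sites:
        if not 0 <= p < chrom_len[c]:
            raise ValueError(f"site {c}:{p} outside the genome")

    half = config.footprint_bp // 2
    rec_chrom: list[str] = []
    rec_strand: list[int] = []  # 1 = '+', 0 = '-'
    rec_pos: list[int] = []
    rec_site: list[int] = []
    site_rows = []
    for site_id, (c, center) in enumerate(sites):
        n_plus = config.reads_per_site // 2
        n_minus = config.reads_per_site - n_plus
        jit_p = np.round(
            rng.normal(0.0, config.border_jitter_sd, size=n_plus)
        ).astype(np.int64)
        jit_m = np.round(
            rng.normal(0.0, config.border_jitter_sd, size=n_minus)
        ).astype(np.int64)
        plus = np.clip(center - half + jit_p, 0, chrom_len[c] - 1)
        minus = np.clip(center + half + jit_m, 0, chrom_len[c] - 1)
        rec_chrom += [c] * (n_plus + n_minus)
        rec_strand += [1] * n_plus + [0] * n_minus
        rec_pos += list(plus) + list(minus)
        rec_site += [site_id] * (n_plus + n_minus)
        site_rows.append((site_id, c, center, n_plus, n_minus))

    n_site_reads = len(rec_pos)
    bf = config.background_fraction
    n_bg = round(n_site_reads * bf / (1.0 - bf)) if n_site_reads else 0
    if n_bg:
        lengths = np.array([chrom_len[c] for c in chroms], dtype=float)
        ci = rng.choice(len(chroms), size=n_bg, p=lengths / lengths.sum())
        for i in range(n_bg):
            c = chroms[ci[i]]
            rec_chrom.append(c)
            rec_strand.append(int(rng.integers(0, 2)))
            rec_pos.append(int(rng.integers(0, chrom_len[c])))
            rec_site.append(-1)

    n_base = len(rec_pos)
    strand_arr = np.array(rec_strand, dtype=np.int64)
    pos_arr = np.array(rec_pos, dtype=np.int64)
    lens_arr = np.array([chrom_len[c] for c in rec_chrom], dtype=np.int64)
    r2_arr = _place_read2(
        rng, strand_arr, pos_arr, lens_arr,
        config.read_length, config.insert_mean, config.insert_sd,
    )

    # enforce distinct duplicate keys among base pairs: re-draw read_2 on
    # collision (sonication breakpoints are effectively unique)
    seen: set[tuple[str, int, int, int]] = set()
    for i in range(n_base):
        key = (rec_chrom[i], int(strand_arr[i]), int(pos_arr[i]), int(r2_arr[i]))
        attempts = 0
        while key in seen:
            attempts += 1
            if attempts < 50:
                r2_arr[i : i + 1] = _place_read2(
                    rng,
                    strand_arr[i : i + 1],
                    pos_arr[i : i + 1],
                    lens_arr[i : i + 1],
                    config.read_length,
                    config.insert_mean,
                    config.insert_sd,
                )
            else:  # pathological geometry; walk deterministically
                r2_arr[i] = (r2_arr[i] + 1) % lens_arr[i]
            key = (rec_chrom[i], int(strand_arr[i]), int(pos_arr[i]), int(r2_arr[i]))
        seen.add(key)

    order = rng.permutation(n_base)
    n_dup = round(config.pcr_duplicate_rate * n_base)
    dup_of = rng.choice(order, size=n_dup, replace=True) if n_dup else np.array([], int)

    pairs: list[AlignedReadPair] = []
    truth_rows = []
    for out_i, i in enumerate(list(order) + list(dup_of)):
        is_dup = out_i >= n_base
        name = f"sim{out_i:07d}"
        pairs.append(
            AlignedReadPair(
                name=name,
                chrom=rec_chrom[i],
                r1_strand="+" if strand_arr[i] else "-",
                r1_five_prime=int(pos_arr[i]),
                r2_five_prime=int(r2_arr[i]),
                mapq=SIM_MAPQ,
                r1_length=config.read_length,
            )
        )
        truth_rows.append(
            (name, rec_site[i], "+" if strand_arr[i] else "-", int(pos_arr[i]), is_dup)
        )
    sites_df = pd.DataFrame(
        site_rows, columns=["site_id", "chrom", "center", "n_plus", "n_minus"]
    )
    reads_df = pd.DataFrame(
        truth_rows,
        columns=["name", "site_id", "strand", "r1_five_prime", "is_duplicate"],
    )
    return SignalSim(pairs=pairs, sites=sites_df, reads=reads_df)


def simulate_noise(
    n_reads: int,
    layout: GenomeLayout,
    seed: int = 0,
    read_length: int = 75,
    insert_mean: float = 225.0,
    insert_sd: float = 75.0,
) -> list[AlignedReadPair]:
    """Uniformly placed mapped pairs: read_1 5' uniform over the genome,
    fair-coin strand, read_2 by the insert model."""
    rng = np.random.default_rng(seed)
    chroms = layout.chroms
    lengths = np.array([layout[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=n_reads, p=lengths / lengths.sum())
    lens_arr = np.array([layout[chroms[i]] for i in ci], dtype=np.int64)
    pos = (rng.random(n_reads) * lens_arr).astype(np.int64)
    strand = rng.integers(0, 2, size=n_reads)
    r2 = _place_read2(rng, strand, pos, lens_arr, read_length, insert_mean, insert_sd)
    return [
        AlignedReadPair(
            name=f"noise{i:07d}",
            chrom=chroms[ci[i]],
            r1_strand="+" if strand[i] else "-",
            r1_five_prime=int(pos[i]),
            r2_five_prime=int(r2[i]),
            mapq=SIM_MAPQ,
            r1_length=read_length,
        )
        for i in range(n_reads)
    ]


def mix_datasets(
    signal_pairs: Sequence[AlignedReadPair],
    noise_pairs: Sequence[AlignedReadPair],
    spec: MixSpec,
) -> list[AlignedReadPair]:
    """Subsample signal and noise pools without replacement and shuffle.

    The composition follows the mixing table exactly: for a total of
    100,000 reads, noise fractions 0/.25/.5/.75/1 give signal/noise
    splits of 100,000/0, 75,000/25,000, 50,000/50,000, 25,000/75,000 and
    0/100,000.
    """
    if spec.n_signal > len(signal_pairs):
        raise ValueError(
            f"signal pool too small: need {spec.n_signal}, have "
            f"{len(signal_pairs)} (short by {spec.n_signal - len(signal_pairs)})"
        )
    if spec.n_noise > len(noise_pairs):
        raise ValueError(
            f"noise pool too small: need {spec.n_noise}, have "
            f"{len(noise_pairs)} (short by {spec.n_noise - len(noise_pairs)})"
        )
    rng = np.random.default_rng(spec.seed)
    sig_idx = rng.choice(len(signal_pairs), size=spec.n_signal, replace=False)
    noi_idx = rng.choice(len(noise_pairs), size=spec.n_noise, replace=False)
    mixed = [signal_pairs[i] for i in sig_idx] + [noise_pairs[i] for i in noi_idx]
    rng.shuffle(mixed)
    return mixed


def run_noise_validation(
    config: SimConfig,
    tss: Sequence[TssAnnotation],
    fractions: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    total_reads: int = 100_000,
    n_replicates: int = 2,
    trim_length: int | None = None,
    min_mapq: int = 20,
    seed: int = 0,
    compute_enrichment: bool = True,
    fig_prefix=None,
) -> pd.DataFrame:
    """Run the graded-noise experiment end to end.

    Builds one shared signal pool (from ``config``; replicates subsample
    the same pool, as pseudo-replicates drawn from one merged library
    do), then for every noise fraction draws ``n_replicates``
    independently seeded mixtures of ``total_reads`` reads, runs each
    through quality-filter -> dedup -> read_1, and reports per fraction
    the replicate Pearson correlation of log2 1-kb bins and (optionally)
    the promoter enrichment of the merged, normalized binding profile.

    Each replicate's noise reads are generated fresh from its own seed:
    a genome-wide artificial read set is vastly deeper than a 100,000
    read subsample, so two subsamples of it share a negligible fraction
    of reads — independent draws model that limit exactly.
    """
    if trim_length is None:
        trim_length = config.footprint_bp
    rng = np.random.default_rng(seed)
    signal = simulate_signal(config)
    if len(signal.pairs) < total_reads:
        raise ValueError(
            f"signal pool ({len(signal.pairs)}) smaller than total_reads "
            f"({total_reads}); increase n_sites or reads_per_site"
        )
    rows = []
    for frac in fractions:
        binned = []
        profiles = []
        for rep in range(n_replicates):
            spec = MixSpec(
                noise_fraction=frac,
                total_reads=total_reads,
                seed=int(rng.integers(2**31)),
            )
            noise_pool = simulate_noise(
                spec.n_noise,
                config.layout,
                seed=int(rng.integers(2**31)),
                read_length=config.read_length,
                insert_mean=config.insert_mean,
                insert_sd=config.insert_sd,
            )
            mixed = mix_datasets(signal.pairs, noise_pool, spec)
            kept = filter_quality(mixed, min_mapq)
            deduped, _ = deduplicate(kept)
            read1s = extract_read1(deduped)
            binned.append(
                bin_reads(read1s, config.layout, sample_id=f"noise{frac:g}_rep{rep}")
            )
            if compute_enrichment:
                trimmed = trim_reads(read1s, trim_length, config.layout)
                fwd, rev = coverage_by_strand(trimmed, config.layout)
                profiles.append(background_normalize(combine_strands(fwd, rev)))
        pcc = float(correlate_samples(binned).iloc[0, 1])
        enrichment = np.nan
        if compute_enrichment:
            merged = merge_replicates(profiles)
            fig = f"{fig_prefix}_tss_{int(frac * 100)}.png" if fig_prefix else None
            meta = tss_metaprofile(merged, list(tss), fig_path=fig)
            enrichment = promoter_enrichment(meta)
        spec0 = MixSpec(noise_fraction=frac, total_reads=total_reads)
        rows.append(
            {
                "noise_fraction": frac,
                "n_signal": spec0.n_signal,
                "n_noise": spec0.n_noise,
                "replicate_pcc": pcc,
                "promoter_enrichment": enrichment,
            }
        )
    return pd.DataFrame(rows)
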