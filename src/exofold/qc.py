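"""Quality-control statistics: replicate correlation, TSS meta-profile,
and per-peak border ("peak shape") profiles.

Three checks tell a ChIP-exo user whether to trust a dataset:

* 1-kb genome bins, log2-transformed, correlated pairwise between
  samples — good replicates reach Pearson r >= 0.9, and r degrades as
  noise increases;
* the average fold-over-background signal in a +/-1000 bp window around
  every TSS — yeast TFs bind mostly upstream of the TSS, so a promoter
  enrichment should be visible;
* read_1 5' end counts around each peak center, per strand — the two
  border pile-ups should flank the center at about half the footprint.

Every figure writer has a TSV twin so plotted numbers stay testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .alignments import GenomeLayout, Read1
from .peaks import Peak, TssAnnotation
from .profiles import BindingProfile

__all__ = [
    "BinnedSample",
    "MetaProfile",
    "bin_reads",
    "correlate_samples",
    "tss_metaprofile",
    "promoter_enrichment",
    "peak_shape_profiles",
]


@dataclass
class BinnedSample:
    """Genome-wide read counts in fixed-size bins, chromosomes concatenated."""

    sample_id: str
    bin_size: int
    counts: np.ndarray


@dataclass
class MetaProfile:
    """Signal averaged over anchor-centered windows.

    ``values[flank]`` is the anchor position itself; for stranded anchors
    upstream is always to the left (indices < flank).
    """

    flank: int
    values: np.ndarray
    n_anchors: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)


def bin_reads(
    read1s: Iterable[Read1],
    layout: GenomeLayout,
    bin_size: int = 1000,
    sample_id: str = "",
) -> BinnedSample:
    """Assign each read_1 to the bin containing its 5' position.

    A point assignment (rather than interval overlap) so no read is
    double-counted at bin edges; the last bin of a chromosome may be
    short.
    """
    n_bins = {name: -(-length // bin_size) for name, length in layout.items()}
    offsets: dict[str, int] = {}
    total = 0
    for name in layout:
        offsets[name] = total
        total += n_bins[name]
    counts = np.zeros(total, dtype=np.int64)
    for read in read1s:
        counts[offsets[read.chrom] + read.five_prime // bin_size] += 1
    return BinnedSample(sample_id, bin_size, counts)


def correlate_samples(
    samples: Sequence[BinnedSample], fig_path: str | Path | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation of log2-transformed bin counts.

    Bins that are zero in *every* sample are removed; survivors are
    transformed as log2(count + 1) (the pseudocount keeps bins that are
    zero in only some samples finite).  Optionally writes a pairwise
    scatter figure annotated with each coefficient.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples to correlate")
    lengths = {len(s.counts) for s in samples}
    if len(lengths) != 1:
        raise ValueError("samples were binned over different layouts")
    mat = np.stack([s.counts for s in samples])
    keep = mat.any(axis=0)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 nonzero bins; correlation is degenerate")
    log = np.log2(mat[:, keep] + 1.0)
    names = [s.sample_id or f"sample_{i}" for i, s in enumerate(samples)]
    corr = pd.DataFrame(np.corrcoef(log), index=names, columns=names)
    if fig_path is not None:
        _plot_correlation(log, names, corr, fig_path)
    return corr


def _plot_correlation(log, names, corr, fig_path):
    k = len(names)
    fig, axes = plt.subplots(k, k, figsize=(2.2 * k, 2.2 * k), squeeze=False)
    for i in range(k):
        for j in range(k):
            ax = axes[i][j]
            if i == j:
                ax.hist(log[i], bins=40, color="grey")
                ax.set_title(names[i], fontsize=8)
            else:
                ax.plot(log[j], log[i], ".", ms=1, alpha=0.3)
                ax.set_title(f"r = {corr.iloc[i, j]:.2f}", fontsize=8)
            ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)


def tss_metaprofile(
    profile: BindingProfile,
    tss: Sequence[TssAnnotation],
    flank: int = 1000,
    fig_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> MetaProfile:
    """Average the binding profile over +/-flank windows around every TSS.

    Windows of minus-strand genes are flipped so upstream is always on
    the left.  Windows truncated at chromosome ends contribute only the
    positions they cover (per-position anchor counts).  Values are mean
    fold-over-background per relative position, so a flat profile of 1
    yields a flat meta-profile of 1.
    """
    if not tss:
        raise ValueError("TSS list is empty")
    width = 2 * flank + 1
    total = np.zeros(width)
    count = np.zeros(width)
    for t in tss:
        chrom_len = profile.layout[t.chrom]
        lo = t.position - flank
        hi = t.position + flank + 1
        clip_lo, clip_hi = max(0, lo), min(chrom_len, hi)
        window = np.full(width, np.nan)
        window[clip_lo - lo : width - (hi - clip_hi)] = profile.values[t.chrom][
            clip_lo:clip_hi
        ]
        if t.strand == "-":
            window = window[::-1]
        ok = ~np.isnan(window)
        total[ok] += window[ok]
        count[ok] += 1
    values = np.divide(total, count, out=np.zeros(width), where=count > 0)
    meta = MetaProfile(flank=flank, values=values, n_anchors=len(tss))
    if tsv_path is not None:
        pd.DataFrame({"offset": meta.offsets, "mean_signal": values}).to_csv(
            tsv_path, sep="\t", index=False
        )
    if fig_path is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(meta.offsets, values)
        ax.axhline(1.0, color="grey", ls="--", lw=0.8)
        ax.set_xlabel("position relative to TSS (bp)")
        ax.set_ylabel("mean fold-over-background")
        fig.tight_layout()
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
    return meta


def promoter_enrichment(meta: MetaProfile) -> float:
    """Mean fold-over-background over the upstream half [-flank, 0)."""
    return float(meta.values[: meta.flank].mean())


def peak_shape_profiles(
    read1s: Iterable[Read1],
    peaks: Sequence[Peak],
    layout: GenomeLayout,
    flank: int = 30,
    fig_prefix: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, MetaProfile]]:
    """Count read_1 5' ends around each peak center, per strand.

    Returns ``(matrices, averages)``: for each strand a (n_peaks,
    2*flank+1) matrix of counts (one row per peak — the individual-peak
    line plot) and its column mean as a :class:`MetaProfile` (the
    averaged border profile).  Untrimmed, deduplicated reads are the
    intended input; the two averaged maxima sit at about -footprint/2
    (plus strand) and +footprint/2 (minus strand).
    """
    ends: dict[str, dict[str, np.ndarray]] = {
        "+": {name: np.zeros(length, dtype=np.int64) for name, length in layout.items()},
        "-": {name: np.zeros(length, dtype=np.int64) for name, length in layout.items()},
    }
    for read in read1s:
        ends[read.strand][read.chrom][read.five_prime] += 1
    width = 2 * flank + 1
    matrices = {
        s: np.zeros((len(peaks), width), dtype=np.int64) for s in "+-"
    }
    for row, peak in enumerate(peaks):
        chrom_len = layout[peak.chrom]
        lo = peak.position - flank
        hi = peak.position + flank + 1
        clip_lo, clip_hi = max(0, lo), min(chrom_len, hi)
        for strand in "+-":
            matrices[strand][row, clip_lo - lo : width - (hi - clip_hi)] = ends[
                strand
            ][peak.chrom][clip_lo:clip_hi]
    averages = {
        s: MetaProfile(
            flank=flank,
            values=(matrices[s].mean(axis=0) if len(peaks) else np.zeros(width)),
            n_anchors=len(peaks),
        )
        for s in "+-"
    }
    offsets = np.arange(-flank, flank + 1)
    if tsv_path is not None:
        pd.DataFrame(
            {
                "offset": offsets,
                "mean_plus": averages["+"].values,
                "mean_minus": averages["-"].values,
            }
        ).to_csv(tsv_path, sep="\t", index=False)
    if fig_prefix is not None:
        fig_prefix = str(fig_prefix)
        fig, ax = plt.subplots(figsize=(6, 4))
        for row in matrices["+"]:
            ax.plot(offsets, row, color="tab:blue", alpha=0.05, lw=0.5)
        for row in matrices["-"]:
            ax.plot(offsets, row, color="tab:red", alpha=0.05, lw=0.5)
        ax.set_xlabel("position relative to peak center (bp)")
        ax.set_ylabel("read_1 5' ends")
        fig.tight_layout()
        fig.savefig(fig_prefix + "_per_peak.png", dpi=120)
        plt.close(fig)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(offsets, averages["+"].values, color="tab:blue", label="+ strand")
        ax.plot(offsets, averages["-"].values, color="tab:red", label="- strand")
        ax.legend()
        ax.set_xlabel("position relative to peak center (bp)")
        ax.set_ylabel("mean read_1 5' ends")
        fig.tight_layout()
        fig.savefig(fig_prefix + "_averaged.png", dpi=120)
        plt.close(fig)
    return matrices, averages
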