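"""Coverage-based enrichment statistics at reference loci.

ChIP enrichment at a reference locus is the log2 ratio of the ChIP RPM
signal over the total-chromatin (input) RPM signal, averaged across
replicates; per-factor Z-scores then standardise these averages over
the whole reference set (population mean / population SD).  Loci are
assigned to the closest transcription start site within 1 kb, and
TSS-centred intensity matrices (RPM in a ±flank window, replicate
averaged, strand-oriented) reproduce factor-binding heatmaps.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .peakset import GenomicInterval, ReferenceLocus

DEFAULT_PSEUDOCOUNT = 0.5  # RPM added to both signals before the log ratio
DEFAULT_TSS_MAX_DIST = 1000  # bp
DEFAULT_FLANK = 500  # bp


@dataclasses.dataclass
class CoverageTrack:
    """Fixed-bin read coverage for one sample.

    ``bins`` maps chromosome name to an array of read counts per bin of
    ``bin_width`` bp; ``total_reads`` is the sample's mapped-read count
    used for RPM scaling (it need not equal the binned sum — the bins may
    cover only a subgenome).
    """

    sample_id: str
    factor: str
    replicate_id: str
    bins: dict[str, np.ndarray]
    total_reads: float
    bin_width: int = 1

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")


@dataclasses.dataclass(frozen=True)
class TSSRecord:
    """A transcription start site with its gene identity and biotype."""

    gene_id: str
    chrom: str
    position: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclasses.dataclass
class LocusEnrichment:
    locus: ReferenceLocus
    per_replicate_log2: list[float]
    mean_log2: float
    z: float | None = None


@dataclasses.dataclass
class IntensityMatrix:
    """Per-gene RPM signal in a TSS-centred window.

    Columns run from -flank to +flank-1 relative to the TSS, with +1
    always downstream of transcription (rows of minus-strand genes are
    flipped).  Windows truncated at a chromosome edge are zero-padded
    and flagged in ``truncated``.
    """

    gene_ids: list[str]
    values: np.ndarray  # shape (n_genes, 2 * flank)
    flank: int
    truncated: np.ndarray  # boolean per gene

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.offsets)


# ---------------------------------------------------------------------------
# Coverage I/O


def read_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    total_reads: float,
    sample_id: str = "",
    factor: str = "",
    replicate_id: str = "",
    bin_width: int = 1,
) -> CoverageTrack:
    """Load a 4-column bedGraph into per-base (or fixed-bin) arrays.

    Interval values are laid down with a difference-array cumulative sum,
    so arbitrarily many (non-overlapping) bedGraph rows load in O(genome).
    """
    nbins = {c: -(-size // bin_width) for c, size in chrom_sizes.items()}
    deltas = {c: np.zeros(n + 1) for c, n in nbins.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#", dtype={"chrom": str},
    )
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in deltas:
            raise KeyError(f"bedGraph chromosome {chrom!r} not in chrom_sizes")
        if bin_width == 1:
            d = deltas[chrom]
            np.add.at(d, sub["start"].to_numpy(), sub["value"].to_numpy())
            np.add.at(d, sub["end"].to_numpy(), -sub["value"].to_numpy())
        else:
            # distribute per-base values into coarse bins
            arr = np.zeros(nbins[chrom] * bin_width)
            for s, e, v in sub[["start", "end", "value"]].itertuples(index=False):
                arr[s:e] += v
            deltas[chrom][:-1] += arr.reshape(-1, bin_width).sum(axis=1)
    if bin_width == 1:
        bins = {c: np.cumsum(d)[:-1] for c, d in deltas.items()}
    else:
        bins = {c: d[:-1].copy() for c, d in deltas.items()}
    return CoverageTrack(
        sample_id=sample_id, factor=factor, replicate_id=replicate_id,
        bins=bins, total_reads=total_reads, bin_width=bin_width,
    )


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as run-length-encoded bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.bins):
            arr = track.bins[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            w = track.bin_width
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s * w}\t{e * w}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Enrichment statistics


def rpm_in_window(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Reads-per-million signal inside an interval.

    Sums the read counts of all bins overlapping the interval and scales
    by 1e6 / total mapped reads.
    """
    if interval.chrom not in track.bins:
        raise KeyError(f"chromosome {interval.chrom!r} not covered by track")
    arr = track.bins[interval.chrom]
    lo = interval.start // track.bin_width
    hi = -(-interval.end // track.bin_width)  # ceil
    counts = float(arr[lo:hi].sum())
    return counts * 1e6 / track.total_reads


def locus_log2_enrichment(
    chip: CoverageTrack,
    input_track: CoverageTrack,
    locus: GenomicInterval,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """log2((ChIP RPM + pseudocount) / (input RPM + pseudocount)) at a locus."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    chip_rpm = rpm_in_window(chip, locus)
    input_rpm = rpm_in_window(input_track, locus)
    return math.log2((chip_rpm + pseudocount) / (input_rpm + pseudocount))


def average_replicates(values: Sequence[float]) -> float:
    """Arithmetic mean of per-replicate log2 ratios."""
    if len(values) == 0:
        raise ValueError("cannot average an empty replicate list")
    return float(np.mean(values))


def zscores(values: Sequence[float]) -> np.ndarray:
    """Standardise values by the population mean and population (N) SD."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values for Z-scores")
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate population: standard deviation is zero")
    return (x - x.mean()) / sd


def locus_enrichments(
    loci: Sequence[ReferenceLocus],
    chip_tracks: Sequence[CoverageTrack],
    input_track: CoverageTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[LocusEnrichment]:
    """Per-locus replicate-averaged enrichment plus population Z-scores
    for one factor's replicate tracks."""
    out = []
    for locus in loci:
        per_rep = [
            locus_log2_enrichment(t, input_track, locus.interval, pseudocount)
            for t in chip_tracks
        ]
        out.append(
            LocusEnrichment(
                locus=locus,
                per_replicate_log2=per_rep,
                mean_log2=average_replicates(per_rep),
            )
        )
    z = zscores([e.mean_log2 for e in out])
    for e, zi in zip(out, z):
        e.z = float(zi)
    return out


# ---------------------------------------------------------------------------
# TSS annotation


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a 5-column TSV: gene_id, chrom, tss, strand, biotype."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    required = {"gene_id", "chrom", "tss", "strand", "biotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    return [
        TSSRecord(r.gene_id, r.chrom, int(r.tss), r.strand, r.biotype)
        for r in df.itertuples(index=False)
    ]


def read_gtf_tss(path: str | Path) -> list[TSSRecord]:
    """Extract gene TSSs from GTF gene lines (1-based inclusive -> 0-based).

    The TSS is the gene start for + genes and the gene end for - genes;
    biotype is taken from the gene_biotype attribute.
    """
    from gffutils.iterators import DataIterator

    records = []
    for feat in DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        gene_id = feat.attributes.get("gene_id", [feat.id or "?"])[0]
        biotype = feat.attributes.get(
            "gene_biotype", feat.attributes.get("gene_type", ["unknown"])
        )[0]
        if feat.strand == "+":
            pos = feat.start - 1  # GTF is 1-based inclusive
        else:
            pos = feat.end - 1
        records.append(TSSRecord(gene_id, feat.seqid, pos, feat.strand, biotype))
    return records


def nearest_tss(
    locus: GenomicInterval,
    annotation: Sequence[TSSRecord],
    max_dist: int = DEFAULT_TSS_MAX_DIST,
) -> TSSRecord | None:
    """Closest same-chromosome TSS within ``max_dist`` bp of the locus.

    Distance is 0 when the TSS lies inside the locus, else the distance to
    the nearer locus edge; ties break to the lexicographically smallest
    gene_id.  Returns None when no TSS qualifies.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    best: tuple[int, str] | None = None
    best_rec = None
    for t in annotation:
        if t.chrom != locus.chrom:
            continue
        if locus.start <= t.position < locus.end:
            d = 0
        else:
            d = min(abs(t.position - locus.start), abs(t.position - (locus.end - 1)))
        if d > max_dist:
            continue
        key = (d, t.gene_id)
        if best is None or key < best:
            best, best_rec = key, t
    return best_rec


def biotype_fraction(assigned: Sequence[TSSRecord], biotype: str) -> float:
    """Fraction of unique assigned genes with the given biotype."""
    if not assigned:
        raise ValueError("no assigned TSS records")
    by_gene = {t.gene_id: t.biotype for t in assigned}
    hits = sum(1 for b in by_gene.values() if b == biotype)
    return hits / len(by_gene)


# ---------------------------------------------------------------------------
# Intensity matrices


def tss_intensity_matrix(
    tracks: Sequence[CoverageTrack],
    tss_list: Sequence[TSSRecord],
    flank: int = DEFAULT_FLANK,
) -> IntensityMatrix:
    """Replicate-averaged RPM signal in TSS-centred, strand-oriented windows.

    All tracks must belong to one factor and share a bin width of 1 bp.
    Column +1 is always one base downstream of transcription; windows
    clipped at a chromosome edge are zero-padded and flagged.
    """
    if not tss_list:
        raise ValueError("tss_list is empty")
    if not tracks:
        raise ValueError("need at least one coverage track")
    factors = {t.factor for t in tracks}
    if len(factors) != 1:
        raise ValueError(f"tracks span multiple factors: {sorted(factors)}")
    if any(t.bin_width != 1 for t in tracks):
        raise ValueError("intensity matrices require 1-bp bins")
    width = 2 * flank
    values = np.zeros((len(tss_list), width))
    truncated = np.zeros(len(tss_list), dtype=bool)
    for i, tss in enumerate(tss_list):
        window = np.zeros(width)
        for track in tracks:
            arr = track.bins.get(tss.chrom)
            if arr is None:
                raise KeyError(f"chromosome {tss.chrom!r} not covered by track")
            if tss.strand == "+":
                lo, hi = tss.position - flank, tss.position + flank
            else:
                # window shifted by one so that, after the flip, column o
                # maps to genomic position TSS - o exactly
                lo, hi = tss.position - flank + 1, tss.position + flank + 1
            clip_lo, clip_hi = max(lo, 0), min(hi, arr.size)
            if clip_lo != lo or clip_hi != hi:
                truncated[i] = True
            seg = np.zeros(width)
            seg[clip_lo - lo : clip_lo - lo + (clip_hi - clip_lo)] = arr[clip_lo:clip_hi]
            window += seg * 1e6 / track.total_reads
        window /= len(tracks)
        if tss.strand == "-":
            window = window[::-1]
        values[i] = window
    return IntensityMatrix(
        gene_ids=[t.gene_id for t in tss_list],
        values=values,
        flank=flank,
        truncated=truncated,
    )
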