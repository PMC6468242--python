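"""Reference peak set construction and locus classification.

ChIP-seq peak calls for several SAGA subunits (multiple replicates per
factor) are reduced to a single set of non-overlapping reference loci.
A peak is kept only if it is reproducible — i.e. overlaps peaks from a
minimum number of distinct replicates of the same factor — and the
surviving peaks of all factors are merged into reference loci.  Each
locus is then classified by which factors support it:

* ``canonical``  — supported by all three configured factors
  (HAT, SPT and DUB module representatives; defaults Ada2b/Spt3/Sgf11),
* ``ada2b_only`` — supported by the primary (HAT) factor and by
  neither of the other two,
* ``other``      — any remaining support pattern.

Coordinates are 0-based half-open (BED convention) throughout; two
intervals overlap when they share at least one base.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

CANONICAL = "canonical"
ADA2B_ONLY = "ada2b_only"
OTHER = "other"

#: default factor scheme: (primary factor, the two co-factors whose joint
#: presence defines a canonical site)
DEFAULT_PRIMARY = "Ada2b"
DEFAULT_COFACTORS = ("Spt3", "Sgf11")

#: default per-factor reproducibility thresholds (replicates required)
DEFAULT_MIN_SUPPORT = {"Ada2b": 3, "Spt3": 2, "Sgf11": 2}


class PeakFileError(ValueError):
    """A peak file line could not be parsed."""


@dataclasses.dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = dataclasses.field(default=None, compare=False)
    score: float | None = dataclasses.field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclasses.dataclass
class ReplicatePeakSet:
    """All peaks called in one replicate of one factor.

    Peaks are sorted by (chrom, start) and exact duplicates dropped on
    construction.
    """

    factor: str
    replicate_id: str
    peaks: list[GenomicInterval]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, int]] = set()
        unique = []
        for p in sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end)):
            key = (p.chrom, p.start, p.end)
            if key not in seen:
                seen.add(key)
                unique.append(p)
        self.peaks = unique


@dataclasses.dataclass
class ReferenceLocus:
    """A merged reference interval with per-factor support flags."""

    interval: GenomicInterval
    support: dict[str, bool]
    locus_class: str


# ---------------------------------------------------------------------------
# I/O


def read_narrowpeak(path: str | Path) -> list[GenomicInterval]:
    """Read a narrowPeak (BED6+4) or plain BED3+ file.

    Columns 1-3 give chrom/start/end (0-based half-open); columns 4 and 5,
    when present, are kept as name and score.  Malformed lines raise
    :class:`PeakFileError` naming the offending line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PeakFileError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PeakFileError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else None
            score = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise PeakFileError(
                        f"{path}: line {lineno}: non-numeric score"
                    ) from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except ValueError as exc:
                raise PeakFileError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED, keeping name/score columns when present."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(f"{iv.score:g}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Interval algebra


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended intervals into a disjoint sorted set.

    The base-set union of the output equals that of the input; bookended
    intervals (``end == start``) are joined.
    """
    merged: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or bookend
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def _overlaps_any(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> bool:
    return any(iv.overlaps(o) for o in others)


def reproducible_peaks(
    replicates: Sequence[ReplicatePeakSet], min_support: int
) -> list[GenomicInterval]:
    """Peaks supported by at least ``min_support`` distinct replicates.

    A peak from any replicate is kept when peaks from ``min_support``
    distinct replicates overlap it by >= 1 bp (the peak's own replicate
    counts).  Kept peaks are merged.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    factors = {r.factor for r in replicates}
    if len(factors) != 1:
        raise ValueError(f"replicates span multiple factors: {sorted(factors)}")
    if not 1 <= min_support <= len(replicates):
        raise ValueError(
            f"min_support ({min_support}) must be in [1, {len(replicates)}]"
        )
    kept: list[GenomicInterval] = []
    for i, rep in enumerate(replicates):
        for peak in rep.peaks:
            support = 1  # a peak supports itself
            for j, other in enumerate(replicates):
                if j == i:
                    continue
                if _overlaps_any(peak, other.peaks):
                    support += 1
            if support >= min_support:
                kept.append(peak)
    return merge_intervals(kept) if kept else []


def classify_locus(
    support: Mapping[str, bool],
    primary: str = DEFAULT_PRIMARY,
    cofactors: Sequence[str] = DEFAULT_COFACTORS,
) -> str:
    """Classify a support vector over the three configured factors.

    Primary present and both co-factors absent -> ``ada2b_only``; all three
    present -> ``canonical``; anything else -> ``other``.
    """
    for f in (primary, *cofactors):
        if f not in support:
            raise ValueError(f"support vector missing factor {f!r}")
    if support[primary] and not any(support[c] for c in cofactors):
        return ADA2B_ONLY
    if support[primary] and all(support[c] for c in cofactors):
        return CANONICAL
    return OTHER


def build_reference_set(
    per_factor: Mapping[str, Sequence[GenomicInterval]],
    primary: str = DEFAULT_PRIMARY,
    cofactors: Sequence[str] = DEFAULT_COFACTORS,
) -> list[ReferenceLocus]:
    """Combine per-factor reproducible peaks into classified reference loci.

    Reference intervals are the merged union of all factors' peaks; each
    locus is flagged as supported by factor *f* when it overlaps any of
    *f*'s peaks by >= 1 bp.
    """
    if not per_factor:
        raise ValueError("need at least one factor")
    pooled = [iv for peaks in per_factor.values() for iv in peaks]
    reference = merge_intervals(pooled) if pooled else []
    loci = []
    for iv in reference:
        support = {
            f: _overlaps_any(iv, peaks) for f, peaks in per_factor.items()
        }
        try:
            cls = classify_locus(support, primary=primary, cofactors=cofactors)
        except ValueError:
            cls = OTHER  # factor scheme not fully represented in inputs
        loci.append(ReferenceLocus(interval=iv, support=support, locus_class=cls))
    return loci


def overlap_fraction(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> float:
    """Fraction of intervals in ``a`` overlapping (>=1 bp) any interval of ``b``."""
    if not a:
        raise ValueError("overlap fraction undefined for empty interval list")
    hits = sum(1 for iv in a if _overlaps_any(iv, b))
    return hits / len(a)


def write_reference_table(loci: Sequence[ReferenceLocus], path: str | Path) -> None:
    """Write the per-locus support table as TSV (one boolean column per factor)."""
    factors = sorted({f for l in loci for f in l.support})
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "start", "end", *factors, "class"]) + "\n")
        for l in loci:
            row = [l.interval.chrom, str(l.interval.start), str(l.interval.end)]
            row += [str(bool(l.support.get(f, False))) for f in factors]
            row.append(l.locus_class)
            fh.write("\t".join(row) + "\n")
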