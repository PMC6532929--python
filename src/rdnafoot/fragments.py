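"""Paired-end fragment records: reading, filtering, BED round-trips, and
collapsing of multi-copy rDNA alignments onto a single repeat unit.

A *fragment* is the full insert of one sequenced paired-end template — the
span from the leftmost mate start to the rightmost mate end.  At the rDNA the
repeats are near-identical, so the defaults deliberately KEEP multi-mapped
reads (``min_mapq=0``) and do NOT remove duplicates: per-repeat composite
footprints pool many cells and many repeat copies, and MAPQ or duplicate
filtering would delete the signal itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import BedParseError, InputError
from .regions import GenomicInterval, RdnaLandmarks

__all__ = [
    "Fragment",
    "Fragments",
    "FragmentFilter",
    "iter_fragments_bam",
    "read_fragments_bam",
    "read_fragments_bed",
    "write_fragments_bed",
    "collapse_to_unit",
    "collapse_fragments",
]

log = logging.getLogger(__name__)


class Fragment(NamedTuple):
    """One sequenced insert: chromosome plus 0-based half-open interval."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


class Fragments:
    """A column-oriented fragment set (numpy-backed for vector operations).

    Iterating yields :class:`Fragment` records; the ``chroms``/``starts``/
    ``ends`` arrays are the fast path used by the matrix builder, the
    occupancy statistics and the simulators.
    """

    __slots__ = ("chroms", "starts", "ends")

    def __init__(self, chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray):
        chroms = np.asarray(chroms)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if not (chroms.shape == starts.shape == ends.shape):
            raise ValueError("chroms, starts, ends must have identical shape")
        if np.any(ends <= starts):
            raise ValueError("all fragments must satisfy end > start")
        self.chroms = chroms
        self.starts = starts
        self.ends = ends

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[Fragment]) -> "Fragments":
        recs = list(records)
        if not recs:
            return cls.empty()
        return cls(
            np.array([r.chrom for r in recs]),
            np.array([r.start for r in recs], dtype=np.int64),
            np.array([r.end for r in recs], dtype=np.int64),
        )

    @classmethod
    def empty(cls) -> "Fragments":
        return cls(
            np.array([], dtype=object),
            np.array([], dtype=np.int64),
            np.array([], dtype=np.int64),
        )

    @classmethod
    def concat(cls, parts: Sequence["Fragments"]) -> "Fragments":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        return cls(
            np.concatenate([np.asarray(p.chroms, dtype=object) for p in parts]),
            np.concatenate([p.starts for p in parts]),
            np.concatenate([p.ends for p in parts]),
        )

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return int(self.starts.size)

    def __iter__(self) -> Iterator[Fragment]:
        for c, s, e in zip(self.chroms, self.starts, self.ends):
            yield Fragment(str(c), int(s), int(e))

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def subset(self, mask: np.ndarray) -> "Fragments":
        return Fragments(self.chroms[mask], self.starts[mask], self.ends[mask])

    def on_chrom(self, chrom: str) -> "Fragments":
        return self.subset(self.chroms == chrom)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends}
        )

    def multiset(self) -> dict:
        """(chrom, start, end) -> multiplicity; order-insensitive identity."""
        df = self.to_dataframe()
        return df.groupby(["chrom", "start", "end"]).size().to_dict()


@dataclass(frozen=True)
class FragmentFilter:
    """Length / region / mapping-quality gate applied when reading fragments.

    The 50 bp lower bound mirrors library protocols that retain fragments as
    small as 50 bp — the smallest protected footprints the assay can report.
    """

    min_length: int = 50
    max_length: int = 250
    region: Optional[GenomicInterval] = None
    min_mapq: int = 0

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError(
                f"min_length {self.min_length} > max_length {self.max_length}"
            )

    def passes(self, fragment: Fragment, mapq: int = 255) -> bool:
        if not (self.min_length <= fragment.length <= self.max_length):
            return False
        if mapq < self.min_mapq:
            return False
        if self.region is not None:
            return self.region.overlaps(
                GenomicInterval(fragment.chrom, fragment.start, fragment.end)
            )
        return True

    def mask(self, fragments: Fragments) -> np.ndarray:
        lengths = fragments.lengths
        keep = (lengths >= self.min_length) & (lengths <= self.max_length)
        if self.region is not None:
            keep &= (
                (fragments.chroms == self.region.chrom)
                & (fragments.starts < self.region.end)
                & (fragments.ends > self.region.start)
            )
        return keep

    def apply(self, fragments: Fragments) -> Fragments:
        return fragments.subset(self.mask(fragments))


# ---------------------------------------------------------------------------
# Alignment-file input
# ---------------------------------------------------------------------------

def iter_fragments_bam(
    path,
    frag_filter: Optional[FragmentFilter] = None,
    dedup: bool = False,
) -> Iterator[Fragment]:
    """Stream fragments from a coordinate-sorted BAM (or SAM) file.

    One fragment per properly paired template, reconstructed as the outer
    template span (leftmost mate start to leftmost start + TLEN), emitted at
    the leftmost mate.  Records failing the filter are dropped and counted.
    When the filter carries a region and the file is indexed, only that
    region is scanned; otherwise the whole file is streamed and the region
    is applied per record.
    """
    frag_filter = frag_filter or FragmentFilter()
    try:
        af = pysam.AlignmentFile(str(path))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot open alignment file {path}: {exc}") from exc

    region = frag_filter.region
    with af:
        if region is not None and af.has_index():
            # pad leftward so fragments overlapping the region only via the
            # rightmost mate are still seen at their leftmost read
            pad = max(frag_filter.max_length, 0)
            reads = af.fetch(region.chrom, max(0, region.start - pad), region.end)
        else:
            reads = af.fetch(until_eof=True)
        kept = dropped = 0
        seen: set = set()
        for read in reads:
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or not read.is_proper_pair
                or read.is_secondary
                or read.is_supplementary
            ):
                continue
            tlen = read.template_length
            if tlen <= 0:  # count each template once, at its leftmost mate
                continue
            frag = Fragment(
                read.reference_name, read.reference_start, read.reference_start + tlen
            )
            if not frag_filter.passes(frag, read.mapping_quality):
                dropped += 1
                continue
            if dedup:
                key = (frag.chrom, frag.start, frag.end)
                if key in seen:
                    dropped += 1
                    continue
                seen.add(key)
            kept += 1
            yield frag
    log.info("read %d fragments from %s (%d dropped by filter)", kept, path, dropped)
    if kept == 0:
        log.warning("no fragments passed the filter for %s", path)


def read_fragments_bam(
    path,
    frag_filter: Optional[FragmentFilter] = None,
    dedup: bool = False,
) -> Fragments:
    """Materialize :func:`iter_fragments_bam` into a :class:`Fragments` set."""
    return Fragments.from_records(iter_fragments_bam(path, frag_filter, dedup))


# ---------------------------------------------------------------------------
# BED input/output
# ---------------------------------------------------------------------------

def read_fragments_bed(path) -> Fragments:
    """Read a 3+ column BED file (0-based half-open) into fragments."""
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return Fragments.empty()
    except (ValueError, pd.errors.ParserError) as exc:
        raise BedParseError(f"malformed BED file {path}: {exc}") from exc
    for col in ("start", "end"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            lineno = int(bad.idxmax()) + 1
            raise BedParseError(
                f"malformed BED file {path}: non-integer {col!r} at line {lineno}"
            )
        df[col] = coerced.astype(np.int64)
    bad = df["end"] <= df["start"]
    if bad.any():
        lineno = int(bad.idxmax()) + 1
        raise BedParseError(
            f"malformed BED file {path}: end <= start at line {lineno}"
        )
    return Fragments(df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy())


def write_fragments_bed(fragments: Fragments | Iterable[Fragment], path) -> None:
    """Write fragments as BED3 (lossless for chrom/start/end)."""
    if not isinstance(fragments, Fragments):
        fragments = Fragments.from_records(fragments)
    fragments.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Repeat-unit collapse
# ---------------------------------------------------------------------------

def _array_region(lm: RdnaLandmarks, n_copies: int) -> GenomicInterval:
    return GenomicInterval(
        lm.chrom, lm.repeat_unit.start, lm.repeat_unit.start + n_copies * lm.unit_length
    )


def collapse_to_unit(
    fragment: Fragment,
    landmarks: RdnaLandmarks,
    rdna_region: Optional[GenomicInterval] = None,
) -> tuple[Fragment, bool]:
    """Remap one fragment into the canonical repeat unit.

    The start is reduced modulo the unit length (lengths are preserved, so a
    fragment one unit downstream lands at the same offset).  Fragments
    outside the rDNA region are returned unchanged with ``collapsed=False``.
    ``rdna_region`` defaults to the full canonical array (150 copies from the
    repeat-unit start).
    """
    region = rdna_region or _array_region(landmarks, 150)
    iv = GenomicInterval(fragment.chrom, fragment.start, fragment.end)
    if not region.overlaps(iv):
        return fragment, False
    unit = landmarks.repeat_unit
    offset = (fragment.start - unit.start) % landmarks.unit_length
    start = unit.start + offset
    return Fragment(fragment.chrom, start, start + fragment.length), True


def collapse_fragments(
    fragments: Fragments,
    landmarks: RdnaLandmarks,
    rdna_region: Optional[GenomicInterval] = None,
) -> tuple[Fragments, np.ndarray]:
    """Vectorized :func:`collapse_to_unit`; returns (fragments, collapsed mask)."""
    region = rdna_region or _array_region(landmarks, 150)
    inside = (
        (fragments.chroms == region.chrom)
        & (fragments.starts < region.end)
        & (fragments.ends > region.start)
    )
    unit = landmarks.repeat_unit
    lengths = fragments.lengths
    starts = fragments.starts.copy()
    starts[inside] = unit.start + (starts[inside] - unit.start) % landmarks.unit_length
    return Fragments(fragments.chroms, starts, starts + lengths), inside
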