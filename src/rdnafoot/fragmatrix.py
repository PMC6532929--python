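"""The 2D fragment-length x genomic-position matrix ("V-plot") and the 1D
profiles derived from it.

Each sequenced fragment reports both where a protective particle sat (its
position) and how big the particle was (its length): nucleosomes protect
~150-200 bp, site-specific factors such as Reb1 or the loaded Mcm2-7 double
hexamer protect 50-100 bp.  Binning fragments jointly by position and length
therefore separates co-located particles of different sizes.

Two assignment modes are supported.  In ``span`` mode (the default; "read
depth" semantics) a fragment increments every position bin it overlaps, in
the row of its length.  In ``midpoint`` mode it increments exactly one cell,
at its midpoint — the dot-plot rendering of the same data.  Midpoint mode
conserves mass exactly: the matrix total equals the number of contributing
fragments, which is asserted on every build.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import NormalizationError, SignalDomainError
from .fragments import Fragments
from .regions import GenomicInterval, to_display_coord

__all__ = [
    "SizeClass",
    "FACTOR_CLASS",
    "NUCLEOSOME_CLASS",
    "FragMatrix",
    "build_matrix",
    "normalize_matrix",
    "size_profile",
    "position_profile",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SizeClass:
    """An inclusive fragment-length band naming a particle type."""

    name: str
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(f"size class {self.name}: min_len > max_len")

    def contains(self, length) -> np.ndarray | bool:
        return (length >= self.min_len) & (length <= self.max_len)


#: 50-100 bp: footprints of site-specific factors (Reb1, loaded Mcm2-7).
FACTOR_CLASS = SizeClass("factor", 50, 100)
#: 150-200 bp: nucleosome-protected fragments.
NUCLEOSOME_CLASS = SizeClass("nucleosome", 150, 200)


@dataclass(frozen=True)
class FragMatrix:
    """2D count density over a window: position bins x fragment-length bins.

    ``counts[i, j]`` covers genomic positions ``window.start + i*pos_bin ..``
    and fragment lengths ``len_min + j*len_bin ..``; ``n_fragments`` is the
    number of fragments that contributed.
    """

    window: GenomicInterval
    pos_bin: int
    len_bin: int
    len_min: int
    len_max: int
    counts: np.ndarray
    n_fragments: int
    assignment: str

    @property
    def n_pos(self) -> int:
        return self.counts.shape[0]

    @property
    def n_len(self) -> int:
        return self.counts.shape[1]

    def positions(self) -> np.ndarray:
        """Genomic start coordinate (0-based) of each position bin."""
        return self.window.start + self.pos_bin * np.arange(self.n_pos)

    def display_positions(self) -> np.ndarray:
        return self.positions() + 1

    def lengths(self) -> np.ndarray:
        """Smallest fragment length falling in each length bin."""
        return self.len_min + self.len_bin * np.arange(self.n_len)

    def pos_slice(self, interval: GenomicInterval) -> slice:
        """Bins whose start coordinate lies inside ``interval`` (clipped)."""
        lo = max(0, -(-(interval.start - self.window.start) // self.pos_bin))
        hi = min(self.n_pos, -(-(interval.end - self.window.start) // self.pos_bin))
        return slice(lo, max(lo, hi))

    def len_slice(self, size_class: SizeClass) -> slice:
        lengths = self.lengths()
        idx = np.nonzero(size_class.contains(lengths))[0]
        if idx.size == 0:
            raise SignalDomainError(
                f"size class {size_class.name} [{size_class.min_len},"
                f" {size_class.max_len}] is disjoint from the matrix length"
                f" range [{self.len_min}, {self.len_max}]"
            )
        return slice(int(idx[0]), int(idx[-1]) + 1)


def build_matrix(
    fragments: Fragments,
    window: GenomicInterval,
    pos_bin: int = 1,
    len_bin: int = 1,
    len_range: tuple[int, int] = (40, 250),
    assignment: str = "span",
) -> FragMatrix:
    """Accumulate fragments into a :class:`FragMatrix` over ``window``.

    The default 1 bp x 1 bp binning over lengths 40-250 gives full
    resolution; locus-scale windows make this cheap.
    """
    if pos_bin < 1 or len_bin < 1:
        raise ValueError("pos_bin and len_bin must be >= 1")
    if assignment not in ("span", "midpoint"):
        raise ValueError(f"unknown assignment mode {assignment!r}")
    len_min, len_max = len_range
    if len_min > len_max:
        raise ValueError("len_range must be (min, max) with min <= max")
    n_pos = -(-window.length // pos_bin)
    n_len = (len_max - len_min) // len_bin + 1

    if not isinstance(fragments, Fragments):
        fragments = Fragments.from_records(fragments)
    lengths = fragments.lengths
    keep = (
        (fragments.chroms == window.chrom)
        & (lengths >= len_min)
        & (lengths <= len_max)
    )
    starts = fragments.starts[keep]
    ends = fragments.ends[keep]
    len_idx = (lengths[keep] - len_min) // len_bin

    counts = np.zeros((n_pos, n_len), dtype=np.float64)
    if assignment == "midpoint":
        mids = (starts + ends) // 2
        inside = (mids >= window.start) & (mids < window.end)
        pos_idx = (mids[inside] - window.start) // pos_bin
        np.add.at(counts, (pos_idx, len_idx[inside]), 1.0)
        n_contrib = int(inside.sum())
        assert counts.sum() == n_contrib, "midpoint-mode mass not conserved"
    else:
        inside = (starts < window.end) & (ends > window.start)
        s = np.maximum(starts[inside], window.start)
        e = np.minimum(ends[inside], window.end)
        b0 = (s - window.start) // pos_bin
        b1 = (e - 1 - window.start) // pos_bin
        li = len_idx[inside]
        diff = np.zeros((n_pos + 1, n_len), dtype=np.float64)
        np.add.at(diff, (b0, li), 1.0)
        np.add.at(diff, (b1 + 1, li), -1.0)
        counts = np.cumsum(diff, axis=0)[:n_pos]
        n_contrib = int(inside.sum())

    if n_contrib == 0:
        log.warning(
            "no fragments fell in window %s:%d-%d", window.chrom,
            to_display_coord(window.start), window.end,
        )
    return FragMatrix(
        window=window,
        pos_bin=pos_bin,
        len_bin=len_bin,
        len_min=len_min,
        len_max=len_max,
        counts=counts,
        n_fragments=n_contrib,
        assignment=assignment,
    )


def normalize_matrix(matrix: FragMatrix, mode: str = "per_million") -> FragMatrix:
    """Scale counts: ``per_million`` by 1e6 / n_fragments (replication-
    invariant relative depth), ``unit_max`` so the maximum cell equals 1."""
    if mode == "per_million":
        if matrix.n_fragments == 0:
            raise NormalizationError("per_million normalization of an empty matrix")
        scale = 1e6 / matrix.n_fragments
    elif mode == "unit_max":
        peak = matrix.counts.max() if matrix.counts.size else 0.0
        if peak <= 0:
            raise NormalizationError("unit_max normalization of an all-zero matrix")
        scale = 1.0 / peak
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(matrix, counts=matrix.counts * scale)


def size_profile(matrix: FragMatrix, interval: GenomicInterval) -> np.ndarray:
    """Depth by fragment length, summed over position bins inside ``interval``.

    This is the fragment-size distribution at a locus — e.g. at the origin it
    exposes the G1/G2 shift between the nucleosome band and the smaller
    pre-RC band.
    """
    sl = matrix.pos_slice(interval)
    if sl.start >= sl.stop:
        log.warning("size_profile: interval %s does not intersect the window", interval)
        return np.zeros(matrix.n_len)
    return matrix.counts[sl].sum(axis=0)


def position_profile(matrix: FragMatrix, size_class: SizeClass) -> np.ndarray:
    """Depth by position, summed over the length bins of ``size_class``."""
    return matrix.counts[:, matrix.len_slice(size_class)].sum(axis=1)


# ---------------------------------------------------------------------------
# Serialization (plain TSV, self-describing via comment header)
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: FragMatrix, path) -> None:
    """Write a matrix as TSV: comment header with metadata, then a table with
    1-based window positions in the first column and length bins as columns."""
    meta = (
        f"# chrom={matrix.window.chrom}"
        f" window_start={to_display_coord(matrix.window.start)}"
        f" window_end={matrix.window.end}"
        f" pos_bin={matrix.pos_bin} len_bin={matrix.len_bin}"
        f" len_min={matrix.len_min} len_max={matrix.len_max}"
        f" n_fragments={matrix.n_fragments} assignment={matrix.assignment}\n"
    )
    df = pd.DataFrame(
        matrix.counts,
        index=pd.Index(matrix.display_positions(), name="position"),
        columns=matrix.lengths(),
    )
    with open(path, "w") as fh:
        fh.write(meta)
        df.to_csv(fh, sep="\t")


def read_matrix_tsv(path) -> FragMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing matrix metadata header")
        meta = dict(item.split("=", 1) for item in header[1:].split())
        df = pd.read_csv(fh, sep="\t", index_col=0)
    window = GenomicInterval(
        meta["chrom"], int(meta["window_start"]) - 1, int(meta["window_end"])
    )
    return FragMatrix(
        window=window,
        pos_bin=int(meta["pos_bin"]),
        len_bin=int(meta["len_bin"]),
        len_min=int(meta["len_min"]),
        len_max=int(meta["len_max"]),
        counts=df.to_numpy(dtype=np.float64),
        n_fragments=int(meta["n_fragments"]),
        assignment=meta["assignment"],
    )
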