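"""Footprint occupancy quantification.

Three complementary abundance measures are implemented:

* size-class integrals of the fragment matrix (``integrate_size_class``),
* Reb1-normalized occupancy: factor-class (50-100 bp) depth over a target
  region divided by the same quantity at the Reb1 binding site, whose stable
  footprint serves as an internal standard — ratios of this statistic
  between strains are insensitive to sequencing depth and to global shifts
  in particle composition,
* the ChEC whole-genome measure: the fraction of all cleavage fragments that
  map to the rDNA, compared between strains as a ratio.

Confidence intervals come from fragment-level bootstrap resampling (the
underlying experiments report point estimates only; the bootstrap is this
package's addition so that strain comparisons carry uncertainty).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import NormalizationError, SignalDomainError
from .fragmatrix import FACTOR_CLASS, NUCLEOSOME_CLASS, FragMatrix, SizeClass
from .fragments import Fragments
from .regions import GenomicInterval, RdnaLandmarks, mcm_quantification_region

__all__ = [
    "OccupancyResult",
    "OccupancyComparison",
    "class_span_weights",
    "integrate_size_class",
    "reb1_normalized_occupancy",
    "compare_occupancy",
    "chec_rdna_fraction",
    "chec_abundance_change",
    "nucleosome_occupancies",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OccupancyResult:
    """A normalized occupancy with bootstrap uncertainty.

    ``normalized = raw_signal / normalizer``; ``boot`` holds the bootstrap
    replicates of ``normalized`` so that comparisons can propagate them.
    """

    raw_signal: float
    normalizer: float
    normalized: float
    ci_low: float
    ci_high: float
    boot: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.normalized > 0 and not self.normalizer > 0:
            raise NormalizationError("normalized > 0 requires normalizer > 0")


@dataclass(frozen=True)
class OccupancyComparison:
    """Percent change of test vs reference occupancy (negative = reduction)."""

    percent_change: float
    ci_low: float
    ci_high: float


def class_span_weights(
    fragments: Fragments, interval: GenomicInterval, size_class: SizeClass
) -> np.ndarray:
    """Per-fragment covered bases within ``interval`` for fragments of the
    size class (0 for all others).  Summing equals the span-mode matrix
    integral over the same interval at 1 bp binning."""
    lengths = fragments.lengths
    in_class = size_class.contains(lengths) & (fragments.chroms == interval.chrom)
    overlap = np.minimum(fragments.ends, interval.end) - np.maximum(
        fragments.starts, interval.start
    )
    return np.where(in_class, np.clip(overlap, 0, None), 0).astype(np.float64)


def integrate_size_class(
    matrix: FragMatrix, interval: GenomicInterval, size_class: SizeClass
) -> float:
    """Sum of matrix cells with position in ``interval`` and length in the
    class.  Empty intersections integrate to 0 (with a warning)."""
    ps = matrix.pos_slice(interval)
    if ps.start >= ps.stop:
        log.warning("integrate_size_class: %s outside matrix window", interval)
        return 0.0
    return float(matrix.counts[ps, matrix.len_slice(size_class)].sum())


def _bootstrap_ratio(
    w_num: np.ndarray,
    w_den: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap the ratio sum(w_num)/sum(w_den) by resampling fragments
    with replacement (multiplicity via bincount)."""
    n = w_num.size
    out = np.empty(n_boot)
    for b in range(n_boot):
        mult = np.bincount(rng.integers(0, n, n), minlength=n).astype(np.float64)
        den = mult @ w_den
        out[b] = (mult @ w_num) / den if den > 0 else np.nan
    return out


def reb1_normalized_occupancy(
    fragments: Fragments,
    landmarks: RdnaLandmarks,
    target: Optional[GenomicInterval] = None,
    size_class: SizeClass = FACTOR_CLASS,
    n_boot: int = 200,
    seed: int = 0,
) -> OccupancyResult:
    """Factor-class depth over ``target`` normalized to the Reb1 footprint.

    ``target`` defaults to the Mcm quantification region (c-pro start through
    the end of the downstream window), which encompasses both displaced and
    non-displaced pre-RC signal while excluding the Reb1 site itself.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    target = target or mcm_quantification_region(landmarks)
    w_t = class_span_weights(fragments, target, size_class)
    w_r = class_span_weights(fragments, landmarks.reb1_site, size_class)
    raw = float(w_t.sum())
    norm = float(w_r.sum())
    if norm <= 0:
        raise NormalizationError(
            "no size-class signal at the Reb1 site; cannot normalize"
        )
    rng = np.random.default_rng(seed)
    boot = _bootstrap_ratio(w_t, w_r, n_boot, rng)
    ci_low, ci_high = np.nanpercentile(boot, [2.5, 97.5])
    return OccupancyResult(raw, norm, raw / norm, float(ci_low), float(ci_high), boot)


def compare_occupancy(
    reference: OccupancyResult, test: OccupancyResult
) -> OccupancyComparison:
    """Percent change of test vs reference, CI propagated from the two
    (independent) bootstrap replicate sets."""
    if not reference.normalized > 0:
        raise SignalDomainError("reference occupancy must be positive")
    pct = 100.0 * (test.normalized - reference.normalized) / reference.normalized
    if reference.boot is None or test.boot is None:
        return OccupancyComparison(pct, float("nan"), float("nan"))
    nb = min(reference.boot.size, test.boot.size)
    pct_boot = 100.0 * (test.boot[:nb] / reference.boot[:nb] - 1.0)
    lo, hi = np.nanpercentile(pct_boot, [2.5, 97.5])
    return OccupancyComparison(pct, float(lo), float(hi))


def chec_rdna_fraction(fragments: Fragments, rdna_region: GenomicInterval) -> float:
    """Fraction of all fragments overlapping the rDNA region.

    All fragment lengths count by default (apply a :class:`FragmentFilter`
    upstream for a size-restricted variant).
    """
    n = len(fragments)
    if n == 0:
        raise SignalDomainError("chec_rdna_fraction of an empty fragment set")
    inside = (
        (fragments.chroms == rdna_region.chrom)
        & (fragments.starts < rdna_region.end)
        & (fragments.ends > rdna_region.start)
    )
    return float(inside.sum()) / n


def chec_abundance_change(
    reference: Fragments,
    test: Fragments,
    rdna_region: GenomicInterval,
    n_boot: int = 1000,
    seed: int = 0,
) -> OccupancyComparison:
    """Percent change of the rDNA fragment fraction, test vs reference.

    The two strains' fractions are compared as a ratio; the CI comes from
    binomial (fragment-level) bootstrap of each fraction.
    """
    p_ref = chec_rdna_fraction(reference, rdna_region)
    p_test = chec_rdna_fraction(test, rdna_region)
    if p_ref <= 0:
        raise SignalDomainError("reference rDNA fraction is zero")
    rng = np.random.default_rng(seed)
    n_r, n_t = len(reference), len(test)
    boot_r = rng.binomial(n_r, p_ref, n_boot) / n_r
    boot_t = rng.binomial(n_t, p_test, n_boot) / n_t
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_boot = 100.0 * (boot_t / boot_r - 1.0)
    lo, hi = np.nanpercentile(pct_boot, [2.5, 97.5])
    return OccupancyComparison(100.0 * (p_test / p_ref - 1.0), float(lo), float(hi))


def nucleosome_occupancies(
    matrix: FragMatrix,
    dyads: Sequence[int],
    size_class: SizeClass = NUCLEOSOME_CLASS,
    flank: int = 73,
) -> np.ndarray:
    """Nucleosome-class integrals around each dyad, relative to the first.

    ``flank`` defaults to 73 bp, the canonical core-particle half-width, so
    each integral covers one nucleosome footprint.  The first entry is 1 by
    construction.
    """
    dyads = list(dyads)
    if not dyads:
        raise ValueError("at least one dyad required")
    if sorted(dyads) != dyads:
        raise ValueError("dyads must be sorted left to right")
    vals = np.array(
        [
            integrate_size_class(
                matrix,
                GenomicInterval(matrix.window.chrom, d - flank, d + flank + 1),
                size_class,
            )
            for d in dyads
        ]
    )
    if vals[0] <= 0:
        raise NormalizationError("no nucleosome signal at the first dyad")
    return vals / vals[0]
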