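"""Rightward repositioning of factor-class signal relative to the origin.

When transcription through the origin is derepressed, loaded Mcm2-7
complexes are pushed from their loading site (adjacent to and left of the
rARS) into the low-nucleosome region downstream.  The statistics here
operationalize that as:

* ``downstream_fraction`` — the share of factor-class (50-100 bp) depth that
  lies right of a boundary (the rARS),
* ``com_shift`` — the center-of-mass displacement of factor-class signal
  between two conditions,
* a fragment-label permutation test for the difference in downstream
  fractions between conditions (the underlying observation is visual; the
  permutation test supplies significance).

All quantities are computed on span-mode (coverage) signal within the Mcm
quantification region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import SignalDomainError
from .fragmatrix import FACTOR_CLASS, FragMatrix, SizeClass, position_profile
from .fragments import Fragments
from .occupancy import class_span_weights
from .regions import GenomicInterval, RdnaLandmarks, mcm_quantification_region

__all__ = [
    "DisplacementResult",
    "downstream_fraction",
    "center_of_mass",
    "displacement_test",
]


@dataclass(frozen=True)
class DisplacementResult:
    fraction_downstream_ref: float
    fraction_downstream_test: float
    delta: float
    com_shift: float
    ci_low: float
    ci_high: float
    p_value: float
    n_perm: int

    def __post_init__(self) -> None:
        for name in ("fraction_downstream_ref", "fraction_downstream_test"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def downstream_fraction(
    matrix: FragMatrix, size_class: SizeClass, boundary: int
) -> float:
    """Share of size-class matrix mass at positions >= ``boundary``."""
    if not matrix.window.contains(boundary):
        raise SignalDomainError(
            f"boundary {boundary} outside matrix window {matrix.window}"
        )
    ls = matrix.len_slice(size_class)
    total = float(matrix.counts[:, ls].sum())
    if total <= 0:
        raise SignalDomainError("no size-class signal in the window")
    down = GenomicInterval(matrix.window.chrom, boundary, matrix.window.end)
    return float(matrix.counts[matrix.pos_slice(down), ls].sum()) / total


def center_of_mass(matrix: FragMatrix, size_class: SizeClass) -> float:
    """Depth-weighted mean genomic coordinate of size-class signal (bin
    centers); equals the boundary exactly for signal mirror-symmetric
    about it."""
    profile = position_profile(matrix, size_class)
    total = profile.sum()
    if total <= 0:
        raise SignalDomainError("no size-class signal in the window")
    centers = matrix.positions() + matrix.pos_bin / 2.0
    return float((centers * profile).sum() / total)


def _fraction_and_com(w_tot, w_down, w_pos):
    tot = w_tot.sum()
    return w_down.sum() / tot, w_pos.sum() / tot


def displacement_test(
    ref_fragments: Fragments,
    test_fragments: Fragments,
    landmarks: RdnaLandmarks,
    size_class: SizeClass = FACTOR_CLASS,
    n_boot: int = 999,
    seed: int = 0,
    region: Optional[GenomicInterval] = None,
    n_perm: Optional[int] = None,
) -> DisplacementResult:
    """Two-condition displacement statistic with bootstrap CI and permutation p.

    The boundary is ``landmarks.rars``; ``region`` defaults to the Mcm
    quantification region.  The bootstrap resamples fragments with
    replacement within each condition; the permutation test shuffles
    condition labels at the fragment level under the null of exchangeability
    and reports a two-sided tail probability for ``delta``.
    """
    region = region or mcm_quantification_region(landmarks)
    boundary = landmarks.rars
    down = GenomicInterval(region.chrom, boundary, region.end)
    n_perm = n_boot if n_perm is None else n_perm
    rng = np.random.default_rng(seed)

    stats = {}
    weights = {}
    for name, frags in (("reference", ref_fragments), ("test", test_fragments)):
        w_tot = class_span_weights(frags, region, size_class)
        if w_tot.sum() <= 0:
            raise SignalDomainError(
                f"{name} condition has no {size_class.name}-class signal in {region}"
            )
        w_down = class_span_weights(frags, down, size_class)
        # per-fragment contribution to sum(position * depth): covered span
        # [a, b) contributes w * (a + b) / 2 with base centers at +0.5
        a = np.maximum(frags.starts, region.start)
        b = np.minimum(frags.ends, region.end)
        w_pos = w_tot * (a + b) / 2.0
        weights[name] = (w_tot, w_down, w_pos)
        stats[name] = _fraction_and_com(w_tot, w_down, w_pos)

    f_ref, com_ref = stats["reference"]
    f_test, com_test = stats["test"]
    delta = f_test - f_ref
    com_shift = com_test - com_ref

    # bootstrap CI on delta (within-condition resampling)
    boot = np.empty(n_boot)
    for b_i in range(n_boot):
        vals = []
        for name in ("reference", "test"):
            w_tot, w_down, _ = weights[name]
            n = w_tot.size
            mult = np.bincount(rng.integers(0, n, n), minlength=n).astype(np.float64)
            tot = mult @ w_tot
            vals.append((mult @ w_down) / tot if tot > 0 else np.nan)
        boot[b_i] = vals[1] - vals[0]
    ci_low, ci_high = np.nanpercentile(boot, [2.5, 97.5])

    # permutation p-value: shuffle fragment labels, keep group sizes
    wt_ref, wd_ref, _ = weights["reference"]
    wt_test, wd_test, _ = weights["test"]
    pool_tot = np.concatenate([wt_ref, wt_test])
    pool_down = np.concatenate([wd_ref, wd_test])
    n_ref = wt_ref.size
    exceed = 0
    for _ in range(n_perm):
        idx = rng.permutation(pool_tot.size)
        ri, ti = idx[:n_ref], idx[n_ref:]
        tr, tt = pool_tot[ri].sum(), pool_tot[ti].sum()
        if tr <= 0 or tt <= 0:
            exceed += 1  # degenerate split counts against significance
            continue
        d = pool_down[ti].sum() / tt - pool_down[ri].sum() / tr
        if abs(d) >= abs(delta):
            exceed += 1
    p_value = (1 + exceed) / (n_perm + 1)

    return DisplacementResult(
        fraction_downstream_ref=float(f_ref),
        fraction_downstream_test=float(f_test),
        delta=float(delta),
        com_shift=float(com_shift),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p_value),
        n_perm=n_perm,
    )
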