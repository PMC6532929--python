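"""Synthetic fragment generator for the rDNA origin locus.

The generator emulates the statistical structure the analysis assumes, so
that every pipeline stage can be tested against known ground truth without
any external data:

* positioned nucleosomes (~147 bp protection) with per-nucleosome occupancy,
* site-specific factor footprints — Reb1 upstream of c-pro and the pre-RC
  (Mcm2-7) adjacent to the rARS — protecting 50-100 bp,
* cell-cycle logic: the pre-RC is G1-specific, and pre-RC binding and the
  origin nucleosome are mutually exclusive on any given repeat copy (the
  nucleosome's effective occupancy is scaled by the probability the pre-RC
  is absent),
* sir2-like perturbation: total pre-RC loading scaled by ``loading_factor``
  and a fraction ``p_push`` of loaded complexes displaced rightward,
  uniformly over ``push_window``,
* MNase-style digestion noise: Gaussian edge jitter, plus a log-normal
  background of fragments from incompletely digested unprotected DNA,
* ChEC mode: cleavage flanks only the MNase-tagged particle, a library-prep
  size cap keeps fragments short, and a genome-wide background pool sized by
  ``rdna_share`` supports rDNA-fraction abundance measures,
* S/G1 count sampling with an rDNA-specific replicated fraction.

Every simulator is deterministic given its seed, and returns a truth record
storing all latent per-fragment choices so parameter-recovery tests never
re-derive them.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ModelError
from .fragments import Fragments
from .regions import GenomicInterval, RdnaLandmarks, default_landmarks
from .sseq import SseqCounts

__all__ = [
    "ParticleSpec",
    "ChromatinModel",
    "SimTruth",
    "wt_g1_model",
    "wt_g2_model",
    "sir2_g1_model",
    "terminator_model",
    "MODEL_PRESETS",
    "origin_interval",
    "simulate_mnase_fragments",
    "simulate_chec_fragments",
    "simulate_sseq_counts",
    "expected_replication_index",
    "write_truth_tsv",
]

#: Non-rDNA fragments in ChEC mode are placed on a decoy chromosome
#: (sacCer3 chromosome IV length); only their count matters downstream.
DECOY_CHROM = "chrIV"
DECOY_CHROM_LEN = 1_531_933

#: sir2-like loading: total pre-RC occupancy multiplier (a 37% reduction).
SIR2_LOADING_FACTOR = 0.63
#: sir2-like displacement probability for a loaded pre-RC.
SIR2_P_PUSH = 0.6
#: Genome-wide ChEC fragment share originating from the rDNA, WT vs sir2
#: (their ratio encodes a 47% abundance reduction).
WT_RDNA_SHARE = 0.10
SIR2_RDNA_SHARE = 0.053

#: Nucleosome spacing used by the presets (center-to-center, bp).
NUCLEOSOME_SPACING = 165
#: Per-nucleosome occupancies left to right: first (at the c-pro initiation
#: site) highest, third next, last three ~10% of the first.
NUCLEOSOME_OCCUPANCIES = (0.9, 0.3, 0.6, 0.1, 0.1, 0.1)


@dataclass(frozen=True)
class ParticleSpec:
    """One protective particle: where it sits, how much DNA it protects, and
    how often it is bound."""

    name: str
    center: int
    kind: str  # {"nucleosome", "factor", "reb1"}
    footprint_mean: float
    footprint_sd: float
    occupancy: float
    tagged: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ModelError(f"{self.name}: occupancy outside [0, 1]")
        if self.footprint_mean <= 0:
            raise ModelError(f"{self.name}: footprint_mean must be positive")
        if self.kind not in ("nucleosome", "factor", "reb1"):
            raise ModelError(f"{self.name}: unknown particle kind {self.kind!r}")


@dataclass(frozen=True)
class ChromatinModel:
    """Generative particle map for one strain/cell-cycle condition."""

    landmarks: RdnaLandmarks
    particles: tuple[ParticleSpec, ...]
    competition_pairs: tuple[tuple[str, str], ...] = ()
    background_rate: float = 0.05
    background_len_mean: float = 200.0
    background_len_sd: float = 100.0
    p_push: float = 0.0
    push_window: Optional[GenomicInterval] = None
    loading_factor: float = 1.0
    jitter_sd: float = 3.0
    rdna_share: float = WT_RDNA_SHARE
    chec_background_len_mean: float = 100.0
    chec_background_len_sd: float = 40.0
    chec_max_length: int = 250

    def __post_init__(self) -> None:
        for name in ("background_rate", "p_push", "rdna_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ModelError(f"{name}={v} outside [0, 1]")
        if self.loading_factor < 0:
            raise ModelError("loading_factor must be non-negative")
        names = [p.name for p in self.particles]
        if len(set(names)) != len(names):
            raise ModelError("particle names must be unique")
        for a, b in self.competition_pairs:
            if a not in names or b not in names:
                raise ModelError(f"competition pair ({a}, {b}) names unknown particle")
        if self.p_push > 0:
            if self.push_window is None:
                raise ModelError("p_push > 0 requires a push_window")
            if not self.landmarks.repeat_unit.contains_interval(self.push_window):
                raise ModelError("push_window must lie within the repeat unit")

    def particle(self, name: str) -> ParticleSpec:
        for p in self.particles:
            if p.name == name:
                return p
        raise KeyError(name)

    def effective_occupancies(self) -> dict[str, float]:
        """Occupancies after applying the loading factor to factor particles
        and resolving mutual exclusion: for each competition pair the
        non-factor member is bound only when the factor is not."""
        eff = {p.name: p.occupancy for p in self.particles}
        for p in self.particles:
            if p.kind == "factor":
                eff[p.name] = min(1.0, p.occupancy * self.loading_factor)
        for a, b in self.competition_pairs:
            pa, pb = self.particle(a), self.particle(b)
            fac, other = (a, b) if pa.kind == "factor" else (b, a)
            eff[other] = self.particle(other).occupancy * (1.0 - eff[fac])
        return eff


@dataclass
class SimTruth:
    """Latent state of one simulation: per-fragment assignments plus the
    effective occupancies and parameters that generated them."""

    per_fragment: pd.DataFrame
    effective_occupancy: dict[str, float]
    params: dict


# ---------------------------------------------------------------------------
# Preset models (strain x cell-cycle scenarios)
# ---------------------------------------------------------------------------

def _base_particles(lm: RdnaLandmarks, prerc_occupancy: float) -> tuple[ParticleSpec, ...]:
    reb1_center = (lm.reb1_site.start + lm.reb1_site.end) // 2
    parts = [
        # The Reb1 genomic site is 25 bp but its MNase-protected fragments
        # run 50-100 bp; the protection length (70±8) models the fragments.
        ParticleSpec("reb1", reb1_center, "reb1", 70.0, 8.0, 0.9),
    ]
    # nucleosome-protected fragments peak near 160 bp (the core particle
    # plus protected linker ends), squarely inside the 150-200 bp band
    for i, occ in enumerate(NUCLEOSOME_OCCUPANCIES):
        parts.append(
            ParticleSpec(
                f"nuc{i + 1}",
                lm.c_pro_start + i * NUCLEOSOME_SPACING,
                "nucleosome",
                160.0,
                8.0,
                occ,
            )
        )
    # pre-RC loads adjacent to (left of) the rARS, on the repeat copy where
    # the second nucleosome is evicted
    parts.append(
        ParticleSpec(
            "prerc",
            lm.c_pro_start + NUCLEOSOME_SPACING,
            "factor",
            60.0,
            10.0,
            prerc_occupancy,
            tagged=True,
        )
    )
    return tuple(parts)


def _push_window(lm: RdnaLandmarks) -> GenomicInterval:
    # displaced complexes land in the low-nucleosome region right of the
    # origin, kept inside the downstream window with room for the footprint
    return GenomicInterval(lm.chrom, lm.rars + 30, lm.rars + 350)


def _model(
    lm: Optional[RdnaLandmarks],
    prerc_occupancy: float,
    loading_factor: float,
    p_push: float,
    rdna_share: float,
) -> ChromatinModel:
    lm = lm or default_landmarks()
    return ChromatinModel(
        landmarks=lm,
        particles=_base_particles(lm, prerc_occupancy),
        competition_pairs=(("nuc2", "prerc"),),
        p_push=p_push,
        push_window=_push_window(lm),
        loading_factor=loading_factor,
        rdna_share=rdna_share,
    )


def wt_g1_model(landmarks: Optional[RdnaLandmarks] = None) -> ChromatinModel:
    """Wild type, G1 arrest: pre-RC loaded, origin nucleosome largely evicted."""
    return _model(landmarks, 0.9, 1.0, 0.0, WT_RDNA_SHARE)


def wt_g2_model(landmarks: Optional[RdnaLandmarks] = None) -> ChromatinModel:
    """Wild type, G2 arrest: the pre-RC is G1-specific, so its occupancy is 0
    and the origin nucleosome is fully available."""
    return _model(landmarks, 0.0, 1.0, 0.0, WT_RDNA_SHARE)


def sir2_g1_model(landmarks: Optional[RdnaLandmarks] = None) -> ChromatinModel:
    """sir2 deletion, G1: reduced total loading (x0.63) and rightward
    displacement of a fraction of loaded complexes by readthrough
    transcription."""
    return _model(landmarks, 0.9, SIR2_LOADING_FACTOR, SIR2_P_PUSH, SIR2_RDNA_SHARE)


def terminator_model(landmarks: Optional[RdnaLandmarks] = None) -> ChromatinModel:
    """sir2 deletion with a transcription terminator between c-pro and the
    origin: loading stays reduced but displacement is abolished."""
    return _model(landmarks, 0.9, SIR2_LOADING_FACTOR, 0.0, SIR2_RDNA_SHARE)


MODEL_PRESETS = {
    "wt-g1": wt_g1_model,
    "wt-g2": wt_g2_model,
    "sir2-g1": sir2_g1_model,
    "sir2-term": terminator_model,
}


def origin_interval(model: ChromatinModel, half_width: int = 50) -> GenomicInterval:
    """Interval centered on the pre-RC loading site / competing nucleosome."""
    prerc = next(p for p in model.particles if p.kind == "factor")
    return GenomicInterval(
        model.landmarks.chrom, prerc.center - half_width, prerc.center + half_width
    )


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) for a log-normal with given mean/sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _jitter(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)


def _assemble(centers, lengths, e1, e2, chrom, n) -> Fragments:
    starts = np.rint(centers - lengths / 2.0 + e1).astype(np.int64)
    ends = np.rint(centers + lengths / 2.0 + e2).astype(np.int64)
    ends = np.maximum(ends, starts + 1)
    return Fragments(np.full(n, chrom, dtype=object), starts, ends)


def simulate_mnase_fragments(
    model: ChromatinModel, n: int, seed: int
) -> tuple[Fragments, SimTruth]:
    """Draw ``n`` MNase-protected fragments from one repeat unit.

    Per fragment: background vs particle by ``background_rate``; particle
    chosen proportional to effective occupancy (competition resolved there);
    a loaded pre-RC is displaced with probability ``p_push`` to a uniform
    position in ``push_window``; both fragment ends get independent Gaussian
    digestion jitter.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lm = model.landmarks
    eff = model.effective_occupancies()
    parts = model.particles
    occ = np.array([eff[p.name] for p in parts])
    if occ.sum() <= 0 and model.background_rate <= 0:
        raise ModelError("model generates no fragments: all occupancies zero")
    probs = np.concatenate(
        [[model.background_rate], (1.0 - model.background_rate) * occ / occ.sum()]
    ) if occ.sum() > 0 else np.array([1.0])
    src = rng.choice(probs.size, size=n, p=probs)  # 0 = background
    is_bg = src == 0
    pidx = src - 1

    centers = np.empty(n)
    lengths = np.empty(n)
    n_bg = int(is_bg.sum())
    mu, sigma = _lognormal_params(model.background_len_mean, model.background_len_sd)
    centers[is_bg] = rng.uniform(lm.repeat_unit.start, lm.repeat_unit.end, n_bg)
    lengths[is_bg] = rng.lognormal(mu, sigma, n_bg)

    p_center = np.array([p.center for p in parts], dtype=float)
    p_mean = np.array([p.footprint_mean for p in parts])
    p_sd = np.array([p.footprint_sd for p in parts])
    m = ~is_bg
    centers[m] = p_center[pidx[m]]
    lengths[m] = rng.normal(p_mean[pidx[m]], p_sd[pidx[m]])

    factor_idx = np.array([i for i, p in enumerate(parts) if p.kind == "factor"])
    loaded = m & np.isin(pidx, factor_idx)
    displaced = loaded & (rng.random(n) < model.p_push)
    n_disp = int(displaced.sum())
    if n_disp:
        centers[displaced] = rng.uniform(
            model.push_window.start, model.push_window.end, n_disp
        )
    lengths = np.maximum(lengths, 2.0)

    frags = _assemble(
        centers, lengths, _jitter(rng, model.jitter_sd, n),
        _jitter(rng, model.jitter_sd, n), lm.chrom, n,
    )
    names = np.array(["background"] + [p.name for p in parts])
    truth = SimTruth(
        per_fragment=pd.DataFrame(
            {"source": names[src], "displaced": displaced, "center": centers,
             "length": lengths}
        ),
        effective_occupancy=eff,
        params={"mode": "mnase", "n": n, "seed": seed,
                "p_push": model.p_push, "loading_factor": model.loading_factor,
                "background_rate": model.background_rate},
    )
    return frags, truth


def simulate_chec_fragments(
    model: ChromatinModel, n: int, seed: int, max_length: Optional[int] = None
) -> tuple[Fragments, SimTruth]:
    """Draw ``n`` ChEC cleavage fragments genome-wide.

    A fraction ``rdna_share`` of fragments originates from the rDNA, where
    cleavage flanks the MNase-tagged particle(s) (cut positions at the
    particle edges plus jitter); the rest form a genome-wide background pool
    on a decoy chromosome.  Library preparation amplifies only short
    fragments, emulated by dropping fragments above ``max_length``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cap = model.chec_max_length if max_length is None else max_length
    tagged = [p for p in model.particles if p.tagged]
    if not tagged:
        raise ModelError("ChEC simulation requires at least one tagged particle")
    rng = np.random.default_rng(seed)
    lm = model.landmarks
    eff = model.effective_occupancies()

    in_rdna = rng.random(n) < model.rdna_share
    n_in = int(in_rdna.sum())
    weights = np.array([max(eff[p.name], 0.0) for p in tagged])
    if weights.sum() <= 0:
        raise ModelError("no tagged particle has positive effective occupancy")
    t_idx = rng.choice(len(tagged), size=n_in, p=weights / weights.sum())

    centers = np.empty(n)
    lengths = np.empty(n)
    t_center = np.array([p.center for p in tagged], dtype=float)
    t_mean = np.array([p.footprint_mean for p in tagged])
    t_sd = np.array([p.footprint_sd for p in tagged])
    centers[in_rdna] = t_center[t_idx]
    lengths[in_rdna] = rng.normal(t_mean[t_idx], t_sd[t_idx])

    displaced = np.zeros(n, dtype=bool)
    disp_draw = rng.random(n_in) < model.p_push
    kinds = np.array([p.kind for p in tagged])
    disp_draw &= kinds[t_idx] == "factor"
    displaced[np.flatnonzero(in_rdna)[disp_draw]] = True
    n_disp = int(disp_draw.sum())
    if n_disp:
        centers[displaced] = rng.uniform(
            model.push_window.start, model.push_window.end, n_disp
        )

    n_out = n - n_in
    mu, sigma = _lognormal_params(
        model.chec_background_len_mean, model.chec_background_len_sd
    )
    centers[~in_rdna] = rng.uniform(200.0, DECOY_CHROM_LEN - 200.0, n_out)
    lengths[~in_rdna] = rng.lognormal(mu, sigma, n_out)
    lengths = np.maximum(lengths, 2.0)

    e1 = _jitter(rng, model.jitter_sd, n)
    e2 = _jitter(rng, model.jitter_sd, n)
    starts = np.rint(centers - lengths / 2.0 + e1).astype(np.int64)
    ends = np.rint(centers + lengths / 2.0 + e2).astype(np.int64)
    ends = np.maximum(ends, starts + 1)
    chroms = np.where(in_rdna, lm.chrom, DECOY_CHROM).astype(object)

    keep = (ends - starts) <= cap
    frags = Fragments(chroms[keep], starts[keep], ends[keep])
    source = np.full(n, "genome_background", dtype=object)
    source[in_rdna] = np.array([p.name for p in tagged], dtype=object)[t_idx]
    truth = SimTruth(
        per_fragment=pd.DataFrame(
            {"source": source[keep], "in_rdna": in_rdna[keep],
             "displaced": displaced[keep]}
        ),
        effective_occupancy=eff,
        params={"mode": "chec", "n": n, "seed": seed, "rdna_share": model.rdna_share,
                "p_push": model.p_push, "max_length": cap,
                "n_dropped_by_cap": int(n - keep.sum())},
    )
    return frags, truth


def simulate_sseq_counts(
    rdna_share_g1: float,
    replicated_fraction_rdna: float,
    replicated_fraction_genome: float,
    n_s: int,
    n_g1: int,
    seed: int,
) -> SseqCounts:
    """Sample S-seq counts under a copy-number model.

    In G1 every locus is at 1 copy, so rDNA counts are binomial with the
    G1 share.  In S phase a region replicated in fraction ``f`` of cells is
    present at ``1 + f`` copies, so the rDNA share is rescaled by relative
    copy number before sampling.
    """
    for name, v in (
        ("rdna_share_g1", rdna_share_g1),
        ("replicated_fraction_rdna", replicated_fraction_rdna),
        ("replicated_fraction_genome", replicated_fraction_genome),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if not 0.0 < rdna_share_g1:
        raise ValueError("rdna_share_g1 must be positive")
    rng = np.random.default_rng(seed)
    s = rdna_share_g1
    share_s = (
        s * (1.0 + replicated_fraction_rdna)
        / (1.0 + replicated_fraction_genome * (1.0 - s) + replicated_fraction_rdna * s)
    )
    return SseqCounts(
        rdna_s=int(rng.binomial(n_s, share_s)),
        total_s=n_s,
        rdna_g1=int(rng.binomial(n_g1, s)),
        total_g1=n_g1,
    )


def expected_replication_index(
    rdna_share_g1: float,
    replicated_fraction_rdna: float,
    replicated_fraction_genome: float,
) -> float:
    """Closed-form expectation of the S/G1 index under the copy-number model
    of :func:`simulate_sseq_counts`."""
    s = rdna_share_g1
    return (1.0 + replicated_fraction_rdna) / (
        1.0 + replicated_fraction_genome * (1.0 - s) + replicated_fraction_rdna * s
    )


def write_truth_tsv(truth: SimTruth, path) -> None:
    """Serialize a truth record: parameter comment lines + per-fragment table."""
    with open(path, "w") as fh:
        for k, v in truth.params.items():
            fh.write(f"# {k}={v}\n")
        for k, v in truth.effective_occupancy.items():
            fh.write(f"# eff_occupancy.{k}={v:.6g}\n")
        truth.per_fragment.to_csv(fh, sep="\t", index=False)
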