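"""Coordinate conventions and the rDNA landmark model.

Everything downstream of this module works in 0-based half-open coordinates
(the BED convention).  All user-facing text — configuration files, serialized
matrices, axis labels — uses 1-based inclusive coordinates, the convention of
genome browsers and of the sacCer3 positions cited throughout the literature
on this locus (e.g. the rDNA origin, rARS, at base pair 458,991 on
chromosome XII).  The two conversion helpers below are the only place the
off-by-one lives.

The budding-yeast rDNA is an array of ~150 tandem 9.1 kb repeats on
chromosome XII.  Each repeat carries, within intergenic spacer 2: the binding
site of the transcription factor Reb1, the Sir2-repressed RNA Pol II promoter
c-pro, the replication origin (rARS) 200 bp downstream of the c-pro
initiation site, and the 5S rRNA gene.  :class:`RdnaLandmarks` pins those
anchors plus the ~1.25 kb analysis window spanning the origin and the
downstream window that receives transcription-displaced pre-RC signal.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, fields
from importlib import resources

import yaml

from .errors import ConfigurationError, LandmarkValidationError

__all__ = [
    "GenomicInterval",
    "RdnaLandmarks",
    "load_landmarks",
    "load_landmarks_file",
    "serialize_landmarks",
    "default_landmarks",
    "to_display_coord",
    "from_display_coord",
    "mcm_quantification_region",
    "rdna_genome_fraction",
    "SACCER3_GENOME_BP",
    "RDNA_REPEAT_COUNT",
    "RDNA_UNIT_BP",
    "REFERENCE_RDNA_COPIES",
]

#: Total length of the sacCer3 reference assembly (16 nuclear chromosomes +
#: mitochondrion).  The reference itself carries only ~2 rDNA repeat copies.
SACCER3_GENOME_BP = 12_157_105
RDNA_REPEAT_COUNT = 150
RDNA_UNIT_BP = 9_100
REFERENCE_RDNA_COPIES = 2


def to_display_coord(internal: int) -> int:
    """Convert an internal 0-based coordinate to 1-based display form."""
    if internal < 0:
        raise ValueError(f"internal coordinate must be >= 0, got {internal}")
    return internal + 1


def from_display_coord(display: int) -> int:
    """Convert a 1-based display coordinate to internal 0-based form."""
    if display < 1:
        raise ValueError(f"display coordinate must be >= 1, got {display}")
    return display - 1


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise LandmarkValidationError(
                f"interval start must be >= 0, got {self.start}"
            )
        if self.end <= self.start:
            raise LandmarkValidationError(
                f"interval end must exceed start: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RdnaLandmarks:
    """Named anchors of one rDNA repeat unit, in internal coordinates.

    ``downstream_window`` starts exactly at ``rars`` and covers the region
    that receives rightward-displaced pre-RC signal; its extent is a tunable
    (the displaced signal lies within a few hundred bp right of the origin,
    but no precise boundary exists), defaulting to 400 bp in the shipped
    configuration.
    """

    repeat_unit: GenomicInterval
    reb1_site: GenomicInterval
    c_pro_start: int
    rars: int
    five_s: GenomicInterval
    analysis_window: GenomicInterval
    downstream_window: GenomicInterval

    def __post_init__(self) -> None:
        unit = self.repeat_unit
        for name in ("reb1_site", "five_s", "analysis_window", "downstream_window"):
            iv: GenomicInterval = getattr(self, name)
            if not unit.contains_interval(iv):
                raise LandmarkValidationError(
                    f"{name} {iv} does not fall within repeat_unit {unit}"
                )
        for name in ("c_pro_start", "rars"):
            if not unit.contains(getattr(self, name)):
                raise LandmarkValidationError(
                    f"{name}={getattr(self, name)} outside repeat_unit {unit}"
                )
        if not self.c_pro_start < self.rars:
            raise LandmarkValidationError(
                "c_pro_start must lie upstream (left) of rars: "
                f"{self.c_pro_start} !< {self.rars}"
            )
        if not self.analysis_window.contains(self.rars):
            raise LandmarkValidationError(
                f"rars={self.rars} must lie inside analysis_window "
                f"{self.analysis_window}"
            )
        if self.downstream_window.start != self.rars:
            raise LandmarkValidationError(
                "downstream_window must start at rars: "
                f"{self.downstream_window.start} != {self.rars}"
            )

    @property
    def chrom(self) -> str:
        return self.repeat_unit.chrom

    @property
    def unit_length(self) -> int:
        return self.repeat_unit.length


#: Keys required in a landmark configuration document (all 1-based inclusive).
LANDMARK_KEYS = (
    "chrom",
    "repeat_start",
    "repeat_end",
    "reb1_start",
    "reb1_end",
    "c_pro_start",
    "rars",
    "five_s_start",
    "five_s_end",
    "window_start",
    "window_end",
    "downstream_end",
)


def load_landmarks(config_text: str) -> RdnaLandmarks:
    """Parse a YAML landmark document (1-based inclusive coordinates).

    Raises :class:`ConfigurationError` naming any missing key, and
    :class:`LandmarkValidationError` naming any violated constraint.
    """
    data = yaml.safe_load(config_text)
    if not isinstance(data, dict):
        raise ConfigurationError("landmark config must be a key: value mapping")
    missing = [k for k in LANDMARK_KEYS if k not in data]
    if missing:
        raise ConfigurationError(f"missing landmark key(s): {', '.join(missing)}")
    chrom = str(data["chrom"])

    def _i(key: str) -> int:
        try:
            return int(data[key])
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"landmark key {key!r} must be an integer") from exc

    def _iv(start_key: str, end_key: str) -> GenomicInterval:
        # 1-based inclusive [s, e] -> 0-based half-open [s-1, e)
        return GenomicInterval(chrom, _i(start_key) - 1, _i(end_key))

    rars0 = _i("rars") - 1
    return RdnaLandmarks(
        repeat_unit=_iv("repeat_start", "repeat_end"),
        reb1_site=_iv("reb1_start", "reb1_end"),
        c_pro_start=_i("c_pro_start") - 1,
        rars=rars0,
        five_s=_iv("five_s_start", "five_s_end"),
        analysis_window=_iv("window_start", "window_end"),
        downstream_window=GenomicInterval(chrom, rars0, _i("downstream_end")),
    )


def load_landmarks_file(path) -> RdnaLandmarks:
    with open(path) as fh:
        return load_landmarks(fh.read())


def serialize_landmarks(lm: RdnaLandmarks) -> str:
    """Render landmarks back to the canonical 1-based YAML document."""
    doc = {
        "chrom": lm.chrom,
        "repeat_start": to_display_coord(lm.repeat_unit.start),
        "repeat_end": lm.repeat_unit.end,
        "reb1_start": to_display_coord(lm.reb1_site.start),
        "reb1_end": lm.reb1_site.end,
        "c_pro_start": to_display_coord(lm.c_pro_start),
        "rars": to_display_coord(lm.rars),
        "five_s_start": to_display_coord(lm.five_s.start),
        "five_s_end": lm.five_s.end,
        "window_start": to_display_coord(lm.analysis_window.start),
        "window_end": lm.analysis_window.end,
        "downstream_end": lm.downstream_window.end,
    }
    lines = [f"{key}: {doc[key]}" for key in LANDMARK_KEYS]
    return "\n".join(lines) + "\n"


@functools.lru_cache(maxsize=1)
def default_landmarks() -> RdnaLandmarks:
    """The landmark set shipped with the package (sacCer3 chromosome XII)."""
    text = (resources.files("rdnafoot") / "data" / "rdna_saccer3.yaml").read_text()
    return load_landmarks(text)


def mcm_quantification_region(lm: RdnaLandmarks) -> GenomicInterval:
    """Region over which total (displaced + non-displaced) Mcm2-7 signal is
    integrated: from the c-pro initiation site — just downstream of the Reb1
    normalization site, so Reb1's own factor-sized fragments are excluded —
    through the end of the downstream displacement window."""
    return GenomicInterval(lm.chrom, lm.c_pro_start, lm.downstream_window.end)


def rdna_genome_fraction(
    n_repeats: int = RDNA_REPEAT_COUNT,
    unit_length: int = RDNA_UNIT_BP,
    genome_length: int = SACCER3_GENOME_BP,
    reference_rdna_copies: int = REFERENCE_RDNA_COPIES,
) -> float:
    """Percent of total genomic DNA contributed by the rDNA array.

    The reference assembly collapses the array to ``reference_rdna_copies``
    repeats, so the full-genome size is the assembly length with the array
    expanded to ``n_repeats`` copies.  With the canonical 150 x 9.1 kb array
    this evaluates to ~10% of the genome.
    """
    if n_repeats < 1 or unit_length < 1:
        raise ValueError("repeat count and unit length must be positive")
    array_bp = n_repeats * unit_length
    non_rdna = genome_length - reference_rdna_copies * unit_length
    if non_rdna <= 0:
        raise ValueError("genome length must exceed the reference rDNA content")
    return 100.0 * array_bp / (non_rdna + array_bp)
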