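"""Steady-state transcription kinetics for a very long gene.

The model: a gene of length L bp is transcribed at a constant rate
(L / total transcription time, ~40 bases·s⁻¹ for a 2.3 Mbp gene at 16 h),
with co-transcriptional splicing, immediate export on completion and
first-order decay of the mature message. A probe targeting 5' sequence
labels both nascent and mature transcripts; a probe near the 3' end labels
(essentially) mature transcripts only. At steady state the abundance ratio

    5'/3' = (nascent + mature) / mature = (T_transcript + T_lifetime) / T_lifetime

links the inter-probe transcription time T_transcript to the mean lifetime
of the mature mRNA, with half-life T_1/2 = 0.693 · T_lifetime.

The factor 0.693 is used verbatim rather than ln 2; the difference
(~2·10⁻⁴ relative) is far below every other uncertainty here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .geometry import FieldGeometry

LN2_APPROX = 0.693

#: Genomic separation between the ends of the 5' and 3' ISH probe regions.
ISH_SEPARATION_BP = 1_550_000
#: Genomic separation between the 5'-most and 3'-most qPCR amplicons.
QPCR_SEPARATION_BP = 1_950_000


@dataclass(frozen=True)
class GeneModel:
    """Gene length, total transcription time and probe-region layout.

    Region spans are (start, end) genomic offsets in bp downstream of the
    transcription start. Defaults describe full-length muscle dystrophin
    (dp427m): 2.3 Mbp, 16 h transcription, 5' probe region ending at
    715 kb and 3' probe region ending 1,550 kbp later.
    """

    gene_length_bp: float = 2_300_000
    total_transcription_time_h: float = 16.0
    regions: dict = field(default_factory=lambda: {
        "5p": (190_000, 715_000),
        "3p": (2_177_000, 2_265_000),
    })

    def __post_init__(self) -> None:
        if self.gene_length_bp <= 0 or self.total_transcription_time_h <= 0:
            raise ValueError("gene length and transcription time must be > 0")
        for name, (start, end) in self.regions.items():
            if not (0 <= start <= end <= self.gene_length_bp):
                raise ValueError(f"region {name!r} outside gene bounds")

    @property
    def elongation_rate_bp_per_s(self) -> float:
        return self.gene_length_bp / (self.total_transcription_time_h * 3600.0)

    def separation_bp(self, upstream: str, downstream: str) -> float:
        """Distance between the ends of two named regions."""
        return self.regions[downstream][1] - self.regions[upstream][1]


def transcription_time_between(gene: GeneModel, distance_bp: float) -> float:
    """Hours needed to transcribe ``distance_bp`` at the gene's constant rate."""
    if distance_bp < 0:
        raise ValueError("distance_bp must be >= 0")
    if distance_bp > gene.gene_length_bp:
        raise ValueError("distance_bp exceeds gene length")
    return distance_bp * gene.total_transcription_time_h / gene.gene_length_bp


def mean_lifetime_from_ratio(ratio_5p_3p: float, t_transcript_h: float) -> float:
    """Mean lifetime of the mature transcript from the steady-state ratio.

    Inverts 5'/3' = (T_transcript + T_lifetime)/T_lifetime, i.e.
    T_lifetime = T_transcript / (ratio − 1). A ratio ≤ 1 has no finite
    steady-state solution and raises.
    """
    if t_transcript_h <= 0:
        raise ValueError("t_transcript_h must be > 0")
    if ratio_5p_3p <= 1:
        raise ValueError("ratio must exceed 1 for a finite mean lifetime")
    return t_transcript_h / (ratio_5p_3p - 1.0)


def half_life(mean_lifetime_h: float) -> float:
    """T_1/2 = 0.693 · T_lifetime."""
    if mean_lifetime_h <= 0:
        raise ValueError("mean_lifetime_h must be > 0")
    return LN2_APPROX * mean_lifetime_h


def mean_lifetime_from_half_life(half_life_h: float) -> float:
    """Inverse of :func:`half_life`."""
    if half_life_h <= 0:
        raise ValueError("half_life_h must be > 0")
    return half_life_h / LN2_APPROX


def nascent_fraction(ratio_5p_3p: float) -> float:
    """Fraction of all transcripts that are nascent: 1 − 1/ratio."""
    if ratio_5p_3p <= 1:
        raise ValueError("ratio must exceed 1")
    return 1.0 - 1.0 / ratio_5p_3p


def nascent_fraction_from_counts(nascent_total: float, mature_total: float) -> float:
    if nascent_total < 0 or mature_total < 0:
        raise ValueError("totals must be >= 0")
    total = nascent_total + mature_total
    if total == 0:
        raise ValueError("both totals are zero")
    return nascent_total / total


@dataclass(frozen=True)
class KineticEstimate:
    """Derived kinetic quantities for one 5'/3' abundance ratio."""

    ratio_5p_3p: float
    t_transcript_h: float
    mean_lifetime_h: float
    half_life_h: float
    nascent_fraction: float

    @classmethod
    def from_ratio(cls, ratio_5p_3p: float, t_transcript_h: float) -> "KineticEstimate":
        life = mean_lifetime_from_ratio(ratio_5p_3p, t_transcript_h)
        return cls(
            ratio_5p_3p=ratio_5p_3p,
            t_transcript_h=t_transcript_h,
            mean_lifetime_h=life,
            half_life_h=half_life(life),
            nascent_fraction=nascent_fraction(ratio_5p_3p),
        )

    @classmethod
    def from_abundances(cls, abundance_5p: float, abundance_3p: float,
                        t_transcript_h: float) -> "KineticEstimate":
        """Accepts per-ng abundances (qPCR-style) or per-field counts."""
        if abundance_3p <= 0:
            raise ValueError("3' abundance must be > 0")
        return cls.from_ratio(abundance_5p / abundance_3p, t_transcript_h)


def field_rna_mass(geometry: FieldGeometry) -> tuple[float, float, float]:
    """(tissue mass μg, RNA low ng, RNA high ng) for one imaging field."""
    low, high = geometry.rna_ng_range
    return (geometry.tissue_mass_ug, low, high)


def transcripts_per_ng(field_counts, geometry: FieldGeometry,
                       assumed_rna_ng: float | None = None,
                       allow_out_of_range: bool = False):
    """Normalize per-field transcript counts to an assumed RNA mass.

    ``field_counts`` may be a scalar, array or mapping of counts per field.
    ``assumed_rna_ng`` defaults to the midpoint of the geometry's computed
    RNA range; an explicit value outside that range raises unless
    ``allow_out_of_range`` is set.
    """
    low, high = geometry.rna_ng_range
    if assumed_rna_ng is None:
        assumed_rna_ng = 0.5 * (low + high)
    if assumed_rna_ng <= 0:
        raise ValueError("assumed_rna_ng must be > 0")
    if not allow_out_of_range and not (low <= assumed_rna_ng <= high):
        raise ValueError(
            f"assumed_rna_ng {assumed_rna_ng:g} outside computed range "
            f"[{low:g}, {high:g}]; pass allow_out_of_range=True to override")
    if isinstance(field_counts, dict):
        return {k: v / assumed_rna_ng for k, v in field_counts.items()}
    return field_counts / assumed_rna_ng


def total_transcripts(nascent_per_nucleus_mean: float, n_large_foci: float,
                      mature_count: float) -> float:
    """Total-transcript metric: nascent per expressing nucleus × expressing
    nuclei, plus all mature foci."""
    if min(nascent_per_nucleus_mean, n_large_foci, mature_count) < 0:
        raise ValueError("inputs must be >= 0")
    return nascent_per_nucleus_mean * n_large_foci + mature_count


def initiation_interval(occupancy_per_nucleus: float,
                        residence_time_h: float) -> float:
    """Minutes between successive transcription initiations in one nucleus.

    Steady-state occupancy = residence time / initiation interval. The
    residence time (how long a polymerase carries probe-detectable
    sequence) is an explicit parameter: the full 16 h transit and the
    ~11 h of 5'-labelled residence are both defensible readings.
    """
    if occupancy_per_nucleus <= 0 or residence_time_h <= 0:
        raise ValueError("occupancy and residence time must be > 0")
    return residence_time_h * 60.0 / occupancy_per_nucleus
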