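"""Core domain types and errors shared across the pipeline.

The analysis links climate-derived photoperiod proxies to allele-frequency
variation across sampling localities of a diploid species. Localities belong
to one of two diverged lineages (WEST / EAST) that are analyzed separately.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Invalid user input (out-of-range value, id mismatch, bad symbol)."""


class FormatError(InputError):
    """Malformed input file (ragged alignment, unknown residue, bad header)."""


class NoCrossingError(ValueError):
    """The annual temperature trajectory never crosses the threshold."""

    def __init__(self, locality_id: str, threshold_c: float):
        self.locality_id = locality_id
        self.threshold_c = threshold_c
        super().__init__(
            f"temperature trajectory of locality {locality_id!r} never crosses "
            f"{threshold_c} degC: threshold must lie strictly between the annual "
            f"minimum and maximum"
        )


class Lineage(str, enum.Enum):
    WEST = "WEST"
    EAST = "EAST"


class Region(str, enum.Enum):
    INTRONIC = "INTRONIC"
    EXONIC = "EXONIC"


class Effect(str, enum.Enum):
    SYNONYMOUS = "SYNONYMOUS"
    NONSYNONYMOUS = "NONSYNONYMOUS"
    NA = "NA"


class Proxy(str, enum.Enum):
    """Environmental proxies tested against allele-frequency differences."""

    GEO = "GEO"    # great-circle distance, km
    LAT = "LAT"    # |delta latitude|, degrees
    LON = "LON"    # |delta longitude|, degrees
    ALT = "ALT"    # |delta altitude|, m
    PCPP = "PCPP"  # |delta predicted critical photoperiod|, h


@dataclass(frozen=True)
class Locality:
    """One sampling site with coordinates, altitude and lineage membership."""

    id: str
    name: str
    latitude: float   # degrees N
    longitude: float  # degrees E (negative = W)
    altitude: float   # m above sea level
    lineage: Lineage
    n_specimens: int

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise InputError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise InputError(f"longitude {self.longitude} outside [-180, 180]")
        if self.n_specimens < 1:
            raise InputError("n_specimens must be >= 1")


@dataclass(frozen=True)
class MonthlyTemperatureSeries:
    """Twelve multi-year monthly mean temperatures (Jan..Dec, degC)."""

    locality_id: str
    temps: tuple

    def __post_init__(self):
        temps = tuple(float(t) for t in self.temps)
        if len(temps) != 12:
            raise InputError(
                f"locality {self.locality_id!r}: expected 12 monthly values, "
                f"got {len(temps)}"
            )
        if not all(np.isfinite(temps)):
            raise InputError(
                f"locality {self.locality_id!r}: non-finite temperature value"
            )
        object.__setattr__(self, "temps", temps)


@dataclass(frozen=True)
class ClimateEllipse:
    """Daily (photoperiod, temperature) trajectory over a 365-day year.

    Traversed Jan 1 -> Dec 31 this traces the closed annual loop in the
    (photoperiod, temperature) plane; with temperature lagging photoperiod
    the loop runs counter-clockwise for Northern-Hemisphere sites.
    """

    locality_id: str
    days: np.ndarray           # 1..365
    photoperiod_h: np.ndarray  # hours of light per 24 h
    temperature_c: np.ndarray  # interpolated daily degC

    def __post_init__(self):
        days = np.asarray(self.days, dtype=int)
        pp = np.asarray(self.photoperiod_h, dtype=float)
        tt = np.asarray(self.temperature_c, dtype=float)
        if not (len(days) == len(pp) == len(tt) == 365):
            raise InputError("climate ellipse must have exactly 365 entries")
        if pp.min() < 0.0 or pp.max() > 24.0:
            raise InputError("photoperiod outside [0, 24] h")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "photoperiod_h", pp)
        object.__setattr__(self, "temperature_c", tt)


@dataclass(frozen=True)
class Pcpp:
    """Predicted critical photoperiod: day length at the spring crossing of
    the temperature threshold."""

    locality_id: str
    threshold_c: float
    pcpp_h: float
    crossing_day: float  # fractional day-of-year of the spring crossing

    def __post_init__(self):
        if not 0.0 < self.pcpp_h < 24.0:
            raise InputError("pcpp_h must lie in (0, 24)")
        if not 1.0 <= self.crossing_day <= 365.0:
            raise InputError("crossing_day must lie in [1, 365]")


@dataclass(frozen=True)
class FragmentAnnotation:
    """Structure of the sequenced gene fragment: an intronic prefix followed
    by an exonic suffix, with the reading-frame phase of the first exonic
    base (0 = first base of a codon)."""

    intron_len: int
    exon_len: int
    cds_frame_offset: int
    reference_seq: str

    def __post_init__(self):
        if self.cds_frame_offset not in (0, 1, 2):
            raise InputError("cds_frame_offset must be 0, 1 or 2")
        if self.intron_len + self.exon_len != len(self.reference_seq):
            raise InputError(
                "intron_len + exon_len must equal reference length "
                f"({self.intron_len}+{self.exon_len} != {len(self.reference_seq)})"
            )


@dataclass(frozen=True)
class SpecimenSequence:
    """Per-specimen consensus sequence; IUPAC two-allele codes mark
    heterozygous positions, N marks missing."""

    specimen_id: str
    locality_id: str
    seq: str


@dataclass
class SnpRecord:
    """One biallelic polymorphic site passing the carrier rule."""

    position_label: int        # negative = intronic offset, positive = exonic
    column_index: int          # 0-based alignment column
    ref_allele: str
    alt_allele: str
    region: Region
    effect: Effect
    carriers: int              # specimens holding >= 1 alt allele
    per_population_counts: dict = field(default_factory=dict)
    # locality_id -> (alt_allele_count, total_allele_count)

    @property
    def label(self) -> str:
        return f"SNP{self.position_label}"


@dataclass
class FrequencyMatrix:
    """Population x SNP alt-allele frequencies with per-cell diploid counts.

    ``freq`` and ``sample_n`` are DataFrames indexed by locality id with one
    column per SNP position label; missing cells (no genotyped specimen) are
    NaN in ``freq`` and 0 in ``sample_n``.
    """

    freq: pd.DataFrame      # values in [0, 1] or NaN
    sample_n: pd.DataFrame  # diploid individuals genotyped per cell

    @property
    def populations(self) -> list:
        return list(self.freq.index)

    @property
    def snps(self) -> list:
        return list(self.freq.columns)


@dataclass(frozen=True)
class AssociationResult:
    """Per-SNP, per-proxy pairwise-difference correlation statistics."""

    snp_label: int
    proxy: Proxy
    n_pairs: int
    r: float
    r2: float
    p: float
    p_adj: float
    significant: bool
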