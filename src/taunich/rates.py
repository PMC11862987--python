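"""Residence-time arithmetic and assay-unit conversions for chemostat experiments.

A chemostat with liquid volume ``V`` (mL) and inflow ``Q`` (mL/h) has residence
time ``tau = V / Q`` — the mean time a passively transported cell or molecule
spends in the vessel — and dilution rate ``D = 1/tau``.  At steady state the
dilution rate equals the specific growth rate, so ``tau`` doubles as the
longest generation time a population can have without washing out.

This module also converts flow-cytometry gate counts to absolute cell
densities, tritiated-leucine scintillation counts to carbon-based bacterial
productivity, and scores Biolog EcoPlate carbon-utilisation assays.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HOURS_PER_DAY",
    "DAYS_PER_YEAR",
    "ChemostatGeometry",
    "ResidenceTime",
    "CytometryReading",
    "LeucineAssayConfig",
    "EcoPlateReading",
    "EcoPlateScore",
    "InfiniteResidenceTimeError",
    "InvalidReadingError",
    "residence_time",
    "dilution_rate",
    "max_generation_time",
    "absolute_count",
    "leucine_to_carbon",
    "ecoplate_score",
    "canonical_ecoplate_substrates",
]

HOURS_PER_DAY = 24.0
DAYS_PER_YEAR = 365.0
HOURS_PER_YEAR = HOURS_PER_DAY * DAYS_PER_YEAR

#: dpm per Curie (disintegrations min^-1 Ci^-1)
DPM_PER_CURIE = 2.22e12
#: molar mass of leucine, g/mol
LEUCINE_MOLAR_MASS = 131.2
#: molar mass of carbon, g/mol
CARBON_MOLAR_MASS = 12.011

ECOPLATE_CATEGORIES = frozenset(
    {
        "carboxylic acids",
        "polymers",
        "carbohydrates",
        "amino acids",
        "amines",
        "esters",
        "phosphorylated",
    }
)


class InfiniteResidenceTimeError(ValueError):
    """Raised when flow rate is zero: residence time is unbounded (closed bottle)."""


class InvalidReadingError(ValueError):
    """Raised for physically impossible assay readings."""


@dataclass(frozen=True)
class ChemostatGeometry:
    """Vessel geometry: liquid volume (mL) and medium inflow (mL/h)."""

    volume: float
    flow_rate: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        if self.flow_rate < 0:
            raise ValueError(f"flow_rate must be >= 0, got {self.flow_rate}")


@dataclass(frozen=True)
class ResidenceTime:
    """Residence time tau.  Canonical unit: hours; 1 year = 365 days."""

    tau: float  # hours

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0 h, got {self.tau}")

    @property
    def hours(self) -> float:
        return self.tau

    @property
    def minutes(self) -> float:
        return self.tau * 60.0

    @property
    def days(self) -> float:
        return self.tau / HOURS_PER_DAY

    @property
    def years(self) -> float:
        return self.tau / HOURS_PER_YEAR

    @classmethod
    def from_minutes(cls, minutes: float) -> "ResidenceTime":
        return cls(minutes / 60.0)

    @classmethod
    def from_days(cls, days: float) -> "ResidenceTime":
        return cls(days * HOURS_PER_DAY)

    @classmethod
    def from_years(cls, years: float) -> "ResidenceTime":
        return cls(years * HOURS_PER_YEAR)

    @classmethod
    def from_rate(cls, rate_per_hour: float) -> "ResidenceTime":
        """Residence time implied by a dilution rate (1/h)."""
        if rate_per_hour <= 0:
            raise ValueError("dilution rate must be > 0")
        return cls(1.0 / rate_per_hour)


@dataclass(frozen=True)
class CytometryReading:
    """One flow-cytometry acquisition: gated event count, fold dilution, volume (mL)."""

    events_in_gate: int
    dilution_factor: float
    acquisition_volume: float

    def __post_init__(self) -> None:
        if self.events_in_gate < 0:
            raise InvalidReadingError("events_in_gate must be >= 0")
        if self.acquisition_volume <= 0:
            raise InvalidReadingError("acquisition_volume must be > 0 mL")
        if self.dilution_factor <= 0:
            raise InvalidReadingError("dilution_factor must be > 0")


@dataclass(frozen=True)
class LeucineAssayConfig:
    """Constants for the 3H-leucine productivity assay.

    ``counting_efficiency`` and ``specific_activity`` are instrument/batch
    properties.  ``leucine_fraction_protein`` (g leucine per g protein) and
    ``carbon_per_protein`` (g C per g protein) are the standard literature
    conversion factors of the leucine method (0.073 and 0.86).
    """

    counting_efficiency: float = 0.639
    specific_activity: float = 161.0  # Ci/mmol
    added_concentration: float = 50.0  # nM, for record-keeping
    leucine_fraction_protein: float = 0.073
    carbon_per_protein: float = 0.86

    def __post_init__(self) -> None:
        if not 0 < self.counting_efficiency <= 1:
            raise ValueError("counting_efficiency must be in (0, 1]")
        if self.specific_activity <= 0:
            raise ValueError("specific_activity must be > 0 Ci/mmol")
        if not 0 < self.leucine_fraction_protein < 1:
            raise ValueError("leucine_fraction_protein must be in (0, 1)")
        if self.carbon_per_protein <= 0:
            raise ValueError("carbon_per_protein must be > 0")


def canonical_ecoplate_substrates() -> pd.DataFrame:
    """The 31 Biolog EcoPlate carbon sources with their seven-category grouping."""
    with importlib.resources.files("taunich.data").joinpath(
        "ecoplate_substrates.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("substrate")


@dataclass
class EcoPlateReading:
    """Blank-uncorrected OD590 readings for the 31 EcoPlate carbon sources.

    Parameters
    ----------
    od_by_substrate
        DataFrame indexed by substrate name, one column per replicate well.
    blank_od
        Water-blank OD590: a scalar, or one value per replicate column.
    substrate_category
        Substrate -> category mapping; defaults to the canonical assignment.
    """

    od_by_substrate: pd.DataFrame
    blank_od: float | np.ndarray
    substrate_category: Mapping[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        canon = canonical_ecoplate_substrates()
        if self.substrate_category is None:
            self.substrate_category = canon["category"].to_dict()
        missing = set(self.substrate_category) - set(self.od_by_substrate.index)
        if missing:
            raise InvalidReadingError(
                "missing EcoPlate substrate(s): " + ", ".join(sorted(missing))
            )
        if len(self.od_by_substrate.index) != 31:
            raise InvalidReadingError(
                f"expected exactly 31 substrates, got {len(self.od_by_substrate.index)}"
            )
        bad = set(self.substrate_category.values()) - ECOPLATE_CATEGORIES
        if bad:
            raise ValueError(f"unknown substrate categories: {sorted(bad)}")


@dataclass(frozen=True)
class EcoPlateScore:
    """Result of scoring one EcoPlate."""

    positive: pd.Series  # substrate -> bool, mean blanked OD strictly above threshold
    mean_blanked_od: pd.Series  # substrate -> mean of blanked replicate ODs
    community_mean_consumption: float  # mean blanked OD over all wells
    category_means: pd.Series  # category -> mean blanked OD over member wells
    n_positive: int
    threshold: float


def residence_time(geometry: ChemostatGeometry) -> ResidenceTime:
    """tau = V / Q in hours.

    Raises
    ------
    InfiniteResidenceTimeError
        If flow rate is zero (a sealed vessel has no finite residence time).
    """
    if geometry.flow_rate == 0:
        raise InfiniteResidenceTimeError(
            "flow_rate is 0 mL/h: residence time is infinite"
        )
    return ResidenceTime(geometry.volume / geometry.flow_rate)


def dilution_rate(tau: ResidenceTime | float) -> float:
    """Dilution rate 1/tau in 1/h."""
    t = tau.tau if isinstance(tau, ResidenceTime) else float(tau)
    if t <= 0:
        raise ValueError("tau must be > 0")
    return 1.0 / t


def max_generation_time(
    tau: ResidenceTime | float, ln2_corrected: bool = False
) -> float:
    """Longest generation time (h) a population can sustain at residence time tau.

    A population persists only if its growth outpaces dilution, so the limiting
    generation time equals tau itself (the 1/mu convention: rate 1.9/h maps to
    ~30 min).  Set ``ln2_corrected=True`` for the doubling-time convention
    ``ln(2)/mu``, which is shorter by a factor ln 2.
    """
    t = tau.tau if isinstance(tau, ResidenceTime) else float(tau)
    if t <= 0:
        raise ValueError("tau must be > 0")
    return t * np.log(2.0) if ln2_corrected else t


def absolute_count(reading: CytometryReading) -> float:
    """Absolute abundance (cells/mL) = events in gate x dilution / acquisition volume."""
    return reading.events_in_gate * reading.dilution_factor / reading.acquisition_volume


def leucine_to_carbon(
    cpm_live: float,
    cpm_kill: float,
    incubation: float,
    cfg: LeucineAssayConfig | None = None,
    *,
    negative_tolerance: float = 0.0,
) -> float:
    """Convert scintillation counts to carbon production (umol C/h).

    The chain: net CPM over the kill control -> DPM via counting efficiency ->
    moles of leucine via the isotope's specific activity -> grams of protein via
    the leucine fraction of protein -> grams of carbon via the C:protein ratio,
    normalised by incubation time.

    A net CPM below ``-negative_tolerance`` triggers a warning and returns 0
    (no measurable incorporation).
    """
    if cfg is None:
        cfg = LeucineAssayConfig()
    if incubation <= 0:
        raise ValueError("incubation must be > 0 h")
    net_cpm = cpm_live - cpm_kill
    if net_cpm < 0:
        if net_cpm < -negative_tolerance:
            warnings.warn(
                f"kill-control CPM exceeds live CPM by {-net_cpm:.1f}; "
                "clamping incorporation to 0",
                stacklevel=2,
            )
        return 0.0
    dpm = net_cpm / cfg.counting_efficiency
    curies = dpm / DPM_PER_CURIE
    mol_leucine = curies / cfg.specific_activity * 1e-3  # Ci/mmol -> mol
    g_protein = mol_leucine * LEUCINE_MOLAR_MASS / cfg.leucine_fraction_protein
    g_carbon = g_protein * cfg.carbon_per_protein
    umol_c = g_carbon / CARBON_MOLAR_MASS * 1e6
    return umol_c / incubation


def ecoplate_score(
    reading: EcoPlateReading, threshold: float = 0.125
) -> EcoPlateScore:
    """Score an EcoPlate: blank-correct, call positives, average consumption.

    Blanked OD is floored at 0 (the dye cannot be un-reduced).  A substrate is
    called positive when its mean blanked OD is strictly greater than
    ``threshold``.  Community mean consumption averages the blanked OD over
    every substrate x replicate well, keeping the continuous signal; the binary
    calls are reported alongside.
    """
    od = reading.od_by_substrate.astype(float)
    blank = np.asarray(reading.blank_od, dtype=float)
    if blank.ndim == 1 and blank.size != od.shape[1]:
        raise InvalidReadingError(
            f"blank_od has {blank.size} values but there are {od.shape[1]} replicates"
        )
    blanked = (od - blank).clip(lower=0.0)
    mean_blanked = blanked.mean(axis=1)
    positive = mean_blanked > threshold
    community_mean = float(blanked.to_numpy().mean())
    cats = pd.Series(dict(reading.substrate_category)).reindex(blanked.index)
    category_means = (
        blanked.assign(_cat=cats).groupby("_cat").mean().mean(axis=1)
    )
    category_means.index.name = "category"
    return EcoPlateScore(
        positive=positive,
        mean_blanked_od=mean_blanked,
        community_mean_consumption=community_mean,
        category_means=category_means,
        n_positive=int(positive.sum()),
        threshold=threshold,
    )
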