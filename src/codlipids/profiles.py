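"""Fatty-acid profile data model and I/O.

A profile is one fish's fatty-acid composition — canonical FA name mapped to
percentage of total fatty acids — plus an origin label (here Norway, Iceland
or Alaska, but the label set is open). Profiles travel as plain CSV: one row
per fish, ``sample_id`` and ``origin`` columns followed by one column per
canonical FA name. Companion lipid totals (total lipid, cholesterol,
α-tocopherol, partial sums in mg/g of edible portion) are carried by
:class:`LipidTotals`.

Units are explicit throughout: compositions are % of total FAs, partial sums
of a :class:`LipidTotals` are mg/g, and :func:`fame_quantity` /
:func:`total_fa_content` return mg/100 g of edible muscle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .nomenclature import (
    FAParseError,
    canonical_name,
    parse_fa_name,
    saturation_class,
)

__all__ = [
    "FattyAcidProfile",
    "GroupSummary",
    "LipidTotals",
    "ProfileValidationError",
    "read_profiles",
    "write_profiles",
    "profiles_to_frame",
    "partial_sums",
    "fame_quantity",
    "total_fa_content",
    "parse_p_value",
]

logger = logging.getLogger(__name__)

#: Percent totals outside this window fail validation outright …
SUM_WINDOW = (95.0, 105.0)
#: … while totals outside this inner window only log a warning. Printed
#: table columns carry rounding, so exact-100 enforcement would reject
#: published data.
SUM_WARN_WINDOW = (99.0, 101.0)


class ProfileValidationError(ValueError):
    """A profile or profile file violates the data contract."""


@dataclass
class FattyAcidProfile:
    """One fish's fatty-acid composition (% of total FAs) plus origin."""

    sample_id: str
    origin: str
    composition: dict[str, float]

    def validate(self, sum_window: tuple[float, float] = SUM_WINDOW) -> "FattyAcidProfile":
        """Check non-negativity and that percentages total ≈ 100."""
        for name, value in self.composition.items():
            if value < 0:
                raise ProfileValidationError(
                    f"sample {self.sample_id!r}: negative percentage "
                    f"{value} for {name!r}"
                )
        total = self.total()
        lo, hi = sum_window
        if not lo <= total <= hi:
            raise ProfileValidationError(
                f"sample {self.sample_id!r}: percentages total {total:.2f}, "
                f"outside [{lo}, {hi}]"
            )
        if not SUM_WARN_WINDOW[0] <= total <= SUM_WARN_WINDOW[1]:
            logger.warning(
                "sample %r: percentage total %.2f outside [%s, %s]",
                self.sample_id, total, *SUM_WARN_WINDOW,
            )
        return self

    def total(self) -> float:
        return float(sum(self.composition.values()))

    def get(self, name: str, default: float = 0.0) -> float:
        """Percentage for a canonical FA name; missing acids read as 0."""
        return self.composition.get(name, default)

    def scaled(self, factor: float) -> "FattyAcidProfile":
        return replace(
            self,
            composition={k: v * factor for k, v in self.composition.items()},
        )


@dataclass
class GroupSummary:
    """Per-origin marginal summary: per-FA mean and SD (% of total FAs)."""

    origin: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ProfileValidationError(f"group {self.origin!r}: n must be >= 2")
        if set(self.means) != set(self.sds):
            raise ProfileValidationError(
                f"group {self.origin!r}: mean and sd FA sets differ"
            )
        for name, sd in self.sds.items():
            if sd < 0:
                raise ProfileValidationError(
                    f"group {self.origin!r}: negative sd for {name!r}"
                )

    @property
    def fatty_acids(self) -> list[str]:
        return list(self.means)

    def mean_profile(self) -> FattyAcidProfile:
        """The group-mean composition as a pseudo-profile."""
        return FattyAcidProfile(
            sample_id=f"{self.origin}-mean",
            origin=self.origin,
            composition=dict(self.means),
        )


@dataclass
class LipidTotals:
    """Lipid totals for one fish or one group (units as annotated)."""

    origin: str
    TL: float | None = None                 # g/100 g edible portion
    TCHR: float | None = None               # mg/100 g
    alpha_tocopherol: float | None = None   # µg/g
    SFA: float = 0.0                        # mg/g edible portion
    MUFA: float = 0.0                       # mg/g
    PUFA: float = 0.0                       # mg/g
    n3: float = 0.0                         # mg/g
    n6: float = 0.0                         # mg/g
    sem: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("TL", "TCHR", "alpha_tocopherol", "SFA", "MUFA", "PUFA", "n3", "n6"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ProfileValidationError(f"{name} must be >= 0, got {value}")
        if self.SFA + self.MUFA + self.PUFA < self.n3 + self.n6:
            raise ProfileValidationError(
                "n-3 + n-6 partial sums exceed SFA+MUFA+PUFA: the omega "
                "families are a subset of PUFA"
            )


# ---------------------------------------------------------------------------
# readers / writers

_META_COLUMNS = ("sample_id", "origin")


def profiles_to_frame(profiles: list[FattyAcidProfile]) -> pd.DataFrame:
    """Tabulate profiles: sample_id, origin, then one column per FA."""
    fa_order: list[str] = []
    for p in profiles:
        for name in p.composition:
            if name not in fa_order:
                fa_order.append(name)
    rows = [
        {"sample_id": p.sample_id, "origin": p.origin,
         **{fa: p.composition.get(fa, 0.0) for fa in fa_order}}
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=[*_META_COLUMNS, *fa_order])


def write_profiles(profiles: list[FattyAcidProfile], path: str | Path) -> None:
    """Write profiles to CSV (UTF-8, '.' decimal, comma separator).

    Floats are written with Python's shortest round-trip repr so that
    ``read_profiles(write_profiles(x)) == x`` at full precision.
    """
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path: str | Path, validate: bool = True) -> list[FattyAcidProfile]:
    """Read a profile CSV written by :func:`write_profiles` (or by hand).

    The header must contain ``sample_id`` and ``origin``; every other column
    name must parse as a fatty acid (any accepted spelling; canonicalized on
    the way in). Negative values and wildly off-100 totals are rejected.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing:
        raise ProfileValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    fa_columns = [c for c in frame.columns if c not in _META_COLUMNS]
    renames: dict[str, str] = {}
    bad: list[str] = []
    for column in fa_columns:
        try:
            renames[column] = canonical_name(column)
        except FAParseError:
            bad.append(column)
    if bad:
        raise ProfileValidationError(
            f"{path}: unknown fatty-acid column header(s): {', '.join(map(repr, bad))}"
        )
    profiles = []
    for _, row in frame.iterrows():
        profile = FattyAcidProfile(
            sample_id=str(row["sample_id"]),
            origin=str(row["origin"]),
            composition={renames[c]: float(row[c]) for c in fa_columns},
        )
        if validate:
            profile.validate()
        profiles.append(profile)
    return profiles


# ---------------------------------------------------------------------------
# derived quantities


def partial_sums(profile: FattyAcidProfile) -> dict[str, float]:
    """Class and family sums (% of total FAs) for one profile.

    Returns ``SFA``, ``MUFA``, ``PUFA`` (a partition of the composition:
    their sum equals the column total) and the PUFA families ``n3``, ``n6``,
    ``n4`` (which partition PUFA).
    """
    if not profile.composition:
        raise ProfileValidationError(
            f"sample {profile.sample_id!r}: empty composition"
        )
    sums = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0, "n3": 0.0, "n6": 0.0, "n4": 0.0}
    for name, pct in profile.composition.items():
        descriptor = parse_fa_name(name)
        sums[saturation_class(descriptor)] += pct
        if descriptor.family is not None:
            sums[descriptor.family.replace("-", "")] += pct
    return sums


def fame_quantity(
    fame_area: float, is_area: float, is_mass: float, sample_mass: float
) -> float:
    """Internal-standard quantification of one FAME peak.

    Converts a detector peak area to absolute fatty-acid mass using a known
    mass of C21:0 internal standard spiked before chromatography:

        mg/100 g edible muscle = 100 × (is_mass × fame_area / is_area) / sample_mass

    Parameters are the FAME peak area and the internal-standard peak area
    (same detector units), the internal-standard mass in mg, and the sample
    mass in g.
    """
    if is_area <= 0:
        raise ValueError(f"internal-standard area must be > 0, got {is_area}")
    if sample_mass <= 0:
        raise ValueError(f"sample mass must be > 0, got {sample_mass}")
    if fame_area < 0 or is_mass < 0:
        raise ValueError("peak area and internal-standard mass must be >= 0")
    return 100.0 * (is_mass * fame_area / is_area) / sample_mass


def total_fa_content(totals: LipidTotals) -> float:
    """Total fatty-acid content in mg/100 g from the mg/g partial sums."""
    return (totals.SFA + totals.MUFA + totals.PUFA) * 100.0


def parse_p_value(value: str | float, censored: float = 0.0009) -> float:
    """Parse a printed p-value; ``"<0.001"``-style strings map to a value
    just below the censoring bound (default 0.0009), preserving significance
    counts at any α ≥ 0.001."""
    if isinstance(value, str):
        text = value.strip()
        if text.startswith("<"):
            bound = float(text[1:])
            return min(censored, math.nextafter(bound, 0.0))
        return float(text)
    return float(value)
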