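"""Lipid nutritional-quality indices and ratios.

Six formula-defined scores summarize the nutritional quality of a fatty-acid
composition (all inputs in % of total FAs; Σ denotes a partial sum over a
class or omega family):

- PI, peroxidability index: enoic-class weighted sum
  0.025·mono + 1·di + 2·tri + 4·tetra + 6·penta + 8·hexa, evaluated on
  fractional proportions (percent ÷ 100).
- AI, atherogenicity index: (C12:0 + 4·C14:0 + C16:0) / (ΣMUFA + Σn-6 + Σn-3).
- TI, thrombogenicity index:
  (C14:0 + C16:0 + C18:0) / (0.5·ΣMUFA + 0.5·Σn-6 + 3·Σn-3 + Σn-3/Σn-6).
- h/H, hypocholesterolaemic/hypercholesterolaemic ratio: seven named
  unsaturated acids over (C14:0 + C16:0).
- P/S: (C18:2 n-6 + C18:3 n-3) / (C14:0 + C16:0 + C18:0).
- n-3/n-6: Σn-3 / Σn-6.

The AI and TI denominators are defined over the MUFA class and the n-3/n-6
families only, so the n-4 acid (C16:2 n-4) is deliberately excluded from
them. An acid named by a formula but absent from the composition (e.g.
C12:0, rarely reported in cod) contributes 0 with a logged notice. Undefined
ratios (zero denominators) raise :class:`UndefinedIndexError` rather than
returning infinities, so batch pipelines can catch them and emit missing
values.

A note on TI scale: evaluating the TI formula above on published cod
group-mean compositions gives values near 0.15–0.19, roughly ten times the
0.015–0.019 that accompanies those compositions in print; the source of that
extra factor is not documented. This implementation follows the formula as
written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .nomenclature import enoic_class, parse_fa_name
from .profiles import (
    FattyAcidProfile,
    LipidTotals,
    partial_sums,
    total_fa_content,
)

__all__ = [
    "IndexPanel",
    "UndefinedIndexError",
    "peroxidability_index",
    "atherogenicity_index",
    "thrombogenicity_index",
    "h_to_H",
    "p_to_s",
    "n3_over_n6",
    "epa_dha",
    "superiority",
    "grams_to_cholesterol_limit",
    "index_panel",
    "batch_index_panels",
]

logger = logging.getLogger(__name__)

PI_WEIGHTS = {
    "monoenoic": 0.025,
    "dienoic": 1.0,
    "trienoic": 2.0,
    "tetraenoic": 4.0,
    "pentaenoic": 6.0,
    "hexaenoic": 8.0,
}

EPA = "C20:5 n-3"
DHA = "C22:6 n-3"

H_NUMERATOR = (
    "C18:1 cis-9", "C18:2 n-6", "C18:3 n-3", "C20:4 n-6",
    "C20:5 n-3", "C22:5 n-3", "C22:6 n-3",
)


class UndefinedIndexError(ZeroDivisionError):
    """An index's denominator is zero for this composition."""


def _pct(profile: FattyAcidProfile, name: str) -> float:
    if name not in profile.composition:
        logger.info(
            "sample %r: %s absent from composition; contributes 0",
            profile.sample_id, name,
        )
        return 0.0
    return profile.composition[name]


@dataclass
class IndexPanel:
    """The index/ratio values for one profile (all dimensionless except the
    EPA+DHA quantities)."""

    sample_id: str
    origin: str
    PI: float
    AI: float
    TI: float
    h_H: float
    P_S: float
    n3_n6: float
    epa_dha_pct: float
    epa_dha_mg_100g: float | None = None


def peroxidability_index(profile: FattyAcidProfile) -> float:
    """Susceptibility of the lipid fraction to peroxidation.

    Weighted sum over enoic classes, on fractional proportions
    (percent ÷ 100); an all-saturated composition scores 0.
    """
    total = 0.0
    for name, pct in profile.composition.items():
        klass = enoic_class(parse_fa_name(name))
        if klass == "saturated":
            continue
        total += PI_WEIGHTS[klass] * pct / 100.0
    return total


def atherogenicity_index(profile: FattyAcidProfile) -> float:
    sums = partial_sums(profile)
    denominator = sums["MUFA"] + sums["n6"] + sums["n3"]
    if denominator == 0:
        raise UndefinedIndexError(
            f"sample {profile.sample_id!r}: AI undefined — no MUFA, n-6 or "
            "n-3 acids in the composition"
        )
    numerator = (
        _pct(profile, "C12:0") + 4.0 * _pct(profile, "C14:0") + _pct(profile, "C16:0")
    )
    return numerator / denominator


def thrombogenicity_index(profile: FattyAcidProfile) -> float:
    sums = partial_sums(profile)
    if sums["n6"] == 0:
        raise UndefinedIndexError(
            f"sample {profile.sample_id!r}: TI undefined — Σn-6 is zero "
            "(the denominator contains Σn-3/Σn-6)"
        )
    denominator = (
        0.5 * sums["MUFA"] + 0.5 * sums["n6"] + 3.0 * sums["n3"]
        + sums["n3"] / sums["n6"]
    )
    if denominator == 0:
        raise UndefinedIndexError(
            f"sample {profile.sample_id!r}: TI undefined — zero denominator"
        )
    numerator = (
        _pct(profile, "C14:0") + _pct(profile, "C16:0") + _pct(profile, "C18:0")
    )
    return numerator / denominator


def h_to_H(profile: FattyAcidProfile) -> float:
    denominator = _pct(profile, "C14:0") + _pct(profile, "C16:0")
    if denominator == 0:
        raise UndefinedIndexError(
            f"sample {profile.sample_id!r}: h/H undefined — C14:0 + C16:0 is zero"
        )
    return sum(_pct(profile, name) for name in H_NUMERATOR) / denominator


def p_to_s(profile: FattyAcidProfile) -> float:
    denominator = (
        _pct(profile, "C14:0") + _pct(profile, "C16:0") + _pct(profile, "C18:0")
    )
    if denominator == 0:
        raise UndefinedIndexError(
            f"sample {profile.sample_id!r}: P/S undefined — "
            "C14:0 + C16:0 + C18:0 is zero"
        )
    return (_pct(profile, "C18:2 n-6") + _pct(profile, "C18:3 n-3")) / denominator


def n3_over_n6(profile: FattyAcidProfile) -> float:
    sums = partial_sums(profile)
    if sums["n6"] == 0:
        raise UndefinedIndexError(
            f"sample {profile.sample_id!r}: n-3/n-6 undefined — Σn-6 is zero"
        )
    return sums["n3"] / sums["n6"]


def epa_dha(
    profile: FattyAcidProfile, totals: LipidTotals | None = None
) -> tuple[float, float | None]:
    """EPA + DHA as (% of total FAs, mg/100 g of edible portion).

    The absolute quantity needs the mg/g partial sums of a companion
    :class:`LipidTotals`; without them only the percentage is returned.
    """
    pct = _pct(profile, EPA) + _pct(profile, DHA)
    if totals is None:
        return pct, None
    return pct, total_fa_content(totals) * pct / 100.0


def superiority(a: float, b: float) -> float:
    """Relative excess of the larger of two quantities: 100·(max−min)/min."""
    lo, hi = min(a, b), max(a, b)
    if lo <= 0:
        raise ValueError(f"superiority undefined for non-positive minimum {lo}")
    return 100.0 * (hi - lo) / lo


def grams_to_cholesterol_limit(
    tchr_mg_per_100g: float, limit_mg: float = 300.0
) -> float:
    """Grams of edible portion needed to reach a cholesterol intake limit."""
    if tchr_mg_per_100g <= 0:
        raise ValueError("cholesterol content must be > 0")
    return 100.0 * limit_mg / tchr_mg_per_100g


def index_panel(
    profile: FattyAcidProfile, totals: LipidTotals | None = None
) -> IndexPanel:
    """All six indices/ratios plus EPA+DHA quantities for one profile."""
    pct, mg = epa_dha(profile, totals)
    return IndexPanel(
        sample_id=profile.sample_id,
        origin=profile.origin,
        PI=peroxidability_index(profile),
        AI=atherogenicity_index(profile),
        TI=thrombogenicity_index(profile),
        h_H=h_to_H(profile),
        P_S=p_to_s(profile),
        n3_n6=n3_over_n6(profile),
        epa_dha_pct=pct,
        epa_dha_mg_100g=mg,
    )


def batch_index_panels(
    profiles: list[FattyAcidProfile],
    totals_by_origin: dict[str, LipidTotals] | None = None,
) -> pd.DataFrame:
    """One index-panel row per fish; undefined indices become NaN.

    Columns: ``sample_id``, ``origin``, ``PI``, ``AI``, ``TI``, ``h_H``,
    ``P_S``, ``n3_n6``, ``epa_dha_pct``, ``epa_dha_mg_100g``.
    """
    computations = {
        "PI": peroxidability_index,
        "AI": atherogenicity_index,
        "TI": thrombogenicity_index,
        "h_H": h_to_H,
        "P_S": p_to_s,
        "n3_n6": n3_over_n6,
    }
    rows = []
    for profile in profiles:
        row: dict[str, object] = {
            "sample_id": profile.sample_id, "origin": profile.origin
        }
        for column, fn in computations.items():
            try:
                row[column] = fn(profile)
            except UndefinedIndexError:
                row[column] = float("nan")
        totals = (totals_by_origin or {}).get(profile.origin)
        row["epa_dha_pct"], row["epa_dha_mg_100g"] = epa_dha(profile, totals)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["sample_id", "origin", *computations, "epa_dha_pct", "epa_dha_mg_100g"],
    )
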