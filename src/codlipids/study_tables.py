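"""Bundled published summary tables for dried salted cod.

Three small CSV fixtures ship with the package, holding the printed group
summaries for 45 dried salted cods (15 per origin: Norway, Iceland, Alaska):

``table1_totals.csv``
    Total lipid (g/100 g), cholesterol (mg/100 g), α-tocopherol (µg/g),
    fatty-acid partial sums (mg/g of edible portion), ratios and lipid
    quality indices — least-squares means per origin, the pooled SEM, and
    the two contrast p-values (species: Atlantic vs Pacific; origin within
    Atlantic: Norway vs Iceland).

``table2_profiles.csv``
    The detailed fatty-acid profile (% of total FAs): mean ± SD per origin
    for 25 fatty acids, with the same two contrast p-value columns.

``table3_coefficients.csv``
    Standardized canonical discriminant coefficients for the 12 stepwise-
    selected fatty acids on the two canonical roots, plus the canonical
    correlations, eigenvalues and cumulative eigenvalue proportions.

Cell values are stored verbatim as printed (including one extra-digit mean,
Alaska C18:0 = 5.337, and censored p-values such as ``<0.001``); row labels
are stored in the source spelling and canonicalized at load time.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .nomenclature import canonical_name
from .profiles import FattyAcidProfile, GroupSummary, LipidTotals, parse_p_value

__all__ = [
    "ORIGINS",
    "GROUP_N",
    "load_table1",
    "load_table2",
    "load_table3",
    "load_group_summaries",
    "load_group_totals",
    "load_contrast_pvalues",
]

#: Origin labels in table order (Atlantic first, then Pacific).
ORIGINS = ("Norway", "Iceland", "Alaska")
#: Fish per origin in the underlying study.
GROUP_N = 15

_STAT_ROWS = {"canonical_R", "eigenvalue", "cumulative_proportion"}


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh, dtype=str)


def load_table1() -> pd.DataFrame:
    """Totals/indices table: one row per measure, columns per origin plus
    ``sem``, ``p_species`` and ``p_origin`` (p-values parsed to float,
    censored entries mapped below their bound)."""
    frame = _read("table1_totals.csv").set_index("measure")
    for col in ("norway", "iceland", "alaska", "sem"):
        frame[col] = frame[col].astype(float)
    for col in ("p_species", "p_origin"):
        frame[col] = frame[col].map(parse_p_value)
    return frame


def load_table2(canonical: bool = True) -> pd.DataFrame:
    """Fatty-acid profile table indexed by FA name (canonicalized unless
    ``canonical=False``), with mean/sd per origin and parsed p-values."""
    frame = _read("table2_profiles.csv")
    if canonical:
        frame["fatty_acid"] = frame["fatty_acid"].map(canonical_name)
    frame = frame.set_index("fatty_acid")
    for col in frame.columns:
        if col.startswith("p_"):
            frame[col] = frame[col].map(parse_p_value)
        else:
            frame[col] = frame[col].astype(float)
    return frame


def load_table3() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Published discriminant model: ``(coefficients, statistics)``.

    ``coefficients`` is indexed by canonical FA name with columns ``root1``
    and ``root2``; ``statistics`` holds the canonical correlation,
    eigenvalue and cumulative proportion rows for the two roots.
    """
    frame = _read("table3_coefficients.csv").set_index("variable")
    frame = frame.astype(float)
    stats = frame.loc[[r for r in frame.index if r in _STAT_ROWS]]
    coef = frame.loc[[r for r in frame.index if r not in _STAT_ROWS]]
    coef.index = [canonical_name(name) for name in coef.index]
    coef.index.name = "variable"
    return coef, stats


def load_group_summaries() -> list[GroupSummary]:
    """Per-origin marginal summaries (mean, SD per FA; n = 15)."""
    table2 = load_table2()
    return [
        GroupSummary(
            origin=origin,
            n=GROUP_N,
            means=table2[f"{origin.lower()}_mean"].to_dict(),
            sds=table2[f"{origin.lower()}_sd"].to_dict(),
        )
        for origin in ORIGINS
    ]


def load_group_totals() -> dict[str, LipidTotals]:
    """Per-origin lipid totals with their SEMs (n = 15 per group)."""
    table1 = load_table1()
    out = {}
    for origin in ORIGINS:
        col = origin.lower()
        out[origin] = LipidTotals(
            origin=origin,
            TL=table1.loc["TL", col],
            TCHR=table1.loc["TCHR", col],
            alpha_tocopherol=table1.loc["alpha_tocopherol", col],
            SFA=table1.loc["SFA", col],
            MUFA=table1.loc["MUFA", col],
            PUFA=table1.loc["PUFA", col],
            n3=table1.loc["n3", col],
            n6=table1.loc["n6", col],
            sem=table1["sem"].to_dict(),
        )
    return out


def load_contrast_pvalues() -> pd.DataFrame:
    """Printed per-FA contrast p-values (``p_species``, ``p_origin``)."""
    return load_table2()[["p_species", "p_origin"]]


def mean_profiles() -> dict[str, FattyAcidProfile]:
    """Group-mean compositions as pseudo-profiles, keyed by origin."""
    return {s.origin: s.mean_profile() for s in load_group_summaries()}
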