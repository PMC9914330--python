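"""One-way ANOVA with orthogonal group contrasts.

The study design has a single fixed effect — the cod group (species plus
harvesting origin) — at three levels, and asks two planned questions:

- species: Atlantic vs Pacific, weights (½, ½, −1) on (Norway, Iceland,
  Alaska), so the estimate is the difference between the Atlantic mean and
  the Pacific mean;
- origin within Atlantic: Norway vs Iceland, weights (1, −1, 0).

Each contrast is tested with the pooled-variance t statistic of one-way
ANOVA: estimate Σwᵢx̄ᵢ, standard error √(MSE·Σwᵢ²/nᵢ) with the residual
mean square pooled over all groups, and a two-sided p-value on N − g
degrees of freedom. With equal group sizes the two weight vectors are
orthogonal, so the two estimates are uncorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import FattyAcidProfile, parse_p_value

__all__ = [
    "ContrastResult",
    "SPECIES_CONTRAST",
    "ORIGIN_CONTRAST",
    "contrast_anova",
    "contrast_table",
    "count_significant",
]

#: Atlantic (Norway, Iceland) vs Pacific (Alaska): A vs. P.
SPECIES_CONTRAST: dict[str, float] = {"Norway": 0.5, "Iceland": 0.5, "Alaska": -1.0}
#: Norway vs Iceland within the Atlantic: N vs. I.
ORIGIN_CONTRAST: dict[str, float] = {"Norway": 1.0, "Iceland": -1.0, "Alaska": 0.0}


@dataclass
class ContrastResult:
    response: str
    contrast: str
    estimate: float
    se: float
    t: float
    df: int
    p: float


def _group_arrays(
    groups: Mapping[str, Sequence[float]]
) -> dict[str, np.ndarray]:
    out = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"group {label!r}: expected a 1-D sample")
        out[label] = arr
    return out


def contrast_anova(
    groups: Mapping[str, Sequence[float]],
    weights: Mapping[str, float],
    response: str = "",
    contrast: str = "",
) -> ContrastResult:
    """Pooled-variance t test of one linear contrast of group means.

    ``groups`` maps group label to the per-fish response values; ``weights``
    maps the same labels to contrast weights summing to zero (labels with
    weight 0 may be omitted from ``weights`` but still contribute to the
    pooled residual variance). Zero residual variance yields p = 0 for a
    nonzero estimate and p = 1 otherwise.
    """
    data = _group_arrays(groups)
    if len(data) < 2:
        raise ValueError("at least two groups are required")
    for label, arr in data.items():
        if arr.size < 2:
            raise ValueError(f"group {label!r} is a singleton; need >= 2 samples")
    unknown = set(weights) - set(data)
    if unknown:
        raise ValueError(f"weights refer to unknown group(s): {sorted(unknown)}")
    w = {label: float(weights.get(label, 0.0)) for label in data}
    if abs(sum(w.values())) > 1e-12:
        raise ValueError(f"contrast weights must sum to 0, got {sum(w.values())}")

    n_total = sum(arr.size for arr in data.values())
    df = n_total - len(data)
    sse = sum(float(((arr - arr.mean()) ** 2).sum()) for arr in data.values())
    mse = sse / df
    estimate = sum(w[label] * data[label].mean() for label in data)
    se = float(np.sqrt(mse * sum(w[label] ** 2 / data[label].size for label in data)))

    if se == 0.0:
        p = 0.0 if estimate != 0.0 else 1.0
        t_stat = np.inf if estimate != 0.0 else 0.0
    else:
        t_stat = estimate / se
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return ContrastResult(
        response=response, contrast=contrast,
        estimate=float(estimate), se=se, t=float(t_stat), df=df, p=p,
    )


def contrast_table(
    profiles: list[FattyAcidProfile],
    contrasts: Mapping[str, Mapping[str, float]] | None = None,
    responses: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-fatty-acid contrast p-values for a cohort.

    Mirrors the published profile-table layout: one row per fatty acid,
    one ``p_<contrast>`` (plus ``est_<contrast>``) column pair per contrast.
    Defaults to the species (``A_vs_P``) and origin (``N_vs_I``) contrasts.
    """
    if contrasts is None:
        contrasts = {"A_vs_P": SPECIES_CONTRAST, "N_vs_I": ORIGIN_CONTRAST}
    if responses is None:
        responses = list(profiles[0].composition)
    by_origin: dict[str, list[FattyAcidProfile]] = {}
    for profile in profiles:
        by_origin.setdefault(profile.origin, []).append(profile)

    rows = []
    for fa in responses:
        groups = {
            origin: [p.get(fa) for p in members]
            for origin, members in by_origin.items()
        }
        row: dict[str, object] = {"fatty_acid": fa}
        for name, weights in contrasts.items():
            result = contrast_anova(groups, weights, response=fa, contrast=name)
            row[f"est_{name}"] = result.estimate
            row[f"p_{name}"] = result.p
        rows.append(row)
    return pd.DataFrame(rows).set_index("fatty_acid")


def count_significant(p_values: Iterable[float | str], alpha: float = 0.05) -> int:
    """Number of p-values strictly below alpha.

    Censored printed entries like ``"<0.001"`` count as below any
    alpha ≥ 0.001.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return sum(1 for p in p_values if parse_p_value(p) < alpha)
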