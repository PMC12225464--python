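"""Posterior summaries: category log-odds-ratio intervals with effort shares,
an annual detectability series, and headline probability summaries.

Credible intervals are equal-tailed 2.5-97.5 percentile pairs of the stored
draws.  The annual detectability series averages posterior-mean detectability
over each year's realized covariate mix (marginal over observed patrols, not
at reference covariates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import posterior_mean_probabilities
from .records import CategoryScheme, Design
from .sampling import PosteriorDraws

_DETECTION_FACTORS = ("region", "actor", "year")
_VIOLATION_FACTORS = ("species", "violation_type")


@dataclass
class HeadlineSummary:
    """Across-record mean and SD of the per-record posterior-mean
    detectability p, violation probability v, and overall probability v*p."""

    mean_detectability: float
    sd_detectability: float
    mean_violation: float
    sd_violation: float
    mean_overall: float
    sd_overall: float


def summarize_categories(
    draws: PosteriorDraws,
    frame: pd.DataFrame,
    scheme: CategoryScheme,
    factor: str,
) -> pd.DataFrame:
    """Per level of ``factor``: posterior mean and 95% CI of its log-odds
    ratio against the reference, plus the share of enforcement effort
    (proportion of patrol records) in that level.

    The reference level is reported as exactly 0 with a degenerate interval.
    """
    if factor not in _DETECTION_FACTORS + _VIOLATION_FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    levels = scheme.levels(factor)
    col = frame[factor].astype(int) if factor == "year" else frame[factor]
    counts = col.value_counts()
    n = len(frame)

    rows = []
    for i, level in enumerate(levels):
        share = counts.get(level, 0) / n
        if i == 0:
            rows.append(dict(factor=factor, level=str(level), mean=0.0, lo=0.0, hi=0.0,
                             effort_share=share, is_reference=True))
            continue
        name = f"{factor}[{level}]"
        if name not in draws.param_names:
            raise ValueError(f"parameter {name!r} not in the fitted draws")
        x = draws.parameter(name).reshape(-1)
        lo, hi = np.percentile(x, [2.5, 97.5])
        rows.append(dict(factor=factor, level=str(level), mean=float(x.mean()),
                         lo=float(lo), hi=float(hi), effort_share=share, is_reference=False))
    return pd.DataFrame(rows)


def annual_detectability(draws: PosteriorDraws, frame: pd.DataFrame, design: Design) -> pd.Series:
    """Per-year average of posterior-mean detectability p over that year's records.

    Years configured but absent from the data are omitted with a warning.
    """
    p_mean, _, _ = posterior_mean_probabilities(draws, design)
    years = frame["year"].astype(int)
    series = pd.Series(p_mean, index=frame.index).groupby(years).mean().sort_index()
    series.name = "mean_detectability"
    return series


def check_missing_years(scheme: CategoryScheme, frame: pd.DataFrame) -> list[int]:
    present = set(frame["year"].astype(int))
    missing = [y for y in scheme.year_levels if y not in present]
    if missing:
        warnings.warn(f"year(s) {missing} have no records and are omitted from the series")
    return missing


def headline_summary(draws: PosteriorDraws, design: Design) -> HeadlineSummary:
    """Across-record summaries of the three probabilities of interest."""
    p_mean, v_mean, vp_mean = posterior_mean_probabilities(draws, design)
    return HeadlineSummary(
        mean_detectability=float(p_mean.mean()),
        sd_detectability=float(p_mean.std()),
        mean_violation=float(v_mean.mean()),
        sd_violation=float(v_mean.std()),
        mean_overall=float(vp_mean.mean()),
        sd_overall=float(vp_mean.std()),
    )
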