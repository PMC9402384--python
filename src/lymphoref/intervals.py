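"""Nonparametric reference-interval estimation.

The reference interval is the central 95% of the reference population: the
2.5th and 97.5th percentiles, reported with the median, all computed on the
original measurement scale by the rank rule r = p(n+1) with linear
interpolation. The nonparametric minimum is n = 39 (the smallest n for
which the 2.5th-percentile rank reaches the first order statistic); n < 120
is allowed with a small-sample warning, mirroring guideline practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import AgeGroupScheme, AnalyteDefinition, AnalyteKind, DEFAULT_AGE_SCHEME
from .partitioning import MergeHistory
from .quantiles import rank_quantile

logger = logging.getLogger(__name__)

MIN_N = 39
RECOMMENDED_N = 120
RI_PROBS = (0.025, 0.5, 0.975)


class InsufficientSampleError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceInterval:
    analyte: str
    group_label: str
    n: int
    median: float
    lower: float  # 2.5th percentile
    upper: float  # 97.5th percentile
    units: str = ""

    def __post_init__(self) -> None:
        if not (self.lower <= self.median <= self.upper):
            raise ValueError("expected lower <= median <= upper")

    def contains(self, x: float) -> bool:
        """Endpoint values count as inside."""
        return self.lower <= x <= self.upper


def nonparametric_ri(
    values: np.ndarray,
    analyte: str = "",
    group_label: str = "",
    units: str = "",
    min_n: int = MIN_N,
) -> ReferenceInterval:
    """Median and central-95% interval of a reference sample."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if v.size < min_n:
        raise InsufficientSampleError(
            f"nonparametric 2.5th/97.5th percentiles need n >= {min_n}, got {v.size}"
        )
    if v.size < RECOMMENDED_N:
        logger.warning(
            "group %r/%r has n=%d < %d; nonparametric endpoints will be imprecise",
            analyte, group_label, v.size, RECOMMENDED_N,
        )
    lo, med, hi = (float(rank_quantile(v, p)) for p in RI_PROBS)
    return ReferenceInterval(analyte, group_label, v.size, med, lo, hi, units)


def format_value(x: float, kind: AnalyteKind) -> str:
    """Counts print as integers, percentages and ratios with 2 decimals."""
    if kind is AnalyteKind.COUNT:
        return f"{x:.0f}"
    return f"{x:.2f}"


def format_interval(ri: ReferenceInterval, kind: AnalyteKind) -> str:
    """Render as 'median (lower-upper)', e.g. '80.59 (52.26-89.74)'."""
    f = lambda v: format_value(v, kind)
    return f"{f(ri.median)} ({f(ri.lower)}-{f(ri.upper)})"


RI_TABLE_COLUMNS = ("analyte", "bin", "final_group", "n", "median", "lower", "upper", "units")


def build_ri_table(
    frame: pd.DataFrame,
    analytes: Sequence[AnalyteDefinition],
    histories: Mapping[str, MergeHistory],
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
    min_n: int = MIN_N,
) -> pd.DataFrame:
    """Tidy RI table: one row per analyte x initial age bin.

    Merged bins repeat the interval of their pooled final group (the visual
    convention of age-partitioned reference tables). Cells whose final group
    has fewer than ``min_n`` usable values are marked unavailable (NaN) and
    the run continues.
    """
    rows = []
    for a in analytes:
        hist = histories[a.name]
        mapping = hist.bin_to_final()
        ri_by_final: dict[str, ReferenceInterval | None] = {}
        for members, flabel in zip(hist.final_bins, hist.final_labels()):
            sub = frame[frame["age_group"].isin(members)]
            vals = sub[a.name].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            try:
                ri_by_final[flabel] = nonparametric_ri(
                    vals, analyte=a.name, group_label=flabel, units=a.units, min_n=min_n
                )
            except InsufficientSampleError as e:
                logger.warning("%s / %s: %s — cell marked unavailable", a.name, flabel, e)
                ri_by_final[flabel] = None
        for b in scheme.bins:
            flabel = mapping.get(b.label)
            ri = ri_by_final.get(flabel) if flabel is not None else None
            rows.append(
                {
                    "analyte": a.name,
                    "bin": b.label,
                    "final_group": flabel,
                    "n": ri.n if ri else np.nan,
                    "median": ri.median if ri else np.nan,
                    "lower": ri.lower if ri else np.nan,
                    "upper": ri.upper if ri else np.nan,
                    "units": a.units,
                }
            )
    return pd.DataFrame(rows, columns=list(RI_TABLE_COLUMNS))


def format_ri_table(
    ri_table: pd.DataFrame,
    analytes: Sequence[AnalyteDefinition],
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
) -> pd.DataFrame:
    """Wide display table: analytes x age bins of 'median (lower-upper)' cells."""
    kinds = {a.name: a.kind for a in analytes}
    wide = {}
    for b in scheme.bins:
        col = []
        for a in analytes:
            row = ri_table[(ri_table["analyte"] == a.name) & (ri_table["bin"] == b.label)]
            if row.empty or np.isnan(row["median"].iloc[0]):
                col.append("n/a")
            else:
                r = row.iloc[0]
                ri = ReferenceInterval(a.name, b.label, int(r["n"]), r["median"], r["lower"], r["upper"])
                col.append(format_interval(ri, kinds[a.name]))
        wide[b.label] = col
    return pd.DataFrame(wide, index=[a.name for a in analytes])
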