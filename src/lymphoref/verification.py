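"""Reference-interval verification on an independent cohort.

The transference check: draw a small verification group (protocol n = 40
per age group), count how many values fall outside the candidate interval,
and accept the interval when the outside fraction is within tolerance. The
default rule is outside <= 5% (pct_within >= 95); a strict '< 5%' variant
is selectable. Values exactly on an endpoint count as inside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import ReferenceInterval

logger = logging.getLogger(__name__)

PROTOCOL_N = 40
PASS_RULES = ("le_5pct", "strict_lt_5pct")


@dataclass(frozen=True)
class VerificationResult:
    analyte: str
    group_label: str
    n: int
    n_outside: int
    pct_within: float
    passed: bool


def verify_ri(
    ri: ReferenceInterval,
    samples: np.ndarray,
    rule: str = "le_5pct",
) -> VerificationResult:
    """Check one interval against verification samples for its group."""
    if rule not in PASS_RULES:
        raise ValueError(f"unknown pass rule {rule!r}")
    v = np.asarray(samples, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("verification sample is empty")
    if v.size != PROTOCOL_N:
        logger.warning(
            "verification group %r/%r has n=%d, protocol specifies %d",
            ri.analyte, ri.group_label, v.size, PROTOCOL_N,
        )
    outside = int(np.sum((v < ri.lower) | (v > ri.upper)))
    pct_within = 100.0 * (v.size - outside) / v.size
    frac_out = outside / v.size
    passed = frac_out <= 0.05 if rule == "le_5pct" else frac_out < 0.05
    return VerificationResult(ri.analyte, ri.group_label, v.size, outside, pct_within, bool(passed))


def _ri_lookup(ri_table: pd.DataFrame) -> dict[tuple[str, str], tuple[float, float]]:
    out = {}
    for _, r in ri_table.iterrows():
        if np.isnan(r["lower"]) or np.isnan(r["upper"]):
            continue
        out[(r["analyte"], r["bin"])] = (float(r["lower"]), float(r["upper"]))
    return out


def verification_table(
    ri_table: pd.DataFrame,
    cohorts_by_group: Mapping[str, pd.DataFrame],
    alt_ri: pd.DataFrame | None = None,
    rule: str = "le_5pct",
) -> tuple[pd.DataFrame, bool]:
    """Per-analyte x per-group verification report.

    ``ri_table`` is the tidy RI table (analyte, bin, lower, upper ...);
    ``cohorts_by_group`` maps each age-bin label to its verification cohort
    frame (analyte columns). With ``alt_ri`` a second interval table is
    verified side by side (columns suffixed ``_alt``). Returns the report and
    the overall pass flag for the primary intervals; groups without a cohort
    are marked unavailable.
    """
    primary = _ri_lookup(ri_table)
    alt = _ri_lookup(alt_ri) if alt_ri is not None else None
    analytes = list(dict.fromkeys(ri_table["analyte"]))
    bins = list(dict.fromkeys(ri_table["bin"]))

    data: dict[str, list] = {}
    all_pass = True
    for b in bins:
        cohort = cohorts_by_group.get(b)
        col, col_alt = [], []
        for a in analytes:
            cell = np.nan
            cell_alt = np.nan
            if cohort is not None and a in cohort.columns and (a, b) in primary:
                lo, hi = primary[(a, b)]
                ri = ReferenceInterval(a, b, 0, (lo + hi) / 2, lo, hi)
                res = verify_ri(ri, cohort[a].to_numpy(dtype=float), rule=rule)
                cell = res.pct_within
                all_pass &= res.passed
                if alt is not None and (a, b) in alt:
                    lo2, hi2 = alt[(a, b)]
                    ri2 = ReferenceInterval(a, b, 0, (lo2 + hi2) / 2, lo2, hi2)
                    cell_alt = verify_ri(ri2, cohort[a].to_numpy(dtype=float), rule=rule).pct_within
            else:
                if cohort is None:
                    all_pass = False  # cannot claim verification for a missing group
            col.append(cell)
            col_alt.append(cell_alt)
        data[b] = col
        if alt is not None:
            data[f"{b}_alt"] = col_alt
    report = pd.DataFrame(data, index=analytes)
    return report, bool(all_pass)
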