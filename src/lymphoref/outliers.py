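"""Tukey-fence outlier elimination.

Fences sit at Q1 - 1.5*IQR and Q3 + 1.5*IQR; values strictly outside are
outliers (values exactly on a fence are kept). Quartiles use the repo-wide
rank rule (r = p(n+1), linear interpolation). When an analyte was judged
non-normal the fences are computed on its Box-Cox (analysis) scale — the
transform is monotone, so this only changes interpolation details — and the
flagged subjects are removed on both scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import AnalyteDefinition, panel_analytes
from .quantiles import rank_quantile

logger = logging.getLogger(__name__)

TUKEY_K = 1.5


class InsufficientSampleError(ValueError):
    pass


@dataclass(frozen=True)
class TukeyFences:
    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float
    outlier_mask: np.ndarray
    n_removed: int


def tukey_fences(values: np.ndarray, k: float = TUKEY_K) -> TukeyFences:
    """Compute Tukey fences and the strict-exceedance outlier mask."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InsufficientSampleError(f"need at least 4 values for Tukey fences, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    q1 = float(rank_quantile(v, 0.25))
    q3 = float(rank_quantile(v, 0.75))
    iqr = q3 - q1
    lower = q1 - k * iqr
    upper = q3 + k * iqr
    mask = (v < lower) | (v > upper)
    return TukeyFences(q1, q3, iqr, lower, upper, mask, int(mask.sum()))


LEDGER_COLUMNS = ("analyte", "group", "subject_id", "value", "fence", "limit")


def filter_cohort(
    frame: pd.DataFrame,
    analytes: Sequence[AnalyteDefinition] | None = None,
    group_cols: Sequence[str] | None = None,
    transforms: Mapping[str, Callable[[np.ndarray], np.ndarray]] | None = None,
    removal: str = "per-analyte",
    passes: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove Tukey outliers per analyte.

    Parameters
    ----------
    frame : validated cohort frame.
    group_cols : columns defining the cells within which fences are computed.
        None (default) pools the whole cohort per analyte — outlier
        elimination precedes subgrouping in the workflow; pass e.g.
        ``("age_group", "sex")`` to fence within demographic cells instead.
    transforms : optional map analyte -> monotone callable giving the analysis
        scale on which fences are computed (e.g. a fitted Box-Cox transform);
        identity when absent.
    removal : "per-analyte" blanks only the offending value (the subject stays
        for other analytes); "whole-subject" drops the row entirely.
    passes : 1 reproduces the single-elimination convention; larger values
        iterate until stable or the pass budget is exhausted.

    Returns
    -------
    (filtered frame, removal ledger) — the ledger has one row per removed
    value: analyte, group, subject_id, raw value, which fence, and the fence
    limit on the analysis scale.
    """
    if removal not in ("per-analyte", "whole-subject"):
        raise ValueError(f"unknown removal mode {removal!r}")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    analytes = list(analytes) if analytes is not None else panel_analytes(frame)
    transforms = transforms or {}

    out = frame.copy()
    pooled = group_cols is None
    if pooled:
        group_cols = ("_pooled",)
        out["_pooled"] = "all"
    ledger_rows: list[dict] = []

    for _ in range(passes):
        removed_this_pass = 0
        drop_subjects: set[str] = set()
        for a in analytes:
            tf = transforms.get(a.name)
            for key, sub in out.groupby(list(group_cols), sort=False, observed=True):
                vals = sub[a.name].to_numpy(dtype=float)
                ok = np.isfinite(vals)
                if ok.sum() < 4:
                    label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
                    logger.warning("group %s too small for %s fences; skipped", label, a.name)
                    continue
                raw = vals[ok]
                analysis = tf(raw) if tf is not None else raw
                fences = tukey_fences(analysis)
                if fences.n_removed == 0:
                    continue
                idx = sub.index[ok][fences.outlier_mask]
                label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
                for i, av, rv in zip(
                    idx, analysis[fences.outlier_mask], raw[fences.outlier_mask]
                ):
                    side = "lower" if av < fences.lower else "upper"
                    ledger_rows.append(
                        {
                            "analyte": a.name,
                            "group": label,
                            "subject_id": out.at[i, "subject_id"],
                            "value": rv,
                            "fence": side,
                            "limit": fences.lower if side == "lower" else fences.upper,
                        }
                    )
                if removal == "per-analyte":
                    out.loc[idx, a.name] = np.nan
                else:
                    drop_subjects.update(out.loc[idx, "subject_id"])
                removed_this_pass += len(idx)
        if removal == "whole-subject" and drop_subjects:
            out = out[~out["subject_id"].isin(drop_subjects)]
        if removed_this_pass == 0:
            break

    if pooled:
        out = out.drop(columns=["_pooled"])
    ledger = pd.DataFrame(ledger_rows, columns=list(LEDGER_COLUMNS))
    return out, ledger
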