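"""End-to-end reference-interval workflow.

``establish`` reenacts the guideline sequence on a cohort table:

1. per analyte, screen normality by the skewness/kurtosis z-test; fit a
   Box-Cox transform when non-normal (the "analysis scale");
2. remove Tukey-fence outliers per analyte within each age x sex cell,
   fences computed on the analysis scale;
3. test the sex partition (omnibus + Harris-Boyd z against z*) on the full
   filtered cohort;
4. merge adjacent age bins per analyte by the same rule;
5. estimate nonparametric 2.5th/50th/97.5th percentiles per final group on
   the original measurement scale.

``verify`` checks an established (or any candidate) interval table against
an independent cohort with the transference rule. Both are deterministic
given input and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    AgeGroupScheme,
    AnalyteDefinition,
    DEFAULT_AGE_SCHEME,
    DEFAULT_PANEL,
    load_cohort,
    panel_analytes,
)
from .intervals import build_ri_table, format_ri_table
from .normality import BoxCoxResult, NormalityAssessment, assess_normality, boxcox_transform
from .outliers import filter_cohort
from .partitioning import (
    MergeHistory,
    PartitionTestResult,
    merge_adjacent_age_groups,
    test_sex_partition,
)
from .verification import verification_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Workflow configuration; defaults reenact the guideline choices."""

    omnibus_method: str = "anova"  # or "kruskal_wallis"
    alpha: float = 0.05
    outlier_passes: int = 1  # single elimination; >1 iterates
    outlier_grouping: str = "pooled"  # fences on the whole cohort ("pooled",
    # elimination precedes subgrouping) or within cells ("per-cell")
    removal_mode: str = "per-analyte"  # or "whole-subject"
    verification_rule: str = "le_5pct"  # or "strict_lt_5pct"
    min_group_n: int = 39
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omnibus_method not in ("anova", "kruskal_wallis"):
            raise ValueError(f"unknown omnibus method {self.omnibus_method!r}")
        if self.outlier_grouping not in ("pooled", "per-cell"):
            raise ValueError(f"unknown outlier grouping {self.outlier_grouping!r}")
        if self.removal_mode not in ("per-analyte", "whole-subject"):
            raise ValueError(f"unknown removal mode {self.removal_mode!r}")
        if self.verification_rule not in ("le_5pct", "strict_lt_5pct"):
            raise ValueError(f"unknown verification rule {self.verification_rule!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnalyteReport:
    analyte: str
    normality: NormalityAssessment
    boxcox_lambda: float | None
    boxcox_shift: float | None
    n_outliers: int
    sex_test: PartitionTestResult | None
    merge_history: MergeHistory

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "normality": asdict(self.normality),
            "boxcox_lambda": self.boxcox_lambda,
            "boxcox_shift": self.boxcox_shift,
            "n_outliers": self.n_outliers,
            "sex_test": self.sex_test.to_dict() if self.sex_test else None,
            "merge_history": self.merge_history.to_dict(),
        }


@dataclass
class RunResult:
    config: RunConfig
    frame: pd.DataFrame  # filtered cohort
    outlier_ledger: pd.DataFrame
    ri_table: pd.DataFrame  # tidy: analyte x bin
    ri_wide: pd.DataFrame  # formatted display table
    reports: dict[str, AnalyteReport]

    @property
    def merge_histories(self) -> dict[str, MergeHistory]:
        return {a: r.merge_history for a, r in self.reports.items()}

    def to_report_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "n_subjects": int(len(self.frame)),
            "n_outlier_removals": int(len(self.outlier_ledger)),
            "analytes": {a: r.to_dict() for a, r in self.reports.items()},
        }

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ri_table.to_csv(outdir / "ri_table.csv", index=False)
        (outdir / "ri_table.txt").write_text(self.ri_wide.to_string(), encoding="utf-8")
        self.outlier_ledger.to_csv(outdir / "outlier_ledger.csv", index=False)
        with open(outdir / "run_report.json", "w", encoding="utf-8") as fh:
            json.dump(self.to_report_dict(), fh, indent=2, default=float)


def establish(
    cohort: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    panel: Sequence[AnalyteDefinition] = DEFAULT_PANEL,
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
) -> RunResult:
    """Run the full establishment workflow on a cohort table."""
    config = config or RunConfig()
    loaded = load_cohort(cohort, panel=panel, scheme=scheme)
    frame = loaded.frame
    if frame.empty:
        raise ValueError("cohort is empty after validation; nothing to establish")
    analytes = panel_analytes(frame, panel)
    if not analytes:
        raise ValueError("no panel analytes present in the cohort")

    # stage 1: normality screen + Box-Cox per analyte, fitted on the full
    # pooled vector (the transform precedes partitioning in the workflow)
    normality: dict[str, NormalityAssessment] = {}
    boxcox: dict[str, BoxCoxResult] = {}
    transforms = {}
    for a in analytes:
        vals = frame[a.name].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        assessment = assess_normality(vals)
        normality[a.name] = assessment
        if not assessment.is_normal:
            bc = boxcox_transform(vals)
            boxcox[a.name] = bc
            transforms[a.name] = bc.apply

    # stage 2: Tukey fences per analyte on the analysis scale; pooled by
    # default (elimination precedes subgrouping), per age x sex cell on request
    filtered, ledger = filter_cohort(
        frame,
        analytes=analytes,
        group_cols=None if config.outlier_grouping == "pooled" else ("age_group", "sex"),
        transforms=transforms,
        removal=config.removal_mode,
        passes=config.outlier_passes,
    )

    reports: dict[str, AnalyteReport] = {}
    for a in analytes:
        tf = transforms.get(a.name, lambda x: x)
        col = filtered[a.name].to_numpy(dtype=float)
        ok = np.isfinite(col)

        # stage 3: sex partition on the full filtered cohort
        m = col[ok & (filtered["sex"].to_numpy() == "M")]
        f = col[ok & (filtered["sex"].to_numpy() == "F")]
        sex_test = None
        if m.size >= 2 and f.size >= 2:
            sex_test = test_sex_partition(tf(m), tf(f), method=config.omnibus_method, alpha=config.alpha)
            if sex_test.decision == "split":
                logger.warning(
                    "%s: sex partition test says split (p=%.3g, z=%.2f > z*=%.2f); "
                    "intervals below pool sexes — consider sex-stratified runs",
                    a.name, sex_test.p_omnibus, sex_test.z, sex_test.z_star,
                )
        else:
            logger.warning("%s: single-sex cohort, sex test skipped", a.name)

        # stage 4: adjacent age-bin merging
        values_by_bin = {}
        groups = filtered["age_group"].to_numpy()
        for b in scheme.labels:
            v = col[ok & (groups == b)]
            if v.size >= 2:
                values_by_bin[b] = tf(v)
        if len(values_by_bin) < 2:
            raise ValueError(f"analyte {a.name!r}: fewer than 2 populated age bins")
        history = merge_adjacent_age_groups(
            values_by_bin, analyte=a.name, method=config.omnibus_method, alpha=config.alpha
        )

        n_out = int((ledger["analyte"] == a.name).sum()) if len(ledger) else 0
        bc = boxcox.get(a.name)
        reports[a.name] = AnalyteReport(
            analyte=a.name,
            normality=normality[a.name],
            boxcox_lambda=bc.lam if bc else None,
            boxcox_shift=bc.shift if bc else None,
            n_outliers=n_out,
            sex_test=sex_test,
            merge_history=history,
        )

    # stage 5: nonparametric intervals on the original scale
    histories = {a: r.merge_history for a, r in reports.items()}
    ri = build_ri_table(filtered, analytes, histories, scheme=scheme, min_n=config.min_group_n)
    wide = format_ri_table(ri, analytes, scheme=scheme)
    return RunResult(config, filtered, ledger, ri, wide, reports)


def verify(
    ri_table: pd.DataFrame | str | Path,
    cohort: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    panel: Sequence[AnalyteDefinition] = DEFAULT_PANEL,
    scheme: AgeGroupScheme = DEFAULT_AGE_SCHEME,
    alt_ri: pd.DataFrame | str | Path | None = None,
) -> tuple[pd.DataFrame, bool]:
    """Verify an interval table against an independent cohort.

    The cohort is split into age groups with the same scheme; the report has
    one within-percentage cell per analyte x group. Raises when the interval
    table's analytes do not appear in the cohort at all.
    """
    config = config or RunConfig()
    if isinstance(ri_table, (str, Path)):
        ri_table = pd.read_csv(ri_table)
    if alt_ri is not None and isinstance(alt_ri, (str, Path)):
        alt_ri = pd.read_csv(alt_ri)
    loaded = load_cohort(cohort, panel=panel, scheme=scheme)
    frame = loaded.frame
    ri_analytes = set(ri_table["analyte"])
    unmatched = ri_analytes - set(frame.columns)
    if unmatched == ri_analytes:
        raise ValueError(f"no interval-table analytes present in the cohort: {sorted(unmatched)}")
    if unmatched:
        logger.warning("analytes absent from the verification cohort: %s", sorted(unmatched))
    cohorts = {b: sub for b, sub in frame.groupby("age_group", observed=True)}
    return verification_table(ri_table, cohorts, alt_ri=alt_ri, rule=config.verification_rule)
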