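"""Sex/age partition testing with the Harris-Boyd criterion.

Whether a demographic split deserves its own reference interval is decided
by two gates that must BOTH fire: the omnibus test on the pair of groups
(ANOVA on the analysis scale, or Kruskal-Wallis on raw values) must reject
at α = 0.05, and the two-sample standard-normal deviate

    z = |m1 - m2| / sqrt(s1²/n1 + s2²/n2)

must exceed the sample-size-scaled critical value

    z* = 3·sqrt((n1 + n2) / 240)  (= 3·sqrt(n_avg / 120)).

Otherwise the groups are merged. z* grows with n, so trivially significant
but clinically negligible differences at large n do not force a partition.
Adjacent age bins are merged greedily: each round tests every adjacent pair,
and among the pairs that the rule says to merge, the one with the largest
omnibus p is merged first; the procedure repeats until no adjacent pair is
mergeable. Non-adjacent bins are never pooled and bin order is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

ALPHA = 0.05
SMALL_GROUP_N = 20


class DegenerateDataError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSummary:
    """Mean/SD/n of one group on the analysis scale."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r} needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def summarize(label: str, values: np.ndarray) -> GroupSummary:
    v = np.asarray(values, dtype=float)
    return GroupSummary(label=label, n=v.size, mean=float(v.mean()), sd=float(v.std(ddof=1)))


def z_star(n1: int, n2: int) -> float:
    """Harris-Boyd critical value 3·sqrt((n1+n2)/240)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be positive")
    return float(3.0 * np.sqrt((n1 + n2) / 240.0))


def harris_boyd_z(a: GroupSummary, b: GroupSummary) -> float:
    """Two-sample standard-normal deviate between group means."""
    denom = a.sd**2 / a.n + b.sd**2 / b.n
    if denom == 0:
        raise DegenerateDataError("both groups have zero variance; z undefined")
    return float(abs(a.mean - b.mean) / np.sqrt(denom))


def omnibus_test(
    values: np.ndarray,
    group_labels: Sequence,
    method: str = "anova",
) -> float:
    """p-value of the omnibus location test across >= 2 groups.

    method="anova" (one-way, on the analysis scale) or "kruskal_wallis"
    (rank-based, indifferent to any monotone transform).
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if v.shape != labels.shape:
        raise ValueError("values and group_labels must align")
    groups = [v[labels == g] for g in pd_unique(labels)]
    return omnibus_groups(groups, method=method)


def omnibus_groups(groups: Sequence[np.ndarray], method: str = "anova") -> float:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(np.concatenate(groups)) == 0:
        raise DegenerateDataError("all groups identical and constant; omnibus test undefined")
    if method == "anova":
        if all(np.ptp(g) == 0 for g in groups):
            raise DegenerateDataError("zero within-group variance; ANOVA undefined")
        _, p = stats.f_oneway(*groups)
    elif method == "kruskal_wallis":
        _, p = stats.kruskal(*groups)
    else:
        raise ValueError(f"unknown omnibus method {method!r}")
    return float(p)


def pd_unique(labels: np.ndarray) -> list:
    """Unique labels in order of first appearance."""
    seen: dict = {}
    for l in labels:
        seen.setdefault(l, None)
    return list(seen)


def decide_merge(p: float, z: float, zs: float, alpha: float = ALPHA) -> str:
    """"split" iff p < alpha AND z > z*; "merge" otherwise."""
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    if z < 0 or zs <= 0:
        raise ValueError("z must be >= 0 and z* > 0")
    return "split" if (p < alpha and z > zs) else "merge"


@dataclass(frozen=True)
class PartitionTestResult:
    pair: tuple[str, str]
    p_omnibus: float
    z: float
    z_star: float
    decision: str

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "p": self.p_omnibus,
            "z": self.z,
            "z_star": self.z_star,
            "decision": self.decision,
        }


@dataclass
class MergeHistory:
    """Per-analyte record of the greedy adjacent-bin merging."""

    analyte: str
    initial_bins: list[str]
    events: list[PartitionTestResult] = field(default_factory=list)
    final_bins: list[list[str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def final_labels(self) -> list[str]:
        out = []
        for members in self.final_bins:
            out.append(members[0] if len(members) == 1 else f"{members[0]} to {members[-1]}")
        return out

    def bin_to_final(self) -> dict[str, str]:
        """Map each initial bin label to its final (possibly pooled) label."""
        mapping = {}
        for members, lab in zip(self.final_bins, self.final_labels()):
            for m in members:
                mapping[m] = lab
        return mapping

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "initial_bins": self.initial_bins,
            "events": [e.to_dict() for e in self.events],
            "final_bins": self.final_bins,
            "final_labels": self.final_labels(),
            "warnings": self.warnings,
        }


def _pair_result(
    label_a: str,
    a: np.ndarray,
    label_b: str,
    b: np.ndarray,
    method: str,
    alpha: float,
) -> PartitionTestResult:
    p = omnibus_groups([a, b], method=method)
    sa, sb = summarize(label_a, a), summarize(label_b, b)
    z = harris_boyd_z(sa, sb)
    zs = z_star(sa.n, sb.n)
    return PartitionTestResult((label_a, label_b), p, z, zs, decide_merge(p, z, zs, alpha))


def merge_adjacent_age_groups(
    values_by_bin: Mapping[str, np.ndarray],
    analyte: str = "",
    method: str = "anova",
    alpha: float = ALPHA,
) -> MergeHistory:
    """Greedy largest-p-first merging of adjacent age bins for one analyte.

    ``values_by_bin`` maps ordered bin labels to analysis-scale value vectors.
    Deterministic given the data: each round evaluates every adjacent pair of
    current bins; the mergeable pair with the largest omnibus p is merged and
    the round repeats on the pooled bins until every adjacent pair says
    "split".
    """
    labels = list(values_by_bin)
    if len(labels) < 2:
        raise ValueError("need at least 2 populated age bins")
    history = MergeHistory(analyte=analyte, initial_bins=labels)
    for lab in labels:
        n = np.asarray(values_by_bin[lab]).size
        if n < SMALL_GROUP_N:
            history.warnings.append(f"bin {lab!r} has only n={n} (< {SMALL_GROUP_N}) subjects")

    members: list[list[str]] = [[l] for l in labels]
    pooled: list[np.ndarray] = [np.asarray(values_by_bin[l], dtype=float) for l in labels]

    def blocklabel(ms: list[str]) -> str:
        return ms[0] if len(ms) == 1 else f"{ms[0]} to {ms[-1]}"

    while len(pooled) > 1:
        results = [
            _pair_result(
                blocklabel(members[i]), pooled[i], blocklabel(members[i + 1]), pooled[i + 1],
                method, alpha,
            )
            for i in range(len(pooled) - 1)
        ]
        history.events.extend(results)
        mergeable = [i for i, r in enumerate(results) if r.decision == "merge"]
        if not mergeable:
            break
        best = max(mergeable, key=lambda i: results[i].p_omnibus)
        members[best] = members[best] + members.pop(best + 1)
        pooled[best] = np.concatenate([pooled[best], pooled.pop(best + 1)])

    history.final_bins = members
    return history


def test_sex_partition(
    male_values: np.ndarray,
    female_values: np.ndarray,
    method: str = "anova",
    alpha: float = ALPHA,
) -> PartitionTestResult:
    """Male-vs-female partition test for one analyte on the analysis scale."""
    return _pair_result("M", np.asarray(male_values, float), "F", np.asarray(female_values, float), method, alpha)
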