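"""Transmembrane migration quantification.

Each well is scored by summing the cells counted in 5 contiguous microscope
fields spanning radially outward across the membrane.  Well totals are
normalised to the control-condition mean (control ≡ 100%), summarised as
mean ± SD over replicates, and compared with two-tailed Student t-tests
(pooled variance by default, Welch optionally).  Significance stars follow
the half-open bins '*' 0.01 ≤ p < 0.05, '**' 0.001 ≤ p < 0.01,
'***' p < 0.001.

The replicate unit is switchable: ``replicate_unit='well'`` pools wells
across experiments; ``'experiment'`` averages wells within each experiment
first and treats experiment means as replicates.  Published summaries of
assays like this are ambiguous about which convention their SDs use, so
both are first-class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MigrationRecord",
    "NormalizedResult",
    "TestResult",
    "aggregate_counts",
    "records_from_frame",
    "normalized_table",
    "normalize",
    "compare",
    "stars",
    "pairwise_tests",
]

N_FIELDS = 5


@dataclass(frozen=True)
class MigrationRecord:
    """Counts for one well: cells in each of 5 contiguous fields."""

    condition: str
    experiment_id: str
    well_id: str
    field_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.field_counts) != N_FIELDS:
            raise ValueError(f"expected {N_FIELDS} field counts")
        if any(c < 0 or int(c) != c for c in self.field_counts):
            raise ValueError("field counts must be non-negative integers")


@dataclass(frozen=True)
class NormalizedResult:
    """Per-condition migration relative to control (control mean ≡ 100%)."""

    condition: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class TestResult:
    group_a: str
    group_b: str
    p_value: float
    stars: str


def aggregate_counts(record: MigrationRecord) -> int:
    """Total migrated cells in a well (sum over its 5 fields)."""
    return int(sum(record.field_counts))


def records_from_frame(df: pd.DataFrame) -> list[MigrationRecord]:
    """Read records from a table with columns condition, experiment_id,
    well_id, f1..f5."""
    cols = [f"f{i}" for i in range(1, N_FIELDS + 1)]
    return [
        MigrationRecord(
            condition=str(r["condition"]),
            experiment_id=str(r["experiment_id"]),
            well_id=str(r["well_id"]),
            field_counts=tuple(int(r[c]) for c in cols),
        )
        for _, r in df.iterrows()
    ]


def normalized_table(
    records: Iterable[MigrationRecord],
    control: str,
    replicate_unit: str = "well",
) -> pd.DataFrame:
    """Per-replicate normalised percentages.

    Replicates are wells (default) or per-experiment means of wells; each
    replicate total is divided by the control condition's mean replicate
    total and scaled to percent."""
    if replicate_unit not in ("well", "experiment"):
        raise ValueError("replicate_unit must be 'well' or 'experiment'")
    rows = [
        {
            "condition": r.condition,
            "experiment_id": r.experiment_id,
            "well_id": r.well_id,
            "total": aggregate_counts(r),
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    if df.empty or control not in set(df["condition"]):
        raise ValueError(f"control condition {control!r} not present")
    if replicate_unit == "experiment":
        df = (
            df.groupby(["condition", "experiment_id"], as_index=False)["total"]
            .mean()
            .rename(columns={"experiment_id": "replicate"})
        )
    else:
        df = df.assign(replicate=df["experiment_id"] + "/" + df["well_id"])[
            ["condition", "replicate", "total"]
        ]
    control_mean = df.loc[df["condition"] == control, "total"].mean()
    if control_mean == 0:
        raise ValueError("control mean count is zero; cannot normalize")
    df["percent"] = 100.0 * df["total"] / control_mean
    return df


def normalize(
    records: Iterable[MigrationRecord],
    control: str,
    replicate_unit: str = "well",
) -> list[NormalizedResult]:
    """Per-condition mean ± SD (sample SD over replicates) of normalised
    migration percentages; the control condition's mean is exactly 100."""
    df = normalized_table(records, control, replicate_unit)
    out = []
    for cond, g in df.groupby("condition", sort=False):
        vals = g["percent"].to_numpy()
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out.append(
            NormalizedResult(condition=cond, mean=float(vals.mean()), sd=sd, n=vals.size)
        )
    return out


def stars(p: float) -> str:
    """Significance annotation: '***' p < 0.001, '**' 0.001 ≤ p < 0.01,
    '*' 0.01 ≤ p < 0.05, 'ns' otherwise."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    welch: bool = False,
) -> TestResult:
    """Two-sample two-tailed Student t-test (pooled variance unless
    ``welch``).  Degenerate zero-variance groups with equal means give
    p = 1."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(sps.ttest_ind(a, b, equal_var=not welch).pvalue)
    return TestResult(group_a=label_a, group_b=label_b, p_value=p, stars=stars(p))


def pairwise_tests(
    records: Iterable[MigrationRecord],
    control: str,
    replicate_unit: str = "well",
    welch: bool = False,
) -> pd.DataFrame:
    """Every condition against the control, on normalised percentages."""
    df = normalized_table(records, control, replicate_unit)
    ctl = df.loc[df["condition"] == control, "percent"].to_numpy()
    rows = []
    for cond, g in df.groupby("condition", sort=False):
        if cond == control:
            continue
        res = compare(ctl, g["percent"].to_numpy(), control, cond, welch=welch)
        rows.append(
            {"group_a": control, "group_b": cond, "p_value": res.p_value,
             "stars": res.stars}
        )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "p_value", "stars"])
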