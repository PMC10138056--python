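"""File formats and conversions: study CSVs, 2x2 tables, scenario configs.

CSV dialect is comma-separated, ``.`` decimal, UTF-8, mandatory header.
A study table carries ``label``, ``effect`` and exactly one of ``se`` or
``variance``; a 2x2 table carries ``label, events_trt, total_trt,
events_ctl, total_ctl`` and is converted internally to log odds-ratio
studies with the Woolf variance (and the Gart +0.5 continuity correction
applied to every cell of a table containing a zero cell).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from ._errors import InputError
from .cherrypick import Direction, Tau2Policy
from .meta_core import MetaResult, Study, StudySet
from .simulation import Scenario

__all__ = [
    "TwoByTwoRecord",
    "RunConfig",
    "read_study_csv",
    "write_study_csv",
    "read_2x2_csv",
    "two_by_two_to_study",
    "convert_2x2",
    "export_forest_table",
    "load_scenarios",
]

_ORIENTATIONS = ("as_given", "benefit_positive")


@dataclass(frozen=True)
class TwoByTwoRecord:
    """Event counts of one two-arm trial with a binary outcome."""

    label: str
    events_trt: int
    total_trt: int
    events_ctl: int
    total_ctl: int

    def __post_init__(self) -> None:
        for name in ("events_trt", "total_trt", "events_ctl", "total_ctl"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InputError(f"{self.label!r}: {name} must be a nonnegative integer")
        if self.total_trt <= 0 or self.total_ctl <= 0:
            raise InputError(f"{self.label!r}: arm totals must be positive")
        if self.events_trt > self.total_trt or self.events_ctl > self.total_ctl:
            raise InputError(f"{self.label!r}: events exceed the arm total")


@dataclass(frozen=True)
class RunConfig:
    """Bundle of analysis options shared by the CLI subcommands."""

    alpha: float = 0.05
    model: str = "fixed"
    direction: Direction = Direction.OVERSTATE
    S: int = 1
    tau2_policy: Tau2Policy = Tau2Policy.FULL_SET
    sided: str = "right"
    seed: int = 0
    orientation: str = "as_given"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InputError("alpha must lie in (0, 1)")
        if self.model not in ("fixed", "random"):
            raise InputError("model must be 'fixed' or 'random'")
        if self.sided not in ("right", "left", "two"):
            raise InputError("sided must be 'right', 'left' or 'two'")
        if self.orientation not in _ORIENTATIONS:
            raise InputError(f"orientation must be one of {_ORIENTATIONS}")


def read_study_csv(path) -> StudySet:
    """Read a study table into a StudySet, preserving file order.

    The header must contain ``label`` and ``effect`` plus exactly one of
    ``se`` (squared into a variance) or ``variance``. Malformed rows are
    rejected with their 1-based file line number.
    """
    df = pd.read_csv(path, dtype={"label": str}, float_precision="round_trip")
    cols = set(df.columns)
    if "label" not in cols or "effect" not in cols:
        raise InputError("study CSV must have 'label' and 'effect' columns")
    has_se, has_var = "se" in cols, "variance" in cols
    if has_se == has_var:
        raise InputError("study CSV must have exactly one of 'se' or 'variance'")
    scale_col = "se" if has_se else "variance"

    studies = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        label = getattr(row, "label")
        if label is None or (isinstance(label, float) and math.isnan(label)) or label == "":
            raise InputError(f"line {line}: missing label")
        if label in seen:
            raise InputError(
                f"line {line}: duplicate label {label!r} (first seen on line {seen[label]})"
            )
        seen[label] = line
        try:
            effect = float(getattr(row, "effect"))
            scale = float(getattr(row, scale_col))
        except (TypeError, ValueError):
            raise InputError(f"line {line}: non-numeric effect or {scale_col}") from None
        if not math.isfinite(effect):
            raise InputError(f"line {line}: effect must be finite")
        variance = scale**2 if has_se else scale
        if not math.isfinite(variance) or variance <= 0:
            raise InputError(f"line {line}: {scale_col} must be positive and finite")
        studies.append(Study(label, effect, variance))
    if not studies:
        raise InputError("study CSV contains no data rows")
    return StudySet(studies)


def write_study_csv(studies: StudySet, path) -> None:
    """Write a StudySet as ``label,effect,variance`` with full float precision."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "effect", "variance"])
        for s in studies:
            writer.writerow([s.label, repr(s.effect), repr(s.variance)])


def read_2x2_csv(path) -> list[TwoByTwoRecord]:
    """Read trial count tables; columns label, events_trt, total_trt,
    events_ctl, total_ctl."""
    df = pd.read_csv(path, dtype={"label": str})
    needed = ["label", "events_trt", "total_trt", "events_ctl", "total_ctl"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InputError(f"2x2 CSV missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        line = int(i) + 2
        try:
            records.append(
                TwoByTwoRecord(
                    label=str(row["label"]),
                    events_trt=int(row["events_trt"]),
                    total_trt=int(row["total_trt"]),
                    events_ctl=int(row["events_ctl"]),
                    total_ctl=int(row["total_ctl"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise InputError(f"line {line}: {exc}") from None
    if not records:
        raise InputError("2x2 CSV contains no data rows")
    return records


def two_by_two_to_study(record: TwoByTwoRecord, orientation: str = "as_given") -> Study:
    """Convert a 2x2 table to a log odds-ratio study.

    Effect is ``log(ad/bc)`` with the treatment-arm events as ``a`` and
    variance ``1/a + 1/b + 1/c + 1/d`` (Woolf). If any cell is zero, 0.5 is
    added to all four cells first. ``benefit_positive`` negates the log-OR
    so a protective treatment (fewer events) maps to a positive effect,
    matching the directional alternative :math:`H_1:\\theta>0`.
    """
    if orientation not in _ORIENTATIONS:
        raise InputError(f"orientation must be one of {_ORIENTATIONS}")
    a = float(record.events_trt)
    b = float(record.total_trt - record.events_trt)
    c = float(record.events_ctl)
    d = float(record.total_ctl - record.events_ctl)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    effect = math.log((a * d) / (b * c))
    variance = 1 / a + 1 / b + 1 / c + 1 / d
    if orientation == "benefit_positive":
        effect = -effect
    return Study(record.label, effect, variance)


def convert_2x2(records: Iterable[TwoByTwoRecord], orientation: str = "as_given") -> StudySet:
    """Convert a collection of 2x2 records into a StudySet."""
    return StudySet(two_by_two_to_study(r, orientation) for r in records)


def export_forest_table(studies: StudySet, result: MetaResult) -> pd.DataFrame:
    """Tidy per-study table behind a forest plot, plus the pooled row.

    Per-study confidence intervals use each study's own variance at the
    result's alpha; ``weight_pct`` is the analysis weight as a percentage
    of the total (sums to 100 over the study rows).
    """
    z = float(norm.ppf(1 - result.alpha / 2))
    w = np.array([result.weights[lab] for lab in studies.labels])
    pct = 100 * w / w.sum()
    rows = []
    for s, p in zip(studies, pct):
        half = z * math.sqrt(s.variance)
        rows.append(
            {
                "label": s.label,
                "effect": s.effect,
                "ci_low": s.effect - half,
                "ci_high": s.effect + half,
                "weight_pct": float(p),
                "pooled": False,
            }
        )
    rows.append(
        {
            "label": "pooled",
            "effect": result.theta_hat,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "weight_pct": 100.0,
            "pooled": True,
        }
    )
    return pd.DataFrame(rows)


def load_scenarios(path) -> list[Scenario]:
    """Load simulation scenarios from a YAML or JSON config.

    Two layouts are accepted: ``scenarios:`` (a list of explicit scenario
    mappings) and/or ``grid:`` (lists of values for S, ratio, theta, tau2
    plus scalar alpha/reps, expanded as a full product; the model defaults
    to fixed when tau2 = 0 and random otherwise).
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or not ({"scenarios", "grid"} & set(cfg)):
        raise InputError("config must define 'scenarios' and/or 'grid'")
    out: list[Scenario] = []
    for item in cfg.get("scenarios", []):
        try:
            out.append(Scenario(**item))
        except TypeError as exc:
            raise InputError(f"bad scenario entry {item!r}: {exc}") from None
    if "grid" in cfg:
        g = dict(cfg["grid"])
        s_values = g.pop("S", list(range(2, 31)))
        ratios = g.pop("ratio", [1 / 3, 1 / 5, 1 / 10])
        thetas = g.pop("theta", [0.0, 0.5, 1.0])
        tau2s = g.pop("tau2", [0.0, 0.01, 0.10, 0.50, 0.70])
        alpha = g.pop("alpha", 0.05)
        reps = g.pop("reps", 200)
        model = g.pop("model", None)
        if g:
            raise InputError(f"unknown grid keys: {sorted(g)}")
        for theta, tau2, ratio, s in product(thetas, tau2s, ratios, s_values):
            out.append(
                Scenario(
                    S=int(s), ratio=float(ratio), theta=float(theta),
                    tau2=float(tau2), alpha=float(alpha),
                    model=model or ("fixed" if tau2 == 0 else "random"),
                    reps=int(reps),
                )
            )
    if not out:
        raise InputError("config produced no scenarios")
    return out
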