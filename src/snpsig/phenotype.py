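"""Symptom-change scoring and quantile-based case/control cohort construction.

Each participant reports, for every symptom, an integer severity score
before and after the acute illness (scales oriented so higher = worse).
The per-sample *change score* is the sum of ``post - pre`` over a symptom
subset: all symptoms for the "total" score, or only fatigue-group symptoms
for the "fatigue" score.  Cases are samples at or above the upper quartile
of the change-score distribution; controls have non-negative scores below
the median; everything else (including negative scores, i.e. samples that
improved) is excluded from both groups.  Quartiles use linear interpolation
between order statistics (numpy's default, the classic "type 7" rule).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDistributionError, ValidationError

logger = logging.getLogger(__name__)

SYMPTOM_GROUPS = ("respiratory", "fatigue", "mental_health", "other")


@dataclass
class SymptomTable:
    """Per-sample pre/post symptom scores plus a symptom -> group mapping.

    ``data`` is indexed by sample id with two columns per symptom,
    ``<symptom>_pre`` and ``<symptom>_post``; extra columns (ancestry,
    covariates) are carried through untouched.
    """

    data: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        for sym, grp in self.groups.items():
            if grp not in SYMPTOM_GROUPS:
                raise ValidationError(f"unknown symptom group {grp!r} for {sym!r}")
            for suffix in ("_pre", "_post"):
                if f"{sym}{suffix}" not in self.data.columns:
                    raise ValidationError(f"missing column {sym}{suffix}")

    @property
    def symptoms(self) -> list[str]:
        return list(self.groups)

    def symptom_subset(self, subset: str) -> list[str]:
        if subset == "total":
            return self.symptoms
        if subset == "fatigue":
            return [s for s, g in self.groups.items() if g == "fatigue"]
        raise ValueError(f"unknown subset {subset!r}; expected 'total' or 'fatigue'")


def read_symptom_table(path: str | Path, groups_path: str | Path | None = None) -> SymptomTable:
    """Read a tab-separated phenotype table plus a JSON symptom-group sidecar."""
    path = Path(path)
    data = pd.read_csv(path, sep="\t", index_col=0)
    data.index = data.index.astype(str)
    if groups_path is None:
        groups_path = path.with_name(path.name + ".groups.json")
    with open(groups_path) as fh:
        groups = json.load(fh)
    return SymptomTable(data, groups)


def write_symptom_table(table: SymptomTable, path: str | Path) -> None:
    path = Path(path)
    table.data.to_csv(path, sep="\t", index_label="sample_id")
    with open(path.with_name(path.name + ".groups.json"), "w") as fh:
        json.dump(table.groups, fh, indent=1)


def change_scores(table: SymptomTable, subset: str = "total") -> pd.Series:
    """Per-sample summed symptom deterioration over the chosen subset.

    ``score = sum(post - pre)``; larger positive values mean worse
    deterioration.  Samples missing any pre/post value in the subset are
    dropped from the result (logged), never silently zeroed.
    """
    symptoms = table.symptom_subset(subset)
    if not symptoms:
        raise ValidationError(f"no symptoms in subset {subset!r}")
    pre = table.data[[f"{s}_pre" for s in symptoms]].to_numpy(dtype=float)
    post = table.data[[f"{s}_post" for s in symptoms]].to_numpy(dtype=float)
    complete = ~(np.isnan(pre).any(axis=1) | np.isnan(post).any(axis=1))
    if not complete.all():
        dropped = list(table.data.index[~complete])
        logger.warning("excluding %d incomplete samples from %s change score: %s%s",
                       len(dropped), subset, dropped[:10], "..." if len(dropped) > 10 else "")
    scores = (post - pre).sum(axis=1)
    return pd.Series(scores[complete], index=table.data.index[complete], name=f"{subset}_change")


@dataclass
class CohortAssignment:
    """Case/control/excluded label per sample plus the thresholds applied."""

    labels: pd.Series  # values in {"case", "control", "excluded"}
    upper_quartile: float | None = None
    median: float | None = None

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"case", "control", "excluded"}
        if bad:
            raise ValidationError(f"invalid cohort labels {sorted(bad)}")

    @classmethod
    def from_labels(cls, case_mask, sample_ids) -> "CohortAssignment":
        """Build an assignment directly from a boolean case indicator."""
        case_mask = np.asarray(case_mask, dtype=bool)
        labels = pd.Series(
            np.where(case_mask, "case", "control"), index=pd.Index(sample_ids, name="sample_id")
        )
        return cls(labels)

    @property
    def cases(self) -> list[str]:
        return list(self.labels.index[self.labels == "case"])

    @property
    def controls(self) -> list[str]:
        return list(self.labels.index[self.labels == "control"])

    @property
    def n_cases(self) -> int:
        return int((self.labels == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == "control").sum())

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("label").to_frame()


def assign_cohort(scores: pd.Series, mode: str = "severe") -> CohortAssignment:
    """Split scored samples into cases, controls and excluded.

    Cases: ``score >= Q3``.  Controls: ``0 <= score < median``.  Remainder
    excluded.  ``mode`` is a label recording which score fed the rule
    ("severe" for the total change, "fatigue" for the fatigue subset); the
    quantile rule itself is identical for both cohort definitions.
    """
    if mode not in ("severe", "fatigue"):
        raise ValueError(f"unknown mode {mode!r}")
    values = scores.to_numpy(dtype=float)
    if values.size < 4:
        raise ValidationError("need at least 4 scored samples to form quartiles")
    q3 = float(np.quantile(values, 0.75))  # linear interpolation ("type 7")
    med = float(np.quantile(values, 0.5))
    if q3 == med:
        raise DegenerateDistributionError(
            f"upper quartile equals median ({med}); supply manual thresholds"
        )
    labels = np.full(values.shape, "excluded", dtype=object)
    labels[values >= q3] = "case"
    labels[(values >= 0) & (values < med)] = "control"
    if not (labels == "control").any():
        raise DegenerateDistributionError("empty control set (no scores in [0, median))")
    logger.info("cohort %s: Q3=%s median=%s -> %d cases, %d controls, %d excluded",
                mode, q3, med, (labels == "case").sum(), (labels == "control").sum(),
                (labels == "excluded").sum())
    return CohortAssignment(pd.Series(labels, index=scores.index), upper_quartile=q3, median=med)


def write_cohort(assignment: CohortAssignment, path: str | Path) -> None:
    """Write labels as TSV with the thresholds in a JSON sidecar."""
    path = Path(path)
    assignment.to_frame().to_csv(path, sep="\t", index_label="sample_id")
    sidecar = {"upper_quartile": assignment.upper_quartile, "median": assignment.median}
    with open(path.with_name(path.name + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
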