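"""GCxGC VOC feature-table algebra and presence/overlap fingerprinting.

The standard reduction for thin-film VOC tables is a fixed four-stage
pipeline whose order matters and is enforced:

1. average replicate peak areas within each condition,
2. subtract the mean of the designated blank means (instrument + media),
3. subtract the autoclaved-control means from the live means,
4. optionally remove every feature whose row still contains a zero.

Subtractions floor at zero so the zero-row removal rule is well defined
for over-subtracted cells.  Presence in a condition is called when the
background-corrected condition mean exceeds a threshold (default 0), and
set overlaps between soil and culture conditions are counted from the
resulting boolean matrix.

A transcription of the published table of KEGG-annotated compounds shared
between thermokarst soil incubations and *Methanosarcina acetivorans*
cultures ships with the package (:func:`load_shared_compound_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VALID_ROLES = ("sample", "instrument_blank", "media_blank", "autoclaved", "live")

#: Condition labels of the packaged shared-compound table.
BTL_CONDITIONS = (
    "BTL 50 cm (5 °C)",
    "BTL 50 cm (12 °C)",
    "BTL 50 cm (-4 °C)",
    "BTL 200 cm (5 °C)",
    "BTL 200 cm (12 °C)",
    "BTL 200 cm (-4 °C)",
    "BTL 400 cm (5 °C)",
    "BTL 400 cm (-4 °C)",
)
CULTURE_CONDITIONS = ("MaC2A (2 °C)", "MaC2A (37 °C)")
BTL_200_CONDITIONS = tuple(c for c in BTL_CONDITIONS if "200 cm" in c)


class PipelineOrderError(RuntimeError):
    """Raised when pipeline stages are applied out of their canonical order."""


_STAGE_ORDER = ("average", "subtract_background", "subtract_control", "drop_zero_rows")


@dataclass
class VOCFeatureTable:
    """Features × samples peak-area matrix with annotations and sample roles.

    ``areas``    — DataFrame indexed by feature id, one column per sample.
    ``features`` — per-feature metadata (mean_rt1, mean_rt2, compound,
                   kegg_id, superclass); same index as ``areas``.
    ``samples``  — per-sample metadata indexed by sample id with columns
                   ``condition`` and ``role`` (one of VALID_ROLES).
    """

    areas: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.areas.index.equals(self.features.index):
            raise ValueError("areas and features must share a feature index")
        if set(self.areas.columns) != set(self.samples.index):
            raise ValueError("areas columns and sample metadata must match")
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("peak areas must be non-negative")
        bad = set(self.samples["role"]) - set(VALID_ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        rt = self.features[["mean_rt1", "mean_rt2"]].round(6)
        if rt.duplicated().any():
            raise ValueError("(mean_rt1, mean_rt2) must be unique per feature")

    def sample_ids(self, role: str) -> list[str]:
        return list(self.samples.index[self.samples["role"] == role])

    def conditions(self, role: str = "live") -> list[str]:
        mask = self.samples["role"] == role
        return list(dict.fromkeys(self.samples.loc[mask, "condition"]))


@dataclass
class ConditionMeans:
    """Condition-mean peak areas moving through the reduction pipeline.

    Tracks which stages have been applied so that out-of-order use (e.g.
    control subtraction before blank subtraction) raises instead of
    silently changing the result.
    """

    values: pd.DataFrame  # features × conditions
    features: pd.DataFrame
    replicate_counts: pd.Series
    blank_means: pd.DataFrame  # features × blank roles (means per role)
    applied: tuple[str, ...] = ("average",)
    removal_log: list = field(default_factory=list)

    def _check_next(self, stage: str) -> None:
        if stage in self.applied:
            pass  # idempotent re-application is allowed
        want = _STAGE_ORDER[: _STAGE_ORDER.index(stage)]
        missing = [s for s in want if s not in self.applied]
        if missing:
            raise PipelineOrderError(
                f"stage {stage!r} requires {missing} to run first "
                f"(applied so far: {list(self.applied)})"
            )

    def with_stage(self, stage: str, values: pd.DataFrame) -> "ConditionMeans":
        applied = self.applied if stage in self.applied else self.applied + (stage,)
        return ConditionMeans(
            values,
            self.features.loc[values.index],
            self.replicate_counts,
            self.blank_means.loc[values.index]
            if len(self.blank_means)
            else self.blank_means,
            applied,
            list(self.removal_log),
        )


def average_replicates(table: VOCFeatureTable, role: str = "live") -> ConditionMeans:
    """Arithmetic mean of replicate peak areas within each condition.

    Blank-role means are computed alongside and carried for the later
    background-subtraction stage.
    """
    mask = table.samples["role"] == role
    if not mask.any():
        raise ValueError(f"no samples with role {role!r}")
    conds = table.conditions(role)
    values = {}
    counts = {}
    for cond in conds:
        ids = table.samples.index[mask & (table.samples["condition"] == cond)]
        values[cond] = table.areas[list(ids)].mean(axis=1)
        counts[cond] = len(ids)
    blank_means = {}
    for brole in ("instrument_blank", "media_blank"):
        ids = table.sample_ids(brole)
        if ids:
            blank_means[brole] = table.areas[ids].mean(axis=1)
    return ConditionMeans(
        pd.DataFrame(values),
        table.features.copy(),
        pd.Series(counts, name="replicates"),
        pd.DataFrame(blank_means) if blank_means else pd.DataFrame(index=table.areas.index),
    )


def subtract_background(
    means: ConditionMeans,
    blank_roles: Sequence[str] = ("instrument_blank", "media_blank"),
) -> ConditionMeans:
    """Subtract the mean of the designated blank means; floor at zero."""
    means._check_next("subtract_background")
    missing = [r for r in blank_roles if r not in means.blank_means.columns]
    if missing:
        raise ValueError(f"no blank columns for roles: {missing}")
    background = means.blank_means[list(blank_roles)].mean(axis=1)
    corrected = means.values.sub(background, axis=0).clip(lower=0.0)
    return means.with_stage("subtract_background", corrected)


def subtract_control(live: ConditionMeans, control: ConditionMeans) -> ConditionMeans:
    """Subtract autoclaved-control means from live means; floor at zero.

    Both tables must have passed blank subtraction and share a feature set;
    control conditions are matched to live conditions by label.
    """
    live._check_next("subtract_control")
    if "subtract_background" not in control.applied:
        raise PipelineOrderError("control table must be blank-subtracted first")
    if not live.values.index.equals(control.values.index):
        raise ValueError("live and control tables must share a feature set")
    missing = [c for c in live.values.columns if c not in control.values.columns]
    if missing:
        raise ValueError(f"control table lacks conditions: {missing}")
    corrected = (
        live.values - control.values[live.values.columns]
    ).clip(lower=0.0)
    return live.with_stage("subtract_control", corrected)


def drop_zero_rows(means: ConditionMeans) -> ConditionMeans:
    """Remove every feature whose row contains at least one zero.

    The removal log (feature id, offending conditions) is carried on the
    returned table.
    """
    means._check_next("drop_zero_rows")
    has_zero = (means.values == 0.0).any(axis=1)
    log = [
        (fid, list(means.values.columns[means.values.loc[fid] == 0.0]))
        for fid in means.values.index[has_zero]
    ]
    kept = means.values.loc[~has_zero]
    out = means.with_stage("drop_zero_rows", kept)
    out.removal_log.extend(log)
    return out


def bin_features_by_max(
    means: ConditionMeans | pd.DataFrame,
    tie_order: Sequence[str] | None = None,
) -> tuple[pd.Series, list[str]]:
    """Assign each feature to the condition with its highest mean area.

    Ties go to the first condition in ``tie_order`` (default: the table's
    column order); tied features are returned in the flag list.
    """
    values = means.values if isinstance(means, ConditionMeans) else means
    if values.shape[1] < 1:
        raise ValueError("need at least one condition")
    order = list(tie_order) if tie_order is not None else list(values.columns)
    missing = [c for c in values.columns if c not in order]
    if missing:
        raise ValueError(f"tie_order missing conditions: {missing}")
    ordered = values[order]
    arr = ordered.to_numpy()
    idx = np.argmax(arr, axis=1)  # argmax takes the first maximum → tie policy
    assignments = pd.Series(
        [order[i] for i in idx], index=values.index, name="condition"
    )
    row_max = arr.max(axis=1, keepdims=True)
    ties = list(values.index[(arr == row_max).sum(axis=1) > 1])
    return assignments, ties


def superclass_counts(
    assignments: pd.Series, annotations: pd.Series | Mapping[str, str]
) -> pd.DataFrame:
    """Contingency counts of features per (condition, chemical superclass).

    Features without a superclass annotation count as "unclassified"; the
    row sums equal the number of features assigned to each condition.
    """
    ann = pd.Series(annotations)
    classes = assignments.index.map(
        lambda fid: ann.get(fid) if pd.notna(ann.get(fid)) else "unclassified"
    )
    frame = pd.DataFrame({"condition": assignments.values, "superclass": classes})
    return pd.crosstab(frame["condition"], frame["superclass"])


@dataclass
class PresenceMatrix:
    """Boolean compounds × conditions matrix (presence/absence calls)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any() or self.frame.index.duplicated().any():
            raise ValueError("presence matrix labels must be unique")
        self.frame = self.frame.astype(bool)

    @property
    def conditions(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def compounds(self) -> list[str]:
        return list(self.frame.index)

    def to_csv(self, path, dialect: str = "+-", sep: str = "\t") -> None:
        if dialect == "+-":
            out = self.frame.replace({True: "+", False: "-"})
        elif dialect == "01":
            out = self.frame.astype(int)
        else:
            raise ValueError("dialect must be '+-' or '01'")
        out.to_csv(path, sep=sep)

    @classmethod
    def from_frame_of_marks(cls, frame: pd.DataFrame) -> "PresenceMatrix":
        def parse(v):
            s = str(v).strip()
            if s in {"+", "1", "True"}:
                return True
            if s in {"-", "−", "0", "False"}:
                return False
            raise ValueError(f"unrecognised presence mark {v!r}")

        return cls(frame.map(parse))

    @classmethod
    def from_csv(cls, path, sep: str = "\t", index_col: int = 0) -> "PresenceMatrix":
        return cls.from_frame_of_marks(pd.read_csv(path, sep=sep, index_col=index_col))


def presence_matrix(
    means: ConditionMeans, threshold: float = 0.0
) -> PresenceMatrix:
    """Presence call: background-corrected condition mean > threshold."""
    if "subtract_background" not in means.applied:
        raise PipelineOrderError("presence calls require a background-corrected table")
    return PresenceMatrix(means.values > threshold)


@dataclass(frozen=True)
class OverlapQuery:
    """Two condition sets, each combined by ``any`` (union) or ``all``."""

    set_a: tuple[str, ...]
    set_b: tuple[str, ...]
    combine_a: str = "any"
    combine_b: str = "any"

    def __post_init__(self) -> None:
        if not self.set_a or not self.set_b:
            raise ValueError("both condition sets must be non-empty")
        for comb in (self.combine_a, self.combine_b):
            if comb not in ("any", "all"):
                raise ValueError("combinators must be 'any' or 'all'")


def overlap_count(
    matrix: PresenceMatrix, query: OverlapQuery
) -> tuple[int, list[str]]:
    """Compounds satisfying both condition-set combinators, with the count.

    The compound list is returned sorted for deterministic output.
    Enlarging either set under ``any`` can only grow the result.
    """
    for label in (*query.set_a, *query.set_b):
        if label not in matrix.frame.columns:
            raise KeyError(f"unknown condition label {label!r}")

    def combine(labels: tuple[str, ...], how: str) -> pd.Series:
        block = matrix.frame[list(labels)]
        return block.any(axis=1) if how == "any" else block.all(axis=1)

    hit = combine(query.set_a, query.combine_a) & combine(query.set_b, query.combine_b)
    compounds = sorted(matrix.frame.index[hit])
    return len(compounds), compounds


def run_standard_pipeline(
    table: VOCFeatureTable,
    blank_roles: Sequence[str] = ("instrument_blank", "media_blank"),
    live_role: str = "live",
    control_role: str = "autoclaved",
    drop_zeros: bool = False,
    presence_threshold: float = 0.0,
) -> dict:
    """Run averaging → blank subtraction → control subtraction [→ zero-row
    removal] and derive the presence matrix.

    Returns a dict with the corrected :class:`ConditionMeans` (``table``),
    the :class:`PresenceMatrix` (``presence``) and the removal log.
    """
    live = average_replicates(table, live_role)
    live = subtract_background(live, blank_roles)
    if control_role in set(table.samples["role"]):
        control = subtract_background(
            average_replicates(table, control_role), blank_roles
        )
        live = subtract_control(live, control)
    presence = presence_matrix(live, presence_threshold)
    if drop_zeros:
        live = drop_zero_rows(live)
    return {"table": live, "presence": presence, "removed": live.removal_log}


def load_shared_compound_table() -> PresenceMatrix:
    """The packaged table of KEGG-annotated compounds shared between
    thermokarst soil incubations and *M. acetivorans* cultures.

    Compounds index the rows; the 10 incubation/culture conditions are the
    columns (see :data:`BTL_CONDITIONS` and :data:`CULTURE_CONDITIONS`).
    """
    ref = resources.files("thawflux.data").joinpath("shared_voc_presence.tsv")
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    frame = frame.drop(columns=["kegg_id"])
    return PresenceMatrix.from_frame_of_marks(frame)


def load_shared_compound_annotations() -> pd.DataFrame:
    """KEGG ids and chemical superclasses for the shared-compound table."""
    ref = resources.files("thawflux.data").joinpath("shared_voc_presence.tsv")
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    sup_ref = resources.files("thawflux.data").joinpath("compound_superclasses.tsv")
    with resources.as_file(sup_ref) as path:
        sup = pd.read_csv(path, sep="\t", index_col=0)
    return frame[["kegg_id"]].join(sup)


def read_feature_table(areas_path, samples_path, features_path=None) -> VOCFeatureTable:
    """Read a wide delimited feature table plus its sample-metadata sidecar."""
    areas = pd.read_csv(areas_path, sep=None, engine="python", index_col=0)
    samples = pd.read_csv(samples_path, sep=None, engine="python", index_col=0)
    if features_path is not None:
        features = pd.read_csv(features_path, sep=None, engine="python", index_col=0)
    else:
        features = pd.DataFrame(
            {
                "mean_rt1": np.arange(len(areas), dtype=float),
                "mean_rt2": np.zeros(len(areas)),
                "compound": areas.index,
                "kegg_id": [None] * len(areas),
                "superclass": [None] * len(areas),
            },
            index=areas.index,
        )
    return VOCFeatureTable(areas, features, samples)
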