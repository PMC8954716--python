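"""Synoptic placental-pathology scoring.

A scoring scheme names a set of placental lesions, assigns each a scale
(binary absent/present or a graded focal/patchy/diffuse scale), and groups
them into etiological categories (maternal vascular malperfusion,
chorioamnionitis, ...). A participant's category severity is the sum of her
observed member-lesion grades capped at the category maximum; the cumulative
severity is the sum over categories. Placentas whose maternal vascular
malperfusion (MVM) score reaches a threshold (default 2) are flagged
``mvm_severe`` — the exposure used downstream for cardiovascular-risk
association.

The default scheme shipped with the package is a plain YAML file
(``data/default_scheme.yaml``); users may supply their own via
:func:`load_scheme`.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import yaml

__all__ = [
    "BINARY_LABELS",
    "GRADED_LABELS",
    "MVM_CATEGORY",
    "LesionDefinition",
    "CategoryDefinition",
    "ScoringScheme",
    "LesionObservation",
    "PlacentaSeverityProfile",
    "SchemeValidationError",
    "UnknownLesionError",
    "GradeRangeError",
    "DuplicateObservationError",
    "load_scheme",
    "default_scheme",
    "score_lesion",
    "category_severity",
    "severity_profile",
    "profiles_for_cohort",
    "read_observations_long",
    "read_observations_wide",
    "profiles_to_frame",
]

MVM_CATEGORY = "MVM"

BINARY_LABELS = ("absent", "present")
GRADED_LABELS = ("absent", "focal", "patchy", "diffuse")


class SchemeValidationError(ValueError):
    """A scoring scheme violates a structural invariant."""


class UnknownLesionError(KeyError):
    """An observation references a lesion the scheme does not define."""


class GradeRangeError(ValueError):
    """An observed grade exceeds the lesion's maximum grade (or is negative)."""


class DuplicateObservationError(ValueError):
    """The same lesion was observed more than once for one participant."""


@dataclass(frozen=True)
class LesionDefinition:
    """One named lesion and its grading scale."""

    lesion_id: str
    display_name: str
    category_id: str
    scale: str  # "binary" | "graded"
    max_grade: int = 0
    grade_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.scale not in ("binary", "graded"):
            raise SchemeValidationError(
                f"lesion {self.lesion_id!r}: scale must be 'binary' or 'graded', "
                f"got {self.scale!r}"
            )
        default_max = 1 if self.scale == "binary" else 3
        if self.max_grade == 0:
            object.__setattr__(self, "max_grade", default_max)
        if self.max_grade != default_max:
            raise SchemeValidationError(
                f"lesion {self.lesion_id!r}: {self.scale} scale requires "
                f"max_grade {default_max}, got {self.max_grade}"
            )
        if not self.grade_labels:
            labels = BINARY_LABELS if self.scale == "binary" else GRADED_LABELS
            object.__setattr__(self, "grade_labels", labels)
        if len(self.grade_labels) != self.max_grade + 1:
            raise SchemeValidationError(
                f"lesion {self.lesion_id!r}: expected {self.max_grade + 1} "
                f"grade labels, got {len(self.grade_labels)}"
            )


@dataclass(frozen=True)
class CategoryDefinition:
    """An etiological lesion category with a severity cap."""

    category_id: str
    display_name: str
    max_score: int
    member_lesions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.max_score <= 0:
            raise SchemeValidationError(
                f"category {self.category_id!r}: max_score must be positive"
            )


@dataclass
class ScoringScheme:
    """A validated collection of categories and lesions.

    Category ``member_lesions`` are derived from the lesions' ``category_id``
    references at construction time.
    """

    categories: tuple[CategoryDefinition, ...]
    lesions: tuple[LesionDefinition, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        self.categories = tuple(self.categories)
        self.lesions = tuple(self.lesions)
        dup = [k for k, n in Counter(l.lesion_id for l in self.lesions).items() if n > 1]
        if dup:
            raise SchemeValidationError(f"duplicate lesion_id(s): {sorted(dup)}")
        dup = [k for k, n in Counter(c.category_id for c in self.categories).items() if n > 1]
        if dup:
            raise SchemeValidationError(f"duplicate category_id(s): {sorted(dup)}")
        cat_ids = {c.category_id for c in self.categories}
        for lesion in self.lesions:
            if lesion.category_id not in cat_ids:
                raise SchemeValidationError(
                    f"lesion {lesion.lesion_id!r} references unknown category "
                    f"{lesion.category_id!r}"
                )
        members: dict[str, list[str]] = {c.category_id: [] for c in self.categories}
        for lesion in self.lesions:
            members[lesion.category_id].append(lesion.lesion_id)
        self.categories = tuple(
            CategoryDefinition(
                c.category_id, c.display_name, c.max_score, tuple(members[c.category_id])
            )
            for c in self.categories
        )
        self._lesion_index = {l.lesion_id: l for l in self.lesions}
        self._category_index = {c.category_id: c for c in self.categories}

    # -- lookups ---------------------------------------------------------
    def lesion(self, lesion_id: str) -> LesionDefinition:
        try:
            return self._lesion_index[lesion_id]
        except KeyError:
            raise UnknownLesionError(lesion_id) from None

    def category(self, category_id: str) -> CategoryDefinition:
        try:
            return self._category_index[category_id]
        except KeyError:
            raise KeyError(f"unknown category {category_id!r}") from None

    @property
    def lesion_ids(self) -> tuple[str, ...]:
        return tuple(l.lesion_id for l in self.lesions)

    @property
    def category_ids(self) -> tuple[str, ...]:
        return tuple(c.category_id for c in self.categories)


@dataclass(frozen=True)
class LesionObservation:
    """One pathologist-recorded grade for one lesion of one participant."""

    participant_id: str
    lesion_id: str
    grade: Union[int, str]


@dataclass(frozen=True)
class PlacentaSeverityProfile:
    """Per-category and cumulative severity for one placenta."""

    participant_id: str
    category_scores: Mapping[str, int]
    cumulative_score: int
    mvm_severe: bool
    missing_lesions: tuple[str, ...] = ()


def _build_scheme(raw: Mapping) -> ScoringScheme:
    for block in ("categories", "lesions"):
        if block not in raw:
            raise SchemeValidationError(f"scheme file missing {block!r} block")
    categories = []
    for entry in raw["categories"]:
        try:
            categories.append(
                CategoryDefinition(
                    category_id=str(entry["category_id"]),
                    display_name=str(entry.get("display_name", entry["category_id"])),
                    max_score=int(entry["max_score"]),
                )
            )
        except KeyError as exc:
            raise SchemeValidationError(f"category entry missing field {exc}") from None
    lesions = []
    for entry in raw["lesions"]:
        try:
            lesions.append(
                LesionDefinition(
                    lesion_id=str(entry["lesion_id"]),
                    display_name=str(entry.get("display_name", entry["lesion_id"])),
                    category_id=str(entry["category_id"]),
                    scale=str(entry["scale"]),
                    grade_labels=tuple(entry.get("grade_labels", ())),
                )
            )
        except KeyError as exc:
            raise SchemeValidationError(f"lesion entry missing field {exc}") from None
    return ScoringScheme(
        categories=tuple(categories),
        lesions=tuple(lesions),
        version=str(raw.get("version", "unversioned")),
    )


def load_scheme(path: Union[str, Path]) -> ScoringScheme:
    """Load and validate a scoring scheme from a YAML file."""
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SchemeValidationError(f"cannot parse scheme file {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise SchemeValidationError(f"scheme file {path} is not a mapping")
    return _build_scheme(raw)


def default_scheme() -> ScoringScheme:
    """The scheme shipped with the package (seven categories, caps 14/4/11/5/6/5/6)."""
    ref = importlib.resources.files("pps.data") / "default_scheme.yaml"
    return _build_scheme(yaml.safe_load(ref.read_text()))


def score_lesion(obs: LesionObservation, scheme: ScoringScheme) -> int:
    """Validate one observation and return its ordinal grade.

    Grades may be integers or grade labels ("absent", "focal", "patchy",
    "diffuse" / "present"); labels are mapped to their ordinal position on
    the lesion's scale.
    """
    lesion = scheme.lesion(obs.lesion_id)
    grade = obs.grade
    if isinstance(grade, str):
        label = grade.strip().lower()
        try:
            grade = lesion.grade_labels.index(label)
        except ValueError:
            raise GradeRangeError(
                f"lesion {obs.lesion_id!r}: unknown grade label {obs.grade!r} "
                f"(expected one of {lesion.grade_labels})"
            ) from None
    grade = int(grade)
    if not 0 <= grade <= lesion.max_grade:
        raise GradeRangeError(
            f"lesion {obs.lesion_id!r}: grade {grade} outside [0, {lesion.max_grade}]"
        )
    return grade


def category_severity(
    observations: Iterable[LesionObservation],
    category: CategoryDefinition,
    scheme: ScoringScheme,
) -> int:
    """Sum of member-lesion grades, capped at the category maximum.

    Observations for lesions outside the category are ignored; a lesion
    observed twice is an error; unobserved lesions contribute 0.
    """
    seen: dict[str, int] = {}
    for obs in observations:
        grade = score_lesion(obs, scheme)
        if scheme.lesion(obs.lesion_id).category_id != category.category_id:
            continue
        if obs.lesion_id in seen:
            raise DuplicateObservationError(
                f"participant {obs.participant_id!r}: duplicate observation for "
                f"lesion {obs.lesion_id!r}"
            )
        seen[obs.lesion_id] = grade
    return min(sum(seen.values()), category.max_score)


def severity_profile(
    observations: Sequence[LesionObservation],
    scheme: ScoringScheme,
    mvm_threshold: int = 2,
) -> PlacentaSeverityProfile:
    """Full severity profile for one participant's observation set."""
    observations = list(observations)
    participants = {o.participant_id for o in observations}
    if len(participants) > 1:
        raise ValueError(f"observations span several participants: {sorted(participants)}")
    participant_id = observations[0].participant_id if observations else ""
    scores = {
        cat.category_id: category_severity(observations, cat, scheme)
        for cat in scheme.categories
    }
    observed = {o.lesion_id for o in observations}
    missing = tuple(l for l in scheme.lesion_ids if l not in observed)
    mvm = scores.get(MVM_CATEGORY, 0)
    return PlacentaSeverityProfile(
        participant_id=participant_id,
        category_scores=scores,
        cumulative_score=sum(scores.values()),
        mvm_severe=mvm >= mvm_threshold,
        missing_lesions=missing,
    )


def profiles_for_cohort(
    observations: Iterable[LesionObservation],
    scheme: ScoringScheme,
    mvm_threshold: int = 2,
) -> list[PlacentaSeverityProfile]:
    """Group observations by participant and score each placenta."""
    by_participant: dict[str, list[LesionObservation]] = {}
    for obs in observations:
        by_participant.setdefault(obs.participant_id, []).append(obs)
    return [
        severity_profile(obs_list, scheme, mvm_threshold)
        for _, obs_list in sorted(by_participant.items())
    ]


# ---------------------------------------------------------------------------
# I/O: long- and wide-format observation tables, profile writer
# ---------------------------------------------------------------------------

def read_observations_long(source: Union[str, Path, pd.DataFrame]) -> list[LesionObservation]:
    """Read observations from a long table (participant_id, lesion_id, grade).

    Missing grades are skipped (they surface as ``missing_lesions`` in the
    profile); grades may be labels or integers.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep=None, engine="python")
    required = {"participant_id", "lesion_id", "grade"}
    if not required.issubset(df.columns):
        raise ValueError(f"long-format table needs columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        if pd.isna(row.grade):
            continue
        grade = row.grade
        if not isinstance(grade, str):
            grade = int(grade)
        out.append(LesionObservation(str(row.participant_id), str(row.lesion_id), grade))
    return out


def read_observations_wide(
    source: Union[str, Path, pd.DataFrame],
    scheme: ScoringScheme,
    prefix: str = "lesion_",
) -> list[LesionObservation]:
    """Read observations from a wide table (one ``lesion_<id>`` column per lesion).

    Columns without the prefix that do not match a lesion id are ignored, so
    a full cohort table can be passed directly. NaN cells become missing
    observations.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep=None, engine="python")
    if "participant_id" not in df.columns:
        raise ValueError("wide-format table needs a participant_id column")
    colmap = {}
    for lesion_id in scheme.lesion_ids:
        for cand in (prefix + lesion_id, lesion_id):
            if cand in df.columns:
                colmap[lesion_id] = cand
                break
    out = []
    for _, row in df.iterrows():
        pid = str(row["participant_id"])
        for lesion_id, col in colmap.items():
            value = row[col]
            if pd.isna(value):
                continue
            grade = value if isinstance(value, str) else int(value)
            out.append(LesionObservation(pid, lesion_id, grade))
    return out


def profiles_to_frame(profiles: Iterable[PlacentaSeverityProfile]) -> pd.DataFrame:
    """Tabulate profiles: one row per participant, one column per category."""
    rows = []
    for prof in profiles:
        row: dict[str, object] = {"participant_id": prof.participant_id}
        for cat_id, score in prof.category_scores.items():
            row[f"score_{cat_id}"] = score
        row["cumulative_score"] = prof.cumulative_score
        row["mvm_severe"] = prof.mvm_severe
        row["n_missing_lesions"] = len(prof.missing_lesions)
        rows.append(row)
    return pd.DataFrame(rows)
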