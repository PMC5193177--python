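"""Subject metadata and illness-course labelling.

Follow-up information for first-episode psychosis patients is recorded as
day-resolution interval histories: psychotic episodes and remission periods
within a follow-up window.  The outcome rule maps each history onto one of
three labels:

``continuous``
    no remission period of six months or more anywhere in the follow-up;
``remitting``
    at least one remission of six months or longer and no episode lasting
    more than six months — or a single psychotic episode of at most six
    months, which counts as remitting regardless of the recorded remissions;
``excluded``
    a long remission together with a long episode, i.e. neither extreme
    course type; such subjects are dropped from outcome modelling but kept
    for sex modelling.

"Six months" is pinned to 183 days.  "Longer than six months" is strict
(``> 183``); "at least six months" is inclusive (``>= 183``).  The clauses
are applied in a fixed precedence (single short episode, then remitting,
then excluded, then continuous) so that every valid history receives
exactly one label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import pandas as pd

SIX_MONTHS_DAYS = 183

SEXES = ("male", "female")
COURSES = ("continuous", "remitting", "excluded")

CONTINUOUS = "continuous"
REMITTING = "remitting"
EXCLUDED = "excluded"


class CohortError(ValueError):
    """Raised for malformed histories, metadata files or cohort invariants."""


@dataclass(frozen=True)
class EpisodeHistory:
    """Interval record of psychotic episodes and remissions during follow-up.

    Intervals are ``(start_day, duration_days)`` pairs with ``duration > 0``,
    contained in ``[0, follow_up_days]``, and pairwise non-overlapping
    (episodes and remissions together partition disjoint stretches of time).
    """

    episodes: tuple[tuple[int, int], ...]
    remissions: tuple[tuple[int, int], ...]
    follow_up_days: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "episodes", tuple(tuple(e) for e in self.episodes))
        object.__setattr__(self, "remissions", tuple(tuple(r) for r in self.remissions))
        if self.follow_up_days <= 0:
            raise CohortError(f"follow_up_days must be positive, got {self.follow_up_days}")
        intervals = [*self.episodes, *self.remissions]
        for start, dur in intervals:
            if dur <= 0:
                raise CohortError(f"interval duration must be positive, got {dur}")
            if start < 0 or start + dur > self.follow_up_days:
                raise CohortError(
                    f"interval ({start}, {dur}) outside follow-up window "
                    f"[0, {self.follow_up_days}]"
                )
        spans = sorted((s, s + d) for s, d in intervals)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise CohortError(f"overlapping intervals: [{a0},{a1}) and [{b0},{b1})")


def classify_illness_course(
    history: EpisodeHistory, six_months_days: int = SIX_MONTHS_DAYS
) -> str:
    """Map a follow-up history to continuous / remitting / excluded.

    Clause precedence (first match wins):

    1. exactly one episode, lasting at most six months -> ``remitting``;
    2. a remission of at least six months and no episode longer than six
       months -> ``remitting``;
    3. a remission of at least six months together with an episode longer
       than six months -> ``excluded``;
    4. otherwise (no remission of six months or more) -> ``continuous``.
    """
    long_episode = any(d > six_months_days for _, d in history.episodes)
    long_remission = any(d >= six_months_days for _, d in history.remissions)
    if len(history.episodes) == 1 and not long_episode:
        return REMITTING
    if long_remission and not long_episode:
        return REMITTING
    if long_remission and long_episode:
        return EXCLUDED
    return CONTINUOUS


@dataclass(frozen=True)
class Subject:
    subject_id: str
    site: str
    sex: str
    diagnosis: str = "psychosis"
    age_years: float = float("nan")
    history: Optional[EpisodeHistory] = None
    course_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CohortError(f"unknown sex {self.sex!r} for subject {self.subject_id}")
        if self.course_label is not None and self.course_label not in COURSES:
            raise CohortError(
                f"unknown course label {self.course_label!r} for subject {self.subject_id}"
            )


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of subjects with unique identifiers."""

    subjects: tuple[Subject, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        seen: set[str] = set()
        for s in self.subjects:
            if s.subject_id in seen:
                raise CohortError(f"duplicate subject_id {s.subject_id!r}")
            seen.add(s.subject_id)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[Subject]:
        return iter(self.subjects)

    def __getitem__(self, i: int) -> Subject:
        return self.subjects[i]

    @property
    def sites(self) -> tuple[str, ...]:
        out: list[str] = []
        for s in self.subjects:
            if s.site not in out:
                out.append(s.site)
        return tuple(out)

    def subset(self, indices: Sequence[int]) -> "Cohort":
        return Cohort(tuple(self.subjects[i] for i in indices))

    def row_index(self) -> dict[str, int]:
        """subject_id -> position, for aligning feature-matrix rows."""
        return {s.subject_id: i for i, s in enumerate(self.subjects)}


def label_cohort(cohort: Cohort, six_months_days: int = SIX_MONTHS_DAYS) -> Cohort:
    """Return a copy with ``course_label`` filled from each history.

    Subjects without a follow-up history are labelled ``excluded``
    (unclassifiable outcome, conservative).
    """
    labelled = []
    for s in cohort:
        if s.history is None:
            labelled.append(replace(s, course_label=EXCLUDED))
        else:
            labelled.append(
                replace(s, course_label=classify_illness_course(s.history, six_months_days))
            )
    return Cohort(tuple(labelled))


def select_outcome_cohort(cohort: Cohort, males_only: bool = False) -> Cohort:
    """Keep only subjects with an extreme course (continuous or remitting).

    Input order is preserved.  With ``males_only`` the female subjects are
    dropped as well, mirroring the reduced-heterogeneity outcome models.
    """
    kept = []
    for s in cohort:
        if s.course_label is None:
            raise CohortError(f"subject {s.subject_id} has no course label; run label_cohort")
        if s.course_label not in (CONTINUOUS, REMITTING):
            continue
        if males_only and s.sex != "male":
            continue
        kept.append(s)
    return Cohort(tuple(kept))


METADATA_COLUMNS = (
    "subject_id",
    "site",
    "sex",
    "diagnosis",
    "age_years",
    "course",
    "follow_up_days",
    "episodes",
    "remissions",
)


def write_metadata(cohort: Cohort, path) -> None:
    """Write the cohort as UTF-8 TSV; interval lists are JSON strings."""
    rows = []
    for s in cohort:
        h = s.history
        rows.append(
            {
                "subject_id": s.subject_id,
                "site": s.site,
                "sex": s.sex,
                "diagnosis": s.diagnosis,
                "age_years": s.age_years,
                "course": "" if s.course_label is None else s.course_label,
                "follow_up_days": "" if h is None else h.follow_up_days,
                "episodes": "" if h is None else json.dumps([list(e) for e in h.episodes]),
                "remissions": "" if h is None else json.dumps([list(r) for r in h.remissions]),
            }
        )
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_metadata(path) -> Cohort:
    """Read a metadata TSV written by :func:`write_metadata`.

    Raises :class:`CohortError` naming the offending row for missing
    columns, duplicate ids, or invalid enum values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"metadata file {path} is missing columns: {missing}")
    subjects = []
    seen: set[str] = set()
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        sid = row.subject_id
        if sid in seen:
            raise CohortError(f"row {row_number}: duplicate subject_id {sid!r}")
        seen.add(sid)
        if row.sex not in SEXES:
            raise CohortError(f"row {row_number}: invalid sex {row.sex!r}")
        course = row.course or None
        if course is not None and course not in COURSES:
            raise CohortError(f"row {row_number}: invalid course {course!r}")
        history = None
        if row.follow_up_days != "":
            try:
                history = EpisodeHistory(
                    episodes=tuple(tuple(e) for e in json.loads(row.episodes or "[]")),
                    remissions=tuple(tuple(r) for r in json.loads(row.remissions or "[]")),
                    follow_up_days=int(row.follow_up_days),
                )
            except (json.JSONDecodeError, CohortError, ValueError) as exc:
                raise CohortError(f"row {row_number}: bad history: {exc}") from exc
        subjects.append(
            Subject(
                subject_id=sid,
                site=row.site,
                sex=row.sex,
                diagnosis=row.diagnosis,
                age_years=float(row.age_years) if row.age_years != "" else float("nan"),
                history=history,
                course_label=course,
            )
        )
    return Cohort(tuple(subjects))
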