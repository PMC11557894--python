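"""Task/condition vocabulary and trait/dimension labels.

The seven in-scanner tasks and their 13 condition-vs-baseline contrast maps
form a fixed catalogue so that tables, models and command-line inputs can be
validated against an exact vocabulary. Extra condition labels can be
registered at run time for user-supplied data.
"""

from __future__ import annotations

# task -> conditions, in canonical order
TASK_CONDITIONS: dict[str, tuple[str, ...]] = {
    "motor": ("motor-avg",),
    "emotion": ("emotion-faces", "emotion-shapes"),
    "language": ("language-math", "language-story"),
    "social": ("social-random", "social-tom"),
    "wm": ("wm-0back", "wm-2back"),
    "gambling": ("gambling-reward", "gambling-punish"),
    "relational": ("relational-match", "relational-rel"),
}

CONDITIONS: tuple[str, ...] = tuple(
    c for conds in TASK_CONDITIONS.values() for c in conds
)

CONDITION_TO_TASK: dict[str, str] = {
    c: task for task, conds in TASK_CONDITIONS.items() for c in conds
}

TASKS: tuple[str, ...] = tuple(TASK_CONDITIONS)

TRAITS: tuple[str, ...] = (
    "neuroticism",
    "openness",
    "conscientiousness",
    "extraversion",
    "agreeableness",
)

DIMENSIONS: tuple[str, ...] = ("D1", "D2", "D3")

COVARIATES: tuple[str, ...] = ("age", "gender", "mean_fd")

# user-registered extra conditions (label -> task), mutated by register_condition
_EXTRA_CONDITIONS: dict[str, str] = {}


class UnknownConditionError(KeyError):
    """A condition label is neither in the catalogue nor user-registered."""


class UndefinedCorrelationError(ValueError):
    """A rank correlation is undefined (constant input vector)."""


class MissingSubjectError(KeyError):
    """Subjects present in a map set are absent from the cohort table."""


class EmptyResultError(ValueError):
    """An operation produced no usable rows (e.g. no complete cases)."""


def register_condition(label: str, task: str) -> None:
    """Register a non-catalogue condition label under a task name."""
    _EXTRA_CONDITIONS[label] = task


def known_conditions() -> tuple[str, ...]:
    return CONDITIONS + tuple(_EXTRA_CONDITIONS)


def task_of(condition: str) -> str:
    """Task owning a condition; raises UnknownConditionError for strangers."""
    if condition in CONDITION_TO_TASK:
        return CONDITION_TO_TASK[condition]
    if condition in _EXTRA_CONDITIONS:
        return _EXTRA_CONDITIONS[condition]
    raise UnknownConditionError(
        f"unknown condition {condition!r}; allowed: {sorted(known_conditions())} "
        "(use register_condition() for custom labels)"
    )


def check_conditions(labels) -> None:
    """Validate an iterable of condition labels against the vocabulary."""
    bad = [c for c in labels if c not in CONDITION_TO_TASK and c not in _EXTRA_CONDITIONS]
    if bad:
        raise UnknownConditionError(
            f"unknown condition(s) {bad}; allowed: {sorted(known_conditions())}"
        )
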