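"""Core domain records shared across the analysis modules.

The study system is a population of individually marked, communally roosting
birds observed in repeated group scans and in a two-option foraging
experiment.  These light dataclasses are the in-memory counterparts of the
CSV inputs; heavier tabular work goes through pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AGE_CLASSES = ("adult", "juvenile", "unknown")
SEX_CLASSES = ("male", "female", "unknown")
OPTIONS = ("red", "blue")


@dataclass(frozen=True)
class Individual:
    """A marked individual with its attribute classes.

    ``age_class`` and ``sex_class`` are three-level factors; "unknown" is a
    real level (unknown-attribute birds form their own cells in the
    hierarchical choice model, and are coded 0 in the diffusion covariates).
    ``tutored_option`` is the colour a trained demonstrator was seeded with,
    or ``None`` for naive birds.
    """

    id: str
    age_class: str = "unknown"
    sex_class: str = "unknown"
    roost: str | None = None
    tutored_option: str | None = None

    def __post_init__(self) -> None:
        if self.age_class not in AGE_CLASSES:
            raise ValueError(
                f"individual {self.id!r}: age_class {self.age_class!r} "
                f"not in {AGE_CLASSES}"
            )
        if self.sex_class not in SEX_CLASSES:
            raise ValueError(
                f"individual {self.id!r}: sex_class {self.sex_class!r} "
                f"not in {SEX_CLASSES}"
            )


@dataclass(frozen=True)
class GroupScan:
    """One instantaneous group scan: everyone present at a site.

    Under the gambit of the group, all individuals in one scan are taken to
    be associating.
    """

    scan_id: str
    time: float
    site: str
    present: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.present:
            raise ValueError(f"scan {self.scan_id!r}: empty presence set")


@dataclass(frozen=True)
class ChoiceEvent:
    """One solve: an individual picks an almond of a colour at a site.

    ``payoff`` is 1 iff the almond was successfully opened; a bird that
    drops the item experiences payoff 0.  ``individual`` may be the sentinel
    ``"UNMARKED"``; such events feed social-information windows but never
    contribute likelihood terms.
    """

    individual: str
    time: float
    site: str
    option: str
    payoff: int

    def __post_init__(self) -> None:
        if self.option not in OPTIONS:
            raise ValueError(f"unknown option {self.option!r}")
        if self.payoff not in (0, 1):
            raise ValueError(f"payoff must be 0 or 1, got {self.payoff!r}")

    @property
    def success(self) -> bool:
        return self.payoff == 1


UNMARKED = "UNMARKED"
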