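"""Experience-weighted attraction (EWA) choice model: core dynamics.

The probability that individual j picks option i at time t combines a
reinforcement-learning "individual" component I (a softmax over attraction
scores updated from experienced payoffs) and a "social" component S built
from demonstrations witnessed in the preceding 60 s window:

    Pr(i) = (1 - gamma_j) * I_ij,t + gamma_j * S_ij,t

Five strategy models differ only in S: pure individual learning (no S),
frequency dependence S_k = N_k^f / sum_m N_m^f (f > 1 conformist, f < 1
anti-conformist), male- and adult-bias (frequency with f = 1 restricted to
demonstrations by that category), and roost-bias (each demonstration by a
same-roost bird weighted exp(beta), the other-roost weight fixed at 1).

This module holds the readable, event-by-event implementation used both as
the public API and as the reference against which the vectorized fitting
kernel is checked.  Internals are K-option generic; the I/O layer assumes
the two colours.
"""

from __future__ import annotations

import bisect
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import OPTIONS, UNMARKED, ChoiceEvent, Individual

STRATEGIES = ("individual", "frequency", "male_bias", "age_bias", "roost_bias")

#: Free parameters (beyond lambda and phi) per strategy model.  The bias
#: models fix f = 1 and add no frequency exponent; roost bias adds the cue
#: strength beta.
STRATEGY_PARAMS: dict[str, tuple[str, ...]] = {
    "individual": ("lambda", "phi"),
    "frequency": ("lambda", "phi", "gamma", "f"),
    "male_bias": ("lambda", "phi", "gamma"),
    "age_bias": ("lambda", "phi", "gamma"),
    "roost_bias": ("lambda", "phi", "gamma", "beta"),
}


def update_attraction(a_k: float, payoff: float, phi: float) -> float:
    """One reinforcement step: A <- (1 - phi) A + phi * payoff.

    phi weighs the latest payoff against memory: phi = 0 never updates,
    phi = 1 forgets everything but the last outcome.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    return (1.0 - phi) * a_k + phi * payoff


def individual_probs(attractions: Sequence[float], lam: float) -> np.ndarray:
    """Softmax over lambda-scaled attractions; lambda = 0 is random choice."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    z = lam * np.asarray(attractions, dtype=float)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def frequency_social_probs(counts: Sequence[float], f: float) -> np.ndarray | None:
    """S_k = N_k^f / sum_m N_m^f, or ``None`` when nothing was witnessed."""
    if f <= 0:
        raise ValueError(f"frequency exponent f must be > 0, got {f}")
    n = np.asarray(counts, dtype=float)
    if n.sum() <= 0:
        return None
    w = np.where(n > 0, n, 1.0) ** f * (n > 0)
    return w / w.sum()


@dataclass
class SocialWindowTally:
    """Demonstrations witnessed by a focal bird in its pre-solve window.

    Counts per option: everyone, and restricted to male, adult, and
    same-roost / other-roost demonstrators (roost relative to the focal;
    unknown-roost and unmarked demonstrators count as other-roost and are
    excluded from the attribute categories).
    """

    total: np.ndarray = field(default_factory=lambda: np.zeros(len(OPTIONS)))
    male: np.ndarray = field(default_factory=lambda: np.zeros(len(OPTIONS)))
    adult: np.ndarray = field(default_factory=lambda: np.zeros(len(OPTIONS)))
    same_roost: np.ndarray = field(default_factory=lambda: np.zeros(len(OPTIONS)))
    other_roost: np.ndarray = field(default_factory=lambda: np.zeros(len(OPTIONS)))

    def __post_init__(self) -> None:
        for cat in (self.male, self.adult, self.same_roost, self.other_roost):
            if (cat > self.total).any() or (cat < 0).any():
                raise ValueError("category counts must be 0 <= n_cat <= n_total")

    @property
    def empty(self) -> bool:
        return self.total.sum() == 0


def cue_bias_social_probs(tally: SocialWindowTally, beta: float) -> np.ndarray | None:
    """Roost-cue weighting: same-roost demonstrations weighted exp(beta).

    Each witnessed demonstration carries weight exp(beta) if the demonstrator
    shares the focal's roost (cue value 1) and weight 1 otherwise (the
    reference category's weight is pinned at 1); option probabilities are the
    normalized summed weights.  beta = 0 reduces to unbiased frequency.
    """
    if tally.empty:
        return None
    w = tally.other_roost + math.exp(beta) * tally.same_roost
    return w / w.sum()


def category_social_probs(tally: SocialWindowTally, category: str) -> np.ndarray | None:
    """Frequency dependence (f = 1) counting one demonstrator category only.

    With no demonstrations by the category the tally is socially empty and
    the caller falls back to the individual component.
    """
    counts = {"male": tally.male, "adult": tally.adult,
              "all": tally.total}.get(category)
    if counts is None:
        raise ValueError(f"unknown demonstrator category {category!r}")
    total = counts.sum()
    if total <= 0:
        return None
    return counts / total


def choice_probability(
    individual: np.ndarray, social: np.ndarray | None, gamma: float
) -> np.ndarray:
    """Convex combination (1 - gamma) I + gamma S; I alone if S is absent."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if social is None:
        return np.asarray(individual, dtype=float)
    return (1.0 - gamma) * np.asarray(individual) + gamma * np.asarray(social)


def tally_social_window(
    events: Sequence[ChoiceEvent],
    focal: str,
    t: float,
    site: str,
    window: float = 60.0,
    attributes: Mapping[str, Individual] | None = None,
    focal_roost: str | None = None,
    demos: str = "all",
) -> SocialWindowTally:
    """Count demonstrations visible to ``focal`` in the half-open window
    [t - window, t) at ``site``.

    The focal's own solves are excluded; unmarked birds' solves count toward
    the totals.  ``demos="successful-only"`` restricts to opened almonds.
    """
    times = [e.time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("events must be sorted by time")
    attributes = attributes or {}
    if focal_roost is None and focal in attributes:
        focal_roost = attributes[focal].roost
    tally = SocialWindowTally()
    lo = bisect.bisect_left(times, t - window)
    hi = bisect.bisect_left(times, t)
    for e in events[lo:hi]:
        if e.site != site or e.individual == focal:
            continue
        if demos == "successful-only" and not e.success:
            continue
        k = OPTIONS.index(e.option)
        tally.total[k] += 1
        demo = attributes.get(e.individual)
        if demo is not None and e.individual != UNMARKED:
            if demo.sex_class == "male":
                tally.male[k] += 1
            if demo.age_class == "adult":
                tally.adult[k] += 1
            if (demo.roost is not None and focal_roost is not None
                    and demo.roost != "unknown" and demo.roost == focal_roost):
                tally.same_roost[k] += 1
                continue
        tally.other_roost[k] += 1
    return tally


def social_probs_for_strategy(
    tally: SocialWindowTally, strategy: str, f: float = 1.0, beta: float = 0.0
) -> np.ndarray | None:
    if strategy == "individual":
        return None
    if strategy == "frequency":
        return frequency_social_probs(tally.total, f)
    if strategy == "male_bias":
        return category_social_probs(tally, "male")
    if strategy == "age_bias":
        return category_social_probs(tally, "adult")
    if strategy == "roost_bias":
        return cue_bias_social_probs(tally, beta)
    raise ValueError(f"unknown strategy {strategy!r}")


def initial_attractions(individual: Individual | None) -> np.ndarray:
    """Tutored demonstrators start at attraction 1 for their trained colour;
    everyone else starts with no preference (0, 0)."""
    a = np.zeros(len(OPTIONS))
    if individual is not None and individual.tutored_option is not None:
        a[OPTIONS.index(individual.tutored_option)] = 1.0
    return a


_PROB_FLOOR = 1e-12


def ewa_loglik(
    events: Sequence[ChoiceEvent],
    param_table: pd.DataFrame,
    strategy: str,
    attributes: Mapping[str, Individual] | None = None,
    window: float = 60.0,
    demos: str = "all",
    pointwise: bool = False,
) -> float | np.ndarray:
    """Log-likelihood of the observed colour choices under one strategy.

    ``param_table`` is indexed by individual id with columns for that
    strategy's parameters (lambda, phi, and gamma/f/beta as applicable).
    Events are replayed in time order, maintaining each marked bird's
    attraction state and a rolling site-specific demonstration window;
    unmarked birds' events update windows but add no likelihood terms.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    times = [e.time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("events must be sorted by time")
    attributes = attributes or {}
    state: dict[str, np.ndarray] = {}
    terms = []
    for idx, event in enumerate(events):
        ind = event.individual
        if ind == UNMARKED:
            continue
        if ind not in param_table.index:
            raise ValueError(f"no parameters for marked individual {ind!r}")
        p = param_table.loc[ind]
        if ind not in state:
            state[ind] = initial_attractions(attributes.get(ind))
        i_comp = individual_probs(state[ind], float(p["lambda"]))
        if strategy == "individual":
            prob = i_comp
        else:
            tally = tally_social_window(
                events, ind, event.time, event.site, window=window,
                attributes=attributes, demos=demos,
            )
            s_comp = social_probs_for_strategy(
                tally, strategy,
                f=float(p["f"]) if "f" in p else 1.0,
                beta=float(p["beta"]) if "beta" in p else 0.0,
            )
            prob = choice_probability(i_comp, s_comp, float(p["gamma"]))
        k = OPTIONS.index(event.option)
        pk = float(prob[k])
        if pk <= _PROB_FLOOR:
            import warnings

            warnings.warn(
                f"event {idx}: observed choice has probability {pk:.3g}; "
                "floored", stacklevel=2,
            )
            pk = _PROB_FLOOR
        terms.append(math.log(pk))
        state[ind][k] = update_attraction(
            state[ind][k], event.payoff, float(p["phi"])
        )
    return np.array(terms) if pointwise else float(np.sum(terms))


def simulate_choices(
    roster: Mapping[str, Individual],
    schedule: Sequence[tuple[str, float, str]],
    param_table: pd.DataFrame,
    strategy: str,
    p_success: float = 0.9,
    window: float = 60.0,
    demos: str = "all",
    unmarked_p: float | Mapping[float, float] | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[ChoiceEvent]:
    """Generative mirror of :func:`ewa_loglik`.

    ``schedule`` lists (individual, time, site) solve opportunities in time
    order; each draw follows the current choice probability, success is
    Bernoulli(p_success), and realized payoffs feed back into attractions.
    Unmarked schedule entries only seed social windows; their colour is
    uniform unless ``unmarked_p`` gives the probability of the first option
    (a scalar, or a map from event time to that probability).
    """
    if not 0.0 <= p_success <= 1.0:
        raise ValueError("p_success must lie in [0, 1]")
    stimes = [t for _, t, _ in schedule]
    if any(b < a for a, b in zip(stimes, stimes[1:])):
        raise ValueError("schedule must be sorted by time")
    rng = np.random.default_rng(rng)
    state: dict[str, np.ndarray] = {}
    events: list[ChoiceEvent] = []
    for ind, t, site in schedule:
        if ind == UNMARKED:
            if unmarked_p is None:
                p0 = 1.0 / len(OPTIONS)
            elif isinstance(unmarked_p, Mapping):
                p0 = unmarked_p.get(t, 1.0 / len(OPTIONS))
            else:
                p0 = float(unmarked_p)
            prob = np.full(len(OPTIONS), (1.0 - p0) / (len(OPTIONS) - 1))
            prob[0] = p0
        else:
            p = param_table.loc[ind]
            if ind not in state:
                state[ind] = initial_attractions(roster.get(ind))
            i_comp = individual_probs(state[ind], float(p["lambda"]))
            if strategy == "individual":
                prob = i_comp
            else:
                tally = tally_social_window(
                    events, ind, t, site, window=window,
                    attributes=roster, demos=demos,
                )
                s_comp = social_probs_for_strategy(
                    tally, strategy,
                    f=float(p["f"]) if "f" in p else 1.0,
                    beta=float(p["beta"]) if "beta" in p else 0.0,
                )
                prob = choice_probability(i_comp, s_comp, float(p["gamma"]))
        k = int(rng.choice(len(OPTIONS), p=prob))
        payoff = int(rng.random() < p_success)
        events.append(ChoiceEvent(ind, t, site, OPTIONS[k], payoff))
        if ind != UNMARKED:
            state[ind][k] = update_attraction(
                state[ind][k], payoff, float(param_table.loc[ind]["phi"])
            )
    return events
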