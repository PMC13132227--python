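"""Order-of-acquisition diffusion analysis (OADA).

Network-based diffusion analysis asks whether the order in which naive
individuals acquire a behaviour follows the social network.  In the
order-of-acquisition variant the baseline asocial rate cancels from the
likelihood, so each acquisition event contributes the probability that the
observed learner, rather than any other naive individual at risk, was next:

    R_i = exp(G . x_i) * s * sum_j a_ij z_j  +  exp(B . x_i)

with ``s`` the social transmission rate per unit of network connection,
``a_ij`` the association strength, ``z_j`` the informed status of j, and
``x_i`` individual-level variables (ILVs) allowed to act independently on
the social (G) and asocial (B) rates ("unconstrained" models).  Multiple
diffusions (one per experimental site) multiply their likelihoods.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import Individual
from .network import AssociationNetwork

SEX_CODE = {"female": -0.5, "male": 0.5, "unknown": 0.0}
AGE_CODE = {"juvenile": -0.5, "adult": 0.5, "unknown": 0.0}


@dataclass(frozen=True)
class Diffusion:
    """One site's diffusion: the observed acquisition order and who was at risk."""

    site: str
    learners: tuple[str, ...]
    risk_set: frozenset[str]
    seeded_informed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not set(self.learners) <= self.risk_set:
            missing = sorted(set(self.learners) - self.risk_set)
            raise ValueError(
                f"diffusion at {self.site!r}: learners {missing} not in risk set"
            )
        if set(self.learners) & set(self.seeded_informed):
            clash = sorted(set(self.learners) & set(self.seeded_informed))
            raise ValueError(
                f"diffusion at {self.site!r}: seeded individuals {clash} "
                "recorded as learners"
            )
        if len(set(self.learners)) != len(self.learners):
            raise ValueError(f"diffusion at {self.site!r}: repeated learner")


@dataclass(frozen=True)
class DiffusionRecord:
    diffusions: tuple[Diffusion, ...]

    @property
    def n_events(self) -> int:
        return sum(len(d.learners) for d in self.diffusions)


class ILVDesign:
    """Per-individual covariates modulating learning rates.

    Sex is coded -0.5 (female) / 0.5 (male) / 0 (unknown) and age -0.5
    (juvenile) / 0.5 (adult) / 0 (unknown); missing individuals code as 0.
    """

    CODES = (-0.5, 0.0, 0.5)

    def __init__(self, table: pd.DataFrame):
        bad = ~table.isin(self.CODES).all(axis=None)
        if bad:
            raise ValueError("ILV codes restricted to {-0.5, 0, 0.5}")
        self.table = table.astype(float)

    @classmethod
    def from_individuals(cls, individuals: Iterable[Individual]) -> "ILVDesign":
        rows = {
            ind.id: {"sex": SEX_CODE[ind.sex_class], "age": AGE_CODE[ind.age_class]}
            for ind in individuals
        }
        return cls(pd.DataFrame.from_dict(rows, orient="index"))

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.table.columns)

    def value(self, individual: str, column: str) -> float:
        if individual in self.table.index:
            return float(self.table.loc[individual, column])
        return 0.0


EMPTY_ILVS = ILVDesign(pd.DataFrame(columns=["sex", "age"]))


@dataclass(frozen=True)
class NBDAParameters:
    """s >= 0 plus named ILV coefficients on the social (gamma) and asocial
    (beta) rates; the asocial baseline is the unit rate."""

    s: float = 0.0
    gamma: Mapping[str, float] = field(default_factory=dict)
    beta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("social transmission rate s must be >= 0")


@dataclass(frozen=True)
class ModelSpec:
    """Which terms a fitted OADA model includes."""

    social: bool = True
    social_ilvs: tuple[str, ...] = ()
    asocial_ilvs: tuple[str, ...] = ()

    @property
    def name(self) -> str:
        parts = ["social" if self.social else "asocial"]
        if self.social_ilvs:
            parts.append("s:" + "+".join(self.social_ilvs))
        if self.asocial_ilvs:
            parts.append("a:" + "+".join(self.asocial_ilvs))
        return "|".join(parts)

    @property
    def k(self) -> int:
        k = len(self.asocial_ilvs)
        if self.social:
            k += 1 + len(self.social_ilvs)
        return k


@dataclass
class NBDAFit:
    spec: ModelSpec
    params: NBDAParameters
    log_likelihood: float
    k: int
    converged: bool
    n_events: int
    aicc: float | None = None
    akaike_weight: float | None = None


def _linear_predictor(
    ids: Sequence[str], coefs: Mapping[str, float], ilvs: ILVDesign
) -> np.ndarray:
    lp = np.zeros(len(ids))
    for col, coef in coefs.items():
        lp += coef * np.array([ilvs.value(i, col) for i in ids])
    return lp


def _event_rates(
    ids: Sequence[str],
    informed: np.ndarray,
    sub_net: np.ndarray,
    params: NBDAParameters,
    ilvs: ILVDesign,
) -> np.ndarray:
    """Acquisition rate for every individual given current informed status."""
    social_mult = np.exp(_linear_predictor(ids, params.gamma, ilvs))
    asocial_mult = np.exp(_linear_predictor(ids, params.beta, ilvs))
    connection = sub_net @ informed.astype(float)
    return social_mult * params.s * connection + asocial_mult


def oada_negloglik(
    record: DiffusionRecord,
    net: AssociationNetwork,
    params: NBDAParameters,
    ilvs: ILVDesign = EMPTY_ILVS,
) -> float:
    """Negative log-likelihood of the observed acquisition orders.

    Informed status updates after every event; seeded demonstrators are
    informed from the start and contribute social connection but no events.
    """
    nll = 0.0
    for diff in record.diffusions:
        ids = sorted(diff.risk_set | set(diff.seeded_informed))
        index = {i: k for k, i in enumerate(ids)}
        sub = net.submatrix(ids)
        informed = np.array([i in diff.seeded_informed for i in ids])
        at_risk = np.array([i in diff.risk_set for i in ids])
        social_mult = np.exp(_linear_predictor(ids, params.gamma, ilvs))
        asocial_mult = np.exp(_linear_predictor(ids, params.beta, ilvs))
        connection = sub @ informed.astype(float)
        for event_no, learner in enumerate(diff.learners):
            if learner not in index or not at_risk[index[learner]]:
                raise ValueError(
                    f"diffusion at {diff.site!r}: learner {learner!r} "
                    "absent from risk set"
                )
            rates = social_mult * params.s * connection + asocial_mult
            naive = at_risk & ~informed
            denom = rates[naive].sum()
            if denom <= 0:
                raise ValueError(
                    f"diffusion at {diff.site!r}, event {event_no}: "
                    "all naive acquisition rates are zero"
                )
            nll -= math.log(rates[index[learner]] / denom)
            k = index[learner]
            informed[k] = True
            connection += sub[:, k]
    return float(nll)


def _pack(spec: ModelSpec, theta: np.ndarray) -> NBDAParameters:
    pos = 0
    s = 0.0
    gamma: dict[str, float] = {}
    if spec.social:
        s = math.exp(theta[pos])
        pos += 1
        for col in spec.social_ilvs:
            gamma[col] = theta[pos]
            pos += 1
    beta = {}
    for col in spec.asocial_ilvs:
        beta[col] = theta[pos]
        pos += 1
    return NBDAParameters(s=s, gamma=gamma, beta=beta)


# s is fitted on the log scale; these starting values bracket weak to very
# strong social transmission to escape boundary local optima.
_LOG_S_STARTS = (-2.0, 0.0, 1.0, 2.5, 4.0)


def fit_oada(
    record: DiffusionRecord,
    net: AssociationNetwork,
    spec: ModelSpec,
    ilvs: ILVDesign = EMPTY_ILVS,
) -> NBDAFit:
    """Maximum-likelihood OADA fit for one model specification.

    Deterministic multi-start L-BFGS on (log s, coefficients); the social
    transmission rate is log-parameterized so s >= 0 holds by construction.
    """
    n_events = record.n_events
    k = spec.k
    if k == 0:
        nll = oada_negloglik(record, net, NBDAParameters(), ilvs)
        return NBDAFit(spec, NBDAParameters(), -nll, 0, True, n_events)
    if n_events < k:
        import warnings

        warnings.warn(
            f"model {spec.name!r}: {n_events} events for {k} free parameters",
            stacklevel=2,
        )

    def objective(theta: np.ndarray) -> float:
        # log s bounded numerically: beyond e^15 the likelihood is flat
        # (the asocial term has vanished), so nothing is lost
        if spec.social and abs(theta[0]) > 15.0:
            return np.inf
        try:
            return oada_negloglik(record, net, _pack(spec, theta), ilvs)
        except (OverflowError, FloatingPointError):
            return np.inf

    best = None
    starts = _LOG_S_STARTS if spec.social else (0.0,)
    for start in starts:
        theta0 = np.zeros(k)
        if spec.social:
            theta0[0] = start
        res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9,
                                         "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    return NBDAFit(
        spec=spec,
        params=_pack(spec, best.x),
        log_likelihood=-float(best.fun),
        k=k,
        converged=bool(best.success),
        n_events=n_events,
    )


def all_model_specs(ilv_columns: Sequence[str] = ("sex", "age")) -> list[ModelSpec]:
    """Every combination of ILVs on each rate, with and without the network."""
    specs = []
    subsets = [
        tuple(c) for r in range(len(ilv_columns) + 1)
        for c in itertools.combinations(ilv_columns, r)
    ]
    for asoc in subsets:
        specs.append(ModelSpec(social=False, asocial_ilvs=asoc))
        for soc in subsets:
            specs.append(ModelSpec(social=True, social_ilvs=soc,
                                   asocial_ilvs=asoc))
    return specs


def aicc_model_table(fits: Sequence[NBDAFit], n_events: int | None = None) -> pd.DataFrame:
    """Rank fitted models by AICc and attach Akaike weights.

    AICc = 2k - 2 lnL + 2k(k+1)/(n-k-1) with n the total number of
    acquisition events.  The returned frame also carries each model's family
    so social-vs-asocial support can be summed.
    """
    if not fits:
        raise ValueError("no fits supplied")
    n = n_events if n_events is not None else fits[0].n_events
    if any(f.n_events != fits[0].n_events for f in fits):
        raise ValueError("fits compare different data (n_events differ)")
    rows = []
    for fit in fits:
        if n <= fit.k + 1:
            raise ValueError(
                f"AICc undefined for model {fit.spec.name!r}: "
                f"n={n} <= k+1={fit.k + 1}"
            )
        aicc = (2 * fit.k - 2 * fit.log_likelihood
                + 2 * fit.k * (fit.k + 1) / (n - fit.k - 1))
        fit.aicc = aicc
        rows.append(
            {
                "model": fit.spec.name,
                "family": "social" if fit.spec.social else "asocial",
                "k": fit.k,
                "log_likelihood": fit.log_likelihood,
                "aicc": aicc,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    rel = np.exp(-table["delta_aicc"] / 2)
    table["akaike_weight"] = rel / rel.sum()
    weight_by_model = dict(zip(table["model"], table["akaike_weight"]))
    for fit in fits:
        fit.akaike_weight = float(weight_by_model[fit.spec.name])
    return table


def family_support(table: pd.DataFrame) -> dict[str, float]:
    """Summed Akaike weight for the social and asocial model families."""
    return table.groupby("family")["akaike_weight"].sum().to_dict()


def _event_social_fractions(
    record: DiffusionRecord,
    net: AssociationNetwork,
    params: NBDAParameters,
    ilvs: ILVDesign,
) -> np.ndarray:
    """Per learning event: social share of the actual learner's rate."""
    fractions = []
    for diff in record.diffusions:
        ids = sorted(diff.risk_set | set(diff.seeded_informed))
        index = {i: k for k, i in enumerate(ids)}
        sub = net.submatrix(ids)
        informed = np.array([i in diff.seeded_informed for i in ids])
        for learner in diff.learners:
            i = index[learner]
            social = (
                math.exp(sum(params.gamma.get(c, 0.0) * ilvs.value(learner, c)
                             for c in params.gamma))
                * params.s
                * float(sub[i] @ informed.astype(float))
            )
            asocial = math.exp(
                sum(params.beta.get(c, 0.0) * ilvs.value(learner, c)
                    for c in params.beta)
            )
            fractions.append(social / (social + asocial))
            informed[i] = True
    return np.array(fractions)


def percent_social(
    fit: NBDAFit,
    record: DiffusionRecord,
    net: AssociationNetwork,
    ilvs: ILVDesign = EMPTY_ILVS,
    ci_level: float = 0.95,
) -> dict:
    """Estimated percentage of learning events due to social transmission.

    The point estimate averages, over the observed events, the social share
    of the learner's own acquisition rate.  The interval comes from a profile
    likelihood over s: the mean is re-evaluated at the values of s where the
    profile deviance crosses the chi-square(1) cutoff, re-optimizing any
    other coefficients.
    """
    if not fit.spec.social:
        raise ValueError("percent_social requires a fitted social model")
    est = 100.0 * _event_social_fractions(record, net, fit.params, ilvs).mean()

    from scipy.stats import chi2

    target = -fit.log_likelihood + chi2.ppf(ci_level, df=1) / 2
    other_cols = list(fit.spec.social_ilvs) + list(fit.spec.asocial_ilvs)

    def profile_nll(log_s: float) -> tuple[float, NBDAParameters]:
        def build(coefs: np.ndarray) -> NBDAParameters:
            n_soc = len(fit.spec.social_ilvs)
            return NBDAParameters(
                s=math.exp(log_s),
                gamma=dict(zip(fit.spec.social_ilvs, coefs[:n_soc])),
                beta=dict(zip(fit.spec.asocial_ilvs, coefs[n_soc:])),
            )

        if not other_cols:
            p = build(np.array([]))
            return oada_negloglik(record, net, p, ilvs), p
        res = optimize.minimize(
            lambda c: oada_negloglik(record, net, build(c), ilvs),
            np.zeros(len(other_cols)),
            method="Nelder-Mead",
        )
        return float(res.fun), build(res.x)

    log_s_hat = min(math.log(max(fit.params.s, 1e-12)), 15.0)

    def crossing(direction: float) -> NBDAParameters:
        step, log_s = 0.5, log_s_hat
        nll, params = profile_nll(log_s)
        lo, hi = log_s, log_s
        for _ in range(60):
            log_s += direction * step
            nll, params = profile_nll(log_s)
            if nll >= target:
                hi = log_s
                lo = log_s - direction * step
                break
        else:  # profile never crosses: s unbounded in this direction
            return params
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            nll, params = profile_nll(mid)
            if nll >= target:
                hi = mid
            else:
                lo = mid
            if abs(hi - lo) < 1e-4:
                break
        _, params = profile_nll(0.5 * (lo + hi))
        return params

    lo_params = crossing(-1.0)
    hi_params = crossing(+1.0)
    ci = sorted(
        100.0 * _event_social_fractions(record, net, p, ilvs).mean()
        for p in (lo_params, hi_params)
    )
    return {"estimate": est, "ci": tuple(ci), "ci_level": ci_level}


def simulate_diffusion(
    net: AssociationNetwork,
    params: NBDAParameters,
    risk_set: Iterable[str],
    seeded_informed: Iterable[str] = (),
    ilvs: ILVDesign = EMPTY_ILVS,
    site: str = "sim",
    n_events: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> Diffusion:
    """Generative mirror of the OADA likelihood.

    Samples learners sequentially with probability proportional to their
    acquisition rate until everyone is informed (or ``n_events`` reached).
    """
    rng = np.random.default_rng(rng)
    risk = sorted(set(risk_set))
    seeded = frozenset(seeded_informed)
    if not risk:
        raise ValueError("empty risk set")
    if not seeded <= set(risk) | seeded:
        raise ValueError("seeded individuals must be known")
    ids = sorted(set(risk) | seeded)
    index = {i: k for k, i in enumerate(ids)}
    sub = net.submatrix(ids)
    informed = np.array([i in seeded for i in ids])
    at_risk = np.array([(i in set(risk)) and (i not in seeded) for i in ids])
    learners: list[str] = []
    max_events = n_events if n_events is not None else at_risk.sum()
    while len(learners) < max_events:
        naive = at_risk & ~informed
        if not naive.any():
            break
        rates = _event_rates(ids, informed, sub, params, ilvs)
        probs = np.where(naive, rates, 0.0)
        total = probs.sum()
        if total <= 0:
            raise ValueError("all naive acquisition rates are zero")
        choice = rng.choice(len(ids), p=probs / total)
        learners.append(ids[choice])
        informed[choice] = True
    return Diffusion(
        site=site,
        learners=tuple(learners),
        risk_set=frozenset(risk) - seeded,
        seeded_informed=seeded,
    )
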