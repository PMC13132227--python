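"""Hierarchical Bayesian fitting of the EWA strategy models.

Each learning parameter (lambda, phi, gamma, and f or beta depending on the
strategy) gets a group-level mean per (age class x sex class) cell plus a
varying individual effect, on a link scale:

    log(lambda_j)  = a_lambda[age_j, sex_j] + sigma_lambda * z_lambda,j
    logit(phi_j)   = a_phi[age_j, sex_j]    + sigma_phi * z_phi,j
    logit(gamma_j) = ...
    log(f_j)       = ...
    beta_j         = ...   (identity link)

with weakly informative priors a ~ Normal(0, 1), z ~ Normal(0, 1) and
sigma ~ Exponential(1) in a non-centered parameterization.  The posterior is
sampled with Hamiltonian Monte Carlo using analytic gradients of the EWA
likelihood (numba-compiled recursion over each bird's choice sequence);
step size adapts by dual averaging and a diagonal mass matrix is estimated
during warmup.  Convergence is summarized with arviz R-hat and effective
sample sizes.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .datatypes import OPTIONS, UNMARKED, ChoiceEvent, Individual
from .ewa import STRATEGY_PARAMS, ewa_loglik, initial_attractions, tally_social_window

K_OPT = len(OPTIONS)

_STRATEGY_CODE = {"individual": 0, "frequency": 1, "male_bias": 2,
                  "age_bias": 3, "roost_bias": 4}
#: link per parameter: 0 = log, 1 = logit, 2 = identity
_LINKS = {"lambda": 0, "phi": 1, "gamma": 1, "f": 0, "beta": 2}


# --------------------------------------------------------------------------
# data preparation (parameter-free, shared by all strategy models)

@dataclass
class ChoiceData:
    """Choice sequences and pre-tallied social windows, padded per individual."""

    ids: list[str]
    cells: list[tuple[str, str]]            # distinct (age, sex) cells present
    cell_index: np.ndarray                  # (n_ind,) index into cells
    lengths: np.ndarray                     # (n_ind,) events per individual
    choice: np.ndarray                      # (n_ind, T) option index
    payoff: np.ndarray                      # (n_ind, T)
    counts: dict[str, np.ndarray]           # each (n_ind, T, K)
    init_attr: np.ndarray                   # (n_ind, K)

    @property
    def n_events(self) -> int:
        return int(self.lengths.sum())

    def social_arrays(self, strategy: str) -> tuple[np.ndarray, np.ndarray]:
        zeros = np.zeros_like(self.counts["total"])
        if strategy == "individual":
            return zeros, zeros
        if strategy == "frequency":
            return self.counts["total"], zeros
        if strategy == "male_bias":
            return self.counts["male"], zeros
        if strategy == "age_bias":
            return self.counts["adult"], zeros
        if strategy == "roost_bias":
            return self.counts["same_roost"], self.counts["other_roost"]
        raise ValueError(f"unknown strategy {strategy!r}")


def prepare_choice_data(
    events: Sequence[ChoiceEvent],
    roster: Mapping[str, Individual],
    window: float = 60.0,
    demos: str = "all",
) -> ChoiceData:
    """Tally each marked bird's social window once and pad into arrays.

    The window tallies depend only on the data, so all five strategy models
    share this preparation.  Events are ordered by individual (then time)
    for the pointwise likelihood partition used by WAIC.
    """
    events = list(events)
    times = [e.time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("events must be sorted by time")
    per_ind: dict[str, list[ChoiceEvent]] = {}
    for e in events:
        if e.individual == UNMARKED:
            continue
        if e.individual not in roster:
            raise ValueError(f"marked individual {e.individual!r} not in roster")
        per_ind.setdefault(e.individual, []).append(e)
    if not per_ind:
        raise ValueError("no marked choosers in the event stream")

    ids = sorted(per_ind)
    cells = sorted({(roster[i].age_class, roster[i].sex_class) for i in ids})
    cell_of = {c: k for k, c in enumerate(cells)}
    n = len(ids)
    lengths = np.array([len(per_ind[i]) for i in ids], dtype=np.int64)
    t_max = int(lengths.max())
    choice = np.zeros((n, t_max), dtype=np.int64)
    payoff = np.zeros((n, t_max))
    counts = {key: np.zeros((n, t_max, K_OPT))
              for key in ("total", "male", "adult", "same_roost", "other_roost")}
    init_attr = np.zeros((n, K_OPT))
    cell_index = np.zeros(n, dtype=np.int64)
    for j, ind in enumerate(ids):
        cell_index[j] = cell_of[(roster[ind].age_class, roster[ind].sex_class)]
        init_attr[j] = initial_attractions(roster[ind])
        for t, e in enumerate(per_ind[ind]):
            choice[j, t] = OPTIONS.index(e.option)
            payoff[j, t] = e.payoff
            tally = tally_social_window(
                events, ind, e.time, e.site, window=window,
                attributes=roster, demos=demos,
            )
            counts["total"][j, t] = tally.total
            counts["male"][j, t] = tally.male
            counts["adult"][j, t] = tally.adult
            counts["same_roost"][j, t] = tally.same_roost
            counts["other_roost"][j, t] = tally.other_roost
    return ChoiceData(ids, cells, cell_index, lengths, choice, payoff,
                      counts, init_attr)


# --------------------------------------------------------------------------
# numba likelihood kernels

@njit(cache=True)
def _ewa_ll_grad(lam, phi, gam, extra, strategy, lengths, choice, payoff,
                 soc_a, soc_b, init_attr):  # pragma: no cover - numba
    """Total log-likelihood and per-individual gradients.

    Gradient columns: d/d lambda, d/d phi, d/d gamma, d/d (f or beta).
    ``soc_a``/``soc_b`` carry the strategy's window counts (see
    ChoiceData.social_arrays).
    """
    n_ind, t_max = choice.shape
    k_opt = init_attr.shape[1]
    ll = 0.0
    grad = np.zeros((n_ind, 4))
    for j in range(n_ind):
        a = init_attr[j].copy()
        da = np.zeros(k_opt)                  # dA/dphi
        lj, pj, gj, xj = lam[j], phi[j], gam[j], extra[j]
        for t in range(lengths[j]):
            # individual component: softmax(lam * A)
            m = lj * a[0]
            for k in range(1, k_opt):
                if lj * a[k] > m:
                    m = lj * a[k]
            zsum = 0.0
            iprob = np.empty(k_opt)
            for k in range(k_opt):
                iprob[k] = math.exp(lj * a[k] - m)
                zsum += iprob[k]
            abar = 0.0
            dabar = 0.0
            for k in range(k_opt):
                iprob[k] /= zsum
                abar += iprob[k] * a[k]
                dabar += iprob[k] * da[k]

            # social component
            have_s = False
            s = np.zeros(k_opt)
            ds = np.zeros(k_opt)              # d/d f or d/d beta
            if strategy == 1:                 # frequency: N^f
                tot = 0.0
                for k in range(k_opt):
                    tot += soc_a[j, t, k]
                if tot > 0.0:
                    have_s = True
                    wsum = 0.0
                    for k in range(k_opt):
                        if soc_a[j, t, k] > 0.0:
                            s[k] = math.exp(min(xj * math.log(soc_a[j, t, k]),
                                                60.0))
                            wsum += s[k]
                    slog = 0.0
                    for k in range(k_opt):
                        s[k] /= wsum
                        if soc_a[j, t, k] > 0.0:
                            slog += s[k] * math.log(soc_a[j, t, k])
                    for k in range(k_opt):
                        if soc_a[j, t, k] > 0.0:
                            ds[k] = s[k] * (math.log(soc_a[j, t, k]) - slog)
            elif strategy == 2 or strategy == 3:   # category counts, f = 1
                tot = 0.0
                for k in range(k_opt):
                    tot += soc_a[j, t, k]
                if tot > 0.0:
                    have_s = True
                    for k in range(k_opt):
                        s[k] = soc_a[j, t, k] / tot
            elif strategy == 4:               # roost cue: other + e^b * same
                eb = math.exp(xj)
                wsum = 0.0
                dwsum = 0.0
                w = np.empty(k_opt)
                dw = np.empty(k_opt)
                for k in range(k_opt):
                    w[k] = soc_b[j, t, k] + eb * soc_a[j, t, k]
                    dw[k] = eb * soc_a[j, t, k]
                    wsum += w[k]
                    dwsum += dw[k]
                if wsum > 0.0:
                    have_s = True
                    for k in range(k_opt):
                        s[k] = w[k] / wsum
                        ds[k] = (dw[k] - s[k] * dwsum) / wsum

            c = choice[j, t]
            if have_s:
                pc = (1.0 - gj) * iprob[c] + gj * s[c]
            else:
                pc = iprob[c]
            if pc < 1e-12:
                pc = 1e-12
                ll += math.log(pc)
            else:
                ll += math.log(pc)
                wi = (1.0 - gj) if have_s else 1.0
                grad[j, 0] += wi * iprob[c] * (a[c] - abar) / pc
                grad[j, 1] += wi * lj * iprob[c] * (da[c] - dabar) / pc
                if have_s:
                    grad[j, 2] += (s[c] - iprob[c]) / pc
                    grad[j, 3] += gj * ds[c] / pc

            # attraction update for the chosen option
            old = a[c]
            a[c] = (1.0 - pj) * old + pj * payoff[j, t]
            da[c] = (1.0 - pj) * da[c] + (payoff[j, t] - old)
    return ll, grad


@njit(cache=True)
def _ewa_pointwise(lam, phi, gam, extra, strategy, lengths, choice, payoff,
                   soc_a, soc_b, init_attr, out):  # pragma: no cover - numba
    """Pointwise log-likelihood in (individual, event) order, into ``out``."""
    n_ind, t_max = choice.shape
    k_opt = init_attr.shape[1]
    pos = 0
    for j in range(n_ind):
        a = init_attr[j].copy()
        lj, pj, gj, xj = lam[j], phi[j], gam[j], extra[j]
        for t in range(lengths[j]):
            m = lj * a[0]
            for k in range(1, k_opt):
                if lj * a[k] > m:
                    m = lj * a[k]
            zsum = 0.0
            iprob = np.empty(k_opt)
            for k in range(k_opt):
                iprob[k] = math.exp(lj * a[k] - m)
                zsum += iprob[k]
            for k in range(k_opt):
                iprob[k] /= zsum
            have_s = False
            s = np.zeros(k_opt)
            if strategy == 1:
                tot = 0.0
                for k in range(k_opt):
                    tot += soc_a[j, t, k]
                if tot > 0.0:
                    have_s = True
                    wsum = 0.0
                    for k in range(k_opt):
                        if soc_a[j, t, k] > 0.0:
                            s[k] = math.exp(min(xj * math.log(soc_a[j, t, k]),
                                                60.0))
                            wsum += s[k]
                    for k in range(k_opt):
                        s[k] /= wsum
            elif strategy == 2 or strategy == 3:
                tot = 0.0
                for k in range(k_opt):
                    tot += soc_a[j, t, k]
                if tot > 0.0:
                    have_s = True
                    for k in range(k_opt):
                        s[k] = soc_a[j, t, k] / tot
            elif strategy == 4:
                eb = math.exp(xj)
                wsum = 0.0
                w = np.empty(k_opt)
                for k in range(k_opt):
                    w[k] = soc_b[j, t, k] + eb * soc_a[j, t, k]
                    wsum += w[k]
                if wsum > 0.0:
                    have_s = True
                    for k in range(k_opt):
                        s[k] = w[k] / wsum
            c = choice[j, t]
            if have_s:
                pc = (1.0 - gj) * iprob[c] + gj * s[c]
            else:
                pc = iprob[c]
            if pc < 1e-12:
                pc = 1e-12
            out[pos] = math.log(pc)
            pos += 1
            a[c] = (1.0 - pj) * a[c] + pj * payoff[j, t]
    return out


# --------------------------------------------------------------------------
# hierarchical posterior

@dataclass
class FitConfig:
    """Sampler settings.  The default is the reduced schedule (2 chains of
    500 warmup + 500 sampling); the full 4 x 1000/1000 schedule is a config
    away."""

    chains: int = 2
    warmup: int = 500
    samples: int = 500
    seed: int = 0
    max_leapfrog: int = 30
    target_accept: float = 0.75
    prior_mean_scale: float = 1.0     # sd of Normal prior on cell means
    prior_sigma_rate: float = 1.0     # rate of Exponential prior on sigmas


class HierarchicalEWA:
    """Log posterior (and gradient) over the hierarchical parameter vector.

    Layout of theta: cell means a (n_cells x P, row-major), log sigmas (P),
    and an individual block (n_ind x P).  Parameters in ``centered_names``
    use a centered parameterization — the individual block holds the
    link-scale value eta_jp directly, with prior Normal(a_cell, sigma);
    the rest are non-centered — the block holds standardized offsets z with
    eta = a_cell + sigma * z.  The sampler interweaves updates under both
    parameterizations, which keeps mixing healthy whether the per-bird
    likelihood is informative (lambda, phi) or weak (gamma, f, beta).
    """

    CENTERED = ("lambda", "phi")

    def __init__(self, data: ChoiceData, strategy: str,
                 config: FitConfig | None = None, prior_only: bool = False,
                 centered_names: tuple[str, ...] | None = None):
        if strategy not in STRATEGY_PARAMS:
            raise ValueError(f"unknown strategy {strategy!r}")
        self.data = data
        self.strategy = strategy
        self.config = config or FitConfig()
        self.prior_only = prior_only
        self.param_names = STRATEGY_PARAMS[strategy]
        self.links = np.array([_LINKS[p] for p in self.param_names])
        self.n_cells = len(data.cells)
        self.n_ind = len(data.ids)
        self.P = len(self.param_names)
        self.code = _STRATEGY_CODE[strategy]
        self.soc_a, self.soc_b = data.social_arrays(strategy)
        if centered_names is None:
            centered_names = self.CENTERED
        self.centered = np.array(
            [p in centered_names for p in self.param_names])
        self.n_hyper = self.n_cells * self.P + self.P
        self.ndim = self.n_hyper + self.n_ind * self.P

    # -- theta <-> natural-scale individual parameters ---------------------
    def _split(self, theta: np.ndarray):
        ncp = self.n_cells * self.P
        a = theta[:ncp].reshape(self.n_cells, self.P)
        log_sig = theta[ncp:ncp + self.P]
        z = theta[ncp + self.P:].reshape(self.n_ind, self.P)
        return a, log_sig, z

    def _eta(self, a, log_sig, z) -> np.ndarray:
        sig = np.exp(np.clip(log_sig, -7.0, 7.0))
        eta = np.where(self.centered, z,
                       a[self.data.cell_index] + sig * z)
        return eta

    def individual_values(self, theta: np.ndarray) -> np.ndarray:
        """(n_ind, P) natural-scale parameter values."""
        a, log_sig, z = self._split(theta)
        return self._inv_link(self._eta(a, log_sig, z))

    def _inv_link(self, eta: np.ndarray) -> np.ndarray:
        out = np.empty_like(eta)
        for p, link in enumerate(self.links):
            e = np.clip(eta[..., p], -30.0, 30.0)
            if link == 0:
                out[..., p] = np.exp(e)
            elif link == 1:
                out[..., p] = np.where(
                    e >= 0, 1.0 / (1.0 + np.exp(-e)),
                    np.exp(e) / (1.0 + np.exp(e)),
                )
            else:
                out[..., p] = eta[..., p]
        return out

    def _kernel_args(self, values: np.ndarray):
        lam = np.ascontiguousarray(values[:, self.param_names.index("lambda")])
        phi = np.ascontiguousarray(values[:, self.param_names.index("phi")])
        if "gamma" in self.param_names:
            gam = np.ascontiguousarray(values[:, self.param_names.index("gamma")])
        else:
            gam = np.zeros(self.n_ind)
        if "f" in self.param_names:
            extra = np.ascontiguousarray(values[:, self.param_names.index("f")])
        elif "beta" in self.param_names:
            extra = np.ascontiguousarray(values[:, self.param_names.index("beta")])
        else:
            extra = np.zeros(self.n_ind)
        return lam, phi, gam, extra

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        a, log_sig, z = self._split(theta)
        sig = np.exp(np.clip(log_sig, -7.0, 7.0))
        eta = self._eta(a, log_sig, z)
        values = self._inv_link(eta)

        if self.prior_only:
            ll, grad_nat = 0.0, np.zeros((self.n_ind, 4))
        else:
            lam, phi, gam, extra = self._kernel_args(values)
            ll, grad_nat = _ewa_ll_grad(
                lam, phi, gam, extra, self.code, self.data.lengths,
                self.data.choice, self.data.payoff, self.soc_a, self.soc_b,
                self.data.init_attr,
            )
        # map kernel gradient columns onto this strategy's parameters and
        # chain through the inverse links to the eta scale
        kernel_col = {"lambda": 0, "phi": 1, "gamma": 2, "f": 3, "beta": 3}
        dll_deta = np.zeros((self.n_ind, self.P))
        for p, name in enumerate(self.param_names):
            g = grad_nat[:, kernel_col[name]]
            link = self.links[p]
            if link == 0:
                dll_deta[:, p] = g * values[:, p]
            elif link == 1:
                dll_deta[:, p] = g * values[:, p] * (1.0 - values[:, p])
            else:
                dll_deta[:, p] = g

        s_mean = self.config.prior_mean_scale
        rate = self.config.prior_sigma_rate
        a_cell = a[self.data.cell_index]
        resid = eta - a_cell                      # centered params only
        cen, non = self.centered, ~self.centered

        lp = ll - 0.5 * float(((a / s_mean) ** 2).sum()) \
            + float((-rate * sig + log_sig).sum())
        # non-centered block: z ~ N(0, 1)
        lp -= 0.5 * float((z[:, non] ** 2).sum())
        # centered block: eta ~ N(a_cell, sigma)
        lp -= float((np.log(sig[cen]).sum()) * self.n_ind)
        lp -= 0.5 * float(((resid[:, cen] / sig[cen]) ** 2).sum())

        grad_a = np.zeros_like(a)
        grad_z = np.zeros_like(z)
        grad_logsig = np.zeros(self.P)
        # likelihood part
        contrib_a = np.where(non, dll_deta, 0.0)
        np.add.at(grad_a, self.data.cell_index, contrib_a)
        grad_z[:, non] = (dll_deta * sig)[:, non]
        grad_logsig[non] = ((dll_deta * z).sum(axis=0) * sig)[non]
        grad_z[:, cen] = dll_deta[:, cen]
        # prior part
        grad_a -= a / s_mean ** 2
        grad_z[:, non] -= z[:, non]
        grad_z[:, cen] -= (resid / sig ** 2)[:, cen]
        prior_a = np.zeros_like(a)
        np.add.at(prior_a, self.data.cell_index,
                  np.where(cen, resid / sig ** 2, 0.0))
        grad_a += prior_a
        grad_logsig[cen] += ((resid ** 2) / sig ** 2).sum(axis=0)[cen] \
            - self.n_ind
        grad_logsig += -rate * sig + 1.0
        grad = np.concatenate([grad_a.ravel(), grad_logsig, grad_z.ravel()])
        if not (np.isfinite(lp) and np.isfinite(grad).all()):
            return -np.inf, np.zeros_like(grad)
        return lp, grad


# --------------------------------------------------------------------------
# Hamiltonian Monte Carlo

def _fresh_da(step0):
    return {"step": step0, "log_step": math.log(step0),
            "log_step_bar": math.log(step0), "m": 0}


def _da_update(da, alpha, target_accept, kappa=0.6, cap=0.25):
    """Damped Robbins-Monro step-size control.

    Per-iteration changes are capped so a single hard rejection (a
    divergence registers as alpha = 0) cannot crash the step size; the
    sampling step is the running average of the last adaptation stretch.
    """
    da["m"] += 1
    gain = min(cap, 1.0 / da["m"] ** kappa)
    da["log_step"] += gain * (alpha - target_accept)
    da["step"] = math.exp(da["log_step"])
    w = min(0.05, 2.0 / da["m"])
    da["log_step_bar"] = (1 - w) * da["log_step_bar"] + w * da["log_step"]


def _hmc_update(logp_grad, theta, idx, rng, step, inv_mass, max_leapfrog):
    """One HMC proposal on the coordinates ``idx``, others held fixed.

    Returns (theta, alpha, diverged); ``theta`` is the (possibly unchanged)
    state after the accept/reject step.
    """
    lp, grad = logp_grad(theta)
    r0 = rng.normal(size=len(idx)) / np.sqrt(inv_mass)
    # jitter trajectory length mildly; very short trajectories degrade to a
    # random walk in the flat directions
    n_leap = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
    th, g = theta.copy(), grad
    r = r0 + 0.5 * step * g[idx]
    lp_new = lp
    diverged = False
    for leap in range(n_leap):
        th[idx] = th[idx] + step * inv_mass * r
        lp_new, g = logp_grad(th)
        if not np.isfinite(lp_new) or not np.isfinite(g).all():
            diverged = True
            break
        r = r + (step if leap < n_leap - 1 else 0.5 * step) * g[idx]
    if diverged:
        return theta, 0.0, True
    h0 = lp - 0.5 * float(r0 * inv_mass @ r0)
    h1 = lp_new - 0.5 * float(r * inv_mass @ r)
    alpha = min(1.0, math.exp(min(h1 - h0, 0.0)))
    if h1 - h0 < -1000:
        return theta, 0.0, True
    if rng.random() < alpha:
        return th, alpha, False
    return theta, alpha, False


def _diag_curvature(logp_grad, theta, idx, eps=1e-4):
    """Negative diagonal Hessian of log p on coordinates ``idx``.

    One-sided gradient differences; a Gaussian direction with sd s yields
    1/s^2 regardless of how far the chain has mixed, which makes this a
    much more reliable warmup metric than sample variances of a
    slowly-moving chain.
    """
    _, g0 = logp_grad(theta)
    h = np.empty(len(idx))
    for k, i in enumerate(idx):
        th = theta.copy()
        th[i] += eps
        _, g1 = logp_grad(th)
        h[k] = -(g1[i] - g0[i]) / eps
    return h


def _curvature_mass(logp_grad, theta, idx):
    # priors bound every marginal sd at O(1), so curvature below ~0.25
    # reflects a local ridge, not a genuinely wide direction; flooring it
    # keeps flat-f excursions from blowing up the metric
    h = _diag_curvature(logp_grad, theta, idx)
    h = np.where(np.isfinite(h), h, 1.0)
    inv_mass = 1.0 / np.maximum(h, 0.25)
    return np.clip(inv_mass, 1e-4, 4.0)


def _map_estimate(post, init, maxiter=300):
    """Posterior mode via L-BFGS on the analytic gradient (chain warm start)."""
    from scipy import optimize

    def neg(th):
        lp, g = post.logp_grad(th)
        if not np.isfinite(lp):
            return 1e12, np.zeros_like(th)
        return -lp, -g

    res = optimize.minimize(neg, init, jac=True, method="L-BFGS-B",
                            options={"maxiter": maxiter})
    # a mode on a flat ridge (weakly identified f or beta) can sit at an
    # extreme; clip so chains start in the bulk the priors support
    return np.clip(res.x, -2.5, 2.5)


def _hmc_chain(post, post_nc, rng, warmup, samples, max_leapfrog,
               target_accept, init_theta=None, init_scale=0.1,
               masses=None):
    """One chain of interweaved blocked HMC over a hierarchical posterior.

    Each sweep performs three conditional updates: (1) the individual block
    under the mixed (centered/non-centered) parameterization, (2) the
    hyperparameter block under the same, and (3) the hyperparameter block
    again under the fully non-centered re-expression of the centered
    coordinates (ancillarity-sufficiency interweaving).  The third move
    decouples the cell means and scales from strongly informed individual
    parameters, whose conditional would otherwise pin them down and stall
    mixing.  Every update has its own dual-averaging step size; diagonal
    mass matrices are re-estimated in doubling windows during warmup.
    """
    ndim = post.ndim
    n_hyper = post.n_hyper
    hyper_idx = np.arange(n_hyper)
    ind_idx = np.arange(n_hyper, ndim)
    cen = post.centered
    n_cells, P = post.n_cells, post.P
    cell_index = post.data.cell_index

    def split(th):
        a = th[:n_cells * P].reshape(n_cells, P)
        log_sig = th[n_cells * P:n_hyper]
        z = th[n_hyper:].reshape(-1, P)
        return a, log_sig, z

    def to_nc(th):
        """Mixed -> fully non-centered coordinates (bijection, z shared)."""
        a, log_sig, z = split(th)
        sig = np.exp(np.clip(log_sig, -7.0, 7.0))
        z_nc = z.copy()
        z_nc[:, cen] = (z[:, cen] - a[cell_index][:, cen]) / sig[cen]
        out = th.copy()
        out[n_hyper:] = z_nc.ravel()
        return out

    def from_nc(th_nc):
        a, log_sig, z_nc = split(th_nc)
        sig = np.exp(np.clip(log_sig, -7.0, 7.0))
        z = z_nc.copy()
        z[:, cen] = a[cell_index][:, cen] + sig[cen] * z_nc[:, cen]
        out = th_nc.copy()
        out[n_hyper:] = z.ravel()
        return out

    theta = rng.normal(scale=init_scale, size=ndim)
    if init_theta is not None:
        theta = theta + init_theta
    # the individual block's conditional is well-scaled, so it gets a short
    # trajectory; the two hyper-block kernels alternate between sweeps
    updates = [
        {"idx": ind_idx, "logp": post.logp_grad, "da": _fresh_da(0.1),
         "inv_mass": np.ones(len(ind_idx)), "nc": False,
         "leapfrog": max(6, max_leapfrog // 3), "phase": None},
        {"idx": hyper_idx, "logp": post.logp_grad, "da": _fresh_da(0.1),
         "inv_mass": np.ones(n_hyper), "nc": False,
         "leapfrog": max_leapfrog, "phase": 0},
        {"idx": hyper_idx, "logp": post_nc.logp_grad, "da": _fresh_da(0.1),
         "inv_mass": np.ones(n_hyper), "nc": True,
         "leapfrog": max_leapfrog, "phase": 1},
    ]
    if masses is not None:
        for upd, m in zip(updates, masses):
            upd["inv_mass"] = m

    draws = np.empty((samples, ndim))
    accept_sum, attempt_count, divergences = 0.0, 0, 0
    # one metric refresh once the chain has settled (the initial metric
    # comes from the curvature at the posterior mode)
    mass_ends = {warmup // 2} if masses is not None else {
        max(10, warmup // 20), warmup // 4, warmup // 2, (3 * warmup) // 4}

    for it in range(warmup + samples):
        adapting = it < warmup
        for upd in updates:
            if upd["phase"] is not None and it % 2 != upd["phase"]:
                continue
            step = (upd["da"]["step"] if adapting
                    else math.exp(upd["da"]["log_step_bar"]))
            if upd["nc"]:
                th_nc = to_nc(theta)
                th_nc, alpha, div = _hmc_update(
                    upd["logp"], th_nc, upd["idx"], rng, step,
                    upd["inv_mass"], upd["leapfrog"])
                theta = from_nc(th_nc)
            else:
                theta, alpha, div = _hmc_update(
                    upd["logp"], theta, upd["idx"], rng, step,
                    upd["inv_mass"], upd["leapfrog"])
            if not adapting:
                divergences += int(div)
                accept_sum += alpha
                attempt_count += 1
            else:
                _da_update(upd["da"], alpha, target_accept)

        if adapting and it in mass_ends:
            th_nc = to_nc(theta)
            for upd in updates:
                th = th_nc if upd["nc"] else theta
                upd["inv_mass"] = _curvature_mass(upd["logp"], th,
                                                  upd["idx"])
                # re-adapt the step to the new metric; rescue a collapsed
                # step so one bad excursion cannot freeze the chain
                upd["da"] = _fresh_da(max(upd["da"]["step"], 5e-3))
        elif not adapting:
            draws[it - warmup] = theta
    accept_rate = accept_sum / max(attempt_count, 1)
    final_step = [math.exp(u["da"]["log_step_bar"]) for u in updates]
    return draws, accept_rate, divergences, final_step


@dataclass
class EWAFit:
    """Posterior draws and diagnostics for one strategy model."""

    strategy: str
    data: ChoiceData
    posterior: "HierarchicalEWA"
    theta_draws: np.ndarray                # (chains, samples, ndim)
    pointwise: np.ndarray                  # (chains*samples, n_events)
    accept_rate: float
    divergences: int
    config: FitConfig
    diagnostics: dict = field(default_factory=dict)
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.theta_draws.shape[0] * self.theta_draws.shape[1]

    def cell_draws(self, param: str) -> dict[tuple[str, str], np.ndarray]:
        """Natural-scale posterior draws of each cell's group-level mean."""
        post = self.posterior
        if param not in post.param_names:
            raise ValueError(f"{param!r} not in model {self.strategy!r}")
        p = post.param_names.index(param)
        flat = self.theta_draws.reshape(-1, post.ndim)
        a = flat[:, :post.n_cells * post.P].reshape(-1, post.n_cells, post.P)
        eta = a[:, :, p]
        link = post.links[p]
        if link == 0:
            nat = np.exp(eta)
        elif link == 1:
            nat = 1.0 / (1.0 + np.exp(-eta))
        else:
            nat = eta
        return {cell: nat[:, c] for c, cell in enumerate(self.data.cells)}

    def to_frame(self) -> pd.DataFrame:
        """Flat draws of all group-level parameters (natural scale)."""
        cols = {}
        for param in self.posterior.param_names:
            for cell, d in self.cell_draws(param).items():
                cols[f"{param}[{cell[0]},{cell[1]}]"] = d
        return pd.DataFrame(cols)


def fit_ewa(
    events: Sequence[ChoiceEvent] | ChoiceData,
    roster: Mapping[str, Individual] | None,
    strategy: str,
    config: FitConfig | None = None,
    window: float = 60.0,
    demos: str = "all",
    prior_only: bool = False,
) -> EWAFit:
    """Sample the hierarchical posterior for one strategy model.

    Accepts either a raw event stream plus roster, or a prepared
    :class:`ChoiceData` (so the five models can share one preparation).
    With ``prior_only=True`` the likelihood is dropped and the sampler
    reproduces the prior (a prior-predictive identity check).
    """
    config = config or FitConfig()
    if isinstance(events, ChoiceData):
        data = events
    else:
        if roster is None:
            raise ValueError("roster required when passing raw events")
        data = prepare_choice_data(events, roster, window=window, demos=demos)
    post = HierarchicalEWA(data, strategy, config, prior_only=prior_only)

    rng_master = np.random.default_rng(config.seed)
    # start sigmas near the prior median rather than at 1, away from the
    # large-sigma funnel mouth
    init = np.zeros(post.ndim)
    init[post.n_cells * post.P: post.n_cells * post.P + post.P] = -1.0
    post_nc = HierarchicalEWA(data, strategy, config,
                              prior_only=prior_only, centered_names=())
    # warm start: chains begin jittered around the posterior mode, with the
    # metric taken from the curvature there
    theta_map = _map_estimate(post, init)
    n_hyper = post.n_hyper
    hyper_idx = np.arange(n_hyper)
    ind_idx = np.arange(n_hyper, post.ndim)
    a_map = theta_map[:post.n_cells * post.P].reshape(post.n_cells, post.P)
    sig_map = np.exp(np.clip(theta_map[post.n_cells * post.P:n_hyper],
                             -7.0, 7.0))
    z_map = theta_map[n_hyper:].reshape(post.n_ind, post.P)
    z_nc = z_map.copy()
    z_nc[:, post.centered] = ((z_map - a_map[data.cell_index])
                              / sig_map)[:, post.centered]
    theta_map_nc = np.concatenate([theta_map[:n_hyper], z_nc.ravel()])
    masses = [
        _curvature_mass(post.logp_grad, theta_map, ind_idx),
        _curvature_mass(post.logp_grad, theta_map, hyper_idx),
        _curvature_mass(post_nc.logp_grad, theta_map_nc, hyper_idx),
    ]
    all_draws = []
    accepts, divs = [], 0
    for _ in range(config.chains):
        rng = np.random.default_rng(rng_master.integers(2 ** 31))
        draws, acc, div, _ = _hmc_chain(
            post, post_nc, rng, config.warmup, config.samples,
            config.max_leapfrog, config.target_accept, init_theta=theta_map,
            masses=masses,
        )
        all_draws.append(draws)
        accepts.append(acc)
        divs += div
    theta = np.stack(all_draws)             # (chains, samples, ndim)

    # pointwise log-likelihood per kept draw, for WAIC
    n_events = data.n_events
    flat = theta.reshape(-1, post.ndim)
    pointwise = np.empty((flat.shape[0], n_events))
    buf = np.empty(n_events)
    for d, th in enumerate(flat):
        values = post.individual_values(th)
        lam, phi, gam, extra = post._kernel_args(values)
        _ewa_pointwise(lam, phi, gam, extra, post.code, data.lengths,
                       data.choice, data.payoff, post.soc_a, post.soc_b,
                       data.init_attr, buf)
        pointwise[d] = buf

    fit = EWAFit(
        strategy=strategy, data=data, posterior=post, theta_draws=theta,
        pointwise=pointwise, accept_rate=float(np.mean(accepts)),
        divergences=divs, config=config,
    )
    fit.diagnostics = _diagnose(fit)
    for msg in fit.warnings_:
        warnings.warn(msg, stacklevel=2)
    return fit


def _diagnose(fit: EWAFit) -> dict:
    """R-hat and bulk ESS on the group-level means, via arviz."""
    import arviz as az

    post = fit.posterior
    ncp = post.n_cells * post.P
    sub = fit.theta_draws[:, :, : ncp + post.P]
    names = [f"a[{c}][{p}]" for c in range(post.n_cells)
             for p in post.param_names] + [f"log_sigma[{p}]"
                                           for p in post.param_names]
    ds = az.convert_to_dataset(
        {name: sub[:, :, i] for i, name in enumerate(names)}
    )
    rhat_ds = az.rhat(ds)
    ess_ds = az.ess(ds)
    rhat = {n: float(rhat_ds[n].values) for n in names}
    ess = {n: float(ess_ds[n].values) for n in names}
    worst = max(rhat.values()) if rhat else float("nan")
    diag = {"rhat": rhat, "ess_bulk": ess, "max_rhat": worst,
            "divergences": fit.divergences, "accept_rate": fit.accept_rate}
    if fit.theta_draws.shape[0] > 1 and worst > 1.05:
        fit.warnings_.append(
            f"{fit.strategy}: max R-hat {worst:.3f} > 1.05; chains may not "
            "have converged"
        )
    if fit.divergences > 0.02 * fit.n_draws:
        fit.warnings_.append(
            f"{fit.strategy}: {fit.divergences} divergent transitions"
        )
    return diag


# --------------------------------------------------------------------------
# WAIC and posterior summaries

def waic_from_pointwise(pointwise: np.ndarray) -> dict:
    """WAIC = -2 (lppd - pWAIC) from an (n_draws, n_events) log-lik matrix."""
    n = pointwise.shape[1]
    m = pointwise.max(axis=0)
    lppd_i = m + np.log(np.mean(np.exp(pointwise - m), axis=0))
    p_i = pointwise.var(axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_i)
    return {
        "waic": float(waic_i.sum()),
        "se": float(math.sqrt(n * waic_i.var(ddof=1))),
        "p_waic": float(p_i.sum()),
        "lppd": float(lppd_i.sum()),
        "pointwise": waic_i,
    }


def waic_table(fits: Sequence[EWAFit]) -> pd.DataFrame:
    """Model comparison table: WAIC, SE, dWAIC, dSE, pWAIC, weight.

    All fits must share the same pointwise event partition; dSE is the
    standard error of the paired pointwise WAIC differences against the
    best model.
    """
    if not fits:
        raise ValueError("no fits supplied")
    n = fits[0].pointwise.shape[1]
    if any(f.pointwise.shape[1] != n for f in fits):
        raise ValueError("fits have mismatched pointwise partitions")
    comps = {f.strategy: waic_from_pointwise(f.pointwise) for f in fits}
    order = sorted(comps, key=lambda s: comps[s]["waic"])
    best = comps[order[0]]
    rows = []
    for name in order:
        c = comps[name]
        diff = c["pointwise"] - best["pointwise"]
        dse = math.sqrt(n * diff.var(ddof=1)) if name != order[0] else np.nan
        rows.append({
            "model": name, "waic": c["waic"], "se": c["se"],
            "d_waic": c["waic"] - best["waic"], "d_se": dse,
            "p_waic": c["p_waic"],
        })
    table = pd.DataFrame(rows).set_index("model")
    rel = np.exp(-0.5 * table["d_waic"])
    table["weight"] = rel / rel.sum()
    return table


def posterior_summary(
    fit: EWAFit,
    ci: float = 0.90,
    threshold_param: str = "f",
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-cell natural-scale summaries of the group-level means.

    Includes the posterior proportion of mass above ``threshold`` for the
    chosen parameter (by default the share of conformist f > 1 mass).
    """
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    for param in fit.posterior.param_names:
        for cell, draws in fit.cell_draws(param).items():
            row = {
                "param": param, "age": cell[0], "sex": cell[1],
                "mean": float(draws.mean()),
                "median": float(np.median(draws)),
                f"q{lo_q:.3f}": float(np.quantile(draws, lo_q)),
                f"q{hi_q:.3f}": float(np.quantile(draws, hi_q)),
            }
            if param == threshold_param:
                row[f"p_gt_{threshold:g}"] = float((draws > threshold).mean())
            rows.append(row)
    return pd.DataFrame(rows)
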