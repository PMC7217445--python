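"""Synthetic respondents under the G-MNL data-generating process.

Utility of alternative i for respondent n in situation t:

    U_int = asc_i * sigma_n + [sigma_n beta + gamma eta_n
            + (1 - gamma) sigma_n eta_n] x_int + e_int

with taste deviations eta_n ~ N(0, diag(eta_sd^2)) on the random
attributes, respondent scale sigma_n = exp(-tau^2/2 + tau * eps0_n)
(normalized so E[sigma_n] = 1), and i.i.d. standard Gumbel noise e_int.
With gamma = 0 and tau = 0 this is exactly a random-coefficients (mixed)
logit; with additionally eta_sd = 0 it is exactly MNL.  Opt-out answers
are generated as an exogenous thinning event — with probability
``opt_out_rate`` a situation's recorded choice is the opt-out — matching
their exclusion from the analysis rather than a utility-bearing option.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from . import tables
from .data import ChoiceDataset
from .design import add_opt_out, assign_blocks, fractional_factorial
from .exceptions import InvalidInputError

__all__ = [
    "TruePreferences",
    "DrawSet",
    "preset_truth",
    "study_design",
    "make_draws",
    "simulate_choices",
]

_MAX_HALTON_DIMS = 100


@dataclass
class TruePreferences:
    """True parameters of the generating process (see module docstring)."""

    beta: dict  # attribute name -> mean part-worth
    random_attrs: list = field(default_factory=list)
    eta_sd: dict = field(default_factory=dict)  # name -> SD of eta_n
    tau: float = 0.0
    asc: list = field(default_factory=list)  # per alternative position; asc[0] = 0
    gamma: float = 0.0
    opt_out_rate: float = 0.0

    def __post_init__(self):
        if any(sd < 0 for sd in self.eta_sd.values()):
            raise InvalidInputError("eta_sd must be nonnegative")
        if self.tau < 0:
            raise InvalidInputError("tau must be nonnegative")
        if not 0.0 <= self.gamma <= 1.0:
            raise InvalidInputError("gamma must lie in [0, 1]")
        if self.asc and self.asc[0] != 0:
            raise InvalidInputError("asc[0] is the zero reference")
        if not 0.0 <= self.opt_out_rate < 1.0:
            raise InvalidInputError("opt_out_rate must lie in [0, 1)")
        unknown = set(self.random_attrs) - set(self.beta)
        if unknown:
            raise InvalidInputError(f"random_attrs not in beta: {sorted(unknown)}")
        for nm in self.random_attrs:
            self.eta_sd.setdefault(nm, 0.0)


_PRESETS = {
    "ram": (tables.RAM_ATTRIBUTES, tables.RAM_GMNL, tables.RAM_OPT_OUT_RATE),
    "ewe": (tables.EWE_ATTRIBUTES, tables.EWE_GMNL, tables.EWE_OPT_OUT_RATE),
}


def preset_truth(scenario):
    """True preferences populated from the study's fitted estimates.

    ``scenario`` is "ram" (6 attributes, near-zero scale heterogeneity) or
    "ewe" (7 attributes, strong scale heterogeneity, tau = 0.7565).
    """
    if scenario not in _PRESETS:
        raise InvalidInputError(
            f"unknown scenario {scenario!r}; available: {sorted(_PRESETS)}"
        )
    _, est, opt_rate = _PRESETS[scenario]
    return TruePreferences(
        beta=dict(est["beta"]),
        random_attrs=list(est["random_attrs"]),
        eta_sd=dict(est["eta_sd"]),
        tau=est["tau"],
        asc=list(est["asc"]),
        opt_out_rate=opt_rate,
    )


def preset_attributes(scenario):
    if scenario not in _PRESETS:
        raise InvalidInputError(
            f"unknown scenario {scenario!r}; available: {sorted(_PRESETS)}"
        )
    return list(_PRESETS[scenario][0])


def study_design(scenario, seed=0, n_runs=16, n_blocks=4):
    """The study's design skeleton: a 16-run resolution-IV fraction of the
    attribute factorial, blocked into four choice situations of four
    alternatives, each augmented with an opt-out."""
    attrs = preset_attributes(scenario)
    profiles = fractional_factorial(attrs, n_runs, min_resolution=4)
    plan = assign_blocks(profiles, n_blocks, seed=seed, attributes=attrs)
    return add_opt_out(plan)


@dataclass
class DrawSet:
    """Simulation draws: eta is (D, K) standard-normal taste draws, eps0 the
    (D,) scale draws."""

    eta: np.ndarray
    eps0: np.ndarray
    scheme: str
    seed: int | None = None

    @property
    def n_draws(self):
        return self.eta.shape[0]


def _halton_normal(n_points, dims, seed):
    """Halton points (distinct prime bases per dimension, first 100 points
    discarded) mapped through the standard normal quantile."""
    if dims > _MAX_HALTON_DIMS:
        raise InvalidInputError(
            f"{dims} dimensions exceed the {_MAX_HALTON_DIMS} supported prime bases"
        )
    engine = qmc.Halton(d=dims, scramble=False, seed=seed)
    engine.fast_forward(100)
    u = engine.random(n_points)
    return stats.norm.ppf(u)


def make_draws(D, K, scheme="halton", seed=None):
    """A DrawSet of D draws for K taste dimensions plus one scale dimension."""
    if D < 1:
        raise InvalidInputError("D must be at least 1")
    if scheme == "halton":
        z = _halton_normal(D, K + 1, seed)
    elif scheme == "pseudo":
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((D, K + 1))
    else:
        raise InvalidInputError(f"unknown draw scheme {scheme!r}")
    return DrawSet(eta=z[:, :K], eps0=z[:, K], scheme=scheme, seed=seed)


def respondent_draws(n_respondents, D, K, scheme="halton", seed=None):
    """Per-respondent draw arrays: eta (N, D, K) and eps0 (N, D).

    Halton respondents take consecutive blocks of one long sequence, the
    usual construction for simulated likelihood.
    """
    ds = make_draws(n_respondents * D, K, scheme=scheme, seed=seed)
    eta = ds.eta.reshape(n_respondents, D, K)
    eps0 = ds.eps0.reshape(n_respondents, D)
    return eta, eps0


def _plan_template(plan):
    """Rows (situation template) shared by every respondent."""
    names = [a.name for a in plan.attributes]
    rows = []
    for b in range(plan.n_blocks):
        profs = plan.block_profiles(b)
        for alt, prof in enumerate(profs, start=1):
            rows.append((b + 1, alt, 0, prof.codes))
        if plan.opt_out[b]:
            rows.append((b + 1, len(profs) + 1, 1, (0,) * len(names)))
    sit = np.array([r[0] for r in rows])
    alt = np.array([r[1] for r in rows])
    opt = np.array([r[2] for r in rows])
    X = np.array([r[3] for r in rows], dtype=float)
    return sit, alt, opt, X, names


def simulate_choices(plan, truth, n_respondents, seed):
    """Simulate a ChoiceDataset: every respondent answers every block once.

    Fully reproducible from ``seed``.  Opt-out rows appear wherever the
    plan carries an opt-out; with probability ``truth.opt_out_rate`` a
    situation's recorded choice is moved to its opt-out row.
    """
    names_plan = [a.name for a in plan.attributes]
    missing = set(truth.beta) - set(names_plan)
    if missing or set(names_plan) - set(truth.beta):
        raise InvalidInputError(
            f"truth and plan attributes differ: plan={names_plan}, beta={sorted(truth.beta)}"
        )
    sit, alt, opt, X, names = _plan_template(plan)
    R = len(sit)
    K = len(names)
    beta = np.array([truth.beta[nm] for nm in names])
    rand_idx = [names.index(nm) for nm in truth.random_attrs]
    sds = np.array([truth.eta_sd.get(names[j], 0.0) for j in rand_idx])

    n_alt_max = int(alt.max())
    asc = np.zeros(n_alt_max)
    if truth.asc:
        asc[: len(truth.asc)] = truth.asc

    rng = np.random.default_rng(seed)
    # respondent-level heterogeneity
    eta = np.zeros((n_respondents, K))
    if rand_idx:
        eta[:, rand_idx] = rng.standard_normal((n_respondents, len(rand_idx))) * sds
    if truth.tau > 0:
        sigma = np.exp(-0.5 * truth.tau**2 + truth.tau * rng.standard_normal(n_respondents))
    else:
        sigma = np.ones(n_respondents)
    g = truth.gamma
    coef = sigma[:, None] * beta[None, :] + (g + (1 - g) * sigma[:, None]) * eta

    designed = opt == 0
    U = coef @ X[designed].T + sigma[:, None] * asc[alt[designed] - 1][None, :]
    U = U + rng.gumbel(size=U.shape)

    # argmax within each situation (designed alternatives only)
    sit_designed = sit[designed]
    frames = []
    chosen = np.zeros((n_respondents, R), dtype=int)
    col_of_designed = np.flatnonzero(designed)
    for b in np.unique(sit):
        cols = np.flatnonzero(sit_designed == b)
        best = cols[np.argmax(U[:, cols], axis=1)]
        chosen[np.arange(n_respondents), col_of_designed[best]] = 1
    # exogenous opt-out thinning
    if truth.opt_out_rate > 0 and opt.any():
        for b in np.unique(sit):
            in_sit = sit == b
            opt_cols = np.flatnonzero(in_sit & (opt == 1))
            if opt_cols.size == 0:
                continue
            hit = rng.random(n_respondents) < truth.opt_out_rate
            chosen[np.ix_(hit, np.flatnonzero(in_sit))] = 0
            chosen[hit, opt_cols[0]] = 1

    resp = np.repeat(np.arange(1, n_respondents + 1), R)
    df = pd.DataFrame(
        {
            "respondent_id": resp,
            "situation_id": np.tile(sit, n_respondents),
            "alternative_id": np.tile(alt, n_respondents),
            "chosen": chosen.ravel(),
            "is_opt_out": np.tile(opt, n_respondents),
        }
    )
    codes = np.tile(X.astype(int), (n_respondents, 1))
    for j, nm in enumerate(names):
        df[nm] = codes[:, j]
    return ChoiceDataset(list(plan.attributes), df)


def mnl_probabilities(X, asc_by_alt, sit, beta):
    """Closed-form MNL choice probabilities for a situation template
    (testing oracle for the simulator)."""
    u = X @ beta + asc_by_alt
    p = np.empty_like(u)
    for b in np.unique(sit):
        m = sit == b
        e = np.exp(u[m] - u[m].max())
        p[m] = e / e.sum()
    return p
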