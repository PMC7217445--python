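"""Generalized multinomial logit (G-MNL) by maximum simulated likelihood.

The model mixes taste heterogeneity (random part-worths with diagonal
covariance) and scale heterogeneity (a respondent-specific multiplier on
the whole utility).  For respondent n, the coefficient vector applied to
the effect-coded attributes is

    c_n = sigma_n * beta + [gamma + (1 - gamma) * sigma_n] * eta_n

with eta_n ~ N(0, diag(eta_sd^2)) on the designated random attributes and
sigma_n = exp(-tau^2/2 + tau * eps0_n), eps0_n ~ N(0, 1).  The scale
normalization sigma_bar = -tau^2/2 keeps E[sigma_n] = 1, so beta retains
its MNL interpretation; alternative-specific constants are scaled by
sigma_n exactly like the attribute part-worths.  The probability of a
respondent's observed choice sequence is simulated by averaging the
product of within-situation logit probabilities over D draws (Halton by
default), and the simulated log-likelihood is maximized over
(ASCs, beta, eta_sd, tau) with gamma held fixed — the conventional
restriction gamma = 0 by default.

``eta_sd`` and ``tau`` enter the likelihood through symmetric functions
of unconstrained parameters and are reported as absolute values, so the
reported heterogeneity parameters are always nonnegative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _mslkernels
from .exceptions import ConvergenceError, InvalidInputError
from .mnl import MultinomialLogit, build_design
from .simulate import respondent_draws
from .utils import segment_logsumexp, segment_softmax, segment_sum

__all__ = [
    "GMNLSpec",
    "GeneralizedMultinomialLogit",
    "GMNLResults",
    "fit_gmnl",
    "gmnl_probability",
    "mcfadden_rho2",
    "odds_ratios",
]

logger = logging.getLogger(__name__)

_CHUNK = 64  # draws processed per pass; bounds peak memory


@dataclass
class GMNLSpec:
    """Estimation configuration for the G-MNL model."""

    random_attrs: list
    n_draws: int = 500
    draw_scheme: str = "halton"
    gamma: float = 0.0
    seed: int = 0
    start: np.ndarray | None = None

    def __post_init__(self):
        if self.n_draws < 1:
            raise InvalidInputError("n_draws must be at least 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise InvalidInputError("gamma must lie in [0, 1]")
        if self.draw_scheme not in ("halton", "pseudo"):
            raise InvalidInputError(f"unknown draw scheme {self.draw_scheme!r}")


class _Core:
    """Vectorized simulated likelihood over contiguous long-format rows.

    eta: (N, D, Kr) taste draws; eps0: (N, D) scale draws.  Utilities for
    draw d are u = sigma * (X theta_mean) + (gamma + (1-gamma) sigma) * dev
    where dev accumulates s_k * eta_k on the random-attribute columns.
    """

    def __init__(self, design, rand_cols, gamma, eta, eps0, fix_tau=None):
        self.fix_tau = fix_tau
        self.X = design["X"]
        self.y = design["y"].astype(bool)
        self.starts = design["starts"]
        self.lengths = design["lengths"]
        self.resp = design["resp_index"]
        self.n_resp = design["n_resp"]
        self.names = design["names"]
        self.rand_cols = rand_cols
        self.gamma = gamma
        self.eta = eta
        self.eps0 = eps0
        self.D = eta.shape[1]
        # situation -> respondent map (situations are contiguous per respondent)
        self.sit_resp = self.resp[self.starts]
        self.resp_sit_starts = np.flatnonzero(
            np.r_[True, self.sit_resp[1:] != self.sit_resp[:-1]]
        )
        self.n_mean = self.X.shape[1]
        self.Xr = self.X[:, rand_cols] if rand_cols else np.empty((self.X.shape[0], 0))
        # fused-kernel path: per-draw registers instead of rows x draws arrays
        self.use_kernels = _mslkernels.HAVE_NUMBA and int(self.lengths.max()) <= 64
        if self.use_kernels:
            self._sit_ptr = np.ascontiguousarray(np.r_[self.starts, len(self.y)])
            self._chosen_idx = np.ascontiguousarray(np.flatnonzero(self.y))
            self._resp_sit_ptr = np.ascontiguousarray(
                np.r_[self.resp_sit_starts, len(self.starts)]
            )
            self._Xc = np.ascontiguousarray(self.X)
            self._Xrc = np.ascontiguousarray(self.Xr)
            self._eta_c = np.ascontiguousarray(self.eta)
            self._eps0_c = np.ascontiguousarray(self.eps0)

    def _loglik_and_grad_kernel(self, params, want_grad):
        theta_mean = np.ascontiguousarray(params[: self.n_mean])
        s = np.ascontiguousarray(params[self.n_mean : self.n_mean + len(self.rand_cols)])
        tau = float(self.fix_tau if self.fix_tau is not None else params[-1])
        base = self._Xc @ theta_mean
        logP = _mslkernels.loglik_kernel(
            base, self._Xrc, s, self._eta_c, self._eps0_c, tau, self.gamma,
            self._sit_ptr, self._chosen_idx, self._resp_sit_ptr,
        )
        m = logP.max(axis=1)
        w_un = np.exp(logP - m[:, None])
        denom = w_un.sum(axis=1)
        ll = float(np.sum(m + np.log(denom)) - self.n_resp * np.log(self.D))
        if not want_grad:
            return ll, None
        w = w_un / denom[:, None]
        raw = _mslkernels.score_kernel(
            base, self._Xc, self._Xrc, s, self._eta_c, self._eps0_c, tau, self.gamma,
            w, self._sit_ptr, self._chosen_idx, self._resp_sit_ptr,
            self.fix_tau is None,
        )
        grad = np.empty(len(params))
        grad[: self.n_mean] = raw[: self.n_mean]
        grad[self.n_mean : self.n_mean + len(self.rand_cols)] = raw[
            self.n_mean : self.n_mean + len(self.rand_cols)
        ]
        if self.fix_tau is None:
            grad[-1] = raw[-1]
        return ll, grad

    def _chunk_utilities(self, base, s, tau, sl):
        """Deterministic utilities for the draws in slice ``sl``.

        Returns (u, a, dev): u is (rows, c) utilities, a the per-row scale
        factors, dev the taste-deviation part (None without random attrs).
        """
        g = self.gamma
        sigma = np.exp(-0.5 * tau**2 + tau * self.eps0[:, sl])  # (N, c)
        a = sigma[self.resp]  # (rows, c)
        u = a * base[:, None]
        dev = None
        if self.rand_cols:
            eta_sl = np.asarray(self.eta[:, sl, :])[self.resp]  # (rows, c, K)
            dev = np.einsum("rk,rck->rc", self.Xr, eta_sl * s)
            u += (g + (1 - g) * a) * dev
        return u, a, dev

    def _chunk_logprob(self, u):
        """Per-respondent log choice-sequence probability for one chunk."""
        lse = segment_logsumexp(u, self.starts, self.lengths)  # (S, c)
        logp_sit = u[self.y] - lse  # chosen row per situation, sorted
        return np.add.reduceat(logp_sit, self.resp_sit_starts, axis=0)

    def loglik_and_grad(self, params, want_grad=True):
        params = np.asarray(params, dtype=float)
        if self.use_kernels:
            return self._loglik_and_grad_kernel(params, want_grad)
        theta_mean = params[: self.n_mean]
        s = params[self.n_mean : self.n_mean + len(self.rand_cols)]
        tau = self.fix_tau if self.fix_tau is not None else params[-1]
        D = self.D
        base = self.X @ theta_mean  # (rows,)

        # pass 1: per-respondent per-draw log path probabilities; cache the
        # per-chunk utilities for reuse in the gradient pass
        logP = np.empty((self.n_resp, D))
        cache = []
        for lo in range(0, D, _CHUNK):
            sl = slice(lo, min(lo + _CHUNK, D))
            u, a, dev = self._chunk_utilities(base, s, tau, sl)
            logP[:, sl] = self._chunk_logprob(u)
            if want_grad:
                cache.append((sl, u, a, dev))
        m = logP.max(axis=1)
        w_un = np.exp(logP - m[:, None])
        denom = w_un.sum(axis=1)
        ll = float(np.sum(m + np.log(denom)) - self.n_resp * np.log(D))
        if not want_grad:
            return ll, None
        w = w_un / denom[:, None]  # (N, D) softmax over draws

        # pass 2: accumulate the weighted score
        grad = np.zeros(len(params))
        g = self.gamma
        n_rand = len(self.rand_cols)
        for sl, u, a, dev in cache:
            p = segment_softmax(u, self.starts, self.lengths)
            np.subtract(self.y[:, None], p, out=p)  # residuals, in place
            Wrow = np.asarray(w[:, sl])[self.resp]
            Wrow *= p
            # mean coefficients (ASCs and attribute part-worths): X is draw-
            # independent, so sum the draw axis first
            grad[: self.n_mean] += self.X.T @ (Wrow * a).sum(axis=1)
            # eta SD parameters
            if self.rand_cols:
                b = g + (1 - g) * a
                eta_sl = np.asarray(self.eta[:, sl, :])[self.resp]
                inner = np.einsum("rc,rck->rk", Wrow * b, eta_sl)
                grad[self.n_mean : self.n_mean + n_rand] += (self.Xr * inner).sum(axis=0)
            # tau: du/dtau = (eps0 - tau) * [a*base + (1-g)*sigma*dev]
            if self.fix_tau is None:
                du_dtau = a * base[:, None]
                if dev is not None:
                    du_dtau += (1 - g) * a * dev
                du_dtau *= np.asarray(self.eps0[:, sl])[self.resp] - tau
                grad[-1] += float(np.sum(Wrow * du_dtau))
        return ll, grad


@dataclass
class GMNLResults:
    """Maximum simulated likelihood estimates for the G-MNL model.

    ``params`` stacks ASCs, attribute part-worth means, the standard
    deviations of the random part-worths (``sd_<attr>``) and ``tau``.
    """

    params: pd.Series
    bse: pd.Series
    llf: float
    llnull: float
    vcov: pd.DataFrame
    n_obs: int
    n_draws: int
    draw_scheme: str
    gamma: float
    seed: int
    random_attrs: list
    boundary_flags: list
    converged: bool
    model: "GeneralizedMultinomialLogit | None" = None
    fixed_tau: float | None = None

    @property
    def rho2(self):
        return mcfadden_rho2(self.llf, self.llnull)

    @property
    def zvalues(self):
        return self.params / self.bse

    @property
    def pvalues(self):
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    @property
    def tau(self):
        if "tau" in self.params.index:
            return float(self.params["tau"])
        return float(self.fixed_tau)

    @property
    def eta_sd(self):
        return self.params[[f"sd_{nm}" for nm in self.random_attrs]]

    def beta(self, attr_names):
        return self.params[attr_names]

    def odds_ratios(self, level=0.95, attr_names=None):
        if attr_names is None:
            attr_names = [
                nm
                for nm in self.params.index
                if not nm.startswith(("asc_", "sd_")) and nm != "tau"
            ]
        return odds_ratios(self.params[attr_names], self.bse[attr_names], level=level)

    def summary(self):
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "z": self.zvalues,
                "P>|z|": self.pvalues,
            }
        )
        lines = [
            "Generalized multinomial logit (maximum simulated likelihood)",
            f"Choice situations: {self.n_obs}   respondents' draws: "
            f"{self.n_draws} {self.draw_scheme}   gamma fixed at {self.gamma}",
            f"Log-likelihood (simulated): {self.llf:.4f}   null: {self.llnull:.4f}   "
            f"McFadden rho2: {self.rho2:.4f}",
            tab.to_string(float_format=lambda v: f"{v:10.4f}"),
        ]
        if self.boundary_flags:
            lines.append(f"boundary (~0) heterogeneity parameters: {self.boundary_flags}")
        return "\n".join(lines)

    def to_dict(self):
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "z": self.zvalues.to_dict(),
            "p": self.pvalues.to_dict(),
            "loglik": self.llf,
            "loglik_null": self.llnull,
            "rho2": self.rho2,
            "n_obs": self.n_obs,
            "n_draws": self.n_draws,
            "draw_scheme": self.draw_scheme,
            "gamma": self.gamma,
            "seed": self.seed,
            "random_attrs": list(self.random_attrs),
            "boundary_flags": list(self.boundary_flags),
            "converged": self.converged,
        }


class GeneralizedMultinomialLogit:
    """G-MNL model object (statsmodels-style): construct from data, ``fit()``.

    Parameters
    ----------
    dataset : ChoiceDataset
        Validated, opt-out-filtered long-format choice data.
    random_attrs : list of str
        Attributes given person-specific part-worth deviations.
    n_draws, draw_scheme, seed
        Simulation draws per respondent (Halton or seeded pseudo-random).
    gamma : float
        Fixed mixing parameter in [0, 1]; 0 is the conventional restriction.
    """

    def __init__(
        self,
        dataset,
        random_attrs=None,
        n_draws=500,
        draw_scheme="halton",
        gamma=0.0,
        seed=0,
        include_asc=True,
        fix_tau=None,
    ):
        spec = GMNLSpec(
            random_attrs=list(random_attrs or []),
            n_draws=n_draws,
            draw_scheme=draw_scheme,
            gamma=gamma,
            seed=seed,
        )
        unknown = set(spec.random_attrs) - set(dataset.attribute_names)
        if unknown:
            raise InvalidInputError(f"random_attrs not in dataset: {sorted(unknown)}")
        self.dataset = dataset
        self.spec = spec
        self.include_asc = include_asc
        self._design = build_design(dataset, include_asc=include_asc)
        names = self._design["names"]
        self._rand_cols = [names.index(nm) for nm in spec.random_attrs]
        eta, eps0 = respondent_draws(
            self._design["n_resp"],
            spec.n_draws,
            len(spec.random_attrs),
            scheme=spec.draw_scheme,
            seed=spec.seed,
        )
        self.fix_tau = fix_tau
        self._core = _Core(self._design, self._rand_cols, spec.gamma, eta, eps0, fix_tau=fix_tau)
        self.param_names = names + [f"sd_{nm}" for nm in spec.random_attrs]
        if fix_tau is None:
            self.param_names = self.param_names + ["tau"]

    def loglike(self, params):
        return self._core.loglik_and_grad(np.asarray(params, float), want_grad=False)[0]

    def score(self, params):
        return self._core.loglik_and_grad(np.asarray(params, float))[1]

    _WARM_START_DRAWS = 100

    def _start_values(self):
        """MNL estimates for the means, small positive heterogeneity; when
        many draws are requested, refined first by a cheap low-draw fit
        (a standard warm-start for maximum simulated likelihood)."""
        mnl = MultinomialLogit(self.dataset, include_asc=self.include_asc).fit()
        theta0 = mnl.params.reindex(self._design["names"]).to_numpy()
        tail = [] if self.fix_tau is not None else [0.1]
        x0 = np.r_[theta0, np.full(len(self._rand_cols), 0.1), tail]
        if self.spec.n_draws > 2 * self._WARM_START_DRAWS:
            pilot = GeneralizedMultinomialLogit(
                self.dataset,
                random_attrs=self.spec.random_attrs,
                n_draws=self._WARM_START_DRAWS,
                draw_scheme=self.spec.draw_scheme,
                gamma=self.spec.gamma,
                seed=self.spec.seed,
                include_asc=self.include_asc,
                fix_tau=self.fix_tau,
            )
            res = optimize.minimize(
                lambda x: tuple(-v for v in pilot._core.loglik_and_grad(x)),
                x0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 200, "ftol": 1e-9, "gtol": 1e-4},
            )
            if np.isfinite(res.fun):
                x0 = res.x
        return x0

    def fit(self, start=None, maxiter=300, gtol=1e-5):
        spec = self.spec
        x0 = np.asarray(start, float) if start is not None else self._start_values()
        if spec.start is not None:
            x0 = np.asarray(spec.start, float)

        def negll(x):
            ll, g = self._core.loglik_and_grad(x)
            return -ll, -g

        res = optimize.minimize(
            negll,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": gtol},
        )
        if not res.success:
            # one restart from a perturbed point, then report the best iterate
            res2 = optimize.minimize(
                negll,
                res.x * 0.95 + 0.01,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": gtol},
            )
            if res2.fun < res.fun:
                res = res2
        grad_norm = float(np.max(np.abs(res.jac)))
        converged = bool(res.success or grad_norm < 5e-3)
        if not converged:
            raise ConvergenceError(
                f"simulated likelihood did not converge (max |grad| = {grad_norm:.2e})",
                best_params=res.x,
                grad_norm=grad_norm,
            )

        theta = res.x.copy()
        n_mean = self._core.n_mean
        # report heterogeneity parameters on the nonnegative scale
        theta[n_mean:] = np.abs(theta[n_mean:])
        boundary = [
            self.param_names[j]
            for j in range(n_mean, len(theta))
            if theta[j] < 1e-3
        ]
        if boundary:
            logger.info("heterogeneity parameters at the boundary: %s", boundary)

        vcov = self._fd_vcov(res.x)
        llnull = MultinomialLogit(self.dataset, include_asc=self.include_asc).loglike_null()
        names = self.param_names
        return GMNLResults(
            params=pd.Series(theta, index=names),
            bse=pd.Series(np.sqrt(np.clip(np.diag(vcov), 0, None)), index=names),
            llf=-float(res.fun),
            llnull=llnull,
            vcov=pd.DataFrame(vcov, index=names, columns=names),
            n_obs=self._design["n_situations"],
            n_draws=spec.n_draws,
            draw_scheme=spec.draw_scheme,
            gamma=spec.gamma,
            seed=spec.seed,
            random_attrs=list(spec.random_attrs),
            boundary_flags=boundary,
            converged=converged,
            model=self,
            fixed_tau=self.fix_tau,
        )

    def _fd_vcov(self, theta, h=1e-4):
        """Covariance from a central finite-difference Hessian of the
        simulated log-likelihood (draws held fixed, so the surface is smooth)."""
        p = len(theta)
        H = np.zeros((p, p))
        for j in range(p):
            step = h * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += step
            tm[j] -= step
            _, gp = self._core.loglik_and_grad(tp)
            _, gm = self._core.loglik_and_grad(tm)
            H[j] = (gp - gm) / (2 * step)
        H = 0.5 * (H + H.T)
        try:
            vcov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(-H)
        if (np.diag(vcov) < 0).any():
            warnings.warn(
                "observed information is not positive definite; "
                "standard errors from the pseudo-inverse may be unreliable",
                stacklevel=2,
            )
            vcov = np.linalg.pinv(-H)
        return vcov


def fit_gmnl(dataset, spec=None, **kwargs):
    """Functional wrapper: fit a G-MNL model from a GMNLSpec or kwargs."""
    if spec is not None:
        model = GeneralizedMultinomialLogit(
            dataset,
            random_attrs=spec.random_attrs,
            n_draws=spec.n_draws,
            draw_scheme=spec.draw_scheme,
            gamma=spec.gamma,
            seed=spec.seed,
            **kwargs,
        )
        return model.fit(start=spec.start)
    return GeneralizedMultinomialLogit(dataset, **kwargs).fit()


def gmnl_probability(params, draws, dataset, random_attrs=None, gamma=0.0, include_asc=True):
    """Simulated probability of each respondent's observed choice sequence.

    ``params`` maps "asc" (list, first entry 0), "beta" (dict), "eta_sd"
    (dict) and "tau"; ``draws`` is a DrawSet shared across respondents.
    Every within-situation probability vector sums to one before the
    chosen entries are multiplied across situations and averaged over
    draws.
    """
    random_attrs = list(random_attrs or params.get("random_attrs", []))
    design = build_design(dataset, include_asc=include_asc)
    names = design["names"]
    K = len(random_attrs)
    if draws.eta.shape[1] != K:
        raise InvalidInputError(
            f"draws carry {draws.eta.shape[1]} taste dimensions but "
            f"{K} random attributes were requested"
        )
    theta_mean = np.zeros(len(names))
    for j, nm in enumerate(names):
        if nm.startswith("asc_"):
            pos = int(nm.split("_")[1])
            asc = params.get("asc", [])
            theta_mean[j] = asc[pos - 1] if len(asc) >= pos else 0.0
        else:
            theta_mean[j] = params["beta"][nm]
    s = np.array([params.get("eta_sd", {}).get(nm, 0.0) for nm in random_attrs])
    tau = float(params.get("tau", 0.0))

    n_resp = design["n_resp"]
    eta = np.broadcast_to(draws.eta, (n_resp, *draws.eta.shape))
    eps0 = np.broadcast_to(draws.eps0, (n_resp, len(draws.eps0)))
    rand_cols = [names.index(nm) for nm in random_attrs]
    core = _Core(design, rand_cols, gamma, eta, eps0)
    base = core.X @ theta_mean
    D = draws.n_draws
    logP = np.empty((n_resp, D))
    for lo in range(0, D, _CHUNK):
        sl = slice(lo, min(lo + _CHUNK, D))
        u, _, _ = core._chunk_utilities(base, s, tau, sl)
        logP[:, sl] = core._chunk_logprob(u)
    m = logP.max(axis=1)
    return np.exp(m) * np.exp(logP - m[:, None]).mean(axis=1)


def mcfadden_rho2(loglik, loglik_null):
    """McFadden pseudo-R^2: 1 - loglik / loglik_null."""
    if loglik > 0:
        raise InvalidInputError(f"log-likelihood must be nonpositive, got {loglik}")
    if loglik_null >= 0:
        raise InvalidInputError(f"null log-likelihood must be negative, got {loglik_null}")
    if loglik < loglik_null:
        raise InvalidInputError("loglik must be at least loglik_null")
    return 1.0 - loglik / loglik_null


def odds_ratios(estimates, se=None, level=0.95):
    """Odds ratios exp(beta) with Wald confidence bounds exp(beta +/- z se).

    For an effect-coded binary attribute exp(beta) is reported as the
    multiplicative change in choice odds between the attribute's two levels.
    """
    estimates = pd.Series(estimates, dtype=float)
    out = pd.DataFrame(index=estimates.index)
    out["odds_ratio"] = np.exp(estimates)
    z = stats.norm.ppf(0.5 + level / 2)
    if se is None:
        logger.warning("no standard errors supplied; confidence bounds omitted")
        out["lower"] = np.nan
        out["upper"] = np.nan
        return out
    se = pd.Series(se, dtype=float).reindex(estimates.index)
    missing = se.isna()
    if missing.any():
        logger.warning("missing SE for %s; bounds omitted there", list(se.index[missing]))
    out["lower"] = np.exp(estimates - z * se)
    out["upper"] = np.exp(estimates + z * se)
    return out
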