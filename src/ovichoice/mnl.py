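"""Conditional (multinomial) logit estimation and the Hausman-McFadden
test of independence of irrelevant alternatives.

The model: utility of alternative i in situation s is
``u_i = asc_i + beta' x_i + e_i`` with i.i.d. standard Gumbel errors, so
choice probabilities are softmax within each situation.  The first
alternative position is the zero-reference for the alternative-specific
constants.  The log-likelihood is globally concave and is maximized by
Newton steps on the analytic gradient and Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConvergenceError, InvalidInputError
from .utils import segment_logsumexp, segment_softmax, segment_sum, situation_starts

__all__ = [
    "MultinomialLogit",
    "MNLResults",
    "fit_mnl",
    "loglik_null",
    "hausman_statistic",
    "hausman_mcfadden",
    "IIATestResult",
]

_SORT_KEYS = ["respondent_id", "situation_id", "alternative_id"]


def build_design(dataset, include_asc=True, include_attrs=True):
    """Design arrays for grouped-softmax likelihoods.

    Returns a dict with the row-sorted frame, design matrix ``X`` (ASC
    dummies for every position above the reference, then the effect-coded
    attributes), the chosen indicator, situation offsets and per-row
    respondent codes.
    """
    df = dataset.df
    if (df["is_opt_out"] == 1).any():
        raise InvalidInputError("dataset still contains opt-out rows; apply drop_opt_outs first")
    df = df.sort_values(_SORT_KEYS, kind="mergesort").reset_index(drop=True)
    starts, lengths = situation_starts(df)
    if (lengths < 2).any():
        raise InvalidInputError("every situation needs at least 2 alternatives")

    cols, names = [], []
    if include_asc:
        alts = np.sort(df["alternative_id"].unique())
        for a in alts[1:]:
            cols.append((df["alternative_id"] == a).to_numpy(dtype=float))
            names.append(f"asc_{a}")
    attr_names = dataset.attribute_names if include_attrs else []
    for nm in attr_names:
        cols.append(df[nm].to_numpy(dtype=float))
        names.append(nm)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))

    resp_codes, resp_index = np.unique(df["respondent_id"].to_numpy(), return_inverse=True)
    return {
        "df": df,
        "X": X,
        "names": names,
        "attr_names": attr_names,
        "y": df["chosen"].to_numpy(dtype=float),
        "starts": starts,
        "lengths": lengths,
        "resp_index": resp_index,
        "n_resp": len(resp_codes),
        "n_situations": len(starts),
    }


def _mnl_loglike_parts(X, y, starts, lengths, theta):
    u = X @ theta
    lse = segment_logsumexp(u, starts, lengths)
    ll = float(u @ y - lse.sum())
    p = segment_softmax(u, starts, lengths)
    return ll, p


def _newton_mnl(X, y, starts, lengths, start=None, tol=1e-6, maxiter=100):
    n_par = X.shape[1]
    theta = np.zeros(n_par) if start is None else np.asarray(start, dtype=float).copy()
    ll, p = _mnl_loglike_parts(X, y, starts, lengths, theta)
    for _ in range(maxiter):
        resid = y - p
        g = X.T @ resid
        if np.max(np.abs(g)) < tol:
            break
        pX = p[:, None] * X
        m = segment_sum(pX, starts)
        H = -(X.T @ pX - m.T @ m)
        H_reg = H - 1e-10 * np.eye(n_par)
        step = np.linalg.solve(H_reg, -g)
        lam = 1.0
        for _ in range(40):
            cand = theta + lam * step
            ll_new, p_new = _mnl_loglike_parts(X, y, starts, lengths, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                theta, ll, p = cand, ll_new, p_new
                break
            lam *= 0.5
        else:
            break
        if np.max(np.abs(theta)) > 50:
            worst = int(np.argmax(np.abs(theta)))
            raise ConvergenceError(
                f"likelihood appears unbounded (complete separation) in parameter index {worst}",
                best_params=theta,
                grad_norm=float(np.max(np.abs(g))),
            )
    resid = y - p
    g = X.T @ resid
    if n_par and np.max(np.abs(g)) > 1e-4:
        raise ConvergenceError(
            "Newton iterations did not converge",
            best_params=theta,
            grad_norm=float(np.max(np.abs(g))),
        )
    pX = p[:, None] * X
    m = segment_sum(pX, starts)
    H = -(X.T @ pX - m.T @ m) if n_par else np.empty((0, 0))
    return theta, ll, H


@dataclass
class MNLResults:
    """Maximum-likelihood estimates for the conditional logit."""

    params: pd.Series
    bse: pd.Series
    llf: float
    llnull: float
    vcov: pd.DataFrame
    n_obs: int  # retained choice situations
    model: "MultinomialLogit"

    @property
    def rho2(self):
        return 1.0 - self.llf / self.llnull

    @property
    def zvalues(self):
        return self.params / self.bse

    @property
    def pvalues(self):
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    def cov_params(self):
        return self.vcov

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
            "Conditional logit (MNL)",
            f"Choice situations: {self.n_obs}",
            f"Log-likelihood: {self.llf:.4f}   null: {self.llnull:.4f}   "
            f"McFadden rho2: {self.rho2:.4f}",
            tab.to_string(float_format=lambda v: f"{v:10.4f}"),
        ]
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
            "vcov": self.vcov.to_numpy().tolist(),
        }


class MultinomialLogit:
    """Conditional logit on a validated, opt-out-filtered ChoiceDataset.

    Parameters
    ----------
    dataset : ChoiceDataset
    include_asc : bool
        Include alternative-specific constants (first position fixed at 0).
    """

    def __init__(self, dataset, include_asc=True):
        self.dataset = dataset
        self.include_asc = include_asc
        self._d = build_design(dataset, include_asc=include_asc)

    def loglike(self, theta):
        ll, _ = _mnl_loglike_parts(
            self._d["X"], self._d["y"], self._d["starts"], self._d["lengths"], np.asarray(theta, float)
        )
        return ll

    def score(self, theta):
        _, p = _mnl_loglike_parts(
            self._d["X"], self._d["y"], self._d["starts"], self._d["lengths"], np.asarray(theta, float)
        )
        return self._d["X"].T @ (self._d["y"] - p)

    def loglike_null(self):
        """Maximized log-likelihood of the ASC-only model."""
        d = build_design(self.dataset, include_asc=self.include_asc, include_attrs=False)
        if d["X"].shape[1] == 0:
            return -float(np.log(d["lengths"]).sum())
        _, ll0, _ = _newton_mnl(d["X"], d["y"], d["starts"], d["lengths"])
        return ll0

    def fit(self, start=None):
        d = self._d
        try:
            theta, ll, H = _newton_mnl(d["X"], d["y"], d["starts"], d["lengths"], start=start)
        except ConvergenceError as err:
            if err.best_params is not None and d["attr_names"]:
                # name the attribute with the largest runaway coefficient
                offset = len(d["names"]) - len(d["attr_names"])
                attr_part = np.abs(np.asarray(err.best_params)[offset:])
                worst = d["attr_names"][int(np.argmax(attr_part))]
                raise ConvergenceError(
                    f"{err} (largest attribute coefficient: {worst})",
                    best_params=err.best_params,
                    grad_norm=err.grad_norm,
                ) from None
            raise
        vcov = np.linalg.inv(-H)
        names = d["names"]
        with np.errstate(invalid="ignore"):  # NaN SE for unidentified params
            bse = np.sqrt(np.diag(vcov))
        return MNLResults(
            params=pd.Series(theta, index=names),
            bse=pd.Series(bse, index=names),
            llf=ll,
            llnull=self.loglike_null(),
            vcov=pd.DataFrame(vcov, index=names, columns=names),
            n_obs=d["n_situations"],
            model=self,
        )


def fit_mnl(dataset, include_asc=True, start=None):
    return MultinomialLogit(dataset, include_asc=include_asc).fit(start=start)


def loglik_null(dataset, include_asc=True):
    return MultinomialLogit(dataset, include_asc=include_asc).loglike_null()


@dataclass
class IIATestResult:
    """Hausman-McFadden contrast between the full fit and a fit with one
    alternative removed.  ``psd_violation`` flags negative eigenvalues in
    the covariance contrast (their mass is dropped by projecting onto the
    positive eigenspace, so the statistic is always nonnegative)."""

    statistic: float
    df: int
    p_value: float
    dropped_alternative: int
    psd_violation: bool
    common_params: list

    @property
    def reject_at_05(self):
        return self.p_value < 0.05


def _restrict_dataset(dataset, drop_alternative):
    from .data import ChoiceDataset

    df = dataset.df
    key = ["respondent_id", "situation_id"]
    chose = df[(df["chosen"] == 1) & (df["alternative_id"] == drop_alternative)][key]
    mask = df.merge(chose.assign(_d=1), on=key, how="left")["_d"].notna().to_numpy()
    sub = df[~mask & (df["alternative_id"] != drop_alternative).to_numpy()]
    return ChoiceDataset(list(dataset.attributes), sub.reset_index(drop=True))


def hausman_statistic(diff, dV):
    """Quadratic form (b_r - b_f)' (V_r - V_f)^+ (b_r - b_f) on the positive
    eigenspace of the covariance contrast.

    Returns (statistic, df, psd_violation): df is the retained rank, and
    psd_violation flags negative eigenvalues (their directions are dropped,
    so the statistic is always nonnegative).
    """
    diff = np.asarray(diff, dtype=float)
    dV = np.asarray(dV, dtype=float)
    dV = 0.5 * (dV + dV.T)
    eigval, eigvec = np.linalg.eigh(dV)
    tol = max(1e-12, 1e-9 * float(np.max(np.abs(eigval), initial=0.0)))
    pos = eigval > tol
    psd_violation = bool((eigval < -tol).any())
    if not pos.any():
        return 0.0, 0, psd_violation
    proj = eigvec[:, pos].T @ diff
    return float(proj @ (proj / eigval[pos])), int(pos.sum()), psd_violation


def hausman_mcfadden(dataset, drop_alternative, include_asc=True):
    """Test IIA by dropping one alternative and contrasting estimates.

    statistic = (b_r - b_f)' (V_r - V_f)^+ (b_r - b_f) on the coefficients
    common to both fits, with degrees of freedom equal to the rank of the
    positive part of (V_r - V_f); chi-square p-value.
    """
    n_alts = dataset.df["alternative_id"].nunique()
    if n_alts < 3:
        raise InvalidInputError("need at least 3 alternatives before dropping one")
    full = fit_mnl(dataset, include_asc=include_asc)
    restricted = fit_mnl(_restrict_dataset(dataset, drop_alternative), include_asc=include_asc)

    common = [nm for nm in restricted.params.index if nm in set(full.params.index)]
    if not common:
        raise InvalidInputError("no common coefficients between full and restricted fits")
    diff = (restricted.params[common] - full.params[common]).to_numpy()
    dV = (
        restricted.vcov.loc[common, common].to_numpy()
        - full.vcov.loc[common, common].to_numpy()
    )
    stat, dof, psd_violation = hausman_statistic(diff, dV)
    p = float(stats.chi2.sf(stat, dof)) if dof else 1.0
    return IIATestResult(
        statistic=stat,
        df=max(dof, 1),
        p_value=p,
        dropped_alternative=drop_alternative,
        psd_violation=psd_violation,
        common_params=common,
    )
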