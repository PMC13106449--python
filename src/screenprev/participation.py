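"""Diagnostic-phase participation modelling among screen-positives.

Participation in the confirmation phase is typically non-random: families of
children with more pronounced symptoms are more likely to attend.  A logistic
regression of participation on the screening score (optionally sex and grade)
quantifies this and justifies carrying the score into the latent prevalence
model, where the adjustment for differential participation actually happens.
Inverse-probability weights are exposed only as a cross-check utility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

DEFAULT_COVARIATES = ("scq_score", "sex", "grade")


class SeparationError(ValueError):
    """Degenerate outcome or perfectly separated design."""


@dataclass(frozen=True)
class ParticipationFit:
    """Maximum-likelihood logistic fit summary (Wald inference)."""

    params: dict[str, float]
    bse: dict[str, float]
    zvalues: dict[str, float]
    pvalues: dict[str, float]
    converged: bool
    n_obs: int
    message: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {"params": self.params, "bse": self.bse, "zvalues": self.zvalues,
             "pvalues": self.pvalues, "converged": self.converged,
             "n_obs": self.n_obs, "message": self.message},
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"{'term':<12}{'coef':>10}{'se':>10}{'z':>8}{'p':>9}"]
        for k in self.params:
            lines.append(
                f"{k:<12}{self.params[k]:>10.4f}{self.bse[k]:>10.4f}"
                f"{self.zvalues[k]:>8.2f}{self.pvalues[k]:>9.4f}"
            )
        lines.append(f"n = {self.n_obs}, converged = {self.converged}")
        return "\n".join(lines)


def _design(records: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=records.index)
    X["intercept"] = 1.0
    for cov in covariates:
        if cov == "sex":
            X["sex_M"] = (records["sex"] == "M").astype(float)
        elif cov in ("scq_score", "grade"):
            X[cov] = records[cov].astype(float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return X


class ParticipationModel(BaseEstimator):
    """Logistic regression of diagnostic-phase participation on covariates.

    Parameters
    ----------
    covariates : tuple of str
        Any of ``scq_score``, ``sex`` (indicator for male), ``grade``
        (ordinal 1–3).  An intercept is always included.
    tol, maxiter : float, int
        Newton convergence tolerance on the relative log-likelihood change
        and the iteration cap.

    Fitted attributes (trailing underscore) mirror :class:`ParticipationFit`.
    """

    def __init__(self, covariates=("scq_score",), tol: float = 1e-8, maxiter: int = 100):
        self.covariates = covariates
        self.tol = tol
        self.maxiter = maxiter

    def fit(self, records: pd.DataFrame, y=None):
        sp = records.loc[records["screen_positive"]]
        if sp.empty:
            raise ValueError("no screen-positive records to fit participation on")
        outcome = sp["participated"].astype("boolean")
        if outcome.isna().any():
            raise ValueError("participation missing for a screen-positive record")
        yv = outcome.to_numpy(dtype=float)
        if yv.min() == yv.max():
            raise SeparationError(
                "participation outcome is constant; the logistic model is degenerate"
            )
        X = _design(sp, self.covariates)
        zero_var = [c for c in X.columns if c != "intercept" and X[c].nunique() <= 1]
        if zero_var:
            raise ValueError(f"zero-variance covariate(s): {zero_var}")

        converged, message = True, ""
        model = sm.Logit(yv, X.to_numpy())
        try:
            res = model.fit(disp=0, tol=self.tol, maxiter=self.maxiter, warn_convergence=False)
            converged = bool(res.mle_retvals.get("converged", False))
            # enormous coefficients with enormous SEs signal quasi-separation
            if converged and (np.abs(res.params).max() > 50 or not np.isfinite(res.bse).all()):
                converged, message = False, "possible complete separation"
            params, bse, zv, pv = res.params, res.bse, res.tvalues, res.pvalues
            if not converged and not message:
                message = "maximum-likelihood iteration did not converge"
        except Exception as exc:  # statsmodels raises on hard separation
            converged, message = False, f"fit failed: {exc}"
            k = X.shape[1]
            params = bse = zv = pv = np.full(k, np.nan)

        names = list(X.columns)
        self.feature_names_ = names
        self.params_ = dict(zip(names, map(float, params)))
        self.bse_ = dict(zip(names, map(float, bse)))
        self.zvalues_ = dict(zip(names, map(float, zv)))
        self.pvalues_ = dict(zip(names, map(float, pv)))
        self.converged_ = converged
        self.message_ = message
        self.n_obs_ = int(len(sp))
        return self

    def predict_proba(self, records: pd.DataFrame) -> np.ndarray:
        """Participation probability per record (screen-positives expected)."""
        if not getattr(self, "converged_", False):
            raise SeparationError("refusing to predict from a non-converged fit")
        X = _design(records, self.covariates)
        eta = X.to_numpy() @ np.array([self.params_[c] for c in self.feature_names_])
        return 1.0 / (1.0 + np.exp(-eta))

    def summary_(self) -> ParticipationFit:
        return ParticipationFit(
            params=self.params_, bse=self.bse_, zvalues=self.zvalues_,
            pvalues=self.pvalues_, converged=self.converged_,
            n_obs=self.n_obs_, message=self.message_,
        )


def fit_participation(records: pd.DataFrame, covariates=("scq_score",)) -> ParticipationFit:
    """Fit the participation logistic model; see :class:`ParticipationModel`."""
    return ParticipationModel(covariates=covariates).fit(records).summary_()


def participation_weights(fit: ParticipationFit, records: pd.DataFrame) -> np.ndarray:
    """Per-child participation probabilities under a converged fit."""
    if not fit.converged:
        raise SeparationError("refusing to compute weights from a non-converged fit")
    covs = tuple(
        "sex" if name == "sex_M" else name for name in fit.params if name != "intercept"
    )
    X = _design(records, covs)
    beta = np.array([fit.params[c] for c in X.columns])
    eta = X.to_numpy() @ beta
    return 1.0 / (1.0 + np.exp(-eta))
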