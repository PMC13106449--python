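"""Bayesian latent-status prevalence model for two-phase screening surveys.

The model treats true case status as a latent binary variable among
screen-positive children:

* priors:       beta_j ~ Normal(m_j, s_j^2)  (weakly informative defaults)
* latent:       z_i ~ Bernoulli(p_i),  logit(p_i) = beta0 + beta1 * x_i
* measurement:  y_i | z_i ~ Bernoulli(z_i * Se + (1 - z_i) * (1 - Sp))
                for diagnostic-phase participants only

where x_i is the (centred) screening score.  Non-participants contribute no
measurement; their latent status is imputed from the prior-predictive
Bernoulli(p_i), which — because the score drives both participation and
latent risk — is precisely how the procedure adjusts for differential
participation.  Se/Sp may be fixed (primary analysis) or given Beta priors
(probabilistic sensitivity analysis); conditional on z the measurement
likelihood is Beta-conjugate, so uncertain Se/Sp get exact Gibbs updates.

Sampling is partially collapsed Gibbs: beta by adaptive random-walk
Metropolis on the observed-data posterior (latent status marginalised out of
the participants' measurement likelihood; adaptation frozen after burn-in),
z redrawn from its full conditional each sweep, Se/Sp conjugate.
Prevalence draws use the sampled latent indicators, so the credible interval
tracks the posterior of the realised case count in the cohort; screen-negative
children count zero cases in the primary path (an optional screening-
sensitivity correction divides stratum case totals by an assumed screening
sensitivity).  Stratum estimates are combined with known population sizes
(post-stratification) and summarised as the posterior median with an
equal-tailed 95% credible interval.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from ._rng import rng_for
from .cohort import StratumSpec


class IdentifiabilityError(ValueError):
    """Se + Sp <= 1: apparent prevalence carries no sign information."""


@dataclass(frozen=True)
class MisclassSpec:
    """Diagnostic misclassification: fixed Se/Sp or Beta priors on both."""

    mode: str = "fixed"  # "fixed" | "beta_prior"
    se: float = 0.85
    sp: float = 0.75
    se_prior: tuple[float, float] = (85.0, 15.0)
    sp_prior: tuple[float, float] = (60.0, 40.0)

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "beta_prior"):
            raise ValueError(f"unknown misclassification mode {self.mode!r}")
        if self.mode == "fixed":
            if not (0.0 < self.se < 1.0 and 0.0 < self.sp < 1.0):
                raise ValueError("fixed se/sp must lie strictly in (0, 1)")
            if self.se + self.sp <= 1.0:
                raise IdentifiabilityError("se + sp must exceed 1 in fixed mode")
        else:
            for name, (a, b) in (("se_prior", self.se_prior), ("sp_prior", self.sp_prior)):
                if not (a > 0 and b > 0):
                    raise ValueError(f"{name}: Beta parameters must be positive")


@dataclass(frozen=True)
class MCMCSpec:
    n_chains: int = 3
    burn_in: int = 5_000
    iterations: int = 10_000
    seed: int = 0
    thinning: int = 1

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for R-hat")
        if self.burn_in < 0 or self.iterations <= 0 or self.thinning < 1:
            raise ValueError("burn_in >= 0, iterations > 0, thinning >= 1 required")


@dataclass(frozen=True)
class LatentModelSpec:
    """Priors, covariates and misclassification for the latent model.

    ``covariates`` names numeric cohort columns entering the linear predictor
    (an intercept is always included; the empty tuple gives the intercept-only
    model).  With ``center_scq`` the screening score is centred at the
    screen-positive sample mean before entering the predictor.
    """

    prior_mean: float = 0.0
    prior_sd: float = 2.5
    covariates: tuple[str, ...] = ("scq_score",)
    center_scq: bool = True
    misclass: MisclassSpec = field(default_factory=MisclassSpec)

    def __post_init__(self) -> None:
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")


@dataclass
class PosteriorDraws:
    """MCMC output of :class:`LatentPrevalenceModel`.

    ``beta`` has shape (chains, draws, p) on the centred-covariate scale;
    ``se``/``sp`` are (chains, draws); ``case_counts`` is (chains, draws,
    n_cells) of sampled latent case counts per demographic cell; ``cells``
    describes each cell (stratum, sex, grade, n = screened children in it);
    ``prob_mean`` is the Rao–Blackwellised posterior case probability per
    screen-positive child, indexed by child id.
    """

    beta: np.ndarray
    beta_names: tuple[str, ...]
    se: np.ndarray
    sp: np.ndarray
    case_counts: np.ndarray
    cells: pd.DataFrame
    prob_mean: pd.Series
    center: float
    misclass: MisclassSpec
    acceptance_rate: tuple[float, ...]

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def beta_uncentered(self) -> np.ndarray:
        """Coefficients on the raw covariate scale (intercept shifted back)."""
        out = self.beta.copy()
        if self.center and "scq_score" in self.beta_names:
            j = self.beta_names.index("scq_score")
            out[:, :, 0] = self.beta[:, :, 0] - self.beta[:, :, j] * self.center
        return out

    def chain_arrays(self) -> dict[str, np.ndarray]:
        """Per-parameter (chains, draws) arrays for convergence diagnostics."""
        out = {name: self.beta[:, :, j] for j, name in enumerate(self.beta_names)}
        if self.misclass.mode == "beta_prior":
            out["se"] = self.se
            out["sp"] = self.sp
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy draws (chain, iteration, parameters) for persistence."""
        c, d, p = self.beta.shape
        rows = {
            "chain": np.repeat(np.arange(c), d),
            "iteration": np.tile(np.arange(d), c),
        }
        for j, name in enumerate(self.beta_names):
            rows[name] = self.beta[:, :, j].ravel()
        rows["se"] = self.se.ravel()
        rows["sp"] = self.sp.ravel()
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PrevalenceResult:
    """Posterior median and equal-tailed 95% CrI, with stratum breakdown."""

    median: float
    lower: float
    upper: float
    scale: str = "per_1000"  # "per_1" | "per_1000"
    stratum: dict = field(default_factory=dict)
    n_draws: int = 0

    def __post_init__(self) -> None:
        if not (self.lower <= self.median <= self.upper):
            raise ValueError("requires lower <= median <= upper")

    def per_1000(self) -> "PrevalenceResult":
        if self.scale == "per_1000":
            return self
        f = 1000.0
        return PrevalenceResult(
            self.median * f, self.lower * f, self.upper * f, "per_1000",
            {k: {kk: vv * f for kk, vv in v.items()} for k, v in self.stratum.items()},
            self.n_draws,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def __str__(self) -> str:
        unit = "per 1,000" if self.scale == "per_1000" else "proportion"
        return f"{self.median:.1f} (95% CrI {self.lower:.1f}-{self.upper:.1f}) {unit}"


def rogan_gladen(apparent_prev: float, se: float, sp: float):
    """Misclassification back-correction (p + Sp - 1) / (Se + Sp - 1).

    Returns a :class:`RoganGladenResult`; the raw value is clamped to [0, 1]
    with the clamp flagged.
    """
    if se + sp <= 1.0:
        raise IdentifiabilityError("rogan_gladen requires se + sp > 1")
    if not (0.0 <= apparent_prev <= 1.0):
        raise ValueError("apparent_prev must be a probability")
    raw = (apparent_prev + sp - 1.0) / (se + sp - 1.0)
    est = min(1.0, max(0.0, raw))
    return RoganGladenResult(estimate=est, raw=raw, clamped=(est != raw))


@dataclass(frozen=True)
class RoganGladenResult:
    estimate: float
    raw: float
    clamped: bool

    def __float__(self) -> float:
        return self.estimate


def latent_conditional_probability(p: float, y: bool, se: float, sp: float) -> float:
    """Full-conditional P(z=1 | y, p, Se, Sp) for one participant.

    p * [y Se + (1-y)(1-Se)] over the two-component normaliser; with a
    perfect test (Se=Sp=1) this collapses to the observed diagnosis.
    """
    w1 = p * (se if y else 1.0 - se)
    w0 = (1.0 - p) * ((1.0 - sp) if y else sp)
    if w1 + w0 == 0.0:
        raise ZeroDivisionError("degenerate conditional: both components have mass 0")
    return w1 / (w1 + w0)


# ----------------------------------------------------------------- sampler


def _build_cells(records: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Demographic cells over ALL screened children; index of each screen-positive."""
    key = records["stratum"].astype(str) + "|" + records["sex"].astype(str) + "|" + \
        records["grade"].astype(str)
    labels, inverse = np.unique(key.to_numpy(), return_inverse=True)
    n = np.bincount(inverse, minlength=labels.size)
    parts = [lab.split("|") for lab in labels]
    cells = pd.DataFrame(
        {"stratum": [p[0] for p in parts], "sex": [p[1] for p in parts],
         "grade": [int(p[2]) for p in parts], "n": n}
    )
    sp_mask = records["screen_positive"].to_numpy(dtype=bool)
    return cells, inverse[sp_mask]


def _log1pexp(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


_INNER_MH_STEPS = 4  # Metropolis proposals per sweep (decorrelates beta)


def _run_chain(rng, X, part, y_part, prior_mean, prior_sd, misclass,
               n_burn, n_keep, thin, cell_idx, n_cells):
    """One chain of the partially collapsed Gibbs sampler.

    Per sweep: (1) adaptive random-walk Metropolis on beta targeting the
    observed-data posterior — participants' diagnoses with the latent status
    marginalised out, P(y=1|beta) = p*Se + (1-p)*(1-Sp); non-participants
    carry no measurement likelihood and therefore do not feed back into beta.
    (2) latent z redrawn from its full conditional (measurement-conditional
    for participants, prior-predictive otherwise).  (3) conjugate Beta
    updates of Se/Sp given z in beta_prior mode.  Marginalising z in the beta
    step and redrawing it immediately afterwards preserves the joint
    posterior and removes the imputation feedback that makes plain data
    augmentation mix slowly when most diagnoses are missing.
    """
    n, p = X.shape
    beta = prior_mean + 0.25 * rng.standard_normal(p)  # overdispersed starts
    if misclass.mode == "beta_prior":
        se = rng.beta(*misclass.se_prior)
        sp = rng.beta(*misclass.sp_prior)
    else:
        se, sp = misclass.se, misclass.sp

    part_idx = np.flatnonzero(part)
    yp = y_part.astype(bool)
    Xp = X[part_idx]

    # adaptive Metropolis: scalar step times a covariance factor from burn-in
    step = 0.5
    L = np.diag(1.0 / np.maximum(X.std(axis=0), 1e-3))
    history = np.empty((max(n_burn, 1), p))
    accepted_total = proposed_total = 0
    batch_acc = batch_n = 0
    beta_out = np.empty((n_keep, p))
    se_out = np.empty(n_keep)
    sp_out = np.empty(n_keep)
    counts_out = np.empty((n_keep, n_cells))
    prob_sum = np.zeros(n)
    total_iter = n_burn + n_keep * thin

    def logpost(b, se_, sp_):
        lp = -0.5 * float(((b - prior_mean) / prior_sd) @ ((b - prior_mean) / prior_sd))
        if part_idx.size:
            eta_p = Xp @ b
            if not np.isfinite(eta_p).all():
                raise FloatingPointError("non-finite linear predictor")
            pc = expit(eta_p)
            q = pc * se_ + (1.0 - pc) * (1.0 - sp_)
            q = np.clip(q, 1e-300, 1.0 - 1e-16)
            lp += float(np.log(q[yp]).sum() + np.log1p(-q[~yp]).sum())
        return lp

    kept = 0
    lp_cur = logpost(beta, se, sp)
    for t in range(total_iter):
        # --- beta: Metropolis on the collapsed (observed-data) posterior
        for _ in range(_INNER_MH_STEPS):
            prop = beta + step * (L @ rng.standard_normal(p))
            lp_prop = logpost(prop, se, sp)
            proposed_total += int(t >= n_burn)
            batch_n += 1
            if np.log(rng.random()) < lp_prop - lp_cur:
                beta, lp_cur = prop, lp_prop
                batch_acc += 1
                accepted_total += int(t >= n_burn)
        if t < n_burn:
            history[t] = beta
            if (t + 1) % 50 == 0:
                rate = batch_acc / batch_n
                step *= float(np.exp(np.clip(rate - 0.30, -0.5, 0.5)))
                batch_acc = batch_n = 0
            if (t + 1) % 200 == 0 and t + 1 >= 400:
                # learn the proposal shape from the post-transient half
                window = history[(t + 1) // 2:t + 1]
                cov = np.cov(window.T).reshape(p, p) + 1e-10 * np.eye(p)
                try:
                    L_new = np.linalg.cholesky(cov)
                    L, step = L_new, max(step, 1.0)
                except np.linalg.LinAlgError:
                    pass

        # --- latent status: full conditional given (beta, se, sp, y)
        pcase = expit(X @ beta)
        pz = pcase.copy()
        if part_idx.size:
            pc = pcase[part_idx]
            w1 = pc * np.where(yp, se, 1.0 - se)
            w0 = (1.0 - pc) * np.where(yp, 1.0 - sp, sp)
            pz[part_idx] = w1 / (w1 + w0)
        z = (rng.random(n) < pz).astype(float)

        # --- Se/Sp: exact conjugate updates given z (participants only)
        if misclass.mode == "beta_prior":
            zp = z[part_idx].astype(bool)
            a_se, b_se = misclass.se_prior
            a_sp, b_sp = misclass.sp_prior
            tp = int(np.sum(yp & zp)); fn = int(np.sum(~yp & zp))
            tn = int(np.sum(~yp & ~zp)); fp = int(np.sum(yp & ~zp))
            se = rng.beta(a_se + tp, b_se + fn)
            sp = rng.beta(a_sp + tn, b_sp + fp)
            lp_cur = logpost(beta, se, sp)

        if t >= n_burn and (t - n_burn) % thin == 0:
            beta_out[kept] = beta
            se_out[kept] = se
            sp_out[kept] = sp
            counts_out[kept] = np.bincount(cell_idx, weights=z, minlength=n_cells)
            prob_sum += pz  # Rao-Blackwellised per-child probability
            kept += 1

    acc_rate = accepted_total / max(1, proposed_total)
    return beta_out, se_out, sp_out, counts_out, prob_sum / max(1, kept), acc_rate


class LatentPrevalenceModel(BaseEstimator):
    """Sklearn-style estimator around the latent misclassification model.

    Parameters mirror :class:`LatentModelSpec` and :class:`MCMCSpec`; see the
    module docstring for the model.  After :meth:`fit`, ``draws_`` holds a
    :class:`PosteriorDraws` and :meth:`predict_proba` returns posterior case
    probabilities for screen-positive records (measurement-conditional for
    participants with an observed diagnosis, prior-predictive otherwise).
    """

    def __init__(self, misclass: MisclassSpec | None = None, prior_mean: float = 0.0,
                 prior_sd: float = 2.5, covariates: tuple[str, ...] = ("scq_score",),
                 center_scq: bool = True, n_chains: int = 3, burn_in: int = 5_000,
                 iterations: int = 10_000, thinning: int = 1, seed: int = 0):
        self.misclass = misclass
        self.prior_mean = prior_mean
        self.prior_sd = prior_sd
        self.covariates = covariates
        self.center_scq = center_scq
        self.n_chains = n_chains
        self.burn_in = burn_in
        self.iterations = iterations
        self.thinning = thinning
        self.seed = seed

    # -- design ------------------------------------------------------------
    def _design(self, records: pd.DataFrame, center: float) -> np.ndarray:
        cols = [np.ones(len(records))]
        for cov in self.covariates:
            if cov == "sex":
                x = (records["sex"] == "M").to_numpy(dtype=float)
            else:
                x = records[cov].to_numpy(dtype=float)
            if cov == "scq_score" and self.center_scq:
                x = x - center
            cols.append(x)
        X = np.column_stack(cols)
        if not np.isfinite(X).all():
            raise ValueError("non-finite covariate values")
        return X

    def fit(self, records: pd.DataFrame, y=None):
        misclass = self.misclass if self.misclass is not None else MisclassSpec()
        mcmc = MCMCSpec(self.n_chains, self.burn_in, self.iterations, self.seed, self.thinning)

        sp_mask = records["screen_positive"].to_numpy(dtype=bool)
        spr = records.loc[sp_mask]
        if spr.empty:
            raise ValueError("no screen-positive records: the latent model has no units")
        part = spr["participated"].fillna(False).to_numpy(dtype=bool)
        diag = spr["diagnosis"]
        if (part & diag.isna().to_numpy()).any():
            raise ValueError("participant without an observed diagnosis")
        if not part.any() and misclass.mode == "fixed":
            raise ValueError(
                "no diagnostic-phase participants; with fixed Se/Sp the model has "
                "no measurement information (use beta_prior mode for prior-only runs)"
            )
        y_part = (diag[part] == "positive").to_numpy(dtype=bool)

        center = float(spr["scq_score"].mean()) if (
            self.center_scq and "scq_score" in self.covariates) else 0.0
        X = self._design(spr, center)
        cells, cell_idx = _build_cells(records)

        names = ("intercept",) + tuple(self.covariates)
        chains = []
        for c in range(mcmc.n_chains):
            rng = rng_for(mcmc.seed, "latent", c)
            chains.append(_run_chain(
                rng, X, part, y_part, self.prior_mean, self.prior_sd, misclass,
                mcmc.burn_in, mcmc.iterations, mcmc.thinning, cell_idx, len(cells),
            ))
        beta = np.stack([c[0] for c in chains])
        se = np.stack([c[1] for c in chains])
        sp = np.stack([c[2] for c in chains])
        counts = np.stack([c[3] for c in chains])
        prob_mean = pd.Series(
            np.mean([c[4] for c in chains], axis=0), index=spr["id"].to_numpy(),
            name="posterior_case_probability",
        )
        self.center_ = center
        self.draws_ = PosteriorDraws(
            beta=beta, beta_names=names, se=se, sp=sp, case_counts=counts,
            cells=cells, prob_mean=prob_mean, center=center, misclass=misclass,
            acceptance_rate=tuple(float(c[5]) for c in chains),
        )
        return self

    def predict_proba(self, records: pd.DataFrame) -> np.ndarray:
        """Posterior case probability per screen-positive record."""
        if not hasattr(self, "draws_"):
            raise ValueError("model is not fitted")
        if not records["screen_positive"].all():
            raise ValueError("posterior case probabilities are defined for "
                             "screen-positive children only")
        d = self.draws_
        X = self._design(records, self.center_)
        beta = d.beta.reshape(-1, d.beta.shape[2])
        se = d.se.ravel()
        sp = d.sp.ravel()
        eta = X @ beta.T  # (n, draws)
        p = expit(eta)
        part = records["participated"].fillna(False).to_numpy(dtype=bool)
        out = p.mean(axis=1)
        if part.any():
            yy = (records.loc[part, "diagnosis"] == "positive").to_numpy(dtype=bool)
            pp = p[part]
            lik1 = np.where(yy[:, None], se[None, :], 1.0 - se[None, :])
            lik0 = np.where(yy[:, None], 1.0 - sp[None, :], sp[None, :])
            w1 = pp * lik1
            out[part] = (w1 / (w1 + (1.0 - pp) * lik0)).mean(axis=1)
        return out


def fit_latent_model(records: pd.DataFrame, model: LatentModelSpec | None = None,
                     mcmc: MCMCSpec | None = None) -> PosteriorDraws:
    """Functional wrapper over :class:`LatentPrevalenceModel`."""
    model = model or LatentModelSpec()
    mcmc = mcmc or MCMCSpec()
    est = LatentPrevalenceModel(
        misclass=model.misclass, prior_mean=model.prior_mean, prior_sd=model.prior_sd,
        covariates=model.covariates, center_scq=model.center_scq,
        n_chains=mcmc.n_chains, burn_in=mcmc.burn_in, iterations=mcmc.iterations,
        thinning=mcmc.thinning, seed=mcmc.seed,
    )
    return est.fit(records).draws_


def posterior_case_probabilities(draws: PosteriorDraws, records: pd.DataFrame) -> pd.Series:
    """Stored Rao–Blackwellised case probabilities for screen-positive records."""
    if not records["screen_positive"].all():
        raise ValueError("posterior case probabilities are defined for "
                         "screen-positive children only")
    try:
        return draws.prob_mean.loc[records["id"].to_numpy()]
    except KeyError as exc:
        raise KeyError(f"record id not in the fitted cohort: {exc}") from exc


# ------------------------------------------------------- post-stratification


def _stratum_tables(draws: PosteriorDraws, stratum_specs: Sequence[StratumSpec],
                    screening_sensitivity: float | None = None):
    """Per-draw stratum prevalence matrix and population weights."""
    labels = [s.label for s in stratum_specs]
    cells = draws.cells
    missing = set(cells["stratum"]) - set(labels)
    if missing:
        raise ValueError(f"no population size for strata: {sorted(missing)}")
    counts = draws.case_counts.reshape(-1, len(cells))  # (draws, cells)
    prev = np.empty((counts.shape[0], len(labels)))
    n_s = np.empty(len(labels))
    for j, lab in enumerate(labels):
        in_s = (cells["stratum"] == lab).to_numpy()
        if not in_s.any() or cells.loc[in_s, "n"].sum() == 0:
            raise ValueError(f"stratum {lab!r} has no sampled children")
        n_s[j] = cells.loc[in_s, "n"].sum()
        prev[:, j] = counts[:, in_s].sum(axis=1) / n_s[j]
    if screening_sensitivity is not None:
        if not (0.0 < screening_sensitivity <= 1.0):
            raise ValueError("screening_sensitivity must lie in (0, 1]")
        prev = np.minimum(prev / screening_sensitivity, 1.0)
    N = np.array([s.population_size for s in stratum_specs], dtype=float)
    return labels, prev, N


def _summarise(overall: np.ndarray, per_stratum: dict[str, np.ndarray] | None,
               scale: str) -> PrevalenceResult:
    f = 1000.0 if scale == "per_1000" else 1.0
    med, lo, hi = (float(np.quantile(overall, q)) for q in (0.5, 0.025, 0.975))
    strat = {}
    if per_stratum:
        for lab, arr in per_stratum.items():
            strat[lab] = {
                "median": float(np.quantile(arr, 0.5)) * f,
                "lower": float(np.quantile(arr, 0.025)) * f,
                "upper": float(np.quantile(arr, 0.975)) * f,
            }
    return PrevalenceResult(median=med * f, lower=lo * f, upper=hi * f,
                            scale=scale, stratum=strat, n_draws=overall.size)


def post_stratify(probabilities, records: pd.DataFrame | None,
                  stratum_specs: Sequence[StratumSpec], scale: str = "per_1000",
                  screening_sensitivity: float | None = None) -> PrevalenceResult:
    """Population prevalence by stratum weighting with known population sizes.

    ``probabilities`` is either a fitted :class:`PosteriorDraws` (full
    posterior summary, per-draw post-stratification) or a per-record case
    probability/indicator vector aligned with ``records`` (point estimate;
    screen-negative records should carry 0).  The optional
    ``screening_sensitivity`` divides stratum case totals by an assumed
    screening-phase sensitivity to correct for screen-negative false
    negatives (off by default).
    """
    if scale not in ("per_1", "per_1000"):
        raise ValueError("scale must be 'per_1' or 'per_1000'")
    if isinstance(probabilities, PosteriorDraws):
        labels, prev, N = _stratum_tables(probabilities, stratum_specs, screening_sensitivity)
        overall = prev @ (N / N.sum())
        return _summarise(overall, {lab: prev[:, j] for j, lab in enumerate(labels)}, scale)

    probs = np.asarray(probabilities, dtype=float)
    if records is None or len(probs) != len(records):
        raise ValueError("per-child probabilities require an aligned records frame")
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    labels = [s.label for s in stratum_specs]
    N = np.array([s.population_size for s in stratum_specs], dtype=float)
    strat_prev = []
    for lab in labels:
        mask = (records["stratum"] == lab).to_numpy()
        if not mask.any():
            raise ValueError(f"stratum {lab!r} has no sampled children")
        p = probs[mask].sum() / mask.sum()
        if screening_sensitivity is not None:
            p = min(p / screening_sensitivity, 1.0)
        strat_prev.append(p)
    strat_prev = np.array(strat_prev)
    overall = np.array([float(strat_prev @ (N / N.sum()))])
    return _summarise(overall, {lab: np.array([v]) for lab, v in zip(labels, strat_prev)}, scale)


def sex_grade_breakdown(draws: PosteriorDraws, records: pd.DataFrame,
                        stratum_specs: Sequence[StratumSpec],
                        scale: str = "per_1000") -> dict:
    """Post-stratified prevalence restricted to each sex and grade subgroup.

    Subgroup population sizes use proportional allocation within stratum
    (N_{s,g} = N_s * n_{s,g} / n_s), so per draw the subgroup estimates
    combine back to the overall estimate exactly.  Returns a dict with keys
    ``('sex', level)`` and ``('grade', level)`` mapping to
    :class:`PrevalenceResult`, plus ``'adjusted_sex_ratio'`` (posterior
    median and CrI of the per-draw male/female rate ratio) when both sexes
    are present.
    """
    cells = draws.cells
    counts = draws.case_counts.reshape(-1, len(cells))
    labels = [s.label for s in stratum_specs]
    N = {s.label: float(s.population_size) for s in stratum_specs}
    n_s = {lab: cells.loc[cells["stratum"] == lab, "n"].sum() for lab in labels}

    def subgroup(column: str, level) -> np.ndarray | None:
        sel = (cells[column] == level).to_numpy()
        if not sel.any():
            return None
        num = np.zeros(counts.shape[0])
        den = 0.0
        for lab in labels:
            in_cell = sel & (cells["stratum"] == lab).to_numpy()
            n_sg = cells.loc[in_cell, "n"].sum()
            if n_sg == 0:
                continue
            w = N[lab] * n_sg / n_s[lab]
            num += w * counts[:, in_cell].sum(axis=1) / n_sg
            den += w
        return num / den if den > 0 else None

    out: dict = {}
    rates = {}
    for sex in ("M", "F"):
        arr = subgroup("sex", sex)
        if arr is not None:
            out[("sex", sex)] = _summarise(arr, None, scale)
            rates[sex] = arr
    for grade in sorted(cells["grade"].unique()):
        arr = subgroup("grade", int(grade))
        if arr is not None:
            out[("grade", int(grade))] = _summarise(arr, None, scale)
    if "M" in rates and "F" in rates:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = rates["M"] / rates["F"]
        ratio = ratio[np.isfinite(ratio)]
        if ratio.size:
            out["adjusted_sex_ratio"] = {
                "median": float(np.quantile(ratio, 0.5)),
                "lower": float(np.quantile(ratio, 0.025)),
                "upper": float(np.quantile(ratio, 0.975)),
            }
    return out


def pooled_crude_prevalence(records: pd.DataFrame,
                            stratum_specs: Sequence[StratumSpec]) -> float:
    """Participation-weighted crude prevalence per 1,000 (pre-Bayesian step).

    Interpretation utility: positive participants are inverse-weighted by
    their fitted participation probability (logistic in the screening score),
    summed per stratum over the screened denominator, and pooled with known
    population sizes.  This is one reading of a "pooled prevalence adjusted
    for participation bias"; the model-based estimate is the primary result.
    """
    from .participation import ParticipationModel

    est = ParticipationModel(covariates=("scq_score",)).fit(records)
    spr = records.loc[records["screen_positive"]]
    w = 1.0 / est.predict_proba(spr)
    pos = (spr["diagnosis"] == "positive").fillna(False).to_numpy(dtype=bool)
    part = spr["participated"].fillna(False).to_numpy(dtype=bool)
    N = np.array([s.population_size for s in stratum_specs], dtype=float)
    prev = []
    for s in stratum_specs:
        in_s = (records["stratum"] == s.label).to_numpy()
        n_s = in_s.sum()
        if n_s == 0:
            raise ValueError(f"stratum {s.label!r} has no sampled children")
        sp_in_s = (spr["stratum"] == s.label).to_numpy()
        cases = float(w[sp_in_s & part & pos].sum())
        prev.append(min(cases / n_s, 1.0))
    return float(np.array(prev) @ (N / N.sum()) * 1000.0)
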