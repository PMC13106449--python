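"""Self-validation studies: simulation-based checks of the whole pipeline.

These routines generate cohorts with known ground truth, run the estimation
machinery, and measure how well it recovers the truth — the closed-form
Rogan–Gladen oracle in the intercept-only limit, frequentist coverage of the
95% credible interval over seeded replicates, and participation-slope
recovery.  They are the package's evidence that the implementation does what
the model promises, and are exercised by the test suite and the acceptance
script alike.
"""

from __future__ import annotations

import numpy as np

from ._rng import child_seed
from .cohort import LogisticSimConfig, SimConfig, StratumSpec, simulate_logistic_cohort, simulate_population
from .diagnostics import effective_sample_size
from .latent import LatentModelSpec, MCMCSpec, _stratum_tables, fit_latent_model, post_stratify, rogan_gladen
from .participation import fit_participation


def oracle_cohort(seed: int, n: int = 2_000, prevalence: float = 0.25) -> tuple:
    """Single-stratum cohort where everyone screens positive and participates.

    In this limit the intercept-only latent model has a closed-form target:
    the Rogan–Gladen correction of the observed positive fraction.
    """
    cfg = SimConfig(
        stratum_specs=(StratumSpec("ALL", 10_000, n),),
        true_prevalence_by_stratum={"ALL": prevalence},
        screen_cutoff=0,
        participation_intercept=50.0,
        participation_slope_scq=0.0,
        seed=seed,
    )
    return cfg, simulate_population(cfg)


def oracle_agreement(seed: int, n: int = 2_000,
                     mcmc: MCMCSpec | None = None) -> dict:
    """Intercept-only posterior median vs the Rogan–Gladen closed form.

    Returns the posterior median, the oracle value, their absolute
    difference, and the Monte-Carlo standard error of the median (so the
    difference can be judged against sampling noise).
    """
    cfg, records = oracle_cohort(child_seed(seed, "replicates", 0), n=n)
    mcmc = mcmc or MCMCSpec(n_chains=3, burn_in=1_000, iterations=3_000,
                            seed=child_seed(seed, "replicates", 0, 1))
    draws = fit_latent_model(records, LatentModelSpec(covariates=()), mcmc)
    res = post_stratify(draws, records, cfg.stratum_specs, scale="per_1")
    apparent = float((records["diagnosis"] == "positive").mean())
    oracle = rogan_gladen(apparent, cfg.se, cfg.sp).estimate
    _, prev, N = _stratum_tables(draws, cfg.stratum_specs)
    overall = prev @ (N / N.sum())
    ess = effective_sample_size({"x": overall.reshape(mcmc.n_chains, -1)})["x"]
    mcse_median = 1.253 * float(overall.std()) / np.sqrt(ess)
    return {
        "posterior_median": res.median,
        "rogan_gladen": oracle,
        "abs_diff": abs(res.median - oracle),
        "mc_se_median": mcse_median,
        "n": n,
    }


def detectable_truth_per_1000(records, stratum_specs) -> float:
    """Post-stratified screen-detectable true prevalence of a synthetic cohort.

    The primary analysis counts screen-negative children as non-cases, so its
    estimand is the prevalence of true cases among screen-positives scaled to
    the stratum populations; this computes that quantity from the generator's
    ground truth.
    """
    num = den = 0.0
    for s in stratum_specs:
        m = (records["stratum"] == s.label).to_numpy()
        detectable = float((records["true_status"].astype(bool).to_numpy()
                            & records["screen_positive"].to_numpy() & m).sum()) / m.sum()
        num += s.population_size * detectable
        den += s.population_size
    return 1_000.0 * num / den


def interval_coverage_study(seed: int, n_replicates: int = 100,
                            n_chains: int = 2, burn_in: int = 1_000,
                            iterations: int = 2_000) -> dict:
    """Frequentist coverage of the 95% CrI over seeded synthetic replicates.

    Each replicate draws a fresh model-consistent cohort (diagnostic
    Se = 0.85, Sp = 0.75), fits the latent model at reduced MCMC settings and
    checks whether the credible interval covers the replicate's
    screen-detectable true prevalence.
    """
    covered = 0
    for r in range(n_replicates):
        cfg = LogisticSimConfig(seed=child_seed(seed, "replicates", r))
        records = simulate_logistic_cohort(cfg)
        draws = fit_latent_model(
            records, LatentModelSpec(),
            MCMCSpec(n_chains=n_chains, burn_in=burn_in, iterations=iterations,
                     seed=child_seed(seed, "replicates", r, 1)))
        res = post_stratify(draws, records, cfg.stratum_specs)
        truth = detectable_truth_per_1000(records, cfg.stratum_specs)
        covered += int(res.lower <= truth <= res.upper)
    return {"covered": covered, "n": n_replicates,
            "coverage_percent": 100.0 * covered / n_replicates}


def slope_recovery(seed: int, n: int = 2_000, slope: float = 0.15,
                   intercept: float = -3.2) -> dict:
    """Participation-slope recovery on a cohort where everyone screens positive."""
    cfg = SimConfig(
        stratum_specs=(StratumSpec("A", 50_000, n),),
        true_prevalence_by_stratum={"A": 0.15},
        screen_cutoff=0,
        participation_intercept=intercept,
        participation_slope_scq=slope,
        seed=child_seed(seed, "replicates", 10),
    )
    records = simulate_population(cfg)
    fit = fit_participation(records, covariates=("scq_score",))
    est, se = fit.params["scq_score"], fit.bse["scq_score"]
    return {"estimate": est, "se": se, "true": slope,
            "abs_error_in_se_units": abs(est - slope) / se, "n": n}


def iid_diagnostic_fixture(seed: int, n_total: int = 10_000) -> dict:
    """R-hat and ESS on chains of independent standard-normal draws."""
    rng = np.random.default_rng(child_seed(seed, "replicates", 20))
    chains = rng.standard_normal((2, n_total // 2))
    from .diagnostics import gelman_rubin
    rhat = gelman_rubin({"x": chains})["x"]
    ess = effective_sample_size({"x": chains})["x"]
    return {"rhat": rhat, "ess": ess, "ess_fraction": ess / n_total, "n": n_total}
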