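"""Robustness analyses for the latent prevalence model.

Three instruments:

* :func:`deterministic_grid` — refit the model at every (Se, Sp) pair of a
  grid (default 4x4 = 16 cells over Se in {0.80..0.95}, Sp in {0.65..0.80})
  and tabulate the post-stratified estimate per cell.
* :func:`probabilistic_sensitivity` — treat Se and Sp as uncertain with
  informative Beta priors (defaults Beta(85,15), mean 0.85, and Beta(60,40),
  mean 0.60) and propagate that uncertainty into the posterior.
* :func:`cap_hr` — cap the high-risk stratum's per-draw prevalence at a
  maximum (default scan 100/95/90/85%) before post-stratification, probing
  the assumption that the HR stratum is (nearly) saturated with cases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import child_seed
from .cohort import StratumSpec
from .latent import (
    LatentModelSpec,
    MCMCSpec,
    MisclassSpec,
    PosteriorDraws,
    PrevalenceResult,
    _stratum_tables,
    _summarise,
    fit_latent_model,
    post_stratify,
)


@dataclass(frozen=True)
class GridSpec:
    se_values: tuple[float, ...] = (0.80, 0.85, 0.90, 0.95)
    sp_values: tuple[float, ...] = (0.65, 0.70, 0.75, 0.80)

    def __post_init__(self) -> None:
        for name, vals in (("se_values", self.se_values), ("sp_values", self.sp_values)):
            if not vals or any(not (0.0 < v < 1.0) for v in vals):
                raise ValueError(f"{name} must be non-empty probabilities in (0, 1)")
        for se in self.se_values:
            for sp in self.sp_values:
                if se + sp <= 1.0:
                    raise ValueError(f"grid cell ({se}, {sp}) violates se + sp > 1")

    @property
    def cells(self) -> list[tuple[float, float]]:
        return [(se, sp) for se in self.se_values for sp in self.sp_values]


@dataclass(frozen=True)
class CapSpec:
    hr_caps: tuple[float, ...] = (1.00, 0.95, 0.90, 0.85)

    def __post_init__(self) -> None:
        if not self.hr_caps or any(not (0.0 < c <= 1.0) for c in self.hr_caps):
            raise ValueError("caps must lie in (0, 1]")


def deterministic_grid(records: pd.DataFrame, base_model: LatentModelSpec,
                       grid: GridSpec, mcmc: MCMCSpec,
                       stratum_specs: Sequence[StratumSpec],
                       scale: str = "per_1000") -> pd.DataFrame:
    """One full model fit per (Se, Sp) grid cell.

    Each cell reuses the primary seed through a per-cell derived stream, so
    cells are reproducible and differences between cells reflect the Se/Sp
    assumption, not the random stream.  Returns a tidy frame with columns
    ``se, sp, median, lower, upper`` on ``scale``.
    """
    rows = []
    for idx, (se, sp) in enumerate(grid.cells):
        model = dataclasses.replace(base_model, misclass=MisclassSpec(mode="fixed", se=se, sp=sp))
        cell_mcmc = dataclasses.replace(mcmc, seed=child_seed(mcmc.seed, "grid", idx))
        draws = fit_latent_model(records, model, cell_mcmc)
        res = post_stratify(draws, records, stratum_specs, scale=scale)
        rows.append({"se": se, "sp": sp, "median": res.median,
                     "lower": res.lower, "upper": res.upper})
    return pd.DataFrame(rows)


def grid_matrix(grid_table: pd.DataFrame, value: str = "median",
                percent: bool = False) -> pd.DataFrame:
    """Pivot a grid table into an Se x Sp matrix (heat-map ready).

    ``percent=True`` renders per-1,000 values as percentages.
    """
    mat = grid_table.pivot(index="se", columns="sp", values=value)
    return mat / 10.0 if percent else mat


def probabilistic_sensitivity(records: pd.DataFrame, base_model: LatentModelSpec,
                              se_prior: tuple[float, float], sp_prior: tuple[float, float],
                              mcmc: MCMCSpec, stratum_specs: Sequence[StratumSpec],
                              scale: str = "per_1000") -> dict:
    """Joint posterior over (beta, z, Se, Sp) with Beta priors on Se/Sp.

    Returns ``{"prevalence": PrevalenceResult, "se": summary, "sp": summary}``
    where each summary has the posterior mean, median and equal-tailed 95%
    interval, plus the prior means for reference.
    """
    misclass = MisclassSpec(mode="beta_prior", se_prior=tuple(se_prior),
                            sp_prior=tuple(sp_prior))
    model = dataclasses.replace(base_model, misclass=misclass)
    draws = fit_latent_model(records, model, mcmc)
    res = post_stratify(draws, records, stratum_specs, scale=scale)

    def summary(arr: np.ndarray, prior: tuple[float, float]) -> dict:
        a, b = prior
        return {
            "mean": float(arr.mean()),
            "median": float(np.quantile(arr, 0.5)),
            "lower": float(np.quantile(arr, 0.025)),
            "upper": float(np.quantile(arr, 0.975)),
            "prior_mean": a / (a + b),
        }

    return {"prevalence": res, "se": summary(draws.se.ravel(), se_prior),
            "sp": summary(draws.sp.ravel(), sp_prior), "draws": draws}


def beta_prior_mean(a: float, b: float) -> float:
    """Mean a / (a + b) of a Beta(a, b) prior."""
    if a <= 0 or b <= 0:
        raise ValueError("Beta parameters must be positive")
    return a / (a + b)


def cap_hr(draws: PosteriorDraws, cap: float, stratum_specs: Sequence[StratumSpec],
           hr_label: str = "HR", scale: str = "per_1000") -> PrevalenceResult:
    """Post-stratified prevalence with the HR stratum capped at ``cap`` per draw."""
    if not (0.0 < cap <= 1.0):
        raise ValueError("cap must lie in (0, 1]")
    labels, prev, N = _stratum_tables(draws, stratum_specs)
    if hr_label not in labels:
        raise ValueError(f"no {hr_label!r} stratum among {labels}")
    j = labels.index(hr_label)
    prev = prev.copy()
    prev[:, j] = np.minimum(prev[:, j], cap)
    overall = prev @ (N / N.sum())
    return _summarise(overall, {lab: prev[:, k] for k, lab in enumerate(labels)}, scale)


def cap_scan(draws: PosteriorDraws, caps: CapSpec, stratum_specs: Sequence[StratumSpec],
             hr_label: str = "HR", scale: str = "per_1000") -> pd.DataFrame:
    """:func:`cap_hr` over a cap list; tidy frame (cap, median, lower, upper)."""
    rows = []
    for cap in caps.hr_caps:
        res = cap_hr(draws, cap, stratum_specs, hr_label=hr_label, scale=scale)
        rows.append({"cap": cap, "median": res.median, "lower": res.lower,
                     "upper": res.upper})
    return pd.DataFrame(rows)
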