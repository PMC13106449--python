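"""Convergence diagnostics for MCMC output.

R-hat is the rank-normalised split potential scale reduction factor and ESS
the rank-normalised bulk effective sample size with Geyer initial-monotone
truncation of the autocorrelation sum, both as implemented by ``arviz``
(Vehtari et al. conventions).  Degenerate inputs (a constant parameter) are
flagged with NaN and a reason rather than raising.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import arviz as az
import numpy as np


def _as_chain_array(draws) -> np.ndarray:
    arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected draws with shape (chains, iterations)")
    if arr.shape[0] < 2:
        raise ValueError("at least 2 chains are required")
    if arr.shape[1] < 4:
        raise ValueError("at least 4 draws per chain are required (split-chain)")
    return arr


def _is_degenerate(arr: np.ndarray) -> bool:
    return bool(np.ptp(arr) == 0.0)


def gelman_rubin(chains: Mapping[str, np.ndarray]) -> dict[str, float]:
    """Rank-normalised split R-hat per parameter; NaN for degenerate draws."""
    out = {}
    for name, draws in chains.items():
        arr = _as_chain_array(draws)
        if _is_degenerate(arr):
            out[name] = float("nan")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[name] = float(az.rhat(az.convert_to_dataset(arr))["x"])
    return out


def effective_sample_size(chains: Mapping[str, np.ndarray]) -> dict[str, float]:
    """Bulk ESS per parameter (autocorrelation-based); NaN for degenerate draws."""
    out = {}
    for name, draws in chains.items():
        arr = _as_chain_array(draws)
        if _is_degenerate(arr):
            out[name] = float("nan")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[name] = float(az.ess(az.convert_to_dataset(arr), method="bulk")["x"])
    return out


@dataclass(frozen=True)
class DiagnosticReport:
    """Per-parameter R-hat/ESS with pass/warn/fail flags.

    Thresholds follow current practice: warn above R-hat 1.01, fail above
    1.05; warn when ESS falls below 400.  ``passed`` is False only on an
    R-hat failure; degenerate parameters are reported, not failed.
    """

    rhat: dict[str, float]
    ess: dict[str, float]
    n_chains: int
    draws_per_chain: int
    flags: dict[str, str] = field(default_factory=dict)
    passed: bool = True
    rhat_warn: float = 1.01
    rhat_fail: float = 1.05
    ess_warn: float = 400.0

    def to_json(self) -> str:
        def clean(d):
            return {k: (None if np.isnan(v) else v) for k, v in d.items()}
        return json.dumps({
            "rhat": clean(self.rhat), "ess": clean(self.ess),
            "n_chains": self.n_chains, "draws_per_chain": self.draws_per_chain,
            "flags": self.flags, "passed": self.passed,
            "thresholds": {"rhat_warn": self.rhat_warn, "rhat_fail": self.rhat_fail,
                           "ess_warn": self.ess_warn},
        }, indent=2)


def diagnose(chains: Mapping[str, np.ndarray], rhat_warn: float = 1.01,
             rhat_fail: float = 1.05, ess_warn: float = 400.0) -> DiagnosticReport:
    """Run both diagnostics over named (chains, draws) arrays and flag them."""
    rhat = gelman_rubin(chains)
    ess = effective_sample_size(chains)
    flags = {}
    passed = True
    first = next(iter(chains.values()))
    arr = _as_chain_array(first)
    for name in chains:
        r, e = rhat[name], ess[name]
        if np.isnan(r):
            flags[name] = "degenerate (zero variance)"
        elif r > rhat_fail:
            flags[name] = "fail (R-hat)"
            passed = False
        elif r > rhat_warn or (not np.isnan(e) and e < ess_warn):
            flags[name] = "warn"
        else:
            flags[name] = "ok"
    return DiagnosticReport(rhat=rhat, ess=ess, n_chains=arr.shape[0],
                            draws_per_chain=arr.shape[1], flags=flags, passed=passed,
                            rhat_warn=rhat_warn, rhat_fail=rhat_fail, ess_warn=ess_warn)


def plot_traces(chains: Mapping[str, np.ndarray], path) -> None:
    """Optional trace/density plot bundle (never on the critical path)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(chains)
    fig, axes = plt.subplots(len(names), 2, figsize=(9, 2.2 * len(names)), squeeze=False)
    for i, name in enumerate(names):
        arr = _as_chain_array(chains[name])
        for c in range(arr.shape[0]):
            axes[i, 0].plot(arr[c], lw=0.4)
            axes[i, 1].hist(arr[c], bins=40, histtype="step", density=True)
        axes[i, 0].set_title(f"{name} trace", fontsize=8)
        axes[i, 1].set_title(f"{name} density", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
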