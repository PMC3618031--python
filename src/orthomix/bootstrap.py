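"""Parametric-bootstrap standard errors for the mixture parameters.

Each replicate (i) draws per-category gene counts from a multinomial with
the estimated mixing weights, (ii) turns those counts into replicate weights
counts/n, (iii) simulates n effect pairs from the resulting mixture with the
estimated component moments, and (iv) refits the constrained EM.  The SE of
each parameter is the sample standard deviation of its fitted values across
replicates.

Replicate fits are warm-started at the original estimates, which keeps the
component labels aligned across replicates (the constraints plus the warm
start pin component identities, so no label-switching correction is needed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixture import MixtureParameters, N_COMPONENTS, fit_em
from .synthetic import simulate_effect_pairs

PARAM_COLUMNS = [
    f"{base}_{k}"
    for k in range(N_COMPONENTS)
    for base in ("pi", "mu_a", "mu_h", "var_a", "cov", "var_h")
]


def params_to_series(params: MixtureParameters) -> pd.Series:
    """Flatten mixture parameters to the canonical bootstrap vector.

    The covariance entry is rho_k * sigma_ak * sigma_hk, matching how the
    within-component dependence is usually tabulated.
    """
    cov = params.cov_ah
    out = {}
    for k in range(N_COMPONENTS):
        out[f"pi_{k}"] = params.weights[k]
        out[f"mu_a_{k}"] = params.mean_a[k]
        out[f"mu_h_{k}"] = params.mean_h[k]
        out[f"var_a_{k}"] = params.var_a[k]
        out[f"cov_{k}"] = cov[k]
        out[f"var_h_{k}"] = params.var_h[k]
    return pd.Series(out)[PARAM_COLUMNS]


@dataclass
class BootstrapResult:
    """Replicate estimates and the derived standard errors."""

    estimates: pd.DataFrame  # successful replicates x parameters
    se: pd.Series
    component_counts: np.ndarray  # B x 9 multinomial draws
    n_failed: int

    @property
    def B(self) -> int:
        return len(self.estimates)


def draw_component_counts(
    weights, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Multinomial draw of per-category gene counts (they sum to n)."""
    w = np.asarray(weights, dtype=float)
    if n <= 0:
        raise ValueError("n must be positive")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multinomial(n, w)


def bootstrap_replicate(
    params_hat: MixtureParameters,
    n: int,
    seed: int | np.random.Generator,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[MixtureParameters, np.ndarray]:
    """One parametric-bootstrap replicate: resample, refit, return the fit.

    Returns ``(fitted_params, counts)``.  A category whose multinomial count
    is zero gets generating weight zero for this replicate; its moment
    parameters are carried along so the refit can repopulate it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = draw_component_counts(params_hat.weights, n, rng)
    gen = params_hat.copy()
    gen.weights = counts / n
    pairs, _ = simulate_effect_pairs(gen, n, rng)
    fit = fit_em(pairs, init=params_hat, tol=tol, max_iter=max_iter)
    return fit.params, counts


def bootstrap_se(estimates: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
    """Per-parameter sample SD across replicates: sqrt(sum (x - mean)^2 / (B-1))."""
    est = estimates.to_numpy() if isinstance(estimates, pd.DataFrame) else np.asarray(estimates)
    est = np.atleast_2d(est)
    if est.shape[0] < 2:
        raise ValueError("need at least 2 bootstrap replicates to estimate an SE")
    se = est.std(axis=0, ddof=1)
    if isinstance(estimates, pd.DataFrame):
        return pd.Series(se, index=estimates.columns)
    return se


def run_bootstrap(
    params_hat: MixtureParameters,
    n: int,
    B: int = 200,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> BootstrapResult:
    """Full bootstrap: B replicates, SEs from the successful ones."""
    if B < 2:
        raise ValueError("B must be at least 2")
    ss = np.random.SeedSequence(seed)
    rows = []
    count_rows = []
    n_failed = 0
    for child in ss.spawn(B):
        try:
            fitted, counts = bootstrap_replicate(
                params_hat, n, np.random.default_rng(child), tol=tol, max_iter=max_iter
            )
        except (RuntimeError, FloatingPointError) as exc:  # EM failure in a replicate
            warnings.warn(f"bootstrap replicate failed and was excluded: {exc}", RuntimeWarning)
            n_failed += 1
            continue
        rows.append(params_to_series(fitted))
        count_rows.append(counts)
    estimates = pd.DataFrame(rows).reset_index(drop=True)
    return BootstrapResult(
        estimates=estimates,
        se=bootstrap_se(estimates),
        component_counts=np.asarray(count_rows),
        n_failed=n_failed,
    )
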