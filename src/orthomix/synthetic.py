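"""Synthetic two-species expression data with known mixture structure.

The generator emulates gene-level, log-scale expression matrices for two
species (``a`` — the animal model, ``h`` — human) whose per-gene treatment
effects are drawn from the nine-component sign-constrained bivariate normal
mixture.  Each gene i, sample j of species a follows

    X_aij = beta0_ai + beta1_ai * T_aj + e_aij,   e_aij ~ N(0, sigma_a^2)

and analogously for species h, where T is a {0, 1} subtype indicator and the
effect pair (beta1_ai, beta1_hi) comes from the mixture.  Every draw is
recorded so downstream estimation, fitting and classification can be checked
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixture import MixtureParameters, N_COMPONENTS

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "reference_mixture",
    "REFERENCE_N_PAIRS",
    "REFERENCE_WEIGHT_SE",
    "simulate_effect_pairs",
    "simulate_expression",
]

#: Number of ortholog pairs in the dog-human lymphoma dataset the reference
#: estimates come from.
REFERENCE_N_PAIRS = 6566

#: Bootstrap standard errors reported alongside the reference mixing weights.
REFERENCE_WEIGHT_SE = np.array([0.077, 0.005, 0.001, 0.004, 0.003, 0.008, 0.004, 0.077, 0.008])


def reference_mixture() -> MixtureParameters:
    """Published mixture parameter estimates from a dog-human DLBCL study.

    These are the fitted weights, means, variances and covariances of the
    nine categories for 6,566 ortholog pairs, used here as the default
    generating truth for simulations.  The printed weights sum to 0.999 from
    rounding; they are renormalized.  The covariance column is converted to
    a correlation; category 4 (weight 0.000) has its printed zero variances
    kept as-is, which is valid for generation because it draws no genes.
    """
    weights = np.array([0.823, 0.001, 0.001, 0.001, 0.000, 0.020, 0.011, 0.130, 0.012])
    mean_a = np.array([0.0, 0.341, -0.602, 0.495, -1.131, 0.0, 0.0, 0.331, -0.478])
    mean_h = np.array([0.0, 0.022, -0.831, -0.564, 0.758, 0.492, -0.517, 0.0, 0.0])
    var_a = np.array([0.013, 0.004, 0.199, 0.042, 0.000, 0.020, 0.034, 0.018, 0.011])
    var_h = np.array([0.012, 0.022, 0.089, 0.119, 0.000, 0.058, 0.040, 0.025, 0.042])
    cov = np.array([0.0, 0.001, -0.128, -0.042, 0.000, 0.0, 0.0, 0.0, 0.0])
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(cov != 0, cov / np.sqrt(var_a * var_h), 0.0)
    params = MixtureParameters(weights / weights.sum(), mean_a, mean_h, var_a, var_h, corr)
    params.validate()
    return params


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator."""

    category: np.ndarray  # per-gene integer 0..8
    beta1a: np.ndarray
    beta1h: np.ndarray

    def to_frame(self, gene_a=None, gene_h=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"category": self.category, "beta1a": self.beta1a, "beta1h": self.beta1h}
        )
        if gene_a is not None:
            df.insert(0, "gene_a", gene_a)
        if gene_h is not None:
            df.insert(1 if gene_a is not None else 0, "gene_h", gene_h)
        return df


@dataclass
class SimulationConfig:
    """Study conditions for the expression-level generator.

    Sample counts mirror the lymphoma study: 14 dogs (9 GCB, 5 ABC) and 156
    humans (79 GCB, 77 ABC), with class 0 = GCB as reference and class 1 =
    ABC.  Residual SDs are chosen so the spread of null-gene effect
    estimates at these sample sizes matches the reference null-component
    variances (0.013 / 0.012).  Intercepts are i.i.d. normal on a
    log-intensity scale.
    """

    n_genes: int = REFERENCE_N_PAIRS
    n_samples_a: tuple[int, int] = (9, 5)  # (class 0, class 1) for species a
    n_samples_h: tuple[int, int] = (79, 77)
    mixture: MixtureParameters = field(default_factory=reference_mixture)
    residual_sd_a: float = 0.20
    residual_sd_h: float = 0.68
    intercept_mean_sd: tuple[float, float] = (8.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for name, counts in (("n_samples_a", self.n_samples_a), ("n_samples_h", self.n_samples_h)):
            if min(counts) < 2:
                raise ValueError(f"{name}: need at least 2 samples per class, got {counts}")
        if self.residual_sd_a < 0 or self.residual_sd_h < 0:
            raise ValueError("residual SDs must be non-negative (0 = noiseless)")
        self.mixture.validate()


def _check_generative(params: MixtureParameters) -> None:
    params.validate()
    active = params.weights > 0
    det = params.var_a * params.var_h * (1.0 - params.corr**2)
    bad = active & (det <= 0)
    if np.any(bad):
        raise ValueError(
            f"component covariance not positive definite for active components "
            f"{np.flatnonzero(bad).tolist()}"
        )


def simulate_effect_pairs(
    params: MixtureParameters, n: int, seed: int | np.random.Generator
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw ``n`` effect pairs from the mixture.

    Category counts are a single multinomial draw with the mixing weights as
    cell probabilities; conditional on its category each pair is bivariate
    normal with that component's mean and covariance.  Returns the pair
    table (columns ``gene_a``, ``gene_h``, ``beta1a``, ``beta1h``) in a
    shuffled gene order plus the ground truth.

    Note the components are plain (untruncated) normals: only the component
    *means* are sign-constrained, so an individual category-1 effect may be
    negative.
    """
    if n < 1:
        raise ValueError("n must be positive")
    _check_generative(params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n, params.weights)

    category = np.repeat(np.arange(N_COMPONENTS), counts)
    beta1a = np.empty(n)
    beta1h = np.empty(n)
    pos = 0
    for k in range(N_COMPONENTS):
        c = counts[k]
        if c == 0:
            continue
        sa = np.sqrt(params.var_a[k])
        sh = np.sqrt(params.var_h[k])
        rho = params.corr[k]
        z1 = rng.standard_normal(c)
        z2 = rng.standard_normal(c)
        beta1a[pos : pos + c] = params.mean_a[k] + sa * z1
        beta1h[pos : pos + c] = params.mean_h[k] + sh * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        pos += c

    perm = rng.permutation(n)
    category, beta1a, beta1h = category[perm], beta1a[perm], beta1h[perm]
    gene_a = np.array([f"a{i:06d}" for i in range(n)])
    gene_h = np.array([f"h{i:06d}" for i in range(n)])
    pairs = pd.DataFrame(
        {"gene_a": gene_a, "gene_h": gene_h, "beta1a": beta1a, "beta1h": beta1h}
    )
    return pairs, SyntheticTruth(category=category, beta1a=beta1a, beta1h=beta1h)


def simulate_expression(config: SimulationConfig):
    """Generate paired expression matrices for both species.

    Returns ``(expr_a, expr_h, truth)`` where each expression set holds a
    genes x samples matrix and the per-sample {0, 1} subtype labels.  A
    master seed spawns independent substreams for the effect pairs and each
    species' intercepts/residuals, so stages are individually reproducible.
    """
    from .effects import ExpressionSet  # local import to avoid a cycle

    config.validate()
    ss = np.random.SeedSequence(config.seed)
    ss_pairs, ss_a, ss_h = ss.spawn(3)

    pairs, truth = simulate_effect_pairs(
        config.mixture, config.n_genes, np.random.default_rng(ss_pairs)
    )

    def one_species(gene_ids, beta1, n_per_class, sd, sub_ss, prefix):
        rng = np.random.default_rng(sub_ss)
        n0, n1 = n_per_class
        treatment = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
        mu0, sd0 = config.intercept_mean_sd
        beta0 = rng.normal(mu0, sd0, size=len(gene_ids))
        values = (
            beta0[:, None]
            + np.outer(beta1, treatment)
            + (rng.standard_normal((len(gene_ids), n0 + n1)) * sd if sd > 0 else 0.0)
        )
        samples = [f"{prefix}s{j:03d}" for j in range(n0 + n1)]
        frame = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=samples)
        return ExpressionSet(values=frame, treatment=treatment)

    expr_a = one_species(
        pairs["gene_a"].to_numpy(), truth.beta1a, config.n_samples_a,
        config.residual_sd_a, ss_a, "a",
    )
    expr_h = one_species(
        pairs["gene_h"].to_numpy(), truth.beta1h, config.n_samples_h,
        config.residual_sd_h, ss_h, "h",
    )
    return expr_a, expr_h, truth
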