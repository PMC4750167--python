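"""Whole-genome regression by single-site Gibbs sampling.

Four models share one sampler and differ only in their priors:

================  ======  ==================  =======================
model             pi      effect variance     variance df (gen, res)
================  ======  ==================  =======================
BayesB            0.99    one per SNP         (4, 10)
BayesC            0.99    common to all SNPs  (4, 10)
BayesC0           0       common              (4, 10)
GBLUP             0       common              (100, 100)
================  ======  ==================  =======================

The model for animal i is ``y_i = sum_k Xf_ik beta_k + sum_j x_ij alpha_j
+ e_i`` with dosages centered by twice the training allele frequency,
hatch-within-generation classes as flat-prior fixed effects, a spike-and-
slab (or ridge, for pi = 0) prior on SNP effects, and scaled-inverse-chi-
square priors on the variance components.  With df = 100 the common effect
variance is pinned near its prior scale, which reproduces GBLUP in its
equivalent marker-effects form; with df = 4 it is estimated mostly from
the data.

The inclusion indicator of each SNP is sampled with the effect integrated
out, so the sampler mixes over models without reversible-jump moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gibbs import gibbs_chain
from .io_formats import GenotypeMatrix, PhenotypeTable
from .window_variance import WindowAssignment, assign_windows

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "ModelData",
    "ModelFit",
    "MODEL_TAGS",
    "default_prior",
    "derive_scales",
    "locus_inclusion_probability",
    "locus_variance_conditional",
    "common_variance_conditional",
    "residual_variance_conditional",
    "sample_scaled_inv_chi2",
    "build_model_data",
    "run_chain",
    "gebv",
]

MODEL_TAGS = ("bayesB", "bayesC", "bayesC0", "gblup")


@dataclass
class PriorSpec:
    """Mixture-prior hyperparameters.

    ``pi`` is the prior fraction of SNPs with no effect.  ``nu_alpha`` and
    ``nu_e`` are the degrees of freedom of the scaled-inverse-chi-square
    priors on the genetic and residual scales; both must exceed 2 so the
    prior means exist.  The target variances set the prior scales via
    :func:`derive_scales`; when left ``None`` they default to an equal
    split of the hatch-corrected phenotypic variance of the training data.
    """

    pi: float = 0.99
    nu_alpha: float = 4.0
    nu_e: float = 10.0
    target_genetic_variance: float | None = None
    target_residual_variance: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi < 1.0):
            raise ValueError("pi must be in [0, 1)")
        if self.nu_alpha <= 2.0 or self.nu_e <= 2.0:
            raise ValueError("degrees of freedom must exceed 2")


def default_prior(model: str) -> PriorSpec:
    if model not in MODEL_TAGS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_TAGS}")
    if model in ("bayesB", "bayesC"):
        return PriorSpec(pi=0.99, nu_alpha=4.0, nu_e=10.0)
    if model == "bayesC0":
        return PriorSpec(pi=0.0, nu_alpha=4.0, nu_e=10.0)
    return PriorSpec(pi=0.0, nu_alpha=100.0, nu_e=100.0)  # gblup


@dataclass
class MCMCConfig:
    n_iter: int = 35_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0
    store_window_samples: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ModelData:
    """Training data prepared for the sampler.

    ``XT`` holds centered dosages SNP-major (p x n, C-contiguous) for cache
    friendly single-site updates; ``freqs`` are the training allele
    frequencies used for centering (and re-used to center validation
    genotypes in :func:`gebv`).
    """

    animal_ids: list[str]
    snp_ids: list[str]
    XT: np.ndarray
    Xf: np.ndarray
    fixed_labels: list[str]
    y: np.ndarray
    freqs: np.ndarray
    map: pd.DataFrame

    @property
    def n_animals(self) -> int:
        return self.y.size

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def build_model_data(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    animals: list[str] | None = None,
) -> ModelData:
    """Assemble centered dosages, hatch incidence and phenotypes.

    ``animals`` restricts training to a subset (default: every phenotyped
    animal present in the genotype matrix).  Hatch classes are nested in
    generation; every class observed in the training records gets one
    incidence column (no intercept, so the design is full rank).
    """
    rec = phenotypes.records
    if animals is not None:
        rec = rec[rec["animal_id"].isin(set(animals))]
    geno_set = set(genotypes.animal_ids)
    rec = rec[rec["animal_id"].isin(geno_set)].reset_index(drop=True)
    if len(rec) == 0:
        raise ValueError("no phenotyped animals with genotypes in the training set")

    sub = genotypes.subset_animals(list(rec["animal_id"]))
    X = sub.dosages
    if np.isnan(X).any():
        raise ValueError("genotypes contain missing calls; run qc_filter first")
    freqs = X.mean(axis=0) / 2.0
    # SNP-major float32: halves memory traffic in the sampler's inner loop;
    # all accumulations there are float64
    XT = np.ascontiguousarray((X - 2.0 * freqs).T, dtype=np.float32)

    classes = rec["generation"].astype(str) + ":" + rec["hatch"].astype(str)
    labels = sorted(classes.unique())
    col = {c: k for k, c in enumerate(labels)}
    Xf = np.zeros((len(rec), len(labels)))
    for i, c in enumerate(classes):
        Xf[i, col[c]] = 1.0

    return ModelData(
        animal_ids=list(rec["animal_id"]),
        snp_ids=list(sub.snp_ids),
        XT=XT,
        Xf=Xf,
        fixed_labels=labels,
        y=rec["y"].to_numpy(dtype=np.float64),
        freqs=freqs,
        map=sub.map,
    )


def derive_scales(prior: PriorSpec, freqs: np.ndarray) -> tuple[float, float]:
    """Prior scales from target variances.

    ``S2_alpha`` is chosen so that the prior mean per-locus effect variance,
    summed over the expected ``(1 - pi) * sum_j 2 p_j q_j`` effective
    dosage variance, aggregates to the target genetic variance; ``S2_e`` so
    that the prior mean residual variance equals the target residual
    variance (prior mean of scaled-inv-chi2(nu, S2) is nu*S2/(nu-2)).
    """
    if prior.target_genetic_variance is None or prior.target_residual_variance is None:
        raise ValueError("target variances must be set before deriving scales")
    sum2pq = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    if sum2pq <= 0.0:
        raise ValueError("panel is entirely monomorphic (sum of 2pq is zero)")
    s2_a = (
        prior.target_genetic_variance
        * (prior.nu_alpha - 2.0)
        / prior.nu_alpha
        / ((1.0 - prior.pi) * sum2pq)
    )
    s2_e = prior.target_residual_variance * (prior.nu_e - 2.0) / prior.nu_e
    return s2_a, s2_e


def locus_inclusion_probability(
    r: float, c: float, sigma2_j: float, sigma2_e: float, pi: float
) -> float:
    """Pr(delta_j = 1) given the rest of the model, effect integrated out.

    ``r = x_j'(e + x_j alpha_j_old)`` is the locus right-hand side and
    ``c = x_j'x_j``.  Marginally ``r | delta=1 ~ N(0, c^2 sigma2_j +
    c sigma2_e)`` and ``r | delta=0 ~ N(0, c sigma2_e)``; the posterior
    odds weight these by (1-pi)/pi.  This is the same closed form the
    compiled sampler evaluates.
    """
    if c <= 0.0:
        return 0.0
    if pi == 0.0:
        return 1.0
    v1 = c * c * sigma2_j + c * sigma2_e
    v0 = c * sigma2_e
    log_l1 = -0.5 * (np.log(v1) + r * r / v1)
    log_l0 = -0.5 * (np.log(v0) + r * r / v0)
    logodds = np.log(1.0 - pi) - np.log(pi) + log_l1 - log_l0
    if logodds > 35.0:
        return 1.0
    if logodds < -35.0:
        return 0.0
    return float(1.0 / (1.0 + np.exp(-logodds)))


def locus_variance_conditional(nu: float, s2: float, alpha: float) -> tuple[float, float]:
    """(df, scale) of the BayesB per-locus variance conditional given alpha."""
    return nu + 1.0, (nu * s2 + alpha * alpha) / (nu + 1.0)


def common_variance_conditional(
    nu: float, s2: float, included_alphas: np.ndarray
) -> tuple[float, float]:
    """(df, scale) of the common effect-variance conditional (BayesC family).

    With no included SNPs this is exactly the prior.
    """
    a = np.asarray(included_alphas, dtype=float)
    m = a.size
    return nu + m, (nu * s2 + float(np.sum(a * a))) / (nu + m)


def residual_variance_conditional(
    nu: float, s2: float, residuals: np.ndarray
) -> tuple[float, float]:
    """(df, scale) of the residual-variance conditional given the residuals."""
    e = np.asarray(residuals, dtype=float)
    n = e.size
    return nu + n, (nu * s2 + float(e @ e)) / (nu + n)


def sample_scaled_inv_chi2(
    rng: np.random.Generator, df: float, scale: float, size=None
) -> np.ndarray | float:
    """Draw from scaled-inv-chi2(df, scale); mean is df*scale/(df-2)."""
    return df * scale / rng.chisquare(df, size=size)


def _hatch_corrected_variance(data: ModelData) -> float:
    """Phenotypic variance after removing fixed-class means."""
    resid = data.y.copy()
    for k in range(data.Xf.shape[1]):
        sel = data.Xf[:, k] == 1.0
        if sel.any():
            resid[sel] -= resid[sel].mean()
    return float(np.var(resid))


@dataclass
class ModelFit:
    """Posterior summaries of one chain."""

    model: str
    snp_ids: list[str]
    map: pd.DataFrame
    freqs: np.ndarray
    pi: float
    alpha_mean: np.ndarray
    inclusion_prob: np.ndarray
    beta_mean: np.ndarray
    fixed_labels: list[str]
    sigma2_e_samples: np.ndarray
    sigma2_alpha_samples: np.ndarray
    genetic_variance_samples: np.ndarray
    window_samples: np.ndarray | None
    window_assignment: WindowAssignment
    prior: PriorSpec
    mcmc: MCMCConfig
    # final chain state, kept so the residual bookkeeping can be audited
    final_alpha: np.ndarray = field(repr=False, default=None)
    final_beta: np.ndarray = field(repr=False, default=None)
    final_residual: np.ndarray = field(repr=False, default=None)

    @property
    def n_stored(self) -> int:
        return self.sigma2_e_samples.size

    def effects_table(self) -> pd.DataFrame:
        out = self.map.copy() if len(self.map) else pd.DataFrame({"snp": self.snp_ids})
        out["posterior_mean"] = self.alpha_mean
        out["inclusion_prob"] = self.inclusion_prob
        return out

    def posterior_mean_genetic_variance(self) -> float:
        return float(self.genetic_variance_samples.mean())


def run_chain(
    data: ModelData,
    model: str = "bayesB",
    prior: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    fix_variances: bool = False,
    sigma2_alpha: float | None = None,
    sigma2_e: float | None = None,
) -> ModelFit:
    """Run one Gibbs chain and aggregate the post-burn-in samples.

    Update order per iteration: fixed effects, all loci in index order
    (inclusion indicator and effect, plus the locus variance for BayesB),
    the common effect variance (BayesC family), then the residual variance.
    With ``fix_variances`` the variance components stay at their initial
    values (``sigma2_alpha`` / ``sigma2_e`` when given, else prior means),
    which is the known-variance ridge configuration.
    """
    if model not in MODEL_TAGS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_TAGS}")
    if prior is None:
        prior = default_prior(model)
    if mcmc is None:
        mcmc = MCMCConfig()

    if prior.target_genetic_variance is None or prior.target_residual_variance is None:
        v_half = _hatch_corrected_variance(data) / 2.0
        prior = PriorSpec(
            pi=prior.pi,
            nu_alpha=prior.nu_alpha,
            nu_e=prior.nu_e,
            target_genetic_variance=prior.target_genetic_variance or v_half,
            target_residual_variance=prior.target_residual_variance or v_half,
        )
    if data.n_snps > 0:
        s2_a, s2_e = derive_scales(prior, data.freqs)
    else:  # fixed-effects-only model: genetic scale is vestigial
        s2_a = prior.target_genetic_variance * (prior.nu_alpha - 2.0) / prior.nu_alpha
        s2_e = prior.target_residual_variance * (prior.nu_e - 2.0) / prior.nu_e

    sigma2_a0 = (
        sigma2_alpha
        if sigma2_alpha is not None
        else prior.nu_alpha * s2_a / (prior.nu_alpha - 2.0)
    )
    sigma2_e0 = (
        sigma2_e if sigma2_e is not None else prior.nu_e * s2_e / (prior.nu_e - 2.0)
    )

    if len(data.map):
        wa = assign_windows(data.map)
    else:  # no positions: one catch-all window
        wa = WindowAssignment(
            window_of=np.zeros(data.n_snps, dtype=np.int64),
            windows=pd.DataFrame(
                {"chrom": ["0"], "mb": [0], "label": ["0_0"], "n_snps": [data.n_snps]}
            ),
        )

    # least-squares start for the fixed effects (class means for incidence)
    if data.Xf.shape[1]:
        beta_init, *_ = np.linalg.lstsq(data.Xf, data.y, rcond=None)
    else:
        beta_init = np.zeros(0)

    (
        alpha_mean,
        incl_prob,
        beta_mean,
        tr_e,
        tr_a,
        tr_g,
        V,
        final_alpha,
        final_beta,
        final_e,
        error_iter,
    ) = gibbs_chain(
        data.XT,
        data.Xf,
        data.y,
        beta_init,
        prior.pi,
        prior.nu_alpha,
        s2_a,
        prior.nu_e,
        s2_e,
        model == "bayesB",
        fix_variances,
        sigma2_a0,
        sigma2_e0,
        mcmc.n_iter,
        mcmc.burn_in,
        mcmc.thin,
        wa.window_of,
        wa.n_windows,
        mcmc.store_window_samples,
        mcmc.seed,
    )
    if error_iter >= 0:
        raise RuntimeError(
            f"chain diverged (non-finite residual variance) at iteration {error_iter}"
        )

    return ModelFit(
        model=model,
        snp_ids=list(data.snp_ids),
        map=data.map,
        freqs=data.freqs,
        pi=prior.pi,
        alpha_mean=alpha_mean,
        inclusion_prob=incl_prob,
        beta_mean=beta_mean,
        fixed_labels=list(data.fixed_labels),
        sigma2_e_samples=tr_e,
        sigma2_alpha_samples=tr_a,
        genetic_variance_samples=tr_g,
        window_samples=V if mcmc.store_window_samples else None,
        window_assignment=wa,
        prior=prior,
        mcmc=mcmc,
        final_alpha=final_alpha,
        final_beta=final_beta,
        final_residual=final_e,
    )


def gebv(
    fit: ModelFit, genotypes: GenotypeMatrix, snp_subset: list[str] | None = None
) -> pd.Series:
    """Genomic value per animal from posterior-mean SNP effects.

    Dosages are centered with the *training* allele frequencies, so
    predictions for validation animals are on the training scale.  With
    ``snp_subset`` only those SNPs contribute (region-restricted GEBV).
    """
    pos = {s: j for j, s in enumerate(fit.snp_ids)}
    if snp_subset is None:
        subset_idx = np.arange(len(fit.snp_ids))
    else:
        missing = [s for s in snp_subset if s not in pos]
        if missing:
            raise KeyError(f"SNPs not in the fitted panel: {missing[:5]}")
        subset_idx = np.array([pos[s] for s in snp_subset], dtype=np.int64)

    gpos = {s: j for j, s in enumerate(genotypes.snp_ids)}
    try:
        gcols = np.array([gpos[fit.snp_ids[j]] for j in subset_idx], dtype=np.int64)
    except KeyError as exc:
        raise KeyError(f"fitted SNP missing from genotype matrix: {exc}") from None

    if subset_idx.size == 0:
        vals = np.zeros(genotypes.n_animals)
    else:
        X = genotypes.dosages[:, gcols] - 2.0 * fit.freqs[subset_idx]
        vals = X @ fit.alpha_mean[subset_idx]
    return pd.Series(vals, index=genotypes.animal_ids, name="gebv")
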