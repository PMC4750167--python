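"""Forward-in-time training/validation: accuracy, persistence, bias.

The design mirrors routine practice in closed breeding populations:
models are trained on one or more early generations and evaluated in later
ones.  Accuracy is the Pearson correlation between the genomic prediction
and the hatch-corrected phenotype of the validation generation;
persistence is the trajectory of that accuracy across increasingly distant
generations; region-restricted prediction uses only the SNPs of a chosen
1-Mb window; and the bias regression is the ordinary least-squares slope
of corrected phenotype on prediction, with b = 1 meaning no shrinkage
bias, b > 1 overshrinkage (predicted differences understate realized
phenotypic differences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes_alphabet import ModelFit, gebv
from .io_formats import GenotypeMatrix, PhenotypeTable
from .window_variance import assign_windows, summarize_windows

__all__ = [
    "ExperimentPlan",
    "hatch_correct",
    "accuracy",
    "bias_regression",
    "region_restricted_prediction",
    "persistence_run",
    "top_snp_of_window",
    "snp_merit_prediction",
    "add_average_row",
]


@dataclass
class ExperimentPlan:
    """Specification of one training/validation experiment."""

    training_generations: tuple[int, ...]
    validation_generations: tuple[int, ...]
    models: tuple[str, ...] = ("bayesB", "bayesC", "bayesC0", "gblup")
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        overlap = set(self.training_generations) & set(self.validation_generations)
        if overlap:
            raise ValueError(f"training and validation overlap: {sorted(overlap)}")


def hatch_correct(phenotypes: PhenotypeTable) -> pd.Series:
    """Phenotypes minus their hatch-within-generation class means.

    Means are computed within the records given (for validation use, pass
    only the validation generation).  Singleton classes are corrected to 0
    with a warning, since their class mean absorbs the observation.
    """
    rec = phenotypes.records
    cls = rec["generation"].astype(str) + ":" + rec["hatch"].astype(str)
    sizes = cls.map(cls.value_counts())
    if (sizes == 1).any():
        warnings.warn(
            f"{int((sizes == 1).sum())} singleton hatch classes corrected to zero",
            stacklevel=2,
        )
    corrected = rec["y"] - rec.groupby(cls)["y"].transform("mean")
    return pd.Series(corrected.to_numpy(), index=rec["animal_id"], name="y_corrected")


def accuracy(predictions: pd.Series, corrected_phenotypes: pd.Series) -> float:
    """Pearson correlation on the common animals; NaN when undefined."""
    common = predictions.index.intersection(corrected_phenotypes.index)
    if len(common) < 3:
        return float("nan")
    a = predictions.loc[common].to_numpy(dtype=float)
    b = corrected_phenotypes.loc[common].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def bias_regression(corrected_phenotypes: pd.Series, predictions: pd.Series) -> float:
    """OLS slope of corrected phenotype on prediction (b = 1: unbiased)."""
    common = predictions.index.intersection(corrected_phenotypes.index)
    p = predictions.loc[common].to_numpy(dtype=float)
    yc = corrected_phenotypes.loc[common].to_numpy(dtype=float)
    if len(common) < 3 or np.var(p) == 0:
        return float("nan")
    cov = np.cov(p, yc)
    return float(cov[0, 1] / cov[0, 0])


def region_restricted_prediction(
    fit: ModelFit, window_label: str, genotypes: GenotypeMatrix
) -> pd.Series:
    """GEBV from the SNPs of one 1-Mb window only."""
    wa = fit.window_assignment
    snps = wa.snps_in_window(window_label, fit.snp_ids)
    if not snps:
        warnings.warn(f"window {window_label} contains no SNPs; predictions are zero",
                      stacklevel=2)
        return pd.Series(np.zeros(genotypes.n_animals), index=genotypes.animal_ids)
    return gebv(fit, genotypes, snp_subset=snps)


def persistence_run(
    fits: dict[str, ModelFit],
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    validation_generations,
    region_window: str | dict[str, str] | None = None,
    extra_predictions: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Accuracy of each model in each validation generation.

    ``fits`` maps a model name to its fitted chain; with ``region_window``
    predictions use only that window's SNPs (a per-model mapping is
    accepted, as each method defines its own top window).
    ``extra_predictions`` adds pre-computed predictors (e.g. PBLUP EBVs)
    evaluated against the same corrected phenotypes.  Rows with a missing
    validation generation carry NaN accuracy.
    """
    rows = []
    for gen in validation_generations:
        val = phenotypes.for_generations([gen])
        if len(val.records) == 0:
            for name in list(fits) + list(extra_predictions or {}):
                rows.append((name, gen, 0, float("nan")))
            continue
        corrected = hatch_correct(val)
        val_animals = [a for a in val.animal_ids if a in set(genotypes.animal_ids)]
        sub = genotypes.subset_animals(val_animals)
        for name, fit in fits.items():
            if region_window is None:
                preds = gebv(fit, sub)
            else:
                win = region_window[name] if isinstance(region_window, dict) else region_window
                preds = region_restricted_prediction(fit, win, sub)
            rows.append((name, gen, len(val_animals), accuracy(preds, corrected)))
        for name, preds in (extra_predictions or {}).items():
            rows.append((name, gen, len(val.records), accuracy(preds, corrected)))
    return pd.DataFrame(rows, columns=["model", "validation_generation", "n", "accuracy"])


def add_average_row(report: pd.DataFrame, value_col: str = "accuracy") -> pd.DataFrame:
    """Append one 'average' row per model (arithmetic mean over generations)."""
    avg = (
        report.groupby("model", sort=False)[value_col]
        .mean()
        .reset_index()
        .assign(
            validation_generation="average",
            n=report.groupby("model", sort=False)["n"].sum().to_numpy(),
        )
    )
    return pd.concat([report, avg.reindex(columns=report.columns)], ignore_index=True)


def run_forward_experiment(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    training_sets: dict[str, tuple[int, ...]],
    validation_generations: tuple[int, ...],
    models: tuple[str, ...] = ("bayesB", "bayesC", "bayesC0", "gblup"),
    mcmc=None,
    pedigree=None,
    variance_components: tuple[float, float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Train each model on each training set and evaluate forward in time.

    Returns a dict of report tables:

    - ``accuracy``: whole-genome accuracy per (training set, model,
      validation generation), with average rows;
    - ``top_windows``: each fit's top 1-Mb window with %Var and p>0;
    - ``region_accuracy``: accuracy using only each fit's own top window;
    - ``bias``: slope of corrected phenotype on single-top-SNP merit per
      training set (whole-pedigree animal-model slope included when a
      pedigree is supplied).

    ``mcmc`` is a base :class:`~bayesqtl.bayes_alphabet.MCMCConfig`; chains
    for different (training set, model) cells get distinct seeds derived
    from its seed.  With ``pedigree`` a PBLUP baseline is evaluated
    alongside the genomic models (variance components either supplied or
    estimated once by EM-REML on the first training set).
    """
    from .bayes_alphabet import MCMCConfig, build_model_data, run_chain

    if mcmc is None:
        mcmc = MCMCConfig()

    acc_rows = []
    win_rows = []
    region_rows = []
    bias_rows = []
    cell = 0
    for ts_name, gens in training_sets.items():
        train_phen = phenotypes.for_generations(gens)
        data = build_model_data(genotypes, train_phen)
        fits: dict[str, ModelFit] = {}
        for model in models:
            cell += 1
            cfg = MCMCConfig(
                n_iter=mcmc.n_iter,
                burn_in=mcmc.burn_in,
                thin=mcmc.thin,
                seed=(mcmc.seed * 1000 + cell) % (2**31),
                store_window_samples=True,
            )
            fits[model] = run_chain(data, model=model, mcmc=cfg)

        extra = None
        if pedigree is not None:
            from .pblup import build_A_inverse, estimate_variance_components, solve_animal_model

            rel = build_A_inverse(pedigree)
            if variance_components is None:
                s2a, s2e, _ = estimate_variance_components(train_phen, rel)
                source = "em-reml"
            else:
                s2a, s2e = variance_components
                source = "supplied"
            sol = solve_animal_model(train_phen, rel, (s2a, s2e), variance_source=source)
            extra = {"pblup": sol.ebv}

        rep = persistence_run(fits, genotypes, phenotypes, validation_generations,
                              extra_predictions=extra)
        rep.insert(0, "training", ts_name)
        acc_rows.append(add_average_row(rep))

        top_wins: dict[str, str] = {}
        for model, fit in fits.items():
            wr = summarize_windows(fit).iloc[0]
            top_wins[model] = str(wr["label"])
            win_rows.append((ts_name, model, wr["label"], wr["pct_var"], wr["p_gt0"]))

        region_rep = persistence_run(fits, genotypes, phenotypes,
                                     validation_generations, region_window=top_wins)
        region_rep.insert(0, "training", ts_name)
        region_rows.append(add_average_row(region_rep))

        # shrinkage-bias check in the last validation generation, using the
        # most variance-contributing SNP of each fit's top window
        last_gen = validation_generations[-1]
        val = phenotypes.for_generations([last_gen])
        if len(val.records):
            corrected = hatch_correct(val)
            val_geno = genotypes.subset_animals(
                [a for a in val.animal_ids if a in set(genotypes.animal_ids)]
            )
            for model, fit in fits.items():
                snp = top_snp_of_window(fit, top_wins[model])
                j = fit.snp_ids.index(snp)
                merit = snp_merit_prediction(val_geno, snp, fit.alpha_mean[j], fit.freqs[j])
                bias_rows.append(
                    (ts_name, model, snp, fit.alpha_mean[j],
                     bias_regression(corrected, merit))
                )

    return {
        "accuracy": pd.concat(acc_rows, ignore_index=True),
        "top_windows": pd.DataFrame(
            win_rows, columns=["training", "model", "window", "pct_var", "p_gt0"]
        ),
        "region_accuracy": pd.concat(region_rows, ignore_index=True),
        "bias": pd.DataFrame(
            bias_rows, columns=["training", "model", "snp", "effect", "regression_b"]
        ),
    }


def top_snp_of_window(fit: ModelFit, window_label: str | None = None) -> str:
    """SNP contributing the most variance inside the (top) window.

    Variance contribution of SNP j is 2 p_j q_j alpha_j^2 with training
    frequencies; the window defaults to the fit's top window by %Var.
    """
    if window_label is None:
        window_label = str(summarize_windows(fit).iloc[0]["label"])
    snps = fit.window_assignment.snps_in_window(window_label, fit.snp_ids)
    if not snps:
        raise ValueError(f"window {window_label} contains no SNPs")
    pos = {s: j for j, s in enumerate(fit.snp_ids)}
    idx = np.array([pos[s] for s in snps])
    contrib = 2.0 * fit.freqs[idx] * (1.0 - fit.freqs[idx]) * fit.alpha_mean[idx] ** 2
    return snps[int(np.argmax(contrib))]


def snp_merit_prediction(
    genotypes: GenotypeMatrix, snp_id: str, effect: float, center_freq: float
) -> pd.Series:
    """Predicted merit from a single SNP: centered dosage times its effect."""
    try:
        j = genotypes.snp_ids.index(snp_id)
    except ValueError:
        raise KeyError(f"SNP {snp_id!r} not in genotype matrix") from None
    x = genotypes.dosages[:, j] - 2.0 * center_freq
    return pd.Series(x * effect, index=genotypes.animal_ids, name=f"merit_{snp_id}")
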