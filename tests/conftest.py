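"""Shared fixtures.

``study_replicates`` is the expensive session fixture: ten independently
seeded populations under the study conditions (8 generations x 300
animals, 3,000-marker panel, h2 = 0.5, one masked QTL at 25 % of genetic
variance at chr1:78.5 Mb), each analysed with BayesB and the GBLUP variant
trained on generations 1-7 and on generation 1 alone, plus a PBLUP
baseline.  Several acceptance and property tests consume its per-seed
summary metrics; chains are shortened (6,000 iterations, 1,000 burn-in)
to keep the whole suite at desk scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from bayesqtl.bayes_alphabet import MCMCConfig, build_model_data, run_chain
from bayesqtl.io_formats import qc_filter
from bayesqtl.pblup import build_A_inverse, solve_animal_model
from bayesqtl.simdata import SimulationConfig, simulate_population
from bayesqtl.window_variance import summarize_windows
from bayesqtl import validation as val

STUDY_SEEDS = tuple(range(1, 11))
PLANTED_WINDOW = "1_78"


@pytest.fixture(scope="session")
def small_pop():
    """Fast 4-generation population for unit tests."""
    cfg = SimulationConfig(
        n_generations=4,
        gen_sizes=(120, 120, 120, 120),
        n_markers=600,
        n_background_qtl=60,
        n_founders=120,
        warmup_pop_size=60,
        warmup_generations=30,
        seed=42,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_population(cfg)


def _study_config(seed: int) -> SimulationConfig:
    return SimulationConfig(n_generations=8, gen_sizes=(300,) * 8, seed=seed)


def _one_replicate(seed: int) -> dict:
    pop = simulate_population(_study_config(seed))
    filt, _ = qc_filter(pop.genotypes, pop.pedigree)
    out = {"seed": seed, "realized_h2": pop.realized_h2}

    def mc(sub):
        return MCMCConfig(n_iter=6000, burn_in=1000, seed=seed * 10 + sub)

    d17 = build_model_data(filt, pop.phenotypes.for_generations(range(1, 8)))
    fb17 = run_chain(d17, "bayesB", mcmc=mc(1))
    fg17 = run_chain(d17, "gblup", mcmc=mc(2))
    rb, rg = summarize_windows(fb17), summarize_windows(fg17)
    out["bayesb_top_window"] = str(rb.iloc[0]["label"])
    out["bayesb_top_pct"] = float(rb.iloc[0]["pct_var"])
    bt = out["bayesb_top_window"]
    out["gblup_pct_at_bayesb_top"] = (
        float(rg.loc[rg.label == bt, "pct_var"].iloc[0]) if (rg.label == bt).any() else 0.0
    )
    ref_window = bt  # reference window for the bias comparison

    d1 = build_model_data(filt, pop.phenotypes.for_generations([1]))
    fb1 = run_chain(d1, "bayesB", mcmc=mc(3))
    fg1 = run_chain(d1, "gblup", mcmc=mc(4))
    gens = tuple(range(2, 9))
    rep = val.persistence_run({"bayesB": fb1, "gblup": fg1}, filt, pop.phenotypes, gens)
    out["acc_bayesb"] = float(rep[rep.model == "bayesB"].accuracy.mean())
    out["acc_gblup"] = float(rep[rep.model == "gblup"].accuracy.mean())

    tb1 = str(summarize_windows(fb1).iloc[0]["label"])
    tg1 = str(summarize_windows(fg1).iloc[0]["label"])
    repw = val.persistence_run(
        {"bayesB": fb1, "gblup": fg1}, filt, pop.phenotypes, gens,
        region_window={"bayesB": tb1, "gblup": tg1},
    )
    out["win_acc_bayesb"] = float(repw[repw.model == "bayesB"].accuracy.mean())
    out["win_acc_gblup"] = float(repw[repw.model == "gblup"].accuracy.mean())

    valgen = pop.phenotypes.for_generations([8])
    corrected = val.hatch_correct(valgen)
    vgeno = filt.subset_animals(list(valgen.animal_ids))
    out["bias_g1"] = float(
        val.bias_regression(
            corrected, val.region_restricted_prediction(fb1, ref_window, vgeno)
        )
    )
    out["bias_g17"] = float(
        val.bias_regression(
            corrected, val.region_restricted_prediction(fb17, ref_window, vgeno)
        )
    )

    rel = build_A_inverse(pop.pedigree)
    s2a = pop.config.genetic_variance
    s2e = s2a * (1 - pop.config.h2) / pop.config.h2
    sol = solve_animal_model(pop.phenotypes.for_generations([1]), rel, (s2a, s2e))
    repp = val.persistence_run({}, filt, pop.phenotypes, gens,
                               extra_predictions={"pblup": sol.ebv})
    pacc = repp.set_index("validation_generation").accuracy
    bacc = rep[rep.model == "bayesB"].set_index("validation_generation").accuracy
    out["pblup_acc_g2"] = float(pacc.loc[2])
    out["pblup_acc_g8"] = float(pacc.loc[8])
    out["bayesb_acc_g2"] = float(bacc.loc[2])
    out["bayesb_acc_g8"] = float(bacc.loc[8])
    return out


@pytest.fixture(scope="session")
def study_replicates():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [_one_replicate(seed) for seed in STUDY_SEEDS]
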