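"""Forward simulator for multi-generation pedigreed breeding populations.

The simulator emulates the statistical structure of a closed layer-type
breeding line genotyped on a medium-density SNP chip: a handful of discrete
generations of a few hundred birds each, hatch-within-generation fixed
effects on the trait, a moderately heritable polygenic trait, and one
quantitative trait locus (QTL) contributing a large fraction of the genetic
variance at a known 1-Mb position.  Linkage disequilibrium between the
causal loci and the neutral marker panel is generated mechanistically, by
meiosis (Haldane model, no interference) through a number of warm-up
random-mating generations starting from linkage-equilibrium founders.

Causal loci (the large QTL plus a polygenic background of small QTL) are by
default *not* part of the marker panel, mirroring the situation on a real
chip where the causal variant is unobserved and must be tagged by nearby
markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, Pedigree, PhenotypeTable

__all__ = [
    "SimulationConfig",
    "SimulatedPopulation",
    "GeneticMap",
    "FounderPopulation",
    "simulate_founders",
    "meiosis",
    "assign_effects",
    "drop_generations",
    "simulate_population",
    "write_population",
]

DEFAULT_GEN_SIZES = (295, 323, 294, 360, 290, 252, 300, 210)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated population.

    ``large_qtl`` is ``(chromosome, bp, fraction_of_genetic_variance)``.
    ``selection`` is ``None`` (random mating) or ``("truncation", prop)``
    with ``prop`` the proportion of each sex kept as parents.  The total
    genetic variance of the trait is scaled to ``genetic_variance``
    (trait units squared) in the founder generation.
    """

    n_generations: int = 8
    gen_sizes: tuple[int, ...] = DEFAULT_GEN_SIZES
    n_chromosomes: int = 3
    chrom_length_bp: int = 100_000_000
    chrom_length_morgans: float = 1.0
    n_markers: int = 3000
    n_background_qtl: int = 300
    large_qtl: tuple[int, int, float] = (1, 78_500_000, 0.25)
    h2: float = 0.5
    hatches_per_generation: int = 3
    hatch_effect_sd: float = 0.5
    selection: tuple[str, float] | None = None
    founder_maf_range: tuple[float, float] = (0.1, 0.5)
    n_founders: int = 300
    warmup_generations: int = 100
    warmup_pop_size: int = 100
    qtl_in_panel: bool = False
    genetic_variance: float = 1.0
    min_qtl_maf: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.gen_sizes) != self.n_generations:
            raise ValueError("gen_sizes length must equal n_generations")
        chrom, bp, f_q = self.large_qtl
        if not (0.0 <= f_q < 1.0):
            raise ValueError("large-QTL variance fraction must be in [0, 1)")
        if not (1 <= chrom <= self.n_chromosomes) or not (0 <= bp < self.chrom_length_bp):
            raise ValueError("large-QTL position outside the simulated genome")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must be in (0, 1]")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must be within (0, 0.5]")
        if self.n_markers < self.n_chromosomes:
            raise ValueError("need at least one marker per chromosome")
        if self.selection is not None:
            mode, prop = self.selection
            if mode != "truncation":
                raise ValueError(f"unknown selection mode {mode!r}")
            if not (0.0 < prop <= 1.0):
                raise ValueError("selection proportion must be in (0, 1]")


@dataclass
class GeneticMap:
    """Positions of all simulated loci, in bp and morgans, per chromosome."""

    chrom: np.ndarray      # int chromosome label per locus (1-based)
    bp: np.ndarray         # int bp per locus, sorted within chromosome
    morgans: np.ndarray    # map position in morgans per locus
    chrom_length_morgans: float
    n_chromosomes: int

    def chrom_slice(self, c: int) -> slice:
        idx = np.flatnonzero(self.chrom == c)
        return slice(idx[0], idx[-1] + 1)

    @property
    def n_loci(self) -> int:
        return self.chrom.size


@dataclass
class FounderPopulation:
    """Founder haplotypes after warm-up random mating, plus the locus table."""

    haplotypes: np.ndarray      # (n_founders, 2, n_loci) int8
    loci: pd.DataFrame          # locus, chrom, bp, is_marker, is_large_qtl
    gmap: GeneticMap

    def genotypes(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


def _build_loci(config: SimulationConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, GeneticMap]:
    """Lay out markers (evenly spaced), background QTL (uniform) and the large QTL."""
    per_chrom = config.n_markers // config.n_chromosomes
    extra = config.n_markers - per_chrom * config.n_chromosomes
    bg_per_chrom = np.full(config.n_chromosomes, config.n_background_qtl // config.n_chromosomes)
    bg_per_chrom[: config.n_background_qtl - bg_per_chrom.sum()] += 1

    rows = []
    qchrom, qbp, f_q = config.large_qtl
    for c in range(1, config.n_chromosomes + 1):
        n_m = per_chrom + (1 if c <= extra else 0)
        if n_m == 0:
            raise ValueError(f"chromosome {c} would carry zero markers")
        spacing = config.chrom_length_bp / n_m
        for k in range(n_m):
            rows.append((f"M{c}_{k + 1}", c, int((k + 0.5) * spacing), True, False))
        for k, pos in enumerate(
            sorted(rng.integers(0, config.chrom_length_bp, size=bg_per_chrom[c - 1]))
        ):
            rows.append((f"Q{c}_{k + 1}", c, int(pos), False, False))
        if c == qchrom:
            rows.append((f"QTL{c}", c, int(qbp), False, True))
    loci = pd.DataFrame(rows, columns=["locus", "chrom", "bp", "is_marker", "is_large_qtl"])
    loci = loci.sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)

    morgans_per_bp = config.chrom_length_morgans / config.chrom_length_bp
    gmap = GeneticMap(
        chrom=loci["chrom"].to_numpy(),
        bp=loci["bp"].to_numpy(),
        morgans=loci["bp"].to_numpy() * morgans_per_bp,
        chrom_length_morgans=config.chrom_length_morgans,
        n_chromosomes=config.n_chromosomes,
    )
    return loci, gmap


def meiosis(parent_haplotypes: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a parent's two haplotypes.

    Crossover counts per chromosome are Poisson with mean equal to the map
    length in morgans and crossover positions are uniform on the map
    (Haldane model, no interference).  The starting haplotype of each
    chromosome is chosen at random.
    """
    gamete = np.empty(gmap.n_loci, dtype=np.int8)
    for c in range(1, gmap.n_chromosomes + 1):
        sl = gmap.chrom_slice(c)
        n_x = rng.poisson(gmap.chrom_length_morgans)
        start = rng.integers(2)
        if n_x == 0:
            gamete[sl] = parent_haplotypes[start, sl]
            continue
        xpos = np.sort(rng.uniform(0.0, gmap.chrom_length_morgans, size=n_x))
        seg = np.searchsorted(xpos, gmap.morgans[sl], side="right")
        choice = (start + seg) % 2
        gamete[sl] = np.where(choice == 0, parent_haplotypes[0, sl], parent_haplotypes[1, sl])
    return gamete


def _random_mating_generation(
    haps: np.ndarray, size: int, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Breed one generation by random union of gametes from random parents."""
    n = haps.shape[0]
    out = np.empty((size, 2, gmap.n_loci), dtype=np.int8)
    sires = rng.integers(n, size=size)
    dams = rng.integers(n, size=size)
    for i in range(size):
        out[i, 0] = meiosis(haps[sires[i]], gmap, rng)
        out[i, 1] = meiosis(haps[dams[i]], gmap, rng)
    return out


def simulate_founders(config: SimulationConfig, rng: np.random.Generator | None = None) -> FounderPopulation:
    """Linkage-equilibrium base haplotypes plus warm-up random mating.

    Per-locus minor allele frequencies are drawn uniformly from
    ``founder_maf_range`` (the counted allele is the minor or major one with
    equal probability); the large-QTL locus starts at frequency 0.5 so that
    it reliably remains segregating through the warm-up drift.
    ``warmup_generations`` rounds of random mating at the (typically small)
    effective size ``warmup_pop_size`` build chip-scale local linkage
    disequilibrium, as in a commercial line of limited effective size; a
    final expansion generation brings the cohort to ``n_founders``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    loci, gmap = _build_loci(config, rng)
    n_loci = len(loci)
    maf = rng.uniform(*config.founder_maf_range, size=n_loci)
    flip = rng.random(n_loci) < 0.5
    freq = np.where(flip, 1.0 - maf, maf)
    freq[loci["is_large_qtl"].to_numpy()] = 0.5

    size0 = config.warmup_pop_size if config.warmup_generations > 0 else config.n_founders
    qtl_col = loci["is_large_qtl"].to_numpy()
    has_qtl = qtl_col.any() and config.large_qtl[2] > 0
    # The simulated line carries a segregating large QTL by premise, so the
    # warm-up is conditioned on the QTL surviving drift: redraw until its
    # founder MAF clears min_qtl_maf (rejection sampling of the conditional
    # process; deterministic for a given seed).
    for _attempt in range(50):
        haps = (rng.random((size0, 2, n_loci)) < freq).astype(np.int8)
        for _ in range(config.warmup_generations):
            haps = _random_mating_generation(haps, config.warmup_pop_size, gmap, rng)
        if haps.shape[0] != config.n_founders:
            haps = _random_mating_generation(haps, config.n_founders, gmap, rng)
        if not has_qtl:
            break
        p = haps[:, :, qtl_col].mean()
        if min(p, 1.0 - p) >= config.min_qtl_maf:
            break
    else:
        raise ValueError(
            "large QTL repeatedly drifted below min_qtl_maf during warm-up"
        )
    return FounderPopulation(haplotypes=haps, loci=loci, gmap=gmap)


def assign_effects(
    config: SimulationConfig, founders: FounderPopulation, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw causal-locus substitution effects hitting the target architecture.

    The large-QTL effect ``a`` solves ``2 p (1-p) a^2 = f_Q * sigma2_g``
    with ``p`` its founder allele frequency.  Background effects are drawn
    i.i.d. standard normal and rescaled so that the empirical founder
    genetic variance (background + QTL, including their covariance) equals
    ``sigma2_g``.
    """
    loci = founders.loci
    sigma2_g = config.genetic_variance
    f_q = config.large_qtl[2]
    freq = founders.allele_frequencies()
    geno = founders.genotypes().astype(np.float64)

    effects = np.zeros(len(loci))
    is_large = loci["is_large_qtl"].to_numpy()
    is_bg = ~loci["is_marker"].to_numpy() & ~is_large

    if f_q > 0:
        j = int(np.flatnonzero(is_large)[0])
        p = freq[j]
        if p <= 0.0 or p >= 1.0:
            raise ValueError("large-QTL locus is monomorphic in the founders")
        effects[j] = np.sqrt(f_q * sigma2_g / (2.0 * p * (1.0 - p)))

    bg_idx = np.flatnonzero(is_bg)
    if bg_idx.size:
        raw = rng.standard_normal(bg_idx.size)
        g_bg = geno[:, bg_idx] @ raw
        g_q = geno[:, is_large] @ effects[is_large]
        v_b = np.var(g_bg)
        v_q = np.var(g_q)
        cov = np.cov(g_bg, g_q)[0, 1] if f_q > 0 else 0.0
        if v_b <= 0:
            raise ValueError("background genetic variance is zero in the founders")
        disc = cov * cov + v_b * (sigma2_g - v_q)
        if disc < 0:
            raise ValueError("cannot scale background effects to the target variance")
        scale = (-cov + np.sqrt(disc)) / v_b
        effects[bg_idx] = raw * scale
    elif f_q == 0.0:
        raise ValueError("no causal loci: f_Q = 0 and no background QTL")

    truth = loci[["locus", "chrom", "bp", "is_large_qtl"]].copy()
    truth["effect"] = effects
    truth["founder_freq"] = freq
    return truth[~loci["is_marker"].to_numpy()].reset_index(drop=True)


@dataclass
class SimulatedPopulation:
    """Ground-truth container: pedigree, panel genotypes, causal truth, phenotypes."""

    config: SimulationConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix          # marker panel (QTL columns included only if configured)
    qtl_genotypes: GenotypeMatrix      # causal-locus dosages, for diagnostics
    phenotypes: PhenotypeTable
    true_bv: pd.Series                 # genetic value per animal, all generations
    qtl_truth: pd.DataFrame            # locus, chrom, bp, is_large_qtl, effect, founder_freq
    realized_h2: float
    realized_qtl_var_fraction: float
    generation: pd.Series              # generation label per animal (0 = founders)

    @property
    def true_window(self) -> tuple[str, int]:
        """(chromosome label, Mb index) of the planted large QTL."""
        chrom, bp, _ = self.config.large_qtl
        return str(chrom), bp // 1_000_000

    def animals_in_generations(self, generations) -> list[str]:
        gens = set(generations)
        return [a for a, g in self.generation.items() if g in gens]


def _founder_tag_r2(founders: FounderPopulation, config: SimulationConfig) -> float:
    """Max founder r^2 between the large QTL and markers in its 1-Mb window."""
    loci = founders.loci
    qchrom, qbp, _ = config.large_qtl
    mb = qbp // 1_000_000
    in_win = (
        loci["is_marker"]
        & (loci["chrom"] == qchrom)
        & (loci["bp"] // 1_000_000 == mb)
    ).to_numpy()
    if not in_win.any():
        return 0.0
    geno = founders.genotypes().astype(float)
    q = geno[:, loci["is_large_qtl"].to_numpy()].ravel()
    if np.var(q) == 0:
        return 0.0
    markers = geno[:, in_win]
    keep = markers.std(axis=0) > 0
    if not keep.any():
        return 0.0
    r = np.corrcoef(np.column_stack([q, markers[:, keep]]).T)[0, 1:]
    return float(np.max(r * r))


def drop_generations(config: SimulationConfig) -> SimulatedPopulation:
    """Run the full simulation: founders, effects, breeding, phenotypes.

    Generation 0 is the (unphenotyped) founder cohort; generations
    1..n_generations are bred from the previous generation by sampling a
    sire and a dam per offspring (random, or by truncation on phenotype
    when selection is configured) and carry phenotypes
    ``y = hatch effect + g + e`` with ``Var(e)`` set from ``h2``.
    """
    rng = np.random.default_rng(config.seed)
    founders = simulate_founders(config, rng)
    truth = assign_effects(config, founders, rng)

    if config.warmup_generations >= 5 and not config.qtl_in_panel and config.large_qtl[2] > 0:
        r2 = _founder_tag_r2(founders, config)
        if r2 < 0.2:
            warnings.warn(
                f"weak founder tagging of the large QTL (max window r^2 = {r2:.3f}); "
                "window detection may be unreliable",
                stacklevel=2,
            )

    loci = founders.loci
    gmap = founders.gmap
    n_loci = gmap.n_loci
    effect_vec = np.zeros(n_loci)
    causal_pos = {loc: i for i, loc in enumerate(loci["locus"])}
    for _, row in truth.iterrows():
        effect_vec[causal_pos[row["locus"]]] = row["effect"]

    sigma2_g = config.genetic_variance
    sigma_e = np.sqrt(sigma2_g * (1.0 - config.h2) / config.h2) if config.h2 < 1.0 else 0.0

    # per-(generation, hatch) fixed effects
    hatch_eff = {
        (g, h): rng.normal(0.0, config.hatch_effect_sd)
        for g in range(config.n_generations + 1)
        for h in range(config.hatches_per_generation)
    }

    ids: list[str] = []
    gens: list[int] = []
    sires: list[str] = []
    dams: list[str] = []
    sexes: list[int] = []   # 0 = male, 1 = female
    hatches: list[int] = []

    haps_prev = founders.haplotypes
    n0 = haps_prev.shape[0]
    ids_prev = [f"G0_{i + 1}" for i in range(n0)]
    ids += ids_prev
    gens += [0] * n0
    sires += ["0"] * n0
    dams += ["0"] * n0
    sex_prev = np.arange(n0) % 2
    sexes += list(sex_prev)
    hatches += list(np.arange(n0) % config.hatches_per_generation)

    all_haps = [haps_prev]
    g_prev = haps_prev.sum(axis=1).astype(np.float64) @ effect_vec
    bv = [g_prev]
    e_prev = rng.normal(0.0, sigma_e, size=n0) if sigma_e > 0 else np.zeros(n0)
    y_prev = (
        np.array([hatch_eff[(0, h)] for h in np.arange(n0) % config.hatches_per_generation])
        + g_prev
        + e_prev
    )
    pheno_rows: list[tuple[str, int, str, float]] = []
    resid = [e_prev]

    for g in range(1, config.n_generations + 1):
        size = config.gen_sizes[g - 1]
        males = np.flatnonzero(sex_prev == 0)
        females = np.flatnonzero(sex_prev == 1)
        if config.selection is not None and g > 1:
            prop = config.selection[1]
            n_m = max(1, int(np.ceil(prop * males.size)))
            n_f = max(1, int(np.ceil(prop * females.size)))
            males = males[np.argsort(-y_prev[males])][:n_m]
            females = females[np.argsort(-y_prev[females])][:n_f]
        if males.size == 0 or females.size == 0:
            raise ValueError(f"no eligible parents of one sex for generation {g}")

        haps_new = np.empty((size, 2, n_loci), dtype=np.int8)
        sire_pick = rng.choice(males, size=size)
        dam_pick = rng.choice(females, size=size)
        for i in range(size):
            haps_new[i, 0] = meiosis(haps_prev[sire_pick[i]], gmap, rng)
            haps_new[i, 1] = meiosis(haps_prev[dam_pick[i]], gmap, rng)

        ids_new = [f"G{g}_{i + 1}" for i in range(size)]
        sex_new = np.arange(size) % 2
        hatch_new = np.arange(size) % config.hatches_per_generation
        g_new = haps_new.sum(axis=1).astype(np.float64) @ effect_vec
        e_new = rng.normal(0.0, sigma_e, size=size) if sigma_e > 0 else np.zeros(size)
        y_new = np.array([hatch_eff[(g, h)] for h in hatch_new]) + g_new + e_new

        ids += ids_new
        gens += [g] * size
        sires += [ids_prev[s] for s in sire_pick]
        dams += [ids_prev[d] for d in dam_pick]
        sexes += list(sex_new)
        hatches += list(hatch_new)
        all_haps.append(haps_new)
        bv.append(g_new)
        resid.append(e_new)
        pheno_rows += [
            (ids_new[i], g, f"h{hatch_new[i] + 1}", float(y_new[i])) for i in range(size)
        ]

        haps_prev, ids_prev, sex_prev, y_prev = haps_new, ids_new, sex_new, y_new

    haps_all = np.concatenate(all_haps, axis=0)
    geno_all = haps_all.sum(axis=1).astype(np.float64)
    bv_all = np.concatenate(bv)
    resid_all = np.concatenate(resid)
    gens_arr = np.array(gens)

    is_marker = loci["is_marker"].to_numpy()
    panel_mask = is_marker | (np.full(n_loci, config.qtl_in_panel) & ~is_marker)
    panel_idx = np.flatnonzero(panel_mask)
    causal_idx = np.flatnonzero(~is_marker)

    map_df = pd.DataFrame(
        {
            "snp": loci["locus"].iloc[panel_idx].to_numpy(),
            "chrom": loci["chrom"].iloc[panel_idx].astype(str).to_numpy(),
            "bp": loci["bp"].iloc[panel_idx].to_numpy(),
        }
    )
    genotypes = GenotypeMatrix(
        animal_ids=list(ids),
        snp_ids=list(map_df["snp"]),
        dosages=geno_all[:, panel_idx],
        map=map_df,
    )
    qtl_map = pd.DataFrame(
        {
            "snp": loci["locus"].iloc[causal_idx].to_numpy(),
            "chrom": loci["chrom"].iloc[causal_idx].astype(str).to_numpy(),
            "bp": loci["bp"].iloc[causal_idx].to_numpy(),
        }
    )
    qtl_genotypes = GenotypeMatrix(
        animal_ids=list(ids),
        snp_ids=list(qtl_map["snp"]),
        dosages=geno_all[:, causal_idx],
        map=qtl_map,
    )

    pedigree = Pedigree(
        pd.DataFrame({"animal": ids, "sire": sires, "dam": dams, "generation": gens})
    )
    phenotypes = PhenotypeTable(
        pd.DataFrame(pheno_rows, columns=["animal_id", "generation", "hatch", "y"])
    )

    phen_mask = gens_arr >= 1
    var_g = float(np.var(bv_all[phen_mask]))
    var_ge = float(np.var(bv_all[phen_mask] + resid_all[phen_mask]))
    realized_h2 = var_g / var_ge if var_ge > 0 else float("nan")

    founder_mask = gens_arr == 0
    large_col = np.flatnonzero(loci["is_large_qtl"].to_numpy()[causal_idx])
    if large_col.size and config.large_qtl[2] > 0:
        a = truth.loc[truth["is_large_qtl"], "effect"].iloc[0]
        vq = np.var(geno_all[founder_mask][:, causal_idx[large_col[0]]] * a)
        vg0 = np.var(bv_all[founder_mask])
        realized_fq = float(vq / vg0) if vg0 > 0 else float("nan")
    else:
        realized_fq = 0.0

    return SimulatedPopulation(
        config=config,
        pedigree=pedigree,
        genotypes=genotypes,
        qtl_genotypes=qtl_genotypes,
        phenotypes=phenotypes,
        true_bv=pd.Series(bv_all, index=ids, name="true_bv"),
        qtl_truth=truth,
        realized_h2=realized_h2,
        realized_qtl_var_fraction=realized_fq,
        generation=pd.Series(gens_arr, index=ids, name="generation"),
    )


simulate_population = drop_generations


def write_population(pop: SimulatedPopulation, out_dir) -> None:
    """Write the simulated dataset as plain-text files (PLINK .raw + TSVs)."""
    from pathlib import Path

    from . import io_formats as io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_genotypes(pop.genotypes, out / "genotypes.raw", dialect="plink_raw")
    io.write_map(pop.genotypes.map, out / "map.tsv")
    io.write_pedigree(pop.pedigree, out / "pedigree.tsv")
    io.write_phenotypes(pop.phenotypes, out / "phenotypes.tsv")
    truth = pop.qtl_truth.copy()
    truth.to_csv(out / "qtl_truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "animal_id": pop.true_bv.index,
            "generation": pop.generation.values,
            "true_bv": pop.true_bv.values,
        }
    ).to_csv(out / "true_bv.tsv", sep="\t", index=False)
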