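"""Tabular genotype/pedigree/phenotype I/O and SNP quality control.

Genotypes are SNP dosages (count of one designated allele, 0/1/2) with
missing calls allowed.  Two dialects are supported: a PLINK ``.raw``-style
space-separated file (``FID IID PAT MAT SEX PHENOTYPE`` followed by one
dosage column per SNP, allele suffix on the column name) and a plain TSV
with an ``animal_id`` column followed by one column per SNP.

Quality control mirrors common SNP-chip practice: a SNP is dropped when its
minor allele frequency is too low, too many calls are missing, or the rate
of opposing-homozygote conflicts across genotyped parent-offspring pairs is
too high.  Surviving missing calls are imputed to the SNP mean so that
downstream whole-genome regression sees a complete matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "Pedigree",
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "qc_filter",
    "QCError",
]

PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class QCError(ValueError):
    """Raised when quality control cannot proceed (e.g. empty panel)."""


class ParseError(ValueError):
    """Raised on malformed genotype files; message names the offending line."""


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix with a marker map.

    ``dosages`` is float64 with ``np.nan`` for missing calls.  ``map`` has
    columns ``snp``, ``chrom``, ``bp`` aligned with ``snp_ids``.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    map: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["snp", "chrom", "bp"]))

    def __post_init__(self) -> None:
        n, p = self.dosages.shape
        if n != len(self.animal_ids) or p != len(self.snp_ids):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_ids)} SNPs"
            )
        if len(self.map) and list(self.map["snp"]) != list(self.snp_ids):
            self.map = (
                self.map.set_index("snp").loc[self.snp_ids].reset_index()
            )

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the counted allele from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            animal_ids=list(self.animal_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            dosages=self.dosages[:, idx].copy(),
            map=self.map.iloc[idx].reset_index(drop=True) if len(self.map) else self.map,
        )

    def subset_animals(self, animal_ids: list[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = [pos[a] for a in animal_ids]
        return GenotypeMatrix(
            animal_ids=list(animal_ids),
            snp_ids=list(self.snp_ids),
            dosages=self.dosages[idx, :].copy(),
            map=self.map,
        )


@dataclass
class PhenotypeTable:
    """One record per animal: generation, hatch-within-generation class, trait value."""

    records: pd.DataFrame  # columns: animal_id, generation, hatch, y

    def __post_init__(self) -> None:
        req = {"animal_id", "generation", "hatch", "y"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if self.records["animal_id"].duplicated().any():
            dup = self.records.loc[self.records["animal_id"].duplicated(), "animal_id"].iloc[0]
            raise ValueError(f"duplicate phenotype record for animal {dup!r}")

    def for_generations(self, generations) -> "PhenotypeTable":
        gens = set(generations)
        return PhenotypeTable(
            self.records[self.records["generation"].isin(gens)].reset_index(drop=True)
        )

    @property
    def animal_ids(self) -> list[str]:
        return list(self.records["animal_id"])

    def hatch_classes(self) -> pd.Series:
        """Hatch nested in generation, encoded 'gen:hatch'."""
        r = self.records
        return r["generation"].astype(str) + ":" + r["hatch"].astype(str)


@dataclass
class Pedigree:
    """Pedigree records (animal, sire, dam); '0' denotes an unknown parent."""

    records: pd.DataFrame  # columns: animal, sire, dam [, generation]

    UNKNOWN = "0"

    def __post_init__(self) -> None:
        req = {"animal", "sire", "dam"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"pedigree missing columns: {sorted(missing)}")
        for c in ("animal", "sire", "dam"):
            self.records[c] = self.records[c].astype(str)

    @property
    def animals(self) -> list[str]:
        return list(self.records["animal"])

    def parent_pairs(self) -> list[tuple[str, str]]:
        """All (offspring, parent) pairs with a known parent."""
        out = []
        for _, row in self.records.iterrows():
            for p in (row["sire"], row["dam"]):
                if p != self.UNKNOWN:
                    out.append((row["animal"], p))
        return out

    def topological_order(self) -> list[str]:
        """Animals ordered parents-before-offspring; raises on cycles."""
        rec = self.records
        known = set(rec["animal"])
        children: dict[str, list[str]] = {a: [] for a in known}
        indeg = {a: 0 for a in known}
        for _, row in rec.iterrows():
            a = row["animal"]
            for p in (row["sire"], row["dam"]):
                if p == self.UNKNOWN:
                    continue
                if p == a:
                    raise ValueError(f"animal {a!r} is its own parent")
                if p in known:
                    children[p].append(a)
                    indeg[a] += 1
        order = [a for a in rec["animal"] if indeg[a] == 0]
        head = 0
        while head < len(order):
            for c in children[order[head]]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
            head += 1
        if len(order) != len(known):
            raise ValueError("pedigree contains a cycle")
        return order


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_ALLELE_SUFFIX = re.compile(r"_[ACGT0-9]+$")


def _parse_dosage_token(tok: str, path, lineno: int) -> float:
    if tok in ("NA", "nan", "-9", "."):
        return np.nan
    if tok in ("0", "1", "2"):
        return float(tok)
    try:
        v = float(tok)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: invalid dosage token {tok!r}") from None
    if v not in (0.0, 1.0, 2.0):
        raise ParseError(f"{path}:{lineno}: dosage {tok!r} not in {{0,1,2,NA}}")
    return v


def read_genotypes(path, dialect: str = "plink_raw", map: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a dosage matrix.

    dialect 'plink_raw': whitespace-separated, PLINK .raw header with allele
    suffixes on SNP names (stripped).  dialect 'simple_tsv': tab-separated,
    'animal_id' then one column per SNP.
    """
    path = Path(path)
    if dialect not in ("plink_raw", "simple_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = r"\s+" if dialect == "plink_raw" else "\t"
    with open(path) as fh:
        header = fh.readline().split() if dialect == "plink_raw" else fh.readline().rstrip("\n").split("\t")
        if dialect == "plink_raw":
            if header[: len(PLINK_META_COLS)] != PLINK_META_COLS:
                raise ParseError(f"{path}:1: not a PLINK .raw header")
            snp_ids = [_ALLELE_SUFFIX.sub("", c) for c in header[len(PLINK_META_COLS):]]
            n_meta = len(PLINK_META_COLS)
            id_col = 1  # IID
        else:
            if header[0] != "animal_id":
                raise ParseError(f"{path}:1: first column must be 'animal_id'")
            snp_ids = header[1:]
            n_meta = 1
            id_col = 0
        animal_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            toks = line.split() if dialect == "plink_raw" else line.rstrip("\n").split("\t")
            if not toks or toks == [""]:
                continue
            if len(toks) != n_meta + len(snp_ids):
                raise ParseError(
                    f"{path}:{lineno}: expected {n_meta + len(snp_ids)} fields, got {len(toks)}"
                )
            animal_ids.append(toks[id_col])
            rows.append([_parse_dosage_token(t, path, lineno) for t in toks[n_meta:]])
    dosages = np.array(rows, dtype=np.float64) if rows else np.empty((0, len(snp_ids)))
    gm = GenotypeMatrix(animal_ids, snp_ids, dosages)
    if map is not None:
        gm.map = map.set_index("snp").loc[snp_ids].reset_index()
    return gm


def write_genotypes(gm: GenotypeMatrix, path, dialect: str = "plink_raw") -> None:
    path = Path(path)
    def fmt(v: float) -> str:
        return "NA" if np.isnan(v) else str(int(v))

    with open(path, "w") as fh:
        if dialect == "plink_raw":
            fh.write(" ".join(PLINK_META_COLS + [f"{s}_A" for s in gm.snp_ids]) + "\n")
            for i, a in enumerate(gm.animal_ids):
                fh.write(
                    " ".join([a, a, "0", "0", "0", "-9"] + [fmt(v) for v in gm.dosages[i]]) + "\n"
                )
        elif dialect == "simple_tsv":
            fh.write("\t".join(["animal_id"] + list(gm.snp_ids)) + "\n")
            for i, a in enumerate(gm.animal_ids):
                fh.write("\t".join([a] + [fmt(v) for v in gm.dosages[i]]) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str, "bp": np.int64})
    return df[["snp", "chrom", "bp"]]


def write_map(map_df: pd.DataFrame, path) -> None:
    map_df[["snp", "chrom", "bp"]].to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return Pedigree(df)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.records.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "hatch": str})
    return PhenotypeTable(df)


def write_phenotypes(pt: PhenotypeTable, path) -> None:
    pt.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def _mendel_rates(gm: GenotypeMatrix, pedigree: Pedigree) -> np.ndarray:
    """Per-SNP opposing-homozygote rate over genotyped parent-offspring pairs.

    A pair is informative at a SNP when both members are genotyped there;
    a mismatch is one member homozygous 0 and the other homozygous 2.
    SNPs with no informative pair get rate 0 (the filter is vacuous there).
    """
    pos = {a: i for i, a in enumerate(gm.animal_ids)}
    pairs = [
        (pos[c], pos[p])
        for c, p in pedigree.parent_pairs()
        if c in pos and p in pos
    ]
    p_snps = gm.n_snps
    if not pairs:
        return np.zeros(p_snps)
    ci = np.array([c for c, _ in pairs])
    pi_ = np.array([p for _, p in pairs])
    gc = gm.dosages[ci, :]
    gp = gm.dosages[pi_, :]
    informative = ~np.isnan(gc) & ~np.isnan(gp)
    mism = ((gc == 0) & (gp == 2)) | ((gc == 2) & (gp == 0))
    n_inf = informative.sum(axis=0)
    n_mis = (mism & informative).sum(axis=0)
    rate = np.zeros(p_snps)
    nz = n_inf > 0
    rate[nz] = n_mis[nz] / n_inf[nz]
    return rate


def qc_filter(
    gm: GenotypeMatrix,
    pedigree: Pedigree | None = None,
    maf_min: float = 0.025,
    max_missing: float = 0.05,
    max_mendel: float = 0.05,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply SNP quality-control filters and mean-impute surviving missing calls.

    A SNP is removed iff MAF < ``maf_min``, or missing fraction >
    ``max_missing``, or parent-offspring opposing-homozygote rate >
    ``max_mendel``.  Each removed SNP is reported once, under the first rule
    it fails in the order MAF, missing, mendel.

    Returns the filtered (and imputed) matrix and an exclusion report with
    columns ``snp``, ``reason``, ``value``.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0 <= max_missing <= 1) or not (0 <= max_mendel <= 1):
        raise ValueError("max_missing and max_mendel must be in [0, 1]")

    freq = gm.allele_frequencies()
    maf = np.minimum(freq, 1 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)  # all-missing SNP: MAF 0, removed
    missing = gm.missing_fraction()
    mendel = (
        _mendel_rates(gm, pedigree) if pedigree is not None else np.zeros(gm.n_snps)
    )

    fail_maf = maf < maf_min
    fail_mis = missing > max_missing
    fail_men = mendel > max_mendel
    removed = fail_maf | fail_mis | fail_men

    rows = []
    for j in np.flatnonzero(removed):
        if fail_maf[j]:
            rows.append((gm.snp_ids[j], "maf", maf[j]))
        elif fail_mis[j]:
            rows.append((gm.snp_ids[j], "missing", missing[j]))
        else:
            rows.append((gm.snp_ids[j], "mendel", mendel[j]))
    report = pd.DataFrame(rows, columns=["snp", "reason", "value"])

    if removed.all():
        raise QCError("quality control removed every SNP")

    out = gm.subset_snps(~removed)
    # mean imputation of remaining missing calls
    col_mean = np.nanmean(out.dosages, axis=0)
    nan_r, nan_c = np.where(np.isnan(out.dosages))
    if nan_r.size:
        out.dosages[nan_r, nan_c] = col_mean[nan_c]
    return out, report
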