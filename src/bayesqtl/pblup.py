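"""Pedigree BLUP: numerator relationship matrix, animal model, EM-REML.

The inverse numerator relationship matrix A^-1 is assembled directly from
the pedigree by Henderson's rules, with inbreeding coefficients from the
Meuwissen-Luo recursion (each animal's F is accumulated by propagating its
gene-contribution coefficients back through its ancestors).  The animal
model is solved through Henderson's mixed-model equations as one sparse
symmetric system; the same machinery fits a single SNP as a fixed
covariate, which is the classical check on shrinkage of a large marker
effect.  Variance components, when not supplied, come from an EM-REML
iteration on the same equations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .io_formats import Pedigree, PhenotypeTable

__all__ = [
    "RelationshipMatrix",
    "AnimalModelSolution",
    "build_A_inverse",
    "solve_animal_model",
    "estimate_variance_components",
]


@dataclass
class RelationshipMatrix:
    """Sparse A^-1 with animal ordering and inbreeding coefficients."""

    ids: list[str]                 # topological order, parents first
    A_inv: sp.csr_matrix
    inbreeding: np.ndarray         # F_i per animal, same order as ids

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.ids)}
        return np.array([pos[a] for a in animal_ids], dtype=np.int64)


def _inbreeding_meuwissen_luo(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients; ``sire``/``dam`` are indices, -1 = unknown.

    Animals must be topologically ordered.  For animal i the algorithm
    propagates contribution coefficients v back through the ancestors and
    accumulates 1 + F_i = sum_k v_k^2 d_k, where d_k is the within-family
    (Mendelian-sampling) variance of ancestor k.
    """
    n = sire.size
    F = np.zeros(n)
    d = np.zeros(n)
    for i in range(n):
        s, dd = sire[i], dam[i]
        if s >= 0 and dd >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[dd])
        elif s >= 0 or dd >= 0:
            p = s if s >= 0 else dd
            d[i] = 0.75 - 0.25 * F[p]
        else:
            d[i] = 1.0
        if s < 0 or dd < 0:
            F[i] = 0.0
            continue
        v = {i: 1.0}
        acc = 0.0
        for k in range(i, -1, -1):
            vk = v.pop(k, 0.0)
            if vk == 0.0:
                continue
            acc += vk * vk * d[k]
            if sire[k] >= 0:
                v[sire[k]] = v.get(sire[k], 0.0) + 0.5 * vk
            if dam[k] >= 0:
                v[dam[k]] = v.get(dam[k], 0.0) + 0.5 * vk
        F[i] = acc - 1.0
    return F


def build_A_inverse(pedigree: Pedigree) -> RelationshipMatrix:
    """Assemble sparse A^-1 by Henderson's rules, accounting for inbreeding.

    The pedigree is reordered internally so that parents precede offspring;
    cycles or self-parenting raise.  Unknown parents are treated as
    unrelated non-inbred founders.
    """
    order = pedigree.topological_order()
    pos = {a: i for i, a in enumerate(order)}
    rec = pedigree.records.set_index("animal")
    sire = np.full(len(order), -1, dtype=np.int64)
    dam = np.full(len(order), -1, dtype=np.int64)
    for i, a in enumerate(order):
        s, d = rec.loc[a, "sire"], rec.loc[a, "dam"]
        if s != Pedigree.UNKNOWN and s in pos:
            sire[i] = pos[s]
        if d != Pedigree.UNKNOWN and d in pos:
            dam[i] = pos[d]

    F = _inbreeding_meuwissen_luo(sire, dam)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(len(order)):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * F[p]
        else:
            di = 1.0
        a = 1.0 / di
        rows.append(i); cols.append(i); vals.append(a)
        for p in (s, d):
            if p >= 0:
                rows += [i, p]; cols += [p, i]; vals += [-0.5 * a, -0.5 * a]
        for p in (s, d):
            if p >= 0:
                for q in (s, d):
                    if q >= 0:
                        rows.append(p); cols.append(q); vals.append(0.25 * a)
    A_inv = sp.coo_matrix((vals, (rows, cols)), shape=(len(order),) * 2).tocsr()
    return RelationshipMatrix(ids=order, A_inv=A_inv, inbreeding=F)


@dataclass
class AnimalModelSolution:
    """Solutions of the mixed-model equations for one animal model."""

    fixed_effects: pd.Series           # hatch-class (and covariate) solutions
    snp_effect: float | None           # fixed substitution-effect estimate
    ebv: pd.Series                     # EBV for every pedigree member
    sigma2_a: float
    sigma2_e: float
    variance_source: str               # 'supplied' | 'em-reml'
    mme_relative_residual: float


def _design(
    phenotypes: PhenotypeTable,
    rel: RelationshipMatrix,
    snp_covariate: pd.Series | None,
):
    rec = phenotypes.records.reset_index(drop=True)
    known = set(rel.ids)
    missing = [a for a in rec["animal_id"] if a not in known]
    if missing:
        raise ValueError(f"phenotyped animals absent from pedigree: {missing[:5]}")
    y = rec["y"].to_numpy(dtype=np.float64)
    classes = rec["generation"].astype(str) + ":" + rec["hatch"].astype(str)
    labels = sorted(classes.unique())
    col = {c: k for k, c in enumerate(labels)}
    X = np.zeros((len(rec), len(labels)))
    for i, c in enumerate(classes):
        X[i, col[c]] = 1.0
    if snp_covariate is not None:
        cov = snp_covariate.reindex(rec["animal_id"]).to_numpy(dtype=np.float64)
        if np.isnan(cov).any():
            raise ValueError("SNP covariate missing for some phenotyped animals")
        X = np.column_stack([X, cov])
        labels = labels + ["snp"]
    zrow = np.arange(len(rec))
    zcol = rel.index_of(list(rec["animal_id"]))
    Z = sp.coo_matrix(
        (np.ones(len(rec)), (zrow, zcol)), shape=(len(rec), rel.n)
    ).tocsr()
    return y, X, labels, Z


def _mme(y, X, Z, A_inv, lam):
    Xs = sp.csr_matrix(X)
    C = sp.bmat(
        [
            [Xs.T @ Xs, Xs.T @ Z],
            [Z.T @ Xs, Z.T @ Z + lam * A_inv],
        ],
        format="csc",
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    return C, rhs


def solve_animal_model(
    phenotypes: PhenotypeTable,
    rel: RelationshipMatrix,
    variance_components: tuple[float, float],
    snp_covariate: pd.Series | None = None,
    variance_source: str = "supplied",
) -> AnimalModelSolution:
    """Solve Henderson's mixed-model equations for the animal model.

    Fixed effects are the hatch-within-generation classes of the phenotype
    table, plus an optional SNP-dosage covariate whose solution is the
    substitution-effect estimate.  EBVs are returned for every animal in
    the pedigree.
    """
    sigma2_a, sigma2_e = variance_components
    if sigma2_a <= 0 or sigma2_e <= 0:
        raise ValueError("variance components must be positive")
    lam = sigma2_e / sigma2_a
    y, X, labels, Z = _design(phenotypes, rel, snp_covariate)

    # guard against empty fixed columns (cannot occur for observed classes,
    # but a constant-zero covariate would make the system singular)
    col_ss = (X * X).sum(axis=0)
    if np.any(col_ss == 0):
        bad = [labels[k] for k in np.flatnonzero(col_ss == 0)]
        warnings.warn(f"dropping empty fixed-effect columns: {bad}", stacklevel=2)
        keep = col_ss > 0
        X = X[:, keep]
        labels = [l for l, k in zip(labels, keep) if k]

    C, rhs = _mme(y, X, Z, rel.A_inv, lam)
    sol = spla.spsolve(C, rhs)
    rel_res = float(
        np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    )
    nf = X.shape[1]
    beta = sol[:nf]
    u = sol[nf:]
    snp_effect = float(beta[-1]) if (snp_covariate is not None and labels[-1] == "snp") else None
    return AnimalModelSolution(
        fixed_effects=pd.Series(beta, index=labels),
        snp_effect=snp_effect,
        ebv=pd.Series(u, index=rel.ids, name="ebv"),
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        variance_source=variance_source,
        mme_relative_residual=rel_res,
    )


def estimate_variance_components(
    phenotypes: PhenotypeTable,
    rel: RelationshipMatrix,
    tol: float = 1e-6,
    max_iter: int = 200,
    init_h2: float = 0.5,
) -> tuple[float, float, bool]:
    """EM-REML estimates of (sigma2_a, sigma2_e) for the animal model.

    Classical EM updates on Henderson's equations:

        sigma2_a <- (u' A^-1 u + tr(A^-1 C_uu) * sigma2_e) / q
        sigma2_e <- (y'y - b'X'y - u'Z'y) / (n - rank(X))

    with C_uu the animal block of the inverse MME coefficient matrix.
    Dense linear algebra: intended for desk-scale pedigrees (a few
    thousand animals).  Returns the estimates and a convergence flag.
    """
    if len(phenotypes.records) < 2:
        raise ValueError("need at least two phenotyped animals")
    y, X, labels, Z = _design(phenotypes, rel, None)
    n = y.size
    q = rel.n
    A_inv = rel.A_inv.toarray()
    Zd = Z.toarray()
    XtX = X.T @ X
    XtZ = X.T @ Zd
    ZtZ = Zd.T @ Zd
    Xty = X.T @ y
    Zty = Zd.T @ y
    yty = float(y @ y)
    rank_x = np.linalg.matrix_rank(XtX)

    vy = np.var(y)
    s2a = max(init_h2 * vy, 1e-8)
    s2e = max((1 - init_h2) * vy, 1e-8)
    converged = False
    for _ in range(max_iter):
        lam = s2e / s2a
        C = np.block([[XtX, XtZ], [XtZ.T, ZtZ + lam * A_inv]])
        rhs = np.concatenate([Xty, Zty])
        Cinv = np.linalg.inv(C)
        sol = Cinv @ rhs
        beta = sol[: X.shape[1]]
        u = sol[X.shape[1]:]
        Cuu = Cinv[X.shape[1]:, X.shape[1]:]
        s2a_new = (u @ A_inv @ u + np.trace(A_inv @ Cuu) * s2e) / q
        s2e_new = (yty - beta @ Xty - u @ Zty) / (n - rank_x)
        s2a_new = max(s2a_new, 1e-10)
        s2e_new = max(s2e_new, 1e-10)
        change = max(abs(s2a_new - s2a) / max(s2a, 1e-10), abs(s2e_new - s2e) / max(s2e, 1e-10))
        s2a, s2e = float(s2a_new), float(s2e_new)
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn("EM-REML did not converge; returning last iterate", stacklevel=2)
    return s2a, s2e, converged
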