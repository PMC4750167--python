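"""Attribution of posterior genetic variance to 1-Mb genomic windows.

Each SNP belongs to the half-open 1-Mb bin ``[k*1e6, (k+1)*1e6)`` on its
chromosome, labelled ``chrom_k`` (so chromosome 4 at 78.5 Mb is ``4_78``).
For every stored MCMC sample the genetic variance of a window is the
empirical variance, across training animals, of the genomic values built
from the SNPs inside the window; dividing by the variance of the full
genomic value gives the proportion of genetic variance the window accounts
for in that sample.  Averaging over samples yields the reported %Var, and
the fraction of samples in which the window accounts for more than 0 % of
the variance gives the posterior probability column (``p > 0``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WindowAssignment",
    "assign_windows",
    "window_variances_per_sample",
    "summarize_windows",
    "top_window",
]

MB = 1_000_000

# relative floor below which a window variance counts as zero for pi = 0
# models, where every polymorphic SNP is always in the model
ZERO_TOL = 1e-12


@dataclass
class WindowAssignment:
    """Mapping from SNPs to 1-Mb windows."""

    window_of: np.ndarray      # int64 per SNP; -1 for SNPs without a position
    windows: pd.DataFrame      # columns: chrom, mb, label, n_snps

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def label_to_index(self, label: str) -> int:
        hit = self.windows.index[self.windows["label"] == label]
        if len(hit) == 0:
            raise KeyError(f"no window labelled {label!r}")
        return int(hit[0])

    def snps_in_window(self, label: str, snp_ids: list[str]) -> list[str]:
        w = self.label_to_index(label)
        return [snp_ids[j] for j in np.flatnonzero(self.window_of == w)]


def assign_windows(map_df: pd.DataFrame) -> WindowAssignment:
    """Bin SNPs into 1-Mb windows by ``floor(bp / 1e6)`` per chromosome."""
    chrom = map_df["chrom"].astype(str).to_numpy()
    bp = map_df["bp"].to_numpy()
    ok = ~pd.isna(bp)
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} SNPs lack a map position and are excluded from windows",
            stacklevel=2,
        )
    mb = np.where(ok, np.floor_divide(np.where(ok, bp, 0).astype(np.int64), MB), -1)
    keys = pd.DataFrame({"chrom": chrom, "mb": mb})
    uniq = (
        keys[ok]
        .drop_duplicates()
        .sort_values(["chrom", "mb"])
        .reset_index(drop=True)
    )
    index = {(c, m): i for i, (c, m) in enumerate(zip(uniq["chrom"], uniq["mb"]))}
    window_of = np.array(
        [index[(c, m)] if o else -1 for c, m, o in zip(chrom, mb, ok)], dtype=np.int64
    )
    uniq["label"] = uniq["chrom"].astype(str) + "_" + uniq["mb"].astype(str)
    counts = np.bincount(window_of[window_of >= 0], minlength=len(uniq))
    uniq["n_snps"] = counts
    return WindowAssignment(window_of=window_of, windows=uniq)


def window_variances_per_sample(
    effects: np.ndarray, centered_dosages: np.ndarray, assignment: WindowAssignment
) -> tuple[np.ndarray, float]:
    """Per-window genetic variance and the total, for one effect vector.

    ``centered_dosages`` is animals x SNPs, already centered as in training.
    Reference implementation (the sampler computes the same quantities
    incrementally); proportions are ``v_w / total`` with 0/0 defined as 0.
    """
    n, p = centered_dosages.shape
    v = np.zeros(assignment.n_windows)
    for w in range(assignment.n_windows):
        sel = assignment.window_of == w
        if sel.any():
            gw = centered_dosages[:, sel] @ effects[sel]
            v[w] = float(np.var(gw))
    total = float(np.var(centered_dosages @ effects))
    return v, total


def summarize_windows(fit) -> pd.DataFrame:
    """Posterior window-variance report from a fitted model.

    Returns one row per window with columns ``chrom``, ``mb``, ``label``,
    ``n_snps``, ``pct_var`` (posterior mean percentage of genetic variance),
    ``p_gt0`` (posterior probability the window accounts for > 0 % of the
    variance) and ``rank`` (1 = largest %Var).
    """
    if fit.window_samples is None or fit.window_samples.shape[0] == 0:
        raise ValueError("fit has no stored window-variance samples")
    V = np.asarray(fit.window_samples, dtype=np.float64)   # (samples, windows)
    total = np.asarray(fit.genetic_variance_samples, dtype=np.float64)
    S = V.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(total[:, None] > 0, V / total[:, None], 0.0)
    pct = 100.0 * prop.mean(axis=0)
    if fit.pi > 0:
        p_gt0 = (V > 0).mean(axis=0)
    else:
        p_gt0 = (V > ZERO_TOL * np.maximum(total[:, None], 0.0)).mean(axis=0)

    report = fit.window_assignment.windows.copy()
    report["pct_var"] = pct
    report["p_gt0"] = p_gt0
    order = np.argsort(-pct, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    report["rank"] = rank
    report["top"] = report["rank"] == 1
    return report.sort_values("rank").reset_index(drop=True)


def top_window(fit) -> str:
    """Label of the window with the largest posterior mean %Var."""
    return str(summarize_windows(fit).iloc[0]["label"])
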