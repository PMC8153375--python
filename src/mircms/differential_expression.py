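"""Two-condition differential expression for miRNAs and genes.

Two testing routes, matching how the two data types are produced:

* **miRNA DE** — replicate-level Student's t-test on normalised counts
  (RPM); a feature is flagged when |log2 fold-change| >= 1 and P < 0.05.
  With fewer than two replicates per side the p-value is undefined and only
  the fold-change rule applies.
* **gene DE** — the two libraries are compared as pooled counts with a
  per-gene two-proportion z-test (normal approximation of the binomial,
  exact binomial fallback at low counts): the same inferential target as
  DEGseq's MA-plot method (per-gene proportion difference between two
  libraries).  P-values are Benjamini-Hochberg adjusted.  Two named
  threshold presets are shipped: ``results`` (FDR <= 0.05 and |lfc| >= 1,
  the default) and ``methods`` (corrected P < 0.005 and |lfc| >= 1).

Fold changes on zero counts use a pseudo-count of 1 for reporting;
exclusive expression (all-zero in exactly one condition) is tracked in its
own column so zeros are not hidden by the pseudo-count.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEConfig",
    "normalize",
    "mirna_de",
    "gene_de",
    "bh_adjust",
    "sample_correlation",
]


@dataclass(frozen=True)
class DEConfig:
    """Significance thresholds; ``gene_preset`` picks the gene-DE rule."""

    mirna_lfc_min: float = 1.0
    mirna_p_max: float = 0.05
    gene_lfc_min: float = 1.0
    gene_fdr_max: float = 0.05       # "results" preset
    gene_padj_max: float = 0.005     # "methods" preset
    gene_preset: str = "results"
    pseudo_count: float = 1.0

    def __post_init__(self):
        if self.gene_preset not in ("results", "methods"):
            raise ValueError(f"unknown gene preset {self.gene_preset!r}")
        for name in ("mirna_lfc_min", "mirna_p_max", "gene_lfc_min",
                     "gene_fdr_max", "gene_padj_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# --------------------------------------------------------------------------
# normalisation

def normalize(counts: pd.DataFrame, method: str = "per-million",
              lengths: Mapping[str, float] | pd.Series | None = None
              ) -> pd.DataFrame:
    """Depth normalisation: reads-per-million or FPKM.

    ``per-million``: column / column-total * 1e6 (columns sum to 1e6).
    ``FPKM``: count * 1e9 / (feature length * column total); requires
    per-feature ``lengths`` in nucleotides.
    """
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero library total for {bad}")
    if method == "per-million":
        return counts / totals * 1e6
    if method.upper() == "FPKM":
        if lengths is None:
            raise ValueError("FPKM requires feature lengths")
        ln = pd.Series(lengths).reindex(counts.index)
        if ln.isna().any():
            missing = list(ln.index[ln.isna()])
            raise ValueError(f"missing lengths for {missing[:5]}")
        return counts.mul(1e9, axis=0).div(ln, axis=0) / totals
    raise ValueError(f"unknown normalisation method {method!r}")


# --------------------------------------------------------------------------
# multiple testing

def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    NaN entries (undefined tests) are passed through and do not count
    toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    pv = p[valid]
    n = pv.size
    if n:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(n)
        res[order] = np.minimum(adj, 1.0)
        out[valid] = res
    return out


# --------------------------------------------------------------------------
# miRNA DE (replicate t-test)

def _log2fc(mean_a: np.ndarray, mean_b: np.ndarray, pseudo: float) -> np.ndarray:
    return np.log2((mean_a + pseudo) / (mean_b + pseudo))


def mirna_de(norm_a: pd.DataFrame, norm_b: pd.DataFrame,
             config: DEConfig = DEConfig()) -> pd.DataFrame:
    """Per-miRNA t-test between two sets of normalised replicate columns.

    Index = features; columns of each frame = replicates of one condition.
    Zero variance in both groups with equal means gives p = 1 by
    convention.  The flag is ``up``/``down`` (A over B) or ``ns``.
    """
    if not norm_a.index.equals(norm_b.index):
        raise ValueError("feature universes differ between conditions")
    a = norm_a.to_numpy(dtype=float)
    b = norm_b.to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = _log2fc(mean_a, mean_b, config.pseudo_count)
    if a.shape[1] >= 2 and b.shape[1] >= 2:
        import warnings
        with np.errstate(divide="ignore", invalid="ignore"), \
                warnings.catch_warnings():
            # near-identical replicate groups trip scipy's precision warning;
            # those cases are overridden by the p = 1 convention below
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_ind(a, b, axis=1)
        degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
        p = np.where(degenerate & (mean_a == mean_b), 1.0, p)
        p = np.where(degenerate & (mean_a != mean_b), 0.0, p)
    else:
        p = np.full(len(lfc), np.nan)
    padj = bh_adjust(p)
    sig = (np.abs(lfc) >= config.mirna_lfc_min) & (
        np.isnan(p) | (p < config.mirna_p_max))
    flag = np.where(sig & (lfc > 0), "up", np.where(sig & (lfc < 0), "down", "ns"))
    exclusive = ((a.sum(axis=1) == 0) & (b.sum(axis=1) > 0)) | (
        (b.sum(axis=1) == 0) & (a.sum(axis=1) > 0))
    return pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "log2fc": lfc,
        "p": p, "p_adjusted": padj, "flag": flag, "exclusive": exclusive,
    }, index=norm_a.index)


# --------------------------------------------------------------------------
# gene DE (two-library proportion test)

def _two_proportion_p(x1: int, n1: int, x2: int, n2: int,
                      exact_threshold: int = 10) -> float:
    """Two-sided test of equal proportions x1/n1 vs x2/n2.

    Pooled z-test; for x1 + x2 below ``exact_threshold`` an exact binomial
    test conditional on the total is used instead.
    """
    if x1 + x2 == 0:
        return 1.0
    if x1 + x2 < exact_threshold:
        return float(stats.binomtest(x1, x1 + x2, n1 / (n1 + n2)).pvalue)
    p_pool = (x1 + x2) / (n1 + n2)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (x1 / n1 - x2 / n2) / se
    return float(2 * stats.norm.sf(abs(z)))


def gene_de(counts: pd.DataFrame, cols_a: Sequence[str], cols_b: Sequence[str],
            config: DEConfig = DEConfig()) -> pd.DataFrame:
    """Per-gene DE between two conditions from raw counts.

    Replicate columns of each condition are pooled into one library (the
    two-library design the proportion test models).  Flags follow the
    active preset; ``exclusive`` marks genes expressed in exactly one
    condition.
    """
    a = counts[list(cols_a)].sum(axis=1).astype(int)
    b = counts[list(cols_b)].sum(axis=1).astype(int)
    n1, n2 = int(a.sum()), int(b.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate library totals")
    # proportion-scale fold change so depth differences are not read as DE
    lfc = _log2fc((a / n1).to_numpy() * 1e6, (b / n2).to_numpy() * 1e6,
                  config.pseudo_count)
    p = np.array([_two_proportion_p(int(x1), n1, int(x2), n2)
                  for x1, x2 in zip(a, b)])
    padj = bh_adjust(p)
    cut = config.gene_fdr_max if config.gene_preset == "results" else config.gene_padj_max
    sig = (np.abs(lfc) >= config.gene_lfc_min) & (padj < cut)
    flag = np.where(sig & (lfc > 0), "up", np.where(sig & (lfc < 0), "down", "ns"))
    exclusive = ((a == 0) & (b > 0)) | ((b == 0) & (a > 0))
    return pd.DataFrame({
        "count_a": a, "count_b": b, "log2fc": lfc,
        "p": p, "p_adjusted": padj, "flag": flag,
        "exclusive": exclusive.to_numpy(),
    }, index=counts.index)


# --------------------------------------------------------------------------
# sample QC

def sample_correlation(normalized: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between sample columns.

    Zero-variance samples give NaN entries (flagged as undefined) rather
    than an arbitrary value; the diagonal is 1 for well-defined samples.
    """
    if normalized.shape[1] < 2:
        raise ValueError("need at least two samples")
    return normalized.corr(method="pearson")
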