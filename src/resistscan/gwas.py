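"""SNP-wise GWAS, contamination filtering, FDR, candidate windows, stepwise models.

The per-SNP model is a binomial GLM with logit link: phenotype
(resistant = 1) as response and genotype dose (number of non-reference
alleles, 0/1/2) as the single numeric predictor; the p-value is the
1-df likelihood-ratio test of the dose slope.  Sites enter the scan only
with no missing data and a minor allele count of at least five, and one
sib-pruned sample subset is used (averaging over subsets would not yield
interpretable p-values).

Plate-borne bacterial contamination can masquerade as association when
contamination levels differ between phenotype plates; SNPs whose
genotype correlates with per-sample contamination abundance (test
p < 0.05) are excluded before FDR.

Because single-SNP significance is scarce at field-study sample sizes,
candidate regions are also called from rank concentration: the 1000
smallest-p SNPs are located on a fixed 100-kb tiling and any tile holding
at least 10 of them (adjacent qualifying tiles merged) is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import logistic_lrt
from .data_model import MISSING, GenotypeData, SiteFilterSpec, site_filter_mask

GWAS_FILTER = SiteFilterSpec(require_accessible=True, max_missing=0.0,
                             min_mac=5, require_biallelic=True)


@dataclass
class AssociationScan:
    """Per-SNP association results plus candidate windows."""

    variants: pd.DataFrame                  # chrom, pos
    p_values: np.ndarray                    # NaN where excluded
    q_values: np.ndarray
    excluded_reason: np.ndarray             # '', 'contamination', ...
    slopes: np.ndarray
    score_fallback: np.ndarray
    top_set: np.ndarray = field(default=None)          # indices
    candidate_windows: pd.DataFrame = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        df = self.variants[["chrom", "pos"]].copy()
        df["p"] = self.p_values
        df["q"] = self.q_values
        df["excluded_reason"] = self.excluded_reason
        return df


def snp_glm_scan(g: GenotypeData, phenotypes: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP binomial-logit LRT p-values.

    Assumes sites are pre-filtered (no missing, MAC >= 5).  Returns
    (p, slope, score-fallback flags); complete separation falls back to
    the score test and is flagged.
    """
    geno = g.genotypes.T          # SNPs x samples
    if (geno == MISSING).any():
        raise ValueError("missing genotypes present; filter sites first")
    return logistic_lrt(geno, np.asarray(phenotypes))


def contamination_filter(g: GenotypeData, contamination: np.ndarray,
                         alpha: float = 0.05, method: str = "pearson"
                         ) -> np.ndarray:
    """Flag SNPs whose genotype correlates with contamination abundance.

    Per SNP, a correlation t-test (n-2 df) of dose against the
    contamination level; SNPs with p < alpha are flagged for exclusion.
    A constant contamination vector leaves every SNP unflagged (warns).
    """
    x = np.asarray(contamination, dtype=float)
    if np.ptp(x) == 0:
        warnings.warn("contamination vector constant; no exclusions",
                      stacklevel=2)
        return np.zeros(g.n_variants, dtype=bool)
    if method == "spearman":
        x = stats.rankdata(x)
        geno = np.apply_along_axis(stats.rankdata, 0,
                                   g.genotypes.astype(float))
    elif method == "pearson":
        geno = g.genotypes.astype(float)
    else:
        raise ValueError(f"unknown method {method!r}")
    n = len(x)
    xc = x - x.mean()
    gc = geno - geno.mean(axis=0)
    denom = np.sqrt((gc ** 2).sum(axis=0) * (xc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, gc.T @ xc / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return p < alpha


def fdr_adjust(p_values: np.ndarray, method: str = "bh",
               storey_lambda: float = 0.5) -> np.ndarray:
    """q-values by BH step-up (default) or Storey's pi0-adjusted variant."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values passed to FDR adjustment")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    if method == "bh":
        return q
    if method == "storey":
        pi0 = min(1.0, np.mean(p > storey_lambda) / (1 - storey_lambda))
        return np.minimum(q * pi0, 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


def top_snp_set(p_values: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
                top_n: int = 1000) -> np.ndarray:
    """Indices of the ``top_n`` smallest-p SNPs, ties broken by (chrom, pos)."""
    valid = np.nonzero(np.isfinite(p_values))[0]
    order = sorted(valid, key=lambda i: (p_values[i], str(chrom[i]),
                                         int(pos[i])))
    return np.array(order[:top_n], dtype=int)


def candidate_windows(chrom: np.ndarray, pos: np.ndarray,
                      top_idx: np.ndarray, window_bp: int = 100_000,
                      min_snps: int = 10) -> pd.DataFrame:
    """Fixed 100-kb tiles (from position 0) holding >= min_snps top SNPs.

    Adjacent qualifying tiles on the same chromosome are merged into one
    region.  Returns chrom, start, end (0-based half-open) and the top-SNP
    count per region.
    """
    rows = []
    top_chrom = np.asarray(chrom)[top_idx]
    top_pos = np.asarray(pos)[top_idx]
    for c in dict.fromkeys(top_chrom.tolist()):
        sel = top_chrom == c
        tiles = ((top_pos[sel].astype(np.int64) - 1) // window_bp).astype(int)
        tile_ids, counts = np.unique(tiles, return_counts=True)
        qual = tile_ids[counts >= min_snps]
        count_of = dict(zip(tile_ids.tolist(), counts.tolist()))
        if len(qual) == 0:
            continue
        # merge adjacent qualifying tiles
        run_start = qual[0]
        prev = qual[0]
        for t in list(qual[1:]) + [None]:
            if t is not None and t == prev + 1:
                prev = t
                continue
            n_top = sum(count_of[u] for u in range(run_start, prev + 1)
                        if u in count_of)
            rows.append((c, int(run_start * window_bp),
                         int((prev + 1) * window_bp), int(n_top)))
            if t is not None:
                run_start = prev = t
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_top_snps"])


def gwas_scan(g: GenotypeData, phenotypes: np.ndarray,
              contamination: np.ndarray | None = None,
              fdr_method: str = "bh", top_n: int = 1000,
              window_bp: int = 100_000, min_snps: int = 10
              ) -> AssociationScan:
    """Full GWAS stage on pre-filtered sites of one sib-pruned subset."""
    n_var = g.n_variants
    excluded = np.array([""] * n_var, dtype=object)
    if contamination is not None:
        contam = contamination_filter(g, contamination)
        excluded[contam] = "contamination"
    keep = excluded == ""
    p = np.full(n_var, np.nan)
    slopes = np.zeros(n_var)
    fallback = np.zeros(n_var, dtype=bool)
    sub = g.take_variants(keep)
    p_k, b_k, f_k = snp_glm_scan(sub, phenotypes)
    p[keep], slopes[keep], fallback[keep] = p_k, b_k, f_k
    q = np.full(n_var, np.nan)
    q[keep] = fdr_adjust(p[keep], method=fdr_method)

    chrom = g.variants["chrom"].to_numpy()
    pos = g.variants["pos"].to_numpy()
    top = top_snp_set(p, chrom, pos, top_n)
    windows = candidate_windows(chrom, pos, top, window_bp, min_snps)
    return AssociationScan(g.variants, p, q, excluded, slopes, fallback,
                           top, windows)


# ---------------------------------------------------------------------------
# Forward stepwise marker / copy-number models

@dataclass
class StepwiseModel:
    """Trace of a forward-stepwise binomial GLM."""

    selected: list[str]
    step_p: list[float]
    coefficients: dict[str, float]
    pool: list[str]


def marker_frequency(values: np.ndarray, kind: str = "snp") -> float:
    """Mutant-allele frequency for 0/1/2 doses; carrier fraction for CNVs."""
    values = np.asarray(values, dtype=float)
    if kind == "snp":
        return float(values.mean() / 2.0)
    if kind == "cnv":
        return float(np.mean(values != 2))
    raise ValueError(f"unknown marker kind {kind!r}")


def stepwise_marker_selection(markers: pd.DataFrame, phenotypes: np.ndarray,
                              freq_min: float = 0.10, alpha: float = 0.05,
                              kind: str = "snp") -> StepwiseModel:
    """Forward stepwise selection of additively coded markers.

    The candidate pool is restricted to markers at frequency >= freq_min.
    At each step every remaining candidate is added to the current model
    and its 1-df deviance-test p computed; the most significant enters if
    p < alpha, otherwise selection stops.  Collinear markers add zero
    deviance and therefore never enter after their proxy.
    """
    import statsmodels.api as sm

    y = np.asarray(phenotypes, dtype=float)
    pool = [m for m in markers.columns
            if marker_frequency(markers[m].to_numpy(), kind) >= freq_min]
    selected: list[str] = []
    step_p: list[float] = []

    def deviance(cols: list[str]) -> float:
        X = sm.add_constant(markers[cols].to_numpy(dtype=float)) \
            if cols else np.ones((len(y), 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        return float(model.deviance)

    dev_current = deviance(selected)
    remaining = list(pool)
    while remaining:
        best_p, best_m, best_dev = None, None, None
        for m in remaining:
            dev_new = deviance(selected + [m])
            drop = max(dev_current - dev_new, 0.0)
            p = float(stats.chi2.sf(drop, df=1))
            if best_p is None or p < best_p:
                best_p, best_m, best_dev = p, m, dev_new
        if best_p is not None and best_p < alpha:
            selected.append(best_m)
            step_p.append(best_p)
            remaining.remove(best_m)
            dev_current = best_dev
        else:
            break

    coefs: dict[str, float] = {}
    if selected:
        import statsmodels.api as sm
        X = sm.add_constant(markers[selected].to_numpy(dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        coefs = {"intercept": float(fit.params[0])}
        for k, m in enumerate(selected):
            coefs[m] = float(fit.params[k + 1])
    return StepwiseModel(selected, step_p, coefs, pool)
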