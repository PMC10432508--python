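"""GWAS power under genome-scale false-discovery-rate control.

How large a cohort is needed before a truly resistance-associated SNP
survives FDR correction alongside millions of null tests?  The
simulation projects an observed effect — summarized as the allele
frequency in the resistant and in the susceptible class — onto new
cohorts of a given size split 50/50 by phenotype.  Per replicate:

* 10 truly associated loci are drawn independently, genotypes
  Binomial(2, class frequency) per sample under within-class HWE;
* each true locus is tested with the same binomial-logit LRT used by the
  GWAS scan;
* 7 million non-associated SNPs contribute p-values drawn Uniform(0, 1)
  (generated in chunks so memory stays bounded);
* all p-values are FDR-adjusted jointly (BH) and the detection
  proportion is the fraction of true loci with q below the FDR level.

The power curve is the mean detection proportion over replicates per
sample size.  Defaults follow the study conditions (10 true loci,
7e6 nulls, 500 replicates); scaled-down runs preserve the null and
monotonicity properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._glm import logistic_lrt

N_TRUE_LOCI = 10
N_NULL = 7_000_000
N_REPS = 500


@dataclass
class PowerSimConfig:
    """Study conditions for the sample-size simulation."""

    freq_resistant: float
    freq_susceptible: float
    sample_sizes: tuple[int, ...]
    n_true_loci: int = N_TRUE_LOCI
    n_null: int = N_NULL
    n_reps: int = N_REPS
    fdr_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.freq_resistant, self.freq_susceptible):
            if not 0.0 <= f <= 1.0:
                raise ValueError("allele frequencies must be in [0, 1]")
        if any(n < 4 or n % 2 for n in self.sample_sizes):
            raise ValueError("sample sizes must be even and >= 4")


@dataclass
class PowerCurve:
    sample_sizes: tuple[int, ...]
    mean_power: np.ndarray
    mc_se: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"sample_size": self.sample_sizes,
                             "mean_power": self.mean_power,
                             "mc_se": self.mc_se})


def null_pvalue_block(n_null: int, seed: int,
                      chunk: int = 1_000_000) -> np.ndarray:
    """i.i.d. Uniform(0,1) p-values, generated in bounded-memory chunks."""
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    parts = [rng.random(min(chunk, n_null - k))
             for k in range(0, n_null, chunk)]
    return np.concatenate(parts)


def _bh_true_locus_hits(p_true: np.ndarray, p_null_sorted: np.ndarray,
                        level: float) -> int:
    """Count true loci significant under joint BH without materializing q.

    BH step-up over the union of true and null p-values: find the largest
    k with p_(k) <= k * level / m; all p below that cutoff are
    discoveries.  The null block is pre-sorted and shared across
    replicates of the same size, which is what makes 7e6 nulls per
    replicate affordable.
    """
    m = len(p_true) + len(p_null_sorted)
    p_all = np.sort(np.concatenate([p_true, p_null_sorted]))
    thresh = level * np.arange(1, m + 1) / m
    passing = np.nonzero(p_all <= thresh)[0]
    if len(passing) == 0:
        return 0
    cutoff = p_all[passing[-1]]
    return int((p_true <= cutoff).sum())


def _merge_sorted_hits(p_true: np.ndarray, p_null_sorted: np.ndarray,
                       level: float) -> int:
    """As :func:`_bh_true_locus_hits` but avoids re-sorting the null block."""
    m = len(p_true) + len(p_null_sorted)
    p_true_sorted = np.sort(p_true)
    # rank of each value in the merged order
    best_cutoff = -1.0
    # candidate k values only occur at the m points; evaluate true and null
    ranks_true = (np.searchsorted(p_null_sorted, p_true_sorted, side="right")
                  + np.arange(1, len(p_true_sorted) + 1))
    ok = p_true_sorted <= level * ranks_true / m
    if ok.any():
        best_cutoff = p_true_sorted[np.nonzero(ok)[0][-1]]
    ranks_null = (np.arange(1, len(p_null_sorted) + 1)
                  + np.searchsorted(p_true_sorted, p_null_sorted,
                                    side="right"))
    ok_null = p_null_sorted <= level * ranks_null / m
    if ok_null.any():
        cut_null = p_null_sorted[np.nonzero(ok_null)[0][-1]]
        best_cutoff = max(best_cutoff, cut_null)
    if best_cutoff < 0:
        return 0
    return int((p_true_sorted <= best_cutoff).sum())


def true_locus_pvalues(rng: np.random.Generator, n: int, f_res: float,
                       f_sus: float, n_loci: int) -> np.ndarray:
    """LRT p-values for ``n_loci`` independent true loci at sample size n.

    Half the cohort is resistant with allele frequency ``f_res``, half
    susceptible with ``f_sus``; a locus with identical genotypes across
    the cohort is untestable and scores p = 1.
    """
    half = n // 2
    g_res = rng.binomial(2, f_res, size=(n_loci, half))
    g_sus = rng.binomial(2, f_sus, size=(n_loci, half))
    geno = np.concatenate([g_res, g_sus], axis=1)
    y = np.concatenate([np.ones(half), np.zeros(half)]).astype(int)
    p, _, _ = logistic_lrt(geno, y)
    return p


def simulate_power(config: PowerSimConfig) -> PowerCurve:
    """Mean detection proportion of true loci per sample size.

    Both the true-locus genotypes and the null p-value block are redrawn
    independently in every replicate.
    """
    rng = np.random.default_rng(config.seed)
    means, ses = [], []
    for n in config.sample_sizes:
        props = np.empty(config.n_reps)
        for r in range(config.n_reps):
            p_true = true_locus_pvalues(rng, n, config.freq_resistant,
                                        config.freq_susceptible,
                                        config.n_true_loci)
            if config.n_null > 0:
                null_seed = int(rng.integers(2 ** 31 - 1))
                p_null = np.sort(null_pvalue_block(config.n_null, null_seed))
            else:
                p_null = np.empty(0)
            hits = _merge_sorted_hits(p_true, p_null, config.fdr_level)
            props[r] = hits / config.n_true_loci
        means.append(props.mean())
        ses.append(props.std(ddof=1) / np.sqrt(config.n_reps)
                   if config.n_reps > 1 else 0.0)
    return PowerCurve(tuple(config.sample_sizes), np.array(means),
                      np.array(ses))
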