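"""Windowed differentiation/selection scans with peak calling.

Statistics are computed in non-overlapping windows of a fixed number of
post-filter SNPs (1000 by default, matching genome-scan practice for
Anopheles cohorts; a trailing partial window is dropped):

* **Hudson F_ST** between resistant and susceptible samples, computed as
  the ratio of window-summed per-site numerator and denominator
  components.  Per site, with sample allele frequencies p1, p2 estimated
  from n1, n2 called allele copies:

      num = (p1 - p2)^2 - p1 (1 - p1)/(n1 - 1) - p2 (1 - p2)/(n2 - 1)
      den = p1 (1 - p2) + p2 (1 - p1)

  To use full sib-structured sample sets without pseudo-replication, the
  scan is averaged over sib-pruned sample subsets.

* **PBS** for the resistant branch against the susceptible group and an
  outgroup: PBS = (T_RS + T_RO - T_SO) / 2 with T = -log(1 - F_ST).
  F_ST is clamped to [0, 1 - 1e-8] before the log.

* **Garud's H12** per group from phased haplotypes: with window haplotype
  frequencies p1 >= p2 >= ..., H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2,
  elevated under both hard and soft sweeps.  **DeltaH12** is
  H12(resistant) - H12(susceptible).

Peak calling anchors on the mode of the per-window distribution: genuine
peaks are one-sided, so the left tail calibrates the expected spread.
With mode m and d = m - min(values), any value above m + 3 d is a
provisional peak.  Provisional peaks are then re-tested against a
phenotype-label permutation null and retained only above its 99th
centile, which removes peaks caused by swept haplotypes unrelated to
phenotype (extended homozygosity inflates window variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .data_model import MISSING, GenotypeData

WINDOW_SNPS = 1000


@dataclass
class WindowScan:
    """Per-window statistic values with peak metadata."""

    statistic: str
    chrom: np.ndarray
    start: np.ndarray            # first SNP position (1-based)
    end: np.ndarray              # last SNP position (1-based)
    values: np.ndarray
    n_snps: int = WINDOW_SNPS
    perm_q99: np.ndarray | None = None
    provisional: np.ndarray | None = None
    retained: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.values)


def window_slices(g: GenotypeData, window_snps: int = WINDOW_SNPS
                  ) -> list[tuple[str, slice]]:
    """Non-overlapping left-aligned windows of ``window_snps`` per chromosome.

    The trailing remainder on each chromosome is dropped.
    """
    out = []
    chroms = g.variants["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):        # preserve order
        idx = np.nonzero(chroms == chrom)[0]
        for k in range(len(idx) // window_snps):
            lo = idx[k * window_snps]
            out.append((chrom, slice(lo, lo + window_snps)))
    return out


def _window_meta(g: GenotypeData, slices: list[tuple[str, slice]]
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pos = g.variants["pos"].to_numpy()
    chrom = np.array([c for c, _ in slices])
    start = np.array([pos[s.start] for _, s in slices])
    end = np.array([pos[s.stop - 1] for _, s in slices])
    return chrom, start, end


def _allele_counts(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele count and called allele copies per site."""
    called = geno != MISSING
    alt = np.where(called, geno, 0).sum(axis=0).astype(float)
    n = 2.0 * called.sum(axis=0)
    return alt, n


def hudson_fst_components(geno1: np.ndarray, geno2: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerator and denominator for two genotype blocks."""
    alt1, n1 = _allele_counts(geno1)
    alt2, n2 = _allele_counts(geno2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, alt1 / n1, np.nan)
        p2 = np.where(n2 > 0, alt2 / n2, np.nan)
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / np.maximum(n1 - 1, 1e-300)
               - p2 * (1 - p2) / np.maximum(n2 - 1, 1e-300))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = ~np.isfinite(num) | ~np.isfinite(den)
    num = np.where(bad, 0.0, num)
    den = np.where(bad, 0.0, den)
    return num, den


def _fst_per_window(geno: np.ndarray, group1: np.ndarray, group2: np.ndarray,
                    slices: list[tuple[str, slice]]) -> np.ndarray:
    num, den = hudson_fst_components(geno[group1], geno[group2])
    vals = np.empty(len(slices))
    for w, (_, s) in enumerate(slices):
        d = den[s].sum()
        vals[w] = num[s].sum() / d if d > 0 else np.nan
    return vals


def windowed_fst(g: GenotypeData, resistant: Sequence[str],
                 susceptible: Sequence[str],
                 sib_subsets: list[list[str]] | None = None,
                 window_snps: int = WINDOW_SNPS) -> WindowScan:
    """Sib-permutation-averaged Hudson F_ST in fixed-SNP windows.

    ``sib_subsets`` come from sib-pruning permutations over the whole
    sample set; each is intersected with the two phenotype groups and the
    window values are averaged across subsets.  Without subsets a single
    pass over all listed samples is used.  A window whose summed
    denominator is zero is NaN and excluded from peak detection.
    """
    slices = window_slices(g, window_snps)
    index = {s: i for i, s in enumerate(g.sample_ids)}
    res_set, sus_set = set(resistant), set(susceptible)
    if sib_subsets is None:
        sib_subsets = [list(resistant) + list(susceptible)]

    acc = np.zeros(len(slices))
    cnt = np.zeros(len(slices))
    for subset in sib_subsets:
        g1 = np.array([index[s] for s in subset if s in res_set], dtype=int)
        g2 = np.array([index[s] for s in subset if s in sus_set], dtype=int)
        vals = _fst_per_window(g.genotypes, g1, g2, slices)
        ok = np.isfinite(vals)
        acc[ok] += vals[ok]
        cnt[ok] += 1
    values = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    chrom, start, end = _window_meta(g, slices)
    return WindowScan("FST", chrom, start, end, values, window_snps)


def _clamped_branch(fst: np.ndarray) -> np.ndarray:
    return -np.log1p(-np.clip(fst, 0.0, 1.0 - 1e-8))


def windowed_pbs(g: GenotypeData, resistant: Sequence[str],
                 susceptible: Sequence[str], outgroup: Sequence[str],
                 window_snps: int = WINDOW_SNPS) -> WindowScan:
    """Population branch statistic for the resistant branch.

    PBS = (T_RS + T_RO - T_SO)/2, T = -log(1 - F_ST), with per-window
    Hudson F_ST between each pair of groups.
    """
    slices = window_slices(g, window_snps)
    index = {s: i for i, s in enumerate(g.sample_ids)}
    gr = np.array([index[s] for s in resistant], dtype=int)
    gs = np.array([index[s] for s in susceptible], dtype=int)
    go = np.array([index[s] for s in outgroup], dtype=int)
    f_rs = _fst_per_window(g.genotypes, gr, gs, slices)
    f_ro = _fst_per_window(g.genotypes, gr, go, slices)
    f_so = _fst_per_window(g.genotypes, gs, go, slices)
    values = (_clamped_branch(f_rs) + _clamped_branch(f_ro)
              - _clamped_branch(f_so)) / 2.0
    chrom, start, end = _window_meta(g, slices)
    return WindowScan("PBS", chrom, start, end, values, window_snps)


def h12_from_haplotypes(hap_window: np.ndarray) -> float:
    """Garud's H12 for one window's haplotypes (rows = haplotypes).

    Haplotype identity is exact allele-string match over the window.
    """
    if hap_window.shape[0] < 2:
        raise ValueError("H12 requires at least two haplotypes")
    _, counts = np.unique(hap_window, axis=0, return_counts=True)
    freqs = np.sort(counts / counts.sum())[::-1]
    h12 = freqs[:2].sum() ** 2 + np.sum(freqs[2:] ** 2)
    return float(h12)


def _hap_rows(g: GenotypeData, samples: Sequence[str]) -> np.ndarray:
    if g.haplotypes is None:
        raise ValueError("phased haplotypes required")
    index = {s: i for i, s in enumerate(g.sample_ids)}
    idx = np.array([index[s] for s in samples], dtype=int)
    return np.ravel(np.column_stack([2 * idx, 2 * idx + 1]))


def windowed_h12(g: GenotypeData, samples: Sequence[str],
                 window_snps: int = WINDOW_SNPS) -> WindowScan:
    """H12 per window for one group, from phased biallelic haplotypes."""
    rows = _hap_rows(g, samples)
    slices = window_slices(g, window_snps)
    values = np.array([h12_from_haplotypes(g.haplotypes[rows, s])
                       for _, s in slices])
    chrom, start, end = _window_meta(g, slices)
    return WindowScan("H12", chrom, start, end, values, window_snps)


def delta_h12(g: GenotypeData, resistant: Sequence[str],
              susceptible: Sequence[str],
              window_snps: int = WINDOW_SNPS) -> WindowScan:
    """DeltaH12 = H12(resistant) - H12(susceptible) per window."""
    res = windowed_h12(g, resistant, window_snps)
    sus = windowed_h12(g, susceptible, window_snps)
    return WindowScan("DeltaH12", res.chrom, res.start, res.end,
                      res.values - sus.values, window_snps)


def estimate_mode(values: np.ndarray, method: str = "kde",
                  grid_points: int = 512) -> float:
    """Mode of a continuous sample.

    ``kde``: Gaussian kernel density (Silverman bandwidth), argmax on a
    regular grid over the data range.  ``histogram``: midpoint of the
    fullest of sqrt(n) bins.
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return float(values[0])
    if method == "kde":
        kde = stats.gaussian_kde(values, bw_method="silverman")
        grid = np.linspace(values.min(), values.max(), grid_points)
        return float(grid[np.argmax(kde(grid))])
    if method == "histogram":
        nbins = max(int(np.sqrt(len(values))), 10)
        hist, edges = np.histogram(values, bins=nbins)
        k = int(np.argmax(hist))
        return float(0.5 * (edges[k] + edges[k + 1]))
    raise ValueError(f"unknown mode method {method!r}")


def detect_outlier_windows(values: np.ndarray, mode_method: str = "kde"
                           ) -> np.ndarray:
    """Mode-anchored one-sided outlier flags.

    With mode m and left-spread d = m - min(values), flags values
    strictly above m + 3 d.  NaN windows are never flagged.  Requires at
    least 30 finite values; all-identical input yields no peaks.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 30:
        raise ValueError("need at least 30 finite window values")
    vals = values[finite]
    m = estimate_mode(vals, method=mode_method)
    d = m - vals.min()
    flags = np.zeros(len(values), dtype=bool)
    flags[finite] = vals > m + 3.0 * d
    return flags


def permutation_filter(stat_fn: Callable[[np.ndarray], np.ndarray],
                       phenotypes: np.ndarray,
                       observed: np.ndarray,
                       provisional: np.ndarray,
                       n_perm: int = 200,
                       centile: float = 0.99,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Retain provisional peaks exceeding a phenotype-permutation null.

    ``stat_fn`` maps a permuted phenotype-label vector to the per-window
    statistic vector (same layout as ``observed``).  Per provisional
    window, the empirical ``centile`` (linear-interpolation quantile) of
    the ``n_perm`` permuted values is computed; the peak is retained iff
    the observed value is strictly greater.

    Returns (retained flags, per-window permutation quantile — NaN for
    non-provisional windows).
    """
    rng = np.random.default_rng(seed)
    phenotypes = np.asarray(phenotypes)
    perm_vals = np.empty((n_perm, len(observed)))
    for k in range(n_perm):
        perm = rng.permutation(phenotypes)
        perm_vals[k] = stat_fn(perm)
    q = np.full(len(observed), np.nan)
    idx = np.nonzero(provisional)[0]
    if len(idx):
        q[idx] = np.quantile(perm_vals[:, idx], centile, axis=0)
    retained = provisional & np.where(np.isnan(q), False, observed > q)
    return retained, q


def scan_to_frame(scan: WindowScan):
    """Window scan as a tidy table for TSV export."""
    import pandas as pd

    df = pd.DataFrame({
        "chrom": scan.chrom, "start": scan.start, "end": scan.end,
        "n_snps": scan.n_snps, "statistic": scan.statistic,
        "value": scan.values,
    })
    if scan.perm_q99 is not None:
        df["perm_q99"] = scan.perm_q99
    if scan.provisional is not None:
        df["provisional_peak"] = scan.provisional
    if scan.retained is not None:
        df["retained_peak"] = scan.retained
    return df
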