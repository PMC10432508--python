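"""Sample QC accounting, sex calling, KING-robust kinship and sib handling.

Larval collections often contain full siblings, which act as hidden
population stratification in case/control comparisons.  The pipeline
estimates pairwise kinship with the KING-robust between-family estimator

    phi_ij = (N_AaAa - 2 * N_AAaa) / (N_Aa(i) + N_Aa(j))

where counts are taken over sites called in both samples: N_AaAa = sites
where both are heterozygous, N_AAaa = sites with opposite homozygotes,
N_Aa(x) = heterozygous sites in sample x.  Full sibs have expected
phi = 0.25, identical samples 0.5, unrelated pairs 0.

Sib groups are the connected components of the graph whose edges join
pairs with phi strictly above a threshold; a group is *inconsistent* when
transitivity forced in a pair that is itself below the threshold.  The
working threshold is chosen empirically by scanning a grid and minimizing
the proportion of inconsistent groups.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import MISSING, GenotypeData

QC_DEFAULTS = {"min_coverage": 10.0, "max_alpha": 0.045,
               "replicate_distance": 0.006}

SEX_MALE = (0.4, 0.6)
SEX_FEMALE = (0.8, 1.2)


@dataclass
class SampleQC:
    """Per-sample sequencing QC record."""

    sample_id: str
    mean_coverage: float
    contamination_alpha: float
    replicate_partner: str | None = None
    replicate_distance: float | None = None


def apply_sequencing_qc(records: list[SampleQC],
                        min_coverage: float = QC_DEFAULTS["min_coverage"],
                        max_alpha: float = QC_DEFAULTS["max_alpha"],
                        replicate_distance: float = QC_DEFAULTS["replicate_distance"],
                        ) -> tuple[list[str], dict[str, int]]:
    """Sequential sample exclusion: low coverage, contamination, replicates.

    Rules apply in order and each sample is counted at most once (a sample
    failing an earlier rule is invisible to later rules).  Coverage uses a
    strict "< min_coverage" cut and contamination a strict "> max_alpha"
    cut.  Of each surviving technical replicate pair (genetic distance
    below ``replicate_distance``) the higher-coverage member is retained.
    """
    removed: set[str] = set()
    counts = {"low_coverage": 0, "contamination": 0, "replicate": 0}

    for rec in records:
        if rec.mean_coverage < min_coverage:
            removed.add(rec.sample_id)
            counts["low_coverage"] += 1
    for rec in records:
        if rec.sample_id in removed:
            continue
        if rec.contamination_alpha > max_alpha:
            removed.add(rec.sample_id)
            counts["contamination"] += 1
    by_id = {rec.sample_id: rec for rec in records}
    for rec in records:
        if rec.sample_id in removed or rec.replicate_partner is None:
            continue
        partner = by_id.get(rec.replicate_partner)
        if partner is None or partner.sample_id in removed:
            continue
        dist = rec.replicate_distance
        if dist is not None and dist < replicate_distance:
            drop = (rec if rec.mean_coverage <= partner.mean_coverage
                    else partner)
            removed.add(drop.sample_id)
            counts["replicate"] += 1
    passed = [rec.sample_id for rec in records if rec.sample_id not in removed]
    return passed, counts


def call_sex(x_cov: float, auto_cov: float) -> str:
    """Classify sex from the X / autosome modal coverage ratio.

    Ratio in [0.4, 0.6] -> male; [0.8, 1.2] -> female (boundaries
    inclusive); anything else leads to sample exclusion.
    """
    if auto_cov <= 0:
        raise ValueError("autosomal coverage must be positive")
    ratio = x_cov / auto_cov
    if SEX_MALE[0] <= ratio <= SEX_MALE[1]:
        return "male"
    if SEX_FEMALE[0] <= ratio <= SEX_FEMALE[1]:
        return "female"
    return "excluded"


@dataclass
class KinshipResult:
    """Pairwise kinship with sib grouping metadata."""

    phi: np.ndarray
    sample_ids: list[str]
    threshold: float | None = None
    sib_groups: list[list[str]] = field(default_factory=list)
    inconsistent: list[bool] = field(default_factory=list)
    scan_trace: list[tuple[float, float]] = field(default_factory=list)
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)


def king_kinship(g: GenotypeData) -> KinshipResult:
    """KING-robust pairwise kinship over all sample pairs.

    Counts use sites non-missing in both samples.  A pair with zero
    informative heterozygous sites has undefined kinship; it is flagged
    and treated as unrelated (phi = 0).
    """
    geno = g.genotypes
    n = g.n_samples
    called = geno != MISSING
    het = (geno == 1) & called
    hom_ref = geno == 0
    hom_alt = geno == 2

    het_f = het.astype(np.float64)
    # pairwise counts via matrix products
    n_het_het = het_f @ het_f.T
    n_opp = (hom_ref.astype(np.float64) @ hom_alt.astype(np.float64).T)
    n_opp = n_opp + n_opp.T
    called_f = called.astype(np.float64)
    # het sites of i restricted to sites called in j (and vice versa)
    het_i_called_j = het_f @ called_f.T

    denom = het_i_called_j + het_i_called_j.T
    phi = np.zeros((n, n))
    undefined = []
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_het_het - 2.0 * n_opp) / denom, 0.0)
    np.fill_diagonal(phi, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            if denom[i, j] == 0:
                undefined.append((g.sample_ids[i], g.sample_ids[j]))
    return KinshipResult(phi, list(g.sample_ids), undefined_pairs=undefined)


def build_sib_groups(phi: np.ndarray, sample_ids: list[str],
                     threshold: float
                     ) -> tuple[list[list[str]], list[bool]]:
    """Connected components of the phi > threshold graph (strict edges).

    Returns only groups of size >= 2 together with a per-group flag that
    is True when some within-group pair sits at or below the threshold
    (a transitivity inconsistency).
    """
    n = len(sample_ids)
    adj = phi > threshold
    np.fill_diagonal(adj, False)
    seen = np.zeros(n, dtype=bool)
    groups, inconsistent = [], []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(adj[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        if len(comp) >= 2:
            comp.sort()
            groups.append([sample_ids[k] for k in comp])
            bad = any(phi[a, b] <= threshold
                      for a, b in itertools.combinations(comp, 2))
            inconsistent.append(bad)
    return groups, inconsistent


def threshold_grid(lo: float = 0.15, hi: float = 0.35,
                   step: float = 0.005) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


def optimize_sib_threshold(phi: np.ndarray, sample_ids: list[str],
                           grid: np.ndarray | None = None
                           ) -> tuple[float, list[tuple[float, float]]]:
    """Scan a threshold grid, minimizing the proportion of inconsistent groups.

    At thresholds producing no groups the proportion is defined as 0.
    Ties are broken toward the largest grid value among the minimizers
    (the most conservative sib-calling).
    """
    if grid is None:
        grid = threshold_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    trace = []
    for t in grid:
        groups, inconsistent = build_sib_groups(phi, sample_ids, t)
        prop = (sum(inconsistent) / len(groups)) if groups else 0.0
        trace.append((float(t), prop))
    props = np.array([p for _, p in trace])
    best = np.nonzero(props == props.min())[0][-1]   # largest minimizer
    return float(grid[best]), trace


def analyse_kinship(g: GenotypeData,
                    grid: np.ndarray | None = None) -> KinshipResult:
    """Full kinship stage: phi, threshold scan, sib groups at the optimum."""
    res = king_kinship(g)
    threshold, trace = optimize_sib_threshold(res.phi, res.sample_ids, grid)
    groups, inconsistent = build_sib_groups(res.phi, res.sample_ids, threshold)
    res.threshold = threshold
    res.scan_trace = trace
    res.sib_groups = groups
    res.inconsistent = inconsistent
    return res


def sib_prune_permutations(groups: list[list[str]], all_samples: list[str],
                           n_max: int = 100, seed: int = 0
                           ) -> list[list[str]]:
    """Distinct sample subsets keeping one member per sib group.

    Each subset contains every non-sib sample plus exactly one member of
    each sib group.  The set of possible keep-combinations is sampled
    without replacement, so the number of subsets is
    min(n_max, product of group sizes); with no sib groups a single
    subset equal to ``all_samples`` is returned.
    """
    rng = np.random.default_rng(seed)
    in_group = {s for grp in groups for s in grp}
    non_sibs = [s for s in all_samples if s not in in_group]
    if not groups:
        return [list(all_samples)]

    total = 1
    for grp in groups:
        total *= len(grp)
        if total > n_max:
            break
    if total <= n_max:
        combos = list(itertools.product(*groups))
    else:
        chosen: set[tuple[str, ...]] = set()
        while len(chosen) < n_max:
            pick = tuple(grp[rng.integers(len(grp))] for grp in groups)
            chosen.add(pick)
        combos = sorted(chosen)
    subsets = []
    for pick in combos:
        subset = [s for s in all_samples if s in non_sibs or s in set(pick)]
        subsets.append(subset)
    return subsets
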