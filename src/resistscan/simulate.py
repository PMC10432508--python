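"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a field-collected, bioassay-phenotyped mosquito
sample set: larval collections contain full-sib families (simulated as two
unobserved parents per family, children inheriting one recombined
haplotype from each), resistance is a logistic-additive function of causal
genotypes, selective sweeps appear as near-identical haplotype clusters
that may be enriched in the resistant class, gene amplifications show up
as elevated normalized coverage, and DNA-plate layout induces a
contamination gradient across well columns.

Founder haplotypes are site-independent by default (allele frequencies
drawn from a Beta prior), which keeps the analytic expectations of the
downstream statistics tractable; an optional block-copying mode introduces
background linkage disequilibrium for sweep realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import GenotypeData, SampleManifest

PLATE_ROWS, PLATE_COLS = 8, 12


@dataclass
class SweepSpec:
    """A swept haplotype cluster injected over ``[start, end)`` variants.

    Carrier haplotypes are overwritten with a shared core haplotype plus
    independent Bernoulli(noise_rate) flips per site.  Carrier fractions
    may differ between phenotype classes so that sweep–phenotype
    association is under the caller's control (equal fractions give an
    unassociated sweep).
    """

    start: int
    end: int
    carrier_frac_resistant: float
    carrier_frac_susceptible: float | None = None
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.carrier_frac_susceptible is None:
            self.carrier_frac_susceptible = self.carrier_frac_resistant
        for f in (self.carrier_frac_resistant, self.carrier_frac_susceptible):
            if not 0.0 <= f <= 1.0:
                raise ValueError("carrier fractions must be in [0, 1]")


@dataclass
class CnvSpec:
    """A copy-number variant: gene span (bp), integer copy number, carrier fraction."""

    start_bp: int
    end_bp: int
    copy_number: int
    carrier_fraction: float


@dataclass
class SimConfig:
    """Study-condition parameters for a synthetic sample set."""

    n_samples: int = 100
    n_variants: int = 2000
    chrom_length: int = 1_000_000
    chrom: str = "2R"
    n_families: int = 0
    family_sizes: tuple[int, ...] = ()          # explicit sizes, each >= 2
    allele_freq_beta: tuple[float, float] = (0.8, 0.8)
    causal_loci: tuple[tuple[int, float], ...] = ()   # (variant index, beta)
    intercept: float = 0.0
    sweep_specs: tuple[SweepSpec, ...] = ()
    cnv_specs: tuple[CnvSpec, ...] = ()
    contamination_slope: float = 0.0            # per plate column
    contamination_noise: float = 0.01
    recombination_rate: float = 1.0             # crossovers per transmitted copy
    coverage_sd: float = 0.1
    coverage_window_bp: int = 300
    ld_block_size: int = 0                      # >0 enables block-copy LD mode
    location: str = "SimTown"
    country: str = "Simland"
    species: str = "gambiae"
    insecticide: str = "deltamethrin"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families and not self.family_sizes:
            self.family_sizes = tuple([4] * self.n_families)
        self.n_families = len(self.family_sizes)
        if any(s < 2 for s in self.family_sizes):
            raise ValueError("family sizes must be >= 2")
        if sum(self.family_sizes) > self.n_samples:
            raise ValueError("family members exceed n_samples")
        for idx, _beta in self.causal_loci:
            if not 0 <= idx < self.n_variants:
                raise ValueError(f"causal locus index {idx} out of range")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated cohort."""

    family_of_sample: dict[str, int]           # -1 = unrelated
    causal_loci: list[tuple[int, float]]
    sweep_carrier_haplotypes: list[list[int]]  # per sweep spec
    cnv_carrier_samples: list[list[str]]       # per cnv spec
    contamination: dict[str, float]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "family_of_sample": self.family_of_sample,
                "causal_loci": [[int(i), float(b)] for i, b in self.causal_loci],
                "sweep_carrier_haplotypes": self.sweep_carrier_haplotypes,
                "cnv_carrier_samples": self.cnv_carrier_samples,
                "contamination": self.contamination,
            }, fh, indent=1)


def _founder_haplotypes(rng: np.random.Generator, n_hap: int,
                        config: SimConfig, freqs: np.ndarray) -> np.ndarray:
    """Founder haplotypes from the shared population site frequencies."""
    hap = (rng.random((n_hap, config.n_variants)) < freqs).astype(np.int8)
    if config.ld_block_size > 0:
        # block-copy mode: haplotypes are mosaics of a small founder pool,
        # creating background LD within blocks
        pool = hap[: max(4, n_hap // 4)]
        out = np.empty_like(hap)
        n_blocks = -(-config.n_variants // config.ld_block_size)
        for i in range(n_hap):
            for blk in range(n_blocks):
                lo = blk * config.ld_block_size
                hi = min(lo + config.ld_block_size, config.n_variants)
                out[i, lo:hi] = pool[rng.integers(len(pool)), lo:hi]
        hap = out
    return hap


def _transmit(rng: np.random.Generator, parent: np.ndarray,
              rate: float, n_variants: int) -> np.ndarray:
    """One recombined gamete from a parent's two haplotypes."""
    n_cross = rng.poisson(rate)
    breaks = np.sort(rng.integers(1, n_variants, size=n_cross))
    gamete = np.empty(n_variants, dtype=np.int8)
    cur = int(rng.integers(2))
    lo = 0
    for brk in list(breaks) + [n_variants]:
        gamete[lo:brk] = parent[cur, lo:brk]
        cur = 1 - cur
        lo = brk
    return gamete


def simulate_cohort(config: SimConfig
                    ) -> tuple[GenotypeData, SampleManifest, SyntheticTruth]:
    """Simulate genotypes, manifest and truth record for one sample set.

    Families come first in sample order, then unrelated individuals.
    Phenotype is Bernoulli(logistic(b0 + sum bk*gk)); sweeps are injected
    after phenotypes are drawn so carrier fractions can be
    phenotype-specific.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    nv = config.n_variants
    a, b = config.allele_freq_beta
    freqs = rng.beta(a, b, size=nv)       # one population frequency vector
    hap = np.empty((2 * n, nv), dtype=np.int8)
    family_of = {}

    i = 0
    for fam, size in enumerate(config.family_sizes):
        parents = _founder_haplotypes(rng, 4, config, freqs)
        mother, father = parents[:2], parents[2:]
        for _ in range(size):
            hap[2 * i] = _transmit(rng, mother, config.recombination_rate, nv)
            hap[2 * i + 1] = _transmit(rng, father, config.recombination_rate, nv)
            family_of[f"S{i:04d}"] = fam
            i += 1
    n_unrel = n - i
    if n_unrel:
        hap[2 * i:] = _founder_haplotypes(rng, 2 * n_unrel, config, freqs)
        for j in range(i, n):
            family_of[f"S{j:04d}"] = -1

    geno = hap[0::2] + hap[1::2]

    # phenotype: logistic-additive over causal doses
    eta = np.full(n, config.intercept, dtype=float)
    for idx, beta in config.causal_loci:
        eta += beta * geno[:, idx]
    p_resistant = 1.0 / (1.0 + np.exp(-eta))
    resistant = rng.random(n) < p_resistant

    # sweeps: overwrite carrier haplotypes with a noisy copy of a core
    sweep_carriers: list[list[int]] = []
    for spec in config.sweep_specs:
        core = (rng.random(spec.end - spec.start) < 0.5).astype(np.int8)
        carriers = []
        for s in range(n):
            frac = (spec.carrier_frac_resistant if resistant[s]
                    else spec.carrier_frac_susceptible)
            for h in (2 * s, 2 * s + 1):
                if rng.random() < frac:
                    noisy = core.copy()
                    flips = rng.random(len(core)) < spec.noise_rate
                    noisy[flips] ^= 1
                    hap[h, spec.start:spec.end] = noisy
                    carriers.append(h)
        sweep_carriers.append(carriers)
    geno = hap[0::2] + hap[1::2]

    sample_ids = [f"S{j:04d}" for j in range(n)]
    positions = np.sort(rng.choice(
        np.arange(1, config.chrom_length + 1), size=nv, replace=False))
    variants = pd.DataFrame({
        "chrom": config.chrom, "pos": positions,
        "ref": "A", "alt": "T", "accessible": True,
        "annotation": None, "biallelic": True,
    })
    gdata = GenotypeData(variants, geno, sample_ids, hap)

    # plate layout: fill plates column-major; contamination rises with column
    wells = []
    contamination = {}
    for j, sid in enumerate(sample_ids):
        plate, pos = divmod(j, PLATE_ROWS * PLATE_COLS)
        col, row = divmod(pos, PLATE_ROWS)
        wells.append((f"P{plate + 1}", row + 1, col + 1))
        level = (config.contamination_slope * col
                 + rng.normal(0.0, config.contamination_noise))
        contamination[sid] = float(max(level, 0.0))

    manifest = SampleManifest(pd.DataFrame({
        "sample_id": sample_ids,
        "location": config.location,
        "country": config.country,
        "species": config.species,
        "insecticide": config.insecticide,
        "phenotype": np.where(resistant, "alive", "dead"),
        "plate_id": [w[0] for w in wells],
        "well_row": [w[1] for w in wells],
        "well_col": [w[2] for w in wells],
        "sex": "female",
        "qc_pass": True,
    }))

    cnv_carriers = [
        [sid for sid in sample_ids
         if rng.random() < spec.carrier_fraction]
        for spec in config.cnv_specs
    ]
    truth = SyntheticTruth(family_of, list(config.causal_loci),
                           sweep_carriers, cnv_carriers, contamination)
    return gdata, manifest, truth


@dataclass
class CoverageProfile:
    """Per-sample normalized coverage over consecutive fixed-width windows."""

    chrom: str
    window_starts: np.ndarray          # 0-based window start (bp)
    window_bp: int
    values: np.ndarray                 # samples × windows, diploid baseline 1.0
    sample_ids: list[str]

    def write(self, path: str | Path) -> None:
        rows = []
        for i, sid in enumerate(self.sample_ids):
            for w, start in enumerate(self.window_starts):
                rows.append((sid, self.chrom, int(start),
                             float(self.values[i, w])))
        pd.DataFrame(rows, columns=["sample", "chrom", "window_start",
                                    "value"]).to_csv(path, sep="\t",
                                                     index=False)


def simulate_coverage(config: SimConfig,
                      truth: SyntheticTruth | None = None
                      ) -> tuple[CoverageProfile, SyntheticTruth]:
    """Normalized coverage tracks with CNV segments at elevated depth.

    Window coverage is Normal(CN/2, sd) truncated at 0, with CN = 2
    outside CNV spans.  If ``truth`` (from :func:`simulate_cohort`) is
    given its CNV carrier assignment is reused; otherwise carriers are
    drawn here and a minimal truth record returned.
    """
    rng = np.random.default_rng(config.seed + 1)
    sample_ids = [f"S{j:04d}" for j in range(config.n_samples)]
    starts = np.arange(0, config.chrom_length, config.coverage_window_bp)
    n_win = len(starts)
    cn = np.full((config.n_samples, n_win), 2, dtype=int)

    if truth is not None and truth.cnv_carrier_samples:
        carrier_lists = truth.cnv_carrier_samples
    else:
        carrier_lists = [
            [sid for sid in sample_ids if rng.random() < spec.carrier_fraction]
            for spec in config.cnv_specs
        ]
    for spec, carriers in zip(config.cnv_specs, carrier_lists):
        if spec.end_bp > config.chrom_length:
            raise ValueError("CNV span exceeds chromosome length")
        w_lo = spec.start_bp // config.coverage_window_bp
        w_hi = -(-spec.end_bp // config.coverage_window_bp)
        for sid in carriers:
            cn[sample_ids.index(sid), w_lo:w_hi] = spec.copy_number

    values = cn / 2.0
    if config.coverage_sd > 0:
        values = values + rng.normal(0.0, config.coverage_sd, values.shape)
        values = np.clip(values, 0.0, None)
    profile = CoverageProfile(config.chrom, starts, config.coverage_window_bp,
                              values, sample_ids)
    if truth is None:
        truth = SyntheticTruth({}, [], [], carrier_lists, {})
    else:
        truth.cnv_carrier_samples = carrier_lists
    return profile, truth


def read_coverage(path: str | Path) -> CoverageProfile:
    """Read a coverage TSV written by :meth:`CoverageProfile.write`."""
    df = pd.read_csv(path, sep="\t")
    samples = df["sample"].drop_duplicates().tolist()
    chrom = df["chrom"].iloc[0]
    starts = np.sort(df["window_start"].unique())
    pivot = df.pivot_table(index="sample", columns="window_start",
                           values="value").loc[samples, starts]
    window_bp = int(starts[1] - starts[0]) if len(starts) > 1 else 300
    return CoverageProfile(chrom, starts, window_bp, pivot.to_numpy(),
                           samples)
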