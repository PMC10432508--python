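"""Core containers and I/O for cohort manifests, genotypes and site filters.

The pipeline operates on three kinds of input: a sample manifest (one row
per sequenced mosquito, carrying location, species, insecticide, bioassay
phenotype and plate position), a diploid genotype matrix read from VCF
(optionally phased, in which case a haplotype matrix is also carried), and
a genome accessibility mask in BED format marking regions where variant
calls are reliable.

Conventions
-----------
* Genotypes are coded as the number of non-reference alleles: 0, 1, 2,
  with ``-1`` as the missing sentinel.  Missing is never conflated with
  homozygous reference.
* Variant positions are stored 1-based (VCF convention); all interval
  arithmetic (BED mask, window tiling) converts to 0-based half-open at
  the boundary.
* A *sample set* is the unit of analysis: mosquitoes of one species from
  one location phenotyped against one insecticide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

PHENOTYPE_LABELS = {"alive": "alive", "resistant": "alive",
                    "dead": "dead", "susceptible": "dead"}
SPECIES_LABELS = {"gambiae", "coluzzii"}
INSECTICIDE_LABELS = {"deltamethrin", "PM"}

MANIFEST_REQUIRED = ["sample_id", "location", "species", "insecticide",
                     "phenotype"]
MANIFEST_OPTIONAL = {"country": "", "plate_id": "", "well_row": 0,
                     "well_col": 0, "sex": "unknown", "qc_pass": True}


class ManifestError(ValueError):
    """Raised when a sample manifest fails validation."""


@dataclass
class SampleManifest:
    """Per-sample metadata table.

    ``table`` has one row per sample with a derived ``sample_set`` column
    (location × species × insecticide).  Phenotype is normalized to
    alive (resistant) / dead (susceptible).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(),
                                  "sample_id"].tolist()
            raise ManifestError(f"duplicate sample ids: {dups}")
        if "sample_set" not in self.table.columns:
            self.table = self.table.assign(
                sample_set=(self.table["location"] + "_"
                            + self.table["species"] + "_"
                            + self.table["insecticide"]))

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def sample_sets(self) -> list[str]:
        return sorted(self.table["sample_set"].unique())

    def phenotypes(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """Binary phenotype vector: 1 = alive/resistant, 0 = dead/susceptible."""
        tab = self.table.set_index("sample_id")
        ids = list(samples) if samples is not None else self.sample_ids
        return (tab.loc[ids, "phenotype"] == "alive").to_numpy(int)

    def subset(self, sample_ids: Sequence[str]) -> "SampleManifest":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleManifest(keep.reset_index(drop=True))

    def counts_by_sample_set(self) -> pd.DataFrame:
        """Dead/alive sample counts per sample set."""
        g = self.table.groupby("sample_set")["phenotype"]
        out = pd.DataFrame({
            "n_dead": g.apply(lambda s: int((s == "dead").sum())),
            "n_alive": g.apply(lambda s: int((s == "alive").sum())),
        })
        out["n_total"] = out["n_dead"] + out["n_alive"]
        return out

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SiteFilterSpec:
    """Site-level filtering rules shared by all pipeline stages.

    ``min_mac`` is inclusive ("at least"); a singleton is a site whose
    minor allele is observed exactly once across the supplied samples.
    """

    require_accessible: bool = True
    max_missing: float = 0.0
    min_mac: int = 0
    drop_singletons: bool = False
    require_segregating: bool = False
    require_biallelic: bool = True

    def __post_init__(self) -> None:
        if self.min_mac < 0:
            raise ValueError("min_mac must be >= 0")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")


@dataclass
class GenotypeData:
    """Variant table plus genotype (and optional haplotype) matrices.

    ``genotypes`` is samples × variants with entries in {0, 1, 2, -1};
    ``haplotypes`` when present is (2·samples) × variants in {0, 1}, with
    haplotypes 2i and 2i+1 belonging to sample i.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    sample_ids: list[str]
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("genotype matrix shape does not match "
                             "samples × variants")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            self.check_consistency()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def check_consistency(self) -> None:
        """Assert genotypes equal column-paired haplotype sums."""
        if self.haplotypes is None:
            return
        if self.haplotypes.shape != (2 * self.n_samples, self.n_variants):
            raise ValueError("haplotype matrix shape mismatch")
        if (self.haplotypes == MISSING).any():
            raise ValueError("missing calls are not allowed in haplotypes")
        sums = self.haplotypes[0::2] + self.haplotypes[1::2]
        called = self.genotypes != MISSING
        if not np.array_equal(self.genotypes[called],
                              sums.astype(np.int8)[called]):
            raise ValueError("genotypes inconsistent with haplotype sums")

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeData":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([index[s] for s in sample_ids], dtype=int)
        hap = None
        if self.haplotypes is not None:
            hap_idx = np.ravel(np.column_stack([2 * idx, 2 * idx + 1]))
            hap = self.haplotypes[hap_idx]
        return GenotypeData(self.variants, self.genotypes[idx],
                            list(sample_ids), hap)

    def take_variants(self, mask: np.ndarray) -> "GenotypeData":
        mask = np.asarray(mask)
        hap = self.haplotypes[:, mask] if self.haplotypes is not None else None
        return GenotypeData(self.variants.loc[mask].reset_index(drop=True),
                            self.genotypes[:, mask], list(self.sample_ids),
                            hap)


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a CSV/TSV sample manifest and validate it.

    Unknown phenotype, species or insecticide labels raise
    :class:`ManifestError` naming the offending row.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else None
    df = pd.read_csv(path, sep=sep, engine="python", dtype={"sample_id": str})
    missing_cols = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing_cols:
        raise ManifestError(f"manifest missing required columns: {missing_cols}")
    for col, default in MANIFEST_OPTIONAL.items():
        if col not in df.columns:
            df[col] = default
        else:
            df[col] = df[col].fillna(default)
    for i, row in df.iterrows():
        ph = str(row["phenotype"]).strip().lower()
        if ph not in PHENOTYPE_LABELS:
            raise ManifestError(
                f"row {i} (sample {row['sample_id']}): unknown phenotype "
                f"label {row['phenotype']!r}")
        df.at[i, "phenotype"] = PHENOTYPE_LABELS[ph]
        if str(row["species"]) not in SPECIES_LABELS:
            raise ManifestError(
                f"row {i} (sample {row['sample_id']}): unknown species "
                f"{row['species']!r}")
        if str(row["insecticide"]) not in INSECTICIDE_LABELS:
            raise ManifestError(
                f"row {i} (sample {row['sample_id']}): unknown insecticide "
                f"{row['insecticide']!r}")
    return SampleManifest(df)


# ---------------------------------------------------------------------------
# VCF I/O

def read_genotypes(path: str | Path, samples: Sequence[str] | None = None
                   ) -> GenotypeData:
    """Read a VCF into a :class:`GenotypeData`.

    Genotypes are decoded to alt-allele dose; fully phased records
    ("|" separator for every sample at every site) populate the haplotype
    matrix, otherwise haplotypes are left absent.  Multiallelic records
    are retained but flagged non-biallelic.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    if samples is not None:
        absent = [s for s in samples if s not in vcf_samples]
        if absent:
            raise ValueError(f"samples not present in VCF: {absent}")
        order = [vcf_samples.index(s) for s in samples]
        sample_ids = list(samples)
    else:
        order = list(range(len(vcf_samples)))
        sample_ids = vcf_samples

    rows, geno_cols, hap_cols = [], [], []
    all_phased = True
    for var in vcf:
        alts = var.ALT if var.ALT else ["."]
        rows.append({
            "chrom": var.CHROM, "pos": var.POS, "ref": var.REF,
            "alt": ",".join(alts), "accessible": True,
            "annotation": var.INFO.get("ANN", None),
            "biallelic": len(alts) == 1,
        })
        # gt_types with gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt = var.gt_types[order].astype(np.int8)
        gt[gt == 3] = MISSING
        geno_cols.append(gt)
        phases = var.gt_phases[order]
        if all_phased and phases.all() and (gt != MISSING).all():
            g = var.genotypes
            hap = np.empty(2 * len(order), dtype=np.int8)
            for k, j in enumerate(order):
                hap[2 * k] = 1 if g[j][0] else 0
                hap[2 * k + 1] = 1 if g[j][1] else 0
            hap_cols.append(hap)
        else:
            all_phased = False

    variants = pd.DataFrame(rows)
    genotypes = (np.column_stack(geno_cols) if geno_cols
                 else np.empty((len(sample_ids), 0), dtype=np.int8))
    haplotypes = np.column_stack(hap_cols) if all_phased and hap_cols else None
    return GenotypeData(variants, genotypes, sample_ids, haplotypes)


def write_vcf(g: GenotypeData, path: str | Path) -> None:
    """Write genotypes back to a minimal VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in g.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        phased = g.haplotypes is not None
        for j in range(g.n_variants):
            v = g.variants.iloc[j]
            fields = [str(v["chrom"]), str(int(v["pos"])), ".", str(v["ref"]),
                      str(v["alt"]), ".", "PASS", ".", "GT"]
            for i in range(g.n_samples):
                dose = g.genotypes[i, j]
                if phased:
                    a, b = g.haplotypes[2 * i, j], g.haplotypes[2 * i + 1, j]
                    fields.append(f"{a}|{b}")
                elif dose == MISSING:
                    fields.append("./.")
                else:
                    fields.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(dose)])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Accessibility mask and site filtering

def read_bed_mask(path: str | Path) -> pd.DataFrame:
    """Read a BED accessibility mask (0-based half-open intervals)."""
    mask = pd.read_csv(path, sep="\t", header=None, comment="#",
                       usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return mask.sort_values(["chrom", "start"]).reset_index(drop=True)


def positions_accessible(chroms: np.ndarray, pos_1based: np.ndarray,
                         mask: pd.DataFrame) -> np.ndarray:
    """Flag 1-based positions covered by mask intervals."""
    acc = np.zeros(len(pos_1based), dtype=bool)
    pos0 = np.asarray(pos_1based) - 1  # to 0-based
    for chrom, sub in mask.groupby("chrom"):
        sel = np.asarray(chroms) == chrom
        if not sel.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # interval index whose start is <= pos; position is inside iff pos < end
        idx = np.searchsorted(starts, pos0[sel], side="right") - 1
        inside = (idx >= 0) & (pos0[sel] < ends[np.clip(idx, 0, None)])
        acc[sel] = inside
    return acc


def apply_mask(g: GenotypeData, mask: pd.DataFrame) -> GenotypeData:
    """Annotate the accessible flag from a BED mask."""
    acc = positions_accessible(g.variants["chrom"].to_numpy(),
                               g.variants["pos"].to_numpy(), mask)
    variants = g.variants.assign(accessible=acc)
    return GenotypeData(variants, g.genotypes, g.sample_ids, g.haplotypes)


def site_filter_mask(g: GenotypeData, spec: SiteFilterSpec) -> np.ndarray:
    """Boolean keep-mask over variants for the given filter spec."""
    geno = g.genotypes
    n_samples = geno.shape[0]
    keep = np.ones(g.n_variants, dtype=bool)

    if spec.require_accessible and "accessible" in g.variants:
        keep &= g.variants["accessible"].to_numpy(bool)
    if spec.require_biallelic and "biallelic" in g.variants:
        keep &= g.variants["biallelic"].to_numpy(bool)

    missing = (geno == MISSING).sum(axis=0)
    keep &= missing <= spec.max_missing * n_samples

    called = geno != MISSING
    alt = np.where(called, geno, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    mac = np.minimum(alt, total - alt)
    if spec.min_mac > 0:
        keep &= mac >= spec.min_mac
    if spec.drop_singletons:
        keep &= mac != 1
    if spec.require_segregating:
        keep &= (mac > 0) & (total > 0)
    return keep


def filter_sites(g: GenotypeData, spec: SiteFilterSpec,
                 mask: pd.DataFrame | None = None) -> GenotypeData:
    """Drop variants violating any enabled rule; idempotent.

    An empty result is permitted (with a warning) — downstream windowing
    simply produces no windows.
    """
    if mask is not None:
        g = apply_mask(g, mask)
    keep = site_filter_mask(g, spec)
    if not keep.any():
        warnings.warn("site filtering removed every variant", stacklevel=2)
    out = g.take_variants(keep)
    out.check_consistency()
    return out
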