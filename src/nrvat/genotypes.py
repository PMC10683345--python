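"""Linked-SNP genotype simulation in pedigrees and genotype file I/O.

Founder haplotypes are drawn from a latent first-order autoregressive
Gaussian process thresholded at Phi^{-1}(MAF_l) per locus, with the latent
correlation of each adjacent pair calibrated numerically (via bivariate
normal orthant probabilities) so that the squared Pearson correlation of
the binary allele indicators hits the target d^2 exactly in expectation.
Genotypes then descend through the pedigree by gene dropping: each
nonfounder inherits one whole haplotype from each parent, chosen uniformly
(no recombination within a region of tightly linked SNPs; an optional
per-interval recombination fraction is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri

from ._bivnorm import bvn_cdf
from .pedigree import Pedigree

__all__ = [
    "RegionSpec",
    "GenotypeSet",
    "calibrate_latent_corr",
    "simulate_founder_haplotypes",
    "gene_drop",
    "simulate_genotypes",
    "founder_maf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "read_vcf_dosages",
    "read_setid",
]


@dataclass(frozen=True)
class RegionSpec:
    """A region of r linked biallelic SNPs.

    maf: per-SNP minor allele frequencies, each in (0, 0.5].
    d2:  target squared correlation between adjacent SNP allele indicators.
    """

    maf: np.ndarray
    d2: float = 0.16

    def __post_init__(self):
        maf = np.atleast_1d(np.asarray(self.maf, dtype=float))
        object.__setattr__(self, "maf", maf)
        if maf.size < 1 or np.any(maf <= 0) or np.any(maf > 0.5):
            raise ValueError("MAFs must lie in (0, 0.5]")
        if not 0.0 <= self.d2 < 1.0:
            raise ValueError(f"d2 must lie in [0, 1); got {self.d2}")

    @property
    def r(self) -> int:
        return self.maf.size

    @classmethod
    def uniform_rare(cls, r: int = 20, low: float = 0.003, high: float = 0.01,
                     d2: float = 0.16, rng=None) -> "RegionSpec":
        """Default study region: r SNPs with MAF ~ Uniform(low, high)."""
        rng = np.random.default_rng(rng)
        return cls(maf=rng.uniform(low, high, size=r), d2=d2)


@dataclass
class GenotypeSet:
    """Minor-allele dosage matrix aligned to pedigree row order."""

    dosages: np.ndarray                  # N x r, entries in {0,1,2}
    variant_ids: list[str]
    individual_keys: list[tuple[str, str]]
    haplotypes: np.ndarray | None = field(default=None, repr=False)  # N x 2 x r

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if not np.isin(self.dosages, [0, 1, 2]).all():
            raise ValueError("dosages must be coded 0/1/2")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def r(self) -> int:
        return self.dosages.shape[1]


def calibrate_latent_corr(maf_a: float, maf_b: float, target_r: float) -> float:
    """Latent Gaussian correlation giving binary-indicator correlation target_r.

    The indicator pair (1{Z_a <= z_a}, 1{Z_b <= z_b}) with latent correlation
    rho has correlation [Phi2(z_a, z_b; rho) - p_a p_b] / sqrt(p_a q_a p_b q_b);
    this is solved for rho by bracketing.  Raises if target_r exceeds the
    Frechet upper bound for the MAF pair.
    """
    if target_r == 0.0:
        return 0.0
    if not 0.0 < target_r < 1.0:
        raise ValueError("target correlation must lie in [0, 1)")
    za, zb = ndtri(maf_a), ndtri(maf_b)
    denom = np.sqrt(maf_a * (1 - maf_a) * maf_b * (1 - maf_b))

    def binary_corr(rho: float) -> float:
        return (float(bvn_cdf(za, zb, rho)) - maf_a * maf_b) / denom

    r_max = (min(maf_a, maf_b) - maf_a * maf_b) / denom
    if target_r >= r_max - 1e-9:
        raise ValueError(
            f"adjacent-SNP correlation {target_r:.4g} infeasible for MAF pair "
            f"({maf_a:.4g}, {maf_b:.4g}); upper bound {r_max:.4g}"
        )
    return brentq(lambda rho: binary_corr(rho) - target_r, 0.0, 1.0 - 1e-9,
                  xtol=1e-10)


def simulate_founder_haplotypes(spec: RegionSpec, n_haplotypes: int, rng) -> np.ndarray:
    """n_haplotypes x r binary haplotypes with target MAFs and adjacent-pair d2."""
    rng = np.random.default_rng(rng)
    r = spec.r
    target_r = float(np.sqrt(spec.d2))
    rho = np.array([
        calibrate_latent_corr(spec.maf[l], spec.maf[l + 1], target_r)
        for l in range(r - 1)
    ])
    z = np.empty((n_haplotypes, r))
    z[:, 0] = rng.standard_normal(n_haplotypes)
    eps = rng.standard_normal((n_haplotypes, max(r - 1, 1)))
    for l in range(r - 1):
        z[:, l + 1] = rho[l] * z[:, l] + np.sqrt(1.0 - rho[l] ** 2) * eps[:, l]
    return (z < ndtri(spec.maf)).astype(np.uint8)


def gene_drop(ped: Pedigree, founder_haplotypes: np.ndarray, rng,
              recomb_fraction: float = 0.0) -> GenotypeSet:
    """Drop founder haplotypes through the pedigree; dosage = sum of alleles.

    founder_haplotypes must have 2 rows per founder, consumed in pedigree
    order.  Each nonfounder receives one gamete from each parent; with the
    default recomb_fraction = 0 a gamete is one of the parent's two whole
    haplotypes chosen uniformly, otherwise a crossover may occur between
    adjacent SNPs with the given probability.
    """
    rng = np.random.default_rng(rng)
    H = np.asarray(founder_haplotypes)
    n_founders = ped.n_founders
    if H.shape[0] != 2 * n_founders:
        raise ValueError(
            f"need {2 * n_founders} founder haplotypes, got {H.shape[0]}"
        )
    r = H.shape[1]
    N = ped.n_individuals
    haps = np.zeros((N, 2, r), dtype=np.uint8)
    next_founder = 0
    ofs = 0
    for fam in ped.families:
        idx = fam.index_of()
        for j in fam._topological_order():
            m = fam.members[j]
            if m.is_founder:
                haps[ofs + j, 0] = H[2 * next_founder]
                haps[ofs + j, 1] = H[2 * next_founder + 1]
                next_founder += 1
            else:
                fa, mo = idx[m.father_id], idx[m.mother_id]
                haps[ofs + j, 0] = _gamete(haps[ofs + fa], rng, recomb_fraction, r)
                haps[ofs + j, 1] = _gamete(haps[ofs + mo], rng, recomb_fraction, r)
        ofs += fam.size
    return GenotypeSet(
        dosages=haps.sum(axis=1).astype(np.int8),
        variant_ids=[f"snp{l + 1}" for l in range(r)],
        individual_keys=ped.individual_keys(),
        haplotypes=haps,
    )


def _gamete(parent_haps: np.ndarray, rng, recomb_fraction: float, r: int) -> np.ndarray:
    which = rng.integers(2)
    if recomb_fraction == 0.0:
        return parent_haps[which]
    switch = rng.random(r - 1) < recomb_fraction
    sel = np.empty(r, dtype=np.intp)
    sel[0] = which
    for l in range(1, r):
        sel[l] = sel[l - 1] ^ switch[l - 1]
    return parent_haps[sel, np.arange(r)]


def simulate_genotypes(ped: Pedigree, spec: RegionSpec, rng,
                       recomb_fraction: float = 0.0) -> GenotypeSet:
    """Founder-haplotype simulation followed by gene dropping, one call."""
    rng = np.random.default_rng(rng)
    H = simulate_founder_haplotypes(spec, 2 * ped.n_founders, rng)
    return gene_drop(ped, H, rng, recomb_fraction=recomb_fraction)


def founder_maf(geno: GenotypeSet, ped: Pedigree) -> np.ndarray:
    """Allele frequency of the counted allele among founders (unbiased in pedigrees)."""
    mask = np.array(
        [m.is_founder for fam in ped.families for m in fam.members], dtype=bool
    )
    return geno.dosages[mask].mean(axis=0) / 2.0


# ---------------------------------------------------------------------------
# file formats


def write_dosage_tsv(geno: GenotypeSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("FID\tIID\t" + "\t".join(geno.variant_ids) + "\n")
        for (fid, iid), row in zip(geno.individual_keys, geno.dosages):
            fh.write(f"{fid}\t{iid}\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_dosage_tsv(path) -> GenotypeSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    variant_ids = [c for c in df.columns if c not in ("FID", "IID")]
    return GenotypeSet(
        dosages=df[variant_ids].to_numpy(dtype=np.int8),
        variant_ids=variant_ids,
        individual_keys=list(zip(df["FID"], df["IID"])),
    )


def write_vcf(geno: GenotypeSet, path, chrom: str = "1", start_pos: int = 1000,
              spacing: int = 100, phased: bool = False) -> None:
    """Minimal biallelic VCF (GT only); REF=A, ALT=C, ALT is the counted allele."""
    samples = [f"{fid}_{iid}" for fid, iid in geno.individual_keys]
    sep = "|" if phased else "/"
    use_haps = phased and geno.haplotypes is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for l, vid in enumerate(geno.variant_ids):
            if use_haps:
                gts = [f"{int(h[0, l])}{sep}{int(h[1, l])}" for h in geno.haplotypes]
            else:
                gts = [("0" + sep + "0", "0" + sep + "1", "1" + sep + "1")[int(d)]
                       for d in geno.dosages[:, l]]
            fh.write(f"{chrom}\t{start_pos + l * spacing}\t{vid}\tA\tC\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_vcf_dosages(path, ped: Pedigree | None = None) -> GenotypeSet:
    """Read biallelic GT dosages from a VCF with cyvcf2; ALT allele is counted.

    Sample names are expected as FID_IID; if a pedigree is given, samples
    are reordered to its row order and completeness is enforced.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    rows, ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"variant {var.ID} is not biallelic")
        gt = np.asarray(var.genotype.array())[:, :2]
        if (gt < 0).any():
            raise ValueError(f"variant {var.ID} has missing genotypes")
        rows.append(gt.sum(axis=1))
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    dos = np.array(rows, dtype=np.int8).T
    keys = [tuple(s.split("_", 1)) if "_" in s else ("0", s) for s in samples]
    geno = GenotypeSet(dosages=dos, variant_ids=ids, individual_keys=keys)
    if ped is not None:
        want = ped.individual_keys()
        pos = {k: i for i, k in enumerate(keys)}
        missing = [k for k in want if k not in pos]
        if missing:
            raise ValueError(f"VCF lacks samples: {missing[:5]}...")
        order = [pos[k] for k in want]
        geno = GenotypeSet(dosages=dos[order], variant_ids=ids,
                           individual_keys=want)
    return geno


def read_setid(path) -> dict[str, list[str]]:
    """SetID file: whitespace-delimited 'set_name variant_id' lines."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            if len(tok) != 2:
                raise ValueError(f"SetID lines need 2 columns, got: {line!r}")
            sets.setdefault(tok[0], []).append(tok[1])
    return sets
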