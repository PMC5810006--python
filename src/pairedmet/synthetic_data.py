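"""Seeded generator of paired germline/primary/metastasis exome datasets.

The generated data carries the statistical structure every downstream stage
assumes: heterozygous germline SNPs with binomial allele counts, tumor
purity diluting copy-neutral LOH blocks, per-SNP amplification dropout
biasing one allele, CNV segments scaling Poisson coverage, and
compartment-specific somatic mutation rates with optional gene-family
enrichment in the metastasis. Identical seeds give identical cases.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .types import RegionSet, SnpObservation, VariantRecord

#: AKAP family symbols used as the default enriched family.
AKAP_GENES = tuple(f"AKAP{i}" for i in range(1, 15))

#: Packaged stand-in for a recurrently-mutated-gene panel (~500 symbols).
GENE_UNIVERSE = AKAP_GENES + tuple(f"GENE{i:03d}" for i in range(1, 492))

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimulationParams:
    n_snps: int = 5000
    mean_depth: int = 60
    purity: float = 0.9
    loh_regions: Optional[RegionSet] = None
    dropout_rate: float = 0.0
    dropout_bias: float = 0.4
    cnv_segments: Tuple[Tuple[Tuple[str, int, int], float], ...] = ()
    somatic_rate_primary: float = 10.0
    somatic_rate_metastasis: float = 40.0
    family_genes: Tuple[str, ...] = AKAP_GENES
    family_enrichment_multiplier: float = 1.0
    shared_fraction: float = 0.1
    seed: int = 0
    chrom: str = "chr1"
    snp_spacing: int = 1000

    def __post_init__(self) -> None:
        for name in ("purity", "dropout_rate", "shared_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.purity == 0.0:
            raise ValueError("purity must be in (0, 1]")
        if self.mean_depth <= 0 or self.n_snps <= 0:
            raise ValueError("mean_depth and n_snps must be positive")
        if not 0.0 <= self.dropout_bias <= 0.5:
            raise ValueError("dropout_bias must be in [0, 0.5]")
        if self.family_enrichment_multiplier < 1.0:
            raise ValueError("family_enrichment_multiplier must be >= 1")
        for (_, _, _), cn in self.cnv_segments:
            if cn < 0:
                raise ValueError("copy_number must be >= 0")
        if self.loh_regions is not None and self.loh_regions.has_self_overlap():
            raise ValueError("loh_regions must not overlap")


@dataclass(frozen=True)
class SomaticTruth:
    gene: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    vaf_primary: float  # 0 when absent
    vaf_metastasis: float
    shared: bool


@dataclass
class SimulationTruth:
    params: SimulationParams
    positions: np.ndarray
    loh_indicator: np.ndarray  # bool per SNP
    retained_allele: np.ndarray  # "ref"/"alt"/"" per SNP
    copy_number: np.ndarray
    dropout_primary: np.ndarray  # bool per SNP
    dropout_metastasis: np.ndarray
    somatic: List[SomaticTruth] = field(default_factory=list)


@dataclass
class SimulatedCase:
    germline: List[SnpObservation]
    primary: List[SnpObservation]
    metastasis: List[SnpObservation]
    variants_primary: List[VariantRecord]
    variants_metastasis: List[VariantRecord]
    truth: SimulationTruth

    def digest(self) -> str:
        """SHA-256 of a canonical serialization; equal for equal cases."""
        h = hashlib.sha256()
        for table in (self.germline, self.primary, self.metastasis):
            for o in table:
                h.update(f"{o.chrom}\t{o.pos}\t{o.ref_count}\t{o.alt_count}\t{o.sample_id}\n".encode())
        for table in (self.variants_primary, self.variants_metastasis):
            for r in table:
                h.update(
                    f"{r.chrom}\t{r.pos}\t{r.ref_base}\t{r.alt_base}\t{r.germline_ref}\t"
                    f"{r.germline_alt}\t{r.tumor_ref}\t{r.tumor_alt}\t{r.tumor_alt_fwd}\t"
                    f"{r.tumor_alt_rev}\t{r.gene}\t{r.compartment}\n".encode()
                )
        return h.hexdigest()


def _tumor_alt_probability(
    i: int, truth: SimulationTruth, dropout: np.ndarray,
    dropout_dir: np.ndarray, purity: float, bias: float,
) -> float:
    if dropout[i]:
        return 0.5 + bias if dropout_dir[i] else 0.5 - bias
    if truth.loh_indicator[i]:
        # copy-neutral LOH diluted by non-tumor cells at purity rho
        if truth.retained_allele[i] == "alt":
            return (1.0 + purity) / 2.0
        return (1.0 - purity) / 2.0
    return 0.5


def _sample_tumor_table(
    rng: np.random.Generator, truth: SimulationTruth, sample_id: str,
    dropout: np.ndarray, dropout_dir: np.ndarray,
) -> List[SnpObservation]:
    p = truth.params
    out = []
    for i, pos in enumerate(truth.positions):
        depth = rng.poisson(p.mean_depth * truth.copy_number[i] / 2.0)
        prob = _tumor_alt_probability(i, truth, dropout, dropout_dir, p.purity, p.dropout_bias)
        alt = rng.binomial(depth, prob) if depth > 0 else 0
        out.append(SnpObservation(chrom=p.chrom, pos=int(pos),
                                  ref_count=int(depth - alt), alt_count=int(alt),
                                  sample_id=sample_id))
    return out


def _draw_somatic_genes(rng: np.random.Generator, n: int, params: SimulationParams,
                        enriched: bool) -> List[str]:
    weights = np.ones(len(GENE_UNIVERSE))
    if enriched:
        family = set(params.family_genes)
        for gi, gene in enumerate(GENE_UNIVERSE):
            if gene in family:
                weights[gi] = params.family_enrichment_multiplier
    weights /= weights.sum()
    idx = rng.choice(len(GENE_UNIVERSE), size=n, replace=True, p=weights)
    return [GENE_UNIVERSE[int(i)] for i in idx]


def _somatic_record(rng: np.random.Generator, gene: str, chrom: str, pos: int,
                    ref: str, alt: str, vaf: float, depth_mean: int,
                    sample_id: str, compartment: str) -> VariantRecord:
    depth = max(int(rng.poisson(depth_mean)), 1)
    alt_n = int(rng.binomial(depth, vaf))
    fwd = int(rng.binomial(alt_n, 0.5)) if alt_n > 0 else 0
    g_depth = max(int(rng.poisson(depth_mean)), 1)
    return VariantRecord(
        chrom=chrom, pos=pos, ref_base=ref, alt_base=alt,
        germline_ref=g_depth, germline_alt=0,
        tumor_ref=depth - alt_n, tumor_alt=alt_n,
        tumor_alt_fwd=fwd, tumor_alt_rev=alt_n - fwd,
        gene=gene, consequence="nonsynonymous",
        sample_id=sample_id, compartment=compartment,
    )


def simulate_case(params: SimulationParams) -> SimulatedCase:
    """Generate one paired case; fully determined by ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    positions = np.arange(1, params.n_snps + 1) * params.snp_spacing

    loh = np.zeros(params.n_snps, dtype=bool)
    if params.loh_regions is not None:
        for i, pos in enumerate(positions):
            loh[i] = params.loh_regions.contains(params.chrom, int(pos))
    cn = np.full(params.n_snps, 2.0)
    for (chrom, start, end), copy_number in params.cnv_segments:
        if chrom != params.chrom:
            continue
        inside = (positions - 1 >= start) & (positions - 1 < end)
        cn[inside] = copy_number

    # per-SNP retained allele inside LOH, shared between the two lesions
    retained = np.where(rng.random(params.n_snps) < 0.5, "ref", "alt")
    retained = np.where(loh, retained, "")

    truth = SimulationTruth(
        params=params, positions=positions, loh_indicator=loh,
        retained_allele=retained, copy_number=cn,
        dropout_primary=rng.random(params.n_snps) < params.dropout_rate,
        dropout_metastasis=rng.random(params.n_snps) < params.dropout_rate,
    )
    dir_primary = rng.random(params.n_snps) < 0.5
    dir_metastasis = rng.random(params.n_snps) < 0.5

    germline = []
    for pos in positions:
        depth = rng.poisson(params.mean_depth)
        alt = rng.binomial(depth, 0.5) if depth > 0 else 0
        germline.append(SnpObservation(chrom=params.chrom, pos=int(pos),
                                       ref_count=int(depth - alt), alt_count=int(alt),
                                       sample_id="germline"))
    primary = _sample_tumor_table(rng, truth, "primary", truth.dropout_primary, dir_primary)
    metastasis = _sample_tumor_table(rng, truth, "metastasis",
                                     truth.dropout_metastasis, dir_metastasis)

    # somatic mutations live beyond the SNP grid so tables never collide
    base_pos = int(positions[-1]) + params.snp_spacing
    n_primary = rng.poisson(params.somatic_rate_primary)
    n_met = rng.poisson(params.somatic_rate_metastasis)
    n_shared = min(int(round(params.shared_fraction * n_met)), n_primary)

    genes_p = _draw_somatic_genes(rng, n_primary, params, enriched=False)
    genes_m_new = _draw_somatic_genes(rng, n_met - n_shared, params, enriched=True)

    variants_primary: List[VariantRecord] = []
    variants_metastasis: List[VariantRecord] = []
    next_pos = base_pos
    for j, gene in enumerate(genes_p):
        ref, alt = [str(b) for b in rng.choice(_BASES, size=2, replace=False)]
        vaf_p = float(rng.uniform(0.1, 0.4) * params.purity)
        shared = j < n_shared
        vaf_m = float(rng.uniform(0.1, 0.4) * params.purity) if shared else 0.0
        variants_primary.append(_somatic_record(
            rng, gene, params.chrom, next_pos, ref, alt, vaf_p,
            params.mean_depth, "primary", "primary"))
        if shared:
            variants_metastasis.append(_somatic_record(
                rng, gene, params.chrom, next_pos, ref, alt, vaf_m,
                params.mean_depth, "metastasis", "metastasis"))
        truth.somatic.append(SomaticTruth(
            gene=gene, chrom=params.chrom, pos=next_pos, ref_base=ref, alt_base=alt,
            vaf_primary=vaf_p, vaf_metastasis=vaf_m, shared=shared))
        next_pos += params.snp_spacing
    for gene in genes_m_new:
        ref, alt = [str(b) for b in rng.choice(_BASES, size=2, replace=False)]
        vaf_m = float(rng.uniform(0.1, 0.4) * params.purity)
        variants_metastasis.append(_somatic_record(
            rng, gene, params.chrom, next_pos, ref, alt, vaf_m,
            params.mean_depth, "metastasis", "metastasis"))
        truth.somatic.append(SomaticTruth(
            gene=gene, chrom=params.chrom, pos=next_pos, ref_base=ref, alt_base=alt,
            vaf_primary=0.0, vaf_metastasis=vaf_m, shared=False))
        next_pos += params.snp_spacing

    return SimulatedCase(
        germline=germline, primary=primary, metastasis=metastasis,
        variants_primary=variants_primary, variants_metastasis=variants_metastasis,
        truth=truth,
    )


def truth_report(case: SimulatedCase) -> dict:
    """Realized per-stage ground truths: the oracle for recovery tests."""
    truth = case.truth
    params = truth.params
    family = set(params.family_genes)
    outside = ~truth.loh_indicator
    n_outside = int(outside.sum())
    dropout_outside = {
        "primary": float(truth.dropout_primary[outside].mean()) if n_outside else float("nan"),
        "metastasis": float(truth.dropout_metastasis[outside].mean()) if n_outside else float("nan"),
    }
    somatic_counts = {
        "primary": sum(1 for s in truth.somatic if s.vaf_primary > 0),
        "metastasis": sum(1 for s in truth.somatic if s.vaf_metastasis > 0),
    }
    family_counts = {
        "primary": sum(1 for s in truth.somatic if s.vaf_primary > 0 and s.gene in family),
        "metastasis": sum(1 for s in truth.somatic if s.vaf_metastasis > 0 and s.gene in family),
    }
    return {
        "loh_fraction": float(truth.loh_indicator.mean()),
        "dropout_fraction_outside_loh": dropout_outside,
        "cnv_segments": [
            {"region": list(region), "copy_number": cn}
            for region, cn in params.cnv_segments
        ],
        "somatic_counts": somatic_counts,
        "family_somatic_counts": family_counts,
        "n_shared_somatic": sum(1 for s in truth.somatic if s.shared),
        "purity": params.purity,
        "seed": params.seed,
    }
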