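"""Somatic-call filtering, shared-position selection and spectrum summaries.

The exome-wide tier keeps a call when all of the following hold:
germline VAF below a cap (default < 1%), tumor alternate reads at or above a
floor (default >= 5), tumor coverage strictly above a floor (default > 30)
and tumor VAF strictly above a floor (default > 16%). Two programmatic QC
flags stand in for manual review: ``normal_support`` (alternate reads in the
germline beyond a tolerated stray read) and ``single_strand`` (alternate
reads on one strand only). Alignment-quality review is not emulated.

For a candidate-gene panel, positions present in either lesion of a pair are
retained even below the alternate-read floor, so true shared low-frequency
mutations are not lost.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .types import VariantRecord

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
#: pyrimidine-context substitution classes (purine substitutions are folded)
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

RULES = (
    "germline_vaf", "low_alt_reads", "low_coverage", "low_vaf",
    "normal_support", "single_strand", "not_evaluable",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the somatic filter.

    ``max_germline_vaf`` and the strand rule are caps/QC flags; the *_min
    fields are floors. ``min_coverage`` and ``min_exomewide_vaf`` are
    exclusive bounds (coverage > 30, VAF > 0.16). ``qc_normal_alt_reads``
    is the germline alternate-read count at which ``normal_support`` fires
    even when the germline VAF cap passes; set ``enable_qc_flags`` False to
    disable both QC proxies.
    """

    max_germline_vaf: float = 0.01
    min_tumor_alt_reads: int = 5
    min_coverage: int = 30
    min_exomewide_vaf: float = 0.16
    min_strand_reads: int = 1
    qc_normal_alt_reads: int = 2
    enable_qc_flags: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_germline_vaf <= 1.0:
            raise ValueError("max_germline_vaf must be in [0, 1]")
        if not 0.0 <= self.min_exomewide_vaf <= 1.0:
            raise ValueError("min_exomewide_vaf must be in [0, 1]")
        for name in ("min_tumor_alt_reads", "min_coverage", "min_strand_reads",
                     "qc_normal_alt_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FilterVerdict:
    kept: bool
    tier: str  # exome_wide | candidate_gene_shared | rejected
    reasons: Tuple[str, ...] = ()
    strand_evaluable: bool = True

    def __post_init__(self) -> None:
        if self.tier == "rejected" and (self.kept or not self.reasons):
            raise ValueError("rejected verdicts need reasons and kept=False")


def _failed_rules(record: VariantRecord, config: FilterConfig) -> List[str]:
    reasons: List[str] = []
    cov = record.tumor_coverage
    gvaf = record.germline_vaf
    # no germline coverage => no evidence of germline support
    if gvaf is not None and record.germline_alt > 0 and gvaf >= config.max_germline_vaf:
        reasons.append("germline_vaf")
    if record.tumor_alt < config.min_tumor_alt_reads:
        reasons.append("low_alt_reads")
    if not cov > config.min_coverage:
        reasons.append("low_coverage")
    if not record.tumor_alt / cov > config.min_exomewide_vaf:
        reasons.append("low_vaf")
    if config.enable_qc_flags:
        if record.germline_alt >= config.qc_normal_alt_reads:
            reasons.append("normal_support")
        if record.strand_evaluable and record.tumor_alt > 0:
            if (record.tumor_alt_fwd < config.min_strand_reads
                    or record.tumor_alt_rev < config.min_strand_reads):
                reasons.append("single_strand")
    return reasons


def filter_somatic(record: VariantRecord, config: FilterConfig = FilterConfig()) -> FilterVerdict:
    """Apply the exome-wide somatic filter to one candidate variant."""
    if record.tumor_coverage == 0:
        return FilterVerdict(kept=False, tier="rejected", reasons=("not_evaluable",),
                             strand_evaluable=record.strand_evaluable)
    reasons = _failed_rules(record, config)
    if reasons:
        return FilterVerdict(kept=False, tier="rejected", reasons=tuple(reasons),
                             strand_evaluable=record.strand_evaluable)
    return FilterVerdict(kept=True, tier="exome_wide",
                         strand_evaluable=record.strand_evaluable)


@dataclass(frozen=True)
class SharedPosition:
    """One retained position of a paired primary/metastasis report."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    gene: str
    label: str  # shared | primary_only | metastasis_only
    tier: str  # exome_wide | candidate_gene_shared
    primary: Optional[VariantRecord]
    metastasis: Optional[VariantRecord]


def _relaxed_ok(record: VariantRecord, config: FilterConfig) -> bool:
    """Germline and coverage rules only: the relaxed panel-gene criterion."""
    if record.tumor_coverage == 0:
        return False
    failed = _failed_rules(record, config)
    return not any(r in ("germline_vaf", "low_coverage", "normal_support") for r in failed)


def select_shared_positions(
    primary: Sequence[VariantRecord],
    metastasis: Sequence[VariantRecord],
    gene_panel: Set[str],
    config: FilterConfig = FilterConfig(),
) -> List[SharedPosition]:
    """Pair positions across lesions, relaxing read floors for panel genes."""
    if not gene_panel:
        warnings.warn("empty gene panel: reporting over all genes")
    by_key: Dict[tuple, Dict[str, VariantRecord]] = {}
    for rec in primary:
        by_key.setdefault(rec.key, {})["primary"] = rec
    for rec in metastasis:
        by_key.setdefault(rec.key, {})["metastasis"] = rec
    report: List[SharedPosition] = []
    for key in sorted(by_key, key=lambda k: (k[0], k[1], k[2], k[3])):
        recs = by_key[key]
        any_rec = next(iter(recs.values()))
        in_panel = (not gene_panel) or (any_rec.gene in gene_panel)
        p, m = recs.get("primary"), recs.get("metastasis")
        strict = [r for r in recs.values() if filter_somatic(r, config).kept]
        if in_panel:
            keep = any(_relaxed_ok(r, config) for r in recs.values())
            tier = "exome_wide" if strict else "candidate_gene_shared"
        else:
            keep = bool(strict)
            tier = "exome_wide"
        if not keep:
            continue
        p_present = p is not None and p.tumor_alt > 0
        m_present = m is not None and m.tumor_alt > 0
        if p_present and m_present:
            label = "shared"
        elif m_present:
            label = "metastasis_only"
        elif p_present:
            label = "primary_only"
        else:
            continue
        report.append(SharedPosition(
            chrom=key[0], pos=key[1], ref_base=key[2], alt_base=key[3],
            gene=any_rec.gene, label=label, tier=tier, primary=p, metastasis=m,
        ))
    return report


@dataclass(frozen=True)
class SpectrumSummary:
    transitions: int
    transversions: int
    titv_ratio: Optional[float]  # None when transversions == 0
    per_substitution_counts: Mapping[str, int]
    n_skipped: int = 0

    @property
    def total(self) -> int:
        return self.transitions + self.transversions


def fold_substitution(ref: str, alt: str) -> Optional[str]:
    """Fold a substitution to its pyrimidine-context class, or None."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        return None
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def substitution_spectrum(records: Sequence[VariantRecord]) -> SpectrumSummary:
    """Count transitions/transversions and the 6 folded substitution classes."""
    counts = {cls: 0 for cls in SPECTRUM_CLASSES}
    ti = tv = skipped = 0
    for rec in records:
        ref, alt = rec.ref_base.upper(), rec.alt_base.upper()
        folded = fold_substitution(ref, alt)
        if folded is None or len(ref) != 1 or len(alt) != 1:
            skipped += 1
            continue
        counts[folded] += 1
        if (ref, alt) in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    ratio = ti / tv if tv > 0 else None
    return SpectrumSummary(transitions=ti, transversions=tv, titv_ratio=ratio,
                           per_substitution_counts=counts, n_skipped=skipped)


@dataclass(frozen=True)
class PatientCase:
    """Filtered variants of one patient keyed by compartment."""

    patient_id: str
    variants: Mapping[str, Sequence[VariantRecord]]


@dataclass(frozen=True)
class MutationLoadSummary:
    per_patient: Mapping[str, Mapping[str, int]]  # compartment -> patient -> count
    means: Mapping[str, float]
    ranges: Mapping[str, Tuple[int, int]]
    t_statistic: Optional[float]
    p_value: Optional[float]
    compared: Tuple[str, str] = ("primary", "metastasis")


def pooled_t_test(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Classic two-sided pooled-variance two-sample t test.

    Degenerate zero-variance inputs yield t=0, p=1 when the group means are
    equal and |t|=inf, p=0 otherwise.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 observations")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), df=na + nb - 2)
    return float(t), float(p)


def mutation_load_summary(
    cases: Sequence[PatientCase],
    gene_restrict: Optional[Set[str]] = None,
    compartments: Tuple[str, str] = ("primary", "metastasis"),
) -> MutationLoadSummary:
    """Per-patient nonsynonymous mutation loads and a between-compartment t test."""
    per_patient: Dict[str, Dict[str, int]] = {c: {} for c in compartments}
    for case in cases:
        for comp in compartments:
            recs = case.variants.get(comp, [])
            n = sum(
                1 for r in recs
                if r.consequence in ("nonsynonymous", "nonsense")
                and (gene_restrict is None or r.gene in gene_restrict)
            )
            per_patient[comp][case.patient_id] = n
    means, ranges = {}, {}
    for comp in compartments:
        vals = list(per_patient[comp].values())
        if vals:
            means[comp] = float(np.mean(vals))
            ranges[comp] = (min(vals), max(vals))
    va = list(per_patient[compartments[0]].values())
    vb = list(per_patient[compartments[1]].values())
    if len(va) >= 2 and len(vb) >= 2:
        t, p = pooled_t_test(va, vb)
    else:
        t = p = None
    return MutationLoadSummary(per_patient=per_patient, means=means, ranges=ranges,
                               t_statistic=t, p_value=p, compared=compartments)
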