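"""Gene-family mutation summaries, Fisher enrichment and VAF trajectories.

The two-sided Fisher exact test is computed with exact integer arithmetic
under the probability-ordering convention: all tables with the observed
margins whose hypergeometric probability does not exceed the observed
table's contribute to the P value.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple

from .types import LESION_ORDER, MutationTableRow

METASTATIC_LESIONS = ("axillary", "metastasis_1", "metastasis_2")


@dataclass(frozen=True)
class MutationTableSummary:
    total_mutations: int
    metastasis_only: int
    primary_only: int
    shared: int
    genes_mutated: frozenset
    patients_mutated: frozenset
    per_patient: Mapping[str, Mapping[str, bool]]  # patient -> lesion-group presence

    def __post_init__(self) -> None:
        assert self.metastasis_only + self.primary_only + self.shared == self.total_mutations


def summarize_mutation_table(
    rows: Sequence[MutationTableRow],
    presence_threshold: float = 0.0,
) -> MutationTableSummary:
    """Classify each mutation as metastasis-only / primary-only / shared.

    A mutation is present in a lesion iff its (maximum multi-block) VAF
    exceeds ``presence_threshold``; missing VAFs count as absent. Axillary
    and distant metastases are pooled as metastatic lesions.
    """
    met_only = prim_only = shared = 0
    genes: Set[str] = set()
    patients: Set[str] = set()
    per_patient: Dict[str, Dict[str, bool]] = {}
    for row in rows:
        p_vaf = row.vaf("primary")
        in_primary = p_vaf is not None and p_vaf > presence_threshold
        in_met = any(
            (v := row.vaf(lesion)) is not None and v > presence_threshold
            for lesion in METASTATIC_LESIONS
        )
        if not in_primary and not in_met:
            continue
        if in_primary and in_met:
            shared += 1
        elif in_primary:
            prim_only += 1
        else:
            met_only += 1
        genes.add(row.gene)
        patients.add(row.patient_id)
        entry = per_patient.setdefault(row.patient_id, {"primary": False, "metastasis": False})
        entry["primary"] = entry["primary"] or in_primary
        entry["metastasis"] = entry["metastasis"] or in_met
    return MutationTableSummary(
        total_mutations=met_only + prim_only + shared,
        metastasis_only=met_only, primary_only=prim_only, shared=shared,
        genes_mutated=frozenset(genes), patients_mutated=frozenset(patients),
        per_patient=per_patient,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    p_two_sided: float
    odds_ratio: float  # sample OR; inf/0 with zero_cell flag
    zero_cell: bool
    zero_margin: bool = False


def fisher_family_enrichment(counts: Sequence[Sequence[int]]) -> EnrichmentResult:
    """Two-sided Fisher exact test on a 2x2 table, probability ordering.

    Implemented over exact integer hypergeometric weights, so ties are
    handled without floating-point tolerance. A zero margin yields p = 1
    with a flag.
    """
    (a, b), (c, d) = counts
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    zero_cell = 0 in (a, b, c, d)
    if b * c == 0:
        odds = math.inf if a * d > 0 else (0.0 if a * d == 0 and not (b == 0 and c == 0) else math.nan)
    else:
        odds = (a * d) / (b * c)
    if min(r1, r2, c1, n - c1) == 0:
        return EnrichmentResult(table=((a, b), (c, d)), p_two_sided=1.0,
                                odds_ratio=odds, zero_cell=zero_cell, zero_margin=True)
    # integer weight of table with top-left cell x: C(r1, x) * C(r2, c1 - x)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    observed = weights[a]
    numer = sum(w for w in weights.values() if w <= observed)
    denom = math.comb(n, c1)
    return EnrichmentResult(table=((a, b), (c, d)), p_two_sided=numer / denom,
                            odds_ratio=odds, zero_cell=zero_cell)


@dataclass(frozen=True)
class VafTrajectory:
    patient_id: str
    gene: str
    ordered_vafs: Tuple[Tuple[str, float], ...]  # (lesion, VAF) in temporal order
    monotone_increasing: bool


def vaf_trajectories(rows: Sequence[MutationTableRow]) -> List[VafTrajectory]:
    """Per-(patient, gene) VAF sequence over the fixed lesion order.

    Multi-block lesions contribute their maximum VAF. ``monotone_increasing``
    is the non-strict check over non-missing entries.
    """
    grouped: Dict[Tuple[str, str], List[MutationTableRow]] = {}
    for row in rows:
        grouped.setdefault((row.patient_id, row.gene), []).append(row)
    out: List[VafTrajectory] = []
    for (patient, gene), group in sorted(grouped.items()):
        series: List[Tuple[str, float]] = []
        for lesion in LESION_ORDER:
            vals = [row.vaf(lesion) for row in group if row.vaf(lesion) is not None]
            if vals:
                series.append((lesion, max(vals)))
        vafs = [v for _, v in series]
        monotone = all(y >= x for x, y in zip(vafs, vafs[1:]))
        out.append(VafTrajectory(patient_id=patient, gene=gene,
                                 ordered_vafs=tuple(series), monotone_increasing=monotone))
    return out


@dataclass(frozen=True)
class PrevalenceReport:
    n_patients: int
    primary_patients: frozenset
    metastasis_patients: frozenset

    @property
    def primary_prevalence(self) -> float:
        return len(self.primary_patients) / self.n_patients

    @property
    def metastasis_prevalence(self) -> float:
        return len(self.metastasis_patients) / self.n_patients


def family_prevalence(
    cohort_summaries: Sequence[MutationTableSummary],
    n_patients: int,
) -> PrevalenceReport:
    """Fraction of patients with >= 1 family mutation, per compartment."""
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    primary: Set[str] = set()
    metastasis: Set[str] = set()
    for summary in cohort_summaries:
        for patient, presence in summary.per_patient.items():
            if presence.get("primary"):
                primary.add(patient)
            if presence.get("metastasis"):
                metastasis.add(patient)
    return PrevalenceReport(n_patients=n_patients,
                            primary_patients=frozenset(primary),
                            metastasis_patients=frozenset(metastasis))
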