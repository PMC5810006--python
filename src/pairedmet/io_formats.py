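"""Readers/writers for the tabular formats the pipeline touches.

Dialects
--------
``snp`` tables: TSV with columns chrom, pos, ref_count, alt_count, sample_id.

``varscan_like`` variant tables: TSV with columns chrom, pos, ref, alt,
germline_ref, germline_alt, tumor_ref, tumor_alt, tumor_alt_fwd,
tumor_alt_rev, gene, consequence, sample_id, compartment. Strand columns may
be empty, in which case strand-based QC is reported as not evaluable.

``vcf``: VCF 4.x with per-sample AD allele depths; the first sample is taken
as germline and the second as tumor unless named explicitly.

Packaged fixtures transcribe the printed AKAP mutation/CNV tables; see
:func:`load_fixture`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from .types import (
    FormatError,
    MutationTableRow,
    RegionSet,
    SnpObservation,
    VariantRecord,
)

SNP_COLUMNS = ["chrom", "pos", "ref_count", "alt_count", "sample_id"]
VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "germline_ref", "germline_alt", "tumor_ref", "tumor_alt",
    "tumor_alt_fwd", "tumor_alt_rev",
    "gene", "consequence", "sample_id", "compartment",
]

FIXTURE_NAMES = ("cohort1_akap", "cohort2_akap", "akap_cnv")


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected a header line")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_snp_table(path) -> List[SnpObservation]:
    """Parse a SNP count TSV; malformed rows are reported with line numbers."""
    df = _read_tsv(path, SNP_COLUMNS)
    out: List[SnpObservation] = []
    errors: List[str] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        lineno = idx + 2  # header is line 1
        try:
            out.append(SnpObservation(
                chrom=row.chrom,
                pos=int(row.pos),
                ref_count=int(row.ref_count),
                alt_count=int(row.alt_count),
                sample_id=row.sample_id,
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise FormatError(f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors))
    return out


def write_snp_table(observations: Sequence[SnpObservation], path) -> None:
    df = pd.DataFrame(
        [(o.chrom, o.pos, o.ref_count, o.alt_count, o.sample_id) for o in observations],
        columns=SNP_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def _opt_int(value: str) -> Optional[int]:
    return None if value == "" else int(value)


def read_variant_table(path, dialect: str = "varscan_like") -> List[VariantRecord]:
    """Parse candidate somatic variants from a TSV or VCF file."""
    if dialect == "varscan_like":
        return _read_varscan_like(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected varscan_like or vcf")


def _read_varscan_like(path) -> List[VariantRecord]:
    df = _read_tsv(path, [c for c in VARIANT_COLUMNS if c not in ("tumor_alt_fwd", "tumor_alt_rev")])
    has_strand = "tumor_alt_fwd" in df.columns and "tumor_alt_rev" in df.columns
    out: List[VariantRecord] = []
    errors: List[str] = []
    for idx, row in df.iterrows():
        lineno = idx + 2
        try:
            fwd = _opt_int(row["tumor_alt_fwd"]) if has_strand else None
            rev = _opt_int(row["tumor_alt_rev"]) if has_strand else None
            out.append(VariantRecord(
                chrom=row["chrom"], pos=int(row["pos"]),
                ref_base=row["ref"], alt_base=row["alt"],
                germline_ref=int(row["germline_ref"]),
                germline_alt=int(row["germline_alt"]),
                tumor_ref=int(row["tumor_ref"]),
                tumor_alt=int(row["tumor_alt"]),
                tumor_alt_fwd=fwd, tumor_alt_rev=rev,
                gene=row["gene"], consequence=row["consequence"] or "other",
                sample_id=row["sample_id"], compartment=row["compartment"],
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise FormatError(f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors))
    return out


def _read_vcf(path, germline_sample: Optional[str] = None,
              tumor_sample: Optional[str] = None) -> List[VariantRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) < 2:
        raise FormatError(f"{path}: paired VCF needs two samples, found {samples}")
    gi = samples.index(germline_sample) if germline_sample else 0
    ti = samples.index(tumor_sample) if tumor_sample else 1
    out: List[VariantRecord] = []
    for var in vcf:
        alts = var.ALT or []
        if len(alts) > 1:
            warnings.warn(
                f"{path}: multi-allelic record at {var.CHROM}:{var.POS} "
                f"split into {len(alts)} biallelic records"
            )
        ad = var.format("AD")
        if ad is None:
            raise FormatError(f"{path}: record at {var.CHROM}:{var.POS} lacks AD depths")
        for ai, alt in enumerate(alts, start=1):
            out.append(VariantRecord(
                chrom=var.CHROM, pos=var.POS,
                ref_base=var.REF, alt_base=alt,
                germline_ref=int(ad[gi][0]), germline_alt=int(ad[gi][ai]),
                tumor_ref=int(ad[ti][0]), tumor_alt=int(ad[ti][ai]),
                sample_id=samples[ti],
            ))
    return out


def write_variant_table(records: Sequence[VariantRecord], path) -> None:
    rows = []
    for r in records:
        rows.append((
            r.chrom, r.pos, r.ref_base, r.alt_base,
            r.germline_ref, r.germline_alt, r.tumor_ref, r.tumor_alt,
            "" if r.tumor_alt_fwd is None else r.tumor_alt_fwd,
            "" if r.tumor_alt_rev is None else r.tumor_alt_rev,
            r.gene, r.consequence, r.sample_id, r.compartment,
        ))
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AkapCnvFixture:
    """Per-patient amp/del status at the seven AKAP loci with printed CNVs.

    ``loci`` carries the locus regions (labels are gene symbols);
    ``calls`` maps (gene, patient, lesion) -> "amp" | "del";
    ``cohort2_counts`` holds the validation-cohort aggregate counts that are
    unambiguous in the source prose, as {gene: {"amp": n} | {"del": n}}.
    """

    loci: RegionSet
    calls: dict
    cohort2_counts: dict

    def call(self, gene: str, patient: str, lesion: str) -> Optional[str]:
        return self.calls.get((gene, patient, lesion))


def _fixture_path(name: str) -> Path:
    return Path(resources.files("pairedmet") / "fixtures" / f"{name}.tsv")


def _load_mutation_fixture(name: str) -> List[MutationTableRow]:
    df = _read_tsv(_fixture_path(name), ["gene", "patient", "primary"])
    lesion_cols = [c for c in ("primary", "axillary", "metastasis_1", "metastasis_2")
                   if c in df.columns]
    rows = []
    for _, r in df.iterrows():
        vafs = []
        for lesion in lesion_cols:
            cell = r[lesion].strip()
            if cell == "":
                continue  # not assayed / not reported
            values = tuple(float(v) for v in cell.split("|"))
            vafs.append((lesion, values))
        rows.append(MutationTableRow(
            gene=r["gene"], patient_id=r["patient"], vafs=tuple(vafs),
            substitution=r["substitution"], consequence=r["consequence"],
            chrom=r["chrom"], pos=int(r["pos"]),
        ))
    return rows


def _load_cnv_fixture() -> AkapCnvFixture:
    loci_df = _read_tsv(_fixture_path("akap_loci"), ["gene", "chrom", "start", "end"])
    loci = RegionSet(
        (r["chrom"], int(r["start"]), int(r["end"]), r["gene"])
        for _, r in loci_df.iterrows()
    )
    cohort2 = {}
    for _, r in loci_df.iterrows():
        counts = {}
        if r.get("cohort2_amp", ""):
            counts["amp"] = int(r["cohort2_amp"])
        if r.get("cohort2_del", ""):
            counts["del"] = int(r["cohort2_del"])
        if counts:
            cohort2[r["gene"]] = counts
    calls_df = _read_tsv(_fixture_path("akap_cnv_calls"), ["gene", "patient", "lesion", "call"])
    calls = {
        (r["gene"], r["patient"], r["lesion"]): r["call"]
        for _, r in calls_df.iterrows()
    }
    return AkapCnvFixture(loci=loci, calls=calls, cohort2_counts=cohort2)


def load_fixture(name: str):
    """Load a packaged fixture transcribing a printed table.

    ``cohort1_akap``/``cohort2_akap`` return mutation rows (9 and 4 rows);
    ``akap_cnv`` returns an :class:`AkapCnvFixture`.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    if name == "akap_cnv":
        return _load_cnv_fixture()
    return _load_mutation_fixture(name)
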