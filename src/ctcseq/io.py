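"""Readers and writers for the file formats the pipeline touches.

Variant tables come in two dialects: a tab-separated table
(``chrom pos ref alt depth alt_count`` with ``#key=value`` metadata lines)
and minimal VCF 4.2 (CHROM/POS/REF/ALT with DP and AD in FORMAT; multi-allelic
records are split by the reader). Panels are BED (regions) plus a primers TSV;
clinical records are CSV. All writers emit deterministic, sorted output so
that equal in-memory objects serialize to identical bytes.
"""

from __future__ import annotations

import math
import os
from typing import Dict, List, Optional

import pandas as pd
import pysam

from .panel import ClinicalRecord, Panel, Region
from .variants import (
    DuplicateVariantError,
    GenomicVariant,
    InvalidVariantError,
    ObservedVariant,
    SampleRole,
    SampleVariantSet,
)

__all__ = [
    "VariantTableParseError",
    "read_variant_table",
    "write_variant_table",
    "read_vcf",
    "write_vcf",
    "read_panel_bed",
    "write_panel_bed",
    "read_primers_tsv",
    "write_primers_tsv",
    "read_clinical_csv",
    "write_clinical_csv",
]

_TSV_COLUMNS = ("chrom", "pos", "ref", "alt", "depth", "alt_count")


class VariantTableParseError(ValueError):
    """A malformed variant table row; the message names the offending line."""


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def write_variant_table(s: SampleVariantSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sample_id={s.sample_id}\n")
        fh.write(f"#patient_id={s.patient_id}\n")
        fh.write(f"#role={s.role.value}\n")
        rep = s.replicate_index if s.replicate_index is not None else "."
        fh.write(f"#replicate_index={rep}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for ov in s:
            v = ov.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{ov.depth}\t{ov.alt_count}\n"
            )


def read_variant_table(
    path: str | os.PathLike,
    sample_id: Optional[str] = None,
    patient_id: Optional[str] = None,
    role: Optional[SampleRole] = None,
    replicate_index: Optional[int] = None,
) -> SampleVariantSet:
    """Read the TSV dialect; explicit arguments override file metadata."""
    meta: Dict[str, str] = {}
    rows: List[tuple[int, List[str]]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, _, v = line[1:].partition("=")
                    meta[k.strip()] = v.strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != _TSV_COLUMNS:
                    raise VariantTableParseError(
                        f"{path}:{lineno}: expected header "
                        f"{' '.join(_TSV_COLUMNS)}, got {line!r}"
                    )
                header_seen = True
                continue
            rows.append((lineno, fields))
    if not header_seen:
        raise VariantTableParseError(f"{path}: missing header line")

    if sample_id is None:
        sample_id = meta.get("sample_id", os.path.splitext(os.path.basename(path))[0])
    if patient_id is None:
        patient_id = meta.get("patient_id", sample_id)
    if role is None:
        if "role" not in meta:
            raise VariantTableParseError(f"{path}: no role metadata and none given")
        role = SampleRole(meta["role"])
    if replicate_index is None:
        rep = meta.get("replicate_index", ".")
        replicate_index = None if rep in (".", "") else int(rep)
    if role is not SampleRole.CTC_WGA:
        replicate_index = None

    out = SampleVariantSet(sample_id, patient_id, role, replicate_index=replicate_index)
    for lineno, fields in rows:
        if len(fields) != len(_TSV_COLUMNS):
            raise VariantTableParseError(
                f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} fields, "
                f"got {len(fields)}"
            )
        chrom, pos_s, ref, alt, depth_s, alt_count_s = fields
        try:
            pos, depth, alt_count = int(pos_s), int(depth_s), int(alt_count_s)
            ov = ObservedVariant(GenomicVariant(chrom, pos, ref, alt), depth, alt_count)
            out.add(ov)
        except (ValueError, InvalidVariantError, DuplicateVariantError) as exc:
            raise VariantTableParseError(f"{path}:{lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Minimal VCF 4.2
# ---------------------------------------------------------------------------

def write_vcf(s: SampleVariantSet, path: str | os.PathLike) -> None:
    chroms = sorted({ov.variant.chrom for ov in s})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##ctcseq_patient_id={s.patient_id}\n")
        fh.write(f"##ctcseq_role={s.role.value}\n")
        rep = s.replicate_index if s.replicate_index is not None else "."
        fh.write(f"##ctcseq_replicate_index={rep}\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref, alt)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + s.sample_id + "\n"
        )
        for ov in s:
            v = ov.variant
            ad = f"{ov.depth - ov.alt_count},{ov.alt_count}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                f"DP:AD\t{ov.depth}:{ad}\n"
            )


def read_vcf(path: str | os.PathLike) -> SampleVariantSet:
    """Read a minimal single-sample VCF; multi-allelic records are split."""
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            if line.startswith("##ctcseq_"):
                k, _, v = line[2:].strip().partition("=")
                meta[k[len("ctcseq_"):]] = v

    role = SampleRole(meta["role"]) if "role" in meta else SampleRole.CTC_WGA
    rep = meta.get("replicate_index", ".")
    replicate_index = None if rep in (".", "") else int(rep)
    if role is not SampleRole.CTC_WGA:
        replicate_index = None

    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if len(sample_names) != 1:
            raise VariantTableParseError(
                f"{path}: expected a single-sample VCF, found {len(sample_names)}"
            )
        sample_id = sample_names[0]
        out = SampleVariantSet(
            sample_id,
            meta.get("patient_id", sample_id),
            role,
            replicate_index=replicate_index,
        )
        for rec in vcf:
            call = rec.samples[0]
            depth = call.get("DP")
            ad = call.get("AD")
            if depth is None or ad is None:
                raise VariantTableParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks DP/AD"
                )
            for i, alt in enumerate(rec.alts or ()):
                try:
                    ov = ObservedVariant(
                        GenomicVariant(rec.chrom, rec.pos, rec.ref, alt),
                        int(depth),
                        int(ad[i + 1]),
                    )
                    out.add(ov)
                except (InvalidVariantError, DuplicateVariantError) as exc:
                    raise VariantTableParseError(
                        f"{path}: record {rec.chrom}:{rec.pos}: {exc}"
                    ) from exc
    return out


# ---------------------------------------------------------------------------
# Panel: BED regions + primers TSV
# ---------------------------------------------------------------------------

def write_panel_bed(panel: Panel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in panel.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\n")


def read_panel_bed(
    path: str | os.PathLike, primers: Optional[Dict[str, List[str]]] = None
) -> Panel:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise VariantTableParseError(
                    f"{path}:{lineno}: BED needs chrom/start/end/gene"
                )
            regions.append(
                Region(fields[0], int(fields[1]), int(fields[2]), fields[3])
            )
    return Panel(regions, primers=primers)


def write_primers_tsv(panel: Panel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tprimer_sequence\n")
        for chrom in sorted(panel.primers):
            for seq in panel.primers[chrom]:
                fh.write(f"{chrom}\t{seq}\n")


def read_primers_tsv(path: str | os.PathLike) -> Dict[str, List[str]]:
    primers: Dict[str, List[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["chrom", "primer_sequence"]:
            raise VariantTableParseError(f"{path}: unexpected primers header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, seq = line.split("\t")
            primers.setdefault(chrom, []).append(seq)
    return primers


# ---------------------------------------------------------------------------
# Clinical records CSV
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = ["patient_id", "age", "dukes", "cea", "msi"]


def write_clinical_csv(records: List[ClinicalRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "dukes": r.dukes,
                "cea": r.cea,
                "msi": r.msi,
            }
            for r in records
        ],
        columns=_CLINICAL_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_clinical_csv(path: str | os.PathLike) -> List[ClinicalRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str, "dukes": str, "msi": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ClinicalRecord(
                patient_id=row.patient_id,
                age=None if pd.isna(row.age) else int(row.age),
                dukes=None if pd.isna(row.dukes) else str(row.dukes),
                cea=None if pd.isna(row.cea) else float(row.cea),
                msi=None if pd.isna(row.msi) else str(row.msi),
            )
        )
    return records
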