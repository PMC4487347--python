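"""Reading called variants (VCF, MuTect call-stats) and writing exports.

Only biallelic SNVs survive reading: the downstream mapping, effect-predictor
join and scoring are defined for single-base substitutions.  Multiallelic VCF
records are split into one candidate per alternate allele and each split is
re-checked for SNV-ness; indels/MNVs are counted in a skip summary rather
than silently dropped.

Positions are 1-based in every file format handled here and in the
:class:`Variant` container; the 0-based half-open arithmetic happens in
:mod:`evanno.annotate`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from cyvcf2 import VCF

logger = logging.getLogger("evanno")

BASES = {"A", "C", "G", "T"}

GERMLINE = "germline_called"
SOMATIC = "somatic_called"

HET = "het"
HOM_ALT = "hom_alt"
UNKNOWN = "unknown"


class VariantReadError(ValueError):
    """Input variant file is unreadable or inconsistent with its declared format."""


@dataclass(frozen=True)
class Variant:
    """One called single-nucleotide variant in one sample."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str
    origin: str = GERMLINE
    zygosity: str = UNKNOWN
    quality: float | None = None
    ref_reads: int | None = None
    alt_reads: int | None = None

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-SNV alleles {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantSet:
    """All retained variants of one sample from one caller."""

    sample_id: str
    origin: str
    variants: list[Variant] = field(default_factory=list)
    #: reasons-to-count map for records not retained (non_snv, filtered, ...)
    skip_summary: dict[str, int] = field(default_factory=dict)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


def _normalize_chrom(chrom: str, normalize: bool) -> str:
    if not normalize:
        return chrom
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


def read_vcf(
    path: str | Path,
    sample_id: str | None = None,
    keep_filtered: bool = False,
    origin: str = GERMLINE,
    normalize_chrom: bool = False,
) -> VariantSet:
    """Read biallelic SNVs for one sample from a VCF 4.x file.

    Records whose FILTER is neither PASS nor '.' are dropped unless
    ``keep_filtered``.  Multiallelic records are split per alternate allele.
    Zygosity comes from the genotype: 0/1 -> het, 1/1 -> hom_alt, missing or
    no sample column -> unknown.
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VariantReadError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if sample_id is None:
        sample_id = samples[0] if samples else path.stem
        sample_idx = 0 if samples else None
    else:
        if samples:
            if sample_id not in samples:
                raise VariantReadError(
                    f"sample {sample_id!r} not in {path.name}; available: {samples}"
                )
            sample_idx = samples.index(sample_id)
        else:
            sample_idx = None

    vset = VariantSet(sample_id=sample_id, origin=origin)
    skip = vset.skip_summary
    seen: set[tuple[str, int, str, str]] = set()
    for rec in vcf:
        if not keep_filtered and rec.FILTER is not None:  # None == PASS or '.'
            skip["filtered"] = skip.get("filtered", 0) + 1
            continue
        chrom = _normalize_chrom(rec.CHROM, normalize_chrom)
        ref = rec.REF.upper()
        if sample_idx is not None:
            gt = rec.genotypes[sample_idx]
            alleles = [a for a in gt[:-1] if isinstance(a, int) and a >= 0]
        else:
            alleles = []
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                skip["non_snv"] = skip.get("non_snv", 0) + 1
                continue
            if not alleles:
                zyg = UNKNOWN
            else:
                n = alleles.count(alt_idx)
                if n == 0:
                    # allele listed but not carried by this sample
                    skip["allele_absent"] = skip.get("allele_absent", 0) + 1
                    continue
                zyg = HOM_ALT if n == len(alleles) and len(alleles) > 1 else HET
            v = Variant(
                chrom=chrom,
                pos=rec.POS,
                ref=ref,
                alt=alt,
                sample_id=sample_id,
                origin=origin,
                zygosity=zyg,
                quality=float(rec.QUAL) if rec.QUAL is not None else None,
            )
            if v.key in seen:
                skip["duplicate_key"] = skip.get("duplicate_key", 0) + 1
                continue
            seen.add(v.key)
            vset.variants.append(v)
    logger.info(
        "read_vcf %s: %d SNVs retained, skipped %s", path.name, len(vset), skip or "none"
    )
    return vset


def read_mutect(
    path: str | Path,
    sample_id: str | None = None,
    keep_all: bool = False,
    normalize_chrom: bool = False,
) -> VariantSet:
    """Read somatic SNVs from a MuTect call-stats TSV.

    Rows with judgement KEEP are retained (``keep_all`` keeps every row).
    Zygosity defaults to het; when a ``tumor_f`` column is present a tumor
    allele fraction >= 0.9 is recorded as hom_alt.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    header: list[str] | None = None
    vset = VariantSet(sample_id=sample_id, origin=SOMATIC)
    skip = vset.skip_summary
    seen: set[tuple[str, int, str, str]] = set()
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                required = {"contig", "position", "ref_allele", "alt_allele", "judgement"}
                missing = required - set(header)
                if missing:
                    raise VariantReadError(
                        f"{path.name}: missing mandatory column(s): {sorted(missing)}"
                    )
                continue
            row = dict(zip(header, fields))
            if not keep_all and row["judgement"] != "KEEP":
                skip["rejected"] = skip.get("rejected", 0) + 1
                continue
            ref, alt = row["ref_allele"].upper(), row["alt_allele"].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                skip["non_snv"] = skip.get("non_snv", 0) + 1
                continue
            zyg = HET
            tumor_f = row.get("tumor_f", "")
            if tumor_f not in ("", "."):
                try:
                    if float(tumor_f) >= 0.9:
                        zyg = HOM_ALT
                except ValueError:
                    pass
            ref_reads = row.get("t_ref_count")
            alt_reads = row.get("t_alt_count")
            v = Variant(
                chrom=_normalize_chrom(row["contig"], normalize_chrom),
                pos=int(row["position"]),
                ref=ref,
                alt=alt,
                sample_id=sample_id,
                origin=SOMATIC,
                zygosity=zyg,
                ref_reads=int(ref_reads) if ref_reads not in (None, "", ".") else None,
                alt_reads=int(alt_reads) if alt_reads not in (None, "", ".") else None,
            )
            if v.key in seen:
                skip["duplicate_key"] = skip.get("duplicate_key", 0) + 1
                continue
            seen.add(v.key)
            vset.variants.append(v)
    if header is None:
        raise VariantReadError(f"{path.name}: empty file, no header")
    logger.info(
        "read_mutect %s: %d somatic SNVs retained, skipped %s",
        path.name, len(vset), skip or "none",
    )
    return vset


def write_pileup(variant_set: VariantSet | Iterable[Variant], path: str | Path) -> None:
    """Write the 4-column pileup export (chrom, 1-based pos, ref, alt).

    Lines are sorted by (chrom, pos, ref, alt) so output is byte-stable; the
    explicit alternate base (rather than an IUPAC consensus code) keeps the
    export lossless for the effect-predictor round trip.
    """
    variants = list(variant_set)
    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with Path(path).open("w") as fh:
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\n")


def read_pileup(
    path: str | Path, sample_id: str = "pileup", origin: str = GERMLINE
) -> VariantSet:
    """Read the 4-column pileup format back into a VariantSet (zygosity unknown)."""
    vset = VariantSet(sample_id=sample_id, origin=origin)
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, pos, ref, alt = line.rstrip("\n").split("\t")
            vset.variants.append(
                Variant(chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                        sample_id=sample_id, origin=origin)
            )
    return vset


# --- generic variant-table TSV (stage intermediates) -----------------------

_TABLE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "sample_id", "origin", "zygosity",
    "quality", "ref_reads", "alt_reads", "genes", "coding",
]


def write_variant_table(records: Sequence, path: str | Path) -> None:
    """Write Variants or AnnotatedVariants as a TSV stage intermediate."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for rec in records:
            v = getattr(rec, "variant", rec)
            genes = ",".join(getattr(rec, "genes", []) or [])
            coding = getattr(rec, "coding", "")
            fh.write(
                "\t".join(
                    str(x) if x is not None else ""
                    for x in (
                        v.chrom, v.pos, v.ref, v.alt, v.sample_id, v.origin,
                        v.zygosity, v.quality, v.ref_reads, v.alt_reads,
                        genes, coding,
                    )
                )
                + "\n"
            )


def read_variant_table(path: str | Path):
    """Read a stage-intermediate TSV back into AnnotatedVariants."""
    from evanno.annotate import AnnotatedVariant  # local import avoids a cycle

    out = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TABLE_COLUMNS:
            raise VariantReadError(f"{path}: unexpected variant-table header")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            v = Variant(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                sample_id=row["sample_id"],
                origin=row["origin"],
                zygosity=row["zygosity"],
                quality=float(row["quality"]) if row["quality"] else None,
                ref_reads=int(row["ref_reads"]) if row["ref_reads"] else None,
                alt_reads=int(row["alt_reads"]) if row["alt_reads"] else None,
            )
            genes = [g for g in row["genes"].split(",") if g]
            out.append(
                AnnotatedVariant(
                    variant=v, genes=genes,
                    coding=row["coding"] == "True",
                )
            )
    return out
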