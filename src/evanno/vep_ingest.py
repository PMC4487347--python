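"""Parsing Variant Effect Predictor tabular output and joining it with calls.

The parser reads VEP's "default" tab-separated output (one row per
variant x transcript) and aggregates to one record per (variant, gene):
SIFT is the minimum over transcript rows and PolyPhen-2 the maximum —
i.e. the most damaging transcript wins on both scales — consequences are
unioned, and the amino-acid change is taken from the first row (file
order) that carries one.

A missing GMAF is kept as missing, never imputed to 0: absence from the
1000 Genomes frequency data is itself informative (the variant is likely
unreported) and the rarity score treats it as maximally rare.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from evanno.annotate import AnnotatedVariant
from evanno.refdata import FocusConfig, GeneEvidence

logger = logging.getLogger("evanno")

NONPOLAR = set("AVLIPFMWGC")
POLAR_UNCHARGED = set("STYNQ")
CHARGED = set("KRHDE")  # histidine grouped with the charged residues

POLARITY_NONE = "none"
POLARITY_GAIN = "gain"
POLARITY_LOSS = "loss"
POLARITY_SWAP = "swap"


class VepFormatError(ValueError):
    """VEP file lacks the expected default-format header or key syntax."""


@dataclass
class VepAnnotation:
    """Aggregated effect prediction for one (variant, gene) pair."""

    key: tuple[str, int, str, str]
    gene_symbol: str
    consequences: list[str] = field(default_factory=list)
    sift: float | None = None
    polyphen: float | None = None
    gmaf: float | None = None
    existing_id: str | None = None
    aa_change: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        for name, val, hi in (("sift", self.sift, 1.0),
                              ("polyphen", self.polyphen, 1.0),
                              ("gmaf", self.gmaf, 0.5)):
            if val is not None and not 0.0 <= val <= hi:
                raise ValueError(f"{name} {val} outside [0, {hi}]")


@dataclass
class EnrichedVariant:
    """A called variant joined with its effect prediction and gene evidence."""

    variant: object  # Variant
    annotation: VepAnnotation
    evidence: GeneEvidence
    polarity_change: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.annotation.key


@dataclass
class EnrichResult:
    """Join output plus the reconciliation summary (nothing silently dropped)."""

    records: list[EnrichedVariant] = field(default_factory=list)
    n_joined: int = 0
    n_joined_keys: int = 0
    n_unmatched_annotations: int = 0
    n_unmatched_variants: int = 0
    unmatched_annotation_keys: list[tuple] = field(default_factory=list)
    unmatched_variant_keys: list[tuple] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


_UV_RE = re.compile(r"^(?P<chrom>.+)_(?P<pos>\d+)_(?P<ref>[ACGT])/(?P<alt>[ACGT])$")


def _parse_key(uploaded: str, location: str, allele: str) -> tuple[str, int, str, str]:
    m = _UV_RE.match(uploaded)
    if m:
        return (m["chrom"], int(m["pos"]), m["ref"], m["alt"])
    # fall back to Location chrom:pos (or chrom:start-end) + Allele column;
    # without an uploaded-variation key the reference base is unrecoverable
    raise VepFormatError(
        f"cannot parse variant key from Uploaded_variation {uploaded!r} "
        f"(expected chrom_pos_ref/alt)"
    )


def _parse_extra(extra: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if extra in ("", "-"):
        return out
    for pair in extra.split(";"):
        if not pair:
            continue
        if "=" not in pair:
            logger.warning("unparseable Extra pair %r skipped", pair)
            continue
        k, v = pair.split("=", 1)
        out[k] = v
    return out


def _parse_float_field(raw: str | None, what: str) -> float | None:
    """Parse '0.03', 'deleterious(0.03)' or allele-prefixed 'G:0.0041' forms."""
    if raw in (None, "", "-"):
        return None
    m = re.search(r"\(([\d.eE+-]+)\)", raw)
    if m:
        raw = m.group(1)
    elif ":" in raw:
        raw = raw.rsplit(":", 1)[1]
    try:
        return float(raw)
    except ValueError:
        logger.warning("unparseable %s value %r skipped", what, raw)
        return None


def parse_vep(path: str | Path) -> list[VepAnnotation]:
    """Parse VEP default tabular output into per-(variant, gene) annotations.

    Transcript rows are aggregated (sift=min, polyphen=max, consequence
    union, first amino-acid change by file order).  The gene symbol is taken
    from the Extra SYMBOL field when present, else from the Gene column.
    """
    path = Path(path)
    header: list[str] | None = None
    # accumulate per (key, gene): order-insensitive except aa_change/file order
    acc: dict[tuple, dict] = {}
    order: list[tuple] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            if header is None:
                raise VepFormatError(f"{path.name}: data before #Uploaded_variation header")
            row = dict(zip(header, line.split("\t")))
            required = {"Uploaded_variation", "Location", "Allele", "Gene", "Consequence"}
            if not required <= set(row):
                raise VepFormatError(
                    f"{path.name}: header missing columns {sorted(required - set(row))}"
                )
            key = _parse_key(row["Uploaded_variation"], row["Location"], row["Allele"])
            extra = _parse_extra(row.get("Extra", ""))
            gene = extra.get("SYMBOL") or row["Gene"]
            k = (key, gene)
            if k not in acc:
                acc[k] = {
                    "consequences": set(), "sift": None, "polyphen": None,
                    "gmaf": None, "existing_id": None, "aa_change": None,
                }
                order.append(k)
            slot = acc[k]
            slot["consequences"].update(
                c for c in row["Consequence"].split(",") if c and c != "-"
            )
            sift = _parse_float_field(extra.get("SIFT"), "SIFT")
            if sift is not None:
                slot["sift"] = sift if slot["sift"] is None else min(slot["sift"], sift)
            poly = _parse_float_field(extra.get("PolyPhen"), "PolyPhen")
            if poly is not None:
                slot["polyphen"] = (
                    poly if slot["polyphen"] is None else max(slot["polyphen"], poly)
                )
            gmaf = _parse_float_field(extra.get("GMAF"), "GMAF")
            if gmaf is not None and slot["gmaf"] is None:
                slot["gmaf"] = gmaf
            existing = row.get("Existing_variation", "-")
            if existing not in ("-", "") and slot["existing_id"] is None:
                slot["existing_id"] = existing.split(",")[0]
            aa = row.get("Amino_acids", "-")
            if slot["aa_change"] is None and aa not in ("-", "") and "/" in aa:
                ref_aa, alt_aa = aa.split("/", 1)
                if len(ref_aa) == 1 and len(alt_aa) == 1:
                    slot["aa_change"] = (ref_aa, alt_aa)
    if header is None:
        raise VepFormatError(f"{path.name}: no header line found")
    return [
        VepAnnotation(
            key=k[0],
            gene_symbol=k[1],
            consequences=sorted(acc[k]["consequences"]),
            sift=acc[k]["sift"],
            polyphen=acc[k]["polyphen"],
            gmaf=acc[k]["gmaf"],
            existing_id=acc[k]["existing_id"],
            aa_change=acc[k]["aa_change"],
        )
        for k in order
    ]


def classify_polarity(aa_change: tuple[str, str] | None) -> str | None:
    """Classify an amino-acid substitution by polarity-class transition.

    Classes: nonpolar {AVLIPFMWGC}, polar-uncharged {STYNQ}, charged {KRHDE}.
    Same class -> 'none'; nonpolar -> polar/charged -> 'gain';
    polar/charged -> nonpolar -> 'loss'; polar <-> charged -> 'swap'.
    Returns None for an absent change or an unknown residue letter.
    """
    if aa_change is None:
        return None
    ref_aa, alt_aa = (a.upper() for a in aa_change)

    def cls(a: str) -> str | None:
        if a in NONPOLAR:
            return "nonpolar"
        if a in POLAR_UNCHARGED:
            return "polar"
        if a in CHARGED:
            return "charged"
        return None

    c1, c2 = cls(ref_aa), cls(alt_aa)
    if c1 is None or c2 is None:
        logger.warning("unknown amino acid in %s/%s; polarity not classified",
                       ref_aa, alt_aa)
        return None
    if c1 == c2:
        return POLARITY_NONE
    if c1 == "nonpolar":
        return POLARITY_GAIN
    if c2 == "nonpolar":
        return POLARITY_LOSS
    return POLARITY_SWAP


def enrich(
    annotations: Sequence[VepAnnotation],
    variants: Sequence[AnnotatedVariant],
    evidence: Mapping[str, GeneEvidence],
    focus: FocusConfig,
) -> EnrichResult:
    """Inner-join effect predictions with called variants and gene evidence.

    The join key is (chrom, pos, ref, alt); zygosity and read support come
    from the called variant, the gene from the effect prediction.  A gene
    absent from the evidence map gets empty-default evidence.  Unmatched
    records on either side are counted (and their keys kept) in the result's
    reconciliation summary.  Zero joins with nonempty inputs raises, since
    that almost always means inconsistent chromosome naming.
    """
    by_key: dict[tuple, AnnotatedVariant] = {}
    for av in variants:
        by_key.setdefault(av.key, av)
    result = EnrichResult()
    joined_keys: set[tuple] = set()
    for ann in annotations:
        av = by_key.get(ann.key)
        if av is None:
            result.n_unmatched_annotations += 1
            result.unmatched_annotation_keys.append(ann.key)
            continue
        joined_keys.add(ann.key)
        ev = evidence.get(ann.gene_symbol) or GeneEvidence.empty(ann.gene_symbol)
        result.records.append(
            EnrichedVariant(
                variant=av.variant,
                annotation=ann,
                evidence=ev,
                polarity_change=classify_polarity(ann.aa_change),
            )
        )
    result.n_joined = len(result.records)
    result.n_joined_keys = len(joined_keys)
    for key, av in by_key.items():
        if key not in joined_keys:
            result.n_unmatched_variants += 1
            result.unmatched_variant_keys.append(key)
    if not result.records and annotations and variants:
        raise ValueError(
            "no effect-prediction keys matched any called variant; check "
            "chromosome naming (try normalize_chrom when reading inputs)"
        )
    logger.info(
        "enrich: %d joined, %d predictions unmatched, %d variants unmatched",
        result.n_joined, result.n_unmatched_annotations, result.n_unmatched_variants,
    )
    return result
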