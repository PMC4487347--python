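"""Mapping variants onto gene models and building pseudo-germline sets.

The mapping is two-stage, mirroring a mapped-then-coding narrowing:

1. a variant maps to a gene iff its 0-based position lies within the
   transcript span [tx_start, tx_end) of at least one transcript of that
   gene (UTRs and introns included; strand is irrelevant for point lookup);
2. it is *coding* iff for at least one transcript the position falls inside
   the CDS interval AND inside an exon.

Interval lookup uses an interval tree per chromosome; the result is
required (and tested) to be observationally identical to the brute-force
scan over every transcript.

The pseudo-germline set of related samples without a true normal — here
the intersection over per-sample call sets — keys variants by
(chrom, pos, ref, alt) only: allele identity, not zygosity or caller,
defines "the same variant" across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from evanno.refdata import TranscriptModel
from evanno.variant_io import Variant, VariantSet


@dataclass
class AnnotatedVariant:
    """A variant plus the gene symbols whose transcript spans contain it."""

    variant: Variant
    genes: list[str] = field(default_factory=list)
    coding: bool = False

    @property
    def intergenic(self) -> bool:
        return not self.genes

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.variant.key


@dataclass
class AnnotationResult:
    """Partition of an input set into gene-mapped and intergenic variants."""

    mapped: list[AnnotatedVariant] = field(default_factory=list)
    intergenic: list[AnnotatedVariant] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mapped) + len(self.intergenic)


def build_gene_index(models: Sequence[TranscriptModel]) -> dict[str, IntervalTree]:
    """Interval tree of transcript spans per chromosome; data = gene symbol."""
    trees: dict[str, IntervalTree] = {}
    for m in models:
        if m.tx_start >= m.tx_end:  # empty span cannot contain a point
            continue
        trees.setdefault(m.chrom, IntervalTree()).addi(
            m.tx_start, m.tx_end, m.gene_symbol
        )
    return trees


def map_variants(
    variant_set: VariantSet | Iterable[Variant],
    models: Sequence[TranscriptModel],
    index: dict[str, IntervalTree] | None = None,
) -> AnnotationResult:
    """Partition variants into gene-mapped and intergenic.

    Gene lists are deduplicated and sorted lexically.  An empty model list
    maps everything to the intergenic bucket.
    """
    if index is None:
        index = build_gene_index(models)
    result = AnnotationResult()
    for v in variant_set:
        tree = index.get(v.chrom)
        genes = sorted({iv.data for iv in tree.at(v.pos - 1)}) if tree else []
        av = AnnotatedVariant(variant=v, genes=genes)
        (result.mapped if genes else result.intergenic).append(av)
    return result


def map_variants_bruteforce(
    variant_set: VariantSet | Iterable[Variant],
    models: Sequence[TranscriptModel],
) -> AnnotationResult:
    """O(V*T) reference scan over every transcript; oracle for map_variants."""
    result = AnnotationResult()
    for v in variant_set:
        p = v.pos - 1
        genes = sorted(
            {m.gene_symbol for m in models if m.chrom == v.chrom and m.tx_start <= p < m.tx_end}
        )
        av = AnnotatedVariant(variant=v, genes=genes)
        (result.mapped if genes else result.intergenic).append(av)
    return result


def _is_coding(p: int, m: TranscriptModel) -> bool:
    if not (m.cds_start <= p < m.cds_end):
        return False
    return any(s <= p < e for s, e in zip(m.exon_starts, m.exon_ends))


def find_coding(
    result: AnnotationResult | Sequence[AnnotatedVariant],
    models: Sequence[TranscriptModel],
) -> list[AnnotatedVariant]:
    """Select mapped variants lying in the CDS and an exon of some transcript.

    Only transcripts of genes the variant already mapped to are consulted.
    Input order is preserved; returned records have ``coding=True``.
    """
    mapped = result.mapped if isinstance(result, AnnotationResult) else list(result)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_symbol, []).append(m)
    coding: list[AnnotatedVariant] = []
    for av in mapped:
        p = av.variant.pos - 1
        if any(
            _is_coding(p, m)
            for g in av.genes
            for m in by_gene.get(g, ())
            if m.chrom == av.variant.chrom
        ):
            av.coding = True
            coding.append(av)
    return coding


def intersect_sets(
    sets: Sequence[Sequence[AnnotatedVariant]],
) -> list[AnnotatedVariant]:
    """Variants whose (chrom, pos, ref, alt) key occurs in every input set.

    Metadata (zygosity, read counts, gene annotation) is taken from the
    first set's record; output is sorted by (chrom, pos, ref, alt).
    """
    if len(sets) < 2:
        raise ValueError(f"intersection needs >= 2 sets, got {len(sets)}")
    common = set(av.key for av in sets[0])
    for s in sets[1:]:
        common &= {av.key for av in s}
    first_by_key = {}
    for av in sets[0]:
        first_by_key.setdefault(av.key, av)
    out = [first_by_key[k] for k in common]
    out.sort(key=lambda av: av.key)
    return out


def write_intersection_tsv(
    intersection: Sequence[AnnotatedVariant], path: str | Path
) -> None:
    """Tabulated export of an intersection (chrom, pos, ref, alt, genes, coding)."""
    with Path(path).open("w") as fh:
        fh.write("chrom\tpos\tref\talt\tgenes\tcoding\n")
        for av in intersection:
            v = av.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                f"{','.join(av.genes)}\t{av.coding}\n"
            )
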