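"""Composite relevance scoring of enriched variants.

The score is a deliberately simple, transparent weighted sum over eight
evidence channels; it is a triage ranking, not a calibrated probability:

====================  ========================================================
channel               value
====================  ========================================================
rarity                1 when the global minor allele frequency (GMAF) is
                      unreported; else clamp((gmax - gmaf)/gmax, 0, 1)
                      with gmax = 0.05 by default
sift_damage           1 when a SIFT score is present and <= 0.05, else 0
polyphen_damage       the PolyPhen-2 probability itself (0 when absent)
literature            log10(1 + pubmed_count) — the logarithm damps the
                      dominance of heavily published biomarker genes
cosmic                min(entries / protein_length, cap) / cap, the per-
                      residue somatic-mutation burden saturating at
                      cap = 1 entry per residue by default
disease               1 when any gene-disease association matches a focus
                      phrase (case-insensitive substring), else 0
function              1 when any functional process term matches a focus
                      phrase (case-insensitive, non-alphanumerics ignored)
zygosity              1.0 homozygous-alt, 0.5 heterozygous or unknown
====================  ========================================================

All channel weights default to 1 and live in FocusConfig.weights, so an
alternative weighting is one configuration away.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from evanno.refdata import CHANNELS, FocusConfig
from evanno.variant_io import HET, HOM_ALT
from evanno.vep_ingest import EnrichedVariant


@dataclass
class ScoredVariant:
    """An enriched variant with per-channel scores, total and rank."""

    enriched: EnrichedVariant
    components: dict[str, float] = field(default_factory=dict)
    total: float = 0.0
    rank: int = 0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.enriched.key

    @property
    def gene_symbol(self) -> str:
        return self.enriched.annotation.gene_symbol


def score_rarity(gmaf: float | None, gmax: float = 0.05) -> float:
    """Rarity in [0,1]; an unreported frequency scores maximal rarity 1."""
    if not 0.0 < gmax <= 0.5:
        raise ValueError(f"gmax must be in (0, 0.5], got {gmax}")
    if gmaf is None:
        return 1.0
    if not 0.0 <= gmaf <= 0.5:
        raise ValueError(f"gmaf {gmaf} outside [0, 0.5]")
    return min(max((gmax - gmaf) / gmax, 0.0), 1.0)


def score_literature(n: int) -> float:
    """log10(1 + n) literature-count score (n = 9 -> 1.0, n = 99 -> 2.0)."""
    if n < 0:
        raise ValueError(f"literature count must be >= 0, got {n}")
    return math.log10(1 + n)


def score_cosmic(entries: int, protein_length: int, cap: float = 1.0) -> float:
    """Somatic-mutation burden per residue, capped and rescaled to [0,1]."""
    if protein_length < 1:
        raise ValueError(f"protein_length must be >= 1, got {protein_length}")
    if cap <= 0:
        raise ValueError(f"cap must be > 0, got {cap}")
    return min(entries / protein_length, cap) / cap


_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def _canon(text: str) -> str:
    return _NON_ALNUM.sub("", text.lower())


def match_disease(disease_names: Sequence[str], focus: Sequence[str]) -> int:
    """Number of gene-disease associations matching any focus phrase
    (case-insensitive substring)."""
    if not focus:
        return 0
    lowered = [f.lower() for f in focus]
    return sum(1 for d in disease_names if any(f in d.lower() for f in lowered))


def match_function(process_terms: Sequence[str], focus: Sequence[str]) -> bool:
    """True when any process term matches any focus phrase, comparing
    case-insensitively with non-alphanumeric characters stripped (so
    'Signal transduction' matches the phrase 'SignalTransduction')."""
    if not focus:
        return False
    canon_focus = [_canon(f) for f in focus if _canon(f)]
    return any(
        cf in _canon(t) for t in process_terms for cf in canon_focus
    )


def score_variant(e: EnrichedVariant, focus: FocusConfig) -> ScoredVariant:
    """Compute all eight channel scores and the weighted total for one variant."""
    ann, ev = e.annotation, e.evidence
    components = {
        "rarity": score_rarity(ann.gmaf, focus.rarity_gmax),
        "sift_damage": 1.0 if ann.sift is not None and ann.sift <= 0.05 else 0.0,
        "polyphen_damage": ann.polyphen if ann.polyphen is not None else 0.0,
        "literature": score_literature(ev.pubmed_count),
        "cosmic": score_cosmic(ev.cosmic_count, ev.protein_length, focus.cosmic_cap),
        "disease": 1.0 if match_disease(ev.disease_names, focus.disease_focus) else 0.0,
        "function": 1.0 if match_function(ev.process_terms, focus.function_focus) else 0.0,
        "zygosity": 1.0 if e.variant.zygosity == HOM_ALT else 0.5,
    }
    total = sum(focus.weights[c] * components[c] for c in CHANNELS)
    return ScoredVariant(enriched=e, components=components, total=total)


def rank_variants(
    scored: Sequence[ScoredVariant], collapse_multigene: bool = True
) -> list[ScoredVariant]:
    """Sort by total descending and assign ranks 1..n.

    Ties break deterministically by (chrom lexical, pos ascending, alt
    lexical).  When ``collapse_multigene`` is set, a variant overlapping
    several genes keeps only its best-scoring gene: the maximum total is the
    variant's ranking score and that gene is the one reported.
    """
    records = list(scored)
    if collapse_multigene:
        best: dict[tuple, ScoredVariant] = {}
        for sv in records:
            cur = best.get(sv.key)
            if (cur is None or sv.total > cur.total
                    or (sv.total == cur.total and sv.gene_symbol < cur.gene_symbol)):
                best[sv.key] = sv
        records = list(best.values())
    records.sort(
        key=lambda sv: (-sv.total, sv.key[0], sv.key[1], sv.key[3])
    )
    out = []
    for i, sv in enumerate(records, start=1):
        out.append(ScoredVariant(enriched=sv.enriched, components=dict(sv.components),
                                 total=sv.total, rank=i))
    return out


SCORE_COLUMNS = [
    "rank", "chrom", "pos", "ref", "alt", "gene", "zygosity", "consequences",
    "aa_change", "polarity_change", "sift", "polyphen", "gmaf", "existing_id",
    "pubmed_count", "cosmic_count", "protein_length", "is_census",
    "interacts_census",
] + [f"score_{c}" for c in CHANNELS] + ["total"]


def write_scored_tsv(scored: Sequence[ScoredVariant], path: str | Path) -> None:
    """Write ranked, scored variants with one column per channel."""
    def fmt(x) -> str:
        if x is None:
            return ""
        if isinstance(x, float):
            return f"{x:.6g}"
        return str(x)

    with Path(path).open("w") as fh:
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        for sv in scored:
            e = sv.enriched
            ann, ev, v = e.annotation, e.evidence, e.variant
            row = [
                sv.rank, v.chrom, v.pos, v.ref, v.alt, ann.gene_symbol,
                v.zygosity, ",".join(ann.consequences),
                "/".join(ann.aa_change) if ann.aa_change else "",
                e.polarity_change or "", ann.sift, ann.polyphen, ann.gmaf,
                ann.existing_id or "", ev.pubmed_count, ev.cosmic_count,
                ev.protein_length, ev.is_census, ev.interacts_census,
            ] + [sv.components[c] for c in CHANNELS] + [sv.total]
            fh.write("\t".join(fmt(x) for x in row) + "\n")
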