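"""Local reference tables: gene models and per-gene evidence.

All genomic coordinates held in memory are 0-based half-open (the UCSC
GenePred convention); conversion to/from 1-based happens only at I/O
boundaries in :mod:`evanno.variant_io`.

The evidence tables are flat TSV stand-ins for the online sources a
variant-prioritization workflow would normally query (PubMed literature
counts per MeSH term, COSMIC somatic-mutation burden, gene-disease
associations, functional process terms, the cancer gene census and a
gene-gene interaction network, plus a tissue expression matrix).  The
tables are the contract: no live fetching, no query expansion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger("evanno")

#: scoring channels, in report column order
CHANNELS = (
    "rarity",
    "sift_damage",
    "polyphen_damage",
    "literature",
    "cosmic",
    "disease",
    "function",
    "zygosity",
)

#: evidence table files required by load_evidence_tables
EVIDENCE_FILES = (
    "literature.tsv",
    "cosmic.tsv",
    "disease.tsv",
    "process.tsv",
    "census.tsv",
    "interactions.tsv",
    "expression.tsv",
)


class GenePredParseError(ValueError):
    """A GenePred row could not be parsed at all (bad field count / non-integer)."""


class EvidenceTableError(ValueError):
    """An evidence table is missing or fails validation."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript of a gene model, 0-based half-open coordinates."""

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems: list[str] = []
        if self.strand not in ("+", "-"):
            problems.append(f"strand {self.strand!r} not +/-")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            problems.append(
                "coordinate order violated: need "
                f"txStart({self.tx_start}) <= cdsStart({self.cds_start}) <= "
                f"cdsEnd({self.cds_end}) <= txEnd({self.tx_end})"
            )
        if len(self.exon_starts) != len(self.exon_ends) or len(self.exon_starts) < 1:
            problems.append("exon start/end lists must be equal length and non-empty")
            return problems
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                problems.append(f"exon [{s},{e}) outside transcript span or empty")
            if prev_end is not None and s < prev_end:
                problems.append(f"exons overlap or unsorted at [{s},{e})")
            prev_end = e
        return problems


@dataclass
class GeneEvidence:
    """Per-gene evidence bundle consumed by scoring and filtering."""

    gene_symbol: str
    pubmed_count: int = 0
    cosmic_count: int = 0
    protein_length: int = 1
    disease_names: list[str] = field(default_factory=list)
    process_terms: list[str] = field(default_factory=list)
    is_census: bool = False
    interacts_census: bool = False
    expression: dict[str, float] | None = None

    @classmethod
    def empty(cls, gene_symbol: str) -> "GeneEvidence":
        """Default evidence for a gene absent from every table."""
        return cls(gene_symbol=gene_symbol)


@dataclass
class FocusConfig:
    """Disease/function focus and scoring parameters.

    Empty focus lists make the corresponding channel/filter inert.
    ``rarity_gmax`` is the allele frequency above which the rarity channel
    reaches 0; ``cosmic_cap`` is the per-residue COSMIC entry rate at which
    the burden channel saturates.
    """

    mesh_term: str = ""
    disease_focus: list[str] = field(default_factory=list)
    function_focus: list[str] = field(default_factory=list)
    weights: dict[str, float] = field(default_factory=lambda: {c: 1.0 for c in CHANNELS})
    rarity_gmax: float = 0.05
    cosmic_cap: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.rarity_gmax <= 0.5:
            raise ValueError(f"rarity_gmax must be in (0, 0.5], got {self.rarity_gmax}")
        if self.cosmic_cap <= 0:
            raise ValueError(f"cosmic_cap must be > 0, got {self.cosmic_cap}")
        for c in CHANNELS:
            self.weights.setdefault(c, 1.0)
        unknown = set(self.weights) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown weight channels: {sorted(unknown)}")


def _parse_coord_list(text: str, line_no: int, what: str) -> tuple[int, ...]:
    # UCSC writes trailing commas ("100,300,")
    items = [t for t in text.strip().split(",") if t != ""]
    try:
        return tuple(int(t) for t in items)
    except ValueError as exc:
        raise GenePredParseError(
            f"line {line_no}: malformed {what} coordinate list {text!r}"
        ) from exc


def load_gene_models(
    path: str | Path, strict: bool = False
) -> list[TranscriptModel]:
    """Load transcript models from a GenePred TSV.

    Expected columns: name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds, geneSymbol.  Rows violating coordinate
    invariants are rejected; the rejections are logged with their 1-based
    line numbers (and raised as :class:`EvidenceTableError` when ``strict``).
    Rows that cannot be parsed at all raise :class:`GenePredParseError`
    naming the line.
    """
    path = Path(path)
    models: list[TranscriptModel] = []
    rejected: list[tuple[int, str]] = []
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise GenePredParseError(
                    f"line {line_no}: expected 11 tab-separated fields, got {len(fields)}"
                )
            try:
                model = TranscriptModel(
                    transcript_id=fields[0],
                    chrom=fields[1],
                    strand=fields[2],
                    tx_start=int(fields[3]),
                    tx_end=int(fields[4]),
                    cds_start=int(fields[5]),
                    cds_end=int(fields[6]),
                    exon_starts=_parse_coord_list(fields[8], line_no, "exonStarts"),
                    exon_ends=_parse_coord_list(fields[9], line_no, "exonEnds"),
                    gene_symbol=fields[10],
                )
                n_exons = int(fields[7])
            except GenePredParseError:
                raise
            except ValueError as exc:
                raise GenePredParseError(f"line {line_no}: {exc}") from exc
            problems = model.validate()
            if n_exons != len(model.exon_starts):
                problems.append(
                    f"exonCount {n_exons} != {len(model.exon_starts)} listed exons"
                )
            if problems:
                rejected.append((line_no, "; ".join(problems)))
            else:
                models.append(model)
    if rejected:
        report = "; ".join(f"line {n}: {msg}" for n, msg in rejected)
        if strict:
            raise EvidenceTableError(f"invalid gene-model rows: {report}")
        logger.warning("rejected %d gene-model row(s): %s", len(rejected), report)
    return models


def _read_tsv(dir_path: Path, name: str) -> pd.DataFrame:
    fp = dir_path / name
    if not fp.exists():
        raise EvidenceTableError(f"missing mandatory evidence table: {name}")
    return pd.read_csv(fp, sep="\t", dtype=str, keep_default_na=False)


def load_evidence_tables(
    directory: str | Path, mesh_term: str
) -> dict[str, GeneEvidence]:
    """Assemble one :class:`GeneEvidence` per gene from the evidence TSVs.

    Every gene appearing in any table gets an entry; channels missing for a
    gene default to zero/empty/false.  Literature counts are taken only for
    rows whose ``mesh_term`` equals ``mesh_term`` exactly.  A gene interacts
    with the census iff it shares an interaction pair (either direction)
    with a census gene.
    """
    directory = Path(directory)
    literature = _read_tsv(directory, "literature.tsv")
    cosmic = _read_tsv(directory, "cosmic.tsv")
    disease = _read_tsv(directory, "disease.tsv")
    process = _read_tsv(directory, "process.tsv")
    census = _read_tsv(directory, "census.tsv")
    interactions = _read_tsv(directory, "interactions.tsv")
    expression = _read_tsv(directory, "expression.tsv")

    evidence: dict[str, GeneEvidence] = {}

    def ev(gene: str) -> GeneEvidence:
        return evidence.setdefault(gene, GeneEvidence.empty(gene))

    for row in literature.itertuples(index=False):
        if row.mesh_term == mesh_term:
            ev(row.gene).pubmed_count = int(row.count)
        else:
            ev(row.gene)  # gene still registered
    for row in cosmic.itertuples(index=False):
        plen = int(row.protein_length)
        if plen <= 0:
            raise EvidenceTableError(
                f"cosmic.tsv: gene {row.gene} has protein_length {plen} (must be >= 1)"
            )
        e = ev(row.gene)
        e.cosmic_count = int(row.entries)
        e.protein_length = plen
    for row in disease.itertuples(index=False):
        ev(row.gene).disease_names.append(row.disease_name)
    for row in process.itertuples(index=False):
        ev(row.gene).process_terms.append(row.term)
    census_genes = set(census["gene"])
    for g in census_genes:
        ev(g).is_census = True
    for row in interactions.itertuples(index=False):
        a, b = row.geneA, row.geneB
        if b in census_genes:
            ev(a).interacts_census = True
        if a in census_genes:
            ev(b).interacts_census = True
        ev(a)
        ev(b)
    tissues = [c for c in expression.columns if c != "gene"]
    for row in expression.itertuples(index=False):
        ev(row.gene).expression = {
            t: float(v) for t, v in zip(tissues, row[1:])
        }
    return evidence


def write_evidence_tables(
    evidence: Mapping[str, GeneEvidence],
    directory: str | Path,
    mesh_term: str,
    interaction_pairs: Sequence[tuple[str, str]] | None = None,
) -> None:
    """Write evidence back out in the table layout load_evidence_tables reads.

    ``interaction_pairs`` must be supplied to reproduce interactions.tsv (the
    evidence map stores only the derived interacts_census flag); pairs for
    which neither end is a census gene are fine and are preserved.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    genes = sorted(evidence)
    rows = [(g, mesh_term, evidence[g].pubmed_count) for g in genes]
    pd.DataFrame(rows, columns=["gene", "mesh_term", "count"]).to_csv(
        directory / "literature.tsv", sep="\t", index=False
    )
    rows = [(g, evidence[g].cosmic_count, evidence[g].protein_length) for g in genes]
    pd.DataFrame(rows, columns=["gene", "entries", "protein_length"]).to_csv(
        directory / "cosmic.tsv", sep="\t", index=False
    )
    rows = [(g, d) for g in genes for d in evidence[g].disease_names]
    pd.DataFrame(rows, columns=["gene", "disease_name"]).to_csv(
        directory / "disease.tsv", sep="\t", index=False
    )
    rows = [(g, t) for g in genes for t in evidence[g].process_terms]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(
        directory / "process.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(g,) for g in genes if evidence[g].is_census], columns=["gene"]
    ).to_csv(directory / "census.tsv", sep="\t", index=False)
    pairs = list(interaction_pairs or [])
    pd.DataFrame(pairs, columns=["geneA", "geneB"]).to_csv(
        directory / "interactions.tsv", sep="\t", index=False
    )
    tissues: list[str] = []
    for g in genes:
        if evidence[g].expression:
            tissues = list(evidence[g].expression)
            break
    rows = [
        [g] + [evidence[g].expression[t] for t in tissues]
        for g in genes
        if evidence[g].expression
    ]
    pd.DataFrame(rows, columns=["gene"] + tissues).to_csv(
        directory / "expression.tsv", sep="\t", index=False
    )
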