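"""Seeded generator of a mutually consistent synthetic fixture universe.

Emulates the study design the toolkit targets: two related individuals
(e.g. monozygotic twins) each contribute a control sample and a target
sample.  Germline variants are shared by every sample; somatic variants
appear only in the target samples and in a MuTect-style call-stats file;
each sample additionally carries a little private call noise.  A subset of
the somatic variants are planted *drivers*: rare (no reported population
frequency), predicted damaging by both SIFT and PolyPhen-2, in genes with
dense somatic-mutation records, focus-matching disease links and process
terms.  Everything else is background: common allele frequencies and
benign predictions.

The generator writes every file format the pipeline reads — a GenePred
gene-model table, four VCFs, a MuTect call-stats TSV, an effect-predictor
tabular file covering exactly the coding variants, and all evidence TSVs —
plus a manifest recording each planted variant's true class and coding
status.  The manifest is the ground-truth oracle for every pipeline stage.
Identical seeds give byte-identical outputs.

This is deliberately a *fixture* universe, not a sequence simulator: no
reference genome, mutational signatures, linkage or read-level error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from evanno.refdata import TranscriptModel

# layout constants: each gene occupies a fixed window followed by an
# intergenic gap; transcripts never leave their gene's window
GENE_WINDOW = 6000
GENE_GAP = 4000
CHROM_MARGIN = 1000

#: shipped hematological disease focus (substring-matched, case-insensitive)
DISEASE_FOCUS = ["Myeloprolif", "Leukemia", "Lymphoma", "Lymphocytosis", "Myelodysplas"]

#: shipped hematological functional focus phrases
FUNCTION_FOCUS = [
    "SignalTransduction", "CellAdhesion", "SignalingPathway", "Differentiation",
    "CellProliferation", "RegulationOfTranscription", "Blood", "Apoptosis",
    "InflammatoryResponse", "Immune", "Chromatin", "SignalingCascade",
    "CellCycle", "CellDivision", "Mitosis", "Hemopoiesis", "B-cell",
    "Methylation", "Telomer", "DNARepair", "migration", "kappa",
    "SurfaceReceptor", "T-cell", "DefenceResponse", "DNADamage",
    "Phosporylation",
]

DEFAULT_TISSUES = ("CD34plus", "B_lymphocytes", "T_cells", "Liver", "Brain", "Heart")

_DRIVER_DISEASES = [
    "Chronic lymphocytic leukemia", "B-cell lymphoma", "Monoclonal B-cell lymphocytosis",
]
_DRIVER_PROCESSES = [
    "Apoptosis", "B-cell receptor signaling pathway", "Signal transduction",
    "Regulation of transcription",
]
_BACKGROUND_DISEASES = ["Cardiomyopathy", "Type 2 diabetes", "Osteoarthritis"]
_BACKGROUND_PROCESSES = ["Lipid metabolic process", "Visual perception", "Ion transport"]

# damaging substitutions cross a polarity class; benign ones stay inside
_DRIVER_AA = [("R", "W"), ("G", "E"), ("S", "K"), ("E", "V")]
_BACKGROUND_AA = [("L", "I"), ("S", "T"), ("K", "R"), ("A", "V")]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class EffectProfile:
    """Ranges effect-prediction values are drawn from; gmaf None = unreported."""

    gmaf: tuple[float, float] | None
    sift: tuple[float, float]
    polyphen: tuple[float, float]


DRIVER_PROFILE = EffectProfile(gmaf=None, sift=(0.0, 0.04), polyphen=(0.90, 0.99))
BACKGROUND_PROFILE = EffectProfile(gmaf=(0.05, 0.45), sift=(0.30, 1.0), polyphen=(0.0, 0.30))


@dataclass
class SimConfig:
    """Study conditions of the synthetic universe."""

    seed: int = 42
    n_genes: int = 30
    n_transcripts_per_gene: tuple[int, int] = (1, 2)
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr3")
    genome_span: int = 400_000  # per chromosome
    n_shared_germline: int = 100
    n_target_only: int = 60
    coding_fraction: float = 0.6
    n_planted_drivers: int = 3
    n_private_per_sample: int = 5
    n_reject_rows: int = 2
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    mesh_term: str = "leukemia"
    driver_profile: EffectProfile = DRIVER_PROFILE
    background_profile: EffectProfile = BACKGROUND_PROFILE

    def __post_init__(self) -> None:
        if self.n_planted_drivers > self.n_target_only:
            raise ValueError("n_planted_drivers cannot exceed n_target_only")
        if not 0.0 <= self.coding_fraction <= 1.0:
            raise ValueError("coding_fraction must lie in [0, 1]")
        lo, hi = self.n_transcripts_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("n_transcripts_per_gene must be a range with 1 <= lo <= hi")


@dataclass
class Manifest:
    """Ground truth of one generated universe."""

    config: SimConfig
    paths: dict[str, Path]
    variants: pd.DataFrame
    transcripts: pd.DataFrame
    driver_genes: list[str]

    def keys(self, *classes: str) -> set[tuple[str, int, str, str]]:
        df = self.variants
        if classes:
            df = df[df["var_class"].isin(classes)]
        return {
            (r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False)
        }

    def keys_for_sample(self, sample: str) -> set[tuple[str, int, str, str]]:
        """Keys a reader should retain from that sample's file."""
        df = self.variants
        mask = df["samples"].str.split(";").apply(lambda s: sample in s)
        df = df[mask & ~df["var_class"].isin(["rejected", "decoy"])]
        return {
            (r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False)
        }

    @property
    def coding_keys(self) -> set[tuple[str, int, str, str]]:
        df = self.variants[self.variants["coding"] == True]  # noqa: E712
        return {
            (r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False)
        }

    @property
    def driver_keys(self) -> set[tuple[str, int, str, str]]:
        return self.keys("driver")


class UnsatisfiableConfig(ValueError):
    """The requested universe does not fit the genome/gene-model space."""


# --------------------------------------------------------------------------
# gene models


def _make_transcript(rng: np.random.Generator, window_start: int) -> dict:
    length = int(rng.integers(3500, 5500))
    start = window_start + int(rng.integers(0, GENE_WINDOW - length + 1))
    n_exons = int(rng.integers(2, 5))
    cuts = np.sort(
        rng.choice(np.arange(50, length - 50), size=2 * n_exons - 2, replace=False)
    )
    bounds = [0, *cuts.tolist(), length]
    exon_starts = tuple(start + bounds[2 * i] for i in range(n_exons))
    exon_ends = tuple(start + bounds[2 * i + 1] for i in range(n_exons))
    cds_start = exon_starts[0] + (exon_ends[0] - exon_starts[0]) // 2
    cds_end = exon_ends[-1] - (exon_ends[-1] - exon_starts[-1]) // 2
    return {
        "tx_start": start,
        "tx_end": start + length,
        "cds_start": cds_start,
        "cds_end": cds_end,
        "exon_starts": exon_starts,
        "exon_ends": exon_ends,
    }


def _build_genes(config: SimConfig, rng: np.random.Generator):
    capacity = (config.genome_span - 2 * CHROM_MARGIN) // (GENE_WINDOW + GENE_GAP)
    if config.n_genes > capacity * len(config.chroms):
        raise UnsatisfiableConfig(
            f"{config.n_genes} genes need more than "
            f"{capacity * len(config.chroms)} available windows; enlarge "
            f"genome_span or add chromosomes"
        )
    next_start = {c: CHROM_MARGIN for c in config.chroms}
    models: list[TranscriptModel] = []
    genes: list[dict] = []
    tx_counter = 0
    for i in range(config.n_genes):
        chrom = config.chroms[i % len(config.chroms)]
        ws = next_start[chrom]
        next_start[chrom] += GENE_WINDOW + GENE_GAP
        symbol = f"GENE{i + 1:03d}"
        lo, hi = config.n_transcripts_per_gene
        n_tx = int(rng.integers(lo, hi + 1))
        gene_models = []
        for _ in range(n_tx):
            t = _make_transcript(rng, ws)
            tx_counter += 1
            gene_models.append(
                TranscriptModel(
                    gene_symbol=symbol,
                    transcript_id=f"NM_{tx_counter:05d}",
                    chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    **t,
                )
            )
        models.extend(gene_models)
        # position pools for this gene, within its private window
        coding = set()
        genic = set()
        for m in gene_models:
            for s, e in zip(m.exon_starts, m.exon_ends):
                for p in range(max(s, m.cds_start), min(e, m.cds_end)):
                    coding.add(p)
            genic.update(range(m.tx_start, m.tx_end))
        genes.append(
            {
                "symbol": symbol,
                "chrom": chrom,
                "window": (ws, ws + GENE_WINDOW),
                "models": gene_models,
                "coding_pool": sorted(coding),
                "noncoding_pool": sorted(genic - coding),
            }
        )
    return models, genes


def _write_genepred(models: Sequence[TranscriptModel], path: Path) -> None:
    rows = sorted(models, key=lambda m: (m.chrom, m.tx_start, m.transcript_id))
    with path.open("w") as fh:
        for m in rows:
            fh.write(
                "\t".join(
                    [
                        m.transcript_id, m.chrom, m.strand,
                        str(m.tx_start), str(m.tx_end),
                        str(m.cds_start), str(m.cds_end),
                        str(len(m.exon_starts)),
                        ",".join(map(str, m.exon_starts)) + ",",
                        ",".join(map(str, m.exon_ends)) + ",",
                        m.gene_symbol,
                    ]
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# variant planting


def _intergenic_positions(config: SimConfig, genes: list[dict]) -> list[tuple[str, int]]:
    """Gap regions guaranteed outside every transcript span (as ranges)."""
    spans: list[tuple[str, int, int]] = []
    for chrom in config.chroms:
        windows = sorted(g["window"] for g in genes if g["chrom"] == chrom)
        cursor = 0
        for ws, we in windows:
            if ws > cursor:
                spans.append((chrom, cursor, ws))
            cursor = we
        if cursor < config.genome_span:
            spans.append((chrom, cursor, config.genome_span))
    return spans


def _sample_intergenic(
    rng: np.random.Generator, spans, n: int, used: set
) -> list[tuple[str, int]]:
    lengths = np.array([e - s for _, s, e in spans])
    cum = np.cumsum(lengths)
    total = int(cum[-1])
    out: list[tuple[str, int]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n + 1000:
            raise UnsatisfiableConfig("cannot place intergenic variants; genome too full")
        r = int(rng.integers(0, total))
        idx = int(np.searchsorted(cum, r, side="right"))
        chrom, s, e = spans[idx]
        pos = s + (r - (int(cum[idx - 1]) if idx else 0))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        out.append((chrom, pos))
    return out


def _alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(0, 4))
    j = (i + 1 + int(rng.integers(0, 3))) % 4
    return str(BASES[i]), str(BASES[j])


def generate_universe(config: SimConfig, outdir: str | Path) -> Manifest:
    """Generate the full fixture universe under ``outdir``.

    Writes gene models, four sample VCFs (control1/2, target1/2), a MuTect
    call-stats file, an effect-predictor tabular file covering exactly the
    coding variants, the seven evidence TSVs and two manifest TSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    models, genes = _build_genes(config, rng)

    # --- choose driver genes and build shuffled position pools
    genes_with_cds = [g for g in genes if g["coding_pool"]]
    if config.n_planted_drivers > len(genes_with_cds):
        raise UnsatisfiableConfig("more drivers requested than genes with coding space")
    driver_idx = rng.choice(len(genes_with_cds), size=config.n_planted_drivers,
                            replace=False)
    driver_genes = [genes_with_cds[int(i)] for i in sorted(driver_idx)]
    driver_symbols = [g["symbol"] for g in driver_genes]

    background_coding_pool = [
        (g["chrom"], p, g["symbol"])
        for g in genes
        if g["symbol"] not in driver_symbols
        for p in g["coding_pool"]
    ]
    genic_noncoding_pool = [
        (g["chrom"], p, g["symbol"]) for g in genes for p in g["noncoding_pool"]
    ]
    rng.shuffle(background_coding_pool)
    rng.shuffle(genic_noncoding_pool)
    pool_cursor = {"coding": 0, "noncoding": 0}

    used: set[tuple[str, int]] = set()

    def take_coding(n: int) -> list[tuple[str, int, str]]:
        i = pool_cursor["coding"]
        if i + n > len(background_coding_pool):
            raise UnsatisfiableConfig(
                f"requested more coding variants than available CDS positions "
                f"({len(background_coding_pool)})"
            )
        out = background_coding_pool[i : i + n]
        pool_cursor["coding"] = i + n
        for chrom, p, _ in out:
            used.add((chrom, p))
        return out

    def take_noncoding(n: int) -> list[tuple[str, int, str]]:
        i = pool_cursor["noncoding"]
        if i + n > len(genic_noncoding_pool):
            raise UnsatisfiableConfig("not enough genic non-coding positions")
        out = genic_noncoding_pool[i : i + n]
        pool_cursor["noncoding"] = i + n
        for chrom, p, _ in out:
            used.add((chrom, p))
        return out

    spans = _intergenic_positions(config, genes)

    rows: list[dict] = []

    def plant(chrom, pos0, gene, var_class, coding, samples, profile, zygosity,
              aa_pool=None):
        ref, alt = _alleles(rng)
        row = {
            "chrom": chrom,
            "pos": pos0 + 1,  # manifest and all file formats are 1-based
            "ref": ref,
            "alt": alt,
            "var_class": var_class,
            "coding": coding,
            "gene": gene,
            "zygosity": zygosity,
            "samples": ";".join(samples),
            "gmaf": "",
            "sift": "",
            "polyphen": "",
            "aa_ref": "",
            "aa_alt": "",
        }
        if coding and profile is not None:
            if profile.gmaf is not None:
                row["gmaf"] = round(float(rng.uniform(*profile.gmaf)), 4)
            row["sift"] = round(float(rng.uniform(*profile.sift)), 3)
            row["polyphen"] = round(float(rng.uniform(*profile.polyphen)), 3)
            aa = aa_pool[int(rng.integers(0, len(aa_pool)))]
            row["aa_ref"], row["aa_alt"] = aa
        rows.append(row)

    all_samples = ["control1", "control2", "target1", "target2"]
    targets = ["target1", "target2"]

    def zyg_germline() -> str:
        return "hom_alt" if rng.random() < 0.3 else "het"

    def zyg_somatic() -> str:
        return "hom_alt" if rng.random() < 0.1 else "het"

    # shared germline
    n_coding_g = round(config.n_shared_germline * config.coding_fraction)
    n_noncod_g = config.n_shared_germline - n_coding_g
    n_genic_g = n_noncod_g // 2
    for chrom, p, gene in take_coding(n_coding_g):
        plant(chrom, p, gene, "germline_shared", True, all_samples,
              config.background_profile, zyg_germline(), _BACKGROUND_AA)
    for chrom, p, gene in take_noncoding(n_genic_g):
        plant(chrom, p, gene, "germline_shared", False, all_samples, None,
              zyg_germline())
    for chrom, p in _sample_intergenic(rng, spans, n_noncod_g - n_genic_g, used):
        plant(chrom, p, "", "germline_shared", False, all_samples, None,
              zyg_germline())

    # target-only somatic: drivers first, then background
    n_coding_t = round(config.n_target_only * config.coding_fraction)
    if n_coding_t < config.n_planted_drivers:
        raise UnsatisfiableConfig(
            "coding_fraction leaves fewer coding somatic slots than planted drivers"
        )
    for g in driver_genes:
        pool = [p for p in g["coding_pool"] if (g["chrom"], p) not in used]
        if not pool:
            raise UnsatisfiableConfig(f"driver gene {g['symbol']} has no free CDS position")
        p = pool[int(rng.integers(0, len(pool)))]
        used.add((g["chrom"], p))
        plant(g["chrom"], p, g["symbol"], "driver", True, targets,
              config.driver_profile, zyg_somatic(), _DRIVER_AA)
    for chrom, p, gene in take_coding(n_coding_t - config.n_planted_drivers):
        plant(chrom, p, gene, "somatic", True, targets,
              config.background_profile, zyg_somatic(), _BACKGROUND_AA)
    n_noncod_t = config.n_target_only - n_coding_t
    n_genic_t = n_noncod_t // 2
    for chrom, p, gene in take_noncoding(n_genic_t):
        plant(chrom, p, gene, "somatic", False, targets, None, zyg_somatic())
    for chrom, p in _sample_intergenic(rng, spans, n_noncod_t - n_genic_t, used):
        plant(chrom, p, "", "somatic", False, targets, None, zyg_somatic())

    # per-sample private noise (intergenic)
    for sample in all_samples:
        for chrom, p in _sample_intergenic(rng, spans, config.n_private_per_sample,
                                           used):
            plant(chrom, p, "", "private", False, [sample], None, "het")

    # MuTect REJECT decoys (never enter any VCF)
    for chrom, p in _sample_intergenic(rng, spans, config.n_reject_rows, used):
        plant(chrom, p, "", "rejected", False, targets, None, "het")

    manifest_df = pd.DataFrame(rows).sort_values(
        ["chrom", "pos", "alt"], kind="mergesort"
    ).reset_index(drop=True)

    # --- write outputs
    paths: dict[str, Path] = {}
    paths["genepred"] = outdir / "genes.genepred"
    _write_genepred(models, paths["genepred"])

    for sample in all_samples:
        paths[sample] = outdir / f"{sample}.vcf"
        _write_vcf(manifest_df, sample, config, paths[sample])
    paths["mutect"] = outdir / "mutect_calls.tsv"
    _write_mutect(manifest_df, rng, paths["mutect"])
    paths["vep"] = outdir / "vep_output.tsv"
    _write_vep({g["symbol"]: g for g in genes}, manifest_df, paths["vep"])

    refdir = outdir / "refs"
    _write_evidence(genes, driver_symbols, config, rng, refdir)
    paths["refdir"] = refdir

    paths["manifest"] = outdir / "manifest.tsv"
    manifest_df.to_csv(paths["manifest"], sep="\t", index=False)

    tx_rows = [
        {
            "transcript_id": m.transcript_id,
            "gene": m.gene_symbol,
            "chrom": m.chrom,
            "strand": m.strand,
            "tx_start": m.tx_start,
            "tx_end": m.tx_end,
            "cds_start": m.cds_start,
            "cds_end": m.cds_end,
            "n_exons": len(m.exon_starts),
        }
        for m in sorted(models, key=lambda m: (m.chrom, m.tx_start, m.transcript_id))
    ]
    tx_df = pd.DataFrame(tx_rows)
    paths["transcripts"] = outdir / "transcripts_manifest.tsv"
    tx_df.to_csv(paths["transcripts"], sep="\t", index=False)

    return Manifest(
        config=config,
        paths=paths,
        variants=manifest_df,
        transcripts=tx_df,
        driver_genes=driver_symbols,
    )


def _write_vcf(df: pd.DataFrame, sample: str, config: SimConfig, path: Path) -> None:
    mask = df["samples"].str.split(";").apply(lambda s: sample in s)
    sub = df[mask & ~df["var_class"].isin(["rejected"])]
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=evanno-synthdata(seed={config.seed})\n")
        for c in config.chroms:
            fh.write(f"##contig=<ID={c},length={config.genome_span}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for r in sub.itertuples(index=False):
            gt = "1/1" if r.zygosity == "hom_alt" else "0/1"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t99\tPASS\t.\tGT\t{gt}\n"
            )


def _write_mutect(df: pd.DataFrame, rng: np.random.Generator, path: Path) -> None:
    sub = df[df["var_class"].isin(["driver", "somatic", "rejected"])]
    with path.open("w") as fh:
        fh.write("## muTector call-stats (synthetic)\n")
        fh.write("contig\tposition\tref_allele\talt_allele\tjudgement\ttumor_f\t"
                 "t_ref_count\tt_alt_count\n")
        for r in sub.itertuples(index=False):
            judgement = "REJECT" if r.var_class == "rejected" else "KEEP"
            tumor_f = 0.95 if r.zygosity == "hom_alt" else round(
                float(rng.uniform(0.15, 0.6)), 3
            )
            depth = int(rng.integers(40, 120))
            alt_reads = max(1, int(round(depth * tumor_f)))
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{judgement}\t{tumor_f}\t"
                f"{depth - alt_reads}\t{alt_reads}\n"
            )


_VEP_HEADER = (
    "#Uploaded_variation\tLocation\tAllele\tGene\tFeature\tFeature_type\t"
    "Consequence\tcDNA_position\tCDS_position\tProtein_position\tAmino_acids\t"
    "Codons\tExisting_variation\tExtra"
)


def _write_vep(gene_map: dict[str, dict], df: pd.DataFrame, path: Path) -> None:
    """Effect-predictor tabular file covering exactly the coding variants.

    Written from planted ground truth (this tests the toolkit's parsing and
    joining, not the predictor itself).  When a gene has several transcripts
    the per-row SIFT/PolyPhen values are jittered so that the stated
    min/max aggregation is actually exercised: the manifest value is the
    minimum SIFT and maximum PolyPhen over rows.
    """
    coding = df[df["coding"] == True]  # noqa: E712
    with path.open("w") as fh:
        fh.write("## ENSEMBL VARIANT EFFECT PREDICTOR (synthetic tabular output)\n")
        fh.write(_VEP_HEADER + "\n")
        for r in coding.itertuples(index=False):
            gene = gene_map[r.gene]
            transcripts = [
                m for m in gene["models"]
                if any(
                    max(s, m.cds_start) <= r.pos - 1 < min(e, m.cds_end)
                    for s, e in zip(m.exon_starts, m.exon_ends)
                )
            ]
            sift = float(r.sift)
            polyphen = float(r.polyphen)
            for j, m in enumerate(transcripts):
                extra = []
                # first row carries the aggregate-defining values
                row_sift = sift if j == 0 else min(round(sift + 0.02 * j, 3), 1.0)
                row_poly = polyphen if j == 0 else max(round(polyphen - 0.02 * j, 3), 0.0)
                extra.append(f"SIFT=deleterious({row_sift})"
                             if row_sift <= 0.05 else f"SIFT=tolerated({row_sift})")
                extra.append(f"PolyPhen=probably_damaging({row_poly})"
                             if row_poly >= 0.85 else f"PolyPhen=benign({row_poly})")
                if r.gmaf != "":
                    extra.append(f"GMAF={r.alt}:{r.gmaf}")
                extra.append(f"SYMBOL={r.gene}")
                existing = f"rs{r.pos}" if r.gmaf != "" else "-"
                fh.write(
                    "\t".join(
                        [
                            f"{r.chrom}_{r.pos}_{r.ref}/{r.alt}",
                            f"{r.chrom}:{r.pos}",
                            r.alt,
                            r.gene,
                            m.transcript_id,
                            "Transcript",
                            "missense_variant",
                            "-", "-", "-",
                            f"{r.aa_ref}/{r.aa_alt}",
                            "-",
                            existing,
                            ";".join(extra),
                        ]
                    )
                    + "\n"
                )


def _write_evidence(
    genes: list[dict],
    driver_symbols: list[str],
    config: SimConfig,
    rng: np.random.Generator,
    refdir: Path,
) -> None:
    refdir.mkdir(parents=True, exist_ok=True)
    symbols = [g["symbol"] for g in genes]
    is_driver = {s: s in driver_symbols for s in symbols}

    lit_rows, cosmic_rows, disease_rows, process_rows = [], [], [], []
    census, pairs, expr_rows = [], [], []
    census_anchor = driver_symbols[0] if driver_symbols else None
    for i, s in enumerate(symbols):
        plen = int(rng.integers(300, 1000))
        if is_driver[s]:
            lit_rows.append((s, config.mesh_term, 99))
            cosmic_rows.append((s, plen, plen))  # one entry per residue: saturated
            d_idx = driver_symbols.index(s)
            disease_rows.append((s, _DRIVER_DISEASES[d_idx % len(_DRIVER_DISEASES)]))
            process_rows.append((s, _DRIVER_PROCESSES[d_idx % len(_DRIVER_PROCESSES)]))
            process_rows.append((s, "Cell proliferation"))
            if d_idx % 2 == 0:
                census.append(s)
            elif census_anchor is not None:
                pairs.append((s, census_anchor))
        else:
            lit_rows.append((s, config.mesh_term, int(rng.integers(0, 10))))
            cosmic_rows.append((s, max(1, plen // 20), plen))
            disease_rows.append(
                (s, _BACKGROUND_DISEASES[i % len(_BACKGROUND_DISEASES)])
            )
            process_rows.append(
                (s, _BACKGROUND_PROCESSES[i % len(_BACKGROUND_PROCESSES)])
            )
        # a non-census, non-driver interaction pair for symmetry coverage
        if not is_driver[s] and i % 5 == 0 and i + 1 < len(symbols):
            pairs.append((s, symbols[i + 1]))
        # most genes get an expression row; every 7th background gene does not
        if is_driver[s]:
            vals = [round(float(rng.uniform(6.0, 12.0)), 3) for _ in range(2)] + [
                round(float(rng.uniform(0.3, 1.5)), 3)
                for _ in range(len(config.tissues) - 2)
            ]
            expr_rows.append([s] + vals)
        elif i % 7 != 3:
            expr_rows.append(
                [s] + [round(float(rng.uniform(0.5, 2.0)), 3)
                       for _ in range(len(config.tissues))]
            )

    pd.DataFrame(lit_rows, columns=["gene", "mesh_term", "count"]).to_csv(
        refdir / "literature.tsv", sep="\t", index=False
    )
    pd.DataFrame(cosmic_rows, columns=["gene", "entries", "protein_length"]).to_csv(
        refdir / "cosmic.tsv", sep="\t", index=False
    )
    pd.DataFrame(disease_rows, columns=["gene", "disease_name"]).to_csv(
        refdir / "disease.tsv", sep="\t", index=False
    )
    pd.DataFrame(process_rows, columns=["gene", "term"]).to_csv(
        refdir / "process.tsv", sep="\t", index=False
    )
    pd.DataFrame([(s,) for s in census], columns=["gene"]).to_csv(
        refdir / "census.tsv", sep="\t", index=False
    )
    pd.DataFrame(pairs, columns=["geneA", "geneB"]).to_csv(
        refdir / "interactions.tsv", sep="\t", index=False
    )
    pd.DataFrame(expr_rows, columns=["gene", *config.tissues]).to_csv(
        refdir / "expression.tsv", sep="\t", index=False
    )


# --------------------------------------------------------------------------
# worked example

WORKED_EXAMPLE_CONFIG = SimConfig(
    seed=2015,
    n_genes=10,
    n_transcripts_per_gene=(1, 2),
    chroms=("chr1", "chr2"),
    genome_span=120_000,
    n_shared_germline=6,
    n_target_only=20,
    coding_fraction=1.0,
    n_planted_drivers=3,
    n_private_per_sample=2,
    n_reject_rows=1,
)


def generate_worked_example(outdir: str | Path) -> Manifest:
    """Fixed miniature scenario: 20 somatic coding SNVs, 3 planted drivers.

    Ships the hematological focus configuration (leukemia MeSH term plus
    the disease and function focus phrase lists) as ``focus.cfg`` next to
    the data.  An end-to-end run over the MuTect calls must rank the three
    drivers 1-3.
    """
    manifest = generate_universe(WORKED_EXAMPLE_CONFIG, outdir)
    focus_path = Path(outdir) / "focus.cfg"
    with focus_path.open("w") as fh:
        fh.write(f"mesh_term={WORKED_EXAMPLE_CONFIG.mesh_term}\n")
        fh.write("disease_focus=" + ",".join(DISEASE_FOCUS) + "\n")
        fh.write("function_focus=" + ",".join(FUNCTION_FOCUS) + "\n")
    manifest.paths["focus"] = focus_path
    return manifest


# --------------------------------------------------------------------------
# light-weight corpora for oracle testing (no files written)


def random_mapping_corpus(
    seed: int, n_variants: int, n_transcripts: int
):
    """Random transcripts (possibly overlapping) and variants for oracle tests.

    Unlike :func:`generate_universe`, transcript spans here may overlap
    arbitrarily and variants are placed uniformly plus deliberately at every
    interval boundary (start, end-1, end — the off-by-one hot spots).
    Returns (models, variants).
    """
    from evanno.variant_io import Variant

    rng = np.random.default_rng(seed)
    chroms = ["chr1", "chr2"]
    span = 100_000
    models = []
    for i in range(n_transcripts):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span - 6000))
        length = int(rng.integers(200, 6000))
        n_ex = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex - 2,
                                  replace=False)) if n_ex > 1 else np.array([], int)
        bounds = [0, *cuts.tolist(), length]
        exon_starts = tuple(start + bounds[2 * j] for j in range(n_ex))
        exon_ends = tuple(start + bounds[2 * j + 1] for j in range(n_ex))
        cds_lo = int(rng.integers(0, length // 2))
        cds_hi = int(rng.integers(length // 2, length + 1))
        models.append(
            TranscriptModel(
                gene_symbol=f"G{int(rng.integers(0, max(2, n_transcripts // 2))):04d}",
                transcript_id=f"T{i:05d}",
                chrom=chrom,
                strand="+",
                tx_start=start,
                tx_end=start + length,
                cds_start=start + cds_lo,
                cds_end=start + cds_hi,
                exon_starts=exon_starts,
                exon_ends=exon_ends,
            )
        )
    positions: list[tuple[str, int]] = []
    for m in models:  # every boundary is a test point
        for p in (m.tx_start, m.tx_end - 1, m.tx_end, m.cds_start, m.cds_end - 1,
                  m.cds_end):
            if p >= 0:
                positions.append((m.chrom, p))
        for s, e in zip(m.exon_starts, m.exon_ends):
            positions.extend([(m.chrom, s), (m.chrom, e - 1), (m.chrom, e)])
    while len(positions) < n_variants:
        positions.append(
            (chroms[int(rng.integers(0, len(chroms)))], int(rng.integers(0, span)))
        )
    positions = positions[:max(n_variants, len(positions))]
    variants = []
    seen = set()
    for chrom, p in positions:
        ref, alt = _alleles(rng)
        if (chrom, p + 1, ref, alt) in seen:
            continue
        seen.add((chrom, p + 1, ref, alt))
        variants.append(
            Variant(chrom=chrom, pos=p + 1, ref=ref, alt=alt, sample_id="oracle")
        )
    return models, variants
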