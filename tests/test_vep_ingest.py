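"""Effect-predictor output parsing, polarity classification and the join."""

import itertools
import random

import pytest

from evanno.annotate import AnnotatedVariant
from evanno.refdata import FocusConfig, GeneEvidence
from evanno.variant_io import Variant
from evanno.vep_ingest import (
    CHARGED,
    NONPOLAR,
    POLAR_UNCHARGED,
    VepFormatError,
    classify_polarity,
    enrich,
    parse_vep,
)

HEADER = (
    "#Uploaded_variation\tLocation\tAllele\tGene\tFeature\tFeature_type\t"
    "Consequence\tcDNA_position\tCDS_position\tProtein_position\tAmino_acids\t"
    "Codons\tExisting_variation\tExtra\n"
)


def _row(chrom="chr1", pos=100, ref="A", alt="G", gene="GENEA", feature="NM_1",
         consequence="missense_variant", aa="R/W", existing="-", extra=""):
    return (
        f"{chrom}_{pos}_{ref}/{alt}\t{chrom}:{pos}\t{alt}\t{gene}\t{feature}\t"
        f"Transcript\t{consequence}\t-\t-\t-\t{aa}\t-\t{existing}\t{extra or '-'}\n"
    )


def _vep(tmp_path, *rows):
    p = tmp_path / "vep.tsv"
    p.write_text("## predictor output\n" + HEADER + "".join(rows))
    return p


class TestParseVep:
    def test_extra_fields_parsed(self, tmp_path):
        p = _vep(tmp_path, _row(extra="SIFT=0.03;PolyPhen=0.92;GMAF=0.0041"))
        (a,) = parse_vep(p)
        assert a.key == ("chr1", 100, "A", "G")
        assert (a.sift, a.polyphen, a.gmaf) == (0.03, 0.92, 0.0041)
        assert a.aa_change == ("R", "W")

    def test_prediction_wrapped_and_allele_prefixed_values(self, tmp_path):
        p = _vep(
            tmp_path,
            _row(extra="SIFT=deleterious(0.01);PolyPhen=probably_damaging(0.97);"
                       "GMAF=G:0.2"),
        )
        (a,) = parse_vep(p)
        assert (a.sift, a.polyphen, a.gmaf) == (0.01, 0.97, 0.2)

    def test_transcript_aggregation_min_sift_max_polyphen(self, tmp_path):
        p = _vep(
            tmp_path,
            _row(feature="NM_1", consequence="missense_variant",
                 extra="SIFT=0.03;PolyPhen=0.50"),
            _row(feature="NM_2", consequence="splice_region_variant",
                 extra="SIFT=0.20;PolyPhen=0.92"),
        )
        (a,) = parse_vep(p)
        assert (a.sift, a.polyphen) == (0.03, 0.92)
        assert a.consequences == ["missense_variant", "splice_region_variant"]

    def test_aggregation_permutation_invariant(self, tmp_path, universe):
        lines = universe.paths["vep"].read_text().splitlines(keepends=True)
        head = [l for l in lines if l.startswith("#")]
        data = [l for l in lines if not l.startswith("#")]
        random.Random(5).shuffle(data)
        shuffled = tmp_path / "shuffled.tsv"
        shuffled.write_text("".join(head + data))

        def norm(anns):
            return sorted(
                (a.key, a.gene_symbol, a.sift, a.polyphen, a.gmaf,
                 tuple(a.consequences), a.aa_change)
                for a in anns
            )

        assert norm(parse_vep(universe.paths["vep"])) == norm(parse_vep(shuffled))

    def test_symbol_from_extra_preferred(self, tmp_path):
        p = _vep(tmp_path, _row(gene="ENSG0001", extra="SYMBOL=GENEB"))
        assert parse_vep(p)[0].gene_symbol == "GENEB"

    def test_missing_header_is_format_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(_row())
        with pytest.raises(VepFormatError):
            parse_vep(p)

    def test_unparseable_extra_pair_skipped_with_warning(self, tmp_path, caplog):
        p = _vep(tmp_path, _row(extra="SIFT=0.03;garbage"))
        with caplog.at_level("WARNING", logger="evanno"):
            (a,) = parse_vep(p)
        assert a.sift == 0.03
        assert "garbage" in caplog.text


class TestClassifyPolarity:
    @pytest.mark.parametrize("pair,expected", [
        (("R", "W"), "loss"),   # charged -> nonpolar
        (("L", "L"), "none"),
        (("S", "K"), "swap"),   # polar -> charged
        (("G", "E"), "gain"),   # nonpolar -> charged
        (("A", "S"), "gain"),   # nonpolar -> polar
        (("K", "R"), "none"),
        (None, None),
    ])
    def test_examples(self, pair, expected):
        assert classify_polarity(pair) == expected

    def test_total_over_standard_amino_acids(self):
        aas = sorted(NONPOLAR | POLAR_UNCHARGED | CHARGED)
        assert len(aas) == 20
        for a, b in itertools.product(aas, repeat=2):
            assert classify_polarity((a, b)) in {"none", "gain", "loss", "swap"}

    def test_unknown_letter_unclassified(self, caplog):
        with caplog.at_level("WARNING", logger="evanno"):
            assert classify_polarity(("R", "X")) is None


def _ann_variant(chrom="chr1", pos=100, ref="A", alt="G", zygosity="het"):
    return AnnotatedVariant(
        variant=Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id="s",
                        zygosity=zygosity),
        genes=["GENEA"], coding=True,
    )


class TestEnrich:
    def test_join_carries_zygosity_and_evidence(self, tmp_path):
        anns = parse_vep(_vep(tmp_path, _row(extra="SIFT=0.03")))
        ev = {"GENEA": GeneEvidence(gene_symbol="GENEA", pubmed_count=5)}
        res = enrich(anns, [_ann_variant(zygosity="hom_alt")], ev, FocusConfig())
        (e,) = res.records
        assert e.variant.zygosity == "hom_alt"
        assert e.evidence.pubmed_count == 5
        assert e.polarity_change == "loss"

    def test_unknown_gene_gets_default_evidence(self, tmp_path):
        anns = parse_vep(_vep(tmp_path, _row(gene="GENEZ", extra="-")))
        res = enrich(anns, [_ann_variant()], {}, FocusConfig())
        (e,) = res.records
        assert e.evidence.gene_symbol == "GENEZ"
        assert e.evidence.pubmed_count == 0 and not e.evidence.is_census

    def test_reconciliation_counts_sum(self, tmp_path):
        anns = parse_vep(_vep(
            tmp_path,
            _row(pos=100),
            _row(pos=999, ref="C", alt="T"),  # no matching variant
        ))
        variants = [_ann_variant(pos=100), _ann_variant(pos=555)]
        res = enrich(anns, variants, {}, FocusConfig())
        assert res.n_joined == 1
        assert res.n_joined + res.n_unmatched_annotations == len(anns)
        assert res.n_joined_keys + res.n_unmatched_variants == len(variants)

    def test_zero_joins_suggests_chrom_normalization(self, tmp_path):
        anns = parse_vep(_vep(tmp_path, _row(chrom="1")))
        with pytest.raises(ValueError, match="chromosome naming"):
            enrich(anns, [_ann_variant(chrom="chr1")], {}, FocusConfig())

    def test_generator_planted_join_count(self, worked):
        from evanno.annotate import find_coding, map_variants
        from evanno.refdata import load_evidence_tables, load_gene_models
        from evanno.variant_io import read_mutect

        models = load_gene_models(worked.paths["genepred"])
        coding = find_coding(
            map_variants(read_mutect(worked.paths["mutect"]), models), models
        )
        anns = parse_vep(worked.paths["vep"])
        ev = load_evidence_tables(worked.paths["refdir"], "leukemia")
        res = enrich(anns, coding, ev, FocusConfig(mesh_term="leukemia"))
        # exactly the somatic coding variants join; germline coding rows in the
        # predictor file stay on the unmatched side of the reconciliation
        assert res.n_joined == len(coding)
        assert {e.key for e in res} == {av.key for av in coding}
        assert len(res) <= min(len(anns), len(coding) + res.n_unmatched_variants)
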