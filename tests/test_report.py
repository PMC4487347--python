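"""Result-table filtering laws, heatmap normalization and report rendering."""

import random

import pytest

from evanno.refdata import FocusConfig, GeneEvidence
from evanno.report import (
    FilterThresholds,
    heatmap_matrix,
    render_report,
    result_table,
)
from evanno.scoring import rank_variants, score_variant
from helpers import make_enriched

FOCUS = FocusConfig(
    mesh_term="leukemia",
    disease_focus=["Leukemia", "Lymphoma"],
    function_focus=["Apoptosis", "SignalTransduction"],
)


def scored_one(**kw):
    return rank_variants([score_variant(make_enriched(**kw), FOCUS)])


def random_scored(seed, n=120):
    """Scored variants spanning the filter space (damaging/benign, rare/common,
    census mixtures)."""
    rng = random.Random(seed)
    out = []
    for i in range(n):
        e = make_enriched(
            chrom=f"chr{rng.randint(1, 3)}",
            pos=1 + i * 10 + rng.randint(0, 5),
            gene=f"G{i:03d}",
            sift=rng.choice([None, round(rng.random(), 3)]),
            polyphen=rng.choice([None, round(rng.random(), 3)]),
            gmaf=rng.choice([None, round(rng.uniform(0, 0.5), 4)]),
            pubmed=rng.randint(0, 200),
            cosmic=rng.randint(0, 800),
            plen=rng.randint(100, 900),
            diseases=rng.choice([[], ["Chronic leukemia"], ["Cardiomyopathy"]]),
            terms=rng.choice([[], ["Apoptosis"], ["Ion transport"]]),
        )
        e.evidence.is_census = rng.random() < 0.3
        e.evidence.interacts_census = rng.random() < 0.3 or e.evidence.is_census
        out.append(score_variant(e, FOCUS))
    return rank_variants(out)


class TestResultTable:
    def test_damaging_rare_focus_variant_retained_under_defaults(self):
        scored = scored_one(sift=0.02, polyphen=0.99, gmaf=None,
                            terms=["Apoptosis"])
        assert result_table(scored, FOCUS) == scored

    def test_present_sift_above_threshold_excluded(self):
        scored = scored_one(sift=0.20, polyphen=0.99, gmaf=None,
                            terms=["Apoptosis"])
        assert result_table(scored, FOCUS) == []
        # but acceptable under the disjunctive damage mode
        assert result_table(scored, FOCUS, damage_mode="any") == scored

    def test_no_predictor_present_fails_damage(self):
        scored = scored_one(terms=["Apoptosis"])
        assert result_table(scored, FOCUS) == []

    def test_empty_function_focus_keeps_damage_predicate_only(self):
        focus = FocusConfig()  # inert focus lists
        scored = random_scored(2)
        kept = result_table(scored, focus)
        expected = [
            sv for sv in scored
            if (sv.enriched.annotation.sift is not None
                or sv.enriched.annotation.polyphen is not None)
            and (sv.enriched.annotation.sift is None
                 or sv.enriched.annotation.sift <= 0.05)
            and (sv.enriched.annotation.polyphen is None
                 or sv.enriched.annotation.polyphen >= 0.85)
        ]
        assert kept == expected

    def test_gmaf_sentinel_is_noop(self):
        scored = random_scored(3)
        loose = FilterThresholds(sift=1.0, polyphen=0.0)
        with_sentinel = result_table(scored, FOCUS, loose)
        # a gmaf threshold of 1 can never exclude a real frequency (<= 0.5)
        assert all(
            sv.enriched.annotation.gmaf is None
            or sv.enriched.annotation.gmaf <= 0.5
            for sv in scored
        )
        assert with_sentinel == result_table(
            scored, FOCUS, FilterThresholds(sift=1.0, polyphen=0.0, gmaf=0.5)
        )

    def test_rank_order_preserved(self):
        scored = random_scored(4)
        kept = result_table(scored, FOCUS, FilterThresholds(sift=1.0, polyphen=0.0))
        assert [sv.rank for sv in kept] == sorted(sv.rank for sv in kept)

    @pytest.mark.parametrize("seed", range(5))
    def test_strictness_monotone_subset(self, seed):
        rng = random.Random(seed + 100)
        scored = random_scored(seed)

        def rand_thresholds():
            return FilterThresholds(
                sift=round(rng.uniform(0, 1), 2),
                polyphen=round(rng.uniform(0, 1), 2),
                gmaf=round(rng.uniform(0.01, 1), 2),
                pubmed=rng.randint(0, 50),
                cosmic=rng.randint(0, 300),
                disassociation=rng.randint(0, 2),
                census=0,
            )

        t1 = rand_thresholds()
        # t2 at least as strict in every constraint
        t2 = FilterThresholds(
            sift=t1.sift * rng.uniform(0, 1),
            polyphen=min(1.0, t1.polyphen + rng.uniform(0, 1 - t1.polyphen)),
            gmaf=max(0.01, t1.gmaf * rng.uniform(0.1, 1)),
            pubmed=t1.pubmed + rng.randint(0, 20),
            cosmic=t1.cosmic + rng.randint(0, 100),
            disassociation=t1.disassociation + rng.randint(0, 1),
            census=rng.choice([0, 3]) if rng.random() < 0.5 else 0,
        )
        keys = lambda t: {sv.key for sv in result_table(scored, FOCUS, t)}
        assert keys(t2) <= keys(t1)

    @pytest.mark.parametrize("seed", range(4))
    def test_census_modes_partition(self, seed):
        scored = random_scored(seed + 50)
        loose = dict(sift=1.0, polyphen=0.0)
        out = {
            mode: {sv.key for sv in result_table(
                scored, FOCUS, FilterThresholds(census=mode, **loose))}
            for mode in (0, 1, 2, 3)
        }
        assert out[1] | out[2] == out[3]
        assert out[1] & out[2] == set()
        assert out[3] <= out[0]


class TestHeatmapMatrix:
    def _evidence(self, profiles):
        return {
            g: GeneEvidence(gene_symbol=g, expression=p) for g, p in profiles.items()
        }

    def test_rows_normalized_to_mean_one(self):
        scored = scored_one(sift=0.01, gene="GENEA")
        ev = self._evidence({"GENEA": {"t1": 2.0, "t2": 4.0, "t3": 6.0}})
        m, nf = heatmap_matrix(scored, ev)
        assert m.loc["GENEA"].tolist() == [0.5, 1.0, 1.5]
        assert nf == []

    def test_uniform_row_is_identity(self):
        scored = scored_one(gene="GENEA")
        ev = self._evidence({"GENEA": {"t1": 5.0, "t2": 5.0}})
        m, _ = heatmap_matrix(scored, ev)
        assert m.loc["GENEA"].tolist() == [1.0, 1.0]

    def test_missing_profile_listed_not_zero_filled(self):
        scored = scored_one(gene="GENEA")
        m, nf = heatmap_matrix(scored, {})
        assert m.empty and nf == ["GENEA"]

    def test_all_zero_row_excluded_with_warning(self, caplog):
        scored = scored_one(gene="GENEA")
        ev = self._evidence({"GENEA": {"t1": 0.0, "t2": 0.0}})
        with caplog.at_level("WARNING", logger="evanno"):
            m, nf = heatmap_matrix(scored, ev)
        assert m.empty and nf == ["GENEA"]

    def test_universe_rows_have_mean_one_and_rank_order(self, universe,
                                                       universe_evidence):
        scored = random_scored(9)
        m, nf = heatmap_matrix(scored, universe_evidence)
        # synthetic genes here are absent from the universe's evidence map
        assert m.empty and len(nf) > 0


class TestRenderReport:
    def test_empty_table_valid_report(self, tmp_path):
        import pandas as pd

        paths = render_report([], pd.DataFrame(), tmp_path)
        assert paths["tsv"].read_text().count("\n") == 1  # header only
        assert "<html>" in paths["html"].read_text()

    def test_schema_and_determinism(self, tmp_path):
        from evanno.scoring import SCORE_COLUMNS

        scored = random_scored(7)[:10]
        ev = {sv.gene_symbol: GeneEvidence(
            gene_symbol=sv.gene_symbol,
            expression={"t1": 1.0, "t2": 3.0}) for sv in scored}
        m, nf = heatmap_matrix(scored, ev)
        assert all(abs(m.loc[g].mean() - 1.0) < 1e-9 for g in m.index)
        p1 = render_report(scored, m, tmp_path / "a", not_found=nf)
        p2 = render_report(scored, m, tmp_path / "b", not_found=nf)
        text = p1["tsv"].read_text()
        lines = text.strip().split("\n")
        assert lines[0].split("\t") == SCORE_COLUMNS
        assert len(lines) == 11
        assert text == p2["tsv"].read_text()
        assert p1["html"].read_text() == p2["html"].read_text()


class TestFilterThresholds:
    def test_validation(self):
        with pytest.raises(ValueError):
            FilterThresholds(sift=1.5)
        with pytest.raises(ValueError):
            FilterThresholds(gmaf=0.0)
        with pytest.raises(ValueError):
            FilterThresholds(census=4)
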