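import random
import warnings

import pytest
from hypothesis import given, settings, strategies as st

from glycofunnel.datasets import id_dd_variant_sites, load_id_dd_variant_table
from glycofunnel.model import GlycoFunnelError, GlycoSite, PipelineConfig
from glycofunnel.variants import (
    VariantRecord,
    classify_polyphen,
    intersect_sites,
    load_variant_table,
    load_variant_vcf,
    normalize_significance,
    parse_hgvs_p,
    screen,
    triage_hit,
)


class TestHgvsParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("S172P", ("S", 172, "P")),
            ("p.Thr556Met", ("T", 556, "M")),
            ("p.Ser802Phe", ("S", 802, "F")),
            ("Ser190Asn", ("S", 190, "N")),
            ("p.(Ser1858Ile)", ("S", 1858, "I")),
        ],
    )
    def test_accepted_forms(self, text, expected):
        assert parse_hgvs_p(text) == expected

    @pytest.mark.parametrize("text", ["p.Ser190Ter", "S190*"])
    def test_stop_gain_rejected_as_not_missense(self, text):
        with pytest.raises(GlycoFunnelError) as err:
            parse_hgvs_p(text)
        assert err.value.code == "not_missense"

    def test_synonymous_rejected(self):
        with pytest.raises(GlycoFunnelError) as err:
            parse_hgvs_p("p.Ser172Ser")
        assert err.value.code == "not_missense"

    @pytest.mark.parametrize("text", ["garbage", "p.172S", "p.Xyz172Pro"])
    def test_unparseable_input(self, text):
        with pytest.raises(GlycoFunnelError) as err:
            parse_hgvs_p(text)
        assert err.value.code == "parse_error"


class TestPolyphenBands:
    @pytest.mark.parametrize(
        "score,band",
        [
            (0.921, "probably_damaging"),
            (0.855, "probably_damaging"),  # strictly above the 0.85 cut-off
            (0.85, "possibly_damaging"),   # boundary itself is not damaging
            (0.50, "possibly_damaging"),
            (0.15, "possibly_damaging"),
            (0.10, "likely_benign"),
            (None, "unscored"),
        ],
    )
    def test_band_assignment(self, score, band):
        assert classify_polyphen(score) == band

    def test_score_outside_unit_interval_rejected(self):
        with pytest.raises(GlycoFunnelError):
            classify_polyphen(1.2)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_bands_partition_the_unit_interval(self, score):
        band = classify_polyphen(score)
        assert band in ("probably_damaging", "possibly_damaging", "likely_benign")
        # exactly one band matches the defining inequalities
        cfg = PipelineConfig()
        checks = [
            score > cfg.polyphen_damaging_cutoff,
            cfg.polyphen_benign_cutoff <= score <= cfg.polyphen_damaging_cutoff,
            score < cfg.polyphen_benign_cutoff,
        ]
        assert sum(checks) == 1


class TestTriage:
    @pytest.mark.parametrize(
        "significance,band,expected",
        [
            ("pathogenic", "unscored", "retained_pathogenic"),
            ("likely_pathogenic", "unscored", "retained_pathogenic"),
            ("uncertain", "probably_damaging", "retained_predicted"),
            ("uncertain", "possibly_damaging", "excluded"),
            ("uncertain", "likely_benign", "excluded"),
            ("benign", "probably_damaging", "excluded"),
            ("likely_benign", "unscored", "excluded"),
        ],
    )
    def test_rule_composition(self, significance, band, expected):
        assert triage_hit(significance, band) == expected


class TestSignificanceNormalization:
    @pytest.mark.parametrize(
        "raw,token",
        [
            ("Pathogenic", "pathogenic"),
            ("Likely pathogenic", "likely_pathogenic"),
            ("Pathogenic/Likely pathogenic", "pathogenic"),
            ("Uncertain significance", "uncertain"),
            ("Likely benign", "likely_benign"),
            ("Benign/Likely benign", "benign"),
            ("Conflicting interpretations of pathogenicity", "other"),
            ("drug response", "other"),
        ],
    )
    def test_tokens(self, raw, token):
        assert normalize_significance(raw) == token


def random_cohort(rng, n_proteins=4, n_variants=30, n_sites=12):
    proteins = [f"P{i}" for i in range(n_proteins)]
    sites = [
        GlycoSite(rng.choice(proteins), rng.randint(1, 80), "S")
        for _ in range(n_sites)
    ]
    # deduplicate keys to satisfy pooling invariants
    seen, unique_sites = set(), []
    for s in sites:
        if s.key not in seen:
            seen.add(s.key)
            unique_sites.append(s)
    variants = [
        VariantRecord(
            gene_symbol="G",
            protein_accession=rng.choice(proteins),
            ref_aa="S",
            position=rng.randint(1, 80),
            alt_aa="A",
            clinical_significance=rng.choice(
                ["pathogenic", "uncertain", "benign"]
            ),
            polyphen_humvar=rng.choice([None, round(rng.random(), 3)]),
        )
        for _ in range(n_variants)
    ]
    return variants, unique_sites


class TestIntersection:
    def test_window_boundaries_inclusive(self):
        site = GlycoSite("P1", 100, "S")
        make = lambda pos: VariantRecord("G", "P1", "S", pos, "A", "pathogenic")
        assert intersect_sites([make(100)], [site])[0].relation == "exact"
        hit5 = intersect_sites([make(105)], [site])
        assert hit5[0].relation == "proximal" and hit5[0].distance == 5
        assert intersect_sites([make(106)], [site]) == []
        assert intersect_sites([make(95)], [site])[0].distance == 5

    def test_variant_can_hit_multiple_sites(self):
        sites = [GlycoSite("P1", 100, "S"), GlycoSite("P1", 103, "T")]
        v = VariantRecord("G", "P1", "S", 101, "A", "pathogenic")
        hits = intersect_sites([v], sites)
        assert len(hits) == 2
        assert sorted(h.distance for h in hits) == [1, 2]

    def test_matches_exhaustive_pairwise_scan(self):
        rng = random.Random(17)
        for _ in range(200):
            variants, sites = random_cohort(rng)
            window = rng.choice([0, 2, 5, 8])
            got = {
                (id(h.variant), h.site.key, h.relation, h.distance)
                for h in intersect_sites(variants, sites, window=window)
            }
            expected = set()
            for v in variants:
                for s in sites:
                    if v.protein_accession != s.protein_accession:
                        continue
                    d = abs(v.position - s.position)
                    if d <= window:
                        expected.add(
                            (id(v), s.key, "exact" if d == 0 else "proximal", d)
                        )
            assert got == expected

    def test_window_growth_is_monotone(self):
        rng = random.Random(23)
        variants, sites = random_cohort(rng)
        previous = set()
        for window in range(0, 8):
            hits = {
                (id(h.variant), h.site.key)
                for h in intersect_sites(variants, sites, window=window)
            }
            assert previous <= hits
            if window == 0:
                assert all(
                    h.relation == "exact"
                    for h in intersect_sites(variants, sites, window=0)
                )
            previous = hits


class TestPublishedVariantTable:
    def test_eight_variants_load_with_six_scores(self):
        variants = load_id_dd_variant_table()
        assert len(variants) == 8
        scored = [v.polyphen_humvar for v in variants if v.polyphen_humvar is not None]
        assert sorted(scored) == [0.855, 0.921, 0.959, 0.989, 0.993, 0.995]
        assert all(v.is_id_dd for v in variants)

    def test_screen_retains_all_eight_as_exact_hits(self):
        variants = load_id_dd_variant_table()
        sites = id_dd_variant_sites()
        result = screen(variants, sites)
        assert result.summary["n_exact"] == 8
        assert result.summary["n_proximal"] == 0
        assert result.summary["n_retained"] == 8
        assert result.summary["n_retained_pathogenic"] == 2  # the two TUBB2B alleles
        assert result.summary["n_retained_predicted"] == 6


class TestBundleScreen:
    def test_vcf_and_tsv_loaders_agree(self, bundle, tmp_path):
        paths = bundle.write(tmp_path / "b")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            amap = {r.gene_symbol: r.accession for r in bundle.proteome.values()}
            from_vcf = load_variant_vcf(paths["variants_vcf"], accession_map=amap)
            from_tsv = load_variant_table(paths["variants"])
        assert len(from_vcf) == len(from_tsv) == len(bundle.variants)
        for a, b in zip(from_vcf, from_tsv):
            assert (a.protein_accession, a.label, a.clinical_significance) == (
                b.protein_accession, b.label, b.clinical_significance
            )
            if a.polyphen_humvar is None:
                assert b.polyphen_humvar is None
            else:
                assert a.polyphen_humvar == pytest.approx(b.polyphen_humvar, abs=1e-5)

    def test_planted_triage_recovered_exactly(self, bundle, pipeline_result):
        variants = [
            VariantRecord(
                v.gene_symbol, v.protein_accession, v.hgvs_p[0], v.position,
                v.hgvs_p[-1], v.significance, v.polyphen_humvar, v.condition,
            )
            for v in bundle.variants
        ]
        result = screen(variants, pipeline_result.sites_by_stage["qc"])
        retained = {
            (h.variant.protein_accession, h.variant.label)
            for h in result.hits
            if h.triage != "excluded"
        }
        expected = {tuple(x) for x in bundle.manifest["expected_retained_variants"]}
        assert retained == expected  # precision = recall = 1.0

    def test_planted_distant_variants_never_hit(self, bundle, pipeline_result):
        distant = [v for v in bundle.variants if v.relation == "distant"]
        variants = [
            VariantRecord(
                v.gene_symbol, v.protein_accession, v.hgvs_p[0], v.position,
                v.hgvs_p[-1], v.significance, v.polyphen_humvar, v.condition,
            )
            for v in distant
        ]
        assert intersect_sites(variants, pipeline_result.sites_by_stage["qc"]) == []

    def test_empty_variant_table_gives_zero_counts(self):
        result = screen([], [GlycoSite("P1", 5, "S")])
        assert result.summary["n_hits"] == 0
        assert result.hit_table.empty
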