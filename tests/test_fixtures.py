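"""Synthetic-generator determinism, self-consistency, and external validity."""

import pytest

from varledger import VariantKey, VariantStore, ingest_annotation, ingest_vcf, search_changes
from varledger.fixtures import (
    SCENARIO_KEY,
    annotation_dialect,
    build_reclassification_scenario,
    ddm_dialect,
    generate_annotation_file,
    generate_ddm_vcf,
    generate_tss_vcf,
    manifest_keys,
)
from varledger.query import ChangeQuery


class TestTssGenerator:
    def test_nonref_count_exact_and_filter_truth(self, tmp_path):
        manifest = generate_tss_vcf(str(tmp_path / "t.vcf"), 100, 9, seed=3)
        gts = [r["gt"] for r in manifest["records"]]
        assert gts.count("0/0") == 91
        assert sum(1 for g in gts if g in ("0/1", "1/1")) == 9
        for r in manifest["records"]:
            if r["gt"] == "0/0":
                assert r["af"] == 0.0
            else:
                assert 0 < r["af"] <= 100
        assert len(manifest["truth_nonref_keys"]) == 9

    def test_zero_nonref_loads_nothing(self, tmp_path, store, tss_spec):
        generate_tss_vcf(str(tmp_path / "t.vcf"), 10, 0, seed=1)
        report = ingest_vcf(store, str(tmp_path / "t.vcf"), tss_spec, sample_id="S1")
        assert report.rows_loaded == 0
        assert store.unique_variant_count() == 0

    def test_byte_identical_on_same_seed(self, tmp_path):
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        generate_tss_vcf(str(a), 50, 5, seed=9)
        generate_tss_vcf(str(b), 50, 5, seed=9)
        assert a.read_bytes() == b.read_bytes()
        generate_tss_vcf(str(b), 50, 5, seed=10)
        assert a.read_bytes() != b.read_bytes()

    def test_invalid_nonref_count_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_tss_vcf(str(tmp_path / "t.vcf"), 5, 6, seed=1)

    def test_parses_as_valid_vcf_under_pysam(self, tmp_path):
        """Independent oracle: the emulated file is real VCF, with the
        expected FORMAT subfields and genotype mix."""
        pysam = pytest.importorskip("pysam")
        path = str(tmp_path / "t.vcf")
        manifest = generate_tss_vcf(path, 40, 4, seed=5)
        with pysam.VariantFile(path) as vcf:
            records = list(vcf)
        assert len(records) == 40
        nonref = 0
        for rec, truth in zip(records, manifest["records"]):
            assert (rec.chrom, rec.pos, rec.ref, rec.alts[0]) == (
                truth["chrom"], truth["pos"], truth["ref"], truth["alt"],
            )
            gt = rec.samples[0]["GT"]
            if gt != (0, 0):
                nonref += 1
        assert nonref == 4


class TestDdmGenerator:
    def test_gene_counts_fixed_by_integer_weights(self, tmp_path):
        pool = {"BRCA1": 3, "BRCA2": 5, "TP53": 2}
        manifest = generate_ddm_vcf(str(tmp_path / "d.vcf"), pool, 10, seed=4)
        assert manifest["gene_counts"] == pool
        genes = [r["gene"] for r in manifest["records"]]
        assert sorted(genes) == sorted(sum(([g] * n for g, n in pool.items()), []))

    def test_manifest_predicts_derived_frequency(self, tmp_path, store, ddm_spec):
        manifest = generate_ddm_vcf(str(tmp_path / "d.vcf"), {"BRCA2": 8}, 8, seed=6)
        ingest_vcf(store, str(tmp_path / "d.vcf"), ddm_spec, sample_id="S1")
        for r in manifest["records"]:
            key = VariantKey(r["chrom"], r["pos"], r["ref"], r["alt"])
            obs = store.sample_observations("S1", key)
            assert float(obs["allele_frequency"]) == pytest.approx(
                r["expected_allele_frequency"]
            )

    def test_full_support_records_hit_100_percent(self, tmp_path):
        manifest = generate_ddm_vcf(str(tmp_path / "d.vcf"), {"G": 30}, 30, seed=7)
        full = [r for r in manifest["records"] if r["gt"] == "1/1"]
        for r in full:
            assert r["expected_allele_frequency"] == 100.0

    def test_byte_identical_on_same_seed(self, tmp_path):
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        generate_ddm_vcf(str(a), {"X": 2, "Y": 3}, 5, seed=8)
        generate_ddm_vcf(str(b), {"X": 2, "Y": 3}, 5, seed=8)
        assert a.read_bytes() == b.read_bytes()

    def test_empty_pool_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_ddm_vcf(str(tmp_path / "d.vcf"), {}, 5, seed=1)

    def test_parses_under_pysam_with_no_af_subfield(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        path = str(tmp_path / "d.vcf")
        generate_ddm_vcf(path, {"BRCA1": 4}, 4, seed=2)
        with pysam.VariantFile(path) as vcf:
            assert "AF" not in vcf.header.formats
            for rec in vcf:
                assert "SGVEP" in rec.info
                sample = rec.samples[0]
                ad, dp = sample["AD"], sample["DP"]
                assert sum(ad) == dp


class TestAnnotationGenerator:
    def setup_store(self, tmp_path, n=20, seed=1):
        store = VariantStore()
        manifest = generate_ddm_vcf(str(tmp_path / "d.vcf"), {"G": n}, n, seed=seed)
        ingest_vcf(store, str(tmp_path / "d.vcf"), ddm_dialect(), sample_id="S1")
        return store, manifest_keys(manifest)

    def test_changed_subset_cardinality_and_truth(self, tmp_path):
        store, keys = self.setup_store(tmp_path, n=100)
        base = str(tmp_path / "base.tsv")
        generate_annotation_file(base, keys, fraction_changed=0.0, seed=2)
        ingest_annotation(store, base, annotation_dialect())

        changed = str(tmp_path / "changed.tsv")
        truth = generate_annotation_file(changed, keys, fraction_changed=0.11, seed=2)
        assert truth["n_changed"] == 11
        ingest_annotation(store, changed, annotation_dialect())

        q = ChangeQuery(
            "ClinVar", previous_in={"uncertain significance"}, current_equals={"pathogenic"}
        )
        hits = search_changes(store, q)
        assert sorted(str(h.variant) for h in hits) == sorted(truth["changed_keys"])
        assert len(hits) == 11
        store.close()

    def test_fraction_zero_reimport_grows_nothing(self, tmp_path):
        store, keys = self.setup_store(tmp_path)
        path = str(tmp_path / "a.tsv")
        generate_annotation_file(path, keys, fraction_changed=0.0, seed=3)
        ingest_annotation(store, path, annotation_dialect())
        before = store.snapshot()["variant_attrs"]
        generate_annotation_file(path, keys, fraction_changed=0.0, seed=4)
        report = ingest_annotation(store, path, annotation_dialect())
        assert report.attributes_updated == 0
        assert [r[:-2] for r in store.snapshot()["variant_attrs"]] == [r[:-2] for r in before]
        store.close()

    def test_fraction_one_grows_every_history_by_one(self, tmp_path):
        store, keys = self.setup_store(tmp_path)
        base = str(tmp_path / "b.tsv")
        generate_annotation_file(base, keys, fraction_changed=0.0, seed=5)
        ingest_annotation(store, base, annotation_dialect())
        flip = str(tmp_path / "f.tsv")
        truth = generate_annotation_file(flip, keys, fraction_changed=1.0, seed=5)
        assert truth["n_changed"] == len(keys)
        ingest_annotation(store, flip, annotation_dialect())
        for key in keys:
            assert len(store.attribute_history(key, "ClinVar")) == 2
        store.close()


class TestReclassificationScenario:
    def test_designated_variant_is_sole_hit(self):
        store, truth = build_reclassification_scenario(seed=0)
        q = ChangeQuery(
            truth["change_query"]["attribute"],
            previous_in=frozenset(truth["change_query"]["previous_in"]),
            current_equals=frozenset(truth["change_query"]["current_equals"]),
        )
        hits = search_changes(store, q)
        assert [str(h.variant) for h in hits] == truth["expected_change_hits"]
        assert hits[0].previous_value == "uncertain significance"
        store.close()

    def test_carrier_lookup_matches_truth(self):
        store, truth = build_reclassification_scenario(seed=0)
        assert sorted(store.samples_with_variant(SCENARIO_KEY)) == truth["carriers"]
        store.close()

    def test_classification_history_c3_to_c5(self):
        store, _ = build_reclassification_scenario(seed=0)
        history = store.attribute_history(SCENARIO_KEY, "classification")
        assert [e.value for e in history] == ["C3", "C5"]
        store.close()

    def test_pathogenic_to_pathogenic_decoy_never_returned(self):
        store, truth = build_reclassification_scenario(seed=0)
        q = ChangeQuery("ClinVar", previous_in={"pathogenic"}, current_equals={"pathogenic"})
        # identical re-imports coalesce, so no decoy has pathogenic before pathogenic
        assert search_changes(store, q) == []
        store.close()

    def test_store_is_wellformed_and_seed_stable(self):
        s1, t1 = build_reclassification_scenario(seed=5)
        s1.check_history_wellformed()
        s2, t2 = build_reclassification_scenario(seed=5)
        assert t1 == t2
        assert s1.snapshot() == s2.snapshot()
        s1.close()
        s2.close()
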