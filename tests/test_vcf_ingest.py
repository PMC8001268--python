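"""Dialect-driven VCF parsing, filtering and loading."""

import pytest

from varledger import (
    VariantKey,
    VcfIngestError,
    create_panel,
    create_virtual_panel,
    ingest_vcf,
    parse_info_subfield,
    split_dbxref,
)
from varledger.fixtures import generate_ddm_vcf, generate_tss_vcf

TSS_HEADER = (
    "##fileformat=VCFv4.1\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)
DDM_HEADER = (
    "##fileformat=VCFv4.2\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def write_vcf(tmp_path, body, header=TSS_HEADER, name="in.vcf"):
    path = tmp_path / name
    path.write_text(header + body)
    return str(path)


class TestParseInfoSubfield:
    @pytest.mark.parametrize(
        "info,key,expected",
        [
            ("SGVEP=BRCA2;TYPE=SNV", "SGVEP", "BRCA2"),
            ("DP=100", "SGVEP", None),
            ("DBXREF=ClinVar:pathogenic,dbsnp:rs1", "DBXREF", "ClinVar:pathogenic,dbsnp:rs1"),
            ("SOMATIC;DP=3", "SOMATIC", ""),  # flag -> empty-string sentinel
            (".", "DP", None),
        ],
    )
    def test_extraction(self, info, key, expected):
        assert parse_info_subfield(info, key) == expected


class TestSplitDbxref:
    def test_source_token_pairs(self):
        assert split_dbxref("ClinVar:pathogenic,dbsnp:rs1") == {
            "dbxref_ClinVar": "pathogenic",
            "dbxref_dbsnp": "rs1",
        }

    def test_empty_and_fallback(self):
        assert split_dbxref("") == {}
        assert split_dbxref("oddtoken") == {"dbxref_raw": "oddtoken"}


class TestRowFilterDuringIngest:
    def test_homref_rows_excluded(self, store, tss_spec, tmp_path):
        body = (
            "chr13\t100\t.\tA\tG\t.\tPASS\t.\tGT:AF\t0/0:0\n"
            "chr13\t200\t.\tC\tT\t.\tPASS\t.\tGT:AF\t0/1:47.3\n"
            "chr13\t300\t.\tG\tA\t.\tPASS\t.\tGT:AF\t0|0:0\n"  # phased homref
            "chr13\t400\t.\tT\tC\t.\tPASS\t.\tGT:AF\t1/1:99.0\n"
        )
        report = ingest_vcf(store, write_vcf(tmp_path, body), tss_spec, sample_id="S1")
        assert report.rows_read == 4
        assert report.rows_dropped_by_row_filter == 2
        assert report.rows_loaded == 2
        assert store.unique_variant_count() == 2
        # no stored observation from this import carries genotype 0/0
        for _, key in store.iter_variants():
            assert store.sample_observations("S1", key).get("genotype") != "0/0"

    def test_conservation_of_rows(self, store, tss_spec, tmp_path):
        manifest = generate_tss_vcf(str(tmp_path / "t.vcf"), 120, 7, seed=11)
        report = ingest_vcf(store, str(tmp_path / "t.vcf"), tss_spec, sample_id="S1")
        assert report.rows_read == 120
        assert (
            report.rows_read
            == report.rows_dropped_by_row_filter
            + report.rows_dropped_by_virtual_panel
            + report.rows_loaded
        )
        assert report.variants_created == 7
        loaded = {str(k) for _, k in store.iter_variants()}
        assert loaded == set(manifest["truth_nonref_keys"])


class TestDerivedAlleleFrequency:
    def test_ad_dp_percent_no_af_subfield_read(self, store, ddm_spec, tmp_path):
        body = "chr13\t500\t.\tA\tG\t.\tPASS\tSGVEP=BRCA2;TYPE=SNV\tGT:AD:DP\t0/1:39,13:52\n"
        ingest_vcf(store, write_vcf(tmp_path, body, DDM_HEADER), ddm_spec, sample_id="S1")
        obs = store.sample_observations("S1", VariantKey("chr13", 500, "A", "G"))
        assert float(obs["allele_frequency"]) == 25.0
        assert "AF" not in obs  # dialect has no AF mapping at all

    def test_zero_depth_omits_attribute_with_warning(self, store, ddm_spec, tmp_path):
        body = "chr13\t500\t.\tA\tG\t.\tPASS\tSGVEP=BRCA2\tGT:AD:DP\t0/1:0,5:0\n"
        report = ingest_vcf(store, write_vcf(tmp_path, body, DDM_HEADER), ddm_spec, sample_id="S1")
        obs = store.sample_observations("S1", VariantKey("chr13", 500, "A", "G"))
        assert "allele_frequency" not in obs
        assert report.warnings.get("derived_undefined:allele_frequency") == 1


class TestInfoAttributes:
    def test_gene_type_and_dbxref_split(self, store, ddm_spec, tmp_path):
        body = (
            "chr13\t500\t.\tA\tG\t.\tPASS\t"
            "SGVEP=BRCA2;DBXREF=ClinVar:pathogenic,dbsnp:rs1;TYPE=SNV\t"
            "GT:AD:DP\t0/1:10,10:20\n"
        )
        ingest_vcf(store, write_vcf(tmp_path, body, DDM_HEADER), ddm_spec, sample_id="S1")
        attrs = store.current_attributes(VariantKey("chr13", 500, "A", "G"))
        assert attrs["gene"] == "BRCA2"
        assert attrs["mutation_type"] == "SNV"
        assert attrs["dbxref_ClinVar"] == "pathogenic"
        assert attrs["dbxref_dbsnp"] == "rs1"
        assert "dbxref" not in attrs  # replaced by per-source attributes


class TestMultiallelicAndSymbolic:
    def test_multiallelic_split_one_record_per_alt(self, store, ddm_spec, tmp_path):
        body = "chr1\t100\t.\tA\tG,T\t.\tPASS\tSGVEP=X\tGT:AD:DP\t1/2:2,13,39:52\n"
        report = ingest_vcf(store, write_vcf(tmp_path, body, DDM_HEADER), ddm_spec, sample_id="S1")
        assert report.rows_read == 1
        assert report.records_stored == 2
        assert store.unique_variant_count() == 2
        obs_g = store.sample_observations("S1", VariantKey("chr1", 100, "A", "G"))
        obs_t = store.sample_observations("S1", VariantKey("chr1", 100, "A", "T"))
        assert float(obs_g["allele_frequency"]) == 25.0  # 13/52
        assert float(obs_t["allele_frequency"]) == 75.0  # 39/52

    def test_symbolic_alts_skipped_with_warning(self, store, tss_spec, tmp_path):
        body = (
            "chr1\t100\t.\tA\t<DEL>\t.\tPASS\t.\tGT:AF\t0/1:50\n"
            "chr2\t200\t.\tG\tG]17:198982]\t.\tPASS\t.\tGT:AF\t0/1:50\n"
            "chr3\t300\t.\tT\tC\t.\tPASS\t.\tGT:AF\t0/1:50\n"
        )
        report = ingest_vcf(store, write_vcf(tmp_path, body), tss_spec, sample_id="S1")
        assert store.unique_variant_count() == 1
        assert report.alt_records_skipped == 2
        assert report.warnings.get("symbolic_alt_skipped") == 2


class TestVirtualPanelFiltering:
    def make_panel(self):
        genes = [f"G{i:02d}" for i in range(22)]
        panel = create_panel("assay", genes + ["EXTRA"])
        return panel, create_virtual_panel("vp22", panel, genes)

    def test_off_panel_records_dropped(self, store, ddm_spec, tmp_path):
        pool = {f"G{i:02d}": 1 for i in range(22)}
        pool.update({f"G{i:02d}": 3 for i in range(6)})  # 16*1 + 6*3 = 34
        pool.update({"OFFA": 5, "OFFB": 5})
        n = sum(pool.values())  # 44 total, 10 off-panel
        generate_ddm_vcf(str(tmp_path / "d.vcf"), pool, n, seed=5)
        panel, vp = self.make_panel()
        report = ingest_vcf(
            store, str(tmp_path / "d.vcf"), ddm_spec, sample_id="S1",
            panel=panel, virtual_panel=vp,
        )
        assert report.rows_read == n
        assert report.rows_dropped_by_virtual_panel == 10
        assert report.rows_loaded == n - 10
        for _, key in store.iter_variants():
            assert store.current_attributes(key)["gene"] in vp.genes

    def test_record_without_gene_symbol_counts_as_panel_filtered(self, store, ddm_spec, tmp_path):
        body = "chr1\t100\t.\tA\tG\t.\tPASS\tTYPE=SNV\tGT:AD:DP\t0/1:5,5:10\n"
        panel, vp = self.make_panel()
        report = ingest_vcf(
            store, write_vcf(tmp_path, body, DDM_HEADER), ddm_spec, sample_id="S1",
            panel=panel, virtual_panel=vp,
        )
        assert report.rows_dropped_by_virtual_panel == 1
        assert store.unique_variant_count() == 0

    def test_virtual_panel_without_gene_source_is_hard_error(self, store, tss_spec, tmp_path):
        path = write_vcf(tmp_path, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AF\t0/1:50\n")
        _, vp = self.make_panel()
        with pytest.raises(VcfIngestError, match="gene_symbol_source"):
            ingest_vcf(store, path, tss_spec, sample_id="S1", virtual_panel=vp)


class TestIdempotenceAndDialectEquivalence:
    def test_reingest_changes_nothing(self, store, ddm_spec, tmp_path):
        generate_ddm_vcf(str(tmp_path / "d.vcf"), {"BRCA1": 5, "BRCA2": 5}, 10, seed=2)
        first = ingest_vcf(store, str(tmp_path / "d.vcf"), ddm_spec, sample_id="S1")
        before = store.snapshot()
        second = ingest_vcf(store, str(tmp_path / "d.vcf"), ddm_spec, sample_id="S1")
        assert second.variants_created == 0
        assert second.attributes_updated == 0
        assert second.attributes_unchanged == first.attributes_created
        # only provenance timestamps may refresh; values, histories, counts identical
        strip = lambda snap: {
            t: [r[:-2] for r in rows] for t, rows in snap.items()
        }
        assert strip(store.snapshot()) == strip(before)
        store.check_history_wellformed()

    def test_same_variant_through_both_dialects_is_one_record(
        self, store, tss_spec, ddm_spec, tmp_path
    ):
        tss = write_vcf(tmp_path, "chr13\t32936829\t.\tA\tG\t.\tPASS\t.\tGT:AF\t0/1:47.3\n")
        ddm = write_vcf(
            tmp_path,
            "13\t32936829\t.\tA\tG\t.\tPASS\tSGVEP=BRCA2\tGT:AD:DP\t0/1:10,9:19\n",
            DDM_HEADER,
            name="ddm.vcf",
        )
        ingest_vcf(store, tss, tss_spec, sample_id="S1")
        ingest_vcf(store, ddm, ddm_spec, sample_id="S2")
        assert store.unique_variant_count() == 1
        key = VariantKey("chr13", 32936829, "A", "G")
        assert store.samples_with_variant(key) == {"S1", "S2"}


class TestMalformedInput:
    def test_missing_chrom_header_is_error(self, store, tss_spec, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("##fileformat=VCFv4.1\nchr1\t1\t.\tA\tG\t.\t.\t.\tGT:AF\t0/1:5\n")
        with pytest.raises(VcfIngestError, match="#CHROM"):
            ingest_vcf(store, str(path), tss_spec, sample_id="S1")

    def test_multi_sample_file_is_error(self, store, tss_spec, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.1\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        )
        with pytest.raises(VcfIngestError, match="multi-sample"):
            ingest_vcf(store, str(path), tss_spec, sample_id="S1")

    def test_failed_import_leaves_store_unchanged(self, store, tss_spec, tmp_path):
        path = tmp_path / "trunc.vcf"
        path.write_text(
            TSS_HEADER
            + "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AF\t0/1:50\n"
            + "chr1\tnotanumber\t.\tA\tG\t.\tPASS\t.\tGT:AF\t0/1:50\n"
        )
        with pytest.raises(VcfIngestError):
            ingest_vcf(store, str(path), tss_spec, sample_id="S1")
        assert store.unique_variant_count() == 0

    def test_missing_format_subfield_warns_and_omits(self, store, ddm_spec, tmp_path):
        body = "chr1\t100\t.\tA\tG\t.\tPASS\tSGVEP=X\tGT:DP\t0/1:52\n"  # no AD
        report = ingest_vcf(store, write_vcf(tmp_path, body, DDM_HEADER), ddm_spec, sample_id="S1")
        obs = store.sample_observations("S1", VariantKey("chr1", 100, "A", "G"))
        assert "allele_depth" not in obs and "allele_frequency" not in obs
        assert report.warnings.get("format_subfield_absent:AD") == 1

    def test_gzip_input_supported(self, store, tss_spec, tmp_path):
        import gzip

        path = tmp_path / "in.vcf.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(TSS_HEADER + "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AF\t0/1:50\n")
        report = ingest_vcf(store, str(path), tss_spec, sample_id="S1")
        assert report.variants_created == 1
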