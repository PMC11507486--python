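"""cohort_io: VCF/TSV parsing, panel deduplication, merging, annotation."""

import numpy as np
import pytest

from tgspipe.cohort_io import (
    CohortIOError,
    MultiAllelicError,
    annotate_nearest_gene,
    intersect_panel,
    merge_cohorts,
    read_genotypes,
    read_panel,
    read_phenotypes,
    write_phenotypes,
    write_vcf,
)
from tgspipe.simulate import SimulationConfig, simulate_cohort

from conftest import make_matrix


class TestReadGenotypes:
    def test_fixture_read_back_verbatim(self, tiny_vcf):
        m = read_genotypes(tiny_vcf)
        assert m.sample_ids == ["S1", "S2", "S3"]
        assert [v.rsid for v in m.variants] == ["rsA", "rsB"]
        assert [(v.chrom, v.pos, v.ref, v.alt) for v in m.variants] == [
            ("1", 100, "A", "G"),
            ("1", 250, "T", "C"),
        ]
        # GT 0/1 -> 1, ./. -> missing, 1/1 -> 2
        expected = np.array([[1.0, 0.0], [np.nan, 1.0], [2.0, 1.0]])
        np.testing.assert_array_equal(m.dosage, expected)
        assert m.variants[0].info_score == pytest.approx(0.95)
        assert m.variants[1].info_score == pytest.approx(0.55)

    def test_multiallelic_rejected(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\trsA\tA\tG,C\t.\t.\t.\tGT\t0/1\n"
        )
        path = tmp_path / "multi.vcf"
        path.write_text(text)
        with pytest.raises(MultiAllelicError, match="normalize"):
            read_genotypes(path)

    def test_write_read_roundtrip_exact(self, tmp_path, rng):
        dosage = rng.choice([0.0, 1.0, 2.0, np.nan], size=(8, 12), p=[0.4, 0.3, 0.2, 0.1])
        m = make_matrix(dosage.tolist(), info=[0.8] * 12)
        path = tmp_path / "rt.vcf"
        write_vcf(m, path)
        back = read_genotypes(path)
        np.testing.assert_array_equal(back.dosage, m.dosage)
        assert [v.pos for v in back.variants] == [v.pos for v in m.variants]
        assert [(v.ref, v.alt) for v in back.variants] == [(v.ref, v.alt) for v in m.variants]
        assert [v.info_score for v in back.variants] == pytest.approx(
            [v.info_score for v in m.variants]
        )


class TestPhenotypes:
    def test_token_parsing_and_subgroup(self, tmp_path):
        path = tmp_path / "ph.tsv"
        path.write_text(
            "sample_id\tphenotype\tsex\tsubgroup\n"
            "S1\tathlete\tfemale\telite\n"
            "S2\tCONTROL\tM\t\n"
            "S3\t1\tunknown\tsub-elite\n"
        )
        recs = read_phenotypes(path)
        assert [r.phenotype for r in recs] == ["case", "control", "case"]
        assert recs[0].reported_sex == "female" and recs[0].subgroup == "elite"
        assert recs[1].reported_sex == "male"

    def test_duplicate_and_unknown_token_errors(self, tmp_path):
        dup = tmp_path / "dup.tsv"
        dup.write_text("sample_id\tphenotype\tsex\nS1\tathlete\tfemale\nS1\tcontrol\tmale\n")
        with pytest.raises(CohortIOError, match="duplicate"):
            read_phenotypes(dup)
        bad = tmp_path / "bad.tsv"
        bad.write_text("sample_id\tphenotype\tsex\nS1\tmaybe\tfemale\n")
        with pytest.raises(CohortIOError, match="unknown phenotype"):
            read_phenotypes(bad)

    def test_cohort_scale_counts_roundtrip(self, tmp_path):
        """A 733-row cohort with 211 athletes parses to exactly 211 cases."""
        rows = ["sample_id\tphenotype\tsex"]
        rows += [f"A{i}\tathlete\t{'male' if i % 2 else 'female'}" for i in range(211)]
        rows += [f"C{i}\tcontrol\tmale" for i in range(522)]
        path = tmp_path / "cohort.tsv"
        path.write_text("\n".join(rows) + "\n")
        recs = read_phenotypes(path)
        assert len(recs) == 733
        assert sum(r.is_case for r in recs) == 211

    def test_write_read_roundtrip(self, tmp_path):
        recs = read_phenotypes(_write_small(tmp_path))
        out = tmp_path / "out.tsv"
        write_phenotypes(recs, out)
        assert read_phenotypes(out) == recs


def _write_small(tmp_path):
    p = tmp_path / "small.tsv"
    p.write_text("sample_id\tphenotype\tsex\nS1\tathlete\tfemale\nS2\tcontrol\tmale\n")
    return p


class TestPanel:
    def test_duplicates_merged_into_trait_sets(self, tmp_path):
        path = tmp_path / "panel.tsv"
        rows = ["rsid\ttrait"]
        rows += [
            "rs1\ttestosterone measurement",
            "rs1\tlean body mass",
            "rs2\thand grip strength",
            "rs3\treaction time measurement",
            "rs3\treaction time measurement",
            "rs4\tlean body mass",
            "rs5\tphysical activity",
            "rs6\tbrisk walking",
            "rs7\tsarcopenia",
            "rs2\tmuscle mass",
        ]
        path.write_text("\n".join(rows) + "\n")
        panel = read_panel(path)
        assert panel.n_input_rows == 10
        assert len(panel.entries) == 7
        assert panel.traits_for("rs1") == frozenset(
            {"testosterone measurement", "lean body mass"}
        )

    def test_empty_panel_warns(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("rsid\ttrait\n")
        with pytest.warns(UserWarning, match="empty"):
            panel = read_panel(path)
        assert panel.entries == []

    def test_missing_column_errors(self, tmp_path):
        path = tmp_path / "nocol.tsv"
        path.write_text("rsid\nrs1\n")
        with pytest.raises(CohortIOError, match="missing columns"):
            read_panel(path)


class TestIntersectPanel:
    def _panel(self, tmp_path, rows):
        path = tmp_path / "p.tsv"
        path.write_text("rsid\ttrait\n" + "\n".join(rows) + "\n")
        return read_panel(path)

    def test_empty_intersection_errors(self, tmp_path):
        m = make_matrix([[0, 1], [1, 2]])
        panel = self._panel(tmp_path, ["rsX\tlean body mass"])
        with pytest.raises(CohortIOError, match="no rsids"):
            intersect_panel(m, panel)

    def test_superset_panel_attaches_traits_only(self, tmp_path):
        m = make_matrix([[0, 1], [1, 2]])
        panel = self._panel(
            tmp_path, ["rs0\tlean body mass", "rs1\tsarcopenia", "rs9\tmuscle mass"]
        )
        out, unmatched = intersect_panel(m, panel)
        assert out.rsids == m.rsids
        np.testing.assert_array_equal(out.dosage, m.dosage)
        assert out.variants[0].traits == frozenset({"lean body mass"})
        assert unmatched == ["rs9"]

    def test_partial_overlap_reports_unmatched(self, tmp_path):
        m = make_matrix([[0, 1, 2, 0, 1]])
        panel = self._panel(
            tmp_path, ["rs1\tmuscle mass", "rs3\tsarcopenia", "rsZ\tbrisk walking"]
        )
        out, unmatched = intersect_panel(m, panel)
        assert out.rsids == ["rs1", "rs3"]
        assert unmatched == ["rsZ"]
        assert out.n_variants <= m.n_variants  # never grows


class TestMergeCohorts:
    def test_training_set_sample_arithmetic(self):
        """169 athletes + 418 controls merge into a 587-sample training set."""
        a = make_matrix(np.zeros((169, 3)).tolist(), phenotypes=["case"] * 169)
        a.samples = [type(s)(sample_id=f"A{i}", phenotype="case") for i, s in enumerate(a.samples)]
        b = make_matrix(np.ones((418, 3)).tolist(), phenotypes=["control"] * 418)
        b.samples = [type(s)(sample_id=f"C{i}", phenotype="control") for i, s in enumerate(b.samples)]
        merged, report = merge_cohorts(a, b)
        assert merged.n_samples == 587
        assert merged.n_variants == 3
        assert not report.only_in_a and not report.only_in_b

    def test_self_merge_rejected(self):
        m = make_matrix([[0, 1], [1, 2]])
        with pytest.raises(CohortIOError, match="share sample ids"):
            merge_cohorts(m, m)

    def test_private_variant_dropped_and_reported(self):
        a = make_matrix([[0, 1, 2]], rsid_prefix="rs")
        b = make_matrix([[1, 0]], rsid_prefix="rs")
        b.samples = [type(b.samples[0])(sample_id="T0")]
        merged, report = merge_cohorts(a, b)
        assert merged.rsids == ["rs0", "rs1"]
        assert report.only_in_a == ["rs2"]

    def test_allele_mismatch_dropped(self):
        from dataclasses import replace

        a = make_matrix([[0, 1]])
        b = make_matrix([[1, 2]])
        b.samples = [type(b.samples[0])(sample_id="T0")]
        b.variants[1] = replace(b.variants[1], ref="T", alt="C")
        merged, report = merge_cohorts(a, b)
        assert merged.rsids == ["rs0"]
        assert "rs1" in report.allele_mismatch

    def test_variant_content_symmetric(self, rng):
        a = make_matrix(rng.integers(0, 3, size=(4, 5)).astype(float).tolist())
        b = make_matrix(rng.integers(0, 3, size=(3, 3)).astype(float).tolist())
        b.samples = [type(s)(sample_id=f"T{i}") for i, s in enumerate(b.samples)]
        ab, _ = merge_cohorts(a, b)
        ba, _ = merge_cohorts(b, a)
        assert set(ab.rsids) == set(ba.rsids)


class TestNearestGene:
    BED = [("1", 100, 200, "GENE1"), ("1", 400, 500, "GENE2"), ("2", 0, 50, "GENE3")]

    def test_inside_interval(self):
        m = make_matrix([[0]], pos_start=150)
        assert annotate_nearest_gene(m.variants, self.BED) == ["GENE1"]

    def test_equidistant_tie_joined(self):
        # pos 301: gap to GENE1 end (200) = 101; to GENE2 start+1 (401) = 100 -> GENE2
        # pos 300: 100 vs 101 -> GENE1;  exact midpoint needs odd gap: use 300/301 checks
        m_mid = make_matrix([[0]], pos_start=300)
        assert annotate_nearest_gene(m_mid.variants, self.BED) == ["GENE1"]
        # construct an exact tie: genes [100,200) and [400,500) around pos 300
        # distance to GENE1 = 300-200=100, to GENE2 = 401-300=101 -> not tied;
        # use intervals symmetric about 300 instead
        bed = [("1", 100, 250, "L"), ("1", 349, 500, "R")]
        m = make_matrix([[0]], pos_start=300)
        assert annotate_nearest_gene(m.variants, bed) == ["L,R"]

    def test_no_interval_on_chromosome_is_na(self):
        m = make_matrix([[0]], chrom="9")
        assert annotate_nearest_gene(m.variants, self.BED) == ["NA"]
        assert annotate_nearest_gene(m.variants, []) == ["NA"]

    def test_matches_bruteforce_distance_scan(self):
        bed = [("1", 1000, 2000, "A"), ("1", 5000, 6000, "B"), ("1", 6500, 7000, "C")]
        positions = [500, 1500, 4200, 6400]
        m = make_matrix([[0, 0, 0, 0]], pos_start=1)
        from dataclasses import replace

        m.variants = [replace(v, pos=p) for v, p in zip(m.variants, positions)]
        got = annotate_nearest_gene(m.variants, bed)

        def brute(pos):
            best, names = None, []
            for chrom, s, e, name in bed:
                if s + 1 <= pos <= e:
                    d = 0
                elif pos < s + 1:
                    d = s + 1 - pos
                else:
                    d = pos - e
                if best is None or d < best:
                    best, names = d, [name]
                elif d == best:
                    names.append(name)
            return ",".join(names)

        assert got == [brute(p) for p in positions]

    def test_bed_file_parsing(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("1\t100\t200\tGENE1\n1\t400\t500\tGENE2\n")
        m = make_matrix([[0]], pos_start=150)
        assert annotate_nearest_gene(m.variants, path) == ["GENE1"]


def test_simulated_bundle_roundtrips_through_readers(tmp_path):
    """simulate_cohort writes exactly the formats the readers consume."""
    cfg = SimulationConfig(
        n_cases=15, n_controls=30, n_variants=40, n_x_variants=6,
        n_related_pairs=1, n_sex_mismatch=1, seed=5,
    )
    bundle = simulate_cohort(cfg, tmp_path)
    back = read_genotypes(bundle.paths["vcf"])
    np.testing.assert_array_equal(back.dosage, bundle.matrix.dosage)
    recs = read_phenotypes(bundle.paths["phenotypes"])
    assert [r.sample_id for r in recs] == bundle.matrix.sample_ids
    assert [r.phenotype for r in recs] == [s.phenotype for s in bundle.matrix.samples]
    panel = read_panel(bundle.paths["panel"])
    assert panel.rsids == bundle.matrix.rsids
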