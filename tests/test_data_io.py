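import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from stftwas import data_io
from stftwas.data_io import (GenotypePanel, TFPeakSet, annotate_binding_status,
                             harmonize_gwas, hwe_exact_p, load_genotype_panel,
                             load_ld_blocks, mean_impute, qc_filter_variants)
from stftwas.synthetic_data import (FixtureSpec, generate_genotypes,
                                    sample_dosages, write_vcf, _block_sizes)

from conftest import make_panel

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1,length=100000>\n"
)


def write_tiny_vcf(path, body, samples=("A", "B", "C")):
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    path.write_text(VCF_HEADER + cols + "\t".join(samples) + "\n" + body)
    return path


class TestLoadGenotypePanel:
    def test_allele_counting(self, tmp_path):
        vcf = write_tiny_vcf(tmp_path / "t.vcf",
                             "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        panel = load_genotype_panel(vcf)
        assert panel.samples == ["A", "B", "C"]
        np.testing.assert_array_equal(panel.dosages[:, 0], [0, 1, 2])
        assert panel.variants.loc[0, "maf"] == pytest.approx(0.5)

    def test_missing_genotype_is_nan(self, tmp_path):
        vcf = write_tiny_vcf(tmp_path / "t.vcf",
                             "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t1/1\n")
        panel = load_genotype_panel(vcf)
        assert np.isnan(panel.dosages[0, 0])
        assert panel.variants.loc[0, "missing_rate"] == pytest.approx(1 / 3)

    def test_empty_body(self, tmp_path):
        vcf = write_tiny_vcf(tmp_path / "t.vcf", "")
        panel = load_genotype_panel(vcf)
        assert panel.n_variants == 0 and panel.samples == ["A", "B", "C"]

    def test_multiallelic_skipped_with_warning(self, tmp_path):
        vcf = write_tiny_vcf(
            tmp_path / "t.vcf",
            "1\t100\trs1\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        with pytest.warns(UserWarning, match="multiallelic"):
            panel = load_genotype_panel(vcf)
        assert list(panel.variants["id"]) == ["rs2"]

    def test_generator_round_trip(self, tmp_path):
        spec = FixtureSpec(n_ref_samples=100, n_variants=50, n_blocks=5,
                           seed=3)
        panel, _ = generate_genotypes(spec)
        write_vcf(panel, tmp_path / "gen.vcf")
        loaded = load_genotype_panel(tmp_path / "gen.vcf")
        np.testing.assert_array_equal(loaded.dosages, panel.dosages)
        assert list(loaded.variants["id"]) == list(panel.variants["id"])


def hwe_exact_oracle(n_het, n_hom_minor, n_hom_major):
    """Direct multinomial-conditional formula (independent of the
    recurrence used by the implementation)."""
    n = n_het + n_hom_minor + n_hom_major
    rare = 2 * n_hom_minor + n_het
    probs, hets = [], []
    for het in range(rare % 2, rare + 1, 2):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        if hom_r < 0 or hom_c < 0:
            continue
        logp = (special.gammaln(n + 1) - special.gammaln(het + 1)
                - special.gammaln(hom_r + 1) - special.gammaln(hom_c + 1)
                + het * np.log(2)
                + special.gammaln(rare + 1) + special.gammaln(2 * n - rare + 1)
                - special.gammaln(2 * n + 1))
        probs.append(np.exp(logp))
        hets.append(het)
    probs = np.asarray(probs)
    obs = probs[hets.index(n_het)]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


class TestQCFilter:
    @pytest.mark.parametrize("het,hom_minor,hom_major", [
        (10, 5, 85), (57, 14, 50), (0, 20, 80), (100, 0, 0), (1, 0, 49),
    ])
    def test_hwe_exact_matches_direct_formula(self, het, hom_minor, hom_major):
        assert hwe_exact_p(het, hom_minor, hom_major) == pytest.approx(
            hwe_exact_oracle(het, hom_minor, hom_major), rel=1e-9)

    def test_threshold_behavior(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(200, 3)).astype(float)
        panel = make_panel(dos)
        panel.variants.loc[0, "maf"] = 0.005          # below MAF cut
        panel.variants.loc[1, ["maf", "missing_rate", "hwe_p"]] = (0.02, 0.05,
                                                                   0.5)
        panel.variants.loc[2, "hwe_p"] = 1e-8          # HWE failure
        out = qc_filter_variants(panel)
        assert list(out.variants["id"]) == ["v0001"]

    def test_empty_panel(self):
        panel = make_panel(np.zeros((3, 0)))
        assert qc_filter_variants(panel).n_variants == 0

    def test_matches_bruteforce_on_generated_panel(self):
        rng = np.random.default_rng(5)
        n, m = 1000, 500
        mafs = rng.uniform(0.08, 0.5, m)
        mafs[rng.choice(m, 50, replace=False)] = 0.002  # forced rare
        dos = sample_dosages(n, mafs, _block_sizes(m, 10), 0.2, rng)
        # inject some missingness, including one column beyond the cutoff
        miss = rng.random((n, m)) < 0.02
        miss[: int(0.15 * n), 7] = True
        dos[miss] = np.nan
        panel = make_panel(dos)
        out = qc_filter_variants(panel)

        # brute-force oracle straight from the dosage matrix
        keep = []
        for j in range(m):
            col = dos[:, j]
            called = col[~np.isnan(col)]
            freq = called.sum() / (2 * len(called))
            maf = min(freq, 1 - freq)
            missing = np.isnan(col).mean()
            het = int((called == 1).sum())
            ha, hr = int((called == 2).sum()), int((called == 0).sum())
            hwe = hwe_exact_oracle(het, *((ha, hr) if 2 * ha + het <= 2 * hr + het
                                          else (hr, ha)))
            keep.append(maf >= 0.01 and missing <= 0.10 and hwe >= 1e-6)
        expected = [f"v{j:04d}" for j in range(m) if keep[j]]
        assert list(out.variants["id"]) == expected
        # the 50 forced-rare variants are all gone
        assert len(expected) <= m - 50

    def test_mean_impute_fills_column_means(self):
        dos = np.array([[0, 1], [np.nan, 1], [2, np.nan]], dtype=float)
        panel = mean_impute(make_panel(dos))
        assert panel.dosages[1, 0] == pytest.approx(1.0)
        assert panel.dosages[2, 1] == pytest.approx(1.0)


class TestBindingStatus:
    def test_halfopen_coordinate_convention(self):
        # peak [100, 105) covers 1-based positions 101..105 only
        positions = np.arange(95, 111)
        variants = pd.DataFrame({
            "id": [f"p{p}" for p in positions], "chrom": "1",
            "pos": positions,
        })
        peak = TFPeakSet.from_intervals("TF1", [("1", 100, 105)])
        status = annotate_binding_status(variants, [peak])
        expected = [(1 if 100 < p <= 105 else 0) for p in positions]
        assert list(status["TF1"]) == expected

    def test_no_peaks_gives_zero_matrix(self):
        variants = pd.DataFrame({"id": ["a"], "chrom": "1", "pos": [5]})
        status = annotate_binding_status(variants, [])
        assert status.shape == (1, 0)

    def test_multiple_tfs_covering_one_variant(self):
        variants = pd.DataFrame({"id": ["a"], "chrom": "1", "pos": [50]})
        peaks = [TFPeakSet.from_intervals(f"TF{i}", [("1", 40, 60)])
                 for i in range(3)]
        status = annotate_binding_status(variants, peaks)
        assert status.loc["a"].sum() == 3

    def test_invariant_to_interval_split_and_order(self):
        rng = np.random.default_rng(1)
        positions = np.sort(rng.choice(np.arange(1, 2000), 100,
                                       replace=False))
        variants = pd.DataFrame({
            "id": [f"v{i}" for i in range(100)], "chrom": "1",
            "pos": positions,
        })
        whole = TFPeakSet.from_intervals("TF", [("1", 300, 900)])
        split = TFPeakSet.from_intervals("TF", [("1", 600, 900),
                                                ("1", 300, 600)])
        a = annotate_binding_status(variants, [whole])
        b = annotate_binding_status(variants, [split])
        pd.testing.assert_frame_equal(a, b)

    def test_chromosome_mismatch_yields_zeros_not_error(self):
        variants = pd.DataFrame({"id": ["a"], "chrom": "2", "pos": [50]})
        peak = TFPeakSet.from_intervals("TF", [("1", 40, 60)])
        status = annotate_binding_status(variants, [peak])
        assert status.loc["a", "TF"] == 0


class TestLDBlocks:
    def test_assignment_and_singletons(self, tmp_path):
        bed = tmp_path / "blocks.bed"
        bed.write_text("1\t0\t1000\tB1\n1\t1000\t2000\tB2\n")
        variants = pd.DataFrame({
            "id": ["a", "b", "c"], "chrom": "1", "pos": [500, 1500, 5000],
        })
        assign = load_ld_blocks(bed, variants)
        assert assign["a"] == "B1" and assign["b"] == "B2"
        assert assign["c"].startswith("singleton:")


def gwas_frame(rows):
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos",
                                       "effect_allele", "other_allele",
                                       "beta", "se", "pvalue", "n"])


class TestHarmonizeGWAS:
    @pytest.fixture()
    def panel(self):
        dos = np.tile([0.0, 1.0, 2.0], (3, 1)).T
        return make_panel(dos, ids=["v1", "v2", "v3"], ref="A", alt="G")

    def test_chi2_closed_form_and_zero_beta(self, panel):
        g = gwas_frame([("x1", "1", 1001, "G", "A", 0.3, 0.1, 0.003, 100),
                        ("x2", "1", 2001, "G", "A", 0.0, 0.1, 1.0, 100)])
        out = harmonize_gwas(g, panel)
        assert out.loc[out["variant_id"] == "v1", "chi2"].iloc[0] == \
            pytest.approx(9.0)
        assert out.loc[out["variant_id"] == "v2", "chi2"].iloc[0] == 0.0

    def test_allele_swap_flips_beta_keeps_chi2(self, panel):
        g = gwas_frame([("x1", "1", 1001, "A", "G", -0.3, 0.1, 0.003, 100)])
        out = harmonize_gwas(g, panel)
        assert out["beta"].iloc[0] == pytest.approx(0.3)
        assert out["chi2"].iloc[0] == pytest.approx(9.0)

    def test_chi2_recovered_from_p_when_beta_missing(self, panel):
        p = stats.chi2.sf(9.0, 1)
        g = gwas_frame([("x1", "1", 1001, "G", "A", np.nan, np.nan, p, 100)])
        out = harmonize_gwas(g, panel)
        assert out["chi2"].iloc[0] == pytest.approx(9.0, rel=1e-6)

    def test_palindromic_dropped_by_default(self):
        dos = np.tile([0.0, 1.0, 2.0], (2, 1)).T
        panel = make_panel(dos, ids=["v1", "v2"])
        panel.variants.loc[0, ["ref", "alt"]] = ("A", "T")
        panel.variants.loc[1, ["ref", "alt"]] = ("A", "G")
        g = gwas_frame([("x1", "1", 1001, "T", "A", 0.2, 0.1, 0.05, 100),
                        ("x2", "1", 2001, "G", "A", 0.2, 0.1, 0.05, 100)])
        out = harmonize_gwas(g, panel)
        assert list(out["variant_id"]) == ["v2"]
        kept = harmonize_gwas(g, panel, drop_ambiguous=False)
        assert len(kept) == 2

    def test_idempotent(self, panel):
        g = gwas_frame([("x1", "1", 1001, "A", "G", -0.3, 0.1, 0.003, 100),
                        ("x2", "1", 2001, "G", "A", 0.5, 0.2, 0.01, 100)])
        once = harmonize_gwas(g, panel)
        twice = harmonize_gwas(once, panel)
        pd.testing.assert_frame_equal(once, twice)

    def test_no_overlap_is_an_error(self, panel):
        g = gwas_frame([("x1", "9", 1, "G", "A", 0.3, 0.1, 0.003, 100)])
        with pytest.raises(ValueError, match="overlap"):
            harmonize_gwas(g, panel)
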