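import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiresponse import diffmeth, geneagg
from epiresponse.errors import ValidationError
from conftest import two_group_m_matrix


def _manifest(rows):
    return pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "gene", "feature"]
    ).set_index("probe_id")


class TestAnnotateProbes:
    @pytest.fixture()
    def gene_table(self):
        return pd.DataFrame(
            {
                "gene": ["ALPHA", "BETA"],
                "chrom": ["chr1", "chr1"],
                "start": [100_000, 300_000],
                "end": [120_000, 320_000],
            }
        )

    def test_window_boundary_inclusive(self, gene_table):
        manifest = _manifest(
            [
                ("cg_in", "chr1", 120_000 + 19_999, None, "unknown"),
                ("cg_out", "chr1", 120_000 + 20_001, None, "unknown"),
            ]
        )
        out = geneagg.annotate_probes(manifest, gene_table)
        assert out.loc["cg_in", "gene"] == "ALPHA"
        assert out.loc["cg_out", "gene"] is None

    def test_overlapping_genes_midpoint_tie_break(self):
        gene_table = pd.DataFrame(
            {
                "gene": ["ANARROW", "WIDE"],
                "chrom": ["chr2", "chr2"],
                "start": [900, 100],
                "end": [1200, 2400],
            }
        )
        # cg_mid (pos 1000) is inside both genes; ANARROW's midpoint (1050)
        # beats WIDE's (1250).  cg_wide (pos 1210) is inside WIDE only.
        manifest = _manifest(
            [("cg_mid", "chr2", 1000, None, "unknown"), ("cg_wide", "chr2", 1210, None, "unknown")]
        )
        out = geneagg.annotate_probes(manifest, gene_table)
        assert out.loc["cg_mid", "gene"] == "ANARROW"
        assert out.loc["cg_wide", "gene"] == "WIDE"

    def test_midpoint_tie_break_overrides_name_order(self):
        # probe inside both genes, equidistant (distance 0); ZFIRST's midpoint
        # is closer, and its name sorts after AWIDE — midpoint must win
        gene_table = pd.DataFrame(
            {
                "gene": ["AWIDE", "ZFIRST"],
                "chrom": ["chr2", "chr2"],
                "start": [100, 900],
                "end": [2400, 1200],
            }
        )
        manifest = _manifest([("cg1", "chr2", 1000, None, "unknown")])
        out = geneagg.annotate_probes(manifest, gene_table)
        assert out.loc["cg1", "gene"] == "ZFIRST"

    def test_exact_tie_lexicographic(self):
        gene_table = pd.DataFrame(
            {
                "gene": ["ZED", "ANN"],
                "chrom": ["chr3", "chr3"],
                "start": [100, 100],
                "end": [200, 200],
            }
        )
        manifest = _manifest([("cg1", "chr3", 150, None, "unknown")])
        out = geneagg.annotate_probes(manifest, gene_table)
        assert out.loc["cg1", "gene"] == "ANN"

    def test_malformed_interval_rejected(self, gene_table):
        bad = gene_table.copy()
        bad.loc[0, "start"] = bad.loc[0, "end"] + 1
        with pytest.raises(ValidationError, match="start > end"):
            geneagg.annotate_probes(_manifest([("cg1", "chr1", 1, None, "x")]), bad)


def fisher_combine(pvalues):
    """Independent closed-form oracle: Fisher's method."""
    psi = -2.0 * np.sum(np.log(pvalues))
    return psi, stats.chi2.sf(psi, 2 * len(pvalues))


class TestBrownCombine:
    def test_independent_equals_fisher(self):
        p = np.array([0.01, 0.5, 0.9])
        agg = geneagg.brown_combine(p, np.eye(3))
        psi, p_fisher = fisher_combine(p)
        assert agg.psi == pytest.approx(psi, abs=1e-12)
        assert agg.df == pytest.approx(6.0)
        assert agg.p_value == pytest.approx(p_fisher, abs=1e-12)

    def test_k1_identity(self):
        agg = geneagg.brown_combine([0.037])
        assert agg.p_value == pytest.approx(0.037, abs=1e-12)

    def test_perfect_correlation_identity(self):
        """k=4, all rho=1, identical p: analytic reduction gives back p."""
        rho = np.ones((4, 4))
        agg = geneagg.brown_combine([0.02] * 4, rho)
        assert agg.df == pytest.approx(2.0)
        assert agg.p_value == pytest.approx(0.02, abs=1e-10)

    def test_zero_correlation_matches_fisher_randomized(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 11)
            p = rng.uniform(1e-6, 1.0, size=k)
            agg = geneagg.brown_combine(p, np.eye(k))
            _, p_fisher = fisher_combine(p)
            assert abs(agg.p_value - p_fisher) < 1e-12

    def test_monotone_in_each_input(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            k = int(rng.integers(2, 6))
            base = rng.uniform(0.05, 0.95, size=k)
            r = rng.uniform(0, 0.9)
            rho = np.full((k, k), r)
            np.fill_diagonal(rho, 1.0)
            p0 = geneagg.brown_combine(base, rho).p_value
            j = int(rng.integers(k))
            smaller = base.copy()
            smaller[j] *= 0.5
            assert geneagg.brown_combine(smaller, rho).p_value <= p0 + 1e-12

    def test_effective_df_decreases_with_correlation(self):
        k = 5
        dfs = []
        for r in np.linspace(0.0, 1.0, 6):
            rho = np.full((k, k), r)
            np.fill_diagonal(rho, 1.0)
            dfs.append(geneagg.brown_combine([0.5] * k, rho).df)
        assert all(a > b for a, b in zip(dfs, dfs[1:]))
        assert dfs[0] == pytest.approx(2 * k)

    def test_zero_pvalue_rejected(self):
        with pytest.raises(ValidationError, match="floor"):
            geneagg.brown_combine([0.0, 0.5])

    def test_non_psd_correlation_warns(self):
        rho = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.warns(UserWarning, match="positive semi-definite"):
            geneagg.brown_combine([0.1, 0.2, 0.3], rho)


class TestGeneLevelScan:
    def test_single_probe_gene(self):
        rng = np.random.default_rng(2)
        m_df, sheet = two_group_m_matrix(1, 6, rng)
        dm = diffmeth.fit_dm(m_df, diffmeth.build_design(sheet))
        manifest = _manifest([(m_df.index[0], "chr1", 100, "SOLO", "TSS")])
        scan = geneagg.gene_level_scan(dm, manifest, m_df, ["SOLO"])
        assert scan.loc["SOLO", "k"] == 1
        assert scan.loc["SOLO", "p_value"] == pytest.approx(dm["p_value"].iloc[0], abs=1e-12)

    def test_absent_gene_reported_not_raised(self):
        rng = np.random.default_rng(3)
        m_df, sheet = two_group_m_matrix(1, 6, rng)
        dm = diffmeth.fit_dm(m_df, diffmeth.build_design(sheet))
        manifest = _manifest([(m_df.index[0], "chr1", 100, "SOLO", "TSS")])
        scan = geneagg.gene_level_scan(dm, manifest, m_df, ["MISSING"])
        assert bool(scan.loc["MISSING", "absent"])
        assert np.isnan(scan.loc["MISSING", "p_value"])

    def test_power_on_planted_gene(self, references):
        """A cohort gene holding 3 planted probes (delta 0.8 logit, n=80)
        reaches a combined p < 0.01 in >= 90% of replicates."""
        from epiresponse import preprocess, synthetic

        hits, n_rep = 0, 40
        for rep in range(n_rep):
            cfg = synthetic.GeneratorConfig(
                n_samples=80, n_probes=130, n_informative=3, delta_logit=0.8,
                n_snp_probes=0, responder_fraction=0.5, seed=1000 + rep,
            )
            beta, sheet, manifest, truth = synthetic.generate_cohort(cfg, references)
            gene = manifest.loc[truth.informative_probe_ids[0], "gene"]
            assert set(truth.informative_probe_ids) <= set(
                manifest.index[manifest["gene"] == gene]
            )
            m_df = preprocess.beta_to_m(beta, offset=1e-6)
            dm = diffmeth.fit_dm(m_df, diffmeth.build_design(sheet))
            scan = geneagg.gene_level_scan(dm, manifest, m_df, [gene])
            if scan.loc[gene, "p_value"] < 0.01:
                hits += 1
        assert hits >= 0.9 * n_rep


class TestRegionalProfile:
    def _setup(self, deltas, positions):
        probes = [f"cg{i}" for i in range(len(deltas))]
        dm = pd.DataFrame({"delta_beta": deltas, "p_value": 0.5}, index=probes)
        manifest = _manifest(
            [(p, "chr1", pos, "GENE", "intron") for p, pos in zip(probes, positions)]
        )
        return dm, manifest

    def test_constant_delta_fits_constant(self):
        dm, manifest = self._setup([0.05] * 8, np.arange(8) * 1000 + 100)
        prof = geneagg.regional_profile("GENE", dm, manifest, span=0.75)
        np.testing.assert_allclose(prof.fit, 0.05, atol=1e-10)

    def test_tss_hypermethylation_shape(self):
        """TSS-proximal elevation (+0.1) decays toward the gene body."""
        positions = np.arange(12) * 1000
        deltas = np.where(positions < 3000, 0.1, 0.0) + np.random.default_rng(5).normal(
            0, 0.005, 12
        )
        dm, manifest = self._setup(deltas, positions)
        prof = geneagg.regional_profile("GENE", dm, manifest, span=0.5)
        assert prof.fit[0] > prof.fit[-1] + 0.05

    def test_global_span_on_collinear_points_equals_ols_line(self):
        positions = np.arange(10) * 500.0
        deltas = 0.02 + 3e-5 * positions  # exactly collinear
        dm, manifest = self._setup(deltas, positions)
        prof = geneagg.regional_profile("GENE", dm, manifest, span=1.0)
        slope, intercept = np.polyfit(positions, deltas, 1)
        np.testing.assert_allclose(prof.fit, intercept + slope * prof.grid, atol=1e-10)

    def test_too_few_probes_skips_smoothing(self):
        dm, manifest = self._setup([0.1, 0.2], [100, 200])
        prof = geneagg.regional_profile("GENE", dm, manifest)
        assert not prof.smoothed
        assert "fewer than 3" in prof.note
        assert len(prof.points) == 2
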