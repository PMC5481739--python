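"""TMM normalization, moderated-t DE and DEG overlaps.

The TMM factors and moderated statistics are cross-checked against the
Bioconductor implementations (edgeR / limma) on small fixtures via
Rscript, keeping the Python implementation and the oracle independent.
"""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tscpipe.expression import (
    deg_overlap,
    filter_low_counts,
    moderated_de,
    normalize_logcpm,
    tmm_factors,
)


def _nb_counts(rng, n_genes=400, n_samples=6, mean=80.0):
    lam = rng.gamma(10.0, mean / 10.0, (n_genes, n_samples))
    return pd.DataFrame(
        rng.poisson(lam),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestTMM:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.poisson(50.0, 300)
        counts = pd.DataFrame({"a": col, "b": col.copy()})
        np.testing.assert_allclose(tmm_factors(counts), 1.0, atol=1e-9)

    def test_doubled_column_unit_factors(self, rng):
        col = rng.poisson(50.0, 300) + 1
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        # composition unchanged: the library size absorbs the doubling
        np.testing.assert_allclose(tmm_factors(counts), 1.0, atol=1e-9)

    def test_geometric_mean_one_and_gene_order_invariance(self, rng):
        counts = _nb_counts(rng)
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)
        perm = rng.permutation(len(counts))
        f2 = tmm_factors(counts.iloc[perm])
        np.testing.assert_allclose(f, f2, rtol=1e-12)

    def test_matches_edger(self, rng, tmp_path):
        counts = _nb_counts(rng, n_genes=500, n_samples=5)
        # skew one sample's composition so factors move away from 1
        counts.iloc[:50, 0] = (counts.iloc[:50, 0] * 8).astype(int)
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        out = tmp_path / "factors.tsv"
        script = (
            "suppressMessages(library(edgeR));"
            f"x <- as.matrix(read.delim('{path}', row.names=1));"
            "f <- calcNormFactors(DGEList(counts=x))$samples$norm.factors;"
            f"write.table(f, '{out}', row.names=FALSE, col.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = np.loadtxt(out)
        np.testing.assert_allclose(tmm_factors(counts).to_numpy(), ref, rtol=1e-6)

    def test_logcpm_prior_count(self):
        counts = pd.DataFrame({"a": [0, 999_990, 10], "b": [0, 999_990, 10]})
        _, logcpm = normalize_logcpm(counts)
        # count 0 in a ~1e6 library with prior 0.5 -> ~log2(0.5) = -1
        assert logcpm.iloc[0, 0] == pytest.approx(-1.0, abs=0.01)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(counts)


class TestModeratedDE:
    def _two_group(self, rng, n_genes=2_000, n=8, spike=0, lfc=4.0):
        base = rng.gamma(8.0, 12.0, n_genes)
        mu = np.tile(base[:, None], (1, 2 * n))
        if spike:
            sign = np.where(np.arange(spike) % 2 == 0, 1.0, -1.0)
            mu[:spike, n:] *= 2.0 ** (lfc * sign[:, None])
        lam = rng.gamma(10.0, mu / 10.0)
        counts = pd.DataFrame(rng.poisson(lam),
                              index=[f"g{i}" for i in range(n_genes)])
        labels = ["A"] * n + ["B"] * n
        return counts, labels

    def test_null_simulation_near_zero_degs(self, rng):
        counts, labels = self._two_group(rng)
        _, logcpm = normalize_logcpm(counts)
        res = moderated_de(logcpm, labels)
        assert int(res.table["deg"].sum()) <= 1

    def test_spike_recovery(self, rng):
        counts, labels = self._two_group(rng, spike=100)
        _, logcpm = normalize_logcpm(counts)
        res = moderated_de(logcpm, labels)
        spiked = [f"g{i}" for i in range(100)]
        recovered = res.table.loc[spiked, "deg"].mean()
        assert recovered >= 0.95

    def test_fold_change_gate(self, rng):
        # an arbitrarily significant gene below |log2FC| = 2 is not a DEG
        n = 200
        logcpm = pd.DataFrame(rng.normal(5.0, 0.05, (50, 2 * n)))
        logcpm.iloc[0, n:] += 1.5
        res = moderated_de(logcpm, ["A"] * n + ["B"] * n)
        row = res.table.iloc[0]
        assert row["p_adj"] < 1e-10 and not row["deg"]

    def test_d0_limits(self, rng):
        logcpm = pd.DataFrame(rng.normal(5, 1, (300, 12)))
        labels = ["A"] * 6 + ["B"] * 6
        res0 = moderated_de(logcpm, labels, d0_override=0.0)
        xa, xb = logcpm.iloc[:, :6], logcpm.iloc[:, 6:]
        ref = stats.ttest_ind(xb, xa, axis=1, equal_var=True)
        np.testing.assert_allclose(res0.table["t"], ref.statistic, rtol=1e-9)
        res_inf = moderated_de(logcpm, labels, d0_override=float("inf"))
        # pooled-variance limit: every gene shares one residual variance
        s_pool = np.sqrt(np.mean(
            ((xa.var(axis=1, ddof=1) * 5) + (xb.var(axis=1, ddof=1) * 5)) / 10
        ))
        manual = (xb.mean(axis=1) - xa.mean(axis=1)) / (s_pool * np.sqrt(2 / 6))
        np.testing.assert_allclose(res_inf.table["t"], manual, rtol=1e-9)

    def test_monotone_in_cutoffs(self, rng):
        counts, labels = self._two_group(rng, n_genes=800, spike=60, lfc=3.0)
        _, logcpm = normalize_logcpm(counts)
        loose = moderated_de(logcpm, labels, lfc_cut=1.0, fdr_cut=0.01)
        tight = moderated_de(logcpm, labels, lfc_cut=2.0, fdr_cut=0.001)
        assert set(tight.degs) <= set(loose.degs)

    def test_matches_limma_ebayes(self, rng, tmp_path):
        counts, labels = self._two_group(rng, n_genes=300, n=5, spike=30, lfc=2.0)
        _, logcpm = normalize_logcpm(counts)
        path = tmp_path / "logcpm.tsv"
        logcpm.to_csv(path, sep="\t")
        out = tmp_path / "limma.tsv"
        script = (
            "suppressMessages(library(limma));"
            f"x <- as.matrix(read.delim('{path}', row.names=1));"
            "design <- cbind(1, rep(c(0,1), each=5));"
            "fit <- eBayes(lmFit(x, design));"
            "res <- data.frame(t=fit$t[,2], p=fit$p.value[,2], lfc=fit$coefficients[,2]);"
            f"write.table(res, '{out}', sep='\\t', quote=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out, sep="\t")
        res = moderated_de(logcpm, labels)
        np.testing.assert_allclose(res.table["log2fc"], ref["lfc"], rtol=1e-8)
        np.testing.assert_allclose(res.table["t"], ref["t"], rtol=1e-3)
        np.testing.assert_allclose(res.table["p"], ref["p"], rtol=5e-3, atol=1e-12)

    def test_group_size_precondition(self, rng):
        logcpm = pd.DataFrame(rng.normal(size=(10, 5)))
        with pytest.raises(ValueError, match=">=3"):
            moderated_de(logcpm, ["A", "A", "B", "B", "B"])


class TestFilterAndOverlap:
    def test_filter_low_counts(self):
        counts = pd.DataFrame(
            {"a": [0, 100, 5000], "b": [1, 120, 5000], "c": [0, 90, 5000]},
            index=["lo", "mid", "hi"],
        )
        kept = filter_low_counts(counts, min_cpm=1.0, min_samples=3)
        assert list(kept.index) == ["mid", "hi"]

    def test_set_overlap_enumeration(self):
        out = deg_overlap({"g1", "g2", "g3"}, {"g2", "g3", "g4"})
        assert out == {"intersection": 2, "a_only": 1, "b_only": 1}

    def test_identical_and_disjoint_sets(self):
        assert deg_overlap({"a"}, {"a"})["a_only"] == 0
        assert deg_overlap({"a"}, {"b"})["intersection"] == 0

    def test_directional_overlap_tables(self, rng):
        idx = [f"g{i}" for i in range(6)]
        def _tab(degs, signs):
            return pd.DataFrame(
                {"log2fc": signs, "deg": degs}, index=idx
            )
        a = _tab([True, True, False, False, True, False], [3, -3, 3, -3, 3, 3])
        b = _tab([True, False, True, False, True, False], [3, -3, 3, -3, -3, 3])
        out = deg_overlap(a, b)
        assert out["increased"]["intersection"] == 1  # g0 up in both
        assert out["decreased"]["intersection"] == 0
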