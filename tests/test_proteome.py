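import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famba.proteome import (
    ProteinGroupTable,
    bh_adjust,
    cyclic_loess_normalize,
    design_matrix,
    filter_proteins,
    fit_moderated,
    fold_change_raw,
    log2_transform,
    read_maxquant,
    sample_weights,
    squeeze_var,
)
from famba.reference import DA_PROTEINS
from famba.synthetic import simulate_proteome


def _stub_table(intensity_rows, peptides=None, reverse=None, contaminant=None,
                diets=("FO", "TOFX"), n_per=4):
    """Protein table with constant replicate intensities per group."""
    samples = pd.DataFrame(
        [
            {"diet": d, "system": f"S{i % 2 + 1}", "tank": f"{d}-{i}"}
            for d in diets
            for i in range(n_per)
        ],
        index=[f"{d}_{i}" for d in diets for i in range(n_per)],
    )
    mat = []
    for row in intensity_rows:
        mat.append([row[d] for d in diets for _ in range(n_per)])
    n = len(mat)
    index = pd.Index([f"P{i}" for i in range(n)], name="protein")
    meta = pd.DataFrame(
        {
            "accession": index,
            "gene": index,
            "unique_peptides": peptides if peptides is not None else [5] * n,
            "reverse": reverse if reverse is not None else [False] * n,
            "contaminant": contaminant if contaminant is not None else [False] * n,
        },
        index=index,
    )
    return ProteinGroupTable(pd.DataFrame(mat, index=index, columns=samples.index), meta, samples)


class TestFilter:
    def test_single_peptide_excluded_even_if_ubiquitous(self):
        t = _stub_table([{"FO": 1e6, "TOFX": 1e6}], peptides=[1])
        assert len(filter_proteins(t).intensities) == 0

    def test_detected_in_three_of_one_group_retained(self, small_proteome):
        table, _ = small_proteome
        kept = filter_proteins(table)
        detected = kept.intensities > 0
        diets = kept.samples["diet"]
        by_group = pd.DataFrame(
            {d: detected.loc[:, diets.index[diets == d]].sum(axis=1) for d in diets.unique()}
        )
        assert (by_group.max(axis=1) >= 3).all()

    def test_two_detections_everywhere_excluded(self):
        t = _stub_table([{"FO": 1e6, "TOFX": 1e6}])
        x = t.intensities.copy()
        x.iloc[0, 2:4] = 0.0  # FO: 2 detected
        x.iloc[0, 6:8] = 0.0  # TOFX: 2 detected
        t2 = ProteinGroupTable(x, t.meta, t.samples)
        assert len(filter_proteins(t2).intensities) == 0

    def test_reverse_and_contaminant_dropped(self):
        t = _stub_table(
            [{"FO": 1e6, "TOFX": 1e6}] * 3,
            reverse=[False, True, False],
            contaminant=[False, False, True],
        )
        assert list(filter_proteins(t).intensities.index) == ["P0"]

    def test_small_groups_error(self):
        t = _stub_table([{"FO": 1e6, "TOFX": 1e6}], n_per=2)
        with pytest.raises(ValueError, match="replicate rule"):
            filter_proteins(t)


class TestLog2:
    def test_values_and_missing_code(self):
        m = log2_transform(pd.DataFrame({"a": [1024.0, 0.0, 2.78e6]}))
        assert m.iloc[0, 0] == 10.0
        assert np.isnan(m.iloc[1, 0])
        assert m.iloc[2, 0] == pytest.approx(21.41, abs=0.005)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(pd.DataFrame({"a": [-1.0]}))


class TestCyclicLoess:
    def test_identical_columns_unchanged(self):
        rng = np.random.default_rng(0)
        col = rng.normal(20, 2, 200)
        m = pd.DataFrame({"a": col, "b": col.copy()})
        out = cyclic_loess_normalize(m)
        assert np.allclose(out["a"], m["a"], atol=1e-8)

    def test_removes_one_log2_shift(self):
        table, _ = simulate_proteome(n_proteins=800, seed=5,
                                     sample_shifts=[1.0] + [0.0] * 11,
                                     missingness=False)
        logm = log2_transform(table.intensities)
        norm = cyclic_loess_normalize(logm)
        resid = norm.iloc[:, 0].mean() - norm.iloc[:, 1:].mean(axis=1).mean()
        assert abs(resid) < 0.05

    def test_missing_entries_untouched(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(20, 2, (100, 4)))
        m.iloc[3, 2] = np.nan
        out = cyclic_loess_normalize(m)
        assert np.isnan(out.iloc[3, 2])

    def test_sparse_sample_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(20, 2, (50, 3)), columns=["a", "b", "c"])
        m.iloc[5:, 2] = np.nan  # only 5 observed values in c
        with pytest.warns(UserWarning, match="excluded from normalization"):
            out = cyclic_loess_normalize(m)
        assert np.allclose(out["c"].dropna(), m["c"].dropna())


class TestSampleWeights:
    def test_iid_weights_near_one_geomean_exact(self):
        table, _ = simulate_proteome(n_proteins=400, seed=4, missingness=False)
        w = sample_weights(log2_transform(table.intensities), table.samples)
        assert np.exp(np.log(w).mean()) == pytest.approx(1.0, abs=1e-12)
        assert (np.abs(np.log(w)) < 0.4).all()

    def test_noisy_sample_downweighted(self):
        table, _ = simulate_proteome(n_proteins=400, seed=4,
                                     variance_factors={"FO_1": 4.0},
                                     missingness=False)
        w = sample_weights(log2_transform(table.intensities), table.samples)
        assert w.idxmin() == "FO_1"
        assert w["FO_1"] < 0.6


class TestModeratedFit:
    def test_equals_direct_wls_oracle_on_complete_data(self):
        """On complete data the coefficients, residual variances and the
        un-moderated t statistics must match an independent per-protein
        weighted least-squares solve to 1e-10."""
        table, _ = simulate_proteome(n_proteins=60, seed=6, missingness=False)
        m = log2_transform(table.intensities)
        w = pd.Series(np.linspace(0.5, 1.5, m.shape[1]), index=m.columns)
        fit = fit_moderated(m, table.samples, w)
        X, names, diets = design_matrix(table.samples)
        cvec = np.zeros(len(names))
        cvec[names.index(f"diet[{diets[1]}]")] = 1.0
        contrast = f"{diets[1]} vs {diets[0]}"
        W = np.diag(w.to_numpy())
        for g in range(m.shape[0]):
            y = m.iloc[g].to_numpy()
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
            resid = y - X @ beta
            df = len(y) - X.shape[1]
            s2 = float(resid @ W @ resid) / df
            row = fit.tables[contrast].iloc[g]
            assert row["logFC"] == pytest.approx(float(cvec @ beta), abs=1e-10)
            assert row["s2"] == pytest.approx(s2, rel=1e-10)
            se2 = s2 * float(cvec @ np.linalg.inv(X.T @ W @ X) @ cvec)
            t_ord = float(cvec @ beta) / np.sqrt(se2)
            t_mod_rescaled = row["t"] * np.sqrt(row["s2_post"] / s2)
            assert t_mod_rescaled == pytest.approx(t_ord, rel=1e-9)

    def test_shrinkage_limits(self):
        s2 = np.array([0.5, 1.0, 2.0])
        df = np.array([4.0, 4.0, 4.0])
        # tiny prior df: posterior ~ observed; huge prior df: posterior ~ s0^2
        d0, s02, post = squeeze_var(s2, df)
        lo = (1e-9 * s02 + df * s2) / (1e-9 + df)
        assert np.allclose(lo, s2, rtol=1e-9)
        hi = (1e12 * s02 + df * s2) / (1e12 + df)
        assert np.allclose(hi, s02, rtol=1e-3)

    def test_prior_recovers_simulation_hyperparameters(self):
        rng = np.random.default_rng(7)
        d0_true, s02_true, df = 5.0, 0.09, 6.0
        s2 = s02_true * d0_true / rng.chisquare(d0_true, 5000) * rng.chisquare(df, 5000) / df
        d0, s02, _ = squeeze_var(s2, np.full(5000, df))
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s02 == pytest.approx(s02_true, rel=0.1)

    def test_null_pvalues_uniform(self):
        table, _ = simulate_proteome(n_proteins=1000, samples_per_group=4,
                                     diets=("A", "B"), seed=6, missingness=False)
        fit = fit_moderated(log2_transform(table.intensities), table.samples)
        p = fit.tables["B vs A"]["p_value"].dropna()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_missing_handled_with_df_adjustment(self):
        table, _ = simulate_proteome(n_proteins=50, seed=8, missingness=False)
        m = log2_transform(table.intensities)
        m.iloc[0, 0] = np.nan
        fit = fit_moderated(m, table.samples)
        tbl = next(iter(fit.tables.values()))
        assert tbl.iloc[0]["df_resid"] == tbl.iloc[1]["df_resid"] - 1

    def test_squeeze_var_matches_limma(self, tmp_path):
        """Independent oracle: the empirical-Bayes moment estimates must
        agree with the reference R implementation."""
        rng = np.random.default_rng(42)
        s2 = 0.09 * rng.chisquare(7, 100) / 7 * (4 / rng.chisquare(4, 100))
        np.savetxt(tmp_path / "s2.txt", s2)
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            s2 <- scan(commandArgs(TRUE)[1])
            r <- squeezeVar(s2, df = 7)
            cat(format(c(r$df.prior, r$var.prior, r$var.post), digits = 17), sep = "\\n")
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "oracle.R"), str(tmp_path / "s2.txt")],
            capture_output=True, text=True, check=True,
        )
        vals = np.array([float(x) for x in out.stdout.split()])
        d0, s02, post = squeeze_var(s2, np.full(100, 7.0))
        assert d0 == pytest.approx(vals[0], rel=1e-6)
        assert s02 == pytest.approx(vals[1], rel=1e-6)
        assert np.allclose(post, vals[2:], rtol=1e-6)


class TestBH:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2])[0] == 0.2
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_order_invariant(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p[perm]), adj[perm])

    def test_fixed_point_on_flat_step(self):
        # a fully tied step (the hand example) is a fixed point of the
        # step-up procedure
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(bh_adjust(adj), adj)

    def test_monotone_in_rank_and_above_raw(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFoldChange:
    def test_published_fold_changes_from_group_means(self):
        rows = [
            {"FO": fo, "TOFX": tofx}
            for _, _, fo, tofx, _, _ in DA_PROTEINS
            if fo is not None and tofx is not None
        ]
        t = _stub_table(rows)
        fc = fold_change_raw(t, "TOFX", "FO")
        published = [f for _, _, fo, tofx, f, _ in DA_PROTEINS if fo and tofx]
        # group means in the reference table are rounded to 3 digits, so
        # recomputed fold changes can drift by a couple of tenths
        assert np.allclose(fc["fold_change"], published, atol=0.25)
        by_gene = dict(zip((g for _, g, fo, tofx, _, _ in DA_PROTEINS if fo and tofx),
                           fc["fold_change"]))
        assert round(by_gene["S61A1"], 1) == 2.8
        assert round(by_gene["ALDH2"], 1) == -1.4

    def test_sign_convention_and_nd(self):
        t = _stub_table([
            {"FO": 2e6, "TOFX": 1e6},
            {"FO": 1e6, "TOFX": 1e6},
            {"FO": 0.0, "TOFX": 1e6},
        ])
        fc = fold_change_raw(t, "TOFX", "FO")
        assert fc.iloc[0]["fold_change"] == pytest.approx(-2.0)
        assert fc.iloc[1]["fold_change"] == pytest.approx(1.0)
        assert fc.iloc[2]["status"] == "ND in FO"
        assert (fc["fold_change"].abs().dropna() >= 1.0).all()


def test_read_maxquant_dialect(tmp_path):
    tsv = tmp_path / "proteinGroups.txt"
    tsv.write_text(
        "Majority protein IDs\tGene names\tUnique peptides\tReverse\t"
        "Potential contaminant\tLFQ intensity A\tLFQ intensity B\n"
        "P1\tGN1\t5\t\t\t1000\t2000\n"
        "REV_P2\tGN2\t3\t+\t\t500\t600\n"
        "P3\tGN3\t1\t\t+\t100\t0\n"
    )
    samples = pd.DataFrame(
        {"diet": ["FO", "TOFX"], "system": ["S1", "S1"], "tank": ["t1", "t2"]},
        index=["A", "B"],
    )
    table = read_maxquant(tsv, samples)
    assert table.intensities.shape == (3, 2)
    assert table.meta["reverse"].tolist() == [False, True, False]
    assert table.meta["contaminant"].tolist() == [False, False, True]
    assert table.intensities.loc["P3", "B"] == 0.0
    with pytest.raises(ValueError, match="absent from the table"):
        read_maxquant(tsv, samples.rename(index={"B": "missing"}))
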