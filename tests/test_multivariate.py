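"""PCA morphospace and RDA variation partitioning."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from conftest import make_line
from plastevol.multivariate import (
    CONSTANT_TERMS,
    DesignTerm,
    build_design,
    condition_centroids,
    partition_frame,
    pca_morphospace,
    rda_partition,
)
from plastevol.synthdata import GeneratorParams, generate_events


def sequential_ss_oracle(Y, term_mats):
    """Brute-force sequential explained SS via cumulative least squares."""
    Y = np.asarray(Y, float)
    n = len(Y)
    ss_tot = ((Y - Y.mean(0)) ** 2).sum()

    def explained(mats):
        X = np.column_stack([np.ones(n)] + [np.asarray(m, float) for m in mats])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        return ss_tot - ((Y - X @ beta) ** 2).sum()

    out = []
    for k in range(len(term_mats)):
        out.append(explained(term_mats[: k + 1]) - (explained(term_mats[:k]) if k else 0.0))
    return np.array(out), ss_tot


class TestPCA:
    def test_recovers_known_diagonal_covariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20_000, 3)) * np.sqrt([4.0, 1.0, 0.25])
        res = pca_morphospace(X)
        np.testing.assert_allclose(res.explained_variance, [4.0, 1.0, 0.25], rtol=0.05)
        # loadings align with the coordinate axes, largest entry positive
        np.testing.assert_allclose(np.abs(res.loadings), np.eye(3), atol=0.05)
        assert (res.loadings.max(axis=0) > 0.9).all()

    def test_collinear_channels_give_zero_second_axis(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        res = pca_morphospace(np.column_stack([x, 2 * x]))
        assert res.explained_variance[1] == pytest.approx(0.0, abs=1e-20)

    def test_scores_are_centred(self):
        rng = np.random.default_rng(2)
        res = pca_morphospace(rng.normal(size=(50, 3)) + 7.0)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-12)


def _metadata(n_sal=3):
    sals = [0.8, 2.4, 4.0][:n_sal]
    rows = []
    rng = np.random.default_rng(0)
    for strain in "AB":
        for day in range(1, 11):
            for sal in sals:
                for _ in range(2):
                    rows.append(
                        {
                            "strain": strain,
                            "day": day,
                            "salinity_M": sal,
                            "growth_rate": rng.normal(),
                            "predictability": rng.uniform(),
                        }
                    )
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_fluctuating_term_dfs(self):
        terms = build_design(_metadata(3), regime="fluctuating")
        assert [t.columns.shape[1] for t in terms] == [1, 1, 9, 2, 1, 2, 18, 9, 18]

    def test_constant_term_dfs(self):
        terms = build_design(_metadata(2), regime="constant")
        assert [t.name for t in terms] == list(CONSTANT_TERMS)
        assert [t.columns.shape[1] for t in terms] == [1, 1, 9, 1, 9]

    def test_single_categorical_df(self):
        meta = pd.DataFrame({"day": [1, 2, 3, 4] * 3, "strain": "A",
                             "salinity_M": 0.8, "growth_rate": 0.0})
        terms = build_design(meta, terms=("day",))
        assert terms[0].columns.shape[1] == 3  # L - 1

    def test_missing_metadata_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_design(pd.DataFrame({"day": [1, 2]}), regime="fluctuating")


class TestRDAPartition:
    def test_exact_fit_has_zero_residual(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 2))
        Y = X @ rng.normal(size=(2, 3))
        parts = rda_partition(Y, [DesignTerm("x", "continuous", X)], n_perm=0)
        assert parts[0].r2 == pytest.approx(1.0, abs=1e-12)
        assert parts[-1].r2 == pytest.approx(0.0, abs=1e-12)

    def test_two_level_factor_matches_between_group_ss(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(6, 3))
        X = np.array([0.0, 0, 0, 1, 1, 1])[:, None]
        parts = rda_partition(Y, [DesignTerm("g", "categorical", X)], n_perm=0)
        ss, ss_tot = sequential_ss_oracle(Y, [X])
        assert parts[0].r2 == pytest.approx(ss[0] / ss_tot, abs=1e-12)

    @pytest.mark.parametrize("n,k,seed", [(5, 2, 0), (6, 3, 1), (8, 3, 2), (8, 2, 3)])
    def test_matches_brute_force_on_toys(self, n, k, seed):
        rng = np.random.default_rng(seed)
        Y = rng.normal(size=(n, k))
        g = (np.arange(n) % 2).astype(float)[:, None]
        x = rng.normal(size=(n, 1))
        mats = [g, x]
        terms = [DesignTerm("g", "categorical", g), DesignTerm("x", "continuous", x)]
        parts = rda_partition(Y, terms, n_perm=0)
        ss, ss_tot = sequential_ss_oracle(Y, mats)
        np.testing.assert_allclose([p.r2 for p in parts[:-1]], ss / ss_tot, atol=1e-12)
        assert sum(p.r2 for p in parts) == pytest.approx(1.0, abs=1e-10)

    def test_total_explained_is_order_invariant(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(30, 3))
        a = DesignTerm("a", "continuous", rng.normal(size=(30, 2)))
        b = DesignTerm("b", "continuous", rng.normal(size=(30, 1)))
        ab = rda_partition(Y, [a, b], n_perm=0)
        ba = rda_partition(Y, [b, a], n_perm=0)
        tot_ab = ab[0].r2 + ab[1].r2
        tot_ba = ba[0].r2 + ba[1].r2
        assert tot_ab == pytest.approx(tot_ba, abs=1e-12)
        assert ab[0].r2 != pytest.approx(ba[1].r2, abs=1e-6)  # sequential shares differ

    def test_strong_effect_reaches_minimum_p(self):
        rng = np.random.default_rng(6)
        g = np.repeat([0.0, 1.0], 15)[:, None]
        Y = g * 10 + rng.normal(size=(30, 3)) * 0.1
        parts = rda_partition(Y, [DesignTerm("g", "categorical", g)], n_perm=199, seed=0)
        assert parts[0].p == pytest.approx(1 / 200)

    def test_rank_deficient_term_reduces_df(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(20, 1))
        dup = np.hstack([x, x])  # second column adds nothing
        with pytest.warns(UserWarning, match="rank-deficient"):
            parts = rda_partition(rng.normal(size=(20, 3)),
                                  [DesignTerm("x", "continuous", dup)], n_perm=0)
        assert parts[0].df == 1

    def test_marginal_mode_matches_drop_one_oracle(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(20, 3))
        a = rng.normal(size=(20, 1))
        b = rng.normal(size=(20, 2))
        terms = [DesignTerm("a", "continuous", a), DesignTerm("b", "continuous", b)]
        parts = rda_partition(Y, terms, n_perm=0, method="marginal")
        ss_ab, ss_tot = sequential_ss_oracle(Y, [a, b])
        ss_ba, _ = sequential_ss_oracle(Y, [b, a])
        # marginal SS of a = full - model(b) = second sequential share of order (b, a)
        assert parts[0].r2 == pytest.approx(ss_ba[1] / ss_tot, abs=1e-12)
        assert parts[1].r2 == pytest.approx(ss_ab[1] / ss_tot, abs=1e-12)

    def test_matches_vegan_rda(self, tmp_path):
        """Independent oracle: vegan's constrained-inertia share."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript is required for the vegan cross-check")
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(12, 3))
        g = np.repeat([0, 1, 2], 4)
        df = pd.DataFrame(Y, columns=["y1", "y2", "y3"])
        df["g"] = g
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "rda.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(vegan))
            d <- read.csv("{csv}")
            m <- rda(d[, 1:3] ~ factor(g), data = d)
            cat(sprintf("%.12f", m$CCA$tot.chi / m$tot.chi))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, check=True)
        vegan_r2 = float(out.stdout.strip())
        G = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
        parts = rda_partition(Y, [DesignTerm("g", "categorical", G)], n_perm=0)
        assert parts[0].r2 == pytest.approx(vegan_r2, abs=1e-9)


class TestCentroids:
    def test_symmetric_lines_average_to_zero(self):
        df = pd.DataFrame(
            {
                "line_id": ["L1"] * 2 + ["L2"] * 2,
                "salinity_M": 0.8,
                "day": 1,
                "pc1": [1.0, 3.0, -1.0, -3.0],
            }
        )
        cond, treat = condition_centroids(df, ["pc1"], treatment_of_line={"L1": 0.9, "L2": 0.9})
        assert sorted(cond["pc1"]) == [-2.0, 2.0]
        assert treat["pc1"].iloc[0] == pytest.approx(0.0)
        assert treat["pc1_se"].iloc[0] == pytest.approx(2.0)  # sd 2*sqrt2 / sqrt(2)

    def test_single_line_has_undefined_se(self):
        df = pd.DataFrame({"line_id": "L1", "salinity_M": 0.8, "day": 1, "pc1": [1.0, 2.0]})
        cond, treat = condition_centroids(df, ["pc1"], treatment_of_line={"L1": 0.5})
        assert cond["pc1"].iloc[0] == pytest.approx(1.5)
        assert np.isnan(treat["pc1_se"].iloc[0])

    def test_ontogenic_loop_closes(self):
        """Day-ordered centroids trace a loop: start and end morphologies
        are nearer each other than either is to mid-trajectory days."""
        p = GeneratorParams(dead_fraction=0, debris_fraction=0, doublet_fraction=0)
        line = make_line(rho2=0.25)
        frames = [
            generate_events(line, 2.4, day, 2000, p, seed=day) for day in range(11)
        ]
        ev = pd.concat(frames, ignore_index=True)
        res = pca_morphospace(ev[["fsc", "ssc", "red_b"]].to_numpy())
        scores = ev[["line_id", "salinity_M", "day"]].copy()
        scores[["pc1", "pc2"]] = res.scores[:, :2]
        cond, _ = condition_centroids(scores, ["pc1", "pc2"])
        cent = cond.set_index("day")[["pc1", "pc2"]]
        d_start_end = np.linalg.norm(cent.loc[0] - cent.loc[10])
        for mid in (3, 5, 7):
            assert d_start_end < np.linalg.norm(cent.loc[0] - cent.loc[mid])
            assert d_start_end < np.linalg.norm(cent.loc[10] - cent.loc[mid])
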