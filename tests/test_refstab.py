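"""BestKeeper / geNorm / NormFinder stability metrics and consensus."""

import numpy as np
import pandas as pd
import pytest

from flaxsrna import refstab


def make_noise_matrix(rng, n_samples, sds, shift_sd=0.0):
    """Samples x candidates matrix: per-candidate baseline + noise."""
    data = {}
    shifts = rng.normal(0, shift_sd, n_samples)
    for i, (name, sd) in enumerate(sds.items()):
        data[name] = 20 + i + shifts + rng.normal(0, sd, n_samples)
    return pd.DataFrame(data, index=[f"s{i}" for i in range(n_samples)])


class TestBestKeeper:
    def test_hand_computed_3x2(self):
        mat = pd.DataFrame(
            {"A": [20.0, 21.0, 22.0], "B": [25.0, 25.0, 25.0]},
            index=["s1", "s2", "s3"],
        )
        out = refstab.bestkeeper(mat)
        assert out.at["A", "sd"] == pytest.approx(1.0)
        assert out.at["A", "cv"] == pytest.approx(100 / 21)
        assert out.at["B", "sd"] == 0.0
        assert out.at["B", "rank"] == 1
        # index = geometric mean; constant B makes index track A
        index = np.exp((np.log(mat["A"]) + np.log(mat["B"])) / 2)
        assert out.at["A", "r"] == pytest.approx(
            float(np.corrcoef(mat["A"], index)[0, 1])
        )

    def test_constant_candidate_ranked_first(self):
        rng = np.random.default_rng(71)
        mat = make_noise_matrix(rng, 20, {"X": 0.5, "Y": 0.0, "Z": 1.0})
        mat["Y"] = 23.0
        out = refstab.bestkeeper(mat)
        assert out.at["Y", "rank"] == 1

    def test_planted_noise_ordering(self):
        rng = np.random.default_rng(72)
        mat = make_noise_matrix(rng, 20, {"lo": 0.2, "hi": 1.0})
        out = refstab.bestkeeper(mat)
        assert out.at["lo", "rank"] < out.at["hi", "rank"]

    def test_per_candidate_shift_invariance(self):
        rng = np.random.default_rng(73)
        mat = make_noise_matrix(rng, 12, {"A": 0.3, "B": 0.6, "C": 0.2})
        shifted = mat + pd.Series({"A": 3.0, "B": -2.0, "C": 0.5})
        sd1 = refstab.bestkeeper(mat)["sd"]
        sd2 = refstab.bestkeeper(shifted)["sd"]
        assert np.allclose(sd1, sd2)

    def test_too_small_matrix(self):
        with pytest.raises(ValueError):
            refstab.bestkeeper(pd.DataFrame({"A": [1.0, 2.0]}))


class TestGeNorm:
    def test_constant_ratio_pair(self):
        mat = pd.DataFrame(
            {"A": [1.0, 2.0, 3.0, 4.0], "B": [2.5, 3.5, 4.5, 5.5]},
            index=list("wxyz"),
        )
        m = refstab.genorm_m(mat)
        assert m["A"] == pytest.approx(0.0, abs=1e-12)
        assert m["B"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_m(self):
        mat = pd.DataFrame(
            {
                "A": [0.0, 1.0, 2.0, 3.0],
                "B": [0.0, 1.1, 2.2, 3.3],
                "C": [1.0, 0.0, 2.0, 1.0],
            },
            index=list("wxyz"),
        )
        m = refstab.genorm_m(mat)
        for j in "ABC":
            sds = [
                (mat[j] - mat[k]).std(ddof=1) for k in "ABC" if k != j
            ]
            assert m[j] == pytest.approx(float(np.mean(sds)))

    def test_per_sample_shift_invariance(self):
        rng = np.random.default_rng(74)
        mat = pd.DataFrame(
            rng.normal(0, 1, (10, 4)),
            columns=list("ABCD"),
            index=[f"s{i}" for i in range(10)],
        )
        shifted = mat.add(pd.Series(rng.normal(0, 2, 10), index=mat.index), axis=0)
        assert np.allclose(refstab.genorm_m(mat), refstab.genorm_m(shifted))

    def test_final_pair_shares_rank_one(self):
        rng = np.random.default_rng(75)
        mat = pd.DataFrame(
            {
                "A": rng.normal(0, 0.05, 12),
                "B": rng.normal(0, 0.05, 12),
                "C": rng.normal(0, 0.8, 12),
                "D": rng.normal(0, 1.2, 12),
            },
            index=[f"s{i}" for i in range(12)],
        )
        out = refstab.genorm(mat)
        assert sorted(out[out["rank"] == 1].index) == ["A", "B"]
        assert out["rank"].max() == 4
        assert 3 in set(out["rank"])
        assert "V2/3" in out.attrs["pairwise_variation"]


class TestNormFinder:
    def test_zero_residual_candidate(self):
        # candidate collinear with the sample effect: residual-free
        samples = [f"s{i}" for i in range(6)]
        effect = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        mat = pd.DataFrame(
            {"A": effect, "B": effect + 1.0, "C": effect + np.array([0, 0.5, -0.5, 0, 0.5, -0.5])},
            index=samples,
        )
        out = refstab.normfinder(mat)
        assert out.at["A", "stability"] == pytest.approx(out.at["B", "stability"])
        assert out.at["C", "rank"] == 3

    def test_hand_computed_residuals_3x3(self):
        mat = pd.DataFrame(
            {"A": [1.0, 2.0, 3.0], "B": [2.0, 2.0, 2.0], "C": [0.0, 4.0, 5.0]},
            index=["s1", "s2", "s3"],
        )
        x = mat.to_numpy()
        resid = x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True) + x.mean()
        expected = np.sqrt((resid**2).sum(0) * 3 / (2 * 2))
        out = refstab.normfinder(mat)
        assert np.allclose(out["stability"], expected)

    def test_planted_low_noise_recovery(self):
        rng = np.random.default_rng(76)
        wins = 0
        reps = 100
        for _ in range(reps):
            mat = pd.DataFrame(
                {
                    "stable": rng.normal(0, 0.1, 20),
                    "n1": rng.normal(0, 0.5, 20),
                    "n2": rng.normal(0, 0.5, 20),
                    "n3": rng.normal(0, 0.5, 20),
                },
                index=[f"s{i}" for i in range(20)],
            )
            out = refstab.normfinder(mat)
            wins += out.at["stable", "rank"] == 1
        assert wins / reps >= 0.95

    def test_groups_add_intergroup_term(self):
        rng = np.random.default_rng(77)
        mat = pd.DataFrame(
            rng.normal(0, 0.3, (12, 3)),
            columns=list("ABC"),
            index=[f"s{i}" for i in range(12)],
        )
        # candidate A responds to condition: bigger intergroup term
        groups = pd.Series(["g1"] * 6 + ["g2"] * 6, index=mat.index)
        mat.loc[groups == "g2", "A"] += 2.0
        out = refstab.normfinder(mat, groups)
        assert out.at["A", "intergroup"] > out.at["B", "intergroup"]
        assert out.at["A", "rank"] == 3


class TestConsensus:
    def make_reports(self, ranks):
        frames = []
        for method_ranks in ranks:
            frames.append(
                pd.DataFrame({"rank": pd.Series(method_ranks)})
            )
        return frames

    def test_unanimous_first(self):
        bk, gn, nf = self.make_reports(
            [{"A": 1, "B": 2}, {"A": 1, "B": 2}, {"A": 1, "B": 2}]
        )
        out = refstab.consensus_rank(bk, gn, nf)
        assert out.at["A", "consensus_rank"] == 1

    def test_mean_rank_decides(self):
        bk, gn, nf = self.make_reports(
            [{"A": 1, "B": 2}, {"A": 2, "B": 1}, {"A": 2, "B": 1}]
        )
        out = refstab.consensus_rank(bk, gn, nf)
        assert out.at["B", "consensus_rank"] == 1  # mean 1.33 vs 1.67
        assert out.at["B", "mean_rank"] == pytest.approx(4 / 3)

    def test_alphabetical_tie_break(self):
        bk, gn, nf = self.make_reports(
            [{"A": 1, "B": 1}, {"A": 1, "B": 1}, {"A": 1, "B": 1}]
        )
        out = refstab.consensus_rank(bk, gn, nf)
        assert out.at["A", "consensus_rank"] == 1
        assert out.at["B", "consensus_rank"] == 2

    def test_mismatched_candidates_raise(self):
        bk, gn, nf = self.make_reports(
            [{"A": 1, "B": 2}, {"A": 1, "C": 2}, {"A": 1, "B": 2}]
        )
        with pytest.raises(ValueError):
            refstab.consensus_rank(bk, gn, nf)


class TestFullReport:
    def test_planted_partition_recovered(self):
        """Two stable and two unstable planted candidates split the
        consensus top-2/bottom-2 on simulated Ct data."""
        from flaxsrna import synthetic_data

        design = [
            synthetic_data.TranscriptDesign("stableA", 1.0, 21.0, {}, 0.05),
            synthetic_data.TranscriptDesign("stableB", 1.0, 22.0, {}, 0.05),
            synthetic_data.TranscriptDesign("midC", 0.99, 23.0, {}, 0.35),
            synthetic_data.TranscriptDesign("noisyD", 0.98, 24.0, {}, 1.0),
            synthetic_data.TranscriptDesign("noisyE", 0.97, 25.0, {}, 1.2),
        ]
        rng = np.random.default_rng(78)
        ct_df = synthetic_data.make_qpcr_dataset(
            design, {"N": 10, "P": 10}, replicate_sd=0.15, rng=rng
        )
        report = refstab.stability_report(
            ct_df, [t.name for t in design], groups_by="condition"
        )
        top2 = set(report.index[report["consensus_rank"] <= 2])
        bottom2 = set(report.index[report["consensus_rank"] >= 4])
        assert top2 == {"stableA", "stableB"}
        assert bottom2 == {"noisyD", "noisyE"}
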