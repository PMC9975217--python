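import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ssnpatterns.core import SampleMetadata
from ssnpatterns.network import ConnectedComponent
from ssnpatterns.spatial import (
    OccurrenceProfile,
    bray_curtis,
    combination_counts,
    depth_sharing_matrix,
    forward_select_env,
    jaccard_from_bray,
    occurrence_profiles,
    rda_anova,
    rda_fit,
    region_dissimilarity,
)

from conftest import make_tax


def sample(sid, region, layer="SRF"):
    return SampleMetadata(
        sample_id=sid, dataset="ds", region=region, station="st",
        date=dt.date(2020, 1, 1), depth_m=3.0, depth_type=layer,
    )


class TestOccurrence:
    def test_region_and_layer_sets(self):
        table = pd.DataFrame(
            {"s1": [0.5, 0.0], "s2": [0.0, 0.2], "s3": [0.1, 0.0]},
            index=["a", "b"],
        )
        meta = [
            sample("s1", "Mediterranean Sea", "SRF"),
            sample("s2", "North Sea", "DCM"),
            sample("s3", "Mediterranean Sea", "DCM"),
        ]
        ccs = [
            ConnectedComponent("cc1", frozenset("a")),
            ConnectedComponent("cc2", frozenset("b")),
        ]
        p1, p2 = occurrence_profiles(ccs, table, meta)
        assert p1.regions == frozenset({"Mediterranean Sea"})
        assert p1.layers_by_region["Mediterranean Sea"] == frozenset({"SRF", "DCM"})
        assert p2.regions == frozenset({"North Sea"})

    def test_zero_abundance_cc_has_empty_profile(self):
        table = pd.DataFrame({"s1": [0.0]}, index=["a"])
        meta = [sample("s1", "North Sea")]
        (p,) = occurrence_profiles(
            [ConnectedComponent("cc", frozenset("a"))], table, meta
        )
        assert p.regions == frozenset()

    def test_unknown_sample_rejected(self):
        table = pd.DataFrame({"mystery": [0.1]}, index=["a"])
        with pytest.raises(ValueError, match="mystery"):
            occurrence_profiles(
                [ConnectedComponent("cc", frozenset("a"))], table, []
            )


class TestCombinations:
    def test_exact_set_counting(self):
        profiles = [
            OccurrenceProfile("c1", frozenset({"A"})),
            OccurrenceProfile("c2", frozenset({"A", "B"})),
            OccurrenceProfile("c3", frozenset({"A", "B"})),
        ]
        counts = combination_counts(profiles)
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"A", "B"})] == 2
        assert sum(counts.values()) == 3

    def test_empty_input(self):
        assert combination_counts([]) == {}


class TestDepthSharing:
    def _profile(self, cc_id, lx, ly):
        return OccurrenceProfile(
            cc_id, frozenset({"X", "Y"}),
            {"X": frozenset(lx), "Y": frozenset(ly)},
        )

    def test_single_cell(self):
        profiles = [self._profile("c1", ["DCM"], ["DCM"]),
                    self._profile("c2", ["DCM"], ["DCM"])]
        mat = depth_sharing_matrix(profiles, "X", "Y", {"c1", "c2"})
        assert mat.loc["DCM", "DCM"] == 100.0
        assert mat.to_numpy().sum() == 100.0

    def test_quarter_cell(self):
        profiles = [self._profile(f"c{i}", ["SRF"], ["SRF"]) for i in range(3)]
        profiles.append(self._profile("c3", ["SRF"], ["BATHY"]))
        mat = depth_sharing_matrix(profiles, "X", "Y", {f"c{i}" for i in range(4)})
        assert mat.loc["BATHY", "SRF"] == 25.0

    def test_multi_layer_cc_counts_in_multiple_cells(self):
        profiles = [self._profile("c1", ["SRF", "DCM"], ["SRF"])]
        mat = depth_sharing_matrix(profiles, "X", "Y", {"c1"})
        assert mat.loc["SRF", "SRF"] == 100.0
        assert mat.loc["SRF", "DCM"] == 100.0
        assert mat.to_numpy().sum() == 200.0  # non-exclusive combinations

    def test_empty_restriction_rejected(self):
        with pytest.raises(ValueError):
            depth_sharing_matrix([], "X", "Y", set())


class TestDissimilarity:
    def test_identical_and_disjoint(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([1, 0], [0, 2]) == 1.0

    def test_hand_computed_value(self):
        assert bray_curtis([1, 0, 3], [0, 2, 1]) == pytest.approx(5 / 7)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    @pytest.mark.parametrize("b, j", [(0.0, 0.0), (1.0, 1.0), (0.5, 2 / 3)])
    def test_jaccard_transform(self, b, j):
        assert jaccard_from_bray(b) == pytest.approx(j, abs=1e-12)

    def test_jaccard_domain(self):
        with pytest.raises(ValueError):
            jaccard_from_bray(1.5)

    def test_region_dissimilarity_ordering(self):
        # regions A and B share their composition; C is disjoint
        table = pd.DataFrame(
            {
                "a1": [1.0, 1.0, 0.0, 0.0],
                "a2": [0.8, 1.2, 0.0, 0.0],
                "b1": [1.1, 0.9, 0.0, 0.0],
                "c1": [0.0, 0.0, 1.0, 1.0],
            },
            index=["m1", "m2", "m3", "m4"],
        )
        taxonomy = {m: make_tax() for m in table.index}
        meta = [sample("a1", "A"), sample("a2", "A"), sample("b1", "B"),
                sample("c1", "C")]
        bmat, jmat = region_dissimilarity(table, taxonomy, "Dinoflagellata", meta)
        assert jmat.loc["A", "B"] < jmat.loc["A", "C"]
        assert jmat.loc["A", "B"] < jmat.loc["B", "C"]
        # J = 2B/(1+B) holds cell-wise
        np.testing.assert_allclose(
            jmat.to_numpy(), 2 * bmat.to_numpy() / (1 + bmat.to_numpy()), atol=1e-12
        )

    def test_unknown_division_rejected(self):
        table = pd.DataFrame({"s": [1.0]}, index=["m1"])
        with pytest.raises(ValueError):
            region_dissimilarity(
                table, {"m1": make_tax()}, "Radiolaria", [sample("s", "A")]
            )


class TestRDA:
    def test_perfect_linear_response(self, rng):
        X = rng.normal(size=(30, 3))
        B = rng.normal(size=(3, 5))
        Y = (X - X.mean(0)) @ B
        fit = rda_fit(Y, X)
        assert fit.constrained_proportion == pytest.approx(1.0, abs=1e-9)
        assert sum(fit.axis_proportions) == pytest.approx(1.0, abs=1e-9)

    def test_standardization_invariance(self, rng):
        X = rng.normal(size=(25, 3))
        Y = rng.normal(size=(25, 4))
        f1 = rda_fit(Y, X)
        f2 = rda_fit(Y, X * np.array([10.0, 0.01, 3.0]))
        assert f1.constrained_proportion == pytest.approx(
            f2.constrained_proportion, abs=1e-12
        )

    def test_zero_variance_column_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match="zero-variance"):
            rda_fit(rng.normal(size=(20, 3)), X)

    def test_collinear_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        X = np.hstack([X, (2 * X[:, :1] - X[:, 1:])])
        with pytest.raises(ValueError, match="collinear"):
            rda_fit(rng.normal(size=(20, 3)), X)

    def test_null_constrained_proportion(self, rng):
        # under independence E[R^2] = q / (n-1)
        n, q, reps = 60, 4, 40
        props = [
            rda_fit(rng.normal(size=(n, 3)), rng.normal(size=(n, q))).constrained_proportion
            for _ in range(reps)
        ]
        assert np.mean(props) == pytest.approx(q / (n - 1), abs=0.02)

    def test_matches_vegan(self, tmp_path, rng):
        """Cross-check constrained proportion against vegan::rda."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        X = rng.normal(size=(20, 3))
        Y = rng.normal(size=(20, 5))
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
        script = tmp_path / "rda.R"
        script.write_text(
            "suppressMessages(library(vegan))\n"
            f"X <- as.data.frame(scale(read.csv('{tmp_path}/X.csv', header=FALSE)))\n"
            f"Y <- read.csv('{tmp_path}/Y.csv', header=FALSE)\n"
            "fit <- rda(Y ~ ., data=X)\n"
            "cat(fit$CCA$tot.chi / fit$tot.chi)\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        expected = float(out.stdout.strip())
        assert rda_fit(Y, X).constrained_proportion == pytest.approx(expected, abs=1e-6)


class TestPermutationAnova:
    def test_perfect_fit_minimal_p(self, rng):
        X = rng.normal(size=(25, 2))
        Y = (X - X.mean(0)) @ rng.normal(size=(2, 3))
        res = rda_anova(Y, X, n_perm=99, rng=0)
        assert res["p_value"] == pytest.approx(1 / 100)

    def test_null_p_uniform(self, rng):
        from scipy.stats import kstest

        pvals = [
            rda_anova(
                rng.normal(size=(30, 3)), rng.normal(size=(30, 2)),
                n_perm=99, rng=int(i),
            )["p_value"]
            for i in range(60)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_axes_scope_shape(self, rng):
        X = rng.normal(size=(30, 3))
        Y = (X - X.mean(0)) @ rng.normal(size=(3, 4)) + 0.1 * rng.normal(size=(30, 4))
        res = rda_anova(Y, X, n_perm=99, scope="axes", n_axes=2, rng=1)
        assert [a["axis"] for a in res["axes"]] == [1, 2]
        assert all(0 < a["p_value"] <= 1 for a in res["axes"])

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            rda_anova(rng.normal(size=(20, 2)), rng.normal(size=(20, 2)), n_perm=10)


class TestForwardSelection:
    def test_planted_driver_selected_first(self, rng):
        n = 60
        temp = np.linspace(10, 25, n) + rng.normal(0, 0.5, n)
        X = np.column_stack([temp] + [rng.normal(size=n) for _ in range(4)])
        Y = np.outer(temp, rng.uniform(0.5, 1.5, 5)) + rng.normal(0, 1.0, (n, 5))
        names = ["temperature", "x1", "x2", "x3", "x4"]
        chosen = forward_select_env(Y, X, names=names, n_perm=99, rng=0)
        assert chosen and chosen[0] == "temperature"

    def test_pure_noise_selects_nothing_usually(self, rng):
        Y = rng.normal(size=(40, 4))
        X = rng.normal(size=(40, 3))
        chosen = forward_select_env(Y, X, alpha=0.01, n_perm=199, rng=0)
        assert len(chosen) <= 1

    def test_duplicate_column_never_selected_twice(self, rng):
        n = 50
        x = rng.normal(size=n)
        X = np.column_stack([x, x, rng.normal(size=n)])
        Y = np.outer(x, [1.0, 2.0]) + 0.1 * rng.normal(size=(n, 2))
        chosen = forward_select_env(Y, X, names=["x", "x_copy", "z"], n_perm=99, rng=0)
        assert not ({"x", "x_copy"} <= set(chosen))
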