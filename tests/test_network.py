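"""MI estimator, DPI, network inference, activity, DA, hidden-driver filter."""

import numpy as np
import pandas as pd
import pytest

import carsx
from carsx import ExpressionMatrix, Interactome, Regulon
from carsx.network import dpi_prune


class TestMutualInformation:
    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert carsx.mutual_information(x, y) == pytest.approx(
            carsx.mutual_information(y, x), abs=1e-14)

    @pytest.mark.parametrize("nb", [2, 4, 5, 10])
    def test_self_information_is_log_bins(self, nb):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20 * nb)  # n divisible by bins
        assert carsx.mutual_information(x, x, n_bins=nb) == pytest.approx(
            np.log(nb), abs=1e-12)

    def test_invariance_under_sign_flip(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        assert carsx.mutual_information(x, -x, n_bins=5) == pytest.approx(
            carsx.mutual_information(x, x, n_bins=5), abs=1e-12)

    def test_independent_uniforms_near_zero(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(10000), rng.random(10000)
        assert carsx.mutual_information(x, y, n_bins=10) < 0.02

    def test_constant_vector_flagged_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            mi = carsx.mutual_information(np.ones(50), np.arange(50.0))
        assert mi == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="8"):
            carsx.mutual_information(np.arange(5.0), np.arange(5.0))


class TestDPI:
    def test_weakest_triangle_edge_removed(self):
        edges = {(0, 1): 1.0, (1, 2): 0.9, (0, 2): 0.3}
        pruned = dpi_prune(edges)
        assert set(pruned) == {(0, 1), (1, 2)}

    def test_tolerance_spares_borderline_edge(self):
        edges = {(0, 1): 1.0, (1, 2): 0.9, (0, 2): 0.85}
        assert set(dpi_prune(edges, tolerance=0.1)) == set(edges)
        assert set(dpi_prune(edges, tolerance=0.0)) == {(0, 1), (1, 2)}

    def test_marks_applied_after_all_triangles(self):
        # two triangles sharing the weak edge: removed once, others intact
        edges = {(0, 1): 1.0, (1, 2): 0.9, (0, 2): 0.2,
                 (2, 3): 0.8, (0, 3): 0.7}
        pruned = dpi_prune(edges)
        assert (0, 2) not in pruned
        assert (0, 3) in pruned

    def test_matches_bruteforce_triangle_enumeration(self):
        rng = np.random.default_rng(4)
        nodes = range(8)
        edges = {}
        for i in nodes:
            for j in nodes:
                if i < j and rng.random() < 0.5:
                    edges[(i, j)] = float(rng.random())
        # oracle: independent exhaustive scan over all node triples
        doomed = set()
        for i in nodes:
            for j in nodes:
                for t in nodes:
                    if not (i < j < t):
                        continue
                    trio = [(i, j), (i, t), (j, t)]
                    if not all(e in edges for e in trio):
                        continue
                    trio.sort(key=lambda e: edges[e])
                    if (edges[trio[0]] < edges[trio[1]]
                            and edges[trio[0]] < edges[trio[2]]):
                        doomed.add(trio[0])
        assert set(dpi_prune(edges)) == set(edges) - doomed


class TestInferNetwork:
    def test_regulon_recovery_small_scale(self, regulon_population):
        expr, truth = regulon_population
        net = carsx.infer_network(expr, sorted(truth.driver_regulons),
                                  n_bootstraps=30, seed=0)
        for driver, targets in truth.driver_regulons.items():
            true_t = {g for g, _ in targets}
            inferred = set(net.regulons[driver].targets["target"])
            tp = len(true_t & inferred)
            assert tp / len(true_t) >= 0.85
            assert tp / max(1, len(inferred)) >= 0.85

    def test_recovered_signs_match_planted(self, regulon_population):
        expr, truth = regulon_population
        net = carsx.infer_network(expr, sorted(truth.driver_regulons),
                                  n_bootstraps=20, seed=1)
        for driver, targets in truth.driver_regulons.items():
            inferred = dict(zip(net.regulons[driver].targets["target"],
                                net.regulons[driver].targets["sign"]))
            agree = [inferred[g] == s for g, s in targets if g in inferred]
            assert np.mean(agree) > 0.95

    def test_negative_construction_gets_negative_sign(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=300)
        t = -d + rng.normal(0, 0.2, 300)
        expr = ExpressionMatrix(pd.DataFrame(
            [d, t, rng.normal(size=300)], index=["D", "T", "N"]))
        net = carsx.infer_network(expr, ["D"], n_bootstraps=1,
                                  consensus_p=None, seed=0)
        tgt = net.regulons["D"].targets.set_index("target")
        assert tgt.loc["T", "sign"] == -1

    def test_chain_indirect_edge_removed_by_dpi(self):
        removed = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = 200
            x = rng.normal(0, 1, n)
            y = x + rng.normal(0, 0.4, n)
            z = y + rng.normal(0, 0.4, n)
            expr = ExpressionMatrix(pd.DataFrame([x, y, z],
                                                 index=["X", "Y", "Z"]))
            net = carsx.infer_network(expr, ["X", "Y"], n_bootstraps=1,
                                      consensus_p=None, seed=seed)
            xz = "Z" in set(net.regulons["X"].targets["target"])
            xy = "Y" in set(net.regulons["X"].targets["target"])
            yz = "Z" in set(net.regulons["Y"].targets["target"])
            removed += (not xz) and xy and yz
        assert removed >= 24

    def test_unknown_drivers_rejected(self, random_expression):
        with pytest.raises(ValueError, match="drivers"):
            carsx.infer_network(random_expression, ["NOPE"], n_bootstraps=1)

    def test_provenance_recorded(self, regulon_population):
        expr, truth = regulon_population
        net = carsx.infer_network(expr, [truth.driver_gene], n_bootstraps=5,
                                  consensus_p=0.05, dpi_tolerance=0.1, seed=2)
        assert net.params["n_bootstraps"] == 5
        assert net.params["consensus_p"] == 0.05
        assert net.params["dpi_tolerance"] == 0.1
        assert net.n_edges == sum(len(r) for r in net.regulons.values())


class TestComputeActivity:
    def _zscale(self, v):
        return (v - v.mean()) / v.std(ddof=1)

    def test_single_target_equals_zscaled_expression(self, random_expression):
        gene = random_expression.genes[3]
        reg = Regulon("DRV", pd.DataFrame(
            {"target": [gene], "mi": [0.7], "sign": [1]}))
        act = carsx.compute_activity(random_expression, Interactome({"DRV": reg}))
        expected = self._zscale(random_expression.values.loc[gene])
        np.testing.assert_allclose(act.values.loc["DRV"], expected, atol=1e-12)

    def test_opposite_signs_closed_form(self, random_expression):
        g1, g2 = random_expression.genes[0], random_expression.genes[1]
        reg = Regulon("DRV", pd.DataFrame(
            {"target": [g1, g2], "mi": [0.5, 0.5], "sign": [1, -1]}))
        act = carsx.compute_activity(random_expression, Interactome({"DRV": reg}))
        z1 = self._zscale(random_expression.values.loc[g1])
        z2 = self._zscale(random_expression.values.loc[g2])
        np.testing.assert_allclose(act.values.loc["DRV"], (z1 - z2) / 2,
                                   atol=1e-12)

    def test_weight_rescaling_invariance(self, random_expression):
        genes = list(random_expression.genes[:4])
        t1 = pd.DataFrame({"target": genes, "mi": [0.1, 0.2, 0.3, 0.4],
                           "sign": [1, -1, 1, 1]})
        t2 = t1.assign(mi=t1["mi"] * 7.5)
        a1 = carsx.compute_activity(
            random_expression, Interactome({"D": Regulon("D", t1)}))
        a2 = carsx.compute_activity(
            random_expression, Interactome({"D": Regulon("D", t2)}))
        np.testing.assert_allclose(a1.values.to_numpy(), a2.values.to_numpy(),
                                   atol=1e-12)

    def test_inferred_activity_tracks_latent(self, regulon_population):
        expr, truth = regulon_population
        act = carsx.compute_activity(
            expr, Interactome(carsx.true_regulons(truth)))
        for driver in truth.driver_regulons:
            r = np.corrcoef(act.values.loc[driver],
                            truth.latent_activity.loc[driver])[0, 1]
            assert r > 0.9

    def test_absent_regulon_omitted_with_warning(self, random_expression):
        regs = {
            "GOOD": Regulon("GOOD", pd.DataFrame(
                {"target": [random_expression.genes[0]], "mi": [1.0],
                 "sign": [1]})),
            "GONE": Regulon("GONE", pd.DataFrame(
                {"target": ["ABSENT"], "mi": [1.0], "sign": [1]})),
        }
        with pytest.warns(UserWarning, match="GONE"):
            act = carsx.compute_activity(random_expression, Interactome(regs))
        assert list(act.values.index) == ["GOOD"]


class TestDifferentialActivityAndHiddenDrivers:
    def test_label_swap_negates_da_z(self, regulon_population):
        expr, truth = regulon_population
        act = carsx.compute_activity(
            expr, Interactome(carsx.true_regulons(truth)))
        groups = carsx.group_series(truth, expr.samples)
        a = carsx.differential_activity(act, groups, "responder",
                                        "nonresponder")
        b = carsx.differential_activity(act, groups, "nonresponder",
                                        "responder")
        np.testing.assert_allclose(a["z"], -b["z"], atol=1e-8)

    def test_planted_driver_has_top_da(self, regulon_population):
        expr, truth = regulon_population
        act = carsx.compute_activity(
            expr, Interactome(carsx.true_regulons(truth)))
        da = carsx.differential_activity(
            act, carsx.group_series(truth, expr.samples),
            "responder", "nonresponder")
        assert da["z"].abs().idxmax() == truth.driver_gene

    def test_filter_rules(self):
        da = pd.DataFrame({"z": [2.5, 2.5, 1.0], "ave_expr": [1.0, 0.5, 2.0]},
                          index=["KEEP", "EXPR_UP", "WEAK"])
        de = pd.DataFrame({"z": [-0.5, 0.5, -3.0]},
                          index=["KEEP", "EXPR_UP", "WEAK"])
        hidden = carsx.hidden_drivers(da, de)
        assert hidden.index.tolist() == ["KEEP"]

    def test_ranked_by_z_da_descending(self):
        da = pd.DataFrame({"z": [2.1, 4.0, 3.0],
                           "ave_expr": [9.0, 1.0, 5.0]},
                          index=["C", "A", "B"])
        de = pd.DataFrame({"z": [-1.0, -1.0, -1.0]}, index=["C", "A", "B"])
        hidden = carsx.hidden_drivers(da, de)
        assert hidden.index.tolist() == ["A", "B", "C"]
        assert hidden["rank_by_activity"].tolist() == [3, 2, 1]

    def test_disjoint_tables_rejected(self):
        da = pd.DataFrame({"z": [1.0], "ave_expr": [0.0]}, index=["A"])
        de = pd.DataFrame({"z": [1.0]}, index=["B"])
        with pytest.raises(ValueError, match="shared"):
            carsx.hidden_drivers(da, de)

    def test_hidden_phenocopy_recovered(self):
        """Activity-up / expression-down driver passes the filter and wins."""
        cfg = carsx.SimConfig.regulon_defaults(
            seed=21, n_genes=60, targets_per_driver=8,
            n_samples_per_group_per_species=150,
            driver_mrna_coupled=False, driver_mrna_shift=-0.3)
        expr, truth = carsx.simulate_regulon_population(cfg)
        groups = carsx.group_series(truth, expr.samples)
        act = carsx.compute_activity(
            expr, Interactome(carsx.true_regulons(truth)))
        da = carsx.differential_activity(act, groups, "responder",
                                         "nonresponder")
        de = carsx.moderated_two_group(expr, groups, "responder",
                                       "nonresponder")
        hidden = carsx.hidden_drivers(da, de)
        assert hidden.index[0] == truth.driver_gene
        assert de.loc[truth.driver_gene, "z"] < 0


class TestSklearnInterface:
    def test_network_estimator_fit_transform(self, regulon_population):
        expr, truth = regulon_population
        est = carsx.MutualInfoNetwork(drivers=sorted(truth.driver_regulons),
                                      n_bootstraps=10, random_state=0)
        X = expr.values.T  # samples x genes
        act = est.fit(X).transform(X)
        assert act.shape == (X.shape[0], len(est.regulons_))

    def test_get_params_round_trip(self):
        est = carsx.MutualInfoNetwork(drivers=["A"], n_bootstraps=7)
        params = est.get_params()
        clone = carsx.MutualInfoNetwork(**params)
        assert clone.n_bootstraps == 7
        assert clone.drivers == ["A"]
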