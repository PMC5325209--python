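import numpy as np
import pytest
from xml.etree import ElementTree as ET

from silacswap.gsa import (
    GsaModel,
    GsaResult,
    combine_study_sets,
    export_association_network,
    mgsa_enumerate,
    mgsa_mcmc,
    perturbed_terms,
    write_graphml,
)
from silacswap.simulate import simulate_annotations


def _items(n):
    return tuple(f"item{i:04d}" for i in range(n))


def _model_from_sim(n_terms, n_items, seed, **kwargs):
    anno, active, study = simulate_annotations(
        n_terms, n_items, seed=seed, **kwargs
    )
    model = GsaModel(annotations=anno, items=_items(n_items),
                     study_set=frozenset(study))
    return model, active


class TestEnumeration:
    def test_noise_free_study_set_pins_term(self):
        # near-zero alpha/beta grids; study set equals one term's items
        anno = {
            "t0": frozenset({"item0000", "item0001", "item0002"}),
            "t1": frozenset({"item0005", "item0006"}),
        }
        model = GsaModel(
            annotations=anno, items=_items(10),
            study_set=anno["t0"],
            alpha_grid=(0.001,), beta_grid=(0.001,), p_grid=(0.1,),
        )
        res = mgsa_enumerate(model)
        by_term = dict(zip(res.terms, res.posterior))
        assert by_term["t0"] > 0.99
        assert by_term["t1"] <= 0.1 + 1e-6  # no more than its prior

    def test_identical_terms_get_equal_posteriors(self):
        shared = frozenset({"item0000", "item0001", "item0002", "item0003"})
        model = GsaModel(
            annotations={"t0": shared, "t1": shared},
            items=_items(12),
            study_set=frozenset({"item0000", "item0001", "item0002"}),
        )
        res = mgsa_enumerate(model)
        assert res.posterior[0] == pytest.approx(res.posterior[1], abs=1e-12)

    def test_union_of_k_terms_ranks_them_top(self):
        anno = {
            "t0": frozenset({"item0000", "item0001"}),
            "t1": frozenset({"item0002", "item0003", "item0004"}),
            "t2": frozenset({"item0006", "item0007"}),
            "t3": frozenset({"item0008"}),
        }
        study = anno["t0"] | anno["t1"]
        model = GsaModel(
            annotations=anno, items=_items(20), study_set=study,
            alpha_grid=(0.001,), beta_grid=(0.001,),
        )
        res = mgsa_enumerate(model)
        order = np.argsort(-res.posterior)
        top2 = {res.terms[i] for i in order[:2]}
        assert top2 == {"t0", "t1"}

    def test_term_limit_enforced(self):
        anno = {f"t{i}": frozenset({f"item{i:04d}"}) for i in range(16)}
        model = GsaModel(annotations=anno, items=_items(16),
                         study_set=frozenset())
        with pytest.raises(ValueError, match="enumeration limit"):
            mgsa_enumerate(model)

    def test_beta_monotonicity_for_absent_term(self):
        # term t1 annotates no study items.  A higher false-negative rate
        # makes observed-off items more compatible with an active term,
        # so its posterior is monotone non-decreasing in beta (and stays
        # far below the active-term posterior throughout).
        anno = {
            "t0": frozenset({"item0000", "item0001"}),
            "t1": frozenset({"item0005", "item0006", "item0007"}),
        }
        study = frozenset({"item0000", "item0001"})
        posts_absent, posts_active = [], []
        for beta in (0.05, 0.15, 0.3):
            model = GsaModel(
                annotations=anno, items=_items(10), study_set=study,
                alpha_grid=(0.05,), beta_grid=(beta,), p_grid=(0.2,),
            )
            res = mgsa_enumerate(model)
            by_term = dict(zip(res.terms, res.posterior))
            posts_absent.append(by_term["t1"])
            posts_active.append(by_term["t0"])
        assert posts_absent[0] <= posts_absent[1] <= posts_absent[2] + 1e-12
        assert all(a < b for a, b in zip(posts_absent, posts_active))


class TestMcmc:
    def test_recovers_active_term(self):
        model, active = _model_from_sim(
            6, 300, seed=5, items_per_term=20, n_active=1, alpha=0.05, beta=0.2
        )
        res = mgsa_mcmc(model, n_runs=4, n_steps=30_000, seed=1)
        by_term = dict(zip(res.terms, res.posterior))
        assert by_term[active[0]] > 0.5
        for t, p in by_term.items():
            if t != active[0]:
                assert p < 0.5

    def test_seed_determinism(self):
        model, _ = _model_from_sim(5, 100, seed=2, items_per_term=10,
                                   n_active=1, alpha=0.1, beta=0.2)
        r1 = mgsa_mcmc(model, n_runs=3, n_steps=5000, seed=9)
        r2 = mgsa_mcmc(model, n_runs=3, n_steps=5000, seed=9)
        np.testing.assert_array_equal(r1.posterior, r2.posterior)
        np.testing.assert_array_equal(r1.run_sd, r2.run_sd)

    def test_agrees_with_enumeration(self):
        model, _ = _model_from_sim(5, 150, seed=3, items_per_term=(5, 15),
                                   n_active=2, alpha=0.1, beta=0.3)
        ex = mgsa_enumerate(model)
        mc = mgsa_mcmc(model, n_runs=4, n_steps=40_000, seed=4)
        assert np.abs(ex.posterior - mc.posterior).mean() < 0.05

    def test_disjoint_seed_sets_agree(self):
        model, _ = _model_from_sim(4, 120, seed=6, items_per_term=15,
                                   n_active=1, alpha=0.05, beta=0.2)
        r1 = mgsa_mcmc(model, n_runs=4, n_steps=30_000, seed=11)
        r2 = mgsa_mcmc(model, n_runs=4, n_steps=30_000, seed=12)
        pooled_sd = np.sqrt((r1.run_sd**2 + r2.run_sd**2) / 2) + 1e-3
        assert (np.abs(r1.posterior - r2.posterior) <= 3 * pooled_sd + 0.02).all()


class TestPerturbedTerms:
    def _result(self, posts):
        return GsaResult(
            terms=[f"t{i}" for i in range(len(posts))],
            posterior=np.asarray(posts), run_sd=np.zeros(len(posts)),
            n_runs=1, n_steps=1,
        )

    def test_all_below_threshold_empty(self):
        assert perturbed_terms(self._result([0.1, 0.45, 0.3])) == []

    def test_single_hit(self):
        hits = perturbed_terms(self._result([0.65, 0.2]))
        assert hits == [("t0", 0.65)]

    def test_zero_threshold_returns_all_sorted(self):
        hits = perturbed_terms(self._result([0.2, 0.9, 0.5]), threshold=0.0)
        assert [t for t, _ in hits] == ["t1", "t2", "t0"]


class TestModelValidation:
    def test_study_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            GsaModel(annotations={"t": frozenset({"item0000"})},
                     items=_items(3), study_set=frozenset({"zzz"}))

    def test_term_with_no_universe_items_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            model = GsaModel(
                annotations={"t0": frozenset({"item0000"}),
                             "t1": frozenset({"outside"})},
                items=_items(3), study_set=frozenset(),
            )
        assert list(model.annotations) == ["t0"]

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            GsaModel(annotations={"t": frozenset({"item0000"})},
                     items=_items(2), study_set=frozenset(),
                     alpha_grid=(0.0, 0.5))


class TestNetworkExport:
    def test_full_bipartite_edges(self):
        anno = {"t0": frozenset({"p1", "p2", "p3"}),
                "t1": frozenset({"p1", "p2", "p3"})}
        edges = export_association_network({"p1", "p2", "p3"}, anno)
        assert len(edges) == 6

    def test_isolated_protein_row(self):
        edges = export_association_network({"p1"}, {"t0": frozenset({"p9"})})
        assert len(edges) == 1
        assert edges.iloc[0]["term"] == ""

    def test_graphml_round_trip(self, tmp_path):
        anno = {"t0": frozenset({"p1", "p2"})}
        edges = export_association_network(
            {"p1", "p2"}, anno, evidence={("p1", "t0"): "IDA"}
        )
        path = tmp_path / "net.graphml"
        write_graphml(edges, path)
        root = ET.parse(path).getroot()
        graph = root.find("graph")
        assert len(graph.findall("node")) == 3  # p1, p2, t0
        assert len(graph.findall("edge")) == 2
        data = graph.findall("edge")[0].find("data")
        assert data is not None and data.text == "IDA"


class TestCombineStudySets:
    def test_union_and_intersection_modes(self):
        u1, u2 = ("a", "b", "c"), ("b", "c", "d")
        s1, s2 = frozenset({"a"}), frozenset({"d"})
        uni_u, study_u = combine_study_sets([u1, u2], [s1, s2], "union")
        assert set(uni_u) == {"a", "b", "c", "d"}
        assert study_u == {"a", "d"}
        uni_i, study_i = combine_study_sets([u1, u2], [s1, s2], "intersection")
        assert set(uni_i) == {"b", "c"}
        assert study_i == frozenset()

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            combine_study_sets([("a",)], [frozenset()], "both")
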