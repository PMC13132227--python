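"""Order-of-acquisition diffusion analysis: likelihood, fitting, AICc, %ST."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from flocklearn.nbda import (
    Diffusion,
    DiffusionRecord,
    ILVDesign,
    ModelSpec,
    NBDAFit,
    NBDAParameters,
    aicc_model_table,
    family_support,
    fit_oada,
    oada_negloglik,
    percent_social,
    simulate_diffusion,
)
from flocklearn.network import AssociationNetwork


def network_from(ids, edges):
    w = np.zeros((len(ids), len(ids)))
    index = {i: k for k, i in enumerate(ids)}
    for (a, b), v in edges.items():
        w[index[a], index[b]] = w[index[b], index[a]] = v
    return AssociationNetwork(ids, w)


def record_one(site, learners, risk, seeded=()):
    return DiffusionRecord((Diffusion(site, tuple(learners),
                                      frozenset(risk), frozenset(seeded)),))


def enumeration_total_probability(net, params, risk, seeded, ilvs=None):
    """Independent oracle: sum of order probabilities over all complete
    acquisition orders must be 1."""
    total = 0.0
    for order in itertools.permutations(sorted(risk)):
        rec = record_one("sim", order, risk, seeded)
        kwargs = {"ilvs": ilvs} if ilvs is not None else {}
        total += math.exp(-oada_negloglik(rec, net, params, **kwargs))
    return total


class TestLikelihood:
    def test_asocial_uniform_null(self):
        """With s=0 and no covariates the order is uniform: NLL = log 4!."""
        ids = ["a", "b", "c", "d"]
        net = network_from(ids, {})
        rec = record_one("x", ids, ids)
        nll = oada_negloglik(rec, net, NBDAParameters(s=0.0))
        assert nll == pytest.approx(math.log(24), abs=1e-12)

    def test_single_edge_worked_example(self):
        """a_AB=1, C isolated, A informed, s=10: first event p=11/12."""
        net = network_from(["A", "B", "C"], {("A", "B"): 1.0})
        rec = record_one("x", ["B", "C"], ["B", "C"], seeded=["A"])
        nll = oada_negloglik(rec, net, NBDAParameters(s=10.0))
        assert nll == pytest.approx(-math.log(11 / 12), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_total_probability_enumeration(self, seed):
        """Brute-force oracle: probabilities over all 5! orders sum to 1."""
        rng = np.random.default_rng(seed)
        ids = [f"i{k}" for k in range(5)]
        w = rng.uniform(0, 1, (5, 5))
        w = np.triu(w, 1)
        net = AssociationNetwork(ids, w + w.T)
        params = NBDAParameters(s=float(rng.uniform(0, 8)),
                                gamma={"sex": 0.4}, beta={"age": -0.3})
        import pandas as pd

        ilvs = ILVDesign(pd.DataFrame(
            {"sex": rng.choice([-0.5, 0, 0.5], 5),
             "age": rng.choice([-0.5, 0, 0.5], 5)}, index=ids))
        total = enumeration_total_probability(
            net, params, ids, seeded=[], ilvs=ilvs)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_relabelling_invariance(self):
        ids = ["a", "b", "c"]
        net = network_from(ids, {("a", "b"): 0.4, ("b", "c"): 0.7})
        rec = record_one("x", ["b", "a", "c"], ids, seeded=[])
        nll = oada_negloglik(rec, net, NBDAParameters(s=3.0))
        relabel = {"a": "z", "b": "y", "c": "x"}
        net2 = network_from(["z", "y", "x"],
                            {("z", "y"): 0.4, ("y", "x"): 0.7})
        rec2 = record_one("x", ["y", "z", "x"], ["z", "y", "x"])
        assert oada_negloglik(rec2, net2, NBDAParameters(s=3.0)) == \
            pytest.approx(nll)

    def test_learner_missing_from_risk_set_rejected(self):
        with pytest.raises(ValueError, match="not in risk set"):
            Diffusion("x", ("a",), frozenset({"b"}))

    def test_seeded_learner_conflict_rejected(self):
        with pytest.raises(ValueError, match="seeded"):
            Diffusion("x", ("a",), frozenset({"a"}), frozenset({"a"}))


class TestFitting:
    @staticmethod
    def _modular_network(n=24, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"i{k}" for k in range(n)]
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < n // 2) == (j < n // 2)
                p, hi = (0.6, 0.5) if same else (0.08, 0.15)
                if rng.random() < p:
                    w[i, j] = w[j, i] = rng.uniform(0.05, hi)
        return AssociationNetwork(ids, w)

    def test_asocial_fit_matches_closed_form(self):
        net = self._modular_network()
        diff = simulate_diffusion(net, NBDAParameters(s=2.0),
                                  risk_set=net.ids, seeded_informed=[],
                                  rng=0)
        rec = DiffusionRecord((diff,))
        fit = fit_oada(rec, net, ModelSpec(social=False))
        assert fit.k == 0
        assert fit.log_likelihood == pytest.approx(
            -oada_negloglik(rec, net, NBDAParameters(s=0.0)))

    def test_social_data_recovers_positive_s(self):
        net = self._modular_network()
        diffs = [simulate_diffusion(net, NBDAParameters(s=8.0),
                                    risk_set=net.ids,
                                    seeded_informed=[net.ids[0]], rng=s)
                 for s in range(3)]
        rec = DiffusionRecord(tuple(
            Diffusion(f"d{k}", d.learners, d.risk_set, d.seeded_informed)
            for k, d in enumerate(diffs)))
        fit = fit_oada(rec, net, ModelSpec(social=True))
        assert fit.params.s > 1.0
        asoc = fit_oada(rec, net, ModelSpec(social=False))
        assert fit.log_likelihood > asoc.log_likelihood + 2

    def test_reproducible(self):
        net = self._modular_network()
        diff = simulate_diffusion(net, NBDAParameters(s=4.0),
                                  risk_set=net.ids,
                                  seeded_informed=[net.ids[0]], rng=1)
        rec = DiffusionRecord((diff,))
        f1 = fit_oada(rec, net, ModelSpec(social=True))
        f2 = fit_oada(rec, net, ModelSpec(social=True))
        assert f1.params.s == f2.params.s


class TestAICc:
    def _fit(self, lnl, k, social=True):
        spec = ModelSpec(social=social,
                         social_ilvs=tuple(f"c{i}" for i in range(max(0, k - 1))) if social else (),
                         asocial_ilvs=() if social else tuple(f"c{i}" for i in range(k)))
        return NBDAFit(spec=spec, params=NBDAParameters(s=1.0 if social else 0.0),
                       log_likelihood=lnl, k=k, converged=True, n_events=50)

    def test_equal_models_share_weight(self):
        table = aicc_model_table([self._fit(-10.0, 1),
                                  self._fit(-10.0, 1, social=False)])
        assert np.allclose(table["akaike_weight"], [0.5, 0.5])

    def test_delta_two_gives_weight_ratio_e(self):
        table = aicc_model_table([self._fit(-10.0, 1),
                                  self._fit(-11.0, 1, social=False)])
        w = table.sort_values("aicc")["akaike_weight"].to_numpy()
        assert w[0] / w[1] == pytest.approx(math.e)

    def test_formula(self):
        table = aicc_model_table([self._fit(-10.0, 2)])
        n, k = 50, 2
        assert table["aicc"].iloc[0] == pytest.approx(
            2 * k + 20.0 + 2 * k * (k + 1) / (n - k - 1))

    def test_family_sums(self):
        table = aicc_model_table([self._fit(-10.0, 1),
                                  self._fit(-10.5, 1),
                                  self._fit(-12.0, 0, social=False)])
        fam = family_support(table)
        assert fam["social"] + fam["asocial"] == pytest.approx(1.0)
        assert fam["social"] == pytest.approx(
            table.loc[table.family == "social", "akaike_weight"].sum())

    def test_small_n_rejected(self):
        fit = self._fit(-10.0, 2)
        with pytest.raises(ValueError, match="AICc undefined"):
            aicc_model_table([fit], n_events=3)


class TestPercentSocial:
    def test_zero_s_gives_zero(self):
        net = network_from(["a", "b"], {("a", "b"): 1.0})
        rec = record_one("x", ["b"], ["b"], seeded=["a"])
        fit = NBDAFit(spec=ModelSpec(social=True),
                      params=NBDAParameters(s=0.0),
                      log_likelihood=-oada_negloglik(
                          rec, net, NBDAParameters(s=0.0)),
                      k=1, converged=True, n_events=1)
        out = percent_social(fit, rec, net)
        assert out["estimate"] == pytest.approx(0.0)

    def test_single_event_ratio(self):
        """Social term 9 vs asocial 1 -> 90% of that event."""
        net = network_from(["a", "b"], {("a", "b"): 1.0})
        rec = record_one("x", ["b"], ["b"], seeded=["a"])
        fit = NBDAFit(spec=ModelSpec(social=True),
                      params=NBDAParameters(s=9.0),
                      log_likelihood=-oada_negloglik(
                          rec, net, NBDAParameters(s=9.0)),
                      k=1, converged=True, n_events=1)
        out = percent_social(fit, rec, net)
        assert out["estimate"] == pytest.approx(90.0)
        lo, hi = out["ci"]
        assert lo <= out["estimate"] <= hi

    def test_asocial_fit_rejected(self):
        net = network_from(["a", "b"], {})
        rec = record_one("x", ["b"], ["a", "b"])
        fit = fit_oada(rec, net, ModelSpec(social=False))
        with pytest.raises(ValueError, match="social model"):
            percent_social(fit, rec, net)


class TestSimulator:
    def test_strong_s_hub_neighbour_learns_first(self):
        net = network_from(["hub", "n", "far"], {("hub", "n"): 1.0})
        for seed in range(20):
            diff = simulate_diffusion(net, NBDAParameters(s=1e9),
                                      risk_set=["n", "far"],
                                      seeded_informed=["hub"], rng=seed)
            assert diff.learners[0] == "n"

    def test_asocial_order_uniform(self):
        """With s=0 the full order is uniform over the 4! permutations."""
        ids = ["a", "b", "c", "d"]
        net = network_from(ids, {})
        rng = np.random.default_rng(7)
        counts: dict[tuple, int] = {}
        for _ in range(5000):
            d = simulate_diffusion(net, NBDAParameters(s=0.0),
                                   risk_set=ids, rng=rng)
            counts[d.learners] = counts.get(d.learners, 0) + 1
        observed = [counts.get(p, 0)
                    for p in itertools.permutations(ids)]
        assert chisquare(observed).pvalue > 0.01

    def test_seed_reproducible(self):
        ids = [f"i{k}" for k in range(8)]
        net = network_from(ids, {(f"i{k}", f"i{k+1}"): 0.5
                                 for k in range(7)})
        d1 = simulate_diffusion(net, NBDAParameters(s=3.0), risk_set=ids,
                                seeded_informed=["i0"], rng=42)
        d2 = simulate_diffusion(net, NBDAParameters(s=3.0), risk_set=ids,
                                seeded_informed=["i0"], rng=42)
        assert d1 == d2

    def test_empty_risk_set_rejected(self):
        net = network_from(["a"], {})
        with pytest.raises(ValueError, match="empty risk set"):
            simulate_diffusion(net, NBDAParameters(s=1.0), risk_set=[])

    def test_monotone_social_probability(self):
        """A stronger s raises the chance the seeded bird's only associate
        learns first."""
        net = network_from(["d", "x", "y", "z"], {("d", "x"): 1.0})
        rec = record_one("m", ["x"], ["x", "y", "z"], seeded=["d"])
        probs = [math.exp(-oada_negloglik(rec, net, NBDAParameters(s=s)))
                 for s in (0.0, 1.0, 5.0, 50.0)]
        assert all(b > a for a, b in zip(probs, probs[1:]))
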