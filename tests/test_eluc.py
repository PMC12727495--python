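"""Transient-density scaling of land-use-change emissions and delta-L."""

import numpy as np
import pytest

from carbonledger import FluxSeries
from carbonledger.eluc import (
    ELUC_SUBCOMPONENTS,
    ElucComponents,
    apply_transient_scaling,
    component_ratios,
    delta_L,
    dersimonian_laird,
)


def make_model(model_id, years, mode="static", scale=1.0, factors=None):
    """Subcomponent table with simple prescribed levels, optionally scaled
    per component by ``factors``."""
    base = {
        "deforestation": 1.4,
        "regrowth": -0.4,
        "harvest_src": 0.3,
        "harvest_snk": -0.2,
        "other": 0.05,
    }
    factors = factors or {}
    comps = {
        name: np.full(years.size, base[name] * scale * factors.get(name, 1.0))
        for name in ELUC_SUBCOMPONENTS
    }
    return ElucComponents(model_id, years, comps, mode)


@pytest.fixture()
def yrs():
    return np.arange(2000, 2010)


class TestComponentRatios:
    def test_identical_runs_give_unit_ratios(self, yrs):
        pair = (make_model("m", yrs), make_model("m", yrs, "transient"))
        ratios = component_ratios([pair])
        for name in ELUC_SUBCOMPONENTS:
            assert ratios[name] == pytest.approx(1.0)

    def test_reference_models_are_averaged(self, yrs):
        f1 = {name: 1.2 for name in ELUC_SUBCOMPONENTS}
        f2 = {name: 1.0 for name in ELUC_SUBCOMPONENTS}
        pairs = [
            (make_model("a", yrs), make_model("a", yrs, "transient", factors=f1)),
            (make_model("b", yrs), make_model("b", yrs, "transient", factors=f2)),
        ]
        ratios = component_ratios(pairs)
        for name in ELUC_SUBCOMPONENTS:
            assert ratios[name] == pytest.approx(1.1)

    def test_ratios_match_direct_quotients(self, yrs):
        """Brute-force oracle: recompute each pair's per-component quotient
        directly and average."""
        rng = np.random.default_rng(5)
        pairs = []
        oracle = {name: np.zeros(yrs.size) for name in ELUC_SUBCOMPONENTS}
        for mid in ("a", "b"):
            static = make_model(mid, yrs, scale=1 + rng.random())
            tr_comps = {
                name: static.components[name] * (1 + rng.random(yrs.size))
                for name in ELUC_SUBCOMPONENTS
            }
            transient = ElucComponents(mid, yrs, tr_comps, "transient")
            pairs.append((static, transient))
            for name in ELUC_SUBCOMPONENTS:
                oracle[name] += (
                    transient.components[name] / static.components[name]
                ) / 2
        ratios = component_ratios(pairs)
        for name in ELUC_SUBCOMPONENTS:
            np.testing.assert_allclose(ratios[name], oracle[name], atol=1e-12)

    def test_zero_static_flux_falls_back_to_unity(self, yrs):
        static = make_model("m", yrs)
        static.components["other"][:] = 0.0
        transient = make_model("m", yrs, "transient")
        with pytest.warns(UserWarning, match="fallback"):
            ratios = component_ratios([(static, transient)])
        assert ratios["other"] == pytest.approx(1.0)


class TestApplyScaling:
    def test_unit_ratios_are_identity(self, yrs):
        target = make_model("t", yrs)
        ratios = {name: np.ones(yrs.size) for name in ELUC_SUBCOMPONENTS}
        out = apply_transient_scaling(target, ratios)
        np.testing.assert_allclose(out.values, target.net.values, atol=1e-15)

    def test_single_component_scaling(self, yrs):
        comps = {name: np.zeros(yrs.size) for name in ELUC_SUBCOMPONENTS}
        comps["deforestation"] = np.ones(yrs.size)
        target = ElucComponents("t", yrs, comps, "static")
        ratios = {name: np.ones(yrs.size) for name in ELUC_SUBCOMPONENTS}
        ratios["deforestation"] = np.full(yrs.size, 1.3)
        assert apply_transient_scaling(target, ratios).values == pytest.approx(1.3)

    def test_ensemble_delta_matches_subtraction_oracle(self, yrs):
        """When every model shares the same density response, the ensemble-
        mean delta-L equals the difference of ensemble-mean net E_LUC
        (transient − static) computed by direct subtraction."""
        rng = np.random.default_rng(11)
        factor = 1.0 + 0.1 * rng.random(yrs.size)
        f = {name: factor for name in ELUC_SUBCOMPONENTS}
        statics, transients = [], []
        for i in range(4):
            static = make_model(f"m{i}", yrs, scale=1 + rng.random())
            statics.append(static)
            transients.append(
                ElucComponents(
                    f"m{i}",
                    yrs,
                    {n: static.components[n] * f[n] for n in ELUC_SUBCOMPONENTS},
                    "transient",
                )
            )
        # ratios from the first two pairs; scale the remaining two models
        ratios = component_ratios(list(zip(statics[:2], transients[:2])))
        deltas = []
        for s, t in zip(statics, transients):
            est = (
                t.net.values
                if s.model_id in ("m0", "m1")
                else apply_transient_scaling(s, ratios).values
            )
            deltas.append(est - s.net.values)
        mean_direct = np.mean(
            [t.net.values for t in transients], axis=0
        ) - np.mean([s.net.values for s in statics], axis=0)
        np.testing.assert_allclose(np.mean(deltas, axis=0), mean_direct,
                                   atol=1e-12)

    def test_requires_static_target(self, yrs):
        target = make_model("t", yrs, "transient")
        ratios = {name: np.ones(yrs.size) for name in ELUC_SUBCOMPONENTS}
        with pytest.raises(ValueError):
            apply_transient_scaling(target, ratios)


class TestDeltaL:
    def test_identical_models_reduce_to_within_sigma(self, yrs):
        s = np.full(yrs.size, 0.03)
        members = {
            m: FluxSeries("delta_L", yrs, np.full(yrs.size, 0.1), s)
            for m in ("a", "b", "c")
        }
        res = delta_L(members)
        assert res.delta == pytest.approx(0.1)
        assert res.sigma == pytest.approx(0.03, abs=1e-12)  # tau² = 0

    def test_two_model_dersimonian_laird_oracle(self, yrs):
        """Hand-computed DL combination of {0.10 ± 0.03, 0.12 ± 0.05}."""
        members = {
            "a": FluxSeries("delta_L", yrs, np.full(yrs.size, 0.10),
                            np.full(yrs.size, 0.03)),
            "b": FluxSeries("delta_L", yrs, np.full(yrs.size, 0.12),
                            np.full(yrs.size, 0.05)),
        }
        res = delta_L(members)
        assert res.delta == pytest.approx(0.11)
        # independent oracle: w1=1/9e-4, w2=1/2.5e-3
        w1, w2 = 1 / 0.03**2, 1 / 0.05**2
        ybar = (w1 * 0.10 + w2 * 0.12) / (w1 + w2)
        q = w1 * (0.10 - ybar) ** 2 + w2 * (0.12 - ybar) ** 2
        tau2 = max(0.0, (q - 1) / ((w1 + w2) - (w1**2 + w2**2) / (w1 + w2)))
        expected = np.sqrt(tau2 + (0.03**2 + 0.05**2) / 2)
        assert res.sigma == pytest.approx(expected, abs=1e-12)
        tau2_impl, _ = dersimonian_laird(
            np.array([0.10, 0.12]), np.array([0.03**2, 0.05**2])
        )
        assert tau2_impl == pytest.approx(tau2, abs=1e-15)

    def test_heterogeneous_models_inflate_sigma(self, yrs):
        members = {
            "a": FluxSeries("delta_L", yrs, np.full(yrs.size, 0.0),
                            np.full(yrs.size, 0.01)),
            "b": FluxSeries("delta_L", yrs, np.full(yrs.size, 0.4),
                            np.full(yrs.size, 0.01)),
        }
        res = delta_L(members)
        assert np.all(res.sigma > 0.1)  # spread dominates tiny within-sigma

    def test_cumulative_equals_running_sum(self, yrs):
        rng = np.random.default_rng(2)
        members = {
            m: FluxSeries("delta_L", yrs, rng.random(yrs.size),
                          np.full(yrs.size, 0.02))
            for m in ("a", "b", "c")
        }
        res = delta_L(members)
        np.testing.assert_allclose(res.cumulative, np.cumsum(res.delta),
                                   atol=1e-12)

    def test_linearity_in_ratio_perturbation(self, yrs):
        """Scaling (ratio − 1) by k scales delta-L by k when subcomponents
        are held fixed."""
        target = make_model("t", yrs)
        base = {n: np.full(yrs.size, 1.0 + 0.08) for n in ELUC_SUBCOMPONENTS}
        for k in (0.5, 2.0, 3.0):
            scaled = {n: 1.0 + k * (base[n] - 1.0) for n in ELUC_SUBCOMPONENTS}
            d1 = apply_transient_scaling(target, base).values - target.net.values
            dk = apply_transient_scaling(target, scaled).values - target.net.values
            np.testing.assert_allclose(dk, k * d1, atol=1e-9)

    def test_single_model_warns(self, yrs):
        members = {"only": FluxSeries("delta_L", yrs, np.full(yrs.size, 0.1),
                                      np.full(yrs.size, 0.04))}
        with pytest.warns(UserWarning, match="single"):
            res = delta_L(members)
        assert res.sigma == pytest.approx(0.04)
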