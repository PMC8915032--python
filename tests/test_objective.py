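"""Coefficients, mass balance, cost index, feasibility and metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ancdnet import (
    Allocation,
    CaseNetwork,
    ConfigurationError,
    ConstraintBounds,
    SynthSpec,
    biogas_estimate,
    blend_profile,
    check_feasibility,
    cost_index,
    evaluate,
    generate_network,
    performance_summary,
    quality_coefficients,
)
from ancdnet.evaluator import VectorEvaluator
from ancdnet.objective import digester_volume, network_quality_coefficients

from conftest import make_receptor, make_source

BOUNDS = ConstraintBounds()


class TestQualityCoefficients:
    def test_zero_toxicity_gives_full_t(self):
        qc = quality_coefficients(make_source(toxicity=0.0), BOUNDS)
        assert qc.t == 1.0

    def test_w8_toxicity_clamps_to_zero(self, baseline):
        # toxicity 2.30 mg Pb/L above the 2.1 ceiling: 1 - 2.30/2.1 < 0 -> 0
        qc = quality_coefficients(baseline.get_source("W8"), BOUNDS)
        assert qc.t == 0.0

    def test_t_non_increasing_in_toxicity(self):
        ts = [quality_coefficients(make_source(toxicity=x), BOUNDS).t for x in (0, 0.5, 1.0, 2.0, 3.0)]
        assert all(b <= a for a, b in zip(ts, ts[1:]))

    @pytest.mark.parametrize(
        "cn, expected",
        [
            (40.0, 1.0),       # plateau interior
            (20.0, 1.0),       # plateau edge
            (60.0, 1.0),
            (15.0, 0.5),       # halfway down the 10-wide shoulder (width 0.25*40)
            (9.9, 0.0),        # beyond the shoulder
            (70.1, 0.0),
        ],
    )
    def test_cn_membership(self, cn, expected):
        qc = quality_coefficients(make_source(cn_ratio=cn), BOUNDS)
        assert qc.f2 == pytest.approx(expected)

    def test_alkalinity_membership_plateau_and_beyond(self):
        assert quality_coefficients(make_source(alkalinity=4000), BOUNDS).f3 == 1.0
        assert quality_coefficients(make_source(alkalinity=20), BOUNDS).f3 == 0.0
        assert quality_coefficients(make_source(alkalinity=10000), BOUNDS).f3 == 0.0

    def test_f1_normalised_by_network_max(self, baseline):
        qcs = network_quality_coefficients(baseline)
        assert qcs["C1"].f1 == pytest.approx(1.0)  # C1 carries the highest COD
        assert qcs["W2"].f1 == pytest.approx(16900 / 667400)

    def test_figure2_mode_requires_equations(self):
        with pytest.raises(ConfigurationError, match="figure2"):
            quality_coefficients(make_source(), BOUNDS, mode="figure2")

    def test_figure2_mode_with_supplied_equations(self):
        eqs = {k: (lambda s, b: 0.5) for k in ("f1", "f2", "f3", "t")}
        qc = quality_coefficients(make_source(), BOUNDS, mode="figure2", equations=eqs)
        assert qc.f_sum == pytest.approx(1.5)


class TestBlendProfile:
    def test_two_stream_mass_balance_matches_hand_arithmetic(self, baseline):
        # independent oracle: direct weighted-sum arithmetic on the W1/C2 rows
        v1, v2 = 10000.0, 1000.0
        w1, c2 = baseline.get_source("W1"), baseline.get_source("C2")
        cod_conc = (v1 * w1.cod + v2 * c2.cod) / (v1 + v2)
        cn = (v1 * w1.cod + v2 * c2.cod) / (v1 * w1.cod / w1.cn_ratio + v2 * c2.cod / c2.cn_ratio)

        a = Allocation({("W1", "R1"): v1, ("C2", "R1"): v2})
        prof = blend_profile(a, baseline.get_receptor("R1"), baseline.sources)
        assert prof.cod_conc == pytest.approx(cod_conc)
        assert prof.cn_ratio == pytest.approx(cn)
        # frozen values from the oracle arithmetic
        assert prof.cod_conc == pytest.approx(63309.09, abs=0.01)
        assert prof.cn_ratio == pytest.approx(56.82, abs=0.01)

    def test_single_source_blend_is_identity(self):
        s = make_source()
        a = Allocation({("W1", "R1"): 5000.0})
        prof = blend_profile(a, make_receptor(), [s])
        assert prof.cod_conc == pytest.approx(s.cod)
        assert prof.cn_ratio == pytest.approx(s.cn_ratio)
        assert prof.alkalinity == pytest.approx(s.alkalinity)
        assert prof.toxicity == pytest.approx(s.toxicity)

    def test_empty_blend_flagged_undefined(self, empty_allocation):
        prof = blend_profile(empty_allocation, make_receptor(), [make_source()])
        assert prof.total_volume == 0
        assert not prof.defined
        assert math.isnan(prof.cod_conc)

    def test_with_base_mixes_receptor_own_stream(self):
        s = make_source(cod=20000, cn_ratio=30)
        r = make_receptor(base_feed_volume=5000.0, own_cod=10000, own_cn=15)
        a = Allocation({("W1", "R1"): 5000.0})
        prof = blend_profile(a, r, [s], mixing="with_base")
        assert prof.total_volume == 10000
        assert prof.cod_conc == pytest.approx(15000)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_blend_cn_bounded_by_constituents(self, data):
        """Mediant inequality: blend C/N lies within the constituent C/N range."""
        n = data.draw(st.integers(2, 5))
        cns = [data.draw(st.floats(5.0, 500.0)) for _ in range(n)]
        cods = [data.draw(st.floats(1000.0, 700000.0)) for _ in range(n)]
        vols = [data.draw(st.floats(100.0, 50000.0)) for _ in range(n)]
        sources = [
            make_source(f"S{i}", cod=cods[i], cn_ratio=cns[i], daily_volume=vols[i])
            for i in range(n)
        ]
        a = Allocation({(f"S{i}", "R1"): vols[i] for i in range(n)})
        prof = blend_profile(a, make_receptor(), sources)
        assert min(cns) * (1 - 1e-9) <= prof.cn_ratio <= max(cns) * (1 + 1e-9)


class TestCostIndex:
    def test_empty_allocation_scores_zero(self, baseline, empty_allocation):
        assert cost_index(empty_allocation, baseline) == (0.0, 0.0)

    def test_k_flips_sign_but_not_magnitude(self, two_source_net):
        a = Allocation({("A", "R1"): 2000.0})
        bs_pos, ba_pos = cost_index(a, two_source_net)
        two_source_net.params.K = -1
        bs_neg, ba_neg = cost_index(a, two_source_net)
        two_source_net.params.K = 1
        assert bs_neg == -bs_pos
        assert ba_neg == ba_pos

    def test_single_edge_unit_term(self):
        # v = V_w, T = 1 (tox 0), F sum = 1 (source holds the max COD so
        # f1 = 1, C/N and alkalinity far outside their shoulders so f2 = f3
        # = 0), negligible logistics -> B = 1 by hand substitution
        s = make_source(cn_ratio=5.0, alkalinity=0.01, toxicity=0.0, distance_km={"R1": 1e-4})
        net = CaseNetwork(sources=[s], receptors=[make_receptor()])
        a = Allocation({("W1", "R1"): s.daily_volume})
        _, b_abs = cost_index(a, net)
        assert b_abs == pytest.approx(1.0, rel=1e-5)

    def test_monotone_in_volume_with_nonnegative_coefficients(self, two_source_net):
        prev = 0.0
        for v in (0.0, 1000.0, 2000.0, 3000.0):
            a = Allocation({("A", "R1"): v} if v else {})
            _, b_abs = cost_index(a, two_source_net)
            assert b_abs >= prev
            prev = b_abs

    def test_penalty_mode_index_nonnegative(self, baseline):
        rng = np.random.default_rng(0)
        ev = VectorEvaluator(baseline)
        res = ev.evaluate(ev.decode(ev.random_indices(rng, 64)))
        assert (res["b_abs"] >= 0).all()


class TestFeasibility:
    def test_cn_above_ceiling_reported(self):
        s = make_source(cn_ratio=70.0)
        net = CaseNetwork(sources=[s], receptors=[make_receptor()])
        a = Allocation({("W1", "R1"): 5000.0})
        feasible, violations = check_feasibility(a, net)
        assert not feasible
        v = next(v for v in violations if v.constraint == "cn_max")
        assert v.where == "R1"
        assert v.observed == pytest.approx(70.0)
        assert v.bound == 60.0

    def test_cn_exactly_at_bound_is_feasible(self):
        s = make_source(cn_ratio=60.0)
        net = CaseNetwork(sources=[s], receptors=[make_receptor()])
        a = Allocation({("W1", "R1"): 5000.0})
        feasible, violations = check_feasibility(a, net)
        assert not any(v.constraint.startswith("cn") for v in violations)

    def test_receptor_capacity_violation_on_baseline(self, baseline):
        a = Allocation({("W2", "R1"): 47000.0, ("W3", "R1"): 46300.0, ("W5", "R1"): 37000.0})
        feasible, violations = check_feasibility(a, baseline)
        v = next(v for v in violations if v.constraint == "volume_max")
        assert v.where == "R1"
        assert v.observed == pytest.approx(130300.0)
        assert v.bound == 122000.0

    def test_empty_allocation_feasible(self, baseline, empty_allocation):
        feasible, violations = check_feasibility(empty_allocation, baseline)
        assert feasible and not violations


class TestBiogas:
    def test_unit_cod_mass_conversion(self):
        # a blend carrying exactly 1 kg COD/day at the default yield
        s = make_source(cod=100000.0)
        a = Allocation({("W1", "R1"): 10.0})
        prof = blend_profile(a, make_receptor(), [s])
        assert prof.cod_mass == pytest.approx(1.0)
        assert biogas_estimate([prof]) == pytest.approx(0.268)

    def test_c1_worked_example(self, baseline):
        # 9000 L/d of C1 at 667,400 mg/L -> 6006.6 kg COD -> 1609.77 m3/d
        a = Allocation({("C1", "R1"): 9000.0})
        prof = blend_profile(a, baseline.get_receptor("R1"), baseline.sources)
        assert prof.cod_mass == pytest.approx(6006.6)
        assert biogas_estimate([prof]) == pytest.approx(1609.77, abs=0.01)

    def test_empty_is_zero(self, baseline, empty_allocation):
        ev = evaluate(empty_allocation, baseline)
        assert ev.biogas_total == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.01, 3.0), st.integers(0, 10))
    def test_linear_in_volume_scaling(self, alpha, seed):
        net = generate_network(SynthSpec(3, 2, 1, seed=seed))
        rng = np.random.default_rng(seed)
        vols = {
            (s.id, "R1"): float(rng.integers(1, 5) * 100) for s in net.sources
        }
        base = evaluate(Allocation(vols), net).biogas_total
        scaled = evaluate(Allocation({k: v * alpha for k, v in vols.items()}), net).biogas_total
        assert scaled == pytest.approx(alpha * base, rel=1e-12)


class TestEvaluatorConsistency:
    """The vectorised solver path must agree with the readable public path."""

    @pytest.mark.parametrize("seed", range(5))
    def test_batch_matches_single_evaluation(self, seed):
        net = generate_network(SynthSpec(3, 2, 2, seed=seed))
        ev = VectorEvaluator(net)
        rng = np.random.default_rng(seed)
        idx = ev.random_indices(rng, 16)
        vols = ev.decode(idx)
        res = ev.evaluate(vols)
        for i in range(idx.shape[0]):
            a = ev.to_allocation(vols[i])
            _, b_abs = cost_index(a, net)
            feasible, _ = check_feasibility(a, net)
            assert res["b_abs"][i] == pytest.approx(b_abs, rel=1e-9, abs=1e-12)
            assert bool(res["feasible"][i]) == feasible

    def test_repair_yields_volume_feasible_grid_values(self):
        net = generate_network(SynthSpec(4, 2, 2, seed=3))
        ev = VectorEvaluator(net)
        rng = np.random.default_rng(1)
        vols = ev.repair(ev.decode(ev.random_indices(rng, 64)))
        for i in range(vols.shape[0]):
            a = ev.to_allocation(vols[i])
            a.validate_against(net)  # grid membership + source conservation
            for j, r in enumerate(net.receptors):
                assert vols[i, :, j].sum() <= r.max_external_volume * (1 + 1e-9)

    def test_repair_keeps_volume_feasible_candidates_unchanged(self, two_source_net):
        ev = VectorEvaluator(two_source_net)
        vols = ev.decode(np.array([[1, 1]]))  # 1000 + 1000 well under every cap
        assert np.array_equal(ev.repair(vols), vols)


class TestPerformanceSummary:
    def test_empty_evaluation(self, baseline, empty_allocation):
        summary = performance_summary(evaluate(empty_allocation, baseline), baseline)
        assert summary["best_index_b"] == 0.0
        assert summary["total_biogas_nm3_d"] == 0.0

    def test_equal_volume_average_cn(self):
        s1 = make_source("S1", cn_ratio=40.0, distance_km={"R1": 5, "R2": 5})
        s2 = make_source("S2", cn_ratio=50.0, distance_km={"R1": 5, "R2": 5})
        net = CaseNetwork(
            sources=[s1, s2], receptors=[make_receptor("R1"), make_receptor("R2")]
        )
        a = Allocation({("S1", "R1"): 5000.0, ("S2", "R2"): 5000.0})
        ev = evaluate(a, net)
        assert ev.avg_cn == pytest.approx(45.0)

    def test_organic_load_division(self):
        r = make_receptor(digester_volume=1000.0)
        s = make_source(cod=232000.0)
        net = CaseNetwork(sources=[s], receptors=[r])
        a = Allocation({("W1", "R1"): 10000.0})  # 2320 kg COD/day
        ev = evaluate(a, net)
        assert ev.organic_load["R1"] == pytest.approx(2.32)
        assert not ev.organic_load_derived

    def test_derived_digester_volume_uses_hrt(self):
        r = make_receptor(max_external_volume=122000.0)
        vol, derived = digester_volume(r, hrt_days=20.0)
        assert derived
        assert vol == pytest.approx(2440.0)  # 20 d x 122,000 L/d in m3
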