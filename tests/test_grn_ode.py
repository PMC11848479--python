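import numpy as np
import pytest
from scipy.optimize import brentq, fsolve

from grnkit import grn_ode
from grnkit.data_core import GenotypeSpec
from grnkit.grn_ode import (
    ACTIVATION,
    REPRESSION,
    LATE_L1_GENES,
    ODEModelSpec,
    ParameterSet,
    RegulationTerm,
    SteadyStateError,
    build_rhs,
    enumerate_logic_variants,
    genotype_panel,
    hill_activation,
    hill_repression,
    late_l1_terms,
    set_partitions,
    steady_state,
)

WT = GenotypeSpec("wild type", (1.0, 1.0, 1.0))


def bell(n):
    # Bell numbers via the recurrence B(n+1) = sum C(n,k) B(k)
    B = [1]
    for n_ in range(n):
        B.append(sum(_comb(n_, k) * B[k] for k in range(n_ + 1)))
    return B[n]


def _comb(n, k):
    import math

    return math.comb(n, k)


class TestEnumeration:
    def test_single_regulator_single_variant(self):
        terms = [RegulationTerm("g1", "g2", ACTIVATION)]
        specs = enumerate_logic_variants(("g1", "g2"), terms)
        assert len(specs) == 1

    def test_three_regulators_five_partitions(self):
        items = ["a", "b", "c"]
        parts = set_partitions(items)
        as_sets = [frozenset(frozenset(b) for b in p) for p in parts]
        expected = [
            {frozenset("a"), frozenset("b"), frozenset("c")},
            {frozenset("ab"), frozenset("c")},
            {frozenset("ac"), frozenset("b")},
            {frozenset("bc"), frozenset("a")},
            {frozenset("abc")},
        ]
        assert len(parts) == 5
        assert [set(s) for s in as_sets] == expected

    def test_late_l1_twenty_variants(self):
        specs = enumerate_logic_variants(LATE_L1_GENES, late_l1_terms())
        assert len(specs) == 20
        assert specs[0].variant_id == 1 and specs[0].is_all_or()
        assert specs[-1].variant_id == 20 and specs[-1].is_all_and()

    @pytest.mark.parametrize("counts", [(0,), (1,), (2,), (3,), (4,), (2, 3), (1, 4)])
    def test_variant_count_is_product_of_bell_numbers(self, counts):
        n_genes = max(counts) + len(counts) + 1
        genes = [f"g{i}" for i in range(n_genes)]
        terms = []
        for gi, c in enumerate(counts):
            for r in range(c):
                terms.append(
                    RegulationTerm(genes[gi], genes[len(counts) + r],
                                   ACTIVATION if r % 2 else REPRESSION)
                )
        specs = enumerate_logic_variants(genes, terms)
        expected = 1
        for c in counts:
            expected *= bell(c)
        assert len(specs) == expected

    def test_enumeration_deterministic(self):
        a = enumerate_logic_variants(LATE_L1_GENES, late_l1_terms())
        b = enumerate_logic_variants(LATE_L1_GENES, late_l1_terms())
        assert [s.blocks for s in a] == [s.blocks for s in b]

    def test_k_sharing_convention(self):
        # one k per regulator role; the self-loop keeps its own k
        spec = enumerate_logic_variants(LATE_L1_GENES, late_l1_terms())[0]
        assert sorted(spec.k_names()) == [
            "k:ceh-16:rep",
            "k:ceh-16:self",
            "k:egl-18:act",
            "k:elt-1:act",
        ]

    def test_all_or_parameter_count(self):
        spec = enumerate_logic_variants(LATE_L1_GENES, late_l1_terms())[0]
        assert len(spec.parameter_names()) == 3 + 7 + 4
        spec20 = enumerate_logic_variants(LATE_L1_GENES, late_l1_terms())[-1]
        assert len(spec20.parameter_names()) == 3 + 3 + 4


class TestHillFunctions:
    def test_half_occupation(self):
        assert hill_activation(5, 1.0, 10.0, 5.0) == pytest.approx(5.0)
        assert hill_repression(5, 1.0, 10.0, 5.0) == pytest.approx(5.0)

    def test_activation_zero_input(self):
        assert hill_activation(0.0, 1.0, 7.0, 3.0) == 0.0

    def test_activation_zero_k_saturates(self):
        assert hill_activation(2.0, 1.0, 10.0, 0.0) == pytest.approx(10.0)

    def test_activation_degenerate_zero_zero(self):
        assert hill_activation(0.0, 1.0, 10.0, 0.0) == 0.0

    def test_repression_no_repressor(self):
        assert hill_repression(0.0, 1.0, 4.0, 2.0) == pytest.approx(4.0)

    def test_repression_zero_k(self):
        assert hill_repression(3.0, 1.0, 4.0, 0.0) == 0.0

    def test_activity_fraction_scales_input(self):
        assert hill_activation(10.0, 0.5, 1.0, 5.0) == pytest.approx(
            hill_activation(5.0, 1.0, 1.0, 5.0)
        )

    def test_alpha_exponent(self):
        # (g f)^a / (k^a + (g f)^a) with a=3, g=2, k=2 -> 1/2
        assert hill_activation(2.0, 1.0, 8.0, 2.0, alpha=3.0) == pytest.approx(4.0)


def basal_spec(genes=("g1", "g2", "g3")):
    return ODEModelSpec(genes=tuple(genes), blocks={g: () for g in genes})


class TestBuildRhs:
    def test_basal_only(self):
        spec = basal_spec()
        params = ParameterSet(values={"b:g1": 5.0, "b:g2": 3.0, "b:g3": 2.0})
        rhs = build_rhs(spec, params, GenotypeSpec("wt", (1, 1, 1)))
        np.testing.assert_allclose(rhs(np.zeros(3)), [5, 3, 2])
        np.testing.assert_allclose(rhs(np.array([5.0, 3.0, 2.0])), [0, 0, 0])

    def test_all_v_zero_reduces_to_basal(self):
        specs = enumerate_logic_variants(LATE_L1_GENES, late_l1_terms())
        spec = specs[0]
        values = {n: 0.0 for n in spec.parameter_names()}
        values.update({"b:elt-1": 4.0, "b:egl-18": 2.0, "b:ceh-16": 1.0})
        rhs = build_rhs(spec, ParameterSet(values=values), WT)
        g = np.array([10.0, 10.0, 10.0])
        np.testing.assert_allclose(rhs(g), np.array([4.0, 2.0, 1.0]) - g)

    def test_and_block_hand_composition(self):
        # one AND block (act by g1, act by g2) OR'd with self-activation
        t1 = RegulationTerm("g3", "g1", ACTIVATION)
        t2 = RegulationTerm("g3", "g2", ACTIVATION)
        t3 = RegulationTerm("g3", "g3", ACTIVATION, self_flag=True)
        spec = ODEModelSpec(
            genes=("g1", "g2", "g3"),
            blocks={"g1": (), "g2": (), "g3": ((t1, t2), (t3,))},
        )
        values = {
            "b:g1": 0.0, "b:g2": 0.0, "b:g3": 1.0,
            "v:g3:g1+g2": 6.0, "v:g3:g3(self)": 2.0,
            "k:g1:act": 10.0, "k:g2:act": 5.0, "k:g3:self": 20.0,
        }
        f = GenotypeSpec("mut", (0.5, 1.0, 1.0))
        rhs = build_rhs(spec, ParameterSet(values=values), f)
        g = np.array([10.0, 10.0, 10.0])
        expected = (
            1.0
            + 6.0 * ((10 * 0.5) / (10 + 10 * 0.5)) * (10 / (5 + 10))
            + 2.0 * (10 / (20 + 10))
            - 10.0
        )
        assert rhs(g)[2] == pytest.approx(expected)

    def test_missing_parameter_raises(self):
        spec = basal_spec()
        with pytest.raises(grn_ode.ParameterMismatchError):
            build_rhs(spec, ParameterSet(values={"b:g1": 1.0}), WT)

    def test_or_blocks_equal_sum_of_hills(self):
        # singleton blocks: rhs is exactly the sum-of-Hills form
        specs = enumerate_logic_variants(LATE_L1_GENES, late_l1_terms())
        spec = specs[0]
        rng = np.random.default_rng(0)
        values = {n: float(rng.uniform(1, 50)) for n in spec.parameter_names()}
        params = ParameterSet(values=values)
        f = GenotypeSpec("mut", (0.25, 0.01, 0.25))
        rhs = build_rhs(spec, params, f)
        g = np.array([12.0, 33.0, 8.0])
        fa = f.activities
        v = values
        expected_g2 = (
            v["b:egl-18"]
            + hill_activation(g[0], fa[0], v["v:egl-18:elt-1"], v["k:elt-1:act"])
            + hill_repression(g[2], fa[2], v["v:egl-18:ceh-16"], v["k:ceh-16:rep"])
            - g[1]
        )
        assert rhs(g)[1] == pytest.approx(expected_g2, rel=1e-12)


class TestSteadyState:
    def test_basal_fixed_point(self):
        spec = basal_spec()
        params = ParameterSet(values={"b:g1": 5.0, "b:g2": 3.0, "b:g3": 2.0})
        s = steady_state(spec, params, GenotypeSpec("wt", (1, 1, 1)), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(s, [5, 3, 2], atol=1e-6)

    def test_self_activation_quadratic_root(self):
        # dg/dt = b + v g/(k+g) - g with b=1, v=4, k=2; multiplying through by
        # (k+g) gives g^2 + (k-b-v) g - b k = 0, i.e. g^2 - 3g - 2 = 0, whose
        # positive root is (3 + sqrt(17))/2
        t = RegulationTerm("g1", "g1", ACTIVATION, self_flag=True)
        spec = ODEModelSpec(genes=("g1",), blocks={"g1": ((t,),)})
        params = ParameterSet(
            values={"b:g1": 1.0, "v:g1:g1(self)": 4.0, "k:g1:self": 2.0}
        )
        s = steady_state(spec, params, GenotypeSpec("wt", (1.0,)), [1.0])
        expected = (3 + np.sqrt(17)) / 2
        assert s[0] == pytest.approx(expected, rel=1e-6)
        # independent oracle: root of the rhs via brentq
        rhs = build_rhs(spec, params, GenotypeSpec("wt", (1.0,)))
        root = brentq(lambda x: rhs(np.array([x]))[0], 1.0, 50.0)
        assert s[0] == pytest.approx(root, rel=1e-6)

    def test_genotype_differs_only_through_f(self):
        spec = basal_spec()
        params = ParameterSet(values={"b:g1": 5.0, "b:g2": 3.0, "b:g3": 2.0})
        wt = steady_state(spec, params, GenotypeSpec("wt", (1, 1, 1)), [1, 1, 1])
        mut = steady_state(spec, params, GenotypeSpec("m", (0.25, 1, 1)), [1, 1, 1])
        np.testing.assert_allclose(wt, mut, atol=1e-6)  # no Hill terms -> f inert

    def test_nonconvergence_raises(self):
        spec = basal_spec()
        params = ParameterSet(values={"b:g1": 5.0, "b:g2": 3.0, "b:g3": 2.0})
        with pytest.raises(SteadyStateError):
            steady_state(spec, params, WT, [1000.0, 1000.0, 1000.0], t_max=0.2)

    def test_invalid_g0(self):
        spec = basal_spec()
        params = ParameterSet(values={"b:g1": 1.0, "b:g2": 1.0, "b:g3": 1.0})
        with pytest.raises(ValueError):
            steady_state(spec, params, WT, [-1.0, 0.0, 0.0])

    def test_root_finding_cross_check(self):
        # forward integration agrees with a numerical root of the rhs
        specs = enumerate_logic_variants(LATE_L1_GENES, late_l1_terms())
        spec = specs[7]
        rng = np.random.default_rng(3)
        values = {n: float(rng.uniform(1, 40)) for n in spec.parameter_names()}
        params = ParameterSet(values=values)
        f = GenotypeSpec("mut", (0.25, 0.01, 0.25))
        s = steady_state(spec, params, f, [10.0, 10.0, 10.0])
        rhs = build_rhs(spec, params, f)
        root = fsolve(rhs, s)
        np.testing.assert_allclose(s, root, rtol=1e-5)
        np.testing.assert_allclose(rhs(s), 0.0, atol=1e-6)

    def test_non_negativity_and_boundedness(self):
        specs = enumerate_logic_variants(LATE_L1_GENES, late_l1_terms())
        rng = np.random.default_rng(11)
        for spec in (specs[0], specs[9], specs[-1]):
            values = {n: float(rng.uniform(0, 60)) for n in spec.parameter_names()}
            params = ParameterSet(values=values)
            s = steady_state(spec, params, WT, [0.0, 0.0, 0.0])
            assert np.all(s >= 0)
            bound = np.array(
                [
                    values[f"b:{g}"]
                    + sum(
                        values[n]
                        for n in spec.v_names()
                        if n.startswith(f"v:{g}:")
                    )
                    for g in spec.genes
                ]
            )
            assert np.all(s <= bound + 1e-6)


class TestGenotypePanel:
    def test_identical_wild_type_columns(self):
        spec = basal_spec()
        params = ParameterSet(values={"b:g1": 5.0, "b:g2": 3.0, "b:g3": 2.0})
        genos = [GenotypeSpec(f"wt{i}", (1, 1, 1)) for i in range(3)]
        S = genotype_panel(spec, params, genos, np.ones(3))
        assert np.allclose(S[:, 0], S[:, 1]) and np.allclose(S[:, 1], S[:, 2])

    def test_single_genotype_equals_steady_state(self, final_l1_gt):
        gt = final_l1_gt
        wt = gt.genotype_specs[0]
        S = genotype_panel(gt.model, gt.params, [wt], np.full(3, 10.0))
        s = steady_state(gt.model, gt.params, wt, np.full(3, 10.0))
        np.testing.assert_allclose(S[:, 0], s, rtol=1e-9)

    def test_final_l1_monotonicity(self, final_l1_gt):
        S = final_l1_gt.steady_states()
        names = [g.name for g in final_l1_gt.genotype_specs]
        i = LATE_L1_GENES.index("egl-18")
        assert S[i, names.index("ceh-16(bp323)")] > S[i, names.index("wild type")]


class TestFinalFamily:
    """Eq-4/{5,6}/{7,8} combinations are restrictions of the variant family."""

    @pytest.mark.parametrize("egl_and", [False, True])
    @pytest.mark.parametrize("ceh_and", [False, True])
    def test_family_member_reachable(self, egl_and, ceh_and):
        specs = enumerate_logic_variants(LATE_L1_GENES, late_l1_terms())
        # select the variant whose egl-18 partition and ceh-16 partition have
        # the requested structure (elt-1 always all-OR here)
        def matches(spec):
            eb = spec.blocks["egl-18"]
            cb = spec.blocks["ceh-16"]
            if len(spec.blocks["elt-1"]) != 2:
                return False
            egl_ok = (len(eb) == 1) == egl_and
            # ceh-16: want {elt-1, egl-18} AND-joined, self separate (or all OR)
            if ceh_and:
                ceh_ok = any(
                    len(b) == 2
                    and {t.regulator for t in b} == {"elt-1", "egl-18"}
                    for b in cb
                )
            else:
                ceh_ok = len(cb) == 3
            return egl_ok and ceh_ok

        matching = [s for s in specs if matches(s)]
        assert matching, "family member not reachable"
        spec = matching[0]
        rng = np.random.default_rng(17)
        values = {n: 0.0 for n in spec.parameter_names()}
        # zero out: elt-1 regulation, egl-18 basal+elt-1 input (eq 5) etc.
        values["b:elt-1"] = 30.0
        values["k:ceh-16:rep"] = 40.0
        values["k:elt-1:act"] = 30.0
        values["k:egl-18:act"] = 40.0
        for n in spec.v_names():
            if n.startswith("v:egl-18") or n.startswith("v:ceh-16"):
                if "(self)" not in n:
                    values[n] = float(rng.uniform(20, 60))
        params = ParameterSet(values=values)
        s = steady_state(spec, params, WT, [10.0, 10.0, 10.0])
        assert np.all(np.isfinite(s))
        # elt-1 decouples: its fixed point is exactly b1/d1
        assert s[0] == pytest.approx(30.0, rel=1e-6)


class TestSerialization:
    def test_spec_round_trip(self):
        spec = enumerate_logic_variants(LATE_L1_GENES, late_l1_terms())[4]
        assert ODEModelSpec.from_json(spec.to_json()) == spec

    def test_params_round_trip(self):
        p = ParameterSet(values={"b:g1": 1.5}, alpha={"g1": 3.0}, d={"g1": 1.0})
        q = ParameterSet.from_json(p.to_json())
        assert q.values == p.values and q.alpha == p.alpha
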