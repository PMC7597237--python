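import math

import numpy as np
import pytest

from pathpid import (
    DiagnosticError,
    InputError,
    JointPMF,
    Path,
    build_lattice,
    decompose,
    imin,
    infer_graph,
    lattice_cumulative_values,
    moebius_atoms,
    named_distribution,
    path_mutual_information,
    path_redundancy,
    random_channel_system,
    random_markov_chain,
    synergy,
    unique_eq25_diagnostic,
    unique_information,
    verify_axioms,
)
from oracles import brute_imin, brute_mi, brute_redundancy, dict_from_pmf

H_AND_Z = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
I_XZ_AND = H_AND_Z - 0.5  # H(Z) - H(Z|X), H(Z|X=1) = 1


class TestPathRedundancy:
    def test_two_bit_copy_zero(self, two_bit_copy):
        assert path_redundancy(two_bit_copy, ["X", "Y"], "Z") == 0.0

    def test_table3a_min_of_both_paths(self, table3a):
        r, used = path_redundancy(table3a, ["X", "Y"], "Z", return_paths=True)
        mis = dict((str(p), mi) for p, mi in used)
        assert round(mis["{X}{Y}{Z}"], 4) == 0.0271
        assert round(mis["{Y}{X}{Z}"], 4) == 0.1226
        assert r == pytest.approx(mis["{X}{Y}{Z}"])

    def test_single_source_self_redundancy(self, table3a):
        assert path_redundancy(table3a, ["X"], "Z") == pytest.approx(
            table3a.mutual_information("X", "Z"), abs=1e-12
        )

    def test_triadic_full_bit(self):
        pmf = named_distribution("triadic")
        r = path_redundancy(pmf, ["X", "Y"], "Z")
        assert r == pytest.approx(1.0, abs=1e-12)
        assert r == pytest.approx(pmf.mutual_information("X", "Z"), abs=1e-12)

    def test_target_among_sources(self, table3a):
        with pytest.raises(InputError):
            path_redundancy(table3a, ["X", "Z"], "Z")

    def test_oracle_equivalence_3var(self, random_systems_small):
        for pmf in random_systems_small[:25]:
            variables, states = dict_from_pmf(pmf)
            assert path_redundancy(pmf, ["X", "Y"], "Z") == pytest.approx(
                brute_redundancy(variables, states, ["X", "Y"], "Z"), abs=1e-12
            )

    def test_oracle_equivalence_4var_groups(self):
        for seed in range(10):
            pmf = random_channel_system(4, 2, edge_density=1.0, seed=seed)
            variables, states = dict_from_pmf(pmf)
            got = path_redundancy(pmf, [("X", "Y"), ("Z",)], "W")
            want = brute_redundancy(variables, states, [("X", "Y"), ("Z",)], ("W",))
            assert got == pytest.approx(want, abs=1e-12)


class TestUniqueInformation:
    def test_pwunq(self):
        pmf = named_distribution("pwunq")
        assert unique_information(pmf, "X", ["Y"], "Z") == pytest.approx(0.5, abs=1e-12)
        assert unique_information(pmf, "Y", ["X"], "Z") == pytest.approx(0.5, abs=1e-12)

    def test_markov_chain_distal_zero_strict(self):
        for seed in range(10):
            pmf = random_markov_chain((2, 2, 2), seed=seed)
            u = unique_information(pmf, "X", ["Y"], "Z", strict=True)
            assert u == pytest.approx(0.0, abs=1e-12)

    def test_5b(self):
        pmf = named_distribution("5b")
        assert unique_information(pmf, "Y", ["X"], "Z") == pytest.approx(1.0, abs=1e-12)
        assert unique_information(pmf, "X", ["Y"], "Z") == pytest.approx(0.5, abs=1e-12)


class TestSynergy:
    def test_xor_one_bit(self):
        assert synergy(named_distribution("xor"), ["X", "Y"], "Z") == pytest.approx(1.0)

    def test_and(self):
        s = synergy(named_distribution("and"), ["X", "Y"], "Z")
        assert s == pytest.approx(H_AND_Z - 2 * I_XZ_AND, abs=1e-12)
        assert round(s, 2) == 0.19

    def test_table3a_negative(self, table3a):
        assert synergy(table3a, ["X", "Y"], "Z") < 0

    def test_requires_two_sources(self, table3a):
        with pytest.raises(InputError):
            synergy(table3a, ["X"], "Z")


class TestDecompose:
    def test_reduced_or_synergy_rounds_to_040(self):
        res = decompose(named_distribution("reduced_or"), ["X", "Y"], "Z")
        assert round(res.synergy, 2) == 0.40

    def test_two_bit_copy(self, two_bit_copy):
        res = decompose(two_bit_copy, ["X", "Y"], "Z")
        assert res.redundancy == 0.0
        assert res.unique[("X",)] == pytest.approx(1.0)
        assert res.unique[("Y",)] == pytest.approx(1.0)
        assert res.synergy == pytest.approx(0.0, abs=1e-12)

    def test_identity_property_join_target(self, table3a):
        res = decompose(table3a, ["X", "Y"], ("X", "Y"))
        assert res.redundancy == pytest.approx(
            table3a.mutual_information("X", "Y"), abs=1e-9
        )

    def test_additivity_exact(self, random_systems_small):
        for pmf in random_systems_small[:25]:
            res = decompose(pmf, ["X", "Y"], "Z")
            assert abs(res.additivity_residual()) < 1e-12

    def test_per_source_identity(self, random_systems_small):
        # I(source; target) = U + R
        for pmf in random_systems_small[:25]:
            res = decompose(pmf, ["X", "Y"], "Z")
            assert res.unique[("X",)] + res.redundancy == pytest.approx(
                pmf.mutual_information("X", "Z"), abs=1e-9
            )
            assert res.unique[("Y",)] + res.redundancy == pytest.approx(
                pmf.mutual_information("Y", "Z"), abs=1e-9
            )

    def test_atoms_mirror_components(self, table3a):
        res = decompose(table3a, ["X", "Y"], "Z")
        assert res.atoms["{1}{2}"] == pytest.approx(res.redundancy)
        assert res.atoms["{1}"] == pytest.approx(res.unique[("X",)])
        assert res.atoms["{2}"] == pytest.approx(res.unique[("Y",)])
        assert res.atoms["{12}"] == pytest.approx(res.synergy)
        assert res.has_negative_atom  # negative synergy flag

    def test_markov_chain_parameter_recovery(self):
        for seed in range(10):
            pmf = random_markov_chain((2, 2, 2), seed=seed)
            res = decompose(pmf, ["X", "Y"], "Z", strict=True)
            i_xz = pmf.mutual_information("X", "Z")
            assert res.redundancy == pytest.approx(i_xz, abs=1e-12)
            assert res.unique[("X",)] == pytest.approx(0.0, abs=1e-12)
            assert res.unique[("Y",)] == pytest.approx(
                pmf.mutual_information("Y", "Z") - i_xz, abs=1e-12
            )


class TestEq25Diagnostic:
    def test_chain_first_sum_zero(self):
        pmf = random_markov_chain((2, 2, 2), seed=7)
        s1, s2 = unique_eq25_diagnostic(pmf, "X", "Z", other="Y")
        assert s1 == pytest.approx(0.0, abs=1e-9)

    def test_copy_second_sum_zero(self):
        # Y is an exact copy of X; Z a noisy function of X
        states = {}
        for x in (0, 1):
            for z in (0, 1):
                states[(x, x, z)] = 0.5 * (0.8 if z == x else 0.2)
        pmf = JointPMF.from_states(("X", "Y", "Z"), states, alphabets=((0, 1),) * 3)
        s1, s2 = unique_eq25_diagnostic(pmf, "Y", "Z", other="X")
        assert s2 == pytest.approx(0.0, abs=1e-9)

    def test_both_zero_implies_equal_channels(self):
        # a copy that is simultaneously a chain mediator: B == C
        states = {(x, x, (x + 1) % 2): 0.5 for x in (0, 1)}
        pmf = JointPMF.from_states(("X", "Y", "Z"), states, alphabets=((0, 1),) * 3)
        s1, s2 = unique_eq25_diagnostic(pmf, "Y", "Z", other="X")
        assert s1 == pytest.approx(0.0, abs=1e-9)
        assert s2 == pytest.approx(0.0, abs=1e-9)


class TestImin:
    def test_two_bit_copy_one_bit(self, two_bit_copy):
        assert imin(two_bit_copy, ["X", "Y"], "Z") == pytest.approx(1.0, abs=1e-12)

    def test_xor_zero(self):
        assert imin(named_distribution("xor"), ["X", "Y"], "Z") == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_source_is_mi(self, table3a):
        assert imin(table3a, ["X"], "Z") == pytest.approx(
            table3a.mutual_information("X", "Z"), abs=1e-12
        )

    def test_matches_oracle(self, random_systems_small):
        for pmf in random_systems_small[:15]:
            variables, states = dict_from_pmf(pmf)
            assert imin(pmf, ["X", "Y"], "Z") == pytest.approx(
                brute_imin(variables, states, ["X", "Y"], ("Z",)), abs=1e-12
            )


class TestLattice:
    def test_two_source_nodes(self):
        lat = build_lattice(2)
        labels = [lat.label(n) for n in lat.nodes]
        assert labels == ["{1}{2}", "{1}", "{2}", "{12}"]
        assert lat.label(lat.bottom) == "{1}{2}"
        assert lat.leq(lat.bottom, lat.top)
        assert not lat.leq(lat.node_from_label("{1}"), lat.node_from_label("{2}"))

    def test_three_source_count(self):
        assert len(build_lattice(3).nodes) == 18

    def test_unsupported_size(self):
        with pytest.raises(InputError):
            build_lattice(4)

    def test_moebius_xor_table(self):
        lat = build_lattice(2)
        atoms = moebius_atoms(
            lat, {"{1}{2}": 0.0, "{1}": 0.0, "{2}": 0.0, "{12}": 1.0}
        )
        assert [atoms[n] for n in lat.nodes] == [0.0, 0.0, 0.0, 1.0]

    def test_moebius_constant_bottom_only(self):
        lat = build_lattice(2)
        atoms = moebius_atoms(
            lat, {"{1}{2}": 0.7, "{1}": 0.7, "{2}": 0.7, "{12}": 0.7}
        )
        assert atoms[lat.bottom] == pytest.approx(0.7)
        assert all(
            atoms[n] == pytest.approx(0.0) for n in lat.nodes if n != lat.bottom
        )

    def test_moebius_pwunq_table(self):
        lat = build_lattice(2)
        atoms = moebius_atoms(
            lat, {"{1}{2}": 0.0, "{1}": 0.5, "{2}": 0.5, "{12}": 1.0}
        )
        assert [round(atoms[n], 4) for n in lat.nodes] == [0.0, 0.5, 0.5, 0.0]

    def test_moebius_resummation(self):
        rng = np.random.default_rng(0)
        for lat in (build_lattice(2), build_lattice(3)):
            atoms_true = {n: float(v) for n, v in zip(lat.nodes, rng.normal(size=len(lat.nodes)))}
            cumulative = {
                n: sum(atoms_true[m] for m in lat.nodes if lat.leq(m, n))
                for n in lat.nodes
            }
            atoms = moebius_atoms(lat, cumulative)
            for n in lat.nodes:
                assert atoms[n] == pytest.approx(atoms_true[n], abs=1e-12)

    def test_three_source_cumulative_partial_order(self):
        # only the orderings the data processing inequality guarantees:
        # adding a whole collection to the antichain (path end-extension)
        # and growing a singleton node's collection (chain rule)
        pmf = random_channel_system(4, 2, edge_density=1.0, seed=2)
        lat = build_lattice(3)
        values = lattice_cumulative_values(pmf, ["X", "Y", "Z"], "W")
        for a in lat.nodes:
            for b in lat.nodes:
                if a != b and b < a:  # a = b plus extra collections
                    assert values[a] <= values[b] + 1e-9
        for a in lat.nodes:
            for b in lat.nodes:
                if len(a) == len(b) == 1 and next(iter(a)) < next(iter(b)):
                    assert values[a] <= values[b] + 1e-9


class TestAxioms:
    @pytest.mark.parametrize(
        "name",
        ["common_cause_3var", "reduced_or", "pwunq", "xor", "and", "5a", "5b",
         "dyadic", "triadic", "two_bit_copy", "sum"],
    )
    def test_fixture_axioms_hold(self, named, name):
        checks = verify_axioms(named(name), ["X", "Y"], "Z")
        failed = [c.name for c in checks.values() if not c.holds]
        assert failed == []

    def test_generalized_self_redundancy_relabeled_copy(self):
        # Y is a noiseless relabeling (permutation) of X
        states = {}
        rng_probs = [0.15, 0.35, 0.3, 0.2]
        i = 0
        for x in (0, 1):
            for z in (0, 1):
                states[(x, 1 - x, z)] = rng_probs[i]
                i += 1
        pmf = JointPMF.from_states(("X", "Y", "Z"), states, alphabets=((0, 1),) * 3)
        r = path_redundancy(pmf, ["X", "Y"], "Z")
        assert r == pytest.approx(pmf.mutual_information("X", "Z"), abs=1e-9)
        # Corollary: swapping the equivalent sources' roles keeps redundancy
        assert path_redundancy(pmf, ["Z", "Y"], "X") == pytest.approx(
            path_redundancy(pmf, ["Z", "X"], "Y"), abs=1e-9
        )

    def test_left_monotonicity_random(self):
        for seed in range(25):
            pmf = random_channel_system(4, 2, edge_density=1.0, seed=seed)
            g = infer_graph(pmf)
            wide = path_redundancy(pmf, ["X", "Y"], ("Z", "W"), graph=g)
            narrow = path_redundancy(pmf, ["X", "Y"], "Z", graph=g)
            assert wide >= narrow - 1e-9


class TestDiscrimination:
    def test_dyadic_vs_triadic(self):
        dy, tri = named_distribution("dyadic"), named_distribution("triadic")
        assert sorted(dy.table.ravel()) == sorted(tri.table.ravel())
        g_dy, g_tri = infer_graph(dy), infer_graph(tri)
        statuses_dy = {g_dy.status(*p) for p in (("X", "Y"), ("X", "Z"), ("Y", "Z"))}
        statuses_tri = {g_tri.status(*p) for p in (("X", "Y"), ("X", "Z"), ("Y", "Z"))}
        assert statuses_dy != statuses_tri
        res_dy = decompose(dy, ["X", "Y"], "Z")
        res_tri = decompose(tri, ["X", "Y"], "Z")
        assert res_dy.redundancy == pytest.approx(0.0, abs=1e-12)
        assert res_tri.redundancy == pytest.approx(1.0, abs=1e-12)
        assert res_tri.unique[("X",)] == pytest.approx(0.0, abs=1e-12)
        assert res_tri.unique[("Y",)] == pytest.approx(0.0, abs=1e-12)
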