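import io
import math
import random

import pytest

import genedup as gd
from genedup import ilp_model, simulate
from genedup.ilp_model import SolverError


class TestBuildIlp:
    def test_variable_counts_balanced_quartet(self):
        """Single gene tree ((a,b),(c,d)): 2 columns of 4 rows, one column
        pair, 2 representative triples, and a single eligible vertex."""
        inst = gd.ProblemInstance((gd.parse_newick("((a,b),(c,d));"),))
        model = gd.build_ilp(inst)
        names = model.variables
        assert sum(v.startswith("M_") for v in names) == 4 * 2
        assert sum(v.startswith("C_") for v in names) == 3
        assert sum(v.startswith("T_") for v in names) == 2 * 3
        assert sum(v.startswith("D_") for v in names) == 1
        assert model.offset == 0

    def test_constraint_counts_balanced_quartet(self):
        inst = gd.ProblemInstance((gd.parse_newick("((a,b),(c,d));"),))
        model = gd.build_ilp(inst)
        kinds = {}
        for con in model.constraints:
            kinds[con.name.split("_")[0]] = kinds.get(con.name.split("_")[0], 0) + 1
        assert kinds["nontrivial"] == 2 * 2  # lo+hi per column
        assert kinds["unique"] == 1  # n-3
        assert kinds["gam01"] == kinds["gam10"] == kinds["gam11"] == 4
        assert kinds["compat"] == 1
        assert kinds["trip"] == 2 * (2 * 3 + 1)  # detection per column + one-of
        assert kinds["tin"] == 2  # one per representative triple of the root

    def test_uniqueness_constraint_count_scales(self, rng):
        t = simulate.random_species_tree(7, rng)
        model = gd.build_ilp(gd.ProblemInstance((t,)))
        assert sum(c.name.startswith("unique") for c in model.constraints) == 7 - 3

    def test_small_n_refused(self, three_triples_instance):
        with pytest.raises(ValueError, match="brute"):
            gd.build_ilp(three_triples_instance)

    def test_model_validates_declared_variables(self, lifted_three_triples_instance):
        model = gd.build_ilp(lifted_three_triples_instance)
        model.validate()

    def test_forced_vertices_enter_offset_not_objective(self):
        trees = (gd.parse_newick("(((a,a),b),(c,d));"),)
        model = gd.build_ilp(gd.ProblemInstance(trees))
        assert model.offset == 1
        # only the root spans >= 3 species with disjoint child sets;
        # the forced (a,a) cherry contributes no D variable
        assert sum(v.startswith("D_") for v in model.variables) == 1


class TestSolve:
    def test_single_gene_tree_recovers_itself(self, rng):
        t = simulate.random_species_tree(6, rng)
        inst = gd.ProblemInstance((t,))
        model = gd.build_ilp(inst)
        sol = gd.solve(model)
        assert sol.status == "optimal" and sol.objective == 0
        assert ilp_model.decode_tree(model, sol.assignment) == t

    def test_lifted_three_triples_objective(self, lifted_three_triples_instance):
        sol = gd.solve(gd.build_ilp(lifted_three_triples_instance))
        assert sol.objective == 2

    def test_decoded_matrix_is_binary_hierarchy(self, lifted_three_triples_instance):
        model = gd.build_ilp(lifted_three_triples_instance)
        sol = gd.solve(model)
        M = ilp_model.decode_matrix(model, sol.assignment)
        assert gd.is_binary_hierarchy(M.cluster_sets(), set(model.taxa))

    def test_triple_variables_match_decoded_tree(self, rng):
        ds = simulate.simulate_dataset(simulate.SimulationConfig(n=6, k=8, seed=21))
        inst = gd.ProblemInstance(tuple(ds.gene_trees))
        model = gd.build_ilp(inst)
        sol = gd.solve(model)
        tree = ilp_model.decode_tree(model, sol.assignment)
        for (a, b, c), tvars in model.triple_vars.items():
            displayed = {
                "011": gd.displays(tree, gd.RootedTriple.of(b, c, a)),
                "101": gd.displays(tree, gd.RootedTriple.of(a, c, b)),
                "110": gd.displays(tree, gd.RootedTriple.of(a, b, c)),
            }
            for code, var in tvars.items():
                assert sol.assignment[var] == int(displayed[code])

    def test_dup_variables_tight_at_optimum(self, rng):
        ds = simulate.simulate_dataset(simulate.SimulationConfig(n=5, k=10, seed=33))
        inst = gd.ProblemInstance(tuple(ds.gene_trees))
        model = gd.build_ilp(inst)
        sol = gd.solve(model)
        tree = ilp_model.decode_tree(model, sol.assignment)
        for dvar, (gi, u) in model.dup_vars.items():
            reps = gd.representative_triples(
                inst.gene_trees[gi], inst.leaf_to_species
            )[u]
            violated = any(not gd.displays(tree, t) for t in reps)
            assert sol.assignment[dvar] == int(violated)


class TestSolveGd:
    def test_tiny_instance_dispatches_to_brute_force(self, three_triples_instance):
        cost, tree, report = gd.solve_gd(three_triples_instance)
        assert cost == 2 and report.total_dup == 2

    def test_self_recovery_with_forced_offset(self):
        trees = (
            gd.parse_newick("((a,a),b);"),
            gd.parse_newick("((a,b),c);"),
        )
        cost, tree, report = gd.solve_gd(gd.ProblemInstance(trees))
        bf_cost, _ = gd.exact_gd(gd.ProblemInstance(trees))
        assert cost == bf_cost == 1  # the forced duplication is the whole cost

    def test_oracle_equivalence_batch(self, rng):
        for seed in range(10):
            n = 4 + seed % 3
            ds = simulate.simulate_dataset(simulate.SimulationConfig(n=n, k=6, seed=seed))
            inst = gd.ProblemInstance(tuple(ds.gene_trees))
            cost, tree, report = gd.solve_gd(inst)
            bf_cost, _ = gd.exact_gd(inst)
            assert cost == bf_cost
            assert report.total_dup == cost

    def test_monotonicity_in_gene_trees(self, rng):
        ds = simulate.simulate_dataset(simulate.SimulationConfig(n=5, k=8, seed=77))
        trees = ds.gene_trees
        prev = 0
        for upto in range(1, len(trees) + 1):
            cost, _, _ = gd.solve_gd(gd.ProblemInstance(tuple(trees[:upto])))
            assert cost >= prev
            prev = cost

    def test_all_triples_mode_same_optimum(self, rng):
        for seed in (5, 6):
            ds = simulate.simulate_dataset(simulate.SimulationConfig(n=5, k=5, seed=seed))
            inst = gd.ProblemInstance(tuple(ds.gene_trees))
            reduced, _, _ = gd.solve_gd(inst)
            full, _, _ = gd.solve_gd(inst, all_triples=True)
            assert reduced == full


class TestEnumerateOptima:
    def test_three_optima_on_lifted_conflict(self, lifted_three_triples_instance):
        model = gd.build_ilp(lifted_three_triples_instance)
        optima = gd.enumerate_optima(model, limit=20)
        bf_cost, bf_optima = gd.exact_gd(lifted_three_triples_instance)
        assert {t.canonical_newick() for t in optima} == {
            t.canonical_newick() for t in bf_optima
        }

    def test_unique_optimum_for_single_tree(self, rng):
        t = simulate.random_species_tree(5, rng)
        model = gd.build_ilp(gd.ProblemInstance((t,)))
        optima = gd.enumerate_optima(model, limit=10)
        assert optima == [t]

    def test_limit_one_returns_first(self, lifted_three_triples_instance):
        model = gd.build_ilp(lifted_three_triples_instance)
        assert len(gd.enumerate_optima(model, limit=1)) == 1


class TestLpFormat:
    def test_lp_text_sections(self, lifted_three_triples_instance):
        model = gd.build_ilp(lifted_three_triples_instance)
        buf = io.StringIO()
        gd.write_lp(model, buf)
        text = buf.getvalue()
        assert "Minimize" in text and "Subject To" in text and "Binary" in text
        for v in model.variables:
            assert v in text

    def test_roundtrip_solve_matches(self, lifted_three_triples_instance, tmp_path):
        model = gd.build_ilp(lifted_three_triples_instance)
        path = tmp_path / "model.lp"
        gd.write_lp(model, path)
        back = ilp_model.read_lp(path)
        assert set(back.variables) == set(model.variables)
        sol_orig = gd.solve(model)
        sol_back = gd.solve(back)
        assert sol_back.objective == sol_orig.objective

    def test_deterministic_output(self, lifted_three_triples_instance):
        model = gd.build_ilp(lifted_three_triples_instance)
        a, b = io.StringIO(), io.StringIO()
        gd.write_lp(model, a)
        gd.write_lp(model, b)
        assert a.getvalue() == b.getvalue()


class TestVerification:
    def test_tampered_assignment_rejected(self, lifted_three_triples_instance):
        model = gd.build_ilp(lifted_three_triples_instance)
        sol = gd.solve(model)
        bad = {v: float(x) for v, x in sol.assignment.items()}
        mvar = model.mvar(0, 0)
        bad[mvar] = 1.0 - bad[mvar]
        with pytest.raises(SolverError):
            ilp_model._verify_assignment(model, bad)

    def test_fractional_assignment_rejected(self, lifted_three_triples_instance):
        model = gd.build_ilp(lifted_three_triples_instance)
        sol = gd.solve(model)
        bad = {v: float(x) for v, x in sol.assignment.items()}
        bad[model.mvar(0, 0)] = 0.5
        with pytest.raises(SolverError, match="binary"):
            ilp_model._verify_assignment(model, bad)
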