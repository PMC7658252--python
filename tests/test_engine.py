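"""Engine: pair enumeration, template application, scoring, classification."""

import pytest
from rdkit import Chem

from synforge.bbs import RoleSet, assign_roles, standardize
from synforge.engine import (
    KILLED,
    apply_transform,
    classify_score,
    enumerate_pairs,
    run_library,
    score_reaction,
)
from synforge.rules import ScoringClause, Transform


def _roles(tid, a_members, b_members):
    return (
        RoleSet(transform_id=tid, role="A", members=list(a_members)),
        RoleSet(transform_id=tid, role="B", members=list(b_members)),
    )


def _mol(s):
    return Chem.MolFromSmiles(s)


class TestEnumeratePairs:
    def test_cross_product_count(self):
        pairs = list(enumerate_pairs(*_roles(1, ["a1", "a2", "a3"], ["b1", "b2", "b3", "b4"])))
        assert len(pairs) == 12
        assert len(set(pairs)) == 12

    def test_empty_role_yields_nothing(self):
        assert list(enumerate_pairs(*_roles(1, [], ["b1"]))) == []

    def test_deterministic_sorted_order(self):
        pairs = list(enumerate_pairs(*_roles(1, ["a2", "a1"], ["b2", "b1"])))
        assert [(p.bb_a, p.bb_b) for p in pairs] == [
            ("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a2", "b2"),
        ]

    def test_count_matches_brute_force_oracle(self, standard_rules):
        """Pair count equals a brute-force match-and-filter over all ordered pairs."""
        amide = next(t for t in standard_rules if "Amide" in t.name)
        smiles = [
            "CC(=O)O", "CCC(=O)O", "OC(=O)c1ccccc1", "Nc1ccc(C(=O)O)cc1",
            "NCC", "NCCC", "Nc1ccccc1", "Nc1cccc(N)c1", "CCO", "CCOCC",
        ]
        bbs = [standardize(s, f"B{i:02d}") for i, s in enumerate(smiles)]
        role_a, role_b = assign_roles(amide, bbs)
        got = len(list(enumerate_pairs(role_a, role_b)))

        # oracle: count ordered pairs where each side matches its role at
        # exactly one distinct site and neither side matches both roles
        def sites(mol, patt):
            return {frozenset(m) for m in mol.GetSubstructMatches(patt, uniquify=False)}

        ok_a, ok_b = [], []
        for bb in bbs:
            sa, sb = sites(bb.mol(), amide.role_a), sites(bb.mol(), amide.role_b)
            if sa and sb:
                continue
            if len(sa) == 1:
                ok_a.append(bb.bb_id)
            if len(sb) == 1:
                ok_b.append(bb.bb_id)
        expected = sum(1 for a in ok_a for b in ok_b if a != b)
        assert got == expected == 9  # 3 clean acids x 3 clean amines


class TestApplyTransform:
    def test_amide_formation(self, standard_rules):
        amide = next(t for t in standard_rules if "Amide" in t.name)
        smiles, reason = apply_transform(amide, _mol("CC(=O)O"), _mol("NCCc1ccccc1"))
        assert reason is None
        assert smiles == "CC(=O)NCCc1ccccc1"

    def test_click_forms_triazole_ring(self, standard_rules):
        click = next(t for t in standard_rules if "cycloaddition" in t.name)
        smiles, reason = apply_transform(
            click, _mol("[N-]=[N+]=Nc1ccccc1"), _mol("C#Cc1ccccc1")
        )
        assert reason is None
        product = _mol(smiles)
        # 1,4-disubstituted 1,2,3-triazole from phenyl azide + phenylacetylene
        assert product.HasSubstructMatch(Chem.MolFromSmarts("c1cn(-c2ccccc2)nn1"))
        assert Chem.rdMolDescriptors.CalcNumRings(product) == 3

    def test_pattern_mismatch_returns_none(self, standard_rules):
        suzuki = next(t for t in standard_rules if "Biaryl" in t.name)
        smiles, reason = apply_transform(suzuki, _mol("CCO"), _mol("OB(O)c1ccccc1"))
        assert smiles is None and reason == "template_mismatch"


class TestScoreReaction:
    @pytest.fixture()
    def transform(self):
        return Transform(
            id=99,
            name="synthetic scoring fixture",
            role_a_pattern="[CX3](=O)[OX2H1]",
            role_b_pattern="[NX3;H2,H1]",
            product_template="[C:1](=[O:2])[OX2H1].[NX3;H2,H1:3]>>[C:1](=[O:2])[N:3]",
            leaving_groups=["O"],
            clauses=[
                ScoringClause(scope="reactant_b", action="ADD", value=10, smarts="[NX3H2][CX4]"),
                ScoringClause(scope="reactant_b", action="SUBTRACT", value=5, smarts="[CX4]"),
                ScoringClause(scope="reactant_a", action="KILL", smarts="[SX2H]"),
                ScoringClause(scope="reactant_a", action="ADD", value=30, smarts="[CX3](=O)"),
            ],
        )

    def test_no_clause_matches_gives_zero_delta(self, transform):
        # aromatic amine: neither the primary-aliphatic ADD nor the CX4 SUBTRACT fires
        delta, trace = score_reaction(
            transform, _mol("OC(=O)c1ccccc1"), _mol("Nc1ccccc1"), _mol("O=C(Nc1ccccc1)c1ccccc1")
        )
        # only the reactant_a ADD 30 matches here
        assert delta == 30 and len(trace) == 1
        no_match = Transform(**{**transform.__dict__, "clauses": transform.clauses[:2]})
        delta, trace = score_reaction(
            no_match, _mol("OC(=O)c1ccccc1"), _mol("Nc1ccccc1"), _mol("O=C(N)c1ccccc1")
        )
        assert delta == 0 and trace == []

    def test_add_and_subtract_sum(self, transform):
        delta, trace = score_reaction(
            transform, _mol("OC(=O)c1ccccc1"), _mol("NCC"), _mol("CCNC(=O)c1ccccc1")
        )
        # ADD 10 (primary aliphatic) + SUBTRACT 5 (alkyl carbon) + ADD 30 = +35
        assert delta == 35
        assert [(a, v) for _, a, v in trace] == [("ADD", 10), ("SUBTRACT", -5), ("ADD", 30)]

    def test_kill_dominates_any_add(self, transform):
        outcome = score_reaction(
            transform, _mol("OC(=O)CS"), _mol("NCC"), _mol("CCNC(=O)CS")
        )
        assert outcome[0] is KILLED
        assert outcome[1][-1][1] == "KILL"


class TestClassifyScore:
    def test_agrees_with_brute_force_binning(self):
        """Oracle: explicit bin table over all deltas in {-40..+40 step 5}."""
        def oracle(delta):
            if delta > 0:
                return "Plus"
            candidates = [n for n in (0, 10, 20, 30) if n <= abs(delta)]
            return f"Neg{max(candidates)}"

        for delta in range(-40, 45, 5):
            assert classify_score(delta) == oracle(delta)

    @pytest.mark.parametrize(
        "delta,label",
        [(5, "Plus"), (0, "Neg0"), (-5, "Neg0"), (-15, "Neg10"), (-40, "Neg30")],
    )
    def test_boundary_cases(self, delta, label):
        assert classify_score(delta) == label


class TestRunLibrary:
    def test_class_counts_partition_saved(self, library_run):
        totals = library_run.stats.totals
        assert sum(totals["class_counts"].values()) == totals["saved"]
        assert totals["saved"] == len(library_run.records)

    def test_success_rates_bounded(self, library_run):
        for pt in library_run.stats.per_transform.values():
            assert 0.0 <= pt["success_rate"] <= 1.0
            assert pt["saved"] + pt["killed"] <= pt["tested_pairs"]

    def test_atom_bookkeeping(self, library_run, standard_rules, prepared_blocks):
        """Heavy atoms of the as-generated product = A + B - declared leaving atoms."""
        by_id = {t.id: t for t in standard_rules}
        heavy = {
            bb.bb_id: bb.mol().GetNumHeavyAtoms()
            for bb in prepared_blocks
            if bb.rejected is None
        }
        assert library_run.records
        for rec in library_run.records:
            t = by_id[rec.transform_id]
            raw = rec.product_protected_smiles or rec.product_smiles
            product_atoms = Chem.MolFromSmiles(raw).GetNumHeavyAtoms()
            expected = heavy[rec.bb_a] + heavy[rec.bb_b] - t.leaving_group_heavy_atoms()
            assert product_atoms == expected, rec.product_id

    def test_ring_forming_rules_add_a_ring(self, library_run, standard_rules, prepared_blocks):
        ring_formers = {t.id for t in standard_rules if t.ring_forming}
        assert ring_formers
        rings = {
            bb.bb_id: Chem.rdMolDescriptors.CalcNumRings(bb.mol())
            for bb in prepared_blocks
            if bb.rejected is None
        }
        checked = 0
        for rec in library_run.records:
            if rec.transform_id not in ring_formers:
                continue
            raw = rec.product_protected_smiles or rec.product_smiles
            n = Chem.rdMolDescriptors.CalcNumRings(Chem.MolFromSmiles(raw))
            assert n >= rings[rec.bb_a] + rings[rec.bb_b] + 1
            checked += 1
        assert checked > 0

    def test_killed_reactions_only_in_audit(self, library_run):
        assert all(not rec.killed for rec in library_run.records)
        killed = [a for a in library_run.audit if a["outcome"] == "killed"]
        assert killed, "fixture library should exercise KILL clauses"
        assert all("clause_trace" in a for a in killed)

    def test_no_ambiguous_products_with_shipped_rules(self, library_run):
        assert not [a for a in library_run.audit if a["outcome"] == "ambiguous_product"]

    def test_always_kill_rule_has_zero_success_rate(self, prepared_blocks):
        t = Transform(
            id=77,
            name="always killed",
            role_a_pattern="[CX3](=O)[OX2H1]",
            role_b_pattern="[NX3;H2,H1;!$([NX3][CX3]=[OX1]);!$([NX3][!#6;!#1])]",
            product_template="[C:1](=[O:2])[OX2H1].[NX3;H2,H1:3]>>[C:1](=[O:2])[N:3]",
            leaving_groups=["O"],
            clauses=[ScoringClause(scope="product", action="KILL", smarts="[#6]")],
        )
        result = run_library([t], prepared_blocks)
        pt = result.stats.per_transform[77]
        assert pt["tested_pairs"] > 0
        assert pt["saved"] == 0 and pt["success_rate"] == 0.0

    def test_un_dp_suffixes(self, library_run):
        suffixes = {rec.product_id.rsplit("-", 1)[1] for rec in library_run.records}
        assert suffixes == {"UN", "DP"}
        for rec in library_run.records:
            has_pg_removed = rec.product_protected_smiles is not None
            assert rec.product_id.endswith("-DP") == has_pg_removed
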