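"""Building-block standardization, filters, deduplication, role assignment."""

import pytest
from rdkit import Chem

from synforge.bbs import (
    FilterConfig,
    assign_roles,
    count_match_sites,
    deduplicate,
    filter_bb,
    standardize,
)


def _prep(smiles, bb_id="X", config=FilterConfig()):
    return filter_bb(standardize(smiles, bb_id), config)


class TestStandardize:
    def test_largest_fragment_kept(self):
        assert standardize("CCN.Cl").smiles_std == "CCN"

    def test_plain_molecule_untouched(self):
        bb = standardize("NCCO")
        assert bb.smiles_std == "NCCO"
        assert bb.protecting_groups == []

    def test_boc_detected(self):
        assert standardize("CC(C)(C)OC(=O)NCCO").protecting_groups == ["Boc"]

    @pytest.mark.parametrize("bad", ["", "   ", "not_a_smiles((", "C1CC"])
    def test_unparseable_rejected(self, bad):
        assert standardize(bad).rejected == "parse_error"

    def test_carboxylate_salt_neutralized(self):
        assert standardize("CC(=O)[O-].[Na+]").smiles_std == "CC(=O)O"


class TestFilters:
    def test_isotope_rejected(self):
        assert _prep("[13CH3]C(=O)O").rejected == "isotope"

    def test_metal_rejected(self):
        assert _prep("CC[Sn](CC)CC").rejected == "metal"

    def test_boron_and_silicon_allowed(self):
        assert _prep("OB(O)c1ccccc1").rejected is None
        assert _prep("C[Si](C)(C)C").rejected is None

    def test_complexity_cutoff(self):
        bb = standardize("CC(=O)Nc1ccc(O)cc1")
        assert filter_bb(bb, FilterConfig(complexity_cutoff=10.0)).rejected == "complexity"

    def test_simple_molecule_accepted(self):
        assert _prep("CCO").rejected is None


class TestDeduplicate:
    def test_same_molecule_different_atom_order(self):
        bbs = [standardize(s, f"B{i}") for i, s in enumerate(["OCC", "CCO"])]
        kept = deduplicate(bbs)
        assert len(kept) == 1
        assert kept[0].bb_id == "B0"  # first occurrence wins

    def test_enantiomers_stay_distinct(self):
        bbs = [
            standardize(s, f"B{i}")
            for i, s in enumerate(["C[C@H](N)C(=O)O", "C[C@@H](N)C(=O)O"])
        ]
        assert len(deduplicate(bbs)) == 2

    def test_tautomer_pair_merges(self):
        """Keto and enol forms of one compound share a unique key.

        Oracle: both SMILES denote 4-hydroxypent-3-en-2-one/pentane-2,4-dione
        tautomers, so tautomer canonicalization must map them together.
        """
        keto, enol = "CC(=O)CC(C)=O", "CC(O)=CC(C)=O"
        bbs = [standardize(keto, "K"), standardize(enol, "E")]
        assert bbs[0].unique_key == bbs[1].unique_key
        assert len(deduplicate(bbs)) == 1

    def test_idempotent(self, prepared_blocks):
        once = deduplicate(prepared_blocks)
        assert deduplicate(once) == once


class TestRoleAssignment:
    @pytest.fixture()
    def amide(self, standard_rules):
        return next(t for t in standard_rules if "Amide" in t.name)

    def test_dual_role_excluded_from_both_sets(self, amide):
        bbs = [_prep("Nc1ccc(C(=O)O)cc1", "PABA")]
        role_a, role_b = assign_roles(amide, bbs)
        assert role_a.excluded_dual_role == ["PABA"]
        assert role_b.excluded_dual_role == ["PABA"]
        assert role_a.members == role_b.members == []

    def test_multi_site_excluded(self, amide):
        bbs = [_prep("Nc1cccc(N)c1", "MPD")]
        _, role_b = assign_roles(amide, bbs)
        assert role_b.excluded_multi_site == ["MPD"]

    def test_aniline_is_member(self, amide):
        bbs = [_prep("Nc1ccccc1", "ANI")]
        _, role_b = assign_roles(amide, bbs)
        assert role_b.members == ["ANI"]

    def test_symmetric_match_counts_one_site(self):
        """A pattern matching the same atoms in both directions is one site."""
        mol = Chem.MolFromSmiles("NCCN")
        patt = Chem.MolFromSmarts("NCCN")
        assert count_match_sites(mol, patt) == 1

    def test_partition_against_brute_force(self, standard_rules, prepared_blocks):
        """Role assignment agrees with a brute-force matcher on a <=50-block set.

        The oracle enumerates every substructure match without uniquification
        and counts distinct atom sets per role, then applies the dual-role and
        multi-site rules independently of assign_roles.
        """
        subset = [bb for bb in prepared_blocks if bb.rejected is None][:50]
        for t in standard_rules:
            role_a, role_b = assign_roles(t, subset)
            for role, patt in ((role_a, t.role_a), (role_b, t.role_b)):
                other = t.role_b if role.role == "A" else t.role_a
                members, dual, multi = [], [], []
                for bb in subset:
                    mol = bb.mol()
                    sites = {
                        frozenset(m)
                        for m in mol.GetSubstructMatches(patt, uniquify=False)
                    }
                    other_sites = {
                        frozenset(m)
                        for m in mol.GetSubstructMatches(other, uniquify=False)
                    }
                    if not sites:
                        continue
                    if other_sites:
                        dual.append(bb.bb_id)
                    elif len(sites) > 1:
                        multi.append(bb.bb_id)
                    else:
                        members.append(bb.bb_id)
                assert sorted(members) == role.members
                assert sorted(dual) == role.excluded_dual_role
                assert sorted(multi) == role.excluded_multi_site
                buckets = role.members + role.excluded_dual_role + role.excluded_multi_site
                assert len(buckets) == len(set(buckets))
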