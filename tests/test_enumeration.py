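"""Signature matching, chirality/sugar filters and the pair verifier."""
import pytest

from redoxqc import enumeration as enu
from redoxqc import fixtures as fix
from redoxqc.enumeration import DEFAULT_SIGNATURES, CategorySignature, RedoxPair
from redoxqc.speciation import Compound


def _compound(cid, name="", carbons=3, **groups):
    vec = dict.fromkeys(enu.GROUP_BASIS, 0)
    vec.update(groups)
    return Compound(cid, name=name, n_carbons=carbons, group_vector=vec)


def _oracle(compounds, signature, max_carbons=7):
    """Exhaustive O(n^2) double-loop reference."""
    out = []
    for a in compounds:
        for b in compounds:
            if a.id == b.id:
                continue
            if a.n_carbons >= max_carbons or b.n_carbons >= max_carbons:
                continue
            keys = set(a.group_vector) | set(signature.group_delta)
            if all(
                b.group_vector.get(k, 0) - a.group_vector.get(k, 0)
                == signature.group_delta.get(k, 0)
                for k in keys
            ):
                out.append((a.id, b.id))
    return sorted(out)


SIGNATURES = {s.category: s for s in DEFAULT_SIGNATURES}


class TestMatchPairs:
    def test_empty_input(self):
        assert enu.match_pairs([], SIGNATURES["G2"]) == []

    def test_planted_g2_pair_in_six_compound_set(self):
        compounds = [
            _compound("ald", carbonyl=1),
            _compound("alc", hydroxycarbon=1),
            _compound("acid", carboxylic_acid=1),
            _compound("amine", amine=1),
            _compound("hc"),
            _compound("diol", hydroxycarbon=2),
        ]
        pairs = enu.match_pairs(compounds, SIGNATURES["G2"])
        assert [(p.substrate_id, p.product_id) for p in pairs] == [("ald", "alc")]
        assert _oracle(compounds, SIGNATURES["G2"]) == [("ald", "alc")]

    def test_equals_oracle_for_all_signatures(self, bundle):
        for signature in DEFAULT_SIGNATURES:
            pairs = enu.match_pairs(bundle.compounds, signature)
            assert [
                (p.substrate_id, p.product_id) for p in pairs
            ] == _oracle(bundle.compounds, signature)

    def test_seven_carbon_compounds_excluded(self, bundle):
        pairs = enu.match_pairs(bundle.compounds, SIGNATURES["G2"])
        involved = {p.substrate_id for p in pairs} | {p.product_id for p in pairs}
        assert "bigald" not in involved and "bigalc" not in involved

    def test_every_planted_reaction_is_found(self, bundle):
        for planted in fix.planted_reactions():
            signature = SIGNATURES[planted.category]
            pairs = enu.match_pairs(bundle.compounds, signature)
            assert (planted.substrate_id, planted.product_id) in [
                (p.substrate_id, p.product_id) for p in pairs
            ]

    def test_inconsistent_basis_rejected(self):
        compounds = [
            _compound("a", carbonyl=1),
            Compound("b", group_vector={"weird_group": 1}),
        ]
        with pytest.raises(ValueError, match="basis"):
            enu.match_pairs(compounds, SIGNATURES["G2"])

    def test_signatures_are_mutually_distinct(self):
        deltas = [tuple(sorted(s.group_delta.items())) for s in DEFAULT_SIGNATURES]
        assert len(set(deltas)) == len(deltas)


class TestChiralityFilter:
    def _pairs_and_map(self):
        compounds = {
            c.id: c
            for c in [
                _compound("rx", name="(R)-X", carbonyl=1),
                _compound("ry", name="(R)-Y", hydroxycarbon=1),
                _compound("sy", name="(S)-Y", hydroxycarbon=1),
                _compound("plain", name="Y", hydroxycarbon=1),
            ]
        }
        return compounds

    def test_matching_and_absent_tokens_pass(self):
        compounds = self._pairs_and_map()
        pairs = [RedoxPair("rx", "ry", "G2"), RedoxPair("rx", "plain", "G2")]
        assert enu.chirality_filter(pairs, compounds) == pairs

    def test_conflicting_tokens_dropped(self):
        compounds = self._pairs_and_map()
        pairs = [RedoxPair("rx", "sy", "G2")]
        assert enu.chirality_filter(pairs, compounds) == []

    def test_cross_family_sugar_pair_survives_chirality(self, bundle):
        """The known failure mode: an L-pentonate to L-pentose reduction with
        mismatched carbon skeletons passes token matching and must be caught
        by the sugar-name filter instead."""
        compounds = {c.id: c for c in bundle.compounds}
        wrong = [RedoxPair("xylonate", "arabinose", "G1")]
        assert enu.chirality_filter(wrong, compounds) == wrong
        assert enu.sugar_name_filter(wrong, compounds) == []


class TestSugarNameFilter:
    def test_empty_rule_table_is_identity(self, bundle):
        compounds = {c.id: c for c in bundle.compounds}
        pairs = [RedoxPair("xylonate", "arabinose", "G1")]
        assert enu.sugar_name_filter(pairs, compounds, families={}) == pairs

    def test_same_family_reduction_retained(self, bundle):
        compounds = {c.id: c for c in bundle.compounds}
        pairs = [
            RedoxPair("xylonate", "xylose", "G1"),
            RedoxPair("xylose", "xylitol", "G2"),
        ]
        assert enu.sugar_name_filter(pairs, compounds) == pairs

    def test_non_sugar_names_unaffected(self, bundle):
        compounds = {c.id: c for c in bundle.compounds}
        pairs = [RedoxPair("ald1", "alc1", "G2")]
        assert enu.sugar_name_filter(pairs, compounds) == pairs


class TestPipelineProperties:
    def _filtered(self, bundle):
        compounds = {c.id: c for c in bundle.compounds}
        pairs = []
        for signature in DEFAULT_SIGNATURES:
            found = enu.match_pairs(bundle.compounds, signature)
            found = enu.chirality_filter(found, compounds)
            found = enu.sugar_name_filter(found, compounds)
            pairs.extend(found)
        return pairs, compounds

    def test_filters_idempotent(self, bundle):
        pairs, compounds = self._filtered(bundle)
        again = enu.sugar_name_filter(
            enu.chirality_filter(pairs, compounds), compounds
        )
        assert again == pairs

    def test_verifier_accepts_output_and_rejects_forgeries(self, bundle):
        pairs, compounds = self._filtered(bundle)
        enu.verify_pairs(pairs, compounds)
        with pytest.raises(AssertionError):
            enu.verify_pairs([RedoxPair("alc1", "ald1", "G2")], compounds)

    def test_natural_flagging(self, bundle):
        pairs, _ = self._filtered(bundle)
        known = [("ald1", "alc1")]
        flagged = enu.flag_natural(pairs, known)
        natural = {(p.substrate_id, p.product_id) for p in flagged if p.natural}
        assert natural == {("ald1", "alc1")}
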