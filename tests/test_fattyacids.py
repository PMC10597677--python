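import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pufascreen.fattyacids import (
    BDELLOID_CHARACTERIZED,
    ActivityKind,
    EnzymeActivity,
    FattyAcid,
    InapplicableReactionError,
    ParseError,
    ValidationError,
    apply_beta_oxidation_shortening,
    apply_elongation,
    apply_front_end_desaturation,
    apply_methyl_end_desaturation,
    close_pathway,
    delta_positions,
    load_activity_preset,
    parse_fatty_acid,
    reachable_set,
)

from oracles import enumerate_delta_positions


def valid_fatty_acids(max_carbons=24):
    out = []
    for carbons in range(4, max_carbons + 1, 2):
        out.append(FattyAcid(carbons, 0))
        for omega in (3, 6, 9):
            db = 1
            while True:
                try:
                    fa = FattyAcid(carbons, db, omega)
                except ValidationError:
                    break
                out.append(fa)
                db += 1
    return out


class TestParse:
    def test_epa_with_spaces(self):
        fa = parse_fatty_acid("20 : 5n-3")
        assert (fa.carbons, fa.double_bonds, fa.omega) == (20, 5, 3)

    def test_saturated(self):
        fa = parse_fatty_acid("18:0")
        assert (fa.carbons, fa.double_bonds, fa.omega) == (18, 0, None)

    def test_infeasible_rejected(self):
        with pytest.raises(ValidationError):
            parse_fatty_acid("18:7n-3")

    @pytest.mark.parametrize("bad", ["", "18", "18:3n3", "n-3", "18:3 n-", "abc"])
    def test_malformed(self, bad):
        with pytest.raises(ParseError):
            parse_fatty_acid(bad)

    def test_round_trip_all_valid(self):
        for fa in valid_fatty_acids():
            assert parse_fatty_acid(str(fa)) == fa

    def test_saturated_with_omega_rejected(self):
        with pytest.raises(ValidationError):
            FattyAcid(18, 0, 9)

    def test_odd_chain_rejected(self):
        with pytest.raises(ValidationError):
            FattyAcid(17, 0)


class TestDeltaPositions:
    @pytest.mark.parametrize(
        "shorthand,expected",
        [
            ("18:1n-9", [9]),
            ("18:3n-3", [9, 12, 15]),
            ("22:6n-3", [4, 7, 10, 13, 16, 19]),
            ("20:5n-3", [5, 8, 11, 14, 17]),
            ("18:0", []),
        ],
    )
    def test_examples(self, shorthand, expected):
        assert delta_positions(parse_fatty_acid(shorthand)) == expected

    def test_agrees_with_enumeration_oracle(self):
        for fa in valid_fatty_acids(24):
            if fa.saturated:
                assert delta_positions(fa) == []
            else:
                assert delta_positions(fa) == enumerate_delta_positions(
                    fa.carbons, fa.double_bonds, fa.omega
                )


class TestReactions:
    def test_d6_front_end(self):
        assert apply_front_end_desaturation(
            parse_fatty_acid("18:3n-3"), 6
        ) == parse_fatty_acid("18:4n-3")
        assert apply_front_end_desaturation(
            parse_fatty_acid("18:2n-6"), 6
        ) == parse_fatty_acid("18:3n-6")

    def test_d5_front_end(self):
        assert apply_front_end_desaturation(
            parse_fatty_acid("20:4n-3"), 5
        ) == parse_fatty_acid("20:5n-3")
        assert apply_front_end_desaturation(
            parse_fatty_acid("20:3n-6"), 5
        ) == parse_fatty_acid("20:4n-6")

    def test_front_end_needs_existing_bond(self):
        with pytest.raises(InapplicableReactionError):
            apply_front_end_desaturation(parse_fatty_acid("18:0"), 6)

    def test_d12_methyl_end(self):
        assert apply_methyl_end_desaturation(
            parse_fatty_acid("18:1n-9"), 12
        ) == parse_fatty_acid("18:2n-6")

    def test_d15_methyl_end(self):
        assert apply_methyl_end_desaturation(
            parse_fatty_acid("18:2n-6"), 15
        ) == parse_fatty_acid("18:3n-3")
        assert apply_methyl_end_desaturation(
            parse_fatty_acid("18:3n-6"), 15
        ) == parse_fatty_acid("18:4n-3")

    def test_methyl_end_needs_distal_bond(self):
        with pytest.raises(InapplicableReactionError):
            apply_methyl_end_desaturation(parse_fatty_acid("18:1n-9"), 15)

    def test_elongation(self):
        assert apply_elongation(parse_fatty_acid("18:3n-3")) == parse_fatty_acid("20:3n-3")
        assert apply_elongation(parse_fatty_acid("20:5n-3")) == parse_fatty_acid("22:5n-3")
        assert apply_elongation(parse_fatty_acid("18:0")) == parse_fatty_acid("20:0")

    def test_elongation_shifts_positions(self):
        fa = parse_fatty_acid("18:3n-3")
        assert delta_positions(apply_elongation(fa)) == [
            p + 2 for p in delta_positions(fa)
        ]

    def test_shortening(self):
        assert apply_beta_oxidation_shortening(
            parse_fatty_acid("24:6n-3")
        ) == parse_fatty_acid("22:6n-3")
        assert apply_beta_oxidation_shortening(
            parse_fatty_acid("24:5n-3")
        ) == parse_fatty_acid("22:5n-3")
        # min delta 9 >= 6, allowed
        assert apply_beta_oxidation_shortening(
            parse_fatty_acid("18:3n-3")
        ) == parse_fatty_acid("16:3n-3")

    def test_shortening_precondition(self):
        # 22:6n-3 has its proximal bond at delta 4 < 6
        with pytest.raises(InapplicableReactionError):
            apply_beta_oxidation_shortening(parse_fatty_acid("22:6n-3"))

    def test_elongate_then_shorten_identity(self):
        for fa in valid_fatty_acids(22):
            elongated = apply_elongation(fa)
            try:
                back = apply_beta_oxidation_shortening(elongated)
            except InapplicableReactionError:
                continue
            assert back == fa


class TestEnzymeActivity:
    def test_front_end_delta_required(self):
        with pytest.raises(ValidationError):
            EnzymeActivity(ActivityKind.FRONT_END_DESATURATION)

    def test_front_end_delta_minimum(self):
        with pytest.raises(ValidationError):
            EnzymeActivity(ActivityKind.FRONT_END_DESATURATION, delta=3)

    def test_elongation_range_required(self):
        with pytest.raises(ValidationError):
            EnzymeActivity(ActivityKind.ELONGATION)

    def test_elongation_respects_range(self):
        elo = EnzymeActivity(ActivityKind.ELONGATION, substrate_carbons=frozenset({18, 20}))
        assert elo.apply(parse_fatty_acid("20:5n-3")) == parse_fatty_acid("22:5n-3")
        with pytest.raises(InapplicableReactionError):
            elo.apply(parse_fatty_acid("22:5n-3"))


OLEIC = parse_fatty_acid("18:1n-9")
EPA = parse_fatty_acid("20:5n-3")
ARA = parse_fatty_acid("20:4n-6")
DHA = parse_fatty_acid("22:6n-3")


class TestReachability:
    def test_characterized_set_reaches_epa_and_ara_not_dha(self):
        reached = reachable_set(BDELLOID_CHARACTERIZED, [OLEIC])
        assert EPA in reached and ARA in reached
        assert DHA not in reached

    def test_empty_activity_list(self):
        assert reachable_set([], [OLEIC]) == {OLEIC}

    def test_monotone_in_activities(self):
        base = reachable_set(BDELLOID_CHARACTERIZED[:3], [OLEIC])
        bigger = reachable_set(BDELLOID_CHARACTERIZED, [OLEIC])
        assert base <= bigger

    def test_idempotent(self):
        once = reachable_set(BDELLOID_CHARACTERIZED, [OLEIC])
        twice = reachable_set(BDELLOID_CHARACTERIZED, once)
        assert once == twice

    def test_path_reconstruction(self):
        closure = close_pathway(BDELLOID_CHARACTERIZED, [OLEIC])
        path = closure.path(EPA)
        assert path[0][0] == OLEIC and path[0][1] is None
        assert path[-1][0] == EPA
        # every step is reproducible by applying the recorded activity
        for (prev, _), (acid, act) in zip(path, path[1:]):
            assert act.apply(prev) == acid

    def test_unreachable_path_raises(self):
        closure = close_pathway(BDELLOID_CHARACTERIZED, [OLEIC])
        with pytest.raises(KeyError):
            closure.path(DHA)

    def test_deterministic(self):
        a = close_pathway(BDELLOID_CHARACTERIZED, [OLEIC])
        b = close_pathway(BDELLOID_CHARACTERIZED, [OLEIC])
        assert a.acids == b.acids
        assert a.predecessor == b.predecessor


class TestDhaRoutes:
    def test_d4_route_requires_c20_elongation(self):
        d4 = EnzymeActivity(ActivityKind.FRONT_END_DESATURATION, delta=4)
        with_d4 = reachable_set(list(BDELLOID_CHARACTERIZED) + [d4], [OLEIC])
        assert DHA in with_d4
        # without C20 elongation 22:5n-3 never forms, so d4 cannot act
        no_c20 = [
            act
            if act.kind is not ActivityKind.ELONGATION
            else EnzymeActivity(ActivityKind.ELONGATION, substrate_carbons=frozenset({18}))
            for act in BDELLOID_CHARACTERIZED
        ]
        assert DHA not in reachable_set(no_c20 + [d4], [OLEIC])

    def test_sprecher_route(self):
        extra = [
            EnzymeActivity(ActivityKind.ELONGATION, substrate_carbons=frozenset({22})),
            EnzymeActivity(ActivityKind.BETA_OXIDATION_SHORTENING),
        ]
        reached = reachable_set(list(BDELLOID_CHARACTERIZED) + extra, [OLEIC])
        assert DHA in reached


class TestPresets:
    def test_bundled_preset(self):
        acts = load_activity_preset("bdelloid_characterized")
        assert set(acts) == set(BDELLOID_CHARACTERIZED)

    def test_from_file(self, tmp_path):
        path = tmp_path / "acts.json"
        path.write_text(
            json.dumps(
                {
                    "activities": [
                        {"kind": "front_end_desaturation", "delta": 4},
                        {"kind": "elongation", "substrate_carbons": [20, 22]},
                    ]
                }
            )
        )
        acts = load_activity_preset(str(path))
        assert acts[0].delta == 4
        assert acts[1].substrate_carbons == frozenset({20, 22})


@given(
    carbons=st.integers(2, 12).map(lambda k: 2 * k),
    double_bonds=st.integers(0, 6),
    omega=st.sampled_from([3, 6, 9]),
)
@settings(max_examples=200)
def test_round_trip_property(carbons, double_bonds, omega):
    try:
        fa = FattyAcid(carbons, double_bonds, omega if double_bonds else None)
    except ValidationError:
        return
    assert parse_fatty_acid(str(fa)) == fa
    positions = delta_positions(fa)
    assert positions == sorted(positions)
    assert len(positions) == fa.double_bonds
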