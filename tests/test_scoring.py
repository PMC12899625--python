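import random

import pytest

from sirnakit.core import RnaStrand
from sirnakit.fixtures import (
    ALL_CRITERIA_SITE,
    FixtureSpec,
    PlantedOfftarget,
    make_fixtures,
)
from sirnakit.scoring import (
    CRITERION_WEIGHTS,
    NOMINAL_MAX_POINTS,
    WEIGHT_SUM,
    ScoringContext,
    rank_candidates,
    score_duplex,
    table5_checks,
)
from conftest import duplex_from_sense


class TestWeights:
    def test_enumerated_weights_sum_to_16(self):
        assert WEIGHT_SUM == 16
        assert CRITERION_WEIGHTS["c3"] == 2 and CRITERION_WEIGHTS["c14"] == 2
        assert sum(1 for w in CRITERION_WEIGHTS.values() if w == 1) == 12

    def test_discrepancy_surfaced_in_metadata(self):
        card = score_duplex(duplex_from_sense(ALL_CRITERIA_SITE))
        assert card.metadata["weight_sum"] == 16
        assert card.metadata["nominal_max_points"] == NOMINAL_MAX_POINTS == 15
        assert "16" in card.metadata["weight_note"]


class TestSequenceCriteria:
    def test_engineered_site_hand_sum(self):
        # rule-by-rule hand evaluation of GCAGCGCGAUUAACUUAUAUU:
        # c1 GC 8/21=38.1% in [36,52]           -> 1
        # c2 aS GC 2-7 = 0% <= 19, 8-18 = 6/11 = 54.5% >= 52 -> 1
        # c3 A/U-rich steps 9-13 vs G/C flanks  -> 2
        # c4 no (GC)3 / (AU)4 tandem repeat     -> 1
        # c5 UU overhang                        -> 1
        # c6 aS starts A                        -> 1
        # c7 S starts G                         -> 1
        # c8 aS pos 6 = A                       -> 1
        # c9 S pos 3 = A, pos 19 = A            -> 1
        # c10 S pos 19 not G/C                  -> 1
        # c11 S pos 13 = A, not G               -> 1
        # c12 S pos 10 = U                      -> 1
        # c13/c14 unevaluated (no context)      -> 0
        card = score_duplex(duplex_from_sense(ALL_CRITERIA_SITE))
        assert card.total == 13
        for cid in [f"c{i}" for i in range(1, 13)]:
            assert card.passed(cid), cid
        assert not card.result("c13").evaluated
        assert not card.result("c14").evaluated

    def test_gc_window_criterion(self):
        card = score_duplex(duplex_from_sense("GCAGCGCGAUUAACUUAUAUU"))
        assert card.passed("c1")  # 38.1% within 36-52

    def test_positional_criteria(self):
        # U at sense 10, A at sense 3 and 19 on the engineered site
        card = score_duplex(duplex_from_sense(ALL_CRITERIA_SITE))
        assert card.passed("c12") and card.passed("c9")

    def test_tandem_repeat_criterion_fails_on_gcgcgc(self):
        seq = "GCGCGCAAUUAACUAAUUAUU"  # (GC)3 at the 5' end
        card = score_duplex(duplex_from_sense(seq))
        assert not card.passed("c4")

    def test_au_repeat_failure(self):
        seq = "GCAUAUAUAUCAAUUCAAUUU"  # (AU)4 run
        card = score_duplex(duplex_from_sense(seq))
        assert not card.passed("c4")


@pytest.fixture(scope="module")
def fixture_set():
    return make_fixtures(
        FixtureSpec(transcript_len=160, site_positions=(70,), seed=3)
    )


class TestContextCriteria:

    def test_purity(self, fixture_set):
        fx = fixture_set
        d = duplex_from_sense(ALL_CRITERIA_SITE, target_start=70)
        ctx = ScoringContext(
            transcript=fx.transcript, background=fx.background,
            target_id=fx.transcript.name,
        )
        a = score_duplex(d, ctx)
        b = score_duplex(d, ctx)
        assert a.total == b.total
        assert [(c.id, c.passed, c.points_awarded) for c in a.criteria] == [
            (c.id, c.passed, c.points_awarded) for c in b.criteria
        ]

    def test_full_context_awards_c13_c14(self, fixture_set):
        fx = fixture_set
        d = duplex_from_sense(ALL_CRITERIA_SITE, target_start=70)
        ctx = ScoringContext(transcript=fx.transcript, background=fx.background,
                             target_id=fx.transcript.name)
        card = score_duplex(d, ctx)
        assert card.result("c13").evaluated and card.result("c14").evaluated
        assert card.total == 16
        assert card.selectable

    def test_offtarget_hit_never_increases_total(self, fixture_set):
        clean = fixture_set
        dirty = make_fixtures(
            FixtureSpec(
                transcript_len=160, site_positions=(70,), seed=3,
                planted_offtargets=(PlantedOfftarget(record=0, mismatches=2),),
            )
        )
        d = duplex_from_sense(ALL_CRITERIA_SITE, target_start=70)
        total_clean = score_duplex(
            d, ScoringContext(transcript=clean.transcript, background=clean.background,
                              target_id=clean.transcript.name)
        ).total
        total_dirty = score_duplex(
            d, ScoringContext(transcript=dirty.transcript, background=dirty.background,
                              target_id=dirty.transcript.name)
        ).total
        assert total_dirty <= total_clean
        assert total_dirty == total_clean - CRITERION_WEIGHTS["c14"]


class TestRanking:
    def test_descending_totals_and_threshold(self):
        random.seed(5)
        seqs = [
            ALL_CRITERIA_SITE,
            "GCGCGCAAUUAACUAAUUAUU",
            "".join(random.choices("ACGU", k=21)),
        ]
        cards = [score_duplex(duplex_from_sense(s, target_start=i + 1))
                 for i, s in enumerate(seqs)]
        ranked = rank_candidates(cards)
        totals = [c.total for c in ranked]
        assert totals == sorted(totals, reverse=True)
        for c in ranked:
            assert c.selectable == (c.total > 10)

    def test_tie_break_by_position(self):
        a = score_duplex(duplex_from_sense(ALL_CRITERIA_SITE, target_start=50))
        b = score_duplex(duplex_from_sense(ALL_CRITERIA_SITE, target_start=10))
        ranked = rank_candidates([a, b])
        assert [c.duplex.target_start for c in ranked] == [10, 50]

    def test_empty_input(self):
        assert rank_candidates([]) == []


class TestTable5Checks:
    def test_alternating_islets(self):
        checks = table5_checks(duplex_from_sense("AUGCAUGCAUGCAUGCAUGCA"))
        assert checks["islands_2_3"]
        assert checks["au_gc_balance"]  # 10/21 = 47.6% GC, within +-10pp

    def test_all_au_fails_balance(self):
        checks = table5_checks(duplex_from_sense("AUAAAUAUAUAAUUAUAUAUU"))
        assert not checks["au_gc_balance"]
        assert not checks["homo_run_4_6"]  # one 21-nt run, not a 4-6-mer

    def test_conditional_34_rule(self):
        # first two A/U and positions 3-4 C/G
        checks = table5_checks(duplex_from_sense("AUCGAUAUCAUUGCAUAUAUU"))
        assert checks["conditional_34_rule"]

    def test_terminal_rule(self):
        checks = table5_checks(duplex_from_sense(ALL_CRITERIA_SITE))
        # sense starts GC (Y class), ends UU (X class)
        assert checks["terminal_rule"]
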