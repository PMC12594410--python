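"""Step execution: gating, scoring, acceptance, uniqueness, protocol runs."""

import random

import pytest

from helpers import make_claims, make_clinical, oracle_protocol
from steplink.engine import (
    accept,
    gate_pass,
    run_protocol,
    run_step,
    score_pair,
    stratify,
)
from steplink.model import (
    AcceptKind,
    AcceptRule,
    Granularity,
    PairScore,
)
from steplink.protocol import canonical_protocol, preprocess
from steplink.synthetic import SyntheticConfig, generate_pair

MONTH, YEAR = Granularity.MONTH, Granularity.YEAR


def steps_by_id(steps):
    return {s.step_id: s for s in steps}


class TestGate:
    def test_sex_and_birth_month_must_agree(self, protocol_steps):
        step1 = steps_by_id(protocol_steps)["1"]
        a = make_clinical("C1", sex="M", birth="1958-04")
        assert gate_pass(a, make_claims("S1", sex="M", birth="1958-04"), step1)
        assert not gate_pass(a, make_claims("S2", sex="F", birth="1958-04"), step1)
        assert not gate_pass(a, make_claims("S3", sex="M", birth="1958-07"), step1)

    def test_year_gate_tolerates_birth_month_discrepancy(self, protocol_steps):
        step5 = steps_by_id(protocol_steps)["5-strict"]
        a = make_clinical("C1", birth="1958-04")
        assert gate_pass(a, make_claims("S1", birth="1958-07"), step5)

    def test_missing_sex_fails_every_gate(self, protocol_steps):
        step1 = steps_by_id(protocol_steps)["1"]
        assert not gate_pass(make_clinical("C1", sex=None),
                             make_claims("S1"), step1)

    def test_ungated_step_always_passes(self, protocol_steps):
        step7 = steps_by_id(protocol_steps)["7-s9"]
        assert gate_pass(make_clinical("C1", sex=None, birth=None),
                         make_claims("S1"), step7)


class TestScorePair:
    def test_full_agreement_on_step1_variables(self, protocol_steps):
        step1 = steps_by_id(protocol_steps)["1"]
        a = make_clinical("C1", consent="2016-03-05", followup="2019-03-01",
                          death="2018-06", surgery="2016-05-10",
                          discharge="2016-05-20")
        b = make_claims("S1", visits=["2016-03-05", "2019-03-01"],
                        death="2018-06", surgery="2016-05-10",
                        discharge="2016-05-20")
        s = score_pair(a, b, step1)
        # gate variables (birth, sex) count toward the score
        assert s.matched_variables == frozenset({1, 2, 3, 4, 5, 6, 7})
        assert s.score == 7 and s.used_adjusted == frozenset()

    def test_month_only_surgery_agreement_is_adjusted_at_step_1a(
            self, protocol_steps):
        by_id = steps_by_id(protocol_steps)
        a = make_clinical("C1", consent="2016-03-05", followup="2019-03-01",
                          death="2018-06", surgery="2016-05-10")
        b = make_claims("S1", visits=["2016-03-05", "2019-03-01"],
                        death="2018-06", surgery="2016-05-28")
        strict = score_pair(a, b, by_id["1"])
        assert 6 not in strict.matched_variables
        relaxed = score_pair(a, b, by_id["1.A"])
        assert relaxed.matched_variables == frozenset({1, 2, 3, 4, 5, 6})
        assert relaxed.used_adjusted == frozenset({6})

    def test_all_step_variables_missing_scores_only_the_gate(
            self, protocol_steps):
        step1 = steps_by_id(protocol_steps)["1"]
        s = score_pair(make_clinical("C1"), make_claims("S1"), step1)
        assert s.matched_variables == frozenset({1, 2}) and s.n_date_matches == 0

    def test_each_variable_counts_once_and_session_dates_aggregate(
            self, protocol_steps):
        step2 = steps_by_id(protocol_steps)["2"]
        a = make_clinical("C1", chemo=["2016-01-04", "2016-01-25"])
        b = make_claims("S1", visits=["2019-01-01"],
                        chemo=["2016-01-04", "2016-01-25", "2016-02-15"])
        s = score_pair(a, b, step2)
        assert 9 in s.matched_variables and s.n_date_matches == 2

    def test_coarsening_never_decreases_the_score(self, protocol_steps):
        by_id = steps_by_id(protocol_steps)
        a = make_clinical("C1", consent="2016-03-05", surgery="2016-05-10",
                          discharge="2016-05-18", death="2018-06")
        b = make_claims("S1", visits=["2016-03-07"], surgery="2016-05-12",
                        discharge="2016-05-18", death="2018-06")
        assert score_pair(a, b, by_id["6-strict"]).score >= \
            score_pair(a, b, by_id["5-strict"]).score


class TestAccept:
    def ps(self, matched, n_dates=0, adjusted=()):
        return PairScore("C1", "S1", frozenset(matched), n_dates,
                         frozenset(adjusted))

    def test_min_score(self):
        rule = AcceptRule(AcceptKind.MIN_SCORE, 4)
        assert accept(self.ps({1, 2, 3, 9}), rule)
        assert not accept(self.ps({1, 2, 3}), rule)

    def test_three_variables_with_two_dates(self):
        rule = AcceptRule(AcceptKind.MIN_SCORE_OR_DATES, 4, min_dates=2)
        assert accept(self.ps({1, 2, 9}, n_dates=2), rule)
        assert not accept(self.ps({1, 2, 9}, n_dates=1), rule)
        assert accept(self.ps({1, 2, 3, 9}, n_dates=1), rule)

    def test_strict_rule_ignores_adjusted_matches(self):
        strict = AcceptRule(AcceptKind.MIN_SCORE, 4, max_adjusted=0)
        one_adj = AcceptRule(AcceptKind.MIN_SCORE, 4, max_adjusted=1)
        s = self.ps({1, 2, 3, 5}, adjusted={1})
        assert not accept(s, strict)
        assert accept(s, one_adj)
        # only one adjusted match may be counted toward the threshold
        two_adj = self.ps({1, 2, 3, 6}, adjusted={1, 6})
        assert not accept(two_adj, one_adj)
        extra = self.ps({1, 2, 3, 5, 6}, adjusted={1, 6})
        assert accept(extra, one_adj)  # three exact + one counted adjusted

    def test_exact_score_rejects_above_and_below(self):
        rule = AcceptRule(AcceptKind.EXACT_SCORE, 9)
        assert accept(self.ps(set(range(1, 10))), rule)
        assert not accept(self.ps(set(range(1, 9))), rule)
        assert not accept(self.ps(set(range(1, 11))), rule)


class TestStratify:
    def test_sex_chemo_yields_at_most_four_blocks(self, protocol_steps):
        step2 = steps_by_id(protocol_steps)["2"]
        clin = [make_clinical(f"C{i}", sex="M" if i % 2 else "F",
                              chemo=["2016-01-04"] if i < 2 else ())
                for i in range(6)]
        clm = [make_claims(f"S{i}", sex="M" if i % 2 else "F",
                           visits=["2016-01-01"]) for i in range(6)]
        blocks = stratify(clin, clm, step2)
        assert 1 <= len(blocks) <= 4

    def test_unstratified_steps_use_single_block(self, protocol_steps):
        step5 = steps_by_id(protocol_steps)["5-strict"]
        clin = [make_clinical(f"C{i}") for i in range(3)]
        clm = [make_claims(f"S{i}", visits=["2016-01-01"]) for i in range(3)]
        assert len(stratify(clin, clm, step5)) == 1

    def test_claims_pool_expansion_changes_block_contents(self, protocol_steps):
        from steplink.model import VisitKind
        from helpers import fev
        by_id = steps_by_id(protocol_steps)
        stay_only = make_claims("S1", visits=[fev("2016-01-01", "F001",
                                                  VisitKind.STAY)])
        blocks_narrow = stratify([], [stay_only], by_id["1"])
        blocks_wide = stratify([], [stay_only], by_id["5-strict"])
        n_narrow = sum(len(c) for _, c in blocks_narrow)
        n_wide = sum(len(c) for _, c in blocks_wide)
        assert (n_narrow, n_wide) == (0, 1)


class TestRunStep:
    def test_empty_claims_pool_yields_no_links(self, protocol_steps):
        step1 = steps_by_id(protocol_steps)["1"]
        out = run_step([make_clinical("C1")], [], step1)
        assert out.new_links == () and out.ambiguous == ()

    def test_two_acceptable_candidates_are_a_linkage_failure(
            self, protocol_steps):
        step1 = steps_by_id(protocol_steps)["1"]
        a = make_clinical("C1", consent="2016-03-05", death="2018-06",
                          surgery="2016-05-10", discharge="2016-05-20")
        twins = [make_claims(f"S{i}", visits=["2016-03-05"], death="2018-06",
                             surgery="2016-05-10", discharge="2016-05-20")
                 for i in (1, 2)]
        out = run_step([a], twins, step1)
        assert out.new_links == ()
        assert any(e.record_id == "C1" for e in out.ambiguous)

    def test_ambiguous_record_remains_eligible_for_later_steps(
            self, protocol_steps):
        # two claims twins at step 1, but only one carries the chemo dates:
        # step 2 resolves what step 1 could not
        a = make_clinical("C1", consent="2016-03-05", death="2018-06",
                          surgery="2016-05-10", discharge="2016-05-20",
                          chemo=["2016-06-01", "2016-08-01"])
        s1 = make_claims("S1", visits=["2016-03-05"], death="2018-06",
                         surgery="2016-05-10", discharge="2016-05-20",
                         chemo=["2016-06-01", "2016-08-01"])
        s2 = make_claims("S2", visits=["2016-03-05"], death="2018-06",
                         surgery="2016-05-10", discharge="2016-05-20")
        result, _ = run_protocol([a], [s1, s2], canonical_protocol())
        assert result.as_mapping() == {"C1": "S1"}
        assert [n for sid, n in result.step_counts if sid == "2"] == [1]


class TestRunProtocol:
    def test_zero_steps_zero_links(self):
        result, _ = run_protocol([make_clinical("C1")],
                                 [make_claims("S1")], [])
        assert result.n_linked == 0
        assert result.unlinked_clinical == frozenset({"C1"})

    def test_duplicate_ids_rejected(self, protocol_steps):
        with pytest.raises(ValueError, match="duplicate"):
            run_protocol([make_clinical("C1"), make_clinical("C1")],
                         [], protocol_steps)

    def test_missing_stratification_data_is_caught_by_part2(
            self, protocol_steps):
        # registry lost all surgery data; the claims twin has it, so the two
        # sit in different step-1 strata and meet only once blocking is gone
        a = make_clinical("C1", consent="2016-03-05", death="2018-06")
        b = make_claims("S1", visits=["2016-03-05"], death="2018-06",
                        surgery="2016-05-10", discharge="2016-05-20")
        result, _ = run_protocol([a], [b], protocol_steps)
        assert result.as_mapping() == {"C1": "S1"}
        linked_step = result.links[0].step_id
        assert linked_step.startswith("5")

    def test_global_one_to_one_and_monotone_cumulative(self, noisy_run):
        _, _, _, result, _ = noisy_run
        clin_ids = [l.clinical_id for l in result.links]
        clm_ids = [l.claims_id for l in result.links]
        assert len(set(clin_ids)) == len(clin_ids)
        assert len(set(clm_ids)) == len(clm_ids)
        running = 0
        for _, n in result.step_counts:
            assert n >= 0
            running += n
        assert running == result.n_linked

    def test_rerun_on_residue_adds_no_links(self, protocol_steps, noisy_run):
        clinical, claims, _, result, _ = noisy_run
        linked_clm = {l.claims_id for l in result.links}
        residue_clin = [r for r in clinical
                        if r.record_id in result.unlinked_clinical]
        residue_clm = [r for r in claims if r.record_id not in linked_clm]
        rerun, _ = run_protocol(residue_clin, residue_clm, protocol_steps)
        assert rerun.n_linked == 0

    def test_deterministic_under_row_permutation(self, protocol_steps):
        cfg = SyntheticConfig(n_clinical=40, n_claims_extra=60, seed=9)
        clinical, claims, _ = generate_pair(cfg)
        clinical = preprocess(clinical)
        claims = preprocess(claims)
        baseline, _ = run_protocol(clinical, claims, protocol_steps)
        rng = random.Random(4)
        for _ in range(3):
            sh_c, sh_m = list(clinical), list(claims)
            rng.shuffle(sh_c)
            rng.shuffle(sh_m)
            permuted, _ = run_protocol(sh_c, sh_m, protocol_steps)
            assert permuted.as_mapping() == baseline.as_mapping()
            assert permuted.step_counts == baseline.step_counts

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_all_pairs_oracle(self, protocol_steps, seed):
        cfg = SyntheticConfig(n_clinical=25, n_claims_extra=25,
                              overlap_fraction=0.8,
                              p_missing=0.25, p_date_error=0.15,
                              p_facility_error=0.05, n_facilities=4,
                              seed=seed)
        clinical, claims, _ = generate_pair(cfg)
        clinical = preprocess(clinical)
        claims = preprocess(claims)
        result, _ = run_protocol(clinical, claims, protocol_steps)
        got = {(l.clinical_id, l.claims_id, l.step_id) for l in result.links}
        assert got == oracle_protocol(clinical, claims, protocol_steps)
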