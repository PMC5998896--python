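"""Core birth-and-death machinery against the enumeration oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgmfrac import (
    EnumerationCapError,
    EventSchedule,
    History,
    InvalidHistoryError,
    ScheduleError,
    enumerate_histories,
    enumeration_expectations,
    expected_gene_count,
    expected_pairs_created,
    expected_pairs_observed,
    expected_unpaired,
    history_probability,
    multiplicity_after_event,
    pair_expectations,
)
from conftest import random_schedule


class TestMultiplicity:
    @pytest.mark.parametrize(
        "a, expected",
        [
            ((2, 1, 1, 1), 11),  # five genes under a ploidy-4 event
            ((0, 7), 14),  # every gene keeps both copies
            ((5,), 5),  # single category, identity
        ],
    )
    def test_copy_weighted_sum(self, a, expected):
        assert multiplicity_after_event(a) == expected

    @pytest.mark.parametrize("bad", [(), (0, 0), (-1, 2)])
    def test_rejects_degenerate_vectors(self, bad):
        with pytest.raises(InvalidHistoryError):
            multiplicity_after_event(bad)


class TestScheduleValidation:
    def test_rejects_unsorted_times(self):
        with pytest.raises(ScheduleError):
            EventSchedule(times=(1.0, 0.5), ploidies=(2,), survival=((0.5, 0.5),))

    def test_rejects_bad_survival_sum(self):
        with pytest.raises(ScheduleError):
            EventSchedule(times=(0, 1), ploidies=(2,), survival=((0.5, 0.6),))

    def test_rejects_ploidy_below_two(self):
        with pytest.raises(ScheduleError):
            EventSchedule(times=(0, 1), ploidies=(1,), survival=((1.0,),))

    def test_json_round_trip(self):
        s = EventSchedule(
            times=(0, 1, 2), ploidies=(2, 3), survival=((0.4, 0.6), (0.2, 0.5, 0.3)), m1=4
        )
        assert EventSchedule.from_json(s.to_json()) == s

    def test_json_rejects_missing_keys(self):
        with pytest.raises(ScheduleError):
            EventSchedule.from_json('{"times": [0, 1]}')


class TestHistoryProbability:
    def test_single_event_single_gene(self):
        s = EventSchedule(times=(0, 1), ploidies=(2,), survival=((0.3, 0.7),))
        assert history_probability(s, History(((0, 1),))) == pytest.approx(0.7, abs=1e-15)

    def test_dup_then_trip_history_is_two_w_v_u(self, rng):
        """The mixed-survival history after duplication+triplication has
        probability 2*w*v*u: the factor 2 counts the two colourings of
        which t_2 litter kept two versus three copies."""
        h = History(((0, 1), (0, 1, 1)))
        for _ in range(100):
            w = rng.uniform(0.05, 0.95)
            u = rng.uniform(0.05, 0.6)
            v = rng.uniform(0.05, 1 - u - 0.01)
            s = EventSchedule(
                times=(0, 1, 2), ploidies=(2, 3), survival=((1 - w, w), (1 - u - v, v, u))
            )
            assert history_probability(s, h) == pytest.approx(2 * w * v * u, abs=1e-12)

    def test_partial_range_probability(self):
        s = EventSchedule(
            times=(0, 1, 2), ploidies=(2, 3), survival=((0.3, 0.7), (0.2, 0.5, 0.3))
        )
        # second event only, starting from 2 genes
        p = history_probability(s, History(((1, 0, 1),)), from_event=2, to_event=3)
        assert p == pytest.approx(2 * 0.2 * 0.3, abs=1e-15)

    def test_inconsistent_history_raises(self):
        s = EventSchedule(times=(0, 1), ploidies=(2,), survival=((0.3, 0.7),))
        with pytest.raises(InvalidHistoryError):
            history_probability(s, History(((1, 1),)))  # sums to 2, but m1 = 1


class TestEnumeration:
    def test_one_gene_one_duplication_two_histories(self):
        s = EventSchedule(times=(0, 1), ploidies=(2,), survival=((0.4, 0.6),))
        assert len(enumerate_histories(s)) == 2

    def test_two_duplications_five_histories(self):
        s = EventSchedule(
            times=(0, 1, 2), ploidies=(2, 2), survival=((0.4, 0.6), (0.3, 0.7))
        )
        # 2 first-event outcomes; the 1-survivor branch has 2 continuations
        # and the 2-survivor branch has 3 second-event compositions
        assert len(enumerate_histories(s)) == 5

    def test_cap_refusal_is_explicit(self):
        s = EventSchedule(
            times=(0, 1, 2),
            ploidies=(3, 3),
            survival=((0.2, 0.5, 0.3),) * 2,
            m1=2,
        )
        with pytest.raises(EnumerationCapError) as err:
            enumerate_histories(s, gene_cap=12)
        assert err.value.required == 18
        assert enumerate_histories(s, gene_cap=18)  # explicit cap succeeds

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        ploidies=st.lists(st.integers(2, 3), min_size=1, max_size=2),
        m1=st.integers(1, 2),
        seed=st.integers(0, 10_000),
    )
    def test_probabilities_sum_to_one(self, ploidies, m1, seed):
        s = random_schedule(np.random.default_rng(seed), tuple(ploidies), m1=m1)
        records = enumerate_histories(s, gene_cap=18)
        assert math.fsum(r.probability for r in records) == pytest.approx(1.0, abs=1e-12)

    def test_grouped_probabilities_match_multinomial_formula(self, rng):
        s = random_schedule(rng, (2, 3))
        for rec in enumerate_histories(s, gene_cap=12):
            assert rec.probability == pytest.approx(
                history_probability(s, rec.history), abs=1e-13
            )

    def test_pair_partition_identity(self, rng):
        """Every surviving same-root pair has exactly one originating event."""
        s = random_schedule(rng, (2, 2, 2))
        for rec in enumerate_histories(s, gene_cap=12):
            total = sum(rec.expected_pairs_observed)
            # for a fixed aggregate history m_n is fixed; with one root the
            # total pair count must be C(m_n, 2) exactly
            assert total == pytest.approx(math.comb(rec.m_n, 2), abs=1e-9)


class TestClosedFormsAgainstOracle:
    def test_two_state_expected_count(self):
        s = EventSchedule(times=(0, 1), ploidies=(2,), survival=((0.4, 0.6),))
        assert expected_gene_count(s) == pytest.approx(1.6, abs=1e-15)

    def test_certain_survival_multiplies_ploidies(self):
        s = EventSchedule(
            times=(0, 1, 2), ploidies=(2, 3), survival=((0.0, 1.0), (0.0, 0.0, 1.0)), m1=5
        )
        assert expected_gene_count(s) == 30
        assert expected_unpaired(s) == 0.0

    def test_pairs_created_examples(self):
        s = EventSchedule(times=(0, 1), ploidies=(2,), survival=((0.4, 0.6),))
        assert expected_pairs_created(s, 1) == pytest.approx(0.6, abs=1e-15)
        s = EventSchedule(
            times=(0, 1), ploidies=(3,), survival=((0.0, 0.0, 1.0),), m1=2
        )
        assert expected_pairs_created(s, 1) == pytest.approx(6.0, abs=1e-15)
        s = EventSchedule(times=(0, 1), ploidies=(3,), survival=((1.0, 0.0, 0.0),))
        assert expected_pairs_created(s, 1) == 0.0

    def test_two_duplications_pair_inflation(self, rng):
        """A t_1-pair under a later duplication with survival beta grows to
        beta * (1 + beta)^2 expected observed pairs."""
        for _ in range(20):
            beta = rng.uniform(0.05, 0.95)
            s = EventSchedule(
                times=(0, 1, 2),
                ploidies=(2, 2),
                survival=((1 - beta, beta), (1 - beta, beta)),
            )
            assert expected_pairs_observed(s, 1) == pytest.approx(
                beta * (1 + beta) ** 2, abs=1e-12
            )
            assert expected_pairs_observed(s, 2) == pytest.approx(
                expected_pairs_created(s, 2), abs=1e-15
            )

    def test_unpaired_product_formula(self):
        s = EventSchedule(
            times=(0, 1, 2), ploidies=(2, 2), survival=((0.5, 0.5), (0.2, 0.8)), m1=10
        )
        assert expected_unpaired(s) == pytest.approx(1.0, abs=1e-15)

    def test_random_schedules_match_enumeration(self, rng):
        for ploidies in [(2,), (3,), (2, 3), (3, 2), (2, 2, 2)]:
            for m1 in (1, 2):
                s = random_schedule(rng, ploidies, m1=m1)
                closed = pair_expectations(s)
                oracle = enumeration_expectations(s, gene_cap=18)
                for a, b in zip(
                    (*closed.pairs_created, *closed.pairs_observed, closed.unpaired,
                     closed.total_genes),
                    (*oracle.pairs_created, *oracle.pairs_observed, oracle.unpaired,
                     oracle.total_genes),
                ):
                    assert a == pytest.approx(b, abs=1e-12)

    def test_gene_count_monotone_in_survival(self):
        """Shifting survival mass from 1 survivor to j >= 2 never shrinks E(m_n)."""
        base = (0.5, 0.3, 0.2)
        s0 = EventSchedule(times=(0, 1, 2), ploidies=(3, 2), survival=(base, (0.4, 0.6)))
        for j in (1, 2):
            shifted = list(base)
            shifted[0] -= 0.1
            shifted[j] += 0.1
            s1 = EventSchedule(
                times=(0, 1, 2), ploidies=(3, 2), survival=(tuple(shifted), (0.4, 0.6))
            )
            assert expected_gene_count(s1) >= expected_gene_count(s0)
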