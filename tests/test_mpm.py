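"""End-to-end pipelines, scheduling, qubit accounting, error protocol."""
import numpy as np
import pytest

import groverseq as gs
from groverseq import (
    ErrorStats,
    Pattern,
    brute_force_matches,
    encode_text,
    error_stats,
    qubits_required,
    run_enqbcea,
    run_enqpbea,
    run_experiment_protocol,
    schedule_patterns,
)
from groverseq.mpm import parallel_cost
from conftest import exact_t_text


def pats(*symbols):
    return [Pattern(s) for s in symbols]


class TestScheduling:
    def test_more_patterns_than_cores(self):
        sched = schedule_patterns(pats("TAA", "TAG", "TGA", "TAC", "TGC", "TTT"), 3)
        assert sched.waves == 2
        assert all(len(core) == 2 for core in sched.assignment)

    def test_idle_cores(self):
        sched = schedule_patterns(pats("TAA"), 3)
        assert sched.assignment == ((0,), (), ())
        assert sched.waves == 1

    def test_equal_patterns_and_cores(self):
        sched = schedule_patterns(pats("TAA", "TAG", "TGA"), 3)
        assert sched.waves == 1
        assert sched.placement(2) == (2, 0)

    def test_every_pattern_assigned_once(self):
        sched = schedule_patterns(pats("TA", "TC", "TG", "AT", "AC"), 2)
        all_idx = [k for core in sched.assignment for k in core]
        assert sorted(all_idx) == list(range(5))


class TestQubitAccounting:
    @pytest.mark.parametrize(
        "n,M,total", [(7, 3, 17), (9, 4, 21), (7, 2, 15), (8, 3, 18), (9, 3, 19)]
    )
    def test_position_based_layout(self, n, M, total):
        got, breakdown = qubits_required("enqpbea", n, M=M, w0=2)
        assert got == total
        assert breakdown["address"] == n and breakdown["data"] == M * 2

    def test_filtered_layout(self):
        total, breakdown = qubits_required("enqbcea", 7, t=23)
        assert (total, breakdown["location"]) == (19, 5)  # 14 + 5

    def test_filtered_layout_single_candidate(self):
        total, _ = qubits_required("enqbcea", 7, t=1)
        assert total == 14  # tq = 0

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError):
            qubits_required("other", 7, M=3)


class TestPositionBasedSearch:
    def test_multi_pattern_fixture_equivalence(self):
        text = gs.generate_synthetic_text(
            gs.SyntheticSpec(length=128, planted={"TAA": [0, 6]}, seed=21)
        )
        patterns = pats("TAA", "TAG", "TGA")
        reports = run_enqpbea(text, patterns, C=3, t_source="brute", seed=2)
        for rep, p in zip(reports, patterns):
            assert rep.found == brute_force_matches(text, p)
            assert (rep.core, rep.wave) == (patterns.index(p), 0)

    def test_absent_pattern_clean_exit(self):
        text, _ = exact_t_text(64, 3, 0, 0)
        rep = run_enqpbea(text, pats("TAG"), t_source=0, seed=0)[0]
        assert rep.found == () and not rep.aborted

    def test_determinism(self):
        text, pattern = exact_t_text(128, 3, 2, 4)
        r1 = run_enqpbea(text, [pattern], t_source=2, seed=77)
        r2 = run_enqpbea(text, [pattern], t_source=2, seed=77)
        assert r1[0].found == r2[0].found
        assert r1[0].trace_rows == r2[0].trace_rows


class TestFilteredSearch:
    def test_toy_end_to_end(self):
        rep = run_enqbcea(encode_text("ATAGC"), pats("TAG"), threshold=0, t_source="brute", seed=0)[0]
        assert rep.found == (1,)
        assert rep.filter.LA == (1,)

    def test_degenerate_filter_matches_position_search(self):
        text, pattern = exact_t_text(128, 3, 3, 8)
        r_pos = run_enqpbea(text, [pattern], t_source="brute", seed=5)[0]
        r_fil = run_enqbcea(text, [pattern], threshold=pattern.M, t_source="brute", seed=5)[0]
        assert r_fil.found == r_pos.found == brute_force_matches(text, pattern)

    def test_empty_filter_means_no_search(self):
        text, _ = exact_t_text(64, 1, 0, 3)  # G-free text
        rep = run_enqbcea(text, pats("G"), t_source="brute", seed=1)[0]
        assert rep.found == () and rep.grover_applications == 0

    def test_query_budget_on_filtered_space(self):
        text, pattern = exact_t_text(256, 3, 2, 9)
        rep = run_enqbcea(text, [pattern], threshold=1, t_source="brute", seed=3)[0]
        assert rep.found == brute_force_matches(text, pattern)
        t_filtered = 1 << rep.filter.tq
        t_exact = len(rep.found)
        per_round = np.ceil(np.pi / 4 * np.sqrt(t_filtered))
        assert rep.grover_applications <= np.pi * np.sqrt(
            t_filtered * max(t_exact, 1)
        ) + (rep.retries + 1) * per_round

    def test_sentinel_padding_never_reported(self):
        text, pattern = exact_t_text(128, 2, 2, 12)
        rep = run_enqbcea(text, [pattern], threshold=0, t_source="brute", seed=6)[0]
        assert all(i <= text.valid_limit(pattern.M) for i in rep.found)


class TestErrorStats:
    @pytest.mark.parametrize("cip,iip,expected", [(923, 77, "7.7"), (1000, 0, "0.0")])
    def test_published_cells(self, cip, iip, expected):
        stats = ErrorStats(CIP=cip, IIP=iip, IMP=0)
        assert stats.formatted_error_pct() == expected

    def test_undefined_when_no_measurements(self):
        stats = ErrorStats(CIP=0, IIP=0, IMP=0)
        assert not stats.defined and stats.error_pct is None
        assert stats.formatted_error_pct() == "undefined"

    def test_tally_from_stream(self):
        stats = error_stats([5, 9, 5, 2], true_indices={5, 7})
        assert (stats.CIP, stats.IIP, stats.IMP) == (2, 2, 1)


class TestProtocol:
    def test_accounting_identity(self):
        text, pattern = exact_t_text(128, 3, 2, 30)
        stats = run_experiment_protocol(text, pattern, t_source="exact", seed=8)
        assert stats.CIP + stats.IIP == 1000

    def test_single_occurrence_success_band(self):
        """With one planted occurrence at N=128 the per-trial success rate
        follows sin^2((2r+1) theta) within a 3-sigma binomial band."""
        text, pattern = exact_t_text(128, 3, 1, 31)
        stats = run_experiment_protocol(text, pattern, t_source="exact", seed=9)
        sched = gs.grover_iterations(128, 1)
        p = sched.success_probability()
        sigma = np.sqrt(p * (1 - p) / 1000)
        assert abs(stats.CIP / 1000 - p) < 3 * sigma
        assert stats.error_pct < 50

    def test_seed_reproducibility(self):
        text, pattern = exact_t_text(128, 3, 2, 32)
        a = run_experiment_protocol(text, pattern, t_source=2, seed=3)
        b = run_experiment_protocol(text, pattern, t_source=2, seed=3)
        assert a.to_dict() == b.to_dict()

    def test_small_iteration_count_can_miss_indices(self):
        # Few trials over many true indices risks IMP > 0 by pigeonhole.
        text, pattern = exact_t_text(128, 1, 10, 33)
        stats = run_experiment_protocol(text, pattern, t_source=10, R=1, I=5, seed=1)
        assert stats.CIP + stats.IIP == 5
        assert stats.IMP >= 5  # 10 true indices, at most 5 measured

    def test_filtered_protocol(self):
        text, pattern = exact_t_text(128, 3, 2, 34)
        stats = run_experiment_protocol(
            text, pattern, algorithm="enqbcea", t_source="exact", seed=4
        )
        assert stats.CIP + stats.IIP == 1000


class TestWaveAccounting:
    def test_parallel_cost_reduces_to_single_core_when_enough_cores(self):
        text = gs.generate_synthetic_text(
            gs.SyntheticSpec(length=128, planted={"TAA": [0, 40]}, seed=40)
        )
        patterns = pats("TAA", "TAG")
        many = run_enqpbea(text, patterns, C=2, t_source="brute", seed=11)
        assert parallel_cost(many, 2) == max(r.grover_applications for r in many)

    def test_cost_sums_wave_maxima(self):
        text = gs.generate_synthetic_text(gs.SyntheticSpec(length=64, seed=41))
        patterns = pats("TA", "TC", "AG", "AC")
        reports = run_enqpbea(text, patterns, C=2, t_source="brute", seed=12)
        by_wave: dict[int, list[int]] = {}
        for r in reports:
            by_wave.setdefault(r.wave, []).append(r.grover_applications)
        assert parallel_cost(reports, 2) == sum(max(v) for v in by_wave.values())
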