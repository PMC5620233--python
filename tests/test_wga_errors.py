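"""WGA error calling, recurrent-error blacklist, VAF summaries, FP match rate."""

import statistics

import numpy as np
import pytest

from ctcseq.variants import (
    GenomicVariant,
    ObservedVariant,
    PairingError,
    SampleRole,
    SampleVariantSet,
)
from ctcseq.wga_errors import (
    Blacklist,
    ErrorCallSet,
    InsufficientControlsError,
    UndefinedRateError,
    build_blacklist,
    call_amplification_errors,
    estimate_fp_match_rate,
    read_blacklist,
    summarize_error_vafs,
    write_blacklist,
)

V = GenomicVariant


def _ov(chrom, pos, ref, alt, depth=400, alt_count=4):
    return ObservedVariant(V(chrom, pos, ref, alt), depth, alt_count)


def _set(sample_id, patient_id, role, ovs):
    return SampleVariantSet(sample_id, patient_id, role, ovs)


class TestCallAmplificationErrors:
    def test_set_difference(self):
        v1, v2 = _ov("chr1", 10, "C", "T"), _ov("chr1", 20, "G", "A")
        amp = _set("A", "P1", SampleRole.AMPLIFIED_NORMAL, [v1, v2])
        norm = _set("N", "P1", SampleRole.NORMAL, [v1])
        errors = call_amplification_errors(amp, norm)
        assert [ov.variant.key for ov in errors.errors] == [v2.variant.key]

    def test_identical_sets_give_empty(self):
        v1 = _ov("chr1", 10, "C", "T")
        amp = _set("A", "P1", SampleRole.AMPLIFIED_NORMAL, [v1])
        norm = _set("N", "P1", SampleRole.NORMAL, [v1])
        assert len(call_amplification_errors(amp, norm)) == 0

    def test_empty_amplified_gives_empty(self):
        amp = _set("A", "P1", SampleRole.AMPLIFIED_NORMAL, [])
        norm = _set("N", "P1", SampleRole.NORMAL, [_ov("chr1", 10, "C", "T")])
        assert len(call_amplification_errors(amp, norm)) == 0

    def test_patient_mismatch_raises(self):
        amp = _set("A", "P1", SampleRole.AMPLIFIED_NORMAL, [])
        norm = _set("N", "P2", SampleRole.NORMAL, [])
        with pytest.raises(PairingError):
            call_amplification_errors(amp, norm)


class TestBuildBlacklist:
    def _sets(self, incidence):
        """incidence: list (per sample) of lists of (pos, vaf)."""
        out = []
        for i, items in enumerate(incidence):
            ovs = [
                ObservedVariant(V("chr1", pos, "C", "T"), 1000, round(vaf * 1000))
                for pos, vaf in items
            ]
            out.append(ErrorCallSet(patient_id=f"P{i}", errors=ovs))
        return out

    def test_key_in_two_of_many_sets_is_blacklisted(self):
        sets = self._sets([[(10, 0.005)], [(10, 0.006)], [(20, 0.01)]])
        bl = build_blacklist(sets, min_recurrence=2)
        assert ("chr1", 10, "C", "T") in bl
        assert bl.entries[("chr1", 10, "C", "T")].n_samples == 2

    def test_singleton_key_absent(self):
        sets = self._sets([[(10, 0.005)], [(20, 0.006)]])
        bl = build_blacklist(sets, min_recurrence=2)
        assert len(bl) == 0

    def test_median_is_middle_order_statistic(self):
        vafs = [0.004, 0.005, 0.006, 0.007, 0.009]
        sets = self._sets([[(10, v)] for v in vafs])
        bl = build_blacklist(sets, min_recurrence=2)
        entry = bl.entries[("chr1", 10, "C", "T")]
        assert entry.n_samples == 5
        assert entry.vaf_median == pytest.approx(0.006)

    def test_fewer_than_two_sets_raises(self):
        with pytest.raises(InsufficientControlsError):
            build_blacklist(self._sets([[(10, 0.005)]]))

    def test_monotone_in_min_recurrence(self, rng):
        sets = self._random_toy_cohort(rng)
        previous = None
        for k in range(2, 6):
            bl = build_blacklist(sets, min_recurrence=k)
            keys = set(bl.entries)
            if previous is not None:
                assert keys <= previous
            previous = keys

    def _random_toy_cohort(self, rng, n_sets=5, n_keys=20):
        keys = [("chr1", int(p), "C", "T") for p in range(10, 10 + n_keys)]
        sets = []
        for i in range(n_sets):
            chosen = [k for k in keys if rng.random() < 0.4]
            ovs = [
                ObservedVariant(
                    V(*k), 1000, int(rng.integers(1, 40))
                )
                for k in chosen
            ]
            sets.append(ErrorCallSet(patient_id=f"P{i}", errors=ovs))
        return sets

    def test_agrees_with_brute_force_incidence_counting(self, rng):
        """Oracle: explicit count over all (key, sample) incidence pairs."""
        for trial in range(25):
            sets = self._random_toy_cohort(rng)
            for k in (2, 3):
                bl = build_blacklist(sets, min_recurrence=k)
                # brute force
                all_keys = {ov.variant.key for es in sets for ov in es.errors}
                expected = {}
                for key in all_keys:
                    hits = [
                        ov.vaf
                        for es in sets
                        for ov in es.errors
                        if ov.variant.key == key
                    ]
                    n = sum(
                        1
                        for es in sets
                        if any(ov.variant.key == key for ov in es.errors)
                    )
                    if n >= k:
                        expected[key] = (n, statistics.median(hits))
                assert set(bl.entries) == set(expected)
                for key, (n, med) in expected.items():
                    assert bl.entries[key].n_samples == n
                    assert bl.entries[key].vaf_median == pytest.approx(med)


class TestSummarizeErrorVafs:
    def test_partition_conservation_and_medians(self, default_error_sets, default_blacklist):
        summ = summarize_error_vafs(default_error_sets, default_blacklist)
        total = sum(len(es) for es in default_error_sets)
        assert summ.n_recurrent + summ.n_nonrecurrent == total
        assert summ.recurrent_vaf_median < summ.nonrecurrent_vaf_median

    def test_single_observation_is_its_own_median(self):
        es = ErrorCallSet("P1", [_ov("chr1", 10, "C", "T", 1000, 7)])
        summ = summarize_error_vafs([es], Blacklist.empty())
        assert summ.nonrecurrent_vaf_median == pytest.approx(0.007)
        assert summ.recurrent_vaf_median is None  # empty partition: undefined

    def test_empty_partition_is_none_not_zero(self):
        summ = summarize_error_vafs([ErrorCallSet("P1", [])], Blacklist.empty())
        assert summ.recurrent_vaf_median is None
        assert summ.nonrecurrent_vaf_median is None


class TestFpMatchRate:
    def _cohort(self, n_sets, per_set, n_match):
        """n_sets error sets with per_set retained errors; n_match of them
        (spread over the first sets) match the paired tumor."""
        error_sets, tumors = [], {}
        pos = 100
        matches_left = n_match
        for i in range(n_sets):
            pid = f"P{i}"
            ovs, tumor_ovs = [], []
            for j in range(per_set):
                ov = _ov("chr1", pos, "C", "T", depth=400, alt_count=8)  # vaf 2%
                ovs.append(ov)
                if matches_left > 0 and j == 0:
                    tumor_ovs.append(
                        ObservedVariant(ov.variant, 500, 200)
                    )
                    matches_left -= 1
                pos += 1
            error_sets.append(ErrorCallSet(pid, ovs))
            tumors[pid] = _set(f"{pid}_T", pid, SampleRole.TUMOR, tumor_ovs)
        return error_sets, tumors

    def test_printed_counts_give_02_percent(self):
        # 14 amplified normals totalling 1915 retained errors, 4 tumor matches
        per_set, rem = divmod(1915, 14)
        error_sets, tumors = self._cohort(14, per_set, 4)
        # pad the remainder into the last set
        for j in range(rem):
            error_sets[-1].errors.append(
                _ov("chr2", 5000 + j, "C", "T", depth=400, alt_count=8)
            )
        fp = estimate_fp_match_rate(error_sets, Blacklist.empty(), tumors)
        assert (fp.n_match, fp.n_total) == (4, 1915)
        assert fp.rate_percent == 0.2

    def test_zero_matches_give_zero_rate(self):
        error_sets, tumors = self._cohort(3, 10, 0)
        fp = estimate_fp_match_rate(error_sets, Blacklist.empty(), tumors)
        assert fp.rate_percent == 0.0

    def test_threshold_is_strictly_greater(self):
        # all error VAFs exactly at the 1% threshold -> empty denominator
        ovs = [_ov("chr1", 10 + i, "C", "T", depth=400, alt_count=4) for i in range(5)]
        es = ErrorCallSet("P0", [o for o in ovs])
        tumors = {"P0": _set("T", "P0", SampleRole.TUMOR, [])}
        with pytest.raises(UndefinedRateError):
            estimate_fp_match_rate([es], Blacklist.empty(), tumors)

    def test_blacklisted_errors_excluded_from_denominator(self):
        error_sets, tumors = self._cohort(2, 10, 0)
        key = error_sets[0].errors[0].variant.key
        from ctcseq.wga_errors import BlacklistEntry

        bl = Blacklist({key: BlacklistEntry(2, 0.005)})
        fp = estimate_fp_match_rate(error_sets, bl, tumors)
        assert fp.n_total == 19

    def test_missing_tumor_raises_pairing_error(self):
        error_sets, _ = self._cohort(2, 5, 0)
        with pytest.raises(PairingError):
            estimate_fp_match_rate(error_sets, Blacklist.empty(), {})


def test_blacklist_tsv_round_trip(tmp_path, default_blacklist):
    path = tmp_path / "blacklist.tsv"
    write_blacklist(default_blacklist, path)
    loaded = read_blacklist(path)
    assert set(loaded.entries) == set(default_blacklist.entries)
    assert loaded.min_recurrence == default_blacklist.min_recurrence
    for key, e in default_blacklist.entries.items():
        assert loaded.entries[key].n_samples == e.n_samples
        assert loaded.entries[key].vaf_median == pytest.approx(
            e.vaf_median, rel=1e-4
        )
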