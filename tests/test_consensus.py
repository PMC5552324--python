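"""Consensus merge, filtering and benchmarking tests (incl. brute-force oracles)."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import binom

from deepintron.consensus import (
    apply_depth_filter,
    benchmark,
    merge_callsets,
    restrict_to_targets,
)
from deepintron.errors import ParameterError
from deepintron.variant_model import (
    CallerObservation,
    GenomicVariant,
    Genotype,
    TargetRegions,
)
from oracles import brute_force_consensus, brute_force_in_targets

CALLERS = ("caller_1", "caller_2", "caller_3", "caller_4")


def obs(caller, pos, sample="S1", genotype=Genotype.HET, depth=30, chrom="1", alt="G"):
    return CallerObservation(caller, GenomicVariant(chrom, pos, "A", alt), sample, genotype, depth)


def random_callsets(rng, n_variants=40, n_samples=3, p_call=0.5):
    callsets = {c: [] for c in CALLERS}
    for c in CALLERS:
        for i in range(n_variants):
            for s in range(n_samples):
                if rng.random() < p_call:
                    genotype = [Genotype.HET, Genotype.HOM_ALT, Genotype.HOM_REF][int(rng.integers(0, 3))]
                    callsets[c].append(
                        obs(c, 100 + i * 10, sample=f"S{s}", genotype=genotype,
                            depth=int(rng.integers(0, 60)))
                    )
    return callsets


class TestMergeCallsets:
    def test_two_supporters_retained_at_k2(self):
        callsets = {
            "caller_1": [obs("caller_1", 100)],
            "caller_2": [obs("caller_2", 100)],
            "caller_3": [],
            "caller_4": [],
        }
        cs = merge_callsets(callsets, k=2)
        assert len(cs) == 1
        assert cs.entries[0].support == {"caller_1", "caller_2"}

    def test_single_supporter_dropped_at_k2(self):
        callsets = {"caller_1": [obs("caller_1", 100)], "caller_2": []}
        assert len(merge_callsets(callsets, k=2)) == 0

    def test_hom_ref_does_not_support(self):
        callsets = {
            "caller_1": [obs("caller_1", 100)],
            "caller_2": [obs("caller_2", 100, genotype=Genotype.HOM_REF)],
        }
        assert len(merge_callsets(callsets, k=2)) == 0

    def test_k1_is_union_and_kn_is_intersection(self, rng):
        callsets = random_callsets(rng)
        union = brute_force_consensus(callsets, 1)
        intersection = brute_force_consensus(callsets, len(CALLERS))
        cs1 = merge_callsets(callsets, k=1)
        csn = merge_callsets(callsets, k=len(CALLERS))
        assert {(e.sample, e.variant.key) for e in cs1.entries} == union
        assert {(e.sample, e.variant.key) for e in csn.entries} == intersection

    def test_k_out_of_range(self):
        with pytest.raises(ParameterError):
            merge_callsets({"caller_1": []}, k=2)
        with pytest.raises(ParameterError):
            merge_callsets({"caller_1": []}, k=0)

    def test_majority_genotype_tie_resolves_het(self):
        callsets = {
            "caller_1": [obs("caller_1", 100, genotype=Genotype.HOM_ALT)],
            "caller_2": [obs("caller_2", 100, genotype=Genotype.HET)],
        }
        cs = merge_callsets(callsets, k=2)
        assert cs.entries[0].genotype is Genotype.HET

    def test_majority_genotype_wins(self):
        callsets = {
            "caller_1": [obs("caller_1", 100, genotype=Genotype.HOM_ALT)],
            "caller_2": [obs("caller_2", 100, genotype=Genotype.HOM_ALT)],
            "caller_3": [obs("caller_3", 100, genotype=Genotype.HET)],
        }
        assert merge_callsets(callsets, k=2).entries[0].genotype is Genotype.HOM_ALT

    def test_oracle_equivalence_500_random_callsets(self, rng):
        for trial in range(500):
            callsets = random_callsets(rng, n_variants=8, n_samples=2, p_call=0.4)
            k = int(rng.integers(1, 5))
            cs = merge_callsets(callsets, k=k)
            assert {(e.sample, e.variant.key) for e in cs.entries} == brute_force_consensus(callsets, k)

    def test_monotone_nonincreasing_in_k(self, rng):
        callsets = random_callsets(rng)
        kept = [
            {(e.sample, e.variant.key) for e in merge_callsets(callsets, k=k).entries}
            for k in range(1, 5)
        ]
        for higher, lower in zip(kept[1:], kept):
            assert higher <= lower


class TestDepthFilter:
    def _cs(self, depths):
        callsets = {
            c: [obs(c, 100, depth=d)] for c, d in zip(CALLERS, depths)
        }
        return merge_callsets({c: callsets.get(c, []) for c in CALLERS[: len(depths)]}, k=2)

    def test_min_depth_inclusive_at_threshold(self):
        cs = self._cs([22, 35])
        assert len(apply_depth_filter(cs, 20)) == 1
        cs = self._cs([20, 20])
        assert len(apply_depth_filter(cs, 20)) == 1

    def test_one_shallow_supporter_removes_variant(self):
        cs = self._cs([19, 40])
        assert len(apply_depth_filter(cs, 20)) == 0

    def test_mean_aggregate_configurable(self):
        cs = self._cs([19, 40])
        assert len(apply_depth_filter(cs, 20, aggregate="mean")) == 1

    def test_min_depth_zero_is_identity(self, rng):
        callsets = random_callsets(rng)
        cs = merge_callsets(callsets, k=2)
        assert apply_depth_filter(cs, 0).entries == cs.entries


class TestTargetRestriction:
    def test_half_open_boundaries(self):
        targets = TargetRegions.from_intervals([("1", 99, 200)])
        inside = merge_callsets({"caller_1": [obs("caller_1", 100)]}, k=1)
        at_end = merge_callsets({"caller_1": [obs("caller_1", 200)]}, k=1)
        assert len(restrict_to_targets(inside, targets)) == 1
        assert len(restrict_to_targets(at_end, targets)) == 1  # pos 200 -> 0-based 199 < 200
        past_end = merge_callsets({"caller_1": [obs("caller_1", 201)]}, k=1)
        assert len(restrict_to_targets(past_end, targets)) == 0

    def test_bed_start_plus_one_kept(self):
        targets = TargetRegions.from_intervals([("1", 99, 200)])
        cs = merge_callsets({"caller_1": [obs("caller_1", 100)]}, k=1)
        assert len(restrict_to_targets(cs, targets)) == 1
        before = merge_callsets({"caller_1": [obs("caller_1", 99)]}, k=1)
        assert len(restrict_to_targets(before, targets)) == 0

    def test_empty_targets_empty_output(self, rng):
        callsets = random_callsets(rng)
        cs = merge_callsets(callsets, k=1)
        assert len(restrict_to_targets(cs, TargetRegions())) == 0

    def test_oracle_equivalence_random(self, rng):
        for _ in range(500):
            intervals = [
                ("1", int(s), int(s) + int(rng.integers(1, 50)))
                for s in rng.integers(0, 500, size=5)
            ]
            targets = TargetRegions.from_intervals(intervals)
            positions = [("1", int(p)) for p in rng.integers(1, 600, size=20)]
            expected = brute_force_in_targets(positions, intervals)
            got = {
                (chrom, pos) for chrom, pos in positions if targets.contains(chrom, pos)
            }
            assert got == expected

    def test_chrom_dialects_reconciled(self):
        targets = TargetRegions.from_intervals([("chr1", 0, 1000)])
        cs = merge_callsets({"caller_1": [obs("caller_1", 100, chrom="1")]}, k=1)
        assert len(restrict_to_targets(cs, targets)) == 1


class TestBenchmark:
    def test_perfect_callset(self):
        truth = [GenomicVariant("1", p, "A", "G") for p in (10, 20, 30)]
        r = benchmark(truth, truth)
        assert (r.sensitivity, r.precision) == (1.0, 1.0)

    def test_published_formula_values(self):
        truth = [GenomicVariant("1", p, "A", "G") for p in range(1, 101)]
        called = [GenomicVariant("1", p, "A", "G") for p in range(1, 98)]  # 97 TP, 3 FN
        called += [GenomicVariant("2", p, "A", "G") for p in (5, 6)]  # 2 FP
        r = benchmark(called, truth)
        assert (r.tp, r.fp, r.fn) == (97, 2, 3)
        assert r.sensitivity == pytest.approx(0.97)
        assert r.precision == pytest.approx(97 / 99)
        assert r.precision == pytest.approx(0.9798, abs=1e-4)

    def test_empty_callset_has_undefined_precision(self):
        truth = [GenomicVariant("1", 10, "A", "G")]
        r = benchmark([], truth)
        assert r.sensitivity == 0.0
        assert r.precision is None

    def test_counts_partition_truth(self, rng):
        callsets = random_callsets(rng)
        cs = merge_callsets(callsets, k=2)
        truth = [GenomicVariant("1", 100 + i * 10, "A", "G") for i in range(20)]
        r = benchmark(cs, truth)
        assert r.tp + r.fn == len(truth)
        assert r.tp >= 0 and r.fp >= 0 and r.fn >= 0


class TestConsensusStatistics:
    """Simulation-backed properties (closed-form checks live here)."""

    def test_k2_of_4_sensitivity_matches_binomial_closed_form(self):
        from deepintron.synthetic import SimulationConfig, simulate_truth_and_callers

        s, n, k = 0.9, 4, 2
        closed_form = float(1 - binom.cdf(k - 1, n, s))
        assert closed_form == pytest.approx(0.9963, abs=1e-4)
        detected = total = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_truth_variants=120, fp_rate_per_kb=0.0,
                                   indel_jitter_prob=0.0, indel_fraction=0.0)
            sim = simulate_truth_and_callers(cfg)
            cs = merge_callsets(sim.callsets, k=k)
            retained = {(e.sample, e.variant.key) for e in cs.entries}
            for t in sim.truth:
                for sample in t.carriers:
                    total += 1
                    detected += (sample, t.variant.key) in retained
        rate = detected / total
        mc_se = np.sqrt(closed_form * (1 - closed_form) / total)
        assert abs(rate - closed_form) <= 3 * mc_se

    def test_consensus_precision_beats_best_single_caller(self):
        from deepintron.synthetic import SimulationConfig, simulate_truth_and_callers

        for seed in (0, 1, 2):
            cfg = SimulationConfig(seed=seed, n_truth_variants=150, fp_rate_per_kb=0.5,
                                   indel_fraction=0.0, indel_jitter_prob=0.0)
            sim = simulate_truth_and_callers(cfg)
            truth = sim.truth_variants
            consensus_precision = benchmark(merge_callsets(sim.callsets, k=2), truth).precision
            single = [
                benchmark(merge_callsets({c: sim.callsets[c]}, k=1), truth).precision
                for c in sim.callsets
            ]
            assert consensus_precision >= max(single)
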