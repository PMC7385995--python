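"""Synthetic-data generator: determinism, the K2P evolution model, planting
structure, reads, and the discovery evaluator against a brute-force matcher."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mitescout.align import revcomp
from mitescout.discovery import at_content
from mitescout.models import GenomicInterval
from mitescout.simulate import (
    PlantSpec,
    evaluate_discovery,
    evolve_k2p,
    excise,
    make_consensus,
    plant_mites,
    simulate_genome,
    simulate_reads,
)
from tests.conftest import family_specs


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        g1, genes1 = simulate_genome(50_000, 0.5, 10, seed=9)
        g2, genes2 = simulate_genome(50_000, 0.5, 10, seed=9)
        assert g1.residues == g2.residues
        assert [(g.gene_id, g.span.start, g.span.end) for g in genes1] == [
            (g.gene_id, g.span.start, g.span.end) for g in genes2
        ]

    def test_gc_extreme(self):
        g, _ = simulate_genome(20_000, 1.0, 0, seed=1)
        assert set(g.residues) <= {"G", "C"}

    def test_zero_genes(self):
        _, genes = simulate_genome(20_000, 0.4, 0, seed=2)
        assert genes == []

    def test_genes_non_overlapping_sorted(self):
        _, genes = simulate_genome(200_000, 0.4, 40, seed=3)
        for a, b in zip(genes, genes[1:]):
            assert a.span.end <= b.span.start


class TestEvolveK2P:
    def test_zero_divergence_identity(self):
        rng = np.random.default_rng(4)
        assert evolve_k2p("ACGTACGT", 0.0, rng) == "ACGTACGT"

    def test_observed_divergence_tracks_k(self):
        rng = np.random.default_rng(5)
        anc = "".join(np.array(list("ACGT"))[rng.choice(4, size=670)])
        k = 0.052
        diffs = []
        for _ in range(100):
            evolved = evolve_k2p(anc, k, rng)
            diffs.append(sum(1 for a, b in zip(anc, evolved) if a != b) / len(anc))
        # observed Hamming divergence ~= k at low k (multiple hits shave a little)
        assert abs(np.mean(diffs) - 0.05) <= 0.01

    def test_clock_slope_recovered(self, config):
        """Regressing observed divergence on true T recovers ~2r."""
        rng = np.random.default_rng(6)
        anc = "".join(np.array(list("ACGT"))[rng.choice(4, size=670)])
        r = config.substitution_rate_r
        Ts, ps = [], []
        for T in np.linspace(0.5e6, 5e6, 10):
            for _ in range(50):
                ev = evolve_k2p(anc, 2 * r * T, rng)
                Ts.append(T)
                ps.append(sum(1 for a, b in zip(anc, ev) if a != b) / len(anc))
        slope = np.polyfit(Ts, ps, 1)[0]
        assert abs(slope - 2 * r) / (2 * r) <= 0.10

    def test_transition_bias_present(self):
        rng = np.random.default_rng(7)
        anc = "A" * 30000
        ev = evolve_k2p(anc, 0.1, rng)
        ti = ev.count("G")
        tv_each = (ev.count("C") + ev.count("T")) / 2
        # alpha = 2*beta: transitions should be ~2x either single transversion
        assert 1.6 < ti / tv_each < 2.4


class TestMakeConsensus:
    def test_tir_structure_and_at(self):
        rng = np.random.default_rng(8)
        spec = PlantSpec(family_id="f", element_len=673, tir_len=25, tsd_len=8,
                         at_fraction=0.70, n_copies=1)
        cons = make_consensus(spec, rng)
        assert len(cons) == 673
        assert cons[:25] == revcomp(cons[-25:])
        assert abs(at_content(cons) - 0.70) < 0.06

    def test_user_consensus_validated(self):
        with pytest.raises(ValueError):
            PlantSpec(family_id="f", element_len=20, tir_len=10, tsd_len=8,
                      consensus="ACGTACGTACCCCCCCCCCC")


class TestPlantMites:
    def test_zero_age_copies_identical_to_consensus(self, config):
        genome, genes = simulate_genome(80_000, 0.36, 5, seed=10)
        spec = PlantSpec(family_id="f", element_len=300, tir_len=12, tsd_len=8,
                         n_copies=5, age_distribution=[(0.0, 1.0)])
        g2, _, truth = plant_mites(genome, genes, spec, config, seed=11)
        consensi = {t.sequence for t in truth}
        assert len(consensi) == 1  # all copies identical
        for t in truth:
            assert g2.residues[t.interval.start : t.interval.end] == t.sequence

    def test_tsd_duplicated_on_both_sides(self, config, small_fixture):
        g = small_fixture["genome"]
        for t in small_fixture["truth"]:
            iv = t.interval
            assert g.residues[iv.start - len(t.tsd) : iv.start] == t.tsd
            assert g.residues[iv.end : iv.end + len(t.tsd)] == t.tsd

    def test_truth_k_equals_clock(self, config, small_fixture):
        r = config.substitution_rate_r
        for t in small_fixture["truth"]:
            assert t.true_k == pytest.approx(2 * r * t.true_T)

    def test_full_genic_bias(self, config):
        genome, genes = simulate_genome(200_000, 0.36, 25, seed=12)
        spec = PlantSpec(family_id="f", element_len=300, tir_len=12, tsd_len=8,
                         n_copies=15, genic_bias=1.0, age_distribution=[(1e6, 1.0)])
        g2, genes2, truth = plant_mites(genome, genes, spec, config, seed=13)
        for t in truth:
            near = min(
                (
                    0
                    if t.interval.overlaps(g.span)
                    else min(
                        abs(t.interval.start - g.span.end),
                        abs(g.span.start - t.interval.end),
                    )
                )
                for g in genes2
                if g.span.seqid == t.interval.seqid
            )
            assert near <= 2000

    def test_gene_models_remapped_consistently(self, config, small_fixture):
        """Shifted exons still sit inside shifted spans (validated on build),
        and gene content is preserved against the pristine genome."""
        for g in small_fixture["genes"]:
            assert g.exons[0].start >= g.span.start
            assert g.exons[-1].end <= g.span.end

    def test_structural_predicate_holds_for_fresh_copies(self, config):
        from mitescout.discovery import find_tir_candidates

        genome, genes = simulate_genome(100_000, 0.36, 5, seed=14)
        spec = PlantSpec(family_id="f", element_len=400, tir_len=14, tsd_len=8,
                         n_copies=8, age_distribution=[(0.0, 1.0)])
        g2, _, truth = plant_mites(genome, genes, spec, config, seed=15)
        cands = find_tir_candidates(g2, config)
        prec, rec = evaluate_discovery(cands, truth)
        assert rec == 1.0  # undiverged copies always pass the structural scan


class TestExcise:
    def test_round_trip_restores_locus(self, config):
        genome, genes = simulate_genome(60_000, 0.36, 3, seed=16)
        spec = PlantSpec(family_id="f", element_len=300, tir_len=12, tsd_len=8,
                         n_copies=1, age_distribution=[(0.0, 1.0)])
        g2, _, truth = plant_mites(genome, genes, spec, config, seed=17)
        restored = excise(g2, truth[0])
        assert restored.residues == genome.residues

    def test_interval_mismatch_errors(self, config, small_fixture):
        bad = small_fixture["truth"][0]
        from dataclasses import replace

        shifted = replace(
            bad, interval=GenomicInterval(bad.interval.seqid,
                                          bad.interval.start + 3,
                                          bad.interval.end + 3)
        )
        with pytest.raises(ValueError):
            excise(small_fixture["genome"], shifted)


class TestSimulateReads:
    def test_total_bases_near_target(self):
        g, _ = simulate_genome(100_000, 0.4, 0, seed=18)
        reads = simulate_reads(g, coverage=10, read_len=100, error_rate=0.0, seed=19)
        total = sum(len(r[1]) for r in reads)
        assert abs(total - 1.0e6) <= 100

    def test_error_free_reads_are_substrings(self):
        g, _ = simulate_genome(20_000, 0.4, 0, seed=20)
        reads = simulate_reads(g, coverage=1, read_len=80, error_rate=0.0, seed=21)
        for _, seq in reads[:50]:
            assert seq in g.residues or revcomp(seq) in g.residues

    def test_deterministic(self):
        g, _ = simulate_genome(20_000, 0.4, 0, seed=22)
        r1 = simulate_reads(g, 2, 100, 0.01, seed=23)
        r2 = simulate_reads(g, 2, 100, 0.01, seed=23)
        assert r1 == r2


class TestEvaluateDiscovery:
    def _ivs(self, spans):
        return [GenomicInterval("chr1", s, e) for s, e in spans]

    def _truth(self, spans):
        from mitescout.simulate import TruthRecord

        return [
            TruthRecord(f"t{i}", "f", GenomicInterval("chr1", s, e), 0.0, 0.0, "AA", "")
            for i, (s, e) in enumerate(spans)
        ]

    def test_perfect_predictions(self):
        spans = [(100, 400), (1000, 1300)]
        assert evaluate_discovery(self._ivs(spans), self._truth(spans)) == (1.0, 1.0)

    def test_empty_predictions(self):
        assert evaluate_discovery([], self._truth([(0, 100)])) == (0.0, 0.0)

    def test_agrees_with_exhaustive_matcher(self):
        """Greedy matching equals the maximum bipartite matching on
        small random instances."""
        rng = np.random.default_rng(24)
        for _ in range(20):
            n_t, n_p = int(rng.integers(1, 8)), int(rng.integers(0, 8))
            truth_spans = []
            pos = 0
            for _ in range(n_t):
                pos += int(rng.integers(50, 200))
                ln = int(rng.integers(100, 300))
                truth_spans.append((pos, pos + ln))
                pos += ln
            preds = []
            for _ in range(n_p):
                if truth_spans and rng.random() < 0.6:
                    s, e = truth_spans[int(rng.integers(0, len(truth_spans)))]
                    jitter = int(rng.integers(-20, 20))
                    preds.append((max(0, s + jitter), e + jitter))
                else:
                    s = int(rng.integers(0, 3000))
                    preds.append((s, s + int(rng.integers(100, 300))))
            truth = self._truth(truth_spans)
            pred_ivs = self._ivs(preds)
            prec, rec = evaluate_discovery(pred_ivs, truth)

            # brute force: maximum matching over all qualifying pairs
            def overlap_ok(p, t):
                ov = max(0, min(p.end, t.interval.end) - max(p.start, t.interval.start))
                return ov >= 0.8 * p.length and ov >= 0.8 * t.interval.length

            pairs = [
                (i, j)
                for i, p in enumerate(pred_ivs)
                for j, t in enumerate(truth)
                if overlap_ok(p, t)
            ]
            best = 0
            for r_size in range(min(len(pred_ivs), len(truth)), 0, -1):
                found = False
                for combo in itertools.combinations(pairs, r_size):
                    ps = [c[0] for c in combo]
                    ts = [c[1] for c in combo]
                    if len(set(ps)) == r_size and len(set(ts)) == r_size:
                        found = True
                        break
                if found:
                    best = r_size
                    break
            expect_prec = best / len(pred_ivs) if pred_ivs else 0.0
            expect_rec = best / len(truth)
            assert prec == pytest.approx(expect_prec)
            assert rec == pytest.approx(expect_rec)
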