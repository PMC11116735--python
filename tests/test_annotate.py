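"""Mapping, bridging, prediction-count filter, clustering, full pipeline."""

import numpy as np
import pytest

from mitannot.annotate import (
    AnnotationError,
    IntervalPrediction,
    MatchProfile,
    Parameters,
    annotate,
    cluster_and_select,
    derive_interval_predictions,
    filter_by_prediction_count,
    map_input,
)
from mitannot.refdb import build_index
from mitannot.taxonomy import EmptyReferenceSetError

from _oracles import oracle_average_linkage_clusters
from conftest import mutate_seq


def make_profile(length, runs, key=("g1", "nad1", "protein", "+"), circular=True):
    mask = np.zeros(length, dtype=bool)
    for s, e in runs:
        mask[s:e] = True
    return MatchProfile(length=length, circular=circular, coverage={key: mask})


class TestParameters:
    @pytest.mark.parametrize(
        "kwargs", [dict(alpha=-0.1), dict(alpha=1.5), dict(edge_weight=0),
                   dict(prediction_count=0), dict(k=0), dict(cluster_cut=0.0)],
    )
    def test_invalid_ranges_rejected(self, kwargs):
        with pytest.raises(AnnotationError):
            Parameters(**kwargs)

    def test_gap_bridge_defaults_to_2k(self):
        assert Parameters(k=24).effective_gap_bridge == 48
        assert Parameters(k=24, gap_bridge=5).effective_gap_bridge == 5


class TestMapInput:
    def test_self_match_covers_every_position(self, identity_family, identity_index):
        _, _, genomes, _, _ = identity_family
        g = genomes[0]
        profile = map_input(g.sequence, identity_index, Parameters(edge_weight=1))
        for p in (0, 100, len(g.sequence) - 1):
            assert any(key[0] == g.label for key in profile.votes_at(p))

    def test_unsatisfiable_edge_weight_empties_profile(self, identity_family, identity_index):
        _, _, genomes, _, _ = identity_family
        profile = map_input(
            genomes[0].sequence, identity_index, Parameters(edge_weight=99)
        )
        assert profile.n_votes == 0

    def test_raising_edge_weight_never_adds_votes(self, diverged_family, diverged_index):
        _, _, genomes, _, _ = diverged_family
        seq = genomes[0].sequence
        prev = None
        for w in (1, 2, 3, 4, 5):
            profile = map_input(seq, diverged_index, Parameters(edge_weight=w))
            votes = profile.n_votes
            if prev is not None:
                assert votes <= prev
            prev = votes

    def test_k_mismatch_rejected(self, identity_index):
        with pytest.raises(AnnotationError, match="k="):
            map_input("ACGT" * 30, identity_index, Parameters(k=10))


class TestDeriveIntervals:
    def test_contiguous_run_single_interval(self):
        profile = make_profile(200, [(10, 100)])
        preds = derive_interval_predictions(profile, Parameters(gap_bridge=10))
        assert [(p.start, p.end) for p in preds] == [(10, 100)]

    def test_gap_bridging_rule(self):
        for gap_bridge, expected in [(10, [(10, 100)]), (3, [(10, 50), (55, 100)])]:
            profile = make_profile(200, [(10, 50), (55, 100)])
            preds = derive_interval_predictions(profile, Parameters(gap_bridge=gap_bridge))
            assert [(p.start, p.end) for p in preds] == expected

    def test_wraps_across_origin_when_circular(self):
        profile = make_profile(100, [(0, 20), (80, 100)])
        preds = derive_interval_predictions(profile, Parameters(gap_bridge=0))
        assert [(p.start, p.end) for p in preds] == [(80, 120)]

    def test_intergenic_votes_never_emitted(self):
        profile = make_profile(100, [(0, 50)], key=("g1", "intergenic", "other", "+"))
        assert derive_interval_predictions(profile, Parameters()) == []


class TestPredictionCountFilter:
    def _preds(self, spec):
        return [
            IntervalPrediction(gene, genome, 0, 10, "+") for gene, genome in spec
        ]

    def test_single_source_dropped_at_threshold_two(self):
        preds = self._preds([("a", "g1"), ("b", "g1"), ("b", "g2")])
        kept = filter_by_prediction_count(preds, 2)
        assert {p.gene_name for p in kept} == {"b"}

    def test_threshold_one_is_identity(self):
        preds = self._preds([("a", "g1"), ("b", "g2")])
        assert filter_by_prediction_count(preds, 1) == preds

    def test_counts_are_distinct_genomes(self):
        # two intervals from the same genome count once
        preds = self._preds([("a", "g1"), ("a", "g1")])
        assert filter_by_prediction_count(preds, 2) == []
        tally = {}
        rng = np.random.default_rng(3)
        preds = self._preds(
            [(f"gene{int(rng.integers(3))}", f"g{int(rng.integers(4))}") for _ in range(40)]
        )
        for p in preds:
            tally.setdefault(p.gene_name, set()).add(p.genome_label)
        for t in (1, 2, 3, 4):
            kept = {p.gene_name for p in filter_by_prediction_count(preds, t)}
            assert kept == {g for g, s in tally.items() if len(s) >= t}


class TestClusterAndSelect:
    def test_identical_members_one_cluster(self):
        preds = [IntervalPrediction("a", f"g{i}", 10, 50, "+") for i in range(5)]
        out = cluster_and_select(preds, Parameters(alpha=1.0), length=200)
        assert len(out) == 1
        assert out[0].rel_freq == 1.0
        assert out[0].consensus == (10, 50, "+")

    def test_minority_cluster_dropped_by_alpha(self):
        big = [IntervalPrediction("a", f"g{i}", 10, 50, "+") for i in range(8)]
        small = [IntervalPrediction("a", f"h{i}", 120, 160, "+") for i in range(2)]
        out = cluster_and_select(big + small, Parameters(alpha=0.5), length=300)
        assert len(out) == 1
        assert out[0].rel_freq == 0.8

    def test_alpha_zero_selects_all_alpha_one_only_max(self):
        big = [IntervalPrediction("a", f"g{i}", 10, 50, "+") for i in range(8)]
        small = [IntervalPrediction("a", f"h{i}", 120, 160, "+") for i in range(2)]
        all_out = cluster_and_select(big + small, Parameters(alpha=0.0), length=300)
        assert len(all_out) == 2
        max_out = cluster_and_select(big + small, Parameters(alpha=1.0), length=300)
        assert len(max_out) == 1
        # ties at the maximum are all kept
        tied = big[:2] + small
        tied_out = cluster_and_select(tied, Parameters(alpha=1.0), length=300)
        assert len(tied_out) == 2

    def test_matches_naive_agglomerative_oracle(self):
        rng = np.random.default_rng(12)
        length = 500
        for _ in range(30):
            n_groups = int(rng.integers(1, 4))
            preds = []
            for gi in range(n_groups):
                center = int(rng.integers(0, 400))
                for m in range(int(rng.integers(1, 5))):
                    jitter = int(rng.integers(-3, 4))
                    preds.append(
                        IntervalPrediction(
                            "gene", f"g{gi}_{m}", max(center + jitter, 0),
                            max(center + jitter, 0) + 60, "+",
                        )
                    )
            params = Parameters(alpha=float(rng.choice([0.0, 0.5, 1.0])))
            got = cluster_and_select(preds, params, length)

            possets = [frozenset(range(p.start, p.end)) for p in sorted(
                preds, key=lambda p: (p.start, p.end, p.strand, p.genome_label))]
            dist = [
                [1 - len(a & b) / len(a | b) for b in possets] for a in possets
            ]
            clusters = oracle_average_linkage_clusters(dist, params.cluster_cut)
            sizes = sorted(len(c) for c in clusters)
            max_size = max(sizes)
            expected_sizes = sorted(
                s for s in sizes if s + 1e-9 >= params.alpha * max_size
            )
            assert sorted(len(c.members) for c in got) == expected_sizes

    def test_strand_majority_ties_break_plus(self):
        preds = [
            IntervalPrediction("a", "g1", 10, 50, "+"),
            IntervalPrediction("a", "g2", 10, 50, "-"),
        ]
        out = cluster_and_select(preds, Parameters(alpha=0.0), length=100)
        assert out[0].consensus[2] == "+"


class TestAnnotatePipeline:
    def test_self_annotation_recovers_exact_boundaries(self, identity_family, identity_index):
        _, _, genomes, annotations, _ = identity_family
        for g in genomes[:2]:
            truth = {
                (a.gene_name, a.start, a.end, a.strand, a.kind)
                for a in annotations if a.genome_label == g.label
            }
            preds = annotate(g.sequence, identity_index, Parameters())
            got = {(p.gene_name, p.start, p.end, p.strand, p.kind) for p in preds}
            assert got == truth

    def test_gene_count_monotone_in_thresholds(self, diverged_family, diverged_index):
        _, _, genomes, _, _ = diverged_family
        seq = mutate_seq(genomes[0].sequence, 0.01, np.random.default_rng(77))
        prev = None
        for w in (1, 2, 3, 4):
            n = len({p.gene_name for p in annotate(seq, diverged_index, Parameters(edge_weight=w))})
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for pc in (1, 2, 3, 4, 5):
            n = len({
                p.gene_name
                for p in annotate(seq, diverged_index, Parameters(prediction_count=pc))
            })
            if prev is not None:
                assert n <= prev
            prev = n

    def test_correction_changes_results_by_at_most_window(self, diverged_family, diverged_index):
        from mitannot.genetic_code import get_genetic_code

        spec, _, genomes, _, _ = diverged_family
        code = get_genetic_code(spec.table_id)
        seq = mutate_seq(genomes[0].sequence, 0.01, np.random.default_rng(78))
        plain = annotate(seq, diverged_index, Parameters())
        corrected = annotate(seq, diverged_index, Parameters(), code=code)
        assert len(corrected) == len(plain)
        key = lambda p: (p.gene_name, p.strand, p.start)
        for p, c in zip(sorted(plain, key=key), sorted(corrected, key=key)):
            assert (p.gene_name, p.strand) == (c.gene_name, c.strand)
            assert abs(c.start - p.start) <= 6
            assert abs(c.end - p.end) <= 6

    def test_filter_requires_taxonomy_and_propagates_empty(self, identity_family, identity_index):
        _, tree, genomes, _, _ = identity_family
        with pytest.raises(AnnotationError, match="taxonomy"):
            annotate(genomes[0].sequence, identity_index,
                     taxa_filter=([1], "include"))
        with pytest.raises(EmptyReferenceSetError):
            annotate(genomes[0].sequence, identity_index, taxonomy=tree,
                     taxa_filter=([1], "exclude"))

    def test_exclude_filter_still_recovers_genes(self, diverged_family, diverged_index):
        _, tree, genomes, annotations, _ = diverged_family
        g = genomes[0]
        # exclude the input's own taxon; relatives remain in the index
        preds = annotate(
            g.sequence, diverged_index, Parameters(edge_weight=1, prediction_count=1),
            taxonomy=tree, taxa_filter=([g.tax_id], "exclude"),
        )
        want = {a.gene_name for a in annotations if a.genome_label == g.label}
        got = {p.gene_name for p in preds}
        assert len(want & got) / len(want) >= 0.9

    def test_deterministic(self, diverged_family, diverged_index):
        _, _, genomes, _, _ = diverged_family
        seq = mutate_seq(genomes[1].sequence, 0.01, np.random.default_rng(80))
        a = annotate(seq, diverged_index, Parameters())
        b = annotate(seq, diverged_index, Parameters())
        assert a == b

    def test_zero_predictions_is_empty_not_error(self, identity_index):
        rng = np.random.default_rng(81)
        unrelated = "".join(rng.choice(list("ACGT"), size=2000))
        assert annotate(unrelated, identity_index, Parameters()) == []
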