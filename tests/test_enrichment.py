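import itertools
import math

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from mirpath.data_io import Pathway, PathwayDatabase
from mirpath.enrichment import (
    associate_all,
    associations_to_frame,
    best_mirna,
    hypergeom_tail,
    storey_pi0,
    storey_qvalues,
)
from mirpath.errors import ValidationError

from conftest import make_pairs


def tail_by_enumeration(x, K, N, M, strict=True):
    """Exhaustive oracle: draw every N-subset of M items, count hits > x.

    The first K items are the successes; every subset is equally likely.
    """
    hits_gt = 0
    total = 0
    for draw in itertools.combinations(range(M), N):
        total += 1
        hits = sum(1 for item in draw if item < K)
        if (hits > x) if strict else (hits >= x):
            hits_gt += 1
    return hits_gt / total


class TestHypergeomTail:
    def test_enumeration_example(self):
        # 15 two-gene draws from 6 genes, 3 targets; 3 draws miss entirely
        assert hypergeom_tail(0, 3, 2, 6) == pytest.approx(0.8, abs=1e-12)
        assert tail_by_enumeration(0, 3, 2, 6) == pytest.approx(0.8, abs=1e-12)

    def test_full_pathway_hit_has_zero_tail(self):
        assert hypergeom_tail(13, 124, 13, 1460) == 0.0
        assert hypergeom_tail(5, 40, 5, 100) == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_on_random_cases(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            M = int(rng.integers(2, 12))
            N = int(rng.integers(1, M + 1))
            K = int(rng.integers(0, M + 1))
            x = int(rng.integers(0, N + 1))
            assert hypergeom_tail(x, K, N, M) == pytest.approx(
                tail_by_enumeration(x, K, N, M), abs=1e-12
            )

    def test_geq_tail_is_one_pmf_term_larger(self):
        gt = hypergeom_tail(6, 124, 13, 1460)
        geq = hypergeom_tail(6, 124, 13, 1460, tail="geq")
        pmf = math.comb(124, 6) * math.comb(1460 - 124, 13 - 6) / math.comb(1460, 13)
        assert geq - gt == pytest.approx(pmf, rel=1e-9)

    def test_monotone_in_x_and_K(self):
        M, N = 200, 20
        for K in (10, 50, 120):
            tails = [hypergeom_tail(x, K, N, M) for x in range(N + 1)]
            assert all(a >= b for a, b in zip(tails, tails[1:]))
        for x in (0, 3, 7):
            tails = [hypergeom_tail(x, K, N, M) for K in range(M + 1)]
            assert all(b >= a - 1e-15 for a, b in zip(tails, tails[1:]))

    @pytest.mark.parametrize("bad", [(-1, 5, 5, 10), (6, 5, 5, 10), (0, 11, 5, 10),
                                     (0, 5, 11, 10)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValidationError):
            hypergeom_tail(*bad)


class TestBestMirna:
    def test_max_overlap_wins(self):
        pathway = Pathway(pathway_id="P", genes=frozenset(f"G{i}" for i in range(13)))
        pairs = make_pairs(
            {
                "miR-532": {f"G{i}" for i in range(6)},
                "miR-x": {f"G{i}" for i in range(5)},
                "miR-y": {"G0", "G1"},
            },
            M=1460,
        )
        assert best_mirna(pathway, pairs) == ("miR-532", 6)

    def test_no_overlap_flags_no_association(self):
        pathway = Pathway(pathway_id="P", genes=frozenset({"A", "B"}))
        pairs = make_pairs({"miR-1": {"X", "Y"}}, M=10)
        assert best_mirna(pathway, pairs) == (None, 0)

    def test_count_tie_broken_by_smaller_p(self):
        # both hit 3 of 5 pathway genes; the K=10 miRNA is the rarer event
        pathway = Pathway(pathway_id="P", genes=frozenset(f"P{i}" for i in range(5)))
        hits = {"P0", "P1", "P2"}
        lean = hits | {f"L{i}" for i in range(7)}
        fat = hits | {f"F{i}" for i in range(47)}
        pairs = make_pairs({"miR-fat": fat, "miR-lean": lean}, M=100)
        p_lean = hypergeom_tail(3, 10, 5, 100)
        p_fat = hypergeom_tail(3, 50, 5, 100)
        assert p_lean < p_fat
        assert best_mirna(pathway, pairs) == ("miR-lean", 3)

    def test_full_tie_broken_lexicographically(self):
        pathway = Pathway(pathway_id="P", genes=frozenset({"A", "B", "C"}))
        pairs = make_pairs({"miR-b": {"A", "B"}, "miR-a": {"A", "B"}}, M=50)
        assert best_mirna(pathway, pairs)[0] == "miR-a"


class TestAssociateAll:
    def _toy(self):
        db = PathwayDatabase(
            pathways=(
                Pathway(pathway_id="P1", genes=frozenset({"A", "B", "C"})),
                Pathway(pathway_id="P2", genes=frozenset({"C", "D", "E", "F"})),
                Pathway(pathway_id="P3", genes=frozenset({"G", "H"})),
            )
        )
        pairs = make_pairs(
            {"miR-1": {"A", "B"}, "miR-2": {"C", "D", "E"}}, M=len(db.gene_universe)
        )
        return db, pairs

    def test_matches_per_pathway_oracle(self):
        db, pairs = self._toy()
        records = {r.pathway_id: r for r in associate_all(db, pairs)}
        for pathway in db:
            mirna, x = best_mirna(pathway, pairs)
            assert records[pathway.pathway_id].mirna_id == mirna
            assert records[pathway.pathway_id].x == x
            if mirna is not None:
                expected_p = hypergeom_tail(
                    x, pairs.target_count(mirna), pathway.size, pairs.universe_size
                )
                assert records[pathway.pathway_id].p_value == pytest.approx(expected_p)

    def test_untargeted_pathway_excluded_from_fdr(self):
        db, pairs = self._toy()
        rec = {r.pathway_id: r for r in associate_all(db, pairs)}["P3"]
        assert not rec.has_association
        assert math.isnan(rec.q_value)

    def test_certain_event_gives_zero_p(self):
        db = PathwayDatabase(
            pathways=(Pathway(pathway_id="P", genes=frozenset({"A", "B"})),)
        )
        pairs = make_pairs({"miR-1": {"A", "B"}}, M=2)
        (rec,) = associate_all(db, pairs)
        assert rec.p_value == 0.0

    def test_permutation_invariance(self, small_bundle):
        from mirpath.targets import filter_min_tools, restrict_to_universe

        pairs = restrict_to_universe(
            filter_min_tools(small_bundle.predictions, 2), small_bundle.pathways
        )
        forward = associate_all(small_bundle.pathways, pairs)
        shuffled_db = PathwayDatabase(pathways=tuple(reversed(small_bundle.pathways.pathways)))
        backward = {r.pathway_id: r for r in associate_all(shuffled_db, pairs)}
        for r in forward:
            assert backward[r.pathway_id] == r

    def test_record_count_matches_pathway_count(self, small_bundle):
        from mirpath.targets import filter_min_tools, restrict_to_universe

        pairs = restrict_to_universe(
            filter_min_tools(small_bundle.predictions, 2), small_bundle.pathways
        )
        assert len(associate_all(small_bundle.pathways, pairs)) == len(small_bundle.pathways)


class TestStoreyQvalues:
    def test_all_ones_stay_ones(self):
        assert np.allclose(storey_qvalues([1.0] * 10), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_pi0_one_equals_benjamini_hochberg(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=50)
        q = storey_qvalues(p, pi0=1.0)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, bh, atol=1e-12)

    def test_documented_step_up_example(self):
        q = storey_qvalues([0.01, 0.02, 0.03, 0.8], pi0=1.0)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.8])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.uniform(size=200), rng.uniform(high=1e-3, size=20)])
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_pi0_near_one_under_uniform(self):
        rng = np.random.default_rng(0)
        estimates = [storey_pi0(rng.uniform(size=2000)) for _ in range(20)]
        assert abs(np.mean(estimates) - 1.0) < 0.05

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            storey_qvalues([0.5, 1.2])


def test_association_frame_sorted_by_q(small_bundle):
    from mirpath.targets import filter_min_tools, restrict_to_universe

    pairs = restrict_to_universe(
        filter_min_tools(small_bundle.predictions, 2), small_bundle.pathways
    )
    frame = associations_to_frame(associate_all(small_bundle.pathways, pairs))
    scored = frame[frame["mirna_id"] != ""]
    assert (np.diff(scored["q_value"].to_numpy()) >= -1e-15).all()
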