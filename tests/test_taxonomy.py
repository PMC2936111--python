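import numpy as np
import pytest

from v6pipe.fileio import ReferenceDB, TagRecord
from v6pipe.taxonomy import (
    STATUS_ASSIGNED,
    STATUS_LOW_SIMILARITY,
    STATUS_NO_CANDIDATES,
    AssignmentThresholds,
    CandidateHit,
    KmerIndex,
    assign_cluster,
    assign_tag,
    assign_tags,
    assign_taxonomy,
    find_candidates,
    select_nearest_set,
)

from conftest import make_ref, random_dna


def hits(*pairs):
    return [CandidateHit(rid, sim) for rid, sim in pairs]


class TestThresholds:
    def test_defaults_decreasing(self):
        th = AssignmentThresholds()
        assert th.genus == 0.95 and th.phylum == 0.75
        assert th.for_rank("class") == 0.80

    def test_increasing_rejected(self):
        with pytest.raises(ValueError):
            AssignmentThresholds(genus=0.80, family=0.90)


class TestFindCandidates:
    def test_identical_ref(self, tiny_db):
        tag = TagRecord("t1", "s", tiny_db["R1"].sequence[30:90])
        out = find_candidates(tag, tiny_db, n_hits=1)
        assert out[0].ref_id in ("R1", "R2")  # R2 differs by 1 nt at pos 60
        assert out[0].similarity == 1.0

    def test_small_db_returns_all_sorted(self, tiny_db):
        tag = TagRecord("t1", "s", tiny_db["R4"].sequence[20:80])
        out = find_candidates(tag, tiny_db, n_hits=100)
        assert len(out) == len(tiny_db)
        sims = [h.similarity for h in out]
        assert sims == sorted(sims, reverse=True)

    def test_tie_broken_by_ref_id(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 100)
        db = ReferenceDB(
            [
                make_ref("Rb", seq, "P;;;;"),
                make_ref("Ra", seq, "P;;;;"),
                make_ref("Rc", random_dna(rng, 100), "Q;;;;"),
            ]
        )
        out = find_candidates(seq[10:70], db, n_hits=2)
        assert [h.ref_id for h in out] == ["Ra", "Rb"]

    def test_empty_db_raises(self):
        with pytest.raises(ValueError):
            find_candidates("ACGT" * 15, ReferenceDB([]))

    def test_prefilter_equals_exhaustive(self):
        # oracle equivalence on a random database
        rng = np.random.default_rng(42)
        refs = [
            make_ref(f"R{i:03d}", random_dna(rng, 120), "P;;;;")
            for i in range(60)
        ]
        db = ReferenceDB(refs)
        index = KmerIndex(db, k=8)
        for _ in range(5):
            src = refs[rng.integers(len(refs))].sequence
            tag = src[rng.integers(0, 60) :][:55]
            exhaustive = find_candidates(tag, db, n_hits=10)
            filtered = find_candidates(
                tag, db, n_hits=10, prefilter=index, prefilter_keep=500
            )
            assert exhaustive == filtered


class TestSelectNearestSet:
    def test_window_rule(self):
        out = select_nearest_set(hits(("a", 0.970), ("b", 0.9695), ("c", 0.950)))
        assert [h.ref_id for h in out] == ["a", "b"]

    def test_single_hit(self):
        out = select_nearest_set(hits(("a", 0.9)))
        assert len(out) == 1

    def test_all_equal(self):
        out = select_nearest_set(hits(("a", 0.8), ("b", 0.8), ("c", 0.8)))
        assert len(out) == 3


def db_for_majority():
    rng = np.random.default_rng(3)
    seq = random_dna(rng, 80)
    return ReferenceDB(
        [
            make_ref("N1", seq, "Chloroflexi;Anaerolineae;OrdA;;"),
            make_ref("N2", seq, "Chloroflexi;Anaerolineae;OrdB;;"),
            make_ref("N3", seq, "Chloroflexi;SAR202;OrdC;;"),
        ]
    )


class TestAssignTaxonomy:
    def test_majority_fails_at_order_despite_threshold(self):
        db = db_for_majority()
        nearest = hits(("N1", 0.86), ("N2", 0.86), ("N3", 0.86))
        res = assign_taxonomy(nearest, db)
        assert res.labels.labels == ("Chloroflexi", "Anaerolineae", "", "", "")
        assert res.status == STATUS_ASSIGNED

    def test_below_phylum_threshold_unassigned(self):
        db = db_for_majority()
        res = assign_taxonomy(hits(("N1", 0.74)), db)
        assert res.status == STATUS_LOW_SIMILARITY
        assert res.labels.depth == 0

    def test_single_perfect_hit_full_depth(self):
        rng = np.random.default_rng(5)
        db = ReferenceDB([make_ref("F1", random_dna(rng, 80), "P;C;O;F;G")])
        res = assign_taxonomy(hits(("F1", 1.0)), db)
        assert res.labels.labels == ("P", "C", "O", "F", "G")

    def test_no_candidates(self):
        db = db_for_majority()
        res = assign_taxonomy([], db)
        assert res.status == STATUS_NO_CANDIDATES

    def test_rank_threshold_stops_depth(self):
        rng = np.random.default_rng(6)
        db = ReferenceDB([make_ref("F1", random_dna(rng, 80), "P;C;O;F;G")])
        # 0.91: genus needs 0.95, family needs 0.90 -> stops after family
        res = assign_taxonomy(hits(("F1", 0.91)), db)
        assert res.labels.labels == ("P", "C", "O", "F", "")

    def test_exact_boundary_inclusive(self):
        rng = np.random.default_rng(7)
        db = ReferenceDB([make_ref("F1", random_dna(rng, 80), "P;C;O;F;G")])
        res = assign_taxonomy(hits(("F1", 0.95)), db)
        assert res.labels.label("genus") == "G"

    def test_majority_monotone_in_threshold(self):
        db = db_for_majority()
        nearest = hits(("N1", 0.99), ("N2", 0.99), ("N3", 0.99))
        depths = []
        for maj in (0.3, 0.6, 0.9):
            res = assign_taxonomy(nearest, db, AssignmentThresholds(majority=maj))
            depths.append(res.labels.depth)
        assert depths == sorted(depths, reverse=True)

    def test_raising_rank_threshold_never_gains(self):
        db = db_for_majority()
        nearest = hits(("N1", 0.93), ("N2", 0.93))
        base = assign_taxonomy(nearest, db, AssignmentThresholds())
        strict = assign_taxonomy(
            nearest, db, AssignmentThresholds(order=0.94, family=0.94)
        )
        assert strict.labels.depth <= base.labels.depth

    def test_prefix_completeness(self):
        db = db_for_majority()
        for sims in [(0.86, 0.86, 0.86), (0.99, 0.99, 0.99), (0.80, 0.80, 0.80)]:
            nearest = hits(*zip(["N1", "N2", "N3"], sims))
            res = assign_taxonomy(nearest, db)
            labels = res.labels.labels
            seen_empty = False
            for lab in labels:
                if lab == "":
                    seen_empty = True
                assert not (seen_empty and lab)


class TestAssignCluster:
    def test_two_of_two_labelled(self):
        rng = np.random.default_rng(8)
        seq = random_dna(rng, 80)
        db = ReferenceDB(
            [
                make_ref("S1", seq, "P;;;;", cluster="SC70"),
                make_ref("S2", seq, "P;;;;", cluster="SC70"),
            ]
        )
        assert assign_cluster(hits(("S1", 0.96), ("S2", 0.96)), db) == "SC70"

    def test_split_labels_no_majority(self):
        rng = np.random.default_rng(9)
        seq = random_dna(rng, 80)
        db = ReferenceDB(
            [
                make_ref("S1", seq, "P;;;;", cluster="SC70"),
                make_ref("S2", seq, "P;;;;", cluster="SC72"),
                make_ref("S3", seq, "P;;;;"),
            ]
        )
        nearest = hits(("S1", 0.9), ("S2", 0.9), ("S3", 0.9))
        assert assign_cluster(nearest, db) is None

    def test_below_threshold(self):
        rng = np.random.default_rng(10)
        seq = random_dna(rng, 80)
        db = ReferenceDB([make_ref("S1", seq, "P;;;;", cluster="SC1")])
        assert assign_cluster(hits(("S1", 0.70)), db) is None

    def test_unlabelled_majority_counts_against(self):
        rng = np.random.default_rng(11)
        seq = random_dna(rng, 80)
        db = ReferenceDB(
            [
                make_ref("S1", seq, "P;;;;", cluster="SC1"),
                make_ref("S2", seq, "P;;;;"),
                make_ref("S3", seq, "P;;;;"),
            ]
        )
        nearest = hits(("S1", 0.9), ("S2", 0.9), ("S3", 0.9))
        assert assign_cluster(nearest, db) is None


class TestGenusRecovery:
    def test_simulated_tags_recover_genus(self):
        """Tags at <=2% substitution divergence recover the source genus."""
        from v6pipe.simulate import simulate_reference_db

        rng = np.random.default_rng(2024)
        db = simulate_reference_db(seed=77)
        refs = list(db)
        n = 500
        tags = []
        truth = []
        for i in range(n):
            ref = refs[rng.integers(len(refs))]
            start = int(rng.integers(45, 55))
            length = int(rng.integers(50, 61))
            window = list(ref.sequence[start : start + length])
            # at most 2% divergence (no indels), as the recovery contract states
            n_sub = min(rng.binomial(len(window), 0.02), int(0.02 * len(window)))
            for pos in rng.choice(len(window), size=n_sub, replace=False):
                window[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[pos]]
            tags.append(TagRecord(f"t{i}", "s", "".join(window)))
            truth.append(ref.taxonomy.label("genus"))
        results = assign_tags(tags, db)
        correct = sum(
            1 for r, g in zip(results, truth) if r.labels.label("genus") == g
        )
        assert correct / n >= 0.95


class TestAssignTag:
    def test_end_to_end_single_tag(self, tiny_db):
        tag = TagRecord("t1", "s", tiny_db["R1"].sequence[25:85])
        res = assign_tag(tag, tiny_db)
        assert res.status == STATUS_ASSIGNED
        assert res.labels.label("phylum") == "PhyA"
        assert res.cluster_label == "SC01"

    def test_batch_cache_consistent(self, tiny_db):
        seq = tiny_db["R4"].sequence[10:70]
        tags = [TagRecord(f"t{i}", "s", seq) for i in range(3)]
        results = assign_tags(tags, tiny_db)
        assert len({r.labels.labels for r in results}) == 1
        assert [r.tag_id for r in results] == ["t0", "t1", "t2"]
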