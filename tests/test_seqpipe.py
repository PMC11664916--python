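"""BLAST-hit filtering, global-alignment identity, clustering, conservation."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from catalocavity.seqpipe import (
    BlastHit,
    SequenceRecord,
    conserved_residue_filter,
    filter_hits,
    greedy_cluster,
    pairwise_identity,
    read_blast_table,
    read_fasta,
    write_fasta,
)
from catalocavity.synthetic_data import make_blast_table, make_sequence_families

AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_score(a: str, b: str, gap_open=11, gap_extend=1) -> float:
    """Independent affine-gap global alignment score (three-matrix DP)."""
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (deletion)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (insertion)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


def hit(pid, qcov, scov, sid="s"):
    return BlastHit("q", sid, pid, 100, qcov, scov)


class TestFilterHits:
    def test_thresholds(self):
        assert filter_hits([hit(45.0, 85, 82)]) == [hit(45.0, 85, 82)]
        assert filter_hits([hit(29.9, 99, 99)]) == []
        assert filter_hits([hit(45.0, 85, 79.9)]) == []  # bidirectional

    def test_planted_table(self, tmp_path):
        p = tmp_path / "hits.tsv"
        _, manifest = make_blast_table(seed=8, n_hits=50, n_pass=23, path=p)
        kept = filter_hits(read_blast_table(p))
        assert len(kept) == 23
        assert sorted(h.subject_id for h in kept) == manifest.planted["pass_ids"]

    def test_idempotent_and_monotone(self, tmp_path):
        p = tmp_path / "hits.tsv"
        make_blast_table(seed=9, n_hits=40, n_pass=15, path=p)
        hits = read_blast_table(p)
        once = filter_hits(hits)
        assert filter_hits(once) == once
        assert len(filter_hits(hits, min_identity=50)) <= len(once)
        assert len(filter_hits(hits, min_cov=90)) <= len(once)

    def test_coverage_derived_from_spans(self, tmp_path):
        p = tmp_path / "twelve_plus.tsv"
        # 14 columns: outfmt 6 + qlen + slen, coverage must be derived
        p.write_text("q\ts\t80.0\t100\t20\t0\t1\t90\t1\t80\t1e-50\t200\t100\t100\n")
        hits = read_blast_table(p)
        assert hits[0].qcov == pytest.approx(90.0)
        assert hits[0].scov == pytest.approx(80.0)


class TestPairwiseIdentity:
    def test_identical(self):
        r = SequenceRecord("a", "MKTAYIAKQR")
        assert pairwise_identity(r, r) == 100.0

    def test_simple_mismatch(self):
        assert pairwise_identity(SequenceRecord("a", "AAAA"),
                                 SequenceRecord("b", "AAAT")) == 75.0

    @pytest.mark.parametrize("seed", range(5))
    def test_score_matches_independent_dp(self, seed):
        """Biopython's optimal score equals an independent Gotoh DP."""
        from catalocavity.seqpipe import _aligner
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list(AA), size=60))
        b = "".join(rng.choice(list(AA), size=55))
        assert _aligner().score(a, b) == pytest.approx(gotoh_score(a, b))

    @pytest.mark.parametrize("seed", range(5))
    def test_substitution_only_identity_hand_count(self, seed):
        """Mutated pairs with a gapless optimum: identity = exact fraction."""
        rng = np.random.default_rng(100 + seed)
        a = list(rng.choice(list(AA), size=60))
        b = list(a)
        pos = rng.choice(60, size=6, replace=False)
        for p in pos:
            b[p] = [c for c in AA if c != b[p]][rng.integers(19)]
        ra, rb = SequenceRecord("a", "".join(a)), SequenceRecord("b", "".join(b))
        # gapless alignment is optimal (gap open 11 >> worst mismatch)
        assert gotoh_score("".join(a), "".join(b)) == pytest.approx(
            sum(BLOSUM62[x, y] for x, y in zip(a, b)))
        assert pairwise_identity(ra, rb) == pytest.approx(100.0 * 54 / 60)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(200 + seed)
        a = SequenceRecord("a", "".join(rng.choice(list(AA), size=70)))
        b = SequenceRecord("b", "".join(rng.choice(list(AA), size=50)))
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_x_never_counts_as_match(self):
        a = SequenceRecord("a", "AXAX")
        b = SequenceRecord("b", "AXAX")
        assert pairwise_identity(a, b) == 50.0  # only the two A columns


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        seqs = [SequenceRecord(f"s{i}", "MKTAYIAKQRQISFVK") for i in range(3)]
        cs = greedy_cluster(seqs)
        assert len(cs.clusters) == 1
        assert set(cs.clusters[0][1]) == {"s0", "s1", "s2"}

    def test_planted_families_recovered(self):
        records, _, manifest = make_sequence_families(
            seed=21, n_families=5, members_per_family=10)
        cs = greedy_cluster(records, 70)
        assert len(cs.clusters) == 5
        planted = manifest.planted["assignment"]
        got = cs.assignment()
        for x in planted:
            for y in planted:
                assert (got[x] == got[y]) == (planted[x] == planted[y])

    def test_unattainable_cutoff_singletons(self):
        records, _, _ = make_sequence_families(seed=22, n_families=2,
                                               members_per_family=3)
        cs = greedy_cluster(records, cutoff=101)
        assert len(cs.clusters) == len(records)

    def test_members_reach_cutoff_to_representative(self):
        records, _, _ = make_sequence_families(seed=23, n_families=3,
                                               members_per_family=5)
        by_id = {r.id: r for r in records}
        cs = greedy_cluster(records, 70)
        for rep, members in cs.clusters:
            for m in members:
                assert pairwise_identity(by_id[rep], by_id[m]) >= 70


class TestConservedResidueFilter:
    def test_reference_keeps_itself(self):
        _, ref, _ = make_sequence_families(seed=24, n_families=1,
                                           members_per_family=1)
        kept, reports = conserved_residue_filter([ref], ref)
        assert kept == [ref]
        assert reports[0].arg_column_residue == "R"
        assert reports[0].cys432_equivalent == "C"
        assert reports[0].tyr466_equivalent == "Y"

    def test_lysine_at_mapped_column_removed(self):
        _, ref, _ = make_sequence_families(seed=25, n_families=1,
                                           members_per_family=1)
        mutated = list(ref.sequence)
        mutated[450] = "K"  # the red-algae-style substitution
        rep = SequenceRecord("mut", "".join(mutated))
        kept, reports = conserved_residue_filter([rep], ref)
        assert kept == []
        assert reports[0].arg_column_residue == "K"

    def test_planted_reps_exactly_recovered(self):
        records, ref, manifest = make_sequence_families(
            seed=26, n_families=20, members_per_family=1,
            arg_conserved_fraction=0.6)
        kept, reports = conserved_residue_filter(records, ref)
        assert sorted(r.id for r in kept) == \
            manifest.planted["expected_kept_representatives"]
        assert all(rep.cys432_equivalent == "C" for rep in reports)

    def test_ref_pos_out_of_range(self):
        ref = SequenceRecord("r", "MKR")
        with pytest.raises(ValueError):
            conserved_residue_filter([ref], ref, ref_pos=10)


def test_fasta_round_trip(tmp_path):
    records, ref, _ = make_sequence_families(seed=27, n_families=2,
                                             members_per_family=2)
    p = tmp_path / "seqs.fasta"
    write_fasta(list(records) + [ref], p)
    back = read_fasta(p)
    assert back == list(records) + [ref]
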