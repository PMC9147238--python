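import re

import dendropy
import numpy as np
import pytest

from fucokit import seqscan as sq

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestFasta:
    def test_round_trip(self, tmp_path):
        seqs = [
            sq.ProteinSequence("mef2_frag", "MKVLLDAAAGHWWRV" * 10),
            sq.ProteinSequence("other", "ACDEFGHIKLMNPQRSTVWYX"),
        ]
        path = tmp_path / "seqs.fasta"
        sq.write_fasta(seqs, path)
        back = sq.read_fasta(path)
        assert back == seqs

    def test_lowercase_input_uppercased(self, tmp_path):
        (tmp_path / "f.fasta").write_text(">s1\nacdef\nghik\n")
        (seq,) = sq.read_fasta(tmp_path / "f.fasta")
        assert seq.residues == "ACDEFGHIK"

    def test_illegal_character_rejected(self, tmp_path):
        (tmp_path / "f.fasta").write_text(">s1\nAC1DEF\n")
        with pytest.raises(ValueError, match="illegal"):
            sq.read_fasta(tmp_path / "f.fasta")

    def test_empty_file_rejected(self, tmp_path):
        (tmp_path / "f.fasta").write_text("")
        with pytest.raises(ValueError, match="no FASTA"):
            sq.read_fasta(tmp_path / "f.fasta")

    def test_duplicate_ids_rejected(self, tmp_path):
        (tmp_path / "f.fasta").write_text(">s1\nACD\n>s1\nACD\n")
        with pytest.raises(ValueError, match="duplicate"):
            sq.read_fasta(tmp_path / "f.fasta")


class TestMotifScan:
    def test_motif_one_marks_both_aspartates(self):
        seq = sq.ProteinSequence("t", "VAAAAADAAAAD")
        (hit,) = sq.scan_motif(seq, sq.MOTIF_I)
        assert hit.start == 1
        assert sorted(hit.marked.values()) == [7, 12]

    def test_motif_two_marks_d_and_h(self):
        seq = sq.ProteinSequence("t", "MDAAAGHM")
        (hit,) = sq.scan_motif(seq, sq.MOTIF_II)
        assert hit.start == 2
        assert hit.marked["catalytic-D"] == 2
        assert hit.marked["catalytic-H"] == 7

    def test_poly_alanine_has_no_hits(self):
        seq = sq.ProteinSequence("t", "A" * 50)
        assert sq.scan_motif(seq, sq.MOTIF_I) == []
        assert sq.scan_motif(seq, sq.MOTIF_II) == []

    def test_overlapping_hits_all_reported(self):
        seq = sq.ProteinSequence("t", "DADAGHGH")
        hits = sq.scan_motif(seq, sq.compile_motif("m", "DxxxGH"))
        assert [h.start for h in hits] == [1, 3]

    def test_malformed_pattern_rejected(self):
        with pytest.raises(ValueError):
            sq.compile_motif("bad", "D[xx")
        with pytest.raises(ValueError):
            sq.compile_motif("empty", "")

    def test_matches_naive_regex_oracle(self):
        """Seeded fuzz: starts found by the scanner equal an overlapping
        regex search, for both shipped motifs."""
        rng = np.random.default_rng(12)
        patterns = [
            (sq.MOTIF_I, "(?=([RV].{5}D.{4}D))"),
            (sq.MOTIF_II, "(?=(D.{3}GH))"),
        ]
        # bias the alphabet so hits actually occur
        letters = np.array(list("RVDGHAX"))
        for _ in range(50):
            n = int(rng.integers(12, 200))
            s = "".join(rng.choice(letters, n))
            seq = sq.ProteinSequence("fuzz", s)
            for pattern, regex in patterns:
                expected = [m.start() + 1 for m in re.finditer(regex, s)]
                got = [h.start for h in sq.scan_motif(seq, pattern)]
                assert got == expected


def brute_force_alignment_score(a, b, match, mismatch, gap):
    """Exhaustive enumeration over all global alignments (no memoization)."""
    if not a and not b:
        return 0.0
    best = -np.inf
    if a and b:
        best = max(
            best,
            brute_force_alignment_score(a[1:], b[1:], match, mismatch, gap)
            + (match if a[0] == b[0] else mismatch),
        )
    if a:
        best = max(best, brute_force_alignment_score(a[1:], b, match, mismatch, gap) + gap)
    if b:
        best = max(best, brute_force_alignment_score(a, b[1:], match, mismatch, gap) + gap)
    return best


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = sq.global_align("ACDE", "ACDE")
        assert aln.identity == 100.0
        assert aln.score == 4.0

    def test_single_mismatch(self):
        aln = sq.global_align("AAAA", "AAAT")
        assert aln.identity == 75.0
        assert "-" not in aln.aligned1 + aln.aligned2

    def test_gap_insertion(self):
        aln = sq.global_align("ACDE", "ACE")
        assert aln.score == 2.0  # 3 matches + 1 gap
        assert aln.aligned2.count("-") == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sq.global_align("", "ACD")

    def test_deterministic(self):
        a1 = sq.global_align("GATTACA", "GCATGCT")
        a2 = sq.global_align("GATTACA", "GCATGCT")
        assert a1 == a2

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        letters = np.array(list("ACDE"))
        for _ in range(30):
            a = "".join(rng.choice(letters, int(rng.integers(1, 7))))
            b = "".join(rng.choice(letters, int(rng.integers(1, 7))))
            aln = sq.global_align(a, b)
            assert aln.score == pytest.approx(
                brute_force_alignment_score(a, b, 1.0, 0.0, -1.0)
            )


class TestIdentityMatrix:
    def test_identical_pair_zero_distance(self):
        seqs = [sq.ProteinSequence("a", "ACDE"), sq.ProteinSequence("b", "ACDE")]
        dm = sq.pairwise_identity_matrix(seqs)
        assert dm.values[0, 1] == 0.0

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(5)
        letters = np.array(list(AA))
        seqs = [
            sq.ProteinSequence(f"s{i}", "".join(rng.choice(letters, 30)))
            for i in range(4)
        ]
        dm = sq.pairwise_identity_matrix(seqs)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_ordering_invariance(self):
        rng = np.random.default_rng(6)
        letters = np.array(list(AA))
        seqs = [
            sq.ProteinSequence(f"s{i}", "".join(rng.choice(letters, 25)))
            for i in range(3)
        ]
        d1 = sq.pairwise_identity_matrix(seqs)
        d2 = sq.pairwise_identity_matrix(seqs[::-1])
        for a in d1.labels:
            for b in d1.labels:
                assert d1.get(a, b) == d2.get(a, b)

    def test_duplicate_ids_rejected(self):
        seqs = [sq.ProteinSequence("a", "ACDE"), sq.ProteinSequence("a", "ACDF")]
        with pytest.raises(ValueError, match="duplicate"):
            sq.pairwise_identity_matrix(seqs)


def random_additive_quartet(rng):
    """Additive distances from a random 4-leaf tree ((A,B),(C,D))."""
    a, b, c, d, e = rng.uniform(0.5, 5.0, 5)
    D = np.zeros((4, 4))
    dist = {
        (0, 1): a + b,
        (0, 2): a + e + c,
        (0, 3): a + e + d,
        (1, 2): b + e + c,
        (1, 3): b + e + d,
        (2, 3): c + d,
    }
    for (i, j), v in dist.items():
        D[i, j] = D[j, i] = v
    return sq.DistanceMatrix(("A", "B", "C", "D"), D), (a, b, c, d, e)


def least_squares_topology(dm):
    """Brute-force oracle: best of the 3 unrooted 4-leaf topologies under
    least-squares branch lengths."""
    labels = dm.labels
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    y = np.array([dm.values[i, j] for i, j in pairs])
    best = None
    for cherry in ((0, 1), (0, 2), (0, 3)):
        group1 = set(cherry)
        # design matrix: columns = 4 external branches + internal branch
        M = np.zeros((6, 5))
        for row, (i, j) in enumerate(pairs):
            M[row, i] = 1
            M[row, j] = 1
            if (i in group1) != (j in group1):
                M[row, 4] = 1
        coef, *_ = np.linalg.lstsq(M, y, rcond=None)
        sse = float(np.sum((M @ coef - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, frozenset(labels[k] for k in cherry))
    return best[1]


def tree_cherry(tree):
    """The sibling leaf pair under the internal child of the 3-way root."""
    for child, _ in tree.root.children:
        if not child.is_leaf():
            names = [c.name for c, _ in child.children if c.is_leaf()]
            if len(names) == 2:
                return frozenset(names)
    raise AssertionError("no cherry found")


class TestNeighborJoining:
    def test_two_taxa_split_evenly(self):
        dm = sq.DistanceMatrix(("A", "B"), np.array([[0.0, 4.0], [4.0, 0.0]]))
        tree = sq.nj_tree(dm)
        (c1, l1), (c2, l2) = tree.root.children
        assert l1 == l2 == 2.0

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        dm = sq.DistanceMatrix(("A", "B", "C"), D)
        tree = sq.nj_tree(dm)
        lengths = {c.name: l for c, l in tree.root.children}
        assert lengths["A"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["B"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["C"] == pytest.approx((6 + 8 - 4) / 2)

    def test_additive_quartets_recovered(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            dm, _ = random_additive_quartet(rng)
            tree = sq.nj_tree(dm)
            # topology matches the least-squares brute-force oracle
            cherry = tree_cherry(tree)
            assert cherry in (frozenset("AB"), frozenset("CD"))
            assert least_squares_topology(dm) in (frozenset("AB"), frozenset("CD"))
            # path lengths reproduce the additive metric exactly
            rec = tree.leaf_distances()
            assert np.allclose(rec.values, dm.values, atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            sq.DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_newick_round_trip(self):
        rng = np.random.default_rng(23)
        dm, _ = random_additive_quartet(rng)
        tree = sq.nj_tree(dm)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        dm.values[i, j], abs=1e-9
                    )

    def test_agrees_with_skbio_on_additive_matrix(self):
        """Cross-check against an independent neighbor-joining implementation."""
        import skbio
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(31)
        dm, _ = random_additive_quartet(rng)
        ours = sq.nj_tree(dm).leaf_distances()
        sk_tree = skbio_nj(
            skbio.DistanceMatrix(dm.values, ids=list(dm.labels))
        )
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    d_sk = sk_tree.find(a).distance(sk_tree.find(b))
                    assert ours.get(a, b) == pytest.approx(d_sk, abs=1e-9)
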