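"""ORF finding, protein properties, identity matrices, NJ trees, Newick IO."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovigene import seqchar, simulate

STOPS = {"TAA", "TAG", "TGA"}


def orf_oracle(seq: str):
    """Exhaustive enumeration of every ATG..stop span in all forward frames."""
    seq = seq.upper()
    spans = []
    for start in range(len(seq) - 2):
        if seq[start:start + 3] != "ATG":
            continue
        for pos in range(start + 3, len(seq) - 2, 3):
            if seq[pos:pos + 3] in STOPS:
                spans.append((start, pos + 3))
                break
    if not spans:
        return None
    return max(spans, key=lambda span: (span[1] - span[0], -span[0]))


class TestOrfFinder:
    def test_minimal_orf(self):
        orf = seqchar.find_longest_orf("ATGTAA")
        assert (orf.start, orf.end, orf.peptide) == (0, 6, "M")

    def test_cloned_cdna_scale(self):
        # 1667-nt sequence whose longest ORF spans 1398 nt -> 465 residues
        cdna = "C" * 137 + "ATG" + "GAA" * 464 + "TAA" + "C" * 132
        assert len(cdna) == 1667
        orf = seqchar.find_longest_orf(cdna)
        assert orf.nt_length == 1398
        assert len(orf.peptide) == 465
        assert orf.peptide == "M" + "E" * 464

    def test_no_orf_is_explicit(self):
        assert seqchar.find_longest_orf("CCCCCCCCC") is None

    def test_reverse_complement_scan(self):
        forward_orf = "ATGGAAGAATAA"
        rc = str(__import__("Bio.Seq", fromlist=["Seq"]).Seq(forward_orf)
                 .reverse_complement())
        seq = "CCCC" + rc + "CCCC"
        assert seqchar.find_longest_orf(seq) is None
        orf = seqchar.find_longest_orf(seq, include_revcomp=True)
        assert orf is not None and orf.strand == "-" and orf.peptide == "MEE"

    def test_matches_exhaustive_oracle_on_random_sequences(self, rng):
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            expected = orf_oracle(seq)
            orf = seqchar.find_longest_orf(seq)
            if expected is None:
                assert orf is None
            else:
                assert (orf.start, orf.end) == expected

    def test_peptide_length_arithmetic(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=240))
            orf = seqchar.find_longest_orf(seq)
            if orf is not None:
                assert len(orf.peptide) == orf.nt_length // 3 - 1


class TestTranslate:
    @pytest.mark.parametrize("nt,aa", [("ATGGCCTAA", "MA"), ("ATGTAA", "M")])
    def test_standard_code(self, nt, aa):
        assert seqchar.translate(nt) == aa

    def test_long_orf_length(self):
        nt = "ATG" + "GCT" * 426 + "TGA"  # 1284 nt
        assert len(nt) == 1284
        assert len(seqchar.translate(nt)) == 427

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            seqchar.translate("ATGTAAGCCTAA")

    def test_non_triplet_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            seqchar.translate("ATGG")

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            seqchar.translate("ATGX{(")


class TestProteinProperties:
    def test_glycine_mass(self):
        # glycine residue 57.0519 Da + water 18.0153 Da
        assert seqchar.protein_mw("G") == pytest.approx(0.07507, abs=2e-5)

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            seqchar.protein_mw("")
        with pytest.raises(ValueError, match="empty"):
            seqchar.isoelectric_point("")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=15),
           st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=15))
    @settings(deadline=None, derandomize=True)
    def test_peptide_bond_mass_balance(self, a, b):
        water = 18.0153 / 1000.0
        assert seqchar.protein_mw(a + b) == pytest.approx(
            seqchar.protein_mw(a) + seqchar.protein_mw(b) - water, abs=1e-9)

    def test_pi_of_peptide_without_ionizable_side_chains(self):
        expected = (seqchar.DEFAULT_PKA["n_term"] + seqchar.DEFAULT_PKA["c_term"]) / 2
        assert seqchar.isoelectric_point("GG") == pytest.approx(expected, abs=0.01)

    def test_basic_residue_raises_pi(self):
        assert seqchar.isoelectric_point("K") > 7.0
        assert seqchar.isoelectric_point("D") < 7.0

    def test_bisection_agrees_with_grid_scan(self, rng):
        """Bisection root vs a 0.001-pH grid scan of the charge curve."""
        residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        grid = np.arange(0.0, 14.0, 0.001)
        for _ in range(20):
            pep = "".join(rng.choice(residues, size=rng.integers(1, 30)))
            charges = np.array([seqchar._net_charge(pep, ph, seqchar.DEFAULT_PKA)
                                for ph in grid])
            root = grid[np.argmin(np.abs(charges))]
            assert seqchar.isoelectric_point(pep) == pytest.approx(root, abs=0.01)


def identity_oracle(a: str, b: str):
    """All optimal global alignments by brute-force enumeration (tiny inputs).

    Returns the best score and the set of identity fractions achieved by
    score-optimal alignments (match +1, mismatch -1, gap -2).
    """
    results = []

    def extend(i, j, score, matches, length):
        if i == len(a) and j == len(b):
            results.append((score, matches / length if length else 1.0))
            return
        if i < len(a) and j < len(b):
            extend(i + 1, j + 1, score + (1 if a[i] == b[j] else -1),
                   matches + (a[i] == b[j]), length + 1)
        if i < len(a):
            extend(i + 1, j, score - 2, matches, length + 1)
        if j < len(b):
            extend(i, j + 1, score - 2, matches, length + 1)

    extend(0, 0, 0, 0, 0)
    best = max(score for score, _ in results)
    return best, {round(frac, 10) for score, frac in results if score == best}


class TestIdentityMatrix:
    def test_identical_sequences(self):
        identity, distance = seqchar.identity_matrix(
            {"a": "ACGTACGT", "b": "ACGTACGT"})
        assert identity.iloc[0, 1] == 100.0
        assert distance.values[0, 1] == 0.0

    def test_single_mismatch(self):
        identity, _ = seqchar.identity_matrix({"a": "ACGT", "b": "ACGA"})
        assert identity.iloc[0, 1] == pytest.approx(75.0)

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValueError, match="mixed alphabets"):
            seqchar.identity_matrix({"dna": "ACGT", "prot": "MKLF"})

    def test_matches_enumeration_oracle_on_tiny_pairs(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(15):
            a = "".join(rng.choice(bases, size=rng.integers(3, 6)))
            b = "".join(rng.choice(bases, size=rng.integers(3, 6)))
            identity, _ = seqchar.identity_matrix({"a": a, "b": b})
            _, optimal_fracs = identity_oracle(a, b)
            assert round(identity.iloc[0, 1] / 100.0, 10) in optimal_fracs

    def test_symmetry_and_bounds_on_simulated_family(self):
        records, _ = simulate.gen_homolog_family(
            simulate.TreeSimSpec(n_taxa=5, seq_length=200, seed=2))
        identity, distance = seqchar.identity_matrix(records)
        values = identity.to_numpy()
        np.testing.assert_allclose(values, values.T)
        assert (np.diag(values) == 100.0).all()
        assert (distance.values >= 0).all()


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = seqchar.DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], dtype=float))
        root, _ = seqchar.nj_tree(dm)
        lengths = {child.name: child.branch_length for child in root.children}
        assert lengths == {"A": 0.0, "B": 2.0, "C": 4.0}

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrices_recovered(self, n_taxa, rng):
        for _ in range(20):
            tree = simulate.gen_random_tree(
                simulate.TreeSimSpec(n_taxa=n_taxa), rng)
            truth = seqchar.leaf_distance_matrix(tree)
            root, _ = seqchar.nj_tree(truth)
            recovered = seqchar.leaf_distance_matrix(root)
            order = [recovered.names.index(n) for n in truth.names]
            np.testing.assert_allclose(
                recovered.values[np.ix_(order, order)][np.ix_(
                    range(n_taxa), range(n_taxa))],
                truth.values, atol=1e-9)

    def test_agrees_with_scikit_bio(self, rng):
        """Independent NJ implementation (scikit-bio) as oracle."""
        import skbio

        tree = simulate.gen_random_tree(simulate.TreeSimSpec(n_taxa=6), rng)
        truth = seqchar.leaf_distance_matrix(tree)
        root, _ = seqchar.nj_tree(truth)
        mine = seqchar.leaf_distance_matrix(root)

        skbio_tree = skbio.tree.nj(
            skbio.DistanceMatrix(truth.values, ids=list(truth.names)))
        for a, b in itertools.combinations(truth.names, 2):
            i, j = mine.names.index(a), mine.names.index(b)
            assert mine.values[i, j] == pytest.approx(
                skbio_tree.find(a).distance(skbio_tree.find(b)), abs=1e-6)

    def test_zero_distance_taxa_are_siblings(self):
        """A taxon at distance 0 from the query joins it first; the far
        taxon attaches on the longest path (the homolog-panel pattern)."""
        names = ("query", "sheep", "yak", "zebra")
        d = np.array([
            [0.0, 0.0, 0.02, 0.40],
            [0.0, 0.0, 0.02, 0.40],
            [0.02, 0.02, 0.0, 0.40],
            [0.40, 0.40, 0.40, 0.0],
        ])
        root, _ = seqchar.nj_tree(seqchar.DistanceMatrix(names, d))
        recovered = seqchar.leaf_distance_matrix(root)
        i, j = recovered.names.index("query"), recovered.names.index("sheep")
        assert recovered.values[i, j] == pytest.approx(0.0, abs=1e-12)
        k = recovered.names.index("zebra")
        assert recovered.values[i, k] == max(recovered.values[i])

    def test_fewer_than_three_taxa_rejected(self):
        dm = seqchar.DistanceMatrix(("A", "B"),
                                    np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            seqchar.nj_tree(dm)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            seqchar.DistanceMatrix(("A", "B", "C"),
                                   np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]]))


class TestNewick:
    def test_round_trip_preserves_topology_and_lengths(self, rng):
        for _ in range(25):
            tree = simulate.gen_random_tree(
                simulate.TreeSimSpec(n_taxa=int(rng.integers(3, 9))), rng)
            text = seqchar.to_newick(tree)
            parsed = seqchar.parse_newick(text)
            before = seqchar.leaf_distance_matrix(tree)
            after = seqchar.leaf_distance_matrix(parsed)
            assert after.names == before.names
            np.testing.assert_allclose(after.values, before.values, atol=1e-10)
            assert seqchar.to_newick(parsed) == text

    def test_nj_newick_round_trips(self):
        dm = seqchar.DistanceMatrix(
            ("A", "B", "C", "D"),
            np.array([[0, 5, 9, 9], [5, 0, 10, 10],
                      [9, 10, 0, 8], [9, 10, 8, 0]], dtype=float))
        _, newick = seqchar.nj_tree(dm)
        parsed = seqchar.parse_newick(newick)
        assert seqchar.to_newick(parsed) == newick

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValueError):
            seqchar.parse_newick("(A:1,B:2")
        with pytest.raises(ValueError):
            seqchar.parse_newick("(A:1,B:2);junk;")
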