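"""Chain representation, motif annotation, alignment and coordinate views."""

import numpy as np
import pytest

from colptm.chain_model import (
    AlignmentResult,
    CollagenChain,
    MotifClass,
    align_global,
    annotate_motifs,
    map_position,
    read_fasta,
    transfer_cleavage_sites,
)
from conftest import write_fasta


# ----------------------------------------------------------------------
# FASTA input
# ----------------------------------------------------------------------
class TestReadFasta:
    def test_basic_record(self, tmp_path):
        chains = read_fasta(write_fasta(tmp_path / "a.fasta", [("colX", "GPPGPK")]))
        assert len(chains) == 1
        assert chains[0].id == "colX"
        assert len(chains[0]) == 6

    def test_lowercase_uppercased(self, tmp_path):
        chains = read_fasta(write_fasta(tmp_path / "a.fasta", [("c", "gppgpk")]))
        assert chains[0].sequence == "GPPGPK"

    def test_nonstandard_residue_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="non-standard residue"):
            read_fasta(write_fasta(tmp_path / "a.fasta", [("c", "GPBGPK")]))

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_fasta(p)

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("GPPGPK\n>c\nGPP\n")
        with pytest.raises(ValueError, match="line 1"):
            read_fasta(p)


# ----------------------------------------------------------------------
# motif annotation
# ----------------------------------------------------------------------
class TestMotifAnnotation:
    def test_gpk_lysine(self):
        # K preceded at -2 by G: the G-X-K motif (hydroxylation/glyco eligible)
        chain = CollagenChain(id="c", sequence="AAAGPKAAA")
        ann = {a.position: a for a in annotate_motifs(chain)}
        assert ann[6].motif_class == MotifClass.GXK_LYS
        assert ann[6].triplet_context == "GPK"

    def test_gpp_xaa_and_yaa(self):
        # in G-P-P the middle P is Xaa (3-HyP candidate), the last P is Yaa (4-HyP)
        chain = CollagenChain(id="c", sequence="GPP")
        ann = annotate_motifs(chain)
        assert ann[1].motif_class == MotifClass.XAA_PRO
        assert ann[2].motif_class == MotifClass.YAA_PRO

    def test_no_motif(self):
        chain = CollagenChain(id="c", sequence="AAAA")
        assert all(a.motif_class == MotifClass.NONE for a in annotate_motifs(chain))

    def test_dual_role_proline_prefers_yaa(self):
        # P at position 3 of GGP is Yaa of G-G-P and Xaa of G-P-?; Yaa wins
        chain = CollagenChain(id="c", sequence="GGPA")
        ann = annotate_motifs(chain)
        assert ann[2].motif_class == MotifClass.YAA_PRO
        assert ann[2].triplet_context == "GGP"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_window_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("GPKARLESTV"), size=2000))
        chain = CollagenChain(id="r", sequence=seq)
        for a in annotate_motifs(chain):
            i, r = a.position, a.residue
            if r == "P" and i >= 3 and seq[i - 3] == "G":
                expected = MotifClass.YAA_PRO
            elif r == "P" and i >= 2 and seq[i - 2] == "G":
                expected = MotifClass.XAA_PRO
            elif r == "K" and i >= 3 and seq[i - 3] == "G":
                expected = MotifClass.GXK_LYS
            else:
                expected = MotifClass.NONE
            assert a.motif_class == expected, (i, r)


# ----------------------------------------------------------------------
# alignment
# ----------------------------------------------------------------------
def brute_force_align_score(query, reference, matrix, gap_open, gap_extend):
    """Exhaustive enumeration of all global alignments (affine gap costs:
    open for the first gapped position, extend for each further one)."""
    best = -np.inf

    def recurse(i, j, score, prev_gap):
        nonlocal best
        if i == len(query) and j == len(reference):
            best = max(best, score)
            return
        if i < len(query) and j < len(reference):
            s = matrix[query[i], reference[j]]
            recurse(i + 1, j + 1, score + s, None)
        if i < len(query):
            cost = gap_extend if prev_gap == "q" else gap_open
            recurse(i + 1, j, score - cost, "q")
        if j < len(reference):
            cost = gap_extend if prev_gap == "r" else gap_open
            recurse(i, j + 1, score - cost, "r")

    recurse(0, 0, 0.0, None)
    return best


class TestAlignGlobal:
    def test_identity(self):
        res = align_global("GPPGPK", "GPPGPK")
        assert res.pairs == [(i, i) for i in range(1, 7)]
        assert all(res.matches)

    def test_terminal_gap(self):
        res = align_global("GPPGPP", "GPPGP")
        assert len(res.pairs) == 5

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_global("", "GPP")

    def test_gap_maps_to_none(self):
        res = align_global("GPPGPP", "GPPGP")
        aligned_refs = {r for _, r in res.pairs}
        assert aligned_refs == {1, 2, 3, 4, 5}
        # the query position opposite no reference residue is unaligned
        unaligned_q = set(range(1, 7)) - {q for q, _ in res.pairs}
        assert len(unaligned_q) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_exhaustive_enumeration(self, seed):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(seed)
        q = "".join(rng.choice(list("GPKAR"), size=rng.integers(3, 8)))
        r = "".join(rng.choice(list("GPKAR"), size=rng.integers(3, 8)))
        res = align_global(q, r)
        expected = brute_force_align_score(q, r, blosum, 10.0, 0.5)
        assert res.score == pytest.approx(expected)


# ----------------------------------------------------------------------
# cleavage-site transfer and coordinates
# ----------------------------------------------------------------------
def _annotated(seq, sig=(1, 4), npro=(5, 8), cpro=None):
    n = len(seq)
    return CollagenChain(id="ref", sequence=seq, signal_peptide=sig,
                         n_propeptide=npro, c_propeptide=cpro or (n - 3, n))


class TestTransferCleavageSites:
    def test_identity_copies_intervals(self):
        ref = _annotated("MALSAGPPGPKGDAGPPGAAGRSTVL")
        query = CollagenChain(id="q", sequence=ref.sequence)
        out = transfer_cleavage_sites(query, ref)
        assert out.signal_peptide == ref.signal_peptide
        assert out.n_propeptide == ref.n_propeptide
        assert out.c_propeptide == ref.c_propeptide

    def test_insertion_shifts_boundaries(self):
        ref = _annotated("MALSAGPPGPKGDAGPPGAAGRSTVL")
        # insert 2 residues inside the helical region (after position 12)
        qseq = ref.sequence[:12] + "GA" + ref.sequence[12:]
        query = CollagenChain(id="q", sequence=qseq)
        out = transfer_cleavage_sites(query, ref)
        assert out.signal_peptide == (1, 4)
        assert out.n_propeptide == (5, 8)
        assert out.c_propeptide == (ref.c_propeptide[0] + 2, ref.c_propeptide[1] + 2)

    def test_unmappable_boundary_raises(self):
        ref = _annotated("MALSAGPPGPKGDAGPPGAAGRSTVL")
        query = CollagenChain(id="q", sequence="GPPGPKGDAGPP")
        aln = AlignmentResult(pairs=[(1, 20)], matches=[True], score=1.0)
        with pytest.raises(ValueError, match="unmappable"):
            transfer_cleavage_sites(query, ref, alignment=aln)


class TestCoordinates:
    def test_first_mature_residue(self):
        # mature numbering starts right after the N-propeptide
        chain = CollagenChain(id="c", sequence="A" * 200,
                              signal_peptide=(1, 22), n_propeptide=(23, 146),
                              c_propeptide=(190, 200))
        assert chain.to_mature(147) == 1
        assert chain.to_full(1) == 147

    def test_round_trip(self):
        chain = CollagenChain(id="c", sequence="A" * 60, signal_peptide=(1, 5),
                              n_propeptide=(6, 10), c_propeptide=(51, 60))
        for p in range(11, 51):
            assert chain.to_full(chain.to_mature(p)) == p

    def test_signal_peptide_position_rejected(self):
        chain = CollagenChain(id="c", sequence="A" * 60, signal_peptide=(1, 22),
                              n_propeptide=(23, 30), c_propeptide=(51, 60))
        with pytest.raises(ValueError, match="not in the mature chain"):
            chain.to_mature(10)

    def test_mature_length_arithmetic(self):
        chain = CollagenChain(id="c", sequence="A" * 100, signal_peptide=(1, 10),
                              n_propeptide=(11, 25), c_propeptide=(81, 100))
        assert chain.mature_length == 100 - 10 - 15 - 20

    def test_interval_order_enforced(self):
        with pytest.raises(ValueError, match="overlaps"):
            CollagenChain(id="c", sequence="A" * 50, signal_peptide=(1, 22),
                          n_propeptide=(20, 30))


# ----------------------------------------------------------------------
# hypothesis property tests
# ----------------------------------------------------------------------
from hypothesis import given, settings, strategies as st

_SEQ = st.text(alphabet="GPKARLESTV", min_size=1, max_size=120)


class TestMotifProperties:
    @settings(derandomize=True, max_examples=60)
    @given(seq=_SEQ)
    def test_classification_invariants(self, seq):
        chain = CollagenChain(id="h", sequence=seq)
        for a in annotate_motifs(chain):
            i = a.position
            if a.motif_class == MotifClass.YAA_PRO:
                assert a.residue == "P" and seq[i - 3] == "G"
            elif a.motif_class == MotifClass.XAA_PRO:
                assert a.residue == "P" and seq[i - 2] == "G"
            elif a.motif_class == MotifClass.GXK_LYS:
                assert a.residue == "K" and seq[i - 3] == "G"
            else:
                # unclassified P/K must genuinely lack the motif context
                if a.residue == "P":
                    assert not (i >= 2 and seq[i - 2] == "G") \
                        and not (i >= 3 and seq[i - 3] == "G")
                if a.residue == "K":
                    assert not (i >= 3 and seq[i - 3] == "G")

    @settings(derandomize=True, max_examples=40)
    @given(seq=st.text(alphabet="GPKA", min_size=20, max_size=80),
           cuts=st.tuples(st.integers(1, 5), st.integers(1, 5), st.integers(1, 5)))
    def test_mature_round_trip(self, seq, cuts):
        sig, npro, cpro = cuts
        if sig + npro + cpro + 1 >= len(seq):
            return
        chain = CollagenChain(id="h", sequence=seq, signal_peptide=(1, sig),
                              n_propeptide=(sig + 1, sig + npro),
                              c_propeptide=(len(seq) - cpro + 1, len(seq)))
        lo, hi = chain.mature_interval
        for p in range(lo, hi + 1):
            assert chain.to_full(chain.to_mature(p)) == p
        assert chain.mature_length == len(seq) - sig - npro - cpro
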