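"""Peptidoform enumeration, fragment matching, scoring, decoys and FDR."""

import itertools

import numpy as np
import pytest

from colptm.chain_model import CollagenChain, MotifClass, motif_map
from colptm.mass_digest import (
    ModifiedPeptide,
    SearchParams,
    WATER_MASS,
    PROTON_MASS,
    digest,
    modification_by_name,
    mono_mass,
    mz,
)
from colptm.motif_search import (
    PSM,
    Spectrum,
    assign_q_values,
    enumerate_peptidoforms,
    fdr_filter,
    make_decoys,
    match_ions,
    read_mgf,
    score_psm,
    search_spectra,
    theoretical_ions,
    write_mgf,
)
from colptm.synthetic_data import SimulationConfig, simulate_spectrum


def _pep(seq, start=1, chain_id="c"):
    return ModifiedPeptide(chain_id, start, start + len(seq) - 1, seq)


def brute_force_count(state_sizes, cap):
    """Number of state assignments with <= cap non-default states."""
    count = 0
    for combo in itertools.product(*[range(s) for s in state_sizes]):
        if sum(1 for c in combo if c > 0) <= cap:
            count += 1
    return count


class TestEnumeratePeptidoforms:
    # GPPGAKGDR: two prolines, one internal G-X-K lysine
    CHAIN = CollagenChain(id="c", sequence="GPPGAKGDR")

    def _params(self, cap=10):
        p = SearchParams()
        p.max_dynamic_mods = cap
        return p

    def test_full_cartesian_count(self):
        motifs = motif_map(self.CHAIN)
        pep = _pep("GPPGAKGDR")
        forms = enumerate_peptidoforms(pep, motifs, self._params())
        assert len(forms) == 2 * 2 * 4  # two P x one GXK-K

    def test_cap_one_counts(self):
        motifs = motif_map(self.CHAIN)
        forms = enumerate_peptidoforms(_pep("GPPGAKGDR"), motifs, self._params(cap=1))
        assert len(forms) == 1 + 2 + 3  # unmodified + one HyP each + three K states

    def test_no_eligible_residues(self):
        chain = CollagenChain(id="c", sequence="GAVGDLGER")
        forms = enumerate_peptidoforms(_pep("GAVGDLGER"), motif_map(chain),
                                       self._params())
        assert len(forms) == 1
        assert forms[0].mods == ()

    def test_cterm_lysine_glyco_excluded(self):
        chain = CollagenChain(id="c", sequence="GAPGAK")
        forms = enumerate_peptidoforms(_pep("GAPGAK"), motif_map(chain),
                                       self._params())
        # C-terminal GXK lysine: {unmod, HyP} x {unmod, HyK} only
        assert len(forms) == 2 * 2
        p = self._params()
        p.allow_cterm_glyco = True
        assert len(enumerate_peptidoforms(_pep("GAPGAK"), motif_map(chain), p)) == 2 * 4

    @pytest.mark.parametrize("seed", range(4))
    def test_counts_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        core = "".join(
            "G" + rng.choice(list("PAES")) + rng.choice(list("PAKQ"))
            for _ in range(4)
        ) + "GDR"
        chain = CollagenChain(id="c", sequence=core)
        motifs = motif_map(chain)
        pep = _pep(core)
        cap = int(rng.integers(1, 5))
        forms = enumerate_peptidoforms(pep, motifs, self._params(cap=cap))
        sizes = []
        for i, r in enumerate(core):
            pos = i + 1
            if r == "P":
                sizes.append(2)
            elif r == "K" and motifs[pos] == MotifClass.GXK_LYS:
                sizes.append(4 if pos != len(core) else 2)
        assert len(forms) == brute_force_count(sizes, cap)

    def test_combinatorial_guard(self):
        chain = CollagenChain(id="c", sequence="P" * 30)
        p = self._params()
        p.enumeration_guard = 1000
        with pytest.raises(ValueError, match="exceeds"):
            enumerate_peptidoforms(_pep("P" * 30), motif_map(chain), p)


class TestTheoreticalIons:
    def test_complementary_pairs_sum_to_precursor(self):
        pf = _pep("GPAGKR")
        ions = dict(theoretical_ions(pf, 1))
        n = len(pf.sequence)
        total = pf.mono_mass + 2 * PROTON_MASS
        for i in range(1, n):
            assert ions[f"b{i}^1"] + ions[f"y{n-i}^1"] == pytest.approx(total, abs=1e-9)

    def test_y1_of_lysine(self):
        ions = dict(theoretical_ions(_pep("GPAGK"), 1))
        assert ions["y1^1"] == pytest.approx(147.112804, abs=1e-5)

    def test_modification_shifts_containing_fragments(self):
        hyp = modification_by_name("HyP")
        plain = dict(theoretical_ions(_pep("GAPGAR"), 1))
        mod = dict(theoretical_ions(
            ModifiedPeptide("c", 1, 6, "GAPGAR", ((3, hyp),)), 1))
        for i in range(1, 6):
            b_shift = mod[f"b{i}^1"] - plain[f"b{i}^1"]
            y_shift = mod[f"y{6-i}^1"] - plain[f"y{6-i}^1"]
            if i >= 3:  # b_i contains position 3
                assert b_shift == pytest.approx(hyp.delta_mass, abs=1e-9)
                assert y_shift == pytest.approx(0.0, abs=1e-9)
            else:
                assert b_shift == pytest.approx(0.0, abs=1e-9)
                assert y_shift == pytest.approx(hyp.delta_mass, abs=1e-9)


class TestScorePsm:
    def _exact_spectrum(self, pf, params):
        ions = theoretical_ions(pf, params.max_fragment_charge)
        mzs = np.array([m for _, m in ions])
        return Spectrum("s", mz(pf.mono_mass, 2), 2, mzs, np.ones_like(mzs))

    def test_exact_spectrum_dominates_siblings(self):
        chain = CollagenChain(id="c", sequence="GPPGAKGDR")
        params = SearchParams()
        motifs = motif_map(chain)
        true_pf = enumerate_peptidoforms(_pep("GPPGAKGDR"), motifs, params)[5]
        spec = self._exact_spectrum(true_pf, params)
        scores = {
            pf.peptidoform_str(): score_psm(spec, pf, params)
            for pf in enumerate_peptidoforms(_pep("GPPGAKGDR"), motifs, params)
        }
        assert max(scores, key=scores.get) == true_pf.peptidoform_str()

    def test_empty_peak_list_scores_zero(self):
        params = SearchParams()
        pf = _pep("GPAGKR")
        spec = Spectrum("s", mz(pf.mono_mass, 2), 2, np.array([]), np.array([]))
        assert score_psm(spec, pf, params) == 0.0

    def test_generator_peptidoform_ranks_first_under_dropout(self):
        """With 10% peak dropout the generating peptidoform outranks its
        enumerated siblings in at least 95% of seeded trials."""
        chain = CollagenChain(id="c", sequence="GPPGAKGDR")
        params = SearchParams()
        motifs = motif_map(chain)
        siblings = enumerate_peptidoforms(_pep("GPPGAKGDR"), motifs, params)
        assert len(siblings) == 16
        true_pf = siblings[7]
        config = SimulationConfig(seed=0, dropout=0.10, n_noise_peaks=10)
        rng = np.random.default_rng(1234)
        wins = 0
        n_trials = 200
        for t in range(n_trials):
            spec = simulate_spectrum(true_pf, config, rng, f"t{t}")
            scores = [(score_psm(spec, pf, params),
                       pf.peptidoform_str() == true_pf.peptidoform_str())
                      for pf in siblings]
            best_score = max(s for s, _ in scores)
            if any(is_true and s == best_score for s, is_true in scores):
                wins += 1
        assert wins / n_trials >= 0.95


class TestDecoys:
    def test_reversal(self):
        chains = [CollagenChain(id="c1", sequence="GPKGDR")]
        decoys = make_decoys(chains)
        assert decoys[0].sequence == "RDGKPG"
        assert decoys[0].id == "DECOY_c1"

    def test_residue_composition_preserved(self, sim_chain):
        decoy = make_decoys([sim_chain])[0]
        assert sorted(decoy.sequence) == sorted(sim_chain.sequence)

    def test_palindromic_collision_counts_as_target(self):
        from colptm.motif_search import build_database

        # GAAG is its own reversal: target and decoy collide, target wins
        params = SearchParams(min_peptide_length=3)
        db = build_database([CollagenChain(id="c", sequence="GAAG")], params)
        shared = [pf for pf in db if pf.sequence == "GAAG"]
        assert len(shared) == 1 and not shared[0].is_decoy


class TestFdr:
    def _psms(self, target_scores, decoy_scores):
        out = []
        for i, s in enumerate(target_scores):
            out.append(PSM(f"t{i}", _pep("GPAGKR", chain_id="c"), s, False))
        for i, s in enumerate(decoy_scores):
            out.append(PSM(f"d{i}", _pep("GPAGKR", chain_id="DECOY_c"), s, True))
        return out

    def test_hand_computed_example(self):
        accepted = fdr_filter(self._psms([10, 9, 8, 7], [6, 5]), 0.01)
        assert len(accepted) == 4
        assert all(not p.is_decoy for p in accepted)
        assert all(p.q_value == 0.0 for p in accepted)

    def test_all_decoys_outscore_targets(self):
        accepted = fdr_filter(self._psms([3, 2, 1], [10, 9, 8]), 0.01)
        assert accepted == []

    def test_q_values_monotone_in_score(self):
        rng = np.random.default_rng(0)
        psms = self._psms(rng.normal(5, 2, 50), rng.normal(3, 2, 50))
        ordered = assign_q_values(psms)
        qs = [p.q_value for p in ordered]
        assert all(q1 <= q2 for q1, q2 in zip(qs, qs[1:]))

    def test_zero_targets_rejected(self):
        with pytest.raises(ValueError, match="no target"):
            assign_q_values(self._psms([], [5.0]))


class TestSearchDeterminism:
    def test_repeat_search_identical(self, sim_chain, sim_config):
        from colptm.synthetic_data import dataset_peptidoforms, place_planted_sites, simulate_spectra

        from colptm.synthetic_data import default_planted_profiles, generate_chain

        profiles = default_planted_profiles()
        config = SimulationConfig(seed=3, helical_triplets=20, n_spectra=15,
                                  planted_sites=[profiles[0], profiles[2]])

        chain = generate_chain(config)
        planted = place_planted_sites(chain, config)
        pfs = dataset_peptidoforms(chain, planted, n_background=3)
        spectra, _ = simulate_spectra(pfs, config)
        r1 = search_spectra(spectra, [chain])
        r2 = search_spectra(spectra, [chain])
        assert [(p.spectrum_id, p.peptidoform.peptidoform_str(), p.score) for p in r1] \
            == [(p.spectrum_id, p.peptidoform.peptidoform_str(), p.score) for p in r2]


class TestMgfRoundTrip:
    def test_peak_counts_preserved(self, tmp_path):
        pf = _pep("GPAGKR")
        config = SimulationConfig(seed=5, n_noise_peaks=7)
        rng = np.random.default_rng(config.seed)
        spectra = [simulate_spectrum(pf, config, rng, f"s{i}") for i in range(3)]
        path = tmp_path / "out.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == 3
        for a, b in zip(spectra, back):
            assert a.id == b.id
            assert len(a.peaks_mz) == len(b.peaks_mz)
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-6)
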