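"""Motif-constrained peptidoform search with target-decoy FDR control.

A transparent native search stage: candidate peptidoforms are enumerated per
tryptic peptide under the motif rules (every P may be hydroxylated; a K in
G-X-K context may be HyK, G-HyK or GG-HyK; every M may be oxidized), scored
against HCD spectra with a binomial b/y-ion matcher, and filtered by
target-decoy competition at a configurable q-value threshold.

The scorer is the negative log10 of the binomial tail probability of seeing
at least the observed number of matched theoretical ions, with the per-ion
match probability estimated from the fragment tolerance and the spectrum's
peak density.  It is deterministic and monotone in the matched-ion count.
"""

from __future__ import annotations

import bisect
import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from pyteomics import mgf as _pyt_mgf
from scipy import stats

from .chain_model import CollagenChain, MotifClass, motif_map
from .mass_digest import (
    ModificationSpec,
    ModifiedPeptide,
    PROTON_MASS,
    SearchParams,
    WATER_MASS,
    digest,
    modification_by_name,
    mono_mass,
    mz as _mz,
    neutral_mass,
    ppm_error,
    std_aa_mass,
)


@dataclass
class Spectrum:
    id: str
    precursor_mz: float
    charge: int
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray

    def __post_init__(self):
        self.peaks_mz = np.asarray(self.peaks_mz, dtype=float)
        self.peaks_intensity = np.asarray(self.peaks_intensity, dtype=float)
        order = np.argsort(self.peaks_mz)
        self.peaks_mz = self.peaks_mz[order]
        self.peaks_intensity = self.peaks_intensity[order]
        if np.any(self.peaks_intensity < 0):
            raise ValueError(f"spectrum {self.id}: negative intensity")


@dataclass
class PSM:
    spectrum_id: str
    peptidoform: ModifiedPeptide
    score: float
    is_decoy: bool
    q_value: Optional[float] = None


# ----------------------------------------------------------------------
# MGF / mzML I/O
# ----------------------------------------------------------------------
def read_mgf(path) -> list[Spectrum]:
    out = []
    with _pyt_mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params.get("charge", [2])[0])
            out.append(
                Spectrum(
                    id=str(params.get("title", f"scan{len(out)}")),
                    precursor_mz=float(params["pepmass"][0]),
                    charge=charge,
                    peaks_mz=entry["m/z array"],
                    peaks_intensity=entry["intensity array"],
                )
            )
    return out


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.peaks_mz,
                "intensity array": s.peaks_intensity,
                "params": {
                    "title": s.id,
                    "pepmass": s.precursor_mz,
                    "charge": f"{s.charge}+",
                },
            }
        )
    _pyt_mgf.write(entries, str(path), file_mode="w")


def read_mzml(path) -> list[Spectrum]:
    """Optional mzML reader (MS2 spectra only)."""
    from pyteomics import mzml as _pyt_mzml

    out = []
    with _pyt_mzml.MzML(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            prec = entry["precursorList"]["precursor"][0]["selectedIonList"]["selectedIon"][0]
            out.append(
                Spectrum(
                    id=str(entry.get("id", f"scan{len(out)}")),
                    precursor_mz=float(prec["selected ion m/z"]),
                    charge=int(prec.get("charge state", 2)),
                    peaks_mz=entry["m/z array"],
                    peaks_intensity=entry["intensity array"],
                )
            )
    return out


# ----------------------------------------------------------------------
# peptidoform enumeration
# ----------------------------------------------------------------------
def enumerate_peptidoforms(
    peptide: ModifiedPeptide,
    motifs: dict[int, MotifClass],
    params: SearchParams,
) -> list[ModifiedPeptide]:
    """All modification-state assignments for a peptide under the motif rules.

    Each P is {unmodified, HyP}; each K in G-X-K context is {unmodified, HyK,
    G-HyK, GG-HyK} (glyco states excluded at the peptide C-terminus unless
    ``params.allow_cterm_glyco``); each M is {unmodified, oxidized}.  Forms
    with more than ``params.max_dynamic_mods`` dynamic modifications are
    dropped.  Output order is canonical (by per-site state indices).
    """
    hyp = modification_by_name("HyP")
    hyk = modification_by_name("HyK")
    ghyk = modification_by_name("G-HyK")
    gghyk = modification_by_name("GG-HyK")
    ox = modification_by_name("Oxidation")

    static = tuple(
        (peptide.start + i, spec)
        for spec in params.static_mods
        for i, r in enumerate(peptide.sequence)
        if r == spec.target
    )

    site_states: list[list[Optional[Tuple[int, ModificationSpec]]]] = []
    total = 1
    for i, r in enumerate(peptide.sequence):
        pos = peptide.start + i
        states: list[Optional[Tuple[int, ModificationSpec]]] = []
        if r == "P":
            states = [None, (pos, hyp)]
        elif r == "K" and motifs.get(pos) == MotifClass.GXK_LYS:
            states = [None, (pos, hyk)]
            at_cterm = pos == peptide.end
            if params.allow_cterm_glyco or not at_cterm:
                states += [(pos, ghyk), (pos, gghyk)]
        elif r == "M":
            states = [None, (pos, ox)]
        if states:
            site_states.append(states)
            total *= len(states)
            if total > params.enumeration_guard:
                raise ValueError(
                    f"peptidoform state space for {peptide.sequence} exceeds "
                    f"{params.enumeration_guard}; reduce peptide length or the "
                    "modification set"
                )

    out = []
    for combo in itertools.product(*site_states):
        dyn = tuple(c for c in combo if c is not None)
        if len(dyn) > params.max_dynamic_mods:
            continue
        out.append(replace(peptide, mods=static + dyn))
    return out


# ----------------------------------------------------------------------
# theoretical fragments and scoring
# ----------------------------------------------------------------------
def theoretical_ions(
    peptidoform: ModifiedPeptide, max_fragment_charge: int = 1
) -> list[Tuple[str, float]]:
    """b- and y-series m/z for i in 1..n-1, charges 1..max_fragment_charge.

    Modification deltas are carried by every fragment containing the modified
    residue; N-terminal modifications ride the b series.
    """
    seq = peptidoform.sequence
    n = len(seq)
    deltas = np.zeros(n)
    nterm_delta = 0.0
    for pos, spec in peptidoform.mods:
        if spec.target == "N-term":
            nterm_delta += spec.delta_mass
        else:
            deltas[pos - peptidoform.start] += spec.delta_mass
    residue = np.array([std_aa_mass[r] for r in seq]) + deltas
    prefix = np.cumsum(residue)
    total = prefix[-1]
    out = []
    for i in range(1, n):
        b_neutral = prefix[i - 1] + nterm_delta          # b ion: sum residues, no water
        y_neutral = total - prefix[i - 1] + WATER_MASS   # y ion: residues + water
        for z in range(1, max_fragment_charge + 1):
            out.append((f"b{i}^{z}", (b_neutral + z * PROTON_MASS) / z))
            out.append((f"y{n - i}^{z}", (y_neutral + z * PROTON_MASS) / z))
    return out


def match_ions(
    spectrum: Spectrum,
    ions: Sequence[Tuple[str, float]],
    fragment_tol_ppm: float,
) -> int:
    """Count matched theoretical ions; greedy by ascending ppm error, each
    experimental peak consumed by at most one ion."""
    peaks = spectrum.peaks_mz
    if len(peaks) == 0:
        return 0
    candidates = []  # (abs_ppm, ion_index, peak_index)
    for ion_idx, (_, imz) in enumerate(ions):
        tol = imz * fragment_tol_ppm * 1e-6
        lo = bisect.bisect_left(peaks, imz - tol)
        hi = bisect.bisect_right(peaks, imz + tol)
        for pk in range(lo, hi):
            candidates.append((abs(ppm_error(peaks[pk], imz)), ion_idx, pk))
    candidates.sort()
    used_ions: set[int] = set()
    used_peaks: set[int] = set()
    matched = 0
    for _, ion_idx, pk in candidates:
        if ion_idx in used_ions or pk in used_peaks:
            continue
        used_ions.add(ion_idx)
        used_peaks.add(pk)
        matched += 1
    return matched


def score_psm(
    spectrum: Spectrum,
    peptidoform: ModifiedPeptide,
    params: SearchParams,
) -> float:
    """-log10 binomial tail probability of >= k matched ions among n."""
    if len(spectrum.peaks_mz) == 0:
        return 0.0
    ions = theoretical_ions(peptidoform, params.max_fragment_charge)
    n = len(ions)
    k = match_ions(spectrum, ions, params.fragment_tol_ppm)
    if k == 0:
        return 0.0
    span = float(spectrum.peaks_mz[-1] - spectrum.peaks_mz[0])
    density = len(spectrum.peaks_mz) / span if span > 0 else 1.0
    mean_window = 2 * params.fragment_tol_ppm * 1e-6 * float(np.mean([m for _, m in ions]))
    p = min(0.5, max(1e-12, density * mean_window))
    tail = stats.binom.sf(k - 1, n, p)
    if tail <= 0:
        # beyond double precision: fall back to the log of the smallest term
        tail = math.exp(stats.binom.logsf(k - 1, n, p)) if k < n else p**n
        if tail <= 0:
            return 320.0
    return float(-math.log10(tail))


# ----------------------------------------------------------------------
# decoys
# ----------------------------------------------------------------------
DECOY_PREFIX = "DECOY_"


def make_decoys(chains: Sequence[CollagenChain]) -> list[CollagenChain]:
    """Per-protein full sequence reversal; ids prefixed with DECOY_."""
    return [
        CollagenChain(id=DECOY_PREFIX + c.id, sequence=c.sequence[::-1], species=c.species)
        for c in chains
    ]


# ----------------------------------------------------------------------
# database search
# ----------------------------------------------------------------------
def build_database(
    chains: Sequence[CollagenChain],
    params: SearchParams,
    with_decoys: bool = True,
) -> list[ModifiedPeptide]:
    """Enumerate candidate peptidoforms for targets (and reversed decoys).

    Target/decoy peptide-sequence collisions are resolved in favour of the
    target: a decoy peptide whose sequence also occurs in the target database
    is dropped.
    """
    all_chains = list(chains)
    if with_decoys:
        all_chains += make_decoys(chains)
    target_seqs: set[str] = set()
    db: list[ModifiedPeptide] = []
    for chain in all_chains:
        is_decoy = chain.id.startswith(DECOY_PREFIX)
        motifs = motif_map(chain)
        for pep in digest(chain, params.max_missed_cleavages):
            if not (params.min_peptide_length <= len(pep.sequence) <= params.max_peptide_length):
                continue
            if not is_decoy:
                target_seqs.add(pep.sequence)
            elif pep.sequence in target_seqs:
                continue  # shared sequence counts as target only
            for pf in enumerate_peptidoforms(
                replace(pep, is_decoy=is_decoy), motifs, params
            ):
                db.append(pf)
    return db


def search_spectra(
    spectra: Sequence[Spectrum],
    chains: Sequence[CollagenChain],
    params: Optional[SearchParams] = None,
    database: Optional[Sequence[ModifiedPeptide]] = None,
) -> list[PSM]:
    """Best PSM per spectrum by precursor-window candidate scoring.

    Ties break toward targets, then the lexicographically smallest
    peptidoform string — reproducibility over optimism.
    """
    params = params or SearchParams()
    if database is None:
        database = build_database(chains, params)
    masses = np.array([pf.mono_mass for pf in database])
    order = np.argsort(masses, kind="stable")
    masses = masses[order]
    db_sorted = [database[i] for i in order]

    psms: list[PSM] = []
    for spec in spectra:
        target_mass = neutral_mass(spec.precursor_mz, spec.charge)
        tol = target_mass * params.precursor_tol_ppm * 1e-6
        lo = np.searchsorted(masses, target_mass - tol, side="left")
        hi = np.searchsorted(masses, target_mass + tol, side="right")
        best: Optional[Tuple[float, int, str, ModifiedPeptide]] = None
        for i in range(lo, hi):
            pf = db_sorted[i]
            s = score_psm(spec, pf, params)
            key = (s, 0 if pf.is_decoy else 1, pf.peptidoform_str())
            if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                key[0] == best[0] and key[1] == best[1] and key[2] < best[2]
            ):
                best = (s, key[1], key[2], pf)
        if best is not None:
            psms.append(PSM(spec.id, best[3], best[0], best[3].is_decoy))
    return psms


# ----------------------------------------------------------------------
# FDR
# ----------------------------------------------------------------------
def assign_q_values(psms: Sequence[PSM]) -> list[PSM]:
    """Target-decoy q-values: q(s) = min over cutoffs <= s of #decoy/#target
    at or above the cutoff; monotone non-increasing in score."""
    if not any(not p.is_decoy for p in psms):
        raise ValueError("no target PSMs: cannot estimate FDR")
    ordered = sorted(psms, key=lambda p: p.score, reverse=True)
    n_target = 0
    n_decoy = 0
    fdrs = []
    for p in ordered:
        if p.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdrs.append(n_decoy / max(1, n_target))
    # convert running FDR to q-values (suffix minimum)
    q = 0.0
    qvals = [0.0] * len(ordered)
    for i in range(len(ordered) - 1, -1, -1):
        q = fdrs[i] if i == len(ordered) - 1 else min(q, fdrs[i])
        qvals[i] = min(q, 1.0)
    for p, qv in zip(ordered, qvals):
        p.q_value = qv
    return ordered


def fdr_filter(psms: Sequence[PSM], threshold: float = 0.01) -> list[PSM]:
    """Assign q-values and retain PSMs with q <= threshold."""
    ordered = assign_q_values(psms)
    return [p for p in ordered if p.q_value <= threshold]


def rollup_best(psms: Sequence[PSM], level: str = "peptide") -> list[PSM]:
    """Best-scoring PSM per peptide sequence or per chain (protein) for
    level-wise FDR estimation."""
    keyfun = {
        "peptide": lambda p: p.peptidoform.sequence,
        "protein": lambda p: p.peptidoform.chain_id,
    }[level]
    best: dict[str, PSM] = {}
    for p in psms:
        k = keyfun(p)
        if k not in best or p.score > best[k].score:
            best[k] = p
    return list(best.values())


def fdr_filter_level(psms: Sequence[PSM], threshold: float = 0.01,
                     level: str = "peptide") -> list[PSM]:
    return fdr_filter(rollup_best(psms, level), threshold)


# ----------------------------------------------------------------------
# PSM table I/O
# ----------------------------------------------------------------------
def write_psm_tsv(psms: Sequence[PSM], path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("spectrum_id\tchain_id\tstart\tend\tpeptidoform\tscore\tq_value\tdecoy\n")
        for p in psms:
            q = f"{p.q_value:.6f}" if p.q_value is not None else "NA"
            fh.write(
                f"{p.spectrum_id}\t{p.peptidoform.chain_id}\t{p.peptidoform.start}\t"
                f"{p.peptidoform.end}\t{p.peptidoform.peptidoform_str()}\t"
                f"{p.score:.4f}\t{q}\t{int(p.is_decoy)}\n"
            )
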