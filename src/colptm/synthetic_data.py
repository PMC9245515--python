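"""Synthetic collagen datasets: chains, planted PTM occupancy, MS1 features, spectra.

The generator emulates the study design the quantitation layer expects:
collagen-like procollagen chains (signal peptide + N-propeptide +
(Gly-Xaa-Yaa)n core + C-propeptide, prolines enriched at Xaa/Yaa and
periodic lysines at Yaa giving G-X-K motifs), per-site modification-state
occupancy profiles over four conditions (sham, 7, 14, 30 DPA) with two
biological replicates each, MS1 areas under multiplicative log-normal noise,
and HCD b/y spectra with peak dropout and uniform noise peaks.

Everything is deterministic under a single seed: the global seed fans out to
per-component child seeds via a stable name hash, so chains, features and
spectra can be regenerated independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chain_model import CollagenChain, MotifClass, annotate_motifs, motif_map
from .mass_digest import ModifiedPeptide, SearchParams, digest, modification_by_name, mz
from .motif_search import Spectrum, enumerate_peptidoforms, theoretical_ions, write_mgf
from .quantitation import CONDITIONS, FEATURE_COLUMNS

_STATE_MODS = {"HyP": "HyP", "HyK": "HyK", "G-HyK": "G-HyK", "GG-HyK": "GG-HyK"}


def child_seed(seed: int, name: str) -> int:
    """Stable component seed below 2**31 derived from the global seed."""
    digest_ = hashlib.sha256(f"{seed}:{name}".encode()).hexdigest()
    return int(digest_[:8], 16) % (2**31 - 1)


@dataclass
class PlantedSite:
    """True occupancy of one site: per condition, percent per state.

    ``position`` None lets the generator pick an eligible motif position.
    States are 'unmod', 'HyP' for prolines; 'unmod', 'HyK', 'G-HyK',
    'GG-HyK' for G-X-K lysines.  Percentages must sum to 100 per condition.
    """

    kind: str                                   # 'P' | 'K'
    occupancy: dict                             # condition -> {state: percent}
    position: Optional[int] = None

    def __post_init__(self):
        normalized = {}
        for cond, states in self.occupancy.items():
            total = sum(states.values())
            if abs(total - 100.0) > 0.5:
                raise ValueError(
                    f"planted occupancy for {cond} sums to {total}, not 100"
                )
            # exact renormalization (fresh dicts: never mutate caller state)
            normalized[cond] = {s: 100.0 * v / total for s, v in states.items()}
        self.occupancy = normalized


# Occupancy templates shaped like the published sham/regeneration profiles:
# a high-HyK lysine whose GG-HyK fraction rises over regeneration, a
# microheterogeneous lysine, and two 3-HyP-like proline profiles.
def default_planted_profiles() -> list[PlantedSite]:
    return [
        PlantedSite("K", {
            "sham": {"unmod": 62.44, "HyK": 34.82, "GG-HyK": 2.74},
            "7DPA": {"unmod": 33.69, "HyK": 62.96, "GG-HyK": 3.35},
            "14DPA": {"unmod": 52.55, "HyK": 36.95, "GG-HyK": 10.50},
            "30DPA": {"unmod": 60.09, "HyK": 24.44, "GG-HyK": 15.47},
        }),
        PlantedSite("K", {
            "sham": {"unmod": 36.62, "HyK": 38.38, "G-HyK": 16.71, "GG-HyK": 8.29},
            "7DPA": {"unmod": 43.75, "HyK": 34.81, "G-HyK": 17.85, "GG-HyK": 3.59},
            "14DPA": {"unmod": 46.09, "HyK": 21.13, "G-HyK": 31.26, "GG-HyK": 1.52},
            "30DPA": {"unmod": 32.30, "HyK": 45.72, "G-HyK": 19.63, "GG-HyK": 2.35},
        }),
        PlantedSite("P", {
            "sham": {"unmod": 51.27, "HyP": 48.73},
            "7DPA": {"unmod": 55.97, "HyP": 44.03},
            "14DPA": {"unmod": 31.04, "HyP": 68.96},
            "30DPA": {"unmod": 92.77, "HyP": 7.23},
        }),
        PlantedSite("P", {
            "sham": {"unmod": 92.45, "HyP": 7.55},
            "7DPA": {"unmod": 68.51, "HyP": 31.49},
            "14DPA": {"unmod": 78.79, "HyP": 21.21},
            "30DPA": {"unmod": 79.50, "HyP": 20.50},
        }),
    ]


@dataclass
class SimulationConfig:
    seed: int = 1
    n_chains: int = 1
    helical_triplets: int = 60
    signal_length: int = 22
    n_propeptide_length: int = 24
    c_propeptide_length: int = 24
    planted_sites: list = field(default_factory=default_planted_profiles)
    noise_cv: float = 0.10
    dropout: float = 0.10
    n_noise_peaks: int = 20
    replicates: int = 2
    conditions: tuple = CONDITIONS
    base_area: float = 1.0e6
    detection_floor: float = 0.0
    n_spectra: int = 200
    fragment_tol_ppm: float = 20.0
    precursor_tol_ppm: float = 10.0

    def __post_init__(self):
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


# ----------------------------------------------------------------------
# chain generation
# ----------------------------------------------------------------------
_XAA = ("P", "A", "E", "S", "L", "D", "Q", "V")
_XAA_P = (0.33, 0.17, 0.12, 0.10, 0.10, 0.08, 0.05, 0.05)
_YAA = ("P", "A", "Q", "S", "E", "T", "N", "V")
_YAA_P = (0.42, 0.15, 0.10, 0.09, 0.09, 0.06, 0.05, 0.04)
_FLANK = tuple("ADESTVLIFNQGY")


def _flank_segment(rng: np.random.Generator, length: int) -> str:
    out = []
    for i in range(length):
        if i and i % 12 == 0:
            out.append(rng.choice(["K", "R"]))
        else:
            out.append(rng.choice(_FLANK))
    return "".join(out)


def generate_chain(config: SimulationConfig, index: int = 0) -> CollagenChain:
    """One procollagen-like chain, deterministic per (seed, index).

    The helical core has G at every first triplet position, prolines enriched
    at Xaa and Yaa, K at the Yaa of every 5th triplet (a G-X-K motif) and R at
    the Xaa of every 7th triplet (with a non-P Yaa so the site is tryptic),
    guaranteeing cleavage sites at least every ~21 core residues.
    """
    rng = np.random.default_rng(child_seed(config.seed, f"chain{index}"))
    signal = _flank_segment(rng, config.signal_length)
    n_pro = _flank_segment(rng, config.n_propeptide_length)
    c_pro = _flank_segment(rng, config.c_propeptide_length)
    triplets = []
    for t in range(config.helical_triplets):
        x = rng.choice(_XAA, p=_XAA_P)
        y = rng.choice(_YAA, p=_YAA_P)
        if (t + 1) % 5 == 0:
            y = "K"
        if (t + 1) % 7 == 0:
            x = "R"
            if y == "P":  # keep the R site tryptic
                y = "A"
        triplets.append("G" + x + y)
    seq = signal + n_pro + "".join(triplets) + c_pro
    n = len(seq)
    sig_end = config.signal_length
    npro_end = sig_end + config.n_propeptide_length
    return CollagenChain(
        id=f"SIM_COL{index + 1}",
        sequence=seq,
        species="synthetic",
        signal_peptide=(1, sig_end),
        n_propeptide=(sig_end + 1, npro_end),
        c_propeptide=(n - config.c_propeptide_length + 1, n),
    )


def place_planted_sites(chain: CollagenChain, config: SimulationConfig) -> list[PlantedSite]:
    """Assign concrete motif positions to the planted profiles.

    Positions are chosen deterministically across the mature helical core so
    that the covering tryptic peptides of distinct planted sites are disjoint
    — each site's MS1 features then quantify that site alone."""
    motifs = annotate_motifs(chain)
    lo, hi = chain.mature_interval
    k_positions = [a.position for a in motifs
                   if a.motif_class == MotifClass.GXK_LYS and lo <= a.position <= hi]
    p_positions = [a.position for a in motifs
                   if a.motif_class == MotifClass.YAA_PRO and lo <= a.position <= hi]
    placed = []
    used_intervals: list[tuple[int, int]] = []

    def _take(pool, kind):
        # prefer positions on disjoint peptides; fall back to overlap if the
        # chain is too short to offer one
        for require_disjoint in (True, False):
            for pos in pool:
                if any(p.position == pos for p in placed if p.position is not None):
                    continue
                try:
                    pep = _covering_peptide(chain, pos)
                except ValueError:
                    continue
                overlaps = any(pep.start <= e and s <= pep.end
                               for s, e in used_intervals)
                if require_disjoint and overlaps:
                    continue
                used_intervals.append((pep.start, pep.end))
                return pos
        raise ValueError(f"no eligible {kind} motif position left to plant")

    for site in config.planted_sites:
        if site.position is not None:
            try:
                pep = _covering_peptide(chain, site.position)
                used_intervals.append((pep.start, pep.end))
            except ValueError:
                pass
            placed.append(site)
            continue
        pool = k_positions if site.kind == "K" else p_positions
        pos = _take(pool, site.kind)
        placed.append(PlantedSite(site.kind, site.occupancy, position=pos))
    return placed


# ----------------------------------------------------------------------
# peptidoforms for planted sites
# ----------------------------------------------------------------------
def _covering_peptide(chain: CollagenChain, position: int,
                      max_missed: int = 2) -> ModifiedPeptide:
    """Shortest tryptic peptide (5-60 residues) containing the position; a
    site on a C-terminal K takes the next-longer missed-cleavage peptide so
    glyco states stay enumerable."""
    candidates = [
        p for p in digest(chain, max_missed)
        if p.start <= position <= p.end and 5 <= len(p.sequence) <= 60
        and not (position == p.end and chain.sequence[position - 1] == "K")
    ]
    if not candidates:
        raise ValueError(f"no tryptic peptide covers position {position}")
    return min(candidates, key=lambda p: (len(p.sequence), p.start))


def planted_peptidoforms(chain: CollagenChain, site: PlantedSite) -> dict[str, ModifiedPeptide]:
    """state -> peptidoform of the covering peptide with that state planted."""
    if site.position is None:
        raise ValueError("planted site has no position")
    motifs = motif_map(chain)
    expected = MotifClass.GXK_LYS if site.kind == "K" else (
        MotifClass.YAA_PRO, MotifClass.XAA_PRO)
    m = motifs.get(site.position)
    ok = (m == expected) if site.kind == "K" else (m in expected)
    if not ok:
        raise ValueError(
            f"planted site at {site.position} is not on an eligible {site.kind} motif"
        )
    pep = _covering_peptide(chain, site.position)
    states = set().union(*(set(v) for v in site.occupancy.values()))
    out = {}
    for state in sorted(states):
        if state == "unmod":
            out[state] = pep
        else:
            spec = modification_by_name(_STATE_MODS[state])
            out[state] = ModifiedPeptide(
                chain_id=pep.chain_id, start=pep.start, end=pep.end,
                sequence=pep.sequence, mods=((site.position, spec),),
                missed_cleavages=pep.missed_cleavages,
            )
    return out


# ----------------------------------------------------------------------
# MS1 features
# ----------------------------------------------------------------------
def simulate_features(
    chain: CollagenChain,
    planted: Sequence[PlantedSite],
    config: SimulationConfig,
) -> pd.DataFrame:
    """MS1 feature table: one row per (peptidoform-state, condition, replicate).

    area = base_area * true state fraction * LogNormal(0, sigma), with sigma
    chosen so the multiplicative noise has the configured CV; areas below the
    detection floor are zeroed (simulated ND).
    """
    rng = np.random.default_rng(child_seed(config.seed, "features"))
    sigma = float(np.sqrt(np.log(1.0 + config.noise_cv**2)))
    rows = []
    for site in planted:
        pfs = planted_peptidoforms(chain, site)
        for cond in config.conditions:
            states = site.occupancy.get(cond, {})
            for rep in range(1, config.replicates + 1):
                for state, pct in states.items():
                    pf = pfs[state]
                    noise = rng.lognormal(0.0, sigma) if sigma > 0 else 1.0
                    area = config.base_area * (pct / 100.0) * noise
                    if area < config.detection_floor:
                        area = 0.0
                    state_str = "" if state == "unmod" else f"{site.kind}{site.position}:{state}"
                    rows.append({
                        "peptidoform": pf.peptidoform_str(),
                        "chain": chain.id,
                        "pep_start": pf.start,
                        "pep_end": pf.end,
                        "states": state_str,
                        "condition": cond,
                        "replicate": rep,
                        "area": area,
                    })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


# ----------------------------------------------------------------------
# spectra
# ----------------------------------------------------------------------
def simulate_spectrum(
    peptidoform: ModifiedPeptide,
    config: SimulationConfig,
    rng: np.random.Generator,
    spectrum_id: str,
    charge: int = 2,
) -> Spectrum:
    """HCD-like b/y spectrum: singly charged fragments with ppm jitter and
    log-normal intensities, per-peak dropout, plus uniform noise peaks."""
    ions = theoretical_ions(peptidoform, max_fragment_charge=1)
    mzs, intens = [], []
    for _, imz in ions:
        if rng.random() < config.dropout:
            continue
        jitter = rng.uniform(-config.fragment_tol_ppm / 2, config.fragment_tol_ppm / 2)
        mzs.append(imz * (1 + jitter * 1e-6))
        intens.append(rng.lognormal(np.log(1e4), 0.5))
    if ions:
        lo = min(imz for _, imz in ions)
        hi = max(imz for _, imz in ions)
    else:  # single-residue edge case
        lo, hi = 100.0, 1500.0
    for _ in range(config.n_noise_peaks):
        mzs.append(rng.uniform(lo * 0.9, hi * 1.1))
        intens.append(rng.lognormal(np.log(1e3), 0.5))
    pjit = rng.uniform(-config.precursor_tol_ppm / 2, config.precursor_tol_ppm / 2)
    prec = mz(peptidoform.mono_mass, charge) * (1 + pjit * 1e-6)
    return Spectrum(spectrum_id, prec, charge, np.array(mzs), np.array(intens))


def simulate_spectra(
    peptidoforms: Sequence[ModifiedPeptide],
    config: SimulationConfig,
    seed_name: str = "spectra",
) -> tuple[list[Spectrum], pd.DataFrame]:
    """n_spectra spectra cycling over the given peptidoforms, with a truth
    ledger mapping spectrum id -> generating peptidoform."""
    rng = np.random.default_rng(child_seed(config.seed, seed_name))
    spectra = []
    truth = []
    for i in range(config.n_spectra):
        pf = peptidoforms[i % len(peptidoforms)]
        sid = f"sim.{i:05d}"
        spectra.append(simulate_spectrum(pf, config, rng, sid))
        truth.append({
            "spectrum_id": sid,
            "chain": pf.chain_id,
            "pep_start": pf.start,
            "pep_end": pf.end,
            "peptidoform": pf.peptidoform_str(),
        })
    return spectra, pd.DataFrame(truth)


# ----------------------------------------------------------------------
# dataset assembly and evaluation
# ----------------------------------------------------------------------
def dataset_peptidoforms(chain: CollagenChain, planted: Sequence[PlantedSite],
                         n_background: int = 10) -> list[ModifiedPeptide]:
    """Planted-state peptidoforms plus unmodified background peptides."""
    pfs: list[ModifiedPeptide] = []
    seen = set()
    for site in planted:
        for state, pf in sorted(planted_peptidoforms(chain, site).items()):
            if pf.key() not in seen:
                seen.add(pf.key())
                pfs.append(pf)
    background = [p for p in digest(chain, 0) if 5 <= len(p.sequence) <= 60]
    for pep in background[:n_background]:
        if pep.key() not in seen:
            pfs.append(pep)
    return pfs


def planted_truth_sites(planted: Sequence[PlantedSite], chain_id: str) -> pd.DataFrame:
    """Ledger of planted modified site states (chain, position, state)."""
    rows = []
    for site in planted:
        states = set().union(*(set(v) for v in site.occupancy.values())) - {"unmod"}
        for state in sorted(states):
            rows.append({"chain": chain_id, "position": site.position, "state": state})
    return pd.DataFrame(rows)


def site_recall(truth: pd.DataFrame, catalog) -> float:
    """Fraction of planted (chain, position, state) triples present in the
    catalog with that state observed."""
    if truth.empty:
        return float("nan")
    hit = 0
    for _, row in truth.iterrows():
        site = catalog.get(row["chain"], int(row["position"]))
        if site is not None and row["state"] in site.states_observed:
            hit += 1
    return hit / len(truth)


def generate_dataset(config: SimulationConfig, outdir) -> dict:
    """Write FASTA, MGF, feature TSV, truth ledgers and the config snapshot."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chains = [generate_chain(config, i) for i in range(config.n_chains)]
    chain = chains[0]
    planted = place_planted_sites(chain, config)

    with open(outdir / "chains.fasta", "w") as fh:
        for c in chains:
            fh.write(f">{c.id}\n{c.sequence}\n")
    features = simulate_features(chain, planted, config)
    features.to_csv(outdir / "features.tsv", sep="\t", index=False)
    pfs = dataset_peptidoforms(chain, planted)
    spectra, spectrum_truth = simulate_spectra(pfs, config)
    write_mgf(spectra, outdir / "spectra.mgf")
    spectrum_truth.to_csv(outdir / "spectrum_truth.tsv", sep="\t", index=False)
    truth_sites = planted_truth_sites(planted, chain.id)
    truth_sites.to_csv(outdir / "site_truth.tsv", sep="\t", index=False)
    snapshot = {
        "seed": config.seed,
        "n_chains": config.n_chains,
        "helical_triplets": config.helical_triplets,
        "noise_cv": config.noise_cv,
        "dropout": config.dropout,
        "replicates": config.replicates,
        "n_spectra": config.n_spectra,
        "chain_intervals": {
            c.id: {"signal_peptide": c.signal_peptide,
                   "n_propeptide": c.n_propeptide,
                   "c_propeptide": c.c_propeptide}
            for c in chains
        },
        "planted": [
            {"kind": s.kind, "position": s.position, "occupancy": s.occupancy}
            for s in planted
        ],
    }
    (outdir / "config.json").write_text(json.dumps(snapshot, indent=2))
    return {
        "chains": chains,
        "planted": planted,
        "features": features,
        "spectra": spectra,
        "spectrum_truth": spectrum_truth,
        "site_truth": truth_sites,
    }
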