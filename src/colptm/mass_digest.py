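"""In-silico tryptic digestion and monoisotopic mass arithmetic.

The modification table carries the study's collagen PTM delta masses as
first-class constants: hydroxylation of proline (any P) and of lysine in the
G-X-K motif context (one oxygen, +15.994915 Da), galactosyl-hydroxylysine
(HyK + one hexose) and glucosylgalactosyl-hydroxylysine (HyK + two hexoses),
alongside the standard carbamidomethyl-C static modification, methionine
oxidation and N-terminal acetylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

from pyteomics import parser as _pyt_parser
from pyteomics.mass import std_aa_mass

from .chain_model import CollagenChain, MotifClass

# Monoisotopic constants (Da), stated to 9 decimals.
PROTON_MASS = 1.007276467
WATER_MASS = 18.010564684
OXYGEN_MASS = 15.994914620          # one O: HyP, HyK, Met oxidation
HEXOSE_MASS = 162.052823418         # C6H10O5: galactosyl/glucosyl unit
CARBAMIDOMETHYL_MASS = 57.021463721  # C2H3NO
ACETYL_MASS = 42.010565             # C2H2O

G_HYK_MASS = OXYGEN_MASS + HEXOSE_MASS            # 178.047738 Da
GG_HYK_MASS = OXYGEN_MASS + 2 * HEXOSE_MASS       # 340.100562 Da


@dataclass(frozen=True)
class ModificationSpec:
    """A (possibly motif-constrained) modification with its monoisotopic delta."""

    name: str
    target: str                       # residue letter or 'N-term'
    delta_mass: float
    motif_constraint: Optional[MotifClass] = None
    mode: str = "dynamic"             # 'static' | 'dynamic'
    printed: Optional[str] = None     # delta string as printed in the source tables

    def __post_init__(self):
        if self.mode not in ("static", "dynamic"):
            raise ValueError(f"mode must be static|dynamic, got {self.mode!r}")
        if self.mode == "static" and self.motif_constraint is not None:
            raise ValueError("static modifications cannot carry a motif constraint")


def build_modification_table() -> list[ModificationSpec]:
    """The pipeline's modification set (deltas from elemental composition)."""
    return [
        ModificationSpec("Carbamidomethyl", "C", CARBAMIDOMETHYL_MASS,
                         mode="static", printed="+57.0236"),
        ModificationSpec("HyP", "P", OXYGEN_MASS, printed="+15.9949"),
        ModificationSpec("HyK", "K", OXYGEN_MASS,
                         motif_constraint=MotifClass.GXK_LYS, printed="+15.994,916"),
        ModificationSpec("G-HyK", "K", G_HYK_MASS,
                         motif_constraint=MotifClass.GXK_LYS, printed="178.047738"),
        ModificationSpec("GG-HyK", "K", GG_HYK_MASS,
                         motif_constraint=MotifClass.GXK_LYS, printed="340.100,562"),
        ModificationSpec("Oxidation", "M", OXYGEN_MASS, printed="+15.9949"),
        ModificationSpec("Acetyl", "N-term", ACETYL_MASS, printed="+42.010565"),
    ]


def modification_by_name(name: str) -> ModificationSpec:
    for m in build_modification_table():
        if m.name == name:
            return m
    raise KeyError(name)


def write_modification_tsv(path) -> None:
    with open(path, "w") as fh:
        fh.write("name\ttarget\tmotif\tdelta_mass\tmode\tprinted\n")
        for m in build_modification_table():
            motif = m.motif_constraint.value if m.motif_constraint else "."
            fh.write(f"{m.name}\t{m.target}\t{motif}\t{m.delta_mass:.9f}\t{m.mode}\t{m.printed}\n")


# ----------------------------------------------------------------------
# masses
# ----------------------------------------------------------------------
def mono_mass(sequence: str, mods: Iterable[Tuple[int, ModificationSpec]] = ()) -> float:
    """Monoisotopic neutral mass: residue masses + water + modification deltas."""
    total = WATER_MASS
    for r in sequence:
        try:
            total += std_aa_mass[r]
        except KeyError:
            raise ValueError(f"unknown residue {r!r}") from None
    for _, spec in mods:
        total += spec.delta_mass
    return total


def mz(mass: float, charge: int) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


def neutral_mass(mz_value: float, charge: int) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz_value * charge - charge * PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


# ----------------------------------------------------------------------
# peptides
# ----------------------------------------------------------------------
@dataclass
class ModifiedPeptide:
    """A digested peptide with positioned modifications (full-length coords)."""

    chain_id: str
    start: int                    # 1-based, closed interval [start, end]
    end: int
    sequence: str
    mods: Tuple[Tuple[int, ModificationSpec], ...] = ()
    missed_cleavages: int = 0
    is_decoy: bool = False

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("interval length does not match sequence length")
        for pos, spec in self.mods:
            if not (self.start <= pos <= self.end):
                raise ValueError(f"mod position {pos} outside [{self.start},{self.end}]")
            if spec.target != "N-term":
                res = self.sequence[pos - self.start]
                if res != spec.target:
                    raise ValueError(
                        f"mod {spec.name} targets {spec.target}, found {res} at {pos}"
                    )
        # canonical ordering: by position then name
        object.__setattr__(
            self, "mods", tuple(sorted(self.mods, key=lambda m: (m[0], m[1].name)))
        )

    @property
    def mono_mass(self) -> float:
        return mono_mass(self.sequence, self.mods)

    def mod_at(self, position: int) -> Optional[ModificationSpec]:
        for pos, spec in self.mods:
            if pos == position and spec.target != "N-term":
                return spec
        return None

    @property
    def n_dynamic_mods(self) -> int:
        return sum(1 for _, s in self.mods if s.mode == "dynamic")

    def peptidoform_str(self) -> str:
        """Bracketed-delta dialect, e.g. ``DGAAGPK[+340.1006]GDR``."""
        parts = []
        nterm = [s for p, s in self.mods if s.target == "N-term"]
        if nterm:
            parts.append(f"[+{nterm[0].delta_mass:.4f}]-")
        for i, r in enumerate(self.sequence):
            parts.append(r)
            spec = self.mod_at(self.start + i)
            if spec is not None:
                parts.append(f"[{spec.delta_mass:+.4f}]")
        return "".join(parts)

    def key(self) -> tuple:
        return (
            self.chain_id,
            self.start,
            self.end,
            tuple((p, s.name) for p, s in self.mods),
        )


@dataclass
class SearchParams:
    """Search configuration; defaults mirror the high-accuracy subset search."""

    precursor_tol_ppm: float = 10.0
    fragment_tol_ppm: float = 20.0
    max_missed_cleavages: int = 4
    max_dynamic_mods: int = 10
    fdr_threshold: float = 0.01
    min_peptide_length: int = 5
    max_peptide_length: int = 60
    max_fragment_charge: int = 2
    allow_cterm_glyco: bool = False
    enumeration_guard: int = 10**6
    static_mods: Tuple[ModificationSpec, ...] = ()
    dynamic_mods: Tuple[ModificationSpec, ...] = ()

    def __post_init__(self):
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if not self.static_mods and not self.dynamic_mods:
            table = build_modification_table()
            self.static_mods = tuple(m for m in table if m.mode == "static")
            self.dynamic_mods = tuple(
                m for m in table if m.mode == "dynamic" and m.target != "N-term"
            )


def myrimatch_like() -> SearchParams:
    """High-accuracy preset: 10/20 ppm, 4 missed cleavages, 10 dynamic mods."""
    return SearchParams()


def msfragger_like() -> SearchParams:
    """Wide-tolerance preset: 50/25 ppm, 3 missed cleavages, 5 dynamic mods."""
    return SearchParams(precursor_tol_ppm=50.0, fragment_tol_ppm=25.0,
                        max_missed_cleavages=3, max_dynamic_mods=5)


# Plain tryptic rule: after K/R, not before P (no WKP/MRP exceptions)
_TRYPSIN = r"[KR](?=[^P])"


def count_missed_cleavages(sequence: str, next_residue: Optional[str] = None) -> int:
    """Internal K/R cleavage sites not followed by P (peptide C-term excluded)."""
    n = 0
    for i, r in enumerate(sequence[:-1]):
        if r in "KR" and sequence[i + 1] != "P":
            n += 1
    return n


def digest(chain: CollagenChain, max_missed: int = 4) -> list[ModifiedPeptide]:
    """All fully tryptic peptides with 0..max_missed missed cleavages.

    Cleaves after K or R except when the next residue is P; peptide bounds are
    full-length chain coordinates.  No length filter is applied here — search
    candidacy filters by length separately, so the 0-missed peptides partition
    the chain exactly.
    """
    seq = chain.sequence
    if not seq:
        raise ValueError("empty chain sequence")
    out = []
    for start0, pep in _pyt_parser.icleave(seq, _TRYPSIN, missed_cleavages=max_missed,
                                           min_length=1):
        out.append(
            ModifiedPeptide(
                chain_id=chain.id,
                start=start0 + 1,
                end=start0 + len(pep),
                sequence=pep,
                missed_cleavages=count_missed_cleavages(pep),
            )
        )
    out.sort(key=lambda p: (p.start, p.end))
    return out


def write_digest_tsv(peptides: Sequence[ModifiedPeptide], path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_id\tstart\tend\tsequence\tmissed_cleavages\tmono_mass\n")
        for p in peptides:
            fh.write(f"{p.chain_id}\t{p.start}\t{p.end}\t{p.sequence}\t"
                     f"{p.missed_cleavages}\t{p.mono_mass:.6f}\n")
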