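"""Collagen chain representation, Gly-Xaa-Yaa motif annotation and coordinates.

Collagen chains are synthesized as procollagen: a signal peptide, an
N-terminal propeptide, the (Gly-Xaa-Yaa)n triple-helical core, and a
C-terminal propeptide.  Site labels throughout the package use 1-based
*full-length* coordinates (signal peptide included); "mature" numbering —
what remains after signal/propeptide cleavage — is a derived view.

Motif context drives modification eligibility: prolines at the Yaa position
of a Gly-Xaa-Yaa triplet are the canonical 4-hydroxylation substrates,
prolines at the Xaa position can be 3-hydroxylated, and lysines at the Yaa
position (a G-X-K triplet) are the hydroxylation/O-glycosylation substrates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

Interval = Tuple[int, int]  # closed, 1-based


class MotifClass(enum.Enum):
    """Positional role of a residue within the collagen triplet repeat."""

    YAA_PRO = "YAA_PRO"    # P at Yaa of G-X-P  -> 4-HyP eligible
    XAA_PRO = "XAA_PRO"    # P at Xaa of G-P-Y  -> 3-HyP candidate
    GXK_LYS = "GXK_LYS"    # K at Yaa of G-X-K  -> HyK / glyco eligible
    NONE = "NONE"


@dataclass(frozen=True)
class MotifAnnotation:
    position: int          # 1-based full-length index
    residue: str
    motif_class: MotifClass
    triplet_context: Optional[str] = None  # containing G-X-Y frame, if complete


@dataclass
class CollagenChain:
    """A collagen chain with optional signal-peptide/propeptide intervals."""

    id: str
    sequence: str
    species: str = ""
    signal_peptide: Optional[Interval] = None
    n_propeptide: Optional[Interval] = None
    c_propeptide: Optional[Interval] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"chain {self.id!r}: non-standard residue(s) {sorted(bad)}"
            )
        self._check_intervals()

    def _check_intervals(self) -> None:
        prev_end = 0
        for name, iv in (
            ("signal_peptide", self.signal_peptide),
            ("n_propeptide", self.n_propeptide),
            ("c_propeptide", self.c_propeptide),
        ):
            if iv is None:
                continue
            lo, hi = iv
            if not (1 <= lo <= hi <= len(self.sequence)):
                raise ValueError(f"chain {self.id!r}: {name} interval {iv} out of range")
            if lo <= prev_end:
                raise ValueError(f"chain {self.id!r}: {name} interval {iv} overlaps/out of order")
            prev_end = hi

    def __len__(self) -> int:
        return len(self.sequence)

    # ------------------------------------------------------------------
    # mature-coordinate view
    # ------------------------------------------------------------------
    @property
    def mature_interval(self) -> Interval:
        """Full-length interval of the mature (processed) chain."""
        start = 1
        if self.signal_peptide is not None:
            start = self.signal_peptide[1] + 1
        if self.n_propeptide is not None:
            start = max(start, self.n_propeptide[1] + 1)
        end = len(self.sequence)
        if self.c_propeptide is not None:
            end = self.c_propeptide[0] - 1
        if start > end:
            raise ValueError(f"chain {self.id!r}: empty mature interval")
        return (start, end)

    @property
    def mature_length(self) -> int:
        lo, hi = self.mature_interval
        return hi - lo + 1

    def to_mature(self, position: int) -> int:
        lo, hi = self.mature_interval
        if not (lo <= position <= hi):
            raise ValueError(
                f"chain {self.id!r}: full-length position {position} is not in the "
                f"mature chain ({lo}-{hi})"
            )
        return position - lo + 1

    def to_full(self, position: int) -> int:
        lo, hi = self.mature_interval
        if not (1 <= position <= hi - lo + 1):
            raise ValueError(f"chain {self.id!r}: mature position {position} out of range")
        return position + lo - 1


# ----------------------------------------------------------------------
# FASTA input
# ----------------------------------------------------------------------
def read_fasta(path) -> list[CollagenChain]:
    """Read chains from a FASTA file; ids are the first header token."""
    path = Path(path)
    text = path.read_text()
    stripped = text.strip()
    if not stripped:
        raise ValueError(f"{path}: empty FASTA input")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(f"{path}: malformed FASTA at line {lineno}: expected '>' header")
            break
    chains = []
    for rec in SeqIO.parse(str(path), "fasta"):
        chains.append(CollagenChain(id=rec.id, sequence=str(rec.seq)))
    if not chains:
        raise ValueError(f"{path}: no FASTA records")
    return chains


# ----------------------------------------------------------------------
# motif annotation
# ----------------------------------------------------------------------
def annotate_motifs(chain: CollagenChain) -> list[MotifAnnotation]:
    """Classify every residue by its collagen-triplet role.

    A proline qualifying both as Yaa of one frame and Xaa of the next
    (e.g. the middle of ``GGP``/overlapping frames) is classified YAA_PRO —
    4-HyP is the dominant, near-complete modification — with its Xaa-frame
    recorded in ``triplet_context`` when the Yaa frame is unavailable.
    """
    seq = chain.sequence
    if not seq:
        raise ValueError("empty chain sequence")
    n = len(seq)
    out: list[MotifAnnotation] = []
    for i in range(1, n + 1):  # 1-based
        r = seq[i - 1]
        cls = MotifClass.NONE
        triplet: Optional[str] = None
        if r == "P":
            if i >= 3 and seq[i - 3] == "G":
                cls = MotifClass.YAA_PRO
                triplet = seq[i - 3 : i]
            elif i >= 2 and seq[i - 2] == "G":
                cls = MotifClass.XAA_PRO
                triplet = seq[i - 2 : i + 1] if i + 1 <= n else None
        elif r == "K":
            if i >= 3 and seq[i - 3] == "G":
                cls = MotifClass.GXK_LYS
                triplet = seq[i - 3 : i]
        out.append(MotifAnnotation(i, r, cls, triplet))
    return out


def motif_map(chain: CollagenChain) -> dict[int, MotifClass]:
    """Position -> motif class, for quick lookups during search/cataloging."""
    return {a.position: a.motif_class for a in annotate_motifs(chain)}


def write_annotation_tsv(chain: CollagenChain, path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_id\tposition\tresidue\tmotif_class\ttriplet\n")
        for a in annotate_motifs(chain):
            fh.write(
                f"{chain.id}\t{a.position}\t{a.residue}\t{a.motif_class.value}\t"
                f"{a.triplet_context or '.'}\n"
            )


# ----------------------------------------------------------------------
# pairwise global alignment and propeptide-boundary transfer
# ----------------------------------------------------------------------
@dataclass
class AlignmentResult:
    """Aligned position pairs (1-based, strictly increasing on both sides)."""

    pairs: list[Tuple[int, int]]          # (query_pos, reference_pos)
    matches: list[bool]
    score: float
    params: dict = field(default_factory=dict)

    def query_to_ref(self) -> dict[int, int]:
        return {q: r for q, r in self.pairs}

    def ref_to_query(self) -> dict[int, int]:
        return {r: q for q, r in self.pairs}


def align_global(
    query: str,
    reference: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal global alignment (affine gaps); deterministic first-optimal path."""
    if not query or not reference:
        raise ValueError("cannot align empty sequence")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(query, reference)[0]
    pairs: list[Tuple[int, int]] = []
    matches: list[bool] = []
    qblocks, rblocks = aln.aligned
    for (qs, qe), (rs, re) in zip(qblocks, rblocks):
        for k in range(qe - qs):
            q, r = qs + k + 1, rs + k + 1
            pairs.append((q, r))
            matches.append(query[q - 1] == reference[r - 1])
    return AlignmentResult(
        pairs=pairs,
        matches=matches,
        score=float(aln.score),
        params={"matrix": matrix, "gap_open": gap_open, "gap_extend": gap_extend},
    )


def map_position(alignment: AlignmentResult, ref_position: int) -> Optional[int]:
    """Query position aligned to a reference position, or None if in a gap."""
    return alignment.ref_to_query().get(ref_position)


def _map_boundary(alignment: AlignmentResult, ref_position: int, snap: int) -> int:
    r2q = alignment.ref_to_query()
    if ref_position in r2q:
        return r2q[ref_position]
    for d in range(1, snap + 1):
        for cand in (ref_position - d, ref_position + d):
            if cand in r2q:
                return r2q[cand] + (ref_position - cand)
    raise ValueError(
        f"reference boundary {ref_position} unmappable within ±{snap} aligned residues"
    )


def transfer_cleavage_sites(
    chain: CollagenChain,
    reference: CollagenChain,
    alignment: Optional[AlignmentResult] = None,
    snap: int = 3,
) -> CollagenChain:
    """Set signal/propeptide intervals on ``chain`` by mapping the reference's
    annotated boundaries through a global alignment.

    Boundaries falling opposite an alignment gap snap to the nearest aligned
    reference residue within ``snap`` positions (offset preserved); beyond that
    the transfer fails naming the boundary.
    """
    if alignment is None:
        alignment = align_global(chain.sequence, reference.sequence)
    new = replace(chain)
    for name in ("signal_peptide", "n_propeptide", "c_propeptide"):
        iv = getattr(reference, name)
        if iv is None:
            continue
        lo = _map_boundary(alignment, iv[0], snap)
        hi = _map_boundary(alignment, iv[1], snap)
        lo = max(1, lo)
        hi = min(len(chain.sequence), hi)
        setattr(new, name, (lo, hi))
    new._check_intervals()
    return new
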