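"""Site-level PTM catalogs from filtered PSMs.

The positional hydroxyproline rule: a hydroxylated proline at the Yaa
position of a Gly-Xaa-Yaa triplet is 4-HyP; one at the Xaa position of a
G-Xaa-HyP motif — i.e. the Yaa residue of the same frame is a proline seen
hydroxylated on the same peptidoform — is 3-HyP; a hydroxylated Xaa proline
whose Yaa partner is not a hydroxylated proline cannot be assigned to either
chemistry and is reported ambiguous.  Lysine sites require the G-X-K motif
context (checked on the full chain, not the peptide).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd

from .chain_model import CollagenChain, MotifClass, motif_map
from .motif_search import PSM
from .mass_digest import ModifiedPeptide


class SiteClass(enum.Enum):
    HYP3 = "HYP3"
    HYP4 = "HYP4"
    HYP_AMBIGUOUS = "HYP_AMBIGUOUS"
    LYS_SITE = "LYS_SITE"


# modification-state vocabulary used throughout quantitation and cataloging
STATES = ("unmod", "HyP", "HyK", "G-HyK", "GG-HyK")
K_MOD_STATES = ("HyK", "G-HyK", "GG-HyK")


@dataclass
class PTMSite:
    chain_id: str
    position: int                       # full-length coordinate
    residue: str
    classification: SiteClass
    psm_support: dict = field(default_factory=dict)  # state -> PSM count

    @property
    def states_observed(self) -> set:
        return {s for s, n in self.psm_support.items() if n >= 1}


@dataclass
class SiteCatalog:
    sites: dict = field(default_factory=dict)     # (chain_id, position) -> PTMSite
    coverage: dict = field(default_factory=dict)  # chain_id -> percent

    def __iter__(self):
        return iter(self.sites.values())

    def __len__(self):
        return len(self.sites)

    def get(self, chain_id: str, position: int) -> Optional[PTMSite]:
        return self.sites.get((chain_id, position))

    def merge(self, other: "SiteCatalog") -> "SiteCatalog":
        """Union of two catalogs; support counts add, HYP3 beats ambiguous."""
        out = SiteCatalog(dict(self.sites), dict(self.coverage))
        for key, site in other.sites.items():
            if key not in out.sites:
                out.sites[key] = PTMSite(site.chain_id, site.position, site.residue,
                                         site.classification, dict(site.psm_support))
                continue
            mine = out.sites[key]
            for state, n in site.psm_support.items():
                mine.psm_support[state] = mine.psm_support.get(state, 0) + n
            if site.classification == SiteClass.HYP3:
                mine.classification = SiteClass.HYP3
        out.coverage.update(other.coverage)
        return out


def _observation_class(
    pf: ModifiedPeptide, position: int, motif: MotifClass, chain: CollagenChain
) -> SiteClass:
    """Classification of one hydroxylated-P observation on one peptidoform."""
    if motif == MotifClass.YAA_PRO:
        return SiteClass.HYP4
    # Xaa proline: inspect the Yaa residue of the same frame
    yaa_pos = position + 1
    if yaa_pos <= len(chain.sequence) and chain.sequence[yaa_pos - 1] == "P":
        yaa_mod = pf.mod_at(yaa_pos) if pf.start <= yaa_pos <= pf.end else None
        if yaa_mod is not None and yaa_mod.name == "HyP":
            return SiteClass.HYP3
    return SiteClass.HYP_AMBIGUOUS


def assign_sites(
    psms: Sequence[PSM],
    chains: dict[str, CollagenChain] | Sequence[CollagenChain],
    strict_hyp3: bool = True,
    min_psms: int = 1,
) -> SiteCatalog:
    """Collapse FDR-filtered target PSMs into a site catalog.

    ``strict_hyp3=True`` (default) requires the Yaa hydroxylation on the same
    peptidoform for a 3-HyP call; with ``False`` a Yaa-P hydroxylation seen at
    that position in *any* peptidoform suffices.
    """
    if not isinstance(chains, dict):
        chains = {c.id: c for c in chains}
    motif_cache: dict[str, dict[int, MotifClass]] = {}
    sites: dict[Tuple[str, int], PTMSite] = {}
    # positions where Yaa-P hydroxylation was observed (for relaxed mode)
    yaa_hyp_positions: set[Tuple[str, int]] = set()

    def _motifs(chain_id: str) -> dict[int, MotifClass]:
        if chain_id not in motif_cache:
            motif_cache[chain_id] = motif_map(chains[chain_id])
        return motif_cache[chain_id]

    for psm in psms:
        if psm.is_decoy:
            continue
        pf = psm.peptidoform
        if pf.chain_id not in chains:
            raise KeyError(f"PSM references unknown chain {pf.chain_id!r}")
        chain = chains[pf.chain_id]
        motifs = _motifs(pf.chain_id)
        for i, residue in enumerate(pf.sequence):
            pos = pf.start + i
            motif = motifs.get(pos, MotifClass.NONE)
            mod = pf.mod_at(pos)
            state = mod.name if mod is not None and mod.mode == "dynamic" else "unmod"
            if residue == "P":
                if state != "HyP":
                    continue
                obs = _observation_class(pf, pos, motif, chain)
                key = (pf.chain_id, pos)
                if key not in sites:
                    sites[key] = PTMSite(pf.chain_id, pos, "P", obs)
                site = sites[key]
                site.psm_support["HyP"] = site.psm_support.get("HyP", 0) + 1
                if obs == SiteClass.HYP3:
                    site.classification = SiteClass.HYP3
                if motif == MotifClass.YAA_PRO:
                    yaa_hyp_positions.add(key)
            elif residue == "K" and motif == MotifClass.GXK_LYS:
                if state not in K_MOD_STATES:
                    continue
                key = (pf.chain_id, pos)
                if key not in sites:
                    sites[key] = PTMSite(pf.chain_id, pos, "K", SiteClass.LYS_SITE)
                site = sites[key]
                site.psm_support[state] = site.psm_support.get(state, 0) + 1

    if not strict_hyp3:
        for key, site in sites.items():
            if site.classification == SiteClass.HYP_AMBIGUOUS:
                yaa_key = (key[0], key[1] + 1)
                chain = chains[key[0]]
                if (
                    key[1] + 1 <= len(chain.sequence)
                    and chain.sequence[key[1]] == "P"
                    and yaa_key in yaa_hyp_positions
                ):
                    site.classification = SiteClass.HYP3

    # enforce minimum modified-PSM support
    kept = {}
    for key, site in sites.items():
        mod_support = sum(n for s, n in site.psm_support.items() if s != "unmod")
        if mod_support >= min_psms:
            kept[key] = site

    catalog = SiteCatalog(sites=kept)
    for chain_id, chain in chains.items():
        try:
            chain.mature_interval
        except ValueError:
            continue
        if chain.signal_peptide or chain.n_propeptide or chain.c_propeptide:
            catalog.coverage[chain_id] = sequence_coverage(psms, chain)
    return catalog


def sequence_coverage(psms: Sequence[PSM], chain: CollagenChain) -> float:
    """Percent of the mature chain covered by >=1 identified target peptide."""
    lo, hi = chain.mature_interval  # raises if the mature interval is unset/empty
    covered: set[int] = set()
    for psm in psms:
        if psm.is_decoy or psm.peptidoform.chain_id != chain.id:
            continue
        covered.update(
            range(max(lo, psm.peptidoform.start), min(hi, psm.peptidoform.end) + 1)
        )
    return 100.0 * len(covered) / (hi - lo + 1)


def tabulate(catalog: SiteCatalog) -> pd.DataFrame:
    """Per-chain counts of 3-HyP, HyK, G-HyK and GG-HyK sites plus totals.

    A lysine site contributes to each glyco column whose state it was observed
    in, so a microheterogeneous site appears in several columns.
    """
    rows: dict[str, dict[str, int]] = {}
    for site in catalog:
        row = rows.setdefault(
            site.chain_id, {"3-HyP": 0, "HyK": 0, "G-HyK": 0, "GG-HyK": 0}
        )
        if site.classification == SiteClass.HYP3:
            row["3-HyP"] += 1
        elif site.classification == SiteClass.LYS_SITE:
            for state in K_MOD_STATES:
                if state in site.states_observed:
                    row[state] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if df.empty:
        df = pd.DataFrame(columns=["3-HyP", "HyK", "G-HyK", "GG-HyK"])
    df.loc["TOTAL"] = df.sum()
    df.index.name = "chain"
    return df.astype(int)


def conserved_sites(
    catalog_a: SiteCatalog,
    catalog_b: SiteCatalog,
    alignment,
    classification: SiteClass = SiteClass.HYP3,
) -> Tuple[list[Tuple[int, int]], list[int], list[int]]:
    """Match same-classification sites across two single-chain catalogs.

    A pair is conserved iff the positions are aligned (no gap) and both carry
    ``classification``.  Returns (conserved pairs, a-only positions, b-only
    positions), all in each chain's own full-length coordinates.
    """
    if alignment is None:
        raise ValueError("alignment between the two chains is required")
    a_positions = sorted(
        s.position for s in catalog_a if s.classification == classification
    )
    b_positions = {
        s.position for s in catalog_b if s.classification == classification
    }
    q2r = alignment.query_to_ref()
    pairs: list[Tuple[int, int]] = []
    only_a: list[int] = []
    matched_b: set[int] = set()
    for pos in a_positions:
        partner = q2r.get(pos)
        if partner is not None and partner in b_positions:
            pairs.append((pos, partner))
            matched_b.add(partner)
        else:
            only_a.append(pos)
    only_b = sorted(b_positions - matched_b)
    return pairs, only_a, only_b


def write_catalog_tsv(catalog: SiteCatalog, chains: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_id\tposition_full\tposition_mature\tresidue\tclassification"
                 "\tstates\tpsm_counts\n")
        for (chain_id, pos), site in sorted(catalog.sites.items()):
            mature = "."
            chain = chains.get(chain_id)
            if chain is not None:
                try:
                    mature = str(chain.to_mature(pos))
                except ValueError:
                    mature = "."
            states = ",".join(sorted(site.states_observed))
            counts = ",".join(f"{s}:{n}" for s, n in sorted(site.psm_support.items()))
            fh.write(f"{chain_id}\t{pos}\t{mature}\t{site.residue}\t"
                     f"{site.classification.value}\t{states}\t{counts}\n")
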