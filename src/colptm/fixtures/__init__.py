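"""Packaged transcriptions of the published zebrafish heart ECM site catalogs.

These fixtures carry the printed site lists and occupancy tables so that the
tally, conservation and self-consistency logic can be exercised without the
deposited raw mass-spectrometry data.  Loaders return pandas DataFrames in
the package's own schemas.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..chain_model import AlignmentResult
from ..site_catalog import PTMSite, SiteCatalog, SiteClass

CONDITIONS = ("sham", "7DPA", "14DPA", "30DPA")
_COND_PREFIX = {"sham": "sham", "7DPA": "dpa7", "14DPA": "dpa14", "30DPA": "dpa30"}


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_table1() -> pd.DataFrame:
    """Printed site catalog: columns chain, category, position (NA-free rows
    only carry real sites; chains listed with no sites have category 'none')."""
    return _read("table1_sites.tsv")


def tabulate_table1() -> pd.DataFrame:
    """Per-chain printed-entry counts by category, plus a TOTAL row."""
    df = load_table1()
    chains = df["chain"].unique()
    cats = ["3-HyP", "HyK", "G-HyK", "GG-HyK"]
    counts = (
        df[df["category"].isin(cats)]
        .groupby(["chain", "category"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=chains, columns=cats, fill_value=0)
    )
    counts.loc["TOTAL"] = counts.sum()
    counts.index.name = "chain"
    return counts.astype(int)


def load_conservation() -> pd.DataFrame:
    """COL1A1a 3-HyP positions with conservation status (conserved | novel)."""
    return _read("col1a1a_3hyp_conservation.tsv")


def conservation_catalogs() -> tuple[SiteCatalog, SiteCatalog, AlignmentResult]:
    """Zebrafish COL1A1a 3-HyP catalog, the human+mouse reference catalog
    (conserved positions, expressed in aligned zebrafish coordinates), and the
    corresponding position-identity alignment — inputs for the conserved-site
    set logic."""
    df = load_conservation()
    zf = SiteCatalog()
    ref = SiteCatalog()
    for _, row in df.iterrows():
        pos = int(row["position"])
        zf.sites[("COL1A1a", pos)] = PTMSite("COL1A1a", pos, "P", SiteClass.HYP3,
                                             {"HyP": 1})
        if row["status"] == "conserved":
            ref.sites[("COL1A1_ref", pos)] = PTMSite("COL1A1_ref", pos, "P",
                                                     SiteClass.HYP3, {"HyP": 1})
    n = max(p for _, p in zf.sites) + 1
    aln = AlignmentResult(pairs=[(i, i) for i in range(1, n + 1)],
                          matches=[True] * n, score=float(n))
    return zf, ref, aln


def load_table2() -> pd.DataFrame:
    """3-HyP occupancy table (mean/SD per condition); long per-condition view
    via :func:`occupancy_long`."""
    return _read("table2_3hyp_occupancy.tsv")


def load_table3() -> pd.DataFrame:
    """Lysine microheterogeneity table (mean/SEM per state and condition)."""
    return _read("table3_lysine_microheterogeneity.tsv")


def occupancy_long(df: pd.DataFrame) -> pd.DataFrame:
    """Wide fixture table -> long (one row per condition) with mean/spread."""
    ids = [c for c in df.columns if not any(c.startswith(p) for p in
                                            ("sham_", "dpa7_", "dpa14_", "dpa30_"))]
    rows = []
    for _, row in df.iterrows():
        for cond in CONDITIONS:
            p = _COND_PREFIX[cond]
            rows.append(
                {**{c: row[c] for c in ids}, "condition": cond,
                 "mean": row[f"{p}_mean"], "spread": row[f"{p}_sd" if f"{p}_sd" in df.columns else f"{p}_sem"]}
            )
    return pd.DataFrame(rows)


def table3_state_sums() -> pd.DataFrame:
    """Sum of detected-state mean percentages per (site, condition).

    The printed microheterogeneity rows partition each site's MS1 signal, so
    each detected-state quadruple should sum to 100 (within rounding)."""
    long = occupancy_long(load_table3())
    long = long.dropna(subset=["mean"])
    return (
        long.groupby(["chain", "site", "condition"])["mean"].sum().reset_index(name="total")
    )
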