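"""Abundance and occupancy quantitation.

Two quantitation layers mirror the study design:

* protein-level relative abundance from spectral counts, normalized to the
  mean per-file total so values stay on a count-like scale (a >=3 normalized
  count threshold then remains meaningful), with row-standardized heatmap
  scaling clipped to [-2, +2];

* site-level MS1-area occupancy: for a site in one replicate, the percent of
  summed extracted MS1 area carried by each modification state.  Lysine
  microheterogeneity is the occupancy vector over {K, HyK, G-HyK, GG-HyK}.
  Percentages sum to 100 per (site, condition, replicate); a replicate with
  no signal is reported not-detected (ND), never silently zero.

One-way ANOVA across the four conditions flags sites whose occupancy changes
during regeneration (p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("sham", "7DPA", "14DPA", "30DPA")

# MS1 feature-table schema: one row per (peptidoform, sample)
FEATURE_COLUMNS = [
    "peptidoform", "chain", "pep_start", "pep_end", "states",
    "condition", "replicate", "area",
]


# ----------------------------------------------------------------------
# spectral-count abundance
# ----------------------------------------------------------------------
def normalize_spectral_counts(raw: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to the global mean file depth.

    value = raw * (mean of per-file totals / file total); this keeps values
    on the raw-count scale while removing per-file depth differences.
    """
    totals = raw.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total file(s): {', '.join(map(str, zero.index))}")
    return raw * (totals.mean() / totals)


def heatmap_eligible(matrix: pd.DataFrame, min_counts: float = 3.0) -> pd.DataFrame:
    """Rows identified with >= min_counts normalized counts in some sample."""
    return matrix[matrix.max(axis=1) >= min_counts]


def fold_change(
    matrix: pd.DataFrame,
    condition_cols: Sequence[str],
    baseline_cols: Sequence[str],
) -> pd.DataFrame:
    """Per-row ratio of condition mean to baseline mean, with percent change.

    percent_change = (1 - ratio) * 100 for a decrease (ratio < 1), negative
    for an increase.  Rows with zero baseline are reported missing.
    """
    base = matrix[list(baseline_cols)].mean(axis=1)
    cond = matrix[list(condition_cols)].mean(axis=1)
    ratio = cond / base.where(base > 0)
    return pd.DataFrame({"ratio": ratio, "percent_change": (1.0 - ratio) * 100.0})


def heatmap_matrix(matrix: pd.DataFrame, clip: float = 2.0) -> pd.DataFrame:
    """Per-row z-scores clipped to [-clip, +clip]; constant rows map to 0."""
    if matrix.shape[1] < 2:
        raise ValueError("heatmap scaling needs >= 2 columns")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    z = matrix.sub(mean, axis=0).div(sd.where(sd > 0), axis=0).fillna(0.0)
    return z.clip(-clip, clip)


# ----------------------------------------------------------------------
# MS1 occupancy / microheterogeneity
# ----------------------------------------------------------------------
@dataclass
class OccupancyRecord:
    chain: str
    site: str                      # position, or 'p1+p2' for a cluster
    condition: str
    state: str
    mean: Optional[float]          # percent; None = ND in every replicate
    sd: Optional[float]
    sem: Optional[float]
    per_replicate: dict            # replicate -> percent (or None if ND)


def _parse_states(states: str) -> dict[int, str]:
    """'K1017:GG-HyK;P869:HyP' -> {1017: 'GG-HyK', 869: 'HyP'}."""
    out: dict[int, str] = {}
    if not states or states in (".", "nan"):
        return out
    for token in str(states).split(";"):
        token = token.strip()
        if not token:
            continue
        left, state = token.split(":")
        out[int(left[1:])] = state
    return out


def _site_state(row_states: str, position: int) -> str:
    return _parse_states(row_states).get(position, "unmod")


def site_occupancy(
    features: pd.DataFrame,
    chain: str,
    position: int,
    states: Sequence[str] = ("unmod", "HyP", "HyK", "G-HyK", "GG-HyK"),
    conditions: Sequence[str] = CONDITIONS,
) -> list[OccupancyRecord]:
    """Per-state percent of MS1 area at one site, per condition.

    Peptidoforms whose state at the site is ambiguous (state token
    'ambiguous', e.g. an unlocalized glycan) are excluded.  Replicates whose
    total area at the site is zero are ND; the mean/SD/SEM aggregate the
    detected replicates only.
    """
    sel = features[
        (features["chain"] == chain)
        & (features["pep_start"] <= position)
        & (features["pep_end"] >= position)
    ]
    out: list[OccupancyRecord] = []
    for cond in conditions:
        cond_rows = sel[sel["condition"] == cond]
        per_state_reps: dict[str, dict] = {s: {} for s in states}
        for rep, rep_rows in cond_rows.groupby("replicate"):
            sums = {s: 0.0 for s in states}
            total = 0.0
            for _, row in rep_rows.iterrows():
                st = _site_state(row["states"], position)
                if st == "ambiguous":
                    continue
                if st not in sums:
                    continue
                sums[st] += row["area"]
                total += row["area"]
            for s in states:
                per_state_reps[s][rep] = (
                    100.0 * sums[s] / total if total > 0 else None
                )
        for s in states:
            reps = per_state_reps[s]
            vals = [v for v in reps.values() if v is not None]
            out.append(
                OccupancyRecord(
                    chain=chain,
                    site=str(position),
                    condition=cond,
                    state=s,
                    mean=float(np.mean(vals)) if vals else None,
                    sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else (0.0 if vals else None),
                    sem=float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else (0.0 if vals else None),
                    per_replicate=reps,
                )
            )
    return out


def cluster_occupancy(
    features: pd.DataFrame,
    chain: str,
    positions: Sequence[int],
    conditions: Sequence[str] = CONDITIONS,
) -> list[OccupancyRecord]:
    """Joint occupancy of a site cluster: a peptidoform counts as modified if
    *any* cluster position carries a hydroxylation; the two states are
    'mod' (any hydroxylation in the cluster) and 'unmod'."""
    positions = list(positions)
    sel = features[
        (features["chain"] == chain)
        & (features["pep_start"] <= min(positions))
        & (features["pep_end"] >= max(positions))
    ]
    site_label = "+".join(str(p) for p in positions)
    out: list[OccupancyRecord] = []
    for cond in conditions:
        cond_rows = sel[sel["condition"] == cond]
        per_state_reps: dict[str, dict] = {"mod": {}, "unmod": {}}
        for rep, rep_rows in cond_rows.groupby("replicate"):
            sums = {"mod": 0.0, "unmod": 0.0}
            total = 0.0
            for _, row in rep_rows.iterrows():
                smap = _parse_states(row["states"])
                if any(smap.get(p) == "ambiguous" for p in positions):
                    continue
                any_mod = any(smap.get(p, "unmod") != "unmod" for p in positions)
                key = "mod" if any_mod else "unmod"
                sums[key] += row["area"]
                total += row["area"]
            for s in ("mod", "unmod"):
                per_state_reps[s][rep] = 100.0 * sums[s] / total if total > 0 else None
        for s in ("mod", "unmod"):
            reps = per_state_reps[s]
            vals = [v for v in reps.values() if v is not None]
            out.append(
                OccupancyRecord(
                    chain=chain, site=site_label, condition=cond, state=s,
                    mean=float(np.mean(vals)) if vals else None,
                    sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else (0.0 if vals else None),
                    sem=float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else (0.0 if vals else None),
                    per_replicate=reps,
                )
            )
    return out


# ----------------------------------------------------------------------
# statistics
# ----------------------------------------------------------------------
@dataclass
class AnovaResult:
    F: Optional[float]
    p: Optional[float]
    significant: Optional[bool]    # None = untestable (insufficient replication)
    note: str = ""


def anova_oneway(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA across condition groups of replicate percents.

    Degenerate inputs follow the reporting conventions of the occupancy
    tables: all-identical values give p = 1 (no evidence of change), and
    insufficient replication is flagged untestable rather than tested.
    """
    groups = [list(g) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        return AnovaResult(None, None, None, "insufficient replication")
    flat = [v for g in groups for v in g]
    if np.allclose(flat, flat[0]):
        return AnovaResult(0.0, 1.0, False, "zero variance")
    F, p = stats.f_oneway(*groups)
    if not np.isfinite(F):
        return AnovaResult(None, 1.0, False, "within-group variance is zero")
    return AnovaResult(float(F), float(p), bool(p < alpha))


def occupancy_table(
    records: Iterable[OccupancyRecord], spread: str = "sem", alpha: float = 0.05
) -> pd.DataFrame:
    """Wide per-state table with per-condition mean +/- spread and ANOVA p."""
    rows = []
    recs = list(records)
    keys = sorted({(r.chain, r.site, r.state) for r in recs},
                  key=lambda k: (k[0], k[1], k[2]))
    for chain, site, state in keys:
        row: dict = {"chain": chain, "site": site, "state": state}
        groups = []
        for cond in CONDITIONS:
            match = [r for r in recs
                     if (r.chain, r.site, r.state, r.condition) == (chain, site, state, cond)]
            if not match or match[0].mean is None:
                row[f"{cond}_mean"] = np.nan
                row[f"{cond}_{spread}"] = np.nan
            else:
                r = match[0]
                row[f"{cond}_mean"] = r.mean
                row[f"{cond}_{spread}"] = getattr(r, spread)
                groups.append([v for v in r.per_replicate.values() if v is not None])
        res = anova_oneway(groups, alpha) if len(groups) == len(CONDITIONS) else \
            AnovaResult(None, None, None, "ND in some condition")
        row["anova_p"] = res.p if res.p is not None else np.nan
        row["significant"] = {True: "*", False: "ns", None: "NA"}[res.significant]
        rows.append(row)
    return pd.DataFrame(rows)
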