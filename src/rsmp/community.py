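"""Univariate community indices, SIMPER characterising taxa and per-group
summary tables for the faunal cluster baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def compute_indices(abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-sample taxon richness and total abundance, with dataset-wide ranks.

    Richness counts families with abundance > 0; total abundance sums counts
    (colonial presences contribute 1 each). Ranks are ascending (1 = lowest)
    with average ranks on ties, so relative "heat" maps can be drawn from
    rank values directly.
    """
    X = abundance.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative abundances")
    richness = (X > 0).sum(axis=1)
    total = X.sum(axis=1)
    return pd.DataFrame(
        {
            "richness": richness,
            "abundance": total,
            "rank_richness": rankdata(richness, method="average"),
            "rank_abundance": rankdata(total, method="average"),
        },
        index=abundance.index,
    )


@dataclass
class SimperEntry:
    taxon: str
    mean_contribution_pct: float
    cumulative_pct: float


def _within_group_simper(Y: np.ndarray) -> np.ndarray:
    """Per-taxon mean contribution to within-group Bray-Curtis similarity.

    For samples i, j the Bray-Curtis similarity decomposes exactly over taxa:
    S_ij = sum_t 200 * min(y_it, y_jt) / sum_u (y_iu + y_ju). The per-taxon
    terms are averaged over all within-group pairs (Clarke's decomposition).
    Returns the vector of mean per-taxon contributions (summing to the mean
    within-group similarity).
    """
    n, p = Y.shape
    contrib = np.zeros(p)
    n_pairs = 0
    for i in range(n - 1):
        yi = Y[i]
        mins = np.minimum(yi, Y[i + 1 :])  # (n-i-1, p)
        denom = (yi.sum() + Y[i + 1 :].sum(axis=1))[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(denom > 0, 200.0 * mins / denom, 0.0)
        contrib += terms.sum(axis=0)
        n_pairs += terms.shape[0]
    return contrib / n_pairs


def simper(
    transformed: pd.DataFrame,
    labels,
    cutoff_pct: float = 50.0,
) -> dict[object, list[SimperEntry]]:
    """Characterising taxa per group from within-group similarity decomposition.

    ``transformed`` is the (fourth-root) matrix used for clustering; ``labels``
    gives each sample's group. For each group with >= 2 samples, taxa are
    ranked by their mean contribution to the average within-group Bray-Curtis
    similarity (expressed as % of that average; ties broken alphabetically)
    and the returned list is the smallest prefix reaching ``cutoff_pct``
    cumulative contribution. With ``cutoff_pct=100`` the full decomposition is
    returned and cumulates to 100 exactly.
    """
    labels = pd.Series(np.asarray(labels), index=transformed.index)
    out: dict[object, list[SimperEntry]] = {}
    for g, idx in labels.groupby(labels).groups.items():
        Y = transformed.loc[idx].to_numpy(dtype=float)
        if len(Y) < 2:
            warnings.warn(f"SIMPER: group {g!r} has <2 samples; skipped")
            continue
        contrib = _within_group_simper(Y)
        total = contrib.sum()
        if total <= 0:
            warnings.warn(f"SIMPER: group {g!r} has zero mean similarity; skipped")
            continue
        pct = 100.0 * contrib / total
        order = sorted(
            range(len(pct)), key=lambda j: (-pct[j], str(transformed.columns[j]))
        )
        entries: list[SimperEntry] = []
        cum = 0.0
        for j in order:
            cum += pct[j]
            entries.append(SimperEntry(str(transformed.columns[j]), float(pct[j]), float(cum)))
            if cum >= cutoff_pct - 1e-12:
                break
        out[g] = entries
    return out


#: Tertile arrows: relative size of a group's mean within the range of all
#: group means — top third up, middle third right, bottom third down.
ARROWS = {"high": "↑", "mid": "→", "low": "↓"}


def _tertile_arrows(means: pd.Series) -> pd.Series:
    lo, hi = float(means.min()), float(means.max())
    if hi - lo <= 0:  # degenerate range: a single group (or identical means)
        return pd.Series(ARROWS["high"], index=means.index)
    third = (hi - lo) / 3.0
    def arrow(m):
        if m >= hi - third:
            return ARROWS["high"]
        if m >= lo + third:
            return ARROWS["mid"]
        return ARROWS["low"]
    return means.map(arrow)


def summarise_groups(indices: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-group summary of richness and abundance with tertile arrows.

    Tertiles split the full *range of group means* (not sample quantiles) into
    three equal-width bands per measure.
    """
    labels = pd.Series(np.asarray(labels), index=indices.index, name="group")
    rows = []
    for g, sub in indices.groupby(labels):
        rec = {"group": g, "n": len(sub)}
        for m in ("richness", "abundance"):
            rec[f"{m}_max"] = float(sub[m].max())
            rec[f"{m}_min"] = float(sub[m].min())
            rec[f"{m}_mean"] = float(sub[m].mean())
            rec[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("group")
    for m in ("richness", "abundance"):
        out[f"{m}_arrow"] = _tertile_arrows(out[f"{m}_mean"])
    return out


def facet_by_time(indices: pd.DataFrame, dates: pd.Series, year_bins=None) -> dict:
    """Partition sample indices by (year group, season) for temporal plots.

    A pure partition: the facet frames concatenate back to the input. Seasons
    are meteorological quarters; ``year_bins`` is an increasing sequence of
    bin edges (defaults to 5-year bins spanning the data).
    """
    dates = pd.to_datetime(dates.loc[indices.index])
    years = dates.dt.year
    if year_bins is None:
        lo = int(years.min()) // 5 * 5
        hi = int(years.max()) + 1
        year_bins = list(range(lo, hi + 5, 5))
    ygroup = pd.cut(years, bins=year_bins, right=False)
    season = dates.dt.month.map(
        lambda m: {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
                   6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}[m]
    )
    out = {}
    for key, idx in indices.groupby([ygroup, season], observed=True).groups.items():
        out[key] = indices.loc[idx]
    return out
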