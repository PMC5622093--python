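"""Exclusion filters producing the faunal and sediment analysis subsets, and
impact flagging from dredging-exposure records.

Both filters apply their rules in a fixed order with first-match attribution,
so every removed sample is counted against exactly one rule and the per-rule
counts plus the retained count always reconstruct the input size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rsmp.datamodel import GRABS_01, SampleTable

log = logging.getLogger(__name__)

#: Default non-macrofaunal taxon groups removed from the abundance matrix.
#: Keys are matched against column names case-insensitively as substrings so
#: that e.g. "Fish_Gobiidae" is caught by "fish".
DEFAULT_TAXON_EXCLUSIONS = ("fish", "diatom", "parasite", "zooplankton", "seed", "egg")


@dataclass
class FilterReport:
    """Per-rule removal counts for one filter pass."""

    name: str
    input_rows: int
    removed: dict[str, int] = field(default_factory=dict)
    removed_taxa: list[str] = field(default_factory=list)

    @property
    def retained(self) -> int:
        return self.input_rows - sum(self.removed.values())

    def as_dict(self) -> dict:
        return {
            "filter": self.name,
            "input_rows": self.input_rows,
            "removed": dict(self.removed),
            "removed_taxa": list(self.removed_taxa),
            "retained": self.retained,
        }


def _apply_rules(table: SampleTable, rules) -> tuple[pd.Index, dict[str, int]]:
    """First-match attribution: a sample is charged to the first rule it fails."""
    keep = pd.Series(True, index=table.sample_ids)
    counts: dict[str, int] = {}
    for rule_name, passes in rules:
        failing = keep & ~passes
        counts[rule_name] = int(failing.sum())
        keep &= passes
    return keep[keep].index, counts


def filter_faunal_subset(
    table: SampleTable,
    taxon_exclusions=DEFAULT_TAXON_EXCLUSIONS,
) -> tuple[SampleTable, FilterReport]:
    """Comparable-gear faunal subset: 0.1 m^2 grabs sieved over 1 mm mesh.

    Also drops non-macrofaunal taxon columns (fish, diatoms, parasites,
    zooplankton, seeds, eggs by default). Samples with and without colonial
    taxa are both retained, to maximise spatial coverage.
    """
    f = table.factors
    rules = [
        ("gear_not_0.1m2_grab", f["gear"].isin(GRABS_01)),
        ("sieve_not_1mm", f["sieve_mm"] == 1.0),
    ]
    kept, counts = _apply_rules(table, rules)
    patterns = tuple(p.lower() for p in taxon_exclusions)
    drop_cols = [
        c for c in table.abundance.columns
        if any(p in str(c).lower() for p in patterns)
    ]
    out = table.subset(kept)
    out.abundance = out.abundance.drop(columns=drop_cols)
    report = FilterReport("faunal_subset", len(table), counts, sorted(drop_cols))
    for rule, n in counts.items():
        log.info("faunal filter: %s removed %d", rule, n)
    return out, report


def filter_sediment_subset(
    table: SampleTable, total_tolerance: float = 1.0
) -> tuple[SampleTable, FilterReport]:
    """Sediment analysis subset, applying all exclusion rules in fixed order:

    Hamon 0.1 m^2 gear -> 1 mm sieve -> sediment data present -> sediment from
    the same grab deployment as the fauna -> total percentage within
    100 +/- ``total_tolerance`` -> top sieve empty -> not flagged impacted ->
    colonial taxa recorded.

    "Top sieve empty" means no mass on the largest aperture used in that
    sample's PSD — otherwise coarser material might have been retained had a
    larger sieve been available, making the distribution unreliable.
    """
    f = table.factors
    has_psd = table.has_psd()

    totals = pd.Series(np.nan, index=table.sample_ids)
    top_empty = pd.Series(False, index=table.sample_ids)
    if table.psd is not None and len(table.psd):
        g = table.psd.groupby("sample_id")
        totals.update(g["percent"].sum())
        top_mass = table.psd.loc[
            table.psd.groupby("sample_id")["aperture_mm"].idxmax()
        ].set_index("sample_id")["percent"]
        top_empty.update(top_mass == 0.0)

    same_dep = f.get("same_deployment", pd.Series(True, index=f.index)).fillna(False)
    colonials = f.get("colonials_recorded", pd.Series(True, index=f.index)).fillna(False)

    rules = [
        ("gear_not_hamon_0.1", f["gear"] == "Hamon_0.1"),
        ("sieve_not_1mm", f["sieve_mm"] == 1.0),
        ("no_sediment_data", has_psd),
        ("different_deployment", same_dep.astype(bool)),
        (
            "total_out_of_tolerance",
            totals.between(100.0 - total_tolerance, 100.0 + total_tolerance),
        ),
        ("top_sieve_not_empty", top_empty),
        ("impacted_site", f["treatment"] != "impacted"),
        ("colonials_not_recorded", colonials.astype(bool)),
    ]
    kept, counts = _apply_rules(table, rules)
    report = FilterReport("sediment_subset", len(table), counts)
    for rule, n in counts.items():
        log.info("sediment filter: %s removed %d", rule, n)
    return table.subset(kept), report


def flag_impacted(exposures: pd.DataFrame) -> pd.Series:
    """Treatment flags from dredging exposure records.

    ``exposures`` columns: ``sample_id``, ``years_since_last_dredging`` (NaN
    when never dredged), ``landscape_recovery_years``. A station is impacted
    when it has been dredged and the elapsed time is less than the predicted
    recovery time of its seabed landscape; never-dredged stations are
    reference.
    """
    years = exposures["years_since_last_dredging"]
    recovery = exposures["landscape_recovery_years"]
    if (years.dropna() < 0).any() or (recovery.dropna() < 0).any():
        raise ValueError("negative years in exposure table")
    impacted = years.notna() & (years < recovery)
    out = pd.Series(
        np.where(impacted, "impacted", "reference"),
        index=pd.Index(exposures["sample_id"], name="sample_id"),
        name="treatment",
    )
    return out
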