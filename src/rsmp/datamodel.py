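"""Core tabular containers for grab-sample datasets.

A :class:`SampleTable` bundles, keyed by ``sample_id``:

* ``factors`` — per-sample metadata (survey, gear, sieve, coordinates, date,
  depth, treatment flag, whether colonial taxa were recorded, whether the
  sediment sub-sample came from the same grab deployment as the fauna);
* ``abundance`` — the wide sample x family count matrix (colonial families are
  presence-coded 0/1);
* ``psd`` — long-format particle-size data (sample_id, aperture_mm, percent),
  optional per sample;
* ``env`` — per-sample environmental variables, optional per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rsmp.sieves import (
    DEFAULT_MAPPING,
    STANDARD_APERTURES_MM,
    WENTWORTH_FRACTIONS,
    SieveMapping,
    collapse_to_standard_sieves,
    psd_from_long,
    to_wentworth,
)

#: Recognised sampling devices. 0.1 m^2 grabs are the comparable faunal set;
#: the Hamon 0.1 m^2 grab is the device used for routine sediment monitoring.
KNOWN_GEARS = (
    "Hamon_0.1",
    "Hamon_0.2",
    "Day_0.1",
    "VanVeen_0.1",
    "SmithMcIntyre_0.1",
    "core",
    "other",
)

GRABS_01 = frozenset({"Hamon_0.1", "Day_0.1", "VanVeen_0.1", "SmithMcIntyre_0.1"})

TREATMENTS = ("reference", "impacted", "unknown")

FACTOR_COLUMNS = [
    "survey_id", "lat", "lon", "gear", "sieve_mm", "date", "depth_m",
    "treatment", "colonials_recorded", "same_deployment",
]


class ValidationError(ValueError):
    """Input data violates a structural contract."""


def _check_factors(factors: pd.DataFrame) -> pd.DataFrame:
    factors = factors.copy()
    if factors.index.has_duplicates:
        dups = factors.index[factors.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample_id values: {dups}")
    unknown = set(factors["gear"]) - set(KNOWN_GEARS)
    if unknown:
        warnings.warn(f"unknown gear strings recorded as 'other': {sorted(unknown)}")
        factors.loc[factors["gear"].isin(unknown), "gear"] = "other"
    if (factors["sieve_mm"] <= 0).any():
        raise ValidationError("sieve_mm must be positive")
    if not factors["lat"].between(-90, 90).all():
        raise ValidationError("latitude outside [-90, 90]")
    if not factors["lon"].between(-180, 180).all():
        raise ValidationError("longitude outside [-180, 180]")
    bad_treat = set(factors["treatment"].dropna()) - set(TREATMENTS)
    if bad_treat:
        raise ValidationError(f"unknown treatment values: {sorted(bad_treat)}")
    return factors


@dataclass
class SampleTable:
    """Joined per-sample dataset; the pipeline's backbone.

    All frames are indexed (or keyed, for the long ``psd``) by ``sample_id``.
    ``colonial_taxa`` names the abundance columns that are presence-coded.
    """

    factors: pd.DataFrame
    abundance: pd.DataFrame
    psd: pd.DataFrame | None = None
    env: pd.DataFrame | None = None
    colonial_taxa: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.factors = _check_factors(self.factors)
        if self.abundance.index.has_duplicates:
            raise ValidationError("duplicate sample_id in abundance matrix")
        if (self.abundance.to_numpy() < 0).any():
            raise ValidationError("negative abundance values")
        missing_fauna = self.factors.index.difference(self.abundance.index)
        if len(missing_fauna):
            raise ValidationError(
                f"samples lack a faunal record: {missing_fauna.tolist()[:10]}"
            )
        # align abundance to factors order; rows without metadata are rejected
        extra = self.abundance.index.difference(self.factors.index)
        if len(extra):
            raise ValidationError(f"abundance rows lack metadata: {extra.tolist()[:10]}")
        self.abundance = self.abundance.loc[self.factors.index]
        colonial_cols = self.colonial_taxa & set(self.abundance.columns)
        if colonial_cols:
            vals = self.abundance[sorted(colonial_cols)].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError("colonial taxa must be presence-coded 0/1")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.factors.index

    def __len__(self) -> int:
        return len(self.factors)

    def has_psd(self) -> pd.Series:
        """Boolean per sample: particle-size data present."""
        present = set() if self.psd is None else set(self.psd["sample_id"])
        return pd.Series(self.sample_ids.isin(present), index=self.sample_ids)

    def psd_for(self, sample_id: str) -> dict[float, float]:
        if self.psd is None:
            raise KeyError(f"no PSD table loaded (sample {sample_id})")
        rows = self.psd[self.psd["sample_id"] == sample_id]
        if rows.empty:
            raise KeyError(f"no PSD for sample {sample_id}")
        return psd_from_long(zip(rows["aperture_mm"], rows["percent"]))

    def standard_psd(self, mapping: SieveMapping = DEFAULT_MAPPING) -> pd.DataFrame:
        """Wide per-sample PSD on the 12 standard classes (columns coarse->fine)."""
        if self.psd is None:
            return pd.DataFrame(columns=list(STANDARD_APERTURES_MM))
        records = {}
        for sid, grp in self.psd.groupby("sample_id", sort=False):
            psd = psd_from_long(zip(grp["aperture_mm"], grp["percent"]))
            records[sid] = collapse_to_standard_sieves(psd, mapping)
        out = pd.DataFrame.from_dict(records, orient="index").fillna(0.0)
        return out.reindex(columns=list(STANDARD_APERTURES_MM), fill_value=0.0)

    def wentworth(self, mapping: SieveMapping = DEFAULT_MAPPING) -> pd.DataFrame:
        """Per-sample Wentworth fractions (7-vector + cobbles + total), % weight."""
        std = self.standard_psd(mapping)
        rows = {}
        for sid, row in std.iterrows():
            comp = to_wentworth(row.to_dict(), mapping)
            rec = dict(comp.fractions)
            rec["cobbles"] = comp.cobbles
            rec["total"] = comp.total
            rows[sid] = rec
        cols = list(WENTWORTH_FRACTIONS) + ["cobbles", "total"]
        return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cols)

    def subset(self, sample_ids) -> "SampleTable":
        """New table restricted to the given samples (order preserved)."""
        idx = pd.Index(sample_ids)
        psd = None
        if self.psd is not None:
            psd = self.psd[self.psd["sample_id"].isin(set(idx))].reset_index(drop=True)
        env = None if self.env is None else self.env.loc[self.env.index.intersection(idx)]
        return SampleTable(
            factors=self.factors.loc[idx],
            abundance=self.abundance.loc[idx],
            psd=psd,
            env=env,
            colonial_taxa=self.colonial_taxa,
        )
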