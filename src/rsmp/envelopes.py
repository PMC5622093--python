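"""Per-group sediment envelopes: the reference distributions against which
monitoring samples are tested.

A group is either a faunal assemblage (e.g. "B1a") or a faunal-physical
combination ("B1a_4": faunal group B1a within physical-environment cluster 4).
Its envelope is the mean vector and covariance matrix of the 7 Wentworth
fraction percentages over the group's reference (non-impacted, filter-passing)
samples, plus a rank-based multivariate dispersion index and a Wentworth-class
summary with a gravel/sand/mud textural description.

Because the 7 fractions of an exactly-closed composition sum to a constant,
the covariance matrix is near-singular along the all-ones direction; the
change test downstream handles this with a pseudo-inverse, and nothing here
attempts to "repair" it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from rsmp.clustering import CentreDendrogram
from rsmp.sieves import WENTWORTH_FRACTIONS


@dataclass(frozen=True)
class GroupKey:
    """Faunal (and optional physical) group identity, e.g. B1a_4."""

    faunal_code: str
    physical_code: int | None = None

    @property
    def label(self) -> str:
        if self.physical_code is None:
            return self.faunal_code
        return f"{self.faunal_code}_{self.physical_code}"

    @classmethod
    def parse(cls, label: str) -> "GroupKey":
        if "_" in label:
            faunal, phys = label.rsplit("_", 1)
            return cls(faunal_code=faunal, physical_code=int(phys))
        return cls(faunal_code=label)

    def __str__(self) -> str:
        return self.label


class NeedsAugmentation(Exception):
    """Too few reference samples for a stable envelope; carries the shortfall."""

    def __init__(self, key: GroupKey, n: int, min_n: int):
        self.key = key
        self.n = n
        self.min_n = min_n
        self.shortfall = min_n - n
        super().__init__(
            f"group {key} has n={n} reference samples, {self.shortfall} short of {min_n}"
        )


@dataclass
class SedimentEnvelope:
    """Reference distribution of Wentworth fraction percentages for one group."""

    key: GroupKey
    n: int
    mean: np.ndarray  # 7-vector, % per fraction
    cov: np.ndarray  # 7x7 unbiased sample covariance
    mvdisp: float | None = None
    augmented_from: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (7,) or self.cov.shape != (7, 7):
            raise ValueError("envelope requires a 7-vector mean and 7x7 covariance")
        if not np.allclose(self.cov, self.cov.T, atol=1e-9):
            raise ValueError("covariance must be symmetric")
        if (np.diag(self.cov) < 0).any():
            raise ValueError("negative variances")
        if self.n < 2:
            raise ValueError("envelope needs n >= 2")
        if (self.mean < 0).any():
            raise ValueError("negative mean fractions")

    # -- summaries -------------------------------------------------------------

    @property
    def mud(self) -> float:
        return float(self.mean[0])

    @property
    def sand(self) -> float:
        return float(self.mean[1:4].sum())

    @property
    def gravel(self) -> float:
        return float(self.mean[4:7].sum())

    def to_dict(self) -> dict:
        return {
            "group": self.key.label,
            "n": self.n,
            "fractions": list(WENTWORTH_FRACTIONS),
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "mvdisp": self.mvdisp,
            "augmented_from": [list(t) for t in self.augmented_from],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SedimentEnvelope":
        return cls(
            key=GroupKey.parse(d["group"]),
            n=int(d["n"]),
            mean=np.asarray(d["mean"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            mvdisp=d.get("mvdisp"),
            augmented_from=[tuple(t) for t in d.get("augmented_from", [])],
        )

    @classmethod
    def from_json(cls, text: str) -> "SedimentEnvelope":
        return cls.from_dict(json.loads(text))


def make_groups(faunal_labels, physical_labels=None) -> list[GroupKey]:
    """Combine aligned faunal and physical labels into group keys."""
    faunal = list(faunal_labels)
    if physical_labels is None:
        return [GroupKey(str(f)) for f in faunal]
    phys = list(physical_labels)
    if len(phys) != len(faunal):
        raise ValueError(
            f"label vectors differ in length ({len(faunal)} vs {len(phys)})"
        )
    return [
        GroupKey(str(f), None if p is None else int(p))
        for f, p in zip(faunal, phys)
    ]


def fit_envelope(
    compositions: pd.DataFrame, key: GroupKey, min_n: int = 30
) -> SedimentEnvelope:
    """Columnwise mean and unbiased (n-1) covariance of a group's compositions.

    ``compositions`` must carry the 7 fraction columns in canonical order.
    Raises :class:`NeedsAugmentation` when fewer than ``min_n`` reference
    samples are available.
    """
    X = compositions[list(WENTWORTH_FRACTIONS)].to_numpy(dtype=float)
    n = len(X)
    if n < min_n:
        raise NeedsAugmentation(key, n, min_n)
    return SedimentEnvelope(
        key=key, n=n, mean=X.mean(axis=0), cov=np.cov(X, rowvar=False, ddof=1)
    )


def augmentation_order(
    physical_code: int, dendrogram: CentreDendrogram
) -> list[int]:
    """Physical group codes (1..k) sorted by cophenetic proximity to the given
    group, nearest first; merge (tie) distances resolve by lower group code."""
    coph = dendrogram.cophenetic()
    i = physical_code - 1
    order = sorted(
        (j for j in range(dendrogram.k) if j != i),
        key=lambda j: (coph[i, j], j),
    )
    return [j + 1 for j in order]


def augment_from_dendrogram(
    key: GroupKey,
    physical_dendrogram: CentreDendrogram,
    compositions: pd.DataFrame,
    min_n: int = 30,
) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Top up an undersized faunal-physical group from related physical groups.

    ``compositions`` must hold all reference samples of the *faunal* group,
    with a ``physical_code`` column alongside the fraction columns. Samples
    from the group itself come first; then whole neighbouring physical groups
    (same faunal code) are added in dendrogram proximity order until
    ``min_n`` is reached. Returns the augmented compositions and a provenance
    list of (group label, samples added).
    """
    if key.physical_code is None:
        raise ValueError("augmentation applies to faunal-physical groups")
    own = compositions[compositions["physical_code"] == key.physical_code]
    chosen = [own]
    provenance: list[tuple[str, int]] = [(key.label, len(own))]
    n = len(own)
    if n >= min_n:
        return own, provenance
    for code in augmentation_order(key.physical_code, physical_dendrogram):
        extra = compositions[compositions["physical_code"] == code]
        if extra.empty:
            continue
        chosen.append(extra)
        provenance.append((GroupKey(key.faunal_code, code).label, len(extra)))
        n += len(extra)
        if n >= min_n:
            break
    if n < min_n:
        raise NeedsAugmentation(key, n, min_n)
    return pd.concat(chosen), provenance


def mvdisp(compositions: pd.DataFrame, labels) -> pd.Series:
    """Rank-based index of multivariate dispersion per group.

    All within-group Bray-Curtis dissimilarities (over the 7 fraction
    percentages) are pooled across groups and jointly ranked (average ranks on
    ties); a group's dispersion is its mean rank rescaled so the
    pair-count-weighted mean over groups is 1. Values above 1 mark groups more
    internally variable than average. Duplicating samples within a group does
    not change the result. Groups of size 1 are excluded with a warning.
    """
    labels = pd.Series(np.asarray(labels), index=compositions.index)
    groups = {}
    for g, idx in labels.groupby(labels).groups.items():
        if len(idx) < 2:
            warnings.warn(f"MVDISP: group {g!r} has a single sample; excluded")
            continue
        X = compositions.loc[idx, list(WENTWORTH_FRACTIONS)].to_numpy(dtype=float)
        groups[g] = pdist(X, metric="braycurtis")
    if not groups:
        return pd.Series(dtype=float)
    pooled = np.concatenate(list(groups.values()))
    ranks = rankdata(pooled)
    scale = (len(pooled) + 1) / 2.0  # mean of all ranks
    out = {}
    start = 0
    for g, d in groups.items():
        r = ranks[start : start + len(d)]
        out[g] = float(r.mean() / scale)
        start += len(d)
    return pd.Series(out, name="mvdisp")


def cumulative_distribution(std_compositions: pd.DataFrame) -> pd.Series:
    """Mean cumulative percentage by standard sieve class, fine to coarse.

    Input columns are the 12 standard classes; the curve is the running sum of
    the per-class means ordered from the pan upward, ending at the mean of the
    per-sample totals.
    """
    means = std_compositions.mean(axis=0)
    order = sorted(means.index, key=float)
    return means.loc[order].cumsum()


# -- gravel/sand/mud textural description (after Blott & Pye's scheme) ---------

def _modifier(pct: float, kind: str) -> str:
    if pct < 0.01:
        return ""
    if pct < 1:
        return f"v slightly {kind}"
    if pct < 5:
        return f"slightly {kind}"
    if pct < 30:
        return kind
    return ""  # >= 30% handled as a principal component


def describe_sediment(mud: float, sand: float, gravel: float) -> str:
    """Textural class from gravel %, and the sand/mud balance of the fines.

    Follows the widely used gravel-sand-mud ternary convention: gravel above
    80% is "gravel", 30-80% a sandy and/or muddy gravel, below 30% a gravelly
    (or slightly/very slightly gravelly) sand, mud or muddy sand, with the
    sand:mud ratio (9:1, 1:1, 1:9) deciding the principal fine fraction.
    """
    total = mud + sand + gravel
    if total <= 0:
        return "no sediment"
    mud, sand, gravel = (100 * v / total for v in (mud, sand, gravel))
    fines = mud + sand
    if gravel >= 80:
        return "gravel"
    if gravel >= 30:
        # principal name gravel, qualified by the dominant fines
        if fines == 0:
            return "gravel"
        ratio = sand / mud if mud > 0 else np.inf
        if ratio >= 9:
            return "sandy gravel"
        if ratio >= 1 / 9:
            return "muddy sandy gravel"
        return "muddy gravel"
    gravel_mod = _modifier(gravel, "gravelly")
    ratio = sand / mud if mud > 0 else np.inf
    if ratio >= 9:
        mud_mod = _modifier(100 * mud / fines if fines else 0.0, "muddy")
        base = "sand"
    elif ratio >= 1:
        mud_mod, base = "muddy", "sand"
    elif ratio >= 1 / 9:
        mud_mod, base = "sandy", "mud"
    else:
        mud_mod = _modifier(100 * sand / fines if fines else 0.0, "sandy")
        base = "mud"
    parts = [p for p in (gravel_mod, mud_mod, base) if p]
    return " ".join(parts)


def wentworth_summary(envelope: SedimentEnvelope) -> dict:
    """Mud/Sand/Gravel means, per-fraction means and the textural description."""
    return {
        "group": envelope.key.label,
        "n": envelope.n,
        "mud_pct": envelope.mud,
        "sand_pct": envelope.sand,
        "gravel_pct": envelope.gravel,
        "fraction_means": dict(zip(WENTWORTH_FRACTIONS, envelope.mean.tolist())),
        "description": describe_sediment(envelope.mud, envelope.sand, envelope.gravel),
        "mvdisp": envelope.mvdisp,
    }
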