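"""k-means machinery for faunal and physical cluster baselines.

The same machinery is used twice: on fourth-root-transformed family abundances
(faunal assemblages, default k = 12) and on transformed, normalised
environmental variables (physical groups, default k = 10). The MacQueen
variant of k-means is used: after an initial assignment pass, samples are
visited one at a time and cluster centres are updated immediately whenever a
sample moves, which converges quickly and makes empty clusters easy to repair.
The best of ``n_restarts`` random initialisations (lowest within-cluster sum
of squares) is kept, so fits are deterministic given the seed.

New monitoring samples are matched to the fitted baseline with
:func:`assign` — this ability to place future samples into existing groups is
the reason a centroid method is used rather than hierarchical clustering.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, pdist


def fourth_root(x) -> np.ndarray:
    """Elementwise fourth-root transform; down-weights highly abundant taxa
    so colonial (0/1) and rarer families carry appropriate weight."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("fourth_root requires non-negative abundances")
    return x ** 0.25


@dataclass
class ClusterModel:
    """A fitted k-means solution in transformed space."""

    k: int
    centres: np.ndarray  # k x p
    transform_spec: str  # "fourth-root" | "log+z-score" | free text
    labels: np.ndarray  # per-training-sample group id, 1..k
    wss: float
    tss: float
    seed: int
    n_restarts: int
    columns: tuple[str, ...] = ()
    #: presentation codes per integer label (1..k), e.g. {1: "A1", ...}
    codes: dict[int, str] = field(default_factory=dict)

    @property
    def explained(self) -> float:
        """Share of total variability captured: 1 - WSS/TSS."""
        return 1.0 - self.wss / self.tss if self.tss > 0 else 0.0

    def code_of(self, label: int) -> str:
        return self.codes.get(int(label), str(int(label)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "centres": self.centres.tolist(),
                "transform_spec": self.transform_spec,
                "wss": self.wss,
                "tss": self.tss,
                "seed": self.seed,
                "n_restarts": self.n_restarts,
                "columns": list(self.columns),
                "codes": {str(i): c for i, c in self.codes.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ClusterModel":
        d = json.loads(text)
        return cls(
            k=d["k"],
            centres=np.asarray(d["centres"], dtype=float),
            transform_spec=d["transform_spec"],
            labels=np.empty(0, dtype=int),
            wss=d["wss"],
            tss=d["tss"],
            seed=d["seed"],
            n_restarts=d["n_restarts"],
            columns=tuple(d.get("columns", ())),
            codes={int(i): c for i, c in d.get("codes", {}).items()},
        )


def _sq_dist_to_centres(x: np.ndarray, centres: np.ndarray) -> np.ndarray:
    d = centres - x
    return np.einsum("ij,ij->i", d, d)


def _assign_all(X: np.ndarray, centres: np.ndarray) -> np.ndarray:
    # ties broken toward the lowest centre index (argmin semantics)
    return np.argmin(cdist(X, centres, "sqeuclidean"), axis=1)


def _wss_of(X: np.ndarray, centres: np.ndarray, labels: np.ndarray) -> float:
    return float(((X - centres[labels]) ** 2).sum())


def _macqueen(X: np.ndarray, centres: np.ndarray, max_iter: int = 100):
    """Run MacQueen passes from the given centres until assignments are stable.

    Centres are maintained as exact cluster means via running sums/counts and
    updated immediately on every reassignment. An emptied cluster is re-seeded
    from the sample currently farthest from its own centre.
    """
    n, p = X.shape
    k = len(centres)
    centres = centres.copy()
    labels = _assign_all(X, centres)
    counts = np.bincount(labels, minlength=k).astype(float)
    sums = np.zeros((k, p))
    np.add.at(sums, labels, X)
    # recompute centres as means of initial assignment (empty keep their seed)
    nonempty = counts > 0
    centres[nonempty] = sums[nonempty] / counts[nonempty, None]

    for _ in range(max_iter):
        moved = 0
        for i in range(n):
            x = X[i]
            j_old = labels[i]
            j_new = int(np.argmin(_sq_dist_to_centres(x, centres)))
            if j_new == j_old:
                continue
            moved += 1
            labels[i] = j_new
            counts[j_old] -= 1.0
            sums[j_old] -= x
            counts[j_new] += 1.0
            sums[j_new] += x
            if counts[j_old] > 0:
                centres[j_old] = sums[j_old] / counts[j_old]
            centres[j_new] = sums[j_new] / counts[j_new]
            if counts[j_old] == 0:
                # re-seed the emptied cluster at the worst-fitting sample
                d2 = np.einsum(
                    "ij,ij->i", X - centres[labels], X - centres[labels]
                )
                far = int(np.argmax(d2))
                j_far = labels[far]
                counts[j_far] -= 1.0
                sums[j_far] -= X[far]
                if counts[j_far] > 0:
                    centres[j_far] = sums[j_far] / counts[j_far]
                labels[far] = j_old
                counts[j_old] = 1.0
                sums[j_old] = X[far].copy()
                centres[j_old] = X[far].copy()
        if moved == 0:
            break
    # final tidy pass so labels are exactly nearest-centre
    labels = _assign_all(X, centres)
    counts = np.bincount(labels, minlength=k).astype(float)
    sums = np.zeros((k, p))
    np.add.at(sums, labels, X)
    nonempty = counts > 0
    centres[nonempty] = sums[nonempty] / counts[nonempty, None]
    return centres, labels


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: each next centre drawn with probability proportional
    to squared distance from the nearest centre chosen so far."""
    n = len(X)
    centres = np.empty((k, X.shape[1]))
    centres[0] = X[rng.integers(n)]
    d2 = ((X - centres[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centres[j:] = X[rng.choice(n, size=k - j, replace=False)]
            break
        centres[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centres[j]) ** 2).sum(axis=1))
    return centres


def fit_kmeans(
    X,
    k: int,
    seed: int,
    n_restarts: int = 25,
    transform_spec: str = "",
    columns=(),
    extra_starts=(),
    max_iter: int = 100,
) -> ClusterModel:
    """Best-of-restarts MacQueen k-means (lowest WSS wins).

    Each restart initialises centres at a random sample of k distinct rows;
    ``extra_starts`` may supply additional explicit k x p initial centre
    matrices (used by :func:`elbow_curve` to warm-start from smaller-k
    solutions). Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside [2, n={n}]")
    if np.isnan(X).any():
        raise ValueError("missing values in clustering input")
    rng = np.random.default_rng(seed)
    tss = float(((X - X.mean(axis=0)) ** 2).sum())

    best = None
    # distance-weighted (k-means++) seeding: far better than uniform row
    # sampling at reaching small clusters when group sizes are uneven
    starts = [_kmeanspp_init(X, k, rng) for _ in range(n_restarts)]
    starts += [np.asarray(s, dtype=float) for s in extra_starts]
    for init in starts:
        centres, labels = _macqueen(X, init, max_iter=max_iter)
        wss = _wss_of(X, centres, labels)
        if best is None or wss < best[0] - 1e-12:
            best = (wss, centres, labels)
    wss, centres, labels = best
    model = ClusterModel(
        k=k,
        centres=centres,
        transform_spec=transform_spec,
        labels=labels + 1,
        wss=wss,
        tss=tss,
        seed=seed,
        n_restarts=n_restarts,
        columns=tuple(columns),
    )
    model.codes = _hierarchical_codes(model)
    return model


def elbow_curve(X, k_range, seed: int, n_restarts: int = 25):
    """(k, wss, explained) across ``k_range``.

    Besides the random restarts, each k is also started from the previous
    best solution's centres plus the sample farthest from its centre, which
    guarantees explained variance is non-decreasing in k.
    """
    X = np.asarray(X, dtype=float)
    out = []
    prev: ClusterModel | None = None
    for k in sorted(k_range):
        extra = []
        if prev is not None and prev.k == k - 1:
            labels0 = prev.labels - 1
            d2 = np.einsum(
                "ij,ij->i", X - prev.centres[labels0], X - prev.centres[labels0]
            )
            extra = [np.vstack([prev.centres, X[int(np.argmax(d2))]])]
        model = fit_kmeans(
            X, k, seed=seed, n_restarts=n_restarts, extra_starts=extra
        )
        out.append((k, model.wss, model.explained))
        prev = model
    return out


@dataclass
class CentreDendrogram:
    """Group-average hierarchical tree over the k cluster centres."""

    linkage: np.ndarray  # scipy linkage matrix, (k-1) x 4
    metric: str
    k: int

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[int]:
        """0-based centre indices in dendrogram display order."""
        return [int(i) for i in hierarchy.leaves_list(self.linkage)]

    def cophenetic(self) -> np.ndarray:
        """k x k cophenetic distance matrix between centres."""
        from scipy.spatial.distance import squareform

        return squareform(hierarchy.cophenet(self.linkage))

    def cut(self, n_groups: int) -> np.ndarray:
        """Flat membership of the k centres into ``n_groups`` broad groups."""
        return hierarchy.fcluster(self.linkage, t=n_groups, criterion="maxclust")


def centre_dendrogram(model: ClusterModel, metric: str = "euclidean") -> CentreDendrogram:
    """Group-average (UPGMA) dendrogram over inter-centre distances.

    ``metric`` is ``"euclidean"`` (default) or ``"cityblock"`` — the absolute
    (Manhattan) distance reading of "distance across all variables".
    """
    if metric not in ("euclidean", "cityblock"):
        raise ValueError("metric must be 'euclidean' or 'cityblock'")
    d = pdist(model.centres, metric=metric)
    Z = hierarchy.linkage(d, method="average")
    return CentreDendrogram(linkage=Z, metric=metric, k=model.k)


def _hierarchical_codes(model: ClusterModel) -> dict[int, str]:
    """Presentation codes (A1, A2, B1, ...) reflecting centre relatedness.

    The centre dendrogram is cut at half its maximum merge height into broad
    groups; groups get letters in dendrogram leaf order and members are
    numbered within each letter, again in leaf order. Purely cosmetic over
    the integer labels.
    """
    if model.k < 2:
        return {1: "A1"}
    dend = centre_dendrogram(model)
    h_max = float(dend.heights.max())
    if h_max <= 0:
        broad = np.ones(model.k, dtype=int)
    else:
        broad = hierarchy.fcluster(dend.linkage, t=0.5 * h_max,
                                   criterion="distance")
    order = dend.leaf_order()
    letters: dict[int, str] = {}
    next_letter = 0
    counters: dict[str, int] = {}
    codes: dict[int, str] = {}
    for idx in order:
        b = int(broad[idx])
        if b not in letters:
            letters[b] = string.ascii_uppercase[next_letter % 26]
            next_letter += 1
        letter = letters[b]
        counters[letter] = counters.get(letter, 0) + 1
        codes[idx + 1] = f"{letter}{counters[letter]}"
    return codes


def assign(model: ClusterModel, X_new, columns=None) -> np.ndarray:
    """Nearest-centre assignment of new samples (labels 1..k).

    ``X_new`` must be in the model's transformed space and column order;
    passing ``columns`` checks the order explicitly. Ties go to the lowest
    group index.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.centres.shape[1]:
        raise ValueError(
            f"column mismatch: model has {model.centres.shape[1]} variables, "
            f"input has {X_new.shape[1]}"
        )
    if columns is not None and model.columns and tuple(columns) != tuple(model.columns):
        raise ValueError("column order differs from the fitted model")
    return _assign_all(X_new, model.centres) + 1
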