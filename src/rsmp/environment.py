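"""Explaining faunal structure from environmental predictors.

The workflow mirrors standard practice in community ecology: prune collinear
predictors by iterated variance-inflation factors, transform right-skewed
variables and normalise, draw a balanced per-group subsample, search predictor
subsets whose Euclidean resemblance best rank-correlates with the faunal
Bray-Curtis resemblance (BIOENV), and partition multivariate variability among
predictors by permutational MANOVA on the distance matrix (McArdle-Anderson).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
import statsmodels.api as sm

#: Variables that receive a log(x + 0.1) transform before normalisation when
#: explaining faunal patterns (right-skewed concentrations/depths).
DEFAULT_LOG_VARS = ("SPM", "Depth", "Mud")


class ZeroVarianceError(ValueError):
    """A column is constant and cannot be normalised."""


def _vif_scores(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1 - R^2_j) from OLS of column j on all others + intercept."""
    scores = {}
    for col in X.columns:
        y = X[col].to_numpy(dtype=float)
        others = sm.add_constant(X.drop(columns=[col]).to_numpy(dtype=float))
        r2 = sm.OLS(y, others).fit().rsquared
        scores[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(scores)


def vif_prune(env: pd.DataFrame, threshold: float = 2.5):
    """Iteratively drop the single worst-collinear variable until all VIF <= threshold.

    Each round recomputes VIFs for the surviving variables and removes the one
    with the highest VIF above ``threshold`` (ties broken alphabetically, so
    perfectly collinear sets resolve deterministically). Returns
    ``(retained_columns, trace)`` where ``trace`` lists (variable, vif) in
    removal order.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if len(env) <= env.shape[1]:
        raise ValueError("need n > p for VIF estimation")
    cols = list(env.columns)
    trace: list[tuple[str, float]] = []
    while len(cols) >= 2:
        vifs = _vif_scores(env[cols])
        worst = vifs.max()
        if worst <= threshold:
            break
        # highest VIF; alphabetical tie-break
        candidates = sorted(vifs.index[vifs == worst])
        victim = candidates[0]
        trace.append((victim, float(worst)))
        cols.remove(victim)
    return cols, trace


def transform_env(env: pd.DataFrame, log_vars=DEFAULT_LOG_VARS) -> pd.DataFrame:
    """log(x + 0.1) on the named variables, then z-score every column.

    Raises :class:`ZeroVarianceError` naming any constant column, and
    ``ValueError`` if a log variable is negative.
    """
    out = env.astype(float).copy()
    for v in log_vars:
        if v not in out.columns:
            continue
        if (out[v] < 0).any():
            raise ValueError(f"negative values in log-transform variable {v}")
        out[v] = np.log(out[v] + 0.1)
    sd = out.std(ddof=1)
    constant = sorted(sd.index[(sd == 0) | sd.isna()])
    if constant:
        raise ZeroVarianceError(f"zero-variance columns: {constant}")
    return (out - out.mean()) / sd


def balanced_subsample(labels, n_per_group: int, seed: int) -> np.ndarray:
    """Positional indices of exactly ``n_per_group`` random samples per group.

    Sampling is without replacement and reproducible by seed; an undersized
    group raises an error naming it. Groups are visited in sorted order so the
    result is independent of input ordering quirks.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    chosen = []
    for g in sorted(pd.unique(labels), key=str):
        members = np.flatnonzero(labels == g)
        if len(members) < n_per_group:
            raise ValueError(
                f"group {g!r} has {len(members)} samples, fewer than {n_per_group}"
            )
        chosen.append(rng.choice(members, size=n_per_group, replace=False))
    return np.concatenate(chosen)


@dataclass
class BioenvResult:
    subset: tuple[str, ...]
    size: int
    rho: float
    best_overall: bool = False


def _spearman_condensed(a_ranked: np.ndarray, b: np.ndarray) -> float:
    rb = rankdata(b)
    ra = a_ranked
    ra_c = ra - ra.mean()
    rb_c = rb - rb.mean()
    denom = np.sqrt((ra_c**2).sum() * (rb_c**2).sum())
    return float((ra_c * rb_c).sum() / denom) if denom > 0 else 0.0


def bioenv(
    faunal_bc, env: pd.DataFrame, max_size: int | None = None
) -> list[BioenvResult]:
    """Exhaustive BIOENV subset search.

    ``faunal_bc`` is the faunal Bray-Curtis distance matrix (condensed or
    square); ``env`` the normalised predictor table in the same sample order.
    For each subset size up to ``max_size`` the subset maximising the Spearman
    rank correlation between the faunal resemblance entries and the Euclidean
    resemblance of the selected predictors is reported; the overall best is
    flagged. More than 20 variables without an explicit ``max_size`` is
    refused (combinatorial guard).
    """
    d = np.asarray(faunal_bc, dtype=float)
    if d.ndim == 2:
        d = squareform(d, checks=False)
    p = env.shape[1]
    if max_size is None:
        if p > 20:
            raise ValueError("more than 20 variables: pass max_size explicitly")
        max_size = p
    n_pairs = len(d)
    expect = env.shape[0] * (env.shape[0] - 1) // 2
    if n_pairs != expect:
        raise ValueError("distance matrix does not match env table size")
    fauna_ranks = rankdata(d)
    cols = list(env.columns)
    E = env.to_numpy(dtype=float)
    results: list[BioenvResult] = []
    for size in range(1, max_size + 1):
        best = None
        for combo in itertools.combinations(range(p), size):
            de = pdist(E[:, combo], metric="euclidean")
            rho = _spearman_condensed(fauna_ranks, de)
            key = tuple(cols[j] for j in combo)
            if best is None or rho > best[0] + 1e-15:
                best = (rho, key)
        results.append(BioenvResult(subset=best[1], size=size, rho=best[0]))
    top = max(range(len(results)), key=lambda i: results[i].rho)
    results[top].best_overall = True
    return results


@dataclass
class PermanovaTerm:
    name: str
    ss: float
    df: int
    pseudo_f: float
    r2: float
    p: float


@dataclass
class PermanovaResult:
    terms: list[PermanovaTerm]
    residual_ss: float
    residual_df: int
    total_ss: float
    n_perm: int

    @property
    def residual_r2(self) -> float:
        return self.residual_ss / self.total_ss

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t.name, "SS": t.ss, "df": t.df, "pseudo_F": t.pseudo_f,
             "R2": t.r2, "p": t.p}
            for t in self.terms
        ]
        rows.append({"term": "Residual", "SS": self.residual_ss,
                     "df": self.residual_df, "pseudo_F": np.nan,
                     "R2": self.residual_r2, "p": np.nan})
        return pd.DataFrame(rows)


def _gower_centred(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = len(A)
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat(Xc: np.ndarray) -> np.ndarray:
    # pseudo-inverse hat matrix; tolerant of rank deficiency
    return Xc @ np.linalg.pinv(Xc.T @ Xc) @ Xc.T


def permanova(
    faunal_bc,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA on a distance matrix with numeric predictors.

    Uses the McArdle-Anderson direct decomposition of the Gower-centred
    distance matrix: SS for a model is tr(H G) with H the hat matrix of the
    (intercept-augmented) predictor columns entered so far; each term's SS is
    the increment over the previous model. p-values come from free permutation
    of sample rows, p = (b + 1)/(n_perm + 1) with b the count of permuted
    pseudo-F >= observed.
    """
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    D = np.asarray(faunal_bc, dtype=float)
    if D.ndim == 1:
        D = squareform(D)
    n = len(D)
    if predictors.shape[0] != n:
        raise ValueError("predictor rows do not match distance matrix")
    G = _gower_centred(D)
    total_ss = float(np.trace(G))

    names = list(predictors.columns)
    X = predictors.to_numpy(dtype=float)
    ones = np.ones((n, 1))
    # cumulative hat matrices: intercept, +term1, +term2, ...
    hats = [_hat(ones)]
    dfs = []
    for j in range(len(names)):
        Xj = np.hstack([ones, X[:, : j + 1]])
        hats.append(_hat(Xj))
        dfs.append(int(round(np.trace(hats[-1] - hats[-2]))) or 1)
    H_full = hats[-1]
    resid_df = n - int(round(np.trace(H_full)))
    R = np.eye(n) - H_full

    def stats_for(Gp: np.ndarray):
        ss_terms = np.array(
            [float(np.trace((hats[j + 1] - hats[j]) @ Gp)) for j in range(len(names))]
        )
        ss_res = float(np.trace(R @ Gp))
        f = (ss_terms / np.array(dfs)) / (ss_res / resid_df)
        return ss_terms, ss_res, f

    ss_terms, ss_res, f_obs = stats_for(G)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        _, _, f_p = stats_for(Gp)
        exceed += f_p >= f_obs
    pvals = (exceed + 1.0) / (n_perm + 1.0)

    terms = [
        PermanovaTerm(
            name=names[j],
            ss=float(ss_terms[j]),
            df=dfs[j],
            pseudo_f=float(f_obs[j]),
            r2=float(ss_terms[j] / total_ss),
            p=float(pvals[j]),
        )
        for j in range(len(names))
    ]
    return PermanovaResult(
        terms=terms,
        residual_ss=ss_res,
        residual_df=resid_df,
        total_ss=total_ss,
        n_perm=n_perm,
    )
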