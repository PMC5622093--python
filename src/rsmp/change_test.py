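"""The sediment-change test: is a monitoring sample's composition still
"favourable" for its baseline assemblage?

A test sample's 7-vector of Wentworth fraction percentages v is compared with
its group envelope (mean x̄, covariance Σ, n reference samples) through the
squared Mahalanobis distance

    D² = (v − x̄)ᵀ Σ⁺ (v − x̄),

with Σ⁺ an eigen-pseudo-inverse: eigenvalues below ``rtol`` times the largest
are treated as null directions and dropped. This matters because closed
compositions (fractions summing to ~100) make Σ singular along the all-ones
direction — perturbations of the sample along a null direction do not change
D². The reported p is the upper tail of a chi-square with the effective rank
as degrees of freedom, the large-n reference distribution; in one informative
dimension this reduces to flagging samples more than 1.96 standard deviations
from the mean at α = 0.05. A finite-n variant (Hotelling-style F for a new
observation) is available behind ``method="hotelling"``.

A failed test (p < α) is diagnosed by the per-fraction differences v − x̄ —
the fractions with the largest departures among those inflating D² are the
likely drivers, to be taken to further investigation rather than interpreted
as proof of a dredging effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rsmp.envelopes import SedimentEnvelope
from rsmp.sieves import WENTWORTH_FRACTIONS


@dataclass
class TestSample:
    """A monitoring sample's 7 Wentworth fraction percentages and its group.

    ``validate=False`` skips the non-negativity check — used for idealised
    multivariate-normal draws in calibration studies, which real laboratory
    compositions never violate.
    """

    sample_id: str
    v: np.ndarray
    group: str = ""
    validate: bool = True

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (7,):
            raise ValueError("test sample must carry exactly the 7 fractions")
        if np.isnan(self.v).any():
            raise ValueError(f"sample {self.sample_id}: missing fraction value")
        if self.validate and (self.v < 0).any():
            raise ValueError(f"sample {self.sample_id}: negative fraction")


@dataclass
class ChangeTestResult:
    sample_id: str
    group: str
    d2: float
    rank: int
    p: float
    alpha: float
    verdict: str  # "favourable" | "unfavourable"
    diff: np.ndarray  # v − x̄, percentage points
    pct_diff: np.ndarray  # 100·(v − x̄)/x̄; NaN where x̄ = 0
    drivers: list[str] = field(default_factory=list)

    def rounded_diff(self) -> list[float]:
        """Difference row at reporting precision (0.1 percentage point)."""
        return [round(d, 1) for d in self.diff]

    def rounded_pct_diff(self) -> list[float | None]:
        """% difference row at reporting precision (integer %)."""
        return [None if np.isnan(d) else round(d) for d in self.pct_diff]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "group": self.group,
            "d2": self.d2,
            "rank": self.rank,
            "p": self.p,
            "alpha": self.alpha,
            "verdict": self.verdict,
            "fractions": list(WENTWORTH_FRACTIONS),
            "diff": self.diff.tolist(),
            "pct_diff": [None if np.isnan(x) else x for x in self.pct_diff],
            "drivers": list(self.drivers),
        }


def _pseudo_inverse(cov: np.ndarray, rtol: float):
    """Eigen-pseudo-inverse and effective rank of a symmetric PSD-ish matrix."""
    w, V = np.linalg.eigh(cov)
    lam_max = float(w.max())
    if lam_max <= 0:
        return np.zeros_like(cov), 0
    keep = w > rtol * lam_max
    rank = int(keep.sum())
    if rank == 0:
        return np.zeros_like(cov), 0
    Vk = V[:, keep]
    pinv = (Vk / w[keep]) @ Vk.T
    return pinv, rank


def diagnose(sample: TestSample, envelope: SedimentEnvelope, rtol: float = 1e-8):
    """Per-fraction differences and the fractions driving the distance.

    Returns ``(diff, pct_diff, drivers)``: diff_i = v_i − x̄_i in percentage
    points; pct_diff_i = 100·diff_i/x̄_i (NaN where x̄_i = 0); drivers are
    fraction names ordered by |diff| descending, restricted to fractions whose
    contribution diff_i · (Σ⁺ diff)_i to D² is positive (those inflating the
    distance).
    """
    diff = sample.v - envelope.mean
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_diff = np.where(envelope.mean > 0, 100.0 * diff / envelope.mean, np.nan)
    pinv, _ = _pseudo_inverse(envelope.cov, rtol)
    contrib = diff * (pinv @ diff)
    order = np.argsort(-np.abs(diff), kind="stable")
    drivers = [WENTWORTH_FRACTIONS[i] for i in order if contrib[i] > 0]
    return diff, pct_diff, drivers


def mahalanobis_test(
    sample: TestSample,
    envelope: SedimentEnvelope,
    alpha: float = 0.05,
    rtol: float = 1e-8,
    method: str = "chi2",
) -> ChangeTestResult:
    """Mahalanobis distance test of a sample against its group envelope.

    ``method="chi2"`` (default) evaluates the upper chi-square tail at the
    effective rank — the large-n reference implied by the 1.96-SD anchor in
    one dimension. ``method="hotelling"`` uses the finite-n predictive
    distribution for a new observation,
    T² = D²·n/(n+1),  F = T²·(n−r)/(r·(n−1)) ~ F(r, n−r),
    which converges to the chi-square form as n grows.
    """
    pinv, rank = _pseudo_inverse(envelope.cov, rtol)
    if rank == 0:
        raise ValueError(f"envelope {envelope.key} has zero effective rank")
    diff, pct_diff, drivers = diagnose(sample, envelope, rtol)
    d2 = float(diff @ pinv @ diff)
    if method == "chi2":
        p = float(stats.chi2.sf(d2, df=rank))
    elif method == "hotelling":
        n = envelope.n
        if n <= rank:
            raise ValueError("hotelling method needs n > effective rank")
        t2 = d2 * n / (n + 1)
        f = t2 * (n - rank) / (rank * (n - 1))
        p = float(stats.f.sf(f, rank, n - rank))
    else:
        raise ValueError(f"unknown method {method!r}")
    # numerically d2 can be a tiny negative for v == x̄ under a null-deficient cov
    d2 = max(d2, 0.0)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    verdict = "favourable" if p >= alpha else "unfavourable"
    return ChangeTestResult(
        sample_id=sample.sample_id,
        group=sample.group or envelope.key.label,
        d2=d2,
        rank=rank,
        p=p,
        alpha=alpha,
        verdict=verdict,
        diff=diff,
        pct_diff=pct_diff,
        drivers=drivers,
    )


def batch_assess(
    samples,
    envelope_store: dict[str, SedimentEnvelope],
    alpha: float = 0.05,
    rtol: float = 1e-8,
    method: str = "chi2",
    bh_correct: bool = False,
) -> dict:
    """Assess a batch of monitoring samples against their group envelopes.

    Samples whose group lacks an envelope produce an error entry and the batch
    continues. No multiplicity adjustment is applied by default — each station
    is judged on its own p, with failures flagged for further investigation;
    ``bh_correct=True`` applies Benjamini-Hochberg across the batch and
    re-derives verdicts from the adjusted p-values.
    """
    results: list[ChangeTestResult] = []
    errors: list[dict] = []
    for s in samples:
        env = envelope_store.get(s.group)
        if env is None:
            errors.append({"sample_id": s.sample_id, "error": f"no envelope for group {s.group!r}"})
            continue
        results.append(mahalanobis_test(s, env, alpha=alpha, rtol=rtol, method=method))
    if bh_correct and results:
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(
            [r.p for r in results], alpha=alpha, method="fdr_bh"
        )
        for r, rej, pa in zip(results, reject, p_adj):
            r.p = float(pa)
            r.verdict = "unfavourable" if rej else "favourable"
    n_unfav = sum(r.verdict == "unfavourable" for r in results)
    return {
        "results": results,
        "errors": errors,
        "summary": {
            "n_tested": len(results),
            "n_unfavourable": n_unfav,
            "n_favourable": len(results) - n_unfav,
            "n_errors": len(errors),
            "alpha": alpha,
            "bh_corrected": bool(bh_correct),
        },
    }


def results_to_frame(report: dict) -> pd.DataFrame:
    """One row per tested sample, suitable for CSV export."""
    rows = []
    for r in report["results"]:
        rec = {
            "sample_id": r.sample_id,
            "group": r.group,
            "d2": r.d2,
            "rank": r.rank,
            "p": r.p,
            "verdict": r.verdict,
            "drivers": ";".join(r.drivers),
        }
        for f, d, pc in zip(WENTWORTH_FRACTIONS, r.rounded_diff(), r.rounded_pct_diff()):
            rec[f"diff_{f}"] = d
            rec[f"pctdiff_{f}"] = pc
        rows.append(rec)
    return pd.DataFrame(rows)
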