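"""Desk-scale synthetic grab-sample datasets with planted ground truth.

The generator emulates the statistical structure of a multi-survey benthic
monitoring dataset: cluster-structured family abundances (negative-binomial
counts around group centroids defined in fourth-root space, colonial families
presence-coded), physical-environment clusters with realistic North-Sea-shelf
variable scales and the collinearity pattern that motivates VIF pruning
(temperature tracks latitude, chlorophyll tracks SPM, bed stress tracks
current speed, and gravel/sand/mud are closed to 100), group-specific
logistic-normal sediment compositions, survey-level detection offsets that
shift richness between surveys, and a minority of impacted stations carrying
a planted fine-sand enrichment.

Faunal group membership is driven by a soft rule on current speed and the
mud/sand tendencies of the station, so environment-to-fauna analyses (BIOENV,
PERMANOVA) have a known planted signal: AvCur and Sand strongly, Mud more
weakly. Groups whose sediments are gravel-rich are given more characteristic
families, so richness rises with gravel across groups while being flat within
a group.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from rsmp.datamodel import SampleTable
from rsmp.envelopes import SedimentEnvelope
from rsmp.change_test import TestSample
from rsmp.sieves import WENTWORTH_FRACTIONS

#: How each Wentworth fraction of a generated composition is spread over the
#: standard sieve ladder when emitting raw PSD rows (retained-on percentages).
FRACTION_TO_SIEVES = {
    "S/C": {0.0: 1.0},
    "fS": {0.063: 0.45, 0.125: 0.55},
    "mS": {0.25: 1.0},
    "cS": {0.5: 0.6, 1.0: 0.4},
    "fG": {2.0: 1.0},
    "mG": {4.0: 0.5, 8.0: 0.5},
    "cG": {16.0: 0.7, 32.0: 0.3},
}

ENV_VARS = ("Sal", "Temp", "Chl_a", "SPM", "Depth", "WOV", "AvCur", "Stress",
            "Gravel", "Sand", "Mud", "Lat")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror a desk-scale regional monitoring campaign: 20 surveys of
    30 stations, 12 faunal assemblages over 150 families (20 of them colonial,
    presence-coded), 10 physical-environment groups, overdispersed counts
    (negative-binomial size 5), well-separated assemblages, ~8% impacted
    stations and 70% of surveys recording colonial taxa.
    """

    n_surveys: int = 20
    stations_per_survey: int = 30
    k_fauna: int = 12
    k_physical: int = 10
    n_families: int = 150
    n_colonial: int = 20
    group_separation: float = 1.0
    nb_dispersion: float = 5.0
    sediment_sigma: float = 0.35
    env_effect_weights: tuple[float, float, float] = (6.1, 3.0, 4.0)  # AvCur, Mud, Sand
    survey_richness_sd: float = 0.10
    impacted_fraction: float = 0.08
    impact_fs_shift: float = 2.5  # logit shift on fine sand for impacted stations
    colonial_survey_fraction: float = 0.7
    n_psd_violations: int = 4  # planted total-tolerance and top-sieve failures (each)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_fauna > self.n_surveys * self.stations_per_survey:
            raise ValueError("more faunal groups than stations")
        if self.k_physical > self.n_surveys * self.stations_per_survey:
            raise ValueError("more physical groups than stations")
        if not 0 <= self.impacted_fraction < 1:
            raise ValueError("impacted_fraction must be in [0, 1)")
        for name in ("n_surveys", "stations_per_survey", "k_fauna", "k_physical",
                     "n_families", "n_colonial"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside the dataset."""

    faunal_group: np.ndarray  # per sample, 1..k_fauna
    physical_group: np.ndarray  # per sample, 1..k_physical
    impacted: np.ndarray  # per sample, bool
    sediment_mean: np.ndarray  # per sample, the 7-fraction mean used (%)
    centroids: np.ndarray  # k_fauna x n_families, fourth-root space
    group_anchors: np.ndarray  # k_fauna x 3 anchors in (AvCur, mud, sand) space
    survey_detection: dict[str, float]
    planted_total_violations: list[str] = field(default_factory=list)
    planted_top_sieve_violations: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("faunal_group", "physical_group", "impacted", "sediment_mean",
                  "centroids", "group_anchors"):
            d[k] = np.asarray(d[k]).tolist()
        return json.dumps(d)


@dataclass
class SyntheticDataset:
    table: SampleTable
    exposures: pd.DataFrame
    truth: PlantedTruth
    config: GeneratorConfig


def _softmax_pct(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return 100.0 * e / e.sum(axis=-1, keepdims=True)


def _faunal_anchors(k: int, w: np.ndarray) -> np.ndarray:
    """k anchor points in (current, mud, sand) driver space.

    Anchors are the centroids of a k-means partition of a standard-normal
    probe cloud in the ``w``-weighted space, so the implied station partition
    is roughly balanced and every driver axis separates several groups. The
    geometry is a fixed design feature — like a real regional baseline, the
    assemblage structure is one property of nature, identical across
    replicate datasets — so a private fixed-seed generator is used rather
    than the dataset seed.
    """
    from rsmp.clustering import _macqueen

    rng = np.random.default_rng(799241)
    probe = rng.standard_normal((3000, 3)) * w
    best = None
    for _ in range(5):
        init = probe[rng.choice(len(probe), size=k, replace=False)]
        centres, labels = _macqueen(probe, init, max_iter=30)
        wss = float(((probe - centres[labels]) ** 2).sum())
        if best is None or wss < best[0]:
            best = (wss, centres)
    return best[1] / w


def generate(config: GeneratorConfig, out_dir=None) -> SyntheticDataset:
    """Generate a dataset (and its planted truth) under the given conditions.

    When ``out_dir`` is given, the CSV layout read by :func:`rsmp.io.read_dataset`
    is written there along with ``exposures.csv`` and ``truth.json``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    # population structure (the regional "nature" being sampled: physical
    # regions, assemblage geometry, taxon pools, sediment signatures) is a
    # fixed design shared by all replicate datasets; only station sampling
    # and noise vary with the dataset seed
    nature = np.random.default_rng(799241)
    n = cfg.n_surveys * cfg.stations_per_survey
    surveys = [f"S{j + 1:02d}" for j in range(cfg.n_surveys)]
    survey_of = np.repeat(np.arange(cfg.n_surveys), cfg.stations_per_survey)
    sample_ids = [
        f"{surveys[survey_of[i]]}_{i % cfg.stations_per_survey + 1:03d}" for i in range(n)
    ]

    # --- physical environment -------------------------------------------------
    phys_group = rng.integers(0, cfg.k_physical, size=n)
    phys_centroids = nature.standard_normal((cfg.k_physical, 6)) * 1.6
    zs = phys_centroids[phys_group] + rng.standard_normal((n, 6)) * 0.8
    zs = zs / np.sqrt(1.6**2 + 0.8**2)  # unit-scale latent scores
    e = rng.standard_normal((n, 5))

    sal = 34.2 + 0.6 * zs[:, 0]
    spm = np.exp(0.8 + 0.75 * zs[:, 1] + 0.35 * e[:, 4])
    depth = np.exp(3.2 + 0.5 * zs[:, 2])
    wov = np.clip(0.45 + 0.16 * zs[:, 3], 0.02, None)
    lat = np.clip(54.0 + 2.5 * (0.95 * zs[:, 5] + 0.31 * e[:, 3]), 48.0, 61.0)
    temp = 11.5 + 1.9 * (-0.85 * zs[:, 5] - 0.35 * zs[:, 2] + 0.4 * e[:, 0])
    chl_a = np.exp(0.5 + 0.9 * (0.8 * zs[:, 1] + 0.35 * zs[:, 0] + 0.3 * e[:, 1]))
    stress = np.clip(
        1.2 + 0.9 * (0.76 * zs[:, 4] + 0.44 * zs[:, 3] + 0.45 * e[:, 2]), 0.01, None
    )

    # --- faunal group assignment (soft rule on AvCur / mud / sand drivers) ----
    w = np.asarray(cfg.env_effect_weights, dtype=float)
    w = w / w.max()
    mud_latent = rng.standard_normal(n)
    sand_latent = rng.standard_normal(n)
    drivers = np.column_stack([
        zs[:, 4] / np.std(zs[:, 4]),
        mud_latent,
        sand_latent,
    ])
    # rank-gaussianise each axis so the station cloud matches the anchor
    # probe's margins and no assemblage collapses to a handful of stations
    from scipy.stats import norm, rankdata as _rankdata

    drivers = norm.ppf((_rankdata(drivers, axis=0) - 0.5) / n)
    anchors = _faunal_anchors(cfg.k_fauna, w)
    d2 = (((drivers * w)[:, None, :] - (anchors * w)[None, :, :]) ** 2).sum(-1)
    soft = d2 + 0.25 * rng.standard_normal(d2.shape) ** 2
    fauna_group = soft.argmin(axis=1)
    # a station's measured current reflects its assemblage's current regime
    # (the group anchor) plus within-regime spread, keeping AvCur informative
    # about assemblage identity at the group level like the sediment proxies
    avcur = np.clip(
        0.50
        + 0.18
        * (0.5 * anchors[fauna_group, 0] + 0.5 * drivers[:, 0]
           + 0.15 * rng.standard_normal(n)),
        0.02,
        None,
    )

    # --- sediments: logistic-normal per faunal(-physical) group ---------------
    # The mud axis trades mud mainly against gravel and the sand axis trades
    # sand against gravel, so gravel carries the largest variance of the
    # closed gravel/sand/mud trio (it is the first of the trio that VIF
    # pruning discards) while sand still separates the faunal groups.
    base_logits = np.log(np.array([0.02, 0.08, 0.22, 0.28, 0.18, 0.12, 0.10]))
    u_mud = np.array([0.7, 0.45, 0.25, 0.1, -0.45, -0.5, -0.5])
    u_sand = np.array([-0.2, 0.9, 1.1, 0.6, -1.4, -1.6, -1.7])
    # group-level sediment signature from the anchors (per-axis normalised)
    a = anchors / np.abs(anchors).max(axis=0)
    group_logits = base_logits[None, :] + 1.6 * (
        a[:, 1:2] * u_mud[None, :] + a[:, 2:3] * u_sand[None, :]
    )
    phys_tweak = nature.standard_normal((cfg.k_physical, 7)) * 0.12
    # each sample's own mud/sand tendencies also reach its sediments, so the
    # realised Mud/Sand percentages track the drivers of assemblage identity
    # silt/clay is the most measurement-variable fraction, so its logit noise
    # is inflated relative to the sand and gravel fractions
    frac_sigma = cfg.sediment_sigma * np.array([1.7, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
    logits = (
        group_logits[fauna_group]
        + 0.30 * mud_latent[:, None] * u_mud
        + 0.75 * sand_latent[:, None] * u_sand
        + phys_tweak[phys_group]
        + rng.standard_normal((n, 7)) * frac_sigma[None, :]
    )

    # impacted stations: dredged recently, planted fine-sand enrichment
    n_impacted = int(round(cfg.impacted_fraction * n))
    impacted_idx = rng.choice(n, size=n_impacted, replace=False)
    impacted = np.zeros(n, dtype=bool)
    impacted[impacted_idx] = True
    logits[impacted, 1] += cfg.impact_fs_shift

    composition = _softmax_pct(logits)
    sediment_mean = _softmax_pct(group_logits[fauna_group])

    # --- fauna: NB counts around fourth-root centroids ------------------------
    group_gravel = _softmax_pct(group_logits)[:, 4:7].sum(1)
    gravel_pref = (group_gravel - group_gravel.min()) / max(
        float(np.ptp(group_gravel)), 1e-9
    )  # 0..1 per group
    centroids = np.zeros((cfg.k_fauna, cfg.n_families))
    base_root = nature.gamma(1.2, 0.25, size=cfg.n_families) * 0.4
    n_char = np.minimum(
        (16 + np.round(20 * gravel_pref)).astype(int), cfg.n_families
    )
    for g in range(cfg.k_fauna):
        members = nature.choice(cfg.n_families, size=n_char[g], replace=False)
        centroids[g] = base_root
        centroids[g, members] = base_root[members] + cfg.group_separation * (
            1.1 + nature.gamma(2.0, 0.5, size=n_char[g])
        )
    # niche turnover along each driver gradient: per axis, a band of families
    # responds unimodally to the group's position on that axis, so assemblages
    # from similar conditions share taxa and faunal similarity is graded along
    # the planted drivers (in proportion to their configured weights) rather
    # than flat between groups
    n_niche = min(12, (cfg.n_families - cfg.n_colonial) // 3)
    niche_centres = np.linspace(-1.4, 1.4, n_niche)
    free = nature.permutation(cfg.n_families - cfg.n_colonial)
    niche_amp = (1.0, 0.5, 1.45)  # current, mud, sand gradient strengths
    niche_boost = np.zeros((n, cfg.n_families))
    for axis in range(3):
        fams = free[axis * n_niche:(axis + 1) * n_niche]
        # group-level component (enters the planted centroids)
        g_resp = np.exp(
            -((anchors[:, axis:axis + 1] - niche_centres[None, :]) ** 2)
            / (2 * 0.45**2)
        )
        centroids[:, fams] += cfg.group_separation * 0.9 * niche_amp[axis] * g_resp
        # station-level refinement on the current axis only: taxa respond to
        # the station's own current regime, so faunal composition also varies
        # continuously with current within groups. The sediment axes stay
        # group-level, keeping within-group richness independent of gravel.
        if axis == 0:
            s_resp = np.exp(
                -((drivers[:, axis:axis + 1] - niche_centres[None, :]) ** 2)
                / (2 * 0.45**2)
            )
            niche_boost[:, fams] += (
                cfg.group_separation * 0.9 * niche_amp[axis]
                * (s_resp - g_resp[fauna_group])
            )

    detection = np.clip(
        rng.normal(0.85, cfg.survey_richness_sd, size=cfg.n_surveys), 0.4, 1.0
    )
    root_mean = np.clip(centroids[fauna_group] + niche_boost, 0.0, None)
    lam = root_mean ** 4 * detection[survey_of][:, None]
    r = cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + np.maximum(lam, 1e-12)))

    families = [f"Fam{j + 1:03d}" for j in range(cfg.n_families)]
    colonial = families[cfg.n_families - cfg.n_colonial:]
    col_idx = np.arange(cfg.n_families - cfg.n_colonial, cfg.n_families)
    presence_p = 1.0 - np.exp(-0.5 * lam[:, col_idx])
    counts[:, col_idx] = (rng.random(presence_p.shape) < presence_p).astype(int)

    colonial_surveys = rng.random(cfg.n_surveys) < cfg.colonial_survey_fraction
    colonials_recorded = colonial_surveys[survey_of]
    counts[np.ix_(~colonials_recorded, col_idx)] = 0

    # --- PSD emission with planted violations ---------------------------------
    totals = 100.0 + rng.uniform(-0.6, 0.6, size=n)
    clean = np.flatnonzero(~impacted)
    viol = rng.choice(clean, size=min(2 * cfg.n_psd_violations, len(clean)), replace=False)
    total_viol = viol[: cfg.n_psd_violations]
    top_viol = viol[cfg.n_psd_violations: 2 * cfg.n_psd_violations]
    totals[total_viol] = np.where(rng.random(len(total_viol)) < 0.5, 97.5, 102.3)

    psd_rows = []
    apertures = [64.0, 32.0, 16.0, 8.0, 4.0, 2.0, 1.0, 0.5, 0.25, 0.125, 0.063, 0.0]
    for i in range(n):
        scaled = composition[i] * totals[i] / 100.0
        row = {ap: 0.0 for ap in apertures}
        for f, pct in zip(WENTWORTH_FRACTIONS, scaled):
            for ap, share in FRACTION_TO_SIEVES[f].items():
                row[ap] += pct * share
        if i in top_viol:
            # shunt some coarse-gravel mass onto the topmost sieve
            moved = max(row[32.0] * 0.5, 0.5)
            row[32.0] = max(row[32.0] - moved, 0.0)
            row[64.0] += moved
        for ap in apertures:
            psd_rows.append((sample_ids[i], ap, row[ap]))
    psd = pd.DataFrame(psd_rows, columns=["sample_id", "aperture_mm", "percent"])

    # --- exposures and treatment ----------------------------------------------
    recovery = 4.0
    years_since = np.full(n, np.nan)
    years_since[impacted] = rng.uniform(0.0, recovery - 0.5, size=n_impacted)
    recovered = rng.random(n) < 0.3
    recovered &= ~impacted
    years_since[recovered] = rng.uniform(recovery + 0.5, 15.0, size=int(recovered.sum()))
    exposures = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "years_since_last_dredging": years_since,
            "landscape_recovery_years": recovery,
        }
    )
    treatment = np.where(impacted, "impacted", "reference")

    # --- assemble tables -------------------------------------------------------
    went = pd.DataFrame(composition * totals[:, None] / 100.0,
                        columns=list(WENTWORTH_FRACTIONS), index=sample_ids)
    env = pd.DataFrame(
        {
            "Sal": sal, "Temp": temp, "Chl_a": chl_a, "SPM": spm, "Depth": depth,
            "WOV": wov, "AvCur": avcur, "Stress": stress,
            # closed percentages (of the 7-fraction total), as PSD labs report
            # them: Gravel + Sand + Mud = 100 exactly
            "Gravel": composition[:, 4:7].sum(1),
            "Sand": composition[:, 1:4].sum(1),
            "Mud": composition[:, 0],
            "Lat": lat,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    start = pd.Timestamp("2005-03-01")
    dates = [
        (start + pd.DateOffset(months=int(7 * survey_of[i]) % 120, days=int(i % 28)))
        .strftime("%Y-%m-%d")
        for i in range(n)
    ]
    factors = pd.DataFrame(
        {
            "survey_id": [surveys[s] for s in survey_of],
            "lat": lat,
            "lon": rng.uniform(-5.0, 2.5, size=n),
            "gear": "Hamon_0.1",
            "sieve_mm": 1.0,
            "date": dates,
            "depth_m": depth,
            "treatment": treatment,
            "colonials_recorded": colonials_recorded,
            "same_deployment": True,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    abundance = pd.DataFrame(counts, columns=families,
                             index=pd.Index(sample_ids, name="sample_id"))
    table = SampleTable(
        factors=factors, abundance=abundance, psd=psd, env=env,
        colonial_taxa=frozenset(colonial),
    )
    truth = PlantedTruth(
        faunal_group=fauna_group + 1,
        physical_group=phys_group + 1,
        impacted=impacted,
        sediment_mean=sediment_mean,
        centroids=centroids,
        group_anchors=anchors,
        survey_detection={surveys[j]: float(detection[j]) for j in range(cfg.n_surveys)},
        planted_total_violations=[sample_ids[i] for i in total_viol],
        planted_top_sieve_violations=[sample_ids[i] for i in top_viol],
    )
    ds = SyntheticDataset(table=table, exposures=exposures, truth=truth, config=cfg)
    if out_dir is not None:
        from rsmp.io import write_dataset

        out = Path(out_dir)
        write_dataset(table, out)
        exposures.to_csv(out / "exposures.csv", index=False)
        (out / "truth.json").write_text(truth.to_json())
        (out / "config.json").write_text(json.dumps(asdict(cfg)))
    return ds


def generate_test_batch(
    envelope: SedimentEnvelope,
    n: int,
    shift_spec: dict[str, float] | None = None,
    seed: int = 0,
    ensure_valid: bool = True,
) -> list[TestSample]:
    """Multivariate-normal monitoring samples around an envelope.

    ``shift_spec`` maps fraction names to shifts in multiples of that
    fraction's envelope standard deviation (e.g. ``{"fS": 3.0}`` for power
    studies); with no shift the batch is a type-I calibration set. With
    ``ensure_valid`` the draws are projected to non-negative values and
    re-closed to the envelope's mean total; pass ``False`` to keep the exact
    normal draws (as assumed by the test's reference distribution).
    """
    rng = np.random.default_rng(seed)
    mean = envelope.mean.copy()
    sd = np.sqrt(np.diag(envelope.cov))
    if shift_spec:
        for frac, mult in shift_spec.items():
            i = WENTWORTH_FRACTIONS.index(frac)
            mean[i] += mult * sd[i]
    w, V = np.linalg.eigh(envelope.cov)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("covariance is not positive semi-definite")
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)
    draws = mean[None, :] + rng.standard_normal((n, 7)) @ L.T
    if ensure_valid:
        draws = np.clip(draws, 0.0, None)
        sums = draws.sum(axis=1, keepdims=True)
        target = envelope.mean.sum()
        draws = np.where(sums > 0, draws * target / sums, draws)
    return [
        TestSample(
            sample_id=f"sim_{i + 1:05d}", v=draws[i], group=envelope.key.label,
            validate=ensure_valid,
        )
        for i in range(n)
    ]
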