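"""End-to-end pipeline orchestration with a run manifest.

Stages run in a fixed order — ingest, filter, faunal clustering, physical
clustering, community statistics, environment analysis, sediment envelopes,
change test, gravel regression — and every intermediate is persisted as CSV
or JSON so any stage can be inspected or re-run from disk. The manifest
records the config hash, seeds, per-stage timings and a digest of every
output file, so a rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import rsmp
from rsmp import io as rio
from rsmp.change_test import batch_assess, results_to_frame, TestSample
from rsmp.clustering import centre_dendrogram, fit_kmeans, fourth_root
from rsmp.community import compute_indices, simper, summarise_groups
from rsmp.environment import (
    balanced_subsample,
    bioenv,
    permanova,
    transform_env,
    vif_prune,
)
from rsmp.envelopes import (
    GroupKey,
    NeedsAugmentation,
    SedimentEnvelope,
    augment_from_dendrogram,
    fit_envelope,
    make_groups,
    mvdisp,
    wentworth_summary,
)
from rsmp.filters import filter_faunal_subset, filter_sediment_subset
from rsmp.gravel import per_group_slopes, slopes_to_frame
from rsmp.sieves import WENTWORTH_FRACTIONS
from scipy.spatial.distance import pdist


DEFAULT_CONFIG = {
    "seed": 0,
    "k_fauna": 12,
    "k_physical": 10,
    "n_restarts": 10,
    "min_n_envelope": 30,
    "n_per_group": None,  # balanced subsample size; None = min group size
    "bioenv_max_size": 4,
    "n_perm": 199,
    "alpha": 0.05,
    "vif_threshold": 2.5,
    "physical_vars": ["Sal", "Temp", "Chl_a", "SPM", "Depth", "WOV", "AvCur", "Stress"],
    "physical_log_vars": ["SPM", "Depth", "Stress"],
    "env_log_vars": ["SPM", "Depth", "Mud"],
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = rsmp.__version__
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, seconds: float, status: str = "ok", reason: str = ""):
        self.stages.append(
            {"stage": stage, "seconds": round(seconds, 3), "status": status,
             **({"reason": reason} if reason else {})}
        )

    def digest(self, path: Path) -> None:
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "version": self.version, "stages": self.stages, "outputs": self.outputs},
            indent=1,
        )


def run_pipeline(data_dir, out_dir, config: dict | None = None) -> RunManifest:
    """Run all stages on a dataset directory; write outputs + manifest.

    ``data_dir`` must hold the CSV layout of :func:`rsmp.io.read_dataset`
    (as written by the generator or `rsmp simulate`). A stage that cannot run
    (e.g. no environment table) is recorded as skipped with its reason; a
    stage failure stops the run with the manifest listing completed stages.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        seed=int(cfg["seed"]),
    )

    def save_csv(frame: pd.DataFrame, name: str, **kw):
        path = out / name
        frame.to_csv(path, **kw)
        manifest.digest(path)

    def save_text(text: str, name: str):
        path = out / name
        path.write_text(text)
        manifest.digest(path)

    t0 = time.perf_counter()
    table = rio.read_written_dataset(data_dir)
    manifest.record("ingest", time.perf_counter() - t0)

    t0 = time.perf_counter()
    faunal_table, faunal_report = filter_faunal_subset(table)
    sed_table, sed_report = filter_sediment_subset(table)
    save_text(json.dumps([faunal_report.as_dict(), sed_report.as_dict()], indent=1),
              "filter_report.json")
    manifest.record("filter", time.perf_counter() - t0)

    t0 = time.perf_counter()
    root = fourth_root(faunal_table.abundance.to_numpy())
    fauna_model = fit_kmeans(
        root, cfg["k_fauna"], seed=cfg["seed"], n_restarts=cfg["n_restarts"],
        transform_spec="fourth-root", columns=faunal_table.abundance.columns,
    )
    save_text(fauna_model.to_json(), "fauna_model.json")
    fauna_codes = pd.Series(
        [fauna_model.code_of(l) for l in fauna_model.labels],
        index=faunal_table.sample_ids, name="faunal_code",
    )
    manifest.record("cluster_fauna", time.perf_counter() - t0)

    t0 = time.perf_counter()
    env_ok = table.env is not None and not table.env.empty
    if env_ok:
        phys_in = transform_env(
            table.env.loc[faunal_table.sample_ids, cfg["physical_vars"]],
            log_vars=cfg["physical_log_vars"],
        )
        phys_model = fit_kmeans(
            phys_in.to_numpy(), cfg["k_physical"], seed=cfg["seed"] + 1,
            n_restarts=cfg["n_restarts"], transform_spec="log+z-score",
            columns=phys_in.columns,
        )
        save_text(phys_model.to_json(), "physical_model.json")
        phys_labels = pd.Series(
            phys_model.labels, index=faunal_table.sample_ids, name="physical_code"
        )
        manifest.record("cluster_physical", time.perf_counter() - t0)
    else:
        phys_model = None
        phys_labels = None
        manifest.record("cluster_physical", time.perf_counter() - t0,
                        "skipped", "no environment table")

    t0 = time.perf_counter()
    indices = compute_indices(faunal_table.abundance)
    save_csv(indices, "indices.csv", index_label="sample_id")
    summary = summarise_groups(indices, fauna_codes)
    save_csv(summary, "group_summary.csv")
    transformed = pd.DataFrame(
        root, index=faunal_table.sample_ids, columns=faunal_table.abundance.columns
    )
    simper_rows = []
    for g, entries in simper(transformed, fauna_codes).items():
        for e in entries:
            simper_rows.append(
                {"group": g, "taxon": e.taxon,
                 "contribution_pct": e.mean_contribution_pct,
                 "cumulative_pct": e.cumulative_pct}
            )
    save_csv(pd.DataFrame(simper_rows), "simper.csv", index=False)
    manifest.record("community_stats", time.perf_counter() - t0)

    t0 = time.perf_counter()
    if env_ok:
        env = table.env.loc[faunal_table.sample_ids]
        retained, trace = vif_prune(env, threshold=cfg["vif_threshold"])
        env_t = transform_env(env[retained], log_vars=cfg["env_log_vars"])
        counts = fauna_codes.value_counts()
        n_per = cfg["n_per_group"] or int(counts.min())
        idx = balanced_subsample(fauna_codes.to_numpy(), n_per, seed=cfg["seed"] + 2)
        sub_bc = pdist(root[idx], metric="braycurtis")
        bres = bioenv(sub_bc, env_t.iloc[idx], max_size=cfg["bioenv_max_size"])
        save_csv(
            pd.DataFrame(
                [{"subset": ", ".join(b.subset), "size": b.size, "rho": b.rho,
                  "best": b.best_overall} for b in bres]
            ),
            "bioenv.csv", index=False,
        )
        best_vars = [b for b in bres if b.best_overall][0].subset
        pres = permanova(
            sub_bc, env_t.iloc[idx][list(best_vars)],
            n_perm=cfg["n_perm"], seed=cfg["seed"] + 3,
        )
        save_csv(pres.as_frame(), "permanova.csv", index=False)
        save_text(json.dumps({"vif_removed": trace, "retained": retained}), "vif.json")
        manifest.record("environment", time.perf_counter() - t0)
    else:
        manifest.record("environment", time.perf_counter() - t0,
                        "skipped", "no environment table")

    t0 = time.perf_counter()
    envelope_store: dict[str, SedimentEnvelope] = {}
    if sed_table.psd is not None and len(sed_table):
        went = sed_table.wentworth()[list(WENTWORTH_FRACTIONS)]
        sed_fauna = fauna_codes.reindex(went.index)
        known = sed_fauna.dropna().index
        went = went.loc[known]
        sed_fauna = sed_fauna.loc[known]
        if phys_labels is not None:
            sed_phys = phys_labels.reindex(known)
            keys = make_groups(sed_fauna, sed_phys)
        else:
            keys = make_groups(sed_fauna)
        key_labels = pd.Series([k.label for k in keys], index=known)
        disp = mvdisp(went, key_labels)
        dend = centre_dendrogram(phys_model) if phys_model is not None else None
        summaries = []
        for label in sorted(key_labels.unique()):
            key = GroupKey.parse(label)
            members = went[key_labels == label]
            try:
                env_fit = fit_envelope(members, key, min_n=cfg["min_n_envelope"])
            except NeedsAugmentation:
                if dend is None or key.physical_code is None:
                    continue
                pool = went[sed_fauna == key.faunal_code].copy()
                pool["physical_code"] = sed_phys.loc[pool.index]
                try:
                    aug, provenance = augment_from_dendrogram(
                        key, dend, pool, min_n=cfg["min_n_envelope"]
                    )
                except NeedsAugmentation:
                    continue
                env_fit = fit_envelope(
                    aug[list(WENTWORTH_FRACTIONS)], key, min_n=cfg["min_n_envelope"]
                )
                env_fit.augmented_from = provenance
            env_fit.mvdisp = float(disp.get(label)) if label in disp.index else None
            envelope_store[label] = env_fit
            summaries.append(wentworth_summary(env_fit))
        save_text(
            json.dumps([e.to_dict() for e in envelope_store.values()], indent=1),
            "envelopes.json",
        )
        save_csv(pd.DataFrame(summaries), "envelope_summary.csv", index=False)
        manifest.record("envelopes", time.perf_counter() - t0)
    else:
        manifest.record("envelopes", time.perf_counter() - t0,
                        "skipped", "no sediment subset")

    t0 = time.perf_counter()
    if envelope_store:
        went_all = table.wentworth()
        monitor = went_all.loc[
            [i for i in table.sample_ids
             if table.factors.loc[i, "treatment"] == "impacted"
             and i in went_all.index and i in fauna_codes.index]
        ]
        samples = []
        for sid, row in monitor.iterrows():
            f = fauna_codes.loc[sid]
            p = int(phys_labels.loc[sid]) if phys_labels is not None else None
            key = GroupKey(str(f), p)
            label = key.label if key.label in envelope_store else key.faunal_code
            samples.append(
                TestSample(sample_id=sid, v=row[list(WENTWORTH_FRACTIONS)].to_numpy(),
                           group=label)
            )
        report = batch_assess(samples, envelope_store, alpha=cfg["alpha"])
        save_csv(results_to_frame(report), "change_test.csv", index=False)
        save_text(json.dumps(report["summary"], indent=1), "change_test_summary.json")
        manifest.record("change_test", time.perf_counter() - t0)
    else:
        manifest.record("change_test", time.perf_counter() - t0,
                        "skipped", "no envelopes")

    t0 = time.perf_counter()
    if env_ok:
        gravel = table.env.loc[faunal_table.sample_ids, "Gravel"].clip(0, 100)
        fits = per_group_slopes(
            indices, gravel, faunal_table.factors["survey_id"], fauna_codes
        )
        save_csv(slopes_to_frame(fits), "gravel_slopes.csv")
        manifest.record("gravel_regression", time.perf_counter() - t0)
    else:
        manifest.record("gravel_regression", time.perf_counter() - t0,
                        "skipped", "no environment table")

    save_text(manifest.to_json(), "manifest.json")
    return manifest
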