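"""CSV reading/writing for the four-table dataset layout.

Files are plain UTF-8 CSVs with a header row:

* abundance matrix — wide, first column ``sample_id``, remaining columns one
  per family; colonial families may be declared in a ``colonial_taxa`` sidecar
  column list in the config or inferred from a ``#colonial:`` marker row (not
  used by default).
* factors — one row per sample with the metadata fields.
* psd — long format: ``sample_id, aperture_mm, percent``.
* env — one row per sample, environmental variables.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from rsmp.datamodel import SampleTable, ValidationError


def read_dataset(
    matrix_path,
    factors_path,
    psd_path=None,
    env_path=None,
    colonial_taxa=(),
) -> SampleTable:
    """Read and join the dataset; every sample needs a faunal record.

    Samples present in the abundance matrix but missing from the factors table
    (or vice versa) raise a :class:`ValidationError` naming the ids. Missing
    PSD or environmental rows are permitted — those samples simply carry no
    sediment/environment data.
    """
    abundance = pd.read_csv(matrix_path, index_col="sample_id")
    factors = pd.read_csv(factors_path, index_col="sample_id")
    for frame, name in ((abundance, "matrix"), (factors, "factors")):
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id in {name} file: {dups}")
    only_matrix = abundance.index.difference(factors.index)
    if len(only_matrix):
        raise ValidationError(
            f"factors file missing sample ids: {only_matrix.tolist()[:10]}"
        )
    only_factors = factors.index.difference(abundance.index)
    if len(only_factors):
        raise ValidationError(
            f"samples lack a faunal record: {only_factors.tolist()[:10]}"
        )
    if "colonials_recorded" in factors:
        factors["colonials_recorded"] = factors["colonials_recorded"].astype(bool)
    if "same_deployment" in factors:
        factors["same_deployment"] = factors["same_deployment"].astype(bool)

    psd = None
    if psd_path is not None:
        psd = pd.read_csv(psd_path)
        required = {"sample_id", "aperture_mm", "percent"}
        if not required <= set(psd.columns):
            raise ValidationError(f"psd file must have columns {sorted(required)}")
    env = None
    if env_path is not None:
        env = pd.read_csv(env_path, index_col="sample_id")

    return SampleTable(
        factors=factors,
        abundance=abundance,
        psd=psd,
        env=env,
        colonial_taxa=frozenset(colonial_taxa),
    )


def write_dataset(table: SampleTable, out_dir) -> dict[str, str]:
    """Write the table back to the CSV layout; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    ab = table.abundance.copy()
    ab.index.name = "sample_id"
    ab.to_csv(out / "matrix.csv")
    paths["matrix"] = str(out / "matrix.csv")
    fa = table.factors.copy()
    fa.index.name = "sample_id"
    fa.to_csv(out / "factors.csv")
    paths["factors"] = str(out / "factors.csv")
    if table.psd is not None:
        table.psd.to_csv(out / "psd.csv", index=False)
        paths["psd"] = str(out / "psd.csv")
    if table.env is not None:
        env = table.env.copy()
        env.index.name = "sample_id"
        env.to_csv(out / "env.csv")
        paths["env"] = str(out / "env.csv")
    if table.colonial_taxa:
        meta = {"colonial_taxa": sorted(table.colonial_taxa)}
        (out / "meta.json").write_text(json.dumps(meta, indent=1))
        paths["meta"] = str(out / "meta.json")
    return paths


def read_written_dataset(in_dir) -> SampleTable:
    """Re-read a dataset written by :func:`write_dataset`."""
    p = Path(in_dir)
    colonial = ()
    if (p / "meta.json").exists():
        colonial = json.loads((p / "meta.json").read_text())["colonial_taxa"]
    return read_dataset(
        p / "matrix.csv",
        p / "factors.csv",
        p / "psd.csv" if (p / "psd.csv").exists() else None,
        p / "env.csv" if (p / "env.csv").exists() else None,
        colonial_taxa=colonial,
    )
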