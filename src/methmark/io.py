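"""Plain-text readers and writers for the pipeline's tabular formats.

Formats: beta-matrix TSV (probes as rows, samples as columns), probe
annotation TSV (probe_id, gene, region), sample metadata TSV, long-format
Cq CSV (sample_id, assay, role, replicate, cq), plasma-series CSV, survival
CSV, and a run-manifest JSON recording config, seed and input digests.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .arrays import ProbeBetaMatrix
from .plasma import PlasmaSeries
from .qpcr import MAX_CYCLES_DEFAULT, QpcrMeasurement

__all__ = [
    "write_beta_bundle",
    "read_beta_bundle",
    "write_cq_table",
    "read_cq_table",
    "write_plasma_table",
    "read_plasma_table",
    "write_survival_table",
    "read_survival_table",
    "write_manifest",
    "file_digest",
]


def write_beta_bundle(matrix: ProbeBetaMatrix, out_dir, prefix: str) -> dict:
    """Write beta matrix + probe annotation + sample metadata TSVs; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out / f"{prefix}_beta.tsv",
        "probes": out / f"{prefix}_probes.tsv",
        "samples": out / f"{prefix}_samples.tsv",
    }
    matrix.beta.to_csv(paths["beta"], sep="\t", index_label="probe_id", float_format="%.6g")
    matrix.probes.to_csv(paths["probes"], sep="\t")
    matrix.samples.to_csv(paths["samples"], sep="\t")
    return {k: str(v) for k, v in paths.items()}


def read_beta_bundle(beta_path, probes_path, samples_path) -> ProbeBetaMatrix:
    beta = pd.read_csv(beta_path, sep="\t", index_col="probe_id")
    probes = pd.read_csv(probes_path, sep="\t", index_col="probe_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id", keep_default_na=False)
    return ProbeBetaMatrix(beta, probes, samples)


def write_cq_table(measurements: list[QpcrMeasurement], path) -> None:
    """Long-format Cq CSV: sample_id, assay, role[target|reference], replicate, cq."""
    rows = []
    for m in measurements:
        for role, assay, cqs in (
            ("target", m.target, m.target_cq),
            ("reference", m.reference, m.reference_cq),
        ):
            for i, cq in enumerate(cqs, start=1):
                rows.append((m.sample_id, assay, role, i, cq))
    pd.DataFrame(rows, columns=["sample_id", "assay", "role", "replicate", "cq"]).to_csv(
        path, index=False
    )


def read_cq_table(path, max_cycles: float = MAX_CYCLES_DEFAULT) -> list[QpcrMeasurement]:
    df = pd.read_csv(path)
    required = {"sample_id", "assay", "role", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    out = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        tgt = grp[grp["role"] == "target"]
        ref = grp[grp["role"] == "reference"]
        if tgt.empty or ref.empty:
            raise ValueError(f"sample {sample_id!r} lacks a target or reference assay")
        out.append(
            QpcrMeasurement(
                sample_id=str(sample_id),
                target=str(tgt["assay"].iloc[0]),
                reference=str(ref["assay"].iloc[0]),
                target_cq=tgt.sort_values("replicate")["cq"].to_numpy(),
                reference_cq=ref.sort_values("replicate")["cq"].to_numpy(),
                max_cycles=max_cycles,
            )
        )
    return out


def write_plasma_table(cohort: list[PlasmaSeries], path) -> None:
    """Plasma-series CSV, one row per patient-timepoint."""
    rows = []
    for s in cohort:
        for j in range(len(s.months)):
            rows.append(
                (
                    s.patient_id, s.months[j], s.levels[j], s.cea[j], s.ca153[j],
                    s.outcome, s.therapy,
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "patient_id", "timepoint_month", "ratio", "cea_ng_ml", "ca153_u_ml",
            "outcome", "therapy",
        ],
    ).to_csv(path, index=False)


def read_plasma_table(path) -> list[PlasmaSeries]:
    df = pd.read_csv(path)
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("timepoint_month")
        out.append(
            PlasmaSeries(
                patient_id=str(pid),
                months=grp["timepoint_month"].to_numpy(dtype=float),
                levels=grp["ratio"].to_numpy(dtype=float),
                cea=grp["cea_ng_ml"].to_numpy(dtype=float),
                ca153=grp["ca153_u_ml"].to_numpy(dtype=float),
                outcome=str(grp["outcome"].iloc[0]),
                therapy=str(grp["therapy"].iloc[0]),
            )
        )
    return out


def write_survival_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_survival_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"time_months", "event"} <= set(df.columns):
        raise ValueError("survival table needs time_months and event columns")
    return df


def file_digest(path) -> str:
    """SHA-256 of a file's bytes."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, subcommand: str, config, seed, inputs: dict | None = None) -> str:
    """Write the run manifest JSON (config snapshot, input digests, seed, version)."""
    from . import __version__

    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config_snapshot = dataclasses.asdict(config)
    else:
        config_snapshot = config
    manifest = {
        "subcommand": subcommand,
        "config": _jsonable(config_snapshot),
        "seed": seed,
        "inputs": {k: file_digest(v) for k, v in (inputs or {}).items()},
        "package_version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return str(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
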