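"""Readers and writers for the TSV interchange formats, plus the pipeline
configuration.

Long-format TSV is the canonical interchange for flux data: one row per
(simulation, reaction, time) with columns ``simulation_id, reaction_id,
time_s, flux``.  Truth labels and phenotype flags travel in sidecar TSVs;
the stoichiometric matrix is a wide TSV (first column metabolite id, one
column per reaction, integer coefficients).  Every writer's output is
readable by the matching reader (round-trip closure).
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .types import (
    FluxProfile,
    FluxSeries,
    PhenotypeFlags,
    SimulationRecord,
    StoichiometricMatrix,
)

FLUX_COLUMNS = ("simulation_id", "reaction_id", "time_s", "flux")
_FLAG_COLUMNS = (
    "dna",
    "rna",
    "protein",
    "growth",
    "division",
    "division_initiated",
)


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file without header") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(
            f"{path}: non-numeric {column!r} value "
            f"{df[column][bad.idxmax()]!r} at line {line}"
        )
    if values.isna().any():
        line = int(values.isna().idxmax()) + 2
        raise ParseError(f"{path}: missing {column!r} value at line {line}")
    return values.to_numpy(dtype=float)


def write_flux_table(records: Sequence[SimulationRecord], path) -> None:
    frames = []
    for rec in records:
        for rid in rec.reaction_ids:
            s = rec.series[rid]
            frames.append(
                pd.DataFrame(
                    {
                        "simulation_id": rec.simulation_id,
                        "reaction_id": rid,
                        "time_s": s.times,
                        "flux": s.values,
                    }
                )
            )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(FLUX_COLUMNS))
    )
    df.to_csv(path, sep="\t", index=False)


def read_flux_table(
    path, genotypes: Optional[Mapping[str, str]] = None
) -> list[SimulationRecord]:
    """Parse a long-format flux TSV into simulation records.

    Series are grouped by (simulation, reaction) and sorted by time;
    duplicate time stamps within a series are an error naming the line.
    ``genotypes`` optionally maps simulation id to genotype (default
    ``"unknown"``).
    """
    df = _read_tsv(path, FLUX_COLUMNS)
    if df.empty:
        return []
    times = _numeric(df, "time_s", path)
    fluxes = _numeric(df, "flux", path)
    df = df.assign(time_s=times, flux=fluxes)
    dup = df.duplicated(
        subset=["simulation_id", "reaction_id", "time_s"], keep="first"
    )
    if dup.any():
        row = df[dup].iloc[0]
        line = int(df.index[dup][0]) + 2
        raise ParseError(
            f"{path}: duplicate (simulation, reaction, time) = "
            f"({row.simulation_id}, {row.reaction_id}, {row.time_s}) "
            f"at line {line}"
        )
    records = []
    for sim_id, sim_df in df.groupby("simulation_id", sort=True):
        series = {}
        for rid, r_df in sim_df.groupby("reaction_id", sort=True):
            r_df = r_df.sort_values("time_s")
            series[rid] = FluxSeries(
                times=r_df["time_s"].to_numpy(),
                values=r_df["flux"].to_numpy(),
            )
        genotype = (
            genotypes.get(str(sim_id), "unknown") if genotypes else "unknown"
        )
        records.append(
            SimulationRecord(
                simulation_id=str(sim_id), genotype=genotype, series=series
            )
        )
    return records


def write_genotypes(records: Sequence[SimulationRecord], path) -> None:
    pd.DataFrame(
        [
            {"simulation_id": r.simulation_id, "genotype": r.genotype}
            for r in records
        ],
        columns=["simulation_id", "genotype"],
    ).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> dict[str, str]:
    df = _read_tsv(path, ("simulation_id", "genotype"))
    return {
        str(row.simulation_id): str(row.genotype) for _, row in df.iterrows()
    }


def write_truth_labels(records: Sequence[SimulationRecord], path) -> None:
    rows = [
        {"simulation_id": rec.simulation_id, "reaction_id": rid, "label": lab}
        for rec in records
        if rec.truth_labels
        for rid, lab in sorted(rec.truth_labels.items())
    ]
    pd.DataFrame(
        rows, columns=["simulation_id", "reaction_id", "label"]
    ).to_csv(path, sep="\t", index=False)


def read_truth_labels(path) -> dict[str, dict[str, int]]:
    df = _read_tsv(path, ("simulation_id", "reaction_id", "label"))
    out: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row.simulation_id), {})[str(row.reaction_id)] = int(
            row.label
        )
    return out


def write_phenotype_flags(records: Sequence[SimulationRecord], path) -> None:
    rows = []
    for rec in records:
        if rec.phenotype_flags is None:
            continue
        row = {"simulation_id": rec.simulation_id, "genotype": rec.genotype}
        row.update(
            {
                c: int(getattr(rec.phenotype_flags, c))
                for c in _FLAG_COLUMNS
            }
        )
        rows.append(row)
    pd.DataFrame(
        rows, columns=["simulation_id", "genotype", *_FLAG_COLUMNS]
    ).to_csv(path, sep="\t", index=False)


def read_phenotype_flags(path) -> dict[str, tuple[str, PhenotypeFlags]]:
    """Map simulation id -> (genotype, flags)."""
    df = _read_tsv(path, ("simulation_id", "genotype", *_FLAG_COLUMNS))
    out = {}
    for i, row in df.iterrows():
        try:
            flags = PhenotypeFlags(
                **{c: bool(int(row[c])) for c in _FLAG_COLUMNS}
            )
        except ValueError:
            raise ParseError(
                f"{path}: non-boolean flag at line {int(i) + 2}"
            ) from None
        out[str(row.simulation_id)] = (str(row.genotype), flags)
    return out


def write_stoichiometric_matrix(S: StoichiometricMatrix, path) -> None:
    df = pd.DataFrame(
        S.coefficients,
        index=pd.Index(S.metabolite_ids, name="metabolite_id"),
        columns=list(S.reaction_ids),
    )
    df.to_csv(path, sep="\t")


def read_stoichiometric_matrix(path) -> StoichiometricMatrix:
    df = _read_tsv(path, ("metabolite_id",))
    df = df.set_index("metabolite_id")
    try:
        coeff = df.to_numpy(dtype=float).astype(int)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric coefficient ({exc})") from None
    return StoichiometricMatrix(
        metabolite_ids=tuple(str(m) for m in df.index),
        reaction_ids=tuple(str(r) for r in df.columns),
        coefficients=coeff,
    )


def write_annotation_table(
    annotation: Mapping[str, Sequence[str]], path
) -> None:
    rows = [
        {"reaction_id": rid, "pathways": ";".join(paths)}
        for rid, paths in sorted(annotation.items())
    ]
    pd.DataFrame(rows, columns=["reaction_id", "pathways"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotation_table(path) -> dict[str, list[str]]:
    """Reaction -> pathway list; pathways are ';'-separated in the file."""
    df = _read_tsv(path, ("reaction_id", "pathways"))
    out = {}
    for _, row in df.iterrows():
        paths = [
            p.strip()
            for p in str(row.pathways).split(";")
            if p.strip() and not pd.isna(row.pathways)
        ]
        out[str(row.reaction_id)] = paths
    return out


def write_profiles(profiles: Sequence[FluxProfile], path) -> None:
    """Binary 0/1 matrix TSV, simulations x reactions."""
    if not profiles:
        pd.DataFrame(columns=["simulation_id"]).to_csv(
            path, sep="\t", index=False
        )
        return
    rids = profiles[0].reaction_ids
    df = pd.DataFrame(
        np.vstack([p.bits for p in profiles]), columns=list(rids)
    )
    df.insert(0, "simulation_id", [p.simulation_id for p in profiles])
    df.to_csv(path, sep="\t", index=False)


def read_profiles(path) -> list[FluxProfile]:
    df = _read_tsv(path, ("simulation_id",))
    rids = tuple(c for c in df.columns if c != "simulation_id")
    return [
        FluxProfile(
            simulation_id=str(row.simulation_id),
            reaction_ids=rids,
            bits=np.array([int(row[r]) for r in rids]),
        )
        for _, row in df.iterrows()
    ]


# --------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline run needs.

    Thresholds default to the published analysis values: classifiers under
    70% accuracy are dropped, markers need >95% linear separability, and
    the wild-type noise fit uses 95% coverage.
    """

    flux_path: str = ""
    genotypes_path: Optional[str] = None
    stoichiometry_path: Optional[str] = None
    phenotype_flags_path: Optional[str] = None
    annotation_path: Optional[str] = None
    output_dir: str = "wcflux_out"

    seed: int = 0
    boundary_schemes: tuple[str, ...] = ("extrema", "ci99", "ci95")
    min_classifier_accuracy: float = 0.70
    separability_accuracy: float = 0.95
    noise_coverage: float = 0.95
    matching_strategy: str = "maximum"
    label_backend: str = "agreement_vote"

    use_grid_search: bool = False
    classifier_width: int = 750
    classifier_epochs: int = 15
    classifier_batch: int = 50
    classifier_input: str = "series"  # or "features"
    input_length: int = 500
    cv_folds: int = 0  # 0 disables cross-validation

    def __post_init__(self):
        for name in (
            "min_classifier_accuracy",
            "separability_accuracy",
            "noise_coverage",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParseError(f"config: {name}={v} outside [0, 1]")
        self.boundary_schemes = tuple(self.boundary_schemes)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
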