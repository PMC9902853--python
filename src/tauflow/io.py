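"""File formats and run configuration.

TAC files are plain CSV with a mandatory header
``frame_start_min,frame_duration_min,target_kBq_per_mL,reference_kBq_per_mL``;
lines starting with ``#`` are ignored.  All times are minutes, activities
kBq/mL (only ratios matter downstream).

The run configuration is a single YAML document with a versioned schema;
it round-trips exactly (load -> save -> load) and hashes stably, which is
what output-table provenance headers are built from.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import FrameSchedule, TimeActivityCurve

__all__ = [
    "TAC_COLUMNS",
    "read_tac_file",
    "write_tac_file",
    "RunConfig",
    "config_hash",
    "provenance_header",
]

TAC_COLUMNS = (
    "frame_start_min",
    "frame_duration_min",
    "target_kBq_per_mL",
    "reference_kBq_per_mL",
)


def read_tac_file(path: str | Path) -> tuple[TimeActivityCurve, TimeActivityCurve]:
    """Read a TAC CSV into (target, reference) curves.

    Schema violations raise ``ValueError`` naming the offending column or
    frame index.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {', '.join(missing)}")
    for c in TAC_COLUMNS:
        if not np.issubdtype(df[c].dtype, np.number):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else 0
            raise ValueError(f"{path.name}: non-numeric value in {c} at frame {row}")
    if df[TAC_COLUMNS[0]].isna().any() or df[TAC_COLUMNS[1]].isna().any():
        raise ValueError(f"{path.name}: empty frame timing cells")
    try:
        schedule = FrameSchedule(
            df["frame_start_min"].to_numpy(), df["frame_duration_min"].to_numpy()
        )
    except ValueError as e:
        raise ValueError(f"{path.name}: {e}") from e
    target = TimeActivityCurve(schedule, df["target_kBq_per_mL"].to_numpy())
    reference = TimeActivityCurve(schedule, df["reference_kBq_per_mL"].to_numpy())
    return target, reference


def write_tac_file(
    path: str | Path,
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    comments: list[str] | None = None,
) -> None:
    """Write a (target, reference) pair in the TAC CSV schema."""
    path = Path(path)
    sched = target.schedule
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write(",".join(TAC_COLUMNS) + "\n")
        for s, d, t, r in zip(
            sched.frame_start, sched.frame_duration, target.activity, reference.activity
        ):
            fh.write(f"{float(s)!r},{float(d)!r},{float(t)!r},{float(r)!r}\n")


@dataclass
class RunConfig:
    """Complete configuration of a simulation / analysis run.

    Everything stochastic flows from ``seed``; the pipeline splits it
    deterministically (numpy SeedSequence spawning), so a config + seed
    pair pins every output byte.
    """

    seed: int = 0
    schema_version: int = 1
    fine_dt: float = 0.05
    basis_k2a_min: float = 0.006
    basis_k2a_max: float = 0.6
    basis_n: int = 64
    # label -> [BPND, R1]; delivery follows the cortical territory the
    # tau-load level typically occupies
    binding_conditions: dict = field(
        default_factory=lambda: {
            "SCD_no_binding": [0.05, 0.71],
            "AD_low": [0.25, 0.84],
            "AD_medium": [0.6, 0.84],
            "AD_high": [1.2, 0.90],
        }
    )
    k2_ref: float = 0.05
    flow_deltas: list = field(
        default_factory=lambda: [-0.3, -0.2, -0.1, 0.0, 0.1, 0.2, 0.3]
    )
    cov_levels: list = field(default_factory=lambda: [0.0005, 0.05])
    suvr_windows: list = field(
        default_factory=lambda: [[40, 60], [60, 80], [80, 100], [100, 120], [110, 130]]
    )
    n_rep: int = 200
    cohort_cov: float = 0.05
    roi_correlation: float = 0.7
    alpha: float = 0.05
    power: float = 0.80

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**doc)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the configuration (timestamp-free)."""
    blob = yaml.safe_dump(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(cfg: RunConfig) -> list[str]:
    return [f"config_hash={config_hash(cfg)}", f"seed={cfg.seed}"]
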