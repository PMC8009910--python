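"""CSV schemas, configuration files and run manifests.

All files are plain RFC-4180 CSV with explicit unit suffixes (``_permil``)
in column names.  Readers validate headers and values and raise
``SchemaError`` listing the offending rows; writers keep full floating
precision (rounding happens only in human-readable reports).

Schemas
-------
sources.csv    : source, tracer, mean_permil, sd_permil
mixtures.csv   : environment, tracer, delta_permil, replicate_id
points.csv     : label, delta_acetic_permil, delta_formic_permil, role
summary.csv    : environment, source, mean, sd, ci_lo, ci_hi

Every CLI run writes a JSON manifest capturing the command, configuration
snapshot, seed, package version and input/output paths — enough to
reproduce the run with the same package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .geometry import IsotopePoint
from .mixing import MixtureObservations, PosteriorFractions, SourceProfile

__all__ = [
    "SchemaError",
    "RunManifest",
    "read_sources_csv",
    "write_sources_csv",
    "read_mixtures_csv",
    "write_mixtures_csv",
    "read_points_csv",
    "write_points_csv",
    "write_posterior_summary",
    "write_draws",
]

SOURCES_COLUMNS = ["source", "tracer", "mean_permil", "sd_permil"]
MIXTURES_COLUMNS = ["environment", "tracer", "delta_permil", "replicate_id"]
POINTS_COLUMNS = ["label", "delta_acetic_permil", "delta_formic_permil", "role"]


class SchemaError(ValueError):
    """A CSV file does not match its expected schema."""


def _check_header(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found "
            f"{list(df.columns)}"
        )


def _check_numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna() & df[col].notna()].tolist()
    if bad:
        raise SchemaError(f"{path}: non-numeric {col!r} in rows {bad}")
    return vals


def read_sources_csv(path) -> list[SourceProfile]:
    """Read source signatures (long format, one row per source × tracer)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_header(df, SOURCES_COLUMNS, path)
    _check_numeric(df, "mean_permil", path)
    sd = _check_numeric(df, "sd_permil", path)
    neg = df.index[sd < 0].tolist()
    if neg:
        raise SchemaError(f"{path}: negative sd_permil in rows {neg}")
    dup = df.duplicated(subset=["source", "tracer"])
    if dup.any():
        raise SchemaError(
            f"{path}: duplicate (source, tracer) rows {df.index[dup].tolist()}"
        )
    sources = []
    for name, grp in df.groupby("source", sort=False):
        sources.append(
            SourceProfile(
                name=str(name),
                mean_delta=dict(zip(grp["tracer"], grp["mean_permil"].astype(float))),
                sd_delta=dict(zip(grp["tracer"], grp["sd_permil"].astype(float))),
            )
        )
    if not sources:
        raise SchemaError(f"{path}: no source rows")
    return sources


def write_sources_csv(sources: list[SourceProfile], path) -> None:
    rows = [
        {
            "source": s.name,
            "tracer": t,
            "mean_permil": s.mean_delta[t],
            "sd_permil": s.sd_delta[t],
        }
        for s in sources
        for t in sorted(s.mean_delta)
    ]
    pd.DataFrame(rows, columns=SOURCES_COLUMNS).to_csv(path, index=False)


def read_mixtures_csv(path) -> list[MixtureObservations]:
    """Read replicate mixture observations, one row per measurement."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_header(df, MIXTURES_COLUMNS, path)
    _check_numeric(df, "delta_permil", path)
    out = []
    for env, grp in df.groupby("environment", sort=False):
        out.append(
            MixtureObservations(
                environment=str(env),
                replicates={
                    str(t): g["delta_permil"].to_numpy(dtype=float)
                    for t, g in grp.groupby("tracer", sort=False)
                },
            )
        )
    if not out:
        raise SchemaError(f"{path}: no mixture rows")
    return out


def write_mixtures_csv(mixtures: list[MixtureObservations], path) -> None:
    rows = [
        {
            "environment": m.environment,
            "tracer": t,
            "delta_permil": v,
            "replicate_id": i + 1,
        }
        for m in mixtures
        for t in m.tracers
        for i, v in enumerate(m.replicates[t])
    ]
    pd.DataFrame(rows, columns=MIXTURES_COLUMNS).to_csv(path, index=False)


def read_points_csv(path) -> tuple[list[IsotopePoint], list[IsotopePoint]]:
    """Read isotope-plane points; returns (sources, mixtures) by role."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_header(df, POINTS_COLUMNS, path)
    _check_numeric(df, "delta_acetic_permil", path)
    _check_numeric(df, "delta_formic_permil", path)
    bad_role = df.index[~df["role"].isin(["source", "mixture"])].tolist()
    if bad_role:
        raise SchemaError(
            f"{path}: role must be 'source' or 'mixture'; bad rows {bad_role}"
        )
    pts = {
        role: [
            IsotopePoint(
                delta_acetic=float(r.delta_acetic_permil),
                delta_formic=float(r.delta_formic_permil),
                label=str(r.label),
            )
            for r in grp.itertuples()
        ]
        for role, grp in df.groupby("role", sort=False)
    }
    return pts.get("source", []), pts.get("mixture", [])


def write_points_csv(sources, mixtures, path) -> None:
    rows = [
        {
            "label": p.label,
            "delta_acetic_permil": p.delta_acetic,
            "delta_formic_permil": p.delta_formic,
            "role": role,
        }
        for role, plist in (("source", sources), ("mixture", mixtures))
        for p in plist
    ]
    pd.DataFrame(rows, columns=POINTS_COLUMNS).to_csv(path, index=False)


def write_posterior_summary(summaries: pd.DataFrame, path) -> None:
    cols = ["environment", "source", "mean", "sd", "ci_lo", "ci_hi"]
    summaries[cols].to_csv(path, index=False)


def write_draws(post: PosteriorFractions, path) -> None:
    pd.DataFrame(post.draws, columns=list(post.source_names)).to_csv(
        path, index=False
    )


@dataclass
class RunManifest:
    """Provenance record for one CLI run."""

    command: str
    config: dict = field(default_factory=dict)
    seed: int | None = None
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def write(self, path) -> None:
        payload = asdict(self)
        payload["config_hash"] = self.config_hash
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
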