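"""Variable transforms, the Complexity Index, and model-by-metric tables.

The six metrics entering the index are C, P_t, D_t, R, H_t and J, where the
transforms put P, D and H on comparable scales:

    P_t = 1 - P        (0 for a convex solid, toward 1 for folded surfaces,
                        slightly negative for open near-convex shells)
    D_t = D - 2        (excess of the surface's box dimension over a plane)
    H_t = H            (identity; entropy in nats is already order-1)

The Complexity Index is simply ``CI = C + P_t + D_t + R + H_t + J``.

A packaged reference table of 20 published reef models (protection,
production and bio-mimicry designs) ships with the library and drives the
ordination/clustering/target-point pipeline without any proprietary CAD
files; see :func:`fixture_table1`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError
from .mesh_io import TriangleMesh

__all__ = [
    "METRIC_COLUMNS",
    "TRANSFORM_SCHEMES",
    "transform_metrics",
    "inverse_transform_metrics",
    "complexity_index",
    "ComplexityRecord",
    "MetricTable",
    "load_table",
    "fixture_table1",
    "evaluate_model",
    "evaluate_mesh",
]

METRIC_COLUMNS = ["C", "P_t", "D_t", "R", "H_t", "J"]

#: name -> (forward (P, D, H) -> (P_t, D_t, H_t), inverse)
TRANSFORM_SCHEMES = {
    "default": (
        lambda P, D, H: (1.0 - P, D - 2.0, H),
        lambda P_t, D_t, H_t: (1.0 - P_t, D_t + 2.0, H_t),
    ),
    "identity": (
        lambda P, D, H: (P, D, H),
        lambda P_t, D_t, H_t: (P_t, D_t, H_t),
    ),
}


def transform_metrics(P: float, D: float, H: float, scheme: str = "default"):
    """Apply a named transform set to the raw P, D, H values."""
    if scheme not in TRANSFORM_SCHEMES:
        raise ConfigurationError(
            f"unknown transform scheme {scheme!r}; known: {sorted(TRANSFORM_SCHEMES)}"
        )
    return TRANSFORM_SCHEMES[scheme][0](P, D, H)


def inverse_transform_metrics(P_t: float, D_t: float, H_t: float, scheme: str = "default"):
    if scheme not in TRANSFORM_SCHEMES:
        raise ConfigurationError(f"unknown transform scheme {scheme!r}")
    return TRANSFORM_SCHEMES[scheme][1](P_t, D_t, H_t)


def complexity_index(C: float, P_t: float, D_t: float, R: float, H_t: float, J: float) -> float:
    """CI = the plain sum of the six metrics."""
    return C + P_t + D_t + R + H_t + J


@dataclass
class ComplexityRecord:
    """One model's six metrics, Complexity Index and run diagnostics."""

    model_id: str
    C: float
    P_t: float
    D_t: float
    R: float
    H_t: float
    J: float
    purpose: str = "unknown"
    diagnostics: dict = field(default_factory=dict)

    @property
    def CI(self) -> float:
        return complexity_index(self.C, self.P_t, self.D_t, self.R, self.H_t, self.J)

    def as_dict(self) -> dict:
        d = {"model_id": self.model_id, "purpose": self.purpose}
        d.update({k: float(getattr(self, k)) for k in METRIC_COLUMNS})
        d["CI"] = float(self.CI)
        return d

    def to_json(self) -> str:
        d = self.as_dict()
        d["diagnostics"] = self.diagnostics
        return json.dumps(d, indent=2, default=str)


class MetricTable:
    """A model-by-metric table (rows = models, columns = metrics + CI).

    Thin wrapper over a :class:`pandas.DataFrame` that enforces the schema
    (unique model ids, all six metric columns finite) and offers the
    validations used throughout the pipeline.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in ["model_id", *METRIC_COLUMNS] if c not in df.columns]
        if missing:
            raise SchemaError(f"metric table missing columns: {missing}")
        if df["model_id"].duplicated().any():
            dupes = df.loc[df["model_id"].duplicated(), "model_id"].tolist()
            raise SchemaError(f"duplicate model ids: {dupes}")
        if len(df) == 0:
            raise SchemaError("metric table has no rows")
        vals = df[METRIC_COLUMNS].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise SchemaError("non-finite metric values in table")
        if "CI" not in df.columns:
            df["CI"] = vals.sum(axis=1)
        if "purpose" not in df.columns:
            df["purpose"] = "unknown"
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def model_ids(self) -> list[str]:
        return self.df["model_id"].tolist()

    def metrics(self) -> np.ndarray:
        return self.df[METRIC_COLUMNS].to_numpy(dtype=float)

    def validate_ci(self, tolerance: float = 0.002) -> pd.DataFrame:
        """Report rows whose stored CI deviates from the six-metric sum.

        The stored CI column is kept as-is (it may carry more precision than
        the printed metrics); discrepancies beyond ``tolerance`` are
        surfaced here rather than silently reconciled.
        """
        sums = self.metrics().sum(axis=1)
        delta = self.df["CI"].to_numpy(dtype=float) - sums
        out = pd.DataFrame(
            {"model_id": self.df["model_id"], "CI": self.df["CI"], "metric_sum": sums,
             "delta": delta, "ok": np.abs(delta) <= tolerance}
        )
        return out

    def purpose_means(self) -> pd.DataFrame:
        """Per-purpose mean of each metric and of CI."""
        cols = METRIC_COLUMNS + ["CI"]
        return self.df.groupby("purpose")[cols].mean()

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @staticmethod
    def from_records(records: list[ComplexityRecord]) -> "MetricTable":
        return MetricTable(pd.DataFrame([r.as_dict() for r in records]))


def load_table(path: str | Path) -> MetricTable:
    """Load a model-by-metric CSV (header row required)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty CSV") from exc
    return MetricTable(df)


def fixture_table1() -> MetricTable:
    """The packaged 20-model reference table.

    Contains the six metrics, CI, first-dimension ordination score and the
    Dim.1 x Dim.2 distance for the 20 published reef models (PROT1-6,
    PROD1-7, BIOM1-7), exactly as printed.
    """
    with resources.files("reefmetrics.data").joinpath("table1.csv").open() as fh:
        return MetricTable(pd.read_csv(fh))


# ---------------------------------------------------------------------------
# full per-model evaluation
# ---------------------------------------------------------------------------


def evaluate_mesh(
    mesh: TriangleMesh,
    resolution: float = 1.0,
    seed: int = 0,
    scheme: str = "default",
    decimals: int = 2,
    n_cells: int = 320,
    n_scales: int | None = None,
    size_range=None,
    purpose: str = "unknown",
) -> ComplexityRecord:
    """Run the whole metric pipeline on an in-memory mesh.

    Orchestrates surface sampling, the three geometric metrics, the three
    orientation metrics, the variable transforms and the Complexity Index.
    Deterministic for a given seed; full diagnostics recorded.
    """
    from .geometric_metrics import geometric_metrics
    from .informational_metrics import informational_metrics
    from .mesh_io import sample_surface, summarize_mesh

    report = summarize_mesh(mesh)
    sample = sample_surface(mesh, resolution=resolution, seed=seed)
    geo = geometric_metrics(
        mesh, sample, mesh_volume=report.volume, n_scales=n_scales, size_range=size_range
    )
    info = informational_metrics(sample, decimals=decimals, n_cells=n_cells)
    P_t, D_t, H_t = transform_metrics(geo.P, geo.D, info.H, scheme=scheme)
    diagnostics = {
        "resolution": resolution,
        "seed": seed,
        "n_points": sample.n,
        "scheme": scheme,
        "richness_mode": info.richness_mode,
        "diversity_mode": info.diversity_mode,
        "normal_decimals": decimals,
        "sphere_cells": n_cells,
        "watertight": report.watertight,
        "volume_is_fallback": report.volume_is_fallback,
        "packing_exceeds_one": geo.packing_exceeds_one,
        "box_fit_r2": geo.fit_r2,
        "box_n_scales": geo.n_scales,
        "raw": {"P": geo.P, "D": geo.D, "H": info.H},
    }
    return ComplexityRecord(
        model_id=mesh.name or "model",
        C=geo.C,
        P_t=P_t,
        D_t=D_t,
        R=info.R,
        H_t=H_t,
        J=info.J,
        purpose=purpose,
        diagnostics=diagnostics,
    )


def evaluate_model(path: str | Path, unit_scale: float = 1.0, **kwargs) -> ComplexityRecord:
    """Read an STL file and evaluate it; see :func:`evaluate_mesh`."""
    from .mesh_io import read_mesh

    mesh = read_mesh(path, unit_scale=unit_scale)
    return evaluate_mesh(mesh, **kwargs)
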