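"""Rotatable central composite designs for reagent-volume factors.

A central composite design (CCD) for ``k`` factors combines a 2^k
factorial in coded levels -1/+1, 2k axial points at coded distance
``±(2^k)^(1/4)`` (the rotatable choice), and replicated center points at
the coded origin.  Factors here are reagent volumes (phenol, sulfuric
acid, water in the motivating assay); each carries a coded <-> uncoded
volume mapping via its center and half-range.

Run order is randomized by a recorded seed, except that one center
point opens and one closes the sequence so process drift over the
plate can be monitored.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InvalidDesignError",
    "FactorSpec",
    "DesignRun",
    "DesignTable",
    "axial_distance",
    "generate_ccd",
    "read_design_csv",
]


class InvalidDesignError(ValueError):
    """Raised when a requested design violates CCD structure."""


class NegativeVolumeWarning(UserWarning):
    """A decoded volume is negative (axial points may be infeasible)."""


@dataclass(frozen=True)
class FactorSpec:
    """One controllable reagent volume and its coding map.

    ``encode`` maps an uncoded volume to a coded level via
    ``(volume - center) / half_range``; ``decode`` is the exact inverse.
    Coded -1/+1 correspond to the low/high factorial volumes.

    Parameters
    ----------
    name : str
        Factor identifier, e.g. ``"phenol"``.
    center : float
        Volume at the coded origin (µl).
    half_range : float
        Half the distance between the factorial low and high volumes (µl).
    units : str
        Unit label for reports; default microliters.
    allow_negative : bool
        If False (default), decoding to a negative volume emits a
        :class:`NegativeVolumeWarning`.  Axial points can sit below zero
        volume; whether that is acceptable is a protocol decision.
    """

    name: str
    center: float
    half_range: float
    units: str = "ul"
    allow_negative: bool = False

    def __post_init__(self) -> None:
        if not self.half_range > 0:
            raise ValueError(f"half_range must be > 0, got {self.half_range}")

    def encode(self, volume: float) -> float:
        return (volume - self.center) / self.half_range

    def decode(self, coded: float) -> float:
        volume = self.center + coded * self.half_range
        if volume < 0 and not self.allow_negative:
            warnings.warn(
                f"factor {self.name!r}: coded level {coded:g} decodes to "
                f"negative volume {volume:g} {self.units}",
                NegativeVolumeWarning,
                stacklevel=2,
            )
        return volume


def axial_distance(k: int) -> float:
    """Coded distance of axial points for a rotatable CCD in ``k`` factors.

    Returns ``(2^k)^(1/4)``: 1.682 for three factors, sqrt(2) for two.
    """
    if k < 2:
        raise InvalidDesignError(f"a CCD needs at least 2 factors, got {k}")
    return (2.0**k) ** 0.25


@dataclass(frozen=True)
class DesignRun:
    run_index: int
    point_type: str  # "factorial" | "axial" | "center"
    coded_levels: tuple[float, ...]


@dataclass
class DesignTable:
    """Ordered CCD runs with point types and coded levels."""

    runs: list[DesignRun]
    seed: int
    n_center: int
    factors: list[FactorSpec] | None = field(default=None)

    @property
    def n_factors(self) -> int:
        return len(self.runs[0].coded_levels)

    @property
    def coded(self) -> np.ndarray:
        """(n_runs, k) array of coded levels in run order."""
        return np.array([r.coded_levels for r in self.runs], dtype=float)

    @property
    def point_types(self) -> list[str]:
        return [r.point_type for r in self.runs]

    def center_mask(self) -> np.ndarray:
        return np.array([t == "center" for t in self.point_types])

    def to_frame(self, factor_names: list[str] | None = None) -> pd.DataFrame:
        """Design sheet with coded levels (6 d.p.) and decoded volumes."""
        if factor_names is None:
            if self.factors is not None:
                factor_names = [f.name for f in self.factors]
            else:
                factor_names = [f"x{i + 1}" for i in range(self.n_factors)]
        coded = np.round(self.coded, 6)
        data: dict[str, object] = {
            "run_index": [r.run_index for r in self.runs],
            "point_type": self.point_types,
        }
        for j, name in enumerate(factor_names):
            data[f"{name}_coded"] = coded[:, j]
        if self.factors is not None:
            for j, spec in enumerate(self.factors):
                data[f"{spec.name}_{spec.units}"] = [
                    spec.decode(c) for c in coded[:, j]
                ]
        data["order"] = np.arange(1, len(self.runs) + 1)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def expected_run_count(k: int, n_center: int) -> int:
    return 2**k + 2 * k + n_center


def generate_ccd(
    factors: list[FactorSpec], n_center: int = 6, seed: int = 0
) -> DesignTable:
    """Generate a rotatable CCD with seeded run-order randomization.

    The design holds ``2^k`` factorial points, ``2k`` axial points at
    coded ``±(2^k)^(1/4)``, and ``n_center`` center replicates.  All runs
    except two center points are shuffled by ``numpy``'s seeded
    generator; one center point is pinned first and one last so the
    sequence is bracketed by process-stability checks.

    Raises
    ------
    InvalidDesignError
        If fewer than 2 factors or fewer than 2 center points.
    """
    k = len(factors)
    alpha = axial_distance(k)  # raises for k < 2
    if n_center < 2:
        raise InvalidDesignError(
            f"need at least 2 center points to bracket the sequence, got {n_center}"
        )

    points: list[tuple[str, tuple[float, ...]]] = []
    for combo in itertools.product((-1.0, 1.0), repeat=k):
        points.append(("factorial", combo))
    for j in range(k):
        for sign in (-1.0, 1.0):
            levels = [0.0] * k
            levels[j] = sign * alpha
            points.append(("axial", tuple(levels)))
    origin = tuple(0.0 for _ in range(k))
    # shuffle factorial + axial + the interior center replicates together
    interior = points + [("center", origin)] * (n_center - 2)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(interior))
    sequence = (
        [("center", origin)]
        + [interior[i] for i in order]
        + [("center", origin)]
    )
    runs = [
        DesignRun(run_index=i + 1, point_type=pt, coded_levels=levels)
        for i, (pt, levels) in enumerate(sequence)
    ]
    assert len(runs) == expected_run_count(k, n_center)
    return DesignTable(runs=runs, seed=seed, n_center=n_center, factors=factors)


def read_design_csv(path) -> DesignTable:
    """Read a design sheet written by :meth:`DesignTable.to_csv`.

    Only the coded columns are required; decoded-volume columns are
    ignored (the coding map is not recoverable from a sheet alone).
    """
    df = pd.read_csv(path)
    coded_cols = [c for c in df.columns if c.endswith("_coded")]
    if not coded_cols:
        raise ValueError("design sheet has no *_coded columns")
    runs = [
        DesignRun(
            run_index=int(row["run_index"]),
            point_type=str(row["point_type"]),
            coded_levels=tuple(float(row[c]) for c in coded_cols),
        )
        for _, row in df.iterrows()
    ]
    n_center = sum(1 for r in runs if r.point_type == "center")
    return DesignTable(runs=runs, seed=-1, n_center=n_center)
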