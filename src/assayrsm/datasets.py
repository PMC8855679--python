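"""Packaged reference data from the published assay-optimization study.

Ships the 20-run rotatable central composite experiment (coded levels
and 490 nm absorbances) used to optimize the phenol-sulfuric acid
glycogen assay, and the selected response-surface model it yielded.
The coding map (uncoded volume grid) was not published, so the fixture
stores coded levels only; that suffices for all fitting work.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .doe import DesignRun, DesignTable
from .rsm import MeasurementSet, ModelTerms, full_quadratic_terms

__all__ = [
    "FACTOR_NAMES",
    "SELECTED_TERMS",
    "FULL_TERMS",
    "REFERENCE_COEFFICIENTS",
    "load_ccd_frame",
    "load_optimization_experiment",
]

FACTOR_NAMES = ["phenol", "h2so4", "water"]

#: The 9-term model selected in the published optimization: intercept,
#: the three linear volume terms, phenol:acid, acid:water and the
#: three-way interaction, plus the acid and water squares.  The phenol
#: square and phenol:water interaction were dropped as consistent with
#: zero; linear phenol stays by hierarchy.
SELECTED_TERMS = ModelTerms(
    (
        (0, 0, 0),
        (1, 0, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 1, 0),
        (0, 1, 1),
        (1, 1, 1),
        (0, 2, 0),
        (0, 0, 2),
    )
)

#: Full quadratic with all interactions for the three volume factors.
FULL_TERMS = full_quadratic_terms(3)

#: Published coefficient estimates of the selected model (A.U. per coded
#: unit); the default "true surface" for the synthetic generator.
REFERENCE_COEFFICIENTS: dict[tuple[int, int, int], float] = {
    (0, 0, 0): 0.2869,
    (1, 0, 0): 0.003508,
    (0, 1, 0): 0.04769,
    (0, 0, 1): -0.08491,
    (1, 1, 0): 0.021,
    (0, 1, 1): 0.047,
    (1, 1, 1): -0.018,
    (0, 2, 0): -0.05295,
    (0, 0, 2): -0.02061,
}


def load_ccd_frame() -> pd.DataFrame:
    """The packaged 20-run experiment as a DataFrame, in printed run order."""
    with resources.files("assayrsm.data").joinpath(
        "phenol_sulfuric_ccd.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def load_optimization_experiment() -> MeasurementSet:
    """The packaged 20-run experiment as a :class:`MeasurementSet`."""
    df = load_ccd_frame()
    coded_cols = [f"{n}_coded" for n in FACTOR_NAMES]
    runs = [
        DesignRun(
            run_index=int(row["run_index"]),
            point_type=str(row["point_type"]),
            coded_levels=tuple(float(row[c]) for c in coded_cols),
        )
        for _, row in df.iterrows()
    ]
    design = DesignTable(runs=runs, seed=-1, n_center=6)
    return MeasurementSet(design=design, y=np.asarray(df["absorbance"], float))
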