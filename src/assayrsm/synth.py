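"""Synthetic assay data with the statistical structure the pipeline assumes.

Three generators, all bit-reproducible under a fixed seed:

* response-surface measurements — a quadratic surface in the coded
  reagent volumes (defaulting to the published selected-model
  coefficients) plus additive Gaussian replicate noise, default sd
  0.013 A.U., the spread of the packaged experiment's center points;
* Beer's-law standard curves — a line in analyte mass with
  multiplicative (CV-structured) noise, because curve precision is
  summarized as %CV, and a saturation flag above the 1.6 A.U. cap;
* an ethanol-precipitation extraction — per spin, free glucose is
  carried over at a small fraction (one spin removes essentially all
  of it) while glycogen is recovered at a 91–95% yield, so total
  carbohydrate drops sharply after the first precipitation and then
  plateaus.

A tissue-panel generator composes these into sample tables the
quantification stage can consume end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import REFERENCE_COEFFICIENTS, SELECTED_TERMS
from .doe import DesignTable
from .rsm import MeasurementSet, ModelTerms, build_design_matrix

__all__ = [
    "SurfaceSimConfig",
    "ExtractionSimConfig",
    "TissuePanelConfig",
    "simulate_surface_measurements",
    "simulate_standard_curve",
    "simulate_extraction",
    "simulate_tissue_panel",
    "simulate_extraction_control",
]

#: Replicate noise of a surface run (A.U.), from the packaged
#: experiment's center-point scatter (sd of the six replicates ≈ 0.0134).
DEFAULT_SURFACE_NOISE_SD = 0.013


@dataclass
class SurfaceSimConfig:
    """True surface coefficients and replicate noise for simulated runs."""

    coefficients: dict[tuple[int, ...], float] = field(
        default_factory=lambda: dict(REFERENCE_COEFFICIENTS)
    )
    noise_sd: float = DEFAULT_SURFACE_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def terms(self) -> ModelTerms:
        return ModelTerms(tuple(self.coefficients.keys()))

    @property
    def beta(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()), dtype=float)


def simulate_surface_measurements(
    cfg: SurfaceSimConfig, design: DesignTable
) -> MeasurementSet:
    """Absorbances = true surface at the coded levels + iid Gaussian noise.

    Readings are floored at zero (a plate reader does not report
    negative absorbance); at the default noise level this clip is
    vanishingly rare inside the design region.
    """
    X = build_design_matrix(design, cfg.terms)
    rng = np.random.default_rng(cfg.seed)
    y = X @ cfg.beta + rng.normal(0.0, cfg.noise_sd, size=X.shape[0])
    return MeasurementSet(design=design, y=np.clip(y, 0.0, None))


DEFAULT_CURVE_LEVELS = (0.0, 2.5, 5.0, 10.0, 15.0, 20.0, 25.0)  # µg per well


def simulate_standard_curve(
    slope: float = 0.07279,
    intercept: float = 0.02,
    cv: float = 0.07,
    levels=DEFAULT_CURVE_LEVELS,
    reps: int = 4,
    seed: int = 0,
    cap: float = 1.6,
) -> pd.DataFrame:
    """Long-form standards table with multiplicative (CV-structured) noise.

    absorbance = (intercept + slope·mass) · (1 + ε), ε ~ N(0, cv).
    Readings above ``cap`` are flagged ``saturating``.  At the default
    slope and intercept the 25 µg standard sits above the cap, mirroring
    a wide 0–25 µg range read against a 1.6 A.U. linear ceiling.
    """
    if slope <= 0:
        raise ValueError("slope must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for lv in levels:
        true = intercept + slope * lv
        noise = rng.normal(0.0, cv, size=reps)
        for r in range(reps):
            a = max(true * (1.0 + noise[r]), 0.0)
            rows.append(
                {
                    "level_ug": lv,
                    "replicate": r + 1,
                    "absorbance": a,
                    "saturating": a > cap,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ExtractionSimConfig:
    """Ethanol-precipitation extraction of glycogen from a glucose background.

    Defaults mirror the control mixture used to tune the protocol:
    60 mg/dl free glucose + 40 mg/dl glycogen, four precipitation
    rounds.  One spin carries over <1% of the free glucose and recovers
    glycogen at the 91–95% yield band's midpoint.
    """

    glycogen_recovery: float = 0.93  # fraction retained per spin
    glucose_carryover_per_spin: float = 0.005  # fraction carried over per spin
    n_precipitations: int = 4
    initial_glucose: float = 60.0  # mg/dl
    initial_glycogen: float = 40.0  # mg/dl
    noise_cv: float = 0.05  # measurement CV on the carbohydrate readout
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("glycogen_recovery", "glucose_carryover_per_spin"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_precipitations < 1:
            raise ValueError("n_precipitations must be >= 1")


def simulate_extraction(cfg: ExtractionSimConfig) -> pd.DataFrame:
    """Per-round carbohydrate content through repeated precipitations.

    Pre-noise, glucose decays geometrically by the carryover fraction
    and glycogen by the recovery fraction each spin; the measured total
    carries multiplicative noise.  Totals are non-increasing in spin
    count, with the big drop at round one (the free glucose leaving).
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for spin in range(1, cfg.n_precipitations + 1):
        glucose = cfg.initial_glucose * cfg.glucose_carryover_per_spin**spin
        glycogen = cfg.initial_glycogen * cfg.glycogen_recovery**spin
        total = glucose + glycogen
        measured = max(total * (1.0 + rng.normal(0.0, cfg.noise_cv)), 0.0)
        rows.append(
            {
                "precipitation": spin,
                "glucose_mgdl": glucose,
                "glycogen_mgdl": glycogen,
                "total_mgdl": total,
                "measured_total_mgdl": measured,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TissuePanelConfig:
    """A small tissue panel pushed through extraction, curve, and assay.

    Defaults sketch a liver-like panel: ~25 mg samples dissolved in
    1 ml after one precipitation, 5 µl assayed in duplicate against a
    glycogen standard curve.
    """

    content_ug_per_mg: float = 25.0  # true glycogen content
    n_samples: int = 3
    m_tissue_mg: float = 25.0
    v_sample_ul: float = 1000.0
    v_assayed_ul: float = 5.0
    n_wells: int = 2  # technical replicate wells per sample
    curve_slope: float = 0.07279  # A.U./µg
    curve_intercept: float = 0.02  # A.U.
    noise_cv: float = 0.05  # per-well assay CV
    extraction: ExtractionSimConfig = field(default_factory=ExtractionSimConfig)
    # extraction control run alongside the panel: a known glycogen mass
    # (50 µl of the 40 mg/dl control mixture = 20 µg) through the same
    # precipitation, dissolved in 250 µl with 50 µl assayed
    control_mass_ug: float = 20.0
    control_v_sample_ul: float = 250.0
    control_v_assayed_ul: float = 50.0
    seed: int = 0


def simulate_tissue_panel(cfg: TissuePanelConfig) -> pd.DataFrame:
    """Per-well sample table for the quantification stage.

    Each sample's glycogen survives one precipitation at the configured
    recovery; the assayed aliquot produces a Beer's-law absorbance with
    multiplicative per-well noise.  Columns follow the samples schema:
    sample_id, m_tissue_mg, V_sample_ul, V_assayed_ul, absorbance.
    """
    rng = np.random.default_rng(cfg.seed)
    recovery = cfg.extraction.glycogen_recovery
    rows = []
    for s in range(1, cfg.n_samples + 1):
        recovered_ug = cfg.content_ug_per_mg * cfg.m_tissue_mg * recovery
        mass_per_well = recovered_ug / cfg.v_sample_ul * cfg.v_assayed_ul
        true_abs = cfg.curve_intercept + cfg.curve_slope * mass_per_well
        for w in range(1, cfg.n_wells + 1):
            a = max(true_abs * (1.0 + rng.normal(0.0, cfg.noise_cv)), 0.0)
            rows.append(
                {
                    "sample_id": f"sample{s}",
                    "m_tissue_mg": cfg.m_tissue_mg,
                    "V_sample_ul": cfg.v_sample_ul,
                    "V_assayed_ul": cfg.v_assayed_ul,
                    "well": w,
                    "absorbance": a,
                }
            )
    return pd.DataFrame(rows)


def simulate_extraction_control(cfg: TissuePanelConfig) -> pd.DataFrame:
    """Per-well readout of the extraction control run with a tissue panel.

    A known glycogen mass goes through the same precipitation as the
    samples, so its curve readout estimates the extraction recovery and
    calibrates the panel.  The control's noise stream is independent of
    the panel's (both derive from ``cfg.seed``).
    """
    rng = np.random.default_rng([cfg.seed, 1])
    recovered_ug = cfg.control_mass_ug * cfg.extraction.glycogen_recovery
    mass_per_well = (
        recovered_ug / cfg.control_v_sample_ul * cfg.control_v_assayed_ul
    )
    true_abs = cfg.curve_intercept + cfg.curve_slope * mass_per_well
    rows = [
        {
            "sample_id": "control",
            "known_mass_ug": cfg.control_mass_ug,
            "V_sample_ul": cfg.control_v_sample_ul,
            "V_assayed_ul": cfg.control_v_assayed_ul,
            "well": w,
            "absorbance": max(true_abs * (1.0 + rng.normal(0.0, cfg.noise_cv)), 0.0),
        }
        for w in range(1, cfg.n_wells + 1)
    ]
    return pd.DataFrame(rows)
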