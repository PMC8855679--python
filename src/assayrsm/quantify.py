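"""Tissue glycogen arithmetic, stoichiometry, and verification statistics.

Converts a standard-curve mass readout into tissue glycogen content

    content (µg/mg) = (m_curve / V_assayed) · V_sample / m_tissue,

where ``m_curve`` is the mass from the standard curve, ``V_assayed``
the volume of dissolved sample put into the assay, ``V_sample`` the
water volume the glycogen pellet was dissolved in, and ``m_tissue`` the
tissue mass.

Stoichiometry: a free glucose molecule weighs ~180 g/mol; a glucosyl
unit inside glycogen ~162 g/mol (water is lost on polymerization), so a
glycogen particle of N units weighs 162N + 18 g/mol.  At an assumed
particle mass of 10^6 g/mol that implies ~6172 glucose units per
particle.  These conversions support mass- and mole-based fractional
yields when glycogen is read against a glucose curve.

Verification comparisons throughout the workflow (model prediction vs.
experiment, sodium-sulfate interference) use the difference of group
means with a two-sample t confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "QuantRecord",
    "quantify_samples",
    "estimate_recovery",
    "GLUCOSE_MOLAR_MASS",
    "GLUCOSYL_UNIT_MASS",
    "WATER_MASS",
    "tissue_glycogen",
    "particle_molar_mass",
    "glycogen_units_per_particle",
    "glucose_equivalents",
    "fractional_yield",
    "mean_difference_ci",
]

GLUCOSE_MOLAR_MASS = 180.0  # g/mol, free glucose
GLUCOSYL_UNIT_MASS = 162.0  # g/mol, glucose residue in glycogen
WATER_MASS = 18.0  # g/mol, terminal water of the particle formula


@dataclass(frozen=True)
class QuantRecord:
    """One sample's masses and volumes for glycogen quantification."""

    m_curve: float  # µg, mass read off the standard curve
    v_assayed: float  # µl of dissolved sample placed in the assay
    v_sample: float  # µl of water the pellet was dissolved in
    m_tissue: float  # mg of tissue

    def __post_init__(self) -> None:
        for name in ("v_assayed", "v_sample", "m_tissue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.m_curve < 0:
            raise ValueError("m_curve must be >= 0")


def tissue_glycogen(rec: QuantRecord) -> float:
    """Glycogen content in µg per mg tissue.

    Homogeneous of degree +1 in ``m_curve`` and ``v_sample`` and −1 in
    ``v_assayed`` and ``m_tissue``; when the whole dissolution volume is
    assayed the dilution cancels and the result is m_curve/m_tissue.
    """
    return (rec.m_curve / rec.v_assayed) * rec.v_sample / rec.m_tissue


def particle_molar_mass(n_units: int) -> float:
    """Molar mass (g/mol) of a glycogen particle of ``n_units`` residues."""
    if n_units < 1:
        raise ValueError("a glycogen particle has at least 1 glucose unit")
    return GLUCOSYL_UNIT_MASS * n_units + WATER_MASS


def glycogen_units_per_particle(particle_mass: float) -> int:
    """Glucose units N implied by a particle molar mass: 162N + 18 = mass.

    Truncated to an integer; the N = 1 limit is free glucose (180 g/mol).
    """
    if particle_mass < GLUCOSE_MOLAR_MASS:
        raise ValueError(
            f"particle mass {particle_mass} g/mol is below free glucose (180)"
        )
    return int((particle_mass - WATER_MASS) // GLUCOSYL_UNIT_MASS)


def glucose_equivalents(mass_ug: float, basis: str = "free-glucose") -> float:
    """Convert a carbohydrate mass (µg) to µmol of glucose equivalents.

    ``basis="free-glucose"`` divides by 180 g/mol (mass read against a
    glucose curve); ``basis="glucosyl-unit"`` divides by 162 g/mol
    (mass of residues inside glycogen).
    """
    if mass_ug < 0:
        raise ValueError("mass must be >= 0")
    if basis == "free-glucose":
        return mass_ug / GLUCOSE_MOLAR_MASS
    if basis == "glucosyl-unit":
        return mass_ug / GLUCOSYL_UNIT_MASS
    raise ValueError(f"unknown basis {basis!r}")


def fractional_yield(
    mass_from_glucose_curve: float,
    mass_from_glycogen_curve: float,
    scale: str = "mass",
    particle_mass: float = 1e6,
) -> float:
    """Hydrolysis yield of the assay: glucose-curve over glycogen-curve readout.

    ``scale="mass"`` is the plain mass ratio (actual over expected).
    ``scale="molar"`` converts the glucose-curve mass to moles of free
    glucose (180 g/mol) and the glycogen-curve mass to moles of glucose
    units via the particle stoichiometry (N units per particle at the
    assumed ``particle_mass``), then takes the ratio.
    """
    if mass_from_glycogen_curve <= 0:
        raise ValueError("glycogen-curve mass must be > 0")
    if scale == "mass":
        return mass_from_glucose_curve / mass_from_glycogen_curve
    if scale == "molar":
        n = glycogen_units_per_particle(particle_mass)
        mol_glucose = mass_from_glucose_curve / GLUCOSE_MOLAR_MASS
        mol_particles = mass_from_glycogen_curve / particle_molar_mass(n)
        mol_units_expected = mol_particles * n
        return mol_glucose / mol_units_expected
    raise ValueError(f"unknown scale {scale!r}")


def quantify_samples(samples, curve) -> "object":
    """Per-sample glycogen content from a samples table and a standard curve.

    ``samples`` is a long-form table (one row per well) with columns
    sample_id, m_tissue_mg, V_sample_ul, V_assayed_ul, absorbance.
    Technical replicate wells are averaged per sample before the curve
    is inverted.  Returns a copy with one row per sample and an added
    ``glycogen_ug_per_mg`` column.
    """
    import pandas as pd

    df = pd.DataFrame(samples)
    keys = ["sample_id", "m_tissue_mg", "V_sample_ul", "V_assayed_ul"]
    agg = df.groupby(keys, as_index=False)["absorbance"].mean()
    contents = []
    for _, row in agg.iterrows():
        m_curve = float(curve.mass_from_absorbance(row["absorbance"]))
        rec = QuantRecord(
            m_curve=max(m_curve, 0.0),
            v_assayed=float(row["V_assayed_ul"]),
            v_sample=float(row["V_sample_ul"]),
            m_tissue=float(row["m_tissue_mg"]),
        )
        contents.append(tissue_glycogen(rec))
    agg["glycogen_ug_per_mg"] = contents
    return agg


def estimate_recovery(control, curve, known_mass_ug: float | None = None) -> float:
    """Extraction recovery fraction from a control of known glycogen mass.

    The control mixture goes through the same precipitation as the
    tissue samples, so the ratio of its curve readout to the mass put in
    estimates the protocol's glycogen recovery (typically 91-95%).
    Dividing sample contents by this factor calibrates out both the
    extraction loss and, since the same curve reads control and samples,
    most of the curve's own estimation error.

    ``control`` is a per-well table with columns V_sample_ul,
    V_assayed_ul, absorbance and (unless ``known_mass_ug`` is given) a
    known_mass_ug column.
    """
    import pandas as pd

    df = pd.DataFrame(control)
    if known_mass_ug is None:
        known_mass_ug = float(df["known_mass_ug"].iloc[0])
    if known_mass_ug <= 0:
        raise ValueError("known control mass must be > 0")
    mean_abs = float(df["absorbance"].mean())
    m_curve = float(curve.mass_from_absorbance(mean_abs))
    v_sample = float(df["V_sample_ul"].iloc[0])
    v_assayed = float(df["V_assayed_ul"].iloc[0])
    recovered = m_curve / v_assayed * v_sample
    return recovered / known_mass_ug


def mean_difference_ci(
    group_a,
    group_b,
    level: float = 0.95,
    pooled: bool = True,
) -> tuple[float, tuple[float, float]]:
    """Difference of means (a − b) with a two-sample t confidence interval.

    Pooled-variance by default (Welch with ``pooled=False``).  The
    interval reflects only replicate scatter; when one group is a model
    prediction, the prediction's own uncertainty is not propagated.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if pooled:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    tcrit = stats.t.ppf(0.5 + level / 2.0, df)
    half = float(tcrit * se)
    return diff, (diff - half, diff + half)
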