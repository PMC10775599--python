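"""Calibrated plate-assay quantification, pH calibration and flux normalization.

Every colorimetric/luminescent assay in the pipeline follows the same
scheme: a linear standard curve is fitted by ordinary least squares,
sample signals are inverted through it, amounts are referenced against
the fresh medium and normalized either to protein (specific amounts) or
to cell number and time (fluxes in pmol/min/1000 cells).

Quantities that fall below the blank are *retained* with a flag rather
than clamped, so replicate averages stay unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "CalibrationCurve",
    "Quantified",
    "MediumDelta",
    "FluxRecord",
    "PhCalibration",
    "fit_calibration",
    "quantify",
    "medium_delta",
    "flux_normalize",
    "lactate_glucose_ratio",
    "ph_from_ratio",
    "ldh_release_fraction",
    "specific_activity",
    "senescence_index",
    "circularity",
    "hypertrophy_index",
    "quantify_plate",
]

#: Standard curves with r^2 below this are flagged, not rejected.
R_SQUARED_WARN = 0.98


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear standard curve ``signal = slope * amount + intercept``.

    ``blank`` is the fitted signal at amount 0 (== intercept for a
    straight line) and is what gets subtracted implicitly when inverting.
    """

    slope: float
    intercept: float
    r_squared: float
    blank: float
    n_standards: int
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n_standards < 2:
            raise ValueError("a calibration needs >= 2 standards")
        if self.slope == 0:
            raise ValueError("degenerate calibration: slope is zero")

    def inverse(self, signal):
        """Amount(s) corresponding to ``signal`` (scalar or array)."""
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class Quantified:
    """An amount read off a calibration curve, with quality flags."""

    amount: float
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class MediumDelta:
    """Concentration change vs. the fresh medium (mmol/l)."""

    delta: float
    direction: str
    substrate: str = ""
    condition: str = ""
    reliable: bool = True


@dataclass(frozen=True)
class FluxRecord:
    """Substrate flux in pmol/min/1000 cells with its provenance.

    Satisfies ``flux * duration * (cells/1000) == delta * volume * 1e9``
    exactly by construction.
    """

    substrate: str
    delta_mM: float
    volume_l: float
    duration_min: float
    cells: float
    flux: float
    condition: str = ""
    reliable: bool = True


@dataclass(frozen=True)
class PhCalibration:
    """Two-point nigericin calibration: (pH, BCECF ratio) pairs."""

    ph1: float
    ratio1: float
    ph2: float
    ratio2: float

    def __post_init__(self) -> None:
        if self.ph1 == self.ph2:
            raise ValueError("calibration pH values must differ")
        if self.ratio1 == self.ratio2:
            raise ValueError("calibration ratios must differ")


def fit_calibration(standards) -> CalibrationCurve:
    """Fit a linear standard curve by ordinary least squares.

    Parameters
    ----------
    standards
        Iterable of ``(amount, signal)`` pairs with at least two distinct
        amounts.

    Raises
    ------
    ValueError
        If all amounts are identical or the fitted slope is zero.
    """
    pairs = np.asarray(list(standards), dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2:
        raise ValueError("need >= 2 (amount, signal) standards")
    amounts, signals = pairs[:, 0], pairs[:, 1]
    if np.ptp(amounts) == 0:
        raise ValueError("degenerate standards: all amounts identical")
    fit = _st.linregress(amounts, signals)
    if fit.slope == 0:
        raise ValueError("degenerate calibration: slope is zero")
    r2 = float(fit.rvalue**2) if np.ptp(signals) > 0 else 1.0
    flags = frozenset() if r2 >= R_SQUARED_WARN else frozenset({"low_r_squared"})
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        blank=float(fit.intercept),
        n_standards=len(amounts),
        flags=flags,
    )


def quantify(signal: float, curve: CalibrationCurve) -> Quantified:
    """Invert a signal through the standard curve.

    Negative amounts (signal below the blank) are retained and flagged
    ``below_blank`` so replicate means remain unbiased.
    """
    amount = float(curve.inverse(signal))
    flags = frozenset({"below_blank"}) if amount < 0 else frozenset()
    return Quantified(amount=amount, flags=flags)


def medium_delta(
    sample_conc: float,
    medium_conc: float,
    direction: str,
    substrate: str = "",
    condition: str = "",
) -> MediumDelta:
    """Concentration change relative to the fresh medium.

    ``consumption`` returns medium − sample, ``production`` sample −
    medium.  Lactate under the LA condition sits on a 24 mmol/l
    background that swamps the produced increment, so that combination
    is always marked ``reliable=False`` irrespective of the numbers.
    """
    if sample_conc < 0 or medium_conc < 0:
        raise ValueError("concentrations must be >= 0")
    if direction == "consumption":
        delta = medium_conc - sample_conc
    elif direction == "production":
        delta = sample_conc - medium_conc
    else:
        raise ValueError("direction must be 'consumption' or 'production'")
    reliable = not (substrate == "lactate" and condition == "LA")
    return MediumDelta(
        delta=delta, direction=direction, substrate=substrate,
        condition=condition, reliable=reliable,
    )


def flux_normalize(
    delta_mM: float,
    volume_l: float,
    duration_min: float,
    cells: float,
    substrate: str = "",
    condition: str = "",
    reliable: bool = True,
) -> FluxRecord:
    """Convert a concentration change into pmol/min/1000 cells.

    ``flux = delta[mmol/l] * volume[l] * 1e9 / duration[min] / (cells/1000)``
    (1 mmol = 1e9 pmol).  The well volume has no default: it must be the
    actual supernatant volume of the experiment.
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be > 0")
    if cells <= 0:
        raise ValueError("cells must be > 0")
    if volume_l <= 0:
        raise ValueError("volume_l must be > 0")
    flux = delta_mM * volume_l * 1.0e9 / duration_min / (cells / 1000.0)
    return FluxRecord(
        substrate=substrate, delta_mM=delta_mM, volume_l=volume_l,
        duration_min=duration_min, cells=cells, flux=flux,
        condition=condition, reliable=reliable,
    )


def lactate_glucose_ratio(lactate_flux, glucose_flux) -> Quantified:
    """Molar Δlactate/Δglucose ratio.

    A value of 2 (flag ``pure_glycolysis``) means every consumed glucose
    appears as two lactates — purely glycolytic glucose disposal.
    Accepts floats or :class:`FluxRecord` objects; an unreliable lactate
    record is rejected, a zero glucose flux yields NaN with an
    ``undefined`` flag.
    """
    if isinstance(lactate_flux, FluxRecord):
        if not lactate_flux.reliable:
            raise ValueError("lactate flux is marked unreliable")
        lactate_flux = lactate_flux.flux
    if isinstance(glucose_flux, FluxRecord):
        glucose_flux = glucose_flux.flux
    if glucose_flux == 0:
        return Quantified(amount=math.nan, flags=frozenset({"undefined"}))
    ratio = lactate_flux / glucose_flux
    flags = frozenset({"pure_glycolysis"}) if math.isclose(ratio, 2.0, rel_tol=1e-6) else frozenset()
    return Quantified(amount=ratio, flags=flags)


def ph_from_ratio(ratio: float, cal: PhCalibration) -> Quantified:
    """pH from a BCECF ratio by linear interpolation between the two
    nigericin points; values outside the calibrated range are returned
    but flagged ``extrapolated``."""
    slope = (cal.ph2 - cal.ph1) / (cal.ratio2 - cal.ratio1)
    ph = cal.ph1 + slope * (ratio - cal.ratio1)
    lo, hi = sorted((cal.ratio1, cal.ratio2))
    flags = frozenset() if lo <= ratio <= hi else frozenset({"extrapolated"})
    return Quantified(amount=ph, flags=flags)


def ldh_release_fraction(media_activity: float, lysate_activity: float) -> float:
    """Fraction of total LDH activity found in the medium (necrosis marker)."""
    if media_activity < 0 or lysate_activity < 0:
        raise ValueError("activities must be >= 0")
    total = media_activity + lysate_activity
    if total == 0:
        raise ValueError("both activities are zero")
    return media_activity / total


def specific_activity(amount_converted: float, time_min: float, protein_ug: float) -> float:
    """Substrate turnover per minute per microgram protein."""
    if time_min <= 0:
        raise ValueError("time_min must be > 0")
    if protein_ug <= 0:
        raise ValueError("protein_ug must be > 0")
    return amount_converted / time_min / protein_ug


def senescence_index(c12fdg_count: float, hoechst_count: float) -> float:
    """SA-β-gal positive signal per nucleus: C12FDG counts / Hoechst counts."""
    if hoechst_count <= 0:
        raise ValueError("hoechst_count must be > 0")
    return c12fdg_count / hoechst_count


def circularity(area: float, perimeter: float) -> Quantified:
    """Shape circularity ``4*pi*area/perimeter^2`` in [0, 1].

    0 = spindle-shaped, 1 = a perfect circle.  Pixelated outlines can
    push the raw value above 1; it is clipped and flagged ``clipped``.
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be > 0")
    raw = 4.0 * math.pi * area / perimeter**2
    if raw > 1.0:
        return Quantified(amount=1.0, flags=frozenset({"clipped"}))
    return Quantified(amount=raw)


def hypertrophy_index(
    protein_per_well: float,
    cells_per_well: float,
    ctrl_protein_per_well: float,
    ctrl_cells_per_well: float,
) -> float:
    """Protein per cell relative to the control condition (hypertrophy marker)."""
    if cells_per_well <= 0 or ctrl_cells_per_well <= 0:
        raise ValueError("cell counts must be > 0")
    if ctrl_protein_per_well <= 0:
        raise ValueError("control protein must be > 0")
    return (protein_per_well / cells_per_well) / (
        ctrl_protein_per_well / ctrl_cells_per_well
    )


def quantify_plate(
    plate: pd.DataFrame,
    r_squared_warn: float = R_SQUARED_WARN,
) -> tuple[pd.DataFrame, CalibrationCurve]:
    """Quantify every sample well of a plate table against its standards.

    ``plate`` follows the generator schema (``well, role, amount, signal,
    condition, protein_ug``).  Returns the per-well table with ``amount``
    filled in (plus ``specific_amount`` where protein is present) and the
    fitted curve.
    """
    required = {"well", "role", "amount", "signal", "condition"}
    missing = required - set(plate.columns)
    if missing:
        raise KeyError(f"plate table missing column(s): {sorted(missing)}")
    std = plate[plate["role"] == "standard"]
    if len(std) < 2:
        raise ValueError("plate has fewer than 2 standard wells")
    curve = fit_calibration(list(zip(std["amount"], std["signal"])))
    samples = plate[plate["role"] == "sample"].copy()
    samples["amount"] = curve.inverse(samples["signal"].to_numpy())
    samples["below_blank"] = samples["amount"] < 0
    if "protein_ug" in samples:
        with np.errstate(divide="ignore", invalid="ignore"):
            samples["specific_amount"] = samples["amount"] / samples["protein_ug"]
    return samples, curve
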