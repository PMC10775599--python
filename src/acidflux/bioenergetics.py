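"""Mito-Stress parameter extraction and the stoichiometric ATP budget.

An extracellular-flux (Seahorse-type) run measures the oxygen
consumption rate (OCR) of a well through four phases separated by
injections: baseline, oligomycin (ATP-synthase block), FCCP (uncoupled,
maximal respiration) and rotenone/antimycin A (non-mitochondrial
residual).  From the four plateaus the six standard mitochondrial
parameters follow by subtraction:

    non_mito     = min OCR after rotenone/antimycin A
    basal        = last baseline OCR − non_mito
    proton_leak  = min OCR after oligomycin − non_mito
    atp_linked   = basal − proton_leak
    maximal      = max OCR after FCCP − non_mito
    spare        = maximal − basal
    coupling     = atp_linked / basal

The ATP budget converts measured substrate fluxes into ATP-production
capacities using fixed molar yields: 2 ATP per glucose through
glycolysis, 30 ATP per glucose fully oxidized, and 10 ATP per glutamine
at a cost of 2 O₂ — which pins the ATP:O₂ conversion of ATP-linked
respiration at 5 (consistent with 30 ATP / 6 O₂ for glucose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assays import FluxRecord

__all__ = [
    "PHASES",
    "OCRTrace",
    "MitoParams",
    "StoichiometryConstants",
    "GlutamineRequirement",
    "ATPBudget",
    "extract_mito_params",
    "glycolytic_atp",
    "max_oxidative_atp_from_glucose",
    "max_atp_from_glutamine",
    "mito_atp_from_ocr",
    "glutamine_required",
    "build_atp_budget",
    "traces_from_table",
]

#: Injection phases in measurement order.
PHASES: tuple[str, ...] = ("baseline", "oligo", "fccp", "rotAA")


@dataclass
class OCRTrace:
    """One well's injection-annotated OCR time series.

    ``ocr`` is in pmol O₂/min/1000 cells; phases must appear in the
    canonical order with at least one measurement each.
    """

    time_min: np.ndarray
    ocr: np.ndarray
    phase: np.ndarray
    well: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.time_min) == len(self.ocr) == len(self.phase)):
            raise ValueError("time, ocr and phase must have equal length")
        if not np.all(np.isfinite(self.ocr)):
            raise ValueError("OCR values must be finite")
        seen = [p for i, p in enumerate(self.phase) if i == 0 or self.phase[i - 1] != p]
        if tuple(seen) != PHASES:
            raise ValueError(
                f"phases must appear once each in order {PHASES}, got {tuple(seen)}"
            )

    def phase_values(self, name: str) -> np.ndarray:
        return self.ocr[self.phase == name]


@dataclass(frozen=True)
class MitoParams:
    """The six Mito-Stress parameters plus the non-mitochondrial residual.

    Internal identities hold exactly: ``basal = atp_linked + proton_leak``
    and ``spare = maximal - basal``.
    """

    non_mito: float
    basal: float
    atp_linked: float
    proton_leak: float
    maximal: float
    spare: float
    coupling_efficiency: float
    flags: frozenset[str] = frozenset()


_PHASE_STATS = {"last": lambda v: v[-1], "min": np.min, "max": np.max, "mean": np.mean}

#: Standard Mito-Stress summary convention per phase.
DEFAULT_PHASE_STATS = {"baseline": "last", "oligo": "min", "fccp": "max", "rotAA": "min"}


def extract_mito_params(
    trace: OCRTrace, phase_stats: dict[str, str] | None = None
) -> MitoParams:
    """Derive the mitochondrial parameters from one OCR trace.

    ``phase_stats`` overrides the per-phase summary statistic (default:
    last baseline cycle, minimum oligomycin, maximum FCCP, minimum
    rotenone/antimycin A).  Negative baseline-corrected rates are kept
    and flagged ``negative_rate``; a non-positive basal rate leaves the
    coupling efficiency NaN with an ``undefined_coupling`` flag.
    """
    stats = dict(DEFAULT_PHASE_STATS)
    if phase_stats:
        stats.update(phase_stats)
    summary = {}
    for phase in PHASES:
        values = trace.phase_values(phase)
        if len(values) == 0:
            raise ValueError(f"trace is missing phase {phase!r}")
        summary[phase] = float(_PHASE_STATS[stats[phase]](values))

    non_mito = summary["rotAA"]
    basal = summary["baseline"] - non_mito
    proton_leak = summary["oligo"] - non_mito
    atp_linked = basal - proton_leak
    maximal = summary["fccp"] - non_mito
    spare = maximal - basal

    flags = set()
    if min(basal, proton_leak, atp_linked, maximal, spare) < 0:
        flags.add("negative_rate")
    if basal > 0:
        coupling = atp_linked / basal
    else:
        coupling = math.nan
        flags.add("undefined_coupling")
    return MitoParams(
        non_mito=non_mito, basal=basal, atp_linked=atp_linked,
        proton_leak=proton_leak, maximal=maximal, spare=spare,
        coupling_efficiency=coupling, flags=frozenset(flags),
    )


@dataclass(frozen=True)
class StoichiometryConstants:
    """Molar ATP yields used by the budget.

    ``atp_per_o2`` is derived from the glutamine stoichiometry
    (10 ATP / 2 O₂ = 5) and equals the glucose value (30 ATP / 6 O₂).
    """

    atp_per_glucose_glycolysis: float = 2.0
    atp_per_glucose_oxidation: float = 30.0
    atp_per_glutamine: float = 10.0
    o2_per_glutamine: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "atp_per_glucose_glycolysis",
            "atp_per_glucose_oxidation",
            "atp_per_glutamine",
            "o2_per_glutamine",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def atp_per_o2(self) -> float:
        return self.atp_per_glutamine / self.o2_per_glutamine


def _flux(value) -> float:
    return value.flux if isinstance(value, FluxRecord) else float(value)


def glycolytic_atp(glucose_flux, k: StoichiometryConstants | None = None) -> float:
    """ATP production flux from glycolysis: 2 ATP per glucose consumed."""
    k = k or StoichiometryConstants()
    return k.atp_per_glucose_glycolysis * _flux(glucose_flux)


def max_oxidative_atp_from_glucose(glucose_flux, k: StoichiometryConstants | None = None) -> float:
    """Maximum possible ATP flux if all consumed glucose were fully oxidized."""
    k = k or StoichiometryConstants()
    return k.atp_per_glucose_oxidation * _flux(glucose_flux)


def max_atp_from_glutamine(glutamine_flux, k: StoichiometryConstants | None = None) -> float:
    """Maximum mitochondrial ATP flux from the measured glutamine consumption."""
    k = k or StoichiometryConstants()
    return k.atp_per_glutamine * _flux(glutamine_flux)


def mito_atp_from_ocr(atp_linked_ocr: float, k: StoichiometryConstants | None = None) -> float:
    """Mitochondrial ATP production from ATP-synthesis-linked respiration.

    Uses the ATP:O₂ ratio of 5 implied by both substrate stoichiometries.
    """
    k = k or StoichiometryConstants()
    if atp_linked_ocr < 0:
        raise ValueError("atp_linked_ocr must be >= 0")
    return k.atp_per_o2 * atp_linked_ocr


@dataclass(frozen=True)
class GlutamineRequirement:
    """Glutamine (and O₂) needed to fuel a given mitochondrial ATP flux."""

    glutamine_flux: float
    o2_flux: float
    sufficient: bool | None = None


def glutamine_required(
    mito_atp_flux: float,
    k: StoichiometryConstants | None = None,
    measured_glutamine_flux: float | None = None,
) -> GlutamineRequirement:
    """Glutamine flux needed to fuel ``mito_atp_flux`` (the red line).

    If a measured glutamine consumption is given, ``sufficient`` reports
    whether it covers the requirement.
    """
    k = k or StoichiometryConstants()
    if mito_atp_flux < 0:
        raise ValueError("mito_atp_flux must be >= 0")
    gln = mito_atp_flux / k.atp_per_glutamine
    sufficient = None
    if measured_glutamine_flux is not None:
        sufficient = bool(measured_glutamine_flux >= gln)
    return GlutamineRequirement(
        glutamine_flux=gln, o2_flux=k.o2_per_glutamine * gln, sufficient=sufficient
    )


@dataclass(frozen=True)
class ATPBudget:
    """The nine-panel ATP-budget reconciliation for one condition.

    Fluxes in pmol/min/1000 cells; ``measured_atp_content`` is the
    independently assayed cellular ATP amount (a content, not a flux) and
    is never derived from the budget.  ``total_atp_capacity`` is the sum
    of glycolytic and OCR-derived mitochondrial ATP production; the
    glycolysis/OXPHOS fractions partition it.
    """

    condition: str
    glucose_flux: float                  # panel 1
    glycolytic_atp: float                # panel 2
    max_ox_atp_from_glucose: float       # panel 3
    mito_atp_from_ocr: float             # panel 4
    glutamine_flux: float                # panel 5
    max_atp_from_glutamine: float        # panel 6
    total_atp_capacity: float            # panel 7
    measured_atp_content: float          # panel 8
    fraction_glycolysis: float           # panel 9
    fraction_oxphos: float               # panel 9
    glutamine_required_red_line: float
    glutamine_sufficient: bool


def build_atp_budget(
    glucose: FluxRecord | None,
    glutamine: FluxRecord | None,
    params: MitoParams | None,
    atp_content: float,
    k: StoichiometryConstants | None = None,
    condition: str = "",
) -> ATPBudget:
    """Assemble the nine-panel budget from one condition's measurements.

    Raises ``ValueError`` naming the affected panel when an input is
    missing.
    """
    k = k or StoichiometryConstants()
    if glucose is None:
        raise ValueError("missing glucose flux (panels 1-3)")
    if glutamine is None:
        raise ValueError("missing glutamine flux (panels 5-6)")
    if params is None:
        raise ValueError("missing mitochondrial parameters (panel 4)")
    if atp_content is None or not math.isfinite(atp_content):
        raise ValueError("missing measured ATP content (panel 8)")

    glyc = glycolytic_atp(glucose, k)
    mito = mito_atp_from_ocr(max(params.atp_linked, 0.0), k)
    total = glyc + mito
    if total > 0:
        f_glyc = glyc / total
    else:
        f_glyc = math.nan
    req = glutamine_required(mito, k, measured_glutamine_flux=_flux(glutamine))
    return ATPBudget(
        condition=condition or glucose.condition,
        glucose_flux=_flux(glucose),
        glycolytic_atp=glyc,
        max_ox_atp_from_glucose=max_oxidative_atp_from_glucose(glucose, k),
        mito_atp_from_ocr=mito,
        glutamine_flux=_flux(glutamine),
        max_atp_from_glutamine=max_atp_from_glutamine(glutamine, k),
        total_atp_capacity=total,
        measured_atp_content=float(atp_content),
        fraction_glycolysis=f_glyc,
        fraction_oxphos=1.0 - f_glyc if math.isfinite(f_glyc) else math.nan,
        glutamine_required_red_line=req.glutamine_flux,
        glutamine_sufficient=bool(req.sufficient),
    )


def traces_from_table(table: pd.DataFrame) -> list[OCRTrace]:
    """Split a long OCR table (well, condition, phase, time_min, ocr)
    into per-well :class:`OCRTrace` objects, preserving time order."""
    required = {"well", "phase", "time_min", "ocr"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"OCR table missing column(s): {sorted(missing)}")
    traces = []
    for well, sub in table.groupby("well", sort=False):
        sub = sub.sort_values("time_min")
        condition = str(sub["condition"].iloc[0]) if "condition" in sub else ""
        traces.append(
            OCRTrace(
                time_min=sub["time_min"].to_numpy(),
                ocr=sub["ocr"].to_numpy(),
                phase=sub["phase"].to_numpy(),
                well=str(well),
                condition=condition,
            )
        )
    return traces
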