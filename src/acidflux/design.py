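"""Experimental design and ground truth for virtual acidosis experiments.

The study design emulated throughout the package is a five-condition
treatment of primary human aortic smooth muscle cells (HAoSMCs) for 48 h:

* ``ctrl``        — DMEM, pH 7.4
* ``HCl``         — hydrochloric acidosis, pH 6.8
* ``LA``          — lactic acidosis, pH 6.8 + 24 mmol/l lactate
* ``mannitol``    — hyperosmolarity control, pH 7.4, 24 mmol/l mannitol
* ``Na_lactate``  — sodium lactate, pH 7.4, 24 mmol/l lactate

:class:`ExperimentDesign` carries the invariant layout of such an
experiment (replication, duration, cell number, medium composition,
seed); :class:`GroundTruth` carries the latent per-condition quantities
(substrate fluxes, OCR phase levels, intracellular pH, assay amounts)
the synthetic generator embeds and the analysis modules must recover.
The default truth encodes the qualitative ordering of effect sizes
observed in this system: lactic acidosis > hydrochloric acidosis >>
lactate alone (which is nearly inert).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CONDITIONS",
    "CONTRASTS",
    "ExperimentDesign",
    "GroundTruth",
    "DEFAULT_DEG_REGIONS",
]

#: Ordered condition labels of the five-arm design.
CONDITIONS: tuple[str, ...] = ("ctrl", "HCl", "LA", "mannitol", "Na_lactate")

#: Treatment-vs-control contrasts for which DEG tables exist.
CONTRASTS: tuple[str, ...] = ("HCl", "LA", "Na_lactate")

#: Conditions whose medium contains a 24 mmol/l lactate background.
_LACTATE_BACKGROUND_MM = {"LA": 24.0, "Na_lactate": 24.0}


def _default_medium() -> dict[str, float]:
    # DMEM used for treatment: 5.5 mmol/l glucose; glutamine set to a
    # typical 2 mmol/l supplementation.
    return {"glucose": 5.5, "glutamine": 2.0}


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of one virtual experiment.

    Parameters
    ----------
    conditions
        Ordered condition labels; defaults to the five-arm design.
    replicates_per_condition
        Sample wells per condition (n per group).
    duration_min
        Treatment duration in minutes; default 2880 (48 h).
    cells_per_well
        Cell count per well at assay time.
    volume_l
        Supernatant volume per well in litres. Required for converting a
        concentration change into an absolute flux; there is no universal
        default in the assay itself, the generator simply records the
        volume it used so the analysis can be given it explicitly.
    medium_mM
        Substrate concentrations of the fresh treatment medium (mmol/l).
    seed
        Master seed; identical (design, truth, seed) gives bit-identical
        synthetic output.
    """

    conditions: tuple[str, ...] = CONDITIONS
    replicates_per_condition: int = 6
    duration_min: float = 2880.0
    cells_per_well: int = 100_000
    volume_l: float = 1.0e-3
    medium_mM: dict[str, float] = field(default_factory=_default_medium)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration_min must be > 0")
        if self.cells_per_well <= 0:
            raise ValueError("cells_per_well must be > 0")
        if self.replicates_per_condition < 1:
            raise ValueError("every condition needs >= 1 replicate")
        if self.volume_l <= 0:
            raise ValueError("volume_l must be > 0")
        if not self.conditions:
            raise ValueError("at least one condition required")

    def lactate_background_mM(self, condition: str) -> float:
        """Lactate concentration already present in the fresh medium."""
        return _LACTATE_BACKGROUND_MM.get(condition, 0.0)


#: Default Venn-region gene counts for the three DEG contrasts.  Keys are
#: frozensets of contrast labels; a gene in region {"HCl", "LA"} is a DEG
#: in both acidosis contrasts but not under Na-lactate.
DEFAULT_DEG_REGIONS: dict[frozenset[str], int] = {
    frozenset({"HCl"}): 59,
    frozenset({"LA"}): 1212,
    frozenset({"Na_lactate"}): 15,
    frozenset({"HCl", "LA"}): 433,
    frozenset({"HCl", "Na_lactate"}): 0,
    frozenset({"LA", "Na_lactate"}): 0,
    frozenset({"HCl", "LA", "Na_lactate"}): 0,
}


def _default_fluxes() -> dict[str, dict[str, float]]:
    # pmol/min/1000 cells; consumption positive for glucose/glutamine,
    # production positive for lactate.  Control glucose is fully
    # glycolytic (lactate = 2 x glucose); lactic acidosis nearly abolishes
    # glycolysis while hydrochloric acidosis halves it.
    return {
        "ctrl": {"glucose": 3.5, "lactate": 7.0, "glutamine": 1.0},
        "HCl": {"glucose": 1.5, "lactate": 3.0, "glutamine": 0.6},
        "LA": {"glucose": 0.1, "lactate": 0.2, "glutamine": 0.25},
        "mannitol": {"glucose": 3.4, "lactate": 6.8, "glutamine": 0.95},
        "Na_lactate": {"glucose": 3.3, "lactate": 6.6, "glutamine": 0.9},
    }


def _default_ocr_levels() -> dict[str, tuple[float, float, float, float]]:
    # (baseline, post-oligomycin, post-FCCP, post-rotenone/antimycin A)
    # in pmol O2/min/1000 cells, on the same per-cell scale as the
    # substrate fluxes.  Acidosis slightly raises basal rate and proton
    # leak and markedly raises maximal (FCCP) respiration.  The implied
    # ATP-linked rates make glutamine consumption sufficient to fuel
    # OCR-derived ATP production under ctrl and HCl but not under LA,
    # and put glycolysis and OXPHOS near parity under ctrl.
    return {
        "ctrl": (2.5, 1.0, 4.5, 0.5),
        "HCl": (2.65, 1.55, 5.65, 0.5),
        "LA": (2.75, 1.55, 5.9, 0.5),
        "mannitol": (2.5, 1.0, 4.5, 0.5),
        "Na_lactate": (2.5, 1.02, 4.55, 0.5),
    }


def _default_ph() -> dict[str, float]:
    # Intracellular pH: slightly alkaline at extracellular pH 7.4,
    # following the extracellular acidification without counter-regulation.
    return {
        "ctrl": 7.53,
        "HCl": 6.8,
        "LA": 6.8,
        "mannitol": 7.53,
        "Na_lactate": 7.53,
    }


def _default_amounts() -> dict[str, dict[str, float]]:
    # True per-well amounts for the non-concentration assays, in the
    # assay's own working units (ATP nmol/well, LDH mU/well, caspase
    # nmol AFC/well, BrdU relative absorbance units, protein ug/well).
    # ATP content falls under lactic acidosis only; LDH release and
    # caspase activity stay low in all arms (no loss of viability);
    # BrdU incorporation drops with acidosis; protein rises 25-35 %
    # (hypertrophy).
    return {
        "ATP": {"ctrl": 2.0, "HCl": 1.95, "LA": 1.2, "mannitol": 2.0, "Na_lactate": 1.9},
        "LDH_media": {"ctrl": 20.0, "HCl": 14.0, "LA": 14.0, "mannitol": 16.0, "Na_lactate": 26.0},
        "LDH_lysate": {"ctrl": 80.0, "HCl": 86.0, "LA": 86.0, "mannitol": 84.0, "Na_lactate": 78.0},
        "caspase": {"ctrl": 0.50, "HCl": 0.48, "LA": 0.52, "mannitol": 0.50, "Na_lactate": 0.62},
        "BrdU": {"ctrl": 1.0, "HCl": 0.70, "LA": 0.40, "mannitol": 0.98, "Na_lactate": 0.95},
        "protein": {"ctrl": 10.0, "HCl": 12.5, "LA": 13.5, "mannitol": 10.0, "Na_lactate": 10.2},
    }


@dataclass
class GroundTruth:
    """Latent per-condition quantities embedded in synthetic data.

    ``fluxes`` are substrate fluxes in pmol/min/1000 cells, ``ocr_levels``
    the four Mito-Stress phase plateaus, ``ph`` the intracellular pH,
    ``amounts`` per-assay true amounts, ``protein_ug`` the per-well
    protein used for normalization.  ``deg_regions``, ``deg_scale`` and
    ``flip_prob`` parameterize the DEG-table generator: the HCl effect of
    a gene regulated by both acidoses is ``deg_scale`` times its LA
    effect, sign-flipped with probability ``flip_prob``.
    """

    fluxes: dict[str, dict[str, float]] = field(default_factory=_default_fluxes)
    ocr_levels: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_ocr_levels
    )
    ph: dict[str, float] = field(default_factory=_default_ph)
    amounts: dict[str, dict[str, float]] = field(default_factory=_default_amounts)
    protein_ug: dict[str, float] = field(
        default_factory=lambda: _default_amounts()["protein"]
    )
    deg_regions: dict[frozenset[str], int] = field(
        default_factory=lambda: dict(DEFAULT_DEG_REGIONS)
    )
    deg_scale: float = 0.7
    flip_prob: float = 0.05

    def __post_init__(self) -> None:
        for cond, sub in self.fluxes.items():
            for name, value in sub.items():
                if not math.isfinite(value):
                    raise ValueError(f"non-finite flux for {cond}/{name}")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0, 1]")

    def true_delta_mM(self, design: ExperimentDesign, condition: str, substrate: str) -> float:
        """Concentration change (mmol/l) over the run implied by the true flux.

        Inverse of the flux-normalization formula
        ``flux = delta * volume * 1e9 / duration / (cells/1000)``.
        """
        flux = self.fluxes[condition][substrate]
        return (
            flux
            * design.duration_min
            * (design.cells_per_well / 1000.0)
            / (design.volume_l * 1.0e9)
        )
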