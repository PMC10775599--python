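"""Seeded generators for virtual plates, OCR traces, pH ratios and DEG tables.

Every generator embeds a known :class:`~acidflux.design.GroundTruth` so
each downstream analysis stage has a recovery test: with zero noise the
quantification pipeline inverts the generator exactly; with noise,
Monte-Carlo means recover the truth within sampling error.

Noise model: multiplicative Gaussian on the instrument signal,
``signal * (1 + cv * z)`` truncated at zero — plate-reader error scales
with signal.  Randomness derives from one master seed with an
independent substream per artifact (per assay label, per generator), so
adding wells to one assay never perturbs another.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .design import CONTRASTS, DEFAULT_DEG_REGIONS, ExperimentDesign, GroundTruth

__all__ = [
    "PLATE_ASSAYS",
    "generate_plate_assay",
    "generate_ocr_trace",
    "generate_bcecf",
    "generate_deg_tables",
    "generate_term_collection",
]

#: Supported plate-assay labels -> (instrument gain: signal per unit,
#: instrument offset: blank signal).  Units per assay: glucose/lactate/
#: glutamine mmol/l in the well; ATP nmol; LDH mU; caspase nmol AFC;
#: BrdU relative units; protein ug.
PLATE_ASSAYS: dict[str, tuple[float, float]] = {
    "glucose": (0.12, 0.05),
    "lactate": (0.04, 0.05),
    "glutamine": (0.30, 0.02),
    "ATP": (5.0e4, 200.0),
    "LDH_media": (12.0, 40.0),
    "LDH_lysate": (12.0, 40.0),
    "caspase": (900.0, 30.0),
    "BrdU": (1.1, 0.08),
    "protein": (0.02, 0.04),
}

#: Assays whose sample wells hold a concentration computed from true
#: fluxes and the medium, rather than a per-condition amount.
_CONCENTRATION_ASSAYS = ("glucose", "lactate", "glutamine")

_N_STANDARDS = 6  # six-point linear series including the blank


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator derived from a master seed and an integer key."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _assay_rng(design: ExperimentDesign, assay: str) -> np.random.Generator:
    index = sorted(PLATE_ASSAYS).index(assay)
    return _substream(design.seed, 1, index)


def _noisy(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    if cv == 0:
        return np.asarray(values, dtype=float)
    out = values * (1.0 + cv * rng.standard_normal(np.shape(values)))
    return np.clip(out, 0.0, None)


def _true_sample_values(
    design: ExperimentDesign, assay: str, truth: GroundTruth
) -> dict[str, float]:
    """True per-well quantity per condition, in the assay's own unit."""
    if assay not in _CONCENTRATION_ASSAYS:
        return dict(truth.amounts[assay])
    values: dict[str, float] = {}
    for cond in design.conditions:
        delta = truth.true_delta_mM(design, cond, assay)
        if assay == "lactate":
            conc = design.lactate_background_mM(cond) + delta  # production adds
        else:
            conc = design.medium_mM[assay] - delta  # consumption depletes
        values[cond] = conc
    return values


def generate_plate_assay(
    design: ExperimentDesign,
    assay: str,
    truth: GroundTruth | None = None,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one plate table (standards + blanks + sample wells).

    Returns ``(plate, sidecar)``.  ``plate`` has the schema the
    quantification module reads: columns ``well, role, amount, signal,
    condition, protein_ug`` where ``amount`` is filled for standards
    only.  ``sidecar`` records the embedded ground truth per sample well.

    The standard series is a six-point linear dilution including the
    blank, spanning 125 % of the largest true sample value, read through
    the same (noisy) instrument model as the samples.
    """
    if assay not in PLATE_ASSAYS:
        raise ValueError(
            f"unknown assay {assay!r}; expected one of {sorted(PLATE_ASSAYS)}"
        )
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    truth = truth or GroundTruth()
    rng = rng if rng is not None else _assay_rng(design, assay)
    gain, offset = PLATE_ASSAYS[assay]

    sample_values = _true_sample_values(design, assay, truth)
    top = 1.25 * max(max(sample_values.values()), 1e-9)
    std_amounts = np.linspace(0.0, top, _N_STANDARDS)

    rows: list[dict] = []
    for i, amt in enumerate(std_amounts):
        signal = float(_noisy(rng, np.array(offset + gain * amt), noise_cv))
        rows.append(
            {"well": f"STD{i + 1}", "role": "standard", "amount": amt,
             "signal": signal, "condition": "", "protein_ug": np.nan}
        )
    for i in range(2):
        signal = float(_noisy(rng, np.array(offset), noise_cv))
        rows.append(
            {"well": f"BLK{i + 1}", "role": "blank", "amount": 0.0,
             "signal": signal, "condition": "", "protein_ug": np.nan}
        )

    sidecar_rows: list[dict] = []
    for cond in design.conditions:
        true_value = sample_values[cond]
        protein = truth.protein_ug[cond]
        for r in range(design.replicates_per_condition):
            well = f"{cond}_{r + 1}"
            signal = float(_noisy(rng, np.array(offset + gain * true_value), noise_cv))
            rows.append(
                {"well": well, "role": "sample", "amount": np.nan,
                 "signal": signal, "condition": cond, "protein_ug": protein}
            )
            sidecar_rows.append(
                {"well": well, "condition": cond, "assay": assay,
                 "true_value": true_value, "true_protein_ug": protein}
            )
    return pd.DataFrame(rows), pd.DataFrame(sidecar_rows)


_PHASES = ("baseline", "oligo", "fccp", "rotAA")
_CYCLE_MIN = 6.5  # minutes between successive OCR measurements


def generate_ocr_trace(
    design: ExperimentDesign,
    truth: GroundTruth | None = None,
    cycles_per_phase: int = 3,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate Mito-Stress OCR traces for every well of the design.

    Each trace visits the four injection phases in order (baseline ->
    oligomycin -> FCCP -> rotenone/antimycin A) with ``cycles_per_phase``
    measurements per phase at the condition's true plateau plus
    multiplicative noise.  Returns a long table with columns
    ``well, condition, phase, time_min, ocr``.
    """
    if cycles_per_phase < 1:
        raise ValueError("cycles_per_phase must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    truth = truth or GroundTruth()
    for cond in design.conditions:
        levels = truth.ocr_levels[cond]
        if any(level <= 0 for level in levels):
            raise ValueError(f"non-positive OCR phase level for condition {cond!r}")
    rng = rng if rng is not None else _substream(design.seed, 2)

    rows: list[dict] = []
    for cond in design.conditions:
        levels = truth.ocr_levels[cond]
        for r in range(design.replicates_per_condition):
            well = f"{cond}_{r + 1}"
            t = 0.0
            for phase, level in zip(_PHASES, levels):
                values = _noisy(rng, np.full(cycles_per_phase, float(level)), noise_cv)
                for v in values:
                    t += _CYCLE_MIN
                    rows.append(
                        {"well": well, "condition": cond, "phase": phase,
                         "time_min": t, "ocr": float(v)}
                    )
    return pd.DataFrame(rows)


# Linear BCECF instrument model used by the generator: emission ratio
# rises with pH.  The two nigericin calibration points bracket the
# physiological range.
_BCECF_SLOPE = 0.9  # ratio units per pH unit
_BCECF_OFFSET = -4.5
_NIGERICIN_PH = (6.8, 7.6)


def generate_bcecf(
    design: ExperimentDesign,
    truth: GroundTruth | None = None,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate BCECF fluorescence ratios plus two nigericin calibration rows.

    Rows with ``role == 'calibration'`` carry the known clamped pH in the
    ``ph`` column; sample rows carry only the measured ratio.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    truth = truth or GroundTruth()
    rng = rng if rng is not None else _substream(design.seed, 3)

    rows: list[dict] = []
    for ph in _NIGERICIN_PH:
        ratio = float(_noisy(rng, np.array(_BCECF_OFFSET + _BCECF_SLOPE * ph), noise_cv))
        rows.append({"well": f"CAL_pH{ph}", "role": "calibration",
                     "condition": "", "ph": ph, "ratio": ratio})
    for cond in design.conditions:
        true_ratio = _BCECF_OFFSET + _BCECF_SLOPE * truth.ph[cond]
        for r in range(design.replicates_per_condition):
            ratio = float(_noisy(rng, np.array(true_ratio), noise_cv))
            rows.append({"well": f"{cond}_{r + 1}", "role": "sample",
                         "condition": cond, "ph": np.nan, "ratio": ratio})
    return pd.DataFrame(rows)


def generate_deg_tables(
    n_genes: int = 12000,
    regions: Mapping[frozenset[str], int] | None = None,
    effect_scale: float = 0.7,
    flip_prob: float = 0.05,
    lfc_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Generate per-contrast DEG tables with a known Venn/concordance structure.

    Parameters
    ----------
    n_genes
        Total genes in each table (identical gene universe).
    regions
        Venn-region gene counts keyed by frozensets of contrast labels;
        defaults to the package's five-arm structure (HCl-specific 59,
        LA-specific 1212, Na-lactate-specific 15, HCl&LA 433).
    effect_scale
        For genes regulated by both HCl and LA, the HCl log2FC is
        ``effect_scale`` times the LA log2FC (the weaker acidosis).
    flip_prob
        Probability that such a shared gene's HCl effect has its sign
        flipped relative to LA.
    lfc_noise_sd
        Additive Gaussian noise on member log2FCs (0 keeps the scaled
        relation exact, so a fitted regression slope equals
        ``effect_scale``).
    seed
        Generator seed.

    Returns
    -------
    tables, truth
        ``tables`` maps contrast label -> DataFrame with columns
        ``gene_id, log2fc, fdr, fpm_ctrl, fpm_<contrast>``; ``truth``
        records the designed DEG sets, flipped genes, scale and
        flip probability.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must lie in [0, 1]")
    regions = dict(regions) if regions is not None else dict(DEFAULT_DEG_REGIONS)
    n_members = sum(regions.values())
    if n_members > n_genes:
        raise ValueError("region counts exceed n_genes")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))

    gene_ids = np.array([f"g{i:06d}" for i in range(n_genes)])
    membership: dict[str, np.ndarray] = {c: np.zeros(n_genes, bool) for c in CONTRASTS}
    pos = 0
    region_of_gene = np.full(n_genes, None, dtype=object)
    for key in sorted(regions, key=lambda k: sorted(k)):
        count = regions[key]
        idx = slice(pos, pos + count)
        for contrast in key:
            membership[contrast][idx] = True
        region_of_gene[idx] = key
        pos += count

    # Latent LA-scale effect per member gene; magnitudes chosen so the
    # weaker (scaled) HCl effect still clears the |log2FC| >= 0.59 gate.
    base_mag = 0.6 + rng.exponential(0.9, n_genes)
    shared = membership["HCl"] & membership["LA"]
    base_mag[shared] = (0.6 + rng.exponential(0.9, int(shared.sum()))) / max(effect_scale, 1e-6)
    base_sign = rng.choice([-1.0, 1.0], n_genes)
    base_effect = base_sign * base_mag
    flipped = shared & (rng.random(n_genes) < flip_prob)

    tables: dict[str, pd.DataFrame] = {}
    for contrast in CONTRASTS:
        member = membership[contrast]
        lfc = np.clip(rng.normal(0.0, 0.15, n_genes), -0.5, 0.5)  # null genes
        if contrast == "LA":
            lfc[member] = base_effect[member]
        elif contrast == "HCl":
            lfc[member] = np.where(
                shared[member], effect_scale * base_effect[member], base_effect[member]
            )
            lfc[flipped] = -effect_scale * base_effect[flipped]
        else:  # Na_lactate: independent small-but-significant effects
            lfc[member] = base_sign[member] * (0.6 + rng.exponential(0.3, int(member.sum())))
        if lfc_noise_sd > 0:
            lfc[member] = lfc[member] + rng.normal(0.0, lfc_noise_sd, int(member.sum()))

        fdr = rng.uniform(0.06, 1.0, n_genes)
        fdr[member] = 10.0 ** rng.uniform(-8.0, np.log10(0.04), int(member.sum()))

        fpm_ctrl = rng.lognormal(np.log(30.0), 1.2, n_genes)
        fpm_treat = fpm_ctrl * 2.0 ** lfc
        # members must survive the abundance gate (> 5 FPM in one group)
        low = member & (np.maximum(fpm_ctrl, fpm_treat) <= 5.0)
        fpm_ctrl[low] = 6.0

        tables[contrast] = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "log2fc": lfc,
                "fdr": fdr,
                "fpm_ctrl": fpm_ctrl,
                f"fpm_{contrast.lower()}": fpm_ctrl * 2.0 ** lfc,
            }
        )

    truth = {
        "deg_sets": {c: set(gene_ids[membership[c]]) for c in CONTRASTS},
        "regions": {key: set(gene_ids[region_of_gene == key]) for key in regions},
        "flipped": set(gene_ids[flipped]),
        "effect_scale": effect_scale,
        "flip_prob": flip_prob,
    }
    return tables, truth


def generate_term_collection(
    deg_set: set[str],
    all_genes: list[str],
    n_enriched: int = 3,
    n_null: int = 20,
    term_size: int = 120,
    enriched_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[dict[str, list[str]], set[str]]:
    """Build a synthetic gene-set collection with known enriched terms.

    Enriched terms draw ``enriched_fraction`` of their genes from
    ``deg_set`` and the rest from the background; null terms are uniform
    draws from the whole universe.  Returns ``(collection, enriched_ids)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    universe = np.asarray(all_genes)
    deg = np.asarray(sorted(deg_set))
    background = np.asarray(sorted(set(all_genes) - deg_set))
    collection: dict[str, list[str]] = {}
    enriched_ids: set[str] = set()
    for i in range(n_enriched):
        k = int(rng.binomial(term_size, enriched_fraction))
        genes = np.concatenate(
            [
                rng.choice(deg, size=min(k, len(deg)), replace=False),
                rng.choice(background, size=term_size - min(k, len(deg)), replace=False),
            ]
        )
        name = f"TERM_ENR_{i:03d}"
        collection[name] = sorted(set(genes))
        enriched_ids.add(name)
    for i in range(n_null):
        genes = rng.choice(universe, size=term_size, replace=False)
        collection[f"TERM_NULL_{i:03d}"] = sorted(set(genes))
    return collection, enriched_ids
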