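"""End-to-end orchestration: simulate -> quantify -> bioenergetics -> degs -> enrich -> stats.

Each stage reads fixed tabular schemas from the run directory and writes
its outputs back there, so stages can be run individually (a missing
upstream file produces an error naming the stage) and disabling one
stage never alters another's outputs.  A run manifest records the
configuration hash, seed, package version and per-file row counts;
identical configurations produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import CONDITIONS, CONTRASTS, ExperimentDesign, GroundTruth
from . import assays, bioenergetics, stats, synth, transcriptome

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("acidflux")

STAGES = ("simulate", "quantify", "bioenergetics", "degs", "enrich", "stats")

#: Caspase assay incubation time (min) used for specific activity.
_CASPASE_TIME_MIN = 90.0


class PipelineError(RuntimeError):
    """A stage could not run; the message names the stage and the input."""


def _default_design() -> dict:
    return {
        "replicates_per_condition": 6,
        "duration_min": 2880.0,
        "cells_per_well": 100000,
        "volume_l": 0.001,
    }


def _default_noise() -> dict:
    return {"plate_cv": 0.02, "ocr_cv": 0.03, "bcecf_cv": 0.01, "cycles_per_phase": 3}


def _default_deg() -> dict:
    return {"n_genes": 12000, "effect_scale": 0.7, "flip_prob": 0.05}


def _default_thresholds() -> dict:
    return {
        "fc": transcriptome.FC_THRESHOLD,
        "fdr": transcriptome.FDR_THRESHOLD,
        "fpm": transcriptome.FPM_THRESHOLD,
        "enrich_p": 0.001,
        "enrich_e": 2.5,
        "min_term": 5,
        "max_term": 3000,
    }


def _default_stoichiometry() -> dict:
    return dataclasses.asdict(bioenergetics.StoichiometryConstants())


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    All analysis thresholds and stoichiometric constants live here with
    their standard defaults; operations never hard-code them.
    """

    outdir: str = "acidflux_run"
    seed: int = 0
    design: dict = field(default_factory=_default_design)
    noise: dict = field(default_factory=_default_noise)
    deg: dict = field(default_factory=_default_deg)
    thresholds: dict = field(default_factory=_default_thresholds)
    stoichiometry: dict = field(default_factory=_default_stoichiometry)
    phase_stats: dict = field(default_factory=lambda: dict(bioenergetics.DEFAULT_PHASE_STATS))

    def __post_init__(self) -> None:
        for name, value in self.thresholds.items():
            if value <= 0:
                raise ValueError(f"threshold {name!r} must be positive")
        self.seed = int(self.seed)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        base = cls()
        merged = base.to_dict()
        for key, value in data.items():
            if key not in merged:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(merged[key], dict) and isinstance(value, dict):
                merged[key] = {**merged[key], **value}
            else:
                merged[key] = value
        return cls(**merged)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()

    # -- typed views --------------------------------------------------
    def experiment_design(self) -> ExperimentDesign:
        return ExperimentDesign(seed=self.seed, **self.design)

    def constants(self) -> bioenergetics.StoichiometryConstants:
        return bioenergetics.StoichiometryConstants(**self.stoichiometry)


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def _write_json(obj, path: Path) -> int:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return len(obj) if hasattr(obj, "__len__") else 1


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage {stage!r}: required input {path.name} missing "
            f"(run the 'simulate' stage first)"
        )
    return path


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, out: Path, counts: dict) -> None:
    design = cfg.experiment_design()
    truth = GroundTruth(
        deg_scale=cfg.deg["effect_scale"], flip_prob=cfg.deg["flip_prob"]
    )
    cv = cfg.noise["plate_cv"]
    for assay in sorted(synth.PLATE_ASSAYS):
        plate, sidecar = synth.generate_plate_assay(design, assay, truth, noise_cv=cv)
        counts[f"plates/{assay}.tsv"] = _write_tsv(plate, out / "plates" / f"{assay}.tsv")
        counts[f"plates/{assay}.truth.tsv"] = _write_tsv(
            sidecar, out / "plates" / f"{assay}.truth.tsv"
        )
    ocr = synth.generate_ocr_trace(
        design, truth, cycles_per_phase=cfg.noise["cycles_per_phase"],
        noise_cv=cfg.noise["ocr_cv"],
    )
    counts["ocr_traces.tsv"] = _write_tsv(ocr, out / "ocr_traces.tsv")
    bcecf = synth.generate_bcecf(design, truth, noise_cv=cfg.noise["bcecf_cv"])
    counts["bcecf.tsv"] = _write_tsv(bcecf, out / "bcecf.tsv")

    tables, deg_truth = synth.generate_deg_tables(
        n_genes=cfg.deg["n_genes"], effect_scale=cfg.deg["effect_scale"],
        flip_prob=cfg.deg["flip_prob"], seed=cfg.seed,
    )
    for contrast, table in tables.items():
        counts[f"degs/{contrast}.tsv"] = _write_tsv(table, out / "degs" / f"{contrast}.tsv")
    truth_json = {
        "deg_set_sizes": {c: len(s) for c, s in deg_truth["deg_sets"].items()},
        "region_sizes": {"&".join(sorted(k)): len(v) for k, v in deg_truth["regions"].items()},
        "effect_scale": deg_truth["effect_scale"],
        "flip_prob": deg_truth["flip_prob"],
        "n_flipped": len(deg_truth["flipped"]),
    }
    counts["degs/truth.json"] = _write_json(truth_json, out / "degs" / "truth.json")

    all_genes = list(tables["LA"]["gene_id"])
    collection, enriched = synth.generate_term_collection(
        deg_truth["deg_sets"]["LA"], all_genes, seed=cfg.seed
    )
    transcriptome.write_gmt(collection, out / "terms.gmt")
    counts["terms.gmt"] = len(collection)
    counts["terms.enriched.json"] = _write_json(sorted(enriched), out / "terms.enriched.json")
    log.info("simulate: wrote %d artifacts", len(counts))


_DIRECTIONS = {"glucose": "consumption", "glutamine": "consumption", "lactate": "production"}


def _stage_quantify(cfg: RunConfig, out: Path, counts: dict) -> None:
    design = cfg.experiment_design()
    flux_rows = []
    condition_means: dict[str, dict[str, float]] = {}
    for assay in sorted(synth.PLATE_ASSAYS):
        plate = pd.read_csv(_require(out / "plates" / f"{assay}.tsv", "quantify"), sep="\t")
        samples, curve = assays.quantify_plate(plate)
        counts[f"quantified/{assay}.tsv"] = _write_tsv(
            samples, out / "quantified" / f"{assay}.tsv"
        )
        condition_means[assay] = samples.groupby("condition")["amount"].mean().to_dict()
        if assay in _DIRECTIONS:
            direction = _DIRECTIONS[assay]
            for cond, conc in condition_means[assay].items():
                if assay == "lactate":
                    medium = design.lactate_background_mM(cond)
                else:
                    medium = design.medium_mM[assay]
                delta = assays.medium_delta(
                    max(conc, 0.0), medium, direction, substrate=assay, condition=cond
                )
                record = assays.flux_normalize(
                    delta.delta, design.volume_l, design.duration_min,
                    design.cells_per_well, substrate=assay, condition=cond,
                    reliable=delta.reliable,
                )
                flux_rows.append(dataclasses.asdict(record))
    fluxes = pd.DataFrame(flux_rows)
    counts["fluxes.tsv"] = _write_tsv(fluxes, out / "fluxes.tsv")

    # Δlactate/Δglucose where the lactate determination is reliable
    ratios = {}
    for cond in design.conditions:
        sub = fluxes[fluxes["condition"] == cond].set_index("substrate")
        lac, glc = sub.loc["lactate"], sub.loc["glucose"]
        if lac["reliable"] and glc["flux"] != 0:
            r = assays.lactate_glucose_ratio(float(lac["flux"]), float(glc["flux"]))
            ratios[cond] = {"ratio": r.amount, "flags": sorted(r.flags)}
    counts["glycolysis_ratio.json"] = _write_json(ratios, out / "glycolysis_ratio.json")

    # viability indices and ATP content per condition
    viability = []
    for cond in design.conditions:
        ldh = assays.ldh_release_fraction(
            condition_means["LDH_media"][cond], condition_means["LDH_lysate"][cond]
        )
        caspase = assays.specific_activity(
            condition_means["caspase"][cond], _CASPASE_TIME_MIN,
            condition_means["protein"][cond],
        )
        hyper = assays.hypertrophy_index(
            condition_means["protein"][cond], design.cells_per_well,
            condition_means["protein"]["ctrl"], design.cells_per_well,
        )
        viability.append(
            {"condition": cond, "ldh_release_fraction": ldh,
             "caspase_specific_activity": caspase, "hypertrophy_index": hyper,
             "brdu_relative": condition_means["BrdU"][cond] / condition_means["BrdU"]["ctrl"],
             "atp_content": condition_means["ATP"][cond]}
        )
    counts["viability.tsv"] = _write_tsv(pd.DataFrame(viability), out / "viability.tsv")

    # intracellular pH from the two-point nigericin calibration
    bcecf = pd.read_csv(_require(out / "bcecf.tsv", "quantify"), sep="\t")
    cal_rows = bcecf[bcecf["role"] == "calibration"]
    cal = assays.PhCalibration(
        ph1=float(cal_rows["ph"].iloc[0]), ratio1=float(cal_rows["ratio"].iloc[0]),
        ph2=float(cal_rows["ph"].iloc[1]), ratio2=float(cal_rows["ratio"].iloc[1]),
    )
    sample_rows = bcecf[bcecf["role"] == "sample"].copy()
    results = [assays.ph_from_ratio(r, cal) for r in sample_rows["ratio"]]
    sample_rows["ph"] = [q.amount for q in results]
    sample_rows["flags"] = [",".join(sorted(q.flags)) for q in results]
    counts["ph.tsv"] = _write_tsv(
        sample_rows[["well", "condition", "ratio", "ph", "flags"]], out / "ph.tsv"
    )
    log.info("quantify: %d flux records", len(fluxes))


def _stage_bioenergetics(cfg: RunConfig, out: Path, counts: dict) -> None:
    k = cfg.constants()
    table = pd.read_csv(_require(out / "ocr_traces.tsv", "bioenergetics"), sep="\t")
    traces = bioenergetics.traces_from_table(table)
    rows = []
    for trace in traces:
        params = bioenergetics.extract_mito_params(trace, cfg.phase_stats)
        row = dataclasses.asdict(params)
        row["flags"] = ",".join(sorted(params.flags))
        row.update({"well": trace.well, "condition": trace.condition})
        rows.append(row)
    mito = pd.DataFrame(rows)
    counts["mito_params.tsv"] = _write_tsv(mito, out / "mito_params.tsv")

    fluxes = pd.read_csv(_require(out / "fluxes.tsv", "bioenergetics"), sep="\t")
    viability = pd.read_csv(_require(out / "viability.tsv", "bioenergetics"), sep="\t")
    atp_content = viability.set_index("condition")["atp_content"]
    budgets = {}
    numeric = [c for c in mito.columns if c not in ("well", "condition", "flags")]
    cond_params = mito.groupby("condition")[numeric].mean()
    for cond in cond_params.index:
        sub = fluxes[fluxes["condition"] == cond].set_index("substrate")
        mp = cond_params.loc[cond]
        params = bioenergetics.MitoParams(
            non_mito=mp["non_mito"], basal=mp["basal"], atp_linked=mp["atp_linked"],
            proton_leak=mp["proton_leak"], maximal=mp["maximal"], spare=mp["spare"],
            coupling_efficiency=mp["coupling_efficiency"],
        )
        glucose = assays.FluxRecord(**sub.loc["glucose"].to_dict(), substrate="glucose")
        glutamine = assays.FluxRecord(**sub.loc["glutamine"].to_dict(), substrate="glutamine")
        budget = bioenergetics.build_atp_budget(
            glucose, glutamine, params, float(atp_content[cond]), k, condition=cond
        )
        budgets[cond] = dataclasses.asdict(budget)
    counts["atp_budget.json"] = _write_json(budgets, out / "atp_budget.json")
    log.info("bioenergetics: %d traces, %d budgets", len(traces), len(budgets))


def _stage_degs(cfg: RunConfig, out: Path, counts: dict) -> None:
    th = cfg.thresholds
    kw = {"fc_threshold": th["fc"], "fdr_threshold": th["fdr"], "fpm_threshold": th["fpm"]}
    tables = {
        c: pd.read_csv(_require(out / "degs" / f"{c}.tsv", "degs"), sep="\t")
        for c in CONTRASTS
    }
    sets = {c: transcriptome.deg_set(t, **kw) for c, t in tables.items()}
    for c, genes in sets.items():
        counts[f"deg_analysis/{c}.degs.txt"] = len(genes)
        path = out / "deg_analysis" / f"{c}.degs.txt"
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("\n".join(sorted(genes)) + "\n")

    venn = transcriptome.venn_partition(sets["HCl"], sets["LA"], sets["Na_lactate"])
    venn_json = {
        "labels": list(venn.labels),
        "regions": {"&".join(sorted(key)): len(g) for key, g in venn.regions.items()},
        "totals": {label: venn.total(label) for label in venn.labels},
    }
    counts["deg_analysis/venn.json"] = _write_json(venn_json, out / "deg_analysis" / "venn.json")

    conc = {}
    for universe in ("union", "intersection"):
        res = transcriptome.concordance(tables["HCl"], tables["LA"], universe=universe, **kw)
        conc[universe] = dataclasses.asdict(res)
    counts["deg_analysis/concordance.json"] = _write_json(
        conc, out / "deg_analysis" / "concordance.json"
    )
    log.info("degs: totals %s", venn_json["totals"])


def _stage_enrich(cfg: RunConfig, out: Path, counts: dict) -> None:
    th = cfg.thresholds
    query_path = _require(out / "deg_analysis" / "LA.degs.txt", "enrich")
    query = set(query_path.read_text().split())
    collection = transcriptome.read_gmt(_require(out / "terms.gmt", "enrich"))
    results = transcriptome.enrich(
        query, collection, domain_size=cfg.deg["n_genes"],
        min_term=th["min_term"], max_term=th["max_term"],
        p_thresh=th["enrich_p"], e_thresh=th["enrich_e"],
    )
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    counts["enrichment.tsv"] = _write_tsv(df, out / "enrichment.tsv")
    log.info("enrich: %d significant terms", len(df))


def _stage_stats(cfg: RunConfig, out: Path, counts: dict) -> None:
    rows = []
    for assay in ("glucose", "ATP", "BrdU"):
        table = pd.read_csv(
            _require(out / "quantified" / f"{assay}.tsv", "stats"), sep="\t"
        )
        groups = {}
        for cond in CONDITIONS:
            values = table.loc[table["condition"] == cond, "amount"].to_numpy()
            if values.size >= 3 and values.var(ddof=1) > 0:
                values = stats.chisq_outlier(values).cleaned  # per-cell screen
            groups[cond] = values
        for res in stats.rank_test(groups):
            rows.append(
                {"assay": assay, "comparison": "|".join(res.comparison),
                 "method": res.method, "statistic": res.statistic,
                 "p_value": res.p_value, "p_adjusted": res.p_adjusted,
                 "n": "|".join(map(str, res.n))}
            )
    counts["stats/rank_tests.tsv"] = _write_tsv(
        pd.DataFrame(rows), out / "stats" / "rank_tests.tsv"
    )
    log.info("stats: %d tests", len(rows))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "bioenergetics": _stage_bioenergetics,
    "degs": _stage_degs,
    "enrich": _stage_enrich,
    "stats": _stage_stats,
}


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Run the requested stages (default: all, in canonical order).

    Returns the manifest dictionary; also writes ``manifest.json`` into
    the run directory.  The manifest contains no absolute paths or
    timestamps, so identical configurations yield byte-identical
    manifests.
    """
    stages = list(STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    for stage in stages:
        log.info("running stage %s", stage)
        _STAGE_FUNCS[stage](config, out, counts)

    manifest = {
        "package": "acidflux",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": {k: v for k, v in config.to_dict().items() if k != "outdir"},
        "stages": stages,
        "outputs": counts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
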