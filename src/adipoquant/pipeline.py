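"""File-in/file-out pipeline: simulate -> quantify -> stats -> associate -> report.

Each stage reads and writes plain TSV files inside one output directory, so
re-running any stage is idempotent and a complete run is reproducible
byte-for-byte given the same configuration and seed. A JSON manifest records
the configuration hash, seed, per-stage outputs and row counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AGES, CohortConfig, IMAGING_PARAMETERS
from .imaging import FrameSchedule
from .kinetics import (
    SteadyPhaseRule,
    bat_sat_ratio,
    fur_matrix,
    sat_mass,
)
from .microbiome import AbundanceTable, spearman_assoc
from .phenotype import StratificationRule, fold_change, stratify_mio, summarize
from .synthetic import ROIS, CohortBundle, generate_cohort

logger = logging.getLogger(__name__)

PHENOTYPE_VARIABLES = [
    "body_weight",
    "fasting_glycemia",
    "scan_glycemia",
    "triglycerides",
    "leptin",
    "resistin",
    "food_intake",
]
KINETIC_VARIABLES = [
    "sat_hu",
    "bat_hu",
    "sat_ge",
    "bat_ge",
    "sat_gu",
    "bat_gu",
    "sat_mass_g",
    "whole_sat_gu",
    "bat_sat_gu_ratio",
]
HEADLINE_FOLDS = [
    # (feature, numerator class, denominator class)
    ("Unclassified.Rikenellaceae", "MIO", "ND"),
    ("Unclassified.Clostridiales", "ND", "MIOR"),
]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: CohortConfig, out_dir: Path) -> dict[str, Path]:
    bundle = generate_cohort(config)
    return bundle.to_dir(out_dir)


def load_tac_matrices(
    tacs_path: Path, schedule: FrameSchedule
) -> tuple[list[str], dict[str, np.ndarray]]:
    """Rebuild per-ROI (animal x frame) activity matrices from the long TSV."""
    long = pd.read_csv(tacs_path, sep="\t")
    animal_ids = sorted(long["animal_id"].unique())
    matrices: dict[str, np.ndarray] = {}
    for roi in ROIS:
        sub = long[long["roi"] == roi].sort_values(
            ["animal_id", "frame_start_min"], kind="stable"
        )
        mat = sub["activity_kBq_per_mL"].to_numpy().reshape(
            len(animal_ids), schedule.n_frames
        )
        matrices[roi] = mat
    return animal_ids, matrices


def quantify(
    animals: pd.DataFrame,
    animal_ids: list[str],
    tac_matrices: dict[str, np.ndarray],
    schedule: FrameSchedule,
    hu: pd.DataFrame,
    rule: SteadyPhaseRule = SteadyPhaseRule(),
) -> pd.DataFrame:
    """Per-animal kinetic results from TAC matrices + metadata."""
    meta = animals.set_index("animal_id").loc[animal_ids]
    times = schedule.mid
    results = {"animal_id": animal_ids}
    ge = {
        roi: fur_matrix(
            tac_matrices[roi], tac_matrices["blood"], times, rule, schedule.scan_end
        )
        for roi in ("SAT", "BAT")
    }
    glycemia = meta["scan_glycemia"].to_numpy()
    results["sat_ge"] = ge["SAT"]
    results["bat_ge"] = ge["BAT"]
    results["sat_gu"] = ge["SAT"] * glycemia * 100.0
    results["bat_gu"] = ge["BAT"] * glycemia * 100.0
    results["sat_mass_g"] = np.array(
        [
            sat_mass(w, a)
            for w, a in zip(meta["body_weight"], meta["age_group"])
        ]
    )
    results["whole_sat_gu"] = results["sat_gu"] * results["sat_mass_g"] / 100.0
    results["bat_sat_gu_ratio"] = np.array(
        [bat_sat_ratio(b, s) for b, s in zip(results["bat_gu"], results["sat_gu"])]
    )
    df = pd.DataFrame(results)
    return df.merge(hu, on="animal_id", how="left")


def quantify_bundle(
    bundle: CohortBundle, rule: SteadyPhaseRule = SteadyPhaseRule()
) -> pd.DataFrame:
    """Kinetic results straight from an in-memory cohort bundle."""
    return quantify(
        bundle.animals,
        bundle.animal_ids,
        bundle.tac_activity,
        bundle.schedule,
        bundle.hu,
        rule,
    )


def stage_quantify(out_dir: Path, rule: SteadyPhaseRule = SteadyPhaseRule()) -> Path:
    schedule = FrameSchedule.from_tsv(out_dir / "schedule.tsv")
    animals = pd.read_csv(out_dir / "animals.tsv", sep="\t")
    hu = pd.read_csv(out_dir / "hu.tsv", sep="\t")
    animal_ids, matrices = load_tac_matrices(out_dir / "tacs.tsv", schedule)
    df = quantify(animals, animal_ids, matrices, schedule, hu, rule)
    path = out_dir / "kinetics.tsv"
    _write_tsv(df, path)
    return path


def stage_stats(
    out_dir: Path, rule: StratificationRule = StratificationRule()
) -> dict[str, Path]:
    animals = pd.read_csv(out_dir / "animals.tsv", sep="\t")
    kin = pd.read_csv(out_dir / "kinetics.tsv", sep="\t")
    merged = animals.merge(kin, on="animal_id")

    summary = summarize(
        merged,
        PHENOTYPE_VARIABLES + KINETIC_VARIABLES,
        ["age_group", "sex", "maternal_diet"],
        compare="maternal_diet",
    )

    adults = merged[merged["age_group"] == "6mo"]
    nd = adults[adults["maternal_diet"] == "ND"]
    hfd = adults[adults["maternal_diet"] == "HFD"]
    labels = stratify_mio(
        hfd["body_weight"].to_numpy(), nd["body_weight"].to_numpy(), rule
    )
    classes = pd.DataFrame(
        {"animal_id": hfd["animal_id"].to_numpy(), "weight_class": labels}
    )
    strat = merged.merge(classes, on="animal_id", how="left")
    strat["weight_class"] = strat["weight_class"].fillna(
        strat["maternal_diet"].map({"ND": "ND"})
    )
    adult_strat = strat[(strat["age_group"] == "6mo") & strat["weight_class"].notna()]
    class_summary = summarize(
        adult_strat,
        PHENOTYPE_VARIABLES + KINETIC_VARIABLES,
        ["weight_class"],
        compare="weight_class",
    )

    folds = []
    caecum_genus = AbundanceTable.from_tsv(
        out_dir / "abundance_caecum_genus.tsv", "caecum", "genus"
    )
    class_ids = adult_strat.set_index("animal_id")["weight_class"]
    for feature, cls_a, cls_b in HEADLINE_FOLDS:
        ids_a = class_ids.index[class_ids == cls_a]
        ids_b = class_ids.index[class_ids == cls_b]
        if len(ids_a) == 0 or len(ids_b) == 0:
            logger.warning("fold change %s: empty class, skipped", feature)
            continue
        folds.append(
            {
                "site": "caecum",
                "level": "genus",
                "feature": feature,
                "group_a": cls_a,
                "group_b": cls_b,
                "n_a": len(ids_a),
                "n_b": len(ids_b),
                "fold": fold_change(caecum_genus, ids_a, ids_b, feature),
            }
        )

    paths = {
        "summary.tsv": out_dir / "summary.tsv",
        "classes.tsv": out_dir / "classes.tsv",
        "class_summary.tsv": out_dir / "class_summary.tsv",
        "fold_changes.tsv": out_dir / "fold_changes.tsv",
    }
    _write_tsv(summary, paths["summary.tsv"])
    _write_tsv(classes, paths["classes.tsv"])
    _write_tsv(class_summary, paths["class_summary.tsv"])
    _write_tsv(pd.DataFrame(folds), paths["fold_changes.tsv"])
    return paths


def stage_associate(
    out_dir: Path, parameters: list[str] | None = None
) -> Path:
    animals = pd.read_csv(out_dir / "animals.tsv", sep="\t")
    kin = pd.read_csv(out_dir / "kinetics.tsv", sep="\t").set_index("animal_id")
    kin = kin.rename(columns={"bat_sat_gu_ratio": "bat_sat_ratio"})
    params = parameters if parameters is not None else list(IMAGING_PARAMETERS)
    age_of = animals.set_index("animal_id")["age_group"]

    results = []
    for path in sorted(out_dir.glob("abundance_*.tsv")):
        _, site, level = path.stem.split("_", 2)
        table = AbundanceTable.from_tsv(path, site, level)
        for age in AGES:
            ids = age_of.index[age_of == age].intersection(table.sample_ids)
            if len(ids) < 4:
                continue
            sub = AbundanceTable(site, level, table.data.loc[ids])
            res = spearman_assoc(sub, kin.loc[ids, params])
            res.insert(0, "age_group", age)
            results.append(res)
    out = pd.concat(results, ignore_index=True) if results else pd.DataFrame()
    path = out_dir / "associations.tsv"
    _write_tsv(out, path)
    return path


def stage_report(out_dir: Path) -> Path:
    """Markdown report with the stratified summary, fold changes and the
    FDR-significant associations; numbers rounded to presentation precision."""
    summary = pd.read_csv(out_dir / "summary.tsv", sep="\t")
    class_summary = pd.read_csv(out_dir / "class_summary.tsv", sep="\t")
    folds = pd.read_csv(out_dir / "fold_changes.tsv", sep="\t")
    assoc = pd.read_csv(out_dir / "associations.tsv", sep="\t")

    def fmt(value: float, var: str) -> str:
        if var.endswith("_ge"):
            return f"{value:.4f}"
        if var == "whole_sat_gu":
            return f"{value:.3f}"
        if var in ("body_weight", "sat_hu", "bat_hu") and abs(value) >= 10:
            return f"{value:.0f}"
        return f"{value:.1f}"

    lines = ["# Synthetic cohort report", ""]
    lines += ["## Group summary (mean ± SEM)", ""]
    piv = summary.copy()
    piv["cell"] = (
        piv["age_group"] + " " + piv["sex"] + " " + piv["maternal_diet"]
    )
    lines += ["| variable | " + " | ".join(piv["cell"].unique()) + " |"]
    lines += ["|---" * (1 + piv["cell"].nunique()) + "|"]
    for var, sub in piv.groupby("variable", sort=True):
        cells = [
            f"{fmt(r['mean'], var)} ± {fmt(r['sem'], var)}"
            for _, r in sub.iterrows()
        ]
        lines += [f"| {var} | " + " | ".join(cells) + " |"]
    lines += ["", "## Adult weight-response classes (ND / MIOR / MIO)", ""]
    lines += ["| variable | class | mean ± SEM | n | p |", "|---|---|---|---|---|"]
    for _, r in class_summary.iterrows():
        p = "" if pd.isna(r["p"]) else f"{r['p']:.3g}"
        lines += [
            f"| {r['variable']} | {r['weight_class']} | "
            f"{fmt(r['mean'], r['variable'])} ± {fmt(r['sem'], r['variable'])} | "
            f"{int(r['n'])} | {p} |"
        ]
    lines += ["", "## Headline caecum fold changes", ""]
    for _, r in folds.iterrows():
        lines += [
            f"- {r['feature']}: {r['group_a']}/{r['group_b']} = {r['fold']:.2f} "
            f"(n = {int(r['n_a'])}/{int(r['n_b'])})"
        ]
    sig = assoc[assoc["q"] <= 0.05].sort_values(["age_group", "q"]) if not assoc.empty else assoc
    lines += ["", f"## FDR-significant associations (q <= 0.05): {len(sig)}", ""]
    if len(sig):
        lines += ["| age | site | level | parameter | feature | rho | p | q |"]
        lines += ["|---|---|---|---|---|---|---|---|"]
        for _, r in sig.head(40).iterrows():
            lines += [
                f"| {r['age_group']} | {r['site']} | {r['level']} | {r['parameter']} | "
                f"{r['feature']} | {r['rho']:.2f} | {r['p']:.2g} | {r['q']:.3f} |"
            ]
    fig_path = _report_figure(summary, folds, out_dir)
    if fig_path is not None:
        lines += ["", f"![group glucose uptake and fold changes]({fig_path.name})"]
    path = out_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path


def _report_figure(
    summary: pd.DataFrame, folds: pd.DataFrame, out_dir: Path
) -> Path | None:
    """Bar panels of group GU and headline fold changes (PNG next to report)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gu = summary[summary["variable"].isin(["sat_gu", "bat_gu"])]
    if gu.empty:
        return None
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), constrained_layout=True)
    labels = gu["age_group"] + "\n" + gu["sex"] + " " + gu["maternal_diet"]
    for var, color in (("sat_gu", "#c49a6c"), ("bat_gu", "#7b4b2a")):
        sub = gu[gu["variable"] == var]
        axes[0].bar(
            labels[sub.index],
            sub["mean"],
            yerr=sub["sem"],
            label=var.replace("_", " ").upper(),
            alpha=0.75,
            color=color,
        )
    axes[0].set_ylabel("GU (µmol/min/100 g)")
    axes[0].tick_params(axis="x", labelsize=6)
    axes[0].legend(fontsize=7)
    if not folds.empty:
        names = folds["feature"] + "\n" + folds["group_a"] + "/" + folds["group_b"]
        axes[1].bar(names, folds["fold"], color="#5b7f5b")
        axes[1].axhline(1.0, color="k", lw=0.5)
        axes[1].set_ylabel("fold change (relative abundance)")
        axes[1].tick_params(axis="x", labelsize=6)
    path = out_dir / "report_panels.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_all(
    config: CohortConfig | str | Path | None = None,
    out_dir: str | Path = "adipoquant_run",
    seed: int | None = None,
) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    if config is None:
        config = CohortConfig()
    elif isinstance(config, (str, Path)):
        config = CohortConfig.from_yaml(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": [],
    }

    def record(name: str, paths) -> None:
        outputs = []
        if isinstance(paths, (str, Path)):
            paths = {Path(paths).name: Path(paths)}
        for _, path in sorted(paths.items()):
            rows = None
            if path.suffix == ".tsv":
                with open(path) as fh:
                    rows = max(0, sum(1 for _ in fh) - 1)
            outputs.append({"path": path.name, "rows": rows})
        manifest["stages"].append({"name": name, "outputs": outputs})

    stage_order = [
        ("simulate", lambda: stage_simulate(config, out)),
        ("quantify", lambda: stage_quantify(out)),
        ("stats", lambda: stage_stats(out)),
        ("associate", lambda: stage_associate(out)),
        ("report", lambda: stage_report(out)),
    ]
    for name, fn in stage_order:
        logger.info("stage %s ...", name)
        try:
            record(name, fn())
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    missing = [
        o["path"]
        for stage in manifest["stages"]
        for o in stage["outputs"]
        if not (out / o["path"]).exists()
    ]
    if missing:
        raise RuntimeError(f"declared outputs missing: {missing}")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
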