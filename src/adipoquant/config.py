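"""Cohort configuration: the study conditions the synthetic generator emulates.

The default configuration encodes, per (age x maternal diet x sex) cell, the
published group means of body weight, glycemia, triglycerides, adipose CT
radiodensity and glucose uptake in offspring of normal-diet (ND) and
high-fat-diet (HFD) dams, together with the adult weight-response dichotomy
(maternally induced obesity, MIO, vs obesity-resistant, MIOR), the headline
caecum microbiota signatures (10-fold Unclassified.Rikenellaceae enrichment
in MIO, 4-fold Unclassified.Clostridiales deficiency in MIOR) and the
rank-correlation targets linking taxa/pathway abundances to the imaging
parameters. Dispersions are standard deviations reconstructed from the
reported standard errors at the study's per-cell group size (about 5
animals per cell).

True fractional extraction (GE, min^-1) per cell is back-calculated from the
reported glucose uptake and scan glycemia via GU = GE x glycemia x 100;
per-animal GE is log-normal around the cell value with a log-SD matched to
the reported GU coefficient of variation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Optional

import yaml

AGES = ("1mo", "6mo")
DIETS = ("ND", "HFD")
SEXES = ("F", "M")
#: Fixed cell order used everywhere (determinism).
CELLS = [(age, diet, sex) for age in AGES for diet in DIETS for sex in SEXES]

#: Imaging parameters a taxon/pathway may be rank-coupled to.
IMAGING_PARAMETERS = (
    "sat_ge",
    "bat_ge",
    "sat_gu",
    "bat_gu",
    "bat_sat_ratio",
    "whole_sat_gu",
    "sat_hu",
    "bat_hu",
)

_REF_CELL_N = 5  # study cells held ~5 animals; converts SEM to SD


def _sd(sem: float, n: int = _REF_CELL_N) -> float:
    return sem * math.sqrt(n)


def _sigma_log(cv: float) -> float:
    """Log-SD of a log-normal with the given coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


def _ge(gu_mean: float, gu_sem: float, glycemia: float) -> tuple[float, float]:
    """(median GE, log-SD) from reported GU mean +/- SEM and scan glycemia."""
    median = gu_mean / (glycemia * 100.0)
    cv = _sd(gu_sem) / gu_mean
    return (median, _sigma_log(cv))


@dataclasses.dataclass
class CellParams:
    """Per-(age, diet, sex) generating distributions. (mean, SD) tuples."""

    body_weight: tuple[float, float]  # g
    fasting_glycemia: tuple[float, float]  # mmol/L
    scan_glycemia: tuple[float, float]  # mmol/L
    triglycerides: tuple[float, float]  # mmol/L
    leptin: tuple[float, float]  # assay units (ng/mL scale)
    resistin: tuple[float, float]
    food_intake: tuple[float, float]  # g/day
    sat_ge: tuple[float, float]  # (median min^-1, log-SD)
    bat_ge: tuple[float, float]
    sat_hu: tuple[float, float]  # Hounsfield units
    bat_hu: tuple[float, float]


@dataclasses.dataclass
class MioConfig:
    """Latent obesity-response class of adult HFD offspring.

    Assignment is Bernoulli per animal with a sex-specific probability
    (maternally induced obesity prevailed in males); body weight, leptin,
    resistin and food intake are then drawn from class-specific
    distributions, the remaining variables from the animal's cell.
    """

    fraction_male: float = 2.0 / 3.0
    fraction_female: float = 0.0
    mio_weight: tuple[float, float] = (42.8, _sd(0.3, 4))
    mior_weight_male: tuple[float, float] = (29.6, _sd(1.1))
    mior_weight_female: tuple[float, float] = (27.0, 0.8)
    mio_leptin: tuple[float, float] = (12.0, 2.0)
    mior_leptin: tuple[float, float] = (3.5, 1.0)
    mio_resistin: tuple[float, float] = (6.0, 1.0)
    mior_resistin: tuple[float, float] = (2.2, 0.5)
    mio_food_intake: tuple[float, float] = (4.2, 0.3)
    mior_food_intake: tuple[float, float] = (3.6, 0.25)

    def fraction(self, sex: str) -> float:
        return self.fraction_male if sex == "M" else self.fraction_female


@dataclasses.dataclass
class BloodCurveParams:
    """Two-exponential intraperitoneal input function (rise then clearance).

    amplitude is the peak blood activity (kBq/mL); the curve is
    amplitude * (exp(-clearance*t) - exp(-absorption*t)) / peak-normalizer.
    """

    absorption_rate: float = 0.3  # min^-1
    clearance_rate: float = 0.05  # min^-1
    amplitude: float = 150.0  # kBq/mL at peak

    def __post_init__(self) -> None:
        if self.absorption_rate <= 0 or self.clearance_rate <= 0 or self.amplitude <= 0:
            raise ValueError("blood-curve parameters must be positive")
        if math.isclose(self.absorption_rate, self.clearance_rate):
            raise ValueError("absorption and clearance rates must differ")


@dataclasses.dataclass
class TaxonSpec:
    """One taxon or KEGG pathway in one (site, level) abundance table.

    mean_pct      baseline mean relative abundance, percent of the table total
    sigma         log-SD of the log-normal marginal (overdispersion)
    class_effects relative (post-TSS) fold change vs baseline keyed by latent
                  class ("MIO"/"MIOR") or maternal diet ("HFD"); the generator
                  converts these to pre-normalization multipliers (closure)
    assoc         optional (imaging parameter, target Spearman rho, age group)
                  realized through a Gaussian copula on per-animal latents
    """

    name: str
    level: str
    site: str
    mean_pct: float
    sigma: float = 0.6
    class_effects: dict[str, float] = dataclasses.field(default_factory=dict)
    assoc: Optional[tuple[str, float, str]] = None

    def validate(self) -> None:
        if self.mean_pct <= 0:
            raise ValueError(f"{self.name}: mean_pct must be positive")
        if self.sigma < 0:
            raise ValueError(f"{self.name}: sigma must be >= 0")
        for key, fold in self.class_effects.items():
            if fold <= 0:
                raise ValueError(f"{self.name}: effect for {key} must be positive")
        if self.assoc is not None:
            param, rho, age = self.assoc
            if param not in IMAGING_PARAMETERS:
                raise ValueError(f"{self.name}: unknown imaging parameter {param!r}")
            if not abs(rho) < 1:
                raise ValueError(f"{self.name}: |target rho| must be < 1")
            if age not in AGES:
                raise ValueError(f"{self.name}: unknown age group {age!r}")


@dataclasses.dataclass
class CohortConfig:
    """Complete specification of one synthetic study."""

    n_per_cell: int = 5
    seed: int = 20220828
    cells: dict[tuple[str, str, str], CellParams] = dataclasses.field(
        default_factory=lambda: dict(_default_cells())
    )
    mio: MioConfig = dataclasses.field(default_factory=MioConfig)
    taxa: list[TaxonSpec] = dataclasses.field(default_factory=lambda: default_taxa())
    blood: BloodCurveParams = dataclasses.field(default_factory=BloodCurveParams)
    amplitude_cv: float = 0.10  # animal-to-animal injected-dose variability
    tac_noise_sd: float = 0.05  # relative (multiplicative) TAC noise
    blood_fraction: float = 0.0  # vascular spillover fraction in tissue TACs
    frame_start: tuple[float, ...] = (0, 1, 2, 3, 4, 7, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55)
    frame_duration: tuple[float, ...] = (1, 1, 1, 1, 3, 3, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5)

    def validate(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        if not 0 <= self.tac_noise_sd:
            raise ValueError("tac_noise_sd must be >= 0")
        if not 0 <= self.blood_fraction < 1:
            raise ValueError("blood_fraction must be in [0, 1)")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")
        for frac in (self.mio.fraction_male, self.mio.fraction_female):
            if not 0 <= frac <= 1:
                raise ValueError("MIO fractions must be in [0, 1]")
        missing = [c for c in CELLS if c not in self.cells]
        if missing:
            raise ValueError(f"cells missing for {missing}")
        for cell, cp in self.cells.items():
            for field in dataclasses.fields(CellParams):
                mean, spread = getattr(cp, field.name)
                if spread < 0:
                    raise ValueError(f"{cell} {field.name}: SD must be >= 0")
        for taxon in self.taxa:
            taxon.validate()
        starts = list(self.frame_start)
        durs = list(self.frame_duration)
        if len(starts) != len(durs) or not starts:
            raise ValueError("frame_start and frame_duration must be equally long")
        for i in range(1, len(starts)):
            if starts[i] <= starts[i - 1]:
                raise ValueError("frame starts must be strictly increasing")
            if starts[i] < starts[i - 1] + durs[i - 1] - 1e-9:
                raise ValueError("frames must not overlap")
        if any(d <= 0 for d in durs):
            raise ValueError("frame durations must be positive")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {
                    ("|".join(k) if isinstance(k, tuple) else k): enc(v)
                    for k, v in obj.items()
                }
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        return enc(self)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        data = dict(data)
        if "cells" in data:
            data["cells"] = {
                tuple(k.split("|")): CellParams(
                    **{kk: tuple(vv) for kk, vv in v.items()}
                )
                for k, v in data["cells"].items()
            }
        if "mio" in data:
            m = dict(data["mio"])
            for key, val in m.items():
                if isinstance(val, list):
                    m[key] = tuple(val)
            data["mio"] = MioConfig(**m)
        if "taxa" in data:
            taxa = []
            for t in data["taxa"]:
                t = dict(t)
                if t.get("assoc") is not None:
                    t["assoc"] = tuple(t["assoc"])
                taxa.append(TaxonSpec(**t))
            data["taxa"] = taxa
        if "blood" in data:
            data["blood"] = BloodCurveParams(**data["blood"])
        for key in ("frame_start", "frame_duration"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _default_cells():
    # (age, diet, sex) -> CellParams; means/SEMs from the stratified group table,
    # GE back-calculated from GU and scan glycemia.
    yield ("1mo", "ND", "F"), CellParams(
        body_weight=(17, _sd(1)),
        fasting_glycemia=(6.3, _sd(0.2)),
        scan_glycemia=(4.6, _sd(0.6)),
        triglycerides=(0.794, _sd(0.004)),
        leptin=(2.0, 0.5),
        resistin=(1.5, 0.4),
        food_intake=(2.5, 0.3),
        sat_ge=_ge(1.9, 0.7, 4.6),
        bat_ge=_ge(2.0, 1.0, 4.6),
        sat_hu=(-34, _sd(48)),
        bat_hu=(-56, _sd(22)),
    )
    yield ("1mo", "HFD", "F"), CellParams(
        body_weight=(13, _sd(1)),
        fasting_glycemia=(8.5, _sd(1.2)),
        scan_glycemia=(6.7, _sd(1.2)),
        triglycerides=(0.805, _sd(0.015)),
        leptin=(2.2, 0.5),
        resistin=(1.7, 0.4),
        food_intake=(2.5, 0.3),
        sat_ge=_ge(1.7, 0.3, 6.7),
        bat_ge=_ge(3.5, 0.8, 6.7),
        sat_hu=(-94, _sd(8)),
        bat_hu=(-78, _sd(31)),
    )
    yield ("1mo", "ND", "M"), CellParams(
        body_weight=(18, _sd(0.4)),
        fasting_glycemia=(8.3, _sd(0.6)),
        scan_glycemia=(7.7, _sd(0.9)),
        triglycerides=(0.819, _sd(0.028)),
        leptin=(2.0, 0.5),
        resistin=(1.5, 0.4),
        food_intake=(2.7, 0.3),
        sat_ge=_ge(5.0, 1.3, 7.7),
        bat_ge=_ge(5.8, 1.5, 7.7),
        sat_hu=(-30, _sd(21)),
        bat_hu=(-46, _sd(28)),
    )
    yield ("1mo", "HFD", "M"), CellParams(
        body_weight=(19, _sd(2)),
        fasting_glycemia=(7.8, _sd(0.4)),
        scan_glycemia=(8.1, _sd(0.7)),
        triglycerides=(0.931, _sd(0.141)),
        leptin=(2.2, 0.5),
        resistin=(1.7, 0.4),
        food_intake=(2.7, 0.3),
        sat_ge=_ge(2.3, 0.4, 8.1),
        bat_ge=_ge(4.3, 1.4, 8.1),
        sat_hu=(-81, _sd(13)),
        bat_hu=(-74, _sd(26)),
    )
    yield ("6mo", "ND", "F"), CellParams(
        body_weight=(26, _sd(2)),
        fasting_glycemia=(5.3, _sd(0.3)),
        scan_glycemia=(5.6, _sd(0.9)),
        triglycerides=(0.790, 0.01),
        leptin=(3.0, 1.0),
        resistin=(2.0, 0.5),
        food_intake=(3.0, 0.25),
        sat_ge=_ge(2.1, 0.3, 5.6),
        bat_ge=_ge(4.9, 1.0, 5.6),
        sat_hu=(-2.2, _sd(31)),
        bat_hu=(61, _sd(20)),
    )
    yield ("6mo", "HFD", "F"), CellParams(
        body_weight=(27, 0.8),  # overridden by latent class (all MIOR)
        fasting_glycemia=(10.5, _sd(0.3)),
        scan_glycemia=(14.5, _sd(3.2)),
        triglycerides=(1.123, _sd(0.333)),
        leptin=(4.0, 1.0),
        resistin=(2.5, 0.6),
        food_intake=(3.6, 0.3),
        sat_ge=_ge(5.1, 2.0, 14.5),
        bat_ge=_ge(6.4, 2.2, 14.5),
        sat_hu=(-19, _sd(3)),
        bat_hu=(-22, _sd(43)),
    )
    yield ("6mo", "ND", "M"), CellParams(
        body_weight=(31, _sd(1)),
        fasting_glycemia=(6.4, _sd(0.7)),
        scan_glycemia=(7.2, _sd(1.0)),
        triglycerides=(0.790, 0.01),
        leptin=(3.0, 1.0),
        resistin=(2.0, 0.5),
        food_intake=(3.0, 0.25),
        sat_ge=_ge(2.5, 1.0, 7.2),
        bat_ge=_ge(6.6, 2.4, 7.2),
        sat_hu=(-51, _sd(53)),
        bat_hu=(-39, _sd(27)),
    )
    yield ("6mo", "HFD", "M"), CellParams(
        body_weight=(38, _sd(2)),  # realized through the MIO/MIOR mixture
        fasting_glycemia=(7.2, _sd(0.8)),
        scan_glycemia=(7.7, _sd(1.1)),
        triglycerides=(1.155, _sd(0.101)),
        leptin=(4.0, 1.0),
        resistin=(2.5, 0.6),
        food_intake=(3.6, 0.3),
        sat_ge=_ge(2.9, 0.8, 7.7),
        bat_ge=_ge(2.4, 0.5, 7.7),
        sat_hu=(-31, _sd(23)),
        bat_hu=(-53, _sd(23)),
    )


def default_cells() -> dict[tuple[str, str, str], CellParams]:
    return dict(_default_cells())


def default_taxa() -> list[TaxonSpec]:
    """Default microbiota/pathway composition with the planted signatures.

    Baseline abundances follow the reported mean relative abundances of the
    significantly associated taxa; filler taxa and an "Other" remainder give
    realistic compositions. The two headline class-effect taxa carry no
    explicit copula entry: their association with BAT/SAT metabolism emerges
    from the class structure itself.
    """
    t = TaxonSpec
    taxa: list[TaxonSpec] = [
        # -- caecum, genus ------------------------------------------------
        t("Dorea", "genus", "caecum", 1.01, assoc=("sat_ge", -0.7, "1mo")),
        t("Unclassified.Enterococcaceae", "genus", "caecum", 1.54, assoc=("bat_gu", -0.79, "6mo")),
        t("Bacillus", "genus", "caecum", 1.53, assoc=("bat_ge", -0.72, "6mo")),
        t("Unclassified.Rikenellaceae", "genus", "caecum", 0.20, class_effects={"MIO": 10.0}),
        t("Unclassified.Clostridiales", "genus", "caecum", 16.01, class_effects={"MIOR": 0.25}),
        t("rc44", "genus", "caecum", 0.38, assoc=("whole_sat_gu", -0.72, "6mo")),
        t("Anaerotruncus", "genus", "caecum", 0.02, assoc=("whole_sat_gu", -0.70, "6mo")),
        t("Oscillospira", "genus", "caecum", 2.01, assoc=("whole_sat_gu", -0.65, "6mo")),
        t("Coprococcus", "genus", "caecum", 0.62, assoc=("whole_sat_gu", -0.71, "6mo")),
        t("Unclassified.Christensenellaceae", "genus", "caecum", 0.14, assoc=("whole_sat_gu", -0.72, "6mo")),
        t("Unclassified.Ruminococcaceae", "genus", "caecum", 3.85, assoc=("whole_sat_gu", -0.71, "6mo")),
        t("Dehalobacterium", "genus", "caecum", 0.07, assoc=("whole_sat_gu", -0.64, "6mo")),
        t("Unclassified.Erysipelotrichaceae", "genus", "caecum", 1.14, assoc=("whole_sat_gu", -0.61, "6mo")),
        t("Lactobacillus", "genus", "caecum", 5.0),
        t("Bacteroides", "genus", "caecum", 12.0),
        t("Blautia", "genus", "caecum", 2.0),
        t("Ruminococcus", "genus", "caecum", 3.0),
        t("Akkermansia", "genus", "caecum", 1.5),
        t("Other", "genus", "caecum", 47.98, sigma=0.25),
        # -- caecum, family ----------------------------------------------
        t("Enterococcaceae", "family", "caecum", 1.55, assoc=("bat_ge", -0.78, "6mo")),
        t("Bacillaceae", "family", "caecum", 1.53, assoc=("bat_ge", -0.72, "6mo")),
        t("Streptococcaceae", "family", "caecum", 0.03, assoc=("bat_ge", -0.63, "6mo")),
        t("Peptostreptococcaceae", "family", "caecum", 2.02, assoc=("bat_ge", 0.62, "6mo")),
        t("Aerococcaceae", "family", "caecum", 0.42, assoc=("bat_ge", -0.62, "6mo")),
        t("Staphylococcaceae", "family", "caecum", 0.98, assoc=("bat_gu", -0.64, "6mo")),
        t("Rikenellaceae", "family", "caecum", 0.20, class_effects={"MIO": 10.0}),
        t("Unclassified.Clostridiales", "family", "caecum", 16.01, class_effects={"MIOR": 0.25}),
        t("Ruminococcaceae", "family", "caecum", 6.67, assoc=("whole_sat_gu", -0.80, "6mo")),
        t("Peptococcaceae", "family", "caecum", 0.38, assoc=("whole_sat_gu", -0.72, "6mo")),
        t("Christensenellaceae", "family", "caecum", 0.14, assoc=("whole_sat_gu", -0.72, "6mo")),
        t("Dehalobacteriaceae", "family", "caecum", 0.07, assoc=("whole_sat_gu", -0.64, "6mo")),
        t("Lachnospiraceae", "family", "caecum", 12.0),
        t("Bacteroidaceae", "family", "caecum", 12.0),
        t("Lactobacillaceae", "family", "caecum", 5.0),
        t("Other", "family", "caecum", 41.0, sigma=0.25),
        # -- caecum, order ------------------------------------------------
        t("Bacillales", "order", "caecum", 2.97, assoc=("bat_ge", -0.67, "6mo")),
        t("Clostridiales", "order", "caecum", 55.0, sigma=0.3),
        t("Bacteroidales", "order", "caecum", 25.0, sigma=0.3),
        t("Lactobacillales", "order", "caecum", 8.0),
        t("Erysipelotrichales", "order", "caecum", 3.0),
        t("Other", "order", "caecum", 6.03, sigma=0.25),
        # -- caecum, phylum ----------------------------------------------
        t("Proteobacteria", "phylum", "caecum", 3.42, assoc=("bat_sat_ratio", -0.67, "6mo")),
        t("Firmicutes", "phylum", "caecum", 58.0, sigma=0.2),
        t("Bacteroidetes", "phylum", "caecum", 30.0, sigma=0.2),
        t("Actinobacteria", "phylum", "caecum", 3.0),
        t("Verrucomicrobia", "phylum", "caecum", 2.0),
        t("Other", "phylum", "caecum", 3.58, sigma=0.25),
        # -- caecum, KEGG pathways ---------------------------------------
        t("Bacterial.secretion.system", "pathway", "caecum", 2.5, sigma=0.4, assoc=("bat_sat_ratio", -0.80, "6mo")),
        t("Fatty.acid.biosynthesis", "pathway", "caecum", 1.2, sigma=0.4, assoc=("sat_hu", -0.77, "1mo")),
        t("Inositol.phosphate.metabolism", "pathway", "caecum", 0.8, sigma=0.4, assoc=("sat_hu", 0.84, "1mo")),
        t("Nitrotoluene.degradation", "pathway", "caecum", 0.15, sigma=0.4, assoc=("sat_ge", -0.82, "1mo")),
        t("beta.Lactam.resistance", "pathway", "caecum", 0.6, sigma=0.4, assoc=("whole_sat_gu", 0.78, "6mo")),
        t("Flagellar.assembly", "pathway", "caecum", 1.0, sigma=0.4, assoc=("whole_sat_gu", -0.77, "6mo")),
        t("Bacterial.chemotaxis", "pathway", "caecum", 1.1, sigma=0.4, assoc=("whole_sat_gu", -0.75, "6mo")),
        t("Sulfur.relay.system", "pathway", "caecum", 0.4, sigma=0.4, assoc=("whole_sat_gu", 0.71, "6mo")),
        t("Other", "pathway", "caecum", 92.25, sigma=0.15),
        # -- colon, genus (no planted signal; most findings were caecal) --
        t("Dorea", "genus", "colon", 0.8),
        t("Lactobacillus", "genus", "colon", 6.0),
        t("Bacteroides", "genus", "colon", 14.0),
        t("Unclassified.Clostridiales", "genus", "colon", 14.0),
        t("Unclassified.Rikenellaceae", "genus", "colon", 0.15),
        t("Oscillospira", "genus", "colon", 1.8),
        t("Other", "genus", "colon", 63.25, sigma=0.25),
    ]
    return taxa


def default_config(**overrides) -> CohortConfig:
    cfg = CohortConfig(**overrides)
    cfg.validate()
    return cfg
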