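"""Synthetic mixed inpatient populations with known ground truth.

Real routine laboratory datasets with ICD-10 coding cannot be shared, so the
pipeline is exercised on generated cohorts that emulate their structure: per
sex × age-band stratum a healthy Gaussian core, plus disease-labelled
subpopulations with shifted means and inflated variances, block-structured
code co-occurrence (comorbidity), and null "background" codes attached to
results regardless of health status.  The true healthy 2.5th/97.5th
percentiles are available in closed form (mu ± 1.96 sigma), which makes
end-to-end recovery checkable.

The default scenario is potassium-like: healthy mean 4.0 mmol/L with SD
rising from 0.35 (ages 20-29) to 0.45 (80-89), and disease components
patterned on the magnitudes seen in renal/cardiac/metabolic inpatient
subgroups (mean shifts +0.4 to +1.2 mmol/L, doubled SD, 25 % combined
prevalence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .io import SEXES, TestResult, age_bands, write_results
from .ri import Z_RI


@dataclass(frozen=True)
class DiseaseComponent:
    """One disease-labelled subpopulation of a stratum."""

    code: str
    prevalence: float
    shift: float  # mean offset from the healthy mean (analyte units)
    sd_scale: float = 1.0  # multiplicative factor on the healthy SD
    comorbidity_block: str | None = None
    lognormal: bool = False  # draw from a shifted lognormal instead (skewed)

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.sd_scale <= 0:
            raise ValueError("sd_scale must be positive")


@dataclass
class SyntheticScenario:
    """Full specification of a generated cohort."""

    strata_specs: dict[tuple[str, int, int], tuple[float, float]]
    components: list[DiseaseComponent] = field(default_factory=list)
    n_per_stratum: int = 20000
    max_codes_per_result: int = 5
    codes_within_block_cooccur: float = 0.35
    background_codes: list[str] = field(default_factory=list)
    background_code_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        total = sum(c.prevalence for c in self.components)
        if total > 1:
            raise ValueError(f"component prevalences sum to {total:.3f} > 1")
        codes = [c.code for c in self.components]
        if len(set(codes)) != len(codes):
            raise ValueError("component codes must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        specs = {
            (s["sex"], int(s["age_lo"]), int(s["age_hi"])): (
                float(s["mean"]), float(s["sd"])
            )
            for s in raw["strata"]
        }
        comps = [DiseaseComponent(**c) for c in raw.get("components", [])]
        kwargs = {
            k: raw[k]
            for k in (
                "n_per_stratum", "max_codes_per_result", "codes_within_block_cooccur",
                "background_code_rate", "seed",
            )
            if k in raw
        }
        return cls(
            strata_specs=specs,
            components=comps,
            background_codes=list(raw.get("background_codes", [])),
            **kwargs,
        )


DEFAULT_BACKGROUND_CODES = [
    "Z03", "Z38", "R07", "M54", "J06", "K52", "R51", "S93", "Z96", "R10",
]


def default_components() -> list[DiseaseComponent]:
    """Renal/cardiac/metabolic disease mix, 25 % combined prevalence."""
    return [
        DiseaseComponent("N18", 0.05, 0.40, 2.0, "renal"),
        DiseaseComponent("N17", 0.04, 0.45, 2.0, "renal"),
        DiseaseComponent("T86", 0.01, 0.50, 2.0, "renal"),
        DiseaseComponent("I50", 0.04, 0.55, 2.0, "cardio"),
        DiseaseComponent("I10", 0.05, 0.40, 2.0, "cardio"),
        DiseaseComponent("I42", 0.02, 0.60, 2.0, "cardio"),
        DiseaseComponent("E11", 0.03, 0.80, 2.0, "metabolic"),
        DiseaseComponent("E87", 0.01, 1.20, 2.0, "metabolic"),
    ]


def default_strata_specs(
    healthy_mean: float = 4.0,
    sd_young: float = 0.35,
    sd_old: float = 0.45,
    band_width: int = 10,
) -> dict[tuple[str, int, int], tuple[float, float]]:
    """Healthy mean/SD per stratum; SD rises linearly across the age bands."""
    bands = age_bands(band_width)
    sds = np.linspace(sd_young, sd_old, len(bands))
    return {
        (sex, lo, hi): (healthy_mean, float(sd))
        for sex in SEXES
        for (lo, hi), sd in zip(bands, sds)
    }


def default_scenario(
    n_per_stratum: int = 20000,
    seed: int = 0,
    components: list[DiseaseComponent] | None = None,
    bands: list[tuple[int, int]] | None = None,
) -> SyntheticScenario:
    """The default contaminated potassium-like cohort."""
    specs = default_strata_specs()
    if bands is not None:
        specs = {k: v for k, v in specs.items() if (k[1], k[2]) in bands}
    return SyntheticScenario(
        strata_specs=specs,
        components=default_components() if components is None else components,
        n_per_stratum=n_per_stratum,
        background_codes=list(DEFAULT_BACKGROUND_CODES),
        seed=seed,
    )


def null_scenario(
    n_per_stratum: int = 5000,
    seed: int = 0,
    n_background_codes: int = 30,
    bands: list[tuple[int, int]] | None = None,
) -> SyntheticScenario:
    """Zero-shift cohort: every code group is a random subsample of the GD."""
    codes = [f"Z{i:02d}" for i in range(n_background_codes)]
    specs = default_strata_specs()
    if bands is not None:
        specs = {k: v for k, v in specs.items() if (k[1], k[2]) in bands}
    return SyntheticScenario(
        strata_specs=specs,
        components=[],
        n_per_stratum=n_per_stratum,
        background_codes=codes,
        background_code_rate=0.5,
        seed=seed,
    )


def generate(scenario: SyntheticScenario) -> tuple[list[TestResult], dict]:
    """Draw a cohort and its ground-truth manifest, deterministic under seed.

    Healthy values come from the stratum Gaussian; a result assigned to a
    disease component draws from N(mean + shift, (sd * sd_scale)^2) (or a
    moment-matched shifted lognormal for skewed components) and carries the
    component's code plus, with the block co-occurrence probability, each
    other code of its comorbidity block.  Background codes are attached to
    results independently of health status, so their groups mirror the GD.
    """
    rng = np.random.default_rng(scenario.seed)
    blocks: dict[str, list[str]] = {}
    for c in scenario.components:
        if c.comorbidity_block:
            blocks.setdefault(c.comorbidity_block, []).append(c.code)

    probs = [c.prevalence for c in scenario.components]
    p_healthy = 1.0 - sum(probs)
    choice_p = np.array(probs + [p_healthy])

    results: list[TestResult] = []
    truth_strata = {}
    truth_codes = {}
    case_counter = 0
    for (sex, lo, hi), (mean, sd) in sorted(scenario.strata_specs.items()):
        n = scenario.n_per_stratum
        assign = rng.choice(len(scenario.components) + 1, size=n, p=choice_p)
        ages = rng.integers(lo, hi + 1, size=n)
        values = rng.normal(mean, sd, size=n)
        for ci, comp in enumerate(scenario.components):
            idx = np.where(assign == ci)[0]
            mu, sig = mean + comp.shift, sd * comp.sd_scale
            if comp.lognormal:
                # moment-matched lognormal, right-skewed
                s2 = np.log1p(sig**2 / mu**2)
                values[idx] = rng.lognormal(np.log(mu) - s2 / 2, np.sqrt(s2), idx.size)
            else:
                values[idx] = rng.normal(mu, sig, size=idx.size)
        for i in range(n):
            codes: list[str] = []
            ai = assign[i]
            if ai < len(scenario.components):
                comp = scenario.components[ai]
                codes.append(comp.code)
                if comp.comorbidity_block:
                    for other in blocks[comp.comorbidity_block]:
                        if other != comp.code and rng.random() < scenario.codes_within_block_cooccur:
                            codes.append(other)
            if scenario.background_codes and rng.random() < scenario.background_code_rate:
                n_bg = int(rng.integers(1, 3))
                for bg in rng.choice(scenario.background_codes, size=n_bg, replace=False):
                    if bg not in codes:
                        codes.append(bg)
            codes = codes[: scenario.max_codes_per_result]
            results.append(
                TestResult(
                    value=float(values[i]),
                    age=int(ages[i]),
                    sex=sex,
                    case_id=f"case{case_counter:08d}",
                    codes=tuple(codes),
                )
            )
            case_counter += 1
        truth_strata[f"{sex}_{lo}-{hi}"] = {
            "healthy_mean": mean,
            "healthy_sd": sd,
            "lower": mean - Z_RI * sd,
            "upper": mean + Z_RI * sd,
        }
        for comp in scenario.components:
            truth_codes.setdefault(comp.code, {}).update(
                {
                    f"{sex}_{lo}-{hi}": {
                        "mean": mean + comp.shift,
                        "sd": sd * comp.sd_scale,
                        "prevalence": comp.prevalence,
                    }
                }
            )
    truth = {
        "seed": scenario.seed,
        "n_per_stratum": scenario.n_per_stratum,
        "strata": truth_strata,
        "codes": truth_codes,
        "background_codes": list(scenario.background_codes),
    }
    return results, truth


def write_fixture(
    results: list[TestResult], truth: dict, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the cohort CSV (core input dialect) and the truth manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_path = out / "results.csv"
    truth_path = out / "truth.json"
    write_results(results, results_path)
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return results_path, truth_path
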