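"""End-to-end orchestration: simulate -> effect table -> indices -> validation.

``run_pipeline`` runs every analysis stage on one dataset (loaded from a CSV
or simulated from a :class:`~dipyrone_pd.cohort.CohortConfig`), writes all
intermediate CSVs so every number in the report can be recomputed by the
individual stage commands, and assembles a :class:`RunReport` with the
significant-parameter list (paired test p < 0.05), the per-analyte LOO gate
verdicts and machine-readable warnings. Output is deterministic under a
fixed seed (no timestamps in any artifact).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import cohort as cohort_mod
from .cohort import CohortConfig, simulate_cohort
from .datamodel import StudyDataset, read_dataset, write_dataset
from .effects import EffectSummary, effect_table_frame, make_effect_table
from .indices import index_frame, index_series, pearson_r2
from .validation import LOOValidationReport, validate_relationship

logger = logging.getLogger("dipyrone_pd")

__all__ = ["RunReport", "run_pipeline", "load_run_config"]

SIGNIFICANCE_ALPHA = 0.05
DEFAULT_WINDOW = (0.0, 72.0)


@dataclass
class RunReport:
    config_echo: dict
    effect_table: list[EffectSummary]
    significant_parameters: list[str]
    index_points: dict[str, list]
    validations: dict[str, LOOValidationReport]
    correlations: dict[str, dict]
    warnings: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "config": self.config_echo,
            "effect_table": [asdict(s) for s in self.effect_table],
            "significant_parameters": self.significant_parameters,
            "validations": {k: v.as_dict() for k, v in self.validations.items()},
            "correlations": self.correlations,
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)


def load_run_config(path) -> dict:
    """Read the YAML run configuration (windows, schedule, variant, seed)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run configuration must be a mapping")
    return cfg


def build_cohort_config(cfg: dict, seed: int | None = None) -> CohortConfig:
    """Turn the run-configuration mapping into a CohortConfig.

    Unspecified fields fall back to the study-calibrated defaults; the
    explicit ``seed`` argument wins over the file.
    """
    base = cohort_mod.default_study_config(seed=cfg.get("seed", 0))
    kwargs: dict = {}
    if "n_animals" in cfg:
        kwargs["n_animals"] = int(cfg["n_animals"])
    if "schedule" in cfg:
        from .datamodel import SamplingSchedule

        kwargs["schedule"] = SamplingSchedule(
            baseline_times=tuple(cfg["schedule"]["baseline_times"]),
            post_times=tuple(cfg["schedule"]["post_times"]),
        )
    if "pk" in cfg:
        kwargs["pk"] = cohort_mod.PKConfig(**cfg["pk"])
    if "noise_rsd_pct" in cfg:
        kwargs["noise_rsd_pct"] = {**base.noise_rsd_pct, **cfg["noise_rsd_pct"]}
    if seed is not None:
        kwargs["seed"] = int(seed)
    from dataclasses import replace

    return replace(base, **kwargs)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(
    config: dict | None = None,
    *,
    seed: int | None = None,
    dataset: StudyDataset | None = None,
    input_csv=None,
    outdir=None,
) -> RunReport:
    """Run the full analysis and (optionally) write all artifacts to ``outdir``."""
    cfg = dict(config or {})
    window = tuple(cfg.get("window", DEFAULT_WINDOW))
    variant = cfg.get("q2asym_variant", "squared_ratio")
    alpha = float(cfg.get("alpha", SIGNIFICANCE_ALPHA))
    warnings: list[dict] = []

    logger.info("run config hash=%s seed=%s", _config_hash(cfg), seed)

    if dataset is None:
        if input_csv is not None:
            dataset = read_dataset(input_csv)
        else:
            cohort_cfg = build_cohort_config(cfg, seed=seed)
            dataset = simulate_cohort(cohort_cfg)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_dataset(dataset, out / "cohort.csv")

    # -- effect table ------------------------------------------------------
    summaries = make_effect_table(dataset)
    for s in summaries:
        if s.degenerate:
            warnings.append({"code": "DEGENERATE_VARIANCE", "parameter": s.parameter,
                             "detail": "paired differences have zero variance"})
    significant = sorted(
        s.parameter for s in summaries if not s.degenerate and s.p_value < alpha
    )
    if out is not None:
        effect_table_frame(summaries).to_csv(out / "effect_table.csv", index=False)

    # -- indices and correlations against the metabolites ------------------
    index_points: dict[str, list] = {}
    correlations: dict[str, dict] = {}
    validations: dict[str, LOOValidationReport] = {}
    for index_name in ("composite", "mcv_pt"):
        try:
            points = index_series(dataset, index=index_name, time_window=window)
        except (KeyError, ValueError) as exc:
            warnings.append({"code": "INDEX_UNAVAILABLE", "parameter": index_name,
                             "detail": str(exc)})
            continue
        index_points[index_name] = points
        if out is not None:
            index_frame(points).to_csv(out / f"index_{index_name}.csv", index=False)

    if "composite" in index_points:
        points = index_points["composite"]
        times = [p.time_h for p in points]
        y = [p.value for p in points]
        for analyte in ("4MAA", "4AA"):
            try:
                profile = dataset.get_metabolite(analyte)
            except KeyError:
                warnings.append({"code": "METABOLITE_MISSING", "parameter": analyte,
                                 "detail": "no concentration profile in the dataset"})
                continue
            conc = dict(profile.samples)
            x = [conc[t] for t in times if t in conc]
            y_paired = [v for t, v in zip(times, y) if t in conc]
            try:
                corr = pearson_r2(x, y_paired)
                correlations[analyte] = asdict(corr)
                validations[analyte] = validate_relationship(x, y_paired, variant=variant)
            except ValueError as exc:
                warnings.append({"code": "VALIDATION_DEGENERATE", "parameter": analyte,
                                 "detail": str(exc)})

    report = RunReport(
        config_echo={**cfg, "seed": seed, "window": list(window),
                     "q2asym_variant": variant, "alpha": alpha,
                     "provenance": dataset.provenance},
        effect_table=summaries,
        significant_parameters=significant,
        index_points=index_points,
        validations=validations,
        correlations=correlations,
        warnings=warnings,
    )
    if out is not None:
        (out / "report.json").write_text(report.to_json())
        for analyte, v in validations.items():
            lines = [f"{k}={v.as_dict()[k]}" for k in sorted(v.as_dict())]
            (out / f"validation_{analyte}.txt").write_text("\n".join(lines) + "\n")
    return report
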