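"""End-to-end experiment orchestration.

``run_experiment`` chains simulate → score → extract → correlate → ICC →
leave-p-out into one reproducible run driven by a single master seed, writing
each stage as plain CSV (plus optional NIfTI images) under an output
directory, and ``summarize`` rebuilds the summary report from those CSVs
without recomputing the stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import (
    ConfigurationError,
    FeatureTable,
    GROUND_TRUTH_SOURCE,
    write_mask,
    write_volume,
)
from .features import (
    ALL_FEATURES,
    DEFAULT_SCHEMES,
    FeatureConfig,
    extract_features,
)
from .metrics import score_cohort, scores_to_frame
from .stats import (
    correlate_error_with_dice,
    icc_per_feature,
    leave_p_out,
    select_robust,
)
from .synthetic import (
    CohortConfig,
    LesionParams,
    RaterProfile,
    default_rater_profiles,
    simulate_cohort,
)

__all__ = ["ExperimentConfig", "AgreementReport", "run_experiment", "summarize"]

log = logging.getLogger("radstab")

STAGE_FILES = {
    "scores": "scores.csv",
    "features": "features.csv",
    "correlations": "correlations.csv",
    "icc": "icc.csv",
    "leavepout": "leavepout.csv",
}


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    schemes: tuple[int, ...] = DEFAULT_SCHEMES
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    icc_form: str = "single"
    alpha: float = 0.05
    threshold: float = 0.950
    p_max: int = 7
    write_images: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigurationError(f"threshold must be in (0, 1], got {self.threshold}")
        bad = [g for g in self.schemes if int(g) < 2]
        if bad:
            raise ConfigurationError(f"inadmissible gray-level counts: {bad}")
        self.schemes = tuple(int(g) for g in self.schemes)

    # -- construction from config files ------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        cohort_d = dict(d.pop("cohort", {}))
        raters = cohort_d.pop("raters", None)
        profiles = (
            [RaterProfile(**r) for r in raters]
            if raters is not None
            else default_rater_profiles()
        )
        lp = LesionParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in dict(cohort_d.pop("lesion_params", {})).items()
        })
        if "complexity_range" in cohort_d:
            cohort_d["complexity_range"] = tuple(cohort_d["complexity_range"])
        cohort = CohortConfig(rater_profiles=profiles, lesion_params=lp, **cohort_d)
        icc_d = dict(d.pop("icc", {}))
        feat_d = dict(d.pop("features", {}))
        return cls(
            cohort=cohort,
            schemes=tuple(d.pop("schemes", DEFAULT_SCHEMES)),
            feature_config=FeatureConfig(**feat_d),
            icc_form=icc_d.get("form", "single"),
            alpha=float(icc_d.get("alpha", 0.05)),
            threshold=float(icc_d.get("threshold", 0.950)),
            p_max=int(icc_d.get("p_max", 7)),
            write_images=bool(d.pop("write_images", False)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def provenance(self) -> dict:
        """Deterministic record sufficient to re-create every output."""
        return {
            "radstab_version": __version__,
            "master_seed": self.cohort.master_seed,
            "n_lesions": self.cohort.n_lesions,
            "raters": [dataclasses.asdict(p) for p in self.cohort.rater_profiles],
            "lesion_params": dataclasses.asdict(self.cohort.lesion_params),
            "complexity_range": list(self.cohort.complexity_range),
            "schemes": list(self.schemes),
            "feature_conventions": dataclasses.asdict(self.feature_config),
            "icc": {
                "form": self.icc_form,
                "alpha": self.alpha,
                "threshold": self.threshold,
                "p_max": self.p_max,
            },
            "smasd_convention": "pooled mean over both surface sets, voxel units",
        }


@dataclass
class AgreementReport:
    """Summary of one experiment: file paths plus headline tallies."""

    files: dict[str, str]
    robust_counts: dict[int, int]  # G -> number of robust features
    correlation_tallies: dict[str, int]  # category -> count over all (feature, G)
    top_stable: dict[int, list[str]]  # G -> top-3 features at p = p_max
    provenance: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "files": self.files,
            "robust_counts": {str(k): v for k, v in self.robust_counts.items()},
            "correlation_tallies": self.correlation_tallies,
            "top_stable": {str(k): v for k, v in self.top_stable.items()},
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _write_cohort_images(cases, out: Path) -> None:
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    rows = []
    for case in cases:
        vpath = img_dir / f"{case.lesion_id}_pet.nii.gz"
        gpath = img_dir / f"{case.lesion_id}_gt.nii.gz"
        write_volume(case.image, vpath)
        write_mask(case.ground_truth, gpath)
        rows.append({"lesion_id": case.lesion_id, "rater_id": "image", "path": str(vpath)})
        rows.append(
            {"lesion_id": case.lesion_id, "rater_id": GROUND_TRUTH_SOURCE, "path": str(gpath)}
        )
        for rid, m in case.rater_masks.items():
            mpath = img_dir / f"{case.lesion_id}_{rid}.nii.gz"
            write_mask(m, mpath)
            rows.append({"lesion_id": case.lesion_id, "rater_id": rid, "path": str(mpath)})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> AgreementReport:
    """Execute every stage; deterministic given the master seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    log.info("simulating cohort: %d lesions x %d raters (seed %d)",
             cfg.cohort.n_lesions, len(cfg.cohort.rater_profiles),
             cfg.cohort.master_seed)
    cases = simulate_cohort(cfg.cohort)
    log.info("cohort simulated in %.1f s", time.perf_counter() - t0)

    if cfg.write_images:
        _write_cohort_images(cases, out)

    t0 = time.perf_counter()
    scores = score_cohort(cases)
    sdf = scores_to_frame(scores)
    sdf.to_csv(out / STAGE_FILES["scores"], index=False)
    log.info("scored %d contours in %.1f s", len(sdf), time.perf_counter() - t0)

    t0 = time.perf_counter()
    tables = []
    for case in cases:
        tables.append(
            extract_features(
                case.image, case.ground_truth, cfg.schemes,
                lesion_id=case.lesion_id, source=GROUND_TRUTH_SOURCE,
                config=cfg.feature_config,
            )
        )
        for rid, m in case.rater_masks.items():
            tables.append(
                extract_features(
                    case.image, m, cfg.schemes,
                    lesion_id=case.lesion_id, source=rid,
                    config=cfg.feature_config,
                )
            )
    features = FeatureTable.concat(tables)
    features.write_csv(out / STAGE_FILES["features"])
    log.info("extracted %d feature rows in %.1f s", len(features),
             time.perf_counter() - t0)

    corr = correlate_error_with_dice(features, sdf)
    pd.DataFrame(
        [
            {
                "feature": c.feature, "gray_levels": c.gray_levels,
                "rho": c.rho, "p_value": c.p_value, "category": c.category,
                "n_pairs": c.n_pairs, "n_excluded": c.n_excluded,
            }
            for c in corr
        ],
        columns=["feature", "gray_levels", "rho", "p_value", "category",
                 "n_pairs", "n_excluded"],
    ).to_csv(out / STAGE_FILES["correlations"], index=False)

    icc = icc_per_feature(features, alpha=cfg.alpha, form=cfg.icc_form)
    pd.DataFrame(
        [
            {
                "feature": r.feature, "gray_levels": r.gray_levels,
                "icc": r.icc, "lb": r.lb, "ub": r.ub,
                "n_targets": r.n_targets, "k_raters": r.k_raters,
                "degenerate": r.degenerate,
            }
            for r in icc
        ]
    ).to_csv(out / STAGE_FILES["icc"], index=False)

    selected = select_robust(icc, cfg.threshold)
    t0 = time.perf_counter()
    curves = leave_p_out(
        features, selected, p_max=cfg.p_max, alpha=cfg.alpha, form=cfg.icc_form
    )
    rows = []
    for c in curves:
        for p in sorted(c.mean_lb):
            rows.append(
                {
                    "feature": c.feature, "gray_levels": c.gray_levels,
                    "p": p, "mean_lb": c.mean_lb[p], "n_subsets": c.n_subsets[p],
                }
            )
    pd.DataFrame(
        rows, columns=["feature", "gray_levels", "p", "mean_lb", "n_subsets"]
    ).to_csv(out / STAGE_FILES["leavepout"], index=False)
    log.info("leave-p-out over %d robust (feature, G) pairs in %.1f s",
             len(selected), time.perf_counter() - t0)

    (out / "provenance.json").write_text(
        json.dumps(cfg.provenance(), indent=2, sort_keys=True)
    )
    report = summarize(out)
    return report


def summarize(report_dir: str | Path) -> AgreementReport:
    """Rebuild the report from stage CSVs; idempotent, no recomputation.

    Raises :class:`FileNotFoundError` naming the first missing stage file.
    """
    out = Path(report_dir)
    paths = {}
    for key, name in STAGE_FILES.items():
        p = out / name
        if not p.exists():
            raise FileNotFoundError(f"missing stage output: {p}")
        paths[key] = str(p)

    icc_df = pd.read_csv(paths["icc"])
    corr_df = pd.read_csv(paths["correlations"])
    lpo_df = pd.read_csv(paths["leavepout"])

    prov_path = out / "provenance.json"
    provenance = (
        json.loads(prov_path.read_text()) if prov_path.exists() else {}
    )
    threshold = provenance.get("icc", {}).get("threshold", 0.950)

    robust = {}
    for G, grp in icc_df.groupby("gray_levels"):
        robust[int(G)] = int((grp["lb"] >= threshold).sum())

    tallies = corr_df["category"].value_counts().to_dict()
    tallies = {k: int(v) for k, v in sorted(tallies.items())}

    top = {}
    if len(lpo_df):
        pmax = int(lpo_df["p"].max())
        at_pmax = lpo_df[lpo_df["p"] == pmax]
        for G, grp in at_pmax.groupby("gray_levels"):
            ranked = grp.sort_values(
                ["mean_lb", "feature"], ascending=[False, True]
            )
            top[int(G)] = ranked["feature"].head(3).tolist()

    report = AgreementReport(
        files=paths,
        robust_counts=robust,
        correlation_tallies=tallies,
        top_stable=top,
        provenance=provenance,
    )
    report.to_json(out / "report.json")
    return report
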