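"""End-to-end runner: simulate (or load) -> features -> embedding -> MPI ->
robustness -> prognostics, with every artifact written under one output
directory and a single master seed propagated to all stochastic stages.
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

from . import io as pio
from .embedding import embed
from .features import compute_feature_matrix, segment_lesions
from .prognostics import (
    bootstrap_optimism,
    calibration_by_decile,
    delong_compare,
    fit_cox,
    fit_logistic,
    km_median,
    likelihood_ratio,
    polynomial_comparator,
    univariable_screen,
    vif,
)
from .robustness import (
    feature_ablation,
    k_sensitivity,
    root_sensitivity,
    subsample_stability,
)
from .synthetic import (
    GeneratorParams,
    cohort_feature_matrix,
    lesion_frame,
    outcomes_frame,
    sample_cohort,
)
from .trajectory import derive_mpi

logger = logging.getLogger("petmpi")

# seed offsets per stochastic stage, so stages stay decoupled
SEED_OFFSETS = {"simulate": 0, "subsample": 101, "bootstrap": 202}


@dataclass
class PipelineConfig:
    input_mode: str = "simulate"  # simulate | voxel-table | image-dir
    input_path: str | None = None
    seed: int = 0
    n_patients: int = 83
    generator: dict = field(default_factory=dict)
    segmentation_threshold: float = 2.5
    k: int = 20
    subsample_fraction: float = 0.8
    subsample_iterations: int = 300
    k_range: tuple[int, int] = (10, 30)
    ablation: tuple[str, ...] = ("Dmax", "DmaxVox")
    bootstrap_iterations: int = 1000
    conventional_covariates: tuple[str, ...] = ("tMTV", "DmaxVox", "bone_met")
    output_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.input_mode not in {"simulate", "voxel-table", "image-dir"}:
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode != "simulate" and not self.input_path:
            raise ValueError("input_path required unless simulating")
        n = self.n_patients if self.input_mode == "simulate" else None
        if n is not None and self.k >= n:
            raise ValueError(f"k={self.k} must be < n={n}")
        if n is not None and int(self.subsample_fraction * n) <= self.k:
            raise ValueError("subsample too small for the chosen k")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def generator_params(self) -> GeneratorParams:
        return GeneratorParams(
            n_patients=self.n_patients,
            seed=self.seed + SEED_OFFSETS["simulate"],
            **self.generator,
        )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("inputs")
def load_inputs(config: PipelineConfig):
    """Return (feature matrix, outcomes-or-None)."""
    if config.input_mode == "simulate":
        params = config.generator_params()
        cohort = sample_cohort(params)
        fm = cohort_feature_matrix(cohort, params)
        return fm, outcomes_frame(cohort), cohort, params
    if config.input_mode == "voxel-table":
        lesion_sets = pio.read_voxel_table(
            config.input_path, threshold=config.segmentation_threshold
        )
        return compute_feature_matrix(lesion_sets), None, None, None
    images = pio.read_image_dir(config.input_path)
    lesion_sets = [
        segment_lesions(img, patient_id=pid, threshold=config.segmentation_threshold)
        for pid, img in images.items()
    ]
    lesion_sets = [ls for ls in lesion_sets if ls.n_lesions > 0]
    return compute_feature_matrix(lesion_sets), None, None, None


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute every stage; write all artifacts; return the result bundle."""
    config.validate()
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()
    logger.info("pipeline start (config %s)", chash)

    fm, outcomes, cohort, params = load_inputs(config)
    pio.write_csv(fm, outdir / "feature_matrix.csv")
    if cohort is not None:
        pio.write_csv(lesion_frame(cohort), outdir / "lesions.csv", index=False)
        pio.write_csv(outcomes, outdir / "outcomes.csv")

    emb = embed(fm, k=config.k)
    pio.write_csv(emb.components, outdir / "embedding.csv")
    pio.write_json(
        {
            "config_hash": chash,
            "k": emb.k,
            "eigenvalues": emb.eigenvalues,
            "sigma_median": float(np.median(emb.sigma)),
            "connected": emb.connected,
        },
        outdir / "embedding.json",
    )

    mpi = derive_mpi(fm, k=config.k)
    pio.write_csv(mpi.frame(), outdir / "mpi.csv")
    pio.write_json(
        {
            "config_hash": chash,
            "root_patient_id": mpi.root_patient_id,
            "anchor": mpi.anchor,
            "sign": mpi.sign,
        },
        outdir / "mpi.json",
    )

    results: dict = {"config_hash": chash, "mpi": mpi, "feature_matrix": fm}

    rob = {
        "subsample": subsample_stability(
            fm,
            k=config.k,
            fraction=config.subsample_fraction,
            iterations=config.subsample_iterations,
            seed=config.seed + SEED_OFFSETS["subsample"],
        ),
        "k_sensitivity": k_sensitivity(
            fm, k_values=range(config.k_range[0], config.k_range[1] + 1), k_ref=config.k
        ),
        "ablation": feature_ablation(fm, drop=config.ablation, k=config.k),
        "root": root_sensitivity(fm, rule="min_tMTV", k=config.k),
    }
    for name, rep in rob.items():
        pio.write_csv(rep.values, outdir / f"stability_{name}.csv", index=False)
    pio.write_json(
        {name: {**rep.summary, "settings": rep.settings} for name, rep in rob.items()},
        outdir / "stability_summary.json",
    )
    results["robustness"] = rob

    if outcomes is not None:
        results["prognostics"] = prognostic_suite(
            fm,
            mpi.mpi,
            outcomes,
            conventional=config.conventional_covariates,
            bootstrap_iterations=config.bootstrap_iterations,
            seed=config.seed + SEED_OFFSETS["bootstrap"],
            outdir=outdir,
        )

    logger.info("pipeline done -> %s", outdir)
    return results


def prognostic_suite(
    fm: pd.DataFrame,
    mpi: pd.Series,
    outcomes: pd.DataFrame,
    conventional: tuple[str, ...] = ("tMTV", "DmaxVox", "bone_met"),
    bootstrap_iterations: int = 1000,
    seed: int = 0,
    outdir: Path | None = None,
) -> dict:
    """The full outcome analysis on one cohort.

    Fits the two predefined logistic models (conventional: tMTV + DmaxVox
    + bone metastasis; MPI-based: MPI + bone metastasis) plus the
    bone-only baseline and the polynomial comparator; compares ROC curves
    with the paired DeLong test; LRT of the MPI model against the
    bone-only baseline; bootstrap optimism correction; decile calibration;
    Kaplan-Meier median OS and Cox models for MPI and the conventional
    covariates.
    """
    out = outcomes.loc[fm.index]
    y = out["dead_12mo"].astype(int)
    covars = pd.concat([fm, out[["bone_met"]]], axis=1)
    covars["MPI"] = mpi

    screen = univariable_screen(
        pd.concat([covars[["MPI"]], fm], axis=1), y
    )

    conv_X = covars[list(conventional)]
    mpi_X = covars[["MPI", "bone_met"]]
    conventional_model = fit_logistic(conv_X, y, name="conventional")
    mpi_model = fit_logistic(mpi_X, y, name="mpi")
    bone_model = fit_logistic(covars[["bone_met"]], y, name="bone_only")
    comparator = polynomial_comparator(covars["tMTV"], covars["DmaxVox"], y)

    roc = delong_compare(
        mpi_model.predictions.to_numpy(),
        conventional_model.predictions.to_numpy(),
        y.to_numpy(),
    )
    lrt = likelihood_ratio(bone_model, mpi_model)
    optimism = bootstrap_optimism(
        mpi_X, y, iterations=bootstrap_iterations, seed=seed
    )
    calibration = calibration_by_decile(mpi_model.predictions, y)
    vifs = {
        "mpi_model": vif(mpi_X),
        "conventional_model": vif(conv_X),
    }

    km = km_median(out["time_months"], out["event"])
    cox_mpi = fit_cox(covars[["MPI"]], out["time_months"], out["event"], name="cox_mpi")
    cox_conv = fit_cox(
        covars[["tMTV", "DmaxVox"]], out["time_months"], out["event"], name="cox_conventional"
    )

    bundle = {
        "screen": screen,
        "conventional_model": conventional_model,
        "mpi_model": mpi_model,
        "bone_model": bone_model,
        "comparator": comparator,
        "delong": roc,
        "lrt": lrt,
        "optimism": optimism,
        "calibration": calibration,
        "vif": vifs,
        "km": km,
        "cox_mpi": cox_mpi,
        "cox_conventional": cox_conv,
    }
    if outdir is not None:
        pio.write_csv(screen, outdir / "univariable_screen.csv")
        for key in ("conventional_model", "mpi_model", "comparator"):
            rep = bundle[key]
            pio.write_csv(rep.coefficients, outdir / f"{rep.name}_coefficients.csv")
            pio.write_csv(
                rep.predictions.to_frame(), outdir / f"{rep.name}_predictions.csv"
            )
        pio.write_json(
            {
                "auc": {
                    "conventional": conventional_model.auc,
                    "mpi": mpi_model.auc,
                    "comparator": comparator.auc,
                },
                "mpi_or_per_0.1": mpi_model.or_per_0p1.get("MPI"),
                "delong": {
                    "delta_auc": roc.delta_auc,
                    "ci": roc.ci,
                    "p": roc.p_value,
                },
                "lrt": {"delta_deviance": lrt.delta_deviance, "df": lrt.df, "p": lrt.p_value},
                "optimism": dataclasses.asdict(optimism),
                "km_median_months": km.median,
                "km_ci": km.ci,
                "cox_mpi_hr": float(cox_mpi.coefficients.loc["MPI", "hr"]),
                "cox_mpi_hr_per_0.1": cox_mpi.hr_per_0p1.get("MPI"),
                "cox_mpi_c_index": cox_mpi.c_index,
                "cox_conventional_c_index": cox_conv.c_index,
                "vif": {k: v.to_dict() for k, v in vifs.items()},
            },
            outdir / "prognostics_summary.json",
        )
        pio.write_csv(calibration.table, outdir / "calibration.csv", index=False)
    return bundle
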