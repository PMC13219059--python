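"""Stability analyses of the MPI ordering.

Four checks, each rerunning the whole derivation (standardize ->
diffusion map -> orientation -> MPI) under a perturbation and scoring
Spearman rank agreement with the reference MPI:

* subsampling concordance (80% of patients, 300 iterations by default);
* neighbourhood-size sweep (k from 10 to 30 against k = 20);
* dissemination-feature ablation (drop Dmax and DmaxVox);
* alternative root/orientation rule (minimal-tMTV patient as root).

Per-iteration correlations are retained, not only summaries, and every
analysis is reproducible bitwise under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .embedding import standardize
from .trajectory import derive_mpi


@dataclass
class StabilityReport:
    analysis: str
    values: pd.DataFrame  # one row per iteration / setting
    summary: dict
    settings: dict

    def __post_init__(self) -> None:
        rho_cols = [c for c in self.values.columns if "rho" in c or c == "pearson_r"]
        for c in rho_cols:
            bad = self.values[c].abs() > 1.0 + 1e-12
            if bad.any():
                raise ValueError(f"correlation out of range in {self.analysis}")


def _abs_spearman(a: pd.Series, b: pd.Series) -> float:
    common = a.index.intersection(b.index)
    return abs(float(spearmanr(a.loc[common], b.loc[common])[0]))


def subsample_stability(
    fm: pd.DataFrame,
    k: int = 20,
    fraction: float = 0.8,
    iterations: int = 300,
    seed: int = 0,
    restandardize: bool = True,
    **mpi_kwargs,
) -> StabilityReport:
    """Concordance of MPI between patient subsamples and the full cohort.

    Each iteration draws ``floor(fraction * n)`` patients without
    replacement, reruns the full derivation inside the subsample (feature
    scaling recomputed within the subsample unless ``restandardize`` is
    False, in which case the full-cohort z-scoring is frozen and reused),
    and scores |Spearman| against the full-cohort MPI restricted to the
    subsample.
    """
    n = fm.shape[0]
    m = math.floor(fraction * n)
    if m <= k:
        raise ValueError(f"subsample size {m} must exceed k={k}")
    full = derive_mpi(fm, k=k, **mpi_kwargs)
    frozen = standardize(fm).values if not restandardize else None
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(iterations):
        pick = fm.index[rng.choice(n, size=m, replace=False)]
        if restandardize:
            sub_mpi = derive_mpi(fm.loc[pick], k=k, **mpi_kwargs)
        else:  # frozen full-cohort scaling
            sub_mpi = derive_mpi(frozen.loc[pick], k=k, pre_standardized=True, **mpi_kwargs)
        rows.append(
            {"iteration": it, "abs_spearman_rho": _abs_spearman(sub_mpi.mpi, full.mpi)}
        )
    values = pd.DataFrame(rows)
    rho = values["abs_spearman_rho"]
    return StabilityReport(
        analysis="subsample_stability",
        values=values,
        summary={
            "median_abs_rho": float(rho.median()),
            "min_abs_rho": float(rho.min()),
            "max_abs_rho": float(rho.max()),
        },
        settings={
            "fraction": fraction,
            "iterations": iterations,
            "k": k,
            "seed": seed,
            "restandardize": restandardize,
        },
    )


def k_sensitivity(
    fm: pd.DataFrame,
    k_values=range(10, 31),
    k_ref: int = 20,
    **mpi_kwargs,
) -> StabilityReport:
    """|Spearman| of MPI at each k against the k = k_ref MPI."""
    n = fm.shape[0]
    k_values = list(k_values)
    if max(k_values) >= n or k_ref >= n:
        raise ValueError("every k must be < n")
    ref = derive_mpi(fm, k=k_ref, **mpi_kwargs)
    rows = []
    for k in k_values:
        mpi_k = ref if k == k_ref else derive_mpi(fm, k=k, **mpi_kwargs)
        rows.append({"k": k, "abs_spearman_rho": _abs_spearman(mpi_k.mpi, ref.mpi)})
    values = pd.DataFrame(rows)
    rho = values["abs_spearman_rho"]
    return StabilityReport(
        analysis="k_sensitivity",
        values=values,
        summary={
            "min_abs_rho": float(rho.min()),
            "median_abs_rho": float(rho.median()),
            "max_abs_rho": float(rho.max()),
        },
        settings={"k_values": k_values, "k_ref": k_ref},
    )


def feature_ablation(
    fm: pd.DataFrame,
    drop: tuple[str, ...] = ("Dmax", "DmaxVox"),
    k: int = 20,
    **mpi_kwargs,
) -> StabilityReport:
    """MPI with a feature family removed vs the full-feature MPI.

    Reports signed Spearman rho and Pearson r (orientation is re-applied
    in both derivations, so the sign is meaningful).
    """
    missing = [c for c in drop if c not in fm.columns]
    if missing:
        raise ValueError(f"columns to drop not present: {missing}")
    remaining = fm.drop(columns=list(drop))
    if remaining.shape[1] < 2:
        raise ValueError("ablation would leave fewer than 2 features")
    full = derive_mpi(fm, k=k, **mpi_kwargs)
    ablated = derive_mpi(remaining, k=k, **mpi_kwargs)
    common = full.mpi.index
    rho = float(spearmanr(full.mpi, ablated.mpi.loc[common])[0])
    r = float(pearsonr(full.mpi, ablated.mpi.loc[common])[0])
    values = pd.DataFrame(
        [{"dropped": ",".join(drop), "spearman_rho": rho, "pearson_r": r}]
    )
    return StabilityReport(
        analysis="feature_ablation",
        values=values,
        summary={"spearman_rho": rho, "pearson_r": r},
        settings={"drop": list(drop), "k": k},
    )


def root_sensitivity(
    fm: pd.DataFrame,
    rule: str = "min_tMTV",
    k: int = 20,
    **mpi_kwargs,
) -> StabilityReport:
    """MPI under an alternative root/orientation rule vs the default."""
    rules = {"min_tMTV": "min_tmtv", "min_DC1": "min_dc1"}
    if rule not in rules:
        raise ValueError(f"unknown root rule {rule!r}; choose from {sorted(rules)}")
    default = derive_mpi(fm, k=k, root_rule="min_dc1", **mpi_kwargs)
    alt = derive_mpi(fm, k=k, root_rule=rules[rule], **mpi_kwargs)
    rho = float(spearmanr(default.mpi, alt.mpi.loc[default.mpi.index])[0])
    values = pd.DataFrame([{"rule": rule, "spearman_rho": rho}])
    return StabilityReport(
        analysis="root_sensitivity",
        values=values,
        summary={"spearman_rho": rho},
        settings={"rule": rule, "k": k},
    )
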