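"""Metabolic Progression Index (MPI) from the first diffusion component.

DC1 is defined only up to sign, so it is first oriented against a tumor
burden anchor (tMTV by default): the sign is flipped when Spearman
correlation with the anchor is negative, so that low DC1 corresponds to
low burden.  The trajectory root is the patient with the lowest oriented
DC1.  MPI is then obtained by rank-ordering patients along oriented DC1
(average ranks on ties) and min-max rescaling the ranks to [0, 1], which
makes MPI invariant to any strictly increasing transform of DC1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .embedding import DiffusionEmbedding, embed


class OrientationError(RuntimeError):
    """DC1 could not be oriented against any burden anchor."""


@dataclass
class OrientedDC1:
    values: pd.Series
    root_patient_id: str
    anchor: str
    anchor_correlation: float
    sign: int


@dataclass
class MPIResult:
    dc1: pd.Series  # oriented
    rank: pd.Series  # average ranks, 1..n
    mpi: pd.Series  # in [0, 1]
    root_patient_id: str
    anchor: str | None = None
    sign: int = 1

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"DC1": self.dc1, "rank": self.rank, "MPI": self.mpi})


def orient_dc1(
    emb: DiffusionEmbedding,
    fm: pd.DataFrame,
    anchor: str = "tMTV",
    fallback: str = "DmaxVox",
    min_abs_correlation: float = 0.05,
) -> OrientedDC1:
    """Fix the sign of DC1 so low DC1 means low tumor burden.

    Falls back to the dissemination anchor when the primary anchor's
    correlation is too weak to orient reliably, and errors out if both are
    ambiguous (caller must then orient explicitly).
    """
    dc1 = emb.components["DC1"]
    for name in (anchor, fallback):
        if name not in fm.columns:
            raise KeyError(f"anchor feature {name!r} not in feature matrix")
        rho = float(spearmanr(dc1.to_numpy(), fm.loc[dc1.index, name].to_numpy())[0])
        if abs(rho) >= min_abs_correlation:
            sign = -1 if rho < 0 else 1
            oriented = sign * dc1
            return OrientedDC1(
                values=oriented,
                root_patient_id=str(oriented.idxmin()),
                anchor=name,
                anchor_correlation=rho,
                sign=sign,
            )
    raise OrientationError(
        "DC1 is uncorrelated with both burden anchors; pass an explicit "
        "orientation"
    )


def mpi_from_dc1(oriented: pd.Series | OrientedDC1, method: str = "rank") -> MPIResult:
    """Convert oriented DC1 into MPI on [0, 1].

    method="rank" (default): average ranks, then (rank - 1) / (n - 1) —
    invariant to strictly increasing transforms of DC1.
    method="raw": plain min-max of the DC1 values themselves (config
    toggle for sensitivity checks).
    """
    if isinstance(oriented, OrientedDC1):
        values, root = oriented.values, oriented.root_patient_id
        anchor, sign = oriented.anchor, oriented.sign
    else:
        values, root = oriented, str(oriented.idxmin())
        anchor, sign = None, 1
    if len(values) < 2:
        raise ValueError("MPI requires at least two patients")
    arr = values.to_numpy(dtype=float)
    if np.ptp(arr) == 0:
        raise ValueError("all DC1 values identical; no ordering exists")
    ranks = rankdata(arr, method="average")
    if method == "rank":
        mpi = (ranks - 1.0) / (len(arr) - 1.0)
    elif method == "raw":
        mpi = (arr - arr.min()) / np.ptp(arr)
    else:
        raise ValueError(f"unknown MPI method {method!r}")
    return MPIResult(
        dc1=values,
        rank=pd.Series(ranks, index=values.index, name="rank"),
        mpi=pd.Series(mpi, index=values.index, name="MPI"),
        root_patient_id=root,
        anchor=anchor,
        sign=sign,
    )


def derive_mpi(
    fm: pd.DataFrame,
    k: int = 20,
    method: str = "rank",
    root_rule: str = "min_dc1",
    anchor: str = "tMTV",
    use_prefactor: bool = False,
    on_disconnected: str = "error",
    pre_standardized: bool = False,
) -> MPIResult:
    """Full chain: standardize -> diffusion map -> orient -> MPI.

    root_rule="min_dc1" (default): orient DC1 by correlation with the
    burden anchor, root = lowest oriented DC1.
    root_rule="min_tmtv": anchor the orientation on the patient with the
    smallest tMTV instead — the sign is chosen to put that patient in the
    lower half of DC1, and it becomes the root.
    """
    emb = embed(
        fm, k=k, on_disconnected=on_disconnected, use_prefactor=use_prefactor,
        pre_standardized=pre_standardized,
    )
    if root_rule == "min_dc1":
        oriented = orient_dc1(emb, fm, anchor=anchor)
        return mpi_from_dc1(oriented, method=method)
    if root_rule == "min_tmtv":
        dc1 = emb.components["DC1"]
        root = fm["tMTV"].idxmin()
        sign = -1 if dc1.loc[root] > float(dc1.median()) else 1
        oriented = OrientedDC1(
            values=sign * dc1,
            root_patient_id=str(root),
            anchor="min_tMTV_patient",
            anchor_correlation=float("nan"),
            sign=sign,
        )
        return mpi_from_dc1(oriented, method=method)
    raise ValueError(f"unknown root_rule {root_rule!r}")
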