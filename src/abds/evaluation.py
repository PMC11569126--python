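"""Accuracy metrics and benchmark harnesses.

Imputation accuracy is measured over the masked index set Omega only:

    RMSE  = sqrt( sum_Omega (Xhat - X)^2 / |Omega| )
    NRMSE = sqrt( sum_Omega (Xhat - X)^2 / (|Omega| * var(X_Omega)) )

with ``var(X_Omega)`` the population variance of the true masked
values.  Detection accuracy uses the partial ROC: the trapezoidal area
under the ROC curve restricted to FPR <= ``fpr_max`` (0.05 by default),
reported raw and standardized to [0, 1] by the McClish transform
``0.5 * (1 + (pAUC - min) / (max - min))`` (chance maps to 0.5, a
perfect classifier to 1); the plain ratio ``pAUC / fpr_max`` is also
available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .matrix import GroupLabels, MissingnessTruth, OmicsMatrix
from . import imputation as imp
from . import signatures as sig
from .simulation import (CLASS_DSG, MissingnessConfig, SimplexSimConfig,
                         inject_missingness, simulate_dataset)

__all__ = [
    "rmse",
    "nrmse",
    "proc_pauc",
    "DetectionEntry",
    "run_imputation_benchmark",
    "run_detection_benchmark",
]


def _omega_pairs(imputed, truth: MissingnessTruth) -> tuple[np.ndarray, np.ndarray]:
    m = imputed.matrix if isinstance(imputed, imp.ImputationResult) else imputed
    rows, cols = truth.positions(m)
    return m.values[rows, cols], truth.table["true_value"].to_numpy(dtype=float)


def rmse(imputed, truth: MissingnessTruth) -> float:
    """Root mean square error over the masked set Omega."""
    if len(truth) == 0:
        raise ValueError("Omega is empty")
    xhat, x = _omega_pairs(imputed, truth)
    return float(np.sqrt(np.mean((xhat - x) ** 2)))


def nrmse(imputed, truth: MissingnessTruth, population: bool = True) -> float:
    """RMSE normalized by the SD of the true masked values.

    Uses the population (divisor ``|Omega|``) variance by default;
    ``population=False`` switches to the sample variance.
    """
    if len(truth) < 2:
        raise ValueError("NRMSE needs at least two masked values")
    xhat, x = _omega_pairs(imputed, truth)
    var = float(np.var(x, ddof=0 if population else 1))
    if var == 0:
        raise ValueError("true masked values have zero variance")
    return float(np.sqrt(np.mean((xhat - x) ** 2) / var))


@dataclass
class DetectionEntry:
    """Partial-ROC summary for one scored method."""

    fpr: np.ndarray
    tpr: np.ndarray
    fpr_max: float
    pauc_raw: float
    pauc_standardized: float
    pauc_ratio: float
    auc: float


def proc_pauc(scores: np.ndarray, is_positive: np.ndarray,
              fpr_max: float = 0.05) -> DetectionEntry:
    """Partial ROC and pAUC at FPR <= ``fpr_max``.

    Ties are grouped: equally scored genes contribute one diagonal ROC
    segment, so the area is order-independent.
    """
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    if not (0.0 < fpr_max <= 1.0):
        raise ValueError("fpr_max must be in (0, 1]")
    if is_positive.all() or (~is_positive).all():
        raise ValueError("both classes must be nonempty")
    fpr, tpr, _ = roc_curve(is_positive, scores, drop_intermediate=False)
    # restrict to [0, fpr_max], interpolating the crossing point
    cut = np.searchsorted(fpr, fpr_max, side="right")
    fx, tx = fpr[:cut], tpr[:cut]
    if fx.size == 0 or fx[-1] < fpr_max:
        t_at = float(np.interp(fpr_max, fpr, tpr))
        fx = np.append(fx, fpr_max)
        tx = np.append(tx, t_at)
    raw = float(np.trapezoid(tx, fx))
    full = float(np.trapezoid(tpr, fpr))
    min_area = fpr_max ** 2 / 2.0  # chance
    max_area = fpr_max            # perfect
    std = 0.5 * (1.0 + (raw - min_area) / (max_area - min_area))
    return DetectionEntry(fpr=fx, tpr=tx, fpr_max=fpr_max, pauc_raw=raw,
                          pauc_standardized=float(std),
                          pauc_ratio=raw / fpr_max, auc=full)


# ----------------------------------------------------------------------
# benchmark harnesses


def run_imputation_benchmark(m: OmicsMatrix, g: GroupLabels,
                             truth: MissingnessTruth,
                             methods: tuple[str, ...] = ("mgpi", "min2", "mean"),
                             sg_genes: set[str] | None = None,
                             seed: int = 0) -> pd.DataFrame:
    """Impute a masked matrix with each method and score against truth.

    Returns one row per method with overall and (optionally) SG-focused
    RMSE/NRMSE.  A method failure is recorded in the ``error`` column
    rather than raised.
    """
    rows = []
    sg_truth = None
    if sg_genes:
        sub = truth.table[truth.table["gene_id"].isin(sg_genes)]
        sg_truth = MissingnessTruth(sub) if len(sub) >= 2 else None
    for method in methods:
        row = {"method": method, "n_omega": len(truth), "error": ""}
        try:
            kwargs = {"seed": seed} if method == "ppca" else {}
            result = imp.impute(m, method, g=g, **kwargs)
            row["rmse_overall"] = rmse(result, truth)
            row["nrmse_overall"] = nrmse(result, truth)
            if sg_truth is not None:
                row["rmse_sg"] = rmse(result, sg_truth)
                row["nrmse_sg"] = nrmse(result, sg_truth)
        except Exception as exc:  # recorded, not fatal
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def run_detection_benchmark(K_values: tuple[int, ...] = (3, 4, 5),
                            seeds: tuple[int, ...] = tuple(range(10)),
                            methods: tuple[str, ...] = ("ecot", "ovr-t", "ovr-fc"),
                            fpr_max: float = 0.05,
                            cfg_factory=None) -> pd.DataFrame:
    """DSG detection benchmark over the simplex simulation design.

    For each K and seed, simulates the standard design, scores genes
    with every method (DSGs positive, everything else — including SGs —
    negative) and reports pAUC at ``fpr_max``.
    """
    rows = []
    for K in K_values:
        for seed in seeds:
            cfg = cfg_factory(K, seed) if cfg_factory else SimplexSimConfig(K=K, seed=seed)
            m, g, truth = simulate_dataset(cfg)
            is_pos = truth.set_index("gene_id")["class"] == CLASS_DSG
            for method in methods:
                table = sig.score_genes(m, g, direction=sig.DSG, method=method)
                table = table.set_index("gene_id")
                common = table.index.intersection(is_pos.index)
                entry = proc_pauc(table.loc[common, "score"].to_numpy(),
                                  is_pos.loc[common].to_numpy(), fpr_max)
                rows.append({
                    "K": K, "seed": seed, "method": method,
                    "pauc_raw": entry.pauc_raw,
                    "pauc_standardized": entry.pauc_standardized,
                    "pauc_ratio": entry.pauc_ratio,
                    "auc": entry.auc,
                })
    return pd.DataFrame(rows)
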