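"""Combining-ability analysis of a full diallel cross.

A full diallel crosses every ordered pair of ``p`` parents (selfs and
reciprocals included).  Under the fixed-effects Griffing Method-1 model the
angular-transformed cell mean of (dam i x sire j) decomposes as

    y_ij = mu + g_i + g_j + s_ij + r_ij

with general combining abilities ``g`` (sum to zero), specific combining
abilities ``s`` (symmetric, rows sum to zero) and reciprocal effects ``r``
(antisymmetric).  On a complete design the decomposition is the orthogonal
split of the cell-mean matrix into its grand mean, additive row+column part,
the remaining symmetric part and the antisymmetric part, so fitted values
reproduce cell means exactly and the sums of squares are additive.  F tests
use the within-cell (replicate) residual mean square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .quantgen import angular_transform, inverse_angular_transform
from .tables import DiallelTable

logger = logging.getLogger(__name__)


@dataclass
class DiallelFit:
    """Estimated diallel effects (angular scale) and the ANOVA partition."""

    parents: list[str]
    mu: float
    gca: pd.Series
    sca: pd.DataFrame
    rec: pd.DataFrame
    anova: pd.DataFrame
    model: str = "full_with_reciprocals"
    cell_means: pd.DataFrame = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "parents": self.parents,
            "mu": self.mu,
            "gca": self.gca.to_dict(),
            "sca": self.sca.to_dict(),
            "rec": self.rec.to_dict(),
            "anova": self.anova.reset_index().to_dict(orient="list"),
            "model": self.model,
        }


def decompose_cell_means(M: np.ndarray):
    """Orthogonal decomposition of a p x p cell-mean matrix.

    Returns ``(mu, g, s, r)`` with ``sum(g) == 0``, ``s`` symmetric with zero
    row sums, and ``r`` antisymmetric; ``M == mu + g_i + g_j + s + r``
    exactly.
    """
    M = np.asarray(M, dtype=float)
    p = M.shape[0]
    sym = (M + M.T) / 2.0
    r = (M - M.T) / 2.0
    mu = sym.mean()
    row = sym.mean(axis=1)
    g = row - mu
    s = sym - mu - g[:, None] - g[None, :]
    return mu, g, s, r


def fit_diallel(data: DiallelTable, model: str = "full_with_reciprocals") -> DiallelFit:
    """Fit combining abilities to replicate-level diallel proportions.

    Proportions are angular-transformed internally.  ``model`` is either
    ``full_with_reciprocals`` (reciprocal term estimated and tested) or
    ``no_reciprocals`` (reciprocal variation pooled into the residual, which
    equals fitting the full model to reciprocal-averaged data).

    Missing cells are handled by iterative least-squares imputation
    (Healy-Westmacott) with a logged note; replicate imbalance uses the
    harmonic-mean cell count in the ANOVA, also logged.
    """
    if model not in ("full_with_reciprocals", "no_reciprocals"):
        raise ValueError(f"unknown model {model!r}")
    parents = data.parents
    p = len(parents)
    if p < 3:
        raise DesignError(f"diallel needs >= 3 parents, got {p}")
    idx = {parent: i for i, parent in enumerate(parents)}
    df = data.records.copy()
    df["y"] = angular_transform(np.asarray(df["proportion"], dtype=float))
    df["i"] = df["dam"].map(idx)
    df["j"] = df["sire"].map(idx)

    counts = np.zeros((p, p), dtype=int)
    sums = np.zeros((p, p))
    ss_within = 0.0
    for (i, j), sub in df.groupby(["i", "j"]):
        counts[i, j] = len(sub)
        sums[i, j] = sub["y"].sum()
        ss_within += float(((sub["y"] - sub["y"].mean()) ** 2).sum())
    observed = counts > 0
    M = np.where(observed, sums / np.maximum(counts, 1), np.nan)

    if not observed.all():
        logger.info(
            "diallel grid has %d empty cell(s); imputing via iterative "
            "least squares", int((~observed).sum())
        )
        M_filled = np.where(observed, M, np.nanmean(M))
        for _ in range(200):
            mu, g, _s, _r = decompose_cell_means(M_filled)
            # the symmetric/antisymmetric terms are cell-saturated, so only
            # the additive sub-model carries information to empty cells
            additive = mu + g[:, None] + g[None, :]
            new = np.where(observed, M, additive)
            if np.nanmax(np.abs(new - M_filled)) < 1e-12:
                M_filled = new
                break
            M_filled = new
        M = M_filled

    mu, g, s, r = decompose_cell_means(M)

    # replicate count entering the between-cell sums of squares
    reps = counts[observed]
    if reps.size and (reps != reps[0]).any():
        r_eff = stats.hmean(reps)
        logger.info("unbalanced replicate counts; using harmonic mean %.3f", r_eff)
    else:
        r_eff = float(reps[0]) if reps.size else 0.0

    ss_gca = 2.0 * p * r_eff * float((g ** 2).sum())
    ss_sca = r_eff * float((s ** 2).sum())
    ss_rec = r_eff * float((r ** 2).sum())
    df_gca = p - 1
    df_sca = p * (p - 1) // 2
    df_rec = p * (p - 1) // 2
    df_res = int((counts[observed] - 1).sum())

    if model == "no_reciprocals":
        # reciprocal variation is pooled into the residual
        ss_res = ss_within + ss_rec
        df_res_eff = df_res + df_rec
        rows = [("GCA", df_gca, ss_gca), ("SCA", df_sca, ss_sca)]
        r = np.zeros_like(r)
    else:
        ss_res = ss_within
        df_res_eff = df_res
        rows = [("GCA", df_gca, ss_gca), ("SCA", df_sca, ss_sca),
                ("reciprocal", df_rec, ss_rec)]

    ms_res = ss_res / df_res_eff if df_res_eff > 0 else np.nan
    table = []
    for name, dfree, ss in rows:
        ms = ss / dfree
        if df_res_eff > 0 and ms_res > 0:
            f = ms / ms_res
            pval = float(stats.f.sf(f, dfree, df_res_eff))
        else:
            f, pval = np.nan, np.nan
        table.append((name, dfree, ss, ms, f, pval))
    table.append(("residual", df_res_eff, ss_res,
                  ms_res, np.nan, np.nan))
    anova = pd.DataFrame(
        table, columns=["source", "df", "SS", "MS", "F", "p"]
    ).set_index("source")

    return DiallelFit(
        parents=list(parents),
        mu=float(mu),
        gca=pd.Series(g, index=parents),
        sca=pd.DataFrame(s, index=parents, columns=parents),
        rec=pd.DataFrame(r, index=parents, columns=parents),
        anova=anova,
        model=model,
        cell_means=pd.DataFrame(M, index=parents, columns=parents),
    )


def predict_hybrid(fit: DiallelFit, dam: str, sire: str) -> float:
    """Expected proportion dead for the cross dam x sire under the fit.

    The angular-scale prediction ``mu + g_dam + g_sire + s + r`` is
    back-transformed and clamped to [0, 1].
    """
    for parent in (dam, sire):
        if parent not in fit.gca.index:
            raise KeyError(f"unknown parent {parent!r}")
    y = (
        fit.mu
        + float(fit.gca[dam])
        + float(fit.gca[sire])
        + float(fit.sca.loc[dam, sire])
        + float(fit.rec.loc[dam, sire])
    )
    y = float(np.clip(y, 0.0, np.pi / 2))
    return float(np.clip(inverse_angular_transform(y), 0.0, 1.0))
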