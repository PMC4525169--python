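"""Phenotype transformation, line summaries, and broad-sense heritability.

The trait is the proportion of dead individuals per replicate vial, measured
on many inbred lines.  Because the lines are (near-)homozygous, half the
between-line variance on the variance-stabilized (angular) scale is taken as
the additive genetic variance, and the heritable component is

    H = V_A / (V_A + V_E),   V_A = V_L / 2,   V_E = V_R + V_eps,

estimated from the two-level random-effects model ``Y = mu + L + R + eps``
fitted to replicate-level angular values.  With one measurement per replicate
the replicate and residual variances are confounded and reported merged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .tables import PhenotypeTable

logger = logging.getLogger(__name__)


def angular_transform(p):
    """Variance-stabilizing transform ``arcsin(sqrt(p))`` of a proportion.

    Accepts scalars or arrays in [0, 1]; returns radians in [0, pi/2].
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValidationError("proportion outside [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def inverse_angular_transform(theta):
    """Inverse of :func:`angular_transform`: ``sin(theta)**2``."""
    arr = np.asarray(theta, dtype=float)
    out = np.sin(arr) ** 2
    return float(out) if np.isscalar(theta) or arr.ndim == 0 else out


def line_means(pheno: PhenotypeTable, scale: str = "proportion") -> pd.DataFrame:
    """Unweighted per-line mean and standard error over replicates.

    On the angular scale the mean is taken over transformed replicate values
    (mean of transforms, not transform of the mean).  The standard error is
    the sample s.d. over replicates divided by sqrt(k); it is NaN for lines
    with a single replicate.
    """
    if scale not in ("proportion", "angular"):
        raise ValueError(f"unknown scale {scale!r}")
    grp = pheno.records.groupby("line_id", sort=False)[scale]
    out = grp.agg(mean="mean", n="size")
    sd = grp.std(ddof=1)
    out["se"] = sd / np.sqrt(out["n"])
    return out[["mean", "se", "n"]]


@dataclass
class VarianceComponents:
    """Variance decomposition of replicate-level angular phenotypes.

    ``V_L`` is the between-line variance, ``V_R`` the between-replicate
    variance and ``V_eps`` the residual; with one observation per replicate
    the last two are confounded (``residual_confounded``) and the merged
    value is reported in ``V_R`` with ``V_eps = 0``.  Negative
    method-of-moments estimates are truncated to zero (``truncated``).
    """

    V_L: float
    V_R: float
    V_eps: float
    method: str = "reml"
    truncated: bool = False
    residual_confounded: bool = True

    def __post_init__(self):
        if min(self.V_L, self.V_R, self.V_eps) < 0:
            raise ValidationError("variance components must be non-negative")

    @property
    def V_A(self) -> float:
        return self.V_L / 2.0

    @property
    def V_E(self) -> float:
        return self.V_R + self.V_eps

    @property
    def H(self) -> float:
        denom = self.V_A + self.V_E
        if denom == 0:
            return 0.0
        return self.V_A / denom

    def to_dict(self) -> dict:
        return {
            "V_L": self.V_L, "V_R": self.V_R, "V_eps": self.V_eps,
            "V_A": self.V_A, "V_E": self.V_E, "H": self.H,
            "method": self.method, "truncated": self.truncated,
            "residual_confounded": self.residual_confounded,
        }


def _anova_moments(y: np.ndarray, groups: np.ndarray):
    """One-way ANOVA mean squares and the effective replicates-per-line k-bar."""
    df = pd.DataFrame({"y": y, "g": groups})
    n = len(df)
    stats_g = df.groupby("g")["y"].agg(["mean", "size"])
    a = len(stats_g)
    grand = df["y"].mean()
    ss_between = float((stats_g["size"] * (stats_g["mean"] - grand) ** 2).sum())
    ss_within = float(
        ((df["y"] - df["g"].map(stats_g["mean"])) ** 2).sum()
    )
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (n - a) if n > a else np.nan
    k = stats_g["size"].to_numpy(dtype=float)
    kbar = (n - (k ** 2).sum() / n) / (a - 1)
    return ms_between, ms_within, kbar, a, n


def estimate_heritability(
    pheno: PhenotypeTable, method: str = "reml"
) -> VarianceComponents:
    """Estimate variance components and H from replicate-level records.

    ``method='reml'`` fits the one-way random-intercept model by restricted
    maximum likelihood (statsmodels MixedLM); ``method='mom'`` uses the
    method-of-moments estimator from the one-way ANOVA mean squares,
    ``V_L = (MS_between - MS_within) / k_bar``.  On balanced designs the two
    agree closely; MoM serves as a dependency-light fallback and oracle.
    """
    df = pheno.records
    y = np.asarray(df["angular"], dtype=float)
    groups = np.asarray(df["line_id"])
    sizes = pd.Series(groups).value_counts()
    if len(sizes) < 2:
        raise InsufficientDataError("need >= 2 lines to estimate heritability")
    if (sizes < 2).all():
        raise InsufficientDataError(
            "all lines have a single replicate; line and residual variance "
            "cannot be separated"
        )
    if method == "mom":
        ms_b, ms_w, kbar, _, _ = _anova_moments(y, groups)
        v_l = (ms_b - ms_w) / kbar
        truncated = v_l < 0
        return VarianceComponents(
            V_L=max(v_l, 0.0), V_R=ms_w, V_eps=0.0,
            method="mom", truncated=bool(truncated),
        )
    if method != "reml":
        raise ValueError(f"unknown method {method!r}")
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, np.ones((len(y), 1)), groups=groups)
        try:
            fit = model.fit(reml=True, method="lbfgs")
            v_l = float(np.asarray(fit.cov_re)[0, 0])
            v_e = float(fit.scale)
        except Exception as exc:  # singular fits fall back to MoM
            logger.warning("REML fit failed (%s); falling back to MoM", exc)
            return estimate_heritability(pheno, method="mom")
    truncated = False
    if v_l < 0:
        v_l, truncated = 0.0, True
    return VarianceComponents(
        V_L=v_l, V_R=v_e, V_eps=0.0, method="reml", truncated=truncated
    )


def phenotype_correlation(a: pd.DataFrame, b: pd.DataFrame):
    """Pearson correlation between two line-mean tables on shared lines.

    Both inputs are tables as returned by :func:`line_means` (indexed by
    line id, column ``mean``), expected on the angular scale.  Returns
    ``(r, n, p)`` with a two-sided p-value from the t distribution with
    n - 2 degrees of freedom.
    """
    shared = a.index.intersection(b.index)
    n = len(shared)
    if n < 3:
        raise InsufficientDataError(f"only {n} shared lines; need >= 3")
    x = np.asarray(a.loc[shared, "mean"], dtype=float)
    y = np.asarray(b.loc[shared, "mean"], dtype=float)
    r, p = stats.pearsonr(x, y)
    return float(r), int(n), float(p)
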