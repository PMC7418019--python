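"""Scale-quality assessment of an indicator panel.

Treats the quarters of a panel as items of a scale and the hospitals as
cases, and asks whether the 25-quarter rate data behave like a reliable,
unidimensional measurement instrument. Four classical-test-theory
indicators are computed:

* Cronbach alpha (internal consistency; accept when > .70),
* the dimension coefficient Z/(1+Z) with Z = (a1/a2)/(a2/a3) from the
  first three principal-component eigenvalues of the item correlation
  matrix (> 0.67 read as unidimensional),
* average variance extracted, AVE = sum(lambda^2) / (sum(lambda^2) + sum(eps)),
* construct (composite) reliability, CR = (sum lambda)^2 / ((sum lambda)^2 + sum eps),

with loadings lambda taken as item/first-component correlations and
standardized measurement errors eps = 1 - lambda^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_io import IndicatorPanel

EIGENVALUE_FLOOR = 1e-10

ALPHA_THRESHOLD = 0.70
DIM_COEF_THRESHOLD = 0.67


class DegenerateSpectrumError(ValueError):
    """Second or third eigenvalue at the numerical floor; Z undefined."""


def _as_matrix(matrix) -> np.ndarray:
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D cases x items matrix")
    if np.isnan(x).any():
        raise ValueError("matrix contains missing cells; filter the panel first")
    return x


def cronbach_alpha(matrix) -> float:
    """Cronbach alpha of a cases x items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total score),
    with k items and sample (n-1) variances. Undefined (raises) when the
    total score has zero variance.
    """
    x = _as_matrix(matrix)
    n_cases, k = x.shape
    if k < 2:
        raise ValueError(f"need >= 2 items, got {k}")
    if n_cases < 2:
        raise ValueError(f"need >= 2 cases, got {n_cases}")
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def _correlation_eigensystem(x: np.ndarray):
    """Eigenvalues (descending) and eigenvectors of the item correlation matrix."""
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        idx = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"item {idx} is constant; correlations undefined")
    corr = np.corrcoef(x, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def dimension_coefficient(matrix) -> tuple[float, float, float, float]:
    """Dimension coefficient and the first three PCA eigenvalues.

    Returns ``(dim_coef, a1, a2, a3)`` where Z = (a1/a2)/(a2/a3) and
    dim_coef = Z/(1+Z). A coefficient above 0.67 indicates a scale
    dominated by a single dimension.
    """
    x = _as_matrix(matrix)
    if x.shape[1] < 3:
        raise ValueError(f"need >= 3 items, got {x.shape[1]}")
    eigvals, _ = _correlation_eigensystem(x)
    a1, a2, a3 = (float(v) for v in eigvals[:3])
    if a2 <= EIGENVALUE_FLOOR or a3 <= EIGENVALUE_FLOOR:
        raise DegenerateSpectrumError(
            f"degenerate spectrum: a2={a2:.3g}, a3={a3:.3g}"
        )
    z = (a1 / a2) / (a2 / a3)
    return z / (1.0 + z), a1, a2, a3


def first_factor_loadings(matrix) -> np.ndarray:
    """Loading of each item on the first principal component.

    lambda_i is the Pearson correlation of item i with the first
    principal-component score; the sign of the component is flipped so the
    loading sum is non-negative.
    """
    x = _as_matrix(matrix)
    eigvals, eigvecs = _correlation_eigensystem(x)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    score = z @ eigvecs[:, 0]
    if score.std(ddof=1) == 0:
        raise ValueError("first component score is constant; loadings undefined")
    lam = np.array(
        [np.corrcoef(x[:, i], score)[0, 1] for i in range(x.shape[1])]
    )
    if lam.sum() < 0:
        lam = -lam
    return lam


def average_variance_extracted(loadings) -> float:
    """AVE: communality share of (communality + standardized error)."""
    lam = np.asarray(loadings, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("loadings must be finite")
    if np.any(np.abs(lam) > 1 + 1e-12):
        raise ValueError("|loading| > 1 is outside the standardized-item domain")
    lam2 = np.clip(lam, -1, 1) ** 2
    eps = 1.0 - lam2
    denom = lam2.sum() + eps.sum()
    return float(lam2.sum() / denom) if denom > 0 else 0.0


def construct_reliability(loadings) -> float:
    """Composite reliability: (sum lambda)^2 / ((sum lambda)^2 + sum eps)."""
    lam = np.asarray(loadings, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("loadings must be finite")
    if np.any(np.abs(lam) > 1 + 1e-12):
        raise ValueError("|loading| > 1 is outside the standardized-item domain")
    s2 = np.clip(lam, -1, 1).sum() ** 2
    eps = (1.0 - np.clip(lam, -1, 1) ** 2).sum()
    denom = s2 + eps
    return float(s2 / denom) if denom > 0 else 0.0


@dataclass
class QualityReport:
    """Bundle of the four scale-quality indicators for one panel."""

    drug: str
    alpha: float
    dim_coef: float
    ave: float
    cr: float
    eigenvalues: tuple[float, float, float]
    loadings: np.ndarray
    passes: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "alpha": self.alpha,
            "dim_coef": self.dim_coef,
            "ave": self.ave,
            "cr": self.cr,
            "eigenvalues": list(self.eigenvalues),
            "passes": dict(self.passes),
        }


def quality_report(panel: IndicatorPanel) -> QualityReport:
    """Compute all four indicators for a complete panel.

    Pass flags use the published strict thresholds: alpha > .70,
    dimension coefficient > 0.67.
    """
    matrix = panel.rates.to_numpy(dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 hospitals (cases) for scale quality")
    alpha = cronbach_alpha(matrix)
    dim_coef, a1, a2, a3 = dimension_coefficient(matrix)
    lam = first_factor_loadings(matrix)
    return QualityReport(
        drug=panel.drug,
        alpha=alpha,
        dim_coef=dim_coef,
        ave=average_variance_extracted(lam),
        cr=construct_reliability(lam),
        eigenvalues=(a1, a2, a3),
        loadings=lam,
        passes={
            "alpha": alpha > ALPHA_THRESHOLD,
            "dim_coef": dim_coef > DIM_COEF_THRESHOLD,
        },
    )


class ScaleQualityModel:
    """statsmodels-style front end: ``ScaleQualityModel(panel).fit()``."""

    def __init__(self, panel: IndicatorPanel):
        self.panel = panel

    def fit(self) -> "ScaleQualityResults":
        return ScaleQualityResults(self.panel, quality_report(self.panel))


class ScaleQualityResults:
    """Results wrapper exposing the report fields plus ``summary()``."""

    def __init__(self, panel: IndicatorPanel, report: QualityReport):
        self.panel = panel
        self.report = report

    def __getattr__(self, name):
        return getattr(self.report, name)

    def summary(self) -> str:
        r = self.report
        lines = [
            f"Scale quality: {r.drug} "
            f"({self.panel.n_hospitals} hospitals x {self.panel.n_quarters} quarters)",
            "-" * 64,
            f"Cronbach alpha        {r.alpha:8.3f}   (pass > {ALPHA_THRESHOLD}: {r.passes['alpha']})",
            f"Dimension coefficient {r.dim_coef:8.3f}   (pass > {DIM_COEF_THRESHOLD}: {r.passes['dim_coef']})",
            f"AVE                   {r.ave:8.3f}",
            f"Construct reliability {r.cr:8.3f}",
            "Eigenvalues (a1,a2,a3) "
            + ", ".join(f"{v:.3f}" for v in r.eigenvalues),
        ]
        return "\n".join(lines)
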