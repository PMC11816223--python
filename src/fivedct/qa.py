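"""Workflow QA: grading data model, usability accounting, statistics, report.

The clinical workflow grades four variables per case on a 1-4 (best-worst)
scale — breathing irregularity, helical image quality, DIR quality, and
suitability for treatment planning (STP) — and records how each image set
was ultimately used (seven usability categories collapsed into used / backup
/ other groups).  This module houses that data model, the rank-correlation
and multiple-regression analyses relating workflow grades to model accuracy,
a Gaussian-copula generator for synthetic grade tables, and the assembly of
the per-session QA report.

Grading itself is a human act; the only automation offered is an explicitly
labeled STP *proxy* thresholded on the residual summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import EmptyInputError, RankDeficiencyError, UndefinedCorrelationError

GRADE_COLUMNS = ("breathing_irregularity", "fhfbct_quality", "dir_quality", "stp")
USABILITY_GROUPS = {"used": (1, 2), "backup": (3, 4), "other": (5, 6, 7)}

#: QA-report data elements, one per row of the clinical report layout
REPORT_ELEMENTS = (
    "scan_start_stop",
    "scan_ranges",
    "corrected_shifts",
    "bellows_abdomen_correlation",
    "respiratory_trace",
    "amplitude_histogram",
    "waveform_segmentation",
    "representative_breath",
    "dir_overlays",
    "model_summary",
    "residual_histogram",
    "residual_mips",
    "original_scan_reconstructions",
)

REPORT_SECTIONS = {
    "acquisition": REPORT_ELEMENTS[0:4],
    "breathing": REPORT_ELEMENTS[4:8],
    "registration": REPORT_ELEMENTS[8:9],
    "modeling": REPORT_ELEMENTS[9:13],
}


@dataclass
class GradeRecord:
    """One case's workflow grades, usability category and residual metrics."""

    case_id: str
    breathing_irregularity: int
    fhfbct_quality: int
    dir_quality: int
    stp: int
    usability_category: int
    mean_residual: float  # mm
    p95_residual: float  # mm

    def __post_init__(self):
        for name in GRADE_COLUMNS:
            g = getattr(self, name)
            if not (isinstance(g, (int, np.integer)) and 1 <= g <= 4):
                raise ValueError(f"{name} must be an integer grade in [1, 4], got {g}")
        if not 1 <= self.usability_category <= 7:
            raise ValueError(f"usability_category must be in [1, 7]")
        if self.mean_residual < 0 or self.p95_residual < 0:
            raise ValueError("residuals must be non-negative")


@dataclass
class StatsResult:
    """Regression summary: coefficients, CIs, p-values, standardized betas."""

    params: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    pvalues: dict[str, float]
    std_beta: dict[str, float]
    r2: float
    r2_adj: float
    n: int


def spearman_ci(
    x,
    y,
    ci_method: str = "fisher",
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float], float]:
    """Spearman rank correlation with 95% CI and two-sided p.

    Ties receive average ranks.  The default CI is the Fisher
    z-transform interval; ``ci_method='bootstrap'`` resamples cases.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need equal-length sequences of at least 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("rank correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    if ci_method == "fisher":
        z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
        half = 1.959963984540054 / np.sqrt(x.size - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, x.size, x.size)
            if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
                continue
            reps.append(sps.spearmanr(x[idx], y[idx]).statistic)
        ci = tuple(np.percentile(reps, [2.5, 97.5]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return rho, ci, float(p)


def multiple_regression(y, X: pd.DataFrame) -> StatsResult:
    """OLS of y on the predictor table, with an intercept.

    Reports unstandardized coefficients B with 95% CIs and t-test p-values,
    standardized coefficients ``beta = B * sd(x) / sd(y)``, and both R² and
    adjusted R².
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    design = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise RankDeficiencyError("collinear predictors (design not full rank)")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    sy = y.std(ddof=1)
    std_beta = {
        c: float(fit.params[c] * X[c].std(ddof=1) / sy) for c in X.columns
    }
    return StatsResult(
        params={k: float(v) for k, v in fit.params.items()},
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in fit.params.index},
        pvalues={k: float(v) for k, v in fit.pvalues.items()},
        std_beta=std_beta,
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        n=n,
    )


def usability_summary(records: list[GradeRecord] | pd.DataFrame) -> dict:
    """Counts, group percentages and group means of the usability table.

    Categories 1-2 form the "used" group, 3-4 "backup", 5-7 "other" (no ITV
    identified).  Percentages are of all records, rounded to the nearest
    integer for display (raw fractions are also returned).  Grade and
    residual means are reported for the used and backup groups.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    if len(df) == 0:
        raise EmptyInputError("no grade records")
    total = len(df)
    cat_counts = {c: int((df["usability_category"] == c).sum()) for c in range(1, 8)}
    out = {"total": total, "category_counts": cat_counts, "groups": {}}
    for group, cats in USABILITY_GROUPS.items():
        sel = df["usability_category"].isin(cats)
        count = int(sel.sum())
        out["groups"][group] = {
            "count": count,
            "fraction": count / total,
            "percent": int(round(100.0 * count / total)),
        }
    means = {}
    for group in ("used", "backup"):
        sel = df["usability_category"].isin(USABILITY_GROUPS[group])
        cols = [c for c in (*GRADE_COLUMNS, "mean_residual", "p95_residual")
                if c in df.columns]
        means[group] = {c: float(df.loc[sel, c].mean()) if sel.any() else float("nan")
                        for c in cols}
    out["group_means"] = means
    return out


def stp_proxy(p95_residual_mm: float) -> int:
    """Automated STP stand-in thresholded on the residual 95th percentile.

    A proxy for triage only — the clinical STP grade is a human judgment of
    original-scan-reconstruction alignment, not a residual threshold.
    """
    for grade, limit in ((1, 1.0), (2, 2.0), (3, 4.0)):
        if p95_residual_mm < limit:
            return grade
    return 4


def generate_grade_table(
    n: int,
    marginals: dict[str, list[float]] | None = None,
    latent_corr: np.ndarray | None = None,
    stp_coeffs: tuple[float, float, float, float] = (0.996, 0.133, 0.290, 0.404),
    noise_sd: float = 0.55,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic grade table via a Gaussian copula.

    Ordinal grades for breathing irregularity, image quality and DIR quality
    are drawn with the requested marginal distributions and latent
    correlation; a continuous STP score is a planted linear combination of
    the three grades plus Gaussian noise, and the STP grade its rounding
    clipped to [1, 4].  Residual columns follow the same latent structure.
    """
    rng = np.random.default_rng(seed)
    if marginals is None:
        # observed clinical marginal grade frequencies
        marginals = {
            "breathing_irregularity": [0.14, 0.39, 0.28, 0.19],
            "fhfbct_quality": [0.62, 0.33, 0.04, 0.01],
            "dir_quality": [0.57, 0.27, 0.09, 0.06],
        }
    names = list(marginals)
    k = len(names)
    if latent_corr is None:
        latent_corr = np.full((k, k), 0.35) + 0.65 * np.eye(k)
    z = rng.multivariate_normal(np.zeros(k), latent_corr, size=n)
    u = sps.norm.cdf(z)
    df = pd.DataFrame({"case_id": [f"case{i:04d}" for i in range(n)]})
    for j, name in enumerate(names):
        cum = np.cumsum(marginals[name])
        df[name] = 1 + np.searchsorted(cum[:-1], u[:, j], side="left")
    c0, c1, c2, c3 = stp_coeffs
    stp_score = (c0 + c1 * df["breathing_irregularity"] + c2 * df["fhfbct_quality"]
                 + c3 * df["dir_quality"] + noise_sd * rng.standard_normal(n))
    df["stp_score"] = stp_score
    df["stp"] = np.clip(np.round(stp_score), 1, 4).astype(int)
    df["mean_residual"] = np.clip(
        0.571 + 0.214 * df["breathing_irregularity"] + 0.147 * df["fhfbct_quality"]
        + 0.102 * df["dir_quality"] + 0.3 * rng.standard_normal(n), 0.05, None)
    df["p95_residual"] = df["mean_residual"] * (2.2 + 0.3 * rng.standard_normal(n)).clip(1.2)
    # usability loosely follows STP: poor reconstructions fall back more often
    p_backup = np.clip(0.04 * (stp_score - 1.0), 0.0, 0.9)
    cat = np.where(rng.random(n) < p_backup,
                   rng.choice([3, 4], size=n),
                   rng.choice([1, 2], size=n, p=[0.85, 0.15]))
    other = rng.random(n) < 0.17
    cat = np.where(other, rng.choice([5, 6, 7], size=n), cat)
    df["usability_category"] = cat.astype(int)
    return df


def load_grades(path) -> pd.DataFrame:
    """Read a grade table CSV with GradeRecord columns."""
    df = pd.read_csv(path)
    missing = {"usability_category", *GRADE_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"grade table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# report assembly


def assemble_report(
    out_dir,
    acquisition: dict | None = None,
    breathing: dict | None = None,
    registration: dict | None = None,
    modeling: dict | None = None,
) -> dict:
    """Assemble the four-section QA report as HTML plus a JSON summary.

    Each section dict maps report-element names (see ``REPORT_ELEMENTS``) to
    serializable values or PNG paths.  Missing sections or elements emit a
    partial-report warning and a placeholder; the returned summary includes
    a manifest of which elements are present.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sections = {
        "acquisition": acquisition,
        "breathing": breathing,
        "registration": registration,
        "modeling": modeling,
    }
    manifest = {}
    html = ["<html><head><title>5DCT QA report</title></head><body>",
            "<h1>5DCT QA report</h1>"]
    for name, content in sections.items():
        html.append(f"<h2>{name.title()}</h2>")
        if content is None:
            warnings.warn(f"QA report section {name!r} missing; placeholder emitted")
            html.append("<p><em>Section unavailable.</em></p>")
            content = {}
        for element in REPORT_SECTIONS[name]:
            value = content.get(element)
            manifest[element] = value is not None
            if value is None:
                warnings.warn(f"QA report element {element!r} missing")
                html.append(f"<p>{element}: <em>missing</em></p>")
            elif isinstance(value, (str,)) and str(value).endswith(".png"):
                html.append(f"<p>{element}</p><img src='{value}' width='640'/>")
            else:
                html.append(f"<p>{element}: <code>{json.dumps(value, default=str)}</code></p>")
    html.append("</body></html>")
    (out_dir / "qa_report.html").write_text("\n".join(html))

    summary = {
        "elements_present": manifest,
        "complete": all(manifest.values()),
        "sections": {
            name: ({k: v for k, v in (content or {}).items()
                    if not (isinstance(v, str) and v.endswith(".png"))})
            for name, content in sections.items()
        },
    }
    (out_dir / "qa_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
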