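"""Validation statistics for the pronunciation distance measure.

Pearson correlation against human native-likeness ratings, multiple linear
regression combining acoustic and transcription-based predictors, Steiger's
modified z for comparing dependent correlations that share one variable,
Bark-scaled formant distances for vowel-quality comparison, and Torgerson's
classical multidimensional scaling for visualizing distance matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p-value (t transform, n-2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson requires two equal-length vectors")
    if x.size < 3:
        raise ValueError("pearson requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class RegressionResult:
    """OLS fit: one row per term (estimate, std_error, t_value, p_value)."""

    table: pd.DataFrame  # indexed by term, intercept row named "intercept"
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared out of [0, 1]")


def fit_regression(data: pd.DataFrame, response: str,
                   predictors: Sequence[str]) -> RegressionResult:
    """Ordinary least squares with intercept on complete cases.

    Standard errors use the unbiased residual variance; p-values are
    two-sided t tests.  Rank-deficient designs are rejected with the
    offending columns named.
    """
    cols = [response, *predictors]
    frame = data[cols].dropna()
    if frame.shape[0] <= len(predictors) + 1:
        raise ValueError(
            f"need n > {len(predictors) + 1} complete cases, got {frame.shape[0]}"
        )
    X = sm.add_constant(frame[list(predictors)].to_numpy(dtype=np.float64))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = frame[list(predictors)].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; collinear columns include {worst}")
    fit = sm.OLS(frame[response].to_numpy(dtype=np.float64), X).fit()
    table = pd.DataFrame({
        "estimate": fit.params,
        "std_error": fit.bse,
        "t_value": fit.tvalues,
        "p_value": fit.pvalues,
    })
    table.index = ["intercept", *predictors]
    return RegressionResult(table=table, r_squared=float(fit.rsquared),
                            n=int(frame.shape[0]))


def steiger_test(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Steiger's modified z for dependent correlations sharing variable 1.

    Tests H0: rho12 = rho13 given the observed r23, using Fisher transforms
    of r12 and r13 and the pooled-correlation covariance term.  Returns
    (z, two-sided p).
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1), got {r}")
    if n <= 3:
        raise ValueError("steiger_test requires n > 3")
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rbar = 0.5 * (r12 + r13)
    psi = r23 * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r23**2)
    s = psi / (1.0 - rbar**2) ** 2
    z = (z12 - z13) * np.sqrt((n - 3.0) / (2.0 - 2.0 * s))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# vowel-quality distances


def bark(f, formula: str = "traunmuller"):
    """Hz to Bark.  Traunmüller: z = 26.81 f / (1960 + f) - 0.53."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    if formula == "traunmuller":
        z = 26.81 * f / (1960.0 + f) - 0.53
    elif formula == "zwicker":
        z = 13.0 * np.arctan(0.00076 * f) + 3.5 * np.arctan((f / 7500.0) ** 2)
    else:
        raise ValueError(f"unknown bark formula {formula!r}")
    return float(z) if z.ndim == 0 else z


@dataclass(frozen=True)
class FormantPoint:
    """Vowel-midpoint F1/F2 measurement in Hz."""

    F1: float
    F2: float

    def __post_init__(self) -> None:
        if not 0 < self.F1 < self.F2:
            raise ValueError(f"need 0 < F1 < F2, got ({self.F1}, {self.F2})")


def formant_distance(a: FormantPoint, b: FormantPoint,
                     formula: str = "traunmuller") -> float:
    """Euclidean distance in Bark-scaled (F1, F2) space."""
    return float(np.hypot(bark(a.F1, formula) - bark(b.F1, formula),
                          bark(a.F2, formula) - bark(b.F2, formula)))


def classical_mds(D: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson classical MDS.

    Double-centers the squared distance matrix, takes the top-k non-negative
    eigenpairs, and returns (coordinates, variance-explained fractions of
    each kept axis relative to the positive eigenvalue total).  Axes are
    oriented so the largest-magnitude loading on each is positive.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12) or np.any(D < -1e-12):
        raise ValueError("D must be non-negative with a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    kept = np.maximum(eigvals[:k], 0.0)
    X = eigvecs[:, :k] * np.sqrt(kept)
    for j in range(X.shape[1]):  # reproducible orientation
        i = np.argmax(np.abs(X[:, j]))
        if X[i, j] < 0:
            X[:, j] = -X[:, j]
    positive = eigvals[eigvals > 0].sum()
    explained = kept / positive if positive > 0 else np.zeros(k)
    return X, explained


# ---------------------------------------------------------------------------
# top-level evaluation report


def evaluate(distances: pd.DataFrame, ratings: pd.DataFrame,
             transcription: pd.DataFrame | None = None,
             mispronunciations: pd.DataFrame | None = None,
             out_json: str | Path | None = None) -> dict:
    """Correlate the distance table with ratings; optionally fit the joint
    regression and the Steiger comparison against a transcription measure.

    ``distances`` needs columns target_speaker_id/mean_distance (the pipeline
    output); ``ratings`` speaker_id/mean_rating; optional tables
    speaker_id/distance and speaker_id/count.  Joined on speaker_id;
    duplicate speaker rows are rejected.
    """
    d = distances.rename(columns={"target_speaker_id": "speaker_id"})
    for name, frame in (("distances", d), ("ratings", ratings)):
        if frame["speaker_id"].duplicated().any():
            raise ValueError(f"duplicated speaker rows in {name} table")
    merged = d[["speaker_id", "mean_distance"]].merge(ratings, on="speaker_id")
    if merged.empty:
        raise ValueError("no overlapping speakers between distances and ratings")
    r, p = pearson(merged["mean_distance"], merged["mean_rating"])
    report: dict = {"n": int(merged.shape[0]), "pearson_r": r, "pearson_p": p}

    predictors = ["mean_distance"]
    if transcription is not None:
        if transcription["speaker_id"].duplicated().any():
            raise ValueError("duplicated speaker rows in transcription table")
        merged = merged.merge(
            transcription.rename(columns={"distance": "transcription_distance"}),
            on="speaker_id",
        )
        predictors.append("transcription_distance")
    if mispronunciations is not None:
        merged = merged.merge(
            mispronunciations.rename(columns={"count": "mispronunciation_count"}),
            on="speaker_id",
        )
        predictors.append("mispronunciation_count")

    if len(predictors) > 1:
        reg = fit_regression(merged, "mean_rating", predictors)
        report["regression"] = {
            "r_squared": reg.r_squared,
            "n": reg.n,
            "terms": reg.table.round(6).to_dict(orient="index"),
        }
    if transcription is not None:
        sub = merged.dropna(subset=["transcription_distance"])
        r12, _ = pearson(sub["mean_rating"], sub["mean_distance"])
        r13, _ = pearson(sub["mean_rating"], sub["transcription_distance"])
        r23, _ = pearson(sub["mean_distance"], sub["transcription_distance"])
        z, pz = steiger_test(r12, r13, r23, n=sub.shape[0])
        report["steiger"] = {"z": z, "p": pz, "n": int(sub.shape[0]),
                             "r_acoustic": r12, "r_transcription": r13}
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report, indent=2), "utf-8")
    return report


def plot_correlation(distances: pd.DataFrame, ratings: pd.DataFrame,
                     path: str | Path) -> None:
    """Scatter of ratings against distances with the fitted line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = distances.rename(columns={"target_speaker_id": "speaker_id"})
    merged = d.merge(ratings, on="speaker_id")
    x = merged["mean_distance"].to_numpy()
    y = merged["mean_rating"].to_numpy()
    r, _ = pearson(x, y)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, alpha=0.7)
    coef = np.polyfit(x, y, 1)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, np.polyval(coef, xs), lw=1.2)
    ax.set_xlabel("acoustic distance")
    ax.set_ylabel("native-likeness rating")
    ax.set_title(f"r = {r:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mds(D: np.ndarray, labels: Sequence[str], path: str | Path) -> None:
    """2-D classical-MDS map of a distance matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X, explained = classical_mds(D, k=2)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(X[:, 0], X[:, 1], s=12, color="0.4")
    for (x0, x1), lab in zip(X, labels):
        ax.annotate(lab, (x0, x1), fontsize=9)
    ax.set_xlabel(f"dim 1 ({100 * explained[0]:.0f}%)")
    ax.set_ylabel(f"dim 2 ({100 * explained[1]:.0f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
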