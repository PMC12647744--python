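"""Tumor-to-myeloid transcriptomic similarity ("myeloid mimicry") panel.

Quantifies how closely tumor-cell transcriptomes resemble the myeloid
compartment, per condition (baseline vs post nivolumab+ipilimumab), with
six metrics on the top highly variable genes: Euclidean, Manhattan,
Bray-Curtis and phi proportionality as dissimilarities, cosine and
Pearson correlation as similarities.  Each tumor cell is compared with
the per-condition myeloid centroid (mean profile); an all-pairs mode is
available for sensitivity analysis.  Conditions are contrasted per
metric by the log2 fold change of medians and a two-sided Wilcoxon
rank-sum test.

Increased mimicry after treatment shows up as negative log fold changes
of all dissimilarities and positive log fold changes of both
similarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu

__all__ = [
    "DISSIMILARITIES",
    "SIMILARITIES",
    "METRICS",
    "select_hvgs",
    "myeloid_reference",
    "compute_panel",
    "contrast_conditions",
    "mimicry_panel",
]

DISSIMILARITIES = ("euclidean", "manhattan", "bray_curtis", "phi")
SIMILARITIES = ("cosine", "pearson")
METRICS = DISSIMILARITIES + SIMILARITIES

#: pseudocount for the log-ratio in phi proportionality
PHI_EPS = 1.0


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=float)


def select_hvgs(adata: AnnData, n: int = 3000, theta: float = 100.0) -> list[str]:
    """Top-``n`` highly variable genes by analytic Pearson residual variance.

    Each entry is residualized against the rank-one expectation implied
    by its cell's total and its gene's overall abundance, scaled by a
    negative-binomial variance function with overdispersion ``theta``,
    and clipped at +/- sqrt(n_cells); genes are ranked by the variance
    of these residuals.  Unlike log-based dispersion statistics this
    does not saturate for abundant marker genes.  Ties are broken by
    gene id, making the selection deterministic.  ``n`` larger than the
    gene count is capped with a warning.
    """
    if n > adata.n_vars:
        warnings.warn(
            f"requested {n} HVGs but only {adata.n_vars} genes; capping",
            stacklevel=2,
        )
        n = adata.n_vars
    X = _dense(adata.X)
    n_cells = X.shape[0]
    total = X.sum()
    if total <= 0:
        raise ValueError("expression matrix has no signal")
    mu = np.outer(X.sum(axis=1), X.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.where(mu > 0, (X - mu) / np.sqrt(mu + mu**2 / theta), 0.0)
    resid = np.clip(resid, -np.sqrt(n_cells), np.sqrt(n_cells))
    score = resid.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(X.shape[1])

    genes = np.asarray(adata.var_names)
    ranking = sorted(range(len(genes)), key=lambda i: (-score[i], genes[i]))
    return [genes[i] for i in ranking[:n]]


def myeloid_reference(
    adata: AnnData, condition: str, compartment: str = "myeloid"
) -> np.ndarray:
    """Per-gene mean profile (centroid) of the myeloid cells in a condition."""
    mask = (adata.obs["compartment"] == compartment) & (
        adata.obs["condition"] == condition
    )
    if not mask.any():
        raise ValueError(
            f"no {compartment!r} cells in condition {condition!r}"
        )
    return _dense(adata.X[mask.to_numpy()]).mean(axis=0)


def _phi(X: np.ndarray, y: np.ndarray, eps: float = PHI_EPS) -> np.ndarray:
    """Lovell-style proportionality phi(x, y) = var(log x - log y)/var(log x)."""
    logX = np.log(X + eps)
    logy = np.log(y + eps)
    diff_var = np.var(logX - logy, axis=1, ddof=1)
    x_var = np.var(logX, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(diff_var == 0, 0.0, diff_var / x_var)
    return out


def compute_panel(X, reference: np.ndarray) -> pd.DataFrame:
    """Six-metric similarity panel: each row of ``X`` against ``reference``.

    ``X`` (cells x genes) and ``reference`` must already be restricted
    to the same highly-variable-gene set.  Cosine is undefined (NaN) for
    a zero-norm vector, Pearson for a constant vector.
    """
    X = np.atleast_2d(_dense(X))
    y = np.asarray(reference, dtype=float)
    if X.shape[1] != y.size:
        raise ValueError("cell matrix and reference differ in gene count")
    y2 = y[None, :]

    panel = pd.DataFrame(
        {
            "euclidean": cdist(X, y2, metric="euclidean")[:, 0],
            "manhattan": cdist(X, y2, metric="cityblock")[:, 0],
            "bray_curtis": np.abs(X - y2).sum(axis=1)
            / np.maximum((X + y2).sum(axis=1), np.finfo(float).tiny),
            "phi": _phi(X, y),
        }
    )

    norms = np.linalg.norm(X, axis=1) * np.linalg.norm(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.where(norms > 0, X @ y / norms, np.nan)
    panel["cosine"] = cos

    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        pear = np.where(denom > 0, xc @ yc / denom, np.nan)
    panel["pearson"] = pear
    return panel


def contrast_conditions(
    panel_baseline: pd.DataFrame, panel_post: pd.DataFrame
) -> pd.DataFrame:
    """Per-metric contrast between conditions.

    Log fold change is log2 of the ratio of medians (post over
    baseline); the p-value is the two-sided Wilcoxon rank-sum test.  A
    non-positive median leaves the LFC missing.
    """
    if panel_baseline.empty or panel_post.empty:
        raise ValueError("both panels must be non-empty")
    rows = []
    for metric in METRICS:
        base = panel_baseline[metric].dropna().to_numpy()
        post = panel_post[metric].dropna().to_numpy()
        med_b, med_p = np.median(base), np.median(post)
        lfc = (
            np.log2(med_p / med_b) if med_b > 0 and med_p > 0 else np.nan
        )
        p = mannwhitneyu(post, base, alternative="two-sided").pvalue
        rows.append(
            {
                "metric": metric,
                "kind": "dissimilarity" if metric in DISSIMILARITIES else "similarity",
                "median_baseline": med_b,
                "median_post": med_p,
                "log2_fold_change": lfc,
                "pvalue": p,
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def mimicry_panel(
    adata: AnnData,
    n_hvgs: int = 3000,
    conditions: tuple[str, str] = ("baseline", "postNI"),
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """End-to-end panel: HVG selection, per-condition panels, contrast.

    Returns the contrast table and the per-condition per-cell panels.
    """
    hvgs = select_hvgs(adata, n=n_hvgs)
    sub = adata[:, hvgs]
    panels: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        ref = myeloid_reference(sub, cond)
        mask = (
            (sub.obs["compartment"] == "tumor") & (sub.obs["condition"] == cond)
        ).to_numpy()
        if not mask.any():
            raise ValueError(f"no tumor cells in condition {cond!r}")
        panels[cond] = compute_panel(sub.X[mask], ref)
    contrast = contrast_conditions(panels[conditions[0]], panels[conditions[1]])
    return contrast, panels
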