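"""Developmental epigenetic signature classification and the study's
statistical comparisons.

The background level ``b`` is the mean anti-GFP (mock IP) occupancy over
all gene TSS windows and stages.  Genes whose 8-dimensional (2 marks x 4
stages) TSS occupancy row has Euclidean norm below ``sqrt(8) * b`` carry
neither mark ("no-mark" genes).  The rod-photoreceptor signature is a
de novo H3K4me2 gain between PN7 and PN15 with no H3K27me3 at any stage;
non-rod retinal genes instead keep high H3K27me3 with lower H3K4me2;
ubiquitous genes hold high H3K4me2 at every stage.  Group comparisons use
the classic two-sample pooled-variance (equal variances assumed) t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import t as t_dist

from .occupancy import MARKS, STAGES

NO_MARK = "NO_MARK"
ROD_SPECIFIC = "ROD_SPECIFIC"
NONROD_RETINAL = "NONROD_RETINAL"
UBIQUITOUS = "UBIQUITOUS"
OTHER = "OTHER"

SIGNATURE_LABELS = (NO_MARK, ROD_SPECIFIC, NONROD_RETINAL, UBIQUITOUS, OTHER)


@dataclass(frozen=True)
class SignatureThresholds:
    """Multiples of the background ``b`` used by the deterministic rules.

    ``c_rep``: a mark below ``c_rep * b`` at a stage counts as absent.
    ``c_act``: a mark at or above ``c_act * b`` counts as clearly present.
    ``f_min``: minimum PN15/E17.5 H3K4me2 gain for the de novo rod rule.
    """

    c_rep: float = 1.5
    c_act: float = 3.0
    f_min: float = 3.0


def gfp_background(values) -> float:
    """Arithmetic mean of the control occupancies (all genes, all stages)."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("no control occupancy values")
    return float(arr.mean())


def no_mark_cutoff(b: float, dims: int = 8) -> float:
    """Euclidean-norm cutoff: a flat background row in ``dims`` dimensions."""
    if b < 0:
        raise ValueError("background must be non-negative")
    return math.sqrt(dims) * b


def classify_no_mark(matrix: pd.DataFrame, cutoff: float) -> pd.Series:
    """True where the row's Euclidean norm is strictly below the cutoff."""
    norms = np.linalg.norm(matrix.to_numpy(dtype=float), axis=1)
    return pd.Series(norms < cutoff, index=matrix.index, name="no_mark")


def _mark_block(matrix: pd.DataFrame, mark: str) -> np.ndarray:
    cols = [f"{mark}_{stage}" for stage in STAGES]
    return matrix[cols].to_numpy(dtype=float)


def rod_signature_screen(
    tss_matrix: pd.DataFrame,
    b: float,
    thresholds: SignatureThresholds | None = None,
    body_matrix: pd.DataFrame | None = None,
    use_body: bool = False,
) -> pd.Series:
    """Flag genes carrying the rod-photoreceptor de novo H3K4me2 signature.

    Conditions (TSS window): (i) H3K27me3 below ``c_rep * b`` at all four
    stages; (ii) H3K4me2 below ``c_rep * b`` at E17.5 and PN1; (iii)
    H3K4me2 at PN15 at least ``c_act * b`` and at least ``f_min`` times
    max(E17.5 value, b).  With ``use_body`` the gain conditions (ii)-(iii)
    must also hold for gene-body H3K4me2.
    """
    thr = thresholds or SignatureThresholds()
    k4 = _mark_block(tss_matrix, "H3K4me2")
    k27 = _mark_block(tss_matrix, "H3K27me3")
    flags = _rod_conditions(k4, k27, b, thr)
    if use_body:
        if body_matrix is None:
            raise ValueError("use_body requires a gene-body matrix")
        k4b = _mark_block(body_matrix.loc[tss_matrix.index], "H3K4me2")
        early_low = (k4b[:, :2] < thr.c_rep * b).all(axis=1)
        late_high = (k4b[:, 3] >= thr.c_act * b) & (
            k4b[:, 3] >= thr.f_min * np.maximum(k4b[:, 0], b)
        )
        flags &= early_low & late_high
    return pd.Series(flags, index=tss_matrix.index, name="rod_specific")


def _rod_conditions(k4: np.ndarray, k27: np.ndarray, b: float, thr: SignatureThresholds) -> np.ndarray:
    k27_absent = (k27 < thr.c_rep * b).all(axis=1)
    k4_early_low = (k4[:, :2] < thr.c_rep * b).all(axis=1)
    k4_late_high = (k4[:, 3] >= thr.c_act * b) & (
        k4[:, 3] >= thr.f_min * np.maximum(k4[:, 0], b)
    )
    return k27_absent & k4_early_low & k4_late_high


def classify_signatures(
    tss_matrix: pd.DataFrame,
    b: float,
    thresholds: SignatureThresholds | None = None,
    body_matrix: pd.DataFrame | None = None,
    use_body: bool = False,
) -> pd.DataFrame:
    """Assign one signature label per transcript with per-rule evidence.

    Precedence: NO_MARK > ROD_SPECIFIC > NONROD_RETINAL > UBIQUITOUS >
    OTHER.  NONROD_RETINAL: H3K27me3 clearly present (>= c_act*b) at every
    stage with H3K4me2 below c_act*b throughout; UBIQUITOUS: H3K4me2
    clearly present at every stage with H3K27me3 absent (< c_rep*b).
    """
    thr = thresholds or SignatureThresholds()
    cutoff = no_mark_cutoff(b, tss_matrix.shape[1])
    no_mark = classify_no_mark(tss_matrix, cutoff).to_numpy()
    rod = rod_signature_screen(tss_matrix, b, thr, body_matrix, use_body).to_numpy()
    k4 = _mark_block(tss_matrix, "H3K4me2")
    k27 = _mark_block(tss_matrix, "H3K27me3")
    nonrod = (k27 >= thr.c_act * b).all(axis=1) & (k4 < thr.c_act * b).all(axis=1)
    ubiq = (k4 >= thr.c_act * b).all(axis=1) & (k27 < thr.c_rep * b).all(axis=1)
    label = np.select(
        [no_mark, rod, nonrod, ubiq],
        [NO_MARK, ROD_SPECIFIC, NONROD_RETINAL, UBIQUITOUS],
        default=OTHER,
    )
    return pd.DataFrame(
        {
            "label": label,
            "no_mark": no_mark,
            "rod_specific": rod,
            "nonrod_retinal": nonrod,
            "ubiquitous": ubiq,
        },
        index=tss_matrix.index,
    )


@dataclass
class ClusterResult:
    """Average-linkage agglomerative tree plus an optional flat cut."""

    linkage: np.ndarray
    labels: pd.Series | None = None


def _uncentered_correlation_distances(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - uncentered-correlation distances.

    Zero-norm rows get distance 1 to every other row (similarity 0), the
    convention of the original clustering software the distance comes from.
    """
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    sim = (x @ x.T) / np.outer(safe, safe)
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
    k: int | None = None,
    height: float | None = None,
) -> ClusterResult:
    """Average-linkage hierarchical clustering of occupancy rows.

    ``metric`` is ``euclidean`` or ``uncentered_correlation`` (the default
    similarity of the clustering software used in this field).  ``k`` or
    ``height`` requests a flat cut of the tree.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    x = matrix.to_numpy(dtype=float)
    if metric == "euclidean":
        dists = pdist(x, metric="euclidean")
    elif metric == "uncentered_correlation":
        dists = _uncentered_correlation_distances(x)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    z = linkage(dists, method=method)
    labels = None
    if k is not None:
        labels = pd.Series(fcluster(z, t=k, criterion="maxclust"), index=matrix.index)
    elif height is not None:
        labels = pd.Series(fcluster(z, t=height, criterion="distance"), index=matrix.index)
    return ClusterResult(linkage=z, labels=labels)


@dataclass(frozen=True)
class ComparisonResult:
    mean_x: float
    mean_y: float
    t: float
    df: int
    p: float
    stars: str


def significance_stars(p: float) -> str:
    """(*) 0.05>P>0.01, (**) 0.01>P>0.001, (***) P<0.001, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pooled_t_test(x, y) -> ComparisonResult:
    """Two-sample t-test assuming equal variances (closed form).

    t = (mean_x - mean_y) / (s_p * sqrt(1/n + 1/m)) with the pooled
    variance s_p^2 = ((n-1)s_x^2 + (m-1)s_y^2) / (n+m-2); the two-sided p
    comes from the t distribution with n+m-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise ValueError("each group needs at least two values")
    df = n + m - 2
    sp2 = ((n - 1) * x.var(ddof=1) + (m - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / n + 1.0 / m))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return ComparisonResult(float(x.mean()), float(y.mean()), float(t), df, p, significance_stars(p))


def compare_promoter_body(
    promoter_matrix: pd.DataFrame,
    body_matrix: pd.DataFrame,
    gene_set=None,
) -> pd.DataFrame:
    """Per (mark, stage): pooled t-test of promoter vs gene-body occupancy.

    Rows of the result are the matrix columns; values are the group means,
    t, df, two-sided p and the star annotation.
    """
    if gene_set is not None:
        gene_set = list(gene_set)
        if not gene_set:
            raise ValueError("empty gene set")
        promoter_matrix = promoter_matrix.loc[gene_set]
        body_matrix = body_matrix.loc[gene_set]
    if promoter_matrix.shape[0] < 2:
        raise ValueError("need at least two genes to compare")
    rows = {}
    for col in promoter_matrix.columns:
        res = pooled_t_test(promoter_matrix[col], body_matrix[col])
        rows[col] = {
            "mean_promoter": res.mean_x,
            "mean_body": res.mean_y,
            "t": res.t,
            "df": res.df,
            "p": res.p,
            "stars": res.stars,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def composition_scale_factor(
    reference: pd.DataFrame | pd.Series,
    target: pd.DataFrame | pd.Series,
) -> float:
    """Between-library composition factor s with reference ~ s * target.

    Depth normalization to a fixed read total makes per-gene occupancies
    sensitive to library composition: when one library loses a large signal
    compartment, occupancies of *unchanged* genes inflate.  The factor is
    the exponentiated mean of the shortest half of the per-gene log-ratio
    distribution (the half-sample mode), which locates the unchanged
    majority of genes even when the truly changed genes all sit on one
    side — where a symmetric trimmed mean or median stays biased.
    Multiplying the target by ``s`` aligns the unchanged majority.
    """
    ref = np.asarray(reference, dtype=float).ravel()
    tgt = np.asarray(target, dtype=float).ravel()
    ok = (ref > 0) & (tgt > 0)
    if not ok.any():
        raise ValueError("no genes with positive occupancy in both libraries")
    logr = np.sort(np.log(ref[ok] / tgt[ok]))
    n = len(logr)
    h = (n + 1) // 2
    if h == n:
        return float(np.exp(logr.mean()))
    widths = logr[h:] - logr[: n - h]
    i = int(np.argmin(widths))
    return float(np.exp(logr[i : i + h + 1].mean()))


@dataclass(frozen=True)
class GenotypeComparison:
    fold: float
    scale: float
    infinite_fold: bool
    test: ComparisonResult


def compare_genotypes(
    wt_matrix: pd.DataFrame,
    mut_matrix: pd.DataFrame,
    gene_set,
    column: str,
    normalize: bool = True,
) -> GenotypeComparison:
    """Mean wt/mutant occupancy fold plus a pooled t-test on a gene set.

    ``column`` selects the (mark, stage) to compare.  With ``normalize``
    (default) the mutant occupancies are rescaled by the composition factor
    estimated over *all* shared genes before the fold and test are
    computed; set ``normalize=False`` for the raw comparison.  A zero
    mutant mean is reported as an infinite fold and flagged.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    shared = wt_matrix.index.intersection(mut_matrix.index)
    wt_all = wt_matrix.loc[shared, column]
    mut_all = mut_matrix.loc[shared, column]
    scale = composition_scale_factor(wt_all, mut_all) if normalize else 1.0
    wt = wt_matrix.loc[gene_set, column].to_numpy(dtype=float)
    mut = mut_matrix.loc[gene_set, column].to_numpy(dtype=float) * scale
    mut_mean = float(mut.mean())
    infinite = mut_mean == 0.0
    fold = math.inf if infinite else float(wt.mean()) / mut_mean
    if np.array_equal(wt, mut):
        test = ComparisonResult(float(wt.mean()), mut_mean, 0.0, 2 * len(wt) - 2, 1.0, "ns")
    else:
        test = pooled_t_test(wt, mut)
    return GenotypeComparison(fold=fold, scale=scale, infinite_fold=infinite, test=test)
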