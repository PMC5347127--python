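"""PCA (centred or non-centred), preprocessing, and discriminative-PC selection.

PCA is computed by singular value decomposition of the (optionally
column-centred) data matrix, so that loadings are exact right singular
vectors with unit Euclidean norm.  Group discrimination along a component
is scored with a two-sided Mann-Whitney U test on the PC scores (Kruskal-
Wallis when more than two groups are labelled).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import OmicMatrix, SampleLabels, ValidationError

CENTERINGS = ("centered", "noncentered")


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(matrix: OmicMatrix, method: str = "none") -> OmicMatrix:
    """Optional dataset normalization applied before PCA and correlations.

    ``zscore_features`` standardizes each feature to mean 0, sd 1 (sample
    sd, n-1 denominator); constant features are set to all-zero with a
    warning.  ``log_shift`` applies log(1 + x) and requires min(x) > -1.
    """
    if method == "none":
        out = matrix.values.copy()
    elif method == "zscore_features":
        mu = matrix.values.mean(axis=0)
        sd = matrix.values.std(axis=0, ddof=1)
        const = sd == 0
        if const.any():
            names = [matrix.feature_names[j] for j in np.flatnonzero(const)[:5]]
            warnings.warn(f"constant features set to zero under zscore: {names}")
        sd_safe = np.where(const, 1.0, sd)
        out = (matrix.values - mu) / sd_safe
        out[:, const] = 0.0
    elif method == "log_shift":
        if np.nanmin(matrix.values) <= -1:
            raise ValidationError("log_shift requires every entry > -1")
        out = np.log1p(matrix.values)
    else:
        raise ValidationError(f"unknown preprocessing method {method!r}")
    result = OmicMatrix(out, matrix.sample_ids, matrix.feature_names)
    result.require_finite()
    return result


def impute_mode(matrix: OmicMatrix, missing_code: int = 3) -> OmicMatrix:
    """Replace a designated missing code by the per-feature mode.

    Intended for integer-recoded genotype matrices (0 homozygous wild-type,
    1 heterozygous, 2 homozygous variant, 3 missing).  Ties between equally
    frequent codes are broken toward the smallest code.
    """
    vals = matrix.values
    if not np.all(np.isfinite(vals)) or not np.all(vals == np.round(vals)) or vals.min() < 0:
        raise ValidationError("impute_mode expects non-negative integer codes")
    out = vals.copy()
    for j in range(matrix.n_features):
        col = out[:, j]
        missing = col == missing_code
        if not missing.any():
            continue
        observed = col[~missing].astype(int)
        if observed.size == 0:
            raise ValidationError(
                f"feature {matrix.feature_names[j]!r} is entirely missing"
            )
        counts = np.bincount(observed)
        col[missing] = int(np.argmax(counts))  # argmax -> smallest code on ties
    return OmicMatrix(out, matrix.sample_ids, matrix.feature_names)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of one PCA fit.

    Loadings columns are unit-norm right singular vectors; ``scores``
    equals the (optionally centred) data times ``loadings``.  For the
    non-centred variant "explained variance" reads as fraction of total
    sum of squares.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    centering: str
    singular_values: np.ndarray
    valid: np.ndarray  # False for components beyond the numerical rank
    sample_ids: list[str]
    feature_names: list[str]

    def loading_vector(self, pc_index: int) -> np.ndarray:
        """Loadings of one component; ``pc_index`` is 1-based."""
        if not 1 <= pc_index <= self.loadings.shape[1]:
            raise ValidationError(f"pc_index {pc_index} out of range")
        return self.loadings[:, pc_index - 1]


def fit_pca(matrix: OmicMatrix, centering: str = "centered", k: int | None = None) -> PCAResult:
    """SVD-based PCA with a deterministic loading-sign convention.

    Each loading column is flipped so that its entry of largest magnitude
    is positive (eigenvector signs are otherwise arbitrary).
    """
    if centering not in CENTERINGS:
        raise ValidationError(f"centering must be one of {CENTERINGS}")
    matrix.require_finite()
    X = matrix.values
    Xw = X - X.mean(axis=0) if centering == "centered" else X
    kmax = min(matrix.n_samples, matrix.n_features)
    if k is None:
        k = kmax
    if not 1 <= k <= kmax:
        raise ValidationError(f"k must be in [1, {kmax}]")
    U, s, Vt = np.linalg.svd(Xw, full_matrices=False)
    V = Vt.T
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] *= -1.0
    total = float((s ** 2).sum())
    evf = (s ** 2) / total if total > 0 else np.zeros_like(s)
    tol = s[0] * max(Xw.shape) * np.finfo(float).eps if s.size else 0.0
    valid = s > tol
    scores = Xw @ V
    return PCAResult(
        scores=scores[:, :k],
        loadings=V[:, :k],
        explained_variance_fraction=evf[:k],
        centering=centering,
        singular_values=s[:k],
        valid=valid[:k],
        sample_ids=list(matrix.sample_ids),
        feature_names=list(matrix.feature_names),
    )


# ---------------------------------------------------------------------------
# discrimination tests

def mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact when both groups have <= 8 samples
    and there are no ties, normal approximation with tie correction
    otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 2:
        raise ValidationError("each group needs at least 2 samples")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 1.0  # all observations identical: the test is degenerate
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


@dataclass
class DiscriminationResult:
    pc_index: int
    centering: str
    p_value: float
    direction: dict[str, str]  # group -> high / low / intermediate


def score_discrimination(
    pca: PCAResult, labels: SampleLabels, pc_index: int
) -> DiscriminationResult:
    """Rank-test the separation of labelled groups along one component."""
    scores = pca.scores[:, pc_index - 1] if 1 <= pc_index <= pca.scores.shape[1] else None
    if scores is None:
        raise ValidationError(f"pc_index {pc_index} out of range")
    idx = labels.indices(pca.sample_ids)
    groups = [g for g in labels.group_order if len(idx[g])]
    if len(groups) < 2:
        raise ValidationError("need at least 2 labelled groups")
    per_group = [scores[idx[g]] for g in groups]
    for g, vals in zip(groups, per_group):
        if vals.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
    if len(groups) == 2:
        p = mann_whitney_p(per_group[0], per_group[1])
    else:
        if np.ptp(scores) == 0:
            p = 1.0
        else:
            p = float(stats.kruskal(*per_group).pvalue)
    medians = {g: float(np.median(v)) for g, v in zip(groups, per_group)}
    hi = max(medians, key=medians.get)
    lo = min(medians, key=medians.get)
    direction = {
        g: "high" if g == hi else ("low" if g == lo else "intermediate")
        for g in groups
    }
    return DiscriminationResult(pc_index, pca.centering, p, direction)


@dataclass
class PCSelection:
    """Outcome of scanning (centering, PC) candidates for group separation.

    ``significant`` applies a Bonferroni correction for the number of
    candidates scanned, so that a pure-noise dataset rarely yields a
    spurious "discriminative" component.
    """

    best: DiscriminationResult
    significant: bool
    alpha: float
    n_tests: int
    all_results: list[DiscriminationResult]


def select_discriminative_pc(
    matrix: OmicMatrix,
    labels: SampleLabels,
    max_pc: int = 2,
    centering: str = "auto",
    alpha: float = 0.05,
) -> PCSelection:
    """Pick the (centering, PC) pair whose scores best separate the groups.

    Candidates are scanned centred-first, then by ascending PC index, and
    the best strictly-smaller p-value wins, so ties prefer centred PCA and
    the lower component.
    """
    labels.validate_against(matrix)
    centerings = list(CENTERINGS) if centering == "auto" else [centering]
    kmax = min(matrix.n_samples, matrix.n_features)
    k = min(max_pc, kmax)
    results: list[DiscriminationResult] = []
    for cent in centerings:
        pca = fit_pca(matrix, cent, k=k)
        for pc in range(1, k + 1):
            results.append(score_discrimination(pca, labels, pc))
    best = results[0]
    for r in results[1:]:
        if r.p_value < best.p_value:
            best = r
    m = len(results)
    significant = best.p_value <= alpha / m
    return PCSelection(best, significant, alpha, m, results)
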