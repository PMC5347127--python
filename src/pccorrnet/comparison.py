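"""Baseline networks the PC-corr network is compared against.

The *P-value network* keeps only features that differ significantly
between the two groups (two-sided Mann-Whitney per feature, Benjamini-
Hochberg adjusted p <= 0.05) and connects them by Pearson correlation.
The *P-value MI network* runs the same screen but scores pairs with the
context likelihood of relatedness (CLR) over a Gaussian mutual-information
estimate MI = -1/2 ln(1 - r^2).  Venn-style node/edge overlaps quantify
how the networks differ.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    EDGE_COLUMNS,
    NODE_COLUMNS,
    NetworkTables,
    OmicMatrix,
    SampleLabels,
    ValidationError,
)
from .network import _hex_gradient, pearson_matrix
from .pca import mann_whitney_p

R_CAP = 0.999999  # |r| = 1 is capped here before the Gaussian MI log


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p-values must be a non-empty 1-d vector")
    if np.isnan(p).any():
        raise ValidationError("NaN p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return np.clip(multipletests(p, method="fdr_bh")[1], 0.0, 1.0)


@dataclass
class FeatureScreenResult:
    """Per-feature univariate screen between the two labelled groups."""

    table: pd.DataFrame  # feature, p_raw, p_adjusted, significant, median_diff
    alpha: float
    group_order: list[str]

    @property
    def significant_features(self) -> list[str]:
        t = self.table
        return list(t.loc[t["significant"], "feature"])


def feature_screen(
    matrix: OmicMatrix, labels: SampleLabels, alpha: float = 0.05
) -> FeatureScreenResult:
    """Mann-Whitney + BH screen of every feature; two groups required.

    median_diff is median(first group) - median(second group), the sign
    convention used for node colouring in the baseline networks.
    """
    labels.validate_against(matrix)
    if labels.n_groups != 2:
        raise ValidationError("feature_screen requires exactly 2 groups")
    idx = labels.indices(matrix.sample_ids)
    g1, g2 = labels.group_order
    i1, i2 = idx[g1], idx[g2]
    raw = np.empty(matrix.n_features)
    diff = np.empty(matrix.n_features)
    for j in range(matrix.n_features):
        col = matrix.values[:, j]
        raw[j] = mann_whitney_p(col[i1], col[i2])
        diff[j] = float(np.median(col[i1]) - np.median(col[i2]))
    adj = bh_adjust(raw)
    table = pd.DataFrame(
        {
            "feature": matrix.feature_names,
            "p_raw": raw,
            "p_adjusted": adj,
            "significant": adj <= alpha,
            "median_diff": diff,
        }
    )
    return FeatureScreenResult(table, alpha, list(labels.group_order))


# ---------------------------------------------------------------------------
# network construction helpers

def _screen_network(
    assoc: np.ndarray,
    weights_for_table: np.ndarray,
    features: list[str],
    screen: FeatureScreenResult,
    cutoff: float,
    method: str,
) -> NetworkTables:
    """Threshold |assoc| >= cutoff among screened features; node colour is
    the (rescaled) group median difference."""
    if not 0 < cutoff <= 1:
        raise ValidationError("cutoff must lie in (0, 1]")
    diffs = dict(zip(screen.table["feature"], screen.table["median_diff"]))
    rows = []
    n = len(features)
    for i, j in combinations(range(n), 2):
        if abs(assoc[i, j]) >= cutoff:
            w = float(weights_for_table[i, j])
            a, b = sorted((features[i], features[j]))
            rows.append((a, b, w, "positive" if w > 0 else "negative"))
    meta = {"method": method, "cutoff": cutoff,
            "node_value": "median_diff rescaled by max |median_diff|",
            "median_diff_sign": f"{screen.group_order[0]} minus {screen.group_order[1]}"}
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    if edges.empty:
        warnings.warn(f"{method} network is empty after thresholding")
        return NetworkTables.empty(metadata=meta)
    degree: dict[str, int] = {}
    for a, b in zip(edges["source"], edges["target"]):
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    max_diff = max(abs(diffs[f]) for f in degree) or 1.0
    node_rows = []
    for f in sorted(degree):
        d = diffs[f] / max_diff
        group = screen.group_order[0] if diffs[f] >= 0 else screen.group_order[1]
        base = "#FF0000" if diffs[f] >= 0 else "#000000"
        node_rows.append((f, float(d), group, _hex_gradient(base, abs(d)), degree[f]))
    nodes = pd.DataFrame(node_rows, columns=NODE_COLUMNS)
    nodes["median_diff"] = [diffs[f] for f in nodes["feature"]]
    return NetworkTables(edges=edges, nodes=nodes, metadata=meta)


def build_pvalue_network(
    matrix: OmicMatrix,
    labels: SampleLabels,
    cutoff: float,
    screen: FeatureScreenResult | None = None,
) -> NetworkTables:
    """Pearson network restricted to BH-significant features.

    With fewer than two significant features the network does not exist;
    an empty NetworkTables with ``exists=False`` is returned rather than
    raising, mirroring datasets where no feature survives the screen.
    """
    screen = screen if screen is not None else feature_screen(matrix, labels)
    sig = screen.significant_features
    if len(sig) < 2:
        return NetworkTables.empty(
            metadata={"method": "pvalue", "cutoff": cutoff,
                      "reason": f"only {len(sig)} significant feature(s)"},
            exists=False,
        )
    sub = matrix.subset_features(sig)
    c = pearson_matrix(sub)
    return _screen_network(c, c, sig, screen, cutoff, "pvalue")


def gaussian_mi(r):
    """Mutual information of a bivariate normal: -1/2 ln(1 - r^2).

    |r| = 1 would be infinite; it is capped at |r| = 0.999999 with a
    warning.  |r| > 1 is an error.
    """
    r = np.asarray(r, dtype=float)
    if (np.abs(r) > 1).any():
        raise ValidationError("|r| > 1")
    if (np.abs(r) == 1).any():
        warnings.warn("|r| = 1 capped before Gaussian MI")
        r = np.clip(r, -R_CAP, R_CAP)
    out = -0.5 * np.log1p(-(r ** 2))
    return float(out) if out.ndim == 0 else out


def clr_scores(mi: np.ndarray) -> np.ndarray:
    """Context likelihood of relatedness over a symmetric MI matrix.

    For each pair, z_i = max(0, (mi_ij - mean_i) / sd_i) with the row
    statistics taken over off-diagonal entries (sd_i = 0 gives z_i = 0),
    and CLR_ij = sqrt(z_i^2 + z_j^2).
    """
    mi = np.asarray(mi, dtype=float)
    n = mi.shape[0]
    if mi.shape != (n, n) or not np.allclose(mi, mi.T, atol=1e-10):
        raise ValidationError("MI matrix must be square and symmetric")
    off = ~np.eye(n, dtype=bool)
    mean = np.array([mi[i, off[i]].mean() for i in range(n)])
    sd = np.array([mi[i, off[i]].std() for i in range(n)])
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (mi - mean[:, None]) / sd_safe[:, None]
    z[sd == 0, :] = 0.0
    z = np.maximum(z, 0.0)
    clr = np.sqrt(z ** 2 + z.T ** 2)
    np.fill_diagonal(clr, 0.0)
    return clr


def build_pvalue_mi_network(
    matrix: OmicMatrix,
    labels: SampleLabels,
    cutoff: float,
    screen: FeatureScreenResult | None = None,
) -> NetworkTables:
    """CLR mutual-information network restricted to BH-significant features.

    CLR scores are min-max rescaled to [0, 1] before the cut-off so the
    same threshold scale as the Pearson-based networks applies.
    """
    screen = screen if screen is not None else feature_screen(matrix, labels)
    sig = screen.significant_features
    if len(sig) < 2:
        return NetworkTables.empty(
            metadata={"method": "pvalue_mi", "cutoff": cutoff,
                      "reason": f"only {len(sig)} significant feature(s)"},
            exists=False,
        )
    sub = matrix.subset_features(sig)
    c = pearson_matrix(sub)
    mi = gaussian_mi(np.where(np.eye(len(sig), dtype=bool), 0.0, c))
    np.fill_diagonal(mi, 0.0)
    clr = clr_scores(mi)
    off = ~np.eye(len(sig), dtype=bool)
    lo, hi = clr[off].min(), clr[off].max()
    scaled = np.zeros_like(clr) if hi == lo else (clr - lo) / (hi - lo)
    np.fill_diagonal(scaled, 0.0)
    # edge table carries the signed correlation so edge colours stay meaningful
    signed = np.sign(c) * scaled
    return _screen_network(scaled, signed, sig, screen, cutoff, "pvalue_mi")


def match_node_count_cutoff(
    weights: np.ndarray, target_n: int, grid=None
) -> float:
    """Cut-off at which the surviving node count best matches a target.

    Sweeps a cut-off grid (default 0.01..1.00 in 0.01 steps), keeps the
    cut-offs whose node count is >= target, and returns the one whose
    count is closest to the target, ties going to the higher cut-off.
    Used to cut big baseline networks at approximately the PC-corr
    network's size.
    """
    W = np.abs(np.asarray(weights, dtype=float))
    np.fill_diagonal(W, 0.0)
    if target_n > W.shape[0]:
        raise ValidationError("target node count exceeds feature count")
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0001, 0.01), 2)
    best: tuple[int, float] | None = None
    for cut in grid:
        count = int((W.max(axis=0) >= cut).sum())
        if count >= target_n:
            key = (count - target_n, -cut)
            if best is None or key < (best[0] - target_n, -best[1]):
                best = (count, float(cut))
    if best is None:
        raise ValidationError("target node count not reachable on the grid")
    return best[1]


# ---------------------------------------------------------------------------
# Venn comparisons

@dataclass
class VennCounts:
    nodes_only_a: int
    nodes_shared: int
    nodes_only_b: int
    edges_only_a: int
    edges_shared: int
    edges_only_b: int


def venn_compare(net_a: NetworkTables, net_b: NetworkTables) -> VennCounts:
    """Node and unordered-edge overlap counts between two networks."""
    na, nb = net_a.node_set(), net_b.node_set()
    ea, eb = net_a.edge_set(), net_b.edge_set()
    return VennCounts(
        nodes_only_a=len(na - nb),
        nodes_shared=len(na & nb),
        nodes_only_b=len(nb - na),
        edges_only_a=len(ea - eb),
        edges_shared=len(ea & eb),
        edges_only_b=len(eb - ea),
    )


def venn_regions(named_sets: dict[str, set]) -> dict[str, int]:
    """Exact region counts of an n-way Venn diagram.

    Keys are '+'-joined sorted member names; the count is the number of
    elements belonging to exactly that subset of the input sets.
    """
    names = list(named_sets)
    universe = set().union(*named_sets.values()) if named_sets else set()
    regions: dict[str, int] = {}
    for element in universe:
        members = tuple(sorted(n for n in names if element in named_sets[n]))
        key = "+".join(members)
        regions[key] = regions.get(key, 0) + 1
    return regions
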