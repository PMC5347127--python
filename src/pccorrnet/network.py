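"""The PC-corr core: loading normalization, min-operator edge fusion,
thresholding, and the frustration cut-off rules.

The edge between features i and j fuses the Pearson correlation c_ij with
the processed PC loadings v_i, v_j of the discriminative component:

    PC-corr_ij = sign(c_ij) * min(|c_ij|, |v_i|, |v_j|)

so an edge is strong only when the two features are simultaneously highly
correlated *and* highly discriminative (an AND gate).  Loadings are first
normalized with a sign-preserving lognormal-inspired transform,

    V*(i) = sign(V(i)) * log10(1 + |V(i)| / mean_j |V(j)|),

which tempers the skewness of raw PC loadings, then scaled by the maximum
absolute value so the processed loadings span [-1, 1] like correlations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import (
    EDGE_COLUMNS,
    NODE_COLUMNS,
    FrustrationError,
    NetworkTables,
    OmicMatrix,
    SampleLabels,
    ValidationError,
)

FRUSTRATION_DROP_LIMIT = 0.05  # drop policy refuses above this fraction
RAISE_STEP = 0.01


# ---------------------------------------------------------------------------
# loading processing

@dataclass
class NormalizedLoadings:
    """Raw (V), normalized (V*) and scaled (V^new) loadings of one PC."""

    v_raw: np.ndarray
    v_star: np.ndarray
    mean_abs: float
    v_new: np.ndarray | None = None
    feature_names: list[str] | None = None


def normalize_loadings(v_raw, feature_names=None) -> NormalizedLoadings:
    """Sign-preserving lognormal-inspired normalization of raw loadings."""
    v = np.asarray(v_raw, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValidationError("loadings must be a non-empty 1-d vector")
    mean_abs = float(np.mean(np.abs(v)))
    if mean_abs == 0:
        raise ValidationError("all-zero loading vector (mean of |V| is 0)")
    v_star = np.sign(v) * np.log10(1.0 + np.abs(v) / mean_abs)
    return NormalizedLoadings(
        v_raw=v, v_star=v_star, mean_abs=mean_abs,
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def scale_loadings(nl: NormalizedLoadings) -> NormalizedLoadings:
    """Scale V* by its maximum absolute value so V^new spans [-1, 1]."""
    m = float(np.max(np.abs(nl.v_star)))
    if m == 0:
        raise ValidationError("cannot scale an all-zero V*")
    return replace(nl, v_new=nl.v_star / m)


def process_loadings(v_raw, feature_names=None) -> NormalizedLoadings:
    """normalize_loadings followed by scale_loadings."""
    return scale_loadings(normalize_loadings(v_raw, feature_names))


# ---------------------------------------------------------------------------
# correlation and fusion

def pearson_matrix(matrix: OmicMatrix) -> np.ndarray:
    """Pairwise feature Pearson correlations; constant features get 0."""
    if matrix.n_samples < 3:
        raise ValidationError("need at least 3 samples for correlations")
    matrix.require_finite()
    X = matrix.values
    sd = X.std(axis=0)
    const = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(X, rowvar=False)
    c = np.atleast_2d(c)
    if const.any():
        names = [matrix.feature_names[j] for j in np.flatnonzero(const)[:5]]
        warnings.warn(f"constant features given zero correlation: {names}")
        c[const, :] = 0.0
        c[:, const] = 0.0
    c = np.clip(np.nan_to_num(c, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return (c + c.T) / 2.0


def pccorr_edge(c_ij, v_i, v_j):
    """sign(c) * min(|c|, |v_i|, |v_j|) — scalar or elementwise on arrays."""
    c_ij = np.asarray(c_ij, dtype=float)
    mags = np.minimum(np.minimum(np.abs(c_ij), np.abs(v_i)), np.abs(v_j))
    out = np.sign(c_ij) * mags
    return float(out) if out.ndim == 0 else out


@dataclass
class PCCorrMatrix:
    """Symmetric signed matrix of PC-corr edge values plus provenance."""

    weights: np.ndarray
    corr: np.ndarray | None
    v_new: np.ndarray | None
    feature_names: list[str]

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValidationError("weights must be square")
        if len(self.feature_names) != W.shape[0]:
            raise ValidationError("feature names do not match weight matrix")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValidationError("weights must be symmetric")
        self.weights = W


def pccorr_from_corr(corr: np.ndarray, v_new: np.ndarray, feature_names) -> PCCorrMatrix:
    """Fuse a precomputed correlation matrix with processed loadings."""
    v = np.asarray(v_new, dtype=float)
    if corr.shape[0] != v.size:
        raise ValidationError("loading length does not match correlation matrix")
    W = pccorr_edge(corr, v[:, None], v[None, :])
    np.fill_diagonal(W, 0.0)
    return PCCorrMatrix(W, corr, v, list(feature_names))


def build_pccorr_matrix(matrix: OmicMatrix, nl: NormalizedLoadings) -> PCCorrMatrix:
    if nl.v_new is None:
        raise ValidationError("loadings must be scaled (v_new) first")
    if nl.v_new.size != matrix.n_features:
        raise ValidationError("loading length does not match matrix features")
    return pccorr_from_corr(pearson_matrix(matrix), nl.v_new, matrix.feature_names)


# ---------------------------------------------------------------------------
# thresholding and node attribution

def _hex_gradient(base: str, t: float) -> str:
    """Linear blend from white (t=0) to ``base`` colour (t=1)."""
    t = float(np.clip(t, 0.0, 1.0))
    rgb = tuple(int(base[i:i + 2], 16) for i in (1, 3, 5))
    mixed = tuple(round(255 + (c - 255) * t) for c in rgb)
    return "#{:02X}{:02X}{:02X}".format(*mixed)


def _node_attribution(
    feature: str,
    v: float,
    data: OmicMatrix | None,
    labels: SampleLabels | None,
) -> tuple[str, str]:
    """(group, color) for one node.

    With labels, a node belongs to the group whose samples have the higher
    median of that feature ("red" = first group in group_order, drawn on a
    red-to-white gradient; the other group black-to-white).  Without
    labels, the loading sign stands in for the group.
    """
    t = abs(v)
    if data is not None and labels is not None:
        idx = labels.indices(data.sample_ids)
        col = data.values[:, data.feature_names.index(feature)]
        medians = {g: float(np.median(col[i])) for g, i in idx.items() if len(i)}
        group = max(labels.group_order, key=lambda g: medians.get(g, -np.inf))
        base = "#FF0000" if group == labels.group_order[0] else "#000000"
        return group, _hex_gradient(base, t)
    group = "positive" if v >= 0 else "negative"
    base = "#FF0000" if v >= 0 else "#000000"
    return group, _hex_gradient(base, t)


def _tables_from_mask(
    pcc: PCCorrMatrix,
    mask: np.ndarray,
    data: OmicMatrix | None,
    labels: SampleLabels | None,
    metadata: dict,
) -> NetworkTables:
    names = pcc.feature_names
    W = pcc.weights
    iu, ju = np.triu_indices(len(names), k=1)
    keep = mask[iu, ju]
    rows = []
    for i, j in zip(iu[keep], ju[keep]):
        w = float(W[i, j])
        a, b = sorted((names[i], names[j]))
        rows.append((a, b, w, "positive" if w > 0 else "negative"))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    if edges.empty:
        warnings.warn("network is empty after thresholding")
        return NetworkTables.empty(metadata=metadata)
    degree: dict[str, int] = {}
    for a, b in zip(edges["source"], edges["target"]):
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    vmap = dict(zip(names, pcc.v_new if pcc.v_new is not None else np.zeros(len(names))))
    node_rows = []
    for f in sorted(degree):
        v = float(vmap[f])
        group, color = _node_attribution(f, v, data, labels)
        node_rows.append((f, v, group, color, degree[f]))
    nodes = pd.DataFrame(node_rows, columns=NODE_COLUMNS)
    return NetworkTables(edges=edges, nodes=nodes, metadata=metadata)


def threshold_network(
    pcc: PCCorrMatrix,
    cutoff: float,
    data: OmicMatrix | None = None,
    labels: SampleLabels | None = None,
    metadata: dict | None = None,
) -> NetworkTables:
    """Keep edges with |weight| >= cutoff and drop the resulting singletons."""
    if not 0 < cutoff <= 1:
        raise ValidationError("cutoff must lie in (0, 1]")
    mask = np.abs(pcc.weights) >= cutoff
    np.fill_diagonal(mask, False)
    meta = {"method": "pccorr", "cutoff": cutoff}
    meta.update(metadata or {})
    return _tables_from_mask(pcc, mask, data, labels, meta)


# ---------------------------------------------------------------------------
# frustration

@dataclass
class FrustrationResult:
    fraction: float
    frustrated: list[tuple[str, str]]
    n_edges: int
    note: str = ""


def compute_frustration(net: NetworkTables) -> FrustrationResult:
    """Edges whose sign contradicts the signs of their endpoint loadings.

    A positive edge should join same-sign nodes and a negative edge
    opposite-sign nodes; any other combination is frustrated.
    """
    if net.n_edges == 0:
        return FrustrationResult(0.0, [], 0, note="empty network: fraction 0 by convention")
    sign = dict(zip(net.nodes["feature"], np.sign(net.nodes["loading"])))
    frustrated = []
    for s, t, w in zip(net.edges["source"], net.edges["target"], net.edges["weight"]):
        same = sign[s] * sign[t] > 0
        if (w > 0 and not same) or (w < 0 and same):
            frustrated.append(tuple(sorted((s, t))))
    return FrustrationResult(len(frustrated) / net.n_edges, frustrated, net.n_edges)


def resolve_frustration(
    pcc: PCCorrMatrix,
    cutoff: float,
    policy: str = "report",
    data: OmicMatrix | None = None,
    labels: SampleLabels | None = None,
) -> tuple[NetworkTables, dict]:
    """Apply one of the frustration cut-off rules.

    report: annotate the network with its frustration fraction only.
    drop:   remove the frustrated edges if they are under 5% of all edges,
            otherwise refuse (raises FrustrationError).
    raise:  increase the cut-off in 0.01 steps until frustration is 0%
            (or the network empties) and return the final cut-off.
    """
    if policy not in ("report", "drop", "raise"):
        raise ValidationError(f"unknown frustration policy {policy!r}")
    net = threshold_network(pcc, cutoff, data, labels)
    fr = compute_frustration(net)
    log = {
        "policy": policy,
        "initial_cutoff": cutoff,
        "initial_fraction": fr.fraction,
        "initial_frustrated": fr.frustrated,
    }
    if policy == "report" or fr.fraction == 0.0:
        net.metadata["frustration_fraction"] = fr.fraction
        log["final_cutoff"] = cutoff
        return net, log
    if policy == "drop":
        if fr.fraction >= FRUSTRATION_DROP_LIMIT:
            raise FrustrationError(
                f"refusing to drop: frustration {fr.fraction:.1%} >= "
                f"{FRUSTRATION_DROP_LIMIT:.0%}; raise the cut-off instead"
            )
        bad = set(fr.frustrated)
        mask = np.abs(pcc.weights) >= cutoff
        np.fill_diagonal(mask, False)
        idx = {f: i for i, f in enumerate(pcc.feature_names)}
        for a, b in bad:
            mask[idx[a], idx[b]] = mask[idx[b], idx[a]] = False
        meta = {"method": "pccorr", "cutoff": cutoff, "frustration_fraction": 0.0,
                "dropped_edges": sorted(bad)}
        net = _tables_from_mask(pcc, mask, data, labels, meta)
        log.update(final_cutoff=cutoff, dropped=sorted(bad))
        return net, log
    # policy == "raise"
    c = cutoff
    while fr.fraction > 0 and c < 1.0:
        c = round(c + RAISE_STEP, 2)
        net = threshold_network(pcc, c, data, labels)
        fr = compute_frustration(net)
    net.metadata["frustration_fraction"] = fr.fraction
    net.metadata["cutoff"] = c
    log["final_cutoff"] = c
    log["final_fraction"] = fr.fraction
    return net, log
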