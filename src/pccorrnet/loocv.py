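"""Leave-one-out cross-validation of PC-corr network robustness.

PCA is repeated with each sample removed in turn (the discriminative
component and centering stay fixed from the full data).  Each iteration's
loading vector is sign-aligned to the full-data vector, a PC-corr matrix
is rebuilt on the reduced sample set, and the per-iteration matrices are
combined entrywise by average, median and minimum absolute value — the
last being the intersection network.  The retention of the original
network's edges in the min-abs network is the robustness score.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .comparison import venn_regions
from .datatypes import NetworkTables, OmicMatrix, SampleLabels, ValidationError
from .network import (
    PCCorrMatrix,
    pccorr_from_corr,
    pearson_matrix,
    process_loadings,
    threshold_network,
)
from .pca import fit_pca

COMBINE_METHODS = ("average", "median", "min_abs")


@dataclass
class LoadingsCollection:
    """Loadings of the fixed discriminative PC across LOOCV iterations.

    Column 0 holds the full-data loadings; column k the loadings with the
    k-th retained sample removed.  Columns are sign-aligned to column 0
    (inner product >= 0 after alignment).
    """

    loadings: np.ndarray  # (n_features, n_kept + 1)
    removed: list[str | None]  # None for the full-data column
    flipped: list[bool]
    skipped: list[str]
    pc_index: int
    centering: str
    feature_names: list[str]


def loocv_loadings(
    matrix: OmicMatrix,
    pc_index: int,
    centering: str,
    labels: SampleLabels | None = None,
) -> LoadingsCollection:
    """Loadings of one fixed (PC, centering) with each sample left out.

    Removals that would leave a labelled group with fewer than 2 samples
    are skipped with a warning.
    """
    if matrix.n_samples < 4:
        raise ValidationError("LOOCV needs at least 4 samples")
    full = fit_pca(matrix, centering, k=pc_index).loading_vector(pc_index)
    cols = [full]
    removed: list[str | None] = [None]
    flipped = [False]
    skipped: list[str] = []
    group_sizes = None
    if labels is not None:
        group_sizes = {g: len(i) for g, i in labels.indices(matrix.sample_ids).items()}
    for sid in matrix.sample_ids:
        if group_sizes is not None:
            g = labels.mapping[sid]
            if group_sizes[g] - 1 < 2:
                warnings.warn(f"skipping removal of {sid!r}: group {g!r} would shrink below 2")
                skipped.append(sid)
                continue
        sub = matrix.drop_sample(sid)
        v = fit_pca(sub, centering, k=pc_index).loading_vector(pc_index)
        flip = bool(v @ full < 0)
        cols.append(-v if flip else v)
        removed.append(sid)
        flipped.append(flip)
    return LoadingsCollection(
        loadings=np.column_stack(cols),
        removed=removed,
        flipped=flipped,
        skipped=skipped,
        pc_index=pc_index,
        centering=centering,
        feature_names=list(matrix.feature_names),
    )


def loocv_pccorr_matrices(
    matrix: OmicMatrix,
    collection: LoadingsCollection,
    cutoff: float,
    speed_filter: bool = True,
) -> list[PCCorrMatrix]:
    """One PC-corr matrix per LOOCV column, on the matching sample subset.

    The speed filter drops features whose maximum |V^new| over all
    columns is below the cut-off before computing correlations; the
    min-operator bound guarantees no surviving edge can involve such a
    feature, so filtered and unfiltered networks coincide at the cut-off.
    """
    ncols = collection.loadings.shape[1]
    v_new = np.column_stack(
        [process_loadings(collection.loadings[:, j]).v_new for j in range(ncols)]
    )
    if speed_filter:
        keep = np.max(np.abs(v_new), axis=1) >= cutoff
    else:
        keep = np.ones(len(collection.feature_names), dtype=bool)
    keep_names = [f for f, k in zip(collection.feature_names, keep) if k]
    if len(keep_names) < 2:
        raise ValidationError("fewer than 2 features pass the loading filter")
    mats = []
    for j in range(ncols):
        sid = collection.removed[j]
        data = matrix if sid is None else matrix.drop_sample(sid)
        sub = data.subset_features(keep_names)
        c = pearson_matrix(sub)
        mats.append(pccorr_from_corr(c, v_new[keep, j], keep_names))
    return mats


@dataclass
class CombinedNetwork:
    """Entrywise combination of LOOCV PC-corr matrices."""

    pccorr: PCCorrMatrix
    method: str
    sign_unstable: np.ndarray  # True where iteration signs disagree


def combine_networks(matrices: list[PCCorrMatrix], method: str) -> CombinedNetwork:
    """Combine per-iteration matrices by average, median or min_abs.

    For min_abs the magnitude is the exact minimum of |entry| over
    iterations and the sign is taken from the first (full-data) matrix;
    entries whose sign varies across iterations are flagged unstable.
    """
    if method not in COMBINE_METHODS:
        raise ValidationError(f"method must be one of {COMBINE_METHODS}")
    if len(matrices) < 2:
        raise ValidationError("need at least 2 matrices to combine")
    names = matrices[0].feature_names
    for m in matrices[1:]:
        if m.feature_names != names:
            raise ValidationError("matrices have mismatched feature sets")
    W = np.stack([m.weights for m in matrices])
    if method == "average":
        comb = W.mean(axis=0)
    elif method == "median":
        comb = np.median(W, axis=0)
    else:
        comb = np.sign(W[0]) * np.min(np.abs(W), axis=0)
    sign_unstable = (W > 0).any(axis=0) & (W < 0).any(axis=0)
    v0 = matrices[0].v_new
    return CombinedNetwork(
        pccorr=PCCorrMatrix(comb, None, v0, list(names)),
        method=method,
        sign_unstable=sign_unstable,
    )


def loocv_report(
    original: PCCorrMatrix,
    combined: dict[str, CombinedNetwork],
    cutoff: float,
    data: OmicMatrix | None = None,
    labels: SampleLabels | None = None,
) -> dict:
    """4-way node/edge Venn counts and the edge-retention robustness score.

    The retention score is the fraction of the original network's edges
    that survive in the min_abs (intersection) network at the same
    cut-off; None when the original network has no edges.
    """
    nets: dict[str, NetworkTables] = {
        "original": threshold_network(original, cutoff, data, labels,
                                      metadata={"variant": "original"})
    }
    for name, cn in combined.items():
        nets[name] = threshold_network(cn.pccorr, cutoff, data, labels,
                                       metadata={"variant": name})
    node_sets = {k: v.node_set() for k, v in nets.items()}
    edge_sets = {k: v.edge_set() for k, v in nets.items()}
    e_orig = edge_sets["original"]
    retention = None
    if "min_abs" in edge_sets and e_orig:
        retention = len(e_orig & edge_sets["min_abs"]) / len(e_orig)
    return {
        "cutoff": cutoff,
        "node_counts": {k: len(v) for k, v in node_sets.items()},
        "edge_counts": {k: len(v) for k, v in edge_sets.items()},
        "node_venn": venn_regions(node_sets),
        "edge_venn": venn_regions(edge_sets),
        "edge_retention_min_abs": retention,
        "sign_unstable_edges": {
            name: int(np.triu(cn.sign_unstable, k=1).sum())
            for name, cn in combined.items()
        },
    }


def run_loocv(
    matrix: OmicMatrix,
    pc_index: int,
    centering: str,
    cutoff: float,
    labels: SampleLabels | None = None,
    speed_filter: bool = True,
) -> dict:
    """Full LOOCV chain; returns the report plus the intermediate objects."""
    coll = loocv_loadings(matrix, pc_index, centering, labels)
    mats = loocv_pccorr_matrices(matrix, coll, cutoff, speed_filter=speed_filter)
    combined = {m: combine_networks(mats, m) for m in COMBINE_METHODS}
    report = loocv_report(mats[0], combined, cutoff, data=matrix, labels=labels)
    report["flipped_iterations"] = [
        s for s, f in zip(coll.removed, coll.flipped) if f and s is not None
    ]
    report["skipped_iterations"] = coll.skipped
    return {"report": report, "collection": coll, "matrices": mats, "combined": combined}
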