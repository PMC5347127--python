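"""Shared in-memory containers: omic matrix, sample labels, network tables."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a structural invariant."""


class FrustrationError(RuntimeError):
    """A frustration-resolution policy refused to act (e.g. drop at >= 5%)."""


EDGE_COLUMNS = ["source", "target", "weight", "sign"]
NODE_COLUMNS = ["feature", "loading", "group", "color", "degree"]


@dataclass
class OmicMatrix:
    """A samples x features numeric matrix with named rows and columns.

    ``values`` is always stored with samples as rows, whatever the on-disk
    orientation was.  Entries may be NaN until imputation/preprocessing;
    routines that feed PCA or correlations call :meth:`require_finite`.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if self.values.ndim != 2:
            raise ValidationError("matrix must be two-dimensional")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if p != len(self.feature_names):
            raise ValidationError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.feature_names)) != p:
            raise ValidationError("duplicate feature names")
        if n < 3:
            raise ValidationError("need at least 3 samples")
        if p < 2:
            raise ValidationError("need at least 2 features")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def require_finite(self) -> None:
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                "non-finite entry at sample "
                f"{self.sample_ids[bad[0]]!r}, feature {self.feature_names[bad[1]]!r}"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OmicMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    def drop_sample(self, sample_id: str) -> "OmicMatrix":
        try:
            i = self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample id {sample_id!r}") from None
        keep = np.ones(self.n_samples, dtype=bool)
        keep[i] = False
        return OmicMatrix(
            self.values[keep],
            [s for j, s in enumerate(self.sample_ids) if keep[j]],
            list(self.feature_names),
        )

    def subset_features(self, names: Sequence[str]) -> "OmicMatrix":
        idx = {f: j for j, f in enumerate(self.feature_names)}
        cols = [idx[n] for n in names]
        return OmicMatrix(self.values[:, cols], list(self.sample_ids), list(names))


@dataclass
class SampleLabels:
    """Mapping sample id -> group name, with a deterministic group order.

    The first group in ``group_order`` is drawn as the "red" group in all
    node-colouring conventions; the second as "black".
    """

    mapping: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}
        if not self.group_order:
            seen: list[str] = []
            for g in self.mapping.values():
                if g not in seen:
                    seen.append(g)
            self.group_order = seen
        extra = set(self.mapping.values()) - set(self.group_order)
        if extra:
            raise ValidationError(f"groups missing from group_order: {sorted(extra)}")

    @property
    def n_groups(self) -> int:
        return len(self.group_order)

    def groups_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise ValidationError(f"samples without a label: {missing[:5]}")
        return np.array([self.mapping[s] for s in sample_ids])

    def indices(self, sample_ids: Sequence[str]) -> dict[str, np.ndarray]:
        groups = self.groups_for(sample_ids)
        return {g: np.flatnonzero(groups == g) for g in self.group_order}

    def validate_against(self, matrix: OmicMatrix, min_per_group: int = 2) -> None:
        ids = set(matrix.sample_ids)
        orphans = [s for s in self.mapping if s not in ids]
        if orphans:
            raise ValidationError(f"labelled samples absent from matrix: {orphans[:5]}")
        for g, idx in self.indices(matrix.sample_ids).items():
            if len(idx) < min_per_group:
                raise ValidationError(
                    f"group {g!r} has {len(idx)} samples (< {min_per_group})"
                )


def _sorted_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Deterministic edge order: descending |weight|, ties by endpoint pair."""
    if edges.empty:
        return edges.reset_index(drop=True)
    out = edges.copy()
    # endpoints in lexicographic order within the row
    swap = out["source"] > out["target"]
    out.loc[swap, ["source", "target"]] = out.loc[swap, ["target", "source"]].to_numpy()
    out = out.sort_values(
        by=["weight", "source", "target"],
        key=lambda s: -s.abs() if s.name == "weight" else s,
        kind="mergesort",
    )
    return out.reset_index(drop=True)


@dataclass
class NetworkTables:
    """Thresholded network as Cytoscape-ready edge and node tables.

    ``exists`` is False for the degenerate "no network" outcome of the
    P-value baselines (fewer than two significant features).
    """

    edges: pd.DataFrame
    nodes: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    exists: bool = True

    def __post_init__(self) -> None:
        self.edges = _sorted_edges(
            self.edges.reindex(columns=list(self.edges.columns))
        )
        self.nodes = self.nodes.reset_index(drop=True)
        node_set = set(self.nodes["feature"]) if len(self.nodes) else set()
        for col in ("source", "target"):
            stray = set(self.edges[col]) - node_set
            if stray:
                raise ValidationError(f"edge endpoint not in node table: {sorted(stray)[:5]}")
        if len(self.edges):
            if (self.edges["source"] == self.edges["target"]).any():
                raise ValidationError("self-edge in edge table")
            pairs = list(zip(self.edges["source"], self.edges["target"]))
            if len(pairs) != len(set(map(frozenset, pairs))):
                raise ValidationError("duplicate unordered edge pair")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_set(self) -> set[str]:
        return set(self.nodes["feature"])

    def edge_set(self) -> set[tuple[str, str]]:
        return {
            tuple(sorted((s, t)))
            for s, t in zip(self.edges["source"], self.edges["target"])
        }

    @classmethod
    def empty(cls, metadata: dict | None = None, exists: bool = True) -> "NetworkTables":
        return cls(
            edges=pd.DataFrame(columns=EDGE_COLUMNS),
            nodes=pd.DataFrame(columns=NODE_COLUMNS),
            metadata=metadata or {},
            exists=exists,
        )
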