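"""Two-group synthetic omic matrices with planted, known structure.

Features come in equicorrelated Gaussian blocks (pairwise correlation
rho within a block, sampled through the Cholesky factor of the
equicorrelation matrix) plus i.i.d. noise features.  A block may carry a
group mean shift of delta standard deviations, applied to the second
group with the block's sign.  This plants exactly the three feature
categories the PC-corr AND gate is meant to separate:

* discriminative AND correlated blocks (delta != 0, rho > 0, size > 1),
* correlated-only blocks (delta = 0),
* discriminative-only singletons (size 1, delta != 0).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import OmicMatrix, SampleLabels, ValidationError

GROUPS = ("A", "B")


@dataclass
class Block:
    size: int
    rho: float
    delta: float = 0.0
    sign: int = 1

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValidationError("block size must be >= 1")
        if not 0 <= self.rho < 1:
            raise ValidationError("rho must lie in [0, 1)")
        if self.sign not in (-1, 1):
            raise ValidationError("sign must be +1 or -1")


@dataclass
class PlantedDesign:
    n_per_group: tuple[int, int]
    blocks: list[Block] = field(default_factory=list)
    n_noise_features: int = 0
    noise_sd: float = 1.0
    seed: int = 0

    @property
    def n_features(self) -> int:
        return sum(b.size for b in self.blocks) + self.n_noise_features


@dataclass
class GroundTruth:
    """Per-feature provenance flags for the planted design."""

    table: pd.DataFrame  # feature, block, is_discriminative, is_correlated, shift_sign

    def features_where(self, discriminative: bool, correlated: bool) -> list[str]:
        t = self.table
        mask = (t["is_discriminative"] == discriminative) & (
            t["is_correlated"] == correlated
        )
        return list(t.loc[mask, "feature"])


def generate(design: PlantedDesign) -> tuple[OmicMatrix, SampleLabels, GroundTruth]:
    """Draw one labelled matrix from a planted design, deterministic per seed."""
    nA, nB = design.n_per_group
    n = nA + nB
    if design.n_features < 2:
        raise ValidationError("design must have at least 2 features")
    rng = np.random.default_rng(design.seed)
    b_rows = np.arange(nA, n)  # second group carries the shift
    columns = []
    names: list[str] = []
    truth_rows = []
    for bi, block in enumerate(design.blocks):
        if block.size == 1 or block.rho == 0:
            X = rng.standard_normal((n, block.size))
        else:
            C = np.full((block.size, block.size), block.rho)
            np.fill_diagonal(C, 1.0)
            L = np.linalg.cholesky(C)
            X = rng.standard_normal((n, block.size)) @ L.T
        X = X * design.noise_sd
        if block.delta != 0:
            X[b_rows] += block.sign * block.delta * design.noise_sd
        columns.append(X)
        for k in range(block.size):
            name = f"b{bi}_{k:03d}"
            names.append(name)
            truth_rows.append(
                (name, bi, block.delta != 0, block.rho > 0 and block.size > 1,
                 block.sign if block.delta != 0 else 0)
            )
    if design.n_noise_features:
        X = rng.standard_normal((n, design.n_noise_features)) * design.noise_sd
        columns.append(X)
        for k in range(design.n_noise_features):
            name = f"noise_{k:03d}"
            names.append(name)
            truth_rows.append((name, -1, False, False, 0))
    values = np.hstack(columns)
    sample_ids = [f"A{i:03d}" for i in range(nA)] + [f"B{i:03d}" for i in range(nB)]
    labels = SampleLabels(
        {s: (GROUPS[0] if i < nA else GROUPS[1]) for i, s in enumerate(sample_ids)},
        group_order=list(GROUPS),
    )
    truth = GroundTruth(
        pd.DataFrame(
            truth_rows,
            columns=["feature", "block", "is_discriminative", "is_correlated", "shift_sign"],
        )
    )
    return OmicMatrix(values, sample_ids, names), labels, truth


def scenario_presets(name: str, seed: int = 0) -> PlantedDesign:
    """Named designs mirroring the regimes the method is exercised in.

    and_gate: one discriminative-correlated block, one correlated-only
        block, discriminative-only singletons, plus noise — the structure
        the min-operator AND gate should separate.
    metagenomics_like: 8 vs 8 samples with one broad panel of weakly
        shifted, weakly correlated features: multivariately separable
        but with essentially no univariately BH-significant feature.
    lipidomics_like: several blocks of mixed correlation and shift
        strength with background noise.
    null: pure noise, for type-I control.
    """
    if name == "and_gate":
        blocks = [Block(12, 0.8, 3.0, 1), Block(12, 0.8, 0.0, 1)]
        blocks += [Block(1, 0.0, 0.75, 1 if k % 2 == 0 else -1) for k in range(5)]
        return PlantedDesign((20, 20), blocks, n_noise_features=25, seed=seed)
    if name == "metagenomics_like":
        return PlantedDesign(
            (8, 8), [Block(60, 0.05, 0.65, 1)], n_noise_features=50, seed=seed
        )
    if name == "lipidomics_like":
        blocks = [
            Block(8, 0.8, 2.5, 1),
            Block(6, 0.7, 2.0, -1),
            Block(6, 0.6, 1.5, 1),
            Block(5, 0.5, 0.0, 1),
        ]
        return PlantedDesign((20, 20), blocks, n_noise_features=25, seed=seed)
    if name == "null":
        return PlantedDesign((20, 20), [], n_noise_features=50, seed=seed)
    raise ValidationError(f"unknown scenario preset {name!r}")
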