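"""Tri-state methylation classification and primary/xenograft retention analysis.

Methylation-array beta values (fraction methylated signal per CpG probe) are
binned into three states — unmethylated, hemi-methylated, methylated — with
cutoffs at 1/3 and 2/3.  The *retention rate* of a primary-tumor/xenograft
pair is the proportion of shared probes whose state is identical in both
samples.  Cohort-level fidelity is further summarised by hierarchical
clustering of all samples on the most variable probes and counting how many
model pairs land on immediately adjacent dendrogram leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

# State codes; bins are half-open [0, 1/3), [1/3, 2/3), [2/3, 1] so that the
# classifier is total on [0, 1] (the boundary points have measure zero on
# real arrays but must still map somewhere deterministic).
UNMETHYLATED = 0
HEMIMETHYLATED = 1
METHYLATED = 2
STATE_NAMES = {UNMETHYLATED: "unmethylated",
               HEMIMETHYLATED: "hemimethylated",
               METHYLATED: "methylated"}

TISSUES = ("primary", "xenograft")


@dataclass
class BetaMatrix:
    """Probe x sample beta-value matrix with a sample-to-model pairing map.

    ``values`` is a DataFrame indexed by probe id with one column per sample;
    entries are beta fractions in [0, 1] or NaN for missing.  ``pairing``
    maps each sample id to ``(model_id, tissue)`` with tissue one of
    ``primary`` / ``xenograft``; each model has at most one sample per
    tissue.
    """

    values: pd.DataFrame
    pairing: pd.DataFrame  # columns: sample_id, model_id, tissue

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        required = {"sample_id", "model_id", "tissue"}
        if not required.issubset(self.pairing.columns):
            raise ValueError(f"pairing needs columns {sorted(required)}")
        bad = set(self.pairing["tissue"]) - set(TISSUES)
        if bad:
            raise ValueError(f"unknown tissue labels: {sorted(bad)}")
        dup = self.pairing.duplicated(subset=["model_id", "tissue"])
        if dup.any():
            raise ValueError("each model may have at most one sample per tissue")
        missing = set(self.pairing["sample_id"]) - set(self.values.columns)
        if missing:
            raise ValueError(f"pairing references absent samples: {sorted(missing)}")

    def iter_pairs(self) -> Iterator[tuple[str, str, str]]:
        """Yield (model_id, primary_sample, xenograft_sample) for complete pairs."""
        wide = self.pairing.pivot(index="model_id", columns="tissue",
                                  values="sample_id")
        for model_id, row in wide.iterrows():
            if "primary" in row and "xenograft" in row:
                p, x = row.get("primary"), row.get("xenograft")
                if isinstance(p, str) and isinstance(x, str):
                    yield model_id, p, x

    @property
    def n_pairs(self) -> int:
        return sum(1 for _ in self.iter_pairs())


def classify_state(beta: float) -> int:
    """Classify a single beta value into its tri-state bin.

    Bins are [0, 1/3) -> unmethylated, [1/3, 2/3) -> hemimethylated,
    [2/3, 1] -> methylated.
    """
    if not np.isfinite(beta) or beta < 0 or beta > 1:
        raise ValueError(f"beta value {beta!r} outside [0, 1]")
    if beta < 1 / 3:
        return UNMETHYLATED
    if beta < 2 / 3:
        return HEMIMETHYLATED
    return METHYLATED


def classify_states(betas: np.ndarray) -> np.ndarray:
    """Vectorised tri-state classification; NaN propagates as -1."""
    arr = np.asarray(betas, dtype=float)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < 0) | (arr[finite] > 1)):
        raise ValueError("beta values outside [0, 1]")
    out = np.full(arr.shape, -1, dtype=int)
    out[finite & (arr < 1 / 3)] = UNMETHYLATED
    out[finite & (arr >= 1 / 3) & (arr < 2 / 3)] = HEMIMETHYLATED
    out[finite & (arr >= 2 / 3)] = METHYLATED
    return out


def retention_rate(beta_a: np.ndarray, beta_b: np.ndarray
                   ) -> tuple[float, np.ndarray]:
    """Proportion of shared probes with identical tri-state methylation bin.

    Probes missing (NaN) in either sample are excluded pairwise.  Returns the
    rate and a boolean retained-flag vector aligned to the shared (non-missing)
    probes.  Symmetric in argument order.
    """
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired beta vectors must have equal length")
    shared = np.isfinite(a) & np.isfinite(b)
    if not shared.any():
        raise ValueError("no shared non-missing probes between the pair")
    retained = classify_states(a[shared]) == classify_states(b[shared])
    return float(retained.mean()), retained


def cohort_retention_summary(matrix: BetaMatrix) -> tuple[pd.DataFrame, dict]:
    """Per-model retention rates plus min/median/max over the cohort."""
    rows = []
    for model_id, p, x in matrix.iter_pairs():
        rate, retained = retention_rate(matrix.values[p].to_numpy(),
                                        matrix.values[x].to_numpy())
        rows.append({"model_id": model_id, "primary": p, "xenograft": x,
                     "n_shared_probes": int(retained.size),
                     "retention_rate": rate})
    if not rows:
        raise ValueError("no complete primary/xenograft pairs in cohort")
    table = pd.DataFrame(rows).set_index("model_id")
    rates = table["retention_rate"]
    summary = {"n_pairs": int(len(table)),
               "min": float(rates.min()),
               "median": float(rates.median()),
               "max": float(rates.max())}
    return table, summary


def top_variable_probes(matrix: BetaMatrix, k: int) -> pd.Index:
    """The k probes with the largest across-sample variance.

    Ties are broken by probe id so the selection is deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(matrix.values):
        raise ValueError(f"k={k} exceeds probe count {len(matrix.values)}")
    var = matrix.values.var(axis=1, ddof=1, skipna=True).fillna(0.0)
    order = np.lexsort((matrix.values.index.to_numpy(), -var.to_numpy()))
    return matrix.values.index[order[:k]]


def cluster_leaf_order(matrix: BetaMatrix, k: int) -> list[str]:
    """Sample leaf order from average-linkage clustering on 1 - Pearson r
    over the top-k most variable probes."""
    probes = top_variable_probes(matrix, k)
    sub = matrix.values.loc[probes]
    corr = np.corrcoef(sub.to_numpy(dtype=float).T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    z = linkage(squareform(dist, checks=False), method="average")
    return [sub.columns[i] for i in leaves_list(z)]


def pair_adjacency_count(matrix: BetaMatrix, k: int
                         ) -> tuple[int, pd.DataFrame]:
    """Count models whose primary and xenograft occupy adjacent leaves.

    Returns the count and a per-model table of adjacency flags.  The count is
    invariant to reflecting the dendrogram leaf order.
    """
    pairs = list(matrix.iter_pairs())
    if len(pairs) < 2:
        raise ValueError("adjacency analysis requires at least 2 pairs")
    order = cluster_leaf_order(matrix, k)
    pos = {s: i for i, s in enumerate(order)}
    rows = []
    for model_id, p, x in pairs:
        adjacent = abs(pos[p] - pos[x]) == 1
        rows.append({"model_id": model_id, "adjacent": adjacent})
    table = pd.DataFrame(rows).set_index("model_id")
    return int(table["adjacent"].sum()), table
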