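"""Transcriptome similarity between paired primary tumors and xenografts.

Expression enters as gene x sample FPKM, is transformed to log2(FPKM + 0.01),
and genes whose maximum transformed value is below 1 are removed.  On the
filtered matrix the module computes the full Spearman correlation matrix with
lowest-quartile flagging of primary/xenograft pairs, gene-centered PCA with
covariate correlations, mean z-score gene-set scores, and per-gene paired
t-tests with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.01
MIN_MAX_LOG = 1.0


@dataclass
class ExpressionMatrix:
    """Gene x sample log2(FPKM + 0.01) matrix with sample labels.

    ``pairing`` columns: sample_id, model_id, tissue; tissue may be
    primary / xenograft / normal_kidney / fetal_kidney.
    """

    values: pd.DataFrame
    pairing: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.pairing["sample_id"]) - set(self.values.columns)
        if missing:
            raise ValueError(f"pairing references absent samples: {sorted(missing)}")

    def iter_pairs(self):
        wide = self.pairing[self.pairing["tissue"].isin(["primary", "xenograft"])] \
            .pivot(index="model_id", columns="tissue", values="sample_id")
        for model_id, row in wide.iterrows():
            p, x = row.get("primary"), row.get("xenograft")
            if isinstance(p, str) and isinstance(x, str):
                yield model_id, p, x


def transform_filter(fpkm: pd.DataFrame, pairing: pd.DataFrame
                     ) -> ExpressionMatrix:
    """log2(FPKM + 0.01) transform, then drop genes with max value < 1.

    Rejects negative input, which also guards against accidentally feeding
    already-log-transformed values (those contain negatives) through the
    transform twice.
    """
    vals = fpkm.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("FPKM values must be non-negative (input may "
                         "already be log-transformed)")
    log = np.log2(vals + PSEUDOCOUNT)
    keep = log.max(axis=1) >= MIN_MAX_LOG
    return ExpressionMatrix(
        values=pd.DataFrame(log[keep], index=fpkm.index[keep],
                            columns=fpkm.columns),
        pairing=pairing)


def spearman_pair_analysis(matrix: ExpressionMatrix
                           ) -> tuple[pd.DataFrame, pd.DataFrame, float | None]:
    """Sample Spearman matrix, per-pair correlations, and quartile flags.

    Pairs whose correlation falls below the cohort's 25th percentile of pair
    correlations are flagged low-fidelity; the threshold is recomputed from
    the data.  With fewer than 4 pairs the flagging is disabled (threshold
    None) and only the matrix and pair correlations are returned.
    """
    corr, _ = stats.spearmanr(matrix.values.to_numpy())
    if np.ndim(corr) == 0:  # scipy collapses the 2-sample case to a scalar
        corr = np.array([[1.0, float(corr)], [float(corr), 1.0]])
    corr = pd.DataFrame(corr, index=matrix.values.columns,
                        columns=matrix.values.columns)
    rows = [{"model_id": m, "primary": p, "xenograft": x,
             "spearman_r": float(corr.loc[p, x])}
            for m, p, x in matrix.iter_pairs()]
    pairs = pd.DataFrame(rows).set_index("model_id") if rows else pd.DataFrame()
    threshold = None
    if len(pairs) >= 4:
        threshold = float(np.quantile(pairs["spearman_r"], 0.25))
        pairs["lowest_quartile"] = pairs["spearman_r"] < threshold
    elif len(pairs):
        import warnings
        warnings.warn("fewer than 4 pairs: lowest-quartile flagging disabled",
                      stacklevel=2)
    return corr, pairs, threshold


def pca_analysis(matrix: ExpressionMatrix, n_components: int = 10,
                 covariates: pd.DataFrame | None = None
                 ) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame | None]:
    """Gene-centered PCA of samples with optional covariate correlations.

    Returns (scores, pct_variance, covariate correlations).  Values are not
    rescaled per gene: the log2 FPKM scale is already comparable across
    genes.  ``covariates`` is sample-indexed; Pearson r of each component
    score with each covariate is reported.
    """
    x = matrix.values.to_numpy(dtype=float).T  # samples x genes
    if x.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    n_components = min(n_components, min(x.shape) - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x - x.mean(axis=0))
    scores = pd.DataFrame(scores, index=matrix.values.columns,
                          columns=[f"PC{i+1}" for i in range(n_components)])
    pct_var = pca.explained_variance_ratio_ * 100.0
    cov_corr = None
    if covariates is not None:
        cov = covariates.loc[scores.index]
        cov_corr = pd.DataFrame(
            {c: {pc: float(stats.pearsonr(scores[pc], cov[c])[0])
                 for pc in scores.columns}
             for c in cov.columns})
    return scores, pct_var, cov_corr


def gene_set_score(matrix: ExpressionMatrix, members: list[str]
                   ) -> pd.Series:
    """Mean across-sample z-score of the member genes, per sample.

    Genes with zero variance across samples contribute 0.  The cohort mean
    of the score is 0 by construction.  Member genes absent from the
    filtered matrix are ignored (they must not all be absent).
    """
    present = [g for g in members if g in matrix.values.index]
    if not present:
        raise ValueError("no gene-set members present in the matrix")
    sub = matrix.values.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (sub - mu) / sd, 0.0)
    return pd.Series(z.mean(axis=0), index=matrix.values.columns,
                     name="gene_set_score")


def paired_de(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene paired two-tailed t-test (xenograft vs primary) with BH q.

    Genes whose paired differences have zero variance get p = 1 and a
    ``degenerate`` flag.  Rows are ordered by p.
    """
    pairs = list(matrix.iter_pairs())
    if len(pairs) < 3:
        raise ValueError("paired differential analysis needs >= 3 pairs")
    prim = matrix.values[[p for _, p, _ in pairs]].to_numpy(dtype=float)
    xeno = matrix.values[[x for _, _, x in pairs]].to_numpy(dtype=float)
    diff = xeno - prim
    n = diff.shape[1]
    mean = diff.mean(axis=1)
    sd = diff.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), n - 1)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame({"mean_log2_difference": mean, "t": t, "p": p, "q": q,
                        "degenerate": degenerate},
                       index=matrix.values.index)
    return out.sort_values("p", kind="stable")


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
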