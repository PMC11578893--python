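"""Cross-modality KNN label transfer through a shared feature space.

A low-dimensional query (e.g. segmented nuclei with a few dozen protein
channels) is annotated against a high-dimensional reference (e.g. a
transcriptome or multimodal atlas) by: (1) restricting both to the features
shared through a protein↔gene bridge table, log-normalizing and z-scoring
each object independently; (2) finding each query observation's k nearest
reference neighbours in that space; (3) assigning the majority label, with
the fraction of neighbours carrying it recorded as the evidence fraction
(KNNf); and (4) imputing features absent from the query as the mean over the
same neighbours. A second, lineage-restricted pass against a richer
reference (e.g. joint RNA + surface-protein data) can refine a subset of
the coarse labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "FeatureBridge",
    "FeatureSet",
    "TransferResult",
    "harmonize_features",
    "knn_transfer",
    "impute_values",
    "two_stage_refine",
    "DEFAULT_K_RNA",
    "DEFAULT_K_CITE",
]

logger = logging.getLogger(__name__)

#: Default neighbour counts: 30 against a transcriptome reference, 7 against
#: a joint RNA/protein reference.
DEFAULT_K_RNA = 30
DEFAULT_K_CITE = 7


@dataclass(frozen=True)
class FeatureBridge:
    """One-to-one pairing of query feature names with reference feature names."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        q = [p[0] for p in self.pairs]
        r = [p[1] for p in self.pairs]
        if len(set(q)) != len(q) or len(set(r)) != len(r):
            raise ValueError("bridge must be one-to-one on mapped pairs")

    @classmethod
    def identity(cls, names: list[str]) -> "FeatureBridge":
        return cls(tuple((n, n) for n in names))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureBridge":
        return cls(tuple(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))

    def untranslated(self, query_features: list[str], ref_features: list[str]) -> tuple[list[str], list[str]]:
        q_mapped = {p[0] for p in self.pairs}
        r_mapped = {p[1] for p in self.pairs}
        return (
            [f for f in query_features if f not in q_mapped],
            [f for f in ref_features if f not in r_mapped],
        )


@dataclass
class FeatureSet:
    """Observations × features with optional labels / samples / annotations."""

    X: pd.DataFrame
    labels: pd.Series | None = None
    samples: pd.Series | None = None
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise ValueError("feature names must be unique")


@dataclass
class TransferResult:
    """Per-query assigned label, evidence fraction and neighbour set."""

    labels: pd.Series
    knnf: pd.Series
    neighbor_indices: np.ndarray
    imputed: pd.DataFrame = dc_field(default_factory=pd.DataFrame)
    k: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"label": self.labels, "knnf": self.knnf})
        for col in self.imputed.columns:
            out[f"imputed_{col}"] = self.imputed[col]
        return out


def _log_zscore(X: pd.DataFrame) -> pd.DataFrame:
    """log1p then per-feature z-score with population (n) variance.

    Constant features standardize to all-zero with a warning rather than NaN.
    """
    logged = np.log1p(X.to_numpy(dtype=float))
    mean = logged.mean(axis=0)
    std = logged.std(axis=0)  # population std (ddof=0)
    constant = std == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) standardized to zero"
        )
    std_safe = np.where(constant, 1.0, std)
    z = (logged - mean) / std_safe
    z[:, constant] = 0.0
    return pd.DataFrame(z, index=X.index, columns=X.columns)


def harmonize_features(
    query: FeatureSet,
    ref: FeatureSet,
    bridge: FeatureBridge | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both objects to the bridged shared space and standardize.

    Both matrices are log-transformed (log(1 + x)) and z-scored per feature
    within each object independently; columns are reported under the
    reference's feature names. Fewer than two shared features is an error.
    """
    if bridge is None:
        shared = [c for c in query.X.columns if c in set(ref.X.columns)]
        bridge = FeatureBridge.identity(shared)
    pairs = [
        (q, r)
        for q, r in bridge.pairs
        if q in query.X.columns and r in ref.X.columns
    ]
    if len(pairs) < 2:
        raise ValueError(
            f"only {len(pairs)} shared feature(s) after bridging; need >= 2"
        )
    q_cols = [p[0] for p in pairs]
    r_cols = [p[1] for p in pairs]
    q_shared = query.X[q_cols].copy()
    q_shared.columns = r_cols
    r_shared = ref.X[r_cols].copy()
    return _log_zscore(q_shared), _log_zscore(r_shared)


def _majority_vote(neigh_labels: np.ndarray) -> tuple[str, float]:
    """Most frequent label among neighbours; lexicographic tie-break."""
    values, counts = np.unique(neigh_labels.astype(str), return_counts=True)
    best = counts.max()
    winners = sorted(values[counts == best])
    if len(winners) > 1:
        logger.info("majority-vote tie among %s; choosing %s", winners, winners[0])
    return winners[0], best / neigh_labels.size


def knn_transfer(
    query_X: pd.DataFrame,
    ref_X: pd.DataFrame,
    ref_labels: pd.Series,
    k: int = DEFAULT_K_RNA,
    query_samples: pd.Series | None = None,
    batch: str = "none",
) -> TransferResult:
    """Assign each query observation the majority label of its k nearest
    reference neighbours (Euclidean in the harmonized space).

    KNNf, the evidence fraction, is the number of neighbours carrying the
    assigned label divided by k. Ties are broken lexicographically by label
    name. With ``batch="center"`` the query features are mean-centered per
    query sample before the search (run independently per sample).
    """
    if k > len(ref_X):
        raise ValueError(f"k={k} exceeds reference size {len(ref_X)}")
    if batch not in ("none", "center"):
        raise ValueError("batch must be 'none' or 'center'")
    qX = query_X.to_numpy(dtype=float).copy()
    if query_samples is None:
        groups = {None: np.arange(len(query_X))}
    else:
        samples = np.asarray(query_samples)
        groups = {s: np.flatnonzero(samples == s) for s in pd.unique(samples)}

    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(
        ref_X.to_numpy(dtype=float)
    )
    ref_lab = np.asarray(ref_labels).astype(str)

    labels = np.empty(len(query_X), dtype=object)
    knnf = np.empty(len(query_X), dtype=float)
    neigh = np.empty((len(query_X), k), dtype=int)
    for _, idx in groups.items():
        sub = qX[idx]
        if batch == "center":
            sub = sub - sub.mean(axis=0)
        _, ind = nn.kneighbors(sub)
        neigh[idx] = ind
        for row, i in zip(ind, idx):
            labels[i], knnf[i] = _majority_vote(ref_lab[row])

    return TransferResult(
        labels=pd.Series(labels, index=query_X.index, name="label"),
        knnf=pd.Series(knnf, index=query_X.index, name="knnf"),
        neighbor_indices=neigh,
        k=k,
    )


def impute_values(
    result: TransferResult,
    ref_values: pd.DataFrame,
    targets: list[str] | None = None,
) -> TransferResult:
    """Impute query values of reference-only features/annotations.

    Imputed value = unweighted mean over the k neighbours; undefined (NaN)
    neighbour values are excluded from the mean, and all-undefined
    neighbourhoods yield NaN.
    """
    targets = targets if targets is not None else list(ref_values.columns)
    missing = [t for t in targets if t not in ref_values.columns]
    if missing:
        raise KeyError(f"unknown imputation target(s): {missing}")
    vals = ref_values[targets].to_numpy(dtype=float)
    neigh_vals = vals[result.neighbor_indices]  # (n_query, k, n_targets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        imputed = np.nanmean(neigh_vals, axis=1)
    result.imputed = pd.DataFrame(
        imputed, index=result.labels.index, columns=targets
    )
    return result


def two_stage_refine(
    query: FeatureSet,
    coarse: TransferResult,
    ref2: FeatureSet,
    lineage_filter: list[str],
    bridge2: FeatureBridge | None = None,
    k2: int = DEFAULT_K_CITE,
    impute_targets: list[str] | None = None,
    batch: str = "none",
) -> TransferResult:
    """Re-annotate a lineage subset of coarse labels against a second reference.

    Query observations whose coarse label is in ``lineage_filter`` are
    harmonized with ``ref2`` (a hybrid space, e.g. bridged protein features)
    and re-labelled with ``k2`` neighbours (default 7), optionally imputing
    reference-only continuous annotations (e.g. lineage pseudotimes).
    Unselected observations keep their coarse labels; an empty subset passes
    the coarse result through with a warning.
    """
    selected = coarse.labels.isin(lineage_filter).to_numpy()
    if not selected.any():
        warnings.warn("lineage filter selects no observations; returning coarse result")
        return coarse

    sub_query = FeatureSet(
        X=query.X.loc[selected],
        samples=None if query.samples is None else query.samples.loc[selected],
    )
    qh, rh = harmonize_features(sub_query, ref2, bridge2)
    refined = knn_transfer(
        qh, rh, ref2.labels, k=k2, query_samples=sub_query.samples, batch=batch
    )
    if impute_targets:
        if ref2.annotations is None:
            raise ValueError("ref2 has no annotations to impute from")
        refined = impute_values(refined, ref2.annotations, impute_targets)

    labels = coarse.labels.copy()
    labels.loc[selected] = refined.labels.to_numpy()
    knnf = coarse.knnf.copy()
    knnf.loc[selected] = refined.knnf.to_numpy()
    imputed = pd.DataFrame(index=coarse.labels.index, columns=refined.imputed.columns,
                           dtype=float)
    if not refined.imputed.empty:
        imputed.loc[selected, :] = refined.imputed.to_numpy()
    neigh = np.full((len(coarse.labels), k2), -1, dtype=int)
    neigh[selected] = refined.neighbor_indices
    return TransferResult(
        labels=labels, knnf=knnf, neighbor_indices=neigh, imputed=imputed, k=k2
    )
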