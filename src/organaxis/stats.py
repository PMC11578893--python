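"""Axis-based spatial statistics on annotated observations.

Once observations (spots or cells) carry a continuous axis value and a
discrete axis bin, downstream questions become ordinary tabular statistics:
where along the axis does a cell type or gene sit (weighted mean position),
how do binned expression profiles cluster and compare between age groups
(Ward clustering, cosine similarity, two-way ANOVA), which genes are
expressed by exactly one cell type (χ² specialization-gene screen), and how
much transcriptome variance does the axis explain (PC–axis correlation
score).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import chi2_contingency, spearmanr
from sklearn.decomposition import PCA
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "qc_filter_spots",
    "weighted_mean_position",
    "BinProfileSet",
    "bin_profiles",
    "cluster_profiles",
    "profile_cosine",
    "group_cosine_similarity",
    "profile_anova",
    "detect_specialization_genes",
    "VarianceAttribution",
    "axis_variance_score",
    "hypercluster_axis_assignment",
    "lognorm",
    "DEFAULT_MIN_FEATURES",
    "DEFAULT_MIN_CELLS",
]

logger = logging.getLogger(__name__)

#: Spot QC defaults: at least 1,000 detected features and 25 predicted cells.
DEFAULT_MIN_FEATURES = 1000
DEFAULT_MIN_CELLS = 25


def qc_filter_spots(
    obs: pd.DataFrame,
    min_features: int = DEFAULT_MIN_FEATURES,
    min_cells: float = DEFAULT_MIN_CELLS,
    feature_col: str = "n_features",
    cell_col: str = "n_cells",
) -> tuple[pd.DataFrame, dict]:
    """Remove spots with fewer than ``min_features`` detected features or
    fewer than ``min_cells`` predicted cells (strict "fewer than": a spot at
    exactly the threshold is retained).

    Returns the filtered table and a report counting removals per criterion.
    """
    low_feat = obs[feature_col] < min_features
    low_cell = obs[cell_col] < min_cells
    keep = ~(low_feat | low_cell)
    report = {
        "n_input": int(len(obs)),
        "removed_low_features": int(low_feat.sum()),
        "removed_low_cells": int(low_cell.sum()),
        "removed_total": int((~keep).sum()),
        "n_kept": int(keep.sum()),
    }
    return obs.loc[keep].copy(), report


def weighted_mean_position(
    weights: np.ndarray,
    axis: np.ndarray,
    threshold: float = 0.0,
) -> float:
    """Abundance-weighted mean axis position: Σ w·x / Σ w over observations
    with weight ≥ threshold.

    The result is bounded by the axis range of the included observations and
    invariant to uniform scaling of the weights. All-below-threshold (or
    all-zero surviving weights) yields NaN with a warning.
    """
    weights = np.asarray(weights, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    keep = (weights >= threshold) & ~np.isnan(axis)
    if not keep.any() or weights[keep].sum() == 0:
        warnings.warn("no observation passes the weight threshold; undefined position")
        return float("nan")
    w = weights[keep]
    return float(np.dot(w, axis[keep]) / w.sum())


def lognorm(
    counts: pd.DataFrame, target_sum: float | None = None
) -> pd.DataFrame:
    """Total-count normalization (to ``target_sum``, default the median
    total) followed by log1p."""
    X = counts.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    totals[totals == 0] = 1.0
    target = float(np.median(totals)) if target_sum is None else float(target_sum)
    norm = X / totals[:, None] * target
    return pd.DataFrame(np.log1p(norm), index=counts.index, columns=counts.columns)


@dataclass
class BinProfileSet:
    """Per-feature mean expression per sample and axis bin.

    ``means`` is a tidy table (feature, sample, group, bin, mean); an empty
    bin for a sample is a missing datapoint, never a zero. ``prevalence`` is
    feature × bin fraction of observations with nonzero expression, pooled
    over samples.
    """

    means: pd.DataFrame
    prevalence: pd.DataFrame
    bin_order: tuple[str, ...]
    features: tuple[str, ...]

    def profile_matrix(self, group: str | None = None) -> pd.DataFrame:
        """Feature × bin matrix of means, averaged over samples (optionally
        within one group), columns in bin order."""
        sub = self.means if group is None else self.means[self.means["group"] == group]
        mat = sub.groupby(["feature", "bin"], observed=True)["mean"].mean().unstack("bin")
        return mat.reindex(columns=[b for b in self.bin_order if b in mat.columns])


def bin_profiles(
    expression: pd.DataFrame,
    bins: pd.Series,
    samples: pd.Series,
    groups: pd.Series | None = None,
    bin_order: tuple[str, ...] | None = None,
    min_prevalence: float = 0.05,
    log: bool = True,
) -> BinProfileSet:
    """Collapse observations to one datapoint per feature, sample and bin.

    Features are retained iff their prevalence (fraction of observations
    with nonzero expression) reaches ``min_prevalence`` (default 5%) in at
    least one bin; means are computed on log-normalized expression when
    ``log`` is set.
    """
    bins = bins.astype(object)
    defined = ~pd.isna(bins)
    expr = expression.loc[defined.to_numpy()]
    bins = bins[defined]
    samples = samples[defined]
    groups = None if groups is None else groups[defined]
    if bin_order is None:
        bin_order = tuple(pd.unique(bins))

    nz = (expr > 0).groupby(bins.to_numpy()).mean()
    prevalence = nz.T.reindex(columns=[b for b in bin_order if b in nz.index])
    kept = prevalence.max(axis=1) >= min_prevalence
    features = tuple(prevalence.index[kept])
    if not features:
        warnings.warn("no feature reaches the prevalence threshold in any bin")

    values = lognorm(expr[list(features)]) if log else expr[list(features)]
    key = pd.DataFrame({"sample": samples.to_numpy(), "bin": bins.to_numpy()},
                       index=values.index)
    if groups is not None:
        key["group"] = groups.to_numpy()
    long = pd.concat([key, values], axis=1).melt(
        id_vars=list(key.columns), var_name="feature", value_name="value"
    )
    by = ["feature", "sample", "bin"] + (["group"] if groups is not None else [])
    means = long.groupby(by, observed=True)["value"].mean().reset_index()
    means = means.rename(columns={"value": "mean"})
    if groups is None:
        means["group"] = "all"
    return BinProfileSet(
        means=means,
        prevalence=prevalence.loc[list(features)],
        bin_order=tuple(bin_order),
        features=features,
    )


def _standardize_rows(mat: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score (population variance); constant rows map to zeros."""
    vals = mat.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (vals - mu) / sd_safe
    z[(sd == 0).ravel(), :] = 0.0
    return pd.DataFrame(z, index=mat.index, columns=mat.columns)


def cluster_profiles(
    profiles: pd.DataFrame, n_clusters: int | None = None
) -> dict:
    """Hierarchically cluster per-feature bin profiles with Ward linkage.

    Profiles (feature × bin) are standardized across bins before clustering
    on Euclidean distances. Equal-height merges follow SciPy's deterministic
    lowest-index order. Returns the linkage matrix, the standardized
    profiles, the leaf order, and flat cluster assignments when
    ``n_clusters`` is given.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    z = _standardize_rows(profiles.dropna(axis=1, how="any"))
    linkage = sch.linkage(z.to_numpy(), method="ward")
    leaves = sch.leaves_list(linkage)
    out = {
        "linkage": linkage,
        "standardized": z,
        "leaf_order": [z.index[i] for i in leaves],
    }
    if n_clusters is not None:
        flat = sch.fcluster(linkage, t=n_clusters, criterion="maxclust")
        out["clusters"] = pd.Series(flat, index=z.index, name="cluster")
    return out


def profile_cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity between two equal-length profiles; NaN (with a
    warning) if either is a zero vector."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("cosine similarity undefined for a zero profile")
        return float("nan")
    return float(np.dot(a, b) / (na * nb))


def group_cosine_similarity(
    profiles: BinProfileSet, group_a: str, group_b: str
) -> pd.Series:
    """Per-feature cosine similarity between two groups' bin profiles.

    Each group's profile is the median across samples of the per-sample bin
    means, compared over the bins present in both groups.
    """
    med = (
        profiles.means.groupby(["feature", "group", "bin"], observed=True)["mean"]
        .median()
        .unstack("bin")
    )
    out = {}
    for feat in profiles.features:
        try:
            pa = med.loc[(feat, group_a)]
            pb = med.loc[(feat, group_b)]
        except KeyError:
            out[feat] = float("nan")
            continue
        common = pa.index[pa.notna() & pb.notna()]
        out[feat] = profile_cosine(pa[common].to_numpy(), pb[common].to_numpy())
    return pd.Series(out, name="cosine")


def profile_anova(
    profiles: BinProfileSet,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature type-II two-way ANOVA of binned means on group, bin and
    their interaction, with Bonferroni correction across features.

    Each sample contributes one datapoint per bin, so the model is fitted on
    the per-sample-per-bin means. Features with an empty group × bin cell are
    skipped with a warning (unbalanced but nonempty designs are allowed via
    type-II sums of squares). Correction is applied separately to the three
    p-value families (group, bin, interaction).
    """
    groups = profiles.means["group"].unique()
    bins = [b for b in profiles.bin_order if b in set(profiles.means["bin"])]
    if len(groups) < 2 or len(bins) < 2:
        raise ValueError("need at least two groups and two bins")

    rows = []
    by_feature = dict(tuple(profiles.means.groupby("feature", observed=True)))
    for feat in profiles.features:
        if feat not in by_feature:
            continue
        sub = by_feature[feat].dropna(subset=["mean"])
        cells = sub.groupby(["group", "bin"], observed=True).size()
        if len(cells) < len(groups) * len(bins):
            warnings.warn(f"feature {feat!r}: empty group x bin cell; skipped")
            continue
        model = smf.ols("Q('mean') ~ C(group) * C(bin)", data=sub).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        rows.append(
            {
                "feature": feat,
                "p_group": tab.loc["C(group)", "PR(>F)"],
                "p_bin": tab.loc["C(bin)", "PR(>F)"],
                "p_interaction": tab.loc["C(group):C(bin)", "PR(>F)"],
            }
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    for col in ("p_group", "p_bin", "p_interaction"):
        res[f"{col}_bonf"] = multipletests(res[col], alpha=alpha, method="bonferroni")[1]
    return res.set_index("feature")


def detect_specialization_genes(
    counts: pd.DataFrame,
    cell_types: pd.Series,
    cell_z_cut: float = 0.05,
    min_mean: float = 1.5,
    quantile: float = 0.95,
    alpha: float = 1e-50,
) -> pd.DataFrame:
    """Screen genes whose top-expressing cells are confined to one cell type.

    Per gene: (1) genes with mean raw count below ``min_mean`` are excluded;
    (2) expression is z-scored across cells and cells with scaled expression
    below ``cell_z_cut`` are dropped from the selection pool; (3) pool cells
    at or above the pool's ``quantile`` expression threshold are selected
    (ties included); (4) a χ² test on the (selected vs not) × cell-type
    contingency table over all cells asks whether selected cells are
    over-represented in one type; (5) the gene is a specialization gene iff
    p < ``alpha`` and a single type holds the unique maximal positive
    standardized residual among selected cells, and is assigned to that type.

    Returns a table with columns included, n_selected, chi2, p,
    assigned_type, sg.
    """
    types = pd.unique(cell_types)
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    type_arr = np.asarray(cell_types)
    type_totals = np.array([(type_arr == t).sum() for t in types])

    rows = []
    for gene in counts.columns:
        x = counts[gene].to_numpy(dtype=float)
        row = {
            "gene": gene, "included": False, "n_selected": 0,
            "chi2": np.nan, "p": np.nan, "assigned_type": None, "sg": False,
        }
        if x.mean() < min_mean:
            rows.append(row)
            continue
        sd = x.std(ddof=0)
        if sd == 0:
            logger.info("gene %s constant across cells; skipped", gene)
            rows.append(row)
            continue
        z = (x - x.mean()) / sd
        pool = z >= cell_z_cut
        if not pool.any():
            logger.info("gene %s: empty selection pool; skipped", gene)
            rows.append(row)
            continue
        thr = np.quantile(x[pool], quantile)
        selected = pool & (x >= thr)
        sel_counts = np.array([(selected & (type_arr == t)).sum() for t in types])
        unsel_counts = type_totals - sel_counts
        table = np.vstack([sel_counts, unsel_counts])
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            logger.info("gene %s: degenerate contingency table; skipped", gene)
            rows.append(row)
            continue
        chi2, p, _, expected = chi2_contingency(table)
        resid = (sel_counts - expected[0]) / np.sqrt(expected[0])
        best = resid.max()
        unique_max = best > 0 and (resid == best).sum() == 1
        row.update(
            included=True,
            n_selected=int(selected.sum()),
            chi2=float(chi2),
            p=float(p),
            assigned_type=types[int(np.argmax(resid))] if unique_max else None,
            sg=bool(p < alpha and unique_max),
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


@dataclass
class VarianceAttribution:
    """Per-PC explained variance and covariate correlations, plus summed
    covariate contribution scores (percentage points of explained variance)."""

    per_pc: pd.DataFrame
    contributions: dict[str, float]
    total_explained: float


def axis_variance_score(
    counts: pd.DataFrame,
    covariates: dict[str, np.ndarray],
    samples: pd.Series | None = None,
    n_pcs: int = 10,
    target_sum: float = 2500.0,
    batch_correct: bool = True,
    seed: int = 0,
) -> VarianceAttribution:
    """Attribute PCA variance to covariates (axis position, technical depth).

    Pipeline: total-count normalization to ``target_sum`` → log1p → optional
    per-sample feature standardization → PCA with ``n_pcs`` components. Each
    covariate's contribution is Σ_i |ρ_i| · v_i, where ρ_i is the Spearman
    correlation of PC i with the covariate and v_i its explained-variance
    percentage; the residual ("other") is Σ v_i minus the covariate
    contributions, floored at 0.
    """
    if len(counts) <= n_pcs:
        raise ValueError("need more observations than principal components")
    X = lognorm(counts, target_sum=target_sum).to_numpy()
    if batch_correct and samples is not None:
        for s in pd.unique(samples):
            idx = np.asarray(samples) == s
            mu = X[idx].mean(axis=0)
            sd = X[idx].std(axis=0)
            sd[sd == 0] = 1.0
            X[idx] = (X[idx] - mu) / sd
    pca = PCA(n_components=n_pcs, random_state=seed)
    pcs = pca.fit_transform(X)
    v = pca.explained_variance_ratio_ * 100.0

    per_pc = pd.DataFrame({"pc": np.arange(1, n_pcs + 1), "explained_pct": v})
    contributions: dict[str, float] = {}
    for name, cov in covariates.items():
        cov = np.asarray(cov, dtype=float)
        if np.all(cov == cov[0]):
            warnings.warn(f"covariate {name!r} constant; contribution 0")
            rhos = np.zeros(n_pcs)
        else:
            rhos = np.array(
                [spearmanr(pcs[:, i], cov).statistic for i in range(n_pcs)]
            )
            rhos = np.nan_to_num(rhos)
        per_pc[f"rho_{name}"] = rhos
        contributions[name] = float(np.sum(np.abs(rhos) * v))
    total = float(v.sum())
    contributions["other"] = max(0.0, total - sum(contributions.values()))
    return VarianceAttribution(
        per_pc=per_pc, contributions=contributions, total_explained=total
    )


def hypercluster_axis_assignment(
    abundances: pd.DataFrame,
    axis: np.ndarray,
    percentile: float = 95.0,
) -> pd.Series:
    """Assign each cluster the abundance-weighted mean axis position of the
    spots where it is most abundant.

    Per cluster, spots above the cluster's ``percentile`` abundance are
    selected (falling back to ties at the threshold when nothing exceeds it)
    and the weighted mean axis value over those spots is assigned to the
    cluster — and thereby to all its member cells. All-zero abundance yields
    NaN with a warning.
    """
    axis = np.asarray(axis, dtype=float)
    out = {}
    for cluster in abundances.columns:
        w = abundances[cluster].to_numpy(dtype=float)
        if not np.any(w > 0):
            warnings.warn(f"cluster {cluster!r} has all-zero abundance; undefined")
            out[cluster] = float("nan")
            continue
        thr = np.percentile(w, percentile)
        sel = w > thr
        if not sel.any():
            sel = w >= thr
        out[cluster] = weighted_mean_position(w[sel], axis[sel], threshold=0.0)
    return pd.Series(out, name="axis_position")
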