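"""Weighted co-expression network analysis.

Pipeline: count filtering -> median-of-ratios normalization (log2 scale) ->
soft-power adjacency |r|^beta -> topological overlap matrix (TOM) -> average
linkage clustering with a dynamic-tree-cut style module detection -> eigengene
merging -> module-trait Pearson statistics with Bonferroni correction ->
beneficial/pathogenic classification -> optional export of a thresholded TOM
edge list as a co-expression layer for the multilayer network.

The model-object surface is :class:`WGCNA` (construct from a counts matrix and
a trait table, call :meth:`WGCNA.fit`) returning :class:`WGCNAResults`.  The
individual steps are also exposed as plain functions operating on pandas
DataFrames (features x samples for expression, samples x traits for traits).
"""

from __future__ import annotations

import logging
import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .network import Layer

logger = logging.getLogger(__name__)

__all__ = [
    "filter_features",
    "size_factors",
    "size_factor_normalize",
    "batch_correct",
    "soft_adjacency",
    "topological_overlap",
    "pick_soft_threshold",
    "detect_modules",
    "module_eigengenes",
    "module_trait_correlation",
    "classify_modules",
    "export_coexpression_layer",
    "LAYER_PRESETS",
    "GREY",
    "POSITIVE_TRAITS",
    "NEGATIVE_TRAITS",
    "WGCNA",
    "WGCNAResults",
]

GREY = "grey"

#: Muscle phenotypes where a larger value means a healthier animal.
POSITIVE_TRAITS = ("normalized_ta_mass", "relative_maximal_force", "hanging_time")
#: Muscle phenotypes where a larger value means more severe disease.
NEGATIVE_TRAITS = ("pct_central_nuclei", "pct_abnormal_mitochondria", "pct_small_fibers")

#: Soft power / TOM threshold presets used to export co-expression layers for
#: the multilayer network, one per omics type.
LAYER_PRESETS: dict[str, dict[str, float]] = {
    "transcriptomic": {"power": 10, "threshold": 0.15},
    "proteomic": {"power": 12, "threshold": 0.25},
    "metabolomic": {"power": 5, "threshold": 0.05},
}

# Module label sequence, assigned by decreasing module size (the unassigned
# label "grey" is reserved).
_MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


# ---------------------------------------------------------------------------
# Filtering and normalization


def filter_features(
    counts: pd.DataFrame, min_count: int = 10, min_fraction: float = 0.9
) -> pd.DataFrame:
    """Keep features with count > ``min_count`` in at least
    ``ceil(min_fraction * n_samples)`` samples.

    Defaults implement the "more than 10 reads in at least 90% of samples"
    rule used for bulk RNA-seq.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    need = math.ceil(min_fraction * counts.shape[1])
    keep = (counts.values > min_count).sum(axis=1) >= need
    if not keep.any():
        warnings.warn("filter_features removed every feature", stacklevel=2)
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    The geometric mean across samples is computed per feature (features with
    any zero count are excluded); each sample's factor is the median of its
    count/geomean ratios.  Falls back to library-size factors (scaled to
    geometric mean 1) when no feature is all-nonzero.
    """
    x = counts.values.astype(float)
    nonzero = (x > 0).all(axis=1)
    if not nonzero.any():
        warnings.warn(
            "no feature with all-nonzero counts; using library-size factors",
            stacklevel=2,
        )
        lib = x.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("sample with zero total counts")
        sf = lib / np.exp(np.mean(np.log(lib)))
        return pd.Series(sf, index=counts.columns, name="size_factor")
    logx = np.log(x[nonzero])
    log_geomean = logx.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logx - log_geomean, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def size_factor_normalize(counts: pd.DataFrame, log2: bool = True) -> pd.DataFrame:
    """Divide each sample by its median-of-ratios size factor.

    With ``log2`` (default) the result is log2(x + 1) transformed, the scale
    on which correlations and adjacency are computed downstream.
    """
    sf = size_factors(counts)
    norm = counts / sf
    if log2:
        norm = np.log2(norm + 1.0)
    return norm


def batch_correct(expr: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Per-feature mean-centering within each batch (cohort), then re-adding
    the global feature mean so expression stays on its original scale."""
    batches = batches.reindex(expr.columns)
    if batches.isna().any():
        raise ValueError("every sample needs a batch label")
    grand = expr.mean(axis=1)
    out = expr.copy()
    for batch in batches.unique():
        cols = batches.index[batches == batch]
        out[cols] = out[cols].sub(out[cols].mean(axis=1), axis=0).add(grand, axis=0)
    return out


# ---------------------------------------------------------------------------
# Adjacency and topological overlap


def _safe_corrcoef(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; zero-variance rows correlate at 0."""
    sd = x.std(axis=1)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance feature(s): correlations set to 0",
                      stacklevel=3)
        x = x.copy()
        x[bad] = 0.0
        # corrcoef would emit nan for these rows; compute manually
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xc**2).sum(axis=1))
    norm[norm == 0] = 1.0
    c = (xc / norm[:, None]) @ (xc / norm[:, None]).T
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    return c


def soft_adjacency(expr: pd.DataFrame, power: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |cor(x_i, x_j)|^power.

    The diagonal is 1; entries lie in [0, 1].  Zero-variance features get
    zero off-diagonal adjacency (with a warning).
    """
    if power <= 0:
        raise ValueError("power must be positive")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    corr = _safe_corrcoef(expr.values.astype(float))
    adj = np.abs(corr) ** power
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def topological_overlap(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix of an unsigned adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), where the
    sum excludes u in {i, j} and k_i is node i's connectivity (row sum minus
    the diagonal).  TOM_ii = 1.  The clustering dissimilarity is 1 - TOM.
    """
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    shared = a0 @ a0  # (i,j) entry excludes u=i and u=j since diag(a0)=0
    k = a0.sum(axis=1)
    num = shared + a0
    den = np.minimum.outer(k, k) + 1.0 - a0
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def pick_soft_threshold(
    expr: pd.DataFrame, powers: Sequence[float] = (1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 18, 20)
) -> pd.DataFrame:
    """Scale-free topology diagnostic across candidate soft powers.

    For each power, fits log10 p(k) ~ log10 k over connectivity bins and
    reports the signed fit R^2 (negated when the slope is positive, as in the
    usual scale-free criterion) and the mean connectivity.  The pipeline takes
    an explicit power; this is an advisory diagnostic only.
    """
    corr = np.abs(_safe_corrcoef(expr.values.astype(float)))
    rows = []
    for p in powers:
        a = corr**p
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        mean_k = float(k.mean())
        pos = k[k > 0]
        if len(pos) < 4:
            rows.append({"power": p, "sft_r2": np.nan, "slope": np.nan, "mean_k": mean_k})
            continue
        n_bins = min(10, max(4, len(pos) // 5))
        bins = np.quantile(pos, np.linspace(0, 1, n_bins + 1))
        bins[-1] += 1e-9
        idx = np.clip(np.digitize(pos, bins) - 1, 0, n_bins - 1)
        freq = np.bincount(idx, minlength=n_bins).astype(float)
        centers = np.array([pos[idx == b].mean() if freq[b] else np.nan for b in range(n_bins)])
        ok = (freq > 0) & np.isfinite(centers)
        if ok.sum() < 3:
            rows.append({"power": p, "sft_r2": np.nan, "slope": np.nan, "mean_k": mean_k})
            continue
        lx = np.log10(centers[ok])
        ly = np.log10(freq[ok] / freq.sum())
        slope, _, r, _, _ = stats.linregress(lx, ly)
        r2 = r**2 if slope < 0 else -(r**2)
        rows.append({"power": p, "sft_r2": r2, "slope": slope, "mean_k": mean_k})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Module detection


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _eigengene(sub: np.ndarray) -> np.ndarray:
    """First right singular vector of the z-scored submatrix, unit norm, with
    sign chosen so it correlates non-negatively with the mean profile."""
    z = _zscore_rows(sub)
    if z.shape[0] == 1:
        v = z[0]
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > 0 else v
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    ref = z.mean(axis=0)
    if np.dot(v, ref - ref.mean()) < 0:
        v = -v
    return v


def module_eigengenes(expr: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Module eigengenes: modules x samples, one unit-norm profile per module.

    The eigengene is the first principal component of the per-feature
    standardized module submatrix; its sign is fixed so that it correlates
    non-negatively with the module's mean expression profile.  The grey
    (unassigned) label is excluded.
    """
    assignment = assignment.reindex(expr.index)
    if assignment.isna().any():
        raise ValueError("assignment does not cover all features")
    rows = {}
    for label in sorted(set(assignment) - {GREY}):
        sub = expr.values[assignment.values == label].astype(float)
        rows[label] = _eigengene(sub)
    return pd.DataFrame(rows, index=expr.columns).T


def _merge_close_modules(
    expr: pd.DataFrame, assignment: pd.Series, merge_threshold: float
) -> pd.Series:
    """Iteratively merge module pairs whose eigengene correlation dissimilarity
    (1 - Pearson r) is below the threshold; recompute eigengenes after each
    merge until no pair qualifies."""
    assignment = assignment.copy()
    while True:
        labels = sorted(set(assignment) - {GREY})
        if len(labels) < 2:
            return assignment
        me = module_eigengenes(expr, assignment)
        corr = np.corrcoef(me.loc[labels].values)
        dis = 1.0 - corr
        np.fill_diagonal(dis, np.inf)
        i, j = np.unravel_index(np.argmin(dis), dis.shape)
        if dis[i, j] >= merge_threshold:
            return assignment
        a, b = labels[i], labels[j]
        # keep the label of the larger module (ties: first label)
        size_a = int((assignment == a).sum())
        size_b = int((assignment == b).sum())
        keep, gone = (a, b) if size_a >= size_b else (b, a)
        assignment[assignment == gone] = keep
        logger.info("merged module %s into %s (dissimilarity %.3f)", gone, keep, dis[i, j])


def _relabel_by_size(assignment: pd.Series) -> pd.Series:
    sizes = assignment[assignment != GREY].value_counts()
    mapping = {}
    for rank, label in enumerate(sizes.index):
        mapping[label] = (
            _MODULE_COLORS[rank] if rank < len(_MODULE_COLORS) else f"module_{rank + 1}"
        )
    return assignment.map(lambda v: GREY if v == GREY else mapping[v])


def detect_modules(
    tom_dissimilarity: pd.DataFrame | np.ndarray,
    expr: pd.DataFrame,
    min_module_size: int = 30,
    merge_threshold: float = 0.25,
    cut_height: float = 0.95,
    assign_r: float = 0.5,
) -> pd.Series:
    """Detect co-expression modules from a TOM dissimilarity matrix.

    Average-linkage hierarchical clustering of 1 - TOM; static branches are
    cut at absolute height ``cut_height`` on the dissimilarity scale (1 - TOM
    lies in [0, 1]; unrelated features sit near 1, so a conservative cut at
    0.95 keeps genuine branches apart from both the background and each
    other); clusters of at least
    ``min_module_size`` features become initial modules.  Remaining features
    are assigned to the module whose eigengene they correlate with most, if
    that correlation exceeds ``assign_r`` (default 0.5, about 2.4 null
    standard deviations at 24 samples); otherwise they are labelled grey.
    Modules with eigengene correlation dissimilarity below ``merge_threshold``
    are merged iteratively to a fixed point.  Final labels are color names
    ordered by decreasing module size.
    """
    d = np.asarray(tom_dissimilarity, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != expr.shape[0]:
        raise ValueError("dissimilarity must be square and aligned with expr features")
    labels = pd.Series(GREY, index=expr.index, dtype=object)
    if min_module_size > n:
        warnings.warn("min_module_size exceeds feature count; all features grey", stacklevel=2)
        return labels

    condensed = squareform(np.maximum(d, 0.0), checks=False)
    link = hierarchy.linkage(condensed, method="average")
    flat = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    counts = np.bincount(flat)
    module_ids = [c for c in np.unique(flat) if counts[c] >= min_module_size]
    if not module_ids:
        warnings.warn("no cluster reaches min_module_size; all features grey", stacklevel=2)
        return labels
    for k, cid in enumerate(module_ids):
        labels.iloc[np.flatnonzero(flat == cid)] = f"m{k}"

    # rescue unassigned features by eigengene correlation
    unassigned = labels.index[labels == GREY]
    if len(unassigned):
        me = module_eigengenes(expr, labels)
        z = _zscore_rows(expr.loc[unassigned].values.astype(float))
        me_z = _zscore_rows(me.values)
        zn = np.linalg.norm(z, axis=1)
        zn[zn == 0] = 1.0
        men = np.linalg.norm(me_z, axis=1)
        men[men == 0] = 1.0
        r = (z @ me_z.T) / (zn[:, None] * men[None, :])
        best = r.argmax(axis=1)
        best_r = r[np.arange(len(unassigned)), best]
        hit = best_r > assign_r
        labels.loc[unassigned[hit]] = me.index.values[best[hit]]

    labels = _merge_close_modules(expr, labels, merge_threshold)
    return _relabel_by_size(labels)


# ---------------------------------------------------------------------------
# Module-trait statistics


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    Pairwise-complete samples; two-sided p-value from the Student t statistic
    t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom; Bonferroni
    adjustment over the number of traits (p_adj = min(1, p * n_traits)).
    Constant traits or n < 3 yield rows with missing statistics.
    """
    shared = [s for s in eigengenes.columns if s in traits.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples between eigengenes and traits")
    me = eigengenes[shared]
    tr = traits.loc[shared]
    n_traits = tr.shape[1]
    rows = []
    for module in me.index:
        x_full = me.loc[module].values.astype(float)
        for trait in tr.columns:
            y_full = tr[trait].values.astype(float)
            mask = np.isfinite(y_full) & np.isfinite(x_full)
            n = int(mask.sum())
            x, y = x_full[mask], y_full[mask]
            if n < 3 or np.std(x) == 0 or np.std(y) == 0:
                rows.append(
                    {"module": module, "trait": trait, "pearson_r": np.nan,
                     "p_value": np.nan, "p_adjusted": np.nan, "n_samples": n}
                )
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            r = max(-1.0, min(1.0, r))
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * math.sqrt((n - 2) / (1.0 - r * r))
                p = 2.0 * stats.t.sf(abs(t), df=n - 2)
            rows.append(
                {"module": module, "trait": trait, "pearson_r": r,
                 "p_value": p, "p_adjusted": min(1.0, p * n_traits), "n_samples": n}
            )
    return pd.DataFrame(rows)


def classify_modules(
    result: pd.DataFrame,
    alpha: float = 0.05,
    positive_traits: Sequence[str] = POSITIVE_TRAITS,
    negative_traits: Sequence[str] = NEGATIVE_TRAITS,
) -> pd.Series:
    """Classify modules as beneficial, pathogenic, or unclassified.

    Beneficial: at least one significant (p_adjusted < alpha) positive
    correlation with a positive-outcome trait (mass, force, hanging time)
    and/or significant negative correlation with a severity trait (central
    nuclei, abnormal mitochondria, small fibers), with no significant
    correlation of the opposite pattern.  Pathogenic is the mirror image;
    anything else (including conflicting evidence) is unclassified.
    """
    present = set(result["trait"])
    pos = [t for t in positive_traits if t in present]
    neg = [t for t in negative_traits if t in present]
    for t in list(positive_traits) + list(negative_traits):
        if t not in present:
            warnings.warn(f"classification trait {t!r} missing; skipped", stacklevel=2)
    out = {}
    for module, grp in result.groupby("module", sort=True):
        sig = grp[(grp["p_adjusted"] < alpha) & grp["pearson_r"].notna()]
        benef = (
            ((sig["trait"].isin(pos)) & (sig["pearson_r"] > 0))
            | ((sig["trait"].isin(neg)) & (sig["pearson_r"] < 0))
        ).any()
        patho = (
            ((sig["trait"].isin(pos)) & (sig["pearson_r"] < 0))
            | ((sig["trait"].isin(neg)) & (sig["pearson_r"] > 0))
        ).any()
        if benef and not patho:
            out[module] = "beneficial"
        elif patho and not benef:
            out[module] = "pathogenic"
        else:
            out[module] = "unclassified"
    return pd.Series(out, name="classification")


# ---------------------------------------------------------------------------
# Layer export


def export_coexpression_layer(
    tom: pd.DataFrame, threshold: float, name: str = "coexpression", weighted: bool = True
) -> Layer:
    """Export a thresholded TOM as an undirected weighted co-expression layer.

    One edge per unordered feature pair with TOM strictly above ``threshold``;
    the edge weight is the TOM value (or 1 when ``weighted`` is False).  See
    :data:`LAYER_PRESETS` for the per-omics soft power / threshold pairings.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    t = np.asarray(tom, dtype=float)
    ids = list(tom.index)
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = t[iu, ju] > threshold
    edges = [
        (ids[i], ids[j], float(t[i, j]) if weighted else 1.0)
        for i, j in zip(iu[mask], ju[mask])
    ]
    return Layer.from_edges(name, edges, directed=False, weighted=weighted)


# ---------------------------------------------------------------------------
# Model / Results objects


@dataclass
class WGCNAResults:
    """Fitted co-expression network: module labels, eigengenes, trait stats.

    Attributes
    ----------
    modules : pd.Series
        feature -> module label ("grey" = unassigned).
    eigengenes : pd.DataFrame
        modules x samples, unit-norm first-PC summaries.
    module_trait : pd.DataFrame or None
        (module, trait) rows with pearson_r, p_value, p_adjusted, n_samples.
    classification : pd.Series or None
        module -> beneficial / pathogenic / unclassified.
    """

    model: "WGCNA"
    expr: pd.DataFrame
    tom: pd.DataFrame
    modules: pd.Series
    eigengenes: pd.DataFrame
    module_trait: pd.DataFrame | None = None
    classification: pd.Series | None = None

    @property
    def module_sizes(self) -> pd.Series:
        return self.modules.value_counts()

    def export_layer(
        self, threshold: float, name: str = "coexpression", weighted: bool = True
    ) -> Layer:
        """Thresholded TOM as a network layer (see module docstring presets)."""
        return export_coexpression_layer(self.tom, threshold, name=name, weighted=weighted)

    def summary(self) -> str:
        """Human-readable fit summary: sizes, classifications, top trait hits."""
        lines = ["Weighted co-expression network fit", "=" * 40]
        lines.append(f"features (filtered): {self.expr.shape[0]}")
        lines.append(f"samples:             {self.expr.shape[1]}")
        lines.append(f"soft power:          {self.model.power}")
        n_mod = int((self.module_sizes.index != GREY).sum())
        lines.append(f"modules:             {n_mod} (+ grey)")
        lines.append("")
        lines.append(f"{'module':<16}{'size':>6}  {'class':<14}")
        cls = self.classification if self.classification is not None else pd.Series(dtype=object)
        for label, size in self.module_sizes.items():
            lines.append(f"{label:<16}{size:>6}  {cls.get(label, '-'):<14}")
        if self.module_trait is not None:
            sig = self.module_trait[self.module_trait["p_adjusted"] < self.model.alpha]
            lines.append("")
            lines.append(f"significant module-trait correlations (p_adj < {self.model.alpha}):")
            if sig.empty:
                lines.append("  none")
            for _, row in sig.sort_values("p_adjusted").iterrows():
                lines.append(
                    f"  {row['module']:<14}{row['trait']:<26}"
                    f"r={row['pearson_r']:+.2f}  p_adj={row['p_adjusted']:.2e}"
                )
        return "\n".join(lines)

    def plot_module_trait_heatmap(self, ax=None):
        """Module x trait heatmap of Pearson r, annotated where significant."""
        if self.module_trait is None:
            raise ValueError("no trait table was supplied to the model")
        import matplotlib.pyplot as plt

        pivot = self.module_trait.pivot(index="module", columns="trait", values="pearson_r")
        padj = self.module_trait.pivot(index="module", columns="trait", values="p_adjusted")
        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * pivot.shape[1] + 2, 0.5 * pivot.shape[0] + 2))
        im = ax.imshow(pivot.values, cmap="PRGn_r", vmin=-1, vmax=1, aspect="auto")
        ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
        ax.set_yticks(range(pivot.shape[0]), pivot.index)
        for i in range(pivot.shape[0]):
            for j in range(pivot.shape[1]):
                if padj.values[i, j] < self.model.alpha:
                    ax.text(j, i, f"{pivot.values[i, j]:.2f}", ha="center", va="center",
                            fontsize=8)
        ax.figure.colorbar(im, ax=ax, label="Pearson r")
        return ax

    def to_dir(self, outdir: str | Path) -> None:
        """Write module assignment, eigengenes, trait stats, and classification
        as TSV files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.modules.rename("module").to_csv(outdir / "modules.tsv", sep="\t")
        self.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
        if self.module_trait is not None:
            self.module_trait.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
        if self.classification is not None:
            self.classification.to_csv(outdir / "classification.tsv", sep="\t")


@dataclass
class WGCNA:
    """Weighted co-expression network model for a counts matrix.

    Parameters
    ----------
    counts : pd.DataFrame
        Raw non-negative counts, features x samples.
    traits : pd.DataFrame, optional
        Samples x traits (group-averaged phenotypes; missing values allowed).
    power : float
        Soft-threshold exponent for the unsigned adjacency (default 12, the
        value used for the multi-cohort transcriptome analysis).
    min_module_size, merge_threshold, alpha
        Module detection / merging / significance parameters.
    batches : pd.Series, optional
        Sample -> cohort labels for mean-centering batch correction.
    normalize : bool
        Apply filtering + median-of-ratios normalization (set False when
        ``counts`` is already normalized, e.g. metabolite abundances on a log
        scale).
    """

    counts: pd.DataFrame
    traits: pd.DataFrame | None = None
    power: float = 12.0
    min_module_size: int = 30
    merge_threshold: float = 0.25
    alpha: float = 0.05
    min_count: int = 10
    min_fraction: float = 0.9
    batches: pd.Series | None = None
    normalize: bool = True
    positive_traits: Sequence[str] = POSITIVE_TRAITS
    negative_traits: Sequence[str] = NEGATIVE_TRAITS

    @classmethod
    def from_files(
        cls, counts_path: str | Path, traits_path: str | Path | None = None, **kwargs
    ) -> "WGCNA":
        """Build from TSV files: counts with feature ids in the first column
        and sample ids in the header; traits as samples x traits."""
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        traits = pd.read_csv(traits_path, sep="\t", index_col=0) if traits_path else None
        return cls(counts, traits, **kwargs)

    def fit(self) -> WGCNAResults:
        """Run the full pipeline and return a :class:`WGCNAResults`."""
        if self.normalize:
            filtered = filter_features(self.counts, self.min_count, self.min_fraction)
            expr = size_factor_normalize(filtered)
        else:
            expr = self.counts.astype(float)
        if self.batches is not None:
            expr = batch_correct(expr, self.batches)
        adj = soft_adjacency(expr, self.power)
        tom = topological_overlap(adj)
        assignment = detect_modules(
            1.0 - tom.values, expr,
            min_module_size=self.min_module_size,
            merge_threshold=self.merge_threshold,
        )
        eigengenes = module_eigengenes(expr, assignment)
        module_trait = None
        classification = None
        if self.traits is not None and not eigengenes.empty:
            module_trait = module_trait_correlation(eigengenes, self.traits)
            classification = classify_modules(
                module_trait, self.alpha, self.positive_traits, self.negative_traits
            )
        return WGCNAResults(
            model=self,
            expr=expr,
            tom=tom,
            modules=assignment,
            eigengenes=eigengenes,
            module_trait=module_trait,
            classification=classification,
        )
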