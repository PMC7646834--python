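"""Statistics on label-free protein quantification tables.

The input is a MaxQuant-style ``proteinGroups`` table: protein rows, one LFQ
intensity column per extraction-spot sample, plus decoy/contaminant flag
columns.  The processing chain mirrors the standard Perseus workflow for
FFPE microproteomics:

    flag filter -> log2 -> valid-value filter -> one-way ANOVA + BH FDR
    -> (for PCA / classification only) down-shifted normal imputation
    -> Z-scoring, hierarchical clustering, PCA with 95% prediction ellipses

ANOVA runs on the unimputed valid values; imputation is applied afterwards
and only for the multivariate views, so MNAR imputation cannot inflate the
differential statistics.

Missing values are explicit ``NaN`` in memory.  Raw zeros in input tables
are treated as missing (the MaxQuant convention for absent LFQ values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProteinQuantTable",
    "DifferentialResult",
    "read_protein_groups",
    "filter_flags",
    "log_transform",
    "filter_valid",
    "anova_bh",
    "impute_normal",
    "zscore_rows",
    "hcluster",
    "pca_with_ellipses",
    "prediction_ellipse",
    "volcano_compare",
    "PredictionEllipse",
]

FLAG_COLUMNS = {
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
    "only_by_site": "Only identified by site",
}


@dataclass
class ProteinQuantTable:
    """Protein rows x extraction-spot sample columns with explicit missingness.

    ``intensities`` is a proteins x samples float array with NaN for missing
    values.  ``scale`` tracks whether values are raw LFQ intensities or
    log2-transformed; every transform checks it so the chain cannot be run
    out of order.
    """

    protein_ids: list[str]
    intensities: np.ndarray
    sample_meta: pd.DataFrame  # columns: sample_id, patient_id, class, spot_id
    flags: pd.DataFrame | None = None  # boolean columns: contaminant, reverse, only_by_site
    scale: str = "raw"
    ground_truth: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        n, m = self.intensities.shape
        if len(self.protein_ids) != n:
            raise ValueError("protein_ids length must match intensity rows")
        if len(self.sample_meta) != m:
            raise ValueError("sample_meta length must match intensity columns")
        if self.sample_meta["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        if self.flags is None:
            self.flags = pd.DataFrame(
                False, index=range(n),
                columns=["contaminant", "reverse", "only_by_site"],
            )
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "raw":
            with np.errstate(invalid="ignore"):
                if np.any(self.intensities <= 0):
                    raise ValueError("raw intensities must be positive where present")

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_meta["sample_id"])

    @property
    def classes(self) -> np.ndarray:
        return self.sample_meta["class"].to_numpy()

    def subset_rows(self, keep: np.ndarray) -> "ProteinQuantTable":
        keep = np.asarray(keep)
        return replace(
            self,
            protein_ids=[self.protein_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool else [self.protein_ids[i] for i in keep],
            intensities=self.intensities[keep],
            flags=self.flags.iloc[keep].reset_index(drop=True),
        )

    def subset_samples(self, keep: Sequence[int]) -> "ProteinQuantTable":
        keep = list(keep)
        return replace(
            self,
            intensities=self.intensities[:, keep],
            sample_meta=self.sample_meta.iloc[keep].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.protein_ids,
                            columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> Path:
        """Write in the MaxQuant proteinGroups dialect (missing -> 0, flags -> '+')."""
        path = Path(path)
        out = pd.DataFrame({"Majority protein IDs": self.protein_ids})
        vals = self.intensities
        if self.scale == "log2":
            vals = np.power(2.0, vals)
        for j, sid in enumerate(self.sample_ids):
            col = vals[:, j].copy()
            col[np.isnan(col)] = 0.0
            out[f"LFQ intensity {sid}"] = col
        for key, colname in FLAG_COLUMNS.items():
            out[colname] = np.where(self.flags[key].to_numpy(), "+", "")
        out.to_csv(path, sep="\t", index=False)
        return path


def read_protein_groups(path: str | Path, sample_meta: pd.DataFrame | str | Path,
                        ) -> ProteinQuantTable:
    """Read a proteinGroups-style TSV plus a sample metadata TSV.

    ``sample_meta`` needs columns sample_id, patient_id, class, spot_id; the
    LFQ columns used are ``LFQ intensity <sample_id>``.  Zeros become NaN.
    """
    df = pd.read_csv(path, sep="\t")
    if isinstance(sample_meta, (str, Path)):
        sample_meta = pd.read_csv(sample_meta, sep="\t")
    sample_meta = sample_meta.reset_index(drop=True)
    cols = [f"LFQ intensity {s}" for s in sample_meta["sample_id"]]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise KeyError(f"missing LFQ columns: {missing_cols[:3]}")
    vals = df[cols].to_numpy(dtype=np.float64)
    vals[vals == 0.0] = np.nan
    flags = pd.DataFrame({
        key: df.get(colname, pd.Series("", index=df.index)).fillna("").astype(str).str.strip() == "+"
        for key, colname in FLAG_COLUMNS.items()
    })
    return ProteinQuantTable(
        protein_ids=list(df["Majority protein IDs"].astype(str)),
        intensities=vals,
        sample_meta=sample_meta,
        flags=flags,
        scale="raw",
    )


# ---------------------------------------------------------------------------
# Filtering and transforms


def filter_flags(table: ProteinQuantTable) -> ProteinQuantTable:
    """Drop rows flagged contaminant, reverse or only-identified-by-site."""
    bad = table.flags[["contaminant", "reverse", "only_by_site"]].any(axis=1).to_numpy()
    return table.subset_rows(~bad)


def log_transform(table: ProteinQuantTable, base: float = 2.0) -> ProteinQuantTable:
    """log-transform present values; missing stays missing; scale becomes log2."""
    if table.scale != "raw":
        raise ValueError("table is already log-transformed")
    vals = table.intensities
    bad = np.argwhere(np.nan_to_num(vals, nan=1.0) <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"nonpositive intensity for protein {table.protein_ids[i]!r} "
            f"sample {table.sample_ids[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        out = np.log(vals) / np.log(base)
    return replace(table, intensities=out, scale="log2")


def filter_valid(table: ProteinQuantTable, min_fraction: float = 0.70) -> ProteinQuantTable:
    """Keep proteins quantified in at least ``min_fraction`` of all samples (inclusive)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    valid = np.sum(~np.isnan(table.intensities), axis=1)
    keep = valid / table.n_samples >= min_fraction
    return table.subset_rows(keep)


# ---------------------------------------------------------------------------
# Differential analysis


@dataclass
class DifferentialResult:
    """Per-protein one-way ANOVA with Benjamini-Hochberg FDR control."""

    protein_ids: list[str]
    group_means: pd.DataFrame  # proteins x classes
    f_stat: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    significant: np.ndarray  # bool, q <= fdr among testable proteins
    testable: np.ndarray
    fdr: float

    def to_frame(self) -> pd.DataFrame:
        out = self.group_means.copy()
        out["F"] = self.f_stat
        out["p"] = self.p_value
        out["q"] = self.q_value
        out["significant"] = self.significant
        return out


def anova_bh(table: ProteinQuantTable, fdr: float = 0.01,
             class_labels: Sequence[str] | None = None) -> DifferentialResult:
    """One-way ANOVA per protein across classes, BH step-up over tested proteins.

    Proteins with fewer than 2 valid values in any class are marked
    untestable (p = q = NaN, never significant).  ANOVA uses valid values
    only — run this before imputation.
    """
    if table.scale != "log2":
        raise ValueError("anova_bh expects log2-scale data")
    labels = np.asarray(class_labels if class_labels is not None else table.classes)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two classes")

    n = table.n_proteins
    f_stat = np.full(n, np.nan)
    p_value = np.full(n, np.nan)
    testable = np.zeros(n, dtype=bool)
    means = np.full((n, len(groups)), np.nan)
    group_cols = [np.flatnonzero(labels == g) for g in groups]

    for i in range(n):
        row = table.intensities[i]
        samples = [row[cols][~np.isnan(row[cols])] for cols in group_cols]
        for g, s in enumerate(samples):
            if s.size:
                means[i, g] = s.mean()
        if any(s.size < 2 for s in samples):
            continue
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            # all values identical: F undefined, treat as null
            f_stat[i], p_value[i] = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f, p = stats.f_oneway(*samples)
            f_stat[i], p_value[i] = f, (1.0 if np.isnan(p) else p)
        testable[i] = True

    q_value = np.full(n, np.nan)
    significant = np.zeros(n, dtype=bool)
    if testable.any():
        rej, q, _, _ = multipletests(p_value[testable], alpha=fdr, method="fdr_bh")
        q_value[testable] = q
        significant[testable] = rej
    return DifferentialResult(
        protein_ids=list(table.protein_ids),
        group_means=pd.DataFrame(means, index=table.protein_ids, columns=list(groups)),
        f_stat=f_stat, p_value=p_value, q_value=q_value,
        significant=significant, testable=testable, fdr=fdr,
    )


# ---------------------------------------------------------------------------
# Imputation and multivariate views


def impute_normal(table: ProteinQuantTable, width: float = 0.3,
                  downshift: float = 1.8, seed: int = 0) -> ProteinQuantTable:
    """Replace missing values by draws from a down-shifted normal, per column.

    For each sample column with valid mean mu and SD sigma, missing entries
    are drawn from Normal(mu - downshift * sigma, (width * sigma)^2) — the
    standard Perseus model for values missing because they fell below the
    detection limit.  Valid values are never altered.
    """
    if table.scale != "log2":
        raise ValueError("impute_normal expects log2-scale data")
    rng = np.random.default_rng(seed)
    vals = table.intensities.copy()
    for j in range(vals.shape[1]):
        col = vals[:, j]
        miss = np.isnan(col)
        valid = col[~miss]
        if valid.size < 3:
            raise ValueError(
                f"sample {table.sample_ids[j]!r} has {valid.size} valid values; "
                "need >= 3 to estimate the imputation distribution"
            )
        if not miss.any():
            continue
        mu, sigma = valid.mean(), valid.std(ddof=1)
        col[miss] = rng.normal(mu - downshift * sigma, width * sigma, size=miss.sum())
    return replace(table, intensities=vals)


def zscore_rows(matrix: np.ndarray, protein_ids: Sequence[str] | None = None) -> np.ndarray:
    """Center and scale each row to mean 0, SD 1 (population SD)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValueError("zscore_rows needs a 2-D matrix with >= 2 columns")
    sd = matrix.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        name = protein_ids[bad[0]] if protein_ids is not None else f"row {bad[0]}"
        raise ValueError(f"constant row cannot be Z-scored: {name}")
    return (matrix - matrix.mean(axis=1, keepdims=True)) / sd[:, None]


def hcluster(matrix: np.ndarray, axis: int = 1, distance: str = "correlation",
             linkage: str = "average") -> tuple[np.ndarray, list[int]]:
    """Agglomerative clustering along ``axis`` (1 = columns/samples).

    Returns the scipy linkage matrix and the dendrogram leaf order.
    Defaults (correlation distance, average linkage) follow the heatmap
    conventions of the visualization tools common in proteomics.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("hcluster requires finite values (impute first)")
    data = matrix.T if axis == 1 else matrix
    if data.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    dists = pdist(data, metric=distance)
    tree = hierarchy.linkage(dists, method=linkage)
    order = list(hierarchy.leaves_list(tree))
    return tree, order


@dataclass
class PredictionEllipse:
    """95% (or other level) prediction ellipse for a group's 2-D PCA scores.

    A new observation from the same population falls inside with the stated
    probability; based on the F-distributed Hotelling statistic
    (x - xbar)' S^-1 (x - xbar) <= 2 (n-1)(n+1) / (n (n-2)) * F_level(2, n-2).
    """

    group: str
    center: np.ndarray
    covariance: np.ndarray
    radius_sq: float  # threshold on the Mahalanobis-squared distance
    level: float

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        solve = np.linalg.solve(self.covariance, d.T)
        return np.einsum("ij,ji->i", d, solve)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.mahalanobis_sq(points) <= self.radius_sq


def prediction_ellipse(points: np.ndarray, group: str = "",
                       level: float = 0.95) -> PredictionEllipse:
    """Prediction ellipse for a new observation from one group's 2-D scores."""
    pts = np.asarray(points, dtype=np.float64)[:, :2]
    n = pts.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 points for an ellipse, got {n}")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    fq = stats.f.ppf(level, 2, n - 2)
    radius_sq = 2.0 * (n - 1) * (n + 1) / (n * (n - 2)) * fq
    return PredictionEllipse(str(group), center, cov, radius_sq, level)


def pca_with_ellipses(matrix: np.ndarray, groups: Sequence[str], level: float = 0.95,
                      n_components: int = 4):
    """PCA scores of samples plus per-group 2-D prediction ellipses on PC1/PC2.

    ``matrix`` is proteins x samples (complete, post-imputation); samples are
    the PCA observations.  Groups with fewer than 3 members get no ellipse
    (covariance is degenerate) — a warning is issued instead.

    Returns (scores, explained_variance_ratio, ellipses dict).
    """
    from sklearn.decomposition import PCA

    X = np.asarray(matrix, dtype=np.float64).T  # samples x proteins
    groups = np.asarray(groups)
    if len(groups) != X.shape[0]:
        raise ValueError("groups length must match sample count")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)

    ellipses: dict[str, PredictionEllipse] = {}
    for g in np.unique(groups):
        pts = scores[groups == g, :2]
        if pts.shape[0] < 3:
            warnings.warn(f"group {g!r} has {pts.shape[0]} samples; ellipse omitted")
            continue
        ellipses[str(g)] = prediction_ellipse(pts, g, level)
    return scores, pca.explained_variance_ratio_, ellipses


# ---------------------------------------------------------------------------
# Two-group volcano contrast (MSI-cluster-guided comparison)


def volcano_compare(table: ProteinQuantTable, group_a: Sequence[str],
                    group_b: Sequence[str], p_max: float = 0.01,
                    min_fold: float = 2.0) -> pd.DataFrame:
    """Welch two-sample contrast of B vs. A on log2 values.

    A protein is significant iff p <= p_max and |mean_B - mean_A| >=
    log2(min_fold); ``difference`` is B - A, so positive means higher in B.
    Proteins with fewer than 2 valid values on either side are untested.
    """
    if table.scale != "log2":
        raise ValueError("volcano_compare expects log2-scale data")
    ids = table.sample_ids
    ia = [ids.index(s) for s in group_a]
    ib = [ids.index(s) for s in group_b]
    if not ia or not ib:
        raise ValueError("both groups must be non-empty")
    rows = []
    for i in range(table.n_proteins):
        a = table.intensities[i, ia]
        b = table.intensities[i, ib]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            rows.append((table.protein_ids[i], np.nan, np.nan, False, False))
            continue
        diff = b.mean() - a.mean()
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = 0.0 if diff != 0 else 1.0
        else:
            _, p = stats.ttest_ind(b, a, equal_var=False)
        sig = (p <= p_max) and (abs(diff) >= np.log2(min_fold))
        rows.append((table.protein_ids[i], diff, p, sig, True))
    return pd.DataFrame(rows, columns=["protein", "difference", "p", "significant",
                                       "tested"]).set_index("protein")
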