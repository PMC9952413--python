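"""Classification, feature selection, regression, feature clustering and
the two-group segment assignment.

The pipeline mirrors the assessment workflow: segments are classified by
model-vs-experiment RMSD into excellent (<= b1), average, and poor
(>= b2) with boundaries either fixed (the published 1.76 / 4.13 A) or
optimized so the feature distributions of the extreme classes are most
distinctive under the Mann-Whitney U-test; features separating excellent
from poor at p < alpha are selected; RMSD is regressed on the selected
features by OLS (t-values rank the contributions, segments beyond an
RMSD outlier threshold are excluded from the fit); the selected features
are Ward-clustered on sign-aligned correlation distances into two
groups; and each segment is assigned to the feature group whose removal
(zeroing its coefficients) perturbs its predicted RMSD more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ProsfoldError

DEFAULT_BOUNDARIES = (1.76, 4.13)
DEFAULT_ALPHA = 0.01
DEFAULT_OUTLIER_THRESHOLD = 7.0

CLASS_LABELS = ("excellent", "average", "poor")


# ---------------------------------------------------------------------------
# Mann-Whitney U

def mann_whitney(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test; returns (U of x, p).

    Exact p by enumeration when both samples have at most ``exact_max_n``
    observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ProsfoldError("Mann-Whitney requires two non-empty samples")
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (x.size <= exact_max_n and y.size <= exact_max_n and no_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# classification

def classify(rmsd: float, b1: float = DEFAULT_BOUNDARIES[0],
             b2: float = DEFAULT_BOUNDARIES[1]) -> str:
    """Class label with inclusive boundaries: <= b1 excellent, >= b2 poor."""
    if not b1 < b2:
        raise ProsfoldError(f"boundaries must satisfy b1 < b2, got {b1}, {b2}")
    if rmsd <= b1:
        return "excellent"
    if rmsd >= b2:
        return "poor"
    return "average"


def classify_all(rmsds, b1: float = DEFAULT_BOUNDARIES[0],
                 b2: float = DEFAULT_BOUNDARIES[1]) -> np.ndarray:
    return np.array([classify(r, b1, b2) for r in np.asarray(rmsds, dtype=float)])


def optimize_boundaries(rmsds, features: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                        min_class_fraction: float = 0.2,
                        max_candidates: int = 40) -> tuple[float, float]:
    """Grid search for the class boundaries (b1, b2).

    Candidates are midpoints of adjacent sorted RMSDs (quantile-thinned
    to at most ``max_candidates``).  Among ordered pairs where each class
    holds at least ``min_class_fraction`` of segments, the pair
    maximizing the number of features with p(excellent vs poor) < alpha
    wins; ties are broken by the smallest sum of log10 p over all
    features.
    """
    rmsds = np.asarray(rmsds, dtype=float)
    n = rmsds.size
    if n < 30:
        raise ProsfoldError(f"boundary optimization needs >= 30 segments, got {n}")
    cols = [c for c in features.columns if c not in ("pros_id", "rmsd")]
    if not cols:
        raise ProsfoldError("no feature columns to optimize boundaries on")

    srt = np.sort(np.unique(rmsds))
    mids = (srt[:-1] + srt[1:]) / 2.0
    if mids.size > max_candidates:
        take = np.unique(np.linspace(0, mids.size - 1, max_candidates).round().astype(int))
        mids = mids[take]

    x = features[cols].to_numpy(dtype=float)
    best = None
    for i, b1 in enumerate(mids):
        exc = rmsds <= b1
        if exc.sum() < min_class_fraction * n:
            continue
        for b2 in mids[i + 1:]:
            poor = rmsds >= b2
            avg = ~exc & ~poor
            if poor.sum() < min_class_fraction * n or avg.sum() < min_class_fraction * n:
                continue
            count, log_p_sum = 0, 0.0
            for k in range(x.shape[1]):
                _, p = mann_whitney(x[exc, k], x[poor, k])
                count += p < alpha
                log_p_sum += np.log10(max(p, 1e-300))
            key = (count, -log_p_sum)  # maximize both
            if best is None or key > best[0]:
                best = (key, (float(b1), float(b2)))
    if best is None:
        raise ProsfoldError("no boundary pair satisfies the class-occupancy constraint")
    return best[1]


# ---------------------------------------------------------------------------
# feature selection

@dataclass
class SelectionResult:
    p_excellent_vs_poor: dict[str, float]
    p_excellent_vs_average: dict[str, float]
    p_average_vs_poor: dict[str, float]
    selected: list[str]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "feature": f,
            "p_ex_vs_poor": self.p_excellent_vs_poor[f],
            "p_ex_vs_avg": self.p_excellent_vs_average.get(f, np.nan),
            "p_avg_vs_poor": self.p_average_vs_poor.get(f, np.nan),
            "selected": f in self.selected,
        } for f in self.p_excellent_vs_poor]
        return pd.DataFrame(rows)


def select_features(features: pd.DataFrame, labels, alpha: float = DEFAULT_ALPHA,
                    ) -> SelectionResult:
    """Mann-Whitney screening of every feature between the classes.

    A feature is selected when its excellent-vs-poor two-sided p-value is
    below alpha.  No multiple-testing correction is applied: the screen
    is reported with raw p-values.
    """
    labels = np.asarray(labels)
    cols = [c for c in features.columns if c not in ("pros_id", "rmsd")]
    masks = {lab: labels == lab for lab in CLASS_LABELS}
    if masks["excellent"].sum() < 2 or masks["poor"].sum() < 2:
        raise ProsfoldError("need at least 2 segments in the excellent and poor classes")

    p_ep, p_ea, p_ap = {}, {}, {}
    for c in cols:
        v = features[c].to_numpy(dtype=float)
        _, p_ep[c] = mann_whitney(v[masks["excellent"]], v[masks["poor"]])
        if masks["average"].sum() >= 2:
            _, p_ea[c] = mann_whitney(v[masks["excellent"]], v[masks["average"]])
            _, p_ap[c] = mann_whitney(v[masks["average"]], v[masks["poor"]])
    selected = [c for c in cols if p_ep[c] < alpha]
    return SelectionResult(p_excellent_vs_poor=p_ep, p_excellent_vs_average=p_ea,
                           p_average_vs_poor=p_ap, selected=selected, alpha=alpha)


# ---------------------------------------------------------------------------
# regression

@dataclass
class RegressionModel:
    feature_names: list[str]
    coefficients: np.ndarray       # per feature
    intercept: float
    t_values: dict[str, float]     # per feature plus "intercept"
    r_squared: float
    pearson_r: float
    outlier_mask: np.ndarray       # True where the row was excluded
    n_used: int

    def predict(self, features: pd.DataFrame,
                zero_features: list[str] | None = None) -> np.ndarray:
        """Predicted RMSD; ``zero_features`` lists coefficients forced to
        zero (the intercept is always kept)."""
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise ProsfoldError(f"feature table lacks columns {missing}")
        beta = self.coefficients.copy()
        if zero_features:
            unknown = set(zero_features) - set(self.feature_names)
            if unknown:
                raise ProsfoldError(f"cannot zero unknown features {sorted(unknown)}")
            for f in zero_features:
                beta[self.feature_names.index(f)] = 0.0
        x = features[self.feature_names].to_numpy(dtype=float)
        return self.intercept + x @ beta

    def to_dict(self) -> dict:
        return {
            "features": self.feature_names,
            "coefficients": dict(zip(self.feature_names, self.coefficients.tolist())),
            "intercept": self.intercept,
            "t_values": self.t_values,
            "r_squared": self.r_squared,
            "pearson_r": self.pearson_r,
            "n_used": self.n_used,
            "n_outliers": int(self.outlier_mask.sum()),
        }


def drop_collinear(features: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Greedy split of feature columns into (kept, dropped) so the kept
    design (with intercept) has full rank.  Columns are scanned in table
    order; a column that adds no rank is dropped."""
    cols = [c for c in features.columns if c not in ("pros_id", "rmsd")]
    x = features[cols].to_numpy(dtype=float)
    design = np.ones((x.shape[0], 1))
    kept, dropped = [], []
    for k, c in enumerate(cols):
        cand = np.column_stack([design, x[:, k]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(design):
            design = cand
            kept.append(c)
        else:
            dropped.append(c)
    return kept, dropped


def fit_regression(features: pd.DataFrame, rmsds,
                   outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
                   ) -> RegressionModel:
    """OLS of RMSD on the feature columns, with intercept.

    Rows whose TRUE RMSD exceeds ``outlier_threshold`` (pass inf to keep
    all) are excluded before fitting; classical t-values, R-squared, and
    the Pearson correlation of fitted vs true RMSD are reported on the
    rows used.
    """
    import statsmodels.api as sm

    y = np.asarray(rmsds, dtype=float)
    cols = [c for c in features.columns if c not in ("pros_id", "rmsd")]
    x = features[cols].to_numpy(dtype=float)
    outlier_mask = y > outlier_threshold
    use = ~outlier_mask
    if use.sum() <= len(cols) + 1:
        raise ProsfoldError(
            f"{use.sum()} usable rows for {len(cols)} features; need more rows")

    design = sm.add_constant(x[use], has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the collinear columns for the error message
        bad = []
        keep = [0]
        for k in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, keep + [k]]) == len(keep):
                bad.append(cols[k - 1])
            else:
                keep.append(k)
        raise ProsfoldError(f"rank-deficient design; collinear features: {bad}")

    fit = sm.OLS(y[use], design).fit()
    predicted = fit.predict(design)
    r = float(np.corrcoef(predicted, y[use])[0, 1])
    t_values = {"intercept": float(fit.tvalues[0])}
    t_values.update({c: float(t) for c, t in zip(cols, fit.tvalues[1:])})
    return RegressionModel(
        feature_names=cols,
        coefficients=np.asarray(fit.params[1:], dtype=float),
        intercept=float(fit.params[0]),
        t_values=t_values,
        r_squared=float(fit.rsquared),
        pearson_r=r,
        outlier_mask=outlier_mask,
        n_used=int(use.sum()),
    )


# ---------------------------------------------------------------------------
# feature clustering

@dataclass
class FeatureGroups:
    linkage: np.ndarray
    group1: list[str]
    group2: list[str]
    sign_flips: dict[str, int] = field(default_factory=dict)

    @property
    def all_features(self) -> list[str]:
        return self.group1 + self.group2

    def to_dict(self) -> dict:
        return {"group1": self.group1, "group2": self.group2,
                "sign_flips": self.sign_flips}


def cluster_features(features: pd.DataFrame, rmsds) -> FeatureGroups:
    """Ward clustering of features on sign-aligned correlation distances.

    Each feature is negated when its Pearson correlation with RMSD is
    negative, so all features increase along RMSD; the pairwise distance
    is then 1 - r (range 0..2) and the Ward tree is cut at its root into
    two groups.  Group 1 is the cluster containing the feature most
    correlated (in magnitude) with RMSD.
    """
    y = np.asarray(rmsds, dtype=float)
    cols = [c for c in features.columns if c not in ("pros_id", "rmsd")]
    if len(cols) < 3:
        raise ProsfoldError(f"need >= 3 features to cluster, got {len(cols)}")
    x = features[cols].to_numpy(dtype=float)
    sds = x.std(axis=0)
    for c, sd in zip(cols, sds):
        if sd == 0:
            raise ProsfoldError(f"feature {c!r} is constant; cannot correlate")

    corr_y = np.array([np.corrcoef(x[:, k], y)[0, 1] for k in range(len(cols))])
    flips = np.where(corr_y < 0, -1.0, 1.0)
    xf = x * flips

    corr = np.corrcoef(xf, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    assign = hierarchy.fcluster(linkage, t=2, criterion="maxclust")

    lead = int(np.argmax(np.abs(corr_y)))
    lead_cluster = assign[lead]
    group1 = [c for c, a in zip(cols, assign) if a == lead_cluster]
    group2 = [c for c, a in zip(cols, assign) if a != lead_cluster]
    return FeatureGroups(
        linkage=linkage, group1=group1, group2=group2,
        sign_flips={c: int(f) for c, f in zip(cols, flips)},
    )


# ---------------------------------------------------------------------------
# group assignment

def assign_groups(model: RegressionModel, groups: FeatureGroups,
                  features: pd.DataFrame) -> pd.DataFrame:
    """Ablated-prediction group assignment per segment.

    rmsd_all is the full prediction; rmsd_1 zeroes the group-2
    coefficients (keeping the intercept) and rmsd_2 zeroes group 1.  A
    segment is group 1 when dropping group 1 perturbs its prediction
    more, i.e. |rmsd_all - rmsd_2| > |rmsd_all - rmsd_1|; ties go to
    group 2.
    """
    extra = set(groups.all_features) - set(model.feature_names)
    if extra:
        raise ProsfoldError(f"groups mention features absent from the model: {sorted(extra)}")
    rmsd_all = model.predict(features)
    rmsd_1 = model.predict(features, zero_features=groups.group2)
    rmsd_2 = model.predict(features, zero_features=groups.group1)
    d1 = np.abs(rmsd_all - rmsd_1)
    d2 = np.abs(rmsd_all - rmsd_2)
    group = np.where(d2 > d1, 1, 2)
    out = pd.DataFrame({
        "rmsd_all": rmsd_all, "rmsd_1": rmsd_1, "rmsd_2": rmsd_2,
        "d1": d1, "d2": d2, "group": group,
    })
    if "pros_id" in features.columns:
        out.insert(0, "pros_id", features["pros_id"].to_numpy())
    return out
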