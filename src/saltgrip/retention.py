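"""Salt Tolerance Score (S-score): a PCA-derived retention metric.

A TF's retention at a motif is proxied by how its ChIP signal decays as the
salt stringency rises.  The per-motif signal across the ordered salt
conditions is log2(1+x)-transformed, each condition column standardized, and
the first principal component extracted; PC1, oriented so that the loading on
the highest-stringency condition is positive (larger score = more retained),
is the S-score.

The module is organised around a Model/Results pair: build
``SaltToleranceModel`` from a motifs x conditions signal matrix, call
``fit()``, and the returned ``SScoreResults`` carries the scores, loadings,
variance explained and a ``summary()`` table, plus the matched-grouping and
rank-evaluation analyses that consume the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class SaltToleranceModel:
    """PCA retention model over a salt-series signal matrix.

    Parameters
    ----------
    signal : DataFrame, motifs x conditions, columns ordered by increasing
        stringency (lowest salt first).  Values are pooled-replicate RPM.
    log_transform : apply log2(1+x) before standardization (default True).
    """

    def __init__(self, signal: pd.DataFrame, log_transform: bool = True) -> None:
        if signal.shape[0] < 3:
            raise ValueError("at least 3 motifs are required")
        if signal.shape[1] < 2:
            raise ValueError("at least 2 conditions are required")
        if (signal.to_numpy() < 0).any():
            raise ValueError("signals must be >= 0")
        self.signal = signal
        self.log_transform = log_transform

    @classmethod
    def from_libraries(
        cls,
        libraries: dict[str, object],
        motifs: pd.DataFrame,
        window: int = 80,
        **kwargs,
    ) -> "SaltToleranceModel":
        """Quantify fragment libraries at motif windows and build the model."""
        from .occupancy import quantify_signal_matrix

        matrix = quantify_signal_matrix(libraries, motifs, window=window)
        return cls(matrix, **kwargs)

    def fit(self) -> "SScoreResults":
        x = self.signal.to_numpy(dtype=float)
        if self.log_transform:
            x = np.log2(1.0 + x)
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            bad = self.signal.columns[np.flatnonzero(zero)[0]]
            raise ValueError(f"zero-variance condition column: {bad!r}")
        z = (x - mean) / sd
        # PC1 via SVD of the standardized matrix
        _, svals, vt = np.linalg.svd(z, full_matrices=False)
        loadings = vt.T  # columns = PCs, unit norm
        if loadings[-1, 0] < 0:  # orient PC1 by the highest-stringency loading
            loadings[:, 0] = -loadings[:, 0]
        scores = z @ loadings
        var = svals**2 / (len(z) - 1)
        var_frac = var / z.var(axis=0, ddof=1).sum()
        return SScoreResults(
            model=self,
            sscore=pd.Series(scores[:, 0], index=self.signal.index, name="sscore"),
            loadings=pd.DataFrame(
                loadings,
                index=self.signal.columns,
                columns=[f"PC{i + 1}" for i in range(loadings.shape[1])],
            ),
            variance_explained=pd.Series(
                var_frac, index=[f"PC{i + 1}" for i in range(len(var_frac))]
            ),
            preprocessing=(
                "log2(1+x), column z-score (ddof=1)"
                if self.log_transform
                else "column z-score (ddof=1)"
            ),
        )


@dataclass
class SScoreResults:
    """Fitted S-score table with loadings and diagnostics."""

    model: SaltToleranceModel
    sscore: pd.Series
    loadings: pd.DataFrame
    variance_explained: pd.Series
    preprocessing: str

    def summary(self) -> str:
        lines = [
            "Salt Tolerance Score (PC1 of salt-series signal)",
            "=" * 48,
            f"motifs:        {len(self.sscore)}",
            f"conditions:    {', '.join(map(str, self.loadings.index))}",
            f"preprocessing: {self.preprocessing}",
            "",
            "PC1 loadings (sign: highest stringency positive):",
        ]
        for cond, v in self.loadings["PC1"].items():
            lines.append(f"  {cond:>12}: {v:+.4f}")
        lines.append("")
        lines.append("variance explained:")
        for pc, v in self.variance_explained.items():
            lines.append(f"  {pc}: {v:.4f}")
        return "\n".join(lines)

    def matched_grouping(
        self, match_signal: pd.Series, k: int = 6, n_bins: int = 20
    ) -> "MotifGrouping":
        return sscore_matched_grouping(self.sscore, match_signal, k=k, n_bins=n_bins)

    def to_frame(self) -> pd.DataFrame:
        return self.sscore.to_frame()

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.sscore.to_numpy(), bins=50)
        ax.set_xlabel("S-score (PC1)")
        ax.set_ylabel("motifs")
        return ax


def compute_sscore(signal: pd.DataFrame, log_transform: bool = True) -> SScoreResults:
    """Functional wrapper: fit the salt-tolerance PCA on a signal matrix."""
    return SaltToleranceModel(signal, log_transform=log_transform).fit()


# ---------------------------------------------------------------------------
# signal-matched sampling and grouping


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        return np.zeros(len(values), dtype=int)
    return np.clip(np.searchsorted(edges, values, side="right") - 1, 0, len(edges) - 2)


def signal_matched_sampling(
    groups: pd.Series,
    match_signal: pd.Series,
    n_bins: int = 20,
    seed: int = 0,
) -> dict[str, pd.Index]:
    """Subsample groups to equal counts within global quantile bins of the
    matching signal, so the sampled groups share its distribution.

    Bins where any group is empty are dropped.  Returns the retained motif
    index per group label.
    """
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups to match")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    groups, match_signal = groups.align(match_signal, join="inner")
    rng = np.random.default_rng(seed)
    bins = pd.Series(
        _quantile_bins(match_signal.to_numpy(dtype=float), n_bins),
        index=match_signal.index,
    )
    labels = sorted(groups.unique())
    kept: dict[str, list] = {g: [] for g in labels}
    any_bin = False
    for b in np.unique(bins):
        members = {
            g: groups.index[(groups == g) & (bins == b)] for g in labels
        }
        m = min(len(ix) for ix in members.values())
        if m == 0:
            continue
        any_bin = True
        for g, ix in members.items():
            take = rng.choice(len(ix), size=m, replace=False)
            kept[g].extend(ix[np.sort(take)])
    if not any_bin:
        raise ValueError("no quantile bin contains all groups")
    return {g: pd.Index(v) for g, v in kept.items()}


@dataclass
class MotifGrouping:
    """k retention-graded groups with matched auxiliary signal.

    assignments maps motif id -> group 1..k (group 1 = highest S-score);
    bin_edges records the matched-signal stratification.
    """

    assignments: pd.Series
    k: int
    bin_edges: np.ndarray
    n_strata: int
    dropped_strata: int = 0

    def members(self, group: int) -> pd.Index:
        return self.assignments.index[self.assignments == group]


def sscore_matched_grouping(
    sscore: pd.Series,
    match_signal: pd.Series,
    k: int = 6,
    n_bins: int = 20,
) -> MotifGrouping:
    """Deal motifs into k groups of descending S-score inside matched-signal
    quantile strata.

    Within each stratum motifs are sorted by S-score descending (ties broken
    by the stable motif order, i.e. genomic coordinate) and cut into k
    contiguous blocks, top block -> group 1; the remainder is trimmed
    symmetrically from both tails.  Strata with fewer than k motifs are
    dropped (all dropped -> error).  By construction every retained stratum
    contributes equally to every group, so the k groups share the matching
    signal but differ in S-score.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sscore, match_signal = sscore.align(match_signal, join="inner")
    vals = match_signal.to_numpy(dtype=float)
    edges = np.unique(np.quantile(vals, np.linspace(0, 1, n_bins + 1)))
    bins = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, len(edges) - 2)
    assignments = {}
    dropped = 0
    n_strata = len(np.unique(bins))
    for b in np.unique(bins):
        ids = sscore.index[bins == b]
        if len(ids) < k:
            dropped += 1
            continue
        order = np.argsort(-sscore.loc[ids].to_numpy(), kind="stable")
        ids = ids[order]
        q, r = divmod(len(ids), k)
        drop_head = r // 2
        ids = ids[drop_head : drop_head + q * k]
        for g in range(k):
            for mid in ids[g * q : (g + 1) * q]:
                assignments[mid] = g + 1
    if not assignments:
        raise ValueError("every stratum has fewer motifs than k")
    series = pd.Series(assignments, name="group")
    # keep the original motif order for determinism
    series = series.loc[[i for i in sscore.index if i in assignments]]
    return MotifGrouping(
        assignments=series,
        k=k,
        bin_edges=edges,
        n_strata=n_strata,
        dropped_strata=dropped,
    )


# ---------------------------------------------------------------------------
# cumulative-rank evaluation of competing metrics


def cumulative_rank_curve(
    metric: pd.Series, feature: pd.Series
) -> pd.DataFrame:
    """Step curve of cumulative feature-positive fraction against normalized
    descending rank under ``metric``.

    x_i = rank_i / N for the i-th feature-positive motif (ties broken by the
    stable input order), y_i = i / n_positives; the curve runs from (0,0) and
    is padded to (1, 1) so the terminus is exact.
    """
    metric, feature = metric.align(feature, join="inner")
    if not np.isfinite(metric.to_numpy(dtype=float)).all():
        raise ValueError("metric must be finite")
    pos = feature.to_numpy(dtype=bool)
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("no feature-positive motifs")
    n = len(metric)
    order = np.argsort(-metric.to_numpy(dtype=float), kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    pos_ranks = np.sort(ranks[pos])
    x = np.concatenate([[0.0], pos_ranks / n, [1.0]])
    y = np.concatenate([[0.0], np.arange(1, n_pos + 1) / n_pos, [1.0]])
    return pd.DataFrame({"x": x, "y": y})


def curve_auc(curve: pd.DataFrame) -> float:
    """Trapezoid area under the cumulative-rank curve over x in [0, 1]."""
    return float(np.trapezoid(curve["y"].to_numpy(), curve["x"].to_numpy()))


def rank_metric_comparison(
    metrics: dict[str, pd.Series],
    feature: pd.Series,
    half_split: bool = False,
) -> pd.DataFrame:
    """Compare metrics by AUC of their cumulative-rank curves plus pairwise
    two-sided Wilcoxon rank-sum tests on the normalized ranks of
    feature-positive motifs.

    With half_split=True, motifs are additionally partitioned at each metric's
    median and the AUC reported separately for the upper and lower halves.
    """
    names = list(metrics)
    index0 = metrics[names[0]].index
    for name in names[1:]:
        if not metrics[name].index.equals(index0):
            raise ValueError("metrics must be defined on the same motif set")
    feature = feature.reindex(index0)
    if feature.isna().any():
        raise ValueError("feature must be defined for every motif")
    n = len(index0)
    norm_ranks = {}
    rows = []
    for name in names:
        m = metrics[name]
        curve = cumulative_rank_curve(m, feature)
        order = np.argsort(-m.to_numpy(dtype=float), kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        norm_ranks[name] = ranks[feature.to_numpy(dtype=bool)] / n
        row = {"metric": name, "auc": curve_auc(curve)}
        if half_split:
            med = float(np.median(m.to_numpy(dtype=float)))
            hi = m >= med
            for label, mask in (("upper", hi), ("lower", ~hi)):
                sub_m = m[mask]
                sub_f = feature[mask]
                if sub_f.sum() > 0:
                    row[f"auc_{label}"] = curve_auc(
                        cumulative_rank_curve(sub_m, sub_f)
                    )
                else:
                    row[f"auc_{label}"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("metric")
    for a in names:
        for b in names:
            if a == b:
                table.loc[a, f"p_vs_{b}"] = 1.0
            else:
                table.loc[a, f"p_vs_{b}"] = float(
                    stats.ranksums(norm_ranks[a], norm_ranks[b]).pvalue
                )
    return table
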