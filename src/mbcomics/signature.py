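"""Core transcriptional signature extraction and subset embedding.

The signature of class-switched memory B cells is the set of genes
differentially expressed in the same direction in BOTH switched-vs-naive
contrasts at a stringent adjusted-p threshold (default 1e-29, the printed
"p_adj < 10 x 10^-30") that additionally "cancel out" in the IgG-vs-IgA
contrast (not significant there at the cancellation threshold, default
p_adj >= 0.05). Ig heavy-chain constant-region features are reported
separately rather than entering the signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

__all__ = [
    "SignatureSet",
    "core_signature",
    "core_signature_at",
    "shared_de",
    "embed_subsets",
    "heatmap_matrix",
]

P_ADJ_CORE = 1e-29
P_ADJ_UNSW = 1e-14
P_CANCEL = 0.05


@dataclass
class SignatureSet:
    up: list[str]
    down: list[str]
    excluded: list[str] = field(default_factory=list)
    p_adj_core: float = P_ADJ_CORE
    p_cancel: float = P_CANCEL

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down sets overlap")

    @property
    def members(self) -> list[str]:
        return self.up + self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "up") for g in self.up] + [(g, "down") for g in self.down]
        rows += [(g, "excluded") for g in self.excluded]
        return pd.DataFrame(rows, columns=["feature_id", "direction"])


def core_signature(
    de_g_vs_n: pd.DataFrame,
    de_a_vs_n: pd.DataFrame,
    de_g_vs_a: pd.DataFrame,
    p_adj_core: float = P_ADJ_CORE,
    p_cancel: float = P_CANCEL,
    exclude_classes: tuple[str, ...] = ("IGHC",),
    feature_class: pd.Series | None = None,
) -> SignatureSet:
    """Intersection-and-cancellation signature from three DE tables.

    A feature enters ``up`` iff p_adj < p_adj_core with log2fc > 0 in BOTH
    switched-vs-naive tables AND p_adj >= p_cancel in the isotype contrast
    (symmetrically for ``down``). Features of an excluded class that would
    otherwise qualify are reported in ``excluded``.
    """
    idx = de_g_vs_n.index
    if not (idx.equals(de_a_vs_n.index) and idx.equals(de_g_vs_a.index)):
        raise ValueError("the three DE tables must share one feature universe")
    sig_g = de_g_vs_n["p_adj"] < p_adj_core
    sig_a = de_a_vs_n["p_adj"] < p_adj_core
    cancels = de_g_vs_a["p_adj"] >= p_cancel
    up = sig_g & sig_a & (de_g_vs_n["log2fc"] > 0) & (de_a_vs_n["log2fc"] > 0) & cancels
    down = (
        sig_g & sig_a & (de_g_vs_n["log2fc"] < 0) & (de_a_vs_n["log2fc"] < 0) & cancels
    )
    qualifying_excluded: list[str] = []
    if feature_class is not None and exclude_classes:
        excluded_mask = feature_class.reindex(idx).isin(exclude_classes)
        both = sig_g & sig_a & (
            np.sign(de_g_vs_n["log2fc"]) == np.sign(de_a_vs_n["log2fc"])
        )
        qualifying_excluded = list(idx[excluded_mask & both])
        up &= ~excluded_mask
        down &= ~excluded_mask
    return SignatureSet(
        up=sorted(idx[up]),
        down=sorted(idx[down]),
        excluded=sorted(qualifying_excluded),
        p_adj_core=p_adj_core,
        p_cancel=p_cancel,
    )


def core_signature_at(
    de_g_vs_n: pd.DataFrame,
    de_a_vs_n: pd.DataFrame,
    de_g_vs_a: pd.DataFrame,
    p_adj_core: float = P_ADJ_UNSW,
    **kwargs,
) -> SignatureSet:
    """The same screen at a relaxed threshold (default 1e-14), as used for
    the unswitched-memory-vs-naive contrast."""
    return core_signature(
        de_g_vs_n, de_a_vs_n, de_g_vs_a, p_adj_core=p_adj_core, **kwargs
    )


def shared_de(
    de_g_vs_n: pd.DataFrame,
    de_a_vs_n: pd.DataFrame,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
    min_delta_abundance: float = 0.0,
) -> pd.DataFrame:
    """Features DE in the same direction in both switched-vs-naive tables.

    ``p_threshold`` applies to raw p (the miRNA/lncRNA screens) or to BH
    p_adj; ``min_delta_abundance`` implements the figure annotation rules
    (delta abundance > 1000 for miRNAs, > 100 for lncRNAs) on the larger of
    the two contrasts' normalized-count changes. Returns the qualifying
    slice of the first table with a ``direction`` column.
    """
    if not de_g_vs_n.index.equals(de_a_vs_n.index):
        raise ValueError("DE tables must share one feature universe")
    col = "p_adj" if use_adjusted else "p"
    sig = (de_g_vs_n[col] < p_threshold) & (de_a_vs_n[col] < p_threshold)
    same_dir = np.sign(de_g_vs_n["log2fc"]) == np.sign(de_a_vs_n["log2fc"])
    keep = sig & same_dir & (de_g_vs_n["log2fc"] != 0)
    if min_delta_abundance > 0:
        delta = np.maximum(
            de_g_vs_n["delta_abundance"], de_a_vs_n["delta_abundance"]
        )
        keep &= delta > min_delta_abundance
    out = de_g_vs_n.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def embed_subsets(
    log_expr: pd.DataFrame,
    labels: pd.Series,
    n_components: int = 2,
) -> dict:
    """PCA embedding of samples on signature features with cluster quality.

    Rows are features (standardized to unit variance), columns samples.
    Returns PC coordinates, explained variance, the silhouette coefficient
    of the subset labelling, and 95% bivariate-normal prediction ellipses
    per subset (chi-square-2 quantile radius).
    """
    if log_expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if log_expr.shape[0] < 2:
        raise ValueError("need at least 2 features")
    x = log_expr.T.values.astype(float)  # samples x features
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    n_components = min(n_components, min(x.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    coord_df = pd.DataFrame(
        coords, index=log_expr.columns,
        columns=[f"PC{i+1}" for i in range(coords.shape[1])],
    )
    labs = labels.reindex(log_expr.columns)
    sil = np.nan
    if labs.nunique() >= 2 and all(labs.value_counts() >= 1):
        try:
            sil = float(silhouette_score(coords, labs.values))
        except ValueError:
            sil = np.nan
    r2 = float(chi2.ppf(0.95, df=2))
    ellipses = {}
    for lab, sub in coord_df.groupby(labs):
        if len(sub) >= 3 and coords.shape[1] >= 2:
            xy = sub.iloc[:, :2].values
            ellipses[lab] = {
                "center": xy.mean(axis=0).tolist(),
                "cov": np.cov(xy.T).tolist(),
                "chi2_95": r2,
            }
    return {
        "coordinates": coord_df,
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
        "silhouette": sil,
        "ellipses": ellipses,
    }


def heatmap_matrix(
    expression: pd.DataFrame,
    signature: "SignatureSet | list[str]",
    sample_order: list[str] | None = None,
) -> pd.DataFrame:
    """Row-standardized (z-score, population sd) expression for a heatmap.

    Constant rows map to all-zero rather than NaN so the output is always
    finite and bit-reproducible.
    """
    members = signature.members if hasattr(signature, "members") else list(signature)
    missing = [g for g in members if g not in expression.index]
    if missing:
        raise KeyError(f"features absent from expression: {missing[:5]}")
    sub = expression.loc[members]
    if sample_order is not None:
        sub = sub[sample_order]
    vals = sub.values.astype(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population sd
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mu) / sd, index=sub.index, columns=sub.columns)
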