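"""Negative-binomial differential expression for count matrices.

This module is shared by the mRNA, miRNA, lncRNA and ATAC-peak analyses. It
implements the classic bulk RNA-seq workflow: expression filtering, TMM
(trimmed mean of M-values) between-library normalization, RPKM/RPM unit
conversion, and a conditional negative-binomial exact test with
Benjamini-Hochberg FDR control.

The NB model is parameterized by its mean ``mu`` and dispersion ``phi`` so
that ``var = mu + phi * mu**2`` (``phi`` is the squared biological
coefficient of variation). Per-feature dispersions are estimated by the
method of moments and shrunk toward an abundance-trended prior; the exact
test conditions the group-B sum on the total, under which the null
distribution is Beta-negative-binomial and free of the unknown mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "filter_expressed",
    "tmm_factors",
    "normalize_units",
    "estimate_dispersions",
    "nb_exact_test",
    "bh_adjust",
]

_MIN_DISPERSION = 1e-6
# beyond this size parameter the Beta-NB conditional is numerically binomial
_POISSON_LIMIT_SIZE = 1e8


@dataclass
class CountMatrix:
    """Integer counts (features x samples) with sample subset/subject labels.

    Parameters
    ----------
    counts
        Non-negative integer matrix, features as rows, samples as columns.
    samples
        Data frame indexed by sample id with at least a ``subset`` column and
        optionally a ``subject`` column; must cover every count column.
    lengths
        Optional per-feature lengths in bp (required for RPKM).
    feature_class
        Optional per-feature class label (e.g. ``IGHC`` for Ig heavy-chain
        constant-region transcripts, which the signature step excludes).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series | None = None
    feature_class: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet does not cover columns: {sorted(missing)}")
        if "subset" not in self.samples.columns:
            raise ValueError("samples sheet requires a 'subset' column")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if (self.lengths <= 0).any() or self.lengths.isna().any():
                raise ValueError("feature lengths must be positive and complete")
        if self.feature_class is not None:
            self.feature_class = self.feature_class.reindex(self.counts.index)

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, subset: str) -> list[str]:
        """Sample ids belonging to one subset label, in column order."""
        labels = self.samples.loc[self.counts.columns, "subset"]
        out = [s for s in self.counts.columns if labels[s] == subset]
        if not out:
            raise ValueError(f"no samples with subset label {subset!r}")
        return out

    def restrict(self, features: pd.Index | list[str]) -> "CountMatrix":
        idx = pd.Index(features)
        return CountMatrix(
            counts=self.counts.loc[idx],
            samples=self.samples,
            lengths=None if self.lengths is None else self.lengths.loc[idx],
            feature_class=None
            if self.feature_class is None
            else self.feature_class.loc[idx],
        )


def filter_expressed(
    matrix: CountMatrix, min_level: float, unit: str = "reads"
) -> CountMatrix:
    """Drop features that never reach ``min_level`` in any library.

    A feature is kept if its maximum across libraries is at least the
    threshold (``unit="reads"`` on raw counts, ``unit="RPKM"`` on
    length-normalized expression, which requires feature lengths).
    """
    if unit == "reads":
        level = matrix.counts
    elif unit == "RPKM":
        if matrix.lengths is None:
            raise ValueError("RPKM filtering requires feature lengths")
        level = normalize_units(matrix, unit="RPKM")
    else:
        raise ValueError(f"unknown unit {unit!r}")
    keep = matrix.counts.index[(level.max(axis=1) >= min_level).values]
    return matrix.restrict(keep)


def _trimmed_mean_m(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    logratio_trim: float = 0.3, abs_trim: float = 0.05,
) -> float:
    """Trimmed mean of per-feature log2 ratios of obs vs ref.

    Trims ``logratio_trim`` from each tail of M and ``abs_trim`` from each
    tail of A (unweighted mean of the doubly-trimmed M values).
    """
    ok = (obs > 0) & (ref > 0)
    if ok.sum() == 0:
        return 0.0
    p_obs = obs[ok] / lib_obs
    p_ref = ref[ok] / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    if np.allclose(m, m[0]):
        return float(m[0])
    lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
    lo_a, hi_a = np.quantile(a, [abs_trim, 1 - abs_trim])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if keep.sum() == 0:
        return float(np.mean(m))
    return float(np.mean(m[keep]))


def tmm_factors(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """TMM scaling factors, normalized to geometric mean 1.

    The reference library is the one whose upper quartile (of counts/libsize)
    is closest to the mean upper quartile across libraries.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    libs = counts.sum(axis=0).astype(float)
    if (libs == 0).any():
        bad = libs.index[libs == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    q = counts.div(libs, axis=1).quantile(0.75)
    ref_name = (q - q.mean()).abs().idxmin()
    ref = counts[ref_name].values.astype(float)
    logf = {}
    for s in counts.columns:
        if s == ref_name:
            logf[s] = 0.0
        else:
            logf[s] = _trimmed_mean_m(
                counts[s].values.astype(float), ref, libs[s], libs[ref_name]
            )
    f = pd.Series({s: 2.0 ** v for s, v in logf.items()})[counts.columns]
    return f / np.exp(np.log(f).mean())


def normalize_units(
    matrix: CountMatrix,
    unit: str = "RPM",
    pseudocount: float = 1.0,
    log2: bool = False,
) -> pd.DataFrame:
    """RPKM or RPM expression (optionally log2 with a pseudocount).

    RPKM = count * 1e9 / (libsize * length); RPM = count * 1e6 / libsize.
    """
    libs = matrix.library_sizes().astype(float)
    if (libs == 0).any():
        bad = libs.index[libs == 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    if unit == "RPM":
        out = matrix.counts.div(libs / 1e6, axis=1)
    elif unit == "RPKM":
        if matrix.lengths is None:
            raise ValueError("RPKM requires feature lengths")
        out = matrix.counts.div(libs / 1e9, axis=1).div(matrix.lengths, axis=0)
    else:
        raise ValueError(f"unknown unit {unit!r}")
    if log2:
        out = np.log2(out + pseudocount)
    return out


def _normalized_counts(matrix: CountMatrix, factors: pd.Series | None) -> pd.DataFrame:
    """Counts rescaled to a common effective library size (geometric mean)."""
    libs = matrix.library_sizes().astype(float)
    if factors is None:
        factors = tmm_factors(matrix)
    eff = libs * factors
    common = np.exp(np.log(eff).mean())
    return matrix.counts.mul(common / eff, axis=1)


def _mom_dispersion(norm: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Per-feature method-of-moments dispersion pooled within groups."""
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in group_idx:
        if len(idx) < 2:
            continue
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(m > 0, (v - m) / m**2, 0.0)
        num += w * phi
        den += w
    if (den == 0).all():
        raise ValueError("dispersion estimation needs a group with >=2 samples")
    return num / np.maximum(den, 1)


def estimate_dispersions(
    matrix: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    mode: str = "trended",
    shrink: float = 0.5,
    factors: pd.Series | None = None,
    n_bins: int = 20,
) -> pd.Series:
    """Per-feature NB dispersions on factor-adjusted counts.

    ``common`` returns the matrix-wide median for every feature; ``trended``
    an abundance-binned median interpolated over log mean abundance;
    ``tagwise`` shrinks the per-feature moment estimate 50% (by default)
    toward the trend. Estimates are floored at 1e-6 (a warning is emitted
    when the raw moment estimate is negative).
    """
    norm = _normalized_counts(matrix, factors)
    cols = list(norm.columns)
    # pool within-group variances over every labelled subset with >=2
    # samples (one dispersion per feature for the whole design); fall back
    # to the two contrast groups when labels don't partition the samples
    labels = matrix.samples.loc[cols, "subset"]
    groups = [
        [s for s in cols if labels[s] == lab]
        for lab in labels.unique()
    ]
    groups = [g for g in groups if len(g) >= 2]
    if not groups:
        groups = [group_a, group_b]
    idx = [np.array([cols.index(s) for s in g]) for g in groups]
    arr = norm.values.astype(float)
    raw = _mom_dispersion(arr, idx)
    if (raw < 0).any():
        warnings.warn(
            "negative moment dispersion estimates clamped to 1e-6", stacklevel=2
        )
    mean_ab = arr.mean(axis=1)
    pos = mean_ab > 0
    # the prior averages the UNclamped estimates: clamping the (frequent)
    # negative small-sample values first would bias the prior low and make
    # the exact test anticonservative
    common = max(_guarded_mean(raw[pos]), _MIN_DISPERSION) if pos.any() else _MIN_DISPERSION
    if mode == "common":
        out = np.full_like(raw, common)
    else:
        trend = _dispersion_trend(mean_ab, raw, n_bins=n_bins, fallback=common)
        if mode == "trended":
            out = trend
        elif mode == "tagwise":
            out = shrink * np.clip(raw, _MIN_DISPERSION, None) + (1.0 - shrink) * trend
        else:
            raise ValueError(f"unknown dispersion mode {mode!r}")
    out = np.clip(out, _MIN_DISPERSION, None)
    return pd.Series(out, index=norm.index, name="dispersion")


def _guarded_mean(x: np.ndarray) -> float:
    """Mean with the extreme upper tail winsorized (outlier guard)."""
    if x.size == 0:
        return _MIN_DISPERSION
    hi = np.quantile(x, 0.999)
    return float(np.mean(np.clip(x, None, hi)))


def _dispersion_trend(
    mean_ab: np.ndarray, raw: np.ndarray, n_bins: int, fallback: float
) -> np.ndarray:
    """Guarded-mean moment dispersion in log-abundance bins, interpolated."""
    pos = mean_ab > 0
    if pos.sum() < 10:
        return np.full_like(raw, fallback)
    la = np.log(mean_ab[pos])
    qs = np.linspace(0, 1, min(n_bins, max(2, pos.sum() // 50)) + 1)
    edges = np.unique(np.quantile(la, qs))
    if len(edges) < 3:
        return np.full_like(raw, fallback)
    which = np.clip(np.searchsorted(edges, la, side="right") - 1, 0, len(edges) - 2)
    centers, meds = [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.sum() >= 5:
            centers.append(la[sel].mean())
            meds.append(_guarded_mean(raw[pos][sel]))
    if len(centers) < 2:
        return np.full_like(raw, fallback)
    order = np.argsort(centers)
    centers = np.array(centers)[order]
    meds = np.array(meds)[order]
    trend = np.full_like(raw, fallback)
    trend[pos] = np.interp(la, centers, meds)
    return np.clip(trend, _MIN_DISPERSION, None)


def _exact_nb_pvalue(sa: int, sb: int, na: int, nb: int, phi: float) -> float:
    """Double-tail conditional NB test p-value for the group-B sum.

    Group sums of i.i.d. NB(mu, phi) samples are NB with size n/phi; given
    the total, the group-B sum follows a Beta-negative-binomial distribution
    independent of mu. The p-value sums the probabilities of all outcomes no
    more likely than the observed one (the double-tail convention). In the
    phi -> 0 limit the conditional law is Binomial(total, nb/(na+nb)).
    """
    t = sa + sb
    if t == 0:
        return 1.0
    ra, rb = na / phi, nb / phi
    if min(ra, rb) > _POISSON_LIMIT_SIZE:
        return binomtest(sb, t, nb / (na + nb), alternative="two-sided").pvalue
    k = np.arange(t + 1)
    lp = (
        gammaln(k + rb) - gammaln(k + 1)
        + gammaln(t - k + ra) - gammaln(t - k + 1)
    )
    lp -= lp.max()
    p = np.exp(lp)
    p /= p.sum()
    return float(min(1.0, p[p <= p[sb] * (1.0 + 1e-12)].sum()))


def nb_exact_test(
    matrix: CountMatrix,
    group_a: str | list[str],
    group_b: str | list[str],
    dispersion_mode: str = "trended",
    shrink: float = 0.5,
    lfc_pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Pairwise NB exact test of group B over group A, per feature.

    Groups may be subset labels or explicit sample-id lists. Returns a data
    frame indexed by feature with columns ``log2fc`` (B over A), ``p``,
    ``p_adj`` (BH), ``mean_a``/``mean_b`` (TMM-normalized means),
    ``delta_abundance`` (|mean_b - mean_a| on the normalized count scale)
    and ``dispersion``.
    """
    ga = matrix.subset_samples(group_a) if isinstance(group_a, str) else list(group_a)
    gb = matrix.subset_samples(group_b) if isinstance(group_b, str) else list(group_b)
    if not ga or not gb:
        raise ValueError("both groups need at least one sample")
    factors = tmm_factors(matrix)
    norm = _normalized_counts(matrix, factors)
    disp = estimate_dispersions(
        matrix, ga, gb, mode=dispersion_mode, shrink=shrink, factors=factors
    )
    mean_a = norm[ga].mean(axis=1)
    mean_b = norm[gb].mean(axis=1)
    sum_a = np.rint(norm[ga].sum(axis=1).values).astype(np.int64)
    sum_b = np.rint(norm[gb].sum(axis=1).values).astype(np.int64)
    na, nb = len(ga), len(gb)
    pvals = np.array(
        [
            _exact_nb_pvalue(int(a), int(b), na, nb, float(ph))
            for a, b, ph in zip(sum_a, sum_b, disp.values)
        ]
    )
    log2fc = np.log2((mean_b + lfc_pseudocount) / (mean_a + lfc_pseudocount))
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": bh_adjust(pvals),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta_abundance": (mean_b - mean_a).abs(),
            "dispersion": disp,
        },
        index=matrix.feature_ids,
    )
    return out


def bh_adjust(pvalues) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(adj, index=pvalues.index)
    return adj
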