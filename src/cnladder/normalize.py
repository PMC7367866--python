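"""Between-library normalization, sample-anchored or ladder-anchored.

Three scaling-factor methods are implemented from scratch on raw count
matrices (features x samples): median of ratios (MR), trimmed mean of
M-values (TMM) and upper-quartile (UQ). Each returns one positive factor
per sample; normalized counts are ``count / factor``.

All three assume the samples share a mostly-unchanged composition. That
assumption fails for *unbalanced* designs (sum of log fold changes != 0),
where sample-anchored factors absorb genuine biological differences. The
ladder-anchored mode instead derives the factors from the ladder k-mers
only -- whose composition is invariant by construction -- and applies them
to every feature, which preserves true fold differences regardless of how
the samples differ.

Conventions (documented because they vary between tools): TMM and UQ
factors are rescaled to geometric mean 1 across samples; factors are
depth-inclusive (no separate library-size division), so they are directly
comparable across methods; MR follows the DESeq2 definition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import TechnicalVariation, diff_test, estimate_technical_sd, roc_auc

__all__ = [
    "CountMatrix", "NormalizationResult", "median_of_ratios", "tmm",
    "upper_quartile", "normalize_counts", "ladder_scaling", "rle_statistics",
    "EvaluationResult", "evaluate_normalization",
]


@dataclass
class CountMatrix:
    """Feature-by-sample counts plus a ladder-membership flag per feature."""

    counts: pd.DataFrame           # features x samples, non-negative
    ladder: pd.Series              # bool per feature
    feature_info: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.ladder.index.equals(self.counts.index):
            raise ValueError("ladder flags must align with count rows")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def _check_matrix(df: pd.DataFrame, min_samples: int = 2) -> None:
    if df.shape[1] < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")


def _geo_rescale(factors: pd.Series) -> pd.Series:
    g = np.exp(np.log(factors).mean())
    return factors / g


def median_of_ratios(df: pd.DataFrame) -> pd.Series:
    """MR (DESeq2) size factors.

    The reference is the per-feature geometric mean over samples, computed
    on features with no zero anywhere; each sample's factor is the median
    over those features of count / reference.
    """
    _check_matrix(df)
    x = df.to_numpy(dtype=float)
    pos = (x > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no feature is positive in all samples")
    logx = np.log(x[pos])
    ref = logx.mean(axis=1)
    factors = np.exp(np.median(logx - ref[:, None], axis=0))
    return pd.Series(factors, index=df.columns, name="factor")


def upper_quartile(df: pd.DataFrame) -> pd.Series:
    """UQ factors: 75th percentile of each sample's nonzero counts,
    rescaled to geometric mean 1. Quantiles use linear interpolation
    between order statistics."""
    _check_matrix(df, min_samples=1)
    factors = {}
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        v = v[v > 0]
        if not v.size:
            raise ValueError(f"sample {col} has no nonzero counts")
        factors[col] = float(np.percentile(v, 75))
    return _geo_rescale(pd.Series(factors, name="factor"))


def _choose_tmm_reference(df: pd.DataFrame) -> str:
    uq = {}
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        v = v[v > 0]
        uq[col] = np.percentile(v, 75) if v.size else 0.0
    uq = pd.Series(uq)
    return (uq - uq.mean()).abs().idxmin()


def tmm(df: pd.DataFrame, reference: str | None = None,
        trim_m: float = 0.30, trim_a: float = 0.05,
        *, weighted: bool = True) -> pd.Series:
    """TMM factors with double trimming and optional precision weights.

    For each sample against the reference column, over features positive in
    both: M = log2 ratio, A = average log2 abundance. Features in the outer
    ``trim_m`` tails of M or ``trim_a`` tails of A are discarded; the factor
    is 2 to the (precision-weighted) mean of the retained M values, and
    factors are rescaled to geometric mean 1. Trim defaults are the edgeR
    convention (30% on M, 5% on A).
    """
    _check_matrix(df)
    if reference is None:
        reference = _choose_tmm_reference(df)
    ref = df[reference].to_numpy(dtype=float)
    log2 = np.log2
    factors = {}
    for col in df.columns:
        if col == reference:
            factors[col] = 1.0
            continue
        x = df[col].to_numpy(dtype=float)
        both = (x > 0) & (ref > 0)
        if not both.any():
            raise ValueError(f"no feature positive in both {col} and reference")
        m = log2(x[both]) - log2(ref[both])
        a = 0.5 * (log2(x[both]) + log2(ref[both]))
        m_lo, m_hi = np.quantile(m, [trim_m, 1.0 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1.0 - trim_a])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if not keep.any():
            raise ValueError("all features trimmed; relax trim fractions")
        if weighted:
            w = 1.0 / (1.0 / x[both][keep] + 1.0 / ref[both][keep])
            factors[col] = float(2.0 ** (np.sum(w * m[keep]) / np.sum(w)))
        else:
            factors[col] = float(2.0 ** np.mean(m[keep]))
    return _geo_rescale(pd.Series(factors, name="factor").reindex(df.columns))


_METHODS = {"mr": median_of_ratios, "tmm": tmm, "uq": upper_quartile}


@dataclass
class NormalizationResult:
    method: str
    mode: str                      # "sample" | "ladder"
    factors: pd.Series
    normalized: pd.DataFrame
    rle: pd.DataFrame              # per-sample RLE summary


def _run_method(method: str, df: pd.DataFrame, **kwargs) -> pd.Series:
    try:
        fn = _METHODS[method.lower()]
    except KeyError:
        raise ValueError(f"unknown normalization method {method!r}") from None
    return fn(df, **kwargs)


def normalize_counts(matrix: CountMatrix, method: str = "mr",
                     mode: str = "sample", **kwargs) -> NormalizationResult:
    """Normalize a count matrix in sample- or ladder-anchored mode.

    ``mode="sample"`` derives factors from the non-ladder (sample) features;
    ``mode="ladder"`` derives them from the ladder-flagged features only.
    Either way the factors divide every row of the matrix.
    """
    df = matrix.counts
    if mode == "ladder":
        sub = df.loc[matrix.ladder]
        if sub.empty or (sub.sum(axis=0) == 0).any():
            raise ValueError("ladder rows missing or empty in some sample")
    elif mode == "sample":
        sub = df.loc[~matrix.ladder]
    else:
        raise ValueError("mode must be 'sample' or 'ladder'")
    factors = _run_method(method, sub, **kwargs)
    normalized = df.div(factors, axis=1)
    rle = rle_statistics(normalized)
    return NormalizationResult(method=method.lower(), mode=mode,
                               factors=factors, normalized=normalized, rle=rle)


def ladder_scaling(matrix: CountMatrix, method: str = "mr",
                   **kwargs) -> NormalizationResult:
    """Ladder-anchored normalization (factors from ladder rows only)."""
    return normalize_counts(matrix, method=method, mode="ladder", **kwargs)


def rle_statistics(df: pd.DataFrame) -> pd.DataFrame:
    """Relative-log-expression summary per sample.

    Per feature, the reference is the across-sample median; RLE values are
    log2(count / reference) over positive counts of features with positive
    reference. A well-normalized library has per-sample RLE median near 0.
    """
    _check_matrix(df, min_samples=2)
    x = df.to_numpy(dtype=float)
    ref = np.median(x, axis=1)
    ok = ref > 0
    n_excluded = int((~ok).sum())
    rows = []
    for j, col in enumerate(df.columns):
        v = x[ok, j]
        with np.errstate(divide="ignore"):
            r = np.log2(v / ref[ok])
        r = r[np.isfinite(r)]
        q1, med, q3 = np.percentile(r, [25, 50, 75]) if r.size else (np.nan,) * 3
        rows.append({"sample": col, "rle_median": float(med),
                     "rle_iqr": float(q3 - q1), "n_features": int(r.size),
                     "n_excluded_zero_median": n_excluded})
    return pd.DataFrame(rows)


@dataclass
class EvaluationResult:
    auc: float
    recovery: pd.DataFrame         # designed fold change -> median observed
    table: pd.DataFrame            # per-feature test results
    variation: TechnicalVariation


def evaluate_normalization(result: NormalizationResult,
                           matrix: CountMatrix,
                           truth_fc: pd.Series,
                           ladder_units: pd.Series,
                           *, pair: tuple[str, str] | None = None,
                           alpha: float = 0.05) -> EvaluationResult:
    """Score a normalization by fold-change recovery and detection AUC.

    ``truth_fc`` gives the designed fold change (B/A) per non-ladder
    feature; ``ladder_units`` gives the cn unit of each ladder feature.
    Technical variation is estimated from the *normalized* ladder rows, the
    per-feature ladder-SD test (two-sided) ranks features, and the AUC
    scores changed (fold change != 1) against unchanged features. The
    recovery table reports the median observed fold change per designed
    group -- under good normalization it matches the design; under
    mis-normalization it is biased by the bulk imbalance.
    """
    df = result.normalized
    if pair is None:
        if df.shape[1] != 2:
            raise ValueError("specify the sample pair for matrices with >2 samples")
        pair = (df.columns[0], df.columns[1])
    a_col, b_col = pair

    lad = df.loc[matrix.ladder]
    units = ladder_units.reindex(lad.index)
    if units.isna().any():
        raise ValueError("ladder_units must cover all ladder features")
    variation = estimate_technical_sd(lad[a_col].to_numpy(),
                                      lad[b_col].to_numpy(),
                                      units.to_numpy())

    feats = df.loc[~matrix.ladder]
    fc = truth_fc.reindex(feats.index)
    if fc.isna().any():
        raise ValueError("truth_fc must cover all non-ladder features")
    a = feats[a_col].to_numpy()
    b = feats[b_col].to_numpy()
    table = diff_test(a, b, variation, ids=feats.index.to_numpy(),
                      alternative="two-sided", alpha=alpha)
    # round group keys so designed values like 0.3 survive float arithmetic
    table["designed_fc"] = np.round(fc.to_numpy(), 9)
    with np.errstate(divide="ignore", invalid="ignore"):
        table["observed_fc"] = np.where(a > 0, b / np.maximum(a, 1e-12), np.nan)

    changed = ~np.isclose(fc.to_numpy(), 1.0, rtol=1e-9)
    score = np.abs(table["z"].to_numpy())
    roc = roc_auc(score, changed, significant=table["significant"].to_numpy())
    recovery = (table.groupby("designed_fc")["observed_fc"]
                .median().rename("median_observed_fc").reset_index())
    return EvaluationResult(auc=roc.auc, recovery=recovery, table=table,
                            variation=variation)
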