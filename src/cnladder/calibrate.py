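"""Calibration to an accompanying sample and ladder-informed fold testing.

The ladder is an internal scale: anchoring its 2-cn unit to the median
count of the accompanying diploid sample expresses sample k-mer counts in
copy-number units, and because the ladder's composition is identical in
every library, the spread of between-sample differences of ladder k-mer
counts at each cn unit estimates *technical* variation directly -- no
replicates needed. A fold difference between two samples is then tested by
comparing the observed count difference against the technical standard
deviation at the matching cn level (one-sided upper-tail test with a
normal reference, Benjamini-Hochberg corrected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .kmerquant import CnProfile, KmerCatalog, KmerCountTable

__all__ = [
    "CalibrationResult", "TechnicalVariation", "calibrate_to_sample",
    "estimate_technical_sd", "estimate_technical_sd_from_tables",
    "diff_test", "RocResult", "roc_auc",
]


@dataclass
class CalibrationResult:
    """Scale anchoring ladder cn units to a sample's count distribution."""

    scale: float                       # multiply ladder counts by this
    unit_medians_raw: dict[int, float]
    unit_medians_calibrated: dict[int, float]
    in_range_fraction: float           # sample k-mers inside the 1..8 cn span

    def nearest_unit(self, count: float | np.ndarray) -> np.ndarray:
        """Calibrated cn unit nearest to a count, on the log scale."""
        units = np.array(sorted(self.unit_medians_calibrated))
        meds = np.array([self.unit_medians_calibrated[u] for u in units])
        c = np.atleast_1d(np.asarray(count, dtype=float))
        d = np.abs(np.log(np.maximum(c, 0.5))[:, None] - np.log(meds)[None, :])
        return units[np.argmin(d, axis=1)]


def calibrate_to_sample(ladder_profile: CnProfile,
                        sample_counts: "KmerCountTable | np.ndarray") -> CalibrationResult:
    """Anchor the ladder so its 2-cn unit matches the sample median count.

    For a diploid genome the bulk of k-mers are present at two copies, so
    the 2-cn unit is the natural anchor. The dynamic-range fraction is the
    share of sample k-mer counts falling between the calibrated 1-cn and
    8-cn medians (the eightfold range the ladder can read off directly).
    """
    if isinstance(sample_counts, KmerCountTable):
        sample = sample_counts.counts.astype(float)
    else:
        sample = np.asarray(sample_counts, dtype=float)
    if sample.size == 0:
        raise ValueError("sample counts must be non-empty")
    raw = {u: float(np.median(ladder_profile.pooled[u]))
           for u in ladder_profile.units}
    if 2 not in raw or raw[2] <= 0:
        raise ValueError("2-cn unit median is zero; cannot calibrate")
    scale = float(np.median(sample)) / raw[2]
    cal = {u: m * scale for u, m in raw.items()}
    lo, hi = cal[min(cal)], cal[max(cal)]
    frac = float(np.mean((sample >= lo) & (sample <= hi)))
    return CalibrationResult(scale=scale, unit_medians_raw=raw,
                             unit_medians_calibrated=cal, in_range_fraction=frac)


@dataclass
class TechnicalVariation:
    """Per-cn-unit spread of between-sample ladder count differences."""

    units: np.ndarray          # cn levels
    level_counts: np.ndarray   # mean ladder count at each unit (for lookup)
    means: np.ndarray          # mean of (B - A) per unit; ~0 for comparable depth
    sds: np.ndarray            # technical SD estimate per unit

    def sd_for_level(self, unit: int | np.ndarray) -> np.ndarray:
        unit = np.atleast_1d(unit)
        idx = np.searchsorted(self.units, unit)
        idx = np.clip(idx, 0, self.units.size - 1)
        return self.sds[idx]

    def nearest_unit(self, count: float | np.ndarray) -> np.ndarray:
        """Unit whose mean ladder count is nearest on the log scale."""
        c = np.atleast_1d(np.asarray(count, dtype=float))
        d = np.abs(np.log(np.maximum(c, 0.5))[:, None]
                   - np.log(np.maximum(self.level_counts, 0.5))[None, :])
        return self.units[np.argmin(d, axis=1)]

    def sd_for_count(self, count: float | np.ndarray,
                     *, interpolate: bool = False) -> np.ndarray:
        """Technical SD at a count level: nearest unit, or log-linear interpolation."""
        c = np.atleast_1d(np.asarray(count, dtype=float))
        if not interpolate:
            units = self.nearest_unit(c)
            idx = np.searchsorted(self.units, units)
            return self.sds[idx]
        logc = np.log(np.maximum(c, 0.5))
        logl = np.log(np.maximum(self.level_counts, 0.5))
        return np.interp(logc, logl, self.sds)


def estimate_technical_sd(counts_a: np.ndarray, counts_b: np.ndarray,
                          units: np.ndarray) -> TechnicalVariation:
    """Technical variation from aligned ladder count vectors of two samples.

    ``counts_a``/``counts_b`` are counts of the same catalogued ladder
    k-mers in samples A and B (comparable depth or pre-normalized);
    ``units`` gives each k-mer's cn unit. The per-unit distributions of
    ``B - A`` should centre on 0 -- a warning is issued when the mean
    exceeds half the SD, which indicates a depth or normalization offset.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    units = np.asarray(units)
    if not (counts_a.size == counts_b.size == units.size):
        raise ValueError("count vectors and unit labels must align")
    uniq = np.unique(units)
    means, sds, levels = [], [], []
    for u in uniq:
        d = counts_b[units == u] - counts_a[units == u]
        means.append(float(d.mean()))
        sds.append(float(d.std(ddof=1)) if d.size > 1 else 0.0)
        levels.append(float((counts_a[units == u].mean()
                             + counts_b[units == u].mean()) / 2.0))
    means = np.array(means)
    sds = np.array(sds)
    off = sds > 0
    if np.any(np.abs(means[off]) > 0.5 * sds[off]):
        warnings.warn("between-sample ladder differences are not centred on 0; "
                      "samples may need depth normalization", stacklevel=2)
    return TechnicalVariation(units=uniq.astype(int), level_counts=np.array(levels),
                              means=means, sds=sds)


def estimate_technical_sd_from_tables(table_a: KmerCountTable,
                                      table_b: KmerCountTable,
                                      catalog: KmerCatalog) -> TechnicalVariation:
    if not (table_a.k == table_b.k == catalog.k):
        raise ValueError("tables and catalog must share k")
    ca = table_a.get(catalog.codes)
    cb = table_b.get(catalog.codes)
    return estimate_technical_sd(ca, cb, catalog.cn)


def diff_test(counts_a: np.ndarray, counts_b: np.ndarray,
              variation: TechnicalVariation,
              *, ids: "np.ndarray | list | None" = None,
              alternative: str = "greater", alpha: float = 0.05,
              interpolate_sd: bool = False) -> pd.DataFrame:
    """Test per-feature count differences against ladder technical variation.

    Each feature's cn level is the variation unit nearest (log scale) to the
    smaller of its two counts; the statistic ``(B - A) / SD(level)`` is
    referred to a standard normal (the ladder SD is estimated from hundreds
    of k-mers, so the degrees of freedom are effectively infinite).
    ``alternative`` is ``greater`` (B > A, the default), ``less`` or
    ``two-sided``. P-values are Benjamini-Hochberg adjusted; a feature is
    significant iff its q-value is at most ``alpha``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size != b.size:
        raise ValueError("count vectors must align")
    level = variation.nearest_unit(np.minimum(a, b))
    sd = variation.sd_for_count(np.minimum(a, b), interpolate=interpolate_sd)
    diff = b - a
    z = np.zeros_like(diff)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, 0.0, diff / np.where(degenerate, 1.0, sd))
    if alternative == "greater":
        p = stats.norm.sf(z)
        p = np.where(degenerate, np.where(diff > 0, 0.0, 1.0), p)
    elif alternative == "less":
        p = stats.norm.cdf(z)
        p = np.where(degenerate, np.where(diff < 0, 0.0, 1.0), p)
    elif alternative == "two-sided":
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.where(degenerate, np.where(diff != 0, 0.0, 1.0), p)
    else:
        raise ValueError("alternative must be greater, less or two-sided")
    p = np.clip(p, 0.0, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame({
        "count_a": a, "count_b": b, "diff": diff, "cn_level": level,
        "sd": sd, "z": z, "p": p, "q": q,
        "significant": q <= alpha, "degenerate_sd": degenerate,
    })
    if ids is not None:
        out.insert(0, "feature", np.asarray(ids))
    return out


@dataclass
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    sensitivity: float | None = None
    specificity: float | None = None


def roc_auc(scores: np.ndarray, truth: np.ndarray,
            *, significant: np.ndarray | None = None) -> RocResult:
    """AUC of a score against binary truth, by the Mann-Whitney U statistic.

    ``AUC = U / (n_pos * n_neg)`` with midranks for ties -- the probability
    that a random true positive outscores a random true negative. If a
    significance mask is given, the sensitivity/specificity of that
    operating point are reported as well.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    sens = spec = None
    if significant is not None:
        significant = np.asarray(significant).astype(bool)
        sens = float(significant[truth].mean())
        spec = float((~significant[~truth]).mean())
    return RocResult(auc=auc, n_pos=n_pos, n_neg=n_neg,
                     sensitivity=sens, specificity=spec)
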