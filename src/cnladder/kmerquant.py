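"""Canonical k-mer counting and ladder-structure statistics.

Quantification is alignment-free: every length-31 window of every read is
counted under its canonical form (the lexicographic minimum of the window
and its reverse complement), and ladder abundance is read off the counts of
*catalogued* k-mers -- the k-mers lying fully inside a ladder element. A
600-nt element yields 600 - 31 + 1 = 570 catalogued k-mers, each expected
at a count proportional to the element's copy number, so a least-squares
regression of count on cn summarises the ladder structure (slope = counts
per cn unit, R^2 = linearity) and per-unit count distributions give the
coefficient of variation and the successive-cn median ratios.

Counting is vectorised: reads are joined with an invalid separator byte and
all windows are packed/canonicalised in a handful of numpy passes, so
megabase-scale simulated libraries are processed in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._codec import canonical_codes, codes_to_kmers, encode, kmers_to_codes
from .design import LadderSet
from .simulate import (ReadBatch, SimulationConfig, inject_duplicates,
                       simulate_ladder_library, subsample_library)

__all__ = [
    "KmerCountTable", "KmerCatalog", "CnProfile", "LadderMetrics",
    "count_kmers", "build_catalog", "partition_reads", "PartitionResult",
    "equalize_ladder_depth", "profile_cn", "ladder_metrics",
    "overlap_fraction", "sweep_technical_variables",
]

_SEP = "N"  # invalid byte: breaks windows across read boundaries
_CHUNK_BASES = 8_000_000


@dataclass
class KmerCountTable:
    """Counts of canonical k-mers, stored as sorted packed codes."""

    sample_id: str
    k: int
    codes: np.ndarray                    # sorted uint64
    counts: np.ndarray                   # int64, parallel to codes
    n_short_reads: int = 0
    n_invalid_windows: int = 0

    def __post_init__(self):
        if self.codes.size and np.any(np.diff(self.codes.astype(np.uint64)) <= 0):
            raise ValueError("codes must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def total(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return int(self.codes.size)

    def get(self, query: np.ndarray) -> np.ndarray:
        """Counts for packed canonical codes; absent k-mers count 0."""
        query = np.asarray(query, dtype=np.uint64)
        idx = np.searchsorted(self.codes, query)
        idx_c = np.clip(idx, 0, max(self.codes.size - 1, 0))
        out = np.zeros(query.size, dtype=np.int64)
        if self.codes.size:
            hit = self.codes[idx_c] == query
            hit &= idx < self.codes.size
            out[hit] = self.counts[idx_c[hit]]
        return out

    def get_kmer(self, kmer: str) -> int:
        code = kmers_to_codes([kmer], self.k)
        rc = kmers_to_codes([_revcomp_str(kmer)], self.k)
        return int(self.get(np.minimum(code, rc))[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"kmer": codes_to_kmers(self.codes, self.k),
                             "count": self.counts})


def _revcomp_str(s: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return s.translate(comp)[::-1]


def _aggregate(codes: np.ndarray, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(codes, kind="stable")
    codes, counts = codes[order], counts[order]
    uniq, start = np.unique(codes, return_index=True)
    summed = np.add.reduceat(counts, start) if codes.size else counts
    return uniq, summed.astype(np.int64)


def _iter_sequences(reads) -> Iterable[str]:
    if isinstance(reads, ReadBatch):
        return reads.sequences()
    return reads


def count_kmers(reads, k: int = 31, *, canonical: bool = True,
                sample_id: str = "sample") -> KmerCountTable:
    """Count canonical k-mers over a collection of read sequences.

    ``reads`` may be a :class:`~cnladder.simulate.ReadBatch` or any iterable
    of sequence strings. Reads shorter than ``k`` are skipped (counted in
    ``n_short_reads``); windows containing non-ACGT characters are skipped
    (counted in ``n_invalid_windows``). With ``canonical=False`` forward
    windows are counted as-is (exposed for diagnostics only).
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31]")
    part_codes: list[np.ndarray] = []
    part_counts: list[np.ndarray] = []
    n_short = 0
    n_invalid = 0
    buf: list[str] = []
    buf_bases = 0

    def flush():
        nonlocal buf, buf_bases, n_invalid
        if not buf:
            return
        joined = _SEP.join(buf)
        arr = encode(joined)
        n_sep = len(buf) - 1
        if canonical:
            codes = canonical_codes(arr, k)
        else:
            from ._codec import forward_codes
            codes = forward_codes(arr, k)
        # windows lost to separators are structural, not invalid data
        expected = sum(len(s) - k + 1 for s in buf)
        n_invalid += expected - codes.size
        u, c = _aggregate(codes, np.ones(codes.size, dtype=np.int64))
        part_codes.append(u)
        part_counts.append(c)
        buf = []
        buf_bases = 0

    for seq in _iter_sequences(reads):
        if len(seq) < k:
            n_short += 1
            continue
        buf.append(seq)
        buf_bases += len(seq)
        if buf_bases >= _CHUNK_BASES:
            flush()
    flush()

    if part_codes:
        codes, counts = _aggregate(np.concatenate(part_codes),
                                   np.concatenate(part_counts))
    else:
        codes = np.empty(0, dtype=np.uint64)
        counts = np.empty(0, dtype=np.int64)
    return KmerCountTable(sample_id=sample_id, k=k, codes=codes, counts=counts,
                          n_short_reads=n_short, n_invalid_windows=n_invalid)


@dataclass
class KmerCatalog:
    """Mapping from canonical k-mer code to (ladder, element, cn)."""

    k: int
    codes: np.ndarray          # sorted uint64
    ladder_idx: np.ndarray     # int32 index into ladder_ids
    element_idx: np.ndarray    # int32 index into element_ids
    cn: np.ndarray             # int32, expected within-molecule multiplicity
    ladder_ids: list[str]
    element_ids: list[str]

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def units(self) -> np.ndarray:
        return np.unique(self.cn)

    def lookup(self, query: np.ndarray) -> np.ndarray:
        """Catalog row index for each query code, -1 where uncatalogued."""
        query = np.asarray(query, dtype=np.uint64)
        idx = np.searchsorted(self.codes, query)
        idx_c = np.clip(idx, 0, self.codes.size - 1)
        out = np.where((idx < self.codes.size) & (self.codes[idx_c] == query),
                       idx_c, -1)
        return out.astype(np.int64)


def build_catalog(ladder_set: LadderSet, k: int = 31) -> KmerCatalog:
    """Catalog the canonical k-mers lying fully inside ladder elements.

    Junction, spacer and flank k-mers are excluded, so each catalogued
    k-mer's expected within-molecule multiplicity equals its element's copy
    number. A canonical collision between two elements violates the design
    invariants and raises.
    """
    codes_parts, lad_parts, el_parts, cn_parts = [], [], [], []
    ladder_ids, element_ids = [], []
    for li, ladder in enumerate(ladder_set):
        ladder_ids.append(ladder.ladder_id)
        for elem in ladder.elements:
            ei = len(element_ids)
            element_ids.append(elem.element_id)
            codes = np.unique(canonical_codes(encode(elem.sequence), k))
            expected = len(elem.sequence) - k + 1
            if codes.size != expected:
                raise ValueError(
                    f"element {elem.element_id} has internal canonical "
                    f"duplicates ({codes.size} != {expected})")
            codes_parts.append(codes)
            lad_parts.append(np.full(codes.size, li, dtype=np.int32))
            el_parts.append(np.full(codes.size, ei, dtype=np.int32))
            cn_parts.append(np.full(codes.size, elem.assigned_cn, dtype=np.int32))
    codes = np.concatenate(codes_parts)
    if np.unique(codes).size != codes.size:
        raise ValueError("canonical k-mer collision between elements")
    order = np.argsort(codes)
    return KmerCatalog(k=k, codes=codes[order],
                       ladder_idx=np.concatenate(lad_parts)[order],
                       element_idx=np.concatenate(el_parts)[order],
                       cn=np.concatenate(cn_parts)[order],
                       ladder_ids=ladder_ids, element_ids=element_ids)


@dataclass
class PartitionResult:
    bins: dict[str, ReadBatch]
    residual: ReadBatch
    n_ambiguous: int
    min_hits: int

    def bin_sizes(self) -> dict[str, int]:
        return {lid: len(b) for lid, b in self.bins.items()}


def partition_reads(batch: ReadBatch, catalog: KmerCatalog,
                    min_hits: int = 5) -> PartitionResult:
    """Assign read pairs to the ladder their catalogued k-mers identify.

    A pair is assigned to a ladder iff at least ``min_hits`` of its k-mers
    (over both mates) are catalogued to that ladder; pairs reaching the
    threshold for more than one ladder are ambiguous and excluded; all other
    pairs go to the residual (sample) bin.
    """
    n_pairs = len(batch)
    n_ladders = len(catalog.ladder_ids)
    hits = np.zeros((n_pairs, n_ladders), dtype=np.int32)
    k = catalog.k
    for mate in (batch.r1, batch.r2):
        start = 0
        while start < n_pairs:
            stop = min(start + 40_000, n_pairs)
            seqs = mate[start:stop]
            joined = _SEP.join(seqs)
            arr = encode(joined)
            codes, pos = canonical_codes(arr, k, return_positions=True)
            starts = np.cumsum([0] + [len(s) + 1 for s in seqs[:-1]])
            read_of = np.searchsorted(starts, pos, side="right") - 1
            cat = catalog.lookup(codes)
            hit = cat >= 0
            np.add.at(hits, (read_of[hit] + start, catalog.ladder_idx[cat[hit]]), 1)
            start = stop
    reach = hits >= min_hits
    n_reached = reach.sum(axis=1)
    assigned = n_reached == 1
    ambiguous = n_reached > 1
    residual = n_reached == 0
    bins = {}
    for li, lid in enumerate(catalog.ladder_ids):
        idx = np.flatnonzero(assigned & reach[:, li])
        bins[lid] = batch.subset(idx)
    return PartitionResult(bins=bins, residual=batch.subset(np.flatnonzero(residual)),
                           n_ambiguous=int(ambiguous.sum()), min_hits=min_hits)


def equalize_ladder_depth(bins: Mapping[str, ReadBatch],
                          seed: int | np.random.Generator = 0) -> dict[str, ReadBatch]:
    """Subsample every ladder bin to the smallest bin size.

    This removes between-ladder abundance differences caused by inexact
    quantification or pipetting when the physical mixture was assembled.
    """
    sizes = [len(b) for b in bins.values()]
    if not sizes or max(sizes) == 0:
        raise ValueError("all ladder bins are empty")
    target = min(s for s in sizes if s > 0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for lid, b in bins.items():
        if len(b) == target:
            out[lid] = b
        else:
            idx = np.sort(rng.choice(len(b), size=target, replace=False))
            out[lid] = b.subset(idx)
    return out


@dataclass
class CnProfile:
    """Per-cn-unit catalogued k-mer count distributions.

    ``pooled`` maps cn unit -> counts over all catalogued k-mers of that
    unit across ladders (absent k-mers included as 0, since dropout is the
    signal at high error or low depth). ``per_ladder`` keeps the same
    vectors split by ladder for median-ratio statistics.
    """

    k: int
    pooled: dict[int, np.ndarray]
    per_ladder: dict[tuple[str, int], np.ndarray]
    ladder_ids: list[str] = field(default_factory=list)

    @property
    def units(self) -> list[int]:
        return sorted(self.pooled)

    def summary(self) -> pd.DataFrame:
        rows = []
        for unit in self.units:
            v = self.pooled[unit].astype(float)
            mean = float(v.mean())
            sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
            rows.append({"cn": unit, "n_kmers": int(v.size), "mean": mean,
                         "median": float(np.median(v)), "sd": sd,
                         "cv": sd / mean if mean > 0 else np.nan})
        return pd.DataFrame(rows)


def profile_cn(table: KmerCountTable, catalog: KmerCatalog) -> CnProfile:
    """Assemble per-unit count vectors from a count table and the catalog."""
    if table.k != catalog.k:
        raise ValueError("table and catalog must share k")
    counts = table.get(catalog.codes)
    pooled = {int(u): counts[catalog.cn == u] for u in catalog.units}
    per_ladder = {}
    for li, lid in enumerate(catalog.ladder_ids):
        mask_l = catalog.ladder_idx == li
        for u in catalog.units:
            per_ladder[(lid, int(u))] = counts[mask_l & (catalog.cn == u)]
    return CnProfile(k=catalog.k, pooled=pooled, per_ladder=per_ladder,
                     ladder_ids=list(catalog.ladder_ids))


@dataclass
class LadderMetrics:
    """Regression and ratio statistics summarising ladder structure."""

    slope: float
    intercept: float
    r_squared: float
    per_ladder_medians: pd.DataFrame      # ladder x cn unit
    ratios: pd.DataFrame                  # ladder, pair, ratio
    ratio_mean: float
    ratio_sd: float
    cv: dict[int, float]


def ladder_metrics(profile: CnProfile, *, mode: str = "kmers") -> LadderMetrics:
    """Least-squares ladder fit and successive-cn ratio statistics.

    ``mode="kmers"`` regresses every catalogued k-mer count on its cn;
    ``mode="medians"`` regresses the per-ladder per-unit medians instead.
    Successive-cn ratios are always computed from per-ladder median counts.
    """
    units = profile.units
    if len(units) < 2:
        raise ValueError("need at least two populated cn units")
    if mode == "kmers":
        x = np.concatenate([np.full(profile.pooled[u].size, u, dtype=float)
                            for u in units])
        y = np.concatenate([profile.pooled[u].astype(float) for u in units])
    elif mode == "medians":
        med_rows = [(u, float(np.median(profile.per_ladder[(lid, u)])))
                    for lid in profile.ladder_ids for u in units
                    if profile.per_ladder[(lid, u)].size]
        x = np.array([r[0] for r in med_rows], dtype=float)
        y = np.array([r[1] for r in med_rows], dtype=float)
    else:
        raise ValueError("mode must be 'kmers' or 'medians'")
    if np.ptp(y) == 0:
        slope, intercept, r2 = 0.0, float(y[0]), float("nan")
    else:
        fit = stats.linregress(x, y)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)

    med = {}
    for lid in profile.ladder_ids:
        med[lid] = {u: float(np.median(profile.per_ladder[(lid, u)]))
                    for u in units if profile.per_ladder[(lid, u)].size}
    med_df = pd.DataFrame(med).T
    med_df.index.name = "ladder"

    rows = []
    for lid in profile.ladder_ids:
        for lo, hi in zip(units[:-1], units[1:]):
            m_lo, m_hi = med[lid].get(lo), med[lid].get(hi)
            if m_lo and m_hi is not None and m_lo > 0:
                rows.append({"ladder": lid, "pair": f"{hi}/{lo}",
                             "ratio": m_hi / m_lo})
    ratios = pd.DataFrame(rows)
    ratio_mean = float(ratios["ratio"].mean()) if len(ratios) else float("nan")
    ratio_sd = (float(ratios["ratio"].std(ddof=1))
                if len(ratios) > 1 else float("nan"))

    summ = profile.summary().set_index("cn")
    cv = {int(u): float(summ.loc[u, "cv"]) for u in units}
    return LadderMetrics(slope=slope, intercept=intercept, r_squared=r2,
                         per_ladder_medians=med_df, ratios=ratios,
                         ratio_mean=ratio_mean, ratio_sd=ratio_sd, cv=cv)


def overlap_fraction(profile: CnProfile, unit_a: int, unit_b: int) -> float:
    """Overlap coefficient of two per-unit count histograms.

    Histograms use unit-width integer bins; the overlap is
    ``sum_bins min(p_a, p_b)`` and measures the fraction of k-mers whose
    counts do not discriminate between the two cn units.
    """
    va = profile.pooled.get(unit_a)
    vb = profile.pooled.get(unit_b)
    if va is None or vb is None or not va.size or not vb.size:
        raise ValueError("both cn units must be populated")
    hi = int(max(va.max(), vb.max())) + 1
    pa = np.bincount(va, minlength=hi) / va.size
    pb = np.bincount(vb, minlength=hi) / vb.size
    return float(np.minimum(pa, pb).sum())


def _metrics_row(batch: ReadBatch, catalog: KmerCatalog, setting: float,
                 variable: str) -> dict:
    table = count_kmers(batch, k=catalog.k)
    prof = profile_cn(table, catalog)
    met = ladder_metrics(prof)
    row = {"variable": variable, "setting": setting, "slope": met.slope,
           "r_squared": met.r_squared, "ratio_mean": met.ratio_mean}
    for u, v in met.cv.items():
        row[f"cv_{u}cn"] = v
    return row


def sweep_technical_variables(variable: str,
                              grid: Sequence[float],
                              ladder_set: LadderSet,
                              config: SimulationConfig = SimulationConfig(),
                              *, depth: float = 40.0,
                              seed: int = 0) -> pd.DataFrame:
    """Ladder metrics across a grid of one technical variable.

    ``variable`` is one of ``error`` (fresh simulation per substitution
    rate), ``depth`` (one base library subsampled to each fraction) or
    ``duplication`` (error-free unique pool, duplicates injected at each
    rate). Returns one row per setting, sorted by setting.
    """
    catalog = build_catalog(ladder_set, k=config.k)
    ss = np.random.SeedSequence(seed)
    rows = []
    if variable == "error":
        for i, e in enumerate(sorted(grid)):
            if not 0.0 <= e < 1.0:
                raise ValueError("error rate grid must lie in [0, 1)")
            cfg = SimulationConfig(read_len=config.read_len,
                                   insert_mean=config.insert_mean,
                                   insert_sd=config.insert_sd,
                                   error_rate=float(e), k=config.k)
            batch = simulate_ladder_library(
                ladder_set, depth, cfg,
                seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31))
            rows.append(_metrics_row(batch, catalog, float(e), variable))
    elif variable == "depth":
        base_seed = int(ss.generate_state(1)[0] % 2**31)
        base = simulate_ladder_library(ladder_set, depth, config, seed=base_seed)
        rng = np.random.default_rng(base_seed + 1)
        for f in sorted(grid):
            if not 0.0 < f <= 1.0:
                raise ValueError("depth grid entries are fractions in (0, 1]")
            sub = subsample_library(base, float(f), rng)
            rows.append(_metrics_row(sub, catalog, float(f), variable))
    elif variable == "duplication":
        cfg = SimulationConfig(read_len=config.read_len,
                               insert_mean=config.insert_mean,
                               insert_sd=config.insert_sd,
                               error_rate=0.0, k=config.k)
        base_seed = int(ss.generate_state(1)[0] % 2**31)
        pool = simulate_ladder_library(ladder_set, depth, cfg, seed=base_seed)
        rng = np.random.default_rng(base_seed + 1)
        for x in sorted(grid):
            lib = inject_duplicates(pool, float(x), target_n=len(pool), seed=rng)
            rows.append(_metrics_row(lib, catalog, float(x), variable))
    else:
        raise ValueError(f"unknown technical variable: {variable!r}")
    return pd.DataFrame(rows)
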