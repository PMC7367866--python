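"""Paired-end read simulation and library manipulation.

A wgsim-style generator: fragments are drawn uniformly along weighted
templates (template probability proportional to molar weight x length),
paired 125-nt reads are taken from the two fragment ends (the reverse-strand
mate reverse-complemented), and substitution errors are applied uniformly
per base. Substitutions only -- downstream k-mer analyses treat errors as
k-mer loss, which substitutions capture with the closed form ``(1-e)^k``
for the fraction of read k-mers still matching the template.

The module also provides the library manipulations used when modelling
technical variables (exact-count subsampling, duplicate injection), and the
synthetic study systems: a diploid genome stand-in with known heterozygous
(1 copy) and homozygous (2 copies) k-mers, and mock microbial communities
with designed fold changes between samples.

Default simulation parameters (read length 125 nt, insert 350 +/- 50 nt,
substitution rate 0.005) emulate a typical Illumina paired-end library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._codec import canonical_codes, encode

__all__ = [
    "SimulationConfig", "ReadBatch", "MockCommunitySpec", "simulate_reads",
    "pairs_for_unit_coverage", "simulate_ladder_library", "subsample_library",
    "inject_duplicates", "make_diploid_sample", "make_trio_pair",
    "make_mock_communities", "default_community_spec",
]

_QUAL_CHAR = chr(30 + 33)  # constant Q30 placeholder


@dataclass(frozen=True)
class SimulationConfig:
    read_len: int = 125
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    error_rate: float = 0.005
    k: int = 31              # used only to convert depth <-> pair counts
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error rate must be in [0, 1)")
        if self.read_len < self.k:
            raise ValueError("read length must be at least k")


@dataclass
class ReadBatch:
    """An in-memory paired-end library (sequences only, constant qualities)."""

    names: list[str]
    r1: list[str]
    r2: list[str]
    template_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.names)

    def subset(self, idx: np.ndarray) -> "ReadBatch":
        idx = np.asarray(idx)
        ti = self.template_index[idx] if self.template_index.size else self.template_index
        return ReadBatch([self.names[i] for i in idx],
                         [self.r1[i] for i in idx],
                         [self.r2[i] for i in idx], ti)

    def __add__(self, other: "ReadBatch") -> "ReadBatch":
        ti = (np.concatenate([self.template_index, other.template_index])
              if self.template_index.size or other.template_index.size
              else np.empty(0, dtype=np.int64))
        return ReadBatch(self.names + other.names, self.r1 + other.r1,
                         self.r2 + other.r2, ti)

    def sequences(self) -> Iterator[str]:
        """All mate sequences, first mates then second mates."""
        yield from self.r1
        yield from self.r2

    def pairs(self) -> Iterator[tuple[str, str, str, str, str]]:
        q = None
        for name, a, b in zip(self.names, self.r1, self.r2):
            if q is None or len(q) != len(a):
                q = _QUAL_CHAR * len(a)
            yield name, a, q, b, _QUAL_CHAR * len(b)


def _decode_matrix(mat: np.ndarray) -> list[str]:
    """uint8 base-code matrix (n_reads x read_len) -> list of strings."""
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    as_bytes = lut[mat].reshape(mat.shape)
    flat = as_bytes.view(f"S{mat.shape[1]}").ravel()
    return [s.decode("ascii") for s in flat]


def _apply_errors(mat: np.ndarray, e: float, rng: np.random.Generator) -> np.ndarray:
    if e <= 0:
        return mat
    mask = rng.random(mat.shape) < e
    n = int(mask.sum())
    if n == 0:
        return mat
    shift = rng.integers(1, 4, size=n).astype(np.uint8)
    mat = mat.copy()
    mat[mask] = (mat[mask] + shift) % 4
    return mat


def simulate_reads(templates: Sequence[tuple[str, str]],
                   weights: Sequence[float],
                   n_pairs: int,
                   config: SimulationConfig = SimulationConfig(),
                   rng: np.random.Generator | None = None) -> ReadBatch:
    """Simulate a paired-end library from weighted templates.

    The number of pairs per template is multinomial with probability
    proportional to ``weight * template_length`` (molar weight times
    molecule size, i.e. base-fraction sampling). Inserts are Gaussian,
    truncated to ``[2 * read_len, template_length]``; fragments that would
    overhang are resampled implicitly through truncation (counted in
    ``ReadBatch.template_index`` bookkeeping only as normal pairs).
    Deterministic for a given rng state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(templates):
        raise ValueError("one weight per template required")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    lengths = np.array([len(seq) for _, seq in templates], dtype=float)
    if np.any(lengths < 2 * config.read_len):
        raise ValueError("every template must be at least 2 x read_len long")
    p = weights * lengths
    p = p / p.sum()
    counts = rng.multinomial(n_pairs, p)

    rl = config.read_len
    names: list[str] = []
    r1: list[str] = []
    r2: list[str] = []
    tidx: list[np.ndarray] = []
    for t, ((tid, seq), n_t) in enumerate(zip(templates, counts)):
        if n_t == 0:
            continue
        arr = encode(seq)
        if np.any(arr > 3):
            raise ValueError(f"template {tid} contains non-ACGT characters")
        tlen = arr.size
        ins = rng.normal(config.insert_mean, config.insert_sd, size=n_t)
        ins = np.clip(np.rint(ins), 2 * rl, tlen).astype(np.int64)
        start = np.floor(rng.random(n_t) * (tlen - ins + 1)).astype(np.int64)
        off = np.arange(rl, dtype=np.int64)
        m1 = arr[start[:, None] + off]
        end = start + ins
        m2 = (3 - arr[(end - rl)[:, None] + off])[:, ::-1]
        m1 = _apply_errors(m1, config.error_rate, rng)
        m2 = _apply_errors(m2, config.error_rate, rng)
        r1.extend(_decode_matrix(m1))
        r2.extend(_decode_matrix(np.ascontiguousarray(m2)))
        names.extend(f"{tid}:{i}" for i in range(n_t))
        tidx.append(np.full(n_t, t, dtype=np.int64))
    template_index = (np.concatenate(tidx) if tidx else np.empty(0, dtype=np.int64))
    return ReadBatch(names, r1, r2, template_index)


def _effective_lengths(templates: Sequence[tuple[str, str]],
                       config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Template lengths and interior (effective) lengths.

    Fragments cannot overhang template ends, so the k-mer mass of a
    template concentrates on an interior of about ``l - insert_mean + 1``
    positions; interior per-position coverage is higher than the naive
    ``mass / length`` by the ratio of the two.
    """
    lengths = np.array([len(seq) for _, seq in templates], dtype=float)
    eff = np.maximum(lengths - config.insert_mean + 1, 2 * config.read_len)
    return lengths, eff


def pairs_for_unit_coverage(templates: Sequence[tuple[str, str]],
                            weights: Sequence[float],
                            unit_weight: float,
                            coverage: float,
                            config: SimulationConfig = SimulationConfig()) -> int:
    """Pairs needed so an interior position of a weight-``unit_weight``
    template reaches the given per-position k-mer coverage.

    Interior coverage of template ``i`` is ``n * wpp * w_i * l_i /
    (eff_i * sum_j(w_j * l_j))`` with ``wpp = 2 * (read_len - k + 1)``
    counted windows per pair and ``eff_i`` the effective interior length;
    the unit template is taken to be the highest-weight one.
    """
    weights = np.asarray(weights, dtype=float)
    lengths, eff = _effective_lengths(templates, config)
    wpp = 2 * (config.read_len - config.k + 1)
    unit = int(np.argmax(weights)) if unit_weight == weights.max() else int(
        np.argmin(np.abs(weights - unit_weight)))
    total_mass = float(np.sum(weights * lengths))
    n = coverage * eff[unit] * total_mass / (wpp * unit_weight * lengths[unit])
    return int(math.ceil(n))


def simulate_ladder_library(ladder_set,
                            depth: float,
                            config: SimulationConfig = SimulationConfig(),
                            *,
                            weights: Sequence[float] | None = None,
                            seed: int | None = None) -> ReadBatch:
    """Equimolar (or custom-weighted) library from a designed ladder set.

    ``depth`` is the target per-copy k-mer coverage: the expected count of a
    catalogued k-mer in a 1-cn element of a weight-1 ladder.
    """
    templates = ladder_set.records()
    if weights is None:
        weights = [1.0] * len(templates)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = pairs_for_unit_coverage(templates, weights, max(weights), depth, config)
    return simulate_reads(templates, weights, n, config, rng)


def subsample_library(batch: ReadBatch, fraction: float,
                      seed: int | np.random.Generator = 0) -> ReadBatch:
    """Exact-count subsample without replacement; read pairs kept intact."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return batch
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = int(len(batch) * fraction)
    idx = np.sort(rng.choice(len(batch), size=m, replace=False))
    return batch.subset(idx)


def inject_duplicates(batch: ReadBatch, dup_rate: float,
                      target_n: int | None = None,
                      seed: int | np.random.Generator = 0) -> ReadBatch:
    """Emulate reduced library complexity at duplication rate ``x``.

    From the unique input pool, ``(1-x) * target_n`` pairs are subsampled
    without replacement; the remaining ``x * target_n`` pairs are drawn with
    replacement from that subsample, so they are guaranteed duplicates of
    retained pairs. With ``x = 0`` the output is a plain subsample.
    """
    if not 0.0 <= dup_rate < 1.0:
        raise ValueError("duplication rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if target_n is None:
        target_n = len(batch)
    n_unique = target_n - int(math.ceil(dup_rate * target_n))
    if n_unique <= 0:
        raise ValueError("target size and duplication rate leave no unique reads")
    if n_unique > len(batch):
        raise ValueError("input pool smaller than requested unique fraction")
    keep = np.sort(rng.choice(len(batch), size=n_unique, replace=False))
    base = batch.subset(keep)
    n_dup = target_n - n_unique
    if n_dup == 0:
        return base
    dup_idx = rng.integers(0, n_unique, size=n_dup)
    dups = base.subset(dup_idx)
    dups.names = [f"{n}:dup{i}" for i, n in enumerate(dups.names)]
    return base + dups


# ---------------------------------------------------------------------------
# synthetic study systems


def _random_seq(rng: np.random.Generator, n: int) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


@dataclass(frozen=True)
class _Segment:
    """One genomic segment of a synthetic diploid blueprint.

    ``core`` is the sequence whose k-mers enter the truth table; ``pad5``
    and ``pad3`` are flanking sequence of the same copy number that buffers
    coverage edge effects, so core k-mer coverage is uniform.
    """

    seg_id: str
    core: str
    pad5: str
    pad3: str
    cn_a: int
    cn_b: int
    kind: str  # "locus" | "background"

    @property
    def template(self) -> str:
        return self.pad5 + self.core + self.pad3


def _segment_truth(segments: list[_Segment], k: int) -> pd.DataFrame:
    """Truth table of canonical k-mer codes per segment core.

    K-mers shared between segments (none in practice for random sequences)
    are dropped so every truth k-mer has a single expected copy number.
    """
    rows = []
    for seg in segments:
        codes = np.unique(canonical_codes(encode(seg.core), k))
        rows.append(pd.DataFrame({
            "code": codes, "locus": seg.seg_id, "kind": seg.kind,
            "cn_a": seg.cn_a, "cn_b": seg.cn_b}))
    truth = pd.concat(rows, ignore_index=True)
    truth = truth[~truth["code"].duplicated(keep=False)].reset_index(drop=True)
    return truth


def _make_segments(loci: list[tuple[str, str, int, int]], n_background: int,
                   rng: np.random.Generator, locus_len: int, pad: int
                   ) -> list[_Segment]:
    segments = [
        _Segment(lid, seq, _random_seq(rng, pad), _random_seq(rng, pad),
                 cn_a, cn_b, "locus")
        for lid, seq, cn_a, cn_b in loci]
    segments += [
        _Segment(f"bg{i}", _random_seq(rng, locus_len), _random_seq(rng, pad),
                 _random_seq(rng, pad), 2, 2, "background")
        for i in range(n_background)]
    order = rng.permutation(len(segments))
    return [segments[i] for i in order]


def _coverage_bias(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Multiplicative per-template coverage bias, lognormal with mean 1.

    Emulates sequence- and preparation-specific coverage variability (GC
    bias, fragmentation bias), the component that makes real count noise
    exceed Poisson; drawn independently per library.
    """
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=n)


def _diploid_library(segments: list[_Segment], which: str, depth: float,
                     ladder_set, shared_bias: np.ndarray, library_cv: float,
                     config: SimulationConfig,
                     rng: np.random.Generator) -> ReadBatch:
    """One library from a segment blueprint.

    Template weights are ``(cn / 2) * bias`` so ``depth`` is the coverage of
    the 2-copy (diploid background) level; ladder molecules are spiked at
    weight ``0.5 * bias`` so the 1-cn unit is commensurate with heterozygous
    k-mers. Coverage bias has two parts: ``shared_bias`` (per template,
    sequence-intrinsic, identical in every library from this blueprint) and
    a lognormal ``library_cv`` residual drawn fresh per library.
    """
    col = {"a": "cn_a", "b": "cn_b"}[which]
    templates = [(f"{seg.seg_id}_{which}", seg.template) for seg in segments]
    base_w = [getattr(seg, col) / 2.0 for seg in segments]
    if ladder_set is not None:
        for lid, seq in ladder_set.records():
            templates.append((f"{lid}_{which}", seq))
            base_w.append(0.5)
    bias = shared_bias * _coverage_bias(rng, len(templates), library_cv)
    base_w = np.asarray(base_w) * bias
    # equalize interior coverage across templates of different lengths
    lengths, eff = _effective_lengths(templates, config)
    weights = base_w * eff / lengths
    wpp = 2 * (config.read_len - config.k + 1)
    n = int(math.ceil(depth * float(np.sum(base_w * eff)) / wpp))
    return simulate_reads(templates, weights, n, config, rng)


def make_diploid_sample(n_hom: int, n_het: int, depth: float,
                        ladder_set=None,
                        config: SimulationConfig = SimulationConfig(),
                        *, locus_len: int = 600, pad: int = 400,
                        n_background: int | None = None,
                        coverage_cv: float = 0.3, library_cv: float = 0.1,
                        seed: int = 0) -> tuple[ReadBatch, pd.DataFrame]:
    """Synthetic diploid sample with known homo-/heterozygous k-mers.

    The genome blueprint is a collection of 600-nt segments: ``n_hom``
    homozygous variant loci and the 2-copy background (by default as many
    background segments as loci) are present at two copies; ``n_het``
    heterozygous loci at one copy, so het k-mers arrive at half the depth
    of hom k-mers. ``depth`` is the coverage of the 2-copy level.
    ``coverage_cv`` adds sequence-intrinsic lognormal per-segment coverage
    bias and ``library_cv`` a smaller per-library residual, together
    emulating the overdispersion of real libraries (0/0 gives clean Poisson
    counts). If a ladder set is given, molecules are spiked at half
    molarity so the 1-cn unit is commensurate with heterozygous k-mers --
    the configuration in which ladder and genome are commutable. Returns
    the library and a truth table (canonical k-mer code -> expected cn,
    with a background flag).
    """
    if n_hom <= 0 or n_het <= 0:
        raise ValueError("need at least one homozygous and one heterozygous locus")
    rng = np.random.default_rng(seed)
    loci = [(f"hom{i}", _random_seq(rng, locus_len), 2, 2) for i in range(n_hom)]
    loci += [(f"het{i}", _random_seq(rng, locus_len), 1, 1) for i in range(n_het)]
    if n_background is None:
        n_background = n_hom + n_het
    segments = _make_segments(loci, n_background, rng, locus_len, pad)
    truth = _segment_truth(segments, config.k)
    truth = truth.rename(columns={"cn_a": "cn"}).drop(columns=["cn_b"])
    n_templates = len(segments) + (len(ladder_set.ladders) if ladder_set is not None else 0)
    shared = _coverage_bias(rng, n_templates, coverage_cv)
    batch = _diploid_library(segments, "a", depth, ladder_set, shared,
                             library_cv, config, rng)
    return batch, truth


def make_trio_pair(n_hom: int, n_het: int, n_gain: int, depth: float,
                   ladder_set=None,
                   config: SimulationConfig = SimulationConfig(),
                   *, n_loss: int | None = None,
                   locus_len: int = 600, pad: int = 400,
                   n_background: int | None = None,
                   coverage_cv: float = 0.3, library_cv: float = 0.1,
                   seed: int = 0) -> tuple[ReadBatch, ReadBatch, pd.DataFrame]:
    """Two related samples sharing variants, subsets at designed 2-fold changes.

    Both samples carry ``n_hom`` homozygous and ``n_het`` heterozygous
    unchanged loci; ``n_gain`` loci go from heterozygous to homozygous in
    sample B (fold change 2) and ``n_loss`` loci (default: same as
    ``n_gain``) go the other way (fold change 0.5), as happens for
    consanguineous variants between related genomes. Both libraries share
    the blueprint's sequence-intrinsic coverage bias (``coverage_cv``) and
    differ by an independent per-library residual (``library_cv``),
    yielding a labelled truth set for ROC evaluation of fold-difference
    detection with and without the ladder.
    """
    if n_loss is None:
        n_loss = n_gain
    rng = np.random.default_rng(seed)
    loci = [(f"hom{i}", _random_seq(rng, locus_len), 2, 2) for i in range(n_hom)]
    loci += [(f"het{i}", _random_seq(rng, locus_len), 1, 1) for i in range(n_het)]
    loci += [(f"gain{i}", _random_seq(rng, locus_len), 1, 2) for i in range(n_gain)]
    loci += [(f"loss{i}", _random_seq(rng, locus_len), 2, 1) for i in range(n_loss)]
    if n_background is None:
        n_background = n_hom + n_het
    segments = _make_segments(loci, n_background, rng, locus_len, pad)
    truth = _segment_truth(segments, config.k)
    truth["fold_change"] = truth["cn_b"] / truth["cn_a"]
    truth["changed"] = truth["cn_a"] != truth["cn_b"]
    n_templates = len(segments) + (len(ladder_set.ladders) if ladder_set is not None else 0)
    shared = _coverage_bias(rng, n_templates, coverage_cv)
    batch_a = _diploid_library(segments, "a", depth, ladder_set, shared,
                               library_cv, config, rng)
    batch_b = _diploid_library(segments, "b", depth, ladder_set, shared,
                               library_cv, config, rng)
    return batch_a, batch_b, truth


# ---------------------------------------------------------------------------
# mock microbial communities


@dataclass
class MockCommunitySpec:
    """Species windows and per-community relative abundances.

    ``abundances`` has one row per community, one column per species, each
    row summing to 1 (the ladder fraction is carved out at simulation time).
    Designed fold changes between a community pair are the ratios of the
    corresponding abundance rows.
    """

    species: list[str]
    window_len: int = 100_000
    windows_per_species: int = 1
    abundances: pd.DataFrame | None = None
    ladder_fraction: float = 0.01

    def __post_init__(self):
        if self.abundances is None:
            raise ValueError("abundances table required")
        if list(self.abundances.columns) != list(self.species):
            raise ValueError("abundance columns must match species")
        sums = self.abundances.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("abundance rows must sum to 1")
        if not 0.0 <= self.ladder_fraction < 1.0:
            raise ValueError("ladder fraction must be in [0, 1)")

    def fold_changes(self, pair: tuple[str, str]) -> pd.Series:
        a, b = pair
        return self.abundances.loc[b] / self.abundances.loc[a]

    def is_balanced(self, pair: tuple[str, str], tol: float = 1e-9) -> bool:
        return bool(abs(np.log(self.fold_changes(pair)).sum()) < tol)


def default_community_spec() -> MockCommunitySpec:
    """Nine-species communities A, B, C with designed fold changes.

    A->B fold changes span {0.3, 0.6, 1, 2} and are unbalanced (sum of log
    fold changes -1.86, window-median fold change 0.6); A->C fold changes
    are balanced (sum of log fold changes exactly 0). Abundances satisfy the
    physical constraint that each community's relative abundances sum to 1,
    i.e. sum_i a_i (FC_i - 1) = 0 for both pairs.
    """
    species = [f"sp{i + 1}" for i in range(9)]
    a = np.array([0.08, 0.16, 0.08, 0.16, 0.06, 0.172, 0.096, 0.096, 0.096])
    fc_b = np.array([0.3, 0.3, 0.6, 0.6, 0.6, 1.0, 2.0, 2.0, 2.0])
    fc_c = np.array([2.0, 0.5, 2.0, 0.5, 1.0, 1.0, 1.0, 1.0, 1.0])
    ab = pd.DataFrame([a, a * fc_b, a * fc_c], index=["A", "B", "C"], columns=species)
    ab = ab.div(ab.sum(axis=1), axis=0)
    return MockCommunitySpec(species=species, abundances=ab)


def make_mock_communities(spec: MockCommunitySpec,
                          ladder_set,
                          library_pairs: int | dict[str, int],
                          config: SimulationConfig = SimulationConfig(),
                          *, seed: int = 0
                          ) -> tuple[dict[str, ReadBatch], pd.DataFrame, dict[str, str]]:
    """Simulate one library per community with the ladder spiked in.

    Returns per-community read batches, a truth table of designed fold
    changes per species and community pair, and the species window
    sequences (for building feature catalogs).
    """
    rng = np.random.default_rng(seed)
    genomes: dict[str, str] = {}
    templates: list[tuple[str, str]] = []
    for sp in spec.species:
        seq = _random_seq(rng, spec.window_len * spec.windows_per_species)
        genomes[sp] = seq
        templates.append((sp, seq))
    ladder_records = ladder_set.records()
    templates.extend(ladder_records)
    ladder_len = sum(len(s) for _, s in ladder_records)

    batches: dict[str, ReadBatch] = {}
    for comm in spec.abundances.index:
        fracs = spec.abundances.loc[comm].to_numpy() * (1.0 - spec.ladder_fraction)
        weights = list(fracs / np.array([len(genomes[sp]) for sp in spec.species]))
        # equimolar ladder molecules totalling ladder_fraction of bases
        for _, seq in ladder_records:
            weights.append(spec.ladder_fraction / ladder_len)
        n = library_pairs[comm] if isinstance(library_pairs, dict) else library_pairs
        batches[comm] = simulate_reads(templates, weights, n, config, rng)

    comms = list(spec.abundances.index)
    rows = []
    for i, a in enumerate(comms):
        for b in comms[i + 1:]:
            fc = spec.fold_changes((a, b))
            for sp in spec.species:
                rows.append({"pair": f"{a}-{b}", "species": sp,
                             "fold_change": float(fc[sp])})
    truth = pd.DataFrame(rows)
    return batches, truth, genomes
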