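"""Design of synthetic copy-number ladder molecules.

A ladder is a single continuous DNA molecule encoding four artificial
600-nt *elements* repeated at copy numbers (cn) 1, 2, 4 and 8. When such a
molecule is sequenced, read (and k-mer) counts per element are proportional
to the element's cn, so the molecule carries a graduated quantitative scale
that needs no mixing of separate spike-ins. Elements are obtained by
shuffling windows of a template genome, which preserves natural base
composition while destroying homology; every element is screened so that it
shares no exact substring longer than a bound (25 nt by default) with the
screened references. Elements are joined with unique 20-nt spacers, and a
common 500-nt flank is added at each end to buffer coverage edge effects.

Default geometry: 2 x 500 (flanks) + 15 x 600 (element copies)
+ 14 x 20 (spacers) = 10,280 nt per molecule, 14 molecules per set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._codec import INVALID, canonical_codes, decode, encode
from .homology import HomologyScreen, ScreenReport, screen_homology

__all__ = [
    "DesignConfig", "SourceWindow", "LadderElement", "AnnotationInterval",
    "LadderDesign", "LadderSet", "shuffle_template", "screen_homology",
    "ScreenReport", "check_composition", "assemble_ladder",
    "design_ladder_set", "random_template",
]


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of ladder design (defaults match the published geometry)."""

    element_len: int = 600
    cn_vector: tuple[int, ...] = (1, 2, 4, 8)
    spacer_len: int = 20
    flank_len: int = 500
    n_ladders: int = 14
    k: int = 31               # k-mer length used for uniqueness screening
    max_match: int = 25       # homology bound, nt
    max_attempts: int = 100   # re-shuffle / spacer retry budget

    @property
    def ladder_len(self) -> int:
        total_cn = sum(self.cn_vector)
        return (2 * self.flank_len + total_cn * self.element_len
                + (total_cn - 1) * self.spacer_len)


@dataclass(frozen=True)
class SourceWindow:
    template_id: str
    start: int
    end: int


@dataclass(frozen=True)
class LadderElement:
    element_id: str
    sequence: str
    source: SourceWindow
    assigned_cn: int


@dataclass(frozen=True)
class AnnotationInterval:
    """Half-open [start, end) interval on the ladder molecule."""

    start: int
    end: int
    feature: str              # "flank_5p" | "element" | "spacer" | "flank_3p"
    element_id: str | None
    copy_index: int | None
    cn: int | None


@dataclass
class LadderDesign:
    ladder_id: str
    elements: list[LadderElement]
    spacer_sequences: list[str]
    flank_5p: str
    flank_3p: str
    full_sequence: str
    annotation: list[AnnotationInterval]

    def element_intervals(self) -> list[AnnotationInterval]:
        return [iv for iv in self.annotation if iv.feature == "element"]


@dataclass
class LadderSet:
    ladders: list[LadderDesign]
    config: DesignConfig
    template_id: str = "template"

    def __iter__(self):
        return iter(self.ladders)

    def __len__(self):
        return len(self.ladders)

    def records(self) -> list[tuple[str, str]]:
        return [(lad.ladder_id, lad.full_sequence) for lad in self.ladders]


def _validate_acgt(seq: str, what: str) -> np.ndarray:
    arr = encode(seq)
    if np.any(arr == INVALID):
        raise ValueError(f"{what} must contain only A/C/G/T characters")
    return arr


def shuffle_template(template_window: str, seed: int) -> str:
    """Uniformly random permutation of a template window's bases.

    Shuffling preserves the length and exact base multiset (hence GC
    content) of the source window while destroying its sequence homology.
    Deterministic for a fixed seed.
    """
    arr = _validate_acgt(template_window, "template window")
    rng = np.random.default_rng(seed)
    return decode(rng.permutation(arr))


def check_composition(candidate: str, bounds: tuple[float, float] = (0.0, 1.0)) -> tuple[bool, float]:
    """GC fraction of a candidate and whether it lies within ``bounds``."""
    if not candidate:
        raise ValueError("candidate must be non-empty")
    arr = _validate_acgt(candidate, "candidate")
    gc = float(np.mean((arr == 1) | (arr == 2)))
    lo, hi = bounds
    return (lo <= gc <= hi), gc


def _random_acgt(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, size=n).astype(np.uint8))


def random_template(length: int = 1_000_000, seed: int = 0,
                    template_id: str = "synthetic_template") -> tuple[str, str]:
    """Seeded random ACGT template for designs that do not start from a genome."""
    rng = np.random.default_rng(seed)
    return template_id, _random_acgt(rng, length)


def _count_occurrences(haystack: str, needle: str) -> int:
    """Occurrences of needle in haystack, overlapping matches included."""
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def assemble_ladder(elements: Sequence[LadderElement],
                    config: DesignConfig = DesignConfig(),
                    *,
                    ladder_id: str = "ladder",
                    flank_5p: str | None = None,
                    flank_3p: str | None = None,
                    seed: int = 0) -> LadderDesign:
    """Join elements into one ladder molecule with spacers and flanks.

    Copies of each element are placed as a tandem block; block order is
    randomised by ``seed``. A fresh unique 20-nt spacer separates every
    adjacent pair of element copies. Spacers and flanks are screened so the
    molecule contains no k-mer outside element intervals that collides with
    an element's canonical k-mer set (such a collision would corrupt the
    catalog); generation is retried up to ``config.max_attempts`` times.
    """
    if len(elements) != len(config.cn_vector):
        raise ValueError("need exactly one element per cn level")
    if any(c <= 0 for c in config.cn_vector):
        raise ValueError("copy numbers must be strictly positive")
    cns = sorted(set(e.assigned_cn for e in elements))
    if cns != sorted(config.cn_vector):
        raise ValueError("element cn assignments must match the config cn vector")

    rng = np.random.default_rng(seed)
    k = config.k
    element_codes = np.unique(np.concatenate(
        [canonical_codes(encode(e.sequence), k) for e in elements]))

    for _ in range(config.max_attempts):
        f5 = flank_5p if flank_5p is not None else _random_acgt(rng, config.flank_len)
        f3 = flank_3p if flank_3p is not None else _random_acgt(rng, config.flank_len)
        order = rng.permutation(len(elements))
        n_spacers = sum(config.cn_vector) - 1
        spacers = [_random_acgt(rng, config.spacer_len) for _ in range(n_spacers)]
        if len(set(spacers)) != n_spacers:
            continue

        parts: list[str] = [f5]
        annotation: list[AnnotationInterval] = [
            AnnotationInterval(0, len(f5), "flank_5p", None, None, None)]
        pos = len(f5)
        spacer_iter = iter(spacers)
        first_copy = True
        for oi in order:
            elem = elements[oi]
            for copy_index in range(elem.assigned_cn):
                if not first_copy:
                    sp = next(spacer_iter)
                    parts.append(sp)
                    annotation.append(AnnotationInterval(
                        pos, pos + len(sp), "spacer", None, None, None))
                    pos += len(sp)
                parts.append(elem.sequence)
                annotation.append(AnnotationInterval(
                    pos, pos + len(elem.sequence), "element",
                    elem.element_id, copy_index, elem.assigned_cn))
                pos += len(elem.sequence)
                first_copy = False
        parts.append(f3)
        annotation.append(AnnotationInterval(pos, pos + len(f3), "flank_3p", None, None, None))
        full = "".join(parts)

        # no k-mer outside element intervals may collide with the element
        # catalog; invalidating element interiors leaves exactly the windows
        # not fully contained in an element (junctions, spacers, flanks)
        masked = np.array(encode(full))
        for iv in annotation:
            if iv.feature == "element":
                masked[iv.start + k - 1 : iv.end - k + 1] = INVALID
        outside = np.unique(canonical_codes(masked, k))
        if np.intersect1d(outside, element_codes, assume_unique=True).size:
            continue

        design = LadderDesign(ladder_id=ladder_id, elements=list(elements),
                              spacer_sequences=spacers, flank_5p=f5, flank_3p=f3,
                              full_sequence=full, annotation=annotation)
        assert len(full) == config.ladder_len
        return design
    raise RuntimeError(
        f"could not assemble {ladder_id}: spacer/flank screening failed "
        f"after {config.max_attempts} attempts")


def design_ladder_set(template: tuple[str, str] | None = None,
                      config: DesignConfig = DesignConfig(),
                      *,
                      extra_references: dict[str, str] | None = None,
                      seed: int = 0) -> LadderSet:
    """Design a full set of ladder molecules from a template sequence.

    ``template`` is a ``(template_id, sequence)`` pair (any genome or a
    seeded random sequence; defaults to a random 1-Mb template derived from
    ``seed``). Disjoint windows of the template are shuffled into elements,
    each screened against the template (both strands, exact substrings
    <= ``config.max_match``) and re-shuffled on failure; canonical k-mer
    sets of all elements are kept pairwise disjoint so the downstream
    catalog is unambiguous. Deterministic for fixed template, config, seed.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(3)
    rng = np.random.default_rng(child[0])

    if template is None:
        template = random_template(seed=int(child[1].generate_state(1)[0] % (2**31)))
    template_id, template_seq = template
    _validate_acgt(template_seq, "template")

    n_elements = config.n_ladders * len(config.cn_vector)
    n_slots = len(template_seq) // config.element_len
    if n_slots < n_elements:
        raise ValueError(
            f"template too short: {len(template_seq)} nt provides {n_slots} "
            f"disjoint windows, need {n_elements}")

    references = {template_id: template_seq}
    if extra_references:
        references.update(extra_references)
    screen = HomologyScreen(references)

    slots = rng.choice(n_slots, size=n_elements, replace=False)
    k = config.k
    accepted: list[LadderElement] = []
    used_codes = np.empty(0, dtype=np.uint64)
    n_per_element = config.element_len - k + 1

    shuffle_seeds = np.random.default_rng(child[2]).integers(0, 2**31, size=10 * n_elements)
    seed_cursor = 0
    for ei, slot in enumerate(slots):
        start = int(slot) * config.element_len
        window = template_seq[start : start + config.element_len]
        ok = False
        for _ in range(config.max_attempts):
            cand = shuffle_template(window, int(shuffle_seeds[seed_cursor % shuffle_seeds.size]))
            seed_cursor += 1
            longest, _ref = screen.longest_match(cand)
            if longest > config.max_match:
                continue
            codes = np.unique(canonical_codes(encode(cand), k))
            if codes.size != n_per_element:
                continue  # internal duplicate or palindromic collision
            if np.intersect1d(codes, used_codes, assume_unique=True).size:
                continue
            used_codes = np.union1d(used_codes, codes)
            accepted.append(LadderElement(
                element_id=f"E{ei + 1:03d}", sequence=cand,
                source=SourceWindow(template_id, start, start + config.element_len),
                assigned_cn=0))
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"homology/uniqueness screen unsatisfiable for window at {start} "
                f"after {config.max_attempts} shuffles")

    # common 5'/3' flanks shared by every ladder in the set, screened against
    # the template and against all element k-mers
    flank_5p = flank_3p = None
    for _ in range(config.max_attempts):
        f5 = _random_acgt(rng, config.flank_len)
        f3 = _random_acgt(rng, config.flank_len)
        if screen.longest_match(f5)[0] > config.max_match:
            continue
        if screen.longest_match(f3)[0] > config.max_match:
            continue
        fc = np.unique(np.concatenate([canonical_codes(encode(f5), k),
                                       canonical_codes(encode(f3), k)]))
        if np.intersect1d(fc, used_codes, assume_unique=True).size:
            continue
        flank_5p, flank_3p = f5, f3
        break
    if flank_5p is None:
        raise RuntimeError("could not generate screened common flanks")

    # randomly organise elements into ladders; cn assigned in vector order
    perm = rng.permutation(n_elements)
    ladders: list[LadderDesign] = []
    assembly_seeds = rng.integers(0, 2**31, size=config.n_ladders)
    for li in range(config.n_ladders):
        group = [accepted[perm[li * len(config.cn_vector) + j]]
                 for j in range(len(config.cn_vector))]
        group = [LadderElement(e.element_id, e.sequence, e.source, cn)
                 for e, cn in zip(group, config.cn_vector)]
        ladders.append(assemble_ladder(
            group, config, ladder_id=f"ladder_{li + 1:02d}",
            flank_5p=flank_5p, flank_3p=flank_3p,
            seed=int(assembly_seeds[li])))
    return LadderSet(ladders=ladders, config=config, template_id=template_id)
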