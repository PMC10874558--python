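"""Amplicon architecture: locus model, fragment library, and pattern arithmetic.

The edited locus is amplified as ``left_flank + (inserted fragments) +
right_flank``.  A double-cut donor releases a small number of linear
fragments (e.g. an expression cassette ``F`` and the vector backbone ``B``)
that can be captured at the break in any combination and orientation.  This
module enumerates those combinations, computes exact expected product
lengths, and derives the read-length grouping windows used to bin noisy
long reads before probe-based content filtering.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations_with_replacement, product
from typing import Iterable, Literal, Sequence

from .errors import ConfigError, ReferenceError_

Rounding = Literal["nearest100", "exact"]


@dataclass(frozen=True)
class FragmentComponent:
    """A named insertable (or scan-only) DNA component.

    ``insertable`` distinguishes linearized donor pieces, which can be
    captured at the break, from circular-plasmid references that are only
    scanned for degraded remnants.
    """

    name: str
    sequence: str
    insertable: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)


class FragmentLibrary:
    """Unique-named collection of :class:`FragmentComponent`."""

    def __init__(self, components: Iterable[FragmentComponent]):
        self._components: dict[str, FragmentComponent] = {}
        for comp in components:
            if comp.name in self._components:
                raise ConfigError(f"duplicate component name: {comp.name!r}")
            self._components[comp.name] = comp

    def __iter__(self):
        return iter(self._components.values())

    def __len__(self) -> int:
        return len(self._components)

    def __contains__(self, name: str) -> bool:
        return name in self._components

    @property
    def names(self) -> list[str]:
        return list(self._components)

    @property
    def insertable(self) -> list[FragmentComponent]:
        return [c for c in self._components.values() if c.insertable]

    def get(self, name: str) -> FragmentComponent:
        try:
            return self._components[name]
        except KeyError:
            raise ReferenceError_(f"unknown component: {name!r}") from None


@dataclass(frozen=True)
class LocusModel:
    """The edited locus: retained flanks, cut position, homology arms.

    ``cut_position`` is the 1-based offset of the double-strand break within
    the background amplicon ``left_flank + right_flank`` (the break falls
    immediately after that base).  Arms may be empty (zero-length homology
    arm designs are legitimate).  ``exclusion_regions`` are (contig, start,
    end) half-open intervals on an optional genome reference whose hits are
    discarded during foreign-insert alignment (homologs of the locus or of
    the donor).
    """

    left_flank: str
    right_flank: str
    cut_position: int | None = None
    left_arm: str = ""
    right_arm: str = ""
    exclusion_regions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        if not self.left_flank or not self.right_flank:
            raise ConfigError("both flanks must be non-empty")
        if self.cut_position is None:
            object.__setattr__(self, "cut_position", len(self.left_flank))

    @property
    def background_length(self) -> int:
        """Length of the insert-free (wild-type) amplicon."""
        return len(self.left_flank) + len(self.right_flank)

    @property
    def background_sequence(self) -> str:
        return self.left_flank + self.right_flank


@dataclass(frozen=True)
class PatternCategory:
    """An unordered multiset of inserted components with its length window."""

    composition: tuple[str, ...]  # sorted component names, possibly repeated
    expected_length: int
    window: tuple[int, int]

    @property
    def name(self) -> str:
        return "".join(self.composition) if self.composition else "background"

    @property
    def multiset(self) -> Counter:
        return Counter(self.composition)


@dataclass(frozen=True)
class OrientationPattern:
    """Ordered chain of (component name, orientation) pairs.

    Orientation is ``"f"`` (forward, as in the library) or ``"r"``
    (reverse complement).
    """

    chain: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for _, orient in self.chain:
            if orient not in ("f", "r"):
                raise ConfigError(f"orientation must be 'f' or 'r', got {orient!r}")

    @property
    def multiset(self) -> Counter:
        return Counter(name for name, _ in self.chain)

    @property
    def composition(self) -> tuple[str, ...]:
        return tuple(sorted(name for name, _ in self.chain))

    def __str__(self) -> str:
        return "+".join(f"{name}{orient}" for name, orient in self.chain) or "empty"

    @classmethod
    def parse(cls, text: str) -> "OrientationPattern":
        """Parse the compact ``"Bf+Fr"`` chain notation."""
        if text in ("", "empty"):
            return cls(())
        chain = []
        for token in text.split("+"):
            if len(token) < 2 or token[-1] not in "fr":
                raise ConfigError(f"malformed pattern token: {token!r}")
            chain.append((token[:-1], token[-1]))
        return cls(tuple(chain))


def expected_length(composition: Sequence[str], library: FragmentLibrary, locus: LocusModel) -> int:
    """Expected perfect product length for a composition (background + pieces)."""
    return locus.background_length + sum(library.get(name).length for name in composition)


def grouping_window(
    expected: int, fraction: float, rounding: Rounding = "nearest100"
) -> tuple[int, int]:
    """Read-length window ``expected +- pad`` for binning noisy reads.

    ``pad = fraction * expected``, with the half-width rounded to the
    nearest 100 bp under the default rule (the rule that reproduces the
    published single-backbone example), or kept exact (bounds rounded to
    the nearest integer).  The lower bound is clamped to 1.
    """
    if not (0 <= fraction < 1):
        raise ConfigError(f"fraction must be in [0, 1), got {fraction}")
    pad = fraction * expected
    if rounding == "nearest100":
        pad = 100 * round(pad / 100)
        lo, hi = expected - pad, expected + pad
    elif rounding == "exact":
        lo, hi = round(expected - pad), round(expected + pad)
    else:
        raise ConfigError(f"unknown rounding rule: {rounding!r}")
    return (max(1, int(lo)), int(hi))


def enumerate_categories(
    library: FragmentLibrary,
    locus: LocusModel,
    max_pieces: int = 3,
    fraction: float = 0.20,
    rounding: Rounding = "nearest100",
) -> list[PatternCategory]:
    """All multisets of 1..max_pieces insertable components, with windows.

    For ``n`` insertable components the count is
    ``sum_k C(n + k - 1, k)`` for ``k = 1..max_pieces`` (e.g. nine
    categories for two components and up to three pieces).
    """
    insertable = library.insertable
    if not insertable:
        raise ConfigError("fragment library has no insertable components")
    if max_pieces < 1:
        raise ConfigError("max_pieces must be >= 1")
    names = sorted(c.name for c in insertable)
    categories = []
    for k in range(1, max_pieces + 1):
        for combo in combinations_with_replacement(names, k):
            length = expected_length(combo, library, locus)
            categories.append(
                PatternCategory(
                    composition=combo,
                    expected_length=length,
                    window=grouping_window(length, fraction, rounding),
                )
            )
    return categories


def background_category(
    locus: LocusModel, fraction: float = 0.20, rounding: Rounding = "nearest100"
) -> PatternCategory:
    """The insert-free pseudo-category (wild-type amplicon)."""
    length = locus.background_length
    return PatternCategory((), length, grouping_window(length, fraction, rounding))


def enumerate_orientation_patterns(
    n_pieces: int, library: FragmentLibrary
) -> list[OrientationPattern]:
    """All ordered chains of exactly ``n_pieces`` oriented insertable components.

    Count is ``(2 * n_components) ** n_pieces``; ``n_pieces = 0`` yields the
    single empty chain.
    """
    if n_pieces < 0:
        raise ConfigError("n_pieces must be >= 0")
    names = sorted(c.name for c in library.insertable)
    alphabet = [(name, orient) for name in names for orient in ("f", "r")]
    return [OrientationPattern(chain) for chain in product(alphabet, repeat=n_pieces)]


def category_count(n_components: int, max_pieces: int) -> int:
    """Closed-form multiset count ``sum_k C(n+k-1, k)``."""
    return sum(math.comb(n_components + k - 1, k) for k in range(1, max_pieces + 1))
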