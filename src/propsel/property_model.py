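"""Magnitude categories and the neutral expected distribution.

Each replacement of one amino acid by another changes the value of a
physicochemical property by some signed amount.  The magnitude |delta| is
binned into 8 equal-width categories spanning [0, max |delta|], where the
maximum is taken over the genetic code's nonsynonymous single-nucleotide
neighborhood: category 1 holds the most conservative changes, category 8 the
most radical.  Under selective neutrality every nonsynonymous neighborhood
pair is equally likely, so the expected probability of category k is simply
the fraction of neighborhood pairs whose magnitude falls in bin k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateRangeError, PropertyLookupError
from .genetic_code import NeighborhoodPair
from .io import PropertyTable

N_CATEGORIES = 8

#: Conservative categories: positive selection here is stabilizing.
STABILIZING_CATEGORIES = (1, 2, 3)
#: Radical categories: positive selection here is destabilizing.
DESTABILIZING_CATEGORIES = (6, 7, 8)


@dataclass(frozen=True)
class MagnitudeBinning:
    """Equal-width 8-category binning of |property change| for one property.

    Bins are half-open [lo, hi) with the final bin closed, so a magnitude
    equal to a bin's upper edge falls in the higher bin except at the global
    maximum, which is category 8.
    """

    property_name: str
    max_magnitude: float

    @property
    def width(self) -> float:
        return self.max_magnitude / N_CATEGORIES

    @property
    def edges(self) -> np.ndarray:
        """The 9 bin edges from 0 to the maximum magnitude."""
        return np.linspace(0.0, self.max_magnitude, N_CATEGORIES + 1)

    def category(self, magnitude: float) -> int:
        """Category 1..8 of an absolute property change."""
        if magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if magnitude >= self.max_magnitude:
            return N_CATEGORIES
        return min(int(magnitude // self.width) + 1, N_CATEGORIES)


def make_binning(
    prop: str, table: PropertyTable, neighborhood: list[NeighborhoodPair]
) -> MagnitudeBinning:
    """Build the 8-category binning for one property over a neighborhood."""
    if prop not in table.values:
        raise PropertyLookupError(f"unknown property {prop!r}")
    if not neighborhood:
        raise DegenerateRangeError("empty neighborhood")
    max_mag = max(abs(table.delta(prop, p.source_aa, p.target_aa)) for p in neighborhood)
    if max_mag == 0.0:
        raise DegenerateRangeError(
            f"property {prop!r} is constant over the neighborhood"
        )
    return MagnitudeBinning(property_name=prop, max_magnitude=max_mag)


def categorize_change(
    from_aa: str, to_aa: str, binning: MagnitudeBinning, table: PropertyTable
) -> int:
    """Magnitude category 1..8 of the replacement from_aa -> to_aa.

    Symmetric in its amino-acid arguments: only |delta| matters, the
    direction of change is recorded on events but does not affect the
    category.
    """
    magnitude = abs(table.delta(binning.property_name, from_aa, to_aa))
    return binning.category(magnitude)


def expected_distribution(
    prop: str,
    table: PropertyTable,
    neighborhood: list[NeighborhoodPair],
    binning: MagnitudeBinning,
) -> np.ndarray:
    """Neutral category probabilities (length 8, sums to 1).

    p_k is the fraction of nonsynonymous neighborhood pairs whose property
    change magnitude falls in bin k, i.e. the category distribution expected
    under completely random amino acid replacement.
    """
    if not neighborhood:
        raise DegenerateRangeError("empty neighborhood")
    counts = np.zeros(N_CATEGORIES)
    for pair in neighborhood:
        cat = categorize_change(pair.source_aa, pair.target_aa, binning, table)
        counts[cat - 1] += 1
    return counts / counts.sum()


@dataclass(frozen=True)
class NullModel:
    """Per-property binnings and expected category distributions.

    Convenience bundle tying one property table to one genetic code's
    nonsynonymous neighborhood; this is the complete neutral reference the
    selection statistics compare against.
    """

    table: PropertyTable
    binnings: dict[str, MagnitudeBinning]
    expecteds: dict[str, np.ndarray]
    #: amino-acid pairs reachable by one nucleotide change (the null's support)
    aa_pairs: frozenset[tuple[str, str]]

    @classmethod
    def build(
        cls, table: PropertyTable, neighborhood: list[NeighborhoodPair]
    ) -> "NullModel":
        binnings = {}
        expecteds = {}
        for prop in table.properties:
            binning = make_binning(prop, table, neighborhood)
            binnings[prop] = binning
            expecteds[prop] = expected_distribution(prop, table, neighborhood, binning)
        aa_pairs = frozenset(
            (p.source_aa, p.target_aa) for p in neighborhood if not p.synonymous
        )
        return cls(
            table=table, binnings=binnings, expecteds=expecteds, aa_pairs=aa_pairs
        )

    def in_support(self, from_aa: str, to_aa: str) -> bool:
        """Whether a replacement lies in the single-step neighborhood."""
        return (from_aa, to_aa) in self.aa_pairs

    @property
    def properties(self) -> list[str]:
        return list(self.binnings)

    def categorize(self, prop: str, from_aa: str, to_aa: str) -> int:
        return categorize_change(from_aa, to_aa, self.binnings[prop], self.table)
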