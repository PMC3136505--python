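"""Cross-clade comparison of positively-destabilized sites.

Each clade group is analyzed separately on the same master alignment
coordinate system, so a codon site is identified across groups by the pair
(gene, site).  For every property the comparison counts the sites flagged as
positive-destabilizing in *all* groups of a grouping (e.g. amphibians and
lungfishes, A-L), and additionally reports a deduplicated total per grouping
in which a site shared under several properties counts once.  Per-property
cells must never be summed across properties to produce a total — the same
site is typically hit by more than one property — so the deduplicated union
count is reported separately and the report enforces the no-totaling rule as
a checked invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError
from .selection import SelectionCall

#: Site identity across separately-analyzed groups: (gene name, 1-based site).
SiteKey = tuple[str, int]

#: The grouping columns of the cross-clade report, in fixed order.
DEFAULT_GROUPINGS: tuple[tuple[str, ...], ...] = (
    ("A", "L"),
    ("A", "C"),
    ("L", "C"),
    ("A", "L", "C"),
)


@dataclass
class GroupCallSet:
    """Per-property sets of positive-destabilizing sites for one group."""

    group: str
    sites_by_property: dict[str, set[SiteKey]] = field(default_factory=dict)

    def add(self, prop: str, site: SiteKey) -> None:
        self.sites_by_property.setdefault(prop, set()).add(site)

    def sites(self, prop: str) -> set[SiteKey]:
        return self.sites_by_property.get(prop, set())

    @property
    def all_sites(self) -> set[SiteKey]:
        out: set[SiteKey] = set()
        for sites in self.sites_by_property.values():
            out |= sites
        return out

    def merge(self, other: "GroupCallSet") -> "GroupCallSet":
        if other.group != self.group:
            raise ConfigError(f"cannot merge call sets of {self.group!r} and {other.group!r}")
        merged = GroupCallSet(group=self.group)
        for src in (self, other):
            for prop, sites in src.sites_by_property.items():
                merged.sites_by_property.setdefault(prop, set()).update(sites)
        return merged


def collect_calls(calls: list[SelectionCall], gene: str, group: str) -> GroupCallSet:
    """Distinct positive-destabilizing sites per property for one gene.

    Calls in categories 6-8 are merged: a site flagged in several radical
    categories appears once per property.
    """
    out = GroupCallSet(group=group)
    for call in calls:
        if call.direction == "positive" and call.regime == "destabilizing":
            out.add(call.property_name, (gene, call.site))
    return out


def merge_call_sets(call_sets: list[GroupCallSet]) -> GroupCallSet:
    """Union call sets of one group across genes."""
    if not call_sets:
        raise ConfigError("no call sets to merge")
    merged = call_sets[0]
    for cs in call_sets[1:]:
        merged = merged.merge(cs)
    return merged


@dataclass
class GroupComparison:
    """The cross-clade shared-site report.

    ``per_property``: rows = properties, columns = grouping names (e.g.
    'A-L'), cells = number of sites flagged positive-destabilizing for that
    property in every group of the grouping.  ``totals``: per grouping, the
    deduplicated count of sites shared under at least one property (a site
    hit by several properties counts once) — per-property cells are NOT to
    be totaled.
    """

    per_property: pd.DataFrame
    totals: dict[str, int]

    def check_invariants(self) -> None:
        for grouping, total in self.totals.items():
            column_sum = int(self.per_property[grouping].sum())
            if total > column_sum:
                raise AssertionError(
                    f"deduplicated total {total} exceeds per-property sum {column_sum} "
                    f"for {grouping}; totaling rule violated"
                )

    def to_tsv(self, path) -> None:
        self.check_invariants()
        with open(path, "w") as fh:
            fh.write("# Shared positive-destabilizing sites per property and grouping.\n")
            fh.write("# Per-property cells are NOT to be totaled: a site affected by\n")
            fh.write("# several properties counts once in the deduplicated totals below.\n")
            fh.write("property\t" + "\t".join(self.per_property.columns) + "\n")
            for prop, row in self.per_property.iterrows():
                fh.write(prop + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
            fh.write("\n")
            fh.write("grouping\tdeduplicated_shared_sites\n")
            for grouping, total in self.totals.items():
                fh.write(f"{grouping}\t{total}\n")


def intersect_groups(
    call_sets: dict[str, GroupCallSet],
    groupings: tuple[tuple[str, ...], ...] = DEFAULT_GROUPINGS,
    properties: list[str] | None = None,
) -> GroupComparison:
    """Count shared flagged sites for each grouping of clade groups.

    For property p and grouping G the cell is |intersection over g in G of
    sites(g, p)|.  The deduplicated total per grouping is the size of the
    union over properties of those per-property intersections.
    """
    if len(call_sets) < 2:
        raise ConfigError("need at least 2 groups to compare")
    for grouping in groupings:
        unknown = [g for g in grouping if g not in call_sets]
        if unknown:
            raise ConfigError(f"unknown group(s) in grouping {grouping}: {unknown}")
    if properties is None:
        props: list[str] = []
        for cs in call_sets.values():
            for prop in cs.sites_by_property:
                if prop not in props:
                    props.append(prop)
    else:
        props = list(properties)

    names = ["-".join(g) for g in groupings]
    rows = []
    union_per_grouping: dict[str, set[SiteKey]] = {name: set() for name in names}
    for prop in props:
        cells = []
        for grouping, name in zip(groupings, names):
            shared = set.intersection(*(call_sets[g].sites(prop) for g in grouping))
            union_per_grouping[name] |= shared
            cells.append(len(shared))
        rows.append(cells)
    per_property = pd.DataFrame(rows, index=pd.Index(props, name="property"), columns=names)
    totals = {name: len(sites) for name, sites in union_per_grouping.items()}
    comparison = GroupComparison(per_property=per_property, totals=totals)
    comparison.check_invariants()
    return comparison
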