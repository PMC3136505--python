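"""Per-site z-score tests, selection calls, and the whole-protein sum.

For each property and magnitude category the observed number of replacement
events is compared with the count expected under the neutral neighborhood
distribution via the normal approximation to the binomial:

    z = (observed - n p) / sqrt(n p (1 - p))

where n is the number of nonsynonymous events in the window around a site
and p the neutral probability of the category.  z > 3.09 (one-tailed
p ~ 0.001) flags positive selection; in radical categories 6-8 this is
positive-destabilizing selection, the signature of molecular adaptation, and
in conservative categories 1-3 positive-stabilizing selection.  The
whole-protein test sums the signed per-site z-scores of one property and
compares the sum with the same threshold.

An exact binomial upper-tail p-value is carried alongside each z for audit;
the decision rule itself is the z threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .ancestral import ReplacementEvent
from .errors import DegenerateExpectationError
from .property_model import (
    DESTABILIZING_CATEGORIES,
    N_CATEGORIES,
    STABILIZING_CATEGORIES,
    NullModel,
)

logger = logging.getLogger(__name__)

#: One-tailed normal cutoff at p ~ 0.001; the conventional threshold for
#: flagging positive selection with this statistic.
DEFAULT_Z_THRESHOLD = 3.09


@dataclass(frozen=True)
class CategoryTest:
    """Observed-vs-expected test for one (site, property, category)."""

    site: int  # 1-based codon site the window is centered on
    property_name: str
    category: int
    observed: int
    n: int
    p: float
    z: float
    p_exact: float  # exact binomial P(X >= observed)


@dataclass(frozen=True)
class SelectionCall:
    """A (site, property, category) whose z exceeded the threshold.

    direction is 'positive' for z above +threshold and 'negative' for z
    below -threshold; regime follows the category band: stabilizing for
    categories 1-3, destabilizing for 6-8, none for the intermediate 4-5.
    """

    site: int
    property_name: str
    category: int
    direction: str
    regime: str
    z: float


@dataclass(frozen=True)
class WholeProteinResult:
    """Sum of signed site z-scores for one property vs the threshold."""

    property_name: str
    total: float
    threshold: float

    @property
    def positive(self) -> bool:
        return self.total > self.threshold


def category_z(observed: int, n: int, p: float) -> float:
    """Normal-approximation z-score for an observed category count.

    Zero events (n = 0) carries no information and scores z = 0.
    """
    if not 0.0 < p < 1.0:
        raise DegenerateExpectationError(f"expected probability {p} outside (0, 1)")
    if n == 0:
        return 0.0
    return (observed - n * p) / np.sqrt(n * p * (1.0 - p))


def _event_category_matrix(
    events: list[ReplacementEvent], null: NullModel, n_sites: int
) -> np.ndarray:
    """counts[site, property, category] over scoreable nonsynonymous events.

    Only replacements inside the null's support enter the statistics: an
    amino-acid pair not reachable by any single nucleotide change (these
    arise when parsimony compresses a multi-hit codon history into one
    branch) has no defined neutral category probability and is excluded.
    """
    props = null.properties
    counts = np.zeros((n_sites, len(props), N_CATEGORIES), dtype=np.int64)
    for event in events:
        if event.synonymous or not null.in_support(event.from_aa, event.to_aa):
            continue
        for j, prop in enumerate(props):
            cat = null.categorize(prop, event.from_aa, event.to_aa)
            counts[event.site - 1, j, cat - 1] += 1
    return counts


def sliding_window_counts(counts: np.ndarray, window: int) -> np.ndarray:
    """Sum counts over a window of codon sites centered on each site.

    The window is clamped at the gene ends; a window wider than the gene is
    clamped to the gene with a warning.
    """
    n_sites = counts.shape[0]
    if window > n_sites:
        logger.warning("window %d wider than gene (%d sites); clamped", window, n_sites)
        window = n_sites
    half_lo = (window - 1) // 2
    half_hi = window - 1 - half_lo
    cum = np.concatenate(
        [np.zeros((1,) + counts.shape[1:], dtype=counts.dtype), np.cumsum(counts, axis=0)]
    )
    lo = np.clip(np.arange(n_sites) - half_lo, 0, n_sites)
    hi = np.clip(np.arange(n_sites) + half_hi + 1, 0, n_sites)
    return cum[hi] - cum[lo]


def site_zscore_arrays(
    events: list[ReplacementEvent],
    null: NullModel,
    n_sites: int,
    window: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized core of :func:`site_profiles`.

    Returns (observed, n, z): observed[site, property, category] windowed
    counts, n[site] the windowed nonsynonymous event totals, and the z-score
    array of the same shape as observed.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    counts = _event_category_matrix(events, null, n_sites)
    windowed = sliding_window_counts(counts, window)
    # every nonsynonymous event is categorized under every property, so the
    # per-property category sums share one n per site
    n = windowed[:, 0, :].sum(axis=1) if null.properties else np.zeros(n_sites)
    p = np.stack([null.expecteds[prop] for prop in null.properties])  # props x 8
    mean = n[:, None, None] * p[None, :, :]
    sd = np.sqrt(n[:, None, None] * p[None, :, :] * (1.0 - p[None, :, :]))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(n[:, None, None] > 0, (windowed - mean) / sd, 0.0)
    # a category with no neutral mass (p = 0: no neighborhood pair falls in
    # its bin) supports no binomial test; it scores z = 0.  Observed counts
    # can still be nonzero there, from multi-nucleotide codon replacements
    # whose amino-acid pair lies outside the single-step neighborhood.
    z = np.where(p[None, :, :] > 0, z, 0.0)
    return windowed, n, z


def site_profiles(
    events: list[ReplacementEvent],
    null: NullModel,
    n_sites: int,
    window: int = 1,
) -> list[CategoryTest]:
    """Per-(site, property, category) tests for one gene/group analysis.

    ``window`` is the number of codon sites pooled around each site
    (default 1: pure per-site).  Sites with no events in their window score
    z = 0 in every category.
    """
    observed, n, z = site_zscore_arrays(events, null, n_sites, window)
    props = null.properties
    p_mat = np.stack([null.expecteds[prop] for prop in props])
    with np.errstate(invalid="ignore", divide="ignore"):
        p_exact = sps.binom.sf(observed - 1, n[:, None, None], p_mat[None, :, :])
    p_exact = np.where(p_mat[None, :, :] > 0, p_exact, 1.0)
    tests: list[CategoryTest] = []
    for s in range(n_sites):
        for j, prop in enumerate(props):
            for k in range(N_CATEGORIES):
                tests.append(
                    CategoryTest(
                        site=s + 1,
                        property_name=prop,
                        category=k + 1,
                        observed=int(observed[s, j, k]),
                        n=int(n[s]),
                        p=float(p_mat[j, k]),
                        z=float(z[s, j, k]),
                        p_exact=float(p_exact[s, j, k]),
                    )
                )
    return tests


def band_zscores(
    events: list[ReplacementEvent],
    null: NullModel,
    n_sites: int,
    window: int = 1,
    categories: tuple[int, ...] = DESTABILIZING_CATEGORIES,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled z-scores for one category band, per (site, property).

    The destabilizing band (categories 6-8) is pooled into a single
    observed-vs-expected test per site and property: observed is the window's
    event count across the band, p the band's summed neutral probability.
    Pooling is the preferred site-level detection statistic because the
    radical signal of a selected site spreads over adjacent categories, and
    single thinly-populated categories make the per-category z
    anticonservative.  Returns (band observed, n, band z), the first and
    last shaped (sites, properties).
    """
    observed, n, _ = site_zscore_arrays(events, null, n_sites, window)
    idx = [c - 1 for c in categories]
    band_obs = observed[:, :, idx].sum(axis=2)
    p_band = np.array([null.expecteds[prop][idx].sum() for prop in null.properties])
    mean = n[:, None] * p_band[None, :]
    sd = np.sqrt(n[:, None] * p_band[None, :] * (1.0 - p_band[None, :]))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where((n[:, None] > 0) & (p_band[None, :] > 0), (band_obs - mean) / sd, 0.0)
    return band_obs, n, z


def classify_band(
    events: list[ReplacementEvent],
    null: NullModel,
    n_sites: int,
    window: int = 1,
    threshold: float = DEFAULT_Z_THRESHOLD,
    categories: tuple[int, ...] = DESTABILIZING_CATEGORIES,
) -> list[SelectionCall]:
    """Site-level selection calls from the pooled band statistic.

    Emits one positive call per (site, property) whose band z exceeds the
    threshold; the recorded category is the most radical band category with
    observed events in the window.
    """
    observed, n, _ = site_zscore_arrays(events, null, n_sites, window)
    band_obs, _, z = band_zscores(events, null, n_sites, window, categories)
    idx = sorted(c - 1 for c in categories)
    calls: list[SelectionCall] = []
    for s, j in zip(*np.where(z > threshold)):
        with_events = [k for k in idx if observed[s, j, k] > 0]
        category = max(with_events) + 1 if with_events else max(idx) + 1
        calls.append(
            SelectionCall(
                site=int(s) + 1,
                property_name=null.properties[j],
                category=category,
                direction="positive",
                regime=_regime(category),
                z=float(z[s, j]),
            )
        )
    return calls


def _regime(category: int) -> str:
    if category in STABILIZING_CATEGORIES:
        return "stabilizing"
    if category in DESTABILIZING_CATEGORIES:
        return "destabilizing"
    return "none"


def bonferroni_threshold(threshold: float, n_tests: int) -> float:
    """Raise a one-tailed z cutoff to control the familywise rate over
    ``n_tests`` tests at the same nominal level."""
    alpha = float(sps.norm.sf(threshold))
    return float(sps.norm.isf(alpha / max(n_tests, 1)))


def classify(
    tests: list[CategoryTest],
    threshold: float = DEFAULT_Z_THRESHOLD,
    bonferroni: bool = False,
) -> list[SelectionCall]:
    """Emit a call for every test whose |z| exceeds the threshold.

    No multiple-testing correction is applied by default, mirroring the
    method's established usage; ``bonferroni=True`` raises the cutoff to
    control the familywise rate over the supplied tests and logs the
    adjusted threshold.
    """
    if bonferroni:
        threshold = bonferroni_threshold(threshold, len(tests))
        logger.info("bonferroni correction on: adjusted z threshold %.3f", threshold)
    calls: list[SelectionCall] = []
    for t in tests:
        if t.z > threshold:
            direction = "positive"
        elif t.z < -threshold:
            direction = "negative"
        else:
            continue
        calls.append(
            SelectionCall(
                site=t.site,
                property_name=t.property_name,
                category=t.category,
                direction=direction,
                regime=_regime(t.category),
                z=t.z,
            )
        )
    return calls


def whole_protein(
    z_by_site: list[float],
    threshold: float = DEFAULT_Z_THRESHOLD,
    property_name: str = "",
) -> WholeProteinResult:
    """Sum signed site z-scores for one property and test the sum.

    Positive and negative site values both enter the sum; an empty list sums
    to 0 and is not positive.
    """
    total = float(np.sum(z_by_site)) if len(z_by_site) else 0.0
    return WholeProteinResult(property_name=property_name, total=total, threshold=threshold)


def whole_protein_from_arrays(
    z: np.ndarray,
    null: NullModel,
    threshold: float = DEFAULT_Z_THRESHOLD,
    categories: tuple[int, ...] = DESTABILIZING_CATEGORIES,
) -> dict[str, WholeProteinResult]:
    """Whole-protein results per property from a site z-score array.

    Each site contributes the sum of its z-scores over ``categories``
    (default: the destabilizing band 6-8; pass ``tuple(range(1, 9))`` to sum
    all categories).  Both modes are signed sums, per the worked definition
    of the statistic.
    """
    idx = [c - 1 for c in categories]
    out: dict[str, WholeProteinResult] = {}
    for j, prop in enumerate(null.properties):
        per_site = z[:, j, idx].sum(axis=1)
        out[prop] = whole_protein(list(per_site), threshold, property_name=prop)
    return out


def write_tests_tsv(tests: list[CategoryTest], path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tproperty\tcategory\tobserved\tn\tp\tz\tp_exact\n")
        for t in tests:
            fh.write(
                f"{t.site}\t{t.property_name}\t{t.category}\t{t.observed}\t{t.n}"
                f"\t{t.p:.6g}\t{t.z:.6g}\t{t.p_exact:.6g}\n"
            )


def write_calls_tsv(calls: list[SelectionCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tproperty\tcategory\tdirection\tregime\tz\n")
        for c in calls:
            fh.write(
                f"{c.site}\t{c.property_name}\t{c.category}\t{c.direction}"
                f"\t{c.regime}\t{c.z:.6g}\n"
            )
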