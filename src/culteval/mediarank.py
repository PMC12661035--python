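"""Media complementarity: coverage sets, greedy ranking, UpSet counts, curves.

Once per-medium recovered-feature sets are known, a media panel can be
ranked by complementarity: starting from a base medium, each step adds the
medium contributing the most not-yet-covered features (greedy set cover,
lexicographic tie-break on the medium label).  UpSet-style exclusive
intersection counts and cumulative coverage curves summarize the panel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .profiles import SampleMeta, TaxonProfile
from .recovery import recovered_fraction


@dataclass
class MediaCoverage:
    """Per-medium recovered feature sets over a shared eligible universe."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for med, s in self.sets.items():
            if not s <= self.universe:
                raise ValueError(f"coverage set for {med!r} exceeds the universe")

    @property
    def media(self) -> list[str]:
        return sorted(self.sets)

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out


def coverage_sets(
    inoculum: TaxonProfile,
    prints: TaxonProfile,
    meta: SampleMeta,
    level: str | None = None,
    inoc_cutoff: float = 0.01,
    print_cutoff: float | None = None,
    eligibility: str = "any",
) -> MediaCoverage:
    """Per-medium recovered sets from a single recovery-scoring pass."""
    report = recovered_fraction(
        inoculum, prints, meta=meta, level=level,
        inoc_cutoff=inoc_cutoff, print_cutoff=print_cutoff,
        eligibility=eligibility,
    )
    return MediaCoverage(sets=dict(report.per_medium), universe=report.eligible)


def greedy_rank(
    cov: MediaCoverage, base: str
) -> list[tuple[str, int, int]]:
    """Greedy complementarity ranking: (medium, incremental gain, cumulative).

    Starts from `base`; each step adds the medium whose set contributes the
    most features not yet covered, breaking ties lexicographically by medium
    label.  Every medium is placed.
    """
    if base not in cov.sets:
        raise KeyError(f"base medium {base!r} not in coverage")
    covered = set(cov.sets[base])
    ranking = [(base, len(covered), len(covered))]
    remaining = sorted(m for m in cov.sets if m != base)
    while remaining:
        best = min(remaining, key=lambda m: (-len(cov.sets[m] - covered), m))
        gain = len(cov.sets[best] - covered)
        covered |= cov.sets[best]
        ranking.append((best, gain, len(covered)))
        remaining.remove(best)
    return ranking


def exhaustive_best_panel(cov: MediaCoverage, size: int) -> tuple[tuple[str, ...], int]:
    """Optimal panel of `size` media by exhaustive search (<= 12 media).

    Quantifies the greedy gap on small instances.
    """
    media = cov.media
    if len(media) > 12:
        raise ValueError("exhaustive search limited to <= 12 media")
    best_combo, best_count = (), -1
    for combo in itertools.combinations(media, size):
        covered: set[str] = set()
        for m in combo:
            covered |= cov.sets[m]
        if len(covered) > best_count:
            best_combo, best_count = combo, len(covered)
    return best_combo, best_count


def upset_counts(cov: MediaCoverage) -> dict[frozenset[str], int]:
    """Exclusive intersection sizes for every non-empty media combination.

    A feature counts toward exactly one combination: the set of media that
    recovered it (UpSet semantics).  Counts sum to the size of the union.
    """
    media = cov.media
    if len(media) > 20:
        raise ValueError("more than 20 media; filter the panel before UpSet counts")
    membership: dict[str, frozenset[str]] = {}
    for med in media:
        for feat in cov.sets[med]:
            membership[feat] = membership.get(feat, frozenset()) | {med}
    counts: dict[frozenset[str], int] = {}
    for pattern in membership.values():
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def cumulative_curve(
    cov: MediaCoverage, order: list[str]
) -> list[float | None]:
    """Cumulative covered fraction of the universe along a media ordering."""
    if sorted(order) != cov.media:
        raise ValueError("order must be a permutation of the media")
    if not cov.universe:
        return [None] * len(order)
    covered: set[str] = set()
    curve = []
    for med in order:
        covered |= cov.sets[med]
        curve.append(len(covered) / len(cov.universe))
    return curve
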