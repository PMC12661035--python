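"""Recovery scoring of cultured prints against inocula.

The central question of a culturomics evaluation: of the taxa present in the
original community at or above an abundance cut-off, which fraction shows up
in the cultured colony arrays?  This module computes that fraction per
taxonomic level / cut-off / medium, detects taxa *enriched* by culture
(below detection in the inoculum, detected in prints), tests per-class
abundance shifts between groups (Mann-Whitney U with Bonferroni correction),
scores how much transcriptional activity an isolate collection covers, and
bounds the carry-over of non-growing input cells by a sphere-volume scaling
argument.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .profiles import SampleMeta, TaxonProfile, aggregate, to_relative

logger = logging.getLogger("culteval")


@dataclass
class RecoveryReport:
    """Per-level, per-cutoff recovered/eligible sets and fractions."""

    level: str
    inoc_cutoff: float
    print_cutoff: float
    eligible: set[str]
    recovered: set[str]
    per_medium: dict[str, set[str]] = field(default_factory=dict)
    enriched: set[str] = field(default_factory=set)

    @property
    def fraction(self) -> float | None:
        if not self.eligible:
            return None
        return len(self.recovered) / len(self.eligible)

    def __post_init__(self) -> None:
        if not self.recovered <= self.eligible:
            raise ValueError("recovered must be a subset of eligible")


def _eligible_features(
    inoculum: TaxonProfile, cutoff: float, mode: str
) -> set[str]:
    """Features reaching `cutoff` in any inoculum sample ('any') or on the
    mean inoculum profile ('mean')."""
    if mode == "any":
        hit = (inoculum.counts >= cutoff).any(axis=1)
    elif mode == "mean":
        hit = inoculum.counts.mean(axis=1) >= cutoff
    else:
        raise ValueError(f"unknown eligibility mode {mode!r}")
    return {f for f, h in zip(inoculum.feature_ids, hit) if h}


def _detected_features(profile: TaxonProfile, cutoff: float) -> set[str]:
    """Features reaching `cutoff` in at least one sample.

    A cutoff of 0 means presence (count/abundance strictly > 0)."""
    if cutoff > 0:
        hit = (profile.counts >= cutoff).any(axis=1)
    else:
        hit = (profile.counts > 0).any(axis=1)
    return {f for f, h in zip(profile.feature_ids, hit) if h}


def _as_relative_at_level(profile: TaxonProfile, level: str | None) -> TaxonProfile:
    prof = aggregate(profile, level) if level else profile
    return to_relative(prof) if prof.units == "reads" else prof


def recovered_fraction(
    inoculum: TaxonProfile,
    prints: TaxonProfile,
    meta: SampleMeta | None = None,
    level: str | None = None,
    inoc_cutoff: float = 0.01,
    print_cutoff: float | None = None,
    eligibility: str = "any",
) -> RecoveryReport:
    """Score recovery of inoculum features by the print group.

    ``eligible`` = inoculum features at >= `inoc_cutoff` relative abundance
    (in any inoculum sample by default); ``recovered`` = eligible features at
    >= `print_cutoff` in at least one print sample.  `print_cutoff` defaults
    to `inoc_cutoff` (symmetric thresholds).  When `meta` is given, the
    report also carries per-medium recovered subsets.
    """
    if print_cutoff is None:
        print_cutoff = inoc_cutoff
    ino = _as_relative_at_level(inoculum, level)
    prt = _as_relative_at_level(prints, level)
    eligible = _eligible_features(ino, inoc_cutoff, eligibility)
    detected = _detected_features(prt, print_cutoff)
    recovered = eligible & detected

    per_medium: dict[str, set[str]] = {}
    if meta is not None:
        media = sorted(
            {
                m
                for s in prt.samples
                if (m := meta.medium_of(s)) is not None
            }
        )
        for med in media:
            samples = [s for s in prt.samples if meta.medium_of(s) == med]
            if not samples:
                logger.warning("medium %s has zero print samples", med)
                per_medium[med] = set()
                continue
            sub = prt.subset_samples(samples)
            per_medium[med] = eligible & _detected_features(sub, print_cutoff)

    enriched = enriched_features(ino, prt, detect_cutoff=print_cutoff)
    return RecoveryReport(
        level=level or "feature",
        inoc_cutoff=inoc_cutoff,
        print_cutoff=print_cutoff,
        eligible=eligible,
        recovered=recovered,
        per_medium=per_medium,
        enriched=enriched,
    )


def enriched_features(
    inoculum: TaxonProfile, prints: TaxonProfile, detect_cutoff: float
) -> set[str]:
    """Features below detection in every inoculum sample but detected in
    at least one print sample — culture-enriched taxa."""
    ino_detected = _detected_features(inoculum, detect_cutoff)
    prt_detected = _detected_features(prints, detect_cutoff)
    shared = set(inoculum.feature_ids) & set(prints.feature_ids)
    return (prt_detected - ino_detected) & shared | (prt_detected - set(inoculum.feature_ids))


# -- class-shift tests ---------------------------------------------------------


def _exact_mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating group assignments.

    Returns (U of group x, two-sided p).  Two-sided p is the probability,
    under random assignment of the pooled values, of a U at least as far
    from its mean n1*n2/2 as the observed one.  Handles ties (U uses the
    midrank convention, i.e. 0.5 credit for equal pairs).
    """
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)

    def u_stat(ix: tuple[int, ...]) -> float:
        a = pooled[list(ix)]
        b = np.delete(pooled, list(ix))
        gt = (a[:, None] > b[None, :]).sum()
        eq = (a[:, None] == b[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_stat(tuple(range(n1)))
    mean = n1 * n2 / 2
    dev = abs(u_obs - mean)
    count = 0
    total = 0
    for ix in itertools.combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_stat(ix) - mean) >= dev - 1e-12:
            count += 1
    return float(u_obs), count / total


def class_shift_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    classes: list[str] | None = None,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Per-class Mann-Whitney U between two sample groups with Bonferroni.

    `group_a`/`group_b` are class x sample relative-abundance tables.  The
    exact enumeration path is used when both groups have <= `exact_max_n`
    samples; otherwise the tie-corrected, continuity-corrected normal
    approximation.  Adjusted p = min(1, n_classes * p).
    """
    if classes is None:
        classes = [c for c in group_a.index if c in set(group_b.index)]
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    k = len(classes)
    rows = []
    for cls in classes:
        x = group_a.loc[cls].to_numpy(dtype=float)
        y = group_b.loc[cls].to_numpy(dtype=float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            u, p = len(x) * len(y) / 2, 1.0
        elif len(x) <= exact_max_n and len(y) <= exact_max_n:
            u, p = _exact_mannwhitney(x, y)
        else:
            res = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            )
            u, p = float(res.statistic), float(res.pvalue)
        rows.append((cls, u, p, min(1.0, k * p)))
    return pd.DataFrame(
        rows, columns=["class", "U", "p", "p_bonferroni"]
    ).set_index("class")


# -- activity coverage ---------------------------------------------------------


def activity_coverage(
    isolate_genera: set[str],
    activity: pd.DataFrame,
    mode: str = "per_sample_mean",
) -> tuple[pd.Series, float]:
    """Fraction of relative transcriptional activity covered by isolates.

    `activity` is a genus x sample table whose columns sum to 1.  Default
    mode sums per-sample activity over isolate genera and averages across
    samples; ``mode='mean_profile'`` instead covers the mean activity
    profile.  Isolate genera absent from the table are logged and count 0.
    """
    sums = activity.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("activity columns must sum to 1")
    missing = set(isolate_genera) - set(activity.index)
    if missing:
        logger.warning(
            "%d isolate genera absent from the activity table: %s",
            len(missing), sorted(missing)[:5],
        )
    present = [g for g in activity.index if g in isolate_genera]
    per_sample = activity.loc[present].sum(axis=0) if present else pd.Series(
        0.0, index=activity.columns
    )
    if mode == "per_sample_mean":
        return per_sample, float(per_sample.mean())
    if mode == "mean_profile":
        mean_prof = activity.mean(axis=1)
        covered = float(mean_prof.loc[present].sum()) if present else 0.0
        return per_sample, covered / float(mean_prof.sum())
    raise ValueError(f"unknown mode {mode!r}")


# -- input/output cell-ratio bound --------------------------------------------


def estimate_io_ratio(
    input_cells_min: float,
    input_cells_max: float,
    reference_output: float,
    r_print: float,
    r_ref: float,
) -> dict[str, float]:
    """Upper bound on the carried-over input / grown output cell ratio.

    The reference colony output is scaled by the cube of the radius ratio
    (sphere-volume scaling) to match the miniature printed colony, and the
    maximal input count is divided by that scaled output.  Example: inputs
    of at most 2e2 cells/droplet, a 2e9-cell reference colony, radii
    0.5 vs 5 mm -> volume factor 1e3, scaled output 2e6, ratio 1e-4.
    """
    if min(input_cells_min, input_cells_max, reference_output, r_print) <= 0:
        raise ValueError("all inputs must be positive")
    if r_ref <= 0:
        raise ValueError("reference radius must be positive")
    volume_factor = (r_ref / r_print) ** 3
    scaled_output = reference_output * (r_print / r_ref) ** 3
    return {
        "volume_factor": volume_factor,
        "scaled_output": scaled_output,
        "ratio_min": input_cells_min / scaled_output,
        "ratio_max": input_cells_max / scaled_output,
    }
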