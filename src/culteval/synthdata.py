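"""Synthetic communities, culture prints, activity tables and IR spectra.

Every downstream stage of the package (recovery scoring, diversity, media
ranking, spectral classification) is testable against known ground truth
produced here.  The generator emulates the structure of a culturomics
experiment on a host-associated biofilm:

* an inoculum community with log-normal ranked abundances under a
  hierarchical taxonomy,
* per-medium culture "prints" whose composition is the inoculum filtered by
  a hard survival indicator (culturability on that medium) and a soft
  growth-bias multiplier, observed through multinomial read sampling at
  realistic depths (6,640-26,728 reads per sample by default),
* genus-level relative-activity tables (Dirichlet draws), and
* class-structured FT-IR spectra: Gaussian peak mixtures inside the
  fingerprint (900-1800 cm^-1) and CH-stretching (2800-3000 cm^-1) regions,
  with a random linear baseline, a random positive intensity scale and
  additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import RANKS, LINEAGE_SEP, TaxonLineage, TaxonProfile
from .ftir import FINGERPRINT, CH_STRETCH, Spectrum, SpectrumSet

#: Read-depth range observed per sample in the motivating experiment.
DEPTH_RANGE: tuple[int, int] = (6640, 26728)

#: Default community size and media-panel width.
DEFAULT_N_FEATURES = 200
DEFAULT_N_MEDIA = 16


# -- communities -------------------------------------------------------------


@dataclass
class CommunityTruth:
    """Ground truth for a synthetic inoculum and its per-medium filters."""

    feature_ids: list[str]
    lineages: dict[str, TaxonLineage]
    abundances: np.ndarray  # true relative abundances, sum to 1
    survival: dict[str, np.ndarray] = field(default_factory=dict)  # medium -> 0/1
    bias: dict[str, np.ndarray] = field(default_factory=dict)  # medium -> >0

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if not np.isclose(self.abundances.sum(), 1.0):
            raise ValueError("true abundances must sum to 1")
        for med, s in self.survival.items():
            if not np.isin(s, (0, 1)).all():
                raise ValueError(f"survival for {med} must be 0/1")
        for med, b in self.bias.items():
            if (np.asarray(b) <= 0).any():
                raise ValueError(f"bias for {med} must be positive")

    @property
    def media(self) -> list[str]:
        return sorted(self.survival)

    def culturable_fraction(self, medium: str, cutoff: float) -> float | None:
        """True fraction of features >= cutoff that survive on `medium`."""
        eligible = self.abundances >= cutoff
        if not eligible.any():
            return None
        return float(self.survival[medium][eligible].mean())

    def culturable_union_fraction(self, cutoff: float) -> float | None:
        """True fraction of eligible features culturable on >= 1 medium."""
        eligible = self.abundances >= cutoff
        if not eligible.any():
            return None
        any_survive = np.zeros(len(self.abundances), dtype=bool)
        for s in self.survival.values():
            any_survive |= s.astype(bool)
        return float(any_survive[eligible].mean())


def _random_lineages(
    n_features: int, branching: tuple[int, ...], rng: np.random.Generator
) -> dict[str, TaxonLineage]:
    """Assign hierarchical lineages by recursive random branching.

    `branching` gives the number of distinct taxa available at each rank
    above the terminal one; a child taxon is drawn uniformly within its
    parent so the tree is properly nested.
    """
    n_ranks = len(RANKS)
    branching = tuple(branching) + (1,) * (n_ranks - 1 - len(branching))
    lineages: dict[str, TaxonLineage] = {}
    for i in range(n_features):
        names = ["Bacteria"]
        parent_code = 0
        for depth, width in enumerate(branching[: n_ranks - 2], start=1):
            child = parent_code * width + int(rng.integers(width))
            names.append(f"{RANKS[depth]}_{child}")
            parent_code = child
        names.append(f"sp_{i:04d}")
        fid = f"F{i:04d}"
        lineages[fid] = TaxonLineage.from_string(LINEAGE_SEP.join(names))
    return lineages


def simulate_inoculum(
    n_features: int = DEFAULT_N_FEATURES,
    taxonomy_shape: tuple[int, ...] = (4, 3, 3, 3, 3),
    lognormal_sigma: float = 1.5,
    seed: int = 0,
) -> tuple[TaxonProfile, CommunityTruth]:
    """Simulate a ranked log-normal inoculum with a hierarchical taxonomy.

    Returns the truth as a single-sample relative-abundance profile plus the
    :class:`CommunityTruth` carrying the same abundances (media filters are
    attached separately by :func:`assign_media_effects`).
    """
    if n_features < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, lognormal_sigma, size=n_features))
    raw = np.sort(raw)[::-1]
    abund = raw / raw.sum()
    lineages = _random_lineages(n_features, taxonomy_shape, rng)
    feature_ids = list(lineages)
    profile = TaxonProfile(
        feature_ids=feature_ids,
        lineages=lineages,
        samples=["inoculum_truth"],
        counts=abund[:, None],
        units="relative",
    )
    truth = CommunityTruth(
        feature_ids=feature_ids, lineages=lineages, abundances=abund
    )
    return profile, truth


def assign_media_effects(
    truth: CommunityTruth,
    media: list[str],
    survival_prob: float = 0.5,
    bias_sigma: float = 0.75,
    seed: int = 0,
) -> CommunityTruth:
    """Attach per-medium survival indicators and log-normal growth biases."""
    rng = np.random.default_rng(seed)
    n = len(truth.feature_ids)
    for med in media:
        truth.survival[med] = (rng.random(n) < survival_prob).astype(np.int64)
        truth.bias[med] = np.exp(rng.normal(0.0, bias_sigma, size=n))
    return truth


def simulate_print(
    truth: CommunityTruth, medium: str, depth: int, seed: int,
    sample_id: str | None = None,
) -> TaxonProfile:
    """Multinomial read sample of the medium-filtered community.

    Post-culture composition is proportional to
    ``abundance x survival x bias`` renormalized; reads are drawn
    multinomially at `depth`, so the output column total equals `depth`.
    """
    if medium not in truth.survival:
        raise KeyError(f"medium {medium!r} not defined in truth")
    rng = np.random.default_rng(seed)
    weights = truth.abundances * truth.survival[medium] * truth.bias[medium]
    total = weights.sum()
    if total == 0:
        raise ValueError(f"medium {medium!r} kills every feature")
    p = weights / total
    counts = rng.multinomial(depth, p)
    return TaxonProfile(
        feature_ids=list(truth.feature_ids),
        lineages=dict(truth.lineages),
        samples=[sample_id or f"print_{medium}"],
        counts=counts[:, None],
        units="reads",
    )


def simulate_inoculum_reads(
    truth: CommunityTruth, depth: int, seed: int, sample_id: str = "inoculum"
) -> TaxonProfile:
    """Multinomial read sample of the unfiltered inoculum itself."""
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, truth.abundances)
    return TaxonProfile(
        feature_ids=list(truth.feature_ids),
        lineages=dict(truth.lineages),
        samples=[sample_id],
        counts=counts[:, None],
        units="reads",
    )


def simulate_activity(
    genera: list[str],
    concentration: float | np.ndarray = 1.0,
    n_samples: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet relative-activity table (genus x sample, columns sum to 1)."""
    if not genera:
        raise ValueError("need at least one genus")
    alpha = np.broadcast_to(
        np.asarray(concentration, dtype=float), (len(genera),)
    )
    if (alpha <= 0).any():
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples).T  # genera x samples
    return pd.DataFrame(
        draws, index=list(genera),
        columns=[f"biofilm_{i:02d}" for i in range(n_samples)],
    )


# -- FT-IR spectra -----------------------------------------------------------


@dataclass
class SpectrumTruth:
    """Per-class Gaussian peak templates plus baseline/noise parameters."""

    peaks: dict[str, list[tuple[float, float, float]]]  # class -> (center, width, height)
    baseline_slope_range: tuple[float, float] = (-5e-5, 5e-5)
    baseline_offset_range: tuple[float, float] = (-0.05, 0.05)
    noise_sd: float = 0.005
    scale_range: tuple[float, float] = (0.7, 1.3)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        regions = (FINGERPRINT, CH_STRETCH)
        for cls, pk in self.peaks.items():
            for center, width, height in pk:
                if not any(lo <= center <= hi for lo, hi in regions):
                    raise ValueError(
                        f"peak at {center} cm^-1 for class {cls!r} lies outside "
                        f"the analysis regions {regions}"
                    )
                if width <= 0 or height <= 0:
                    raise ValueError("peak width and height must be positive")

    @property
    def classes(self) -> list[str]:
        return list(self.peaks)

    def template(self, cls: str, grid: np.ndarray) -> np.ndarray:
        out = np.zeros_like(grid, dtype=float)
        for center, width, height in self.peaks[cls]:
            out += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
        return out


def default_spectrum_truth(
    n_classes: int = 5, seed: int = 0, noise_sd: float = 0.005
) -> SpectrumTruth:
    """Random truth with class-specific (disjointly centred) peak sets.

    Each class gets 4 fingerprint peaks and 1 CH-stretch peak; centres are
    jittered inside class-private slots so class templates never coincide.
    """
    rng = np.random.default_rng(seed)
    classes = [f"species_{chr(ord('A') + i)}" for i in range(n_classes)]
    peaks: dict[str, list[tuple[float, float, float]]] = {}
    fp_lo, fp_hi = FINGERPRINT
    slot = (fp_hi - fp_lo - 80) / (n_classes * 4)
    k = 0
    for cls in classes:
        pk = []
        for _ in range(4):
            center = fp_lo + 40 + slot * (k + 0.5) + rng.uniform(-slot / 6, slot / 6)
            pk.append((float(center), float(rng.uniform(8, 18)), float(rng.uniform(0.3, 1.0))))
            k += 1
        ch_lo, ch_hi = CH_STRETCH
        ch_slot = (ch_hi - ch_lo - 40) / n_classes
        center = ch_lo + 20 + ch_slot * (classes.index(cls) + 0.5)
        pk.append((float(center), float(rng.uniform(6, 12)), float(rng.uniform(0.2, 0.6))))
        peaks[cls] = pk
    return SpectrumTruth(peaks=peaks, noise_sd=noise_sd)


def simulate_spectra(
    truth: SpectrumTruth,
    classes: list[str] | None = None,
    n_per_class: int = 8,
    wavenumber_grid: tuple[float, float, float] = (525.0, 4000.0, 2.0),
    seed: int = 0,
) -> SpectrumSet:
    """Class-structured spectra: template x scale + linear baseline + noise."""
    lo, hi, step = wavenumber_grid
    grid = np.arange(lo, hi + step / 2, step)
    for rlo, rhi in (FINGERPRINT, CH_STRETCH):
        if grid[0] > rlo or grid[-1] < rhi:
            raise ValueError(
                f"grid [{grid[0]}, {grid[-1]}] does not cover the analysis "
                f"region [{rlo}, {rhi}]"
            )
    classes = list(classes) if classes is not None else truth.classes
    rng = np.random.default_rng(seed)
    spectra = []
    for cls in classes:
        template = truth.template(cls, grid)
        for i in range(n_per_class):
            scale = rng.uniform(*truth.scale_range)
            slope = rng.uniform(*truth.baseline_slope_range)
            offset = rng.uniform(*truth.baseline_offset_range)
            noise = rng.normal(0.0, truth.noise_sd, size=grid.size) if truth.noise_sd else 0.0
            a = template * scale + slope * grid + offset + noise
            spectra.append(
                Spectrum(w=grid.copy(), a=a, label=cls, name=f"{cls}_{i:02d}")
            )
    return SpectrumSet(spectra=spectra)


def simulate_study(
    n_features: int = DEFAULT_N_FEATURES,
    n_media: int = DEFAULT_N_MEDIA,
    n_inoculum_samples: int = 3,
    prints_per_medium: int = 1,
    depth_range: tuple[int, int] = DEPTH_RANGE,
    survival_prob: float = 0.5,
    bias_sigma: float = 0.75,
    lognormal_sigma: float = 1.5,
    seed: int = 0,
):
    """One full synthetic study: inocula + per-medium prints + metadata.

    Returns ``(profile, meta, truth)`` where `profile` pools every sample
    (read units) and `meta` annotates roles/media.
    """
    from .profiles import SampleMeta  # local to avoid cycle at import time

    rng = np.random.default_rng(seed)
    _, truth = simulate_inoculum(
        n_features=n_features, lognormal_sigma=lognormal_sigma,
        seed=int(rng.integers(2**31)),
    )
    media = [f"MSPS_{i:03d}" for i in range(1, n_media + 1)]
    assign_media_effects(
        truth, media, survival_prob=survival_prob, bias_sigma=bias_sigma,
        seed=int(rng.integers(2**31)),
    )
    columns, samples, rows = [], [], []
    for i in range(n_inoculum_samples):
        depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        sid = f"ino_{i:02d}"
        prof = simulate_inoculum_reads(
            truth, depth, seed=int(rng.integers(2**31)), sample_id=sid
        )
        columns.append(prof.counts[:, 0])
        samples.append(sid)
        rows.append((sid, "inoculum", "donor_1", "", "na"))
    for med in media:
        for r in range(prints_per_medium):
            depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
            sid = f"print_{med}_{r}"
            prof = simulate_print(
                truth, med, depth, seed=int(rng.integers(2**31)), sample_id=sid
            )
            columns.append(prof.counts[:, 0])
            samples.append(sid)
            rows.append((sid, "print", "donor_1", med, "anaerobic"))
    profile = TaxonProfile(
        feature_ids=list(truth.feature_ids),
        lineages=dict(truth.lineages),
        samples=samples,
        counts=np.column_stack(columns),
        units="reads",
    )
    meta = SampleMeta(
        table=pd.DataFrame(
            rows, columns=["sample_id", "role", "donor", "medium", "atmosphere"]
        )
    )
    return profile, meta, truth
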