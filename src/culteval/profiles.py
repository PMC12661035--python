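"""Taxon profiles: the sample x feature count table with taxonomy.

A :class:`TaxonProfile` is the universal community object of the package:
a non-negative features x samples matrix, a taxonomy lineage per feature,
and a ``units`` flag (``"reads"`` for integer counts, ``"relative"`` for
column-normalized abundances).  Profiles are read from and written to a
plain tab-separated wide format::

    #feature_id<TAB>lineage<TAB>sampleA<TAB>sampleB ...
    ASV_1<TAB>Bacteria;Firmicutes;Bacilli;...;Streptococcus;S. oralis<TAB>12<TAB>0

Lineages are semicolon-delimited, ordered domain -> terminal level.  Ranks
missing from an input lineage are filled with an explicit
``unclassified-at-<rank>`` sentinel so that aggregation at any rank is total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("culteval")

#: Canonical rank order, domain to terminal feature level.
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Sentinel prefix for ranks absent from an input lineage.
UNCLASSIFIED = "unclassified-at-{rank}"

COMMENT_CHAR = "#"
LINEAGE_SEP = ";"


def _sentinel(rank: str) -> str:
    return UNCLASSIFIED.format(rank=rank)


@dataclass(frozen=True)
class TaxonLineage:
    """Ordered (rank, name) pairs from domain down to the terminal level."""

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [r for r, _ in self.ranks]
        if tuple(names) != RANKS[: len(names)]:
            raise ValueError(f"rank order must follow {RANKS}, got {names}")

    @classmethod
    def from_string(cls, lineage: str) -> "TaxonLineage":
        """Parse a semicolon-delimited lineage, filling missing ranks."""
        parts = [p.strip() for p in lineage.split(LINEAGE_SEP)]
        parts = [p for p in parts if p]
        if len(parts) > len(RANKS):
            parts = parts[: len(RANKS)]
        full = []
        for i, rank in enumerate(RANKS):
            name = parts[i] if i < len(parts) and parts[i] else _sentinel(rank)
            full.append((rank, name))
        return cls(ranks=tuple(full))

    @property
    def terminal_level(self) -> str:
        return self.ranks[-1][0]

    def name_at(self, rank: str) -> str:
        for r, name in self.ranks:
            if r == rank:
                return name
        raise KeyError(f"unknown rank {rank!r}")

    def prefix(self, rank: str) -> str:
        """Lineage-prefix string down to `rank` (aggregation feature id)."""
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        idx = RANKS.index(rank)
        return LINEAGE_SEP.join(name for _, name in self.ranks[: idx + 1])

    def __str__(self) -> str:
        return LINEAGE_SEP.join(name for _, name in self.ranks)


@dataclass
class TaxonProfile:
    """Features x samples count/abundance table with per-feature lineages."""

    feature_ids: list[str]
    lineages: dict[str, TaxonLineage]
    samples: list[str]
    counts: np.ndarray  # features x samples
    units: str = "reads"  # "reads" | "relative"

    def __post_init__(self) -> None:
        self.counts = np.asarray(
            self.counts, dtype=np.int64 if self.units == "reads" else float
        )
        if self.counts.shape != (len(self.feature_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.samples)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.units == "relative":
            sums = self.counts.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative profile columns must sum to 1")

    # -- convenience ------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def column(self, sample: str) -> np.ndarray:
        return self.counts[:, self.samples.index(sample)]

    def subset_samples(self, keep: list[str]) -> "TaxonProfile":
        idx = [self.samples.index(s) for s in keep]
        return TaxonProfile(
            feature_ids=list(self.feature_ids),
            lineages=dict(self.lineages),
            samples=list(keep),
            counts=self.counts[:, idx].copy(),
            units=self.units,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.samples
        )


@dataclass
class SampleMeta:
    """Role/donor/medium/atmosphere annotations, one row per sample."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("sample_id", "role", "donor", "medium", "atmosphere")
    ROLES = ("inoculum", "print", "isolate_set")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        bad = set(self.table["role"]) - set(self.ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        self.table = self.table.set_index("sample_id", drop=False)

    def samples_with(self, **criteria: str) -> list[str]:
        """Sample ids matching all the given column == value criteria."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in criteria.items():
            mask &= self.table[col] == val
        return list(self.table.loc[mask, "sample_id"])

    def medium_of(self, sample: str) -> str | None:
        med = self.table.loc[sample, "medium"]
        return None if pd.isna(med) or med == "" else str(med)


# -- I/O -------------------------------------------------------------------


def read_profile(path, format: str = "tsv-wide") -> TaxonProfile:
    """Read a wide TSV feature table (feature id, lineage, one column/sample)."""
    if format != "tsv-wide":
        raise ValueError(f"unsupported format {format!r}")
    df = pd.read_csv(path, sep="\t", comment=COMMENT_CHAR, dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError("profile needs feature id, lineage and >=1 sample column")
    fid_col, lin_col = df.columns[0], df.columns[1]
    feature_ids = df[fid_col].astype(str).tolist()
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError(f"duplicate feature id in {path}")
    if df[fid_col].isna().any() or df.iloc[:, 2:].isna().any().any():
        raise ValueError(f"ragged or missing values in {path}")
    counts = df.iloc[:, 2:].to_numpy()
    if (counts < 0).any():
        raise ValueError(f"negative count in {path}")
    lineages = {
        fid: TaxonLineage.from_string(lin)
        for fid, lin in zip(feature_ids, df[lin_col].fillna("").astype(str))
    }
    return TaxonProfile(
        feature_ids=feature_ids,
        lineages=lineages,
        samples=[str(c) for c in df.columns[2:]],
        counts=counts,
        units="reads",
    )


def write_profile(profile: TaxonProfile, path) -> None:
    """Write a profile in the wide TSV dialect read by :func:`read_profile`."""
    df = pd.DataFrame(
        {
            "feature_id": profile.feature_ids,
            "lineage": [str(profile.lineages[f]) for f in profile.feature_ids],
        }
    )
    body = profile.to_frame().reset_index(drop=True)
    out = pd.concat([df, body], axis=1)
    if profile.units == "relative":
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")
    else:
        out.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> SampleMeta:
    df = pd.read_csv(path, sep="\t", comment=COMMENT_CHAR, dtype=str)
    return SampleMeta(table=df)


def write_metadata(meta: SampleMeta, path) -> None:
    meta.table.reset_index(drop=True).to_csv(path, sep="\t", index=False)


# -- transformations -------------------------------------------------------


def aggregate(profile: TaxonProfile, level: str) -> TaxonProfile:
    """Sum features sharing a lineage prefix down to `level`.

    Output feature ids are the lineage-prefix strings; per-sample totals are
    conserved exactly (integer arithmetic for read units).
    """
    if level not in RANKS:
        raise KeyError(f"unknown rank {level!r}; valid: {RANKS}")
    prefixes = [profile.lineages[f].prefix(level) for f in profile.feature_ids]
    order: list[str] = []
    seen: dict[str, int] = {}
    for p in prefixes:
        if p not in seen:
            seen[p] = len(order)
            order.append(p)
    dtype = np.int64 if profile.units == "reads" else float
    out = np.zeros((len(order), profile.n_samples), dtype=dtype)
    for row, p in enumerate(prefixes):
        out[seen[p]] += profile.counts[row]
    lineages = {}
    for p in order:
        # prefix string parses back into a lineage (sentinels fill the tail)
        lineages[p] = TaxonLineage.from_string(p)
    return TaxonProfile(
        feature_ids=order,
        lineages=lineages,
        samples=list(profile.samples),
        counts=out,
        units=profile.units,
    )


def to_relative(profile: TaxonProfile) -> TaxonProfile:
    """Convert read counts to per-sample relative abundances."""
    if profile.units == "relative":
        return profile
    sums = profile.counts.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        bad = [profile.samples[i] for i in zero]
        raise ValueError(f"zero-total sample column(s): {bad}")
    return TaxonProfile(
        feature_ids=list(profile.feature_ids),
        lineages=dict(profile.lineages),
        samples=list(profile.samples),
        counts=profile.counts / sums,
        units="relative",
    )


def rarefy(profile: TaxonProfile, depth: int, seed: int) -> TaxonProfile:
    """Subsample each sample to exactly `depth` reads without replacement.

    Samples with fewer than `depth` total reads are dropped with a logged
    warning.  Columns are drawn with the multivariate hypergeometric
    distribution, so output column totals equal `depth` exactly.
    """
    if profile.units != "reads":
        raise ValueError("rarefy requires read counts")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    keep, cols = [], []
    for j, sample in enumerate(profile.samples):
        col = profile.counts[:, j]
        total = int(col.sum())
        if total < depth:
            logger.warning(
                "dropping sample %s: %d reads < rarefaction depth %d",
                sample, total, depth,
            )
            continue
        keep.append(sample)
        if total == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    if not keep:
        raise ValueError("no sample reaches the rarefaction depth")
    return TaxonProfile(
        feature_ids=list(profile.feature_ids),
        lineages=dict(profile.lineages),
        samples=keep,
        counts=np.column_stack(cols),
        units="reads",
    )
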