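"""Genomic interval data model and interval arithmetic.

Coordinates follow two dialects:

* printed locus strings (``chr16:22684122-22685282``) are 1-based inclusive,
  the convention of genome-browser position strings;
* internal and BED coordinates are 0-based half-open.

All interval arithmetic (merge, overlap, feature coverage, base coverage)
operates on the internal convention. Strand is ignored throughout; genome
builds are treated as opaque labels on a declared :class:`GenomeAssembly`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomeAssembly",
    "Interval",
    "FeatureSet",
    "FeatureCoverage",
    "BaseCoverage",
    "LocusParseError",
    "parse_locus",
    "read_chrom_sizes",
    "read_feature_table",
    "read_bed",
    "write_bed",
    "merge",
    "overlaps",
    "feature_coverage",
    "base_coverage",
]


class LocusParseError(ValueError):
    """Raised when a locus string or feature record cannot be interpreted."""


@dataclass(frozen=True)
class GenomeAssembly:
    """A named genome build: an ordered list of chromosomes with lengths."""

    name: str
    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names in assembly")
        for chrom, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_size(self) -> int:
        """Total genome size in bp — the denominator of genome coverage fractions."""
        return sum(length for _, length in self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return any(c == chrom for c, _ in self.chromosomes)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path, name: str | None = None) -> "GenomeAssembly":
        return read_chrom_sizes(path, name=name)


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, with optional id and attributes."""

    chrom: str
    start: int
    end: int
    id: str | None = None
    attrs: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_locus_string(self) -> str:
        """Serialize as a 1-based inclusive position string (browser dialect)."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def overlaps(self, other: "Interval") -> bool:
        return overlaps(self, other)

    def contains(self, other: "Interval") -> bool:
        """True iff ``other`` lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


# locus strings tolerate unicode ratio/dash separators and thousands commas
_LOCUS_RE = re.compile(
    r"^\s*(?P<chrom>[A-Za-z0-9_.]+)\s*[:∶﹕]\s*"
    r"(?P<start>[0-9][0-9,]*)\s*[-–−—]\s*(?P<end>[0-9][0-9,]*)\s*$"
)


def parse_locus(
    text: str,
    assembly: GenomeAssembly | None = None,
    id: str | None = None,
    attrs: Mapping[str, str] | None = None,
) -> Interval:
    """Parse a 1-based inclusive position string into an internal Interval.

    Accepts ``:`` or the unicode ratio character as chromosome separator, any
    of the ASCII/en/em/minus dashes between coordinates, and thousands commas
    within numbers. ``chr16:22684122-22685282`` maps to the half-open interval
    ``(22684121, 22685282)`` of length 1161.
    """
    m = _LOCUS_RE.match(text)
    if m is None:
        raise LocusParseError(f"malformed locus string: {text!r}")
    chrom = m.group("chrom")
    start1 = int(m.group("start").replace(",", ""))
    end1 = int(m.group("end").replace(",", ""))
    if start1 > end1:
        raise LocusParseError(f"start > end in locus string {text!r} ({start1} > {end1})")
    if start1 < 1:
        raise LocusParseError(f"1-based coordinate must be >= 1 in {text!r}")
    if assembly is not None:
        if chrom not in assembly:
            raise LocusParseError(f"unknown chromosome {chrom!r} in locus string {text!r}")
        if end1 > assembly.sizes[chrom]:
            raise LocusParseError(
                f"locus {text!r} extends beyond {chrom} length {assembly.sizes[chrom]}"
            )
    return Interval(chrom, start1 - 1, end1, id=id, attrs=dict(attrs or {}))


class FeatureSet:
    """A collection of intervals (enhancers, CNVs, Indels, ...) on an assembly.

    Feature kinds mirror the analysis inputs: ``enhancer``, ``cnv``, ``indel``,
    ``syndrome_region`` or ``generic``.
    """

    KINDS = ("enhancer", "cnv", "indel", "syndrome_region", "generic")

    def __init__(
        self,
        features: Iterable[Interval],
        assembly: GenomeAssembly | None = None,
        kind: str = "generic",
        label: str | None = None,
    ) -> None:
        if kind not in self.KINDS:
            raise ValueError(f"unknown feature kind {kind!r}")
        self.features: list[Interval] = list(features)
        self.assembly = assembly
        self.kind = kind
        self.label = label or kind
        # ids may repeat when a table lists one feature per overlapping
        # variant; deduplication is the caller's decision (see datasets)
        if assembly is not None:
            sizes = assembly.sizes
            for f in self.features:
                if f.chrom not in sizes:
                    raise ValueError(f"feature {f.id or f} on unknown chromosome {f.chrom!r}")
                if f.end > sizes[f.chrom]:
                    raise ValueError(
                        f"feature {f.id or f} extends beyond {f.chrom} length {sizes[f.chrom]}"
                    )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.features)

    def __getitem__(self, i: int) -> Interval:
        return self.features[i]

    @property
    def total_bases(self) -> int:
        """Sum of feature lengths (not deduplicated; merge first if needed)."""
        return sum(f.length for f in self.features)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, original indices), sorted by start."""
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        chroms: dict[str, list[int]] = {}
        for i, f in enumerate(self.features):
            chroms.setdefault(f.chrom, []).append(i)
        for chrom, idx in chroms.items():
            idx_a = np.asarray(idx, dtype=np.int64)
            starts = np.asarray([self.features[i].start for i in idx], dtype=np.int64)
            ends = np.asarray([self.features[i].end for i in idx], dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            out[chrom] = (starts[order], ends[order], idx_a[order])
        return out

    def merged_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome disjoint union as sorted (starts, ends) arrays."""
        out = {}
        for chrom, (starts, ends, _) in self.by_chrom().items():
            out[chrom] = merge_arrays(starts, ends)
        return out

    def merged_bases(self) -> int:
        """Number of distinct bases covered by the set (union size)."""
        return int(
            sum((e - s).sum() for s, e in self.merged_arrays().values())
        )

    def genome_fraction(self) -> float:
        """Fraction of the bound assembly covered by the merged set."""
        if self.assembly is None:
            raise ValueError("FeatureSet is not bound to an assembly")
        return self.merged_bases() / self.assembly.total_size

    def subset(self, ids: Iterable[str]) -> "FeatureSet":
        wanted = set(ids)
        return FeatureSet(
            [f for f in self.features if f.id in wanted],
            assembly=self.assembly,
            kind=self.kind,
            label=self.label,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": f.chrom, "start": f.start, "end": f.end, "id": f.id, **f.attrs}
            for f in self.features
        ]
        return pd.DataFrame(rows)


def merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping intervals into a minimal disjoint set.

    Input arrays need not be sorted. Book-ended intervals ([0,5),[5,9)) are
    joined: the result is the minimal interval list with the same base union.
    """
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    cummax = np.maximum.accumulate(e)
    is_new = np.empty(len(s), dtype=bool)
    is_new[0] = True
    is_new[1:] = s[1:] > cummax[:-1]
    first = np.flatnonzero(is_new)
    last = np.append(first[1:], len(s)) - 1
    return s[first], cummax[last]


def merge(feature_set: FeatureSet) -> FeatureSet:
    """Return the minimal disjoint FeatureSet with the same base union.

    Idempotent and order-invariant; ids and attrs are dropped because merged
    intervals no longer correspond to single input features.
    """
    out: list[Interval] = []
    chrom_order = (
        [c for c, _ in feature_set.assembly.chromosomes]
        if feature_set.assembly is not None
        else sorted({f.chrom for f in feature_set})
    )
    merged = feature_set.merged_arrays()
    for chrom in chrom_order:
        if chrom not in merged:
            continue
        s, e = merged[chrom]
        out.extend(Interval(chrom, int(a), int(b)) for a, b in zip(s, e))
    return FeatureSet(out, assembly=feature_set.assembly, kind=feature_set.kind,
                      label=feature_set.label)


def overlaps(a: Interval, b: Interval) -> bool:
    """True iff the intervals share at least one base (half-open convention)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass
class FeatureCoverage:
    """Result of a feature-coverage computation: targets hit by a cover set."""

    n_targets: int
    count: int
    fraction: float
    hits: list[tuple[Interval, Interval]]  # (target, cover) overlapping pairs

    @property
    def hit_ids(self) -> list[str]:
        seen: list[str] = []
        for target, _ in self.hits:
            if target.id is not None and target.id not in seen:
                seen.append(target.id)
        return seen


@dataclass
class BaseCoverage:
    """Result of a base-coverage computation: target bases covered."""

    covered_bases: int
    total_bases: int

    @property
    def fraction(self) -> float:
        return self.covered_bases / self.total_bases if self.total_bases else 0.0


def _check_same_assembly(a: FeatureSet, b: FeatureSet) -> None:
    if a.assembly is not None and b.assembly is not None and a.assembly != b.assembly:
        raise ValueError(
            f"assembly mismatch: {a.assembly.name!r} vs {b.assembly.name!r}"
        )


def covered_mask(
    t_starts: np.ndarray, t_ends: np.ndarray, m_starts: np.ndarray, m_ends: np.ndarray
) -> np.ndarray:
    """Boolean mask of targets overlapping a merged (disjoint, sorted) cover."""
    if len(m_starts) == 0 or len(t_starts) == 0:
        return np.zeros(len(t_starts), dtype=bool)
    lo = np.searchsorted(m_ends, t_starts, side="right")
    hi = np.searchsorted(m_starts, t_ends, side="left")
    return hi > lo


def covered_bases_per_target(
    t_starts: np.ndarray, t_ends: np.ndarray, m_starts: np.ndarray, m_ends: np.ndarray
) -> np.ndarray:
    """Covered bases of each target interval given a merged sorted cover."""
    n = len(t_starts)
    if len(m_starts) == 0 or n == 0:
        return np.zeros(n, dtype=np.int64)
    lengths = m_ends - m_starts
    prefix = np.concatenate([[0], np.cumsum(lengths)])
    lo = np.searchsorted(m_ends, t_starts, side="right")
    hi = np.searchsorted(m_starts, t_ends, side="left")
    full = prefix[hi] - prefix[lo]
    any_hit = hi > lo
    left_clip = np.where(any_hit, np.maximum(0, t_starts - m_starts[np.minimum(lo, len(m_starts) - 1)]), 0)
    right_clip = np.where(any_hit, np.maximum(0, m_ends[np.maximum(hi, 1) - 1] - t_ends), 0)
    return np.where(any_hit, full - left_clip - right_clip, 0)


def feature_coverage(targets: FeatureSet, cover: FeatureSet) -> FeatureCoverage:
    """Count targets overlapped by at least one cover interval.

    A target counts once no matter how many cover intervals hit it; the hit
    list records every overlapping (target, cover) pair for reporting.
    """
    _check_same_assembly(targets, cover)
    trees: dict[str, IntervalTree] = {}
    for f in cover:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    hits: list[tuple[Interval, Interval]] = []
    hit_targets: set[int] = set()
    for i, t in enumerate(targets):
        tree = trees.get(t.chrom)
        if tree is None:
            continue
        found = sorted(tree.overlap(t.start, t.end), key=lambda iv: (iv.begin, iv.end))
        if found:
            hit_targets.add(i)
            hits.extend((t, iv.data) for iv in found)
    n = len(targets)
    count = len(hit_targets)
    return FeatureCoverage(n, count, count / n if n else 0.0, hits)


def base_coverage(targets: FeatureSet, cover: FeatureSet) -> BaseCoverage:
    """Fraction of target bases covered by the merged cover set.

    Overlapping cover intervals are unioned first so shared bases are not
    double-counted; overlapping *targets* each contribute their own bases.
    """
    _check_same_assembly(targets, cover)
    merged = cover.merged_arrays()
    covered = 0
    total = 0
    for chrom, (t_starts, t_ends, _) in targets.by_chrom().items():
        total += int((t_ends - t_starts).sum())
        if chrom in merged:
            m_starts, m_ends = merged[chrom]
            covered += int(covered_bases_per_target(t_starts, t_ends, m_starts, m_ends).sum())
    return BaseCoverage(covered, total)


# ---------------------------------------------------------------------------
# file I/O: chrom.sizes, BED3/BED6, TSV feature tables
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path, name: str | None = None) -> GenomeAssembly:
    """Read a UCSC-style two-column chrom.sizes file into an assembly."""
    path = Path(path)
    chroms: list[tuple[str, int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise LocusParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
        try:
            chroms.append((parts[0], int(parts[1])))
        except ValueError as exc:
            raise LocusParseError(f"{path}:{lineno}: bad chromosome length {parts[1]!r}") from exc
    return GenomeAssembly(name or path.stem, tuple(chroms))


def read_bed(
    path: str | Path,
    assembly: GenomeAssembly | None = None,
    kind: str = "generic",
    label: str | None = None,
) -> FeatureSet:
    """Read BED3/BED6 (already 0-based half-open) into a FeatureSet."""
    path = Path(path)
    features: list[Interval] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise LocusParseError(f"{path}:{lineno}: BED line needs >= 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise LocusParseError(f"{path}:{lineno}: non-integer BED coordinates") from exc
        name = parts[3] if len(parts) > 3 and parts[3] != "." else None
        try:
            features.append(Interval(parts[0], start, end, id=name))
        except ValueError as exc:
            raise LocusParseError(f"{path}:{lineno}: {exc}") from exc
    return FeatureSet(features, assembly=assembly, kind=kind, label=label or path.stem)


def write_bed(feature_set: FeatureSet, path: str | Path, score_attr: str | None = None) -> None:
    """Write a FeatureSet as BED (BED4, or BED6 when a score attribute is named)."""
    path = Path(path)
    with path.open("w") as fh:
        for f in feature_set:
            cols = [f.chrom, str(f.start), str(f.end), f.id or "."]
            if score_attr is not None:
                cols += [str(f.attrs.get(score_attr, 0)), "."]
            fh.write("\t".join(cols) + "\n")


def read_feature_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    assembly: GenomeAssembly | None = None,
    kind: str = "generic",
    label: str | None = None,
    sep: str = "\t",
) -> FeatureSet:
    """Read a TSV feature table with a declared column schema.

    ``schema`` maps roles to column names. Either ``locus`` (a 1-based
    position string column) or all of ``chrom``/``start``/``end`` (0-based
    half-open) must be declared; ``id`` is optional; every other column is
    preserved as interval attributes. Defaults to ``{"locus": "locus",
    "id": "id"}``.
    """
    schema = dict(schema or {"locus": "locus", "id": "id"})
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    have_locus = "locus" in schema
    needed = [schema["locus"]] if have_locus else [schema.get(k) for k in ("chrom", "start", "end")]
    if not have_locus and any(c is None for c in needed):
        raise LocusParseError(
            "schema must declare a 'locus' column or all of 'chrom'/'start'/'end'"
        )
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise LocusParseError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    id_col = schema.get("id")
    reserved = set(needed) | ({id_col} if id_col else set())
    attr_cols = [c for c in df.columns if c not in reserved]
    features: list[Interval] = []
    for row_idx, row in df.iterrows():
        lineno = row_idx + 2  # header is line 1
        fid = None
        if id_col and id_col in df.columns and pd.notna(row[id_col]):
            fid = str(row[id_col])
        attrs = {c: str(row[c]) for c in attr_cols if pd.notna(row[c])}
        try:
            if have_locus:
                iv = parse_locus(str(row[schema["locus"]]), assembly=assembly, id=fid, attrs=attrs)
            else:
                iv = Interval(
                    str(row[schema["chrom"]]),
                    int(row[schema["start"]]),
                    int(row[schema["end"]]),
                    id=fid,
                    attrs=attrs,
                )
        except (ValueError, LocusParseError) as exc:
            raise LocusParseError(f"{path}: line {lineno}: {exc}") from exc
        features.append(iv)
    return FeatureSet(features, assembly=assembly, kind=kind,
                      label=label or Path(path).stem)
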