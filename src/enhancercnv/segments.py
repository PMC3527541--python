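"""aCGH probe-track QC, segmentation, aberration filtering and annotation.

A :class:`ProbeTrack` holds ordered per-probe log2 test/reference ratios.
Track noise is summarised by the derivative log ratio spread (DLRS), a
robust estimate of probe-to-probe noise computed from consecutive-probe
differences. Copy-number segments are found by recursive binary mean-shift
segmentation (split where the two-sample t statistic is maximal, accept
while |t| exceeds a threshold), and surviving calls are screened by the
standard aberration filter: at least three probes in the same direction and
an absolute mean log2 ratio no smaller than the track DLRS. Filtered calls
are then annotated against enhancer, known-variation and disease-region
sets with a fixed classification precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import FeatureSet, Interval, feature_coverage

__all__ = [
    "ProbeTrack",
    "SegmentCall",
    "dlr_spread",
    "segment",
    "aberration_filter",
    "annotate_calls",
]

# IQR of a standard normal; used to convert IQR to an SD-scale estimate
_NORMAL_IQR = 1.349


class ProbeTrack:
    """Ordered probe positions with log2 ratios, grouped by chromosome."""

    def __init__(self, chroms: np.ndarray, positions: np.ndarray, log2: np.ndarray):
        self.chroms = np.asarray(chroms)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.log2 = np.asarray(log2, dtype=float)
        if not (len(self.chroms) == len(self.positions) == len(self.log2)):
            raise ValueError("chrom/position/log2 arrays must have equal length")
        if not np.all(np.isfinite(self.log2)):
            raise ValueError("log2 ratios must be finite")
        for chrom in self.chrom_order():
            pos = self.positions[self.chroms == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"probe positions not strictly increasing on {chrom}")

    def __len__(self) -> int:
        return len(self.positions)

    def chrom_order(self) -> list[str]:
        seen: list[str] = []
        for c in self.chroms:
            if c not in seen:
                seen.append(str(c))
        return seen

    def by_chrom(self):
        for chrom in self.chrom_order():
            mask = self.chroms == chrom
            yield chrom, self.positions[mask], self.log2[mask]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeTrack":
        """Read a three-column TSV: chrom, position (bp), log2 ratio."""
        df = pd.read_csv(path, sep="\t", comment="#")
        cols = list(df.columns[:3])
        return cls(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(), df[cols[2]].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"chrom": self.chroms, "position": self.positions, "log2": self.log2}
        ).to_csv(path, sep="\t", index=False)

    @property
    def dlrs(self) -> float:
        return dlr_spread(self)


@dataclass
class SegmentCall:
    """A contiguous probe run with a common copy-number level."""

    interval: Interval
    probe_count: int
    mean_log2: float
    passes_filter: bool = False
    annotations: list[tuple[str, str, int]] = field(default_factory=list)
    classification: str | None = None

    def __post_init__(self) -> None:
        if self.probe_count < 1:
            raise ValueError("a segment must contain at least one probe")

    @property
    def direction(self) -> str:
        return "gain" if self.mean_log2 > 0 else "loss"


def dlr_spread(track: ProbeTrack) -> float:
    """Derivative log ratio spread: robust noise of consecutive-probe steps.

    Differences are taken within each chromosome (never across chromosome
    boundaries), pooled, and scaled as ``IQR / (1.349 * sqrt(2))`` so that
    for i.i.d. Gaussian probe noise of SD sigma the statistic estimates
    sigma itself.
    """
    diffs = []
    for _, _, log2 in track.by_chrom():
        if len(log2) >= 2:
            diffs.append(np.diff(log2))
    if not diffs:
        raise ValueError("DLRS needs at least 2 probes on some chromosome")
    pooled = np.concatenate(diffs)
    return float(stats.iqr(pooled) / (_NORMAL_IQR * np.sqrt(2.0)))


def _best_window(x: np.ndarray, min_probes: int) -> tuple[int, int, float]:
    """Window [i, j) maximising the inside-vs-outside two-sample |t|.

    Scans every contiguous window of >= min_probes probes (with at least one
    probe outside) and compares the window mean against the rest of the
    segment with a pooled-variance t statistic. An edge-anchored window
    (i = 0 or j = n) reduces to a plain binary split, so single level shifts
    are found as well as interior events. A zero-variance window whose mean
    differs from the outside is an exact step and scores infinite t.
    Returns (-1, -1, 0.0) when no admissible window exists.
    """
    n = len(x)
    if n < min_probes + 1:
        return -1, -1, 0.0
    cs = np.concatenate([[0.0], np.cumsum(x)])
    css = np.concatenate([[0.0], np.cumsum(x * x)])
    total, total_ss = cs[n], css[n]
    df = max(n - 2, 1)
    best = (-1, -1, 0.0)
    for w in range(min_probes, n):
        i = np.arange(0, n - w + 1)
        sum_in = cs[i + w] - cs[i]
        ss_in = (css[i + w] - css[i]) - sum_in**2 / w
        n_out = n - w
        sum_out = total - sum_in
        ss_out = (total_ss - (css[i + w] - css[i])) - sum_out**2 / n_out
        diff = np.abs(sum_in / w - sum_out / n_out)
        pooled = np.maximum(ss_in + ss_out, 0.0) / df
        se = np.sqrt(np.maximum(pooled, 1e-300) * (1.0 / w + 1.0 / n_out))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        t = np.where(np.isfinite(t), t, 0.0)
        t = np.where((pooled <= 1e-300) & (diff > 0), np.inf, t)
        k = int(np.argmax(t))
        if t[k] > best[2]:
            best = (int(i[k]), int(i[k]) + w, float(t[k]))
    return best


def _segment_chrom(
    pos: np.ndarray,
    log2: np.ndarray,
    chrom: str,
    min_probes: int,
    t_threshold: float,
) -> list[SegmentCall]:
    """Recursive two-cut segmentation of one chromosome."""
    boundaries: list[int] = []

    def recurse(i: int, j: int) -> None:
        a, b, t = _best_window(log2[i:j], min_probes)
        if a < 0 or t < t_threshold:
            return
        for cut in (i + a, i + b):
            if i < cut < j:
                boundaries.append(cut)
        for lo, hi in ((i, i + a), (i + a, i + b), (i + b, j)):
            if hi - lo > 0 and (lo, hi) != (i, j):
                recurse(lo, hi)

    recurse(0, len(log2))
    cuts = [0] + sorted(boundaries) + [len(log2)]
    calls = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        # segment footprint spans probe midpoint coverage: from this
        # segment's first probe to its last probe, inclusive of that base
        iv = Interval(chrom, int(pos[a]), int(pos[b - 1]) + 1)
        calls.append(SegmentCall(iv, probe_count=b - a, mean_log2=float(np.mean(log2[a:b]))))
    return calls


def segment(
    track: ProbeTrack,
    min_probes: int = 2,
    t_threshold: float = 6.0,
) -> list[SegmentCall]:
    """Recursive mean-shift segmentation, per chromosome.

    At each step the contiguous window maximising the inside-vs-outside
    two-sample t statistic is cut out; the cut is accepted while
    ``|t| >= t_threshold`` and the three resulting pieces are segmented
    recursively. ``min_probes`` is the smallest window considered.
    Deterministic for fixed input.
    """
    if len(track) == 0:
        raise ValueError("cannot segment an empty track")
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    calls: list[SegmentCall] = []
    for chrom, pos, log2 in track.by_chrom():
        calls.extend(_segment_chrom(pos, log2, chrom, min_probes, t_threshold))
    return calls


def aberration_filter(calls: list[SegmentCall], dlrs: float) -> list[SegmentCall]:
    """Keep calls with >= 3 probes and |mean log2| >= the track DLRS.

    Both rules come from the standard aCGH aberration filter: a credible
    aberration needs at least three probes changed in the same direction
    and a mean shift that clears the probe-to-probe noise level. The
    ``passes_filter`` flag is set on every input call; the returned list is
    the passing subset (a pure predicate — idempotent under re-application).
    A segment whose mean shift is exactly zero has no copy-number direction
    and is never called aberrant, even on a noiseless track where DLRS = 0.
    """
    if dlrs < 0:
        raise ValueError("DLRS must be non-negative")
    kept = []
    for call in calls:
        call.passes_filter = (
            call.probe_count >= 3
            and abs(call.mean_log2) >= dlrs
            and call.mean_log2 != 0.0
        )
        if call.passes_filter:
            kept.append(call)
    return kept


# classification precedence: disease region > known polymorphism > enhancer
_PRECEDENCE = (
    ("syndrome_regions", "disease-region"),
    ("known_cnvs", "known-polymorphic"),
    ("enhancers", "enhancer-CNV"),
)


def annotate_calls(
    calls: list[SegmentCall],
    enhancers: FeatureSet | None = None,
    known_cnvs: FeatureSet | None = None,
    syndrome_regions: FeatureSet | None = None,
) -> list[SegmentCall]:
    """Annotate calls with overlapping features and classify each call.

    Every overlapping feature of every provided set is recorded as
    ``(set label, feature id, overlap bases)``. Classification applies a
    fixed precedence: a call overlapping a syndrome region is
    "disease-region" regardless of other overlaps; otherwise a known-CNV
    overlap gives "known-polymorphic"; otherwise an enhancer overlap gives
    "enhancer-CNV"; calls with no overlap are "uncertain".
    """
    sets = {
        "syndrome_regions": syndrome_regions,
        "known_cnvs": known_cnvs,
        "enhancers": enhancers,
    }
    assemblies = {fs.assembly.name for fs in sets.values() if fs is not None and fs.assembly}
    if len(assemblies) > 1:
        raise ValueError(f"annotation sets on different assemblies: {sorted(assemblies)}")
    for call in calls:
        call.annotations = []
        call.classification = "uncertain"
        call_set = FeatureSet([call.interval])
        for set_name, classification in _PRECEDENCE:
            fs = sets[set_name]
            if fs is None:
                continue
            fc = feature_coverage(call_set, fs)
            for _, feature in fc.hits:
                ov = min(call.interval.end, feature.end) - max(call.interval.start, feature.start)
                call.annotations.append((set_name, feature.id or "", ov))
            if fc.count and call.classification == "uncertain":
                call.classification = classification
    return calls


def calls_to_frame(calls: list[SegmentCall]) -> pd.DataFrame:
    """Tabular report of calls (one row per call, annotations joined)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "probe_count": c.probe_count,
                "mean_log2": c.mean_log2,
                "direction": c.direction,
                "passes_filter": c.passes_filter,
                "classification": c.classification,
                "annotations": ";".join(
                    f"{s}:{fid}:{ov}" for s, fid, ov in c.annotations
                ),
            }
        )
    return pd.DataFrame(rows)
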