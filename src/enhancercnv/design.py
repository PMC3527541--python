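"""Tiered probe-layout planning for a targeted aCGH design.

A custom array has a fixed feature capacity that must be split across
tiers: a genome-wide *backbone* at coarse spacing, densely tiled
*targeted* regions (telomeres, centromeres, disease loci), an *enhancer*
tier guaranteeing a minimum probe count per enhancer, reserved
*normalization* and *replicate* probe groups consumed as opaque counts,
and a *filler* tier absorbing the residual capacity.

"Resolution" is formalised by a 3-probe detection rule: the smallest
aberration reliably callable spans 3 probes, so resolution = 3 x spacing
(100 kb backbone spacing gives 300 kb resolution) and, conversely, a
requested regional resolution R is tiled at spacing R/3.

Probes are modelled as point positions (probe midpoints); oligo sequence
selection and thermodynamics are out of scope. An optional candidate-
position list emulates a validated-probe catalogue: ideal positions snap
to the nearest in-feature candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .intervals import FeatureSet, GenomeAssembly

__all__ = [
    "TierSpec",
    "Placement",
    "ProbePlan",
    "tile_backbone",
    "tile_regions",
    "tile_enhancers",
    "assemble_plan",
    "DEFAULT_CAPACITY",
]

# usable feature capacity implied by the published tier counts
# (25,000 + 18,000 + 7,790 + 1,262 + 5,000 + 2,853 filler)
DEFAULT_CAPACITY = 59_905

TIER_NAMES = ("backbone", "targeted", "enhancer", "normalization", "replicate", "filler")


@dataclass(frozen=True)
class TierSpec:
    """Budget and layout parameters of one design tier.

    ``target_spacing`` is in bp (backbone), or nt within a feature
    (enhancer tier); for the targeted tier pass ``resolution`` instead and
    the spacing follows from the 3-probe rule. Reserved tiers
    (normalization/replicate) only carry a budget.
    """

    name: str
    budget: int
    target_spacing: int | None = None
    resolution: int | None = None
    min_probes_per_feature: int = 3

    def __post_init__(self) -> None:
        if self.name not in TIER_NAMES:
            raise ValueError(f"unknown tier {self.name!r}; expected one of {TIER_NAMES}")
        if self.budget < 0:
            raise ValueError("tier budget must be >= 0")
        if self.target_spacing is not None and self.target_spacing <= 0:
            raise ValueError("target_spacing must be > 0")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.min_probes_per_feature < 1:
            raise ValueError("min_probes_per_feature must be >= 1")


class Placement(NamedTuple):
    tier: str
    chrom: str
    position: int
    feature_id: str | None


@dataclass
class TierStats:
    name: str
    budget: int
    placed: int
    achieved_spacing: float | None = None
    achieved_resolution: float | None = None


@dataclass
class ProbePlan:
    """A complete tiered probe layout with per-tier achieved statistics."""

    placements: list[Placement]
    tier_stats: dict[str, TierStats]
    capacity: int
    reserved_counts: dict[str, int] = field(default_factory=dict)
    seed: int | None = None

    @property
    def total_features(self) -> int:
        return len(self.placements) + sum(self.reserved_counts.values())

    @property
    def residual(self) -> int:
        return self.capacity - self.total_features

    @property
    def residual_fraction(self) -> float:
        return self.residual / self.capacity

    def tier_placements(self, tier: str) -> list[Placement]:
        return [p for p in self.placements if p.tier == tier]

    def validate(self, enhancers: FeatureSet | None = None) -> None:
        """Check all plan invariants; raise ValueError on any violation."""
        if self.total_features > self.capacity:
            counts = {t: s.placed for t, s in self.tier_stats.items()}
            raise ValueError(
                f"plan exceeds capacity {self.capacity}: per-tier counts {counts}"
            )
        per_tier: dict[str, int] = {}
        for p in self.placements:
            per_tier[p.tier] = per_tier.get(p.tier, 0) + 1
        for tier, n in per_tier.items():
            stats = self.tier_stats.get(tier)
            if stats is not None and n > stats.budget:
                raise ValueError(f"tier {tier!r} placed {n} > budget {stats.budget}")
        seen: set[tuple[str, str, int]] = set()
        last: dict[tuple[str, str], int] = {}
        for p in self.placements:
            key = (p.tier, p.chrom, p.position)
            if key in seen:
                raise ValueError(f"duplicate probe at {key}")
            seen.add(key)
            tk = (p.tier, p.chrom)
            if tk in last and p.position <= last[tk]:
                raise ValueError(f"positions not strictly increasing within {tk}")
            last[tk] = p.position
        if enhancers is not None:
            need = self.tier_stats.get("enhancer")
            min_needed = 3
            counts: dict[str, int] = {}
            for p in self.tier_placements("enhancer"):
                counts[p.feature_id or ""] = counts.get(p.feature_id or "", 0) + 1
            for f in enhancers:
                if counts.get(f.id or "", 0) < min_needed:
                    raise ValueError(
                        f"enhancer {f.id!r} has {counts.get(f.id or '', 0)} probes (< {min_needed})"
                    )
            del need

    def report(self) -> dict:
        return {
            "capacity": self.capacity,
            "total_features": self.total_features,
            "residual": self.residual,
            "residual_fraction": self.residual_fraction,
            "seed": self.seed,
            "tiers": {
                t: {
                    "budget": s.budget,
                    "placed": s.placed,
                    "achieved_spacing": s.achieved_spacing,
                    "achieved_resolution": s.achieved_resolution,
                }
                for t, s in self.tier_stats.items()
            },
        }

    def to_bed(self, path) -> None:
        """Emit probe placements as BED4 (name = tier or tier/feature id)."""
        with open(path, "w") as fh:
            for p in self.placements:
                name = f"{p.tier}/{p.feature_id}" if p.feature_id else p.tier
                fh.write(f"{p.chrom}\t{p.position}\t{p.position + 1}\t{name}\n")


def tile_backbone(assembly: GenomeAssembly, spec: TierSpec) -> list[Placement]:
    """Uniform genome-wide tiling at the tier's target spacing.

    Probes sit at spacing/2, 3*spacing/2, ... on each chromosome; every
    chromosome gets at least one probe (its midpoint). If the implied count
    exceeds the budget, spacing is widened to ceil(genome_size / budget)
    and the tiling is recomputed.
    """
    if spec.budget == 0:
        raise ValueError("backbone budget must be > 0")
    if spec.budget < len(assembly.chromosomes):
        raise ValueError("backbone budget smaller than the chromosome count")
    if spec.target_spacing is None:
        raise ValueError("backbone tier needs a target_spacing")

    def _tile(spacing: int) -> list[Placement]:
        out: list[Placement] = []
        for chrom, length in assembly.chromosomes:
            if length < spacing:
                out.append(Placement("backbone", chrom, length // 2, None))
                continue
            n = length // spacing
            positions = spacing // 2 + spacing * np.arange(n)
            out.extend(Placement("backbone", chrom, int(p), None) for p in positions)
        return out

    spacing = spec.target_spacing
    placements = _tile(spacing)
    if len(placements) > spec.budget:
        spacing = math.ceil(assembly.total_size / spec.budget)
        placements = _tile(spacing)
    return placements


def tile_regions(regions: FeatureSet, spec: TierSpec) -> list[Placement]:
    """Dense tiling of targeted regions at a requested resolution.

    Within-region spacing is resolution/3 (3-probe rule) with a minimum of
    ``min_probes_per_feature`` probes per region. Budget overflow is
    resolved by deterministic proportional thinning: every k-th probe is
    kept, k = ceil(total/budget), so achieved resolution degrades by the
    same factor everywhere.
    """
    if len(regions) == 0:
        raise ValueError("no regions to tile")
    resolution = spec.resolution
    if resolution is None:
        if spec.target_spacing is None:
            raise ValueError("targeted tier needs a resolution (or target_spacing)")
        resolution = 3 * spec.target_spacing
    spacing = resolution / 3
    placements: list[Placement] = []
    for f in regions:
        n = max(spec.min_probes_per_feature, math.ceil(f.length / spacing))
        n = min(n, f.length)  # cannot place more distinct positions than bases
        offs = ((np.arange(n) + 0.5) * f.length / n).astype(np.int64)
        placements.extend(
            Placement("targeted", f.chrom, int(f.start + o), f.id) for o in offs
        )
    if len(placements) > spec.budget:
        k = math.ceil(len(placements) / spec.budget)
        placements = placements[::k]
    return placements


def tile_enhancers(
    enhancers: FeatureSet,
    spec: TierSpec,
    candidates: FeatureSet | None = None,
) -> list[Placement]:
    """Per-enhancer tiling: n = max(min_probes, ceil(length / spacing)).

    The n probes sit at the n evenly spaced interior positions
    ``start + floor((j + 0.5) * L / n)``. With a candidate-position list,
    each ideal position snaps to the nearest candidate inside the enhancer
    (ties resolved toward the lower coordinate); candidates are consumed so
    no two probes share a position.
    """
    if len(enhancers) == 0:
        raise ValueError("no enhancers to tile")
    if spec.target_spacing is None:
        raise ValueError("enhancer tier needs a target_spacing (nt)")
    cand_by_chrom: dict[str, np.ndarray] = {}
    if candidates is not None:
        for chrom, (s, _, _) in candidates.by_chrom().items():
            cand_by_chrom[chrom] = s
    placements: list[Placement] = []
    for f in enhancers:
        n = max(spec.min_probes_per_feature, math.ceil(f.length / spec.target_spacing))
        if f.length < n:
            raise ValueError(
                f"enhancer {f.id or f.to_locus_string()} of length {f.length} "
                f"cannot hold {n} distinct probe positions"
            )
        ideal = f.start + ((np.arange(n) + 0.5) * f.length / n).astype(np.int64)
        if f.chrom in cand_by_chrom:
            pool = cand_by_chrom[f.chrom]
            inside = pool[(pool >= f.start) & (pool < f.end)]
            if len(inside) < n:
                raise ValueError(
                    f"enhancer {f.id or f.to_locus_string()}: only {len(inside)} "
                    f"candidate positions for {n} probes"
                )
            chosen: list[int] = []
            avail = inside.astype(np.int64).tolist()
            for target in ideal:
                # nearest available candidate; tie -> lower coordinate
                best = min(avail, key=lambda c: (abs(c - int(target)), c))
                avail.remove(best)
                chosen.append(best)
            positions = sorted(chosen)
        else:
            positions = [int(p) for p in ideal]
        placements.extend(Placement("enhancer", f.chrom, p, f.id) for p in positions)
    return placements


def _mean_spacing(placements: Iterable[Placement]) -> float | None:
    by_chrom: dict[str, list[int]] = {}
    for p in placements:
        by_chrom.setdefault(p.chrom, []).append(p.position)
    gaps: list[int] = []
    for positions in by_chrom.values():
        positions.sort()
        gaps.extend(np.diff(positions).tolist())
    return float(np.mean(gaps)) if gaps else None


def assemble_plan(
    backbone: list[Placement] | None = None,
    targeted: list[Placement] | None = None,
    enhancer: list[Placement] | None = None,
    tier_specs: dict[str, TierSpec] | None = None,
    capacity: int = DEFAULT_CAPACITY,
    normalization_budget: int = 0,
    replicate_budget: int = 0,
    filler_catalogue: FeatureSet | None = None,
    seed: int = 0,
    enhancers: FeatureSet | None = None,
) -> ProbePlan:
    """Combine tier placements into a validated plan with filler.

    Reserved tiers (normalization, replicate) consume their budgets as
    opaque feature counts. The filler tier absorbs the residual capacity:
    when a catalogue of filler positions is supplied, the residual count is
    drawn from it by seeded uniform sampling without replacement; otherwise
    the residual is reported unfilled.
    """
    if capacity <= 0:
        raise ValueError("capacity must be > 0")
    tier_specs = tier_specs or {}
    placements: list[Placement] = []
    stats: dict[str, TierStats] = {}
    for name, placed in (("backbone", backbone), ("targeted", targeted), ("enhancer", enhancer)):
        placed = placed or []
        placements.extend(placed)
        spec = tier_specs.get(name)
        budget = spec.budget if spec else len(placed)
        mean_sp = _mean_spacing(placed)
        stats[name] = TierStats(
            name,
            budget,
            len(placed),
            achieved_spacing=mean_sp,
            achieved_resolution=3 * mean_sp if mean_sp is not None else None,
        )
    reserved = {"normalization": normalization_budget, "replicate": replicate_budget}
    for name, count in reserved.items():
        stats[name] = TierStats(name, count, count)
    used = len(placements) + sum(reserved.values())
    if used > capacity:
        counts = {t: s.placed for t, s in stats.items()}
        raise ValueError(f"placements exceed capacity {capacity}: {counts}")
    residual = capacity - used
    filler: list[Placement] = []
    if filler_catalogue is not None and residual > 0:
        entries = sorted(
            ((f.chrom, f.start, f.id) for f in filler_catalogue),
            key=lambda t: (t[0], t[1]),
        )
        if len(entries) < residual:
            raise ValueError(
                f"filler catalogue has {len(entries)} entries for residual {residual}"
            )
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(entries), size=residual, replace=False))
        filler = [Placement("filler", entries[i][0], entries[i][1], entries[i][2]) for i in idx]
        placements.extend(filler)
    stats["filler"] = TierStats("filler", residual, len(filler))
    plan = ProbePlan(
        placements=placements,
        tier_stats=stats,
        capacity=capacity,
        reserved_counts=reserved,
        seed=seed,
    )
    plan.validate(enhancers=enhancers)
    return plan
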