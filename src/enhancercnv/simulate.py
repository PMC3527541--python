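"""Seeded synthetic inputs: genome, enhancers, CNV sets, probe tracks.

The generator emulates the statistical structure the depletion analysis
assumes: enhancers (~1-2 kb conserved elements) placed uniformly without
overlap on a multi-chromosome genome, and a CNV set sampled uniformly
until its merged footprint reaches a target genome-coverage fraction
``c``. Negative selection at enhancers is modelled by a thinning
(depletion) parameter ``delta``: a sampled CNV that overlaps any enhancer
is retained with probability delta, so delta = 1 gives placement with no
relationship to enhancers and delta = 0 total exclusion. Under this
mechanism the expected enhancer base coverage is ~delta * c, so the
observed/expected fold statistic estimates delta directly.

Probe tracks are Gaussian log2-ratio baselines with planted aberrations:
a heterozygous deletion shifts probes by log2(1/2) = -1 and a single-copy
duplication by log2(3/2) = +0.585.

Everything is reproducible from the scenario seed alone; all coordinate
sampling is integer-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intervals import FeatureSet, GenomeAssembly, Interval, write_bed
from .segments import ProbeTrack

__all__ = [
    "PlantedAberration",
    "SyntheticScenario",
    "generate_features",
    "generate_probe_track",
    "scenario_truth",
    "write_scenario",
]

LOSS_LOG2 = float(np.log2(0.5))  # one copy lost from two
GAIN_LOG2 = float(np.log2(1.5))  # one copy gained over two


@dataclass(frozen=True)
class PlantedAberration:
    """A ground-truth copy-number event on a probe track."""

    chrom: str
    start: int  # bp; the event spans `n_probes` probes at/after this position
    n_probes: int
    log2_shift: float

    @property
    def direction(self) -> str:
        return "gain" if self.log2_shift > 0 else "loss"


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study, reproducible from ``seed`` alone.

    Defaults describe a desk-scale genome with enhancer lengths matching
    the published ~0.8-2.2 kb loci and a log-uniform CNV length
    distribution spanning 1 kb - 500 kb.
    """

    seed: int = 0
    n_chromosomes: int = 5
    chromosome_length: int = 20_000_000
    n_enhancers: int = 500
    enhancer_length_range: tuple[int, int] = (800, 2200)
    n_cnvs: int = 1000
    cnv_length_range: tuple[int, int] = (1_000, 500_000)
    coverage_target: float | None = 0.15
    delta: float = 1.0
    probe_noise_sd: float = 0.2
    probe_spacing: int = 10_000
    planted: tuple[PlantedAberration, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must lie in [0, 1]")
        if self.coverage_target is not None and not 0 < self.coverage_target < 1:
            raise ValueError("coverage_target must lie in (0, 1)")
        if self.n_enhancers <= 0 or self.n_cnvs <= 0 or self.n_chromosomes <= 0:
            raise ValueError("all counts must be positive")
        if self.probe_noise_sd < 0:
            raise ValueError("probe_noise_sd must be >= 0")

    @property
    def assembly(self) -> GenomeAssembly:
        return GenomeAssembly(
            f"synthetic-{self.seed}",
            tuple(
                (f"chr{i + 1}", self.chromosome_length) for i in range(self.n_chromosomes)
            ),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted"] = [dataclasses.asdict(p) for p in self.planted]
        return d


def _sample_nonoverlapping(
    rng: np.random.Generator,
    assembly: GenomeAssembly,
    n: int,
    length_range: tuple[int, int],
    max_attempts_factor: int = 50,
) -> list[Interval]:
    """Uniformly place n non-overlapping intervals; error if infeasible."""
    chrom_names = [c for c, _ in assembly.chromosomes]
    sizes = assembly.sizes
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    out: list[Interval] = []
    attempts = 0
    limit = max_attempts_factor * n
    while len(out) < n:
        attempts += 1
        if attempts > limit:
            raise RuntimeError(
                f"failed to place {n} non-overlapping features after {limit} attempts"
            )
        chrom = chrom_names[rng.integers(0, len(chrom_names))]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if length > sizes[chrom]:
            continue
        start = int(rng.integers(0, sizes[chrom] - length + 1))
        end = start + length
        if any(start < e and s < end for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        out.append(Interval(chrom, start, end, id=f"enh{len(out) + 1:04d}"))
    out.sort(key=lambda f: (f.chrom, f.start))
    return out


def _log_uniform_length(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_features(
    scenario: SyntheticScenario,
) -> tuple[FeatureSet, FeatureSet]:
    """Generate the enhancer set and a CNV set with depletion ``delta``.

    CNVs are drawn uniformly (chromosome by length-proportional choice,
    start uniform, length log-uniform); each draw overlapping any enhancer
    is retained with probability delta. When ``coverage_target`` is set,
    sampling continues until the merged CNV footprint reaches the target
    within 2% relative tolerance (a draw that would overshoot the upper
    tolerance is redrawn with a capped length); otherwise exactly
    ``n_cnvs`` retained CNVs are produced.
    """
    rng = np.random.default_rng(scenario.seed)
    assembly = scenario.assembly
    enhancers = FeatureSet(
        _sample_nonoverlapping(rng, assembly, scenario.n_enhancers,
                               scenario.enhancer_length_range),
        assembly=assembly,
        kind="enhancer",
        label="enhancers",
    )
    enh_by_chrom = {
        chrom: (s, e) for chrom, (s, e, _) in enhancers.by_chrom().items()
    }
    chrom_names = [c for c, _ in assembly.chromosomes]
    sizes = assembly.sizes
    lengths_arr = np.array([sizes[c] for c in chrom_names], dtype=float)
    chrom_p = lengths_arr / lengths_arr.sum()
    genome = assembly.total_size
    target = scenario.coverage_target
    lo, hi = scenario.cnv_length_range

    cnvs: list[Interval] = []
    # incremental merged-coverage tracking: per-chromosome interval buffers
    # and their merged base counts, so each draw costs one per-chrom merge
    buf: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    chrom_covered: dict[str, int] = {c: 0 for c in chrom_names}
    covered_frac = 0.0
    attempts = 0
    limit = 200 * max(scenario.n_cnvs, 1000)

    def merged_with(chrom: str, start: int, end: int) -> int:
        from .intervals import merge_arrays

        pairs = buf[chrom] + [(start, end)]
        s = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
        e = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
        ms, me = merge_arrays(s, e)
        return int((me - ms).sum())

    while True:
        if target is None and len(cnvs) >= scenario.n_cnvs:
            break
        if target is not None and covered_frac >= target * 0.98:
            break
        attempts += 1
        if attempts > limit:
            raise RuntimeError(
                f"could not reach coverage target {target} after {limit} draws; "
                "target may be infeasible for this genome"
            )
        max_len = hi
        if target is not None:
            # never overshoot the upper tolerance band
            room = int((target * 1.02 - covered_frac) * genome)
            if room < lo:
                max_len = max(1, room)
            else:
                max_len = min(hi, room)
        length = _log_uniform_length(rng, min(lo, max_len), max_len)
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
        if length > sizes[chrom]:
            continue
        start = int(rng.integers(0, sizes[chrom] - length + 1))
        end = start + length
        hits_enh = False
        if chrom in enh_by_chrom:
            es, ee = enh_by_chrom[chrom]
            k = np.searchsorted(ee, start, side="right")
            hits_enh = k < len(es) and es[k] < end
        if hits_enh and rng.random() >= scenario.delta:
            continue  # thinned: negative selection removed this variant
        if target is not None:
            new_chrom_cov = merged_with(chrom, start, end)
            new_frac = covered_frac + (new_chrom_cov - chrom_covered[chrom]) / genome
            if new_frac > target * 1.02:
                continue
            chrom_covered[chrom] = new_chrom_cov
            covered_frac = new_frac
        buf[chrom].append((start, end))
        cnvs.append(Interval(chrom, start, end, id=f"cnv{len(cnvs) + 1:05d}"))
    cnvs.sort(key=lambda f: (f.chrom, f.start))
    cnv_set = FeatureSet(cnvs, assembly=assembly, kind="cnv", label="cnvs")
    return enhancers, cnv_set


def generate_probe_track(
    scenario: SyntheticScenario,
    positions: dict[str, np.ndarray] | None = None,
) -> ProbeTrack:
    """Gaussian-noise log2 track with the scenario's planted aberrations.

    Probes sit at the provided per-chromosome positions, or at uniform
    ``probe_spacing`` across the genome. Each planted aberration shifts
    the ``n_probes`` probes at/after its start position by its log2 shift.
    """
    assembly = scenario.assembly
    sizes = assembly.sizes
    if positions is None:
        positions = {}
        for chrom, length in assembly.chromosomes:
            sp = scenario.probe_spacing
            positions[chrom] = np.arange(sp // 2, length, sp, dtype=np.int64)
    # derive the track stream from the scenario seed, decoupled from the
    # feature-sampling stream so tracks and feature sets are independent
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 7]))
    chroms_list = []
    pos_list = []
    log2_list = []
    for chrom, _ in assembly.chromosomes:
        pos = positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        noise = rng.normal(0.0, scenario.probe_noise_sd, size=len(pos))
        chroms_list.append(np.full(len(pos), chrom, dtype=object))
        pos_list.append(np.asarray(pos, dtype=np.int64))
        log2_list.append(noise)
    chroms = np.concatenate(chroms_list)
    pos = np.concatenate(pos_list)
    log2 = np.concatenate(log2_list)
    for ab in scenario.planted:
        if ab.chrom not in sizes or not 0 <= ab.start < sizes[ab.chrom]:
            raise ValueError(f"planted aberration outside genome: {ab}")
        mask = chroms == ab.chrom
        idx = np.flatnonzero(mask & (pos >= ab.start))
        if len(idx) < ab.n_probes:
            raise ValueError(
                f"planted aberration {ab} spans {ab.n_probes} probes but only "
                f"{len(idx)} remain on {ab.chrom}"
            )
        log2[idx[: ab.n_probes]] += ab.log2_shift
    return ProbeTrack(chroms, pos, log2)


def planted_intervals(
    scenario: SyntheticScenario, track: ProbeTrack
) -> list[tuple[Interval, str]]:
    """Genomic footprint (and direction) of each planted aberration."""
    out = []
    for ab in scenario.planted:
        mask = track.chroms == ab.chrom
        pos = track.positions[mask]
        idx = np.flatnonzero(pos >= ab.start)[: ab.n_probes]
        iv = Interval(ab.chrom, int(pos[idx[0]]), int(pos[idx[-1]]) + 1)
        out.append((iv, ab.direction))
    return out


def scenario_truth(
    scenario: SyntheticScenario,
    enhancers: FeatureSet,
    cnvs: FeatureSet,
) -> pd.DataFrame:
    """Ground-truth (enhancer, CNV) overlap pairs for scoring recovery."""
    from .intervals import feature_coverage

    fc = feature_coverage(enhancers, cnvs)
    rows = [
        {
            "enhancer_id": t.id,
            "cnv_id": c.id,
            "chrom": t.chrom,
            "enhancer_start": t.start,
            "enhancer_end": t.end,
            "cnv_start": c.start,
            "cnv_end": c.end,
        }
        for t, c in fc.hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "enhancer_id", "cnv_id", "chrom",
            "enhancer_start", "enhancer_end", "cnv_start", "cnv_end",
        ],
    )


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, Path]:
    """Emit all pipeline inputs for a scenario into a directory.

    Writes chrom.sizes, enhancers.bed, cnvs.bed, probes.tsv, truth.tsv and
    scenario.yaml; returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assembly = scenario.assembly
    enhancers, cnvs = generate_features(scenario)
    track = generate_probe_track(scenario)
    truth = scenario_truth(scenario, enhancers, cnvs)
    paths = {
        "chrom_sizes": outdir / "chrom.sizes",
        "enhancers": outdir / "enhancers.bed",
        "cnvs": outdir / "cnvs.bed",
        "probes": outdir / "probes.tsv",
        "truth": outdir / "truth.tsv",
        "scenario": outdir / "scenario.yaml",
    }
    with paths["chrom_sizes"].open("w") as fh:
        for chrom, length in assembly.chromosomes:
            fh.write(f"{chrom}\t{length}\n")
    write_bed(enhancers, paths["enhancers"])
    write_bed(cnvs, paths["cnvs"])
    track.to_tsv(paths["probes"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["scenario"].write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=False))
    return paths
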