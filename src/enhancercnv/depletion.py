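"""Observed-vs-expected coverage of enhancer loci by CNV sets.

The headline analysis: under a null of no relationship between CNVs and
enhancers, the fraction of enhancer loci hit by a CNV set should match the
fraction of the genome that set covers. The expected number of covered
enhancers is therefore ``N_targets x genome_coverage_fraction``, and a
deficit of observed coverage (fold < 1) indicates depletion — negative
selection against copy-number change at regulatory elements.

Two parametric tests are computed on absolute counts (1-df chi-square
goodness of fit and an exact binomial test), plus an optional permutation
null that re-places every cover interval uniformly at random on its own
chromosome, preserving interval lengths and per-chromosome CNV density.

The module is organised around :class:`EnhancerDepletionModel` (built from
two feature sets on an assembly) whose :meth:`~EnhancerDepletionModel.fit`
returns a :class:`DepletionResults` with estimates, p-values, the
permutation summary and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    FeatureSet,
    GenomeAssembly,
    base_coverage,
    covered_bases_per_target,
    covered_mask,
    feature_coverage,
    merge_arrays,
    read_bed,
    read_chrom_sizes,
)

__all__ = [
    "CoverageComparison",
    "PermutationSummary",
    "EnhancerDepletionModel",
    "DepletionResults",
    "expected_counts",
    "depletion_statistic",
    "test_counts",
    "permutation_null",
    "figure1_table",
]


@dataclass
class PermutationSummary:
    """Monte-Carlo null for the coverage statistics under random placement.

    Empirical p-values use the add-one correction
    ``p = (1 + #{null <= observed}) / (1 + n_permutations)`` so that a
    permutation p can never be exactly zero.
    """

    n_permutations: int
    seed: int
    null_counts: np.ndarray
    null_base_fractions: np.ndarray
    observed_count: int
    observed_base_fraction: float
    alternative: str = "less"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def _empirical_p(self, null: np.ndarray, observed: float) -> float:
        if self.alternative == "less":
            extreme = int(np.sum(null <= observed))
        elif self.alternative == "greater":
            extreme = int(np.sum(null >= observed))
        else:  # two-sided: double the smaller tail, capped at 1
            lo = int(np.sum(null <= observed))
            hi = int(np.sum(null >= observed))
            extreme = 2 * min(lo, hi)
        return min(1.0, (1 + extreme) / (1 + self.n_permutations))

    @property
    def p_count(self) -> float:
        return self._empirical_p(self.null_counts, self.observed_count)

    @property
    def p_base_fraction(self) -> float:
        return self._empirical_p(self.null_base_fractions, self.observed_base_fraction)

    @property
    def null_mean_count(self) -> float:
        return float(np.mean(self.null_counts))

    def null_count_ci(self, level: float = 0.95) -> tuple[float, float]:
        a = 100 * (1 - level) / 2
        return tuple(np.percentile(self.null_counts, [a, 100 - a]))

    def null_base_fraction_ci(self, level: float = 0.95) -> tuple[float, float]:
        a = 100 * (1 - level) / 2
        return tuple(np.percentile(self.null_base_fractions, [a, 100 - a]))


@dataclass
class CoverageComparison:
    """Observed vs expected coverage of a target set by one cover set."""

    target_label: str
    cover_label: str
    n_targets: int
    observed_count: int
    expected_count: float
    observed_base_fraction: float
    expected_base_fraction: float
    fold: float
    p_chisq: float
    p_binomial: float
    permutation: PermutationSummary | None = field(default=None, repr=False)

    @property
    def observed_feature_fraction(self) -> float:
        return self.observed_count / self.n_targets if self.n_targets else 0.0


def expected_counts(
    targets: FeatureSet | int,
    cover: FeatureSet | float,
    assembly: GenomeAssembly | None = None,
) -> tuple[float, float]:
    """Expected covered-target count and base fraction under the random null.

    ``expected_base_fraction`` is the merged cover footprint divided by the
    genome size; ``expected_count = N_targets x expected_base_fraction``.
    Accepts either feature sets on an assembly or the raw ``(N, fraction)``
    numbers.
    """
    if isinstance(targets, FeatureSet):
        n_targets = len(targets)
    else:
        n_targets = int(targets)
    if isinstance(cover, FeatureSet):
        assembly = assembly or cover.assembly
        if assembly is None or assembly.total_size <= 0:
            raise ValueError("an assembly with positive genome size is required")
        frac = cover.merged_bases() / assembly.total_size
    else:
        frac = float(cover)
        if not 0 <= frac <= 1:
            raise ValueError(f"genome coverage fraction must be in [0,1], got {frac}")
    return n_targets * frac, frac


def test_counts(
    observed_count: int,
    expected_count: float,
    n_targets: int,
    alternative: str = "less",
) -> tuple[float, float]:
    """Parametric tests on absolute covered-target counts.

    Returns ``(p_chisq, p_binomial)``: a 1-df chi-square goodness of fit on
    the {covered, uncovered} split (two-sided by construction) and an exact
    binomial test, one-sided toward depletion by default. Neither p-value is
    floored: values below double precision are reported as computed.
    """
    if not 0 <= observed_count <= n_targets:
        raise ValueError("observed_count must be in [0, n_targets]")
    if not 0 < expected_count < n_targets:
        raise ValueError(
            f"degenerate expectation {expected_count} for N={n_targets}: "
            "the null must give both categories positive mass"
        )
    p = expected_count / n_targets
    chi = stats.chisquare(
        [observed_count, n_targets - observed_count],
        [expected_count, n_targets - expected_count],
    )
    binom = stats.binomtest(observed_count, n_targets, p, alternative=alternative)
    return float(chi.pvalue), float(binom.pvalue)


def depletion_statistic(
    targets: FeatureSet,
    cover: FeatureSet,
    assembly: GenomeAssembly | None = None,
    alternative: str = "less",
) -> CoverageComparison:
    """Full observed/expected comparison of one cover set against targets."""
    assembly = assembly or targets.assembly or cover.assembly
    if assembly is None:
        raise ValueError("an assembly is required (bind it to a FeatureSet or pass it)")
    fc = feature_coverage(targets, cover)
    bc = base_coverage(targets, cover)
    exp_count, exp_frac = expected_counts(len(targets), cover, assembly)
    obs_frac = bc.fraction
    if exp_frac == 0:
        fold = 0.0 if obs_frac == 0 else float("nan")
    else:
        fold = obs_frac / exp_frac
    if 0 < exp_count < len(targets):
        p_chisq, p_binom = test_counts(fc.count, exp_count, len(targets), alternative)
    else:  # degenerate expectation: tests undefined
        p_chisq = p_binom = float("nan")
    return CoverageComparison(
        target_label=targets.label,
        cover_label=cover.label,
        n_targets=len(targets),
        observed_count=fc.count,
        expected_count=exp_count,
        observed_base_fraction=obs_frac,
        expected_base_fraction=exp_frac,
        fold=fold,
        p_chisq=p_chisq,
        p_binomial=p_binom,
    )


def _target_arrays(targets: FeatureSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return {c: (s, e) for c, (s, e, _) in targets.by_chrom().items()}


def permutation_null(
    targets: FeatureSet,
    cover: FeatureSet,
    assembly: GenomeAssembly | None = None,
    n_permutations: int = 199,
    seed: int = 0,
    alternative: str = "less",
) -> PermutationSummary:
    """Random-placement null for the coverage statistics.

    Each permutation re-places every cover interval uniformly at random on
    its original chromosome with its length preserved (start drawn from
    ``[0, chrom_len - length]``), then recomputes the covered-target count
    and the covered-base fraction. Reproducible from ``seed`` alone.
    """
    assembly = assembly or targets.assembly or cover.assembly
    if assembly is None:
        raise ValueError("an assembly is required for random placement")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    sizes = assembly.sizes
    cov_by_chrom: dict[str, np.ndarray] = {}
    for chrom, (s, e, _) in cover.by_chrom().items():
        lengths = e - s
        too_long = lengths > sizes[chrom]
        if np.any(too_long):
            bad = int(lengths[too_long][0])
            raise ValueError(
                f"cover interval of length {bad} exceeds chromosome {chrom} "
                f"length {sizes[chrom]}"
            )
        cov_by_chrom[chrom] = lengths
    tgt = _target_arrays(targets)
    total_target_bases = sum(int((e - s).sum()) for s, e in tgt.values())
    rng = np.random.default_rng(seed)
    null_counts = np.zeros(n_permutations, dtype=np.int64)
    null_fracs = np.zeros(n_permutations, dtype=float)
    for b in range(n_permutations):
        count = 0
        covered = 0
        for chrom, lengths in cov_by_chrom.items():
            starts = rng.integers(0, sizes[chrom] - lengths + 1)
            ms, me = merge_arrays(starts, starts + lengths)
            if chrom in tgt:
                ts, te = tgt[chrom]
                count += int(covered_mask(ts, te, ms, me).sum())
                covered += int(covered_bases_per_target(ts, te, ms, me).sum())
        null_counts[b] = count
        null_fracs[b] = covered / total_target_bases if total_target_bases else 0.0
    fc = feature_coverage(targets, cover)
    bc = base_coverage(targets, cover)
    return PermutationSummary(
        n_permutations=n_permutations,
        seed=seed,
        null_counts=null_counts,
        null_base_fractions=null_fracs,
        observed_count=fc.count,
        observed_base_fraction=bc.fraction,
        alternative=alternative,
    )


def figure1_table(comparisons: list[CoverageComparison]) -> pd.DataFrame:
    """Long-format observed/expected report, one row per cover set.

    Suitable for plotting paired observed/expected bars per CNV set.
    """
    if not comparisons:
        raise ValueError("need at least one CoverageComparison")
    rows = []
    for c in comparisons:
        row = {
            "cover_set": c.cover_label,
            "n_targets": c.n_targets,
            "observed_count": c.observed_count,
            "expected_count": c.expected_count,
            "observed_feature_fraction": c.observed_feature_fraction,
            "observed_base_fraction": c.observed_base_fraction,
            "expected_base_fraction": c.expected_base_fraction,
            "fold": c.fold,
            "p_chisq": c.p_chisq,
            "p_binomial": c.p_binomial,
        }
        if c.permutation is not None:
            row["p_permutation_count"] = c.permutation.p_count
            row["p_permutation_base_fraction"] = c.permutation.p_base_fraction
        rows.append(row)
    return pd.DataFrame(rows)


class EnhancerDepletionModel:
    """Depletion of a cover set (CNVs) at target loci (enhancers).

    Parameters
    ----------
    targets : FeatureSet
        The loci tested for depletion (typically enhancers).
    cover : FeatureSet
        The variant set whose footprint is compared against the genome
        (CNVs, Indels, syndrome regions).
    assembly : GenomeAssembly, optional
        Required if neither feature set is bound to one.
    alternative : {"less", "greater", "two-sided"}
        Direction of the binomial/permutation alternative; "less" tests for
        depletion.

    Examples
    --------
    >>> model = EnhancerDepletionModel(enhancers, cnvs)       # doctest: +SKIP
    >>> res = model.fit(n_permutations=199, seed=1)           # doctest: +SKIP
    >>> print(res.summary())                                  # doctest: +SKIP
    """

    def __init__(
        self,
        targets: FeatureSet,
        cover: FeatureSet,
        assembly: GenomeAssembly | None = None,
        alternative: str = "less",
    ) -> None:
        self.targets = targets
        self.cover = cover
        self.assembly = assembly or targets.assembly or cover.assembly
        if self.assembly is None:
            raise ValueError("an assembly is required")
        if alternative not in ("less", "greater", "two-sided"):
            raise ValueError(f"unknown alternative {alternative!r}")
        self.alternative = alternative

    @classmethod
    def from_files(
        cls,
        targets_path: str | Path,
        cover_path: str | Path,
        chrom_sizes_path: str | Path,
        alternative: str = "less",
    ) -> "EnhancerDepletionModel":
        """Build a model from BED files and a chrom.sizes table."""
        assembly = read_chrom_sizes(chrom_sizes_path)
        targets = read_bed(targets_path, assembly=assembly, kind="enhancer")
        cover = read_bed(cover_path, assembly=assembly, kind="cnv")
        return cls(targets, cover, assembly=assembly, alternative=alternative)

    def fit(self, n_permutations: int = 0, seed: int | None = None) -> "DepletionResults":
        """Compute the comparison; optionally attach a permutation null."""
        comparison = depletion_statistic(
            self.targets, self.cover, self.assembly, self.alternative
        )
        if n_permutations > 0:
            comparison.permutation = permutation_null(
                self.targets,
                self.cover,
                self.assembly,
                n_permutations=n_permutations,
                seed=0 if seed is None else seed,
                alternative=self.alternative,
            )
        return DepletionResults(self, comparison)


class DepletionResults:
    """Fitted observed/expected comparison with tests and reporting."""

    def __init__(self, model: EnhancerDepletionModel, comparison: CoverageComparison):
        self.model = model
        self.comparison = comparison

    @property
    def fold(self) -> float:
        """Observed/expected ratio of base fractions; < 1 means depletion."""
        return self.comparison.fold

    @property
    def permutation(self) -> PermutationSummary | None:
        return self.comparison.permutation

    def to_frame(self) -> pd.DataFrame:
        return figure1_table([self.comparison])

    def summary(self) -> str:
        c = self.comparison
        lines = [
            "Enhancer copy-number depletion",
            "=" * 46,
            f"targets ({c.target_label}): {c.n_targets}",
            f"cover set: {c.cover_label}",
            f"genome coverage of cover set: {c.expected_base_fraction:.4%}",
            f"observed covered targets: {c.observed_count}"
            f" ({c.observed_feature_fraction:.4%})",
            f"expected covered targets: {c.expected_count:.1f}",
            f"observed target base fraction: {c.observed_base_fraction:.4%}",
            f"fold (observed/expected base fraction): {c.fold:.3f}",
            f"p (chi-square, 1 df, counts): {c.p_chisq:.3g}",
            f"p (exact binomial, {self.model.alternative}): {c.p_binomial:.3g}",
        ]
        if c.permutation is not None:
            perm = c.permutation
            lo, hi = perm.null_count_ci()
            lines += [
                f"permutations: {perm.n_permutations} (seed {perm.seed})",
                f"null covered-target count: mean {perm.null_mean_count:.1f},"
                f" 95% CI [{lo:.0f}, {hi:.0f}]",
                f"p (permutation, counts): {perm.p_count:.3g}",
                f"p (permutation, base fraction): {perm.p_base_fraction:.3g}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Paired observed/expected bars of feature and base fractions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        c = self.comparison
        x = np.arange(2)
        obs = [c.observed_feature_fraction, c.observed_base_fraction]
        exp = [c.expected_base_fraction, c.expected_base_fraction]
        width = 0.38
        ax.bar(x - width / 2, obs, width, color="0.6", label="observed")
        ax.bar(x + width / 2, exp, width, color="0.1", label="expected")
        ax.set_xticks(x)
        ax.set_xticklabels(["feature fraction", "base fraction"])
        ax.set_ylabel("fraction covered")
        ax.set_title(c.cover_label)
        ax.legend(frameon=False)
        return ax
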