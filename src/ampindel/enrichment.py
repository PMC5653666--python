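"""Two-sample chi-square test of proportions and the all-pairs comparison
grid between two treatment groups.

Each comparison tests whether the non-frameshift (NFS) fraction among mutant
reads is higher in a group-A sample than in a group-B sample. Significance
requires both p < alpha and the enrichment direction (NFS higher in A); no
continuity correction is applied by default and no multiple-testing
correction is performed across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from scipy.stats import chi2 as chi2_dist

from .errors import ConfigurationError


@dataclass(frozen=True)
class ProportionTable:
    """2x2 table: (NFS, FS) counts for sample A and sample B."""

    a: int  # NFS, sample A
    b: int  # FS, sample A
    c: int  # NFS, sample B
    d: int  # FS, sample B

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def testable(self) -> bool:
        """All four margins must be positive for the statistic to exist."""
        return (self.a + self.b > 0 and self.c + self.d > 0
                and self.a + self.c > 0 and self.b + self.d > 0)


@dataclass(frozen=True)
class EnrichmentResult:
    chi2: float
    df: int
    p: float
    direction: int  # sign of NFS_fraction(A) - NFS_fraction(B)
    significant: bool
    testable: bool = True


def chi2_proportions(table: ProportionTable, alpha: float = 0.05,
                     correction: bool = False) -> EnrichmentResult:
    """Pearson chi-square on the 2x2 table, df = 1, two-sided p.

    ``significant`` additionally requires NFS enrichment in sample A
    (direction > 0). Tables with an empty margin are returned untestable.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    a, b, c, d = table.a, table.b, table.c, table.d
    if not table.testable:
        return EnrichmentResult(chi2=0.0, df=1, p=1.0, direction=0,
                                significant=False, testable=False)
    n = a + b + c + d
    observed = ((a, b), (c, d))
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            expected = rows[i] * cols[j] / n
            diff = abs(observed[i][j] - expected)
            if correction:
                diff = max(diff - 0.5, 0.0)
            stat += diff * diff / expected
    p = float(chi2_dist.sf(stat, 1))
    frac_a = a / (a + b)
    frac_b = c / (c + d)
    direction = (frac_a > frac_b) - (frac_a < frac_b)
    significant = p < alpha and direction > 0
    return EnrichmentResult(chi2=stat, df=1, p=p, direction=direction,
                            significant=significant)


@dataclass(frozen=True)
class SampleCounts:
    sample_id: str
    nfs: int
    fs: int


@dataclass
class ComparisonRecord:
    sample_a: str
    sample_b: str
    table: ProportionTable
    result: EnrichmentResult


@dataclass
class PairwiseEnrichment:
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    results: list[ComparisonRecord] = field(default_factory=list)
    n_comparisons: int = 0
    n_significant: int = 0
    n_untestable: int = 0

    @property
    def fraction_significant(self) -> float:
        if self.n_comparisons == 0:
            return 0.0
        return self.n_significant / self.n_comparisons

    def verdict(self) -> str:
        return (f"NFS enriched in group A in {self.n_significant}/{self.n_comparisons} "
                f"comparisons ({100.0 * self.fraction_significant:.1f}%)")


def pairwise_enrichment(
    group_a: Sequence[SampleCounts],
    group_b: Sequence[SampleCounts],
    alpha: float = 0.05,
    correction: bool = False,
) -> PairwiseEnrichment:
    """Test every group-A sample against every group-B sample."""
    if not group_a or not group_b:
        raise ConfigurationError("both groups must contain at least one sample")
    grid = PairwiseEnrichment(
        group_a=tuple(s.sample_id for s in group_a),
        group_b=tuple(s.sample_id for s in group_b),
    )
    for sa in group_a:
        for sb in group_b:
            table = ProportionTable(sa.nfs, sa.fs, sb.nfs, sb.fs)
            result = chi2_proportions(table, alpha=alpha, correction=correction)
            grid.results.append(ComparisonRecord(sa.sample_id, sb.sample_id, table, result))
            grid.n_comparisons += 1
            if not result.testable:
                grid.n_untestable += 1
            elif result.significant:
                grid.n_significant += 1
    assert grid.n_comparisons == len(group_a) * len(group_b)
    return grid
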