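"""Asymmetric-introgression tests for pairwise species comparisons.

For each locality assigned to one species of a pair, the *foreign-allele
fraction* is the share of scored diagnostic alleles that belong to the
other species; *presence* is any foreign allele at all.  A moving hybrid
zone leaves foreign alleles of the receding species strewn through the
invader's range but not vice versa, so presence is compared between sides
with Fisher's exact test, and the fractions with a one-tailed
Mann-Whitney U test in the a-priori direction (introgression into the
putative invader is greater).  Localities carrying ancestry of a third
species are excluded beforehand so three-way gene flow cannot masquerade
as pairwise asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact, norm, rankdata

from .ancestry import LocalitySummary
from .core import MISSING, GenotypeMatrix, LocalityTable
from .markers import DiagnosticPanel

__all__ = [
    "IntrogressionRecord",
    "AsymmetryTestResult",
    "exclude_third_species",
    "introgression_table",
    "fisher_asymmetry",
    "mannwhitney_asymmetry",
]


@dataclass(frozen=True)
class IntrogressionRecord:
    locality_id: str
    side: str                   # species of the pair this locality belongs to
    foreign_present: bool
    foreign_fraction: float
    n_alleles_scored: int
    excluded: bool = False
    reason: str = ""


@dataclass
class AsymmetryTestResult:
    pair: tuple[str, str]
    fisher_p: Optional[float] = None
    fisher_table: Optional[tuple[tuple[int, int], tuple[int, int]]] = None
    U: Optional[float] = None
    U_greater_side: Optional[float] = None
    Z: Optional[float] = None
    mannwhitney_p: Optional[float] = None
    direction: str = ""
    exact: bool = False
    all_tied: bool = False
    n_per_side: Optional[dict[str, int]] = None


# ---------------------------------------------------------------------------
# exclusion of third-species-admixed localities
# ---------------------------------------------------------------------------

def exclude_third_species(
    localities: LocalityTable,
    summaries: Sequence[LocalitySummary],
    G: GenotypeMatrix,
    panel: DiagnosticPanel,
    adjacency: Mapping[str, Iterable[str]],
    pair: tuple[str, str],
) -> dict[str, str]:
    """Localities to drop from a pairwise comparison, with reasons.

    A locality is excluded when (a) a third species' mean ancestry exceeds
    the admixture threshold, or (b) it carries at least one allele
    diagnostic for a third species *and* a neighbouring Thiessen polygon
    is dominated by that species (low-frequency introgression corroborated
    by the neighbourhood).
    """
    if adjacency is None:
        raise ValueError("adjacency graph required for third-species exclusion")
    by_loc = {s.locality_id: s for s in summaries}
    dominant = {s.locality_id: s.dominant_species for s in summaries}
    all_species = set().union(*(s.mean_q.keys() for s in summaries)) if summaries else set()
    third = sorted(all_species - set(pair))
    out: dict[str, str] = {}
    if not third:
        return out
    for loc in localities.locality_ids:
        s = by_loc.get(loc)
        if s is None:
            continue
        # rule (a): clustering shows third-species ancestry over threshold
        over = [sp for sp in third if s.mean_q.get(sp, 0.0) > s.threshold]
        if over:
            out[loc] = f"third-species ancestry above threshold: {','.join(over)}"
            continue
        # rule (b): third-species diagnostic allele + third-species neighbour
        neighbours = set(adjacency.get(loc, ()))
        third_neigh = {dominant[n] for n in neighbours if n in dominant} & set(third)
        if not third_neigh:
            continue
        carried = set()
        for sp in third_neigh:
            for locus in panel.loci:
                if sp not in panel.alleles[locus]:
                    continue
                sp_allele = panel.species_allele(locus, sp)
                # allele must be exclusive to that third species
                if sp_allele in {
                    panel.alleles[locus][q] for q in panel.alleles[locus] if q != sp
                }:
                    continue
                alleles = G.alleles_at(locus, [
                    i for i in localities.individuals[loc] if i in G.individual_ids
                ])
                if sp_allele in alleles:
                    carried.add(sp)
                    break
        if carried:
            out[loc] = (
                "third-species diagnostic allele with third-species neighbour: "
                + ",".join(sorted(carried))
            )
    return out


# ---------------------------------------------------------------------------
# introgression records
# ---------------------------------------------------------------------------

def introgression_table(
    G: GenotypeMatrix,
    panel: DiagnosticPanel,
    localities: LocalityTable,
    dominant: Mapping[str, str],
    pair: tuple[str, str],
    excluded: Optional[Mapping[str, str]] = None,
) -> list[IntrogressionRecord]:
    """Per-locality foreign-allele presence and fraction for a species pair.

    A locality dominated by species X of the pair scores, over its
    individuals' diagnostic alleles, the fraction belonging to the *other*
    species of the pair.  Excluded localities are carried through flagged
    but take no part in the tests.
    """
    excluded = dict(excluded or {})
    focal, other = pair
    loci = [l for l in panel.loci if other in panel.alleles[l]]
    out = []
    for loc in localities.locality_ids:
        side = dominant.get(loc)
        if side not in pair:
            continue
        if loc in excluded:
            out.append(IntrogressionRecord(loc, side, False, 0.0, 0, True, excluded[loc]))
            continue
        foreign_allele_of = {
            l: panel.species_allele(l, other if side == focal else focal) for l in loci
        }
        own_or_foreign = {
            l: {panel.focal_allele(l), panel.species_allele(l, other)} for l in loci
        }
        foreign = scored = 0
        for iid in localities.individuals[loc]:
            if iid not in G.individual_ids:
                continue
            i = G.individual_ids.index(iid)
            for l in loci:
                j = G.locus_ids.index(l)
                a, b = G.calls[i][j]
                if a is MISSING:
                    continue
                for al in (a, b):
                    if al in own_or_foreign[l]:
                        scored += 1
                        if al == foreign_allele_of[l]:
                            foreign += 1
        if scored == 0:
            out.append(IntrogressionRecord(loc, side, False, 0.0, 0, True,
                                           "no scored diagnostic alleles"))
            continue
        frac = foreign / scored
        out.append(IntrogressionRecord(loc, side, frac > 0, frac, scored))
    return out


def _sides(records: Sequence[IntrogressionRecord]) -> dict[str, list[IntrogressionRecord]]:
    sides: dict[str, list[IntrogressionRecord]] = {}
    for r in records:
        if r.excluded:
            continue
        sides.setdefault(r.side, []).append(r)
    return sides


# ---------------------------------------------------------------------------
# Fisher's exact test on presence/absence
# ---------------------------------------------------------------------------

def fisher_asymmetry(records: Sequence[IntrogressionRecord]) -> AsymmetryTestResult:
    """Two-sided Fisher's exact test of foreign-allele presence by side."""
    sides = _sides(records)
    if len(sides) != 2:
        raise ValueError(f"need records on exactly 2 sides, got {sorted(sides)}")
    (sa, ra), (sb, rb) = sorted(sides.items())
    table = (
        (sum(r.foreign_present for r in ra), sum(not r.foreign_present for r in ra)),
        (sum(r.foreign_present for r in rb), sum(not r.foreign_present for r in rb)),
    )
    _, p = fisher_exact(table, alternative="two-sided")
    return AsymmetryTestResult(
        pair=(sa, sb), fisher_p=float(p), fisher_table=table,
        n_per_side={sa: len(ra), sb: len(rb)},
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U on the foreign-allele fractions
# ---------------------------------------------------------------------------

def _exact_u_sf(u_obs: float, n1: int, n2: int) -> float:
    """P(U1 >= u_obs) under the null, by enumeration of rank arrangements
    (no ties).  DP over the number of 'wins' of group 1 over group 2."""
    # f[m][u] = number of ways to choose m group-1 ranks among the first i
    # values with U statistic u
    max_u = n1 * n2
    f = np.zeros((n1 + 1, max_u + 1), dtype=float)
    f[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):
        for m in range(min(i, n1), 0, -1):
            wins = i - m  # group-2 values smaller than this group-1 value
            if wins > max_u:
                continue
            f[m, wins:] += f[m - 1, : max_u + 1 - wins]
    total = comb(n1 + n2, n1)
    u_lo = int(np.ceil(u_obs - 1e-9))
    return float(f[n1, u_lo:].sum() / total)


def mannwhitney_asymmetry(
    records: Sequence[IntrogressionRecord],
    greater_side: str,
) -> AsymmetryTestResult:
    """One-tailed Mann-Whitney U test that foreign-allele fractions on
    ``greater_side`` are stochastically greater than on the other side.

    Uses midranks for ties; p is exact (rank enumeration) when there are
    no ties and n1*n2 <= 400, otherwise a normal approximation with
    tie-corrected variance and continuity correction.  When every value is
    tied across both sides, p = 1 is reported with a flag.
    """
    sides = _sides(records)
    if len(sides) != 2:
        raise ValueError(f"need records on exactly 2 sides, got {sorted(sides)}")
    if greater_side not in sides:
        raise ValueError(f"{greater_side!r} is not a side of this comparison")
    other_side = next(s for s in sides if s != greater_side)
    xg = np.array([r.foreign_fraction for r in sides[greater_side]])
    xo = np.array([r.foreign_fraction for r in sides[other_side]])
    n1, n2 = len(xg), len(xo)
    combined = np.concatenate([xg, xo])
    ranks = rankdata(combined)
    u_g = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u_o = float(n1 * n2 - u_g)
    result = AsymmetryTestResult(
        pair=(greater_side, other_side),
        U=min(u_g, u_o),
        U_greater_side=u_g,
        direction=f"{greater_side} > {other_side}",
        n_per_side={greater_side: n1, other_side: n2},
    )
    if np.all(combined == combined[0]):
        result.mannwhitney_p = 1.0
        result.all_tied = True
        result.Z = 0.0
        return result
    has_ties = len(np.unique(combined)) < len(combined)
    # tie-corrected normal approximation (Z reported in all cases)
    N = n1 + n2
    _, t_counts = np.unique(combined, return_counts=True)
    tie_term = float(((t_counts**3 - t_counts).sum()) / (N * (N - 1)))
    var_u = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    mu_u = n1 * n2 / 2.0
    z = (u_g - mu_u - 0.5) / np.sqrt(var_u) if var_u > 0 else 0.0
    result.Z = float(z)
    if not has_ties and n1 * n2 <= 400:
        result.mannwhitney_p = _exact_u_sf(u_g, n1, n2)
        result.exact = True
    else:
        result.mannwhitney_p = float(norm.sf(z))
    return result
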