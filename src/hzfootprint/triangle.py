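"""Heterozygosity-versus-ancestry statistics and core/edge classification.

For a pairwise species comparison on diagnostic markers, each individual
is placed in the triangle plot by its ancestry S (fraction of alleles from
the focal parental species) and interclass heterozygosity H (fraction of
scored diagnostic loci heterozygous focal/other).  Pure parentals sit at
the bottom corners (1, 0) and (0, 0) and an F1 at the apex (0.5, 1); the
allele-count identity H <= 2 min(S, 1-S) bounds every genotype.

With fully diagnostic markers the maximum-likelihood ancestry and
interclass-heterozygosity estimates reduce exactly to these counting
forms, since every allele's parental origin is known.

Core/edge classification labels a locality *core* when every Thiessen
neighbour shares its genetically dominant species, *edge* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from .core import MISSING, GenotypeMatrix, LocalityTable
from .markers import DiagnosticPanel

__all__ = [
    "TriangleStats",
    "CoreEdgeLabel",
    "heterozygosity_ancestry",
    "locality_triangle_summary",
    "classify_core_edge",
]


@dataclass(frozen=True)
class TriangleStats:
    individual_id: str
    S: float            # ancestry: fraction of alleles from the focal species
    H: float            # interclass heterozygosity
    n_loci_scored: int
    locality_id: str = ""


@dataclass(frozen=True)
class CoreEdgeLabel:
    locality_id: str
    label: str          # "core" | "edge"
    dominant_species: str


def heterozygosity_ancestry(
    G: GenotypeMatrix,
    panel: DiagnosticPanel,
    pair: tuple[str, str],
) -> list[TriangleStats]:
    """Per-individual (S, H) for the species pair ``(focal, other)``.

    Only loci diagnostic for the pair are used; missing genotypes drop out
    of both numerator and denominator.  Individuals with no scored
    diagnostic locus are excluded with a warning.
    """
    focal, other = pair
    if panel.focal_species != focal:
        raise ValueError(
            f"panel is diagnostic for {panel.focal_species!r}, pair names {focal!r}"
        )
    loci = [
        (G.locus_ids.index(l), l)
        for l in panel.loci
        if l in G.locus_ids and other in panel.alleles[l]
    ]
    out = []
    for i, iid in enumerate(G.individual_ids):
        n_focal = n_het = scored = 0
        for j, locus in loci:
            a, b = G.calls[i][j]
            if a is MISSING:
                continue
            fa = panel.focal_allele(locus)
            oa = panel.species_allele(locus, other)
            scored += 1
            n_focal += (a == fa) + (b == fa)
            if {a, b} == {fa, oa}:
                n_het += 1
        if scored == 0:
            warnings.warn(f"individual {iid!r} has no scored diagnostic locus; excluded")
            continue
        S = n_focal / (2 * scored)
        H = n_het / scored
        assert H <= 2 * min(S, 1 - S) + 1e-9, "triangle constraint violated"
        out.append(TriangleStats(iid, S, H, scored))
    return out


def locality_triangle_summary(
    stats: Iterable[TriangleStats],
    localities: LocalityTable,
) -> dict[str, tuple[float, float]]:
    """Arithmetic mean (S, H) over the scored individuals of each locality."""
    by_ind = {t.individual_id: t for t in stats}
    out = {}
    for loc in localities.locality_ids:
        members = [by_ind[i] for i in localities.individuals[loc] if i in by_ind]
        if not members:
            continue
        out[loc] = (
            sum(t.S for t in members) / len(members),
            sum(t.H for t in members) / len(members),
        )
    return out


def classify_core_edge(
    locality_ids: Iterable[str],
    adjacency: Mapping[str, Iterable[str]],
    dominant: Mapping[str, str],
    isolated_is_core: bool = True,
) -> list[CoreEdgeLabel]:
    """Label localities core (all Thiessen neighbours share the dominant
    species) or edge (at least one neighbour differs).

    A locality with no neighbours is core by the vacuous reading of
    "only borders others with the same dominant species"; set
    ``isolated_is_core=False`` for the strict reading.
    """
    out = []
    for loc in locality_ids:
        if loc not in adjacency:
            raise ValueError(f"locality {loc!r} missing from adjacency graph")
        if loc not in dominant:
            raise ValueError(f"locality {loc!r} missing from dominant-species map")
        neighbours = list(adjacency[loc])
        if not neighbours:
            label = "core" if isolated_is_core else "edge"
        elif all(dominant[n] == dominant[loc] for n in neighbours):
            label = "core"
        else:
            label = "edge"
        out.append(CoreEdgeLabel(loc, label, dominant[loc]))
    return out
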