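"""Diagnostic markers, hybrid index, and mtDNA haplotype handling.

A locus is *diagnostic* when every species' reference panel is fixed for a
single allele (missing calls ignored) and the focal species' allele occurs
in no other species — then every allele's species origin is known and the
hybrid index is simply the proportion of focal alleles among scored
diagnostic alleles.

The mtDNA side mirrors a classic workflow: collapse aligned sequences into
haplotypes (an ``N`` matches anything), place them on a neighbour-joining
tree built from p-distances with site-resampling bootstrap, assign query
haplotypes to the species whose reference clade they nest in, and allocate
short internal fragments by matching them against the trimmed,
re-collapsed haplotype set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .core import MISSING, GenotypeMatrix, LocalityTable, ReferencePanel, SequenceSet

__all__ = [
    "UNASSIGNED",
    "AMBIGUOUS",
    "DiagnosticPanel",
    "HybridIndexTable",
    "HaplotypeSet",
    "find_diagnostic_markers",
    "hybrid_index",
    "individual_hybrid_index",
    "collapse_haplotypes",
    "p_distance_matrix",
    "build_nj_tree",
    "write_newick",
    "assign_haplotype_species",
    "assign_internal_fragment",
]

UNASSIGNED = "UNASSIGNED"
AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class DiagnosticPanel:
    """Loci with fixed allelic differences between the focal species and
    every other species, with the fixed allele per species."""

    focal_species: str
    alleles: Mapping[str, Mapping[str, str]]  # locus -> species -> fixed allele

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.alleles)

    def focal_allele(self, locus: str) -> str:
        return self.alleles[locus][self.focal_species]

    def species_allele(self, locus: str, species: str) -> str:
        return self.alleles[locus][species]

    def restrict(self, loci: Sequence[str]) -> "DiagnosticPanel":
        return DiagnosticPanel(
            self.focal_species, {l: dict(self.alleles[l]) for l in loci}
        )


@dataclass
class HybridIndexTable:
    """Mean hybrid index per locality: focal alleles / scored alleles."""

    focal_species: str
    h: dict[str, float]                 # locality -> hybrid index
    n_genotypes: dict[str, int]         # loci x individuals, missing excluded
    n_alleles: dict[str, int]
    undefined: tuple[str, ...] = ()     # localities with zero scored genotypes


@dataclass
class Haplotype:
    haplotype_id: str
    sequence: str
    multiplicity: int
    members: tuple[str, ...]
    species: str = UNASSIGNED


@dataclass
class HaplotypeSet:
    haplotypes: dict[str, Haplotype]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.haplotypes)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __getitem__(self, hid: str) -> Haplotype:
        return self.haplotypes[hid]

    def total_multiplicity(self) -> int:
        return sum(h.multiplicity for h in self.haplotypes.values())

    def as_sequence_set(self) -> SequenceSet:
        return SequenceSet({h.haplotype_id: h.sequence for h in self.haplotypes.values()})


# ---------------------------------------------------------------------------
# diagnostic markers and hybrid index
# ---------------------------------------------------------------------------

def find_diagnostic_markers(
    G: GenotypeMatrix, panel: ReferencePanel, focal_species: str
) -> DiagnosticPanel:
    """Find loci fixed within every species' reference panel with the focal
    allele absent from all other species."""
    if focal_species not in panel.members:
        raise ValueError(f"focal species {focal_species!r} not in reference panel")
    panel.validate_against(G)
    diagnostic: dict[str, dict[str, str]] = {}
    for locus in G.locus_ids:
        fixed: dict[str, str] = {}
        ok = True
        for sp in panel.species:
            alleles = set(G.alleles_at(locus, sorted(panel.members[sp])))
            if not alleles:
                warnings.warn(f"locus {locus!r}: all reference genotypes missing for {sp!r}; locus skipped")
                ok = False
                break
            if len(alleles) != 1:
                ok = False
                break
            fixed[sp] = next(iter(alleles))
        if not ok:
            continue
        focal_allele = fixed[focal_species]
        if any(fixed[sp] == focal_allele for sp in panel.species if sp != focal_species):
            continue
        diagnostic[locus] = fixed
    return DiagnosticPanel(focal_species, diagnostic)


def individual_hybrid_index(
    G: GenotypeMatrix, panel: DiagnosticPanel
) -> dict[str, tuple[Optional[float], int]]:
    """Per-individual hybrid index: (h, number of scored diagnostic
    genotypes); h is None when nothing was scored."""
    loci_idx = [(G.locus_ids.index(l), l) for l in panel.loci if l in G.locus_ids]
    out = {}
    for i, iid in enumerate(G.individual_ids):
        focal = scored = 0
        for j, locus in loci_idx:
            a, b = G.calls[i][j]
            if a is MISSING:
                continue
            scored += 1
            fa = panel.focal_allele(locus)
            focal += (a == fa) + (b == fa)
        out[iid] = (focal / (2 * scored) if scored else None, scored)
    return out


def hybrid_index(
    G: GenotypeMatrix, panel: DiagnosticPanel, localities: LocalityTable
) -> HybridIndexTable:
    """Mean hybrid index per locality over all scored diagnostic genotypes
    of its individuals (missing genotypes excluded from both counts)."""
    if not panel.loci:
        raise ValueError("empty diagnostic panel")
    loci_idx = [(G.locus_ids.index(l), l) for l in panel.loci if l in G.locus_ids]
    h, n_gen, n_all, undefined = {}, {}, {}, []
    for loc in localities.locality_ids:
        focal = scored = 0
        for iid in localities.individuals[loc]:
            if iid not in G.individual_ids:
                continue
            i = G.individual_ids.index(iid)
            for j, locus in loci_idx:
                a, b = G.calls[i][j]
                if a is MISSING:
                    continue
                scored += 1
                fa = panel.focal_allele(locus)
                focal += (a == fa) + (b == fa)
        n_gen[loc] = scored
        n_all[loc] = 2 * scored
        if scored == 0:
            undefined.append(loc)
        else:
            h[loc] = focal / (2 * scored)
    return HybridIndexTable(panel.focal_species, h, n_gen, n_all, tuple(undefined))


# ---------------------------------------------------------------------------
# haplotype collapsing
# ---------------------------------------------------------------------------

def _matches(a: str, b: str) -> bool:
    """True when two equal-length sequences agree at every position where
    neither carries an N."""
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


def collapse_haplotypes(S: SequenceSet) -> HaplotypeSet:
    """Collapse sequences identical at all unambiguous positions.

    Sequences are processed most-complete-first (fewest Ns, ties by id) so
    fully resolved sequences define the haplotypes; each remaining sequence
    joins the first haplotype it matches.  The canonical representative of
    a haplotype is its member with fewest Ns (ties by id sort), and the
    operation is idempotent.
    """
    order = sorted(S.ids, key=lambda sid: (S[sid].count("N"), sid))
    clusters: list[list[str]] = []
    for sid in order:
        seq = S[sid]
        for members in clusters:
            if _matches(seq, S[members[0]]):
                members.append(sid)
                break
        else:
            clusters.append([sid])
    haplos = {}
    for members in clusters:
        rep = min(members, key=lambda sid: (S[sid].count("N"), sid))
        haplos[rep] = Haplotype(rep, S[rep], len(members), tuple(sorted(members)))
    return HaplotypeSet(haplos)


# ---------------------------------------------------------------------------
# neighbour-joining tree and species assignment
# ---------------------------------------------------------------------------

def p_distance_matrix(S: SequenceSet, ids: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """Pairwise proportion of differing sites over positions where both
    sequences are unambiguous (no N, no gap)."""
    ids = list(ids) if ids is not None else list(S.ids)
    arr = np.array([list(S[sid]) for sid in ids])
    ok = (arr != "N") & (arr != "-")
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = ok[i] & ok[j]
            n_comp = int(comp.sum())
            if n_comp == 0:
                raise ValueError(f"sequences {ids[i]!r} and {ids[j]!r} share no comparable sites")
            mat[i, j] = mat[j, i] = float((arr[i][comp] != arr[j][comp]).sum()) / n_comp
    return DistanceMatrix(mat, ids)


def _splits(tree: TreeNode, taxa: frozenset[str], ref: str) -> set[frozenset[str]]:
    out = set()
    for node in tree.non_tips():
        below = frozenset(t.name for t in node.tips())
        if not 1 < len(below) < len(taxa) - 1:
            continue
        side = below if ref not in below else taxa - below
        out.add(side)
    return out


def build_nj_tree(
    S: SequenceSet,
    outgroup_ids: Sequence[str],
    bootstrap_n: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Neighbour-joining phylogeny from p-distances, rooted on the
    outgroup, with site-resampling bootstrap support per bipartition.

    Returns the rooted tree and a map from bipartition (the leaf set of an
    internal edge, canonicalized away from a reference taxon) to the
    fraction of bootstrap trees containing it.
    """
    if len(S) < 3:
        raise ValueError("need at least 3 sequences")
    missing_out = [o for o in outgroup_ids if o not in S.ids]
    if missing_out:
        raise ValueError(f"outgroups absent from sequence set: {missing_out}")
    taxa = frozenset(S.ids)
    ref = sorted(taxa)[0]

    tree = nj(p_distance_matrix(S))
    main_splits = _splits(tree, taxa, ref)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in main_splits}
    L = S.length
    ids = list(S.ids)
    base = np.array([list(S[sid]) for sid in ids])
    for _ in range(bootstrap_n):
        cols = rng.integers(0, L, size=L)
        boot = SequenceSet({sid: "".join(base[i][cols]) for i, sid in enumerate(ids)})
        try:
            btree = nj(p_distance_matrix(boot))
        except ValueError:
            continue
        for s in _splits(btree, taxa, ref) & set(counts):
            counts[s] += 1
    support = {s: c / bootstrap_n for s, c in counts.items()} if bootstrap_n else {}

    out_tip = tree.find(outgroup_ids[0])
    rooted = tree.root_at(out_tip.parent)
    return rooted, support


def write_newick(tree: TreeNode, path) -> None:
    """Write a tree in newick format."""
    tree.write(str(path), format="newick")


def assign_haplotype_species(
    H: HaplotypeSet,
    reference_species: Mapping[str, str],
    tree: TreeNode,
) -> HaplotypeSet:
    """Assign each query haplotype to the species of the smallest clade
    containing it together with references of exactly one species.

    ``reference_species`` maps reference haplotype ids (leaves of the
    tree) to species labels.  A query whose nearest reference-containing
    clade mixes species is AMBIGUOUS.
    """
    if not reference_species:
        raise ValueError("no reference haplotypes")
    leaf_names = {t.name for t in tree.tips()}
    out = {}
    for hid, hap in H.haplotypes.items():
        if hid in reference_species:
            out[hid] = Haplotype(hid, hap.sequence, hap.multiplicity, hap.members,
                                 reference_species[hid])
            continue
        if hid not in leaf_names:
            raise ValueError(f"query haplotype {hid!r} absent from tree")
        node = tree.find(hid)
        species = UNASSIGNED
        while node.parent is not None:
            node = node.parent
            found = {
                reference_species[t.name]
                for t in node.tips()
                if t.name in reference_species
            }
            if found:
                species = next(iter(found)) if len(found) == 1 else AMBIGUOUS
                break
        out[hid] = Haplotype(hid, hap.sequence, hap.multiplicity, hap.members, species)
    return HaplotypeSet(out)


def assign_internal_fragment(
    fragment: str,
    H: HaplotypeSet,
    window: tuple[int, int],
) -> str:
    """Allocate a short internal fragment to a species.

    Full-length assigned haplotypes are trimmed to the window and
    re-collapsed; the fragment is assigned iff every trimmed haplotype it
    matches belongs to a single species.  No match -> UNASSIGNED; matches
    spanning several species (or a trimmed haplotype that merged several
    species) -> AMBIGUOUS.
    """
    start, end = window
    fragment = fragment.upper()
    if len(fragment) != end - start:
        raise ValueError(f"fragment length {len(fragment)} does not fit window [{start}, {end})")
    trimmed = collapse_haplotypes(H.as_sequence_set().window(start, end))
    species_of_full = {hid: hap.species for hid, hap in H.haplotypes.items()}
    matched_species: set[str] = set()
    for hap in trimmed.haplotypes.values():
        if _matches(fragment, hap.sequence):
            matched_species |= {species_of_full[m] for m in hap.members}
    if not matched_species:
        return UNASSIGNED
    if len(matched_species) == 1:
        return next(iter(matched_species))
    return AMBIGUOUS
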