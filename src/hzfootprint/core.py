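"""Domain types shared by every stage of the pipeline.

The central objects are a diploid :class:`GenotypeMatrix` (individuals x
co-dominant nuclear loci, unordered allele pairs), a :class:`LocalityTable`
of sampling sites on a planar km grid, a :class:`ReferencePanel` of
presumed-pure individuals per species, and a :class:`SequenceSet` of aligned
mtDNA sequences.  All stages are pure functions of these inputs; nothing
mutates a matrix in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "LocalityTable",
    "ReferencePanel",
    "SequenceSet",
    "AnalysisConfig",
    "mean_individuals_per_locality",
    "isolation_to_dispersal_ratio",
]

#: Sentinel for a missing allele call.  Distinguishable from any allele
#: symbol because allele symbols are non-empty strings.
MISSING: None = None

_SEQ_ALPHABET = set("ACGTN-")


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid genotype calls for ``n`` individuals at ``L`` loci.

    ``calls[i][l]`` is an unordered pair ``(a, b)`` of allele symbols
    (opaque strings) or ``(MISSING, MISSING)`` when the genotype was not
    scored.  Pairs are stored sorted so that phase never leaks into
    comparisons.
    """

    individual_ids: tuple[str, ...]
    locus_ids: tuple[str, ...]
    calls: tuple[tuple[tuple[Optional[str], Optional[str]], ...], ...]
    ploidy: int = 2

    def __post_init__(self) -> None:
        n, L = len(self.individual_ids), len(self.locus_ids)
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicate locus ids")
        if len(self.calls) != n:
            raise ValueError(f"expected {n} rows of calls, got {len(self.calls)}")
        norm_rows = []
        for i, row in enumerate(self.calls):
            if len(row) != L:
                raise ValueError(
                    f"ragged genotype row for individual "
                    f"{self.individual_ids[i]!r}: {len(row)} loci, expected {L}"
                )
            norm_row = []
            for cell in row:
                a, b = cell
                if (a is MISSING) != (b is MISSING):
                    raise ValueError(
                        f"half-missing genotype for {self.individual_ids[i]!r}"
                    )
                if a is not MISSING and a > b:
                    a, b = b, a
                norm_row.append((a, b))
            norm_rows.append(tuple(norm_row))
        object.__setattr__(self, "calls", tuple(norm_rows))

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def row(self, individual_id: str) -> tuple[tuple[Optional[str], Optional[str]], ...]:
        return self.calls[self.individual_ids.index(individual_id)]

    def alleles_at(self, locus: str, individual_ids: Optional[Iterable[str]] = None) -> list[str]:
        """Observed (non-missing) alleles at ``locus``, optionally restricted
        to a subset of individuals."""
        j = self.locus_ids.index(locus)
        ids = self.individual_ids if individual_ids is None else tuple(individual_ids)
        out: list[str] = []
        for iid in ids:
            a, b = self.calls[self.individual_ids.index(iid)][j]
            if a is not MISSING:
                out.extend((a, b))
        return out

    def subset(self, individual_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individual_ids.index(i) for i in individual_ids]
        return GenotypeMatrix(
            tuple(individual_ids), self.locus_ids,
            tuple(self.calls[i] for i in idx),
        )

    def symbol_table(self) -> dict[str, tuple[str, ...]]:
        """Per-locus sorted allele alphabet, missing excluded."""
        table = {}
        for j, locus in enumerate(self.locus_ids):
            seen = set()
            for row in self.calls:
                a, b = row[j]
                if a is not MISSING:
                    seen.update((a, b))
            table[locus] = tuple(sorted(seen))
        return table

    def encode(self) -> tuple[np.ndarray, dict[str, tuple[str, ...]]]:
        """Integer-encode calls as an ``(n, L, 2)`` int32 array, ``-1`` for
        missing, alleles indexed into the per-locus symbol table."""
        table = self.symbol_table()
        lut = [
            {sym: k for k, sym in enumerate(table[locus])}
            for locus in self.locus_ids
        ]
        arr = np.full((self.n_individuals, self.n_loci, 2), -1, dtype=np.int32)
        for i, row in enumerate(self.calls):
            for j, (a, b) in enumerate(row):
                if a is not MISSING:
                    arr[i, j, 0] = lut[j][a]
                    arr[i, j, 1] = lut[j][b]
        return arr, table


@dataclass(frozen=True)
class LocalityTable:
    """Sampling localities on a planar km grid, each holding the ids of the
    1-3 individuals collected there."""

    locality_ids: tuple[str, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]
    individuals: Mapping[str, tuple[str, ...]]
    species_hint: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.locality_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locality ids")
        if not (len(self.x) == len(self.y) == len(ids)):
            raise ValueError("coordinate arrays must match locality ids")
        if not all(np.isfinite(self.x)) or not all(np.isfinite(self.y)):
            raise ValueError("non-finite coordinates")
        seen: set[str] = set()
        for loc in ids:
            for iid in self.individuals.get(loc, ()):
                if iid in seen:
                    raise ValueError(f"individual {iid!r} listed in two localities")
                seen.add(iid)

    @property
    def n_localities(self) -> int:
        return len(self.locality_ids)

    @property
    def individual_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for loc in self.locality_ids:
            out.extend(self.individuals[loc])
        return tuple(out)

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y]).astype(float)

    def locality_of(self) -> dict[str, str]:
        return {
            iid: loc for loc in self.locality_ids for iid in self.individuals[loc]
        }

    def position(self, locality_id: str) -> tuple[float, float]:
        i = self.locality_ids.index(locality_id)
        return self.x[i], self.y[i]

    def subset(self, locality_ids: Sequence[str]) -> "LocalityTable":
        idx = [self.locality_ids.index(l) for l in locality_ids]
        return LocalityTable(
            tuple(locality_ids),
            tuple(self.x[i] for i in idx),
            tuple(self.y[i] for i in idx),
            {l: tuple(self.individuals[l]) for l in locality_ids},
            {l: self.species_hint[l] for l in locality_ids if l in self.species_hint},
        )


@dataclass(frozen=True)
class ReferencePanel:
    """Reference individuals presumed pure for each species, used to call
    diagnostic loci and to anchor supervised clustering."""

    members: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "members",
            {sp: frozenset(ids) for sp, ids in dict(self.members).items()},
        )
        all_ids: set[str] = set()
        for sp, ids in self.members.items():
            if not ids:
                raise ValueError(f"empty reference panel for species {sp!r}")
            if all_ids & ids:
                raise ValueError("reference panels overlap between species")
            all_ids |= ids

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))

    def individual_ids(self) -> frozenset[str]:
        return frozenset().union(*self.members.values())

    def species_of(self, individual_id: str) -> Optional[str]:
        for sp, ids in self.members.items():
            if individual_id in ids:
                return sp
        return None

    def validate_against(self, G: GenotypeMatrix) -> None:
        missing = self.individual_ids() - set(G.individual_ids)
        if missing:
            raise ValueError(f"reference individuals absent from genotype matrix: {sorted(missing)}")


@dataclass(frozen=True)
class SequenceSet:
    """Aligned nucleotide sequences keyed by haplotype/individual id."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        seqs = {k: v.upper() for k, v in dict(self.sequences).items()}
        if not seqs:
            raise ValueError("empty sequence set")
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences of unequal length: {sorted(lengths)}")
        for sid, s in seqs.items():
            bad = set(s) - _SEQ_ALPHABET
            if bad:
                raise ValueError(f"invalid symbols {sorted(bad)} in sequence {sid!r}")
        object.__setattr__(self, "sequences", seqs)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]

    def window(self, start: int, end: int) -> "SequenceSet":
        """Trim all sequences to the half-open column window ``[start, end)``."""
        if not (0 <= start < end <= self.length):
            raise ValueError(f"window [{start}, {end}) outside alignment of length {self.length}")
        return SequenceSet({k: v[start:end] for k, v in self.sequences.items()})


@dataclass
class AnalysisConfig:
    """Explicit knobs for a full pipeline run; every threshold is recorded
    so runs are reproducible from the manifest alone."""

    seed: int = 0
    # clustering
    sweeps: int = 20_000
    burnin: int = 5_000
    thin: int = 10
    replicates: int = 3
    alpha: float = 1.0
    supervised: bool = True
    admixture_threshold: Optional[float] = None  # None -> derive from reference panel
    # spatial
    grid_resolution: int = 200
    clip_margin: float = 0.10
    # cline fitting
    restarts: int = 20
    # bootstrap (NJ trees)
    bootstrap_replicates: int = 1000
    # verdict conventions
    fisher_alpha: float = 0.01
    isolated_locality_is_core: bool = True

    def with_seed(self, seed: int) -> "AnalysisConfig":
        return replace(self, seed=seed)


# -- bookkeeping helpers -------------------------------------------------

def mean_individuals_per_locality(localities: LocalityTable) -> float:
    """Mean number of individuals sampled per locality."""
    counts = [len(localities.individuals[l]) for l in localities.locality_ids]
    if not counts:
        raise ValueError("empty locality table")
    return float(np.mean(counts))


def isolation_to_dispersal_ratio(distance_km: float, dispersal_km: float) -> float:
    """Ratio of an enclave's distance from the main range to the species'
    lifetime dispersal distance.

    A large ratio (>> 1) makes long-distance colonization implausible and
    favours the species-replacement origin of the enclave.
    """
    if dispersal_km <= 0:
        raise ValueError("dispersal distance must be positive")
    return float(distance_km) / float(dispersal_km)
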