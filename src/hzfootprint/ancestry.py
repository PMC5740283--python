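"""Bayesian admixture clustering and genepool-number selection.

A Gibbs sampler estimates, for each individual, the fraction of ancestry Q
derived from each of k genepools, under the admixture model with
independent per-population allele frequencies (symmetric Dirichlet(1)
prior) and a symmetric Dirichlet(alpha) prior on Q.  Model choice across k
uses the harmonic-style evidence estimate mean(lnL) - var(lnL)/2 on the
post-burn-in likelihood trace, fed into the Evanno delta-k second-difference
criterion.  Replicate runs are aligned over label switching by assignment
optimization, and per-locality summaries apply the admixture threshold
rule: the threshold is one minus the lowest own-species Q among reference
individuals, and a locality is admixed when two or more species exceed it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._gibbs import gibbs_admixture
from .core import GenotypeMatrix, LocalityTable, ReferencePanel

__all__ = [
    "AncestryMatrix",
    "KSelectionTable",
    "LocalitySummary",
    "run_admixture_sampler",
    "estimate_evidence",
    "evanno_delta_k",
    "align_replicates",
    "mean_ancestry",
    "admixture_threshold",
    "summarize_localities",
]


@dataclass
class AncestryMatrix:
    """Posterior-mean ancestry fractions for one sampler replicate."""

    individual_ids: tuple[str, ...]
    k: int
    Q: np.ndarray                       # (n, k), rows sum to 1
    loglik_trace: np.ndarray            # thinned data log-likelihood, all sweeps
    trace_sweeps: np.ndarray            # sweep index of each trace entry
    burnin: int
    replicate_id: int = 0
    column_labels: Optional[tuple[str, ...]] = None  # species per column if known

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.shape != (len(self.individual_ids), self.k):
            raise ValueError("Q shape does not match ids/k")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")

    @property
    def post_burnin_trace(self) -> np.ndarray:
        return self.loglik_trace[self.trace_sweeps >= self.burnin]

    def q_of(self, individual_id: str) -> np.ndarray:
        return self.Q[self.individual_ids.index(individual_id)]


@dataclass
class KSelectionTable:
    """Evanno delta-k summary across candidate genepool numbers."""

    ks: tuple[int, ...]
    mean_evidence: dict[int, float]
    sd_evidence: dict[int, float]
    delta_k: dict[int, float]           # interior k only
    best_k: int


@dataclass
class LocalitySummary:
    locality_id: str
    mean_q: dict[str, float]
    dominant_species: str
    admixed: bool
    threshold: float
    n_individuals: int = 0


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def run_admixture_sampler(
    G: GenotypeMatrix,
    k: int,
    iters: int = 20_000,
    burnin: int = 5_000,
    seed: int = 0,
    supervised: Optional[ReferencePanel] = None,
    alpha: float = 1.0,
    thin: int = 10,
    replicate_id: int = 0,
) -> AncestryMatrix:
    """Estimate ancestry fractions by Gibbs sampling.

    ``supervised`` pins reference individuals' allele origins to their
    species (species sorted alphabetically onto the first columns of Q);
    their Q is still sampled, so reference Q spread remains informative.
    Loci with no scored genotypes are dropped with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > G.n_individuals:
        raise ValueError(f"k={k} exceeds the number of individuals ({G.n_individuals})")
    if not iters > burnin >= 0:
        raise ValueError("need iters > burnin >= 0")

    alleles, table = G.encode()
    observed = (alleles[:, :, 0] >= 0).any(axis=0)
    if not observed.all():
        dropped = [G.locus_ids[j] for j in np.flatnonzero(~observed)]
        warnings.warn(f"dropping all-missing loci: {dropped}")
        alleles = alleles[:, observed, :]
    n_alleles = np.array(
        [len(table[G.locus_ids[j]]) for j in np.flatnonzero(observed)], dtype=np.int32
    )
    n_alleles = np.maximum(n_alleles, 1).astype(np.int32)

    fixed_pop = np.full(G.n_individuals, -1, dtype=np.int32)
    column_labels = None
    if supervised is not None:
        supervised.validate_against(G)
        species = supervised.species
        if len(species) > k:
            raise ValueError(f"k={k} smaller than the {len(species)} reference species")
        for si, sp in enumerate(species):
            for iid in supervised.members[sp]:
                fixed_pop[G.individual_ids.index(iid)] = si
        column_labels = tuple(species) + tuple(
            f"genepool{j + 1}" for j in range(len(species), k)
        )

    q_mean, trace, trace_sweeps, _ = gibbs_admixture(
        np.ascontiguousarray(alleles),
        n_alleles,
        k,
        float(alpha),
        int(iters),
        int(burnin),
        int(thin),
        fixed_pop,
        int(seed) & 0x7FFFFFFF,
    )
    # guard against accumulated float error on the simplex
    q_mean = q_mean / q_mean.sum(axis=1, keepdims=True)
    return AncestryMatrix(
        G.individual_ids, k, q_mean, trace, trace_sweeps, burnin,
        replicate_id=replicate_id, column_labels=column_labels,
    )


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------

def estimate_evidence(trace: Sequence[float]) -> float:
    """Model evidence proxy from a post-burn-in log-likelihood trace:
    ``mean(lnL) - var(lnL)/2`` (sample variance)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace must contain at least 2 post-burn-in values")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


def evanno_delta_k(evidence_by_k: Mapping[int, Sequence[float]]) -> KSelectionTable:
    """Second-difference criterion for the number of genepools.

    ``evidence_by_k`` maps each k to replicate evidence estimates.  For
    interior k, ``delta_k = |mean L(k+1) - 2 mean L(k) + mean L(k-1)| /
    sd(L(k))``; the k maximizing delta_k is reported.
    """
    ks = sorted(evidence_by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive k values")
    for k in ks:
        if len(evidence_by_k[k]) < 2:
            raise ValueError(f"need >= 2 replicates at k={k}")
    mean_L = {k: float(np.mean(evidence_by_k[k])) for k in ks}
    sd_L = {k: float(np.std(evidence_by_k[k], ddof=1)) for k in ks}
    delta = {}
    for k in ks[1:-1]:
        if sd_L[k] == 0.0:
            raise ValueError(
                f"zero replicate variance at k={k}: delta-k is undefined; "
                "run more replicates or perturb seeds"
            )
        delta[k] = abs(mean_L[k + 1] - 2.0 * mean_L[k] + mean_L[k - 1]) / sd_L[k]
    best = max(delta, key=lambda k: (delta[k], -k))
    return KSelectionTable(tuple(ks), mean_L, sd_L, delta, best)


# ---------------------------------------------------------------------------
# replicate alignment (label switching)
# ---------------------------------------------------------------------------

def align_replicates(replicates: Sequence[AncestryMatrix]) -> list[AncestryMatrix]:
    """Undo label switching across replicates.

    Each replicate's columns are permuted to maximize the summed
    column-wise dot product with the first replicate (optimal assignment).
    """
    if not replicates:
        return []
    ref = replicates[0]
    for r in replicates[1:]:
        if r.k != ref.k or r.individual_ids != ref.individual_ids:
            raise ValueError("replicates must share individuals and k")
    aligned = [ref]
    for r in replicates[1:]:
        score = ref.Q.T @ r.Q  # score[a, b] = dot(ref col a, rep col b)
        rows, cols = linear_sum_assignment(-score)
        perm = np.empty(ref.k, dtype=int)
        perm[rows] = cols
        aligned.append(
            AncestryMatrix(
                r.individual_ids, r.k, r.Q[:, perm], r.loglik_trace,
                r.trace_sweeps, r.burnin, replicate_id=r.replicate_id,
                column_labels=ref.column_labels,
            )
        )
    return aligned


def mean_ancestry(aligned: Sequence[AncestryMatrix]) -> AncestryMatrix:
    """Mean Q across aligned replicates."""
    if not aligned:
        raise ValueError("no replicates")
    ref = aligned[0]
    Q = np.mean([a.Q for a in aligned], axis=0)
    Q = Q / Q.sum(axis=1, keepdims=True)
    return AncestryMatrix(
        ref.individual_ids, ref.k, Q, ref.loglik_trace, ref.trace_sweeps,
        ref.burnin, replicate_id=-1, column_labels=ref.column_labels,
    )


# ---------------------------------------------------------------------------
# locality summaries and the admixture threshold rule
# ---------------------------------------------------------------------------

def _species_columns(am: AncestryMatrix, panel: ReferencePanel) -> dict[str, int]:
    if am.column_labels is not None:
        known = {sp: j for j, sp in enumerate(am.column_labels)}
        if set(panel.species) <= set(known):
            return {sp: known[sp] for sp in panel.species}
    # map each species to the column with highest mean Q over its references
    cols = {}
    for sp in panel.species:
        rows = [am.individual_ids.index(i) for i in sorted(panel.members[sp])]
        cols[sp] = int(np.argmax(am.Q[rows].mean(axis=0)))
    if len(set(cols.values())) != len(cols):
        raise ValueError("could not assign distinct Q columns to reference species")
    return cols


def admixture_threshold(am: AncestryMatrix, panel: ReferencePanel) -> float:
    """Threshold = 1 - (lowest own-species Q among reference individuals).

    Ancestry fractions above this value are treated as real admixture;
    below it they are within the noise observed in presumed-pure animals.
    """
    if not panel.members:
        raise ValueError("empty reference panel: threshold undefined")
    cols = _species_columns(am, panel)
    lowest = min(
        am.Q[am.individual_ids.index(iid), cols[sp]]
        for sp in panel.species
        for iid in sorted(panel.members[sp])
    )
    return float(1.0 - lowest)


def summarize_localities(
    am: AncestryMatrix,
    localities: LocalityTable,
    panel: ReferencePanel,
    threshold: Optional[float] = None,
) -> list[LocalitySummary]:
    """Per-locality mean Q, dominant species, and admixed flag.

    A locality is admixed when two or more species exceed the threshold
    (derived from the reference panel unless given explicitly).
    """
    if threshold is None:
        threshold = admixture_threshold(am, panel)
    cols = _species_columns(am, panel)
    out = []
    for loc in localities.locality_ids:
        members = [i for i in localities.individuals[loc] if i in am.individual_ids]
        if not members:
            continue
        rows = [am.individual_ids.index(i) for i in members]
        mean_q = {sp: float(am.Q[rows, j].mean()) for sp, j in cols.items()}
        dominant = max(mean_q, key=lambda sp: (mean_q[sp], sp))
        n_over = sum(1 for v in mean_q.values() if v > threshold)
        out.append(
            LocalitySummary(loc, mean_q, dominant, n_over >= 2, float(threshold), len(members))
        )
    return out
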