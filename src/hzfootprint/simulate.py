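"""Synthetic contact-zone and structured-population generators.

Two generators cover the two kinds of inputs the pipeline consumes:

* :func:`simulate_structured_populations` draws k diverged genepools under
  a Balding–Nichols model (ancestral frequency ~ Uniform(0.1, 0.9),
  population frequencies Beta-distributed around it with divergence F),
  for testing admixture clustering and genepool-number selection.

* :func:`simulate_contact_zone` lays localities across a two-species
  contact front on a planar km grid.  The focal species' allele frequency
  follows a sigmoid cline of width ``w`` centred on the front.  In a
  *moving* scenario the front has advanced from ``x0`` to ``x1`` and the
  invaded strip carries a wake of focal alleles decaying exponentially
  behind the front — the genomic footprint of hybrid zone movement.  An
  optional enclave disc keeps a pure focal population surviving deep in
  the invaded range, and the mtDNA contact front can lag behind the
  nuclear one.

Every draw flows from a single seed; identical scenarios reproduce
byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import GenotypeMatrix, LocalityTable, ReferencePanel, SequenceSet
from .io import write_genotype_table, write_locality_table

#: Lifetime dispersal distance (km) reported for crested newts; the ratio
#: of enclave distance to this sets how implausible long-distance
#: colonization is as an origin for the enclave.
NEWT_LIFETIME_DISPERSAL_KM = 3.7

__all__ = [
    "NEWT_LIFETIME_DISPERSAL_KM",
    "StructuredPopScenario",
    "ZoneScenario",
    "ZoneSimulation",
    "simulate_structured_populations",
    "simulate_contact_zone",
    "focal_frequency",
    "mtdna_frequency",
    "generate_mtdna_sequences",
    "write_fixture_bundle",
]


# ---------------------------------------------------------------------------
# structured populations (clustering fixtures)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructuredPopScenario:
    """k diverged genepools with Balding–Nichols divergence ``fst``."""

    k_true: int = 4
    fst: float = 0.3
    n_loci: int = 50
    n_per_pop: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        if self.k_true * self.n_per_pop == 0:
            raise ValueError("scenario generates zero individuals")


def simulate_structured_populations(
    scn: StructuredPopScenario,
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Simulate genotypes for ``k_true`` diverged populations.

    Returns the genotype matrix and a truth map individual id -> population
    label (``pop1`` ... ``popk``).
    """
    rng = np.random.default_rng(scn.seed)
    k, L, n = scn.k_true, scn.n_loci, scn.n_per_pop
    p_anc = rng.uniform(0.1, 0.9, size=L)
    if scn.fst == 0:
        pop_freq = np.tile(p_anc, (k, 1))
    else:
        ratio = (1 - scn.fst) / scn.fst
        pop_freq = rng.beta(p_anc * ratio, (1 - p_anc) * ratio, size=(k, L))
    individual_ids, calls, labels = [], [], {}
    for pop in range(k):
        for i in range(n):
            iid = f"pop{pop + 1}_ind{i + 1}"
            labels[iid] = f"pop{pop + 1}"
            n_a = rng.binomial(2, pop_freq[pop])  # copies of allele "A"
            row = []
            for c in n_a:
                row.append(tuple(["A"] * c + ["B"] * (2 - c)))
            individual_ids.append(iid)
            calls.append(tuple(row))
    locus_ids = tuple(f"L{j + 1}" for j in range(L))
    return GenotypeMatrix(tuple(individual_ids), locus_ids, tuple(calls)), labels


# ---------------------------------------------------------------------------
# contact zones
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZoneScenario:
    """A pairwise contact-zone window between a focal species and one
    neighbour.

    Geometry is planar km.  The focal species occupies high ``x``; a
    *moving* scenario means the neighbour advanced from ``x0`` (old front)
    to ``x1`` (current front), claiming the strip in between and leaving a
    wake of focal alleles of amplitude ``wake_amplitude`` decaying with
    length ``wake_lambda`` behind the front.  ``mtdna_lag`` displaces the
    mtDNA front relative to the nuclear one (negative values push it into
    the invaded range, the lag expected when nuclear clines re-centre
    faster than maternally inherited markers).
    """

    scenario: str = "stable"                # "stable" | "moving"
    x1: float = 0.0                         # current front (km)
    x0: Optional[float] = None              # initial front; x1 when stable
    cline_width: float = 30.0               # sigmoid width w (km)
    wake_amplitude: float = 0.3             # A in (0, 1]
    wake_lambda: float = 40.0               # decay length (km)
    enclave_center: Optional[tuple[float, float]] = None
    enclave_radius: float = 8.0
    n_loci_diagnostic: int = 23
    n_loci_nondiagnostic: int = 29
    n_localities: int = 60
    window: tuple[float, float] = (-100.0, 100.0)
    y_extent: float = 40.0
    mtdna_lag: float = -25.0
    n_ref_localities: int = 5
    ref_individuals_per_locality: int = 3
    focal_species: str = "blue"
    other_species: str = "green"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("stable", "moving"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "stable":
            object.__setattr__(self, "x0", self.x1 if self.x0 is None else self.x0)
            if self.x0 != self.x1:
                raise ValueError("stable scenario requires x0 == x1")
        else:
            if self.x0 is None or not self.x0 < self.x1:
                raise ValueError("moving scenario requires x0 < x1")
        if self.wake_lambda <= 0:
            raise ValueError("wake_lambda must be positive")
        if not 0 < self.wake_amplitude <= 1:
            raise ValueError("wake_amplitude must be in (0, 1]")
        if self.cline_width <= 0:
            raise ValueError("cline_width must be positive")
        if self.enclave_center is not None:
            ex = self.enclave_center[0]
            if ex + self.enclave_radius >= self.x1:
                raise ValueError("enclave must lie strictly behind the front")
            if self.scenario == "moving" and ex - self.enclave_radius <= self.x0:
                raise ValueError("enclave must lie inside the invaded strip (x0, x1)")

    @property
    def enclave_distance(self) -> float:
        """Distance (km) from the enclave centre to the current front."""
        if self.enclave_center is None:
            raise ValueError("scenario has no enclave")
        return self.x1 - self.enclave_center[0]

    @classmethod
    def stable(cls, seed: int = 0, **kw) -> "ZoneScenario":
        """Stable contact zone with an enclave 83 km behind the front —
        the colonization (leapfrog) hypothesis."""
        kw.setdefault("enclave_center", (-83.0, 20.0))
        return cls(scenario="stable", seed=seed, **kw)

    @classmethod
    def moving(cls, seed: int = 0, **kw) -> "ZoneScenario":
        """Front advanced 100 km (x0 = -100 to x1 = 0) leaving a wake,
        with a relict enclave 83 km behind — the species-replacement
        hypothesis."""
        kw.setdefault("x0", -100.0)
        kw.setdefault("enclave_center", (-83.0, 20.0))
        return cls(scenario="moving", seed=seed, **kw)


def _sigmoid_cline(x: np.ndarray, centre: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-4.0 * (x - centre) / width))


def _field(x, y, scn: ZoneScenario, centre: float, enclave: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = _sigmoid_cline(x, centre, scn.cline_width)
    if scn.scenario == "moving":
        lo, hi = scn.x0 + (centre - scn.x1), centre
        in_wake = (x > lo) & (x < hi)
        p = p + np.where(in_wake, scn.wake_amplitude * np.exp(-(hi - x) / scn.wake_lambda), 0.0)
    p = np.clip(p, 0.0, 1.0)
    if enclave and scn.enclave_center is not None:
        ex, ey = scn.enclave_center
        inside = (x - ex) ** 2 + (y - ey) ** 2 <= scn.enclave_radius**2
        p = np.where(inside, 1.0, p)
    return p


def focal_frequency(x, y, scn: ZoneScenario) -> np.ndarray:
    """Closed-form expected focal-allele frequency at planar position(s).

    Sigmoid cline centred on the current front, plus — in moving scenarios —
    an exponential wake over the invaded strip, with the enclave disc held
    at the pure focal value.
    """
    return _field(x, y, scn, centre=scn.x1, enclave=True)


def mtdna_frequency(x, y, scn: ZoneScenario) -> np.ndarray:
    """Closed-form probability of carrying focal-species mtDNA: the same
    field with the front displaced by ``mtdna_lag``."""
    return _field(x, y, scn, centre=scn.x1 + scn.mtdna_lag, enclave=True)


@dataclass
class ZoneSimulation:
    """Bundle returned by :func:`simulate_contact_zone`."""

    scenario: ZoneScenario
    genotypes: GenotypeMatrix
    localities: LocalityTable
    reference_panel: ReferencePanel
    mtdna_labels: dict[str, str]            # individual id -> species label
    truth: dict = field(default_factory=dict)

    @property
    def diagnostic_loci(self) -> tuple[str, ...]:
        return tuple(self.truth["diagnostic_loci"])


def simulate_contact_zone(scn: ZoneScenario) -> ZoneSimulation:
    """Simulate a pairwise contact-zone dataset.

    Localities are scattered uniformly over the window (with jitter);
    each holds 1–3 individuals.  Diagnostic loci are biallelic with the
    focal allele ``A`` fixed in the focal species and ``B`` in the
    neighbour; genotypes are Binomial(2, p(x, y)) draws from the closed
    form field.  Non-diagnostic loci segregate everywhere at a shared
    frequency.  Reference localities for both species are planted at
    least 3 wake-lengths beyond the front on either side.
    """
    rng = np.random.default_rng(scn.seed)
    xmin, xmax = scn.window

    # sampled localities on a jittered 3-row quasi-grid: even coverage in
    # both axes so the interpolated 0.5 contour can track the front
    n_rows = 3
    n_cols = int(np.ceil(scn.n_localities / n_rows))
    dx = (xmax - xmin) / n_cols
    dy = scn.y_extent / n_rows
    idx = np.arange(scn.n_localities)
    cols, rows = idx // n_rows, idx % n_rows
    loc_x = np.clip(
        xmin + (cols + 0.5) * dx + rng.uniform(-0.4 * dx, 0.4 * dx, scn.n_localities),
        xmin, xmax,
    )
    loc_y = np.clip(
        (rows + 0.5) * dy + rng.uniform(-0.4 * dy, 0.4 * dy, scn.n_localities),
        0.0, scn.y_extent,
    )

    # make sure the enclave is actually sampled
    if scn.enclave_center is not None:
        ex, ey = scn.enclave_center
        d2 = (loc_x - ex) ** 2 + (loc_y - ey) ** 2
        if not np.any(d2 <= scn.enclave_radius**2):
            i = int(np.argmin(np.abs(loc_x - ex)))
            loc_x[i], loc_y[i] = ex, ey

    locality_ids = [f"loc{i + 1:03d}" for i in range(scn.n_localities)]
    n_per_loc = rng.choice([1, 2, 3], size=scn.n_localities, p=[0.10, 0.15, 0.75])

    # reference localities beyond 3 wake-lengths of either range core
    margin = 3.0 * scn.wake_lambda
    ref_rows = []
    for side, sp in ((+1, scn.focal_species), (-1, scn.other_species)):
        base = scn.x1 + margin if side > 0 else (scn.x0 - margin)
        for r in range(scn.n_ref_localities):
            rx = base + side * (10.0 + 15.0 * r)
            ry = rng.uniform(0.0, scn.y_extent)
            ref_rows.append((f"ref_{sp}_{r + 1}", rx, ry, sp))

    all_ids = list(locality_ids) + [r[0] for r in ref_rows]
    all_x = list(loc_x) + [r[1] for r in ref_rows]
    all_y = list(loc_y) + [r[2] for r in ref_rows]
    hints = {r[0]: r[3] for r in ref_rows}

    individuals: dict[str, tuple[str, ...]] = {}
    ind_ids: list[str] = []
    ind_x: list[float] = []
    ind_y: list[float] = []
    for i, loc in enumerate(locality_ids):
        members = tuple(f"{loc}_i{j + 1}" for j in range(n_per_loc[i]))
        individuals[loc] = members
        ind_ids.extend(members)
        ind_x.extend([all_x[i]] * len(members))
        ind_y.extend([all_y[i]] * len(members))
    panel_members: dict[str, set[str]] = {scn.focal_species: set(), scn.other_species: set()}
    for k, (loc, rx, ry, sp) in enumerate(ref_rows):
        members = tuple(f"{loc}_i{j + 1}" for j in range(scn.ref_individuals_per_locality))
        individuals[loc] = members
        ind_ids.extend(members)
        ind_x.extend([rx] * len(members))
        ind_y.extend([ry] * len(members))
        panel_members[sp].update(members)

    localities = LocalityTable(tuple(all_ids), tuple(all_x), tuple(all_y), individuals, hints)
    panel = ReferencePanel({sp: frozenset(ids) for sp, ids in panel_members.items()})

    # genotypes
    px = np.asarray(ind_x)
    py = np.asarray(ind_y)
    p_focal = focal_frequency(px, py, scn)
    diag_loci = tuple(f"D{j + 1:02d}" for j in range(scn.n_loci_diagnostic))
    nd_loci = tuple(f"N{j + 1:02d}" for j in range(scn.n_loci_nondiagnostic))
    nd_freq = rng.uniform(0.2, 0.8, size=scn.n_loci_nondiagnostic)

    n_ind = len(ind_ids)
    n_a_diag = rng.binomial(2, p_focal[:, None], size=(n_ind, scn.n_loci_diagnostic))
    n_a_nd = rng.binomial(2, nd_freq[None, :], size=(n_ind, scn.n_loci_nondiagnostic))
    calls = []
    for i in range(n_ind):
        row = [("A",) * c + ("B",) * (2 - c) for c in n_a_diag[i]]
        row += [("A",) * c + ("B",) * (2 - c) for c in n_a_nd[i]]
        calls.append(tuple(row))
    G = GenotypeMatrix(tuple(ind_ids), diag_loci + nd_loci, tuple(calls))

    # mtDNA labels from the lagged field
    p_mt = mtdna_frequency(px, py, scn)
    is_focal_mt = rng.random(n_ind) < p_mt
    mtdna = {
        iid: (scn.focal_species if f else scn.other_species)
        for iid, f in zip(ind_ids, is_focal_mt)
    }

    truth = {
        "scenario": asdict(scn),
        "diagnostic_loci": list(diag_loci),
        "nondiagnostic_loci": list(nd_loci),
        "locality_true_frequency": {
            loc: float(focal_frequency(all_x[i], all_y[i], scn))
            for i, loc in enumerate(all_ids)
        },
        "individual_positions": {
            iid: (float(ind_x[i]), float(ind_y[i])) for i, iid in enumerate(ind_ids)
        },
    }
    return ZoneSimulation(scn, G, localities, panel, mtdna, truth)


# ---------------------------------------------------------------------------
# mtDNA sequences
# ---------------------------------------------------------------------------

def generate_mtdna_sequences(
    labels: dict[str, str],
    species: tuple[str, ...],
    length: int = 658,
    diff_every: int = 20,
    seed: int = 0,
) -> tuple[SequenceSet, dict[str, str]]:
    """Simulate species-diagnostic mtDNA haplotypes.

    A random backbone sequence is mutated so each species carries a
    distinctive base at every ``diff_every``-th site, giving fixed
    interspecific differences.  All individuals of a species share that
    haplotype.  Returns the per-individual sequences plus the species
    haplotypes themselves.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    backbone = rng.choice(bases, size=length)
    haplos = {}
    for i, sp in enumerate(species):
        seq = backbone.copy()
        for pos in range(0, length, diff_every):
            seq[pos] = bases[(int(np.where(bases == backbone[pos])[0][0]) + i) % 4]
        haplos[sp] = "".join(seq)
    per_ind = {iid: haplos[sp] for iid, sp in labels.items()}
    return SequenceSet(per_ind), haplos


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------

def write_fixture_bundle(sim: ZoneSimulation, out_dir, force: bool = False) -> None:
    """Write a simulation as a directory of plain-text files.

    ``genotypes.csv`` + ``localities.csv`` re-read through the I/O layer
    reproduce the in-memory objects exactly; ``truth.json`` carries the
    generating field so any downstream stage can be checked against the
    closed form; ``manifest.json`` records the scenario and seed.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (pass force=True to overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    write_genotype_table(sim.genotypes, out / "genotypes.csv", dialect="csv")
    write_locality_table(sim.localities, out / "localities.csv")
    with open(out / "mtdna_labels.csv", "w") as fh:
        fh.write("individual_id,mtdna_species\n")
        for iid in sim.genotypes.individual_ids:
            fh.write(f"{iid},{sim.mtdna_labels[iid]}\n")
    with open(out / "reference_panel.json", "w") as fh:
        json.dump({sp: sorted(ids) for sp, ids in sim.reference_panel.members.items()}, fh, indent=1)
    with open(out / "truth.json", "w") as fh:
        json.dump(sim.truth, fh, indent=1, sort_keys=True)
    manifest = {"scenario": asdict(sim.scenario), "seed": sim.scenario.seed}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
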