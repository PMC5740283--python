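"""Readers and writers for the formats the pipeline touches.

Genotypes come in two dialects: a comma-separated table with two columns
per locus (``<locus>.1``, ``<locus>.2``), and the classic two-row-per-
individual whitespace layout used by Structure, where ``-9`` (or another
declared code) marks a missing allele.  Sequences are plain FASTA.  All
result tables are CSV with a header row, fixed float precision and a
deterministic row order, so repeated runs produce byte-identical files.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import MISSING, GenotypeMatrix, LocalityTable, SequenceSet

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_fasta",
    "write_fasta",
    "read_locality_table",
    "write_locality_table",
    "write_results_table",
]

DEFAULT_MISSING_CODES = ("", "NA", "N/A", "?", "-9", ".")

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised when an input file violates its dialect."""


def _normalize(symbol: str, missing_codes: Sequence[str]):
    symbol = symbol.strip()
    return MISSING if symbol in missing_codes else symbol


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotype_table(
    path: PathLike,
    dialect: str = "csv",
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
) -> GenotypeMatrix:
    """Read a diploid genotype table.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"csv"`` for the two-column-per-locus CSV layout, or
        ``"structure"`` for the two-row-per-individual layout.
    missing_codes:
        Symbols normalized to the MISSING sentinel.  The set is exposed
        because missing-data conventions vary between marker panels.
    """
    path = Path(path)
    if dialect == "csv":
        return _read_genotype_csv(path, missing_codes)
    if dialect == "structure":
        return _read_genotype_structure(path, missing_codes)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_genotype_csv(path: Path, missing_codes: Sequence[str]) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 3 or (len(header) - 1) % 2:
        raise ParseError(f"{path}: header must be individual_id plus two columns per locus")
    locus_ids = []
    for j in range(1, len(header), 2):
        a, b = header[j], header[j + 1]
        la, lb = a.rsplit(".", 1)[0], b.rsplit(".", 1)[0]
        if la != lb:
            raise ParseError(f"{path}: columns {a!r}/{b!r} do not form a locus pair")
        locus_ids.append(la)
    individual_ids, calls = [], []
    for ln, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise ParseError(f"{path}: line {ln}: {len(row)} fields, expected {len(header)}")
        individual_ids.append(row[0])
        cells = []
        for j in range(1, len(row), 2):
            a = _normalize(row[j], missing_codes)
            b = _normalize(row[j + 1], missing_codes)
            if (a is MISSING) != (b is MISSING):
                raise ParseError(f"{path}: line {ln}: half-missing genotype in columns {j + 1}-{j + 2}")
            cells.append((a, b))
        calls.append(tuple(cells))
    return GenotypeMatrix(tuple(individual_ids), tuple(locus_ids), tuple(calls))


def _read_genotype_structure(path: Path, missing_codes: Sequence[str]) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    body_width = len(lines[-1])
    if len(lines[0]) == body_width - 1:
        locus_ids = tuple(lines[0])
        lines = lines[1:]
    else:
        locus_ids = tuple(f"L{j + 1}" for j in range(body_width - 1))
    L = len(locus_ids)
    if len(lines) % 2:
        raise ParseError(f"{path}: odd number of allele rows ({len(lines)})")
    individual_ids, calls = [], []
    for r in range(0, len(lines), 2):
        top, bot = lines[r], lines[r + 1]
        if len(top) != L + 1 or len(bot) != L + 1:
            raise ParseError(
                f"{path}: rows {r + 1}/{r + 2}: expected {L + 1} fields, "
                f"got {len(top)}/{len(bot)}"
            )
        if top[0] != bot[0]:
            raise ParseError(f"{path}: rows {r + 1}/{r + 2}: individual ids differ ({top[0]!r} vs {bot[0]!r})")
        individual_ids.append(top[0])
        cells = []
        for j in range(L):
            a = _normalize(top[j + 1], missing_codes)
            b = _normalize(bot[j + 1], missing_codes)
            if (a is MISSING) != (b is MISSING):
                raise ParseError(f"{path}: individual {top[0]!r}, locus {locus_ids[j]!r}: half-missing genotype")
            cells.append((a, b))
        calls.append(tuple(cells))
    return GenotypeMatrix(tuple(individual_ids), locus_ids, tuple(calls))


def write_genotype_table(
    G: GenotypeMatrix, path: PathLike, dialect: str = "csv", missing_code: str = "-9"
) -> None:
    path = Path(path)
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["individual_id"]
            for locus in G.locus_ids:
                header += [f"{locus}.1", f"{locus}.2"]
            w.writerow(header)
            for iid, row in zip(G.individual_ids, G.calls):
                out = [iid]
                for a, b in row:
                    out += [missing_code if a is MISSING else a,
                            missing_code if b is MISSING else b]
                w.writerow(out)
    elif dialect == "structure":
        with open(path, "w") as fh:
            fh.write(" ".join(G.locus_ids) + "\n")
            for iid, row in zip(G.individual_ids, G.calls):
                for k in range(2):
                    alleles = [missing_code if cell[k] is MISSING else cell[k] for cell in row]
                    fh.write(" ".join([iid, *alleles]) + "\n")
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> SequenceSet:
    """Read an aligned FASTA file into a :class:`SequenceSet`.

    Duplicate headers and empty files are errors; sequences are upper-cased.
    """
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate FASTA header {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return SequenceSet(records)


def write_fasta(S: SequenceSet, path: PathLike) -> None:
    recs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in S.sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# localities
# ---------------------------------------------------------------------------

def read_locality_table(path: PathLike) -> LocalityTable:
    df = pd.read_csv(path, dtype={"locality_id": str, "individual_ids": str})
    required = {"locality_id", "x", "y", "individual_ids"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    individuals = {}
    hints = {}
    for _, row in df.iterrows():
        individuals[row["locality_id"]] = tuple(str(row["individual_ids"]).split(";"))
        if "species_hint" in df.columns and pd.notna(row.get("species_hint")):
            hints[row["locality_id"]] = str(row["species_hint"])
    return LocalityTable(
        tuple(df["locality_id"]),
        tuple(float(v) for v in df["x"]),
        tuple(float(v) for v in df["y"]),
        individuals,
        hints,
    )


def write_locality_table(localities: LocalityTable, path: PathLike) -> None:
    rows = []
    for loc in localities.locality_ids:
        x, y = localities.position(loc)
        rows.append({
            "locality_id": loc,
            "x": f"{x:.6f}",
            "y": f"{y:.6f}",
            "individual_ids": ";".join(localities.individuals[loc]),
            "species_hint": localities.species_hint.get(loc, ""),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# generic results tables
# ---------------------------------------------------------------------------

def write_results_table(
    records: Iterable[Mapping[str, object]],
    path: PathLike,
    float_precision: int = 6,
    sort_key: Optional[str] = None,
    fieldnames: Optional[Sequence[str]] = None,
) -> None:
    """Write records sharing one schema as a deterministic CSV.

    Rows are sorted by ``sort_key`` (default: the first column), floats are
    formatted at fixed precision, and two runs on equal input produce
    byte-identical files.  ``fieldnames`` supplies the header when the
    record list is empty.
    """
    records = [dict(r) for r in records]
    path = Path(path)
    if not records:
        if fieldnames is None:
            raise ValueError("empty record list requires explicit fieldnames")
        with open(path, "w", newline="") as fh:
            csv.DictWriter(fh, fieldnames=list(fieldnames)).writeheader()
        return
    schema = list(records[0].keys())
    for r in records[1:]:
        if list(r.keys()) != schema:
            raise ValueError(f"mixed record schemas: {schema} vs {list(r.keys())}")
    key = sort_key if sort_key is not None else schema[0]
    records.sort(key=lambda r: str(r[key]))
    fmt = f"{{:.{float_precision}f}}"
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=schema)
        w.writeheader()
        for r in records:
            w.writerow({
                k: (fmt.format(v) if isinstance(v, float) else v)
                for k, v in r.items()
            })
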