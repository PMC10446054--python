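"""Genotype and plant-metadata containers, file dialects, and QC filters.

The central object is :class:`GenotypeTable`: individuals × microsatellite
loci, two integer allele calls (fragment lengths) per locus, with a distinct
missing state. Allele pairs are unordered; the table stores them sorted so
that equality and duplicate detection are well defined.

Two on-disk dialects are supported:

* a plain CSV with columns ``id, <locus>.1, <locus>.2, ...`` (missing = NA);
* a whitespace ``.dat`` dialect modeled on the input format of pedigree
  software for codominant markers: a header line ``<npops> <nloci> / <title>``,
  one ``<count> <name>`` line per population, then one row per individual of
  the form ``id birth death a/b a/b ...`` with ``?/?`` for missing loci.

QC follows the field-survey convention for marker panels: loci with too much
missing data are dropped first, then individuals are re-evaluated against the
surviving loci, both with a *strict* "less than" threshold.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel allele value for a missing call. A missing locus has both
#: alleles equal to MISSING; partially missing calls are promoted to fully
#: missing on construction (a single microsatellite peak is not a genotype).
MISSING: int = -9


class GenotypeParseError(ValueError):
    """Raised on malformed genotype input, with the offending line number."""


@dataclass
class GenotypeTable:
    """Individuals × loci table of unordered allele pairs.

    Parameters
    ----------
    ids : list of str
        Unique individual identifiers, row order of ``alleles``.
    loci : list of str
        Locus names, column order of ``alleles``.
    alleles : ndarray of shape (n_individuals, n_loci, 2), int
        Allele calls (integer fragment sizes); missing cells are
        ``(MISSING, MISSING)``. Pairs are stored sorted ascending.
    """

    ids: list[str]
    loci: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.loci = [str(l) for l in self.loci]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("individual ids must be unique")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names must be unique")
        a = np.asarray(self.alleles, dtype=np.int32)
        if a.shape != (len(self.ids), len(self.loci), 2):
            raise ValueError(
                f"alleles shape {a.shape} does not match "
                f"({len(self.ids)}, {len(self.loci)}, 2)"
            )
        # any missing half-call voids the whole cell, then sort pairs
        half_missing = (a == MISSING).any(axis=2)
        a[half_missing] = MISSING
        a = np.sort(a, axis=2)
        self.alleles = a

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the cell is missing."""
        return self.alleles[:, :, 0] == MISSING

    def n_typed(self) -> np.ndarray:
        """Number of non-missing loci per individual."""
        return (~self.missing_mask).sum(axis=1)

    def id_index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}

    # -- manipulation --------------------------------------------------------

    def select(
        self,
        ids: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeTable":
        """Subset by individual ids and/or locus names (order preserved)."""
        idx = self.id_index()
        rows = np.arange(self.n_individuals) if ids is None else np.array(
            [idx[i] for i in ids], dtype=int
        )
        lmap = {l: k for k, l in enumerate(self.loci)}
        cols = np.arange(self.n_loci) if loci is None else np.array(
            [lmap[l] for l in loci], dtype=int
        )
        return GenotypeTable(
            ids=[self.ids[r] for r in rows],
            loci=[self.loci[c] for c in cols],
            alleles=self.alleles[np.ix_(rows, cols)].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.loci == other.loci
            and np.array_equal(self.alleles, other.alleles)
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame with columns ``<locus>.1``/``<locus>.2`` (NA missing)."""
        data: dict[str, np.ndarray] = {}
        for j, locus in enumerate(self.loci):
            for k in (0, 1):
                col = self.alleles[:, j, k].astype(float)
                col[col == MISSING] = np.nan
                data[f"{locus}.{k + 1}"] = col
        return pd.DataFrame(data, index=pd.Index(self.ids, name="id"))


@dataclass
class PlantRecord:
    """One surveyed plant: id, habitat patch, planar coordinates, first year.

    Every plant has a patch id even when coordinates are absent; ``has_coords``
    distinguishes located plants from patch-only ones.
    """

    id: str
    patch: int
    x: float
    y: float
    first_year: int

    @property
    def has_coords(self) -> bool:
        return np.isfinite(self.x) and np.isfinite(self.y)


def records_to_frame(records: Iterable[PlantRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalize plant records to a DataFrame indexed by id.

    Columns: ``patch`` (int), ``x``, ``y`` (m, NaN when unlocated),
    ``first_year`` (int).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "id" in df.columns:
            df = df.set_index("id")
        df.index = df.index.astype(str)
    else:
        rows = list(records)
        df = pd.DataFrame(
            {
                "patch": [r.patch for r in rows],
                "x": [r.x for r in rows],
                "y": [r.y for r in rows],
                "first_year": [r.first_year for r in rows],
            },
            index=pd.Index([r.id for r in rows], name="id"),
        )
    df["patch"] = df["patch"].astype(int)
    df["first_year"] = df["first_year"].astype(int)
    df[["x", "y"]] = df[["x", "y"]].astype(float)
    return df[["patch", "x", "y", "first_year"]]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_genotypes_csv(g: GenotypeTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        header = ["id"]
        for locus in g.loci:
            header += [f"{locus}.1", f"{locus}.2"]
        w.writerow(header)
        for i, ind in enumerate(g.ids):
            row: list[str] = [ind]
            for j in range(g.n_loci):
                a, b = g.alleles[i, j]
                row += (["NA", "NA"] if a == MISSING else [str(a), str(b)])
            w.writerow(row)
    logger.info("wrote %d individuals x %d loci to %s", g.n_individuals, g.n_loci, path)


def _parse_allele(tok: str, path: Path, lineno: int) -> int:
    tok = tok.strip()
    if tok in ("NA", "na", "", "?"):
        return MISSING
    try:
        return int(tok)
    except ValueError:
        raise GenotypeParseError(
            f"{path}:{lineno}: non-numeric allele {tok!r}"
        ) from None


def read_genotypes_csv(path: str | Path) -> GenotypeTable:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeParseError(f"{path}:1: empty file") from None
        if not header or header[0] != "id":
            raise GenotypeParseError(f"{path}:1: first column must be 'id'")
        cols = header[1:]
        if len(cols) % 2:
            raise GenotypeParseError(f"{path}:1: odd number of allele columns")
        loci = []
        for k in range(0, len(cols), 2):
            name = cols[k].rsplit(".", 1)[0]
            if cols[k + 1].rsplit(".", 1)[0] != name:
                raise GenotypeParseError(
                    f"{path}:1: allele columns {cols[k]!r}/{cols[k+1]!r} do not pair"
                )
            loci.append(name)
        ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 1 + 2 * len(loci):
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {1 + 2 * len(loci)} fields, got {len(row)}"
                )
            ids.append(row[0])
            rows.append([_parse_allele(t, path, lineno) for t in row[1:]])
    alleles = np.array(rows, dtype=np.int32).reshape(len(ids), len(loci), 2)
    g = GenotypeTable(ids=ids, loci=loci, alleles=alleles)
    logger.info("read %d individuals x %d loci from %s", g.n_individuals, g.n_loci, path)
    return g


def write_genotypes_dat(
    g: GenotypeTable,
    path: str | Path,
    records: pd.DataFrame | Iterable[PlantRecord] | None = None,
    title: str = "pedconnect genotypes",
) -> None:
    """Write the whitespace ``.dat`` dialect (one population block)."""
    path = Path(path)
    birth: dict[str, int] = {}
    if records is not None:
        rf = records_to_frame(records)
        birth = rf["first_year"].to_dict()
    with path.open("w") as fh:
        fh.write(f"1 {g.n_loci} / {title}\n")
        fh.write(f"{g.n_individuals} all\n")
        for i, ind in enumerate(g.ids):
            b = birth.get(ind, "?")
            toks = [ind, str(b), "?"]
            for j in range(g.n_loci):
                a, c = g.alleles[i, j]
                toks.append("?/?" if a == MISSING else f"{a}/{c}")
            fh.write(" ".join(toks) + "\n")
    logger.info("wrote %d individuals x %d loci to %s", g.n_individuals, g.n_loci, path)


def read_genotypes_dat(
    path: str | Path, loci: Sequence[str] | None = None
) -> GenotypeTable:
    """Read the whitespace ``.dat`` dialect.

    Locus names are not part of the format; pass ``loci`` to assign them,
    otherwise ``L01..Lnn`` is used.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}:1: empty file")
    head = lines[0].split("/")[0].split()
    if len(head) < 2:
        raise GenotypeParseError(f"{path}:1: header must be '<npops> <nloci> / title'")
    try:
        npops, nloci = int(head[0]), int(head[1])
    except ValueError:
        raise GenotypeParseError(f"{path}:1: non-integer header fields") from None
    if loci is None:
        loci = [f"L{j + 1:02d}" for j in range(nloci)]
    elif len(loci) != nloci:
        raise GenotypeParseError(f"{path}: {len(loci)} locus names for {nloci} loci")
    ids: list[str] = []
    rows: list[list[int]] = []
    lineno = 1
    for _ in range(npops):
        lineno += 1
        if lineno > len(lines):
            raise GenotypeParseError(f"{path}:{lineno}: missing population header")
        pop_head = lines[lineno - 1].split()
        try:
            count = int(pop_head[0])
        except (IndexError, ValueError):
            raise GenotypeParseError(
                f"{path}:{lineno}: population header must start with a count"
            ) from None
        for _ in range(count):
            lineno += 1
            if lineno > len(lines):
                raise GenotypeParseError(f"{path}:{lineno}: truncated file")
            toks = lines[lineno - 1].split()
            if len(toks) != 3 + nloci:
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {3 + nloci} fields, got {len(toks)}"
                )
            ids.append(toks[0])
            cells: list[int] = []
            for tok in toks[3:]:
                parts = tok.split("/")
                if len(parts) != 2:
                    raise GenotypeParseError(
                        f"{path}:{lineno}: malformed genotype {tok!r}"
                    )
                cells += [_parse_allele(p, path, lineno) for p in parts]
            rows.append(cells)
    alleles = np.array(rows, dtype=np.int32).reshape(len(ids), nloci, 2)
    g = GenotypeTable(ids=ids, loci=list(loci), alleles=alleles)
    logger.info("read %d individuals x %d loci from %s", g.n_individuals, g.n_loci, path)
    return g


def read_genotypes(path: str | Path, dialect: str = "csv", **kw) -> GenotypeTable:
    """Dispatch on dialect: ``csv`` or ``franz_dat``."""
    if dialect == "csv":
        return read_genotypes_csv(path)
    if dialect in ("franz_dat", "dat"):
        return read_genotypes_dat(path, **kw)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_metadata_tsv(
    records: pd.DataFrame | Iterable[PlantRecord], path: str | Path
) -> None:
    df = records_to_frame(records)
    df.to_csv(path, sep="\t", na_rep="NA")
    logger.info("wrote %d plant records to %s", len(df), path)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA"])
    return records_to_frame(df)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Which loci/individuals were dropped and their missing fractions."""

    max_locus_missing: float
    max_indiv_missing: float
    dropped_loci: list[tuple[str, float]] = field(default_factory=list)
    dropped_individuals: list[tuple[str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("locus", n, f) for n, f in self.dropped_loci]
        rows += [("individual", n, f) for n, f in self.dropped_individuals]
        return pd.DataFrame(rows, columns=["kind", "name", "missing_fraction"])


def qc_filter(
    g: GenotypeTable,
    max_locus_missing: float = 0.05,
    max_indiv_missing: float = 0.10,
) -> tuple[GenotypeTable, QCReport]:
    """Drop loci then individuals whose missing fraction is NOT strictly below
    the threshold (loci first; individuals re-evaluated on surviving loci).

    Raises ``ValueError`` if no locus survives.
    """
    for t in (max_locus_missing, max_indiv_missing):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    report = QCReport(max_locus_missing, max_indiv_missing)
    miss = g.missing_mask
    locus_frac = miss.mean(axis=0)
    keep_loci = locus_frac < max_locus_missing
    for j in np.flatnonzero(~keep_loci):
        report.dropped_loci.append((g.loci[j], float(locus_frac[j])))
    if not keep_loci.any():
        raise ValueError("QC removed every locus; thresholds too strict for data")
    miss2 = miss[:, keep_loci]
    ind_frac = miss2.mean(axis=1)
    keep_ind = ind_frac < max_indiv_missing
    for i in np.flatnonzero(~keep_ind):
        report.dropped_individuals.append((g.ids[i], float(ind_frac[i])))
    out = GenotypeTable(
        ids=[g.ids[i] for i in np.flatnonzero(keep_ind)],
        loci=[g.loci[j] for j in np.flatnonzero(keep_loci)],
        alleles=g.alleles[np.ix_(np.flatnonzero(keep_ind), np.flatnonzero(keep_loci))].copy(),
    )
    logger.info(
        "QC: kept %d/%d loci and %d/%d individuals",
        out.n_loci, g.n_loci, out.n_individuals, g.n_individuals,
    )
    return out, report


# ---------------------------------------------------------------------------
# duplicate detection
# ---------------------------------------------------------------------------


def _encode_cells(g: GenotypeTable) -> np.ndarray:
    """Encode each genotype cell as a single int64 (missing → -1)."""
    a = g.alleles.astype(np.int64)
    code = a[:, :, 0] * 1_000_000 + a[:, :, 1]
    code[g.missing_mask] = -1
    return code


def find_duplicates(
    g: GenotypeTable, max_mismatch_loci: int = 0, min_compared_loci: int = 1
) -> list[list[str]]:
    """Groups of individuals with (near-)identical multilocus genotypes.

    Two individuals match when their genotypes differ at ≤ ``max_mismatch_loci``
    of the loci typed in both (and at least ``min_compared_loci`` loci are
    comparable). Matching is symmetric; groups are the connected components of
    the match graph, each sorted, returned sorted by first member.
    """
    if max_mismatch_loci < 0:
        raise ValueError("max_mismatch_loci must be >= 0")
    code = _encode_cells(g)
    n = g.n_individuals
    import networkx as nx

    graph = nx.Graph()
    chunk = 256
    for start in range(0, n, chunk):
        block = code[start : start + chunk]  # (b, L)
        both = (block[:, None, :] >= 0) & (code[None, :, :] >= 0)
        differ = (block[:, None, :] != code[None, :, :]) & both
        mism = differ.sum(axis=2)
        comparable = both.sum(axis=2)
        ok = (mism <= max_mismatch_loci) & (comparable >= min_compared_loci)
        bi, bj = np.nonzero(ok)
        for i, j in zip(bi + start, bj):
            if i < j:
                graph.add_edge(g.ids[i], g.ids[j])
    groups = [sorted(c) for c in nx.connected_components(graph)]
    groups.sort()
    if groups:
        logger.info("found %d duplicate group(s)", len(groups))
    return groups
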