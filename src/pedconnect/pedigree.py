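"""Triad-only pedigree container, relationship classification and families.

The pedigree keeps only offspring with *two* assigned parents (triads), so
every non-founder node has exactly two parents and founders have none.
Relationship categories follow the usual wild-pedigree summaries:
parent–offspring links, full/half siblings, grandparent–offspring, full/half
avuncular, and full first cousins. Because the plants are hermaphrodites,
parental roles are ignored throughout (a pair sharing one parent is one
half-sib pair regardless of which gamete that parent contributed). A pair
qualifying for several categories is reported once, under the genealogically
closest one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .genotype_io import records_to_frame

logger = logging.getLogger(__name__)

#: category precedence, closest first; parent-offspring is a link count,
#: the rest are unordered pair counts
CATEGORIES = [
    "parent_offspring",
    "full_sib",
    "half_sib",
    "grandparent",
    "full_avuncular",
    "half_avuncular",
    "full_cousin",
]


class PedigreeError(ValueError):
    pass


@dataclass
class PedigreeGraph:
    """Triad pedigree: offspring → (parent1, parent2), plus node metadata.

    ``records`` is the plant-metadata frame (patch, x, y, first_year) indexed
    by id; it must cover every node that appears in a triad.
    """

    parents: dict[str, tuple[str, str]]
    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = records_to_frame(self.records)
        for off, (p1, p2) in self.parents.items():
            if p1 == p2:
                raise PedigreeError(f"{off}: identical parents (self-incompatible)")
            if off in (p1, p2):
                raise PedigreeError(f"{off}: plant listed as its own parent")
        missing = self.nodes() - set(self.records.index)
        if missing:
            raise PedigreeError(f"records missing for {sorted(missing)[:5]} ...")
        g = self.digraph()
        if not nx.is_directed_acyclic_graph(g):
            raise PedigreeError("pedigree contains a cycle")

    @classmethod
    def from_assignments(cls, result, records) -> "PedigreeGraph":
        """Build from an AssignmentResult, keeping triads only."""
        parents = {
            a.offspring: (a.parent1, a.parent2)
            for a in result.assignments
            if a.n_identified == 2
        }
        rec = records_to_frame(records)
        nodes = set(parents)
        for p1, p2 in parents.values():
            nodes |= {p1, p2}
        return cls(parents=parents, records=rec.loc[sorted(nodes)])

    @classmethod
    def from_truth(cls, truth, records) -> "PedigreeGraph":
        """Build the true pedigree from a simulator TruthSet."""
        rec = records_to_frame(records)
        nodes = set(truth.pedigree)
        for p1, p2 in truth.pedigree.values():
            nodes |= {p1, p2}
        return cls(parents=dict(truth.pedigree), records=rec.loc[sorted(nodes)])

    def nodes(self) -> set[str]:
        out = set(self.parents)
        for p1, p2 in self.parents.values():
            out.add(p1)
            out.add(p2)
        return out

    def founders(self) -> set[str]:
        return self.nodes() - set(self.parents)

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes())
        for off, (p1, p2) in self.parents.items():
            g.add_edge(p1, off)
            g.add_edge(p2, off)
        return g

    def check_years(self, strict: bool = True) -> list[str]:
        """Offspring whose parents are not observed strictly earlier."""
        bad = []
        fy = self.records["first_year"]
        for off, (p1, p2) in self.parents.items():
            lim = fy[off]
            for p in (p1, p2):
                if (fy[p] >= lim) if strict else (fy[p] > lim):
                    bad.append(off)
                    break
        return bad

    def to_frame(self) -> pd.DataFrame:
        """Interchange table: id, parent1, parent2, year, patch, x, y."""
        rows = []
        for node in sorted(self.nodes()):
            p1, p2 = self.parents.get(node, (None, None))
            r = self.records.loc[node]
            rows.append(
                {
                    "id": node,
                    "parent1": p1,
                    "parent2": p2,
                    "first_year": int(r["first_year"]),
                    "patch": int(r["patch"]),
                    "x": r["x"],
                    "y": r["y"],
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pedigree_tsv(path: str | Path) -> PedigreeGraph:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "parent1": str, "parent2": str},
                     na_values=["NA"])
    parents = {
        r.id: (r.parent1, r.parent2)
        for r in df.itertuples(index=False)
        if isinstance(r.parent1, str) and isinstance(r.parent2, str)
    }
    return PedigreeGraph(parents=parents, records=df.drop(columns=["parent1", "parent2"]))


# ---------------------------------------------------------------------------
# relationship classification
# ---------------------------------------------------------------------------


def classify_relationships(ped: PedigreeGraph) -> dict[str, int]:
    """Count relationship categories (wild-pedigree description table).

    ``parent_offspring`` counts directed links (2 per triad); all other
    categories count unordered pairs, each pair once under its closest
    category in :data:`CATEGORIES` order.
    """
    parents = ped.parents
    po_pairs: set[frozenset] = set()
    for off, (p1, p2) in parents.items():
        po_pairs.add(frozenset((p1, off)))
        po_pairs.add(frozenset((p2, off)))

    # candidate pairs per category (may overlap; precedence dedupes)
    by_parent_pair: dict[frozenset, list[str]] = {}
    by_parent: dict[str, list[str]] = {}
    for off, (p1, p2) in parents.items():
        by_parent_pair.setdefault(frozenset((p1, p2)), []).append(off)
        by_parent.setdefault(p1, []).append(off)
        by_parent.setdefault(p2, []).append(off)

    full_sibs: set[frozenset] = set()
    for sibs in by_parent_pair.values():
        for i in range(len(sibs)):
            for j in range(i + 1, len(sibs)):
                full_sibs.add(frozenset((sibs[i], sibs[j])))
    any_share: set[frozenset] = set()
    for sibs in by_parent.values():
        for i in range(len(sibs)):
            for j in range(i + 1, len(sibs)):
                if sibs[i] != sibs[j]:
                    any_share.add(frozenset((sibs[i], sibs[j])))
    half_sibs = any_share - full_sibs

    grandparent: set[frozenset] = set()
    for off, (p1, p2) in parents.items():
        for p in (p1, p2):
            if p in parents:
                for gp in parents[p]:
                    if gp != off:
                        grandparent.add(frozenset((gp, off)))

    full_sib_of: dict[str, set[str]] = {}
    half_sib_of: dict[str, set[str]] = {}
    for pair in full_sibs:
        a, b = tuple(pair)
        full_sib_of.setdefault(a, set()).add(b)
        full_sib_of.setdefault(b, set()).add(a)
    for pair in half_sibs:
        a, b = tuple(pair)
        half_sib_of.setdefault(a, set()).add(b)
        half_sib_of.setdefault(b, set()).add(a)

    full_avuncular: set[frozenset] = set()
    half_avuncular: set[frozenset] = set()
    for off, (p1, p2) in parents.items():
        for p in (p1, p2):
            for s in full_sib_of.get(p, ()):
                if s != off:
                    full_avuncular.add(frozenset((s, off)))
            for s in half_sib_of.get(p, ()):
                if s != off:
                    half_avuncular.add(frozenset((s, off)))

    full_cousin: set[frozenset] = set()
    for pair in full_sibs:
        a, b = tuple(pair)
        for ca in by_parent.get(a, ()):
            for cb in by_parent.get(b, ()):
                if ca != cb:
                    full_cousin.add(frozenset((ca, cb)))

    counts = {"parent_offspring": len(po_pairs)}
    assigned: set[frozenset] = set(po_pairs)
    for name, pairs in [
        ("full_sib", full_sibs),
        ("half_sib", half_sibs),
        ("grandparent", grandparent),
        ("full_avuncular", full_avuncular),
        ("half_avuncular", half_avuncular),
        ("full_cousin", full_cousin),
    ]:
        fresh = pairs - assigned
        counts[name] = len(fresh)
        assigned |= fresh
    return counts


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------


@dataclass
class FamilyTable:
    families: pd.DataFrame  # family_id, size, generations
    membership: dict[str, int]
    max_depth: int

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def mean_size(self) -> float:
        return float(self.families["size"].mean())


def families(ped: PedigreeGraph) -> FamilyTable:
    """Weakly connected components of the link graph, with generation depth.

    Depth = length of the longest ancestor chain within the family + 1
    (a disjoint triad spans 2 generations).
    """
    g = ped.digraph()
    depth_memo: dict[str, int] = {}

    def depth(node: str) -> int:
        if node in depth_memo:
            return depth_memo[node]
        if node not in ped.parents:
            depth_memo[node] = 1
            return 1
        d = 1 + max(depth(p) for p in ped.parents[node])
        depth_memo[node] = d
        return d

    rows = []
    membership: dict[str, int] = {}
    comps = sorted(nx.weakly_connected_components(g), key=lambda c: sorted(c)[0])
    for fid, comp in enumerate(comps, start=1):
        gen = max(depth(n) for n in comp)
        rows.append({"family_id": fid, "size": len(comp), "generations": gen})
        for n in comp:
            membership[n] = fid
    fam = pd.DataFrame(rows, columns=["family_id", "size", "generations"])
    max_depth = int(fam["generations"].max()) if len(fam) else 0
    logger.info(
        "%d families, mean size %.1f, max depth %d generations",
        len(fam), fam["size"].mean() if len(fam) else float("nan"), max_depth,
    )
    return FamilyTable(families=fam, membership=membership, max_depth=max_depth)


def pedigree_summary(ped: PedigreeGraph) -> pd.Series:
    """One-column pedigree description (counts per category + structure)."""
    counts = classify_relationships(ped)
    fam = families(ped)
    n_offspring = len(ped.parents)
    data = {
        "individuals": len(ped.nodes()),
        "parent_offspring_links": counts["parent_offspring"],
        "full_sib_links": counts["full_sib"],
        "half_sib_links": counts["half_sib"],
        "grandparent_offspring_links": counts["grandparent"],
        "full_avuncular_links": counts["full_avuncular"],
        "full_first_cousin_links": counts["full_cousin"],
        "half_avuncular_links": counts["half_avuncular"],
        "founders": len(ped.founders()),
        "offspring_with_two_parents": n_offspring,
        "families": fam.n_families,
        "mean_family_size": fam.mean_size,
        "max_depth_generations": fam.max_depth,
    }
    return pd.Series(data, name="quantity")
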