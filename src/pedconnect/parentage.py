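"""Likelihood-based parent-pair assignment for codominant markers.

For each offspring, candidate parents are the plants first observed strictly
before the offspring's first year (and young enough to reproduce). The
posterior is computed over every eligible *unordered* candidate pair plus the
alternatives "one parent unsampled" and "both parents unsampled", where an
unsampled parent transmits a gamete drawn from the population allele
frequencies (HWE). Hermaphroditism means pairs carry no mother/father labels;
maternal vs paternal roles are inferred spatially downstream.

Genotyping error is handled on the offspring observation: each observed
allele equals the transmitted one with probability 1 − e, otherwise it is a
random allele drawn by frequency. Candidate genotypes are taken at face
value; a candidate's missing locus falls back to the HWE gamete model so all
hypotheses are scored over the same locus set.

An exclusion prefilter (bitmask shared-allele screen) removes candidates with
more than a few Mendelian-incompatible loci before pair enumeration; with a
panel of ≥16 informative microsatellites the pruned hypotheses carry
vanishing likelihood, which keeps the per-offspring posterior practically
exact while making the enumeration desk-scale.

Only offspring whose top hypothesis is a *pair of sampled plants* with
posterior above the threshold become triads — the only links retained in the
final pedigree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeTable, records_to_frame
from .popgen import AlleleFreqs, allele_freqs

logger = logging.getLogger(__name__)


@dataclass
class AssignmentConfig:
    """Parentage-assignment settings.

    ``posterior_threshold`` follows the conservative triads-only convention
    (default 0.95); ``min_typed_loci`` is the minimum number of loci typed in
    both offspring and candidate; ``repro_age_range`` bounds parent age at the
    offspring's recruitment year.
    """

    error_rate: float = 0.01
    posterior_threshold: float = 0.95
    min_typed_loci: int = 16
    repro_age_max: int = 20
    max_candidates: int = 14000
    prefilter_max_mismatch: int = 4
    strict_year: bool = True  # parent first_year strictly before offspring's

    def __post_init__(self) -> None:
        if not 0.5 < self.posterior_threshold <= 1.0:
            raise ValueError("posterior_threshold must lie in (0.5, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.min_typed_loci < 0 or self.prefilter_max_mismatch < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class ParentageAssignment:
    """Retained hypothesis for one offspring.

    ``parent1``/``parent2`` are unordered; ``None`` stands for an unsampled
    parent. ``posterior`` is the posterior mass of the retained hypothesis.
    """

    offspring: str
    parent1: str | None
    parent2: str | None
    posterior: float
    log_likelihood: float
    n_loci_compared: int
    n_mismatch_loci: int

    @property
    def n_identified(self) -> int:
        return int(self.parent1 is not None) + int(self.parent2 is not None)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


class _LocusModel:
    """Per-locus arrays shared by all triad-likelihood evaluations."""

    def __init__(self, g: GenotypeTable, freqs: AlleleFreqs):
        self.n_loci = g.n_loci
        self.freq: list[np.ndarray] = []
        self.codes: list[np.ndarray] = []  # (n, 2) allele indices, −1 missing
        self.gametes: list[np.ndarray] = []  # (n+1, k); last row = HWE parent
        self.masks: np.ndarray | None = None
        all_masks = np.zeros((g.n_individuals, g.n_loci), dtype=np.uint64)
        for j, locus in enumerate(g.loci):
            f = freqs.pooled(locus)
            alleles = f.index.to_numpy()
            p = f.to_numpy().astype(float)
            lookup = {a: i for i, a in enumerate(alleles)}
            cell = g.alleles[:, j, :]
            codes = np.full(cell.shape, -1, dtype=np.int64)
            for a, i in lookup.items():
                codes[cell == a] = i
            # alleles observed in individuals but absent from the frequency
            # table (possible when freqs come from a filtered table): give
            # them a tiny floor frequency so likelihoods stay defined
            unknown = (codes < 0) & (cell != MISSING)
            if unknown.any():
                extra = np.unique(cell[unknown])
                p = np.concatenate([p, np.full(len(extra), 1e-6)])
                p = p / p.sum()
                for t, a in enumerate(extra):
                    codes[cell == a] = len(alleles) + t
                alleles = np.concatenate([alleles, extra])
            self.freq.append(p)
            self.codes.append(codes)
            typed = codes[:, 0] >= 0
            m = np.zeros(g.n_individuals, dtype=np.uint64)
            for copy in (0, 1):
                m[typed] |= np.uint64(1) << codes[typed, copy].astype(np.uint64)
            all_masks[:, j] = m
            # gamete distribution rows for every individual + a final row for
            # the unsampled (HWE) parent, indexed as row n_individuals
            gam = np.tile(p, (g.n_individuals + 1, 1))
            rows = np.flatnonzero(typed)
            gam[rows] = 0.0
            np.add.at(gam, (rows, codes[rows, 0]), 0.5)
            np.add.at(gam, (rows, codes[rows, 1]), 0.5)
            self.gametes.append(gam)
        self.masks = all_masks  # 0 where missing (no bits set)
        self.codes_arr = np.stack(self.codes, axis=1)  # (n, L, 2)
        self._w_cache: dict[tuple[int, int, int, float], np.ndarray] = {}

    def obs_matrix(self, j: int, off_codes: np.ndarray, e: float) -> np.ndarray:
        """W[a, b] = P(observed offspring genotype | true genotype {a, b})."""
        o1, o2 = int(off_codes[0]), int(off_codes[1])
        key = (j, o1, o2, e)
        cached = self._w_cache.get(key)
        if cached is not None:
            return cached
        p = self.freq[j]
        k = p.size
        # per-allele observation kernel: P(o | true x) = (1-e) δ(o,x) + e p_o
        e1 = np.full(k, e * p[o1])
        e1[o1] += 1.0 - e
        if o1 == o2:
            W = np.outer(e1, e1)
        else:
            e2 = np.full(k, e * p[o2])
            e2[o2] += 1.0 - e
            W = np.outer(e1, e2)
            W += W.T.copy()
        self._w_cache[key] = W
        return W

    def gamete_vector(self, j: int, codes_row: np.ndarray) -> np.ndarray:
        """Gamete allele distribution for a parent (typed: half/half on its
        alleles; missing: HWE population frequencies)."""
        p = self.freq[j]
        if codes_row[0] < 0:
            return p.copy()
        v = np.zeros(p.size)
        v[codes_row[0]] += 0.5
        v[codes_row[1]] += 0.5
        return v


def triad_likelihood(
    off_codes: np.ndarray,
    p1_codes: np.ndarray,
    p2_codes: np.ndarray,
    model: _LocusModel,
    error_rate: float,
) -> float:
    """Log-likelihood of an offspring genotype given two parent genotypes.

    All ``*_codes`` are (L, 2) allele-index arrays (−1 missing). Loci missing
    in the offspring are skipped; parent-missing loci use HWE gametes.
    """
    ll = 0.0
    for j in range(model.n_loci):
        if off_codes[j, 0] < 0:
            continue
        W = model.obs_matrix(j, off_codes[j], error_rate)
        g1 = model.gamete_vector(j, p1_codes[j])
        g2 = model.gamete_vector(j, p2_codes[j])
        lik = float(g1 @ W @ g2)
        ll += -np.inf if lik <= 0 else float(np.log(lik))
    return ll


def triad_loglik_from_table(
    g: GenotypeTable,
    offspring: str,
    parent1: str | None,
    parent2: str | None,
    freqs: AlleleFreqs | None = None,
    error_rate: float = 0.01,
) -> float:
    """Convenience wrapper: triad log-likelihood by individual id.

    ``None`` for a parent means "unsampled" (HWE gamete).
    """
    freqs = freqs or allele_freqs(g)
    model = _LocusModel(g, freqs)
    idx = g.id_index()
    off = model_codes(model, idx[offspring])
    missing_row = np.full((model.n_loci, 2), -1, dtype=np.int64)
    p1 = model_codes(model, idx[parent1]) if parent1 else missing_row
    p2 = model_codes(model, idx[parent2]) if parent2 else missing_row
    return triad_likelihood(off, p1, p2, model, error_rate)


def model_codes(model: _LocusModel, row: int) -> np.ndarray:
    return model.codes_arr[row]


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


@dataclass
class AssignmentResult:
    assignments: list[ParentageAssignment]
    config: AssignmentConfig
    #: offspring id -> DataFrame(parent1, parent2, log_likelihood, posterior)
    #: populated only when assign_parents(..., keep_posteriors=True)
    posteriors: dict[str, pd.DataFrame] | None = None

    def triads(self) -> list[ParentageAssignment]:
        return [a for a in self.assignments if a.n_identified == 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offspring": [a.offspring for a in self.assignments],
                "parent1": [a.parent1 for a in self.assignments],
                "parent2": [a.parent2 for a in self.assignments],
                "posterior": [a.posterior for a in self.assignments],
                "log_likelihood": [a.log_likelihood for a in self.assignments],
                "n_loci_compared": [a.n_loci_compared for a in self.assignments],
                "n_mismatch_loci": [a.n_mismatch_loci for a in self.assignments],
            }
        )


def _exact_mismatch_count(
    off: np.ndarray, p1: np.ndarray, p2: np.ndarray
) -> int:
    """Loci where the pair cannot produce the offspring without error."""
    n = 0
    for j in range(off.shape[0]):
        if off[j, 0] < 0:
            continue
        o = set(off[j])
        s1 = set(p1[j]) if p1[j, 0] >= 0 else None
        s2 = set(p2[j]) if p2[j, 0] >= 0 else None
        a, b = off[j, 0], off[j, 1]
        ok = False
        for x, y in ((a, b), (b, a)):
            in1 = s1 is None or x in s1
            in2 = s2 is None or y in s2
            if in1 and in2:
                ok = True
                break
        if not ok:
            n += 1
    return n


def assign_parents(
    g: GenotypeTable,
    records,
    config: AssignmentConfig | None = None,
    freqs: AlleleFreqs | None = None,
    keep_posteriors: bool = False,
) -> AssignmentResult:
    """Assign parent pairs to every plant with at least one eligible candidate.

    Returns one :class:`ParentageAssignment` per evaluated offspring with the
    retained (top-posterior) hypothesis; plants without eligible candidates
    are founders and get no entry. The posterior over all enumerated
    hypotheses sums to one per offspring.
    """
    config = config or AssignmentConfig()
    rec = records_to_frame(records)
    freqs = freqs or allele_freqs(g)
    model = _LocusModel(g, freqs)
    idx = g.id_index()
    ids = np.array(g.ids)
    years = rec.loc[ids, "first_year"].to_numpy()
    typed = model.masks != 0  # (n, L)
    n_typed = typed.sum(axis=1)
    e = config.error_rate
    out: list[ParentageAssignment] = []
    posteriors: dict[str, pd.DataFrame] = {}

    order = np.argsort(years, kind="stable")
    for row in order:
        off_id = ids[row]
        fy = years[row]
        if config.strict_year:
            elig = years < fy
        else:
            elig = years <= fy
            elig[row] = False
        elig &= (fy - years) <= config.repro_age_max
        if not elig.any():
            continue  # founder: no candidates at all
        # shared-typed-loci and Mendelian-mismatch screens
        off_mask = model.masks[row]  # (L,)
        off_typed = typed[row]
        shared_typed = (typed[elig] & off_typed).sum(axis=1)
        no_share = (model.masks[elig] & off_mask) == 0
        mismatch = (no_share & typed[elig] & off_typed).sum(axis=1)
        cand_rows = np.flatnonzero(elig)
        keep = (shared_typed >= config.min_typed_loci) & (
            mismatch <= config.prefilter_max_mismatch
        )
        cand_rows = cand_rows[keep]
        if cand_rows.size > config.max_candidates:
            order_m = np.argsort(mismatch[keep], kind="stable")
            cand_rows = cand_rows[order_m[: config.max_candidates]]
        cand_rows = cand_rows[np.argsort(ids[cand_rows])]  # order-invariant
        s = cand_rows.size
        off_codes = model_codes(model, row)
        # per-locus pair-likelihood matrices over candidates + unsampled (last)
        total_ll = np.zeros((s + 1, s + 1))
        n_compared = 0
        for j in range(model.n_loci):
            if off_codes[j, 0] < 0:
                continue
            n_compared += 1
            W = model.obs_matrix(j, off_codes[j], e)
            G = model.gametes[j][np.append(cand_rows, model.gametes[j].shape[0] - 1)]
            M = G @ W @ G.T
            with np.errstate(divide="ignore"):
                total_ll += np.log(np.maximum(M, 0.0))
        # hypotheses: unordered pairs {i<j} over candidates ∪ {U}, plus {U,U}
        iu, ju = np.triu_indices(s + 1, k=1)
        iu = np.append(iu, s)
        ju = np.append(ju, s)
        ll = total_ll[iu, ju]
        finite = np.isfinite(ll)
        if not finite.any():
            continue
        mx = ll[finite].max()
        w = np.where(finite, np.exp(np.where(finite, ll, mx) - mx), 0.0)
        post = w / w.sum()
        if keep_posteriors:
            posteriors[off_id] = pd.DataFrame(
                {
                    "parent1": [ids[cand_rows[i]] if i < s else None for i in iu],
                    "parent2": [ids[cand_rows[j]] if j < s else None for j in ju],
                    "log_likelihood": ll,
                    "posterior": post,
                }
            )
        best = int(np.argmax(post))
        bi, bj = int(iu[best]), int(ju[best])
        p1 = ids[cand_rows[bi]] if bi < s else None
        p2 = ids[cand_rows[bj]] if bj < s else None
        if post[best] <= config.posterior_threshold:
            # retain as unresolved: report alternative with both unsampled
            p1 = p2 = None
            best = len(ll) - 1
        missing_row = np.full((model.n_loci, 2), -1, dtype=np.int64)
        c1 = model_codes(model, idx[p1]) if p1 else missing_row
        c2 = model_codes(model, idx[p2]) if p2 else missing_row
        out.append(
            ParentageAssignment(
                offspring=off_id,
                parent1=p1,
                parent2=p2,
                posterior=float(post[best]) if (p1 or p2) else float(post[len(ll) - 1]),
                log_likelihood=float(ll[best]),
                n_loci_compared=n_compared,
                n_mismatch_loci=_exact_mismatch_count(off_codes, c1, c2),
            )
        )
    n_triads = sum(1 for a in out if a.n_identified == 2)
    logger.info(
        "assigned %d offspring: %d triads, %d single-parent, %d unresolved",
        len(out), n_triads,
        sum(1 for a in out if a.n_identified == 1),
        sum(1 for a in out if a.n_identified == 0),
    )
    return AssignmentResult(
        assignments=out, config=config, posteriors=posteriors if keep_posteriors else None
    )


# ---------------------------------------------------------------------------
# assignment-rate table
# ---------------------------------------------------------------------------


def assignment_rates(result: AssignmentResult, records) -> pd.DataFrame:
    """Fractions of plants with 0/1/2 identified parents per patch × year.

    Plants with no assignment entry (founders / unresolved) count as two
    unidentified parents. Returns a long table with a per-patch median row
    appended (year = "median").
    """
    rec = records_to_frame(records)
    n_ident = {a.offspring: a.n_identified for a in result.assignments}
    rec = rec.copy()
    rec["n_identified"] = rec.index.map(lambda i: n_ident.get(i, 0))
    rows = []
    for (patch, year), grp in rec.groupby(["patch", "first_year"]):
        n = len(grp)
        rows.append(
            {
                "patch": patch,
                "year": year,
                "n": n,
                "frac_two_unidentified": float((grp["n_identified"] == 0).mean()),
                "frac_one_unidentified": float((grp["n_identified"] == 1).mean()),
                "frac_both_identified": float((grp["n_identified"] == 2).mean()),
            }
        )
    df = pd.DataFrame(rows)
    med = (
        df.groupby("patch")[
            ["frac_two_unidentified", "frac_one_unidentified", "frac_both_identified"]
        ]
        .median()
        .reset_index()
    )
    med["year"] = "median"
    med["n"] = df.groupby("patch")["n"].sum().to_numpy()
    return pd.concat([df, med], ignore_index=True)


def write_assignments_tsv(result: AssignmentResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_parentage_csv(path: str | Path) -> pd.DataFrame:
    """Read an externally produced parentage CSV (offspring, parent columns)
    for cross-checking; column names are normalized to lower case."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return df
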