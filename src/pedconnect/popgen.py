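"""Marker diagnostics and population-structure statistics.

Implements the standard toolbox for codominant microsatellite panels:

* allele-frequency tallies per population (non-missing genes only);
* per-locus diversity: allelic richness A, observed/expected heterozygosity
  (Hexp with the small-sample factor n/(n−1)), polymorphic information
  content PIC, and Nei's multilocus within-population gene diversity Hs with
  its standard error over loci;
* parent-pair exclusion probability per locus and cumulated over a panel;
* Hardy–Weinberg tests (chi-square with pooling of rare genotype classes,
  exact conditional test for biallelic loci);
* Weir & Cockerham's θST from per-locus, per-allele variance components
  (a, b, c), multilocus as Σa / Σ(a+b+c), with permutation p-values obtained
  by shuffling individuals among populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class AlleleFreqs:
    """Per-locus, per-population allele counts and frequencies.

    ``counts[locus]`` is a DataFrame (index: allele, columns: population) of
    gene counts; ``n_genes`` is loci × populations. Cells with zero genes are
    listed in ``undefined``.
    """

    loci: list[str]
    populations: list
    counts: dict[str, pd.DataFrame]
    n_genes: pd.DataFrame
    undefined: list[tuple[str, object]] = field(default_factory=list)

    def freqs(self, locus: str, pop=None) -> pd.Series:
        c = self.counts[locus]
        col = c.sum(axis=1) if pop is None else c[pop]
        total = col.sum()
        if total == 0:
            raise ValueError(f"no genes at locus {locus!r} for population {pop!r}")
        return col / total

    def pooled(self, locus: str) -> pd.Series:
        return self.freqs(locus, None)


def _pop_series(g: GenotypeTable, pops) -> pd.Series:
    """Normalize a population assignment (dict/Series/array) over table ids."""
    if pops is None:
        return pd.Series("all", index=g.ids)
    if isinstance(pops, Mapping):
        s = pd.Series({i: pops[i] for i in g.ids})
    else:
        s = pd.Series(pops)
        if not set(g.ids) <= set(s.index.astype(str)):
            if len(s) == g.n_individuals:
                s.index = g.ids
            else:
                raise ValueError("population assignment does not cover all individuals")
        s = s.loc[g.ids]
    if s.isna().any():
        raise ValueError("every individual must be assigned to exactly one population")
    return s


def allele_freqs(g: GenotypeTable, pops=None) -> AlleleFreqs:
    """Tally allele counts per locus × population from non-missing genes."""
    s = _pop_series(g, pops)
    pop_labels = sorted(s.unique().tolist())
    pop_code = s.map({p: k for k, p in enumerate(pop_labels)}).to_numpy()
    counts: dict[str, pd.DataFrame] = {}
    n_genes = pd.DataFrame(0, index=g.loci, columns=pop_labels, dtype=int)
    undefined: list[tuple[str, object]] = []
    for j, locus in enumerate(g.loci):
        cell = g.alleles[:, j, :]
        ok = cell[:, 0] != MISSING
        alleles = np.unique(cell[ok])
        tab = pd.DataFrame(0, index=alleles, columns=pop_labels, dtype=int)
        for k, pop in enumerate(pop_labels):
            sel = ok & (pop_code == k)
            genes = cell[sel].ravel()
            vals, cnt = np.unique(genes, return_counts=True)
            tab.loc[vals, pop] = cnt
            n_genes.loc[locus, pop] = genes.size
            if genes.size == 0:
                undefined.append((locus, pop))
        counts[locus] = tab
    if undefined:
        logger.warning("%d locus x population cells have zero genes", len(undefined))
    return AlleleFreqs(
        loci=list(g.loci), populations=pop_labels, counts=counts,
        n_genes=n_genes, undefined=undefined,
    )


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------


def _hexp(freq: np.ndarray, n_genes: int) -> float:
    """Nei's unbiased expected heterozygosity, n/(n−1) (1 − Σp²)."""
    if n_genes <= 1:
        return float("nan")
    return n_genes / (n_genes - 1) * (1.0 - float((freq**2).sum()))

def _pic(freq: np.ndarray) -> float:
    """Polymorphic information content: 1 − Σp² − [(Σp²)² − Σp⁴]."""
    a2 = float((freq**2).sum())
    a4 = float((freq**4).sum())
    return 1.0 - a2 - (a2**2 - a4)


@dataclass
class DiversityResult:
    markers: pd.DataFrame  # per-locus: A, N, Hobs, Hexp, PIC, PPexp
    hs: pd.DataFrame | None  # per-population: Hs, SE, n_loci
    cumulative_ppexp: float


def diversity(g: GenotypeTable, pops=None) -> DiversityResult:
    """Per-locus marker summary on pooled data, plus per-population Hs ± SE.

    Hs is the mean over loci of within-population Hexp; its SE is the
    standard error of that mean over loci. Loci with ≤1 gene in a population
    are flagged NaN and excluded from the mean.
    """
    pooled = allele_freqs(g, None)
    rows = []
    ex = exclusion_probability(pooled)
    for j, locus in enumerate(g.loci):
        cell = g.alleles[:, j, :]
        ok = cell[:, 0] != MISSING
        n_ind = int(ok.sum())
        n_genes = 2 * n_ind
        freq = pooled.pooled(locus).to_numpy() if n_genes else np.array([])
        hobs = float((cell[ok, 0] != cell[ok, 1]).mean()) if n_ind else float("nan")
        rows.append(
            {
                "locus": locus,
                "A": int(len(freq)),
                "N": n_ind,
                "Hobs": hobs,
                "Hexp": _hexp(freq, n_genes),
                "PIC": _pic(freq) if n_genes else float("nan"),
                "PPexp": ex.per_locus.loc[locus],
            }
        )
    markers = pd.DataFrame(rows).set_index("locus")
    hs = None
    if pops is not None:
        by_pop = allele_freqs(g, pops)
        recs = []
        for pop in by_pop.populations:
            vals = []
            for locus in g.loci:
                n = int(by_pop.n_genes.loc[locus, pop])
                if n > 1:
                    f = by_pop.freqs(locus, pop).to_numpy()
                    vals.append(_hexp(f, n))
            v = np.array(vals)
            recs.append(
                {
                    "population": pop,
                    "Hs": v.mean() if v.size else float("nan"),
                    "SE": v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else float("nan"),
                    "n_loci": v.size,
                }
            )
        hs = pd.DataFrame(recs).set_index("population")
    return DiversityResult(markers=markers, hs=hs, cumulative_ppexp=ex.cumulative)


# ---------------------------------------------------------------------------
# parent-pair exclusion probability
# ---------------------------------------------------------------------------


@dataclass
class ExclusionResult:
    per_locus: pd.Series
    cumulative: float


def ppexp_locus(freq: np.ndarray) -> float:
    """Parent-pair exclusion probability for one locus.

    The probability that a random (HWE) candidate pair is Mendelian-excluded
    as the parents of a random offspring produced by HWE random mating.
    A genotype G contains allele x with probability u_x = p_x (2 − p_x); a
    pair (G1, G2) can produce offspring {x, y} iff one member carries x and
    the other carries y. Summing over the HWE offspring distribution:

        PPexp = Σ_x p_x² (1 − u_x²)
              + Σ_{x<y} 2 p_x p_y [1 − (2 u_x u_y − 4 p_x² p_y²)]

    Monomorphic loci have no exclusion power (PPexp = 0).
    """
    p = np.asarray(freq, float)
    if p.size < 2:
        return 0.0
    u = p * (2.0 - p)
    total = float((p**2 * (1.0 - u**2)).sum())
    # heterozygous offspring classes
    px, py = np.meshgrid(p, p, indexing="ij")
    ux, uy = np.meshgrid(u, u, indexing="ij")
    prod = 2.0 * ux * uy - 4.0 * px**2 * py**2
    het = 2.0 * px * py * (1.0 - prod)
    iu = np.triu_indices(p.size, k=1)
    total += float(het[iu].sum())
    return total


def exclusion_probability(freqs: AlleleFreqs) -> ExclusionResult:
    """Per-locus PPexp from pooled frequencies, cumulated as 1 − Π(1 − P_l)."""
    vals = {}
    for locus in freqs.loci:
        p = freqs.pooled(locus).to_numpy()
        vals[locus] = ppexp_locus(p)
    per_locus = pd.Series(vals, name="PPexp")
    cumulative = 1.0 - float(np.prod(1.0 - per_locus.to_numpy()))
    return ExclusionResult(per_locus=per_locus, cumulative=cumulative)


def cumulative_ppexp(per_locus: Sequence[float]) -> float:
    arr = np.asarray(list(per_locus), float)
    return 1.0 - float(np.prod(1.0 - arr))


# ---------------------------------------------------------------------------
# Hardy-Weinberg tests
# ---------------------------------------------------------------------------


class HWETestUnavailable(ValueError):
    """Too few observations after pooling to test HWE at this locus."""


def _exact_biallelic_hwe(n_het: int, n_a: int, n: int) -> float:
    """Exact conditional HWE test (Levene/Haldane distribution of the
    heterozygote count given allele counts); two-sided by probability mass."""
    n_b = 2 * n - n_a
    if n_a > n_b:
        n_a, n_b = n_b, n_a
    hets = np.arange(n_a % 2, n_a + 1, 2)
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln((n_a - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_b - hets) / 2 + 1)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob = prob / prob.sum()
    obs = prob[hets == n_het]
    if obs.size == 0:
        raise HWETestUnavailable("heterozygote count has wrong parity")
    return float(prob[prob <= obs[0] * (1 + 1e-12)].sum())


@dataclass
class HWEResult:
    locus: str
    statistic: float | None
    p_value: float
    df: int | None
    method: str


def hwe_test(g: GenotypeTable, locus: str, exact: str = "auto") -> HWEResult:
    """HWE goodness-of-fit at one locus, all individuals pooled.

    Biallelic loci use the exact conditional test when ``exact`` is "auto" or
    "always". Multi-allelic loci use a chi-square test on genotype classes,
    pooling classes with expected count < 5 into one; raises
    :class:`HWETestUnavailable` when no valid test remains.
    """
    j = g.loci.index(locus)
    cell = g.alleles[:, j, :]
    ok = cell[:, 0] != MISSING
    cell = cell[ok]
    n = cell.shape[0]
    alleles, inv = np.unique(cell, return_inverse=True)
    k = alleles.size
    if k < 2:
        raise HWETestUnavailable(f"{locus}: fewer than 2 alleles")
    inv = inv.reshape(-1, 2)
    freq = np.bincount(inv.ravel(), minlength=k) / (2 * n)
    if k == 2 and exact in ("auto", "always"):
        n_het = int((inv[:, 0] != inv[:, 1]).sum())
        n_a = int(np.bincount(inv.ravel(), minlength=2)[0])
        p = _exact_biallelic_hwe(n_het, n_a, n)
        return HWEResult(locus=locus, statistic=None, p_value=p, df=None, method="exact")
    # observed genotype counts
    obs_counts: dict[tuple[int, int], int] = {}
    for a, b in inv:
        key = (min(a, b), max(a, b))
        obs_counts[key] = obs_counts.get(key, 0) + 1
    classes = [(a, b) for a in range(k) for b in range(a, k)]
    obs = np.array([obs_counts.get(c, 0) for c in classes], float)
    expv = np.array(
        [n * (freq[a] ** 2 if a == b else 2 * freq[a] * freq[b]) for a, b in classes]
    )
    # pool rare classes (expected < 5) into one
    small = expv < 5.0
    if small.any():
        obs = np.append(obs[~small], obs[small].sum())
        expv = np.append(expv[~small], expv[small].sum())
    if expv.size < 2 or expv[-1] < 1e-12:
        raise HWETestUnavailable(f"{locus}: insufficient counts after pooling")
    df = int(expv.size - k)
    if df < 1:
        df = int(expv.size - 1)  # conservative fallback for heavily pooled loci
        if df < 1:
            raise HWETestUnavailable(f"{locus}: no degrees of freedom after pooling")
    chi2 = float(((obs - expv) ** 2 / expv).sum())
    p = float(stats.chi2.sf(chi2, df))
    return HWEResult(locus=locus, statistic=chi2, p_value=p, df=df, method="chi2")


def hwe_filter(g: GenotypeTable, alpha: float = 0.05) -> tuple[list[str], list[str]]:
    """Split loci into (passing, failing) HWE at level ``alpha``; untestable
    loci are kept (no evidence of deviation)."""
    keep, drop = [], []
    for locus in g.loci:
        try:
            res = hwe_test(g, locus)
        except HWETestUnavailable:
            keep.append(locus)
            continue
        (drop if res.p_value < alpha else keep).append(locus)
    if drop:
        logger.info("HWE filter removed %d loci: %s", len(drop), ", ".join(drop))
    return keep, drop


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def _locus_arrays(g: GenotypeTable):
    """Per locus: (allele codes (n,2) with −1 missing, number of alleles)."""
    out = []
    for j in range(g.n_loci):
        cell = g.alleles[:, j, :]
        ok = cell[:, 0] != MISSING
        alleles = np.unique(cell[ok])
        lookup = {a: i for i, a in enumerate(alleles)}
        codes = np.full(cell.shape, -1, dtype=np.int64)
        for a, i in lookup.items():
            codes[cell == a] = i
        codes[~ok] = -1
        out.append((codes, len(alleles)))
    return out


def _wc_components_locus(codes: np.ndarray, k: int, pop_code: np.ndarray, r_total: int):
    """Summed (a, b, c) variance components over alleles at one locus.

    ``codes``: (n, 2) allele indices, −1 missing; ``pop_code``: (n,) ints.
    Populations without data at this locus are dropped (r adjusts).
    """
    ok = codes[:, 0] >= 0
    if k < 2 or not ok.any():
        return 0.0, 0.0, 0.0
    pops_present, pop_inv = np.unique(pop_code[ok], return_inverse=True)
    r = pops_present.size
    if r < 2:
        return 0.0, 0.0, 0.0
    c0 = codes[ok]
    n_i = np.bincount(pop_inv, minlength=r).astype(float)  # individuals per pop
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    het = c0[:, 0] != c0[:, 1]
    a_sum = b_sum = c_sum = 0.0
    for allele in range(k):
        dose = (c0 == allele).sum(axis=1)  # 0/1/2 copies
        p_i = np.bincount(pop_inv, weights=dose, minlength=r) / (2 * n_i)
        h_i = np.bincount(pop_inv, weights=(het & (dose == 1)).astype(float), minlength=r) / n_i
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        if nbar <= 1:
            continue
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _theta_multilocus(locus_arrays, pop_code: np.ndarray) -> tuple[float, pd.DataFrame | None]:
    r_total = np.unique(pop_code).size
    rows = []
    A = B = C = 0.0
    for codes, k in locus_arrays:
        a, b, c = _wc_components_locus(codes, k, pop_code, r_total)
        rows.append((a, b, c))
        A += a
        B += b
        C += c
    denom = A + B + C
    theta = A / denom if denom != 0 else float("nan")
    per_locus = pd.DataFrame(rows, columns=["a", "b", "c"])
    per_locus["theta"] = np.where(
        per_locus[["a", "b", "c"]].sum(axis=1) != 0,
        per_locus["a"] / per_locus[["a", "b", "c"]].sum(axis=1),
        np.nan,
    )
    return float(theta), per_locus


@dataclass
class FstResult:
    """θST estimates with permutation p-values."""

    scope: str
    theta: float
    p_value: float | None
    n_permutations: int
    per_locus: pd.DataFrame | None = None
    pairwise: pd.DataFrame | None = None
    pairwise_p: pd.DataFrame | None = None
    removed_loci: list[str] = field(default_factory=list)


def _perm_pvalue(
    locus_arrays, pop_code: np.ndarray, theta_obs: float, n_perm: int,
    rng: np.random.Generator,
) -> float:
    if np.isnan(theta_obs):
        return float("nan")
    count = 0
    labels = pop_code.copy()
    for _ in range(n_perm):
        rng.shuffle(labels)
        t, _ = _theta_multilocus(locus_arrays, labels)
        if not np.isnan(t) and t >= theta_obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def fst(
    g: GenotypeTable,
    pops,
    n_perm: int = 999,
    filter_hwe: bool = True,
    alpha: float = 0.05,
    pairwise: bool = True,
    rng: np.random.Generator | int | None = None,
) -> FstResult:
    """Multilocus Weir–Cockerham θST: global and (optionally) pairwise.

    Individuals are permuted among populations for significance; p-values are
    (1 + #{θ_perm ≥ θ_obs}) / (1 + n_perm). When ``filter_hwe`` is set, loci
    that fail HWE on the pooled data at ``alpha`` are removed first.
    """
    rng = np.random.default_rng(rng if not isinstance(rng, np.random.Generator) else None) \
        if not isinstance(rng, np.random.Generator) else rng
    removed: list[str] = []
    if filter_hwe:
        keep, removed = hwe_filter(g, alpha=alpha)
        if not keep:
            logger.warning(
                "HWE filter would remove every locus; computing θ on the full panel"
            )
            removed = []
        else:
            g = g.select(loci=keep)
    s = _pop_series(g, pops)
    pop_labels = sorted(s.unique().tolist())
    if len(pop_labels) < 2:
        raise ValueError("need at least 2 populations")
    pop_code = s.map({p: i for i, p in enumerate(pop_labels)}).to_numpy()
    locus_arrays = _locus_arrays(g)
    theta, per_locus = _theta_multilocus(locus_arrays, pop_code)
    per_locus.index = g.loci
    p = _perm_pvalue(locus_arrays, pop_code, theta, n_perm, rng) if n_perm else None
    result = FstResult(
        scope="global", theta=theta, p_value=p, n_permutations=n_perm,
        per_locus=per_locus, removed_loci=removed,
    )
    if pairwise:
        mat = pd.DataFrame(np.nan, index=pop_labels, columns=pop_labels, dtype=float)
        pmat = pd.DataFrame(np.nan, index=pop_labels, columns=pop_labels, dtype=float)
        for i, pa in enumerate(pop_labels):
            for pb in pop_labels[i + 1 :]:
                sel = np.isin(pop_code, [i, pop_labels.index(pb)])
                sub = g.select(ids=[g.ids[t] for t in np.flatnonzero(sel)])
                sub_arrays = _locus_arrays(sub)
                sub_code = pop_code[sel]
                t_ab, _ = _theta_multilocus(sub_arrays, sub_code)
                mat.loc[pa, pb] = mat.loc[pb, pa] = t_ab
                if n_perm:
                    pmat.loc[pa, pb] = pmat.loc[pb, pa] = _perm_pvalue(
                        sub_arrays, sub_code, t_ab, n_perm, rng
                    )
        np.fill_diagonal(mat.values, 0.0)
        result.pairwise = mat
        result.pairwise_p = pmat
    return result


def fst_per_year(
    g: GenotypeTable,
    pops,
    records: pd.DataFrame,
    n_perm: int = 0,
    filter_hwe: bool = True,
    alpha: float = 0.05,
    min_per_pop: int = 2,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Global θST per cohort (individuals whose first_year equals that year)."""
    years = sorted(records["first_year"].unique().tolist())
    s = _pop_series(g, pops)
    rows = []
    for year in years:
        ids = [i for i in g.ids if records.loc[i, "first_year"] == year]
        sub = g.select(ids=ids)
        sub_pops = s.loc[ids]
        counts = sub_pops.value_counts()
        use = counts[counts >= min_per_pop].index
        if len(use) < 2:
            rows.append({"year": year, "theta": np.nan, "p_value": np.nan, "n": len(ids)})
            continue
        keep_ids = [i for i in ids if sub_pops[i] in set(use)]
        sub = g.select(ids=keep_ids)
        res = fst(
            sub, sub_pops.loc[keep_ids], n_perm=n_perm,
            filter_hwe=filter_hwe, alpha=alpha, pairwise=False, rng=rng,
        )
        rows.append(
            {"year": year, "theta": res.theta, "p_value": res.p_value, "n": len(keep_ids)}
        )
    return pd.DataFrame(rows).set_index("year")
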