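"""Forward-in-time, spatially explicit simulator of a patchy plant population.

The simulated species is a short-lived, hermaphroditic, self-incompatible
perennial growing on small disjoint habitat patches. Each year surviving
adults flower; every adult can act as seed (ovule) parent and as pollen
donor. Seeds fall by gravity near the mother (exponential kernel, a few
meters, clipped to the mother's patch), so offspring always recruit on the
maternal patch. Pollen usually moves within the patch (exponential kernel,
tens of meters) but with a small probability ``m_pollen`` comes from another
patch, chosen with probability proportional to the inverse barycenter
distance — between-patch dispersal is therefore purely pollen-borne, exactly
the process the downstream pedigree analysis tries to recover.

The simulator emits the observed data (genotype table with genotyping error
and missingness, plant metadata) *and* the ground truth (pedigree, true
dispersal class per offspring), so parentage assignment, connectivity and
fitness estimation can all be validated against known answers.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeTable,
    PlantRecord,
    read_genotypes_csv,
    read_metadata_tsv,
    write_genotypes_csv,
    write_genotypes_dat,
    write_metadata_tsv,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Patch:
    patch_id: int
    x: float
    y: float
    radius: float


@dataclass
class LandscapeSpec:
    """Disjoint circular habitat patches on a planar (meter) landscape."""

    patches: list[Patch]

    def __post_init__(self) -> None:
        ids = [p.patch_id for p in self.patches]
        if len(set(ids)) != len(ids):
            raise ValueError("patch ids must be unique")
        if any(p.radius <= 0 for p in self.patches):
            raise ValueError("patch radii must be positive")
        for i, p in enumerate(self.patches):
            for q in self.patches[i + 1 :]:
                d = math.hypot(p.x - q.x, p.y - q.y)
                if d <= p.radius + q.radius:
                    raise ValueError(
                        f"patches {p.patch_id} and {q.patch_id} overlap "
                        f"(separation {d:.1f} m <= radii sum)"
                    )

    @property
    def patch_ids(self) -> list[int]:
        return [p.patch_id for p in self.patches]

    def barycenter_distances(self) -> pd.DataFrame:
        """Pairwise distances between patch centers (zero diagonal)."""
        ids = self.patch_ids
        xy = np.array([[p.x, p.y] for p in self.patches])
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
        return pd.DataFrame(d, index=ids, columns=ids)


# Six patches laid out to reproduce the study system's barycenter separations
# (a few hundred meters to ~1.6 km along a roughly linear archipelago) and
# within-patch spread (mean within-patch distance ~20-95 m; for a uniform
# disk the mean pairwise distance is 128 R / 45 pi ≈ 0.905 R).
_DEFAULT_PATCH_GEOMETRY = [
    # (id, x, y, radius)
    (1, 0.0, 0.0, 105.0),
    (2, 570.0, 105.0, 53.0),
    (3, 940.0, 130.0, 26.0),
    (4, 1165.0, 175.0, 45.0),
    (5, 1550.0, 250.0, 51.0),
    (6, 1700.0, 310.0, 23.0),
]


def default_landscape() -> LandscapeSpec:
    return LandscapeSpec([Patch(*row) for row in _DEFAULT_PATCH_GEOMETRY])


# ---------------------------------------------------------------------------
# loci and configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusSpec:
    name: str
    frequencies: tuple[float, ...]  # founder allele frequencies
    allele_sizes: tuple[int, ...]  # fragment lengths (integers)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, float)
        if len(f) != len(self.allele_sizes):
            raise ValueError(f"{self.name}: frequency/size length mismatch")
        if (f < 0).any() or not math.isclose(f.sum(), 1.0, abs_tol=1e-8):
            raise ValueError(f"{self.name}: frequencies must be >=0 and sum to 1")


# Allelic richness profile of an 18-marker microsatellite panel typical of
# outcrossing plants (3-29 alleles per locus).
_DEFAULT_ALLELE_COUNTS = [17, 6, 7, 3, 19, 6, 17, 10, 29, 10, 9, 29, 7, 24, 9, 6, 17, 6]
_LOCI_FREQ_SEED = 20_240_117  # fixed: locus frequencies are part of the design


def default_loci(allele_counts: Sequence[int] | None = None) -> list[LocusSpec]:
    """Deterministic panel of microsatellite loci with skewed (Dirichlet(1))
    founder frequencies; expected heterozygosity ≈ 1 − 2/(k+1) per locus."""
    counts = list(allele_counts or _DEFAULT_ALLELE_COUNTS)
    rng = np.random.default_rng(_LOCI_FREQ_SEED)
    loci = []
    for j, k in enumerate(counts):
        freq = rng.dirichlet(np.ones(k))
        freq = freq / freq.sum()
        sizes = tuple(100 + 2 * a for a in range(k))
        loci.append(LocusSpec(name=f"ms{j + 1:02d}", frequencies=tuple(freq), allele_sizes=sizes))
    return loci


@dataclass
class SimConfig:
    """Simulation parameters (the study conditions, not tuning dials)."""

    n_years: int = 10
    founders_per_patch: int = 25
    loci: list[LocusSpec] = field(default_factory=default_loci)
    seed_kernel_mean: float = 4.0  # m, exponential; gravity dispersal
    pollen_kernel_mean: float = 20.0  # m, exponential, within-patch donors
    m_pollen: float = 0.03  # between-patch pollination probability
    fecundity: float = 1.6  # mean recruits per mother-year; with annual
    # survival 0.5 this gives λ = s(1+f) ≈ 1.3, a tenfold rise over 10 years
    adult_survival: float = 0.5  # annual survival of adults
    max_repro_age: int = 20  # years; reproduction allowed at ages 1..20
    migrant_fecundity_multiplier: float = 1.0  # fitness of migrant-derived plants
    genotyping_error_rate: float = 0.01  # per-allele miscall probability
    missing_rate: float = 0.005  # per-cell missing probability
    capacity_per_patch: int | None = None  # cap on alive plants per patch
    start_year: int = 2010
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        for name in ("m_pollen", "adult_survival", "genotyping_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.migrant_fecundity_multiplier < 0:
            raise ValueError("migrant_fecundity_multiplier must be >= 0")
        if self.fecundity < 0 or self.seed_kernel_mean <= 0 or self.pollen_kernel_mean <= 0:
            raise ValueError("kernel means must be positive and fecundity >= 0")


@dataclass
class TruthSet:
    """Ground truth emitted by the simulator.

    ``pedigree`` maps offspring id → (mother id, father id); founders are
    absent from it. ``events`` has one row per non-founder with the true
    dispersal classification and kernel draws.
    """

    pedigree: dict[str, tuple[str, str]]
    events: pd.DataFrame  # offspring, mother, father, year, patch,
    # father_patch, between_patch, seed_distance, pollen_distance

    @property
    def n_between(self) -> int:
        return int(self.events["between_patch"].sum())


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _sample_position_in_patch(
    rng: np.random.Generator, patch: Patch, mother_xy: tuple[float, float], mean: float
) -> tuple[float, float]:
    """Mother position + exponential-kernel displacement, kept inside the
    patch disk (rejection with radial clipping as last resort)."""
    mx, my = mother_xy
    for _ in range(20):
        d = rng.exponential(mean)
        theta = rng.uniform(0, 2 * math.pi)
        x, y = mx + d * math.cos(theta), my + d * math.sin(theta)
        if math.hypot(x - patch.x, y - patch.y) <= patch.radius:
            return x, y
    # clip radially toward the patch center
    dx, dy = x - patch.x, y - patch.y
    r = math.hypot(dx, dy)
    scale = 0.999 * patch.radius / r
    return patch.x + dx * scale, patch.y + dy * scale


def simulate(
    config: SimConfig, landscape: LandscapeSpec | None = None
) -> tuple[GenotypeTable, list[PlantRecord], TruthSet]:
    """Run the forward simulation.

    Returns the observed genotype table (error + missingness applied), the
    plant records (patch, coordinates, first sampling year = recruitment
    year), and the :class:`TruthSet`. Fully reproducible for a fixed
    ``config.rng_seed``.
    """
    landscape = landscape or default_landscape()
    if len(landscape.patches) < 2:
        raise ValueError("simulation needs at least 2 patches")
    rng = np.random.default_rng(config.rng_seed)
    loci = config.loci
    L = len(loci)
    freq_vecs = [np.asarray(l.frequencies, float) for l in loci]
    patches = {p.patch_id: p for p in landscape.patches}
    pids = landscape.patch_ids
    bary = landscape.barycenter_distances()

    # plant state (parallel lists; index = plant number)
    ids: list[str] = []
    patch_of: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    birth: list[int] = []
    alive: list[bool] = []
    migrant: list[bool] = []  # true dispersal class of the plant itself
    true_geno: list[np.ndarray] = []  # (L, 2) allele indices
    mother_of: dict[str, tuple[str, str]] = {}
    event_rows: list[dict] = []

    def new_plant(pid, x, y, year, geno, is_migrant):
        k = len(ids)
        ids.append(f"ind{k + 1:06d}")
        patch_of.append(pid)
        xs.append(x)
        ys.append(y)
        birth.append(year)
        alive.append(True)
        migrant.append(is_migrant)
        true_geno.append(geno)
        return k

    # founders, year 0, genotypes from HWE at the configured frequencies
    for pid in pids:
        p = patches[pid]
        for _ in range(config.founders_per_patch):
            r = p.radius * math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * math.pi)
            geno = np.empty((L, 2), dtype=np.int16)
            for j in range(L):
                geno[j] = rng.choice(len(freq_vecs[j]), size=2, p=freq_vecs[j])
            new_plant(pid, p.x + r * math.cos(th), p.y + r * math.sin(th), 0, geno, False)

    for year in range(1, config.n_years):
        # survival of last year's adults
        idx_alive = [k for k in range(len(ids)) if alive[k]]
        for k in idx_alive:
            if birth[k] < year and rng.uniform() > config.adult_survival:
                alive[k] = False
        # reproductive adults per patch
        adults: dict[int, list[int]] = {pid: [] for pid in pids}
        for k in range(len(ids)):
            if alive[k] and birth[k] < year and (year - birth[k]) <= config.max_repro_age:
                adults[patch_of[k]].append(k)
        for pid in pids:
            if not adults[pid]:
                warnings.warn(
                    f"patch {pid} has no reproductive adults in year {year}",
                    stacklevel=2,
                )
        occupied = [pid for pid in pids if adults[pid]]
        # per-patch father arrays
        pos = {pid: np.array([[xs[k], ys[k]] for k in adults[pid]]) for pid in occupied}
        fweight = {
            pid: np.array(
                [config.migrant_fecundity_multiplier if migrant[k] else 1.0 for k in adults[pid]]
            )
            for pid in occupied
        }
        recruits: dict[int, list[tuple]] = {pid: [] for pid in pids}
        for pid in occupied:
            p = patches[pid]
            other_pids = [q for q in occupied if q != pid]
            if other_pids:
                w = np.array([1.0 / bary.loc[pid, q] for q in other_pids])
                w = w / w.sum()
            for mk in adults[pid]:
                mean_off = config.fecundity * (
                    config.migrant_fecundity_multiplier if migrant[mk] else 1.0
                )
                n_off = rng.poisson(mean_off)
                for _ in range(n_off):
                    # pollen donor
                    go_between = other_pids and rng.uniform() < config.m_pollen
                    if go_between:
                        donor_pid = other_pids[rng.choice(len(other_pids), p=w)]
                        cand = adults[donor_pid]
                        cw = fweight[donor_pid]
                        fk = cand[rng.choice(len(cand), p=cw / cw.sum())]
                    else:
                        cand = [k for k in adults[pid] if k != mk]
                        if not cand:
                            # a lone plant cannot self; pollen must come from
                            # elsewhere, which requires between-patch flow
                            if not other_pids or config.m_pollen == 0.0:
                                continue
                            donor_pid = other_pids[rng.choice(len(other_pids), p=w)]
                            go_between = True
                            cand2 = adults[donor_pid]
                            cw = fweight[donor_pid]
                            fk = cand2[rng.choice(len(cand2), p=cw / cw.sum())]
                        else:
                            dist = np.hypot(
                                np.array([xs[k] for k in cand]) - xs[mk],
                                np.array([ys[k] for k in cand]) - ys[mk],
                            )
                            cw = np.exp(-dist / config.pollen_kernel_mean)
                            cw *= np.array(
                                [
                                    config.migrant_fecundity_multiplier if migrant[k] else 1.0
                                    for k in cand
                                ]
                            )
                            fk = cand[rng.choice(len(cand), p=cw / cw.sum())]
                    ox, oy = _sample_position_in_patch(
                        rng, p, (xs[mk], ys[mk]), config.seed_kernel_mean
                    )
                    geno = np.empty((L, 2), dtype=np.int16)
                    for j in range(L):
                        geno[j, 0] = true_geno[mk][j, rng.integers(2)]
                        geno[j, 1] = true_geno[fk][j, rng.integers(2)]
                    recruits[pid].append((mk, fk, ox, oy, geno, go_between))
        # recruit, enforcing optional capacity
        for pid in pids:
            rows = recruits[pid]
            if config.capacity_per_patch is not None:
                n_alive = sum(
                    1 for k in range(len(ids)) if alive[k] and patch_of[k] == pid
                )
                room = max(config.capacity_per_patch - n_alive, 0)
                if len(rows) > room:
                    keep = rng.choice(len(rows), size=room, replace=False)
                    rows = [rows[i] for i in sorted(keep)]
            for mk, fk, ox, oy, geno, between in rows:
                ck = new_plant(pid, ox, oy, year, geno, between)
                mother_of[ids[ck]] = (ids[mk], ids[fk])
                seed_d = math.hypot(ox - xs[mk], oy - ys[mk])
                pollen_d = math.hypot(ox - xs[fk], oy - ys[fk])
                event_rows.append(
                    {
                        "offspring": ids[ck],
                        "mother": ids[mk],
                        "father": ids[fk],
                        "year": config.start_year + year,
                        "patch": pid,
                        "father_patch": patch_of[fk],
                        "between_patch": between,
                        "seed_distance": seed_d,
                        "pollen_distance": pollen_d,
                    }
                )

    # observed genotypes: genotyping error then missingness
    n = len(ids)
    obs = np.empty((n, L, 2), dtype=np.int32)
    for j in range(L):
        k_alleles = len(freq_vecs[j])
        sizes = np.asarray(loci[j].allele_sizes, dtype=np.int32)
        calls = np.stack([g[j] for g in true_geno]).astype(np.int64)  # (n, 2)
        if config.genotyping_error_rate > 0:
            err = rng.uniform(size=calls.shape) < config.genotyping_error_rate
            calls[err] = rng.choice(k_alleles, size=int(err.sum()), p=freq_vecs[j])
        cell = sizes[calls]
        if config.missing_rate > 0:
            drop = rng.uniform(size=n) < config.missing_rate
            cell[drop] = MISSING
        obs[:, j, :] = cell
    genotypes = GenotypeTable(ids=list(ids), loci=[l.name for l in loci], alleles=obs)
    records = [
        PlantRecord(
            id=ids[k],
            patch=patch_of[k],
            x=xs[k],
            y=ys[k],
            first_year=config.start_year + birth[k],
        )
        for k in range(n)
    ]
    events = pd.DataFrame(
        event_rows,
        columns=[
            "offspring", "mother", "father", "year", "patch",
            "father_patch", "between_patch", "seed_distance", "pollen_distance",
        ],
    )
    truth = TruthSet(pedigree=mother_of, events=events)
    logger.info(
        "simulated %d plants over %d years (%d non-founders, %d between-patch events)",
        n, config.n_years, len(events), truth.n_between if len(events) else 0,
    )
    return genotypes, records, truth


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------


def write_fixture(
    genotypes: GenotypeTable,
    records: list[PlantRecord] | pd.DataFrame,
    truth: TruthSet,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write genotype CSV + .dat, metadata TSV and truth TSV into ``out_dir``.

    The files round-trip losslessly through the readers in ``genotype_io``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes_csv": out / "genotypes.csv",
        "genotypes_dat": out / "genotypes.dat",
        "metadata_tsv": out / "metadata.tsv",
        "truth_tsv": out / "truth.tsv",
    }
    write_genotypes_csv(genotypes, paths["genotypes_csv"])
    write_genotypes_dat(genotypes, paths["genotypes_dat"], records=records)
    write_metadata_tsv(records, paths["metadata_tsv"])
    truth.events.to_csv(paths["truth_tsv"], sep="\t", index=False)
    logger.info("fixture written to %s (%d truth rows)", out, len(truth.events))
    return paths


def read_fixture(out_dir: str | Path) -> tuple[GenotypeTable, pd.DataFrame, TruthSet]:
    """Re-read a fixture written by :func:`write_fixture`."""
    out = Path(out_dir)
    genotypes = read_genotypes_csv(out / "genotypes.csv")
    records = read_metadata_tsv(out / "metadata.tsv")
    events = pd.read_csv(out / "truth.tsv", sep="\t")
    pedigree = {
        r.offspring: (r.mother, r.father) for r in events.itertuples(index=False)
    }
    return genotypes, records, TruthSet(pedigree=pedigree, events=events)
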