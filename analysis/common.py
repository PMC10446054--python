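"""Shared paths and loaders for the numbered analysis drivers.

Run the scripts in order from the repository root; every step writes its
tables under results/ and prints a short narrative of what it found.
"""

from pathlib import Path

import pandas as pd

import pedconnect as pc

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

#: study-like generating conditions: 6 patches, 10 annual cohorts, 3%
#: between-patch pollination, migrants reproduce twice as much
SIM = dict(m_pollen=0.03, migrant_fecundity_multiplier=2.0)
SEED = 1


def load_dataset():
    """Re-read the simulated dataset written by 01_simulate.py."""
    genotypes, records, truth = pc.simdata.read_fixture(DATA)
    return genotypes, records, truth


def load_qc():
    """QC'd genotypes + aligned records (recomputed: QC is deterministic)."""
    genotypes, records, _ = load_dataset()
    g, _ = pc.qc_filter(genotypes)
    return g, records.loc[g.ids]


def load_pedigree():
    ped_path = RESULTS / "pedigree.tsv"
    from pedconnect.pedigree import read_pedigree_tsv

    return read_pedigree_tsv(ped_path)


def save(df: pd.DataFrame, name: str, index: bool = True) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=index, na_rep="NA")
    print(f"  wrote {path.relative_to(ROOT)} ({len(df)} rows)")
    return path
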