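"""Marker diagnostics and population structure: per-locus diversity and
exclusion power, Nei's Hs per patch, Weir-Cockerham θST with permutation
p-values, and the per-cohort θST series."""

import numpy as np

import pedconnect as pc
from pedconnect import popgen
from common import SEED, load_qc, save


def main():
    g, records = load_qc()
    pops = records["patch"]
    div = pc.diversity(g, pops=pops)
    save(div.markers.round(4), "marker_summary.tsv")
    save(div.hs.round(4), "hs_per_patch.tsv")
    print(
        f"mean Hs = {div.hs['Hs'].mean():.3f}; "
        f"cumulative parent-pair exclusion = {div.cumulative_ppexp:.6f}"
    )
    rng = np.random.default_rng(SEED)
    res = popgen.fst(g, pops, n_perm=199, rng=rng)
    save(res.pairwise.round(4), "fst_pairwise.tsv")
    save(res.pairwise_p.round(4), "fst_pairwise_p.tsv")
    print(f"global θST = {res.theta:.4f} (permutation p = {res.p_value:.3f})")
    per_year = popgen.fst_per_year(g, pops, records, n_perm=0)
    save(per_year.round(4), "fst_per_year.tsv")


if __name__ == "__main__":
    main()
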