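"""Marker and sample QC: drop loci with ≥5% missing data, then individuals
with ≥10% missing over the surviving loci; scan for genotype duplicates."""

import pedconnect as pc
from common import load_dataset, save


def main():
    genotypes, records, _ = load_dataset()
    g, report = pc.qc_filter(genotypes)
    save(report.to_frame(), "qc_report.tsv", index=False)
    dups = pc.find_duplicates(g)
    print(
        f"kept {g.n_loci}/{genotypes.n_loci} loci and "
        f"{g.n_individuals}/{genotypes.n_individuals} individuals; "
        f"{len(dups)} duplicate group(s)"
    )


if __name__ == "__main__":
    main()
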