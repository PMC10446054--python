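"""Build the triad-only pedigree and summarize it: relationship category
counts, family decomposition and generation depth."""

import pandas as pd

import pedconnect as pc
from pedconnect.parentage import AssignmentConfig
from common import RESULTS, load_qc, save


def main():
    g, records = load_qc()
    result = pc.assign_parents(g, records, AssignmentConfig())
    ped = pc.PedigreeGraph.from_assignments(result, records)
    ped.write_tsv(RESULTS / "pedigree.tsv")
    summary = pc.pedigree_summary(ped)
    save(summary.to_frame(), "pedigree_summary.tsv")
    fam = pc.families(ped)
    save(fam.families, "families.tsv", index=False)
    print(
        f"pedigree: {summary['individuals']:.0f} plants, "
        f"{summary['parent_offspring_links']:.0f} parent-offspring links, "
        f"{summary['half_sib_links']:.0f} half-sib links, "
        f"{summary['families']:.0f} families spanning up to "
        f"{summary['max_depth_generations']:.0f} generations"
    )


if __name__ == "__main__":
    main()
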