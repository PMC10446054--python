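"""Parentage assignment: per-offspring posterior over candidate parent pairs
(plus unsampled-parent alternatives), triads retained above posterior 0.95."""

import pedconnect as pc
from pedconnect.parentage import write_assignments_tsv
from common import RESULTS, load_qc, save


def main():
    g, records = load_qc()
    result = pc.assign_parents(g, records, pc.AssignmentConfig())
    write_assignments_tsv(result, RESULTS / "assignments.tsv")
    rates = pc.assignment_rates(result, records)
    save(rates.round(3), "assignment_rates.tsv", index=False)
    triads = result.triads()
    n_eval = len(result.assignments)
    print(
        f"{len(triads)} triads among {n_eval} evaluated offspring "
        f"({100 * len(triads) / n_eval:.0f}% both parents assigned)"
    )


if __name__ == "__main__":
    main()
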