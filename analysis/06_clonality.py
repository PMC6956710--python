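#!/usr/bin/env python
"""X-inactivation clonality for the multi-fibroid patients, plus variant
arithmetic: the in-frame MED12 deletion effect and mutation burden.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import load_cohort

from fibrointegra.clonality import clonality_call, deletion_effect, mutation_burden
from fibrointegra.core_io import write_table
from fibrointegra.subtyping import select_variable_probes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "clonality")
    args = ap.parse_args()

    ds, truth, cfg = load_cohort(args.cohort)
    top = select_variable_probes(ds.beta, ds.annotation, cfg.variable_fraction)

    rows = []
    for pid, mode in sorted(truth.xci_assignment.items()):
        call = clonality_call(
            ds.allelic, f"{pid}_F1", f"{pid}_F2", ds.samples,
            beta=ds.beta, variable_probes=top,
            min_depth=cfg.xci_min_depth, het_band=cfg.xci_het_band,
            mono_frac=cfg.xci_mono_fraction,
            min_informative=cfg.xci_min_informative,
            shared_min=cfg.xci_shared_min,
            independent_max=cfg.xci_independent_max,
        )
        rows.append(
            dict(patient_id=pid, tumor1=call.tumor_pair[0], tumor2=call.tumor_pair[1],
                 n_informative=call.n_informative, n_concordant=call.n_concordant,
                 concordance=call.concordance, meth_correlation=call.meth_correlation,
                 verdict=call.verdict, planted=mode)
        )
        print(f"{pid} ({call.tumor_pair[0]} vs {call.tumor_pair[1]}): "
              f"{call.n_concordant}/{call.n_informative} loci concordant, "
              f"methylation r = {call.meth_correlation:.2f} -> {call.verdict} "
              f"(planted: {mode})")
    write_table(pd.DataFrame(rows), args.out / "clonality_calls.tsv", seed=cfg.seed)

    # in-frame deletion arithmetic mirroring the two MED12 events
    rng = np.random.default_rng(cfg.seed)
    codons = ["TTC", "GCT", "GGA", "CTT", "AAG", "GAC", "TGT", "CCG"]
    cds = "ATG" + "".join(rng.choice(codons, 98)) + "TAA"
    for n_nt in (24, 45):
        eff = deletion_effect(cds, (60, 60 + n_nt))
        print(f"{n_nt}-nt in-frame CDS deletion removes {eff.residues_removed} "
              "amino acids")

    burden, flagged = mutation_burden(32, 64)
    print(f"example burden: 32 somatic variants / 64 Mb = {burden}/Mb"
          f"{' (outlier)' if flagged else ''}")


if __name__ == "__main__":
    main()
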