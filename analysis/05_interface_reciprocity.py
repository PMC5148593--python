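#!/usr/bin/env python
"""Dimer-interface reciprocity on synthetic twofold-symmetric dimers.

A dimer whose chains are related by an exact twofold rotation must show a
fully reciprocal interface: residue i of A touching residue j of B implies
residue i of B touching residue j of A.  Appending a single unpaired
residue to one chain breaks the symmetry and is reported pair by pair.

Writes results/interface_reciprocity.csv.
"""

import pandas as pd

from shellmap.interface import (
    check_reciprocity,
    interchain_contacts,
    interface_residue_sets,
)
from shellmap.synth import make_symmetric_dimer

OUT = "results/interface_reciprocity.csv"


def main() -> None:
    rows = []
    for seed in range(10):
        for broken in (False, True):
            st = make_symmetric_dimer(12, seed=seed, extra_one_sided=broken)
            xy = interchain_contacts(st, "A", "B")
            yx = interchain_contacts(st, "B", "A")
            report = check_reciprocity(xy, yx)
            rows.append(
                {
                    "seed": seed,
                    "symmetric": not broken,
                    "n_contacts": report.total,
                    "reciprocity": round(report.fraction, 3),
                    "n_non_reciprocal": len(report.non_reciprocal_pairs),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT, index=False)
    sym = df[df["symmetric"]]
    broken = df[~df["symmetric"]]
    print(f"symmetric dimers: reciprocity {sym['reciprocity'].min():.2f} "
          f"across {len(sym)} seeds (always 1.00 by construction)")
    print(f"one-sided-contact dimers: mean reciprocity "
          f"{broken['reciprocity'].mean():.2f}, offending pairs named in report")
    st = make_symmetric_dimer(12, seed=0)
    sets = interface_residue_sets(interchain_contacts(st, "A", "B"))
    print(f"example interface residue sets: {sets}")
    print(f"table at {OUT}")


if __name__ == "__main__":
    main()
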