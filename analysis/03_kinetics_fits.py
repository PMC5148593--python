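#!/usr/bin/env python
"""Michaelis–Menten fitting: recovery study and audit of the printed table.

Part 1 — simulation study: forward-simulate initial-rate series at the
wild-type cellobiose parameters (Km 2.36 mM, kcat 2.61 1/s) over the
log-spaced 10-point design spanning 0.2–10×Km, with 2% Vmax Gaussian noise,
and fit each replicate.

Part 2 — audit: recompute kcat/Km and relative efficiency from the printed
Km/kcat of the cellobiose table and flag rows whose printed efficiency does
not round-trip.

Writes results/km_recovery.csv and results/cellobiose_audit.csv.
"""

import numpy as np
import pandas as pd

from shellmap.data import load_cellobiose_kinetics
from shellmap.kinetics import audit_printed_kinetics, fit_michaelis_menten
from shellmap.synth import simulate_rate_series

RECOVERY_OUT = "results/km_recovery.csv"
AUDIT_OUT = "results/cellobiose_audit.csv"


def main() -> None:
    Km, kcat = 2.36, 2.61
    concs = tuple(Km * np.geomspace(0.2, 10, 10))
    rows = []
    for rep in range(200):
        fit = fit_michaelis_menten(
            simulate_rate_series(Km, kcat, concs, noise_sd=0.02, seed=rep)
        )
        rows.append(
            {"replicate": rep, "Km_hat": fit.Km, "kcat_hat": fit.kcat,
             "rel_err_Km": abs(fit.Km - Km) / Km}
        )
    rec = pd.DataFrame(rows)
    rec.to_csv(RECOVERY_OUT, index=False)
    print(f"200 noisy replicates: median |Km_hat-Km|/Km = "
          f"{rec['rel_err_Km'].median():.3f} (2% rate noise, n=10 design)")

    audit = audit_printed_kinetics(load_cellobiose_kinetics())
    audit.to_csv(AUDIT_OUT, index=False)
    flagged = audit.loc[audit["discrepant"], "mutation"].tolist()
    print(f"printed-table audit: {len(audit)} rows, "
          f"{len(flagged)} rounding discrepancies flagged: {', '.join(flagged)}")
    wt = audit.set_index("mutation").loc["WT", "efficiency_recomputed"]
    r97a = audit.set_index("mutation").loc["R97A", "efficiency_recomputed"]
    print(f"R97A cellobiose efficiency drop: {wt / r97a:.0f}-fold")
    print(f"tables at {RECOVERY_OUT} and {AUDIT_OUT}")


if __name__ == "__main__":
    main()
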