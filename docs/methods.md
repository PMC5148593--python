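# Methods

## Structural model

Structures are read from PDB-format text (via gemmi) into an explicit
chain → residue → atom model. Policies applied at parse time, all of which
downstream contact counts depend on:

- **Hydrogens** are dropped by default. The deposited X-ray structure
  carries none, and contact censuses must not depend on protonation
  modelling. A flag re-enables them.
- **Alternate conformations** collapse to the highest-occupancy conformer,
  ties broken by file order, so atom names are unique within a residue and
  the network is single-conformer.
- **Numbering** is the author numbering, kept verbatim: functional-residue
  labels (E187, E399, …) must match the mutagenesis literature. Insertion
  codes sort after the same number without a code.
- **Waters** never enter residue networks. Other hetero groups (the Tris
  inhibitor bound in the active site, NAG glycans) stay in the model,
  flagged non-polymer, and join networks only on request.

Atom classes partition heavy atoms into main chain (N, CA, C, O, OXT) and
side chain (everything else); glycine therefore has no side-chain atoms,
and hetero residues are all "side chain" for flag purposes.

## Contact criterion and network construction

Two distinct residues are in contact when at least one heavy-atom pair lies
**strictly** below the cutoff (default 5.0 Å); a pair at exactly the cutoff
never creates an edge. All heavy atoms participate — backbone-mediated
contacts are physically real couplings and several of the dataset's
assignments depend on them. Sequence-adjacent residues receive no special
treatment.

Construction queries a k-d tree over all atom coordinates at radius equal
to the cutoff (the tree query is inclusive; candidates are then filtered by
the strict inequality) and aggregates qualifying atom pairs per residue
pair: minimum distance at full precision (reports round to 2 decimals),
pair count, and one side-chain-involvement flag per endpoint (true iff some
qualifying pair uses that residue's side chain). An exhaustive all-pairs,
all-atom-pairs builder exists solely as the test oracle; the suite holds
the optimised builder to edge-for-edge equality, including minimum
distances to 1e-9 Å, over a hundred seeded random structures. Monotonicity
in the cutoff and invariance under residue reordering are asserted as
properties.

## Shells and region association

Functional regions are disjoint named residue sets. Steps to a region are
multi-source BFS distances (networkx shortest paths with unit edges) from
the region's members; the all-pairs Floyd–Warshall distances serve as an
independent oracle in tests. Region members missing from the network are
warned about and listed in the returned table — never silently dropped.

- **Layer** = minimum step count over regions (0 for functional residues).
  Partitions report L0, L1, L2 and "beyond" (the analysis only interprets
  the first two shells); residues disconnected from every region are listed
  separately rather than given an infinite distance.
- **Association** = the set of regions achieving the minimum. Ties are
  always reported in full (rendering order GBS, ABS, CR fixed for
  reproducibility); collapsing a tie to a single region is a rendering
  choice left to report templates.
- **Side-chain-constrained association** recomputes the minimum with the
  first step restricted to contacts in which the query residue's side chain
  participates; later steps are unrestricted. This models which regions a
  side-chain substitution can perturb, and resolves positions whose
  backbone and side chain point at different neighbourhoods. Queries with
  no side-chain-mediated contact (glycine) return an empty set with a
  warning. When the constraint removes no first edges the result equals the
  unconstrained association.

Layers are computed on a single chain's intra-chain network; chains are
analysed separately, never averaged.

## Kinetics

Michaelis–Menten fits use scipy nonlinear least squares on
v₀ = k_cat·[S]/(K_m+[S]) with rates pre-normalised per enzyme (so Vmax is
k_cat), initialised at K_m⁰ = median concentration and Vmax⁰ = max rate —
robust for saturating and non-saturating designs. Standard errors come from
the fit covariance; the efficiency error propagates in quadrature from
se(K_m) and se(k_cat) (the source tables report errors but not a
propagation rule, so quadrature is this package's choice). Non-convergence
and non-physical optima (K_m ≤ 0, k_cat < 0) raise with diagnostics rather
than returning silently bad parameters.

The pseudo-first-order route covers enzymes too slow to saturate: when all
concentrations sit far below K_m the rate law is linear through the origin
with slope k_cat/K_m, so the efficiency is the through-origin least-squares
slope, and K_m, k_cat are individually undetermined. A through-origin R²
below 0.98 indicates curvature toward saturation and raises an error
advising the full fit. An all-zero rate series returns efficiency 0 flagged
inactive.

**Effect classes.** Relative efficiency r = (k_cat/K_m)_mut/(k_cat/K_m)_WT.
With fold threshold F = 4: r > 1 positive; 1/F ≤ r ≤ 1 mild negative;
r < 1/F strong negative; the inactive marker is its own class. Boundary
conventions: r = 1 and r = 1/F are both mild — only genuine increments
count as positive, only decrements beyond the threshold as strong. A
configurable neutral sub-band (default [0.4, 1.0)) flags mild mutants whose
effect is within ~2-fold of wild type, the range the source studies discuss
as near-neutral.

**Printed-table audit.** Where a table prints K_m, k_cat *and* k_cat/K_m,
the efficiency is recomputed and compared at the printed precision: a row
is flagged discrepant when the recomputed value, rounded to the decimals
the table prints, differs from the printed number; the percent difference
is reported alongside, with >2% marked severe. This rounding-based rule is
deliberately stricter than a pure percentage cut: it flags every row a
reader would notice failing to round-trip (including a ~1.6% case) while
keeping the audit non-fatal — both the printed and the recomputed values
are carried forward.

**Simulation study.** The recovery study forward-simulates rates at the
wild-type cellobiose parameters (K_m 2.36 mM, k_cat 2.61 s⁻¹) over a
log-spaced 10-point design spanning 0.2–10×K_m — the standard design for
Michaelis–Menten estimation, spanning an order of magnitude either side of
K_m — with Gaussian noise of 2% of Vmax, truncated at zero. Noiseless data
must return the generating parameters to at least six significant digits
across K_m ∈ [0.1, 100] mM, k_cat ∈ [0.01, 100] s⁻¹; under noise the median
relative K_m error over 200 replicates stays under 5%; and the
pseudo-first-order slope matches k_cat/K_m within 1% when the largest
concentration is K_m/100.

## Effect integration and hotspots

Joining mutation records to per-position shell data is lossless: rows whose
position is absent from the structure table go to an exceptions report, and
joined + exceptions equals the input. Inactive mutants carry their class
but no log-ratio. Group summaries count effect classes per
association × layer category with a deterministic, input-order-invariant
ordering.

The hotspot predicate: a position qualifies when its *effective*
association — the side-chain-constrained set when one is known, otherwise
the plain shortest-path set — includes ABS and excludes GBS, and its best
characterised substitution is positive or mildly negative. Positions with
several substitutions are judged by the best one (the same position can
host opposing effects, e.g. K201A vs K201F), and ranked by best relative
efficiency descending, ties broken by layer ascending. The predicate is
monotone in an optional minimum-ratio threshold. Against the packaged
dataset the default predicate returns a superset of the literature's
curated nine-position shortlist (it additionally admits M57 and S358, whose
exclusion in the source rests on cross-species evidence the predicate does
not compute; that evidence can be supplied as a config flag).

## Interface analysis

Inter-chain contacts use the same strict 5 Å criterion (one contact
definition throughout). Reciprocity asks, for each contact (residue i of
chain X, residue j of chain Y), whether (i of Y, j of X) also exists, and
reports the fraction plus the offending pairs. On a dimer related by an
exact twofold this fraction is 1 by symmetry — the synthetic dimer
generator constructs exactly that, plus an optional one-sided extra residue
to exercise the failure path. Interface residue sets are simply the contact
endpoints per chain. Published interface lists derived from
buried-surface-area criteria may differ from the distance census, so exact
reproduction of such lists is a soft check, not a gate.

## Synthetic data: what it emulates, what it does not

- **Bead polymers** (collinear single-atom residues, spacing s): contact
  truth is arithmetic — edge iff |i−j|·s < cutoff — exercising the strict
  inequality and edge census. A multi-atom variant adds a jittered atom
  cloud (≤0.3 Å) per bead, with truth recomputed exhaustively from actual
  coordinates by a plain double loop.
- **Shell clusters**: region members sit in small balls near the origin;
  each layer-k residue lies at radius 4.4 + 4.5·(k−1) from its parent's
  anchor member, its direction tilted from the parent's by at most the
  angle keeping the parent within the cutoff. The radii force the layer
  decomposition (every layer-k residue touches layer k−1 and clears
  everything at k−2 and deeper by construction), so recovered layers must
  equal construction layers exactly. Step-count and association truth are
  recomputed at generation by an exhaustive distance census plus a plain
  queue BFS — code shared with nothing in the analysis pipeline — and the
  generator asserts self-consistency before returning.
- **Rate series**: the forward model plus truncated Gaussian noise
  described above.

These fixtures validate graph logic and fit behaviour, not protein physics:
single-pseudo-atom residues have no packing, secondary structure, or
realistic contact degree distribution, so passing tests demonstrate
correctness of the network/shell/fit machinery, not predictive power on
real structures. The structure-dependent checks against the deposited
Sfβgly coordinates close that gap when a local copy of the file is present.

## Reproducibility

Every random draw sits behind an explicit integer seed (numpy Generator;
no global state). The pipeline writes a manifest with input hashes,
parameters, versions and per-output SHA-256; identical configurations
reproduce byte-identical bundles. The acceptance script derives all
stochastic sub-seeds from its single `--seed` argument. Problem sizes used
by the standing checks — 100 seeded structures of 20–60 residues for oracle
equality, 50 seeded graphs for the BFS oracle, 50 shell clusters, 200 noise
replicates — keep the full suite comfortably within a desk-scale run while
giving the property checks real coverage.

## Known limitations

- Layer assignments for the packaged mutational dataset are transcribed
  from the source studies' structure analysis; recomputing them requires a
  local copy of the deposited coordinates (no downloads are performed).
- The side-chain-constrained association is recorded only where the source
  analysis established it (K366); other multi-region positions fall back to
  the unconstrained tie set.
- The contact definition is purely geometric: no hydrogen-bond detection,
  energies, or co-evolutionary weighting.
- Minor internal inconsistencies in the printed kinetic tables are flagged,
  not resolved; both printed and recomputed values are reported.
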