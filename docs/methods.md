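# Methods

## The model

`rwpot` implements a pair of knowledge-based statistical potentials for
protein model quality assessment:

* **distance term** — a residue-specific, atomic, distance-dependent
  potential whose reference state is an ideal random-walk
  (freely-jointed) chain;
* **orientation term** — a side-chain packing potential over a
  coarse-grained relative-orientation space of residue "vector pairs";
* **hybrid score** — `E_total = E_dist + w_orient * E_orient`.

Both terms follow the inverse-Boltzmann form

    E(feature) = -ln( N_obs(feature) / N_exp(feature) )     [kT units]

where `N_obs` is counted in a training library and `N_exp` is what an
interaction-free reference state predicts. kT ≡ 1 throughout: only
rankings and energy ratios matter for decoy discrimination.

### Random-walk reference state

A freely-jointed chain of Kuhn length `b` (with `lam = b²`) has the
Gaussian end-to-end radial density at separation `n`

    P(R | n) = 4 pi R^2 (3 / (2 pi n lam))^{3/2} exp(-3 R^2 / (2 n lam)).

Chain nodes are mapped to residues: every atom pair of residues `i, j`
carries separation `n = |i − j|`. The aggregate reference for a protein
of `N` residues sums these densities over the separations that the pair
counting actually admits, `n = min_separation .. N−1`; separations at or
beyond the chain length contribute exactly zero. Starting the sum at
`min_separation` (rather than 1) keeps the reference describing the same
pair population as the observed counts — summing from `n = 1` while
counting from `n = 2` produces a measurable systematic offset in
controlled self-consistency experiments, because the `n = 1` term is the
most short-range-weighted.

Two aggregation variants are exposed (`RWParams.aggregation`):
`"uniform"` (default) sums separations with equal weight;
`"multiplicity"` weights separation `n` by its pair multiplicity `N − n`.
Overall constants cancel in the anchored ratio, so only the shape
differs, and it differs only mildly; the multiplicity variant is the one
that exactly matches ensembles of physical chains (each chain realizes
`N − n` pairs at separation `n`) and is therefore used by the
self-consistency tests.

### Distance potential

Distances below the cutoff `R0` are binned into half-open 0.5 Å shells
(31 shells for `R0 = 15.5 Å`). Observed counts accumulate over all
unordered heavy-atom pairs with residue separation `≥ min_separation`
(default 2: intra-residue and consecutive-residue pairs excluded) and
distance `< R0`, stored symmetrically over the 158 × 158 atom-type
pairs. Expected counts are built **per training structure** (the
reference depends on that structure's own `N`): the shell weights
(16-point Gauss–Legendre integral of the aggregate reference per shell)
are scaled so that expected equals observed in the shell containing
`R0`; if that shell is empty for a pair type, the outer 2 Å is used
instead. This anchoring implements the convention that the pair
interaction vanishes at `R0` and makes the trained energy of the cutoff
shell exactly zero for every pair with counts there.

Special cases: shells with expected weight but zero observed count get a
finite cap (default +10 kT — dominant over typical favourable energies
of a few kT, and it avoids log 0); pair types that never reach the
anchoring region are uninformative and stay identically zero.

### Atom typing

167 heavy atoms of the 20 standard residues, with nine chemically
symmetric pairs merged (PHE/TYR CD1≡CD2 and CE1≡CE2, ASP OD1≡OD2,
GLU OE1≡OE2, ARG NH1≡NH2, LEU CD1≡CD2, VAL CG1≡CG2), give 158
residue-specific types. The full table ships as code
(`rwpot.atom_types`) and can be exported as TSV for auditing; a stable
hash of the table is stamped into every saved potential so that tables
trained under a different typing cannot be silently mixed. MSE is read
as MET; OXT and hydrogens are untyped.

### Orientation descriptor and potential

Each residue carries up to three "vector pairs": one side-chain atom
triple per residue type (18 types — every residue except GLY and ALA)
plus two backbone triples, (N, CA, C) and (CA, C, O), defined for all
residues — 20 types total. A triple (X0, X1, X2) defines a right-handed
frame: ẑ along X0→X1, x̂ the Gram–Schmidt component of X0→X2, ŷ = ẑ × x̂.
The relative orientation of two triples A, B is coded by

* the direction of B0 − A0 in A's frame — 26 bins: two polar caps
  (θ < π/6, θ > 5π/6) plus three latitude bands × eight π/4 azimuth
  sectors opening at φ = π/8 (the last sector wraps);
* the direction of A0 − B0 in B's frame (same 26 bins);
* the torsion A1–A0–B0–B1 in four π/2 bins —

26·26·4 = 2704 orientation bins. The reference probability of each bin
is analytic: the sphere surface-area fraction for each direction factor
(cap (1 − cos π/6)/2 ≈ 0.0670; outer-band sector
(cos π/6 − cos π/3)/16 ≈ 0.0229; equatorial sector 1/16) times 1/4 for
the torsion, the three factors independent. Counts accumulate over all
vector-pair instance combinations of contacting (any heavy-atom pair
closer than 10 Å, strict), non-consecutive residue pairs, in both
orders, so the table is symmetric under the A↔B swap transformation.
Under that swap the two direction bins exchange and the torsion bin is
unchanged (a dihedral is invariant under reversing its atom sequence).

The frame convention, the side-chain triples (the most distal branched
triple of each residue, e.g. PHE CG/CD1/CD2, ARG NE/NH1/NH2, SER
CB/OG/CA), the torsion origin, and the treatment of the wrap-around
azimuth sector are package conventions; any fixed, shared convention
yields a self-consistent potential because training and scoring use the
same descriptor. The definitions are data (`DEFAULT_VECTOR_PAIRS`,
loadable/savable as TSV), not hard-wired.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `lam` (= b²) | 460 | Å² | squared Kuhn length of the reference chain (b = 21.4 Å) |
| `R0` | 15.5 | Å | distance cutoff; anchoring point of the potential |
| `dR` | 0.5 | Å | half-open distance bin width (31 bins) |
| `min_separation` | 2 | residues | minimum sequence separation of counted pairs |
| `cap` | 10 | kT | energy of unobserved shells/bins |
| `contact_cutoff` | 10 | Å | residue contact criterion for the orientation term |
| `w_orient` | 0.1 | — | weight of the orientation term in the hybrid score |
| `aggregation` | uniform | — | separation weighting of the reference (see above) |

The first three and `w_orient` are the published operating point of the
method; they are configuration inputs here, and no re-optimization loop
is included.

## Evaluation statistics

`evaluate_decoy_set` ranks native + decoys by the hybrid energy
(deterministic tie-break by name) and reports: native rank; the native
Z-score `(E_native − mean E) / sd E` computed over the full set with the
native included (reported as undefined when sd = 0); the best quality
(lowest RMSD, highest TM-score) among the top-1/5/10 lowest-energy
decoys; and Pearson correlations of energy with RMSD and with TM-score
over the decoys, native excluded. RMSD is Cα RMSD after optimal proper
superposition (Kabsch SVD with reflection correction). TM-score
(`d0 = 1.24 (L − 15)^{1/3} − 1.8`) is available built-in as a
fixed-correspondence, iterative-superposition approximation of the
canonical program — adequate for synthetic ladders, and replaceable by
an external per-decoy quality table for benchmark work.

## Synthetic data: what it emulates and what it does not

The generators make every statistical property of the pipeline testable
without any structure downloads:

* **Gaussian-chain training sets** (`make_training_set`): residue
  centers perform an ideal random walk with step variance `lam`, each
  residue a rigid template in an iid uniformly random orientation. Atom
  pairs then sample exactly the reference distribution (multiplicity
  aggregation), so training must return a flat potential; an injected
  `PairBias` pins chosen atom-atom distances and must surface as an
  energy minimum in the corresponding shell. `template_scale` collapses
  residues toward their node; the self-consistency experiments use 0.15
  because full-size rigid residues smear the node-distance distribution
  slightly across the cutoff boundary (directions, and hence orientation
  statistics, are unaffected by the scale).
* **Contact-pair sets** (`make_orientation_set`): isolated residue pairs
  in contact with iid uniform rotations — the analytic product reference
  is then exact provided rotations pivot about the tested triple's X0
  atom (`anchor_atom`); a lever arm between pivot and X0 correlates
  direction with orientation, as it does in real chains. An
  `OrientationBias` pins pairs into one target orientation bin by
  explicit construction (`place_pair_in_bin`).
* **Perturbation decoys** (`make_decoy_set`): iid Gaussian coordinate
  noise at a ladder of σ values, with the true Cα RMSD table emitted
  alongside (RMSD ≈ σ√3 per rung).

None of this is protein chemistry: no excluded volume between residues,
no rotamers, no secondary structure, no H-bonding. Passing tests
demonstrate that the estimator recovers exactly the signals put in, at
the right location and magnitude, and nothing else — they do not
demonstrate benchmark performance on real decoy sets, which requires
real training structures and external decoys.

## Statistical design of the calibration tests

"Trained energies are zero up to counting noise" is asserted as a proper
family-wise test. The sampling sd of `E = −ln(N_obs/N_exp)` is
`sqrt(m (1/N_obs + 1/N_anchor))`: the anchor count that scales the
expected shape is itself Poisson-noisy, and `m = 2` accounts for the
count clustering of compact all-GLY residue pairs (every residue pair
deposits its atom pairs into one shell together, and same-type cells
take both symmetric increments). Per-bin thresholds are Šidák-corrected
so the whole table forms a single 3σ test (for one bin this reduces to
the familiar 3/√count); only shells with at least 25 counts enter, the
anchored cutoff shell (zero by construction) is excluded, and a pooled
3σ check on the count-weighted mean energy guards against systematic
offsets that per-bin tests would dilute. The same construction, with
Poisson variance, applies to the 2704-bin orientation table and to the
10⁶-sample sphere-partition Monte Carlo.

## Numerical choices

* Shell integrals: 16-point Gauss–Legendre per 0.5 Å shell (matches a
  64-point reference to < 1e-4 relative); midpoint rules drift near
  R = 0 where the integrand is ∝ R².
* Bins are half-open `[k dR, (k+1) dR)`; a pair at exactly `R0` is not
  counted. Azimuth sectors and torsion bins are half-open the same way.
* Degenerate geometry (collinear triples, coincident origins; tolerance
  1e-8 on the cross-product norm) raises in the scalar API and is
  skipped with a log entry in batch training/scoring.
* Fixture coordinates are quantized to 0.001 Å so PDB round-trips are
  exact; table persistence uses `repr` floats for bit-exact reload.
* Energy ranking ties are broken by decoy name; all generators are
  bit-reproducible under a fixed seed.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
self-consistency at 200 chains × 50 residues (~77k counted pairs),
orientation calibration at 20k contact pairs, the funnel experiment at a
50-residue native with 200 decoys over σ = 0.5/1/2/4 Å, and a 10⁶-sample
sphere Monte Carlo. These sizes give per-shell counts in the hundreds —
enough for the 3σ calibration machinery to be meaningful — while the
whole suite stays around half a minute.

## Known limitations

* Trained on toy ensembles only; shipping tables for real use requires a
  curated high-resolution, low-redundancy structure library.
* The exact partition of the 158 types and the exact side-chain triples
  follow this package's documented conventions; other implementations of
  the same family of potentials may partition differently, so tables are
  not interchangeable across packages (the typing hash enforces this).
* Single chain, first model only; no mmCIF; no multi-chain scoring.
* The built-in TM-score is an approximation (fixed residue
  correspondence, iterative superposition) and can underestimate the
  canonical value on adversarial topologies.
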