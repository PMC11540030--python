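# Methods

This note documents the models and procedures implemented in
`resistoscope`, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical choices
that matter for reproducibility.

## Coordinate model and conventions

Structures are read with gemmi (mmCIF and PDB, gzip accepted,
multi-model files supported; the first model is used unless one is
requested). The in-memory model keeps author residue numbering
throughout — deposited NLR structures and their figures are discussed
in author numbering, and insertion codes order alphabetically after the
same number. Waters are dropped on read; other heteroatoms (ATP,
lipids) are kept with a `het` flag and excluded from protein-only
selections and from all contact/SASA computations unless requested.
Alternate locations collapse to the highest-occupancy atom, ties broken
by altloc id — deterministic and standard practice. Hydrogens are
retained at the I/O level for round-trip fidelity but ignored in every
distance computation, since cryo-EM models effectively lack them.

Domain annotation is range-based. The shipped NbNRC2 map is
α1 1–26, CC 27–133, NB 156–303, HD1 315–376, WHD 392–497, LRR 497–882;
the WHD/LRR ranges share boundary residue 497, which the map resolves
by earlier-label precedence (497 → WHD, LRR effectively 498–882), so
annotation is always a partition into labels plus "unassigned" (the
inter-domain linkers, e.g. 134–155). Author numbering was assumed for
these ranges; entity (label_seq) numbering is never used.

## Cyclic symmetry

A Cn assembly maps onto itself under rotation by 360°/n, permuting its
m chains by m/n positions. Detection therefore scores each candidate
order n dividing m by the Cα mapping RMSD of the Kabsch superposition
of the assembly onto its shifted self (residues paired by number within
mapped chains). Orders with RMSD ≤ `rmsd_accept` (default 3.0 Å —
tolerant of local deviations, rejecting accidental matches) are
acceptable; if none is, order 1 is returned.

One subtlety: a true C6 assembly also matches C2 and C3 with
near-identical RMSD (the divisor permutations are compositions of the
one-step map), so picking the raw RMSD minimum would let measurement
noise decide between 2, 3 and 6. The detector instead returns the
highest acceptable order whose RMSD lies within a small band of the
best (10% relative + 0.05 Å absolute). This is what makes the
generator/detector inverse exact for every n: a constructed Cn ring is
always reported as Cn, not as one of its divisors.

The axis is estimated independently of the order: the point is the
centroid of chain centroids and the direction the least-squares normal
of the centroid ring, oriented so the chain sequence winds
counterclockwise. Both transform covariantly under rigid motion of the
assembly, which the tests assert.

## Superposition and conformational decomposition

All rigid fits are Kabsch SVD fits with reflections excluded
(det = +1); collinear point sets raise rather than returning an
arbitrary rotation. Rotation angles are reported in [0°, 180°] via
arccos((tr R − 1)/2), with handedness available from the screw axis.

Pruned alignment pairs Cα by author residue number within
corresponding chains (identical-sequence assumption; non-identical
sequences would need an externally supplied pairing and are out of
scope). Each iteration fits on the retained pairs and drops, in one
batch, every pair farther than the cutoff (default 2.0 Å, max 100
iterations). Batch dropping is deterministic and converges in a few
iterations; because published "matchmaker-style" pruned RMSDs rarely
state their exact settings, results always carry both the pruned RMSD
and the unpruned RMSD of all matched pairs under the final transform.
Unmodeled residues (e.g. a disordered inter-domain linker present in
one state only) are silently excluded from pairing; the matched and
retained counts are part of every result.

Chain correspondence between two ring assemblies of equal
stoichiometry is found exhaustively over the n cyclic shifts in both
ring orientations (2n candidates), minimizing whole-assembly Cα RMSD.

The module-rotation decomposition answers "by how much does one domain
block rotate relative to another between two conformational states":
superpose state 2 on state 1 using the anchor module's shared Cα
(≥10 required), then take the Kabsch rotation of the mobile module in
that frame. Each module's internal RMSD after its own best fit is
reported as a rigidity check — on synthetic two-state fixtures it is
asserted to be far below the inter-state displacement; on real
structures it is reported, not asserted, since real "rigid" modules
flex. A generic three-centroid angle utility is provided for
interdomain-angle measurements, but no specific vector definition is
endorsed: published interdomain angles usually leave the definition
unstated, so the choice of centroids is the user's.

## Interfaces

Contacts are residue pairs whose minimum heavy-atom distance is within
the cutoff. The default cutoff is 5 Å (the common cataloguing choice
for interface residues); predicted-vs-experimental contact comparison
uses 4.5 Å. The k-d tree search is exact, and the test suite verifies
it against an all-pairs brute-force oracle on 50 seeded random
fixtures at both cutoffs. Reported distances are minima over a chosen
atom scope (all heavy atoms, side-chain heavy atoms, or Cα); because
published figure distances rarely name their atoms, every record
carries the achieving atom pair for auditability, and the side-chain
scope is the default when reproducing printed residue-pair distances.

Category assignment inside `find_contacts` uses the full side-chain
geometry of the pair (a salt bridge is recognized even when the closest
atom pair is carbon–carbon); the standalone `classify_contact` applies
the same thresholds to a record's achieving pair alone. Thresholds:
acidic carboxyl O to Arg/Lys/His side-chain N ≤ 4.0 Å → salt bridge;
N/O–N/O ≤ 3.5 Å → polar; otherwise nonpolar.

SASA is Shrake–Rupley sphere sampling with a deterministic golden-
spiral point set (default 960 points, probe 1.4 Å) over a bundled
element radius table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å, plus
halogens and common metals). The isolated-atom closed form
4π(r + probe)² is reproduced within 2%, and totals agree with an
independent implementation (biotite) within 5% in the tests. BSA is
half the SASA lost on complexation; it is symmetric by construction
and zero for non-touching chain groups within sampling tolerance.

## Pore geometry

Ring diameters at a named residue/atom come in two definitions. The
"opposite" method (even n only) averages the distances between
diametrically opposite chains — the convention behind Cα–Cα pore
widths quoted for hexamers. The "axis" method, 2 × mean distance to
the symmetry axis, is the general definition valid for pentamers and
is the documented common scale when comparing C5 and C6 pores; on
ideal even rings the two agree to within 0.2 Å (exactly, for perfect
geometry).

The axial radius profile is a slab-minimum approximation: at stations
spaced `step` (default 1.0 Å) along the axis, the radius is the
minimum over slab atoms of (distance to axis − vdW radius), floored at
zero. It is cheap, deterministic and adequate for locating and sizing
constrictions; it is *not* a Monte-Carlo probe fit in the style of
HOLE and can underestimate radii in strongly off-axis channels. A
small (1e-9 Å) membership margin keeps atoms that fall exactly on a
slab boundary in the same slab after rigid motion of the assembly.
Profiles use vdW-corrected radii; diameters quoted for comparison with
Cα–Cα figures are Cα-based.

Pore chemistry uses a fixed residue-type table (D/E acidic; K/R/H
basic; S/T/N/Q/Y/W polar; the rest hydrophobic); a set of rings is
"mixed" unless unanimous.

## Predicted-model confidence

Metadata JSON files are parsed tolerantly: flat layouts with aliased
key names (`ptm`/`pTM`, `chain_ptm`/`per_chain_ptm`, ...) are accepted
and unknown keys ignored, since predictor output schemas drift. Real
summary files do not label chain types, so stoichiometry inference
prefers an explicit `chain_types` list (protein chains counted, ligand
copies such as bulk lipids excluded — the synthetic generator emits
this), then an explicit `stoichiometry` field, then the chain count.
When a directory contains ranked siblings (`*_model_0.json`,
`*_model_1.json`, ...), only the top-ranked model per run is retained.

Stoichiometry ranking groups records by protein-chain count and takes
medians (and interquartile spreads) of pTM, ipTM and the minimum
per-chain pTM across seeds; the ranking order is median ipTM, then
median pTM, then median min chain pTM. The metrics are usually
reported side by side without a composite, so this tie-break order is
a repository convention, chosen because ipTM is the interface-
sensitive score and oligomer stoichiometry is an interface question.
Confidence tiers follow the common conventions: below 0.6 on pTM or
ipTM → low; 0.7 or higher on pTM, ipTM and min chain pTM →
confident; otherwise moderate.

The prediction report combines, for one model/reference pair: the
cyclically-paired pruned-RMSD alignment, the fraction of reference
interface contacts (4.5 Å) recovered by the model (pooled and per
adjacent-chain interface), and the confidence tier.

## Synthetic generators

The toy protomer is five stacked ideal α-helical segments (1.5 Å rise,
100° twist per residue, Cα radius 2.3 Å; 20 residues per segment by
default) labeled with the five-domain CC/NB/HD1/WHD/LRR layout; each
residue carries N, CA, C, O, CB pseudo-atoms. One designated residue's
Cα sits exactly on the protomer axis so that ring diameters of built
assemblies are known in closed form. Ring fixtures place the protomer
at ring radius 9.5 Å (matching the ~19 Å Cα pore scale of real
hexamers) and replicate it by exact rotations; planted contacts are
realized by marker atoms positioned so that every adjacent-chain pair
hits its target distance exactly, with a feasibility check that errors
if pre-existing geometry comes closer than the target. Two-state
fixtures rotate the NB+HD1 analogue about a hinge through the module
boundary by a configurable angle (default 180°, the scale of the
resting-to-active NB-ARC rearrangement in helper NLRs). Confidence
grids default to stoichiometries 4–8 with 10 seeds each, base score
0.65, spread 0.02 and a +0.1 shift planted on the hexamer — the design
used when ranking candidate oligomeric states.

Noise, when requested, is i.i.d. Gaussian per coordinate with the
given σ; for two independently noised copies the expected pairwise Cα
RMSD is √6·σ (≈0.73 Å at σ = 0.3), and the tests freeze empirical
bands from the generator's own statistics rather than guessing. All
randomness flows through numpy's PCG64 generator seeded from the
fixture spec, so outputs are byte-identical across platforms; ground
truths are returned as dictionaries and written as JSON sidecars next
to on-disk fixtures. Fixtures are written as standard mmCIF so the
I/O layer is exercised by every downstream test.

What the generators do not emulate: real side-chain rotamers and
stereochemistry (residues are poly-alanine-like), crystallographic
disorder, partial occupancy, sequence differences between chains, and
realistic inter-atomic packing (adjacent toy protomers can clash).
Passing tests therefore demonstrate the correctness of the geometry,
search and aggregation machinery under known ground truth — not that
biological interpretation thresholds (e.g. the 5 Å interface cutoff)
are optimal for real structures.

## Problem sizes and degenerate inputs

Test and acceptance runs use 100-residue protomers (500 heavy atoms
per chain, up to 12 chains), 50-fixture brute-force contact
comparisons, 960-point SASA sampling (240 points for BSA symmetry
checks, 8000 for the dense-sampling oracle), and 20 independent
confidence grids of 50 models each; the whole suite runs in well under
a minute on one CPU. Degenerate inputs are errors, not silent
results: fewer than 3 chains for axis estimation, collinear point sets
for Kabsch, pruning that leaves fewer than 3 pairs, unknown elements
in SASA, empty chain selections, and same-residue distance queries all
raise with messages naming the offending entity.

## Known limitations

* Sequence-identical chains are assumed wherever residues pair by
  number; no sequence alignment engine is included.
* Dihedral, helical and icosahedral symmetries are out of scope, as is
  the dimer-of-hexamers (dodecamer) stacking occasionally seen for
  helper-NLR particles.
* The slab-minimum pore profile underestimates radii for tilted or
  off-axis channels.
* Reproduction tests against deposited experimental structures require
  those files locally (`scripts/fetch_structures.py`); they are
  multi-megabyte entries and are not redistributed with the package.
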