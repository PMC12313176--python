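# Methods

This note records the models and procedures implemented in `pmhclens`, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the package's numerical conventions and limitations.

## Structure model

Structures are read from PDB or mmCIF via gemmi. Waters and non-polymer
heteroatoms are dropped; alternate locations collapse to the
highest-occupancy conformer (ties broken by altloc identifier) so every
analysis sees a single deterministic conformer. Hydrogens, when deposited,
stay in atom lists but are excluded from all heavy-atom computations:
typical ~2 Å crystal structures lack them, and no result should depend on
their presence. Nonstandard residues outside the peptide are kept and
flagged rather than dropped, since chaperone chains may carry
modifications.

Chain roles (binder, MHC heavy chain, β2-microglobulin, peptide, chaperone)
are assigned heuristically: the peptide is the shortest chain of class I
length (8–13 residues); the MHC heavy chain is a ~250–300-residue chain
contacting the peptide most; β2M is a ~90–110-residue chain contacting the
heavy chain; the binder is the remaining chain with the largest peptide
contact count. Ties raise an error asking for explicit hints, and hints
always override the heuristics (with a recorded warning when they
contradict the evidence — e.g. a peptide hint on a chain outside the class
I length range). Toy complexes are far smaller than real MHC molecules, so
their groove mimic is labelled by hint; the heuristic sizes target real
depositions. Peptide positions are 1-based from the N terminus everywhere,
regardless of author numbering; author numbers are preserved for reporting
and for cross-structure footprint comparison.

## SASA and buried surface area

SASA uses Shrake–Rupley sphere sampling: each heavy atom is inflated by the
probe radius (default 1.4 Å, water) and sampled with a deterministic
Fibonacci spiral (default 960 points/atom); a point is accessible when
outside every neighbouring inflated sphere. Radii are the Bondi (1964)
van der Waals set, by element, with 1.8 Å for anything unlisted.
Determinism and auditability drove the choice: the same input always gives
the same area, and the quadrature is independently checked in the tests
against a latitude-longitude grid integrator (agreement ≤1% on small
clusters) and the closed form 4π(r+w)² for an isolated atom (≤0.5%).

Because the sample directions are fixed in space, a naive implementation
would not be invariant under rigid motion of the input. Coordinates are
therefore first moved into an intrinsic principal-axis frame (centroid at
the origin, axes by descending covariance eigenvalue, signs fixed by the
third moment), which makes SASA exact-invariant under rotation and
translation of the file. Within one BSA evaluation all three SASA calls
(side A alone, side B alone, complex) share a single frame, so separated
chains bury exactly zero and per-residue burial is an exact difference.
Congruence identities that the quadrature cannot represent exactly (e.g.
two sides related by a rotation burying identical area) hold to quadrature
resolution, about 1% at the default point count.

Buried surface area is reported in the per-side-average convention,
`BSA = [SASA(A) + SASA(B) − SASA(AB)] / 2`, with both one-sided burials
also emitted, because published totals do not always state their
convention. The peptide fraction divides target-side burial between the
peptide chain and the MHC chains.

## Contacts and polar bridges

A residue is an interface contact iff at least one heavy-atom pair across
the interface is within the cutoff (default 4.5 Å, exposed as
configuration; contact counts are criterion-sensitive and every report
carries the criterion used). Hydrogen bonds use a distance-only criterion
(donor-capable heavy atom to acceptor-capable heavy atom ≤3.5 Å) from a
fixed per-residue donor/acceptor table — a deliberate simplification since
donor hydrogens are absent; no angular term is applied. Salt bridges pair
side-chain N of Lys/Arg/His with side-chain carboxylate O of Asp/Glu within
4.0 Å; His-mediated bridges are flagged because protonation at
crystallization pH is unknown.

## Docking geometry

The groove axis is the first principal component of peptide Cα coordinates,
oriented N→C. The platform normal is the least-squares plane normal of the
Cα atoms of MHC residues contacting the peptide (self-contained and
allele-agnostic). The binder axis is the principal component of the Cα
atoms of the two longest contiguous runs of binder contact residues — the
interface-dominant helices — projected into the platform plane; when the
interface is too sparse to trace runs (fewer than four contact Cα, as in
minimal toys) the whole chain is used and the result flagged. The docking
angle is arccos of the absolute in-plane dot product, in [0°, 90°],
invariant to axis sign flips and global rigid motion. The axis conventions
are versioned (`convention_id`) since published crossing angles rarely
state theirs.

Superposition is closed-form Kabsch (SVD with reflection correction); the
returned rotation is proper to machine precision and the optimum is
cross-checked in tests against an independent solver and against random
rigid transforms.

## Off-target screen

The screen operates on a single-length ligandome (mixed lengths are
rejected; the screen never mixes lengths). Every entry is ranked by Hamming
distance to the target with deterministic (distance, lexicographic)
ordering. Selection keeps organism-matching entries (case-insensitive
string match on the annotation column; no taxonomy resolution) whose
distance equals the minimum over the organism-matching, non-identical
subset — so a closer foreign peptide cannot mask the relevant candidates.
The motif pass adds organism-matching entries identical to the target at
every motif position (default {4, 5}, the Met-Trp bulge of the NY-ESO-1
9-mer), whatever their overall distance; the panel is the provenance-tagged
union. The target itself, if present, stays in the ranking but is never a
candidate. All tie-breaks are lexicographic so reports reproduce byte for
byte.

## Off-target scoring

A likelihood engine maps a peptide to a per-position cost (negative-log-
likelihood-like; lower = better fit to the fixed structural context); the
off-target score of a candidate is `Δ = cost(candidate) − cost(reference)`,
so the reference scores exactly 0 and more negative means more compatible.
The built-in baseline engine is deliberately simple and fully
deterministic: `cost(p)ᵢ = wᵢ · d(refᵢ, pᵢ)` with nonnegative position
weights summing to 1 and a BLOSUM62-derived substitution dissimilarity
`d(a,b) = (s(a,a)+s(b,b))/2 − s(a,b)` (symmetric, zero diagonal). Weights
default to the per-position peptide burial of the interface fingerprint;
a hotspot alternative puts all weight on the motif positions, reflecting
the experimental observation that only the hotspot positions are
indispensable. Neural inverse-folding engines integrate through an adapter
that reads an exported per-position log-probability table (TSV, rows =
positions, columns = 20 amino acids); the network itself is never bundled
or reimplemented, and no claim is made to reproduce any specific engine's
score values — the reproducible content is the ordinal ranking. Whether a
published "likelihood" sums or averages over positions is generally
unstated; costs here sum, which leaves rankings unchanged.

## Design triage

PAE matrices are read from the AlphaFold JSON dialect with chain spans from
an embedded mapping, a sidecar file, or caller-provided lengths. iPAE is
the mean of the symmetrized matrix `(v[i,j]+v[j,i])/2` over binder↔target
inter-chain pairs (selector recorded; a contact-pair mode restricts to an
explicit list). "Under a threshold of 10.0" is implemented as strict `<`,
configurable. Scaffold bookkeeping counts passing designs, pass rates, and
flags a scaffold as a hit iff at least one design passes.

## Synthetic generators

Every generator is a pure function of (plan, seed): identical inputs give
byte-identical files, and each output ships with a JSON manifest holding
the planted ground truth, which is the only thing downstream checks read.

*Ligandome*: background 9-mers are sampled from an anchor profile emulating
the HLA-A\*02 motif (position 2 favouring L/M/I, position 9 V/L/I) — a
plausible emulation, not a fit to any measured atlas. Planted entries
realize exactly their planned Hamming distance and motif status; background
entries are constrained to at least Hamming distance 7 from the target
(configurable) with the motif broken, so the planted panel is recoverable
by construction. The default planted design — five human distance-4
neighbours plus motif-preserving entries at distances 5 and 6 over a
500-peptide background — mirrors the structure of a real mass-spectrometry
immunopeptidome screen at desk scale. What the generator does *not*
emulate: realistic position-specific amino-acid frequencies beyond the two
anchors, source-protein structure, or presentation thermodynamics; passing
screens on synthetic data therefore validates the selection logic, not any
biological claim about a particular proteome.

*Toy complexes*: the peptide is an extended strand (Cα every 3.8 Å);
binder and groove chains are ideal α-helices (rise 1.5 Å/residue, 100°
twist, Cα radius 2.3 Å) with interpolated backbone N/C and radially placed
O/Cβ. Paired binder helices run with 180°-offset phases so the pooled Cα
wobble cancels and the bundle's principal axis equals the construction
direction exactly — this is what lets angle-recovery tests assert ±0.5°.
Designed cross-chain contacts are realized by placing the named side-chain
atoms on the inter-Cα line at the exact planned distance (side-chain reach
limited to 0.5–5.5 Å; infeasible plans error out), and cross-chain clashes
under 2.0 Å are rejected. No rotamer realism is attempted.

*PAE*: block-structured matrices with planned per-block means, optional
clipped Gaussian noise, zeroed diagonal; the manifest records the exact
realized symmetrized inter-chain means, which iPAE must reproduce
(exactly at zero noise).

## Problem sizes and defaults

Tests and the acceptance script run on toy complexes of a few hundred
atoms, ligandomes of ~60–500 peptides (100 seeds for recovery and
brute-force-equivalence checks), and PAE matrices of tens of residues —
sizes chosen so the whole suite exercises every code path in seconds while
the oracles (grid integration, exhaustive filters, direct optimizers)
remain cheap to evaluate. Reproduction of published crystal-structure
quantities runs on the real depositions when those files are available
locally or fetchable; the fetch helper is never called implicitly.

## Known limitations

- Distance-only H-bond criterion (no angles, no hydrogen placement);
  counts at 3.5 Å are criterion-sensitive.
- Contact counts depend on the cutoff; comparisons across binders are only
  meaningful at one shared, reported cutoff on a shared allele numbering.
- The baseline scoring engine is a structure-weighted substitution model,
  not a learned likelihood; it reproduces hotspot logic and ordinal
  behaviour, not neural engine scores.
- SASA congruence identities hold to quadrature resolution (~1% at 960
  points), though rigid-motion invariance and BSA differencing are exact
  via the canonical frame.
- Role assignment presumes a class I complex; class II, multi-peptide or
  multi-binder assemblies need explicit hints.
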