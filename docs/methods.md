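# Methods

## Scope and model of the screen

`pgpscreen` implements every computation of a counter-selective,
multi-conformation virtual screen against P-glycoprotein and of its
downstream cell-assay analysis. External engines — molecular dynamics for
receptor generation, AutoDock Vina for docking, QSAR/property servers —
are treated as producers of parseable inputs: the package defines the
receptor manifest they are driven from and ingests their outputs, but does
not reimplement them. A deterministic mock docking engine with planted
affinity landscapes substitutes for the external engine in tests and in
the reproduction script; it is an abstraction for pipeline testing, not a
physical model.

## Drug-likeness filter

The library filter keeps molecules satisfying, simultaneously:
150 < MW < 500 g/mol, logP < 5, TPSA < 150 Å², H-bond donors < 5,
acceptors < 10, rotatable bonds ≤ 7, and no aldehyde or thiol group.
All bounds are strict except rotatable bonds, which is inclusive — the
boundary cases (MW exactly 500 rejected, 7 rotatable bonds retained)
follow the rule's standard phrasing and are pinned by tests. A molecule
failing several criteria is counted once per criterion in the filter
history but removed once, so the history explains rejections while
retained + rejected + descriptor-failures = input size holds as a
conservation law over records.

Descriptor definitions follow the calculator, which is a pluggable
contract (`PropertyCalculator`); the default uses RDKit (Crippen logP,
Ertl TPSA, RDKit's rotatable-bond definition, which excludes amide C–N
bonds). Different descriptor software disagrees near boundaries; pinning
the calculator in provenance is the reproducibility mechanism. Protonation
state is taken as given in the input structures; the assumed pH is
metadata, not a computation.

## Fingerprints, sphere exclusion, band expansion

Fingerprints are hashed circular (Morgan) substructure fingerprints,
radius 2, 2048 bits — the de-facto standard and configurable via
`FingerprintScheme`. Tanimoto similarity is |a∧b|/|a∨b| with one
documented edge case: two all-zero fingerprints score 1.0, treating
featureless molecules as mutually redundant (the alternative, 0.0, would
let them all through every diversity cutoff).

A "diversity subset at cutoff c" is built by sphere exclusion (the leader
algorithm): walk the library in input order (or a seeded shuffle, recorded
in provenance) and retain a molecule iff its similarity to every
previously retained molecule is ≤ c. Excluded molecules are assigned to
the first retained molecule exceeding the cutoff. This construction
satisfies two checkable invariants — no retained pair above the cutoff,
every exclusion covered by its representative — which the test suite
verifies by exhaustive pairwise comparison up to 10³ ligands. The
percentage language sometimes used for such sets ("a 90% set") is read
here as the similarity threshold of the exclusion sphere; a
"fraction-of-diversity-retained" reading exists but has no comparable
testable construction, so only sphere exclusion is implemented.

Similarity-band expansion returns, for each query, every pool molecule
with similarity in an inclusive band (default [0.70, 0.99]); the query
itself falls outside at similarity 1.0. Ordering is descending similarity
with ties broken by ligand id, making expansion deterministic.

## Counter-selection scoring

Docking energies convert to estimated dissociation constants by inverting
ΔG = RT·ln(K_D) with R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 310 K (matching
physiological temperature and the MD conditions the receptors come from);
K_D is dimensionless relative to a 1 M standard state. The per-pair
counter-selection ratio

    K_D^DBD / K_D^NBD = exp((ΔG^DBD − ΔG^NBD)/RT)

depends only on the energy difference (shift invariance, tested to 1e-12
relative over 10⁴ random pairs). Within a receptor pair group that has
several boxes of one domain class (e.g. one box per NBD), the tightest
(minimum) best-pose energy per domain class is used, i.e. each domain is
represented by its best predicted site.

Aggregation across conformation pairs is a genuinely open design point;
the default is the **minimum** over pairs — conservative, a ligand must
prefer the NBDs in every conformation — with geometric mean as an option.
Both are recorded in provenance. Under the min policy a ligand missing
either domain of any pair scores 0 and drops out of top-n contention
(configurable to skip missing pairs instead); missing results are never
imputed. Ranking is total and deterministic: aggregate descending, ties by
ligand id ascending, so input permutation cannot change a selection.

The two-round screen docks the diversity subset, takes the top 100 by
aggregate ratio, expands them through the similarity band, docks the
previously-undocked expansion, and merges rankings deduplicated by ligand
with the best aggregate winning; round-2 scores never overwrite round-1
scores. Subset sizes, expansion counts per query, seeds and policies go
into the outcome's provenance.

## Assay analysis

**MTT.** Percent survival per well is 100 × absorbance / mean(control
absorbance), so the control group's own wells average to exactly 100%.
Re-sensitization is a decrease of at least 30 between chemo-only and
compound+chemo survival, both computed against the same vehicle control.
The 30 is interpreted as percentage points on that shared scale (not a
relative 30% of chemo-only survival) and the threshold is inclusive;
both the interpretation and the threshold are configurable.

**LC-MS/MS.** Per sample: ratio = analyte peak / internal-standard peak;
normalized ratio = ratio / lysate content (mg/mL); group mean over
triplicates with sample SD (n−1). The ±tariquidar comparison is a
pooled-variance two-sample Student's t-test with df = n₁+n₂−2 — the
pooled (not Welch) form is deliberate: it reproduces the embedded panel's
printed p-values from printed summary statistics, which the test suite
checks to one significant figure for all 19 printed values. The test
accepts raw replicates or (mean, SD, n) summaries. Degenerate inputs are
defined, not left to chance: both SDs zero with equal means → t = 0,
p = 1; with unequal means → infinite t, p = 0, with a warning. Printed
">1" p-values are treated as p capped at 1.0. A compound is a likely
transport substrate iff some trial shows p < 0.05 **and** the mean
increased with tariquidar (direction rule); trials with analyte below
quantification in both conditions are indeterminate and never trigger a
substrate call — a compound with only such trials is indeterminate, not a
clean non-substrate.

**Daunorubicin accumulation.** Fold change is mean(compound+DAU
fluorescence)/mean(DAU alone), tested against DAU alone by the same pooled
t-test. Background subtraction is assumed already applied; an optional
blank parameter subtracts a constant when it is not.

No multiple-testing correction is applied anywhere — each trial is
reported as its own test, matching how such panels are read.

## Synthetic data: what it emulates and what it does not

The library generator assembles molecules from a small fragment alphabet —
benzene/pyridine/furan rings joined by short polar linkers — chosen so
descriptors land mostly inside the drug-likeness bounds (rings keep
rotatable bonds near the ≤7 bound, heteroatoms keep logP < 5) and no
aldehyde or thiol can form, with an optional fraction of deliberate
violators (long alkyl tails). Cluster structure is planted: each cluster
has a base molecule, and members are generated by trying several candidate
edits (tail extension, ring or linker swaps) and keeping the candidate
whose Tanimoto similarity to the base is closest to the requested
within-cluster target. This hits targets in roughly [0.3, 1.0] for this
alphabet (requests outside that range raise an error); the calibration —
ring swaps land near 0.8–1.0, unit swaps near 0.6–0.85, cross-cluster
pairs near 0.1–0.35 — was established once on the alphabet and is treated
as a property of the generator.

The planted affinity landscape gives every ligand a base ΔG per domain
class, adds a per-ligand NBD offset for planted ligands, and Gaussian
noise per ligand×target. Gaussian noise on energies and on assay readouts
is the simplest model consistent with mean ± SD reporting. Assay
generators default to the study conditions the analysis rules expect:
chemo-only survival 90%, inhibitors dropping it by 50 points, 3-fold
substrate accumulation under tariquidar (the scale of real positive
panel rows), triplicates, and replicate SD of 10% of the group mean.

None of this emulates chemistry or physics: real docking noise is not
Gaussian or independent across targets, real libraries are not cleanly
clustered, and real assay noise has plate and batch structure. Passing
tests therefore demonstrate that the *computations* are correct and that
the pipeline recovers a planted signal under its stated noise model — not
that the screen would achieve any particular hit rate on real data.

## Reproduction-script problem sizes

The recovery experiment in `scripts/acceptance.py` (and the mirror test)
uses a 1,000-ligand library in 50 clusters, 20 planted NBD-preferrers with
ΔΔG = −3 kcal/mol and noise SD 0.5 kcal/mol, a 9-box manifest (three
conformation pair groups of 1 DBD + 2 NBD boxes), cutoff 0.95, band
[0.70, 0.99], top 100, min policy. The planted offset goes on each
cluster's representative (first) molecule: a planted ligand hidden behind
a non-planted representative would never be offered to docking and could
not be recovered by construction, so planting on representatives is what
makes "recovery of planted ligands" a well-posed measure of the ranking
machinery rather than of subset luck. At ΔΔG = −3 kcal/mol the planted
ratio signal (≈130×) dominates the noise-induced background ratios by
orders of magnitude, so recovery is expected to be complete at this noise
level; the zero-noise run recovers every planted ligand that survives the
diversity subset exactly.

## Known limitations

- Sphere exclusion is order-dependent; only the given ordering's subset is
  produced (no MaxMin or k-medoid pickers).
- The 14-box example manifest illustrates a multi-conformation design; box
  geometries in it are placeholders, not curated docking boxes.
- The mock engine's pose list (best + two fixed decoys) exercises parsers
  and best-pose extraction, not pose diversity.
- Substrate classification from summaries inherits the printed precision
  of those summaries; one-significant-figure agreement is the strongest
  claim the inputs support.
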