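# Methods

This note documents the statistical models and numerical conventions
of the package, the design choices made where the published workflow
left details open, and what the synthetic data generator does and does
not emulate.

## Data model

Each worker carries 22 linear measurements in μm.  Body size is
summarised by cephalic size, CS = (CL + CWb)/2, and analysis mostly
uses dimensionless ratios: the trait/CS family plus CL/CWb, PoOC/CL,
SPST/CL, SPBA/CWb, PoOC/NOH and FRS/SL.  Ratios are computed in double
precision; measurements are stored as read (the recording protocol's
precision is about ±2 μm, and no rounding is imposed).

Hard structural invariants are always enforced (all values positive,
PoOC < CL, NOH ≤ PEH, SPBA < SPWI).  A plausibility window of
[100, 2000] μm per measurement is enforced by default when reading
files but can be disabled: the smallest sclerite measurements of small
workers (petiolar node height NOH, spiracle–excavation distance SPL)
legitimately fall below 100 μm, and the synthetic generator produces
such values.  The command-line tools read with the window disabled.

The nest sample — all workers of one colony, summarised by arithmetic
trait means — is the unit of clustering and of the identification key.
Nests whose members carry conflicting species labels are kept but
flagged and excluded from supervised fitting; the workflow gives no
rule for them, and silently picking a label would bias the fits.

## Nest-centroid clustering

Nest-mean trait vectors are z-scored per trait (population sd; a
two-nest dataset standardises to ±1) and clustered agglomeratively on
Euclidean distances under average linkage (UPGMA) and under Ward's
minimum-variance criterion in the Ward.D2 convention (Euclidean input
distances; dialects differ, so this is stated explicitly).  Merge
heights are the linkage distances, unhalved.  The exact
standardisation used by the original NC-clustering script is not
restated in its description, so z-scoring is adopted and isolated
behind one function (`centroid_matrix`) where an alternative
size-correction could be plugged in.

The number of clusters k is user-supplied: the original analysis
assessed cluster number visually from the dendrogram, and automating
that choice would overstate what the method does.

Cross-linkage congruence: both trees are cut into k groups
(`scipy` maxclust criterion), groups are matched one-to-one by
maximum overlap (Hungarian assignment), and a nest keeps a label only
when its two group memberships are matched to each other; all other
nests become wild-cards.

## Confirmatory LDA

Classical Gaussian LDA on individual workers with pooled within-class
covariance.  Class priors are equal by default: per-species sample
sizes reflect collecting effort, not abundance.  Proportional priors
are available behind a flag and change posteriors, not the discriminant
directions.  A singular pooled covariance raises immediately; an
optional small shrinkage (λ = 10⁻⁶ toward the average eigenvalue)
handles collinear traits.  Discriminant axes are sign-fixed (first
nonzero loading positive) so fits are reproducible.

Wild-card iteration: workers of hypothesis-labeled nests train the
model; each wild-card nest is assigned to the class with the highest
arithmetic mean of its members' posteriors; the model is refit with
those assignments until they stop changing (the loop is idempotent at
the fixpoint).  Oscillation beyond `max_iter` returns the last state
flagged non-converged rather than raising.

LOOCV at the individual level refits without one worker at a time; at
the nest level the entire nest is removed per refit and the nest is
predicted from its held-out mean posterior — removing the whole nest
prevents within-colony leakage, which would otherwise inflate
nest-level rates.  A unit whose removal leaves its class with fewer
than two members is skipped and reported.

Complex-level score plots center each discriminant axis on the
unweighted mean of the class score means, so a two-class model yields
exactly symmetric ± group means.

### Reduced discriminant functions

The search for the "simplest function with acceptably low error" is
greedy-forward: starting from no traits, each step adds the trait that
maximises LOOCV success of the two-group LDA on the selected set,
stopping at `max_terms` or when the best gain drops below 0.5
percentage points.  The published account names only "reduced
character number", so the stopping rule is this package's choice.  The
final coefficients are per μm; the intercept is recentred to the
midpoint of the two group score means, reproducing the published
symmetric ± score pattern, and the function is oriented so the
designated positive class scores positive.  With more than two classes
one species is contrasted against the pooled remainder, matching how
the published multi-species functions are framed.

## Identification engine

The bundled 19-couplet worker key is stored as JSON, each node
carrying its verbatim printed text alongside the machine-readable
threshold, so the encoding can be audited against the print.  Design
conventions:

- Thresholds are strict as printed; a value exactly at a threshold is
  a tie, reported, never silently assigned.  Two couplets print
  non-adjacent bounds for their two lobes (spine angle 28.5°/30°;
  PEH/CS 0.380/0.402) — values inside those gaps are ties too.
- Two couplets test geography ("replaced by more reliable data about
  geographic distribution"); they are encoded over a small region
  enumeration (mainland Europe, Anatolia/Crete, Central+West Europe,
  East Europe/Balkans/Caucasus).
- Printed inconsistencies are preserved and flagged, not corrected:
  couplet 6's comparison signs contradict its own printed branch
  statistics (flag `suspect`), couplet 7's second lobe repeats "<"
  where its range shows ">", and couplet 11's second bracketed range
  is inconsistent with a CL/CWb ratio and is stored as unreliable with
  no invented replacement.
- The key operates on nest means; single-specimen mode attaches the
  published >95% caveat to every report.
- A missing feature at a traversed couplet raises an error naming the
  couplet and feature — the engine never guesses.

The registry of published discriminant functions stores coefficients
and intercepts verbatim with each function's printed group score
means, ranges and 5–95% percentile bands at individual and (where
published) nest-mean level.  Classification is by score sign (the
class with the negative published mean is the negative-score class);
the FRS/SL entry is a plain ratio and classifies by the nearer
published group mean.  A score outside every published band is flagged
atypical.

## Decision-tree key induction

CART with Gini impurity, binary splits on continuous nest-mean ratios,
minimum leaf size 3 nests (the rpart-style defaults; the original
control parameters are unreported and are exposed as configuration),
optional depth limit and a single cost-complexity penalty.  Split
thresholds fall at midpoints of adjacent sorted values (single
precision inside the splitter).  Determinism comes from a fixed sorted
feature order; exact split ties are measure-zero on continuous ratios.

Validation mirrors the published display: the overall rate is
leave-one-nest-out (full refits); per-node rates are branch-decision
accuracies of held-out nests routed through the full tree, scoring a
node only for nests whose class occurs on exactly one side of it.
Node reliability is additionally checked by Welch two-sample t-tests
on the split feature between the two branch groups; raw p-values are
reported with Holm-adjusted values alongside.

The induced tree serialises to the same JSON schema the identification
engine reads, so `render_key` → key-engine round trips are
classification-preserving by construction, and the published key's
manual substitution of two thresholds by geography is available as a
node-replacement operation on any serialised key.

## Synthetic data generator

Workers are generated hierarchically in ratio space.  For species s,
nest j, worker i:

    CS_sij  = μ_s + u_j + e_i,          u_j ~ N(0, f·σ²),  e_i ~ N(0, (1−f)·σ²)
    r_sij   = ρ_rs + β_rs·(CS−μ_s) + v_rj + ε_ri

with the same nest-share f for every ratio, allometry slopes β
defaulting to 0, and traits reconstructed as ratio × CS (CL and CWb
solved from CS and CL/CWb; PoOC through PoOC/CL).  Ratio-space
generation matches the size-relative analysis and guarantees positive
traits; a worker that still violates a structural invariant is
redrawn, up to a bounded retry count.  Everything is deterministic
given the seed.  A log-normal CS option and optional rounding to whole
μm exist; rounding is off by default (no attempt is made to simulate
the measurement protocol's operator error structure).

Defaults are the study's design: 18 species with the per-species nest
counts of the published accounts (525 nests in total), 3 workers per
nest (the study averaged ≈3.2 and the key asks for 2–3 per nest), and
nest-level variance share f = 0.3 — the real within/between-nest split
is unreported, so f is exposed as a parameter and 0.3 encodes the
common observation that colonies differ noticeably but less than
species do.

Profile calibration.  For each species, CS and ten ratios (CL/CWb,
PoOC/CL, EL/CS, FRS/CS, SL/CS, MW/CS, SPST/CS, SPBA/CS, SPWI/CS,
SPTI/CS) take their published means; standard deviations are imputed
from published ranges by sd ≈ (max − min)/4, an approximation that
treats the range of a modest sample as ±2 sd.  The eleven remaining
trait/CS ratios are not published per species; they use genus-plausible
baselines with per-species offsets chosen for consistency with the
published key couplets (e.g. petiole node heights that place each
species on its printed side of the PoOC/NOH = 2.678 couplet) and with
the sign structure of the published discriminant functions.  One
published value is corrected: the crasecundus PoOC/CL mean as printed
lies outside its own printed range and would misroute the species in
the key, so the range midpoint is used.

Consequences worth knowing:

- Quantities built entirely from published ratios are reproduced
  closely by construction-independent recomputation (e.g. nest-mean
  SPST/CL of parvulus ≈ 0.282, FRS/SL of angustifrons ≈ 0.398, and
  the group score means of D2, both D3s, D4 subtilis|lucidus and both
  D5s).
- Functions that weight unpublished traits (D4 artvinensis-group, D4
  crassispinus|crasecundus via SPL, D7) separate the simulated species
  with the published signs but not the published magnitudes.
- Passing tests on this generator show the pipeline recovers the
  structure the generator encodes; they cannot show how the pipeline
  behaves under real measurement error, non-normal trait
  distributions, or the correlated allometry of real colonies.

Separation scaling.  For recovery tests the generator can shrink all
sds by one common factor until every pair of species profiles is at
least a requested number of "pooled sds" apart (`scale_separation`).
Separation is measured where the clustering operates — on the 22
reconstructed trait means, each coordinate scaled by the pooled
within-species trait sd implied by the profiles (delta method
combining ratio spread and body-size spread) — and is expressed in
units of the multivariate noise scale √(2p)·σ, the typical distance
between two same-species nest centroids in p dimensions.  A
per-coordinate 6-sd rule sounds strict but still lets an agglomerative
cut merge the closest species pair, because inter-point distances in
22 dimensions are dominated by accumulated noise; dividing by √(2p)
makes "6 sds apart" mean what the cluster-recovery property needs it
to mean.  Means are never moved.

## Known limitations

- The published classification rates (94% resubstitution, 93% LOOCV,
  98.5% of nest means) can only be verified against the original
  supplementary dataset, which is not redistributable inside this
  repository; the refit tests look for it at
  `data/s3_morphometrics.csv` and fail without it.  On synthetic data
  at the same scale the pipeline produces rates of the same order
  (≈96/96/99), but that is a property of the generator's calibration,
  not a verification.
- Equal priors and the classical pooled-covariance model are
  assumptions; the original analysis does not state its prior
  convention, so printed rates are matched within tolerance, not
  bit-exactly, even with the original data.
- The key engine preserves the print's errors (couplets 6, 7, 11) by
  design; users identifying parvulus-complex material should rely on
  the discriminant functions, as the published differential diagnoses
  themselves recommend.
- No queen or male morphometrics; the worker caste only.
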