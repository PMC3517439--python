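# Methods note

This note records the model, the numerical choices, and the defaults
used throughout `tehop`, in enough detail to re-derive or challenge any
number the package prints.

## Sequence model

All distances assume the Kimura two-parameter (K80) substitution
model: a single transition/transversion rate ratio κ, equal base
frequencies, independent sites. With transition proportion *P* and
transversion proportion *Q* between two sequences,

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)   substitutions/site.

Sites where either residue is a gap or `N` are excluded; a comparison
with no usable sites raises an error rather than returning a silent
zero. When the argument of either logarithm is non-positive the
distance is undefined — the pair is *saturated* and a dedicated
exception is raised, never `inf` or a clamped number.

The simulator uses the exact K80 finite-time transition probabilities
(with β = 1/(κ+2), α = κ/(κ+2)):

    P(d) = ¼ + ¼e^(−4βd) − ½e^(−2(α+β)d),   Q(d) = ½ − ½e^(−4βd),

so simulated divergences are unbiased at any depth, including near the
0.25-per-offdiagonal equilibrium. Default κ = 2.

## Consensus and family divergence

A family consensus is the per-column majority base over aligned copies,
after dropping columns whose gap fraction exceeds 0.5; base ties break
alphabetically (A < C < G < T) for determinism. Family divergence is
the mean ± sample SD (ddof = 1), in percent, of per-copy K2P distances
to this consensus, restricted to copies covering at least 70% of the
ungapped consensus length. The consensus approximates the ancestral
active element, so this mean measures time since the amplification
burst under a neutral-decay model (TE copies are generally dead on
arrival and evolve at the host's neutral rate).

## Relative-age dating

Absolute neutral rates per genome are unknown, so ages are obtained by
scaling against a calibration family in the *same* genome whose
expansion age is bracketed phylogenetically:

    age_bound = (d_family / d_calibration) × calibration_age_bound.

The mammalian calibration (TIGGER1) is bracketed 100–190 MYA (after
the marsupial/placental split, before the placental radiation); the
ant calibration is a single 140-MYA point ("as old as ants
themselves"), which yields an upper bound only. A calibration may be
measured in a third genome (the ant case): the window carries a
`divergence_genome`, and rows from that genome are treated as
calibration sources, not dated against themselves.

Phylogenetic constraints (e.g. a placental family cannot predate the
100-MYA placental radiation; a family shared by cattle and dolphin
via their common ancestor cannot predate the ~90-MYA ruminant/cetacean
group) are applied *after* the raw scaling, are recorded on the
estimate, and raise an error if the cap falls below the raw lower
bound. Reported ages are rounded half-up to integer MYA.

## Neighbor joining and bootstrap

NJ uses the Studier–Keppler Q-criterion; ties are broken by the
lexicographically smallest taxon-label pair so results are
permutation-invariant. Negative branch lengths are clamped to zero
with the deficit transferred to the sister branch (total path lengths
preserved). The final three clusters are joined by the three-point
formulas; output is an unrooted dendropy tree. On additive matrices
the true topology and branch lengths are recovered exactly (tested
against random 5-taxon trees and cross-checked against scikit-bio).

Bootstrap: Felsenstein column resampling with replacement, supports as
integer percentages written as internal-node labels (MEGA convention).
Replicates whose distance matrix contains a saturated pair are
dropped; if more than 50% drop, the run errors instead of reporting
supports from a biased sample.

## HT verdicts

For two genomes separated at `split_age`, vertical inheritance of a
shared family predicts a consensus-to-consensus divergence of

    expected = min(2 × rate × split_age, 75%)

where `rate` (substitutions/site/MY) is calibrated per genome as
d_calibration / calibration-window midpoint, and 75% is the K80
saturation ceiling (expected divergence of unrelated sequences). The
test statistic is ratio = observed / expected:

- ratio < 0.25 → **HT-supported**
- ratio ≥ 0.75 → **vertical-plausible**
- otherwise → **indeterminate**

Observed divergence comes from a global Needleman–Wunsch alignment of
the two consensuses (match +1, mismatch −1, gap −2). Forcing truly
unrelated sequences through a global alignment yields ~51% identity
and a spurious K2P of ~0.55–0.62 — below the analytic ceiling — so
pairs under **60% alignable identity** (the classic DNA "twilight
zone") are declared saturated and scored at the ceiling. This keeps
calibration-family controls stably on the vertical side without tuning
the verdict thresholds.

Dollo parsimony supplies the corroborating patchiness evidence: under
a single gain at the MRCA of the presence set, the implied number of
independent losses is the count of maximal presence-free subtrees
below that MRCA (verified in tests against brute-force enumeration of
internal states).

## Copy finding

`find_copies` is a word-seeded ungapped extender: exact 11-mer seeds
on both strands, X-drop 20 extension with match +1 / mismatch −2,
hits reported at ≥60% identity and ≥100 bp, overlapping hits merged
per strand. It is intended for counting near-intact copies in
simulated or small real genomes, not as a general aligner.

## Simulator

`simulate_ht_scenario` evolves a shared focal-family ancestor on an
ultrametric species tree: donor-lineage genomes carry copies diverged
by rate × burst_age, recipient genomes by rate × transfer_age, and
each genome additionally carries an independent calibration family of
its own. Defaults used in tests and examples: element length
1500–2000 bp, 30–40 copies per family, rate 0.001 subs/site/MY,
calibration burst 145 MYA, transfer 80 MYA. Copies within a family
are conditionally independent given the ancestor (a star phylogeny —
no master-gene lineage, no within-family subfamily structure), indels
are off by default (geometric length, mean 3, when enabled), and there
is no selection, GC bias or rate variation across sites. Ground truth
(true ages, donor/recipient roles) is written alongside the FASTA
output; all generation is deterministic per seed.

## Limitations

- K80 only; no gamma rate variation or unequal base frequencies, so
  deep distances are mildly underestimated relative to richer models.
- Relative dating inherits the calibration's uncertainty wholesale and
  assumes a shared neutral rate between the family and the calibration
  family within a genome.
- The 0.25 / 0.75 ratio bands and the 60% identity floor are
  conventions, not fitted quantities; borderline cases are deliberately
  reported as indeterminate.
- The simulator's star-phylogeny families make consensus reconstruction
  easier than in real genomes with nested subfamilies.
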