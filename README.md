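# tehop

Detection and relative-age dating of horizontally transferred
transposable elements (TEs), built around the classic line of evidence:
TE families whose sequences are far more similar across two genomes
than the host species' divergence time allows, and whose distribution
across the host phylogeny is patchy, were probably moved by horizontal
transfer (HT) rather than inherited vertically. The motivating case is
the *Mariner* superfamily of cut-and-paste DNA transposons, where
near-identical families occur in both insect and mammalian genomes that
diverged on the order of a billion years ago.

The package is aimed at researchers in molecular evolution who want a
tested, scriptable version of this inference chain — from aligned TE
copies all the way to HT verdicts — plus a simulator that generates
data with known ground truth for validating every stage.

## What it computes

1. **Consensus reconstruction** (`family_stats.build_consensus`):
   per-column majority over aligned copies (gap columns above a 0.5
   fraction dropped; ties broken A<C<G<T), approximating the ancestral
   active element.
2. **Kimura two-parameter distance** (`family_stats.k2p_distance`):
   with transition proportion *P* and transversion proportion *Q*,

   d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

   computed over columns where both residues are unambiguous bases.
3. **Family divergence** (`family_stats.family_divergence`): mean ± SD
   (in %) of per-copy K2P distances to the consensus, over copies
   covering ≥70% of the consensus — a proxy for time since the family's
   amplification burst.
4. **Relative-age dating** (`dating.estimate_age_range`): a calibration
   family whose expansion age is bracketed by phylogenetic events (for
   the mammalian calibration: after the marsupial/placental split at
   190 MYA, before the placental radiation at ~100 MYA) shares its
   genome's substitution rate with the family of interest, so

   age_bound = (d_family / d_calibration) × calibration_age_bound,

   with explicit phylogenetic caps applied afterwards (never silently).
5. **NJ phylogeny with bootstrap** (`phylogeny`): Saitou–Nei neighbor
   joining on K2P matrices (Studier–Keppler criterion, deterministic
   tie-breaks) and Felsenstein column-resampling bootstrap supports.
6. **HT verdicts** (`ht_pipeline`): observed consensus-to-consensus
   divergence compared with the vertical expectation
   2 × rate × split_age (capped at a 75% saturation ceiling); the ratio
   observed/expected drives the verdict (HT-supported below 0.25,
   vertical-plausible at ≥0.75), and Dollo parsimony counts the losses
   a vertical scenario would require.
7. **Synthetic data** (`synthetic_data`): exact-K80 sequence evolution,
   amplification bursts of known age, and transfer scenarios on an
   ultrametric species tree — the ground truth for every test.

## Worked example

`examples/04_published_survey_dating.py` dates every family in the
bundled published divergence survey:

```text
        family genome  raw_min  raw_max        reported
Mariner-1_Tbel   Tbel     70.8    134.4   100 to 71 MYA
Mariner-1_Tbel    EEu     69.3    131.6   100 to 69 MYA
Mariner-1_Tbel    PBa     43.9     43.9 at most ~44 MYA
Mariner-1_Tbel    HSa     50.1     50.1 at most ~50 MYA
   Mariner1_BT     BT     85.0    161.4    90 to 85 MYA
   Mariner1_BT    TTr     62.8    119.3    90 to 63 MYA
```

Reading: in the tree shrew (Tbel), the family's divergence ratio
against TIGGER1 (15.0/21.2) scales the 100–190-MYA calibration window
to a raw 71–134 MYA; since a placental family cannot predate the
placental radiation, the upper bound is capped at 100 MYA. The ant
families (PBa, HSa) get upper bounds only, because the ant calibration
is a single "common ancestor of all ants" age (140 MYA). These young
ages — against insect/mammal splits of ~1,000 MY and >95% cross-genome
consensus identities — are what makes vertical inheritance untenable.

`examples/02_detect_horizontal_transfer.py` runs the whole pipeline on
a simulated transfer (insect → mammal at 80 MYA) and prints:

```text
age estimates (MYA):
  focal@insect1: at most ~152 MYA
  focal@mammal1: at most ~80 MYA
HT verdicts:
  focal@insect1 vs focal@mammal1: HT-supported (ratio 0.000, identity 100.0%)
  calib@insect1 vs calib@mammal1: vertical-plausible (ratio 1.000, identity 51.0%)
Dollo losses implied by the focal family's distribution: 2
```

The recipient's copies date to the transfer age (80 MYA), not the
family's age, and the cross-genome comparison is flagged HT-supported
while the independent calibration families look vertical.

There is also a thin CLI (`tehop simulate|consensus|divergence|identity|date|tree|detect|run`)
wrapping the same functions for shell use.

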