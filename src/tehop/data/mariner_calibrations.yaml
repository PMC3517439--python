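# Calibration windows, phylogenetic caps and deep split ages used to date
# Mariner families in the published divergence survey. Genome labels:
# Tbel = Tupaia belangeri (tree shrew), EEu = Erinaceus europaeus (hedgehog),
# BT = Bos taurus, TTr = Tursiops truncatus, PBa = Pogonomyrmex barbatus,
# HSa = Harpegnathos saltator, SIn = Solenopsis invicta.
calibrations:
  - genome: Tbel
    family: TIGGER1
    age_min: 100
    age_max: 190
    rationale: >
      TIGGER1 is common across placentals but essentially absent from
      marsupials, so it expanded after the marsupial/placental split
      (190 MYA) and before the placental radiation (~100 MYA).
  - genome: EEu
    family: TIGGER1
    age_min: 100
    age_max: 190
    rationale: same TIGGER1 bracketing as in the tree shrew
  - genome: BT
    family: TIGGER1
    age_min: 100
    age_max: 190
    rationale: same TIGGER1 bracketing, bovine genome
  - genome: TTr
    family: TIGGER1
    age_min: 100
    age_max: 190
    rationale: same TIGGER1 bracketing, dolphin genome
  - genome: PBa
    family: Mariner-28_SIn
    divergence_genome: SIn
    age_min: 140
    age_max: 140
    rationale: >
      the oldest known ant Mariner families (e.g. Mariner-28_SIn) may
      have expanded in the common ancestor of all ant species (140 MYA);
      a point calibration yields an upper bound only. The calibration
      divergence is measured in the fire-ant genome under a shared ant
      substitution rate.
  - genome: HSa
    family: Mariner-28_SIn
    divergence_genome: SIn
    age_min: 140
    age_max: 140
    rationale: same ant-wide point calibration
caps:
  # placental families cannot predate the placental radiation
  Mariner-1_Tbel: 100
  # phylogenetic upper limit for the ruminant/cetacean family
  Mariner1_BT: 90
splits:
  # deep insect/mammal split, MYA (order of magnitude; any value this
  # deep saturates the expected divergence)
  - [Tbel, PBa, 1000]
  - [Tbel, HSa, 1000]
  - [EEu, PBa, 1000]
  - [EEu, HSa, 1000]
  - [Tbel, EEu, 95]
  - [PBa, HSa, 100]
  - [BT, TTr, 60]
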