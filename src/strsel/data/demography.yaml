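# Eight-population human demographic schedule.
#
# Topology: UCA -> (YRI, NWACA); NWACA -> (LWK, NACA); NACA -> (MCA, EGCA);
# MCA -> (MXL, CHB); EGCA -> (GIH, ECA); ECA -> (FIN, WECA); WECA -> (CEU, TSI).
# NWACA = non-West-African common ancestor, NACA = non-African common ancestor,
# MCA = MXL/CHB common ancestor, EGCA = European/GIH common ancestor,
# ECA = European common ancestor, WECA = West-European common ancestor.
#
# Split generations are offsets from the first split (UCA -> YRI/NWACA at 0)
# inside the 4,750-generation post-split epoch.  The offsets below are an
# approximation consistent with the split ordering; they are configurable.
# Founding proportions follow the two described patterns: splits where one
# descendant continues the resident population are peripatric (0.99/0.01);
# splits whose descendants are both dispersed daughter populations found
# each at 0.01 of the parent (as CEU and TSI do from WECA).
equilibrium_Ne: 10000
burn_in_generations: 2000
post_split_generations: 4750
growth_increment: 100
generation_years: 20.0
splits:
  - parent: UCA
    generation: 0
    children:
      - {name: YRI, proportion: 0.99}
      - {name: NWACA, proportion: 0.01}
  - parent: NWACA
    generation: 1500
    children:
      - {name: LWK, proportion: 0.99}
      - {name: NACA, proportion: 0.01}
  - parent: NACA
    generation: 2500
    children:
      - {name: MCA, proportion: 0.01}
      - {name: EGCA, proportion: 0.01}
  - parent: MCA
    generation: 3250
    children:
      - {name: MXL, proportion: 0.01}
      - {name: CHB, proportion: 0.01}
  - parent: EGCA
    generation: 3250
    children:
      - {name: GIH, proportion: 0.01}
      - {name: ECA, proportion: 0.99}
  - parent: ECA
    generation: 3750
    children:
      - {name: FIN, proportion: 0.01}
      - {name: WECA, proportion: 0.99}
  - parent: WECA
    generation: 4000
    children:
      - {name: CEU, proportion: 0.01}
      - {name: TSI, proportion: 0.01}
sample_sizes:
  CEU: 25
  CHB: 27
  FIN: 30
  GIH: 25
  LWK: 25
  MXL: 18
  TSI: 25
  YRI: 25
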