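# Two-dimensional Hofmeister scheme for dried fibrinogen precipitate
# morphology. Cations and anions each carry a kosmotropic/intermediate/
# chaotropic class; the grid rule scores kosmotropic=2, intermediate=1,
# chaotropic=0 and maps the pair's score sum to a morphology. Pairs whose
# observed morphology deviates from the idealized grid are listed as
# overrides, which take precedence.
cations:
  NA: kosmotropic
  K: intermediate      # the more chaotropic monovalent cation relative to Na+
  MG: chaotropic
  CA: chaotropic
anions:
  HPO4: kosmotropic
  H2PO4: kosmotropic
  SO4: kosmotropic
  CITRATE: kosmotropic
  CL: intermediate     # only slightly kosmotropic; fibers with Na+ only
  ACETATE: intermediate
  OXALATE: intermediate
grid:                  # score sum -> morphology
  4: dense_fibers
  3: coarse_or_local_fibers
  2: rough_nonfibrous
  1: smooth
  0: smooth
overrides:             # observed exceptions to the grid
  - {cation: K, anion: HPO4, morphology: dense_fibers}       # dense, partly coalesced fibers
  - {cation: K, anion: SO4, morphology: rough_nonfibrous}    # rough, much flatter than Na2SO4
  - {cation: NA, anion: OXALATE, morphology: rough_nonfibrous}   # rough without defined fibers
  - {cation: NA, anion: CITRATE, morphology: coarse_or_local_fibers} # fibers only at localized spots
aliases:
  SODIUM: NA
  POTASSIUM: K
  MAGNESIUM: MG
  CALCIUM: CA
  CHLORIDE: CL
  PHOSPHATE: HPO4
  HYDROGENPHOSPHATE: HPO4
  DIHYDROGENPHOSPHATE: H2PO4
  SULFATE: SO4
  SULPHATE: SO4
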