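# Phylogeny-derived classification scheme for ketosynthase (KS) and
# condensation (C) domains.
#
# The KS scheme is a three-level hierarchy (type -> class -> subclass)
# covering type I and type II PKS and FAS ketosynthases.  Class and
# subclass labels are the assignments a query domain can receive; the
# shipped KS scheme carries 41 such assignments (11 classes + 30
# subclasses).  Explicit "unclassified" buckets mark clades that fall
# inside a class but outside its functionally defined subclasses.
#
# Labels are data, not code: new classes or subclasses can be added here
# without touching the pipeline.
KS:
  type_I:
    modular_cis_AT:
      - hybrid
      - olefin_synthase
      - tandem_ECH
      - KSQ_loading
      - modular_cis_AT_unclassified
    iterative_cis_AT:
      - bacterial_aromatic
      - PTM
      - enediyne
      - PUFA
      - fungal_HR
      - fungal_PR
      - fungal_NR
    trans_AT:
      - beta_branching
      - hybrid_nonelongating
      - hybrid_trans_AT
      - trans_AT_unclassified
    type_I_FAS:
      - bacterial_FAS
      - fungal_FAS
      - protist_FAS
      - metazoan_FAS
  type_II:
    type_II_aromatic:
      - anthracycline
      - angucycline
      - tetracycline
      - aureolic_acid
      - tetracenomycin
      - pentangular_polyphenol
      - benzoisochromanequinone
      - spore_pigment
      - polycyclic_xanthone
      - type_II_aromatic_unclassified
    type_II_polyene: []
    type_II_aryl_polyene: []
    type_II_noniterative: []
    type_II_beta_branching: []
    type_II_FAS: []
    type_II_unclassified: []
C:
  NRPS:
    condensation: []
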