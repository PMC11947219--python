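# Parent-group canonical markers and sub-population annotation rules.
# Thresholds apply to mean normalised ([0,1]) marker intensity of a
# fine cluster; rules are tried in order, first match wins, cells in
# clusters matching no rule become "Other".
group_markers:
  Schwann: [S100B, SOX10]
  Myeloid: [Iba1, CD68, CD163]
  Lymphoid: [CD3, CD20]
  Vascular: [CD31, SMA]

population_rules:
  - name: Schwann_PDL1
    parent_group: Schwann
    positive: {S100B: 0.25, PDL1: 0.25}
  - name: Schwann_core
    parent_group: Schwann
    positive: {S100B: 0.25}
  - name: TAM_alternative
    parent_group: Myeloid
    positive: {Iba1: 0.2, CD163: 0.25}
  - name: TAM_classical
    parent_group: Myeloid
    positive: {Iba1: 0.2, HLADR: 0.2}
  - name: T_TEMRA
    parent_group: Lymphoid
    positive: {CD3: 0.2, CD8a: 0.2, CD45RA: 0.2}
  - name: T_CD8
    parent_group: Lymphoid
    positive: {CD3: 0.2, CD8a: 0.2}
  - name: T_CD4
    parent_group: Lymphoid
    positive: {CD3: 0.2, CD4: 0.2}
  - name: B_cell
    parent_group: Lymphoid
    positive: {CD20: 0.25}
  - name: Endothelial
    parent_group: Vascular
    positive: {CD31: 0.25}
  - name: Pericyte
    parent_group: Vascular
    positive: {SMA: 0.25}
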