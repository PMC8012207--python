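# Default cell-type marker panels for annotating clusters in early human
# cortical tissue. Gene symbols are the canonical field markers:
#   SOX2/VIM      - all progenitors
#   NES/HES5      - neurogenic program (radial glia vs neuroepithelium)
#   PPP1R17/EOMES - intermediate progenitor cells
#   DCX/STMN2     - newborn neurons
#   LUM/ALX1      - mesenchymal-like population
#   CLDN5, AIF1, PDGFRB - endothelium, microglia, pericytes
# Panels are editable; min_score is on the marker gene-score scale.
panels:
  - name: mesenchymal
    required_genes: [LUM]
    min_score: 0.5
  - name: ipc
    required_genes: [PPP1R17, EOMES]
    match_any: true
    forbidden_genes: [LUM]
    min_score: 0.5
  - name: neuron
    required_genes: [DCX, STMN2]
    match_any: true
    forbidden_genes: [SOX2]
    min_score: 0.5
  - name: endothelial
    required_genes: [CLDN5]
    min_score: 0.5
  - name: microglia
    required_genes: [AIF1]
    min_score: 0.5
  - name: pericyte
    required_genes: [PDGFRB]
    min_score: 0.5
  - name: progenitor
    required_genes: [SOX2, VIM]
    min_score: 0.5
  - name: neurogenic
    required_genes: [NES, HES5]
    match_any: true
    min_score: 0.5
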