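# Default metacluster rule table (a reconstruction of the marker->lineage
# logic used for imaging-cytometry cluster annotation; edit to taste).
# First matching rule wins; thresholds are on mean standardized intensity.
- label: Tumor (basal)
  markers_high: [panKeratin, KRT5]
  markers_low: [CD3]
  threshold: 0.5
- label: Tumor (luminal)
  markers_high: [panKeratin, GATA3]
  markers_low: [CD3]
  threshold: 0.5
- label: Tumor (other keratins)
  markers_high: [panKeratin, Ecadherin]
  markers_low: [CD3]
  threshold: 0.5
- label: Treg
  markers_high: [CD3, CD4, FOXP3]
  markers_low: []
  threshold: 0.5
- label: CD8 T cell
  markers_high: [CD3, CD8a]
  markers_low: []
  threshold: 0.5
- label: CD4 T cell
  markers_high: [CD3, CD4]
  markers_low: []
  threshold: 0.5
- label: Immunosuppressive myeloid
  markers_high: [CD11b, CD68, GranzymeB, PDL1]
  markers_low: []
  threshold: 0.5
- label: Macrophage
  markers_high: [CD68, CD11b]
  markers_low: [CD3]
  threshold: 0.5
- label: Fibroblast
  markers_high: [aSMA, Vimentin]
  markers_low: [CD31, panKeratin]
  threshold: 0.5
- label: Endothelial
  markers_high: [CD31]
  markers_low: [panKeratin]
  threshold: 0.5
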