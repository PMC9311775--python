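# Synthetic foam compressive stress-strain tables (strain, stress kPa).
# The curves are NOT digitized measurements: they are smooth synthetic laws
# with the classic foam shape (elastic toe, plateau, densification),
# calibrated so the surrogate 25% ILD on the standard 323 cm^2 indenter is
# 20 / 42 / 120 lbf for the soft / medium / hard mattress, and so the pillow
# tracks the medium-mattress law.
SM:
  csv: sm_mattress_synthetic.csv
  thickness_mm: 200.0
  poisson: 0.01
MM:
  csv: mm_mattress_synthetic.csv
  thickness_mm: 200.0
  poisson: 0.01
HM:
  csv: hm_mattress_synthetic.csv
  thickness_mm: 200.0
  poisson: 0.01
pillow:
  csv: pillow_synthetic.csv
  thickness_mm: 90.0
  poisson: 0.01
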