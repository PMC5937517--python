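# ILLUSTRATIVE grading thresholds for eight laboratory adverse events.
#
# These values emulate the shape of CTCAE v4.03 laboratory criteria but are
# NOT the official table — sites must supply their own validated thresholds.
# Units: HGB g/L; WBC, NEUT#, PLT 10^9/L; ALT, AST as multiples of the upper
# reference limit; GLU, Ca mmol/L.
- ae_term: Anemia
  soc: Blood and lymphatic system disorders
  test_code: HGB
  direction: below
  kind: absolute
  boundaries: [110, 100, 80, 65]
- ae_term: White blood cell decreased
  soc: Investigations
  test_code: WBC
  direction: below
  kind: absolute
  boundaries: [3.8, 3.0, 2.0, 1.0]
- ae_term: Neutrophil count decreased
  soc: Investigations
  test_code: "NEUT#"
  direction: below
  kind: absolute
  boundaries: [1.8, 1.5, 1.0, 0.5]
- ae_term: Platelet count decreased
  soc: Investigations
  test_code: PLT
  direction: below
  kind: absolute
  boundaries: [100, 75, 50, 25]
- ae_term: Alanine aminotransferase increased
  soc: Investigations
  test_code: ALT
  direction: above
  kind: ratio
  boundaries: [1.0, 3.0, 5.0, 20.0]
- ae_term: Aspartate aminotransferase increased
  soc: Investigations
  test_code: AST
  direction: above
  kind: ratio
  boundaries: [1.0, 3.0, 5.0, 20.0]
- ae_term: Hyperglycemia
  soc: Metabolism and nutrition disorders
  test_code: GLU
  direction: above
  kind: absolute
  boundaries: [6.1, 8.9, 13.9, 27.8]
- ae_term: Hypocalcemia
  soc: Metabolism and nutrition disorders
  test_code: Ca
  direction: below
  kind: absolute
  boundaries: [2.1, 2.0, 1.75, 1.5]
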