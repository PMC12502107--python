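# Default urine metabolite peak library: 21 metabolite regions resolvable in
# 300 MHz 1H NMR urine spectra of the control (C), prediabetes (PD) and type 2
# diabetes (T2D) groups.  Chemical shifts are per-group line positions in ppm;
# a {lo, hi} entry is a multiplet envelope.  Relative intensities are unitless
# amplitudes encoding the qualitative group contrasts of the cohort:
#   - glucose appears only in T2D (anomeric doublet at 5.15 ppm + 3.20-3.80 m)
#   - glycine is absent in T2D and weaker in PD than in C
#   - urea decreases strictly C > PD > T2D
#   - acetate and citrate are elevated in T2D
#   - pyruvate, glycolate and hippurate are strongest in C
#   - creatinine dominates every spectrum (~10x the median amplitude)
#   - hypoxanthine, formate and trigonelline are the weakest signals
- code: 1
  name: Valine
  pathway: protein metabolism
  multiplicity: doublet
  intensity: {C: 1.0, PD: 1.0, T2D: 1.0}
  shifts:
    C: [{center: 1.02}]
    PD: [{center: 1.00}]
    T2D: [{center: 0.98}]
- code: 2
  name: OH Butyrate
  pathway: fatty acid metabolism
  multiplicity: doublet
  intensity: {C: 0.8, PD: 0.8, T2D: 1.0}
  shifts:
    C: [{center: 1.22}]
    PD: [{center: 1.23}]
    T2D: [{center: 1.22}]
- code: 3
  name: Lactate
  pathway: carbohydrate metabolism
  multiplicity: doublet
  intensity: {C: 1.2, PD: 1.2, T2D: 1.2}
  shifts:
    C: [{center: 1.37}]
    PD: [{center: 1.37}]
    T2D: [{center: 1.37}]
- code: 4
  name: Acetate
  pathway: fatty acid metabolism
  multiplicity: singlet
  intensity: {C: 0.8, PD: 0.8, T2D: 2.0}
  shifts:
    C: [{center: 1.92}]
    PD: [{center: 1.88}]
    T2D: [{center: 1.83}]
- code: 5
  name: Acetone
  pathway: fatty acid metabolism
  multiplicity: singlet
  intensity: {C: 0.0, PD: 0.5, T2D: 0.8}
  shifts:
    C: []
    PD: [{center: 2.13}]
    T2D: [{center: 2.13}]
- code: 6
  name: Acetoacetate
  pathway: fatty acid metabolism
  multiplicity: singlet
  intensity: {C: 0.6, PD: 0.6, T2D: 0.8}
  shifts:
    C: [{center: 2.29}]
    PD: [{center: 2.25}]
    T2D: [{center: 2.23}]
- code: 7
  name: Pyruvate
  pathway: carbohydrate metabolism
  multiplicity: singlet
  intensity: {C: 1.5, PD: 0.8, T2D: 0.6}
  shifts:
    C: [{center: 2.39}]
    PD: [{center: 2.31}]
    T2D: [{center: 2.34}]
- code: 8
  name: Succinate
  pathway: Krebs cycle metabolism
  multiplicity: singlet
  intensity: {C: 1.0, PD: 0.5, T2D: 1.0}
  shifts:
    C: [{center: 2.45}]
    PD: [{center: 2.41}]
    T2D: [{center: 2.43}]
- code: 9
  name: Citrate
  pathway: Krebs cycle metabolism
  multiplicity: doublet
  intensity: {C: 1.0, PD: 1.0, T2D: 2.5}
  shifts:
    C: [{lo: 2.56, hi: 2.62}]
    PD: [{lo: 2.50, hi: 2.60}]
    T2D: [{lo: 2.50, hi: 2.60}]
- code: 10
  name: Creatine
  pathway: protein metabolism
  multiplicity: singlet
  intensity: {C: 1.2, PD: 1.2, T2D: 1.2}
  shifts:
    C: [{center: 2.92}]
    PD: [{center: 2.82}]
    T2D: [{center: 2.92}]
- code: 11
  name: Creatinine
  pathway: protein metabolism
  multiplicity: singlet
  intensity: {C: 10.0, PD: 10.0, T2D: 10.0}
  shifts:
    C: [{center: 2.93}]
    PD: [{center: 2.95}]
    T2D: [{center: 2.94}]
- code: 12
  name: Malonate
  pathway: fatty acid metabolism
  multiplicity: singlet
  intensity: {C: 0.7, PD: 0.7, T2D: 0.7}
  shifts:
    C: [{center: 3.15}]
    PD: [{center: 3.16}]
    T2D: [{center: 3.11}]
- code: 13
  name: Glucose
  pathway: carbohydrate metabolism
  multiplicity: multiplet
  intensity: {C: 0.0, PD: 0.0, T2D: 6.0}
  shifts:
    C: []
    PD: []
    T2D:
      - {lo: 3.20, hi: 3.80, multiplicity: multiplet}
      - {center: 5.15, multiplicity: doublet}
- code: 14
  name: Glycine
  pathway: protein metabolism
  multiplicity: singlet
  intensity: {C: 1.5, PD: 1.0, T2D: 0.0}
  shifts:
    C: [{center: 3.45}]
    PD: [{center: 3.59}]
    T2D: []
- code: 15
  name: Glycolate
  pathway: carbohydrate metabolism
  multiplicity: singlet
  intensity: {C: 1.5, PD: 0.9, T2D: 0.8}
  shifts:
    C: [{center: 3.94}]
    PD: [{center: 3.84}]
    T2D: [{center: 3.87}]
- code: 16
  name: Hippurate
  pathway: hippuric acid
  multiplicity: multiplet
  intensity: {C: 1.2, PD: 0.7, T2D: 0.6}
  shifts:
    C: [{lo: 7.50, hi: 7.80}]
    PD:
      - {center: 3.87, multiplicity: doublet}
      - {lo: 7.40, hi: 7.80, multiplicity: multiplet}
    T2D: [{lo: 7.40, hi: 7.60}]
- code: 17
  name: Urea
  pathway: protein metabolism
  multiplicity: broad_singlet
  intensity: {C: 4.0, PD: 2.8, T2D: 1.6}
  shifts:
    C: [{center: 5.70}]
    PD: [{center: 5.70}]
    T2D: [{center: 5.70}]
- code: 18
  name: Phenylalanine
  pathway: protein metabolism
  multiplicity: multiplet
  intensity: {C: 0.6, PD: 0.6, T2D: 0.6}
  shifts:
    C: [{center: 7.28}]
    PD: [{lo: 7.10, hi: 7.30}]
    T2D: [{center: 7.25}]
- code: 19
  name: Hypoxanthine
  pathway: purines metabolism
  multiplicity: singlet
  intensity: {C: 0.3, PD: 0.3, T2D: 0.3}
  shifts:
    C: [{center: 8.19}]
    PD: [{center: 8.35}]
    T2D: [{center: 8.11}]
- code: 20
  name: Formate
  pathway: carboxylic acids
  multiplicity: singlet
  intensity: {C: 0.3, PD: 0.0, T2D: 0.3}
  shifts:
    C: [{center: 8.35}]
    PD: []
    T2D: [{center: 8.47}]
- code: 21
  name: Trigonelline
  pathway: alkaloids and derivatives
  multiplicity: multiplet
  intensity: {C: 0.35, PD: 0.3, T2D: 0.2}
  shifts:
    C:
      - {lo: 8.70, hi: 8.80, multiplicity: multiplet}
      - {center: 9.01, multiplicity: singlet}
    PD:
      - {lo: 8.70, hi: 8.80, multiplicity: multiplet}
      - {center: 9.05, multiplicity: singlet}
    T2D:
      - {lo: 8.60, hi: 8.70, multiplicity: multiplet}
      - {center: 9.02, multiplicity: singlet}
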