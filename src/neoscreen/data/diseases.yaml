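# Default disease registry: the 16 inherited metabolic diseases observed in a
# 309,102-newborn regional screening program, with per-disease prevalence
# (confirmed cases / newborns screened) and marker-analyte concentration
# statistics (mean, sd in μmol/L) for the affected class (homozygous or
# compound heterozygous) and the carrier class (heterozygous).
#
# Where a class was observed only once, the sd is a synthetic estimate set to
# 25% of the mean; where a class was not observed at all, both mean and sd are
# synthetic estimates placed between the observed class and the healthy
# baseline. Synthetic entries are marked below.
diseases:
  - abbr: PAHD
    genes: [PAH]
    markers: [{analyte: PHE, direction: high}]
    prevalence: 7.4409e-05        # 23 / 309,102
    affected: {PHE: {mean: 966.45, sd: 618.33}}
    carrier: {PHE: {mean: 270.15, sd: 256.90}}
  - abbr: BH4D
    genes: [PTS, GCH1, QDPR, PCBD1]
    markers: [{analyte: PHE, direction: high}]
    prevalence: 3.2352e-06        # 1 / 309,102
    affected: {PHE: {mean: 600.0, sd: 250.0}}    # synthetic: class unobserved
    carrier: {PHE: {mean: 196.22, sd: 49.06}}    # sd synthetic (single case)
  - abbr: PCD
    genes: [SLC22A5]
    markers: [{analyte: C0, direction: low}]
    prevalence: 9.7055e-05        # 30 / 309,102
    affected: {C0: {mean: 6.98, sd: 1.73}}
    carrier: {C0: {mean: 8.84, sd: 9.44}}
  - abbr: MMA
    genes: [MUT, MMAA, MMAB]
    markers: [{analyte: C3, direction: high}]
    prevalence: 1.9411e-05        # 6 / 309,102
    affected: {C3: {mean: 5.96, sd: 1.96}}
    carrier: {C3: {mean: 4.38, sd: 1.10}}        # sd synthetic (single case)
  - abbr: SCADD
    genes: [ACADS]
    markers: [{analyte: C4, direction: high}]
    prevalence: 2.5881e-05        # 8 / 309,102
    affected: {C4: {mean: 0.94, sd: 0.30}}
    carrier: {C4: {mean: 0.79, sd: 0.08}}
  - abbr: IBDD
    genes: [ACAD8]
    markers: [{analyte: C4, direction: high}]
    prevalence: 2.9116e-05        # 9 / 309,102
    affected: {C4: {mean: 1.10, sd: 0.25}}
    carrier: {C4: {mean: 0.70, sd: 0.18}}        # sd synthetic (single case)
  - abbr: 3-MCCD
    genes: [MCCC1, MCCC2]
    markers: [{analyte: C5OH, direction: high}]
    prevalence: 1.3264e-04        # 41 / 309,102
    affected: {C5OH: {mean: 4.35, sd: 4.44}}
    carrier: {C5OH: {mean: 1.52, sd: 1.99}}
  - abbr: 3-HMGD
    genes: [HMGCL]
    markers: [{analyte: C5OH, direction: high}]
    prevalence: 1.2941e-05        # 4 / 309,102
    affected: {C5OH: {mean: 2.50, sd: 1.00}}     # synthetic: class unobserved
    carrier: {C5OH: {mean: 0.87, sd: 0.33}}
  - abbr: NICCD
    genes: [SLC25A13]
    markers: [{analyte: CIT, direction: high}]
    prevalence: 9.7055e-06        # 3 / 309,102
    affected: {CIT: {mean: 38.01, sd: 22.54}}
    carrier: {CIT: {mean: 25.00, sd: 6.00}}      # synthetic: class unobserved
  - abbr: CIT-I
    genes: [ASS1]
    markers: [{analyte: CIT, direction: high}]
    prevalence: 2.5881e-05        # 8 / 309,102
    affected: {CIT: {mean: 120.82, sd: 20.39}}
    carrier: {CIT: {mean: 42.42, sd: 9.79}}
  - abbr: HMET
    genes: [MAT1A]
    markers: [{analyte: MET, direction: high}]
    prevalence: 2.9116e-05        # 9 / 309,102
    affected: {MET: {mean: 375.44, sd: 93.86}}   # sd synthetic (single case)
    carrier: {MET: {mean: 91.40, sd: 62.59}}
  - abbr: 2-MBDD
    genes: [ACADSB]
    markers: [{analyte: C5, direction: high}]
    prevalence: 1.2941e-05        # 4 / 309,102
    affected: {C5: {mean: 1.43, sd: 1.00}}
    carrier: {C5: {mean: 0.60, sd: 0.20}}        # synthetic: class unobserved
  - abbr: MCADD
    genes: [ACADM]
    markers: [{analyte: C6, direction: high}, {analyte: C8, direction: high}]
    prevalence: 9.7055e-06        # 3 / 309,102
    affected: {C6: {mean: 0.34, sd: 0.04}, C8: {mean: 1.69, sd: 0.57}}
    carrier: {C6: {mean: 0.18, sd: 0.05}, C8: {mean: 0.34, sd: 0.09}}  # sds synthetic
  - abbr: GA-II
    genes: [ETFA, ETFB, ETFDH]
    markers:
      - {analyte: C6, direction: high}
      - {analyte: C8, direction: high}
      - {analyte: C10, direction: high}
      - {analyte: C12, direction: high}
      - {analyte: C14, direction: high}
      - {analyte: "C14:1", direction: high}
      - {analyte: "C14:2", direction: high}
    prevalence: 3.2352e-06        # 1 / 309,102
    affected:                      # sds synthetic (single case)
      C6: {mean: 0.20, sd: 0.05}
      C8: {mean: 0.29, sd: 0.07}
      C10: {mean: 0.57, sd: 0.14}
      C12: {mean: 0.87, sd: 0.22}
      C14: {mean: 0.45, sd: 0.11}
      "C14:1": {mean: 0.41, sd: 0.10}
      "C14:2": {mean: 0.07, sd: 0.02}
    carrier:                       # synthetic: class unobserved
      C6: {mean: 0.12, sd: 0.03}
      C8: {mean: 0.18, sd: 0.05}
      C10: {mean: 0.30, sd: 0.08}
      C12: {mean: 0.45, sd: 0.11}
      C14: {mean: 0.30, sd: 0.08}
      "C14:1": {mean: 0.22, sd: 0.06}
      "C14:2": {mean: 0.05, sd: 0.01}
  - abbr: OTCD
    genes: [OTC]
    markers: [{analyte: CIT, direction: low}]
    prevalence: 3.2352e-06        # 1 / 309,102
    affected: {CIT: {mean: 2.47, sd: 0.62}}      # sd synthetic (single case)
    carrier: {CIT: {mean: 6.00, sd: 1.50}}       # synthetic: class unobserved
  - abbr: HARG
    genes: [ARG1]
    markers: [{analyte: ARG, direction: high}]
    prevalence: 3.2352e-06        # 1 / 309,102
    affected: {ARG: {mean: 150.0, sd: 40.0}}     # synthetic: class unobserved
    carrier: {ARG: {mean: 93.93, sd: 23.48}}     # sd synthetic (single case)
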