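# Default model parameter registry: every input of the screening cost model,
# transcribed from the programme/literature sources it was assembled from.
# Percent-valued entries are written as printed (units "%") and converted to
# fractions on load.  Distribution labels: Normal, Binomial (a proportion),
# Point (no uncertainty).
parameters:
  - name: women_tested_annual
    distribution: Normal
    mean: 723829
    low95: 583056
    high95: 869393
    units: women/year
    source: NHLS database

  - name: or_endocervical_broom_vs_spatula
    distribution: Normal
    mean: 1.57
    low95: 1.44
    high95: 1.70
    units: odds ratio
    source: Cochrane review of collection devices

  - name: or_detection_with_endocervical
    distribution: Normal
    mean: 1.89
    low95: 1.80
    high95: 1.98
    units: odds ratio
    source: Cochrane review of collection devices

  - name: or_detection_severe_with_endocervical
    distribution: Normal
    mean: 2.46
    low95: 1.75
    high95: 3.17
    units: odds ratio
    source: Cochrane review of collection devices

  - name: hiv_positive_fraction
    distribution: Binomial
    mean: 51
    low95: 40
    high95: 64
    units: "%"
    source: NHLS database

  - name: hiv_women_tested_annual
    distribution: Normal
    mean: 372340
    low95: 261707
    high95: 493988
    units: women/year
    source: Calculated

  - name: p_abnormal
    distribution: Binomial
    mean: 73
    low95: 71
    high95: 75
    units: "% of all smears"
    source: literature (HIV-infected cohort)

  - name: f_hsil
    distribution: Binomial
    mean: 31
    low95: 29
    high95: 33
    units: "% of all smears"
    source: literature (HIV-infected cohort)

  - name: f_lsil
    distribution: Binomial
    mean: 37
    low95: 35
    high95: 39
    units: "% of all smears"
    source: literature (HIV-infected cohort)

  - name: f_ascus
    distribution: Binomial
    mean: 5
    low95: 4
    high95: 6
    units: "% of all smears"
    source: literature (HIV-infected cohort)

  - name: p_endocervical_spatula
    distribution: Binomial
    mean: 53
    low95: 52
    high95: 54
    units: "% of all smears"
    source: NHLS database

  - name: p_endocervical_broom
    distribution: Binomial
    mean: 83
    low95: 76
    high95: 90
    units: "% of all smears"
    source: Calculated

  - name: sensitivity_with_endocervical
    distribution: Binomial
    mean: 76
    low95: 72
    high95: 80
    units: "%"
    source: literature (HIV-infected cohort)

  - name: sensitivity_no_endocervical
    distribution: Binomial
    mean: 40
    low95: 35
    high95: 45
    units: "%"
    source: Calculated

  - name: sensitivity_no_endocervical_hsil
    distribution: Binomial
    mean: 32
    low95: 23
    high95: 44
    units: "%"
    source: Calculated

  - name: p_repeat_done
    distribution: Binomial
    mean: 90
    low95: 85
    high95: 95
    units: "% of patients"
    source: Assumption

  - name: p_satisfactory
    distribution: Binomial
    mean: 98
    low95: 98
    high95: 99
    units: "% of all smears"
    source: NHLS database

  - name: specificity
    distribution: Binomial
    mean: 84
    low95: 81
    high95: 87
    units: "%"
    source: literature (HIV-infected cohort)

  - name: p_lost_to_followup
    distribution: Binomial
    mean: 8
    low95: 6
    high95: 10
    units: "% of patients"
    source: South African cohort study

  # --- Cost parameters (2014 USD) ---
  - name: usd_per_zar
    distribution: Point
    mean: 0.09
    units: USD/ZAR
    source: 2014 average exchange rate

  - name: cost_spatula
    distribution: Point
    mean: 0.02
    units: USD
    source: NHLS 2014 tender

  - name: cost_broom
    distribution: Point
    mean: 0.22
    units: USD
    source: Quotation 2014

  - name: cost_clinic_visit
    distribution: Point
    mean: 8.36
    units: USD
    source: WHO CHOICE, inflated to 2014

  - name: cost_lab_test
    distribution: Point
    mean: 4.89
    units: USD
    source: NHLS 2014 charge (device excluded)
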