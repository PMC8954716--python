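# Default risk-factor stratification rules for the categorical lifetime
# cardiovascular risk estimate.
#
# PROVENANCE: the seven factors and the four strata (optimal, not_optimal,
# elevated, major) follow the postpartum screening protocol; the numeric
# cut-points below are transcribed from the Framingham lifetime-risk
# literature (Lloyd-Jones et al. 2006 risk-factor burden strata, converted
# to SI units), with fasting-glucose strata adapted from ADA fasting-glucose
# cut-points because the original stratifies only on diagnosed diabetes.
# They are defaults, not the tested contract: edit this file to match a
# local protocol and the categorization machinery applies it unchanged.
#
# Numeric factors list half-open intervals [lower, upper): a value falls in
# the first interval whose upper bound exceeds it; "upper: null" means
# unbounded. "range" bounds the admissible measurement values. Boolean
# factors map false/true directly to strata.
version: "1.0"

factors:
  total_cholesterol:
    kind: numeric
    units: mmol/L
    range: [1.0, 20.0]
    intervals:
      - {stratum: optimal, upper: 4.65}       # < 180 mg/dL
      - {stratum: not_optimal, upper: 5.18}   # 180-199 mg/dL
      - {stratum: elevated, upper: 6.22}      # 200-239 mg/dL
      - {stratum: major, upper: null}         # >= 240 mg/dL

  systolic_bp:
    kind: numeric
    units: mmHg
    range: [60.0, 260.0]
    intervals:
      - {stratum: optimal, upper: 120.0}
      - {stratum: not_optimal, upper: 140.0}
      - {stratum: elevated, upper: 160.0}
      - {stratum: major, upper: null}

  diastolic_bp:
    kind: numeric
    units: mmHg
    range: [30.0, 160.0]
    intervals:
      - {stratum: optimal, upper: 80.0}
      - {stratum: not_optimal, upper: 90.0}
      - {stratum: elevated, upper: 100.0}
      - {stratum: major, upper: null}

  fasting_glucose:
    kind: numeric
    units: mmol/L
    range: [2.0, 30.0]
    intervals:
      - {stratum: optimal, upper: 5.6}        # < 100 mg/dL
      - {stratum: not_optimal, upper: 6.1}    # impaired fasting glucose
      - {stratum: elevated, upper: 7.0}
      - {stratum: major, upper: null}         # diabetic-range fasting glucose

  antihypertensive_use:
    kind: boolean
    when_false: optimal
    when_true: major       # treated hypertension counts as a major factor

  diabetes_diagnosis:
    kind: boolean
    when_false: optimal
    when_true: major

  current_smoker:
    kind: boolean
    when_false: optimal
    when_true: major
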