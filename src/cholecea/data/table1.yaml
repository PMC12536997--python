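# Literature-derived parameter table for the cholecystitis care-model
# comparison: conventional inpatient care vs acute day-surgery with remote
# patient monitoring.  All costs in 2023 AU$; horizon one year.
#
# 23 rows are independent axes of uncertainty ("variable": swept in one-way
# sensitivity analysis and sampled in probabilistic analysis):
#   5 branch probabilities + 5 utilities + 7 lengths of stay + 6 costs.
# The three "complement: true" probability rows balance their chance nodes
# (each node is proportionally renormalized at evaluation time); the acute
# mortality utility is fixed at 0.
#
# Note: printed standard deviations for branch probabilities are not on the
# probability scale (most exceed the feasible beta bound); they are retained
# for the record but probabilistic sampling derives probability SDs from the
# range column as (high - low)/4.  Utility and cost SDs are used as printed.

settings:
  wtp_bed_day: 4000.0
  wtp_qaly: 50000.0
  horizon_years: 1.0
  n_psa: 5000
  seed: 2023
  default_range_fraction: 0.5

parameters:
  # ---- chance-node branch probabilities (shared by both strategies) -------
  - name: p_lap
    strategy: shared
    role: probability
    base: 0.97
    low: 0.96
    high: 0.98
    sd: 0.18
    dist: beta
    node: root
    branch: lap
    complement: true
  - name: p_open_conversion
    strategy: shared
    role: probability
    base: 0.03
    low: 0.02
    high: 0.05
    sd: 0.25
    dist: beta
    node: root
    branch: open
  - name: p_lap_no_comp
    strategy: shared
    role: probability
    base: 0.94
    low: 0.90
    high: 0.98
    sd: 0.18
    dist: beta
    node: lap
    branch: lap_no_comp
    complement: true
  - name: p_lap_minor
    strategy: shared
    role: probability
    base: 0.06
    low: 0.04
    high: 0.09
    sd: 0.84
    dist: beta
    node: lap
    branch: lap_minor
  - name: p_open_no_comp
    strategy: shared
    role: probability
    base: 0.88
    low: 0.84
    high: 0.94
    sd: 0.18
    dist: beta
    node: open
    branch: open_no_comp
    complement: true
  - name: p_open_minor
    strategy: shared
    role: probability
    base: 0.08
    low: 0.04
    high: 0.16
    sd: 1.83
    dist: beta
    node: open
    branch: open_minor
  - name: p_open_major
    strategy: shared
    role: probability
    base: 0.01
    low: 0.00
    high: 0.06
    sd: 0.94
    dist: beta
    node: open
    branch: open_major
  - name: p_open_mortality
    strategy: shared
    role: probability
    base: 0.02
    low: 0.01
    high: 0.08
    sd: 1.15
    dist: beta
    node: open
    branch: open_mortality

  # ---- utilities (equal point estimates in both arms; sampled with
  # ---- independent per-arm uncertainty in probabilistic analysis) ----------
  - name: u_lap_no_comp
    strategy: shared
    role: utility
    base: 0.98
    low: 0.93
    high: 0.99
    sd: 0.02
    dist: beta
    applies: [both/lap_no_comp]
  - name: u_lap_minor
    strategy: shared
    role: utility
    base: 0.97
    low: 0.92
    high: 0.99
    sd: 0.02
    dist: beta
    applies: [both/lap_minor]
  - name: u_open_no_comp
    strategy: shared
    role: utility
    base: 0.87
    low: 0.82
    high: 0.92
    sd: 0.10
    dist: beta
    applies: [both/open_no_comp]
  - name: u_open_minor
    strategy: shared
    role: utility
    base: 0.85
    low: 0.78
    high: 0.90
    sd: 0.10
    dist: beta
    applies: [both/open_minor]
  - name: u_open_major
    strategy: shared
    role: utility
    base: 0.82
    low: 0.77
    high: 0.87
    sd: 0.10
    dist: beta
    applies: [both/open_major]
  - name: u_mortality
    strategy: shared
    role: utility
    base: 0.0
    low: 0.0
    high: 0.0
    dist: fixed
    applies: [both/open_mortality]

  # ---- inpatient bed days (PERT: min = low, mode = base, max = high) -------
  - name: los_conventional_lap_no_comp
    strategy: conventional
    role: bed_days
    base: 3.0
    low: 1.0
    high: 5.0
    dist: pert
    applies: [conventional/lap_no_comp]
  - name: los_day_surgery_lap_no_comp
    strategy: day_surgery
    role: bed_days
    base: 1.0
    low: 1.0
    high: 2.0
    dist: pert
    applies: [day_surgery/lap_no_comp]
  - name: los_lap_minor
    strategy: shared
    role: bed_days
    base: 5.0
    low: 2.0
    high: 8.0
    dist: pert
    applies: [both/lap_minor]
  - name: los_open_no_comp
    strategy: shared
    role: bed_days
    base: 4.0
    low: 2.0
    high: 8.0
    dist: pert
    applies: [both/open_no_comp]
  - name: los_open_minor
    strategy: shared
    role: bed_days
    base: 7.0
    low: 3.0
    high: 11.0
    dist: pert
    applies: [both/open_minor]
  - name: los_open_major
    strategy: shared
    role: bed_days
    base: 8.0
    low: 4.0
    high: 15.0
    dist: pert
    applies: [both/open_major]
  - name: los_open_mortality
    strategy: shared
    role: bed_days
    base: 8.0
    low: 1.0
    high: 15.0
    dist: pert
    applies: [both/open_mortality]

  # ---- health care costs (2023 AU$; gamma by moment matching) --------------
  # Inpatient laparoscopic procedure cost: conventional arm uncomplicated and
  # minor-complication cases, and day-surgery minor-complication cases (which
  # follow the usual inpatient protocol).
  - name: cost_lap_inpatient
    strategy: shared
    role: cost
    base: 11300.0
    low: 5650.0
    high: 16950.0
    sd: 5650.0
    dist: gamma
    applies: [conventional/lap_no_comp, conventional/lap_minor, day_surgery/lap_minor]
  # Same-day laparoscopic procedure cost: 11300 / 1.38 rounded to the dollar.
  - name: cost_same_day_procedure
    strategy: day_surgery
    role: cost
    base: 8188.0
    low: 4094.0
    high: 12282.0
    sd: 4094.0
    dist: gamma
    applies: [day_surgery/lap_no_comp]
  # Remote patient monitoring program, total per case over a 3-day episode:
  # 50% of the 11300 - 8188 = 3112 saving.  One-way range is the broad
  # AU$166-1666 per-day literature span expressed as a 3-day total.
  - name: cost_remote_monitoring
    strategy: day_surgery
    role: cost
    base: 1556.0
    low: 500.0
    high: 5000.0
    sd: 778.0
    dist: gamma
    applies: [day_surgery/lap_no_comp]
  - name: cost_open
    strategy: shared
    role: cost
    base: 17238.0
    low: 8619.0
    high: 25857.0
    sd: 8619.0
    dist: gamma
    applies: [both/open_no_comp, both/open_minor]
  - name: cost_open_major
    strategy: shared
    role: cost
    base: 43575.0
    low: 21787.0
    high: 65362.0
    sd: 21787.0
    dist: gamma
    applies: [both/open_major]
  - name: cost_open_mortality
    strategy: shared
    role: cost
    base: 38149.0
    low: 19074.0
    high: 57223.0
    sd: 19074.0
    dist: gamma
    applies: [both/open_mortality]
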