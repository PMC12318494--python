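# Default model inputs (2022 Australian dollars).
#
# Keys mirror the published input tables one-to-one so every value can be
# audited against its source row.  Probabilities and utilities with a
# published interval carry a triangular distribution {mode, low, high};
# plain scalars are fixed (no distribution) and are held constant in
# probabilistic sensitivity analysis.
#
# mRS = modified Rankin Scale: 0 no symptoms ... 5 severe disability, 6 dead.

short_term:
  # Probability stroke is accurately identified by EMS, by sex
  p_accurate_women: {mode: 0.29, low: 0.28, high: 0.30}
  p_accurate_men:   {mode: 0.35, low: 0.34, high: 0.36}
  # Probability of receiving thrombolysis within 60 minutes of hospital
  # arrival (fixed), and of an adverse event following thrombolysis (fixed)
  p_ivt_within_60min: 0.41
  p_adverse_event: 0.02
  # 90-day transition probability following thrombolysis, by mRS 0-6
  dist_ivt:
    - {mode: 0.32, low: 0.29, high: 0.36}
    - {mode: 0.24, low: 0.21, high: 0.27}
    - {mode: 0.16, low: 0.14, high: 0.19}
    - {mode: 0.11, low: 0.09, high: 0.14}
    - {mode: 0.08, low: 0.06, high: 0.10}
    - {mode: 0.03, low: 0.02, high: 0.04}
    - {mode: 0.06, low: 0.04, high: 0.07}
  # 90-day transition probability following an adverse event, by mRS 0-6
  # (fixed; published without a distribution)
  dist_adverse:
    - 0.00
    - 0.00
    - 0.09
    - 0.05
    - 0.05
    - 0.19
    - 0.62
  # 90-day transition probability following usual care, by mRS 0-6
  # (the published row sums to 0.99 through rounding; the engine
  # renormalises it proportionally)
  dist_usual_care:
    - {mode: 0.09, low: 0.07, high: 0.10}
    - {mode: 0.19, low: 0.17, high: 0.22}
    - {mode: 0.18, low: 0.16, high: 0.21}
    - {mode: 0.23, low: 0.20, high: 0.25}
    - {mode: 0.13, low: 0.11, high: 0.16}
    - {mode: 0.09, low: 0.06, high: 0.11}
    - {mode: 0.08, low: 0.06, high: 0.11}

markov:
  # Probability of recurrent stroke at 12 months, and in later years
  p_recurrent_year1: {mode: 0.10, low: 0.09, high: 0.12}
  p_recurrent_later: {mode: 0.02, low: 0.02, high: 0.02}
  # Case fatality applied following a recurrent stroke (fixed)
  p_death_given_recurrence: 0.0866
  # All-cause mortality at 12 months (total first-year death probability)
  p_allcause_mortality_12m: {mode: 0.12, low: 0.11, high: 0.12}
  discount_rate: 0.05
  horizon_years: 50
  cycle_length_years: 1.0
  start_age: 57.8
  start_age_sd: 10.9           # used only as the one-way sensitivity range
  indirect_cost_age_cutoff: 64 # indirect costs accrue while age < 64
  cohort_size: 5513

utilities:
  # Health state utility by mRS, first 12-month cycle
  year1:
    - {mode: 0.85, low: 0.76, high: 1.00}
    - {mode: 0.78, low: 0.67, high: 0.94}
    - {mode: 0.67, low: 0.53, high: 0.89}
    - {mode: 0.30, low: 0.12, high: 0.42}
    - {mode: 0.11, low: 0.02, high: 0.20}
    - {mode: 0.03, low: 0.00, high: 0.07}
  # Health state utility by mRS, all subsequent years
  later:
    - {mode: 0.85, low: 0.80, high: 1.00}
    - {mode: 0.80, low: 0.75, high: 0.90}
    - {mode: 0.70, low: 0.53, high: 0.75}
    - {mode: 0.51, low: 0.45, high: 0.65}
    - {mode: 0.30, low: 0.25, high: 0.55}
    - {mode: 0.15, low: 0.00, high: 0.32}

costs:
  # ASSUMPTION: the cost of thrombolysis delivery and of an incident
  # recurrent stroke are sourced from external studies and are not printed
  # in the input tables this file transcribes.  The values below are
  # placeholder assumptions (order-of-magnitude plausible for Australian
  # practice) and MUST be replaced for any real reimbursement analysis.
  # Both are varied +/- 50% in one-way sensitivity analysis.
  ivt_cost: 3500.0
  recurrent_stroke_cost: 20000.0
  # Cost inputs in year 1 by health state: medical, non-medical, indirect.
  # mRS 6 is the one-off cost of a death occurring in the first model year.
  # Some published base values lie outside their published interval; they
  # are transcribed as printed and flagged with a warning at load time.
  year1:
    - medical:     {base: 17375,  low: 6387,  high: 29799}
      non_medical: {base: 640,    low: 0,     high: 1281}
      indirect:    {base: 16553,  low: 0,     high: 36174}
    - medical:     {base: 24607,  low: 6860,  high: 44216}
      non_medical: {base: 2373,   low: 0,     high: 4746}
      indirect:    {base: 30786,  low: 0,     high: 56845}
    - medical:     {base: 45401,  low: 16670, high: 57816}
      non_medical: {base: 5883,   low: 157,   high: 7258}
      indirect:    {base: 53408,  low: 0,     high: 98187}
    - medical:     {base: 76626,  low: 49744, high: 77473}
      non_medical: {base: 34269,  low: 14756, high: 45917}
      indirect:    {base: 40849,  low: 0,     high: 98187}
    - medical:     {base: 96153,  low: 80229, high: 116819}
      non_medical: {base: 65806,  low: 32967, high: 83829}
      indirect:    {base: 48652,  low: 0,     high: 103355}
    - medical:     {base: 157399, low: 80295, high: 181813}
      non_medical: {base: 93225,  low: 52065, high: 78688}
      indirect:    {base: 45820,  low: 0,     high: 98187}
    - medical:     {base: 49037,  low: 4402,  high: 47593}
      non_medical: {base: 22177,  low: 0,     high: 2952}
      indirect:    {base: 44507,  low: 0,     high: 93019}
  # Cost inputs in all subsequent years by health state (mRS 0-5; the dead
  # state accrues nothing after year 1).  The mRS 0 indirect cell is
  # published as a dash, i.e. zero.
  later:
    - medical:     {base: 1573,  low: 0, high: 3146}
      non_medical: {base: 647,   low: 0, high: 1294}
      indirect:    {base: 0,     low: 0, high: 0}
    - medical:     {base: 1573,  low: 0, high: 3146}
      non_medical: {base: 647,   low: 0, high: 1294}
      indirect:    {base: 3368,  low: 0, high: 6737}
    - medical:     {base: 1993,  low: 0, high: 3986}
      non_medical: {base: 820,   low: 0, high: 1640}
      indirect:    {base: 22308, low: 0, high: 44617}
    - medical:     {base: 1993,  low: 0, high: 3986}
      non_medical: {base: 820,   low: 0, high: 1640}
      indirect:    {base: 31319, low: 0, high: 62639}
    - medical:     {base: 15410, low: 0, high: 30819}
      non_medical: {base: 6346,  low: 0, high: 12692}
      indirect:    {base: 48764, low: 0, high: 97303}
    - medical:     {base: 19713, low: 0, high: 39423}
      non_medical: {base: 8118,  low: 0, high: 16236}
      indirect:    {base: 45820, low: 0, high: 91640}

extrapolation:
  # Annual stroke hospitalisations among women aged 18-64 (financial year
  # 2020-21), the ischaemic fraction, and the national rate of thrombolysis
  # within 60 minutes of hospital arrival.
  annual_hospitalisations: 7471
  ischaemic_fraction: 0.83
  ivt60_rate_national: 0.29
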