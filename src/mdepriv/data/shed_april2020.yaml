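# Default codebook: four indicators of economic deprivation from the
# April 2020 SHED supplemental survey, equal weights 1/4.
# "deprived" lists the response codes that flag deprivation in each indicator.
indicators:
  - id: financial_condition
    question: >-
      Overall, which one of the following best describes how well you are
      managing financially these days?
    responses:
      1: Living comfortably
      2: Doing okay
      3: Just getting by
      4: Finding it difficult to get by
    deprived: [3, 4]
    weight: 1/4
  - id: employment_status
    question: >-
      Which one of the following best describes your employment status last
      week?
    responses:
      1: Employed
      2: Self-employed
      3: Not working, but being paid my normal wages
      4: Temporarily laid off or furloughed
      5: Not employed, but looking for a job
      6: Not employed and not looking for a job
    deprived: [4, 5]
    weight: 1/4
  - id: income_change
    question: >-
      How did your income last month (March) compare to your income two months
      ago (February)?
    responses:
      1: Much higher
      2: Somewhat higher
      3: About the same
      4: Somewhat lower
      5: Much lower
    deprived: [4, 5]
    weight: 1/4
  - id: pay_bills
    question: >-
      Which best describes your ability to pay all of your bills in full this
      month?
    responses:
      1: Able to pay all bills
      2: Cannot pay some bills
    deprived: [2]
    weight: 1/4
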