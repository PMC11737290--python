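# Default synthetic-cohort calibration.
#
# These values parameterise the generator at the scale observed in the source
# survey of older Swedish adults (meal protein means/SDs, anthropometry, meal
# timing, ~4.7 eating occasions/day). They are CALIBRATION inputs for
# generating realistic test data, not ground truth about any population.
# seed is intentionally absent: every run must supply one.

n_participants: 500
sex_ratio: 0.4693   # fraction male
n_days: 4

anthropometry:
  male:   {age_yr: [68.0, 6.0], height_m: [1.78, 0.065], bmi: [26.5, 3.3]}
  female: {age_yr: [68.0, 5.0], height_m: [1.65, 0.060], bmi: [25.5, 4.1]}

meal_times:   # mean clock hour, SD
  breakfast: [7.5, 0.9]
  lunch: [12.5, 0.9]
  dinner: [18.5, 1.1]

meal_protein:  # day-level mean, SD in grams; "other" is per snack occasion
  male:
    breakfast: [17.3, 7.5]
    lunch: [23.2, 12.4]
    dinner: [33.4, 15.0]
    other: [5.5, 4.5]
  female:
    breakfast: [14.0, 6.4]
    lunch: [20.0, 11.5]
    dinner: [27.4, 11.3]
    other: [4.8, 4.2]

protein_e_fraction:  # share of occasion energy from protein
  breakfast: 0.15
  lunch: 0.18
  dinner: 0.20
  other: 0.12

snack_rate: 2.4          # expected snacks/day
day_correlation: 0.0     # within-person day-to-day correlation of meal protein
missingness_rate: 0.03   # fraction with missing height or weight

education_probs: {primary: 0.21, secondary: 0.44, university: 0.35}
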