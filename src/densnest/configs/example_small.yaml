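# Compact end-to-end run: reduced term lists so every dredge stays small.
seed: 1
outdir: densnest_out
simulate:
  n_farms: 18
analyses:
  territories:
    data: counts
    response: n_territories
    family: poisson
    terms: ["log_len_Hedge", "log_len_Fence with vegetation", "year_2008", "landscape"]
    groups: [farm_id]
  egg_failure:
    data: egg
    response: egg_failed
    exposure: egg_exposure
    family: binomial-exposure
    terms: [nnd, clutch]
  nestling_failure:
    data: nestling
    response: nestling_failed
    exposure: nestling_exposure
    family: binomial-exposure
    terms: [nnd, concealment]
    groups: [farm_id]
  brood_reduction:
    data: brood
    response: brood_reduced
    exposure: nestling_exposure
    family: binomial-exposure
    terms: [concealment, day_found]
  fledglings:
    data: fledglings
    response: n_fledged
    family: ordinal-cumulative-logit
    terms: [nnd, concealment]
  provisioning:
    data: watches
    response: trips_per_hour
    family: gaussian
    terms: [nestling_age, brood_size, nnd, "nnd:brood_size"]
    locked: [nestling_age]
    groups: [nest_id]
  mass_gain:
    data: masses
    response: second_mass
    family: gaussian
    terms: [first_mass, hours_between, age_second, nnd]
    locked: [first_mass, hours_between, age_second]
    groups: [nest_id]
demography:
  organic:
    renest_rate: 1.66
    nest_success: 0.45
    young_per_successful_nest: 2.42
    adult_survival: 0.449
    juvenile_survival: 0.440
  conventional:
    renest_rate: 1.66
    nest_success: 0.45
    young_per_successful_nest: 3.19
    adult_survival: 0.449
    juvenile_survival: 0.440
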