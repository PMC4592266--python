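# Faithful template: the seven analyses with their full global-model term
# lists (density metric = NND; set ntnd_swap true for the sensitivity rerun).
# The all-subsets searches over these global models fit thousands of mixed
# models per analysis; expect a long run.  example_small.yaml is the quick
# variant.
seed: 1
outdir: densnest_out
ntnd_swap: false
simulate:
  n_farms: 18
analyses:
  territories:
    data: counts
    response: n_territories
    family: poisson
    terms: [
      "log_len_Hedge", "log_len_Hedge with 10-50% trees",
      "log_len_Hedge with >50% trees", "log_len_Fence with vegetation",
      "log_len_Gappy hedge", "log_len_Fence or wall",
      "year_2008", "cluster", "management", "landscape", "management:landscape",
    ]
    groups: [farm_id]
  egg_failure:
    data: egg
    response: egg_failed
    exposure: egg_exposure
    family: binomial-exposure
    terms: [day_found, "day_found^2", nest_height, concealment, management,
            nnd, clutch]
    groups: [farm_id]
  nestling_failure:
    data: nestling
    response: nestling_failed
    exposure: nestling_exposure
    family: binomial-exposure
    terms: [day_found, "day_found^2", nest_height, concealment, management,
            nnd, brood_initial, provisioning_rate, "provisioning_rate:concealment"]
    groups: [farm_id]
  brood_reduction:
    data: brood
    response: brood_reduced
    exposure: nestling_exposure
    family: binomial-exposure
    terms: [day_found, "day_found^2", nest_height, concealment, management,
            nnd, brood_initial, provisioning_rate, "provisioning_rate:concealment"]
    groups: [farm_id]
  fledglings:
    data: fledglings
    response: n_fledged
    family: ordinal-cumulative-logit
    terms: [day_found, "day_found^2", nest_height, concealment, management,
            nnd, brood_initial, provisioning_rate, "provisioning_rate:concealment"]
    groups: [farm_id]
  provisioning:
    data: watches
    response: trips_per_hour
    family: gaussian
    terms: [nestling_age, time_of_day, "time_of_day^2", temperature,
            "temperature^2", year_2008, management, nnd, invertebrates,
            brood_size, corvid_activity, "nnd:invertebrates",
            "nnd:corvid_activity", "nnd:brood_size", "nnd:management"]
    locked: [nestling_age]
    groups: [nest_id]
  mass_gain:
    data: masses
    response: second_mass
    family: gaussian
    terms: [first_mass, hours_between, age_second, time_of_day_second,
            temperature, "temperature^2", year_2008, nnd, invertebrates,
            brood_initial, corvid_abundance, provisioning_rate, management,
            "nnd:invertebrates", "nnd:corvid_abundance",
            "nnd:provisioning_rate", "nnd:brood_initial", "nnd:management"]
    locked: [first_mass, hours_between, age_second, time_of_day_second]
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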