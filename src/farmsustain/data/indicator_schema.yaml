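# Default sustainability indicator schema for smallholder dairy-buffalo
# survey data.  Each entry defines one indicator: the sustainability
# dimension it belongs to, the direction of its contribution (+1 higher is
# better, -1 lower is better), and its measurement scale.  The file is a
# plain schema users can copy and edit; nothing in the pipeline is
# hard-wired to these names.
#
# scale: one of binary (0/1), likert5 (1-5), frequency6 (1-6), continuous.
indicators:
  # --- economic -----------------------------------------------------------
  - {name: gross_production_value, dimension: economic, direction: 1, scale: continuous, units: "$/farm"}
  - {name: relative_profit, dimension: economic, direction: 1, scale: continuous, units: "$/LU"}
  - {name: absolute_profit, dimension: economic, direction: 1, scale: continuous, units: "$/farm"}
  - {name: livestock_units, dimension: economic, direction: -1, scale: continuous, units: "LU"}
  - {name: production_cost, dimension: economic, direction: -1, scale: continuous, units: "$/LU"}
  - {name: milk_yield, dimension: economic, direction: 1, scale: continuous, units: "L/head"}
  - {name: lactation_period, dimension: economic, direction: 1, scale: continuous, units: "days"}
  - {name: animal_deaths, dimension: economic, direction: -1, scale: continuous, units: "head/farm"}
  - {name: forage_crop_production, dimension: economic, direction: 1, scale: binary, units: ""}
  - {name: savings_status, dimension: economic, direction: 1, scale: binary, units: ""}
  - {name: indoor_feeding_period, dimension: economic, direction: -1, scale: continuous, units: "days"}
  - {name: record_keeping, dimension: economic, direction: 1, scale: binary, units: ""}
  - {name: pasture_feeding, dimension: economic, direction: 1, scale: binary, units: ""}
  # --- social -------------------------------------------------------------
  - {name: manager_age, dimension: social, direction: -1, scale: continuous, units: "years"}
  - {name: education_duration, dimension: social, direction: 1, scale: continuous, units: "years"}
  - {name: experience_years, dimension: social, direction: 1, scale: continuous, units: "years"}
  - {name: institution_communication, dimension: social, direction: 1, scale: frequency6, units: ""}
  - {name: extension_participation, dimension: social, direction: 1, scale: frequency6, units: ""}
  - {name: organization_membership, dimension: social, direction: 1, scale: binary, units: ""}
  - {name: social_life_satisfaction, dimension: social, direction: 1, scale: binary, units: ""}
  - {name: social_activities, dimension: social, direction: 1, scale: binary, units: ""}
  - {name: healthcare_access, dimension: social, direction: 1, scale: binary, units: ""}
  - {name: education_access, dimension: social, direction: 1, scale: binary, units: ""}
  - {name: transport_infrastructure, dimension: social, direction: 1, scale: binary, units: ""}
  - {name: veterinary_access, dimension: social, direction: 1, scale: binary, units: ""}
  - {name: farming_satisfaction, dimension: social, direction: 1, scale: likert5, units: ""}
  - {name: farming_interest, dimension: social, direction: 1, scale: likert5, units: ""}
  - {name: communication_tool_use, dimension: social, direction: 1, scale: frequency6, units: ""}
  - {name: family_opinion_importance, dimension: social, direction: 1, scale: likert5, units: ""}
  - {name: family_contribution_importance, dimension: social, direction: 1, scale: likert5, units: ""}
  - {name: family_continuation_willingness, dimension: social, direction: 1, scale: binary, units: ""}
  # --- environmental ------------------------------------------------------
  - {name: pasture_adequacy, dimension: environmental, direction: 1, scale: binary, units: ""}
  - {name: pasture_reduction, dimension: environmental, direction: -1, scale: binary, units: ""}
  - {name: pasture_quality, dimension: environmental, direction: 1, scale: binary, units: ""}
  - {name: pasture_pressure_on_herd, dimension: environmental, direction: -1, scale: binary, units: ""}
  - {name: biodiversity_importance, dimension: environmental, direction: 1, scale: binary, units: ""}
  - {name: eco_friendly_practices, dimension: environmental, direction: 1, scale: binary, units: ""}
  - {name: equipment_hygiene, dimension: environmental, direction: 1, scale: binary, units: ""}
  - {name: indoor_area_per_animal, dimension: environmental, direction: 1, scale: continuous, units: "m2"}
  - {name: manure_as_fuel, dimension: environmental, direction: -1, scale: binary, units: ""}
  - {name: shelter_adequacy, dimension: environmental, direction: 1, scale: likert5, units: ""}
  - {name: other_cattle_presence, dimension: environmental, direction: -1, scale: binary, units: ""}
  - {name: manure_pit, dimension: environmental, direction: 1, scale: binary, units: ""}
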