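# Scalar model parameters and index-set classifications for the 2018
# Madrid food-bank instance.  Units: masses kg, energy Mcal, money EUR.
params:
  shortfall_penalty: 1000.0            # EUR per kg of non-supplied nutrient
  energy_shortfall_penalty: 1000.0     # EUR per Mcal of non-supplied energy
  min_animal_to_vegetable_protein_ratio: 0.3333333333333333   # 1 g animal : 3 g vegetable
  min_fruit_veg_per_person: 2.0        # kg/week (286 g/day food-bank minimum)
  coverage_fraction: 0.5               # share of registered beneficiaries served weekly
  weeks_per_year: 52
  weeks_per_month: 4.333333333333333   # 52/12

food_groups:
  cereal:        {protein_class: vegetable, fruit_or_vegetable: false}
  vegetables:    {protein_class: vegetable, fruit_or_vegetable: true}
  fruit:         {protein_class: vegetable, fruit_or_vegetable: true}
  fats_and_oils: {protein_class: none,      fruit_or_vegetable: false}
  dairy:         {protein_class: animal,    fruit_or_vegetable: false}
  fish:          {protein_class: animal,    fruit_or_vegetable: false}
  meat:          {protein_class: animal,    fruit_or_vegetable: false}
  eggs:          {protein_class: animal,    fruit_or_vegetable: false}
  pulses:        {protein_class: vegetable, fruit_or_vegetable: false}

# caloric_density in kcal/g (Atwater factors); max_caloric_fraction are the
# AMDRS upper bounds on the share of energy each macronutrient may supply.
# counts_toward_mass: false marks fatty-acid fractions already contained in
# the lipids column, excluded from the 1000 g/kg mass normalization.
nutrients:
  carbohydrates: {caloric_density: 4.0, max_caloric_fraction: 0.65}
  fibre: {}
  lipids:        {caloric_density: 9.0, max_caloric_fraction: 0.35}
  omega6:        {counts_toward_mass: false}
  omega3:        {counts_toward_mass: false}
  protein:       {caloric_density: 4.0, max_caloric_fraction: 0.35}
  energy:        {is_energy: true}
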