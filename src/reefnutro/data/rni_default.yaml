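# Default recommended nutrient intakes (RNI) for adult women aged 18-65,
# per day, based on WHO/FAO reference values as used in the reef-fish
# nutrition literature. Units match trait-table concentrations per 100 g:
#   calcium, iron, zinc: mg; selenium, vitamin_a: ug; omega3: g.
# Replace this file (or pass --rni) to use a different reference population.
reference_population: adult women 18-65
intakes:
  calcium: 1000.0
  iron: 29.4
  zinc: 4.9
  selenium: 26.0
  vitamin_a: 500.0
  omega3: 1.1
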