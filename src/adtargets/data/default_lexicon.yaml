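# Default token lexicon for agent-name harmonization.
# Editable: extend these lists to suit a registry's vocabulary.
# Tokens are matched case-insensitively against whole words after
# surrounding punctuation is stripped.
salts:
  - hydrochloride
  - dihydrochloride
  - hydrobromide
  - hcl
  - hbr
  - sulfate
  - sulphate
  - bisulfate
  - sodium
  - potassium
  - calcium
  - magnesium
  - mesylate
  - besylate
  - tosylate
  - maleate
  - fumarate
  - tartrate
  - bitartrate
  - citrate
  - succinate
  - acetate
  - phosphate
  - oxalate
  - bromide
  - chloride
  - iodide
  - nitrate
  - lactate
  - gluconate
  - salicylate
  - stearate
formulations:
  - tablet
  - tablets
  - capsule
  - capsules
  - caplet
  - transdermal
  - patch
  - injection
  - injectable
  - oral
  - solution
  - suspension
  - syrup
  - cream
  - gel
  - ointment
  - spray
  - intravenous
  - subcutaneous
  - intranasal
  - nasal
units:
  - mg
  - mcg
  - ug
  - iu
  - ml
  - mg/ml
  - mg/kg
  - "%"
  - unit
  - units
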