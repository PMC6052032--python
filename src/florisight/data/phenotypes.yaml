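# Colour-vision phenotype registry: the six phenotypes of the study
# population.  All values overridable; omitted noise entries fall back to the
# package defaults (S-cone 430 nm; receptor densities S : L/M = 1 : 16, split
# equally between the two L/M classes of a trichromat; single-cell noise nu
# scaled so the most abundant class has Weber fraction 0.05; luminance Weber
# fraction 0.05).
phenotypes:
  "532":
    lm_lambda_max: [532]
  "543":
    lm_lambda_max: [543]
  "561":
    lm_lambda_max: [561]
  "532/543":
    lm_lambda_max: [532, 543]
  "532/561":
    lm_lambda_max: [532, 561]
  "543/561":
    lm_lambda_max: [543, 561]
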