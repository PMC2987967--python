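# Schema and value vocabularies for the synthetic clinical-trials project.
# Editable: tests pin expected query results against these lists.
root: Patient ID
root_rules:
  participant number:
    type: text
collections:
  Demographics:
    name:
      type: text
      values: [Alex Souza, Maria Prado, Jonas Reis, Ana Costa, Rui Gomes,
               Lena Marsh, Omar Diaz, Iris Wong, Tomas Iwu, Vera Lund]
    gender:
      type: options
      values: [female, male]
    date of birth:
      type: date
      start: 1930
      end: 1990
    smoking status:
      type: options
      values: [smoker, non-smoker, former smoker]
  Histology:
    tumor grade:
      type: options
      values: [G1 well differentiated, G2 moderately differentiated,
               G3 poorly differentiated]
    tumor type:
      type: options
      values: [adenocarcinoma, signet ring cell, squamous cell]
  Tissue:
    sample type:
      type: options
      values: [biopsy, resection, blood]
    collection date:
      type: date
      start: 2005
      end: 2009
    storage location:
      type: text
      values: [freezer A, freezer B, freezer C]
  Treatment:
    regimen:
      type: options
      values: [FOLFOX, ECF, DCF]
    cycles:
      type: number
      low: 1
      high: 8
    dose:
      type: number
      low: 50
      high: 200
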