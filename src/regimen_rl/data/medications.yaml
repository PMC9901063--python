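# Drug-name lexicon mapping free-text medication entries to the six action
# classes.  Names are matched case-insensitively after splitting compound
# entries on ';', ',', '+' and '/'.  Anything not listed here falls back to
# the supplements_other catch-all class.
chei:
  - donepezil
  - aricept
  - galantamine
  - razadyne
  - rivastigmine
  - exelon
memantine:
  - memantine
  - namenda
antihypertensive:
  - lisinopril
  - enalapril
  - ramipril
  - losartan
  - valsartan
  - amlodipine
  - nifedipine
  - metoprolol
  - atenolol
  - carvedilol
  - hydrochlorothiazide
  - chlorthalidone
  - furosemide
supplements_other:
  - vitamin d
  - vitamin e
  - vitamin b12
  - vitamin c
  - multivitamin
  - folic acid
  - calcium
  - fish oil
  - omega-3
  - ginkgo biloba
  - melatonin
  - aspirin
  - zolpidem
  - trazodone
  - sertraline
  - citalopram
  - escitalopram
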