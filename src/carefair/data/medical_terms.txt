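# medical term list v1 (starter list of common long-term-care diagnoses;
# edit or extend per deployment — counts are reported with this version)
dementia
alzheimer
diabetes
delirium
depression
anxiety
stroke
arthritis
osteoporosis
hypertension
hypotension
incontinence
cancer
copd
asthma
epilepsy
schizophrenia
psychosis
cataract
glaucoma
anaemia
pneumonia
sepsis
fracture
ulcer
eczema
shingles
gout
angina
thrombosis
hypothyroidism
hyperthyroidism
obesity
malnutrition
dysphagia
aphasia
neuropathy
parkinson
fibrillation
bronchitis
cellulitis
cirrhosis
emphysema
insomnia
migraine
osteoarthritis
psoriasis
sciatica
scoliosis
tinnitus
vertigo
hernia
jaundice
meningitis
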