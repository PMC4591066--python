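semantic_type	prime_category
Disease or Syndrome	Disease
Neoplastic Process	Disease
Mental or Behavioral Dysfunction	Disease
Pathologic Function	Disease
Congenital Abnormality	Disease
Acquired Abnormality	Disease
Anatomical Abnormality	Disease
Pharmacologic Substance	Drug
Clinical Drug	Drug
Antibiotic	Drug
Hazardous or Poisonous Substance	Drug
Organic Chemical	Drug
Therapeutic or Preventive Procedure	Medical Procedure
Health Care Activity	Medical Procedure
Tissue	Tissue
Biomedical or Dental Material	Biomedical
Biologically Active Substance	Biomedical
Intellectual Product	Biomedical
Biomedical Occupation or Discipline	Biomedical
Research Activity	Biomedical
Amino Acid Peptide or Protein	Biomedical
Enzyme	Biomedical
Immunologic Factor	Biomedical
Cell	Cell
Cell Component	Cell
Cell Function	Cell
Organism Function	Organism Function
Physiologic Function	Organism Function
Genetic Function	Organism Function
Molecular Function	Organism Function
Organ or Tissue Function	Organism Function
Finding	Finding
Body Part Organ or Organ Component	Body Part
Body Location or Region	Body Part
Body System	Body Part
Body Space or Junction	Body Part
Gene or Genome	Gene
Clinical Attribute	Clinical Attribute
Organism Attribute	Clinical Attribute
Patient or Disabled Group	Patient
Population Group	Patient
Human	Patient
Diagnostic Procedure	Diagnosis
Age Group	Age
Molecular Sequence	Molecular Sequence
Nucleotide Sequence	Molecular Sequence
Amino Acid Sequence	Molecular Sequence
Medical Device	Device
Research Device	Device
Drug Delivery Device	Device
Sign or Symptom	Symptom
Virus	Virus
Injury or Poisoning	Injury or Poisoning
Vitamin	Vitamin
Laboratory Procedure	Laboratory
Laboratory or Test Result	Laboratory
Food	Food
Temporal Concept	Temporal Concept
EDAM Data	EDAM Data/Format
EDAM Format	EDAM Data/Format
EDAM Operation	EDAM Operation
EDAM Topic	EDAM Topic
EDAM Identifier	EDAM Identifier
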